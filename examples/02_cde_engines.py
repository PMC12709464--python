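"""The three CDE engines and their exact agreement on saturated data.

On fully discrete data with saturated (cell-mean / cell-frequency)
nuisances fit without sample splitting, g-computation, Horvitz-Thompson
IPW and the doubly-robust estimator are algebraically identical.
"""

import numpy as np
import pandas as pd

import unmask

rng = np.random.default_rng(0)
n = 400
df = pd.DataFrame({
    "x": rng.integers(0, 2, n),
    "A": rng.integers(0, 2, n),
    "E": rng.integers(0, 2, n),
    "z": rng.integers(0, 2, n),
})
df["Y"] = (rng.normal(size=n) + 2.0 * df.A + 1.5 * df.E
           + 0.5 * df.z + 0.3 * df.x)
data = unmask.TrialDataset(df, unmask.TrialSchema(
    treatment="A", expectancy="E", outcome="Y",
    covariates=("x",), post_confounders=("z",),
))

spec = unmask.EstimandSpec(kind="CDE", a1=1, a0=0, e=1)
nuis = unmask.fit_nuisances(
    data, spec, unmask.LearnerSpec(family="saturated", n_folds=1), delta=0.0,
)
g = unmask.estimate_cde_gcomp(data, spec, nuisances=nuis, n_boot=0)
i = unmask.estimate_cde_ipw(data, spec, nuisances=nuis, hajek=False, n_boot=0)
d = unmask.estimate_cde_dr(data, spec, nuisances=nuis)

print(f"g-computation CDE:   {g.point:.12f}")
print(f"IPW (HT) CDE:        {i.point:.12f}")
print(f"doubly-robust CDE:   {d.point:.12f}")
print(f"max pairwise gap:    {max(abs(g.point-i.point), abs(g.point-d.point)):.2e}")
print()
print("All three target E[Y(1,e)-Y(0,e)] at e=1 (true direct effect 2.0);")
print("on saturated discrete data they coincide to floating-point error.")
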