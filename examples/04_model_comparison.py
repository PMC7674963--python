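"""Compare polynomial orders by AIC/BIC, homogeneous vs heterogeneous residuals.

Fits orders 1-3 in both residual modes on one simulated dataset and prints
the goodness-of-fit table: -2 logL never increases with order (the models
are nested), and lower AIC/BIC means a better fit-complexity trade-off.
"""

import rrtdm as r
from rrtdm.reml import REMLOptions

ds = r.generate_dataset(r.SimulationConfig(n_base_dams=80, true_order=3, seed=12))
prep = r.prepare(ds.records, ds.pedigree)
table = r.compare_models(
    prep, orders=(1, 2, 3), modes=("homogeneous", "heterogeneous"),
    opts=REMLOptions(tol=1e-4, max_iter=60),
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print(
    "\np counts the (co)variance parameters (3+3+1=7 for order 1 up to "
    "10+10+10=30 for order 3 with 10 class variances); n is records minus "
    "the rank of the fixed-effects design.  The data were generated with an "
    "order-3 curve, so the higher orders fit markedly better."
)
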