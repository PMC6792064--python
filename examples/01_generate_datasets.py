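"""Generate ground-truth datasets from the four bundled simulators.

Each model produces a feature matrix X and an outcome y by simulating a
population of mechanistically distinct samples.  The printed class
tables (or outcome spread, for the regression task) show that every
outcome is well represented — the precondition for a meaningful ML
benchmark.
"""
import pandas as pd

from simkern.models import get_model

for name in ("radiation", "flowering", "boolean", "netflow"):
    model = get_model(name)
    ds = model.generate(300, seed=1)
    print(f"\n{name}: N={ds.n_samples}, p={ds.n_features}, task={ds.task}")
    if ds.task == "classification":
        print(pd.Series(ds.y).value_counts(normalize=True).round(3))
    else:
        print(pd.Series(ds.y).describe().round(1))
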