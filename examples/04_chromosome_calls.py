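"""Chromosome-level calling: HMM mode vs decision tree vs SVM.

Runs a small accuracy grid (FF 2-16%, two read depths, all three fetal
conditions) with the fixed-FF RC model and the 7-state combined model.
The mode rule works at high fetal fraction; the supervised callers on the
decoded state frequencies recover most of the accuracy lost at low FF.
"""

import pandas as pd

from nipthmm import GridConfig, run_grid

cfg = GridConfig(
    ff_values=(0.02, 0.05, 0.10, 0.16),
    rd_values=(1000, 10000),
    model_kinds=("RC_fixed", "RCAR"),
    n_train=60,
    n_test=60,
    seed=11,
)
report = run_grid(cfg)

pd.set_option("display.width", 200)
table = report.band_table().dropna(how="all")
print("accuracy by fetal-fraction band (mean over conditions and depths):\n")
print(table.round(3))
print("\noverall (unweighted mean over all grid cells):")
for model in ("RC_fixed", "RCAR"):
    row = {m: round(report.overall(model, m), 3) for m in ("mode", "tree", "margin")}
    print(f"  {model}: {row}")
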