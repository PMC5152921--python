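#!/usr/bin/env python
"""Summarize dual-luciferase fold activation per construct.

Normalizes each well to its internal control, computes per-experiment
folds against the empty-vector reference, and reports mean +/- SEM over
experiments for every construct next to its planted fold.
"""

import argparse
from pathlib import Path

import pandas as pd

from vdrassay import fold_activation, io, summarize_fold

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/fold_summary.csv"))
args = parser.parse_args()

table = pd.read_csv(args.data_dir / "luciferase.csv")
truth = io.read_truth(args.data_dir / "luciferase_truth.json")
tab = table.assign(ratio=table.firefly / table.internal_control)
rows = []
for construct, grp in tab[tab.construct != "empty"].groupby("construct"):
    per_exp = [fold_activation(g.ratio, tab[(tab.construct == "empty")
                                            & (tab.experiment == exp)].ratio)
               for exp, g in grp.groupby("experiment")]
    mean, sem = summarize_fold(per_exp)
    rows.append({"construct": construct, "fold_mean": mean, "fold_sem": sem,
                 "n_experiments": len(per_exp),
                 "planted_fold": truth["true_folds"][construct]})
summary = pd.DataFrame(rows)
summary.to_csv(args.out, index=False, float_format="%.4g")
print(summary.to_string(index=False))
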