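#!/usr/bin/env python
"""Fit the one-site competition curve and convert IC50 to Ki.

Reads the curve written by 01_simulate.py, fits the one-site model by
nonlinear least squares, applies the Cheng-Prusoff correction with the
known hot-ligand Kd, and compares the recovered Ki with the planted one.
"""

import argparse
from pathlib import Path

from vdrassay import analyze_competition, io

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/binding_fit.json"))
args = parser.parse_args()

truth = io.read_truth(args.data_dir / "binding_curve_truth.json")
curve = io.read_curve(args.data_dir / "binding_curve.csv",
                      radioligand_conc_nM=truth["radioligand_conc_nM"])
fit = analyze_competition(curve, kd_nM=truth["true_kd_nM"])
io.write_json(fit, args.out)
print(f"IC50 = {fit.ic50_uM:.2f} uM (95% CI {fit.ic50_ci_uM[0]:.2f}-{fit.ic50_ci_uM[1]:.2f}), "
      f"Ki = {fit.ki_uM:.2f} uM vs planted {truth['true_ki_uM']} uM; "
      f"converged={fit.converged}")
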