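#!/usr/bin/env python
"""Generate all synthetic inputs for the downstream analyses.

Writes a competition-binding curve (true Ki 5 uM at 4 nM hot ligand), a
dual-luciferase well table (planted folds 3.6 for hVDR, 1.8 for zfVDRa),
and the 14-assay x 8-species response matrix with the planted two-group
partition carried by RXR/SRC1 assays, each with a JSON truth sidecar.
"""

import argparse
from pathlib import Path

from vdrassay import io, simulate_assay_matrix, simulate_competition_curve, simulate_luciferase

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
args = parser.parse_args()
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

curve, truth_b = simulate_competition_curve(seed=args.seed)
io.write_curve(curve, out / "binding_curve.csv")
io.write_truth(truth_b, out / "binding_curve_truth.json")
print(f"binding curve: {curve.n_conc} concentrations, true Ki {truth_b.true_ki_uM} uM "
      f"(IC50 {truth_b.true_ic50_uM} uM)")

table, truth_l = simulate_luciferase(seed=args.seed)
table.to_csv(out / "luciferase.csv", index=False, float_format="%.17g")
io.write_truth(truth_l, out / "luciferase_truth.json")
print(f"luciferase table: {len(table)} wells, planted folds {truth_l.true_folds}")

matrix, truth_m = simulate_assay_matrix(seed=args.seed)
io.write_matrix(matrix, out / "assay_matrix.tsv")
io.write_truth(truth_m, out / "assay_matrix_truth.json")
print(f"assay matrix: {matrix.values.shape[0]} assays x {matrix.values.shape[1]} species, "
      f"drivers {sorted(truth_m.driver_coregulators)}")
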