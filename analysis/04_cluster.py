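#!/usr/bin/env python
"""Cluster species by functional-assay profile.

Row-normalizes the assay matrix, computes Manhattan distances between
species, builds the complete-linkage dendrogram, and compares the k=2
cut with the planted partition.
"""

import argparse
import json
from pathlib import Path

from vdrassay import (complete_linkage, cut_partition, io, row_normalize,
                      species_distance, to_newick)

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--row-norm", default="zscore", choices=["zscore", "minmax", "none"])
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

matrix = io.read_matrix(args.data_dir / "assay_matrix.tsv")
truth = io.read_truth(args.data_dir / "assay_matrix_truth.json")
normalized = row_normalize(matrix, args.row_norm)
io.write_matrix(normalized, args.out_dir / "assay_matrix_normalized.tsv")
tree = complete_linkage(species_distance(normalized))
newick = to_newick(tree)
(args.out_dir / "species_dendrogram.nwk").write_text(newick + "\n")
partition = [sorted(g) for g in cut_partition(tree, 2)]
planted = [sorted(g) for g in truth["true_partition"]]
match = {frozenset(g) for g in partition} == {frozenset(g) for g in planted}
(args.out_dir / "partition.json").write_text(
    json.dumps({"partition": partition, "planted": planted, "match": match}, indent=1))
print("dendrogram:", newick)
print("k=2 partition:", partition)
print("matches planted partition:", match)
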