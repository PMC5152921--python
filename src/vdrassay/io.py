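"""Readers and writers for the pipeline's on-disk formats.

* assay matrix: TSV of values plus a JSON sidecar ``<stem>.annotations.json``
  holding per-assay class, ligand and coregulator flags;
* competition curves: long CSV with columns
  ``conc_M, lysate (vdr|empty), counts, experiment, replicate``;
* luciferase records: CSV with the reporter record schema;
* truth sidecars, binding fits and stability reports: JSON;
* dendrograms: Newick text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingFit, CompetitionCurve
from .reporter import COREGULATORS, AssayMatrix
from .stability import ClusterPattern, StabilityReport
from .synthetic import SimulationTruth

__all__ = [
    "write_matrix", "read_matrix",
    "write_curve", "read_curve",
    "write_truth", "read_truth",
    "write_json", "read_pattern", "write_pattern",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annotations.json") if path.suffix != ".tsv" \
        else path.with_suffix(".annotations.json")


def write_matrix(matrix: AssayMatrix, path) -> None:
    """TSV values + JSON annotation sidecar, full float precision."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", float_format="%.17g")
    ann = {
        assay: {
            "assay_class": row["assay_class"],
            "ligand": row["ligand"],
            "coregulators": [g for g in COREGULATORS if row[g] == 1],
        }
        for assay, row in matrix.annotations.iterrows()
    }
    _sidecar(path).write_text(json.dumps(ann, indent=1) + "\n")


def read_matrix(path) -> AssayMatrix:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing annotation sidecar: expected {sidecar}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate species column")
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        raise ValueError(f"{path}: duplicate assay row")
    ann_raw = json.loads(sidecar.read_text())
    missing = set(values.index) - set(ann_raw)
    if missing:
        raise ValueError(f"{sidecar}: no annotations for assays {sorted(missing)}")
    rows = []
    for assay in values.index:
        a = ann_raw[assay]
        row = {"assay_class": a["assay_class"], "ligand": a["ligand"]}
        row.update({g: int(g in a["coregulators"]) for g in COREGULATORS})
        rows.append(row)
    annotations = pd.DataFrame(rows, index=values.index)
    return AssayMatrix(values, annotations)


def write_curve(curve: CompetitionCurve, path) -> None:
    rows = []
    for c, totals, nonspecifics in zip(curve.competitor_conc, curve.total_counts,
                                       curve.nonspecific_counts):
        for lysate, reps in (("vdr", totals), ("empty", nonspecifics)):
            per_exp = max(1, len(reps) // curve.n_experiments)
            for i, count in enumerate(reps):
                rows.append({"conc_M": c, "lysate": lysate, "counts": count,
                             "experiment": i // per_exp + 1, "replicate": i % per_exp + 1})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_curve(path, radioligand_conc_nM: float = 4.0) -> CompetitionCurve:
    df = pd.read_csv(path)
    required = {"conc_M", "lysate", "counts", "experiment", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    bad = set(df["lysate"].unique()) - {"vdr", "empty"}
    if bad:
        raise ValueError(f"{path}: unknown lysate values {sorted(bad)}")
    conc = np.sort(df["conc_M"].unique())
    total, nonspecific = [], []
    for c in conc:
        sub = df[df["conc_M"] == c]
        total.append(list(sub.loc[sub["lysate"] == "vdr", "counts"]))
        nonspecific.append(list(sub.loc[sub["lysate"] == "empty", "counts"]))
    n_exp = int(df["experiment"].nunique())
    return CompetitionCurve(conc, total, nonspecific, radioligand_conc_nM, n_exp)


def write_truth(truth: SimulationTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj, path) -> None:
    if isinstance(obj, (BindingFit, StabilityReport)):
        obj = obj.to_dict()
    elif hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


def write_pattern(pattern: ClusterPattern, path) -> None:
    obj = {"partition": [sorted(g) for g in pattern.reference_partition],
           "subclusters": {k: sorted(v) for k, v in pattern.named_subclusters.items()}}
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_pattern(path) -> ClusterPattern:
    obj = json.loads(Path(path).read_text())
    return ClusterPattern.from_lists(obj["partition"], obj.get("subclusters"))
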