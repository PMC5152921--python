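"""Dual-luciferase normalization and assay-matrix assembly.

Firefly luminescence from the reporter construct is divided well-by-well
by the Renilla signal of a co-transfected internal control (pRL-CMV) to
remove transfection-efficiency variation. Fold activation (transient
transactivation, TT) or fold interaction (mammalian two-hybrid, M2H) is
the ratio of the mean normalized sample signal to the mean normalized
reference signal, where the reference depends on the question asked:

* TT without coregulators: empty expression vector;
* TT with coregulators: the same receptor without coregulators;
* M2H: the VP16-receptor prey without any bait construct.

All three are the same arithmetic (``fold_activation``) with a different
reference set, which the caller selects; record tables carry an explicit
``role`` column (``sample``/``reference``) so assembly is mechanical.
Experiment-level folds (not wells) are the unit of replication when
summarizing, giving the mean +/- SEM with n = number of experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COREGULATORS",
    "AssayDef",
    "AssayMatrix",
    "normalize_to_control",
    "fold_activation",
    "summarize_fold",
    "fold_table",
    "assemble_assay_matrix",
]

#: coregulator constructs tracked as presence/absence flags; the AF2-truncated
#: RXR is its own flag, not a form of "RXR present" -- losing the AF2 helix
#: changes it from a coactivation partner to a dominant-negative bait.
COREGULATORS = ("RXR_WT", "RXR_AF2", "SRC1", "GRIP1", "ACTR")

RECORD_COLUMNS = ("assay_id", "species", "role", "firefly", "internal_control",
                  "assay_class", "ligand", "coregulators", "experiment", "well")


@dataclass(frozen=True)
class AssayDef:
    """One assay row: a unique (class, ligand, coregulator-set) combination."""

    assay_id: str
    assay_class: str            # "TT" or "M2H"
    ligand: str                 # "LCA", "1,25D3", or "vehicle"
    coregulators: frozenset = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.coregulators) - set(COREGULATORS)
        if unknown:
            raise ValueError(f"unknown coregulators {sorted(unknown)}")

    def annotation_row(self) -> dict:
        row = {"assay_class": self.assay_class, "ligand": self.ligand}
        row.update({g: int(g in self.coregulators) for g in COREGULATORS})
        return row


class AssayMatrix:
    """Assays x species response matrix with per-assay annotations.

    ``values`` is a DataFrame (rows = assay ids, columns = species);
    ``annotations`` is row-aligned with columns ``assay_class``, ``ligand``
    and one binary flag per coregulator (the Pickett-plot structure).
    """

    def __init__(self, values: pd.DataFrame, annotations: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate assay ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate species names")
        if values.isna().any().any():
            raise ValueError("assay matrix contains missing cells")
        if not values.index.equals(annotations.index):
            raise ValueError("annotations must be row-aligned with values")
        missing = {"assay_class", "ligand", *COREGULATORS} - set(annotations.columns)
        if missing:
            raise ValueError(f"annotations missing columns {sorted(missing)}")
        flags = annotations[list(COREGULATORS)]
        if not flags.isin([0, 1]).all().all():
            raise ValueError("coregulator annotation flags must be binary")
        self.values = values.astype(float)
        self.annotations = annotations.copy()
        self.annotations[list(COREGULATORS)] = flags.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    def assays_with(self, coregulator: str) -> list[str]:
        """Assay ids annotated as containing the given coregulator."""
        if coregulator not in COREGULATORS:
            raise ValueError(f"unknown coregulator {coregulator!r}")
        mask = self.annotations[coregulator] == 1
        return list(self.values.index[mask])

    def take_rows(self, index: Sequence) -> "AssayMatrix":
        """Row subset/resample by positional indices (labels deduplicated)."""
        vals = self.values.iloc[list(index)].copy()
        anns = self.annotations.iloc[list(index)].copy()
        labels = pd.Index([f"{a}#{i}" for i, a in enumerate(vals.index)])
        vals.index = labels
        anns.index = labels
        return AssayMatrix(vals, anns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssayMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.annotations.equals(other.annotations)


def normalize_to_control(firefly, internal_control):
    """Firefly / internal-control ratio (elementwise; scalars or arrays)."""
    fire = np.asarray(firefly, dtype=float)
    ctrl = np.asarray(internal_control, dtype=float)
    if np.any(ctrl <= 0):
        raise ValueError("internal control luminescence must be > 0")
    out = fire / ctrl
    return float(out) if out.ndim == 0 else out


def fold_activation(sample_ratios: Sequence[float], reference_ratios: Sequence[float]) -> float:
    """mean(sample) / mean(reference) of control-normalized ratios."""
    sample = np.asarray(sample_ratios, dtype=float)
    reference = np.asarray(reference_ratios, dtype=float)
    if sample.size == 0 or reference.size == 0:
        raise ValueError("sample and reference ratio lists must be nonempty")
    ref_mean = reference.mean()
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    return float(sample.mean() / ref_mean)


def summarize_fold(per_experiment_folds: Sequence[float]) -> tuple[float, float]:
    """Mean and SEM over experiment-level folds (n = experiments)."""
    folds = np.asarray(per_experiment_folds, dtype=float)
    if folds.size < 2:
        raise ValueError("SEM requires >=2 experiment-level folds")
    return float(folds.mean()), float(stats.sem(folds, ddof=1))


def _require_columns(records: pd.DataFrame) -> None:
    missing = set(RECORD_COLUMNS[:-1]) - set(records.columns)
    if missing:
        raise ValueError(f"record table missing columns {sorted(missing)}")


def fold_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per (assay_id, species, experiment) fold from a role-labelled table.

    Each group's fold is mean(sample ratios)/mean(reference ratios) within
    that experiment, after well-level control normalization.
    """
    _require_columns(records)
    ratios = normalize_to_control(records["firefly"], records["internal_control"])
    df = records.assign(ratio=ratios)
    rows = []
    for (assay_id, species, experiment), grp in df.groupby(
            ["assay_id", "species", "experiment"], sort=True):
        sample = grp.loc[grp["role"] == "sample", "ratio"]
        reference = grp.loc[grp["role"] == "reference", "ratio"]
        if sample.empty or reference.empty:
            raise ValueError(
                f"assay {assay_id!r}, species {species!r}, experiment {experiment!r}: "
                "needs both sample and reference wells")
        rows.append({"assay_id": assay_id, "species": species, "experiment": experiment,
                     "fold": fold_activation(sample, reference)})
    return pd.DataFrame(rows)


def assemble_assay_matrix(records: pd.DataFrame, layout: Iterable[AssayDef], *,
                          species: Sequence[str] | None = None,
                          fill_value: float | None = None) -> AssayMatrix:
    """Build the annotated assays x species matrix from luciferase records.

    Each cell is the across-experiment mean fold for that (assay, species)
    combination (single-experiment cells use the lone fold). Missing cells
    are a hard error unless an explicit ``fill_value`` is given.
    """
    layout = list(layout)
    ids = [a.assay_id for a in layout]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate assay definitions in layout")
    folds = fold_table(records)
    if species is None:
        species = sorted(records["species"].unique())
    by_cell = folds.groupby(["assay_id", "species"])["fold"].mean()

    values = pd.DataFrame(index=pd.Index(ids, name="assay_id"),
                          columns=pd.Index(species, name="species"), dtype=float)
    for a in layout:
        for sp in species:
            try:
                values.loc[a.assay_id, sp] = by_cell[(a.assay_id, sp)]
            except KeyError:
                if fill_value is None:
                    raise ValueError(f"no records for assay {a.assay_id!r}, species {sp!r} "
                                     "and no fill_value set")
                values.loc[a.assay_id, sp] = fill_value
    annotations = pd.DataFrame([a.annotation_row() for a in layout],
                               index=values.index)
    return AssayMatrix(values, annotations)
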