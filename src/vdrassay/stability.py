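"""Bootstrap cluster-recapitulation analysis and coregulator importance.

The reference dendrogram clusters species by their functional-assay
profiles. To ask how stable that pattern is, assays (matrix rows) are
resampled with replacement B times; each resample is re-clustered and
scored against the reference pattern: does the k-cluster cut reproduce
the reference partition, and is each named subcluster still a clade?
Rates are fractions of the B draws. The phrase "resampling over the
assays according to presence/absence of each of the co-regulators" is
operationalized two ways, both exposed:

* ``stratified`` — resample within strata of identical coregulator
  presence/absence signatures, preserving stratum sizes;
* leave-one-coregulator-out — drop every assay containing coregulator g,
  bootstrap the remainder, and score the drop in recapitulation.

The leave-out drop defines importance: importance(g) = r_full - r_g, so
the more the pattern degrades without g's assays, the higher g's inferred
importance as a driver of the cluster pattern.

Resampling happens after row normalization; per-row transforms commute
with row resampling, and a ``renormalize_per_draw`` flag allows the
sensitivity variant. One seeded generator drives everything; draw order
is B blocks of row-index vectors, so runs are reproducible.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .cluster import (Dendrogram, complete_linkage, cut_partition, is_clade,
                      manhattan_condensed)
from .reporter import COREGULATORS, AssayMatrix

__all__ = [
    "ClusterPattern",
    "StabilityReport",
    "ImportanceReport",
    "recapitulation_check",
    "bootstrap_recapitulation",
    "coregulator_importance",
]


@dataclass(frozen=True)
class ClusterPattern:
    """Reference partition plus named subclusters to test as clades."""

    reference_partition: tuple[frozenset, ...]
    named_subclusters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_species: set = set()
        for group in self.reference_partition:
            if not group:
                raise ValueError("empty set in reference partition")
            if all_species & group:
                raise ValueError("reference partition sets must be disjoint")
            all_species |= group
        for name, sub in self.named_subclusters.items():
            if not set(sub) <= all_species:
                raise ValueError(f"subcluster {name!r} contains species outside the partition")

    @classmethod
    def from_lists(cls, partition, subclusters: dict | None = None) -> "ClusterPattern":
        return cls(tuple(frozenset(g) for g in partition),
                   {k: frozenset(v) for k, v in (subclusters or {}).items()})

    @property
    def species(self) -> frozenset:
        return frozenset().union(*self.reference_partition)

    @property
    def k(self) -> int:
        return len(self.reference_partition)


@dataclass
class StabilityReport:
    n_bootstrap: int
    seed: int
    mode: str
    overall_recapitulation: float
    partition_recapitulation: float
    subcluster_recapitulation: dict
    coregulator_importance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": "vdrassay.stability/1",
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "mode": self.mode,
            "overall_recapitulation": self.overall_recapitulation,
            "partition_recapitulation": self.partition_recapitulation,
            "subcluster_recapitulation": dict(self.subcluster_recapitulation),
            "coregulator_importance": dict(self.coregulator_importance),
        }


class ImportanceReport(Mapping):
    """Per-coregulator leave-out importance; maps coregulator -> drop."""

    def __init__(self, overall: dict, per_subcluster: dict, r_full: float,
                 leave_out_rates: dict, warnings_: tuple = ()):  # noqa: D401
        self.overall = dict(overall)
        self.per_subcluster = {k: dict(v) for k, v in per_subcluster.items()}
        self.r_full = r_full
        self.leave_out_rates = dict(leave_out_rates)
        self.warnings = tuple(warnings_)

    def __getitem__(self, key):
        return self.overall[key]

    def __iter__(self):
        return iter(self.overall)

    def __len__(self):
        return len(self.overall)

    def ranked(self) -> list[tuple[str, float]]:
        """Coregulators sorted by decreasing importance (name breaks ties)."""
        return sorted(self.overall.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {
            "importance": self.overall,
            "r_full": self.r_full,
            "leave_out_rates": self.leave_out_rates,
            "per_subcluster_drops": self.per_subcluster,
            "warnings": list(self.warnings),
        }


def recapitulation_check(tree: Dendrogram, pattern: ClusterPattern) -> tuple[bool, dict]:
    """Score one tree against the reference pattern.

    Returns (partition_match, {subcluster name: clade flag}). The
    partition match compares the k-cut of the tree with the reference
    partition as unordered sets.
    """
    if set(tree.leaves) != pattern.species:
        raise ValueError("tree leaves do not match the pattern's species")
    cut = set(cut_partition(tree, pattern.k))
    partition_match = cut == set(pattern.reference_partition)
    clade_flags = {name: is_clade(tree, sub) for name, sub in pattern.named_subclusters.items()}
    return partition_match, clade_flags


def _score_draw(values: np.ndarray, rows: np.ndarray, leaves: tuple,
                pattern: ClusterPattern, renormalize: bool) -> tuple[bool, dict]:
    sub = values[rows]
    if renormalize:
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = np.inf
        sub = (sub - mean) / sd
    dist = manhattan_condensed(sub)
    tree = complete_linkage(dist, leaves)
    return recapitulation_check(tree, pattern)


def _strata(matrix: AssayMatrix) -> list[np.ndarray]:
    flags = matrix.annotations[list(COREGULATORS)].to_numpy()
    signatures = [tuple(row) for row in flags]
    order: dict[tuple, list[int]] = {}
    for i, sig in enumerate(signatures):
        order.setdefault(sig, []).append(i)
    strata = [np.array(idx) for idx in order.values()]
    if any(len(s) == 0 for s in strata):
        raise ValueError("empty stratum")
    return strata


def bootstrap_recapitulation(matrix: AssayMatrix, pattern: ClusterPattern,
                             B: int, seed: int, mode: str = "plain", *,
                             renormalize_per_draw: bool = False) -> StabilityReport:
    """Bootstrap assays, re-cluster, and score pattern recovery.

    ``matrix`` must already be row-normalized. ``mode`` is ``plain``
    (free resampling of rows) or ``stratified`` (within coregulator-
    signature strata, preserving stratum sizes). The overall rate
    requires the partition match and every named subcluster jointly;
    per-criterion rates are reported alongside so either convention can
    be read out.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if set(matrix.species) != pattern.species:
        raise ValueError("pattern species do not match matrix species")
    if mode not in ("plain", "stratified"):
        raise ValueError(f"unknown mode {mode!r}")

    values = matrix.values.to_numpy()
    leaves = tuple(matrix.species)
    n_rows = values.shape[0]
    rng = np.random.default_rng(seed)
    strata = _strata(matrix) if mode == "stratified" else None

    part_hits = 0
    joint_hits = 0
    sub_hits = {name: 0 for name in pattern.named_subclusters}
    for _ in range(B):
        if mode == "plain":
            rows = rng.integers(0, n_rows, size=n_rows)
        else:
            rows = np.concatenate([s[rng.integers(0, len(s), size=len(s))] for s in strata])
        ok, clades = _score_draw(values, rows, leaves, pattern, renormalize_per_draw)
        part_hits += ok
        for name, flag in clades.items():
            sub_hits[name] += flag
        joint_hits += ok and all(clades.values())
    return StabilityReport(
        n_bootstrap=B, seed=seed, mode=mode,
        overall_recapitulation=joint_hits / B,
        partition_recapitulation=part_hits / B,
        subcluster_recapitulation={name: hits / B for name, hits in sub_hits.items()},
    )


def coregulator_importance(matrix: AssayMatrix, pattern: ClusterPattern,
                           B: int, seed: int, *,
                           coregulators=COREGULATORS) -> ImportanceReport:
    """Leave-one-coregulator-out importance.

    For each coregulator g, re-run the plain bootstrap on the matrix with
    g's assays removed and report importance(g) = r_full - r_g. A lower
    leave-out agreement means g's assays were carrying the pattern, hence
    higher importance. Coregulators absent from every assay get
    importance 0 with a warning. Per-subcluster drops are reported too.
    Child seeds are spawned deterministically from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(coregulators) + 1) % (2 ** 31)
    full = bootstrap_recapitulation(matrix, pattern, B, int(seeds[0]), mode="plain")
    overall: dict = {}
    per_sub: dict = {}
    rates: dict = {}
    warn: list = []
    for g, g_seed in zip(coregulators, seeds[1:]):
        with_g = matrix.assays_with(g)
        if not with_g:
            warnings.warn(f"coregulator {g} absent from every assay; importance set to 0")
            warn.append(g)
            overall[g] = 0.0
            per_sub[g] = {name: 0.0 for name in pattern.named_subclusters}
            rates[g] = full.overall_recapitulation
            continue
        keep = [i for i, a in enumerate(matrix.assays) if a not in set(with_g)]
        if len(keep) < 2:
            raise ValueError(f"removing {g} assays leaves <2 rows")
        reduced = matrix.take_rows(keep)
        rep = bootstrap_recapitulation(reduced, pattern, B, int(g_seed), mode="plain")
        overall[g] = full.overall_recapitulation - rep.overall_recapitulation
        per_sub[g] = {name: full.subcluster_recapitulation[name] - rep.subcluster_recapitulation[name]
                      for name in pattern.named_subclusters}
        rates[g] = rep.overall_recapitulation
    return ImportanceReport(overall, per_sub, full.overall_recapitulation, rates, tuple(warn))
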