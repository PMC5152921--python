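"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here with known truth, emulating
the statistical structure of the three assay families:

* an annotated assay-response matrix in which a chosen species partition
  is separated only in assays containing "driver" coregulators;
* one-site competition-binding curves with a known Ki (the generated
  IC50 inverts the Cheng-Prusoff relation, IC50 = Ki*(1 + L/Kd)),
  emitted as total and nonspecific count series with multiplicative
  (CV-parameterized) noise, matching the scale-dependent error of
  scintillation counting;
* dual-luciferase well tables with known fold effects and lognormal
  multiplicative noise on both firefly and control channels.

Each generator returns its dataset together with a SimulationTruth
recording the planted parameters and seed; a fixed seed regenerates
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import CompetitionCurve, one_site_competition
from .reporter import COREGULATORS, AssayDef, AssayMatrix

__all__ = [
    "SimulationTruth",
    "SPECIES_C1",
    "SPECIES_C2",
    "default_assay_layout",
    "simulate_assay_matrix",
    "simulate_competition_curve",
    "simulate_luciferase",
    "simulate_reporter_records",
    "default_concentration_series",
]

#: the two species clusters the default simulation plants: basal/beta
#: receptors (C1) versus the alpha paralogs grouped with human (C2)
SPECIES_C1 = ("lVDR", "bVDR", "sVDR", "zfVDRb", "mVDRb")
SPECIES_C2 = ("zfVDRa", "mVDRa", "hVDR")

#: default planted drivers: the cluster pattern is carried by assays that
#: contain RXR and SRC1, the coregulators the functional data single out
DEFAULT_DRIVERS = frozenset({"RXR_WT", "SRC1"})


@dataclass
class SimulationTruth:
    """Planted parameters emitted alongside every synthetic dataset."""

    seed: int
    true_partition: tuple = ()
    driver_coregulators: frozenset = frozenset()
    effect_size: float | None = None
    noise_sd: float | None = None
    true_ic50_uM: float | None = None
    true_ki_uM: float | None = None
    true_kd_nM: float | None = None
    radioligand_conc_nM: float | None = None
    true_folds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "true_partition": [sorted(g) for g in self.true_partition],
            "driver_coregulators": sorted(self.driver_coregulators),
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "true_ic50_uM": self.true_ic50_uM,
            "true_ki_uM": self.true_ki_uM,
            "true_kd_nM": self.true_kd_nM,
            "radioligand_conc_nM": self.radioligand_conc_nM,
            "true_folds": dict(self.true_folds),
        }


def default_assay_layout() -> list[AssayDef]:
    """The default 14-assay roster: 7 (class, coregulator-set) combos x 2 ligands.

    Mirrors the presence/absence combinations of the annotation grid:
    transactivation alone, with RXR (wild-type or AF2-truncated), and with
    RXR+SRC1; two-hybrid against each p160 bait. Every coregulator flag
    appears in at least one assay.
    """
    combos = [
        ("TT", frozenset()),
        ("TT", frozenset({"RXR_WT"})),
        ("TT", frozenset({"RXR_AF2"})),
        ("TT", frozenset({"RXR_WT", "SRC1"})),
        ("M2H", frozenset({"SRC1"})),
        ("M2H", frozenset({"GRIP1"})),
        ("M2H", frozenset({"ACTR"})),
    ]
    layout = []
    for ligand in ("LCA", "1,25D3"):
        for assay_class, coregs in combos:
            tag = "+".join(sorted(coregs)) if coregs else "none"
            layout.append(AssayDef(f"{assay_class}_{tag}_{ligand}", assay_class, ligand, coregs))
    return layout


def simulate_assay_matrix(species_groups: Sequence[Sequence[str]] | None = None,
                          assays: Sequence[AssayDef] | None = None,
                          effect_size: float = 6.0,
                          noise_sd: float = 1.0,
                          seed: int = 0,
                          drivers: frozenset = DEFAULT_DRIVERS,
                          baseline: float = 1.0) -> tuple[AssayMatrix, SimulationTruth]:
    """Plant a species partition carried by driver-coregulator assays.

    Assays annotated with any driver coregulator give group means offset
    by delta between consecutive groups, where delta = effect_size *
    noise_sd (noise-SD units); in the noiseless limit noise_sd = 0 the SD
    unit is taken as 1 so the separation is effect_size itself. Non-driver
    assays have identical group means. Gaussian noise of SD noise_sd is
    added to every cell.
    """
    if species_groups is None:
        species_groups = [SPECIES_C1, SPECIES_C2]
    if assays is None:
        assays = default_assay_layout()
    if len(species_groups) < 2:
        raise ValueError("need >=2 species groups")
    if len(assays) < 2:
        raise ValueError("need >=2 assays")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    species: list[str] = []
    for g in species_groups:
        if len(g) == 0:
            raise ValueError("empty species group")
        species.extend(g)
    if len(set(species)) != len(species):
        raise ValueError("duplicate species name across groups")
    if len(species) < 2:
        raise ValueError("need >=2 species in total")

    delta = effect_size * (noise_sd if noise_sd > 0 else 1.0)
    group_of = {sp: gi for gi, g in enumerate(species_groups) for sp in g}
    rng = np.random.default_rng(seed)
    rows = []
    for assay in assays:
        is_driver = bool(set(assay.coregulators) & drivers)
        mean = np.array([baseline + delta * group_of[sp] if is_driver else baseline
                         for sp in species])
        rows.append(mean + rng.normal(0.0, noise_sd, size=len(species)))
    values = pd.DataFrame(rows, index=pd.Index([a.assay_id for a in assays], name="assay_id"),
                          columns=pd.Index(species, name="species"))
    annotations = pd.DataFrame([a.annotation_row() for a in assays], index=values.index)
    truth = SimulationTruth(
        seed=seed,
        true_partition=tuple(frozenset(g) for g in species_groups),
        driver_coregulators=frozenset(drivers),
        effect_size=effect_size,
        noise_sd=noise_sd,
    )
    return AssayMatrix(values, annotations), truth


def default_concentration_series() -> np.ndarray:
    """Competitor series in molar: 0 plus half-decade steps over 10 nM - 1 mM."""
    series = [0.0] + list(np.concatenate(
        [[1.0 * 10.0 ** e, 3.16 * 10.0 ** e] for e in range(-8, -3)]) ) + [1e-3]
    return np.array(series)


def simulate_competition_curve(true_ki_uM: float = 5.0,
                               kd_nM: float = 1.0,
                               radioligand_conc_nM: float = 4.0,
                               concentrations: Sequence[float] | None = None,
                               top: float = 1000.0,
                               bottom: float = 0.0,
                               cv: float = 0.05,
                               replicates: int = 2,
                               n_experiments: int = 3,
                               seed: int = 0) -> tuple[CompetitionCurve, SimulationTruth]:
    """One-site competition curve with a known Ki.

    The generated IC50 inverts Cheng-Prusoff: IC50 = Ki*(1 + L/Kd). Per
    tube, expected specific binding follows the one-site model; the
    nonspecific floor is flat at 20% of the c=0 total (so NS = top/4).
    Total = specific + NS; both series get multiplicative Gaussian noise
    of coefficient of variation ``cv``. ``replicates`` tubes per
    concentration per experiment, pooled across ``n_experiments``.
    """
    if kd_nM <= 0:
        raise ValueError("kd must be > 0")
    if true_ki_uM <= 0:
        raise ValueError("true_ki must be > 0")
    if radioligand_conc_nM < 0:
        raise ValueError("radioligand concentration must be >= 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if replicates < 1 or n_experiments < 1:
        raise ValueError("replicates and n_experiments must be >= 1")
    conc = default_concentration_series() if concentrations is None else np.asarray(
        concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative competitor concentration")
    if 0.0 not in conc:
        raise ValueError("concentration series must include 0 (no-competitor tubes)")

    ic50_m = true_ki_uM * 1e-6 * (1.0 + radioligand_conc_nM / kd_nM)
    specific = one_site_competition(conc, top, bottom, ic50_m)
    ns_floor = 0.25 * top  # 20% of the c=0 total (top + floor)

    rng = np.random.default_rng(seed)
    n_rep = replicates * n_experiments
    noise_t = rng.normal(1.0, cv, size=(conc.size, n_rep)) if cv > 0 else np.ones((conc.size, n_rep))
    noise_n = rng.normal(1.0, cv, size=(conc.size, n_rep)) if cv > 0 else np.ones((conc.size, n_rep))
    total = (specific[:, None] + ns_floor) * noise_t
    nonspecific = ns_floor * noise_n
    curve = CompetitionCurve(
        competitor_conc=conc,
        total_counts=[list(row) for row in total],
        nonspecific_counts=[list(row) for row in nonspecific],
        radioligand_conc_nM=radioligand_conc_nM,
        n_experiments=n_experiments,
    )
    truth = SimulationTruth(
        seed=seed,
        true_ic50_uM=ic50_m * 1e6,
        true_ki_uM=true_ki_uM,
        true_kd_nM=kd_nM,
        radioligand_conc_nM=radioligand_conc_nM,
    )
    return curve, truth


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_luciferase(true_folds: Mapping[str, float] | None = None,
                        baseline: float = 100.0,
                        cv: float = 0.2,
                        wells: int = 4,
                        n_experiments: int = 3,
                        seed: int = 0,
                        reference: str = "empty") -> tuple[pd.DataFrame, SimulationTruth]:
    """Dual-luciferase well table with planted fold effects.

    Firefly = baseline * fold * eps, control = baseline * eps', with eps
    unit-mean lognormal of CV ``cv``. The ``reference`` construct (fold
    forced to 1 if absent from the map) serves as the normalization
    baseline. Default folds echo the LCA transactivation magnitudes the
    assay family produces (strong human response, weak zebrafish-alpha).
    """
    if true_folds is None:
        true_folds = {"empty": 1.0, "hVDR": 3.6, "zfVDRa": 1.8, "lVDR": 1.0}
    folds = dict(true_folds)
    folds.setdefault(reference, 1.0)
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if any(f <= 0 for f in folds.values()):
        raise ValueError("all folds must be > 0")
    if wells < 1:
        raise ValueError("wells must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for exp in range(1, n_experiments + 1):
        for construct, fold in folds.items():
            eps = _lognormal_factors(rng, cv, wells)
            eps_ctrl = _lognormal_factors(rng, cv, wells)
            for w in range(1, wells + 1):
                rows.append({
                    "construct": construct,
                    "experiment": exp,
                    "well": w,
                    "firefly": baseline * fold * eps[w - 1],
                    "internal_control": baseline * eps_ctrl[w - 1],
                    "role": "reference" if construct == reference else "sample",
                })
    table = pd.DataFrame(rows)
    truth = SimulationTruth(seed=seed, true_folds=dict(folds))
    return table, truth


def simulate_reporter_records(fold_matrix: pd.DataFrame,
                              layout: Sequence[AssayDef],
                              baseline: float = 100.0,
                              cv: float = 0.2,
                              wells: int = 4,
                              n_experiments: int = 3,
                              seed: int = 0) -> pd.DataFrame:
    """Well-level records for a full assay x species panel.

    For each (assay, species, experiment), emits ``wells`` sample wells
    with planted fold ``fold_matrix.loc[assay, species]`` and ``wells``
    reference wells at fold 1, all with lognormal noise. Assembling the
    result recovers the fold matrix (exactly at cv=0).
    """
    if (fold_matrix <= 0).any().any():
        raise ValueError("planted folds must be > 0")
    rng = np.random.default_rng(seed)
    by_id = {a.assay_id: a for a in layout}
    rows = []
    for assay_id in fold_matrix.index:
        a = by_id[assay_id]
        for species in fold_matrix.columns:
            fold = float(fold_matrix.loc[assay_id, species])
            for exp in range(1, n_experiments + 1):
                for role, f in (("sample", fold), ("reference", 1.0)):
                    eps = _lognormal_factors(rng, cv, wells)
                    eps_ctrl = _lognormal_factors(rng, cv, wells)
                    for w in range(1, wells + 1):
                        rows.append({
                            "assay_id": assay_id, "species": species, "role": role,
                            "firefly": baseline * f * eps[w - 1],
                            "internal_control": baseline * eps_ctrl[w - 1],
                            "assay_class": a.assay_class, "ligand": a.ligand,
                            "coregulators": "+".join(sorted(a.coregulators)),
                            "experiment": exp, "well": w,
                        })
    return pd.DataFrame(rows)
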