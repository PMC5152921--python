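"""Competitive radioligand-binding analysis.

A fixed concentration ``L`` of radiolabelled hormone (here 4 nM
[3H]-1,25-dihydroxyvitamin D3) is incubated with receptor lysate and a
dilution series of an unlabelled competitor (lithocholic acid, 0-1 mM).
Specific binding is total binding minus nonspecific binding (empty-vector
lysate). The competitor concentration displacing half of specific binding
(IC50) is estimated by nonlinear regression of a one-site competition
model, and converted to the competitor's inhibition constant Ki with the
Cheng-Prusoff correction for radioligand occupancy::

    Ki = IC50 / (1 + L / Kd)

Kd, the radioligand's dissociation constant for the receptor, is an
external per-receptor input and is never fitted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit

__all__ = [
    "CompetitionCurve",
    "BindingFit",
    "specific_binding",
    "fit_competition",
    "cheng_prusoff",
    "analyze_competition",
]

#: multiplicative factors to molar for the unit strings accepted below
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def _to_molar(value: float, unit: str) -> float:
    try:
        return value * _UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")


@dataclass
class CompetitionCurve:
    """One competition-binding experiment (possibly pooling replicates).

    Parameters
    ----------
    competitor_conc
        Cold-competitor concentrations in molar, ascending and unique;
        may include 0 (no-competitor tubes, which pin the top plateau).
    total_counts, nonspecific_counts
        Per-concentration lists of replicate scintillation counts from the
        receptor lysate and the empty-vector lysate respectively.
    radioligand_conc_nM
        The fixed hot-ligand concentration L, in nM.
    n_experiments
        Number of independent experiments pooled into the replicate lists.
    """

    competitor_conc: Sequence[float]
    total_counts: Sequence[Sequence[float]]
    nonspecific_counts: Sequence[Sequence[float]]
    radioligand_conc_nM: float = 4.0
    n_experiments: int = 1

    def __post_init__(self) -> None:
        conc = np.asarray(self.competitor_conc, dtype=float)
        if conc.ndim != 1 or conc.size == 0:
            raise ValueError("competitor_conc must be a nonempty 1-D sequence")
        if np.any(conc < 0):
            raise ValueError("competitor concentrations must be nonnegative")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("competitor concentrations must be ascending and unique")
        if len(self.total_counts) != conc.size or len(self.nonspecific_counts) != conc.size:
            raise ValueError("total/nonspecific replicate lists must match the concentration grid")
        for reps in (*self.total_counts, *self.nonspecific_counts):
            if len(reps) < 1:
                raise ValueError("every concentration needs >=1 total and >=1 nonspecific replicate")
        self.competitor_conc = conc

    @property
    def n_conc(self) -> int:
        return len(self.competitor_conc)


@dataclass
class BindingFit:
    """Result of a one-site competition fit plus the Cheng-Prusoff Ki."""

    ic50_uM: float
    top: float
    bottom: float
    ic50_ci_uM: tuple[float, float]
    converged: bool
    residual_sse: float
    kd_nM: float | None = None
    ki_uM: float | None = None
    radioligand_conc_nM: float | None = None
    per_experiment_ic50_uM: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ic50_uM": self.ic50_uM,
            "ki_uM": self.ki_uM,
            "kd_nM": self.kd_nM,
            "radioligand_conc_nM": self.radioligand_conc_nM,
            "top": self.top,
            "bottom": self.bottom,
            "ic50_ci_uM": list(self.ic50_ci_uM),
            "converged": self.converged,
            "residual_sse": self.residual_sse,
            "per_experiment_ic50_uM": self.per_experiment_ic50_uM,
        }


def specific_binding(total: Sequence[Sequence[float]],
                     nonspecific: Sequence[Sequence[float]]) -> np.ndarray:
    """Per-concentration specific binding: mean(total) - mean(nonspecific).

    Negative values are retained, not clamped -- at high competitor
    concentrations noise can push the empty-vector mean above the
    receptor-lysate mean and clamping would bias the bottom plateau.
    """
    if len(total) != len(nonspecific):
        raise ValueError("total and nonspecific must share the concentration grid")
    return np.array([np.mean(t) for t in total]) - np.array([np.mean(n) for n in nonspecific])


def one_site_competition(conc: np.ndarray, top: float, bottom: float, ic50: float) -> np.ndarray:
    """S(c) = bottom + (top - bottom) / (1 + c/IC50), Hill slope fixed at -1."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + conc / ic50)


def fit_competition(curve: CompetitionCurve) -> BindingFit:
    """Least-squares one-site competition fit of a pooled curve.

    All replicate points are fitted jointly (not mean-of-fits). Each total
    replicate is converted to a specific-binding point by subtracting the
    mean nonspecific count at its concentration. IC50 is optimized on a
    log10 scale (the design is log-spaced; c=0 tubes are handled in linear
    space and constrain the top plateau). Returns IC50 in uM with an
    asymptotic 95% confidence interval; ``converged`` reflects the
    optimizer's own status, and non-convergence is flagged, not raised.
    """
    conc = np.asarray(curve.competitor_conc, dtype=float)
    nonzero = conc[conc > 0]
    if nonzero.size < 4:
        raise ValueError("need >=4 distinct nonzero competitor concentrations")
    if nonzero.max() / nonzero.min() < 100:
        raise ValueError("nonzero concentrations must span >=2 decades")

    ns_mean = np.array([np.mean(n) for n in curve.nonspecific_counts])
    xs, ys = [], []
    for c, reps, ns in zip(conc, curve.total_counts, ns_mean):
        for t in reps:
            xs.append(c)
            ys.append(t - ns)
    x = np.array(xs)
    y = np.array(ys)
    if np.allclose(y, y[0]):
        raise ValueError("degenerate curve: all specific-binding responses equal")

    params = lmfit.Parameters()
    params.add("top", value=float(y.max()))
    params.add("bottom", value=float(y.min()))
    # initial IC50: geometric mean of the nonzero concentration range
    params.add("log_ic50", value=float(np.log10(math.sqrt(nonzero.min() * nonzero.max()))))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return one_site_competition(x, p["top"].value, p["bottom"].value,
                                    10.0 ** p["log_ic50"].value) - y

    result = lmfit.minimize(residual, params, method="leastsq", xtol=1e-8, ftol=1e-8)
    p = result.params
    log_ic50 = p["log_ic50"].value
    ic50_m = 10.0 ** log_ic50
    stderr = p["log_ic50"].stderr
    if stderr is not None and np.isfinite(stderr):
        ci = (10.0 ** (log_ic50 - 1.96 * stderr) * 1e6, 10.0 ** (log_ic50 + 1.96 * stderr) * 1e6)
    else:
        ci = (float("nan"), float("nan"))
    return BindingFit(
        ic50_uM=ic50_m * 1e6,
        top=p["top"].value,
        bottom=p["bottom"].value,
        ic50_ci_uM=ci,
        converged=bool(result.success),
        residual_sse=float(np.sum(result.residual ** 2)),
        radioligand_conc_nM=curve.radioligand_conc_nM,
    )


def cheng_prusoff(ic50: float, radioligand_conc: float, kd: float, *,
                  ic50_unit: str = "uM", l_unit: str = "nM", kd_unit: str = "nM") -> float:
    """Cheng-Prusoff conversion Ki = IC50 / (1 + L/Kd), returned in uM.

    Units are reconciled internally to molar, so the result is invariant
    under any consistent re-expression of the inputs. ``radioligand_conc``
    may be 0 (then Ki == IC50); ``kd`` must be positive.
    """
    kd_m = _to_molar(kd, kd_unit)
    if kd_m <= 0:
        raise ValueError("kd must be > 0")
    ic50_m = _to_molar(ic50, ic50_unit)
    if ic50_m <= 0:
        raise ValueError("ic50 must be > 0")
    l_m = _to_molar(radioligand_conc, l_unit)
    if l_m < 0:
        raise ValueError("radioligand concentration must be >= 0")
    return ic50_m / (1.0 + l_m / kd_m) / 1e-6


def analyze_competition(curve: CompetitionCurve, kd_nM: float) -> BindingFit:
    """Fit a curve and attach the Cheng-Prusoff Ki for the given Kd (nM)."""
    fit = fit_competition(curve)
    fit.kd_nM = kd_nM
    fit.ki_uM = cheng_prusoff(fit.ic50_uM, curve.radioligand_conc_nM, kd_nM)
    return fit
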