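"""End-to-end orchestration: simulate -> fit/normalize -> cluster -> stability.

A single :class:`PipelineConfig` drives the run; every source of
randomness derives deterministically from its one top-level seed, so a
fixed config yields byte-identical artifacts. Each stage writes its own
artifact into the output directory and contributes to a single JSON
summary carrying a provenance block (config hash, seed, package version).
Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import analyze_competition
from .cluster import complete_linkage, cut_partition, row_normalize, species_distance, to_newick
from .io import (read_matrix, write_curve, write_json, write_matrix, write_pattern,
                 write_truth)
from .reporter import assemble_assay_matrix, fold_table, summarize_fold
from .stability import ClusterPattern, bootstrap_recapitulation, coregulator_importance
from .synthetic import (default_assay_layout, simulate_assay_matrix,
                        simulate_competition_curve, simulate_luciferase,
                        simulate_reporter_records)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # synthetic design
    effect_size: float = 6.0
    noise_sd: float = 1.0
    binding_true_ki_uM: float = 5.0
    binding_kd_nM: float = 1.0
    hot_conc_nM: float = 4.0
    binding_cv: float = 0.05
    luciferase_cv: float = 0.2
    # analysis choices
    row_norm: str = "zscore"
    distance: str = "manhattan"
    linkage: str = "complete"
    B: int = 1000
    mode: str = "plain"
    # optional external matrix instead of simulation
    matrix_path: str | None = None
    pattern: dict | None = None  # {"partition": [[...], [...]], "subclusters": {...}}

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.row_norm not in ("zscore", "minmax", "none"):
            raise ValueError(f"row_norm must be zscore|minmax|none, got {self.row_norm!r}")
        if self.distance != "manhattan" or self.linkage != "complete":
            raise ValueError("only manhattan distance with complete linkage is supported")
        if self.mode not in ("plain", "stratified"):
            raise ValueError(f"mode must be plain|stratified, got {self.mode!r}")
        if self.noise_sd < 0 or self.binding_cv < 0 or self.luciferase_cv < 0:
            raise ValueError("noise/cv parameters must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the JSON summary."""
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)
    summary: dict = {
        "provenance": {
            "package": "vdrassay",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": asdict(config),
        }
    }

    # --- binding: simulate a competition curve, fit IC50, convert to Ki
    try:
        curve, truth_b = simulate_competition_curve(
            true_ki_uM=config.binding_true_ki_uM, kd_nM=config.binding_kd_nM,
            radioligand_conc_nM=config.hot_conc_nM, cv=config.binding_cv, seed=seeds[0])
        write_curve(curve, out / "binding_curve.csv")
        write_truth(truth_b, out / "binding_truth.json")
        fit = analyze_competition(curve, kd_nM=config.binding_kd_nM)
        write_json(fit, out / "binding_fit.json")
        summary["binding"] = fit.to_dict()
        summary["binding"]["true_ki_uM"] = truth_b.true_ki_uM
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("binding", str(exc)) from exc

    # --- reporter: simulate luciferase wells and summarize fold activation
    try:
        table, truth_l = simulate_luciferase(cv=config.luciferase_cv, seed=seeds[1])
        table.to_csv(out / "luciferase.csv", index=False, float_format="%.17g")
        write_truth(truth_l, out / "luciferase_truth.json")
        folds = {}
        ratios = table["firefly"] / table["internal_control"]
        tab = table.assign(ratio=ratios)
        ref = tab[tab["role"] == "reference"]
        for construct, grp in tab[tab["role"] == "sample"].groupby("construct"):
            per_exp = []
            for exp, g in grp.groupby("experiment"):
                r = ref[ref["experiment"] == exp]
                per_exp.append(g["ratio"].mean() / r["ratio"].mean())
            mean, sem = summarize_fold(per_exp)
            folds[construct] = {"mean": mean, "sem": sem, "n": len(per_exp),
                                "true_fold": truth_l.true_folds[construct]}
        summary["reporter_folds"] = folds
        write_json(folds, out / "reporter_folds.json")
    except Exception as exc:
        raise PipelineError("reporter", str(exc)) from exc

    # --- matrix: simulate (or load) the annotated assay-response matrix
    try:
        if config.matrix_path:
            matrix = read_matrix(config.matrix_path)
            truth_m = None
        else:
            matrix, truth_m = simulate_assay_matrix(
                effect_size=config.effect_size, noise_sd=config.noise_sd, seed=seeds[2])
            write_truth(truth_m, out / "matrix_truth.json")
        write_matrix(matrix, out / "assay_matrix.tsv")
    except Exception as exc:
        raise PipelineError("matrix", str(exc)) from exc

    # --- clustering
    try:
        normalized = row_normalize(matrix, config.row_norm)
        write_matrix(normalized, out / "assay_matrix_normalized.tsv")
        dist = species_distance(normalized)
        tree = complete_linkage(dist)
        newick = to_newick(tree)
        (out / "species_dendrogram.nwk").write_text(newick + "\n")
        k = 2 if config.pattern is None else len(config.pattern["partition"])
        partition = [sorted(g) for g in cut_partition(tree, k)]
        summary["clustering"] = {"newick": newick, "k": k, "partition": partition,
                                 "row_norm": config.row_norm}
    except Exception as exc:
        raise PipelineError("clustering", str(exc)) from exc

    # --- stability: bootstrap recapitulation + coregulator importance
    try:
        if config.pattern is not None:
            pattern = ClusterPattern.from_lists(config.pattern["partition"],
                                                config.pattern.get("subclusters"))
        elif truth_m is not None:
            groups = [sorted(g) for g in truth_m.true_partition]
            pattern = ClusterPattern.from_lists(
                groups, {f"G{i + 1}": g for i, g in enumerate(groups)})
        else:
            groups = partition
            pattern = ClusterPattern.from_lists(
                groups, {f"G{i + 1}": g for i, g in enumerate(groups)})
        write_pattern(pattern, out / "pattern.json")
        report = bootstrap_recapitulation(normalized, pattern, config.B, seeds[3],
                                          mode=config.mode)
        importance = coregulator_importance(normalized, pattern, config.B, seeds[3])
        report.coregulator_importance = dict(importance)
        write_json(report, out / "stability_report.json")
        write_json(importance, out / "coregulator_importance.json")
        summary["stability"] = report.to_dict()
        summary["importance"] = importance.to_dict()
    except Exception as exc:
        raise PipelineError("stability", str(exc)) from exc

    write_json(summary, out / "summary.json")
    return summary
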