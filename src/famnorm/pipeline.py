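"""End-to-end comparison pipeline: load/simulate -> QC -> normalise ->
batch-correct -> evaluate, with a cross-method ranking report.

QC runs once; every normalisation branch starts from the same QC'd dataset
and is evaluated with and without ComBat. Branch failures are recorded
without affecting other branches, and the whole run is deterministic given
the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from famnorm.datatypes import GenotypeTable, KinshipMatrix, MethylDataset
from famnorm.metrics import MetricReport, compute_metrics, ibs_kinship
from famnorm.normalize import NORMALIZERS, combat_dataset, norm_swan
from famnorm.qc import QCReport, run_qc
from famnorm.simulate import SimulationConfig, SimulationTruth, simulate_dataset

DEFAULT_METHODS = ["qn", "stratified_qn", "swan", "bmiq", "noob", "dasen", "funnorm"]

#: metric -> direction; True means larger is better
RANKED_METRICS = {
    "pc1_anova_p_batch": True,
    "replicate_mad_mean": False,
    "dmrse": False,
    "cluster_batch_ari": False,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    genotypes_path: str | None = None
    kinship_path: str | None = None
    target_probe: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    with_combat: bool = True
    k_top: int = 1000
    # QC thresholds
    detection_p_threshold: float = 0.05
    detection_max_failed: int = 1
    min_beads: int = 3
    bead_fail_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one normalisation method is required")
        unknown = [m for m in self.methods if m not in NORMALIZERS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}; choose from {sorted(NORMALIZERS)}")


@dataclass
class ComparisonReport:
    reports: dict[str, MetricReport]
    ranking: pd.DataFrame | None
    qc: QCReport
    failed: dict[str, str] = field(default_factory=dict)
    config_snapshot: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "branches": {label: r.to_dict() for label, r in self.reports.items()},
            "failed": dict(self.failed),
            "qc": self.qc.to_dict(),
            "ranking": None if self.ranking is None else self.ranking.to_dict(orient="index"),
            "config": self.config_snapshot,
        }


def rank_methods(reports: dict[str, MetricReport]) -> pd.DataFrame:
    """Per-metric branch ranking with the stated directions (rank 1 = best).

    Ties receive average ranks; the summary column is the mean rank over the
    four headline metrics. meQTL preservation and lambda are reported
    alongside but not ranked.
    """
    if len(reports) < 2:
        raise ValueError("ranking needs at least 2 branches")
    labels = list(reports)
    values = {m: [] for m in RANKED_METRICS}
    for label in labels:
        d = reports[label].to_dict()
        for m in RANKED_METRICS:
            v = d.get(m)
            values[m].append(np.nan if v is None else float(v))
    out = pd.DataFrame(index=labels)
    for m, larger_better in RANKED_METRICS.items():
        col = np.asarray(values[m], dtype=float)
        signed = -col if larger_better else col
        ranks = np.full(len(col), np.nan)
        ok = ~np.isnan(signed)
        if ok.sum():
            ranks[ok] = rankdata(signed[ok], method="average")
        out[m] = col
        out[f"rank_{m}"] = ranks
    rank_cols = [f"rank_{m}" for m in RANKED_METRICS]
    out["mean_rank"] = out[rank_cols].mean(axis=1)
    out["meqtl_min_adjusted_p"] = [
        reports[lb].meqtl_min_adjusted_p for lb in labels
    ]
    out["ewas_lambda"] = [reports[lb].ewas_lambda for lb in labels]
    return out.sort_values("mean_rank")


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    if config.simulate:
        dataset, truth = simulate_dataset(config.simulation, seed=config.seed)
        genotypes: GenotypeTable | None = truth.genotypes
        # IBS kinship from genome-wide background SNPs (never from the test window)
        if truth.background_genotypes is not None:
            kinship: KinshipMatrix | None = ibs_kinship(truth.background_genotypes)
        else:
            kinship = truth.kinship
        target_probe = config.target_probe or truth.meqtl_probe
    else:
        from famnorm.io import load_dataset, read_genotypes, read_kinship

        if config.input_dir is None:
            raise ValueError("input_dir required when simulate is false")
        dataset = load_dataset(config.input_dir)
        genotypes = read_genotypes(config.genotypes_path) if config.genotypes_path else None
        if config.kinship_path:
            kinship = read_kinship(config.kinship_path)
        elif genotypes is not None:
            kinship = ibs_kinship(genotypes)
        else:
            kinship = None
        target_probe = config.target_probe

    qc_ds, qc_report = run_qc(
        dataset,
        p_threshold=config.detection_p_threshold,
        max_failed_samples=config.detection_max_failed,
        min_beads=config.min_beads,
        max_fail_fraction=config.bead_fail_fraction,
    )

    metric_kwargs = dict(
        k_top=config.k_top,
        meqtl_probe=target_probe,
        genotypes=genotypes,
        kinship=kinship,
    )

    reports: dict[str, MetricReport] = {}
    failed: dict[str, str] = {}
    reports["raw"] = compute_metrics(qc_ds, "raw", **metric_kwargs)

    for method in config.methods:
        try:
            if method == "swan":
                normalised = norm_swan(qc_ds, seed=config.seed)
            else:
                normalised = NORMALIZERS[method](qc_ds)
            reports[method] = compute_metrics(normalised, method, **metric_kwargs)
        except Exception as exc:  # isolate branch failures
            failed[method] = f"{type(exc).__name__}: {exc}"
            if config.with_combat:
                failed[f"{method}+combat"] = "upstream normalisation failed"
            continue
        if config.with_combat:
            label = f"{method}+combat"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    corrected = combat_dataset(normalised)
                reports[label] = compute_metrics(corrected, label, **metric_kwargs)
            except Exception as exc:
                failed[label] = f"{type(exc).__name__}: {exc}"

    ranking = rank_methods(reports) if len(reports) >= 2 else None
    snapshot = {
        "seed": config.seed,
        "simulate": config.simulate,
        "methods": list(config.methods),
        "with_combat": config.with_combat,
        "k_top": config.k_top,
        "simulation": asdict(config.simulation) if config.simulate else None,
    }
    return ComparisonReport(
        reports=reports, ranking=ranking, qc=qc_report, failed=failed, config_snapshot=snapshot
    )


def write_report(report: ComparisonReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
    if report.ranking is not None:
        report.ranking.to_csv(out / "ranking.tsv", sep="\t", float_format="%.6g")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
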