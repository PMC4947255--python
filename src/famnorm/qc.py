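"""Probe- and sample-level quality control.

The probe filters follow the conventional 450k thresholds: a probe is
dropped when its detection p-value exceeds 0.05 in more than one sample, or
when its bead count is below 3 in at least 5 % of samples; sex-chromosome
probes are removed outright (X-inactivation dosage effects would otherwise
dominate) and never re-introduced. Sample QC flags arrays with a high mean
detection p-value but never drops them silently — the caller decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from famnorm.datatypes import SEX_CHROMOSOME_NAMES, MethylDataset


@dataclass
class QCReport:
    n_probes_removed_detection: int = 0
    n_probes_removed_beadcount: int = 0
    n_probes_removed_sex: int = 0
    samples_flagged: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_probes_removed_detection": self.n_probes_removed_detection,
            "n_probes_removed_beadcount": self.n_probes_removed_beadcount,
            "n_probes_removed_sex": self.n_probes_removed_sex,
            "samples_flagged": list(self.samples_flagged),
            "thresholds": dict(self.thresholds),
        }


def detection_filter(
    dataset: MethylDataset, p_threshold: float = 0.05, max_failed_samples: int = 1
) -> tuple[MethylDataset, int]:
    """Remove probes whose detection p exceeds the threshold in more than
    ``max_failed_samples`` samples (a single failing sample is tolerated)."""
    if dataset.detection_p is None:
        raise ValueError("detection_filter requires a detection_p matrix")
    failures = (dataset.detection_p.to_numpy() > p_threshold).sum(axis=1)
    keep = failures <= max_failed_samples
    removed = int((~keep).sum())
    out = dataset.subset_probes(dataset.probe_ids[keep]).with_provenance(
        f"detection_filter(p>{p_threshold} in >{max_failed_samples} samples): removed {removed}"
    )
    return out, removed


def beadcount_filter(
    dataset: MethylDataset, min_beads: int = 3, max_fail_fraction: float = 0.05
) -> tuple[MethylDataset, int]:
    """Remove probes with bead count < ``min_beads`` in at least
    ``max_fail_fraction`` of samples (boundary inclusive)."""
    if dataset.bead_count is None:
        raise ValueError("beadcount_filter requires a bead_count matrix")
    frac = (dataset.bead_count.to_numpy() < min_beads).mean(axis=1)
    keep = frac < max_fail_fraction
    removed = int((~keep).sum())
    out = dataset.subset_probes(dataset.probe_ids[keep]).with_provenance(
        f"beadcount_filter(<{min_beads} beads in >={max_fail_fraction:g} of samples): removed {removed}"
    )
    return out, removed


def remove_sex_chromosomes(dataset: MethylDataset) -> tuple[MethylDataset, int]:
    """Drop every probe on chrX/chrY (any naming convention in the name set)."""
    chroms = dataset.annotation.table["chromosome"].astype(str)
    on_sex = chroms.isin(SEX_CHROMOSOME_NAMES) | dataset.annotation.on_sex_chromosome
    removed = int(on_sex.sum())
    out = dataset.subset_probes(dataset.probe_ids[~on_sex.to_numpy()]).with_provenance(
        f"remove_sex_chromosomes: removed {removed}"
    )
    return out, removed


def sample_qc(dataset: MethylDataset, mean_detp_threshold: float = 0.05) -> list[str]:
    """Flag (never drop) samples whose mean detection p exceeds the threshold."""
    if dataset.detection_p is None:
        raise ValueError("sample_qc requires a detection_p matrix")
    means = dataset.detection_p.mean(axis=0)
    return [str(s) for s in means.index[means > mean_detp_threshold]]


def run_qc(
    dataset: MethylDataset,
    p_threshold: float = 0.05,
    max_failed_samples: int = 1,
    min_beads: int = 3,
    max_fail_fraction: float = 0.05,
    mean_detp_threshold: float = 0.05,
) -> tuple[MethylDataset, QCReport]:
    """Full probe QC in the fixed order detection -> bead count -> sex chromosomes."""
    flagged = sample_qc(dataset, mean_detp_threshold) if dataset.detection_p is not None else []
    ds = dataset
    n_det = 0
    if ds.detection_p is not None:
        ds, n_det = detection_filter(ds, p_threshold, max_failed_samples)
    n_bead = 0
    if ds.bead_count is not None:
        ds, n_bead = beadcount_filter(ds, min_beads, max_fail_fraction)
    ds, n_sex = remove_sex_chromosomes(ds)
    report = QCReport(
        n_probes_removed_detection=n_det,
        n_probes_removed_beadcount=n_bead,
        n_probes_removed_sex=n_sex,
        samples_flagged=flagged,
        thresholds={
            "p_threshold": p_threshold,
            "max_failed_samples": max_failed_samples,
            "min_beads": min_beads,
            "max_fail_fraction": max_fail_fraction,
            "mean_detp_threshold": mean_detp_threshold,
        },
    )
    return ds, report
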