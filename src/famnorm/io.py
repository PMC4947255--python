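"""Readers and writers for the package's plain-text dialects.

Matrices (signal, beta, detection-p, bead-count) are TSV with a leading
``probe_id`` column; the sample sheet is CSV; genotypes come from a VCF (GT
field) or a 0/1/2 TSV; kinship is a square TSV. A write -> load round trip
is lossless to well beyond 10 significant digits.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from famnorm.datatypes import (
    GenotypeTable,
    IntensityMatrix,
    KinshipMatrix,
    MethylDataset,
    ProbeAnnotation,
    SampleSheet,
)

_FLOAT_FMT = "%.12g"

MATRIX_FILES = {
    "meth": "meth.tsv",
    "unmeth": "unmeth.tsv",
    "oob_meth": "oob_meth.tsv",
    "oob_unmeth": "oob_unmeth.tsv",
    "beta": "beta.tsv",
    "detection_p": "detection_p.tsv",
    "bead_count": "bead_count.tsv",
}


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")


def read_annotation(path: str | os.PathLike) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    return ProbeAnnotation(table)


def write_annotation(annotation: ProbeAnnotation, path: str | os.PathLike) -> None:
    annotation.table.to_csv(path, sep="\t")


def read_samplesheet(path: str | os.PathLike) -> SampleSheet:
    table = pd.read_csv(path, dtype={"sample_id": str, "batch": str, "family_id": str})
    return SampleSheet(table)


def write_samplesheet(samples: SampleSheet, path: str | os.PathLike) -> None:
    out = samples.table.copy()
    out["replicate_group"] = out["replicate_group"].fillna("")
    out.to_csv(path)


def _check_alignment(df: pd.DataFrame, probes: pd.Index, samples: pd.Index, name: str) -> pd.DataFrame:
    missing_p = probes.difference(df.index)[:10].tolist()
    missing_s = samples.difference(df.columns)[:10].tolist()
    extra_p = df.index.difference(probes)[:10].tolist()
    extra_s = df.columns.difference(samples)[:10].tolist()
    if missing_p or missing_s or extra_p or extra_s:
        raise ValueError(
            f"{name}: probe/sample ids disagree with annotation and sample sheet "
            f"(missing probes: {missing_p}, missing samples: {missing_s}, "
            f"unexpected probes: {extra_p}, unexpected samples: {extra_s})"
        )
    return df.loc[probes, samples]


def load_dataset(directory: str | os.PathLike) -> MethylDataset:
    """Load a MethylDataset from a directory written by :func:`write_dataset`."""
    d = Path(directory)
    annotation = read_annotation(d / "annotation.tsv")
    samples = read_samplesheet(d / "samples.csv")
    probes = pd.Index(annotation.probe_ids)
    sample_ids = pd.Index(samples.sample_ids)

    beta = _check_alignment(read_matrix(d / "beta.tsv"), probes, sample_ids, "beta")

    def optional(name: str) -> pd.DataFrame | None:
        p = d / MATRIX_FILES[name]
        return read_matrix(p) if p.exists() else None

    intensities = None
    if (d / "meth.tsv").exists():
        meth = _check_alignment(read_matrix(d / "meth.tsv"), probes, sample_ids, "meth")
        unmeth = _check_alignment(read_matrix(d / "unmeth.tsv"), probes, sample_ids, "unmeth")
        oobm = optional("oob_meth")
        oobu = optional("oob_unmeth")
        controls = None
        if (d / "controls.tsv").exists():
            controls = pd.read_csv(d / "controls.tsv", sep="\t", index_col=[0, 1])
        intensities = IntensityMatrix(
            meth=meth, unmeth=unmeth, oob_meth=oobm, oob_unmeth=oobu, controls=controls
        )

    detection_p = optional("detection_p")
    if detection_p is not None:
        detection_p = _check_alignment(detection_p, probes, sample_ids, "detection_p")
    bead_count = optional("bead_count")
    if bead_count is not None:
        bead_count = _check_alignment(bead_count, probes, sample_ids, "bead_count").astype(int)

    provenance: list[str] = []
    prov_path = d / "provenance.txt"
    if prov_path.exists():
        provenance = [line for line in prov_path.read_text().splitlines() if line]

    return MethylDataset(
        beta=beta,
        annotation=annotation,
        samples=samples,
        intensities=intensities,
        detection_p=detection_p,
        bead_count=bead_count,
        provenance=provenance,
    )


def write_dataset(dataset: MethylDataset, directory: str | os.PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_annotation(dataset.annotation, d / "annotation.tsv")
    write_samplesheet(dataset.samples, d / "samples.csv")
    write_matrix(dataset.beta, d / "beta.tsv")
    if dataset.intensities is not None:
        i = dataset.intensities
        write_matrix(i.meth, d / "meth.tsv")
        write_matrix(i.unmeth, d / "unmeth.tsv")
        if i.oob_meth is not None:
            write_matrix(i.oob_meth, d / "oob_meth.tsv")
        if i.oob_unmeth is not None:
            write_matrix(i.oob_unmeth, d / "oob_unmeth.tsv")
        if i.controls is not None:
            i.controls.to_csv(d / "controls.tsv", sep="\t", float_format=_FLOAT_FMT)
    if dataset.detection_p is not None:
        write_matrix(dataset.detection_p, d / "detection_p.tsv")
    if dataset.bead_count is not None:
        write_matrix(dataset.bead_count, d / "bead_count.tsv")
    (d / "provenance.txt").write_text("\n".join(dataset.provenance) + "\n")


def read_kinship(path: str | os.PathLike) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return KinshipMatrix(df)


def write_kinship(kinship: KinshipMatrix, path: str | os.PathLike) -> None:
    kinship.k.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_genotypes_tsv(path: str | os.PathLike, positions_path: str | os.PathLike | None = None) -> GenotypeTable:
    """Genotype TSV: first column snp_id, then chromosome, position, samples."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    if not {"chromosome", "position"}.issubset(df.columns):
        raise ValueError("genotype TSV needs chromosome and position columns")
    positions = df[["chromosome", "position"]].copy()
    positions["chromosome"] = positions["chromosome"].astype(str)
    g = df.drop(columns=["chromosome", "position"]).astype(float)
    return GenotypeTable(g=g, positions=positions)


def write_genotypes_tsv(genotypes: GenotypeTable, path: str | os.PathLike) -> None:
    out = pd.concat([genotypes.positions, genotypes.g], axis=1)
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes_vcf(path: str | os.PathLike) -> GenotypeTable:
    """Read diploid GT fields from a VCF into additive 0/1/2 dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    ids = []
    chroms = []
    positions = []
    for i, variant in enumerate(vcf):
        gt = np.asarray(variant.gt_types, dtype=float)  # 0=hom ref,1=het,2=missing?,3=hom alt
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dosage = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dosage)
        ids.append(variant.ID if variant.ID else f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        positions.append(int(variant.POS))
    g = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    pos = pd.DataFrame(
        {"chromosome": chroms, "position": positions}, index=g.index
    )
    return GenotypeTable(g=g, positions=pos)


def read_genotypes(path: str | os.PathLike) -> GenotypeTable:
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return read_genotypes_vcf(path)
    return read_genotypes_tsv(path)


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    """Pedigree TSV: columns id, father, mother, family; '' or NA = founder."""
    ped = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""])
    ped = ped.where(ped.notna(), None)
    return ped


def write_pedigree(pedigree: pd.DataFrame, path: str | os.PathLike) -> None:
    pedigree.to_csv(path, sep="\t", index=False, na_rep="NA")
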