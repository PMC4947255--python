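"""Domain containers for 450k-style methylation data.

All matrices are pandas DataFrames with probe ids as the row index and sample
ids as columns; containers validate the invariants that the rest of the
package relies on (index alignment, value ranges, uniqueness) at
construction time so downstream code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SEX_CHROMOSOME_NAMES = {"chrX", "chrY", "X", "Y", "chrx", "chry", "x", "y"}

REGION_STRATA = ("island", "shore_shelf", "open_sea")


def _check_finite_nonneg(df: pd.DataFrame, name: str) -> None:
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"{name} contains non-finite value at probe "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    if (vals < 0).any():
        bad = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"{name} contains negative intensity at probe "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )


@dataclass
class IntensityMatrix:
    """Methylated/unmethylated fluorescence intensities (probes x samples).

    ``oob_meth``/``oob_unmeth`` hold out-of-band intensities (type I probes
    read in the opposite colour channel; pure non-specific background) and
    ``controls`` holds control-probe intensities (control type x sample).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    oob_meth: pd.DataFrame | None = None
    oob_unmeth: pd.DataFrame | None = None
    controls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index):
            raise ValueError("meth and unmeth probe indices differ")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise ValueError("meth and unmeth sample columns differ")
        _check_finite_nonneg(self.meth, "meth")
        _check_finite_nonneg(self.unmeth, "unmeth")
        for name in ("oob_meth", "oob_unmeth"):
            df = getattr(self, name)
            if df is not None:
                _check_finite_nonneg(df, name)

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            meth=self.meth.copy(),
            unmeth=self.unmeth.copy(),
            oob_meth=None if self.oob_meth is None else self.oob_meth.copy(),
            oob_unmeth=None if self.oob_unmeth is None else self.oob_unmeth.copy(),
            controls=None if self.controls is None else self.controls.copy(),
        )


@dataclass
class BetaMatrix:
    """Proportion-methylated values in [0, 1] (probes x samples)."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("beta matrix contains non-finite values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


@dataclass
class MValueMatrix:
    """Base-2 logit of beta; the variance-stabilised scale for statistics."""

    m: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.m.to_numpy(dtype=float)).all():
            raise ValueError("M-value matrix contains non-finite values")


class ProbeAnnotation:
    """Per-probe manifest: chemistry, genomic context and QC flags.

    Wraps a DataFrame indexed by probe_id with columns design_type ('I'/'II'),
    channel ('red'/'green'/'both'), chromosome, position (1-based),
    region_stratum ('island'/'shore_shelf'/'open_sea'), is_idmr,
    cpg_body_count and the derived on_sex_chromosome flag.
    """

    REQUIRED = [
        "design_type",
        "channel",
        "chromosome",
        "position",
        "region_stratum",
        "is_idmr",
        "cpg_body_count",
    ]

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "probe_id":
            if "probe_id" in table.columns:
                table = table.set_index("probe_id")
            else:
                table.index.name = "probe_id"
        if table.index.duplicated().any():
            dups = table.index[table.index.duplicated()].unique()[:10].tolist()
            raise ValueError(f"duplicate probe_id in annotation: {dups}")
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        bad_type = ~table["design_type"].isin(["I", "II"])
        if bad_type.any():
            raise ValueError("design_type must be 'I' or 'II'")
        # Infinium II probes are read in both colour channels by construction.
        type2 = table["design_type"] == "II"
        if (table.loc[type2, "channel"] != "both").any():
            raise ValueError("type II probes must have channel 'both'")
        if (table["cpg_body_count"].astype(int) < 1).any():
            raise ValueError("cpg_body_count must be >= 1")
        table["is_idmr"] = table["is_idmr"].astype(bool)
        table["cpg_body_count"] = table["cpg_body_count"].astype(int)
        table["position"] = table["position"].astype(int)
        if "on_sex_chromosome" not in table.columns:
            table["on_sex_chromosome"] = table["chromosome"].isin(SEX_CHROMOSOME_NAMES)
        else:
            table["on_sex_chromosome"] = table["on_sex_chromosome"].astype(bool)
        self.table = table

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def design_type(self) -> pd.Series:
        return self.table["design_type"]

    @property
    def is_idmr(self) -> pd.Series:
        return self.table["is_idmr"]

    @property
    def region_stratum(self) -> pd.Series:
        return self.table["region_stratum"]

    @property
    def cpg_body_count(self) -> pd.Series:
        return self.table["cpg_body_count"]

    @property
    def on_sex_chromosome(self) -> pd.Series:
        return self.table["on_sex_chromosome"]

    def type_ids(self, design: str) -> pd.Index:
        return self.table.index[self.table["design_type"] == design]

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table.loc[probe_ids])

    def __len__(self) -> int:
        return len(self.table)


class SampleSheet:
    """Sample metadata: batch, family, replicate group, age and sex."""

    REQUIRED = ["batch", "family_id", "replicate_group", "age", "sex"]

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "sample_id":
            if "sample_id" in table.columns:
                table = table.set_index("sample_id")
            else:
                table.index.name = "sample_id"
        if table.index.duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if table["batch"].isna().any():
            raise ValueError("every sample needs a batch")
        if table["family_id"].isna().any():
            raise ValueError("every sample needs a family_id")
        rg = table["replicate_group"]
        table["replicate_group"] = rg.where(rg.notna() & (rg.astype(str) != ""), None)
        counts = table["replicate_group"].value_counts()
        singletons = counts[counts < 2]
        if len(singletons):
            raise ValueError(
                f"replicate groups with a single member: {singletons.index.tolist()}"
            )
        self.table = table

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def batch(self) -> pd.Series:
        return self.table["batch"]

    @property
    def family_id(self) -> pd.Series:
        return self.table["family_id"]

    @property
    def age(self) -> pd.Series:
        return self.table["age"]

    @property
    def sex(self) -> pd.Series:
        return self.table["sex"]

    def replicate_groups(self) -> dict[str, list[str]]:
        """Mapping replicate_group -> member sample ids (groups of >= 2)."""
        out: dict[str, list[str]] = {}
        rg = self.table["replicate_group"]
        for group, members in rg.groupby(rg).groups.items():
            out[str(group)] = list(members)
        return out

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MethylDataset:
    """Index-aligned bundle of everything one processing state carries.

    ``provenance`` is an append-only list of processing-step labels; every
    transformation returns a new dataset with its label appended.
    """

    beta: pd.DataFrame
    annotation: ProbeAnnotation
    samples: SampleSheet
    intensities: IntensityMatrix | None = None
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        probes = self.beta.index
        samples = self.beta.columns
        if not probes.equals(pd.Index(self.annotation.probe_ids)):
            extra = probes.difference(self.annotation.probe_ids)[:10].tolist()
            missing = pd.Index(self.annotation.probe_ids).difference(probes)[:10].tolist()
            raise ValueError(
                f"beta probes and annotation misaligned; beta-only={extra}, annotation-only={missing}"
            )
        if not samples.equals(pd.Index(self.samples.sample_ids)):
            extra = samples.difference(self.samples.sample_ids)[:10].tolist()
            missing = pd.Index(self.samples.sample_ids).difference(samples)[:10].tolist()
            raise ValueError(
                f"beta samples and sample sheet misaligned; beta-only={extra}, sheet-only={missing}"
            )
        for name in ("detection_p", "bead_count"):
            df = getattr(self, name)
            if df is not None and (
                not df.index.equals(probes) or not df.columns.equals(samples)
            ):
                raise ValueError(f"{name} not aligned with beta matrix")
        if self.intensities is not None:
            if not self.intensities.probe_ids.equals(probes) or not self.intensities.sample_ids.equals(samples):
                raise ValueError("intensities not aligned with beta matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def mvalues(self, epsilon: float = 1e-6) -> pd.DataFrame:
        from famnorm.transforms import m_from_beta

        return m_from_beta(BetaMatrix(self.beta), epsilon=epsilon).m

    def with_provenance(self, label: str) -> "MethylDataset":
        out = replace(self, provenance=self.provenance + [label])
        return out

    def subset_probes(self, probe_ids) -> "MethylDataset":
        probe_ids = pd.Index(probe_ids)
        intens = None
        if self.intensities is not None:
            i = self.intensities
            keep1 = None
            keep2 = None
            if i.oob_meth is not None:
                keep = i.oob_meth.index.intersection(probe_ids)
                keep1 = i.oob_meth.loc[keep]
            if i.oob_unmeth is not None:
                keep = i.oob_unmeth.index.intersection(probe_ids)
                keep2 = i.oob_unmeth.loc[keep]
            intens = IntensityMatrix(
                meth=i.meth.loc[probe_ids],
                unmeth=i.unmeth.loc[probe_ids],
                oob_meth=keep1,
                oob_unmeth=keep2,
                controls=i.controls,
            )
        return MethylDataset(
            beta=self.beta.loc[probe_ids],
            annotation=self.annotation.subset(probe_ids),
            samples=self.samples,
            intensities=intens,
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
            bead_count=None if self.bead_count is None else self.bead_count.loc[probe_ids],
            provenance=list(self.provenance),
        )


@dataclass
class KinshipMatrix:
    """Pairwise relatedness (samples x samples), symmetric, entries in [0, 1].

    IBS matrices legitimately have off-diagonal entries comparable to the
    diagonal, so no diagonal-dominance is required.
    """

    k: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.k.to_numpy(dtype=float)
        if vals.shape[0] != vals.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not self.k.index.equals(self.k.columns):
            raise ValueError("kinship row and column sample ids differ")
        if not np.allclose(vals, vals.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise ValueError("kinship entries must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.k.index


@dataclass
class GenotypeTable:
    """Additive genotypes (SNPs x samples) in {0, 1, 2}, NaN for missing."""

    g: pd.DataFrame
    positions: pd.DataFrame  # index snp_id, columns chromosome, position

    def __post_init__(self) -> None:
        vals = self.g.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotypes must be 0/1/2 or missing")
        if not self.g.index.equals(self.positions.index):
            raise ValueError("genotype rows and position table misaligned")

    @property
    def snp_ids(self) -> pd.Index:
        return self.g.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.g.columns
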