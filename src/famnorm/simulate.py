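"""Synthetic Infinium-450k-style datasets with familial structure.

The generator emulates the design the evaluation metrics assume: ~50 blood
samples from a handful of multi-generation families, run in three batches
with technical replicates split across batches, two probe chemistries with a
compressed type II beta distribution, a block of hemi-methylated imprinted
(iDMR) probes centred at beta = 0.5, one planted cis-meQTL inside a window of
SNPs in LD, and a subset of probes drifting with age. Batch artefacts are
applied as per-probe location shifts plus a scale factor on the technical
noise (on the M-value scale, i.e. the location/scale model ComBat assumes),
with an additional batch- and sample-level background shift at the intensity
level (processing-date effects on non-specific fluorescence). Intensities
follow a normal-background + exponential-signal convolution so that
background-model-based correction is correctly specified.

Everything is drawn from named sub-streams of a single seed, so results are
bit-reproducible and adding probes does not perturb sample-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from famnorm.datatypes import (
    GenotypeTable,
    IntensityMatrix,
    KinshipMatrix,
    MethylDataset,
    ProbeAnnotation,
    SampleSheet,
)
from famnorm.transforms import beta_from_intensities

LOG2 = np.log(2.0)


@dataclass
class SimulationConfig:
    """Study-design knobs; defaults reproduce the familial 3-batch design.

    Units: M-value effects in base-2 logits, intensities in arbitrary
    fluorescence units (a.u.), ages in years.
    """

    # array content
    n_probes: int = 10000
    frac_type2: float = 0.72
    strata_proportions: tuple[float, float, float] = (0.31, 0.33, 0.36)  # island, shore_shelf, open_sea
    frac_sex_probes: float = 0.02
    n_idmr: int = 227
    # cohort
    n_samples: int = 45
    n_replicate_pairs: int = 6
    n_batches: int = 3
    n_families: int = 4
    age_min: float = 23.0
    age_max: float = 89.0
    # biology: methylation-state composition differs by genomic context
    # (islands are mostly unmethylated, open sea mostly methylated)
    state_probs_island: tuple[float, float, float] = (0.65, 0.15, 0.20)  # unmeth, hemi, meth
    state_probs_shore_shelf: tuple[float, float, float] = (0.40, 0.20, 0.40)
    state_probs_open_sea: tuple[float, float, float] = (0.20, 0.12, 0.68)
    family_effect_sd: float = 0.5  # M units; covariance 2*K*sd^2
    # batch artefact (location/scale on M values) and background shifts
    batch_shift_sd: float = 1.0  # sigma_gamma, M units
    batch_scale_shape: float = 40.0  # delta_b ~ Gamma(shape, 1/shape), mean 1
    batch_global_shift_sd: float = 0.3  # M units; common shift of a whole batch
    sample_shift_sd: float = 0.15  # M units; per-array global technical offset
    bg_batch_sd: float = 100.0  # a.u.; processing-date background shift
    bg_sample_sd: float = 50.0  # a.u.; per-array background shift
    # probe chemistry
    type2_compression: float = 0.8  # c in (0,1]; beta' = 0.5 + c*(beta-0.5)
    # intensity model
    background_mean: float = 500.0  # mu_bg, a.u.
    background_sd: float = 100.0  # sigma_bg, a.u.
    signal_mean: float = 3000.0  # theta: mean probe hybridisation affinity
    signal_floor: float = 800.0  # a.u.; dimmest functioning probe (vendor QC)
    noise_sd: float = 0.2  # technical noise on M values
    # meQTL plant
    meqtl_effect: float = 0.8  # M units per allele
    n_snps: int = 50
    causal_maf: float = 0.4
    ld_rho: float = 0.7  # AR(1) correlation between adjacent SNPs
    # genome-wide background SNPs transmitted through the pedigree; these
    # back the identity-by-state kinship the meQTL model adjusts with
    n_background_snps: int = 500
    # age drift: methylation drifts with age across a broad swathe of the
    # epigenome; weak slopes on a large fraction of probes
    frac_age_probes: float = 0.35
    age_slope_sd: float = 0.012  # M units per year
    # QC planting
    frac_failed_probes: float = 0.014  # hybridisation failures caught by detection p
    low_bead_fraction: float = 0.004
    n_bad_samples: int = 0
    # kinship model: "pedigree" or "exchangeable"
    kinship_model: str = "pedigree"
    family_rho: float = 0.25  # used when kinship_model == "exchangeable"

    def validate(self) -> None:
        if not 0 <= self.frac_type2 <= 1:
            raise ValueError("frac_type2 must be in [0, 1]")
        if abs(sum(self.strata_proportions) - 1) > 1e-9:
            raise ValueError("strata_proportions must sum to 1")
        if self.n_idmr > self.n_probes:
            raise ValueError("n_idmr cannot exceed n_probes")
        if self.n_replicate_pairs > self.n_samples:
            raise ValueError("more replicate pairs than samples")
        if not 0 < self.type2_compression <= 1:
            raise ValueError("type2_compression must be in (0, 1]")
        if self.n_batches < 1 or self.n_families < 1 or self.n_samples < self.n_families:
            raise ValueError("infeasible cohort configuration")
        if self.kinship_model not in ("pedigree", "exchangeable"):
            raise ValueError("kinship_model must be 'pedigree' or 'exchangeable'")
        if self.signal_mean <= self.signal_floor:
            raise ValueError("signal_mean must exceed signal_floor")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    true_beta: pd.DataFrame  # probes x array columns, pre-artefact biology
    batch_gamma: pd.DataFrame  # probes x batches, M-scale location shifts
    batch_delta: pd.Series  # per-batch noise-scale factor
    batch_global_shift: pd.Series  # common M-scale shift per batch
    bg_batch_shift: pd.Series  # per-batch background shift, a.u.
    meqtl_probe: str
    meqtl_snp: str
    meqtl_effect: float
    age_slopes: pd.Series  # per age-probe slope, M units / year
    pedigree: pd.DataFrame  # id, father, mother, family (founders NA parents)
    kinship: KinshipMatrix  # pedigree kinship over array columns
    genotypes: GenotypeTable  # meQTL-window SNPs over array columns
    background_genotypes: GenotypeTable | None = None  # genome-wide SNPs for IBS kinship
    replicate_map: dict[str, str] = field(default_factory=dict)  # original -> replicate column


# ---------------------------------------------------------------------------
# pedigree utilities


def kinship_from_pedigree(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Kinship coefficients from parent links by the standard recursion.

    phi_ii = 0.5 * (1 + phi_fm); phi_ij = 0.5 * (phi_fj + phi_mj) for i with
    parents f, m (a missing parent contributes 0). Requires an acyclic
    pedigree; founders have both parents missing.
    """
    ped = pedigree.copy()
    ids = list(ped["id"].astype(str))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    parents = {}
    for _, row in ped.iterrows():
        f = row.get("father")
        m = row.get("mother")
        f = None if f in (None, "", "NA") or (isinstance(f, float) and np.isnan(f)) else str(f)
        m = None if m in (None, "", "NA") or (isinstance(m, float) and np.isnan(m)) else str(m)
        parents[str(row["id"])] = (f, m)
    for i, (f, m) in parents.items():
        for p in (f, m):
            if p is not None and p not in parents:
                raise ValueError(f"parent {p!r} of {i!r} not in pedigree")

    # topological order; failure to make progress means a cycle
    order: list[str] = []
    placed: set[str] = set()
    remaining = set(parents)
    while remaining:
        layer = [
            i
            for i in remaining
            if all(p is None or p in placed for p in parents[i])
        ]
        if not layer:
            raise ValueError("pedigree contains a cycle")
        for i in sorted(layer):
            order.append(i)
            placed.add(i)
        remaining -= set(layer)

    idx = {i: n for n, i in enumerate(order)}
    phi = np.zeros((len(order), len(order)))
    for i in order:
        f, m = parents[i]
        ii = idx[i]
        for j in order[: ii]:
            jj = idx[j]
            val = 0.0
            if f is not None:
                val += 0.5 * phi[idx[f], jj]
            if m is not None:
                val += 0.5 * phi[idx[m], jj]
            phi[ii, jj] = phi[jj, ii] = val
        phi_fm = phi[idx[f], idx[m]] if (f is not None and m is not None) else 0.0
        phi[ii, ii] = 0.5 * (1.0 + phi_fm)

    out = pd.DataFrame(phi, index=order, columns=order).loc[ids, ids]
    return KinshipMatrix(out)


def _build_pedigree(config: SimulationConfig) -> tuple[pd.DataFrame, list[str]]:
    """Three-generation pedigrees per family; returns (pedigree, sampled ids).

    Each family has two founders, their children (each married to an
    unsampled founder spouse) and grandchildren; sampled individuals are the
    founders, children and grandchildren.
    """
    base = config.n_samples // config.n_families
    extra = config.n_samples % config.n_families
    sizes = [base + (1 if i < extra else 0) for i in range(config.n_families)]
    rows = []
    sampled: list[str] = []
    for fi, size in enumerate(sizes, start=1):
        fam = f"F{fi}"
        gp_f, gp_m = f"{fam}-gf", f"{fam}-gm"
        rows.append((gp_f, None, None, fam))
        rows.append((gp_m, None, None, fam))
        take = [gp_f, gp_m]
        n_children = max(1, round((size - 2) / 3))
        n_grand = max(0, size - 2 - n_children)
        couples = []
        for ci in range(1, n_children + 1):
            child = f"{fam}-c{ci}"
            spouse = f"{fam}-s{ci}"
            rows.append((child, gp_f, gp_m, fam))
            rows.append((spouse, None, None, fam))
            take.append(child)
            couples.append((child, spouse))
        gi = 0
        while gi < n_grand:
            child, spouse = couples[gi % len(couples)]
            gc = f"{child}g{gi // len(couples) + 1}"
            rows.append((gc, child, spouse, fam))
            take.append(gc)
            gi += 1
        sampled.extend(take[:size])
    ped = pd.DataFrame(rows, columns=["id", "father", "mother", "family"])
    return ped, sampled


# ---------------------------------------------------------------------------
# main generator


def _logit2(b: np.ndarray) -> np.ndarray:
    return np.log2(b / (1 - b))


def _expit2(m: np.ndarray) -> np.ndarray:
    return expit(m * LOG2)


def simulate_dataset(config: SimulationConfig, seed: int) -> tuple[MethylDataset, SimulationTruth]:
    """Generate one dataset plus its ground truth. Bitwise-deterministic in seed."""
    config.validate()
    ss = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["probes", "cohort", "biology", "genotypes", "batch", "intensity", "qc"],
            ss.spawn(7),
        )
    }

    # ---- probe annotation -------------------------------------------------
    rng = streams["probes"]
    n = config.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(1, n + 1)])
    design = np.where(rng.random(n) < config.frac_type2, "II", "I")
    strata = rng.choice(
        ["island", "shore_shelf", "open_sea"], size=n, p=list(config.strata_proportions)
    )
    n_sex = int(round(config.frac_sex_probes * n))
    sex_idx = rng.choice(n, size=n_sex, replace=False) if n_sex else np.array([], dtype=int)
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n)], dtype=object)
    if n_sex:
        half = n_sex // 2
        chroms[sex_idx[:half]] = "chrX"
        chroms[sex_idx[half:]] = "chrY"
    positions = (np.arange(n) // 22 + 1) * 500 + 10000
    cpg_body = 1 + rng.poisson(1.2, size=n)
    autosomal = np.flatnonzero(~np.isin(chroms, ("chrX", "chrY")))
    idmr_idx = rng.choice(autosomal, size=config.n_idmr, replace=False)
    is_idmr = np.zeros(n, dtype=bool)
    is_idmr[idmr_idx] = True

    # baseline methylation state and per-probe centres; composition by stratum
    probs_by_stratum = {
        "island": config.state_probs_island,
        "shore_shelf": config.state_probs_shore_shelf,
        "open_sea": config.state_probs_open_sea,
    }
    state = np.empty(n, dtype=int)  # 0 unmeth, 1 hemi, 2 meth
    for s_name, probs in probs_by_stratum.items():
        mask = strata == s_name
        state[mask] = rng.choice(3, size=mask.sum(), p=list(probs))
    centre = np.empty(n)
    centre[state == 0] = rng.beta(2, 10, size=(state == 0).sum())
    centre[state == 1] = rng.beta(10, 10, size=(state == 1).sum())
    centre[state == 2] = rng.beta(10, 2, size=(state == 2).sum())
    centre[is_idmr] = 0.5  # imprinted regions are hemi-methylated by definition
    centre = np.clip(centre, 0.01, 0.99)

    # meQTL target: a bright, autosomal, non-imprinted hemi-state probe
    candidates = np.flatnonzero((state == 1) & ~is_idmr & ~np.isin(chroms, ("chrX", "chrY")))
    meqtl_idx = int(rng.choice(candidates))
    meqtl_probe = probe_ids[meqtl_idx]

    age_candidates = np.setdiff1d(autosomal, np.concatenate([idmr_idx, [meqtl_idx]]))
    n_age = min(int(round(config.frac_age_probes * n)), len(age_candidates))
    age_idx = rng.choice(age_candidates, size=n_age, replace=False)
    age_slopes = rng.normal(0.0, config.age_slope_sd, size=n_age)

    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "design_type": design,
                "channel": np.where(
                    design == "II", "both", np.where(rng.random(n) < 0.5, "red", "green")
                ),
                "chromosome": chroms,
                "position": positions,
                "region_stratum": strata,
                "is_idmr": is_idmr,
                "cpg_body_count": cpg_body,
            }
        )
    )

    # ---- cohort: pedigree, batches, replicates, ages ----------------------
    rng = streams["cohort"]
    pedigree, sampled = _build_pedigree(config)
    fam_of = dict(zip(pedigree["id"], pedigree["family"]))

    if config.kinship_model == "pedigree":
        phi_all = kinship_from_pedigree(pedigree)
        phi = phi_all.k.loc[sampled, sampled].to_numpy()
    else:
        fams = np.array([fam_of[s] for s in sampled])
        phi = np.where(fams[:, None] == fams[None, :], config.family_rho / 2.0, 0.0)
        np.fill_diagonal(phi, 0.5)

    ages = rng.uniform(config.age_min, config.age_max, size=len(sampled))
    sexes = rng.choice(["F", "M"], size=len(sampled))

    # batch assignment: interleave within families so batch is not confounded
    # with family; replicate copies go to the next batch round-robin
    batch_of: dict[str, int] = {}
    counter = 0
    for s in sampled:
        batch_of[s] = counter % config.n_batches
        counter += 1
    rep_sources = list(rng.choice(sampled, size=config.n_replicate_pairs, replace=False))
    columns = list(sampled)
    col_bio = {s: s for s in sampled}
    replicate_map = {}
    replicate_group: dict[str, str] = {}
    for s in rep_sources:
        rep = f"{s}-rep"
        columns.append(rep)
        col_bio[rep] = s
        batch_of[rep] = (batch_of[s] + 1) % config.n_batches if config.n_batches > 1 else 0
        replicate_map[s] = rep
        replicate_group[s] = s
        replicate_group[rep] = s

    n_cols = len(columns)
    bio_index = {s: i for i, s in enumerate(sampled)}
    col_bio_idx = np.array([bio_index[col_bio[c]] for c in columns])
    col_batch = np.array([batch_of[c] for c in columns])

    samples = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": columns,
                "batch": [f"B{batch_of[c] + 1}" for c in columns],
                "family_id": [fam_of[col_bio[c]] for c in columns],
                "replicate_group": [replicate_group.get(c) for c in columns],
                "age": [ages[bio_index[col_bio[c]]] for c in columns],
                "sex": [sexes[bio_index[col_bio[c]]] for c in columns],
            }
        )
    )

    # ---- biology on the M scale -------------------------------------------
    rng = streams["biology"]
    m_bio = np.tile(_logit2(centre)[:, None], (1, len(sampled)))
    if config.family_effect_sd > 0:
        cov = 2.0 * phi + 1e-9 * np.eye(len(sampled))
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((len(sampled), n))
        m_bio += config.family_effect_sd * (chol @ z).T

    age_centred = ages - ages.mean()
    m_bio[age_idx, :] += age_slopes[:, None] * age_centred[None, :]

    # ---- genotypes (HWE, AR(1) LD window around the target probe) ---------
    rng = streams["genotypes"]
    n_snps = config.n_snps
    causal = n_snps // 2
    mafs = rng.uniform(0.1, 0.5, size=n_snps)
    mafs[causal] = config.causal_maf
    thresh = ndtri(mafs)
    sigma = config.ld_rho ** np.abs(np.subtract.outer(np.arange(n_snps), np.arange(n_snps)))
    chol_ld = np.linalg.cholesky(sigma + 1e-12 * np.eye(n_snps))
    g = np.zeros((n_snps, len(sampled)))
    for _hap in range(2):
        z = chol_ld @ rng.standard_normal((n_snps, len(sampled)))
        g += (z < thresh[:, None]).astype(float)
    snp_ids = [f"rs{j + 1:06d}" for j in range(n_snps)]
    snp_pos = positions[meqtl_idx] + np.linspace(-1_000_000, 1_000_000, n_snps).astype(int)
    geno_bio = pd.DataFrame(g, index=pd.Index(snp_ids, name="snp_id"), columns=sampled)

    m_bio[meqtl_idx, :] += config.meqtl_effect * g[causal, :]

    # genome-wide background SNPs dropped through the pedigree (IBS kinship)
    n_bg = config.n_background_snps
    bg_geno = None
    if n_bg > 0:
        bg_maf = rng.uniform(0.1, 0.5, size=n_bg)
        haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        parent_of = dict(zip(pedigree["id"], zip(pedigree["father"], pedigree["mother"])))
        # pedigree rows are emitted parents-first by construction
        for pid in pedigree["id"]:
            f, m = parent_of[pid]
            haps = []
            for parent in (f, m):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    haps.append((rng.random(n_bg) < bg_maf).astype(float))
                else:
                    ph = haplo[parent]
                    pick = rng.integers(0, 2, size=n_bg)
                    haps.append(np.where(pick == 0, ph[0], ph[1]))
            haplo[pid] = (haps[0], haps[1])
        bg = np.column_stack([haplo[s][0] + haplo[s][1] for s in sampled])
        bg_ids = pd.Index([f"bg{j + 1:06d}" for j in range(n_bg)], name="snp_id")
        bg_geno = pd.DataFrame(bg, index=bg_ids, columns=sampled)

    true_beta_bio = _expit2(m_bio)

    # expand biology to array columns (replicates share the biological layer)
    m_cols = m_bio[:, col_bio_idx]

    # ---- batch artefact and technical offsets on the M scale ---------------
    rng = streams["batch"]
    gamma = rng.normal(0.0, config.batch_shift_sd, size=(n, config.n_batches))
    delta = rng.gamma(config.batch_scale_shape, 1.0 / config.batch_scale_shape, size=config.n_batches)
    batch_global = rng.normal(0.0, config.batch_global_shift_sd, size=config.n_batches)
    sample_shift = rng.normal(0.0, config.sample_shift_sd, size=n_cols)
    noise = rng.standard_normal((n, n_cols)) * (config.noise_sd * np.sqrt(delta[col_batch]))[None, :]
    m_obs = m_cols + gamma[:, col_batch] + (batch_global[col_batch] + sample_shift)[None, :] + noise

    beta_obs = _expit2(m_obs)
    type2 = design == "II"
    beta_obs[type2, :] = 0.5 + config.type2_compression * (beta_obs[type2, :] - 0.5)

    # ---- intensities: probe affinity * beta + normal background ------------
    rng = streams["intensity"]
    affinity = config.signal_floor + rng.exponential(
        config.signal_mean - config.signal_floor, size=n
    )
    affinity[meqtl_idx] = config.signal_mean  # planted meQTL sits on a bright probe
    n_failed = int(round(config.frac_failed_probes * n))
    if n_failed:
        failed = rng.choice(np.setdiff1d(np.arange(n), [meqtl_idx]), size=n_failed, replace=False)
        affinity[failed] = 5.0
    bg_batch = rng.normal(0.0, config.bg_batch_sd, size=config.n_batches)
    bg_sample = rng.normal(0.0, config.bg_sample_sd, size=n_cols)
    bad_cols = rng.choice(n_cols, size=config.n_bad_samples, replace=False) if config.n_bad_samples else np.array([], dtype=int)
    sample_scale = np.ones(n_cols)
    sample_scale[bad_cols] = 0.01

    bg_mu = config.background_mean + bg_batch[col_batch] + bg_sample  # per column
    sig = affinity[:, None] * sample_scale[None, :]
    s_meth = beta_obs * sig
    s_unmeth = (1.0 - beta_obs) * sig
    meth = s_meth + np.maximum(rng.normal(bg_mu[None, :], config.background_sd, size=(n, n_cols)), 0.0)
    unmeth = s_unmeth + np.maximum(rng.normal(bg_mu[None, :], config.background_sd, size=(n, n_cols)), 0.0)

    type1_ids = probe_ids[~type2]
    oob_meth = np.maximum(
        rng.normal(bg_mu[None, :], config.background_sd, size=(len(type1_ids), n_cols)), 0.0
    )
    oob_unmeth = np.maximum(
        rng.normal(bg_mu[None, :], config.background_sd, size=(len(type1_ids), n_cols)), 0.0
    )

    n_neg = 60
    neg = np.maximum(rng.normal(bg_mu[None, :], config.background_sd, size=(n_neg, n_cols)), 0.0)
    n_stain = 20
    stain = 1500.0 * sample_scale[None, :] + np.maximum(
        rng.normal(bg_mu[None, :], config.background_sd, size=(n_stain, n_cols)), 0.0
    )
    control_index = pd.MultiIndex.from_tuples(
        [("negative", f"neg{i + 1:03d}") for i in range(n_neg)]
        + [("staining", f"stn{i + 1:03d}") for i in range(n_stain)],
        names=["control_type", "control_id"],
    )
    controls = pd.DataFrame(np.vstack([neg, stain]), index=control_index, columns=columns)

    # detection p: upper tail of total intensity under the per-sample
    # negative-control normal fit
    neg_mean = neg.mean(axis=0)
    neg_sd = neg.std(axis=0, ddof=1)
    total = meth + unmeth
    from scipy.stats import norm as _norm

    detection_p = _norm.sf(total, loc=2 * neg_mean[None, :], scale=np.sqrt(2) * neg_sd[None, :])

    # bead counts
    rng = streams["qc"]
    beads = 3 + rng.poisson(12, size=(n, n_cols))
    if config.low_bead_fraction > 0:
        low = rng.random((n, n_cols)) < config.low_bead_fraction
        low[meqtl_idx, :] = False  # the analysed meQTL probe is a QC-passing probe
        beads = np.where(low, rng.integers(0, 3, size=(n, n_cols)), beads)

    pidx = pd.Index(probe_ids, name="probe_id")
    cols = pd.Index(columns, name=None)
    intensities = IntensityMatrix(
        meth=pd.DataFrame(meth, index=pidx, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=pidx, columns=cols),
        oob_meth=pd.DataFrame(oob_meth, index=pd.Index(type1_ids, name="probe_id"), columns=cols),
        oob_unmeth=pd.DataFrame(oob_unmeth, index=pd.Index(type1_ids, name="probe_id"), columns=cols),
        controls=controls,
    )
    beta = beta_from_intensities(intensities)
    dataset = MethylDataset(
        beta=beta.beta,
        annotation=annotation,
        samples=samples,
        intensities=intensities,
        detection_p=pd.DataFrame(detection_p, index=pidx, columns=cols),
        bead_count=pd.DataFrame(beads, index=pidx, columns=cols),
        provenance=[f"simulate(seed={seed})"],
    )

    phi_cols = phi[np.ix_(col_bio_idx, col_bio_idx)]
    kin_cols = KinshipMatrix(pd.DataFrame(phi_cols, index=cols, columns=cols))
    geno_cols = GenotypeTable(
        g=geno_bio.iloc[:, col_bio_idx].set_axis(cols, axis=1),
        positions=pd.DataFrame(
            {"chromosome": [chroms[meqtl_idx]] * n_snps, "position": snp_pos},
            index=geno_bio.index,
        ),
    )
    truth = SimulationTruth(
        true_beta=pd.DataFrame(true_beta_bio[:, col_bio_idx], index=pidx, columns=cols),
        batch_gamma=pd.DataFrame(
            gamma, index=pidx, columns=[f"B{b + 1}" for b in range(config.n_batches)]
        ),
        batch_delta=pd.Series(delta, index=[f"B{b + 1}" for b in range(config.n_batches)]),
        batch_global_shift=pd.Series(
            batch_global, index=[f"B{b + 1}" for b in range(config.n_batches)]
        ),
        bg_batch_shift=pd.Series(bg_batch, index=[f"B{b + 1}" for b in range(config.n_batches)]),
        meqtl_probe=meqtl_probe,
        meqtl_snp=snp_ids[causal],
        meqtl_effect=config.meqtl_effect,
        age_slopes=pd.Series(age_slopes, index=pd.Index(probe_ids[age_idx], name="probe_id")),
        pedigree=pedigree,
        kinship=kin_cols,
        genotypes=geno_cols,
        background_genotypes=(
            None
            if bg_geno is None
            else GenotypeTable(
                g=bg_geno.iloc[:, col_bio_idx].set_axis(cols, axis=1),
                positions=pd.DataFrame(
                    {
                        "chromosome": [f"chr{(j % 22) + 1}" for j in range(n_bg)],
                        "position": [10_000_000 + 1000 * j for j in range(n_bg)],
                    },
                    index=bg_geno.index,
                ),
            )
        ),
        replicate_map=replicate_map,
    )
    return dataset, truth
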