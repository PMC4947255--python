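"""Evaluation battery for one processing state.

Eight metrics quantify how well a normalisation removed technical bias while
preserving biology: beta density summaries and type I/II KS distance, MDS
coordinates, ANOVA of batch (or family) on the first principal component,
replicate median absolute differences, the imprinted-region dispersion
DMRSE, hierarchical-cluster agreement with batch, meQTL association with
kinship adjustment, and the age-EWAS inflation factor lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from famnorm.datatypes import (
    BetaMatrix,
    GenotypeTable,
    KinshipMatrix,
    MethylDataset,
    MValueMatrix,
    ProbeAnnotation,
)
from famnorm.transforms import top_variable_probes


@dataclass
class MetricReport:
    """Numbers for one processing state; p-values in [0,1], dispersions >= 0."""

    label: str
    density_grid: np.ndarray | None = None
    densities: pd.DataFrame | None = None  # grid x samples
    ks_type1_type2: float | None = None
    mds: pd.DataFrame | None = None
    mds_variance_share: tuple[float, float] | None = None
    pc1_anova_p_batch: float | None = None
    pc1_anova_p_family: float | None = None
    cluster_batch_ari: float | None = None
    replicate_mad: dict[str, float] = field(default_factory=dict)
    dmrse: float | None = None
    meqtl_min_adjusted_p: float | None = None
    meqtl_table: pd.DataFrame | None = None
    ewas_lambda: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "ks_type1_type2": self.ks_type1_type2,
            "pc1_anova_p_batch": self.pc1_anova_p_batch,
            "pc1_anova_p_family": self.pc1_anova_p_family,
            "cluster_batch_ari": self.cluster_batch_ari,
            "replicate_mad_mean": (
                float(np.mean(list(self.replicate_mad.values()))) if self.replicate_mad else None
            ),
            "replicate_mad": dict(self.replicate_mad),
            "dmrse": self.dmrse,
            "meqtl_min_adjusted_p": self.meqtl_min_adjusted_p,
            "ewas_lambda": self.ewas_lambda,
        }


# ---------------------------------------------------------------------------


def density_summary(
    beta: BetaMatrix, annotation: ProbeAnnotation, grid_step: float = 0.005
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Per-sample beta densities on a fixed grid plus the type I/II KS distance.

    Gaussian kernel, Silverman bandwidth; each density is renormalised to
    integrate to one over the [0, 1] grid so that edge mass is not lost.
    """
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    vals = beta.beta.to_numpy(dtype=float)
    dens = np.empty((len(grid), vals.shape[1]))
    for j in range(vals.shape[1]):
        kde = stats.gaussian_kde(vals[:, j], bw_method="silverman")
        d = kde(grid)
        area = np.trapezoid(d, grid)
        dens[:, j] = d / area if area > 0 else d
    densities = pd.DataFrame(dens, index=grid, columns=beta.beta.columns)
    design = annotation.design_type.to_numpy()
    b1 = vals[design == "I"].ravel()
    b2 = vals[design == "II"].ravel()
    if len(b1) and len(b2):
        ks = float(stats.ks_2samp(b1, b2).statistic)
    else:
        ks = float("nan")
    return grid, densities, ks


def mds_coordinates(mvals: MValueMatrix | pd.DataFrame, k: int = 1000) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Classical MDS of samples on the top-k most variable M-value rows.

    Double-centred squared Euclidean distances; coordinates are the top two
    eigenvectors scaled by sqrt(eigenvalue), sign fixed so the first nonzero
    loading of each axis is positive.
    """
    df = mvals.m if isinstance(mvals, MValueMatrix) else mvals
    if df.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    k = min(k, len(df))
    top = df.loc[top_variable_probes(df, k=k)]
    X = top.to_numpy(dtype=float).T  # samples x probes
    d2 = np.square(
        np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    )
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = np.zeros((n, 2))
    for axis in range(2):
        lam = max(evals[axis], 0.0)
        v = evecs[:, axis]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if len(nz) and v[nz[0]] < 0:
            v = -v
        coords[:, axis] = v * np.sqrt(lam)
    total = np.sum(np.maximum(evals, 0.0))
    shares = (
        (float(max(evals[0], 0) / total), float(max(evals[1], 0) / total)) if total > 0 else (0.0, 0.0)
    )
    out = pd.DataFrame(coords, index=df.columns, columns=["mds1", "mds2"])
    return out, shares


def pc_anova(beta: BetaMatrix | pd.DataFrame, labels, k: int = 1000) -> float:
    """One-way ANOVA p of labels on PC1 of the top-k most variable rows."""
    df = beta.beta if isinstance(beta, BetaMatrix) else beta
    labels = pd.Series(np.asarray(labels, dtype=object), index=df.columns)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("pc_anova needs at least 2 label levels")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every label level needs at least 2 samples")
    k = min(k, len(df))
    top = df.loc[top_variable_probes(df, k=k)].to_numpy(dtype=float).T  # samples x probes
    top = top - top.mean(axis=0)
    # PC1 score per sample via SVD
    _, _, vt = np.linalg.svd(top, full_matrices=False)
    pc1 = top @ vt[0]
    groups = [pc1[(labels == lv).to_numpy()] for lv in levels]
    if all(np.allclose(g, g.mean()) for g in groups) and np.allclose(pc1, pc1.mean()):
        return 1.0
    stat, p = stats.f_oneway(*groups)
    if np.isnan(p):  # zero within- and between-group variance
        return 1.0
    return float(p)


def replicate_mad(mvals: MValueMatrix | pd.DataFrame, replicate_groups: dict[str, list[str]]) -> dict[str, float]:
    """Median over probes of |m1 - m2| per replicate pair (lower = less bias).

    Groups with more than two members are evaluated pairwise; a group with a
    missing member is skipped with a warning.
    """
    import warnings

    df = mvals.m if isinstance(mvals, MValueMatrix) else mvals
    out: dict[str, float] = {}
    for group, members in replicate_groups.items():
        present = [m for m in members if m in df.columns]
        if len(present) < 2:
            warnings.warn(f"replicate group {group!r} missing members; skipped")
            continue
        for a_i in range(len(present)):
            for b_i in range(a_i + 1, len(present)):
                a, b = present[a_i], present[b_i]
                key = group if len(present) == 2 else f"{group}:{a}|{b}"
                diffs = np.abs(df[a].to_numpy(dtype=float) - df[b].to_numpy(dtype=float))
                out[key] = float(np.median(diffs))
    return out


def dmrse(beta: BetaMatrix | pd.DataFrame, idmr_flags: pd.Series | np.ndarray) -> float:
    """Imprinted-region standard error: between-sample dispersion at iDMRs.

    iDMR probes are hemi-methylated (expected beta 0.5); each probe row is
    centred at its cross-sample mean, each sample's mean deviation is taken,
    and the n-1 standard deviation of those per-sample means is divided by
    sqrt(#iDMR probes).
    """
    df = beta.beta if isinstance(beta, BetaMatrix) else beta
    flags = np.asarray(idmr_flags, dtype=bool)
    if flags.sum() == 0:
        raise ValueError("no iDMR probes present")
    if df.shape[1] < 2:
        raise ValueError("dmrse needs at least 2 samples")
    sub = df.to_numpy(dtype=float)[flags]
    centred = sub - sub.mean(axis=1, keepdims=True)
    sample_means = centred.mean(axis=0)
    return float(sample_means.std(ddof=1) / np.sqrt(flags.sum()))


def cluster_batch_agreement(
    mvals: MValueMatrix | pd.DataFrame, labels
) -> tuple[np.ndarray, float]:
    """Complete-linkage Euclidean clustering on all probes, scored against labels.

    The dendrogram is cut at the number of label levels and agreement is the
    adjusted Rand index: 1 means clusters reproduce the batches (bad after
    correction), ~0 means no batch structure remains.
    """
    from sklearn.metrics import adjusted_rand_score

    df = mvals.m if isinstance(mvals, MValueMatrix) else mvals
    if df.shape[1] < 3:
        raise ValueError("clustering needs at least 3 samples")
    labels = np.asarray(labels, dtype=object)
    X = df.to_numpy(dtype=float).T
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    n_levels = len(pd.unique(labels))
    assign = hierarchy.fcluster(Z, t=n_levels, criterion="maxclust")
    ari = float(adjusted_rand_score(labels, assign))
    return Z, ari


def ibs_kinship(genotypes: GenotypeTable, min_snps: int = 10) -> KinshipMatrix:
    """Identity-by-state kinship: K_ij = mean over SNPs of (2 - |g_i - g_j|)/2."""
    g = genotypes.g.to_numpy(dtype=float)
    if g.shape[0] < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs for IBS kinship")
    n = g.shape[1]
    K = np.empty((n, n))
    for i in range(n):
        diff = np.abs(g - g[:, [i]])  # SNPs x samples
        shared = (2.0 - diff) / 2.0
        with np.errstate(invalid="ignore"):
            K[i] = np.nanmean(shared, axis=0)
        if np.isnan(K[i]).any():
            j = int(np.flatnonzero(np.isnan(K[i]))[0])
            raise ValueError(
                f"samples {genotypes.sample_ids[i]!r} and {genotypes.sample_ids[j]!r} share no genotyped SNPs"
            )
    K = (K + K.T) / 2.0
    return KinshipMatrix(pd.DataFrame(K, index=genotypes.sample_ids, columns=genotypes.sample_ids))


def _lmm_residuals(y: np.ndarray, K2: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Environmental residuals of y ~ N(mu, sg^2*K2 + se^2*I) by profiled ML.

    The heritability ratio r = sg^2/se^2 is profiled on the eigenbasis of K2
    (one-dimensional optimisation); residuals are y - mu - BLUP.
    """
    n = len(y)
    K2 = K2 + 1e-8 * np.eye(n)  # ridge for numerically singular kinships
    evals, evecs = np.linalg.eigh(K2)
    evals = np.maximum(evals, 0.0)
    yt = evecs.T @ y
    xt = evecs.T @ np.ones(n)

    def profile(r: float) -> tuple[float, float, float]:
        w = 1.0 / (r * evals + 1.0)
        mu = float((w * xt * yt).sum() / (w * xt * xt).sum())
        resid = yt - mu * xt
        se2 = float((w * resid**2).sum() / n)
        nll = 0.5 * (n * np.log(2 * np.pi * max(se2, 1e-300)) + np.log(r * evals + 1.0).sum() + n)
        return nll, mu, se2

    res = minimize_scalar(
        lambda t: profile(np.exp(t))[0], bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": tol},
    )
    r = float(np.exp(res.x))
    nll0, mu0, _ = profile(0.0)
    nll_r, mu, _ = profile(r)
    # flat or uninformative profile (e.g. kinship proportional to identity):
    # tie-break toward the no-heritability model, whose residuals are exact
    if nll0 <= nll_r + 1e-8 * (abs(nll0) + 1.0):
        return y - mu0
    w = 1.0 / (r * evals + 1.0)
    blup = evecs @ (r * evals * w * (yt - mu * xt))
    return y - mu - blup


def meqtl_association(
    y: pd.Series | np.ndarray,
    genotypes: GenotypeTable,
    kinship: KinshipMatrix,
) -> tuple[pd.DataFrame, float]:
    """Two-stage meQTL scan: kinship LMM residuals, then per-SNP OLS.

    Stage 1 fits methylation at the target probe against a random effect with
    covariance 2K (profiled-ML variance ratio) and takes the environmental
    residuals; stage 2 regresses those residuals on each SNP's additive
    dosage, with two-sided t-tests and Bonferroni adjustment over the window.
    Returns the per-SNP table and the minimum adjusted p.
    """
    if isinstance(y, pd.Series):
        sample_ids = y.index
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        sample_ids = genotypes.sample_ids
    if len(yv) < 10:
        raise ValueError("meQTL association needs at least 10 samples")
    K2 = 2.0 * kinship.k.loc[sample_ids, sample_ids].to_numpy(dtype=float)
    resid = _lmm_residuals(yv, K2)

    g = genotypes.g.loc[:, sample_ids].to_numpy(dtype=float)
    n_snps = g.shape[0]
    rows = []
    for s in range(n_snps):
        gs = g[s]
        ok = ~np.isnan(gs)
        if ok.sum() < 3 or np.nanstd(gs) == 0:
            rows.append((0.0, np.nan, 1.0))
            continue
        slope, intercept, r, p, se = stats.linregress(gs[ok], resid[ok])
        rows.append((float(slope), float(se), float(p)))
    table = pd.DataFrame(rows, index=genotypes.snp_ids, columns=["beta", "se", "p"])
    table["p_bonferroni"] = np.minimum(table["p"] * n_snps, 1.0)
    return table, float(table["p_bonferroni"].min())


def age_ewas_lambda(
    matrix: MValueMatrix | BetaMatrix | pd.DataFrame, ages
) -> tuple[pd.Series, float]:
    """Epigenome-wide age regression and the inflation factor lambda.

    Per probe, simple linear regression of methylation on age with a
    two-sided t-test; lambda = median(observed -log10 p) / median(expected
    -log10 p) with expected quantiles at (i - 0.5)/n.
    """
    if isinstance(matrix, MValueMatrix):
        df = matrix.m
    elif isinstance(matrix, BetaMatrix):
        df = matrix.beta
    else:
        df = matrix
    ages = np.asarray(ages, dtype=float)
    if np.allclose(ages, ages[0]):
        raise ValueError("ages are constant")
    X = df.to_numpy(dtype=float)
    n = X.shape[1]
    xc = ages - ages.mean()
    sxx = float((xc**2).sum())
    yc = X - X.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    slope = sxy / sxx
    rss = (yc**2).sum(axis=1) - slope * sxy
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
        t = np.where(se > 0, slope / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    constant = yc.std(axis=1) == 0
    p[constant] = 1.0
    p = np.clip(p, 1e-300, 1.0)
    pvals = pd.Series(p, index=df.index, name="p")
    k = len(p)
    expected = (np.arange(1, k + 1) - 0.5) / k
    lam = float(np.median(-np.log10(np.sort(p))) / np.median(-np.log10(expected)))
    return pvals, lam


# ---------------------------------------------------------------------------


def compute_metrics(
    dataset: MethylDataset,
    label: str,
    k_top: int = 1000,
    meqtl_probe: str | None = None,
    genotypes: GenotypeTable | None = None,
    kinship: KinshipMatrix | None = None,
    with_densities: bool = False,
    lambda_on: str = "m",
) -> MetricReport:
    """All applicable metrics for one processing state of a dataset."""
    from famnorm.transforms import m_from_beta

    report = MetricReport(label=label)
    beta = BetaMatrix(dataset.beta)
    mvals = m_from_beta(beta)
    if with_densities:
        grid, dens, ks = density_summary(beta, dataset.annotation)
        report.density_grid, report.densities, report.ks_type1_type2 = grid, dens, ks
    else:
        design = dataset.annotation.design_type.to_numpy()
        vals = dataset.beta.to_numpy(dtype=float)
        b1, b2 = vals[design == "I"].ravel(), vals[design == "II"].ravel()
        if len(b1) and len(b2):
            report.ks_type1_type2 = float(stats.ks_2samp(b1, b2).statistic)

    if dataset.beta.shape[1] >= 3:
        report.mds, report.mds_variance_share = mds_coordinates(mvals, k=k_top)
        _, report.cluster_batch_ari = cluster_batch_agreement(mvals, dataset.samples.batch)

    try:
        report.pc1_anova_p_batch = pc_anova(beta, dataset.samples.batch, k=k_top)
    except ValueError:
        pass
    try:
        report.pc1_anova_p_family = pc_anova(beta, dataset.samples.family_id, k=k_top)
    except ValueError:
        pass

    groups = dataset.samples.replicate_groups()
    if groups:
        report.replicate_mad = replicate_mad(mvals, groups)

    if dataset.annotation.is_idmr.any() and dataset.beta.shape[1] >= 2:
        report.dmrse = dmrse(beta, dataset.annotation.is_idmr.to_numpy())

    if meqtl_probe is not None and genotypes is not None and kinship is not None:
        if meqtl_probe in mvals.m.index:
            y = mvals.m.loc[meqtl_probe]
            table, min_p = meqtl_association(y, genotypes, kinship)
            report.meqtl_table = table
            report.meqtl_min_adjusted_p = min_p

    ages = dataset.samples.age.to_numpy(dtype=float)
    if not np.allclose(ages, ages[0]):
        target = mvals if lambda_on == "m" else beta
        _, report.ewas_lambda = age_ewas_lambda(target, ages)
    return report
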