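"""Eight normalisation strategies plus empirical-Bayes batch correction.

Every method is exposed as a scikit-learn-style transformer over a
:class:`~famnorm.datatypes.MethylDataset` (``fit`` learns per-sample or
per-probe parameters, ``transform`` applies them, fitted attributes carry a
trailing underscore) plus a thin module-level function. Intensity-level
methods (QN, stratified QN, SWAN, noob, dasen, funnorm) rewrite the
intensity matrices and recompute beta; BMIQ operates on beta directly;
ComBat operates on M values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr, logsumexp
from sklearn.base import BaseEstimator

from famnorm.datatypes import BetaMatrix, IntensityMatrix, MethylDataset, MValueMatrix
from famnorm.transforms import beta_from_intensities, beta_from_m, m_from_beta

_CLIP = 1e-6


# ---------------------------------------------------------------------------
# shared quantile-normalisation kernel


def quantile_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Force every column onto the cross-column mean of sorted values.

    Ties receive the mean of the reference values spanned by their rank
    range, so tied entries stay tied and column-wise rank order is preserved.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("quantile_normalize does not accept missing values")
    if X.shape[1] < 2:
        warnings.warn("single column: quantile normalisation is the identity")
        return matrix.copy() if is_df else X.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sv = col[order]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(sv)) + 1])
        ends = np.concatenate([starts[1:], [len(sv)]])
        sizes = ends - starts
        group_means = np.add.reduceat(ref, starts) / sizes
        # untied entries take the reference value exactly
        single = sizes == 1
        group_means[single] = ref[starts[single]]
        out[order, j] = np.repeat(group_means, sizes)
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _rank_quantiles(values: np.ndarray) -> np.ndarray:
    """Mid-rank plotting positions (rank - 0.5)/n, ties averaged."""
    ranks = stats.rankdata(values, method="average")
    return (ranks - 0.5) / len(values)


def _map_to_reference(values: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """Map values onto a reference distribution via their mid-rank quantiles."""
    probs = (np.arange(len(ref_sorted)) + 0.5) / len(ref_sorted)
    return np.interp(_rank_quantiles(values), probs, ref_sorted)


def _rebuild(dataset: MethylDataset, intensities: IntensityMatrix, label: str, offset: float = 100.0) -> MethylDataset:
    beta = beta_from_intensities(intensities, offset=offset)
    return MethylDataset(
        beta=beta.beta,
        annotation=dataset.annotation,
        samples=dataset.samples,
        intensities=intensities,
        detection_p=dataset.detection_p,
        bead_count=dataset.bead_count,
        provenance=dataset.provenance + [label],
    )


class _DatasetTransformer(BaseEstimator):
    """fit/transform over MethylDataset with sklearn parameter semantics."""

    def fit_transform(self, dataset: MethylDataset) -> MethylDataset:
        return self.fit(dataset).transform(dataset)

    def fit(self, dataset: MethylDataset) -> "_DatasetTransformer":  # pragma: no cover - overridden
        raise NotImplementedError

    def transform(self, dataset: MethylDataset) -> MethylDataset:  # pragma: no cover - overridden
        raise NotImplementedError

    def _require_intensities(self, dataset: MethylDataset) -> IntensityMatrix:
        if dataset.intensities is None:
            raise ValueError(f"{type(self).__name__} requires intensity matrices")
        return dataset.intensities


# ---------------------------------------------------------------------------
# quantile normalisation of intensities


class QuantileNormalizer(_DatasetTransformer):
    """Between-array quantile normalisation of meth/unmeth intensities."""

    def __init__(self, offset: float = 100.0):
        self.offset = offset

    def fit(self, dataset: MethylDataset) -> "QuantileNormalizer":
        i = self._require_intensities(dataset)
        self.reference_meth_ = np.sort(i.meth.to_numpy(dtype=float), axis=0).mean(axis=1)
        self.reference_unmeth_ = np.sort(i.unmeth.to_numpy(dtype=float), axis=0).mean(axis=1)
        return self

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        i = self._require_intensities(dataset)
        meth = quantile_normalize(i.meth)
        unmeth = quantile_normalize(i.unmeth)
        out = IntensityMatrix(
            meth=meth, unmeth=unmeth, oob_meth=i.oob_meth, oob_unmeth=i.oob_unmeth, controls=i.controls
        )
        return _rebuild(dataset, out, "qn", offset=self.offset)


class StratifiedQuantileNormalizer(_DatasetTransformer):
    """Quantile normalisation stratified by genomic region.

    Within each region stratum (island / shore_shelf / open_sea) the type II
    meth and unmeth intensities are quantile-normalised across samples, and
    each sample's type I intensities are mapped by monotone interpolation
    onto the stratum's type II reference quantile function. No background
    correction is applied.
    """

    def __init__(self, offset: float = 100.0):
        self.offset = offset

    def fit(self, dataset: MethylDataset) -> "StratifiedQuantileNormalizer":
        self.strata_ = sorted(dataset.annotation.region_stratum.unique())
        return self

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        i = self._require_intensities(dataset)
        ann = dataset.annotation
        meth = i.meth.to_numpy(dtype=float).copy()
        unmeth = i.unmeth.to_numpy(dtype=float).copy()
        design = ann.design_type.to_numpy()
        stratum = ann.region_stratum.to_numpy()
        type2_all = design == "II"

        global_refs = {}
        for channel, X in (("meth", meth), ("unmeth", unmeth)):
            if type2_all.sum() >= 2:
                global_refs[channel] = np.sort(X[type2_all], axis=0).mean(axis=1)
            else:
                global_refs[channel] = np.sort(X, axis=0).mean(axis=1)

        for s in np.unique(stratum):
            in_stratum = stratum == s
            t2 = in_stratum & type2_all
            t1 = in_stratum & ~type2_all
            for channel, X in (("meth", meth), ("unmeth", unmeth)):
                if t2.sum() >= 2:
                    X[t2] = quantile_normalize(X[t2])
                    ref = np.sort(X[t2][:, 0])
                else:
                    warnings.warn(
                        f"stratum {s!r} has <2 type II probes; using global reference"
                    )
                    ref = global_refs[channel]
                if t1.any():
                    for j in range(X.shape[1]):
                        X[t1, j] = _map_to_reference(X[t1, j], ref)

        out = IntensityMatrix(
            meth=pd.DataFrame(meth, index=i.probe_ids, columns=i.sample_ids),
            unmeth=pd.DataFrame(unmeth, index=i.probe_ids, columns=i.sample_ids),
            oob_meth=i.oob_meth,
            oob_unmeth=i.oob_unmeth,
            controls=i.controls,
        )
        return _rebuild(dataset, out, "stratified_qn", offset=self.offset)


# ---------------------------------------------------------------------------
# SWAN


class SwanNormalizer(_DatasetTransformer):
    """Subset-quantile within-array normalisation.

    Per sample and channel: equal-sized random subsets of type I and type II
    probes are drawn within each CpG-body-count class (1, 2, 3+); the mean of
    the two sorted subset vectors defines a target quantile distribution;
    subset probes are set to it by rank within their type and the remaining
    probes follow by monotone interpolation between flanking subset values.
    """

    def __init__(self, seed: int = 0, offset: float = 100.0):
        self.seed = seed
        self.offset = offset

    def fit(self, dataset: MethylDataset) -> "SwanNormalizer":
        ann = dataset.annotation
        counts = np.minimum(ann.cpg_body_count.to_numpy(), 3)  # classes 1, 2, 3+
        design = ann.design_type.to_numpy()
        rng = np.random.default_rng(self.seed)
        subset1: list[int] = []
        subset2: list[int] = []
        for c in (1, 2, 3):
            idx1 = np.flatnonzero((design == "I") & (counts == c))
            idx2 = np.flatnonzero((design == "II") & (counts == c))
            size = min(len(idx1), len(idx2))
            if size == 0:
                warnings.warn(f"CpG-count class {c} empty in one probe type; dropped")
                continue
            subset1.extend(rng.choice(idx1, size=size, replace=False))
            subset2.extend(rng.choice(idx2, size=size, replace=False))
        if not subset1:
            raise ValueError("no usable CpG-body-count classes for SWAN")
        self.subset1_ = np.array(sorted(subset1))
        self.subset2_ = np.array(sorted(subset2))
        return self

    @staticmethod
    def _adjust(values: np.ndarray, subset_idx: np.ndarray, target_sorted: np.ndarray) -> np.ndarray:
        out = values.copy()
        sub_vals = values[subset_idx]
        order = np.argsort(sub_vals, kind="mergesort")
        adjusted = np.empty_like(sub_vals)
        adjusted[order] = target_sorted
        out[subset_idx] = adjusted
        rest = np.setdiff1d(np.arange(len(values)), subset_idx, assume_unique=False)
        if len(rest):
            xp = sub_vals[order]
            fp = target_sorted
            # strictly increasing xp for interpolation
            xp = xp + np.arange(len(xp)) * 1e-9
            x = values[rest]
            mapped = np.interp(x, xp, fp)
            low = x < xp[0]
            high = x > xp[-1]
            mapped[low] = x[low] + (fp[0] - xp[0])
            mapped[high] = x[high] + (fp[-1] - xp[-1])
            out[rest] = mapped
        return out

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        i = self._require_intensities(dataset)
        design = dataset.annotation.design_type.to_numpy()
        idx1_all = np.flatnonzero(design == "I")
        idx2_all = np.flatnonzero(design == "II")
        meth = i.meth.to_numpy(dtype=float).copy()
        unmeth = i.unmeth.to_numpy(dtype=float).copy()
        for X in (meth, unmeth):
            for j in range(X.shape[1]):
                s1 = np.sort(X[self.subset1_, j])
                s2 = np.sort(X[self.subset2_, j])
                target = 0.5 * (s1 + s2)
                col = X[:, j]
                # adjust within each probe type separately
                new = col.copy()
                for idx_all, sub in ((idx1_all, self.subset1_), (idx2_all, self.subset2_)):
                    if len(idx_all) == 0:
                        continue
                    local_sub = np.searchsorted(idx_all, sub)
                    new[idx_all] = self._adjust(col[idx_all], local_sub, target)
                X[:, j] = np.maximum(new, 0.0)
        out = IntensityMatrix(
            meth=pd.DataFrame(meth, index=i.probe_ids, columns=i.sample_ids),
            unmeth=pd.DataFrame(unmeth, index=i.probe_ids, columns=i.sample_ids),
            oob_meth=i.oob_meth,
            oob_unmeth=i.oob_unmeth,
            controls=i.controls,
        )
        return _rebuild(dataset, out, f"swan(seed={self.seed})", offset=self.offset)


# ---------------------------------------------------------------------------
# BMIQ


@dataclass
class BetaMixtureFit:
    """Three-state beta mixture (U/H/M) fitted to one sample and probe type."""

    a: np.ndarray  # shape (3,)
    b: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)


def _mom_beta(mean: float, var: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    var = max(min(var, mean * (1 - mean) * 0.99), 1e-6)
    common = mean * (1 - mean) / var - 1.0
    return max(mean * common, 1e-2), max((1 - mean) * common, 1e-2)


def fit_beta_mixture(
    values: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
    init: BetaMixtureFit | None = None,
    fix_weights: bool = False,
) -> BetaMixtureFit:
    """EM fit of a 3-component beta mixture.

    By default the fit is initialised by splitting at beta thresholds 1/3 and
    2/3 with method-of-moments component parameters. Passing ``init`` starts
    from another fit's parameters, and ``fix_weights`` keeps that fit's
    mixture weights frozen — used by BMIQ to tie the type II state
    composition to the type I fit, since the biological states are shared
    between chemistries and only the component shapes differ technically.
    """
    x = np.clip(np.asarray(values, dtype=float), 1e-4, 1 - 1e-4)
    a = np.empty(3)
    b = np.empty(3)
    w = np.empty(3)
    defaults = [(0.15, 0.005), (0.5, 0.01), (0.85, 0.005)]
    if init is not None:
        a[:] = init.a
        b[:] = init.b
        w[:] = init.weights
    else:
        groups = [x[x < 1 / 3], x[(x >= 1 / 3) & (x <= 2 / 3)], x[x > 2 / 3]]
        for k, g in enumerate(groups):
            if len(g) >= 5:
                a[k], b[k] = _mom_beta(g.mean(), max(g.var(), 1e-6))
                w[k] = len(g) / len(x)
            else:
                a[k], b[k] = _mom_beta(*defaults[k])
                w[k] = 1.0 / len(x)
    w = w / w.sum()

    loglik = -np.inf
    converged = False
    it = 0
    reinitialised = False
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(w[k]) + stats.beta.logpdf(x, a[k], b[k]) for k in range(3)]
        )
        norm = logsumexp(logp, axis=0)
        new_loglik = float(norm.sum())
        resp = np.exp(logp - norm)
        nk = resp.sum(axis=1)
        if not fix_weights:
            w = nk / len(x)
        for k in range(3):
            if nk[k] < 2:
                # degenerate component: reinitialise once at a spread prior
                if not reinitialised:
                    a[k], b[k] = _mom_beta(*defaults[k])
                    w[k] = max(w[k], 0.01)
                    reinitialised = True
                continue
            mean_k = float((resp[k] * x).sum() / nk[k])
            var_k = float((resp[k] * (x - mean_k) ** 2).sum() / nk[k])
            a[k], b[k] = _mom_beta(mean_k, var_k)
        w = w / w.sum()
        if abs(new_loglik - loglik) < tol * (abs(loglik) + 1.0):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    order = np.argsort(a / (a + b))
    return BetaMixtureFit(a=a[order], b=b[order], weights=w[order], loglik=loglik, n_iter=it, converged=converged)


class BMIQNormalizer(_DatasetTransformer):
    """Beta-mixture quantile dilation of type II probes onto the type I scale.

    Per sample, 3-state beta mixtures are fitted to the type I and type II
    beta values; type II probes assigned to the unmethylated state are
    remapped by quantile matching between the two U components (left tail),
    the methylated state analogously via the right tail, and the
    hemi-methylated state is stretched affinely so that its range abuts the
    transformed U and M ranges. Type I values are untouched.
    """

    def __init__(self, em_tol: float = 1e-4, em_max_iter: int = 100, fit_subsample: int = 5000, seed: int = 0):
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.fit_subsample = fit_subsample
        self.seed = seed

    def fit(self, dataset: MethylDataset) -> "BMIQNormalizer":
        design = dataset.annotation.design_type.to_numpy()
        idx1 = design == "I"
        idx2 = design == "II"
        if not idx1.any() or not idx2.any():
            raise ValueError("BMIQ requires both probe types")
        rng = np.random.default_rng(self.seed)
        beta = dataset.beta.to_numpy(dtype=float)
        self.fits_: dict[str, dict[str, BetaMixtureFit]] = {}
        for j, sample in enumerate(dataset.sample_ids):
            vals1 = beta[idx1, j]
            if len(vals1) > self.fit_subsample:
                vals1 = rng.choice(vals1, size=self.fit_subsample, replace=False)
            fit1 = fit_beta_mixture(vals1, tol=self.em_tol, max_iter=self.em_max_iter)
            vals2 = beta[idx2, j]
            if len(vals2) > self.fit_subsample:
                vals2 = rng.choice(vals2, size=self.fit_subsample, replace=False)
            # type II: initialise at the type I solution and tie the state
            # weights to it — the biological state composition is shared
            # between chemistries, only the component shapes differ
            fit2 = fit_beta_mixture(
                vals2, tol=self.em_tol, max_iter=self.em_max_iter, init=fit1, fix_weights=True
            )
            for key, fit in (("I", fit1), ("II", fit2)):
                if not fit.converged:
                    warnings.warn(f"BMIQ EM did not converge for sample {sample} type {key}")
            self.fits_[str(sample)] = {"I": fit1, "II": fit2}
        return self

    @staticmethod
    def _state_boundary(fit: BetaMixtureFit, k_left: int, k_right: int) -> float:
        """Value between two component means where their weighted densities cross."""
        means = fit.means
        grid = np.linspace(means[k_left], means[k_right], 512)
        diff = (
            np.log(fit.weights[k_left])
            + stats.beta.logpdf(grid, fit.a[k_left], fit.b[k_left])
            - np.log(fit.weights[k_right])
            - stats.beta.logpdf(grid, fit.a[k_right], fit.b[k_right])
        )
        sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
        if len(sign_change):
            return float(grid[sign_change[0] + 1])
        return float(0.5 * (means[k_left] + means[k_right]))

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        design = dataset.annotation.design_type.to_numpy()
        idx2 = np.flatnonzero(design == "II")
        beta = dataset.beta.to_numpy(dtype=float).copy()
        for j, sample in enumerate(dataset.sample_ids):
            pair = self.fits_[str(sample)]
            f1, f2 = pair["I"], pair["II"]
            x = np.clip(beta[idx2, j], 1e-4, 1 - 1e-4)
            # monotone state assignment: cut at the density crossings so the
            # U / H / M regions are genuine intervals of the beta axis
            b_uh = self._state_boundary(f2, 0, 1)
            b_hm = self._state_boundary(f2, 1, 2)
            u_mask = x < b_uh
            m_mask = x > b_hm
            h_mask = ~u_mask & ~m_mask
            new = x.copy()
            if u_mask.any():
                q = stats.beta.cdf(x[u_mask], f2.a[0], f2.b[0])
                new[u_mask] = stats.beta.ppf(q, f1.a[0], f1.b[0])
            if m_mask.any():
                p = stats.beta.sf(x[m_mask], f2.a[2], f2.b[2])
                new[m_mask] = stats.beta.isf(p, f1.a[2], f1.b[2])
            if h_mask.any():
                # transform the boundaries through the flanking state maps so
                # the dilated hemi range abuts the transformed U and M ranges
                lo = float(stats.beta.ppf(stats.beta.cdf(b_uh, f2.a[0], f2.b[0]), f1.a[0], f1.b[0]))
                hi = float(stats.beta.isf(stats.beta.sf(b_hm, f2.a[2], f2.b[2]), f1.a[2], f1.b[2]))
                if hi <= lo:
                    lo, hi = min(lo, hi), max(lo, hi)
                if b_hm > b_uh and hi > lo:
                    new[h_mask] = lo + (x[h_mask] - b_uh) * (hi - lo) / (b_hm - b_uh)
                else:
                    new[h_mask] = 0.5 * (lo + hi)
            beta[idx2, j] = np.clip(new, 0.0, 1.0)
        out_beta = pd.DataFrame(beta, index=dataset.probe_ids, columns=dataset.sample_ids)
        return MethylDataset(
            beta=out_beta,
            annotation=dataset.annotation,
            samples=dataset.samples,
            intensities=None,  # beta-level method: intensities no longer consistent
            detection_p=dataset.detection_p,
            bead_count=dataset.bead_count,
            provenance=dataset.provenance + ["bmiq"],
        )


# ---------------------------------------------------------------------------
# noob


@dataclass
class NormexpFit:
    """Normal background + exponential signal parameters for one sample/channel."""

    mu: float
    sigma: float
    theta: float
    offset: float = 15.0


def _truncnorm_mle(values: np.ndarray, upper_quantile: float = 0.95) -> tuple[float, float]:
    """MLE of a normal from observations truncated above a high quantile.

    Truncation guards the background estimate against contamination from
    genuine signal leaking into the out-of-band measurements.
    """
    v = np.asarray(values, dtype=float)
    t = np.quantile(v, upper_quantile)
    x = v[v <= t]
    if len(x) < 10:
        x = v
        t = v.max() + 1.0

    def nll(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        z = (x - mu) / sigma
        return -(stats.norm.logpdf(z).sum() - len(x) * np.log(sigma) - len(x) * log_ndtr((t - mu) / sigma))

    from scipy.optimize import minimize

    res = minimize(nll, x0=np.array([x.mean(), np.log(max(x.std(), 1e-3))]), method="Nelder-Mead")
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sigma


def normexp_signal(x: np.ndarray, mu: float, sigma: float, theta: float) -> np.ndarray:
    """Posterior expected signal E[S | X=x] for X = S + B, S~Exp(theta), B~N(mu, sigma^2)."""
    mu_sf = x - mu - sigma**2 / theta
    r = mu_sf / sigma
    log_phi = stats.norm.logpdf(r)
    log_Phi = log_ndtr(r)
    return mu_sf + sigma * np.exp(log_phi - log_Phi)


class NoobCorrector(_DatasetTransformer):
    """Background correction from out-of-band (type I opposite-channel) signal.

    The out-of-band intensities measure pure non-specific fluorescence; a
    truncated-normal MLE per sample/channel gives the background (mu, sigma),
    an exponential signal mean follows by moments, and every in-band
    intensity is replaced by its posterior expected signal plus a small
    offset, guaranteeing strictly positive corrected intensities.
    """

    def __init__(self, offset: float = 15.0, beta_offset: float = 100.0, min_oob: int = 50):
        self.offset = offset
        self.beta_offset = beta_offset
        self.min_oob = min_oob

    def fit(self, dataset: MethylDataset) -> "NoobCorrector":
        i = self._require_intensities(dataset)
        if i.oob_meth is None or i.oob_unmeth is None:
            raise ValueError("noob requires out-of-band intensities")
        if len(i.oob_meth) + len(i.oob_unmeth) < self.min_oob:
            raise ValueError(
                f"too few out-of-band probes ({len(i.oob_meth) + len(i.oob_unmeth)} < {self.min_oob})"
            )
        self.fits_: dict[str, dict[str, NormexpFit]] = {}
        for j, sample in enumerate(i.sample_ids):
            per_channel = {}
            for channel, oob, inband in (
                ("meth", i.oob_meth, i.meth),
                ("unmeth", i.oob_unmeth, i.unmeth),
            ):
                mu, sigma = _truncnorm_mle(oob.iloc[:, j].to_numpy())
                theta = max(float(inband.iloc[:, j].mean() - mu), 10.0)
                per_channel[channel] = NormexpFit(mu=mu, sigma=sigma, theta=theta, offset=self.offset)
            self.fits_[str(sample)] = per_channel
        return self

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        i = self._require_intensities(dataset)
        meth = i.meth.to_numpy(dtype=float).copy()
        unmeth = i.unmeth.to_numpy(dtype=float).copy()
        for j, sample in enumerate(i.sample_ids):
            fits = self.fits_[str(sample)]
            for channel, X in (("meth", meth), ("unmeth", unmeth)):
                f = fits[channel]
                X[:, j] = normexp_signal(X[:, j], f.mu, f.sigma, f.theta) + f.offset
        out = IntensityMatrix(
            meth=pd.DataFrame(meth, index=i.probe_ids, columns=i.sample_ids),
            unmeth=pd.DataFrame(unmeth, index=i.probe_ids, columns=i.sample_ids),
            oob_meth=i.oob_meth,
            oob_unmeth=i.oob_unmeth,
            controls=i.controls,
        )
        return _rebuild(dataset, out, "noob", offset=self.beta_offset)


# ---------------------------------------------------------------------------
# dasen


class DasenNormalizer(_DatasetTransformer):
    """Per-type background equalisation then between-array QN within type.

    For each sample and channel the background level of each probe type is
    estimated as the mode of a kernel-density fit to the low-intensity half;
    type I intensities are shifted so their background matches type II, and
    meth/unmeth are then quantile-normalised across samples within each
    probe type separately.
    """

    def __init__(self, offset: float = 100.0, grid_size: int = 256):
        self.offset = offset
        self.grid_size = grid_size

    @staticmethod
    def _background_mode(values: np.ndarray, grid_size: int) -> float:
        v = np.asarray(values, dtype=float)
        hi = np.quantile(v, 0.5)
        lo = v.min()
        if hi <= lo:
            return float(lo)
        kde = stats.gaussian_kde(v[v <= np.quantile(v, 0.9)])
        grid = np.linspace(lo, hi, grid_size)
        return float(grid[np.argmax(kde(grid))])

    def fit(self, dataset: MethylDataset) -> "DasenNormalizer":
        i = self._require_intensities(dataset)
        design = dataset.annotation.design_type.to_numpy()
        idx1 = design == "I"
        idx2 = design == "II"
        self.background_shift_ = {}
        for channel, X in (("meth", i.meth), ("unmeth", i.unmeth)):
            shifts = np.zeros(X.shape[1])
            if idx1.any() and idx2.any():
                vals = X.to_numpy(dtype=float)
                for j in range(X.shape[1]):
                    mode1 = self._background_mode(vals[idx1, j], self.grid_size)
                    mode2 = self._background_mode(vals[idx2, j], self.grid_size)
                    shifts[j] = mode2 - mode1
            self.background_shift_[channel] = shifts
        return self

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        i = self._require_intensities(dataset)
        design = dataset.annotation.design_type.to_numpy()
        idx1 = design == "I"
        idx2 = design == "II"
        mats = {}
        for channel, X in (("meth", i.meth), ("unmeth", i.unmeth)):
            vals = X.to_numpy(dtype=float).copy()
            vals[idx1] = vals[idx1] + self.background_shift_[channel][None, :]
            for mask in (idx1, idx2):
                if mask.sum() >= 2 and vals.shape[1] >= 2:
                    vals[mask] = quantile_normalize(vals[mask])
            # flooring after between-array QN keeps the shared reference
            # distribution (and hence sorted-equality) intact
            vals = np.maximum(vals, 1.0)
            mats[channel] = pd.DataFrame(vals, index=i.probe_ids, columns=i.sample_ids)
        out = IntensityMatrix(
            meth=mats["meth"],
            unmeth=mats["unmeth"],
            oob_meth=i.oob_meth,
            oob_unmeth=i.oob_unmeth,
            controls=i.controls,
        )
        return _rebuild(dataset, out, "dasen", offset=self.offset)


# ---------------------------------------------------------------------------
# functional normalisation


class FunnormNormalizer(_DatasetTransformer):
    """Control-probe functional normalisation.

    Control-probe summaries (per-type means and sds, plus out-of-band means
    when present) are standardised and reduced to their first principal
    components; within each stratum (meth/unmeth x type I/II) the per-sample
    empirical quantile functions at fixed anchors are regressed on the PCs
    and the fitted technical deviations subtracted, keeping the across-sample
    mean quantile. Probe intensities are then mapped through the adjusted
    quantile functions by monotone interpolation.
    """

    def __init__(self, n_pcs: int = 2, n_quantile_anchors: int = 500, offset: float = 100.0):
        self.n_pcs = n_pcs
        self.n_quantile_anchors = n_quantile_anchors
        self.offset = offset

    def _control_summaries(self, i: IntensityMatrix) -> np.ndarray:
        if i.controls is None:
            raise ValueError("funnorm requires a control-probe table")
        parts = []
        ctl = i.controls
        types = ctl.index.get_level_values(0).unique() if isinstance(ctl.index, pd.MultiIndex) else [None]
        for t in types:
            block = ctl.loc[t] if t is not None else ctl
            vals = block.to_numpy(dtype=float)
            parts.append(vals.mean(axis=0))
            parts.append(vals.std(axis=0, ddof=1))
        if i.oob_meth is not None:
            parts.append(i.oob_meth.to_numpy(dtype=float).mean(axis=0))
        if i.oob_unmeth is not None:
            parts.append(i.oob_unmeth.to_numpy(dtype=float).mean(axis=0))
        return np.column_stack(parts)  # samples x summaries

    def fit(self, dataset: MethylDataset) -> "FunnormNormalizer":
        i = self._require_intensities(dataset)
        if self.n_pcs > 0 and len(i.sample_ids) < self.n_pcs + 2:
            raise ValueError("funnorm needs at least n_pcs + 2 samples")
        summaries = self._control_summaries(i)
        sds = summaries.std(axis=0, ddof=1)
        if (sds < 1e-12).all():
            raise ValueError("control summaries are constant: nothing to model")
        keep = sds > 1e-12
        z = (summaries[:, keep] - summaries[:, keep].mean(axis=0)) / sds[keep]
        if self.n_pcs > 0:
            from sklearn.decomposition import PCA

            self.pc_scores_ = PCA(n_components=min(self.n_pcs, z.shape[1]), svd_solver="full").fit_transform(z)
        else:
            self.pc_scores_ = np.zeros((z.shape[0], 0))
        return self

    def transform(self, dataset: MethylDataset) -> MethylDataset:
        i = self._require_intensities(dataset)
        if self.pc_scores_.shape[1] == 0:
            out = IntensityMatrix(
                meth=i.meth.copy(), unmeth=i.unmeth.copy(), oob_meth=i.oob_meth,
                oob_unmeth=i.oob_unmeth, controls=i.controls,
            )
            return _rebuild(dataset, out, "funnorm(n_pcs=0)", offset=self.offset)
        design = dataset.annotation.design_type.to_numpy()
        probs = np.linspace(0.0, 1.0, self.n_quantile_anchors)
        A = self.pc_scores_  # centred by construction
        hat = A @ np.linalg.pinv(A.T @ A) @ A.T  # samples x samples projector
        mats = {}
        for channel, X in (("meth", i.meth), ("unmeth", i.unmeth)):
            vals = X.to_numpy(dtype=float).copy()
            for mask in (design == "I", design == "II"):
                if mask.sum() < 2:
                    continue
                sub = vals[mask]
                Q = np.quantile(sub, probs, axis=0)  # anchors x samples
                fitted = Q @ hat.T
                adj = Q - fitted
                adj = np.maximum.accumulate(adj, axis=0)  # keep quantile functions monotone
                for j in range(sub.shape[1]):
                    xp = Q[:, j] + np.arange(len(probs)) * 1e-9
                    p = np.interp(sub[:, j], xp, probs)
                    sub[:, j] = np.interp(p, probs, adj[:, j])
                vals[mask] = np.maximum(sub, 0.0)
            mats[channel] = pd.DataFrame(vals, index=i.probe_ids, columns=i.sample_ids)
        out = IntensityMatrix(
            meth=mats["meth"], unmeth=mats["unmeth"], oob_meth=i.oob_meth,
            oob_unmeth=i.oob_unmeth, controls=i.controls,
        )
        return _rebuild(dataset, out, "funnorm", offset=self.offset)


# ---------------------------------------------------------------------------
# ComBat


@dataclass
class CombatFit:
    """Fitted empirical-Bayes batch model: shrunken per-batch location/scale."""

    batches: list[str]
    grand_mean: np.ndarray  # per probe
    pooled_var: np.ndarray  # per probe
    gamma_hat: pd.DataFrame  # probes x batches
    delta_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    prior_gamma_bar: dict = field(default_factory=dict)
    prior_tau2: dict = field(default_factory=dict)
    prior_a: dict = field(default_factory=dict)
    prior_b: dict = field(default_factory=dict)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z_b: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    n = z_b.shape[1]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(500):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class ComBat(BaseEstimator):
    """Parametric empirical-Bayes location/scale batch adjustment on M values.

    Each probe is standardised against its batch-size-weighted grand mean and
    pooled variance; per-batch per-probe location (gamma) and scale (delta)
    estimates are shrunk toward batch-level priors (normal for gamma,
    inverse-gamma for delta, hyperparameters by method of moments, iterated
    to convergence) and divided out.
    """

    def __init__(self, parametric: bool = True, conv: float = 1e-4):
        self.parametric = parametric
        self.conv = conv

    def fit(self, m: pd.DataFrame | MValueMatrix, batch: pd.Series | np.ndarray) -> "ComBat":
        X = m.m if isinstance(m, MValueMatrix) else m
        data = X.to_numpy(dtype=float)
        batch = pd.Series(np.asarray(batch, dtype=object), index=X.columns)
        levels = list(pd.unique(batch))
        counts = batch.value_counts()
        if len(levels) < 2:
            warnings.warn("single batch: ComBat is the identity")
            self.identity_ = True
            self.batch_levels_ = levels
            return self
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"batches with a single sample: {small}")
        self.identity_ = False
        self.batch_levels_ = levels
        n_total = data.shape[1]
        masks = {lv: (batch == lv).to_numpy() for lv in levels}
        batch_means = np.column_stack([data[:, masks[lv]].mean(axis=1) for lv in levels])
        weights = np.array([masks[lv].sum() / n_total for lv in levels])
        grand_mean = batch_means @ weights
        fitted = np.zeros_like(data)
        for bi, lv in enumerate(levels):
            fitted[:, masks[lv]] = batch_means[:, [bi]]
        pooled_var = ((data - fitted) ** 2).mean(axis=1)
        pooled_var = np.maximum(pooled_var, 1e-12)
        Z = (data - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

        gamma_hat = np.column_stack([Z[:, masks[lv]].mean(axis=1) for lv in levels])
        delta_hat = np.column_stack([Z[:, masks[lv]].var(axis=1, ddof=1) for lv in levels])
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        prior_gamma_bar, prior_tau2, prior_a, prior_b = {}, {}, {}, {}
        for bi, lv in enumerate(levels):
            g_bar = float(gamma_hat[:, bi].mean())
            t2 = float(gamma_hat[:, bi].var(ddof=1))
            a = _aprior(delta_hat[:, bi])
            b = _bprior(delta_hat[:, bi])
            prior_gamma_bar[lv], prior_tau2[lv], prior_a[lv], prior_b[lv] = g_bar, t2, a, b
            if self.parametric:
                g_star, d_star = _it_sol(
                    Z[:, masks[lv]], gamma_hat[:, bi], delta_hat[:, bi], g_bar, t2, a, b, self.conv
                )
            else:
                g_star, d_star = gamma_hat[:, bi], delta_hat[:, bi]
            gamma_star[:, bi] = g_star
            delta_star[:, bi] = d_star

        probe_index = X.index
        lev_str = [str(lv) for lv in levels]
        self.fit_ = CombatFit(
            batches=lev_str,
            grand_mean=grand_mean,
            pooled_var=pooled_var,
            gamma_hat=pd.DataFrame(gamma_hat, index=probe_index, columns=lev_str),
            delta_hat=pd.DataFrame(delta_hat, index=probe_index, columns=lev_str),
            gamma_star=pd.DataFrame(gamma_star, index=probe_index, columns=lev_str),
            delta_star=pd.DataFrame(delta_star, index=probe_index, columns=lev_str),
            prior_gamma_bar=prior_gamma_bar,
            prior_tau2=prior_tau2,
            prior_a=prior_a,
            prior_b=prior_b,
        )
        self._masks = masks
        return self

    def transform(self, m: pd.DataFrame | MValueMatrix, batch: pd.Series | np.ndarray) -> pd.DataFrame:
        X = m.m if isinstance(m, MValueMatrix) else m
        if self.identity_:
            return X.copy()
        data = X.to_numpy(dtype=float)
        batch = pd.Series(np.asarray(batch, dtype=object), index=X.columns)
        f = self.fit_
        Z = (data - f.grand_mean[:, None]) / np.sqrt(f.pooled_var)[:, None]
        out = np.empty_like(data)
        for lv in self.batch_levels_:
            mask = (batch == lv).to_numpy()
            g = f.gamma_star[str(lv)].to_numpy()
            d = f.delta_star[str(lv)].to_numpy()
            out[:, mask] = (Z[:, mask] - g[:, None]) / np.sqrt(d)[:, None]
        out = out * np.sqrt(f.pooled_var)[:, None] + f.grand_mean[:, None]
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    def fit_transform(self, m, batch) -> pd.DataFrame:
        return self.fit(m, batch).transform(m, batch)


def combat(
    mvals: MValueMatrix | pd.DataFrame, batch, parametric: bool = True
) -> tuple[MValueMatrix, CombatFit | None]:
    """Functional ComBat: returns adjusted M values and the fitted record."""
    est = ComBat(parametric=parametric)
    adjusted = est.fit_transform(mvals, batch)
    return MValueMatrix(adjusted), getattr(est, "fit_", None)


def combat_dataset(dataset: MethylDataset, epsilon: float = 1e-6) -> MethylDataset:
    """Apply ComBat to the dataset's M values (batches from the sample sheet)."""
    mvals = m_from_beta(BetaMatrix(dataset.beta), epsilon=epsilon)
    adjusted, _ = combat(mvals, dataset.samples.batch)
    beta = beta_from_m(adjusted)
    return MethylDataset(
        beta=beta.beta,
        annotation=dataset.annotation,
        samples=dataset.samples,
        intensities=None,
        detection_p=dataset.detection_p,
        bead_count=dataset.bead_count,
        provenance=dataset.provenance + ["combat"],
    )


# ---------------------------------------------------------------------------
# thin functional wrappers


def norm_qn(dataset: MethylDataset) -> MethylDataset:
    return QuantileNormalizer().fit_transform(dataset)


def norm_stratified_qn(dataset: MethylDataset) -> MethylDataset:
    return StratifiedQuantileNormalizer().fit_transform(dataset)


def norm_swan(dataset: MethylDataset, seed: int = 0) -> MethylDataset:
    return SwanNormalizer(seed=seed).fit_transform(dataset)


def norm_bmiq(dataset: MethylDataset, em_tol: float = 1e-4, em_max_iter: int = 100) -> MethylDataset:
    return BMIQNormalizer(em_tol=em_tol, em_max_iter=em_max_iter).fit_transform(dataset)


def norm_noob(dataset: MethylDataset, offset: float = 15.0) -> MethylDataset:
    return NoobCorrector(offset=offset).fit_transform(dataset)


def norm_dasen(dataset: MethylDataset) -> MethylDataset:
    return DasenNormalizer().fit_transform(dataset)


def norm_funnorm(dataset: MethylDataset, n_pcs: int = 2, n_quantile_anchors: int = 500) -> MethylDataset:
    return FunnormNormalizer(n_pcs=n_pcs, n_quantile_anchors=n_quantile_anchors).fit_transform(dataset)


NORMALIZERS = {
    "qn": norm_qn,
    "stratified_qn": norm_stratified_qn,
    "swan": norm_swan,
    "bmiq": norm_bmiq,
    "noob": norm_noob,
    "dasen": norm_dasen,
    "funnorm": norm_funnorm,
}
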