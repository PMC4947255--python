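"""Beta/M-value transforms and probe selection.

The proportion-methylated beta value is M/(M+U+offset): biologically
intuitive but heteroskedastic near 0 and 1. The M value, the base-2 logit of
beta, stabilises the variance and is the working scale for most statistics
here; results are mapped back to beta for interpretation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from famnorm.datatypes import BetaMatrix, IntensityMatrix, MValueMatrix


def beta_from_intensities(intensities: IntensityMatrix, offset: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + offset).

    The offset (default 100) regularises the ratio when both the methylated
    and unmethylated signals are very low; with offset > 0 all values fall in
    [0, 1).
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    meth = intensities.meth.to_numpy(dtype=float)
    unmeth = intensities.unmeth.to_numpy(dtype=float)
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, meth / np.where(denom > 0, denom, 1.0), 0.0)
    return BetaMatrix(
        pd.DataFrame(beta, index=intensities.probe_ids, columns=intensities.sample_ids)
    )


def m_from_beta(beta: BetaMatrix, epsilon: float = 1e-6) -> MValueMatrix:
    """Base-2 logit, total on [0, 1] via clipping to [epsilon, 1-epsilon]."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.clip(beta.beta.to_numpy(dtype=float), epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    return MValueMatrix(pd.DataFrame(m, index=beta.beta.index, columns=beta.beta.columns))


def beta_from_m(m: MValueMatrix) -> BetaMatrix:
    """Inverse logit: beta = 2^m / (1 + 2^m), computed overflow-safely."""
    mv = m.m.to_numpy(dtype=float)
    # expit on the natural-log scale avoids overflow for large |m|
    from scipy.special import expit

    beta = expit(mv * np.log(2.0))
    return BetaMatrix(pd.DataFrame(beta, index=m.m.index, columns=m.m.columns))


def top_variable_probes(matrix: BetaMatrix | MValueMatrix | pd.DataFrame, k: int = 1000) -> list[str]:
    """Probe ids of the k rows with largest cross-sample variance.

    Sorted by decreasing variance; ties broken by probe_id lexical order so
    the selection is deterministic.
    """
    if isinstance(matrix, BetaMatrix):
        df = matrix.beta
    elif isinstance(matrix, MValueMatrix):
        df = matrix.m
    else:
        df = matrix
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(df):
        raise ValueError(f"k={k} exceeds number of probes ({len(df)})")
    var = df.to_numpy(dtype=float).var(axis=1, ddof=1)
    order = sorted(range(len(df)), key=lambda i: (-var[i], str(df.index[i])))
    return [df.index[i] for i in order[:k]]
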