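"""Biweight midcorrelation (bicor) with Student p-values and
Benjamini-Hochberg q-values.

bicor is a robust correlation: each vector is centered on its median,
scaled by 9x its median absolute deviation (MAD), and observations beyond
that window receive zero weight, so a handful of outliers cannot inflate
the coefficient.  With weights ``w_i = (1 - u_i^2)^2 * 1(|u_i| < 1)`` for
``u_i = (x_i - med) / (9 MAD)`` the transformed coordinates are

    a_i = (x_i - med) w_i / sqrt(sum_j ((x_j - med) w_j)^2)

and ``bicor(x, y) = sum_i a_i b_i``, clamped to [-1, 1].  When a vector's
MAD is zero but its variance is not, that vector falls back to the
Pearson standardisation (mean-centred, L2-normalised); the occurrence is
logged.  P-values use the Student t approximation with n - 2 degrees of
freedom, the same large-sample treatment used for Pearson's r.

Missing data are handled by pairwise-complete deletion: each gene pair is
correlated over the subjects observed in both vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionPanel
from .errors import InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

#: records with fewer pairwise-complete subjects than this carry NaN statistics
DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class CorrelationRecord:
    """One gene-tissue ~ gene-tissue correlation test."""

    source_gene: str
    source_tissue: str
    gene: str
    tissue: str
    r: float
    n: int
    p: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# The biweight transform
# ---------------------------------------------------------------------------

def _biweight_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise biweight transform of a complete (no-NaN) 2-D array.

    Returns the matrix of ``a_i`` coordinates, so that the bicor of any
    two rows is the dot product of their transforms.  Rows with zero MAD
    but positive variance use the Pearson standardisation; rows with zero
    dispersion come back as all-NaN.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    d = X - med
    mad = np.median(np.abs(d), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = d / (9.0 * mad)
        uc = np.clip(u, -1.0, 1.0)  # w is zero outside the window anyway
        w = (1.0 - uc**2) ** 2 * (np.abs(u) < 1.0)
        num = d * w
        norm = np.sqrt(np.sum(num**2, axis=1, keepdims=True))
        a = num / norm
    # fallback and degenerate rows
    sd = X.std(axis=1)
    bad = (mad[:, 0] == 0) | (norm[:, 0] == 0) | ~np.isfinite(norm[:, 0])
    fallback = bad & (sd > 0)
    degenerate = sd == 0
    if fallback.any():
        logger.info("bicor: Pearson fallback for %d zero-MAD vector(s)", fallback.sum())
        c = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
        a[fallback] = c / np.sqrt(np.sum(c**2, axis=1, keepdims=True))
    if degenerate.any():
        a[degenerate] = np.nan
    return a


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete).

    Raises
    ------
    InsufficientDataError
        if fewer than 3 pairwise-complete observations remain.
    UndefinedCorrelationError
        if either vector has zero dispersion on the complete subset.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {n}")
    a = _biweight_rows(np.vstack([x[ok], y[ok]]))
    if np.isnan(a).any():
        raise UndefinedCorrelationError("zero dispersion in an input vector")
    return float(np.clip(a[0] @ a[1], -1.0, 1.0))


def bicor_pvalue(r: float, n: int) -> float:
    """Two-sided Student p-value for a bicor coefficient at sample size n.

    ``t = r sqrt((n-2)/(1-r^2))`` against t(n-2); ``|r| = 1`` gives p = 0
    exactly (reported as 0, not clamped to machine epsilon).
    """
    if n < 3:
        raise InsufficientDataError(f"need n >= 3, got {n}")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _pvalues(R: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Student p-values; NaN where r is NaN or n < 3."""
    R = np.asarray(R, dtype=float)
    N = np.asarray(N, dtype=float)
    P = np.full(R.shape, np.nan)
    ok = np.isfinite(R) & (N >= 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R[ok] * np.sqrt((N[ok] - 2) / (1.0 - R[ok] ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), N[ok] - 2)
    p[np.abs(R[ok]) == 1.0] = 0.0
    P[ok] = p
    return P


def _mask_groups(M: np.ndarray):
    """Group rows of a boolean mask matrix by identical pattern."""
    uniq, inverse = np.unique(M, axis=0, return_inverse=True)
    for g in range(uniq.shape[0]):
        yield np.flatnonzero(inverse == g), uniq[g]


def bicor_cross(X: np.ndarray, Y: np.ndarray, min_n: int = 3):
    """All-pairs bicor between rows of X and rows of Y (pairwise-complete).

    X is (mx, n) and Y is (my, n) over a shared column (subject) space;
    NaN marks missing.  Returns ``(R, N)`` where R is (mx, my) with NaN
    for pairs below ``min_n`` complete observations or with zero
    dispersion, and N counts the complete observations of each pair.

    Rows are grouped by missingness pattern so the common case —
    tissue-level subject dropout with identical masks within a tissue —
    reduces to one biweight transform and a matrix product per group.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the subject dimension")
    R = np.full((X.shape[0], Y.shape[0]), np.nan)
    N = np.zeros((X.shape[0], Y.shape[0]), dtype=int)
    mx = np.isfinite(X)
    my = np.isfinite(Y)
    for xi, xmask in _mask_groups(mx):
        for yi, ymask in _mask_groups(my):
            shared = xmask & ymask
            n = int(shared.sum())
            N[np.ix_(xi, yi)] = n
            if n < max(min_n, 3):
                continue
            ax = _biweight_rows(X[np.ix_(xi, np.flatnonzero(shared))])
            ay = _biweight_rows(Y[np.ix_(yi, np.flatnonzero(shared))])
            with np.errstate(invalid="ignore"):
                R[np.ix_(xi, yi)] = np.clip(ax @ ay.T, -1.0, 1.0)
    return R, N


# ---------------------------------------------------------------------------
# Panel sweep
# ---------------------------------------------------------------------------

def bicor_against_panel(
    source: tuple[str, str],
    panel: ExpressionPanel,
    exclude_self: bool = True,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Correlate one source gene-tissue against every gene-tissue
    combination in the panel.

    Returns a long DataFrame with columns ``source_gene, source_tissue,
    gene, tissue, bicor, n, p`` — one row per target combination, with
    NaN statistics (never a dropped row) where fewer than ``min_n``
    pairwise-complete subjects exist, so downstream counts stay
    auditable.  q-values are not attached here; the caller decides the
    adjustment family.
    """
    gene, tissue = source
    x = panel.gene_vector(gene, tissue).to_numpy()[None, :]
    frames = []
    for target_tissue in panel.tissues:
        mat = panel.aligned_matrix(target_tissue)
        R, N = bicor_cross(x, mat.to_numpy(), min_n=min_n)
        P = _pvalues(R, N)
        frames.append(
            pd.DataFrame(
                {
                    "source_gene": gene,
                    "source_tissue": tissue,
                    "gene": mat.index,
                    "tissue": target_tissue,
                    "bicor": R[0],
                    "n": N[0],
                    "p": P[0],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    if exclude_self:
        records = records.loc[
            ~((records["gene"] == gene) & (records["tissue"] == tissue))
        ].reset_index(drop=True)
    return records


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    Missing entries pass through as NaN and do not count toward the
    family size m.  Input order is preserved.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        bad = p[ok][(p[ok] < 0) | (p[ok] > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
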