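"""Signature-based deconvolution of bulk expression into cell-type
proportions, and correlation of the inferred fractions with gene
expression.

Per subject the model is ``b ~ S f`` with a genes x cell-types signature
S: the fractions are estimated by non-negative least squares and
projected onto the probability simplex by renormalisation, the
constrained-least-squares formulation popularised for bulk RNA-seq.  The
scale-then-normalise route makes the estimate invariant to positive
rescaling of the bulk vector, so TPM-like and count-like inputs agree up
to the per-subject residual.  Bulk and signature are expected in linear
(non-log) units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_io import ExpressionPanel
from .errors import InsufficientDataError, SignatureError
from .robust_corr import bh_adjust, bicor_cross, _pvalues

#: minimum genes shared between bulk and signature
MIN_SHARED_GENES = 20


@dataclass
class DeconResult:
    """Inferred cell-type proportions with per-subject fit residuals."""

    fractions: pd.DataFrame  # subjects x cell types, rows on the simplex
    residuals: pd.Series  # L2 residual of the normalised fit per subject
    shared_genes: pd.Index


def _check_linear_units(name: str, values: np.ndarray) -> None:
    finite = values[np.isfinite(values)]
    if finite.size and finite.max() < 30:
        warnings.warn(
            f"{name} max value {finite.max():.3g} < 30 — input may be "
            "log-scaled; deconvolution expects linear units",
            stacklevel=3,
        )


def decon_lsq(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    min_shared: int = MIN_SHARED_GENES,
) -> DeconResult:
    """Estimate per-subject cell-type proportions.

    Parameters
    ----------
    bulk
        Genes x subjects expression of one tissue (a panel slice).
    signature
        Genes x cell-types reference expression; must be full column
        rank on the genes shared with the bulk matrix.

    Genes are intersected by exact symbol.  Subjects with missing values
    use only their observed shared genes.  Rows of the returned fraction
    table are non-negative and sum to one; a subject whose fit is
    identically zero (no signal on the shared genes) gets a uniform row
    with a warning.
    """
    shared = bulk.index.intersection(signature.index)
    if len(shared) < min_shared:
        raise SignatureError(
            f"only {len(shared)} genes shared between bulk ({bulk.shape[0]}) "
            f"and signature ({signature.shape[0]}); need >= {min_shared}"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise SignatureError(
            f"signature is rank deficient on the {len(shared)} shared genes"
        )
    _check_linear_units("bulk", bulk.to_numpy(dtype=float))
    _check_linear_units("signature", S)
    B = bulk.loc[shared].to_numpy(dtype=float)
    k = S.shape[1]
    fracs = np.empty((bulk.shape[1], k))
    resid = np.empty(bulk.shape[1])
    for j in range(bulk.shape[1]):
        b = B[:, j]
        ok = np.isfinite(b)
        if ok.sum() < min_shared:
            raise InsufficientDataError(
                f"subject {bulk.columns[j]!r} has only {int(ok.sum())} observed "
                f"shared genes; need >= {min_shared}"
            )
        f, rnorm = nnls(S[ok], b[ok])
        total = f.sum()
        if total == 0:
            warnings.warn(
                f"subject {bulk.columns[j]!r}: zero fit, uniform fractions assigned",
                stacklevel=2,
            )
            fracs[j] = 1.0 / k
            resid[j] = float(np.linalg.norm(b[ok]))
        else:
            fracs[j] = f / total
            # residual of the unit-sum fit against the same-scaled bulk
            resid[j] = rnorm / total
    fractions = pd.DataFrame(fracs, index=bulk.columns, columns=signature.columns)
    return DeconResult(fractions, pd.Series(resid, index=bulk.columns), shared)


def celltype_gene_correlation(
    fractions: pd.DataFrame,
    panel: ExpressionPanel,
    gene: str,
    tissue: str,
) -> pd.DataFrame:
    """Bicor of one gene's expression with every inferred cell-type
    fraction over shared subjects; BH q across cell types.

    A constant fraction column yields NaN statistics for that cell type
    without affecting the others.
    """
    expr = panel.gene_vector(gene, tissue)
    shared = fractions.index.intersection(expr.index[np.isfinite(expr)])
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} subjects shared between fractions and "
            f"{gene}@{tissue}; need >= 3"
        )
    x = expr.loc[shared].to_numpy()[None, :]
    F = fractions.loc[shared].to_numpy().T  # cell types x subjects
    R, N = bicor_cross(x, F, min_n=3)
    P = _pvalues(R, N)
    out = pd.DataFrame(
        {
            "cell_type": fractions.columns,
            "r": R[0],
            "n": N[0],
            "p": P[0],
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
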