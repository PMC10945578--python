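"""Gene ~ clinical-trait correlation for strain panels (HMDP-style).

Expression and traits are compared at the strain (or subject) level over
pairwise-complete identifiers; the top traits are ranked by p-value, the
scale used for display, with p = 0.05 and p = 0.001 as the conventional
reference lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import ExpressionPanel
from .errors import InsufficientDataError
from .robust_corr import bh_adjust, bicor_cross, _pvalues

#: reference significance lines annotated on trait rankings
REFERENCE_P = (0.05, 0.001)


def gene_trait_correlations(
    gene: str,
    tissue: str,
    panel: ExpressionPanel,
    traits: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Bicor of one gene-tissue against every trait.

    Traits sharing fewer than ``min_n`` complete strains with the
    expression vector carry NaN statistics.  q-values are BH-adjusted
    across traits; ``direction`` is the sign of r.
    """
    expr = panel.gene_vector(gene, tissue)
    shared = traits.index.intersection(expr.index)
    if len(shared) == 0:
        raise InsufficientDataError(
            f"no subject/strain IDs shared between the panel and the trait table"
        )
    x = expr.loc[shared].to_numpy()[None, :]
    T = traits.loc[shared].to_numpy(dtype=float).T  # traits x strains
    R, N = bicor_cross(x, T, min_n=min_n)
    P = _pvalues(R, N)
    out = pd.DataFrame(
        {
            "gene": gene,
            "tissue": tissue,
            "trait": traits.columns,
            "r": R[0],
            "n": N[0],
            "p": P[0],
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["r"] >= 0, "positive", "negative")
    out.loc[~np.isfinite(out["r"]), "direction"] = ""
    return out


def top_traits(records: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k most significant traits, ordered by p ascending (the
    -log10 p display order), ties broken by trait name.

    Each record is annotated with whether it crosses the p = 0.05 and
    p = 0.001 reference thresholds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rec = records.loc[np.isfinite(records["p"])].copy()
    rec = rec.sort_values(["p", "trait"], kind="mergesort").head(k)
    rec["crosses_p05"] = rec["p"] < REFERENCE_P[0]
    rec["crosses_p001"] = rec["p"] < REFERENCE_P[1]
    return rec.reset_index(drop=True)
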