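"""The headline pan-tissue query: one gene in one tissue against every
other gene-tissue combination, with FDR-binned tissue summaries and
deterministic top-correlate lists.

The BH family of a query is *all* gene-tissue tests it emits, jointly —
never per tissue — so the tissue-binned summaries compare tissues within
one adjusted family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionPanel
from .robust_corr import DEFAULT_MIN_N, bh_adjust, bicor_against_panel


@dataclass
class QueryResult:
    """Pan-tissue correlation table for one source gene-tissue."""

    source_gene: str
    source_tissue: str
    records: pd.DataFrame  # columns: source_gene, source_tissue, gene, tissue, bicor, n, p, q
    thresholds: tuple[float, ...] = (0.1, 0.01, 0.001)


@dataclass
class TissueBinSummary:
    """Per-tissue counts of significant records at one q threshold —
    the tabular form of the web tool's pie charts."""

    q_threshold: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        tot = self.total
        return {t: (c / tot if tot else 0.0) for t, c in self.counts.items()}


def pan_tissue_query(
    gene: str,
    tissue: str,
    panel: ExpressionPanel,
    min_n: int = DEFAULT_MIN_N,
    thresholds: tuple[float, ...] = (0.1, 0.01, 0.001),
) -> QueryResult:
    """Correlate ``gene`` in ``tissue`` against all other gene-tissue
    combinations and attach BH q-values over the whole record family.

    The source tissue's other genes are included (within-tissue
    correlates); the source gene-tissue itself is excluded.  Output is a
    pure function of the panel — no hidden randomness.
    """
    records = bicor_against_panel((gene, tissue), panel, exclude_self=True, min_n=min_n)
    records = records.copy()
    records["q"] = bh_adjust(records["p"].to_numpy())
    return QueryResult(gene, tissue, records, tuple(thresholds))


def bin_by_tissue(result: QueryResult, q_threshold: float) -> TissueBinSummary:
    """Count significant records per target tissue at one q threshold."""
    if not (0.0 < q_threshold < 1.0):
        raise ValueError(f"q threshold must be in (0, 1), got {q_threshold}")
    rec = result.records
    sig = rec.loc[rec["q"] < q_threshold]
    counts = sig.groupby("tissue", sort=False).size().to_dict()
    return TissueBinSummary(q_threshold, {t: int(c) for t, c in counts.items()})


def top_correlates(
    result: QueryResult,
    n: int,
    scope: str = "all",
    direction: str = "absolute",
) -> pd.DataFrame:
    """The strongest correlates of the query source, deterministically
    ordered.

    Parameters
    ----------
    scope
        ``"within"`` restricts to the source tissue, ``"peripheral"`` to
        all other tissues, ``"all"`` keeps everything.
    direction
        ``"absolute"`` ranks by |r|, ``"positive"`` by signed r
        descending, ``"negative"`` by signed r ascending.

    Ties in the ranking key are broken by p ascending, then gene symbol,
    then tissue — fixed ordering so repeated runs are byte-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rec = result.records
    rec = rec.loc[np.isfinite(rec["bicor"])]
    if scope == "within":
        rec = rec.loc[rec["tissue"] == result.source_tissue]
    elif scope == "peripheral":
        rec = rec.loc[rec["tissue"] != result.source_tissue]
    elif scope != "all":
        raise ValueError(f"scope must be within|peripheral|all, got {scope!r}")
    rec = rec.copy()
    if direction == "absolute":
        rec["_key"] = -rec["bicor"].abs()
    elif direction == "positive":
        rec["_key"] = -rec["bicor"]
    elif direction == "negative":
        rec["_key"] = rec["bicor"]
    else:
        raise ValueError(f"direction must be positive|negative|absolute, got {direction!r}")
    rec = rec.sort_values(
        ["_key", "p", "gene", "tissue"], kind="mergesort"
    ).drop(columns="_key")
    return rec.head(n).reset_index(drop=True)


def group_mean_summary(
    panel: ExpressionPanel,
    gene: str,
    tissue: str,
    groups: pd.Series | dict,
) -> pd.DataFrame:
    """Mean, SD and n of one gene's expression per subject-group label
    (e.g. reported sex or age bracket).  Descriptive only — no
    inferential statistic is attached.
    """
    x = panel.gene_vector(gene, tissue)
    g = pd.Series(groups)
    df = pd.DataFrame({"value": x, "group": g.reindex(x.index)}).dropna()
    out = df.groupby("group")["value"].agg(mean="mean", sd="std", n="count")
    return out.reset_index()
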