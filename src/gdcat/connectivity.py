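"""Pathway-level cross-tissue connectivity survey.

For a gene set, every member gene in tissue A is correlated with every
member gene in tissue B across individuals, for all unordered tissue
pairs; within-tissue correlations are omitted.  Counts of tests passing
each significance threshold populate a tissue x tissue matrix,
normalised by pathway size, and tissues are rank-ordered by their total
significant cross-tissue correlations.  Size-matched random gene sets
provide the null against which pathway-specific structure is judged, and
a missingness diagnostic checks whether low-ranked tissues owe their
rank to sparse data rather than weak biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionPanel
from .errors import GDCATError, InsufficientDataError, UndefinedCorrelationError
from .robust_corr import DEFAULT_MIN_N, bh_adjust, bicor, bicor_cross, bicor_pvalue, _pvalues

#: (kind, cutoff) pairs; kind "p" tests raw p-values, "q" BH-adjusted ones
DEFAULT_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("p", 1e-3),
    ("p", 1e-6),
    ("q", 0.1),
    ("q", 0.01),
)


def threshold_label(thr: tuple[str, float]) -> str:
    kind, value = thr
    return f"{kind}<{value:g}"


@dataclass
class PathwayConnectivity:
    """Cross-tissue significant-correlation counts for one gene set."""

    name: str
    size: int  # pathway size used for normalisation
    thresholds: tuple[tuple[str, float], ...]
    counts: dict[str, pd.DataFrame]  # label -> symmetric tissue x tissue ints
    normalized: dict[str, pd.DataFrame]  # counts / size
    totals: pd.DataFrame  # tissues x threshold labels
    tests: pd.DataFrame  # long audit table of every cross-tissue test
    unit: str = "pairs"


@dataclass
class TissueRank:
    """Tissues ordered by significant cross-tissue correlations at a
    reference threshold; counts at every threshold travel along."""

    order: list[str]
    reference: tuple[str, float]
    totals: pd.DataFrame  # tissues x threshold labels, rows in rank order

    def tertile(self, which: str) -> list[str]:
        """Tissues in the top / middle / bottom third of the ranking.

        Tertile size is floor(T/3); the middle absorbs the remainder, so
        rank ties sit in the better tertile by construction (the order
        is already deterministic).
        """
        t = len(self.order)
        k = t // 3
        if which == "top":
            return self.order[:k]
        if which == "middle":
            return self.order[k : t - k]
        if which == "bottom":
            return self.order[t - k :]
        raise ValueError(f"tertile must be top|middle|bottom, got {which!r}")


@dataclass
class RandomSetNull:
    """Per-tissue count distributions over random size-matched gene sets."""

    size: int
    n_draws: int
    draws: list[pd.DataFrame] = field(default_factory=list)  # totals per draw

    def summary(self) -> dict[str, pd.DataFrame]:
        stacked = {
            "mean": sum(self.draws) / len(self.draws),
            "sd": pd.concat(self.draws).groupby(level=0).std(ddof=1),
        }
        return stacked


def pathway_cross_tissue(
    panel: ExpressionPanel,
    members,
    thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS,
    name: str = "pathway",
    min_n: int = DEFAULT_MIN_N,
    unit: str = "pairs",
) -> PathwayConnectivity:
    """Count significant cross-tissue correlations among a gene set.

    Every (gene g in tissue a) x (gene h in tissue b) pair with a != b is
    tested; q-values are BH-adjusted over the pathway's full cross-tissue
    family.  ``unit="pairs"`` counts significant tests; ``"unique-genes"``
    counts distinct member genes participating in at least one
    significant test of the cell.  The normalised matrix divides by the
    pathway size (number of distinct member genes supplied).
    """
    if unit not in ("pairs", "unique-genes"):
        raise ValueError(f"unit must be 'pairs' or 'unique-genes', got {unit!r}")
    members = list(dict.fromkeys(members))
    size = len(members)
    tissues = panel.tissues
    present = {
        t: [g for g in members if g in set(panel.genes(t))] for t in tissues
    }
    n_instances = sum(len(v) for v in present.values())
    tissues_hit = sum(1 for v in present.values() if v)
    if n_instances < 2 or tissues_hit < 2:
        raise GDCATError(
            f"pathway {name!r}: needs members mappable in >=2 tissues "
            f"({n_instances} gene-tissue instances across {tissues_hit} tissue(s))"
        )
    frames = []
    for i, a in enumerate(tissues):
        if not present[a]:
            continue
        A = panel.aligned_matrix(a).loc[present[a]].to_numpy()
        for b in tissues[i + 1 :]:
            if not present[b]:
                continue
            B = panel.aligned_matrix(b).loc[present[b]].to_numpy()
            R, N = bicor_cross(A, B, min_n=min_n)
            P = _pvalues(R, N)
            ga, gb = np.meshgrid(
                np.arange(len(present[a])), np.arange(len(present[b])), indexing="ij"
            )
            frames.append(
                pd.DataFrame(
                    {
                        "tissue_a": a,
                        "tissue_b": b,
                        "gene_a": np.asarray(present[a])[ga.ravel()],
                        "gene_b": np.asarray(present[b])[gb.ravel()],
                        "r": R.ravel(),
                        "n": N.ravel(),
                        "p": P.ravel(),
                    }
                )
            )
    tests = pd.concat(frames, ignore_index=True)
    tests["q"] = bh_adjust(tests["p"].to_numpy())

    counts: dict[str, pd.DataFrame] = {}
    normalized: dict[str, pd.DataFrame] = {}
    labels = [threshold_label(t) for t in thresholds]
    totals = pd.DataFrame(0.0, index=tissues, columns=labels)
    for thr, label in zip(thresholds, labels):
        kind, cutoff = thr
        sig = tests.loc[tests[kind] < cutoff]
        mat = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
        for (a, b), group in sig.groupby(["tissue_a", "tissue_b"], sort=False):
            if unit == "pairs":
                c = len(group)
            else:
                c = len(set(group["gene_a"]) | set(group["gene_b"]))
            mat.loc[a, b] += c
            mat.loc[b, a] += c
        counts[label] = mat
        normalized[label] = mat / size
        totals[label] = mat.sum(axis=1).astype(float)
    return PathwayConnectivity(
        name, size, tuple(thresholds), counts, normalized, totals, tests, unit
    )


def tissue_ranking(
    connectivity: PathwayConnectivity,
    reference: tuple[str, float],
) -> TissueRank:
    """Rank tissues by total significant cross-tissue correlations at the
    reference threshold (descending; ties broken lexicographically).

    Counts at the other thresholds are reported in the same fixed order,
    matching the convention of ranking once and re-reporting.
    """
    label = threshold_label(reference)
    if label not in connectivity.totals.columns:
        raise KeyError(
            f"reference {label} not among computed thresholds "
            f"{list(connectivity.totals.columns)}"
        )
    totals = connectivity.totals
    order = sorted(totals.index, key=lambda t: (-totals.loc[t, label], t))
    return TissueRank(order, reference, totals.loc[order])


def random_set_null(
    panel: ExpressionPanel,
    size: int,
    n_draws: int,
    seed: int,
    thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS,
    min_n: int = DEFAULT_MIN_N,
) -> RandomSetNull:
    """Repeat the cross-tissue survey on uniformly drawn gene sets of the
    pathway's size.

    Genes are drawn from the pool present in every tissue, so each draw
    is comparable across the full tissue grid.  Fully seeded.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    pool: set[str] | None = None
    for t in panel.tissues:
        g = set(panel.genes(t))
        pool = g if pool is None else pool & g
    pool_sorted = sorted(pool or set())
    if size > len(pool_sorted):
        raise ValueError(
            f"size {size} exceeds the {len(pool_sorted)} genes shared by all tissues"
        )
    rng = np.random.default_rng(seed)
    null = RandomSetNull(size=size, n_draws=n_draws)
    for d in range(n_draws):
        draw = list(rng.choice(pool_sorted, size=size, replace=False))
        conn = pathway_cross_tissue(
            panel, draw, thresholds=thresholds, name=f"random_{d}", min_n=min_n
        )
        null.draws.append(conn.totals)
    return null


def tissue_missingness(panel: ExpressionPanel) -> pd.Series:
    """Absent subject-gene values per tissue, counted against the full
    subject registry (an unassayed subject contributes one missing value
    per gene)."""
    return pd.Series(
        {t: int(panel.aligned_matrix(t).isna().to_numpy().sum()) for t in panel.tissues},
        name="missing_values",
    )


def missingness_diagnostic(
    panel: ExpressionPanel,
    rankings,
    tertile: str = "bottom",
) -> tuple[float, float]:
    """Correlate per-tissue missing-data burden with significant-count
    totals within one tertile of the connectivity ranking.

    ``rankings`` may be a single TissueRank or a list; with a list the
    (tissue, pathway) points of the chosen tertile are pooled across
    pathways before correlating, which is how a per-tertile test gains
    power.  Returns ``(bicor, p)``; zero dispersion in either variable
    (e.g. no missing data anywhere) yields ``(nan, nan)``.
    """
    if isinstance(rankings, TissueRank):
        rankings = [rankings]
    missing = tissue_missingness(panel)
    xs, ys = [], []
    for rank in rankings:
        label = threshold_label(rank.reference)
        for t in rank.tertile(tertile):
            xs.append(float(missing.loc[t]))
            ys.append(float(rank.totals.loc[t, label]))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"tertile {tertile!r} pools only {len(xs)} tissue point(s); need >= 3"
        )
    try:
        r = bicor(np.array(xs), np.array(ys))
    except UndefinedCorrelationError:
        return float("nan"), float("nan")
    return r, bicor_pvalue(r, len(xs))
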