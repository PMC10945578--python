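"""Readers, writers and containers for expression panels, gene sets,
cell-type signatures and clinical trait tables.

All tabular formats are tab-separated with row labels in the first column
and a header row of subject / cell-type IDs.  Missing values are written as
``NA``; both ``NA`` and the empty cell are accepted on read.  Gene sets use
the standard GMT dialect (name TAB description TAB gene TAB gene ...).

Subjects are matched across tissues by exact string ID — no fuzzy joins.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: tokens accepted as missing on input
NA_TOKENS = ("", "NA")


# ---------------------------------------------------------------------------
# Expression panel
# ---------------------------------------------------------------------------

class ExpressionPanel:
    """Per-tissue genes x subjects expression matrices over a shared
    subject registry.

    Parameters
    ----------
    matrices
        Mapping of tissue label to a genes x subjects DataFrame of
        non-negative expression values (TPM-like or strain means).  NaN
        marks a missing measurement.

    Notes
    -----
    The subject registry is the ordered union of subject IDs across
    tissues (order of first appearance).  ``presence`` records which
    subjects were assayed in which tissue; a subject absent from a
    tissue's columns is treated as missing for every gene of that tissue.
    """

    def __init__(self, matrices: Mapping[str, pd.DataFrame]):
        self._matrices: dict[str, pd.DataFrame] = {}
        registry: list[str] = []
        seen: set[str] = set()
        for tissue, mat in matrices.items():
            mat = mat.copy()
            mat.index = mat.index.astype(str)
            mat.columns = mat.columns.astype(str)
            if mat.index.has_duplicates:
                dups = mat.index[mat.index.duplicated()].unique().tolist()
                raise FormatError(
                    f"duplicate gene symbol(s) {dups} in tissue {tissue!r}"
                )
            if mat.columns.has_duplicates:
                dups = mat.columns[mat.columns.duplicated()].unique().tolist()
                raise FormatError(
                    f"duplicate subject ID(s) {dups} in tissue {tissue!r}"
                )
            values = mat.to_numpy(dtype=float)
            if np.isinf(values).any():
                raise FormatError(f"non-finite expression value in tissue {tissue!r}")
            with np.errstate(invalid="ignore"):
                if (values < 0).any():
                    raise FormatError(f"negative expression value in tissue {tissue!r}")
            self._matrices[tissue] = mat.astype(float)
            for s in mat.columns:
                if s not in seen:
                    seen.add(s)
                    registry.append(s)
        self._registry = pd.Index(registry, name="subject")
        self._presence = pd.DataFrame(
            {t: self._registry.isin(m.columns) for t, m in self._matrices.items()},
            index=self._registry,
        ).T

    # -- basic accessors ----------------------------------------------------

    @property
    def tissues(self) -> list[str]:
        return list(self._matrices)

    @property
    def subjects(self) -> pd.Index:
        """Ordered union of subject IDs across all tissues."""
        return self._registry

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean tissues x subjects table of per-tissue assay presence."""
        return self._presence

    def genes(self, tissue: str) -> pd.Index:
        return self.matrix(tissue).index

    def matrix(self, tissue: str) -> pd.DataFrame:
        try:
            return self._matrices[tissue]
        except KeyError:
            raise KeyError(
                f"unknown tissue {tissue!r}; panel has {self.tissues}"
            ) from None

    def aligned_matrix(self, tissue: str) -> pd.DataFrame:
        """Tissue matrix reindexed to the full subject registry.

        Subjects not assayed in the tissue appear as NaN columns, so a
        single column space serves every cross-tissue computation.
        """
        return self.matrix(tissue).reindex(columns=self._registry)

    def gene_vector(self, gene: str, tissue: str) -> pd.Series:
        """One gene's expression across the full registry (NaN where absent)."""
        mat = self.aligned_matrix(tissue)
        if gene not in mat.index:
            from difflib import get_close_matches

            from .errors import GeneLookupError

            near = get_close_matches(gene, list(mat.index), n=3)
            raise GeneLookupError(
                f"gene {gene!r} not found in tissue {tissue!r}", suggestions=near
            )
        return mat.loc[gene]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionPanel):
            return NotImplemented
        if self.tissues != other.tissues:
            return False
        return all(self.matrix(t).equals(other.matrix(t)) for t in self.tissues)

    def __repr__(self) -> str:
        shapes = {t: self.matrix(t).shape for t in self.tissues}
        return f"ExpressionPanel(tissues={shapes}, subjects={len(self._registry)})"


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(NA_TOKENS),
        keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row label(s) {dups} in {path}")
    try:
        out = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return out


def read_expression_panel(paths: Mapping[str, str | Path]) -> ExpressionPanel:
    """Load one tab-separated genes x subjects file per tissue.

    The registry is the union of subject IDs across files; per-tissue
    presence flags are derived from each file's columns.
    """
    matrices = {}
    for tissue, path in paths.items():
        try:
            matrices[tissue] = _read_matrix(path)
        except FormatError as exc:
            raise FormatError(f"tissue {tissue!r}: {exc}") from exc
    return ExpressionPanel(matrices)


def write_expression_panel(panel: ExpressionPanel, paths: Mapping[str, str | Path]) -> None:
    for tissue, path in paths.items():
        panel.matrix(tissue).to_csv(path, sep="\t", na_rep="NA")


def filter_complete_genes(panel: ExpressionPanel, scope: str = "per-tissue") -> ExpressionPanel:
    """Keep genes whose observed values are all strictly positive.

    This is the guard against genes detected only in some individuals,
    whose zeros would otherwise create spurious correlation structure.
    Missing cells (absent subject or NA measurement) do not count against
    a gene; they are handled downstream by pairwise-complete deletion.

    Parameters
    ----------
    scope
        ``"per-tissue"`` (default): a gene may survive in one tissue and
        be dropped from another.  ``"global"``: a gene with a zero in any
        tissue is dropped from all tissues.
    """
    if scope not in ("per-tissue", "global"):
        raise ValueError(f"scope must be 'per-tissue' or 'global', got {scope!r}")
    passing: dict[str, pd.Index] = {}
    for tissue in panel.tissues:
        mat = panel.matrix(tissue)
        ok = ((mat > 0) | mat.isna()).all(axis=1)
        passing[tissue] = mat.index[ok]
    if scope == "global":
        failed_anywhere: set[str] = set()
        for tissue in panel.tissues:
            failed_anywhere.update(set(panel.genes(tissue)) - set(passing[tissue]))
        passing = {
            t: idx[~idx.isin(sorted(failed_anywhere))] for t, idx in passing.items()
        }
    out = {}
    for tissue in panel.tissues:
        kept = panel.matrix(tissue).loc[passing[tissue]]
        if kept.shape[0] == 0:
            warnings.warn(
                f"tissue {tissue!r} has no genes left after the positive-value filter",
                stacklevel=2,
            )
        out[tissue] = kept
    return ExpressionPanel(out)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        deduped = tuple(dict.fromkeys(genes))
        if not deduped:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = (description, deduped)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            try:
                coll.add(name, desc, genes)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.names():
            desc, genes = coll.sets[name]
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Trait tables and signature matrices
# ---------------------------------------------------------------------------

def read_traits(path: str | Path) -> pd.DataFrame:
    """Subjects/strains x traits table; missing cells preserved as NaN.

    Rows are subject or strain IDs, columns are trait names; downstream
    statistics use pairwise-complete observations.
    """
    df = _read_matrix(path)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate trait name(s) {dups} in {path}")
    df.index.name = "subject"
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", na_rep="NA")


def read_signature(path: str | Path) -> pd.DataFrame:
    """Genes x cell-types reference expression for deconvolution.

    Entries must be finite and non-negative and the matrix must have at
    least two cell-type columns.
    """
    df = _read_matrix(path)
    validate_signature(df)
    return df


def validate_signature(sig: pd.DataFrame) -> None:
    if sig.shape[1] < 2:
        raise FormatError(
            f"signature needs >=2 cell types, got {sig.shape[1]}"
        )
    vals = sig.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise FormatError("signature contains missing or non-finite entries")
    if (vals < 0).any():
        raise FormatError("signature contains negative entries")
    if sig.index.has_duplicates:
        raise FormatError("duplicate gene symbols in signature")


def write_signature(sig: pd.DataFrame, path: str | Path) -> None:
    sig.to_csv(path, sep="\t")
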