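"""Synthetic multi-tissue expression panels with planted, analytically
controlled correlation structure.

The generator uses a Gaussian latent-factor design: every gene-tissue
combination has a latent standard-normal vector across subjects; planted
hub targets are built as ``r z + sqrt(1 - r^2) eps`` against the hub's
latent vector, gene-set blocks share a common factor at loading
``sqrt(rho)`` (pairwise latent correlation rho), and everything else is
independent noise.  Latents map to a positive expression scale as
``exp(scale z + loc)`` — mildly log-normal, so the zero-positive filter
is meaningful while planted latent correlations survive nearly intact on
the expression scale (the mild default scale keeps the transform close
to affine over the bulk of the distribution).

Missingness is per-tissue Bernoulli subject dropout, the dominant
structure of real multi-tissue panels where not every donor is assayed
in every tissue.  Every planted edge is recorded in a manifest so each
analysis module can be tested against ground truth.  All outputs are
pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionPanel

GeneTissue = tuple[str, str]


@dataclass
class HubSpec:
    """One source gene-tissue with planted cross-combination partners."""

    source: GeneTissue
    targets: list[tuple[str, str, float]]  # (gene, tissue, latent r)


@dataclass
class BlockSpec:
    """A gene-set block sharing a latent factor at pairwise correlation rho."""

    name: str
    members: list[GeneTissue]
    rho: float


@dataclass
class TraitSpec:
    """A clinical trait linearly coupled to one driver gene-tissue."""

    name: str
    driver: GeneTissue
    r: float


@dataclass
class SimConfig:
    n_subjects: int
    tissues: dict[str, int]  # tissue -> number of genes
    missingness: dict[str, float] = field(default_factory=dict)
    zero_fraction: dict[str, float] = field(default_factory=dict)
    hubs: list[HubSpec] = field(default_factory=list)
    blocks: list[BlockSpec] = field(default_factory=list)
    traits: list[TraitSpec] = field(default_factory=list)
    seed: int = 0
    log_scale: float = 0.25  # sd of the latent on the log-expression scale
    log_loc: float = 2.0  # log-expression location (exp(2) ~ 7.4 units)

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not self.tissues:
            raise ValueError("at least one tissue required")
        for t, m in self.missingness.items():
            if not (0.0 <= m < 1.0):
                raise ValueError(f"missingness for {t!r} must be in [0, 1), got {m}")
        for t, z in self.zero_fraction.items():
            if not (0.0 <= z < 1.0):
                raise ValueError(f"zero_fraction for {t!r} must be in [0, 1), got {z}")
        for block in self.blocks:
            if not (0.0 <= block.rho < 1.0):
                raise ValueError(
                    f"block {block.name!r}: rho {block.rho} not in [0, 1) — "
                    "the implied correlation matrix would not be PSD"
                )
            if len(block.members) < 2:
                raise ValueError(f"block {block.name!r} needs >= 2 members")
        for hub in self.hubs:
            for g, t, r in hub.targets:
                if not (-1.0 < r < 1.0):
                    raise ValueError(
                        f"hub target {g}@{t}: r must be in (-1, 1), got {r}"
                    )
                if (g, t) == hub.source:
                    raise ValueError("hub target equals its source")
        for spec in self.traits:
            if not (-1.0 <= spec.r <= 1.0):
                raise ValueError(f"trait {spec.name!r}: r must be in [-1, 1]")


def gene_names(n: int) -> list[str]:
    """Shared gene universe G0001, G0002, ... (same symbols across tissues,
    as in real panels)."""
    return [f"G{i:04d}" for i in range(1, n + 1)]


def simulate_panel(config: SimConfig) -> tuple[ExpressionPanel, dict]:
    """Draw a panel with the configured planted structure.

    Returns the panel and a ground-truth manifest listing every planted
    hub edge, block and dropout rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(1, n + 1)]

    latents: dict[str, np.ndarray] = {}
    gene_index: dict[str, list[str]] = {}
    for tissue, n_genes in config.tissues.items():
        gene_index[tissue] = gene_names(n_genes)
        latents[tissue] = rng.standard_normal((n_genes, n))

    def _row(gt: GeneTissue) -> int:
        g, t = gt
        try:
            return gene_index[t].index(g)
        except (KeyError, ValueError):
            raise KeyError(f"gene-tissue {g}@{t} not in the simulated panel") from None

    manifest: dict = {"seed": config.seed, "hubs": [], "blocks": [], "traits": []}

    for block in config.blocks:
        factor = rng.standard_normal(n)
        load = np.sqrt(block.rho)
        for gt in block.members:
            i = _row(gt)
            eps = rng.standard_normal(n)
            latents[gt[1]][i] = load * factor + np.sqrt(1.0 - block.rho) * eps
        manifest["blocks"].append(
            {"name": block.name, "members": block.members, "rho": block.rho}
        )

    for hub in config.hubs:
        zi = latents[hub.source[1]][_row(hub.source)]
        for g, t, r in hub.targets:
            eps = rng.standard_normal(n)
            latents[t][_row((g, t))] = r * zi + np.sqrt(1.0 - r * r) * eps
            manifest["hubs"].append(
                {"source": list(hub.source), "target": [g, t], "r": r}
            )

    matrices: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        expr = np.exp(config.log_scale * latents[tissue] + config.log_loc)
        zf = config.zero_fraction.get(tissue, 0.0)
        if zf > 0:
            mask = rng.random(expr.shape) < zf
            expr = np.where(mask, 0.0, expr)
        mat = pd.DataFrame(expr, index=gene_index[tissue], columns=subjects)
        m = config.missingness.get(tissue, 0.0)
        if m > 0:
            keep = rng.random(n) >= m
            if keep.sum() < 3:  # never drop a tissue below usability
                keep[:3] = True
            mat = mat.loc[:, keep]
        matrices[tissue] = mat
    manifest["missingness"] = dict(config.missingness)
    return ExpressionPanel(matrices), manifest


# ---------------------------------------------------------------------------
# Cell-type mixtures
# ---------------------------------------------------------------------------

def make_signature(
    n_genes: int, cell_types: list[str] | int, seed: int, marker_strength: float = 8.0
) -> pd.DataFrame:
    """A synthetic genes x cell-types signature with marker structure.

    Each gene gets a gamma-distributed baseline; a disjoint block of
    genes per cell type is up-weighted by ``marker_strength`` so columns
    are well separated (full column rank for any sensible size).
    """
    if isinstance(cell_types, int):
        cell_types = [f"celltype_{chr(ord('A') + i)}" for i in range(cell_types)]
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    base = rng.gamma(shape=2.0, scale=5.0, size=(n_genes, k))
    block = max(1, n_genes // (k + 1))
    for j in range(k):
        base[j * block : (j + 1) * block, j] *= marker_strength
    return pd.DataFrame(base, index=gene_names(n_genes), columns=cell_types)


def simulate_mixtures(
    signature: pd.DataFrame,
    n_subjects: int,
    concentration: float | np.ndarray = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk profiles as signature-weighted mixtures of known fractions.

    Fractions are Dirichlet(concentration) per subject; bulk is
    ``S f`` plus Gaussian noise with sd ``noise_sd`` x mean bulk value,
    truncated at zero.  Returns ``(bulk genes x subjects, true fractions
    subjects x cell types)``.
    """
    rng = np.random.default_rng(seed)
    k = signature.shape[1]
    conc = np.broadcast_to(np.asarray(concentration, dtype=float), (k,))
    fracs = rng.dirichlet(conc, size=n_subjects)  # subjects x k
    S = signature.to_numpy(dtype=float)
    bulk = S @ fracs.T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd * bulk.mean(), size=bulk.shape)
        bulk = np.clip(bulk, 0.0, None)
    subjects = [f"S{i:04d}" for i in range(1, n_subjects + 1)]
    return (
        pd.DataFrame(bulk, index=signature.index, columns=subjects),
        pd.DataFrame(fracs, index=subjects, columns=signature.columns),
    )


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(
    panel: ExpressionPanel,
    specs: list[TraitSpec],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Traits linearly coupled to driver gene expression.

    Each trait is ``r z + sqrt(1 - r^2) eps`` with z the standardised
    driver expression over subjects present in the driver tissue; other
    subjects are missing.  ``r = +/-1`` yields an exact affine image of
    the driver.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    manifest = {"seed": seed, "traits": []}
    for spec in specs:
        expr = panel.gene_vector(*spec.driver)
        ok = np.isfinite(expr.to_numpy())
        z = np.full(len(expr), np.nan)
        v = expr.to_numpy()[ok]
        z[ok] = (v - v.mean()) / v.std()
        eps = rng.standard_normal(len(expr))
        trait = spec.r * z + np.sqrt(max(0.0, 1.0 - spec.r**2)) * eps
        trait[~ok] = np.nan
        cols[spec.name] = trait
        manifest["traits"].append(
            {"name": spec.name, "driver": list(spec.driver), "r": spec.r}
        )
    traits = pd.DataFrame(cols, index=panel.subjects)
    traits.index.name = "subject"
    return traits, manifest
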