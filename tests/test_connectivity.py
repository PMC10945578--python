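import numpy as np
import pandas as pd
import pytest

from gdcat import (
    missingness_diagnostic,
    pathway_cross_tissue,
    random_set_null,
    simulate_panel,
    tissue_missingness,
    tissue_ranking,
)
from gdcat.errors import GDCATError, InsufficientDataError
from gdcat.simulate import BlockSpec, SimConfig


def _block_panel(seed=9, rho=0.4, n=200):
    """20-gene set block-correlated between adipose and muscle only."""
    genes = [f"G{i:04d}" for i in range(1, 21)]
    members = [(g, "adipose") for g in genes] + [(g, "muscle") for g in genes]
    cfg = SimConfig(
        n_subjects=n,
        tissues={"adipose": 60, "muscle": 60, "spleen": 60},
        blocks=[BlockSpec("am", members, rho)],
        seed=seed,
    )
    return simulate_panel(cfg)[0], genes


class TestPathwayCrossTissue:
    def test_single_gene_pathway_counts_cross_tissue_self_pairs(self, null_panel):
        conn = pathway_cross_tissue(
            null_panel, ["G0001"], thresholds=(("p", 0.9999),), min_n=3
        )
        # 3 tissues -> 3 unordered pairs, one test each, within-tissue omitted
        assert len(conn.tests) == 3
        assert conn.counts["p<0.9999"].to_numpy().sum() == 2 * 3

    def test_matrix_symmetric_zero_diagonal(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(panel, genes)
        for mat in conn.counts.values():
            assert (mat.to_numpy() == mat.to_numpy().T).all()
            assert (np.diag(mat.to_numpy()) == 0).all()

    def test_tightening_threshold_never_increases_cells(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(
            panel, genes, thresholds=(("p", 1e-2), ("p", 1e-4), ("p", 1e-6))
        )
        a = conn.counts["p<0.01"].to_numpy()
        b = conn.counts["p<0.0001"].to_numpy()
        c = conn.counts["p<1e-06"].to_numpy()
        assert (b <= a).all() and (c <= b).all()

    def test_totals_conserve_grand_total(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(panel, genes)
        for label, mat in conn.counts.items():
            assert conn.totals[label].sum() == mat.to_numpy().sum()

    def test_normalized_divides_by_pathway_size(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(panel, genes)
        label = "p<0.001"
        assert np.allclose(
            conn.normalized[label].to_numpy(),
            conn.counts[label].to_numpy() / len(genes),
        )

    def test_planted_block_dominates_count_matrix(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(panel, genes)
        mat = conn.counts["p<0.001"]
        planted = mat.loc["adipose", "muscle"]
        others = [
            mat.loc["adipose", "spleen"],
            mat.loc["muscle", "spleen"],
        ]
        assert planted > max(others)

    def test_null_calibration_at_1e3(self):
        fracs = []
        for seed in range(3):
            cfg = SimConfig(
                n_subjects=200, tissues={"a": 50, "b": 50, "c": 50}, seed=300 + seed
            )
            panel, _ = simulate_panel(cfg)
            conn = pathway_cross_tissue(
                panel, [f"G{i:04d}" for i in range(1, 51)], thresholds=(("p", 1e-3),)
            )
            fracs.append(conn.counts["p<0.001"].to_numpy().sum() / 2 / len(conn.tests))
        alpha = 1e-3
        pooled = np.mean(fracs)
        se = np.sqrt(alpha * (1 - alpha) / (3 * 7500))
        assert abs(pooled - alpha) < 4 * se

    def test_unique_genes_unit_bounded_by_pairs(self):
        panel, genes = _block_panel()
        pairs = pathway_cross_tissue(panel, genes, unit="pairs")
        uniq = pathway_cross_tissue(panel, genes, unit="unique-genes")
        label = "p<0.001"
        # each significant pair involves at most two distinct genes
        assert (uniq.counts[label].to_numpy() <= 2 * pairs.counts[label].to_numpy()).all()
        assert (uniq.counts[label].to_numpy() <= 2 * len(genes)).all()

    def test_unmappable_pathway_errors(self, null_panel):
        with pytest.raises(GDCATError, match="mappable"):
            pathway_cross_tissue(null_panel, ["NOPE1", "NOPE2"])


class TestTissueRanking:
    def test_symmetric_two_tissue_totals_match(self):
        cfg = SimConfig(n_subjects=80, tissues={"x": 30, "y": 30}, seed=77)
        panel, _ = simulate_panel(cfg)
        conn = pathway_cross_tissue(
            panel, [f"G{i:04d}" for i in range(1, 16)], thresholds=(("p", 0.05),)
        )
        rank = tissue_ranking(conn, ("p", 0.05))
        assert rank.totals.iloc[0, 0] == rank.totals.iloc[1, 0]
        assert rank.order == ["x", "y"]  # lexicographic on ties

    def test_rank_order_fixed_by_reference_threshold(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(
            panel, genes, thresholds=(("p", 1e-2), ("p", 1e-4))
        )
        rank = tissue_ranking(conn, ("p", 1e-2))
        # counts at the other threshold are re-reported in the same order
        assert list(rank.totals.index) == rank.order
        assert "p<0.0001" in rank.totals.columns

    def test_all_zero_counts_lexicographic(self, null_panel):
        conn = pathway_cross_tissue(
            null_panel, ["G0001", "G0002", "G0003"], thresholds=(("p", 1e-9),), min_n=3
        )
        rank = tissue_ranking(conn, ("p", 1e-9))
        assert rank.order == sorted(null_panel.tissues)
        assert (rank.totals.to_numpy() == 0).all()

    def test_unknown_reference_rejected(self, null_panel):
        conn = pathway_cross_tissue(
            null_panel, ["G0001", "G0002"], thresholds=(("p", 1e-3),), min_n=3
        )
        with pytest.raises(KeyError):
            tissue_ranking(conn, ("q", 0.1))


class TestRandomSetNull:
    def test_same_seed_identical_draws(self, null_panel):
        a = random_set_null(null_panel, 10, 3, seed=5, thresholds=(("p", 0.01),))
        b = random_set_null(null_panel, 10, 3, seed=5, thresholds=(("p", 0.01),))
        for da, db in zip(a.draws, b.draws):
            pd.testing.assert_frame_equal(da, db)

    def test_planted_pathway_beats_null_95th_percentile(self):
        panel, genes = _block_panel()
        conn = pathway_cross_tissue(panel, genes, thresholds=(("p", 1e-3),))
        null = random_set_null(
            panel, len(genes), 20, seed=8, thresholds=(("p", 1e-3),)
        )
        planted = conn.counts["p<0.001"].loc["adipose", "muscle"]
        null_cells = [
            d.loc["adipose", "p<0.001"] + d.loc["muscle", "p<0.001"] for d in null.draws
        ]
        assert planted > np.percentile(null_cells, 95)

    def test_size_exceeding_pool_rejected(self, null_panel):
        with pytest.raises(ValueError, match="exceeds"):
            random_set_null(null_panel, 1000, 1, seed=1)


class TestMissingnessDiagnostic:
    def test_zero_missingness_gives_undefined_marker(self):
        cfg = SimConfig(
            n_subjects=60, tissues={f"t{i}": 12 for i in range(6)}, seed=11
        )
        panel, _ = simulate_panel(cfg)
        conn = pathway_cross_tissue(
            panel, [f"G{i:04d}" for i in range(1, 11)], thresholds=(("p", 0.05),)
        )
        rank = tissue_ranking(conn, ("p", 0.05))
        r, p = missingness_diagnostic(panel, [rank, rank], "bottom")
        assert np.isnan(r) and np.isnan(p)

    def test_tissue_missingness_counts_absent_subjects(self):
        cfg = SimConfig(
            n_subjects=100, tissues={"a": 10, "b": 10}, missingness={"b": 0.4}, seed=2
        )
        panel, _ = simulate_panel(cfg)
        miss = tissue_missingness(panel)
        assert miss["a"] == 0
        dropped = 100 - panel.matrix("b").shape[1]
        assert miss["b"] == dropped * 10

    def test_small_tertile_errors(self, null_panel):
        conn = pathway_cross_tissue(
            null_panel, [f"G{i:04d}" for i in range(1, 11)], thresholds=(("p", 0.05),)
        )
        rank = tissue_ranking(conn, ("p", 0.05))  # 3 tissues -> tertile of 1
        with pytest.raises(InsufficientDataError):
            missingness_diagnostic(null_panel, rank, "bottom")

    def test_planted_bottom_tertile_suppression_detected(self):
        panel, rankings = _missingness_scenario(seed=101)
        r, p = missingness_diagnostic(panel, rankings, "bottom")
        assert r < 0
        assert p < 0.05

    def test_shuffled_missingness_destroys_association(self):
        panel, rankings = _missingness_scenario(seed=102)
        # re-attribute the bottom-tertile totals to shuffled tissues
        rng = np.random.default_rng(0)
        shuffled = []
        for rank in rankings:
            perm = rank.totals.copy()
            perm.index = rng.permutation(perm.index.to_numpy())
            shuffled.append(
                type(rank)(list(perm.index), rank.reference, perm)
            )
        r_obs, _ = missingness_diagnostic(panel, rankings, "bottom")
        rs = []
        for trial in range(5):
            rng2 = np.random.default_rng(trial)
            sh = []
            for rank in rankings:
                perm = rank.totals.copy()
                perm.index = rng2.permutation(perm.index.to_numpy())
                sh.append(type(rank)(list(perm.index), rank.reference, perm))
            r, _ = missingness_diagnostic(panel, sh, "bottom")
            rs.append(abs(r))
        assert np.median(rs) < abs(r_obs)


def _missingness_scenario(seed: int, n_pathways: int = 4):
    """12 tissues; bottom four carry a subject-dropout gradient that
    mechanically suppresses significant cross-tissue counts."""
    tissues = [f"t{i:02d}" for i in range(12)]
    miss = {t: 0.0 for t in tissues}
    for t, m in zip(tissues[-4:], [0.2, 0.4, 0.6, 0.75]):
        miss[t] = m
    blocks, paths = [], []
    for b in range(n_pathways):
        genes = [f"G{i:04d}" for i in range(1 + b * 12, 13 + b * 12)]
        paths.append(genes)
        blocks.append(
            BlockSpec(f"pw{b}", [(g, t) for g in genes for t in tissues], 0.45)
        )
    cfg = SimConfig(
        n_subjects=180,
        tissues={t: 50 for t in tissues},
        missingness=miss,
        blocks=blocks,
        seed=seed,
    )
    panel, _ = simulate_panel(cfg)
    rankings = []
    for genes in paths:
        conn = pathway_cross_tissue(panel, genes, thresholds=(("p", 1e-3),))
        rankings.append(tissue_ranking(conn, ("p", 1e-3)))
    return panel, rankings
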