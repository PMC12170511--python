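import math

import numpy as np
import pytest
import scipy.stats

from hexniche.niche import call_immune_spots, marker_score
from hexniche.preprocess import normalize
from hexniche.simdata import (
    GroundTruth,
    SyntheticConfig,
    generate_grid,
    plant_truth,
    simulate_composition,
    simulate_counts,
    write_dataset,
)
from hexniche.spatial_io import read_counts, read_positions


class TestGrid:
    def test_parity_positions_tiny_grid(self):
        cfg = SyntheticConfig(seed=0, slides=1, n_rows=2, n_cols=3, n_genes=50,
                              n_response_genes_tumor=5, n_response_genes_benign=2)
        grid = generate_grid(cfg)
        pos = sorted(zip(grid.table["array_row"], grid.table["array_col"]))
        assert pos == [(0, 0), (0, 2), (0, 4), (1, 1), (1, 3), (1, 5)]

    def test_zero_benign_fraction(self):
        cfg = SyntheticConfig(seed=0, benign_fraction_slide1=0.0, n_rows=8, n_cols=8,
                              n_genes=100, n_response_genes_tumor=5, n_response_genes_benign=2)
        grid = generate_grid(cfg)
        assert (grid.table["region"] == "benign").sum() == 0

    def test_default_spot_count_near_study_scale(self):
        grid = generate_grid(SyntheticConfig(seed=0))
        assert len(grid) == 2 * 56 * 56 == 6272

    def test_benign_band_contiguous_on_slide1_only(self):
        cfg = SyntheticConfig(seed=0, n_rows=12, n_cols=6, benign_fraction_slide1=0.25,
                              n_genes=100, n_response_genes_tumor=5, n_response_genes_benign=2)
        grid = generate_grid(cfg)
        t = grid.table
        benign = t[t["region"] == "benign"]
        assert set(benign["slide_id"]) == {"slide1"}
        assert set(benign["array_row"]) == set(range(math.ceil(0.25 * 12)))
        assert (t[t["slide_id"] == "slide2"]["region"] == "tumor").all()

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=0, n_rows=0)


class TestTruth:
    def test_default_immune_count_matches_ceiling(self):
        cfg = SyntheticConfig(seed=3)
        grid = generate_grid(cfg)
        truth = plant_truth(grid, cfg)
        assert len(truth.immune_spot_ids) == math.ceil(0.046 * 6272) == 289

    def test_deterministic_under_seed(self, small_cfg):
        grid = generate_grid(small_cfg)
        t1 = plant_truth(grid, small_cfg)
        t2 = plant_truth(grid, small_cfg)
        assert t1.immune_spot_ids == t2.immune_spot_ids
        assert t1.response_genes_tumor == t2.response_genes_tumor
        assert t1.subclone_assignment == t2.subclone_assignment

    def test_response_sets_disjoint_from_markers(self, small_cfg):
        grid = generate_grid(small_cfg)
        truth = plant_truth(grid, small_cfg)
        markers = set(small_cfg.marker_symbols())
        rt = set(truth.response_genes_tumor)
        rb = set(truth.response_genes_benign)
        assert not rt & rb and not (rt | rb) & markers
        assert len(rt) == 30 and len(rb) == 10

    def test_unbiased_placement_is_uniform(self):
        # with bias 1, immune frequency near the benign band matches elsewhere
        from hexniche.simdata import _ring

        table = np.zeros((2, 2))
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed, n_rows=24, n_cols=24, immune_benign_bias=1.0,
                                  immune_spot_fraction=0.05, n_genes=200,
                                  n_response_genes_tumor=10, n_response_genes_benign=5)
            grid = generate_grid(cfg)
            truth = plant_truth(grid, cfg)
            benign = set(grid.table.index[grid.table["region"] == "benign"])
            near = _ring(grid, benign, 2)
            for b in grid.analyzed:
                table[int(b in near), int(b in truth.immune_spot_ids)] += 1
        _, p, _, _ = scipy.stats.chi2_contingency(table)
        assert p > 0.01

    def test_biased_placement_enriches_near_benign(self):
        from hexniche.simdata import _ring

        cfg = SyntheticConfig(seed=1, n_rows=24, n_cols=24, immune_benign_bias=5.0,
                              immune_spot_fraction=0.05, n_genes=200,
                              n_response_genes_tumor=10, n_response_genes_benign=5)
        grid = generate_grid(cfg)
        truth = plant_truth(grid, cfg)
        benign = set(grid.table.index[grid.table["region"] == "benign"])
        near = _ring(grid, benign, 2)
        far = set(grid.analyzed) - near
        rate_near = len(truth.immune_spot_ids & near) / len(near)
        rate_far = len(truth.immune_spot_ids & far) / len(far)
        assert rate_near > 2 * rate_far

    def test_subclone_patches_contiguous(self, small_cfg):
        from hexniche.niche import hex_neighbors

        grid = generate_grid(small_cfg)
        truth = plant_truth(grid, small_cfg)
        patches = {}
        for b, p in truth.subclone_assignment.items():
            patches.setdefault(p, set()).add(b)
        for p, spots in patches.items():
            if p == -1 or len(spots) == 1:
                continue
            # breadth-first reachability inside the patch
            seen = {next(iter(spots))}
            frontier = list(seen)
            while frontier:
                nxt = []
                for b in frontier:
                    for nb in hex_neighbors(grid, b) & spots:
                        if nb not in seen:
                            seen.add(nb)
                            nxt.append(nb)
                frontier = nxt
            assert seen == spots, f"patch {p} not contiguous"

    def test_json_round_trip(self, small_cfg, tmp_path):
        grid = generate_grid(small_cfg)
        truth = plant_truth(grid, small_cfg)
        truth.to_json(tmp_path / "truth.json")
        back = GroundTruth.from_json(tmp_path / "truth.json")
        assert back.immune_spot_ids == truth.immune_spot_ids
        assert back.response_genes_tumor == truth.response_genes_tumor
        assert back.subclone_assignment == truth.subclone_assignment


class TestCounts:
    def test_deterministic_bit_identical(self, small_cfg):
        grid = generate_grid(small_cfg)
        truth = plant_truth(grid, small_cfg)
        a = simulate_counts(grid, truth, small_cfg, "deep")
        b = simulate_counts(grid, truth, small_cfg, "deep")
        assert (a.matrix != b.matrix).nnz == 0

    def test_library_sizes_near_targets_both_regimes(self, small_cfg):
        grid = generate_grid(small_cfg)
        truth = plant_truth(grid, small_cfg)
        deep = simulate_counts(grid, truth, small_cfg, "deep")
        std = simulate_counts(grid, truth, small_cfg, "standard")
        mean_deep = deep.spot_totals().mean()
        mean_std = std.spot_totals().mean()
        assert mean_deep == pytest.approx(small_cfg.depth_deep_mean, rel=0.10)
        assert mean_std == pytest.approx(small_cfg.depth_standard_mean, rel=0.10)
        assert mean_deep / mean_std == pytest.approx(35, rel=0.15)

    def test_unknown_depth_regime(self, small_cfg, small_dataset):
        grid, truth, _ = small_dataset
        with pytest.raises(ValueError, match="regime"):
            simulate_counts(grid, truth, small_cfg, "ultra")

    def test_marker_calling_recovers_planted_spots(self, small_cfg, small_dataset):
        grid, truth, counts = small_dataset
        nm = normalize(counts)
        scores = marker_score(nm)
        called = call_immune_spots(scores)
        ti = truth.immune_spot_ids
        recall = len(called & ti) / len(ti)
        fpr = len(called - ti) / (len(grid.analyzed) - len(ti))
        assert recall >= 0.95 and fpr <= 0.01

    def test_null_effect_sizes_leave_adjacency_clean(self):
        # response_log2fc=0: planted "response" genes are indistinguishable
        from hexniche.diffexpr import de_analysis
        from hexniche.niche import build_contrasts, classify_niche

        cfg = SyntheticConfig(seed=5, n_rows=20, n_cols=20, n_genes=600,
                              response_log2fc=0.0, n_subclones=4,
                              n_response_genes_tumor=40, n_response_genes_benign=10)
        grid = generate_grid(cfg)
        truth = plant_truth(grid, cfg)
        nm = normalize(simulate_counts(grid, truth, cfg, "deep"))
        labels = classify_niche(grid, call_immune_spots(marker_score(nm)))
        cs = build_contrasts(labels)
        table = de_analysis(nm, cs["tumor_adjacent_vs_away"])
        resp = table.loc[list(truth.response_genes_tumor)]
        # empirical type-I on the planted-null genes near nominal
        assert (resp["p"] < 0.05).mean() <= 0.15
        assert int(table["significant"].sum()) <= 3


class TestComposition:
    def _factors(self, n_per_cell=8):
        import pandas as pd

        rows = []
        for d in ("deep", "standard"):
            for r in ("tumor", "benign"):
                for i in range(n_per_cell):
                    rows.append({"obs": f"{d}_{r}_{i}", "depth": d, "region": r})
        return pd.DataFrame(rows).set_index("obs")

    def test_rows_on_simplex(self):
        t = simulate_composition(self._factors(), seed=0)
        sums = t.proportions.sum(axis=1)
        np.testing.assert_allclose(sums, 1, atol=1e-9)
        assert (t.proportions.to_numpy() >= 0).all()

    def test_planted_effects_detected(self):
        from hexniche.composition import clr_transform, permanova

        t = simulate_composition(self._factors(12), depth_effect=1.0, region_effect=1.2, seed=1)
        res = permanova(clr_transform(t), t.factors["depth"], t.factors["region"],
                        n_perm=199, seed=2)
        assert res.table.loc["factor_a", "p_value"] < 0.05
        assert res.table.loc["factor_b", "p_value"] < 0.05

    def test_deterministic(self):
        import pandas as pd

        a = simulate_composition(self._factors(), seed=3)
        b = simulate_composition(self._factors(), seed=3)
        pd.testing.assert_frame_equal(a.proportions, b.proportions)


class TestDatasetExport:
    def test_write_then_read_round_trip(self, small_cfg, small_dataset, tmp_path):
        grid, truth, counts = small_dataset
        write_dataset(tmp_path, grid, truth, {"deep": counts})
        g2 = read_positions(tmp_path / "tissue_positions.csv", tmp_path / "regions.csv")
        assert list(g2.barcodes) == list(grid.barcodes)
        assert (g2.table["region"] == grid.table["region"]).all()
        m2 = read_counts(tmp_path / "counts_deep" / "matrix.mtx",
                         tmp_path / "counts_deep" / "features.tsv",
                         tmp_path / "counts_deep" / "barcodes.tsv")
        assert (m2.matrix != counts.matrix).nnz == 0
        assert m2.genes == counts.genes
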