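import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from tqrank import (
    CANONICAL_CELL_TYPES,
    GeneProfile,
    PhiMatrix,
    SampleSheet,
    call_pattern,
    celltype_distances,
    discover_and_rank,
    quantile_type5,
    single_linkage_two_cut,
    tqr_score,
)
from tqrank.discovery import build_profile_tensor

from conftest import make_phi_frame


def profile_from_rows(rows, gene_id="g"):
    rows = np.asarray(rows, dtype=float)
    cts = CANONICAL_CELL_TYPES[: rows.shape[0]]
    embryos = tuple(f"E{i + 1}" for i in range(rows.shape[1]))
    return GeneProfile(gene_id, rows, cts, embryos)


class TestDistances:
    def test_three_four_five(self):
        prof = profile_from_rows([[0, 0, 0, 0], [3, 4, 0, 0]])
        d = celltype_distances(prof)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0 and d[1, 1] == 0

    def test_matches_brute_force_double_loop(self, rng):
        values = rng.uniform(0, np.pi, size=(8, 4))
        prof = profile_from_rows(values)
        d = celltype_distances(prof)
        for u in range(8):
            for v in range(8):
                expect = np.sqrt(np.sum((values[u] - values[v]) ** 2))
                assert d[u, v] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(d, d.T)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            GeneProfile("g", np.zeros((3, 4)), CANONICAL_CELL_TYPES[:4],
                        ("E1", "E2", "E3", "E4"))


def dist_from_values(vals):
    """Distance matrix of scalar items (1-replicate profiles)."""
    v = np.asarray(vals, dtype=float)
    return np.abs(v[:, None] - v[None, :])


class TestTwoCut:
    def test_separated_pairs(self):
        cut = single_linkage_two_cut(dist_from_values([0.0, 0.1, 0.9, 1.0]))
        assert set(cut.cluster_a) == {0, 1}
        assert set(cut.cluster_b) == {2, 3}
        assert cut.merge_height == pytest.approx(0.8)

    def test_singleton_side_allowed(self):
        cut = single_linkage_two_cut(dist_from_values([0.0, 0.05, 0.1, 2.0]))
        assert set(cut.cluster_a) == {0, 1, 2}
        assert set(cut.cluster_b) == {3}

    def test_two_items(self):
        cut = single_linkage_two_cut(dist_from_values([0.3, 0.9]))
        assert cut.cluster_a == (0,) and cut.cluster_b == (1,)
        assert cut.merge_height == pytest.approx(0.6)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            single_linkage_two_cut(np.array([[0, 1.0], [2.0, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            single_linkage_two_cut(np.array([[0, -1.0], [-1.0, 0]]))
        with pytest.raises(ValueError, match="2 items"):
            single_linkage_two_cut(np.zeros((1, 1)))

    def test_matches_scipy_single_linkage(self, rng):
        """The two top-level clusters equal hclust-style single linkage cut
        at k=2 (scipy is the independent reference)."""
        for _ in range(200):
            n = int(rng.integers(3, 9))
            pts = rng.uniform(0, 1, size=(n, 3))
            d = squareform(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)),
                           checks=False)
            labels = fcluster(linkage(d, method="single"), 2, criterion="maxclust")
            ours = single_linkage_two_cut(squareform(d))
            ref = {frozenset(np.where(labels == k)[0]) for k in (1, 2)}
            assert {frozenset(ours.cluster_a), frozenset(ours.cluster_b)} == ref


class TestQuantileType5:
    @pytest.mark.parametrize("values,p,expect", [
        ([1, 2, 3, 4], 0.25, 1.5),
        ([10, 20], 0.5, 15.0),
        ([5], 0.0, 5.0),
        ([5], 0.5, 5.0),
        ([5], 1.0, 5.0),
        ([1, 2, 3, 4], 0.0, 1.0),
        ([1, 2, 3, 4], 1.0, 4.0),
    ])
    def test_hand_computed_cases(self, values, p, expect):
        assert quantile_type5(values, p) == pytest.approx(expect, abs=1e-15)

    def test_matches_numpy_hazen(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            x = rng.normal(size=n)
            p = float(rng.uniform())
            assert quantile_type5(x, p) == pytest.approx(
                float(np.quantile(x, p, method="hazen")), abs=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
           st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True)
    def test_monotone_in_p(self, values, p1, p2):
        lo, hi = sorted([p1, p2])
        assert quantile_type5(values, lo) <= quantile_type5(values, hi)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            quantile_type5([], 0.5)
        with pytest.raises(ValueError, match="outside"):
            quantile_type5([1.0], 1.5)


class TestTqr:
    def test_worked_example(self):
        assert tqr_score([0.8, 0.9, 1.0, 1.1], [0.0, 0.1, 0.2, 0.3]) == \
            pytest.approx(0.60, abs=1e-12)

    def test_identical_lists_non_positive(self, rng):
        x = rng.uniform(size=8).tolist()
        assert tqr_score(x, x) <= 0

    def test_constant_lists_zero(self):
        assert tqr_score([0.3] * 4, [0.3] * 4) == 0.0

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            tqr_score([], [1.0])

    def test_decreases_with_spread_at_fixed_means(self):
        scores = [tqr_score([1 - s, 1 + s], [-s, s]) for s in np.linspace(0.0, 0.45, 12)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_increases_with_mean_separation_at_fixed_spread(self):
        s = 0.1
        scores = [tqr_score([m - s, m + s], [-s, s]) for m in np.linspace(0.1, 1.0, 12)]
        assert all(a < b for a, b in zip(scores, scores[1:]))


class TestCallPattern:
    def test_single_cell_marker_pattern(self, rng):
        base = rng.uniform(0.0005, 0.0015, size=(8, 4))
        base[7] = rng.uniform(0.045, 0.055, size=4)  # B5.2 high
        call = call_pattern(profile_from_rows(base))
        assert call.pattern == (0, 0, 0, 0, 0, 0, 0, 1)
        assert call.tqr > 0
        assert len(call.on_values) == 4 and len(call.off_values) == 28

    def test_anterior_pattern_membership(self, rng):
        # high in a5.3, a5.4, A5.1, A5.2; low elsewhere
        base = rng.uniform(0.001, 0.002, size=(8, 4))
        for i in (0, 1, 4, 5):
            base[i] = rng.uniform(0.04, 0.05, size=4)
        call = call_pattern(profile_from_rows(base))
        assert call.pattern == (1, 1, 0, 0, 1, 1, 0, 0)

    def test_constant_profile_scores_zero(self):
        call = call_pattern(profile_from_rows(np.full((8, 4), 0.2)))
        assert call.tqr == 0.0
        assert 1 <= sum(call.pattern) <= 7

    def test_all_zero_profile_scores_zero(self):
        call = call_pattern(profile_from_rows(np.zeros((8, 4))))
        assert call.tqr == 0.0

    def test_tie_goes_to_cluster_with_earlier_canonical_cell(self):
        # constant profile: every cut has equal pooled means, so the ON
        # side must be the cluster containing a5.3
        call = call_pattern(profile_from_rows(np.full((8, 2), 0.1)))
        assert call.pattern[0] == 1

    def test_larger_mean_cluster_is_on(self):
        vals = np.zeros((8, 1))
        vals[4:, 0] = [0.49, 0.51, 0.49, 0.51]
        call = call_pattern(profile_from_rows(vals))
        assert call.pattern == (0, 0, 0, 0, 1, 1, 1, 1)

    def test_on_mean_dominates_off_mean(self, rng):
        for _ in range(50):
            call = call_pattern(profile_from_rows(rng.uniform(0, 0.3, (8, 4))))
            assert np.mean(call.on_values) >= np.mean(call.off_values)
            assert 1 <= sum(call.pattern) <= 7

    def test_quartile_basis_flag_changes_score_not_pattern(self, rng):
        base = rng.uniform(0.001, 0.002, size=(8, 4))
        base[7] = rng.uniform(0.04, 0.05, size=4)
        prof = profile_from_rows(base)
        pooled = call_pattern(prof, quartile_basis="pooled")
        cellmean = call_pattern(prof, quartile_basis="cellmean")
        assert pooled.pattern == cellmean.pattern
        assert pooled.tqr != cellmean.tqr
        with pytest.raises(ValueError, match="quartile_basis"):
            call_pattern(prof, quartile_basis="median")


class TestDiscoverAndRank:
    def make_inputs(self, rng, sheet, n_genes=6):
        vals = rng.uniform(0.0, 0.2, size=(n_genes, 16))
        return PhiMatrix(make_phi_frame(vals, sheet))

    def test_sorted_by_tqr_descending_rank_1_based(self, rng, two_embryo_sheet):
        calls = discover_and_rank(self.make_inputs(rng, two_embryo_sheet),
                                  two_embryo_sheet)
        tqrs = [c.tqr for c in calls]
        assert tqrs == sorted(tqrs, reverse=True)
        assert [c.rank for c in calls] == list(range(1, len(calls) + 1))

    def test_equal_tqr_breaks_ties_by_gene_id(self, two_embryo_sheet):
        vals = np.zeros((3, 16))
        mat = PhiMatrix(make_phi_frame(vals, two_embryo_sheet,
                                       gene_ids=["zed", "alpha", "mid"]))
        calls = discover_and_rank(mat, two_embryo_sheet)
        assert [c.gene_id for c in calls] == ["alpha", "mid", "zed"]

    def test_sample_order_permutation_changes_nothing(self, rng, two_embryo_sheet):
        mat = self.make_inputs(rng, two_embryo_sheet)
        calls = discover_and_rank(mat, two_embryo_sheet)
        perm = rng.permutation(mat.values.columns)
        mat2 = PhiMatrix(mat.values[perm])
        shuffled_sheet = SampleSheet(
            two_embryo_sheet.table.sample(frac=1, random_state=7).reset_index(drop=True))
        calls2 = discover_and_rank(mat2, shuffled_sheet)
        assert [(c.gene_id, c.pattern, c.tqr) for c in calls] == \
            [(c.gene_id, c.pattern, c.tqr) for c in calls2]

    def test_incomplete_embryo_dropped_not_imputed(self, rng, two_embryo_sheet):
        mat = self.make_inputs(rng, two_embryo_sheet)
        # remove one sample of embryo E2: E2 is dropped entirely
        sub = two_embryo_sheet.table[two_embryo_sheet.table["sample_id"] != "E2_b5.4"]
        sheet = SampleSheet(sub.reset_index(drop=True))
        tensor, _, _, embryos = build_profile_tensor(mat, sheet)
        assert embryos == ("E1",)
        calls = discover_and_rank(mat, sheet)
        assert len(calls) == mat.values.shape[0]

    def test_mixed_platforms_require_selection(self, rng):
        rows = [
            {"sample_id": f"{plat}_{ct}", "embryo": "E1", "cell_type": ct,
             "platform": plat}
            for plat in ("HiSeq", "MiSeq") for ct in CANONICAL_CELL_TYPES
        ]
        sheet = SampleSheet(pd.DataFrame(rows))
        vals = rng.uniform(0, 0.1, size=(3, 16))
        mat = PhiMatrix(make_phi_frame(vals, sheet))
        with pytest.raises(ValueError, match="platform"):
            discover_and_rank(mat, sheet)
        calls = discover_and_rank(mat, sheet, platform="MiSeq")
        assert len(calls) == 3
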