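"""Homologue pairing, sign-count contingency tests, hemisphere correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import chi2_contingency

from sesmap.inference import BaggedSolution, SignificanceReport
from sesmap.laterality import (
    HomologueMap,
    SignCountTable,
    chi_square_test,
    chisq_sf,
    homologue_correlation,
    pair_homologues,
    sign_count_table,
)


def make_atlas(n_pairs=4, n_midline=1, tissue="cortical"):
    rows = []
    for i in range(n_pairs):
        for hemi in ("L", "R"):
            rows.append(
                dict(
                    feature_id=f"f{hemi}{i}",
                    name=f"region {i} {hemi}",
                    hemisphere=hemi,
                    tissue=tissue,
                    homologue_id=f"pair{i}",
                )
            )
    for i in range(n_midline):
        rows.append(
            dict(
                feature_id=f"fM{i}",
                name=f"mid {i}",
                hemisphere="M",
                tissue=tissue,
                homologue_id=np.nan,
            )
        )
    return pd.DataFrame(rows)


class TestPairHomologues:
    def test_direct_construction(self):
        hmap = pair_homologues(make_atlas(4, 1))
        assert len(hmap.pairs) == 4
        assert hmap.midline == ["fM0"]
        for left, right, hid in hmap.pairs:
            assert left.startswith("fL") and right.startswith("fR")

    def test_dangling_homologue_id_named_in_error(self):
        atlas = make_atlas(2, 0)
        atlas = atlas[atlas["feature_id"] != "fR1"]  # orphan pair1
        with pytest.raises(ValueError, match="pair1"):
            pair_homologues(atlas)

    def test_same_hemisphere_twice_rejected(self):
        atlas = make_atlas(1, 0)
        atlas.loc[atlas["feature_id"] == "fR0", "hemisphere"] = "L"
        with pytest.raises(ValueError):
            pair_homologues(atlas)

    def test_duplicate_feature_rejected(self):
        atlas = pd.concat([make_atlas(1, 0)] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            pair_homologues(atlas)

    def test_generator_atlas_pair_count(self, small_cohort):
        config, _, _, atlas = small_cohort
        hmap = pair_homologues(atlas)
        assert len(hmap.pairs) == config.n_pairs
        assert len(hmap.midline) == config.n_midline_regions + config.n_midline_tracts


def report_from(sig: pd.DataFrame, means: pd.DataFrame):
    zeros = means * 0.0
    bagged = BaggedSolution(mean=means, sd=zeros + 1.0, lo5=means, hi95=means)
    rep = SignificanceReport(p_fwe=1.0 - sig.astype(float) * 0.9995, significant=sig, threshold=0.001)
    return rep, bagged


class TestSignCountTable:
    def test_hand_built_counts(self):
        """20 L+, 5 L-, 8 R+, 17 R- significant cells -> [[20,5],[8,17]]."""
        atlas = make_atlas(25, 0)
        hmap = pair_homologues(atlas)
        features = atlas["feature_id"].tolist()
        inds = ["i1"]
        means = pd.DataFrame(0.0, index=features, columns=inds)
        sig = pd.DataFrame(False, index=features, columns=inds)
        left = [f"fL{i}" for i in range(25)]
        right = [f"fR{i}" for i in range(25)]
        for fid in left[:20]:
            means.loc[fid], sig.loc[fid] = 1.0, True
        for fid in left[20:25]:
            means.loc[fid], sig.loc[fid] = -1.0, True
        for fid in right[:8]:
            means.loc[fid], sig.loc[fid] = 1.0, True
        for fid in right[8:25]:
            means.loc[fid], sig.loc[fid] = -1.0, True
        rep, bagged = report_from(sig, means)
        table = sign_count_table(rep, bagged, hmap, atlas)
        assert table.counts.tolist() == [[20, 5], [8, 17]]

    def test_no_significant_cells_gives_zero_table_and_refusal(self):
        atlas = make_atlas(3, 0)
        hmap = pair_homologues(atlas)
        features = atlas["feature_id"].tolist()
        means = pd.DataFrame(0.5, index=features, columns=["i1"])
        sig = pd.DataFrame(False, index=features, columns=["i1"])
        rep, bagged = report_from(sig, means)
        table = sign_count_table(rep, bagged, hmap, atlas)
        assert table.counts.sum() == 0
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_test(table)

    def test_midline_features_excluded(self):
        atlas = make_atlas(3, 2)
        hmap = pair_homologues(atlas)
        features = atlas["feature_id"].tolist()
        means = pd.DataFrame(1.0, index=features, columns=["i1"])
        sig = pd.DataFrame(True, index=features, columns=["i1"])
        rep, bagged = report_from(sig, means)
        table = sign_count_table(rep, bagged, hmap, atlas)
        assert table.total == 6  # 3 pairs x 2 sides, midline ignored

    def test_mirrored_pattern_concentrates_diagonal(self, small_cohort):
        _, _, truth, atlas = small_cohort
        hmap = pair_homologues(atlas)
        W = truth.true_coefficients
        sig = W != 0
        rep, bagged = report_from(sig, W)
        # restrict counting to mirrored pairs: symmetric-effect pairs add
        # i.i.d. signs, mirrored pairs only fill (L,+) and (R,-)
        mirrored_features = atlas[
            atlas["homologue_id"].isin(truth.asymmetric_pair_ids)
        ]["feature_id"]
        only = atlas[atlas["feature_id"].isin(mirrored_features)]
        table = sign_count_table(rep, bagged, pair_homologues(only), only)
        n_cells = len(truth.asymmetric_pair_ids) * 6
        assert table.counts.tolist() == [[n_cells, 0], [0, n_cells]]

    def test_empty_subset_rejected(self, small_cohort):
        _, _, truth, atlas = small_cohort
        regions_only = atlas[atlas["tissue"] != "tract"].copy()
        hmap = pair_homologues(regions_only)
        W = truth.true_coefficients.loc[regions_only["feature_id"]]
        rep, bagged = report_from(W != 0, W)
        with pytest.raises(ValueError, match="no features"):
            sign_count_table(rep, bagged, hmap, regions_only, subset="tracts")


class TestChiSquare:
    def test_hand_evaluated_pearson_statistic(self):
        result = chi_square_test(np.array([[20, 5], [8, 17]]))
        assert result.statistic == pytest.approx(11.688, abs=5e-4)
        assert result.df == 1

    def test_perfect_independence(self):
        result = chi_square_test(np.array([[10, 10], [10, 10]]))
        assert result.statistic == 0.0
        assert result.p == 1.0

    def test_proportional_rows_give_zero(self):
        # ad = bc
        result = chi_square_test(np.array([[6, 9], [2, 3]]))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_small_tables_match_scipy(self):
        """Pearson statistic agrees with scipy's chi2_contingency on every
        2x2 table with positive margins and total <= 12."""
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if a + b + c + d > 12 or a + b + c + d == 0:
                continue
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = chi_square_test(np.array([[a, b], [c, d]]))
            ref_stat, ref_p, ref_df, _ = chi2_contingency(
                np.array([[a, b], [c, d]]), correction=False
            )
            assert ours.statistic == pytest.approx(ref_stat, abs=1e-10)
            assert ours.p == pytest.approx(ref_p, abs=1e-10)
            assert ref_df == 1

    def test_yates_matches_scipy(self):
        table = np.array([[12, 5], [6, 14]])
        ours = chi_square_test(table, correction="yates")
        ref_stat, ref_p, *_ = chi2_contingency(table, correction=True)
        assert ours.statistic == pytest.approx(ref_stat, abs=1e-10)
        assert ours.p == pytest.approx(ref_p, abs=1e-10)

    def test_hemisphere_relabel_invariance(self, rng):
        table = np.array([[20, 5], [8, 17]])
        swapped = table[::-1]
        assert chi_square_test(table).statistic == pytest.approx(
            chi_square_test(swapped).statistic, abs=1e-12
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_test(np.array([[3, 0], [5, 0]]))


class TestChisqSf:
    def test_reported_gray_matter_value(self):
        """The gray-matter laterality test statistic converts to P = 0.025."""
        assert chisq_sf(4.991, 1) == pytest.approx(0.025, abs=5e-4)

    def test_reported_tract_value(self):
        """The fiber-tract laterality test statistic converts to P = 0.653."""
        assert chisq_sf(0.202, 1) == pytest.approx(0.653, abs=5e-4)

    def test_boundary(self):
        assert chisq_sf(0.0, 1) == 1.0

    def test_df1_equals_normal_two_sided_tail(self):
        for stat in (0.5, 1.0, 4.0, 9.0):
            expected = 2 * stats.norm.sf(np.sqrt(stat))
            assert chisq_sf(stat, 1) == pytest.approx(expected, abs=1e-12)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chisq_sf(-0.1, 1)


class TestHomologueCorrelation:
    def _values(self, atlas, fill):
        return pd.DataFrame(fill, index=atlas["feature_id"].tolist(), columns=["i1", "i2"])

    def test_mirrored_map_gives_minus_one(self, rng):
        atlas = make_atlas(5, 0)
        hmap = pair_homologues(atlas)
        v = self._values(atlas, 0.0)
        left_vals = rng.normal(size=(5, 2))
        for i in range(5):
            v.loc[f"fL{i}"] = left_vals[i]
            v.loc[f"fR{i}"] = -left_vals[i]
        [hc] = homologue_correlation(v, hmap, atlas)
        assert hc.r == pytest.approx(-1.0, abs=1e-12)
        assert hc.n_pairs == 5

    def test_identical_map_gives_plus_one(self, rng):
        atlas = make_atlas(4, 1)
        hmap = pair_homologues(atlas)
        v = self._values(atlas, 0.0)
        vals = rng.normal(size=(4, 2))
        for i in range(4):
            v.loc[f"fL{i}"] = vals[i]
            v.loc[f"fR{i}"] = vals[i]
        [hc] = homologue_correlation(v, hmap, atlas)
        assert hc.r == pytest.approx(1.0, abs=1e-12)

    def test_pair_order_symmetry(self, rng):
        """Swapping L and R labels everywhere leaves r unchanged."""
        atlas = make_atlas(6, 0)
        v = self._values(atlas, 0.0)
        v.loc[:, :] = rng.normal(size=(12, 2))
        [forward] = homologue_correlation(v, pair_homologues(atlas), atlas)
        swapped = atlas.copy()
        swapped["hemisphere"] = swapped["hemisphere"].map({"L": "R", "R": "L"})
        [backward] = homologue_correlation(v, pair_homologues(swapped), swapped)
        assert forward.r == pytest.approx(backward.r, abs=1e-12)

    def test_per_indicator_mode_returns_six(self, small_cohort):
        _, _, truth, atlas = small_cohort
        hmap = pair_homologues(atlas)
        results = homologue_correlation(
            truth.true_coefficients + 1e-9 * np.random.default_rng(0).normal(
                size=truth.true_coefficients.shape
            ),
            hmap,
            atlas,
            per_indicator=True,
        )
        assert len(results) == 6
        assert all(-1 <= hc.r <= 1 for hc in results)

    def test_too_few_pairs_rejected(self):
        atlas = make_atlas(2, 0)
        hmap = pair_homologues(atlas)
        v = self._values(atlas, 1.0)
        with pytest.raises(ValueError, match="3"):
            homologue_correlation(v, hmap, atlas)

    def test_null_cohort_correlation_centered_on_zero(self, rng):
        """With no planted effects, pooled homologue correlation of noise
        maps is centered on zero: mean |r| <= 2/sqrt(n_pairs) over 50 seeds."""
        atlas = make_atlas(30, 0)
        hmap = pair_homologues(atlas)
        rs = []
        for seed in range(50):
            local = np.random.default_rng(seed)
            v = pd.DataFrame(
                local.normal(size=(60, 6)),
                index=atlas["feature_id"].tolist(),
                columns=[f"i{j}" for j in range(6)],
            )
            rs.append(abs(homologue_correlation(v, hmap, atlas)[0].r))
        assert np.mean(rs) <= 2 / np.sqrt(30)
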