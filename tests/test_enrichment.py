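from math import comb

import numpy as np
import pandas as pd
import pytest

from glycoshift import (
    GlycoSite,
    ProteinRecord,
    SiteKey,
    annotation_set_enrichment,
    classify_site,
    fisher_enrichment,
    fisher_two_sided,
    multiplicity_enrichment,
    multiplicity_group_test,
    nxs_multiplicity_correlation,
    sequon_position_enrichment,
)


class TestFisher:
    def test_balanced_table_no_association(self):
        res = fisher_enrichment(5, 10, 10, 20)
        assert res.fold_enrichment == 1.0 and res.p_value == 1.0

    def test_perfect_separation_p(self):
        # [[10,0],[0,10]]: the two extreme tables out of C(20,10)
        p = fisher_two_sided([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 5, 10)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="subset|margins"):
            fisher_enrichment(5, 10, 3, 20)  # more hits in set than background

    def test_degenerate_margin_p_one(self):
        assert fisher_two_sided([[0, 0], [3, 4]]) == 1.0


def profile_frame(mults: dict[str, int]) -> pd.DataFrame:
    df = pd.DataFrame({"multiplicity": pd.Series(mults)})
    df.index.name = "protein_id"
    df["scanned_multiplicity"] = df["multiplicity"]
    return df


class TestMultiplicityEnrichment:
    def test_threshold_one_fold_is_always_one(self):
        profiles = profile_frame({f"p{i}": 1 + i % 5 for i in range(40)})
        res = multiplicity_enrichment([f"p{i}" for i in range(0, 40, 7)], profiles)
        assert res[1].fold_enrichment == 1.0 and res[1].p_value == 1.0

    def test_fold_two_when_background_half(self):
        # decreased: 10 proteins all multiplicity >= 4; background 50% >= 4
        mults = {f"d{i}": 4 for i in range(10)}
        mults.update({f"u{i}": 4 if i < 5 else 1 for i in range(30)})
        profiles = profile_frame(mults)
        res = multiplicity_enrichment(list(mults)[:10], profiles)
        assert res[4].fold_enrichment == pytest.approx((10 / 10) / (15 / 40))

    def test_all_singletons_fold_zero_at_higher_threshold(self):
        mults = {"d1": 1, "d2": 1, "u1": 3, "u2": 2}
        res = multiplicity_enrichment(["d1", "d2"], profile_frame(mults))
        assert res[2].fold_enrichment == 0.0

    def test_empty_decreased_set_rejected(self):
        with pytest.raises(ValueError):
            multiplicity_enrichment([], profile_frame({"p": 2}))


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        res = multiplicity_group_test([2, 2, 2], [2, 2, 2])
        assert res.p_value == 1.0 and res.mean_a == res.mean_b

    def test_fully_separated_small_groups(self):
        res = multiplicity_group_test([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / comb(8, 4), rel=1e-12)

    def test_exact_branch_matches_labeling_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(5)
        for _ in range(15):
            n_a, n_b = rng.integers(2, 7, size=2)
            pooled = rng.integers(0, 6, size=n_a + n_b).astype(float)
            a, b = pooled[:n_a], pooled[n_a:]
            res = multiplicity_group_test(a, b)
            # oracle: U by direct pairwise comparisons over all labelings
            def u_of(sel):
                sel = set(sel)
                grp_a = [pooled[i] for i in sel]
                grp_b = [pooled[i] for i in range(len(pooled)) if i not in sel]
                return sum((x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b)

            u_obs = u_of(range(n_a))
            mu = n_a * n_b / 2
            dist = [u_of(sel) for sel in combinations(range(n_a + n_b), n_a)]
            p_oracle = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in dist])
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(6)
        res = multiplicity_group_test(rng.integers(1, 10, 50), rng.integers(1, 10, 60))
        assert res.method == "asymptotic" and 0 < res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            multiplicity_group_test([], [1, 2])


def make_site(pid, pos, seq) -> GlycoSite:
    return classify_site(ProteinRecord(pid, seq), SiteKey(pid, pos))


@pytest.fixture()
def nxs_site():
    return make_site("A", 3, "AANGSAA")  # NxS, minus2 A (non-aromatic)


@pytest.fixture()
def nxt_site():
    return make_site("B", 3, "FWNGTAA")  # NxT, minus2 W (aromatic)


class TestMotifEnrichment:
    def test_identical_composition_all_p_one(self, nxs_site):
        analysis = sequon_position_enrichment([nxs_site] * 5, [nxs_site] * 9)
        assert all(f.p_value == 1.0 for f in analysis.features)

    def test_plus2_ser_enriched_when_decreased_all_nxs(self, nxs_site, nxt_site):
        analysis = sequon_position_enrichment([nxs_site] * 8, [nxt_site] * 8)
        plus2 = next(f for f in analysis.features if (f.position, f.feature) == (2, "S"))
        assert plus2.fold_enrichment > 1
        # oracle: the induced table is [[8,0],[0,8]]
        assert plus2.p_value == pytest.approx(2 / comb(16, 8), rel=1e-9)

    def test_histidine_counts_as_aromatic(self):
        site = make_site("H", 3, "HANGSAA")
        assert site.minus2_aromatic is True
        analysis = sequon_position_enrichment([site] * 4, [make_site("A", 3, "AANGSAA")] * 4)
        m2 = next(f for f in analysis.features if (f.position, f.feature) == (-2, "non_aromatic"))
        assert m2.n_decreased_with == 0 and m2.n_unchanged_with == 4

    def test_minus2_undefined_sites_excluded_from_minus2_only(self, nxs_site):
        near_terminus = make_site("C", 1, "NGSAA")
        analysis = sequon_position_enrichment([near_terminus, nxs_site], [nxs_site] * 3)
        m2 = next(f for f in analysis.features if (f.position, f.feature) == (-2, "non_aromatic"))
        assert m2.n_decreased_total == 1  # the undefined -2 site dropped here
        plus2 = next(f for f in analysis.features if (f.position, f.feature) == (2, "S"))
        assert plus2.n_decreased_total == 2  # but kept for +2

    def test_empty_set_rejected(self, nxs_site):
        with pytest.raises(ValueError):
            sequon_position_enrichment([], [nxs_site])

    def test_logo_counts_sum_to_defined_sites(self, nxs_site, nxt_site):
        analysis = sequon_position_enrichment([nxs_site, nxt_site], [nxt_site])
        assert analysis.logo_decreased.loc[1].sum() == 2
        assert analysis.logo_decreased.loc[-3].sum() == 0  # both contexts padded there


def correlated_sites(percent_by_mult, series_size=10):
    """Construct decreased/unchanged NxS sites so that the decreased share of
    NxS sites in bin m equals percent_by_mult[m]."""
    decreased, unchanged, mults = [], [], {}
    for m, pct in percent_by_mult.items():
        n_dec = round(series_size * pct / 100)
        for i in range(series_size):
            pid = f"m{m}p{i}"
            mults[pid] = m
            site = make_site(pid, 3, "AANGSAA")
            (decreased if i < n_dec else unchanged).append(site)
    return decreased, unchanged, profile_frame(mults)


class TestNxsCorrelation:
    def test_exact_linearity_gives_r_one(self):
        dec, unch, profiles = correlated_sites({1: 10, 2: 20, 3: 30, 4: 40})
        res = nxs_multiplicity_correlation(dec, unch, profiles)
        assert res["decreased"].r == pytest.approx(1.0)
        assert res["unchanged"].r == pytest.approx(-1.0)

    def test_constant_percentage_defined_as_r_zero(self):
        dec, unch, profiles = correlated_sites({1: 50, 2: 50, 3: 50})
        res = nxs_multiplicity_correlation(dec, unch, profiles)
        assert res["decreased"].r == 0.0 and res["decreased"].p_value == 1.0

    def test_fewer_than_three_bins_rejected(self):
        dec, unch, profiles = correlated_sites({1: 10, 2: 90})
        with pytest.raises(ValueError, match="bins"):
            nxs_multiplicity_correlation(dec, unch, profiles)

    def test_small_bins_dropped(self):
        dec, unch, profiles = correlated_sites({1: 10, 2: 20, 3: 30, 4: 40})
        # an extra bin with fewer than min_bin_size NxS sites disappears
        extra = make_site("solo", 3, "AANGSAA")
        profiles.loc["solo"] = [7, 7]
        res = nxs_multiplicity_correlation(dec + [extra], unch, profiles, min_bin_size=3)
        assert all(x != 7 for x, _ in res["decreased"].points)

    def test_literal_share_mode(self):
        # decreased series 100% NxS everywhere -> flat 100% -> r = 0
        dec, unch, profiles = correlated_sites({1: 30, 2: 50, 3: 70})
        res = nxs_multiplicity_correlation(
            dec, unch, profiles, mode="nxs_share_of_series"
        )
        assert all(y == 100.0 for _, y in res["decreased"].points)
        assert res["decreased"].r == 0.0

    def test_pooled_bin_at_cap(self):
        dec, unch, profiles = correlated_sites({1: 10, 4: 40, 9: 80, 12: 90})
        res = nxs_multiplicity_correlation(dec, unch, profiles, cap=8)
        xs = [x for x, _ in res["decreased"].points]
        assert xs == [1.0, 4.0, 8.0]


class TestAnnotationEnrichment:
    def test_membership_equals_background_fold_one(self):
        feature_to_protein = {f"f{i}": f"p{i}" for i in range(10)}
        res = annotation_set_enrichment(
            ["f0", "f1"],
            list(feature_to_protein),
            {f"p{i}" for i in range(10)},
            feature_to_protein,
        )
        assert res.fold_enrichment == 1.0 and res.p_value == 1.0

    def test_fold_two_with_half_background(self):
        feature_to_protein = {f"f{i}": f"p{i}" for i in range(20)}
        members = {f"p{i}" for i in range(10)}
        decreased = [f"f{i}" for i in range(10)]  # all members
        res = annotation_set_enrichment(
            decreased, list(feature_to_protein), members, feature_to_protein
        )
        assert res.fold_enrichment == pytest.approx(2.0)
        assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_disjoint_annotation_rejected(self):
        feature_to_protein = {"f1": "p1", "f2": "p2"}
        with pytest.raises(ValueError, match="intersect"):
            annotation_set_enrichment(["f1"], ["f1", "f2"], {"zz"}, feature_to_protein)
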