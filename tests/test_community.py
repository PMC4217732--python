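import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import beescape as b
from beescape.community import DistanceMatrix, wisconsin
from beescape.synthgen import HONEYBEE, ValidationError
from conftest import surveys_from_matrix


def visits_table(site, totals, species="wild"):
    return pd.DataFrame(
        [(site, v + 1, species, t) for v, t in enumerate(totals)],
        columns=["site_id", "visit", "species", "count"])


class TestSiteAbundance:
    def test_mean_then_sqrt(self):
        table = visits_table("S1", (4, 4, 4))
        assert b.site_abundance(table, exclude=())["S1"] == pytest.approx(2.0)
        table = visits_table("S1", (1, 2, 3))
        assert b.site_abundance(table, exclude=())["S1"] == pytest.approx(np.sqrt(2.0))

    def test_exclusion_zeroes_total(self):
        apis = visits_table("S1", (5, 5), species=HONEYBEE)
        wild = visits_table("S1", (0, 0), species="wild")
        table = pd.concat([apis, wild], ignore_index=True)
        assert b.site_abundance(table)["S1"] == 0.0
        assert b.site_abundance(table, exclude=())["S1"] == pytest.approx(np.sqrt(5.0))

    def test_excluded_only_visits_still_counted_in_mean(self):
        # visit 2 contains only an excluded species: it must still dilute the mean
        table = pd.DataFrame([
            ("S1", 1, "wild", 4), ("S1", 2, HONEYBEE, 9),
        ], columns=["site_id", "visit", "species", "count"])
        assert b.site_abundance(table)["S1"] == pytest.approx(np.sqrt(2.0))


class TestSimpson:
    def test_single_species_zero(self):
        assert b.simpson_diversity([7]) == 0.0

    def test_even_two_species(self):
        assert b.simpson_diversity([5, 5]) == pytest.approx(0.5)

    def test_three_to_one_split(self):
        assert b.simpson_diversity([3, 1]) == pytest.approx(0.375)

    @pytest.mark.parametrize("k", range(1, 11))
    def test_equal_counts_identity(self, k):
        counts = [4] * k
        assert b.simpson_diversity(counts) == pytest.approx(1.0 - 1.0 / k)

    def test_unbiased_variant(self):
        # 1 - sum n(n-1)/(N(N-1)) for counts (3,1): 1 - 6/12 = 0.5
        assert b.simpson_diversity([3, 1], variant="unbiased") == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            b.simpson_diversity([0, 0])


class TestCommunityMatrix:
    def test_hand_worked_standardization(self):
        surveys = surveys_from_matrix([[4, 0], [0, 16]])
        matrix = b.build_community_matrix(surveys)
        expected = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(matrix.values.to_numpy(), expected)
        assert matrix.stage == "wisconsin"

    def test_rows_sum_to_one(self, survey_setup):
        matrix = b.build_community_matrix(survey_setup[2])
        sums = matrix.values.sum(axis=1).to_numpy()
        nonempty = sums > 0
        np.testing.assert_allclose(sums[nonempty], 1.0, atol=1e-9)

    def test_duplicate_sites_standardize_identically(self):
        surveys = surveys_from_matrix([[3, 1, 0], [3, 1, 0], [0, 2, 5]])
        matrix = b.build_community_matrix(surveys)
        np.testing.assert_allclose(matrix.values.iloc[0], matrix.values.iloc[1])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            b.build_community_matrix(surveys_from_matrix([[0, 0], [0, 0]]))


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_case(self):
        matrix = b.CommunityMatrix(pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0], [1.0, 2.0], [3.0, 0.0], [0.0, 3.0]],
            index=list("abcde"), columns=["s1", "s2"]))
        d = b.bray_curtis(matrix).values
        assert d[0, 2] == 0.0                       # identical rows
        assert d[3, 4] == pytest.approx(1.0)        # disjoint rows
        assert d[0, 1] == pytest.approx(2.0 / 6.0)  # (1,2) vs (2,1)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, size=(8, 5))
        matrix = b.CommunityMatrix(pd.DataFrame(x))
        d = b.bray_curtis(matrix).values
        for i in range(8):
            for j in range(8):
                num = sum(abs(x[i, s] - x[j, s]) for s in range(5))
                den = sum(x[i, s] + x[j, s] for s in range(5))
                assert d[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_zero_pair_is_zero(self):
        matrix = b.CommunityMatrix(pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
        with pytest.warns(UserWarning, match="all-zero"):
            d = b.bray_curtis(matrix).values
        assert d[0, 1] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_scipy_condensed(self, seed):
        x = np.random.default_rng(seed).uniform(0.1, 4, size=(6, 4))
        ours = b.bray_curtis(b.CommunityMatrix(pd.DataFrame(x))).condensed()
        theirs = pdist(x, metric="braycurtis")
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


def _dist_from_points(points):
    d = squareform(pdist(points))
    d = d / d.max()
    return DistanceMatrix(d, [f"p{i}" for i in range(len(points))])


class TestNMDS:
    def test_perfectly_embeddable_low_stress(self):
        rng = np.random.default_rng(1)
        dist = _dist_from_points(rng.uniform(0, 1, size=(5, 2)))
        ordination = b.nmds(dist, k=2, n_starts=5, seed=0)
        assert ordination.stress < 1e-3

    def test_mutually_equidistant_sites_embed(self):
        # an equilateral configuration exists, so stress should vanish
        d4 = np.ones((4, 4)) - np.eye(4)
        dist4 = DistanceMatrix(d4, list("abcd"))
        ord2 = b.nmds(dist4, k=2, n_starts=10, seed=0)
        assert ord2.stress < 1e-6

    def test_near_equidistant_triangle_k2(self):
        # slight perturbation breaks the all-ties degeneracy; a 2-D embedding
        # still fits the ordinal structure essentially perfectly
        d = np.array([[0, 1.0, 0.99, 0.98],
                      [1.0, 0, 0.97, 0.96],
                      [0.99, 0.97, 0, 0.95],
                      [0.98, 0.96, 0.95, 0]])
        ordination = b.nmds(DistanceMatrix(d, list("abcd")), k=2, n_starts=10, seed=0)
        assert ordination.stress < 1e-6

    def test_stress_trace_monotone_nonincreasing(self, survey_setup):
        matrix = b.build_community_matrix(survey_setup[2])
        dist = b.bray_curtis(matrix)
        ordination = b.nmds(dist, k=2, n_starts=4, seed=3)
        trace = np.array(ordination.stress_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert trace[-1] <= trace[0]

    def test_seeded_determinism_and_centering(self, survey_setup):
        matrix = b.build_community_matrix(survey_setup[2])
        dist = b.bray_curtis(matrix)
        o1 = b.nmds(dist, k=2, n_starts=4, seed=5)
        o2 = b.nmds(dist, k=2, n_starts=4, seed=5)
        pd.testing.assert_frame_equal(o1.scores, o2.scores)
        np.testing.assert_allclose(o1.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(bad, list("ab"))


class TestOrientAxis:
    @staticmethod
    def _ordination():
        scores = pd.DataFrame({"NMDS1": [1.0, -1.0, 0.5, -0.5],
                               "NMDS2": [0.2, 0.1, -0.2, -0.1]},
                              index=list("abcd"))
        return b.Ordination(scores=scores, stress=0.1, k=2, converged=True,
                            n_starts_used=1)

    def test_positive_correlation_identity(self):
        ordination = self._ordination()
        anchor = pd.Series([1.0, 0.0, 0.6, 0.2], index=list("abcd"))
        out = b.orient_axis(ordination, anchor)
        pd.testing.assert_frame_equal(out.scores, ordination.scores)

    def test_negative_correlation_flips_axis1_only(self):
        ordination = self._ordination()
        anchor = pd.Series([-1.0, 1.0, -0.5, 0.5], index=list("abcd"))
        out = b.orient_axis(ordination, anchor)
        np.testing.assert_allclose(out.scores["NMDS1"], -ordination.scores["NMDS1"])
        np.testing.assert_allclose(out.scores["NMDS2"], ordination.scores["NMDS2"])
        assert out.stress == ordination.stress

    def test_zero_correlation_warns_and_keeps(self):
        ordination = self._ordination()
        anchor = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        with pytest.warns(UserWarning, match="anchor"):
            out = b.orient_axis(ordination, anchor)
        pd.testing.assert_frame_equal(out.scores, ordination.scores)


class TestEnvfit:
    @staticmethod
    def _ordination(n=12, seed=0):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(rng.standard_normal((n, 2)),
                              index=[f"s{i}" for i in range(n)],
                              columns=["NMDS1", "NMDS2"])
        scores -= scores.mean()
        return b.Ordination(scores=scores, stress=0.1, k=2, converged=True,
                            n_starts_used=1)

    def test_axis_variable_perfect_fit(self):
        ordination = self._ordination()
        env = pd.DataFrame({"v": ordination.scores["NMDS1"]})
        (fit,) = b.envfit(ordination, env, n_perm=99, seed=1)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-8)
        assert fit.p_value <= 0.05

    def test_r2_equals_squared_pearson_in_1d(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"NMDS1": rng.standard_normal(15)},
                              index=[f"s{i}" for i in range(15)])
        scores -= scores.mean()
        ordination = b.Ordination(scores=scores, stress=0.0, k=1,
                                  converged=True, n_starts_used=1)
        v = pd.Series(rng.standard_normal(15), index=scores.index)
        (fit,) = b.envfit(ordination, pd.DataFrame({"v": v}), n_perm=0)
        r = np.corrcoef(v, scores["NMDS1"])[0, 1]
        assert fit.r2 == pytest.approx(r**2, abs=1e-12)

    def test_constant_variable_degenerate(self):
        ordination = self._ordination()
        env = pd.DataFrame({"flat": np.ones(len(ordination.scores))},
                           index=ordination.scores.index)
        with pytest.warns(UserWarning, match="constant"):
            (fit,) = b.envfit(ordination, env, n_perm=9)
        assert fit.r2 == 0.0 and fit.p_value == 1.0


class TestSimper:
    def test_single_differing_species_takes_all(self):
        matrix = b.CommunityMatrix(pd.DataFrame(
            [[1.0, 2.0], [1.0, 5.0]], index=["a", "b"], columns=["s1", "s2"]))
        table = b.simper(matrix, {"a": "high", "b": "low"})
        top = table.iloc[0]
        assert top["species"] == "s2"
        assert top["percent"] == pytest.approx(100.0)

    def test_contributions_reconstruct_mean_dissimilarity(self, survey_setup):
        matrix = b.build_community_matrix(survey_setup[2])
        sites = matrix.sites
        groups = {s: ("high" if i % 2 else "low") for i, s in enumerate(sites)}
        table = b.simper(matrix, groups)
        d = b.bray_curtis(matrix)
        idx = {s: i for i, s in enumerate(sites)}
        pairs = [(idx[i], idx[j]) for i in sites for j in sites
                 if groups[i] == "high" and groups[j] == "low"]
        mean_d = np.mean([d.values[i, j] for i, j in pairs])
        assert table["contribution"].sum() == pytest.approx(mean_d, abs=1e-12)
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_identical_groups_all_zero(self):
        matrix = b.CommunityMatrix(pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0]], index=["a", "b"], columns=["s1", "s2"]))
        with pytest.warns(UserWarning, match="identical"):
            table = b.simper(matrix, {"a": "high", "b": "low"})
        assert (table["contribution"] == 0).all()

    def test_empty_group_rejected(self):
        matrix = b.CommunityMatrix(pd.DataFrame(
            [[1.0], [2.0]], index=["a", "b"], columns=["s1"]))
        with pytest.raises(ValidationError):
            b.simper(matrix, {"a": "high", "b": "high"})


def test_wisconsin_column_max_then_row_sum_order():
    values = pd.DataFrame([[2.0, 8.0], [4.0, 2.0]], index=["a", "b"], columns=["s1", "s2"])
    out = wisconsin(b.CommunityMatrix(values)).values
    # col max -> [[0.5, 1.0], [1.0, 0.25]]; row sums -> 1.5, 1.25
    np.testing.assert_allclose(out.to_numpy(),
                               [[0.5 / 1.5, 1.0 / 1.5], [1.0 / 1.25, 0.25 / 1.25]])
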