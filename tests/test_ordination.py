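"""Community matrix, Bray–Curtis, NMDS and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedbank import (
    ValidationError,
    bray_curtis,
    community_matrix,
    confidence_ellipse,
    nmds,
    permanova,
)
from .conftest import make_quadrat
from .oracles import naive_bray_curtis


def euclidean(x):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))


class TestCommunityMatrix:
    def test_shape_and_row_sums(self, small_dataset):
        _, quadrats, practices, _ = small_dataset
        cm = community_matrix(quadrats, practices)
        assert cm.values.shape[0] == 36  # 12 sites × 3 fields
        np.testing.assert_allclose(cm.values.sum(axis=1), 3.0, atol=1e-9)
        assert (cm.values.to_numpy() >= 0).all()
        assert set(cm.meta["mode"]) == {"RG", "RM", "RC", "RD"}

    def test_identical_fields_identical_rows(self):
        quadrats = [
            make_quadrat({"a": 2, "b": 1}, site="S1", field=1),
            make_quadrat({"a": 2, "b": 1}, site="S1", field=2),
        ]
        cm = community_matrix(quadrats)
        np.testing.assert_allclose(cm.values.iloc[0], cm.values.iloc[1])

    def test_single_field_rejected(self):
        with pytest.raises(ValidationError):
            community_matrix([make_quadrat({"a": 1})])


class TestBrayCurtis:
    def test_examples(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 1.0], [1.0, 2.0], [0.0, 5.0]])
        d = bray_curtis(m)
        assert d.iloc[0, 1] == pytest.approx(1 / 3)  # 1 − 2·2/6
        assert d.iloc[0, 2] == 0.0  # identical rows
        x = np.array([[1.0, 0.0], [0.0, 3.0]])
        assert bray_curtis(x).iloc[0, 1] == 1.0  # disjoint supports

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=(8, 6))
        d = bray_curtis(x).to_numpy()
        for i in range(8):
            for j in range(8):
                expected = 0.0 if i == j else naive_bray_curtis(x[i], x[j])
                assert d[i, j] == pytest.approx(expected, abs=1e-12)
        assert ((d >= 0) & (d <= 1)).all()
        np.testing.assert_allclose(d, d.T, atol=1e-15)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.array([[1.0, -1.0], [0.0, 1.0]]))

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.zeros((2, 2)))


class TestNMDS:
    def test_collinear_points_recovered_with_low_stress(self):
        coords = np.linspace(0, 5, 6)[:, None] * np.array([[2.0, 1.0]])
        res = nmds(euclidean(coords), k=2, n_runs=10, rng=0)
        assert res.stress < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        d = euclidean(rng.normal(size=(9, 3)))
        r1 = nmds(d, n_runs=3, rng=123)
        r2 = nmds(d, n_runs=3, rng=123)
        assert r1.stress == r2.stress
        pd.testing.assert_frame_equal(r1.coords, r2.coords)
        assert r1.best_run_seed == r2.best_run_seed

    def test_stress_nonincreasing_in_dimension(self):
        rng = np.random.default_rng(21)
        d = euclidean(rng.normal(size=(10, 5)))
        s2 = nmds(d, k=2, n_runs=8, rng=2).stress
        s3 = nmds(d, k=3, n_runs=8, rng=2).stress
        assert s3 <= s2 + 1e-9

    def test_coords_centered(self):
        rng = np.random.default_rng(3)
        d = euclidean(rng.normal(size=(8, 2)))
        res = nmds(d, n_runs=4, rng=1)
        np.testing.assert_allclose(res.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1.0, 2], [1, 0, 3], [2.5, 3, 0]])
        with pytest.raises(ValidationError):
            nmds(np.vstack([bad, [[1, 1, 1.0]]])[:3, :3], n_runs=1)


class TestPermanova:
    def test_euclidean_case_equals_classical_anova(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=21)
        groups = np.repeat(["a", "b", "c"], 7)
        res = permanova(euclidean(y), groups, n_perm=99, rng=0)
        f_classic = stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert res.pseudo_F == pytest.approx(f_classic, abs=1e-9)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 4))
        x[8:] += 1.0
        d = euclidean(x)
        groups = ["a"] * 8 + ["b"] * 7
        mine = permanova(d, groups, n_perm=0)
        ref = skbio_permanova(DistanceMatrix(d), groups, permutations=9)
        assert mine.pseudo_F == pytest.approx(float(ref["test statistic"]), abs=1e-9)

    def test_separated_clusters_attain_minimum_p(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 0.01, (8, 2)), rng.normal(50, 0.01, (8, 2))])
        res = permanova(euclidean(x), [0] * 8 + [1] * 8, n_perm=999, rng=1)
        assert res.p_value == pytest.approx(0.001)

    def test_identical_points_no_between_structure(self):
        d = np.zeros((10, 10))
        res = permanova(d, [0] * 5 + [1] * 5, n_perm=99, rng=0)
        assert res.R2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(9)
        d = euclidean(rng.normal(size=(12, 3)))
        g = [0] * 6 + [1] * 6
        r1 = permanova(d, g, n_perm=0)
        r2 = permanova(7.5 * d, g, n_perm=0)
        assert r1.R2 == pytest.approx(r2.R2, abs=1e-12)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-9)

    def test_contract_errors(self):
        d = euclidean(np.arange(6.0))
        with pytest.raises(ValidationError):
            permanova(d, [0] * 6, n_perm=9)
        with pytest.raises(ValidationError):
            permanova(d, list(range(6)), n_perm=9)  # all singletons


class TestConfidenceEllipse:
    def test_isotropic_cloud_near_circular(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4000, 2))
        ell = confidence_ellipse(pts, ["g"] * 4000)["g"]
        assert not ell.degenerate
        assert ell.axes[1] / ell.axes[0] == pytest.approx(1.0, abs=0.1)

    def test_level_zero_degenerates_to_point(self):
        rng = np.random.default_rng(1)
        ell = confidence_ellipse(rng.normal(size=(30, 2)), ["g"] * 30, level=0.0)["g"]
        np.testing.assert_allclose(ell.axes, 0.0)

    def test_rank_deficient_group_omitted(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        # three points on a line: singular covariance
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        ell = confidence_ellipse(pts, ["g"] * 3)["g"]
        assert ell.degenerate
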