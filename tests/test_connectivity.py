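"""Pearson connectivity matrices, positive-edge graphs, group summaries and
BrainNet Viewer exports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osaconnect.connectivity import (
    BrainGraph,
    ConnectivityMatrix,
    ConstantInputError,
    band_connectivity,
    export_brainnet,
    group_min_max,
    pearson,
    positive_edges,
    read_brainnet,
)

LABELS = ["F4-A1", "F3-A2", "O1-A2", "O2-A1"]


def _matrix(offdiag, labels=LABELS):
    k = len(labels)
    r = np.eye(k)
    iu = np.triu_indices(k, 1)
    r[iu] = offdiag
    r = r + r.T - np.eye(k) * 1.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(band="delta", channel_labels=labels, r=r, n_obs=100)


class TestPearson:
    def test_identity_reflection_and_hand_example(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == 1.0
        assert pearson([1, 2, 3], [3, 2, 1]) == -1.0
        # cov = 4, sd^2 = 5 each -> r = 4/5
        assert abs(pearson([1, 2, 3, 4], [1, 3, 2, 4]) - 0.8) < 1e-12

    def test_matches_scipy_on_random_pairs(self, rng):
        from scipy.stats import pearsonr

        for _ in range(200):
            n = int(rng.integers(3, 50))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert abs(pearson(x, y) - pearsonr(x, y).statistic) < 1e-12

    def test_constant_input_raises(self):
        with pytest.raises(ConstantInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_checks(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


class TestBandConnectivity:
    def test_identical_channels_give_all_ones(self, rng):
        x = rng.standard_normal(500)
        m = band_connectivity([[x, x, x, x]], LABELS, "delta")
        np.testing.assert_allclose(m.r, 1.0)

    def test_independent_noise_near_zero(self, rng):
        epochs = [
            [rng.standard_normal(3000) for _ in range(4)] for _ in range(10)
        ]
        m = band_connectivity(epochs, LABELS, "delta")
        off = m.offdiag()
        assert np.all(np.abs(off) < 3 / np.sqrt(3000 * 10))

    def test_common_source_gives_half_correlation(self, rng):
        # x = s + e1, y = s + e2, Var s = Var e  ->  rho = 1/2
        n = 6000
        epochs = []
        for _ in range(5):
            s = rng.standard_normal(n)
            chans = [s + rng.standard_normal(n) for _ in range(4)]
            epochs.append(chans)
        m = band_connectivity(epochs, LABELS, "delta")
        assert np.all(np.abs(m.offdiag() - 0.5) < 0.05)

    def test_constant_epoch_excluded_with_warning(self, rng):
        good = [rng.standard_normal(100) for _ in range(4)]
        bad = [np.ones(100)] + [rng.standard_normal(100) for _ in range(3)]
        with pytest.warns(UserWarning, match="constant"):
            m = band_connectivity([good, bad], LABELS, "delta")
        ref = band_connectivity([good], LABELS, "delta")
        np.testing.assert_allclose(m.r, ref.r)

    def test_all_epochs_excluded_raises(self):
        bad = [np.ones(100)] * 4
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all epochs"):
                band_connectivity([bad], LABELS, "delta")

    def test_relabeling_permutes_matrix(self, rng):
        chans = [rng.standard_normal(400) for _ in range(4)]
        m = band_connectivity([chans], LABELS, "delta")
        perm = [2, 0, 3, 1]
        m2 = band_connectivity(
            [[chans[i] for i in perm]], [LABELS[i] for i in perm], "delta"
        )
        np.testing.assert_allclose(m2.r, m.r[np.ix_(perm, perm)], atol=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(99)
        chans = [rng.standard_normal(300) for _ in range(4)]
        m = band_connectivity([chans], LABELS, "delta")
        chans[0] = chans[0] * scale
        m2 = band_connectivity([chans], LABELS, "delta")
        np.testing.assert_allclose(m2.r, m.r, atol=1e-10)


class TestPositiveEdges:
    def test_all_positive_complete_graph(self):
        g = positive_edges(_matrix([0.5] * 6))
        assert g.n_edges == 6
        assert g.degrees.tolist() == [3, 3, 3, 3]

    def test_all_negative_empty_graph(self):
        g = positive_edges(_matrix([-0.2] * 6))
        assert g.n_edges == 0
        assert g.degrees.tolist() == [0, 0, 0, 0]

    def test_single_positive_pair(self):
        g = positive_edges(_matrix([0.9, -0.1, -0.2, -0.3, -0.4, -0.5]))
        assert g.n_edges == 1
        assert g.degrees.tolist() == [1, 1, 0, 0]
        assert g.edges[0][:2] == (0, 1)

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_handshake_lemma(self, offdiag):
        g = positive_edges(_matrix(offdiag))
        assert int(g.degrees.sum()) == 2 * g.n_edges


class TestGroupMinMax:
    def test_single_matrix(self):
        s = group_min_max([_matrix([0.2, 0.5, -0.1, 0.7, 0.3, 0.4])], "OSA")
        assert (s.min_pos_r, s.max_pos_r) == (0.2, 0.7)
        assert not s.empty

    def test_across_subjects(self):
        s = group_min_max(
            [_matrix([0.3, -1, -1, -1, -1, -1]), _matrix([0.6, -1, -1, -1, -1, -1])]
        )
        assert (s.min_pos_r, s.max_pos_r) == (0.3, 0.6)

    def test_all_negative_flagged_empty(self):
        s = group_min_max([_matrix([-0.5] * 6)])
        assert s.empty

    def test_band_mixing_rejected(self):
        a = _matrix([0.1] * 6)
        b = _matrix([0.1] * 6)
        b.band = "beta"
        with pytest.raises(ValueError, match="mix"):
            group_min_max([a, b])


class TestBrainNet:
    def test_k4_round_trip(self, tmp_path):
        g = positive_edges(_matrix([1.0 - 1e-9] * 6))
        n, e = export_brainnet(g, tmp_path / "g.node", tmp_path / "g.edge")
        w = np.loadtxt(e)
        assert w.shape == (4, 4)
        assert np.all(np.diag(w) == 0)
        back = read_brainnet(n, e)
        assert back.labels == g.labels
        assert back.edges == g.edges
        assert back.degrees.tolist() == g.degrees.tolist()

    def test_empty_graph_export(self, tmp_path):
        g = positive_edges(_matrix([-0.5] * 6))
        n, e = export_brainnet(g, tmp_path / "g.node", tmp_path / "g.edge")
        assert np.all(np.loadtxt(e) == 0)
        back = read_brainnet(n, e)
        assert back.n_edges == 0
        assert back.degrees.tolist() == [0, 0, 0, 0]

    def test_missing_coordinates_rejected(self, tmp_path):
        m = ConnectivityMatrix(
            band="delta", channel_labels=["X1", "X2", "X3"], r=np.eye(3), n_obs=10
        )
        g = positive_edges(m)
        assert g.coords is None
        with pytest.raises(ValueError, match="coordinates"):
            export_brainnet(g, tmp_path / "g.node", tmp_path / "g.edge")


class TestMatrixValidation:
    def test_asymmetric_and_bad_diagonal_rejected(self):
        r = np.eye(2)
        r[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix("delta", ["a", "b"], r, 10)
        with pytest.raises(ValueError, match="diagonal"):
            ConnectivityMatrix("delta", ["a", "b"], np.full((2, 2), 0.5), 10)
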