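"""Channel layout, canonical correlation, and network construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oscdecomp.connectivity import (
    ConnectivityNetwork,
    build_network,
    canonical_corr,
    corr_connectivity,
    default_layout,
    group_connectivity,
    select_band_oscillator,
)
from oscdecomp.ssm_core import OscillatorParams, OscModel


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


class TestLayout:
    def test_default_partition_counts(self):
        sizes = default_layout().group_sizes()
        assert sizes == {
            "short_range": 16,
            "contralateral_transverse": 25,
            "ipsilateral_longitudinal": 20,
            "control": 92,
        }
        assert sum(sizes.values()) == 18 * 17 // 2

    @pytest.mark.parametrize(
        "a,b,group",
        [
            ("L1", "L2", "short_range"),
            ("L1", "R1", "contralateral_transverse"),
            ("L4", "R5", "contralateral_transverse"),
            ("L1", "L9", "ipsilateral_longitudinal"),
            ("L1", "L4", "control"),
            ("L3", "R5", "control"),
        ],
    )
    def test_pair_group_rule(self, a, b, group):
        lay = default_layout()
        assert lay.pair_group(a, b) == group
        assert lay.pair_group(b, a) == group

    def test_bad_labels_rejected(self):
        from oscdecomp.connectivity import ChannelLayout

        with pytest.raises(ValueError, match="convention"):
            ChannelLayout(labels=("L1", "M2"))

    def test_self_pair_undefined(self):
        with pytest.raises(ValueError):
            default_layout().pair_group("L1", "L1")


# ---------------------------------------------------------------------------
# band selection
# ---------------------------------------------------------------------------


def _model(freq_power_phase):
    oscs, deoxy = [], []
    for f, power, phase in freq_power_phase:
        a = 0.9
        oscs.append(OscillatorParams(a=a, f=f, sigma2=power * (1 - a**2)))
        phi = np.radians(phase)
        deoxy.append([0.5 * np.cos(phi), 0.5 * np.sin(phi)])
    proj = np.array([[[1.0, 0.0]] * len(oscs), deoxy])
    return OscModel(oscillators=tuple(oscs), projections=proj, tau2=1e-6, dt=0.1)


class TestBandSelection:
    def test_selects_only_in_band_oscillator(self):
        m = _model([(0.025, 0.01, 230), (2.0, 0.5, 0), (4.0, 0.5, 0)])
        assert select_band_oscillator(m, (0.01, 0.1)) == 0

    def test_empty_band_gives_none(self):
        m = _model([(2.0, 0.5, 0)])
        assert select_band_oscillator(m, (0.01, 0.1)) is None

    def test_max_power_wins_and_tie_breaks_low_index(self):
        m = _model([(1.8, 0.3, 0), (2.1, 0.4, 0)])
        assert select_band_oscillator(m, (1.6, 2.4)) == 1
        tie = _model([(1.8, 0.4, 0), (2.1, 0.4, 0)])
        assert select_band_oscillator(tie, (1.6, 2.4)) == 0

    def test_phase_class_separates_pulse_from_mirror(self):
        m = _model([(2.0, 0.3, 5.0), (2.07, 0.4, 178.0)])
        assert select_band_oscillator(m, (1.6, 2.4), phase_class="in_phase") == 0
        assert select_band_oscillator(m, (1.6, 2.4), phase_class="anti_phase") == 1


# ---------------------------------------------------------------------------
# canonical correlation
# ---------------------------------------------------------------------------


class TestCanonicalCorr:
    def test_invertible_transform_gives_one(self, rng):
        X = rng.normal(size=(500, 2))
        A = np.array([[2.0, 1.0], [0.5, -1.0]])
        assert canonical_corr(X, X @ A) == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_is_small(self, rng):
        X = rng.normal(size=(1800, 2))
        Y = rng.normal(size=(1800, 2))
        assert canonical_corr(X, Y) < 0.2

    def test_univariate_reduction_to_pearson(self, rng):
        x = rng.normal(size=800)
        y = 0.6 * x + 0.8 * rng.normal(size=800)
        r = canonical_corr(x[:, None], y[:, None])
        assert r == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), rel=1e-10)

    def test_degenerate_second_coordinate_ridge_path(self, rng):
        x = rng.normal(size=600)
        y = -0.7 * x + rng.normal(size=600)
        X = np.column_stack([x, np.zeros(600)])
        Y = np.column_stack([y, np.zeros(600)])
        with pytest.warns(UserWarning, match="rank-deficient"):
            r = canonical_corr(X, Y)
        assert r == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-4)

    def test_symmetry(self, rng):
        X = rng.normal(size=(300, 2))
        Y = rng.normal(size=(300, 2)) + 0.5 * X
        assert canonical_corr(X, Y) == pytest.approx(canonical_corr(Y, X), rel=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_invariance_under_per_set_linear_maps(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 2))
        Y = 0.4 * X + rng.normal(size=(200, 2))
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        B = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        assert canonical_corr(X @ A, Y @ B) == pytest.approx(canonical_corr(X, Y), abs=1e-8)

    def test_zero_variance_rejected(self):
        X = np.zeros((100, 2))
        with pytest.raises(ValueError, match="zero variance"):
            canonical_corr(X, X)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            canonical_corr(np.ones((3, 2)), np.ones((3, 2)))


# ---------------------------------------------------------------------------
# networks and groups
# ---------------------------------------------------------------------------


def _toy_network(labels, r_entries):
    c = len(labels)
    r = np.full((c, c), np.nan)
    for (i, j), v in r_entries.items():
        r[i, j] = r[j, i] = v
    return ConnectivityNetwork(band=(0.01, 0.1), labels=tuple(labels), r_matrix=r)


class TestNetworks:
    def test_adjacency_monotone_in_threshold(self, rng):
        c = 6
        r = np.abs(rng.uniform(size=(c, c)))
        r = (r + r.T) / 2
        net = ConnectivityNetwork(band=(0, 1), labels=tuple(f"L{i+1}" for i in range(c)), r_matrix=r)
        prev = None
        for th in (0.7, 0.6, 0.5, 0.4):
            adj = net.adjacency(th)
            if prev is not None:
                assert np.all(prev <= adj)
            prev = adj

    def test_missing_entries_never_connect(self):
        net = _toy_network(["L1", "L2", "L3"], {(0, 1): 0.9})
        adj = net.adjacency(0.4)
        assert adj[0, 1] and not adj[0, 2] and not adj[1, 2]

    def test_group_means_match_hand_computation(self):
        """4-channel toy: group means equal hand-computed averages."""
        labels = ["L1", "L2", "L9", "R1"]
        # pairs: L1-L2 short(0.8); L1-L9 long(0.3); L1-R1 contra(0.7);
        #        L2-L9 long(.. |2-9|=7 ->long, 0.1); L2-R1 contra(0.6); L9-R1 control(0.2)
        net = _toy_network(
            labels,
            {(0, 1): 0.8, (0, 2): 0.3, (0, 3): 0.7, (1, 2): 0.1, (1, 3): 0.6, (2, 3): 0.2},
        )
        lay = default_layout(labels)
        means = group_connectivity(net, lay)
        assert means["short_range"] == pytest.approx(0.8)
        assert means["contralateral_transverse"] == pytest.approx(0.65)
        assert means["ipsilateral_longitudinal"] == pytest.approx(0.2)
        assert means["control"] == pytest.approx(0.2)

    def test_all_equal_matrix_gives_equal_group_means(self):
        labels = [f"L{i}" for i in range(1, 7)] + [f"R{i}" for i in range(1, 7)]
        c = len(labels)
        r = np.full((c, c), 0.42)
        net = ConnectivityNetwork(band=(0, 1), labels=tuple(labels), r_matrix=r)
        means = group_connectivity(net, default_layout(labels))
        for v in means.values():
            assert v == pytest.approx(0.42)

    def test_empty_group_warns(self):
        net = _toy_network(["L1", "L2"], {(0, 1): 0.5})
        with pytest.warns(UserWarning, match="no available"):
            means = group_connectivity(net, default_layout(["L1", "L2"]))
        assert np.isnan(means["control"])

    def test_build_network_trajectory_override_and_missing(self, rng):
        """Channels without an in-band oscillator give NaN rows; overrides connect."""

        class FakeDecomp:
            def __init__(self, model):
                self.best = type("B", (), {"model": model})()

        m_in = _model([(0.03, 0.5, 230)])
        m_out = _model([(2.0, 0.5, 0)])
        x = rng.normal(size=(200, 2))
        decomps = {"L1": FakeDecomp(m_in), "L2": FakeDecomp(m_out), "L3": FakeDecomp(m_in)}
        traj = {"L1": x, "L3": x @ np.array([[1.0, 0.2], [0.0, 1.0]])}
        net = build_network(decomps, (0.01, 0.1), trajectories=traj)
        i = {lab: idx for idx, lab in enumerate(net.labels)}
        assert net.r_matrix[i["L1"], i["L3"]] == pytest.approx(1.0, abs=1e-10)
        assert np.isnan(net.r_matrix[i["L1"], i["L2"]])


class TestCorrBaseline:
    def test_shared_component_and_independence(self, rng):
        shared = rng.normal(size=500)
        labels, r = corr_connectivity(
            {"L1": shared, "L2": shared * 2.0 + 1.0, "L3": rng.normal(size=500)}
        )
        i = {lab: idx for idx, lab in enumerate(labels)}
        assert r[i["L1"], i["L2"]] == pytest.approx(1.0)
        assert abs(r[i["L1"], i["L3"]]) < 0.2

    def test_zero_variance_channel_is_missing(self, rng):
        labels, r = corr_connectivity({"L1": rng.normal(size=100), "L2": np.zeros(100)})
        assert np.isnan(r[0, 1])
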