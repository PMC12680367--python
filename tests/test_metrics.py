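"""Orientation tensor, region statistics, Welch test and percolation path."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fibranet.ecm_network import FibreNetwork
from fibranet.metrics import (
    compare_anisotropy,
    dominant_direction,
    interaction_force_summary,
    max_stress_path,
    orientation_field,
    orientation_tensor,
    region_alignment_stats,
)

from conftest import star_network


# ---------------------------------------------------------------------------
# orientation tensor
# ---------------------------------------------------------------------------


def test_isotropic_pair_gives_half_identity_and_zero_anisotropy():
    net = star_network([[1.0, 0.0], [0.0, 1.0]])
    r = orientation_tensor(net, net.positions, 0)
    assert np.allclose(r.tensor, 0.5 * np.eye(2))
    assert r.anisotropy == 0.0
    assert r.degenerate


def test_collinear_fibres_are_fully_anisotropic():
    net = star_network([[1.0, 0.0], [-1.0, 0.0]])
    r = orientation_tensor(net, net.positions, 0)
    assert r.eigenvalues == pytest.approx((0.0, 1.0), abs=1e-12)
    assert r.anisotropy == pytest.approx(1.0)
    assert r.alignment_angle == pytest.approx(0.0, abs=1e-9)


def test_three_fibre_case_matches_direct_summation():
    s = 1.0 / np.sqrt(2.0)
    net = star_network([[1.0, 0.0], [0.0, 1.0], [s, s]])
    r = orientation_tensor(net, net.positions, 0)
    # direct summation oracle: sum(p p^T) / sum(|p|^2), unit p-norms
    p = np.array([[1.0, 0.0], [0.0, 1.0], [s, s]])
    oracle = sum(np.outer(v, v) for v in p) / 3.0
    assert np.allclose(r.tensor, oracle)
    assert np.allclose(r.tensor, [[0.5, 1 / 6], [1 / 6, 0.5]])
    assert r.eigenvalues == pytest.approx((1 / 3, 2 / 3))
    assert r.anisotropy == pytest.approx(0.5)
    assert r.alignment_angle == pytest.approx(45.0)


def test_orientation_requires_two_incident_fibres():
    net = star_network([[1.0, 0.0]])
    with pytest.raises(ValueError):
        orientation_tensor(net, net.positions, 0)
    # degree-1 crosslinks are reported missing from the field
    assert 1 not in orientation_field(net, net.positions)


def test_tensor_invariants_on_random_stars():
    rng = np.random.default_rng(11)
    for _ in range(20):
        k = rng.integers(2, 6)
        dirs = rng.normal(size=(k, 2))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        net = star_network(dirs)
        r = orientation_tensor(net, net.positions, 0)
        assert np.trace(r.tensor) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(r.tensor, r.tensor.T)
        assert r.eigenvalues[0] >= -1e-12
        assert 0.0 <= r.anisotropy < 1.0 + 1e-12
        assert -90.0 < r.alignment_angle <= 90.0


def test_rotation_equivariance_of_angle_and_invariance_of_anisotropy():
    rng = np.random.default_rng(4)
    dirs = rng.normal(size=(3, 2))
    net = star_network(dirs)
    base = orientation_tensor(net, net.positions, 0)
    for phi_deg in (17.0, 45.0, 130.0):
        phi = np.radians(phi_deg)
        R = np.array([[np.cos(phi), -np.sin(phi)],
                      [np.sin(phi), np.cos(phi)]])
        rot = star_network(dirs @ R.T)
        r = orientation_tensor(rot, rot.positions, 0)
        assert r.anisotropy == pytest.approx(base.anisotropy, abs=1e-10)
        diff = (r.alignment_angle - base.alignment_angle - phi_deg) % 180.0
        assert min(diff, 180.0 - diff) == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# region statistics and Welch test
# ---------------------------------------------------------------------------


def _grid_network(n=6, spacing=5.0, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.array([[i * spacing, j * spacing]
                    for j in range(n) for i in range(n)], dtype=float)
    pts += rng.normal(0, jitter, pts.shape)
    fibres = []
    for j in range(n):
        for i in range(n):
            k = j * n + i
            if i + 1 < n:
                fibres.append([k, k + 1])
            if j + 1 < n:
                fibres.append([k, k + n])
    pts_a = np.asarray(pts)
    f = np.asarray(fibres)
    rest = np.linalg.norm(pts_a[f[:, 1]] - pts_a[f[:, 0]], axis=1)
    return FibreNetwork(positions=pts, fibres=fibres, rest_lengths=rest,
                        pinned=np.zeros(len(pts), bool))


def test_region_stats_on_jittered_grid():
    net = _grid_network(jitter=0.8, seed=2)
    poly = [[-1, -1], [30, -1], [30, 30], [-1, 30]]
    st_ = region_alignment_stats(net, net.positions, poly)
    assert st_.n > 10
    assert 0.0 <= st_.mean < 1.0
    assert st_.sigma_hist[0].sum() == st_.n
    assert st_.theta_hist[0].sum() == st_.n


def test_region_stats_rejects_empty_region():
    net = _grid_network()
    with pytest.raises(ValueError):
        region_alignment_stats(net, net.positions,
                               [[100, 100], [101, 100], [101, 101]])


def test_welch_p_value_edge_cases():
    x = np.array([0.1, 0.4, 0.5, 0.6, 0.9])
    assert compare_anisotropy(x, x) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, 100)
    assert compare_anisotropy(a, a + 10.0) < 1e-6


def test_welch_matches_textbook_computation():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / 5 + vb / 5
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    dof = se2 ** 2 / ((va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4)
    expected = 2.0 * sps.t.sf(abs(t), dof)
    assert compare_anisotropy(a, b) == pytest.approx(expected, abs=1e-10)


def test_dominant_direction_of_axial_samples():
    assert dominant_direction([44.0, 46.0]) == pytest.approx(45.0)
    # axial wrap-around: -88 and +88 are 4 degrees apart, not 176
    assert abs(dominant_direction([-88.0, 88.0])) == pytest.approx(90.0)


# ---------------------------------------------------------------------------
# maximum-stress percolation path
# ---------------------------------------------------------------------------


def test_straight_path_has_unit_tortuosity():
    net = FibreNetwork(positions=[[0, 0], [1, 0], [2, 0]],
                       fibres=[[0, 1], [1, 2]],
                       rest_lengths=[0.9, 0.9],
                       pinned=[False] * 3, E_t=1.0,
                       reference_lengths_t0=[0.9, 0.9])
    r = max_stress_path(net, net.positions, 0, 2)
    assert r.exists and r.path == (0, 1, 2)
    assert r.tortuosity == pytest.approx(1.0)


def test_triangle_path_prefers_high_stress_detour():
    """A-C-B carries stress 3 per fibre; the direct A-B fibre only 1."""
    A, B, C = [0.0, 0.0], [1.0, 0.0], [0.5, 0.8]
    lac = np.sqrt(0.89)
    net = FibreNetwork(
        positions=[A, B, C],
        fibres=[[0, 1], [0, 2], [2, 1]],
        rest_lengths=[0.5, lac / 4.0, lac / 4.0],  # strains 1, 3, 3
        pinned=[False] * 3, E_t=1.0,
        reference_lengths_t0=[0.9, 0.9 * lac, 0.9 * lac])
    r = max_stress_path(net, net.positions, 0, 1)
    assert r.path == (0, 2, 1)
    assert r.total_stress == pytest.approx(6.0)
    assert r.mean_stress == pytest.approx(3.0)
    assert r.tortuosity == pytest.approx(1.0 / (2.0 * lac))
    # brute-force oracle over all simple paths
    best = min(((1.0 / 1.0, (0, 1)), (1.0 / 3 + 1.0 / 3, (0, 2, 1))))
    assert r.path == best[1]


def test_no_stretched_fibres_means_no_communication():
    net = FibreNetwork(positions=[[0, 0], [1, 0], [2, 0]],
                       fibres=[[0, 1], [1, 2]],
                       rest_lengths=[1.2, 1.2],
                       pinned=[False] * 3, E_t=1.0,
                       reference_lengths_t0=[1.0, 1.0])
    r = max_stress_path(net, net.positions, 0, 2)
    assert not r.exists
    assert r.mean_stress == 0.0 and r.path == ()


def test_source_equal_target_rejected():
    net = _grid_network()
    with pytest.raises(ValueError):
        max_stress_path(net, net.positions, 3, 3)


def _brute_force_min_inverse_stress(n_nodes, edges, source, target):
    """Exhaustive minimisation of sum(1/sigma) over all simple paths."""
    best = None
    adj = {}
    for (a, b), sigma in edges.items():
        adj.setdefault(a, []).append((b, sigma))
        adj.setdefault(b, []).append((a, sigma))
    for k in range(2, n_nodes + 1):
        for perm in itertools.permutations(range(n_nodes), k):
            if perm[0] != source or perm[-1] != target:
                continue
            w = 0.0
            ok = True
            for a, b in zip(perm[:-1], perm[1:]):
                sigma = edges.get((min(a, b), max(a, b)))
                if sigma is None:
                    ok = False
                    break
                w += 1.0 / sigma
            if ok and (best is None or (w, perm) < best):
                best = (w, perm)
    return best


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000_000))
def test_dijkstra_equals_brute_force_on_small_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    pos = rng.random((n, 2)) * 10.0
    all_pairs = list(itertools.combinations(range(n), 2))
    rng.shuffle(all_pairs)
    chosen = [tuple(p) for p in all_pairs[: max(n, int(rng.integers(n, 2 * n)))]]
    # spanning chain keeps the fibre graph connected
    chosen += [(i, i + 1) for i in range(n - 1)]
    chosen = sorted(set(tuple(sorted(e)) for e in chosen))
    lengths = np.linalg.norm(pos[[b for _, b in chosen]]
                             - pos[[a for a, _ in chosen]], axis=1)
    stretched = rng.random(len(chosen)) < 0.7
    rest = np.where(stretched, lengths / (1.0 + rng.uniform(
        0.01, 0.5, len(chosen))), lengths * 1.5)
    net = FibreNetwork(positions=pos, fibres=list(chosen),
                       rest_lengths=rest, pinned=np.zeros(n, bool),
                       E_t=1.0, reference_lengths_t0=rest)
    from fibranet.ecm_network import tensional_stress_field
    stresses = tensional_stress_field(net, net.positions)
    edges = {tuple(sorted(map(int, net.fibres[i]))): s
             for i, s in stresses.items()}
    result = max_stress_path(net, net.positions, 0, n - 1)
    oracle = _brute_force_min_inverse_stress(n, edges, 0, n - 1)
    if oracle is None:
        assert not result.exists
    else:
        assert result.exists
        assert sum(1.0 / edges[tuple(sorted(p))] for p in
                   zip(result.path[:-1], result.path[1:])) == pytest.approx(
            oracle[0], rel=1e-9)
        assert result.path == oracle[1]


def test_path_metrics_are_rotation_invariant():
    net = _grid_network(jitter=0.5, seed=8)
    shrunk = net.copy()
    rng = np.random.default_rng(9)
    factor = 1.0 / (1.0 + rng.uniform(0.05, 0.4, net.n_fibres))
    shrunk.rest_lengths = net.rest_lengths * factor  # heterogeneous stretch
    shrunk.reference_lengths_t0 = shrunk.rest_lengths.copy()
    base = max_stress_path(shrunk, shrunk.positions, 0, 35)
    phi = 0.61
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    rot = shrunk.copy()
    rot.positions = shrunk.positions @ R.T
    rot.reference_lengths_t0 = shrunk.reference_lengths_t0
    r = max_stress_path(rot, rot.positions, 0, 35)
    assert r.path == base.path
    assert r.total_stress == pytest.approx(base.total_stress, rel=1e-6)
    assert r.tortuosity == pytest.approx(base.tortuosity, rel=1e-6)


# ---------------------------------------------------------------------------
# interaction-force summary
# ---------------------------------------------------------------------------


class _FakeTrajectory:
    def __init__(self, times, forces):
        forces = np.asarray(forces, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.fa_forces = np.dstack([forces, np.zeros_like(forces)])
        self.fa_attached = np.ones(forces.shape, dtype=bool)


def test_monotone_series_peaks_at_first_sample():
    traj = _FakeTrajectory([0, 1, 2, 3], [[5], [4], [3], [2]])
    s = interaction_force_summary(traj)
    assert s["peak_time"] == 0.0 and s["peak_mean_force"] == 5.0


def test_triangular_pulse_peaks_at_its_apex():
    times = np.linspace(0, 4, 9)
    mags = 10.0 - np.abs(times - 2.0) * 4.0
    traj = _FakeTrajectory(times, mags[:, None])
    s = interaction_force_summary(traj)
    assert s["peak_time"] == pytest.approx(2.0)
    assert s["peak_mean_force"] == pytest.approx(10.0)


def test_summary_averages_over_attached_adhesions_only():
    traj = _FakeTrajectory([0.0, 1.0], [[2.0, 4.0], [2.0, 8.0]])
    traj.fa_attached[1, 1] = False
    s = interaction_force_summary(traj)
    assert s["mean"][0] == pytest.approx(3.0)
    assert s["mean"][1] == pytest.approx(2.0)
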