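"""Quantification layer: fibre alignment, stress percolation, force summaries.

Local fibre alignment is measured by a per-crosslink orientation tensor: the
second moment of the rest-length-normalised direction vectors of the incident
fibres.  Its eigenstructure yields the local alignment direction (principal
eigenvector) and an anisotropy parameter sigma_al = 1 - lambda_min/lambda_max
in [0, 1).  Stress transmission between two cells is quantified by the
maximum-stress percolation path: on the subgraph of fibres stretched beyond
their t=0 length, the path minimising the sum of inverse tensile stresses
(found with Dijkstra's algorithm), together with its total/mean stress and
tortuosity (end-to-end distance over path length).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely import contains_xy
from shapely.geometry import Polygon

from .ecm_network import FibreNetwork, tensional_stress_field

__all__ = [
    "OrientationResult",
    "PercolationResult",
    "RegionAlignmentStats",
    "orientation_tensor",
    "orientation_field",
    "region_alignment_stats",
    "compare_anisotropy",
    "dominant_direction",
    "max_stress_path",
    "interaction_force_summary",
]


@dataclass(frozen=True)
class OrientationResult:
    tensor: np.ndarray           # symmetric 2x2, unit trace
    eigenvalues: tuple           # (lambda_min, lambda_max)
    alignment_angle: float       # degrees in (-90, 90]
    anisotropy: float            # sigma_al in [0, 1)
    degenerate: bool = False     # eigen-tie: angle undefined, reported as 0


@dataclass(frozen=True)
class PercolationResult:
    exists: bool
    path: tuple                  # crosslink index sequence
    total_stress: float          # Pa
    mean_stress: float           # Pa
    path_length: float           # um, summed fibre lengths
    tortuosity: float            # in (0, 1] when the path exists


@dataclass(frozen=True)
class RegionAlignmentStats:
    mean: float
    skewness: float
    sigma_hist: tuple            # (counts, bin_edges) over [0, 1)
    theta_hist: tuple            # (counts, bin_edges) over (-90, 90]
    sigmas: np.ndarray
    thetas: np.ndarray
    n: int


# ---------------------------------------------------------------------------
# orientation tensor
# ---------------------------------------------------------------------------


def _fold_angle_deg(theta: float) -> float:
    """Fold an angle in degrees to (-90, 90]."""
    t = (theta + 90.0) % 180.0 - 90.0
    return 90.0 if t == -90.0 else t


def orientation_tensor(network: FibreNetwork, positions: np.ndarray,
                       crosslink_l: int) -> OrientationResult:
    """Local orientation tensor at one crosslink.

    Direction vectors p = (x_m - x_l)/L0 of all incident fibres, normalised
    by rest length; Theta = sum(p (x) p) / sum(|p|^2).  Requires at least two
    incident fibres.
    """
    mask_a = network.fibres[:, 0] == crosslink_l
    mask_b = network.fibres[:, 1] == crosslink_l
    idx = np.nonzero(mask_a | mask_b)[0]
    if len(idx) < 2:
        raise ValueError(
            f"crosslink {crosslink_l} has fewer than 2 incident fibres")
    other = np.where(mask_a[idx], network.fibres[idx, 1], network.fibres[idx, 0])
    p = (positions[other] - positions[crosslink_l]) / \
        network.rest_lengths[idx][:, None]
    theta = p.T @ p / np.sum(np.einsum("ij,ij->i", p, p))
    evals, evecs = np.linalg.eigh(theta)  # ascending
    lo, hi = float(evals[0]), float(evals[1])
    degenerate = np.isclose(lo, hi, rtol=1e-12, atol=1e-12)
    sigma = 0.0 if degenerate else 1.0 - lo / hi
    if degenerate:
        angle = 0.0
    else:
        v = evecs[:, 1]
        angle = _fold_angle_deg(np.degrees(np.arctan2(v[1], v[0])))
    return OrientationResult(tensor=theta, eigenvalues=(lo, hi),
                             alignment_angle=float(angle),
                             anisotropy=float(sigma), degenerate=bool(degenerate))


def orientation_field(network: FibreNetwork, positions: np.ndarray,
                      crosslinks=None):
    """OrientationResult per crosslink with >= 2 incident fibres.

    Returns dict crosslink -> OrientationResult; crosslinks with fewer than
    two incident fibres are reported as missing (excluded).
    """
    deg = np.bincount(network.fibres.ravel(), minlength=network.n_crosslinks)
    if crosslinks is None:
        crosslinks = np.arange(network.n_crosslinks)
    return {int(l): orientation_tensor(network, positions, int(l))
            for l in crosslinks if deg[l] >= 2}


# ---------------------------------------------------------------------------
# region statistics
# ---------------------------------------------------------------------------


def region_alignment_stats(network: FibreNetwork, positions: np.ndarray,
                           region_polygon, *, sigma_bins: int = 20,
                           theta_bins: int = 18) -> RegionAlignmentStats:
    """Alignment statistics over crosslinks inside a polygonal region.

    Mean and adjusted Fisher-Pearson (bias-corrected) skewness of the
    anisotropy parameter, with histograms of anisotropy and alignment angle.
    """
    poly = Polygon(region_polygon)
    inside = np.nonzero(
        contains_xy(poly, positions[:, 0], positions[:, 1]))[0]
    field = orientation_field(network, positions, inside)
    if len(field) < 2:
        raise ValueError("region contains fewer than 2 valid crosslinks")
    sigmas = np.array([r.anisotropy for r in field.values()])
    thetas = np.array([r.alignment_angle for r in field.values()])
    skew = float(stats.skew(sigmas, bias=False)) if sigmas.std() > 0 else 0.0
    sh = np.histogram(sigmas, bins=sigma_bins, range=(0.0, 1.0))
    th = np.histogram(thetas, bins=theta_bins, range=(-90.0, 90.0))
    return RegionAlignmentStats(
        mean=float(sigmas.mean()), skewness=skew, sigma_hist=sh, theta_hist=th,
        sigmas=sigmas, thetas=thetas, n=len(sigmas))


def dominant_direction(thetas_deg) -> float:
    """Dominant axial direction of a sample of alignment angles, degrees.

    Axial data (theta and theta+180 equivalent): the circular mean of the
    doubled angles, folded back to (-90, 90].  A robust estimator of the
    centre of the alignment-angle histogram.
    """
    ang = np.deg2rad(2.0 * np.asarray(thetas_deg, dtype=float))
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return _fold_angle_deg(np.degrees(mean) / 2.0)


def compare_anisotropy(sample_a, sample_b, *, welch: bool = True) -> float:
    """Two-sided two-sample t-test p-value on anisotropy samples.

    Welch's unequal-variance test by default; set ``welch=False`` for the
    pooled-variance variant.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    if a.std() == 0.0 and b.std() == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        raise ValueError("zero variance in both samples with distinct means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# maximum-stress percolation path
# ---------------------------------------------------------------------------


def _dijkstra_lex(adjacency, source, target):
    """Dijkstra minimising total weight, breaking ties by lexicographically
    smallest node sequence.  Returns (cost, path tuple) or None."""
    heap = [(0.0, (source,))]
    best = {}
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node == target:
            return cost, path
        if node in best and best[node] < (cost, path):
            continue
        for nbr, w in adjacency.get(node, ()):
            if nbr in path:
                continue
            cand = (cost + w, path + (nbr,))
            key = cand[1][-1]
            if key not in best or best[key] > cand:
                best[key] = cand
                heapq.heappush(heap, cand)
    return None


def max_stress_path(network: FibreNetwork, positions: np.ndarray,
                    source_crosslink: int, target_crosslink: int
                    ) -> PercolationResult:
    """Maximum-stress transmission path between two crosslinks.

    Only fibres stretched beyond their t=0 length carry stress; on that
    subgraph the Dijkstra path minimising sum(1/sigma) maximises transmitted
    stress.  When no stretched-fibre path connects the endpoints there is no
    mechanical communication and ``exists`` is False.  Tortuosity is the
    end-to-end Euclidean distance over the summed fibre lengths of the path.
    """
    if source_crosslink == target_crosslink:
        raise ValueError("source and target crosslinks must differ")
    stress = tensional_stress_field(network, positions)
    adjacency: dict[int, list] = {}
    for fi, sigma in stress.items():
        a, b = map(int, network.fibres[fi])
        w = 1.0 / sigma
        adjacency.setdefault(a, []).append((b, w))
        adjacency.setdefault(b, []).append((a, w))
    for node in adjacency:
        adjacency[node].sort()
    found = _dijkstra_lex(adjacency, int(source_crosslink),
                          int(target_crosslink))
    if found is None:
        return PercolationResult(exists=False, path=(), total_stress=0.0,
                                 mean_stress=0.0, path_length=0.0,
                                 tortuosity=0.0)
    _, path = found
    edge_stress = {tuple(sorted(map(int, network.fibres[fi]))): s
                   for fi, s in stress.items()}
    stresses, length = [], 0.0
    for a, b in zip(path[:-1], path[1:]):
        stresses.append(edge_stress[tuple(sorted((a, b)))])
        length += float(np.linalg.norm(positions[a] - positions[b]))
    euclid = float(np.linalg.norm(positions[path[0]] - positions[path[-1]]))
    return PercolationResult(
        exists=True, path=tuple(path), total_stress=float(np.sum(stresses)),
        mean_stress=float(np.mean(stresses)), path_length=length,
        tortuosity=euclid / length)


# ---------------------------------------------------------------------------
# interaction-force summaries
# ---------------------------------------------------------------------------


def interaction_force_summary(trajectory):
    """Peak of the mean adhesion force and the full mean +/- sd time series.

    At every sample, the mean and standard deviation of the adhesion force
    magnitude over all attached adhesions; returns a dict with the peak of
    the mean curve, its time, and the per-time series.
    """
    times = np.asarray(trajectory.times)
    forces = np.linalg.norm(np.asarray(trajectory.fa_forces), axis=2)
    attached = np.asarray(trajectory.fa_attached, dtype=bool)
    if forces.size == 0:
        raise ValueError("trajectory carries no adhesion records")
    mean = np.full(len(times), np.nan)
    sd = np.full(len(times), np.nan)
    any_attached = attached.any(axis=1)
    for s in np.nonzero(any_attached)[0]:
        vals = forces[s, attached[s]]
        mean[s] = vals.mean()
        sd[s] = vals.std()
    if not any_attached.any():
        raise ValueError("no attached adhesions at any sample")
    idx = int(np.nanargmax(mean))
    return {
        "peak_mean_force": float(mean[idx]),
        "peak_time": float(times[idx]),
        "times": times,
        "mean": mean,
        "sd": sd,
    }
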