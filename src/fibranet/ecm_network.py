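"""Crosslinked elastic fibre networks representing the extracellular matrix.

The ECM is a graph whose nodes are crosslinks (points where fibres are bound
together) and whose edges are elastic fibres.  Fibres respond asymmetrically to
stretch and compression: a stretched fibre behaves as a linear spring with
Young's modulus ``E_t`` while a buckled (compressed) fibre resists with the
reduced modulus ``rho * E_t``.  Forces follow the convention 1 Pa = 1 pN/um^2,
so ``E_t [Pa] * A [um^2] * strain`` is a force in pN directly.

Networks are generated as Voronoi tessellations of uniformly random seed
points, mirroring the architecture of random collagenous gels: low nodal
connectivity (generic Voronoi vertices have degree 3) and no preferred
orientation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi

logger = logging.getLogger(__name__)

__all__ = [
    "FibreNetwork",
    "generate_voronoi_network",
    "fibre_tension",
    "fibre_lengths",
    "net_elastic_forces",
    "elastic_energy",
    "relax_network",
    "tensional_stress_field",
    "save_network_csv",
    "load_network_csv",
    "network_to_json",
    "network_from_json",
]

#: relative elongation beyond the t=0 length above which a fibre counts as
#: stretched (stress-carrying); separates mechanically loaded fibres from the
#: far-field tail of numerically tiny length changes.
STRETCH_EPS = 1e-4


@dataclass
class FibreNetwork:
    """Crosslinked elastic fibre network.

    Parameters
    ----------
    positions : (M, 2) float array
        Crosslink coordinates, um.
    fibres : (K, 2) int array
        Crosslink index pairs, one row per fibre.
    rest_lengths : (K,) float array
        Load-free fibre lengths L0, um.
    pinned : (M,) bool array
        Crosslinks held fixed (domain-boundary nodes by default).
    E_t : float
        Young's modulus of a stretched fibre, Pa.
    compression_factor : float
        rho in [0, 1]; buckled fibres use modulus ``rho * E_t``.
    area : float
        Fibre cross-section, um^2.
    eta : float
        Damping coefficient, pN s/um.
    reference_lengths_t0 : (K,) float array
        Fibre lengths at the start of the simulation of interest (used by the
        tensional-stress selection rule).
    """

    positions: np.ndarray
    fibres: np.ndarray
    rest_lengths: np.ndarray
    pinned: np.ndarray
    E_t: float = 1e7
    compression_factor: float = 0.1
    area: float = 0.01
    eta: float = 2000.0
    reference_lengths_t0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.fibres = np.asarray(self.fibres, dtype=int).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float).ravel()
        self.pinned = np.asarray(self.pinned, dtype=bool).ravel()
        if self.reference_lengths_t0 is None:
            self.reference_lengths_t0 = fibre_lengths(self, self.positions)
        else:
            self.reference_lengths_t0 = np.asarray(
                self.reference_lengths_t0, dtype=float
            ).ravel()
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        M, K = self.n_crosslinks, self.n_fibres
        if self.pinned.shape != (M,):
            raise ValueError("pinned mask length mismatch")
        if self.rest_lengths.shape != (K,) or self.reference_lengths_t0.shape != (K,):
            raise ValueError("per-fibre array length mismatch")
        if K and (self.fibres.min() < 0 or self.fibres.max() >= M):
            raise ValueError("fibre references an invalid crosslink index")
        if np.any(self.fibres[:, 0] == self.fibres[:, 1]):
            raise ValueError("fibre connects a crosslink to itself")
        key = np.sort(self.fibres, axis=1)
        if len({tuple(k) for k in key}) != K:
            raise ValueError("duplicate fibres")
        if np.any(self.rest_lengths <= 0):
            raise ValueError("rest lengths must be positive")
        if self.E_t <= 0 or self.area <= 0 or self.eta <= 0:
            raise ValueError("E_t, area and eta must be positive")
        if not 0.0 <= self.compression_factor <= 1.0:
            raise ValueError("compression_factor must lie in [0, 1]")
        # connectivity on non-isolated crosslinks
        if K:
            deg = np.bincount(self.fibres.ravel(), minlength=M)
            used = deg > 0
            adj = csr_matrix(
                (np.ones(K), (self.fibres[:, 0], self.fibres[:, 1])), shape=(M, M)
            )
            n_comp, labels = connected_components(adj, directed=False)
            if len(set(labels[used])) > 1:
                raise ValueError("fibre graph is not connected")

    # -- convenience ------------------------------------------------------
    @property
    def n_crosslinks(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fibres(self) -> int:
        return self.fibres.shape[0]

    def mean_fibre_length(self) -> float:
        return float(np.mean(self.rest_lengths))

    def spring_constants(self) -> np.ndarray:
        """Tensile spring constant E_t*A/L0 per fibre, pN/um."""
        return self.E_t * self.area / self.rest_lengths

    def copy(self) -> "FibreNetwork":
        return replace(
            self,
            positions=self.positions.copy(),
            fibres=self.fibres.copy(),
            rest_lengths=self.rest_lengths.copy(),
            pinned=self.pinned.copy(),
            reference_lengths_t0=self.reference_lengths_t0.copy(),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _clip_segment(p0, p1, width, height):
    """Liang-Barsky clip of segment p0-p1 to [0, width] x [0, height].

    Returns (q0, q1) or None when the segment misses the box.
    """
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for dim, lim in ((0, width), (1, height)):
        for sign, bound in ((-1.0, 0.0), (1.0, lim)):
            denom = sign * d[dim]
            dist = sign * (bound - p0[dim])
            if denom == 0.0:
                if dist < 0.0:
                    return None
                continue
            t = dist / denom
            if denom < 0.0:
                if t > t1:
                    return None
                t0 = max(t0, t)
            else:
                if t < t0:
                    return None
                t1 = min(t1, t)
    if t1 <= t0:
        return None
    return p0 + t0 * d, p0 + t1 * d


def _voronoi_segments(seeds: np.ndarray, width: float, height: float):
    """Voronoi edge segments of `seeds` clipped to the domain box."""
    vor = Voronoi(seeds)
    centre = seeds.mean(axis=0)
    span = 4.0 * max(width, height)
    segments = []
    for (a, b), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            seg = _clip_segment(vor.vertices[v1], vor.vertices[v2], width, height)
        else:
            # semi-infinite ridge: extend from the finite vertex along the
            # outward normal of the seed pair
            vfin = vor.vertices[v2 if v1 < 0 else v1]
            tangent = seeds[b] - seeds[a]
            tangent = tangent / np.linalg.norm(tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = 0.5 * (seeds[a] + seeds[b])
            if np.dot(midpoint - centre, normal) < 0:
                normal = -normal
            seg = _clip_segment(vfin, vfin + span * normal, width, height)
        if seg is not None:
            segments.append(seg)
    return segments


def generate_voronoi_network(
    domain_width: float,
    domain_height: float,
    n_seeds: int,
    seed: int,
    *,
    E_t: float = 1e7,
    compression_factor: float = 0.1,
    area: float = 0.01,
    eta: float = 2000.0,
    max_retries: int = 5,
) -> FibreNetwork:
    """Seeded random Voronoi fibre network on ``[0, W] x [0, H]``.

    Crosslinks are Voronoi vertices of ``n_seeds`` uniformly random points;
    fibres are Voronoi edges, clipped at the domain boundary.  Cut points on
    the boundary become pinned crosslinks.  Rest lengths equal the generated
    lengths, so the network starts load-free.  Deterministic for fixed seed.
    """
    if n_seeds < 4:
        raise ValueError("need at least 4 seed points")
    if domain_width <= 0 or domain_height <= 0:
        raise ValueError("domain dimensions must be positive")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        seeds = rng.random((n_seeds, 2)) * np.array([domain_width, domain_height])
        try:
            segments = _voronoi_segments(seeds, domain_width, domain_height)
            net = _segments_to_network(
                segments, domain_width, domain_height,
                E_t=E_t, compression_factor=compression_factor, area=area, eta=eta,
            )
            return net
        except Exception as exc:  # degenerate (e.g. collinear) seed sets
            logger.warning(
                "Voronoi generation attempt %d failed (%s); regenerating with "
                "perturbed seeds", attempt + 1, exc,
            )
    raise RuntimeError(f"Voronoi generation failed after {max_retries} attempts")


def _segments_to_network(segments, width, height, **params) -> FibreNetwork:
    decimals = 9
    index: dict[tuple, int] = {}
    points: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []

    def node_id(p: np.ndarray) -> int:
        key = (round(float(p[0]), decimals), round(float(p[1]), decimals))
        if key not in index:
            index[key] = len(points)
            points.append(np.array(key))
        return index[key]

    for p0, p1 in segments:
        if np.linalg.norm(p1 - p0) < 10 ** (-decimals + 1):
            continue
        a, b = node_id(p0), node_id(p1)
        if a != b:
            edges.append((min(a, b), max(a, b)))
    edges = sorted(set(edges))
    pos = np.array(points)
    fib = np.array(edges, dtype=int)
    if len(fib) == 0:
        raise ValueError("no fibres inside the domain")

    # keep largest connected component
    adj = csr_matrix((np.ones(len(fib)), (fib[:, 0], fib[:, 1])),
                     shape=(len(pos), len(pos)))
    _, labels = connected_components(adj, directed=False)
    main = np.argmax(np.bincount(labels))
    keep = labels == main
    remap = -np.ones(len(pos), dtype=int)
    remap[keep] = np.arange(keep.sum())
    pos = pos[keep]
    fib = remap[fib]
    fib = fib[(fib >= 0).all(axis=1)]

    tol = 10 ** (-decimals + 2)
    on_boundary = (
        (np.abs(pos[:, 0]) < tol) | (np.abs(pos[:, 0] - width) < tol)
        | (np.abs(pos[:, 1]) < tol) | (np.abs(pos[:, 1] - height) < tol)
    )
    lengths = np.linalg.norm(pos[fib[:, 1]] - pos[fib[:, 0]], axis=1)
    return FibreNetwork(
        positions=pos, fibres=fib, rest_lengths=lengths, pinned=on_boundary,
        reference_lengths_t0=lengths.copy(), **params,
    )


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------


def fibre_lengths(network: FibreNetwork, positions: np.ndarray) -> np.ndarray:
    d = positions[network.fibres[:, 1]] - positions[network.fibres[:, 0]]
    return np.linalg.norm(d, axis=1)


def _tensions(network: FibreNetwork, lengths: np.ndarray) -> np.ndarray:
    """Signed fibre tensions, pN (+ = tensile), bilinear stretch/buckle law."""
    strain = (lengths - network.rest_lengths) / network.rest_lengths
    ea = network.E_t * network.area
    return np.where(strain >= 0.0, ea * strain,
                    network.compression_factor * ea * strain)


def fibre_tension(network: FibreNetwork, fibre_index: int,
                  positions: np.ndarray) -> float:
    """Signed axial force in one fibre, pN; positive = tensile."""
    if not 0 <= fibre_index < network.n_fibres:
        raise IndexError("fibre index out of range")
    a, b = network.fibres[fibre_index]
    length = float(np.linalg.norm(positions[b] - positions[a]))
    if length == 0.0:
        raise ValueError("degenerate fibre of zero length")
    return float(_tensions(network, np.array([length]))[0])


def net_elastic_forces(network: FibreNetwork, positions: np.ndarray) -> np.ndarray:
    """Net elastic force on every crosslink, pN, shape (M, 2).

    Each fibre contributes equal and opposite forces at its two endpoints
    (bit-exact Newton pairs).
    """
    d = positions[network.fibres[:, 1]] - positions[network.fibres[:, 0]]
    lengths = np.linalg.norm(d, axis=1)
    if np.any(lengths == 0.0):
        raise ValueError("degenerate fibre of zero length")
    t = _tensions(network, lengths)
    contrib = (t / lengths)[:, None] * d  # force on endpoint a, toward b
    forces = np.zeros_like(positions)
    np.add.at(forces, network.fibres[:, 0], contrib)
    np.subtract.at(forces, network.fibres[:, 1], contrib)
    return forces


def elastic_energy(network: FibreNetwork, positions: np.ndarray) -> float:
    """Total piecewise-quadratic elastic energy, pN um."""
    lengths = fibre_lengths(network, positions)
    dl = lengths - network.rest_lengths
    k = network.spring_constants()
    k_eff = np.where(dl >= 0.0, k, network.compression_factor * k)
    return float(0.5 * np.sum(k_eff * dl * dl))


def relax_network(network: FibreNetwork, tol: float = 1e-3,
                  max_steps: int = 200_000) -> FibreNetwork:
    """Overdamped relaxation eta dx/dt = F_el with pinned nodes fixed.

    Forward Euler with adaptive step dt <= 0.2 eta / k_max where k_max is the
    stiffest spring constant incident on any node; steps that increase the
    elastic energy are rejected and the step halved.  Terminates when the
    largest per-node force drops below ``tol`` (pN); the reference lengths at
    t=0 are reset to the relaxed lengths.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pos = network.positions.copy()
    free = ~network.pinned
    k = network.spring_constants()
    k_max = 0.0
    for i, (a, b) in enumerate(network.fibres):
        k_max = max(k_max, k[i])
    dt = 0.2 * network.eta / k_max
    energy = elastic_energy(network, pos)
    for _ in range(max_steps):
        forces = net_elastic_forces(network, pos)
        forces[~free] = 0.0
        fmax = np.abs(forces).max() if len(forces) else 0.0
        if fmax < tol:
            out = network.copy()
            out.positions = pos
            out.reference_lengths_t0 = fibre_lengths(out, pos)
            return out
        step = dt
        while True:
            trial = pos + step * forces / network.eta
            new_energy = elastic_energy(network, trial)
            if new_energy <= energy or step < 1e-12 * dt:
                break
            step *= 0.5
        pos, energy = trial, new_energy
    residual = np.abs(forces).max()
    raise RuntimeError(
        f"relaxation did not converge within {max_steps} steps "
        f"(residual {residual:.3g} pN > tol {tol:.3g} pN)"
    )


def tensional_stress_field(network: FibreNetwork,
                           positions: np.ndarray) -> dict[int, float]:
    """Tensile stress (Pa) of fibres longer now than at t=0.

    sigma = E_t * (len - L0) / L0 for every fibre whose current length exceeds
    its recorded length at t=0; all other fibres are absent from the map.
    """
    lengths = fibre_lengths(network, positions)
    ref = network.reference_lengths_t0
    stretched = lengths > ref * (1.0 + STRETCH_EPS)
    strain = (lengths - network.rest_lengths) / network.rest_lengths
    return {
        int(i): float(network.E_t * strain[i]) for i in np.nonzero(stretched)[0]
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_network_csv(network: FibreNetwork, nodes_path, edges_path) -> None:
    import pandas as pd

    pd.DataFrame({
        "id": np.arange(network.n_crosslinks),
        "x": network.positions[:, 0],
        "y": network.positions[:, 1],
        "pinned": network.pinned.astype(int),
    }).to_csv(nodes_path, index=False)
    pd.DataFrame({
        "id": np.arange(network.n_fibres),
        "node_a": network.fibres[:, 0],
        "node_b": network.fibres[:, 1],
        "rest_length": network.rest_lengths,
    }).to_csv(edges_path, index=False)


def load_network_csv(nodes_path, edges_path, **params) -> FibreNetwork:
    import pandas as pd

    nodes = pd.read_csv(nodes_path).sort_values("id")
    edges = pd.read_csv(edges_path).sort_values("id")
    return FibreNetwork(
        positions=nodes[["x", "y"]].to_numpy(),
        fibres=edges[["node_a", "node_b"]].to_numpy(dtype=int),
        rest_lengths=edges["rest_length"].to_numpy(),
        pinned=nodes["pinned"].to_numpy(dtype=bool),
        **params,
    )


def network_to_json(network: FibreNetwork) -> str:
    return json.dumps({
        "positions": network.positions.tolist(),
        "fibres": network.fibres.tolist(),
        "rest_lengths": network.rest_lengths.tolist(),
        "pinned": network.pinned.astype(int).tolist(),
        "E_t": network.E_t,
        "compression_factor": network.compression_factor,
        "area": network.area,
        "eta": network.eta,
        "reference_lengths_t0": network.reference_lengths_t0.tolist(),
    })


def network_from_json(doc: str) -> FibreNetwork:
    data = json.loads(doc)
    return FibreNetwork(
        positions=np.array(data["positions"]),
        fibres=np.array(data["fibres"], dtype=int),
        rest_lengths=np.array(data["rest_lengths"]),
        pinned=np.array(data["pinned"], dtype=bool),
        E_t=data["E_t"],
        compression_factor=data["compression_factor"],
        area=data["area"],
        eta=data["eta"],
        reference_lengths_t0=np.array(data["reference_lengths_t0"]),
    )
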