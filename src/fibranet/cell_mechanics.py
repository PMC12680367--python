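"""Polygonal cell agents: viscoelastic structure and active contraction.

A cell is an organising centre plus a set of vertices joined to it by
Kelvin-Voigt segments (spring + dashpot in parallel) that stand for actin
bundles.  Harmonic angular springs between consecutive segments resist shape
changes, and myosin-driven contraction is a constant force pulling every
vertex toward the centre.  Elongated cells have two segments and a single
natural angle of pi; round and fan-shaped cells are closed polygons whose
natural angles sum to 2*pi.

All structural and contraction forces are internal: the centre receives the
exact negative of the summed vertex forces, so an isolated cell conserves
momentum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Cell",
    "make_cell",
    "structural_forces",
    "elastic_angular_forces",
    "contraction_forces",
    "cell_mechanical_energy",
]


@dataclass
class Cell:
    centre: np.ndarray                    # (2,) um
    vertices: np.ndarray                  # (N, 2) um
    segment_rest_lengths: np.ndarray      # (N,) um
    natural_angles: np.ndarray            # (N,) closed / (1,) elongated, rad
    k_seg: float = 1.5e4                  # pN/um
    gamma_seg: float = 4e3                # pN s/um
    k_ang: float = 1e4                    # pN um/rad
    eta: float = 1e4                      # pN s/um, cell damping
    F_co: float = 0.0                     # pN, contraction magnitude
    shape_tag: str = "round"
    N_per_fa: int = 1000                  # available integrins per adhesion site
    closed: bool = True

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(2)
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        self.segment_rest_lengths = np.asarray(
            self.segment_rest_lengths, dtype=float).ravel()
        self.natural_angles = np.asarray(self.natural_angles, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        n = self.n_vertices
        if n < 2:
            raise ValueError("a cell needs at least 2 vertices")
        if (self.shape_tag == "elongated") != (n == 2):
            raise ValueError("elongated cells have exactly 2 vertices")
        if np.any(self.segment_rest_lengths <= 0):
            raise ValueError("segment rest lengths must be positive")
        if self.k_seg < 0 or self.gamma_seg < 0 or self.k_ang < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.closed:
            if self.natural_angles.shape != (n,):
                raise ValueError("closed cells need one natural angle per vertex")
            if not np.isclose(self.natural_angles.sum(), 2 * np.pi, atol=1e-8):
                raise ValueError("natural angles of a closed cell must sum to 2*pi")
        else:
            if self.natural_angles.shape != (1,):
                raise ValueError("elongated cells carry a single natural angle")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def copy(self) -> "Cell":
        return Cell(
            centre=self.centre.copy(), vertices=self.vertices.copy(),
            segment_rest_lengths=self.segment_rest_lengths.copy(),
            natural_angles=self.natural_angles.copy(), k_seg=self.k_seg,
            gamma_seg=self.gamma_seg, k_ang=self.k_ang, eta=self.eta,
            F_co=self.F_co,
            shape_tag=self.shape_tag, N_per_fa=self.N_per_fa, closed=self.closed,
        )


def geometry_angles(cell: Cell) -> np.ndarray:
    """Angles at the centre between consecutive segments, in (0, 2*pi).

    For closed cells the N cyclic angles; for elongated cells the single angle
    between the two segments.
    """
    rel = cell.vertices - cell.centre
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    if cell.closed:
        d = phi[np.r_[1:len(phi), 0]] - phi
    else:
        d = phi[1:] - phi[:-1]
    return np.mod(d, 2 * np.pi)


def _angles_from_geometry(centre, vertices, closed) -> np.ndarray:
    rel = np.asarray(vertices) - np.asarray(centre)
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    if closed:
        d = phi[np.r_[1:len(phi), 0]] - phi
    else:
        d = phi[1:] - phi[:-1]
    return np.mod(d, 2 * np.pi)


def make_cell(shape_tag: str, centre, size: float, orientation: float = 0.0,
              *, n_vertices: int = 8, **params) -> Cell:
    """Construct a cell of the given shape at mechanical equilibrium.

    ``size`` is the circumradius for round/fan cells and the end-to-end length
    for elongated cells.  Rest lengths and natural angles are taken from the
    constructed geometry, so a freshly made cell exerts no structural force.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    centre = np.asarray(centre, dtype=float).reshape(2)
    if shape_tag == "elongated":
        u = np.array([np.cos(orientation), np.sin(orientation)])
        vertices = np.array([centre + 0.5 * size * u, centre - 0.5 * size * u])
        rest = np.full(2, 0.5 * size)
        angles = np.array([np.pi])
        closed = False
    elif shape_tag == "round":
        phi = orientation + 2 * np.pi * np.arange(n_vertices) / n_vertices
        vertices = centre + size * np.c_[np.cos(phi), np.sin(phi)]
        rest = np.full(n_vertices, float(size))
        angles = np.full(n_vertices, 2 * np.pi / n_vertices)
        closed = True
    elif shape_tag == "fan":
        # leading arc spanning a half-disc plus a single rear vertex
        n_front = max(n_vertices - 1, 4)
        phi = orientation + np.linspace(-np.pi / 2, np.pi / 2, n_front)
        front = centre + size * np.c_[np.cos(phi), np.sin(phi)]
        rear = centre + 0.5 * size * np.array(
            [np.cos(orientation + np.pi), np.sin(orientation + np.pi)])
        vertices = np.vstack([front, rear])
        # order by polar angle so cyclic angles are positive
        rel = vertices - centre
        order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
        vertices = vertices[order]
        rest = np.linalg.norm(vertices - centre, axis=1)
        angles = _angles_from_geometry(centre, vertices, True)
        closed = True
    else:
        raise ValueError(f"unknown shape_tag {shape_tag!r}")
    return Cell(centre=centre, vertices=vertices, segment_rest_lengths=rest,
                natural_angles=angles, shape_tag=shape_tag, closed=closed,
                **params)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def elastic_angular_forces(cell: Cell) -> np.ndarray:
    """Position-dependent structural forces on the vertices, pN, shape (N, 2).

    Spring term along each segment plus the analytic gradient of the harmonic
    angle potential 0.5*k_ang*(theta - theta0)^2.  The viscous Kelvin-Voigt
    branch is velocity-dependent and handled separately.  The centre reaction
    is the exact negative of the summed vertex forces.
    """
    rel = cell.vertices - cell.centre
    lengths = np.linalg.norm(rel, axis=1)
    if np.any(lengths == 0.0):
        raise ValueError("zero-length cell segment")
    unit = rel / lengths[:, None]
    forces = -cell.k_seg * (lengths - cell.segment_rest_lengths)[:, None] * unit

    if cell.k_ang > 0.0:
        theta = geometry_angles(cell)
        if cell.closed:
            dev = theta - cell.natural_angles
            pairs = [(j, (j + 1) % cell.n_vertices, dev[j])
                     for j in range(cell.n_vertices)]
        else:
            dev = theta - cell.natural_angles
            pairs = [(0, 1, dev[0])]
        # d phi_i / d x_i = perp(unit_i) / r_i ; theta_j = phi_{j+1} - phi_j
        perp = np.c_[-unit[:, 1], unit[:, 0]] / lengths[:, None]
        for i, j, d in pairs:
            g = cell.k_ang * d
            forces[i] += g * perp[i]
            forces[j] -= g * perp[j]
    return forces


def structural_forces(cell: Cell, vertex_velocities=None,
                      centre_velocity=None) -> np.ndarray:
    """Full structural force F_st on each vertex, pN, shape (N, 2).

    Includes the Kelvin-Voigt viscous term gamma_seg * (segment elongation
    rate) along the segment axis when velocities are supplied.
    """
    forces = elastic_angular_forces(cell)
    if vertex_velocities is not None and cell.gamma_seg > 0.0:
        vv = np.asarray(vertex_velocities, dtype=float).reshape(-1, 2)
        vc = (np.zeros(2) if centre_velocity is None
              else np.asarray(centre_velocity, dtype=float).reshape(2))
        rel = cell.vertices - cell.centre
        lengths = np.linalg.norm(rel, axis=1)
        unit = rel / lengths[:, None]
        rate = np.einsum("ij,ij->i", vv - vc, unit)  # elongation rate
        forces -= cell.gamma_seg * rate[:, None] * unit
    return forces


def contraction_forces(cell: Cell) -> np.ndarray:
    """Active contraction force on each vertex: F_co toward the centre."""
    if cell.F_co == 0.0:
        return np.zeros_like(cell.vertices)
    rel = cell.vertices - cell.centre
    lengths = np.linalg.norm(rel, axis=1)
    unit = rel / lengths[:, None]
    return -cell.F_co * unit


def cell_mechanical_energy(cell: Cell) -> float:
    """Segment-spring plus angular potential energy, pN um (no contraction)."""
    rel = cell.vertices - cell.centre
    lengths = np.linalg.norm(rel, axis=1)
    e = 0.5 * cell.k_seg * np.sum((lengths - cell.segment_rest_lengths) ** 2)
    theta = geometry_angles(cell)
    e += 0.5 * cell.k_ang * np.sum((theta - cell.natural_angles) ** 2)
    return float(e)
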