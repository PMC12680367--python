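"""Coupled overdamped dynamics of ECM network, cell agents and adhesions.

The full model couples three sets of equations in the overdamped limit:
crosslink positions move under net fibre elasticity plus adhesion forces,
cell centres and vertices move under structural, contractile and adhesion
forces, and the bound-integrin count of every focal adhesion follows the
catch-bond binding ODE.  Adhesion forces obey Newton's third law between the
cell vertex and its ECM crosslink.

The Kelvin-Voigt dashpot of the cell segments makes the velocity field
implicit within each cell; the per-cell linear system (a few degrees of
freedom) is solved exactly at every right-hand-side evaluation.  Time
integration uses an implicit multistep scheme (BDF) with an explicit
Jacobian sparsity pattern, which copes with the wide stiffness range spanned
by soft (kPa) and stiff (100 MPa) fibre networks.

A detachment event fires when the bound-integrin count of an adhesion drops
below one; the adhesion is then removed from both coupled equations for the
rest of the run (no de novo adhesion formation).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.sparse import lil_matrix

from .cell_mechanics import (
    Cell,
    _angles_from_geometry,
    cell_mechanical_energy,
    contraction_forces,
    elastic_angular_forces,
    make_cell,
)
from .ecm_network import (
    FibreNetwork,
    elastic_energy,
    fibre_lengths,
    generate_voronoi_network,
    net_elastic_forces,
)
from .focal_adhesion import CatchBondParams, FocalAdhesion, koff

__all__ = [
    "SimulationState",
    "Trajectory",
    "build_named_scenario",
    "initialize_scenario",
    "step",
    "run",
    "evaluate_forces",
    "total_energy",
]

NAMED_SCENARIOS = ("single_round", "two_elongated", "zigzag", "ladder", "multi_fan")


@dataclass
class SimulationState:
    """Complete model state advanced by the integrator."""

    time: float
    network: FibreNetwork
    cells: list[Cell]
    fas: list[FocalAdhesion]
    events: list[tuple] = field(default_factory=list)
    config: dict | None = None
    contraction_on: bool = True
    pulling: list[dict] = field(default_factory=list)
    contraction_ramp: float = 0.0   # s; activation time of the contraction

    def copy(self) -> "SimulationState":
        return SimulationState(
            time=self.time,
            network=self.network.copy(),
            cells=[c.copy() for c in self.cells],
            fas=[copy.copy(f) for f in self.fas],
            events=list(self.events),
            config=self.config,
            contraction_on=self.contraction_on,
            pulling=copy.deepcopy(self.pulling),
            contraction_ramp=self.contraction_ramp,
        )


@dataclass
class Trajectory:
    """Sampled output of a run: times, positions, adhesion records, events."""

    times: np.ndarray                 # (S,)
    ecm_positions: np.ndarray         # (S, M, 2)
    cell_centres: np.ndarray          # (S, C, 2)
    cell_vertices: list               # per cell: (S, Nv, 2)
    nb: np.ndarray                    # (S, n_fa)
    fa_forces: np.ndarray             # (S, n_fa, 2), force on the cell vertex
    fa_eps: np.ndarray                # (S, n_fa) integrin extension, um
    fa_attached: np.ndarray           # (S, n_fa) bool
    events: list
    final_state: SimulationState | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------


class _Layout:
    def __init__(self, state: SimulationState) -> None:
        self.free_idx = np.nonzero(~state.network.pinned)[0]
        n = 2 * len(self.free_idx)
        self.ecm_slice = slice(0, n)
        self.cell_slices = []
        for cell in state.cells:
            c = slice(n, n + 2)
            v = slice(n + 2, n + 2 + 2 * cell.n_vertices)
            self.cell_slices.append((c, v))
            n = v.stop
        self.nb_offset = n
        self.size = n + len(state.fas)

    def pack(self, state: SimulationState) -> np.ndarray:
        y = np.empty(self.size)
        y[self.ecm_slice] = state.network.positions[self.free_idx].ravel()
        for cell, (c, v) in zip(state.cells, self.cell_slices):
            y[c] = cell.centre
            y[v] = cell.vertices.ravel()
        for k, fa in enumerate(state.fas):
            y[self.nb_offset + k] = fa.N_b
        return y

    def unpack_into(self, state: SimulationState, y: np.ndarray) -> None:
        state.network.positions[self.free_idx] = y[self.ecm_slice].reshape(-1, 2)
        for cell, (c, v) in zip(state.cells, self.cell_slices):
            cell.centre = y[c].copy()
            cell.vertices = y[v].reshape(-1, 2).copy()
        for k, fa in enumerate(state.fas):
            if fa.attached:
                fa.N_b = float(min(max(y[self.nb_offset + k], 0.0), fa.N))


# ---------------------------------------------------------------------------
# force assembly
# ---------------------------------------------------------------------------


def _assemble_forces(state: SimulationState):
    """All position-dependent forces of the coupled system.

    Returns (ecm_forces, vertex_forces, centre_loads, fa_eps, fa_force_vec):
    ecm_forces include fibre elasticity and adhesion reactions; vertex_forces
    include elastic+angular, contraction, adhesion and external pulling;
    centre_loads are the Eq-of-motion right-hand sides for the cell centres,
    i.e. minus the summed internal (structural + contraction) vertex forces.
    """
    net = state.network
    ecm_forces = net_elastic_forces(net, net.positions)
    if state.contraction_on:
        # smooth myosin activation: contraction builds up over the ramp time
        if state.contraction_ramp > 0.0:
            ramp = min(max(state.time, 0.0) / state.contraction_ramp, 1.0)
        else:
            ramp = 1.0
    else:
        ramp = 0.0
    vertex_forces = []
    centre_loads = []
    for cell in state.cells:
        e = elastic_angular_forces(cell)
        c = ramp * contraction_forces(cell) if ramp else np.zeros_like(e)
        vertex_forces.append(e + c)
        centre_loads.append(-(e + c).sum(axis=0))
    for pull in state.pulling:
        vertex_forces[pull["cell"]][pull["vertex"]] += np.asarray(
            pull["force"], dtype=float)
    n_fa = len(state.fas)
    fa_eps = np.zeros(n_fa)
    fa_force = np.zeros((n_fa, 2))
    for k, fa in enumerate(state.fas):
        if not fa.attached:
            continue
        vpos = state.cells[fa.cell_index].vertices[fa.vertex_index]
        xpos = net.positions[fa.crosslink_index]
        d = vpos - xpos
        dist = float(np.hypot(d[0], d[1]))
        if dist == 0.0:
            raise ValueError("coincident adhesion endpoints")
        eps = dist - fa.params.L0_i
        fvec = -fa.N_b * fa.params.k_i * eps * d / dist
        fa_eps[k] = eps
        fa_force[k] = fvec
        vertex_forces[fa.cell_index][fa.vertex_index] += fvec
        ecm_forces[fa.crosslink_index] -= fvec
    return ecm_forces, vertex_forces, centre_loads, fa_eps, fa_force


def _cell_velocities(cell: Cell, vertex_force: np.ndarray,
                     centre_load: np.ndarray, eta: float):
    """Solve the per-cell implicit velocity system (Kelvin-Voigt dashpot)."""
    n = cell.n_vertices
    dim = 2 * (n + 1)
    rel = cell.vertices - cell.centre
    lengths = np.linalg.norm(rel, axis=1)
    unit = rel / lengths[:, None]
    gamma = cell.gamma_seg
    A = np.zeros((dim, dim))
    b = np.empty(dim)
    A[0:2, 0:2] = eta * np.eye(2)
    b[0:2] = centre_load
    for i in range(n):
        P = gamma * np.outer(unit[i], unit[i])
        s = slice(2 + 2 * i, 4 + 2 * i)
        A[s, s] = eta * np.eye(2) + P
        A[s, 0:2] = -P
        A[0:2, s] = -P
        A[0:2, 0:2] += P
        b[s] = vertex_force[i]
    sol = np.linalg.solve(A, b)
    return sol[0:2], sol[2:].reshape(n, 2)


def _make_rhs(template: SimulationState, layout: _Layout):
    """Right-hand side of the coupled ODE system on the packed state vector."""
    scratch = template.copy()
    eta_ecm = template.network.eta

    def rhs(t, y):
        scratch.time = t
        layout.unpack_into(scratch, y)
        ecm_f, vert_f, centre_l, fa_eps, _ = _assemble_forces(scratch)
        dy = np.empty_like(y)
        dy[layout.ecm_slice] = (ecm_f[layout.free_idx] / eta_ecm).ravel()
        for cell, vf, cl, (c, v) in zip(scratch.cells, vert_f, centre_l,
                                        layout.cell_slices):
            if cell.gamma_seg > 0.0:
                v0, vi = _cell_velocities(cell, vf, cl, cell.eta)
            else:
                v0, vi = cl / cell.eta, vf / cell.eta
            dy[c] = v0
            dy[v] = vi.ravel()
        for k, fa in enumerate(scratch.fas):
            if fa.attached:
                p = fa.params
                F_i = p.k_i * max(fa_eps[k], 0.0)
                nb = min(max(y[layout.nb_offset + k], 0.0), fa.N)
                dy[layout.nb_offset + k] = (
                    p.K_on * fa.N - (p.K_on + float(koff(F_i, p))) * nb)
            else:
                dy[layout.nb_offset + k] = 0.0
        return dy

    return rhs


def _jac_sparsity(state: SimulationState, layout: _Layout) -> lil_matrix:
    S = lil_matrix((layout.size, layout.size), dtype=np.int8)
    free_pos = -np.ones(state.network.n_crosslinks, dtype=int)
    free_pos[layout.free_idx] = np.arange(len(layout.free_idx))

    def node_dofs(l):
        j = free_pos[l]
        return [] if j < 0 else [2 * j, 2 * j + 1]

    def couple(rows, cols):
        for r in rows:
            for c in cols:
                S[r, c] = 1

    for a, b in state.network.fibres:
        da, db = node_dofs(a), node_dofs(b)
        couple(da, da + db)
        couple(db, da + db)
    for c, v in layout.cell_slices:
        dofs = list(range(c.start, v.stop))
        couple(dofs, dofs)
    for k, fa in enumerate(state.fas):
        c, v = layout.cell_slices[fa.cell_index]
        cell_dofs = list(range(c.start, v.stop))
        vert_dofs = [v.start + 2 * fa.vertex_index, v.start + 2 * fa.vertex_index + 1]
        xl_dofs = node_dofs(fa.crosslink_index)
        nb = layout.nb_offset + k
        couple(cell_dofs, xl_dofs + [nb])
        couple(xl_dofs, cell_dofs + xl_dofs + [nb])
        couple([nb], vert_dofs + xl_dofs + [nb])
    for i in range(layout.size):
        S[i, i] = 1
    return S


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def evaluate_forces(state: SimulationState):
    """Forces and adhesion records of the current state (diagnostics/tests)."""
    ecm_f, vert_f, centre_l, fa_eps, fa_force = _assemble_forces(state)
    return {
        "ecm": ecm_f,
        "vertices": vert_f,
        "centres": centre_l,
        "fa_eps": fa_eps,
        "fa_force": fa_force,
    }


def total_energy(state: SimulationState) -> float:
    """Elastic energy of network, cells and adhesion springs (no contraction)."""
    e = elastic_energy(state.network, state.network.positions)
    for cell in state.cells:
        e += cell_mechanical_energy(cell)
    for fa in state.fas:
        if fa.attached:
            vpos = state.cells[fa.cell_index].vertices[fa.vertex_index]
            xpos = state.network.positions[fa.crosslink_index]
            eps = float(np.linalg.norm(vpos - xpos)) - fa.params.L0_i
            e += 0.5 * fa.N_b * fa.params.k_i * eps * eps
    return float(e)


def step(state: SimulationState, dt: float) -> SimulationState:
    """One explicit Heun (trapezoidal predictor-corrector) step of size dt.

    The detachment rule (N_b < 1) is applied after the step.  Intended for
    short, well-resolved integrations and convergence checks; ``run`` uses
    the adaptive implicit scheme.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    layout = _Layout(state)
    rhs = _make_rhs(state, layout)
    y0 = layout.pack(state)
    k1 = rhs(state.time, y0)
    k2 = rhs(state.time + dt, y0 + dt * k1)
    y1 = y0 + 0.5 * dt * (k1 + k2)
    if not np.all(np.isfinite(y1)):
        raise FloatingPointError("non-finite state after step")
    out = state.copy()
    out.time = state.time + dt
    layout.unpack_into(out, y1)
    for k, fa in enumerate(out.fas):
        if fa.attached and y1[layout.nb_offset + k] < 1.0:
            fa.attached = False
            fa.N_b = 0.0
            out.events.append((out.time, "detachment", {"fa": k}))
    return out


def run(state: SimulationState, t_end: float, observers=None,
        n_samples: int = 51, rtol: float = 1e-5, atol: float = 1e-6,
        method: str = "BDF") -> Trajectory:
    """Advance the coupled system to ``state.time + t_end`` adaptively.

    Detachment events (N_b crossing one bound integrin from above) terminate
    the current integration segment; the adhesion force is removed from both
    coupled equations and integration restarts from the event time.
    Observers are callables ``obs(t, state)`` invoked at every sample.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    work = state.copy()
    t0, t_stop = work.time, work.time + t_end
    grid = np.linspace(t0, t_stop, n_samples)

    times, rows = [], []

    def record(t, y):
        if times and t <= times[-1]:
            return
        times.append(t)
        rows.append(y.copy())

    t_cur = t0
    y = None
    while True:
        layout = _Layout(work)
        if y is None:
            y = layout.pack(work)
        rhs = _make_rhs(work, layout)
        sparsity = _jac_sparsity(work, layout)
        events = []
        for k, fa in enumerate(work.fas):
            if not fa.attached:
                continue

            def ev(t, yv, _k=k):
                return yv[layout.nb_offset + _k] - 1.0

            ev.terminal = True
            ev.direction = -1
            ev.fa_index = k
            events.append(ev)
        t_eval = grid[(grid >= t_cur) & (grid <= t_stop)]
        sol = solve_ivp(rhs, (t_cur, t_stop), y, method=method,
                        jac_sparsity=sparsity, events=events or None,
                        t_eval=t_eval if len(t_eval) else None,
                        rtol=rtol, atol=atol)
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"integration failed: {sol.message}")
        if len(sol.t):
            for t, col in zip(sol.t, np.asarray(sol.y).T):
                if not np.all(np.isfinite(col)):
                    raise FloatingPointError(
                        f"non-finite state at t={t:.4g}; aborting")
                record(float(t), col)
        if sol.status == 1:  # detachment event
            te = min(t[0] for t in sol.t_events if len(t))
            for ev, tev, yev in zip(events, sol.t_events, sol.y_events):
                if len(tev) and tev[0] == te:
                    k = ev.fa_index
                    layout.unpack_into(work, yev[0])
                    rec = evaluate_forces(work)
                    force = float(np.linalg.norm(rec["fa_force"][k]))
                    work.fas[k].attached = False
                    work.fas[k].N_b = 0.0
                    work.events.append(
                        (float(te), "detachment",
                         {"fa": k, "force_at_onset": force}))
                    y = layout.pack(work)
                    y[layout.nb_offset + k] = 0.0
            record(float(te), y)
            t_cur = float(te)
            if t_cur >= t_stop:
                break
            continue
        y_final = np.asarray(sol.y)[:, -1] if len(sol.t) else y
        layout.unpack_into(work, y_final)
        break

    work.time = t_stop
    traj = _build_trajectory(state, work, np.array(times), rows)
    if observers:
        snap = state.copy()
        lay = _Layout(snap)
        for t, row in zip(traj.times, rows):
            snap.time = t
            lay.unpack_into(snap, row)
            for obs in observers:
                obs(t, snap)
    return traj


def _build_trajectory(initial: SimulationState, final: SimulationState,
                      times: np.ndarray, rows: list) -> Trajectory:
    snap = initial.copy()
    layout = _Layout(snap)
    S = len(times)
    M = snap.network.n_crosslinks
    C = len(snap.cells)
    n_fa = len(snap.fas)
    ecm = np.empty((S, M, 2))
    centres = np.empty((S, C, 2))
    verts = [np.empty((S, c.n_vertices, 2)) for c in snap.cells]
    nb = np.empty((S, n_fa))
    ff = np.zeros((S, n_fa, 2))
    feps = np.zeros((S, n_fa))
    fatt = np.zeros((S, n_fa), dtype=bool)
    det_times = {p["fa"]: t for t, kind, p in final.events if kind == "detachment"}
    for s, (t, row) in enumerate(zip(times, rows)):
        layout.unpack_into(snap, row)
        for k, fa in enumerate(snap.fas):
            fa.attached = not (k in det_times and t >= det_times[k])
            if not fa.attached:
                fa.N_b = 0.0
        rec = evaluate_forces(snap)
        ecm[s] = snap.network.positions
        for j, cell in enumerate(snap.cells):
            centres[s, j] = cell.centre
            verts[j][s] = cell.vertices
        nb[s] = [fa.N_b for fa in snap.fas]
        ff[s] = rec["fa_force"]
        feps[s] = rec["fa_eps"]
        fatt[s] = [fa.attached for fa in snap.fas]
    return Trajectory(times=times, ecm_positions=ecm, cell_centres=centres,
                      cell_vertices=verts, nb=nb, fa_forces=ff, fa_eps=feps,
                      fa_attached=fatt, events=list(final.events),
                      final_state=final)


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------


def _deep_merge(base: dict, overrides: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _base_config() -> dict:
    return {
        "seed": 0,
        "domain": {"width": 100.0, "height": 100.0},
        "ecm": {
            "n_seeds": 150,
            "E_t": 1e7,
            "compression_factor": 0.1,
            "area": 0.01,
            "eta": 2000.0,
        },
        "cells": [],
        "fa": {
            "K_on": 0.5, "k_c": 0.5, "F_c": 30.0, "k_s": 0.05, "F_s": 30.0,
            "k_i": 1e3, "L0_i": 0.02,
            "capture_radius_factor": 2.0,
            "initial_bound_fraction": None,
        },
        "integration": {
            "t_end": 5.0, "n_samples": 51, "rtol": 1e-5, "atol": 1e-6,
            "init_tol": 1.0, "contraction_ramp": 1.0,
        },
    }


def _cell_defaults() -> dict:
    return {"k_seg": 1.5e4, "gamma_seg": 4e3, "k_ang": 1e4, "eta": 1e4,
            "n_vertices": 8, "orientation": 0.0}


def build_named_scenario(name: str, overrides: dict | None = None) -> dict:
    """Complete configuration for one of the study scenarios.

    single_round : one 8-vertex round cell contracting on a random network
                   (E_t=1e7 Pa, N=857 integrins per adhesion, F_co=2e4 pN).
    two_elongated: two elongated cells 80 um apart facing each other along
                   the domain diagonal (E_t=1e8 Pa, N=3000, F_co=5e4 pN).
    zigzag       : simplified topology, two cells pulled apart (F_pu=3.5e4 pN)
                   joined by a zigzag fibre path with pinned lateral fibres.
    ladder       : as zigzag but two straight rails joined by transversal
                   rungs (effectively rigid topology).
    multi_fan    : fan-shaped cells on a soft network (E_t=1e6 Pa, N=1000,
                   F_co=6.6e3 pN).
    """
    cfg = _base_config()
    if name == "single_round":
        cfg["domain"] = {"width": 100.0, "height": 100.0}
        cfg["ecm"]["n_seeds"] = 350
        cfg["ecm"]["E_t"] = 1e7
        cfg["cells"] = [dict(_cell_defaults(), shape="round",
                             centre=[50.0, 50.0], size=10.0,
                             F_co=2e4, N_per_fa=857)]
    elif name == "two_elongated":
        cfg["domain"] = {"width": 120.0, "height": 120.0}
        cfg["ecm"]["n_seeds"] = 500
        cfg["ecm"]["E_t"] = 1e8
        off = 40.0 / np.sqrt(2.0)
        cfg["cells"] = [
            dict(_cell_defaults(), shape="elongated",
                 centre=[60.0 - off, 60.0 - off], size=20.0,
                 orientation=np.pi / 4, F_co=5e4, N_per_fa=3000),
            dict(_cell_defaults(), shape="elongated",
                 centre=[60.0 + off, 60.0 + off], size=20.0,
                 orientation=np.pi / 4, F_co=5e4, N_per_fa=3000),
        ]
    elif name in ("zigzag", "ladder"):
        # geometry parameters may be overridden, so merge before construction
        cfg["ecm"]["E_t"] = 1e8
        cfg = _topology_config(name, _deep_merge(cfg, overrides))
        overrides = None
    elif name == "multi_fan":
        cfg["domain"] = {"width": 120.0, "height": 120.0}
        cfg["ecm"]["n_seeds"] = 400
        cfg["ecm"]["E_t"] = 1e6
        cfg["cells"] = [
            dict(_cell_defaults(), shape="fan", centre=[35.0, 35.0], size=10.0,
                 orientation=np.pi / 4, n_vertices=5, F_co=6.6e3, N_per_fa=1000),
            dict(_cell_defaults(), shape="fan", centre=[85.0, 85.0], size=10.0,
                 orientation=np.pi / 4 + np.pi, n_vertices=5, F_co=6.6e3,
                 N_per_fa=1000),
        ]
    else:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {NAMED_SCENARIOS}")
    return _deep_merge(cfg, overrides)


def _topology_config(kind: str, cfg: dict) -> dict:
    """Simplified-topology pulling scenarios (zigzag / ladder)."""
    cfg["fa"].setdefault("initial_bound_fraction", None)
    if cfg["fa"]["initial_bound_fraction"] is None:
        cfg["fa"]["initial_bound_fraction"] = 0.25
    F_pu = 3.5e4
    N_per_fa = 1200
    geom = cfg.setdefault("topology", {})
    if kind == "zigzag":
        n_seg = geom.setdefault("n_segments", 10)
        pitch = geom.setdefault("pitch", 2.0)
        amp = geom.setdefault("amplitude", 8.0)
        lat = geom.setdefault("lateral_length", 10.0)
        pos, fib, pinned = [], [], []
        for j in range(n_seg + 1):
            pos.append([j * pitch, amp * (j % 2)])
            pinned.append(False)
        for j in range(n_seg):
            fib.append([j, j + 1])
        for j in range(1, n_seg):
            side = 1.0 if j % 2 else -1.0
            pos.append([j * pitch, amp * (j % 2) + side * lat])
            pinned.append(True)
            fib.append([j, len(pos) - 1])
        left, right = 0, n_seg
        span_y = 0.0
    else:
        n_seg = geom.setdefault("n_segments", 4)
        spacing = geom.setdefault("rung_spacing", 8.0)
        gap = geom.setdefault("rail_gap", 4.0)
        hub = geom.setdefault("hub_offset", 8.0)
        pos, fib, pinned = [[0.0, 0.0]], [], [False]
        top = []
        bot = []
        for j in range(n_seg + 1):
            pos.append([hub + j * spacing, gap / 2]); top.append(len(pos) - 1)
            pinned.append(False)
            pos.append([hub + j * spacing, -gap / 2]); bot.append(len(pos) - 1)
            pinned.append(False)
        pos.append([2 * hub + n_seg * spacing, 0.0]); pinned.append(False)
        left, right = 0, len(pos) - 1
        fib += [[left, top[0]], [left, bot[0]],
                [right, top[-1]], [right, bot[-1]]]
        for j in range(n_seg):
            fib += [[top[j], top[j + 1]], [bot[j], bot[j + 1]]]
        for j in range(n_seg + 1):
            fib.append([top[j], bot[j]])
        span_y = 0.0

    xs = [p[0] for p in pos]
    cell_len = 10.0
    cfg["domain"] = {"width": max(xs) - min(xs), "height": 40.0}
    cfg["ecm"]["explicit"] = {"positions": pos, "fibres": fib, "pinned": pinned}
    # stiff fast cells: the pulled cell body should not rate-limit the
    # loading of the adhesion, only the ECM compliance should
    cell_kw = dict(_cell_defaults(), shape="elongated", size=cell_len,
                   orientation=0.0, F_co=0.0, N_per_fa=N_per_fa, k_seg=2e5,
                   eta=2e3)
    cfg["cells"] = [
        dict(cell_kw, centre=[min(xs) - cell_len / 2, span_y]),
        dict(cell_kw, centre=[max(xs) + cell_len / 2, span_y]),
    ]
    # vertex 0 of a fresh elongated cell points along +orientation; the vertex
    # facing the network carries the adhesion, the outer one is pulled
    cfg["fa_links"] = [[0, 0, left], [1, 1, right]]
    cfg["pulling"] = [
        {"cell": 0, "vertex": 1, "force": [-F_pu, 0.0]},
        {"cell": 1, "vertex": 0, "force": [F_pu, 0.0]},
    ]
    return cfg


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _network_from_config(config: dict) -> FibreNetwork:
    ecm = config["ecm"]
    mech = {k: ecm[k] for k in ("E_t", "compression_factor", "area", "eta")}
    if "explicit" in ecm:
        ex = ecm["explicit"]
        pos = np.asarray(ex["positions"], dtype=float)
        fib = np.asarray(ex["fibres"], dtype=int)
        lengths = np.linalg.norm(pos[fib[:, 1]] - pos[fib[:, 0]], axis=1)
        return FibreNetwork(positions=pos, fibres=fib, rest_lengths=lengths,
                            pinned=np.asarray(ex["pinned"], dtype=bool), **mech)
    dom = config["domain"]
    return generate_voronoi_network(dom["width"], dom["height"],
                                    ecm["n_seeds"], config["seed"], **mech)


def _catch_params(config: dict) -> CatchBondParams:
    fa = config["fa"]
    return CatchBondParams(
        K_on=fa["K_on"], k_c=fa["k_c"], F_c=fa["F_c"], k_s=fa["k_s"],
        F_s=fa["F_s"], k_i=fa["k_i"], L0_i=fa["L0_i"],
        eta=config["ecm"]["eta"])


def initialize_scenario(config: dict) -> SimulationState:
    """Build the relaxed, attached, contraction-free initial condition.

    Each cell vertex adheres to the nearest crosslink within the capture
    radius; the vertex is placed one integrin rest-length from its crosslink
    and the cell's rest lengths and natural angles are re-set to the attached
    geometry, so the coupled passive system starts load-free (fibres carry no
    initial load).  A guarded energy minimisation then enforces the relaxed
    start to the configured force tolerance, and the bound-integrin count is
    set to its equilibrium (or the configured initial bound fraction).
    Deterministic for a fixed config seed.
    """
    net = _network_from_config(config)
    params = _catch_params(config)
    fa_cfg = config["fa"]
    cap = fa_cfg.get("capture_radius")
    if cap is None:
        cap = fa_cfg.get("capture_radius_factor", 0.15) * net.mean_fibre_length()

    cells: list[Cell] = []
    fas: list[FocalAdhesion] = []
    explicit_links = config.get("fa_links")
    used: set[int] = set()
    for n, spec in enumerate(config["cells"]):
        cell = make_cell(
            spec["shape"], spec["centre"], spec["size"],
            spec.get("orientation", 0.0),
            n_vertices=spec.get("n_vertices", 8),
            k_seg=spec.get("k_seg", 1.5e4),
            gamma_seg=spec.get("gamma_seg", 4e3),
            k_ang=spec.get("k_ang", 1e4),
            eta=spec.get("eta", 1e4),
            F_co=spec.get("F_co", 0.0),
            N_per_fa=spec.get("N_per_fa", 1000),
        )
        if explicit_links is not None:
            links = {v: l for c, v, l in explicit_links if c == n}
        else:
            links = {}
            candidates = np.nonzero(~net.pinned)[0]
            for i in range(cell.n_vertices):
                d = np.linalg.norm(net.positions[candidates] - cell.vertices[i],
                                   axis=1)
                order = np.argsort(d)
                choice = next(
                    (candidates[j] for j in order
                     if d[j] <= cap and candidates[j] not in used), None)
                if choice is None:
                    raise RuntimeError(
                        f"cell {n} vertex {i} has no free crosslink within "
                        f"capture radius {cap:.3g} um")
                links[i] = int(choice)
                used.add(int(choice))
        # adapt the cell to its adhesion sites: vertex sits one integrin
        # rest-length from the crosslink, rest geometry re-set to match
        for i, l in links.items():
            xl = net.positions[l]
            u = cell.centre - xl
            nu = np.linalg.norm(u)
            u = u / nu if nu > 0 else np.array([1.0, 0.0])
            cell.vertices[i] = xl + params.L0_i * u
        if cell.closed:
            rel = cell.vertices - cell.centre
            order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
            cell.vertices = cell.vertices[order]
            inv = {int(old): new for new, old in enumerate(order)}
            links = {inv[i]: l for i, l in links.items()}
            cell.natural_angles = _angles_from_geometry(
                cell.centre, cell.vertices, True)
        else:
            cell.natural_angles = _angles_from_geometry(
                cell.centre, cell.vertices, False)
        cell.segment_rest_lengths = np.linalg.norm(
            cell.vertices - cell.centre, axis=1)
        cell.validate()
        cells.append(cell)
        for i, l in sorted(links.items()):
            fas.append(FocalAdhesion(
                cell_index=n, vertex_index=i, crosslink_index=l,
                N=cell.N_per_fa, N_b=0.0, params=params))

    frac0 = fa_cfg.get("initial_bound_fraction")
    for fa in fas:
        if frac0 is not None:
            fa.N_b = float(frac0) * fa.N
        else:
            fa.N_b = params.K_on * fa.N / (params.K_on + float(koff(0.0, params)))
        fa.validate()

    state = SimulationState(
        time=0.0, network=net, cells=cells, fas=fas, config=config,
        contraction_on=True, pulling=copy.deepcopy(config.get("pulling", [])),
        contraction_ramp=config["integration"].get("contraction_ramp", 1.0))

    tol = config["integration"].get("init_tol", 1.0)
    _relax_coupled(state, tol)
    state.network.reference_lengths_t0 = fibre_lengths(
        state.network, state.network.positions)
    return state


def _relax_coupled(state: SimulationState, tol: float,
                   nb_iterations: int = 3) -> None:
    """Minimise the passive (F_co=0) elastic energy over all mobile nodes."""
    layout = _Layout(state)
    n_mech = layout.nb_offset
    work = state.copy()
    work.contraction_on = False
    work.pulling = []

    def fun(x):
        y = layout.pack(work)
        y[:n_mech] = x
        layout.unpack_into(work, y)
        e = total_energy(work)
        ecm_f, vert_f, centre_l, _, _ = _assemble_forces(work)
        g = np.empty(n_mech)
        g[layout.ecm_slice] = -ecm_f[layout.free_idx].ravel()
        for vf, cl, (c, v) in zip(vert_f, centre_l, layout.cell_slices):
            g[c] = -cl
            g[v] = -vf.ravel()
        return e, g

    prescribed_nb = (state.config is not None and
                     state.config["fa"].get("initial_bound_fraction") is not None)
    x = layout.pack(work)[:n_mech]
    for _ in range(1 if prescribed_nb else nb_iterations):
        res = minimize(fun, x, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "gtol": 0.1 * tol,
                                "ftol": 1e-18})
        x = res.x
        if prescribed_nb:
            break
        # refresh N_b to the binding equilibrium at the relaxed extensions
        _, _, _, fa_eps, _ = _assemble_forces(work)
        changed = False
        for k, fa in enumerate(work.fas):
            p = fa.params
            nb = p.K_on * fa.N / (
                p.K_on + float(koff(p.k_i * max(fa_eps[k], 0.0), p)))
            if abs(nb - fa.N_b) > 1e-9 * fa.N:
                changed = True
            fa.N_b = nb
        if not changed:
            break

    y = layout.pack(work)
    y[:n_mech] = x
    layout.unpack_into(work, y)
    _, vert_f, centre_l, _, _ = _assemble_forces(work)
    ecm_f = _assemble_forces(work)[0]
    resid = [np.abs(ecm_f[layout.free_idx]).max(initial=0.0)]
    for vf, cl in zip(vert_f, centre_l):
        resid += [np.abs(vf).max(initial=0.0), np.abs(cl).max(initial=0.0)]
    if max(resid) > tol:
        raise RuntimeError(
            f"coupled relaxation residual {max(resid):.3g} pN exceeds "
            f"tolerance {tol:.3g} pN")

    # copy relaxed geometry back to the state
    state.network.positions = work.network.positions
    for cell, wcell in zip(state.cells, work.cells):
        cell.centre = wcell.centre
        cell.vertices = wcell.vertices
    if not prescribed_nb:
        for fa, wfa in zip(state.fas, work.fas):
            fa.N_b = wfa.N_b


def config_hash(config: dict) -> str:
    import hashlib

    doc = json.dumps(config, sort_keys=True, default=float)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]
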