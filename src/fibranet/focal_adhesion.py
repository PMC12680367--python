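"""Catch-bond integrin-cluster model of focal adhesions.

A focal adhesion (FA) couples one cell vertex to one ECM crosslink through a
cluster of N parallel integrin springs of which a continuous (mean-field)
number N_b is bound.  Bound integrins share a common extension eps, so the
cluster force is N_b * k_i * eps.  Integrins bind at a constant rate K_on and
unbind at a force-dependent rate following the two-pathway catch-slip model

    K_off(F) = k_c * exp(-F / F_c) + k_s * exp(F / F_s),

whose lifetime is maximal at an intermediate per-integrin force.  The reduced
two-variable system (cluster stretch eps_b, bound count N_b) under a constant
external load exhibits a saddle-node bifurcation: above the bifurcation force
F_BP no bound state exists and the adhesion detaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "CatchBondParams",
    "FocalAdhesion",
    "BifurcationResult",
    "koff",
    "koff_prime",
    "koff_minimiser",
    "integrin_cluster_force",
    "binding_rhs",
    "bound_equilibrium",
    "reduced_rhs",
    "equilibria",
    "bifurcation_point",
    "classify_basin",
]


@dataclass(frozen=True)
class CatchBondParams:
    """Kinetic and mechanical constants of an integrin cluster.

    K_on : binding rate, 1/s.
    k_c, F_c : catch-pathway prefactor (1/s) and force scale (pN).
    k_s, F_s : slip-pathway prefactor (1/s) and force scale (pN).
    k_i : integrin spring constant, pN/um.
    L0_i : integrin rest length, um.
    eta : damping of the reduced stretch equation, pN s/um.
    """

    K_on: float = 0.5
    k_c: float = 0.5
    F_c: float = 30.0
    k_s: float = 0.05
    F_s: float = 30.0
    k_i: float = 1e3
    L0_i: float = 0.02
    eta: float = 1e4

    def __post_init__(self) -> None:
        for name in ("K_on", "k_c", "F_c", "k_s", "F_s", "k_i", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FocalAdhesion:
    """One (cell vertex, ECM crosslink) adhesion link."""

    cell_index: int
    vertex_index: int
    crosslink_index: int
    N: int                       # total integrins, conserved
    N_b: float                   # bound integrins, mean-field continuous
    params: CatchBondParams
    attached: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.N_b <= self.N:
            raise ValueError("N_b must lie in [0, N]")
        if not self.attached and self.N_b != 0.0:
            raise ValueError("a detached adhesion has no bound integrins")


@dataclass(frozen=True)
class BifurcationResult:
    F_BP: float                  # pN
    eps_BP: float                # um
    bound_fraction_BP: float     # dimensionless

    def __post_init__(self) -> None:
        if self.F_BP <= 0 or not 0.0 < self.bound_fraction_BP < 1.0:
            raise ValueError("invalid bifurcation point")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def koff(F, params: CatchBondParams):
    """Two-pathway catch-slip unbinding rate, 1/s, for per-integrin force F (pN)."""
    F = np.asarray(F, dtype=float)
    return params.k_c * np.exp(-F / params.F_c) + params.k_s * np.exp(F / params.F_s)


def koff_prime(F, params: CatchBondParams):
    """dK_off/dF, 1/(s pN)."""
    F = np.asarray(F, dtype=float)
    return (-params.k_c / params.F_c * np.exp(-F / params.F_c)
            + params.k_s / params.F_s * np.exp(F / params.F_s))


def koff_minimiser(params: CatchBondParams) -> float:
    """Force (pN) at which K_off is minimal (longest bond lifetime)."""
    p = params
    return (p.F_c * p.F_s / (p.F_c + p.F_s)) * np.log(
        p.k_c * p.F_s / (p.k_s * p.F_c))


def bound_equilibrium(F_per_integrin: float, N: float,
                      params: CatchBondParams) -> float:
    """Fixed point of the binding ODE at constant per-integrin force."""
    return params.K_on * N / (params.K_on + koff(F_per_integrin, params))


# ---------------------------------------------------------------------------
# forces and ODE right-hand sides
# ---------------------------------------------------------------------------


def integrin_cluster_force(fa: FocalAdhesion, vertex_pos, crosslink_pos):
    """Force of the bound-integrin cluster on the cell vertex, pN, shape (2,).

    Magnitude N_b*k_i*eps with eps the common integrin extension; directed
    from the vertex toward the crosslink when stretched (eps > 0).  The force
    on the crosslink is the exact negative.
    """
    if not fa.attached:
        return np.zeros(2)
    vertex_pos = np.asarray(vertex_pos, dtype=float)
    crosslink_pos = np.asarray(crosslink_pos, dtype=float)
    d = vertex_pos - crosslink_pos
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise ValueError("coincident vertex and crosslink")
    eps = dist - fa.params.L0_i
    return -fa.N_b * fa.params.k_i * eps * d / dist


def binding_rhs(N_b: float, F_per_integrin: float, fa: FocalAdhesion) -> float:
    """dN_b/dt at per-integrin force F (tensile, pN), 1/s."""
    p = fa.params
    return p.K_on * fa.N - (p.K_on + float(koff(F_per_integrin, p))) * N_b


def reduced_rhs(eps_b: float, N_b: float, F_ext: float,
                params: CatchBondParams, N: float) -> tuple[float, float]:
    """Reduced FA system under constant external load F_ext (pN).

    eta * deps/dt = -2 * k_i * N_b * eps + F_ext
    dN_b/dt = K_on*N - (K_on + K_off(k_i * max(eps, 0))) * N_b

    Compressed integrins push but do not accelerate unbinding (tensile-only
    load in K_off).
    """
    p = params
    deps = (-2.0 * p.k_i * N_b * eps_b + F_ext) / p.eta
    F_i = p.k_i * max(eps_b, 0.0)
    dNb = p.K_on * N - (p.K_on + float(koff(F_i, p))) * N_b
    return deps, dNb


def _reduced_jacobian(eps_b, N_b, params: CatchBondParams, N):
    p = params
    F_i = p.k_i * max(eps_b, 0.0)
    dk = float(koff_prime(F_i, p)) * p.k_i if eps_b > 0 else 0.0
    return np.array([
        [-2.0 * p.k_i * N_b / p.eta, -2.0 * p.k_i * eps_b / p.eta],
        [-dk * N_b, -(p.K_on + float(koff(F_i, p)))],
    ])


# ---------------------------------------------------------------------------
# equilibria and bifurcation analysis
# ---------------------------------------------------------------------------


def _load_curve(eps, params: CatchBondParams, N):
    """External load sustained at stretch eps on the slow (binding) manifold:
    F(eps) = 2*k_i*eps*N_b*(eps) with N_b* the binding fixed point."""
    p = params
    return 2.0 * p.k_i * eps * bound_equilibrium(p.k_i * max(eps, 0.0), N, p)


def equilibria(F_ext: float, params: CatchBondParams, N: float,
               xtol: float = 1e-12) -> list[tuple[float, float, str]]:
    """Fixed points of the reduced system as (eps*, N_b*, stability).

    For 0 < F_ext < F_BP one stable and one unstable positive equilibrium; an
    empty list above the bifurcation force (detachment).  Stability from the
    eigenvalues of the analytic Jacobian.
    """
    p = params
    if F_ext < 0:
        raise ValueError("F_ext must be non-negative")
    if F_ext == 0.0:
        return [(0.0, bound_equilibrium(0.0, N, p), "stable")]
    bp = bifurcation_point(params, N)
    if F_ext > bp.F_BP:
        return []
    # upper bracket for the unstable branch: beyond the fold the sustainable
    # load decays, so expand until it falls below F_ext
    hi = 2.0 * bp.eps_BP
    while _load_curve(hi, p, N) > F_ext:
        hi *= 2.0
        if hi > 1e6 * bp.eps_BP:
            raise RuntimeError(
                f"failed to bracket the unstable equilibrium above "
                f"eps_BP={bp.eps_BP:.3g} for F_ext={F_ext:.3g}")
    out = []
    for lo, up in ((0.0, bp.eps_BP), (bp.eps_BP, hi)):
        f = lambda e: _load_curve(e, p, N) - F_ext
        flo, fhi = f(lo), f(up)
        if flo == 0.0:
            eps = lo
        elif fhi == 0.0:
            eps = up
        elif flo * fhi > 0:
            continue  # F_ext at the fold itself within round-off
        else:
            eps = brentq(f, lo, up, xtol=xtol)
        nb = bound_equilibrium(p.k_i * eps, N, p)
        eig = np.linalg.eigvals(_reduced_jacobian(eps, nb, p, N))
        stab = "stable" if np.all(eig.real < 0) else "unstable"
        out.append((float(eps), float(nb), stab))
    return out


def bifurcation_point(params: CatchBondParams, N: float) -> BifurcationResult:
    """Saddle-node (fold) of the reduced FA system.

    Solves the implicit condition  k_i*eps*K_off'(k_i*eps) = K_on + K_off
    for the stretch at the fold by bracketed root finding on the slip side of
    the off-rate minimum, then evaluates the closed forms

        N_b^BP/N = K_on / (K_on + K_off(k_i eps_BP)),
        F_BP     = 2 k_i eps_BP N_b^BP.

    eps_BP and the bound fraction depend only on the kinetic constants; F_BP
    scales linearly with N.
    """
    p = params
    f_star = koff_minimiser(p)

    def g(F):  # F = k_i * eps, per-integrin force
        return F * float(koff_prime(F, p)) - (p.K_on + float(koff(F, p)))

    lo = max(f_star, 1e-12)
    hi = 2.0 * lo + 1.0
    it = 0
    while g(hi) < 0:
        hi *= 2.0
        it += 1
        if it > 200:
            raise RuntimeError(
                f"no bifurcation root found in [{lo:.3g}, {hi:.3g}] pN")
    F_root = brentq(g, lo, hi, xtol=1e-14, rtol=1e-15)
    eps_bp = F_root / p.k_i
    frac = p.K_on / (p.K_on + float(koff(F_root, p)))
    F_bp = 2.0 * p.k_i * eps_bp * frac * N
    return BifurcationResult(F_BP=float(F_bp), eps_BP=float(eps_bp),
                             bound_fraction_BP=float(frac))


def classify_basin(eps0: float, N_b0: float, F_ext: float,
                   params: CatchBondParams, N: float,
                   horizon: float | None = None) -> str:
    """Integrate the reduced system and report 'attach' or 'detach'.

    attach: the trajectory enters a ball (1% of the equilibrium coordinates)
    around the stable fixed point; detach: N_b drops below one integrin.
    Undecided trajectories raise rather than defaulting silently.
    """
    if horizon is None:
        horizon = 50.0 / params.K_on
    eqs = [e for e in equilibria(F_ext, params, N) if e[2] == "stable"]
    stable = eqs[0] if eqs else None

    def rhs(t, y):
        return reduced_rhs(y[0], min(max(y[1], 0.0), N), F_ext, params, N)

    events = []
    if stable is not None:
        es, nbs, _ = stable
        scale = np.array([max(abs(es), params.L0_i * 1e-3), max(nbs, 1.0)])

        def near(t, y):
            d = np.hypot((y[0] - es) / scale[0], (y[1] - nbs) / scale[1])
            return d - 0.01
        if near(0.0, np.array([eps0, N_b0])) <= 0.0:
            return "attach"
        near.terminal = True
        events.append(near)

    def lost(t, y):
        return y[1] - 1.0
    lost.terminal = True
    lost.direction = -1
    events.append(lost)

    sol = solve_ivp(rhs, (0.0, horizon), [eps0, N_b0], method="LSODA",
                    events=events, rtol=1e-8, atol=1e-10)
    if stable is not None and len(sol.t_events[0]):
        return "attach"
    if len(sol.t_events[-1]):
        return "detach"
    raise RuntimeError(
        f"undecided after horizon {horizon:.3g} s "
        f"(final state eps={sol.y[0, -1]:.3g}, N_b={sol.y[1, -1]:.3g})")
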