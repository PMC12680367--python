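"""Scripted computational experiments: parameter sweeps and topology studies.

Each experiment is a seedable, reproducible pipeline around the two-cell
contraction scenario (sweeps over contraction force and fibre Young's
modulus) or the simplified-topology pulling scenarios (zigzag vs ladder).
Results are returned as tidy pandas tables, one row per realization and
parameter value, together with summary statistics (e.g. the linear
regression of peak adhesion force on contraction force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .focal_adhesion import bifurcation_point
from .metrics import (
    compare_anisotropy,
    dominant_direction,
    interaction_force_summary,
    max_stress_path,
    region_alignment_stats,
)
from .simulator import (
    build_named_scenario,
    config_hash,
    initialize_scenario,
    run,
)

__all__ = [
    "SweepSpec",
    "run_contraction_sweep",
    "run_stiffness_sweep",
    "run_topology_experiment",
    "two_cell_realization",
    "interaction_regions",
]


@dataclass
class SweepSpec:
    """Specification of a parameter sweep.

    parameter : "F_co" or "E_t" (two-cell sweeps) or "E_t" list for topology.
    values    : swept values, model units (pN or Pa).
    realizations : number of random network realizations per value.
    base_seed : seeds are base_seed + realization index.
    overrides : config overrides applied to every run (desk-scale factors,
                network density, integration settings).
    """

    scenario: str
    parameter: str
    values: list
    realizations: int = 5
    base_seed: int = 1
    t_end: float = 5.0
    n_samples: int = 201
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("value list must not be empty")
        if self.realizations < 1:
            raise ValueError("need at least one realization")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def interaction_regions(config: dict, half_width_fraction: float = 0.25):
    """High- and low-interaction rhombi for a two-cell scenario.

    The high-interaction rhombus has the inter-cell segment as its long
    diagonal and a half-width of ``half_width_fraction`` times the cell
    separation; the low-interaction region is the same rhombus displaced
    perpendicular to the inter-cell axis (far from both cells).
    """
    c1 = np.asarray(config["cells"][0]["centre"], dtype=float)
    c2 = np.asarray(config["cells"][1]["centre"], dtype=float)
    mid = 0.5 * (c1 + c2)
    axis = c2 - c1
    sep = float(np.linalg.norm(axis))
    u = axis / sep
    perp = np.array([-u[1], u[0]])
    b = half_width_fraction * sep

    def rhombus(centre):
        return np.array([centre + 0.5 * sep * u, centre + b * perp,
                         centre - 0.5 * sep * u, centre - b * perp])

    high = rhombus(mid)
    low = rhombus(mid + (b + 0.5 * b + 0.25 * sep) * perp)
    return high, low


def _facing_fa_crosslinks(state):
    """The adhesion crosslink of each cell closest to the other cell."""
    picks = []
    for n, cell in enumerate(state.cells[:2]):
        other = state.cells[1 - n].centre
        fas = [fa for fa in state.fas if fa.cell_index == n]
        best = min(fas, key=lambda fa: np.linalg.norm(
            state.network.positions[fa.crosslink_index] - other))
        picks.append(best.crosslink_index)
    return picks


def path_tortuosity(positions: np.ndarray, path) -> float:
    """Tortuosity of a node sequence evaluated in a given configuration."""
    if len(path) < 2:
        return 0.0
    length = sum(float(np.linalg.norm(positions[a] - positions[b]))
                 for a, b in zip(path[:-1], path[1:]))
    euclid = float(np.linalg.norm(positions[path[0]] - positions[path[-1]]))
    return euclid / length


# ---------------------------------------------------------------------------
# single two-cell realization
# ---------------------------------------------------------------------------


def two_cell_realization(E_t: float, F_co: float, seed: int,
                         overrides: dict | None = None, t_end: float = 5.0,
                         n_samples: int = 201) -> dict:
    """One seeded two-elongated-cell contraction run with all metrics."""
    cfg = build_named_scenario("two_elongated", None)
    cfg["seed"] = seed
    cfg["ecm"]["E_t"] = E_t
    for c in cfg["cells"]:
        c["F_co"] = F_co
    if overrides:
        from .simulator import _deep_merge
        cfg = _deep_merge(cfg, overrides)
    state = initialize_scenario(cfg)
    pos0 = state.network.positions.copy()
    traj = run(state, t_end, n_samples=n_samples)
    final = traj.final_state
    pos1 = final.network.positions

    high, low = interaction_regions(cfg)
    out = {"seed": seed, "E_t": E_t, "F_co": F_co,
           "config_hash": config_hash(cfg),
           "n_crosslinks": state.network.n_crosslinks,
           "detachments": sum(1 for e in final.events if e[1] == "detachment")}
    for name, poly in (("high", high), ("low", low)):
        before = region_alignment_stats(state.network, pos0, poly)
        after = region_alignment_stats(final.network, pos1, poly)
        out[f"{name}_mean_before"] = before.mean
        out[f"{name}_mean_after"] = after.mean
        out[f"{name}_skew_before"] = before.skewness
        out[f"{name}_skew_after"] = after.skewness
        out[f"{name}_p_value"] = compare_anisotropy(before.sigmas, after.sigmas)
        out[f"{name}_sigmas_before"] = before.sigmas
        out[f"{name}_sigmas_after"] = after.sigmas
        out[f"{name}_thetas_after"] = after.thetas
        out[f"{name}_dominant_direction"] = dominant_direction(after.thetas)
    src, dst = _facing_fa_crosslinks(state)
    perc = max_stress_path(final.network, pos1, src, dst)
    out["path_exists"] = perc.exists
    out["mean_path_stress"] = perc.mean_stress
    out["total_path_stress"] = perc.total_stress
    out["tortuosity_after"] = perc.tortuosity
    out["tortuosity_before"] = path_tortuosity(pos0, perc.path)
    summary = interaction_force_summary(traj)
    out["peak_force"] = summary["peak_mean_force"]
    out["peak_time"] = summary["peak_time"]
    return out


def _tidy(rows: list[dict]) -> pd.DataFrame:
    scalars = [{k: v for k, v in r.items() if not isinstance(v, np.ndarray)}
               for r in rows]
    return pd.DataFrame(scalars)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def run_contraction_sweep(spec: SweepSpec):
    """Sweep the active contraction force in the two-cell scenario.

    Returns (table, summary): the tidy per-run table and a summary dict with
    realization-averaged curves and the OLS regression of the mean peak
    adhesion force on F_co (slope, intercept, r_squared).
    """
    if spec.scenario != "two_elongated":
        raise ValueError("contraction sweep is defined for 'two_elongated'")
    E_t = spec.overrides.get("ecm", {}).get("E_t", 1e7)
    rows = []
    for F_co in spec.values:
        for r in range(spec.realizations):
            rows.append(two_cell_realization(
                E_t, F_co, spec.base_seed + r, spec.overrides,
                t_end=spec.t_end, n_samples=spec.n_samples))
    table = _tidy(rows)
    mean_by_f = table.groupby("F_co", sort=True).agg(
        peak_force=("peak_force", "mean"),
        peak_time=("peak_time", "mean"),
        mean_path_stress=("mean_path_stress", "mean"),
        high_mean_after=("high_mean_after", "mean"),
        high_skew_after=("high_skew_after", "mean"),
        tortuosity_after=("tortuosity_after", "mean"),
    ).reset_index()
    reg = stats.linregress(mean_by_f["F_co"], mean_by_f["peak_force"])
    summary = {
        "by_value": mean_by_f,
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r_squared": float(reg.rvalue ** 2),
    }
    return table, summary


def run_stiffness_sweep(spec: SweepSpec):
    """Sweep the fibre Young's modulus in the two-cell scenario."""
    if spec.scenario != "two_elongated":
        raise ValueError("stiffness sweep is defined for 'two_elongated'")
    F_co = spec.overrides.get("F_co", 5e4)
    rows = []
    for E_t in spec.values:
        for r in range(spec.realizations):
            rows.append(two_cell_realization(
                E_t, F_co, spec.base_seed + r, spec.overrides,
                t_end=spec.t_end, n_samples=spec.n_samples))
    table = _tidy(rows)
    mean_by_e = table.groupby("E_t", sort=True).agg(
        peak_force=("peak_force", "mean"),
        peak_time=("peak_time", "mean"),
        mean_path_stress=("mean_path_stress", "mean"),
        high_mean_after=("high_mean_after", "mean"),
        path_fraction=("path_exists", "mean"),
        detachments=("detachments", "sum"),
    ).reset_index()
    return table, {"by_value": mean_by_e}


# ---------------------------------------------------------------------------
# topology experiment
# ---------------------------------------------------------------------------


def run_topology_experiment(spec: SweepSpec):
    """Zigzag / ladder pulling experiments across fibre stiffness values.

    For every (topology, E_t) configuration: whether the cells detach, the
    adhesion force at detachment onset compared with the bifurcation force
    F_BP, and the time series of the bound fraction N_b/N and the integrin
    stretch.  ``overrides['remove_rung_fraction']`` removes a random subset
    of the ladder's transversal fibres before the run.
    """
    if spec.scenario not in ("zigzag", "ladder"):
        raise ValueError("topology experiment runs 'zigzag' or 'ladder'")
    remove_frac = spec.overrides.pop("remove_rung_fraction", 0.0) \
        if spec.overrides else 0.0
    rows, series = [], {}
    for E_t in spec.values:
        cfg = build_named_scenario(spec.scenario,
                                   {"ecm": {"E_t": E_t}, **(spec.overrides or {})})
        cfg["seed"] = spec.base_seed
        if remove_frac > 0.0 and spec.scenario == "ladder":
            _remove_rungs(cfg, remove_frac, spec.base_seed)
        state = initialize_scenario(cfg)
        params = state.fas[0].params
        N = state.fas[0].N
        bp = bifurcation_point(params, N)
        traj = run(state, spec.t_end, n_samples=spec.n_samples)
        final = traj.final_state
        det = [e for e in final.events if e[1] == "detachment"]
        onset_forces = [e[2]["force_at_onset"] for e in det]
        rows.append({
            "scenario": spec.scenario, "E_t": E_t,
            "outcome": "detached" if det else "attached",
            "n_detachments": len(det),
            "first_detachment_time": det[0][0] if det else np.nan,
            "force_at_onset": onset_forces[0] if det else np.nan,
            "F_BP": bp.F_BP,
            "onset_below_F_BP": bool(onset_forces[0] < bp.F_BP) if det else np.nan,
            "config_hash": config_hash(cfg),
        })
        series[(spec.scenario, E_t)] = {
            "times": traj.times,
            "bound_fraction": traj.nb / N,
            "stretch": traj.fa_eps,
        }
    return pd.DataFrame(rows), series


def _remove_rungs(cfg: dict, fraction: float, seed: int) -> None:
    """Randomly drop transversal (vertical) fibres from a ladder network."""
    ex = cfg["ecm"]["explicit"]
    pos = np.asarray(ex["positions"])
    fib = np.asarray(ex["fibres"])
    vertical = np.isclose(pos[fib[:, 0], 0], pos[fib[:, 1], 0])
    rungs = np.nonzero(vertical)[0]
    rng = np.random.default_rng(seed)
    drop = rng.choice(rungs, size=int(round(fraction * len(rungs))),
                      replace=False)
    keep = np.setdiff1d(np.arange(len(fib)), drop)
    ex["fibres"] = fib[keep].tolist()
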