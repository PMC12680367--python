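# fibranet

A force-based, multiscale simulator of mechanical cell–extracellular-matrix
(ECM) interaction, written for researchers in cell and tissue biomechanics
who want to study how contractile cells deform fibrous substrates,
communicate through them, and attach to or detach from them.

The model couples three layers in the overdamped limit:

- **ECM**: a crosslinked elastic fibre network generated as the Voronoi
  tessellation of random seed points. Each fibre is a bilinear spring with
  Young's modulus `E_t` under stretch and a reduced modulus `ρ·E_t` when
  buckled. Crosslink positions obey `η_e dx/dt = F_el + F_ec`.
- **Cells**: polygonal agents whose vertices are joined to an organising
  centre by Kelvin–Voigt segments (spring `k_seg` + dashpot `γ_seg`) with
  harmonic angular springs between consecutive segments; myosin-driven
  contraction applies a constant force `F_co` pulling every vertex toward
  the centre. Elongated, round and fan-shaped cells are built in.
- **Focal adhesions**: each cell vertex binds one ECM crosslink through a
  cluster of `N` parallel integrin springs (stiffness `k_i`, rest length
  `L0_i`), of which a mean-field number `N_b` is bound. The cluster force is
  `N_b·k_i·ε` along the vertex–crosslink axis; binding follows
  `dN_b/dt = K_on·N − (K_on + K_off(k_i ε))·N_b` with the two-pathway
  catch–slip off-rate `K_off(F) = k_c e^{−F/F_c} + k_s e^{F/F_s}`.

The reduced two-variable adhesion system under a constant load `ℱ`
(`η dε/dt = −2 k_i N_b ε + ℱ` coupled to the binding equation) has a
saddle-node bifurcation: the package computes the critical load `F_BP`, the
stretch `ε_BP` and bound fraction `N_b^BP/N` at the fold in closed form, and
classifies initial conditions into attachment/detachment basins. The
quantification layer implements the local fibre-orientation tensor (alignment
angle and anisotropy `σ_al = 1 − λ_min/λ_max`), region statistics with
Welch's t-test, and the maximum-stress percolation path (Dijkstra on
stretched fibres with weights `1/σ`, plus tortuosity).

## Worked example

```python
import numpy as np
from fibranet.simulator import build_named_scenario, initialize_scenario, run
from fibranet.metrics import interaction_force_summary
from fibranet.focal_adhesion import bifurcation_point

cfg = build_named_scenario("single_round", {"seed": 1})
state = initialize_scenario(cfg)          # relaxed, attached, load-free
traj = run(state, 5.0, n_samples=201)     # 5 s of contraction
s = interaction_force_summary(traj)
bp = bifurcation_point(state.fas[0].params, state.fas[0].N)
print(f"peak mean adhesion force {s['peak_mean_force']:.0f} pN "
      f"at t = {s['peak_time']:.2f} s")
print(f"final mean force {s['mean'][-1]:.0f} pN")
print(f"detachment threshold F_BP = {bp.F_BP:.0f} pN")
```

prints (a round 8-vertex cell with `F_co = 2·10⁴ pN`, `N = 857` integrins per
adhesion, on a 350-seed Voronoi network with `E_t = 10⁷ Pa`):

```
peak mean adhesion force 4899 pN at t = 1.35 s
final mean force 2902 pN
detachment threshold F_BP = 56382 pN
```

The mean adhesion force rises during contraction, peaks early at a few
thousand pN — well below the detachment threshold — and then relaxes as the
deformation spreads through the network. The bound-integrin count evolves on
a slower timescale (~1 s) than the integrin stretch (~0.01 s).

A command-line interface mirrors the library:

```bash
fibranet run --scenario two_elongated --seed 7 --out out/   # trajectory CSVs
fibranet bifurcate --n-values 200,500,1000,1500 --out bp.csv
fibranet metrics --frames out/ --out metrics.csv
fibranet sweep --spec sweep.yaml --out results/
```

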