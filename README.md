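# grnland

Quantified Waddington landscapes and kinetic paths for gene regulatory
networks.

Cell types are attractors of a gene regulatory network's dynamics, and
developmental transitions — differentiation and reprogramming — are noisy
barrier crossings between them. `grnland` turns a signed regulatory network
(activation/repression edges between genes) into:

* a deterministic **Hill-kinetics force field**
  `dx_i/dt = -k x_i + Σ_act a x_j^n/(S^n+x_j^n) + Σ_rep b S^n/(S^n+x_j^n)`
  with its attractors and basin weights (multi-start integration),
* the **potential landscape** `U = -ln P_ss` from two routes: a Gaussian
  moment-closure mixture (self-consistent mean field, diagonal variances)
  and direct Langevin sampling (Euler–Maruyama, histogram landscapes,
  RMSD coordinates for high-dimensional networks),
* the **curl flux** `J = F P - D ∇P` whose non-gradient part marks
  non-equilibrium dynamics,
* **barrier heights** (watershed minimax saddles on the 2-D grid) and
  **mean first passage times** between attractors,
* **dominant kinetic paths** minimising the Onsager–Machlup action
  `S = ∫ Σ_i (ẋ_i - F_i)² / 4D dt` — in a non-gradient network the
  differentiation and reprogramming paths are irreversible,
* **discretised cell-state graphs** (binarised trajectories projected onto
  marker genes, occupancy/transition probabilities, GraphML/SIF export),
* **global sensitivity analysis**: per-link perturbations and gene
  knockdowns scored by barrier and MFPT changes, plus slow annealing of
  the activation constant with hysteresis detection (`a_c1 < a_c2`).

It ships a reconstruction of a 52-gene human stem-cell network (123 links:
84 activations, 39 repressions; 11 pluripotency + 11 differentiation
markers; the non-text-attested wiring is synthetic — see
`docs/methods.md`), the two-gene GATA1/PU1 fate-decision motif, random
toggle networks, and analytic double-well oracles.

## Worked example

```python
import numpy as np
import grnland as gl

net, meta = gl.make_stemcell_fixture()
p = meta["balanced_params"]            # a=0.35, b=0.4, k=1, S=0.5, n=4

atts = gl.find_attractors(net, p, n_starts=300, seed=1)
for a in atts:
    iN, iG = net.index_of("NANOG"), net.index_of("GATA6")
    print(f"weight={a.weight:.3f}  NANOG={a.state[iN]:.2f}  GATA6={a.state[iG]:.2f}")
```

prints

```
weight=0.953  NANOG=2.02  GATA6=0.94
weight=0.047  NANOG=0.01  GATA6=2.36
```

— exactly two stable cell states: a stem-like attractor (high NANOG, low
GATA6, 95% of random initial conditions) and a differentiated attractor
(the reverse). Building the mean-field landscape over the two markers and
the dominant paths between the states:

```python
basins = [gl.propagate_moments(net, p, a.state, D=0.05, weight=a.weight)
          for a in atts]
grid = gl.potential_from_probability(
    gl.mixture_probability(basins, ("NANOG", "GATA6"), net=net))
grid.to_tsv("landscape.tsv")           # (x, y, P, U) table

path = gl.optimize_path(gl.NetworkForce(net, p), D=0.05,
                        start=atts[0], end=atts[1])
print(f"differentiation action: {path.action:.2f}")
```

which prints `differentiation action: 0.15` — the Onsager–Machlup cost of
the most probable 52-dimensional route from the stem attractor into the
differentiated one (lower action = more probable transition; the reverse
reprogramming route has its own, different path and action because the
dynamics are non-gradient).

A command-line interface mirrors the library:

```
grnland fixtures --kind stemcell52 --out net.tsv --annotations ann.tsv
grnland attractors --network net.tsv --annotations ann.tsv --starts 300 --seed 7 --out attractors.tsv
grnland landscape --network net.tsv --method meanfield --axes NANOG,GATA6 --out landscape.tsv
grnland anneal --network net.tsv --a-start 1.8 --a-end 0.3
```

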