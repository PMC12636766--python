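# raftnet

Lattice Monte Carlo simulation of protein-protein interaction (PPI)
networks solvated by a membrane near its liquid-liquid miscibility
critical point.

Plasma membranes of many cell types sit just above a demixing critical
point, where liquid-ordered ("raft") and liquid-disordered domains
fluctuate on scales much larger than any single lipid. Membrane proteins
partition into these domains, so the rate at which two signaling
components meet — and therefore the outcome of a reaction network built
from contact-driven activation and deactivation — depends on how far the
membrane is from criticality. `raftnet` is a simulation framework for
exploring exactly that coupling, aimed at membrane biophysicists and
systems biologists who want a minimal, fully controlled model of
domain-regulated signaling.

## Model

* **Membrane** — an `L x L` periodic lattice of Ising spins `s_i = ±1`
  (ordered/disordered-preferring lipids) with Hamiltonian
  `H = -J Σ_<ij> s_i s_j + Σ_k H_int(k)`, evolved by Kawasaki spin
  exchange (Metropolis, conserved order parameter, model B). Temperature
  is the rescaled `τ = T/T_c` with `T_c = 2J/ln(1+√2)`; composition is
  the conserved magnetization `m = <s_i>`.
* **Proteins** — disk-shaped inclusions whose boundary sites carry a
  uniform preference `b = ±1` coupling to adjacent lipids,
  `H_int = -J_int Σ_∂ b s`. Disks diffuse by single-site moves obeying
  detailed balance.
* **Reactions** — when an actor touches a substrate, the substrate's
  state switches at a fixed rate (`A + T_I → A + T_A`,
  `I + T_A → I + T_I`). Rates ignore the lipid configuration, so the
  state dynamics are out of equilibrium; *partition-switching* rules
  also flip the substrate's domain preference (palmitoylation-like),
  pushing the spatial ensemble itself out of equilibrium and producing
  emergent "pockets".
* **Analysis** — steady-state active-target fraction `f_A`, tanh-form
  logistic fits `f_A(τ) = (R-L)/2·tanh((τ-τ0)/(2Δτ)) + (R+L)/2`,
  radially averaged cross-correlations, activity histograms, pocket
  detection, and a diagrammatic sign-product predictor for the sign of
  `d f_A / dτ`.

Everything is validated against exhaustive Boltzmann enumeration on tiny
systems; see `docs/methods.md` for the full model account, parameter
table and numerical choices.

## Worked example

```python
import numpy as np
import raftnet as rn

net = rn.bundled_network("fig1")        # A (disordered), I, T (ordered), r=0
print(rn.sign_predict(net))             # -> 1  (activity rises with tau)

cfg = rn.SimulationConfig(
    L=64, thermo=rn.ThermoParams(tau=1.05), network=net,
    sweeps=50_000, record_every=100, seed=7,
)
res = rn.run_simulation(cfg)
print(round(res.steady_state_activity, 3))   # -> 0.299

tab = rn.run_scan(cfg, "tau", np.linspace(0.85, 1.4, 8), replicates=3, seed=42)
fit = rn.fit_logistic(tab["value"], tab["f_A"])
print(round(fit.tau0, 2), round(fit.delta_tau, 2))   # -> 1.06 0.08
```

The first number is the prediction of the sign-product diagram: in this
cascade the activator partitions opposite to the target while the
inactivator partitions with it, so both pathways carry a positive
product and target activity must rise with `τ`. The simulated
steady-state activity at `τ = 1.05` (fraction of the 20 targets in the
active state, averaged after burn-in) is `0.299` for this seed. The scan
plus fit estimate where the response is steepest (`τ0`, near the
critical point) and how sharp it is (`Δτ`; smaller for larger disks).

A command-line interface wraps the same library:

```bash
raftnet run  --config examples/run.yaml --out out/
raftnet scan --config examples/run.yaml --axis tau --values 0.85:1.4:8 \
             --replicates 5 --out scan.csv
raftnet fit  --scan-csv scan.csv --out fit.json
raftnet analyze --snapshots out/snapshots.h5 --pair A,T
```

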