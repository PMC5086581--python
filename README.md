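# chondrosim

Simulator of the biochemical cascade that follows a blunt impact on
articular cartilage — the initiating events of post-traumatic
osteoarthritis (PTOA).

A single injurious impact kills a fraction of chondrocytes outright.  The
necrotic cells release damage-associated molecular patterns (DAMPs), which
push healthy cells through a catabolic cascade: they release
pro-inflammatory cytokines (PIC) and reactive oxygen species (ROS), PIC
degrade the extracellular matrix (ECM) and drive apoptosis, while ROS
trigger an erythropoietin (EPO) counter-response that can arrest the
inflammation once EPO passes a threshold.  `chondrosim` integrates this
coupled chemical/cellular system over a 14-day post-impact horizon on a
cylindrical cartilage explant and is aimed at computational-biology groups
studying mechanotransduction and PTOA onset.

## Model

The explant is a cylinder with rotational symmetry; fields live on the
(r, z) half-plane, 1.25 cm × 1.0 cm by default.  The model tracks

* cell populations (cells/cm³): healthy unsignalled `C_U`; DAMP-signalled
  pre-catabolic `C_T(a)`; EPO-producing `C_E`; catabolic `S_T(a)`;
  EPOR-active `S_A`; necrotic `D_N` — where `a` is *state age*, the time a
  cell has spent in its current state;
* chemicals (nM): ROS `R`, DAMPs `M`, PIC `F`, EPO `P`, each obeying a
  reaction–diffusion equation with no-flux boundaries, e.g.

  ∂ₜM = (1/r)∂ᵣ(r K_M ∂ᵣM) + K_M ∂zzM − δ_M M + σ_M D_N + σ_U U·F/(λ_F+F);

* the ECM density `U` (mg/cm³), degraded by PIC unless EPO exceeds its
  threshold P_c:  ∂ₜU = −δ_U U · F/(λ_F+F) · H(P_c − P).

Cells do not move; their equations are ordinary in space but the signalled
states are age-structured, with transport ∂ₜ + ∂ₐ along state age and
delayed transitions governed by the sharp switch
γ(a − τ) = (γ₀/σ)(tanh((a − τ)/σ) + 1).  Saturating (Hill) factors
x/(λ + x) gate every signalling term, and the Heaviside factors H(P_c − P)
arrest inflammatory transitions wherever EPO is high.

The impact enters through the initial condition: an axial strain field
ε(r, z) (percent) is mapped to the fraction of cells killed on impact,

Γ(ε) = 0.01·p₀·(e^{K_U ε} − e^{10 K_U}) for ε > 10 %, else 0,

so that `C_U(0) = (1 − Γ)·ρ₀` and `D_N(0) = Γ·ρ₀` with ρ₀ = 100,000
cells/cm³.  The strain field is either read from a finite-element
displacement deck (strain = 100·|U2|/z per node, nearest-neighbour mapped
onto the model grid) or generated by a deterministic synthetic indenter
profile.

The numerics combine a Peaceman–Rachford ADI scheme for the chemicals
(linear decay folded into the sweeps, conservative flux form), exact
exponential bookkeeping for the cell transitions (live cells plus audit
sinks are conserved to rounding), cohort transport along age
characteristics, and step-doubling adaptive time-step control.  See
`docs/methods.md` for the full account.

## Worked example

```python
import chondrosim as cs

cfg = cs.SimulationConfig()          # default impact scenario
traj = cs.simulate(cfg, cfg.strain_field())
s = traj.state_at(14.0)
print(f"day 14: mean C_U {s.C_U.mean():.0f} cells/cm3, "
      f"peak S_T {s.S_T.total().max():.0f} cells/cm3, "
      f"mean ECM {s.U.mean():.2f} mg/cm3")
print(f"steps: {traj.diagnostics.n_accepted} accepted, "
      f"{traj.diagnostics.n_rejected} rejected")
```

prints (exactly reproducible — the solver has no randomness):

```
day 14: mean C_U 37896 cells/cm3, peak S_T 6950 cells/cm3, mean ECM 29.97 mg/cm3
steps: 1299 accepted, 9 rejected
```

Reading: under the default 60 % peak-strain impact roughly a quarter of
the cells under the indenter die at once; over two weeks DAMP signalling
converts much of the healthy population into signalled states concentrated
near the impact site, yet the ECM loses well under 1 % of its density —
the impact triggers the inflammatory cascade without causing overt matrix
damage within 14 days.

The same scenario from the shell:

```sh
chondrosim simulate --out out/          # snapshot CSVs at days 0, 1, 7, 14
chondrosim synth-strain --out strain.csv
chondrosim strain deck.csv --out strain.csv   # from an FE displacement deck
chondrosim refine --out out/            # discretisation-error study
chondrosim sensitivity --out out/       # one-at-a-time parameter scan
```

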