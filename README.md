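# acdsim

Spatial simulation and analysis of **autologous cell defection (ACD)** — a
proposed cancer therapy in which a patient's own cancer cells are modified
to stop secreting costly diffusible cancer growth factors (CGFs), then
re-implanted into the tumour as intra-tumour parasites ("hypertumours").
Because the defectors enjoy the growth factors without paying the secretion
cost, they can outcompete the producers at the interface, collapse the
cooperating cancer cluster, and — lacking self-sustaining benefits — later
collapse themselves.

The package is aimed at researchers in cancer evolutionary dynamics and
evolutionary medicine who want a reproducible, configurable testbed for
defector-based therapy questions: When does an implant invade? What does
the Warburg phenotype (acidifying lactate secretion) change? Do
CGF-targeting drugs help or hurt the therapy?

## What is implemented

**1. A stochastic lattice simulator.** A 100 × 100 death–birth process:
each cell carries nine one-way-mutating oncogene loci (secretion of CGF
1–3 and lactate, receptors 1–3, lactate resistance, immune evasion).
Secreted factors diffuse with factor-specific kernels (three permeability
variants — Model B short/concentrated, A intermediate, C long/dilute —
under conserved total kernel mass); fitness is linear in received CGF
minus secretion costs, lactate damage and mutation burden; deceased sites
are recolonised by von Neumann neighbours proportionally to fitness.
The reference experiment implants a 12 × 7 block of hypertumours (with or
without the Warburg effect, or normal cells as control) into the centre of
a 22 × 22 cancer cluster and tracks class proportions over replicate
ensembles, with or without a drug halving the effect of CGFs 1–2.

**2. A deterministic interface model.** Four cells straddle a straight
hypertumour–cancer interface with CGF concentrations g1 > g2 > g3 > g4:

    ω1 = F(g1) − c,  ω2 = F(g2) − c,  ω3 = F(g3),  ω4 = F(g4)

Hypertumours invade iff ω1 < ω3 and ω2 < ω4. A proportional CGF-reducing
drug (g → r·g, 0 < r < 1) changes each fitness by Δωi = F(r·gi) − F(gi),
and the **relative drug effect** φ = Δω1 − Δω3 is negative exactly when
the drug promotes the defector. For linear F the drug *always* promotes
it (Δω1 < Δω3 ⇔ g1 > g3); for the logistic
F(t) = k0/(1 + e^(−k1(t−1))) + k2 — with (k0, k2) solved from F(0) = 0 and
F(∞) = 1, giving k0 = 1.0067, k2 = −0.0067 at k1 = 5 — φ takes both signs
depending on where the two cell types sit on the curve.

See `docs/methods.md` for model details, parameter defaults and their
calibration, and known limitations.

## Worked example

```python
import numpy as np
from acdsim import (LogisticF, InterfaceScenario, interface_fitness,
                    hypertumour_progresses, phi, Scenario, run_ensemble)

F = LogisticF.from_steepness(5.0)
print(round(F.k0, 4), round(F.k2, 4))       # 1.0067 -0.0067

s = InterfaceScenario(g1=2.0, g2=1.2, g3=1.0, g4=0.8, c=0.6, r=0.5)
w = interface_fitness(s, F)
print([round(x, 3) for x in w])             # [0.393, 0.129, 0.497, 0.264]
print(hypertumour_progresses(w))            # True
print(round(phi(s, F), 4))                  # -0.0696

scn = Scenario(centre_fill="HT_NO_WARBURG", drug_on=False, model="A",
               n_steps=1500, n_replicates=5, base_seed=0)
ens = run_ensemble(scn, keep_replicates=False)
final = ens.mean.iloc[-1]
print(round(final["cancer"], 3), round(final["hypertumour"], 3))  # 0.131 0.124
```

Reading the output: the logistic constants satisfy the two boundary
conditions; in the four-cell scenario the secretion cost c = 0.6 outweighs
the cancer side's concentration advantage, so both border inequalities
favour the hypertumour (it invades), and φ = −0.0696 < 0 means a drug
halving the CGF would *further* promote the defector. In the ensemble, by
step 1500 the implanted non-Warburg hypertumours (initially 84 cells,
0.8 % of the lattice) have risen to 12 % of live cells while cancer is at
13 % — the invasion phase of the ACD arc.

The same experiments are scriptable from the shell:

```sh
acd-sim simulate --scenario ht-no-warburg --model A --drug off \
        --steps 3000 --replicates 20 --seed 7 --out results/
acd-sim interface-grid --f logistic --k1 5 --r 0.5 --out phi.csv
acd-sim make-config --out acdsim.yaml   # every default, ready to edit
```

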