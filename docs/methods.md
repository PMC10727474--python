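# Methods

`acdsim` models autologous cell defection (ACD): the deliberate implantation
of engineered "hypertumour" cells — cancer cells modified to stop secreting
costly diffusible cancer growth factors (CGFs) while keeping the receptors
that let them benefit from the factors secreted by their neighbours — into
an established cancer cluster, so that the cluster is undermined from within
by social defection rather than attacked from outside. The package contains
two independent models: a stochastic spatial lattice simulator and a
deterministic four-cell interface model of drug effects.

## The lattice simulator

### State

The tissue is a rectangular grid (default 100 × 100) whose sites are either
vacant or hold one cell. A cell's heritable state is nine boolean oncogene
loci: secretion of CGF 1–3, secretion of lactate (the Warburg phenotype),
receptors for CGF 1–3, lactate resistance, and immune evasion. Mutation is
one-way: a mutated locus never reverts, so wild-type (normal) cells can only
be produced by replication of normal cells.

Phenotype classes depend only on CGF secretion/reception and lactate
resistance: *normal* (all wild-type), *cancer* (secretes and receives all
three CGFs), *hypertumour* (secretes none, receives all three, resists
lactate), *partial hypertumour* (secretes none, receives one or two), and
*other mutant* for everything else. Warburg status and immune evasion are
deliberately excluded from the classification so that class counts reflect
the defector/producer structure of the population.

### Diffusion

Each secreted factor spreads according to a fixed kernel; a step's
concentration field is the discrete convolution of the producer-occupancy
mask with that kernel (FFT-based, absorbing grid edges — kernel mass
falling off the lattice is lost). Fields are instantaneous maps of the
current occupancy; there is no temporal accumulation or decay. Kernel
weights decay exponentially with Euclidean distance (decay length
radius/2) over the square support of side 2·radius + 1, and are rescaled
so that each factor's total kernel mass is a configured constant. Tissue
permeability enters through three model variants that rescale the radius —
Model B (×0.5, short and concentrated), A (×1), C (×2, long and dilute) —
under conserved per-factor mass. Default base radii are 2/4/6 cells for
CGF 1/2/3 (chosen so the strict CGF1 < CGF2 < CGF3 range ordering survives
the Model-B rounding) and 3 for lactate.

### Fitness

Benefits are linear in the simulator: a cell with the receptor for factor k
gains `A_k · r_k · g_k`, where `g_k` is the local concentration and
`r_k ∈ (0, 1]` the drug multiplier (the reference treatment halves the
effect of CGFs 1 and 2: r = (0.5, 0.5, 1)). Producing CGF k costs `c_k`,
the Warburg phenotype costs `c_L`, lactate damages non-resistant cells by
`d · g_lactate`, and each mutated locus carries a burden `mu`. Fitness is
clamped below at a tiny positive floor so fitness-proportional selection is
always defined.

### Update loop

Each time step: (1) fields from current occupancy; (2) fitness map;
(3) death — every live cell independently dies with probability
`1 − (1 − p_death)(1 − p_imm)`, where immune detection `p_imm` is `alpha ×`
(mutated fraction) and zero for immune-evading cells; (4) birth — every
vacancy with a live von Neumann neighbour is filled by a copy of a
neighbour drawn with probability proportional to fitness, all parents taken
synchronously from the pre-fill occupancy (death–birth process);
(5) one-way mutation of every live cell at the per-locus rate;
(6) class proportions and mean mutated-allele fraction are recorded over
live cells (so fixation of a class is exactly proportion 1).

A single seeded NumPy generator drives a run, with draws consumed in the
fixed phase order above; a run is bit-reproducible from (initial lattice,
config, seed). Replicate i of an ensemble uses seed base_seed + i.

### Default parameters and their calibration

The headline magnitudes are not uniquely determined by the model structure,
so the defaults were fixed once against static, checkable properties of
the intended regime, all evaluated on the initial configuration or in
closed form — none against simulation outcomes:

| parameter | default | role |
|---|---|---|
| `w_base` | 1.0 | baseline fitness (sets the scale) |
| `A_k` | 1.0 | linear CGF benefit per unit concentration |
| `c_k` | 0.3 | CGF secretion cost |
| `c_L` | 0.05 | Warburg (lactate secretion) cost |
| `d` | 0.3 | lactate damage per unit concentration |
| `mu` | 0.05 | fitness burden per mutated locus |
| CGF masses | 1.0 | total kernel mass per CGF |
| lactate mass | 3.0 | total kernel mass of lactate |
| `p_death` | 0.05 | baseline per-step death probability |
| `alpha` | 0.1 | immune-detection scale |
| mutation rate | 1e-5 | per locus per step |

The calibration constraints: (a) implanted hypertumours have higher fitness
than the adjacent cancer cells at t = 0 (the defector's saved secretion
cost, 3 × 0.3, exceeds the concentration drop across the interface plus its
class differences); (b) cancer at its own fringe outcompetes adjacent
normal tissue, so an untreated cluster grows; (c) a full-hallmark cancer
cell beats normal tissue inside its own factor cloud, a hypertumour beats
cancer at an equal field, and normal tissue beats an isolated hypertumour —
these three orderings are re-asserted by a startup self-check whenever a
run config is built; (d) the acid shield of a Warburg hypertumour cluster
(border lactate ≈ 0.45 × mass at `d` = 0.3 gives ≈ 0.40) exceeds its
baseline deficit against normal tissue (6·mu + c_L = 0.35), while the
non-Warburg deficit (5·mu = 0.25) is unshielded — so Warburg clusters
persist after the cancer collapses and non-Warburg clusters are reclaimed
by normal cells; (e) the mutation rate leaves normal tissue intact on the
run horizon (erosion timescale 1/(9 × 1e-5) ≈ 1e4 steps) while still
producing spontaneous partial hypertumours (~0.3 receptor mutations per
step on a full lattice).

### What the generated data does and does not emulate

The initial geometry is the reference layout: a centred 22 × 22 cancer
block whose 12 × 7 centre holds the implant (control normals, Warburg
hypertumours, or non-Warburg hypertumours); because 22 − 7 is odd the hole
sits one row below centre (rows 46–52, columns 44–55, 0-based inclusive).
The simulator captures the social-evolution structure of a tumour — public
goods, defection, spatial assortment, acidification, immune pressure — but
not tissue mechanics, vasculature, cell migration, continuous time, or
measured human parameter values. Passing tests therefore establish the
internal logic and the qualitative treatment contrasts, not quantitative
clinical predictions.

### Scaled-down ensembles

The reference experiment is 500 replicates × 10 000 steps per condition
(30 000 for Model B without the drug). The package's own acceptance runs
use 20 replicates × 3 000 steps, Model A, default parameters — large
enough that the full ACD arc (implant invasion, cancer collapse,
hypertumour regression) completes and the three treatment contrasts are
stable at ensemble-mean level, small enough for a desk machine. The full
design remains reachable through configuration (`scenario_matrix`).

## The interface model

At a straight hypertumour–cancer interface, four cells are compared: cancer
interior (1), cancer border (2), hypertumour border (3), hypertumour
interior (4), with CGF concentrations g1 > g2 > g3 > g4 ≥ 0 because the
cancer side is the source. With F the monotone CGF-to-fitness
transformation and c the secretion cost, ω1 = F(g1) − c, ω2 = F(g2) − c,
ω3 = F(g3), ω4 = F(g4); hypertumours stably invade iff ω1 < ω3 and
ω2 < ω4. A proportional CGF-reducing drug maps every g to r·g (0 < r < 1);
its per-cell effect Δωi = F(r·gi) − F(gi) is cost-free, and the relative
drug effect φ = Δω1 − Δω3 (or Δω2 − Δω4) is negative exactly when the drug
promotes hypertumour progression.

For linear F = At + B (A > 0), Δω1 < Δω3 reduces algebraically to g1 > g3,
which always holds — a proportional CGF drug always helps the defector.
This is verified both by randomized sampling and symbolically (sympy).

The logistic transformation is `F(t) = k0 / (1 + exp(−k1 (t − 1))) + k2`
with the inflection at t = 1. The two boundary conditions F(0) = 0 and
F(∞) = 1 form a 2 × 2 linear system in (k0, k2), solved at run time; for
steepness k1 = 5 this gives k0 = 1 + e⁻⁵ ≈ 1.0067 and k2 = −e⁻⁵ ≈ −0.0067.
Because the logistic has a concave plateau, φ can take either sign: with
the cancer side on the plateau and the hypertumour near the inflection
(e.g. g = 3, ratio 0.4, r = 0.8) the drug barely touches the cancer but
cuts the defector's benefit sharply, so φ > 0 and the drug impedes the
therapy; nearer the inflection on both sides (g = 2, ratio 0.5, r = 0.5)
φ < 0. The `phi_grid` sweep (default 101 concentrations × 99
hypertumour/cancer ratios, drug presets r = 0.8/0.5/0.2) maps this sign
structure.

Convex/concave sweeps use a normalized power family
`F(t) = min(t/t_max, 1)^p` (p > 1 convex, p < 1 concave, default
t_max = 5 matching the grid range); any monotone callable can be wrapped
for custom shapes. The interface model is purely analytic — the
replacement geometry enters only through the two inequalities — and is
deliberately not coupled to the lattice simulator.

## Numerical choices

* FFT convolution with per-factor kernel spectra precomputed per run;
  negative round-off dust (≈1e−15) is clamped to zero. Agreement with a
  direct double-loop accumulation is tested to 1e−10.
* Kernel radius = round(base_radius × model scale), minimum 1.
* Birth sampling: cumulative-sum inversion over the ≤ 4 neighbour weights;
  if every candidate is at the fitness floor the parent is uniform among
  live neighbours.
* Mutation events are generated by walking the flattened site × locus
  sequence with geometric gaps — exactly equivalent to independent
  Bernoulli draws per locus, with work proportional to the number of
  events; events landing on vacant sites are discarded.
* Vacant sites carry NaN in fitness maps, −1 in exported class grids and
  a `.........` token in genotype grids, none of which collide with live
  values.
* Degenerate inputs: empty lattices yield zero proportions; an ensemble
  group left empty by the 0.5-threshold split is returned empty and
  flagged rather than raising.

## Known limitations

* The reference parameter table of the original study design is not
  reproduced here; defaults are the package's own calibration (above) and
  every one of them is configuration.
* Synchronous updating only; no asynchronous single-site (Gillespie-style)
  variant.
* The immune model is minimal (linear detection, absolute evasion).
* No plotting; grids and time series are exported as CSV for external
  rendering.
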