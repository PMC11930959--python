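# Methods

`riboworld` simulates communities of RNA replicators that jointly
catalyse an implicit metabolism, in two spatial organisations — a
surface-bound lattice (the Metabolically Coupled Replicator System,
MCRS) and a population of fissioning vesicles (the Stochastic Corrector
Model, SCM) — together with the explicit transition of communities from
the surface into vesicles. This note records the model, its
parameters, the numerical choices, and the limits of what the test
suite demonstrates.

## The genotype→phenotype map

A replicator is a single RNA strand. Its phenotype derives entirely
from its minimum-free-energy (MFE) secondary structure with energy
ΔG_min:

* **Degradation.** `P_deg = 0.1 + 0.8·exp(d·ΔG_min)` with slope
  `d = 0.2` — the per-update probability of decay, 0.9 for an open
  chain and approaching 0.1 for very stable folds.
* **Foldedness.** `P_fold = 1 − 1/(1 + exp(−c·ΔG_min))` with
  `c = 0.3`, hard-clamped to 1 for `ΔG_min ≤ E_min = −25 kcal/mol`
  (the empirical minimum energy of random sequences in the 15–75 nt
  range). The sign convention is fixed so that more stable folds spend
  *more* time folded; the clamp realises the calibration that the most
  stable sequences are always folded. P_fold is the fraction of a
  strand's lifetime spent in the MFE structure, during which it can
  catalyse but cannot be copied.
* **Replicability.** `R = g·(l + (1 − P_fold)) / (b1 + b2·L)` with
  `g = 10`, `l = 1`, `b1 = 0.75` (initiation time), `b2 = 0.005` per
  base. This encodes the central trade-off: catalysts fold tightly and
  template poorly.
* **Enzymatic activities.** A packaged table of ten rules assigns
  activities to structural motifs: a hairpin ("loop") or interior loop
  ("interloop", bulges included) whose length *exactly* equals the
  rule's length. The three central bases of the 5'→3' concatenated
  loop sequence are compared with the rule's triplet; 0/1/2/3 matches
  give base activity ā = 0/0.1/0.8/1. Flanking loop bases add a GC
  bonus, `α = ā + 0.5/(1 + exp(n_GC·ξ))` with `ξ = −0.3`. A strand
  with `m` concurrently active motifs (ā > 0) divides its attention
  sub-additively: each active motif contributes
  `a = P_fold·α / m^σ`, `σ = 1.1`, into its rule's activity slot.
  Multiloops and exterior bases carry no motifs; only the first `A`
  rules (the system size, 3–10) participate in a run.

Copying is complementary and mutagenic: per template base, deletion
(p_del = 0.005), insertion of a uniform random base (p_ins = 0.005) and
substitution by a uniform random *different* base (p_sub = 0.05) act
independently; a deleted base can be neither substituted nor carry an
insertion. The copy is the reverse complement (A↔U, G↔C), so an
identical copy needs two error-free rounds. Copies shorter than 8 nt
(too short for any hairpin) count as failed replications in both
models.

## Metabolism and selection

The metabolic function of an environment (a lattice neighbourhood or a
vesicle) is the geometric mean of the per-activity summed strengths,
`M = (Π_e Σ_r a_{r,e})^(1/A)`; it is zero as soon as any activity is
missing — an incomplete metabolism produces no monomers, so no
replication. A replicator's claim in a replication lottery is
`C = R·M`; winners are drawn by the broken-stick (roulette-wheel)
method, with an empty lattice site holding a fixed claim `C_e = 0.1`
to stay empty. The focal replicator is included in its own metabolic
neighbourhood: the sums run over all replicators of the environment.

## The surface model (MCRS)

A Z×Z toroidal lattice, each cell empty or holding one replicator.
Per generation, Z² cells are chosen uniformly *with replacement* (each
cell updated once per generation on average): occupied cells degrade
with P_deg; for an empty cell, the occupants of its replication
neighbourhood (N_rep cells) compete with claims computed over each
contestant's *own* metabolic neighbourhood (N_met cells). After every
cell update, D random Toffoli–Margolus rotations (a random 2×2 block
turned 90° clockwise or anticlockwise with equal probability) model
limited surface diffusion — D·Z² rotations per generation.

Neighbourhood shapes are quasi-circular: the N offsets nearest the
origin in Euclidean distance, ties broken deterministically by angle.
This reduces to the von Neumann neighbourhood at N = 5 and the Moore
block at N = 9. (The shapes are a documented package choice; the
stated sizes are honoured exactly.)

Initialisation: a pool of random sequences (lengths Poisson(λ = 45),
truncated at ≥ 8 nt; bases uniform) is *enriched* by duplicating
randomly chosen catalytically active entries until 80% of entries carry
at least one activity, then the lattice is filled to exactly
⌊0.8·Z²⌋ sites with uniform pool draws. Enrichment is a bootstrap
for finite lattices — it guarantees a few metabolically complete seed
neighbourhoods.

## The vesicle model (SCM)

N compartments each hold 0..S−1 replicators. An update step is one
degradation event (a uniformly chosen replicator dies with its own
P_deg — identical in law to a broken-stick draw over everyone's
{P_deg, 1−P_deg} tokens, since each replicator's token mass is 1)
followed by one replication event (claims `C = M_v·R` pooled over all
vesicles; the winner's mutagenic copy joins its own vesicle). A
vesicle reaching S immediately splits: daughters of ⌊S/2⌋ and ⌈S/2⌉
assembled by uniform without-replacement assortment (multivariate
hypergeometric over types); one daughter keeps the parent slot (coin
flip), the other overwrites a uniformly random *other* compartment, so
N is constant. One SCM timestep is ⌊N(S−1)/2⌋ update steps, making
event counts comparable to a lattice generation (Z² one-event updates
vs. two-event steps at capacity N(S−1)).

## The transition

Vesicles are sampled from the lattice as circular patches: a uniform
random centre cell and a Gaussian diameter (mean 7.5 cells, SD 1.0,
truncated at ≥ 2 — chosen so that a patch at the typical ~80%
occupancy holds ≈ 35 replicators, matching the scale at which patch
content and metabolic neighbourhoods are commensurate). Membership is
toroidal Euclidean distance ≤ diameter/2. Sampling copies replicators
and leaves the lattice unchanged. A sampled patch larger than S−1 is
uniformly subsampled to S−1 (it must fit below the split size).

Four SCM initialisations: `random` (every vesicle gets n_init pool
draws), `single` (one sampled vesicle, N−1 empty), `simultaneous`
(n_sampling patches from one snapshot), and `sequential` (a co-running
surface simulation is sampled n_sampling times per generation for
dt_trans generations, each generation followed by one SCM timestep).

## Folding backends

The genotype→phenotype map is built on a pluggable MFE backend:

* **vienna** — the ViennaRNA engine through its Python bindings, with
  the engine's default model (temperature, dangles). This is the
  production map and the default when the bindings are importable.
* **nussinov** — a self-contained base-pair maximisation backend (min
  hairpin loop 3, Watson–Crick + G·U pairs, deterministic traceback,
  surrogate energy −2 kcal/mol per pair). It exists so that structural
  code paths run without the compiled engine, and it is verified
  against an exhaustive nested-matching oracle on short sequences. A
  numba-compiled twin of the same dynamic program is used when numba
  is importable; both paths produce identical structures.

The two backends are *not* interchangeable for population dynamics:
maximising pairs squeezes loops to their minimum lengths, so the larger
loop motifs of the rule table essentially never occur under the
fallback and a metabolism requiring them cannot assemble. Dynamics
experiments therefore use the Vienna backend; the fallback serves
structural and mechanical tests.

Folding results are memoised by exact sequence (folding is
deterministic), and traits are computed once per distinct sequence in a
registry shared by all simulations of a `Chemistry` instance.

## Problem sizes of the shipped experiments

Published explorations of this model family use lattices of 300×300
cells for 200,000 generations. The experiments shipped with the
package (tests and `scripts/acceptance.py`) are desk-scale: they are
chosen to demonstrate the same qualitative regime — a quasi-stationary
grid occupancy near 80%, largely insensitive to parameters — at sizes
a single CPU handles in minutes:

* construction checks: 10⁴-sequence pools, Z = 100 fills;
* quasi-stationary occupancy: A = 3, Z = 48, N_met = N_rep = 49,
  D = 4, 250 generations, occupancy averaged over the last 100
  generations and across 3 replicate seeds (pool size 2000);
* qualitative selection properties: Z = 10–30, tens of generations,
  5 seeds.

Two caveats are known and accepted. First, small lattices carry a
real stochastic-extinction risk: with N_met a sizeable fraction of the
lattice the system approaches the mean-field regime, and a single
activity class can drift to global extinction (observed repeatedly at
Z ≤ 40), after which the whole community decays — which is itself the
behaviour the mean-field limit predicts. A quasi-stationary occupancy
only exists for a living population, so the occupancy experiment
reports the survivor-conditioned mean alongside the unconditional one
and the per-seed survival flags; at Z = 48 all tested replicates
survive the 250-generation horizon. Second, at a few hundred
generations the trait distributions (length, ΔG_min) are still slowly
drifting; occupancy plateaus within ~150 generations, which is the
quantity these runs measure.

A related desk-scale limit: the mean-field prediction (whole-lattice
metabolic neighbourhoods destroy coexistence by competitive exclusion)
is a long-horizon statement. On small lattices at A = 3 the mean-field
system actually *establishes* more easily than spatially structured
runs — every replicator sees the globally complete metabolism — and
its collapse takes hundreds to thousands of generations because each
activity is redundantly carried. Short desk-scale comparisons can
therefore show mean-field runs out-surviving local-neighbourhood runs;
the corresponding qualitative test documents this in its docstring.

## What the synthetic data does and does not show

All inputs are generated internally: random pools, the packaged rule
table, and the simulations themselves. The random pool emulates an
unevolved prebiotic sequence population (i.i.d. bases, Poisson
lengths); it does not emulate any empirical RNA ensemble, and the
motif rules are arbitrary by construction — they stand in for unknown
sequence–function relationships. Passing tests therefore demonstrate
the *dynamical* claims (coexistence through spatial/compartment group
selection, assortment load, parasite tolerance) for this synthetic
chemistry, not statements about real ribozymes.

## Numerical choices

* Geometric means are computed in log space in the scalar API; the
  lattice inner loop uses the algebraically identical vectorised
  `prod(·)^(1/A)` (claims are moderate and A ≤ 10, so overflow is not
  reachable); agreement is asserted by a test.
* Broken-stick draws consume exactly one uniform variate and fall back
  to the designated "no event" owner without consuming randomness when
  all claims are zero.
* Every run takes one `numpy.random.Generator`; per-generation
  randomness is pre-drawn in blocks. With a fixed seed and backend,
  runs are bit-reproducible.
* Degradation warnings clamp positive ΔG_min to 0 (cannot occur with
  either backend, which return ≤ 0 by construction).
* Vesicle activity sums are recomputed from members on every
  membership change rather than updated incrementally — at S ≤ 100
  this is cheap and immune to floating-point drift, keeping the
  "M_v = 0 iff an activity is absent" invariant exact.

## Known limitations

* No duplex bookkeeping: a replication event creates the complement as
  an independent strand; co-folding and G·U-aware complementarity are
  out of scope.
* The mutation kernel is maximum-entropy uniform; no thermodynamic
  mutation spectra.
* Metabolites are implicit; there is no explicit metabolite diffusion
  or stoichiometry.
* The Nussinov backend's surrogate energies make nearly every random
  sequence maximally stable (P_fold ≈ 1), collapsing the
  catalysis/replicability trade-off; it is a structural test backend,
  not an alternative chemistry.
* Desk-scale runs cannot reproduce evolved-state statistics that need
  10⁵-generation horizons (promiscuity structure, evolved trait
  optima); the analysis surfaces that measure them are implemented and
  tested mechanically.
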