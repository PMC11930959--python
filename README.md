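# riboworld

Agent-based simulation of metabolically cooperating RNA replicators on
mineral surfaces and in protocell vesicles, with an explicit
surface-to-vesicle transition.

## The problem

In RNA-world scenarios for the origin of life, a community of RNA
strands must simultaneously act as templates and as ribozymes
catalysing a shared metabolism that produces the monomers for their
own replication. Such communities face competitive exclusion (the
fastest template wins and the metabolism loses an essential enzyme)
and parasite invasion, so their survival depends on *group* selection
imposed by spatial structure. `riboworld` implements two coupled
organisations of that idea for people studying replicator ecology and
prebiotic evolution:

* **MCRS** (Metabolically Coupled Replicator System) — a toroidal
  Z×Z lattice where each cell holds at most one replicator. Empty
  cells are colonised by mutagenic complementary copies of
  neighbours, weighted by claims `C_i = R_i·M_i`; occupied cells decay
  with probability `P_deg`; a Toffoli–Margolus block-rotation scheme
  provides limited surface diffusion.
* **SCM** (Stochastic Corrector Model) — N vesicles, each a
  well-mixed community of up to S−1 replicators. Degradation and
  replication are pooled stochastic events; a vesicle reaching size S
  splits with multivariate-hypergeometric assortment of its contents,
  one daughter overwriting a random compartment.
* **Transition** — circular patches of the lattice are sampled into
  vesicles (single, simultaneous or sequential modes), modelling the
  prebiotic "take-off" of surface communities into compartments.

The genotype→phenotype map is structural: each strand is folded to its
minimum-free-energy secondary structure (ViennaRNA by default) with
energy ΔG_min, giving

```
P_deg  = 0.1 + 0.8·exp(d·ΔG_min)                 degradation
P_fold = 1 − 1/(1 + exp(−c·ΔG_min))  (clamped)   foldedness
R      = g·(l + 1 − P_fold)/(b1 + b2·L)          replicability
a_i    = P_fold·α_i/m^σ                          enzymatic activities
M      = (Π_e Σ_r a_{r,e})^(1/A)                 metabolic function
```

where activities come from hairpin/interior-loop motifs matched
against a packaged rule table (exact loop length, central base
triplet, GC bonus), and the geometric mean `M` makes every one of the
A activities essential. See `docs/methods.md` for the full model.

## Worked example

```sh
python examples/fold_and_traits.py
```

prints, for a designed specialist ribozyme:

```
sequence        GGGGGUUAGCUUCCCCC
structure       (((((.......)))))
dG_min          -8.80 kcal/mol
P_deg           0.2376   (per-update degradation probability)
P_fold          0.9334   (fraction of lifetime spent folded)
R               12.7737   (replication rate)
activities      [1.1667, 0.0, 0.0]
classification  specialist
```

The stem gives a stable fold (high `P_fold`, low `P_deg`), the 7-base
loop with central `AGC` fully matches activity rule 1, and the
sub-additivity penalty is absent (one motif), so the strand is a
specialist: one catalytic activity, on one strand only — its
complement is a functional parasite. `examples/surface_run.py`,
`examples/vesicle_run.py`, `examples/takeoff_transition.py` and
`examples/promiscuity_report.py` walk through the population-level
capabilities the same way.

A thin CLI wraps the library for batch runs:

```sh
riboworld make-pool --seed 1 --out pool.fasta
riboworld run-mcrs --config config.yaml --seed 1 --out run1/
riboworld transition --snapshot run1/snapshot.tsv --mode simultaneous --out scm0/
riboworld run-scm --snapshot scm0/scm_population.tsv --out scm1/
riboworld report --snapshot scm1/snapshot.tsv --out matrix.tsv
```

Every run writes a JSON manifest (config, seed, outputs) sufficient to
reproduce its outputs exactly.

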