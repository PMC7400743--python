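# Methods

## The screen, in outline

`pitscreen` looks for genes that evolved unusually fast, or under altered
selection pressure, on the branch ancestral to a focal clade — pit vipers
(Crotalinae) in the motivating application, where the trait of interest is
infrared perception.  Two screens run independently and their candidate
lists are combined:

- the **branch-length screen** works on per-gene trees whose branch lengths
  were estimated on a single fixed genome topology, so lengths are
  comparable across genes;
- the **selection screen** works on per-gene in-frame codon alignments and
  a pruned, foreground-labeled copy of the genome tree.

The union of the two candidate lists is the final set; the intersection is
the doubly-supported set.  A substitution scan then reports, for any gene,
the alignment columns fixed for one residue in the foreground and a
different residue in all background snakes.

## Branch-length screen

For a gene tree and a clade configuration (foreground pit vipers; a
colubrid+elapid outgroup; Viperinae; Azemiopinae), three (x, y) points are
computed per gene:

| step | origin node | x | y |
|---|---|---|---|
| 1 | MRCA(foreground ∪ outgroup) | mean root-to-tip length, outgroup | mean root-to-tip length, foreground |
| 2 | MRCA(all Viperidae present) | mean root-to-tip length, Viperinae+Azemiopinae | mean root-to-tip length, foreground |
| 3 | MRCA(all Viperidae present) | longest root-to-tip length, Viperinae+Azemiopinae | foreground stem branch length |

A gene survives a step when its point lies strictly above the 1:1 line and
(steps 1–2) strictly above an ordinary-least-squares line fit on the genes
entering that step.  Strict inequalities make ties deterministic (a
zero-length stem is a legal value that simply fails).  Undefined metrics —
a comparison clade absent from the tree, or a non-monophyletic foreground,
which has no stem branch — fail the step rather than erroring the batch.

Two behaviors are configurable because they are genuinely underdetermined:

- **Regression pool.** The OLS line can be refit on each step's surviving
  pool (default) or fit once on the full input set.  Refitting makes the
  filter pool-dependent: the same gene can pass in one pool and fail in
  another.  In particular, an OLS line fit through two points interpolates
  them exactly, so pools smaller than three fall back to the 1:1 line (with
  a warning), and `use_regression=False` disables the fitted lines entirely,
  leaving a pure per-gene rule.  Exact idempotence of the re-screen on
  unchanged trees holds only in that mode; with regression enabled the
  re-screen is by construction a different test on a smaller pool.
- **Step-2/3 origin.** The measurement origin is the MRCA of all Viperidae
  present (default) or the MRCA of foreground+Azemiopinae
  (`viper_origin="crotalinae_azemiopinae_mrca"`).

The re-screen on topology-unconstrained trees reruns the same three steps on
the candidate subset; a candidate whose unconstrained tree breaks foreground
monophyly has no stem and fails step 3.

## Likelihood engine

**Codon model.** States are the 61 sense codons of the standard genetic
code.  Instantaneous rates for single-nucleotide changes are
κ^{ti}·ω^{nonsyn}·π_j (transition factor κ, nonsynonymous factor ω, target
codon frequency π_j); multi-nucleotide changes have rate zero.  Each branch
class (background `BG`, foreground stem `FG`) carries its own ω; each
class's matrix is scaled so −Σ π_i Q_ii = 1, making branch lengths expected
substitutions per codon.  Codon frequencies default to F3x4 (products of
position-specific nucleotide frequencies, floored at 1e-4 per nucleotide and
renormalized to guard sparse data); F61 and uniform are selectable.  Stop
codons and ambiguous codons are treated as missing data at read time, since
consensus-called coding sequences routinely contain artifacts.

**Protein model.** WAG exchangeabilities (shipped as packaged data, PAML
residue order) with either WAG or empirical ("+F") frequencies and optional
discrete-gamma rate variation (4 equal-probability categories by default;
category rates are the exact conditional means, so they average to 1).

**Pruning.** Felsenstein pruning runs over compressed site patterns with
per-node rescaling; missing states contribute partial likelihood 1 in every
state, so an all-missing column contributes exactly zero log-likelihood.
Transition matrices come from eigendecomposition in the π-symmetrized basis
(B = D Q D⁻¹ with D = diag(√π) is symmetric for reversible Q, so the
spectrum is real); `transition_matrix` falls back to scaling-and-squaring
when no frequency vector is supplied.  Mixtures (gamma rate categories,
branch-site site classes) are handled as weighted components sharing the
tree traversal.

**Fitting.** Scalar parameters (κ, the ω's, optionally the gamma shape) are
optimized by L-BFGS-B on log-transformed values within bounds ω ∈ [1e-6,
100], κ ∈ [0.05, 100], t ∈ [0, 50]; branch lengths by exact coordinate
ascent — with inside (post-order) and outside (pre-order) partials around
one edge, the site likelihood is Σ_k a_k e^{λ_k t}, a one-dimensional
profile that Brent's method maximizes per edge, with outside partials
maintained fresh during a top-down pass so every update is an exact
conditional maximization.  The two are alternated until the relative lnL
change is below 1e-8 (`converged` reports whether that was reached).
Multi-start fitting (default 3 starts, jittered from a single run seed)
guards against local optima.  The two-ratio fit in `branch_model_test`
starts from the one-ratio optimum plus one perturbed-ω₁ restart, so the
nested-model dominance lnL₁ ≥ lnL₀ holds by construction and the LRT is
clamped at zero.

**Fixed-topology branch lengths** (`estimate_branch_lengths`) reuse the
same machinery with only branch lengths free under the protein model — the
step that standardizes gene-tree branch lengths on the genome topology.

## Selection screen

Alignment filtering removes species with a missing-data fraction above 0.20
(missing = `-`, `N`, `?`, `X`; the fraction is per nucleotide column) and
rejects genes with fewer than 4 foreground or 4 background species ("more
than three" read literally; the boundary is tested).  The user tree is the
genome tree pruned to the surviving taxa, unary nodes collapsed with lengths
summed, and the foreground stem labeled — at least 2 foreground species are
required for a stem to exist.

The LRT statistic 2(lnL₁−lnL₀) is referred to χ² with one degree of
freedom.  Benjamini–Hochberg adjustment runs across the genes that survive
the low-rate exclusion; the exclusion removes genes whose fitted foreground
branch is shorter than 1e-4 expected substitutions per codon — such a branch
carries no information about ω₁, so its ω̂₁ is arbitrary.  The threshold is
configurable; excluding before the adjustment keeps the BH denominator
honest.  Candidates require q < 0.05 and ω₁ > ω₀.

The optional branch-site scan fits model-A-style site classes (purifying
ω₀ ≤ 1 everywhere; neutral ω = 1; two classes with ω₂ ≥ 1 on the foreground
branch), tests ω₂ against the ω₂ = 1 null with df = 1, and reports per-site
positive-class posteriors by naive empirical Bayes — mixture weights plugged
in at their ML estimates, a deliberate simplification relative to
hierarchical-Bayes site scoring, adequate for ranking sites but not for
calibrated per-site probabilities.

## Substitution scan

A protein-alignment column is scanned iff every foreground sequence has a
non-missing residue and at least 3 background sequences do — strict on the
foreground because the claim is about its state, tolerant on background
coverage.  A hit requires all foreground residues identical, all observed
background residues identical, and the two states different.  The reported
proportion divides by scanned columns rather than raw alignment length so
genes with different missingness remain comparable.

## Synthetic data

The generator emulates the study design the screens assume:

- a 19-taxon snake species tree (8 Crotalinae, 1 Azemiopinae, 2 Viperinae,
  2 colubrids, 1 elapid, 3 pythonoid/henophidian lineages, 2 boids),
  ultrametric with root-to-tip depth 0.16 substitutions/site; the pit-viper
  stem is 0.05 and the deepest non-pit viper inside Viperidae is 0.10, so a
  3× stem acceleration (0.15) clears the step-3 comparison while
  unaccelerated genes sit well below it;
- per-gene rates drawn lognormal (σ = 0.3, median 1) — genes share a
  topology but differ in overall rate;
- a chosen fraction of genes have the foreground stem multiplied by an
  acceleration factor a ≥ 1 (default 3, the "ancestral branch more than
  three times the sister branch" regime of the strongest real exemplars);
  a tip-wide mode also accelerates branches inside the clade;
- every branch gets independent mean-one lognormal noise (default σ = 0.1);
- codon alignments evolve forward under the branch-class codon model;
  accelerated genes carry the elevated foreground ω (default ω_FG = 2.0 vs
  ω_BG = 0.2) on the stem, coupling the two signals the way a genuinely
  accelerated gene would.

All randomness derives from one run seed; a bundle regenerated from the same
spec is byte-identical.  What the generator does **not** emulate — alignment
error, gene-tree/species-tree discordance, indels, GC-content heterogeneity,
reference bias in consensus calling — bounds what passing tests show: they
validate the statistical machinery under the model's own assumptions, not
robustness to real-data artifacts.

## Validation batteries and problem sizes

The test suite's statistical checks use these conditions (also the
quantities `scripts/acceptance.py` recomputes, at the sizes noted there):

- **Likelihood exactness:** pruning vs direct enumeration over all
  internal-state assignments on trees of 2–5 tips, ≤4 sites, codon and
  protein, with missing data and a two-class model; agreement to 1e-10
  relative.
- **LRT calibration:** 300 replicates, 6 taxa, 300 codons simulated with
  ω₁ = ω₀ = 0.3; the α = 0.05 rejection count must fall inside the exact
  central 95% binomial interval.
- **Power and ω₁ recovery:** 50 replicates at ω₁ = 2.0, ω₀ = 0.2, 500
  codons on a tree whose foreground stem is 0.5 substitutions/codon.
- **Screen recovery:** 200 genes, 10 accelerated 3×, branch noise σ = 0.1;
  recall and false-positive rate against truth labels.
- **Determinism:** the full pipeline rerun with the same config and seed is
  byte-identical (the timestamped log excluded).

### Precision of per-branch ω estimates

Estimating ω on a single branch is information-limited.  Numerical
Cramér–Rao bounds for this design (observed information at the truth, all
nuisance parameters known) give a coefficient of variation for ω̂₁ of about
0.32, 0.23, 0.19 and 0.16 at foreground stems of 0.2, 0.4, 0.6 and 1.0
expected substitutions per codon — longer stems stop helping because
multiple hits saturate the signal.  The full ML fit (κ, ω₀, branch lengths
co-estimated) measures CV ≈ 0.21 at a 0.5 stem with essentially no bias
(mean ω̂₁ ≈ 2.03–2.07 across 50-replicate runs), i.e. the estimator operates
at the information bound.  Consequently roughly 82–88% of replicates land
within ±30% of the truth; a 90% within-±30% frequency would require CV ≤
0.16 plus zero nuisance inflation, which this design cannot supply at 500
codons.  The estimates are right-skewed, so the misses are mostly
overestimates; the LRT's power is unaffected (1.0 in the same runs).

## Numerical choices and edge cases

- Positional nucleotide frequencies in F3x4 are floored at 1e-4 so sparse
  alignments cannot produce zero equilibrium frequencies (which would break
  the symmetrized eigendecomposition).
- Transition-matrix entries are clamped at 0 and rows renormalized after
  exponentiation; negative entries beyond −1e-9 raise.
- Partial likelihoods are rescaled per node; per-pattern log-scales are
  tracked separately per mixture component and combined by a max-shift.
- Rooted trees are taken as given; reversibility makes the one-ratio lnL
  root-independent (tested), and the degree-2 root's two branch lengths are
  jointly identified only through their sum, which the coordinate-ascent
  optimizer handles without special-casing.
- TSV output renders floats with 8 significant digits and `None` as `NA`;
  Newick output uses 10 significant digits, round-tripping lengths to 1e-9.

## Known limitations

- No codon-level among-site rate variation, non-reversible models, or
  topology search; trees come in with topologies fixed.
- The branch-site scan's naive empirical Bayes is a ranking tool, not a
  calibrated posterior.
- lnL values are not numerically comparable to other programs' constants
  (pattern compression and scaling differ); only differences matter.
- The screen's regression lines presume a genome-scale pool of mostly-null
  genes; on small gene sets use `use_regression=False`.
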