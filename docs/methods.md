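# Methods

## The comparative design

The package implements a sister-clade relative-rates analysis.  Each
comparison contrasts one clade of parasitic plants with a non-parasitic
sister clade, plus an outgroup used only to root the extracted subtree.
Because both clades descend from the same ancestral node, they have had
exactly the same time to accumulate substitutions, so a difference in total
branch length between the clades estimates a difference in substitution
rate, not in elapsed time.  Twelve phylogenetically independent comparisons
make the per-pair signs and magnitudes exchangeable units for paired
nonparametric inference.

A clade's statistic is the sum of all edge lengths from the shared node down
to the clade's tips — the stem edge plus every internal and terminal edge.
The stem is included deliberately: both stems accumulated substitutions
since the common ancestor, and dropping them would discard half of the
deepest signal.  For one-tip clades the statistic reduces to the single
stem-plus-terminal edge.

## Branch-length estimation

Total branch lengths come from maximum likelihood under GTR+G; synonymous
and nonsynonymous lengths and dN/dS (omega) come from the GY94 codon model
over the 61 sense codons of the universal genetic code (plant mitochondria
and plastids both use the universal code).

The likelihood engine computes exact log-likelihoods by Felsenstein pruning
over compressed site patterns.  Gaps, N, and any partial ambiguity code are
treated as fully missing data (summed over states); an all-gap column
therefore contributes exactly zero log-likelihood.  Per-node rescaling
prevents underflow; the per-category log scalers are retained so the
discrete-gamma mixture is formed correctly.  Transition matrices come from a
single symmetric eigendecomposition per rate matrix (all models here are
time-reversible).

Branch lengths are optimized one edge at a time with bounded Brent searches
on [0, 20] substitutions/site (or /codon).  Each edge's one-dimensional
profile is evaluated from cached "inside" (below-edge) and "outside"
(rest-of-tree) conditional likelihoods that are maintained incrementally
during a pre-order sweep, so a sweep costs a small multiple of one full
likelihood evaluation.  Free model parameters are interleaved with sweeps:

- GTR: five exchangeabilities (GT fixed at 1) and the gamma shape, on log
  scale, by L-BFGS-B with finite-difference gradients; base frequencies are
  the empirical frequencies of the alignment.
- GY94: kappa by bounded Brent; omega per parameterization — `single`,
  `free` (one omega per edge, re-optimized inside the sweep with the same
  cached partials), or `per-clade` (parasite edges, non-parasite edges,
  remaining edges).  Codon frequencies are F3x4, computed from positional
  base composition of the data.

Iteration stops when the log-likelihood improves by less than the tolerance
(default 1e-6; the heavier validation studies use 1e-5 or 1e-4, where the
residual optimization error is orders of magnitude below sampling noise).
The returned trace is non-decreasing, and restarting from a fitted optimum
moves the log-likelihood by less than the tolerance.  Gamma rate variation
uses four equal-weight categories with category-mean rates (the dominant
convention); category means are computed from regularized incomplete gamma
functions and renormalized to mean 1.

Numerical edge cases: identical sequences drive all lengths to the lower
bound (0 within ~1e-7); free-ratio omega is bounded to [1e-4, 99] so
saturated edges cannot diverge; stop codons or ambiguous codons in data are
treated as missing rather than rejected.

## dN/dS decomposition

A codon branch length t (expected substitutions per codon) is split using
the mutational-opportunity convention: the fitted matrix's equilibrium flux
is partitioned into nonsynonymous and synonymous fractions (rho_N, rho_S),
and site proportions (pi_N, pi_S) come from the same model with omega set
to 1.  Then dN = t rho_N / (3 pi_N) and dS = t rho_S / (3 pi_S), so
t = 3 (dN pi_N + dS pi_S) exactly, and omega = 1 forces dN = dS = t/3.
The alternative "physical sites" convention would change pi_N and pi_S only;
the decomposition function takes the model explicitly so conventions can be
compared.

## Paired tests

The Wilcoxon signed-ranks test drops zero differences, ranks absolute
differences with midranks for ties, and uses the normal approximation
Z = (W+ − n(n+1)/4 ∓ 0.5)/σ with the 0.5 continuity correction toward the
mean and the tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48.  This is
the convention of the classic statistics packages and reproduces published
Z values from rounded table entries; it is used even at n = 6 and n = 8.
An exact-distribution option (dynamic programming over doubled midranks) is
provided; exhaustive enumeration at n = 8 shows the approximation within
0.021 of the exact two-tailed p over all sign patterns.

The sign test is the exact two-tailed binomial: p = min(1, 2 P[Bin(n, ½) ≥
max(k+, k−)]).  Base-composition (GC) differences are tested on sign only.
For a genome with heterogeneous gene availability (the chloroplast case:
16S rRNA for some pairs, protein-coding genes for others), each pair
contributes the sign agreed by whichever genes it has; if genes ever
conflicted, the sign of the summed differences would decide — a rule that
the published data never actually exercises, since all multi-gene pairs
agree.  No multiple-testing correction is applied, matching the original
analysis.

## The embedded tables

The published per-pair clade statistics (nuclear and mitochondrial totals,
mitochondrial dN/dS/omega, chloroplast 16S and protein-coding classes) are
embedded as a fixture with the printed availability pattern, and the
comparative-test layer reproduces every printed Z, sign count, and the
combined sign test from them.  The branch-length values themselves are not
recomputed from sequence data: the underlying GenBank alignments and the
original programs' exact runtime options are outside this package's scope,
so the tables enter as inputs and only the statistics computed from them
are reproduced.

## Synthetic data: what it emulates and what it does not

The generator builds balanced sister clades (1–9 tips per side, equal on
both sides, as in the study design that controls the node-density effect):
each clade is an ultrametric Yule tree of fixed height, joined by stem
edges at a shared node, with an outgroup below the root.  A rate multiplier
m scales every parasite-side edge, stem included, mirroring the clade-sum
definition; clade-specific omegas can be set for codon simulation.
Sequences evolve site-independently from the stationary distribution with
the model's own transition matrices, with a per-site gamma category for
nucleotide models.

Defaults: 12 pairs, 4+4 tips, one outgroup, clade height 0.15 and stem 0.05
substitutions/site (clades are moderately diverged but unsaturated, typical
of the genus-to-family-level comparisons the design needs), outgroup depth
0.35, 2,000 codons — a full 12-pair study simulates and fits in minutes on
one CPU.

The generator does not emulate alignment error, pseudogenization, gene
loss, rate variation among lineages within a clade, or non-stationary base
composition.  Passing validation therefore shows the estimation and testing
machinery is correct and calibrated under the model family; it does not
certify robustness to real-data pathologies, which the alignment-hygiene
operations (intron masking, pseudogene flagging, clade-coverage filtering)
only partially address.

## Validation studies and problem sizes

- Pruning is checked against brute-force enumeration of internal states on
  all shapes with ≤4 tips and ≤6 sites, against the JC closed form on
  two-tip trees, and for invariance under re-rooting (GTR and GY94).
- dN/dS is checked against a Gillespie substitution-counting simulation
  (120,000 codon sites on one branch; agreement within 2%).
- Branch-length recovery: 20 seeded replicates, 4+4 tips, 10,000 sites
  under GTR+G with full re-estimation; the median total-length error must
  stay below 5%.  Per-clade omega recovery: truth 0.3, 10,000 codons,
  estimates within [0.25, 0.35].
- Whole-pipeline calibration: 200 null studies (m = 1, 12 pairs, 2+2 tips,
  500 sites, JC track) must reject at α = 0.05 between 2% and 9% of the
  time; power at m = 3 with 2,000 codons must find ≥10 of 12 positive
  differences in ≥90% of 20 studies.  The null and power studies use the
  nucleotide track for total branch length (the same track the real
  analysis uses for totals), at sizes chosen so the whole suite runs on a
  single CPU in minutes.

## Known limitations

- Topologies are inputs; there is no tree search, partitioned model
  selection, or rate smoothing.
- Codon frequencies are F3x4 only; codon fits have no gamma rate variation
  (matching common practice for branch-model fits).
- The per-clade omega classes are defined by descendant tip sets on the
  outgroup-rooted subtree; edges ancestral to both clades and outgroup
  edges share the third "background" class.
- GC content is pooled across tips by default (a per-tip-mean flag exists);
  with balanced clades the two differ negligibly.
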