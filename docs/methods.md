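# Methods

## The substitution model and its inference

The evolutionary unit is a rooted phylogeny whose branches *b* (one per
non-root node, identifying parent(*b*) → *b*) each carry a conditional
substitution table P<sub>b</sub>(y | x; l, r): the probability that a
site whose parent state is *x*, with parent flanking bases (*l*, *r*),
is *y* in the child. Branch lengths are absorbed into the tables, so no
molecular clock or reversibility is assumed; conditioning on flanks is
what lets the expected divergence track context effects (hypermutable
dinucleotides, composition-dependent rates) instead of mistaking them
for selection. Contexts are the 16 ordered ACGT flank pairs plus one
pooled fallback used where a flank is a sequence edge, gap or N; the
pooled row is trained on all events.

Fitting is EM. The E-step runs per-position sum-product over the tree
with flank contexts held fixed — reference-sequence flanks on the first
iteration, posterior-mode ancestral flanks of each branch's parent node
afterwards. Any tree node whose name matches an alignment row is clamped
to its observed bases; gap/N symbols are marginalized. The M-step
re-estimates each table from expected parent–child counts plus a
pseudocount (α = 0.5 per cell); rows with essentially zero expected
opportunity are set to the identity and flagged. Full joint inference
over flanking triplets is deliberately not attempted: the fixed-flank
approximation preserves the property the pipeline needs (context-corrected
expected rates) at a fraction of the cost.

Two choices matter numerically:

* **The root prior is flank-conditioned and anchored, not learned.** The
  likelihood of a non-reversible per-branch model has a nearly flat ridge
  along which root composition trades off against substitution direction
  on the root-adjacent branches — EM walks this ridge and can deflate a
  context-specific rate by tens of percent while gaining almost no
  likelihood. We therefore pin the root prior to the empirical contextual
  base composition averaged over the aligned species (a near-stationarity
  assumption) and never update it. A `root_prior="learn"` mode exists but
  is only advisable with external constraints.
* **Trees used for parameter studies should pin their ancestors.** On a
  bifurcating root the direction of root-adjacent events is close to
  unidentifiable; a trifurcating (or star) root gives every ancestral
  node at least three incident lineages. The package's parameter-recovery
  study uses a 5-taxon star for exactly this reason: it measures
  estimator accuracy where the parameters are identified, rather than
  confounding it with topology-induced ambiguity.

Per-position statistics follow from the posteriors: obs(l) is the
posterior probability of a parent≠child change summed over branches,
exp(l) the model-expected change given the parent-node marginal and the
flank context. Over a correctly learned model Σobs/Σexp ≈ 1 (measured
0.993–0.994 on 200 kb neutral simulations); EM is run to 4 iterations in
the recovery study (the default of 2 is adequate for divergence tracks
but not yet converged for individual context cells).

## Conserved-element calling

Each locus is scored by the 20 bp window centered on it; it is a hotspot
when the window's Σobs ≤ 0.5·Σexp, Σexp > 0, and the window contains no
masked base (windows touching a mask are skipped outright, avoiding
renormalization artifacts at exon borders). Center-scoring leaves hotspot
runs half a window short of the conserved span on each side, which the
subsequent 10 bp (= window/2) expansion exactly compensates; expanded
intervals are merged (bookended intervals fuse) and kept when strictly
longer than 30 bp, then rescored as Σobs/Σexp over the final interval.
Lowering the qualifying ratio can only remove elements; enlarging the
expansion can only grow or merge them.

Detection power is set by the tree depth: a neutral 20 bp window carries
20·T expected substitutions for total tree length T, and the chance that
it dips below half of that is roughly the lower Poisson tail. The
default pipeline tree (8 taxa, T ≈ 2.1) puts ~42 expected substitutions
in a window, making spurious two-fold depletion negligible while leaving
alignment columns informative.

## Profiles, normalization, peaks

All spatial profiles use signed minimal distance: every genomic position
contributes to exactly one offset, that of its nearest anchor (ties to
the smaller coordinate; positive = genomic right, or downstream when a
per-locus orientation is given). Composition profiles report per-offset
base frequencies with binomial 95% CIs; signal profiles report means
with normal-approximation CIs. Signal tracks are binned at 20 bp,
optionally pre-smoothed with an overlapping running mean (200 bp for
DHS-like data), and normalized to genome-wide percentiles (rank/n,
average ranks on ties; an all-equal track maps to 0.5). Peak calling
takes bins above a percentile threshold in at least one
replicate/stage, enforces a minimum distance to annotated TSSs when
given, and reports the maximal-value bin of each run as the peak center.
Site-set enrichment is log2(observed/expected) per distance bin with the
expectation proportional to assignable unmasked bp; bins with expected
counts below 0.5 are reported absent rather than letting a pseudo-count
fabricate enrichment.

## Compensation statistics

For two aligned species, δ(l) = [species-1 base is G/C] − [species-2 base
is G/C] at positions where both are plain bases. The coupling score C(d)
is, among position pairs (l, l+d) that are both diverged with δ ≠ 0 and
have at most 4 undefined positions in between, the fraction with
opposite-sign δ — compensation of a GC excess in one species at one locus
by a GC excess of the other species nearby. CIs are binomial
(normal approximation with continuity correction). The permutation
control shuffles δ labels among usable loci; the fraction of d-points
whose CI excludes the permuted global mean calibrates the flatness test.

The single-lineage (parametric) version calls gain events where the
posterior mass of (parent ∈ {A,T} → child ∈ {G,C}) on a chosen branch
exceeds τ = 0.9 (loss symmetric; precision ≥ 0.9 against the simulation
log when the lineage's parent is corroborated by ≥ 3 other lineages) and
then measures each event type's rate conditioned on a same- or
opposite-type event within a one-sided distance d. The spatial
gain/loss balance around CEs divides posterior gain mass by AT
opportunity and loss mass by GC opportunity per distance bin, with all
12 directed type rates emitted alongside.

## SNP spectra

SNPs are filtered to biallelic records with minor-allele frequency
> 0.01 and coverage ≥ 10, outside masked regions; the major allele
serves as the proxy ancestral state for typing (GC gain / loss / neutral
× transition / transversion). Local GC is the G+C fraction of the 20 bp
window centered on the site, focal base excluded by default — including
it couples the bin to the allele identity mechanically (a G-site's own G
inflates its bin); both modes are available. Bins are equal-width on
[0,1] by default with a quantile option. The statistic per
(type × local bin [× regional bin]) cell is f_rare = P(maf < 0.05)
(mammalian preset: < 0.082; 20 bp × 5 bins × 1 kb × 5 bins), with
binomial CIs and a low-n flag under 25 records. A single regional bin
reduces the two-scale analysis exactly to the one-scale one.

## k-mer and microsatellite scans

k-mer frequencies are computed per signed-distance bin around CE centers
(overlapping starts, stride 1; a start belongs to the bin of its first
base and is dropped if any covered base is masked or ambiguous). Raw
enrichment is log2(f_bin / f_global). Composition-normalized enrichment
divides each bin's frequency by the product of that bin's single-base
frequencies *first* and only then forms the ratio to the start-weighted
global mean of the normalized values. Normalizing before pooling
matters: a pooled global denominator retains a Jensen-gap residual
wherever composition varies between bins, and a sequence i.i.d. within
each stratum would not score zero. With the order used here the
composition-matched null is flat to sampling noise (measured
|norm_log2| < 0.03 at 10⁷ starts/bin), k = 1 self-normalizes to exactly
zero, and zero-frequency cells receive a flagged pseudo-frequency
0.5/n_starts. Tandem repeats are maximal exact-motif runs (per phase,
with a family helper that unions rotations and reverse complements), and
divergence around repeats simply composes repeat finding with the signal
profiler on obs and exp.

## The synthetic-data generator

The generator is the package's instrument for validation, not a fixture:
its defaults define the study conditions and every draw comes from one
seed via named substreams.

**Landscape.** Planted cores are 20–40 bp at target GC 0.25, flanked by
a continuous profile that ramps to 0.55 at 30 bp from the core edge and
decays (exponentially, scale 80 bp) to a 0.40 background exactly at
300 bp; cores are separated by ≥ 600 bp so flanks never interact. A
second constructor provides a smooth two-scale landscape (sinusoids of
period 4 kb and 120 bp, amplitudes 0.13 and 0.12 around 0.45) for
polymorphism studies, where the quantity of interest is the association
between allele frequencies and local GC *within and across* regional
strata — that requires genuine regional GC variation, and sharp
core/flank boundaries would put window-versus-point target mismatches
exactly where SNP density is highest.

**Sequence evolution.** Along each branch of length t (expected neutral
substitutions/site), candidate mutations arise from a rate-form 4×4
matrix (transitions 2× transversions; G/C rows accelerated 1.5×, putting
the mutational GC equilibrium at 0.40) with optional per-(left, focal)
context multipliers, thinned from a static per-position envelope. A
candidate changing window GC g to g′ at a site with target τ has
s = κ·(|g−τ| − |g′−τ|) (window 20 bp, centered, focal included) and is
accepted with 2N·π(s)/A, where π is the diffusion fixation probability
(1−e<sup>−2s</sup>)/(1−e<sup>−4Ns</sup>), N = 10, and A is the envelope
boost; at κ = 0 every candidate is accepted and the realized rate equals
the nominal rate exactly (Poisson-calibrated to 3σ in tests). κ = 10 is
the compensatory reference setting (4Ns = ±20 at a full one-base
displacement); it both tightens g around τ and produces the short-range
coupling of opposing substitutions that the compensation statistics
detect. The fixation form and N are stand-ins for an unspecified
population process — N is a shape knob, never an inference target.
Accepted events are logged as (branch, position, from, to) and replay of
the log reproduces every leaf exactly.

**SNP panels.** Positions are uniform outside an exclusion zone around
cores; the minor allele is drawn from the mutation matrix row of the
reference base; the minor-allele frequency is a two-component mixture
whose rare component (maf ∈ (0.01, 0.05)) has weight
expit(logit(0.30) − 0.08·4N·s) with s computed exactly as in the
evolutionary simulator. For trend studies the reference sequence is
produced at approximate mutation–selection balance
(`balance_sequence`): standing local GC is displaced from the target
toward the mutational equilibrium (g* = gc_mut + 0.55·(τ − gc_mut)) and
sampled with an error-diffusion scheme that keeps window GC tightly on
g*. The displacement is what generates the observed trend — in GC-rich
elements the sequence sits below its target, so further GC loss is
deleterious and GC-losing minor alleles are rarer there, and conversely
in AT-rich elements — which is the mechanism the analysis is meant to
detect. A per-position Bernoulli draw would bury this displacement under
binomial window noise; the tight-tracking regime corresponds to the
assumption that selection maintains local composition closely.

**Signal tracks.** The nucleosome-like track is a logistic function of
binned GC plus Gaussian noise; mark tracks add Gaussian bumps (σ = 75 bp,
amplitude 4) over one of three disjoint core subsets each, with subset
memberships recorded, so epigenetic clustering has planted classes to
recover.

## Reference studies and the sizes used

* Ancestral-inference oracle: 4 taxa, 200 positions, random tables —
  pruning vs exhaustive enumeration agrees to ~10⁻¹⁵.
* Model recovery: 5-taxon star, 200 kb, CpG-like multiplier 2.5,
  κ = 0, stationary start (burn-in 4 expected subs/site), 4 EM
  iterations. All table cells backed by ≥ 200 realized events recovered
  within ±15% (typically within ±7%); Σobs/Σexp within [0.99, 1.00].
  The stationary start matters: a root drawn directly from the target
  profile is measurably out of equilibrium with an AT-biased mutation
  process, and the resulting mismatch between root composition and the
  anchored prior biases CpG-context rates on root-adjacent branches.
* CE recovery: 8 taxa, 500 kb, 100 cores, ρ = 0.25, κ = 0. Sensitivity
  ≈ 0.9 at Jaccard ≥ 0.5 with no false calls; recovered-element
  composition profile shows the planted punctuated pattern.
* Compensation: 200 kb two-species alignments (flat landscape, burn-in
  2); κ = 0 null flat under 50 δ-permutations, κ = 10 gives pooled
  C(d ≤ 20) ≈ 0.62–0.64 vs C(500) ≈ 0.43–0.52 with disjoint CIs;
  conditional opposite/same ratios ≫ 1 at d ≤ 20 on a 3-taxon lineage
  test.
* SNP trends: 50,000 SNPs on the smooth landscape; null panel flat
  (|ρ| ≈ 0.02), selected panel gives per-SNP Spearman ≈ +0.24 for
  GC-losing and ≈ −0.34 for GC-gaining types, sign preserved in every
  populated regional stratum.
* k-mer null: 6 strata × 10⁷ i.i.d. bases spanning GC 0.32–0.62;
  |norm_log2| < 0.03 for CA/TA/CAA/poly-A repeat units while raw (CA)₃
  enrichment in GC-elevated strata is strongly positive — the
  raw-versus-normalized contrast arises from composition alone.
* Clustering: 120 cores in 3 planted mark classes; k-means on the CE ×
  mark matrix recovers them exactly (ARI 1.0), deterministically under a
  fixed seed.

## What the simulations do and do not show

The generator reproduces the *statistical structure* of the phenomenon —
context-dependent rates, rate suppression in elements, GC-targeted
stabilizing selection, allele-frequency coupling to local GC, GC-driven
signal tracks — under exactly known truth, so it validates that each
estimator recovers what it claims to recover at realistic effect sizes.
It does not contain indels or alignment error (all coordinates are
exact), recombination, biased gene conversion (a known confounder of
GC-favoring patterns), linked selection, demography (the SFS is a
phenomenological mixture, not a population simulation), or real
epigenomic noise structure. Passing these studies therefore establishes
correctness and calibration of the pipeline, not that real-genome
signals are free of those confounders.

## Known limitations

* The EM estimator conditions flanks on a single (posterior-mode)
  ancestral assignment per iteration; on trees with long leaf branches
  above internal nodes, context-specific internal-branch rates carry
  attribution noise of several percent (worse near the event-count
  threshold), and on bifurcating-root trees the root-adjacent direction
  is poorly identified even with the anchored prior.
* The anchored root prior assumes near-stationary composition; strongly
  non-equilibrium data (e.g. a recent composition shift) will bias
  root-adjacent branch tables.
* CE scores are fold-depletion summaries with no per-element
  significance; elements shorter than ~15 bp are not separable from the
  window acceptance region.
* The SNP rare-allele machinery treats the major allele as ancestral;
  with no outgroup polarization, strongly skewed sites can be
  mis-typed.
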