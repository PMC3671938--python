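# cescape

Analysis pipeline for the evolutionary landscape around short conserved
sequence elements (CEs) in compact genomes — the pattern in which an
AT-rich, slowly evolving core of a few tens of base pairs sits inside a
few hundred base pairs of GC-elevated flanking sequence, maintained not by
static conservation but by a shifted balance between G/C-gaining and
G/C-losing substitutions under weak, compensatory selection on local
(20 bp) GC content.

The package is aimed at molecular-evolution researchers who want to
detect and characterize this regime end to end on alignments and
polymorphism panels:

* **Context-dependent substitution model** (`cescape.subst_model`): for
  every branch *b* of a rooted phylogeny it learns conditional tables
  P<sub>b</sub>(y | x; l, r) — the probability that parent base *x* with
  parent flanks (*l*, *r*) becomes child base *y* — by EM with per-position
  sum-product (Felsenstein pruning) as the E-step, and computes posterior
  expected (obs) and model-expected (exp) substitution counts per position.
* **CE calling** (`cescape.ce_caller`): loci whose centered 20 bp window
  has obs ≤ ½·exp form hotspots; hotspots are expanded by 10 bp, merged,
  and kept when longer than 30 bp.
* **Profiles, clustering, compensation, SNP spectra, k-mer scans**
  (`cescape.profiles`, `.clustering`, `.compensation`, `.snp_freq`,
  `.kmer_scan`): signed minimal-distance profiling around locus sets,
  percentile normalization of signal tracks and percentile peak calling,
  k-means clustering of CEs by epigenetic marks and by 2 bp-step GC
  encoding, the coupling score C(d) (fraction of diverged locus pairs at
  distance *d* with opposite interspecies GC change), conditional
  gain/loss rate tests, rare-allele spectra stratified by mutation type ×
  local GC, and composition-normalized k-mer/microsatellite enrichment.
* **Synthetic data with full ground truth** (`cescape.synthetic_data`):
  a sequential origination–fixation simulator in which candidate
  mutations fix with the diffusion probability
  (1−e<sup>−2s</sup>)/(1−e<sup>−4Ns</sup>), s = κ·(|g−τ| − |g′−τ|) for
  local window GC g and target τ; plus SNP panels whose rare-allele mass
  tracks the same s, and GC-correlated signal tracks. Every substitution
  is logged, so recovery can be scored exactly.

## Worked example

Run the full pipeline on a small simulated genome:

```
cescape run --config run.yaml --outdir demo --seed 4
```

with `run.yaml` containing, e.g., `{length: 60000, n_ces: 12, n_snps: 3000}`.
Equivalently from Python:

```python
from cescape.pipeline import RunConfig, run_pipeline
out = run_pipeline(RunConfig(seed=4, outdir="demo", length=60_000,
                             n_ces=12, n_snps=3000))
```

The run directory then contains `leaves.fa`, `ce_truth.bed`, `snps.tsv`,
the learned `model.json`, per-bp `obs.bedgraph`/`exp.bedgraph`, called
elements in `ces.bed`, profile/cluster/coupling/spectrum TSVs, and a
`manifest.json` with parameters and output checksums. On this 60 kb
genome with 12 planted cores the caller reports 10 elements in `ces.bed`,
every one matching a planted core (10/12 recovered, none spurious), with
BED scores 1000·(1−obs/exp) between about 410 and 550: the cores evolve
at ρ = 0.25 of the neutral rate, and the element-wide ratio is diluted
toward ~0.5 by the 10 bp expansions on either side.

A focused recovery experiment:

```python
from cescape.studies import ce_recovery_study
print(ce_recovery_study(seed=1))
```

prints (among other keys) `sensitivity: 0.94`,
`false_call_fraction: 0.0`, `profile_center_gc: 0.253`,
`profile_flank_max_gc: 0.60`, `profile_background_gc: 0.396` — 94 of 100
planted cores recovered at Jaccard ≥ 0.5 with no spurious calls, and the
composition profile around the *recovered* elements reproducing the
punctuated pattern: AT-rich at the element (GC ≈ 0.25), GC maximum a few
tens of bp away (≈ 0.60), background (≈ 0.40) by 500 bp.

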