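# Methods

## Kinetic model and its assumptions

Each gene's mRNA count follows a birth–death process with zero-order
synthesis rate α (molecules·h⁻¹) and first-order degradation constant β
(h⁻¹).  Three assumptions make the rates identifiable from a single
labeling window of length t:

1. **Steady state.** Perturbations were established long before labeling,
   so dR/dt = 0 and R = α/β per gene.  The labeling itself does not perturb
   the steady state.
2. **Complete labeling.** Every molecule synthesized during the window
   incorporates label (efficiency 100%), so the nascent pool is
   Rn = (α/β)(1 − e^(−βt)) and the pre-existing pool decays as
   Rp = (α/β)e^(−βt).  An optional efficiency correction is deliberately
   not applied by default.
3. **Accurate partitioning.** Measured whole counts R and nascent counts Rn
   stand in for the true pools; misclassification by the read-level caller
   biases the estimated nascent fraction (see caller section).

Under these, β = −ln(1 − Rn/R)/t and α = R·β in the count scale of the
pseudobulk.  α therefore grows with the number of cells aggregated; all
cross-group uses (fold changes, the global synthesis screen) rescale to a
per-million depth first, while β — a pure ratio — needs no normalization.
Degenerate pseudobulks (Rn = 0, Rn = R, or R = 0) are flagged with a reason
code and excluded from testing rather than regularized with pseudocounts:
at pseudobulk depth degeneracy indicates genuinely insufficient signal, and
smoothing would bias β toward arbitrary values.

**Numerical range.** The closed form is exact; in double precision the
round trip forward-model → solver is accurate to better than 1e-10 relative
error while βt ≲ 12.  Past that the labeled fraction saturates
(1 − e^(−βt) rounds to 1) and no estimator can recover β from counts, which
is a property of the chemistry horizon, not of the implementation: rates of
genes with half-lives far below the labeling window are not measurable by
design.

## Nascent-read calling

A read is classified from its mismatches in transcript orientation
(genomic T>C for plus-strand genes, A>G for minus-strand genes).  Eligible
mismatches must sit in aligned (CIGAR M) columns, exceed the base-quality
threshold, and fall outside the SNP background mask.  The read is nascent
iff it has at least one eligible mismatch and the conversion fraction
strictly exceeds `min_tc_fraction` (default 0.30); reads with zero eligible
mismatches are pre-existing (0/0 counts as 0).  The same eligibility
filters apply to numerator and denominator.

Choices worth knowing:

- `min_base_quality` defaults to 45 (strict >), mirroring the published
  filter; platforms capping Phred at 40–41 (and the bundled simulator,
  which emits Phred 40) require lowering it or every conversion is
  discarded.
- Transcript orientation comes from the annotated gene strand via the
  unique-overlap gene assignment; reads overlapping no unique gene fall
  back to alignment strand and are flagged `strand_fallback`.
- The SNP background is built from an unlabeled control sample: a site is
  masked when coverage ≥ 10 and one alternate base reaches ≥ 50% of
  covering reads.  These thresholds are explicit configuration, not claims
  about how any published mask was built.

**Operating characteristics.** At a per-T conversion probability of 0.05 on
50-nt reads, a nascent read carries zero conversions ~53% of the time
(binomial with ~12.5 templated Ts), so molecule-level recall is bounded
near 0.47 by the chemistry regardless of the caller.  The caller is
therefore characterized on the evidence it can see: sensitivity on nascent
reads carrying ≥ 1 true conversion (> 0.99 in the test conditions) and
specificity on pre-existing reads (> 0.99 at a 1e-3 sequencing error
rate).  Whole-transcriptome nascent fractions are consequently
underestimates of the true fraction of young molecules — consistent with
conversion-based assays generally — and comparisons between perturbations
remain valid because the undercount is shared.

## Guide assignment and filtering rules

Observed protospacers are corrected against the whitelist allowing one
mismatch; an exact hit always wins, a distance-1 tie is rejected (avoiding
systematic misassignment between near-identical protospacers), and `N`
counts as a mismatch.  After UMI collapse per (cell, guide), a cell is a
singlet iff its total guide UMIs exceed 10 (strictly), the top guide holds
≥ 60% of them, and the top is ≥ 3× the second (a zero second passes; a tie
for top is a doublet).

Cell QC keeps cells with ≥ 300 transcriptome UMIs, ≥ 200 genes, ≥ 10 guide
UMIs and an unannotated-read fraction < 40%.  Knockdown efficiency is
computed per guide on whole-transcriptome pseudobulk CPM against the NTC
pseudobulk; guides reaching ≥ 40% target reduction are effective, their
singlets are on-target cells, and targets with fewer than 50 on-target
cells are dropped.  Gene assignment uses unique gene-span overlap with
strand match (exonic status recorded separately) — nascent reads are
intron-rich, so exon-restricted counting would discard much of the signal;
multi-gene overlaps are discarded rather than fractionally assigned.

## Significance testing

**Randomization test (per gene, per perturbation).** Background rates come
from resampling cell subsets of the perturbation's size, without
replacement, from the pooled perturbed+NTC cells; each subset is
re-aggregated and re-solved.  Degenerate resamples ("invalid samplings")
contribute rate 0 to the background and the gene is untestable once they
reach 10% of iterations (strict <, i.e. fewer than 50 of 500).  The
two-sided empirical p is

    p = min(1, 2·min(1 + #{bg ≥ obs}, 1 + #{bg ≤ obs}) / (n_iter + 1)),

never zero by construction; direction compares the observed rate with the
background mean.  Equal subset sizes make the count-scale α comparable
within the test, so no normalization is needed there.  Under the exact
null (perturbed cells drawn from the NTC distribution) the rejection rate
at p < 0.05 is ~0.048 by the discreteness of the formula; the test suite
checks it stays within [0.03, 0.07].

**Global screens.** Distributions of per-gene rates (over the top 1,000
NTC-expressed genes, α depth-normalized) or per-cell fractions (exonic
share of nascent reads; mitochondrial nascent/whole turnover) are compared
with NTC by two-sample KS tests, BH-corrected per metric, significant at
FDR ≤ 0.05 with direction from the sign of the log2 median ratio.  Sides
with fewer than 10 finite values stay untested.

**Differential expression.** The engine is a deliberately simple two-sided
rank-sum test on per-cell CPM (pluggable; heavier GLM engines are out of
scope); what is faithful to the screening procedure are the post-filters:
FDR < 0.05, fold change ≥ 1.5, and CPM ≥ 5 (loose) or ≥ 50 (strict) in at
least one group.  Embedding feature selection bins NTC-expressed genes into
10 equal-count expression bins (bin count is a package choice) and keeps
the top ceil(3%) of genes by fold change per bin per perturbation, ties
broken by higher NTC CPM then gene id, unioned across perturbations.

## Synthetic data: what it emulates and what it does not

The generator draws, per gene, α log-uniform and half-life log-uniform over
0.5–24 h; defaults give a few thousand UMIs per cell at ~300 genes,
matching the shallow depth of combinatorial-indexing screens.  Whole counts
are Poisson around s_c·α′/β (lognormal size factors; optional
negative-binomial overdispersion via a dispersion parameter), nascent
counts Binomial(whole, 1 − e^(−βt)).  Knockdown multiplies the target's α
by (1 − effect), default effect 0.7 (the screen-realistic ~70% median);
guide doublets carry two guides with effects applied independently (and
multiplicatively if they share a target).  Guide capture gives the true
guide(s) Poisson(~30) UMIs — split ~50/50 for doublets — plus ambient
single-UMI guides at a configurable rate.  Read-level simulation places one
50-nt read per molecule uniformly within its gene on 1–2 nuclear contigs
plus an intronless mitochondrial contig, plants per-T conversions on
nascent reads, SNP alternate alleles on all reads, uniform sequencing
errors, and a small intergenic read fraction, emitting SAM with MD/NM tags
and barcode/UMI in the read name.  The per-T conversion probability is
exposed as configuration (default 0.05), not asserted as biological truth.

Not emulated: fragment-length/GC/positional bias, cell-barcode sequencing
errors, transcriptome doublets, ambient mRNA, real exon–intron geometry,
bursty transcription.  Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions and realistic count
depths — not robustness to every artifact of real libraries.

## Problem sizes used by the test suite and acceptance script

Solver round trip on 10⁴ random (α, β, t) triples; rate recovery on 300
genes × 500 cells; caller characterization on ~120 cells over 25 genes
(~35k reads) plus a conversion-free control; null calibration on 200 genes
(100 perturbed vs 300 NTC cells, 500 iterations); KS screen on 50 null
perturbations of 120 cells each against 400 NTC cells over 1,200 genes; the
end-to-end toy screen on 2,000 cells × 300 genes with 20 guides (15
targeting 5 genes + 5 NTCs).  These sizes keep every experiment
deterministic and fast while leaving pseudobulks deep enough that the
estimators operate in their intended regime.

## Known limitations

- Rates are relative (count scale), not absolute molecule rates; only fold
  changes and distribution shifts are interpreted.
- The hard T>C threshold is not a statistical nascent-fraction estimator;
  genes with very low conversion content are systematically undercalled.
- Randomization-test p-values have resolution 2/(n_iter+1); n_iter = 500
  caps significance at ~0.004.
- The DEG engine is a rank-sum stand-in; its p-values are not exchangeable
  with GLM-based engines, though the post-filters are.
- With βt outside roughly [0.05, 12] the solver is dominated by sampling or
  floating-point limits and estimates should not be trusted even when
  formally valid.
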