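# Methods

This note records the statistical models behind each chromkit stage, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the choices made where the design was genuinely open.

## Reproducible-peak finalization

Peak callers produce replicate-specific call sets with q-values. A site is
considered reproducible when it is called at a stringent threshold
(q ≤ `q_strong`, default 0.05) in one replicate and at least at a relaxed
threshold (q ≤ `q_weak`, default 0.5) in every other replicate. The
two-threshold rule tolerates borderline significance in one replicate
without admitting sites supported by a single library. With more than two
replicates we generalize to "stringent in ≥ 1 replicate AND lenient in all
others", the natural extension of the pairwise wording. Overlap means ≥ 1
shared base on 0-based half-open coordinates (GTF and SAM are converted at
the I/O boundary). Surviving stringent calls that overlap each other are
merged into union intervals; a lenient-only partner supports survival but
contributes no interval of its own. Requesting finalization with a single
replicate is an explicit error rather than a silent pass-through.

Reference accessible-region sets merge the finalized peaks of all groups
into a non-overlapping union (bookended intervals merge; gap 0).

## Peak-to-gene assignment

Promoters are symmetric ±`promoter_halfwidth` (default 2000 bp) windows
around the TSS (gene start on '+', gene end on '−'), clipped at chromosome
edges. The symmetric reading is the standard promoter convention; a
one-sided window would be an equally defensible reading of "2 kb from the
TSS", so the halfwidth is config-exposed. A gene is bound iff its window
intersects ≥ 1 peak; peaks may bind several genes and no nearest-gene
tie-break is applied, because downstream statistics count genes, not peaks.

Distal elements are regions whose closest-point distance to the TSS lies in
[`distal_min`, `distal_max`] (defaults 2–50 kb) and which do not intersect
the promoter window, making promoter and distal assignments disjoint by
construction for the same region/gene pair. The anchor is the TSS for
consistency with promoter anchoring; `distal_anchor="gene_edge"` switches to
the nearest gene-body point.

## Differential testing

**TMM.** The trimmed mean of M-values corrects for library composition: the
reference sample is the one whose upper-quartile of library-scaled counts is
closest to the mean upper-quartile; for each sample, per-gene log-ratios
M = log2((x/N)/(x_r/N_r)) and abundances A are computed over genes positive
in both (prior count 0, as in the original method), doubly trimmed (30% on
M, 5% on A, rank-based with average ranks for ties), and combined as an
inverse-variance-weighted mean using the binomial delta-method variance
(N−x)/(Nx) + (N_r−x_r)/(N_r x_r). Factors are rescaled to geometric mean 1.
The implementation is checked against edgeR's `calcNormFactors` to 1e-6 on a
200-gene fixture (observed agreement ~1e-10). One degenerate regime is worth
knowing: if many genes have *byte-identical* counts in two samples, their
log-ratios form floating-point tie groups whose average ranks can all fall
outside the trim window, degenerating the factor to 1 — the reference
implementation behaves identically; realistic (noisy) counts do not trigger
it.

**Moderated test.** On log2-CPM (voom's transform, log2((x+0.5)/(N·f+1)·1e6),
prior count 0.5), each feature gets a two-group mean difference and a pooled
residual variance s²_g on d_g = n1+n2−2 df. A scaled-inverse-chi-square
prior (s²_0, d_0) is moment-matched on log variances: the excess variance of
log s²_g beyond the trigamma(d_g/2) sampling component determines d_0 (via a
Newton trigamma inverse); non-positive excess yields d_0 = ∞ (fully pooled
z-test, exposed through `prior_df` for testing the limit). The moderated
statistic uses the shrunk variance and t(d_0 + d_g). Voom's
observation-level precision weights are deliberately omitted: they require
the mean–variance lowess machinery and change results modestly at these
sample sizes; the moderated-t core is implemented in full.

**Multiple testing and calls.** FDR is Benjamini–Hochberg step-up (the
default of the originating toolchain; computed via statsmodels behind the
`bh_fdr` surface, with an O(m²) direct-definition oracle in the tests).
Calls are up/down at fdr < 0.05 and |log2fc| > log2(2), both strict, applied
to the model's fold-change estimate rather than a ratio of normalized means.

## Enrichment statistics

Binding–expression overlap uses the exact hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K, n), computed with log-gamma arithmetic
(stable to the double-precision floor near 1e-300); a normal-approximation
mode exists for comparison only. The universe defaults to all features in
the count matrix after expression filtering and is config-overridable —
p-values depend on this choice, so reports always print N. Empty
differential sets produce an explicit NA report, never a silent zero.
Fractions print as whole percents rounded half-up (888/1718 → 52).
Feature co-occurrence on 2×2 region tables uses Fisher's exact test
(two-sided, with the conditional-MLE odds ratio); the test suite checks it
against full table enumeration.

## ATAC fragment processing

Tn5 inserts as a dimer and duplicates 9 bp, so cut sites are corrected +4 bp
on the sense strand and −5 bp on the antisense strand; applied to both
fragment ends the fragment shrinks by 9 bp. The correction is applied once,
before fragment-size classification (the ordering is not dictated by the
protocol; applying it first keeps lengths consistent with corrected
coordinates). Fragments collapsing under the shift are dropped with a
counted warning.

Length classes default to the fragment-periodicity convention:
nucleosome-free ≤ 100 bp, mono 180–247, di 315–473, tri 558–615, everything
else "other"; bounds are config-exposed since conventions differ at the
margins (the NFR upper bound is inclusive at 100 so that a 100-bp fragment —
the canonical worked example — is nucleosome-free). Classification
partitions the input exactly.

NFR tracks cover the central `center_width` = 80 bp of each nucleosome-free
fragment, scaled by `scale_depth` / (2 × n_NFR) with `scale_depth` = 30 M
reads (paired-end: reads = 2 × fragments, switchable). The track integral is
therefore center_width × scale_depth / 2 for any input — a conservation law
the tests assert. Tracks are written as bedGraph, which is bit-checkable;
bigwig is a compiled container and out of scope.

## Spike-in-normalized promoter signal

Each sample's scale factor is `reference_constant` / spike-in read count,
with the constant defaulting to 10,000 — it cancels in between-sample
ratios, so its value is arbitrary. Spike-in species is recognized by the
`dm_` chromosome prefix, matching how combined-genome alignments are
distinguished in practice; spike-in fragments never count as signal.
Promoter signal is whole-fragment overlap counting (≥ 1 bp) against the
±2 kb TSS window, config-switchable to 5′-end counting. Multiplying one
sample's target and spike-in fragments by the same factor leaves its
normalized values unchanged (equivariance, asserted in tests).

## WGS off-target screen

**Site enumeration.** Every 20-nt window on either strand whose Hamming
distance to the protospacer is ≤ 4 substitutions and which is immediately
followed 3′ by an NGG PAM (IUPAC patterns supported). Ambiguous reference
bases count as mismatches. Bulged (gapped) alignments are not modelled —
the screen's mismatch budget is substitution-only. The vectorized scanner is
verified against an independently coded per-window re-scan.

**Small indels.** CIGAR I/D pileups keyed by (chrom, pos, ref_len, alt_len);
calls require ≥ 5× coverage and ≥ 5% allele fraction. Cross-sample
validation partitions edited-sample calls: shared with any control →
artifact; near the on-target locus → on-target; within `site_proximity`
(default 50 bp) of a predicted site → candidate off-target; everything else
goes to a review table — "manual confirmation" steps are emitted tables,
never silent drops. The coding-region/splice-site restriction is an
optional annotation mask, off by default; the generic screen is the useful
artifact.

**Long deletions.** The per-position p-value is the Poisson lower tail of
the edited sample's depth under λ = control median depth in the surrounding
1 kb tile (the original procedure names only thresholds, not the depth
model, so the null is documented and swappable). Flagged regions are maximal
runs of positions with p ≤ 1e-4, strictly longer than 50 bp, whose mean p is
below the threshold, minus regions equally improbable in a control (this
cross-filter also absorbs chromosome-end coverage taper). "Greater than
50 bp" and "more than a 10-bp overhang" are read as strict inequalities.

**Insertions.** Soft clips with overhang strictly > 10 bp define breakpoints
(trailing clip → right_clip at the aligned block's reference end; leading
clip → left_clip at the alignment start), clustered at exact positions.
Clusters matching a control cluster within the 5-bp window are removed as
non-specific; an insertion site is a right_clip/left_clip cluster pair
within 5 bp in an edited sample.

## Synthetic data: what it emulates, and what it does not

The generators produce every input class with ground truth: replicate peak
sets with a controlled reproducible fraction; negative-binomial counts
(variance = μ + μ²·disp) with gene means log-uniform on [20, 2000] so TMM
trimming has dynamic range to act on, a planted DE fraction (half up, half
down) and uniform [0.7, 1.3] library factors; ATAC fragment-length mixtures
over the four classes (defaults 45/35/12/5% with a 3% remainder, an
NFR-dominant mixture typical of a good library) with a binomial spike-in
fraction; CUT&RUN-like promoter-concentrated fragments with a per-sample
capture-efficiency factor that spike-in normalization must cancel; and
uniform-coverage WGS alignments (deterministic read tiling at the stated
depth) carrying planted CIGAR indels, coverage-free deletion spans, and
insertion breakpoints encoded as soft clips with no supplementary records.

Deliberately not modelled: sequencing errors, base qualities, PCR
duplicates, mappability structure, GC bias, realistic insert-size continua,
correlated biological replicates, and genuine binding–expression coupling
(peaks and DE genes are planted independently). Passing the recovery tests
therefore demonstrates that the *logic* of each stage is correct under its
own model — thresholds partition exactly, planted signal at the stated
effect sizes is recovered, nulls are calibrated — not that the pipeline is
robust to artifacts these simulations omit. Genes occupy a 6 kb grid (2 kb
bodies) so neighbouring ±2 kb promoter windows can never collide, which
makes promoter-level truth exact but removes the overlapping-gene ambiguity
real annotations carry.

Every generator is byte-reproducible under a fixed seed, and generated
FASTA/GTF/BED/BEDPE/SAM files re-parse to equal in-memory objects.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to exercise every
code path with stable statistics: 60–2000 gene genomes, 100-site replicate
peak sets, 3v3 count matrices of 2000 genes (10% DE at |log2fc| = 2,
dispersion 0.05; recovery ≥ 80% and observed false-discovery proportion
≤ 0.10 averaged over 20 seeds, with margin in practice), and a 1 Mb
off-target genome with 20 planted sites at 0–4 mismatches, a 200 bp
deletion, a 400 bp insertion and a 50% small indel at 30× depth. Exact-test
oracles run exhaustively (all hypergeometric configurations with N ≤ 25;
Fisher tables enumerated). Ties in TMM trimming use average ranks; BH
q-values are clipped to 1; the trigamma inverse iterates Newton steps to
1e-8 relative change; hypergeometric tails are computed via survival
functions rather than summation.

## Known limitations

- The universe behind published overlap p-values is rarely recoverable;
  chromkit prints N with every report but cannot reconstruct someone else's.
- The moderated test omits voom precision weights; at very low counts or
  highly unequal library sizes, limma-voom will differ modestly.
- The deletion-scan null is Poisson; overdispersed real coverage will
  inflate the per-position tail, so the threshold is conservative on clean
  simulations and should be recalibrated on real data.
- The off-target scanner does not model DNA/RNA bulges or alternative PAMs
  beyond IUPAC patterns.
- Single-end data: fragment-based stages (ATAC, CUT&RUN) assume paired-end
  fragments.
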