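# Methods

This note documents the models implemented in `ribodyn`, the defaults and
why they were chosen, the numerical details, and what validation on the
synthetic generator does and does not establish about real data.

## Coordinates and transcript model

All coordinates are 0-based, half-open, in transcript space; genome
mapping, splicing, and strand handling are out of scope (inputs are
assumed to be aligned to a transcriptome).  One representative transcript
per gene is kept: the isoform with the longest CDS, ties broken by total
transcript length and then lexicographic id so selection is
deterministic.  CDSs whose length is not a multiple of 3 are skipped with
a warning; an in-frame stop before the annotated end truncates codon
counting and flags the transcript, on the assumption that annotations are
normally clean.

## P-site offset calibration

Footprint 5′ ends sit a fixed, length-dependent distance upstream of the
ribosomal P-site, blurred by library chemistry (template-switch reverse
transcription adds untemplated 5′ nucleotides).  For each read length the
calibration scans candidate offsets 11–14 nt and scores the fraction of
reads whose inferred P-site lands in frame 0 of the CDS.  Two facts shape
the procedure:

1. **Periodicity identifies the offset only modulo 3.**  Candidates 11
   and 14 produce identical frames.  Candidates whose in-frame fractions
   lie within two binomial standard errors of the best are therefore
   treated as tied and resolved by the start-codon anchor: initiating
   ribosomes accumulate with the P-site on the AUG, so the candidate that
   places the most reads exactly on annotated start codons wins.  This is
   the classical two-step offset calling used by metagene-based tools.
2. **The in-frame fraction at the chosen offset is the QC fidelity**
   reported per length and globally (read-weighted).  A global fraction
   indistinguishable from the uniform baseline of 1/3 (within three
   standard errors plus a 2% margin) flags the model low-confidence.

Length classes with fewer than 200 reads (configurable) inherit the
read-weighted modal offset.  A learned-classifier backend could replace
this calibration where training data exist; the periodicity procedure is
the deterministic default because it needs no labels and reproduces the
same QC surface (3-nt periodicity, ~74% in-frame fraction on data of that
fidelity).

A-site codon index = P-site codon index + 1, the standard elongating
ribosome geometry.  Reads whose inferred site falls in a UTR are tallied
per region rather than entering CDS codon vectors, and total reads are
conserved across CDS vectors, UTR tallies, and out-of-bounds drops.

## Read filters

Alignments with multiplicity > 1, more than 2 mismatches, or length
< 15 nt are dropped, with per-filter tallies.  BED6 records carry no
mismatch field and are treated as 0-mismatch; SAM records use the NM/NH
tags and fall back to unique/0-mismatch with a warning when the tags are
absent.

## Quantification and time-course statistics

RPKM = count / (length/10³) / (library/10⁶).  TE = Ribo CDS RPKM / RNA
CDS RPKM, reported missing when RNA RPKM < 1 — an instability guard, since
a TE ratio over a near-zero denominator is noise.  The upstream ratio is
5′UTR footprint count / CDS footprint count; genes ranked by its change
get High/Low labels for the top/bottom 30%, ties broken by gene id.

Per-gene z-scores across timepoints use the sample (n−1) standard
deviation; constant profiles are excluded rather than z-scored.
Time-course clustering is gated by a per-gene one-way ANOVA across
timepoints with replicates kept separate (implemented vectorized and
verified against `scipy.stats.f_oneway`), BH-adjusted; genes with
q < 0.05 are averaged over replicates, z-scored, and clustered with Ward
linkage on Euclidean distance, cutting the tree into k = 6 groups.
Euclidean distance is the canonical pairing for Ward linkage.  Negative
binomial differential testing is intentionally out of scope; the ANOVA
path is the clustering route.

## uORF calling

Candidates are every (start codon ∈ {AUG, CUG, UUG, GUG} in the 5′UTR,
first in-frame stop ∈ {UAG, UGA, UAA}) pair; nested candidates are all
retained, and candidates whose stop lies at or beyond the CDS start are
kept but flagged `overlaps_cds`.  The test unit is the per-codon-position
P-site count within the candidate, phased to the candidate's own start: a
translated uORF concentrates P-sites in its frame 0.  Frame 0 is compared
against frames 1 and 2 with one-sided Wilcoxon rank-sum tests; the exact
null is used whenever each frame has ≤ 50 positions, because the
tie-corrected normal approximation was measured anti-conservative on
sparse, heavily tied counts (≈7.5% rejections at nominal 5% under a
frame-uniform null), whereas the exact null (which ignores ties) is
conservative — the right direction for FDR control.  The two p-values are
combined with Stouffer's equal-weight method, BH-corrected over the full
tested list, and candidates with FDR < 0.1 are called translated.
Candidates with fewer than 3 codons or fewer than 5 total P-site reads
are not tested (an evidence gate preventing vacuous tests).  Calling is
available per timepoint (replicates pooled) or pooled overall;
per-timepoint is the default, since uORF usage is expected to change
along the time course.

Truth-scoring on the simulator counts a call correct when it shares its
stop (and hence frame) with a planted uORF — nested starts over one stop
carry the same phased signal and are not separable — and excludes
CDS-overlapping candidates in the main ORF's frame, which genuinely read
main-CDS translation.

## Codon analytics

**RSCU.**  For codon j of amino acid i with pooled count x_ij over a
gene set and family size n_i, RSCU_ij = x_ij · n_i / Σ_j x_ij; the family
mean is 1 by construction and single-codon families are identically 1.
Pooled counting over the gene set is the default; a per-gene-mean variant
is provided.

**A-site occupancy.**  Per transcript, counts at interior codons
(excluding the first and last 30) are normalized by the mean interior
density; occupancies of one codon identity are averaged within the
transcript, then across transcripts.  Within-transcript averaging first
prevents long or deeply covered mRNAs from dominating the
transcriptome-wide mean.  Transcripts with fewer than 32 total CDS
footprints, or too short to have an interior window, are excluded.
Condition comparisons divide per-codon occupancies (later / earlier) and
test AU3 vs GC3 fold changes with a two-sided rank-sum test.

**Pause sites.**  Transcripts with ≥ 10 total footprints and ≥ 20
occupied codons get a zero-truncated negative binomial (ZTNB) fitted to
their nonzero codon counts: the NB(size r, mean μ) likelihood conditioned
on X ≥ 1, maximized over (log r, log μ) by Nelder–Mead from a
method-of-moments start.  Underdispersed samples (variance ≤ mean) fall
back to a zero-truncated Poisson with its closed-form MLE; MLE
non-convergence falls back to the moment estimate, flagged.  Each
occupied codon gets p = P(X ≥ x | X ≥ 1) under the fit; sites with raw
p < 0.05 are reported.  Raw (not multiplicity-adjusted) p-values are the
default, matching the per-transcript P < 0.05 convention of this analysis
style; a BH mode is available.

**CSC.**  The codon stabilization coefficient of codon j is the Pearson
correlation, across mRNAs with both a codon profile and a passing decay
fit (minimum 10), between the codon's within-mRNA frequency and the
mRNA's stability.  Half-life in hours is the default stability measure;
any monotone transform changes only the interpretation, not the sign
structure, and CSC is invariant to rescaling all half-lives.

## mRNA stability

Levels after transcription shutoff follow level(t) = level(0)·e^(−λt);
the fit regresses ln(level_t/level_0) on t by ordinary least squares and
reports λ = −slope, t½ = ln 2/λ, R², and the two-sided slope p.  Fits
pass when p < 0.05, R² > 0.5, and λ > 0.  The regression includes an
intercept by default — it absorbs normalization error in the t = 0
reference — with a through-origin mode for the strict ratio form.
Replicates are averaged per timepoint for the primary fit; per-replicate
fits feed a two-sample t-test on half-lives between conditions.
Nonpositive levels are dropped; fewer than three surviving points fails
the fit.  Library normalization across shutoff timepoints is total-count
by construction of the input (relative levels); spike-in normalization is
out of scope.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults matching the emulated study design: 500 genes; 5′UTR
lengths lognormal with median 150 nt, CDS lengths median 400 codons;
footprint lengths 26–32 nt with mode 29; per-length P-site offsets
11–14 nt; frame fidelity 0.74 (reads land at the true offset with that
probability, else ±1 nt); two replicates at timepoints 0/6/12/24 h;
300,000 footprints per sample; 30% of genes with a planted 5–15-codon
uORF (loading 0.5× the gene's CDS reads, CDS attenuated ×0.6) plus a 2%
frame-uniform UTR background; codon dwell times lognormal (σ = 0.15)
with an AU3-wide ×0.8 multiplier at 24 h; a start-codon initiation peak
(×5) as real libraries show, which is what makes offsets absolutely
identifiable; six archetypal time-course expression profiles over a 20%
null fraction; and decay over a 0/1/3 h shutoff chase with λ lognormal
(median 0.35 h⁻¹, i.e., t½ ≈ 2 h), three replicates, 10% multiplicative
noise.  The decay–codon coupling is parameterized so that positive β
makes AU3-rich mRNAs *more* stable (λ = base·e^(−β·(AU3 − mean AU3))),
matching the biology being emulated — AU3 codons stabilizing mRNAs — so
that CSC sign recovery is meaningful.  Everything derives from the config
seed (per-function salted child seeds), so identical configs give
byte-identical files.

What the generator does **not** model: sequence/ligation bias, UMI
structure, nucleotide-level error, isoform mixtures, initiation-site
heterogeneity beyond the single start peak, ramp effects beyond the
trimmed 30 codons, transcriptional compensation during the shutoff, or
correlated replicate noise.  Passing the truth-scored tests therefore
demonstrates that the estimators are correct and calibrated under the
assumed model, not that they are robust to every artifact of real
libraries.

## Problem sizes and observed behavior

Validation runs use 500-gene transcriptomes at 300k reads per sample —
large enough that per-codon and per-family statistics are well resolved,
small enough to iterate quickly.  At these sizes, observed behavior
(recomputed by the test suite and `scripts/acceptance.py`, not asserted
from memory): planted offsets are recovered exactly and the in-frame
fraction matches the planted fidelity within binomial error; uORF recall
is ≈ 0.9 with empirical FDR well under the 0.1 target — the misses are
planted uORFs on weakly expressed genes that fall under the 5-read
evidence gate, a power limit, not a calibration failure; occupancy
tracks the planted dwell map with Spearman ρ > 0.9; the ZTNB pause
caller's type-I error sits near its nominal 0.05 (slightly conservative,
as discrete tails force p-values past the threshold); and the no-decay
null passes the fit filters at well under 5%.

## Known limitations

- Offsets outside the 11–14 nt candidate window are not searched.
- The uORF test assumes P-site counts at different codon positions are
  exchangeable under the null; strong within-uORF coverage gradients
  would violate this.
- The pause model fits one ZTNB per transcript; genes with strongly
  position-dependent coverage (e.g., 5′ ramps inside the analysis
  window) inflate its dispersion estimate and lose power rather than
  gaining false positives.
- CSC inherits the composition constraint of codon frequencies (they sum
  to 1 per mRNA), so per-codon correlations are not independent.
- The condition t-test on half-lives treats per-replicate fits as
  independent samples; with 3 replicates its power is limited and it is
  reported per gene without multiplicity adjustment.
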