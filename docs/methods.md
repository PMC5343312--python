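# Methods

## Peak calling model

Probe intensities are modeled as strictly positive array signals. Quantile
normalization maps every sample column onto the per-rank column means;
within-column ties receive the mean of the tied ranks' reference values, so
normalization is monotone per column and exactly rank-preserving. ChIP and
input columns for one comparison are normalized **jointly** so their ranks
are comparable; because normalization is monotone, local enrichment survives
the shared marginal. (A consequence, surfaced by the property tests: with
tied values the per-column sorted multisets are no longer bitwise identical
— the tie rule trades that for stability. Continuous intensities are
effectively tie-free.)

The window test is probe-centric: for each probe, the window is its center
± 250 bp, and all ChIP values for probes in the window (replicates pooled as
independent observations) are compared to all input values likewise with a
one-sided Wilcoxon rank-sum test (enrichment direction). For pooled sizes
≤ 12 the p-value is computed by exhaustive enumeration over labelings with
midranks; beyond that, a normal approximation with midranks, tie-corrected
variance and continuity correction. Windows with fewer than two probes get
p = 1. Fold is mean(ChIP)/mean(input) over the window and the fold filter is
applied per window, before merging — the conservative reading of an
ambiguous convention. Windows passing p < 10⁻⁴ and fold ≥ 1.5 are merged
when their spans are within 500 bp; peak score is −log₁₀ of the best window
p. No multiple-testing correction is applied anywhere: the 10⁻⁴ raw
threshold *is* the filter, and the CLI help says so.

Sliding windows share probes, so neighboring tests are strongly correlated;
the null calibration criterion is therefore a bound (fraction of windows at
p < 10⁻⁴ at most 5×10⁻⁴ over ≥ 10⁵ windows), not an equality. In practice
the discrete rank statistic plus continuity correction make the empirical
rate ~0 at these window sizes (42 pooled values).

## Synthetic data model

The generator emulates the assay geometry: segments tiled by 50-mer probes
at 80 bp spacing, three biological replicates of ChIP and input per
condition, quadruplicate spots emitted pre-averaged (the analysis averages
quadruplicates before testing, so the simulator emits that level directly).

Intensity model: each probe has a lognormal baseline (probe affinity,
mean 10 log₂ units, sd 0.5 log₂) shared by *all* samples; every sample value
multiplies the baseline by an independent lognormal noise term
(sd 0.25 log₂) and, for ChIP samples over a planted peak of the matching TF
and condition, by the planted enrichment fold. This keeps log-ratios
Gaussian, makes ChIP and input exchangeable wherever nothing is planted
(the null experiment), and encodes the key power trade-off of the window
test: the rank-sum pools *different* probes, so the probe-affinity sd
competes with the enrichment fold. The defaults (fold 4 = +2 log₂ vs
baseline sd 0.5 + noise sd 0.25) put planted windows at near-complete
group separation, which is the regime a caller run at p < 10⁻⁴ with high
validation rates must have operated in. Planted peaks with condition
`basal` are constitutive (present in untreated **and** treated ChIP),
mirroring the observation that basally occupied sites remain occupied after
induction; `induced` plants appear only post-treatment.

What the simulator does **not** model: cross-hybridization, GC/dye bias,
repeat masking, spatial array artifacts, or biological covariance between
neighboring genes. Passing round-trip tests therefore demonstrates
correctness of the algorithms under the stated statistical assumptions, not
robustness to real-array pathologies.

Expression tables are generated per declared class label by sampling fold
changes and differential scores from ranges strictly inside the class
definitions (e.g. strong induction: fold ∈ [2.5, 8], score ∈ [16, 30];
quiet timepoints: |score| < 13), so generated tables re-classify to their
labels by construction — the round trip validates the classifier's rule
boundaries and the generator's margins jointly.

## Expression classification

A timepoint "calls" a gene when |differential score| ≥ 13; induction is
strong at fold ≥ 2, repression strong at fold ≤ 0.5. The earliest called
timepoint decides the class (a 6 h call = early; first call at 24/48 h =
late), so a gene induced early and repressed late takes its 6 h class.
"Late" requires *absence* of a 6 h call, not merely a later first strong
call. The differential score is treated as an opaque platform score —
recomputing it from bead-level data is out of scope, and the generator
emits it directly. The class vocabulary has no early-repressed label (no
such gene was observed in the assayed system); if one occurs, it is
assigned the repressed class of matching strength. resISG is only reachable
for genes flagged as known ISGs; potISG is an input flag (paralogy/promoter
evidence), never computed.

## Occupancy statistics

Distances are measured peak-center to TSS, strand-ignored, with the 5 kb
proximal boundary inclusive; nearest-gene ties break deterministically to
the smaller gene id. Pseudogenes are excluded from assignment by default
and included via a flag, because proximal fractions are reported both ways.
The region ledger links peaks (across TFs) that overlap by ≥ 1 bp or lie
within 500 bp — the same distance used for window merging; a flag restricts
linkage to strict overlap. The dual share of a TF is reported as the number
of dual *regions* over that TF's *peak* count, matching the arithmetic of
the reference decomposition the summary is validated against (a dual region
can contain two peaks of one TF).

Random controls are matched 1:1 in length to the real peaks (cycled if more
sites are requested), drawn per segment proportionally to the real
per-segment peak counts (largest-remainder rounding), and rejected if they
overlap any real peak; placement failure after bounded retries raises with
the segment name rather than silently relaxing the exclusion. TER cells
with zero random support but observed sites are flagged infinite — no
number is substituted. Binding profiles use 401 oriented 1 kb windows
(window 0 centered on the TSS, upstream negative); windows extending beyond
the gene's tiled segment are missing data and are excluded from the
denominator of the per-window mean.

## Motif scanning

PFM counts become probabilities via per-cell pseudo-counts (default 0.5,
exposed). The background is an add-1-smoothed k-th order Markov chain
(default k = 3) trained on each sequence concatenated with its reverse
complement, so the model is strand-balanced by construction. A window's
background probability conditions each base on its k-base left context
within the full sequence; where fewer than k context bases exist the
order-0 composition is used for those positions. Minus-strand windows are
scored on the minus-strand text conditioned on the minus-strand left
context (the reverse complement of the forward right context) under the
same shared model — this choice makes scanning exactly strand-symmetric at
every order, which a forward-text denominator would only approximate.
Windows containing N are skipped and tallied. Hits require LR strictly
greater than the cutoff (default 500).

The peak-vs-random frequency comparison is a two-sided two-proportion test:
Fisher's exact test up to a pooled size of 10⁴, a pooled z-test beyond;
significance is marked at p < 5×10⁻⁵. Sharpness matters for planted-motif
recovery: with consensus probability 0.97 per column a one-mismatch window
of a 10-mer still clears LR 500 on a uniform background, at 0.999 it does
not; the no-off-target guarantee in the tests therefore uses the sharper
matrix, and the default scanning matrices accept near-consensus matches by
design.

## SNP scoring

Allele contexts are ±50 bp around the SNP, truncated *symmetrically* at
segment edges (effective flank = min(50, distance to either edge)) so the
SNP stays centered. Per allele, the score is the maximum LR over motif
windows (both strands) covering the SNP coordinate; if no window clears the
LR cutoff the allele is NULL with score exactly 0. Fold change is
variant/reference, undefined for a NULL reference; verdicts: NULL→scored is
a gain and scored→NULL a loss outright, otherwise the symmetric 1.5× cutoff
decides (≥ 1.5 gain, ≤ 1/1.5 loss, else neutral). Either allele clearing
the cutoff suffices to keep a SNP in the screen (NULL→0 semantics). The
screen filters SNPs to those inside binding regions, then to those
overlapping a motif hit, reporting counts at every stage; swapping
ref/alt provably inverts the fold change and the gain/loss verdict.

## Problem sizes and numerical choices

The validation suite uses a peak-free experiment of ~101,000 windows for
null calibration, 20 seeds × 4 planted peaks for recovery, 20 seeds × 9
labels for the expression round trip, and 5 seeds × 4 planted variants for
the SNP screen — sizes at which every stochastic criterion is stable across
seeds while the whole suite runs in well under a minute per module. The
benchmark ledgers in `isgscape.benchmarks` are fully synthetic
constructions whose *composition* (230 regions splitting 36/140/54, a
5 Mb segment with 56:16 sites, a 16 Mb / 375-gene table) is fixed so that
the summary operations can be checked against hand-computable expectations;
every reported number is still produced by running the operations.

Degenerate inputs: empty peak sets produce empty ledgers and zeroed
summaries; a segment-less chromosome flags peaks unassigned with infinite
distance; zero rank-sum variance (all values tied) yields p = 1; infinite
TER and undefined ratios are flagged, never imputed.

## Known limitations

- The caller's power model assumes within-window exchangeability of probes;
  strong probe-affinity gradients would reduce power below the simulated
  regime.
- The background Markov model is global per run; locally biased composition
  (CpG islands) is not modeled separately.
- The two-proportion z fallback above pooled size 10⁴ is asymptotic.
- Sharing classes consume per-cell-type induction calls; harmonizing call
  thresholds across heterogeneous expression platforms is the caller's
  responsibility.
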