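# isgscape

Analysis of STAT1 and IRF1 enhancer occupancy around interferon-γ stimulated
genes (ISGs), built for regulatory genomicists who want the complete chain —
from tiling-array probe intensities to co-occupancy statistics and
regulatory-SNP verdicts — as a tested, reusable Python library and CLI.

IFNγ signaling activates STAT1 homodimers (binding GAS motifs) and induces
IRF1 (binding IRF-E/ISRE motifs). Whether these factors act alone or together
at promoter-proximal and remote enhancers determines which ISGs respond in a
given cell type. `isgscape` implements the computational pipeline for that
question:

- **Peak calling** — replicate ChIP and input probe intensities are quantile
  normalized, then each probe is tested with a one-sided Wilcoxon rank-sum
  statistic over a 500 bp sliding window (ChIP vs input values pooled across
  probes and replicates). Windows with fold ≥ 1.5 and p < 10⁻⁴ are merged
  (gap ≤ 500 bp) into peaks. Exact enumeration is used for pooled sizes ≤ 12,
  a tie-corrected normal approximation beyond.
- **Expression classes** — each gene's 6/24/48 h time course is classified by
  the differential-score (±13) and fold (2× / 0.5×) rules into
  es/ls/ew/lw-indISG, resISG, ls/lw-IRG, potISG or other; cross-cell-type
  sharing is Ex (1), pSh (2–4) or Ub (5–7 cell types).
- **Occupancy statistics** — nearest-TSS assignment with the inclusive 5 kb
  proximal rule; an isolated-STAT1 / isolated-IRF1 / dual region ledger
  (peaks linked when overlapping or within 500 bp); matched random-site
  controls (length- and segment-frequency matched, peak-excluding); the TF
  enrichment ratio TER = observed% / random% per gene class × location with
  the TER > 2 flag; TSS ± 200 kb binding profiles in 1 kb windows with
  missing (not zero) values beyond tiled segments; per-segment summaries.
- **Motif scanning** — JASPAR PFMs with pseudo-counts are scored as
  likelihood ratios LR = P_pwm(w) / P_bg(w) against a 3rd-order Markov
  background trained on both strands; hits require LR > 500. Peak vs random
  motif frequencies are compared with a two-sided two-proportion test.
- **SNP effects** — ±50 bp allele contexts are scored per allele by the best
  motif window overlapping the SNP (zero = "NULL" when nothing clears the LR
  cutoff); the variant/reference fold change with a symmetric 1.5× cutoff
  yields gain / loss / neutral / null_both verdicts.
- **Synthetic studies** — a generator emulates the assay end to end (80 bp
  probe spacing, 50-mers, 3 replicates × ChIP/input × untreated/treated,
  planted enrichment, motifs and SNPs, class-consistent expression tables)
  with full ground truth, so every stage is validated against known answers.

## Worked example

```sh
isgscape run --seed 1 --out demo_out
```

simulates a scaled-down study (eleven ISG-rich segments with planted STAT1
and IRF1 enrichment), calls peaks per TF and condition, and writes the report
bundle. The run prints, among other output (`demo_out/report.txt`):

```
peak counts:
  IRF1_basal: 1
  IRF1_induced: 9
  STAT1_basal: 0
  STAT1_induced: 4

binding regions: 13
  isolated-STAT1: 4
  isolated-IRF1: 9
  dual: 0

motif IRF1: 69% of peaks vs 0% of random regions (p=0.000458)

SNP screen: {"input": 15, "in_peaks": 10, "in_motifs": 5, "scored": 5, "affected": 5}
```

Reading: all 13 planted induced enrichment regions were recovered (9 IRF1,
4 STAT1); the one constitutive IRF1 plant is also found in the untreated
condition. 69% of called binding regions contain an IRF-E motif versus none
of the matched random controls, and all 5 SNPs planted inside motif
instances are scored as affecting binding (the `affected` count), while SNPs
planted inside peaks but outside motifs are dropped at the `in_motifs`
filter stage. The same stages are available individually
(`isgscape simulate/callpeaks/classify-genes/occupancy/motifs/snps`) and as
library functions.

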