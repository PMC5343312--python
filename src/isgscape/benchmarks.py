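"""Synthetic benchmark datasets with known composition.

These construct small, fully synthetic stand-in datasets whose composition
matches the reference decompositions the summary statistics are validated
against: a 230-region binding ledger splitting 36/140/54 into isolated-STAT1 /
isolated-IRF1 / dual (92 STAT1 and 196 IRF1 peaks in total), an MHC-like
segment with a 3.5:1 IRF1:STAT1 excess and pseudogene-driven proximality, a
16 Mb gene table with a 25% known-ISG fraction, and basal/induced peak counts.
Every quantity derived from them is computed by the package's own operations;
only the composition is fixed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPACING = 20_000  # distance between benchmark regions, far beyond linkage


def ledger_peaks() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak sets realising the benchmark co-occupancy decomposition:
    36 isolated STAT1 peaks, 140 isolated IRF1 peaks and 54 dual regions
    (52 with one peak of each TF, 2 with two of each), i.e. 92 STAT1 and
    196 IRF1 peaks over 230 discrete regions."""
    stat1, irf1 = [], []
    pos = 0

    def advance():
        nonlocal pos
        pos += SPACING
        return pos

    for _ in range(36):
        x = advance()
        stat1.append(("chrB", x, x + 400))
    for _ in range(140):
        x = advance()
        irf1.append(("chrB", x, x + 400))
    for _ in range(52):  # dual regions: one overlapping pair
        x = advance()
        stat1.append(("chrB", x, x + 400))
        irf1.append(("chrB", x + 200, x + 600))
    for _ in range(2):  # dual regions carrying two peaks of each TF
        x = advance()
        stat1.append(("chrB", x, x + 300))
        irf1.append(("chrB", x + 200, x + 500))
        stat1.append(("chrB", x + 400, x + 700))
        irf1.append(("chrB", x + 600, x + 900))
    cols = ["chrom", "start", "end"]
    return (
        pd.DataFrame(stat1, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
        pd.DataFrame(irf1, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
    )


def mhc_segment() -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """An MHC-class-I-like 5 Mb segment: 56 IRF1 vs 16 STAT1 sites, with 26
    IRF1 sites proximal to genes, 17 proximal only to pseudogenes and 13
    remote."""
    genes = []
    for i in range(26):
        genes.append((f"G{i:02d}", "mhc", 100_000 + 60_000 * i, "+", "other", False, False))
    for i in range(17):
        genes.append((f"PG{i:02d}", "mhc", 3_000_000 + 60_000 * i, "+", "other", False, True))
    genes = pd.DataFrame(
        genes,
        columns=["gene_id", "chrom", "tss", "strand", "class_label", "known_isg",
                 "is_pseudogene"],
    )
    rows = []
    for i in range(26):  # proximal to real genes
        t = 100_000 + 60_000 * i
        rows.append(("mhc", t - 100, t + 100, "IRF1"))
    for i in range(17):  # proximal only to pseudogenes
        t = 3_000_000 + 60_000 * i
        rows.append(("mhc", t - 100, t + 100, "IRF1"))
    for i in range(13):  # remote
        rows.append(("mhc", 4_400_000 + 30_000 * i, 4_400_000 + 30_000 * i + 200, "IRF1"))
    for i in range(16):
        rows.append(("mhc", 2_000_000 + 30_000 * i, 2_000_000 + 30_000 * i + 200, "STAT1"))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    return peaks, genes, {"mhc": 5_000_000}


def study_gene_table() -> tuple[pd.DataFrame, dict[str, int]]:
    """A 16 Mb study-wide gene table: 375 annotated genes of which 95 are
    known ISGs and 31 are early-strong induced."""
    rows = []
    for i in range(375):
        label = "es-indISG" if i < 31 else ("resISG" if i < 95 else "other")
        rows.append((f"G{i:03d}", "study", 10_000 + 42_000 * i, "+", label, i < 95, False))
    genes = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "tss", "strand", "class_label", "known_isg",
                 "is_pseudogene"],
    )
    return genes, {"study": 16_000_000}


def condition_peaks() -> pd.DataFrame:
    """Benchmark basal/induced peak counts: 2 basal + 92 induced STAT1 and
    28 basal + 196 induced IRF1."""
    rows = []
    counts = {
        ("STAT1", "basal"): 2,
        ("STAT1", "induced"): 92,
        ("IRF1", "basal"): 28,
        ("IRF1", "induced"): 196,
    }
    pos = 0
    for (tf, cond), n in counts.items():
        for _ in range(n):
            pos += SPACING
            rows.append(("chrC", pos, pos + 400, tf, cond))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf", "condition"])
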