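"""SNP effects on STAT1/IRF1 binding motifs.

For each SNP inside a binding region, the ±50 bp context is extracted for the
reference and variant allele, every motif window overlapping the SNP is
scored with the PWM likelihood ratio, and the best overlapping window per
allele gives that allele's likelihood score (zero — "NULL" — when no window
clears the LR cutoff). The variant/reference fold change with a symmetric
1.5-fold cutoff yields a gain / loss / neutral / null_both verdict; an allele
going from NULL to scored (or back) is a gain (loss) outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import LR_MIN, MarkovBackground, PwmModel, scan

SNP_FOLD_CUTOFF = 1.5
CONTEXT_FLANK = 50


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"{self.snp_id}: alleles must be single ACGT bases")
        if self.ref == self.alt:
            raise ValueError(f"{self.snp_id}: ref equals alt")


def extract_context(
    snp: SnpRecord, genome: dict[str, str], flank: int = CONTEXT_FLANK
) -> tuple[str, str, int]:
    """Return (ref_seq, var_seq, snp_offset): two sequences differing only at
    the center base. Near a segment edge the flank is truncated symmetrically
    (effective flank = min(flank, distance to either edge)) so the SNP stays
    centered on its true coordinate."""
    seq = genome[snp.chrom]
    if not 0 <= snp.pos < len(seq):
        raise ValueError(f"{snp.snp_id}: position outside segment {snp.chrom}")
    eff = min(flank, snp.pos, len(seq) - 1 - snp.pos)
    lo, hi = snp.pos - eff, snp.pos + eff + 1
    window = seq[lo:hi]
    if window[eff].upper() != snp.ref:
        warnings.warn(
            f"{snp.snp_id}: genome base {window[eff]!r} differs from declared "
            f"ref {snp.ref!r}; proceeding with the declared ref",
            stacklevel=2,
        )
    ref_seq = window[:eff] + snp.ref + window[eff + 1 :]
    var_seq = window[:eff] + snp.alt + window[eff + 1 :]
    return ref_seq, var_seq, eff


def _best_overlapping_lr(
    seq: str,
    snp_offset: int,
    pwm: PwmModel,
    background: MarkovBackground,
    lr_min: float,
) -> float:
    """Max LR among motif windows covering the SNP offset; 0 ("NULL") when no
    overlapping window clears lr_min."""
    L = pwm.length
    hits = scan(seq, pwm, background, lr_min=lr_min, both_strands=True)
    if hits.empty:
        return 0.0
    cover = (hits["start"] <= snp_offset) & (snp_offset < hits["start"] + L)
    if not cover.any():
        return 0.0
    return float(hits.loc[cover, "lr"].max())


def score_allele_pair(
    ref_seq: str,
    var_seq: str,
    snp_offset: int,
    pwm: PwmModel,
    background: MarkovBackground,
    lr_min: float = LR_MIN,
    fold_cutoff: float = SNP_FOLD_CUTOFF,
) -> dict:
    """Score one SNP against one motif: per-allele likelihood scores, fold
    change (variant/reference; undefined when the reference is NULL) and the
    verdict."""
    if len(ref_seq) != len(var_seq):
        raise ValueError("ref and variant sequences must be aligned")
    L = pwm.length
    if len(ref_seq) < L or not (
        max(0, snp_offset - L + 1) <= min(snp_offset, len(ref_seq) - L)
    ):
        raise ValueError(
            f"context too short for motif {pwm.name} (length {L}): no window "
            "can overlap the SNP"
        )
    lr_ref = _best_overlapping_lr(ref_seq, snp_offset, pwm, background, lr_min)
    lr_var = _best_overlapping_lr(var_seq, snp_offset, pwm, background, lr_min)

    if lr_ref > 0:
        fold = lr_var / lr_ref
    else:
        fold = np.nan  # undefined: reference allele is NULL

    if lr_ref == 0 and lr_var == 0:
        verdict = "null_both"
    elif lr_ref == 0:
        verdict = "gain"
    elif lr_var == 0:
        verdict = "loss"
    elif fold >= fold_cutoff:
        verdict = "gain"
    elif fold <= 1.0 / fold_cutoff:
        verdict = "loss"
    else:
        verdict = "neutral"
    return {
        "motif": pwm.name,
        "lr_ref": lr_ref,
        "lr_var": lr_var,
        "fold_change": fold,
        "verdict": verdict,
    }


def screen_snps(
    snps: list[SnpRecord],
    peaks: pd.DataFrame,
    motif_hits: pd.DataFrame,
    genome: dict[str, str],
    pwms: dict[str, PwmModel],
    background: MarkovBackground,
    flank: int = CONTEXT_FLANK,
    lr_min: float = LR_MIN,
    fold_cutoff: float = SNP_FOLD_CUTOFF,
) -> tuple[pd.DataFrame, dict]:
    """Pipeline filter: SNPs inside binding regions -> SNPs overlapping a
    motif hit -> scored allele effects. Returns the effect table and the
    per-stage counts."""
    counts = {"input": len(snps)}

    def in_any(df, chrom, pos, width_from=None):
        sel = df[df["chrom"] == chrom]
        if width_from is not None:
            ends = sel["start"] + width_from
        else:
            ends = sel["end"]
        return bool(((sel["start"] <= pos) & (pos < ends)).any())

    in_peaks = [s for s in snps if in_any(peaks, s.chrom, s.pos)]
    counts["in_peaks"] = len(in_peaks)

    motif_lengths = {name: p.length for name, p in pwms.items()}
    overlapping: list[tuple[SnpRecord, str]] = []
    for s in in_peaks:
        sel = motif_hits[motif_hits["chrom"] == s.chrom]
        for name, L in motif_lengths.items():
            msel = sel[sel["motif"] == name]
            if ((msel["start"] <= s.pos) & (s.pos < msel["start"] + L)).any():
                overlapping.append((s, name))
    counts["in_motifs"] = len({s.snp_id for s, _ in overlapping})

    rows = []
    for s, name in overlapping:
        ref_seq, var_seq, offset = extract_context(s, genome, flank=flank)
        eff = score_allele_pair(
            ref_seq,
            var_seq,
            offset,
            pwms[name],
            background,
            lr_min=lr_min,
            fold_cutoff=fold_cutoff,
        )
        rows.append(
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                **eff,
            }
        )
    effects = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "motif",
            "lr_ref",
            "lr_var",
            "fold_change",
            "verdict",
        ],
    )
    counts["scored"] = len(effects)
    counts["affected"] = (
        int((effects["verdict"].isin(["gain", "loss"])).sum()) if len(effects) else 0
    )
    return effects, counts
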