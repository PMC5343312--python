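"""Readers and writers for the plain-text interchange formats.

FASTA via Bio.SeqIO, BED6 / TSV tables via pandas, a minimal VCF dialect
(CHROM POS ID REF ALT) for SNP records, and the intensity/probe-map TSV
dialect emitted by the synthetic generator (sample columns named
``{tf|input}_{condition}_rep{i}``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import IntensityMatrix
from .snps import SnpRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(df: pd.DataFrame, path, name_col=None, score_col=None, strand_col=None) -> None:
    """Write intervals as BED6; missing name/score/strand become ./0/."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[name_col] if name_col else ".",
            "score": df[score_col] if score_col else 0,
            "strand": df[strand_col] if strand_col else ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def peak_bed_frame(peaks: pd.DataFrame) -> pd.DataFrame:
    """Peaks as a BED6-ready frame: name = {tf}_{condition}_{k}, score =
    round(10 * -log10 p), capped at 1000."""
    out = peaks.copy().reset_index(drop=True)
    out["name"] = [
        f"{r.tf}_{r.condition}_{k}" for k, r in enumerate(out.itertuples(index=False))
    ]
    score = np.minimum(np.round(10.0 * out["score"].replace(np.inf, 100.0)), 1000)
    out["bed_score"] = score.astype(int)
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def write_intensity_tsv(matrix: IntensityMatrix, path) -> None:
    write_tsv(matrix.to_frame(), path)


def read_intensity_tsv(path, normalized: bool = False) -> IntensityMatrix:
    df = read_tsv(path)
    probe_cols = ["probe_id", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in probe_cols]
    return IntensityMatrix(
        probes=df[probe_cols],
        values=df[samples].to_numpy(dtype=float),
        samples=samples,
        normalized=normalized,
    )


VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\n"


def write_vcf(snps: list[SnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref}\t{s.alt}\n")


def read_vcf(path) -> list[SnpRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, snp_id, ref, alt = line.rstrip("\n").split("\t")[:5]
            out.append(
                SnpRecord(
                    snp_id=snp_id, chrom=chrom, pos=int(pos) - 1, ref=ref, alt=alt
                )
            )
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
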