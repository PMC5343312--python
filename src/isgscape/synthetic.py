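"""Synthetic inputs with known ground truth.

Emulates the data the pipeline consumes: multi-Mb genomic segments tiled by
50-mer probes at 80 bp median spacing, three biological replicates of ChIP and
input intensities per condition with planted enrichment regions, planted
STAT1/IRF1 motif instances and SNPs, gene annotation, and per-gene expression
time courses (6/24/48 h) built to satisfy the response-class rules.

Quadruplicate spots are emitted pre-averaged (one value per probe per
replicate), matching an analysis that averages quadruplicates before testing.
The noise model is multiplicative lognormal per probe per replicate; a
per-probe lognormal baseline (probe affinity) is shared by every sample so
that ChIP and input are exchangeable wherever nothing is planted.

All generators are pure functions of (spec, seed): per-artifact random streams
are spawned deterministically from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import IntensityMatrix

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: concrete consensus instances used when planting motifs (GAS for STAT1,
#: IRF-E for IRF1)
DEFAULT_MOTIF_INSTANCES = {
    "STAT1": "TTCCGGGAA",
    "IRF1": "TTTCACTTTC",
}

GENE_CLASS_VOCAB = (
    "es-indISG",
    "ls-indISG",
    "ew-indISG",
    "lw-indISG",
    "resISG",
    "ls-IRG",
    "lw-IRG",
    "potISG",
    "other",
)

TIMEPOINTS_H = (6, 24, 48)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")


@dataclass(frozen=True)
class PlantedPeak:
    """Ground-truth enrichment region (0-based half-open)."""

    segment: str
    start: int
    end: int
    enrichment_fold: float
    tf: str = "STAT1"  # STAT1 | IRF1 | both
    condition: str = "induced"  # basal (constitutive) | induced

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("planted peak: end must exceed start")
        if self.enrichment_fold < 1:
            raise ValueError("planted peak: enrichment_fold must be >= 1")
        if self.tf not in ("STAT1", "IRF1", "both"):
            raise ValueError(f"planted peak: unknown tf {self.tf!r}")
        if self.condition not in ("basal", "induced"):
            raise ValueError(f"planted peak: unknown condition {self.condition!r}")


@dataclass(frozen=True)
class PlantedMotif:
    segment: str
    position: int
    strand: str = "+"
    name: str = "IRF1"
    sequence: str | None = None  # defaults to the named consensus instance

    def instance(self) -> str:
        seq = self.sequence or DEFAULT_MOTIF_INSTANCES[self.name]
        return seq if self.strand == "+" else reverse_complement(seq)


@dataclass(frozen=True)
class PlantedSnp:
    segment: str
    position: int
    ref: str
    alt: str
    snp_id: str = ""


@dataclass(frozen=True)
class GeneTemplate:
    gene_id: str
    segment: str
    tss: int
    strand: str
    class_label: str
    known_isg: bool = False
    pot_isg: bool = False
    is_pseudogene: bool = False


@dataclass
class SyntheticSpec:
    """Full description of one synthetic study."""

    seed: int
    segments: list[Segment]
    probe_spacing_bp: int = 80
    probe_len_bp: int = 50
    n_replicates: int = 3
    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 0.5
    gene_templates: list[GeneTemplate] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def segment_lengths(self) -> dict[str, int]:
        return {s.name: s.length for s in self.segments}

    def validate(self) -> None:
        if self.probe_spacing_bp < 1:
            raise ValueError("probe_spacing_bp must be >= 1")
        if self.probe_len_bp < 1:
            raise ValueError("probe_len_bp must be >= 1")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        lengths = self.segment_lengths()
        if len(lengths) != len(self.segments):
            raise ValueError("duplicate segment names")
        for pk in self.planted_peaks:
            if pk.segment not in lengths:
                raise ValueError(f"planted peak in unknown segment {pk.segment!r}")
            if pk.end > lengths[pk.segment]:
                raise ValueError(f"planted peak exceeds segment {pk.segment!r}")
        for m in self.planted_motifs:
            if m.segment not in lengths:
                raise ValueError(f"planted motif in unknown segment {m.segment!r}")
            if m.position < 0 or m.position + len(m.instance()) > lengths[m.segment]:
                raise ValueError(f"planted motif outside segment {m.segment!r}")
        for s in self.planted_snps:
            if s.segment not in lengths or not 0 <= s.position < lengths[s.segment]:
                raise ValueError(f"planted SNP outside segment {s.segment!r}")
        for g in self.gene_templates:
            if g.segment not in lengths or not 0 <= g.tss < lengths[g.segment]:
                raise ValueError(f"gene {g.gene_id}: TSS outside segment")
            if g.class_label not in GENE_CLASS_VOCAB:
                raise ValueError(
                    f"gene {g.gene_id}: class {g.class_label!r} not in vocabulary"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-artifact random stream derived from the seed."""
        child = np.random.SeedSequence(
            [self.seed, int.from_bytes(stream.encode(), "little") % (2**31)]
        )
        return np.random.default_rng(child)


def generate_genome(spec: SyntheticSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """i.i.d. uniform A/C/G/T background per segment with planted motif
    instances spliced in; returns (genome, gene annotation)."""
    rng = spec.rng("genome")
    genome: dict[str, str] = {}
    for seg in spec.segments:
        arr = rng.integers(0, 4, size=seg.length)
        genome[seg.name] = "".join(BASES[b] for b in arr)

    occupied: dict[str, list[tuple[int, int, PlantedMotif]]] = {}
    for m in spec.planted_motifs:
        inst = m.instance()
        span = (m.position, m.position + len(inst))
        for s, e, prev in occupied.get(m.segment, []):
            if span[0] < e and s < span[1]:
                raise ValueError(
                    f"overlapping planted motifs in {m.segment}: "
                    f"{prev.name}@{prev.position} and {m.name}@{m.position}"
                )
        occupied.setdefault(m.segment, []).append((span[0], span[1], m))
        seq = genome[m.segment]
        genome[m.segment] = seq[: span[0]] + inst + seq[span[1] :]

    ann = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.segment,
                "tss": g.tss,
                "strand": g.strand,
                "class_label": g.class_label,
                "known_isg": g.known_isg,
                "pot_isg": g.pot_isg,
                "is_pseudogene": g.is_pseudogene,
            }
            for g in spec.gene_templates
        ],
        columns=[
            "gene_id",
            "chrom",
            "tss",
            "strand",
            "class_label",
            "known_isg",
            "pot_isg",
            "is_pseudogene",
        ],
    )
    return genome, ann


def probe_map(spec: SyntheticSpec) -> pd.DataFrame:
    """Tile each segment with probes at the declared spacing."""
    rows = []
    for seg in spec.segments:
        if seg.length < spec.probe_len_bp:
            raise ValueError(
                f"segment {seg.name}: shorter than one probe "
                f"({seg.length} < {spec.probe_len_bp} bp)"
            )
        starts = np.arange(0, seg.length - spec.probe_len_bp + 1, spec.probe_spacing_bp)
        for i, s in enumerate(starts):
            rows.append(
                {
                    "probe_id": f"{seg.name}_p{i:06d}",
                    "chrom": seg.name,
                    "start": int(s),
                    "end": int(s + spec.probe_len_bp),
                }
            )
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


CONDITIONS = ("basal", "induced")
TFS = ("STAT1", "IRF1")


@dataclass
class TilingExperiment:
    """Synthetic ChIP-chip experiment with its ground truth."""

    probes: pd.DataFrame
    chip: dict[tuple[str, str], IntensityMatrix]  # (tf, condition) -> matrix
    input_: dict[str, IntensityMatrix]  # condition -> matrix
    truth: pd.DataFrame  # planted peaks: chrom start end tf condition fold


def _enrichment_folds(
    spec: SyntheticSpec, probes: pd.DataFrame, tf: str, condition: str
) -> np.ndarray:
    """Per-probe enrichment factor for one ChIP track. Basal plants are
    constitutive (present in both conditions); induced plants appear only in
    the induced ChIP. Overlapping plants multiply."""
    fold = np.ones(len(probes))
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    for pk in spec.planted_peaks:
        if pk.tf not in (tf, "both"):
            continue
        if pk.condition == "induced" and condition != "induced":
            continue
        mask = (chroms == pk.segment) & (starts < pk.end) & (ends > pk.start)
        fold[mask] *= pk.enrichment_fold
    return fold


def generate_tiling_experiment(spec: SyntheticSpec) -> TilingExperiment:
    """Intensity matrices for every (TF, condition) ChIP track and per-condition
    input, with a shared per-probe lognormal baseline and independent
    multiplicative lognormal noise per replicate."""
    probes = probe_map(spec)
    n = len(probes)
    rng = spec.rng("tiling")
    baseline = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n)

    def draw(samples_prefix: str, fold: np.ndarray) -> tuple[np.ndarray, list[str]]:
        noise = 2.0 ** rng.normal(0.0, spec.noise_sd_log2, (n, spec.n_replicates))
        vals = baseline[:, None] * fold[:, None] * noise
        names = [f"{samples_prefix}_rep{i + 1}" for i in range(spec.n_replicates)]
        return vals, names

    chip: dict[tuple[str, str], IntensityMatrix] = {}
    input_: dict[str, IntensityMatrix] = {}
    for condition in CONDITIONS:
        for tf in TFS:
            fold = _enrichment_folds(spec, probes, tf, condition)
            vals, names = draw(f"{tf}_{condition}", fold)
            chip[(tf, condition)] = IntensityMatrix(probes.copy(), vals, names)
        vals, names = draw(f"input_{condition}", np.ones(n))
        input_[condition] = IntensityMatrix(probes.copy(), vals, names)

    truth_rows = []
    for pk in spec.planted_peaks:
        tfs = TFS if pk.tf == "both" else (pk.tf,)
        conds = CONDITIONS if pk.condition == "basal" else ("induced",)
        for tf in tfs:
            for condition in conds:
                truth_rows.append(
                    {
                        "chrom": pk.segment,
                        "start": pk.start,
                        "end": pk.end,
                        "tf": tf,
                        "condition": condition,
                        "fold": pk.enrichment_fold,
                    }
                )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "tf", "condition", "fold"]
    )
    return TilingExperiment(probes=probes, chip=chip, input_=input_, truth=truth)


# --- expression time courses -------------------------------------------------

# (fold_change range, diff_score range) for a timepoint that carries the call
_CALL_RANGES = {
    "strong_induced": ((2.5, 8.0), (16.0, 30.0)),
    "weak_induced": ((1.2, 1.9), (14.0, 25.0)),
    "strong_repressed": ((0.2, 0.45), (-30.0, -16.0)),
    "weak_repressed": ((0.55, 0.9), (-25.0, -14.0)),
}
# a timepoint with no call: |diff| < 13 and unremarkable fold
_QUIET = ((0.85, 1.25), (-8.0, 8.0))


def _draw(rng: np.random.Generator, ranges) -> tuple[float, float]:
    (flo, fhi), (dlo, dhi) = ranges
    return float(rng.uniform(flo, fhi)), float(rng.uniform(dlo, dhi))


def generate_expression_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene fold change and differential score at 6/24/48 h whose values
    satisfy the class-definition rules for the declared label (round-trip
    property with the classifier)."""
    rng = spec.rng("expression")
    rows = []
    for g in spec.gene_templates:
        label = g.class_label
        if label not in GENE_CLASS_VOCAB:
            raise ValueError(f"gene {g.gene_id}: class {label!r} not in vocabulary")
        per_tp: dict[int, tuple[float, float]] = {}
        if label in ("resISG", "potISG", "other"):
            for tp in TIMEPOINTS_H:
                per_tp[tp] = _draw(rng, _QUIET)
        else:
            kind = {
                "es-indISG": ("strong_induced", 6),
                "ls-indISG": ("strong_induced", 24),
                "ew-indISG": ("weak_induced", 6),
                "lw-indISG": ("weak_induced", 24),
                "ls-IRG": ("strong_repressed", 24),
                "lw-IRG": ("weak_repressed", 24),
            }[label]
            call, first_tp = kind
            for tp in TIMEPOINTS_H:
                per_tp[tp] = _draw(rng, _CALL_RANGES[call]) if tp >= first_tp else _draw(
                    rng, _QUIET
                )
        for tp in TIMEPOINTS_H:
            fc, ds = per_tp[tp]
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "timepoint_h": tp,
                    "fold_change": fc,
                    "diff_score": ds,
                    "known_isg": g.known_isg,
                    "pot_isg": g.pot_isg,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "timepoint_h",
            "fold_change",
            "diff_score",
            "known_isg",
            "pot_isg",
        ],
    )


# --- study-scale default spec ------------------------------------------------


def default_study_spec(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """A synthetic study mirroring the analysed design: eleven ISG-rich
    segments (nine of 1 Mb, one of 2 Mb, one of 5 Mb; 16 Mb total), ~24
    genes/Mb, 95 known ISGs among 375 annotated genes, and planted induced
    STAT1/IRF1 enrichment with a 2:1 IRF1:STAT1 excess plus a small
    constitutive (basal) subset.

    scale < 1 shrinks segment lengths and counts proportionally for quick
    runs; defaults reproduce the study geometry.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_654_321]))
    seg_defs = [("seg%02d" % i, 1_000_000) for i in range(1, 10)]
    seg_defs.append(("segCIITA", 2_000_000))
    seg_defs.append(("segMHC", 5_000_000))
    segments = [Segment(n, max(int(L * scale), 20_000)) for n, L in seg_defs]
    lengths = {s.name: s.length for s in segments}

    def pick_positions(n_items: int, min_gap: int = 3_000) -> list[tuple[str, int]]:
        out = []
        weights = np.array([s.length for s in segments], dtype=float)
        weights /= weights.sum()
        for _ in range(n_items):
            seg = segments[rng.choice(len(segments), p=weights)]
            pos = int(rng.integers(min_gap, seg.length - min_gap))
            out.append((seg.name, pos))
        return out

    n_genes = max(int(375 * scale), 20)
    n_isg = max(int(95 * scale), 6)
    class_cycle = (
        ["es-indISG"] * 31 + ["ls-indISG"] * 15 + ["ew-indISG"] * 15
        + ["lw-indISG"] * 14 + ["resISG"] * 20
    )
    templates = []
    positions = pick_positions(n_genes)
    for i, (segname, pos) in enumerate(positions):
        if i < n_isg:
            label = class_cycle[i % len(class_cycle)]
            known = True
        else:
            j = i - n_isg
            if j < max(int(19 * scale), 1):
                label, known = "ls-IRG", False
            elif j < max(int(42 * scale), 2):
                label, known = "lw-IRG", False
            else:
                label, known = "other", False
        templates.append(
            GeneTemplate(
                gene_id=f"G{i:04d}",
                segment=segname,
                tss=pos,
                strand="+" if rng.random() < 0.5 else "-",
                class_label=label,
                known_isg=known,
            )
        )

    n_stat1 = max(int(92 * scale), 4)
    n_irf1 = max(int(196 * scale), 8)
    peaks: list[PlantedPeak] = []
    width = 640  # >= 8 probes at 80 bp spacing
    for k, (segname, pos) in enumerate(pick_positions(n_stat1 + n_irf1)):
        tf = "STAT1" if k < n_stat1 else "IRF1"
        cond = "induced"
        # small constitutive subset (2/92 STAT1, 28/196 IRF1 in the study)
        if tf == "STAT1" and k < max(int(2 * scale), 0):
            cond = "basal"
        if tf == "IRF1" and n_stat1 <= k < n_stat1 + max(int(28 * scale), 0):
            cond = "basal"
        start = min(pos, lengths[segname] - width - 1)
        peaks.append(
            PlantedPeak(
                segment=segname,
                start=start,
                end=start + width,
                enrichment_fold=4.0,
                tf=tf,
                condition=cond,
            )
        )

    return SyntheticSpec(
        seed=seed,
        segments=segments,
        planted_peaks=peaks,
        gene_templates=templates,
    )
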