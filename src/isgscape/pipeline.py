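"""End-to-end orchestration: simulate -> normalize -> call peaks ->
classify genes -> occupancy statistics -> motif scan -> SNP screen -> report.

All randomness flows from the one root seed in the configuration; each stage
draws from a deterministically derived stream, so a rerun with the same
configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, io, motifs, occupancy, peaks, snps, synthetic

log = logging.getLogger("isgscape")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "isgscape_out"
    p_max: float = 1e-4
    fold_min: float = 1.5
    window_bp: int = 500
    merge_bp: int = 500
    proximal_bp: int = 5000
    dual_link_bp: int = 500
    lr_min: float = 500.0
    bg_order: int = 3
    snp_cutoff: float = 1.5
    ter_threshold: float = 2.0
    pwm_pseudocount: float = 0.5
    include_pseudogenes: bool = False
    n_random: int = 0  # 0 -> match total peak count
    scale: float = 1.0  # synthetic study scale factor

    def validate(self) -> None:
        for name in (
            "p_max",
            "fold_min",
            "window_bp",
            "merge_bp",
            "proximal_bp",
            "lr_min",
            "snp_cutoff",
            "ter_threshold",
            "pwm_pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def demo_spec(seed: int = 0, scale: float = 0.05) -> synthetic.SyntheticSpec:
    """The default study layout with motif instances planted inside a subset
    of binding regions and SNPs planted inside/outside motifs, so every
    pipeline stage has work to do. ``scale`` shrinks the study for quick runs."""
    spec = synthetic.default_study_spec(seed=seed, scale=scale)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424_242]))
    motifs_planted: list[synthetic.PlantedMotif] = []
    snps_planted: list[synthetic.PlantedSnp] = []
    spans: dict[str, list[tuple[int, int]]] = {}

    def free(seg, s, e):
        return all(not (s < pe and ps < e) for ps, pe in spans.get(seg, ()))

    n_snp = 0
    for i, pk in enumerate(spec.planted_peaks):
        if pk.condition != "induced":
            continue
        name = pk.tf if pk.tf in synthetic.DEFAULT_MOTIF_INSTANCES else "IRF1"
        inst = synthetic.DEFAULT_MOTIF_INSTANCES[name]
        pos = pk.start + (pk.end - pk.start) // 2
        if not free(pk.segment, pos, pos + len(inst)):
            continue
        spans.setdefault(pk.segment, []).append((pos, pos + len(inst)))
        motifs_planted.append(
            synthetic.PlantedMotif(segment=pk.segment, position=pos, name=name)
        )
        # every third motif gets a consensus-breaking SNP (expected loss)
        if i % 3 == 0:
            off = 2
            ref = inst[off]
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
            snps_planted.append(
                synthetic.PlantedSnp(
                    segment=pk.segment,
                    position=pos + off,
                    ref=ref,
                    alt=alt,
                    snp_id=f"snp_loss_{n_snp:03d}",
                )
            )
            n_snp += 1
    # a few SNPs inside peaks but outside motifs, and intergenic ones
    lengths = spec.segment_lengths()
    for j, pk in enumerate(spec.planted_peaks[:5]):
        snps_planted.append(
            synthetic.PlantedSnp(
                segment=pk.segment,
                position=pk.start + 5,
                ref="N",  # resolved to the genome base at generation time
                alt="",
                snp_id=f"snp_peak_{j}",
            )
        )
    for j in range(5):
        seg = spec.segments[j % len(spec.segments)]
        snps_planted.append(
            synthetic.PlantedSnp(
                segment=seg.name,
                position=int(rng.integers(0, lengths[seg.name])),
                ref="N",
                alt="",
                snp_id=f"snp_bg_{j}",
            )
        )
    return dataclasses.replace(
        spec, planted_motifs=motifs_planted, planted_snps=snps_planted
    )


def _resolve_snps(
    spec: synthetic.SyntheticSpec, genome: dict[str, str]
) -> list[snps.SnpRecord]:
    """Turn planted SNPs into records; placeholder alleles (ref 'N') take the
    genome base as ref and a transversion as alt."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = []
    for s in spec.planted_snps:
        ref = s.ref
        alt = s.alt
        if ref not in "ACGT":
            ref = genome[s.segment][s.position]
            alt = swap[ref]
        out.append(
            snps.SnpRecord(
                snp_id=s.snp_id or f"snp_{s.segment}_{s.position}",
                chrom=s.segment,
                pos=s.position,
                ref=ref,
                alt=alt,
            )
        )
    return out


def run(config: PipelineConfig, spec: synthetic.SyntheticSpec | None = None) -> dict:
    """Run every stage on a synthetic study and write the report bundle."""
    config.validate()
    outdir = io.ensure_dir(config.outdir)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    if spec is None:
        spec = demo_spec(seed=config.seed, scale=config.scale)

    log.info("stage simulate: seed=%d, %d segments", spec.seed, len(spec.segments))
    genome, genes = synthetic.generate_genome(spec)
    io.write_fasta(genome, outdir / "genome.fa")
    io.write_tsv(genes, outdir / "genes.tsv")
    experiment = synthetic.generate_tiling_experiment(spec)
    io.write_tsv(experiment.probes, outdir / "probes.tsv")
    io.write_bed(experiment.truth, outdir / "truth_peaks.bed", score_col="fold")
    expr = synthetic.generate_expression_table(spec)
    io.write_tsv(expr, outdir / "expression.tsv")
    snp_records = _resolve_snps(spec, genome)
    io.write_vcf(snp_records, outdir / "snps.vcf")
    segments = spec.segment_lengths()

    log.info("stage callpeaks: p<%g, fold>=%g", config.p_max, config.fold_min)
    called = {}
    for (tf, condition), chip in experiment.chip.items():
        chip_n, input_n = peaks.quantile_normalize_together(
            chip, experiment.input_[condition]
        )
        stats = peaks.window_test(chip_n, input_n, window_bp=config.window_bp)
        io.write_tsv(stats, outdir / f"windows_{tf}_{condition}.tsv")
        called[(tf, condition)] = peaks.call_peaks(
            stats,
            p_max=config.p_max,
            fold_min=config.fold_min,
            merge_bp=config.merge_bp,
            tf=tf,
            condition=condition,
        )
    nonempty = [df for df in called.values() if len(df)]
    all_peaks = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else next(iter(called.values()))
    )
    io.write_tsv(all_peaks, outdir / "peaks.tsv")
    io.write_bed(io.peak_bed_frame(all_peaks), outdir / "peaks.bed",
                 name_col="name", score_col="bed_score")

    log.info("stage classify-genes")
    classes = expression.classify_table(expr)
    io.write_tsv(classes, outdir / "gene_classes.tsv")
    genes_classified = genes.drop(columns=["class_label"]).merge(
        classes, on="gene_id", how="left"
    )

    log.info("stage occupancy")
    stat1 = called[("STAT1", "induced")]
    irf1 = called[("IRF1", "induced")]
    ledger = occupancy.build_ledger(stat1, irf1, link_bp=config.dual_link_bp)
    io.write_tsv(ledger, outdir / "regions.tsv")
    cooc = occupancy.summarize_cooccupancy(ledger)

    induced = all_peaks[all_peaks["condition"] == "induced"]
    assigned = occupancy.assign_peaks(
        induced, genes_classified, config.proximal_bp, config.include_pseudogenes
    )
    io.write_tsv(assigned, outdir / "peak_assignments.tsv")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1_111]))
    n_random = config.n_random or len(induced)
    ter_table = pd.DataFrame()
    random_sites = pd.DataFrame(columns=["chrom", "start", "end"])
    if len(induced):
        random_sites = occupancy.sample_random_sites(
            induced, segments, n_random, seed=rng
        )
        io.write_bed(random_sites, outdir / "random_sites.bed")
        assigned_random = occupancy.assign_peaks(
            random_sites, genes_classified, config.proximal_bp,
            config.include_pseudogenes,
        )
        ter_table = occupancy.compute_ter(
            assigned, assigned_random, ter_threshold=config.ter_threshold
        )
        io.write_tsv(ter_table, outdir / "ter.tsv")

    profiles = {}
    for label in ("es-indISG", "resISG"):
        sel = genes_classified[genes_classified["class_label"] == label]
        if len(sel):
            prof = occupancy.binding_profile(induced, sel, segments)
            io.write_tsv(prof, outdir / f"profile_{label}.tsv")
            profiles[label] = prof
    seg_stats = occupancy.segment_stats(
        induced, genes_classified, segments, config.proximal_bp
    )
    io.write_tsv(seg_stats, outdir / "segment_stats.tsv")
    basal_frac = occupancy.basal_induced_fractions(all_peaks)

    log.info("stage motifs: LR>%g, order-%d background", config.lr_min, config.bg_order)
    background = motifs.fit_background(list(genome.values()), k=config.bg_order)
    pwms = {
        name: motifs.consensus_pwm(seq, name=name)
        for name, seq in synthetic.DEFAULT_MOTIF_INSTANCES.items()
    }
    motif_results = []
    hit_frames = []
    region_ivs = ledger[["chrom", "start", "end"]] if len(ledger) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    for name, pwm in pwms.items():
        hits = motifs.scan_regions(genome, region_ivs, pwm, background, config.lr_min)
        hit_frames.append(hits)
        if len(region_ivs) and len(random_sites):
            peak_seqs = [
                genome[r.chrom][int(r.start) : int(r.end)]
                for r in region_ivs.itertuples(index=False)
            ]
            rand_seqs = [
                genome[r.chrom][int(r.start) : int(r.end)]
                for r in random_sites.itertuples(index=False)
            ]
            motif_results.append(
                motifs.motif_frequency_compare(
                    peak_seqs, rand_seqs, pwm, background, lr_min=config.lr_min
                )
            )
    motif_hits = (
        pd.concat(hit_frames, ignore_index=True)
        if hit_frames
        else pd.DataFrame(columns=["chrom", "start", "strand", "motif", "lr"])
    )
    io.write_tsv(motif_hits, outdir / "motif_hits.tsv")

    log.info("stage snps: %d records", len(snp_records))
    effects, snp_counts = snps.screen_snps(
        snp_records,
        region_ivs,
        motif_hits,
        genome,
        pwms,
        background,
        lr_min=config.lr_min,
        fold_cutoff=config.snp_cutoff,
    )
    io.write_tsv(effects, outdir / "snp_effects.tsv")

    report = {
        "seed": config.seed,
        "thresholds": {
            "p_max": config.p_max,
            "fold_min": config.fold_min,
            "window_bp": config.window_bp,
            "merge_bp": config.merge_bp,
            "proximal_bp": config.proximal_bp,
            "dual_link_bp": config.dual_link_bp,
            "lr_min": config.lr_min,
            "bg_order": config.bg_order,
            "snp_cutoff": config.snp_cutoff,
            "ter_threshold": config.ter_threshold,
        },
        "peak_counts": {
            f"{tf}_{cond}": int(len(df)) for (tf, cond), df in called.items()
        },
        "cooccupancy": {
            "n_regions": cooc["n_regions"],
            "counts": cooc["counts"],
            "pct": cooc["rounded"],
        },
        "basal_pct_of_induced": {k: round(v, 1) for k, v in basal_frac.items()},
        "ter_cells_above_threshold": int(ter_table["above_threshold"].sum())
        if len(ter_table)
        else 0,
        "motif_frequencies": motif_results,
        "snp_screen": snp_counts,
        "gene_class_counts": classes["class_label"].value_counts().to_dict(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_text_report(report, outdir / "report.txt")
    log.info("done: report at %s", outdir / "report.json")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["isgscape pipeline report", "=" * 28, ""]
    lines.append(f"seed: {report['seed']}")
    lines.append("")
    lines.append("peak counts:")
    for k, v in sorted(report["peak_counts"].items()):
        lines.append(f"  {k}: {v}")
    co = report["cooccupancy"]
    lines.append("")
    lines.append(f"binding regions: {co['n_regions']}")
    for label, n in co["counts"].items():
        lines.append(f"  {label}: {n}")
    lines.append("  shares (%): " + json.dumps(co["pct"]))
    lines.append("")
    lines.append("basal as % of induced peaks: " + json.dumps(report["basal_pct_of_induced"]))
    lines.append(f"TER cells above threshold: {report['ter_cells_above_threshold']}")
    lines.append("")
    for m in report["motif_frequencies"]:
        lines.append(
            f"motif {m['motif']}: {m['pct_peaks_with_motif']:.0f}% of peaks vs "
            f"{m['pct_random_with_motif']:.0f}% of random regions (p={m['p_value']:.3g})"
        )
    lines.append("")
    lines.append("SNP screen: " + json.dumps(report["snp_screen"]))
    lines.append("")
    lines.append("gene classes: " + json.dumps(report["gene_class_counts"], sort_keys=True))
    Path(path).write_text("\n".join(lines) + "\n")
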