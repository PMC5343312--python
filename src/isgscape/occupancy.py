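"""Relating TF binding sites to genes and response classes.

Covers nearest-gene assignment with the <=5 kb proximal rule, the
isolated/dual co-occupancy region ledger, matched random-site sampling, the
TF enrichment ratio (TER) against random sites, TSS-centered binding
profiles, and per-segment summary statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PROXIMAL_BP = 5000
DUAL_LINK_BP = 500
TER_THRESHOLD = 2.0

REGION_LABELS = ("isolated-STAT1", "isolated-IRF1", "dual")


def peak_centers(peaks: pd.DataFrame) -> np.ndarray:
    return (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0


def assign_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    proximal_bp: int = PROXIMAL_BP,
    include_pseudogenes: bool = False,
) -> pd.DataFrame:
    """Assign each peak to its nearest gene (|peak center - TSS|, same
    chromosome); proximal iff distance <= proximal_bp (inclusive). Distance
    ties break to the smaller gene_id. Pseudogenes are excluded unless
    requested. Peaks on chromosomes without genes are flagged unassigned."""
    if not include_pseudogenes and "is_pseudogene" in genes:
        genes = genes[~genes["is_pseudogene"].astype(bool)]
    gene_by_chrom = {
        chrom: grp.sort_values(["tss", "gene_id"], kind="stable")
        for chrom, grp in genes.groupby("chrom", sort=False)
    }
    centers = peak_centers(peaks)
    rows = []
    for i, (row, center) in enumerate(zip(peaks.itertuples(index=False), centers)):
        grp = gene_by_chrom.get(row.chrom)
        if grp is None or len(grp) == 0:
            rows.append(
                {
                    "gene_id": None,
                    "gene_class": None,
                    "distance": np.inf,
                    "proximal": False,
                    "assigned": False,
                }
            )
            continue
        tss = grp["tss"].to_numpy()
        d = np.abs(tss - center)
        dmin = d.min()
        cand = grp[d == dmin]
        best = cand.sort_values("gene_id", kind="stable").iloc[0]
        rows.append(
            {
                "gene_id": best["gene_id"],
                "gene_class": best.get("class_label"),
                "distance": float(dmin),
                "proximal": bool(dmin <= proximal_bp),
                "assigned": True,
            }
        )
    out = peaks.reset_index(drop=True).copy()
    for col in ("gene_id", "gene_class", "distance", "proximal", "assigned"):
        out[col] = [r[col] for r in rows]
    return out


def build_ledger(
    stat1_peaks: pd.DataFrame,
    irf1_peaks: pd.DataFrame,
    link_bp: int = DUAL_LINK_BP,
) -> pd.DataFrame:
    """Merge STAT1 and IRF1 peaks into discrete regions: two peaks belong to
    the same region when their intervals overlap by >= 1 bp or lie within
    link_bp of each other (gap <= link_bp). Each region is labeled
    isolated-STAT1 / isolated-IRF1 / dual.

    link_bp=0 restricts linkage to strictly overlapping or touching peaks.
    """
    s = stat1_peaks.copy()
    s["tf"] = "STAT1"
    r = irf1_peaks.copy()
    r["tf"] = "IRF1"
    allp = pd.concat([s, r], ignore_index=True)
    if allp.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_stat1", "n_irf1", "label"]
        )
    allp = allp.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )
    regions = []
    cur = None
    for row in allp.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start - cur["end"] <= link_bp
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["n_stat1"] += row.tf == "STAT1"
            cur["n_irf1"] += row.tf == "IRF1"
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n_stat1": int(row.tf == "STAT1"),
                "n_irf1": int(row.tf == "IRF1"),
            }
    regions.append(cur)
    out = pd.DataFrame(regions)
    out["label"] = np.where(
        (out["n_stat1"] > 0) & (out["n_irf1"] > 0),
        "dual",
        np.where(out["n_stat1"] > 0, "isolated-STAT1", "isolated-IRF1"),
    )
    return out


def summarize_cooccupancy(ledger: pd.DataFrame) -> dict:
    """Counts and percentages of isolated/dual regions, and the dual share of
    each TF's peaks (number of dual regions over that TF's peak count, the
    convention of the printed ledger). Percentages are rounded to the nearest
    integer for reporting; raw fractions are retained."""
    n_regions = len(ledger)
    counts = {label: 0 for label in REGION_LABELS}
    if n_regions:
        counts.update(ledger["label"].value_counts().to_dict())
    n_stat1 = int(ledger["n_stat1"].sum()) if n_regions else 0
    n_irf1 = int(ledger["n_irf1"].sum()) if n_regions else 0
    n_dual = counts["dual"]

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    raw = {
        "pct_isolated_stat1": pct(counts["isolated-STAT1"], n_regions),
        "pct_isolated_irf1": pct(counts["isolated-IRF1"], n_regions),
        "pct_dual": pct(n_dual, n_regions),
        "pct_dual_of_stat1_peaks": pct(n_dual, n_stat1),
        "pct_dual_of_irf1_peaks": pct(n_dual, n_irf1),
    }
    return {
        "n_regions": n_regions,
        "n_stat1_peaks": n_stat1,
        "n_irf1_peaks": n_irf1,
        "counts": counts,
        "raw": raw,
        "rounded": {k: int(round(v)) for k, v in raw.items()},
    }


def sample_random_sites(
    peaks: pd.DataFrame,
    segments: dict[str, int],
    n: int,
    seed=None,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Sample n control intervals from the tiled segments, avoiding every real
    peak, length-matched 1:1 to the input peaks (cycled when n exceeds the
    peak count) and with per-segment counts proportional to the real
    per-segment peak counts (largest-remainder rounding)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if peaks.empty:
        raise ValueError("cannot length-match against an empty peak set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    seg_counts = peaks["chrom"].value_counts()
    for seg in seg_counts.index:
        if seg not in segments:
            raise ValueError(f"peak segment {seg!r} not among declared segments")
    quota_exact = seg_counts / seg_counts.sum() * n
    quotas = quota_exact.astype(int)
    remainder = n - int(quotas.sum())
    if remainder:
        frac_order = (quota_exact - quotas).sort_values(ascending=False)
        for seg in frac_order.index[:remainder]:
            quotas[seg] += 1

    blocked = {
        chrom: sorted(zip(grp["start"], grp["end"]))
        for chrom, grp in peaks.groupby("chrom", sort=False)
    }

    def overlaps_peak(chrom, s, e):
        for ps, pe in blocked.get(chrom, ()):
            if s < pe and ps < e:
                return True
        return False

    rows = []
    for seg, quota in quotas.items():
        seg_len = segments[seg]
        lengths = (
            peaks.loc[peaks["chrom"] == seg, "end"].to_numpy()
            - peaks.loc[peaks["chrom"] == seg, "start"].to_numpy()
        )
        for i in range(int(quota)):
            L = int(lengths[i % len(lengths)])
            for _ in range(max_tries):
                s = int(rng.integers(0, max(seg_len - L, 1)))
                if not overlaps_peak(seg, s, s + L):
                    rows.append({"chrom": seg, "start": s, "end": s + L})
                    break
            else:
                raise RuntimeError(
                    f"segment {seg!r}: could not place a {L} bp random site "
                    f"after {max_tries} tries"
                )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def compute_ter(
    assigned_peaks: pd.DataFrame,
    assigned_random: pd.DataFrame,
    ter_threshold: float = TER_THRESHOLD,
) -> pd.DataFrame:
    """TF enrichment ratio per (tf, gene class, proximal/distal) cell:
    the percent of that TF's sites in the cell divided by the percent of
    random sites in the same cell. Cells with random support 0 but observed
    sites get ter = inf (flagged, not substituted)."""
    peaks = assigned_peaks[assigned_peaks["assigned"]]
    rand = assigned_random[assigned_random["assigned"]]
    classes = sorted(
        set(peaks["gene_class"].dropna()) | set(rand["gene_class"].dropna())
    )
    tf_groups = {"either": peaks}
    if "tf" in peaks.columns:
        for tf, grp in peaks.groupby("tf", sort=True):
            tf_groups[tf] = grp
    rows = []
    n_rand = len(rand)
    for tf, grp in tf_groups.items():
        n_tf = len(grp)
        for gene_class in classes:
            for location, prox in (("proximal", True), ("distal", False)):
                obs = int(
                    ((grp["gene_class"] == gene_class) & (grp["proximal"] == prox)).sum()
                )
                rnd = int(
                    ((rand["gene_class"] == gene_class) & (rand["proximal"] == prox)).sum()
                )
                obs_pct = 100.0 * obs / n_tf if n_tf else 0.0
                rnd_pct = 100.0 * rnd / n_rand if n_rand else 0.0
                if rnd_pct > 0:
                    ter = obs_pct / rnd_pct
                elif obs_pct > 0:
                    ter = np.inf
                else:
                    ter = np.nan  # undefined: no support on either side
                rows.append(
                    {
                        "tf": tf,
                        "gene_class": gene_class,
                        "location": location,
                        "n_observed": obs,
                        "n_random": rnd,
                        "observed_pct": obs_pct,
                        "random_pct": rnd_pct,
                        "ter": ter,
                        "above_threshold": bool(np.isfinite(ter) and ter > ter_threshold)
                        or (np.isinf(ter) and obs_pct > 0),
                    }
                )
    return pd.DataFrame(rows)


PROFILE_FLANK_KB = 200
PROFILE_WINDOW_BP = 1000


def binding_profile(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    segments: dict[str, int],
    flank_kb: int = PROFILE_FLANK_KB,
    window_bp: int = PROFILE_WINDOW_BP,
) -> pd.DataFrame:
    """Mean TF binding frequency in 1 kb windows spanning TSS +/- flank_kb
    (401 windows by default, window 0 centered at the TSS; upstream is
    negative, oriented by gene strand). A peak is counted in the window
    containing its center. Windows extending beyond the gene's tiled segment
    are missing data, not zero, and are ignored in the average."""
    if genes.empty:
        raise ValueError("binding_profile: no genes supplied")
    n_win = 2 * flank_kb + 1
    offsets = np.arange(-flank_kb, flank_kb + 1)
    counts = np.zeros((len(genes), n_win))
    valid = np.zeros((len(genes), n_win), dtype=bool)
    centers_by_chrom = {
        chrom: np.sort(peak_centers(grp)) for chrom, grp in peaks.groupby("chrom")
    }
    for gi, gene in enumerate(genes.itertuples(index=False)):
        seg_len = segments[gene.chrom]
        sign = -1 if gene.strand == "-" else 1
        # genomic bounds of each oriented window
        win_centers = gene.tss + sign * offsets * window_bp
        lo = win_centers - window_bp / 2
        hi = win_centers + window_bp / 2
        inside = (lo >= 0) & (hi <= seg_len)
        valid[gi] = inside
        pc = centers_by_chrom.get(gene.chrom)
        if pc is None:
            continue
        glo = np.minimum(lo, hi)
        ghi = np.maximum(lo, hi)
        counts[gi] = np.searchsorted(pc, ghi) - np.searchsorted(pc, glo)
    with np.errstate(invalid="ignore"):
        n_per_win = valid.sum(axis=0)
        mean = np.where(
            n_per_win > 0,
            np.where(valid, counts, 0.0).sum(axis=0) / np.maximum(n_per_win, 1),
            np.nan,
        )
    return pd.DataFrame(
        {"window": offsets, "mean_freq": mean, "n_genes": n_per_win}
    )


def segment_stats(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    segments: dict[str, int],
    proximal_bp: int = PROXIMAL_BP,
) -> pd.DataFrame:
    """Per-segment binding and gene statistics: peak counts per TF, the
    IRF1:STAT1 ratio, proximal fractions with and without pseudogenes,
    es-indISG density per Mb and the known-ISG fraction of annotated
    (non-pseudo) genes. A TOTAL row aggregates all segments."""
    assigned = assign_peaks(peaks, genes, proximal_bp, include_pseudogenes=False)
    assigned_pg = assign_peaks(peaks, genes, proximal_bp, include_pseudogenes=True)
    rows = []
    seg_names = list(segments) + ["TOTAL"]
    for seg in seg_names:
        if seg == "TOTAL":
            mask = np.ones(len(assigned), dtype=bool)
            gmask = np.ones(len(genes), dtype=bool)
            mb = sum(segments.values()) / 1e6
        else:
            mask = (assigned["chrom"] == seg).to_numpy()
            gmask = (genes["chrom"] == seg).to_numpy()
            mb = segments[seg] / 1e6
        sub = assigned[mask]
        sub_pg = assigned_pg[mask]
        gsub = genes[gmask]
        real_genes = (
            gsub[~gsub["is_pseudogene"].astype(bool)] if "is_pseudogene" in gsub else gsub
        )
        n_stat1 = int((sub["tf"] == "STAT1").sum())
        n_irf1 = int((sub["tf"] == "IRF1").sum())
        n_es = int((real_genes["class_label"] == "es-indISG").sum())
        n_isg = (
            int(real_genes["known_isg"].astype(bool).sum())
            if "known_isg" in real_genes
            else 0
        )
        rows.append(
            {
                "segment": seg,
                "mb": mb,
                "n_stat1": n_stat1,
                "n_irf1": n_irf1,
                "irf1_stat1_ratio": n_irf1 / n_stat1 if n_stat1 else np.nan,
                "pct_proximal": 100.0 * sub["proximal"].mean() if len(sub) else 0.0,
                "pct_proximal_with_pseudogenes": 100.0 * sub_pg["proximal"].mean()
                if len(sub_pg)
                else 0.0,
                "es_indisg_per_mb": n_es / mb,
                "n_genes": len(real_genes),
                "n_known_isg": n_isg,
                "pct_known_isg": 100.0 * n_isg / len(real_genes)
                if len(real_genes)
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def basal_induced_fractions(peaks: pd.DataFrame) -> dict[str, float]:
    """Basal peak count as a percentage of induced peaks, per TF."""
    out = {}
    for tf, grp in peaks.groupby("tf", sort=True):
        n_basal = int((grp["condition"] == "basal").sum())
        n_induced = int((grp["condition"] == "induced").sum())
        out[tf] = 100.0 * n_basal / n_induced if n_induced else np.nan
    return out
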