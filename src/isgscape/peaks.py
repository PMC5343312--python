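"""Tiling-array peak calling.

Replicate ChIP and input intensities are quantile normalized, each probe is
tested with a one-sided Wilcoxon rank-sum statistic over a 500 bp sliding
window centered on the probe (ChIP values vs input values for all probes in
the window, replicates pooled), and windows passing the enrichment filters
(fold >= 1.5, p < 1e-4) are merged into peaks when their spans lie within
500 bp of each other.

No multiple-testing correction is applied: the filter is on the raw
per-window p-value, matching the thresholds the pipeline is built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end"]


@dataclass
class IntensityMatrix:
    """Probe x sample intensity table for one antibody/condition.

    probes: DataFrame with columns (probe_id, chrom, start, end), sorted by
        (chrom, start); coordinates are 0-based half-open.
    values: float array of shape (n_probes, n_samples), strictly positive.
    samples: column names, e.g. ``STAT1_induced_rep1`` or ``input_basal_rep2``.
    normalized: whether the columns have been quantile normalized.
    """

    probes: pd.DataFrame
    values: np.ndarray
    samples: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.probes):
            raise ValueError("values must be (n_probes, n_samples)")
        if self.values.shape[1] != len(self.samples):
            raise ValueError("sample names do not match value columns")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one sample column")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"non-finite intensity at probe {self.probes['probe_id'].iloc[i]}"
            )
        if (self.values <= 0).any():
            i = int(np.argwhere(self.values <= 0)[0, 0])
            raise ValueError(
                f"non-positive intensity at probe {self.probes['probe_id'].iloc[i]}"
            )
        order = self.probes.sort_values(["chrom", "start"], kind="stable").index
        if not np.array_equal(order.to_numpy(), np.arange(len(self.probes))):
            raise ValueError("probes must be sorted by (chrom, start)")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def to_frame(self) -> pd.DataFrame:
        df = self.probes.copy()
        for j, name in enumerate(self.samples):
            df[name] = self.values[:, j]
        return df

    def same_probe_map(self, other: "IntensityMatrix") -> bool:
        return self.probes[PROBE_COLUMNS].equals(other.probes[PROBE_COLUMNS])


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns; ties receive the mean of the tied ranks'
    reference values."""
    n, p = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(p):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = reference
        sorted_col = col[order]
        # tie groups in the sorted column share the mean reference value
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        if len(starts) < n:  # at least one tie group
            group_means = np.add.reduceat(reference, starts) / (ends - starts)
            expanded = np.empty(n)
            for s, e, m in zip(starts, ends, group_means):
                expanded[s:e] = m
            ranked[order] = expanded
        out[:, j] = ranked
    return out


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Return a quantile-normalized copy: every column carries the identical
    sorted value multiset (the per-rank column means); row order preserved."""
    if matrix.values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 sample columns")
    return IntensityMatrix(
        probes=matrix.probes.copy(),
        values=_quantile_normalize_values(matrix.values),
        samples=list(matrix.samples),
        normalized=True,
    )


def quantile_normalize_together(
    chip: IntensityMatrix, input_: IntensityMatrix
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Quantile-normalize ChIP and input columns jointly so that ranks are
    comparable across the two sample groups (local enrichment survives the
    shared marginal)."""
    if not chip.same_probe_map(input_):
        raise ValueError("ChIP and input probe maps differ")
    stacked = np.hstack([chip.values, input_.values])
    normed = _quantile_normalize_values(stacked)
    k = chip.values.shape[1]
    chip_n = IntensityMatrix(chip.probes.copy(), normed[:, :k], list(chip.samples), True)
    input_n = IntensityMatrix(
        input_.probes.copy(), normed[:, k:], list(input_.samples), True
    )
    return chip_n, input_n


EXACT_MAX_N = 12  # exact rank-sum enumeration up to this pooled sample size


def exact_ranksum_p_greater(chip_values, input_values) -> float:
    """Exact one-sided rank-sum p-value P(rank sum of first group >= observed)
    by enumeration of all labelings; midranks for ties."""
    chip_values = np.asarray(chip_values, dtype=float)
    input_values = np.asarray(input_values, dtype=float)
    n1 = len(chip_values)
    pooled = np.concatenate([chip_values, input_values])
    ranks = rankdata(pooled)
    observed = ranks[:n1].sum()
    total = comb(len(pooled), n1)
    hits = sum(
        1
        for idx in combinations(range(len(pooled)), n1)
        if ranks[list(idx)].sum() >= observed - 1e-9
    )
    return hits / total


def _normal_ranksum_p_greater(values: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized one-sided (first-group-greater) rank-sum p with mid-ranks,
    tie-corrected variance and continuity correction.

    values: (m, N) pooled rows, first n1 columns are the ChIP group.
    """
    m, n_total = values.shape
    n2 = n_total - n1
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    base_var = n1 * n2 * (n_total + 1) / 12.0

    var = np.full(m, base_var)
    sorted_vals = np.sort(values, axis=1)
    has_ties = (np.diff(sorted_vals, axis=1) == 0).any(axis=1)
    for i in np.flatnonzero(has_ties):
        _, counts = np.unique(sorted_vals[i], return_counts=True)
        tie_term = float(((counts**3) - counts).sum())
        var[i] = (
            n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
        )

    p = np.ones(m)
    ok = var > 0
    z = (u1[ok] - mu - 0.5) / np.sqrt(var[ok])
    p[ok] = norm.sf(z)
    return np.clip(p, 0.0, 1.0)


WINDOW_STAT_COLUMNS = [
    "chrom",
    "center_probe_id",
    "window_start",
    "window_end",
    "n_probes",
    "n_chip",
    "n_input",
    "fold",
    "p_value",
]


def window_test(
    chip: IntensityMatrix, input_: IntensityMatrix, window_bp: int = 500
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum test per probe-centered sliding window.

    For each probe, all ChIP values (probes in the window x replicates) are
    compared against all input values likewise; p is the one-sided probability
    of the ChIP group ranking at least as high (enrichment). fold is
    mean(ChIP)/mean(input) over the window. Windows with fewer than 2 probes
    get p = 1.
    """
    if not chip.same_probe_map(input_):
        raise ValueError("ChIP and input probe maps differ")
    probes = chip.probes
    half = window_bp / 2.0
    n = len(probes)

    p_out = np.ones(n)
    fold_out = np.ones(n)
    win_start = np.zeros(n, dtype=int)
    win_end = np.zeros(n, dtype=int)
    k_out = np.zeros(n, dtype=int)

    r1 = chip.values.shape[1]
    r2 = input_.values.shape[1]

    for chrom, grp in probes.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        # probes are sorted within chrom already
        centers = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0
        left = np.searchsorted(centers, centers - half, side="left")
        right = np.searchsorted(centers, centers + half, side="right")
        k = right - left
        k_out[idx] = k
        win_start[idx] = np.floor(centers - half).astype(int)
        win_end[idx] = np.ceil(centers + half).astype(int)

        chip_vals = chip.values[idx]
        input_vals = input_.values[idx]

        for kk in np.unique(k):
            rows = np.flatnonzero(k == kk)
            take = left[rows, None] + np.arange(kk)[None, :]
            cv = chip_vals[take].reshape(len(rows), kk * r1)
            iv = input_vals[take].reshape(len(rows), kk * r2)
            fold_out[idx[rows]] = cv.mean(axis=1) / iv.mean(axis=1)
            if kk < 2:
                continue  # p stays 1
            pooled = np.hstack([cv, iv])
            n1 = kk * r1
            if pooled.shape[1] <= EXACT_MAX_N:
                for r, row in zip(rows, range(len(rows))):
                    p_out[idx[r]] = exact_ranksum_p_greater(cv[row], iv[row])
            else:
                p_out[idx[rows]] = _normal_ranksum_p_greater(pooled, n1)

    out = pd.DataFrame(
        {
            "chrom": probes["chrom"],
            "center_probe_id": probes["probe_id"],
            "window_start": win_start,
            "window_end": win_end,
            "n_probes": k_out,
            "n_chip": k_out * r1,
            "n_input": k_out * r2,
            "fold": fold_out,
            "p_value": p_out,
        }
    )
    return out


PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "tf",
    "condition",
    "score",
    "fold",
    "n_windows",
]


def call_peaks(
    stats: pd.DataFrame,
    p_max: float = 1e-4,
    fold_min: float = 1.5,
    merge_bp: int = 500,
    tf: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """Merge significant windows (p < p_max and fold >= fold_min) into peaks.

    Windows on the same chromosome whose spans are separated by at most
    merge_bp are merged; peak bounds are the union of contributing window
    spans, score is -log10 of the best p, fold the best fold.
    """
    passing = stats[(stats["p_value"] < p_max) & (stats["fold"] >= fold_min)]
    records = []
    for chrom, grp in passing.groupby("chrom", sort=True):
        grp = grp.sort_values("window_start", kind="stable")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.window_start - cur["end"] <= merge_bp:
                cur["end"] = max(cur["end"], row.window_end)
                cur["p"] = min(cur["p"], row.p_value)
                cur["fold"] = max(cur["fold"], row.fold)
                cur["n"] += 1
            else:
                if cur is not None:
                    records.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": row.window_start,
                    "end": row.window_end,
                    "p": row.p_value,
                    "fold": row.fold,
                    "n": 1,
                }
        if cur is not None:
            records.append(cur)

    with np.errstate(divide="ignore"):
        rows = [
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "tf": tf,
                "condition": condition,
                "score": float(-np.log10(r["p"])) if r["p"] > 0 else np.inf,
                "fold": r["fold"],
                "n_windows": r["n"],
            }
            for r in records
        ]
    out = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
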