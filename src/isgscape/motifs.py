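"""PWM likelihood-ratio motif scanning against a k-th order Markov background.

A position frequency matrix (base counts) is converted with pseudo-counts into
a column-stochastic probability matrix. Each sequence window is scored by the
likelihood ratio LR = P_pwm(window) / P_bg(window), where the background
probability conditions each base on the k preceding bases (falling back to the
order-0 composition when fewer than k bases of context exist). Windows with
LR above the cutoff (default 500) are motif hits.

The background is trained on both strands (each training sequence
concatenated with its reverse complement). Minus-strand windows are scored on
the minus-strand text with their own minus-strand left context under the same
model, which makes scanning exactly strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

from .synthetic import reverse_complement

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}

LR_MIN = 500.0
BG_ORDER = 3
PSEUDOCOUNT = 0.5
MOTIF_COMPARE_ALPHA = 5e-5


@dataclass
class PwmModel:
    """Pseudo-count probability matrix derived from a PFM."""

    name: str
    counts: np.ndarray  # (4, L) non-negative
    pseudocount: float
    probs: np.ndarray  # (4, L) column-stochastic

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))


def build_pwm(counts, pseudocount: float = PSEUDOCOUNT, name: str = "motif") -> PwmModel:
    """probs[b][j] = (counts[b][j] + pseudocount) / (col_total + 4*pseudocount)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("PFM must have 4 rows (A, C, G, T)")
    if counts.shape[1] < 4:
        raise ValueError("PFM must have length >= 4")
    if (counts < 0).any():
        raise ValueError("PFM counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    totals = counts.sum(axis=0)
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    return PwmModel(name=name, counts=counts, pseudocount=pseudocount, probs=probs)


def consensus_pwm(sequence: str, p_major: float = 0.97, name: str = "motif") -> PwmModel:
    """Sharp PWM putting p_major on each consensus base (testing helper and
    default planted-motif model)."""
    L = len(sequence)
    counts = np.full((4, L), 0.0)
    # encode directly as probabilities via counts proportional to them
    probs = np.full((4, L), (1 - p_major) / 3)
    for j, b in enumerate(sequence.upper()):
        probs[_INDEX[b], j] = p_major
    counts = probs * 1000.0
    return build_pwm(counts, pseudocount=1e-9, name=name)


def read_jaspar_pfm(path_or_text: str) -> PwmModel:
    """Read a JASPAR-format PFM (">name" header plus four labeled rows)."""
    try:
        from Bio import motifs as bio_motifs
    except ImportError as exc:  # pragma: no cover
        raise ImportError("biopython is required to read JASPAR files") from exc
    if "\n" in path_or_text or path_or_text.lstrip().startswith(">"):
        handle = StringIO(path_or_text)
    else:
        handle = open(path_or_text)
    with handle:
        m = bio_motifs.read(handle, "jaspar")
    counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
    return build_pwm(counts, name=m.name or m.matrix_id or "motif")


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for b, i in _INDEX.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class MarkovBackground:
    """k-th order background: P(base | preceding k-mer), add-1 smoothed."""

    order: int
    conditional: np.ndarray  # (4**k, 4), rows sum to 1
    p0: np.ndarray  # order-0 composition, sums to 1
    training_bp: int

    def context_index(self, codes: np.ndarray) -> int:
        idx = 0
        for c in codes:
            idx = idx * 4 + int(c)
        return idx


def fit_background(sequences, k: int = BG_ORDER) -> MarkovBackground:
    """Estimate the background from sequences (trained on both strands).

    (k+1)-mer counts with add-1 smoothing define the conditionals; the order-0
    composition is the smoothed base frequency.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    sequences = [s for s in sequences if s]
    if not sequences or sum(len(s) for s in sequences) == 0:
        raise ValueError("fit_background: empty input")
    if k < 0:
        raise ValueError("order must be >= 0")
    n_ctx = 4**k
    counts = np.zeros((n_ctx, 4))
    base_counts = np.zeros(4)
    total = 0
    for seq in sequences:
        for strand_seq in (seq, reverse_complement(seq)):
            codes = encode(strand_seq)
            total += len(codes)
            good = codes >= 0
            base_counts += np.bincount(codes[good], minlength=4)
            if k == 0:
                counts[0] += np.bincount(codes[good], minlength=4)
                continue
            # context index per position via rolling base-4 encoding
            if len(codes) <= k:
                continue
            valid = np.ones(len(codes), dtype=bool)
            ctx = np.zeros(len(codes), dtype=np.int64)
            c = codes.copy()
            pow4 = 4 ** np.arange(k - 1, -1, -1)
            for j in range(k):
                shifted = np.roll(c, j + 1)
                shifted[: j + 1] = -1
                valid &= shifted >= 0
                ctx += np.where(shifted >= 0, shifted, 0) * pow4[k - 1 - j]
            use = valid & (codes >= 0)
            np.add.at(counts, (ctx[use], codes[use]), 1)
    conditional = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 4.0)
    p0 = (base_counts + 1.0) / (base_counts.sum() + 4.0)
    return MarkovBackground(order=k, conditional=conditional, p0=p0, training_bp=total)


def _conditional_logp(codes: np.ndarray, bg: MarkovBackground) -> np.ndarray:
    """log P(s_i | k preceding bases) per position; order-0 fallback where the
    left context is truncated or contains N; NaN at N positions."""
    n = len(codes)
    logp = np.full(n, np.nan)
    good = codes >= 0
    logp[good] = np.log(bg.p0[codes[good]])
    k = bg.order
    if k == 0 or n <= k:
        return logp
    ctx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    pow4 = 4 ** np.arange(k - 1, -1, -1)
    for j in range(k):
        shifted = np.roll(codes, j + 1)
        shifted[: j + 1] = -1
        valid &= shifted >= 0
        ctx += np.where(shifted >= 0, shifted, 0) * pow4[k - 1 - j]
    use = valid & good
    logp[use] = np.log(bg.conditional[ctx[use], codes[use]])
    return logp


def _window_sums(x: np.ndarray, L: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[L:] - c[:-L]


def scan(
    sequence: str,
    pwm: PwmModel,
    background: MarkovBackground,
    lr_min: float = LR_MIN,
    both_strands: bool = True,
    chrom: str = "",
) -> pd.DataFrame:
    """Scan a sequence for PWM hits with LR > lr_min on one or both strands.

    Returns a hit table (chrom, start, strand, motif, lr) sorted by position;
    the number of windows skipped for containing N is in
    ``hits.attrs['n_skipped']``.
    """
    L = pwm.length
    n = len(sequence)
    empty = pd.DataFrame(columns=["chrom", "start", "strand", "motif", "lr"])
    empty.attrs["n_skipped"] = 0
    if n < L:
        return empty
    codes = encode(sequence)
    n_win = n - L + 1
    logprobs = np.log(pwm.probs)

    # numerator: sum_j log probs[s_{i+j}, j]
    safe = np.where(codes >= 0, codes, 0)
    pwm_fwd = np.zeros(n_win)
    for j in range(L):
        pwm_fwd += logprobs[safe[j : j + n_win], j]
    # minus strand: window text is revcomp; base at window pos j is
    # complement(s_{i+L-1-j})
    if both_strands:
        pwm_rev = np.zeros(n_win)
        for j in range(L):
            pwm_rev += logprobs[3 - safe[L - 1 - j : L - 1 - j + n_win], j]

    has_n = _window_sums((codes < 0).astype(float), L) > 0
    n_skipped = int(has_n.sum()) * (2 if both_strands else 1)

    bg_fwd = _window_sums(np.nan_to_num(_conditional_logp(codes, background)), L)
    rows_start, rows_strand, rows_lr = [], [], []
    with np.errstate(over="ignore"):
        lr_f = np.exp(pwm_fwd - bg_fwd)
    keep = (~has_n) & (lr_f > lr_min)
    for i in np.flatnonzero(keep):
        rows_start.append(i)
        rows_strand.append("+")
        rows_lr.append(float(lr_f[i]))

    if both_strands:
        rc_codes = encode(reverse_complement(sequence))
        bg_rc = _window_sums(
            np.nan_to_num(_conditional_logp(rc_codes, background)), L
        )
        # window starting at i on the forward strand corresponds to the
        # reverse-complement window starting at n - L - i
        bg_rev = bg_rc[::-1]
        with np.errstate(over="ignore"):
            lr_r = np.exp(pwm_rev - bg_rev)
        keep = (~has_n) & (lr_r > lr_min)
        for i in np.flatnonzero(keep):
            rows_start.append(i)
            rows_strand.append("-")
            rows_lr.append(float(lr_r[i]))

    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start": rows_start,
            "strand": rows_strand,
            "motif": pwm.name,
            "lr": rows_lr,
        }
    )
    out = out.sort_values(["start", "strand"], kind="stable").reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def scan_regions(
    genome: dict[str, str],
    regions: pd.DataFrame,
    pwm: PwmModel,
    background: MarkovBackground,
    lr_min: float = LR_MIN,
) -> pd.DataFrame:
    """Scan each region (chrom, start, end) of a genome; hit coordinates are
    genomic. The k bases left of each region boundary are included as context
    by scanning the padded sequence and trimming hits outside the region."""
    frames = []
    k = background.order
    for row in regions.itertuples(index=False):
        seq = genome[row.chrom]
        lo = max(0, int(row.start) - k)
        sub = seq[lo : int(row.end)]
        hits = scan(sub, pwm, background, lr_min=lr_min, chrom=row.chrom)
        hits["start"] = hits["start"] + lo
        hits = hits[hits["start"] >= int(row.start)]
        frames.append(hits)
    if not frames:
        out = pd.DataFrame(columns=["chrom", "start", "strand", "motif", "lr"])
        out.attrs["n_skipped"] = 0
        return out
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_skipped"] = sum(f.attrs.get("n_skipped", 0) for f in frames)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test that two proportions differ: Fisher exact for moderate
    totals, normal-approximation two-proportion z-test beyond."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("two_proportion_test: empty group")
    if n1 + n2 <= 10_000:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(2 * norm.sf(abs(z)))


def motif_frequency_compare(
    peak_seqs,
    random_seqs,
    pwm: PwmModel,
    background: MarkovBackground,
    lr_min: float = LR_MIN,
    alpha: float = MOTIF_COMPARE_ALPHA,
) -> dict:
    """Fraction of peak vs matched random regions containing >= 1 motif hit,
    with a two-sided two-proportion p-value and a significance marker at
    p < alpha."""
    peak_seqs = list(peak_seqs)
    random_seqs = list(random_seqs)
    if not peak_seqs or not random_seqs:
        raise ValueError("motif_frequency_compare: zero regions")

    def n_with_motif(seqs):
        return sum(
            1 for s in seqs if len(scan(s, pwm, background, lr_min=lr_min)) > 0
        )

    k1, k2 = n_with_motif(peak_seqs), n_with_motif(random_seqs)
    n1, n2 = len(peak_seqs), len(random_seqs)
    p = two_proportion_test(k1, n1, k2, n2)
    return {
        "motif": pwm.name,
        "n_peaks": n1,
        "n_random": n2,
        "n_peaks_with_motif": k1,
        "n_random_with_motif": k2,
        "pct_peaks_with_motif": 100.0 * k1 / n1,
        "pct_random_with_motif": 100.0 * k2 / n2,
        "p_value": p,
        "significant": p < alpha,
    }
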