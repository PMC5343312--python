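"""IFNγ response classes from expression time courses.

A gene is called at a timepoint when its differential score clears ±13:
induced (diff >= 13; strong if fold >= 2, else weak) or repressed
(diff <= -13; strong if fold <= 0.5, else weak). The earliest called
timepoint decides the class; a 6 h call is "early" (es/ew), a first call at
24 or 48 h is "late" (ls/lw). Known ISGs with no call in this cell type are
resistant (resISG); unflagged genes with no call are "other" (or potISG when
flagged as a potential ISG).

The differential score is treated as an opaque signed platform score with the
±13 thresholds; it is never recomputed from raw data here.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import GENE_CLASS_VOCAB, TIMEPOINTS_H

DIFF_SCORE_CALL = 13.0
FOLD_STRONG_INDUCED = 2.0
FOLD_STRONG_REPRESSED = 0.5

SHARING_LABELS = ("Ex", "pSh", "Ub")


def _call(fold_change: float, diff_score: float) -> str | None:
    if diff_score >= DIFF_SCORE_CALL:
        return "strong_induced" if fold_change >= FOLD_STRONG_INDUCED else "weak_induced"
    if diff_score <= -DIFF_SCORE_CALL:
        return (
            "strong_repressed"
            if fold_change <= FOLD_STRONG_REPRESSED
            else "weak_repressed"
        )
    return None


def classify_gene(
    records: pd.DataFrame, known_isg: bool = False, pot_isg: bool = False
) -> str:
    """Assign one response class from a gene's (timepoint_h, fold_change,
    diff_score) records. The 6 h timepoint is required."""
    tps = set(records["timepoint_h"])
    if 6 not in tps:
        raise ValueError("classify_gene: missing 6 h record")
    by_tp = records.set_index("timepoint_h")
    for tp in TIMEPOINTS_H:
        if tp not in tps:
            continue
        row = by_tp.loc[tp]
        call = _call(float(row["fold_change"]), float(row["diff_score"]))
        if call is None:
            continue
        early = tp == 6
        if call == "strong_induced":
            return "es-indISG" if early else "ls-indISG"
        if call == "weak_induced":
            return "ew-indISG" if early else "lw-indISG"
        # repression was observed only late in the study; the vocabulary has
        # no early repressed label, so strength alone decides
        return "ls-IRG" if call == "strong_repressed" else "lw-IRG"
    if known_isg:
        return "resISG"
    return "potISG" if pot_isg else "other"


def classify_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Classify every gene in a long-format expression table
    (gene_id, timepoint_h, fold_change, diff_score, known_isg[, pot_isg])."""
    out = []
    for gene_id, grp in expression.groupby("gene_id", sort=True):
        known = bool(grp["known_isg"].iloc[0]) if "known_isg" in grp else False
        pot = bool(grp["pot_isg"].iloc[0]) if "pot_isg" in grp else False
        out.append(
            {
                "gene_id": gene_id,
                "class_label": classify_gene(grp, known_isg=known, pot_isg=pot),
            }
        )
    df = pd.DataFrame(out, columns=["gene_id", "class_label"])
    bad = set(df["class_label"]) - set(GENE_CLASS_VOCAB)
    assert not bad, f"classifier produced labels outside the vocabulary: {bad}"
    return df


def classify_sharing(induced_in, universe: int = 7) -> str:
    """Cross-cell-type sharing class from the set (or count) of cell types in
    which a gene is IFNγ-induced: exclusive (1), partially shared (2-4),
    ubiquitous (5-7)."""
    n = induced_in if isinstance(induced_in, int) else len(set(induced_in))
    if n < 1:
        raise ValueError("classify_sharing: gene is not induced in any cell type")
    if n > universe:
        raise ValueError(f"classify_sharing: {n} exceeds the {universe}-cell universe")
    if n == 1:
        return "Ex"
    if n <= 4:
        return "pSh"
    return "Ub"
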