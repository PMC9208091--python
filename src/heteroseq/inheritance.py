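"""Eight-way expression-inheritance classification for a hybrid/parent trio.

Each gene is placed in the (log2(hyb/P1), log2(hyb/P2)) plane — P1 is the
maternal inbred (Z58), P2 the paternal inbred (C72) — and classified by
strict unit-threshold inequalities:

========================  =============================================
class                     region
========================  =============================================
ADD_P2_GT_P1 (additive)   log2(h/P1) > 1  and  log2(h/P2) < -1
ADD_P1_GT_P2 (additive)   log2(h/P1) < -1 and  log2(h/P2) > 1
P2_DOM_UP                 log2(h/P1) > 1  and |log2(h/P2)| < 1
P2_DOM_DOWN               log2(h/P1) < -1 and |log2(h/P2)| < 1
P1_DOM_UP                 log2(h/P2) > 1  and |log2(h/P1)| < 1
P1_DOM_DOWN               log2(h/P2) < -1 and |log2(h/P1)| < 1
TRANS_UP (transgressive)  both > 1
TRANS_DOWN                both < -1
CONSERVED                 both strictly inside (-1, 1)
========================  =============================================

Points with either coordinate exactly at +-1 satisfy no strict rule and are
labelled UNCLASSIFIED_BOUNDARY; with continuous expression ratios this set
has measure zero. Summaries count only the eight divergent classes — the
set of genes differentially expressed between the hybrid and at least one
parent — matching how the shares are conventionally reported.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import ZERO_MEAN_FLOOR, genotype_means
from .iomod import HeteroseqError, SampleDesign

EIGHT_CLASSES = (
    "ADD_P2_GT_P1",
    "ADD_P1_GT_P2",
    "P2_DOM_UP",
    "P2_DOM_DOWN",
    "P1_DOM_UP",
    "P1_DOM_DOWN",
    "TRANS_UP",
    "TRANS_DOWN",
)
ALL_CLASSES = EIGHT_CLASSES + ("CONSERVED", "UNCLASSIFIED_BOUNDARY")

INHERITANCE_COLUMNS = ["gene_id", "hybrid", "log2_h_p1", "log2_h_p2", "klass", "in_summary"]


def classify_gene(log2_h_p1: float, log2_h_p2: float) -> str:
    """Classify one gene from its two hybrid/parent log2 ratios."""
    a, b = float(log2_h_p1), float(log2_h_p2)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise HeteroseqError(f"non-finite log2 ratio: ({log2_h_p1}, {log2_h_p2})")
    if a > 1 and b < -1:
        return "ADD_P2_GT_P1"
    if a < -1 and b > 1:
        return "ADD_P1_GT_P2"
    if a > 1 and abs(b) < 1:
        return "P2_DOM_UP"
    if a < -1 and abs(b) < 1:
        return "P2_DOM_DOWN"
    if b > 1 and abs(a) < 1:
        return "P1_DOM_UP"
    if b < -1 and abs(a) < 1:
        return "P1_DOM_DOWN"
    if a > 1 and b > 1:
        return "TRANS_UP"
    if a < -1 and b < -1:
        return "TRANS_DOWN"
    if abs(a) < 1 and abs(b) < 1:
        return "CONSERVED"
    return "UNCLASSIFIED_BOUNDARY"


def classify_points(log2_h_p1: np.ndarray, log2_h_p2: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_gene`."""
    a = np.asarray(log2_h_p1, dtype=float)
    b = np.asarray(log2_h_p2, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise HeteroseqError("non-finite log2 ratios")
    out = np.full(a.shape, "UNCLASSIFIED_BOUNDARY", dtype=object)
    out[(np.abs(a) < 1) & (np.abs(b) < 1)] = "CONSERVED"
    out[(a > 1) & (b < -1)] = "ADD_P2_GT_P1"
    out[(a < -1) & (b > 1)] = "ADD_P1_GT_P2"
    out[(a > 1) & (np.abs(b) < 1)] = "P2_DOM_UP"
    out[(a < -1) & (np.abs(b) < 1)] = "P2_DOM_DOWN"
    out[(b > 1) & (np.abs(a) < 1)] = "P1_DOM_UP"
    out[(b < -1) & (np.abs(a) < 1)] = "P1_DOM_DOWN"
    out[(a > 1) & (b > 1)] = "TRANS_UP"
    out[(a < -1) & (b < -1)] = "TRANS_DOWN"
    return out


def classify_hybrid(
    norm_counts: pd.DataFrame,
    design: Sequence[SampleDesign],
    hybrid: str,
    deg_flags: Mapping[str, bool] | pd.Series,
) -> pd.DataFrame:
    """Classify every gene for one hybrid; flag the DEG-restricted subset.

    ``deg_flags`` marks genes differentially expressed between the hybrid
    and at least one parent; only those enter downstream summaries
    (``in_summary``), but every gene is classified and emitted.
    Genotype means reuse the same 0.5 zero-mean floor as the DE test.
    """
    if hybrid not in ("F1a", "F1b"):
        raise HeteroseqError(f"hybrid must be F1a or F1b, got {hybrid!r}")
    means = genotype_means(norm_counts, design)
    for g in (hybrid, "P1", "P2"):
        if g not in means.columns:
            raise HeteroseqError(f"genotype {g!r} missing from design/counts")
    h = means[hybrid].to_numpy(dtype=float)
    p1 = means["P1"].to_numpy(dtype=float)
    p2 = means["P2"].to_numpy(dtype=float)
    h = np.where(h == 0, ZERO_MEAN_FLOOR, h)
    p1 = np.where(p1 == 0, ZERO_MEAN_FLOOR, p1)
    p2 = np.where(p2 == 0, ZERO_MEAN_FLOOR, p2)
    a = np.log2(h / p1)
    b = np.log2(h / p2)
    flags = pd.Series(deg_flags).reindex(means.index).fillna(False).astype(bool)
    return pd.DataFrame(
        {
            "gene_id": means.index,
            "hybrid": hybrid,
            "log2_h_p1": a,
            "log2_h_p2": b,
            "klass": classify_points(a, b),
            "in_summary": flags.to_numpy(),
        }
    ).reset_index(drop=True)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_classes(records: pd.DataFrame | Mapping[str, int], hybrid: str = "F1a") -> dict:
    """Tally the eight divergent classes and their percentage shares.

    Accepts either an InheritanceRecord table (only rows with
    ``in_summary`` count) or a ready-made mapping class -> count.
    CONSERVED and UNCLASSIFIED_BOUNDARY never enter the denominator.
    Percentages are rounded half-up to 2 decimals. Also reports the
    combined dominance-up share (P1_DOM_UP + P2_DOM_UP) and the
    dominance-up-or-higher share (those plus TRANS_UP).
    """
    if isinstance(records, pd.DataFrame):
        sub = records[records["in_summary"]] if "in_summary" in records.columns else records
        tallies = sub["klass"].value_counts().to_dict()
        if "hybrid" in sub.columns and len(sub):
            hybrid = sub["hybrid"].iloc[0]
    else:
        tallies = dict(records)
    counts = {k: int(tallies.get(k, 0)) for k in EIGHT_CLASSES}
    total = sum(counts.values())
    if total == 0:
        raise HeteroseqError("no divergently expressed genes to summarize")
    percentages = {k: _round2(100.0 * v / total) for k, v in counts.items()}
    dom_up = counts["P1_DOM_UP"] + counts["P2_DOM_UP"]
    dom_up_or_higher = dom_up + counts["TRANS_UP"]
    return {
        "hybrid": hybrid,
        "counts": counts,
        "total": total,
        "percentages": percentages,
        "dominance_up_share": _round2(100.0 * dom_up / total),
        "dominance_up_or_higher_share": _round2(100.0 * dom_up_or_higher / total),
    }


def summary_to_frame(summary: dict) -> pd.DataFrame:
    """Flatten a class summary into a tidy one-row-per-class table."""
    rows = [
        {
            "hybrid": summary["hybrid"],
            "klass": k,
            "count": summary["counts"][k],
            "percentage": summary["percentages"][k],
        }
        for k in EIGHT_CLASSES
    ]
    return pd.DataFrame(rows, columns=["hybrid", "klass", "count", "percentage"])


def reciprocal_direction_summary(de_results: pd.DataFrame) -> dict:
    """Direction split of the reciprocal-hybrid DEGs (F1a as numerator).

    Returns counts and 1-decimal percentages of DEGs up- vs down-regulated
    in F1a relative to F1b; percentages are None when there are no DEGs.
    """
    degs = de_results[de_results["is_deg"]]
    n_up = int((degs["log2fc"] > 0).sum())
    n_down = int((degs["log2fc"] < 0).sum())
    total = n_up + n_down
    if total == 0:
        return {"n_up": 0, "n_down": 0, "pct_up": None, "pct_down": None}
    r1 = lambda x: float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return {
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": r1(100.0 * n_up / total),
        "pct_down": r1(100.0 * n_down / total),
    }
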