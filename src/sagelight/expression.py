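"""Per-gene expression in tags per 100,000 and Fisher-exact DEG calling.

Expression of a gene in one library is the number of uniquely mapped tags
falling in its sense 5'-UTR window, divided by the library's total of
uniquely genome-mapped tags, times 100,000 ("tphk"). Differential expression
between the two stages is tested per gene with the two-sided Fisher exact
test on the 2x2 table

    (count_myc, total_myc - count_myc)
    (count_pri, total_pri - count_pri)

at an unadjusted alpha of 0.05 by default (optional Benjamini-Hochberg).
Log2 expression ratios are computed Myc over S1-Pri after replacing a zero
tphk with a pseudo value (1.0 by default, which makes the ratio of a
one-sided gene simply log2 of its nonzero tphk).

The two-sided Fisher p-value uses the minimum-likelihood rule: the sum of
hypergeometric probabilities of all tables with the observed margins whose
point probability does not exceed the observed one (with a 1e-7 relative
tolerance for floating-point ties). For supports up to a few hundred the sum
is evaluated in exact integer arithmetic, making the tie rule exact; larger
tables fall back to scipy's implementation of the same rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

MYC_UP = "myc_up"
PRI_UP = "pri_up"
NO_DIRECTION = "none"

#: numerator/denominator of the relative tie tolerance 1 + 1e-7
_TIE_NUM = 10_000_001
_TIE_DEN = 10_000_000

#: largest support size handled by exact integer enumeration
_EXACT_SUPPORT_LIMIT = 512


@dataclass(frozen=True)
class DeConfig:
    alpha: float = 0.05
    pseudo_tphk: float = 1.0
    fold_threshold: float = 3.0
    adjust: Literal["none", "benjamini_hochberg"] = "none"
    #: which library total to use as the tphk denominator
    denominator: Literal["unique_mapped", "total_valid"] = "unique_mapped"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudo_tphk <= 0:
            raise ValueError("pseudo_tphk must be > 0")


@dataclass
class GeneExpression:
    gene_id: str
    count_myc: int
    count_pri: int
    total_myc: int
    total_pri: int
    tphk_myc: float = 0.0
    tphk_pri: float = 0.0
    p_value: float = 1.0
    log2_ratio: float = 0.0
    is_deg: bool = False
    deg_direction: str = NO_DIRECTION
    fold3_flag: bool = False


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table ((a, b), (c, d)).

    Degenerate margins (an empty row or column) return 1.0.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if hi - lo + 1 <= _EXACT_SUPPORT_LIMIT:
        ps = fisher_exact_margin_batch(r1, r2, c1)
        return ps[a - lo]
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact_margin_batch(r1: int, r2: int, c1: int) -> List[float]:
    """Two-sided p-values for every table with row sums (r1, r2) and first
    column sum c1, indexed by the top-left cell a over its support.

    Point probabilities are proportional to the integer weights
    w(a) = C(r1, a) * C(r2, c1 - a); the minimum-likelihood sum and its
    1e-7 relative tie tolerance are evaluated in exact integer arithmetic.
    """
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = range(lo, hi + 1)
    w = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in support]
    total = sum(w)
    order = sorted(range(len(w)), key=w.__getitem__)
    sorted_w = [w[i] for i in order]
    prefix = [0]
    for wi in sorted_w:
        prefix.append(prefix[-1] + wi)
    scaled = [wi * _TIE_DEN for wi in sorted_w]
    ps = []
    for wa in w:
        threshold = wa * _TIE_NUM
        # number of sorted weights with w * 1e7 <= wa * (1e7 + 1)
        n_in = _bisect_right(scaled, threshold)
        ps.append(prefix[n_in] / total)
    return ps


def _bisect_right(arr: List[int], x: int) -> int:
    lo, hi = 0, len(arr)
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# quantification

def quantify(
    counts: Dict[str, Tuple[int, int]],
    totals: Tuple[int, int],
    config: Optional[DeConfig] = None,
) -> List[GeneExpression]:
    """Convert per-gene tag counts to tags per 100,000.

    ``counts`` maps gene_id -> (count_myc, count_pri); ``totals`` are the
    per-stage library denominators (genome-mapped tag totals). Genes with
    zero counts in both stages are excluded from the assessed-gene list.
    """
    config = config or DeConfig()
    total_myc, total_pri = totals
    if total_myc <= 0 or total_pri <= 0:
        raise ValueError("library totals must be positive")
    out = []
    for gene_id in sorted(counts):
        c_myc, c_pri = counts[gene_id]
        if c_myc == 0 and c_pri == 0:
            continue
        out.append(GeneExpression(
            gene_id=gene_id,
            count_myc=c_myc, count_pri=c_pri,
            total_myc=total_myc, total_pri=total_pri,
            tphk_myc=c_myc / total_myc * 100_000,
            tphk_pri=c_pri / total_pri * 100_000,
        ))
    return out


def log2_ratio(tphk_myc: float, tphk_pri: float, pseudo_tphk: float = 1.0) -> float:
    """Log2 of Myc over S1-Pri expression, with zeros replaced by
    ``pseudo_tphk`` before taking the ratio."""
    if tphk_myc < 0 or tphk_pri < 0:
        raise ValueError("tphk values must be >= 0")
    num = tphk_myc if tphk_myc > 0 else pseudo_tphk
    den = tphk_pri if tphk_pri > 0 else pseudo_tphk
    return math.log2(num / den)


def call_degs(
    expressions: Sequence[GeneExpression],
    config: Optional[DeConfig] = None,
) -> Tuple[List[GeneExpression], Dict[str, dict]]:
    """Annotate each gene with its Fisher p-value, DEG call, direction,
    log2 ratio and >fold_threshold flag, plus a stage-level summary."""
    config = config or DeConfig()
    p_values = []
    for e in expressions:
        e.p_value = fisher_exact_2x2(
            e.count_myc, e.total_myc - e.count_myc,
            e.count_pri, e.total_pri - e.count_pri)
        p_values.append(e.p_value)
    if config.adjust == "benjamini_hochberg":
        effective = _benjamini_hochberg(p_values)
    else:
        effective = p_values
    for e, p_eff in zip(expressions, effective):
        e.log2_ratio = log2_ratio(e.tphk_myc, e.tphk_pri, config.pseudo_tphk)
        e.is_deg = p_eff < config.alpha
        if e.is_deg:
            e.deg_direction = MYC_UP if e.log2_ratio > 0 else PRI_UP
        else:
            e.deg_direction = NO_DIRECTION
        e.fold3_flag = e.is_deg and (
            abs(e.log2_ratio) > math.log2(config.fold_threshold))
    summary = _deg_summary(expressions, config)
    return list(expressions), summary


def _benjamini_hochberg(p: Sequence[float]) -> List[float]:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()


def _deg_summary(expressions: Sequence[GeneExpression], config: DeConfig) -> dict:
    assessed = len(expressions)
    expressed_myc = sum(1 for e in expressions if e.count_myc > 0)
    expressed_pri = sum(1 for e in expressions if e.count_pri > 0)
    deg_myc = [e for e in expressions if e.deg_direction == MYC_UP]
    deg_pri = [e for e in expressions if e.deg_direction == PRI_UP]

    def _block(degs, expressed):
        n = len(degs)
        fold = sum(1 for e in degs if e.fold3_flag)
        return {
            "expressed_genes": expressed,
            "degs": n,
            "degs_percent_of_expressed": 100.0 * n / expressed if expressed else 0.0,
            "degs_over_fold_threshold": fold,
            "fold_percent_of_degs": 100.0 * fold / n if n else 0.0,
        }

    return {
        "assessed_genes": assessed,
        "alpha": config.alpha,
        "fold_threshold": config.fold_threshold,
        "Myc": _block(deg_myc, expressed_myc),
        "S1-Pri": _block(deg_pri, expressed_pri),
    }


# ---------------------------------------------------------------------------
# tables

def expressions_to_frame(expressions: Sequence[GeneExpression]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": e.gene_id,
        "count_myc": e.count_myc, "count_pri": e.count_pri,
        "tphk_myc": e.tphk_myc, "tphk_pri": e.tphk_pri,
        "p_value": e.p_value, "log2_ratio": e.log2_ratio,
        "is_deg": e.is_deg, "deg_direction": e.deg_direction,
        "fold3_flag": e.fold3_flag,
    } for e in expressions])


def write_deg_tables(expressions: Sequence[GeneExpression], outdir) -> None:
    """Write the full expression table plus per-stage DEG lists ranked by
    log2 ratio, in the (gene, Myc tphk, S1-Pri tphk, log2 ratio) layout."""
    from pathlib import Path
    outdir = Path(outdir)
    df = expressions_to_frame(expressions)
    df.to_csv(outdir / "expression.tsv", sep="\t", index=False,
              float_format="%.6g")
    for direction, name, ascending in ((MYC_UP, "degs_myc.tsv", False),
                                       (PRI_UP, "degs_pri.tsv", True)):
        sub = df[df.deg_direction == direction].copy()
        sub = sub.sort_values("log2_ratio", ascending=ascending)
        sub[["gene_id", "tphk_myc", "tphk_pri", "log2_ratio", "p_value"]].to_csv(
            outdir / name, sep="\t", index=False, float_format="%.4g")
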