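"""Cross-platform agreement between 5'-SAGE, microarray and qPCR log2 ratios.

A platform panel is a table of per-gene log2 expression ratios (Myc over
S1-Pri) measured on up to three platforms; agreement is summarised as the
pairwise Pearson correlation over complete cases. A reference 18-gene panel
is shipped with the package so the validation stage runs offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

PLATFORM_COLUMNS = ("log2_ratio_sage", "log2_ratio_microarray", "log2_ratio_qpcr")
MIN_PAIRS = 3


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for constant input."""


def load_reference_panel() -> pd.DataFrame:
    """The packaged 18-gene cross-platform panel."""
    with resources.files("sagelight").joinpath(
            "data/cross_platform_panel.tsv").open() as fh:
        return read_panel(fh)


def read_panel(handle_or_path) -> pd.DataFrame:
    df = pd.read_csv(handle_or_path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("platform panel must have a gene_id column")
    if df.gene_id.duplicated().any():
        dupes = df.gene_id[df.gene_id.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in panel: {dupes}")
    return df


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length sequences.

    Pairs with a missing value are dropped (complete-case). Requires at
    least 3 complete pairs and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one platform's ratios")
    return float(sps.pearsonr(x, y)[0])


def validate_report(panel: pd.DataFrame) -> Dict[str, dict]:
    """All pairwise platform correlations with the complete-case n used.

    Pairs that cannot be correlated (a platform entirely missing, or fewer
    than 3 complete cases) are flagged unavailable rather than erroring.
    """
    report: Dict[str, dict] = {"n_genes": int(len(panel)), "pairs": {}}
    cols = [c for c in PLATFORM_COLUMNS if c in panel.columns]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            name = f"{_short(a)}_vs_{_short(b)}"
            x = pd.to_numeric(panel[a], errors="coerce")
            y = pd.to_numeric(panel[b], errors="coerce")
            n = int((~(x.isna() | y.isna())).sum())
            entry: dict = {"n": n}
            try:
                entry["r"] = pearson_correlation(x.to_numpy(), y.to_numpy())
                entry["available"] = True
            except ValueError as exc:
                entry["available"] = False
                entry["reason"] = str(exc)
            entry["scatter"] = [
                [float(xv), float(yv)]
                for xv, yv in zip(x, y)
                if not (np.isnan(xv) or np.isnan(yv))
            ]
            report["pairs"][name] = entry
    return report


def _short(column: str) -> str:
    return column.replace("log2_ratio_", "")
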