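"""Table formatting and report writers.

Reports mirror the layout of classical G x E analysis software: ANOVA rows
with significance stars (** for p < 0.01, * for p < 0.05), numbers rounded
to 4 decimals for display, and displayed p-values floored at 1e-7.  Every
display table is accompanied by a full-precision machine-readable CSV
sidecar so that no information is lost to rounding.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .ammi import AmmiResult
from .gge import GgeResult
from .ssp import SspAnovaTable

P_DISPLAY_FLOOR = 1e-7


def stars(p: float) -> str:
    """Significance marker: '**' below 0.01, '*' below 0.05, '' otherwise."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_p(p: float) -> str:
    """Display p-value, floored at 1e-7 (reported as '1e-07')."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    return f"{max(p, P_DISPLAY_FLOOR):.4g}"


def _fmt(x: float, nd: int = 4) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.{nd}f}"


def ssp_report(result: SspAnovaTable) -> pd.DataFrame:
    """Display frame of the 11-row split-split-plot ANOVA."""
    rows = []
    for _, r in result.table.iterrows():
        f_str = _fmt(r["F"]) + (" " + stars(r["p"]) if stars(r["p"]) else "")
        rows.append((r["source"], _fmt(r["ss"]), int(r["df"]), _fmt(r["ms"]),
                     f_str.strip(), format_p(r["p"])))
    return pd.DataFrame(
        rows, columns=["Source", "SS", "df", "MS", "F", "p"]
    )


def ammi_report(result: AmmiResult) -> pd.DataFrame:
    """Display frame of one temperature's AMMI ANOVA with SS percentages."""
    pct_total = result.percent_of_total
    pct_inter = result.percent_of_interaction
    rows = []
    for _, r in result.anova.iterrows():
        src = r["source"]
        pct = ""
        if src in pct_total:
            pct = _fmt(pct_total[src])
        elif src in pct_inter:
            pct = _fmt(pct_inter[src])
        f_str = _fmt(r["F"]) + (" " + stars(r["p"]) if stars(r["p"]) else "")
        rows.append((src, int(r["df"]), _fmt(r["ss"]), _fmt(r["ms"]),
                     f_str.strip(), format_p(r["p"]), pct))
    return pd.DataFrame(
        rows, columns=["Source", "df", "SS", "MS", "F", "Prob.", "% SS"]
    )


def gge_report(result: GgeResult) -> pd.DataFrame:
    """Display frame of GGE scores (PCA1-3 and distance from center)."""
    frame = result.scores_frame()
    out = frame.copy()
    for col in ("PCA1", "PCA2", "PCA3", "D_i"):
        out[col] = out[col].map(_fmt)
    return out


def write_report(display: pd.DataFrame, raw: pd.DataFrame, path: Path) -> list[Path]:
    """Write a display TSV plus a full-precision CSV sidecar.

    Returns the paths written (``<path>.tsv`` and ``<path>.full.csv``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tsv = path.with_suffix(".tsv")
    sidecar = path.with_suffix(".full.csv")
    display.to_csv(tsv, sep="\t", index=False)
    raw.to_csv(sidecar, index=False, float_format="%.17g")
    return [tsv, sidecar]
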