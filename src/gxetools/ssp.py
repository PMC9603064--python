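"""Split-split-plot analysis of variance for factorial expression experiments.

The design: temperature is the main-plot factor (hardest to randomize --
whole tanks are heated), tissue the subplot factor, gene the sub-subplot
factor, replicated in complete blocks.  The model is

    y_ihjk = mu + b_k + d_ihj + f_ik + g_ihk + e_ihjk

with fixed block effects ``b_k`` and treatment effects ``d_ihj`` (all main
effects and interactions of temperature x tissue x gene), and three
independent random error strata: main-plot error ``f_ik``, subplot error
``g_ihk``, and sub-subplot residual ``e_ihjk``.  Under balance the classical
closed-form sums of squares apply, and every F ratio is taken against the
error stratum at its own tier:

* temperature            vs  main-plot error
* tissue, temp x tissue  vs  split-plot error
* gene and every gene-containing interaction  vs  split-split-plot error

Blocks are reported without an F ratio.  Block x treatment interactions
beyond the three defined strata are pooled into those strata, the standard
convention that yields exactly three error rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BalanceError, InvalidInputError
from .expression import ExpressionTable

#: Row order of the ANOVA table.
SSP_SOURCES = [
    "Blocks",
    "Temperature",
    "Main-plot error",
    "Tissue",
    "Temperature x Tissue",
    "Split-plot error",
    "Gene",
    "Temperature x Gene",
    "Tissue x Gene",
    "Temperature x Tissue x Gene",
    "Split-split-plot error",
]

_F_DENOMINATOR = {
    "Temperature": "Main-plot error",
    "Tissue": "Split-plot error",
    "Temperature x Tissue": "Split-plot error",
    "Gene": "Split-split-plot error",
    "Temperature x Gene": "Split-split-plot error",
    "Tissue x Gene": "Split-split-plot error",
    "Temperature x Tissue x Gene": "Split-split-plot error",
}


@dataclass
class SspAnovaTable:
    """Ordered ANOVA rows (source, SS, df, MS, F, p) plus design bookkeeping."""

    table: pd.DataFrame
    total_ss: float
    total_df: int

    def row(self, source: str) -> pd.Series:
        match = self.table[self.table["source"] == source]
        if match.empty:
            raise KeyError(f"no ANOVA row named {source!r}")
        return match.iloc[0]

    def __getitem__(self, source: str) -> pd.Series:
        return self.row(source)


def _group_ss(df: pd.DataFrame, by: list[str], grand: float, weight: int) -> float:
    """weight * sum over groups of (group mean - grand)^2."""
    means = df.groupby(by, sort=False)["value"].mean()
    return float(weight * ((means - grand) ** 2).sum())


def fit_ssp_anova(table: ExpressionTable) -> SspAnovaTable:
    """Closed-form balanced split-split-plot ANOVA.

    Requires a complete balanced design with at least two blocks and at
    least two levels of every treatment factor (otherwise an error stratum
    would have zero degrees of freedom).
    """
    table.require_balanced()
    df = table.data
    k = len(table.blocks)
    t = len(table.temperatures)
    s = len(table.tissues)
    g = len(table.genes)
    if k < 2:
        raise BalanceError("split-split-plot ANOVA needs >= 2 replicate blocks")
    for n, label in ((t, "temperature"), (s, "tissue"), (g, "gene")):
        if n < 2:
            raise InvalidInputError(
                f"factor {label!r} has a single level; its error stratum "
                "would have zero degrees of freedom"
            )

    y = df["value"].to_numpy()
    grand = float(y.mean())
    ss_total = float(((y - grand) ** 2).sum())

    ss_blocks = _group_ss(df, ["block"], grand, t * s * g)
    ss_temp = _group_ss(df, ["temperature"], grand, k * s * g)
    ss_mpe = (
        _group_ss(df, ["temperature", "block"], grand, s * g)
        - ss_blocks - ss_temp
    )
    ss_tissue = _group_ss(df, ["tissue"], grand, k * t * g)
    ss_ts = (
        _group_ss(df, ["temperature", "tissue"], grand, k * g)
        - ss_temp - ss_tissue
    )
    ss_spe = (
        _group_ss(df, ["temperature", "tissue", "block"], grand, g)
        - ss_blocks - ss_temp - ss_mpe - ss_tissue - ss_ts
    )
    ss_gene = _group_ss(df, ["gene"], grand, k * t * s)
    ss_tg = (
        _group_ss(df, ["temperature", "gene"], grand, k * s)
        - ss_temp - ss_gene
    )
    ss_sg = (
        _group_ss(df, ["tissue", "gene"], grand, k * t)
        - ss_tissue - ss_gene
    )
    ss_tsg = (
        _group_ss(df, ["temperature", "tissue", "gene"], grand, k)
        - ss_temp - ss_tissue - ss_gene - ss_ts - ss_tg - ss_sg
    )
    partial = (ss_blocks + ss_temp + ss_mpe + ss_tissue + ss_ts + ss_spe
               + ss_gene + ss_tg + ss_sg + ss_tsg)
    ss_sspe = ss_total - partial

    rows = {
        "Blocks": (ss_blocks, k - 1),
        "Temperature": (ss_temp, t - 1),
        "Main-plot error": (ss_mpe, (k - 1) * (t - 1)),
        "Tissue": (ss_tissue, s - 1),
        "Temperature x Tissue": (ss_ts, (t - 1) * (s - 1)),
        "Split-plot error": (ss_spe, t * (k - 1) * (s - 1)),
        "Gene": (ss_gene, g - 1),
        "Temperature x Gene": (ss_tg, (t - 1) * (g - 1)),
        "Tissue x Gene": (ss_sg, (s - 1) * (g - 1)),
        "Temperature x Tissue x Gene": (ss_tsg, (t - 1) * (s - 1) * (g - 1)),
        "Split-split-plot error": (ss_sspe, t * s * (k - 1) * (g - 1)),
    }

    ms = {src: ss / dof for src, (ss, dof) in rows.items()}
    out = []
    for src in SSP_SOURCES:
        ss, dof = rows[src]
        f_val = p_val = np.nan
        denom = _F_DENOMINATOR.get(src)
        if denom is not None and ms[denom] > 0:
            denom_ms = ms[denom]
            denom_df = rows[denom][1]
            f_val = ms[src] / denom_ms
            p_val = float(stats.f.sf(f_val, dof, denom_df))
        out.append((src, ss, dof, ms[src], f_val, p_val))

    frame = pd.DataFrame(out, columns=["source", "ss", "df", "ms", "F", "p"])
    return SspAnovaTable(table=frame, total_ss=ss_total, total_df=len(y) - 1)
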