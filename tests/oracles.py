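"""Independent brute-force oracles used to check the matrix implementations.

Everything here is deliberately naive: explicit loops over the textbook
definitions of each sum of squares, and dense eigendecompositions where the
implementation uses an SVD.  Nothing imports the code paths under test
beyond the shared table container.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ssp_ss_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Split-split-plot sums of squares by explicit summation.

    Expects the tidy columns ``temperature,tissue,gene,block,value`` of a
    balanced design.  Returns SS per ANOVA source.
    """
    temps = list(dict.fromkeys(df["temperature"]))
    tissues = list(dict.fromkeys(df["tissue"]))
    genes = list(dict.fromkeys(df["gene"]))
    blocks = sorted(set(df["block"]))
    t, s, g, k = len(temps), len(tissues), len(genes), len(blocks)

    y = {}
    for _, row in df.iterrows():
        y[(row["temperature"], row["tissue"], row["gene"], row["block"])] = row["value"]

    def mean(sel):
        vals = [v for key, v in y.items() if sel(key)]
        return sum(vals) / len(vals)

    grand = mean(lambda key: True)

    ss = {}
    ss["Blocks"] = t * s * g * sum(
        (mean(lambda key, b=b: key[3] == b) - grand) ** 2 for b in blocks)
    ss["Temperature"] = k * s * g * sum(
        (mean(lambda key, i=i: key[0] == i) - grand) ** 2 for i in temps)
    ss_ik = s * g * sum(
        (mean(lambda key, i=i, b=b: key[0] == i and key[3] == b) - grand) ** 2
        for i in temps for b in blocks)
    ss["Main-plot error"] = ss_ik - ss["Blocks"] - ss["Temperature"]
    ss["Tissue"] = k * t * g * sum(
        (mean(lambda key, h=h: key[1] == h) - grand) ** 2 for h in tissues)
    ss_ih = k * g * sum(
        (mean(lambda key, i=i, h=h: key[0] == i and key[1] == h) - grand) ** 2
        for i in temps for h in tissues)
    ss["Temperature x Tissue"] = ss_ih - ss["Temperature"] - ss["Tissue"]
    ss_ihk = g * sum(
        (mean(lambda key, i=i, h=h, b=b: key[:2] == (i, h) and key[3] == b) - grand) ** 2
        for i in temps for h in tissues for b in blocks)
    ss["Split-plot error"] = (
        ss_ihk - ss["Blocks"] - ss["Temperature"] - ss["Main-plot error"]
        - ss["Tissue"] - ss["Temperature x Tissue"])
    ss["Gene"] = k * t * s * sum(
        (mean(lambda key, j=j: key[2] == j) - grand) ** 2 for j in genes)
    ss_ij = k * s * sum(
        (mean(lambda key, i=i, j=j: key[0] == i and key[2] == j) - grand) ** 2
        for i in temps for j in genes)
    ss["Temperature x Gene"] = ss_ij - ss["Temperature"] - ss["Gene"]
    ss_hj = k * t * sum(
        (mean(lambda key, h=h, j=j: key[1] == h and key[2] == j) - grand) ** 2
        for h in tissues for j in genes)
    ss["Tissue x Gene"] = ss_hj - ss["Tissue"] - ss["Gene"]
    ss_ihj = k * sum(
        (mean(lambda key, i=i, h=h, j=j: key[:3] == (i, h, j)) - grand) ** 2
        for i in temps for h in tissues for j in genes)
    ss["Temperature x Tissue x Gene"] = (
        ss_ihj - ss["Temperature"] - ss["Tissue"] - ss["Gene"]
        - ss["Temperature x Tissue"] - ss["Temperature x Gene"] - ss["Tissue x Gene"])
    ss_total = sum((v - grand) ** 2 for v in y.values())
    ss["Split-split-plot error"] = ss_total - sum(ss.values())
    ss["Total"] = ss_total
    return ss


def ammi_ss_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Gene/Tissue/Interaction/Error SS of a replicated two-way table by loops."""
    genes = list(dict.fromkeys(df["gene"]))
    tissues = list(dict.fromkeys(df["tissue"]))
    blocks = sorted(set(df["block"]))
    g, e, r = len(genes), len(tissues), len(blocks)

    cell = {}
    for gi in genes:
        for ei in tissues:
            vals = df[(df["gene"] == gi) & (df["tissue"] == ei)]["value"].tolist()
            cell[(gi, ei)] = vals
    grand = sum(v for vals in cell.values() for v in vals) / (g * e * r)
    gene_mean = {gi: sum(v for ei in tissues for v in cell[(gi, ei)]) / (e * r)
                 for gi in genes}
    tissue_mean = {ei: sum(v for gi in genes for v in cell[(gi, ei)]) / (g * r)
                   for ei in tissues}
    cell_mean = {key: sum(vals) / r for key, vals in cell.items()}

    ss = {}
    ss["Gene"] = e * r * sum((gene_mean[gi] - grand) ** 2 for gi in genes)
    ss["Tissue"] = g * r * sum((tissue_mean[ei] - grand) ** 2 for ei in tissues)
    ss["Interaction"] = r * sum(
        (cell_mean[(gi, ei)] - gene_mean[gi] - tissue_mean[ei] + grand) ** 2
        for gi in genes for ei in tissues)
    ss["Error"] = sum(
        (v - cell_mean[key]) ** 2 for key, vals in cell.items() for v in vals)
    ss["Total"] = sum(
        (v - grand) ** 2 for vals in cell.values() for v in vals)
    ss["Treatment"] = r * sum(
        (cell_mean[key] - grand) ** 2 for key in cell)
    return ss


def gge_variance_shares_oracle(matrix: np.ndarray) -> np.ndarray:
    """Axis variance shares of the column-centered matrix via eigendecomposition.

    Eigenvalues of the centered cross-product equal the squared singular
    values; shares are returned in decreasing order as fractions of 1.
    """
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    cross = centered.T @ centered
    eig = np.linalg.eigvalsh(cross)[::-1]
    eig = np.clip(eig, 0.0, None)
    return eig / eig.sum()
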