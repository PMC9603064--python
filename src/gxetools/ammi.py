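"""Additive main effects and multiplicative interaction (AMMI) analysis.

For one temperature, the replicated gene x tissue table is modelled as

    y_ge = mu + alpha_g + beta_e + sum_n lambda_n gamma_gn delta_en + theta_ge

where ``alpha_g`` and ``beta_e`` are the gene (genotype) and tissue
(environment) main effects -- each level mean minus the grand mean -- and the
multiplicative terms come from the singular value decomposition of the
doubly-centered interaction residual matrix

    z_ge = mean_ge - gene mean_g - tissue mean_e + grand mean.

Sums of squares are expressed on the replicate-observation scale: the
means-based SS are multiplied by the replicate count ``r``, so that the
interaction SS equals ``r * sum_n lambda_n**2`` and the within-cell (pure
error) stratum keeps its ``g*e*(r-1)`` degrees of freedom.  Each interaction
principal-component axis (IPCA) is F-tested with Gollob degrees of freedom
``g + e - 1 - 2n`` against the pooled within-cell error mean square.  The
Gollob test is known to be liberal under the null (the first axis of a pure
noise matrix soaks up more than its nominal share of SS); see the package
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .expression import ExpressionTable, cell_means


def gollob_df(g: int, e: int, n: int) -> int:
    """Degrees of freedom of the n-th IPCA axis for g genotypes, e environments.

    ``df_n = g + e - 1 - 2n``; valid for ``1 <= n <= min(g, e) - 1``.
    """
    if min(g, e) < 2:
        raise InvalidInputError("need at least 2 genotypes and 2 environments")
    if not 1 <= n <= min(g, e) - 1:
        raise InvalidInputError(
            f"axis index n={n} out of range 1..{min(g, e) - 1} for g={g}, e={e}"
        )
    return g + e - 1 - 2 * n


@dataclass
class AmmiResult:
    """Decomposition of one temperature's gene x tissue table.

    ``gene_scores`` and ``tissue_scores`` hold the unit-norm singular
    vectors, one column per axis (all ``min(g,e)-1`` axes, not only the
    retained ones); display scaling is applied at reporting time.  The
    ANOVA frame pools axes beyond ``n_axes`` into the Residual row.
    """

    temperature: str
    genes: list[str]
    tissues: list[str]
    replicates: int
    n_axes: int
    grand_mean: float
    genotype_effects: np.ndarray     # alpha_g
    tissue_effects: np.ndarray       # beta_e
    interaction: np.ndarray          # z_ge, doubly centered
    singular_values: np.ndarray      # all min(g,e)-1 values, non-increasing
    gene_scores: np.ndarray          # g x n_all, unit-norm columns
    tissue_scores: np.ndarray        # e x n_all, unit-norm columns
    anova: pd.DataFrame = field(repr=False)

    def row(self, source: str) -> pd.Series:
        match = self.anova[self.anova["source"] == source]
        if match.empty:
            raise KeyError(f"no ANOVA row named {source!r}")
        return match.iloc[0]

    def __getitem__(self, source: str) -> pd.Series:
        return self.row(source)

    @property
    def percent_of_total(self) -> dict[str, float]:
        """% of total SS contributed by each main effect and the interaction."""
        total = self.row("Total")["ss"]
        return {
            src: 100.0 * self.row(src)["ss"] / total
            for src in ("Gene", "Tissue", "Interaction")
        }

    @property
    def percent_of_interaction(self) -> dict[str, float]:
        """% of interaction SS captured by each retained IPCA axis."""
        inter = self.row("Interaction")["ss"]
        return {
            f"IPCA{n}": 100.0 * self.row(f"IPCA{n}")["ss"] / inter
            for n in range(1, self.n_axes + 1)
        }


def _orient_axes(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix SVD sign indeterminacy: largest-|entry| of each tissue vector positive."""
    for n in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, n])))
        if v[j, n] < 0:
            v[:, n] = -v[:, n]
            u[:, n] = -u[:, n]
    return u, v


def ammi_decompose(
    table: ExpressionTable,
    temperature: str,
    n_axes: int = 2,
) -> AmmiResult:
    """AMMI analysis of the replicated gene x tissue data at one temperature.

    Requires a balanced design with ``r >= 2`` replicate blocks (the pure
    error stratum needs ``g*e*(r-1) > 0`` degrees of freedom).  ``n_axes``
    axes are tested individually; the rest are pooled into Residual.
    """
    means = cell_means(table, temperature)
    r = means.replicates
    if r < 2:
        raise InvalidInputError(
            "AMMI needs >= 2 replicate blocks to form the within-cell error "
            "stratum; supply replicated data"
        )
    g, e = len(means.genes), len(means.tissues)
    n_max = min(g, e) - 1
    if not 1 <= n_axes <= n_max:
        raise InvalidInputError(
            f"n_axes={n_axes} out of range 1..{n_max} for g={g}, e={e}"
        )

    m = means.means
    grand = float(m.mean())
    gene_means = m.mean(axis=1)
    tissue_means = m.mean(axis=0)
    alpha = gene_means - grand
    beta = tissue_means - grand
    z = m - gene_means[:, None] - tissue_means[None, :] + grand

    u, svals, vt = np.linalg.svd(z, full_matrices=False)
    u, v = _orient_axes(u[:, :n_max].copy(), vt.T[:, :n_max].copy())
    svals = svals[:n_max]

    # observation-scale sums of squares
    df_sub = table._subset(temperature)
    values = df_sub["value"].to_numpy()
    ss_total = float(((values - grand) ** 2).sum())
    ss_treat = float(r * ((m - grand) ** 2).sum())
    ss_gene = float(r * e * (alpha ** 2).sum())
    ss_tissue = float(r * g * (beta ** 2).sum())
    ss_inter = float(r * (z ** 2).sum())
    ss_error = ss_total - ss_treat  # pooled within-cell SS
    ss_axes = r * svals ** 2

    df_error = g * e * (r - 1)
    ms_error = ss_error / df_error

    rows: list[tuple] = []

    def add(source, dof, ss, tested=True):
        ms = ss / dof if dof > 0 else np.nan
        if tested and dof > 0 and ms_error > 0:
            f_val = ms / ms_error
            p_val = float(stats.f.sf(f_val, dof, df_error))
        else:
            f_val = p_val = np.nan
        rows.append((source, dof, ss, ms, f_val, p_val))

    add("Total", g * e * r - 1, ss_total, tested=False)
    add("Treatment", g * e - 1, ss_treat)
    add("Gene", g - 1, ss_gene)
    add("Tissue", e - 1, ss_tissue)
    add("Interaction", (g - 1) * (e - 1), ss_inter)
    used_df = 0
    for n in range(1, n_axes + 1):
        dof = gollob_df(g, e, n)
        used_df += dof
        add(f"IPCA{n}", dof, float(ss_axes[n - 1]))
    resid_df = (g - 1) * (e - 1) - used_df
    resid_ss = float(ss_axes[n_axes:].sum())
    add("Residual", resid_df, resid_ss, tested=False)
    add("Error", df_error, ss_error, tested=False)

    anova = pd.DataFrame(rows, columns=["source", "df", "ss", "ms", "F", "p"])
    return AmmiResult(
        temperature=str(temperature),
        genes=means.genes,
        tissues=means.tissues,
        replicates=r,
        n_axes=n_axes,
        grand_mean=grand,
        genotype_effects=alpha,
        tissue_effects=beta,
        interaction=z,
        singular_values=svals,
        gene_scores=u,
        tissue_scores=v,
        anova=anova,
    )


def contribution_profile(results: Sequence[AmmiResult]) -> pd.DataFrame:
    """Per-temperature genotype / tissue / interaction contributions (% of total SS).

    Ordered as given; suitable for plotting effect-contribution trends
    across the temperature series.
    """
    if len(results) == 0:
        raise InvalidInputError("need at least one AmmiResult")
    rows = []
    for res in results:
        pct = res.percent_of_total
        rows.append((res.temperature, pct["Gene"], pct["Tissue"], pct["Interaction"]))
    return pd.DataFrame(
        rows, columns=["temperature", "genotype_pct", "tissue_pct", "interaction_pct"]
    )
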