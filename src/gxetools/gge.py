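"""GGE biplot analysis: environment-centered SVD and biplot geometry.

The GGE model keeps genotype main effect and genotype x environment
interaction together: each tissue (environment) column of the gene x tissue
mean table is centered by its own mean, removing ``mu + beta_e`` and leaving
``G + GE``, which is then decomposed by SVD:

    y_ge - mean_e = sum_n lambda_n gamma_gn delta_en + theta_ge

Scores for plotting depend on how the singular values are split between the
gene and tissue sides (the singular-value partition ``f``): gene scores are
``lambda^f * gamma`` and tissue scores ``lambda^(1-f) * delta``, so the inner
product -- and every rank-based reading of the biplot -- is independent of
``f``.

Four standard readings of the planar (PC1-PC2) biplot are implemented as
geometry, not images:

* tissue relationships -- angles between tissue vectors approximate the
  correlation of gene rankings; vector length is discriminating ability;
* which-won-where -- the convex-hull polygon of gene scores with
  perpendicular sector boundaries; the vertex gene of a sector has the
  highest centered expression in every tissue of that sector;
* mean vs stability -- projections on the average-tissue axis estimate mean
  expression, orthogonal deviations estimate instability;
* ideal-point (concentric circles) -- distance to a hypothetical gene with
  maximal mean projection and zero instability ranks genes jointly on level
  and stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .expression import TwoWayMeans

PARTITIONS = {"symmetric": 0.5, "genotype-focused": 1.0, "environment-focused": 0.0}


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class GgeResult:
    """Environment-centered SVD of a gene x tissue mean table, 3 axes retained.

    ``gene_scores`` (g x 3) and ``tissue_scores`` (e x 3) carry the chosen
    singular-value partition.  When built from externally supplied scores
    (e.g. a published table) the singular values may be absent and only the
    score-based geometry is available.
    """

    genes: list[str]
    tissues: list[str]
    gene_scores: np.ndarray
    tissue_scores: np.ndarray
    singular_values: np.ndarray | None = None
    variance_explained: np.ndarray | None = None
    partition: str = "symmetric"
    temperature: str = ""
    centered: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gene_scores = np.atleast_2d(np.asarray(self.gene_scores, float))
        self.tissue_scores = np.atleast_2d(np.asarray(self.tissue_scores, float))
        if self.gene_scores.shape != (len(self.genes), 3):
            raise InvalidInputError(
                f"gene_scores shape {self.gene_scores.shape} != ({len(self.genes)}, 3)"
            )
        if self.tissue_scores.shape != (len(self.tissues), 3):
            raise InvalidInputError(
                f"tissue_scores shape {self.tissue_scores.shape} != ({len(self.tissues)}, 3)"
            )

    @classmethod
    def from_scores(
        cls,
        genes: list[str],
        tissues: list[str],
        gene_scores,
        tissue_scores,
        temperature: str = "",
    ) -> "GgeResult":
        """Build a result from already-partitioned score triples.

        Used when scores come from an external source (a published score
        table); all rank-based geometry applies unchanged because it is
        invariant to the singular-value partition.
        """
        return cls(
            genes=list(genes), tissues=list(tissues),
            gene_scores=np.asarray(gene_scores, float),
            tissue_scores=np.asarray(tissue_scores, float),
            temperature=temperature, partition="external",
        )

    # -- distances -----------------------------------------------------------
    @property
    def gene_distances(self) -> pd.Series:
        d = [distance_from_center(s) for s in self.gene_scores]
        return pd.Series(d, index=self.genes, name="D_i")

    @property
    def tissue_distances(self) -> pd.Series:
        d = [distance_from_center(s) for s in self.tissue_scores]
        return pd.Series(d, index=self.tissues, name="D_i")

    def scores_frame(self) -> pd.DataFrame:
        """Long frame of PC1-PC3 scores and D_i for genes then tissues."""
        rows = []
        for name, s in zip(self.genes, self.gene_scores):
            rows.append(("gene", name, *s, distance_from_center(s)))
        for name, s in zip(self.tissues, self.tissue_scores):
            rows.append(("tissue", name, *s, distance_from_center(s)))
        return pd.DataFrame(
            rows, columns=["kind", "label", "PCA1", "PCA2", "PCA3", "D_i"]
        )


def distance_from_center(scores) -> float:
    """Euclidean norm of a 3-axis score vector (distance from biplot origin)."""
    s = np.asarray(scores, dtype=float)
    if s.shape != (3,):
        raise InvalidInputError(f"expected 3 scores, got shape {s.shape}")
    if not np.isfinite(s).all():
        raise InvalidInputError("scores must be finite")
    return float(np.linalg.norm(s))


def gge_decompose(
    means: TwoWayMeans,
    partition: str = "symmetric",
) -> GgeResult:
    """Environment-centered SVD of the mean table with 3 retained axes.

    Each tissue column is centered by its own mean; the centered matrix has
    rank at most ``min(g - 1, e)``, so for a 4-gene study three axes carry
    the entire G + GE signal.  Axes beyond the matrix rank get zero scores.
    A constant (all-equal-columns-up-to-column-means) matrix yields all-zero
    scores, which is a valid degenerate result, not an error.
    """
    if partition not in PARTITIONS:
        raise InvalidInputError(
            f"unknown partition {partition!r}; choose from {sorted(PARTITIONS)}"
        )
    f = PARTITIONS[partition]
    m = means.means
    g, e = m.shape
    if g < 2 or e < 2:
        raise InvalidInputError("GGE needs at least 2 genes and 2 tissues")
    centered = m - m.mean(axis=0, keepdims=True)

    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # truncate numerically-zero axes so degenerate data gives exact zeros
    svals = np.where(svals > 1e-12 * max(svals[0], 1e-300), svals, 0.0)
    # orient each axis: largest-|entry| tissue score positive
    v = vt.T
    for n in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, n])))
        if v[j, n] < 0:
            v[:, n] = -v[:, n]
            u[:, n] = -u[:, n]

    n_keep = 3
    lam = np.zeros(n_keep)
    gene_scores = np.zeros((g, n_keep))
    tissue_scores = np.zeros((e, n_keep))
    avail = min(n_keep, len(svals))
    lam[:avail] = svals[:avail]
    with np.errstate(divide="ignore", invalid="ignore"):
        for n in range(avail):
            if svals[n] > 0:
                gene_scores[:, n] = (svals[n] ** f) * u[:, n]
                tissue_scores[:, n] = (svals[n] ** (1.0 - f)) * v[:, n]
    total_var = float((svals ** 2).sum())
    var_exp = (
        lam ** 2 / total_var * 100.0 if total_var > 0 else np.zeros(n_keep)
    )
    return GgeResult(
        genes=list(means.genes), tissues=list(means.tissues),
        gene_scores=gene_scores, tissue_scores=tissue_scores,
        singular_values=lam, variance_explained=var_exp,
        partition=partition, temperature=means.temperature,
        centered=centered,
    )


# ---------------------------------------------------------------------------
# biplot view 1: relationships among tissues
# ---------------------------------------------------------------------------

@dataclass
class TissueRelationships:
    """Pairwise angles/cosines of tissue vectors on the PC1-PC2 plane."""

    tissues: list[str]
    cosine: pd.DataFrame
    angle_deg: pd.DataFrame
    vector_length: pd.Series
    degenerate: list[str]  # zero-length tissues whose angles are undefined


def tissue_relationships(result: GgeResult) -> TissueRelationships:
    """Angles between tissue vectors (ranking correlation) and their lengths.

    An acute angle means the two tissues rank the genes similarly, a right
    angle means unrelated rankings, an obtuse angle opposed rankings; a
    longer vector marks a tissue that discriminates the genes more strongly.
    Zero-length tissue vectors are flagged: their angles are undefined (NaN),
    not an error.
    """
    planar = result.tissue_scores[:, :2]
    lengths = np.linalg.norm(planar, axis=1)
    degenerate = [t for t, l in zip(result.tissues, lengths) if l == 0.0]
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = planar / lengths[:, None]
    cos = unit @ unit.T
    cos = np.clip(cos, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    idx = result.tissues
    return TissueRelationships(
        tissues=list(idx),
        cosine=pd.DataFrame(cos, index=idx, columns=idx),
        angle_deg=pd.DataFrame(ang, index=idx, columns=idx),
        vector_length=pd.Series(lengths, index=idx, name="length"),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# biplot view 2: which-won-where
# ---------------------------------------------------------------------------

@dataclass
class SectorAssignment:
    """Polygon-view partition of the biplot plane.

    ``hull`` lists the vertex genes in counter-clockwise angular order;
    ``boundary_angles`` the sector-boundary rays (radians, one per hull
    edge, perpendicular to that edge); ``tissue_winner`` maps every tissue
    to the vertex gene with the highest projection on it; ``sectors`` groups
    tissues by winner (unoccupied sectors simply do not appear).
    ``degenerate`` is set when all gene points are collinear and the plane
    splits into two half-plane sectors.
    """

    hull: list[str]
    boundary_angles: list[float]
    tissue_winner: dict[str, str]
    sectors: dict[str, list[str]]
    degenerate: bool = False


def _collinear(points: np.ndarray, tol: float = 1e-12) -> bool:
    if len(points) < 3:
        return True
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    return s[-1] <= tol * scale


def _hull_ccw(points: np.ndarray) -> list[int]:
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    return list(hull.vertices)  # already counter-clockwise for 2-D


def which_won_where(result: GgeResult) -> SectorAssignment:
    """Convex-hull sector partition of the planar biplot.

    Every tissue is assigned to the hull-vertex gene maximizing the inner
    product of their planar scores; this is exactly the sector membership
    induced by the perpendicular boundary rays, and the winning gene has
    the highest centered expression in each of its tissues whenever the
    planar biplot captures the data (exact for rank <= 2).  Projection ties
    are broken by gene label order (arbitrary, documented).
    """
    pts = result.gene_scores[:, :2]
    tissues_pl = result.tissue_scores[:, :2]
    genes = result.genes

    degenerate = _collinear(pts)
    if degenerate:
        # two half-plane sectors: the extremes along the dominant direction
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        direction = vt[0]
        proj = pts @ direction
        order = np.argsort(proj)
        hull_idx = [int(order[0]), int(order[-1])]
        if hull_idx[0] == hull_idx[1]:  # all genes coincide
            hull_idx = [int(order[0])]
        boundary = [math.atan2(direction[0], -direction[1])] if len(hull_idx) == 2 else []
    else:
        hull_idx = _hull_ccw(pts)
        boundary = []
        for a, b in zip(hull_idx, hull_idx[1:] + hull_idx[:1]):
            edge = pts[b] - pts[a]
            # perpendicular to the edge, pointing away from the origin side
            perp = np.array([edge[1], -edge[0]])
            mid = 0.5 * (pts[a] + pts[b])
            if perp @ mid < 0:
                perp = -perp
            boundary.append(math.atan2(perp[1], perp[0]))

    hull_genes = [genes[i] for i in hull_idx]
    tissue_winner: dict[str, str] = {}
    for tname, tvec in zip(result.tissues, tissues_pl):
        projections = {genes[i]: float(pts[i] @ tvec) for i in hull_idx}
        best = max(projections.values())
        winners = sorted(gn for gn, p in projections.items() if p == best)
        tissue_winner[tname] = winners[0]
    sectors: dict[str, list[str]] = {}
    for tname, gname in tissue_winner.items():
        sectors.setdefault(gname, []).append(tname)
    return SectorAssignment(
        hull=hull_genes,
        boundary_angles=boundary,
        tissue_winner=tissue_winner,
        sectors=sectors,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# biplot views 3-4: mean vs stability, ideal point
# ---------------------------------------------------------------------------

@dataclass
class MeanStability:
    """Average-tissue-axis reading of the planar biplot.

    ``mean_projection`` approximates each gene's average centered expression
    across tissues; ``instability`` is the absolute deviation orthogonal to
    the axis.  Rankings: descending projection (high expression), ascending
    instability (stable expression).
    """

    axis: np.ndarray  # unit 2-vector, direction of the mean tissue score
    mean_projection: pd.Series
    instability: pd.Series
    ranking_high: list[str]
    ranking_stable: list[str]


def mean_vs_stability(result: GgeResult) -> MeanStability:
    """Project gene scores on the average-tissue axis; split level from stability."""
    tissues_pl = result.tissue_scores[:, :2]
    axis = tissues_pl.mean(axis=0)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise InvalidInputError(
            "mean tissue score vector is zero; the average-tissue axis is undefined"
        )
    axis = axis / nrm
    orth = np.array([-axis[1], axis[0]])
    pts = result.gene_scores[:, :2]
    proj = pd.Series(pts @ axis, index=result.genes, name="mean_projection")
    instab = pd.Series(np.abs(pts @ orth), index=result.genes, name="instability")
    ranking_high = list(proj.sort_values(ascending=False, kind="stable").index)
    ranking_stable = list(instab.sort_values(ascending=True, kind="stable").index)
    return MeanStability(
        axis=axis,
        mean_projection=proj,
        instability=instab,
        ranking_high=ranking_high,
        ranking_stable=ranking_stable,
    )


@dataclass
class IdealPointRanking:
    """Concentric-circles view: distance of each gene to the ideal point."""

    ideal: np.ndarray  # planar coordinates of the ideal point
    distance: pd.Series
    ranking: list[str]


def ideal_point_ranking(result: GgeResult) -> IdealPointRanking:
    """Rank genes by distance to the ideal (max mean projection, zero instability).

    The ideal point sits on the average-tissue axis at the largest observed
    gene projection; smaller distance means jointly higher and more stable
    expression.  The ranking is invariant under rigid rotations and axis
    sign flips of the planar scores.
    """
    ms = mean_vs_stability(result)
    best = float(ms.mean_projection.max())
    ideal = best * ms.axis
    pts = result.gene_scores[:, :2]
    dist = np.linalg.norm(pts - ideal[None, :], axis=1)
    distance = pd.Series(dist, index=result.genes, name="distance_to_ideal")
    ranking = list(distance.sort_values(ascending=True, kind="stable").index)
    return IdealPointRanking(ideal=ideal, distance=distance, ranking=ranking)


# ---------------------------------------------------------------------------
# rankings across temperatures
# ---------------------------------------------------------------------------

def ranking_table(results: dict[str, GgeResult]) -> pd.DataFrame:
    """Per-temperature gene orderings by level, stability, and both combined.

    Returns a long frame with columns ``temperature, criterion, rank, gene``
    where criterion is one of ``high`` (descending mean projection),
    ``stable`` (ascending instability), ``comprehensive`` (ascending
    ideal-point distance).  Each ordering is a permutation of the gene set.
    """
    rows = []
    for temp, res in results.items():
        ms = mean_vs_stability(res)
        ip = ideal_point_ranking(res)
        for crit, order in (
            ("high", ms.ranking_high),
            ("stable", ms.ranking_stable),
            ("comprehensive", ip.ranking),
        ):
            for rank, gene in enumerate(order, start=1):
                rows.append((temp, crit, rank, gene))
    return pd.DataFrame(rows, columns=["temperature", "criterion", "rank", "gene"])
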