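"""Synthetic expression tables with known ground truth.

Two generators mirror the two model families the package fits:

* :func:`simulate_two_way` draws replicated gene x tissue data from the
  additive-main-effects-plus-multiplicative-interaction model
  ``y_ge = mu + alpha_g + beta_e + sum_n lambda_n gamma_gn delta_en + noise``,
  so AMMI and GGE fits can be checked against planted effects and singular
  structure.

* :func:`simulate_ssp` draws a full split-split-plot layout
  (temperature = main plot, tissue = subplot, gene = sub-subplot) with three
  independent error strata, matching the variance ladder the SSP ANOVA
  estimates.

The module-level ``study_*_spec`` constructors reproduce the dimensions of
the turbot PPAR experiment (4 genes x 10 tissues x 5 temperatures x 3
replicate blocks) with effect and noise magnitudes on the scale of that
study's printed variance decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .expression import ExpressionTable

_ZERO_SUM_TOL = 1e-10

STUDY_GENES = ["PPARa1", "PPARa2", "PPARb", "PPARg"]
STUDY_TISSUES = [
    "intestine", "liver", "gill", "heart", "kidney",
    "brain", "muscle", "spleen", "skin", "stomach",
]
STUDY_TEMPERATURES = ["14", "20", "23", "25", "28"]


def _check_zero_sum(arr: np.ndarray, name: str) -> None:
    arr = np.asarray(arr, dtype=float)
    sums = arr
    for axis in range(arr.ndim):
        if np.abs(arr.sum(axis=axis)).max() > _ZERO_SUM_TOL * max(1.0, np.abs(arr).max()):
            raise SpecError(f"{name} must sum to zero over every index")


def _orthonormal_zero_sum(vectors: list[np.ndarray], name: str) -> list[np.ndarray]:
    """Gram-Schmidt within the zero-sum subspace; rejects near-dependent input."""
    out: list[np.ndarray] = []
    for k, v in enumerate(vectors):
        v = np.asarray(v, dtype=float).copy()
        if abs(v.sum()) > _ZERO_SUM_TOL * max(1.0, np.abs(v).max()):
            raise SpecError(f"{name}[{k}] must sum to zero")
        for u in out:
            v -= (v @ u) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-8:
            raise SpecError(f"{name}[{k}] is linearly dependent on earlier vectors")
        out.append(v / nrm)
    return out


# ---------------------------------------------------------------------------
# two-way (AMMI-structured) generator
# ---------------------------------------------------------------------------

@dataclass
class TwoWaySimSpec:
    """Ground truth for a replicated gene x tissue table.

    ``multiplicative_terms`` is a list of ``(lambda_n, gamma_n, delta_n)``
    triples: a non-negative singular value with zero-sum gene and tissue
    score vectors.  Vectors are orthonormalized internally (within the
    zero-sum subspace) so that the planted decomposition is a valid SVD.
    """

    mu: float
    genotype_effects: np.ndarray
    tissue_effects: np.ndarray
    multiplicative_terms: list[tuple[float, np.ndarray, np.ndarray]] = field(default_factory=list)
    sigma: float = 0.0
    replicates: int = 3
    seed: int = 0
    genes: list[str] | None = None
    tissues: list[str] | None = None
    temperature: str = "sim"
    noise: str = "gaussian"  # or "lognormal" (multiplicative, log-scale s.d. sigma)

    def __post_init__(self) -> None:
        self.genotype_effects = np.asarray(self.genotype_effects, dtype=float)
        self.tissue_effects = np.asarray(self.tissue_effects, dtype=float)
        _check_zero_sum(self.genotype_effects, "genotype_effects")
        _check_zero_sum(self.tissue_effects, "tissue_effects")
        g, e = len(self.genotype_effects), len(self.tissue_effects)
        if self.genes is None:
            self.genes = [f"G{i + 1}" for i in range(g)]
        if self.tissues is None:
            self.tissues = [f"E{j + 1}" for j in range(e)]
        if len(self.genes) != g or len(self.tissues) != e:
            raise SpecError("label lists must match effect-vector lengths")
        lams = [t[0] for t in self.multiplicative_terms]
        if any(l < 0 for l in lams):
            raise SpecError("singular values must be non-negative")
        if any(l2 > l1 + 1e-12 for l1, l2 in zip(lams, lams[1:])):
            raise SpecError("singular values must be non-increasing")
        gammas = _orthonormal_zero_sum(
            [np.asarray(t[1], float) for t in self.multiplicative_terms], "gamma")
        deltas = _orthonormal_zero_sum(
            [np.asarray(t[2], float) for t in self.multiplicative_terms], "delta")
        for gam, dlt in zip(gammas, deltas):
            if len(gam) != g or len(dlt) != e:
                raise SpecError("score vectors must match effect-vector lengths")
        self.multiplicative_terms = [
            (float(l), gam, dlt) for l, gam, dlt in zip(lams, gammas, deltas)
        ]
        if self.sigma < 0:
            raise SpecError("sigma must be non-negative")
        if self.replicates < 1:
            raise SpecError("replicates must be >= 1")
        if self.noise not in ("gaussian", "lognormal"):
            raise SpecError(f"unknown noise model {self.noise!r}")

    def expectation(self) -> np.ndarray:
        """g x e grid of cell expectations (no noise)."""
        g, e = len(self.genes), len(self.tissues)
        mean = np.full((g, e), self.mu)
        mean += self.genotype_effects[:, None]
        mean += self.tissue_effects[None, :]
        for lam, gam, dlt in self.multiplicative_terms:
            mean += lam * np.outer(gam, dlt)
        return mean

    # -- plain-dict round trip for YAML/JSON configs ------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "two_way",
            "mu": self.mu,
            "genotype_effects": self.genotype_effects.tolist(),
            "tissue_effects": self.tissue_effects.tolist(),
            "multiplicative_terms": [
                {"lambda": l, "gamma": g.tolist(), "delta": d.tolist()}
                for l, g, d in self.multiplicative_terms
            ],
            "sigma": self.sigma,
            "replicates": self.replicates,
            "seed": self.seed,
            "genes": self.genes,
            "tissues": self.tissues,
            "temperature": self.temperature,
            "noise": self.noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoWaySimSpec":
        return cls(
            mu=float(d["mu"]),
            genotype_effects=np.asarray(d["genotype_effects"], float),
            tissue_effects=np.asarray(d["tissue_effects"], float),
            multiplicative_terms=[
                (float(t["lambda"]), np.asarray(t["gamma"], float), np.asarray(t["delta"], float))
                for t in d.get("multiplicative_terms", [])
            ],
            sigma=float(d.get("sigma", 0.0)),
            replicates=int(d.get("replicates", 3)),
            seed=int(d.get("seed", 0)),
            genes=d.get("genes"),
            tissues=d.get("tissues"),
            temperature=str(d.get("temperature", "sim")),
            noise=str(d.get("noise", "gaussian")),
        )


def simulate_two_way(spec: TwoWaySimSpec) -> ExpressionTable:
    """Draw ``replicates`` observations per gene x tissue cell.

    Gaussian noise adds an independent N(0, sigma^2) draw per observation;
    lognormal noise multiplies each (necessarily positive) cell expectation
    by exp(N(0, sigma^2)).  Output is reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mean = spec.expectation()
    g, e = mean.shape
    rows = []
    negative = False
    for k in range(1, spec.replicates + 1):
        if spec.noise == "gaussian":
            draw = mean + rng.normal(0.0, spec.sigma, size=mean.shape)
        else:
            if (mean <= 0).any():
                raise SpecError("lognormal noise requires strictly positive expectations")
            draw = mean * np.exp(rng.normal(0.0, spec.sigma, size=mean.shape))
        negative = negative or bool((draw < 0).any())
        for i in range(g):
            for j in range(e):
                rows.append((spec.temperature, spec.tissues[j], spec.genes[i], k, draw[i, j]))
    if negative:
        warnings.warn(
            "simulate_two_way produced negative expression values; the "
            "least-squares analyses accept them, but they are not physical",
            stacklevel=2,
        )
    df = pd.DataFrame(rows, columns=["temperature", "tissue", "gene", "block", "value"])
    return ExpressionTable(df)


# ---------------------------------------------------------------------------
# split-split-plot generator
# ---------------------------------------------------------------------------

@dataclass
class SspSimSpec:
    """Ground truth for a full split-split-plot expression experiment.

    Fixed effects are arrays over the factor levels, each constrained to sum
    to zero over every one of its indices.  The three noise standard
    deviations place independent Gaussian draws at the main-plot
    (block x temperature), subplot (block x temperature x tissue) and
    sub-subplot (per observation) strata.
    """

    blocks: int
    temperatures: list[str]
    tissues: list[str]
    genes: list[str]
    mu: float = 0.0
    block_effects: np.ndarray | None = None
    temp_effects: np.ndarray | None = None
    tissue_effects: np.ndarray | None = None
    gene_effects: np.ndarray | None = None
    temp_tissue: np.ndarray | None = None
    temp_gene: np.ndarray | None = None
    tissue_gene: np.ndarray | None = None
    temp_tissue_gene: np.ndarray | None = None
    sigma_f: float = 0.0
    sigma_g: float = 0.0
    sigma_e: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t, s, g, k = (len(self.temperatures), len(self.tissues),
                      len(self.genes), self.blocks)
        if k < 1:
            raise SpecError("blocks must be >= 1")
        shapes = {
            "block_effects": (k,),
            "temp_effects": (t,),
            "tissue_effects": (s,),
            "gene_effects": (g,),
            "temp_tissue": (t, s),
            "temp_gene": (t, g),
            "tissue_gene": (s, g),
            "temp_tissue_gene": (t, s, g),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            arr = np.zeros(shape) if arr is None else np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise SpecError(f"{name} has shape {arr.shape}, expected {shape}")
            _check_zero_sum(arr, name)
            setattr(self, name, arr)
        if min(self.sigma_f, self.sigma_g, self.sigma_e) < 0:
            raise SpecError("noise standard deviations must be non-negative")

    def expectation(self) -> np.ndarray:
        """t x s x g grid of treatment-cell expectations (block effects excluded)."""
        mean = np.full((len(self.temperatures), len(self.tissues), len(self.genes)), self.mu)
        mean += self.temp_effects[:, None, None]
        mean += self.tissue_effects[None, :, None]
        mean += self.gene_effects[None, None, :]
        mean += self.temp_tissue[:, :, None]
        mean += self.temp_gene[:, None, :]
        mean += self.tissue_gene[None, :, :]
        mean += self.temp_tissue_gene
        return mean

    def to_dict(self) -> dict:
        return {
            "kind": "ssp",
            "blocks": self.blocks,
            "temperatures": self.temperatures,
            "tissues": self.tissues,
            "genes": self.genes,
            "mu": self.mu,
            "block_effects": self.block_effects.tolist(),
            "temp_effects": self.temp_effects.tolist(),
            "tissue_effects": self.tissue_effects.tolist(),
            "gene_effects": self.gene_effects.tolist(),
            "temp_tissue": self.temp_tissue.tolist(),
            "temp_gene": self.temp_gene.tolist(),
            "tissue_gene": self.tissue_gene.tolist(),
            "temp_tissue_gene": self.temp_tissue_gene.tolist(),
            "sigma_f": self.sigma_f,
            "sigma_g": self.sigma_g,
            "sigma_e": self.sigma_e,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SspSimSpec":
        arrays = {
            name: (np.asarray(d[name], float) if d.get(name) is not None else None)
            for name in (
                "block_effects", "temp_effects", "tissue_effects", "gene_effects",
                "temp_tissue", "temp_gene", "tissue_gene", "temp_tissue_gene",
            )
            if name in d
        }
        return cls(
            blocks=int(d["blocks"]),
            temperatures=[str(x) for x in d["temperatures"]],
            tissues=[str(x) for x in d["tissues"]],
            genes=[str(x) for x in d["genes"]],
            mu=float(d.get("mu", 0.0)),
            sigma_f=float(d.get("sigma_f", 0.0)),
            sigma_g=float(d.get("sigma_g", 0.0)),
            sigma_e=float(d.get("sigma_e", 0.0)),
            seed=int(d.get("seed", 0)),
            **arrays,
        )


def simulate_ssp(spec: SspSimSpec) -> ExpressionTable:
    """Draw a complete balanced split-split-plot table.

    The main-plot error ``f`` is shared by every observation within one
    block x temperature main plot; the subplot error ``g`` within one
    block x temperature x tissue subplot; the residual ``e`` is drawn per
    observation.
    """
    rng = np.random.default_rng(spec.seed)
    t, s, g, k = (len(spec.temperatures), len(spec.tissues),
                  len(spec.genes), spec.blocks)
    mean = spec.expectation()
    f_err = rng.normal(0.0, spec.sigma_f, size=(t, k))
    g_err = rng.normal(0.0, spec.sigma_g, size=(t, s, k))
    e_err = rng.normal(0.0, spec.sigma_e, size=(t, s, g, k))
    rows = []
    for i in range(t):
        for h in range(s):
            for j in range(g):
                for kk in range(k):
                    value = (
                        mean[i, h, j]
                        + spec.block_effects[kk]
                        + f_err[i, kk]
                        + g_err[i, h, kk]
                        + e_err[i, h, j, kk]
                    )
                    rows.append((
                        spec.temperatures[i], spec.tissues[h],
                        spec.genes[j], kk + 1, value,
                    ))
    df = pd.DataFrame(rows, columns=["temperature", "tissue", "gene", "block", "value"])
    return ExpressionTable(df)


# ---------------------------------------------------------------------------
# study-scale default specifications
# ---------------------------------------------------------------------------

def _random_zero_sum_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=n)
    v -= v.mean()
    return v / np.linalg.norm(v)


def study_two_way_spec(seed: int = 0, *, sigma: float = 0.54,
                       replicates: int = 3) -> TwoWaySimSpec:
    """A 4-gene x 10-tissue replicated table at study scale.

    Magnitudes follow the intermediate-stress condition of the turbot PPAR
    experiment: grand mean ~1.77, gene and tissue main-effect spreads of
    roughly 1.0 and 0.8 s.d., a rank-2 interaction with singular values
    (5.7, 3.6) on the cell-mean scale, and within-cell noise s.d. ~0.54.
    """
    rng = np.random.default_rng(seed)
    g, e = len(STUDY_GENES), len(STUDY_TISSUES)
    alpha = rng.normal(0.0, 1.0, size=g)
    alpha -= alpha.mean()
    beta = rng.normal(0.0, 0.8, size=e)
    beta -= beta.mean()
    gamma1 = _random_zero_sum_unit(rng, g)
    delta1 = _random_zero_sum_unit(rng, e)
    gamma2 = _random_zero_sum_unit(rng, g)
    delta2 = _random_zero_sum_unit(rng, e)
    return TwoWaySimSpec(
        mu=1.77,
        genotype_effects=alpha,
        tissue_effects=beta,
        multiplicative_terms=[(5.7, gamma1, delta1), (3.6, gamma2, delta2)],
        sigma=sigma,
        replicates=replicates,
        seed=seed,
        genes=list(STUDY_GENES),
        tissues=list(STUDY_TISSUES),
        temperature="23",
    )


def study_ssp_spec(seed: int = 0) -> SspSimSpec:
    """The full 5 x 10 x 4 x 3 split-split-plot layout at study scale.

    Fixed-effect spreads are chosen so each source's expected sum of squares
    sits at the order of magnitude of the study's printed ANOVA (temperature
    ~0.3 s.d., tissue ~0.67, gene ~0.55, interactions 0.6-0.9), with error
    strata s.d. (sigma_f, sigma_g, sigma_e) = (0.12, 0.10, 0.49).
    """
    rng = np.random.default_rng(seed)
    t, s, g = len(STUDY_TEMPERATURES), len(STUDY_TISSUES), len(STUDY_GENES)

    def centered(shape, sd):
        arr = rng.normal(0.0, sd, size=shape)
        for axis in range(arr.ndim):
            arr -= arr.mean(axis=axis, keepdims=True)
        return arr

    return SspSimSpec(
        blocks=3,
        temperatures=list(STUDY_TEMPERATURES),
        tissues=list(STUDY_TISSUES),
        genes=list(STUDY_GENES),
        mu=1.66,
        temp_effects=centered((t,), 0.31),
        tissue_effects=centered((s,), 0.67),
        gene_effects=centered((g,), 0.55),
        temp_tissue=centered((t, s), 0.74),
        temp_gene=centered((t, g), 0.73),
        tissue_gene=centered((s, g), 0.61),
        temp_tissue_gene=centered((t, s, g), 0.90),
        sigma_f=0.12,
        sigma_g=0.10,
        sigma_e=0.49,
        seed=seed,
    )
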