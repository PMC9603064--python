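"""Replicate-level relative-expression tables and qPCR quantification.

The canonical interchange format is a long (tidy) table with one row per
observation::

    temperature,tissue,gene,block,value

``temperature`` is treated as a categorical label throughout (the downstream
models fit it as a factor, never as a numeric covariate).  ``value`` is a
relative-expression measurement: a dimensionless positive real, typically the
output of the 2^-ddCt method.  Any unit label attached by an instrument or a
lab convention is carried as opaque metadata.

Wide gene x tissue matrices (:class:`TwoWayMeans`) are always derived from the
long table, never stored as primary input, so that balance of the replicated
design can be checked unambiguously.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BalanceError, InvalidInputError, ParseError

REQUIRED_COLUMNS = ("temperature", "tissue", "gene", "block", "value")
CT_COLUMNS = ("sample", "gene", "ct_target", "ct_reference", "is_calibrator")


# ---------------------------------------------------------------------------
# ddCt quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtObservation:
    """One qPCR measurement: target and reference-gene cycle thresholds.

    Parameters
    ----------
    sample_id : str
        Label of the biological sample (e.g. a tissue/temperature replicate).
    gene : str
        Target gene label.
    ct_target : float
        Cycle threshold of the target gene, in cycles; finite and > 0.
    ct_reference : float
        Cycle threshold of the internal reference (housekeeping) gene.
    """

    sample_id: str
    gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidInputError(
                    f"{name}={v!r} for sample {self.sample_id!r}: "
                    "Ct values must be finite and positive"
                )

    @property
    def delta_ct(self) -> float:
        """Ct(target) - Ct(reference) for this sample."""
        return self.ct_target - self.ct_reference


def relative_expression(sample: CtObservation, calibrator: CtObservation) -> float:
    """Relative expression of ``sample`` vs ``calibrator`` by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator,
    and the returned fold change is ``2 ** -ddCt`` -- strictly positive, equal
    to 1.0 when the two delta-Ct values coincide, and halving for every extra
    cycle the sample needs relative to the calibrator.
    """
    if sample.gene != calibrator.gene:
        raise InvalidInputError(
            f"sample targets {sample.gene!r} but calibrator targets "
            f"{calibrator.gene!r}; ddCt requires the same target gene"
        )
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def relative_expression_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ddCt over a Ct table with one calibrator row per gene.

    Expects columns ``sample,gene,ct_target,ct_reference,is_calibrator``;
    exactly one row per gene must be flagged as calibrator.  Returns a frame
    with columns ``sample,gene,value``.
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ParseError(f"Ct table is missing column(s) {missing}")
    out = []
    for gene, grp in ct_table.groupby("gene", sort=False):
        cal = grp[grp["is_calibrator"].astype(bool)]
        if len(cal) != 1:
            raise ParseError(
                f"gene {gene!r}: expected exactly one calibrator row, got {len(cal)}"
            )
        cal_obs = CtObservation(
            str(cal["sample"].iloc[0]), str(gene),
            float(cal["ct_target"].iloc[0]), float(cal["ct_reference"].iloc[0]),
        )
        for _, row in grp.iterrows():
            obs = CtObservation(
                str(row["sample"]), str(gene),
                float(row["ct_target"]), float(row["ct_reference"]),
            )
            out.append((obs.sample_id, gene, relative_expression(obs, cal_obs)))
    return pd.DataFrame(out, columns=["sample", "gene", "value"])


# ---------------------------------------------------------------------------
# the tidy expression table
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Tidy replicate-level expression observations.

    Wraps a :class:`pandas.DataFrame` with the five canonical columns and
    offers the balance bookkeeping the classical ANOVA decompositions need.
    Factor level order follows first appearance in the data.
    """

    data: pd.DataFrame
    unit: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"expression table is missing column(s) {missing}")
        df = self.data.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("temperature", "tissue", "gene"):
            df[col] = df[col].astype(str)
        df["block"] = pd.to_numeric(df["block"], errors="raise").astype(int)
        values = pd.to_numeric(df["value"], errors="raise").astype(float)
        if not np.isfinite(values).all():
            bad = df.index[~np.isfinite(values)][0]
            raise ParseError(f"non-finite expression value at row {bad}")
        df["value"] = values
        dup = df.duplicated(subset=["temperature", "tissue", "gene", "block"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["temperature", "tissue", "gene", "block"]]
            raise ParseError(
                "duplicated design cell "
                f"(temperature={first['temperature']}, tissue={first['tissue']}, "
                f"gene={first['gene']}, block={first['block']})"
            )
        self.data = df.reset_index(drop=True)

    # -- factor levels, in order of first appearance ------------------------
    @property
    def temperatures(self) -> list[str]:
        return list(dict.fromkeys(self.data["temperature"]))

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.data["tissue"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def blocks(self) -> list[int]:
        return sorted(set(self.data["block"]))

    def __len__(self) -> int:
        return len(self.data)

    # -- balance bookkeeping -------------------------------------------------
    def is_balanced(self, temperature: str | None = None) -> bool:
        """True when every factor combination appears exactly once per block."""
        df = self._subset(temperature) if temperature is not None else self.data
        temps = df["temperature"].nunique()
        expected = temps * df["tissue"].nunique() * df["gene"].nunique() * df["block"].nunique()
        return len(df) == expected

    def require_balanced(self, temperature: str | None = None) -> None:
        if not self.is_balanced(temperature):
            where = f" at temperature {temperature!r}" if temperature else ""
            raise BalanceError(
                f"design{where} is unbalanced: every temperature x tissue x gene "
                "x block combination must appear exactly once"
            )

    def _subset(self, temperature: str) -> pd.DataFrame:
        temperature = str(temperature)
        if temperature not in set(self.data["temperature"]):
            raise InvalidInputError(
                f"unknown temperature {temperature!r}; "
                f"table has {self.temperatures}"
            )
        return self.data[self.data["temperature"] == temperature]

    # -- I/O -----------------------------------------------------------------
    def write(self, path_or_buf, sep: str = ",") -> None:
        """Write the canonical five-column delimited file."""
        self.data.to_csv(path_or_buf, sep=sep, index=False)

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        self.write(buf)
        return buf.getvalue()


def read_expression_table(path_or_buf, sep: str = ",", unit: str = "") -> ExpressionTable:
    """Parse a delimited expression file into an :class:`ExpressionTable`.

    The header must name the five canonical columns; extra columns are
    ignored.  Duplicate design cells and non-numeric values raise
    :class:`~gxetools.errors.ParseError`.
    """
    try:
        df = pd.read_csv(path_or_buf, sep=sep, float_precision="round_trip")
    except Exception as exc:  # malformed CSV surfaces as ParseError
        raise ParseError(f"could not parse expression file: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"expression file is missing column(s) {missing}")
    try:
        return ExpressionTable(df, unit=unit)
    except (ParseError, InvalidInputError):
        raise
    except Exception as exc:
        raise ParseError(f"invalid expression file: {exc}") from exc


# ---------------------------------------------------------------------------
# aggregation to the two-way gene x tissue grid
# ---------------------------------------------------------------------------

@dataclass
class TwoWayMeans:
    """Gene x tissue grid of cell means at one temperature.

    ``means[i, j]`` is the arithmetic mean over replicate blocks of gene
    ``genes[i]`` in tissue ``tissues[j]``; ``replicates`` records how many
    observations were averaged per cell.
    """

    genes: list[str]
    tissues: list[str]
    means: np.ndarray
    replicates: int
    temperature: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.genes), len(self.tissues)):
            raise InvalidInputError(
                f"means grid has shape {self.means.shape}, expected "
                f"({len(self.genes)}, {len(self.tissues)})"
            )
        if not np.isfinite(self.means).all():
            raise InvalidInputError("means grid contains non-finite entries")

    @property
    def grand_mean(self) -> float:
        return float(self.means.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.genes, columns=self.tissues)


def cell_means(table: ExpressionTable, temperature: str) -> TwoWayMeans:
    """Average replicate blocks into the gene x tissue mean grid.

    Requires a balanced design at that temperature; the result is the
    two-way table the AMMI and GGE analyses consume.
    """
    df = table._subset(temperature)
    sub = ExpressionTable(df, unit=table.unit)
    sub.require_balanced()
    genes = sub.genes
    tissues = sub.tissues
    r = len(sub.blocks)
    grid = (
        df.pivot_table(index="gene", columns="tissue", values="value", aggfunc="mean")
        .reindex(index=genes, columns=tissues)
    )
    return TwoWayMeans(
        genes=genes, tissues=tissues, means=grid.to_numpy(),
        replicates=r, temperature=str(temperature), unit=table.unit,
    )


def temperature_grand_mean(table: ExpressionTable, temperature: str) -> float:
    """Mean expression over every gene x tissue x block observation at one temperature."""
    df = table._subset(temperature)
    ExpressionTable(df, unit=table.unit).require_balanced()
    return float(df["value"].mean())
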