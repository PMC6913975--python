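"""Situating a focal gene against its genome and a reference gene.

Provides z-scores against the genome distribution (population standard
deviation, as the genome is the whole population of genes), the percentage
of genome genes strictly below the gene's value, Spearman rank correlation,
polynomial least-squares fits (for the Nc ~ GC3 relationship), the
neutrality-plot regression of mean(GC1, GC2) on GC3, and the Nc-plot table
with the mutational null curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import CubMetrics, expected_nc

logger = logging.getLogger(__name__)


@dataclass
class ZScoreReport:
    gene_id: str
    metric: str
    x: float
    mu: float
    delta: float
    z: float


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class FitResult:
    degree: int
    coefficients: np.ndarray  # ascending powers
    r_squared: float
    see: float  # standard error of estimate
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)


def zscore(
    x: float,
    genome_values: list[float] | np.ndarray,
    gene_id: str = "",
    metric: str = "",
) -> ZScoreReport:
    """Standard score of a gene value within its genome's distribution.

    z = (x - mu) / delta with delta the population (N-denominator)
    standard deviation of the genome values.
    """
    vals = np.asarray(genome_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 genome values")
    mu = float(np.mean(vals))
    delta = float(np.std(vals, ddof=0))
    if delta == 0.0:
        logger.warning("%s/%s: zero genome spread, z undefined", gene_id, metric)
        z = math.nan
    else:
        z = (x - mu) / delta
    return ZScoreReport(gene_id=gene_id, metric=metric, x=x, mu=mu, delta=delta, z=z)


def percent_genes_below(
    genome_values: list[float] | np.ndarray, gene_value: float
) -> float:
    """Percentage of genome genes with value strictly less than the gene's."""
    vals = np.asarray(genome_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty genome value list")
    return 100.0 * float(np.sum(vals < gene_value)) / vals.size


def spearman(
    xs: list[float] | np.ndarray, ys: list[float] | np.ndarray
) -> CorrelationResult:
    """Spearman rank correlation with midrank ties; p from the t approximation."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.size != ys.size:
        raise ValueError("length mismatch")
    if xs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("constant vector: correlation undefined")
    res = stats.spearmanr(xs, ys)
    return CorrelationResult(
        rho=float(res.statistic), p_value=float(res.pvalue), n=int(xs.size)
    )


def fit_polynomial(
    xs: list[float] | np.ndarray, ys: list[float] | np.ndarray, degree: int
) -> FitResult:
    """Unweighted least-squares polynomial fit with R^2 and SEE.

    SEE = sqrt(SSE / (n - degree - 1)), the residual standard error.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    n = xs.size
    if n <= degree + 1:
        raise ValueError(f"need more than {degree + 1} points for degree {degree}")
    if np.unique(xs).size <= degree:
        raise ValueError("rank-deficient design (too few distinct x values)")
    coeffs = np.polynomial.polynomial.polyfit(xs, ys, degree)
    fitted = np.polynomial.polynomial.polyval(xs, coeffs)
    sse = float(np.sum((ys - fitted) ** 2))
    sst = float(np.sum((ys - np.mean(ys)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    see = math.sqrt(sse / (n - degree - 1))
    return FitResult(degree=degree, coefficients=coeffs, r_squared=r2, see=see, n=n)


def neutrality_fit(
    gc1: list[float] | np.ndarray,
    gc2: list[float] | np.ndarray,
    gc3: list[float] | np.ndarray,
) -> FitResult:
    """Neutrality plot: linear fit of (GC1+GC2)/2 on GC3.

    Slope near 1 indicates mutation pressure acting uniformly on all codon
    positions; slope near 0 indicates selection constraining GC1/GC2 while
    GC3 drifts.
    """
    gc1 = np.asarray(gc1, float)
    gc2 = np.asarray(gc2, float)
    gc3 = np.asarray(gc3, float)
    if not (gc1.size == gc2.size == gc3.size):
        raise ValueError("length mismatch")
    gc12 = (gc1 + gc2) / 2.0
    return fit_polynomial(gc3, gc12, degree=1)


def ncplot_table(metrics: list[CubMetrics], use_gc3s: bool = True) -> pd.DataFrame:
    """Nc-plot dataset: per-gene (gc3, nc, expected, below_curve).

    Rows with undefined Nc are skipped with a warning.  ``use_gc3s`` selects
    the synonymous GC3 for the abscissa (the plot's convention) when it is
    available, falling back to positional GC3 otherwise.
    """
    rows = []
    for m in metrics:
        if math.isnan(m.nc):
            logger.warning("%s: undefined Nc, skipped from Nc-plot", m.seq_id)
            continue
        s = m.gc3s if (use_gc3s and not math.isnan(m.gc3s)) else m.gc3
        exp = expected_nc(s)
        rows.append(
            {
                "seq_id": m.seq_id,
                "species": m.species,
                "lifestyle": m.lifestyle,
                "gram": m.gram,
                "gc3": s,
                "nc": m.nc,
                "expected": exp,
                "below_curve": bool(m.nc < exp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "species", "lifestyle", "gram",
            "gc3", "nc", "expected", "below_curve",
        ],
    )
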