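"""Per-sequence codon-usage-bias metrics.

The central statistic is Wright's effective number of codons

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

where ``Fk`` is the mean codon homozygosity of the k-fold degenerate
amino-acid families.  For one family used n times with within-family codon
frequencies ``p_i = n_i/n`` the bias-corrected homozygosity is

    F = (n * sum(p_i^2) - 1) / (n - 1),

the probability that two codons drawn without replacement from the family
are identical.  Nc ranges from 20 (one codon per amino acid, maximal bias)
to 61 (uniform usage of all sense codons, no bias).

Rare-amino-acid handling (the field's standard tools are silent here):
families used fewer than twice are excluded from their class mean; an
undefined 3-fold class (Ile) is imputed as (F2+F4)/2 and an undefined
6-fold class as F4; if the 2-fold or 4-fold class is wholly undefined, Nc
is undefined (NaN).  The imputation can be disabled with ``fallback=False``,
in which case any undefined class makes Nc undefined.

Also provided: positional GC fractions, synonymous GC3 (degenerate families
only, the convention of Nc-plots), relative synonymous codon usage (RSCU),
and the Nc expected under third-position composition alone,

    Nc*(s) = 2 + s + 29 / (s^2 + (1-s)^2),   s = GC3,

the null curve of the Nc-plot (no translational selection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import BACTERIAL_CODE, CodonCountTable, GeneticCode

logger = logging.getLogger(__name__)

NC_MIN = 20.0
NC_MAX = 61.0


@dataclass
class FamilyHomozygosity:
    """Codon homozygosity F of one synonymous family (defined for n >= 2)."""

    amino_acid: str
    n: int
    f_hat: float  # NaN when n < 2


@dataclass
class CubMetrics:
    """Nc and (positional) GC content for one sequence."""

    seq_id: str
    nc: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float = math.nan
    n_codons: int = 0
    species: str = ""
    lifestyle: str = "unknown"
    gram: str = "unknown"


@dataclass
class RscuTable:
    """Per-codon RSCU values, optionally labelled by SSE stratum."""

    seq_id: str
    rscu: dict[str, float]
    stratum: str = "all"
    unused_families: tuple[str, ...] = ()


def family_homozygosity(
    counts: CodonCountTable, amino_acid: str, code: GeneticCode = BACTERIAL_CODE
) -> FamilyHomozygosity:
    """Bias-corrected homozygosity of one family; NaN when used < 2 times."""
    codons = code.families[amino_acid]
    n = sum(counts.counts[c] for c in codons)
    if n < 2:
        return FamilyHomozygosity(amino_acid, n, math.nan)
    sum_p2 = sum((counts.counts[c] / n) ** 2 for c in codons)
    f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
    return FamilyHomozygosity(amino_acid, n, f_hat)


def effective_number_of_codons(
    counts: CodonCountTable,
    code: GeneticCode = BACTERIAL_CODE,
    fallback: bool = True,
) -> float:
    """Wright's Nc, capped to [20, 61]; NaN when undefined (see module doc)."""
    class_means: dict[int, float] = {}
    for k, aas in code.degeneracy_classes.items():
        if k < 2:
            continue
        fhats = []
        for aa in aas:
            fh = family_homozygosity(counts, aa, code)
            if not math.isnan(fh.f_hat):
                fhats.append(fh.f_hat)
        if fhats:
            class_means[k] = float(np.mean(fhats))

    f2 = class_means.get(2)
    f4 = class_means.get(4)
    if f2 is None or f4 is None or f2 <= 0 or f4 <= 0:
        logger.warning("%s: Nc undefined (2-fold or 4-fold class unusable)", counts.seq_id)
        return math.nan
    f3 = class_means.get(3)
    f6 = class_means.get(6)
    if f3 is None or f3 <= 0:
        if not fallback:
            return math.nan
        f3 = (f2 + f4) / 2.0
    if f6 is None or f6 <= 0:
        if not fallback:
            return math.nan
        f6 = f4
    nc = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return float(min(NC_MAX, max(NC_MIN, nc)))


def gc_positional(counts: CodonCountTable) -> tuple[float, float, float, float]:
    """(gc, gc1, gc2, gc3): G+C fraction overall and at each codon position.

    Computed over counted sense codons only, so all metrics share one
    denominator (terminal stop already trimmed at the counting stage).
    """
    if counts.n_codons < 1:
        raise ValueError(f"{counts.seq_id}: empty codon count table")
    gc_pos = [0, 0, 0]
    total = 0
    for codon, n in counts.counts.items():
        if n == 0 or BACTERIAL_CODE.codon_to_aa.get(codon) == "*":
            continue
        total += n
        for i in range(3):
            if codon[i] in "GC":
                gc_pos[i] += n
    gc1, gc2, gc3 = (g / total for g in gc_pos)
    gc = sum(gc_pos) / (3 * total)
    return gc, gc1, gc2, gc3


def gc3_synonymous(
    counts: CodonCountTable, code: GeneticCode = BACTERIAL_CODE
) -> float:
    """Third-position G+C over degenerate families only (GC3s).

    Excludes Met and Trp, whose third position is fixed; this is the s used
    on the Nc-plot abscissa.
    """
    gc = 0
    total = 0
    for aa, codons in code.families.items():
        if len(codons) < 2:
            continue
        for c in codons:
            n = counts.counts[c]
            total += n
            if c[2] in "GC":
                gc += n
    if total == 0:
        return math.nan
    return gc / total


def rscu(
    counts: CodonCountTable, code: GeneticCode = BACTERIAL_CODE, stratum: str = "all"
) -> RscuTable:
    """Relative synonymous codon usage: observed over uniform-family expectation.

    RSCU = 1 means unbiased; families with zero usage get RSCU 0 for all
    members and are flagged in ``unused_families``.
    """
    values: dict[str, float] = {}
    unused: list[str] = []
    for aa, codons in code.families.items():
        k = len(codons)
        total = sum(counts.counts[c] for c in codons)
        if total == 0:
            unused.append(aa)
            for c in codons:
                values[c] = 0.0
            continue
        for c in codons:
            values[c] = counts.counts[c] * k / total
    return RscuTable(
        seq_id=counts.seq_id,
        rscu=values,
        stratum=stratum,
        unused_families=tuple(sorted(unused)),
    )


def expected_nc(s: float) -> float:
    """Null-curve Nc at synonymous third-position GC content s.

    The expectation when codon choice reflects third-position composition
    alone (mutation, no selection); symmetric about s = 0.5, capped at 61.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0, 1], got {s}")
    value = 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)
    return min(NC_MAX, value)


def compute_metrics(
    counts: CodonCountTable,
    code: GeneticCode = BACTERIAL_CODE,
    fallback: bool = True,
) -> CubMetrics:
    """Bundle Nc and GC metrics for one count table."""
    gc, gc1, gc2, gc3 = gc_positional(counts)
    return CubMetrics(
        seq_id=counts.seq_id,
        nc=effective_number_of_codons(counts, code, fallback=fallback),
        gc=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc3s=gc3_synonymous(counts, code),
        n_codons=counts.n_codons,
        species=counts.species,
        lifestyle=counts.lifestyle,
        gram=counts.gram,
    )


def metrics_frame(metrics: list[CubMetrics]) -> pd.DataFrame:
    """Tabulate a list of per-sequence metrics."""
    return pd.DataFrame(
        {
            "seq_id": [m.seq_id for m in metrics],
            "species": [m.species for m in metrics],
            "lifestyle": [m.lifestyle for m in metrics],
            "gram": [m.gram for m in metrics],
            "n_codons": [m.n_codons for m in metrics],
            "nc": [m.nc for m in metrics],
            "gc": [m.gc for m in metrics],
            "gc1": [m.gc1 for m in metrics],
            "gc2": [m.gc2 for m in metrics],
            "gc3": [m.gc3 for m in metrics],
            "gc3s": [m.gc3s for m in metrics],
        }
    )
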