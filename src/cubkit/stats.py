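"""Rank tests and factorial ANOVA for codon-preference detection.

The core-codon question — does a synonymous family have a preferred subset
of codons across species? — is answered nonparametrically: the per-species
usage values of each codon form one group, and the groups are compared with
a Mann-Whitney rank-sum test (2-fold families) or a tie-corrected
Kruskal-Wallis one-way ANOVA on ranks (3/4/6-fold families).  The reported
Mann-Whitney statistic is min(U1, U2), the convention of bench statistics
packages.  For small samples (n1 + n2 <= 12) the Mann-Whitney p-value comes
from exact enumeration of all group assignments over the pooled midranks;
otherwise from the normal approximation with tie correction.

The factorial layer crosses bacterial lifestyle (pathogenic vs
non-pathogenic) with Gram nature in a two-way ANOVA with interaction.  The
design is unbalanced, so hierarchical (Type II) sums of squares are used
(fitted through statsmodels OLS).  Post-hoc pairwise level comparisons are
adjusted with the step-down Holm-Sidak method.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .codons import BACTERIAL_CODE, CodonCountTable, GeneticCode

logger = logging.getLogger(__name__)


@dataclass
class RankTestResult:
    test: str  # "mann_whitney" or "kruskal_wallis"
    statistic: float  # min-U or tie-corrected H
    df: int | None
    p_value: float
    group_sizes: list[int]


@dataclass
class AnovaResult:
    """Per-term two-way decomposition plus Holm-Sidak post-hoc comparisons."""

    terms: pd.DataFrame  # index: factor_A, factor_B, interaction, residual
    posthoc: list[tuple[str, float]] = field(default_factory=list)
    interaction_dropped: bool = False

    def p_value(self, term: str) -> float:
        return float(self.terms.loc[term, "p_value"])


# ---------------------------------------------------------------------------
# rank tests

def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(
    a: list[float] | np.ndarray, b: list[float] | np.ndarray
) -> RankTestResult:
    """Two-sample Mann-Whitney rank-sum test, reporting min(U1, U2)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = float(np.sum(ranks[:n1]))
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)
    N = n1 + n2
    if N <= 12:
        p = _mw_exact_p(ranks, n1, n2, u_min)
    else:
        mean_u = n1 * n2 / 2.0
        tie = _tie_term(pooled)
        var_u = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var_u <= 0:
            p = 1.0
        else:
            z = (u1 - mean_u) / math.sqrt(var_u)
            p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(
        test="mann_whitney",
        statistic=u_min,
        df=None,
        p_value=min(1.0, p),
        group_sizes=[n1, n2],
    )


def _mw_exact_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all assignments over the midranks."""
    N = n1 + n2
    base = n1 * (n1 + 1) / 2.0
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(N), n1):
        u1 = float(np.sum(ranks[list(idx)])) - base
        u = min(u1, n1 * n2 - u1)
        total += 1
        if u <= u_obs + 1e-9:
            extreme += 1
    return extreme / total


def kruskal_wallis(groups: list[list[float]] | list[np.ndarray]) -> RankTestResult:
    """k-group Kruskal-Wallis ANOVA on ranks with tie correction."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [g.size for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    N = int(np.sum(sizes))
    if N < 3:
        raise ValueError("total sample size must be >= 3")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return RankTestResult("kruskal_wallis", 0.0, df, 1.0, sizes)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = float(np.sum(ranks[start : start + g.size]))
        h += r * r / g.size
        start += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction > 0:
        h /= correction
    p = float(sps.chi2.sf(h, df))
    return RankTestResult("kruskal_wallis", float(h), df, p, sizes)


def core_codon_scan(
    tables: list[CodonCountTable],
    code: GeneticCode = BACTERIAL_CODE,
    mode: str = "counts",
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Scan the 18 degenerate amino acids for non-random codon preference.

    Each codon contributes one group: its per-species usage values across the
    cohort (raw counts, or per-1000-codon frequencies with
    ``mode="frequencies"``).  2-fold families use Mann-Whitney; 3/4/6-fold
    families use Kruskal-Wallis.  A family is called significant (a "core"
    codon set exists) at ``alpha``.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 species")
    if mode not in ("counts", "frequencies"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for aa in sorted(code.families):
        codons = code.families[aa]
        k = len(codons)
        if k < 2:
            continue  # Met, Trp
        groups = []
        for c in codons:
            vals = []
            for t in tables:
                v = float(t.counts[c])
                if mode == "frequencies":
                    v = 1000.0 * v / t.n_codons if t.n_codons else 0.0
                vals.append(v)
            groups.append(vals)
        if k == 2:
            res = mann_whitney_u(groups[0], groups[1])
        else:
            res = kruskal_wallis(groups)
        rows.append(
            {
                "amino_acid": aa,
                "family_size": k,
                "test": res.test,
                "statistic": res.statistic,
                "df": res.df if res.df is not None else "",
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# factorial ANOVA

def two_way_anova(
    values: list[float] | np.ndarray,
    lifestyle: list[str],
    gram: list[str],
    posthoc_alpha: float = 0.05,
) -> AnovaResult:
    """Two-factor (lifestyle x Gram) ANOVA with interaction, Type II SS.

    Empty cells in the factor crossing drop the interaction term with a
    warning.  A constant response yields zero factor SS and p = 1.  Post-hoc
    pairwise level comparisons (t tests on the residual mean square) are
    Holm-Sidak adjusted within each factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(values, float)
    df = pd.DataFrame({"y": y, "A": list(lifestyle), "B": list(gram)})
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 observed levels")

    cells = df.groupby(["A", "B"]).size().unstack(fill_value=0)
    interaction_dropped = bool((cells.values == 0).any())
    if interaction_dropped:
        logger.warning("empty factor cell(s): interaction term dropped")
        formula = "y ~ C(A) + C(B)"
    else:
        formula = "y ~ C(A) + C(B) + C(A):C(B)"

    model = smf.ols(formula, data=df).fit()
    constant = bool(np.allclose(y, y[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 F ratios on degenerate input
        tab = anova_lm(model, typ=2)

    name_map = {"C(A)": "factor_A", "C(B)": "factor_B",
                "C(A):C(B)": "interaction", "Residual": "residual"}
    terms = tab.rename(index=name_map).rename(
        columns={"sum_sq": "sum_of_squares", "mean_sq": "mean_square",
                 "F": "F", "PR(>F)": "p_value"}
    )
    if "mean_square" not in terms.columns:
        terms["mean_square"] = terms["sum_of_squares"] / terms["df"]
    terms = terms[["sum_of_squares", "df", "mean_square", "F", "p_value"]]
    if constant:
        terms.loc[terms.index != "residual", "F"] = 0.0
        terms.loc[terms.index != "residual", "p_value"] = 1.0
    terms["p_value"] = terms["p_value"].fillna(1.0)

    posthoc = _pairwise_posthoc(df, terms, constant)
    return AnovaResult(terms=terms, posthoc=posthoc,
                       interaction_dropped=interaction_dropped)


def _pairwise_posthoc(
    df: pd.DataFrame, terms: pd.DataFrame, constant: bool
) -> list[tuple[str, float]]:
    """Pairwise factor-level t comparisons on the residual MS, Holm-Sidak adjusted."""
    mse = float(terms.loc["residual", "mean_square"])
    dfe = float(terms.loc["residual", "df"])
    out: list[tuple[str, float]] = []
    for factor, label in (("A", "factor_A"), ("B", "factor_B")):
        levels = sorted(df[factor].unique())
        if len(levels) < 2:
            continue
        comps, ps = [], []
        for l1, l2 in itertools.combinations(levels, 2):
            g1 = df.loc[df[factor] == l1, "y"]
            g2 = df.loc[df[factor] == l2, "y"]
            if constant or mse <= 0 or dfe <= 0:
                p = 1.0
            else:
                t = (g1.mean() - g2.mean()) / math.sqrt(
                    mse * (1.0 / len(g1) + 1.0 / len(g2))
                )
                p = 2.0 * float(sps.t.sf(abs(t), dfe))
            comps.append(f"{label}: {l1} vs {l2}")
            ps.append(p)
        adj = holm_sidak(ps)
        out.extend(zip(comps, adj))
    return out


def holm_sidak(p_values: list[float] | np.ndarray) -> list[float]:
    """Step-down Sidak multiple-comparison adjustment.

    Sort p ascending; adjusted p_(i) = 1 - (1 - p_(i))^(m - i + 1); enforce
    monotone non-decreasing down the sorted list; restore input order.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_max = 0.0
    for i, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - i)
        running_max = max(running_max, a)
        adj_sorted[i] = running_max
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out.tolist()
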