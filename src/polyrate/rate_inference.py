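"""Relative-rate inference from per-gene p-distance tables.

The distribution-level test is a one-tailed Wilcoxon signed-rank on
per-gene distance differences, with the tail fixed by the sample median and
Bonferroni correction over the family of comparisons run together.  The
per-gene screen is a Tajima-style unique-substitution chi-square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import p_distance

__all__ = [
    "RateTestResult",
    "GeneRateClass",
    "ChiSquareResult",
    "build_pdist_table",
    "wilcoxon_signed_rank",
    "lineage_rate_test",
    "subgenome_rate_test",
    "all_combination_tests",
    "classify_gene_rate_shifts",
    "chisq_substitution_totals",
]


@dataclass(frozen=True)
class RateTestResult:
    label: str
    n_genes: int
    statistic: float  # signed-rank W+ (sum of ranks of positive differences)
    p_raw: float
    p_adjusted: float
    direction: str | None
    family_size: int = 1
    method: str = "exact"


@dataclass(frozen=True)
class GeneRateClass:
    gene: str
    gene_class: str  # "indistinguishable" | "A-shifted" | "D-shifted"
    stat_a: float
    p_a: float
    stat_d: float
    p_d: float


@dataclass(frozen=True)
class ChiSquareResult:
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    statistic: float
    df: int
    p: float


# --- p-distance table ----------------------------------------------------


def build_pdist_table(alignments, pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Long-form per-gene p-distance table (columns gene, tip1, tip2, p).

    Pairs default to all tip pairs present; genes missing a tip or with no
    comparable column for a pair are simply absent for that pair.
    """
    rows = []
    for gene in alignments:
        seqs = alignments[gene]
        tips = sorted(seqs)
        use = pairs if pairs is not None else list(itertools.combinations(tips, 2))
        for t1, t2 in use:
            if t1 not in seqs or t2 not in seqs:
                continue
            try:
                rec = p_distance(seqs[t1], seqs[t2], gene=gene, pair=(t1, t2))
            except ValueError:
                continue
            rows.append((gene, t1, t2, rec.p))
    return pd.DataFrame(rows, columns=["gene", "tip1", "tip2", "p"])


def pair_series(pdist: pd.DataFrame, a: str, b: str) -> pd.Series:
    """p-distances for an unordered pair, indexed by gene."""
    m = ((pdist["tip1"] == a) & (pdist["tip2"] == b)) | (
        (pdist["tip1"] == b) & (pdist["tip2"] == a)
    )
    sub = pdist.loc[m]
    return pd.Series(sub["p"].to_numpy(), index=sub["gene"].to_numpy())


# --- Wilcoxon signed-rank -------------------------------------------------


def _exact_tail(doubled_ranks: np.ndarray, w2: int, upper: bool) -> float:
    """P(W+ >= w2/2) (or <=) by dynamic programming over sign assignments.

    ``doubled_ranks`` are midranks times 2 (integers), so ties are exact.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt * 0.5
    if upper:
        return float(dist[w2:].sum())
    return float(dist[: w2 + 1].sum())


def wilcoxon_signed_rank(
    deltas: np.ndarray, exact_max_n: int = 25, tail: str = "auto"
) -> tuple[float, float, int, int, str]:
    """One-sided signed-rank test.

    ``tail`` fixes the tested tail (``greater``/``less``); the default
    ``auto`` picks it from the sample median's sign.  Zeros are dropped;
    ties are midranked.  Exact null distribution for nonzero n <=
    *exact_max_n*, otherwise a normal approximation with tie and continuity
    corrections.

    Returns ``(W_plus, p_one_sided, n_used, sign, method)`` where ``sign`` is
    +1 when the positive tail was tested, -1 otherwise.  Note the returned p
    is the pure tail probability: callers that let the data choose the tail
    must correct for that selection (see :func:`lineage_rate_test`).
    """
    deltas = np.asarray(deltas, dtype=float)
    nz = deltas[deltas != 0]
    n = nz.size
    if n == 0:
        raise ValueError("no signal: all per-gene differences are zero")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if tail == "greater":
        sign = 1
    elif tail == "less":
        sign = -1
    elif tail == "auto":
        med = np.median(nz)
        sign = 1 if med > 0 else (-1 if med < 0 else (1 if nz.sum() >= 0 else -1))
    else:
        raise ValueError(f"tail must be 'auto', 'greater' or 'less', got {tail!r}")
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        doubled = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p = _exact_tail(doubled, w2, upper=sign > 0)
        method = "exact"
    else:
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        sd = float(np.sqrt(var))
        if sign > 0:
            p = float(stats.norm.sf((w_plus - mu - 0.5) / sd))
        else:
            p = float(stats.norm.cdf((w_plus - mu + 0.5) / sd))
        method = "normal"
    return w_plus, min(1.0, p), n, sign, method


def _run_test(
    delta: pd.Series,
    label: str,
    pos_name: str,
    neg_name: str,
    alpha: float,
    tail: str = "auto",
    min_genes: int = 6,
) -> RateTestResult:
    delta = delta.dropna()
    if len(delta) < min_genes:
        raise ValueError(f"{label}: only {len(delta)} genes with all distances defined (need >= {min_genes})")
    w, p, n, sign, method = wilcoxon_signed_rank(delta.to_numpy(), tail=tail)
    if tail == "auto":
        # the tail was chosen from the data: double the tail probability so
        # the directional procedure keeps its nominal type-I rate
        p = min(1.0, 2.0 * p)
    direction = (pos_name if sign > 0 else neg_name) if p < alpha else None
    return RateTestResult(label, n, w, p, p, direction, 1, method)


def lineage_rate_test(
    pdist: pd.DataFrame,
    tip1: str,
    tip2: str,
    outgroup: str,
    alpha: float = 0.05,
    tail: str = "auto",
) -> RateTestResult:
    """Relative-rate test: per-gene ``p(tip1, outgroup) - p(tip2, outgroup)``.

    With ``tail='auto'`` (default) the tested tail follows the sample median
    and the reported p is doubled to correct for that selection; pass
    ``'greater'``/``'less'`` for a pre-specified one-tailed test.
    """
    d1 = pair_series(pdist, tip1, outgroup)
    d2 = pair_series(pdist, tip2, outgroup)
    delta = (d1 - d2).dropna()
    return _run_test(delta, f"{tip1} vs {tip2} | {outgroup}", tip1, tip2, alpha, tail)


def subgenome_rate_test(
    pdist: pd.DataFrame,
    species: str,
    a_outgroup: str = "Ga",
    d_outgroup: str = "Gr",
    alpha: float = 0.05,
    tail: str = "auto",
) -> RateTestResult:
    """Within-species A vs D subgenome rate comparison, each subgenome
    measured against its own diploid progenitor proxy."""
    da = pair_series(pdist, f"{species}_A", a_outgroup)
    dd = pair_series(pdist, f"{species}_D", d_outgroup)
    delta = (da - dd).dropna()
    return _run_test(delta, f"{species}: A vs D", f"{species}_A", f"{species}_D", alpha, tail)


def all_combination_tests(
    pdist: pd.DataFrame,
    tips: list[str],
    outgroups: list[str],
    alpha: float = 0.05,
) -> list[RateTestResult]:
    """One test per unordered tip pair x outgroup, Bonferroni-corrected over
    the whole family run in this invocation."""
    if len(tips) < 2 or not outgroups:
        raise ValueError("need >= 2 tips and >= 1 outgroup")
    combos = [
        (t1, t2, o)
        for (t1, t2) in itertools.combinations(tips, 2)
        for o in outgroups
        if o not in (t1, t2)
    ]
    family = len(combos)
    results = []
    for t1, t2, o in combos:
        res = lineage_rate_test(pdist, t1, t2, o, alpha=alpha)
        p_adj = min(1.0, res.p_raw * family)
        results.append(
            replace(
                res,
                p_adjusted=p_adj,
                family_size=family,
                direction=res.direction if p_adj < alpha else None,
            )
        )
    return results


# --- per-gene screen ------------------------------------------------------


def _unique_subs(tip: str, dip: str, out: str) -> tuple[int, int]:
    """(m1, m2): sites where only the tip (resp. only the diploid) differs."""
    m1 = m2 = 0
    for x, y, z in zip(tip, dip, out):
        triple = x + y + z
        if any(c in "N-" for c in triple):
            continue
        if y == z and x != y:
            m1 += 1
        elif x == z and y != x:
            m2 += 1
    return m1, m2


def tajima_1d(m1: int, m2: int) -> tuple[float, float]:
    """Tajima-style chi-square on unique substitution counts (df = 1)."""
    if m1 + m2 == 0:
        return 0.0, 1.0
    stat = (m1 - m2) ** 2 / (m1 + m2)
    return stat, float(stats.chi2.sf(stat, 1))


def classify_gene_rate_shifts(
    alignments,
    species: str,
    a_outgroup: str = "Ga",
    d_outgroup: str = "Gr",
    alpha: float = 0.05,
) -> list[GeneRateClass]:
    """Classify each gene as A-shifted, D-shifted or indistinguishable.

    Each subgenome copy is screened by a per-gene relative-rate chi-square
    against its diploid progenitor with the other diploid as outgroup; alpha
    is applied per gene without correction.  Genes significant on both
    screens are reported indistinguishable (no subgenome-specific shift).
    """
    out: list[GeneRateClass] = []
    for gene in alignments:
        seqs = alignments[gene]
        ta, td = f"{species}_A", f"{species}_D"
        if any(t not in seqs for t in (ta, td, a_outgroup, d_outgroup)):
            continue
        m1a, m2a = _unique_subs(seqs[ta], seqs[a_outgroup], seqs[d_outgroup])
        stat_a, p_a = tajima_1d(m1a, m2a)
        m1d, m2d = _unique_subs(seqs[td], seqs[d_outgroup], seqs[a_outgroup])
        stat_d, p_d = tajima_1d(m1d, m2d)
        sig_a, sig_d = p_a < alpha, p_d < alpha
        if sig_a and not sig_d:
            cls = "A-shifted"
        elif sig_d and not sig_a:
            cls = "D-shifted"
        else:
            cls = "indistinguishable"
        out.append(GeneRateClass(gene, cls, stat_a, p_a, stat_d, p_d))
    return out


def chisq_substitution_totals(totals, expected: list[float] | None = None) -> ChiSquareResult:
    """Goodness-of-fit chi-square on total substitution counts.

    *totals* is a list of :class:`~polyrate.divergence.SubstitutionTotals`
    (or raw counts); the default expectation is equal counts.
    """
    observed = [float(getattr(t, "total_differences", t)) for t in totals]
    if len(observed) < 2:
        raise ValueError("need at least 2 cells")
    if any(o < 0 for o in observed):
        raise ValueError("counts must be >= 0")
    if expected is None:
        expected = [sum(observed) / len(observed)] * len(observed)
    if len(expected) != len(observed):
        raise ValueError("expected/observed length mismatch")
    if any(e <= 0 for e in expected):
        raise ValueError("expected cell counts must be > 0")
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = len(observed) - 1
    return ChiSquareResult(
        tuple(observed), tuple(expected), float(stat), df, float(stats.chi2.sf(stat, df))
    )
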