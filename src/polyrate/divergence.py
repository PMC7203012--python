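"""Pairwise divergence primitives.

Two distinct gap policies are implemented on purpose: :func:`p_distance`
excludes gap/N columns pairwise (pair-local), while
:func:`count_substitution_totals` drops any column gapped in *any* taxon of
the gene's alignment before counting the focal pair (set-wide).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._codon import STOP_CODONS, is_stop, syn_sites, translate

__all__ = [
    "DivergenceRecord",
    "SubstitutionTotals",
    "KaKsRecord",
    "SaturationError",
    "p_distance",
    "jc_distance",
    "count_substitution_totals",
    "ng86_ka_ks",
]

_VALID = frozenset("ACGTN-")


class SaturationError(ValueError):
    """Observed proportion of differences is beyond the JC domain (p >= 0.75)."""


@dataclass(frozen=True)
class DivergenceRecord:
    gene: str
    pair: tuple[str, str]
    compared_sites: int
    mismatches: int

    @property
    def p(self) -> float:
        return self.mismatches / self.compared_sites


@dataclass(frozen=True)
class SubstitutionTotals:
    pair: tuple[str, str]
    total_differences: int
    total_sites: int
    n_genes: int
    skipped_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class KaKsRecord:
    gene: str
    pair: tuple[str, str]
    codons_compared: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float | None
    Ks: float | None
    flags: tuple[str, ...] = ()

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or None when Ks is zero/saturated (flagged)."""
        if self.Ka is None or self.Ks is None or self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def _check_alphabet(seq: str, label: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"sequence {label!r} contains unsupported characters {sorted(bad)}; "
            "only A,C,G,T,N,- are accepted"
        )


def p_distance(a: str, b: str, gene: str = "", pair: tuple[str, str] = ("a", "b")) -> DivergenceRecord:
    """Proportion of differing sites with pairwise deletion of gap/N columns.

    Symmetric in its arguments; raises on length mismatch or when no column
    is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    _check_alphabet(a, pair[0])
    _check_alphabet(b, pair[1])
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    skip = np.isin(xa, (45, 78)) | np.isin(xb, (45, 78))  # '-' or 'N'
    keep = ~skip
    compared = int(keep.sum())
    if compared == 0:
        raise ValueError("no comparable (gap/N-free) columns")
    mismatches = int((xa[keep] != xb[keep]).sum())
    return DivergenceRecord(gene, pair, compared, mismatches)


def jc_distance(p: float) -> float:
    """Jukes–Cantor correction ``d = -(3/4) ln(1 - 4p/3)``."""
    if p < 0:
        raise ValueError(f"p must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond the JC saturation limit 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def count_substitution_totals(alignments, pair: tuple[str, str]) -> SubstitutionTotals:
    """Sum pairwise differences over genes, excluding columns gapped (or N)
    in *any* taxon of each gene's alignment.

    Genes lacking either taxon are skipped and reported in the result.
    """
    t1, t2 = pair
    total_diff = 0
    total_sites = 0
    n_genes = 0
    skipped: list[str] = []
    for gene in alignments:
        seqs = alignments[gene]
        if t1 not in seqs or t2 not in seqs:
            skipped.append(gene)
            continue
        mats = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs.values()]
        stack = np.vstack(mats)
        keep = ~np.any((stack == 45) | (stack == 78), axis=0)
        xa = np.frombuffer(seqs[t1].encode(), dtype=np.uint8)[keep]
        xb = np.frombuffer(seqs[t2].encode(), dtype=np.uint8)[keep]
        total_diff += int((xa != xb).sum())
        total_sites += int(keep.sum())
        n_genes += 1
    if n_genes == 0:
        raise ValueError(f"no gene carries both taxa {pair}")
    return SubstitutionTotals(pair, total_diff, total_sites, n_genes, tuple(skipped))


# --- NG86 ----------------------------------------------------------------


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over all shortest mutational
    pathways; pathways passing through a stop codon are excluded.  If every
    pathway is blocked, all pathways are used with stop-involving steps
    counted as nonsynonymous."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def steps(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if pos != order[-1] and is_stop(nxt):
                return None  # intermediate stop: pathway excluded
            if not is_stop(cur) and not is_stop(nxt) and translate(cur) == translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in map(steps, itertools.permutations(diffs)) if r is not None]
    if not results:
        # all pathways blocked: count every step, stop steps as nonsynonymous
        results = []
        for order in itertools.permutations(diffs):
            sd = nd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if not is_stop(cur) and not is_stop(nxt) and translate(cur) == translate(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def ng86_ka_ks(a: str, b: str, gene: str = "", pair: tuple[str, str] = ("a", "b")) -> KaKsRecord:
    """Nei–Gojobori (1986) Ka/Ks for a pair of aligned coding sequences.

    Codons containing gaps, N, or a stop in either sequence are excluded
    pairwise.  Synonymous/nonsynonymous site counts are fractional and
    averaged over the two sequences; multi-hit codons average their
    substitution classes over all shortest pathways (stop-free pathways
    only).  ``Ka``/``Ks`` are Jukes–Cantor corrected; saturation or ``Ks = 0``
    leaves the ratio undefined and sets a flag.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValueError(f"length {len(a)} is not a multiple of 3")
    _check_alphabet(a, pair[0])
    _check_alphabet(b, pair[1])

    S_a = S_b = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(ch in "N-" for ch in ca + cb) or is_stop(ca) or is_stop(cb):
            continue
        n_codons += 1
        S_a += syn_sites(ca)
        S_b += syn_sites(cb)
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")

    S = 0.5 * (S_a + S_b)
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    flags: list[str] = []
    try:
        Ka: float | None = jc_distance(pN)
    except SaturationError:
        Ka = None
        flags.append("ka_saturated")
    try:
        Ks: float | None = jc_distance(pS)
    except SaturationError:
        Ks = None
        flags.append("ks_saturated")
    if Ks == 0.0:
        flags.append("ks_zero")
    return KaKsRecord(gene, pair, n_codons, N, S, Nd, Sd, pN, pS, Ka, Ks, tuple(flags))
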