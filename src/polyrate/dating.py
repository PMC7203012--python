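"""Molecular-clock conversion of synonymous divergence into time.

``T = Ks / (2 r)`` with ``r`` defaulting to 3.48e-9 substitutions per site
per year; the same clock dates LTR element insertions from the divergence
between an element's two terminal repeats (all aligned sites, since LTRs
are non-coding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .divergence import SaturationError, jc_distance, ng86_ka_ks, p_distance

__all__ = ["ClockEstimate", "DEFAULT_RATE", "clock_time", "date_species_pair", "date_ltr_insertion"]

DEFAULT_RATE = 3.48e-9


@dataclass(frozen=True)
class ClockEstimate:
    label: str
    ks_summary: float
    r: float
    T: float  # years
    n_genes: int
    n_excluded: int = 0
    summary: str = "median"


def clock_time(ks: float, r: float = DEFAULT_RATE) -> float:
    """Years since divergence: ``T = ks / (2 r)``."""
    if r <= 0:
        raise ValueError(f"rate r must be > 0, got {r}")
    if ks < 0:
        raise ValueError(f"ks must be >= 0, got {ks}")
    return ks / (2.0 * r)


def date_species_pair(
    alignments,
    pair: tuple[str, str],
    r: float = DEFAULT_RATE,
    summary: str = "median",
) -> ClockEstimate:
    """Date a species split from per-gene NG86 Ks values.

    Saturated genes (and genes lacking either taxon or comparable codons)
    are excluded and counted; ``summary`` is ``median`` (default) or
    ``mean``.
    """
    if summary not in ("median", "mean"):
        raise ValueError(f"summary must be 'median' or 'mean', got {summary!r}")
    t1, t2 = pair
    ks_values = []
    excluded = 0
    for gene in alignments:
        seqs = alignments[gene]
        if t1 not in seqs or t2 not in seqs:
            excluded += 1
            continue
        try:
            rec = ng86_ka_ks(seqs[t1], seqs[t2], gene=gene, pair=pair)
        except ValueError:
            excluded += 1
            continue
        if rec.Ks is None:  # saturated
            excluded += 1
            continue
        ks_values.append(rec.Ks)
    if not ks_values:
        raise ValueError(f"no gene yields a valid Ks for pair {pair}")
    ks = float(np.median(ks_values) if summary == "median" else np.mean(ks_values))
    return ClockEstimate(
        f"{t1}-{t2}", ks, r, clock_time(ks, r), len(ks_values), excluded, summary
    )


def _align_global(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
    )
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def date_ltr_insertion(
    five_prime: str,
    three_prime: str,
    r: float = DEFAULT_RATE,
    element_id: str = "",
) -> ClockEstimate:
    """Date an LTR element insertion from its two terminal repeats.

    Equal-length inputs are treated as already aligned; otherwise a global
    pairwise alignment is computed first.  K is the JC-corrected p-distance
    over all comparable sites; raises :class:`SaturationError` at p >= 0.75.
    """
    if len(five_prime) != len(three_prime):
        five_prime, three_prime = _align_global(five_prime, three_prime)
    rec = p_distance(five_prime, three_prime, gene=element_id, pair=("5ltr", "3ltr"))
    k = jc_distance(rec.p)  # SaturationError propagates
    return ClockEstimate(element_id or "ltr", k, r, clock_time(k, r), 1, 0, "single")
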