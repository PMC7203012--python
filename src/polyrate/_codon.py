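"""Standard-genetic-code tables shared by the simulator and NG86 counting."""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _AA[_stop] = "*"


def translate(codon: str) -> str:
    return _AA[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_synonymous(c1: str, c2: str) -> bool:
    """Same amino acid, neither codon a stop."""
    return c1 not in STOP_CODONS and c2 not in STOP_CODONS and _AA[c1] == _AA[c2]


@lru_cache(maxsize=None)
def syn_site_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the three single-nucleotide changes that are
    synonymous.  Changes to stop codons count as nonsynonymous."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    out = []
    for pos in range(3):
        syn = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if not is_stop(mutant) and _AA[mutant] == _AA[codon]:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)  # type: ignore[return-value]


def syn_sites(codon: str) -> float:
    """Fractional synonymous sites in *codon* (0..3)."""
    return sum(syn_site_fractions(codon))
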