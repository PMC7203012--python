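"""LTR retrotransposon pair simulation: two terminal repeats identical at
insertion, each accumulating Jukes–Cantor substitutions for *age* years."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .history import DEFAULT_CLOCK_RATE
from .sequences import SimTruth

__all__ = ["LTRPair", "LTRPairSet", "sim_ltr_pairs"]

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LTRPair:
    element_id: str
    five_prime: str
    three_prime: str


@dataclass
class LTRPairSet:
    pairs: list[LTRPair] = field(default_factory=list)

    def __iter__(self) -> Iterator[LTRPair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _jc_mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor endpoint sampling at branch length *d* subs/site."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p_change)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


def sim_ltr_pairs(
    n: int,
    age_dist: float | Sequence[float] | Callable[[np.random.Generator], float],
    r: float = DEFAULT_CLOCK_RATE,
    seed: int | None = None,
    length: int = 1000,
) -> tuple[LTRPairSet, SimTruth]:
    """Simulate *n* LTR element pairs whose 5'/3' repeats have diverged for
    ``2 * r * age`` expected substitutions/site.

    *age_dist* is a fixed age in years, a per-element sequence, or a
    callable drawing from the element's RNG stream.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if r <= 0:
        raise ValueError(f"rate r must be > 0, got {r}")
    out = LTRPairSet()
    truth = SimTruth()
    width = max(4, len(str(n)))
    for k in range(n):
        rng = np.random.default_rng([seed, k])
        if callable(age_dist):
            age = float(age_dist(rng))
        elif isinstance(age_dist, (int, float)):
            age = float(age_dist)
        else:
            age = float(age_dist[k % len(age_dist)])
        if age < 0:
            raise ValueError(f"ages must be >= 0, got {age}")
        ancestor = _NUC[rng.integers(0, 4, size=length)]
        d = r * age
        five = _jc_mutate(np.searchsorted(_NUC, ancestor), d, rng)
        three = _jc_mutate(np.searchsorted(_NUC, ancestor), d, rng)
        elem = f"ltr{k:0{width}d}"
        out.pairs.append(
            LTRPair(elem, _NUC[five].tobytes().decode(), _NUC[three].tobytes().decode())
        )
        truth.ltr_ages[elem] = age
    return out, truth
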