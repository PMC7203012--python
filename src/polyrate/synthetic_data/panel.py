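"""Recombination-landscape panel simulator.

Phased haplotypes are founder mosaics whose switch (recombination)
probability between adjacent SNPs is distance-scaled, suppressed inside
planted low-recombination blocks.  Per-window methylation (CG/CHG/CHH) and
chromatin-contact records are drawn with block-conditional parameters:
planted blocks are hypermethylated and carry more-but-weaker, longer-range
contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..recomb_epigenome import GenotypePanel
from .sequences import SimTruth

__all__ = ["PanelConfig", "sim_recomb_panel", "sim_marey_map"]

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class PanelConfig:
    chrom: str = "chr1"
    length: int = 2_000_000
    n_snps: int = 200
    n_haplotypes: int = 100
    #: planted low-recombination blocks, 0-based half-open bp intervals
    blocks: list[tuple[int, int]] = field(default_factory=list)
    #: per-bp founder-switch intensity outside blocks
    background_recomb: float = 1e-3
    #: multiplier on background_recomb inside blocks (~0 = complete LD)
    within_block_factor: float = 0.0
    n_founders: int = 2
    missing_rate: float = 0.0
    #: context -> (block mean, background mean), proportions in [0, 1]
    meth_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CG": (0.85, 0.55), "CHG": (0.65, 0.35), "CHH": (0.25, 0.10)}
    )
    meth_sd: float = 0.05
    meth_window: int = 1000
    contact_window: int = 100_000
    #: mean number of contacts per contact window (block, background).
    #: blocks carry many more contacts, each somewhat weaker, so that the
    #: count of strong contacts (intensity > 5) is still higher in blocks
    contact_rate: tuple[float, float] = (30.0, 6.0)
    #: mean contact intensity (block, background)
    contact_intensity: tuple[float, float] = (6.0, 8.0)
    #: mean contact genomic distance in bp (block, background)
    contact_distance: tuple[float, float] = (5e6, 1e6)

    def validate(self) -> None:
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid VCF output)")
        if self.n_snps < 2:
            raise ValueError("need >= 2 SNPs")
        blocks = sorted(self.blocks)
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError(f"planted blocks overlap: {(s0, e0)} and {(s1, e1)}")
        for s, e in blocks:
            if not 0 <= s < e <= self.length:
                raise ValueError(f"block {(s, e)} outside [0, {self.length})")
        for ctx, (m1, m0) in self.meth_means.items():
            if not (0 <= m1 <= 1 and 0 <= m0 <= 1):
                raise ValueError(f"methylation means for {ctx} outside [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _in_block(blocks: list[tuple[int, int]], lo: int, hi: int) -> bool:
    """True when [lo, hi) lies entirely inside one planted block."""
    return any(s <= lo and hi <= e for s, e in blocks)


def _block_cover(blocks: list[tuple[int, int]], lo: int, hi: int) -> float:
    cov = sum(max(0, min(hi, e) - max(lo, s)) for s, e in blocks)
    return cov / max(1, hi - lo)


def sim_recomb_panel(
    config: PanelConfig, seed: int | None = None
) -> tuple[GenotypePanel, dict[str, pd.DataFrame], pd.DataFrame, SimTruth]:
    """Returns (panel, methylation tracks per context, contact table, truth).

    Tracks are bedGraph-dialect frames (``chrom start end value``); the
    contact table has one row per simulated contact (``chrom start end
    intensity distance``, window coordinates).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    config.validate()
    rng = np.random.default_rng([seed, 0])
    blocks = sorted(config.blocks)

    positions = np.sort(
        rng.choice(np.arange(1, config.length + 1), size=config.n_snps, replace=False)
    )
    k = config.n_founders
    if k == 2:
        founders = np.zeros((2, config.n_snps), dtype=np.int8)
        founders[1] = 1  # complementary founders: every SNP polymorphic
    else:
        founders = (rng.random((k, config.n_snps)) < 0.5).astype(np.int8)
        mono = founders.min(axis=0) == founders.max(axis=0)
        founders[0, mono] = 1 - founders[0, mono]

    # switch probability per adjacent-SNP interval
    gaps = np.diff(positions)
    rate = np.full(gaps.size, config.background_recomb)
    for g in range(gaps.size):
        if _in_block(blocks, int(positions[g]), int(positions[g + 1])):
            rate[g] = config.background_recomb * config.within_block_factor
    p_switch = 0.5 * (1.0 - np.exp(-2.0 * rate * gaps))

    haps = np.empty((config.n_haplotypes, config.n_snps), dtype=np.int8)
    for h in range(config.n_haplotypes):
        state = int(rng.integers(k))
        switches = rng.random(gaps.size) < p_switch
        new_states = rng.integers(0, k, size=gaps.size)
        haps[h, 0] = founders[state, 0]
        for j in range(1, config.n_snps):
            if switches[j - 1]:
                state = int(new_states[j - 1])
            haps[h, j] = founders[state, j]
    if config.missing_rate > 0:
        haps[rng.random(haps.shape) < config.missing_rate] = -1
    panel = GenotypePanel(config.chrom, positions, haps)

    truth = SimTruth()
    truth.blocks = [tuple(b) for b in blocks]
    truth.effects = {
        "meth_means": dict(config.meth_means),
        "contact_rate": config.contact_rate,
        "contact_intensity": config.contact_intensity,
        "contact_distance": config.contact_distance,
    }

    meth_tracks: dict[str, pd.DataFrame] = {}
    n_meth = math.ceil(config.length / config.meth_window)
    starts = np.arange(n_meth) * config.meth_window
    ends = np.minimum(starts + config.meth_window, config.length)
    cold = np.array(
        [_block_cover(blocks, int(s), int(e)) > 0.5 for s, e in zip(starts, ends)]
    )
    for ctx in CONTEXTS:
        m_block, m_bg = config.meth_means.get(ctx, (0.5, 0.5))
        mu = np.where(cold, m_block, m_bg)
        vals = np.clip(rng.normal(mu, config.meth_sd), 0.0, 1.0)
        meth_tracks[ctx] = pd.DataFrame(
            {"chrom": config.chrom, "start": starts, "end": ends, "value": vals}
        )

    rows = []
    for w0 in range(0, config.length, config.contact_window):
        w1 = min(w0 + config.contact_window, config.length)
        is_cold = _block_cover(blocks, w0, w1) > 0.5
        lam = config.contact_rate[0] if is_cold else config.contact_rate[1]
        mu_i = config.contact_intensity[0] if is_cold else config.contact_intensity[1]
        mu_d = config.contact_distance[0] if is_cold else config.contact_distance[1]
        n_contacts = rng.poisson(lam)
        intensities = rng.exponential(mu_i, size=n_contacts)
        distances = rng.exponential(mu_d, size=n_contacts)
        for it, dist in zip(intensities, distances):
            rows.append((config.chrom, w0, w1, float(it), float(dist)))
    contacts = pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity", "distance"])
    return panel, meth_tracks, contacts, truth


def sim_marey_map(
    config: PanelConfig,
    seed: int | None = None,
    n_markers: int = 400,
    background_rate: float = 2.0,
    noise_sd_cm: float = 0.0,
) -> pd.DataFrame:
    """Genetic-map points (``pos`` bp, ``cm``) consistent with the planted
    blocks: recombination accrues at *background_rate* cM/Mb outside blocks
    and not at all inside them.

    Optional marker-level noise is drawn per marker and kept monotone by a
    cumulative-maximum pass.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    config.validate()
    rng = np.random.default_rng([seed, 1])
    blocks = sorted(config.blocks)
    pos = np.sort(rng.choice(np.arange(1, config.length + 1), size=n_markers, replace=False))

    def cm_at(x: int) -> float:
        covered = sum(max(0, min(x, e) - s) for s, e in blocks if s < x)
        return background_rate * (x - covered) / 1e6

    cm = np.array([cm_at(int(p)) for p in pos])
    if noise_sd_cm > 0:
        cm = np.maximum.accumulate(cm + rng.normal(0, noise_sd_cm, size=cm.size))
        cm -= cm[0]
    return pd.DataFrame({"pos": pos, "cm": cm})
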