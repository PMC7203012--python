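"""Recombination-landscape analyses.

Haplotype-block (cold-spot) calling from phased panels via D' confidence
bounds, Marey-map recombination rates by local linear regression, and
correlation of block membership with methylation and chromatin-contact
summaries.  Genomic intervals are 0-based half-open internally; VCF
positions are 1-based on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypePanel",
    "HaplotypeBlock",
    "DPrimeResult",
    "MareyTrack",
    "LandscapeWindow",
    "filter_panel",
    "dprime",
    "call_blocks",
    "marey_rates",
    "summarize_windows",
    "correlate_landscape",
]

MISSING = -1


@dataclass
class GenotypePanel:
    """Phased haplotypes: ``haplotypes[h, s]`` in {0, 1, -1=missing};
    positions 1-based as in VCF, strictly increasing."""

    chrom: str
    positions: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix shape does not match positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haplotypes, (0, 1, MISSING)).all():
            raise ValueError("haplotype alleles must be 0, 1 or -1 (missing)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.positions.size

    def missing_rate(self) -> np.ndarray:
        return (self.haplotypes == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        called = self.haplotypes != MISSING
        ones = np.where(self.haplotypes == 1, 1, 0).sum(axis=0)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = ones / n
        freq = np.where(n == 0, 0.0, freq)
        return np.minimum(freq, 1 - freq)


@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snps: int
    mean_abs_dprime: float
    snp_indices: tuple[int, int] = (0, 0)  # inclusive index range in the panel


@dataclass(frozen=True)
class DPrimeResult:
    d: float
    dprime: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class MareyTrack:
    chrom: str
    windows: pd.DataFrame  # start, end, n_snps, rate, raw_rate, flag
    span_markers: int
    n_markers: int
    monotonicity_violations: int = 0


@dataclass(frozen=True)
class LandscapeWindow:
    chrom: str
    start: int
    end: int
    is_cold: bool
    meth: dict  # context -> level in [0,1] (NaN when uncovered)
    n_strong_contacts: int
    mean_intensity: float
    mean_contact_distance: float


# --- panel filtering ------------------------------------------------------


def filter_panel(
    panel: GenotypePanel, maf_min: float = 0.05, missing_max: float = 0.10
) -> tuple[GenotypePanel, int]:
    """Retain SNPs with MAF strictly greater than *maf_min* and missing rate
    strictly less than *missing_max*.  Returns (panel, n_removed)."""
    keep = (panel.maf() > maf_min) & (panel.missing_rate() < missing_max)
    if not keep.any():
        raise ValueError("no SNP passes the MAF/missingness filters")
    removed = int((~keep).sum())
    return (
        GenotypePanel(panel.chrom, panel.positions[keep], panel.haplotypes[:, keep]),
        removed,
    )


# --- D' -------------------------------------------------------------------


def _dprime_from_freqs(p11: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    d = p11 - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        dmax = np.where(
            d >= 0,
            np.minimum(pa * (1 - pb), (1 - pa) * pb),
            np.minimum(pa * pb, (1 - pa) * (1 - pb)),
        )
        out = np.where(dmax > 0, d / np.where(dmax > 0, dmax, 1.0), 0.0)
    return out


def dprime(
    counts, n_boot: int = 200, ci: float = 0.90, seed: int = 0
) -> DPrimeResult:
    """D' for a 2x2 table of phased haplotype counts, with a bootstrap CI.

    ``counts[i][j]`` is the number of haplotypes carrying allele ``i`` at
    locus 1 and ``j`` at locus 2.  The CI (default 90%) is a percentile
    bootstrap over haplotypes of ``|D'|``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    n = c.sum()
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    pa = (c[1, 0] + c[1, 1]) / n
    pb = (c[0, 1] + c[1, 1]) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: D' undefined")
    p11 = c[1, 1] / n
    d = p11 - pa * pb
    dp = float(_dprime_from_freqs(np.array(p11), np.array(pa), np.array(pb)))

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(n), c.flatten() / n, size=n_boot).astype(float) / n
    b_pa = draws[:, 2] + draws[:, 3]
    b_pb = draws[:, 1] + draws[:, 3]
    b_dp = np.abs(_dprime_from_freqs(draws[:, 3], b_pa, b_pb))
    lo, hi = np.quantile(b_dp, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return DPrimeResult(float(d), dp, float(lo), float(hi), int(n))


def _pair_counts(panel: GenotypePanel, i: int, j: int) -> np.ndarray | None:
    hi = panel.haplotypes[:, i]
    hj = panel.haplotypes[:, j]
    ok = (hi != MISSING) & (hj != MISSING)
    hi, hj = hi[ok], hj[ok]
    if hi.size < 4 or len(set(hi.tolist())) < 2 or len(set(hj.tolist())) < 2:
        return None
    c = np.zeros((2, 2))
    np.add.at(c, (hi, hj), 1)
    return c


# --- block calling --------------------------------------------------------


def call_blocks(
    panel: GenotypePanel,
    dprime_upper_min: float = 0.90,
    dprime_lower_min: float = 0.70,
    strong_fraction: float = 0.95,
    max_span: int = 60,
    min_snps: int = 2,
    n_boot: int = 200,
    ci: float = 0.90,
    seed: int = 0,
) -> list[HaplotypeBlock]:
    """Gabriel-style haplotype-block partition.

    A SNP pair is in *strong LD* when the bootstrap CI of |D'| has upper
    bound >= *dprime_upper_min* and lower bound >= *dprime_lower_min*.
    Candidate runs of consecutive SNPs (up to *max_span* SNPs) qualify when
    the fraction of informative pairs in strong LD is >= *strong_fraction*;
    qualifying runs are accepted greedily longest first, non-overlapping.
    """
    n = panel.n_snps
    if n < 2:
        raise ValueError("need >= 2 SNPs")
    rng = np.random.default_rng(seed)

    strong = {}
    informative = {}
    absdp = {}
    for i in range(n):
        for j in range(i + 1, min(n, i + max_span + 1)):
            c = _pair_counts(panel, i, j)
            if c is None:
                informative[(i, j)] = False
                continue
            res = dprime(c, n_boot=n_boot, ci=ci, seed=int(rng.integers(2**31)))
            informative[(i, j)] = True
            absdp[(i, j)] = abs(res.dprime)
            strong[(i, j)] = (res.ci_high >= dprime_upper_min) and (
                res.ci_low >= dprime_lower_min
            )

    candidates = []
    for i in range(n):
        n_inf = n_str = 0
        for j in range(i + 1, min(n, i + max_span + 1)):
            for k in range(i, j):
                if informative.get((k, j), False):
                    n_inf += 1
                    if strong[(k, j)]:
                        n_str += 1
            if j - i + 1 >= min_snps and n_inf > 0 and n_str / n_inf >= strong_fraction:
                candidates.append((i, j, n_str, n_inf))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    taken = np.zeros(n, dtype=bool)
    blocks: list[HaplotypeBlock] = []
    for i, j, _ns, _ni in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        vals = [absdp[(k, l)] for k in range(i, j) for l in range(k + 1, j + 1) if (k, l) in absdp]
        blocks.append(
            HaplotypeBlock(
                panel.chrom,
                int(panel.positions[i] - 1),
                int(panel.positions[j]),
                j - i + 1,
                float(np.mean(vals)) if vals else float("nan"),
                (i, j),
            )
        )
    blocks.sort(key=lambda b: b.start)
    # contract: sorted, non-overlapping, >= 2 SNPs each
    for a, b in zip(blocks, blocks[1:]):
        assert a.end <= b.start
    assert all(b.n_snps >= 2 for b in blocks)
    return blocks


# --- Marey map ------------------------------------------------------------


def marey_rates(
    map_points: pd.DataFrame,
    span_fraction: float = 0.075,
    window: int = 1_000_000,
    min_snps: int = 4,
    chrom_length: int | None = None,
    chrom: str = "chr",
) -> MareyTrack:
    """Recombination rate (cM/Mb) per non-overlapping window from a Marey
    map (physical bp vs genetic cM).

    At each window midpoint a local linear regression of cM on bp is fitted
    over the ``ceil(span_fraction * n)`` nearest markers with tricube
    weights; the slope is the rate.  Windows with fewer than *min_snps*
    markers are no-call.  Negative slopes are reported raw and flagged;
    ``rate`` is clamped at 0.
    """
    pts = map_points[["pos", "cm"]].dropna().sort_values("pos")
    pos = pts["pos"].to_numpy(dtype=float)
    cm = pts["cm"].to_numpy(dtype=float)
    n = pos.size
    if n < 10:
        raise ValueError("need >= 10 markers")
    if np.ptp(pos) == 0:
        raise ValueError("all markers at one physical position")
    violations = int((np.diff(cm) < 0).sum())
    span = max(2, math.ceil(span_fraction * n))

    length = int(chrom_length if chrom_length is not None else pos.max())
    starts = np.arange(0, length, window, dtype=np.int64)
    rows = []
    for start in starts:
        end = min(start + window, length)
        mid = (start + end) / 2.0
        n_in = int(((pos >= start) & (pos < end)).sum())
        dist = np.abs(pos - mid)
        idx = np.argsort(dist, kind="stable")[:span]
        dmax = dist[idx].max()
        if dmax == 0:
            raw = float("nan")
        else:
            w = (1 - (dist[idx] / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-12)
            x, y = pos[idx], cm[idx]
            xm = np.average(x, weights=w)
            ym = np.average(y, weights=w)
            sxx = np.sum(w * (x - xm) ** 2)
            raw = float(np.sum(w * (x - xm) * (y - ym)) / sxx) * 1e6 if sxx > 0 else float("nan")
        if n_in < min_snps:
            flag = "no_call"
            rate = float("nan")
        elif not np.isfinite(raw):
            flag = "degenerate"
            rate = float("nan")
        elif raw < 0:
            flag = "negative"
            rate = 0.0
        else:
            flag = ""
            rate = raw
        rows.append((int(start), int(end), n_in, rate, raw, flag))
    df = pd.DataFrame(rows, columns=["start", "end", "n_snps", "rate", "raw_rate", "flag"])
    return MareyTrack(chrom, df, span, n, violations)


# --- landscape windows ----------------------------------------------------


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def summarize_windows(
    blocks: list[HaplotypeBlock],
    meth_tracks: dict[str, pd.DataFrame],
    contact_table: pd.DataFrame,
    strong_threshold: float = 5.0,
    window: int = 1_000_000,
    chrom_length: int | None = None,
    chrom: str = "chr",
    cold_overlap: float = 0.5,
) -> list[LandscapeWindow]:
    """Aggregate block membership, methylation and contact statistics into
    non-overlapping analysis windows.

    Methylation tracks (``chrom start end value``, 0-based half-open) are
    aggregated by coverage-weighted mean; a window is cold when blocks cover
    more than *cold_overlap* of its length; contacts are counted as strong
    when ``intensity > strong_threshold``.
    """
    ends = [int(t["end"].max()) for t in meth_tracks.values() if len(t)]
    if len(contact_table):
        ends.append(int(contact_table["end"].max()))
    ends.extend(b.end for b in blocks)
    length = int(chrom_length if chrom_length is not None else max(ends))
    out: list[LandscapeWindow] = []
    for start in range(0, length, window):
        end = min(start + window, length)
        cov = sum(_overlap(start, end, b.start, b.end) for b in blocks)
        is_cold = cov > cold_overlap * (end - start)
        meth = {}
        for context, track in meth_tracks.items():
            sub = track[(track["end"] > start) & (track["start"] < end)]
            if len(sub) == 0:
                meth[context] = float("nan")
                continue
            w = np.minimum(sub["end"], end) - np.maximum(sub["start"], start)
            meth[context] = float(np.average(sub["value"], weights=w))
        sub = contact_table[(contact_table["start"] >= start) & (contact_table["start"] < end)]
        n_strong = int((sub["intensity"] > strong_threshold).sum())
        mean_int = float(sub["intensity"].mean()) if len(sub) else float("nan")
        mean_dist = float(sub["distance"].mean()) if len(sub) else float("nan")
        out.append(
            LandscapeWindow(chrom, start, end, bool(is_cold), meth, n_strong, mean_int, mean_dist)
        )
    return out


def correlate_landscape(windows: list[LandscapeWindow]) -> pd.DataFrame:
    """Cold-vs-hot comparison per landscape variable.

    For each variable: point-biserial Pearson r against the cold indicator,
    one-way ANOVA F and p between classes, class means and n.  Variables
    with zero variance get NaN statistics and a note.
    """
    if len(windows) < 10:
        raise ValueError("need >= 10 windows")
    cold = np.array([w.is_cold for w in windows], dtype=float)
    if cold.all() or not cold.any():
        raise ValueError("both cold and hot windows are required")
    contexts = sorted({c for w in windows for c in w.meth})
    variables = {f"meth_{c}": np.array([w.meth.get(c, np.nan) for w in windows]) for c in contexts}
    variables["n_strong_contacts"] = np.array([w.n_strong_contacts for w in windows], dtype=float)
    variables["mean_intensity"] = np.array([w.mean_intensity for w in windows])
    variables["mean_contact_distance"] = np.array([w.mean_contact_distance for w in windows])

    rows = []
    for name, vals in variables.items():
        ok = np.isfinite(vals)
        v, c = vals[ok], cold[ok]
        n = int(ok.sum())
        note = ""
        if n < 3 or np.std(v) == 0 or np.std(c) == 0:
            r = f_stat = p = float("nan")
            note = "undefined (zero variance or too few windows)"
            mean_cold = float(v[c == 1].mean()) if (c == 1).any() else float("nan")
            mean_hot = float(v[c == 0].mean()) if (c == 0).any() else float("nan")
        else:
            r = float(stats.pearsonr(c, v).statistic)
            f_stat, p = stats.f_oneway(v[c == 1], v[c == 0])
            mean_cold = float(v[c == 1].mean())
            mean_hot = float(v[c == 0].mean())
        rows.append((name, n, r, float(f_stat), float(p), mean_cold, mean_hot, note))
    return pd.DataFrame(
        rows,
        columns=["variable", "n", "pearson_r", "anova_F", "anova_p", "mean_cold", "mean_hot", "note"],
    )
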