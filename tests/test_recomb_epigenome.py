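import numpy as np
import pandas as pd
import pytest

from polyrate.recomb_epigenome import (
    GenotypePanel,
    HaplotypeBlock,
    call_blocks,
    correlate_landscape,
    dprime,
    filter_panel,
    marey_rates,
    summarize_windows,
)
from polyrate.synthetic_data import PanelConfig, sim_recomb_panel
from polyrate.synthetic_data.panel import sim_marey_map

# ---------------------------------------------------------------- helpers


def dprime_formula_oracle(c):
    """Direct D' formula on a 2x2 haplotype count table."""
    c = np.asarray(c, dtype=float)
    n = c.sum()
    pa = (c[1, 0] + c[1, 1]) / n
    pb = (c[0, 1] + c[1, 1]) / n
    d = c[1, 1] / n - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    return d / dmax if dmax > 0 else 0.0


def make_panel(haps, positions=None, chrom="chr1"):
    haps = np.asarray(haps, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, haps.shape[1] + 1) * 100
    return GenotypePanel(chrom, positions, haps)


# ---------------------------------------------------------------- panel


class TestGenotypePanel:
    def test_position_order_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            make_panel([[0, 1], [1, 0]], positions=[5, 5])

    def test_allele_domain_enforced(self):
        with pytest.raises(ValueError, match="alleles"):
            make_panel([[0, 2]])

    def test_maf_and_missing(self):
        panel = make_panel([[0, 1], [0, -1], [1, 1], [1, 0]])
        assert panel.maf() == pytest.approx([0.5, 1 / 3])
        assert panel.missing_rate() == pytest.approx([0.0, 0.25])


class TestFilterPanel:
    def _panel(self, mafs, missings, n_hap=100):
        cols = []
        for maf, miss in zip(mafs, missings):
            n_miss = int(round(miss * n_hap))
            n_one = int(round(maf * (n_hap - n_miss)))
            col = [1] * n_one + [0] * (n_hap - n_miss - n_one) + [-1] * n_miss
            cols.append(col)
        return make_panel(np.array(cols).T)

    def test_maf_exactly_at_threshold_removed(self):
        panel = self._panel([0.05, 0.2], [0.0, 0.0])
        kept, removed = filter_panel(panel)
        assert kept.n_snps == 1
        assert removed == 1

    def test_missing_below_threshold_kept(self):
        panel = self._panel([0.3, 0.3], [0.09, 0.10])
        kept, removed = filter_panel(panel)
        assert kept.n_snps == 1  # 0.10 removed by strict <

    def test_hand_filter(self):
        mafs = [0.02, 0.06, 0.5, 0.04, 0.2, 0.3, 0.05, 0.1, 0.45, 0.25]
        miss = [0.0, 0.0, 0.2, 0.0, 0.0, 0.04, 0.0, 0.12, 0.0, 0.06]
        kept, removed = filter_panel(self._panel(mafs, miss))
        assert kept.n_snps == 5  # indices 1, 4, 5, 8, 9
        assert removed == 5

    def test_empty_result(self):
        panel = self._panel([0.01], [0.0])
        with pytest.raises(ValueError, match="no SNP"):
            filter_panel(panel)


# ---------------------------------------------------------------- D'


class TestDprime:
    def test_complete_ld(self):
        res = dprime([[25, 0], [0, 25]])
        assert res.dprime == pytest.approx(1.0)

    def test_independence(self):
        res = dprime([[25, 25], [25, 25]])
        assert res.dprime == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            dprime([[50, 0], [50, 0]])

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError, match="4"):
            dprime([[1, 0], [0, 2]])

    def test_against_formula_oracle(self, rng):
        for _ in range(50):
            c = rng.integers(1, 50, size=(2, 2))
            res = dprime(c)
            assert res.dprime == pytest.approx(dprime_formula_oracle(c), abs=1e-12)

    def test_range_and_missing_class(self, rng):
        for _ in range(50):
            c = rng.integers(0, 40, size=(2, 2))
            if (c.sum(axis=1) == 0).any() or (c.sum(axis=0) == 0).any() or c.sum() < 4:
                continue
            res = dprime(c)
            assert -1 - 1e-12 <= res.dprime <= 1 + 1e-12
            if (c == 0).any():
                assert abs(res.dprime) == pytest.approx(1.0)

    def test_ci_brackets_point(self):
        res = dprime([[40, 3], [2, 55]], n_boot=500, seed=1)
        assert res.ci_low <= abs(res.dprime) <= res.ci_high


# ---------------------------------------------------------------- blocks


def _panel_cfg(**kw):
    base = dict(length=600_000, n_snps=120, n_haplotypes=80,
                blocks=[(100_000, 250_000), (400_000, 520_000)],
                background_recomb=5e-4)
    base.update(kw)
    return PanelConfig(**base)


class TestCallBlocks:
    def test_planted_blocks_recovered(self):
        cfg = _panel_cfg()
        panel, *_ = sim_recomb_panel(cfg, seed=11)
        blocks = call_blocks(panel, seed=1)
        for s, e in cfg.blocks:
            inside = [i for i, p in enumerate(panel.positions) if s < p <= e]
            covered = sum(
                1 for i in inside
                if any(b.snp_indices[0] <= i <= b.snp_indices[1] for b in blocks)
            )
            assert covered / len(inside) >= 0.9

    def test_two_planted_blocks_disjoint_calls(self):
        cfg = _panel_cfg()
        panel, *_ = sim_recomb_panel(cfg, seed=12)
        blocks = call_blocks(panel, seed=2)
        hits = set()
        for s, e in cfg.blocks:
            for b in blocks:
                mid = (b.start + b.end) / 2
                if s <= mid < e:
                    hits.add((s, e))
        assert len(hits) == 2

    def test_free_recombination_no_blocks(self):
        cfg = _panel_cfg(blocks=[], background_recomb=1.0, n_snps=60)
        for seed in range(3):
            panel, *_ = sim_recomb_panel(cfg, seed=seed)
            blocks = call_blocks(panel, seed=seed)
            assert all(b.n_snps < 5 for b in blocks)

    def test_sorted_nonoverlapping_invariant(self):
        panel, *_ = sim_recomb_panel(_panel_cfg(), seed=13)
        blocks = call_blocks(panel, seed=3)
        for a, b in zip(blocks, blocks[1:]):
            assert a.end <= b.start
        assert all(b.n_snps >= 2 for b in blocks)

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            call_blocks(make_panel([[0], [1], [0], [1]]))


# ---------------------------------------------------------------- Marey


class TestMareyRates:
    def _linear_map(self, n=200, length=20_000_000, rate=1.0):
        pos = np.linspace(1, length, n)
        return pd.DataFrame({"pos": pos, "cm": pos * rate / 1e6})

    def test_linear_map_recovered(self):
        track = marey_rates(self._linear_map(), chrom_length=20_000_000)
        called = track.windows[track.windows["flag"] == ""]
        assert len(called) > 0
        assert np.allclose(called["rate"], 1.0, atol=1e-6)

    def test_flat_map_zero(self):
        m = self._linear_map()
        m["cm"] = 0.0
        track = marey_rates(m, chrom_length=20_000_000)
        called = track.windows.dropna(subset=["rate"])
        assert np.allclose(called["rate"], 0.0, atol=1e-9)

    def test_piecewise_cold_region(self):
        # 0 cM/Mb inside [20,30] Mb, 2 cM/Mb outside
        pos = np.linspace(1, 50_000_000, 600)
        cold = (pos >= 20e6) & (pos < 30e6)
        cm = np.empty_like(pos)
        for i, p in enumerate(pos):
            covered = min(max(p - 20e6, 0), 10e6)
            cm[i] = 2.0 * (p - covered) / 1e6
        track = marey_rates(pd.DataFrame({"pos": pos, "cm": cm}), chrom_length=50_000_000)
        w = track.windows
        mids = (w["start"] + w["end"]) / 2
        deep_cold = w[(mids > 22e6) & (mids < 28e6) & w["rate"].notna()]
        hot = w[((mids < 15e6) | (mids > 35e6)) & w["rate"].notna()]
        assert (deep_cold["rate"] < 0.5).all()
        assert (hot["rate"] > 1.5).all()

    def test_min_marker_count(self):
        with pytest.raises(ValueError, match="10"):
            marey_rates(pd.DataFrame({"pos": [1, 2], "cm": [0, 1]}))

    def test_single_position_error(self):
        df = pd.DataFrame({"pos": [5] * 12, "cm": range(12)})
        with pytest.raises(ValueError, match="position"):
            marey_rates(df)

    def test_low_snp_windows_flagged(self):
        m = self._linear_map(n=40, length=40_000_000)
        track = marey_rates(m, chrom_length=40_000_000)
        flagged = track.windows[track.windows["n_snps"] < 4]
        assert (flagged["flag"] == "no_call").all()
        assert flagged["rate"].isna().all()

    def test_planted_map_round_trip(self):
        cfg = _panel_cfg(length=10_000_000, blocks=[(2_000_000, 4_000_000)])
        m = sim_marey_map(cfg, seed=5, n_markers=500, background_rate=2.0)
        track = marey_rates(m, chrom_length=10_000_000)
        w = track.windows
        cold = w[(w["start"] >= 2e6) & (w["end"] <= 4e6)]["rate"].dropna()
        hot = w[(w["end"] <= 1e6) | (w["start"] >= 5e6)]["rate"].dropna()
        assert cold.mean() < 0.5
        assert hot.mean() > 1.0


# ---------------------------------------------------------------- windows


class TestSummarizeWindows:
    def _blocks(self):
        return [HaplotypeBlock("chr1", 0, 150_000, 10, 0.95)]

    def test_window_inside_block_cold(self):
        meth = {"CG": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "value": [0.5]})}
        contacts = pd.DataFrame(columns=["chrom", "start", "end", "intensity", "distance"])
        windows = summarize_windows(self._blocks(), meth, contacts, window=100_000,
                                    chrom_length=300_000)
        assert windows[0].is_cold is True
        assert windows[2].is_cold is False

    def test_coverage_weighted_mean(self):
        meth = {"CG": pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [0, 600],
            "end": [600, 1000],
            "value": [0.2, 0.8],
        })}
        contacts = pd.DataFrame(columns=["chrom", "start", "end", "intensity", "distance"])
        windows = summarize_windows([], meth, contacts, window=1000, chrom_length=1000)
        assert windows[0].meth["CG"] == pytest.approx(0.2 * 0.6 + 0.8 * 0.4)

    def test_strong_contact_count(self):
        meth = {"CG": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "value": [0.5]})}
        contacts = pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [0, 0, 0],
            "end": [1000] * 3,
            "intensity": [6.0, 7.0, 3.0],
            "distance": [1e6, 2e6, 3e6],
        })
        windows = summarize_windows([], meth, contacts, strong_threshold=5,
                                    window=1000, chrom_length=1000)
        assert windows[0].n_strong_contacts == 2
        assert windows[0].mean_intensity == pytest.approx(16 / 3)


# ---------------------------------------------------------------- correlation


def _simulated_windows(seed, **cfg_kw):
    cfg = _panel_cfg(length=3_000_000, n_snps=40,
                     blocks=[(500_000, 1_200_000), (1_800_000, 2_400_000)], **cfg_kw)
    _, meth, contacts, truth = sim_recomb_panel(cfg, seed=seed)
    blocks = [HaplotypeBlock("chr1", s, e, 5, 1.0) for s, e in truth.blocks]
    return summarize_windows(blocks, meth, contacts, window=100_000,
                             chrom_length=cfg.length)


class TestCorrelateLandscape:
    def test_planted_difference_detected(self):
        windows = _simulated_windows(7)
        report = correlate_landscape(windows).set_index("variable")
        assert report.loc["meth_CG", "anova_p"] < 1e-3
        assert report.loc["meth_CG", "pearson_r"] > 0
        assert report.loc["mean_intensity", "pearson_r"] < 0

    def test_single_class_rejected(self):
        windows = _simulated_windows(8)
        hot_only = [w for w in windows if not w.is_cold]
        with pytest.raises(ValueError, match="cold and hot"):
            correlate_landscape(hot_only)

    def test_too_few_windows(self):
        windows = _simulated_windows(9)[:5]
        with pytest.raises(ValueError, match="10"):
            correlate_landscape(windows)

    def test_constant_variable_flagged(self):
        windows = _simulated_windows(10)
        frozen = [
            LandscapeWindowPatch(w) for w in windows
        ]
        report = correlate_landscape(frozen).set_index("variable")
        assert np.isnan(report.loc["meth_CG", "pearson_r"])
        assert "undefined" in report.loc["meth_CG", "note"]

    def test_null_calibration(self):
        # identical distributions: rejection rate ~ alpha
        alpha = 0.05
        rejections = 0
        n_rep = 120
        for seed in range(n_rep):
            cfg_kw = dict(meth_means={"CG": (0.5, 0.5), "CHG": (0.5, 0.5), "CHH": (0.5, 0.5)},
                          contact_rate=(8.0, 8.0), contact_intensity=(5.0, 5.0),
                          contact_distance=(2e6, 2e6))
            windows = _simulated_windows(100 + seed, **cfg_kw)
            report = correlate_landscape(windows).set_index("variable")
            if report.loc["meth_CG", "anova_p"] < alpha:
                rejections += 1
        assert rejections / n_rep < 0.12


def LandscapeWindowPatch(w):
    from polyrate.recomb_epigenome import LandscapeWindow

    meth = dict(w.meth)
    meth["CG"] = 0.5
    return LandscapeWindow(w.chrom, w.start, w.end, w.is_cold, meth,
                          w.n_strong_contacts, w.mean_intensity, w.mean_contact_distance)
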