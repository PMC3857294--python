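import math

import numpy as np
import pandas as pd
import pytest

import chipbias as cb
from chipbias import peaks as pk
from chipbias.genome import CONTROL, TREATMENT


def poisson_tail_series(k, lam):
    """Brute-force upper tail P(X >= k) by direct series summation."""
    term = math.exp(-lam)
    cdf = 0.0
    for i in range(k):
        cdf += term
        term *= lam / (i + 1)
    return 1.0 - cdf


class TestPoissonTail:
    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 5.0, 12.5, 20.0])
    def test_matches_series_oracle(self, lam):
        ks = np.arange(1, 51)
        ours = pk.poisson_sf(ks, np.full_like(ks, lam, dtype=float))
        for k, p in zip(ks, ours):
            assert abs(p - poisson_tail_series(int(k), lam)) < 1e-10

    def test_example_k20_lambda5(self):
        assert pk.poisson_sf(np.array([20]), np.array([5.0]))[0] == pytest.approx(
            poisson_tail_series(20, 5.0), abs=1e-12
        )


class TestCallPeaks:
    def test_spike_is_recovered_with_summit(self, toy_fragments, genome):
        """A strong localized pile-up over a flat control yields one peak with
        the summit at the pile-up."""
        rng = np.random.default_rng(0)
        bg = [("chr1", int(s), int(s) + 150)
              for s in rng.integers(0, 49_000, 3000)]
        spike = [("chr1", int(s), int(s) + 150)
                 for s in rng.normal(25_000, 40, 400).astype(int)]
        chip = toy_fragments(bg + spike, sample_id="chip")
        ctrl = toy_fragments(
            [("chr1", int(s), int(s) + 150)
             for s in rng.integers(0, 49_000, 3000)],
            sample_id="ctl",
        )
        called = cb.call_peaks(chip, ctrl, {"chr1": 50_000}, qmin=2.0)
        assert len(called) == 1
        assert abs(called.iloc[0]["summit"] - 25_000 - 75) < 300
        assert called.iloc[0]["fold_enrichment"] > 2

    def test_zero_depth_control_falls_back_to_genome_lambda(self, toy_fragments):
        rng = np.random.default_rng(1)
        chip = toy_fragments(
            [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 9_900, 500)]
        )
        empty = toy_fragments([("chr1", 0, 50)])
        empty.records = empty.records.iloc[:0]
        called = cb.call_peaks(chip, empty, {"chr1": 10_000}, qmin=2.0)
        assert isinstance(called, pd.DataFrame)  # no crash, uniform -> no peaks
        assert len(called) == 0

    def test_threshold_nesting(self, genome, sizes, study_samples):
        """High-stringency peaks lie inside low-stringency peaks."""
        scan = pk.scan_windows(
            study_samples[("tf_chip", CONTROL)],
            study_samples[("input", CONTROL)],
            sizes,
        )
        low = pk.peaks_from_scan(scan, 2.0)
        high = pk.peaks_from_scan(scan, 20.0)
        assert len(high) <= len(low)
        for h in high.itertuples():
            inside = low[
                (low["chrom"] == h.chrom)
                & (low["start"] <= h.start)
                & (low["end"] >= h.end)
            ]
            assert len(inside) == 1

    def test_qmin_must_be_positive(self, study_samples, sizes):
        scan = pk.scan_windows(
            study_samples[("tf_chip", CONTROL)],
            study_samples[("input", CONTROL)],
            sizes,
        )
        with pytest.raises(ValueError):
            pk.peaks_from_scan(scan, 0.0)


def synthetic_region_pair(seed, n_loci=20, boost_loci=(), boost=3.0,
                          depth=200, chrom_len=None):
    if chrom_len is None:
        chrom_len = 2000 * n_loci + 2000
    """Poisson count libraries with discrete loci; returns peak frames and
    fragment sets for MA-normalization tests."""
    rng = np.random.default_rng(seed)
    rows_a, rows_b, peaks = [], [], []
    # per-locus depths span a range so the M-A fit is anchored by null loci
    depths = depth * 10 ** rng.uniform(-0.4, 0.4, n_loci)
    for i in range(n_loci):
        center = 1000 + 2000 * i
        lam = depths[i] * (boost if i in boost_loci else 1.0)
        for n, rows in ((rng.poisson(depths[i]), rows_b), (rng.poisson(lam), rows_a)):
            starts = rng.normal(center, 60, n).astype(int)
            rows += [("chr1", int(s), int(s) + 100) for s in starts]
        peaks.append(
            {"chrom": "chr1", "start": center - 250, "end": center + 250,
             "summit": center, "fold_enrichment": 5.0, "neglog10_q": 10.0,
             "n_windows": 1}
        )
    frame = pd.DataFrame(peaks)
    mk = lambda rows, sid: cb.FragmentSet(
        sid, "unknown", "",
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(strand="+"),
    ).sorted()
    return frame, mk(rows_a, "treat"), mk(rows_b, "ctl"), {"chr1": chrom_len}


class TestMaNormalize:
    def test_global_scaling_is_removed(self):
        frame, treat, ctrl, sizes = synthetic_region_pair(0)
        # double the treatment library by duplicating every fragment
        rec = pd.concat([treat.records] * 2, ignore_index=True)
        doubled = cb.FragmentSet("treat2", "unknown", "", rec).sorted()
        ma = cb.ma_normalize(frame, frame, doubled, ctrl, sizes)
        common = ma.regions[ma.regions["common"]]
        assert abs(common["M_norm"].mean()) < 1e-6
        assert common["M"].mean() == pytest.approx(1.0, abs=0.15)

    def test_common_peak_mean_is_centred_for_any_input(self):
        for seed in (1, 2, 3):
            frame, treat, ctrl, sizes = synthetic_region_pair(seed, boost_loci=(0, 5))
            ma = cb.ma_normalize(frame, frame, treat, ctrl, sizes)
            common = ma.regions[ma.regions["common"]]
            assert abs(common["M_norm"].mean()) < 1e-6

    def test_too_few_common_peaks_aborts(self):
        frame, treat, ctrl, sizes = synthetic_region_pair(4)
        with pytest.raises(ValueError, match="common peaks"):
            cb.ma_normalize(frame.head(3), frame.head(3), treat, ctrl, sizes)

    def test_known_threefold_effect_is_recovered(self):
        # 3 of 60 loci truly tripled; the fit (anchored by the unchanged
        # majority) leaves their normalized M near log2(3)
        frame, treat, ctrl, sizes = synthetic_region_pair(
            5, n_loci=60, boost_loci=(10, 30, 50), boost=3.0, depth=400
        )
        ma = cb.ma_normalize(frame, frame, treat, ctrl, sizes)
        boosted = ma.regions.iloc[[10, 30, 50]]
        assert len(ma.regions) == 60
        assert boosted["M_norm"].mean() == pytest.approx(np.log2(3), abs=0.3)


class TestIdentifyDbts:
    def test_null_pair_yields_no_dbts(self):
        hits = 0
        for seed in range(10):
            frame, treat, ctrl, sizes = synthetic_region_pair(100 + seed)
            ma = cb.ma_normalize(frame, frame, treat, ctrl, sizes)
            hits += len(cb.identify_dbts(ma, qmin=5.0)) > 0
        assert hits <= 1

    def test_stringency_monotonicity_and_direction(self):
        frame, treat, ctrl, sizes = synthetic_region_pair(
            6, n_loci=24, boost_loci=(1, 7, 13), boost=3.0, depth=400
        )
        ma = cb.ma_normalize(frame, frame, treat, ctrl, sizes)
        d5 = cb.identify_dbts(ma, qmin=5.0)
        d20 = cb.identify_dbts(ma, qmin=20.0)
        assert len(d20) <= len(d5)
        assert (d5["M_norm"] > 0).all()  # control-higher regions are ignored
        assert len(d5) >= 3


class TestAssignToOrfs:
    GENES = pd.DataFrame(
        [
            {"gene_id": "plus", "chrom": "c", "strand": "+",
             "start": 1000, "end": 2000, "tss": 1000, "tes": 2000},
            {"gene_id": "minus", "chrom": "c", "strand": "-",
             "start": 3000, "end": 4000, "tss": 4000, "tes": 3000},
        ]
    )

    @staticmethod
    def dbts(summits):
        return pd.DataFrame(
            [{"chrom": "c", "start": s - 50, "end": s + 50, "summit": s,
              "M_norm": 1.0} for s in summits]
        )

    @pytest.mark.parametrize(
        "summit,expected",
        [
            (1001, "gene_body"),   # TSS+1, half-open interval
            (999, "promoter"),     # TSS-1, upstream window
            (1000, "gene_body"),   # boundary base belongs to the body
            (4000, "promoter"),    # minus-strand upstream is to the right
            (3999, "gene_body"),
            (2500, "intergenic"),
        ],
    )
    def test_summit_classification(self, summit, expected):
        out, _ = cb.assign_to_orfs(self.dbts([summit]), self.GENES)
        assert out.iloc[0]["orf_overlap"] == expected

    def test_summary_percentage(self):
        out, summary = cb.assign_to_orfs(
            self.dbts([1500, 3500, 999, 2500]), self.GENES
        )
        assert summary.n_dbts == 4
        assert summary.n_dbts_in_gene_bodies == 2
        assert summary.pct_in_gene_bodies == pytest.approx(50.0)


class TestQuadrantOverlay:
    def test_all_positive_deltas_fill_upper_right(self):
        dr = pd.Series({"a": 1.0, "b": 2.0})
        de = pd.Series({"a": 0.5, "b": 0.1})
        _, frac, dropped = cb.quadrant_overlay(["a", "b"], dr, de)
        assert frac == 1.0
        assert dropped == 0

    def test_missing_genes_are_dropped_and_counted(self):
        dr = pd.Series({"a": 1.0})
        de = pd.Series({"a": 1.0})
        table, frac, dropped = cb.quadrant_overlay(["a", "zzz"], dr, de)
        assert dropped == 1
        assert len(table) == 1

    def test_empty_dbt_list_flags_undefined_fraction(self):
        _, frac, _ = cb.quadrant_overlay([], pd.Series(dtype=float),
                                         pd.Series(dtype=float))
        assert math.isnan(frac)


class TestFourPair:
    def test_stringency_monotonicity_within_branches(
        self, genome, genes, sizes, study_samples
    ):
        summary, _ = cb.four_pair_comparison(
            {c: study_samples[("tf_chip", c)] for c in (CONTROL, TREATMENT)},
            {c: study_samples[("input", c)] for c in (CONTROL, TREATMENT)},
            {c: study_samples[("mock", c)] for c in (CONTROL, TREATMENT)},
            genes,
            sizes,
        )
        r = summary.set_index(["control_kind", "stringency"])
        for kind in ("input", "mock"):
            assert r.loc[(kind, "high"), "n_dbts"] <= r.loc[(kind, "low"), "n_dbts"]
            assert (
                r.loc[(kind, "high"), "n_dbts_in_gene_bodies"]
                <= r.loc[(kind, "high"), "n_dbts"]
            )

    def test_identical_chip_conditions_give_near_empty_summaries(
        self, genome, genes, sizes, study_samples
    ):
        same = study_samples[("tf_chip", CONTROL)]
        summary, _ = cb.four_pair_comparison(
            {CONTROL: same, TREATMENT: same},
            {c: study_samples[("input", c)] for c in (CONTROL, TREATMENT)},
            {c: study_samples[("mock", c)] for c in (CONTROL, TREATMENT)},
            genes,
            sizes,
        )
        assert (summary["n_dbts"] <= 2).all()
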