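import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import chipbias as cb
from chipbias.coverage import RAW, RPM, CoverageTrack
from chipbias.genome import CONTROL


def per_base_oracle(rows, length, bin_size):
    """Naive oracle: walk every base of every fragment, record the distinct
    bins it touches, and count one increment per (fragment, bin)."""
    nb = int(np.ceil(length / bin_size))
    out = np.zeros(nb)
    for _, s, e in rows:
        touched = set()
        for pos in range(max(s, 0), min(e, length)):
            touched.add(pos // bin_size)
        for b in touched:
            out[b] += 1
    return out


class TestExtendAndCount:
    def test_single_fragment_increments_every_overlapped_bin(self, toy_fragments):
        fs = toy_fragments([("chr1", 100, 180)])
        track = cb.extend_and_count(fs, {"chr1": 1000}, bin_size=10)
        v = track.data["chr1"]
        assert (v[10:18] == 1).all()
        assert v.sum() == 8

    def test_empty_fragment_set_gives_zero_track(self, toy_fragments):
        fs = toy_fragments([("chr1", 0, 50)])
        fs.records = fs.records.iloc[:0]
        track = cb.extend_and_count(fs, {"chr1": 1000})
        assert track.data["chr1"].sum() == 0

    def test_out_of_genome_records_are_dropped_not_fatal(self, toy_fragments):
        fs = toy_fragments([("chr1", 100, 180), ("chrX", 0, 50)])
        track = cb.extend_and_count(fs, {"chr1": 1000})
        assert track.total_fragments == 1

    @given(
        frags=st.lists(
            st.tuples(st.integers(0, 9_900), st.integers(1, 300)),
            min_size=1,
            max_size=60,
        ),
        bin_size=st.sampled_from([7, 10, 25]),
    )
    def test_matches_per_base_oracle(self, frags, bin_size):
        rows = [("chr1", s, min(s + l, 10_000)) for s, l in frags]
        fs_rows = [(c, s, e) for c, s, e in rows if e > s]
        records = pd.DataFrame(
            [(c, s, e, "+") for c, s, e in fs_rows],
            columns=["chrom", "start", "end", "strand"],
        )
        fs = cb.FragmentSet("h", "unknown", "", records).sorted()
        track = cb.extend_and_count(fs, {"chr1": 10_000}, bin_size=bin_size)
        expect = per_base_oracle(fs_rows, 10_000, bin_size)
        assert np.array_equal(track.data["chr1"], expect)


class TestNormalizeRpm:
    def test_scaling_arithmetic(self):
        track = CoverageTrack(
            data={"c": np.array([4.0, 0.0])}, total_fragments=2_000_000
        )
        rpm = cb.normalize_rpm(track)
        assert rpm.data["c"][0] == pytest.approx(2.0)
        assert rpm.norm_state == RPM

    def test_double_normalization_rejected(self):
        track = CoverageTrack(data={"c": np.ones(5)}, total_fragments=10)
        rpm = cb.normalize_rpm(track)
        with pytest.raises(ValueError):
            cb.normalize_rpm(rpm)

    def test_zero_depth_rejected(self):
        track = CoverageTrack(data={"c": np.zeros(5)}, total_fragments=0)
        with pytest.raises(ValueError):
            cb.normalize_rpm(track)

    def test_total_mass_is_conserved(self, toy_fragments):
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", int(s), int(s) + 80) for s in rng.integers(0, 9_900, 500)
        ]
        fs = toy_fragments(rows)
        track = cb.extend_and_count(fs, {"chr1": 10_000})
        rpm = cb.normalize_rpm(track)
        # each fragment's rpm contribution, divided by the bins it spans,
        # is 1e6/N; summed over fragments the normalized mass is 1e6
        nbins = np.array([(e - 1) // 10 - s // 10 + 1 for _, s, e in rows])
        assert rpm.genome_sum() == pytest.approx(
            1e6 * nbins.mean(), rel=1e-9
        )
        assert rpm.genome_sum() / nbins.mean() == pytest.approx(1e6, rel=1e-6)


class TestMetageneProfile:
    def test_uniform_track_gives_flat_profile_with_zero_ci(self, genome, genes):
        data = {c: np.full(int(np.ceil(l / 10)), 3.5) for c, l in genome.chrom_sizes.items()}
        track = CoverageTrack(data=data, norm_state=RPM, total_fragments=1)
        prof = cb.metagene_profile(track, genes, window=1000)
        assert np.allclose(prof.mean, 3.5)
        assert np.allclose(prof.ci_hi - prof.ci_lo, 0.0)

    def test_single_gene_profile_is_degenerate(self, genome, genes):
        data = {c: np.arange(int(np.ceil(l / 10)), dtype=float)
                for c, l in genome.chrom_sizes.items()}
        track = CoverageTrack(data=data, norm_state=RPM, total_fragments=1)
        g = genes[genes["strand"] == "+"].iloc[[0]]
        with pytest.warns(UserWarning, match="degenerate"):
            prof = cb.metagene_profile(track, g, window=500)
        assert prof.degenerate
        start_bin = g.iloc[0]["tss"] // 10
        assert np.allclose(prof.mean, data[g.iloc[0]["chrom"]][start_bin:start_bin + 50])

    def test_empty_gene_set_rejected(self, genome, genes):
        data = {c: np.zeros(int(np.ceil(l / 10))) for c, l in genome.chrom_sizes.items()}
        track = CoverageTrack(data=data, norm_state=RPM, total_fragments=1)
        with pytest.raises(ValueError):
            cb.metagene_profile(track, genes.iloc[:0], window=500)

    def test_invariant_under_relabeling_and_strand_flip(self, toy_fragments):
        """Renaming chromosomes or mirroring the whole genome (coordinates
        reversed, strands swapped) leaves the metagene profile unchanged."""
        L = 5_000
        rng = np.random.default_rng(1)
        rows = [("chr1", int(s), int(s) + 120) for s in rng.integers(0, L - 120, 400)]
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": "chr1",
                "strand": ["+", "-"],
                "start": [500, 3000],
                "end": [2000, 4500],
                "tss": [500, 4500],
                "tes": [2000, 3000],
            }
        )
        fs = toy_fragments(rows)
        track = cb.normalize_rpm(cb.extend_and_count(fs, {"chr1": L}))
        prof = cb.metagene_profile(track, genes, window=800)

        relabel = toy_fragments([("chrZ", s, e) for _, s, e in rows])
        track2 = cb.normalize_rpm(cb.extend_and_count(relabel, {"chrZ": L}))
        prof2 = cb.metagene_profile(track2, genes.assign(chrom="chrZ"), window=800)
        assert np.allclose(prof.mean, prof2.mean)

        flipped = toy_fragments([("chr1", L - e, L - s) for _, s, e in rows])
        track3 = cb.normalize_rpm(cb.extend_and_count(flipped, {"chr1": L}))
        flip_genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": "chr1",
                "strand": ["-", "+"],
                "start": [L - 2000, L - 4500],
                "end": [L - 500, L - 3000],
                "tss": [L - 500, L - 4500],
                "tes": [L - 2000, L - 3000],
            }
        )
        prof3 = cb.metagene_profile(track3, flip_genes, window=800)
        assert np.allclose(prof.mean, prof3.mean)


class TestGeneBodyOccupancy:
    def test_reads_per_kb_per_million_unit_case(self, toy_fragments):
        # 1-kb gene holding 100 fragments in a 1e6-fragment library -> 100.0
        rng = np.random.default_rng(2)
        starts = np.concatenate(
            [rng.integers(1000, 1900, 100), np.full(999_900, 5000)]
        )
        records = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 100, "strand": "+"}
        )
        fs = cb.FragmentSet("unit", "unknown", "", records).sorted()
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "strand": "+",
              "start": 1000, "end": 2000, "tss": 1000, "tes": 2000}]
        )
        track = cb.count_midpoints(fs, {"chr1": 10_000})
        occ = cb.gene_body_occupancy(track, genes)
        assert occ.iloc[0]["occupancy"] == pytest.approx(100.0)

    def test_doubling_gene_length_halves_occupancy(self, toy_fragments):
        fs = toy_fragments([("chr1", 1200, 1300)] * 50)
        track = cb.count_midpoints(fs, {"chr1": 10_000})
        mk = lambda end: pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "strand": "+",
              "start": 1000, "end": end, "tss": 1000, "tes": end}]
        )
        short = cb.gene_body_occupancy(track, mk(2000)).iloc[0]["occupancy"]
        long = cb.gene_body_occupancy(track, mk(3000)).iloc[0]["occupancy"]
        assert short == pytest.approx(2 * long)

    def test_matches_interval_overlap_oracle_on_toy(self, toy_fragments):
        rng = np.random.default_rng(3)
        genes = pd.DataFrame(
            [
                {"gene_id": f"g{i}", "chrom": "chr1", "strand": "+",
                 "start": 1000 + 2000 * i, "end": 2500 + 2000 * i,
                 "tss": 1000 + 2000 * i, "tes": 2500 + 2000 * i}
                for i in range(5)
            ]
        )
        rows = []
        for g in genes.itertuples():
            n = int(rng.integers(20, 80))
            starts = rng.integers(g.start, g.end - 150, n)
            rows += [("chr1", int(s), int(s) + 120) for s in starts]
        fs = toy_fragments(rows)
        track = cb.count_midpoints(fs, {"chr1": 12_000})
        occ = cb.gene_body_occupancy(track, genes).set_index("gene_id")
        for g in genes.itertuples():
            n_overlap = sum(1 for _, s, e in rows if s < g.end and e > g.start)
            expect = n_overlap / ((g.end - g.start) / 1e3) / (fs.n / 1e6)
            assert occ.loc[g.gene_id, "occupancy"] == pytest.approx(expect)

    def test_requires_midpoint_track(self, toy_fragments, genes):
        fs = toy_fragments([("chr1", 0, 100)])
        track = cb.extend_and_count(fs, {"chr1": 1000})
        with pytest.raises(ValueError, match="midpoint"):
            cb.gene_body_occupancy(track, genes.head(1))


class TestRankings:
    @staticmethod
    def occ_frame(values):
        return pd.DataFrame(
            {"gene_id": list(values), "sample_id": "s", "condition": "",
             "occupancy": list(values.values())}
        )

    def test_ties_break_lexically(self):
        occ = self.occ_frame({"e": 9, "c": 7, "b": 7, "d": 2, "a": 1})
        assert cb.rank_top(occ, k=2) == ["e", "b"]

    def test_k_larger_than_universe_returns_all(self):
        occ = self.occ_frame({"a": 1, "b": 2})
        assert set(cb.rank_top(occ, k=10**9)) == {"a", "b"}

    def test_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.random(50))}
        occ = self.occ_frame(vals)
        scaled = self.occ_frame({k: np.expm1(3 * v) for k, v in vals.items()})
        assert cb.rank_top(occ, 10) == cb.rank_top(scaled, 10)

    def test_condition_up_degenerate_and_mismatch(self):
        occ = self.occ_frame({"a": 1.0, "b": 2.0, "c": 3.0})
        top = cb.rank_condition_up(occ, occ, k=2)
        assert top == ["a", "b"]  # all-zero differences: lexical order
        other = self.occ_frame({"a": 1.0, "x": 2.0})
        with pytest.raises(ValueError, match="universe"):
            cb.rank_condition_up(occ, other, k=2)

    def test_condition_up_recovers_induced_genes(self, genome, study_occupancy):
        top = cb.rank_condition_up(
            study_occupancy[("rnapii_chip", "treatment")],
            study_occupancy[("rnapii_chip", CONTROL)],
            k=100,
        )
        up = set(genome.up_genes())
        sensitivity = len(up & set(top)) / len(up)
        assert sensitivity >= 0.9


class TestSubtractControl:
    def _rpm(self, arr):
        return CoverageTrack(
            data={"c": np.asarray(arr, dtype=float)},
            norm_state=RPM,
            total_fragments=1,
        )

    def test_self_subtraction_is_zero(self):
        t = self._rpm([1.0, 2.0, 3.0])
        out = cb.subtract_control(t, t)
        assert np.allclose(out.data["c"], 0.0)
        assert out.norm_state == "subtracted"

    def test_zero_control_is_identity(self):
        t = self._rpm([1.0, 2.0, 3.0])
        out = cb.subtract_control(t, self._rpm([0.0, 0.0, 0.0]))
        assert np.allclose(out.data["c"], t.data["c"])

    def test_result_is_floored_at_zero(self):
        out = cb.subtract_control(self._rpm([1.0, 0.0]), self._rpm([0.0, 5.0]))
        assert np.allclose(out.data["c"], [1.0, 0.0])

    def test_raw_tracks_and_mismatched_bins_rejected(self):
        raw = CoverageTrack(data={"c": np.ones(3)}, total_fragments=1)
        with pytest.raises(ValueError):
            cb.subtract_control(raw, raw)
        a, b = self._rpm([1, 2, 3]), self._rpm([1, 2])
        with pytest.raises(ValueError):
            cb.subtract_control(a, b)
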