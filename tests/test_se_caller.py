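"""Stitching, ranking, inflection cutoff and gene assignment."""

import numpy as np
import pytest

import oracles
from secircuit.genomic_core import GeneModel, GenomicInterval, Peak, SignalTrack
from secircuit.se_caller import (
    EnhancerTable,
    assign_genes,
    call_super_enhancers,
    exclude_tss,
    find_inflection,
    hockey_normalize,
    score_and_rank,
    stitch,
)


def _peaks(spans, chrom="chr1"):
    return [Peak(GenomicInterval(chrom, s, e)) for s, e in spans]


def _gene(tss, strand="+", gid="g", chrom="chr1"):
    if strand == "+":
        return GeneModel(gid, chrom, strand, tss, tss + 5000)
    return GeneModel(gid, chrom, strand, tss, tss - 5000)


class TestExcludeTss:
    def test_peak_inside_exclusion_zone_is_dropped(self):
        # zone [8750, 11251) fully covers the peak
        out = exclude_tss(_peaks([(9000, 11000)]), [_gene(10000)], pad=1250)
        assert out == []

    def test_distant_peak_is_unchanged(self):
        out = exclude_tss(_peaks([(0, 5000)]), [_gene(10000)], pad=1250)
        assert [(p.start, p.end) for p in out] == [(0, 5000)]

    def test_straddling_peak_is_split(self):
        out = exclude_tss(_peaks([(8000, 12000)]), [_gene(10000)], pad=1250)
        assert [(p.start, p.end) for p in out] == [(8000, 8750), (11251, 12000)]

    def test_pad_zero_removes_single_tss_base(self):
        out = exclude_tss(_peaks([(9998, 10002)]), [_gene(10000)], pad=0)
        assert [(p.start, p.end) for p in out] == [(9998, 10000), (10001, 10002)]

    def test_matches_per_base_oracle(self, rng):
        genome = 100_000
        spans = sorted({(int(s), int(s) + int(w))
                        for s, w in zip(rng.integers(0, genome - 600, 40),
                                        rng.integers(50, 600, 40))})
        tsses = [int(t) for t in rng.integers(0, genome, 8)]
        genes = [_gene(t, gid=f"g{i}") for i, t in enumerate(tsses)
                 if t + 5000 < genome]
        got = sorted((p.start, p.end)
                     for p in exclude_tss(_peaks(list(spans)), genes, pad=700))
        # oracle subtracts zones per base then re-forms runs per input peak;
        # overlapping input peaks may yield duplicate fragments either way
        expected = sorted(oracles.bf_exclude(list(spans),
                                             [g.tss for g in genes], 700, genome))
        assert got == expected


class TestStitch:
    def test_gap_rule(self):
        regions = stitch(_peaks([(100, 200), (300, 400), (20000, 20100)]),
                         distance=12_500)
        assert [(r.start, r.end) for r, _ in regions] == [(100, 400), (20000, 20100)]

    def test_distance_zero_merges_only_touching(self):
        regions = stitch(_peaks([(0, 100), (100, 200), (201, 300)]), distance=0)
        assert [(r.start, r.end) for r, _ in regions] == [(0, 200), (201, 300)]

    def test_matches_union_find_oracle(self, rng):
        spans = [(int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 500_000, 200),
                                 rng.integers(10, 3_000, 200))]
        got = sorted((r.start, r.end) for r, _ in stitch(_peaks(spans), 5_000))
        assert got == oracles.bf_stitch(spans, 5_000)

    def test_idempotent(self, rng):
        spans = [(int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 100_000, 60),
                                 rng.integers(10, 2_000, 60))]
        once = stitch(_peaks(spans), 3_000)
        twice = stitch([Peak(r) for r, _ in once], 3_000)
        assert [(r.start, r.end) for r, _ in once] == \
            [(r.start, r.end) for r, _ in twice]

    def test_constituents_partition_input(self):
        peaks = _peaks([(0, 10), (5, 30), (100, 110)])
        regions = stitch(peaks, 50)
        assert sum(len(cs) for _, cs in regions) == len(peaks)


class TestScoreAndRank:
    def test_input_subtraction_and_floor(self):
        chip = SignalTrack.from_records([("chr1", 0, 1000, 1.0)])
        inp = SignalTrack.from_records([("chr1", 0, 1000, 0.2),
                                        ("chr1", 2000, 3000, 9.0)])
        regions = [(GenomicInterval("chr1", 0, 1000), []),
                   (GenomicInterval("chr1", 2000, 3000), [])]
        ranked = score_and_rank(regions, chip, inp)
        assert ranked[0].net_signal == pytest.approx(800.0)
        assert ranked[1].net_signal == 0.0       # floor at zero, kept at bottom
        assert [e.rank for e in ranked] == [1, 2]

    def test_ordering_matches_independent_area_recomputation(self, rng):
        per_base = rng.uniform(0, 3, size=50_000)
        segs = [("chr1", i, i + 1, float(per_base[i])) for i in range(len(per_base))]
        chip = SignalTrack.from_pieces(segs)
        regions = []
        for s in rng.integers(0, 45_000, 50):
            regions.append((GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 4000))), []))
        ranked = score_and_rank(regions, chip, None)
        for e in ranked:
            assert e.net_signal == pytest.approx(
                oracles.bf_area(per_base, e.region.start, e.region.end), rel=1e-9)
        nets = [e.net_signal for e in ranked]
        assert nets == sorted(nets, reverse=True)

    def test_increasing_signal_never_lowers_rank(self):
        chip = SignalTrack.from_records([("chr1", 0, 100, 2.0), ("chr1", 200, 300, 5.0)])
        regions = [(GenomicInterval("chr1", 0, 100), []),
                   (GenomicInterval("chr1", 200, 300), [])]
        before = {e.region.start: e.rank for e in score_and_rank(regions, chip, None)}
        boosted = SignalTrack.from_records([("chr1", 0, 100, 9.0), ("chr1", 200, 300, 5.0)])
        after = {e.region.start: e.rank for e in score_and_rank(regions, boosted, None)}
        assert after[0] <= before[0]


class TestInflection:
    def test_single_dominant_region(self):
        assert find_inflection([100, 1, 1, 1, 1]) == 1

    def test_linear_curve_has_no_se(self):
        with pytest.warns(UserWarning):
            assert find_inflection([5, 4, 3, 2, 1]) == 0

    def test_all_equal_signals_warn_and_yield_zero(self):
        with pytest.warns(UserWarning):
            assert find_inflection([5, 5, 5, 5]) == 0

    def test_too_few_regions(self):
        with pytest.warns(UserWarning):
            assert find_inflection([10, 1]) == 0

    def test_matches_slope_scan_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 120))
            vals = np.sort(rng.lognormal(3, 1.5, size=n))[::-1].tolist()
            assert find_inflection(vals) == oracles.bf_inflection_count(vals)

    def test_hockey_stick_shape(self):
        nets = [5000.0, 4000.0] + [float(x) for x in range(100, 0, -1)]
        n_se = find_inflection(nets)
        assert n_se == 2


class TestNormalization:
    def _table(self, nets):
        enhancers = score_and_rank(
            [(GenomicInterval("chr1", 1000 * i, 1000 * i + 500), []) for i in range(len(nets))],
            SignalTrack.from_pieces(
                [("chr1", 1000 * i, 1000 * i + 500, nets[i] / 500) for i in range(len(nets))]
            ),
            None,
        )
        return EnhancerTable("s", enhancers)

    def test_printed_formulas(self):
        table = self._table([50.0] + [1.0] * 498 + [949.0])
        hockey_normalize(table)
        top = table.enhancers[0]
        assert top.rank == 1
        assert top.relative_rank == pytest.approx(1 / 500)
        by_net = {round(e.net_signal): e for e in table.enhancers}
        assert by_net[50].pct_signal == pytest.approx(100 * 50 / 1497.0)

    def test_percentages_sum_to_100(self, rng):
        table = self._table(rng.lognormal(2, 1, size=40).tolist())
        hockey_normalize(table)
        assert sum(e.pct_signal for e in table.enhancers) == pytest.approx(100, abs=1e-6)
        assert all(0 < e.relative_rank <= 1 for e in table.enhancers)

    def test_zero_total_signal_is_an_error(self):
        table = self._table([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            hockey_normalize(table)


class TestAssignGenes:
    def _table_at(self, start, end):
        e = score_and_rank([(GenomicInterval("chr1", start, end), [])],
                           SignalTrack.from_records([("chr1", start, end, 1.0)]), None)
        return EnhancerTable("s", e)

    def test_tss_inside_region_is_assigned(self):
        table = self._table_at(1000, 2000)
        asg = assign_genes(table, [_gene(1500)], flank=0)
        assert asg.genes[table.enhancers[0].name] == ["g"]

    def test_nearest_fallback_beyond_flank(self):
        table = self._table_at(1000, 2000)
        asg = assign_genes(table, [_gene(72_000)], flank=50_000)
        assert asg.genes[table.enhancers[0].name] == ["g"]
        assert asg.nearest[table.enhancers[0].name] == "g"

    def test_empty_gene_set_warns(self):
        table = self._table_at(0, 100)
        with pytest.warns(UserWarning):
            asg = assign_genes(table, [])
        assert asg.genes[table.enhancers[0].name] == []

    def test_matches_all_pairs_distance_oracle(self, rng):
        genes = [_gene(int(t), gid=f"g{i}")
                 for i, t in enumerate(rng.integers(0, 2_000_000, 60))]
        table = EnhancerTable("s", score_and_rank(
            [(GenomicInterval("chr1", int(s), int(s) + 5_000), [])
             for s in rng.integers(0, 1_900_000, 20) ],
            SignalTrack.from_records([("chr1", 0, 2_000_000, 1.0)]), None))
        flank = 50_000
        asg = assign_genes(table, genes, flank=flank)
        for e in table.enhancers:
            dists = {g.gene_id: max(e.region.start - g.tss,
                                    g.tss - (e.region.end - 1), 0) for g in genes}
            expected = sorted((g.tss, g.gene_id) for g in genes
                              if dists[g.gene_id] <= flank)
            if expected:
                assert asg.genes[e.name] == [gid for _, gid in expected]
            else:
                nearest = min(dists, key=lambda k: dists[k])
                assert dists[asg.genes[e.name][0]] == dists[nearest]


class TestFullCall:
    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        """Full chain equals the per-base oracle region-for-region."""
        for trial in range(5):
            genome = 150_000
            n = int(rng.integers(5, 60))
            spans = sorted({(int(s), int(s) + int(w))
                            for s, w in zip(rng.integers(0, genome - 2000, n),
                                            rng.integers(100, 1500, n))})
            tsses = sorted({int(t) for t in rng.integers(6000, genome - 6000, 5)})
            genes = [_gene(t, gid=f"g{i}") for i, t in enumerate(tsses)]
            chip_pb = np.round(rng.uniform(0, 4, genome), 3)
            input_pb = np.round(rng.uniform(0, 1, genome), 3)
            chip = SignalTrack.from_pieces(
                [("chr1", i, i + 1, float(v)) for i, v in enumerate(chip_pb)])
            inp = SignalTrack.from_pieces(
                [("chr1", i, i + 1, float(v)) for i, v in enumerate(input_pb)])
            with np.errstate(all="ignore"):
                table, _ = call_super_enhancers(
                    _peaks(list(spans)), chip, inp, genes,
                    stitch_distance=2_000, tss_pad=900)
            expected = oracles.bf_call_se(list(spans), [g.tss for g in genes],
                                          chip_pb, input_pb, 900, 2_000)
            got = [(e.region.start, e.region.end, e.net_signal, e.is_se)
                   for e in table.enhancers]
            assert len(got) == len(expected)
            for (gs, ge, gn, gl), (es, ee, en, el) in zip(got, expected):
                assert (gs, ge, gl) == (es, ee, el)
                assert gn == pytest.approx(en, rel=1e-9, abs=1e-9)

    def test_se_te_partition(self, small_config):
        from secircuit.synthetic_data import simulate_all

        art = simulate_all(small_config)
        table, _ = call_super_enhancers(art["peaks"], art["chip"], art["input"],
                                        art["genes"])
        assert table.n_se + table.n_te == len(table.enhancers)
        assert all(e.is_se == (e.rank <= table.n_se) for e in table.enhancers)
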