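from itertools import product

import numpy as np
import pytest

from conftest import make_block
from helpers_oracle import brute_force_events

from meiorec.event_caller import (
    ProgenyHaplotype,
    bin_events_by_length,
    classify_fragments,
    filter_progeny_genotype,
    infer_inherited_haplotype,
    segment_runs,
    summarize_per_progeny,
    RecombinationEvent,
    BIN_LABELS,
)
from meiorec.formats_io import VcfSiteCall


def _gcall(genotype, depth=20, ad=(10, 10), gq=99, chrom="Chr01", pos=100):
    return VcfSiteCall(
        chrom=chrom,
        pos=pos,
        ref_allele="A",
        alt_allele="C",
        genotype=genotype,
        depth=depth,
        allele_depths=ad,
        genotype_quality=gq,
    )


class TestProgenyFilter:
    @pytest.mark.parametrize(
        "call,passes",
        [
            (_gcall("het"), True),
            (_gcall("het", depth=14), False),  # at least 15 reads
            (_gcall("het", gq=60), False),  # strictly greater than 60
            (_gcall("het", gq=60.5), True),
            (_gcall("het", ad=(4, 16)), False),  # both alleles need 5 reads
            (_gcall("hom_ref", ad=(15, 0)), True),  # only called allele counts
            (_gcall("hom_alt", ad=(16, 4)), False),
            (_gcall("missing"), False),
        ],
    )
    def test_thresholds(self, call, passes):
        assert filter_progeny_genotype(call) is passes


class TestInferInheritedHaplotype:
    def _block(self):
        # hap1 carries A everywhere; other parent homozygous A -> A='a', C='b'
        return make_block([100, 200, 300, 400], "aaaa")

    def _calls(self, genotypes):
        # genotype 'aa' -> hom for the a-allele (A, the ref); 'ab' -> het
        gmap = {"aa": "hom_ref", "ab": "het", "bb": "hom_alt"}
        out = {}
        for pos, g in zip([100, 200, 300, 400], genotypes):
            ad = {"hom_ref": (20, 0), "het": (10, 10), "hom_alt": (0, 20)}[gmap[g]]
            out[("Chr01", pos)] = _gcall(gmap[g], pos=pos, ad=ad)
        return out

    def test_fig2_pattern(self):
        ph = infer_inherited_haplotype(self._calls(["aa", "ab", "ab", "aa"]),
                                       self._block())
        assert ph.calls == ["a", "b", "b", "a"]

    def test_all_aa_no_signal(self):
        ph = infer_inherited_haplotype(self._calls(["aa"] * 4), self._block())
        assert ph.calls == ["a"] * 4

    def test_bb_is_mendelian_impossible(self):
        ph = infer_inherited_haplotype(self._calls(["aa", "bb", "aa", "aa"]),
                                       self._block())
        assert ph.calls == ["a", "missing", "a", "a"]
        assert ph.n_incompatible == 1

    def test_absent_and_filtered_sites_missing(self):
        calls = self._calls(["aa", "aa", "aa", "aa"])
        del calls[("Chr01", 200)]
        calls[("Chr01", 300)] = _gcall("hom_ref", pos=300, depth=5, ad=(5, 0))
        ph = infer_inherited_haplotype(calls, self._block())
        assert ph.calls == ["a", "missing", "missing", "a"]


def _hap(block, labels):
    return ProgenyHaplotype(
        progeny_id="p1", parent_of_origin="P1", block=block, calls=list(labels)
    )


class TestSegmentRuns:
    def test_alternating_pattern(self):
        block = make_block([100, 200, 300, 400], "aaaa")
        runs = segment_runs(_hap(block, ["a", "a", "b", "a"]))
        assert [(r.homolog, r.first_site_idx, r.last_site_idx) for r in runs] == [
            (1, 0, 1),
            (2, 2, 2),
            (1, 3, 3),
        ]

    def test_single_run_matches_hap2(self):
        block = make_block([100, 200, 300], "aaa")
        runs = segment_runs(_hap(block, ["b", "b", "b"]))
        assert len(runs) == 1 and runs[0].homolog == 2 and runs[0].n_snps == 3

    def test_missing_bridges_runs(self):
        block = make_block([100, 200, 300], "aaa")
        (run,) = segment_runs(_hap(block, ["a", "missing", "a"]))
        assert (run.n_snps, run.first_site_idx, run.last_site_idx) == (2, 0, 2)
        assert run.span_bp == 201

    def test_max_gap_breaks_runs(self):
        block = make_block([100, 200, 50000], "aaa")
        runs = segment_runs(_hap(block, ["a", "a", "a"]), max_gap_bp=10000)
        assert len(runs) == 2


def _runs_block(spans_snps):
    """Build a block + labels realizing runs of given (span, n_snps, homolog)."""
    positions, labels = [], []
    pos = 1000
    for span, n_snps, hom in spans_snps:
        step = (span - 1) // (n_snps - 1) if n_snps > 1 else 0
        sites = [pos + i * step for i in range(n_snps)]
        if n_snps > 1:
            sites[-1] = pos + span - 1
        positions.extend(sites)
        labels.extend(["a" if hom == 1 else "b"] * n_snps)
        pos = sites[-1] + 3000  # inter-run gap
    block = make_block(positions, "a" * len(positions))
    return block, labels


class TestClassifyFragments:
    def test_gc_between_long_flanks(self):
        block, labels = _runs_block([(12000, 5, 1), (150, 3, 2), (20000, 5, 1)])
        events = classify_fragments(segment_runs(_hap(block, labels)), block)
        classes = [e.event_class for e in events]
        assert classes == ["gene_conversion"]
        assert events[0].n_snps == 3 and events[0].span_bp == 150

    def test_crossover_junction(self):
        block, labels = _runs_block([(12000, 5, 1), (15000, 5, 2)])
        events = classify_fragments(segment_runs(_hap(block, labels)), block)
        assert [e.event_class for e in events] == ["crossover"]
        ev = events[0]
        assert ev.start == block.sites[4].pos and ev.end == block.sites[5].pos

    def test_too_short_fragment_ignored_and_no_crossover(self):
        block, labels = _runs_block([(12000, 5, 1), (15, 2, 2), (11000, 5, 1)])
        events = classify_fragments(segment_runs(_hap(block, labels)), block)
        assert [e.event_class for e in events] == ["ignored_short"]

    def test_mid_length_fragment_ambiguous(self):
        block, labels = _runs_block([(12000, 5, 1), (5000, 4, 2), (11000, 5, 1)])
        events = classify_fragments(segment_runs(_hap(block, labels)), block)
        assert [e.event_class for e in events] == ["ambiguous"]

    def test_terminal_runs_never_gc(self):
        block, labels = _runs_block([(150, 3, 2), (12000, 5, 1)])
        events = classify_fragments(segment_runs(_hap(block, labels)), block)
        assert events == []


class TestOracleEquivalence:
    def _compare(self, positions, inherited):
        block = make_block(positions, "a" * len(positions))
        labels = list(inherited)
        got = sorted(
            (e.event_class, e.start, e.end, e.n_snps)
            for e in classify_fragments(segment_runs(_hap(block, labels)), block)
        )
        want = brute_force_events(positions, "a" * len(positions), labels)
        assert got == want, (positions, labels)

    def test_exhaustive_small_blocks(self):
        """Classification equals brute force on every label sequence."""
        layouts = [
            [100, 130, 20000, 20040, 20100, 42000, 42010],
            [1000, 1500, 2500, 14000, 26000, 26100, 27000],
        ]
        for positions in layouts:
            for inherited in product("ab?", repeat=len(positions)):
                labels = ["missing" if c == "?" else c for c in inherited]
                self._compare(positions, labels)

    def test_exhaustive_twelve_sites_no_missing(self):
        rng = np.random.default_rng(2)
        positions = sorted(int(p) for p in rng.choice(60000, 12, replace=False) + 1)
        for inherited in product("ab", repeat=12):
            self._compare(positions, list(inherited))

    def test_random_twelve_sites_with_missing(self):
        rng = np.random.default_rng(3)
        for _ in range(400):
            positions = sorted(
                int(p) for p in rng.choice(80000, 12, replace=False) + 1
            )
            labels = [str(x) for x in rng.choice(["a", "b", "missing"], size=12)]
            self._compare(positions, labels)


class TestClassifierProperties:
    def _random_case(self, rng):
        n = int(rng.integers(4, 25))
        positions = sorted(int(p) for p in rng.choice(100000, n, replace=False) + 1)
        labels = [str(x) for x in rng.choice(["a", "b", "missing"], size=n)]
        block = make_block(positions, "a" * n)
        return block, labels

    def test_gc_count_monotone_in_gc_max(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            block, labels = self._random_case(rng)
            runs = segment_runs(_hap(block, labels))
            counts = []
            for gc_max in (500, 2000, 8000):
                events = classify_fragments(runs, block, gc_max_bp=gc_max)
                counts.append(
                    sum(e.event_class == "gene_conversion" for e in events)
                )
            assert counts == sorted(counts)

    def test_co_count_antitone_in_flank(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            block, labels = self._random_case(rng)
            runs = segment_runs(_hap(block, labels))
            counts = []
            for flank in (2000, 10000, 40000):
                events = classify_fragments(runs, block, co_flank_bp=flank)
                counts.append(sum(e.event_class == "crossover" for e in events))
            assert counts == sorted(counts, reverse=True)

    def test_conservation_of_interior_runs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            block, labels = self._random_case(rng)
            runs = segment_runs(_hap(block, labels))
            events = classify_fragments(runs, block)
            n_junctions = sum(
                l.span_bp > 10000 and r.span_bp > 10000
                for l, r in zip(runs, runs[1:])
            )
            assert len(events) == max(len(runs) - 2, 0) + n_junctions


def _event(chrom, start, end, cls="gene_conversion", pid="p1", block="b1"):
    return RecombinationEvent(
        progeny_id=pid,
        parent_of_origin="P1",
        chrom=chrom,
        event_class=cls,
        start=start,
        end=end,
        n_snps=2,
        source_block=block,
    )


class TestBinning:
    def test_one_event_per_bin(self):
        spans = [15, 150, 500, 1500, 5000, 12000]
        events = [_event("Chr01", 1000, 1000 + s - 1) for s in spans]
        df = bin_events_by_length(events)
        assert list(df.loc["Chr01"]) == [1] * 6
        assert list(df.columns) == BIN_LABELS

    def test_empty(self):
        assert bin_events_by_length([]).empty

    def test_crossovers_not_binned(self):
        events = [_event("Chr01", 1000, 1100, cls="crossover")]
        assert bin_events_by_length(events).empty

    def test_simulated_tracts_match_truth_histogram(self, clean_dataset,
                                                    clean_analysis):
        """Every called GC length falls in the simulated tract-length support
        (SNP span never exceeds the true tract length ceiling)."""
        lo, hi = 20, 1500
        for ev in clean_analysis.events:
            if ev.event_class == "gene_conversion":
                assert lo <= ev.span_bp <= hi


class TestSummaries:
    def test_average_over_progeny(self):
        events = [_event("Chr01", 1000 + i * 10, 1005 + i * 10, pid="p1")
                  for i in range(3)]
        events += [_event("Chr01", 2000 + i * 10, 2005 + i * 10, pid="p2")
                   for i in range(5)]
        table = summarize_per_progeny(events)["per_chrom"]
        assert table.loc["Chr01", "Aver."] == 4.0

    def test_block_shared_by_all_progeny(self):
        events = [_event("Chr01", 1000, 1100, pid=f"p{i}") for i in range(10)]
        sharing = summarize_per_progeny(events)["block_sharing"]
        assert sharing[10] == 1 and sharing.drop(10).sum() == 0

    def test_accounting_identity_random(self):
        rng = np.random.default_rng(9)
        events = [
            _event(
                f"Chr{rng.integers(1, 4):02d}",
                int(rng.integers(1, 10**6)),
                int(rng.integers(1, 10**6)) + 100,
                pid=f"p{rng.integers(1, 6)}",
                block=f"b{rng.integers(1, 20)}",
            )
            for _ in range(300)
        ]
        table = summarize_per_progeny(events)["per_chrom"]
        totals = table.drop(index="Total").drop(columns="Aver.").to_numpy().sum()
        assert totals == len(events)
        assert table.loc["Total", "Aver."] == pytest.approx(len(events) / 5)


class TestClassifierHypothesis:
    from hypothesis import given, settings, strategies as st

    @given(data=st.data())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_random_blocks_match_brute_force(self, data):
        st = self.st
        n = data.draw(st.integers(min_value=2, max_value=12))
        positions = sorted(
            data.draw(
                st.sets(
                    st.integers(min_value=1, max_value=120000),
                    min_size=n, max_size=n,
                )
            )
        )
        labels = data.draw(
            st.lists(
                st.sampled_from(["a", "b", "missing"]),
                min_size=n, max_size=n,
            )
        )
        block = make_block(positions, "a" * n)
        got = sorted(
            (e.event_class, e.start, e.end, e.n_snps)
            for e in classify_fragments(
                segment_runs(_hap(block, labels)), block
            )
        )
        assert got == brute_force_events(positions, "a" * n, labels)
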