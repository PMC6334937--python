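"""Seed-and-extend mapper: scoring, mapq proxy, competitive assignment,
iterative remapping."""

import numpy as np
import pytest

from parchmentid.formats import Read, reverse_complement
from parchmentid.mapping import (
    KmerIndex,
    competitive_assign,
    iterative_remap,
    map_library,
    map_read,
    mapq_proxy,
)
from parchmentid.preprocess import preprocess_pairs
from parchmentid.synthetic_data import (
    DamageParams,
    SimConfig,
    divergent_reference,
    generate_donor_genome,
    simulate_reads,
    synthetic_reference,
)


def _read(seq, id="r"):
    return Read(id, seq, [37] * len(seq))


@pytest.fixture(scope="module")
def panel(small_reference):
    return [
        small_reference,
        divergent_reference(small_reference, 0.15, seed=201, name="cow_mt", species_label="cow"),
        divergent_reference(small_reference, 0.20, seed=202, name="goat_mt", species_label="goat"),
        divergent_reference(small_reference, 0.30, seed=203, name="human_mt", species_label="human"),
    ]


@pytest.fixture(scope="module")
def index(panel):
    return KmerIndex(panel)


class TestIndex:
    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex([])

    def test_duplicate_names_rejected(self, small_reference):
        import copy

        with pytest.raises(ValueError, match="duplicate"):
            KmerIndex([small_reference, copy.deepcopy(small_reference)])

    def test_duplicate_sequences_rejected(self, small_reference):
        import dataclasses

        twin = dataclasses.replace(small_reference, name="other")
        with pytest.raises(ValueError, match="identical"):
            KmerIndex([small_reference, twin])
        KmerIndex([small_reference, twin], allow_duplicate_sequences=True)

    def test_circular_wrap_is_seeded(self, small_reference):
        idx = KmerIndex([small_reference], k=15)
        L = len(small_reference)
        junction = small_reference.sequence[L - 7 :] + small_reference.sequence[:8]
        assert any(pos == L - 7 for _, pos in idx.lookup(junction))


class TestMapRead:
    def test_verbatim_read_scores_its_length(self, small_reference, index):
        seq = small_reference.sequence[1000:1100]
        alns = map_read(_read(seq), index)
        best = alns[0]
        assert best.score == 100
        assert best.n_mismatches == 0
        assert (best.start, best.end, best.strand) == (1000, 1100, "+")
        assert best.ref_name == "sheep_mt"

    def test_strand_symmetry(self, small_reference, index):
        for start in (0, 1717, 3333, 5950):
            seq = (small_reference.sequence * 2)[start : start + 90]
            fwd = map_read(_read(seq), index)[0]
            rev = map_read(_read(reverse_complement(seq)), index)[0]
            assert fwd.score == rev.score
            assert {fwd.strand, rev.strand} == {"+", "-"}
            assert fwd.start == rev.start % len(small_reference)

    def test_unmappable_read_returns_empty(self, index):
        assert map_read(_read("A" * 60), index) in ([],)

    def test_short_read_skipped(self, index):
        assert map_read(_read("ACGTACGTAC"), index) == []


class TestMapqProxy:
    @pytest.mark.parametrize(
        "best, second, expected",
        [(40, 0, 60), (50, 50, 0), (30, 22, 32), (10, 9, 4)],
    )
    def test_formula(self, best, second, expected):
        assert mapq_proxy(best, second) == expected

    def test_requires_ordering(self):
        with pytest.raises(ValueError):
            mapq_proxy(10, 20)


class TestCompetitiveAssignment:
    def test_best_species_wins(self, small_reference, index):
        seq = small_reference.sequence[2000:2100]
        assert competitive_assign(map_read(_read(seq), index)) == "sheep"

    def test_cross_species_tie_is_ambiguous(self):
        a = synthetic_reference(2_000, seed=55, name="a", species_label="spA")
        shared = a.sequence[500:580]
        b_seq = a.sequence[:1000] + synthetic_reference(1_000, seed=56).sequence
        from parchmentid.formats import Reference

        b = Reference("b", "spB", b_seq)
        idx = KmerIndex([a, b])
        alns = map_read(_read(shared), idx)
        assert competitive_assign(alns) is None

    def test_simulated_reads_assign_to_their_species(self, panel):
        """Sheep-origin reads against the four-species panel: >=99% of
        mapq-passing reads are assigned to sheep."""
        cfg = SimConfig(panel=panel, n_variants=0, coverage=20.0,
                        damage=DamageParams(0, 0, 3, 0), sample_name="sp", seed=71)
        res = simulate_reads(cfg)
        pre = preprocess_pairs(res.pairs)
        summary = map_library(pre.reads, KmerIndex(panel))
        total = sum(summary.species_counts.values())
        assert total > 1000
        assert summary.species_counts["sheep"] / total >= 0.99

    def test_mixture_fractions_recovered(self, panel):
        """95:5 sheep/cow mixture: assigned fractions within 2 SE of truth."""
        cow_donor = generate_donor_genome(panel[1], 0, None, seed=1)
        cfg = SimConfig(panel=panel, n_variants=0, coverage=19.0,
                        contamination_fraction=0.05, contaminant=panel[1],
                        damage=DamageParams(0, 0, 3, 0), sample_name="mix", seed=72)
        res = simulate_reads(cfg)
        truth_cow = sum(1 for r in res.truth["reads"] if r["source"] == "contaminant")
        truth_frac = truth_cow / len(res.truth["reads"])
        pre = preprocess_pairs(res.pairs)
        summary = map_library(pre.reads, KmerIndex(panel))
        n = summary.species_counts["sheep"] + summary.species_counts["cow"]
        obs = summary.species_counts["cow"] / n
        se = np.sqrt(truth_frac * (1 - truth_frac) / n)
        assert abs(obs - truth_frac) <= 2 * se + 0.005

    def test_read_accounting_conserved(self, panel):
        cfg = SimConfig(panel=panel, n_variants=0, coverage=5.0, sample_name="acct", seed=73)
        res = simulate_reads(cfg)
        pre = preprocess_pairs(res.pairs)
        s = map_library(pre.reads, KmerIndex(panel))
        assigned = sum(len(v) for v in s.assigned.values())
        assert assigned + s.n_unmapped + s.n_ambiguous + s.n_low_mapq == s.n_input


class TestZeroNoiseMappingInvariant:
    def test_every_read_maps_home_with_max_mapq(self, panel):
        cfg = SimConfig(panel=panel, n_variants=0, coverage=4.0,
                        damage=DamageParams(0, 0, 3, 0), sample_name="z", seed=74)
        res = simulate_reads(cfg)
        pre = preprocess_pairs(res.pairs)
        truth = {r["id"]: r for r in res.truth["reads"]}
        L = len(panel[0])
        idx = KmerIndex(panel)
        mapqs = []
        for read in pre.reads:
            best = map_read(read, idx)[0]
            # always well above the filter; short reads can have a distant
            # runner-up on the 15%-divergent panel, so not always capped
            assert best.mapq >= 30
            mapqs.append(best.mapq)
            rec = truth[read.id.split("/")[0]]
            assert best.ref_name == "sheep_mt"
            assert best.start % L == rec["start"] % L
        assert np.median(mapqs) == 60


class TestIterativeRemap:
    def test_reference_donor_converges_immediately(self, small_reference):
        cfg = SimConfig(panel=[small_reference], n_variants=0, coverage=8.0,
                        damage=DamageParams(0, 0, 3, 0), sample_name="c", seed=81)
        res = simulate_reads(cfg)
        pre = preprocess_pairs(res.pairs)
        out = iterative_remap(pre.reads, small_reference, iterations=5)
        assert out.n_iterations == 1
        assert out.per_iteration_changes == [0]
        assert out.template == small_reference.sequence

    def test_single_iteration_equals_plain_mapping(self, small_reference):
        cfg = SimConfig(panel=[small_reference], n_variants=25, coverage=6.0,
                        sample_name="one", seed=82)
        res = simulate_reads(cfg)
        pre = preprocess_pairs(res.pairs)
        once = iterative_remap(pre.reads, small_reference, iterations=1)
        idx = KmerIndex([small_reference])
        plain = [a[0] for r in pre.reads if (a := map_read(r, idx)) and a[0].mapq >= 30]
        assert [(a.read_id, a.start, a.score) for a in once.alignments] == [
            (a.read_id, a.start, a.score) for a in plain
        ]
        assert once.template == small_reference.sequence

    def test_iteration_recovers_at_least_as_many_variants(self, small_reference):
        """With 30 substitutions at 20x, remapping against the updated
        consensus recovers at least as many truth variants as pass 1."""
        from parchmentid.variants import Pileup, call_consensus

        donor = generate_donor_genome(small_reference, 30, None, seed=83)
        cfg = SimConfig(panel=[small_reference], donor=donor, n_variants=0,
                        coverage=20.0, sample_name="it", seed=84)
        res = simulate_reads(cfg)
        pre = preprocess_pairs(res.pairs)

        def recovered(iterations):
            out = iterative_remap(pre.reads, small_reference, iterations=iterations)
            pp = Pileup.build(out.alignments, out.template)
            cons = call_consensus(pp, small_reference.sequence)
            return len(set(cons.tokens) & set(donor.truth_tokens))

        assert recovered(5) >= recovered(1)
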