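"""Consensus calling, N-masking, heteroplasmy detection, coverage."""

import numpy as np
import pytest

from parchmentid.formats import TokenKind, VariantToken
from parchmentid.preprocess import preprocess_pairs
from parchmentid.mapping import iterative_remap
from parchmentid.synthetic_data import (
    DamageParams,
    HeteroplasmySpec,
    SimConfig,
    generate_donor_genome,
    simulate_reads,
    synthetic_reference,
)
from parchmentid.variants import (
    ConsensusResult,
    Pileup,
    attribute_heteroplasmy_to_contamination,
    call_consensus,
    coverage_stats,
    detect_heteroplasmy,
)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def make_pileup(reference: str, depth_per_site, overrides=None) -> Pileup:
    """Pileup where every position holds `depth` copies of the reference
    base, except `overrides[pos_1based] = {base: count}`."""
    L = len(reference)
    pp = Pileup.empty(L)
    depths = depth_per_site if hasattr(depth_per_site, "__len__") else [depth_per_site] * L
    for i, base in enumerate(reference):
        pp.counts[i, _BASE_IDX[base]] = depths[i]
    for pos, counts in (overrides or {}).items():
        pp.counts[pos - 1, :] = 0
        for base, n in counts.items():
            pp.counts[pos - 1, _BASE_IDX[base]] = n
    return pp


class TestNMasking:
    @pytest.mark.parametrize("depth, expect_n", [(0, True), (1, True), (2, True), (3, False)])
    def test_min_depth_is_strict(self, depth, expect_n):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 5, overrides={4: {"T": depth}})
        cons = call_consensus(pp, ref)
        if expect_n:
            assert cons.consensus[3] == "N" and 4 in cons.n_positions
        else:
            assert cons.consensus[3] == "T" and 4 not in cons.n_positions

    def test_masked_position_emits_no_token(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 5, overrides={4: {"G": 1}})  # single discrepant read
        cons = call_consensus(pp, ref)
        assert cons.consensus[3] == "N"
        assert all(t.position != 4 for t in cons.tokens)

    def test_raising_min_depth_never_unmasks(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 60))
        depths = rng.integers(0, 8, 60)
        pp = make_pileup(ref, depths)
        n_counts = [
            len(call_consensus(pp, ref, min_depth=d).n_positions) for d in range(1, 7)
        ]
        assert n_counts == sorted(n_counts)


class TestHeteroplasmy:
    @pytest.mark.parametrize("a, g", [(6, 6), (13, 13)])
    def test_balanced_sites_detected(self, a, g):
        het = detect_heteroplasmy({"A": a, "C": 0, "G": g, "T": 0})
        assert het is not None
        (major, minor), counts, frac = het
        assert {major, minor} == {"A", "G"}
        assert frac == pytest.approx(0.5)

    def test_skewed_site_is_homoplasmic(self):
        assert detect_heteroplasmy({"A": 11, "C": 0, "G": 1, "T": 0}) is None

    @pytest.mark.parametrize("counts", [{"A": 2, "G": 2}, {"A": 10, "G": 2}, {"A": 17, "G": 4}])
    def test_gates(self, counts):
        full = {"A": 0, "C": 0, "G": 0, "T": 0} | counts
        assert detect_heteroplasmy(full) is None

    def test_consensus_emits_iupac_token(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 12, overrides={5: {"A": 6, "G": 6}})
        cons = call_consensus(pp, ref)
        assert cons.consensus[4] == "R"
        assert VariantToken(5, TokenKind.SUBSTITUTION, "R") in cons.tokens
        [site] = cons.heteroplasmic_sites
        assert site.position == 5 and set(site.alleles) == {"A", "G"}

    def test_heteroplasmy_always_in_tokens(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 12, overrides={5: {"A": 6, "G": 6}, 8: {"T": 7, "C": 5}})
        cons = call_consensus(pp, ref)
        token_positions = {t.position for t in cons.tokens}
        for site in cons.heteroplasmic_sites:
            assert site.position in token_positions

    def test_damage_artifact_flagged_not_rejected(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 12, overrides={2: {"C": 9, "T": 3}})
        pp.ct_terminal[1] = 3  # every minor T sits at a read 5' terminus
        cons = call_consensus(pp, ref)
        [site] = cons.heteroplasmic_sites
        assert site.possible_damage_artifact
        pp.ct_terminal[1] = 1
        [site2] = call_consensus(pp, ref).heteroplasmic_sites
        assert not site2.possible_damage_artifact


class TestIndels:
    def test_majority_deletion_called(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 10)
        pp.counts[5, :] = 0
        pp.deletions[5] = 9
        cons = call_consensus(pp, ref)
        assert VariantToken(6, TokenKind.DELETION) in cons.tokens
        assert cons.consensus[5] == "-"
        assert cons.sequence == ref[:5] + ref[6:]

    def test_supported_insertion_called(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 10)
        pp.insertions[4] = {"G": 8}
        cons = call_consensus(pp, ref)
        assert VariantToken(4, TokenKind.INSERTION, "G") in cons.tokens
        assert cons.sequence == ref[:4] + "G" + ref[4:]

    def test_minority_insertion_ignored(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 10)
        pp.insertions[4] = {"G": 2}
        assert call_consensus(pp, ref).tokens == []


class TestConsensusBasics:
    def test_substitution_only_length_preserved(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 100))
        pp = make_pileup(ref, 8)
        cons = call_consensus(pp, ref)
        assert len(cons.consensus) == 100 and cons.tokens == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_consensus(Pileup.empty(5), "ACGTACGT")

    def test_tie_below_het_gates_favours_reference(self):
        ref = "AAAA"
        pp = make_pileup(ref, 5, overrides={2: {"A": 2, "G": 2}})
        cons = call_consensus(pp, ref, min_depth=3)
        # depth 4 is called; 2/2 fails the >=3-reads-each heteroplasmy gate;
        # the majority tie resolves to the reference allele, so no token
        assert cons.consensus[1] == "A"
        assert cons.tokens == [] and cons.heteroplasmic_sites == []

    def test_coverage_stats(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 10)
        stats = coverage_stats(pp)
        assert stats.mean == pytest.approx(10.0)
        assert stats.mean_1dp == 10.0
        assert stats.fraction_at_least_min_depth == 1.0
        empty = coverage_stats(Pileup.empty(10))
        assert empty.mean == 0.0 and empty.fraction_at_least_min_depth == 0.0


def test_zero_noise_round_trip(small_reference):
    """Tokens recovered from a clean 40x simulation equal the injected truth
    set exactly (substitutions incl. a balanced heteroplasmy)."""
    donor = generate_donor_genome(
        small_reference, 25, HeteroplasmySpec(2500, 0.5), seed=501
    )
    cfg = SimConfig(panel=[small_reference], donor=donor, n_variants=0, coverage=40.0,
                    damage=DamageParams(0, 0, 3, 0), sample_name="rt", seed=502)
    res = simulate_reads(cfg)
    pre = preprocess_pairs(res.pairs)
    remap = iterative_remap(pre.reads, small_reference)
    pp = Pileup.build(remap.alignments, remap.template)
    cons = call_consensus(pp, small_reference.sequence)
    assert set(cons.tokens) == set(donor.truth_tokens)
    assert cons.n_positions == set()


def test_indel_round_trip():
    from parchmentid.formats import parse_token_list

    toks = parse_token_list("500T,1200+G,2500deletion,4000C")
    ref = synthetic_reference(5_000, seed=61, name="mt", species_label="sheep", tokens=toks)
    donor = generate_donor_genome(ref, 0, None, seed=62, tokens=toks)
    cfg = SimConfig(panel=[ref], donor=donor, n_variants=0, coverage=30.0,
                    damage=DamageParams(0, 0, 3, 0), sample_name="ind", seed=63)
    res = simulate_reads(cfg)
    pre = preprocess_pairs(res.pairs)
    remap = iterative_remap(pre.reads, ref)
    pp = Pileup.build(remap.alignments, remap.template)
    cons = call_consensus(pp, ref.sequence)
    assert set(cons.tokens) == set(toks)


class TestContaminationAttribution:
    def test_pseudo_het_at_defining_site_resolved(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 12, overrides={3: {"T": 9, "G": 3}})  # ref G, derived T
        cons = call_consensus(pp, ref)
        assert cons.consensus[2] == "K"
        fixed = attribute_heteroplasmy_to_contamination(cons, ref, {3})
        assert fixed.consensus[2] == "T"
        assert VariantToken(3, TokenKind.SUBSTITUTION, "T") in fixed.tokens
        assert fixed.heteroplasmic_sites == []

    def test_non_defining_site_untouched(self):
        ref = "ACGTACGTAC"
        pp = make_pileup(ref, 12, overrides={3: {"T": 9, "G": 3}})
        cons = call_consensus(pp, ref)
        fixed = attribute_heteroplasmy_to_contamination(cons, ref, {8})
        assert fixed.consensus[2] == "K"
        assert len(fixed.heteroplasmic_sites) == 1

    def test_true_het_with_nonref_minor_kept(self):
        ref = "ACGTACGTAC"  # position 5 ref A
        pp = make_pileup(ref, 12, overrides={5: {"G": 7, "T": 5}})  # neither is ref
        cons = call_consensus(pp, ref)
        fixed = attribute_heteroplasmy_to_contamination(cons, ref, {5})
        assert len(fixed.heteroplasmic_sites) == 1
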