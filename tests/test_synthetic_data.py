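"""The degraded-read generator: determinism, truth sidecar, recovery oracles."""

import dataclasses
import math

import numpy as np
import pytest

from parchmentid.formats import TokenKind, VariantToken, parse_token_list
from parchmentid.synthetic_data import (
    DamageParams,
    HeteroplasmySpec,
    SimConfig,
    divergent_reference,
    generate_donor_genome,
    simulate_reads,
    simulate_sex_reads,
    synthetic_reference,
)


@pytest.fixture(scope="module")
def ref():
    return synthetic_reference(5_000, seed=7, name="mt", species_label="sheep")


def test_zero_variants_is_identity(ref):
    donor = generate_donor_genome(ref, 0, None, seed=1)
    assert donor.major == ref.sequence
    assert donor.truth_tokens == frozenset()
    assert donor.minor is None


def test_explicit_token_injection_ground_truth(membranes):
    """Injecting the published lower-membrane list onto a compatible
    synthetic reference reproduces exactly that list as ground truth."""
    tokens = membranes["lower_membrane"].all_tokens
    ref = synthetic_reference(16_616, seed=3, name="mt", species_label="sheep", tokens=tokens)
    donor = generate_donor_genome(ref, 0, None, seed=5, tokens=tokens)
    assert donor.truth_tokens == frozenset(tokens)
    assert donor.heteroplasmy is not None and donor.heteroplasmy.position == 6907
    # three insertions and two deletions in the list: net length change +1
    assert len(donor.major) == 16_616 + 3 - 2


def test_random_donor_tokens_differ_from_reference(ref, rng):
    donor = generate_donor_genome(ref, 30, None, seed=rng)
    assert len(donor.truth_tokens) == 30
    for tok in donor.truth_tokens:
        assert tok.kind is TokenKind.SUBSTITUTION
        assert ref.sequence[tok.position - 1] != tok.allele
        assert donor.major[tok.position - 1] == tok.allele


def test_variant_budget_guard(ref):
    with pytest.raises(ValueError):
        generate_donor_genome(ref, len(ref) // 100 + 1, None)


def test_simulation_is_deterministic(ref, tmp_path):
    cfg = SimConfig(panel=[ref], n_variants=10, coverage=5.0, sample_name="d", seed=42)
    a = simulate_reads(cfg)
    b = simulate_reads(cfg)
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    assert (tmp_path / "a_R1.fastq").read_bytes() == (tmp_path / "b_R1.fastq").read_bytes()
    assert (tmp_path / "a_truth.json").read_text() == (tmp_path / "b_truth.json").read_text()


def test_config_validation(ref):
    with pytest.raises(ValueError):
        SimConfig(panel=[ref], coverage=0.0)
    with pytest.raises(ValueError):
        SimConfig(panel=[ref], contamination_fraction=1.0)
    with pytest.raises(ValueError):
        SimConfig(panel=[ref], contamination_fraction=0.05)  # no contaminant genome
    with pytest.raises(ValueError):
        SimConfig(panel=[ref], fragment_mean=20.0, fragment_min=35)
    with pytest.raises(ValueError):
        HeteroplasmySpec(100, 0.7)
    with pytest.raises(ValueError):
        DamageParams(p_ct_5prime=1.5)


def test_heteroplasmy_fraction_recovered_from_truth(ref):
    """At high coverage the simulated minor-haplotype fraction sits inside
    the binomial 99% interval around the configured 0.5."""
    cfg = SimConfig(
        panel=[ref],
        n_variants=0,
        heteroplasmy=HeteroplasmySpec(2500, 0.5),
        coverage=40.0,
        damage=DamageParams(0, 0, 3, 0),
        sample_name="het",
        seed=11,
    )
    res = simulate_reads(cfg)
    donor_reads = [r for r in res.truth["reads"] if r["source"] == "donor"]
    n = len(donor_reads)
    k = sum(1 for r in donor_reads if r["haplotype"] == "minor")
    half_width = 2.576 * math.sqrt(0.25 / n)
    assert abs(k / n - 0.5) <= half_width


def test_damage_rate_recovered_from_truth(ref):
    """First-position C->T frequency in the truth sidecar within 3 SE of the
    configured 0.3."""
    cfg = SimConfig(
        panel=[ref],
        n_variants=0,
        coverage=20.0,
        damage=DamageParams(0.3, 0.0, 3.0, 0.0),
        sample_name="dmg",
        seed=13,
    )
    res = simulate_reads(cfg)
    # denominator: molecules whose first base was C before damage
    n_c = 0
    n_ct = 0
    for rec in res.truth["reads"]:
        if any(e["pos"] == 0 and e["class"] == "ct5" for e in rec["damage_edits"]):
            n_c += 1
            n_ct += 1
    # count undamaged C starts from the reads themselves
    for (r1, _), rec in zip(res.pairs, res.truth["reads"]):
        if r1.sequence[0] == "C" and not any(
            e["pos"] == 0 for e in rec["damage_edits"]
        ):
            n_c += 1
    p_hat = n_ct / n_c
    se = math.sqrt(0.3 * 0.7 / n_c)
    assert abs(p_hat - 0.3) <= 3 * se


def test_fragment_length_bounds(ref):
    cfg = SimConfig(panel=[ref], n_variants=0, coverage=5.0, fragment_min=40,
                    fragment_max=110, sample_name="f", seed=3)
    res = simulate_reads(cfg)
    lengths = [r["length"] for r in res.truth["reads"]]
    assert min(lengths) >= 40 and max(lengths) <= 110


def test_adapter_read_through_when_fragment_short(ref):
    cfg = SimConfig(panel=[ref], n_variants=0, coverage=2.0, fragment_max=80,
                    read_length=125, sample_name="a", seed=9)
    res = simulate_reads(cfg)
    r1, _ = res.pairs[0]
    frag_len = res.truth["reads"][0]["length"]
    assert len(r1) == 125 and frag_len < 125  # padded into adapter


def test_sex_read_depth_structure():
    x = synthetic_reference(4_000, seed=21, name="X", species_label="sheep", circular=False)
    a = synthetic_reference(4_000, seed=22, name="chr6", species_label="sheep", circular=False)
    # male: roughly half the X rate
    _, truth_m = simulate_sex_reads("male", x, a, depth=40.0, seed=5)
    ratio_m = truth_m["n_x"] / truth_m["n_autosome"]
    assert 0.35 < ratio_m < 0.65
    # large-sample female limit: ~50k reads, ratio within [0.93, 1.07]
    _, truth_f = simulate_sex_reads("female", x, a, depth=600.0, seed=6)
    assert truth_f["n_x"] + truth_f["n_autosome"] > 40_000
    ratio_f = truth_f["n_x"] / truth_f["n_autosome"]
    assert 0.93 <= ratio_f <= 1.07


def test_sex_read_validation():
    x = synthetic_reference(1_000, seed=1, circular=False)
    a = synthetic_reference(1_000, seed=2, circular=False)
    with pytest.raises(ValueError):
        simulate_sex_reads("other", x, a, depth=1.0)
    with pytest.raises(ValueError):
        simulate_sex_reads("female", x, a, depth=0.0)


def test_divergent_reference_distance(ref):
    other = divergent_reference(ref, 0.15, seed=4, name="cow_mt", species_label="cow")
    diffs = sum(1 for a, b in zip(ref.sequence, other.sequence) if a != b)
    assert diffs == round(0.15 * len(ref))


def test_pair_code_token_realised_as_heteroplasmy():
    toks = parse_token_list("300A,900R")
    ref = synthetic_reference(2_000, seed=8, tokens=toks)
    donor = generate_donor_genome(ref, 0, None, seed=2, tokens=toks)
    assert donor.heteroplasmy is not None
    assert donor.heteroplasmy.position == 900
    assert {donor.major[899], donor.minor[899]} == {"A", "G"}
    assert VariantToken(900, TokenKind.SUBSTITUTION, "R") in donor.truth_tokens
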