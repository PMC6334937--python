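"""The three-membrane identification scenario, end to end on synthetic data.

Builds the study structure the pipeline was designed for: two donor ewes
whose mitogenomes differ by 28 substitutions — one donor (carrying a
balanced A/G heteroplasmy at position 6907) sampled twice, as a "lower
membrane" library at 9x and a "blank parchment" library at 18x; the second
donor sampled once as an "upper membrane" library at 6x — each library with
2-6% exogenous contamination from a reference-haplotype individual, terminal
deamination damage on, and a female nuclear read set.  Runs the full
pipeline on all three and reports what it recovered: source species, sex,
haplogroup, contamination, and the pairwise identity verdicts (the
same-donor pair should match; cross-donor pairs should not).

Genome sizes are scaled-down surrogates (8 kb mitogenome, 4 kb sex
chromosomes): every decision the pipeline makes depends on relative
structure — variant content, depth ratios, mismatch fractions — not on
absolute genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import HaplogroupTable, Reference, TokenKind, VariantToken
from .identity import IdentityReport
from .pipeline import RunConfig, SampleCallset, Thresholds, compare_samples, run_sample
from .synthetic_data import (
    DamageParams,
    HeteroplasmySpec,
    SimConfig,
    divergent_reference,
    generate_donor_genome,
    simulate_sex_reads,
    synthetic_reference,
)

MITO_LENGTH = 8_000
SEX_REF_LENGTH = 4_000
HET_POSITION = 6_907
N_SHARED = 10  # substitutions common to both donors (clade backbone)
N_PRIVATE_A = 13  # private to the twice-sampled donor
N_PRIVATE_B = 15  # private to the other donor (symmetric difference = 28)
COVERAGES = {"lower_membrane": 9.0, "blank_parchment": 18.0, "upper_membrane": 6.0}
SEX_DEPTH = 8.0
MIN_COMPARABLE = 5_000


@dataclass
class Scenario:
    panel: list[Reference]
    table: HaplogroupTable
    x_reference: Reference
    autosome_reference: Reference
    sim_configs: dict[str, SimConfig]
    contamination: dict[str, float]
    truth_tokens: dict[str, frozenset[VariantToken]]


def build_scenario(seed: int) -> Scenario:
    """Deterministically derive the full study setup from one seed."""
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    rng = rngs[0]

    # donor variant structure: disjoint positions, away from the edges and
    # spaced beyond the fragment length so no two variant sites (or the
    # heteroplasmic site) share a read — contamination mismatch counts at
    # defining sites then behave binomially, as the recovery check assumes
    n_total = N_SHARED + N_PRIVATE_A + N_PRIVATE_B
    min_sep = 130  # > the scenario's fragment length cap (125)
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_total:
        p = int(rng.integers(101, MITO_LENGTH - 100))
        if abs(p - HET_POSITION) >= min_sep and all(abs(p - q) >= min_sep for q in positions):
            positions.append(p)
        attempts += 1
        if attempts > 200_000:  # jammed packing: restart
            positions, attempts = [], 0
    shared = positions[:N_SHARED]
    private_a = positions[N_SHARED : N_SHARED + N_PRIVATE_A]
    private_b = positions[N_SHARED + N_PRIVATE_A :]

    def random_tokens(pos_list) -> list[VariantToken]:
        toks = []
        for pos in sorted(pos_list):
            toks.append(VariantToken(pos, TokenKind.SUBSTITUTION, "ACGT"[int(rng.integers(4))]))
        return toks

    shared_t = random_tokens(shared)
    private_a_t = random_tokens(private_a)
    private_b_t = random_tokens(private_b)
    tokens_a = shared_t + private_a_t + [VariantToken(HET_POSITION, TokenKind.SUBSTITUTION, "R")]
    tokens_b = shared_t + private_b_t

    sheep = synthetic_reference(
        MITO_LENGTH, seed=rngs[1], name="sheep_mt", species_label="sheep",
        tokens=tokens_a + tokens_b,
    )
    # fix alleles that collided with the adjusted reference
    def definite(toks):
        out = []
        for t in toks:
            if t.allele in "ACGT" and sheep.sequence[t.position - 1] == t.allele:
                alt = "ACGT"[(("ACGT".index(t.allele)) + 1) % 4]
                out.append(VariantToken(t.position, t.kind, alt))
            else:
                out.append(t)
        return out

    shared_t = definite(shared_t)
    private_a_t = definite(private_a_t)
    private_b_t = definite(private_b_t)
    tokens_a = shared_t + private_a_t + [VariantToken(HET_POSITION, TokenKind.SUBSTITUTION, "R")]
    tokens_b = shared_t + private_b_t

    panel = [
        sheep,
        divergent_reference(sheep, 0.15, seed=rngs[2], name="cow_mt", species_label="cow"),
        divergent_reference(sheep, 0.20, seed=rngs[3], name="goat_mt", species_label="goat"),
        divergent_reference(sheep, 0.30, seed=rngs[4], name="human_mt", species_label="human"),
    ]
    table = HaplogroupTable(
        {
            "ANC": frozenset(shared_t),
            "CLADE_A": frozenset(shared_t + private_a_t),
            "CLADE_B": frozenset(shared_t + private_b_t),
        }
    )

    donor_a = generate_donor_genome(sheep, 0, None, seed=rngs[5], tokens=tokens_a, name="donor_a")
    donor_b = generate_donor_genome(sheep, 0, None, seed=rngs[5], tokens=tokens_b, name="donor_b")

    contamination = {
        name: float(np.round(rng.uniform(0.02, 0.06), 4)) for name in COVERAGES
    }
    donors = {
        "lower_membrane": donor_a,
        "blank_parchment": donor_a,
        "upper_membrane": donor_b,
    }
    sim_configs = {
        name: SimConfig(
            panel=panel,
            donor=donors[name],
            n_variants=0,
            coverage=COVERAGES[name],
            contamination_fraction=contamination[name],
            contaminant=sheep,
            damage=DamageParams(),
            fragment_max=125,  # keeps any read to at most one variant site
            sample_name=name,
        )
        for name in COVERAGES
    }
    x_ref = synthetic_reference(SEX_REF_LENGTH, seed=rngs[6], name="chrX", species_label="sheep",
                                circular=False)
    auto_ref = synthetic_reference(SEX_REF_LENGTH, seed=rngs[7], name="chr6",
                                   species_label="sheep", circular=False)
    return Scenario(
        panel=panel,
        table=table,
        x_reference=x_ref,
        autosome_reference=auto_ref,
        sim_configs=sim_configs,
        contamination=contamination,
        truth_tokens={
            "lower_membrane": donor_a.truth_tokens,
            "blank_parchment": donor_a.truth_tokens,
            "upper_membrane": donor_b.truth_tokens,
        },
    )


@dataclass
class ScenarioOutcome:
    callsets: dict[str, SampleCallset]
    comparisons: dict[tuple[str, str], IdentityReport]
    contamination_truth: dict[str, float]

    def realized_contamination(self, sample: str) -> float:
        """Contaminant fragment fraction actually simulated (truth sidecar)."""
        reads = self.callsets[sample].truth["reads"]
        return sum(1 for r in reads if r["source"] == "contaminant") / len(reads)

    def contamination_within_2se(self, sample: str) -> bool:
        est = self.callsets[sample].contamination
        if est is None or est.total_bases == 0:
            return False
        f = self.realized_contamination(sample)
        se = float(np.sqrt(f * (1.0 - f) / est.total_bases))
        return abs(est.fraction - f) <= 2.0 * se

    def summary(self) -> dict:
        out = {
            "species": {s: c.species for s, c in self.callsets.items()},
            "sex": {s: (c.sex.call if c.sex else None) for s, c in self.callsets.items()},
            "haplogroup": {
                s: (c.haplogroup.haplogroup if c.haplogroup else None)
                for s, c in self.callsets.items()
            },
            "contamination_percent": {
                s: (c.contamination.percent if c.contamination else None)
                for s, c in self.callsets.items()
            },
            "contamination_truth_percent": {
                s: 100.0 * f for s, f in self.contamination_truth.items()
            },
            "verdicts": {f"{a}|{b}": r.verdict for (a, b), r in self.comparisons.items()},
        }
        return out


def run_scenario(seed: int, thresholds: Thresholds | None = None) -> ScenarioOutcome:
    """Simulate and analyse the full three-membrane scenario at one seed."""
    scenario = build_scenario(seed)
    th = thresholds or Thresholds(min_comparable_sites=MIN_COMPARABLE)
    sample_seeds = np.random.SeedSequence(seed).generate_state(2 * len(COVERAGES) + 1)
    callsets: dict[str, SampleCallset] = {}
    for i, name in enumerate(COVERAGES):
        sex_reads, _ = simulate_sex_reads(
            "female",
            scenario.x_reference,
            scenario.autosome_reference,
            depth=SEX_DEPTH,
            seed=int(sample_seeds[2 * i] % (2**31)),
        )
        config = RunConfig(
            panel=scenario.panel,
            haplogroup_table=scenario.table,
            sim=scenario.sim_configs[name],
            sex_reads=sex_reads,
            x_reference=scenario.x_reference,
            autosome_reference=scenario.autosome_reference,
            thresholds=th,
            sample_name=name,
            seed=int(sample_seeds[2 * i + 1] % (2**31)),
        )
        callsets[name] = run_sample(config)
    comparisons = {}
    for pair in [
        ("lower_membrane", "blank_parchment"),
        ("upper_membrane", "lower_membrane"),
        ("upper_membrane", "blank_parchment"),
    ]:
        comparisons[pair] = compare_samples(
            callsets[pair[0]], callsets[pair[1]], min_comparable=th.min_comparable_sites
        )
    return ScenarioOutcome(
        callsets=callsets,
        comparisons=comparisons,
        contamination_truth=scenario.contamination,
    )
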