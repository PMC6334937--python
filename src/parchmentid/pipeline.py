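"""End-to-end orchestration: reads in, sample callset and reports out.

One ``run_sample`` call takes a library (real FASTQ pair or a simulation
config), cleans it, maps it competitively against the species panel, decides
the source species, iteratively remaps against that species' mitogenome,
calls the consensus with N-masking, assigns the haplogroup, estimates
contamination at the matched haplogroup-defining sites, optionally calls sex
from a nuclear read set, and profiles damage.  ``compare_samples`` then
renders the pairwise identity verdict.

Everything is deterministic given the config seed; every stage's counts and
thresholds are echoed into the report JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import damage as damage_mod
from .formats import (
    HaplogroupTable,
    Read,
    Reference,
    VariantToken,
    parse_variant_token,
    write_fasta,
)
from .haplo_contam import (
    ContaminationEstimate,
    HaplogroupCall,
    assign_haplogroup,
    estimate_contamination,
)
from .identity import ExclusionRegion, IdentityReport, compare_callsets
from .mapping import KmerIndex, iterative_remap, map_library
from .preprocess import preprocess_pairs
from .species_sex import SexCall, call_sex, call_source_species
from .synthetic_data import SimConfig, simulate_reads
from .variants import (
    ConsensusResult,
    HeteroplasmicSite,
    Pileup,
    attribute_heteroplasmy_to_contamination,
    call_consensus,
    coverage_stats,
)

log = logging.getLogger("parchmentid")


@dataclass
class Thresholds:
    """Every stage threshold in one place (defaults as documented)."""

    q_threshold: int = 20
    min_read_length: int = 30
    min_overlap: int = 11
    max_mismatch_frac: float = 0.1
    min_mapq: int = 30
    map_iterations: int = 5
    k: int = 15
    min_depth: int = 3
    het_min_reads_each: int = 3
    het_min_minor_frac: float = 0.2
    species_min_reads: int = 100
    species_min_fold: float = 10.0
    female_min: float = 0.8
    male_max: float = 0.6
    min_comparable_sites: int = 10_000

    def validate(self) -> None:
        if not (0 < self.het_min_minor_frac <= 0.5):
            raise ValueError("het_min_minor_frac must be in (0, 0.5]")
        if self.min_depth < 1 or self.min_mapq < 0 or self.min_read_length < 1:
            raise ValueError("thresholds out of range")


@dataclass
class RunConfig:
    panel: Sequence[Reference]
    haplogroup_table: HaplogroupTable | None = None
    sim: SimConfig | None = None
    pairs: list[tuple[Read, Read]] | None = None
    sex_reads: list[Read] | None = None
    x_reference: Reference | None = None
    autosome_reference: Reference | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    exclusions: Sequence[ExclusionRegion] = ()
    output_dir: Path | None = None
    sample_name: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds.validate()
        if (self.sim is None) == (self.pairs is None):
            raise ValueError("provide exactly one of sim= or pairs=")


@dataclass
class SampleCallset:
    """Everything the pipeline derives for one parchment/sample."""

    name: str
    species: str | None
    species_counts: dict[str, int]
    consensus: ConsensusResult | None
    reference_length: int
    mean_coverage: float
    haplogroup: HaplogroupCall | None
    contamination: ContaminationEstimate | None
    sex: SexCall | None
    damage_profile: damage_mod.DamageProfile | None
    preprocess_counts: dict[str, int]
    mapping_counts: dict[str, int]
    truth: dict | None = None

    @property
    def tokens(self) -> list[VariantToken]:
        return self.consensus.tokens if self.consensus else []

    @property
    def heteroplasmic_sites(self) -> list[HeteroplasmicSite]:
        return self.consensus.heteroplasmic_sites if self.consensus else []

    @property
    def n_positions(self) -> set[int]:
        return self.consensus.n_positions if self.consensus else set()

    def to_dict(self) -> dict:
        return {
            "sample": self.name,
            "species": self.species,
            "species_counts": self.species_counts,
            "reference_length": self.reference_length,
            "mean_coverage": round(self.mean_coverage, 1),
            "tokens": [t.format() for t in self.tokens],
            "n_positions": sorted(self.n_positions),
            "heteroplasmic_sites": [
                {
                    "position": s.position,
                    "alleles": list(s.alleles),
                    "counts": list(s.counts),
                    "minor_fraction": s.minor_fraction,
                    "possible_damage_artifact": s.possible_damage_artifact,
                }
                for s in self.heteroplasmic_sites
            ],
            "haplogroup": self.haplogroup.haplogroup if self.haplogroup else None,
            "haplogroup_score": self.haplogroup.score if self.haplogroup else None,
            "contamination_percent": self.contamination.percent if self.contamination else None,
            "contamination_detail": (
                {
                    "mismatches": self.contamination.mismatches,
                    "total_bases": self.contamination.total_bases,
                    "n_sites": self.contamination.n_sites,
                }
                if self.contamination
                else None
            ),
            "sex": dataclasses.asdict(self.sex) if self.sex else None,
            "preprocess_counts": self.preprocess_counts,
            "mapping_counts": self.mapping_counts,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_sample(config: RunConfig) -> SampleCallset:
    th = config.thresholds
    truth = None

    # --- acquire reads -----------------------------------------------------
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed,
                                  sample_name=config.sample_name)
        result = simulate_reads(sim)
        pairs = result.pairs
        truth = result.truth
        log.info("simulated %d read pairs for %s", len(pairs), config.sample_name)
    else:
        pairs = config.pairs

    # --- preprocess --------------------------------------------------------
    pre = preprocess_pairs(
        pairs,
        q_threshold=th.q_threshold,
        min_len=th.min_read_length,
        min_overlap=th.min_overlap,
        max_mismatch_frac=th.max_mismatch_frac,
    )
    log.info("preprocess %s: %s", config.sample_name, pre.counts)

    # --- competitive species mapping --------------------------------------
    try:
        index = KmerIndex(config.panel, k=th.k)
    except ValueError as exc:
        raise StageError(f"mapping: {exc}") from exc
    summary = map_library(pre.reads, index, min_mapq=th.min_mapq)
    mapping_counts = {
        "input_reads": summary.n_input,
        "unmapped": summary.n_unmapped,
        "ambiguous": summary.n_ambiguous,
        "low_mapq": summary.n_low_mapq,
        **{f"assigned_{sp}": n for sp, n in sorted(summary.species_counts.items())},
    }
    species = call_source_species(
        summary.species_counts, min_reads=th.species_min_reads, min_fold=th.species_min_fold
    )

    consensus = None
    haplogroup = None
    contamination = None
    profile = None
    mean_cov = 0.0
    ref_len = 0
    if species is not None:
        reference = next(r for r in config.panel if r.species_label == species)
        ref_len = len(reference)
        assigned_ids = {a.read_id for a in summary.assigned.get(species, [])}
        species_reads = [read for read in pre.reads if read.id in assigned_ids]
        remap = iterative_remap(
            species_reads,
            reference,
            iterations=th.map_iterations,
            min_mapq=th.min_mapq,
            k=th.k,
            min_depth=th.min_depth,
        )
        pileup = Pileup.build(remap.alignments, remap.template, circular=reference.circular)
        consensus = call_consensus(
            pileup,
            reference.sequence,
            min_depth=th.min_depth,
            het_min_reads_each=th.het_min_reads_each,
            het_min_minor_frac=th.het_min_minor_frac,
        )
        mean_cov = coverage_stats(pileup, th.min_depth).mean
        mapping_counts["remap_iterations"] = remap.n_iterations

        if config.haplogroup_table is not None:
            # pseudo-heteroplasmy from exogenous reads is resolved against
            # every defining position known to the table (a candidate clade
            # should not have to win the provisional assignment first)
            defining_all = {
                t.position
                for name in config.haplogroup_table
                for t in config.haplogroup_table[name]
                if t.kind.value == "substitution" and t.allele in "ACGT"
            }
            consensus = attribute_heteroplasmy_to_contamination(
                consensus, reference.sequence, defining_all
            )
            haplogroup = assign_haplogroup(
                consensus.tokens, config.haplogroup_table, consensus.n_positions
            )
            defining_positions = [
                t.position for t in haplogroup.matched if t.allele in "ACGT" and t.kind.value == "substitution"
            ]
            if defining_positions:
                contamination = estimate_contamination(
                    pileup, defining_positions, consensus.consensus
                )
        profile = damage_mod.misincorporation_profile(remap.alignments, remap.template)

    sex = None
    if config.sex_reads is not None:
        if config.x_reference is None or config.autosome_reference is None:
            raise StageError("sex: sex_reads given without X/autosome references")
        sex = call_sex(
            config.sex_reads,
            config.x_reference,
            config.autosome_reference,
            female_min=th.female_min,
            male_max=th.male_max,
            min_mapq=th.min_mapq,
        )

    callset = SampleCallset(
        name=config.sample_name,
        species=species,
        species_counts=summary.species_counts,
        consensus=consensus,
        reference_length=ref_len,
        mean_coverage=mean_cov,
        haplogroup=haplogroup,
        contamination=contamination,
        sex=sex,
        damage_profile=profile,
        preprocess_counts=pre.counts,
        mapping_counts=mapping_counts,
        truth=truth,
    )
    if config.output_dir is not None:
        _write_reports(callset, config)
    return callset


def _write_reports(callset: SampleCallset, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{callset.name}.callset.json").write_text(
        json.dumps(callset.to_dict(), indent=1, sort_keys=True)
    )
    if callset.consensus is not None:
        write_fasta(
            outdir / f"{callset.name}.consensus.fasta",
            [(callset.name, callset.consensus.consensus.replace("-", ""))],
        )
        lines = ["position\ttoken\tkind"]
        for tok in callset.tokens:
            lines.append(f"{tok.position}\t{tok.format()}\t{tok.kind.value}")
        (outdir / f"{callset.name}.tokens.tsv").write_text("\n".join(lines) + "\n")
    if callset.damage_profile is not None:
        damage_mod.write_profile_tsv(callset.damage_profile, outdir / f"{callset.name}.damage.tsv")


def compare_samples(
    callset_a: SampleCallset,
    callset_b: SampleCallset,
    exclusions: Sequence[ExclusionRegion] = (),
    min_comparable: int = 10_000,
    flag_sensitive: bool = False,
) -> IdentityReport:
    """Delegates to the identity module on two pipeline callsets."""
    return compare_callsets(
        callset_a,
        callset_b,
        exclusions=exclusions,
        min_comparable=min_comparable,
        flag_sensitive=flag_sensitive,
    )


def load_callset_json(path: str | Path) -> SampleCallset:
    """Rehydrate the comparison-relevant parts of a callset report."""
    data = json.loads(Path(path).read_text())
    tokens = [parse_variant_token(t, lenient=True) for t in data["tokens"]]
    het = [
        HeteroplasmicSite(
            position=s["position"],
            alleles=tuple(s["alleles"]),
            counts=tuple(s["counts"]),
            minor_fraction=s["minor_fraction"],
            possible_damage_artifact=s.get("possible_damage_artifact", False),
        )
        for s in data.get("heteroplasmic_sites", [])
    ]
    consensus = ConsensusResult(
        consensus="",
        tokens=tokens,
        heteroplasmic_sites=het,
        n_positions=set(data.get("n_positions", [])),
    )
    return SampleCallset(
        name=data["sample"],
        species=data.get("species"),
        species_counts=data.get("species_counts", {}),
        consensus=consensus,
        reference_length=data.get("reference_length", 0),
        mean_coverage=data.get("mean_coverage", 0.0),
        haplogroup=None,
        contamination=None,
        sex=None,
        damage_profile=None,
        preprocess_counts=data.get("preprocess_counts", {}),
        mapping_counts=data.get("mapping_counts", {}),
    )
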