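"""Source-species decision from competitive read counts, and sex
determination from the X:autosome normalized depth ratio.

Parchment can in principle derive from sheep, calf or goat; human reads are
a contamination channel and never a candidate source.  A species is called
only when its unique mapped read count both clears an absolute floor and
dominates the runner-up by a fold factor — otherwise the source is
undetermined (the fate of heavily degraded libraries).

Females carry two X chromosomes, so X and a similar-length autosome collect
reads at the same per-base rate (ratio ~1); males at half (ratio ~0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import Read, Reference, ReferenceRole
from .mapping import DEFAULT_MIN_MAPQ, KmerIndex, map_library

DEFAULT_MIN_READS = 100
DEFAULT_MIN_FOLD = 10.0
DEFAULT_FEMALE_MIN = 0.8
DEFAULT_MALE_MAX = 0.6


@dataclass
class SpeciesCounts:
    """Per-species unique mapped mtDNA read counts (post-filter)."""

    counts: dict[str, int]
    total_raw_pairs: int = 0
    human_label: str = "human"

    @property
    def human_count(self) -> int:
        return self.counts.get(self.human_label, 0)


def call_source_species(
    counts: SpeciesCounts | dict[str, int],
    min_reads: int = DEFAULT_MIN_READS,
    min_fold: float = DEFAULT_MIN_FOLD,
    human_label: str = "human",
) -> str | None:
    """Top non-human species, or ``None`` (undetermined) when the winner
    lacks ``min_reads`` reads or ``min_fold`` dominance over the runner-up."""
    mapping = counts.counts if isinstance(counts, SpeciesCounts) else counts
    candidates = sorted(
        ((n, sp) for sp, n in mapping.items() if sp != human_label),
        key=lambda t: (-t[0], t[1]),
    )
    if not candidates:
        return None
    top_n, top_sp = candidates[0]
    runner_n = candidates[1][0] if len(candidates) > 1 else 0
    if top_n < min_reads:
        return None
    if runner_n > 0 and top_n < min_fold * runner_n:
        return None
    return top_sp


@dataclass
class SexCall:
    ratio: float | None
    call: str  # female | male | indeterminate
    reads_x: int
    reads_autosome: int


def call_sex_from_counts(
    reads_x: int,
    length_x: int,
    reads_autosome: int,
    length_autosome: int,
    female_min: float = DEFAULT_FEMALE_MIN,
    male_max: float = DEFAULT_MALE_MAX,
) -> SexCall:
    """Length-normalized X:autosome ratio with an indeterminate band."""
    if reads_autosome == 0:
        return SexCall(None, "indeterminate", reads_x, reads_autosome)
    ratio = (reads_x / length_x) / (reads_autosome / length_autosome)
    if ratio >= female_min:
        call = "female"
    elif ratio <= male_max:
        call = "male"
    else:
        call = "indeterminate"
    return SexCall(ratio, call, reads_x, reads_autosome)


def call_sex(
    reads: Iterable[Read] | Sequence[Read],
    x_reference: Reference,
    autosome_reference: Reference,
    female_min: float = DEFAULT_FEMALE_MIN,
    male_max: float = DEFAULT_MALE_MAX,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> SexCall:
    """Competitively map reads to the X/autosome pair and call sex from the
    length-normalized unique read ratio (standard mapq filter applied)."""
    if x_reference.role is not ReferenceRole.SEX_X:
        x_reference.role = ReferenceRole.SEX_X
    if autosome_reference.role is not ReferenceRole.SEX_AUTOSOME:
        autosome_reference.role = ReferenceRole.SEX_AUTOSOME
    index = KmerIndex([x_reference, autosome_reference])
    summary = map_library(reads, index, min_mapq=min_mapq)
    n_x = summary.species_counts.get(x_reference.species_label, 0)
    n_auto = summary.species_counts.get(autosome_reference.species_label, 0)
    if x_reference.species_label == autosome_reference.species_label:
        # same species label on both chromosomes: count by reference name
        n_x = sum(
            1 for alns in summary.assigned.values() for a in alns if a.ref_name == x_reference.name
        )
        n_auto = sum(
            1
            for alns in summary.assigned.values()
            for a in alns
            if a.ref_name == autosome_reference.name
        )
    return call_sex_from_counts(
        n_x, len(x_reference), n_auto, len(autosome_reference), female_min, male_max
    )
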