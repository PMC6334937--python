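"""Haplogroup assignment and contamination estimation.

A sample's variant tokens are scored against every haplogroup's defining
polymorphism set; the best match-score wins, with ties broken by the larger
(more specific) defining set and then lexicographically.  Tokens falling on
N-masked positions are removed from the denominator — an unreadable site
neither supports nor contradicts a clade.

Contamination is estimated at the haplogroup-defining positions: reads
mismatching the consensus allele there are (predominantly) exogenous
molecules, so the pooled mismatch fraction across those sites estimates the
contaminant fraction of the library.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Collection, Iterable

from .formats import HaplogroupTable, VariantToken
from .variants import Pileup

_ACGT = set("ACGT")


@dataclass
class HaplogroupCall:
    haplogroup: str | None
    matched: frozenset[VariantToken]
    missed: frozenset[VariantToken]
    extra: frozenset[VariantToken]
    score: float

    @property
    def defining_set(self) -> frozenset[VariantToken]:
        return self.matched | self.missed


def assign_haplogroup(
    tokens: Iterable[VariantToken],
    table: HaplogroupTable,
    masked_positions: Collection[int] = (),
) -> HaplogroupCall:
    """Best-matching haplogroup for a sample token set.

    score = |defining ∩ sample| / |defining \\ masked|.  An empty token set
    yields a score-0 call with a warning rather than an error.
    """
    token_set = frozenset(tokens)
    masked = set(masked_positions)
    if not token_set:
        warnings.warn("empty token set: haplogroup call has score 0", stacklevel=2)
    best: tuple[float, int, str] | None = None
    best_call: HaplogroupCall | None = None
    for name in sorted(table):
        defining = table[name]
        usable = frozenset(t for t in defining if t.position not in masked)
        matched = frozenset(t for t in usable if t in token_set)
        score = len(matched) / len(usable) if usable else 0.0
        rank = (score, len(defining), *[-ord(c) for c in name])
        if best is None or rank > best:
            best = rank
            best_call = HaplogroupCall(
                haplogroup=name,
                matched=matched,
                missed=usable - matched,
                extra=token_set - defining,
                score=score,
            )
    assert best_call is not None
    return best_call


@dataclass
class ContaminationEstimate:
    mismatches: int
    total_bases: int
    n_sites: int

    @property
    def fraction(self) -> float:
        return self.mismatches / self.total_bases if self.total_bases else float("nan")

    @property
    def percent(self) -> int:
        """Pooled mismatch percentage, rounded half-up to the integer."""
        if not self.total_bases:
            return 0
        return int(math.floor(100.0 * self.fraction + 0.5))


def estimate_contamination(
    pileup: Pileup,
    defining_positions: Collection[int],
    consensus: str,
    per_site: bool = False,
) -> ContaminationEstimate | float:
    """Mismatch-based contamination rate at haplogroup-defining sites.

    Pools mismatched bases over all reads covering each defining position
    whose consensus call is an unambiguous base (N and IUPAC-ambiguity sites
    are skipped).  ``per_site=True`` instead averages the per-site mismatch
    rates (returned as a float fraction); pooling is the default because it
    is what the printed worked examples (4/200 -> 2%, 21/355 -> 6%) imply.
    """
    mismatches = 0
    total = 0
    n_sites = 0
    rates = []
    for pos in sorted(set(defining_positions)):
        if not 1 <= pos <= pileup.length:
            raise ValueError(f"defining position {pos} outside pileup")
        allele = consensus[pos - 1]
        if allele not in _ACGT:
            continue
        counts = pileup.base_counts(pos - 1)
        depth = sum(counts.values())
        if depth == 0:
            continue
        mm = depth - counts[allele]
        mismatches += mm
        total += depth
        n_sites += 1
        rates.append(mm / depth)
    if total == 0:
        warnings.warn("no bases inspected at defining sites; contamination undefined",
                      stacklevel=2)
    if per_site:
        return sum(rates) / len(rates) if rates else float("nan")
    return ContaminationEstimate(mismatches, total, n_sites)
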