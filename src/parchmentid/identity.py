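"""Pairwise identity comparison of two sample callsets.

Two parchments cut from the same skin must show the same mitogenome: zero
variant-token differences over the sites callable in both, and concordant
heteroplasmy (same site, same allele pair, overlapping minor-fraction
confidence intervals).  N-masked positions are excluded from the comparison
rather than counted as differences — a masked site is uncertain, not
discrepant — and an optional exclusion region (the control-region tandem
repeats, which resist alignment) can be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .formats import VariantToken
from .variants import HeteroplasmicSite

DEFAULT_MIN_COMPARABLE = 10_000


@dataclass(frozen=True)
class ExclusionRegion:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("exclusion region start > end")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


#: 75/76 bp control-region tandem repeats; hard to align across individuals,
#: excluded from phylogeny-style comparisons (default OFF in identity diffs).
TANDEM_REPEAT_REGION = ExclusionRegion(15650, 15905, "control-region tandem repeats")


@dataclass
class DiffResult:
    differing: list[VariantToken]
    count: int
    excluded: list[VariantToken] = field(default_factory=list)


def diff_variants(
    tokens_a: Iterable[VariantToken],
    tokens_b: Iterable[VariantToken],
    exclusions: Sequence[ExclusionRegion] = (),
    masked_a: Collection[int] = (),
    masked_b: Collection[int] = (),
    flag_sensitive: bool = False,
) -> DiffResult:
    """Symmetric difference of two token sets.

    Token identity is (position, kind, allele); low-coverage flags are
    ignored unless ``flag_sensitive``.  Tokens inside an exclusion region or
    at positions N-masked in either sample are removed from the difference
    and listed separately.
    """
    set_a, set_b = set(tokens_a), set(tokens_b)
    if flag_sensitive:
        keyed_a = {t.flagged_key(): t for t in set_a}
        keyed_b = {t.flagged_key(): t for t in set_b}
        sym = [keyed_a[k] for k in keyed_a.keys() - keyed_b.keys()]
        sym += [keyed_b[k] for k in keyed_b.keys() - keyed_a.keys()]
    else:
        sym = list((set_a - set_b) | (set_b - set_a))
    masked = set(masked_a) | set(masked_b)
    differing: list[VariantToken] = []
    excluded: list[VariantToken] = []
    for tok in sorted(sym, key=lambda t: t.key):
        if tok.position in masked or any(tok.position in region for region in exclusions):
            excluded.append(tok)
        else:
            differing.append(tok)
    return DiffResult(differing=differing, count=len(differing), excluded=excluded)


def region_diff(
    tokens_a: Iterable[VariantToken],
    tokens_b: Iterable[VariantToken],
    region: tuple[int, int] | ExclusionRegion,
    **kwargs,
) -> DiffResult:
    """Symmetric difference restricted to a 1-based inclusive interval."""
    if isinstance(region, ExclusionRegion):
        lo, hi = region.start, region.end
    else:
        lo, hi = region
    full = diff_variants(tokens_a, tokens_b, **kwargs)
    inside = [t for t in full.differing if lo <= t.position <= hi]
    return DiffResult(differing=inside, count=len(inside), excluded=full.excluded)


def _minor_fraction_ci(site: HeteroplasmicSite, alpha: float = 0.05) -> tuple[float, float]:
    n = sum(site.counts)
    lo, hi = proportion_confint(site.counts[1], n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass
class ConcordanceReport:
    concordant: list[tuple[HeteroplasmicSite, HeteroplasmicSite]]
    discordant: list[tuple[HeteroplasmicSite | None, HeteroplasmicSite | None]]

    @property
    def all_concordant(self) -> bool:
        return not self.discordant


def heteroplasmy_concordance(
    sites_a: Sequence[HeteroplasmicSite],
    sites_b: Sequence[HeteroplasmicSite],
) -> ConcordanceReport:
    """A site is concordant iff both samples show it at the same position
    with the same allele pair and overlapping 95% Wilson intervals for the
    minor fraction.  Sites present in only one sample are discordant."""
    by_pos_a = {s.position: s for s in sites_a}
    by_pos_b = {s.position: s for s in sites_b}
    concordant = []
    discordant: list[tuple[HeteroplasmicSite | None, HeteroplasmicSite | None]] = []
    for pos in sorted(set(by_pos_a) | set(by_pos_b)):
        sa, sb = by_pos_a.get(pos), by_pos_b.get(pos)
        if sa is None or sb is None:
            discordant.append((sa, sb))
            continue
        if frozenset(sa.alleles) != frozenset(sb.alleles):
            discordant.append((sa, sb))
            continue
        lo_a, hi_a = _minor_fraction_ci(sa)
        lo_b, hi_b = _minor_fraction_ci(sb)
        if max(lo_a, lo_b) <= min(hi_a, hi_b):
            concordant.append((sa, sb))
        else:
            discordant.append((sa, sb))
    return ConcordanceReport(concordant=concordant, discordant=discordant)


@dataclass
class IdentityReport:
    sample_a: str
    sample_b: str
    diff: DiffResult
    concordance: ConcordanceReport
    comparable_sites: int
    verdict: str
    rationale: str

    def to_dict(self) -> dict:
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "differing_tokens": [t.format() for t in self.diff.differing],
            "diff_count": self.diff.count,
            "excluded_tokens": [t.format() for t in self.diff.excluded],
            "heteroplasmy_concordant": self.concordance.all_concordant,
            "n_heteroplasmy_shared": len(self.concordance.concordant),
            "comparable_sites": self.comparable_sites,
            "verdict": self.verdict,
            "rationale": self.rationale,
        }

    def to_text(self) -> str:
        lines = [
            f"Identity comparison: {self.sample_a} vs {self.sample_b}",
            f"  differing variants : {self.diff.count}"
            + (f" ({', '.join(t.format() for t in self.diff.differing)})"
               if self.diff.differing else ""),
            f"  excluded from diff : {len(self.diff.excluded)}",
            f"  comparable sites   : {self.comparable_sites}",
            f"  heteroplasmy       : "
            + ("concordant" if self.concordance.all_concordant else "DISCORDANT"),
            f"  verdict            : {self.verdict} — {self.rationale}",
        ]
        return "\n".join(lines)


def identity_verdict(
    diff_count: int,
    concordance: ConcordanceReport | bool,
    comparable_sites: int,
    min_comparable: int = DEFAULT_MIN_COMPARABLE,
) -> tuple[str, str]:
    """match / non_match / inconclusive from the diff count and concordance.

    match: zero differences, concordant heteroplasmy, and enough mutually
    callable sites to make "identical" meaningful.  non_match: two or more
    differences.  Anything else is inconclusive.
    """
    concordant = concordance if isinstance(concordance, bool) else concordance.all_concordant
    if diff_count >= 2:
        return "non_match", f"{diff_count} variant differences"
    if diff_count == 0 and concordant and comparable_sites >= min_comparable:
        return "match", (
            f"identical variants over {comparable_sites} comparable sites; "
            "heteroplasmy concordant"
        )
    if diff_count == 0 and comparable_sites < min_comparable:
        return "inconclusive", (
            f"only {comparable_sites} comparable sites (< {min_comparable})"
        )
    if diff_count == 1:
        return "inconclusive", "a single variant difference"
    return "inconclusive", "heteroplasmy discordant"


def compare_callsets(
    callset_a,
    callset_b,
    exclusions: Sequence[ExclusionRegion] = (),
    min_comparable: int = DEFAULT_MIN_COMPARABLE,
    flag_sensitive: bool = False,
) -> IdentityReport:
    """Full identity report between two ``SampleCallset`` objects."""
    diff = diff_variants(
        callset_a.tokens,
        callset_b.tokens,
        exclusions=exclusions,
        masked_a=callset_a.n_positions,
        masked_b=callset_b.n_positions,
        flag_sensitive=flag_sensitive,
    )
    concordance = heteroplasmy_concordance(
        callset_a.heteroplasmic_sites, callset_b.heteroplasmic_sites
    )
    masked = set(callset_a.n_positions) | set(callset_b.n_positions)
    length = min(callset_a.reference_length, callset_b.reference_length)
    excluded_sites = sum(
        1
        for pos in range(1, length + 1)
        if pos in masked or any(pos in region for region in exclusions)
    )
    comparable = length - excluded_sites
    verdict, rationale = identity_verdict(diff.count, concordance, comparable, min_comparable)
    return IdentityReport(
        sample_a=callset_a.name,
        sample_b=callset_b.name,
        diff=diff,
        concordance=concordance,
        comparable_sites=comparable,
        verdict=verdict,
        rationale=rationale,
    )
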