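# Methods

This note documents the models, parameters and design choices behind
`parchmentid`, and what the synthetic validation does and does not show.

## The identification problem

Mitochondrial DNA is the workhorse of degraded-tissue identification: it is
present at hundreds of copies per cell, survives in short fragments, and is
maternally inherited, so two pieces of parchment cut from one skin carry
the same mitogenome haplotype — including somatic peculiarities such as
heteroplasmy (two alleles at one site within one individual). The pipeline
therefore reconstructs, per sample: the source species, the mitogenome
consensus and its variant list, the haplogroup, the contamination level,
the animal's sex, and the post-mortem damage profile; identity between two
samples is then a statement about their variant lists and shared
heteroplasmies.

## Synthetic degraded libraries

The generator (`synthetic_data`) emulates the statistical structure of
shotgun libraries from parchment:

- **Fragments.** Lengths are truncated-normal (mean 100 bp, sd 25, minimum
  35 by default; an optional maximum), drawn uniformly from a circular
  donor genome. The fragment count is `coverage · L / E[length]`, where
  `E[length]` is the mean of the *truncated* distribution — nominal
  coverage is delivered coverage.
- **Reads.** Each fragment is sequenced as a 2×125 bp pair reading inward;
  fragments shorter than the read length read through into a fixed
  synthetic adapter. Qualities are constant Q37: quality modelling is not
  the subject here, and the preprocessing stages treat qualities generically.
- **Damage.** A simplified single-strand deamination model: a 5′-terminal
  C→T probability `p` decaying as `p·exp(−i/decay_length)` with position
  `i`, mirrored as G→A at the 3′ terminus, plus a uniform background error
  (default 10⁻³). Defaults `p = 0.1`, `decay_length = 3` produce the
  characteristic exponential terminal curves at the modest level expected
  when libraries are amplified with a uracil-intolerant polymerase. The
  full nick/overhang double-strand model is intentionally not implemented;
  the single-strand model suffices to generate and recover the
  terminal-excess signature.
- **Fragmentation context.** An optional purine cut bias places the
  fragment 5′ end so that the upstream genomic base (in molecule
  orientation) is a purine with a configurable probability, emulating
  depurination-driven fragmentation.
- **Heteroplasmy.** One biallelic site, realised as two genome versions
  mixed per-fragment at the minor fraction (default 0.5 at the site of
  interest).
- **Contamination.** A configurable fraction of fragments drawn from a
  contaminant genome. In the validation scenario the contaminant is a
  *reference-haplotype* conspecific — the worst case, since its reads map
  perfectly and differ from the sample only at haplotype-defining sites.
- **Truth sidecar.** Every read records its source, haplotype, coordinates,
  strand and individual damage edits; every recovery test compares pipeline
  output against direct counts over this sidecar.

What the generator does *not* model: indel sequencing errors, per-cycle
quality decay, index hopping, reference bias from a diverged reference, and
real mitogenome repeat structure. Passing tests therefore demonstrate
algorithmic correctness under the stated statistical structure, not
performance on any particular archival library.

## Preprocessing

Fixed stage order: quality-trim both ends (threshold Q20) → discard reads
shorter than 30 bp (strictly shorter; a 30 bp read survives) → merge mate
pairs → collapse exact duplicates (first representative kept). Merging
slides the reverse-complemented second mate across every offset with at
least 11 overlapping bases and accepts the best-matching offset if its
mismatch fraction is ≤ 0.1; a negative offset implies the fragment is
shorter than the read, and only the overlap (the fragment) is kept — this
is how adapter read-through is clipped without an adapter list.
Disagreeing overlap bases take the higher-quality base. The trimming
threshold and merge parameters are package defaults, not values asserted by
any source; all are configurable.

## Mapping

A k-mer index (k = 15, both strands at query time, circular references
wrapped by k−1) seeds candidate (reference, strand, diagonal) clusters;
the best clusters are extended by alignment inside a padded window around
the diagonal. The optimal path inside the window is computed by edlib and
rescored with the affine scheme match +1, mismatch −1, gap open −3, gap
extend −1; whenever the unit-cost path contains indels it is recomputed
under the affine scheme directly (unit-cost ties can write a mismatching
terminal base as an insertion, which would corrupt terminal damage
statistics and indel placement). Mapping quality is the proxy
`min(60, 4·(best − second_best))`, zero for ties; reads under 30 are
excluded from every downstream count, mirroring a minimum-mapping-quality
30 filter. A read whose best score is tied across species is ambiguous and
dropped; within a species, ties break to the lowest coordinate.

Iterative remapping (default 5 iterations) alternates mapping with a
substitution-only template update (majority base at positions with depth
≥ 3), stopping early when the template is stable. Updating substitutions
only keeps template coordinates identical to the input reference, so the
final pileup is directly in reference coordinates; insertion and deletion
tokens are emitted from the final pileup's indel observations instead of
being folded into the template. Indel observations are left-normalized
(shifted through repeat/homopolymer context) so calls and injected truth
agree on a canonical placement.

## Consensus, heteroplasmy, haplogroups, contamination

Consensus is a per-position majority vote — at 6–19× coverage, read-count
thresholds are more transparent than genotype likelihoods, and they match
how such assemblies are verified in practice. Positions with fewer than 3
reads are masked to `N` and emit no token (strictly fewer: depth 3 is
called). Ties resolve to the reference allele, then alphabetically. A site
is heteroplasmic when the top two alleles each have ≥ 3 reads and the minor
fraction is ≥ 0.2; the consensus symbol and token allele become the IUPAC
pair code (A+G → R). Candidate heteroplasmies whose minor observations are
exclusively terminal C→T (5′) or G→A (3′) are flagged as possible damage
artifacts but not auto-rejected.

Haplogroup assignment maximizes the match score
`|defining ∩ sample| / |defining \ masked|`; ties break to the larger
(more specific) defining set, then lexicographically. Tokens at N-masked
positions leave the denominator — an unreadable site neither supports nor
contradicts a clade.

Contamination is the pooled fraction of read bases mismatching the
consensus at the matched haplogroup-defining substitution sites, reported
rounded half-up to an integer percent (pooling, not per-site averaging,
reproduces printed worked fractions such as 4/200 → 2% and 21/355 → 6%;
per-site averaging is available as an option). Two properties of this
estimator matter for interpretation:

- it inherits a small positive bias (~0.3–0.4 percentage points under the
  default damage model) from deamination and sequencing error at the
  inspected sites, since every mismatch is counted;
- conversely, *pseudo-heteroplasmy*: at a few percent contamination by a
  reference-haplotype individual, reference-allele reads under a
  derived-allele site can pass the heteroplasmy gates. Because mismatching
  reads at haplogroup-defining sites are, by this very estimator, the
  contamination channel, a candidate heteroplasmy at any table-defining
  position whose minor allele equals the reference base is resolved to its
  derived major allele and removed from the heteroplasmy list. The union
  of defining positions across the whole table is used (a clade should not
  have to win the assignment before its sites are recognised). Genuine
  heteroplasmies at non-defining sites — the forensically interesting ones
  — are untouched.

## Sexing

Sheep X and chromosome 6 are of similar length, so a ewe yields similar
numbers of reads on both while a ram yields about half on X. The call uses
the length-normalized ratio with an indeterminate band: female at ≥ 0.8,
male at ≤ 0.6. The cutoffs are package defaults chosen to put ~4 standard
errors between the two hypotheses at a few hundred reads per chromosome;
they are configurable. Tests use scaled-down synthetic chromosomes (4 kb)
because only the depth *ratio* carries information.

## Identity verdict

Two callsets are compared by the symmetric difference of their token sets
(position, kind, allele; low-coverage flags ignored unless requested).
Positions N-masked in either sample, and positions inside exclusion
regions, are excluded and listed separately — a masked site is uncertain,
not discrepant. The control-region tandem repeats (15650–15905), which
resist alignment, ship as a default-off exclusion preset. Shared
heteroplasmic sites are concordant when the allele pairs agree and the 95%
Wilson intervals of the minor fractions overlap. The verdict is `match`
when there are zero differences, all shared heteroplasmies are concordant,
and at least `min_comparable` sites (default 10 000) were callable in both
samples; `non_match` at ≥ 2 differences; otherwise `inconclusive`. The 0/≥2
thresholds are declared package policy for a qualitative judgement.

## The three-membrane validation scenario

`scenarios.run_scenario(seed)` rebuilds the full study design
synthetically: two donor ewes whose mitogenomes differ by 28 substitutions
(10 shared clade-backbone variants, 13 and 15 private), one donor carrying
a balanced A/G heteroplasmy at position 6907 and sampled twice (9× and
18×), the other sampled once (6×); each library gets 2–6% contamination
from a reference-haplotype conspecific, the default damage model, and a
female nuclear read set at 8× over 4 kb X/autosome surrogates.

Scenario-specific choices: an 8 kb mitogenome surrogate (every decision the
pipeline makes depends on relative structure, not genome length;
`min_comparable_sites` is scaled to 5 000 accordingly); variant positions
spaced > 130 bp with fragment lengths capped at 125 bp so no read spans two
variant sites, keeping defining-site mismatch counts binomial as the
contamination recovery check assumes; contamination recovery is judged
against the truth sidecar's realized contaminant fraction.

**A known, quantified limitation.** At 9× the depth at a single site is
Poisson-distributed, and the heteroplasmy gate (both alleles ≥ 3 reads)
passes in only ~65–70% of libraries for a balanced site — measured at 0.65
over 80 independent simulated 9× libraries, matching the binomial
calculation. A same-donor pair that includes a 9× sample therefore reaches
a `match` verdict in only ~60% of runs; the failures are all at the
heteroplasmic site (the missing or excess `6907R`/`6907G` token), never at
ordinary variants. Reliable matching of heteroplasmy-bearing individuals
requires ≥ 15–20× at the site, or relaxed gates with a corresponding
false-positive cost. Species, sex, non-match discrimination, haplogroup
and contamination recovery are all robust at these coverages.

## Numerical choices and degenerate inputs

- All randomness flows from a single integer seed per simulation; identical
  configs produce byte-identical FASTQ and sidecars.
- Alignment tie-breaks (sort by score, then reference name, then
  coordinate) and consensus tie-breaks (reference allele, then
  alphabetical) are deterministic.
- Zero-depth pileups give 0× coverage and all-`N` consensus; empty token
  sets yield a score-0 haplogroup call with a warning; contamination with
  zero inspected bases warns and reports an undefined fraction.
- Percent rounding is half-up (`floor(x + 0.5)`), matching printed
  integer-percent conventions.
- The mapq proxy is a declared device, not an estimate of any published
  mapper's scale; only its role as a ≥ 30 filter is relied on.
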