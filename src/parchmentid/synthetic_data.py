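"""Synthetic degraded-shotgun-read generator.

Emulates the statistical structure of parchment DNA libraries: short
fragments (truncated-normal length, mean 100 bp), sequenced as 2x125 bp
pairs that read through into adapter when the fragment is shorter than the
read length; terminal cytosine deamination (C->T excess at 5' ends, G->A at
3' ends, geometrically decaying into the read); a low uniform background
error; optional exogenous contamination mixed in at a fixed fraction; one
optional biallelic heteroplasmic site realised as two genome versions mixed
at the stated minor fraction; and X-vs-autosome read-depth structure for
sexing (females ~1x relative X depth, males ~0.5x).

Every read's provenance (source genome, haplotype version, fragment
coordinates, strand, individual damage and error edits, duplicate status) is
recorded in a truth sidecar, which is sufficient to recompute by direct
counting every summary the analysis pipeline later estimates.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import (
    IUPAC_PAIR,
    Read,
    Reference,
    TokenKind,
    VariantToken,
    reverse_complement,
    write_fastq,
)

#: Synthetic adapter read through when fragments are shorter than the read
#: length (any fixed non-genomic sequence works; 120 bp covers 125 bp reads
#: of minimum-length fragments).
ADAPTER_1 = ("AGATCGGAAGAGCACACGTCTGAACTCCAGTCACACGTGATCTCGTATGC"
             "CGTCTTCTGCTTGAAAAAGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
             "CACGTGATCTCGTATGCCGT")
ADAPTER_2 = ("AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCC"
             "GTATCATTAAAAAGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATC"
             "TCGGTGGTCGCCGTATCATT")

_BASES = "ACGT"
_Q37 = 37


@dataclass
class DamageParams:
    """Terminal deamination model (single-strand, geometric decay).

    ``p_ct_5prime``/``p_ga_3prime`` are the misincorporation probabilities at
    the terminal base; position ``i`` from the end carries
    ``p * exp(-i / decay_length)``.  ``background_error`` is a uniform
    per-base miscall probability (any base to any other).
    """

    p_ct_5prime: float = 0.1
    p_ga_3prime: float = 0.1
    decay_length: float = 3.0
    background_error: float = 0.001

    def __post_init__(self) -> None:
        for name in ("p_ct_5prime", "p_ga_3prime", "background_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.decay_length < 1:
            raise ValueError("decay_length must be >= 1")

    def rate_at(self, offset: int) -> float:
        return self.p_ct_5prime * math.exp(-offset / self.decay_length)


@dataclass
class HeteroplasmySpec:
    """A biallelic heteroplasmic site mixed at ``minor_fraction``."""

    position: int  # 1-based
    minor_fraction: float = 0.5
    minor_allele: str | None = None  # chosen at generation time if None

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_fraction <= 0.5:
            raise ValueError("heteroplasmy minor fraction must be in (0, 0.5]")


@dataclass
class DonorGenome:
    """A simulated individual: mutated genome plus its ground-truth tokens."""

    name: str
    species_label: str
    major: str
    minor: str | None  # differs from major only at the heteroplasmic site
    truth_tokens: frozenset[VariantToken]
    heteroplasmy: HeteroplasmySpec | None
    circular: bool = True

    def version(self, minor: bool) -> str:
        return self.minor if (minor and self.minor is not None) else self.major


@dataclass
class SimConfig:
    """Study conditions for one simulated shotgun library."""

    panel: Sequence[Reference]
    donor_species: str = "sheep"
    n_variants: int = 25
    heteroplasmy: HeteroplasmySpec | None = None
    fragment_mean: float = 100.0
    fragment_sd: float = 25.0
    fragment_min: int = 35
    fragment_max: int | None = None
    coverage: float = 18.0
    read_length: int = 125
    contamination_fraction: float = 0.0
    contaminant: Reference | None = None
    sex: str = "female"
    damage: DamageParams = field(default_factory=DamageParams)
    duplicate_rate: float = 0.0
    purine_cut_bias: float | None = None
    donor: DonorGenome | None = None  # reuse an existing donor (same individual)
    sample_name: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must be in [0,1)")
        if self.fragment_mean < self.fragment_min:
            raise ValueError("fragment mean below minimum length")
        if self.contamination_fraction > 0 and self.contaminant is None:
            raise ValueError("contamination requested but no contaminant genome given")

    def donor_reference(self) -> Reference:
        for ref in self.panel:
            if ref.species_label == self.donor_species:
                return ref
        raise ValueError(f"no panel member with species {self.donor_species!r}")


_PAIR_BASES = {code: tuple(sorted(pair)) for pair, code in IUPAC_PAIR.items()}


def synthetic_reference(
    length: int,
    seed: int | np.random.Generator = 0,
    name: str = "ref",
    species_label: str = "species",
    tokens: Sequence[VariantToken] = (),
    circular: bool = True,
) -> Reference:
    """A random reference compatible with a token set to be injected later:
    at substitution positions the reference base differs from the token
    allele; at IUPAC-pair (heteroplasmy) positions the reference base is the
    alphabetically first base of the pair (the convention under which the
    pair code itself is a difference versus the reference)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = rng.choice(list(_BASES), size=length).tolist()
    for tok in tokens:
        if tok.kind is not TokenKind.SUBSTITUTION or tok.position > length:
            continue
        if tok.allele in _PAIR_BASES:
            seq[tok.position - 1] = _PAIR_BASES[tok.allele][0]
        elif seq[tok.position - 1] == tok.allele:
            alt = _BASES[int(rng.integers(4))]
            while alt == tok.allele:
                alt = _BASES[int(rng.integers(4))]
            seq[tok.position - 1] = alt
    return Reference(name, species_label, "".join(seq), circular=circular)


def divergent_reference(
    reference: Reference,
    divergence: float,
    seed: int | np.random.Generator = 0,
    name: str = "other",
    species_label: str = "other",
) -> Reference:
    """Mutate a fraction ``divergence`` of bases — a panel member of another
    species, distant enough for competitive mapping to separate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(reference.sequence)
    n = int(round(divergence * len(seq)))
    for pos in rng.choice(len(seq), size=n, replace=False):
        alt = _BASES[int(rng.integers(4))]
        while alt == seq[pos]:
            alt = _BASES[int(rng.integers(4))]
        seq[pos] = alt
    return Reference(name, species_label, "".join(seq), circular=reference.circular)


def generate_donor_genome(
    reference: Reference,
    n_variants: int,
    heteroplasmy: HeteroplasmySpec | None = None,
    seed: int | np.random.Generator = 0,
    tokens: Sequence[VariantToken] | None = None,
    name: str = "donor",
) -> DonorGenome:
    """Mutate ``reference`` into a donor individual.

    Either draws ``n_variants`` random substitutions (positions unique, new
    base differs from the reference base) or, when ``tokens`` is given,
    injects exactly that token set (substitutions, insertions, deletions;
    positions interpreted in reference coordinates; one substitution token
    carrying an IUPAC pair code is realised as a heteroplasmic site).  The
    heteroplasmic site is realised as a second genome version differing at
    that single position; its ground-truth token is the IUPAC pair code of
    the two alleles.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(reference)
    seq = list(reference.sequence)
    truth: set[VariantToken] = set()
    insertions: dict[int, str] = {}
    deleted: set[int] = set()
    pair_token: VariantToken | None = None

    if tokens is not None:
        if n_variants:
            raise ValueError("give either n_variants or an explicit token list")
        for tok in tokens:
            if tok.position > L:
                raise ValueError(f"token {tok.format()} beyond reference length {L}")
            if tok.kind is TokenKind.SUBSTITUTION:
                if tok.allele in _PAIR_BASES:
                    if pair_token is not None:
                        raise ValueError("at most one heteroplasmic pair token supported")
                    pair_token = tok
                else:
                    seq[tok.position - 1] = tok.allele
            elif tok.kind is TokenKind.INSERTION:
                insertions[tok.position - 1] = tok.allele
            elif tok.kind is TokenKind.DELETION:
                deleted.add(tok.position - 1)
            # position_only tokens carry no sequence edit
            truth.add(tok)
        if insertions or deleted:
            out = []
            for i, base in enumerate(seq):
                if i not in deleted:
                    out.append(base)
                if i in insertions:
                    out.append(insertions[i])
            seq = out
    else:
        if n_variants > L // 100:
            raise ValueError("n_variants too large for reference length")
        positions: set[int] = set()
        attempts = 0
        while len(positions) < n_variants:
            pos = int(rng.integers(L)) + 1
            if pos in positions:
                attempts += 1
                if attempts > 1000:
                    raise RuntimeError("variant position collision after 1000 draws")
                continue
            positions.add(pos)
        for pos in sorted(positions):
            ref_base = seq[pos - 1]
            alt = _BASES[int(rng.integers(4))]
            while alt == ref_base:
                alt = _BASES[int(rng.integers(4))]
            seq[pos - 1] = alt
            truth.add(VariantToken(pos, TokenKind.SUBSTITUTION, alt))

    def shifted_index(pos: int) -> int:
        """Reference 1-based position -> 0-based index in the donor genome
        (insertions/deletions upstream shift coordinates)."""
        idx = pos - 1
        idx += sum(1 for i in insertions if i < pos - 1)
        idx -= sum(1 for d in deleted if d < pos - 1)
        return idx

    major = "".join(seq)
    minor_seq: str | None = None
    het: HeteroplasmySpec | None = None

    if pair_token is not None:
        if heteroplasmy is not None and heteroplasmy.position != pair_token.position:
            raise ValueError("pair token and heteroplasmy spec disagree on position")
        frac = heteroplasmy.minor_fraction if heteroplasmy else 0.5
        pair = _PAIR_BASES[pair_token.allele]
        idx = shifted_index(pair_token.position)
        major_allele = major[idx] if major[idx] in pair else pair[0]
        minor_allele = pair[1] if major_allele == pair[0] else pair[0]
        if major[idx] != major_allele:
            major = major[:idx] + major_allele + major[idx + 1 :]
        minor_seq = major[:idx] + minor_allele + major[idx + 1 :]
        het = HeteroplasmySpec(pair_token.position, frac, minor_allele)
    elif heteroplasmy is not None:
        pos = heteroplasmy.position
        if pos > L:
            raise ValueError("heteroplasmic position beyond genome length")
        idx = shifted_index(pos)
        major_allele = major[idx]
        minor_allele = heteroplasmy.minor_allele
        if minor_allele is None:
            minor_allele = _BASES[int(rng.integers(4))]
            while minor_allele == major_allele:
                minor_allele = _BASES[int(rng.integers(4))]
        elif minor_allele == major_allele:
            raise ValueError("heteroplasmy minor allele equals major allele")
        minor_seq = major[:idx] + minor_allele + major[idx + 1 :]
        het = HeteroplasmySpec(pos, heteroplasmy.minor_fraction, minor_allele)
        code = IUPAC_PAIR[frozenset((major_allele, minor_allele))]
        truth.add(VariantToken(pos, TokenKind.SUBSTITUTION, code))

    return DonorGenome(
        name=name,
        species_label=reference.species_label,
        major=major,
        minor=minor_seq,
        truth_tokens=frozenset(truth),
        heteroplasmy=het,
        circular=reference.circular,
    )


def _expected_fragment_length(cfg: SimConfig) -> float:
    """Mean of the truncated fragment-length distribution, so that nominal
    coverage refers to bases actually delivered."""
    from scipy.stats import truncnorm

    upper = cfg.fragment_max if cfg.fragment_max is not None else np.inf
    a = (cfg.fragment_min - cfg.fragment_mean) / cfg.fragment_sd
    b = (upper - cfg.fragment_mean) / cfg.fragment_sd
    return float(truncnorm.mean(a, b, loc=cfg.fragment_mean, scale=cfg.fragment_sd))


def _draw_fragment_length(rng: np.random.Generator, cfg: SimConfig, limit: int) -> int:
    if cfg.fragment_max is not None:
        limit = min(limit, cfg.fragment_max)
    for _ in range(1000):
        length = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        if cfg.fragment_min <= length <= limit:
            return length
    raise RuntimeError("could not draw a fragment length within bounds")


def _fragment_from(seq: str, start: int, length: int, circular: bool) -> str | None:
    L = len(seq)
    if start + length <= L:
        return seq[start : start + length]
    if circular:
        return seq[start:] + seq[: start + length - L]
    return None


def _breakpoint_pools(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Genome positions partitioned by base: (purine A/G, pyrimidine/other).

    A fragment's 5'-upstream base in molecule orientation is the genomic
    base just outside its 5' end: position start-1 for plus-strand
    molecules, and the complement of position start+length for minus-strand
    molecules (complement purine <=> genomic pyrimidine)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    purine = (arr == ord("A")) | (arr == ord("G"))
    idx = np.arange(len(seq))
    return idx[purine], idx[~purine]


def _apply_damage(
    fragment: str, damage: DamageParams, rng: np.random.Generator
) -> tuple[str, list[dict]]:
    """Deaminate and miscall a fragment in its sequencing orientation."""
    n = len(fragment)
    bases = list(fragment)
    edits: list[dict] = []
    u = rng.random(n)
    u2 = rng.random(n)
    for i in range(n):
        base = bases[i]
        if base == "C" and u[i] < damage.p_ct_5prime * math.exp(-i / damage.decay_length):
            bases[i] = "T"
            edits.append({"pos": i, "from": "C", "to": "T", "class": "ct5"})
            continue
        j = n - 1 - i
        if base == "G" and u[i] < damage.p_ga_3prime * math.exp(-j / damage.decay_length):
            bases[i] = "A"
            edits.append({"pos": i, "from": "G", "to": "A", "class": "ga3"})
            continue
        if damage.background_error and u2[i] < damage.background_error:
            alt = _BASES[int(rng.integers(4))]
            while alt == base:
                alt = _BASES[int(rng.integers(4))]
            bases[i] = alt
            edits.append({"pos": i, "from": base, "to": alt, "class": "error"})
    return "".join(bases), edits


@dataclass
class SimResult:
    pairs: list[tuple[Read, Read]]
    truth: dict
    donor: DonorGenome

    def write(self, prefix: str | Path) -> tuple[Path, Path, Path]:
        prefix = Path(prefix)
        r1 = prefix.with_name(prefix.name + "_R1.fastq")
        r2 = prefix.with_name(prefix.name + "_R2.fastq")
        sidecar = prefix.with_name(prefix.name + "_truth.json")
        write_fastq(r1, (p[0] for p in self.pairs))
        write_fastq(r2, (p[1] for p in self.pairs))
        sidecar.write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return r1, r2, sidecar


def simulate_reads(config: SimConfig) -> SimResult:
    """Simulate one paired-end shotgun library under ``config``.

    Fragment count is ``round(coverage * genome_length / fragment_mean)`` so
    that the nominal coverage refers to unique template molecules (the
    quantity the downstream pileup sees after pair merging and duplicate
    removal).
    """
    rng = np.random.default_rng(config.seed)
    donor = config.donor
    if donor is None:
        donor = generate_donor_genome(
            config.donor_reference(),
            config.n_variants,
            config.heteroplasmy,
            seed=rng,
            name=config.sample_name + "_donor",
        )

    sources = {"donor": donor.major}
    if donor.minor is not None:
        sources["donor_minor"] = donor.minor
    if config.contaminant is not None:
        sources["contaminant"] = config.contaminant.sequence

    start_pools = {}
    if config.purine_cut_bias is not None:
        for key, seq in sources.items():
            start_pools[key] = _breakpoint_pools(seq)

    L = len(donor.major)
    n_fragments = max(1, int(round(config.coverage * L / _expected_fragment_length(config))))
    pairs: list[tuple[Read, Read]] = []
    read_truth: list[dict] = []

    def emit(source_key: str, pair_id: str) -> dict | None:
        seq = sources[source_key]
        circular = donor.circular if source_key.startswith("donor") else config.contaminant.circular
        limit = len(seq) if circular else min(len(seq), 10 * int(config.fragment_mean))
        length = _draw_fragment_length(rng, config, limit)
        strand = "-" if rng.random() < 0.5 else "+"
        if config.purine_cut_bias is None:
            start = int(rng.integers(len(seq)))
        else:
            purine_pos, pyrimidine_pos = start_pools[source_key]
            want_purine = rng.random() < config.purine_cut_bias
            if strand == "+":
                pool = purine_pos if want_purine else pyrimidine_pos
                start = (int(pool[int(rng.integers(len(pool)))]) + 1) % len(seq)
            else:
                pool = pyrimidine_pos if want_purine else purine_pos
                start = (int(pool[int(rng.integers(len(pool)))]) - length) % len(seq)
        fragment = _fragment_from(seq, start, length, circular)
        if fragment is None:
            return None
        molecule = fragment if strand == "+" else reverse_complement(fragment)
        molecule, edits = _apply_damage(molecule, config.damage, rng)
        r1_seq = (molecule + ADAPTER_1)[: config.read_length]
        r2_seq = (reverse_complement(molecule) + ADAPTER_2)[: config.read_length]
        quals = [_Q37] * config.read_length
        pairs.append(
            (Read(pair_id + "/1", r1_seq, list(quals)), Read(pair_id + "/2", r2_seq, list(quals)))
        )
        return {
            "id": pair_id,
            "source": "contaminant" if source_key == "contaminant" else "donor",
            "haplotype": "minor" if source_key == "donor_minor" else "major",
            "start": start,
            "length": length,
            "strand": strand,
            "damage_edits": edits,
            "duplicate_of": None,
        }

    i = 0
    while i < n_fragments:
        if config.contamination_fraction and rng.random() < config.contamination_fraction:
            source_key = "contaminant"
        elif donor.minor is not None and rng.random() < donor.heteroplasmy.minor_fraction:
            source_key = "donor_minor"
        else:
            source_key = "donor"
        rec = emit(source_key, f"{config.sample_name}_frag{i:06d}")
        if rec is None:
            continue
        read_truth.append(rec)
        i += 1
        if config.duplicate_rate and rng.random() < config.duplicate_rate and pairs:
            j = int(rng.integers(len(pairs)))
            r1, r2 = pairs[j]
            dup_id = f"{config.sample_name}_dup{len(pairs):06d}"
            pairs.append(
                (
                    Read(dup_id + "/1", r1.sequence, list(r1.qualities)),
                    Read(dup_id + "/2", r2.sequence, list(r2.qualities)),
                )
            )
            dup_rec = dict(read_truth[j])
            dup_rec["id"] = dup_id
            dup_rec["duplicate_of"] = read_truth[j]["id"]
            read_truth.append(dup_rec)

    truth = {
        "sample": config.sample_name,
        "seed": config.seed,
        "donor_name": donor.name,
        "species": donor.species_label,
        "genome_length": L,
        "coverage": config.coverage,
        "contamination_fraction": config.contamination_fraction,
        "heteroplasmy": asdict(donor.heteroplasmy) if donor.heteroplasmy else None,
        "damage": asdict(config.damage),
        "truth_tokens": sorted(t.format() for t in donor.truth_tokens),
        "reads": read_truth,
    }
    return SimResult(pairs=pairs, truth=truth, donor=donor)


def simulate_sex_reads(
    sex: str,
    x_reference: Reference,
    autosome_reference: Reference,
    depth: float,
    seed: int = 0,
    fragment_mean: float = 100.0,
    fragment_sd: float = 25.0,
    fragment_min: int = 35,
) -> tuple[list[Read], dict]:
    """Simulate nuclear reads with female (X:autosome ~ 1) or male (~0.5)
    depth structure.

    ``depth`` is the autosomal coverage; the X chromosome is sampled at the
    same per-base rate for females and half that rate for males.  Reads are
    emitted merged-style (one read per fragment, constant quality).
    """
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    for ref in (x_reference, autosome_reference):
        if len(ref) == 0:
            raise ValueError("zero-length reference")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth = {"sex": sex, "depth": depth, "n_x": 0, "n_autosome": 0}
    plan = [
        (autosome_reference, depth, "n_autosome", "auto"),
        (x_reference, depth if sex == "female" else depth / 2.0, "n_x", "x"),
    ]
    for ref, rate, key, tag in plan:
        n = rng.poisson(rate * len(ref) / fragment_mean)
        truth[key] = int(n)
        for i in range(n):
            length = fragment_min
            for _ in range(100):
                length = int(round(rng.normal(fragment_mean, fragment_sd)))
                if fragment_min <= length <= len(ref):
                    break
            start = int(rng.integers(len(ref)))
            frag = _fragment_from(ref.sequence, start, length, ref.circular)
            if frag is None:
                frag = ref.sequence[start:]
                if len(frag) < fragment_min:
                    continue
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            reads.append(Read(f"{tag}_{i:06d}", frag, [_Q37] * len(frag), merged=True))
    return reads, truth
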