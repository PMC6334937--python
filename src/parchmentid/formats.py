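"""Core domain types and file formats.

Sequences travel as plain FASTA/FASTQ (Phred+33); per-sample haplotypes are
expressed in the compact variant-token dialect used by domestic-animal
mitogenome haplogroup databases: ``281C`` (substitution), ``566+G``
(insertion of G after position 566), ``11710deletion`` (single-base
deletion), with a trailing ``#`` marking a site covered by fewer than three
reads.  Positions are 1-based in the coordinate system of the reference
mitogenome; all internal alignment coordinates are 0-based half-open and
converted at the reporting boundary.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CODES = set("ACGTRYSWKMBDHVN")
#: IUPAC code for an unordered pair of bases (heteroplasmy notation, A+G -> R).
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TokenParseError(ValueError):
    """Raised when a variant token cannot be parsed."""


class TokenKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    POSITION_ONLY = "position_only"


@dataclass(frozen=True)
class VariantToken:
    """One positional difference versus a reference mitogenome.

    Equality and hashing consider only ``(position, kind, allele)`` so that
    set arithmetic over token lists ignores low-coverage ``#`` flags; callers
    needing flag-sensitive comparison use :meth:`flagged_key`.
    """

    position: int
    kind: TokenKind
    allele: str = ""
    low_coverage_flag: bool = field(default=False, compare=False)
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"token position must be >= 1, got {self.position}")
        if self.kind in (TokenKind.SUBSTITUTION, TokenKind.INSERTION):
            if self.allele not in IUPAC_CODES:
                raise ValueError(f"invalid allele {self.allele!r} at {self.position}")
        elif self.allele:
            raise ValueError(f"{self.kind.value} token carries no allele")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.kind.value, self.allele)

    def flagged_key(self) -> tuple[int, str, str, bool]:
        return (*self.key, self.low_coverage_flag)

    def format(self, include_flag: bool = True) -> str:
        if self.kind is TokenKind.SUBSTITUTION:
            body = f"{self.position}{self.allele}"
        elif self.kind is TokenKind.INSERTION:
            body = f"{self.position}+{self.allele}"
        elif self.kind is TokenKind.DELETION:
            body = f"{self.position}deletion"
        else:
            body = str(self.position)
        if include_flag and self.low_coverage_flag:
            body += "#"
        return body

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


_TOKEN_RE = re.compile(r"(\d+)(.*)")


def parse_variant_token(token: str, lenient: bool = False) -> VariantToken:
    """Parse one token of the variant dialect.

    A trailing letter is a substitution allele, ``+X`` an insertion after the
    stated position, a literal ``deletion`` suffix a single-base deletion and
    a trailing ``#`` flags low coverage.  Digits-only tokens (an allele-less
    site, as occasionally printed) are accepted as ``position_only`` under
    ``lenient=True`` and rejected otherwise.
    """
    raw = token.strip()
    body = raw
    flag = body.endswith("#")
    if flag:
        body = body[:-1]
    m = _TOKEN_RE.fullmatch(body)
    if m is None:
        raise TokenParseError(f"malformed variant token {raw!r}: no leading position")
    position = int(m.group(1))
    suffix = m.group(2)
    if suffix == "":
        if not lenient:
            raise TokenParseError(
                f"allele-less token {raw!r} (position only); pass lenient=True to accept"
            )
        kind, allele = TokenKind.POSITION_ONLY, ""
    elif suffix == "deletion":
        kind, allele = TokenKind.DELETION, ""
    elif len(suffix) == 2 and suffix[0] == "+" and suffix[1] in IUPAC_CODES:
        kind, allele = TokenKind.INSERTION, suffix[1]
    elif len(suffix) == 1 and suffix in IUPAC_CODES:
        kind, allele = TokenKind.SUBSTITUTION, suffix
    else:
        raise TokenParseError(f"malformed variant token {raw!r}: unknown suffix {suffix!r}")
    return VariantToken(position, kind, allele, low_coverage_flag=flag, raw=raw)


def parse_token_list(text: str, lenient: bool = True) -> list[VariantToken]:
    """Parse a comma-separated token list (whitespace around commas ignored)."""
    return [
        parse_variant_token(item, lenient=lenient)
        for item in (part.strip() for part in text.split(","))
        if item
    ]


class ReferenceRole(str, enum.Enum):
    MITO_PANEL = "mito_panel"
    SEX_X = "sex_x"
    SEX_AUTOSOME = "sex_autosome"


@dataclass
class Reference:
    """A named reference sequence (mitogenome panel member or nuclear surrogate)."""

    name: str
    species_label: str
    sequence: str
    circular: bool = False
    role: ReferenceRole = ReferenceRole.MITO_PANEL

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"reference {self.name!r} has empty sequence")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"reference {self.name!r} contains invalid symbols {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    """A sequencing read with Phred quality scores."""

    id: str
    sequence: str
    qualities: list[int]
    merged: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HaplogroupTable:
    """Map from haplogroup name to its set of defining variant tokens."""

    groups: dict[str, frozenset[VariantToken]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("no haplogroups in table")
        for name, tokens in self.groups.items():
            if not tokens:
                raise ValueError(f"haplogroup {name!r} has no defining tokens")

    def __iter__(self) -> Iterator[str]:
        return iter(self.groups)

    def __getitem__(self, name: str) -> frozenset[VariantToken]:
        return self.groups[name]


def load_haplogroup_table(path: str | Path, lenient: bool = True) -> HaplogroupTable:
    """Load a TSV of ``haplogroup<TAB>comma-separated tokens``.

    Lines starting with ``#`` are comments.  Duplicate haplogroup names and
    unparseable tokens are errors.
    """
    groups: dict[str, frozenset[VariantToken]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"haplogroup row needs two columns: {row!r}")
            name = row[0].strip()
            if name in groups:
                raise ValueError(f"duplicate haplogroup name {name!r}")
            groups[name] = frozenset(parse_token_list(row[1], lenient=lenient))
    if not groups:
        raise ValueError(f"no haplogroups found in {path}")
    return HaplogroupTable(groups)


# ---------------------------------------------------------------------------
# FASTA / FASTQ plumbing (Biopython-backed)

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    def _records():
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")
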