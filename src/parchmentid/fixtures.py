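"""Accessors for the packaged reference fixtures.

``membrane_variants()`` returns the published polymorphism lists of the three
shotgun-sequenced parchment membranes (upper membrane, lower membrane, blank
parchment) as parsed token sets; ``haplogroup_table()`` returns the minimal
haplogroup definition table (published B1a / B1a2a1 sets plus synthetic
intermediate clades used to exercise the specificity tie-break).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .formats import HaplogroupTable, VariantToken, load_haplogroup_table, parse_token_list


@dataclass(frozen=True)
class MembraneHaplotype:
    sample: str
    haplogroup: str
    defining_tokens: tuple[VariantToken, ...]
    private_tokens: tuple[VariantToken, ...]

    @property
    def all_tokens(self) -> tuple[VariantToken, ...]:
        return self.defining_tokens + self.private_tokens


def _data_path(name: str):
    return resources.files("parchmentid.data") / name


def membrane_variants() -> dict[str, MembraneHaplotype]:
    out: dict[str, MembraneHaplotype] = {}
    with _data_path("membrane_variants.tsv").open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            sample, haplogroup, defining, private = row[:4]
            out[sample] = MembraneHaplotype(
                sample=sample,
                haplogroup=haplogroup,
                defining_tokens=tuple(parse_token_list(defining, lenient=True)),
                private_tokens=tuple(parse_token_list(private, lenient=True)),
            )
    return out


def haplogroup_table() -> HaplogroupTable:
    with resources.as_file(_data_path("haplogroups_minimal.tsv")) as path:
        return load_haplogroup_table(path, lenient=True)
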