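"""Post-mortem damage profiling from aligned reads.

Ancient or degraded DNA shows an excess of C->T mismatches at read 5' ends
and G->A at 3' ends (cytosine deamination read through a blunt-end library),
plus an excess of purines at the genomic position immediately preceding the
read start (depurination-driven fragmentation).  This module computes those
empirical frequencies per read position over a terminal window — the
standard misincorporation plot — with no model fitting.

All positions are handled in read orientation: minus-strand alignments are
flipped (reverse-complemented) before counting, which makes strand-flipping
an involution on the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import Reference, reverse_complement

DEFAULT_WINDOW = 25
DEFAULT_UPSTREAM_SPAN = 10
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class DamageProfile:
    """Empirical misincorporation frequencies over terminal windows.

    ``ct_5prime[i]`` is the fraction of reads with reference C at read
    position i (0-based from the 5' end) that read T; ``ga_3prime[j]`` the
    G->A fraction at distance j from the 3' end.  Positions with zero
    denominator are NaN (missing), never 0.  ``purine_upstream[o-1]`` is the
    fraction of A/G at genomic offset -o before the read start.
    """

    ct_5prime: np.ndarray
    ga_3prime: np.ndarray
    ct_denominator: np.ndarray
    ga_denominator: np.ndarray
    purine_upstream: np.ndarray
    purine_denominator: np.ndarray
    window: int = DEFAULT_WINDOW

    def to_rows(self) -> list[dict]:
        rows = []
        for i in range(self.window):
            rows.append(
                {
                    "position": i + 1,
                    "ct_5prime": float(self.ct_5prime[i]),
                    "ct_n": int(self.ct_denominator[i]),
                    "ga_3prime": float(self.ga_3prime[i]),
                    "ga_n": int(self.ga_denominator[i]),
                }
            )
        return rows


def _read_oriented_columns(aln, ref_seq: str):
    """Yield (read_pos, ref_base, read_base) for aligned (non-gap) columns,
    in read orientation."""
    L = len(ref_seq)
    cols = []
    rpos, qpos = aln.start, 0
    s = aln.oriented_sequence
    for op, ln in aln.cigar:
        if op in ("=", "X", "M"):
            for j in range(ln):
                cols.append((ref_seq[(rpos + j) % L], s[qpos + j]))
            rpos += ln
            qpos += ln
        elif op == "D":
            rpos += ln
        elif op == "I":
            qpos += ln
    if aln.strand == "-":
        cols = [(_COMP[r], _COMP[q]) for r, q in reversed(cols)]
    return cols


def misincorporation_profile(
    alignments: Sequence,
    reference: Reference | str,
    window: int = DEFAULT_WINDOW,
    upstream_span: int = DEFAULT_UPSTREAM_SPAN,
) -> DamageProfile:
    """Empirical C->T (5') and G->A (3') frequencies per terminal position,
    plus the upstream purine-context fractions."""
    if window < 1:
        raise ValueError("window must be >= 1")
    ref_seq = reference.sequence if isinstance(reference, Reference) else reference
    ct_num = np.zeros(window)
    ct_den = np.zeros(window)
    ga_num = np.zeros(window)
    ga_den = np.zeros(window)
    for aln in alignments:
        cols = _read_oriented_columns(aln, ref_seq)
        n = len(cols)
        for i in range(min(window, n)):
            ref_b, read_b = cols[i]
            if ref_b == "C":
                ct_den[i] += 1
                if read_b == "T":
                    ct_num[i] += 1
        for j in range(min(window, n)):
            ref_b, read_b = cols[n - 1 - j]
            if ref_b == "G":
                ga_den[j] += 1
                if read_b == "A":
                    ga_num[j] += 1
    circular = reference.circular if isinstance(reference, Reference) else True
    pur_num, pur_den = _upstream_counts(alignments, ref_seq, upstream_span, circular)
    with np.errstate(invalid="ignore", divide="ignore"):
        return DamageProfile(
            ct_5prime=np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), np.nan),
            ga_3prime=np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), np.nan),
            ct_denominator=ct_den.astype(int),
            ga_denominator=ga_den.astype(int),
            purine_upstream=np.where(pur_den > 0, pur_num / np.maximum(pur_den, 1), np.nan),
            purine_denominator=pur_den.astype(int),
            window=window,
        )


def _upstream_counts(alignments, ref_seq: str, span: int, circular: bool):
    L = len(ref_seq)
    num = np.zeros(span)
    den = np.zeros(span)
    for aln in alignments:
        for o in range(1, span + 1):
            if aln.strand == "+":
                p = aln.start - o
                if not circular and p < 0:
                    continue
                base = ref_seq[p % L]
            else:
                p = aln.end - 1 + o
                if not circular and p >= L:
                    continue
                base = _COMP[ref_seq[p % L]]
            den[o - 1] += 1
            if base in "AG":
                num[o - 1] += 1
    return num, den


def purine_excess_upstream(
    alignments: Sequence,
    reference: Reference | str,
    span: int = DEFAULT_UPSTREAM_SPAN,
) -> np.ndarray:
    """Fractions of purines (A/G) at genomic offsets -1..-span before read
    starts, in read orientation; NaN where no reads contribute."""
    ref_seq = reference.sequence if isinstance(reference, Reference) else reference
    circular = reference.circular if isinstance(reference, Reference) else True
    num, den = _upstream_counts(alignments, ref_seq, span, circular)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def write_profile_tsv(profile: DamageProfile, path: str | Path) -> None:
    lines = ["position\tct_5prime\tct_n\tga_3prime\tga_n"]
    for row in profile.to_rows():
        lines.append(
            f"{row['position']}\t{row['ct_5prime']:.6f}\t{row['ct_n']}"
            f"\t{row['ga_3prime']:.6f}\t{row['ga_n']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def plot_profile(profile: DamageProfile, path: str | Path) -> None:
    """Two-panel misincorporation plot (frequency vs terminal position)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    x = np.arange(1, profile.window + 1)
    ax1.plot(x, profile.ct_5prime, color="red", marker=".")
    ax1.set_xlabel("position from 5' end")
    ax1.set_ylabel("C→T frequency")
    ax2.plot(x, profile.ga_3prime, color="blue", marker=".")
    ax2.set_xlabel("position from 3' end")
    ax2.set_ylabel("G→A frequency")
    ax2.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
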