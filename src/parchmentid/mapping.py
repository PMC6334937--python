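"""Seed-and-extend read mapping against a small mitogenome panel.

Reads are seeded by exact k-mer lookup on both strands, seed votes are
accumulated per (reference, strand, diagonal), and the best diagonals are
extended by banded alignment (edlib computes the optimal path inside a
window around the diagonal; the path is rescored with an affine scheme:
match +1, mismatch -1, gap open -3, gap extend -1).  A mapping-quality proxy
``min(60, 4 * (best - second_best))`` stands in for the minimum-mapping-
quality filter (default threshold 30); reads tied between species are
ambiguous and excluded from per-species counts.

Circular references are indexed with the first k-1 bases appended so every
rotation is seeded; reported coordinates are taken modulo the length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .formats import Read, Reference, reverse_complement

DEFAULT_K = 15
DEFAULT_MIN_MAPQ = 30
DEFAULT_SEED_STEP = 5
GAP_OPEN = 3
GAP_EXTEND = 1
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Alignment:
    """One read-to-reference alignment.

    ``start``/``end`` are 0-based half-open reference coordinates; for
    circular references ``end`` may exceed the reference length, meaning the
    alignment wraps (positions are reduced modulo length when consumed).
    ``oriented_sequence`` is the read in reference orientation (reverse-
    complemented for minus-strand hits) so downstream consumers can walk the
    CIGAR directly against the reference.
    """

    read_id: str
    ref_name: str
    species_label: str
    start: int
    end: int
    strand: str
    score: int
    cigar: list[tuple[str, int]]
    oriented_sequence: str
    n_mismatches: int = 0
    mapq: int = 0

    @property
    def ref_span(self) -> int:
        return self.end - self.start


def _affine_score(cigar: list[tuple[str, int]]) -> tuple[int, int]:
    score = 0
    mismatches = 0
    for op, ln in cigar:
        if op == "=":
            score += ln
        elif op == "X":
            score -= ln
            mismatches += ln
        else:  # I or D
            score -= GAP_OPEN + GAP_EXTEND * (ln - 1)
    return score, mismatches


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(ln)) for ln, op in _CIGAR_RE.findall(cigar)]


class KmerIndex:
    """Exact k-mer lookup over a reference panel (forward strand only;
    reverse-complement handled at query time)."""

    def __init__(self, panel: Sequence[Reference], k: int = DEFAULT_K,
                 allow_duplicate_sequences: bool = False):
        if not panel:
            raise ValueError("empty reference panel")
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        names = [ref.name for ref in panel]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names in panel")
        if not allow_duplicate_sequences:
            seqs = [ref.sequence for ref in panel]
            if len(set(seqs)) != len(seqs):
                raise ValueError("identical sequence under two panel names")
        self.k = k
        self.panel = list(panel)
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for ref_i, ref in enumerate(panel):
            seq = ref.sequence + (ref.sequence[: k - 1] if ref.circular else "")
            for pos in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[pos : pos + k], []).append((ref_i, pos))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self._kmers.get(kmer, [])


def mapq_proxy(best_score: int, second_score: int = 0, cap: int = 60) -> int:
    """Mapping-quality proxy: 4x the score gap to the runner-up, capped."""
    if best_score < second_score:
        raise ValueError("best_score must be >= second_score")
    return max(0, min(cap, 4 * (best_score - second_score)))


def _candidate_windows(index: KmerIndex, seq: str, step: int) -> dict[tuple[int, str], list[int]]:
    """Seed both strands, cluster votes by diagonal, return the top diagonal
    clusters per (reference, strand)."""
    k = index.k
    votes: dict[tuple[int, str], dict[int, int]] = {}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(0, len(s) - k + 1, step):
            for ref_i, pos in index.lookup(s[off : off + k]):
                diag = pos - off
                d = votes.setdefault((ref_i, strand), {})
                d[diag] = d.get(diag, 0) + 1
    out: dict[tuple[int, str], list[int]] = {}
    for key, diags in votes.items():
        # merge diagonals within +/-8 (indel slack) into clusters
        clusters: list[tuple[int, int]] = []  # (votes, representative diag)
        for diag in sorted(diags):
            if clusters and diag - clusters[-1][1] <= 8:
                v, rep = clusters[-1]
                clusters[-1] = (v + diags[diag], rep)
            else:
                clusters.append((diags[diag], diag))
        clusters.sort(reverse=True)
        out[key] = [rep for _, rep in clusters[:2]]
    return out


def _extend(ref: Reference, s: str, diag: int, pad: int = 24) -> tuple[int, int, list[tuple[str, int]]] | None:
    """Align oriented read ``s`` inside a window around ``diag``; returns
    (ref_start, ref_end, cigar) in unwrapped coordinates or None."""
    L = len(ref)
    lo = diag - pad
    hi = diag + len(s) + pad
    if ref.circular:
        base = lo % L
        window = (ref.sequence * 2)[base : base + (hi - lo)]
        origin = lo  # unwrapped coordinate of window[0]
    else:
        base = max(0, lo)
        window = ref.sequence[base : min(L, hi)]
        origin = base
    if len(window) < len(s) // 2:
        return None
    res = edlib.align(s, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    cigar = _parse_cigar(res["cigar"])
    if any(op in ("I", "D") for op, _ in cigar):
        # unit-cost path ties resolve differently under affine scoring
        realigned = _affine_realign(s, window)
        if realigned is None:
            return None
        t_start, t_end_excl, cigar = realigned
        t_end = t_end_excl - 1
    else:
        t_start, t_end = res["locations"][0]
    start = origin + t_start
    end = origin + t_end + 1
    if ref.circular:
        start_mod = start % L
        return start_mod, start_mod + (end - start), cigar
    return start, end, cigar


_NEG = -(10**8)


def _affine_realign(q: str, t: str) -> tuple[int, int, list[tuple[str, int]]] | None:
    """Optimal semi-global alignment of query ``q`` inside target ``t``
    under the affine scheme (match +1, mismatch -1, gap open -3, extend -1;
    a gap of length g costs 3 + (g-1)).

    The query is aligned end to end; target overhangs are free.  Used to
    replace the unit-cost edlib path whenever that path contains indels —
    unit cost ties (e.g. a mismatching terminal base written as an
    insertion) are resolved differently under affine scoring, and terminal
    columns must stay aligned for damage profiling.  Returns
    (t_start, t_end_exclusive, cigar).
    """
    m, n = len(q), len(t)
    if m == 0 or n == 0:
        return None
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in query (D)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in target (I)
    M[0, :] = 0  # free start anywhere in the target
    j_idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        Y[i] = np.maximum(M[i - 1] - 3, Y[i - 1] - 1)
        s = np.where(ta == qa[i - 1], 1, -1).astype(np.int32)
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev + s
        M[i, 0] = _NEG
        # X[i,j] = max_{k<j} (M[i,k] + k) - j - 2
        B = M[i] + j_idx
        A = np.empty(n + 1, dtype=np.int32)
        A[0] = _NEG
        np.maximum.accumulate(B[:-1], out=A[1:])
        X[i] = np.maximum(A - j_idx - 2, _NEG)
    end_scores = np.maximum(M[m], Y[m])
    j = int(end_scores.argmax())
    state = "M" if M[m, j] >= Y[m, j] else "Y"
    t_end = j
    ops: list[str] = []
    i = m
    while i > 0:
        if state == "M":
            s = 1 if qa[i - 1] == ta[j - 1] else -1
            ops.append("=" if s == 1 else "X")
            prev_val = M[i, j] - s
            if M[i - 1, j - 1] == prev_val:
                state = "M"
            elif X[i - 1, j - 1] == prev_val:
                state = "X"
            else:
                state = "Y"
            i -= 1
            j -= 1
        elif state == "X":
            ops.append("D")
            if M[i, j - 1] - 3 == X[i, j]:
                state = "M"
            else:
                state = "X"
            j -= 1
        else:  # Y
            ops.append("I")
            if M[i - 1, j] - 3 == Y[i, j]:
                state = "M"
            else:
                state = "Y"
            i -= 1
    t_start = j
    cigar: list[tuple[str, int]] = []
    for op in reversed(ops):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    # drop terminal deletions (free target overhang)
    if cigar and cigar[0][0] == "D":
        t_start += cigar[0][1]
        cigar = cigar[1:]
    if cigar and cigar[-1][0] == "D":
        t_end -= cigar[-1][1]
        cigar = cigar[:-1]
    if not cigar:
        return None
    return t_start, t_end, cigar


def map_read(
    read: Read,
    index: KmerIndex,
    seed_step: int = DEFAULT_SEED_STEP,
) -> list[Alignment]:
    """Map one read; returns candidate alignments sorted by descending score
    (best per distinct location), each with its mapq proxy filled in.

    An unmappable read returns an empty list.
    """
    if len(read) < index.k:
        return []
    candidates = _candidate_windows(index, read.sequence, seed_step)
    seen: set[tuple[int, str, int]] = set()
    alignments: list[Alignment] = []
    for (ref_i, strand), diags in candidates.items():
        ref = index.panel[ref_i]
        s = read.sequence if strand == "+" else reverse_complement(read.sequence)
        for diag in diags:
            ext = _extend(ref, s, diag)
            if ext is None:
                continue
            start, end, cigar = ext
            key = (ref_i, strand, start)
            if key in seen:
                continue
            seen.add(key)
            score, mismatches = _affine_score(cigar)
            alignments.append(
                Alignment(
                    read_id=read.id,
                    ref_name=ref.name,
                    species_label=ref.species_label,
                    start=start,
                    end=end,
                    strand=strand,
                    score=score,
                    cigar=cigar,
                    oriented_sequence=s,
                    n_mismatches=mismatches,
                )
            )
    alignments.sort(key=lambda a: (-a.score, a.ref_name, a.start))
    if alignments:
        second = alignments[1].score if len(alignments) > 1 else 0
        alignments[0].mapq = mapq_proxy(alignments[0].score, max(0, second))
        for aln in alignments[1:]:
            aln.mapq = 0
    return alignments


def competitive_assign(alignments: list[Alignment]) -> str | None:
    """Assign a read to the species of its highest-scoring alignment.

    A score tie across species is ambiguous (``None``); a within-species tie
    is broken by the lowest reference coordinate (already the sort order).
    """
    if not alignments:
        return None
    best = alignments[0]
    for other in alignments[1:]:
        if other.score < best.score:
            break
        if other.species_label != best.species_label:
            return None
    return best.species_label


@dataclass
class MappingSummary:
    """Read accounting from competitive mapping of one library."""

    assigned: dict[str, list[Alignment]] = field(default_factory=dict)
    species_counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_low_mapq: int = 0


def map_library(
    reads: Iterable[Read],
    index: KmerIndex,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    seed_step: int = DEFAULT_SEED_STEP,
) -> MappingSummary:
    """Competitively map a read set; keep best alignments passing the mapq
    filter, grouped by assigned species."""
    out = MappingSummary()
    out.species_counts = {ref.species_label: 0 for ref in index.panel}
    for read in reads:
        out.n_input += 1
        alignments = map_read(read, index, seed_step)
        if not alignments:
            out.n_unmapped += 1
            continue
        species = competitive_assign(alignments)
        if species is None:
            out.n_ambiguous += 1
            continue
        best = alignments[0]
        if best.mapq < min_mapq:
            out.n_low_mapq += 1
            continue
        out.assigned.setdefault(species, []).append(best)
        out.species_counts[species] = out.species_counts.get(species, 0) + 1
    return out


@dataclass
class IterativeMapResult:
    alignments: list[Alignment]
    template: str
    n_iterations: int
    per_iteration_changes: list[int]


def iterative_remap(
    reads: Sequence[Read],
    reference: Reference,
    iterations: int = 5,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    k: int = DEFAULT_K,
    min_depth: int = 3,
    seed_step: int = DEFAULT_SEED_STEP,
) -> IterativeMapResult:
    """Map -> call a substitution-only consensus -> remap against it.

    The template is updated with majority substitutions only, keeping
    coordinates identical to the input reference throughout; it converges
    (and stops early) when an iteration changes nothing.  The final
    alignments are those of the last mapping pass, in reference coordinates.
    """
    from .variants import Pileup  # local import to avoid a cycle

    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    template = reference.sequence
    changes: list[int] = []
    alignments: list[Alignment] = []
    mapped_template = template
    for it in range(iterations):
        mapped_template = template
        ref = Reference(reference.name, reference.species_label, template,
                        circular=reference.circular, role=reference.role)
        index = KmerIndex([ref], k=k)
        alignments = []
        for read in reads:
            alns = map_read(read, index, seed_step)
            if alns and alns[0].mapq >= min_mapq:
                alignments.append(alns[0])
        pileup = Pileup.build(alignments, template, circular=reference.circular)
        new_template, n_changed = _update_template(pileup, template, min_depth)
        changes.append(n_changed)
        if n_changed == 0 or it == iterations - 1:
            break
        template = new_template
    return IterativeMapResult(
        alignments=alignments,
        template=mapped_template,
        n_iterations=len(changes),
        per_iteration_changes=changes,
    )


def _update_template(pileup, template: str, min_depth: int) -> tuple[str, int]:
    seq = list(template)
    n_changed = 0
    for i in range(len(seq)):
        counts = pileup.base_counts(i)
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        best = max(sorted(counts), key=lambda b: counts[b])
        if counts[best] * 2 > depth and best != seq[i]:
            seq[i] = best
            n_changed += 1
    return "".join(seq), n_changed
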