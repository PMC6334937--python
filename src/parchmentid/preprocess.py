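"""Read cleaning: quality trimming, length filtering, pair merging, dedup.

The stage order is fixed — trim both ends, drop short reads, merge mates by
overlap, collapse exact duplicates.  Adapter removal falls out of the merge:
when the detected overlap implies a fragment shorter than the read length
(read-through), everything outside the overlap is adapter and is clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import Read, reverse_complement

DEFAULT_Q_THRESHOLD = 20
DEFAULT_MIN_LENGTH = 30
DEFAULT_MIN_OVERLAP = 11
DEFAULT_MAX_MISMATCH_FRAC = 0.1


def quality_trim(read: Read, q_threshold: int = DEFAULT_Q_THRESHOLD) -> Read:
    """Remove the maximal low-quality prefix and suffix; interior untouched."""
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    quals = read.qualities
    start, end = 0, len(quals)
    while start < end and quals[start] < q_threshold:
        start += 1
    while end > start and quals[end - 1] < q_threshold:
        end -= 1
    if start == 0 and end == len(quals):
        return read
    return Read(read.id, read.sequence[start:end], quals[start:end], merged=read.merged)


def length_filter(reads: list[Read], min_len: int = DEFAULT_MIN_LENGTH) -> tuple[list[Read], int]:
    """Keep reads of length >= ``min_len``; return (kept, n_discarded)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in reads if len(r) >= min_len]
    return kept, len(reads) - len(kept)


def merge_pairs(
    r1: Read,
    r2: Read,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> Read | None:
    """Overlap-merge a mate pair; ``None`` when no acceptable overlap exists.

    The second mate is reverse-complemented, then slid against the first over
    every relative offset with at least ``min_overlap`` overlapping bases.
    The best-matching offset wins if its overlap mismatch fraction is within
    ``max_mismatch_frac``.  A non-negative offset means the fragment is
    longer than one read (merged length = |r1| + |r2| - overlap); a negative
    offset means adapter read-through, and only the overlap region (the
    fragment itself) is kept.  Disagreeing overlap bases take the base with
    the higher quality.
    """
    s1, q1 = r1.sequence, r1.qualities
    s2 = reverse_complement(r2.sequence)
    q2 = r2.qualities[::-1]
    n1, n2 = len(s1), len(s2)
    if min(n1, n2) < min_overlap:
        return None

    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    best = None  # ((score, overlap, -|offset|), offset, overlap, mismatches)
    for offset in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo = max(0, offset)
        hi = min(n1, offset + n2)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        matches = int(np.count_nonzero(a1[lo:hi] == a2[lo - offset : hi - offset]))
        mism = overlap - matches
        cand = (matches - 4 * mism, overlap, -abs(offset))
        if best is None or cand > best[0]:
            best = (cand, offset, overlap, mism)
    if best is None:
        return None
    _, offset, overlap, mismatches = best
    if mismatches > max_mismatch_frac * overlap:
        return None

    lo = max(0, offset)
    hi = min(n1, offset + n2)
    mid_seq, mid_q = [], []
    for i in range(lo, hi):
        b1, b2 = s1[i], s2[i - offset]
        qa, qb = q1[i], q2[i - offset]
        if b1 == b2:
            mid_seq.append(b1)
            mid_q.append(max(qa, qb))
        elif qa >= qb:
            mid_seq.append(b1)
            mid_q.append(qa)
        else:
            mid_seq.append(b2)
            mid_q.append(qb)
    if offset >= 0:
        seq = s1[:lo] + "".join(mid_seq) + s2[hi - offset :]
        quals = q1[:lo] + mid_q + q2[hi - offset :]
    else:  # read-through: clip adapter tails on both sides
        seq = "".join(mid_seq)
        quals = mid_q
    return Read(r1.id.removesuffix("/1"), seq, quals, merged=True)


def deduplicate(reads: list[Read]) -> tuple[list[Read], int]:
    """Collapse exact-sequence duplicates, keeping the first representative."""
    seen: set[str] = set()
    out: list[Read] = []
    for read in reads:
        if read.sequence not in seen:
            seen.add(read.sequence)
            out.append(read)
    return out, len(reads) - len(out)


@dataclass
class PreprocessResult:
    reads: list[Read]
    counts: dict[str, int] = field(default_factory=dict)


def preprocess_pairs(
    pairs: list[tuple[Read, Read]],
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    min_len: int = DEFAULT_MIN_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> PreprocessResult:
    """Full cleaning pipeline: trim -> length filter -> merge -> dedupe.

    Mates that fail the length filter are dropped individually; a pair with
    one survivor keeps that survivor unmerged.  Unmergeable surviving pairs
    contribute both mates as single reads (flagged unmerged).
    """
    counts = {"raw_pairs": len(pairs), "short_discarded": 0, "merged": 0,
              "unmerged": 0, "duplicates_removed": 0}
    pooled: list[Read] = []
    for r1, r2 in pairs:
        t1 = quality_trim(r1, q_threshold)
        t2 = quality_trim(r2, q_threshold)
        kept, dropped = length_filter([t1, t2], min_len)
        counts["short_discarded"] += dropped
        if len(kept) == 2:
            merged = merge_pairs(kept[0], kept[1], min_overlap, max_mismatch_frac)
            if merged is not None and len(merged) >= min_len:
                counts["merged"] += 1
                pooled.append(merged)
            else:
                counts["unmerged"] += 1
                pooled.extend(kept)
        else:
            counts["unmerged"] += len(kept)
            pooled.extend(kept)
    unique, removed = deduplicate(pooled)
    counts["duplicates_removed"] = removed
    counts["reads_out"] = len(unique)
    return PreprocessResult(reads=unique, counts=counts)
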