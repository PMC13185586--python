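"""Ungapped alignment of short inserts against a small (<= a few kb) reference.

Strategy: exact k-mer seeding (default k=12) proposes candidate diagonals;
candidates are scored by mismatch count.  If the best seeded candidate is not
an exact match, an exhaustive scan over every offset (both strands, all
segments) guarantees the reported placement is the global mismatch-count
optimum.  This is affordable because references here are tiny, and it keeps
the contract simple: best ungapped placement, ties broken by segment order,
then leftmost coordinate, then sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reference import BASE_ORDER, GenomeReference, encode_bases, revcomp


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped placement of a read insert on the reference.

    ``start``/``end`` are 1-based inclusive.  ``mismatches`` holds
    ``(position, base)`` pairs where ``base`` is the read base expressed in
    the *sense* orientation (antisense reads are complemented), so pileup
    construction never needs to re-orient bases.
    """

    segment_id: str
    start: int
    end: int
    strand: str  # '+' (sense) or '-' (antisense)
    mismatches: tuple[tuple[int, str], ...] = ()
    mate: int = 0  # 1, 2, or 0 when unknown
    umi: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' terminus."""
        return self.end if self.strand == "-" else self.start


class ReferenceIndex:
    """k-mer seed index over the sense strand of every segment."""

    def __init__(self, reference: GenomeReference, k: int = 12):
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.reference = reference
        self.k = k
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for seg_idx, (sid, seq) in enumerate(reference):
            for off in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[off : off + k], []).append((seg_idx, off))

    def seed_hits(self, kmer: str) -> list[tuple[int, int]]:
        return self._seeds.get(kmer, [])


def _score_candidate(
    enc_query: np.ndarray, enc_ref: np.ndarray, start0: int
) -> tuple[int, np.ndarray]:
    window = enc_ref[start0 : start0 + len(enc_query)]
    diff = np.nonzero(window != enc_query)[0]
    return len(diff), diff


def _full_scan_best(
    enc_query: np.ndarray, enc_ref: np.ndarray
) -> tuple[int, int] | None:
    """(best_start0, mismatches) over all offsets, leftmost on ties."""
    m = len(enc_query)
    if len(enc_ref) < m:
        return None
    windows = sliding_window_view(enc_ref, m)
    counts = (windows != enc_query).sum(axis=1)
    best = int(counts.argmin())  # argmin is leftmost on ties
    return best, int(counts[best])


def align_insert(
    insert: str,
    index: ReferenceIndex,
    max_mismatch_frac: float = 0.1,
    *,
    try_both_strands: bool = True,
) -> Optional[AlignmentRecord]:
    """Best ungapped placement of ``insert``; ``None`` if unalignable.

    A placement is rejected when its mismatch fraction exceeds
    ``max_mismatch_frac`` or the insert is shorter than the seed length.
    """
    m = len(insert)
    k = index.k
    if m < k:
        return None
    reference = index.reference
    seg_ids = reference.segment_ids

    strands = [("+", insert)]
    if try_both_strands:
        strands.append(("-", revcomp(insert)))

    # key: (mismatches, seg_idx, start0, strand_rank) -- lower is better
    best_key: tuple[int, int, int, int] | None = None
    best_payload: tuple[str, int, np.ndarray, str] | None = None

    def consider(mm: int, seg_idx: int, start0: int, strand_rank: int,
                 strand: str, oriented: str, diff: np.ndarray) -> None:
        nonlocal best_key, best_payload
        key = (mm, seg_idx, start0, strand_rank)
        if best_key is None or key < best_key:
            best_key = key
            best_payload = (seg_ids[seg_idx], start0, diff, oriented)

    seed_offsets = sorted({0, max(0, (m - k) // 2), m - k})
    for strand_rank, (strand, oriented) in enumerate(strands):
        enc_q = encode_bases(oriented)
        seen: set[tuple[int, int]] = set()
        for off in seed_offsets:
            for seg_idx, hit in index.seed_hits(oriented[off : off + k]):
                start0 = hit - off
                enc_ref = reference.encoded(seg_ids[seg_idx])
                if start0 < 0 or start0 + m > len(enc_ref):
                    continue
                if (seg_idx, start0) in seen:
                    continue
                seen.add((seg_idx, start0))
                mm, diff = _score_candidate(enc_q, enc_ref, start0)
                consider(mm, seg_idx, start0, strand_rank, strand, oriented, diff)

    # Exhaustive fallback whenever seeding did not find a perfect match:
    # guarantees the reported placement is the global optimum.
    if best_key is None or best_key[0] > 0:
        for strand_rank, (strand, oriented) in enumerate(strands):
            enc_q = encode_bases(oriented)
            for seg_idx, sid in enumerate(seg_ids):
                hit = _full_scan_best(enc_q, reference.encoded(sid))
                if hit is None:
                    continue
                start0, mm = hit
                _, diff = _score_candidate(enc_q, reference.encoded(sid), start0)
                consider(mm, seg_idx, start0, strand_rank, strand, oriented, diff)

    if best_key is None:
        return None
    mm = best_key[0]
    if mm / m > max_mismatch_frac:
        return None
    sid, start0, diff, oriented = best_payload
    strand = "+" if best_key[3] == 0 else "-"
    mismatches = tuple(
        (start0 + int(i) + 1, oriented[int(i)]) for i in diff
    )
    return AlignmentRecord(
        segment_id=sid,
        start=start0 + 1,
        end=start0 + m,
        strand=strand,
        mismatches=mismatches,
    )
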