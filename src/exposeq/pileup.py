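"""UMI deduplication and per-position base-count pileups.

Deduplication keeps exactly one molecule per distinct
``(segment, priming-anchor coordinate, UMI)`` key, the anchor being the
genomic coordinate of the trimmed R2 read's 5' terminus.  Pileups count
read bases in the sense orientation; antisense alignments contribute their
complements (already applied when the alignment was produced, see
:class:`exposeq.align.AlignmentRecord`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .reference import BASE_ORDER, GenomeReference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedPair:
    """Both mates of one processed read pair (either may be unaligned)."""

    umi: str
    r1: Optional[AlignmentRecord] = None
    r2: Optional[AlignmentRecord] = None

    def dedup_key(self) -> tuple[str, int, str] | None:
        """(segment, R2 5' genomic coordinate, UMI); None without an R2."""
        if self.r2 is None:
            return None
        return (self.r2.segment_id, self.r2.five_prime(), self.umi)

    @property
    def anchor(self) -> int | None:
        return None if self.r2 is None else self.r2.five_prime()


def dedup(pairs: Iterable[AlignedPair]) -> list[AlignedPair]:
    """One retained molecule per distinct dedup key, first-encountered wins.

    Pairs without an R2 alignment carry no key and are dropped (counted by
    the caller via the difference in lengths).
    """
    seen: set[tuple[str, int, str]] = set()
    retained: list[AlignedPair] = []
    for pair in pairs:
        key = pair.dedup_key()
        if key is None:
            continue
        if key not in seen:
            seen.add(key)
            retained.append(pair)
    return retained


@dataclass(frozen=True)
class CoverageBlock:
    """A contiguous covered interval with sparse base substitutions."""

    segment_id: str
    start: int
    end: int
    mismatches: tuple[tuple[int, str], ...] = ()


def merge_pair(pair: AlignedPair) -> list[CoverageBlock]:
    """Merge both mates of a molecule into non-double-counted blocks.

    On overlap R1 takes precedence (its base calls win); if the two mates
    land on different segments the pair is treated as discordant and only
    R2 (the anchor-bearing mate) is kept.
    """
    r1, r2 = pair.r1, pair.r2
    records = [r for r in (r1, r2) if r is not None]
    if not records:
        return []
    if len(records) == 1 or r1.segment_id != r2.segment_id:
        r = records[-1]
        return [CoverageBlock(r.segment_id, r.start, r.end, r.mismatches)]

    lo = min(r1.start, r2.start)
    hi = max(r1.end, r2.end)
    mism: dict[int, str] = {}
    for pos, base in r2.mismatches:
        if not (r1.start <= pos <= r1.end):  # R1 wins inside its own span
            mism[pos] = base
    for pos, base in r1.mismatches:
        mism[pos] = base

    if r2.end + 1 < r1.start or r1.end + 1 < r2.start:
        # fragment longer than both reads: keep the two covered blocks
        blocks = []
        for r in (r1, r2):
            mm = tuple((p, b) for p, b in sorted(mism.items()) if r.start <= p <= r.end)
            blocks.append(CoverageBlock(r.segment_id, r.start, r.end, mm))
        return blocks
    return [CoverageBlock(r1.segment_id, lo, hi, tuple(sorted(mism.items())))]


@dataclass
class PileupMatrix:
    """Per-segment position x {A,C,G,T,N} count tables.

    ``counts[sid]`` has shape ``(5, L)`` in :data:`exposeq.reference.BASE_ORDER`
    order; depth is the column sum.
    """

    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, reference: GenomeReference) -> "PileupMatrix":
        return cls(
            {sid: np.zeros((5, L), dtype=np.int64) for sid, L in reference.lengths.items()}
        )

    def depth(self, segment_id: str) -> np.ndarray:
        return self.counts[segment_id].sum(axis=0)

    def base_count(self, segment_id: str, base: str) -> np.ndarray:
        return self.counts[segment_id][BASE_ORDER.index(base)]

    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def total_depth(self, segment_id: str) -> int:
        return int(self.depth(segment_id).sum())

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path) -> None:
        frames = []
        for sid, mat in self.counts.items():
            df = pd.DataFrame(mat.T, columns=list(BASE_ORDER))
            df.insert(0, "position", np.arange(1, mat.shape[1] + 1))
            df.insert(0, "segment", sid)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PileupMatrix":
        df = pd.read_csv(path, sep="\t")
        counts = {}
        for sid, sub in df.groupby("segment", sort=False):
            sub = sub.sort_values("position")
            counts[sid] = sub[list(BASE_ORDER)].to_numpy().T.astype(np.int64)
        return cls(counts)


def build_pileup(
    blocks: Iterable[CoverageBlock | AlignmentRecord],
    reference: GenomeReference,
) -> PileupMatrix:
    """Accumulate base counts from coverage blocks or alignment records.

    Every covered position contributes the reference base unless overridden
    by a recorded mismatch.  Out-of-bounds blocks indicate corrupt input and
    raise.
    """
    pile = PileupMatrix.zeros(reference)
    # depth via interval difference arrays, then sparse mismatch corrections
    diffs = {sid: np.zeros(L + 1, dtype=np.int64) for sid, L in reference.lengths.items()}
    corrections: dict[str, dict[int, dict[str, int]]] = {
        sid: {} for sid in reference.segment_ids
    }
    for blk in blocks:
        sid = blk.segment_id
        if sid not in diffs:
            raise ValueError(f"pileup block on unknown segment {sid!r}")
        L = reference.length(sid)
        if blk.start < 1 or blk.end > L:
            raise ValueError(
                f"alignment {sid}:{blk.start}-{blk.end} outside segment bounds 1-{L}"
            )
        diffs[sid][blk.start - 1] += 1
        diffs[sid][blk.end] -= 1
        if blk.mismatches:
            seg_corr = corrections[sid]
            for pos, base in blk.mismatches:
                if not (blk.start <= pos <= blk.end):
                    raise ValueError(
                        f"mismatch at {sid}:{pos} outside block {blk.start}-{blk.end}"
                    )
                seg_corr.setdefault(pos, {}).setdefault(base, 0)
                seg_corr[pos][base] += 1

    for sid in reference.segment_ids:
        depth = np.cumsum(diffs[sid][:-1])
        ref_idx = reference.encoded(sid)
        mat = pile.counts[sid]
        np.add.at(mat, (ref_idx, np.arange(len(ref_idx))), depth)
        for pos, by_base in corrections[sid].items():
            total = sum(by_base.values())
            mat[ref_idx[pos - 1], pos - 1] -= total
            for base, n in by_base.items():
                mat[BASE_ORDER.index(base), pos - 1] += n
        if (mat < 0).any():
            raise AssertionError("negative pileup count: inconsistent mismatches")
    return pile


def pileup_from_pairs(
    pairs: Sequence[AlignedPair], reference: GenomeReference
) -> PileupMatrix:
    """Molecule-level pileup: mates merged so overlap is counted once."""
    blocks: list[CoverageBlock] = []
    for pair in pairs:
        blocks.extend(merge_pair(pair))
    return build_pileup(blocks, reference)
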