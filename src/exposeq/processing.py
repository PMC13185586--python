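"""End-to-end read processing: FASTQ pair -> deduplicated molecules + pileup."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .align import ReferenceIndex, align_insert
from .fastqio import extract_umi_and_trim, parse_fastq_pair
from .pileup import AlignedPair, PileupMatrix, dedup, pileup_from_pairs
from .reference import GenomeReference

logger = logging.getLogger(__name__)


@dataclass
class ProcessStats:
    """Per-stage counters; parsed == dropped_short + unaligned + aligned."""

    parsed: int = 0
    dropped_short: int = 0
    unaligned: int = 0
    aligned: int = 0
    retained: int = 0
    duplicates: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def check_conservation(self) -> None:
        if self.parsed != self.dropped_short + self.unaligned + self.aligned:
            raise AssertionError(f"read accounting violated: {self.as_dict()}")


@dataclass
class ProcessResult:
    molecules: list[AlignedPair]
    pileup: PileupMatrix
    stats: ProcessStats
    index: ReferenceIndex = field(repr=False, default=None)


def process_fastq_pair(
    r1_path: Path,
    r2_path: Path,
    reference: GenomeReference,
    *,
    umi_length: int = 12,
    umi_offset: int = 0,
    r2_trim: int = 7,
    max_mismatch_frac: float = 0.1,
    seed_k: int = 12,
    index: Optional[ReferenceIndex] = None,
) -> ProcessResult:
    """Parse, trim, align, deduplicate and pile up one paired library.

    A pair counts as *aligned* when its anchor-bearing R2 insert aligns;
    the R1 insert is aligned opportunistically and merged into coverage
    when it lands on the same segment.
    """
    if index is None:
        index = ReferenceIndex(reference, k=seed_k)
    stats = ProcessStats()
    aligned_pairs: list[AlignedPair] = []
    for pair in parse_fastq_pair(r1_path, r2_path):
        stats.parsed += 1
        processed = extract_umi_and_trim(
            pair, umi_length=umi_length, umi_offset=umi_offset, r2_trim=r2_trim
        )
        if processed is None:
            stats.dropped_short += 1
            continue
        rec2 = align_insert(processed.r2_insert, index, max_mismatch_frac)
        if rec2 is None:
            stats.unaligned += 1
            continue
        rec1 = align_insert(processed.r1_insert, index, max_mismatch_frac)
        stats.aligned += 1
        aligned_pairs.append(
            AlignedPair(
                umi=processed.umi,
                r1=None if rec1 is None else _with_mate(rec1, 1, processed.umi),
                r2=_with_mate(rec2, 2, processed.umi),
            )
        )
    molecules = dedup(aligned_pairs)
    stats.retained = len(molecules)
    stats.duplicates = stats.aligned - stats.retained
    stats.check_conservation()
    pile = pileup_from_pairs(molecules, reference)
    logger.info("processed %s: %s", r1_path, stats.as_dict())
    return ProcessResult(molecules=molecules, pileup=pile, stats=stats, index=index)


def _with_mate(record, mate: int, umi: str):
    from dataclasses import replace

    return replace(record, mate=mate, umi=umi)
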