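"""Paired FASTQ parsing, UMI extraction and prefix trimming."""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    name: str
    mate: int
    sequence: str
    quality: Optional[str] = None


@dataclass(frozen=True)
class ProcessedPair:
    """A read pair after UMI extraction and R2 prefix trimming."""

    name: str
    umi: str
    r1_insert: str
    r2_insert: str


class FastqPairError(ValueError):
    pass


def _open_text(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _base_name(title: str) -> str:
    name = title.split()[0]
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def parse_fastq_pair(
    r1_path: Path, r2_path: Path
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Stream mate-paired records from two FASTQ files in matched order.

    A name mismatch or a missing mate is a hard error carrying the record
    index; empty files yield an empty stream with a warning.
    """
    count = 0
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for idx, (rec1, rec2) in enumerate(zip_longest(it1, it2)):
            if rec1 is None or rec2 is None:
                which = r1_path if rec1 is None else r2_path
                raise FastqPairError(
                    f"mate files of unequal length: {which} ended at record {idx}"
                )
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            n1, n2 = _base_name(t1), _base_name(t2)
            if n1 != n2:
                raise FastqPairError(
                    f"mate name mismatch at record {idx}: {n1!r} vs {n2!r}"
                )
            yield (
                ReadRecord(n1, 1, s1.upper(), q1),
                ReadRecord(n2, 2, s2.upper(), q2),
            )
            count += 1
    if count == 0:
        logger.warning("empty FASTQ pair: %s / %s", r1_path, r2_path)


def extract_umi_and_trim(
    pair: tuple[ReadRecord, ReadRecord],
    umi_length: int = 12,
    umi_offset: int = 0,
    r2_trim: int = 7,
) -> Optional[ProcessedPair]:
    """Split the UMI off R1 and remove the R2 hexamer+buffer prefix.

    The UMI is taken verbatim (N bases included).  Returns ``None`` when
    either read is too short to leave a non-empty insert; callers count
    these drops.
    """
    r1, r2 = pair
    head = umi_offset + umi_length
    if len(r1.sequence) <= head or len(r2.sequence) <= r2_trim:
        return None
    umi = r1.sequence[umi_offset:head]
    return ProcessedPair(
        name=r1.name,
        umi=umi,
        r1_insert=r1.sequence[head:],
        r2_insert=r2.sequence[r2_trim:],
    )
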