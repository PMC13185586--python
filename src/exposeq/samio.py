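"""SAM import/export for interoperability with external aligners.

Only ungapped primary alignments are representable: records whose CIGAR
contains indels or reference skips are rejected (and counted) on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .align import AlignmentRecord
from .pileup import AlignedPair
from .reference import GenomeReference, revcomp

logger = logging.getLogger(__name__)

_ALLOWED_OPS = {0, 7, 8}  # M, =, X
_CLIP_OPS = {4, 5}  # S, H


class SamIngestError(ValueError):
    pass


@dataclass
class IngestStats:
    parsed: int = 0
    converted: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_indel: int = 0


def _reconstruct_seq(record: AlignmentRecord, reference: GenomeReference) -> str:
    """Forward-strand sequence implied by span + mismatch list."""
    seq = list(reference.sequence(record.segment_id)[record.start - 1 : record.end])
    for pos, base in record.mismatches:
        seq[pos - record.start] = base
    return "".join(seq)


def write_sam(
    pairs: Sequence[AlignedPair], reference: GenomeReference, path: Path
) -> int:
    """Write aligned pairs as a text SAM file; returns records written."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": sid, "LN": L} for sid, L in reference.lengths.items()],
    }
    tid = {sid: i for i, sid in enumerate(reference.segment_ids)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, pair in enumerate(pairs):
            for mate, record in ((1, pair.r1), (2, pair.r2)):
                if record is None:
                    continue
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = f"pair{i:07d}_{pair.umi}"
                seg.reference_id = tid[record.segment_id]
                seg.reference_start = record.start - 1
                seg.mapping_quality = 60
                fwd = _reconstruct_seq(record, reference)
                seg.query_sequence = fwd  # SAM stores forward-strand sequence
                seg.cigarstring = f"{record.span}M"
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if record.strand == "-":
                    flag |= 0x10
                seg.flag = flag
                seg.set_tag("RX", pair.umi)
                seg.set_tag("NM", len(record.mismatches))
                out.write(seg)
                n += 1
    return n


def ingest_sam(
    path: Path,
    reference: GenomeReference,
    *,
    umi_source: str = "tag",  # 'tag' (RX) or 'name' (suffix after umi_sep)
    umi_sep: str = "_",
) -> tuple[list[AlignedPair], IngestStats]:
    """Convert primary, mapped, ungapped SAM records into aligned pairs.

    The header must declare exactly the reference's segment names and
    lengths.  Mates are paired by query name; UMIs come from the RX tag or
    the read-name suffix.
    """
    stats = IngestStats()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        names = list(sam.references)
        lengths = list(sam.lengths)
        expected = reference.lengths
        if dict(zip(names, lengths)) != expected:
            raise SamIngestError(
                f"SAM header {dict(zip(names, lengths))} does not match "
                f"reference {expected}"
            )
        by_name: dict[str, dict[int, AlignmentRecord]] = {}
        umis: dict[str, str] = {}
        order: list[str] = []
        for rec in sam:
            stats.parsed += 1
            if rec.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.skipped_secondary += 1
                continue
            ops = {op for op, _ in (rec.cigartuples or ())}
            if not ops <= (_ALLOWED_OPS | _CLIP_OPS):
                stats.skipped_indel += 1
                continue
            sid = rec.reference_name
            start = rec.reference_start + 1
            aligned = rec.query_alignment_sequence.upper()
            end = start + len(aligned) - 1
            if end > reference.length(sid):
                raise SamIngestError(
                    f"record {rec.query_name} extends past segment {sid}"
                )
            ref_slice = reference.sequence(sid)[start - 1 : end]
            mismatches = tuple(
                (start + i, aligned[i])
                for i in range(len(aligned))
                if aligned[i] != ref_slice[i]
            )
            mate = 2 if rec.is_read2 else 1
            record = AlignmentRecord(
                segment_id=sid,
                start=start,
                end=end,
                strand="-" if rec.is_reverse else "+",
                mismatches=mismatches,
                mate=mate,
            )
            name = rec.query_name
            if umi_source == "tag" and rec.has_tag("RX"):
                umi = rec.get_tag("RX")
            else:
                umi = name.rsplit(umi_sep, 1)[-1]
            if name not in by_name:
                by_name[name] = {}
                order.append(name)
                umis[name] = umi
            by_name[name][mate] = record
            stats.converted += 1

    pairs = [
        AlignedPair(umi=umis[name], r1=by_name[name].get(1), r2=by_name[name].get(2))
        for name in order
    ]
    return pairs, stats
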