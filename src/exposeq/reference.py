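"""Genome references and region coordinates.

Coordinates are 1-based inclusive everywhere inside the package; conversion
to 0-based half-open happens only at bedGraph boundaries (see
:mod:`exposeq.exposure`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_STRICT_ALPHABET = frozenset("ACGT")
_INGEST_ALPHABET = frozenset("ACGTN")

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")

#: integer encoding used for pileups and alignment: A=0 C=1 G=2 T=3 N=4
BASE_ORDER = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_bases(seq: str) -> np.ndarray:
    """Encode a base string into uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True, order=True)
class Region:
    """A 1-based inclusive interval on one reference segment."""

    segment_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid region {self.segment_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``"SEG:start-end"`` notation, e.g. ``"RNA1:26-75"``."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected 'SEG:start-end'")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))

    def __str__(self) -> str:
        return f"{self.segment_id}:{self.start}-{self.end}"

    def slice0(self) -> slice:
        """0-based slice covering the region."""
        return slice(self.start - 1, self.end)


class GenomeReference:
    """An ordered collection of named reference segments.

    Parameters
    ----------
    segments:
        Sequence of ``(segment_id, sequence)`` pairs.  Sequences must be
        uppercase over ``ACGT``; ``allow_n=True`` additionally admits ``N``
        (used when ingesting externally produced references).
    """

    def __init__(self, segments: Sequence[tuple[str, str]], *, allow_n: bool = False):
        if not segments:
            raise ValueError("reference must contain at least one segment")
        alphabet = _INGEST_ALPHABET if allow_n else _STRICT_ALPHABET
        seen: set[str] = set()
        cooked: list[tuple[str, str]] = []
        for seg_id, seq in segments:
            if seg_id in seen:
                raise ValueError(f"duplicate segment id {seg_id!r}")
            seen.add(seg_id)
            if len(seq) < 100:
                raise ValueError(
                    f"segment {seg_id!r} is {len(seq)} nt; minimum is 100"
                )
            bad = set(seq) - alphabet
            if bad:
                raise ValueError(
                    f"segment {seg_id!r} contains invalid characters {sorted(bad)}"
                )
            cooked.append((seg_id, seq))
        self._segments: tuple[tuple[str, str], ...] = tuple(cooked)
        self._by_id: dict[str, str] = dict(cooked)
        self._encoded: dict[str, np.ndarray] = {
            sid: encode_bases(seq) for sid, seq in cooked
        }

    # -- accessors ---------------------------------------------------------
    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self._segments)

    def sequence(self, segment_id: str) -> str:
        try:
            return self._by_id[segment_id]
        except KeyError:
            raise KeyError(f"unknown segment {segment_id!r}") from None

    def encoded(self, segment_id: str) -> np.ndarray:
        """uint8-encoded sequence (see :func:`encode_bases`)."""
        return self._encoded[segment_id]

    def length(self, segment_id: str) -> int:
        return len(self.sequence(segment_id))

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self._segments}

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._segments)

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def __len__(self) -> int:
        return len(self._segments)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeReference) and self._segments == other._segments

    # -- validation --------------------------------------------------------
    def check_region(self, region: Region) -> Region:
        """Validate a region against segment bounds; returns the region."""
        if region.segment_id not in self._by_id:
            raise ValueError(f"region {region}: unknown segment {region.segment_id!r}")
        L = self.length(region.segment_id)
        if region.end > L:
            raise ValueError(
                f"region {region} exceeds segment length {L} of {region.segment_id!r}"
            )
        return region

    # -- construction ------------------------------------------------------
    @classmethod
    def from_fasta(cls, path, *, allow_n: bool = True) -> "GenomeReference":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records, allow_n=allow_n)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in self._segments
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def random(
        cls,
        lengths: Mapping[str, int],
        rng: np.random.Generator,
        base_probs: Sequence[float] | None = None,
    ) -> "GenomeReference":
        """Draw i.i.d. random segments (``base_probs`` over A,C,G,T)."""
        probs = np.asarray(base_probs if base_probs is not None else [0.25] * 4, float)
        if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("base_probs must be 4 probabilities summing to 1")
        segs = []
        bases = np.array(list("ACGT"))
        for sid, L in lengths.items():
            seq = "".join(bases[rng.choice(4, size=int(L), p=probs)])
            segs.append((sid, seq))
        return cls(segs)
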