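"""Crosslink-induced U->C transition statistics.

Transitions are counted only at reference-T positions, on the sense
orientation, from deduplicated pileups.  Positions below the depth
threshold are masked (never zero-filled) and masked positions are excluded
from every downstream statistic.  The per-position signal is the fold
change of the mean transition rate between crosslinked (CL+) and control
(CL-) libraries, stabilized with a pseudocount of ``1/min_depth`` (one
read-equivalent at the masking threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pileup import PileupMatrix
from .reference import BASE_ORDER, GenomeReference

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 1000


@dataclass
class TransitionSegment:
    positions: np.ndarray  # 1-based reference-T positions
    depth: np.ndarray
    c_count: np.ndarray
    masked: np.ndarray  # True where depth < min_depth

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.depth > 0, self.c_count / np.maximum(self.depth, 1), 0.0)
        return r


@dataclass
class TransitionTable:
    """Per-U-position transition rates for one sample."""

    segments: dict[str, TransitionSegment]
    condition: str = "CL-"
    label: str = ""
    replicate: int = 0
    min_depth: int = DEFAULT_MIN_DEPTH

    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(self.segments)

    def unmasked_rates(self, segment_id: str | None = None) -> np.ndarray:
        segs = [segment_id] if segment_id else list(self.segments)
        parts = [
            self.segments[s].rate[~self.segments[s].masked] for s in segs
        ]
        return np.concatenate(parts) if parts else np.array([])


def transition_rates(
    pileup: PileupMatrix,
    reference: GenomeReference,
    min_depth: int = DEFAULT_MIN_DEPTH,
    *,
    condition: str = "CL-",
    label: str = "",
    replicate: int = 0,
) -> TransitionTable:
    """Compute C/depth at every reference-T position of a deduplicated pileup."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    segments = {}
    t_row = BASE_ORDER.index("T")
    c_row = BASE_ORDER.index("C")
    for sid in reference.segment_ids:
        if sid not in pileup.counts:
            raise ValueError(f"pileup lacks segment {sid!r}")
        mat = pileup.counts[sid]
        if mat.shape[1] != reference.length(sid):
            raise ValueError(
                f"pileup length {mat.shape[1]} != reference length "
                f"{reference.length(sid)} for segment {sid!r}"
            )
        tmask = reference.encoded(sid) == t_row
        positions = np.nonzero(tmask)[0] + 1
        depth = mat.sum(axis=0)[tmask]
        c_count = mat[c_row][tmask]
        segments[sid] = TransitionSegment(
            positions=positions,
            depth=depth,
            c_count=c_count,
            masked=depth < min_depth,
        )
    return TransitionTable(
        segments=segments,
        condition=condition,
        label=label,
        replicate=replicate,
        min_depth=min_depth,
    )


@dataclass
class SignalSegment:
    positions: np.ndarray
    r_plus: np.ndarray
    r_minus: np.ndarray
    signal: np.ndarray
    masked: np.ndarray


@dataclass
class SignalTrack:
    """Fold-change signal (CL+/CL-) per reference-T position."""

    segments: dict[str, SignalSegment]
    pseudo: float
    min_depth: int
    label: str = ""

    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(self.segments)

    def unmasked(self, segment_id: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(positions-with-segment-offsetless, signal) over unmasked entries."""
        segs = [segment_id] if segment_id else list(self.segments)
        pos_parts, sig_parts = [], []
        for s in segs:
            seg = self.segments[s]
            keep = ~seg.masked
            pos_parts.append(seg.positions[keep])
            sig_parts.append(seg.signal[keep])
        return np.concatenate(pos_parts), np.concatenate(sig_parts)

    def to_tsv(self, path: Path) -> None:
        frames = []
        for sid, seg in self.segments.items():
            frames.append(
                pd.DataFrame(
                    {
                        "segment": sid,
                        "position": seg.positions,
                        "r_plus": seg.r_plus,
                        "r_minus": seg.r_minus,
                        "signal": seg.signal,
                        "masked": seg.masked.astype(int),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def vparcl_signal(
    plus: Sequence[TransitionTable],
    minus: Sequence[TransitionTable],
    pseudo: float | None = None,
) -> SignalTrack:
    """Average replicate rates per condition, then take their ratio.

    A position is masked when any contributing replicate is masked there
    (insufficient depth in one library invalidates the comparison).  With
    ``pseudo=None`` the default ``1/min_depth`` pseudocount is used.
    """
    if not plus or not minus:
        raise ValueError("need at least one replicate per condition")
    min_depth = plus[0].min_depth
    for table in (*plus, *minus):
        if table.min_depth != min_depth:
            raise ValueError("all tables must share the same min_depth")
    if pseudo is None:
        pseudo = 1.0 / min_depth
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")

    segments = {}
    any_unmasked = False
    for sid in plus[0].segment_ids:
        pos = plus[0].segments[sid].positions
        rp = np.mean([t.segments[sid].rate for t in plus], axis=0)
        rm = np.mean([t.segments[sid].rate for t in minus], axis=0)
        masked = np.zeros(len(pos), dtype=bool)
        for t in (*plus, *minus):
            masked |= t.segments[sid].masked
        with np.errstate(divide="ignore", invalid="ignore"):
            signal = (rp + pseudo) / (rm + pseudo)
        signal[masked] = np.nan
        any_unmasked |= bool((~masked).any())
        segments[sid] = SignalSegment(
            positions=pos, r_plus=rp, r_minus=rm, signal=signal, masked=masked
        )
    if not any_unmasked:
        logger.warning("vparcl_signal: every position is masked")
    return SignalTrack(segments=segments, pseudo=float(pseudo), min_depth=min_depth)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    n_plus: int
    n_minus: int


def ks_compare(plus_rates: np.ndarray, minus_rates: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test on per-position mean rates.

    Uses the exact small-sample distribution when both samples have
    n <= 25, the asymptotic one otherwise.
    """
    x = np.asarray(plus_rates, float)
    y = np.asarray(minus_rates, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("ks_compare requires >= 2 unmasked positions per condition")
    method = "exact" if max(len(x), len(y)) <= 25 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_plus=len(x),
        n_minus=len(y),
    )


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: Optional[float]
    pvalue: Optional[float]
    n: int
    method: str
    undefined: bool = False
    window: Optional[int] = None


def correlate_signals(
    track_a: np.ndarray,
    track_b: np.ndarray,
    method: str = "pearson",
    window: int | None = None,
) -> CorrelationResult:
    """Pearson or Spearman correlation with a t-distribution p-value.

    Constant inputs yield an explicitly flagged undefined result rather
    than NaN propagation.
    """
    a = np.asarray(track_a, float)
    b = np.asarray(track_b, float)
    if a.shape != b.shape:
        raise ValueError("tracks must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 3:
        raise ValueError("correlation requires n >= 3 shared positions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(None, None, n, method, undefined=True, window=window)
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(
        coefficient=float(res.statistic),
        pvalue=float(res.pvalue),
        n=n,
        method=method,
        window=window,
    )


@dataclass(frozen=True)
class ThresholdResult:
    positions: dict[str, np.ndarray]  # unmasked positions with signal > cutoff
    cutoff: float
    n_above: int
    n_unmasked: int
    quantile_pct: float  # percent of unmasked signals above the cutoff

    @property
    def percentile_pct(self) -> float:
        """Percentile rank of the cutoff (percent of signals <= cutoff)."""
        return 100.0 - self.quantile_pct


def threshold_signals(track: SignalTrack, cutoff: float = 1.5) -> ThresholdResult:
    """Positions whose signal exceeds the cutoff, plus the achieved quantile."""
    positions = {}
    n_above = 0
    n_total = 0
    for sid, seg in track.segments.items():
        keep = ~seg.masked
        above = keep & (seg.signal > cutoff)
        positions[sid] = seg.positions[above]
        n_above += int(above.sum())
        n_total += int(keep.sum())
    quantile = 100.0 * n_above / n_total if n_total else 0.0
    return ThresholdResult(
        positions=positions,
        cutoff=float(cutoff),
        n_above=n_above,
        n_unmasked=n_total,
        quantile_pct=quantile,
    )
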