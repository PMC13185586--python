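"""Coverage/priming readouts over a disassembly temperature series.

All percentages are ratiometric per segment: a position's percent is its
depth (or priming count) over the segment total, times 100.  Window
statistics, moving averages, trend classification over a temperature grid,
and bedGraph/TSV export live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .pileup import AlignedPair, PileupMatrix
from .reference import GenomeReference, Region

logger = logging.getLogger(__name__)


def _normalize(counts: Mapping[str, np.ndarray], kind: str) -> dict[str, np.ndarray]:
    out = {}
    for sid, arr in counts.items():
        total = arr.sum()
        if total <= 0:
            logger.warning("segment %s has zero total %s; percents set to 0", sid, kind)
            out[sid] = np.zeros_like(arr, dtype=float)
        else:
            out[sid] = 100.0 * arr / total
    return out


@dataclass
class CoverageProfile:
    """Per-position depth and percent-of-total-depth, per segment."""

    depths: dict[str, np.ndarray]
    percents: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.percents:
            self.percents = _normalize(self.depths, "depth")

    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(self.depths)

    def segment_length(self, sid: str) -> int:
        return len(self.depths[sid])


@dataclass
class PrimingProfile:
    """Per-position deduplicated priming-site counts and percents."""

    counts: dict[str, np.ndarray]
    percents: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""
    temperature: Optional[float] = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not self.percents:
            self.percents = _normalize(self.counts, "priming")

    @property
    def segment_ids(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def segment_length(self, sid: str) -> int:
        return len(self.counts[sid])


def normalize_coverage(
    pileup: PileupMatrix, label: str = "", temperature: float | None = None
) -> CoverageProfile:
    """Ratiometric per-segment coverage percents from a deduplicated pileup."""
    depths = {sid: pileup.depth(sid).astype(np.int64) for sid in pileup.segment_ids}
    return CoverageProfile(depths=depths, label=label, temperature=temperature)


def call_priming_sites(
    pairs: Iterable[AlignedPair],
    reference: GenomeReference,
    label: str = "",
    temperature: float | None = None,
) -> PrimingProfile:
    """Count each retained molecule once at its R2-derived priming anchor."""
    counts = {sid: np.zeros(L, dtype=np.int64) for sid, L in reference.lengths.items()}
    skipped = 0
    for pair in pairs:
        if pair.r2 is None:
            skipped += 1
            continue
        counts[pair.r2.segment_id][pair.r2.five_prime() - 1] += 1
    if skipped:
        logger.info("call_priming_sites: %d molecules lacked an R2 alignment", skipped)
    return PrimingProfile(
        counts=counts, label=label, temperature=temperature, n_skipped=skipped
    )


@dataclass(frozen=True)
class WindowStat:
    region: Region
    pct_of_length: float
    pct_of_signal: float  # coverage or priming, depending on the input profile
    label: str = ""
    temperature: Optional[float] = None

    @property
    def pct_of_coverage(self) -> float:  # convenience alias
        return self.pct_of_signal


def window_stats(
    profile: CoverageProfile | PrimingProfile, region: Region
) -> WindowStat:
    """Window share of segment length and of total signal.

    ``pct_of_length`` = 100 * width / segment_length;
    ``pct_of_signal`` = sum of per-position percents inside the window.
    """
    sid = region.segment_id
    if sid not in profile.percents:
        raise ValueError(f"window {region}: unknown segment {sid!r}")
    L = profile.segment_length(sid)
    if region.end > L:
        raise ValueError(f"window {region} exceeds segment length {L}")
    pct_len = 100.0 * region.width / L
    pct_sig = float(profile.percents[sid][region.slice0()].sum())
    return WindowStat(
        region=region,
        pct_of_length=pct_len,
        pct_of_signal=pct_sig,
        label=profile.label,
        temperature=profile.temperature,
    )


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    Output length equals input length.  For even windows the extra element
    is taken from the right.  A window at least as long as the track
    collapses to the global mean (with a warning).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n == 0 or window == 1:
        return v.copy()
    if window >= n:
        if window > n:
            logger.warning("moving_average window %d > track length %d", window, n)
        return np.full(n, v.mean())
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class TemperatureSeries:
    """Coverage (and optional priming) profiles over an increasing T grid."""

    temperatures: tuple[float, ...]
    profiles: tuple[CoverageProfile, ...]
    priming: tuple[PrimingProfile, ...] | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        if len(temps) != len(self.profiles):
            raise ValueError("one profile required per temperature")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = temps
        self.profiles = tuple(self.profiles)

    def profile_at(self, temperature: float) -> CoverageProfile:
        for t, p in zip(self.temperatures, self.profiles):
            if t == temperature:
                return p
        raise KeyError(f"no profile at temperature {temperature}")


TREND_CLASSES = ("increasing", "decreasing", "flat_low", "fluctuating")


@dataclass(frozen=True)
class TrendClass:
    label: str
    rho: float
    range_fraction: float
    mean_pct: float
    pct_of_length: float
    region: Region


def classify_trend(
    series: TemperatureSeries,
    region: Region,
    rho_threshold: float = 0.7,
    range_threshold: float = 0.25,
) -> TrendClass:
    """Classify a window's coverage trend across the temperature grid.

    increasing/decreasing when the Spearman rank correlation of the window's
    coverage share against temperature passes +/- ``rho_threshold``;
    flat_low when the dynamic range is small and the mean share sits below
    the uniform expectation (the window's share of segment length);
    fluctuating otherwise.
    """
    if len(series.temperatures) < 4:
        raise ValueError("trend classification requires >= 4 temperatures")
    values = np.array(
        [window_stats(p, region).pct_of_signal for p in series.profiles]
    )
    rho = stats.spearmanr(series.temperatures, values).statistic
    if np.isnan(rho):  # constant series
        rho = 0.0
    vmax = values.max()
    range_fraction = 0.0 if vmax <= 0 else float((vmax - values.min()) / vmax)
    pct_len = window_stats(series.profiles[0], region).pct_of_length
    mean_pct = float(values.mean())
    if rho >= rho_threshold:
        label = "increasing"
    elif rho <= -rho_threshold:
        label = "decreasing"
    elif range_fraction < range_threshold and mean_pct < pct_len:
        label = "flat_low"
    else:
        label = "fluctuating"
    return TrendClass(
        label=label,
        rho=float(rho),
        range_fraction=range_fraction,
        mean_pct=mean_pct,
        pct_of_length=pct_len,
        region=region,
    )


@dataclass(frozen=True)
class FoldChange:
    ratio: Optional[float]
    undefined: bool
    region: Region
    t_from: float
    t_to: float


def region_fold_change(
    series: TemperatureSeries, region: Region, t_from: float, t_to: float
) -> FoldChange:
    """Ratio of a window's coverage share between two grid temperatures."""
    v_from = window_stats(series.profile_at(t_from), region).pct_of_signal
    v_to = window_stats(series.profile_at(t_to), region).pct_of_signal
    if v_from <= 0:
        return FoldChange(None, True, region, t_from, t_to)
    return FoldChange(float(v_to / v_from), False, region, t_from, t_to)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_bedgraph(
    values: Mapping[str, np.ndarray], path: Path, track_name: str = "track"
) -> None:
    """Write per-position values as bedGraph (0-based half-open intervals).

    Runs of equal adjacent values are merged into single intervals.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for sid, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) == 0:
                continue
            breaks = np.nonzero(np.diff(arr) != 0)[0] + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{sid}\t{s}\t{e}\t{arr[s]:.10g}\n")


def read_bedgraph(path: Path) -> dict[str, np.ndarray]:
    """Inverse of :func:`write_bedgraph` (requires contiguous coverage)."""
    chunks: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            sid, s, e, v = line.split("\t")
            chunks.setdefault(sid, []).append((int(s), int(e), float(v)))
    out = {}
    for sid, rows in chunks.items():
        length = max(e for _, e, _ in rows)
        arr = np.zeros(length)
        for s, e, v in rows:
            arr[s:e] = v
        out[sid] = arr
    return out


def profile_to_tsv(profile: CoverageProfile | PrimingProfile, path: Path) -> None:
    counts = profile.depths if isinstance(profile, CoverageProfile) else profile.counts
    frames = []
    for sid in profile.segment_ids:
        df = pd.DataFrame(
            {
                "segment": sid,
                "position": np.arange(1, len(counts[sid]) + 1),
                "count": counts[sid],
                "percent": profile.percents[sid],
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def coverage_from_tsv(path: Path, label: str = "", temperature: float | None = None) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t")
    depths = {}
    for sid, sub in df.groupby("segment", sort=False):
        depths[sid] = sub.sort_values("position")["count"].to_numpy(np.int64)
    return CoverageProfile(depths=depths, label=label, temperature=temperature)


def window_table(
    profiles: Sequence[CoverageProfile | PrimingProfile],
    regions: Sequence[Region],
    decimals: int = 1,
) -> pd.DataFrame:
    """Tidy table of window statistics (percent columns rounded for report)."""
    rows = []
    for profile in profiles:
        for region in regions:
            ws = window_stats(profile, region)
            rows.append(
                {
                    "label": ws.label,
                    "temperature": ws.temperature,
                    "region": str(region),
                    "pct_of_length": round(ws.pct_of_length, decimals),
                    "pct_of_signal": round(ws.pct_of_signal, decimals),
                }
            )
    return pd.DataFrame(rows)
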