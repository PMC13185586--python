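"""Synthetic particle/library simulator.

Generates paired-end, UMI-tagged, terminator-limited cDNA libraries from a
parameterized model of a partially disassembled particle:

* priming anchors are drawn with probability proportional to the mean
  accessibility of the 6-nt hexamer annealing window just 3' of the anchor;
* cDNA length follows a geometric law (per-nucleotide termination
  probability ``p_term``, default 1/6 from the 1:5 terminator:extender
  ratio), truncated below at the minimum library length and above at the
  anchor (synthesis cannot run past position 1);
* covered reference-T positions convert to C with the site's crosslink
  probability (crosslinked condition only) plus a global background rate;
* UMIs are uniform 12-mers; PCR duplication repeats molecules with shared
  UMI/coordinates but independent sequencing errors.

Coordinate-only fast paths (:func:`sample_fragment_coordinates`,
:func:`anchor_histogram`, :func:`span_depth`, :func:`truth_pileup`) support
large-scale statistical runs without materializing per-fragment objects.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .barrier import ExposureProfile
from .pileup import PileupMatrix
from .reference import BASE_ORDER, GenomeReference, revcomp

CONDITIONS = ("CL+", "CL-")
_BASES = np.array(list("ACGT"))

HEXAMER_LEN = 6


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryParams:
    """Library chemistry and sequencing parameters."""

    n_fragments: int = 10_000
    p_term: float = 1.0 / 6.0
    min_length: int = 20
    max_read_length: int = 75
    umi_length: int = 12
    r2_prefix_length: int = 7  # hexamer + 1 buffer base
    p_error: float = 0.0
    dup_mean: float = 1.0
    dup_model: str = "fixed"  # 'fixed' (round(dup_mean)) or 'poisson' (1+Pois(mean-1))
    buffer_base: str = "A"
    terminator_bias: float = 1.0  # reserved: polymerase discrimination factor

    def __post_init__(self) -> None:
        if not 0.0 < self.p_term < 1.0:
            raise ValueError("p_term must be in (0,1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_read_length <= self.umi_length:
            raise ValueError("max_read_length must exceed umi_length")
        if not 0.0 <= self.p_error <= 0.1:
            raise ValueError("p_error must be in [0, 0.1]")
        if self.dup_mean < 1.0:
            raise ValueError("PCR duplication mean must be >= 1")
        if self.dup_model not in ("fixed", "poisson"):
            raise ValueError("dup_model must be 'fixed' or 'poisson'")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be positive")


@dataclass(frozen=True)
class CrosslinkProfile:
    """Crosslink conversion probabilities at reference-T positions."""

    sites: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    p_background: float = 0.0
    p_error: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_background, self.p_error):
            if not 0.0 <= p <= 0.1:
                raise ValueError("background/error rates must be in [0, 0.1]")
        for seg, by_pos in self.sites.items():
            for pos, p_xl in by_pos.items():
                if not 0.0 <= p_xl <= 1.0:
                    raise ValueError(
                        f"crosslink probability at {seg}:{pos} outside [0,1]"
                    )

    def validate(self, reference: GenomeReference) -> None:
        for seg, by_pos in self.sites.items():
            seq = reference.sequence(seg)
            for pos in by_pos:
                if not 1 <= pos <= len(seq):
                    raise ValueError(f"crosslink site {seg}:{pos} out of bounds")
                if seq[pos - 1] != "T":
                    raise ValueError(
                        f"crosslink site {seg}:{pos} is {seq[pos - 1]}, not T"
                    )

    @classmethod
    def none(cls) -> "CrosslinkProfile":
        return cls()


@dataclass(frozen=True)
class SimulatedFragment:
    """One cDNA molecule: covers [start, anchor] on the sense strand."""

    segment_id: str
    start: int  # 5'-most covered position (t)
    anchor: int  # priming anchor (p); hexamer window is [p+1, p+6]
    umi: str
    condition: str = "CL-"
    converted: tuple[int, ...] = ()  # reference-T positions read as C

    @property
    def length(self) -> int:
        return self.anchor - self.start + 1


@dataclass
class FragmentCoordinates:
    """Vectorized fragment coordinates for large-scale statistics."""

    segment_index: np.ndarray  # int, index into reference.segment_ids
    start: np.ndarray  # 1-based
    anchor: np.ndarray  # 1-based
    segment_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.anchor)

    @property
    def lengths(self) -> np.ndarray:
        return self.anchor - self.start + 1


def anchor_weights(
    reference: GenomeReference, profile: ExposureProfile, params: LibraryParams
) -> dict[str, np.ndarray]:
    """Unnormalized anchor sampling weights per segment.

    ``weights[sid][p-1]`` is the mean exposure over the hexamer window
    ``[p+1, p+6]``; anchors must leave room for the window
    (``p + 6 <= L``) and for a minimum-length fragment (``p >= min_length``).
    Ineligible positions get weight 0.
    """
    out = {}
    kernel = np.full(HEXAMER_LEN, 1.0 / HEXAMER_LEN)
    for sid in reference.segment_ids:
        expo = np.asarray(profile.segment(sid), dtype=float)
        L = len(expo)
        w = np.zeros(L)
        if L > HEXAMER_LEN:
            # window mean starting at 0-based i covers 1-based [i+1, i+6],
            # which is the hexamer window of anchor p = i (1-based)
            means = np.convolve(expo, kernel, mode="valid")  # length L-5
            # weight for anchor p lives at index p-1; valid p in [1, L-6]
            w[0 : L - HEXAMER_LEN] = means[1:]
        w[: params.min_length - 1] = 0.0  # p < min_length cannot host a fragment
        out[sid] = w
    return out


def _sample_truncated_geometric(
    upper: np.ndarray, p_term: float, min_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Geometric(p_term) lengths conditioned on min_length <= L <= upper."""
    q = 1.0 - p_term
    lo_cdf = -np.expm1((min_length - 1) * np.log(q))  # F(min_length - 1)
    hi_cdf = -np.expm1(upper * np.log(q))  # F(upper)
    u = lo_cdf + rng.random(len(upper)) * (hi_cdf - lo_cdf)
    lengths = np.ceil(np.log1p(-u) / np.log(q)).astype(np.int64)
    return np.clip(lengths, min_length, upper)


def sample_fragment_coordinates(
    reference: GenomeReference,
    profile: ExposureProfile,
    params: LibraryParams,
    rng: np.random.Generator,
    n: int | None = None,
) -> FragmentCoordinates:
    """Draw anchors and fragment spans without building per-fragment objects."""
    n = params.n_fragments if n is None else int(n)
    weights = anchor_weights(reference, profile, params)
    seg_ids = reference.segment_ids
    flat = np.concatenate([weights[sid] for sid in seg_ids])
    total = flat.sum()
    if total <= 0:
        raise SimulationError(
            "no priming-competent positions: exposure is zero at every "
            "eligible anchor"
        )
    cum = np.cumsum(flat) / total
    draws = np.searchsorted(cum, rng.random(n), side="right")
    seg_offsets = np.cumsum([0] + [reference.length(sid) for sid in seg_ids])
    seg_index = np.searchsorted(seg_offsets, draws, side="right") - 1
    anchors = draws - seg_offsets[seg_index] + 1  # back to 1-based positions
    lengths = _sample_truncated_geometric(anchors, params.p_term, params.min_length, rng)
    starts = anchors - lengths + 1
    return FragmentCoordinates(
        segment_index=seg_index.astype(np.int64),
        start=starts,
        anchor=anchors.astype(np.int64),
        segment_ids=seg_ids,
    )


def _draw_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    flat = _BASES[codes]
    return ["".join(row) for row in flat]


def simulate_fragments(
    reference: GenomeReference,
    profile: ExposureProfile,
    xl: CrosslinkProfile,
    params: LibraryParams,
    condition: str = "CL-",
    rng: np.random.Generator | None = None,
) -> list[SimulatedFragment]:
    """Simulate molecules for one library (one condition)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if rng is None:
        rng = np.random.default_rng()
    xl.validate(reference)
    profile.validate(reference)
    coords = sample_fragment_coordinates(reference, profile, params, rng)
    umis = _draw_umis(len(coords), params.umi_length, rng)

    # per-segment conversion probability vectors over T positions
    t_positions: dict[int, np.ndarray] = {}
    t_probs: dict[int, np.ndarray] = {}
    for seg_idx, sid in enumerate(coords.segment_ids):
        enc = reference.encoded(sid)
        tpos = np.nonzero(enc == BASE_ORDER.index("T"))[0] + 1
        probs = np.full(len(tpos), xl.p_background, dtype=float)
        if condition == "CL+" and sid in xl.sites:
            site_map = xl.sites[sid]
            for j, pos in enumerate(tpos):
                p_xl = site_map.get(int(pos))
                if p_xl:
                    probs[j] = min(1.0, probs[j] + p_xl)
        t_positions[seg_idx] = tpos
        t_probs[seg_idx] = probs

    any_conversion = any(p.any() for p in t_probs.values())
    fragments: list[SimulatedFragment] = []
    for i in range(len(coords)):
        seg_idx = int(coords.segment_index[i])
        t, p = int(coords.start[i]), int(coords.anchor[i])
        converted: tuple[int, ...] = ()
        if any_conversion:
            tpos = t_positions[seg_idx]
            lo, hi = np.searchsorted(tpos, (t, p + 1))
            if hi > lo:
                probs = t_probs[seg_idx][lo:hi]
                hits = rng.random(hi - lo) < probs
                if hits.any():
                    converted = tuple(int(x) for x in tpos[lo:hi][hits])
        fragments.append(
            SimulatedFragment(
                segment_id=coords.segment_ids[seg_idx],
                start=t,
                anchor=p,
                umi=umis[i],
                condition=condition,
                converted=converted,
            )
        )
    return fragments


def apply_pcr_duplication(
    fragments: Sequence[SimulatedFragment],
    params: LibraryParams,
    rng: np.random.Generator | None = None,
) -> list[SimulatedFragment]:
    """Emit each molecule >= 1 times; copies share UMI and coordinates."""
    if params.dup_mean < 1.0:
        raise ValueError("PCR duplication mean must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if params.dup_model == "fixed":
        factors = np.full(len(fragments), max(1, round(params.dup_mean)), dtype=int)
    else:
        factors = 1 + rng.poisson(params.dup_mean - 1.0, size=len(fragments))
    out: list[SimulatedFragment] = []
    for frag, k in zip(fragments, factors):
        out.extend([frag] * int(k))
    return out


# ---------------------------------------------------------------------------
# read rendering
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, p_error: float, rng: np.random.Generator) -> str:
    if p_error <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p_error)[0]
    if len(hits) == 0:
        return seq
    for i in hits:
        current = chr(arr[i])
        choices = [b for b in "ACGT" if b != current]
        arr[i] = ord(choices[rng.integers(0, len(choices))])
    return arr.tobytes().decode("ascii")


def render_read_pair(
    fragment: SimulatedFragment,
    reference: GenomeReference,
    params: LibraryParams,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Render (R1, R2) sequences for one molecule copy.

    R1 = UMI + sense strand from ``start`` ascending; R2 = 6 bases of
    hexamer complement + 1 buffer base + antisense strand from ``anchor``
    descending; both capped at ``max_read_length``.  Converted positions
    read C on the sense strand (G on the antisense strand).  Sequencing
    errors are applied per rendered copy.
    """
    if rng is None:
        rng = np.random.default_rng()
    if fragment.length < params.min_length:
        raise ValueError("fragment shorter than the minimum library length")
    seq = reference.sequence(fragment.segment_id)
    t, p = fragment.start, fragment.anchor
    if p + HEXAMER_LEN > len(seq):
        raise ValueError("hexamer window extends past the segment end")
    converted = set(fragment.converted)

    sense = list(seq[t - 1 : p])
    for pos in converted:
        if t <= pos <= p:
            sense[pos - t] = "C"
    r1_core_len = params.max_read_length - params.umi_length
    r1 = fragment.umi + "".join(sense[:r1_core_len])

    prefix = revcomp(seq[p : p + HEXAMER_LEN]) + params.buffer_base
    r2_core_len = min(p - t + 1, params.max_read_length - params.r2_prefix_length)
    antis = []
    for pos in range(p, p - r2_core_len, -1):
        base = "C" if pos in converted else seq[pos - 1]
        antis.append(revcomp(base))
    r2 = prefix + "".join(antis)

    return (
        _apply_errors(r1, params.p_error, rng),
        _apply_errors(r2, params.p_error, rng),
    )


# ---------------------------------------------------------------------------
# truth helpers (coordinate-level fast paths)
# ---------------------------------------------------------------------------


def anchor_histogram(
    coords: FragmentCoordinates, reference: GenomeReference
) -> dict[str, np.ndarray]:
    """Per-position anchor counts per segment."""
    out = {}
    for seg_idx, sid in enumerate(coords.segment_ids):
        mask = coords.segment_index == seg_idx
        out[sid] = np.bincount(
            coords.anchor[mask] - 1, minlength=reference.length(sid)
        ).astype(np.int64)
    return out


def span_depth(
    coords: FragmentCoordinates, reference: GenomeReference
) -> dict[str, np.ndarray]:
    """Per-position coverage depth of fragment spans [start, anchor]."""
    out = {}
    for seg_idx, sid in enumerate(coords.segment_ids):
        mask = coords.segment_index == seg_idx
        L = reference.length(sid)
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, coords.start[mask] - 1, 1)
        np.add.at(diff, coords.anchor[mask], -1)
        out[sid] = np.cumsum(diff[:-1])
    return out


def truth_pileup(
    coords: FragmentCoordinates,
    reference: GenomeReference,
    xl: CrosslinkProfile | None = None,
    condition: str = "CL-",
    rng: np.random.Generator | None = None,
) -> PileupMatrix:
    """Pileup implied by fragment spans, bypassing read rendering/alignment.

    Depth comes from the span coverage; when a crosslink profile is given,
    C counts at reference-T positions are drawn binomially with the same
    per-molecule conversion probability the read-level simulation uses, so
    the two routes agree in distribution.
    """
    pile = PileupMatrix.zeros(reference)
    depths = span_depth(coords, reference)
    t_row = BASE_ORDER.index("T")
    c_row = BASE_ORDER.index("C")
    for sid in coords.segment_ids:
        depth = depths[sid]
        ref_idx = reference.encoded(sid)
        mat = pile.counts[sid]
        mat[ref_idx, np.arange(len(ref_idx))] += depth
        if xl is not None:
            if rng is None:
                rng = np.random.default_rng()
            tmask = ref_idx == t_row
            probs = np.full(int(tmask.sum()), xl.p_background, dtype=float)
            tpos = np.nonzero(tmask)[0] + 1
            if condition == "CL+" and sid in xl.sites:
                site_map = xl.sites[sid]
                for j, pos in enumerate(tpos):
                    p_xl = site_map.get(int(pos))
                    if p_xl:
                        probs[j] = min(1.0, probs[j] + p_xl)
            conv = rng.binomial(depth[tmask], probs)
            mat[t_row, tmask] -= conv
            mat[c_row, tmask] += conv
    return pile


# ---------------------------------------------------------------------------
# run output
# ---------------------------------------------------------------------------


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pair(
    read_pairs: Iterable[tuple[str, str, str]],
    r1_path: Path,
    r2_path: Path,
    quality_char: str = "I",
) -> int:
    """Write (name, r1_seq, r2_seq) triples as a mate-paired FASTQ pair."""
    n = 0
    with _open_text(Path(r1_path), "w") as f1, _open_text(Path(r2_path), "w") as f2:
        for name, s1, s2 in read_pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{quality_char * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{quality_char * len(s2)}\n")
            n += 1
    return n


def write_truth_table(fragments: Sequence[SimulatedFragment], path: Path) -> None:
    rows = [
        {
            "segment": f.segment_id,
            "start": f.start,
            "anchor": f.anchor,
            "umi": f.umi,
            "condition": f.condition,
            "converted": ",".join(map(str, f.converted)),
        }
        for f in fragments
    ]
    pd.DataFrame(
        rows, columns=["segment", "start", "anchor", "umi", "condition", "converted"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: Path) -> list[SimulatedFragment]:
    df = pd.read_csv(path, sep="\t", dtype={"converted": "string"})
    out = []
    for row in df.itertuples(index=False):
        conv = row.converted
        converted = (
            tuple(int(x) for x in str(conv).split(",")) if pd.notna(conv) and str(conv) else ()
        )
        out.append(
            SimulatedFragment(
                segment_id=row.segment,
                start=int(row.start),
                anchor=int(row.anchor),
                umi=row.umi,
                condition=row.condition,
                converted=converted,
            )
        )
    return out


def write_run(
    fragments: Sequence[SimulatedFragment],
    reference: GenomeReference,
    params: LibraryParams,
    out_dir: Path,
    *,
    name: str = "sim",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    compress: bool = True,
    extra_manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Render and persist a full run: FASTQ pair, truth TSV, FASTA, manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if rng is None:
        rng = np.random.default_rng(seed)
    suffix = ".fastq.gz" if compress else ".fastq"
    paths = {
        "r1": out_dir / f"{name}_R1{suffix}",
        "r2": out_dir / f"{name}_R2{suffix}",
        "truth": out_dir / f"{name}_truth.tsv",
        "reference": out_dir / f"{name}_reference.fasta",
        "manifest": out_dir / f"{name}_manifest.json",
    }

    def pairs():
        for i, frag in enumerate(fragments):
            r1, r2 = render_read_pair(frag, reference, params, rng)
            yield f"{name}:{i:07d}", r1, r2

    try:
        n = write_fastq_pair(pairs(), paths["r1"], paths["r2"])
        write_truth_table(fragments, paths["truth"])
        reference.to_fasta(paths["reference"])
        manifest = {
            "name": name,
            "seed": seed,
            "n_read_pairs": n,
            "params": asdict(params),
            "segments": reference.lengths,
        }
        if extra_manifest:
            manifest.update(extra_manifest)
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing simulated run under {out_dir}: {exc}") from exc
    return paths
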