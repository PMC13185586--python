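"""End-to-end orchestration: simulate -> process -> analyze -> report.

A run is fully described by a :class:`RunConfig` (deserializable from YAML)
plus its seed; rerunning the same config/seed reproduces every output
byte-for-byte.  Each stage writes its intermediates so externally produced
data (e.g. SAM alignments) can enter mid-pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import crosslink as xlmod
from . import exposure as exmod
from .barrier import BarrierModel, exposure_at_temperature
from .processing import process_fastq_pair
from .reference import GenomeReference, Region
from .simulate import (
    CrosslinkProfile,
    LibraryParams,
    SimulationError,
    apply_pcr_duplication,
    simulate_fragments,
    write_run,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class CrosslinkConfig:
    temperature: float = 50.0
    replicates: int = 1
    n_fragments: int = 5000
    p_background: float = 0.01
    p_error: float = 0.0
    sites: dict[str, dict[int, float]] = field(default_factory=dict)
    n_sites: int = 0  # alternative to explicit sites: draw from U positions
    p_xl: float = 0.4


@dataclass
class Thresholds:
    min_depth: int = 1000
    signal_cutoff: float = 1.5
    trend_rho: float = 0.7
    trend_range: float = 0.25
    coverage_window: int = 50
    priming_window: int = 15


@dataclass
class RunConfig:
    seed: int = 0
    reference_lengths: dict[str, int] = field(default_factory=lambda: {"RNA1": 1000})
    reference_fasta: Optional[str] = None
    base_probs: Optional[list[float]] = None
    default_exposure: float = 0.05
    barriers: list[dict] = field(default_factory=list)
    temperatures: list[float] = field(default_factory=lambda: [50.0, 55.0, 60.0, 65.0])
    library: LibraryParams = field(default_factory=LibraryParams)
    crosslink: Optional[CrosslinkConfig] = None
    regions: list[str] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    compress_fastq: bool = True

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        ref = dict(raw.pop("reference", {}))
        expo = dict(raw.pop("exposure", {}))
        cfg = cls(
            seed=int(raw.pop("seed", 0)),
            reference_lengths={k: int(v) for k, v in ref.get("lengths", {}).items()}
            or {"RNA1": 1000},
            reference_fasta=ref.get("fasta"),
            base_probs=ref.get("base_probs"),
            default_exposure=float(expo.get("default", 0.05)),
            barriers=list(expo.get("barriers", [])),
            temperatures=[float(t) for t in raw.pop("temperatures", [50, 55, 60, 65])],
            library=LibraryParams(**raw.pop("library", {})),
            regions=[str(r) for r in raw.pop("regions", [])],
            thresholds=Thresholds(**raw.pop("thresholds", {})),
            compress_fastq=bool(raw.pop("compress_fastq", True)),
        )
        xl = raw.pop("crosslink", None)
        if xl is not None:
            xl = dict(xl)
            sites = {
                seg: {int(p): float(v) for p, v in by_pos.items()}
                for seg, by_pos in dict(xl.pop("sites", {})).items()
            }
            cfg.crosslink = CrosslinkConfig(sites=sites, **xl)
        if raw:
            raise ConfigError(f"unknown config keys: {sorted(raw)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    # -- validation (before any compute) ----------------------------------
    def build_reference(self, rng: np.random.Generator) -> GenomeReference:
        if self.reference_fasta:
            return GenomeReference.from_fasta(self.reference_fasta)
        return GenomeReference.random(self.reference_lengths, rng, self.base_probs)

    def validate(self, reference: GenomeReference) -> None:
        if sorted(self.temperatures) != self.temperatures or len(
            set(self.temperatures)
        ) != len(self.temperatures):
            raise ConfigError("temperatures must be strictly increasing")
        model = self.barrier_model()
        for barrier in model.barriers:
            try:
                reference.check_region(barrier.region)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        for region_text in self.regions:
            try:
                reference.check_region(Region.parse(region_text))
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        if self.crosslink is not None:
            self.crosslink_profile(reference, np.random.default_rng(0)).validate(
                reference
            )

    def barrier_model(self) -> BarrierModel:
        return BarrierModel.from_dicts(self.barriers, self.default_exposure)

    def crosslink_profile(
        self, reference: GenomeReference, rng: np.random.Generator
    ) -> CrosslinkProfile:
        assert self.crosslink is not None
        xl = self.crosslink
        sites = {seg: dict(by_pos) for seg, by_pos in xl.sites.items()}
        if not sites and xl.n_sites > 0:
            # deterministic draw (given rng) from reference-T positions
            sites = {}
            all_t = []
            for sid, seq in reference:
                all_t.extend((sid, i + 1) for i, b in enumerate(seq) if b == "T")
            if len(all_t) < xl.n_sites:
                raise ConfigError("fewer reference-T positions than requested sites")
            picks = rng.choice(len(all_t), size=xl.n_sites, replace=False)
            for k in sorted(picks):
                sid, pos = all_t[int(k)]
                sites.setdefault(sid, {})[pos] = xl.p_xl
        return CrosslinkProfile(
            sites=sites, p_background=xl.p_background, p_error=xl.p_error
        )


@dataclass
class ReportBundle:
    window_table: pd.DataFrame
    trend_table: pd.DataFrame
    vparcl_summary: dict
    integration: dict
    counters: dict
    manifest: dict
    series: exmod.TemperatureSeries | None = None
    signal: xlmod.SignalTrack | None = None
    priming: dict[float, exmod.PrimingProfile] = field(default_factory=dict)


def correlate_priming_vs_signal(
    priming: exmod.PrimingProfile,
    signal: xlmod.SignalTrack,
    window: int = 15,
) -> xlmod.CorrelationResult:
    """Spearman correlation of smoothed priming percent vs crosslink signal.

    The priming percent track is smoothed with a centered ``window``-nt
    moving average; the correlation runs over the unmasked reference-T
    positions of every shared segment.
    """
    smoothed_parts, signal_parts = [], []
    for sid in signal.segment_ids:
        if sid not in priming.percents:
            continue
        smooth = exmod.moving_average(priming.percents[sid], window)
        seg = signal.segments[sid]
        keep = ~seg.masked
        smoothed_parts.append(smooth[seg.positions[keep] - 1])
        signal_parts.append(seg.signal[keep])
    if not smoothed_parts:
        raise ValueError("no shared segments between priming and signal tracks")
    a = np.concatenate(smoothed_parts)
    b = np.concatenate(signal_parts)
    return xlmod.correlate_signals(a, b, method="spearman", window=window)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, out_dir: Path) -> ReportBundle:
    """Execute the full simulate -> process -> analyze -> integrate run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seedseq = np.random.SeedSequence(config.seed)
    # stable stage order => deterministic child streams
    children = seedseq.spawn(4)
    rng_ref, rng_sim, rng_xl, _spare = (np.random.default_rng(s) for s in children)

    manifest: dict[str, Any] = {"seed": config.seed, "stages": []}
    counters: dict[str, Any] = {}

    def _stage(name):
        manifest["stages"].append(name)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("stage: %s", name)

    try:
        _stage("reference")
        reference = config.build_reference(rng_ref)
        config.validate(reference)
        reference.to_fasta(out_dir / "reference.fasta")
        manifest["segments"] = reference.lengths
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageFailure("reference", exc) from exc

    model = config.barrier_model()
    regions = [Region.parse(r) for r in config.regions]
    thr = config.thresholds

    # -- temperature series -------------------------------------------------
    profiles: list[exmod.CoverageProfile] = []
    primings: dict[float, exmod.PrimingProfile] = {}
    try:
        _stage("temperature_series")
        for temperature in config.temperatures:
            tag = f"T{temperature:g}"
            run_dir = out_dir / "runs" / tag
            profile = exposure_at_temperature(model, reference, temperature)
            fragments = simulate_fragments(
                reference,
                profile,
                CrosslinkProfile.none(),
                config.library,
                "CL-",
                rng_sim,
            )
            fragments = apply_pcr_duplication(fragments, config.library, rng_sim)
            paths = write_run(
                fragments,
                reference,
                config.library,
                run_dir,
                name=tag,
                rng=rng_sim,
                compress=config.compress_fastq,
                extra_manifest={"temperature": temperature},
            )
            result = process_fastq_pair(
                paths["r1"], paths["r2"], reference,
                umi_length=config.library.umi_length,
                r2_trim=config.library.r2_prefix_length,
            )
            counters[tag] = result.stats.as_dict()
            coverage = exmod.normalize_coverage(
                result.pileup, label=tag, temperature=temperature
            )
            priming = exmod.call_priming_sites(
                result.molecules, reference, label=tag, temperature=temperature
            )
            profiles.append(coverage)
            primings[temperature] = priming
            result.pileup.to_tsv(run_dir / f"{tag}_pileup.tsv")
            exmod.profile_to_tsv(coverage, run_dir / f"{tag}_coverage.tsv")
            exmod.profile_to_tsv(priming, run_dir / f"{tag}_priming.tsv")
            exmod.write_bedgraph(
                coverage.percents, run_dir / f"{tag}_coverage.bedgraph", tag
            )
            smoothed = {
                sid: exmod.moving_average(coverage.percents[sid], thr.coverage_window)
                for sid in coverage.segment_ids
            }
            exmod.write_bedgraph(
                smoothed, run_dir / f"{tag}_coverage_smoothed.bedgraph", f"{tag}-smoothed"
            )
        series = exmod.TemperatureSeries(
            temperatures=tuple(config.temperatures), profiles=tuple(profiles)
        )
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("temperature_series", exc) from exc

    # -- exposure analysis --------------------------------------------------
    try:
        _stage("exposure_analysis")
        window_df = exmod.window_table(profiles, regions) if regions else pd.DataFrame()
        trend_rows = []
        if regions and len(config.temperatures) >= 4:
            for region in regions:
                tc = exmod.classify_trend(
                    series, region, thr.trend_rho, thr.trend_range
                )
                trend_rows.append(
                    {
                        "region": str(region),
                        "class": tc.label,
                        "rho": tc.rho,
                        "range_fraction": tc.range_fraction,
                        "mean_pct": tc.mean_pct,
                        "pct_of_length": tc.pct_of_length,
                    }
                )
        trend_df = pd.DataFrame(trend_rows)
        if not window_df.empty:
            window_df.to_csv(out_dir / "window_stats.tsv", sep="\t", index=False)
        if not trend_df.empty:
            trend_df.to_csv(out_dir / "trend_classes.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("exposure_analysis", exc) from exc

    # -- crosslink analysis -------------------------------------------------
    vparcl_summary: dict[str, Any] = {}
    signal: xlmod.SignalTrack | None = None
    if config.crosslink is not None:
        try:
            _stage("crosslink_analysis")
            xl_cfg = config.crosslink
            xl_profile = config.crosslink_profile(reference, rng_xl)
            expo = exposure_at_temperature(model, reference, xl_cfg.temperature)
            params = dataclasses.replace(
                config.library,
                n_fragments=xl_cfg.n_fragments,
                p_error=xl_cfg.p_error,
            )
            tables: dict[str, list[xlmod.TransitionTable]] = {"CL+": [], "CL-": []}
            for condition in ("CL+", "CL-"):
                for rep in range(xl_cfg.replicates):
                    tag = f"xl_{'plus' if condition == 'CL+' else 'minus'}_r{rep}"
                    run_dir = out_dir / "runs" / tag
                    frags = simulate_fragments(
                        reference, expo, xl_profile, params, condition, rng_xl
                    )
                    frags = apply_pcr_duplication(frags, params, rng_xl)
                    paths = write_run(
                        frags, reference, params, run_dir, name=tag, rng=rng_xl,
                        compress=config.compress_fastq,
                        extra_manifest={"condition": condition, "replicate": rep},
                    )
                    result = process_fastq_pair(
                        paths["r1"], paths["r2"], reference,
                        umi_length=params.umi_length,
                        r2_trim=params.r2_prefix_length,
                    )
                    counters[tag] = result.stats.as_dict()
                    result.pileup.to_tsv(run_dir / f"{tag}_pileup.tsv")
                    tables[condition].append(
                        xlmod.transition_rates(
                            result.pileup,
                            reference,
                            thr.min_depth,
                            condition=condition,
                            label=tag,
                            replicate=rep,
                        )
                    )
            signal = xlmod.vparcl_signal(tables["CL+"], tables["CL-"])
            signal.to_tsv(out_dir / "vparcl_signal.tsv")
            ks = {}
            for sid in reference.segment_ids:
                plus_rates = np.mean(
                    [t.segments[sid].rate for t in tables["CL+"]], axis=0
                )
                minus_rates = np.mean(
                    [t.segments[sid].rate for t in tables["CL-"]], axis=0
                )
                keep = ~signal.segments[sid].masked
                if keep.sum() >= 2:
                    res = xlmod.ks_compare(plus_rates[keep], minus_rates[keep])
                    ks[sid] = {"D": res.statistic, "p": res.pvalue, "n": int(keep.sum())}
            threshold = xlmod.threshold_signals(signal, thr.signal_cutoff)
            vparcl_summary = {
                "ks": ks,
                "cutoff": threshold.cutoff,
                "n_above_cutoff": threshold.n_above,
                "n_unmasked": threshold.n_unmasked,
                "quantile_pct": threshold.quantile_pct,
            }
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("crosslink_analysis", exc) from exc

    # -- integration --------------------------------------------------------
    integration: dict[str, Any] = {}
    if signal is not None and primings:
        try:
            _stage("integration")
            base_t = config.crosslink.temperature
            priming = primings.get(base_t) or next(iter(primings.values()))
            corr = correlate_priming_vs_signal(
                priming, signal, window=thr.priming_window
            )
            integration = {
                "spearman_rho": corr.coefficient,
                "p_value": corr.pvalue,
                "n": corr.n,
                "window_nt": corr.window,
                "undefined": corr.undefined,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("integration", exc) from exc

    manifest["counters"] = counters
    manifest["config"] = config.to_dict()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    bundle = ReportBundle(
        window_table=window_df,
        trend_table=trend_df,
        vparcl_summary=vparcl_summary,
        integration=integration,
        counters=counters,
        manifest=manifest,
        series=series,
        signal=signal,
        priming=primings,
    )
    generate_report(bundle, out_dir)
    return bundle


def generate_report(
    bundle: ReportBundle, out_dir: Path, formats: Sequence[str] = ("tsv", "json"),
    plots: bool = False,
) -> list[Path]:
    """Emit the report bundle as TSV/JSON (and optional matplotlib plots)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary = {
        "vparcl": bundle.vparcl_summary,
        "integration": bundle.integration,
        "counters": bundle.counters,
    }
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(json.dumps(summary, indent=2, default=float))
        written.append(path)
    if "tsv" in formats:
        if not bundle.window_table.empty:
            path = out_dir / "report_windows.tsv"
            bundle.window_table.to_csv(path, sep="\t", index=False)
            written.append(path)
        if not bundle.trend_table.empty:
            path = out_dir / "report_trends.tsv"
            bundle.trend_table.to_csv(path, sep="\t", index=False)
            written.append(path)
    if plots:
        written.extend(_plot_report(bundle, out_dir))
    return written


def _plot_report(bundle: ReportBundle, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if bundle.series is not None:
        for sid in bundle.series.profiles[0].segment_ids:
            fig, ax = plt.subplots(figsize=(10, 3))
            for t, prof in zip(bundle.series.temperatures, bundle.series.profiles):
                ax.plot(prof.percents[sid], lw=0.7, label=f"{t:g} C")
            ax.set_xlabel(f"{sid} position")
            ax.set_ylabel("% of total depth")
            ax.legend(fontsize=6, ncol=5)
            path = out_dir / f"coverage_{sid}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
    return written
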