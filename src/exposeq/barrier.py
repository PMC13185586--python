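"""Per-region logistic temperature-response model of RNA accessibility.

Each region carries a logistic "barrier": exposure rises from a baseline
``b`` by an amplitude ``a`` as temperature crosses a midpoint ``T50`` with
steepness ``k`` (degrees Celsius).  Overlapping regions are combined by
taking the position-wise maximum; unlisted positions receive a flat default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference import GenomeReference, Region


@dataclass(frozen=True)
class RegionBarrier:
    """Logistic exposure response of one region.

    exposure(T) = baseline + amplitude / (1 + exp(-(T - midpoint) / steepness))
    """

    region: Region
    baseline: float = 0.0
    amplitude: float = 1.0
    midpoint: float = 60.0
    steepness: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError(f"baseline must be in [0,1], got {self.baseline}")
        if not 0.0 <= self.amplitude <= 1.0 - self.baseline:
            raise ValueError(
                f"amplitude must be in [0, 1-baseline], got {self.amplitude} "
                f"with baseline {self.baseline}"
            )
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def exposure(self, temperature: float) -> float:
        z = (temperature - self.midpoint) / self.steepness
        return float(self.baseline + self.amplitude / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class BarrierModel:
    """Collection of region barriers plus a default exposure elsewhere."""

    barriers: tuple[RegionBarrier, ...] = ()
    default_exposure: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.default_exposure <= 1.0:
            raise ValueError("default_exposure must be in [0,1]")
        object.__setattr__(self, "barriers", tuple(self.barriers))

    @classmethod
    def from_dicts(
        cls, barriers: Sequence[Mapping], default_exposure: float = 0.0
    ) -> "BarrierModel":
        """Build from config-style dicts with a ``region: "SEG:a-b"`` key."""
        cooked = []
        for spec in barriers:
            spec = dict(spec)
            region = spec.pop("region")
            if isinstance(region, str):
                region = Region.parse(region)
            cooked.append(RegionBarrier(region=region, **spec))
        return cls(tuple(cooked), default_exposure)


@dataclass(frozen=True)
class ExposureProfile:
    """Per-position accessibility in [0,1] at one fixed temperature."""

    temperature: float
    exposures: Mapping[str, np.ndarray] = field(default_factory=dict)

    def segment(self, segment_id: str) -> np.ndarray:
        return self.exposures[segment_id]

    def validate(self, reference: GenomeReference) -> None:
        for sid, arr in self.exposures.items():
            if len(arr) != reference.length(sid):
                raise ValueError(
                    f"exposure length {len(arr)} != segment length "
                    f"{reference.length(sid)} for {sid!r}"
                )
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"exposure values outside [0,1] on {sid!r}")


def exposure_at_temperature(
    model: BarrierModel, reference: GenomeReference, temperature: float
) -> ExposureProfile:
    """Evaluate the barrier model on every position at one temperature.

    Overlapping regions on the same segment are resolved by taking the
    maximum exposure; positions in no region get ``model.default_exposure``.
    """
    if not np.isfinite(temperature):
        raise ValueError("temperature must be finite")
    exposures = {
        sid: np.full(reference.length(sid), model.default_exposure, dtype=float)
        for sid in reference.segment_ids
    }
    for barrier in model.barriers:
        region = reference.check_region(barrier.region)
        arr = exposures[region.segment_id]
        sl = region.slice0()
        arr[sl] = np.maximum(arr[sl], barrier.exposure(temperature))
    return ExposureProfile(temperature=float(temperature), exposures=exposures)
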