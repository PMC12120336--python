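"""Analysis configuration and biological constants.

Holds the tunable tolerances of the pipeline: observation-model standard
deviations for the geolocation likelihoods, the quality-control thresholds
for acoustic detections, and the behavioural thresholds (residency gap,
survival week).  All values are strictly positive; defaults are chosen for
a slow-moving bentho-demersal gadid tracked on a ~2 km grid.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

#: Length at which 50% / 95% of pollack are mature (mm total length).
LMAT50_MM = 437.0
LMAT95_MM = 553.0

#: Mean Earth radius used for all great-circle distances (km).
EARTH_RADIUS_KM = 6371.0


@dataclass
class AnalysisConfig:
    """Tolerances and thresholds shared across the pipeline.

    Parameters
    ----------
    sigma_t : float
        Standard deviation (°C) of the Gaussian temperature observation
        model: mismatch between tag-recorded and reference temperature.
    sigma_z : float
        Depth slack (m) allowed before a cell shallower than the recorded
        maximum depth is penalised.
    residency_threshold_h : float
        Gap (hours) between consecutive same-station detections above which
        a new residency period starts.
    survival_week_days : float
        Days at sea after release required for the long-term survival proxy.
    vmax : float
        Maximum plausible sustained swimming speed (m/s) for the velocity
        and release-distance QC criteria.
    isolation_window_h : float
        A detection with no same-tag neighbour within this window (hours)
        is flagged as isolated.
    snr_min : float
        Detections with a reported signal-to-noise ratio below this value
        (dB) receive a soft QC flag.
    kernel_truncation : float
        Movement-kernel support radius in multiples of sigma.
    nondetection_value : float
        Likelihood assigned to cells outside every active receiver's range
        in hours without detections.
    ping_interval_s : float
        Nominal mean random delay between transmitter emissions (s).
    """

    sigma_t: float = 1.0
    sigma_z: float = 5.0
    residency_threshold_h: float = 24.0
    survival_week_days: float = 7.0
    vmax: float = 2.0
    isolation_window_h: float = 24.0
    snr_min: float = 6.0
    kernel_truncation: float = 4.0
    nondetection_value: float = 1.0
    ping_interval_s: float = 180.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"AnalysisConfig.{f.name} must be > 0, got {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"Unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
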