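"""Ultrasonic tissue characterization (UTC) indices.

Two indices are computed from integrated-backscatter (IBS) intensity traces
sampled over the posterior myocardial wall:

* **CC-IBS** — the corrected coefficient of IBS: mean tissue IBS intensity
  divided by the mean IBS intensity of a rubber reference phantom acquired at
  the same depth. The ratio calibrates for system settings and attenuation.
* **MCV** — the magnitude of cardiac cyclic variation: the peak-to-peak
  (max - min) IBS intensity within a cardiac cycle, averaged over up to three
  consecutive complete cycles.

The ratio is taken on the dB-scale readouts of the densitometry package (the
scale on which CC-IBS values near 1.1 arise); an optional linear-power mode
converts to linear intensity before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    DivisionError,
    InputError,
    InsufficientDataError,
)

#: Default tolerance for the tissue/phantom acquisition-depth match (cm).
DEPTH_TOLERANCE_CM = 0.1

#: Number of consecutive cardiac cycles averaged, as in the exam protocol.
MAX_CYCLES = 3


@dataclass
class IBSTrace:
    """An IBS intensity trace across one or more cardiac cycles.

    Attributes
    ----------
    time_s, intensity_db:
        Sample times (strictly increasing, seconds) and IBS intensities (dB).
    depth_cm:
        Acquisition depth of the sample volume.
    heart_rate_bpm:
        Heart rate during acquisition; defines the cycle length.
    source:
        ``"tissue"`` or ``"phantom"``.
    """

    time_s: np.ndarray
    intensity_db: np.ndarray
    depth_cm: float
    heart_rate_bpm: float
    source: str = "tissue"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity_db = np.asarray(self.intensity_db, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.intensity_db.shape:
            raise InputError("time and intensity must be 1-D arrays of equal length")
        if self.time_s.size < 2:
            raise InputError("a trace needs at least two samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise InputError("sample times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity_db)):
            raise InputError("intensities must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    @property
    def duration_s(self) -> float:
        """Nominal covered duration: n samples at the median sampling step."""
        return self.time_s.size * self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.time_s.size),
                "time_s": self.time_s,
                "intensity_db": self.intensity_db,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        depth_cm: float,
        heart_rate_bpm: float,
        source: str = "tissue",
    ) -> "IBSTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            intensity_db=df["intensity_db"].to_numpy(),
            depth_cm=depth_cm,
            heart_rate_bpm=heart_rate_bpm,
            source=source,
        )


@dataclass
class UTCIndices:
    """Per-exam UTC result: calibrated intensity ratio and cyclic variation."""

    cc_ibs: float
    mcv: float
    n_cycles_used: int
    tissue_mean_db: float
    phantom_mean_db: float


def segment_cycles(trace: IBSTrace) -> List[np.ndarray]:
    """Split a trace into consecutive cardiac-cycle windows.

    Windows of length 60/heart-rate seconds tile the trace from its start;
    a partial trailing window is discarded. Returns per-cycle intensity
    arrays.
    """
    if trace.heart_rate_bpm <= 0:
        raise InputError("heart rate must be positive")
    period = 60.0 / trace.heart_rate_bpm
    dt = trace.dt
    n = trace.time_s.size
    # Small tolerance so a trace covering exactly k cycles yields k windows
    # despite floating-point accumulation in the time stamps.
    n_windows = int(np.floor(n * dt / period + 1e-9))
    if n_windows < 1:
        raise InsufficientDataError(
            f"trace covers {n * dt:.4f}s, less than one cycle ({period:.4f}s)"
        )
    samples_per_cycle = period / dt
    windows = []
    for k in range(n_windows):
        lo = int(round(k * samples_per_cycle))
        hi = int(round((k + 1) * samples_per_cycle))
        windows.append(trace.intensity_db[lo:hi])
    return windows


def compute_mcv(trace: IBSTrace, max_cycles: int = MAX_CYCLES) -> float:
    """Magnitude of cyclic variation: mean per-cycle peak-to-peak intensity (dB).

    Averaged over the first ``max_cycles`` complete cycles available
    (three by default, matching the exam's 3-cycle averaging convention).
    """
    windows = segment_cycles(trace)[:max_cycles]
    return float(np.mean([w.max() - w.min() for w in windows]))


def _trace_mean(trace: IBSTrace, linear_power: bool) -> float:
    if linear_power:
        return float(np.mean(10.0 ** (trace.intensity_db / 10.0)))
    return float(np.mean(trace.intensity_db))


def compute_cc_ibs(
    tissue: IBSTrace,
    phantom: IBSTrace,
    depth_tolerance_cm: float = DEPTH_TOLERANCE_CM,
    linear_power: bool = False,
) -> float:
    """Corrected coefficient of IBS: mean tissue / mean phantom intensity.

    The phantom must have been acquired at the same depth as the tissue
    sample (within ``depth_tolerance_cm``); a non-positive phantom mean makes
    the ratio undefined.
    """
    if abs(tissue.depth_cm - phantom.depth_cm) > depth_tolerance_cm:
        raise CalibrationError(
            f"phantom depth {phantom.depth_cm} cm does not match tissue depth "
            f"{tissue.depth_cm} cm within ±{depth_tolerance_cm} cm"
        )
    phantom_mean = _trace_mean(phantom, linear_power)
    if phantom_mean <= 0:
        raise DivisionError("phantom mean intensity must be positive")
    return _trace_mean(tissue, linear_power) / phantom_mean


def compute_indices(
    tissue: IBSTrace,
    phantom: IBSTrace,
    depth_tolerance_cm: float = DEPTH_TOLERANCE_CM,
    linear_power: bool = False,
    max_cycles: int = MAX_CYCLES,
) -> UTCIndices:
    """Compute both UTC indices for one exam."""
    cc = compute_cc_ibs(tissue, phantom, depth_tolerance_cm, linear_power)
    windows = segment_cycles(tissue)
    n_used = min(max_cycles, len(windows))
    mcv = float(np.mean([w.max() - w.min() for w in windows[:n_used]]))
    return UTCIndices(
        cc_ibs=cc,
        mcv=mcv,
        n_cycles_used=n_used,
        tissue_mean_db=_trace_mean(tissue, False),
        phantom_mean_db=_trace_mean(phantom, False),
    )
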