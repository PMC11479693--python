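"""Ca2+ oscillation scoring of sperm-injected oocytes.

Ratiometric (Fura-2-style) traces are reduced to a spike train by a
deterministic detector: a rolling-median baseline removes slow drift, noise
is estimated robustly (scaled MAD of the residual), and local maxima whose
baseline-relative height clears ``max(noise_k * sd, min_amplitude)`` are
called spikes, subject to a refractory spacing.  The per-oocyte summary is
the product A x F of the mean spike amplitude A (AU) and the mean spike
frequency F (spikes per hour), together with a count-based frequency
category ("0" .. "++++").  Mean A x F above an assay-specific threshold
(>9 AU for 2-h mouse recordings, >0.6 AU for 10-h human recordings) marks a
sperm sample as competent for normal fertilization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

__all__ = [
    "Assay",
    "CalciumTrace",
    "DetectorParams",
    "SpikeTrain",
    "OocyteScore",
    "AssayThresholds",
    "Competence",
    "detect_spikes",
    "score_oocyte",
    "categorize_count",
    "patient_summary",
    "competence_flag",
    "compare_with_control",
]


class TraceError(ValueError):
    """Invalid calcium trace or detector configuration."""


class Assay(str, Enum):
    MOCA = "MOCA"  # mouse oocytes, 2 h recordings
    HOCA = "HOCA"  # in-vitro-matured human oocytes, 10 h recordings


#: nominal recording duration per assay, hours
ASSAY_DURATION_H = {Assay.MOCA: 2.0, Assay.HOCA: 10.0}


@dataclass(frozen=True)
class CalciumTrace:
    oocyte_id: str
    assay: Assay
    times: np.ndarray  # seconds
    values: np.ndarray  # ratio units (AU)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise TraceError(f"{self.oocyte_id}: need matching 1-D arrays with >=2 samples")
        if not np.all(np.diff(times) > 0):
            raise TraceError(f"{self.oocyte_id}: times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise TraceError(f"{self.oocyte_id}: non-finite ratio values")

    @property
    def duration_hours(self) -> float:
        return float(self.times[-1] - self.times[0]) / 3600.0


@dataclass(frozen=True)
class DetectorParams:
    baseline_window: float = 300.0  # s, rolling-median span; must exceed spike width
    noise_k: float = 4.0  # prominence multiplier on the robust noise SD
    min_amplitude: float = 0.05  # AU, absolute amplitude floor
    refractory: float = 30.0  # s, minimum spacing between called spikes

    def __post_init__(self) -> None:
        if min(self.baseline_window, self.noise_k, self.refractory) <= 0:
            raise TraceError("baseline_window, noise_k and refractory must be positive")
        if self.min_amplitude < 0:
            raise TraceError("min_amplitude must be >= 0")


@dataclass(frozen=True)
class SpikeTrain:
    times: np.ndarray  # s
    amplitudes: np.ndarray  # AU, baseline-relative

    def __len__(self) -> int:
        return int(self.times.size)


class FreqCategory(str, Enum):
    NONE = "0"
    PLUS = "+"
    PLUS2 = "++"
    PLUS3 = "+++"
    PLUS4 = "++++"


@dataclass(frozen=True)
class OocyteScore:
    oocyte_id: str
    assay: Assay
    n_spikes: int
    mean_amplitude: float  # A, AU
    frequency: float  # F, spikes per hour
    category: FreqCategory

    @property
    def axf(self) -> float:
        return self.mean_amplitude * self.frequency


@dataclass(frozen=True)
class AssayThresholds:
    moca_normal: float = 9.0  # AU
    hoca_normal: float = 0.6  # AU

    def __post_init__(self) -> None:
        if self.moca_normal <= 0 or self.hoca_normal <= 0:
            raise TraceError("competence thresholds must be positive")

    def for_assay(self, assay: Assay) -> float:
        return {Assay.MOCA: self.moca_normal, Assay.HOCA: self.hoca_normal}[assay]


class Competence(str, Enum):
    NORMAL_RANGE = "normal_range"
    DEFICIENT = "deficient"


def read_traces_csv(path) -> list[CalciumTrace]:
    """Long-format trace CSV (time_s, ratio, oocyte_id, assay) -> traces."""
    df = pd.read_csv(path)
    required = {"time_s", "ratio", "oocyte_id", "assay"}
    missing = required - set(df.columns)
    if missing:
        raise TraceError(f"{path}: missing column(s) {sorted(missing)}")
    traces = []
    for oocyte_id, group in df.groupby("oocyte_id", sort=False):
        assays = group["assay"].unique()
        if len(assays) != 1:
            raise TraceError(f"{path}: oocyte {oocyte_id} spans multiple assays")
        group = group.sort_values("time_s")
        traces.append(
            CalciumTrace(
                oocyte_id=str(oocyte_id),
                assay=Assay(assays[0]),
                times=group["time_s"].to_numpy(float),
                values=group["ratio"].to_numpy(float),
            )
        )
    return traces


def traces_to_csv(traces: Sequence[CalciumTrace], path) -> None:
    """Inverse of :func:`read_traces_csv`."""
    frames = [
        pd.DataFrame(
            {
                "time_s": t.times,
                "ratio": t.values,
                "oocyte_id": t.oocyte_id,
                "assay": t.assay.value,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _rolling_median(values: np.ndarray, window_samples: int) -> np.ndarray:
    window_samples = max(3, int(window_samples))
    if window_samples % 2 == 0:
        window_samples += 1
    return ndimage.median_filter(values, size=window_samples, mode="nearest")


def detect_spikes(trace: CalciumTrace, params: DetectorParams | None = None) -> SpikeTrain:
    """Call spikes in one trace; deterministic for fixed input.

    Amplitude of a spike is peak value minus the local rolling-median
    baseline, which makes scoring invariant to constant offsets and robust
    to slow drift.
    """
    params = params or DetectorParams()
    dt = float(np.median(np.diff(trace.times)))
    baseline = _rolling_median(trace.values, round(params.baseline_window / dt))
    residual = trace.values - baseline
    # robust noise SD: scaled median absolute deviation of the residual
    noise_sd = float(stats.median_abs_deviation(residual, scale="normal"))
    threshold = max(params.noise_k * noise_sd, params.min_amplitude)
    distance = max(1, round(params.refractory / dt))
    # prominence alongside height: a noise bump riding a decaying tail has
    # height above baseline but negligible prominence, so is not re-counted
    peaks, _ = signal.find_peaks(
        residual, height=threshold, prominence=threshold, distance=distance
    )
    return SpikeTrain(times=trace.times[peaks], amplitudes=residual[peaks])


def categorize_count(n_spikes: int) -> FreqCategory:
    """Frequency category from the spike count over the full recording."""
    if n_spikes < 0 or int(n_spikes) != n_spikes:
        raise TraceError(f"spike count must be a non-negative integer, got {n_spikes}")
    n = int(n_spikes)
    if n == 0:
        return FreqCategory.NONE
    if n <= 2:
        return FreqCategory.PLUS
    if n <= 9:
        return FreqCategory.PLUS2
    if n <= 20:
        return FreqCategory.PLUS3
    return FreqCategory.PLUS4


def score_oocyte(trace: CalciumTrace, params: DetectorParams | None = None) -> OocyteScore:
    """A, F (per hour), A x F and category for one oocyte."""
    spikes = detect_spikes(trace, params)
    n = len(spikes)
    duration = trace.duration_hours
    if duration <= 0:
        raise TraceError(f"{trace.oocyte_id}: zero-duration trace")
    mean_amp = float(np.mean(spikes.amplitudes)) if n else 0.0
    freq = n / duration
    return OocyteScore(
        oocyte_id=trace.oocyte_id,
        assay=trace.assay,
        n_spikes=n,
        mean_amplitude=mean_amp,
        frequency=freq,
        category=categorize_count(n),
    )


def patient_summary(scores: Sequence[OocyteScore]) -> dict[str, object]:
    """n oocytes, mean A x F and category histogram for one patient sample."""
    if not scores:
        raise TraceError("patient_summary requires at least one oocyte score")
    counts = {cat: 0 for cat in FreqCategory}
    for s in scores:
        counts[s.category] += 1
    return {
        "n": len(scores),
        "mean_axf": float(np.mean([s.axf for s in scores])),
        "category_counts": {cat.value: n for cat, n in counts.items()},
    }


def competence_flag(
    mean_axf: float,
    assay: Assay | str,
    thresholds: AssayThresholds | None = None,
) -> Competence:
    """Normal-range iff mean A x F strictly exceeds the assay threshold."""
    if mean_axf < 0:
        raise TraceError(f"mean A x F must be >= 0, got {mean_axf}")
    thresholds = thresholds or AssayThresholds()
    limit = thresholds.for_assay(Assay(assay))
    return Competence.NORMAL_RANGE if mean_axf > limit else Competence.DEFICIENT


def compare_with_control(
    patient_axf: Sequence[float],
    control_axf: Sequence[float],
    alpha: float = 0.05,
) -> dict[str, object]:
    """Patient-vs-control comparison, normality-gated.

    Shapiro-Wilk on both samples at ``alpha``: if both look normal, a
    two-sided two-sample t-test; otherwise a two-sided Mann-Whitney U.
    Degenerate (constant) samples cannot be tested for normality and fall
    back to the rank test with a warning.
    """
    x = np.asarray(patient_axf, dtype=float)
    y = np.asarray(control_axf, dtype=float)
    if x.size < 3 or y.size < 3:
        raise TraceError("compare_with_control needs >=3 values per sample")
    degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
    if degenerate:
        warnings.warn(
            "constant sample: normality not assessable, using rank test", stacklevel=2
        )
        normal = False
    else:
        normal = (
            stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha
        )
    if normal:
        test_used = "t_test"
        p_value = float(stats.ttest_ind(x, y).pvalue)
    else:
        test_used = "mann_whitney"
        p_value = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return {"test_used": test_used, "p_value": p_value, "significant": bool(p_value < alpha)}
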