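"""Seeded synthetic inputs for every pipeline stage.

Three generators mirror the statistical structure of the real inputs:

* :func:`simulate_trace` — Fura-2-style ratio traces: baseline + linear
  drift + Poisson-timed instant-rise/exponential-decay spikes (refractory-
  thinned) + i.i.d. Gaussian noise, with the ground-truth spike train
  returned for detector-recovery tests.
* :func:`simulate_cohort` — binomial fertilization and Bernoulli pregnancy
  outcomes per treatment cycle at configurable per-arm rates; the defaults
  are the observed rates of the study cohort (fertilization 0.11 ICSI vs
  0.62 ICSI-AOA, etc.).
* :func:`simulate_evidence` — random ACMG evidence sets with known net
  point totals for round-trip tests of the Bayesian classifier.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acmg import Direction, EvidenceItem, Strength
from .calcium import Assay, CalciumTrace, SpikeTrain
from .outcomes import Arm, CycleRecord, Outcome, SpermCellAnnotation

__all__ = [
    "TraceSimParams",
    "CohortSimParams",
    "simulate_trace",
    "simulate_cohort",
    "simulate_evidence",
    "evidence_for_points",
    "synthetic_sperm_cells",
]


class SimConfigError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class TraceSimParams:
    duration_h: float = 2.0
    dt: float = 1.0  # s
    baseline: float = 1.0  # AU
    drift_per_hour: float = 0.0  # AU/h
    spike_rate: float = 3.0  # events/h
    refractory: float = 60.0  # s
    amplitude_mean: float = 1.0  # AU
    amplitude_sd: float = 0.0  # AU (draws truncated > 0)
    decay_tau: float = 15.0  # s
    noise_sd: float = 0.0  # AU

    def __post_init__(self) -> None:
        if min(self.duration_h, self.dt, self.decay_tau, self.amplitude_mean) <= 0:
            raise SimConfigError("duration, dt, decay_tau and amplitude_mean must be positive")
        if self.spike_rate < 0 or self.noise_sd < 0 or self.amplitude_sd < 0:
            raise SimConfigError("rates and SDs must be non-negative")
        if self.dt >= self.refractory:
            raise SimConfigError("dt must be smaller than the refractory period")


def _poisson_times(rng: np.random.Generator, rate_per_h: float, duration_s: float,
                   refractory_s: float) -> np.ndarray:
    if rate_per_h == 0:
        return np.empty(0)
    rate_per_s = rate_per_h / 3600.0
    times = []
    t = rng.exponential(1.0 / rate_per_s)
    while t < duration_s:
        if not times or t - times[-1] >= refractory_s:
            times.append(t)
        t += rng.exponential(1.0 / rate_per_s)
    return np.asarray(times)


def _truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float,
                               size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    draws = rng.normal(mean, sd, size)
    while np.any(draws <= 0):
        bad = draws <= 0
        draws[bad] = rng.normal(mean, sd, int(bad.sum()))
    return draws


def simulate_trace(
    params: TraceSimParams,
    seed: int,
    oocyte_id: str = "sim",
    assay: Assay = Assay.MOCA,
    schedule: list[tuple[float, float]] | None = None,
) -> tuple[CalciumTrace, SpikeTrain]:
    """One synthetic trace plus its ground-truth spike train.

    ``schedule`` (time_s, amplitude) overrides the Poisson draw for
    closed-form recovery tests.  The spike kernel is an instantaneous rise
    followed by exponential decay, truncated at 6 decay constants: the
    finite support (90 s at the default tau) stays below half the default
    rolling-median window, which keeps the local baseline of well-separated
    spikes exact and noiseless recovery lossless.
    """
    rng = np.random.default_rng(seed)
    duration_s = params.duration_h * 3600.0
    times = np.arange(0.0, duration_s + params.dt / 2, params.dt)
    values = np.full_like(times, params.baseline)
    values += params.drift_per_hour * times / 3600.0

    if schedule is None:
        spike_times = _poisson_times(rng, params.spike_rate, duration_s, params.refractory)
        amplitudes = _truncated_positive_normal(
            rng, params.amplitude_mean, params.amplitude_sd, spike_times.size
        )
    else:
        spike_times = np.asarray([t for t, _ in schedule], dtype=float)
        amplitudes = np.asarray([a for _, a in schedule], dtype=float)
    # snap onsets to the sampling grid: rises are only observable at frame
    # times, and grid-aligned onsets make noiseless recovery exact
    spike_times = np.round(spike_times / params.dt) * params.dt
    keep = spike_times <= duration_s
    spike_times, amplitudes = spike_times[keep], amplitudes[keep]

    support = 6.0 * params.decay_tau
    for t0, amp in zip(spike_times, amplitudes):
        mask = (times >= t0) & (times < t0 + support)
        values[mask] += amp * np.exp(-(times[mask] - t0) / params.decay_tau)

    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, values.shape)

    trace = CalciumTrace(oocyte_id=oocyte_id, assay=assay, times=times, values=values)
    return trace, SpikeTrain(times=spike_times, amplitudes=amplitudes)


@dataclass(frozen=True)
class CohortSimParams:
    """Per-arm outcome rates; defaults follow the study cohort's observed rates."""

    n_patients: int = 19
    cycles_per_patient: tuple[int, int] = (1, 4)  # inclusive range, per arm
    mii_per_cycle: tuple[int, int] = (4, 18)  # inclusive range
    fert_rate: dict[Arm, float] = field(
        default_factory=lambda: {Arm.ICSI: 0.11, Arm.ICSI_AOA: 0.62}
    )
    hcg_rate: dict[Arm, float] = field(
        default_factory=lambda: {Arm.ICSI: 0.11, Arm.ICSI_AOA: 0.60}
    )
    lb_given_hcg: float = 0.62
    blastocyst_rate: float = 0.66  # per 2PN, ICSI-AOA cycles with culture

    def __post_init__(self) -> None:
        rates = [*self.fert_rate.values(), *self.hcg_rate.values(),
                 self.lb_given_hcg, self.blastocyst_rate]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise SimConfigError("all rates must lie in [0, 1]")
        if self.n_patients < 1:
            raise SimConfigError("need at least one patient")


def simulate_cohort(params: CohortSimParams, seed: int) -> list[CycleRecord]:
    """Cycle records for both arms of a synthetic cohort."""
    rng = np.random.default_rng(seed)
    lo_c, hi_c = params.cycles_per_patient
    lo_m, hi_m = params.mii_per_cycle
    records: list[CycleRecord] = []
    for i in range(params.n_patients):
        pid = f"S{i + 1}"
        for arm in (Arm.ICSI, Arm.ICSI_AOA):
            n_cycles = int(rng.integers(lo_c, hi_c + 1))
            for j in range(n_cycles):
                mii = int(rng.integers(lo_m, hi_m + 1))
                two_pn = int(rng.binomial(mii, params.fert_rate[arm]))
                hcg = int(rng.random() < params.hcg_rate[arm])
                outcomes: tuple[Outcome, ...] = ()
                if hcg and rng.random() < params.lb_given_hcg:
                    outcomes = (Outcome.LIVE_BIRTH,)
                blasts = None
                if arm is Arm.ICSI_AOA:
                    blasts = int(rng.binomial(two_pn, params.blastocyst_rate))
                records.append(
                    CycleRecord(
                        patient_id=pid,
                        arm=arm,
                        mii=mii,
                        two_pn=two_pn,
                        blastocysts=blasts,
                        hcg_positive=hcg,
                        outcomes=outcomes,
                    )
                )
    return records


_STRENGTHS = [Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG, Strength.VERY_STRONG]
_PATH_CODE = {
    Strength.SUPPORTING: "PP3",
    Strength.MODERATE: "PM2",
    Strength.STRONG: "PS3",
    Strength.VERY_STRONG: "PVS1",
}
_BENIGN_CODE = {
    Strength.SUPPORTING: "BP4",
    Strength.MODERATE: "BS3",  # modified strength, code decoupled
    Strength.STRONG: "BS3",
    Strength.VERY_STRONG: "BS3",
}


def simulate_evidence(
    n_variants: int,
    strength_distribution: dict[Strength, float],
    seed: int,
    p_pathogenic: float = 0.7,
    items_per_variant: tuple[int, int] = (0, 6),
) -> list[list[EvidenceItem]]:
    """Random evidence sets; net points follow from the items themselves."""
    probs = np.asarray([strength_distribution.get(s, 0.0) for s in _STRENGTHS], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise SimConfigError("strength_distribution must sum to 1")
    rng = np.random.default_rng(seed)
    sets: list[list[EvidenceItem]] = []
    for _ in range(n_variants):
        n_items = int(rng.integers(items_per_variant[0], items_per_variant[1] + 1))
        items = []
        for _ in range(n_items):
            strength = _STRENGTHS[int(rng.choice(len(_STRENGTHS), p=probs))]
            if rng.random() < p_pathogenic:
                items.append(EvidenceItem(_PATH_CODE[strength], Direction.PATHOGENIC, strength))
            else:
                items.append(EvidenceItem(_BENIGN_CODE[strength], Direction.BENIGN, strength))
        sets.append(items)
    return sets


def evidence_for_points(n_points: int) -> list[EvidenceItem]:
    """A minimal generic evidence set totalling ``n_points``.

    Greedy decomposition into 8/4/2/1-point items; pathogenic codes for
    positive totals, benign for negative.  Used where only a net point
    total is recoverable (e.g. published posterior probabilities without
    itemized criteria).
    """
    direction = Direction.PATHOGENIC if n_points >= 0 else Direction.BENIGN
    codes = _PATH_CODE if n_points >= 0 else _BENIGN_CODE
    remaining = abs(n_points)
    items: list[EvidenceItem] = []
    for strength in (Strength.VERY_STRONG, Strength.STRONG, Strength.MODERATE, Strength.SUPPORTING):
        worth = {Strength.VERY_STRONG: 8, Strength.STRONG: 4,
                 Strength.MODERATE: 2, Strength.SUPPORTING: 1}[strength]
        while remaining >= worth:
            items.append(EvidenceItem(codes[strength], direction, strength))
            remaining -= worth
    return items


# --- synthetic sperm-cell annotation tables --------------------------------

# count pairs (events/cells) consistent with the published per-sample summary
# rates; the per-cell values themselves are synthetic stand-ins.
_TEM_COUNTS = {  # detached / intact cells imaged by TEM
    "CONTROL": (10, 30),
    "P29": (25, 28),
    "P32": (10, 26),
    "P34": (13, 29),
    "P46": (14, 22),
    "P54": (15, 24),
}
_IF_COUNTS = {  # expressing (weak+obvious) / intact cells imaged by IF
    "CONTROL": (34, 51),
    "P29": (14, 57),
    "P32": (43, 64),
    "P46": (8, 51),
    "P54": (30, 51),
}


def synthetic_sperm_cells() -> dict[str, dict[str, list[SpermCellAnnotation]]]:
    """Synthetic per-cell TEM and immunofluorescence annotation tables.

    Deterministic reconstruction: cell counts match the published summary
    rates exactly; per-cell measurements (detachment fractions, intensities)
    are plausible synthetic values, not observed data.  Intended thresholds
    for the IF classes: invisible <= 10 AU, obvious >= 50 AU after
    background correction.
    """
    samples: dict[str, dict[str, list[SpermCellAnnotation]]] = {}
    for sample, (detached, total) in _TEM_COUNTS.items():
        cells = []
        for i in range(total):
            if i < detached:
                folded = i % 2 == 0
                cells.append(
                    SpermCellAnnotation(
                        cell_id=f"{sample}-tem-{i + 1}",
                        acrosome_intact=True,
                        detachment_fraction=0.75 if folded else 0.55,
                        folded_curved=folded,
                    )
                )
            else:
                cells.append(
                    SpermCellAnnotation(
                        cell_id=f"{sample}-tem-{i + 1}",
                        acrosome_intact=True,
                        detachment_fraction=0.10,
                    )
                )
        samples.setdefault(sample, {})["tem"] = cells
    for sample, (expressing, total) in _IF_COUNTS.items():
        cells = []
        for i in range(total):
            if i < expressing:
                # alternate weak / obvious signal
                intensity = 5.0 + (35.0 if i % 2 else 85.0)
            else:
                intensity = 5.0 + 2.0
            cells.append(
                SpermCellAnnotation(
                    cell_id=f"{sample}-if-{i + 1}",
                    acrosome_intact=True,
                    detachment_fraction=0.0,
                    if_intensity=intensity,
                    if_background=5.0,
                )
            )
        samples.setdefault(sample, {})["if"] = cells
    return samples
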