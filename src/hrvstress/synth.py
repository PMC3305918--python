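"""Synthetic paired rest/stress RR cohorts for end-to-end testing.

Each 5-minute record is a sum of a session mean, a slow 0.1 Hz oscillation
(long-term spread), a respiratory-frequency oscillation, and AR(1) noise:

    RR_i = mean_rr + A_lf sin(2*pi*0.1*t_i + phi1)
                   + A_hf sin(2*pi*f_resp*t_i + phi2) + e_i

with e_i = ar * e_{i-1} + innovation.  Stress sessions have a shorter mean
RR, a much smaller slow-oscillation amplitude and weaker, more persistent
noise, which lowers long-term variability and complexity and raises
recurrence — the qualitative direction pattern the paired analysis
expects.  Magnitudes are not calibrated to any particular cohort.

Randomness is counter-based: every (seed, subject, session) triple derives
an independent stream, so adding subjects never perturbs existing records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .rr_io import NORMAL_LABEL, RRSeries

_SESSION_CODE = {"rest": 0, "stress": 1}
ECTOPIC_LABEL = "V"


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration; defaults give a clearly separable cohort."""

    n_subjects: int = 42
    duration: float = 300.0           # seconds of recording per session
    rest_mean_rr: float = 0.85        # seconds
    stress_mean_rr: float = 0.75
    lf_amplitude_rest: float = 0.055  # slow 0.1 Hz oscillation, seconds
    lf_amplitude_stress: float = 0.006
    hf_amplitude_rest: float = 0.016  # respiratory oscillation, seconds
    hf_amplitude_stress: float = 0.025
    respiratory_freq: float = 0.30    # Hz
    ar_coeff_rest: float = 0.3
    ar_coeff_stress: float = 0.95
    noise_sd_rest: float = 0.014      # AR(1) innovation SD, seconds
    noise_sd_stress: float = 0.001
    # random-walk step (radians/beat) on the respiratory phase; a slow
    # breathing-rate drift that shortens long diagonal recurrences without
    # changing local regularity
    resp_phase_drift_rest: float = 0.0
    resp_phase_drift_stress: float = 0.10
    ectopic_rate: float = 0.01
    between_subject_sd: float = 0.15  # multiplicative jitter on amplitudes
    seed: int = 0
    #: testing hook: lifts the 0.1 cap on ectopic_rate when True
    allow_high_ectopic_rate: bool = field(default=False, compare=False)

    def __post_init__(self):
        positive = {
            "duration": self.duration,
            "rest_mean_rr": self.rest_mean_rr,
            "stress_mean_rr": self.stress_mean_rr,
            "respiratory_freq": self.respiratory_freq,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValidationError(f"{name} must be > 0, got {value}")
        nonnegative = {
            "lf_amplitude_rest": self.lf_amplitude_rest,
            "lf_amplitude_stress": self.lf_amplitude_stress,
            "hf_amplitude_rest": self.hf_amplitude_rest,
            "hf_amplitude_stress": self.hf_amplitude_stress,
            "noise_sd_rest": self.noise_sd_rest,
            "noise_sd_stress": self.noise_sd_stress,
            "resp_phase_drift_rest": self.resp_phase_drift_rest,
            "resp_phase_drift_stress": self.resp_phase_drift_stress,
            "between_subject_sd": self.between_subject_sd,
        }
        for name, value in nonnegative.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        for name, value in (("ar_coeff_rest", self.ar_coeff_rest),
                            ("ar_coeff_stress", self.ar_coeff_stress)):
            if not 0.0 <= value < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1), got {value}")
        cap = 1.0 if self.allow_high_ectopic_rate else 0.1
        if not 0.0 <= self.ectopic_rate <= cap:
            raise ValidationError(
                f"ectopic_rate must lie in [0, {cap}], got {self.ectopic_rate}")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")

    def with_(self, **updates) -> "SyntheticParams":
        return replace(self, **updates)


def _subject_rng(params: SyntheticParams, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), int(subject_index)]))

def _session_rng(params: SyntheticParams, subject_index: int,
                 session: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [int(params.seed), int(subject_index), _SESSION_CODE[session]]))


def _subject_profile(params: SyntheticParams, subject_index: int) -> dict:
    """Per-subject jitter and phases, shared by both sessions."""
    rng = _subject_rng(params, subject_index)
    jitter = np.clip(
        1.0 + params.between_subject_sd * rng.standard_normal(3), 0.1, None)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=2)
    return {
        "lf_jitter": float(jitter[0]),
        "hf_jitter": float(jitter[1]),
        "noise_jitter": float(jitter[2]),
        "phi_lf": float(phases[0]),
        "phi_hf": float(phases[1]),
    }


#: floor keeping generated intervals physiologically positive
_MIN_RR = 0.25


def generate_session(params: SyntheticParams, subject_index: int,
                     session: str) -> RRSeries:
    """One synthetic 5-minute record, deterministic in (seed, subject, session)."""
    if session not in _SESSION_CODE:
        raise ValidationError(f"unknown session {session!r}")
    profile = _subject_profile(params, subject_index)
    rng = _session_rng(params, subject_index, session)
    if session == "rest":
        mean_rr = params.rest_mean_rr
        lf_amp = params.lf_amplitude_rest * profile["lf_jitter"]
        ar = params.ar_coeff_rest
        innovation_sd = params.noise_sd_rest * profile["noise_jitter"]
        hf_amp = params.hf_amplitude_rest * profile["hf_jitter"]
        phase_drift_sd = params.resp_phase_drift_rest
    else:
        mean_rr = params.stress_mean_rr
        lf_amp = params.lf_amplitude_stress * profile["lf_jitter"]
        ar = params.ar_coeff_stress
        innovation_sd = params.noise_sd_stress * profile["noise_jitter"]
        hf_amp = params.hf_amplitude_stress * profile["hf_jitter"]
        phase_drift_sd = params.resp_phase_drift_stress

    intervals: list[float] = []
    labels: list[str] = []
    t = 0.0
    noise = 0.0
    phase_walk = 0.0
    while t < params.duration:
        noise = ar * noise + innovation_sd * rng.standard_normal()
        if phase_drift_sd > 0:
            phase_walk += phase_drift_sd * rng.standard_normal()
        rr = (mean_rr
              + lf_amp * math.sin(2.0 * math.pi * 0.1 * t + profile["phi_lf"])
              + hf_amp * math.sin(2.0 * math.pi * params.respiratory_freq * t
                                  + profile["phi_hf"] + phase_walk)
              + noise)
        label = NORMAL_LABEL
        if params.ectopic_rate > 0 and rng.random() < params.ectopic_rate:
            label = ECTOPIC_LABEL
            rr *= 1.0 + 0.3 * (1.0 if rng.random() < 0.5 else -1.0)
        rr = max(rr, _MIN_RR)
        intervals.append(rr)
        labels.append(label)
        t += rr
    return RRSeries(np.asarray(intervals), np.asarray(labels, dtype=object),
                    subject_id=f"S{subject_index:03d}", session=session)


def generate_cohort(params: SyntheticParams) -> list[RRSeries]:
    """n_subjects paired records; rest precedes stress for each subject."""
    records = []
    for subject in range(params.n_subjects):
        records.append(generate_session(params, subject, "rest"))
        records.append(generate_session(params, subject, "stress"))
    return records
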