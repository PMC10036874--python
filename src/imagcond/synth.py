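"""Synthetic participants: SCR traces, ROI patterns, BOLD runs, ratings.

The generator emulates the statistical structure the analysis pipeline
assumes: event-locked electrodermal responses whose amplitude depends on CS
type, trial-wise ROI voxel patterns in which CS+ and CS− class means are
separated along modality-specific discriminative directions that share a
controllable fraction of their energy between viewing and imagining, BOLD
run time series built from known trial betas plus AR(1) noise, and 7-point
Likert fear ratings from a thresholded latent normal.  Every artifact is a
deterministic function of (config, participant, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from . import design as _design
from .design import (
    CSType,
    Modality,
    Phase,
    TrialEvent,
    TrialSchedule,
    conditioned_modality,
    select_analysis_trials,
)
from .glm import DesignMatrix, PatternDataset, build_trialwise_design, labels_for_events

__all__ = [
    "SynthConfig",
    "SCRTrace",
    "ParticipantBasis",
    "participant_basis",
    "simulate_scr_trace",
    "simulate_pattern_dataset",
    "simulate_bold_run",
    "simulate_ratings",
    "BoldSimulation",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort.

    Defaults describe the emulated study: 27 participants, a 248-voxel
    anterior-insula ROI, 50% reinforcement handled by the design module,
    a moderate CS+/CS− pattern separation partially shared between view and
    imagine modalities, differential SCR amplitudes, and a CS+ shift on the
    latent fear-rating scale.
    """

    n_participants: int = 27
    seed: int = 0

    # voxel patterns
    roi_n_voxels: int = 248
    pattern_effect: float = 0.8  # class-mean separation in noise-sd units
    shared_fraction: float = 0.6  # energy shared between view/imagine directions
    pattern_noise_sd: float = 1.0
    participant_effect_sd: float = 0.2  # normal hyperprior on pattern_effect

    # skin conductance (µS)
    scr_amp_csplus: float = 0.4
    scr_amp_csminus: float = 0.15
    scr_amp_us: float = 0.6  # extra response on reinforced trials
    scr_zero_prob: float = 0.25
    scr_noise_sd: float = 0.01
    scr_sampling_rate: float = 100.0  # Hz; the scorer is rate-agnostic
    scr_tonic: float = 2.0  # µS baseline level
    scr_drift: float = 0.002  # µS/s linear tonic drift
    participant_amp_sd: float = 0.08

    # BOLD
    bold_noise_sd: float = 1.0
    ar1_coef: float = 0.3
    tr: float = _design.TR

    # ratings (7-point Likert)
    rating_shift: float = 1.8  # latent shift for conditioned-modality CS+
    rating_generalization: float = 0.5  # fraction of the shift transferring
    rating_baseline: float = 2.5  # latent mean for CS− conditions
    rating_noise_sd: float = 1.2
    rating_participant_sd: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.scr_zero_prob <= 1.0):
            raise ValueError("scr_zero_prob must lie in [0, 1]")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.roi_n_voxels < 1:
            raise ValueError("roi_n_voxels must be >= 1")
        for name in ("scr_amp_csplus", "scr_amp_csminus", "scr_amp_us"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (-1.0 < self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass
class SCRTrace:
    """A conductance time series (µS) for one run."""

    sampling_rate: float
    values: np.ndarray
    event_onsets: np.ndarray

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.values)) / self.sampling_rate
        return pd.DataFrame({"time": t, "conductance": self.values})


def _seed_key(config: SynthConfig, participant_id: str, *salts: int) -> list[int]:
    import zlib

    return [int(config.seed), zlib.crc32(participant_id.encode()), *[int(s) for s in salts]]


@dataclass
class ParticipantBasis:
    """Per-participant latent quantities shared across phases and runs.

    The discriminative directions live in ROI voxel space: ``u_view`` and
    ``u_imagine`` are unit vectors built from a shared component and
    modality-specific components so that their inner product equals
    ``shared_fraction``.  Random effects perturb the pattern separation, the
    SCR amplitudes, and the latent rating intercept.
    """

    participant_id: str
    u_view: np.ndarray
    u_imagine: np.ndarray
    pattern_effect: float
    scr_amp_offset: float
    rating_intercept: float


def participant_basis(config: SynthConfig, participant_id: str) -> ParticipantBasis:
    rng = np.random.default_rng(_seed_key(config, participant_id, 101))
    p = config.roi_n_voxels
    if p >= 3:
        raw = rng.standard_normal((p, 3))
        q, _ = np.linalg.qr(raw)
        u_shared, u_view_spec, u_imag_spec = q[:, 0], q[:, 1], q[:, 2]
    else:
        # degenerate tiny-ROI fallback: orthogonality not representable
        u_shared = rng.standard_normal(p)
        u_shared /= np.linalg.norm(u_shared)
        u_view_spec = u_imag_spec = u_shared
    s = math.sqrt(config.shared_fraction)
    c = math.sqrt(1.0 - config.shared_fraction)
    u_view = s * u_shared + c * u_view_spec
    u_imag = s * u_shared + c * u_imag_spec
    effect = max(0.0, config.pattern_effect + config.participant_effect_sd * rng.standard_normal())
    amp_offset = config.participant_amp_sd * rng.standard_normal()
    intercept = config.rating_participant_sd * rng.standard_normal()
    return ParticipantBasis(
        participant_id=participant_id,
        u_view=u_view,
        u_imagine=u_imag,
        pattern_effect=effect,
        scr_amp_offset=amp_offset,
        rating_intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Skin conductance

_KERNEL_RISE_CENTER = 2.2  # s, sigmoid midpoint
_KERNEL_RISE_SCALE = 0.3  # s
_KERNEL_DECAY_TAU = 4.0  # s


def scr_response_kernel(fs: float, duration: float = 12.0) -> np.ndarray:
    """Unit-peak event kernel: sigmoid rise times exponential decay.

    Parameters place the peak near 3 s after event onset, inside the 1–6 s
    scoring window.
    """
    t = np.arange(0.0, duration, 1.0 / fs)
    rise = 1.0 / (1.0 + np.exp(-(t - _KERNEL_RISE_CENTER) / _KERNEL_RISE_SCALE))
    decay = np.exp(-t / _KERNEL_DECAY_TAU)
    k = rise * decay
    return k / k.max()


def simulate_scr_trace(
    schedule_run: Sequence[TrialEvent],
    config: SynthConfig,
    basis: ParticipantBasis | None = None,
    run_duration: float | None = None,
) -> SCRTrace:
    """One run's conductance trace with condition-dependent event responses.

    Each trial contributes, with probability ``1 − scr_zero_prob``, an
    event-locked response whose amplitude is the condition mean (CS+ vs CS−,
    plus an unconditioned-response increment on shock trials) adjusted by the
    participant's random effect; smooth Gaussian noise and a linear tonic
    drift ride on a constant baseline.
    """
    events = list(schedule_run)
    if not events:
        raise ValueError("empty run")
    if config.scr_sampling_rate < 10:
        raise ValueError("sampling rate must be at least 10 Hz")
    phase = events[0].phase
    run_index = events[0].run_index
    if run_duration is None:
        run_duration = (
            _design.ACQUISITION_RUN_DURATION
            if any(e.reinforced for e in events) or len(events) == _design.N_ACQ_TRIALS
            else _design.HABITUATION_RUN_DURATION
        )
    pid = basis.participant_id if basis is not None else ""
    amp_offset = basis.scr_amp_offset if basis is not None else 0.0
    phase_key = 0 if Phase(phase) is Phase.IMAGERY_ACQUISITION else 1
    rng = np.random.default_rng(_seed_key(config, pid, 201, phase_key, run_index))

    fs = config.scr_sampling_rate
    n = int(round(run_duration * fs)) + 1
    t = np.arange(n) / fs
    values = config.scr_tonic + config.scr_drift * t
    kernel = scr_response_kernel(fs)
    for ev in events:
        amp = config.scr_amp_csplus if ev.cs_type is CSType.CSPLUS else config.scr_amp_csminus
        if ev.reinforced:
            amp += config.scr_amp_us
        if amp > 0:
            amp = max(0.0, amp + amp_offset)
        responds = rng.uniform() >= config.scr_zero_prob
        if not responds or amp == 0.0:
            continue
        i0 = int(round(ev.onset * fs))
        seg = kernel[: n - i0]
        values[i0 : i0 + len(seg)] += amp * seg
    if config.scr_noise_sd > 0:
        noise = rng.standard_normal(n)
        noise = gaussian_filter1d(noise, sigma=0.2 * fs)  # ~200 ms smoothness
        noise *= config.scr_noise_sd / noise.std()
        values = values + noise
    return SCRTrace(
        sampling_rate=fs,
        values=values,
        event_onsets=np.array([ev.onset for ev in events]),
    )


# ---------------------------------------------------------------------------
# Voxel patterns


def simulate_pattern_dataset(
    schedule: TrialSchedule,
    config: SynthConfig,
    basis: ParticipantBasis | None = None,
) -> PatternDataset:
    """Trial-wise ROI patterns for the analysis trials of one phase.

    Row for a trial of modality *m* and CS type *c*:
    ``±(effect/2)·u_m + noise`` with isotropic Gaussian noise, where the sign
    is + for CS+ and − for CS−.  ``basis`` carries the participant's
    directions; passing the same basis for both phases makes the
    representation transfer across phases, which is what cross-phase
    classification probes.
    """
    if schedule.kind != "acquisition":
        raise ValueError("pattern simulation requires an acquisition schedule")
    pid = basis.participant_id if basis is not None else schedule.participant_id
    if basis is None:
        basis = participant_basis(config, pid)
    trials = sorted(
        select_analysis_trials(schedule, Modality.IMAGINE)
        + select_analysis_trials(schedule, Modality.VIEW),
        key=lambda ev: (ev.run_index, ev.trial_index),
    )
    phase_key = 0 if Phase(schedule.phase) is Phase.IMAGERY_ACQUISITION else 1
    rng = np.random.default_rng(_seed_key(config, pid, 301, phase_key))
    rows = np.empty((len(trials), config.roi_n_voxels))
    half = 0.5 * basis.pattern_effect
    for i, ev in enumerate(trials):
        u = basis.u_imagine if ev.modality is Modality.IMAGINE else basis.u_view
        sign = 1.0 if ev.cs_type is CSType.CSPLUS else -1.0
        rows[i] = sign * half * u + config.pattern_noise_sd * rng.standard_normal(
            config.roi_n_voxels
        )
    labels = labels_for_events(trials, participant_id=pid)
    return PatternDataset(rows, labels)


def simulate_cohort_patterns(
    config: SynthConfig, participant_ids: Sequence[str] | None = None
) -> dict[str, PatternDataset]:
    """Both phases' pattern datasets for every participant in the cohort.

    Each participant gets their own acquisition schedules (seeded from the
    config seed) and a single basis shared across phases, concatenated into
    one labeled PatternDataset — the input shape the decoding layer expects.
    """
    if participant_ids is None:
        participant_ids = [f"sub-{i + 1:02d}" for i in range(config.n_participants)]
    cohort = {}
    for pid in participant_ids:
        basis = participant_basis(config, pid)
        parts = []
        for phase in (Phase.IMAGERY_ACQUISITION, Phase.VISUAL_ACQUISITION):
            schedule = _design.build_acquisition_schedule(phase, pid, config.seed)
            parts.append(simulate_pattern_dataset(schedule, config, basis=basis))
        cohort[pid] = PatternDataset.concat(parts)
    return cohort


# ---------------------------------------------------------------------------
# BOLD


@dataclass
class BoldSimulation:
    time_series: np.ndarray  # volumes × voxels
    true_betas: np.ndarray  # regressors × voxels (matches design columns)
    design: DesignMatrix


def simulate_bold_run(
    schedule_run: Sequence[TrialEvent],
    config: SynthConfig,
    n_voxels: int = 10,
    true_betas: np.ndarray | None = None,
    run_duration: float | None = None,
    seed_salt: int = 0,
) -> BoldSimulation:
    """BOLD time series from known betas: ``Y = X·B + AR(1) noise``.

    The design is the same trial-wise matrix the estimator uses, so the
    recorded ``true_betas`` support exact recovery checks in the noiseless
    limit.
    """
    events = list(schedule_run)
    if not events:
        raise ValueError("empty run")
    if run_duration is None:
        run_duration = (
            _design.ACQUISITION_RUN_DURATION
            if len(events) == _design.N_ACQ_TRIALS
            else _design.HABITUATION_RUN_DURATION
        )
    n_volumes = int(round(run_duration / config.tr))
    dm = build_trialwise_design(events, config.tr, n_volumes)
    rng = np.random.default_rng([int(config.seed), 401, int(seed_salt), events[0].run_index])
    n_cols = dm.matrix.shape[1]
    if true_betas is None:
        true_betas = rng.standard_normal((n_cols, n_voxels))
    else:
        true_betas = np.asarray(true_betas, dtype=float)
        if true_betas.shape != (n_cols, n_voxels):
            raise ValueError(f"true_betas must have shape {(n_cols, n_voxels)}")
    y = dm.matrix @ true_betas
    if config.bold_noise_sd > 0:
        innov_sd = config.bold_noise_sd * math.sqrt(1.0 - config.ar1_coef**2)
        innov = innov_sd * rng.standard_normal((n_volumes, n_voxels))
        noise = lfilter([1.0], [1.0, -config.ar1_coef], innov, axis=0)
        y = y + noise
    return BoldSimulation(time_series=y, true_betas=true_betas, design=dm)


# ---------------------------------------------------------------------------
# Ratings


def simulate_ratings(config: SynthConfig) -> pd.DataFrame:
    """7-point Likert fear ratings, one row per participant × condition cell.

    Latent normal: baseline + participant intercept + CS+ shift (full for the
    conditioned modality, ``rating_generalization`` of it for the other) +
    noise, rounded and clipped to 1..7.
    """
    rows = []
    for i in range(config.n_participants):
        pid = f"sub-{i + 1:02d}"
        basis = participant_basis(config, pid)
        rng = np.random.default_rng(_seed_key(config, pid, 501))
        for phase in (Phase.IMAGERY_ACQUISITION, Phase.VISUAL_ACQUISITION):
            cond = conditioned_modality(phase)
            for modality in (Modality.IMAGINE, Modality.VIEW):
                for cs in (CSType.CSPLUS, CSType.CSMINUS):
                    latent = config.rating_baseline + basis.rating_intercept
                    if cs is CSType.CSPLUS:
                        frac = 1.0 if modality is cond else config.rating_generalization
                        latent += frac * config.rating_shift
                    latent += config.rating_noise_sd * rng.standard_normal()
                    rating = int(np.clip(round(latent), 1, 7))
                    rows.append(
                        {
                            "participant_id": pid,
                            "phase": phase.value,
                            "modality": modality.value,
                            "cs_type": cs.value,
                            "rating": rating,
                        }
                    )
    return pd.DataFrame(rows)
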