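"""Trial-schedule generation and validation for the two-phase conditioning task.

The experiment has two phases — an *imagery acquisition* phase, in which the
participant is fear-conditioned to an imagined grating, and a *visual
acquisition* phase, in which conditioning is to a viewed grating.  Each phase
comprises six habituation/practice runs of 8 trials followed by six fear
acquisition runs of 12 trials.  Acquisition runs obey several placement
constraints (fixed CS− endpoints, early first reinforcement, one reinforced
trial per run half); this module generates schedules satisfying them,
validates arbitrary schedules against the full invariant set, applies the
analysis-trial exclusion rules, and round-trips schedules through BIDS-style
events TSV files.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Modality",
    "CSType",
    "TrialEvent",
    "TrialSchedule",
    "ScheduleError",
    "conditioned_modality",
    "build_habituation_schedule",
    "build_acquisition_schedule",
    "validate_schedule",
    "select_analysis_trials",
    "write_events_tsv",
    "read_events_tsv",
]

# Timing (seconds).  The CS epoch is 4 s, preceded by a 2 s auditory cue;
# the shock, when delivered, co-terminates with the CS epoch.  Run lengths
# correspond to 73 / 109 volumes at a 2 s repetition time.
CUE_DURATION = 2.0
CS_DURATION = 4.0
TR = 2.0
HABITUATION_RUN_DURATION = 146.0
ACQUISITION_RUN_DURATION = 218.0

N_RUNS = 6
N_HAB_TRIALS = 8
N_ACQ_TRIALS = 12


class Phase(str, enum.Enum):
    IMAGERY_ACQUISITION = "imagery_acquisition"
    VISUAL_ACQUISITION = "visual_acquisition"


class Modality(str, enum.Enum):
    VIEW = "view"
    IMAGINE = "imagine"


class CSType(str, enum.Enum):
    CSPLUS = "CSplus"
    CSMINUS = "CSminus"


class ScheduleError(ValueError):
    """Raised when a schedule violates the design invariants."""


def conditioned_modality(phase: Phase) -> Modality:
    """The modality whose CS+ is reinforced in the given phase."""
    phase = Phase(phase)
    return Modality.IMAGINE if phase is Phase.IMAGERY_ACQUISITION else Modality.VIEW


def other_modality(modality: Modality) -> Modality:
    return Modality.VIEW if Modality(modality) is Modality.IMAGINE else Modality.IMAGINE


# Gabor orientation labels per phase; counterbalancing of the orientation
# assignment across participants is bookkeeping outside this module's scope.
_GABOR_LABEL = {
    (Phase.IMAGERY_ACQUISITION, CSType.CSPLUS): "left",
    (Phase.IMAGERY_ACQUISITION, CSType.CSMINUS): "vertical",
    (Phase.VISUAL_ACQUISITION, CSType.CSPLUS): "right",
    (Phase.VISUAL_ACQUISITION, CSType.CSMINUS): "horizontal",
}


def cue_label(phase: Phase, modality: Modality, cs_type: CSType) -> str:
    verb = "imagine" if Modality(modality) is Modality.IMAGINE else "attend"
    return f"{verb} {_GABOR_LABEL[(Phase(phase), CSType(cs_type))]}"


@dataclass(frozen=True)
class TrialEvent:
    """One conditioning trial.

    ``onset`` is the CS onset (seconds from run start); the auditory cue
    begins ``CUE_DURATION`` seconds earlier.  ``reinforced`` marks delivery of
    the shock, which co-terminates with the CS epoch.
    """

    phase: Phase
    run_index: int
    trial_index: int
    modality: Modality
    cs_type: CSType
    reinforced: bool
    onset: float
    cs_duration: float = CS_DURATION
    cue_label: str = ""

    @property
    def trial_type(self) -> str:
        base = f"{self.modality.value}_{self.cs_type.value}"
        return base + "_shock" if self.reinforced else base


@dataclass
class TrialSchedule:
    """An ordered collection of runs of :class:`TrialEvent` for one phase."""

    participant_id: str
    phase: Phase
    kind: str  # "habituation" | "acquisition"
    runs: list[list[TrialEvent]]
    run_duration: float
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(r) for r in self.runs)

    def events(self) -> list[TrialEvent]:
        return [ev for run in self.runs for ev in run]


def _rng(seed: int, participant_id: str, phase: Phase, salt: int) -> np.random.Generator:
    pid_key = zlib.crc32(participant_id.encode())
    phase_key = 0 if Phase(phase) is Phase.IMAGERY_ACQUISITION else 1
    return np.random.default_rng([int(seed), pid_key, phase_key, salt])


def _assign_onsets(
    specs: Sequence[tuple[Modality, CSType, bool]],
    phase: Phase,
    run_index: int,
    run_duration: float,
    rng: np.random.Generator,
) -> list[TrialEvent]:
    """Place trials in time: gaps drawn uniformly, rescaled to fill the run."""
    n = len(specs)
    trial_len = CUE_DURATION + CS_DURATION
    free = run_duration - n * trial_len
    if free <= 0:
        raise ScheduleError("run too short for its trials")
    gaps = rng.uniform(1.0, 2.0, size=n + 1)
    gaps *= free / gaps.sum()
    events = []
    t = 0.0
    for i, (modality, cs_type, reinforced) in enumerate(specs):
        t += gaps[i]
        onset = t + CUE_DURATION  # CS onset follows the auditory cue
        events.append(
            TrialEvent(
                phase=Phase(phase),
                run_index=run_index,
                trial_index=i + 1,
                modality=modality,
                cs_type=cs_type,
                reinforced=reinforced,
                onset=round(onset, 3),
                cs_duration=CS_DURATION,
                cue_label=cue_label(phase, modality, cs_type),
            )
        )
        t += trial_len
    return events


def build_habituation_schedule(phase: Phase, participant_id: str, seed: int) -> TrialSchedule:
    """Six habituation runs of 8 trials each, fully randomized, no shocks.

    Per run: 2 CS+ imagine, 2 CS− imagine, 2 CS+ view, 2 CS− view, so each
    CS is viewed 12× and imagined 12× across the phase (48 trials).
    """
    phase = Phase(phase)
    rng = _rng(seed, participant_id, phase, salt=1)
    runs = []
    base = [
        (m, c, False)
        for m in (Modality.IMAGINE, Modality.VIEW)
        for c in (CSType.CSPLUS, CSType.CSMINUS)
        for _ in range(2)
    ]
    for run_index in range(1, N_RUNS + 1):
        order = rng.permutation(len(base))
        specs = [base[i] for i in order]
        runs.append(_assign_onsets(specs, phase, run_index, HABITUATION_RUN_DURATION, rng))
    return TrialSchedule(
        participant_id=participant_id,
        phase=phase,
        kind="habituation",
        runs=runs,
        run_duration=HABITUATION_RUN_DURATION,
        seed=int(seed),
    )


def build_acquisition_schedule(phase: Phase, participant_id: str, seed: int) -> TrialSchedule:
    """Six acquisition runs of 12 trials with the pseudo-random constraints.

    Per run: 2 reinforced CS+ and 2 non-reinforced CS+ of the conditioned
    modality (50% reinforcement), 4 CS− of the conditioned modality, and
    2 CS+ / 2 CS− of the other modality.  Every run begins and ends with a
    conditioned-modality CS− trial.  Run 1 places its first reinforced trial
    at position 2; otherwise one reinforced trial falls in each half of the
    run (positions 2–6 and 7–11).
    """
    phase = Phase(phase)
    rng = _rng(seed, participant_id, phase, salt=2)
    cond = conditioned_modality(phase)
    other = other_modality(cond)
    runs = []
    for run_index in range(1, N_RUNS + 1):
        specs: list[tuple[Modality, CSType, bool] | None] = [None] * N_ACQ_TRIALS
        specs[0] = (cond, CSType.CSMINUS, False)
        specs[-1] = (cond, CSType.CSMINUS, False)
        reinforced = (cond, CSType.CSPLUS, True)
        if run_index == 1:
            first_pos = 2
        else:
            first_pos = int(rng.integers(2, 7))  # positions 2..6
        second_pos = int(rng.integers(7, 12))  # positions 7..11
        specs[first_pos - 1] = reinforced
        specs[second_pos - 1] = reinforced
        remaining = (
            [(cond, CSType.CSPLUS, False)] * 2
            + [(cond, CSType.CSMINUS, False)] * 2
            + [(other, CSType.CSPLUS, False)] * 2
            + [(other, CSType.CSMINUS, False)] * 2
        )
        order = rng.permutation(len(remaining))
        shuffled = [remaining[i] for i in order]
        for pos in range(N_ACQ_TRIALS):
            if specs[pos] is None:
                specs[pos] = shuffled.pop()
        runs.append(_assign_onsets(specs, phase, run_index, ACQUISITION_RUN_DURATION, rng))
    schedule = TrialSchedule(
        participant_id=participant_id,
        phase=phase,
        kind="acquisition",
        runs=runs,
        run_duration=ACQUISITION_RUN_DURATION,
        seed=int(seed),
    )
    validate_schedule(schedule)  # must hold by construction
    return schedule


def _count(events: Iterable[TrialEvent], modality=None, cs_type=None, reinforced=None) -> int:
    n = 0
    for ev in events:
        if modality is not None and ev.modality is not Modality(modality):
            continue
        if cs_type is not None and ev.cs_type is not CSType(cs_type):
            continue
        if reinforced is not None and ev.reinforced is not reinforced:
            continue
        n += 1
    return n


def validate_schedule(schedule: TrialSchedule) -> None:
    """Assert every design invariant; raise :class:`ScheduleError` on failure."""
    phase = Phase(schedule.phase)
    cond = conditioned_modality(phase)
    other = other_modality(cond)
    if len(schedule.runs) != N_RUNS:
        raise ScheduleError(f"expected {N_RUNS} runs, got {len(schedule.runs)}")
    for run in schedule.runs:
        onsets = [ev.onset for ev in run]
        if any(b - a < CS_DURATION for a, b in zip(onsets, onsets[1:])):
            raise ScheduleError("overlapping or non-increasing trial onsets")
        if run[-1].onset + run[-1].cs_duration > schedule.run_duration:
            raise ScheduleError("trial extends beyond run end")
        for ev in run:
            if ev.reinforced and not (ev.cs_type is CSType.CSPLUS and ev.modality is cond):
                raise ScheduleError("reinforcement outside conditioned-modality CS+")
        if schedule.kind == "habituation":
            if len(run) != N_HAB_TRIALS:
                raise ScheduleError("habituation run must have 8 trials")
            if _count(run, reinforced=True):
                raise ScheduleError("habituation run contains a reinforced trial")
            for m in (Modality.IMAGINE, Modality.VIEW):
                for c in (CSType.CSPLUS, CSType.CSMINUS):
                    if _count(run, m, c) != 2:
                        raise ScheduleError(f"habituation cell {m.value}/{c.value} != 2")
        elif schedule.kind == "acquisition":
            if len(run) != N_ACQ_TRIALS:
                raise ScheduleError("acquisition run must have 12 trials")
            checks = [
                (_count(run, cond, CSType.CSPLUS, True), 2),
                (_count(run, cond, CSType.CSPLUS, False), 2),
                (_count(run, cond, CSType.CSMINUS), 4),
                (_count(run, other, CSType.CSPLUS), 2),
                (_count(run, other, CSType.CSMINUS), 2),
            ]
            for got, want in checks:
                if got != want:
                    raise ScheduleError(f"acquisition run composition {got} != {want}")
            for endpoint in (run[0], run[-1]):
                if not (endpoint.cs_type is CSType.CSMINUS and endpoint.modality is cond):
                    raise ScheduleError("run must begin and end with a conditioned-modality CS−")
            shock_pos = [ev.trial_index for ev in run if ev.reinforced]
            first, second = sorted(shock_pos)
            if run[0].run_index == 1 and first != 2:
                raise ScheduleError("run 1 must reinforce at trial 2")
            if not (2 <= first <= 6 and 7 <= second <= 11):
                raise ScheduleError("one reinforced trial required per run half")
        else:
            raise ScheduleError(f"unknown schedule kind {schedule.kind!r}")


def select_analysis_trials(schedule: TrialSchedule, modality: Modality) -> list[TrialEvent]:
    """Analysis trials for one modality of an acquisition schedule.

    Excludes reinforced trials (shock confound) and, for the conditioned
    modality, the first and last CS− trial of every run (the fixed run
    endpoints), leaving equal CS+ and CS− counts (12 each per modality).
    """
    if schedule.kind != "acquisition":
        raise ScheduleError("analysis-trial selection applies to acquisition schedules only")
    modality = Modality(modality)
    cond = conditioned_modality(schedule.phase)
    selected: list[TrialEvent] = []
    for run in schedule.runs:
        events = [ev for ev in run if ev.modality is modality and not ev.reinforced]
        if modality is cond:
            minus = [ev for ev in events if ev.cs_type is CSType.CSMINUS]
            drop = {id(minus[0]), id(minus[-1])}
            events = [ev for ev in events if id(ev) not in drop]
        selected.extend(events)
    return selected


# ---------------------------------------------------------------------------
# BIDS-style events TSV I/O


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    rows = [
        {
            "onset": ev.onset,
            "duration": ev.cs_duration,
            "trial_type": ev.trial_type,
            "run": ev.run_index,
            "phase": ev.phase.value,
        }
        for ev in schedule.events()
    ]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run", "phase"])


def write_events_tsv(schedule: TrialSchedule, path: str | Path) -> Path:
    path = Path(path)
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False)
    return path


def _parse_trial_type(trial_type: str) -> tuple[Modality, CSType, bool]:
    parts = trial_type.split("_")
    reinforced = parts[-1] == "shock"
    if reinforced:
        parts = parts[:-1]
    modality, cs = parts
    return Modality(modality), CSType(cs), reinforced


def read_events_tsv(path: str | Path, participant_id: str = "", seed: int = 0) -> TrialSchedule:
    """Reconstruct a schedule from an events TSV written by this module."""
    df = pd.read_csv(path, sep="\t")
    phase = Phase(df["phase"].iloc[0])
    runs = []
    for run_index, grp in df.groupby("run", sort=True):
        run = []
        for i, row in enumerate(grp.itertuples(index=False), start=1):
            modality, cs_type, reinforced = _parse_trial_type(row.trial_type)
            run.append(
                TrialEvent(
                    phase=phase,
                    run_index=int(run_index),
                    trial_index=i,
                    modality=modality,
                    cs_type=cs_type,
                    reinforced=reinforced,
                    onset=float(row.onset),
                    cs_duration=float(row.duration),
                    cue_label=cue_label(phase, modality, cs_type),
                )
            )
        runs.append(run)
    n = len(runs[0])
    kind = "acquisition" if n == N_ACQ_TRIALS else "habituation"
    duration = ACQUISITION_RUN_DURATION if kind == "acquisition" else HABITUATION_RUN_DURATION
    return TrialSchedule(
        participant_id=participant_id,
        phase=phase,
        kind=kind,
        runs=runs,
        run_duration=duration,
        seed=seed,
    )
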