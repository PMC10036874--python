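"""Skin-conductance response scoring and condition aggregation.

Trough-to-peak scoring of event-related electrodermal responses: the trial
amplitude is the maximum conductance in the 1–6 s window after CS onset minus
the mean conductance over the first second after onset; deflections of
0.02 µS or less score zero.  Amplitudes are square-root transformed before
averaging into per-participant condition means, with shock trials and the
fixed first/last CS− trials excluded per the analysis-trial rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .design import Modality, TrialEvent, TrialSchedule, select_analysis_trials

__all__ = [
    "SCRScore",
    "score_trial",
    "score_run",
    "sqrt_transform",
    "aggregate_condition_means",
    "is_non_responder",
    "InvalidWindowError",
    "MissingCellError",
    "AMPLITUDE_FLOOR",
]

AMPLITUDE_FLOOR = 0.02  # µS; smaller baseline-to-peak deflections score zero
BASELINE_WINDOW = (0.0, 1.0)  # [onset, onset+1): mean = baseline
PEAK_WINDOW = (1.0, 6.0)  # [onset+1, onset+6]: max = peak


class InvalidWindowError(ValueError):
    pass


class MissingCellError(ValueError):
    pass


@dataclass(frozen=True)
class SCRScore:
    trial_id: str
    raw_amplitude: float  # µS, 0 or > AMPLITUDE_FLOOR
    transformed: float  # sqrt(µS)
    valid: bool  # True when the deflection cleared the floor


def sqrt_transform(raw: float) -> float:
    """Square-root transform of a non-negative amplitude (normality)."""
    if raw < 0:
        raise ValueError("SCR amplitude must be non-negative")
    return math.sqrt(raw)


def score_trial(trace, onset: float, trial_id: str = "") -> SCRScore:
    """Score one trial from a conductance trace.

    ``trace`` provides ``values`` (µS) and ``sampling_rate`` (Hz); sample k
    sits at time k / sampling_rate.  Baseline is the mean over
    [onset, onset+1), peak the max over [onset+1, onset+6]; the amplitude is
    peak − baseline when that exceeds 0.02 µS, else zero.
    """
    values = np.asarray(trace.values, dtype=float)
    fs = float(trace.sampling_rate)
    t_end = (len(values) - 1) / fs
    if onset < 0 or onset + PEAK_WINDOW[1] > t_end:
        raise InvalidWindowError(
            f"scoring window [{onset}, {onset + PEAK_WINDOW[1]}] s exceeds trace [0, {t_end:.3f}] s"
        )
    t = np.arange(len(values)) / fs
    base_mask = (t >= onset + BASELINE_WINDOW[0]) & (t < onset + BASELINE_WINDOW[1])
    peak_mask = (t >= onset + PEAK_WINDOW[0]) & (t <= onset + PEAK_WINDOW[1])
    baseline = values[base_mask].mean()
    peak = values[peak_mask].max()
    deflection = peak - baseline
    if deflection > AMPLITUDE_FLOOR:
        raw = float(deflection)
        valid = True
    else:
        raw = 0.0
        valid = False
    return SCRScore(trial_id=trial_id, raw_amplitude=raw, transformed=sqrt_transform(raw), valid=valid)


def score_run(trace, run_events: Sequence[TrialEvent]) -> list[SCRScore]:
    """Score every trial of a run (reinforced trials included; exclusion
    happens at aggregation)."""
    return [
        score_trial(trace, ev.onset, trial_id=f"r{ev.run_index:02d}t{ev.trial_index:02d}")
        for ev in run_events
    ]


def scores_to_frame(scores: Iterable[SCRScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": s.trial_id,
                "raw_amplitude": s.raw_amplitude,
                "transformed": s.transformed,
                "valid": s.valid,
            }
            for s in scores
        ]
    )


def aggregate_condition_means(
    scores: dict[str, SCRScore] | pd.DataFrame,
    schedule: TrialSchedule,
) -> pd.DataFrame:
    """Mean transformed SCR per (phase, modality, cs_type) cell.

    ``scores`` maps trial_id → :class:`SCRScore` (or is a frame with
    trial_id/transformed columns) covering at least the analysis trials of
    ``schedule``.  Shock trials and boundary CS− trials never enter the
    means; zero-scored trials do.
    """
    if isinstance(scores, pd.DataFrame):
        lookup = dict(zip(scores["trial_id"], scores["transformed"]))
    else:
        lookup = {tid: s.transformed for tid, s in scores.items()}
    rows = []
    for modality in (Modality.IMAGINE, Modality.VIEW):
        events = select_analysis_trials(schedule, modality)
        for cs in ("CSplus", "CSminus"):
            cell = [
                ev for ev in events if ev.cs_type.value == cs
            ]
            vals = []
            for ev in cell:
                tid = f"r{ev.run_index:02d}t{ev.trial_index:02d}"
                if tid not in lookup:
                    raise MissingCellError(
                        f"no score for analysis trial {tid} "
                        f"({schedule.phase.value}/{modality.value}/{cs})"
                    )
                vals.append(lookup[tid])
            if not vals:
                raise MissingCellError(
                    f"empty cell {schedule.phase.value}/{modality.value}/{cs}"
                )
            rows.append(
                {
                    "participant_id": schedule.participant_id,
                    "phase": schedule.phase.value,
                    "modality": modality.value,
                    "cs_type": cs,
                    "mean_scr": float(np.mean(vals)),
                    "n_trials": len(vals),
                }
            )
    return pd.DataFrame(rows)


def is_non_responder(scores: dict[str, SCRScore] | pd.DataFrame, schedule: TrialSchedule) -> bool:
    """True when every shock trial scored zero (no detectable response to the
    US), the exclusion rule for non-responders."""
    if isinstance(scores, pd.DataFrame):
        lookup = dict(zip(scores["trial_id"], scores["raw_amplitude"]))
    else:
        lookup = {tid: s.raw_amplitude for tid, s in scores.items()}
    shock_amps = [
        lookup[f"r{ev.run_index:02d}t{ev.trial_index:02d}"]
        for ev in schedule.events()
        if ev.reinforced
    ]
    if not shock_amps:
        raise ValueError("schedule has no reinforced trials")
    return all(a == 0.0 for a in shock_amps)


def write_scores_tsv(scores: Iterable[SCRScore], path: str | Path) -> Path:
    path = Path(path)
    scores_to_frame(scores).to_csv(path, sep="\t", index=False)
    return path
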