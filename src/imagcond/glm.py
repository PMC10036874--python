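"""Trial-wise GLM: double-gamma HRF, design matrices, and beta estimation.

A beta-series ("least squares all") first level: every analysis trial gets
its own regressor — a boxcar over the CS epoch convolved with the canonical
double-gamma hemodynamic response — while shock trials and the fixed first/
last CS− trials of each run are collapsed into nuisance columns.  Ordinary
least squares at run level yields one parameter estimate per trial per voxel;
trial betas are normalized (z-scored per voxel within run) to form the
pattern matrices used by the decoding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import design as _design
from .design import CSType, TrialEvent, conditioned_modality

__all__ = [
    "double_gamma_hrf",
    "DesignMatrix",
    "build_trialwise_design",
    "estimate_trial_betas",
    "PatternDataset",
    "SingularDesignError",
    "InvalidEventError",
]

HRF_LENGTH = 32.0  # seconds
_PEAK = 6.0
_UNDERSHOOT_PEAK = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


class SingularDesignError(np.linalg.LinAlgError):
    pass


class InvalidEventError(ValueError):
    pass


def double_gamma_hrf(dt: float, length: float = HRF_LENGTH) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, unit peak.

    Difference of two gamma densities with modes at 6 s (response) and 16 s
    (undershoot, weighted 1/6), truncated at 32 s and scaled so max = 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    # gamma density mode = (shape-1)*scale; scale 1 → shapes 7 and 17
    peak = sps.gamma.pdf(t, a=_PEAK + 1.0)
    undershoot = sps.gamma.pdf(t, a=_UNDERSHOOT_PEAK + 1.0)
    h = peak - _UNDERSHOOT_RATIO * undershoot
    return h / h.max()


@dataclass
class DesignMatrix:
    """Volumes × regressors matrix with trial/nuisance column bookkeeping."""

    matrix: np.ndarray
    trial_events: list[TrialEvent]
    column_names: list[str]
    tr: float

    @property
    def n_trial_columns(self) -> int:
        return len(self.trial_events)


def _convolve_onsets(
    onsets: Sequence[float],
    durations: Sequence[float],
    tr: float,
    n_volumes: int,
    oversample: int = 20,
) -> np.ndarray:
    """Boxcar(s) convolved with the HRF, sampled at volume acquisition times."""
    dt = tr / oversample
    n_fine = n_volumes * oversample + int(HRF_LENGTH / dt)
    boxcar = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        boxcar[i0:i1] = 1.0
    hrf = double_gamma_hrf(dt)
    conv = np.convolve(boxcar, hrf)[:n_fine] * dt
    return conv[: n_volumes * oversample : oversample]


def build_trialwise_design(
    schedule_run: Sequence[TrialEvent],
    tr: float,
    n_volumes: int,
    drift_order: int = 0,
) -> DesignMatrix:
    """One regressor per analysis trial plus nuisance columns and intercept.

    Nuisance columns collapse (a) reinforced trials and (b) the first and
    last conditioned-modality CS− trial of the run; ``drift_order`` adds
    Legendre polynomial drift regressors.
    """
    events = list(schedule_run)
    if not events:
        raise InvalidEventError("empty run")
    run_len = n_volumes * tr
    for ev in events:
        if ev.onset >= run_len:
            raise InvalidEventError(f"trial onset {ev.onset}s beyond run end {run_len}s")

    cond = conditioned_modality(events[0].phase)
    minus_cond = [ev for ev in events if ev.cs_type is CSType.CSMINUS and ev.modality is cond]
    boundary: set[int] = set()
    if len(minus_cond) >= 2 and any(ev.reinforced for ev in events):
        # acquisition run: fixed endpoints are modeled as nuisance
        boundary = {id(minus_cond[0]), id(minus_cond[-1])}
    shock = [ev for ev in events if ev.reinforced]
    trial_events = [ev for ev in events if not ev.reinforced and id(ev) not in boundary]

    cols = []
    names = []
    for ev in trial_events:
        cols.append(_convolve_onsets([ev.onset], [ev.cs_duration], tr, n_volumes))
        names.append(f"trial{ev.trial_index:02d}_{ev.trial_type}")
    if shock:
        cols.append(
            _convolve_onsets([e.onset for e in shock], [e.cs_duration for e in shock], tr, n_volumes)
        )
        names.append("nuisance_shock")
    if boundary:
        bevs = [ev for ev in events if id(ev) in boundary]
        cols.append(
            _convolve_onsets([e.onset for e in bevs], [e.cs_duration for e in bevs], tr, n_volumes)
        )
        names.append("nuisance_boundary_csminus")
    for order in range(1, drift_order + 1):
        x = np.linspace(-1.0, 1.0, n_volumes)
        cols.append(np.polynomial.legendre.Legendre.basis(order)(x))
        names.append(f"drift{order}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(cols), trial_events=trial_events, column_names=names, tr=tr
    )


@dataclass
class PatternDataset:
    """Trials × voxels matrix of normalized trial betas with labels.

    ``labels`` rows align 1:1 with ``X`` rows and carry trial_id, cs_type,
    modality, run, phase, reinforced and participant_id.
    """

    X: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.labels):
            raise ValueError("pattern rows and label rows misaligned")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def select(self, **criteria) -> "PatternDataset":
        """Subset rows by label equality, e.g. ``select(modality="imagine")``."""
        mask = np.ones(len(self.labels), dtype=bool)
        for key, value in criteria.items():
            col = self.labels[key]
            mask &= (col == value).to_numpy()
        return PatternDataset(self.X[mask], self.labels[mask].reset_index(drop=True))

    def y(self) -> np.ndarray:
        """Binary class labels: 1 for CS+, 0 for CS−."""
        return (self.labels["cs_type"] == CSType.CSPLUS.value).to_numpy().astype(int)

    @staticmethod
    def concat(parts: Sequence["PatternDataset"]) -> "PatternDataset":
        X = np.vstack([p.X for p in parts])
        labels = pd.concat([p.labels for p in parts], ignore_index=True)
        return PatternDataset(X, labels)

    def write(self, matrix_path: str | Path, labels_path: str | Path) -> None:
        np.savetxt(matrix_path, self.X, delimiter="\t")
        self.labels.to_csv(labels_path, sep="\t", index=False)

    @staticmethod
    def read(matrix_path: str | Path, labels_path: str | Path) -> "PatternDataset":
        X = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
        labels = pd.read_csv(labels_path, sep="\t")
        return PatternDataset(X, labels)


def labels_for_events(events: Sequence[TrialEvent], participant_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [f"r{ev.run_index:02d}t{ev.trial_index:02d}" for ev in events],
            "cs_type": [ev.cs_type.value for ev in events],
            "modality": [ev.modality.value for ev in events],
            "run": [ev.run_index for ev in events],
            "phase": [ev.phase.value for ev in events],
            "reinforced": [ev.reinforced for ev in events],
            "participant_id": participant_id,
        }
    )


def estimate_trial_betas(
    time_series: np.ndarray,
    design: DesignMatrix,
    participant_id: str = "",
    normalize: bool = True,
) -> PatternDataset:
    """OLS trial betas for one run; optionally z-scored per voxel.

    ``time_series`` is volumes × voxels.  Raises
    :class:`SingularDesignError` on a rank-deficient design.
    """
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    betas, *_ = np.linalg.lstsq(X, np.asarray(time_series, dtype=float), rcond=None)
    trial_betas = betas[: design.n_trial_columns]
    if normalize:
        mu = trial_betas.mean(axis=0, keepdims=True)
        sd = trial_betas.std(axis=0, ddof=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        trial_betas = (trial_betas - mu) / sd
    labels = labels_for_events(design.trial_events, participant_id)
    return PatternDataset(trial_betas, labels)
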