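"""Normalization, reference-based calibration, and rotation augmentation.

EIT amplitude measurements carry large session-specific offsets (electrode
placement, contact impedance) and a slow within-session drift (electrode
warm-up). Calibration subtracts a reference measurement — the mean of the
neutral-gesture frames — so classifiers see changes of muscle state relative
to the relaxed hand rather than absolute physiology:

* **global** calibration uses one reference per session, the neutral mean of
  the session's *first* iteration; it cancels the static session offset but
  not within-session drift.
* **local** calibration uses one reference per iteration, cancelling drift
  that is common to all gestures of the iteration.
* **learned** calibration does not subtract at all: the uncalibrated frame
  and its (local) reference are handed to a dual-input network which learns
  its own, possibly non-linear, offsetting. :func:`pair_with_reference`
  prepares those input pairs.

The processing order is normalize first (min-max to [0, 1] fitted on the
training split), then calibrate; calibrated values are signed and are not
re-scaled. The two operations do not commute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, MissingReferenceError
from .frames import Frame, FrameMeta, GestureDataset, NEUTRAL_GESTURE
from .schedule import MeasurementSchedule


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationState:
    """Dataset-global min-max scaling parameters, fitted on training data only.

    Maps ``x -> (x - vmin) / (vmax - vmin)``; values outside the fitted span
    (possible at test time) are clipped to [0, 1].
    """

    vmin: float
    vmax: float
    fitted_on: str = "train"

    def transform_values(self, values: np.ndarray) -> np.ndarray:
        scaled = (np.asarray(values, dtype=float) - self.vmin) / (self.vmax - self.vmin)
        return np.clip(scaled, 0.0, 1.0)

    def transform(self, ds: GestureDataset) -> GestureDataset:
        return ds.with_values(self.transform_values(ds.values))


def fit_normalizer(train: GestureDataset, fitted_on: str = "train") -> NormalizationState:
    """Fit min-max scaling over *all* values of the training split."""
    if train.n_frames == 0:
        raise DegenerateDataError("cannot fit a normalizer on an empty training set")
    vmin = float(train.values.min())
    vmax = float(train.values.max())
    if vmax == vmin:
        raise DegenerateDataError(f"all training values equal {vmin}; min-max scaling undefined")
    return NormalizationState(vmin=vmin, vmax=vmax, fitted_on=fitted_on)


# ---------------------------------------------------------------------------
# reference frames and calibration
# ---------------------------------------------------------------------------

SESSION_GLOBAL = "session-global"
ITERATION_LOCAL = "iteration-local"


@dataclass(frozen=True)
class ReferenceFrame:
    """Mean of the neutral-gesture frames within one calibration scope."""

    values: np.ndarray
    scope: str  # SESSION_GLOBAL | ITERATION_LOCAL
    subject: str
    session: str
    source_iteration: int


def _session_groups(ds: GestureDataset):
    return ds.meta.groupby(["subject", "session"], sort=False).indices.items()


def compute_references(ds: GestureDataset, scope: str) -> dict[tuple, ReferenceFrame]:
    """Neutral-gesture reference per session (global) or per iteration (local).

    Keys are ``(subject, session)`` for session-global scope and
    ``(subject, session, iteration)`` for iteration-local scope.
    """
    refs: dict[tuple, ReferenceFrame] = {}
    if scope == SESSION_GLOBAL:
        for (subj, sess), idx in _session_groups(ds):
            sel = ds.mask(subject=subj, session=sess, iteration=1, gesture=NEUTRAL_GESTURE)
            if not sel.any():
                raise MissingReferenceError(
                    f"session {subj}/{sess}: no neutral-gesture (label {NEUTRAL_GESTURE}) "
                    f"frames in iteration 1"
                )
            refs[(subj, sess)] = ReferenceFrame(
                values=ds.values[sel].mean(axis=0), scope=scope,
                subject=subj, session=sess, source_iteration=1,
            )
    elif scope == ITERATION_LOCAL:
        groups = ds.meta.groupby(["subject", "session", "iteration"], sort=False).indices
        for (subj, sess, it) in groups:
            sel = ds.mask(subject=subj, session=sess, iteration=it, gesture=NEUTRAL_GESTURE)
            if not sel.any():
                raise MissingReferenceError(
                    f"iteration {it} of session {subj}/{sess} has no neutral-gesture frames"
                )
            refs[(subj, sess, int(it))] = ReferenceFrame(
                values=ds.values[sel].mean(axis=0), scope=scope,
                subject=subj, session=sess, source_iteration=int(it),
            )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return refs


def _reference_matrix(ds: GestureDataset, scope: str) -> np.ndarray:
    """Per-frame reference vectors, aligned with ``ds`` rows."""
    refs = compute_references(ds, scope)
    out = np.empty_like(ds.values)
    m = ds.meta
    if scope == SESSION_GLOBAL:
        keys = zip(m["subject"], m["session"])
    else:
        keys = zip(m["subject"], m["session"], m["iteration"].astype(int))
    for i, k in enumerate(keys):
        out[i] = refs[k].values
    return out


def global_calibrate(ds: GestureDataset) -> GestureDataset:
    """Subtract each session's iteration-1 neutral mean from all its frames."""
    return ds.with_values(ds.values - _reference_matrix(ds, SESSION_GLOBAL))


def local_calibrate(ds: GestureDataset) -> GestureDataset:
    """Subtract each iteration's own neutral mean from that iteration's frames."""
    return ds.with_values(ds.values - _reference_matrix(ds, ITERATION_LOCAL))


def calibrate(ds: GestureDataset, mode: str) -> GestureDataset:
    """Dispatch on ``mode`` in {none, global, local}."""
    if mode == "none":
        return ds
    if mode == "global":
        return global_calibrate(ds)
    if mode == "local":
        return local_calibrate(ds)
    raise ValueError(f"unknown calibration mode {mode!r}")


@dataclass
class PairedDataset:
    """Frames paired with their calibration references, for dual-input models.

    ``references[i]`` is the reference vector for ``dataset`` row ``i``. Values
    stay uncalibrated — subtracting (or any other combination) is the
    network's job. Neutral frames are paired like any other class: the neutral
    gesture is one of the 12 classes to classify, not an excluded posture.
    """

    dataset: GestureDataset
    references: np.ndarray
    scope: str


def pair_with_reference(ds: GestureDataset, scope: str = ITERATION_LOCAL) -> PairedDataset:
    """Pair every frame with its scope's neutral reference.

    Iteration-local pairing is the default; session-global pairing (the
    first-iteration reference for every iteration) is available but
    experimental — with drifting data it is known to give much weaker
    classifiers.
    """
    return PairedDataset(dataset=ds, references=_reference_matrix(ds, scope), scope=scope)


# ---------------------------------------------------------------------------
# circular-shift augmentation
# ---------------------------------------------------------------------------

def circular_shift_values(
    values: np.ndarray, k: int, schedule: MeasurementSchedule
) -> np.ndarray:
    """Rotate frames by ``k`` electrode positions (360 k / N degrees).

    Cycle ``i`` of the output equals cycle ``(i - k) mod N`` of the input;
    within-cycle order is unchanged because measurement positions are defined
    relative to the injecting pair. Accepts a single frame vector or a stack.
    """
    n, c = schedule.n_electrodes, schedule.cycle_length
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    stack = values.reshape(-1, n, c)
    out = np.roll(stack, k % n, axis=1).reshape(values.shape if not single else (1, -1))
    return out[0] if single else out.reshape(values.shape)


def circular_shift(frame: Frame, k: int) -> Frame:
    """Rotation-augmented copy of ``frame``; shift by 0 or N is the identity."""
    return Frame(
        values=circular_shift_values(frame.values, k, frame.layout),
        layout=frame.layout,
        meta=frame.meta,
    )


def circular_shift_dataset(ds: GestureDataset, k: int) -> GestureDataset:
    return ds.with_values(circular_shift_values(ds.values, k, ds.schedule))
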