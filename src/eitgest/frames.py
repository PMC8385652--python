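"""Frame and dataset containers for gesture-labelled EIT recordings.

A *frame* is one full rotation of the adjacency protocol: ``N * (N - 3)``
amplitude measurements with known cycle structure. Frames are recorded in
bursts of up to 10 per gesture; one pass through all 12 gestures is an
*iteration*; everything recorded between attaching and removing the wristband
is a *session*. :class:`GestureDataset` stores a whole study — any number of
subjects, sessions and iterations — column-oriented: a metadata table plus a
dense ``(n_frames, n_measurements)`` value matrix, so transforms and model
code operate on plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import CorruptFrameError, IntegrityError
from .schedule import MeasurementSchedule, build_schedule

#: Number of distinct gesture classes in the study protocol.
N_GESTURES = 12
#: Label of the relaxed claw hand used as the calibration reference posture.
NEUTRAL_GESTURE = 6
#: Maximum consecutive frames recorded per gesture and iteration.
MAX_FRAMES_PER_GESTURE = 10

META_COLUMNS = ["subject", "session", "iteration", "gesture", "frame_index"]
KEY_COLUMNS = META_COLUMNS  # full key: one row per (s, sess, it, g, fi)


@dataclass(frozen=True)
class FrameMeta:
    subject: str
    session: str
    iteration: int  # 1-based
    gesture: int  # 0..11
    frame_index: int  # 0..9


@dataclass(frozen=True)
class Frame:
    """A single EIT acquisition with its measurement layout and provenance."""

    values: np.ndarray
    layout: MeasurementSchedule
    meta: FrameMeta

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.shape[0] != self.layout.n_measurements:
            raise CorruptFrameError(
                f"frame has {v.shape} values, schedule expects "
                f"{self.layout.n_measurements}"
            )
        if not 0 <= self.meta.gesture < N_GESTURES:
            raise IntegrityError(f"gesture label {self.meta.gesture} out of range 0..11")


@dataclass(frozen=True)
class FrameMatrix:
    """Square (cycle x position) view of a frame.

    Row ``i`` holds cycle ``i``'s ``N - 3`` measurements in schedule order,
    left-aligned; the remaining ``3 N`` cells carry no measurement and are
    marked in ``mask`` (True = undefined) and zero-filled in ``matrix`` so the
    view can feed zero-padded convolutions directly.
    """

    matrix: np.ndarray
    mask: np.ndarray


def frame_to_matrix(frame: Frame) -> FrameMatrix:
    """Reshape a frame into its N x N matrix view (e.g. 208 values -> 16 x 16)."""
    return values_to_matrix(frame.values, frame.layout)


def values_to_matrix(values: np.ndarray, layout: MeasurementSchedule) -> FrameMatrix:
    n, c = layout.n_electrodes, layout.cycle_length
    values = np.asarray(values, dtype=float)
    if values.shape != (layout.n_measurements,):
        raise CorruptFrameError(
            f"expected {layout.n_measurements} values, got {values.shape}"
        )
    m = np.zeros((n, n))
    m[:, :c] = values.reshape(n, c)
    mask = np.ones((n, n), dtype=bool)
    mask[:, :c] = False
    return FrameMatrix(matrix=m, mask=mask)


def matrix_to_frame(fm: FrameMatrix, layout: MeasurementSchedule, meta: FrameMeta) -> Frame:
    """Inverse of :func:`frame_to_matrix` on valid frames."""
    c = layout.cycle_length
    return Frame(values=fm.matrix[:, :c].reshape(-1).copy(), layout=layout, meta=meta)


def dataset_to_tensors(ds: "GestureDataset") -> np.ndarray:
    """Stack every frame's matrix view into an ``(n, N, N)`` array (zero-filled)."""
    n, c = ds.schedule.n_electrodes, ds.schedule.cycle_length
    out = np.zeros((ds.n_frames, n, n))
    out[:, :, :c] = ds.values.reshape(ds.n_frames, n, c)
    return out


class GestureDataset:
    """Column-oriented collection of frames keyed by subject/session/iteration/gesture.

    Parameters
    ----------
    meta
        Table with columns ``subject, session, iteration, gesture, frame_index``,
        one row per frame, in the same order as ``values``.
    values
        ``(n_frames, n_measurements)`` float array of amplitude measurements.
    schedule
        Measurement layout shared by all frames.
    convention
        On-disk value convention the data was loaded from: ``"compact"``
        (``N (N - 3)`` values per row) or ``"padded"`` (``N^2`` values, masked
        cells included).
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        values: np.ndarray,
        schedule: MeasurementSchedule,
        convention: str = "compact",
    ):
        meta = meta.reset_index(drop=True)
        values = np.asarray(values, dtype=float)
        if list(meta.columns) != META_COLUMNS:
            raise IntegrityError(f"meta columns must be {META_COLUMNS}, got {list(meta.columns)}")
        if values.ndim != 2 or values.shape != (len(meta), schedule.n_measurements):
            raise IntegrityError(
                f"values shape {values.shape} inconsistent with {len(meta)} frames "
                f"x {schedule.n_measurements} measurements"
            )
        self.meta = meta
        self.values = values
        self.schedule = schedule
        self.convention = convention
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def empty(cls, schedule: MeasurementSchedule | None = None) -> "GestureDataset":
        schedule = schedule or build_schedule(16)
        meta = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            META_COLUMNS, [str, str, int, int, int])})
        return cls(meta, np.empty((0, schedule.n_measurements)), schedule)

    # -- invariants --------------------------------------------------------

    def validate(self, strict: bool = False) -> None:
        """Check dataset invariants.

        The cheap per-row checks always run (they hold for any subset). With
        ``strict=True`` the as-recorded session structure is also enforced —
        iterations consecutive from 1 — which derived splits legitimately
        violate; readers and the simulator validate strictly.
        """
        self._validate_rows()
        if strict:
            self._validate_sessions()

    def _validate_rows(self) -> None:
        m = self.meta
        bad = m.index[(m["gesture"] < 0) | (m["gesture"] >= N_GESTURES)]
        if len(bad):
            raise IntegrityError(
                f"gesture label out of range 0..{N_GESTURES - 1} at rows {list(bad[:5])}"
            )
        bad = m.index[(m["frame_index"] < 0) | (m["frame_index"] >= MAX_FRAMES_PER_GESTURE)]
        if len(bad):
            raise IntegrityError(f"frame_index out of range 0..9 at rows {list(bad[:5])}")
        dup = m.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = m[dup].iloc[0]
            raise IntegrityError(
                "duplicate frame key "
                + str(tuple(first[c] for c in KEY_COLUMNS))
            )
        # groups of (subject, session, iteration, gesture) hold at most 10 frames
        sizes = m.groupby(["subject", "session", "iteration", "gesture"], sort=False).size()
        if (sizes > MAX_FRAMES_PER_GESTURE).any():
            raise IntegrityError("a (subject, session, iteration, gesture) group exceeds 10 frames")

    def _validate_sessions(self) -> None:
        m = self.meta
        for (subj, sess), grp in m.groupby(["subject", "session"], sort=False):
            its = np.sort(grp["iteration"].unique())
            if len(its) and not np.array_equal(its, np.arange(1, len(its) + 1)):
                raise IntegrityError(
                    f"iterations of session {subj}/{sess} not consecutive from 1: {list(its)}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.meta)

    def __len__(self) -> int:
        return self.n_frames

    @property
    def labels(self) -> np.ndarray:
        return self.meta["gesture"].to_numpy()

    def session_keys(self) -> list[tuple[str, str]]:
        return list(dict.fromkeys(zip(self.meta["subject"], self.meta["session"])))

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.meta["subject"]))

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def frame(self, i: int) -> Frame:
        r = self.meta.iloc[i]
        return Frame(
            values=self.values[i],
            layout=self.schedule,
            meta=FrameMeta(r["subject"], r["session"], int(r["iteration"]),
                           int(r["gesture"]), int(r["frame_index"])),
        )

    # -- selection ---------------------------------------------------------

    def mask(self, **criteria) -> np.ndarray:
        """Boolean row mask; criteria values may be scalars or collections."""
        m = np.ones(self.n_frames, dtype=bool)
        for col, val in criteria.items():
            series = self.meta[col]
            if isinstance(val, (list, tuple, set, np.ndarray)):
                m &= series.isin(list(val)).to_numpy()
            else:
                m &= (series == val).to_numpy()
        return m

    def select(self, **criteria) -> "GestureDataset":
        return self.take(np.flatnonzero(self.mask(**criteria)))

    def take(self, idx: np.ndarray) -> "GestureDataset":
        return GestureDataset(
            self.meta.iloc[idx].reset_index(drop=True),
            self.values[idx],
            self.schedule,
            self.convention,
        )

    def with_values(self, values: np.ndarray) -> "GestureDataset":
        """Same frames, new measurement values (used by transforms)."""
        return GestureDataset(self.meta.copy(), values, self.schedule, self.convention)

    def sorted(self) -> "GestureDataset":
        order = self.meta.sort_values(KEY_COLUMNS, kind="mergesort").index.to_numpy()
        return self.take(order)

    def equals(self, other: "GestureDataset") -> bool:
        return (
            self.schedule.n_electrodes == other.schedule.n_electrodes
            and self.meta.astype(str).equals(other.meta.astype(str))
            and np.array_equal(self.values, other.values)
        )
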