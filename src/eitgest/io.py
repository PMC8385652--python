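"""Readers and writers for the canonical tabular frame format.

Canonical format: UTF-8 CSV, a leading ``# n_electrodes=N`` declaration line,
then a header row ``subject,session,iteration,gesture,frame_index,v000,...``
followed by one row per frame, values as decimal floats. The format is
deliberately plain so datasets diff cleanly and other toolchains can read
them without this package.

Deposited or third-party datasets plug in through :func:`register_loader`:
a loader takes a directory path and returns a :class:`GestureDataset`. Rows
may be 208-wide (compact, measurements only) or 256-wide (padded, the full
16 x 16 matrix row-major including undefined cells); the detected convention
is recorded on the returned dataset.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .frames import GestureDataset, META_COLUMNS, N_GESTURES, MAX_FRAMES_PER_GESTURE
from .schedule import build_schedule

_HEADER_RE = re.compile(r"#\s*n_electrodes\s*=\s*(\d+)")

_LOADERS: dict[str, Callable[..., GestureDataset]] = {}


def register_loader(name: str):
    """Register a dataset loader plugin under ``name``.

    The decorated callable receives a path (file or directory) and returns a
    :class:`GestureDataset`. Intended for deposited datasets whose on-disk
    layout differs from the canonical CSV.
    """

    def deco(fn: Callable[..., GestureDataset]):
        _LOADERS[name] = fn
        return fn

    return deco


def available_loaders() -> list[str]:
    return sorted(_LOADERS)


def _infer_n_electrodes(n_value_cols: int) -> int:
    """Solve N(N-3) == n_value_cols (compact) or N^2 == n_value_cols (padded)."""
    # compact: N = (3 + sqrt(9 + 4 w)) / 2
    disc = 9 + 4 * n_value_cols
    root = math.isqrt(disc)
    if root * root == disc and (3 + root) % 2 == 0:
        return (3 + root) // 2
    root = math.isqrt(n_value_cols)
    if root * root == n_value_cols:
        return root
    raise FormatError(
        f"{n_value_cols} value columns match neither N(N-3) nor N^2 for integer N"
    )


def read_dataset(path, format: str = "canonical") -> GestureDataset:
    """Load a gesture dataset.

    Parameters
    ----------
    path
        Canonical CSV file, or whatever the named loader plugin expects.
    format
        ``"canonical"`` or a registered plugin name.
    """
    if format != "canonical":
        if format not in _LOADERS:
            raise FormatError(
                f"unknown format {format!r}; registered loaders: {available_loaders()}"
            )
        return _LOADERS[format](path)

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        declared_n = None
        m = _HEADER_RE.match(first)
        if m:
            declared_n = int(m.group(1))
            header_line = fh.readline()
        else:
            header_line = first
        header = [c.strip() for c in header_line.rstrip("\n").split(",")]
        if header[: len(META_COLUMNS)] != META_COLUMNS:
            raise FormatError(
                f"{path}: header must start with {','.join(META_COLUMNS)}; got {header[:5]}"
            )
        value_cols = header[len(META_COLUMNS) :]
        if not value_cols:
            raise FormatError(f"{path}: no measurement columns in header")
        df = pd.read_csv(fh, names=header, dtype={"subject": str, "session": str},
                         float_precision="round_trip")

    n = declared_n if declared_n is not None else _infer_n_electrodes(len(value_cols))
    schedule = build_schedule(n)

    convention = "compact"
    width = len(value_cols)
    if width == n * n:
        convention = "padded"
    elif width != schedule.n_measurements:
        raise FormatError(
            f"{path}: {width} value columns inconsistent with n_electrodes={n} "
            f"(expected {schedule.n_measurements} or {n * n})"
        )

    meta = df[META_COLUMNS].copy()
    meta["iteration"] = meta["iteration"].astype(int)
    meta["gesture"] = meta["gesture"].astype(int)
    meta["frame_index"] = meta["frame_index"].astype(int)

    bad = meta.index[(meta["gesture"] < 0) | (meta["gesture"] >= N_GESTURES)]
    if len(bad):
        lines = [int(i) + (3 if declared_n is not None else 2) for i in bad[:10]]
        raise IntegrityError(
            f"{path}: gesture label out of range 0..{N_GESTURES - 1} "
            f"on file line(s) {lines}"
        )
    bad = meta.index[(meta["frame_index"] < 0) | (meta["frame_index"] >= MAX_FRAMES_PER_GESTURE)]
    if len(bad):
        lines = [int(i) + (3 if declared_n is not None else 2) for i in bad[:10]]
        raise IntegrityError(f"{path}: frame_index out of range 0..9 on file line(s) {lines}")

    values = df[value_cols].to_numpy(dtype=float)
    if convention == "padded":
        # keep only the defined cells: first N-3 entries of each length-N row
        values = values.reshape(len(df), n, n)[:, :, : schedule.cycle_length]
        values = values.reshape(len(df), schedule.n_measurements)

    ds = GestureDataset(meta, values, schedule, convention=convention)
    ds.validate(strict=True)
    return ds


def write_dataset(dataset: GestureDataset, path) -> None:
    """Write the canonical CSV; rows sorted by the full frame key.

    Round-trips bit-exactly for finite values (17 significant digits).
    """
    path = Path(path)
    ds = dataset.sorted()
    width = len(str(ds.schedule.n_measurements - 1))
    value_cols = [f"v{i:0{max(width, 3)}d}" for i in range(ds.schedule.n_measurements)]
    out = pd.concat(
        [ds.meta.reset_index(drop=True),
         pd.DataFrame(ds.values, columns=value_cols)],
        axis=1,
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# n_electrodes={ds.schedule.n_electrodes}\n")
        out.to_csv(fh, index=False, float_format="%.17g")
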