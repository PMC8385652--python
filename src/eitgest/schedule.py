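"""Adjacency measurement schedule for ring-electrode EIT.

An EIT wristband carries ``N`` electrodes arranged equidistantly on a ring.
Under the adjacency (neighbouring) protocol, current is injected through one
pair of adjacent electrodes while the differential voltage is read from every
other pair of adjacent electrodes that does not touch the injecting pair.
That yields ``N - 3`` measurements per injection position (a *cycle*); rotating
the injection pair once around the ring produces ``N`` cycles and hence
``N * (N - 3)`` scalar measurements, which together form a *frame* — the unit
of input for gesture classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MeasurementSchedule:
    """Ordered list of (injection pair, measurement pair) electrode indices.

    Entries are cycle-major: cycle ``i`` occupies positions
    ``i * (N - 3) ... (i + 1) * (N - 3) - 1`` and uses the fixed injection pair
    ``(i, (i + 1) % N)``. Within a cycle, measurement pairs walk around the
    ring in increasing electrode order starting just after the injection pair.
    Electrode and cycle indices are 0-based.
    """

    n_electrodes: int
    entries: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = field(repr=False)

    @property
    def cycle_length(self) -> int:
        return self.n_electrodes - 3

    @property
    def n_measurements(self) -> int:
        return len(self.entries)

    def cycle(self, i: int) -> tuple[tuple[tuple[int, int], tuple[int, int]], ...]:
        """Entries of cycle ``i`` (injection pair ``(i, i+1 mod N)``)."""
        c = self.cycle_length
        if not 0 <= i < self.n_electrodes:
            raise IndexError(f"cycle index {i} out of range for N={self.n_electrodes}")
        return self.entries[i * c : (i + 1) * c]


def build_schedule(n_electrodes: int) -> MeasurementSchedule:
    """Build the adjacency-protocol schedule for a ring of ``n_electrodes``.

    Parameters
    ----------
    n_electrodes
        Ring size ``N``; must be at least 5 so that each cycle contains
        at least two distinct measurement pairs.

    Returns
    -------
    MeasurementSchedule
        ``N * (N - 3)`` entries in deterministic cycle-major order.
    """
    n = n_electrodes
    if n < 5:
        raise ValueError(
            f"n_electrodes must be >= 5 for the four-electrode adjacency "
            f"protocol, got {n}"
        )
    entries = []
    for i in range(n):
        inject = (i, (i + 1) % n)
        # measurement pairs start one electrode past the injection pair and
        # stop one short of wrapping back onto it
        for j in range(i + 2, i + n - 1):
            entries.append((inject, (j % n, (j + 1) % n)))
    return MeasurementSchedule(n_electrodes=n, entries=tuple(entries))
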