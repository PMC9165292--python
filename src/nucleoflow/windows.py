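"""Analysis time windows.

Quantities such as the mean square strain, the divergence spread and the
relative stiffness are estimated inside sliding time windows, by default
five half-overlapping intervals covering the whole record (for a 24 h
record: 0-8 h, 4-12 h, 8-16 h, 12-20 h and 16-24 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeWindow:
    start_h: float
    end_h: float

    @property
    def mid_h(self) -> float:
        return 0.5 * (self.start_h + self.end_h)

    @property
    def length_h(self) -> float:
        return self.end_h - self.start_h

    def label(self) -> str:
        return f"{self.start_h:g}-{self.end_h:g}h"

    def contains(self, t_h: np.ndarray) -> np.ndarray:
        t_h = np.asarray(t_h)
        return (t_h >= self.start_h - 1e-9) & (t_h <= self.end_h + 1e-9)


def make_windows(
    duration_h: float,
    n_windows: int = 5,
    length_h: float | None = None,
    overlap_frac: float = 0.5,
) -> list[TimeWindow]:
    """Build ``n_windows`` half-overlapping windows spanning ``duration_h``.

    With the defaults the window length is a third of the record and
    consecutive windows overlap by half their length, reproducing the
    0-8/4-12/.../16-24 h scheme on a 24 h record.  ``n_windows=1`` returns a
    single window covering the whole record.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if n_windows == 1:
        return [TimeWindow(0.0, duration_h)]
    if length_h is None:
        # length L and step s=L*(1-overlap) with (n-1)*s + L = duration
        length_h = duration_h / ((n_windows - 1) * (1 - overlap_frac) + 1)
    step = length_h * (1 - overlap_frac)
    return [TimeWindow(i * step, i * step + length_h) for i in range(n_windows)]
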