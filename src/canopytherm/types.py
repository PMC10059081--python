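"""Shared frame containers.

Conventions used throughout the package: arrays are row-major with a
top-left origin, indices are 0-based, and rectangles are half-open
``(row0, col0, row1, col1)``.  Visible frames are ``(H, W, 3)`` uint8 RGB;
canopy masks are boolean arrays at visible resolution; registered masks are
boolean arrays at thermal-grid resolution; thermal data are float64 degrees
Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ThermalFrame:
    """A radiometric temperature matrix in degrees Celsius.

    Parameters
    ----------
    data
        2-D float array of per-cell temperatures (C).
    time_since_ffc_s
        Seconds elapsed since the flat-field correction that opened the
        series this frame belongs to.  Microbolometer readings drift for a
        short transient after an FFC, so downstream statistics may exclude
        frames captured too early.
    timestamp_s
        Capture time in seconds from the start of the session (or epoch
        seconds when loaded from disk).
    emissivity, reflected_temp_C
        Radiometric parameters carried as metadata; synthetic and decoded
        values are already surface temperatures in C.
    """

    data: np.ndarray
    time_since_ffc_s: float = 0.0
    timestamp_s: float = 0.0
    emissivity: float = 1.0
    reflected_temp_C: float = 22.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("thermal data must be a 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]
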