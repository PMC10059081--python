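"""Visible-to-thermal field-of-view registration.

The RGB camera and the thermal camera are rigidly co-mounted at minimal
offset, so their fields of view differ only by an axis-aligned crop and a
per-axis scale: the thermal matrix sees an *intersection region* of the
visible image.  A one-off laboratory calibration provides point pairs
(visible pixel of the top-left corner of a thermal cell's footprint,
thermal cell index); from those we fit per-axis affine maps and obtain the
rectangle + scales model used to project leaf masks onto the thermal grid.

No rotation or shear is modelled, and no lens-distortion correction is
applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from canopytherm.errors import FitError, ShapeError, ConfigurationError

__all__ = ["RegistrationModel", "fit_registration", "register_mask"]


@dataclass(frozen=True)
class RegistrationModel:
    """Axis-aligned map between visible pixels and thermal cells.

    Thermal cell ``(i, j)`` covers the half-open visible-pixel block
    ``rows [row0 + i*scale_rows, row0 + (i+1)*scale_rows)`` and likewise for
    columns, with ``(row0, col0) = visible_roi[:2]``.

    Attributes
    ----------
    visible_roi
        ``(row0, col0, row1, col1)`` half-open rectangle, in visible
        coordinates, of the intersection region imaged by the thermal grid.
    scale_rows, scale_cols
        Visible pixels per thermal cell along each axis (> 0).
    grid_size
        ``(rows, cols)`` of the thermal matrix.
    residual_cells
        RMS calibration residual, in thermal-cell units (0 for exact fits).
    """

    visible_roi: tuple[float, float, float, float]
    scale_rows: float
    scale_cols: float
    grid_size: tuple[int, int]
    residual_cells: float = 0.0

    def __post_init__(self) -> None:
        row0, col0, row1, col1 = self.visible_roi
        if self.scale_rows <= 0 or self.scale_cols <= 0:
            raise ConfigurationError("registration scales must be positive")
        if row1 <= row0 or col1 <= col0:
            raise ConfigurationError("visible_roi must have positive extent")
        gr, gc = self.grid_size
        if gr <= 0 or gc <= 0:
            raise ConfigurationError("thermal grid size must be positive")
        if abs((row1 - row0) / self.scale_rows - gr) > 1.0:
            raise ConfigurationError(
                "roi height / scale_rows inconsistent with thermal grid rows"
            )
        if abs((col1 - col0) / self.scale_cols - gc) > 1.0:
            raise ConfigurationError(
                "roi width / scale_cols inconsistent with thermal grid cols"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegistrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            visible_roi=tuple(d["visible_roi"]),
            scale_rows=d["scale_rows"],
            scale_cols=d["scale_cols"],
            grid_size=tuple(d["grid_size"]),
            residual_cells=d.get("residual_cells", 0.0),
        )


def _fit_axis(vis: np.ndarray, th: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of vis = scale * th + offset along one axis."""
    if np.ptp(th) == 0:
        raise FitError("calibration pairs do not span one of the axes")
    scale, offset = np.polyfit(th, vis, 1)
    if scale <= 0:
        raise FitError("non-positive fitted scale; pairs are inconsistent")
    return float(scale), float(offset)


def fit_registration(
    point_pairs: Iterable[tuple[Sequence[float], Sequence[float]]],
    grid_size: tuple[int, int],
) -> RegistrationModel:
    """Fit the intersection-region model from calibration point pairs.

    Parameters
    ----------
    point_pairs
        Iterable of ``((vis_row, vis_col), (th_row, th_col))``.  The visible
        point is the top-left visible pixel of the thermal cell's footprint;
        the thermal point is the 0-based cell index.  At least two pairs are
        required and they must span both axes.
    grid_size
        ``(rows, cols)`` of the thermal matrix.

    Returns
    -------
    RegistrationModel
        With per-axis scale and offset recovered by ordinary least squares
        and ``residual_cells`` set to the RMS residual in cell units.
    """
    pairs = list(point_pairs)
    if len(pairs) < 2:
        raise FitError("at least two calibration pairs are required")
    vis = np.asarray([p[0] for p in pairs], dtype=float)
    th = np.asarray([p[1] for p in pairs], dtype=float)

    scale_r, row0 = _fit_axis(vis[:, 0], th[:, 0])
    scale_c, col0 = _fit_axis(vis[:, 1], th[:, 1])

    pred_r = row0 + scale_r * th[:, 0]
    pred_c = col0 + scale_c * th[:, 1]
    res = np.concatenate(
        [(vis[:, 0] - pred_r) / scale_r, (vis[:, 1] - pred_c) / scale_c]
    )
    rms = float(np.sqrt(np.mean(res**2)))

    gr, gc = grid_size
    return RegistrationModel(
        visible_roi=(row0, col0, row0 + gr * scale_r, col0 + gc * scale_c),
        scale_rows=scale_r,
        scale_cols=scale_c,
        grid_size=(gr, gc),
        residual_cells=rms,
    )


def register_mask(
    mask: np.ndarray,
    model: RegistrationModel,
    min_fraction: float = 0.5,
) -> np.ndarray:
    """Project a visible-resolution canopy mask onto the thermal grid.

    The mask is cropped to the model's intersection region; each thermal
    cell becomes canopy iff the fraction of its contributing visible pixels
    that are canopy is ``>= min_fraction`` (ties count as canopy).

    Parameters
    ----------
    mask
        Boolean array at visible resolution.
    model
        Fitted registration model.
    min_fraction
        Canopy-pixel fraction required for a cell, in (0, 1].

    Returns
    -------
    numpy.ndarray
        Boolean array of shape ``model.grid_size``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ShapeError("mask must be 2-D")
    if not 0 < min_fraction <= 1:
        raise ConfigurationError("min_fraction must be in (0, 1]")
    row0, col0, row1, col1 = model.visible_roi
    H, W = mask.shape
    if row0 < 0 or col0 < 0 or row1 > H + 1e-9 or col1 > W + 1e-9:
        raise ShapeError(
            f"intersection region {model.visible_roi} exceeds mask shape {mask.shape}"
        )
    return _bin_fractions(mask, model) >= min_fraction


def _bin_fractions(mask: np.ndarray, model: RegistrationModel) -> np.ndarray:
    """Per-thermal-cell fraction of true visible pixels inside the ROI."""
    row0, col0, row1, col1 = model.visible_roi
    gr, gc = model.grid_size
    rows = np.arange(int(np.ceil(row0)), int(np.floor(row1 - 1e-9)) + 1)
    cols = np.arange(int(np.ceil(col0)), int(np.floor(col1 - 1e-9)) + 1)
    rows = rows[(rows >= 0) & (rows < mask.shape[0])]
    cols = cols[(cols >= 0) & (cols < mask.shape[1])]
    ri = np.floor((rows - row0) / model.scale_rows).astype(int).clip(0, gr - 1)
    ci = np.floor((cols - col0) / model.scale_cols).astype(int).clip(0, gc - 1)

    sub = mask[np.ix_(rows, cols)].astype(np.int64)
    flat_idx = (ri[:, None] * gc + ci[None, :]).ravel()
    true_counts = np.bincount(flat_idx, weights=sub.ravel(), minlength=gr * gc)
    tot_counts = np.bincount(flat_idx, minlength=gr * gc)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot_counts > 0, true_counts / tot_counts, 0.0)
    return frac.reshape(gr, gc)
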