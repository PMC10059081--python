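"""On-disk formats, session manifests, configuration and the pipeline runner.

Formats: visible frames and masks are 8-bit PNG (masks 0/255); thermal
matrices are either plain CSV in degrees Celsius (the canonical,
human-diffable test format) or 16-bit grayscale TIFF in centikelvin
(``value = K * 100``, the native radiometric convention of low-cost
longwave cameras), with the encoding declared in the session manifest.
Manifests, registration models and results are JSON; field-day time series
are long-form CSV (timestamp, channel, value) with ISO 8601 timestamps
carrying an explicit UTC offset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from canopytherm import extraction, segmentation
from canopytherm.comparison import AgreementResult, FieldDay
from canopytherm.errors import (
    CanopyThermError,
    ConfigurationError,
    FormatError,
    InsufficientROIError,
)
from canopytherm.protocol import ProtocolConfig
from canopytherm.registration import RegistrationModel, register_mask
from canopytherm.scene_sim import (
    DriftModel,
    FieldDayConfig,
    RepetitionCapture,
    SceneConfig,
    SeriesCapture,
    Session,
)
from canopytherm.segmentation import SegmentationConfig
from canopytherm.types import ThermalFrame

__all__ = [
    "read_thermal",
    "write_thermal",
    "read_mask",
    "write_mask",
    "read_visible",
    "write_visible",
    "write_session",
    "read_session",
    "write_field_day",
    "read_field_day",
    "load_config",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger(__name__)

THERMAL_ENCODINGS = ("csv_celsius", "tiff_centikelvin_u16")
MIN_PHYSICAL_C = -80.0  # coldest plausible field temperature
DEFAULT_BASE_TIME = "2022-07-22T10:00:00+02:00"


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def read_thermal(
    path: str | Path,
    declared_encoding: str = "csv_celsius",
    expected_shape: Optional[tuple[int, int]] = None,
) -> ThermalFrame:
    """Read a thermal matrix in degrees Celsius.

    ``tiff_centikelvin_u16`` values decode as ``value / 100 - 273.15``.
    Non-finite values and temperatures below -80 C (non-physical for field
    scenes, e.g. a zero-filled raw file) are rejected.
    """
    path = Path(path)
    if declared_encoding == "csv_celsius":
        data = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    elif declared_encoding == "tiff_centikelvin_u16":
        raw = tifffile.imread(path)
        if raw.dtype != np.uint16:
            raise FormatError(f"{path}: expected uint16 centikelvin TIFF, got {raw.dtype}")
        data = raw.astype(float) / 100.0 - 273.15
    else:
        raise FormatError(f"unknown thermal encoding {declared_encoding!r}")
    if data.ndim != 2:
        raise FormatError(f"{path}: thermal data must be 2-D")
    if not np.isfinite(data).all():
        raise FormatError(f"{path}: non-finite temperature values")
    if data.min() < MIN_PHYSICAL_C:
        raise FormatError(
            f"{path}: non-physical temperature {data.min():.2f} C (< {MIN_PHYSICAL_C} C)"
        )
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise FormatError(
            f"{path}: shape {data.shape} does not match declared {expected_shape}"
        )
    return ThermalFrame(data=data)


def write_thermal(
    path: str | Path, frame: ThermalFrame | np.ndarray, encoding: str = "csv_celsius"
) -> None:
    data = frame.data if isinstance(frame, ThermalFrame) else np.asarray(frame)
    path = Path(path)
    if encoding == "csv_celsius":
        np.savetxt(path, data, delimiter=",", fmt="%.4f")
    elif encoding == "tiff_centikelvin_u16":
        ck = np.round((data + 273.15) * 100.0)
        if ck.min() < 0 or ck.max() > np.iinfo(np.uint16).max:
            raise FormatError("temperatures out of centikelvin uint16 range")
        tifffile.imwrite(path, ck.astype(np.uint16))
    else:
        raise FormatError(f"unknown thermal encoding {encoding!r}")


def read_mask(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_visible(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim != 3 or img.shape[2] < 3:
        raise FormatError(f"{path}: expected an RGB image")
    return img[..., :3]


def write_visible(path: str | Path, visible: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(visible, dtype=np.uint8))


# ---------------------------------------------------------------------------
# session manifests
# ---------------------------------------------------------------------------

def _iso(base: pd.Timestamp, offset_s: float) -> str:
    return (base + pd.Timedelta(seconds=float(offset_s))).isoformat()


def write_session(
    session: Session,
    out_dir: str | Path,
    *,
    thermal_encoding: str = "csv_celsius",
    base_time: str = DEFAULT_BASE_TIME,
    session_id: str = "session",
    include_truth: bool = True,
) -> Path:
    """Write a session to disk and return the manifest path."""
    if thermal_encoding not in THERMAL_ENCODINGS:
        raise FormatError(f"unknown thermal encoding {thermal_encoding!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = pd.Timestamp(base_time)

    write_visible(out_dir / "visible.png", session.visible)
    ext = "csv" if thermal_encoding == "csv_celsius" else "tif"

    series_records = []
    for s_idx, series in enumerate(session.series):
        reps = []
        for r_idx, rep in enumerate(series.repetitions):
            rel = f"thermal_s{s_idx:02d}_r{r_idx:03d}.{ext}"
            write_thermal(out_dir / rel, rep.thermal, thermal_encoding)
            reps.append(
                {
                    "visible_path": "visible.png",
                    "thermal_path": rel,
                    "capture_time": _iso(base, rep.thermal.timestamp_s),
                    "timestamp_s": rep.thermal.timestamp_s,
                    "time_since_ffc_s": rep.thermal.time_since_ffc_s,
                    "transient": rep.transient,
                    "gust": rep.gust,
                }
            )
        series_records.append(
            {
                "ffc_time": _iso(base, series.ffc_time_s),
                "ffc_time_s": series.ffc_time_s,
                "repetitions": reps,
            }
        )

    manifest = {
        "session_id": session_id,
        "base_time": base.isoformat(),
        "thermal_encoding": thermal_encoding,
        "grid_size_thermal": list(session.series[0].repetitions[0].thermal.shape),
        "emissivity": session.series[0].repetitions[0].thermal.emissivity,
        "reflected_temp_C": session.series[0].repetitions[0].thermal.reflected_temp_C,
        "series": series_records,
    }
    if session.protocol is not None:
        manifest["protocol"] = dataclasses.asdict(session.protocol)
    if include_truth:
        write_mask(out_dir / "truth_mask.png", session.truth_mask)
        write_mask(out_dir / "truth_mask_thermal.png", session.truth_mask_thermal)
        manifest["ground_truth"] = {
            "canopy_temp_C": session.truth_canopy_temp_C,
            "mask_path": "truth_mask.png",
            "mask_thermal_path": "truth_mask_thermal.png",
        }

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_session(manifest_path: str | Path) -> Session:
    """Load a session from its manifest, validating paths and timing."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    m = json.loads(manifest_path.read_text())
    encoding = m.get("thermal_encoding")
    if encoding not in THERMAL_ENCODINGS:
        raise FormatError(f"manifest declares unknown thermal encoding {encoding!r}")
    grid = tuple(m["grid_size_thermal"])

    def _resolve(rel: str) -> Path:
        p = root / rel
        if not p.exists():
            raise FormatError(f"manifest references missing file: {p}")
        return p

    visible = read_visible(_resolve(m["series"][0]["repetitions"][0]["visible_path"]))

    series_list = []
    for s in m["series"]:
        reps = []
        for r in s["repetitions"]:
            if r["timestamp_s"] < s["ffc_time_s"]:
                raise FormatError("repetition captured before its series FFC")
            frame = read_thermal(_resolve(r["thermal_path"]), encoding, expected_shape=grid)
            frame.time_since_ffc_s = r["time_since_ffc_s"]
            frame.timestamp_s = r["timestamp_s"]
            frame.emissivity = m.get("emissivity", 1.0)
            frame.reflected_temp_C = m.get("reflected_temp_C", 22.0)
            reps.append(
                RepetitionCapture(
                    thermal=frame,
                    transient=bool(r["transient"]),
                    gust=bool(r.get("gust", False)),
                )
            )
        series_list.append(SeriesCapture(ffc_time_s=s["ffc_time_s"], repetitions=reps))

    proto = None
    if m.get("protocol"):
        proto = ProtocolConfig(**m["protocol"])

    truth = m.get("ground_truth", {})
    if truth:
        truth_mask = read_mask(_resolve(truth["mask_path"]))
        truth_mask_th = read_mask(_resolve(truth["mask_thermal_path"]))
        truth_temp = float(truth["canopy_temp_C"])
    else:
        truth_mask = np.zeros(visible.shape[:2], dtype=bool)
        truth_mask_th = np.zeros(grid, dtype=bool)
        truth_temp = float("nan")

    return Session(
        visible=visible,
        truth_mask=truth_mask,
        truth_mask_thermal=truth_mask_th,
        truth_canopy_temp_C=truth_temp,
        series=series_list,
        config=None,
        drift=None,
        protocol=proto,
    )


# ---------------------------------------------------------------------------
# field days
# ---------------------------------------------------------------------------

def write_field_day(day: FieldDay, path: str | Path) -> None:
    """Long-form CSV: timestamp, channel, value."""
    frames = []
    for name, series in day.channels.items():
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": [t.isoformat() for t in series.index],
                    "channel": name,
                    "value": series.to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_field_day(path: str | Path, metadata: Optional[dict] = None) -> FieldDay:
    df = pd.read_csv(path)
    required = {"timestamp", "channel", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"field-day CSV needs columns {sorted(required)}")
    channels = {}
    for name, grp in df.groupby("channel"):
        idx = pd.DatetimeIndex(pd.to_datetime(grp["timestamp"]))
        channels[name] = pd.Series(
            grp["value"].to_numpy(), index=idx, name=name
        ).sort_index()
    meta = dict(metadata or {})
    if "T_S" in channels and len(channels["T_S"]) > 1:
        diffs = np.diff(channels["T_S"].index.asi8)
        meta.setdefault(
            "thermal_period_min", float(np.median(diffs)) / 60e9
        )
    return FieldDay(channels=channels, metadata=meta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {
    "scene": SceneConfig,
    "drift": DriftModel,
    "protocol": ProtocolConfig,
    "field_day": FieldDayConfig,
    "segmentation": SegmentationConfig,
}


def _build_dataclass(cls, values: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in values.items():
        if key not in fields:
            raise ConfigurationError(f"{cls.__name__}: unknown option {key!r}")
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path) -> dict:
    """Parse a YAML config file into the package's dataclasses by section."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for section, values in raw.items():
        if section not in _CONFIG_SECTIONS:
            raise ConfigurationError(f"unknown config section {section!r}")
        out[section] = _build_dataclass(_CONFIG_SECTIONS[section], values or {})
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    session: Session | str | Path,
    registration_model: RegistrationModel,
    seg_config: Optional[SegmentationConfig] = None,
    *,
    min_canopy_cells: int = extraction.DEFAULT_MIN_CANOPY_CELLS,
    out_dir: Optional[str | Path] = None,
) -> tuple[extraction.SessionResult, dict]:
    """Segment -> register -> extract -> summarise for one session.

    Returns the session result plus per-stage artifacts (visible mask,
    registered mask, per-repetition readings, series summaries).  Stage
    failures are re-raised with the stage named; when ``out_dir`` is given
    the intermediate mask, readings table and result JSON are written
    there.
    """
    if isinstance(session, (str, Path)):
        session = read_session(session)
    seg_config = seg_config or SegmentationConfig()

    try:
        mask_vis = segmentation.segment(session.visible, seg_config)
    except CanopyThermError as exc:
        raise type(exc)(f"segmentation stage: {exc}") from exc

    try:
        mask_th = register_mask(mask_vis, registration_model)
    except CanopyThermError as exc:
        raise type(exc)(f"registration stage: {exc}") from exc

    try:
        per_series = extraction.session_readings(
            session, mask_th, min_canopy_cells=min_canopy_cells
        )
        summaries = [
            extraction.summarize_series(r) for r in per_series if r
        ]
        if not summaries:
            raise InsufficientROIError("no series produced usable repetitions")
        result = extraction.summarize_session(summaries)
    except CanopyThermError as exc:
        raise type(exc)(f"extraction stage: {exc}") from exc

    artifacts = {
        "mask_visible": mask_vis,
        "mask_thermal": mask_th,
        "readings": per_series,
        "series_summaries": summaries,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mask(out_dir / "mask_visible.png", mask_vis)
        write_mask(out_dir / "mask_thermal.png", mask_th)
        rows = [
            {
                "series": s_idx,
                "repetition": r_idx,
                "median_C": rd.median_C,
                "mean_C": rd.mean_C,
                "std_C": rd.std_C,
                "n_masked": rd.n_masked,
                "n_retained": rd.n_retained,
                "threshold_C": rd.threshold_C,
            }
            for s_idx, readings in enumerate(per_series)
            for r_idx, rd in enumerate(readings)
        ]
        pd.DataFrame(rows).to_csv(
            out_dir / "readings.csv", index=False, float_format="%.3f"
        )
        (out_dir / "result.json").write_text(
            json.dumps(dataclasses.asdict(result), indent=2)
        )
    return result, artifacts


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(
    out_dir: str | Path,
    *,
    results: Optional[Sequence[extraction.SessionResult]] = None,
    agreement: Optional[AgreementResult] = None,
    costs: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Write a JSON + CSV report bundle.

    The JSON carries full-precision values (round-trips exactly); CSV
    tables format temperatures at 3 decimals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload: dict = {}
    if results is not None:
        payload["sessions"] = [dataclasses.asdict(r) for r in results]
    if agreement is not None:
        payload["agreement"] = agreement.to_dict()
    if costs is not None:
        payload["protocols"] = costs.to_dict(orient="records")
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2))
    written["json"] = json_path

    if costs is not None:
        csv_path = out_dir / "protocols.csv"
        costs.to_csv(csv_path, index=False, float_format="%.3f")
        written["protocols_csv"] = csv_path
    if results is not None:
        csv_path = out_dir / "sessions.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            csv_path, index=False, float_format="%.3f"
        )
        written["sessions_csv"] = csv_path
    return written
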