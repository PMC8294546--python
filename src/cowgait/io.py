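"""Trial data model and delimited-text I/O.

A trial is a directory with one tab-separated file per sensor location.  Each
file carries a ``# key: value`` metadata header (location, rate, ranges,
units) followed by a column header and the sample rows ``t ax ay az gx gy gz``.
Units are fixed internally: seconds, m/s^2 and deg/s; accelerations declared
in g in the header are converted at ingest.

Plain text was chosen over a binary container deliberately: at 200 Hz and
desk-scale trial lengths the files stay inspectable with ordinary tools, and
floats are written with 17 significant digits so a write/read round trip is
bit exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import GRAVITY, LIMBS, LOCATIONS, Config

log = logging.getLogger("cowgait")

#: factory accelerometer/gyro range metadata per placement class
UPPER_BODY_RANGES = {"accel_low_g": 8, "accel_high_g": 100, "gyro_dps": 2000}
LIMB_RANGES = {"accel_low_g": 16, "accel_high_g": 200, "gyro_dps": 2000}


class TrialFormatError(ValueError):
    """Malformed trial file content; message names the file (and line)."""


@dataclass
class SensorStream:
    """One location's synchronized 6-axis IMU time series.

    time is 0-based seconds from recording start, strictly increasing and
    uniform at ``rate``; accel in m/s^2, gyro in deg/s, both shaped (n, 3).
    """

    location: str
    rate: float
    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.location not in LOCATIONS:
            raise TrialFormatError(f"unknown sensor location {self.location!r}")
        n = self.time.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise TrialFormatError(
                f"{self.location}: channel lengths differ "
                f"(time {n}, accel {self.accel.shape}, gyro {self.gyro.shape})"
            )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - 1.0 / self.rate) > 1e-6):
                raise TrialFormatError(f"{self.location}: non-uniform sampling")
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.accel))
            and np.all(np.isfinite(self.gyro))
        ):
            raise TrialFormatError(f"{self.location}: non-finite samples")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclass
class Trial:
    """All sensor streams of one measurement on one cow, plus provenance."""

    cow_id: str
    measurement_id: str
    streams: dict[str, SensorStream]
    calibration_window: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        t0, t1 = self.calibration_window
        if t1 - t0 < 0:
            raise TrialFormatError("calibration window has negative length")
        rates = {s.rate for s in self.streams.values()}
        if len(rates) > 1:
            raise TrialFormatError(f"streams disagree on sampling rate: {rates}")

    def limb_streams(self) -> dict[str, SensorStream]:
        return {k: v for k, v in self.streams.items() if k in LIMBS}

    def upper_body_streams(self) -> dict[str, SensorStream]:
        return {k: v for k, v in self.streams.items() if k not in LIMBS}

    def require_limbs(self) -> None:
        missing = [l for l in LIMBS if l not in self.streams]
        if missing:
            raise TrialFormatError(f"trial lacks limb streams {missing}")


_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def _default_ranges(location: str) -> dict:
    return dict(LIMB_RANGES if location in LIMBS else UPPER_BODY_RANGES)


def write_trial(trial: Trial, path: str | Path, force: bool = False) -> None:
    """Write one delimited file per stream plus a trial metadata file.

    Floats carry 17 significant digits so read∘write is the identity on the
    sample values.  Refuses to overwrite an existing trial unless ``force``.
    """
    if not trial.streams:
        raise TrialFormatError("refusing to write a trial with no streams")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta_path = path / "trial.txt"
    if meta_path.exists() and not force:
        raise FileExistsError(f"{path} already holds a trial (use force=True)")
    t0, t1 = trial.calibration_window
    meta_path.write_text(
        f"cow_id: {trial.cow_id}\n"
        f"measurement_id: {trial.measurement_id}\n"
        f"calibration_start_s: {t0!r}\n"
        f"calibration_end_s: {t1!r}\n"
    )
    for loc, s in sorted(trial.streams.items()):
        lines = [
            f"# location: {loc}",
            f"# rate_hz: {s.rate!r}",
            f"# accel_units: m/s^2",
            f"# gyro_units: deg/s",
        ]
        ranges = {**_default_ranges(loc), **s.meta}
        for key in ("accel_low_g", "accel_high_g", "gyro_dps"):
            lines.append(f"# {key}: {ranges[key]}")
        lines.append("\t".join(_COLUMNS))
        data = np.column_stack([s.time, s.accel, s.gyro])
        for row in data:
            lines.append("\t".join(f"{v:.17g}" for v in row))
        (path / f"{loc}.tsv").write_text("\n".join(lines) + "\n")
    log.info("wrote trial %s/%s to %s", trial.cow_id, trial.measurement_id, path)


def _read_stream_file(fp: Path) -> SensorStream:
    meta: dict = {}
    header_done = False
    rows: list[list[float]] = []
    with fp.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header_done:
                    raise TrialFormatError(f"{fp}:{lineno}: comment after data")
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError as exc:
                    raise TrialFormatError(f"{fp}:{lineno}: malformed header") from exc
                meta[key.strip()] = value.strip()
                continue
            if not header_done:
                if tuple(line.split("\t")) != _COLUMNS:
                    raise TrialFormatError(
                        f"{fp}:{lineno}: expected column header {' '.join(_COLUMNS)}"
                    )
                header_done = True
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise TrialFormatError(f"{fp}:{lineno}: expected {len(_COLUMNS)} columns")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise TrialFormatError(f"{fp}:{lineno}: non-numeric sample") from exc
    if "location" not in meta or "rate_hz" not in meta:
        raise TrialFormatError(f"{fp}: header lacks location/rate_hz")
    if not rows:
        raise TrialFormatError(f"{fp}: no samples")
    data = np.array(rows, dtype=float)
    accel = data[:, 1:4]
    if meta.get("accel_units", "m/s^2") == "g":
        accel = accel * GRAVITY
    ranges = {
        k: float(meta[k]) for k in ("accel_low_g", "accel_high_g", "gyro_dps") if k in meta
    }
    return SensorStream(
        location=meta["location"],
        rate=float(meta["rate_hz"]),
        time=data[:, 0],
        accel=accel,
        gyro=data[:, 4:7],
        meta=ranges,
    )


def read_trial(path: str | Path, config: Config | None = None) -> Trial:
    """Read a trial directory written by :func:`write_trial`.

    Missing optional (upper-body) locations are tolerated; downstream stages
    that need limb streams check for them explicitly.
    """
    path = Path(path)
    meta_path = path / "trial.txt"
    if not meta_path.exists():
        raise TrialFormatError(f"{path}: no trial.txt metadata file")
    tmeta: dict = {}
    for lineno, line in enumerate(meta_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            key, value = line.split(":", 1)
        except ValueError as exc:
            raise TrialFormatError(f"{meta_path}:{lineno}: malformed line") from exc
        tmeta[key.strip()] = value.strip()
    streams = {}
    for fp in sorted(path.glob("*.tsv")):
        if fp.stem not in LOCATIONS:  # sidecars (e.g. ground truth) are not streams
            continue
        s = _read_stream_file(fp)
        streams[s.location] = s
    lengths = {s.n for s in streams.values()}
    if len(lengths) > 1:
        raise TrialFormatError(f"{path}: streams have mismatched lengths {lengths}")
    return Trial(
        cow_id=tmeta.get("cow_id", "unknown"),
        measurement_id=tmeta.get("measurement_id", "unknown"),
        streams=streams,
        calibration_window=(
            float(tmeta.get("calibration_start_s", 0.0)),
            float(tmeta.get("calibration_end_s", 5.0)),
        ),
    )
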