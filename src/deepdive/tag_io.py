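"""Tag-record I/O, run configuration and result export.

The on-disk tag format is a plain CSV with columns
``t,depth,ax,ay,az,mx,my,mz[,speed]`` sampled on a uniform grid.  Depth is
metres positive down; acceleration is specific acceleration in m s^-2 in the
whale frame (after the mounting rotation has been applied); magnetism is the
unit-normalised field vector.  Click-bout annotations live in a separate CSV
``deployment_id,start_s,end_s``.

Missing rows split a record into segments: dives are never detected across a
gap, and filters never smooth across one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyRecordError, FormatError

__all__ = [
    "TagSeries",
    "RunConfig",
    "read_tag_csv",
    "write_tag_csv",
    "read_click_csv",
    "write_results",
    "trim_deployment",
]

_TAG_COLUMNS = ["t", "depth", "ax", "ay", "az", "mx", "my", "mz"]


@dataclass
class TagSeries:
    """Synchronised multi-sensor time series for one tag deployment.

    Attributes
    ----------
    deployment_id, location
        Identifiers carried into every output table.
    fs
        Sampling rate in Hz.  ``t`` advances by ``1/fs`` within a segment.
    t, depth
        Seconds since tag-on and depth in metres (positive down).
    accel, mag
        ``(n, 3)`` whale-frame specific acceleration (m s^-2) and
        unit-normalised magnetic field vector.
    speed
        Optional paddlewheel speed in m s^-1.
    click_bouts
        Optional list of ``(start_s, end_s)`` intervals of regular clicking.
        ``None`` means *no acoustic coverage* (distinct from an empty list).
    mounting_rotation
        3x3 orthonormal matrix that was used to map tag frame to whale frame.
    segment_bounds
        Half-open ``(start, stop)`` index pairs delimiting gap-free segments.
    """

    deployment_id: str
    location: str
    fs: float
    t: np.ndarray
    depth: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    speed: np.ndarray | None = None
    click_bouts: list[tuple[float, float]] | None = None
    mounting_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
        if not self.segment_bounds:
            self.segment_bounds = [(0, len(self.t))]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.t)
        if n == 0:
            raise EmptyRecordError("tag series has no samples")
        for arr, name in ((self.depth, "depth"), (self.accel, "accel"), (self.mag, "mag")):
            if len(arr) != n:
                raise FormatError(f"{name} length {len(arr)} != t length {n}")
        if self.accel.shape != (n, 3) or self.mag.shape != (n, 3):
            raise FormatError("accel and mag must be (n, 3) arrays")
        dt = 1.0 / self.fs
        for i0, i1 in self.segment_bounds:
            seg_dt = np.diff(self.t[i0:i1])
            if seg_dt.size and (np.any(seg_dt <= 0) or np.any(np.abs(seg_dt - dt) > 1e-5)):
                raise FormatError("t must increase uniformly by 1/fs within a segment")
        if np.any(self.depth < -1.0):
            raise FormatError("depth below -1 m (sensor offset too large)")
        norms = np.linalg.norm(self.mag, axis=1)
        if np.any(np.abs(norms - 1.0) > 0.05):
            raise FormatError("magnetic field vector norm outside 1 +/- 0.05")
        R = np.asarray(self.mounting_rotation, dtype=float)
        if R.shape != (3, 3) or np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6:
            raise FormatError("mounting_rotation must be orthonormal to 1e-6")
        if self.click_bouts is not None:
            bouts = sorted(self.click_bouts)
            for (s0, e0), (s1, _e1) in zip(bouts, bouts[1:]):
                if s1 < e0:
                    raise FormatError("click bouts overlap")
            for s, e in bouts:
                if s < self.t[0] - 1e-9 or e > self.t[-1] + 1e-9 or e < s:
                    raise FormatError("click bout outside record span")
            self.click_bouts = [tuple(b) for b in bouts]

    # -- conveniences -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(sum(self.t[i1 - 1] - self.t[i0] for i0, i1 in self.segment_bounds))

    def segments(self):
        """Iterate over gap-free ``slice`` objects."""
        for i0, i1 in self.segment_bounds:
            yield slice(i0, i1)


@dataclass
class RunConfig:
    """Pipeline configuration with the study defaults.

    ``dive_threshold_m=40`` (a submergence deeper than 40 m is a dive),
    ``trim_min=20`` (initial minutes excluded to let behaviour normalise
    after tagging), ``band_width_m=50`` depth bands, dead-reckoning at an
    assumed ``2 m s^-1``, and candidate cluster counts 2..6.
    """

    dive_threshold_m: float = 40.0
    trim_min: float = 20.0
    band_width_m: float = 50.0
    assumed_speed_ms: float = 2.0
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    seed: int = 0
    rounding: int = 1
    surface_band_m: float = 5.0
    min_dive_s: float = 60.0
    orient_smooth_s: float = 3.0
    pitch_smooth_s: float = 5.0
    restarts: int = 50

    def __post_init__(self) -> None:
        if self.dive_threshold_m <= 0 or self.band_width_m <= 0:
            raise ValueError("dive_threshold_m and band_width_m must be positive")
        self.k_range = tuple(int(k) for k in self.k_range)
        if min(self.k_range) < 2:
            raise ValueError("k_range minimum must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw.get("run", raw))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_tag_csv(
    path: str | Path,
    fs: float,
    mounting_rotation: np.ndarray | None = None,
    deployment_id: str | None = None,
    location: str = "",
    click_bouts: list[tuple[float, float]] | None = None,
) -> TagSeries:
    """Read a tag CSV into a validated :class:`TagSeries`.

    The mounting rotation (tag frame -> whale frame) is applied to the
    acceleration and magnetism columns.  Rows missing from the uniform grid
    are flagged as segment breaks; timestamps that are non-monotone or off
    the grid raise :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) == 0:
        raise EmptyRecordError(f"{path.name}: empty file")
    dt = 1.0 / fs
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        raise FormatError(f"{path.name}: timestamps not strictly increasing")
    steps = diffs / dt
    if np.any(np.abs(steps - np.round(steps)) > 1e-3):
        raise FormatError(f"{path.name}: timestamps off the 1/fs grid")
    breaks = np.nonzero(np.round(steps) > 1)[0]
    bounds = []
    start = 0
    for b in breaks:
        bounds.append((start, int(b) + 1))
        start = int(b) + 1
    bounds.append((start, len(t)))

    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    mag = df[["mx", "my", "mz"]].to_numpy(dtype=float)
    R = np.eye(3) if mounting_rotation is None else np.asarray(mounting_rotation, float)
    accel = accel @ R.T
    mag = mag @ R.T
    speed = df["speed"].to_numpy(dtype=float) if "speed" in df.columns else None
    return TagSeries(
        deployment_id=deployment_id or path.stem,
        location=location,
        fs=fs,
        t=t,
        depth=df["depth"].to_numpy(dtype=float),
        accel=accel,
        mag=mag,
        speed=speed,
        click_bouts=click_bouts,
        mounting_rotation=R,
        segment_bounds=bounds,
    )


def write_tag_csv(series: TagSeries, path: str | Path) -> Path:
    """Write a :class:`TagSeries` to CSV (6-decimal fixed point).

    Sensor values are written in the whale frame; a read/write round trip is
    lossless to 1e-6.
    """
    path = Path(path)
    cols = {
        "t": series.t,
        "depth": series.depth,
        "ax": series.accel[:, 0],
        "ay": series.accel[:, 1],
        "az": series.accel[:, 2],
        "mx": series.mag[:, 0],
        "my": series.mag[:, 1],
        "mz": series.mag[:, 2],
    }
    if series.speed is not None:
        cols["speed"] = series.speed
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    return path


def read_click_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read click-bout annotations: ``deployment_id,start_s,end_s``."""
    df = pd.read_csv(path)
    for col in ("deployment_id", "start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"click CSV missing column {col}")
    out: dict[str, list[tuple[float, float]]] = {}
    for dep, grp in df.groupby("deployment_id"):
        out[str(dep)] = [(float(s), float(e)) for s, e in zip(grp["start_s"], grp["end_s"])]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
) -> dict[str, Path]:
    """Write one CSV per table plus a JSON run manifest.

    The manifest records the configuration, seed, package/library versions
    and SHA-256 digests of any input files, so a run can be reproduced and
    audited.  Re-running with the same seed yields byte-identical tables.
    """
    if not tables:
        raise ValueError("tables must be non-empty")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    from . import __version__

    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "versions": {
            "deepdive": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "tables": {name: int(len(df)) for name, df in tables.items()},
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = mpath
    return written


def trim_deployment(series: TagSeries, trim_min: float) -> TagSeries:
    """Drop the first ``trim_min`` minutes of a deployment.

    Times stay expressed relative to the original tag-on instant.  Click
    bouts are clipped to the retained span.
    """
    if trim_min < 0:
        raise ValueError("trim_min must be >= 0")
    if trim_min == 0:
        return series
    t0 = series.t[0] + trim_min * 60.0
    keep = series.t >= t0 - 1e-9
    if not np.any(keep):
        raise EmptyRecordError("deployment shorter than the trim window")
    offset = int(np.argmax(keep))
    bounds = []
    for i0, i1 in series.segment_bounds:
        j0, j1 = max(i0, offset), i1
        if j1 > j0:
            bounds.append((j0 - offset, j1 - offset))
    if not bounds:
        raise EmptyRecordError("deployment shorter than the trim window")
    bouts = None
    if series.click_bouts is not None:
        bouts = [
            (max(s, t0), e)
            for s, e in series.click_bouts
            if e > t0
        ]
    return TagSeries(
        deployment_id=series.deployment_id,
        location=series.location,
        fs=series.fs,
        t=series.t[offset:],
        depth=series.depth[offset:],
        accel=series.accel[offset:],
        mag=series.mag[offset:],
        speed=None if series.speed is None else series.speed[offset:],
        click_bouts=bouts,
        mounting_rotation=series.mounting_rotation,
        segment_bounds=bounds,
    )
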