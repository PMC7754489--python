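"""Raster and table I/O plus run configuration.

Conventions used throughout the package
---------------------------------------
* All rasters are indexed ``[row, col]`` (cine series ``[row, col, cardiac_phase]``),
  0-based, with the row index increasing downward.
* The phase-encoding axis (``pe_axis``) -- the image axis along which ghosting
  replicas propagate -- is explicit metadata and is never inferred from image
  content.
* Phase images are radians in ``[-pi, pi)``; velocity images are cm/s, signed,
  with negative values meaning downward (caudal, through-plane) flow. The
  caller declares which of the two a file contains.

Rasters travel as NIfTI (.nii / .nii.gz), perforator tables as CSV with a
header row, and run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, io is the lower layer
    from .detection import PerforatorRecord

PEAxis = Literal["rows", "cols"]

#: Fixed CSV columns of a perforator table; one extra column per cardiac phase
#: (``v_t00``, ``v_t01``, ...) follows them.
PERFORATOR_TABLE_COLUMNS = (
    "id",
    "row",
    "col",
    "cluster_id",
    "cluster_size",
    "v_mean",
    "ci_low",
    "ci_high",
    "included",
    "exclusion_reason",
)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CardiacPCSeries:
    """A cardiac-resolved 2D phase-contrast acquisition of one slice.

    Attributes
    ----------
    magnitude:
        ``(rows, cols, n_phases)`` array, arbitrary intensity units.
    velocity:
        ``(rows, cols, n_phases)`` array in cm/s, signed; negative values are
        downward (caudal) through-plane flow. Values may exceed ``venc`` in
        real (aliased) data; they are never clipped here.
    venc:
        Velocity-encoding parameter in cm/s (> 0); a phase of pi maps to venc.
    pixel_size:
        In-plane pixel size in mm, ``(row, col)``.
    pe_axis:
        ``"rows"`` or ``"cols"``; the axis along which ghosts propagate.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    venc: float
    pixel_size: tuple[float, float] = (0.2, 0.2)
    pe_axis: PEAxis = "rows"

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        if mag.ndim != 3 or vel.ndim != 3:
            raise FormatError("magnitude and velocity must be 3-D (row, col, phase)")
        if mag.shape != vel.shape:
            raise FormatError(
                f"magnitude shape {mag.shape} != velocity shape {vel.shape}"
            )
        if mag.shape[2] < 2:
            raise FormatError("a cardiac series needs at least 2 cardiac phases")
        if not self.venc > 0:
            raise ConfigurationError("venc must be a positive velocity in cm/s")
        if self.pe_axis not in ("rows", "cols"):
            raise ConfigurationError(f"pe_axis must be 'rows' or 'cols', got {self.pe_axis!r}")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "velocity", vel)

    @property
    def shape(self) -> tuple[int, int]:
        """In-plane shape ``(rows, cols)``."""
        return self.magnitude.shape[:2]

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[2]

    @property
    def pe_axis_index(self) -> int:
        """0 if ghosts propagate along rows, 1 if along columns."""
        return 0 if self.pe_axis == "rows" else 1


MaskKind = Literal["brain_slice", "white_matter", "central_wm", "stripe", "ghost_truth"]


@dataclass(frozen=True)
class MaskRaster:
    """A binary in-plane mask with a declared role."""

    data: np.ndarray
    kind: MaskKind = "white_matter"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise FormatError("masks must be 2-D (row, col)")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be in {{0, 1}}, found {uniq[:5]}")
        object.__setattr__(self, "data", data.astype(bool))

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunable parameters of the detection + censoring pipeline.

    Pixel-unit parameters are defined on the (interpolated) acquisition grid.
    """

    # magnitude detrending before large-vessel identification
    detrend_window: int = 70
    # large-vessel identification
    vessel_top_fraction: float = 0.003
    vessel_min_cluster: int = 3
    # stripe geometry: clusters >= big_cluster_threshold voxels get the
    # (big_dilate, big_extend) rule, smaller ones (small_dilate, small_extend)
    big_cluster_threshold: int = 80
    big_dilate: int = 2
    big_extend: int = 200
    small_dilate: int = 1
    small_extend: int = 110
    #: "per_side": stripes grow by extend px on each side along pe_axis;
    #: "total": extend is the total added length (extend // 2 per side).
    extend_mode: Literal["per_side", "total"] = "per_side"
    #: scope of the top-percentile sort: brain mask (default) or whole image
    percentile_scope: Literal["brain", "image"] = "brain"
    # central-WM margin from the brain outside contour
    wm_margin: int = 80
    # detection
    alpha: float = 0.05
    phase_bg_window: int = 31
    connectivity: Literal[4, 8] = 8
    seed: int = 0

    _POSITIVE_INT_KEYS = (
        "detrend_window",
        "vessel_min_cluster",
        "big_cluster_threshold",
        "big_dilate",
        "big_extend",
        "small_dilate",
        "small_extend",
        "phase_bg_window",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key in self._POSITIVE_INT_KEYS:
            value = getattr(self, key)
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ConfigurationError(f"{key} must be a positive integer, got {value!r}")
        if not (isinstance(self.wm_margin, (int, np.integer)) and self.wm_margin >= 0):
            raise ConfigurationError(f"wm_margin must be a nonnegative integer, got {self.wm_margin!r}")
        if not 0 < self.vessel_top_fraction < 1:
            raise ConfigurationError(
                f"vessel_top_fraction must be in (0, 1), got {self.vessel_top_fraction!r}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if self.connectivity not in (4, 8):
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity!r}")
        if self.extend_mode not in ("per_side", "total"):
            raise ConfigurationError(f"extend_mode must be 'per_side' or 'total', got {self.extend_mode!r}")
        if self.percentile_scope not in ("brain", "image"):
            raise ConfigurationError(
                f"percentile_scope must be 'brain' or 'image', got {self.percentile_scope!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing keys take the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as YAML (reproduces the run)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def phase_to_velocity(phase: np.ndarray, venc: float) -> np.ndarray:
    """Map phase (radians) to velocity (cm/s): linear, odd, pi -> venc."""
    return np.asarray(phase, dtype=float) / np.pi * venc


def write_raster(data: np.ndarray, path: str | Path) -> None:
    """Write a 2-D or 3-D array as NIfTI with an identity affine."""
    arr = np.asarray(data)
    nib.save(nib.Nifti1Image(arr.astype(np.float64), affine=np.eye(4)), str(path))


def read_raster(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float)


def write_mask(mask: MaskRaster, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), affine=np.eye(4)), str(path)
    )


def read_mask(path: str | Path, kind: MaskKind = "white_matter") -> MaskRaster:
    return MaskRaster(data=np.rint(read_raster(path)).astype(np.uint8), kind=kind)


def read_pc_series(
    magnitude_path: str | Path,
    velocity_or_phase_path: str | Path,
    *,
    venc: float,
    pe_axis: PEAxis = "rows",
    pixel_size: tuple[float, float] = (0.2, 0.2),
    velocity_units: Literal["phase_rad", "cm_s"] = "phase_rad",
) -> CardiacPCSeries:
    """Read a magnitude/velocity NIfTI pair into a :class:`CardiacPCSeries`.

    If ``velocity_units`` is ``"phase_rad"``, the second raster is a phase
    image in radians and is converted linearly (``v = phase / pi * venc``);
    if ``"cm_s"`` it is passed through unchanged. Aliased velocities are
    preserved, never clipped.
    """
    if venc is None:
        raise ConfigurationError("venc is required metadata")
    mag = read_raster(magnitude_path)
    second = read_raster(velocity_or_phase_path)
    if mag.shape != second.shape:
        raise FormatError(
            f"magnitude {mag.shape} and velocity/phase {second.shape} shapes differ"
        )
    if velocity_units == "phase_rad":
        vel = phase_to_velocity(second, venc)
    elif velocity_units == "cm_s":
        vel = second
    else:
        raise ConfigurationError(f"velocity_units must be 'phase_rad' or 'cm_s', got {velocity_units!r}")
    return CardiacPCSeries(
        magnitude=mag, velocity=vel, venc=venc, pixel_size=pixel_size, pe_axis=pe_axis
    )


def write_pc_series(
    series: CardiacPCSeries, magnitude_path: str | Path, velocity_path: str | Path
) -> None:
    """Write magnitude and velocity (cm/s) stacks as a NIfTI pair."""
    write_raster(series.magnitude, magnitude_path)
    write_raster(series.velocity, velocity_path)


# ---------------------------------------------------------------------------
# Perforator tables
# ---------------------------------------------------------------------------


def records_to_frame(records: Sequence["PerforatorRecord"]) -> pd.DataFrame:
    """Tabulate perforator records: fixed columns then one per cardiac phase."""
    n_phases = len(records[0].v_curve) if records else 0
    curve_cols = [f"v_t{t:02d}" for t in range(n_phases)]
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "row": rec.row,
            "col": rec.col,
            "cluster_id": rec.cluster_id,
            "cluster_size": rec.cluster_size,
            "v_mean": rec.v_mean,
            "ci_low": rec.ci[0],
            "ci_high": rec.ci[1],
            "included": bool(rec.included),
            "exclusion_reason": rec.exclusion_reason,
        }
        row.update(dict(zip(curve_cols, rec.v_curve)))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PERFORATOR_TABLE_COLUMNS) + curve_cols)


def write_perforator_table(
    records: Sequence["PerforatorRecord"], path: str | Path
) -> None:
    """Write perforator records as CSV (header always present)."""
    records_to_frame(records).to_csv(path, index=False)


def read_perforator_table(path: str | Path) -> list["PerforatorRecord"]:
    """Inverse of :func:`write_perforator_table`."""
    from .detection import PerforatorRecord  # deferred: io is the lower layer

    frame = pd.read_csv(path)
    missing = set(PERFORATOR_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"perforator table missing columns: {sorted(missing)}")
    curve_cols = sorted(c for c in frame.columns if c.startswith("v_t"))
    records = []
    for _, row in frame.iterrows():
        records.append(
            PerforatorRecord(
                id=int(row["id"]),
                row=int(row["row"]),
                col=int(row["col"]),
                cluster_id=int(row["cluster_id"]),
                cluster_size=int(row["cluster_size"]),
                v_curve=row[curve_cols].to_numpy(dtype=float),
                v_mean=float(row["v_mean"]),
                ci=(float(row["ci_low"]), float(row["ci_high"])),
                included=bool(row["included"]),
                exclusion_reason=str(row["exclusion_reason"]),
            )
        )
    return records
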