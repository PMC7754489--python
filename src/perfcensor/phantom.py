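"""Synthetic 2D phase-contrast phantom with full ground truth.

The phantom emulates, statistically rather than via MR physics, the features
of a cardiac-gated 2D PC slice through deep white matter that the pipeline
must cope with:

* subvoxel perforating arteries — single-pixel sources with pulsatile
  downward (negative) velocity waveforms, attenuated by a partial-volume
  fraction;
* bright large-vessel clusters, plus attenuated ghost replicas of each
  cluster displaced along the phase-encoding axis at multiples of a ghost
  spacing (ghosts are modeled directly in image space as displaced copies;
  the analysis treats them purely as image-space bands);
* spurious velocity fluctuations inside the ghost bands (the false-positive
  generator the censoring step exists to remove);
* smooth multiplicative intensity inhomogeneity and Gaussian magnitude /
  velocity noise.

Two independently seeded random streams drive (a) scene geometry and (b)
noise, so different noise realizations can share an identical scene.

By default the injected per-sample velocity noise is derived from the
realized magnitude SNR through the phase-contrast relation
``sigma_v = sqrt(2) * venc / (pi * SNR)``, making the phantom's noise
self-consistent with the detector's noise model; set ``noise_sd_velocity``
explicitly to decouple them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .exceptions import ParameterError
from .io import CardiacPCSeries, MaskRaster, PEAxis, write_mask, write_pc_series
from .masking import central_wm


def make_waveform(
    v_mean: float,
    pi: float,
    n_phases: int,
    peak_phase_index: int = 3,
    pulse_width: float = 0.5,
) -> np.ndarray:
    """Raised-cosine systolic pulse on a baseline, with exact mean and PI.

    The curve is built so its arithmetic mean equals ``v_mean`` exactly and
    the pulsatility index of its magnitude, ``(max - min) / mean``, equals
    ``pi`` exactly: a raised-cosine bump of width ``pulse_width`` (fraction
    of the cardiac cycle) peaking at ``peak_phase_index`` is centered and
    scaled to unit range, then applied as ``|v_mean| * (1 + pi * bump)``.
    The sign of ``v_mean`` carries through (negative = downward flow).
    """
    if v_mean == 0:
        raise ParameterError("v_mean must be nonzero")
    if pi < 0:
        raise ParameterError(f"pi must be >= 0, got {pi}")
    if n_phases < 3:
        raise ParameterError(f"need n_phases >= 3, got {n_phases}")
    if not 0 < pulse_width <= 1:
        raise ParameterError(f"pulse_width must be in (0, 1], got {pulse_width}")
    if pi == 0:
        return np.full(n_phases, float(v_mean))
    t = np.arange(n_phases) / n_phases
    x = t - peak_phase_index / n_phases
    x -= np.round(x)  # wrap to [-0.5, 0.5): the cycle is periodic
    bump = np.where(
        np.abs(x) < pulse_width / 2,
        0.5 * (1.0 + np.cos(2 * np.pi * x / pulse_width)),
        0.0,
    )
    centered = bump - bump.mean()
    span = centered.max() - centered.min()
    if span == 0:
        raise ParameterError("pulse too narrow for the sampling: waveform is flat")
    shape_curve = centered / span  # unit range, zero mean
    magnitudes = np.abs(v_mean) * (1.0 + pi * shape_curve)
    if magnitudes.min() <= 0:
        raise ParameterError(
            f"pi={pi} too large: the velocity magnitude would cross zero"
        )
    return np.sign(v_mean) * magnitudes


@dataclass
class PhantomSpec:
    """Scene and noise parameters of the synthetic PC acquisition.

    Geometry defaults put two large-vessel clusters just outside the deep-WM
    analysis region with their ghost replicas crossing it, on a 256-square
    grid with 14 cardiac phases and venc 4 cm/s (the low-venc regime in which
    sub-cm/s perforator flow is measurable).
    """

    image_shape: tuple[int, int] = (256, 256)
    n_phases: int = 14
    venc: float = 4.0
    pe_axis: PEAxis = "rows"
    pixel_size: tuple[float, float] = (0.2, 0.2)
    # anatomy
    brain_radius: int = 120
    wm_radius: int = 105
    central_margin: int = 80  # planting margin from the brain contour, px
    tissue_intensity: float = 100.0
    # perforators
    n_perforators: int = 12
    n_on_ghost: int = 0
    perforator_vmean_range: tuple[float, float] = (-1.2, -0.5)
    perforator_pi: float = 0.45
    perforator_pv_fraction: float = 0.6
    peak_phase_index: int = 3
    min_separation: int = 5
    off_band_clearance: int = 12
    # large vessels and ghosts
    n_big_vessels: int = 2
    vessel_cluster_sizes: tuple[int, ...] = (100, 40)
    vessel_amplitude: float = 400.0
    ghost_spacing: int = 40
    n_ghost_replicas: int = 2
    #: explicit per-vessel readout-axis offsets from the image center;
    #: None places vessels on alternating sides at offset ~28 px
    vessel_ro_offsets: tuple[int, ...] | None = None
    ghost_amplitude_decay: float = 0.35
    ghost_velocity_factor: float = 3.0  # band velocity-noise sd, x background
    # intensity field and noise
    inhomogeneity_amplitude: float = 0.1
    noise_sd_magnitude: float = 2.0
    #: None derives the value from the realized magnitude SNR via the
    #: phase-contrast noise relation (self-consistent noise model).
    noise_sd_velocity: float | None = None
    rician_magnitude_noise: bool = False
    seed: int = 0
    geometry_seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_perforators < 0 or self.n_on_ghost < 0 or self.n_big_vessels < 0:
            raise ParameterError("counts must be nonnegative")
        if self.n_on_ghost > self.n_perforators:
            raise ParameterError("n_on_ghost cannot exceed n_perforators")
        if self.n_on_ghost > 0 and self.n_big_vessels == 0:
            raise ParameterError("on-ghost perforators need at least one vessel")
        lo, hi = self.perforator_vmean_range
        if not (lo < 0 and hi < 0 and lo <= hi):
            raise ParameterError(
                "perforator_vmean_range must be negative (downward flow)"
            )
        if not 0 < self.perforator_pv_fraction <= 1:
            raise ParameterError("perforator_pv_fraction must be in (0, 1]")
        if not 0 < self.ghost_amplitude_decay < 1:
            raise ParameterError("ghost_amplitude_decay must be in (0, 1)")
        if self.perforator_pi < 0:
            raise ParameterError("perforator_pi must be >= 0")
        if self.noise_sd_magnitude < 0 or (
            self.noise_sd_velocity is not None and self.noise_sd_velocity < 0
        ):
            raise ParameterError("noise SDs must be >= 0")
        if self.wm_radius > self.brain_radius:
            raise ParameterError("wm_radius cannot exceed brain_radius")
        if self.ghost_velocity_factor < 1:
            raise ParameterError("ghost_velocity_factor must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d


@dataclass(frozen=True)
class PlantedPerforator:
    """Ground truth for one planted perforator.

    ``v_curve`` is the velocity curve present in the velocity image at the
    planted pixel, i.e. the physiologic waveform already scaled by the
    partial-volume fraction.
    """

    row: int
    col: int
    v_curve: np.ndarray
    on_ghost: bool

    @property
    def v_mean(self) -> float:
        return float(self.v_curve.mean())


@dataclass(frozen=True)
class PhantomTruth:
    """Everything a test needs to grade the pipeline on one phantom."""

    perforators: tuple[PlantedPerforator, ...]
    ghost_truth: MaskRaster  # per-vessel bands extended across the image
    replica_mask: MaskRaster  # actual ghost-replica footprints
    vessel_clusters: tuple[frozenset[tuple[int, int]], ...]
    wm_mask: MaskRaster
    brain_mask: MaskRaster
    noise_sd_velocity: float

    @property
    def on_ghost(self) -> tuple[PlantedPerforator, ...]:
        return tuple(p for p in self.perforators if p.on_ghost)

    @property
    def off_ghost(self) -> tuple[PlantedPerforator, ...]:
        return tuple(p for p in self.perforators if not p.on_ghost)


# ---------------------------------------------------------------------------
# scene construction helpers
# ---------------------------------------------------------------------------


def _disk(shape: tuple[int, int], radius: int) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2


def _grow_blob(
    rng: np.random.Generator,
    seed_voxel: tuple[int, int],
    size: int,
    shape: tuple[int, int],
) -> frozenset[tuple[int, int]]:
    """Grow a compact connected blob by random 4-neighbor accretion."""
    blob = {seed_voxel}
    frontier = [seed_voxel]
    while len(blob) < size:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(4)]
        nr, nc = r + dr, c + dc
        if 0 <= nr < shape[0] and 0 <= nc < shape[1] and (nr, nc) not in blob:
            blob.add((nr, nc))
            frontier.append((nr, nc))
    return frozenset(blob)


def _sample_positions(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    taken: list[tuple[int, int]],
    min_sep: float,
) -> list[tuple[int, int]]:
    """Greedily sample ``n`` candidate pixels at pairwise distance >= min_sep."""
    order = rng.permutation(candidates.shape[0])
    chosen: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(candidates[idx, 0]), int(candidates[idx, 1])
        if all((r - tr) ** 2 + (c - tc) ** 2 >= min_sep**2 for tr, tc in taken + chosen):
            chosen.append((r, c))
            if len(chosen) == n:
                return chosen
    raise ParameterError(
        f"cannot plant {n} perforators at separation {min_sep}px: "
        f"only {len(chosen)} positions available"
    )


def synthesize(spec: PhantomSpec) -> tuple[CardiacPCSeries, PhantomTruth]:
    """Render the phantom scene into a magnitude/velocity series plus truth.

    Identical ``(seed, geometry_seed)`` give bit-identical output; changing
    ``seed`` alone changes only the noise realization, never the scene.
    """
    spec.validate()
    shape = tuple(spec.image_shape)
    geometry_seed = spec.geometry_seed if spec.geometry_seed is not None else spec.seed
    rng_geom = np.random.default_rng([geometry_seed, 1])
    rng_noise = np.random.default_rng([spec.seed, 2])
    pe = 0 if spec.pe_axis == "rows" else 1
    readout = 1 - pe
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    brain = _disk(shape, spec.brain_radius)
    wm = _disk(shape, spec.wm_radius)

    # --- large vessels and their ghost replicas -------------------------
    vessels: list[frozenset[tuple[int, int]]] = []
    for i in range(spec.n_big_vessels):
        size = spec.vessel_cluster_sizes[i % len(spec.vessel_cluster_sizes)]
        sign = -1 if i % 2 == 0 else 1
        # pe offset ~ 2 ghost spacings: the k=2 replica lands in deep WM;
        # readout offsets alternate sides so an artifact-free corridor
        # always remains between the two ghost bands
        pe_offset = sign * (2 * spec.ghost_spacing + int(rng_geom.integers(0, 6)))
        if spec.vessel_ro_offsets is not None:
            ro_offset = spec.vessel_ro_offsets[i % len(spec.vessel_ro_offsets)]
        else:
            ro_offset = sign * (28 + int(rng_geom.integers(-2, 3)))
        seed_voxel = [0, 0]
        seed_voxel[pe] = int(round(center[pe])) + pe_offset
        seed_voxel[readout] = int(round(center[readout])) + ro_offset
        vessels.append(_grow_blob(rng_geom, tuple(seed_voxel), size, shape))

    replica = np.zeros(shape, dtype=bool)
    ghost_truth = np.zeros(shape, dtype=bool)
    vessel_only = np.zeros(shape, dtype=bool)
    vessel_img = np.zeros(shape, dtype=float)
    for blob in vessels:
        vox = np.array(sorted(blob), dtype=int)
        vessel_img[vox[:, 0], vox[:, 1]] += spec.vessel_amplitude
        vessel_only[vox[:, 0], vox[:, 1]] = True
        # band: the blob's readout extent, swept across the full pe axis
        band = np.zeros(shape, dtype=bool)
        if pe == 0:
            band[:, vox[:, 1].min() : vox[:, 1].max() + 1] = True
        else:
            band[vox[:, 0].min() : vox[:, 0].max() + 1, :] = True
        ghost_truth |= band
        for k in range(1, spec.n_ghost_replicas + 1):
            amp = spec.vessel_amplitude * spec.ghost_amplitude_decay**k
            for sign in (-1, 1):
                shifted = vox.copy()
                shifted[:, pe] += sign * k * spec.ghost_spacing
                keep = (shifted[:, pe] >= 0) & (shifted[:, pe] < shape[pe])
                shifted = shifted[keep]
                vessel_img[shifted[:, 0], shifted[:, 1]] += amp
                replica[shifted[:, 0], shifted[:, 1]] = True

    wm &= ~vessel_only  # vessels are not WM tissue (replicas are: artifact, not anatomy)
    wm_mask = MaskRaster(data=wm.astype(np.uint8), kind="white_matter")
    brain_mask = MaskRaster(data=brain.astype(np.uint8), kind="brain_slice")

    # --- perforator placement in deep WM --------------------------------
    central = central_wm(wm_mask, brain_mask, spec.central_margin).data
    band_dist = ndimage.distance_transform_edt(~ghost_truth)
    off_candidates = np.argwhere(central & (band_dist >= spec.off_band_clearance))
    on_candidates = np.argwhere(central & replica)
    n_off = spec.n_perforators - spec.n_on_ghost
    positions: list[tuple[int, int]] = []
    flags: list[bool] = []
    if n_off:
        off = _sample_positions(rng_geom, off_candidates, n_off, [], spec.min_separation)
        positions += off
        flags += [False] * n_off
    if spec.n_on_ghost:
        on = _sample_positions(
            rng_geom, on_candidates, spec.n_on_ghost, positions, spec.min_separation
        )
        positions += on
        flags += [True] * spec.n_on_ghost

    perforators = []
    for (r, c), on_ghost in zip(positions, flags):
        lo, hi = spec.perforator_vmean_range
        v_mean = float(rng_geom.uniform(lo, hi))
        curve = make_waveform(
            v_mean, spec.perforator_pi, spec.n_phases, spec.peak_phase_index
        )
        perforators.append(
            PlantedPerforator(
                row=r,
                col=c,
                v_curve=spec.perforator_pv_fraction * curve,
                on_ghost=on_ghost,
            )
        )

    # --- magnitude -------------------------------------------------------
    smooth_brain = ndimage.gaussian_filter(brain.astype(float), sigma=2.0)
    field = np.ones(shape)
    if spec.inhomogeneity_amplitude > 0:
        low = ndimage.gaussian_filter(
            rng_geom.standard_normal(shape), sigma=min(shape) / 6.0
        )
        low /= np.abs(low).max()
        field = 1.0 + spec.inhomogeneity_amplitude * low
    mag0 = spec.tissue_intensity * smooth_brain * field + vessel_img

    n = spec.n_phases
    if spec.noise_sd_magnitude > 0:
        noise = rng_noise.normal(0.0, spec.noise_sd_magnitude, size=shape + (n,))
        if spec.rician_magnitude_noise:
            noise2 = rng_noise.normal(0.0, spec.noise_sd_magnitude, size=shape + (n,))
            magnitude = np.sqrt((mag0[:, :, None] + noise) ** 2 + noise2**2)
        else:
            magnitude = mag0[:, :, None] + noise
    else:
        magnitude = np.repeat(mag0[:, :, None], n, axis=2)

    # --- velocity --------------------------------------------------------
    if spec.noise_sd_velocity is not None:
        sd_v = spec.noise_sd_velocity
    elif spec.noise_sd_magnitude > 0:
        snr_true = float(mag0[central].mean()) / spec.noise_sd_magnitude
        sd_v = float(np.sqrt(2.0) * spec.venc / (np.pi * snr_true))
    else:
        sd_v = 0.0
    velocity = np.zeros(shape + (n,))
    if sd_v > 0:
        sd_map = np.full(shape, sd_v)
        sd_map[ghost_truth] *= spec.ghost_velocity_factor
        velocity += rng_noise.standard_normal(shape + (n,)) * sd_map[:, :, None]
    for p in perforators:
        velocity[p.row, p.col, :] += p.v_curve

    series = CardiacPCSeries(
        magnitude=magnitude,
        velocity=velocity,
        venc=spec.venc,
        pixel_size=spec.pixel_size,
        pe_axis=spec.pe_axis,
    )
    truth = PhantomTruth(
        perforators=tuple(perforators),
        ghost_truth=MaskRaster(data=ghost_truth.astype(np.uint8), kind="ghost_truth"),
        replica_mask=MaskRaster(data=replica.astype(np.uint8), kind="ghost_truth"),
        vessel_clusters=tuple(vessels),
        wm_mask=wm_mask,
        brain_mask=brain_mask,
        noise_sd_velocity=sd_v,
    )
    return series, truth


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[CardiacPCSeries, PhantomTruth]:
    """Synthesize and write the phantom plus ground truth next to it.

    Writes magnitude/velocity NIfTI, brain/WM/ghost-truth masks, a truth CSV
    of planted perforators (position, on-ghost flag, per-phase curve) and the
    resolved spec as YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth = synthesize(spec)
    write_pc_series(series, out / "magnitude.nii.gz", out / "velocity.nii.gz")
    write_mask(truth.brain_mask, out / "brain_mask.nii.gz")
    write_mask(truth.wm_mask, out / "wm_mask.nii.gz")
    write_mask(truth.ghost_truth, out / "ghost_truth.nii.gz")
    rows = []
    for i, p in enumerate(truth.perforators):
        row = {"id": i, "row": p.row, "col": p.col, "on_ghost": p.on_ghost,
               "v_mean": p.v_mean}
        row.update({f"v_t{t:02d}": v for t, v in enumerate(p.v_curve)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "truth_perforators.csv", index=False)
    (out / "phantom_spec.yaml").write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
    return series, truth
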