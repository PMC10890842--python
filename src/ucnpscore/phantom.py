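"""Synthetic microscopy phantoms with ground truth.

Emulates the two sample types the scoring pipeline is calibrated and applied
on, without any microscope data:

* **CPA phantoms** — near-monolayer fields of circular cells all at one HER2
  level, standing in for control pellet arrays. Each cell is drawn as a
  membrane ring arc whose angular extent encodes staining *completeness* and
  whose intensity encodes labeling strength, over a weak cytoplasmic fill.
* **Tissue phantoms** — the same geometry but with a per-region level map,
  standing in for tumor tissue with HER2-positive regions among negative
  cells.

Optional sparse bright Gaussian "cluster" artifacts model non-specifically
bound label aggregates, which persist through washing and matter most on the
low-expression samples. Noise is the conventional sCMOS model: Poisson shot
noise on the expected counts plus additive Gaussian read noise. A DAPI
channel (nuclear disks) and a Beer–Lambert brightfield counterpart (for
absorption-mode contrast comparisons) are generated from the same geometry.

Generation is a pure function of the spec, including its seed: identical
specs give bit-identical outputs, and every cell is recorded (center, radius,
level, realized completeness) as ground truth alongside a per-pixel level
grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import ALL_LEVELS, HER2Level
from .errors import PhantomError, UCNPScoreError
from .io import CalibratedImage, Channel, write_image

__all__ = [
    "LevelPreset",
    "DEFAULT_PRESETS",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "generate_cpa_series",
    "generate_dab_counterpart",
    "disk_region_map",
]


@dataclass(frozen=True)
class LevelPreset:
    """Staining appearance of one HER2 level.

    completeness: fraction of the membrane circumference stained, in [0, 1].
    membrane_intensity / cytoplasm_intensity: expected counts above background.
    """

    completeness: float
    membrane_intensity: float
    cytoplasm_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 1.0):
            raise PhantomError(f"completeness must be in [0,1], got {self.completeness}")
        if self.membrane_intensity < 0 or self.cytoplasm_intensity < 0:
            raise PhantomError("intensities must be >= 0")


# Complete intense rings for 3+, nearly complete moderate for 2+, patchy weak
# for 1+, unstained for 0 — mirroring the four-tier membrane-scoring rubric.
DEFAULT_PRESETS: dict[HER2Level, LevelPreset] = {
    HER2Level.THREE_PLUS: LevelPreset(1.0, 100.0, 5.0),
    HER2Level.TWO_PLUS: LevelPreset(0.9, 40.0, 2.0),
    HER2Level.ONE_PLUS: LevelPreset(0.4, 12.0, 1.0),
    HER2Level.ZERO: LevelPreset(0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one synthetic field."""

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # µm/px
    cell_count: int = 150
    cell_radius_um: float = 7.0
    cell_radius_sd_um: float = 1.0
    membrane_thickness_um: float = 1.0
    presets: Mapping[HER2Level, LevelPreset] = field(
        default_factory=lambda: dict(DEFAULT_PRESETS)
    )
    level: HER2Level = HER2Level.THREE_PLUS
    region_map: np.ndarray | None = None  # per-pixel level codes; overrides `level`
    clusters: bool = False
    cluster_density_per_mm2: float = 80.0
    cluster_intensity: float = 500.0
    cluster_sigma_um: float = 1.0
    background: float = 10.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    nucleus_radius_frac: float = 0.4
    dapi_intensity: float = 80.0
    dapi_background: float = 5.0
    placement_retries: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or min(self.shape) < 8:
            raise PhantomError(f"shape must be 2-D and at least 8 px, got {self.shape}")
        if self.pixel_size <= 0:
            raise PhantomError("pixel_size must be > 0")
        for name in ("cell_radius_um", "membrane_thickness_um", "cluster_sigma_um"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be > 0")
        if self.cell_count < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise PhantomError("counts and noise levels must be >= 0")
        if self.region_map is not None:
            rm = np.asarray(self.region_map)
            if rm.shape != tuple(self.shape):
                raise PhantomError(
                    f"region_map shape {rm.shape} != image shape {self.shape}"
                )
            if rm.min() < 0 or rm.max() > 3:
                raise PhantomError("region_map codes must be in {0,1,2,3}")
            object.__setattr__(self, "region_map", rm.astype(np.uint8))
        # level ordering must imply non-decreasing completeness and intensity
        ps = [self.presets[lvl] for lvl in ALL_LEVELS if lvl in self.presets]
        for a, b in zip(ps[:-1], ps[1:]):
            if b.completeness < a.completeness or b.membrane_intensity < a.membrane_intensity:
                raise PhantomError(
                    "presets must be non-decreasing in completeness and intensity "
                    "with HER2 level"
                )


@dataclass(frozen=True)
class PhantomOutput:
    """Generated channels plus ground truth."""

    ucnp: CalibratedImage
    dapi: CalibratedImage
    truth: np.ndarray  # per-pixel HER2 level codes (uint8)
    cells: pd.DataFrame  # center_x, center_y (px), radius_um, level, realized_completeness
    label_density: np.ndarray  # noiseless specific signal (counts above background)
    spec: PhantomSpec


_PLACEMENT_RESTARTS = 10  # whole-field restarts before declaring infeasible


def _place_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping cell centers; (cy, cx, radius_px).

    Each cell gets ``placement_retries`` darts; if a configuration jams
    before all cells are placed, the whole field is resampled (bounded number
    of restarts) before the density is declared infeasible. Deterministic:
    all draws come from the caller's generator.
    """
    H, W = spec.shape
    r_mean = spec.cell_radius_um / spec.pixel_size
    r_sd = spec.cell_radius_sd_um / spec.pixel_size
    margin_extra = spec.membrane_thickness_um / spec.pixel_size
    for _ in range(_PLACEMENT_RESTARTS):
        placed: list[tuple[float, float, float]] = []
        jammed = False
        for _i in range(spec.cell_count):
            ok = False
            for _try in range(spec.placement_retries):
                r = max(2.0, rng.normal(r_mean, r_sd))
                m = r + margin_extra
                if 2 * m >= min(H, W):
                    continue
                cy = rng.uniform(m, H - m)
                cx = rng.uniform(m, W - m)
                # allow a sliver of overlap (5%) — pellets are near-monolayer
                if all(
                    (cy - y) ** 2 + (cx - x) ** 2 >= (0.95 * (r + pr)) ** 2
                    for y, x, pr in placed
                ):
                    placed.append((cy, cx, r))
                    ok = True
                    break
            if not ok:
                jammed = True
                break
        if not jammed:
            return placed
    raise PhantomError(
        f"could not place {spec.cell_count} cells of radius ~{spec.cell_radius_um} µm "
        f"in a {H}×{W} px field within {spec.placement_retries} retries per cell "
        f"({_PLACEMENT_RESTARTS} restarts) — density too high"
    )


def _render_cell(
    signal: np.ndarray,
    truth: np.ndarray,
    dapi: np.ndarray,
    cy: float,
    cx: float,
    r: float,
    preset: LevelPreset,
    level: HER2Level,
    theta0: float,
    spec: PhantomSpec,
) -> float:
    """Draw one cell into the accumulators; returns realized completeness."""
    th = spec.membrane_thickness_um / spec.pixel_size
    ext = int(np.ceil(r + th / 2)) + 1
    y0, y1 = max(0, int(cy) - ext), min(signal.shape[0], int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(signal.shape[1], int(cx) + ext + 1)
    yy = np.arange(y0, y1)[:, None] - cy
    xx = np.arange(x0, x1)[None, :] - cx
    dist = np.hypot(yy, xx)
    box_sig = signal[y0:y1, x0:x1]
    box_truth = truth[y0:y1, x0:x1]
    box_dapi = dapi[y0:y1, x0:x1]

    inside = dist <= r
    box_truth[inside] = np.maximum(box_truth[inside], np.uint8(level))
    interior = dist <= r - th / 2
    if preset.cytoplasm_intensity > 0:
        np.maximum(box_sig, np.where(interior, preset.cytoplasm_intensity, 0.0), out=box_sig)

    ring = np.abs(dist - r) <= th / 2
    realized = 0.0
    if preset.completeness > 0 and preset.membrane_intensity > 0 and ring.any():
        ang = np.mod(np.arctan2(yy, xx) - theta0, 2 * np.pi)
        arc = ring & (ang <= 2 * np.pi * preset.completeness)
        np.maximum(box_sig, np.where(arc, preset.membrane_intensity, 0.0), out=box_sig)
        realized = float(arc.sum() / ring.sum())

    nucleus = dist <= spec.nucleus_radius_frac * r
    np.maximum(box_dapi, np.where(nucleus, spec.dapi_intensity, 0.0), out=box_dapi)
    return realized


def _add_clusters(signal: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Sprinkle sparse bright Gaussian spots (non-specifically bound label)."""
    H, W = spec.shape
    area_mm2 = H * W * (spec.pixel_size * 1e-3) ** 2
    n = rng.poisson(spec.cluster_density_per_mm2 * area_mm2)
    sigma = spec.cluster_sigma_um / spec.pixel_size
    ext = int(np.ceil(4 * sigma))
    for _ in range(n):
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        y0, y1 = max(0, int(cy) - ext), min(H, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(W, int(cx) + ext + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] - cy
        xx = np.arange(x0, x1)[None, :] - cx
        signal[y0:y1, x0:x1] += spec.cluster_intensity * np.exp(
            -(yy**2 + xx**2) / (2 * sigma**2)
        )


def _apply_noise(expected: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    img = rng.poisson(expected).astype(float) if spec.shot_noise else expected.copy()
    if spec.read_noise_sd > 0:
        img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    return np.maximum(img, 0.0)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate one synthetic field (UCNP + DAPI channels + ground truth).

    Cells are placed without overlap by rejection sampling; each is drawn as
    a single contiguous membrane arc of angular extent 2π·completeness
    starting at a random angle, over a cytoplasmic fill, with a nuclear disk
    in the DAPI channel. Cluster artifacts (if enabled) and noise are applied
    last. Deterministic in the spec, seed included.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    signal = np.zeros((H, W))
    truth = np.zeros((H, W), dtype=np.uint8)
    dapi_sig = np.zeros((H, W))

    cells = _place_cells(spec, rng)
    records = []
    for cy, cx, r in cells:
        if spec.region_map is not None:
            level = HER2Level(int(spec.region_map[int(round(cy)), int(round(cx))]))
        else:
            level = spec.level
        preset = spec.presets[level]
        theta0 = rng.uniform(0, 2 * np.pi)
        realized = _render_cell(
            signal, truth, dapi_sig, cy, cx, r, preset, level, theta0, spec
        )
        records.append(
            {
                "center_x": cx,
                "center_y": cy,
                "radius_um": r * spec.pixel_size,
                "level": int(level),
                "realized_completeness": realized,
            }
        )

    if spec.clusters and spec.cluster_density_per_mm2 > 0:
        _add_clusters(signal, spec, rng)

    ucnp_img = _apply_noise(signal + spec.background, spec, rng)
    dapi_img = _apply_noise(dapi_sig + spec.dapi_background, spec, rng)

    return PhantomOutput(
        ucnp=CalibratedImage(ucnp_img, spec.pixel_size, Channel.UCNP, dark_subtracted=True),
        dapi=CalibratedImage(dapi_img, spec.pixel_size, Channel.DAPI, dark_subtracted=True),
        truth=truth,
        cells=pd.DataFrame.from_records(
            records,
            columns=[
                "center_x",
                "center_y",
                "radius_um",
                "level",
                "realized_completeness",
            ],
        ),
        label_density=signal,
        spec=spec,
    )


def derived_seed(seed: int, level: HER2Level, replicate: int) -> int:
    """Deterministic, collision-avoiding sub-seed below 2^31."""
    return (seed * 100003 + int(level) * 1009 + replicate * 17) % (2**31)


def generate_cpa_series(
    base: PhantomSpec,
    levels: Sequence[HER2Level] = ALL_LEVELS,
    n_per_level: int = 1,
    seed: int = 0,
) -> dict[HER2Level, list[PhantomOutput]]:
    """One single-level phantom per (level, replicate) — a synthetic CPA.

    Sub-seeds derive deterministically from (seed, level, replicate), so
    replicates have distinct noise realizations while the whole series is
    reproducible from one seed.
    """
    if n_per_level < 1:
        raise UCNPScoreError("n_per_level must be >= 1")
    out: dict[HER2Level, list[PhantomOutput]] = {}
    for lvl in levels:
        out[lvl] = [
            generate_phantom(
                dataclasses.replace(
                    base, level=lvl, region_map=None, seed=derived_seed(seed, lvl, rep)
                )
            )
            for rep in range(n_per_level)
        ]
    return out


def generate_dab_counterpart(
    output: PhantomOutput, optical_depth_scale: float, incident_intensity: float = 200.0
) -> CalibratedImage:
    """Brightfield absorption-mode counterpart of a phantom.

    Beer–Lambert darkening of a uniform incident intensity by the (max-
    normalized) label density: I = I₀ · exp(−scale · density). High label
    density drives the transmitted intensity toward zero — the saturation
    that limits the dynamic range of absorption-based chromogens.
    """
    if optical_depth_scale <= 0:
        raise PhantomError("optical_depth_scale must be > 0")
    density = output.label_density
    peak = density.max()
    norm = density / peak if peak > 0 else np.zeros_like(density)
    bright = incident_intensity * np.exp(-optical_depth_scale * norm)
    return CalibratedImage(
        bright, output.spec.pixel_size, Channel.DAB, dark_subtracted=True
    )


def disk_region_map(
    shape: tuple[int, int],
    area_fraction: float,
    inside_level: HER2Level = HER2Level.THREE_PLUS,
    outside_level: HER2Level = HER2Level.ZERO,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Level map with a central disk covering ``area_fraction`` of the image.

    Convenience layout for tissue phantoms: a contiguous high-expression
    region among negative cells.
    """
    if not (0 < area_fraction < 1):
        raise PhantomError("area_fraction must be in (0, 1)")
    H, W = shape
    cy, cx = center if center is not None else ((H - 1) / 2, (W - 1) / 2)
    radius = np.sqrt(area_fraction * H * W / np.pi)
    yy = np.arange(H)[:, None] - cy
    xx = np.arange(W)[None, :] - cx
    rm = np.full(shape, int(outside_level), dtype=np.uint8)
    rm[np.hypot(yy, xx) <= radius] = int(inside_level)
    return rm


def save_phantom(output: PhantomOutput, directory: str | Path, prefix: str = "phantom") -> None:
    """Write a phantom as 16-bit TIFF pair + truth TIFF + per-cell CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(output.ucnp, directory / f"{prefix}_ucnp.tif", dtype=np.uint16)
    write_image(output.dapi, directory / f"{prefix}_dapi.tif", dtype=np.uint16)
    write_image(
        CalibratedImage(
            output.truth.astype(float), output.spec.pixel_size, Channel.BRIGHTFIELD, True
        ),
        directory / f"{prefix}_truth.tif",
        dtype=np.uint8,
    )
    output.cells.to_csv(directory / f"{prefix}_cells.csv", index=False)
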