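"""HER2 level calibration, classification, and rendering.

Area scores measured on control pellet arrays (CPAs) — reference slides with
graded, known HER2 expression — anchor the scale: per-level score statistics
yield three ordered thresholds (0|1+, 1+|2+, 2+|3+) placed at the midpoints
of adjacent level means. A pixel-score image of an unknown sample is then
mapped through the thresholds into a per-pixel HER2 level map ("heat map"),
and per-level area fractions support the clinical "over 10% of cell area at
3+" style of statement.

The 1+/0 pair is allowed to be statistically indistinguishable (weak
expression plus non-specifically bound label clusters make their area scores
similar); that case is flagged degenerate rather than fatal, since the tool's
main job — separating 2+ and 3+ — survives it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import imageio.v3 as iio

from .errors import CalibrationError, ShapeMismatchError, UCNPScoreError
from .fourier import AreaScore, PixelScoreImage, ScoringConfig
from .io import CalibratedImage

__all__ = [
    "HER2Level",
    "CalibrationModel",
    "HER2LevelMap",
    "calibrate_thresholds",
    "classify_value",
    "classify_scores",
    "level_fractions",
    "render_heatmap",
    "render_overlay",
    "save_model",
    "load_model",
    "DEFAULT_LEVEL_COLORS",
]


class HER2Level(enum.IntEnum):
    """Ordinal HER2 immunohistochemistry score (ASCO/CAP four-tier system)."""

    ZERO = 0
    ONE_PLUS = 1
    TWO_PLUS = 2
    THREE_PLUS = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "HER2Level":
        try:
            return _FROM_LABEL[label]
        except KeyError:
            raise UCNPScoreError(f"unknown HER2 label {label!r}") from None


_LABELS = {
    HER2Level.ZERO: "0",
    HER2Level.ONE_PLUS: "1+",
    HER2Level.TWO_PLUS: "2+",
    HER2Level.THREE_PLUS: "3+",
}
_FROM_LABEL = {v: k for k, v in _LABELS.items()}

ALL_LEVELS = tuple(HER2Level)


@dataclass(frozen=True)
class CalibrationModel:
    """Per-level area-score statistics plus the ordered level thresholds."""

    means: dict[HER2Level, float]
    stds: dict[HER2Level, float]
    thresholds: tuple[float, float, float]  # 0|1+, 1+|2+, 2+|3+
    degenerate: bool = False
    config: ScoringConfig | None = None

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (t1 <= t2 <= t3) or not (t2 < t3):
            raise CalibrationError(f"thresholds must be ordered, got {self.thresholds}")


@dataclass(frozen=True)
class HER2LevelMap:
    """Grid of HER2 level codes aligned to its source pixel-score image."""

    levels: np.ndarray  # uint8 codes 0..3
    origin_offset: tuple[int, int]
    stride: int
    model: CalibrationModel

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2 or lv.size == 0:
            raise UCNPScoreError("level map must be a non-empty 2-D grid")
        if lv.min() < 0 or lv.max() > 3:
            raise UCNPScoreError("level codes must be in {0,1,2,3}")
        object.__setattr__(self, "levels", lv.astype(np.uint8))


def _pool(scores: AreaScore | Sequence[AreaScore]) -> tuple[float, float]:
    """Pool one or more per-image area scores into a (mean, std) pair.

    Several replicate images: mean of means, spread of means across
    replicates. A single image: its own (mean, std).
    """
    if isinstance(scores, AreaScore):
        return scores.mean, scores.std
    seq = list(scores)
    if not seq:
        raise CalibrationError("empty area-score sequence for a level")
    if len(seq) == 1:
        return seq[0].mean, seq[0].std
    means = np.array([s.mean for s in seq])
    return float(means.mean()), float(means.std())


def calibrate_thresholds(
    level_scores: Mapping[HER2Level, AreaScore | Sequence[AreaScore]],
    config: ScoringConfig | None = None,
) -> CalibrationModel:
    """Fit level thresholds from per-level CPA area scores.

    Thresholds are midpoints of adjacent level means after verifying the
    means are non-decreasing with level. An inversion beyond the combined
    spread of the two levels is an error; an inversion (or equality) within
    it collapses the threshold onto the common value and flags the model
    degenerate — the empirically expected situation for the 1+/0 pair.
    """
    missing = [lvl for lvl in ALL_LEVELS if lvl not in level_scores]
    if missing:
        raise CalibrationError(f"missing levels: {[l.label for l in missing]}")
    means: dict[HER2Level, float] = {}
    stds: dict[HER2Level, float] = {}
    for lvl in ALL_LEVELS:
        means[lvl], stds[lvl] = _pool(level_scores[lvl])

    thresholds: list[float] = []
    degenerate = False
    for lo, hi in zip(ALL_LEVELS[:-1], ALL_LEVELS[1:]):
        m_lo, m_hi = means[lo], means[hi]
        if m_hi >= m_lo:
            mid = 0.5 * (m_lo + m_hi)
            if m_hi == m_lo:
                degenerate = True
        else:
            tol = stds[lo] + stds[hi]
            if m_lo - m_hi > tol:
                raise CalibrationError(
                    f"area-score means inverted between {lo.label} and "
                    f"{hi.label}: {m_lo:.4g} > {m_hi:.4g} beyond tolerance {tol:.4g}"
                )
            mid = 0.5 * (m_lo + m_hi)
            degenerate = True
        thresholds.append(mid)
    return CalibrationModel(
        means=means,
        stds=stds,
        thresholds=tuple(thresholds),  # type: ignore[arg-type]
        degenerate=degenerate,
        config=config,
    )


def classify_value(score: float, model: CalibrationModel) -> HER2Level:
    """Map a single (area or pixel) score to a HER2 level.

    Boundary scores go to the higher level: s < t1 → 0, t1 ≤ s < t2 → 1+,
    t2 ≤ s < t3 → 2+, s ≥ t3 → 3+.
    """
    if not np.isfinite(score):
        raise UCNPScoreError(f"cannot classify non-finite score {score}")
    return HER2Level(int(np.digitize(score, model.thresholds, right=False)))


def classify_scores(psi: PixelScoreImage, model: CalibrationModel) -> HER2LevelMap:
    """Classify every pixel score into a HER2 level map."""
    s = psi.scores
    if not np.all(np.isfinite(s)):
        raise UCNPScoreError("pixel-score image contains non-finite scores")
    codes = np.digitize(s, model.thresholds, right=False).astype(np.uint8)
    return HER2LevelMap(
        levels=codes, origin_offset=psi.origin_offset, stride=psi.stride, model=model
    )


def level_fractions(level_map: HER2LevelMap) -> dict[HER2Level, float]:
    """Fraction of scored area at each level; fractions sum to 1."""
    lv = level_map.levels
    n = lv.size
    counts = np.bincount(lv.ravel(), minlength=4)
    return {lvl: float(counts[lvl] / n) for lvl in ALL_LEVELS}


DEFAULT_LEVEL_COLORS: dict[HER2Level, tuple[int, int, int]] = {
    HER2Level.ZERO: (45, 45, 60),
    HER2Level.ONE_PLUS: (70, 130, 180),
    HER2Level.TWO_PLUS: (255, 165, 0),
    HER2Level.THREE_PLUS: (220, 20, 60),
}


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.ones_like(img, dtype=float) if hi > 0 else np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


def render_heatmap(
    level_map: HER2LevelMap,
    background: CalibratedImage | None = None,
    colors: Mapping[HER2Level, tuple[int, int, int]] = DEFAULT_LEVEL_COLORS,
    alpha: float = 0.6,
) -> np.ndarray:
    """Render the level map as a categorical RGB image (uint8).

    Without a background, one pixel per scored cell. With a background image,
    the level map is nearest-neighbour resampled onto the background grid
    (honouring origin offset and stride) and alpha-blended over the min-max
    scaled background.
    """
    lut = np.zeros((4, 3), dtype=float)
    for lvl in ALL_LEVELS:
        lut[lvl] = colors[lvl]
    rgb = lut[level_map.levels]
    if background is None:
        return rgb.astype(np.uint8)

    H, W = background.shape
    oy, ox = level_map.origin_offset
    nr, nc = level_map.levels.shape
    extent_y = oy + (nr - 1) * level_map.stride
    extent_x = ox + (nc - 1) * level_map.stride
    if extent_y >= H or extent_x >= W:
        raise ShapeMismatchError(
            f"level map extent ({extent_y}, {extent_x}) exceeds background {background.shape}"
        )
    yy = np.clip(np.round((np.arange(H) - oy) / level_map.stride), 0, nr - 1).astype(int)
    xx = np.clip(np.round((np.arange(W) - ox) / level_map.stride), 0, nc - 1).astype(int)
    overlay = lut[level_map.levels[yy[:, None], xx[None, :]]]
    base = _minmax(background.pixels)[..., None] * 255.0
    blended = (1.0 - alpha) * base + alpha * overlay
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def render_overlay(ucnp: CalibratedImage, dapi: CalibratedImage) -> np.ndarray:
    """Two-channel composite: UCNP → green, DAPI → blue, red zero (uint8).

    Each channel is min-max scaled independently; a uniform positive channel
    maps to full intensity.
    """
    if ucnp.shape != dapi.shape:
        raise ShapeMismatchError(f"shape mismatch: {ucnp.shape} vs {dapi.shape}")
    if not np.isclose(ucnp.pixel_size, dapi.pixel_size):
        raise ShapeMismatchError(
            f"pixel-size mismatch: {ucnp.pixel_size} vs {dapi.pixel_size}"
        )
    rgb = np.zeros(ucnp.shape + (3,), dtype=float)
    rgb[..., 1] = _minmax(ucnp.pixels)
    rgb[..., 2] = _minmax(dapi.pixels)
    return np.round(rgb * 255.0).astype(np.uint8)


def save_heatmap_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write an RGB rendering losslessly as PNG."""
    iio.imwrite(Path(path), rgb.astype(np.uint8), extension=".png")


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a calibration model as a key-value text file."""
    lines = []
    for lvl in ALL_LEVELS:
        lines.append(f"mean_{lvl.label} = {model.means[lvl]!r}")
        lines.append(f"std_{lvl.label} = {model.stds[lvl]!r}")
    t1, t2, t3 = model.thresholds
    lines += [
        f"threshold_0_1p = {t1!r}",
        f"threshold_1p_2p = {t2!r}",
        f"threshold_2p_3p = {t3!r}",
        f"degenerate = {model.degenerate}",
    ]
    if model.config is not None:
        c = model.config
        lines += [
            f"window_size = {c.window_size}",
            f"gaussian_sigma = {c.gaussian_sigma!r}",
            f"stride = {c.stride}",
            f"magnitude_mode = {c.magnitude_mode}",
            f"edge_mode = {c.edge_mode}",
            f"band_r_inner = {c.band.r_inner!r}",
            f"band_r_outer = {c.band.r_outer!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> CalibrationModel:
    """Read a calibration model written by :func:`save_model`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    try:
        means = {lvl: float(kv[f"mean_{lvl.label}"]) for lvl in ALL_LEVELS}
        stds = {lvl: float(kv[f"std_{lvl.label}"]) for lvl in ALL_LEVELS}
        thresholds = (
            float(kv["threshold_0_1p"]),
            float(kv["threshold_1p_2p"]),
            float(kv["threshold_2p_3p"]),
        )
        degenerate = kv.get("degenerate", "False") == "True"
    except KeyError as exc:
        raise CalibrationError(f"model file {path} is missing {exc}") from exc
    config = None
    if "window_size" in kv:
        from .fourier import BandpassSpec

        config = ScoringConfig(
            window_size=int(kv["window_size"]),
            gaussian_sigma=float(kv["gaussian_sigma"]),
            stride=int(kv["stride"]),
            magnitude_mode=kv["magnitude_mode"],  # type: ignore[arg-type]
            edge_mode=kv["edge_mode"],  # type: ignore[arg-type]
            band=BandpassSpec(float(kv["band_r_inner"]), float(kv["band_r_outer"])),
        )
    return CalibrationModel(
        means=means, stds=stds, thresholds=thresholds, degenerate=degenerate, config=config
    )
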