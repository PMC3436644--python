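"""Automatic-threshold quantification of immunostained area.

The stained fraction of a bright-field microphotograph is measured by
(1) picking a grey-level threshold with the iterative-intermeans
(isodata) algorithm and (2) counting the fraction of pixels on the
stained side of it. With a dark chromogen on a bright background
(e.g. DAB with nickel intensification) the stained side is the dark
one; a flag flips the polarity.

The isodata recurrence is pinned for bit-exact reproducibility: start
at the mid-level of the occupied intensity range, then iterate
``t ← round((mean of pixels ≤ t + mean of pixels > t) / 2)`` with
round-half-up until the threshold stops changing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: Nominal sampling-frame size for area-fraction measurements (μm).
DEFAULT_FRAME_WIDTH_UM = 640.0
DEFAULT_FRAME_HEIGHT_UM = 380.0


@dataclass(frozen=True)
class FrameImage:
    """8-bit grayscale sampling frame with its spatial scale."""

    pixels: np.ndarray
    um_per_pixel: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")

    @property
    def width_um(self) -> float:
        return self.pixels.shape[1] * self.um_per_pixel

    @property
    def height_um(self) -> float:
        return self.pixels.shape[0] * self.um_per_pixel

    @classmethod
    def open(cls, path: str | Path, um_per_pixel: float) -> "FrameImage":
        img = Image.open(path).convert("L")
        return cls(np.asarray(img, dtype=np.uint8), um_per_pixel)

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def auto_threshold(image: FrameImage | np.ndarray) -> int:
    """Isodata (iterative intermeans) threshold of an 8-bit image.

    Fixed point of ``t = round((mean(px ≤ t) + mean(px > t)) / 2)``,
    iterated from the mid-level of the occupied range with
    round-half-up. Deterministic; raises on a constant image, which has
    no meaningful threshold.
    """
    px = image.pixels if isinstance(image, FrameImage) else np.asarray(image)
    hist = np.bincount(px.ravel().astype(np.uint8), minlength=256).astype(float)
    occupied = np.flatnonzero(hist)
    if len(occupied) < 2:
        raise ValueError("constant image: threshold undefined")
    lo, hi = int(occupied[0]), int(occupied[-1])
    levels = np.arange(256, dtype=float)
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * levels)

    t = _round_half_up((lo + hi) / 2)
    seen = set()
    while t not in seen:
        seen.add(t)
        n_below = csum[t]
        n_above = csum[255] - n_below
        if n_below == 0 or n_above == 0:
            # start level outside the bimodal mass; nudge inward
            t = hi - 1 if n_above == 0 else lo + 1
            continue
        mean_below = cmoment[t] / n_below
        mean_above = (cmoment[255] - cmoment[t]) / n_above
        t = _round_half_up((mean_below + mean_above) / 2)
    return int(t)


def stained_fraction(
    image: FrameImage | np.ndarray, threshold: int, stain_is_dark: bool = True
) -> float:
    """Percentage of pixels on the stained side of the threshold.

    Stained pixels are those ≤ threshold when ``stain_is_dark`` (dark
    chromogen on bright field) and those ≥ threshold otherwise.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    px = image.pixels if isinstance(image, FrameImage) else np.asarray(image)
    if stain_is_dark:
        stained = px <= threshold
    else:
        stained = px >= threshold
    return 100.0 * float(np.count_nonzero(stained)) / px.size


def measure_frame(
    image: FrameImage, stain_is_dark: bool = True
) -> tuple[int, float]:
    """Auto-threshold one frame and return ``(threshold, pct_stained)``."""
    t = auto_threshold(image)
    return t, stained_fraction(image, t, stain_is_dark)


def frame_summary(
    fractions_by_case: Mapping[tuple[str, str], Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-frame stained fractions into case and group values.

    ``fractions_by_case`` maps (group, case) to that case's per-frame
    percentages (all frames of all its sections). The case value is the
    mean over frames; the group value is mean ± sample SD over its
    cases.
    """
    rows = []
    for (group, case), fracs in fractions_by_case.items():
        fracs = np.asarray(list(fracs), dtype=float)
        if fracs.size == 0:
            raise ValueError(f"case {case!r} has no frames")
        rows.append(
            {
                "group": group,
                "case": case,
                "n_frames": fracs.size,
                "pct_stained": float(fracs.mean()),
            }
        )
    case_df = pd.DataFrame(rows)
    group_df = (
        case_df.groupby("group")
        .agg(
            n_cases=("case", "size"),
            mean_pct=("pct_stained", "mean"),
            sd_pct=("pct_stained", lambda v: v.std(ddof=1)),
        )
        .reset_index()
    )
    return case_df, group_df
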