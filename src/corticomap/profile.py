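"""Rectangular-ROI column profiling of normalized ion images.

A rectangular region of interest is drawn from the renal pelvis out to the
outer cortical edge and collapsed to a 1-D profile by averaging the defined
ratio pixels in each column.  The profile axis therefore runs pelvis →
outer cortex, which is the coordinate along which histological zones are
annotated and sections are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msi_io import IonImage

__all__ = ["RectROI", "ColumnProfile", "column_profile", "profile_histogram"]


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle; ``orientation`` picks the profile axis.

    orientation 0: the profile runs along x (one value per image column);
    orientation 90: the profile runs along y (one value per image row).
    ``(x0, y0)`` is the inclusive top-left corner.
    """

    x0: int
    y0: int
    width_px: int
    height_px: int
    orientation: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("ROI must be at least 1x1 pixels")
        if self.orientation not in (0, 90):
            raise ValueError("orientation must be 0 or 90 degrees")

    def n_columns(self) -> int:
        return self.width_px if self.orientation == 0 else self.height_px

    def area_mm2(self, pixel_size_um: float) -> float:
        return self.width_px * self.height_px * (pixel_size_um / 1000.0) ** 2


@dataclass
class ColumnProfile:
    """Ordered per-column mean ratios with defined-pixel counts.

    ``values[j]`` is the arithmetic mean of the defined pixels in column j
    (NaN when the column has no defined pixel); ``counts[j]`` is that
    defined-pixel count.
    """

    values: np.ndarray
    counts: np.ndarray
    section_id: str = ""
    roi: RectROI | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != self.counts.shape or self.values.ndim != 1:
            raise ValueError("values and counts must be 1-D arrays of equal length")
        if np.any(np.isnan(self.values) != (self.counts == 0)):
            raise ValueError("values must be NaN exactly where counts are zero")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tvalue\tcount\n")
            for j, (v, c) in enumerate(zip(self.values, self.counts)):
                fh.write(f"{j}\t{'nan' if np.isnan(v) else repr(float(v))}\t{c}\n")


def column_profile(image: IonImage, roi: RectROI, min_count: int = 0) -> ColumnProfile:
    """Average the defined pixels of each ROI column into a 1-D profile.

    Columns run along the ROI's orientation axis; a column whose
    defined-pixel count is zero (or below ``min_count``) is UNDEFINED (NaN).
    The ROI must lie fully inside the image.
    """
    h, w = image.values.shape
    if not (0 <= roi.x0 and 0 <= roi.y0
            and roi.x0 + roi.width_px <= w and roi.y0 + roi.height_px <= h):
        raise ValueError(
            f"ROI {roi} exceeds image bounds {w}x{h}"
        )
    block = image.values[roi.y0 : roi.y0 + roi.height_px, roi.x0 : roi.x0 + roi.width_px]
    if roi.orientation == 90:
        block = block.T  # profile runs along y; rows become columns
    n_cols = block.shape[1]
    values = np.full(n_cols, np.nan)
    counts = np.zeros(n_cols, dtype=int)
    # sequential accumulation top-to-bottom: deterministic and independent of
    # any vectorised summation order
    for j in range(n_cols):
        acc, c = 0.0, 0
        for v in block[:, j]:
            if not np.isnan(v):
                acc += v
                c += 1
        if c > 0 and c >= min_count:
            values[j] = acc / c
            counts[j] = c
    return ColumnProfile(values=values, counts=counts, roi=roi)


def profile_histogram(profile: ColumnProfile, out_path: str | Path) -> None:
    """Render the column profile as a bar plot (UNDEFINED columns are gaps)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(profile) == 0:
        raise ValueError("profile is empty")
    fig, ax = plt.subplots(figsize=(7, 3.2))
    x = np.arange(len(profile))
    defined = ~np.isnan(profile.values)
    if not defined.any():
        import warnings

        warnings.warn("profile has no defined columns; rendering empty axes", stacklevel=2)
    else:
        ax.bar(x[defined], profile.values[defined], width=0.9, color="#3a6ea5")
    ax.set_xlabel("column (pelvis → outer cortex)")
    ax.set_ylabel("mean ratio (analyte / IS)")
    title = profile.section_id or "column profile"
    if profile.roi is not None:
        title += f"  ROI ({profile.roi.x0},{profile.roi.y0}) {profile.roi.width_px}x{profile.roi.height_px}"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
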