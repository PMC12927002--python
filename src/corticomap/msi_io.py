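"""imzML input/output and pixel-indexed access to centroided MSI spectra.

Datasets live on an integer raster grid: ``(x, y)`` with ``x`` the column
(left to right) and ``y`` the row (top to bottom), both 0-based.  imzML scan
positions are 1-based and are converted on read and write.  Off-tissue pixels
are simply absent from the spectrum map.

Reading and writing delegate to :mod:`pyimzml`; processed-mode files are
written with float64 m/z *and* intensity arrays so that a write/read
round-trip is bit-exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "MSIDataset",
    "IonImage",
    "read_imzml",
    "write_imzml",
    "window_intensity",
    "centroid_spectrum",
]

DEFAULT_PIXEL_SIZE_UM = 75.0


@dataclass
class MSIDataset:
    """Centroided spectra indexed by integer pixel coordinates."""

    width: int
    height: int
    spectra: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (x, y), (mz, inten) in self.spectra.items():
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"pixel ({x},{y}) outside {self.width}x{self.height} grid")
            if len(mz) != len(inten):
                raise ValueError(f"pixel ({x},{y}): m/z and intensity lengths differ")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError(f"pixel ({x},{y}): m/z array not strictly increasing")

    def pixels(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.spectra))

    def has_pixel(self, x: int, y: int) -> bool:
        return (x, y) in self.spectra

    def spectrum(self, x: int, y: int) -> tuple[np.ndarray, np.ndarray]:
        return self.spectra[(x, y)]

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)


@dataclass
class IonImage:
    """Per-pixel intensity lattice for one target ion.

    ``values`` is a (height, width) float array; NaN marks UNDEFINED pixels
    (absent from the dataset or excluded by the extraction rule).
    """

    values: np.ndarray
    target_label: str = ""
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("IonImage values must be 2-D (height, width)")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.10g")

    def to_png(self, path: str | Path, cmap: str = "viridis") -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(self.values, cmap=cmap, origin="upper", interpolation="nearest")
        ax.set_title(self.target_label)
        fig.colorbar(im, ax=ax, label="intensity")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def window_intensity(
    spectrum: tuple[np.ndarray, np.ndarray], center: float, tol_ppm: float
) -> float:
    """Summed intensity of centroid peaks within ±tol_ppm of ``center``.

    The window is symmetric on the ppm scale: a peak at m is inside when
    |m - center| / center * 1e6 <= tol_ppm.  Returns 0.0 when no peak falls
    in the window.  Summing (rather than taking the maximum) makes the
    extraction robust to split centroids.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz, inten = spectrum
    if len(mz) == 0:
        return 0.0
    half = center * tol_ppm * 1e-6
    lo = np.searchsorted(mz, center - half, side="left")
    hi = np.searchsorted(mz, center + half, side="right")
    if hi <= lo:
        return 0.0
    return float(np.sum(inten[lo:hi]))


def centroid_spectrum(
    mz: np.ndarray, inten: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picker for profile-mode spectra (off by default).

    Keeps points that are strictly greater than both neighbours (plateaus keep
    their first point).  Adequate for converting smooth profile data to
    centroids before targeted extraction; not a fitted centroider.
    """
    mz = np.asarray(mz, float)
    inten = np.asarray(inten, float)
    if len(mz) < 3:
        return mz.copy(), inten.copy()
    left = inten[1:-1] > inten[:-2]
    right = inten[1:-1] >= inten[2:]
    keep = np.zeros(len(mz), dtype=bool)
    keep[1:-1] = left & right & (inten[1:-1] > 0)
    return mz[keep], inten[keep]


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a processed-mode imzML/ibd pair (1-based scan positions)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    with ImzMLWriter(
        path,
        mode="processed",
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
        polarity=dataset.metadata.get("polarity", "positive"),
    ) as writer:
        for (x, y) in sorted(dataset.spectra):
            mz, inten = dataset.spectra[(x, y)]
            if len(mz) == 0:
                # imzML cannot represent an empty peak list; the pixel becomes
                # indistinguishable from an absent one
                warnings.warn(
                    f"pixel ({x},{y}) has an empty spectrum; omitted from imzML",
                    stacklevel=2,
                )
                continue
            writer.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (x + 1, y + 1, 1))


def read_imzml(
    path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    centroid_profile: bool = False,
) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Scan positions are converted to the 0-based top-left convention.  Profile
    spectra are accepted but flagged with a warning; pass
    ``centroid_profile=True`` to run the local-maximum picker on read.
    Non-monotone m/z arrays are rejected with the offending pixel.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing ibd file for {path}: {ibd}")

    parser = ImzMLParser(str(path))
    try:
        names = set(parser.metadata.file_description.param_by_name)
    except Exception:
        names = set()
    spec_mode = "profile" if any("profile" in n.lower() for n in names) else "centroid"
    if spec_mode == "profile" and not centroid_profile:
        warnings.warn(
            "imzML file contains profile spectra; extraction expects centroids "
            "(pass centroid_profile=True to pick peaks on read)",
            stacklevel=2,
        )

    spectra: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    max_x = max_y = 0
    for idx, (cx, cy, _cz) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(idx)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError(
                f"non-monotone m/z array in scan {idx} at imzML position ({cx},{cy})"
            )
        if spec_mode == "profile" and centroid_profile:
            mz, inten = centroid_spectrum(mz, inten)
        x, y = int(cx) - 1, int(cy) - 1
        spectra[(x, y)] = (mz, inten)
        max_x = max(max_x, x)
        max_y = max(max_y, y)

    # grid extent: the file's scan-settings pixel counts when present, else
    # the bounding box of recorded scans (an empty off-tissue margin in the
    # source grid is not representable in imzML)
    width = int(parser.imzmldict.get("max count of pixels x", max_x + 1))
    height = int(parser.imzmldict.get("max count of pixels y", max_y + 1))
    return MSIDataset(
        width=max(width, max_x + 1),
        height=max(height, max_y + 1),
        spectra=spectra,
        pixel_size=pixel_size,
        metadata={"source": str(path), "spectrum_mode": spec_mode},
    )
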