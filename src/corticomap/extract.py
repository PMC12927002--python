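"""Targeted ion-image extraction and per-pixel internal-standard normalization.

MALDI signal varies across a tissue section because of matrix inhomogeneity
and regional ion suppression.  Because the deuterated internal standard (IS)
is sprayed uniformly with the derivatization reagent, dividing each analyte
pixel by the IS intensity *in the same pixel* cancels these common-mode
multiplicative effects; the resulting ratio image is the semi-quantitative
map the downstream zonal profiling consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import IonSpecies
from .msi_io import IonImage, MSIDataset, window_intensity

__all__ = ["RatioImage", "ion_image", "normalize", "DEFAULT_TOL_PPM"]

# MS1 extraction window; FT-ICR mass accuracy is ~1 ppm so ±5 ppm comfortably
# contains the jittered peak without admitting neighbours.
DEFAULT_TOL_PPM = 5.0


@dataclass
class RatioImage(IonImage):
    """Per-pixel analyte/IS ratio lattice; NaN marks UNDEFINED pixels."""

    analyte_label: str = ""
    is_label: str = ""


def ion_image(
    dataset: MSIDataset,
    target: IonSpecies | float,
    tol_ppm: float = DEFAULT_TOL_PPM,
    label: str = "",
) -> IonImage:
    """Extract the summed-window intensity of ``target`` at every pixel.

    ``target`` is an :class:`~corticomap.chem.IonSpecies` (its theoretical
    m/z is used) or a bare m/z value.  Absent (off-tissue) pixels are NaN.
    """
    if dataset.n_pixels == 0:
        raise ValueError("dataset has no pixels")
    if isinstance(target, IonSpecies):
        center = target.mz
        label = label or target.label
    else:
        center = float(target)
        label = label or f"m/z {center:.4f}"
    values = np.full((dataset.height, dataset.width), np.nan)
    for (x, y), spectrum in dataset.spectra.items():
        values[y, x] = window_intensity(spectrum, center, tol_ppm)
    return IonImage(values=values, target_label=label, pixel_size=dataset.pixel_size)


def normalize(
    analyte: IonImage, internal_standard: IonImage, is_floor: float = 0.0
) -> RatioImage:
    """Per-pixel analyte/IS ratio image.

    The ratio is defined only where both images are defined and the IS
    intensity is strictly above ``is_floor`` (default 0: any positive IS is
    accepted; raise the floor to suppress unstable low-IS ratios).
    """
    if analyte.values.shape != internal_standard.values.shape:
        raise ValueError(
            f"shape mismatch: analyte {analyte.values.shape} vs "
            f"IS {internal_standard.values.shape}"
        )
    a = analyte.values
    s = internal_standard.values
    with np.errstate(invalid="ignore"):
        ok = ~np.isnan(a) & ~np.isnan(s) & (s > is_floor)
    values = np.full_like(a, np.nan)
    values[ok] = a[ok] / s[ok]
    return RatioImage(
        values=values,
        target_label=f"{analyte.target_label}/{internal_standard.target_label}",
        pixel_size=analyte.pixel_size,
        analyte_label=analyte.target_label,
        is_label=internal_standard.target_label,
    )
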