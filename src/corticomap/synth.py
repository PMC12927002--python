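"""Ground-truthed synthetic kidney-section MSI datasets and plasma panels.

No public MSI data accompany this workflow, so every downstream module is
exercised on simulated inputs whose generating parameters are recorded as
explicit truth objects.  A synthetic section is a cartoon kidney: concentric
elliptical bands (pelvis, inner medulla IM, outer medulla OM, inner cortex
IC, outer cortex OC) on a 75 μm raster, with

* a uniformly sprayed internal-standard (IS) ion whose intensity carries a
  smooth low-order-polynomial spatial drift (matrix inhomogeneity / regional
  ion suppression),
* the three GirT-derivative analyte ions at their theoretical m/z, generated
  proportional to the *realized* IS intensity in the same pixel (suppression
  and drift are common-mode between analyte and IS — the physical premise of
  per-pixel IS normalization) times a zone-specific true ratio and
  independent multiplicative log-normal noise with mean 1,
* planted zone-marker ions and optional decoys for the supervised marker
  search, and
* a small uniform m/z jitter on every peak.

Plasma panels mirror the salt-diet study design: three groups (low 0.03%,
control 0.3%, high 3% w/w sodium), n = 6 animals per group, with an 11-point
weighted calibration design per analyte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Zone, ZoneAnnotation
from .chem import default_targets
from .markers import ZoneMask
from .msi_io import MSIDataset
from .profile import RectROI

__all__ = [
    "ANALYTES",
    "SectionConfig",
    "SectionTruth",
    "CohortSection",
    "PlasmaConfig",
    "PlasmaTruth",
    "generate_section",
    "generate_cohort",
    "generate_plasma",
    "section_roi_and_zones",
]

ANALYTES = ("corticosterone", "11-dehydrocorticosterone", "aldosterone")

_TARGETS = default_targets()
ANALYTE_MZ = {name: _TARGETS[name].mz for name in ANALYTES}
IS_MZ = _TARGETS["d8-corticosterone"].mz

# Qualitative zonal localisation emulated by the default truth (analyte/IS
# ratio per zone): corticosterone along papilla, medulla and inner cortex;
# 11-dehydrocorticosterone concentrated in the outer medulla; aldosterone in
# outer medulla and outer cortex.
DEFAULT_ZONE_RATIOS: dict[str, dict[str, float]] = {
    "corticosterone": {"pelvis": 0.30, "IM": 1.20, "OM": 0.90, "IC": 1.00, "OC": 0.50},
    "11-dehydrocorticosterone": {"pelvis": 0.10, "IM": 0.40, "OM": 1.00, "IC": 0.30, "OC": 0.20},
    "aldosterone": {"pelvis": 0.10, "IM": 0.30, "OM": 0.80, "IC": 0.30, "OC": 0.90},
}

# One planted marker ion per scored zone (m/z, in/out intensity ratio source
# is SectionConfig.marker_in_out_ratio).  476.308 echoes a typical
# architecture-tracing ion; the rest are arbitrary distinct channels.
DEFAULT_MARKER_IONS: dict[str, float] = {
    "IM": 476.308,
    "OM": 520.340,
    "IC": 610.400,
    "OC": 700.450,
}


@dataclass(frozen=True)
class SectionConfig:
    """Generating parameters for one synthetic kidney section."""

    width: int = 112
    height: int = 72
    pixel_size: float = 75.0  # μm
    center: tuple[float, float] = (54.0, 36.0)  # (x, y) of the pelvis centre
    # ordered outer semi-major axes (px) of the nested elliptical bands
    zone_bands: tuple[tuple[str, float], ...] = (
        ("pelvis", 8.0),
        ("IM", 20.0),
        ("OM", 30.0),
        ("IC", 40.0),
        ("OC", 50.0),
    )
    axis_ratio: float = 0.62  # semi-minor / semi-major
    zone_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(z) for a, z in DEFAULT_ZONE_RATIOS.items()}
    )
    is_base_intensity: float = 1000.0
    drift_amplitude: float = 0.30  # ±30 % smooth IS drift
    noise_cv: float = 0.20  # multiplicative log-normal CV per pixel per ion
    mz_jitter_ppm: float = 1.0  # FT-ICR-like mass accuracy
    marker_ions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_IONS))
    marker_in_out_ratio: float = 8.0
    marker_base_intensity: float = 500.0
    decoy_ions: tuple[tuple[float, str, float], ...] = ()  # (m/z, zone, in/out ratio)
    seed: int = 0

    def __post_init__(self) -> None:
        axes = [a for _, a in self.zone_bands]
        if any(b <= a for a, b in zip(axes, axes[1:])):
            raise ValueError("zone bands must be strictly nested (increasing axes)")
        if self.mz_jitter_ppm > 5:
            raise ValueError("m/z jitter above 5 ppm would defeat targeted extraction")
        for analyte, zones in self.zone_ratios.items():
            for zone, v in zones.items():
                if v <= 0:
                    raise ValueError(f"zone ratio for {analyte}/{zone} must be > 0")

    def scaled(self, scale: float) -> "SectionConfig":
        """Same section with all band axes scaled (smaller/larger kidney)."""
        from dataclasses import replace

        return replace(
            self,
            zone_bands=tuple((lbl, a * scale) for lbl, a in self.zone_bands),
        )


@dataclass
class SectionTruth:
    """Serializable generating truth for one synthetic section."""

    zone_ratios: dict[str, dict[str, float]]
    marker_ions: dict[str, float]
    marker_in_out_ratio: float
    zone_mask: ZoneMask
    seed: int
    zone_pixel_counts: dict[str, int] = field(default_factory=dict)
    group: str = "control"
    applied_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "zone_ratios": self.zone_ratios,
            "marker_ions": self.marker_ions,
            "marker_in_out_ratio": self.marker_in_out_ratio,
            "seed": self.seed,
            "zone_pixel_counts": self.zone_pixel_counts,
            "group": self.group,
            "applied_multipliers": self.applied_multipliers,
            "zone_mask": ["\t".join(row) for row in self.zone_mask.labels.astype(str)],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SectionTruth":
        payload = json.loads(Path(path).read_text())
        mask = ZoneMask(
            np.asarray([row.split("\t") for row in payload.pop("zone_mask")], dtype=object)
        )
        return cls(zone_mask=mask, **payload)


def _zone_index_grid(cfg: SectionConfig) -> np.ndarray:
    """Band index per pixel (-1 = off tissue) from the nested ellipses."""
    cx, cy = cfg.center
    ys, xs = np.mgrid[0 : cfg.height, 0 : cfg.width]
    dx = xs - cx
    dy = ys - cy
    idx = np.full((cfg.height, cfg.width), -1, dtype=int)
    for i in reversed(range(len(cfg.zone_bands))):
        _, a = cfg.zone_bands[i]
        b = a * cfg.axis_ratio
        inside = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        idx[inside] = i
    return idx


def _drift_field(cfg: SectionConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative drift, exactly within 1 ± drift_amplitude."""
    ys, xs = np.mgrid[0 : cfg.height, 0 : cfg.width]
    u = 2.0 * xs / max(cfg.width - 1, 1) - 1.0
    v = 2.0 * ys / max(cfg.height - 1, 1) - 1.0
    c = rng.uniform(-1.0, 1.0, size=4)
    g = c[0] * u + c[1] * v + c[2] * u * v + c[3] * (u * u - 1.0 / 3.0)
    peak = np.max(np.abs(g))
    if peak > 0:
        g = g / peak
    return 1.0 + cfg.drift_amplitude * g


def _lognormal_mean1(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_section(cfg: SectionConfig) -> tuple[MSIDataset, SectionTruth]:
    """Generate one centroided synthetic section and its truth.

    Per tissue pixel the spectrum contains the three analyte derivative
    peaks, the IS peak, and the planted marker/decoy ions, each m/z jittered
    uniformly within ±cfg.mz_jitter_ppm.  Off-tissue pixels are absent.
    """
    rng = np.random.default_rng(cfg.seed)
    zone_idx = _zone_index_grid(cfg)
    drift = _drift_field(cfg, rng)
    labels_by_idx = [lbl for lbl, _ in cfg.zone_bands]

    tissue = zone_idx >= 0
    ys, xs = np.nonzero(tissue)
    zidx = zone_idx[tissue]
    n_pix = len(xs)

    # ion channel layout: analytes + IS + markers + decoys, sorted by m/z
    channels: list[tuple[str, float]] = [(a, ANALYTE_MZ[a]) for a in ANALYTES]
    channels.append(("IS", IS_MZ))
    for zone, mz in cfg.marker_ions.items():
        channels.append((f"marker:{zone}", mz))
    for mz, zone, ratio in cfg.decoy_ions:
        channels.append((f"decoy:{zone}:{mz}", mz))
    channels.sort(key=lambda c: c[1])
    base_mz = np.array([mz for _, mz in channels])
    if np.any(np.diff(base_mz) / base_mz[:-1] * 1e6 <= 4 * cfg.mz_jitter_ppm):
        raise ValueError("ion channels closer than the jitter window")

    intens = np.zeros((n_pix, len(channels)))
    local_drift = drift[tissue]
    is_col = next(i for i, (name, _) in enumerate(channels) if name == "IS")
    is_real = cfg.is_base_intensity * local_drift * _lognormal_mean1(rng, cfg.noise_cv, n_pix)
    intens[:, is_col] = is_real

    for i, (name, _mz) in enumerate(channels):
        if name == "IS":
            continue
        if name in ANALYTES:
            ratios = np.array(
                [cfg.zone_ratios[name][labels_by_idx[z]] for z in range(len(labels_by_idx))]
            )
            truth_ratio = ratios[zidx]
            intens[:, i] = truth_ratio * is_real * _lognormal_mean1(rng, cfg.noise_cv, n_pix)
        else:
            kind, zone, *_ = name.split(":")
            if kind == "decoy":
                in_out = next(r for m, z, r in cfg.decoy_ions if f"decoy:{z}:{m}" == name)
            else:
                in_out = cfg.marker_in_out_ratio
            in_zone = np.array([labels_by_idx[z] == zone for z in zidx])
            level = np.where(in_zone, in_out, 1.0)
            intens[:, i] = (
                cfg.marker_base_intensity
                * level
                * local_drift
                * _lognormal_mean1(rng, cfg.noise_cv, n_pix)
            )

    jitter = rng.uniform(-cfg.mz_jitter_ppm, cfg.mz_jitter_ppm, size=intens.shape)
    mz_obs = base_mz[None, :] * (1.0 + jitter * 1e-6)

    spectra: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for p in range(n_pix):
        spectra[(int(xs[p]), int(ys[p]))] = (mz_obs[p].copy(), intens[p].copy())

    dataset = MSIDataset(
        width=cfg.width,
        height=cfg.height,
        spectra=spectra,
        pixel_size=cfg.pixel_size,
        metadata={"polarity": "positive", "seed": cfg.seed, "synthetic": True},
    )

    mask_labels = np.full((cfg.height, cfg.width), "", dtype=object)
    for i, lbl in enumerate(labels_by_idx):
        mask_labels[zone_idx == i] = lbl
    mask = ZoneMask(mask_labels)
    counts = {lbl: int(np.sum(zone_idx == i)) for i, lbl in enumerate(labels_by_idx)}
    truth = SectionTruth(
        zone_ratios={a: dict(z) for a, z in cfg.zone_ratios.items()},
        marker_ions=dict(cfg.marker_ions),
        marker_in_out_ratio=cfg.marker_in_out_ratio,
        zone_mask=mask,
        seed=cfg.seed,
        zone_pixel_counts=counts,
    )
    return dataset, truth


def section_roi_and_zones(
    cfg: SectionConfig, roi_height: int = 8, section_id: str = ""
) -> tuple[RectROI, ZoneAnnotation]:
    """Pelvis→outer-cortex rectangular ROI and its column zone annotation.

    The ROI starts at the pelvis centre and runs rightward to the outer
    cortical edge along the semi-major axis, ``roi_height`` rows tall;
    profile column j (at x = x0 + j) is annotated with the band its
    centre-row pixel falls in.
    """
    cx, cy = cfg.center
    x0 = int(np.ceil(cx))
    y0 = int(round(cy)) - roi_height // 2
    axes = [a for _, a in cfg.zone_bands]
    labels = [lbl for lbl, _ in cfg.zone_bands]
    width = int(np.floor(axes[-1]))
    if x0 + width > cfg.width or y0 < 0 or y0 + roi_height > cfg.height:
        raise ValueError("ROI exceeds section grid; enlarge the grid")
    roi = RectROI(x0=x0, y0=y0, width_px=width, height_px=roi_height, orientation=0)
    zones = []
    prev = 0
    for lbl, a in zip(labels, axes):
        end = min(int(np.ceil(a - (cx - np.floor(cx)))), width)
        end = max(end, prev + 1)
        zones.append(Zone(label=lbl, start=prev, end=end))
        prev = end
    zones[-1] = Zone(label=labels[-1], start=zones[-1].start, end=width)
    return roi, ZoneAnnotation(tuple(zones), section_id=section_id)


@dataclass
class CohortSection:
    section_id: str
    group: str
    dataset: MSIDataset
    truth: SectionTruth
    roi: RectROI
    annotation: ZoneAnnotation
    config: SectionConfig


def generate_cohort(
    base_cfg: SectionConfig,
    n_sections: int = 6,
    group: str = "control",
    group_effects: dict[str, dict[str, float]] | None = None,
    width_variation: float = 0.12,
    animal_cv: float = 0.15,
    seed: int = 0,
) -> list[CohortSection]:
    """Generate a diet-group cohort of sections with varying zone widths.

    ``group_effects`` maps zone → analyte → multiplier applied to the true
    zone ratios (e.g. ``{"OC": {"corticosterone": 2.0}}`` for the low-salt
    outer-cortex glucocorticoid elevation).  Section sizes vary by a uniform
    scale in [1 - width_variation, 1] (the first section keeps scale 1, so
    the reference/widest section is deterministic), exercising the
    imputation-based alignment.  ``animal_cv`` adds a per-animal, per-analyte
    log-normal multiplier (biological variability).  All randomness derives
    from ``seed``.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    group_effects = group_effects or {}
    out: list[CohortSection] = []
    for k in range(n_sections):
        scale = 1.0 if k == 0 else float(rng.uniform(1.0 - width_variation, 1.0))
        section_seed = int(rng.integers(0, 2**31 - 1))
        ratios = {a: dict(z) for a, z in base_cfg.zone_ratios.items()}
        applied: dict[str, dict[str, float]] = {}
        for zone, effects in group_effects.items():
            for analyte, mult in effects.items():
                ratios[analyte][zone] *= mult
                applied.setdefault(zone, {})[analyte] = mult
        for analyte in ratios:
            animal_mult = float(_lognormal_mean1(rng, animal_cv, None)) if animal_cv > 0 else 1.0
            for zone in ratios[analyte]:
                ratios[analyte][zone] *= animal_mult
        cfg = replace(base_cfg.scaled(scale), zone_ratios=ratios, seed=section_seed)
        dataset, truth = generate_section(cfg)
        truth.group = group
        truth.applied_multipliers = applied
        section_id = f"{group}-{k + 1}"
        roi, ann = section_roi_and_zones(cfg, section_id=section_id)
        out.append(
            CohortSection(
                section_id=section_id,
                group=group,
                dataset=dataset,
                truth=truth,
                roi=roi,
                annotation=ann,
                config=cfg,
            )
        )
    return out


def scaled_section_config(scale: float = 0.6, seed: int = 0, **overrides) -> SectionConfig:
    """A smaller kidney section (all band axes scaled) on a matching grid.

    Used for repeated-simulation studies (e.g. power checks) where the full
    default section would be needlessly large; the margin, centre and grid
    are shrunk together so the geometry is the same cartoon at lower pixel
    count.
    """
    base = SectionConfig()
    bands = tuple((lbl, a * scale) for lbl, a in base.zone_bands)
    outer = bands[-1][1]
    cx = outer + 4.0
    cy = outer * base.axis_ratio + 4.0
    width = int(np.ceil(cx + outer)) + 4
    height = int(np.ceil(2 * cy)) + 1
    from dataclasses import replace

    return replace(
        base,
        width=width,
        height=height,
        center=(cx, cy),
        zone_bands=bands,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# plasma panels


@dataclass(frozen=True)
class PlasmaConfig:
    """Generating parameters for a plasma calibration + sample panel."""

    groups: tuple[str, ...] = ("low", "control", "high")
    n_per_group: int = 6
    # true plasma concentration means (ng/mL) per analyte per group: the
    # qualitative study structure — aldosterone falls as salt intake rises,
    # corticosterone is unchanged, 11-DHC is lower in both low and high salt
    group_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "aldosterone": {"low": 1.6, "control": 0.8, "high": 0.2},
            "corticosterone": {"low": 30.0, "control": 30.0, "high": 30.0},
            "11-dehydrocorticosterone": {"low": 5.0, "control": 10.0, "high": 5.0},
        }
    )
    sample_cv: float = 0.20
    # validated calibration ranges (ng/mL)
    calibration_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "aldosterone": (0.05, 2.5),
            "corticosterone": (0.05, 250.0),
            "11-dehydrocorticosterone": (0.10, 25.0),
        }
    )
    n_calibration_points: int = 11
    true_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "aldosterone": 1.20,
            "corticosterone": 0.04,
            "11-dehydrocorticosterone": 0.35,
        }
    )
    true_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "aldosterone": 0.005,
            "corticosterone": 0.002,
            "11-dehydrocorticosterone": 0.004,
        }
    )
    calibration_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for analyte, by_group in self.group_means.items():
            for g, m in by_group.items():
                if m <= 0:
                    raise ValueError(f"group mean for {analyte}/{g} must be > 0")


@dataclass
class PlasmaTruth:
    group_means: dict[str, dict[str, float]]
    true_slopes: dict[str, float]
    true_intercepts: dict[str, float]
    calibration_ranges: dict[str, tuple[float, float]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def generate_plasma(
    cfg: PlasmaConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlasmaTruth]:
    """Generate (calibration table, sample table, truth).

    Calibration: per analyte, ``n_calibration_points`` geometrically spaced
    nominal levels across the validated range with multiplicative response
    noise around the true line.  Samples: per group, log-normal
    concentrations around the group mean, converted to responses through the
    true line with the same response noise.
    """
    rng = np.random.default_rng(cfg.seed)
    cal_rows = []
    for analyte in cfg.group_means:
        lo, hi = cfg.calibration_ranges[analyte]
        nominal = np.geomspace(lo, hi, cfg.n_calibration_points)
        slope, icept = cfg.true_slopes[analyte], cfg.true_intercepts[analyte]
        noise = _lognormal_mean1(rng, cfg.calibration_noise_cv, len(nominal))
        response = (slope * nominal + icept) * noise
        for x, y in zip(nominal, response):
            cal_rows.append({"analyte": analyte, "nominal": float(x), "response": float(y)})

    sample_rows = []
    for group in cfg.groups:
        for i in range(cfg.n_per_group):
            sample_id = f"{group}-{i + 1}"
            for analyte in cfg.group_means:
                mu = cfg.group_means[analyte][group]
                conc = mu * float(_lognormal_mean1(rng, cfg.sample_cv, None))
                slope, icept = cfg.true_slopes[analyte], cfg.true_intercepts[analyte]
                resp = (slope * conc + icept) * float(
                    _lognormal_mean1(rng, cfg.calibration_noise_cv, None)
                )
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "analyte": analyte,
                        "true_conc": conc,
                        "response": resp,
                    }
                )
    truth = PlasmaTruth(
        group_means={a: dict(g) for a, g in cfg.group_means.items()},
        true_slopes=dict(cfg.true_slopes),
        true_intercepts=dict(cfg.true_intercepts),
        calibration_ranges={a: tuple(r) for a, r in cfg.calibration_ranges.items()},
        seed=cfg.seed,
    )
    return pd.DataFrame(cal_rows), pd.DataFrame(sample_rows), truth
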