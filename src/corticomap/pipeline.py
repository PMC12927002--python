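"""End-to-end convenience wrappers: dataset → ratio images → aligned zone means.

These functions chain the module-level operations in the order the analysis
runs them: targeted extraction of the three analyte derivative ions and the
internal standard, per-pixel normalization, ROI column profiling, zone
annotation, imputation-based alignment across sections, and per-zone means
per animal — the unit on which the diet-group statistics operate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import AlignmentConfig, align_sections, zone_means
from .chem import default_targets
from .extract import DEFAULT_TOL_PPM, RatioImage, ion_image, normalize
from .msi_io import MSIDataset
from .profile import ColumnProfile, RectROI, column_profile
from .synth import ANALYTES, CohortSection

__all__ = [
    "ratio_images",
    "section_profiles",
    "cohort_zone_means",
    "plasma_study",
    "msi_diet_study",
]


def ratio_images(
    dataset: MSIDataset,
    tol_ppm: float = DEFAULT_TOL_PPM,
    is_floor: float = 0.0,
) -> dict[str, RatioImage]:
    """Analyte/IS ratio image for each of the three targeted steroids."""
    targets = default_targets()
    is_img = ion_image(dataset, targets["d8-corticosterone"], tol_ppm)
    return {
        name: normalize(ion_image(dataset, targets[name], tol_ppm), is_img, is_floor)
        for name in ANALYTES
    }


def section_profiles(
    dataset: MSIDataset,
    roi: RectROI,
    tol_ppm: float = DEFAULT_TOL_PPM,
    section_id: str = "",
) -> dict[str, ColumnProfile]:
    """Per-analyte pelvis→cortex column profiles of one section's ratio images."""
    profiles = {}
    for name, img in ratio_images(dataset, tol_ppm).items():
        prof = column_profile(img, roi)
        prof.section_id = section_id
        profiles[name] = prof
    return profiles


def cohort_zone_means(
    sections: list[CohortSection],
    config: AlignmentConfig = AlignmentConfig(),
    tol_ppm: float = DEFAULT_TOL_PPM,
    scored_zones: tuple[str, ...] = ("IM", "OM", "IC", "OC"),
) -> pd.DataFrame:
    """Tidy per-section per-zone mean ratios for one or more cohorts.

    Sections from multiple diet groups may be concatenated; alignment
    (reference lengths) is computed over all of them together, as in a
    single study.  Returns columns: section, group, analyte, zone, value.
    """
    per_analyte_profiles: dict[str, list[ColumnProfile]] = {a: [] for a in ANALYTES}
    annotations = []
    for sec in sections:
        profs = section_profiles(sec.dataset, sec.roi, tol_ppm, sec.section_id)
        for a in ANALYTES:
            per_analyte_profiles[a].append(profs[a])
        annotations.append(sec.annotation)

    rows = []
    for analyte in ANALYTES:
        aligned, _report = align_sections(per_analyte_profiles[analyte], annotations, config)
        for sec, ap in zip(sections, aligned):
            means = zone_means(ap)
            for zone in scored_zones:
                rows.append(
                    {
                        "section": sec.section_id,
                        "group": sec.group,
                        "analyte": analyte,
                        "zone": zone,
                        "value": means.get(zone, np.nan),
                    }
                )
    return pd.DataFrame(rows)


def plasma_study(seed: int, cfg=None) -> pd.DataFrame:
    """Full plasma quantification study on one synthetic panel.

    Generates calibration + sample tables, fits the 1/x-weighted curve per
    analyte, back-calculates sample concentrations, derives the per-animal
    active:inactive glucocorticoid ratio, and returns the per-analyte
    diet-group report (means ± SEM, ANOVA, Dunnett p, stars).
    """
    from .stats import active_inactive_ratio, back_calculate, fit_calibration, group_statistics
    from .synth import PlasmaConfig, generate_plasma

    if cfg is None:
        cfg = PlasmaConfig(seed=seed)
    cal, samples, _truth = generate_plasma(cfg)
    curves = {
        analyte: fit_calibration(
            list(zip(sub["nominal"], sub["response"])),
            weighting="1/x",
            analyte=analyte,
            valid_range=cfg.calibration_ranges[analyte],
        )
        for analyte, sub in cal.groupby("analyte")
    }
    measured = samples.copy()
    measured["value"] = [
        back_calculate(curves[row["analyte"]], row["response"])[0]
        for _, row in samples.iterrows()
    ]
    wide = measured.pivot(index=["sample_id", "group"], columns="analyte", values="value")
    ratio = active_inactive_ratio(
        wide["corticosterone"].to_numpy(), wide["11-dehydrocorticosterone"].to_numpy()
    )
    ratio_rows = pd.DataFrame(
        {
            "sample_id": [i[0] for i in wide.index],
            "group": [i[1] for i in wide.index],
            "analyte": "active:inactive",
            "value": ratio,
        }
    )
    table = pd.concat(
        [measured[["sample_id", "group", "analyte", "value"]], ratio_rows],
        ignore_index=True,
    )
    return group_statistics(table, control_label="control")


def msi_diet_study(
    seed: int,
    scale: float = 0.75,
    n_per_group: int = 6,
    group_effects: dict[str, dict[str, float]] | None = None,
    animal_cv: float = 0.15,
    width_variation: float = 0.07,
) -> pd.DataFrame:
    """Two-group tissue study: control vs low-salt cohorts through the pipeline.

    Generates a control cohort and a low-salt cohort carrying
    ``group_effects`` (default: outer-cortex corticosterone x2), runs
    extraction → normalization → profiling → alignment on all sections
    together, and Dunnett-tests each analyte/zone mean (low vs control).
    Returns columns: analyte, zone, estimate, t, p_adjusted.
    """
    from .stats import dunnett
    from .synth import generate_cohort, scaled_section_config

    if group_effects is None:
        group_effects = {"OC": {"corticosterone": 2.0}}
    rng = np.random.default_rng(seed)
    seed_control = int(rng.integers(0, 2**31 - 1))
    seed_low = int(rng.integers(0, 2**31 - 1))
    base = scaled_section_config(scale=scale)
    control = generate_cohort(
        base, n_sections=n_per_group, group="control", animal_cv=animal_cv,
        width_variation=width_variation, seed=seed_control,
    )
    low = generate_cohort(
        base, n_sections=n_per_group, group="low", group_effects=group_effects,
        animal_cv=animal_cv, width_variation=width_variation, seed=seed_low,
    )
    df = cohort_zone_means(control + low)
    rows = []
    for (analyte, zone), sub in df.groupby(["analyte", "zone"]):
        ctrl = sub.loc[sub["group"] == "control", "value"].dropna().to_numpy()
        treat = sub.loc[sub["group"] == "low", "value"].dropna().to_numpy()
        res = dunnett([treat], ctrl, labels=["low"])
        comp = res.comparisons[0]
        rows.append(
            {
                "analyte": analyte,
                "zone": zone,
                "estimate": comp.estimate,
                "t": comp.t,
                "p_adjusted": comp.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
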