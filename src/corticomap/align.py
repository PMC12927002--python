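"""Zone annotation and spatial alignment of column profiles across sections.

Kidney sections differ in size, so the same histological zone (inner medulla
IM, outer medulla OM, inner cortex IC, outer cortex OC) spans different
numbers of profile columns in different sections.  To make sections
comparable, each zone's reference length is taken from the widest section and
shorter zones are brought up to it by deterministic adjacent-point
imputation: the missing points are distributed equally along the zone and
each imputed value is the average of its two flanking original points.

Two QC thresholds are tracked.  A zone needing more than
``max_imputed_fraction`` (default 20%) imputed points is flagged
non-compliant and excluded from group statistics (it is kept, with a
warning, for inspection).  Whether a zone was shorter than
``min_column_fraction`` (default 70%) of the reference is recorded as an
annotation on the compliance report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import ColumnProfile

__all__ = [
    "Zone",
    "ZoneAnnotation",
    "AlignmentConfig",
    "ZoneCompliance",
    "AlignedProfile",
    "reference_lengths",
    "impute_zone",
    "align_sections",
    "zone_means",
    "DEFAULT_ZONES",
]

# Anatomical order, pelvis → outer cortex.  The pelvis is the profile origin
# and is not a scored zone by default.
DEFAULT_ZONES = ("IM", "OM", "IC", "OC")


@dataclass(frozen=True)
class Zone:
    label: str
    start: int  # inclusive column index
    end: int  # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ZoneAnnotation:
    """Ordered, contiguous, non-overlapping zones along one section profile."""

    zones: tuple[Zone, ...]
    section_id: str = ""

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("annotation must contain at least one zone")
        labels = [z.label for z in self.zones]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate zone labels: {labels}")
        for z in self.zones:
            if z.length < 1:
                raise ValueError(f"zone {z.label} has non-positive length")
        for a, b in zip(self.zones, self.zones[1:]):
            if b.start != a.end:
                raise ValueError(
                    f"zones {a.label} and {b.label} are not contiguous "
                    f"({a.end} != {b.start})"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(z.label for z in self.zones)

    def segment(self, profile: ColumnProfile, label: str) -> np.ndarray:
        (zone,) = [z for z in self.zones if z.label == label]
        if zone.end > len(profile):
            raise ValueError(
                f"zone {label} [{zone.start},{zone.end}) exceeds profile length {len(profile)}"
            )
        return profile.values[zone.start : zone.end]


@dataclass(frozen=True)
class AlignmentConfig:
    min_column_fraction: float = 0.70
    max_imputed_fraction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_column_fraction", "max_imputed_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ZoneCompliance:
    n: int  # observed columns
    reference: int  # reference (widest-section) columns
    imputed_fraction: float  # (reference - n) / reference
    meets_min_fraction: bool  # n >= min_column_fraction * reference (QC note)
    compliant: bool  # imputed_fraction <= max_imputed_fraction


@dataclass
class AlignedProfile:
    """One section's per-zone values on the common (reference-length) grid."""

    section_id: str
    zones: dict[str, np.ndarray]
    imputed_flags: dict[str, np.ndarray]
    reference_lengths: dict[str, int]
    compliance: dict[str, ZoneCompliance]


def reference_lengths(annotations: list[ZoneAnnotation]) -> dict[str, int]:
    """Per-zone reference column count: the maximum across sections.

    All sections must carry the same ordered zone label sequence.
    """
    if not annotations:
        raise ValueError("no annotations given")
    labels = annotations[0].labels
    for ann in annotations[1:]:
        if ann.labels != labels:
            raise ValueError(
                f"inconsistent zone label sequences: {labels} vs {ann.labels} "
                f"(section {ann.section_id!r})"
            )
    return {
        label: max(ann.zones[i].length for ann in annotations)
        for i, label in enumerate(labels)
    }


def impute_zone(
    segment: np.ndarray, target_len: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Expand a zone segment to ``target_len`` by equal-spread midpoint imputation.

    The k = N - n missing points are placed at fractional positions
    p_j = j (n-1)/(k+1), j = 1..k along the original index axis; the point
    for p_j is inserted in the gap after original index floor(p_j) and takes
    the value (x[floor(p_j)] + x[floor(p_j)+1]) / 2.  Original values are
    never altered, reordered or dropped.  A length-1 segment is replicated.

    Returns (values, imputed_flags, imputed_fraction) where
    imputed_fraction = k / N.
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("cannot impute an empty segment")
    if n > target_len:
        raise ValueError(f"segment length {n} exceeds target {target_len}")
    k = target_len - n
    if k == 0:
        return x.copy(), np.zeros(n, dtype=bool), 0.0
    if n == 1:
        values = np.full(target_len, x[0])
        flags = np.ones(target_len, dtype=bool)
        flags[0] = False
        return values, flags, k / target_len

    # number of imputed points falling in each inter-original gap
    positions = np.arange(1, k + 1) * (n - 1) / (k + 1)
    gaps = np.floor(positions).astype(int)
    out: list[float] = []
    flags: list[bool] = []
    for i in range(n):
        out.append(x[i])
        flags.append(False)
        n_here = int(np.sum(gaps == i))
        if n_here and i + 1 < n:
            mid = (x[i] + x[i + 1]) / 2.0
            out.extend([mid] * n_here)
            flags.extend([True] * n_here)
    return np.asarray(out), np.asarray(flags, dtype=bool), k / target_len


def align_sections(
    profiles: list[ColumnProfile],
    annotations: list[ZoneAnnotation],
    config: AlignmentConfig = AlignmentConfig(),
) -> tuple[list[AlignedProfile], pd.DataFrame]:
    """Bring every section's zones to the common reference lengths.

    Every zone shorter than the reference is imputed up to it; zones whose
    required imputed fraction exceeds ``config.max_imputed_fraction`` are
    flagged non-compliant (they are still returned, with a warning, but
    should be excluded from group statistics).  The second return value is a
    per-section x zone compliance report.
    """
    if len(profiles) != len(annotations):
        raise ValueError("one annotation per profile required")
    refs = reference_lengths(annotations)
    aligned: list[AlignedProfile] = []
    rows: list[dict] = []
    for profile, ann in zip(profiles, annotations):
        section = ann.section_id or profile.section_id
        zones: dict[str, np.ndarray] = {}
        flags: dict[str, np.ndarray] = {}
        compliance: dict[str, ZoneCompliance] = {}
        for zone in ann.zones:
            seg = ann.segment(profile, zone.label)
            N = refs[zone.label]
            values, fl, frac = impute_zone(seg, N)
            ok = frac <= config.max_imputed_fraction
            comp = ZoneCompliance(
                n=zone.length,
                reference=N,
                imputed_fraction=frac,
                meets_min_fraction=zone.length >= config.min_column_fraction * N,
                compliant=ok,
            )
            if not ok:
                warnings.warn(
                    f"section {section!r} zone {zone.label}: imputed fraction "
                    f"{frac:.2f} exceeds {config.max_imputed_fraction:.2f}; "
                    "zone flagged non-compliant",
                    stacklevel=2,
                )
            zones[zone.label] = values
            flags[zone.label] = fl
            compliance[zone.label] = comp
            rows.append(
                {
                    "section": section,
                    "zone": zone.label,
                    "n": zone.length,
                    "reference": N,
                    "imputed_fraction": frac,
                    "meets_min_fraction": comp.meets_min_fraction,
                    "compliant": ok,
                }
            )
        aligned.append(
            AlignedProfile(
                section_id=section,
                zones=zones,
                imputed_flags=flags,
                reference_lengths=dict(refs),
                compliance=compliance,
            )
        )
    return aligned, pd.DataFrame(rows)


def zone_means(
    aligned: AlignedProfile,
    include_imputed: bool = True,
    compliant_only: bool = True,
) -> dict[str, float]:
    """Arithmetic mean of defined values per zone (NaN when none).

    Imputed points are included by default (each is an average of its
    neighbours, so zone means are only mildly affected); pass
    ``include_imputed=False`` to average original points only.  Non-compliant
    zones report NaN unless ``compliant_only=False``.
    """
    out: dict[str, float] = {}
    for label, values in aligned.zones.items():
        if compliant_only and not aligned.compliance[label].compliant:
            out[label] = float("nan")
            continue
        v = values if include_imputed else values[~aligned.imputed_flags[label]]
        v = v[~np.isnan(v)]
        out[label] = float(np.mean(v)) if len(v) else float("nan")
    return out
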