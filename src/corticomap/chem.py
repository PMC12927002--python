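"""Formula algebra and Girard T derivative mass chemistry.

Girard T (GirT) is a (carboxymethyl)trimethylammonium hydrazide reagent that
condenses with the 3-keto group of Δ4-3-ketosteroids, losing water and leaving
a permanently charged hydrazone cation.  The net composition change on the
steroid is +C5H12N3 with charge +1, which is what makes poorly ionising
corticosteroids visible in positive-mode MALDI.

This module provides exact monoisotopic mass arithmetic for those derivatives:
Hill-notation formula parsing, derivative transformation, charged-species m/z
(electron mass corrected), ppm mass errors, and prediction/matching of the
diagnostic CID neutral losses (trimethylamine, then carbon monoxide) used to
confirm derivative identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC_MASSES",
    "ELECTRON_MASS",
    "MolecularFormula",
    "IonSpecies",
    "FragmentPrediction",
    "FragmentMatch",
    "FragmentReport",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "girt_derivative",
    "ppm_error",
    "delta_ppm",
    "predict_girt_fragments",
    "match_fragments",
    "format_mz",
    "format_ppm",
    "STEROIDS",
    "default_targets",
]

# Fixed monoisotopic mass table (Da).  Deuterium is a distinct symbol "D",
# not an isotope annotation on H.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "D": 2.0141017780,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

ELECTRON_MASS = 0.00054857990  # Da per elementary charge

# Net composition change of a 3-ketosteroid upon GirT hydrazone formation:
# condensation with the C5H14N3O+ cation loses H2O.
GIRT_NET_ADDITION: dict[str, int] = {"C": 5, "H": 12, "N": 3}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill convention: C first, H second, remaining symbols alphabetical.
_HILL_TAIL = sorted(set(MONOISOTOPIC_MASSES) - {"C", "H"})


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral or charged species composition."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction underflow: {el} count would be {merged[el]}"
                )
        return MolecularFormula(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts: list[str] = []
        for el in ["C", "H", *_HILL_TAIL]:
            n = self.counts.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        # elements outside the registered table keep alphabetical order
        extra = sorted(set(self.counts) - set(MONOISOTOPIC_MASSES))
        for el in extra:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.hill()


@dataclass(frozen=True)
class IonSpecies:
    """A charged species whose m/z can be computed from its formula."""

    formula: MolecularFormula
    charge: int
    label: str = ""

    @property
    def mz(self) -> float:
        return ion_mz(self)


@dataclass(frozen=True)
class FragmentPrediction:
    """Predicted CID product ions as cumulative neutral losses."""

    precursor_mz: float
    losses: tuple[tuple[str, float], ...]
    predicted_mz: tuple[float, ...]


@dataclass(frozen=True)
class FragmentMatch:
    predicted_mz: float
    loss_name: str
    matched: bool
    observed_mz: float | None
    ppm_deviation: float | None


@dataclass(frozen=True)
class FragmentReport:
    matches: tuple[FragmentMatch, ...]
    confirmed: bool


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C26H42N3O4"``.

    Deuterium is written ``D``.  Implicit count 1 is allowed (``"H2O"``).
    Unknown element symbols and malformed strings are rejected.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASSES:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of per-element masses)."""
    try:
        return sum(n * MONOISOTOPIC_MASSES[el] for el, n in f.counts.items())
    except KeyError as exc:  # pragma: no cover - table is closed over parse
        raise ValueError(f"element {exc.args[0]!r} has no registered mass") from exc


def ion_mz(species: IonSpecies) -> float:
    """Theoretical m/z of a charged species, electron-mass corrected.

    m/z = (monoisotopic mass - z * m_e) / |z|.  Full double precision is
    retained; use :func:`format_mz` for the conventional 4-dp display.
    """
    z = species.charge
    if z == 0:
        raise ValueError("m/z is undefined for a neutral species (charge 0)")
    return (monoisotopic_mass(species.formula) - z * ELECTRON_MASS) / abs(z)


def girt_derivative(steroid: MolecularFormula, label: str = "") -> IonSpecies:
    """GirT hydrazone cation of a 3-ketosteroid: formula +C5H12N3, charge +1.

    The ketone itself is assumed; only the presence of at least one oxygen is
    checked (no regiochemistry).
    """
    if steroid.counts.get("O", 0) < 1:
        raise ValueError("steroid formula has no oxygen; 3-keto group required")
    return IonSpecies(
        formula=steroid + MolecularFormula(GIRT_NET_ADDITION),
        charge=+1,
        label=label or f"GirT-{steroid.hill()}",
    )


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


def delta_ppm(measured: float, theoretical: float) -> float:
    """|ppm error| rounded half-up to 2 dp — the conventional Δppm report."""
    return float(
        Decimal(abs(ppm_error(measured, theoretical))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


# Diagnostic neutral losses of GirT hydrazone cations under CID: the
# trimethylamine group is expelled first, then carbon monoxide.
TRIMETHYLAMINE = parse_formula("C3H9N")
CARBON_MONOXIDE = parse_formula("CO")
_TMA_MASS = monoisotopic_mass(TRIMETHYLAMINE)  # 59.07350 Da
_CO_MASS = monoisotopic_mass(CARBON_MONOXIDE)  # 27.99491 Da


def predict_girt_fragments(precursor_mz: float) -> FragmentPrediction:
    """Predict the two diagnostic GirT product ions by sequential neutral loss.

    Returns precursor - 59.07350 (TMA loss) and precursor - 87.06841
    (TMA + CO), strictly decreasing.
    """
    total = _TMA_MASS + _CO_MASS
    if precursor_mz <= total:
        raise ValueError(
            f"precursor m/z {precursor_mz} at or below total loss mass {total:.5f}"
        )
    losses = (("trimethylamine", _TMA_MASS), ("carbon monoxide", _CO_MASS))
    predicted = (precursor_mz - _TMA_MASS, precursor_mz - total)
    return FragmentPrediction(precursor_mz, losses, predicted)


def match_fragments(
    observed: Sequence[tuple[float, float]],
    prediction: FragmentPrediction,
    tol_ppm: float = 10.0,
) -> FragmentReport:
    """Match observed (m/z, intensity) peaks against predicted product ions.

    A predicted fragment is matched if any observed peak lies within
    ±tol_ppm; the derivative is confirmed only if every predicted fragment
    matched.  An empty observed list confirms nothing (not an error).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    matches: list[FragmentMatch] = []
    for (name, _), pred in zip(prediction.losses, prediction.predicted_mz):
        best_obs: float | None = None
        best_dev: float | None = None
        for mz, _intensity in observed:
            dev = ppm_error(mz, pred)
            if abs(dev) <= tol_ppm and (best_dev is None or abs(dev) < abs(best_dev)):
                best_obs, best_dev = mz, dev
        matches.append(
            FragmentMatch(
                predicted_mz=pred,
                loss_name=name,
                matched=best_obs is not None,
                observed_mz=best_obs,
                ppm_deviation=best_dev,
            )
        )
    return FragmentReport(tuple(matches), confirmed=all(m.matched for m in matches))


def format_mz(mz: float) -> str:
    """m/z display convention: 4 dp, half-up."""
    return str(Decimal(mz).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def format_ppm(ppm: float) -> str:
    """Δppm display convention: 2 dp, half-up."""
    return str(Decimal(abs(ppm)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# Neutral formulas of the corticosteroids handled by the pipeline.  D8-CORT is
# the 2,2,4,6,6,17,21,21-[2H8] internal standard sprayed with the reagent.
STEROIDS: dict[str, MolecularFormula] = {
    "corticosterone": parse_formula("C21H30O4"),
    "11-dehydrocorticosterone": parse_formula("C21H28O4"),
    "aldosterone": parse_formula("C21H28O5"),
    "d8-corticosterone": parse_formula("C21H22D8O4"),
}


def default_targets() -> dict[str, IonSpecies]:
    """GirT derivative cations of the standard analyte/IS panel."""
    return {name: girt_derivative(f, label=name) for name, f in STEROIDS.items()}
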