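"""Elemental-composition arithmetic for annotating ions, adducts and fragments.

Nominal masses are integer sums over the most abundant isotope of each
element (C=12, H=1, N=14, O=16, ...), matching the integer m/z assignments
of routine MS spectra; monoisotopic masses use exact isotope masses with an
electron-mass correction for charged species.  Isotope patterns are built by
per-element multinomial convolution with 0.01 Da bin aggregation.

The adduct mini-grammar covers the common ESI species: ``[M+H]+``,
``[2M+Na]+``, ``[M+H-H2O]+``, ``[M+NH4]+`` and so on, with any Hill-style
formula accepted as the added or removed part.  ``D`` is accepted as a
pseudo-element for deuterium so labelled internal standards (d3 analogues)
can be written directly.

The isotope masses and abundances below are pinned snapshot values from the
standard atomic-weights compilations, shipped in-package so annotation is
download-free and version-stable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .errors import ParseError, ValidationError

ELECTRON_MASS = 0.000548579909  # Da

#: integer mass of the most abundant isotope
NOMINAL_MASS: dict[str, int] = {
    "H": 1, "D": 2, "C": 12, "N": 14, "O": 16, "F": 19, "Na": 23, "Mg": 24,
    "Si": 28, "P": 31, "S": 32, "Cl": 35, "K": 39, "Ca": 40, "Fe": 56,
    "Cu": 63, "Zn": 64, "Br": 79, "I": 127,
}

#: exact mass of the most abundant isotope (Da)
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319, "D": 2.0141017778, "C": 12.0, "N": 14.0030740052,
    "O": 15.9949146221, "F": 18.9984031627, "Na": 22.9897692820,
    "Mg": 23.9850416970, "Si": 27.9769265350, "P": 30.9737619984,
    "S": 31.9720711744, "Cl": 34.9688526932, "K": 38.9637064864,
    "Ca": 39.9625909830, "Fe": 55.9349363000, "Cu": 62.9295977200,
    "Zn": 63.9291420100, "Br": 78.9183376000, "I": 126.9044719000,
}

#: (mass, fractional abundance) per naturally occurring isotope
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017778, 0.000115)),
    "D": ((2.0141017778, 1.0),),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740052, 0.99636), (15.0001088989, 0.00364)),
    "O": ((15.9949146221, 0.99757), (16.9991315650, 0.00038), (17.9991604000, 0.00205)),
    "F": ((18.9984031627, 1.0),),
    "Na": ((22.9897692820, 1.0),),
    "P": ((30.9737619984, 1.0),),
    "S": (
        (31.9720711744, 0.9499), (32.9714589098, 0.0075),
        (33.9678670040, 0.0425), (35.9670807100, 0.0001),
    ),
    "Cl": ((34.9688526932, 0.7576), (36.9659026000, 0.2424)),
    "K": ((38.9637064864, 0.932581), (39.9639981660, 0.000117), (40.9618252579, 0.067302)),
    "Br": ((78.9183376000, 0.5069), (80.9162897000, 0.4931)),
    "I": ((126.9044719000, 1.0),),
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
# charge suffixes: "+", "-", "++", "+2", "-3"  (digit-before-sign forms like
# "2+" are rejected as ambiguous against a trailing element count)
_CHARGE_RE = re.compile(r"(\+{1,9}|-{1,9}|[+\-]\d+)$")


@dataclass(frozen=True)
class Composition:
    """Elemental composition with an integer charge."""

    element_counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        counts = {el: int(n) for el, n in self.element_counts.items() if n != 0}
        if not counts:
            raise ValidationError("composition must contain at least one element")
        if any(n < 0 for n in counts.values()):
            raise ValidationError("element counts must be non-negative")
        object.__setattr__(self, "element_counts", counts)

    def __add__(self, other: "Composition") -> "Composition":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return Composition(counts, self.charge + other.charge)

    def scaled(self, k: int) -> "Composition":
        return Composition({el: n * k for el, n in self.element_counts.items()}, self.charge * k)

    def atom_count(self) -> int:
        return sum(self.element_counts.values())


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation recipe: ``multiplier * M + added - removed`` at ``charge``."""

    multiplier: int = 1
    added: Composition | None = None
    removed: Composition | None = None
    charge: int = 1

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValidationError("adduct multiplier must be >= 1")


@dataclass
class IsotopePattern:
    peaks: list[tuple[float, float]]  # (m/z, relative intensity)
    normalization: Literal["max_100", "sum_1"]


def parse_formula(text: str) -> Composition:
    """Parse a Hill-style formula with an optional trailing charge.

    ``C8H9NO2`` -> {C:8, H:9, N:1, O:2}; ``C21H38N+`` carries charge +1;
    ``+2`` / ``--`` suffixes give multiply charged species.
    """
    s = text.strip()
    if not s:
        raise ParseError("empty formula")
    charge = 0
    m = _CHARGE_RE.search(s)
    if m:
        token = m.group(1)
        sign = 1 if token[0] == "+" else -1
        mag = int(token[1:]) if token[1:].isdigit() else len(token)
        charge = sign * mag
        s = s[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or not m.group(1):
            raise ParseError(f"cannot parse formula {text!r} at position {pos}")
        el = m.group(1)
        if el not in NOMINAL_MASS:
            raise ParseError(f"unknown element {el!r} in formula {text!r} at position {pos}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Composition(counts, charge)


def nominal_mass(c: Composition) -> int:
    """Integer mass from most-abundant-isotope integer masses."""
    try:
        return sum(NOMINAL_MASS[el] * n for el, n in c.element_counts.items())
    except KeyError as exc:
        raise ValidationError(f"no nominal mass for element {exc.args[0]!r}") from None


def monoisotopic_mass(c: Composition) -> float:
    """Exact mass from the packaged isotope table, electron-corrected for ions."""
    try:
        m = sum(MONOISOTOPIC_MASS[el] * n for el, n in c.element_counts.items())
    except KeyError as exc:
        raise ValidationError(f"no monoisotopic mass for element {exc.args[0]!r}") from None
    return m - c.charge * ELECTRON_MASS


_ADDUCT_RE = re.compile(r"^\[(\d*)M((?:[+\-][A-Za-z0-9]+)*)\](\d*)([+\-])$")


def parse_adduct(text: str) -> AdductSpec:
    """Parse the ``[nM+X-Y]z±`` adduct mini-grammar (e.g. ``[2M+Na]+``)."""
    s = text.strip().replace("−", "-").replace(" ", "")
    m = _ADDUCT_RE.match(s)
    if not m:
        raise ParseError(f"cannot parse adduct {text!r}; expected the form [nM+X-Y]z+")
    multiplier = int(m.group(1)) if m.group(1) else 1
    z = int(m.group(3)) if m.group(3) else 1
    charge = z if m.group(4) == "+" else -z
    added: Composition | None = None
    removed: Composition | None = None
    for sign, count, formula in re.findall(
        r"([+\-])(\d*)([A-Za-z][A-Za-z0-9]*)", m.group(2)
    ):
        part = parse_formula(formula)
        if count:
            part = part.scaled(int(count))
        if sign == "+":
            added = part if added is None else added + part
        else:
            removed = part if removed is None else removed + part
    return AdductSpec(multiplier=multiplier, added=added, removed=removed, charge=charge)


def adduct_mz(
    base: Composition,
    adduct: AdductSpec | str,
    mode: Literal["nominal", "monoisotopic"] = "nominal",
) -> float:
    """m/z of ``multiplier*M + added - removed`` at the adduct's charge.

    Nominal mode stays in integer arithmetic with no electron correction
    (printed assignments are integer-level); monoisotopic mode corrects for
    the electron count of the final charge state.
    """
    if isinstance(adduct, str):
        adduct = parse_adduct(adduct)
    if adduct.charge == 0:
        raise ValidationError("adduct charge must be non-zero")
    counts = {el: n * adduct.multiplier for el, n in base.element_counts.items()}
    if adduct.added is not None:
        for el, n in adduct.added.element_counts.items():
            counts[el] = counts.get(el, 0) + n
    if adduct.removed is not None:
        for el, n in adduct.removed.element_counts.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ValidationError(
                    f"adduct removes more {el} than present ({counts[el]})"
                )
    ion = Composition(counts, adduct.charge)
    if mode == "nominal":
        return nominal_mass(ion) / abs(adduct.charge)
    if mode == "monoisotopic":
        return monoisotopic_mass(ion) / abs(adduct.charge)
    raise ValidationError(f"unknown mode {mode!r}")


def _convolve(a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]],
              prune: float) -> dict[int, tuple[float, float]]:
    """Convolve two binned (mass-moment, abundance) maps; 0.01 Da bins."""
    out: dict[int, tuple[float, float]] = {}
    for ka, (ma, pa) in a.items():
        for kb, (mb, pb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            mass = ma / pa + mb / pb
            key = round(mass * 100)
            m_prev, p_prev = out.get(key, (0.0, 0.0))
            out[key] = (m_prev + mass * p, p_prev + p)
    return out


def _element_pattern(el: str, n: int, prune: float) -> dict[int, tuple[float, float]]:
    """n-fold self-convolution of one element's isotope distribution."""
    base = {round(m * 100): (m * p, p) for m, p in ISOTOPES[el]}
    result: dict[int, tuple[float, float]] | None = None
    power = base
    k = n
    while k:
        if k & 1:
            result = power if result is None else _convolve(result, power, prune)
        k >>= 1
        if k:
            power = _convolve(power, power, prune)
    assert result is not None
    return result


def isotope_pattern(
    c: Composition,
    threshold: float = 1e-4,
    normalization: Literal["max_100", "sum_1"] = "max_100",
) -> IsotopePattern:
    """Theoretical isotope pattern by multinomial convolution.

    Peaks are aggregated into 0.01 Da bins (abundance-weighted mean mass per
    bin) and pruned below ``threshold`` of the normalised scale.  Charged
    compositions report m/z with the electron-mass correction.
    """
    if c.atom_count() > 10_000:
        raise ValidationError("composition too large for polynomial convolution")
    for el in c.element_counts:
        if el not in ISOTOPES:
            raise ValidationError(f"no isotope data for element {el!r}")
    prune = 1e-12
    acc: dict[int, tuple[float, float]] | None = None
    for el, n in sorted(c.element_counts.items()):
        pat = _element_pattern(el, n, prune)
        acc = pat if acc is None else _convolve(acc, pat, prune)
    assert acc is not None
    peaks = []
    for _key, (m_weighted, p) in acc.items():
        mass = m_weighted / p - c.charge * ELECTRON_MASS
        mz = mass / abs(c.charge) if c.charge else mass
        peaks.append((mz, p))
    peaks.sort()
    total = sum(p for _, p in peaks)
    pmax = max(p for _, p in peaks)
    if normalization == "max_100":
        peaks = [(mz, 100.0 * p / pmax) for mz, p in peaks]
        cut = threshold * 100.0
    elif normalization == "sum_1":
        peaks = [(mz, p / total) for mz, p in peaks]
        cut = threshold
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    peaks = [(mz, p) for mz, p in peaks if p >= cut]
    if normalization == "sum_1":
        s = sum(p for _, p in peaks)
        peaks = [(mz, p / s) for mz, p in peaks]
    return IsotopePattern(peaks=peaks, normalization=normalization)
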