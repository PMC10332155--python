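"""Concentration arithmetic for herbicide formulations.

Commercial glyphosate-based herbicides (GBHs) contain a glyphosate *salt*
(usually the isopropylamine salt) plus co-ingredients.  To compare a
formulation against pure glyphosate, doses are expressed as glyphosate
*acid equivalents* (ae): the molar/mass amount of the parent free acid the
salt corresponds to.  This module converts between molar (µM ae) and mass
(mg/L ae) concentrations, derives the ae mass fraction of a formulation
from its label composition, computes the co-ingredient mass concentration
carried along at a given ae dose, and builds half-log dilution series.

Units: molar masses g/mol, concentrations µM or mg/L, fractions w/w in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GLYPHOSATE_ACID_MM",
    "GLYPHOSATE_IPA_SALT_MM",
    "Formulation",
    "ConcentrationSeries",
    "ROUNDUP_CONCENTRATE",
    "ROUNDUP_READY_TO_USE",
    "round_sig",
    "truncate_sig",
    "um_to_mgL",
    "mgL_to_um",
    "ae_mass_fraction",
    "co_ingredient_equivalent",
    "halflog_series",
]

#: Molar mass of glyphosate free acid (g/mol); standard chemistry, configurable.
GLYPHOSATE_ACID_MM = 169.07
#: Molar mass of glyphosate isopropylamine salt (g/mol).
GLYPHOSATE_IPA_SALT_MM = 228.18


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures (round-half-even via float repr)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def truncate_sig(x: float, sig: int = 2) -> float:
    """Truncate (floor toward zero) ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exp - sig + 1)
    out = math.trunc(x / factor) * factor
    # tidy float representation (e.g. 2.9000000000000004 -> 2.9)
    return round(out, max(0, sig - 1 - exp))


@dataclass(frozen=True)
class Formulation:
    """Label composition of a commercial product, for ae equivalence arithmetic.

    ``equivalence_ratio``, when given, overrides the theoretical co-ingredient
    arithmetic: it is the mg/L of co-ingredient carried per mg/L glyphosate ae.
    Some products' printed equivalent series are not derivable from the salt
    conversion alone, so an explicit ratio can reproduce a printed series.
    """

    name: str
    glyphosate_salt_fraction: float
    salt_molar_mass: float = GLYPHOSATE_IPA_SALT_MM
    acid_molar_mass: float = GLYPHOSATE_ACID_MM
    co_ingredient_name: str = ""
    co_ingredient_fraction: float = 0.0
    equivalence_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        for frac in (self.glyphosate_salt_fraction, self.co_ingredient_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"mass fractions must lie in [0, 1]; got {frac}")
        if self.salt_molar_mass <= 0 or self.acid_molar_mass <= 0:
            raise ValueError("molar masses must be positive")
        if self.acid_molar_mass > self.salt_molar_mass:
            raise ValueError("acid molar mass cannot exceed salt molar mass")


#: 18% glyphosate IPA salt + 0.73% diquat dibromide.
ROUNDUP_CONCENTRATE = Formulation(
    name="RC",
    glyphosate_salt_fraction=0.18,
    co_ingredient_name="diquat dibromide",
    co_ingredient_fraction=0.0073,
)

#: 2% glyphosate IPA salt + 2% pelargonic (and related) fatty acids.  The
#: printed pelargonic equivalent series implies an empirical ratio of
#: ~1.668 mg pelargonic acid per mg glyphosate ae rather than the value the
#: salt arithmetic yields; the ratio is supplied explicitly.
ROUNDUP_READY_TO_USE = Formulation(
    name="RR",
    glyphosate_salt_fraction=0.02,
    co_ingredient_name="pelargonic acid",
    co_ingredient_fraction=0.02,
    equivalence_ratio=282.0 / 169.07,
)


def um_to_mgL(conc_uM: float, molar_mass: float, sig: Optional[int] = None) -> float:
    """Convert a molar concentration (µM) to mass concentration (mg/L).

    ``sig`` optionally rounds the result to that many significant figures
    (3 s.f. matches the conventional reporting of ae concentrations).
    """
    if conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    out = conc_uM * molar_mass / 1000.0
    return round_sig(out, sig) if sig is not None else out


def mgL_to_um(conc_mgL: float, molar_mass: float, sig: Optional[int] = None) -> float:
    """Convert a mass concentration (mg/L) to molar concentration (µM).

    Exact inverse of :func:`um_to_mgL` (before any rounding).
    """
    if conc_mgL < 0:
        raise ValueError("concentration must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    out = conc_mgL * 1000.0 / molar_mass
    return round_sig(out, sig) if sig is not None else out


def ae_mass_fraction(f: Formulation) -> float:
    """Glyphosate acid-equivalent mass fraction (w/w) of a formulation.

    The salt fraction is scaled by the acid/salt molar-mass ratio: every gram
    of salt contributes ``acid_mm / salt_mm`` grams of parent acid.
    """
    return f.glyphosate_salt_fraction * f.acid_molar_mass / f.salt_molar_mass


def co_ingredient_equivalent(
    f: Formulation,
    ae_uM: float,
    sig: Optional[int] = 2,
    rounding: str = "truncate",
) -> float:
    """Co-ingredient mass concentration (mg/L) at a given glyphosate ae dose.

    At ``ae_uM`` glyphosate ae the solution contains
    ``mgL_ae / ae_mass_fraction`` mg/L of total product and hence
    ``product * co_ingredient_fraction`` mg/L of the co-ingredient.  When the
    formulation carries an explicit ``equivalence_ratio`` that ratio is used
    directly.

    The default presentation is truncation to 2 significant figures, the
    convention that reproduces conventionally printed equivalent series
    (e.g. the diquat dibromide series 0.0092–9.2 mg/L); set
    ``rounding="round"`` or ``sig=None`` for alternatives.
    """
    if ae_uM < 0:
        raise ValueError("ae concentration must be non-negative")
    mgL_ae = um_to_mgL(ae_uM, f.acid_molar_mass)
    if f.equivalence_ratio is not None:
        out = mgL_ae * f.equivalence_ratio
    else:
        frac = ae_mass_fraction(f)
        if frac == 0:
            raise ValueError(f"{f.name}: ae mass fraction is zero")
        out = mgL_ae * f.co_ingredient_fraction / frac
    if sig is None:
        return out
    if rounding == "truncate":
        return truncate_sig(out, sig)
    if rounding == "round":
        return round_sig(out, sig)
    raise ValueError(f"unknown rounding mode {rounding!r}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """A matched (µM ae, mg/L ae) dilution series, stored in ascending order."""

    values_uM: tuple
    values_mgL: tuple

    def __post_init__(self) -> None:
        if len(self.values_uM) != len(self.values_mgL):
            raise ValueError("µM and mg/L series must have equal length")
        if any(b <= a for a, b in zip(self.values_uM, self.values_uM[1:])):
            raise ValueError("series must be strictly increasing")

    @property
    def descending_uM(self) -> tuple:
        """The µM values from the top dose downward (dilution order)."""
        return tuple(reversed(self.values_uM))

    @property
    def descending_mgL(self) -> tuple:
        return tuple(reversed(self.values_mgL))


def halflog_series(
    top_uM: float, n: int, molar_mass: float = GLYPHOSATE_ACID_MM, sig: int = 3
) -> ConcentrationSeries:
    """Half-log (factor 10^0.5) dilution series descending from ``top_uM``.

    Generates ``n`` concentrations ``top / 10^(k/2)`` for k = 0..n-1, rounds
    each to ``sig`` significant figures and pairs it with the matching mg/L
    value (rounded the same way).  Values are stored ascending.
    """
    if top_uM <= 0:
        raise ValueError("top concentration must be positive")
    if n < 1:
        raise ValueError("need at least one concentration")
    raw = [top_uM / (10.0 ** (k / 2.0)) for k in range(n)]
    uM = tuple(round_sig(v, sig) for v in reversed(raw))
    mgL = tuple(um_to_mgL(v, molar_mass, sig=sig) for v in uM)
    return ConcentrationSeries(values_uM=uM, values_mgL=mgL)
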