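"""Target-boundary estimation and the four upper-bound rarity estimators.

All probabilities here are carried as log10 reals (they are far below
float underflow on the linear scale).  Two exponent-formatting
conventions coexist because published order-of-magnitude chains use
both:

* ``round`` — nearest-integer log10 exponent (10**-73.6 reported as
  10**-74); used for the epistatic-target pipeline.
* ``floor`` — scientific-notation exponent (10**-123.2 = 6.0e-124
  reported as 10**-124); used for tolerance/stability table outputs.

The raw log10 value always travels alongside the formatted exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ValidationError

__all__ = [
    "PTH_GLOBAL",
    "PTH_EUKARYOTE",
    "format_exponent",
    "boundary_from_tolerance",
    "prob_functional_in_target",
    "composite_rarity",
    "rarity_from_tolerance",
    "tolerance_from_rarity",
    "rarity_from_nondestabilizing",
    "RarityReport",
]

#: Discoverability threshold ~ 1/Tm for all life over Earth's history.
PTH_GLOBAL = 1e-40
#: Effective threshold for multicellular eukaryotes (smaller populations,
#: longer generations).
PTH_EUKARYOTE = 1e-20


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_exponent(log10_value: float, convention: str = "round") -> int:
    """Integer power-of-ten exponent for a log10 value.

    ``round`` gives the nearest order of magnitude; ``floor`` gives the
    scientific-notation exponent (mantissa in [1, 10)).
    """
    if convention == "round":
        return _round_half_away(log10_value)
    if convention == "floor":
        return int(math.floor(log10_value))
    raise ValidationError(f"unknown exponent convention {convention!r}")


def boundary_from_tolerance(p_n0: float, ptol: float, n0: int,
                            p_min: float = PTH_GLOBAL,
                            rounding: str = "round") -> int:
    """Target boundary nb = log(p_min / P(n0)) / log(ptol) + n0.

    Extrapolates the survival probability geometrically from its value
    at n0, at the per-substitution tolerance ptol, down to the
    discoverability floor p_min (default 1e-40): the distance at which
    functional sequences become too rare for any search to find.
    Rounded to the nearest integer by default.
    """
    if not 0 < ptol < 1:
        raise ValidationError("ptol must be in (0, 1)")
    if not 0 < p_min < p_n0 <= 1:
        raise ValidationError("need 0 < p_min < P(n0) <= 1")
    x = math.log10(p_min / p_n0) / math.log10(ptol) + n0
    if rounding == "round":
        return _round_half_away(x)
    if rounding == "floor":
        return int(math.floor(x))
    if rounding == "ceil":
        return int(math.ceil(x))
    raise ValidationError(f"unknown rounding {rounding!r}")


def prob_functional_in_target(ptol: float, nb: int) -> float:
    """log10 of Pubt = ptol**nb, the functional fraction inside the target."""
    if nb < 0:
        raise ValidationError("nb must be >= 0")
    if not 0 < ptol <= 1:
        raise ValidationError("ptol must be in (0, 1]")
    return nb * math.log10(ptol)


def rarity_from_tolerance(ptol: float, L: int) -> float:
    """log10 of Pub = ptol**L: the whole-sequence tolerance bound.

    Used when no target can be defined; always weaker (larger) than the
    composite target estimate because it pretends the functional
    fraction outside the target equals that inside.
    """
    if not 0 < ptol <= 1:
        raise ValidationError("ptol must be in (0, 1]")
    return L * math.log10(ptol)


def tolerance_from_rarity(log10_pfs: float, L: int) -> float:
    """Invert the tolerance bound: effective Ptol (percent) from a rarity.

    Solves pfs = ptol**L for ptol, i.e. 10**(log10_pfs / L), expressed
    as a percentage rounded to the nearest whole percent.
    """
    if log10_pfs >= 0:
        raise ValidationError("log10_pfs must be negative")
    return float(_round_half_away(100.0 * 10.0 ** (log10_pfs / L)))


def rarity_from_nondestabilizing(pnd: float, L: int) -> float:
    """log10 of Pub = pnd**L, with Pnd standing proxy for Ptol.

    Justified by the tight coupling between destabilizing and
    deleterious mutations once a protein sits past its stability
    threshold.  Table outputs conventionally format this with the floor
    (scientific-notation) exponent.
    """
    if not 0 < pnd <= 1:
        raise ValidationError("pnd must be in (0, 1]")
    return L * math.log10(pnd)


@dataclass
class RarityReport:
    """Composite rarity estimate Pub = Pt * Pubt, with formatting metadata.

    ``log10_*`` fields are raw; ``exponent_*`` apply the declared
    convention.  The composite formatted exponent is the sum of the two
    component formatted exponents — order-of-magnitude chains multiply
    rounded powers of ten, so the composite must be consistent with its
    printed factors.
    """

    log10_pt: float
    log10_pubt: float
    nb_used: int
    ptol_used: float
    convention: str = "round"
    log10_pub: float = field(init=False)
    exponent_pt: int = field(init=False)
    exponent_pubt: int = field(init=False)
    exponent_pub: int = field(init=False)

    def __post_init__(self):
        if self.log10_pt > 0 or self.log10_pubt > 0:
            raise ValidationError("log10 probabilities must be <= 0")
        self.log10_pub = self.log10_pt + self.log10_pubt
        self.exponent_pt = format_exponent(self.log10_pt, self.convention)
        self.exponent_pubt = format_exponent(self.log10_pubt, self.convention)
        self.exponent_pub = self.exponent_pt + self.exponent_pubt

    def to_dict(self) -> dict:
        return {
            "log10_pt": self.log10_pt,
            "log10_pubt": self.log10_pubt,
            "log10_pub": self.log10_pub,
            "exponent_pt": self.exponent_pt,
            "exponent_pubt": self.exponent_pubt,
            "exponent_pub": self.exponent_pub,
            "nb_used": self.nb_used,
            "ptol_used": self.ptol_used,
            "convention": self.convention,
        }

    def summary(self) -> str:
        return "\n".join([
            "Composite rarity estimate",
            "-" * 40,
            f"target boundary nb       {self.nb_used}",
            f"Ptol                     {self.ptol_used:.4g}",
            f"Pt    = 10^{self.exponent_pt}   (raw log10 {self.log10_pt:.2f})",
            f"Pubt  = 10^{self.exponent_pubt}   (raw log10 {self.log10_pubt:.2f})",
            f"Pub   = 10^{self.exponent_pub}  (raw log10 {self.log10_pub:.2f})",
        ])


def composite_rarity(log10_pt: float, log10_pubt: float, nb: int,
                     ptol: float, convention: str = "round") -> RarityReport:
    """Combine Pt and Pubt into the global upper bound Pub = Pt * Pubt."""
    return RarityReport(log10_pt=log10_pt, log10_pubt=log10_pubt,
                        nb_used=nb, ptol_used=ptol, convention=convention)
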