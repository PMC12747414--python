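"""Discovery time and probability for undirected searches of sequence space.

The expected number of trials for a random search to first enter a
target of fractional size c around a length-L protein grows
exponentially with L, d = A * B**L, with constants fitted to search
simulations for the two calibrated target sizes:

    c = 1/3:  d = 2.21 * 3.25**L
    c = 1/2:  d = 5.36 * 1.56**L

Given a trial budget Tm (~1e38 distinct gene variants over Earth's
history), the success probability is Pdt = 1 - exp(-Tm/d).  The
multi-target generalization d_m = (1/m) * exp(6L(3/4 - c)^2) inverts to
the smallest discoverable target size

    c_min = 3/4 - sqrt(ln(m*d) / (6L)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError

__all__ = [
    "SearchConstants",
    "DiscoveryConstants",
    "DISCOVERY_PRESETS",
    "discovery_time",
    "discovery_probability",
    "multi_target_time",
    "minimum_discoverable_target",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class SearchConstants:
    """Search-budget constants: Tm trials, threshold Pth, m targets."""

    t_m: float = 1e38
    p_th: float = 1e-40
    m: int = 1

    def __post_init__(self):
        if self.t_m <= 0:
            raise ValidationError("t_m must be positive")
        if not 0 < self.p_th < 1:
            raise ValidationError("p_th must be in (0, 1)")
        if self.m < 1:
            raise ValidationError("m must be >= 1")


@dataclass(frozen=True)
class DiscoveryConstants:
    """Coefficient and base of d = a * b**L for one target-size class."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 1:
            raise ValidationError("need a > 0 and b > 1")


DISCOVERY_PRESETS = {
    "one_third": DiscoveryConstants(a=2.21, b=3.25),
    "one_half": DiscoveryConstants(a=5.36, b=1.56),
}


def _constants(c_class) -> DiscoveryConstants:
    if isinstance(c_class, DiscoveryConstants):
        return c_class
    try:
        return DISCOVERY_PRESETS[c_class]
    except KeyError:
        raise ValidationError(
            f"unknown target class {c_class!r}; use 'one_third', 'one_half' "
            "or a DiscoveryConstants instance") from None


def discovery_time(L: int, c_class="one_third") -> float:
    """log10 of the expected trials d = A * B**L to discover the target."""
    if L < 0:
        raise ValidationError("L must be >= 0")
    k = _constants(c_class)
    return math.log10(k.a) + L * math.log10(k.b)


def discovery_probability(d_log10: float,
                          constants: SearchConstants = SearchConstants()
                          ) -> float:
    """log10 of Pdt = 1 - exp(-Tm/d), evaluated stably.

    For Tm << d the probability is Tm/d to first order, so the log is
    computed directly in log space (no underflow for d up to any size);
    for Tm >> d the probability saturates at 1 (log10 -> 0).
    """
    if not math.isfinite(d_log10):
        raise ValidationError("d_log10 must be finite")
    log10_x = math.log10(constants.t_m) - d_log10  # x = Tm / d
    if log10_x < -8:
        # 1 - e^-x = x (1 - x/2 + ...); correction below double precision
        return log10_x
    x = 10.0 ** log10_x
    if x > 745.0:  # exp(-x) underflows; probability is exactly 1.0
        return 0.0
    return math.log10(-math.expm1(-x))


def multi_target_time(L: int, c: float, m: int = 1) -> float:
    """log10 of d_m = (1/m) * exp(6 L (3/4 - c)^2), m same-size targets."""
    if L < 1:
        raise ValidationError("L must be >= 1")
    if not 0 < c < 0.75:
        raise ValidationError(
            "c must be in (0, 3/4): at c >= 3/4 the target covers typical "
            "sequences and the search is trivial")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return 6.0 * L * (0.75 - c) ** 2 / LN10 - math.log10(m)


def minimum_discoverable_target(L: int, d_max_log10: float,
                                m: float = 1) -> float:
    """Smallest discoverable target fraction c_min, in whole percent.

    c_min = 3/4 - sqrt(ln(m * 10**d_max) / (6L)); a search limited to
    d_max trials cannot find targets smaller than this.
    """
    if L < 1:
        raise ValidationError("L must be >= 1")
    if m < 1:
        raise ValidationError("m must be >= 1")
    ln_md = d_max_log10 * LN10 + math.log(m)
    if ln_md < 0:
        raise ValidationError("m * d must be >= 1")
    arg = ln_md / (6.0 * L)
    if arg > 0.75 ** 2:
        raise ValidationError(
            "search budget exceeds what any target in (0, 3/4) requires; "
            "c_min would be negative")
    c_min = 0.75 - math.sqrt(arg)
    return float(math.floor(100.0 * c_min + 0.5))
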