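"""Combinatorics of amino-acid sequence space.

A protein of length L lives in a space of 20**L sequences.  The number of
sequences at Hamming distance exactly n from a reference is
C(L, n) * 19**n (choose the positions, then any of the 19 alternative
residues at each).  Combining these counts with a fitted survival model
P(n) gives the density of functional sequences over distance,

    PDF(n) = P(n) * Nseq(n) / NFS,

and summing the counts out to a boundary radius nb gives the probability
that a uniformly random sequence falls inside the target region,

    Pt = sum_{n=0}^{nb} C(L, n) 19**n / 20**L.

Counts are kept exact (Python integers) where feasible and in log10
space everywhere else; probabilities this small (10**-70 and beyond)
never exist as floats on the linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .exceptions import ValidationError

__all__ = [
    "count_sequences_at_distance",
    "log10_sequences_at_distance",
    "FunctionalDensity",
    "functional_density",
    "prob_in_target",
    "TargetRegion",
    "target_from_fraction",
    "fsh_map_data",
    "CA_FROM_C",
]

LOG10_19 = math.log10(19.0)
LOG10_20 = math.log10(20.0)
LN10 = math.log(10.0)

#: Default mapping from nucleotide-space target fraction c to the
#: amino-acid-space fraction ca (supplementary calibration constants).
CA_FROM_C = {1 / 3: 0.57, 1 / 2: 0.77}


def count_sequences_at_distance(L: int, n: int) -> int:
    """Exact number of length-L sequences at Hamming distance n: C(L,n)*19^n."""
    if not 0 <= n <= L:
        raise ValidationError(f"need 0 <= n <= L, got n={n}, L={L}")
    return math.comb(L, n) * 19 ** n


def log10_sequences_at_distance(L: int, n) -> np.ndarray:
    """log10 of C(L,n)*19^n, vectorized over n via gammaln."""
    n = np.asarray(n, dtype=float)
    log_comb = gammaln(L + 1) - gammaln(n + 1) - gammaln(L - n + 1)
    return log_comb / LN10 + n * LOG10_19


@dataclass
class FunctionalDensity:
    """Distribution of functional sequences over Hamming distance n = 0..L.

    ``log10_weight[n]`` is log10(P(n) * Nseq(n)); ``pdf`` is that weight
    normalized to sum to one; ``log10_nfs`` is log10 of the implied total
    count of functional sequences, NFS.  The model P(n) is fit to data at
    small n only, so the far tail is qualitative — useful for comparing
    proteins, not for quantitative tail probabilities.
    """

    n: np.ndarray
    log10_weight: np.ndarray
    pdf: np.ndarray
    log10_nfs: float
    L: int
    alpha: float = math.nan
    beta: float = math.nan
    qualitative_tail: bool = True

    @property
    def mode(self) -> int:
        """Distance with the highest functional-sequence density."""
        return int(self.n[int(np.argmax(self.pdf))])

    def mass_between(self, lo: int, hi: int) -> float:
        """Total pdf mass on lo <= n <= hi (inclusive)."""
        sel = (self.n >= lo) & (self.n <= hi)
        return float(self.pdf[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n, "pdf": self.pdf,
                             "log10_weight": self.log10_weight})


def functional_density(fit, L: int) -> FunctionalDensity:
    """Build PDF(n) over n = 0..L from a fitted survival model.

    ``fit`` is anything with ``alpha`` and ``beta`` attributes (a
    :class:`~prism_rarity.survival.HyperExpResults` or equivalent).  All
    arithmetic happens in log10 space, so arbitrarily long proteins are
    overflow-free.
    """
    if L < 1:
        raise ValidationError("L must be a positive integer")
    alpha, beta = float(fit.alpha), float(fit.beta)
    n = np.arange(L + 1)
    log10_pn = (-alpha * n - beta * n.astype(float) ** 2) / LN10
    w = log10_pn + log10_sequences_at_distance(L, n)
    log10_nfs = float(logsumexp(w * LN10) / LN10)
    pdf = np.exp((w - log10_nfs) * LN10)
    pdf = pdf / pdf.sum()  # remove residual float error
    return FunctionalDensity(n=n, log10_weight=w, pdf=pdf,
                             log10_nfs=log10_nfs, L=L,
                             alpha=alpha, beta=beta)


def prob_in_target(L: int, nb: int, mode: str = "exact") -> float:
    """log10 probability that a random length-L sequence is within nb.

    ``mode='exact'`` sums C(L,n)*19^n as exact integers and takes one
    log10 at the end; ``mode='log'`` uses log-sum-exp throughout.  The
    two agree to ~1e-9 and the exact path is the reference.
    Returns 0.0 at nb = L (the sum is the binomial expansion of 20^L).
    """
    if not 0 <= nb <= L:
        raise ValidationError(f"need 0 <= nb <= L, got nb={nb}, L={L}")
    if mode == "exact":
        total = 0
        term = 1  # C(L,0)*19^0
        for n in range(nb + 1):
            total += term
            term = term * (L - n) * 19 // (n + 1)
        return math.log10(total) - L * LOG10_20
    if mode == "log":
        n = np.arange(nb + 1)
        w = log10_sequences_at_distance(L, n) * LN10
        return float(logsumexp(w) / LN10 - L * LOG10_20)
    raise ValidationError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class TargetRegion:
    """A target: the neighborhood of the wildtype holding the functional set.

    ``c`` is the maximum differing fraction in nucleotide space, ``ca``
    its amino-acid-space equivalent, ``nb`` the boundary radius in
    substitutions, and ``L`` the protein length.
    """

    c: Optional[float]
    ca: float
    nb: int
    L: int
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.nb <= self.L:
            raise ValidationError(f"nb={self.nb} outside [0, L={self.L}]")


def target_from_fraction(L: int, c: Optional[float] = None,
                         ca: Optional[float] = None,
                         rounding: str = "floor",
                         ca_map: Optional[dict] = None) -> TargetRegion:
    """Convert a target fraction into a boundary radius nb.

    Give either the nucleotide-space fraction ``c`` (mapped to amino-acid
    space through the calibrated constants, by default 1/3 -> 0.57 and
    1/2 -> 0.77) or the amino-acid fraction ``ca`` directly.  ``nb`` is
    floor(ca*L) by default; ``rounding='round'`` rounds to nearest.
    """
    if ca is None:
        if c is None:
            raise ValidationError("give either c or ca")
        table = CA_FROM_C if ca_map is None else ca_map
        for key, val in table.items():
            if math.isclose(c, key, rel_tol=1e-9):
                ca = val
                break
        else:
            raise ValidationError(
                f"no amino-acid-space mapping configured for c={c}; "
                "pass ca explicitly")
    if not 0 < ca <= 1:
        raise ValidationError("ca must be in (0, 1]")
    x = ca * L
    if rounding == "floor":
        nb = math.floor(x)
    elif rounding == "round":
        nb = math.floor(x + 0.5)
    else:
        raise ValidationError(f"unknown rounding {rounding!r}")
    label = "" if c is None else f"c={c:.3g}"
    return TargetRegion(c=c, ca=ca, nb=min(nb, L), L=L, label=label)


def fsh_map_data(density: FunctionalDensity,
                 boundaries: Iterable[TargetRegion] = ()
                 ) -> Tuple[pd.DataFrame, List[dict]]:
    """Data behind a functional-sequence-heat map.

    The FSH map draws sequence space as a radial plot centred on the
    wildtype: radius = n, shade proportional to PDF(n), with target
    boundaries as rings.  This returns the (n, pdf, log10_weight) table
    and a list of boundary descriptors; rendering is left to
    :mod:`prism_rarity.plotting`.
    """
    table = density.to_frame()
    rings = [{"radius": b.nb, "label": b.label or f"ca={b.ca:.2f}",
              "c": b.c, "ca": b.ca} for b in boundaries]
    return table, rings
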