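"""Stability-change (ddG) distributions and non-destabilizing fractions.

Mutational ddG distributions of globular proteins are well described by
a two-component Gaussian mixture (a narrow near-neutral component plus
a broad destabilizing one), in kcal/mol with positive values
destabilizing.  The fraction of mutations that do not destabilize the
protein past a cutoff Gth,

    Pnd = F(Gth) = w * Phi((Gth - mu1)/s1) + (1 - w) * Phi((Gth - mu2)/s2),

serves as a proxy for the tolerated-mutation fraction Ptol in the
whole-sequence rarity bound Pub = Pnd**L.  Gth itself can be calibrated
from a benchmark protein by inverting the mixture CDF at a known Ptol
(the standard calibration lands near 0.5 kcal/mol); 0.5 and 1.0
kcal/mol are the conventional cutoff presets.

Empirical tables of per-mutation ddG records (one row per measurement,
FireProtDB-style) yield per-protein Pnd as the fraction of entries
strictly below the cutoff, with a minimum-record filter (default 30)
to exclude poorly sampled proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import NumericError, ValidationError

__all__ = [
    "BiGaussian",
    "DdgTable",
    "read_ddg_csv",
    "nondestabilizing_fraction_empirical",
    "GTH_PRESETS",
]

#: Conventional destabilization cutoffs (kcal/mol).
GTH_PRESETS = (0.5, 1.0)


@dataclass(frozen=True)
class BiGaussian:
    """Two-component Gaussian mixture for a ddG distribution (kcal/mol).

    ``w`` weights the first component; means ``mu1``/``mu2`` and widths
    ``s1``/``s2`` are in kcal/mol, positive ddG = destabilizing.
    """

    w: float
    mu1: float
    s1: float
    mu2: float = 0.0
    s2: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValidationError("w must be in [0, 1]")
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValidationError("component widths must be > 0")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = (self.w * norm.pdf(x, self.mu1, self.s1)
               + (1 - self.w) * norm.pdf(x, self.mu2, self.s2))
        return out if out.ndim else float(out)

    def cdf(self, x) -> float:
        """Mixture CDF: probability a mutation's ddG falls below x."""
        x = np.asarray(x, dtype=float)
        out = (self.w * norm.cdf(x, self.mu1, self.s1)
               + (1 - self.w) * norm.cdf(x, self.mu2, self.s2))
        return out if out.ndim else float(out)

    def quantile(self, p: float, xtol: float = 1e-6) -> float:
        """Inverse CDF by monotone root finding, to ``xtol`` kcal/mol.

        Calibrates the destabilization threshold: the ptol-quantile of a
        benchmark protein's mixture is the Gth at which the tolerated
        fraction equals ptol.
        """
        if not 0 < p < 1:
            raise ValidationError("p must be in (0, 1)")
        lo = min(self.mu1 - 12 * self.s1, self.mu2 - 12 * self.s2)
        hi = max(self.mu1 + 12 * self.s1, self.mu2 + 12 * self.s2)
        try:
            return float(brentq(lambda x: self.cdf(x) - p, lo, hi,
                                xtol=xtol, maxiter=200))
        except (RuntimeError, ValueError) as exc:
            raise NumericError(f"quantile inversion failed: {exc}") from exc

    def nondestabilizing_fraction(self, g_th: float = 0.5) -> float:
        """Pnd under the mixture: CDF at the cutoff Gth (kcal/mol)."""
        return float(self.cdf(g_th))

    def mean(self) -> float:
        return self.w * self.mu1 + (1 - self.w) * self.mu2

    def to_dict(self) -> dict:
        return {"w": self.w, "mu1": self.mu1, "s1": self.s1,
                "mu2": self.mu2, "s2": self.s2}


class DdgTable:
    """Per-mutation ddG records, one row per measurement.

    Backed by a DataFrame with columns ``protein`` and ``ddg``
    (kcal/mol, positive destabilizing) plus optional annotations
    (position, wt, mut).  Duplicate measurements of the same mutation
    are kept as separate entries by default; ``dedup_mean()`` collapses
    them to their mean when position/wt/mut are present.
    """

    REQUIRED = ("protein", "ddg")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"ddG table missing columns: {missing}")
        ddg = pd.to_numeric(frame["ddg"], errors="coerce")
        bad = frame.index[~np.isfinite(ddg)].tolist()
        if bad:
            raise ValidationError(f"non-finite ddG values at rows {bad}")
        self.frame = frame.assign(ddg=ddg).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def proteins(self) -> List[str]:
        return sorted(self.frame["protein"].unique())

    def dedup_mean(self) -> "DdgTable":
        keys = [c for c in ("protein", "position", "wt", "mut")
                if c in self.frame.columns]
        if len(keys) < 2:
            raise ValidationError(
                "deduplication needs mutation annotations (position/wt/mut)")
        out = (self.frame.groupby(keys, as_index=False)["ddg"].mean())
        return DdgTable(out)


def read_ddg_csv(path) -> DdgTable:
    """Load a ddG CSV with header ``protein,ddg[,position,wt,mut]``."""
    frame = pd.read_csv(path, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return DdgTable(frame)


def nondestabilizing_fraction_empirical(
        table: DdgTable, g_th: float = 0.5, min_records: int = 30
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-protein Pnd: fraction of ddG entries strictly below the cutoff.

    Proteins with fewer than ``min_records`` entries are excluded and
    returned separately.  Ties exactly at the cutoff count as
    destabilizing.  Returns (results frame with columns protein,
    n_records, pnd; list of excluded protein ids).
    """
    if len(table) == 0:
        warnings.warn("empty ddG table: no proteins to evaluate", stacklevel=2)
        return (pd.DataFrame(columns=["protein", "n_records", "pnd"]), [])
    rows, excluded = [], []
    for protein, grp in table.frame.groupby("protein", sort=True):
        if len(grp) < min_records:
            excluded.append(str(protein))
            continue
        pnd = float((grp["ddg"] < g_th).mean())
        rows.append({"protein": str(protein), "n_records": len(grp),
                     "pnd": pnd})
    result = pd.DataFrame(rows, columns=["protein", "n_records", "pnd"])
    return result, excluded
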