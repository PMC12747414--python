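"""Seeded generators for synthetic survival curves and ddG samples.

These emulate the two data shapes the estimators consume, with known
ground truth, so every fit and fraction estimate can be validated
end-to-end without external data:

* mutational-survival curves — per-n functional counts drawn
  Binomial(clones, P(n)) under the hyper-exponential model, optionally
  with the per-clone mutation count drawn Poisson(lambda * round) to
  mimic rounds of mutagenic drift;
* ddG samples — draws from a two-component Gaussian mixture.

A single experiment seed expands into independent per-generator streams
through ``numpy.random.SeedSequence`` spawn keys, so adding a generator
never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .stability import BiGaussian, DdgTable
from .survival import SurvivalCurve, survival_probability

__all__ = [
    "SimulationDesign",
    "simulate_survival_curve",
    "simulate_ddg_sample",
    "SYNTHETIC_PROFILES",
]

# stream ids for seed expansion; append-only
_STREAM_SURVIVAL = 0
_STREAM_DDG = 1
_STREAM_POISSON = 2

#: Synthetic benchmark profiles (alpha, beta, L) mimicking the three
#: published epistatic-protein fits; for tests and demos only.
SYNTHETIC_PROFILES = {
    "beta_lactamase_like": {"alpha": 0.104, "beta": 0.019, "L": 263},
    "gfp_like": {"alpha": -0.047, "beta": 0.054, "L": 238},
    "hisa_like": {"alpha": 0.096, "beta": 0.039, "L": 254},
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class SimulationDesign:
    """Design of a synthetic mutagenesis experiment.

    ``clones_per_n`` clones are assayed at each n in ``n_range``
    (inclusive).  Defaults mirror the deepest published design: n = 0..14
    with on the order of a thousand clones per mutational load.
    """

    alpha_true: float
    beta_true: float
    n_range: Tuple[int, int] = (0, 14)
    clones_per_n: int = 1000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.n_range
        if lo < 0 or hi < lo:
            raise ValidationError("n_range must satisfy 0 <= lo <= hi")
        if self.clones_per_n < 1:
            raise ValidationError("clones_per_n must be >= 1")


def simulate_survival_curve(design: SimulationDesign) -> SurvivalCurve:
    """Draw a survival curve: functional ~ Binomial(clones, P(n)) per n."""
    rng = _rng(design.seed, _STREAM_SURVIVAL)
    lo, hi = design.n_range
    ns = np.arange(lo, hi + 1)
    p = survival_probability(design.alpha_true, design.beta_true, ns)
    p = np.clip(p, 0.0, 1.0)
    func = rng.binomial(design.clones_per_n, p)
    return SurvivalCurve.from_counts(
        ns.tolist(), func.tolist(), [design.clones_per_n] * len(ns),
        label=f"synthetic(alpha={design.alpha_true}, beta={design.beta_true})")


def simulate_drift_rounds(design: SimulationDesign, lam: float,
                          rounds: int, clones_per_round: int
                          ) -> SurvivalCurve:
    """Drift-style variant: each clone's n ~ Poisson(lam * round).

    Mimics rounds of mutagenesis without selection, where the mutation
    count per clone is itself random; clones are then scored
    Bernoulli(P(n)) and aggregated per observed n.
    """
    if lam <= 0 or rounds < 1 or clones_per_round < 1:
        raise ValidationError("need lam > 0, rounds >= 1, clones >= 1")
    rng = _rng(design.seed, _STREAM_POISSON)
    ns_all, ok_all = [], []
    for r in range(1, rounds + 1):
        n_clone = rng.poisson(lam * r, size=clones_per_round)
        p = np.clip(survival_probability(
            design.alpha_true, design.beta_true, n_clone), 0.0, 1.0)
        ok = rng.random(clones_per_round) < p
        ns_all.append(n_clone)
        ok_all.append(ok)
    ns_all = np.concatenate(ns_all)
    ok_all = np.concatenate(ok_all)
    grid = np.unique(ns_all)
    assayed = np.array([(ns_all == n).sum() for n in grid])
    func = np.array([ok_all[ns_all == n].sum() for n in grid])
    return SurvivalCurve.from_counts(grid.tolist(), func.tolist(),
                                     assayed.tolist(),
                                     label="synthetic drift rounds")


def simulate_ddg_sample(model: BiGaussian, n: int, seed: int = 0,
                        protein_id: str = "synthetic") -> DdgTable:
    """Draw n ddG values from the mixture into a single-protein table."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed, _STREAM_DDG)
    pick1 = rng.random(n) < model.w
    vals = np.where(pick1,
                    rng.normal(model.mu1, model.s1, size=n),
                    rng.normal(model.mu2, model.s2, size=n))
    frame = pd.DataFrame({"protein": protein_id, "ddg": vals})
    return DdgTable(frame)
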