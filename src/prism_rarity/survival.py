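"""Hyper-exponential modelling of mutational survival curves.

The central object is the probability ``P(n)`` that a protein remains
functional after ``n`` nonsynonymous amino-acid substitutions.  For
proteins whose accumulated mutations interact through prevalent negative
epistasis, ``P(n)`` is well described by a hyper-exponential decay

    P(n) = exp(-alpha * n - beta * n**2),

where ``alpha`` is the initial per-substitution decline and ``beta`` the
rate at which the decay accelerates — the strength of negative epistasis.
``beta > 0`` (significantly above its standard error) is the signature of
an epistatic protein and the gateway to the target-region rarity
pipeline; ``beta = 0`` recovers the ordinary exponential null model.

The module follows the Model/Results convention: build a
:class:`HyperExponentialModel` from a :class:`SurvivalCurve`, call
``fit()``, and work with the returned :class:`HyperExpResults`, which
carries the estimates, their one-standard-deviation errors from the fit
covariance, coefficients of determination for both the hyper-exponential
and the nested exponential model, and derived tolerance quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, NotFoundError, ValidationError

__all__ = [
    "SurvivalCurve",
    "HyperExponentialModel",
    "HyperExpResults",
    "survival_probability",
    "fit_response",
]


def survival_probability(alpha: float, beta: float, n) -> float:
    """Evaluate P(n) = exp(-alpha*n - beta*n**2).

    Accepts scalar or array ``n``; P(0) is exactly 1 for any parameters.
    """
    n = np.asarray(n, dtype=float)
    out = np.exp(-alpha * n - beta * n * n)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical P(n): proportion of clones still functional at each n.

    Parameters
    ----------
    n : sequence of int
        Nonsynonymous substitution counts, strictly increasing, >= 0.
    proportion : sequence of float
        Fraction functional at each n, in [0, 1].
    n_assayed, n_functional : optional sequences of int
        Raw clone counts; when present, ``proportion`` must equal
        ``n_functional / n_assayed`` exactly.
    """

    n: Tuple[int, ...]
    proportion: Tuple[float, ...]
    n_assayed: Optional[Tuple[int, ...]] = None
    n_functional: Optional[Tuple[int, ...]] = None
    label: str = ""

    def __post_init__(self):
        n = tuple(int(v) for v in self.n)
        prop = tuple(float(v) for v in self.proportion)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "proportion", prop)
        if len(n) != len(prop):
            raise ValidationError("n and proportion must have equal length")
        if any(v < 0 for v in n):
            raise ValidationError("substitution counts must be >= 0")
        if any(b <= a for a, b in zip(n, n[1:])):
            raise ValidationError("n values must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in prop):
            raise ValidationError("proportions must lie in [0, 1]")
        if (self.n_assayed is None) != (self.n_functional is None):
            raise ValidationError("assayed and functional counts go together")
        if self.n_assayed is not None:
            assayed = tuple(int(v) for v in self.n_assayed)
            func = tuple(int(v) for v in self.n_functional)
            object.__setattr__(self, "n_assayed", assayed)
            object.__setattr__(self, "n_functional", func)
            if len(assayed) != len(n) or len(func) != len(n):
                raise ValidationError("count columns must match curve length")
            if any(a <= 0 for a in assayed):
                raise ValidationError("n_assayed must be positive")
            if any(f < 0 or f > a for f, a in zip(func, assayed)):
                raise ValidationError("need 0 <= n_functional <= n_assayed")
            for i, (p, f, a) in enumerate(zip(prop, func, assayed)):
                if p != f / a:
                    raise ValidationError(
                        f"row {i}: proportion {p} != functional/assayed {f}/{a}"
                    )

    def __len__(self) -> int:
        return len(self.n)

    @classmethod
    def from_counts(cls, n: Sequence[int], n_functional: Sequence[int],
                    n_assayed: Sequence[int], label: str = "") -> "SurvivalCurve":
        prop = tuple(f / a for f, a in zip(n_functional, n_assayed))
        return cls(tuple(n), prop, tuple(n_assayed), tuple(n_functional), label)


def _hyper(n, alpha, beta):
    return np.exp(-alpha * n - beta * n * n)


def _expo(n, alpha):
    return np.exp(-alpha * n)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


class HyperExponentialModel:
    """Least-squares model for a mutational survival curve.

    Fits the hyper-exponential P(n) = exp(-alpha*n - beta*n**2) to the
    observed proportions on the linear scale, unweighted by default, and
    the nested exponential (beta = 0) alongside for comparison.

    Parameters
    ----------
    curve : SurvivalCurve
    max_n : int, optional
        Exclude points with n > max_n from the fit.
    drop_zeros : bool
        Drop rows with proportion exactly 0 (they are kept by default;
        the tail zeros inform the epistasis estimate).
    """

    def __init__(self, curve: SurvivalCurve, max_n: Optional[int] = None,
                 drop_zeros: bool = False):
        self.curve = curve
        mask = np.ones(len(curve), dtype=bool)
        n = np.asarray(curve.n, dtype=float)
        p = np.asarray(curve.proportion, dtype=float)
        if max_n is not None:
            mask &= n <= max_n
        if drop_zeros:
            mask &= p > 0
        self.endog = p[mask]
        self.exog = n[mask]
        self.n_assayed = (np.asarray(curve.n_assayed, dtype=float)[mask]
                          if curve.n_assayed is not None else None)
        if self.endog.size < 3:
            raise FitError(
                f"need at least 3 usable points to fit, have {self.endog.size}"
            )

    def fit(self, start: Tuple[float, float] = (0.1, 0.01),
            weighted: bool = False, log_scale: bool = False) -> "HyperExpResults":
        """Fit both models and return a results object.

        ``weighted`` uses the known binomial standard deviations
        sqrt(p(1-p)/m) from the clone counts as absolute errors, so the
        reported parameter sigmas are on the z (not residual-rescaled)
        scale; ``log_scale`` fits log P(n) instead of P(n).  Both default
        to off, matching the plain use of a generic curve-fitting routine
        on the linear scale.
        """
        n, p = self.exog, self.endog
        sigma = None
        absolute_sigma = False
        if weighted:
            if self.n_assayed is None:
                raise ValidationError("weighted fit requires clone counts")
            q = np.clip(p, 1e-6, 1 - 1e-6)
            sigma = np.sqrt(q * (1 - q) / self.n_assayed)
            absolute_sigma = True
        if log_scale:
            if np.any(p <= 0):
                raise ValidationError("log-scale fit requires proportions > 0")
            y = np.log(p)
            f2 = lambda x, a, b: -a * x - b * x * x  # noqa: E731
            f1 = lambda x, a: -a * x  # noqa: E731
        else:
            y, f2, f1 = p, _hyper, _expo

        def _try_fit(fun, p0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return curve_fit(fun, n, y, p0=p0, sigma=sigma,
                                 absolute_sigma=absolute_sigma, maxfev=20000)

        try:
            popt_e, pcov_e = _try_fit(f1, [start[0]])
        except RuntimeError as exc:
            raise FitError(f"exponential fit failed: {exc}") from exc
        try:
            popt_h, pcov_h = _try_fit(f2, list(start))
            # restart from the fitted exponential to honour model nesting
            popt_h2, pcov_h2 = _try_fit(f2, [popt_e[0], 0.0])
            sse = np.sum((y - f2(n, *popt_h)) ** 2)
            sse2 = np.sum((y - f2(n, *popt_h2)) ** 2)
            if sse2 < sse:
                popt_h, pcov_h = popt_h2, pcov_h2
        except RuntimeError as exc:
            raise FitError(f"hyper-exponential fit failed: {exc}",
                           last_iterate=tuple(start)) from exc

        r2_h = _r_squared(p, _hyper(n, *popt_h) if log_scale else f2(n, *popt_h))
        r2_e = _r_squared(p, _expo(n, *popt_e) if log_scale else f1(n, *popt_e))
        se_h = np.sqrt(np.clip(np.diag(pcov_h), 0, np.inf))
        se_e = math.sqrt(max(float(pcov_e[0, 0]), 0.0))
        return HyperExpResults(
            alpha=float(popt_h[0]), beta=float(popt_h[1]),
            sigma_alpha=float(se_h[0]), sigma_beta=float(se_h[1]),
            r2_hyper=r2_h, r2_exp=r2_e,
            alpha_exp=float(popt_e[0]), sigma_alpha_exp=se_e,
            model=self,
        )


@dataclass
class HyperExpResults:
    """Fitted hyper-exponential response with the nested exponential fit.

    Can also be constructed directly from published parameter values via
    :meth:`from_params` to drive downstream calculations.
    """

    alpha: float
    beta: float
    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0
    r2_hyper: float = math.nan
    r2_exp: float = math.nan
    alpha_exp: float = math.nan
    sigma_alpha_exp: float = math.nan
    model: Optional[HyperExponentialModel] = field(default=None, repr=False)

    def __post_init__(self):
        if self.sigma_alpha < 0 or self.sigma_beta < 0:
            raise ValidationError("parameter standard errors must be >= 0")

    @classmethod
    def from_params(cls, alpha: float, beta: float,
                    sigma_alpha: float = 0.0, sigma_beta: float = 0.0
                    ) -> "HyperExpResults":
        return cls(alpha=alpha, beta=beta,
                   sigma_alpha=sigma_alpha, sigma_beta=sigma_beta)

    # -- core quantities --------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    @property
    def bse(self) -> np.ndarray:
        """One-standard-deviation errors from the fit covariance."""
        return np.array([self.sigma_alpha, self.sigma_beta])

    def predict(self, n) -> float:
        """P(n) under the fitted model; 1 at n = 0."""
        return survival_probability(self.alpha, self.beta, n)

    def is_epistatic(self, k_sigma: float = 2.0) -> bool:
        """Whether beta clears ``k_sigma`` standard errors above zero.

        With no error estimate available, any beta > 0 counts.
        """
        if self.sigma_beta == 0.0:
            return self.beta > 0.0
        return self.beta >= k_sigma * self.sigma_beta

    def tolerated_ratio(self, n: int) -> float:
        """Model ratio P(n+1)/P(n) = exp(-alpha - beta*(2n+1)).

        This is the fraction of additional mutations tolerated at
        mutational load n.  A ratio >= 1 means the model is not in a
        negative-epistasis regime at this n; the value is still returned
        but a warning is issued.
        """
        ratio = math.exp(-self.alpha - self.beta * (2 * n + 1))
        if ratio >= 1.0:
            warnings.warn(
                f"P({n + 1})/P({n}) = {ratio:.3f} >= 1: no negative-epistasis "
                "regime at this n", stacklevel=2)
        return ratio

    def select_reference_n(self, target_ptol: float, n_max: int = 1000,
                           atol: float = 0.1) -> int:
        """Smallest n where P(n+1)/P(n) first approximates ``target_ptol``.

        Scans n upward to the first sign change of (ratio - target) and
        returns whichever of the bracketing pair {n, n+1} deviates least.
        Requires beta > 0 (otherwise the ratio never moves).
        """
        if self.beta <= 0:
            raise ValidationError("select_reference_n requires beta > 0")
        ratios = [self.tolerated_ratio(k) for k in range(n_max + 2)]
        for k in range(n_max + 1):
            if (ratios[k] - target_ptol) * (ratios[k + 1] - target_ptol) <= 0:
                pick = min((k, k + 1),
                           key=lambda j: abs(ratios[j] - target_ptol))
                if abs(ratios[pick] - target_ptol) <= atol:
                    return pick
                break
        raise NotFoundError(
            f"no n in [0, {n_max}] brings P(n+1)/P(n) within {atol} of "
            f"{target_ptol}")

    # -- reporting --------------------------------------------------------

    def to_dict(self, k_sigma: float = 2.0) -> dict:
        def _num(x):
            return None if not math.isfinite(x) else x
        return {
            "alpha": self.alpha, "beta": self.beta,
            "sigma_alpha": self.sigma_alpha, "sigma_beta": self.sigma_beta,
            "r2_hyper": _num(self.r2_hyper), "r2_exp": _num(self.r2_exp),
            "epistatic": self.is_epistatic(k_sigma),
        }

    def summary(self) -> str:
        lines = [
            "Hyper-exponential survival model  P(n) = exp(-a*n - b*n^2)",
            "-" * 58,
            f"alpha  {self.alpha:12.5f}   +/- {self.sigma_alpha:.5f}",
            f"beta   {self.beta:12.5f}   +/- {self.sigma_beta:.5f}",
            f"R^2 (hyper-exponential)  {self.r2_hyper:8.4f}",
            f"R^2 (exponential null)   {self.r2_exp:8.4f}",
            f"epistatic (beta >= 2*sigma_beta): {self.is_epistatic()}",
        ]
        return "\n".join(lines)


def fit_response(curve: SurvivalCurve, max_n: Optional[int] = None,
                 **fit_kwargs) -> HyperExpResults:
    """Convenience wrapper: build the model and fit in one call."""
    return HyperExponentialModel(curve, max_n=max_n).fit(**fit_kwargs)
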