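"""Evidence routing and the end-to-end epistatic-target pipeline.

A protein's rarity is estimated by whichever method its evidence
supports, chosen by a fixed decision tree:

1. low functional specificity  -> direct library screening (advisory:
   measure Pfs directly; nothing to compute here);
2. high specificity, P(n) known and epistatic (beta significantly
   above zero) -> the three-step target pipeline;
3. high specificity, no usable P(n) but Ptol known -> whole-sequence
   tolerance bound Pub = Ptol**L;
4. otherwise, ddG data available -> stability proxy Pub = Pnd**L.

The epistatic pipeline chains: fit P(n) and build the functional
density; extrapolate the target boundary nb from the tolerance and
clamp it outward to the calibrated c = 1/3 (or, failing that, c = 1/2)
boundary; compute Pt, the discovery time d and probability Pdt; and
close with Pubt = Ptol**nb and the composite Pub = Pt * Pubt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from . import discovery as disc
from . import rarity as rar
from . import seqspace as seq
from .exceptions import RoutingError, ValidationError
from .seqspace import FunctionalDensity, TargetRegion
from .stability import BiGaussian, DdgTable
from .survival import HyperExpResults, SurvivalCurve, fit_response

__all__ = [
    "EvidenceProfile",
    "MethodRoute",
    "PipelineConfig",
    "EpistaticPipelineResult",
    "route_method",
    "run_epistatic_pipeline",
]

#: Benchmark substitution values from the calibration standard: a
#: well-characterized, low-complexity-function enzyme whose tolerance
#: and stability cutoff anchor other proteins' estimates.
BENCHMARK_PTOL = 1 / 3
BENCHMARK_GTH = 0.5  # kcal/mol


@dataclass
class EvidenceProfile:
    """What is known about a protein, for routing and the pipeline."""

    L: int
    specificity: str = "high"  # "low" | "high"
    curve: Optional[SurvivalCurve] = None
    fit: Optional[HyperExpResults] = None
    epistatic: Optional[bool] = None  # asserted; else derived from fit
    ptol: Optional[float] = None
    n0: Optional[int] = None
    p_n0: Optional[float] = None
    ddg_table: Optional[DdgTable] = None
    ddg_model: Optional[BiGaussian] = None
    name: str = ""

    def __post_init__(self):
        if self.L < 1:
            raise ValidationError("L must be a positive integer")
        if self.specificity not in ("low", "high"):
            raise ValidationError("specificity must be 'low' or 'high'")
        if self.epistatic is not None and not self.has_pn:
            raise ValidationError(
                "an epistasis assertion is only meaningful with P(n) data")

    @property
    def has_pn(self) -> bool:
        return self.curve is not None or self.fit is not None

    @property
    def has_ptol(self) -> bool:
        return self.ptol is not None

    @property
    def has_ddg(self) -> bool:
        return self.ddg_table is not None or self.ddg_model is not None

    def resolve_fit(self, k_sigma: float = 2.0) -> Optional[HyperExpResults]:
        if self.fit is None and self.curve is not None:
            self.fit = fit_response(self.curve)
        return self.fit

    def is_epistatic(self, k_sigma: float = 2.0) -> bool:
        if self.epistatic is not None:
            return self.epistatic
        fit = self.resolve_fit(k_sigma)
        return fit is not None and fit.is_epistatic(k_sigma)


@dataclass(frozen=True)
class MethodRoute:
    """The selected estimation method and why."""

    method: str  # direct_library | epistatic_target | ptol_only | ddg_proxy
    rationale: str


def route_method(profile: EvidenceProfile, k_sigma: float = 2.0
                 ) -> MethodRoute:
    """Route an evidence profile to its rarity-estimation method."""
    if profile.specificity == "low":
        return MethodRoute(
            "direct_library",
            "low-specificity function: screen a random library and measure "
            "the functional fraction directly; no statistical bound needed")
    if profile.has_pn and profile.is_epistatic(k_sigma):
        return MethodRoute(
            "epistatic_target",
            "P(n) available with significant negative epistasis: the "
            "functional set is confined to a target region")
    if profile.has_ptol:
        why = ("P(n) unavailable" if not profile.has_pn
               else "P(n) shows no significant negative epistasis")
        return MethodRoute(
            "ptol_only",
            f"{why}; tolerated-mutation fraction known, use Pub = Ptol^L")
    if profile.has_ddg:
        return MethodRoute(
            "ddg_proxy",
            "no P(n) target or Ptol; use the non-destabilizing fraction "
            "from ddG data as a tolerance proxy, Pub = Pnd^L")
    raise RoutingError(
        "high-specificity protein with no usable evidence channel: supply "
        "a survival curve, a tolerated-mutation fraction, or ddG data")


@dataclass(frozen=True)
class PipelineConfig:
    """Conventions and constants for the epistatic pipeline."""

    p_min: float = rar.PTH_GLOBAL
    t_m: float = 1e38
    convention: str = "round"  # exponent formatting
    nb_rounding: str = "round"  # Eq-3 boundary rounding
    target_rounding: str = "floor"  # ca*L -> nb conversion
    ca_map: Optional[dict] = None
    k_sigma: float = 2.0


@dataclass
class EpistaticPipelineResult:
    """All intermediates and outputs of the three-step pipeline."""

    profile_name: str
    L: int
    fit: Optional[HyperExpResults]
    density: Optional[FunctionalDensity]
    ptol: float
    n0: int
    p_n0: float
    nb_raw: int
    target: TargetRegion
    clamped: bool
    log10_pt: float
    log10_d: Optional[float]
    log10_pdt: Optional[float]
    report: rar.RarityReport
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "protein": self.profile_name,
            "L": self.L,
            "ptol": self.ptol,
            "n0": self.n0,
            "p_n0": self.p_n0,
            "nb_raw": self.nb_raw,
            "nb_used": self.target.nb,
            "target_c": self.target.c,
            "target_ca": self.target.ca,
            "clamped": self.clamped,
            "log10_pt": self.log10_pt,
            "log10_d": self.log10_d,
            "log10_pdt": self.log10_pdt,
            "warnings": list(self.warnings),
        }
        out.update(self.report.to_dict())
        if self.fit is not None:
            out["fit"] = self.fit.to_dict()
        return out


def run_epistatic_pipeline(profile: EvidenceProfile,
                           config: PipelineConfig = PipelineConfig()
                           ) -> EpistaticPipelineResult:
    """Run the three-step target pipeline on an epistatic protein.

    Tolerance inputs resolve in order of preference: explicit
    (ptol, n0, p_n0) on the profile; else n0 from the model ratio scan
    at the benchmark tolerance and ptol/p_n0 from the fit.
    """
    route = route_method(profile, config.k_sigma)
    if route.method != "epistatic_target":
        raise RoutingError(
            f"profile routes to {route.method}, not the epistatic pipeline")

    notes: List[str] = []
    fit = profile.resolve_fit(config.k_sigma)

    # step 1 — functional-sequence density over Hamming distance
    density = seq.functional_density(fit, profile.L) if fit else None

    # resolve (ptol, n0, p_n0)
    n0 = profile.n0
    if n0 is None:
        if fit is None:
            raise ValidationError("need either n0 or a fitted model")
        n0 = fit.select_reference_n(profile.ptol or BENCHMARK_PTOL)
        notes.append(f"n0={n0} chosen where the model ratio first "
                     "approximates the target tolerance")
    ptol = profile.ptol
    if ptol is None:
        ptol = fit.tolerated_ratio(n0)
        notes.append(f"ptol={ptol:.4f} from the model ratio P(n0+1)/P(n0)")
    p_n0 = profile.p_n0
    if p_n0 is None:
        if fit is None:
            raise ValidationError("need either p_n0 or a fitted model")
        p_n0 = float(fit.predict(n0))

    # step 2 — boundary, clamped outward to a calibrated target
    nb_raw = rar.boundary_from_tolerance(p_n0, ptol, n0, p_min=config.p_min,
                                         rounding=config.nb_rounding)
    third = seq.target_from_fraction(profile.L, c=1 / 3,
                                     rounding=config.target_rounding,
                                     ca_map=config.ca_map)
    half = seq.target_from_fraction(profile.L, c=1 / 2,
                                    rounding=config.target_rounding,
                                    ca_map=config.ca_map)
    if nb_raw <= third.nb:
        target, clamped, c_class = third, True, "one_third"
    elif nb_raw <= half.nb:
        target, clamped, c_class = half, True, "one_half"
        notes.append("nb exceeds the c=1/3 boundary; clamped to c=1/2")
    else:
        target = TargetRegion(c=None, ca=nb_raw / profile.L,
                              nb=min(nb_raw, profile.L), L=profile.L,
                              label="nb (unclamped)")
        clamped, c_class = False, None
        notes.append("nb exceeds the c=1/2 boundary; used directly — "
                     "requires high confidence in beta and ptol")

    log10_pt = seq.prob_in_target(profile.L, target.nb)
    if c_class is not None:
        log10_d = disc.discovery_time(profile.L, c_class)
        log10_pdt = disc.discovery_probability(
            log10_d, disc.SearchConstants(t_m=config.t_m))
    else:
        log10_d = log10_pdt = None
        notes.append("no discovery-time constants for a custom boundary")

    # step 3 — functional fraction in target and composite rarity
    log10_pubt = rar.prob_functional_in_target(ptol, target.nb)
    report = rar.composite_rarity(log10_pt, log10_pubt, target.nb, ptol,
                                  convention=config.convention)

    return EpistaticPipelineResult(
        profile_name=profile.name, L=profile.L, fit=fit, density=density,
        ptol=ptol, n0=n0, p_n0=p_n0, nb_raw=nb_raw, target=target,
        clamped=clamped, log10_pt=log10_pt, log10_d=log10_d,
        log10_pdt=log10_pdt, report=report, warnings=notes)
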