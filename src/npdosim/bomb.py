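"""The Bomb model of nanoparticle radiosensitization.

A phenomenological model in which each NP ionization acts like a bomb:
it kills the host cell with probability p1 if the NP sits outside the
nucleus and p2 if inside, regardless of mechanism. With N1 NPs outside
and N2 inside, and p1Gy expected ionizations per NP per Gy, the extra
lethal events per Gy are a pure increase in the linear term of the
linear-quadratic (LQ) survival model:

    delta_alpha = p1Gy * (N1 * p1 + N2 * p2)

Inverting this for p1 (with N2 = 0, as NPs are not observed inside
nuclei) turns published alpha values with and without NPs into a
per-ionization kill probability. Survival follows the LQ model
SF = exp(-alpha D - beta D^2), and the RBE at a dose D_NP is the ratio
D / D_NP where the NP-free dose D produces the same LQ effect as D_NP
with NPs. Because p1 <= 1, measured NP uptake bounds the achievable
delta_alpha — an inferred p1 > 1 signals data or simulation
inconsistency and is flagged, not clipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import constants

__all__ = [
    "LQParams",
    "BombParams",
    "delta_alpha_bomb",
    "infer_p1",
    "sf_lq",
    "rbe_lq",
    "predict_scaling",
    "BombModel",
    "BombResults",
]


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic survival parameters (alpha in Gy^-1, beta in Gy^-2).

    A negative fitted alpha (one published value is -0.05) may be stored,
    but RBE operations refuse it.
    """

    alpha: float
    beta: float
    alpha_sigma: float | None = None

    def effect(self, dose_gy: float) -> float:
        """LQ exponent alpha*D + beta*D^2 at dose D."""
        return self.alpha * dose_gy + self.beta * dose_gy**2


@dataclass(frozen=True)
class BombParams:
    """Bomb-model parameter set.

    N1/N2 are NP counts outside/inside the nucleus; p1/p2 the matching
    per-ionization kill probabilities. An inferred p1 > 1 is stored as-is
    (``p1_valid`` flags it) — it indicates inconsistent input data, not a
    probability to clip.
    """

    n1: float
    p1: float
    p1Gy: float
    n2: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.p1Gy <= 0:
            raise ValueError("N1, N2 must be non-negative and p1Gy positive")
        if self.p1 < 0 or self.p2 < 0:
            raise ValueError("kill probabilities must be non-negative")

    @property
    def p1_valid(self) -> bool:
        return self.p1 <= 1.0

    @property
    def delta_alpha(self) -> float:
        return self.p1Gy * (self.n1 * self.p1 + self.n2 * self.p2)


def delta_alpha_bomb(
    p1Gy: float, n1: float, p1: float, n2: float = 0.0, p2: float = 0.0
) -> float:
    """delta_alpha = p1Gy * (N1 p1 + N2 p2), Gy^-1. Linear in every argument."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if n1 < 0 or n2 < 0 or p1Gy < 0:
        raise ValueError("N1, N2 and p1Gy must be non-negative")
    return p1Gy * (n1 * p1 + n2 * p2)


def infer_p1(
    delta_alpha: float,
    p1Gy: float,
    n1: float,
    sigma_dalpha: float | None = None,
    p1Gy_rel_sigma: float = 0.0,
) -> tuple[float, float | None]:
    """Kill probability per NP ionization, p1 = delta_alpha / (p1Gy * N1).

    ``sigma_dalpha`` should already combine the alpha uncertainties with
    and without NPs (quadrature of independent sigmas); the relative
    uncertainty of p1Gy is folded in first-order. A negative delta_alpha
    (NPs made cells less sensitive, outside model scope) yields p1 = 0
    with a warning. Values above 1 are returned as-is; validity is the
    caller's to flag.
    """
    if n1 <= 0 or p1Gy <= 0:
        raise ValueError("N1 and p1Gy must be positive")
    if delta_alpha < 0:
        warnings.warn(
            "negative delta_alpha: NPs reduced radiosensitivity, outside "
            "the Bomb model's scope; returning p1 = 0",
            stacklevel=2,
        )
        return 0.0, None
    p1 = delta_alpha / (p1Gy * n1)
    sigma = None
    if sigma_dalpha is not None and delta_alpha > 0:
        rel = math.hypot(sigma_dalpha / delta_alpha, p1Gy_rel_sigma)
        sigma = p1 * rel
    return p1, sigma


def sf_lq(params: LQParams, dose_gy: float) -> float:
    """Surviving fraction exp(-alpha D - beta D^2)."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    return math.exp(-params.effect(dose_gy))


def rbe_lq(base: LQParams, with_np: LQParams, dose_np_gy: float) -> float:
    """RBE at D_NP: the NP-free dose of equal LQ effect divided by D_NP.

    Solves base.beta D^2 + base.alpha D = with_np.effect(D_NP) for the
    positive root.
    """
    if dose_np_gy <= 0:
        raise ValueError("dose must be positive")
    if base.alpha < 0 or with_np.alpha < 0:
        raise ValueError("negative alpha: LQ effect matching is not meaningful")
    if base.beta <= 0:
        raise ValueError("base beta must be positive to solve for the equal-effect dose")
    effect = with_np.effect(dose_np_gy)
    if effect <= 0:
        raise ValueError(f"non-positive LQ effect {effect} at D_NP={dose_np_gy}")
    disc = base.alpha**2 + 4.0 * base.beta * effect
    dose_eq = (-base.alpha + math.sqrt(disc)) / (2.0 * base.beta)
    return dose_eq / dose_np_gy


def predict_scaling(
    p1: float,
    p1Gy: float,
    n1: float,
    base: LQParams,
    with_np_beta: float,
    factor: float,
    dose_np_gy: float = 2.0,
) -> float:
    """RBE after scaling the NP load N1 by ``factor``.

    delta_alpha is linear in N1, so the with-NP alpha is rebuilt as
    base.alpha + factor * delta_alpha(p1, N1) with beta unchanged at the
    with-NP value, and the equal-effect RBE recomputed.
    """
    if factor < 0:
        raise ValueError("factor must be non-negative")
    dalpha = delta_alpha_bomb(p1Gy, n1 * factor, p1)
    scaled = LQParams(alpha=base.alpha + dalpha, beta=with_np_beta)
    return rbe_lq(base, scaled, dose_np_gy)


@dataclass(frozen=True)
class BombResults:
    """Fitted Bomb-model quantities for one irradiation condition."""

    model: "BombModel" = field(repr=False)
    delta_alpha: float
    sigma_dalpha: float | None
    p1: float
    p1_sigma: float | None
    p1_valid: bool
    sf_base: float
    sf_np: float
    rbe: float
    dose_gy: float

    def to_dict(self) -> dict:
        return {
            "delta_alpha": self.delta_alpha,
            "sigma_dalpha": self.sigma_dalpha,
            "p1": self.p1,
            "p1_sigma": self.p1_sigma,
            "p1_valid": self.p1_valid,
            "sf_base": self.sf_base,
            "sf_np": self.sf_np,
            "rbe": self.rbe,
            "dose_gy": self.dose_gy,
        }

    def predict_scaling(self, factor: float, dose_np_gy: float | None = None) -> float:
        """RBE if the NP load were scaled by ``factor``."""
        m = self.model
        return predict_scaling(
            self.p1, m.p1Gy, m.n_np, m.base, m.with_np.beta,
            factor, dose_np_gy if dose_np_gy is not None else self.dose_gy,
        )

    def summary(self) -> str:
        name = self.model.name or "(unnamed)"
        sig = f" +/- {self.p1_sigma:.3g}" if self.p1_sigma is not None else ""
        flag = "" if self.p1_valid else "  [p1 > 1: inconsistent inputs]"
        lines = [
            f"Bomb model fit: {name}",
            "=" * 48,
            f"{'delta_alpha':26s} {self.delta_alpha:10.4g} Gy^-1",
            f"{'p1 (kill prob/ionization)':26s} {self.p1:10.4g}{sig}{flag}",
            f"{'SF(%g Gy) without NPs' % self.dose_gy:26s} {self.sf_base:10.4g}",
            f"{'SF(%g Gy) with NPs' % self.dose_gy:26s} {self.sf_np:10.4g}",
            f"{'RBE at %g Gy' % self.dose_gy:26s} {self.rbe:10.4g}",
        ]
        return "\n".join(lines)


class BombModel:
    """Bomb-model analysis of one published irradiation condition.

    Built from the LQ parameters without (``base``) and with NPs
    (``with_np``), the per-ionization coefficient ``p1Gy`` and the NP
    count per cell ``n_np`` (all NPs outside the nucleus; N2 = 0).
    ``fit()`` infers p1 with first-order uncertainty and evaluates
    survival and RBE at the reference dose.
    """

    def __init__(
        self,
        base: LQParams,
        with_np: LQParams,
        p1Gy: float,
        n_np: float,
        p1Gy_rel_sigma: float = 0.0,
        name: str = "",
    ) -> None:
        self.base = base
        self.with_np = with_np
        self.p1Gy = p1Gy
        self.n_np = n_np
        self.p1Gy_rel_sigma = p1Gy_rel_sigma
        self.name = name

    @classmethod
    def from_fixture(cls, fixture_id: str) -> "BombModel":
        """Build from a packaged published parameter set."""
        fx = constants.survival_fixture(fixture_id)
        exp = constants.exposure_coefficients(fx["np"], fx["beam"])
        return cls(
            base=LQParams(fx["alpha"], fx["beta"], fx["alpha_sigma"]),
            with_np=LQParams(fx["alpha_np"], fx["beta_np"], fx["alpha_np_sigma"]),
            p1Gy=exp["p1Gy"],
            n_np=fx["n_np"],
            p1Gy_rel_sigma=exp["p1Gy_sigma"] / exp["p1Gy"],
            name=fixture_id,
        )

    def fit(self, dose_gy: float = 2.0) -> BombResults:
        dalpha = self.with_np.alpha - self.base.alpha
        sigma_dalpha = None
        if self.base.alpha_sigma is not None and self.with_np.alpha_sigma is not None:
            sigma_dalpha = math.hypot(self.base.alpha_sigma, self.with_np.alpha_sigma)
        p1, p1_sigma = infer_p1(
            dalpha, self.p1Gy, self.n_np, sigma_dalpha, self.p1Gy_rel_sigma
        )
        return BombResults(
            model=self,
            delta_alpha=dalpha,
            sigma_dalpha=sigma_dalpha,
            p1=p1,
            p1_sigma=p1_sigma,
            p1_valid=p1 <= 1.0,
            sf_base=sf_lq(self.base, dose_gy),
            sf_np=sf_lq(self.with_np, dose_gy),
            rbe=rbe_lq(self.base, self.with_np, dose_gy),
            dose_gy=dose_gy,
        )
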