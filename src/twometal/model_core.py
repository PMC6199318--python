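"""Closed-form kinetics of the three-state (E / EM / EMM) metal-ion cycle.

Two model variants are supported:

* ``model1`` -- sequential dissociation: the B-site ion is released on every
  cleavage/translocation step (EMM -> EM carries the position increment in the
  mean-velocity bookkeeping), the A-site ion dissociates only occasionally
  (EM -> E).
* ``model2`` -- coincident dissociation: every cleavage releases both ions
  (EMM -> E carries the position increment); the cycle is completed by A-site
  rebinding (E -> EM) followed by B-site rebinding (EM -> EMM).

Units are fixed package-wide: seconds, millimolar, nucleotides.  Bimolecular
binding rates are expressed in s^-1 mM^-1, so pseudo-first-order on-rates are
``k_on = k_b * c`` with ``c`` the free-ion concentration in mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

__all__ = [
    "ModelVariant",
    "RateConstants",
    "MgCondition",
    "ModelSpec",
    "HillParams",
    "InfeasibleModelError",
    "mean_velocity",
    "tau1",
    "tau_d",
    "hill_velocity",
    "mm_velocity",
    "barrier_difference",
    "model2_binding_rates",
    "model2_kAoff_lower_bound",
    "model2_effective_constants",
]


class ModelVariant(str, Enum):
    """Which dissociation scheme the kinetic cycle follows."""

    MODEL1 = "model1"
    MODEL2 = "model2"


class InfeasibleModelError(ValueError):
    """Raised when requested rate constants violate a feasibility bound."""


def _require_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if allow_zero:
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")
    elif value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """The four kinetic constants of the cycle.

    Parameters
    ----------
    k_B_off : float
        B-site ion dissociation rate (s^-1); in model1 this is also the
        cleavage/translocation rate.
    k_B_b : float
        B-site bimolecular binding rate (s^-1 mM^-1).
    k_A_off : float
        A-site ion dissociation rate (s^-1).  Zero is permitted as a
        degenerate limit (the E state becomes unreachable).
    k_A_b : float
        A-site bimolecular binding rate (s^-1 mM^-1).  Zero is permitted as
        the blocked-rebinding limit (K_A diverges; absorption may become
        uncertain).

    The equilibrium constants ``K_A = k_A_off / k_A_b`` and
    ``K_B = k_B_off / k_B_b`` (mM) are derived read-only properties and are
    never stored independently.
    """

    k_B_off: float
    k_B_b: float
    k_A_off: float
    k_A_b: float

    def __post_init__(self) -> None:
        _require_positive("k_B_off", self.k_B_off)
        _require_positive("k_B_b", self.k_B_b)
        _require_positive("k_A_off", self.k_A_off, allow_zero=True)
        _require_positive("k_A_b", self.k_A_b, allow_zero=True)

    @property
    def K_A(self) -> float:
        """A-site equilibrium (dissociation) constant, mM."""
        if self.k_A_b == 0:
            return math.inf if self.k_A_off > 0 else math.nan
        return self.k_A_off / self.k_A_b

    @property
    def K_B(self) -> float:
        """B-site equilibrium (dissociation) constant, mM."""
        return self.k_B_off / self.k_B_b

    def k_A_on(self, c: "MgCondition | float") -> float:
        """Pseudo-first-order A-site on-rate at concentration ``c`` (s^-1)."""
        return self.k_A_b * as_condition(c).concentration

    def k_B_on(self, c: "MgCondition | float") -> float:
        """Pseudo-first-order B-site on-rate at concentration ``c`` (s^-1)."""
        return self.k_B_b * as_condition(c).concentration

    def scaled(self, factor: float) -> "RateConstants":
        """All four constants multiplied by a common factor.

        This is the quenched-disorder perturbation: one molecule-specific
        activation-free-energy offset rescales every rate by ``exp(-dG)``,
        leaving K_A and K_B invariant.
        """
        _require_positive("factor", factor)
        return replace(
            self,
            k_B_off=self.k_B_off * factor,
            k_B_b=self.k_B_b * factor,
            k_A_off=self.k_A_off * factor,
            k_A_b=self.k_A_b * factor,
        )


@dataclass(frozen=True)
class MgCondition:
    """A free divalent-ion concentration, mM (non-negative).

    Zero is allowed only for degenerate-input handling; every kinetic
    operation rejects it unless an explicit limit flag is passed.
    """

    concentration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"concentration must be finite and >= 0 mM, got {self.concentration!r}"
            )


def as_condition(c: "MgCondition | float") -> MgCondition:
    """Coerce a float (mM) to an :class:`MgCondition`."""
    return c if isinstance(c, MgCondition) else MgCondition(float(c))


@dataclass(frozen=True)
class ModelSpec:
    """Model variant, number of nucleotides to degrade, and rate constants."""

    variant: ModelVariant
    rates: RateConstants
    n_sites: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", ModelVariant(self.variant))
        if int(self.n_sites) != self.n_sites or self.n_sites < 1:
            raise ValueError(f"n_sites must be an integer >= 1, got {self.n_sites!r}")
        object.__setattr__(self, "n_sites", int(self.n_sites))

    def with_rates(self, rates: RateConstants) -> "ModelSpec":
        return replace(self, rates=rates)


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: ``V = v_max c^n / (c^n + K^n)``."""

    v_max: float
    K: float
    n: float

    def __post_init__(self) -> None:
        _require_positive("v_max", self.v_max)
        _require_positive("K", self.K)
        _require_positive("n", self.n)


def _check_positive_concentration(c: MgCondition) -> float:
    if c.concentration == 0:
        raise ValueError(
            "velocity is undefined at zero concentration; "
            "pass zero_limit=True to obtain the limiting value 0"
        )
    return c.concentration


def tau_d(rates: RateConstants, c: "MgCondition | float") -> float:
    """Mean extra dwell from A-site excursions per EMM->EM cycle (s).

    Closed form of the geometric series over the number of excursions to E
    before the B site rebinds: ``k_A_off / (k_A_on * k_B_on)``.
    """
    conc = _check_positive_concentration(as_condition(c))
    if rates.k_A_off == 0:
        return 0.0
    if rates.k_A_b == 0:
        return math.inf
    return rates.k_A_off / (rates.k_A_b * conc * rates.k_B_b * conc)


def tau1(spec: ModelSpec, c: "MgCondition | float") -> float:
    """Mean degradation time per nucleotide (s); exactly ``1 / mean_velocity``."""
    cond = as_condition(c)
    conc = _check_positive_concentration(cond)
    r = spec.rates
    k_B_on = r.k_B_b * conc
    if spec.variant is ModelVariant.MODEL1:
        return 1.0 / r.k_B_off + tau_d(r, cond) + 1.0 / k_B_on
    # model2: every cycle passes through E, so one full A-site rebinding
    # (1/k_A_on) is mandatory in addition to the excursion term.
    k_A_on = r.k_A_b * conc
    if k_A_on == 0:
        return math.inf
    return 1.0 / r.k_B_off + 1.0 / k_A_on + 1.0 / k_B_on + r.k_A_off / (k_A_on * k_B_on)


def mean_velocity(
    spec: ModelSpec, c: "MgCondition | float", *, zero_limit: bool = False
) -> float:
    """Mean degradation velocity (nt s^-1) at concentration ``c``.

    model1:
        ``V = k_B_off c / (c + K_B + K_B K_A / c)``

    model2 (exact reciprocal of the per-cycle mean first-passage time):
        ``V = k_B_off / (1 + S/c + P/c^2)`` with the effective coefficients
        ``S = k_B_off/k_A_b + k_B_off/k_B_b`` and
        ``P = k_A_off k_B_off / (k_A_b k_B_b)``
        (see :func:`model2_effective_constants`).

    Both variants are strictly increasing in ``c`` and saturate at
    ``k_B_off`` as ``c -> inf``.  ``zero_limit=True`` returns 0 at ``c = 0``
    instead of raising.
    """
    cond = as_condition(c)
    if cond.concentration == 0:
        if zero_limit:
            return 0.0
        raise ValueError(
            "velocity is undefined at zero concentration; "
            "pass zero_limit=True to obtain the limiting value 0"
        )
    t = tau1(spec, cond)
    return 0.0 if math.isinf(t) else 1.0 / t


def model2_effective_constants(rates: RateConstants) -> tuple[float, float]:
    """Effective (S, P) coefficients of the model-2 velocity curve.

    The model-2 mean velocity has the form ``k_B_off / (1 + S/c + P/c^2)``.
    ``S`` plays the role of a summed equilibrium constant (mM) and ``P`` of a
    product of equilibrium constants (mM^2); a curve fit determines (S, P),
    which :func:`model2_binding_rates` inverts back to binding rates.
    """
    S = rates.k_B_off / rates.k_A_b + rates.k_B_off / rates.k_B_b
    P = rates.k_A_off * rates.k_B_off / (rates.k_A_b * rates.k_B_b)
    return S, P


def hill_velocity(p: HillParams, c: "MgCondition | float") -> float:
    """Hill-equation velocity ``v_max c^n / (c^n + K^n)``; 0 at ``c = 0``."""
    conc = as_condition(c).concentration
    if conc == 0:
        return 0.0
    cn = conc**p.n
    return p.v_max * cn / (cn + p.K**p.n)


def mm_velocity(v_max: float, K_m: float, c: "MgCondition | float") -> float:
    """Michaelis-Menten velocity, the ``n = 1`` special case of the Hill curve."""
    return hill_velocity(HillParams(v_max=v_max, K=K_m, n=1.0), c)


def barrier_difference(rates: RateConstants) -> float:
    """Activation-barrier difference between the two dissociations (k_B T).

    ``ln(k_B_off / k_A_off)``: how much higher the A-site dissociation
    barrier sits above the B-site one.
    """
    if rates.k_A_off <= 0:
        raise ValueError("barrier_difference requires k_A_off > 0")
    return math.log(rates.k_B_off / rates.k_A_off)


def model2_kAoff_lower_bound(K_A: float, K_B: float, k_B_off: float) -> float:
    """Smallest A-site off-rate for which model-2 binding rates are real.

    Returns ``4 K_A K_B k_B_off / (K_A + K_B)^2``.
    :func:`model2_binding_rates` is feasible iff ``k_A_off`` is at least this
    value (discriminant sign); equality gives the double root.
    """
    _require_positive("K_A", K_A)
    _require_positive("K_B", K_B)
    _require_positive("k_B_off", k_B_off)
    return 4.0 * K_A * K_B * k_B_off / (K_A + K_B) ** 2


def model2_binding_rates(
    K_A: float, K_B: float, k_B_off: float, k_A_off: float
) -> tuple[float, float]:
    """Invert a fitted model-2 velocity curve into binding rates.

    Given the fitted coefficients of the velocity curve -- parameterized as
    two equilibrium-like constants with sum ``S = K_A + K_B`` and product
    ``P = K_A K_B`` -- together with the cleavage rate ``k_B_off`` and a
    candidate ``k_A_off``, return the unique pair ``(k_A_b, k_B_b)`` with
    ``k_A_b <= k_B_b`` that reproduces the same curve:

        ``k_A_b = (S k_A_off - sqrt(D)) / (2 P)``
        ``k_B_b = (S k_A_off + sqrt(D)) / (2 P)``

    with discriminant ``D = k_A_off^2 S^2 - 4 k_B_off k_A_off P``.

    Raises
    ------
    InfeasibleModelError
        If ``D < 0``, i.e. ``k_A_off`` is below
        :func:`model2_kAoff_lower_bound`.
    """
    _require_positive("K_A", K_A)
    _require_positive("K_B", K_B)
    _require_positive("k_B_off", k_B_off)
    _require_positive("k_A_off", k_A_off)
    S = K_A + K_B
    P = K_A * K_B
    disc = k_A_off**2 * S**2 - 4.0 * k_B_off * k_A_off * P
    if -1e-12 * k_A_off**2 * S**2 < disc < 0:  # exact-bound roundoff
        disc = 0.0
    if disc < 0:
        bound = model2_kAoff_lower_bound(K_A, K_B, k_B_off)
        raise InfeasibleModelError(
            f"k_A_off = {k_A_off:g} s^-1 is below the feasibility bound "
            f"4 K_A K_B k_B_off / (K_A + K_B)^2 = {bound:g} s^-1; "
            "no real binding-rate pair exists"
        )
    root = math.sqrt(disc)
    k_A_b = (S * k_A_off - root) / (2.0 * P)
    k_B_b = (S * k_A_off + root) / (2.0 * P)
    return k_A_b, k_B_b
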