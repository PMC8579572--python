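"""Deterministic two-deme epidemic model and basic reproduction number.

The structured host population is a pair of sub-populations (demes) S1, S2
with per-lineage birth rates ``lambda_i``, death rates ``mu_i`` and migration
rates ``alpha_ij`` (deme i to deme j).  The deterministic counterpart of the
branching process is the linear ODE system

    dS1/dt = (lambda_1 S1 + alpha_21 S2) - (mu_1 S1 + alpha_12 S1)
    dS2/dt = (lambda_2 S2 + alpha_12 S1) - (mu_2 S2 + alpha_21 S2)

whose disease-free equilibrium is (0, 0).  R0 is the dominant eigenvalue of
the next-generation matrix F V^{-1}, where F holds the new-infection terms
(births) and V the remaining transfer terms (deaths and migrations), both
linearised at the disease-free equilibrium.

Two closed-form special cases are used to parameterise simulations:

* a single non-structured population: ``R0 = lambda / mu``;
* the per-deme scaling convention ``R0_i = lambda_i / (2 alpha_ij + mu_i)``,
  inverted as ``lambda_i = R0_i (2 alpha_ij + mu_i)`` to derive birth rates
  from literature R0 values.  Note this per-deme convention is *not* the
  dominant eigenvalue of F V^{-1} for general rates (see docs/methods.md);
  it is retained because it defines the simulation parameterisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import DemeParameters

__all__ = [
    "StructuredModelParameters", "R0Result", "ode_rhs",
    "next_generation_matrices", "r0_numeric", "r0_general",
    "r0_unstructured", "r0_scaled_structured", "birth_rate_from_r0",
]


@dataclass(frozen=True)
class StructuredModelParameters:
    """Rates of the two-deme model: (lambda_1, mu_1, alpha_12; lambda_2, mu_2, alpha_21)."""

    deme1: DemeParameters
    deme2: DemeParameters

    @classmethod
    def from_rates(cls, lambda1, mu1, alpha12, lambda2, mu2, alpha21):
        return cls(DemeParameters(lambda1, mu1, alpha12),
                   DemeParameters(lambda2, mu2, alpha21))

    def rates(self) -> tuple[float, float, float, float, float, float]:
        p1, p2 = self.deme1, self.deme2
        return (p1.birth_rate, p1.death_rate, p1.emigration_rate,
                p2.birth_rate, p2.death_rate, p2.emigration_rate)


@dataclass(frozen=True)
class R0Result:
    """A basic reproduction number with its intermediate discriminant."""

    value: float
    delta: float | None
    method: str  # "general-closed-form" | "numeric-eigenvalue" | "special-case"

    def __float__(self) -> float:
        return self.value


def ode_rhs(state, params: StructuredModelParameters):
    """Right-hand side of the two-deme ODE system at ``state = (S1, S2)``."""
    s1, s2 = state
    l1, m1, a12, l2, m2, a21 = params.rates()
    ds1 = (l1 * s1 + a21 * s2) - (m1 * s1 + a12 * s1)
    ds2 = (l2 * s2 + a12 * s1) - (m2 * s2 + a21 * s2)
    return ds1, ds2


def next_generation_matrices(params: StructuredModelParameters):
    """Jacobians (F, V) of new-infection and transfer terms at the DFE.

    F = diag(lambda_1, lambda_2);
    V = [[alpha_12 + mu_1, -alpha_21], [-alpha_12, alpha_21 + mu_2]].
    """
    l1, m1, a12, l2, m2, a21 = params.rates()
    F = np.array([[l1, 0.0], [0.0, l2]])
    V = np.array([[a12 + m1, -a21], [-a12, a21 + m2]])
    return F, V


def r0_numeric(params: StructuredModelParameters) -> R0Result:
    """R0 as the numerically computed dominant eigenvalue of F V^{-1}.

    Serves as the independent oracle for :func:`r0_general`; V is inverted
    numerically rather than symbolically.
    """
    F, V = next_generation_matrices(params)
    det = np.linalg.det(V)
    if abs(det) < 1e-300:
        raise ZeroDivisionError("degenerate model: V is singular")
    ngm = F @ np.linalg.inv(V)
    eigvals = np.linalg.eigvals(ngm)
    return R0Result(float(np.max(eigvals.real)), None, "numeric-eigenvalue")


def r0_general(params: StructuredModelParameters) -> R0Result:
    """Closed-form R0 of the two-deme model.

    R0 = (a21 l1 + a12 l2 + l2 m1 + l1 m2 + sqrt(Delta))
         / (2 (a21 m1 + (a12 + m1) m2))

    with discriminant

    Delta = a21^2 l1^2 + 2 a12 a21 l1 l2 + a12^2 l2^2 + l2^2 m1^2 + l1^2 m2^2
            - 2 (a21 l1 l2 - a12 l2^2) m1
            + 2 (a21 l1^2 - a12 l1 l2 - l1 l2 m1) m2.
    """
    l1, m1, a12, l2, m2, a21 = params.rates()
    denom = a21 * m1 + (a12 + m1) * m2
    if denom <= 0:
        raise ZeroDivisionError("degenerate model: use a special-case formula")
    delta = (a21 ** 2 * l1 ** 2 + 2 * a12 * a21 * l1 * l2 + a12 ** 2 * l2 ** 2
             + l2 ** 2 * m1 ** 2 + l1 ** 2 * m2 ** 2
             - 2 * (a21 * l1 * l2 - a12 * l2 ** 2) * m1
             + 2 * (a21 * l1 ** 2 - a12 * l1 * l2 - l1 * l2 * m1) * m2)
    # Delta = tr^2 - 4 det of F V^{-1} scaled by denom^2; nonnegative for
    # nonnegative rates (real eigenvalues), but guard against roundoff.
    if delta < 0 and delta > -1e-12 * max(1.0, l1, l2) ** 2:
        delta = 0.0
    value = (a21 * l1 + a12 * l2 + l2 * m1 + l1 * m2 + math.sqrt(delta)) / (2 * denom)
    return R0Result(value, delta, "general-closed-form")


def r0_unstructured(birth_rate: float, death_rate: float) -> float:
    """R0 of a single homogeneous population: lambda / mu."""
    if death_rate <= 0:
        raise ZeroDivisionError("R0 undefined for zero death rate")
    return birth_rate / death_rate


def r0_scaled_structured(birth_rate: float, death_rate: float,
                         emigration_rate: float, k: float = 1.0) -> float:
    """Per-deme R0 under the proportional-rates convention.

    When the second deme's rates are the first deme's multiplied by a common
    factor ``k > 0``, the convention assigns R0 = lambda_1 / (2 alpha_12 +
    mu_1), independent of ``k``.  This is the relation used to derive birth
    rates from target R0 values; with no migration it reduces to lambda/mu.
    """
    if k <= 0:
        raise ValueError("scale factor k must be positive")
    denom = 2 * emigration_rate + death_rate
    if denom <= 0:
        raise ZeroDivisionError("R0 undefined: 2*alpha + mu must be positive")
    return birth_rate / denom


def birth_rate_from_r0(r0: float, death_rate: float,
                       emigration_rate: float = 0.0) -> float:
    """Invert the per-deme R0 convention: lambda = R0 (2 alpha + mu).

    With ``emigration_rate = 0`` this is the non-structured inverse
    lambda = R0 mu.
    """
    if r0 <= 0:
        raise ValueError("target R0 must be positive")
    return r0 * (2 * emigration_rate + death_rate)
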