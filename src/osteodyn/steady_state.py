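"""Closed-form nontrivial steady states for every variant, plus an oracle.

All closed forms are powers of the two rate ratios ``b1 = beta1/alpha1`` and
``b2 = beta2/alpha2``; powers are computed as ``exp(e * log(ratio))`` on
strictly positive ratios, so a nonpositive ratio is a validation error and
never silently produces a complex number.

Model-2 note
------------
Two conventions are implemented for the model-2 steady state.  The default
(``self_consistent=False``) carries the tumor factor
``sigma**((g31 - g31*g22 - g21*g32)/gamma)`` on ``x1bar``; it is the form
used throughout this package's reference stability classifications and
worked examples.  Direct solution of the fixed-point equations instead
gives ``sigma**((g31*g22 - g31 - g21*g32)/gamma)`` — the sign of the
``g31*(1-g22)`` contribution flips — and only that form satisfies
``f(x1bar, x2bar) = 0`` exactly.  The ``x2bar`` factor is identical under
both conventions.  Pass ``self_consistent=True`` whenever an actual fixed
point is needed (residual checks, trajectory convergence references).
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .models import powerlaw_form
from .params import (ModelSpec, RemodelingParams, SteadyState, TumorParams,
                     Variant)


class UndefinedSteadyStateError(ValueError):
    """Raised when gamma (or Lambda) vanishes: no nontrivial fixed point."""


class OracleFailure(RuntimeError):
    """Root finding did not converge; the cross-check is inconclusive."""


def _check_ratios(params: RemodelingParams) -> tuple[float, float]:
    b1 = params.beta1 / params.alpha1
    b2 = params.beta2 / params.alpha2
    if b1 <= 0.0 or b2 <= 0.0:
        raise ValueError("rate ratios beta_i/alpha_i must be positive")
    return b1, b2


def _pow(base: float, exponent: float) -> float:
    return math.exp(exponent * math.log(base))


def base_steady_state(params: RemodelingParams) -> SteadyState:
    """Nontrivial fixed point of the tumor-free system.

    x1bar = (beta1/alpha1)**((1-g22)/gamma) * (beta2/alpha2)**(g21/gamma)
    x2bar = (beta1/alpha1)**(g12/gamma) * (beta2/alpha2)**((1-g11)/gamma)
    """
    gamma = params.gamma
    if gamma == 0.0:
        raise UndefinedSteadyStateError(
            "gamma == 0: the nontrivial steady state is undefined")
    b1, b2 = _check_ratios(params)
    x1 = _pow(b1, (1.0 - params.g22) / gamma) * _pow(b2, params.g21 / gamma)
    x2 = _pow(b1, params.g12 / gamma) * _pow(b2, (1.0 - params.g11) / gamma)
    return SteadyState(x1, x2, 0.0, source="base")


def _h_exponents(params: RemodelingParams,
                 scenario: int) -> tuple[float, float]:
    """Per-scenario exponents (e1, e2) of the ``(1-sigma)`` factors.

    The model-1 steady state is the base value times ``(1-sigma)**e_i``;
    scenarios 0-2 leave it unchanged (the same ``(1-D)`` factor cancels in
    ``beta_hat/alpha_hat``).  Encoded as one lookup so the table has a
    single source of truth.
    """
    g11, g21, g12, g22 = params.g11, params.g21, params.g12, params.g22
    gamma = params.gamma
    if scenario in (0, 1, 2):
        return 0.0, 0.0
    if scenario == 3:
        return (2.0 * (1.0 - g22 - g21) / gamma,
                2.0 * (-1.0 + g11 + g12) / gamma)
    if scenario == 4:
        return (2.0 * (-1.0 + g22 + g21) / gamma,
                2.0 * (1.0 - g11 - g12) / gamma)
    if scenario in (5, 6):
        return (1.0 - g22) / gamma, g12 / gamma
    if scenario in (7, 8):
        return g21 / gamma, (1.0 - g11) / gamma
    raise ValueError(f"scenario must be in 0..8, got {scenario}")


def model1_steady_state(params: RemodelingParams, sigma: float,
                        scenario: int) -> SteadyState:
    """Model-1 fixed point: base value times the scenario's (1-sigma) power."""
    if not 0.0 < sigma < 1.0:
        raise ValueError(f"sigma must be in (0, 1), got {sigma}")
    base = base_steady_state(params)
    e1, e2 = _h_exponents(params, scenario)
    return SteadyState(base.x1bar * (1.0 - sigma) ** e1,
                       base.x2bar * (1.0 - sigma) ** e2,
                       sigma, source=f"model1/scenario-{scenario}")


def model2_steady_state(params: RemodelingParams, sigma: float, g31: float,
                        g32: float,
                        self_consistent: bool = False) -> SteadyState:
    """Model-2 fixed point: base value times a power of sigma.

    See the module docstring for the two x1bar conventions; ``x2bar`` is
    ``base * sigma**((g32*g11 - g31*g12 - g32)/gamma)`` under both.
    """
    if not 0.0 < sigma < 1.0:
        raise ValueError(f"sigma must be in (0, 1), got {sigma}")
    gamma = params.gamma
    base = base_steady_state(params)
    g22, g21, g11, g12 = params.g22, params.g21, params.g11, params.g12
    if self_consistent:
        e1 = (g31 * g22 - g31 - g21 * g32) / gamma
        tag = "model2/self-consistent"
    else:
        e1 = (g31 - g31 * g22 - g21 * g32) / gamma
        tag = "model2/as-printed"
    e2 = (g32 * g11 - g31 * g12 - g32) / gamma
    return SteadyState(base.x1bar * _pow(sigma, e1),
                       base.x2bar * _pow(sigma, e2), sigma, source=tag)


def model3_steady_state(params: RemodelingParams, sigma: float, r11: float,
                        r12: float, r21: float, r22: float) -> SteadyState:
    """Model-3 fixed point via the tumor-deformed exponent combination Lambda.

    At ``D = sigma`` the effective exponents are ``g11*(1+r11)``,
    ``g21*(1+r21)``, ``g12/(1+r12)``, ``g22-r22`` and the closed form is the
    base formula with those exponents and
    ``Lambda = (g12/(1+r12))*(g21*(1+r21)) - (1-g11*(1+r11))*(1-g22+r22)``
    in place of gamma.
    """
    if not 0.0 < sigma < 1.0:
        raise ValueError(f"sigma must be in (0, 1), got {sigma}")
    if 1.0 + r12 == 0.0:
        raise ValueError("r12 == -1 makes the g12 modifier undefined")
    g11e = params.g11 * (1.0 + r11)
    g21e = params.g21 * (1.0 + r21)
    g12e = params.g12 / (1.0 + r12)
    g22e = params.g22 - r22
    lam = g12e * g21e - (1.0 - g11e) * (1.0 - g22e)
    if lam == 0.0:
        raise UndefinedSteadyStateError(
            "Lambda == 0: the model-3 steady state is undefined")
    b1, b2 = _check_ratios(params)
    x1 = _pow(b1, (1.0 - g22e) / lam) * _pow(b2, g21e / lam)
    x2 = _pow(b1, g12e / lam) * _pow(b2, (1.0 - g11e) / lam)
    return SteadyState(x1, x2, sigma, source="model3")


def steady_state(spec: ModelSpec, params: RemodelingParams,
                 tumor: TumorParams,
                 self_consistent: bool = False) -> SteadyState:
    """Dispatch to the variant's closed form at ``D = sigma``."""
    if spec.variant is Variant.BASE:
        return base_steady_state(params)
    if spec.variant is Variant.MODEL1:
        return model1_steady_state(params, tumor.sigma, spec.scenario)
    if spec.variant is Variant.MODEL2:
        return model2_steady_state(params, tumor.sigma, spec.g31, spec.g32,
                                   self_consistent=self_consistent)
    return model3_steady_state(params, tumor.sigma, spec.r11, spec.r12,
                               spec.r21, spec.r22)


def steady_state_oracle(rhs: Callable[[float, float], Sequence[float]],
                        initial_guess: Sequence[float],
                        tol: float = 1e-12) -> SteadyState:
    """Numerically solve ``rhs(x1, x2) = 0`` in the positive orthant.

    The root search runs in log coordinates, which both enforces positivity
    and excludes the trivial fixed point at the origin, and solves the
    per-capita rates ``rhs_i / x_i`` so the problem is well conditioned at
    any population scale.  Used in tests to certify the closed forms;
    raises :class:`OracleFailure` when the solver does not converge (the
    cross-check is then inconclusive, not failed).
    """
    x1g, x2g = initial_guess
    if x1g <= 0.0 or x2g <= 0.0:
        raise ValueError("initial guess must lie in the positive orthant")

    def f(u: np.ndarray) -> list[float]:
        x1, x2 = math.exp(u[0]), math.exp(u[1])
        r1, r2 = rhs(x1, x2)
        return [r1 / x1, r2 / x2]

    sol = optimize.root(f, [math.log(x1g), math.log(x2g)], tol=tol)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise OracleFailure(f"root finding failed: {sol.message}")
    return SteadyState(math.exp(sol.x[0]), math.exp(sol.x[1]),
                       0.0, source="oracle")


def rhs_at_sigma(spec: ModelSpec, params: RemodelingParams,
                 tumor: TumorParams) -> Callable[[float, float], tuple]:
    """Cell-equation RHS with the tumor frozen at ``D = sigma``.

    This is the function whose positive root is the variant's nontrivial
    steady state; convenience wrapper for the oracle.
    """
    form = powerlaw_form(spec, params, tumor)
    D = 0.0 if spec.variant is Variant.BASE else tumor.sigma

    def rhs(x1: float, x2: float) -> tuple[float, float]:
        return form.cell_rates(x1, x2, D)

    return rhs


def residual(spec: ModelSpec, params: RemodelingParams, tumor: TumorParams,
             ss: SteadyState) -> float:
    """Max relative cell-equation residual of ``ss`` at ``D = Dbar``.

    Rates are normalized by the removal fluxes ``beta_i * x_i_bar`` so the
    residual is scale free.
    """
    form = powerlaw_form(spec, params, tumor)
    D = ss.Dbar if spec.variant is not Variant.BASE else 0.0
    dx1, dx2 = form.cell_rates(ss.x1bar, ss.x2bar, D)
    return max(abs(dx1) / (params.beta1 * ss.x1bar),
               abs(dx2) / (params.beta2 * ss.x2bar))
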