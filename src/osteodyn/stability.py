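"""Analytic Jacobians, Routh-Hurwitz verdicts, and stability-region scans.

The coupled system is block triangular: the tumor equation depends only on
``D``, so the third Jacobian row is ``(0, 0, -mu/ln 10)`` at ``D = sigma``
and the spectrum is always {eigenvalues of the 2x2 cell block} union
{-mu/ln 10}.  Jacobian entries are derived by differentiating the
implemented right-hand sides through the canonical coefficient form — they
are never transcribed from any printed matrix — and are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .models import LN10, powerlaw_form
from .params import (ModelSpec, RemodelingParams, SteadyState, TumorParams,
                     Variant)
from .steady_state import steady_state

#: zero-real-part tolerance (relative to max(1, ||J||)) for analytic work;
#: the base model's center is structurally exact but floating-point fuzzy.
ANALYTIC_TOL = 1e-9
#: coarser tolerance used by grid scans.
SCAN_TOL = 1e-6


class EigClass(Enum):
    """Eigenvalue taxonomy of the 3x3 system Jacobian."""

    STABLE_SPIRAL = "stable_spiral"    # all Re<0, some Im!=0: damped osc.
    STABLE_NODE = "stable_node"        # all Re<0, all Im==0
    CENTER_LIKE = "center_like"        # a zero-Re pair: sustained osc.
    UNSTABLE = "unstable"              # any Re>0
    UNDEFINED = "undefined"            # steady state does not exist


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian, spectrum, invariants and verdicts at a steady state."""

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    invariants: tuple[float, float, float]
    routh_hurwitz_stable: bool
    eig_class: EigClass
    tol: float
    steady: SteadyState


def jacobian_at_point(spec: ModelSpec, params: RemodelingParams,
                      tumor: TumorParams, x1: float, x2: float,
                      D: float) -> np.ndarray:
    """Analytic 3x3 Jacobian of (x1, x2, D) dynamics at an arbitrary point.

    Valid at any point of the open positive orthant, not only at fixed
    points — the stability classification of model 2 evaluates it at the
    as-printed reference point, which is not an exact root.
    """
    form = powerlaw_form(spec, params, tumor)
    A1, B1, A2, B2, G11, G21, G12, G22 = form.coeffs(D)
    dA1, dB1, dA2, dB2, dG11, dG21, dG12, dG22 = form.dcoeffs(D)
    P1 = A1 * x1 ** G11 * x2 ** G21
    P2 = A2 * x1 ** G12 * x2 ** G22
    lx1, lx2 = math.log(x1), math.log(x2)
    J = np.zeros((3, 3))
    J[0, 0] = G11 * P1 / x1 - B1
    J[0, 1] = G21 * P1 / x2
    J[1, 0] = G12 * P2 / x1
    J[1, 1] = G22 * P2 / x2 - B2
    # d/dD: product rule over A_i(D) and the two exponents
    J[0, 2] = ((dA1 / A1 if A1 != 0.0 else 0.0) * P1
               + P1 * (dG11 * lx1 + dG21 * lx2) - dB1 * x1)
    J[1, 2] = ((dA2 / A2 if A2 != 0.0 else 0.0) * P2
               + P2 * (dG12 * lx1 + dG22 * lx2) - dB2 * x2)
    # tumor row: d/dD [mu*D*log10(sigma/D)] = mu*log10(sigma/D) - mu/ln10
    J[2, 2] = tumor.mu * (math.log10(tumor.sigma / D) - 1.0 / LN10) \
        if D > 0.0 else 0.0
    return J


def jacobian_at_steady(spec: ModelSpec, params: RemodelingParams,
                       tumor: TumorParams,
                       steady: SteadyState | None = None) -> np.ndarray:
    """Jacobian evaluated at the variant's reference steady state.

    At ``D = sigma`` the (3,3) entry is exactly ``-mu/ln 10`` and rows
    ``J31 = J32 = 0``.  For the BASE variant the cell block is embedded in
    the same 3x3 frame (tumor decoupled) so every report carries the
    ``-mu/ln 10`` factor.
    """
    if steady is None:
        steady = steady_state(spec, params, tumor)
    J = jacobian_at_point(spec, params, tumor, steady.x1bar, steady.x2bar,
                          tumor.sigma)
    J[2, 2] = -tumor.mu / LN10  # exact at D = sigma
    if spec.variant is Variant.BASE:
        J[0, 2] = J[1, 2] = 0.0  # tumor decoupled
    return J


def characteristic_invariants(J: np.ndarray) -> tuple[float, float, float]:
    """Coefficients (a1, a2, a3) of ``lambda^3 + a1 l^2 + a2 l + a3``.

    Computed from the matrix itself: ``a1 = -tr J``, ``a2`` the sum of
    principal 2x2 minors, ``a3 = -det J``.
    """
    J = np.asarray(J, dtype=float)
    a1 = -np.trace(J)
    a2 = 0.0
    for i, j in itertools.combinations(range(3), 2):
        a2 += J[i, i] * J[j, j] - J[i, j] * J[j, i]
    a3 = -np.linalg.det(J)
    return float(a1), float(a2), float(a3)


def routh_hurwitz(a1: float, a2: float, a3: float) -> bool:
    """True iff every root of the cubic has negative real part.

    Conditions: ``a1 > 0``, ``a3 > 0`` and ``a1*a2 - a3 > 0``.
    """
    return a1 > 0.0 and a3 > 0.0 and a1 * a2 - a3 > 0.0


def classify_eigenvalues(eigs: Sequence[complex],
                         tol: float) -> EigClass:
    """Map three eigenvalues to the stability taxonomy at tolerance ``tol``.

    Marginal cases (a real part within ``tol`` of zero, no positive real
    part) are labeled CENTER_LIKE, never silently as stable.
    """
    eigs = np.asarray(eigs, dtype=complex)
    re, im = eigs.real, eigs.imag
    if np.any(re > tol):
        return EigClass.UNSTABLE
    if np.any(np.abs(re) <= tol):
        return EigClass.CENTER_LIKE
    if np.any(np.abs(im) > tol):
        return EigClass.STABLE_SPIRAL
    return EigClass.STABLE_NODE


def stability_report(spec: ModelSpec, params: RemodelingParams,
                     tumor: TumorParams,
                     steady: SteadyState | None = None,
                     tol_scale: float = ANALYTIC_TOL) -> StabilityReport:
    """Full stability analysis at the variant's reference steady state."""
    if steady is None:
        steady = steady_state(spec, params, tumor)
    J = jacobian_at_steady(spec, params, tumor, steady)
    eigs = np.linalg.eigvals(J)
    a1, a2, a3 = characteristic_invariants(J)
    tol = tol_scale * max(1.0, float(np.abs(J).max()))
    return StabilityReport(
        jacobian=J, eigenvalues=eigs, invariants=(a1, a2, a3),
        routh_hurwitz_stable=routh_hurwitz(a1, a2, a3),
        eig_class=classify_eigenvalues(eigs, tol), tol=tol, steady=steady)


def _scan_row(spec: ModelSpec, params: RemodelingParams,
              tumor: TumorParams) -> dict:
    try:
        rep = stability_report(spec, params, tumor, tol_scale=SCAN_TOL)
    except (ValueError, FloatingPointError, OverflowError):
        return {"a1": np.nan, "a2": np.nan, "a3": np.nan,
                "routh_hurwitz_stable": False,
                "eig_class": EigClass.UNDEFINED.value,
                **{f"{p}{i}": np.nan for i in (1, 2, 3)
                   for p in ("re", "im")}}
    out = {"a1": rep.invariants[0], "a2": rep.invariants[1],
           "a3": rep.invariants[2],
           "routh_hurwitz_stable": rep.routh_hurwitz_stable,
           "eig_class": rep.eig_class.value}
    eigs = np.sort_complex(rep.eigenvalues)
    for i, ev in enumerate(eigs, start=1):
        out[f"re{i}"] = ev.real
        out[f"im{i}"] = ev.imag
    return out


def stability_region_scan(variant: Variant,
                          params: RemodelingParams,
                          mu: float = 0.005,
                          g31_grid: Sequence[float] = (),
                          g32_grid: Sequence[float] = (),
                          sigma_grid: Sequence[float] = (0.05,),
                          r_grids: dict[str, Sequence[float]] | None = None,
                          ) -> pd.DataFrame:
    """Classify stability over a coupling-parameter grid.

    For MODEL2 the grid is the Cartesian product of ``g31_grid``,
    ``g32_grid`` and ``sigma_grid``; for MODEL3 supply ``r_grids`` with
    keys ``r11, r12, r21, r22`` (slice ``r21`` to visualise surfaces).
    Returns a long-format table, one row per grid point, with columns
    (couplings..., sigma, a1, a2, a3, re/im of each eigenvalue,
    eig_class); undefined steady states are recorded, not dropped.
    """
    rows = []
    if variant is Variant.MODEL2:
        for sigma in sigma_grid:
            tumor = TumorParams(mu=mu, sigma=float(sigma))
            for g31 in g31_grid:
                for g32 in g32_grid:
                    spec = ModelSpec(Variant.MODEL2, g31=float(g31),
                                     g32=float(g32))
                    rows.append({"g31": float(g31), "g32": float(g32),
                                 "sigma": float(sigma),
                                 **_scan_row(spec, params, tumor)})
    elif variant is Variant.MODEL3:
        if not r_grids:
            raise ValueError("MODEL3 scan requires r_grids")
        names = ("r11", "r12", "r21", "r22")
        grids = [r_grids.get(n, (0.0,)) for n in names]
        for sigma in sigma_grid:
            tumor = TumorParams(mu=mu, sigma=float(sigma))
            for vals in itertools.product(*grids):
                spec = ModelSpec(Variant.MODEL3,
                                 **dict(zip(names, map(float, vals))))
                rows.append({**dict(zip(names, map(float, vals))),
                             "sigma": float(sigma),
                             **_scan_row(spec, params, tumor)})
    else:
        raise ValueError("region scans are defined for MODEL2 and MODEL3")
    return pd.DataFrame(rows)
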