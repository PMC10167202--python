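"""Domain types and canonical parameters for the tumor-bone-remodeling models.

The bone-remodeling core is the Komarova osteoclast-osteoblast power-law
system: two cell populations ``x1`` (osteoclasts) and ``x2`` (osteoblasts)
whose production is regulated by autocrine and paracrine signalling encoded
as exponents ``g_ij``, plus a bone-mass bookkeeping equation driven by the
excess of each population over its nontrivial steady state.  Tumor burden
enters as a normalized Gompertz variable ``D`` with asymptote ``sigma``.

The canonical physiological parameter set (production/removal rates,
exponents, resorption/formation activities) lives in
:func:`default_params`; all rates are per day, cell counts dimensionless,
bone mass a percentage of its initial value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional


class Variant(Enum):
    """Model variant selector.

    BASE
        Tumor-free Komarova system (x1, x2 only).
    MODEL1
        Tumor modulates the production/removal rates alpha_i, beta_i via
        ``(1-D)`` factors; nine scenarios (0-8) select which rates are
        multiplied or divided by ``(1-D)``.
    MODEL2
        Tumor enters the cell equations as a power-law factor ``D**g31`` /
        ``D**g32`` alongside the paracrine terms.
    MODEL3
        Tumor deforms the autocrine/paracrine exponents themselves through
        modifiers ``r_ij`` (Ayati-style coupling).
    """

    BASE = "base"
    MODEL1 = "model1"
    MODEL2 = "model2"
    MODEL3 = "model3"


@dataclass(frozen=True)
class RemodelingParams:
    """Constants of the osteoclast-osteoblast power-law system.

    Parameters
    ----------
    alpha1, alpha2
        Osteoclast / osteoblast production-rate constants (cells/day scale).
    beta1, beta2
        Osteoclast / osteoblast removal rates (1/day).
    g11, g21, g12, g22
        Dimensionless autocrine/paracrine exponents: ``g_ij`` is the net
        effect of cell type *i* on cell type *j*.
    k1, k2
        Normalized bone resorption / formation activities
        (% per cell per day).
    """

    alpha1: float = 3.0
    alpha2: float = 4.0
    beta1: float = 0.2
    beta2: float = 0.02
    g11: float = 1.1
    g21: float = -0.5
    g12: float = 1.0
    g22: float = 0.0
    k1: float = 0.093
    k2: float = 0.0008

    @property
    def gamma(self) -> float:
        """Exponent combination ``g12*g21 - (1-g11)*(1-g22)``.

        The nontrivial steady state exists only when ``gamma != 0``; it is
        checked lazily at steady-state computation, not at construction.
        """
        return self.g12 * self.g21 - (1.0 - self.g11) * (1.0 - self.g22)


@dataclass(frozen=True)
class TumorParams:
    """Gompertz tumor-burden parameters.

    ``mu`` is the proliferation rate (1/day), ``sigma`` the dimensionless
    asymptotic normalized burden (the tumor equation drives ``D`` toward
    ``sigma``), and ``D0`` the initial normalized burden.
    """

    mu: float = 0.005
    sigma: float = 0.05
    D0: Optional[float] = None

    @property
    def initial_burden(self) -> float:
        """D(0): explicit ``D0`` if given, else ``0.005 * sigma``.

        The default is a small positive fraction of the carrying scale;
        the Gompertz form requires a strictly positive start.
        """
        return self.D0 if self.D0 is not None else 0.005 * self.sigma


@dataclass(frozen=True)
class ModelSpec:
    """Which variant to run and its coupling constants.

    Only the fields of the selected variant are meaningful: ``scenario``
    for MODEL1, ``(g31, g32)`` for MODEL2, ``(r11, r12, r21, r22)`` for
    MODEL3.
    """

    variant: Variant = Variant.BASE
    scenario: int = 0
    g31: float = 0.0
    g32: float = 0.0
    r11: float = 0.0
    r12: float = 0.0
    r21: float = 0.0
    r22: float = 0.0


@dataclass(frozen=True)
class SystemState:
    """Point state of the coupled system.

    x1, x2 : cell counts (strictly positive on any valid trajectory —
    the power-law right-hand sides are undefined otherwise).
    D : normalized tumor burden in [0, 1).
    z : bone mass as a percentage of its initial value.
    """

    x1: float
    x2: float
    D: float = 0.0
    z: float = 100.0


@dataclass(frozen=True)
class SteadyState:
    """Nontrivial fixed point of a variant's cell equations at ``D = sigma``.

    ``source`` records which closed form produced it (e.g. ``"base"``,
    ``"model1/scenario-3"``, ``"model2/as-printed"``, ``"oracle"``).
    """

    x1bar: float
    x2bar: float
    Dbar: float = 0.0
    source: str = "base"


def default_params(sigma: float = 0.05, D0: Optional[float] = None,
                   mu: float = 0.005) -> tuple[RemodelingParams, TumorParams]:
    """Canonical physiological parameter set.

    Returns the standard remodeling constants (alpha1=3, alpha2=4,
    beta1=0.2, beta2=0.02, g11=1.1, g21=-0.5, g12=1, g22=0, k1=0.093,
    k2=0.0008) together with tumor parameters at the requested ``sigma``.
    ``sigma`` and ``D0`` are run-level settings — the reference studies
    sweep sigma over {0.05, 0.10, 0.20, 0.40, 0.80, 0.99} — so they are
    arguments, not constants.
    """
    return RemodelingParams(), TumorParams(mu=mu, sigma=sigma, D0=D0)


#: sigma values conventionally swept in stability studies of these models.
SIGMA_SWEEP = (0.05, 0.10, 0.20, 0.40, 0.80, 0.99)


def validate(params: RemodelingParams,
             tumor: Optional[TumorParams] = None,
             spec: Optional[ModelSpec] = None) -> list[str]:
    """Check all type invariants; return a list of human-readable violations.

    Total on finite numeric input: never raises, an empty list means the
    combination is valid.  ``gamma == 0`` is reported here as a warning-level
    violation because no steady state exists, even though the ODEs
    themselves remain integrable.
    """
    errs: list[str] = []
    for name in ("alpha1", "alpha2", "beta1", "beta2", "k1", "k2"):
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            errs.append(f"{name} must be a finite positive number, got {v!r}")
    for name in ("g11", "g21", "g12", "g22"):
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            errs.append(f"{name} must be a finite number, got {v!r}")
    if not errs and params.gamma == 0.0:
        errs.append("gamma is zero: g12*g21 == (1-g11)*(1-g22); "
                    "no nontrivial steady state exists")

    if tumor is not None:
        if not (math.isfinite(tumor.mu) and tumor.mu >= 0):
            errs.append(f"mu must be >= 0, got {tumor.mu!r}")
        if not (math.isfinite(tumor.sigma) and 0.0 < tumor.sigma < 1.0):
            errs.append(f"sigma must be in (0, 1), got {tumor.sigma!r}")
        else:
            d0 = tumor.initial_burden
            if not (math.isfinite(d0) and 0.0 < d0 <= tumor.sigma):
                errs.append(f"D0 must satisfy 0 < D0 <= sigma, got {d0!r}")

    if spec is not None:
        if spec.variant is Variant.MODEL1 and spec.scenario not in range(9):
            errs.append(f"scenario must be in 0..8, got {spec.scenario!r}")
        for name in ("g31", "g32", "r11", "r12", "r21", "r22"):
            v = getattr(spec, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                errs.append(f"{name} must be a finite number, got {v!r}")
        if spec.variant is Variant.MODEL3 and spec.r12 <= -1.0:
            # 1 + r12*D/sigma must stay nonzero over D in (0, sigma]
            errs.append(
                f"r12 must be > -1 so that 1 + r12*D/sigma != 0 "
                f"for D in (0, sigma], got {spec.r12!r}")
    return errs


def params_to_dict(params: RemodelingParams, tumor: TumorParams,
                   spec: ModelSpec) -> dict:
    """Flatten a (params, tumor, spec) triple into plain config keys."""
    out = {"params": {f.name: getattr(params, f.name)
                      for f in fields(RemodelingParams)},
           "tumor": {"mu": tumor.mu, "sigma": tumor.sigma, "D0": tumor.D0},
           "model": {"variant": spec.variant.value}}
    if spec.variant is Variant.MODEL1:
        out["model"]["scenario"] = spec.scenario
    elif spec.variant is Variant.MODEL2:
        out["model"]["g31"] = spec.g31
        out["model"]["g32"] = spec.g32
    elif spec.variant is Variant.MODEL3:
        out["model"].update(r11=spec.r11, r12=spec.r12,
                            r21=spec.r21, r22=spec.r22)
    return out
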