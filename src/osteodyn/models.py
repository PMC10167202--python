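"""Right-hand sides of all model variants, the tumor law, and bone-mass rate.

Every variant shares one canonical shape for the two cell equations,

    dx1/dt = A1(D) * x1**G11(D) * x2**G21(D) - B1(D) * x1
    dx2/dt = A2(D) * x1**G12(D) * x2**G22(D) - B2(D) * x2

with variant-specific coefficient functions of the tumor burden ``D``:

* model 1 folds the ``(1-D)`` scenario modulations into ``A_i``/``B_i``,
* model 2 folds the tumor power-law factor ``D**g3i`` into ``A_i``,
* model 3 deforms the exponents ``G_ij`` themselves.

The :class:`PowerLawForm` object exposes those coefficients and their exact
D-derivatives so that the stability module can differentiate the system
analytically instead of transcribing printed Jacobian entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

from .params import ModelSpec, RemodelingParams, SteadyState, TumorParams, Variant

LN10 = math.log(10.0)


class Modulation(Enum):
    """How the tumor modulates one rate constant in model 1."""

    ORIGINAL = "original"            # gamma_i
    MULTIPLICATIVE = "multiplicative"  # gamma_i * (1 - D)
    INVERSE = "inverse"              # gamma_i / (1 - D)


_O, _M, _I = Modulation.ORIGINAL, Modulation.MULTIPLICATIVE, Modulation.INVERSE

#: Scenario table for model 1: scenario index -> modulation of
#: (alpha1, alpha2, beta1, beta2).  Encoded as data, not as nine functions,
#: so the table is directly diffable against its printed source.
SCENARIOS: dict[int, tuple[Modulation, Modulation, Modulation, Modulation]] = {
    0: (_O, _O, _O, _O),
    1: (_I, _M, _I, _M),
    2: (_M, _I, _M, _I),
    3: (_I, _M, _M, _I),
    4: (_M, _I, _I, _M),
    5: (_I, _O, _O, _O),
    6: (_O, _O, _M, _O),
    7: (_O, _I, _O, _O),
    8: (_O, _O, _O, _M),
}


def modulate(value: float, mod: Modulation, D: float) -> float:
    """Apply one tumor modulation to a rate constant at burden ``D``."""
    if mod is Modulation.MULTIPLICATIVE:
        return value * (1.0 - D)
    if mod is Modulation.INVERSE:
        if D >= 1.0:
            raise ValueError("inverse modulation requires D < 1")
        return value / (1.0 - D)
    return value


def modulate_deriv(value: float, mod: Modulation, D: float) -> float:
    """d/dD of :func:`modulate` at burden ``D``."""
    if mod is Modulation.MULTIPLICATIVE:
        return -value
    if mod is Modulation.INVERSE:
        return value / (1.0 - D) ** 2
    return 0.0


def gompertz_rate(D: float, mu: float, sigma: float) -> float:
    """Gompertz tumor growth rate ``mu * D * log10(sigma / D)``.

    The logarithm is base 10: the tumor row of the Jacobian is then exactly
    ``-mu/ln 10`` at ``D = sigma``, which is the factor every model
    Jacobian must carry.  ``D = 0`` is a removable singularity
    (``D*log -> 0``) and is defined as rate 0, making extinction an
    unstable fixed point.
    """
    if D < 0.0:
        raise ValueError(f"tumor burden must be nonnegative, got {D}")
    if D == 0.0:
        return 0.0
    return mu * D * math.log10(sigma / D)


def _powers(x1: float, x2: float, e1: float, e2: float) -> float:
    if x1 <= 0.0 or x2 <= 0.0:
        raise ValueError(
            f"cell counts must be strictly positive (fractional powers are "
            f"undefined otherwise), got x1={x1}, x2={x2}")
    return x1 ** e1 * x2 ** e2


def rhs_base(x1: float, x2: float,
             params: RemodelingParams) -> tuple[float, float]:
    """Cell-equation rates of the tumor-free base model."""
    p = params
    prod = _powers(x1, x2, p.g11, p.g21)
    dx1 = p.alpha1 * prod - p.beta1 * x1
    dx2 = p.alpha2 * _powers(x1, x2, p.g12, p.g22) - p.beta2 * x2
    return dx1, dx2


def rhs_model1(x1: float, x2: float, D: float, params: RemodelingParams,
               tumor: TumorParams,
               scenario: int) -> tuple[float, float, float]:
    """Model 1: scenario-modulated rates plus the Gompertz tumor equation."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be in 0..8, got {scenario}")
    if D >= 1.0:
        raise ValueError(f"tumor burden must be < 1, got {D}")
    ma1, ma2, mb1, mb2 = SCENARIOS[scenario]
    p = params
    a1 = modulate(p.alpha1, ma1, D)
    a2 = modulate(p.alpha2, ma2, D)
    b1 = modulate(p.beta1, mb1, D)
    b2 = modulate(p.beta2, mb2, D)
    dx1 = a1 * _powers(x1, x2, p.g11, p.g21) - b1 * x1
    dx2 = a2 * _powers(x1, x2, p.g12, p.g22) - b2 * x2
    return dx1, dx2, gompertz_rate(D, tumor.mu, tumor.sigma)


def rhs_model2(x1: float, x2: float, D: float, params: RemodelingParams,
               tumor: TumorParams, g31: float,
               g32: float) -> tuple[float, float, float]:
    """Model 2: tumor burden as an extra power-law factor D**g31 / D**g32."""
    if D == 0.0 and (g31 < 0.0 or g32 < 0.0):
        raise ValueError("D=0 with a negative tumor exponent diverges; "
                         "start the run with D0 > 0")
    p = params
    dx1 = p.alpha1 * _powers(x1, x2, p.g11, p.g21) * D ** g31 - p.beta1 * x1
    dx2 = p.alpha2 * _powers(x1, x2, p.g12, p.g22) * D ** g32 - p.beta2 * x2
    return dx1, dx2, gompertz_rate(D, tumor.mu, tumor.sigma)


def effective_exponents(params: RemodelingParams, spec: ModelSpec,
                        sigma: float,
                        D: float) -> tuple[float, float, float, float]:
    """Model-3 tumor-deformed exponents (G11, G21, G12, G22) at burden D.

    At ``D = 0`` all four reduce to the unmodified ``g_ij``; ``G12`` is
    defined only while ``1 + r12*D/sigma != 0``.
    """
    s = D / sigma
    den = 1.0 + spec.r12 * s
    if den == 0.0:
        raise ValueError("exponent modifier undefined: 1 + r12*D/sigma == 0")
    return (params.g11 * (1.0 + spec.r11 * s),
            params.g21 * (1.0 + spec.r21 * s),
            params.g12 / den,
            params.g22 - spec.r22 * s)


def rhs_model3(x1: float, x2: float, D: float, params: RemodelingParams,
               tumor: TumorParams, r11: float, r12: float, r21: float,
               r22: float) -> tuple[float, float, float]:
    """Model 3: tumor deforms the autocrine/paracrine exponents."""
    spec = ModelSpec(Variant.MODEL3, r11=r11, r12=r12, r21=r21, r22=r22)
    G11, G21, G12, G22 = effective_exponents(params, spec, tumor.sigma, D)
    p = params
    dx1 = p.alpha1 * _powers(x1, x2, G11, G21) - p.beta1 * x1
    dx2 = p.alpha2 * _powers(x1, x2, G12, G22) - p.beta2 * x2
    return dx1, dx2, gompertz_rate(D, tumor.mu, tumor.sigma)


def bone_mass_rate(x1: float, x2: float, steady: SteadyState,
                   params: RemodelingParams) -> float:
    """Bone-mass rate ``dz/dt = -k1*y1 + k2*y2`` in %/day.

    ``y_i = max(x_i - x_i_bar, 0)`` — only the cells in excess of the
    nontrivial steady state resorb or form bone (half-rectification
    ``2y_i = (x_i - x_i_bar) + |x_i - x_i_bar|``).
    """
    y1 = max(x1 - steady.x1bar, 0.0)
    y2 = max(x2 - steady.x2bar, 0.0)
    return -params.k1 * y1 + params.k2 * y2


# ---------------------------------------------------------------------------
# Canonical coefficient form shared by all variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawForm:
    """Coefficients A_i(D), B_i(D), G_ij(D) of the canonical cell equations.

    ``coeffs(D)`` returns ``(A1, B1, A2, B2, G11, G21, G12, G22)`` and
    ``dcoeffs(D)`` their exact derivatives with respect to ``D``; the
    stability module uses both to build analytic Jacobians.
    """

    coeffs: Callable[[float], tuple[float, ...]]
    dcoeffs: Callable[[float], tuple[float, ...]]

    def cell_rates(self, x1: float, x2: float,
                   D: float) -> tuple[float, float]:
        A1, B1, A2, B2, G11, G21, G12, G22 = self.coeffs(D)
        dx1 = A1 * _powers(x1, x2, G11, G21) - B1 * x1
        dx2 = A2 * _powers(x1, x2, G12, G22) - B2 * x2
        return dx1, dx2


def powerlaw_form(spec: ModelSpec, params: RemodelingParams,
                  tumor: TumorParams) -> PowerLawForm:
    """Build the canonical coefficient form for any variant."""
    p = params
    if spec.variant in (Variant.BASE, Variant.MODEL1):
        mods = SCENARIOS[spec.scenario if spec.variant is Variant.MODEL1
                         else 0]

        def coeffs(D: float) -> tuple[float, ...]:
            return (modulate(p.alpha1, mods[0], D),
                    modulate(p.beta1, mods[2], D),
                    modulate(p.alpha2, mods[1], D),
                    modulate(p.beta2, mods[3], D),
                    p.g11, p.g21, p.g12, p.g22)

        def dcoeffs(D: float) -> tuple[float, ...]:
            return (modulate_deriv(p.alpha1, mods[0], D),
                    modulate_deriv(p.beta1, mods[2], D),
                    modulate_deriv(p.alpha2, mods[1], D),
                    modulate_deriv(p.beta2, mods[3], D),
                    0.0, 0.0, 0.0, 0.0)

    elif spec.variant is Variant.MODEL2:
        g31, g32 = spec.g31, spec.g32

        def coeffs(D: float) -> tuple[float, ...]:
            return (p.alpha1 * D ** g31, p.beta1,
                    p.alpha2 * D ** g32, p.beta2,
                    p.g11, p.g21, p.g12, p.g22)

        def dcoeffs(D: float) -> tuple[float, ...]:
            return (p.alpha1 * g31 * D ** (g31 - 1.0), 0.0,
                    p.alpha2 * g32 * D ** (g32 - 1.0), 0.0,
                    0.0, 0.0, 0.0, 0.0)

    elif spec.variant is Variant.MODEL3:
        sigma = tumor.sigma

        def coeffs(D: float) -> tuple[float, ...]:
            G11, G21, G12, G22 = effective_exponents(p, spec, sigma, D)
            return (p.alpha1, p.beta1, p.alpha2, p.beta2, G11, G21, G12, G22)

        def dcoeffs(D: float) -> tuple[float, ...]:
            s = D / sigma
            return (0.0, 0.0, 0.0, 0.0,
                    p.g11 * spec.r11 / sigma,
                    p.g21 * spec.r21 / sigma,
                    -p.g12 * spec.r12 / sigma / (1.0 + spec.r12 * s) ** 2,
                    -spec.r22 / sigma)

    else:  # pragma: no cover - exhaustive over Variant
        raise ValueError(f"unknown variant {spec.variant!r}")

    return PowerLawForm(coeffs=coeffs, dcoeffs=dcoeffs)


def cell_rates(spec: ModelSpec, params: RemodelingParams,
               tumor: TumorParams, x1: float, x2: float,
               D: float) -> tuple[float, float]:
    """(dx1/dt, dx2/dt) for any variant at burden ``D``."""
    return powerlaw_form(spec, params, tumor).cell_rates(x1, x2, D)


def make_rhs(spec: ModelSpec, params: RemodelingParams, tumor: TumorParams,
             steady: SteadyState | None = None):
    """Uniform ``f(t, y) -> dy/dt`` for initial-value-problem integrators.

    State vector ``y = (x1, x2, D, z)`` for tumor variants, ``(x1, x2, z)``
    for BASE.  Bone mass is included only when ``steady`` (the reference
    fixed point for the rectified excess) is supplied.
    """
    form = powerlaw_form(spec, params, tumor)
    tumor_coupled = spec.variant is not Variant.BASE

    def f(t: float, y) -> list[float]:
        x1, x2 = y[0], y[1]
        D = y[2] if tumor_coupled else 0.0
        dx1, dx2 = form.cell_rates(x1, x2, D)
        out = [dx1, dx2]
        if tumor_coupled:
            out.append(gompertz_rate(D, tumor.mu, tumor.sigma))
        if steady is not None:
            out.append(bone_mass_rate(x1, x2, steady, params))
        return out

    return f
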