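"""Run configuration: YAML parsing, defaults, and the fixture generator.

A config file has four sections (all optional except ``model``)::

    model:  {variant: model1, scenario: 2}          # or g31/g32, r11..r22
    params: {alpha1: 3, alpha2: 4, beta1: 0.2, ...} # remodeling constants
    tumor:  {mu: 0.005, sigma: 0.4, D0: null}       # null D0 -> 0.005*sigma
    run:    {t_end: 2000, dt_out: 1.0, z0: 100,
             x1_0: null, x2_0: null}                # null -> perturbed start

Unknown keys are errors; every violation is collected and reported in one
consolidated message, and the provenance of each value (default vs
user-set) is retained for the run log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .params import (ModelSpec, RemodelingParams, TumorParams, Variant,
                     params_to_dict, validate)


class ConfigError(ValueError):
    """Consolidated configuration failure: ``.errors`` lists every rule."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " +
                         "\n  - ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run description with all defaults filled."""

    spec: ModelSpec
    params: RemodelingParams
    tumor: TumorParams
    t_end: float = 2000.0
    dt_out: float = 1.0
    z0: float = 100.0
    x1_0: Optional[float] = None   # None -> base steady state + 10
    x2_0: Optional[float] = None   # None -> base steady state
    provenance: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        out = params_to_dict(self.params, self.tumor, self.spec)
        out["run"] = {"t_end": self.t_end, "dt_out": self.dt_out,
                      "z0": self.z0, "x1_0": self.x1_0, "x2_0": self.x2_0}
        return out


_RUN_KEYS = {"t_end", "dt_out", "z0", "x1_0", "x2_0"}
_MODEL_KEYS = {"variant", "scenario", "g31", "g32",
               "r11", "r12", "r21", "r22"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(RemodelingParams)}
_TUMOR_KEYS = {"mu", "sigma", "D0"}


def parse_config(raw: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed mapping."""
    errors: list[str] = []
    raw = dict(raw or {})
    unknown = set(raw) - {"model", "params", "tumor", "run"}
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")

    model = dict(raw.get("model") or {})
    pblock = dict(raw.get("params") or {})
    tblock = dict(raw.get("tumor") or {})
    rblock = dict(raw.get("run") or {})
    for name, block, allowed in (("model", model, _MODEL_KEYS),
                                 ("params", pblock, _PARAM_KEYS),
                                 ("tumor", tblock, _TUMOR_KEYS),
                                 ("run", rblock, _RUN_KEYS)):
        bad = set(block) - allowed
        if bad:
            errors.append(f"unknown keys in '{name}': {sorted(bad)}")
            for k in bad:
                block.pop(k)

    provenance = {f"{sec}.{k}": "user"
                  for sec, block in (("model", model), ("params", pblock),
                                     ("tumor", tblock), ("run", rblock))
                  for k in block}

    try:
        variant = Variant(str(model.get("variant", "base")).lower())
    except ValueError:
        errors.append(f"unknown variant {model.get('variant')!r}; expected "
                      f"one of {[v.value for v in Variant]}")
        variant = Variant.BASE
    spec_kwargs = {k: model[k] for k in model if k != "variant"}
    try:
        spec = ModelSpec(variant=variant, **spec_kwargs)
        params = RemodelingParams(**pblock)
        tumor = TumorParams(**tblock)
    except TypeError as exc:
        errors.append(str(exc))
        raise ConfigError(errors)

    errors.extend(validate(params, tumor, spec))
    for key in _RUN_KEYS:
        v = rblock.get(key)
        if v is not None and not isinstance(v, (int, float)):
            errors.append(f"run.{key} must be numeric, got {v!r}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(spec=spec, params=params, tumor=tumor,
                     t_end=float(rblock.get("t_end", 2000.0)),
                     dt_out=float(rblock.get("dt_out", 1.0)),
                     z0=float(rblock.get("z0", 100.0)),
                     x1_0=rblock.get("x1_0"), x2_0=rblock.get("x2_0"),
                     provenance=provenance)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON, a YAML subset) config file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError([f"parse error: {exc}"])
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    return parse_config(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Randomized fixtures for property tests
# ---------------------------------------------------------------------------

def fixture_generator(seed: int, n: int,
                      variant: Variant = Variant.MODEL1,
                      ) -> list[tuple[ModelSpec, RemodelingParams,
                                      TumorParams]]:
    """Draw ``n`` random valid parameter sets for property tests.

    Rates are drawn log-uniformly within a factor of 2 of the canonical
    values, exponents uniformly in moderate windows around them; draws with
    ``|gamma|`` (or ``|Lambda|``) below 1e-3, sigma outside (0.01, 0.99),
    or a steady state outside [1e-6, 1e8] cells are rejected so every
    returned set has a well-conditioned steady state.  Deterministic for a
    given seed.
    """
    from .steady_state import steady_state
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        p = RemodelingParams(
            alpha1=float(3.0 * 2.0 ** rng.uniform(-1, 1)),
            alpha2=float(4.0 * 2.0 ** rng.uniform(-1, 1)),
            beta1=float(0.2 * 2.0 ** rng.uniform(-1, 1)),
            beta2=float(0.02 * 2.0 ** rng.uniform(-1, 1)),
            g11=float(rng.uniform(0.5, 1.4)),
            g21=float(rng.uniform(-0.9, -0.1)),
            g12=float(rng.uniform(0.5, 1.4)),
            g22=float(rng.uniform(-0.4, 0.4)),
        )
        tumor = TumorParams(mu=float(rng.uniform(0.001, 0.02)),
                            sigma=float(rng.uniform(0.02, 0.95)))
        if variant is Variant.BASE:
            spec = ModelSpec(Variant.BASE)
        elif variant is Variant.MODEL1:
            spec = ModelSpec(Variant.MODEL1,
                             scenario=int(rng.integers(0, 9)))
        elif variant is Variant.MODEL2:
            spec = ModelSpec(Variant.MODEL2,
                             g31=float(rng.uniform(-0.3, 0.3)),
                             g32=float(rng.uniform(-0.3, 0.3)))
        else:
            spec = ModelSpec(Variant.MODEL3,
                             r11=float(rng.uniform(-0.4, 0.4)),
                             r12=float(rng.uniform(-0.4, 0.4)),
                             r21=float(rng.uniform(-0.4, 0.4)),
                             r22=float(rng.uniform(-0.4, 0.4)))
        if abs(p.gamma) < 1e-3:
            continue
        if variant is Variant.MODEL3:
            g11e = p.g11 * (1.0 + spec.r11)
            g21e = p.g21 * (1.0 + spec.r21)
            g12e = p.g12 / (1.0 + spec.r12)
            g22e = p.g22 - spec.r22
            lam = g12e * g21e - (1.0 - g11e) * (1.0 - g22e)
            if abs(lam) < 1e-3:
                continue
        if validate(p, tumor, spec):
            continue
        try:
            ss = steady_state(spec, p, tumor, self_consistent=True)
        except (ValueError, OverflowError):
            continue
        if not (1e-6 < ss.x1bar < 1e8 and 1e-6 < ss.x2bar < 1e8):
            continue
        out.append((spec, p, tumor))
    return out
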