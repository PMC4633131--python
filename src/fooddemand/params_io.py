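"""Flat, diffable text serialization of fitted model parameters.

One line per coefficient: ``model<TAB>name<TAB>value`` with 12 significant
digits, so fitted-parameter files can be inspected and compared by eye.
"""

from __future__ import annotations

from typing import Mapping

from .engel_models import GAParams, GBParams, SaturatingCurveParams
from .errors import ConfigError
from .share_models import HAParams, HBParams

__all__ = ["flatten_params", "unflatten_params", "save_params", "load_params"]

_GA_FIELDS = ("alpha1", "alpha2", "beta1", "beta2")
_HA_FIELDS = ("kappa1", "kappa2", "kappa3", "kappa4")
_HB_FIELDS = ("rho1", "rho2", "lambda1", "lambda2")
_GB_FIELDS = tuple(
    f"{part}.{name}"
    for part in ("m_alpha", "m_beta")
    for name in ("omega1", "omega2", "omega3", "t1")
)


def flatten_params(model_id: str, params) -> dict[str, float]:
    """Coefficients of one fitted model as an ordered name->value mapping."""
    if model_id == "gA":
        return {f: getattr(params, f) for f in _GA_FIELDS}
    if model_id == "hA":
        return {f: getattr(params, f) for f in _HA_FIELDS}
    if model_id == "hB":
        return {f: getattr(params, f) for f in _HB_FIELDS}
    if model_id == "gB":
        out = {}
        for key in _GB_FIELDS:
            part, name = key.split(".")
            out[key] = getattr(getattr(params, part), name)
        return out
    raise ConfigError(f"unknown model id {model_id!r}")


def unflatten_params(model_id: str, coefs: Mapping[str, float]):
    """Inverse of :func:`flatten_params`."""
    if model_id == "gA":
        return GAParams(*(float(coefs[f]) for f in _GA_FIELDS))
    if model_id == "hA":
        return HAParams(*(float(coefs[f]) for f in _HA_FIELDS))
    if model_id == "hB":
        return HBParams(*(float(coefs[f]) for f in _HB_FIELDS))
    if model_id == "gB":
        curves = []
        for part in ("m_alpha", "m_beta"):
            curves.append(SaturatingCurveParams(
                *(float(coefs[f"{part}.{n}"]) for n in ("omega1", "omega2", "omega3", "t1"))
            ))
        return GBParams(*curves)
    raise ConfigError(f"unknown model id {model_id!r}")


def save_params(store: Mapping[str, object], path) -> None:
    """Write a {model_id: params} store as flat tab-separated text."""
    with open(path, "w", encoding="utf-8") as fh:
        for model_id, params in store.items():
            for name, value in flatten_params(model_id, params).items():
                fh.write(f"{model_id}\t{name}\t{value:.12g}\n")


def load_params(path) -> dict[str, object]:
    """Read a parameter file written by :func:`save_params`."""
    raw: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ConfigError(f"{path}:{lineno}: expected 3 tab-separated fields")
            model_id, name, value = parts
            raw.setdefault(model_id, {})[name] = float(value)
    return {mid: unflatten_params(mid, coefs) for mid, coefs in raw.items()}
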