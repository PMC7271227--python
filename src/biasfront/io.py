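"""Config files and result serialization for the command-line layer.

Run configurations are YAML mappings; exactly one of a built-in case name or
an explicit kernel (CSV path or inline bins) must be given.  Results are
written as CSV (with a ``#``-prefixed metadata header) or JSON, floats at six
significant digits, deterministic column order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .casestudies import builtin_case
from .errors import ValidationError
from .growth import Demography
from .kernels import RadialKernel

__all__ = ["RunConfig", "load_config", "write_results", "kernel_hash"]

_KNOWN_KEYS = {
    "case",
    "kernel_csv",
    "kernel",
    "a_per_yr",
    "T_yr",
    "K",
    "model",
    "p",
    "p_grid",
    "simulation",
    "output",
    "seed",
}
_SIM_KEYS = {"grid_spacing", "domain_length", "n_generations", "burn_in",
             "front_threshold", "theta_nodes"}


@dataclass(frozen=True)
class RunConfig:
    kernel: RadialKernel
    case: Optional[str] = None
    demography: Optional[Demography] = None
    model: Optional[str] = None
    p: Optional[float] = None
    p_grid: Optional[tuple] = None
    simulation: dict = field(default_factory=dict)
    output: Optional[str] = None
    seed: Optional[int] = None


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ValidationError(f"malformed YAML in {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown keys: {sorted(unknown)}")

    sources = [k for k in ("case", "kernel_csv", "kernel") if k in raw]
    if len(sources) != 1:
        raise ValidationError(
            f"{path}: exactly one of 'case', 'kernel_csv' or 'kernel' required "
            f"(got {sources or 'none'})"
        )
    case_name = None
    if "case" in raw:
        case_name = raw["case"]
        kernel = builtin_case(case_name).kernel
    elif "kernel_csv" in raw:
        kpath = Path(raw["kernel_csv"])
        if not kpath.is_absolute():
            kpath = path.parent / kpath
        if not kpath.exists():
            raise ValidationError(f"kernel file not found: {kpath}")
        kernel = RadialKernel.from_csv(kpath)
    else:
        inline = raw["kernel"]
        if not isinstance(inline, dict) or set(inline) != {"r_km", "prob"}:
            raise ValidationError(
                f"{path}: inline kernel must be a mapping with keys r_km, prob"
            )
        kernel = RadialKernel(tuple(inline["r_km"]), tuple(inline["prob"]))

    demog = None
    if "a_per_yr" in raw or "T_yr" in raw:
        if not ("a_per_yr" in raw and "T_yr" in raw):
            raise ValidationError(f"{path}: a_per_yr and T_yr must be given together")
        demog = Demography(a=float(raw["a_per_yr"]), T=float(raw["T_yr"]),
                           K=float(raw.get("K", 1.0)))

    sim = raw.get("simulation", {}) or {}
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ValidationError(f"{path}: unknown simulation keys: {sorted(bad)}")

    model = raw.get("model")
    if model is not None:
        model = _canonical_model(str(model))

    p_grid = raw.get("p_grid")
    return RunConfig(
        kernel=kernel,
        case=case_name,
        demography=demog,
        model=model,
        p=float(raw["p"]) if "p" in raw else None,
        p_grid=tuple(float(x) for x in p_grid) if p_grid is not None else None,
        simulation=dict(sim),
        output=raw.get("output"),
        seed=int(raw["seed"]) if "seed" in raw else None,
    )


def _canonical_model(name: str) -> str:
    aliases = {
        "1": "model1", "2": "model2", "3": "model3",
        "model1": "model1", "model2": "model2", "model3": "model3",
        "delta": "delta", "iso": "isotropic", "isotropic": "isotropic",
    }
    try:
        return aliases[name]
    except KeyError:
        raise ValidationError(f"unknown model {name!r}") from None


def kernel_hash(kernel: RadialKernel) -> str:
    """Short content hash identifying a kernel in output metadata."""
    payload = ",".join(f"{r:.12g}:{p:.12g}" for r, p in zip(kernel.r, kernel.p))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _metadata(meta: dict) -> dict:
    out = {"library_version": __version__}
    for k, v in meta.items():
        if isinstance(v, RadialKernel):
            out["kernel_hash"] = kernel_hash(v)
        elif v is not None:
            out[k] = v
    return out


def write_results(results, path, format: str = "csv", metadata: Optional[dict] = None):
    """Write a DataFrame or mapping of results with a metadata header.

    CSV gets ``# key: value`` comment lines before the header row; JSON nests
    the payload under ``results`` with a sibling ``metadata`` object.  An
    empty table still produces a header-only file (the caller may warn).
    """
    path = Path(path)
    meta = _metadata(metadata or {})
    if format == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            results.to_csv(fh, index=False, float_format="%.6g")
    elif format == "json":
        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        else:
            payload = results
        with open(path, "w") as fh:
            json.dump({"metadata": meta, "results": payload}, fh, indent=2,
                      default=_json_default)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown format {format!r}; use 'csv' or 'json'")


def _json_default(obj):
    try:
        return float(obj)
    except (TypeError, ValueError):
        return str(obj)


def read_results_csv(path) -> pd.DataFrame:
    """Parse back a CSV written by :func:`write_results` (skips ``#`` lines)."""
    return pd.read_csv(path, comment="#")
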