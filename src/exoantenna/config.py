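"""Run configuration: schema, validation, defaults, and result serialization.

One YAML (or JSON — YAML is a superset) config file drives every command.
Unknown keys are rejected with an error naming each offender; every default
is resolved at load time and the fully-resolved config can be echoed next
to results so a run is reproducible from its outputs alone.

Rates under ``thermo:`` may be given either as plain numbers (s^-1) or as
timescale strings with a unit suffix ("10 ps", "1 ns", "10 ms", "2 s"),
which are converted to rates as 1/timescale.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .antenna import (PhotosystemGraph, ReactionCentre, assign_funnel,
                      build_branched, build_illustrative)
from .photophysics import AbsorptionProfile, ThermoParams
from .spectra import StellarModel, load_flux, planet_flux

__all__ = ["RunConfig", "ConfigError", "load_config", "write_result",
           "parse_rate"]

_TIME_UNITS = {"fs": 1e-15, "ps": 1e-12, "ns": 1e-9, "us": 1e-6,
               "ms": 1e-3, "s": 1.0}
_RATE_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(fs|ps|ns|us|ms|s)\s*$")


class ConfigError(ValueError):
    """Raised for schema violations; message lists each offending key."""


def parse_rate(value) -> float:
    """Parse a rate given as s^-1 (number) or a timescale string ("10 ps")."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _RATE_RE.match(str(value))
    if not m:
        raise ConfigError(f"cannot parse rate/timescale {value!r}")
    return 1.0 / (float(m.group(1)) * _TIME_UNITS[m.group(2)])


_SCHEMA = {
    "star": {"t_star", "r_star", "distance"},
    "flux": {"source", "path"},
    "thermo": {"temperature", "k_hop", "k_diss", "k_trap", "k_out"},
    "rc": {"n_pigments", "lambda_peak", "width"},
    "topology": {"kind", "n_pigments", "n_branches", "n_shells",
                 "lambda_peak", "lambda_inner", "delta_lambda", "width",
                 "sigma_peak"},
    "sweep": {"family", "lambda_min", "lambda_max", "lambda_step",
              "delta_min", "delta_max", "delta_step", "sizes"},
}
_TOP_LEVEL = set(_SCHEMA) | {"seed", "raw_overlap"}


@dataclass(frozen=True)
class RunConfig:
    """A fully-resolved run configuration."""

    star: dict
    flux: dict
    thermo: ThermoParams
    rc: ReactionCentre
    topology: dict
    sweep: dict | None = None
    seed: int | None = None
    raw_overlap: bool = True

    def stellar_model(self) -> StellarModel:
        return StellarModel.from_solar(self.star["t_star"], self.star["r_star"])

    def planet_flux(self):
        """Resolve the light environment: loaded file or blackbody stand-in."""
        if self.flux["source"] == "file":
            return load_flux(self.flux["path"])
        dist = self.star["distance"]
        return planet_flux(self.stellar_model(),
                           None if dist == "mid" else float(dist))

    def graph(self) -> PhotosystemGraph:
        topo = self.topology
        kind = topo["kind"]
        if kind == "illustrative":
            return build_illustrative(topo["n_pigments"], topo["lambda_peak"],
                                      width=topo["width"],
                                      sigma_peak=topo["sigma_peak"], rc=self.rc)
        graph = build_branched(topo["n_branches"], topo["n_shells"],
                               topo["n_pigments"],
                               [topo.get("lambda_inner") or topo["lambda_peak"]],
                               width=topo["width"],
                               sigma_peak=topo["sigma_peak"], rc=self.rc)
        if topo.get("delta_lambda"):
            graph = assign_funnel(graph,
                                  topo.get("lambda_inner") or topo["lambda_peak"],
                                  topo["delta_lambda"])
        return graph

    def resolved(self) -> dict:
        """Echo of the config with every default filled in."""
        out = {
            "star": dict(self.star),
            "flux": dict(self.flux),
            "thermo": {k: getattr(self.thermo, k) for k in
                       ("temperature", "k_hop", "k_diss", "k_trap", "k_out")},
            "rc": {"n_pigments": self.rc.n_pigments,
                   "lambda_peak": self.rc.profile.lambda_peak,
                   "width": self.rc.profile.width},
            "topology": dict(self.topology),
            "raw_overlap": self.raw_overlap,
        }
        if self.sweep is not None:
            out["sweep"] = dict(self.sweep)
        if self.seed is not None:
            out["seed"] = self.seed
        return out


def _check_unknown(section: str, data: dict, allowed: set) -> list[str]:
    return [f"{section}.{key}" for key in data if key not in allowed]


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a config file (YAML/JSON) or an equivalent dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_dict)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    bad = [k for k in data if k not in _TOP_LEVEL]
    for section, allowed in _SCHEMA.items():
        sub = data.get(section) or {}
        if not isinstance(sub, dict):
            bad.append(section)
            continue
        bad.extend(_check_unknown(section, sub, allowed))
    if bad:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))

    star = dict(data.get("star") or {})
    if "t_star" not in star or "r_star" not in star:
        raise ConfigError("star.t_star and star.r_star are required")
    star.setdefault("distance", "mid")

    flux = dict(data.get("flux") or {})
    flux.setdefault("source", "blackbody")
    if flux["source"] not in ("blackbody", "file"):
        raise ConfigError(f"flux.source must be blackbody|file, got {flux['source']!r}")
    if flux["source"] == "file" and not flux.get("path"):
        raise ConfigError("flux.path is required when flux.source = file")
    flux.setdefault("path", None)

    th = dict(data.get("thermo") or {})
    thermo = ThermoParams(
        temperature=float(th.get("temperature", 300.0)),
        k_hop=parse_rate(th.get("k_hop", "10 ps")),
        k_diss=parse_rate(th.get("k_diss", "1 ns")),
        k_trap=parse_rate(th.get("k_trap", "5 ps")),
        k_out=parse_rate(th.get("k_out", "10 ms")),
    )

    rc_d = dict(data.get("rc") or {})
    rc = ReactionCentre(
        n_pigments=int(rc_d.get("n_pigments", 10)),
        profile=AbsorptionProfile(float(rc_d.get("lambda_peak", 680.0)),
                                  float(rc_d.get("width", 10.0))))

    topo = dict(data.get("topology") or {})
    topo.setdefault("kind", "illustrative")
    if topo["kind"] not in ("illustrative", "branched"):
        raise ConfigError(f"topology.kind must be illustrative|branched, "
                          f"got {topo['kind']!r}")
    topo.setdefault("n_pigments", 100)
    topo.setdefault("n_branches", 6)
    topo.setdefault("n_shells", 1)
    topo.setdefault("lambda_peak", 665.0)
    topo.setdefault("lambda_inner", None)
    topo.setdefault("delta_lambda", 0.0)
    topo.setdefault("width", 10.0)
    topo.setdefault("sigma_peak", 1e-20)

    sweep = data.get("sweep")
    seed = data.get("seed")
    return RunConfig(star=star, flux=flux, thermo=thermo, rc=rc,
                     topology=topo, sweep=None if sweep is None else dict(sweep),
                     seed=None if seed is None else int(seed),
                     raw_overlap=bool(data.get("raw_overlap", True)))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_result(result, path, fmt: str = "json",
                 provenance: dict | None = None) -> None:
    """Serialize a solve result or sweep table with stable formatting.

    JSON output has sorted keys and no float repr jitter (two identical
    runs produce byte-identical files); CSV column order is the sweep
    table's documented order.
    """
    path = Path(path)
    if fmt == "json":
        payload = result.as_dict() if hasattr(result, "as_dict") else result
        doc = {"result": _jsonable(payload)}
        if provenance:
            doc["provenance"] = _jsonable(provenance)
        path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    elif fmt == "csv":
        if hasattr(result, "write_csv"):
            result.write_csv(path)
        else:
            raise ConfigError("csv output is only available for sweep results")
    else:
        raise ConfigError(f"unknown output format {fmt!r}")
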