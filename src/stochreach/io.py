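"""Model configuration files: schema, loading, writing.

A model config is a YAML (or JSON) document describing a reaction
network together with everything a reachability run needs: input
placement and bounds, parameter-uncertainty intervals, the initial set,
horizon/step and reporting options.  The three worked example models
ship as packaged configs under ``model_configs/``.

Schema (top-level keys)::

    name:         string
    species:      [names...]
    parameters:   {name: value, ...}
    reactions:    [{stoichiometry: [per-species change], propensity: expr}, ...]
    input:        {bounds: [lo, hi]}            # optional; 'mu' in propensities
    initial:
      means:        {species: value | [lo, hi]}
      covariances:  {var_X | cov_X_Y: value | [lo, hi]}   # optional, default 0
    reach:
      horizon: T
      step: tau
      order_limit: 20          # optional
      analysis: lna | macroscopic    # default lna
    uncertainty:  [{parameter: name, delta: abs | delta_fraction: rel}, ...]
    nonnegative:  [state names reported with a zero clamp]

Propensity expressions use species names, parameter names and the input
multiplier ``mu``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .moment_odes import (
    MomentSystem,
    ReactionNetwork,
    lna_derive,
    macroscopic_system,
)
from .reach_linear import ParameterUncertainty, ReachConfig
from .zonotope import Zonotope

__all__ = ["ModelConfig", "load_model", "load_packaged_model", "packaged_model_path"]


@dataclass
class ModelConfig:
    """Parsed model document; builds the runtime objects on demand."""

    name: str
    species: list[str]
    parameters: dict[str, float]
    reactions: list[dict]
    input_bounds: tuple[float, float] | None = None
    initial_means: dict[str, object] = field(default_factory=dict)
    initial_covariances: dict[str, object] = field(default_factory=dict)
    reach: dict = field(default_factory=dict)
    uncertainty: list[dict] = field(default_factory=list)
    nonnegative: list[str] = field(default_factory=list)

    # -- parsing -----------------------------------------------------------
    @staticmethod
    def from_dict(doc: dict) -> "ModelConfig":
        for key in ("species", "reactions"):
            if key not in doc:
                raise ValueError(f"config missing required key {key!r}")
        species = list(doc["species"])
        reactions = []
        for i, r in enumerate(doc["reactions"]):
            if "stoichiometry" not in r or "propensity" not in r:
                raise ValueError(
                    f"reactions[{i}] needs 'stoichiometry' and 'propensity'"
                )
            if len(r["stoichiometry"]) != len(species):
                raise ValueError(
                    f"reactions[{i}].stoichiometry length != number of species"
                )
            reactions.append(
                {
                    "stoichiometry": [float(v) for v in r["stoichiometry"]],
                    "propensity": str(r["propensity"]),
                }
            )
        bounds = None
        if doc.get("input") is not None:
            b = doc["input"].get("bounds")
            if b is not None:
                bounds = (float(b[0]), float(b[1]))
                if bounds[1] < bounds[0]:
                    raise ValueError("input.bounds upper < lower")
        initial = doc.get("initial") or {}
        return ModelConfig(
            name=str(doc.get("name", "")),
            species=species,
            parameters={k: float(v) for k, v in (doc.get("parameters") or {}).items()},
            reactions=reactions,
            input_bounds=bounds,
            initial_means=dict(initial.get("means") or {}),
            initial_covariances=dict(initial.get("covariances") or {}),
            reach=dict(doc.get("reach") or {}),
            uncertainty=[dict(u) for u in (doc.get("uncertainty") or [])],
            nonnegative=list(doc.get("nonnegative") or []),
        )

    def to_dict(self) -> dict:
        doc: dict = {
            "name": self.name,
            "species": list(self.species),
            "parameters": dict(self.parameters),
            "reactions": [dict(r) for r in self.reactions],
        }
        if self.input_bounds is not None:
            doc["input"] = {"bounds": list(self.input_bounds)}
        doc["initial"] = {
            "means": dict(self.initial_means),
            "covariances": dict(self.initial_covariances),
        }
        doc["reach"] = dict(self.reach)
        if self.uncertainty:
            doc["uncertainty"] = [dict(u) for u in self.uncertainty]
        if self.nonnegative:
            doc["nonnegative"] = list(self.nonnegative)
        return doc

    # -- runtime objects ---------------------------------------------------
    def network(self) -> ReactionNetwork:
        S = np.array([r["stoichiometry"] for r in self.reactions]).T
        return ReactionNetwork(
            species=list(self.species),
            stoichiometry=S,
            propensities=[r["propensity"] for r in self.reactions],
            parameters=dict(self.parameters),
            name=self.name,
        )

    @property
    def analysis(self) -> str:
        return str(self.reach.get("analysis", "lna"))

    def system(self) -> MomentSystem:
        net = self.network()
        if self.analysis == "macroscopic":
            return macroscopic_system(net)
        if self.analysis != "lna":
            raise ValueError(f"unknown analysis kind {self.analysis!r}")
        return lna_derive(net)

    def reach_config(self, **overrides) -> ReachConfig:
        r = dict(self.reach)
        r.pop("analysis", None)
        u_c, u_d = 0.0, 0.0
        if self.input_bounds is not None:
            lo, hi = self.input_bounds
            u_c, u_d = 0.5 * (lo + hi), 0.5 * (hi - lo)
        uncs = []
        for u in self.uncertainty:
            name = u["parameter"]
            if name not in self.parameters:
                raise ValueError(f"uncertainty on unknown parameter {name!r}")
            nominal = float(u.get("nominal", self.parameters[name]))
            if "delta" in u:
                delta = float(u["delta"])
            elif "delta_fraction" in u:
                delta = abs(nominal) * float(u["delta_fraction"])
            else:
                raise ValueError(
                    f"uncertainty for {name!r} needs 'delta' or 'delta_fraction'"
                )
            uncs.append(ParameterUncertainty(name, nominal, delta))
        cfg = dict(
            horizon=float(r["horizon"]),
            step=float(r["step"]),
            input_center=u_c,
            input_halfwidth=u_d,
            order_limit=float(r.get("order_limit", 20)),
            uncertainties=uncs,
            nonnegative=list(self.nonnegative),
        )
        cfg.update(overrides)
        return ReachConfig(**cfg)

    def initial_set(self, sys: MomentSystem | None = None) -> Zonotope:
        """Initial zonotope in the analysis state space.

        Scalar entries are points; ``[lo, hi]`` entries become box
        generators.  Unspecified covariance coordinates start at zero
        (no molecules measured / declared spread only).
        """
        sys = sys or self.system()
        lo = np.zeros(sys.n)
        hi = np.zeros(sys.n)

        def assign(name: str, value) -> None:
            if name not in sys.state_names:
                raise ValueError(f"unknown state coordinate {name!r} in initial set")
            i = sys.state_names.index(name)
            if isinstance(value, (list, tuple)):
                lo[i], hi[i] = float(value[0]), float(value[1])
            else:
                lo[i] = hi[i] = float(value)

        for sp_name, v in self.initial_means.items():
            if sp_name not in self.species:
                raise ValueError(f"initial mean for unknown species {sp_name!r}")
            assign(f"mean_{sp_name}", v)
        if self.analysis != "macroscopic":
            for cname, v in self.initial_covariances.items():
                assign(cname, v)
        return Zonotope.from_box(lo, hi)


def _read_doc(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_config(path) -> ModelConfig:
    doc = _read_doc(path)
    try:
        return ModelConfig.from_dict(doc)
    except (KeyError, ValueError, TypeError) as e:
        raise ValueError(f"invalid model config {path}: {e}") from e


def save_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_model(path) -> tuple[ReactionNetwork, ReachConfig, Zonotope]:
    """Load a config file into (network, reach settings, initial set)."""
    cfg = load_config(path)
    sys = cfg.system()
    return cfg.network(), cfg.reach_config(), cfg.initial_set(sys)


def packaged_model_path(name: str) -> Path:
    """Filesystem path of a packaged example model config."""
    ref = resources.files("stochreach") / "model_configs" / f"{name}.yaml"
    p = Path(str(ref))
    if not p.exists():
        raise KeyError(f"no packaged model named {name!r}")
    return p


def load_packaged_model(name: str) -> ModelConfig:
    return load_config(packaged_model_path(name))
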