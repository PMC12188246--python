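"""Config and result serialization.

Network topologies are stored as a small JSON dialect::

    {
      "id": "wnt3",
      "nodes": [{"name": "WNT2", "diffusible": true, "diffusion": 1.0,
                 "role": "ligand"}, ...],
      "edges": [{"source": "WNT2", "target": "CTNNB1", "sign": "+",
                 "tested": true}, ...]
    }

``sign`` is ``"+"``, ``"-"`` or ``"?"`` (ambiguous).  The same structure is
accepted in YAML.  Writing is canonical (fixed key order, 2-space indent,
trailing newline) so write(read(config)) round-trips byte-identically.
Schema violations are rejected with the JSON-path of the offending entry.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .network import AMBIGUOUS, Interaction, NetworkTopology, Node, ROLE_TAGS


class ConfigError(ValueError):
    """Malformed or schema-violating network config."""


_SIGN_TO_STR = {1: "+", -1: "-", AMBIGUOUS: "?"}
_STR_TO_SIGN = {"+": 1, "-": -1, "?": AMBIGUOUS}

_NODE_KEYS = {"name", "diffusible", "diffusion", "role"}
_EDGE_KEYS = {"source", "target", "sign", "tested"}
_TOP_KEYS = {"id", "nodes", "edges", "notes"}


def _require(cond: bool, where: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{where}: {msg}")


def topology_to_dict(t: NetworkTopology) -> dict:
    d: dict[str, Any] = {"id": t.id}
    if t.notes:
        d["notes"] = t.notes
    d["nodes"] = [
        {
            "name": n.name,
            "diffusible": n.diffusible,
            "diffusion": n.default_diffusion,
            "role": n.role_tag,
        }
        for n in t.nodes
    ]
    d["edges"] = [
        {
            "source": e.source,
            "target": e.target,
            "sign": _SIGN_TO_STR[e.sign],
            "tested": e.tested,
        }
        for e in t.interactions
    ]
    return d


def topology_from_dict(data: Any, where: str = "config") -> NetworkTopology:
    _require(isinstance(data, dict), where, "expected a mapping at top level")
    unknown = set(data) - _TOP_KEYS
    _require(not unknown, where, f"unknown keys: {sorted(unknown)}")
    for key in ("id", "nodes", "edges"):
        _require(key in data, where, f"missing required key {key!r}")
    _require(isinstance(data["id"], str), f"{where}.id", "must be a string")
    _require(isinstance(data["nodes"], list), f"{where}.nodes", "must be a list")
    _require(isinstance(data["edges"], list), f"{where}.edges", "must be a list")

    nodes = []
    for i, nd in enumerate(data["nodes"]):
        loc = f"{where}.nodes[{i}]"
        _require(isinstance(nd, dict), loc, "expected a mapping")
        unknown = set(nd) - _NODE_KEYS
        _require(not unknown, loc, f"unknown keys: {sorted(unknown)}")
        for key in ("name", "diffusible"):
            _require(key in nd, loc, f"missing required key {key!r}")
        _require(isinstance(nd["name"], str), f"{loc}.name", "must be a string")
        _require(
            isinstance(nd["diffusible"], bool), f"{loc}.diffusible", "must be a boolean"
        )
        diffusion = nd.get("diffusion", 1.0 if nd["diffusible"] else 0.0)
        _require(
            isinstance(diffusion, (int, float)) and not isinstance(diffusion, bool),
            f"{loc}.diffusion",
            "must be a number",
        )
        role = nd.get("role", "transcription_factor")
        _require(role in ROLE_TAGS, f"{loc}.role", f"must be one of {ROLE_TAGS}")
        try:
            nodes.append(
                Node(
                    name=nd["name"],
                    diffusible=nd["diffusible"],
                    default_diffusion=float(diffusion),
                    role_tag=role,
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{loc}: {exc}") from None

    edges = []
    for i, ed in enumerate(data["edges"]):
        loc = f"{where}.edges[{i}]"
        _require(isinstance(ed, dict), loc, "expected a mapping")
        unknown = set(ed) - _EDGE_KEYS
        _require(not unknown, loc, f"unknown keys: {sorted(unknown)}")
        for key in ("source", "target", "sign"):
            _require(key in ed, loc, f"missing required key {key!r}")
        _require(
            ed["sign"] in _STR_TO_SIGN,
            f"{loc}.sign",
            f"must be one of {sorted(_STR_TO_SIGN)} "
            f"(edge {ed.get('source')}->{ed.get('target')})",
        )
        tested = ed.get("tested", True)
        _require(isinstance(tested, bool), f"{loc}.tested", "must be a boolean")
        edges.append(
            Interaction(
                source=ed["source"],
                target=ed["target"],
                sign=_STR_TO_SIGN[ed["sign"]],
                tested=tested,
            )
        )

    notes = data.get("notes", "")
    _require(isinstance(notes, str), f"{where}.notes", "must be a string")
    try:
        return NetworkTopology(
            id=data["id"], nodes=tuple(nodes), interactions=tuple(edges), notes=notes
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def read_network_config(path: str | Path) -> NetworkTopology:
    """Read a topology from a JSON (or YAML) config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from None
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(
                f"{path}:{exc.lineno}:{exc.colno}: invalid JSON: {exc.msg}"
            ) from None
    return topology_from_dict(data, where=str(path))


def write_network_config(t: NetworkTopology, path: str | Path) -> None:
    """Write a topology as canonical JSON (stable byte-level round trip)."""
    Path(path).write_text(canonical_json(topology_to_dict(t)))


def canonical_json(data: Any) -> str:
    return json.dumps(data, indent=2, ensure_ascii=False) + "\n"


def config_hash(t: NetworkTopology) -> str:
    """SHA-256 of the canonical serialization; stable across runs."""
    return hashlib.sha256(canonical_json(topology_to_dict(t)).encode()).hexdigest()


# -- kinetic model parameter files --------------------------------------------


def kinetic_model_to_dict(m) -> dict:
    """Serialize a KineticModel's parameters (topology stored by id only)."""
    t = m.topology
    strengths = {}
    for e in t.interactions:
        i, j = t.index(e.target), t.index(e.source)
        val = m.strengths[i, j]
        if val != 0.0:
            strengths[f"{e.source}->{e.target}"] = abs(float(val))
    return {
        "topology_id": t.id,
        "strengths": strengths,
        "decay": {n.name: float(d) for n, d in zip(t.nodes, m.decay)},
        "diffusion": {
            n.name: float(d) for n, d in zip(t.nodes, m.diffusion) if n.diffusible
        },
        "saturation": float(m.saturation),
    }


def kinetic_model_from_dict(t: NetworkTopology, data: dict):
    from .stability import build_kinetic_model

    strengths = {}
    for key, mag in data["strengths"].items():
        source, target = key.split("->", 1)
        strengths[(source, target)] = float(mag)
    decay = np.array([data["decay"][n.name] for n in t.nodes], dtype=float)
    diffusion_overrides = {k: float(v) for k, v in data.get("diffusion", {}).items()}
    return build_kinetic_model(
        t,
        strengths,
        decay,
        diffusion_overrides=diffusion_overrides,
        saturation=float(data.get("saturation", 1.0)),
    )


# -- run manifests ------------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    kind: str
    seed: Optional[int] = None
    config_hash: Optional[str] = None


def run_manifest(
    outputs: list[ManifestEntry], command_line: Optional[list[str]] = None
) -> dict:
    """Machine-readable record of what a run produced and how."""
    from . import __version__

    return {
        "tool": "digituring",
        "version": __version__,
        "command": command_line if command_line is not None else sys.argv,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "outputs": [asdict(e) for e in outputs],
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(canonical_json(manifest))
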