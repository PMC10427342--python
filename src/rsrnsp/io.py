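"""Configuration files, run archives, event logs and manifests.

A run archive is a single compressed ``.npz`` holding every array of the
network (weights, mask, thresholds, traces, states), a JSON echo of the
configuration, and the bit-generator state of the model RNG, so training
can checkpoint and resume bit-exactly.  Structural events stream to a
tab-separated log; a JSON manifest ties a run's config, seed and metrics
together for reproduction.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .config import ConfigurationError, NetworkConfig, TrainProtocol
from .plasticity import StructuralEvent
from .training import Model
from .analysis import ConnectivityLog

_NETWORK_KEYS = ("w_ee", "w_ei", "w_ie", "w_oe", "c_ee", "s_e", "s_in",
                 "s_o", "theta_e", "theta_in", "theta_o", "e_ee", "e_oe")


def load_config(path) -> tuple[NetworkConfig, TrainProtocol]:
    """Read a YAML experiment file into validated config objects.

    The file may contain two top-level sections, ``network`` and
    ``protocol`` (either may be omitted for pure defaults); unknown keys
    in either section are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must hold a mapping")
    unknown = set(raw) - {"network", "protocol"}
    if unknown:
        raise ConfigurationError(
            f"unknown top-level sections: {sorted(unknown)}"
        )
    cfg = NetworkConfig.from_dict(raw.get("network") or {})
    proto = TrainProtocol.from_dict(raw.get("protocol") or {})
    return cfg, proto


def save_config(path, config: NetworkConfig,
                protocol: TrainProtocol | None = None) -> None:
    doc = {"network": config.to_dict()}
    if protocol is not None:
        doc["protocol"] = protocol.to_dict()
    Path(path).write_text(yaml.safe_dump(_plainify(doc), sort_keys=False))


def _plainify(obj):
    """Recursively convert tuples/numpy scalars for clean YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_network(path, model: Model) -> None:
    """Write the model to a compressed array archive (see module doc)."""
    W, S = model.weights, model.state
    arrays = dict(w_ee=W.w_ee, w_ei=W.w_ei, w_ie=W.w_ie, w_oe=W.w_oe,
                  c_ee=W.c_ee, s_e=S.s_e, s_in=S.s_in, s_o=S.s_o,
                  theta_e=S.theta_e, theta_in=S.theta_in,
                  theta_o=S.theta_o, e_ee=S.e_ee, e_oe=S.e_oe)
    meta = {
        "config": _plainify(model.config.to_dict()),
        "symbols": list(model.symbols),
        "baseline_b": float(S.baseline_b),
        "t": int(S.t),
        "rng_state": model.rng.bit_generator.state,
    }
    np.savez_compressed(path, meta=json.dumps(_plainify(meta)), **arrays)


def load_network(path) -> Model:
    """Rebuild a model bit-exactly from a run archive."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        arrays = {k: npz[k] for k in _NETWORK_KEYS}
    config = NetworkConfig.from_dict(meta["config"])
    model = Model(config, meta["symbols"])
    W, S = model.weights, model.state
    W.w_ee, W.w_ei, W.w_ie, W.w_oe = (arrays["w_ee"], arrays["w_ei"],
                                      arrays["w_ie"], arrays["w_oe"])
    W.c_ee = arrays["c_ee"].astype(bool)
    S.s_e, S.s_in, S.s_o = arrays["s_e"], arrays["s_in"], arrays["s_o"]
    S.theta_e, S.theta_in, S.theta_o = (arrays["theta_e"],
                                        arrays["theta_in"],
                                        arrays["theta_o"])
    S.e_ee, S.e_oe = arrays["e_ee"], arrays["e_oe"]
    S.baseline_b = meta["baseline_b"]
    S.t = meta["t"]
    model.rng.bit_generator.state = meta["rng_state"]
    return model


def write_event_log(path, events, initial_mask: np.ndarray | None = None
                    ) -> None:
    """Append-style TSV event log: t, kind, i, j, weight."""
    lines = ["t\tkind\ti\tj\tweight"]
    for ev in events:
        lines.append(f"{ev.t}\t{ev.kind}\t{ev.i}\t{ev.j}\t{ev.weight:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")
    if initial_mask is not None:
        np.savez_compressed(str(path) + ".mask.npz", initial_mask=initial_mask)


def read_event_log(path) -> list[StructuralEvent]:
    events = []
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        t, kind, i, j, w = line.split("\t")
        events.append(StructuralEvent(kind, int(i), int(j), int(t), float(w)))
    return events


def read_connectivity_log(path, final_weights=None) -> ConnectivityLog:
    events = read_event_log(path)
    with np.load(str(path) + ".mask.npz") as npz:
        initial_mask = npz["initial_mask"].astype(bool)
    return ConnectivityLog(events, initial_mask, final_weights)


def write_manifest(path, config: NetworkConfig, protocol: TrainProtocol,
                   metrics: dict, artifacts: dict | None = None) -> None:
    """JSON sidecar from which a run can be reproduced exactly."""
    doc = {
        "config": _plainify(config.to_dict()),
        "protocol": _plainify(protocol.to_dict()),
        "seed": config.seed,
        "metrics": _plainify(metrics),
        "artifacts": _plainify(artifacts or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def sequence_to_text(path, seq) -> None:
    Path(path).write_text(seq.to_text())


def sequence_from_text(path) -> list[str]:
    return Path(path).read_text().split()
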