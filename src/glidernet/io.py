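"""HDF5 / YAML serialization of stimuli, populations, responses and networks."""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np
import yaml

from .network import NetworkParams
from .surrogates import SurrogateNeuron

__all__ = [
    "save_textures",
    "load_textures",
    "save_responses",
    "load_responses",
    "save_network",
    "load_network",
    "save_population",
    "load_population",
]


def save_textures(path, grids: np.ndarray, class_name: str, seed: int) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("grids", data=np.asarray(grids, dtype=np.int8))
        d.attrs["class_name"] = class_name
        d.attrs["seed"] = int(seed)


def load_textures(path) -> tuple[np.ndarray, str, int]:
    with h5py.File(path, "r") as f:
        d = f["grids"]
        return d[...], str(d.attrs["class_name"]), int(d.attrs["seed"])


def save_responses(path, counts: np.ndarray, class_names: list[str]) -> None:
    """Counts array (n_neurons, n_classes, n_examples, n_repeats, n_bins)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=np.asarray(counts, dtype=np.uint16))
        d.attrs["class_names"] = [str(c) for c in class_names]


def load_responses(path) -> tuple[np.ndarray, list[str]]:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        return d[...].astype(np.float64), [str(c) for c in d.attrs["class_names"]]


def save_network(path, params: NetworkParams, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for name in NetworkParams._FIELDS:
            f.create_dataset(name, data=getattr(params, name))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_network(path) -> tuple[NetworkParams, dict]:
    with h5py.File(path, "r") as f:
        params = NetworkParams(**{n: f[n][...] for n in NetworkParams._FIELDS})
        return params, dict(f.attrs)


def save_population(path, neurons: list[SurrogateNeuron]) -> None:
    records = []
    for n in neurons:
        d = asdict(n)
        d["rf_corner"] = list(d["rf_corner"])
        records.append(d)
    with open(path, "w") as f:
        yaml.safe_dump({"neurons": records}, f, sort_keys=False)


def load_population(path) -> list[SurrogateNeuron]:
    with open(path) as f:
        data = yaml.safe_load(f)
    out = []
    for d in data["neurons"]:
        d["rf_corner"] = tuple(d["rf_corner"])
        out.append(SurrogateNeuron(**d))
    return out
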