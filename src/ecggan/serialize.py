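"""Model checkpoints: one ``.npz`` weight file plus a JSON sidecar.

The sidecar records the model kind, its full configuration, the seed and
library versions, so a checkpoint is sufficient to rebuild the model and
replay a run exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import numpy as np

from . import __version__
from .baselines import AEConfig, RecurrentAutoencoder
from .errors import FormatError
from .models import (
    ConvLayerSpec,
    DiscriminatorSpec,
    Generator,
    GeneratorConfig,
    PoolLayerSpec,
    build_discriminator,
    build_generator,
)

__all__ = ["save_checkpoint", "load_checkpoint"]


def _config_to_dict(model) -> Tuple[str, dict]:
    if isinstance(model, Generator):
        c = model.config
        return "generator", {
            "noise_dim": c.noise_dim,
            "seq_len": c.seq_len,
            "hidden_units": c.hidden_units,
            "n_bilstm_layers": c.n_bilstm_layers,
            "dropout_p": c.dropout_p,
            "output_dim": c.output_dim,
            "seed": c.seed,
        }
    if isinstance(model, RecurrentAutoencoder):
        return "autoencoder", model.config.to_dict()
    spec = model.spec
    layers = []
    for layer in spec.layers:
        if isinstance(layer, ConvLayerSpec):
            layers.append(
                {
                    "type": "conv",
                    "n_filters": layer.n_filters,
                    "filter_length": layer.filter_length,
                    "stride": layer.stride,
                    "zero_padding": layer.zero_padding,
                }
            )
        else:
            layers.append(
                {"type": "pool", "window": layer.window, "stride": layer.stride}
            )
    return "discriminator", {
        "kind": spec.kind,
        "input_length": spec.input_length,
        "layers": layers,
        "fc_units": spec.fc_units,
        "hidden_sizes": list(spec.hidden_sizes),
        "leaky_slope": spec.leaky_slope,
    }


def save_checkpoint(model, path, seed: int = 0, extra: dict = None) -> Path:
    """Write weights to ``<path>`` (.npz) and metadata to ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kind, config = _config_to_dict(model)
    np.savez(path, **model.state_dict())
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "kind": kind,
        "config": config,
        "seed": seed,
        "versions": {"ecggan": __version__, "numpy": np.__version__},
    }
    if extra:
        sidecar.update(extra)
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def _spec_from_dict(d: dict) -> DiscriminatorSpec:
    layers = []
    for layer in d.get("layers", []):
        if layer["type"] == "conv":
            layers.append(
                ConvLayerSpec(
                    n_filters=layer["n_filters"],
                    filter_length=layer["filter_length"],
                    stride=layer["stride"],
                    zero_padding=layer.get("zero_padding", 0),
                )
            )
        else:
            layers.append(
                PoolLayerSpec(window=layer["window"], stride=layer["stride"])
            )
    return DiscriminatorSpec(
        kind=d["kind"],
        input_length=d["input_length"],
        layers=layers,
        fc_units=d.get("fc_units", 25),
        hidden_sizes=tuple(d.get("hidden_sizes", (64, 32))),
        leaky_slope=d.get("leaky_slope", 0.2),
    )


def load_checkpoint(path) -> Tuple[Union[Generator, RecurrentAutoencoder, object], dict]:
    """Rebuild a model from a checkpoint; returns (model, sidecar dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"checkpoint sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    kind = sidecar.get("kind")
    config = sidecar.get("config", {})
    if kind == "generator":
        model = build_generator(GeneratorConfig(**config))
    elif kind == "autoencoder":
        model = RecurrentAutoencoder(AEConfig(**config))
    elif kind == "discriminator":
        model = build_discriminator(_spec_from_dict(config))
    else:
        raise FormatError(f"unknown checkpoint kind {kind!r} in {sidecar_path}")
    with np.load(path) as npz:
        state = {name: npz[name] for name in npz.files}
    try:
        model.load_state_dict(state)
    except ValueError as exc:
        raise FormatError(f"incompatible checkpoint {path}: {exc}") from exc
    model.eval()
    return model, sidecar
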