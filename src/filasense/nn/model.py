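"""Sequential container with named layers, checkpointing, and taps for Grad-CAM."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Layer, softmax

F32 = np.float32


class Sequential:
    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers
        for name, layer in layers:
            layer.name = name

    # ------------------------------------------------------------------ passes
    def forward(self, x: np.ndarray, mode: str = "eval",
                tap: str | None = None):
        """Run the network; if ``tap`` names a layer, also return its output."""
        tapped = None
        for name, layer in self.layers:
            x = layer.forward(x.astype(F32, copy=False), mode)
            if name == tap:
                tapped = x
        return (x, tapped) if tap is not None else x

    def backward(self, dy: np.ndarray, stop_at: str | None = None) -> np.ndarray:
        """Backpropagate; optionally stop once the gradient w.r.t. ``stop_at``'s
        output has been computed (that gradient is returned)."""
        for name, layer in reversed(self.layers):
            if name == stop_at:
                return dy
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x: np.ndarray, batch: int = 8) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch], mode="eval"))
               for i in range(0, len(x), batch)]
        return np.concatenate(out, axis=0)

    # -------------------------------------------------------------- parameters
    def parameters(self) -> list[np.ndarray]:
        return [p for _, layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for _, layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_layer(self, name: str) -> Layer:
        for lname, layer in self.layers:
            if lname == name:
                return layer
        raise KeyError(f"no layer named {name!r}")

    def layer_names(self) -> list[str]:
        return [name for name, _ in self.layers]

    # ------------------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for i, p in enumerate(layer.params):
                state[f"{name}.p{i}"] = p.copy()
            for attr in ("running_mean", "running_var"):
                if hasattr(layer, attr):
                    state[f"{name}.{attr}"] = getattr(layer, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for i, p in enumerate(layer.params):
                p[...] = state[f"{name}.p{i}"]
            for attr in ("running_mean", "running_var"):
                if hasattr(layer, attr):
                    getattr(layer, attr)[...] = state[f"{name}.{attr}"]

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        if meta is not None:
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    def load(self, path: str | Path) -> None:
        with np.load(Path(path).with_suffix(".npz")) as data:
            self.load_state_dict({k: data[k] for k in data.files})
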