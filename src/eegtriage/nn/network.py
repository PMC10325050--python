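"""Declarative network specifications and their numpy instantiation.

A :class:`NetworkSpec` is an ordered DAG of named layers. It can be shape-
audited and parameter-counted without instantiation (pure functions of the
spec), serialized to and from plain dicts/JSON, and instantiated into a
:class:`Model` for forward passes, training, and gradient-based attribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import LAYER_TYPES, Conv1D, Conv2D, Layer, Softmax

INPUT = "input"


@dataclass
class Node:
    name: str
    layer: Layer
    inputs: list[str]


@dataclass
class NetworkSpec:
    """Ordered layer graph with a single input and a single output node."""

    input_shape: tuple
    nodes: list[Node] = field(default_factory=list)
    n_classes: int = 3

    def add(self, name: str, layer: Layer, inputs: str | list[str] | None = None) -> str:
        """Append a node; default input is the previously added node."""
        if isinstance(inputs, str):
            inputs = [inputs]
        if inputs is None:
            inputs = [self.nodes[-1].name if self.nodes else INPUT]
        if name in {n.name for n in self.nodes} or name == INPUT:
            raise ValueError(f"duplicate node name {name!r}")
        known = {n.name for n in self.nodes} | {INPUT}
        unknown = set(inputs) - known
        if unknown:
            raise ValueError(f"node {name!r} references unknown inputs {unknown}")
        self.nodes.append(Node(name, layer, list(inputs)))
        return name

    @property
    def output(self) -> str:
        return self.nodes[-1].name

    # -- audit ------------------------------------------------------------

    def audit_shapes(self) -> dict[str, tuple]:
        """Propagate shapes through the graph; raises if layers don't compose."""
        shapes: dict[str, tuple] = {INPUT: tuple(self.input_shape)}
        for node in self.nodes:
            in_shapes = [shapes[i] for i in node.inputs]
            try:
                shapes[node.name] = tuple(node.layer.out_shape(in_shapes))
            except Exception as exc:
                raise ValueError(
                    f"shape audit failed at node {node.name!r} "
                    f"({type(node.layer).__name__}) with inputs {in_shapes}: {exc}"
                ) from exc
        return shapes

    def count_parameters(self) -> int:
        """Total trainable scalars (weights, biases, batch-norm affine terms)."""
        shapes = self.audit_shapes()
        return int(
            sum(
                node.layer.n_params([shapes[i] for i in node.inputs])
                for node in self.nodes
            )
        )

    def n_layers(self) -> int:
        """Node count including the input (reported for audits, one drawing
        convention among several)."""
        return len(self.nodes) + 1

    def layer_summary(self) -> list[dict]:
        shapes = self.audit_shapes()
        rows = []
        for node in self.nodes:
            in_shapes = [shapes[i] for i in node.inputs]
            rows.append(
                {
                    "name": node.name,
                    "type": type(node.layer).__name__,
                    "inputs": list(node.inputs),
                    "out_shape": shapes[node.name],
                    "params": node.layer.n_params(in_shapes),
                }
            )
        return rows

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "nodes": [
                {
                    "name": n.name,
                    "type": type(n.layer).__name__,
                    "config": _jsonable(n.layer.config()),
                    "inputs": list(n.inputs),
                }
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        spec = cls(input_shape=tuple(d["input_shape"]), n_classes=d.get("n_classes", 3))
        for nd in d["nodes"]:
            layer_cls = LAYER_TYPES[nd["type"]]
            cfg = dict(nd["config"])
            for key in ("kernel", "stride", "pool", "indices"):
                if key in cfg and isinstance(cfg[key], list):
                    cfg[key] = tuple(cfg[key])
            spec.add(nd["name"], layer_cls(**cfg), nd["inputs"])
        return spec

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _jsonable(cfg: dict) -> dict:
    out = {}
    for k, v in cfg.items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


class Model:
    """A NetworkSpec instantiated with parameter arrays."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        shapes = spec.audit_shapes()
        self.shapes = shapes
        self.params: dict[str, dict] = {}
        for node in spec.nodes:
            in_shapes = [shapes[i] for i in node.inputs]
            self.params[node.name] = node.layer.init_params(in_shapes, self.rng)

    # -- execution --------------------------------------------------------

    def forward(
        self, X: np.ndarray, training: bool = False, keep_caches: bool = False
    ):
        """Run the graph; returns (output, activations) and stores caches
        when requested (needed for backward)."""
        acts: dict[str, np.ndarray] = {INPUT: np.asarray(X, dtype=float)}
        caches: dict[str, object] = {}
        for node in self.spec.nodes:
            xs = [acts[i] for i in node.inputs]
            y, cache = node.layer.forward(
                xs, self.params[node.name], training=training, rng=self.rng
            )
            acts[node.name] = y
            if keep_caches:
                caches[node.name] = cache
        self._caches = caches if keep_caches else None
        return acts[self.spec.output], acts

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        outs = []
        for i in range(0, X.shape[0], batch_size):
            out, _ = self.forward(X[i : i + batch_size], training=False)
            outs.append(out)
        return np.vstack(outs)

    def backward(
        self,
        acts: dict[str, np.ndarray],
        seed_node: str,
        seed_grad: np.ndarray,
        stop_nodes: set[str] | None = None,
    ):
        """Reverse-accumulate gradients from ``seed_node``.

        Returns (param_grads, activation_grads). Fixed front-end transforms
        (STFT, channel routing on the raw input) absorb the gradient.
        """
        if self._caches is None:
            raise RuntimeError("run forward(..., keep_caches=True) first")
        stop_nodes = stop_nodes or set()
        dacts: dict[str, np.ndarray] = {seed_node: seed_grad}
        pgrads: dict[str, dict] = {}
        order = [n for n in self.spec.nodes]
        seen = {n.name for n in order}
        if seed_node not in seen:
            raise KeyError(seed_node)
        started = False
        for node in reversed(order):
            if node.name == seed_node:
                started = True
            if not started or node.name not in dacts:
                continue
            if node.name in stop_nodes:
                continue
            dy = dacts[node.name]
            try:
                dxs, dp = node.layer.backward(
                    dy, self._caches[node.name], self.params[node.name]
                )
            except NotImplementedError:
                continue  # fixed transform: do not propagate further
            if dp:
                pgrads[node.name] = dp
            for inp, dx in zip(node.inputs, dxs):
                if inp in dacts:
                    dacts[inp] = dacts[inp] + dx
                else:
                    dacts[inp] = dx
        return pgrads, dacts

    # -- introspection ----------------------------------------------------

    def trainable_items(self):
        for name, p in self.params.items():
            for key, arr in p.items():
                if not key.startswith("_"):
                    yield name, key, arr

    def last_conv_node(self) -> str | None:
        """Topologically last convolutional node (Grad-CAM default target)."""
        last = None
        for node in self.spec.nodes:
            if isinstance(node.layer, (Conv1D, Conv2D)):
                last = node.name
        return last

    def softmax_input(self) -> str:
        out_node = self.spec.nodes[-1]
        if not isinstance(out_node.layer, Softmax):
            raise ValueError("network output is not a softmax")
        return out_node.inputs[0]
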