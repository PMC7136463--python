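"""Sparse recurrent network genomes and gradient training.

A decoder network is a *genome*: a list of typed nodes and a list of weighted
connections over three layers (input, a single hidden layer of variable width,
one output neuron).  Admissible connections are

* input -> hidden        (``forward``)
* input -> output        (``skip``, bridging the discontinuous layers)
* hidden -> output       (``forward``)
* hidden -> same hidden  (``self_recurrent``)

All hidden units and the output use the hyperbolic-tangent transfer function.
One input node may carry the ``error_input`` role: it receives the
error-feedback signal |v(t_pre) - v_hat(t_pre)| instead of a spike count.

Training is plain backpropagation through time on the squared-error loss,
unrolled over the fixed number of bins per trial, with the connection pattern
held fixed (only weights present in the genome receive gradient).  When the
genome has an error input, the training forward pass fills that input at each
step from the network's own previous-bin prediction; no gradient is propagated
through the feedback path.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

Layer = Literal["input", "hidden", "output"]
Role = Literal["neuronal_input", "error_input", "hidden", "output"]
ConnKind = Literal["forward", "skip", "self_recurrent"]

__all__ = [
    "NodeGene",
    "ConnectionGene",
    "NetworkGenome",
    "TrainingConfig",
    "NetworkMetrics",
    "TrainingDivergedError",
    "CompiledNetwork",
    "forward_step",
    "forward_sequence",
    "mse_loss",
    "bptt_gradient",
    "bptt_train",
    "numeric_gradient_oracle",
    "count_metrics",
    "genome_to_json",
    "genome_from_json",
    "validate_genome",
    "random_weight",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NodeGene:
    id: int
    layer: Layer
    role: Role


@dataclass
class ConnectionGene:
    source: int
    target: int
    weight: float
    kind: ConnKind


@dataclass
class NetworkGenome:
    """Partially connected recurrent network: nodes, weighted connections, age.

    ``age`` counts the generations the structure has survived in an
    evolutionary population; it is bookkeeping for age-based survival
    selection and does not affect evaluation.
    """

    nodes: list[NodeGene]
    connections: list[ConnectionGene]
    age: int = 0

    # -- structural accessors ------------------------------------------------

    def input_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.layer == "input")

    def hidden_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.layer == "hidden")

    def output_id(self) -> int:
        outs = [n.id for n in self.nodes if n.layer == "output"]
        if len(outs) != 1:
            raise ValueError(f"genome must have exactly one output node, found {len(outs)}")
        return outs[0]

    def error_input_id(self) -> int | None:
        ids = [n.id for n in self.nodes if n.role == "error_input"]
        if len(ids) > 1:
            raise ValueError("at most one error input allowed")
        return ids[0] if ids else None

    @property
    def n_inputs(self) -> int:
        return len(self.input_ids())

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_ids())

    def has_connection(self, source: int, target: int) -> bool:
        return any(c.source == source and c.target == target for c in self.connections)

    def copy(self) -> "NetworkGenome":
        return copy.deepcopy(self)

    def weight_vector(self) -> np.ndarray:
        return np.array([c.weight for c in self.connections], dtype=float)

    def set_weight_vector(self, w: Sequence[float]) -> None:
        if len(w) != len(self.connections):
            raise ValueError("weight vector length mismatch")
        for c, wi in zip(self.connections, w):
            c.weight = float(wi)


@dataclass
class TrainingConfig:
    """Gradient-descent settings for BPTT training.

    ``learning_rate`` is the step size applied to the gradient of the mean
    per-bin squared error (the summed loss divided by the number of scored
    bins), which keeps the effective step independent of the number of trials.
    """

    learning_rate: float = 0.05
    epochs: int = 40
    gradient_clip: float | None = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class NetworkMetrics:
    n_hidden: int
    n_connections: int
    n_full: int
    connection_ratio: float


# ---------------------------------------------------------------------------
# validation


def validate_genome(genome: NetworkGenome, require_error_input: bool = False) -> None:
    """Check the structural invariants; raise ``ValueError`` on violation."""
    ids = [n.id for n in genome.nodes]
    if len(ids) != len(set(ids)):
        raise ValueError("node ids must be unique")
    genome.output_id()
    err = genome.error_input_id()
    if require_error_input and err is None:
        raise ValueError("genome requires an error input node")
    layer = {n.id: n.layer for n in genome.nodes}
    seen: set[tuple[int, int]] = set()
    for c in genome.connections:
        if c.source not in layer or c.target not in layer:
            raise ValueError(f"connection references unknown node: {c}")
        if (c.source, c.target) in seen:
            raise ValueError(f"duplicate connection ({c.source}, {c.target})")
        seen.add((c.source, c.target))
        if layer[c.target] == "input":
            raise ValueError("input nodes cannot be connection targets")
        if c.source == c.target:
            if layer[c.source] != "hidden" or c.kind != "self_recurrent":
                raise ValueError("self connections only on hidden nodes, kind self_recurrent")
        else:
            pair = (layer[c.source], layer[c.target])
            if pair == ("input", "hidden") and c.kind == "forward":
                continue
            if pair == ("hidden", "output") and c.kind == "forward":
                continue
            if pair == ("input", "output") and c.kind == "skip":
                continue
            raise ValueError(f"inadmissible connection {pair} kind={c.kind}")


def random_weight(rng: np.random.Generator) -> float:
    """Fresh connection weight, uniform on (-0.5, 0.5)."""
    return float(rng.uniform(-0.5, 0.5))


# ---------------------------------------------------------------------------
# compiled evaluation


class CompiledNetwork:
    """Dense masked-matrix view of a genome for fast batched evaluation.

    The genome's sparse connection list is laid out into four weight blocks
    (input->hidden, hidden self-recurrence, hidden->output, input->output
    skips) with 0/1 masks marking which entries exist.  ``sync_to_genome``
    writes trained weights back onto the connection genes.
    """

    def __init__(self, genome: NetworkGenome):
        self.genome = genome
        in_ids = genome.input_ids()
        hid_ids = genome.hidden_ids()
        self.in_index = {nid: i for i, nid in enumerate(in_ids)}
        self.hid_index = {nid: i for i, nid in enumerate(hid_ids)}
        self.out_id = genome.output_id()
        self.n_in = len(in_ids)
        self.n_h = len(hid_ids)
        err = genome.error_input_id()
        self.error_slot: int | None = self.in_index[err] if err is not None else None

        self.W_ih = np.zeros((self.n_h, self.n_in))
        self.M_ih = np.zeros((self.n_h, self.n_in))
        self.w_self = np.zeros(self.n_h)
        self.m_self = np.zeros(self.n_h)
        self.W_ho = np.zeros(self.n_h)
        self.M_ho = np.zeros(self.n_h)
        self.W_io = np.zeros(self.n_in)
        self.M_io = np.zeros(self.n_in)

        # position of each connection gene inside the blocks, in genome order
        self._slots: list[tuple[str, int | tuple[int, int]]] = []
        for c in genome.connections:
            if c.kind == "self_recurrent":
                j = self.hid_index[c.source]
                self.w_self[j] = c.weight
                self.m_self[j] = 1.0
                self._slots.append(("self", j))
            elif c.source in self.in_index and c.target in self.hid_index:
                j, i = self.hid_index[c.target], self.in_index[c.source]
                self.W_ih[j, i] = c.weight
                self.M_ih[j, i] = 1.0
                self._slots.append(("ih", (j, i)))
            elif c.source in self.hid_index and c.target == self.out_id:
                j = self.hid_index[c.source]
                self.W_ho[j] = c.weight
                self.M_ho[j] = 1.0
                self._slots.append(("ho", j))
            elif c.source in self.in_index and c.target == self.out_id:
                i = self.in_index[c.source]
                self.W_io[i] = c.weight
                self.M_io[i] = 1.0
                self._slots.append(("io", i))
            else:
                raise ValueError(f"cannot place connection {c}")

    # -- forward -------------------------------------------------------------

    def step(self, x: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One time step.  ``x``: (..., n_in), ``h``: (..., n_h)."""
        h_new = np.tanh(x @ self.W_ih.T + self.w_self * h) if self.n_h else h
        y = np.tanh((h_new @ self.W_ho if self.n_h else 0.0) + x @ self.W_io)
        return y, h_new

    def forward(
        self,
        X: np.ndarray,
        targets: np.ndarray | None = None,
        dynamic_feedback: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Unroll over a batch of sequences.

        Parameters
        ----------
        X : (B, T, n_in)
            Feature sequences.  When ``dynamic_feedback`` is set and the
            genome has an error input, the corresponding column is
            overwritten in place with |target(t-1) - y(t-1)| (0 at t = 0).
        targets : (B, T), optional
            Reference series for the feedback signal.

        Returns
        -------
        Y : (B, T) predictions; H : (B, T, n_h) hidden activations.
        """
        B, T, n_in = X.shape
        if n_in != self.n_in:
            raise ValueError(f"feature width {n_in} != {self.n_in} input nodes")
        Y = np.empty((B, T))
        H = np.empty((B, T, self.n_h))
        h = np.zeros((B, self.n_h))
        fill = dynamic_feedback and self.error_slot is not None
        if fill and targets is None:
            raise ValueError("dynamic_feedback requires targets")
        for t in range(T):
            if fill:
                X[:, t, self.error_slot] = (
                    0.0 if t == 0 else np.abs(targets[:, t - 1] - Y[:, t - 1])
                )
            y, h = self.step(X[:, t, :], h)
            Y[:, t] = y
            H[:, t, :] = h
        return Y, H

    # -- backward ------------------------------------------------------------

    def gradients(
        self, X: np.ndarray, targets: np.ndarray, Y: np.ndarray, H: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Masked gradients of the summed squared error over all bins.

        ``X`` must be the feature array actually used in the forward pass
        (including any dynamically filled feedback column, treated as
        constant input).
        """
        B, T, _ = X.shape
        g_ih = np.zeros_like(self.W_ih)
        g_self = np.zeros_like(self.w_self)
        g_ho = np.zeros_like(self.W_ho)
        g_io = np.zeros_like(self.W_io)
        carry = np.zeros((B, self.n_h))  # dL/d(hidden preact at t+1) * w_self
        for t in range(T - 1, -1, -1):
            delta = 2.0 * (Y[:, t] - targets[:, t]) * (1.0 - Y[:, t] ** 2)  # (B,)
            if self.n_h:
                g_ho += delta @ H[:, t, :]
            g_io += delta @ X[:, t, :]
            if self.n_h:
                g_h = delta[:, None] * self.W_ho[None, :] + carry
                e = g_h * (1.0 - H[:, t, :] ** 2)  # grad wrt hidden preactivation
                g_ih += e.T @ X[:, t, :]
                h_prev = H[:, t - 1, :] if t > 0 else np.zeros((B, self.n_h))
                g_self += np.sum(e * h_prev, axis=0)
                carry = e * self.w_self
        return {
            "ih": g_ih * self.M_ih,
            "self": g_self * self.m_self,
            "ho": g_ho * self.M_ho,
            "io": g_io * self.M_io,
        }

    def apply_update(self, grads: dict[str, np.ndarray], step: float) -> None:
        self.W_ih -= step * grads["ih"]
        self.w_self -= step * grads["self"]
        self.W_ho -= step * grads["ho"]
        self.W_io -= step * grads["io"]

    def grads_as_connection_vector(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        out = np.empty(len(self._slots))
        for n, (block, pos) in enumerate(self._slots):
            if block == "ih":
                out[n] = grads["ih"][pos]
            elif block == "self":
                out[n] = grads["self"][pos]
            elif block == "ho":
                out[n] = grads["ho"][pos]
            else:
                out[n] = grads["io"][pos]
        return out

    def sync_to_genome(self) -> None:
        for c, (block, pos) in zip(self.genome.connections, self._slots):
            if block == "ih":
                c.weight = float(self.W_ih[pos])
            elif block == "self":
                c.weight = float(self.w_self[pos])
            elif block == "ho":
                c.weight = float(self.W_ho[pos])
            else:
                c.weight = float(self.W_io[pos])


# ---------------------------------------------------------------------------
# public operations


def forward_step(
    genome: NetworkGenome, features: np.ndarray, state: np.ndarray
) -> tuple[float, np.ndarray]:
    """Evaluate one time step of the network.

    ``features`` must have one entry per input node, ``state`` one per hidden
    node (previous hidden activations).  Returns the tanh-bounded prediction
    and the updated hidden state.
    """
    features = np.asarray(features, dtype=float)
    state = np.asarray(state, dtype=float)
    net = CompiledNetwork(genome)
    if features.shape != (net.n_in,):
        raise ValueError(f"expected {net.n_in} features, got {features.shape}")
    if state.shape != (net.n_h,):
        raise ValueError(f"expected hidden state of length {net.n_h}, got {state.shape}")
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(state))):
        raise ValueError("non-finite values in features or state")
    y, h = net.step(features, state)
    return float(y), h


def forward_sequence(
    genome: NetworkGenome,
    feature_sequence: np.ndarray,
    expected_bins: int | None = None,
) -> np.ndarray:
    """Run the network over a trial's feature sequence from a zero hidden state.

    ``feature_sequence`` is (T, n_in); returns the length-T prediction vector.
    """
    X = np.asarray(feature_sequence, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature_sequence must be 2-D (bins x features)")
    if expected_bins is not None and X.shape[0] != expected_bins:
        raise ValueError(f"expected {expected_bins} bins, got {X.shape[0]}")
    net = CompiledNetwork(genome)
    Y, _ = net.forward(X[None, :, :].copy())
    return Y[0]


def mse_loss(
    predictions: np.ndarray,
    targets: np.ndarray,
    reduction: Literal["sum", "mean"] = "sum",
) -> float:
    """Squared-error loss over bins: summed by default, or the per-bin mean.

    The summed form is the quantity the training gradient descends on; the
    per-bin mean is what training/validation errors are reported as, so that
    errors are comparable across sets of different size.
    """
    p = np.asarray(predictions, dtype=float)
    v = np.asarray(targets, dtype=float)
    if p.shape != v.shape:
        raise ValueError("predictions and targets must have equal shape")
    if p.size == 0:
        raise ValueError("empty inputs")
    sse = float(np.sum((p - v) ** 2))
    return sse if reduction == "sum" else sse / p.size


def _stack_trials(
    trials: Iterable[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    feats, targs = [], []
    for f, v in trials:
        feats.append(np.asarray(f, dtype=float))
        targs.append(np.asarray(v, dtype=float))
    if not feats:
        raise ValueError("no trials supplied")
    return np.stack(feats), np.stack(targs)


def bptt_gradient(
    genome: NetworkGenome,
    features: np.ndarray,
    targets: np.ndarray,
    dynamic_feedback: bool = False,
) -> np.ndarray:
    """Analytic gradient of the summed squared error wrt each connection weight.

    Returned in the order of ``genome.connections``.  With
    ``dynamic_feedback`` the error-input column is filled from the net's own
    previous-bin predictions and treated as a constant input.
    """
    X = np.array(features, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    V = np.array(targets, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    net = CompiledNetwork(genome)
    Y, H = net.forward(X, targets=V, dynamic_feedback=dynamic_feedback)
    grads = net.gradients(X, V, Y, H)
    return net.grads_as_connection_vector(grads)


def bptt_train(
    genome: NetworkGenome,
    trials: Sequence[tuple[np.ndarray, np.ndarray]] | tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
    dynamic_feedback: bool = False,
) -> tuple[NetworkGenome, float]:
    """Train the genome's weights in place by full-batch BPTT.

    Parameters
    ----------
    trials
        Either a list of ``(features (T, n_in), targets (T,))`` pairs with a
        common T, or a pre-stacked ``(features (B, T, n_in), targets (B, T))``
        pair.
    config
        Learning rate (on the mean per-bin loss), epoch count, optional
        global-norm gradient clip.
    dynamic_feedback
        Fill the error-input column each step from the net's previous-bin
        prediction error (used when training feedback decoders).

    Returns the genome (weights updated, structure untouched) and the final
    training error as mean squared error per bin.
    """
    if isinstance(trials, tuple) and isinstance(trials[0], np.ndarray):
        X0, V = trials  # type: ignore[misc]
        X0 = np.asarray(X0, dtype=float)
        V = np.asarray(V, dtype=float)
    else:
        X0, V = _stack_trials(trials)  # type: ignore[arg-type]
    if X0.ndim != 3 or V.ndim != 2:
        raise ValueError("expected features (B, T, n_in) and targets (B, T)")
    net = CompiledNetwork(genome)
    n_bins = V.size
    for _ in range(config.epochs):
        X = X0.copy()  # feedback column may be rewritten per epoch
        Y, H = net.forward(X, targets=V, dynamic_feedback=dynamic_feedback)
        loss = np.sum((Y - V) ** 2)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"training loss diverged (loss={loss})")
        grads = net.gradients(X, V, Y, H)
        # step on the mean per-bin loss so the rate is dataset-size free
        scale = 1.0 / n_bins
        if config.gradient_clip is not None:
            norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values())) * scale
            if norm > config.gradient_clip:
                scale *= config.gradient_clip / norm
        net.apply_update(grads, config.learning_rate * scale)
    X = X0.copy()
    Y, _ = net.forward(X, targets=V, dynamic_feedback=dynamic_feedback)
    final = float(np.mean((Y - V) ** 2))
    if not np.isfinite(final):
        raise TrainingDivergedError("training loss diverged after final epoch")
    net.sync_to_genome()
    return genome, final


def numeric_gradient_oracle(
    genome: NetworkGenome,
    features: np.ndarray,
    targets: np.ndarray,
    step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference estimate of the summed-squared-error gradient.

    Test-support oracle, independent of the analytic backward pass: each
    connection weight is displaced by ±``step`` and the loss re-evaluated with
    a fresh forward pass.  Intended for small genomes (<= 200 weights).
    """
    if len(genome.connections) > 200:
        raise ValueError("numeric oracle restricted to small genomes")
    X = np.array(features, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    V = np.array(targets, dtype=float)
    if V.ndim == 1:
        V = V[None, :]

    def loss_at(w: np.ndarray) -> float:
        g = genome.copy()
        g.set_weight_vector(w)
        net = CompiledNetwork(g)
        Y, _ = net.forward(X.copy())
        return float(np.sum((Y - V) ** 2))

    w0 = genome.weight_vector()
    grad = np.empty_like(w0)
    for i in range(len(w0)):
        wp, wm = w0.copy(), w0.copy()
        wp[i] += step
        wm[i] -= step
        grad[i] = (loss_at(wp) - loss_at(wm)) / (2 * step)
    return grad


def count_metrics(genome: NetworkGenome) -> NetworkMetrics:
    """Connection-count statistics, including the connection ratio R_c.

    The fully connected reference count N_f covers every admissible slot for
    the genome's node set: all input->hidden and input->output connections,
    all hidden->output connections, and one self-recurrence per hidden node.
    R_c = N_c / N_f equals 1 exactly when every admissible slot is filled.
    """
    n_in = genome.n_inputs
    n_h = genome.n_hidden
    n_full = n_in * n_h + n_in + n_h + n_h
    if n_full == 0:
        raise ValueError("genome admits no connections")
    n_c = len(genome.connections)
    return NetworkMetrics(
        n_hidden=n_h,
        n_connections=n_c,
        n_full=n_full,
        connection_ratio=n_c / n_full,
    )


# ---------------------------------------------------------------------------
# serialization


def genome_to_json(genome: NetworkGenome) -> str:
    payload = {
        "nodes": [{"id": n.id, "layer": n.layer, "role": n.role} for n in genome.nodes],
        "connections": [
            {"source": c.source, "target": c.target, "weight": c.weight, "kind": c.kind}
            for c in genome.connections
        ],
        "age": genome.age,
    }
    return json.dumps(payload)


def genome_from_json(text: str) -> NetworkGenome:
    payload = json.loads(text)
    nodes = [NodeGene(int(n["id"]), n["layer"], n["role"]) for n in payload["nodes"]]
    conns = [
        ConnectionGene(int(c["source"]), int(c["target"]), float(c["weight"]), c["kind"])
        for c in payload["connections"]
    ]
    return NetworkGenome(nodes=nodes, connections=conns, age=int(payload.get("age", 0)))
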