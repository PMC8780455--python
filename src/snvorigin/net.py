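"""Feed-forward classifiers with three feature-integration wirings.

The three architectures combine the bin-density, trinucleotide and
driver-gene feature sets at different depths:

* ``early`` — all feature sets concatenated into one input vector feeding a
  single dense stack (the original single-feature model is the one-set
  special case);
* ``multi_branch`` — one dense stack per feature set, the final branch
  layers concatenated before the softmax head;
* ``consecutive`` — feature sets processed hierarchically: the last dense
  layer of each stage is concatenated with the next raw feature set to form
  the next stage's input.

Networks are trained with Adam (batch size 32, 50 epochs by default) on
categorical cross-entropy; weights start glorot-uniform, biases at zero;
dropout follows each hidden layer and the L2 penalty applies to dense
kernels only. Everything is plain NumPy with explicit backpropagation so
that training is deterministic under a seed and so that gradients of the
class score with respect to the *inputs* — the quantity integrated-gradients
attribution needs — are available exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARCHITECTURES = ("early", "multi_branch", "consecutive")
ACTIVATION_SET = ("relu", "tanh", "sigmoid", "elu")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "elu":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a * a
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "elu":
        return np.where(z > 0, 1.0, a + 1.0)
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class Hyperparams:
    """Per-stack hyperparameters; bounds follow the HPO search space."""

    learning_rate: float = 1e-3
    l2_penalty: float = 1e-4
    dropout: float = 0.0
    n_layers: int = 2
    n_nodes: int = 64
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")
        if self.activation not in ACTIVATION_SET:
            raise ValueError(f"activation must be one of {ACTIVATION_SET}")
        if self.n_layers < 1 or self.n_nodes < 1 or self.learning_rate <= 0 or self.l2_penalty < 0:
            raise ValueError("hyperparameters out of range")


@dataclass
class IntegrationSpec:
    """Architecture plus one Hyperparams set per entry point.

    ``early`` takes one set; ``multi_branch`` and ``consecutive`` take one
    per feature set, in ``feature_order``. The Adam learning rate is global
    and read from the first set.
    """

    architecture: str
    hyperparams: list[Hyperparams]
    feature_order: list[str] = field(default_factory=lambda: ["bins", "tri", "drivers"])

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        need = 1 if self.architecture == "early" else len(self.feature_order)
        if len(self.hyperparams) != need:
            raise ValueError(
                f"{self.architecture} needs {need} hyperparameter set(s), got {len(self.hyperparams)}")

    @property
    def learning_rate(self) -> float:
        return self.hyperparams[0].learning_rate


@dataclass
class TrainingSchedule:
    batch_size: int = 32
    epochs: int = 50


class _Dense:
    """One dense layer: glorot-uniform kernel, zero bias, optional dropout."""

    def __init__(self, n_in: int, n_out: int, activation: str, l2: float,
                 dropout: float, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.l2 = l2
        self.dropout = dropout
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        z = x @ self.W + self.b
        a = _act(self.activation, z)
        mask = None
        if train and self.dropout > 0.0:
            mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
        self._cache = (x, z, a, mask)
        return a if mask is None else a * mask

    def backward(self, da: np.ndarray) -> np.ndarray:
        x, z, a, mask = self._cache
        if mask is not None:
            da = da * mask
        dz = da * _act_grad(self.activation, z, a)
        self.dW = x.T @ dz + self.l2 * self.W
        self.db = dz.sum(axis=0)
        return dz @ self.W.T


class _Stack:
    """A sequence of identical hidden dense layers driven by one Hyperparams."""

    def __init__(self, n_in: int, hp: Hyperparams, rng: np.random.Generator):
        self.layers = []
        d = n_in
        for _ in range(hp.n_layers):
            self.layers.append(_Dense(d, hp.n_nodes, hp.activation, hp.l2_penalty, hp.dropout, rng))
            d = hp.n_nodes
        self.n_out = d

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class IntegrationModel:
    """A trainable classifier in one of the three integration wirings.

    ``predict_proba`` rows are softmax outputs (non-negative, sum to one);
    top-k rankings break probability ties by ascending class index.
    """

    def __init__(self, spec: IntegrationSpec, input_dims: list[int], n_classes: int,
                 class_names: list[str], seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if any(d <= 0 for d in input_dims):
            raise ValueError(f"input dims must be positive, got {input_dims}")
        if len(class_names) != n_classes:
            raise ValueError("class_names length must equal n_classes")
        if spec.architecture != "early" and len(input_dims) != len(spec.hyperparams):
            raise ValueError(
                f"{spec.architecture}: {len(spec.hyperparams)} hyperparameter sets "
                f"but {len(input_dims)} feature sets")
        self.spec = spec
        self.input_dims = list(input_dims)
        self.n_classes = n_classes
        self.class_names = list(class_names)
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.stacks: list[_Stack] = []
        if spec.architecture == "early":
            stack = _Stack(sum(input_dims), spec.hyperparams[0], rng)
            self.stacks.append(stack)
            head_in, head_l2 = stack.n_out, spec.hyperparams[0].l2_penalty
        elif spec.architecture == "multi_branch":
            for d, hp in zip(input_dims, spec.hyperparams):
                self.stacks.append(_Stack(d, hp, rng))
            head_in = sum(s.n_out for s in self.stacks)
            head_l2 = spec.hyperparams[-1].l2_penalty
        else:  # consecutive
            prev = 0
            for d, hp in zip(input_dims, spec.hyperparams):
                stack = _Stack(prev + d, hp, rng)
                self.stacks.append(stack)
                prev = stack.n_out
            head_in, head_l2 = prev, spec.hyperparams[-1].l2_penalty
        self.head = _Dense(head_in, n_classes, "linear", head_l2, 0.0, rng)

    # -- forward / backward ------------------------------------------------

    def _forward(self, inputs: list[np.ndarray], train: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        if len(inputs) != len(self.input_dims):
            raise ValueError(f"expected {len(self.input_dims)} input blocks, got {len(inputs)}")
        for x, d in zip(inputs, self.input_dims):
            if x.shape[1] != d:
                raise ValueError(f"input width {x.shape[1]} != expected {d}")
        arch = self.spec.architecture
        if arch == "early":
            h = self.stacks[0].forward(np.concatenate(inputs, axis=1), train, rng)
        elif arch == "multi_branch":
            h = np.concatenate(
                [s.forward(x, train, rng) for s, x in zip(self.stacks, inputs)], axis=1)
        else:
            h = self.stacks[0].forward(inputs[0], train, rng)
            for stack, x in zip(self.stacks[1:], inputs[1:]):
                h = stack.forward(np.concatenate([h, x], axis=1), train, rng)
        return self.head.forward(h, train, rng)

    def _backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Backprop ``dlogits`` through the net; returns gradients w.r.t. inputs."""
        dh = self.head.backward(dlogits)
        arch = self.spec.architecture
        if arch == "early":
            dx = self.stacks[0].backward(dh)
            return list(np.split(dx, np.cumsum(self.input_dims)[:-1], axis=1))
        if arch == "multi_branch":
            widths = [s.n_out for s in self.stacks]
            parts = np.split(dh, np.cumsum(widths)[:-1], axis=1)
            return [s.backward(p) for s, p in zip(self.stacks, parts)]
        # consecutive: unwind the stages from the last one back
        input_grads: list[np.ndarray] = [None] * len(self.stacks)
        grad = dh
        for i in range(len(self.stacks) - 1, 0, -1):
            dcat = self.stacks[i].backward(grad)
            grad, input_grads[i] = np.split(dcat, [self.stacks[i - 1].n_out], axis=1)
        input_grads[0] = self.stacks[0].backward(grad)
        return input_grads

    def _all_layers(self) -> list[_Dense]:
        return [l for s in self.stacks for l in s.layers] + [self.head]

    # -- training ----------------------------------------------------------

    def fit(self, Xs: list[np.ndarray], y: np.ndarray,
            Xs_val: list[np.ndarray] | None = None, y_val: np.ndarray | None = None,
            schedule: TrainingSchedule | None = None, seed: int = 0) -> list[dict]:
        """Train with Adam on categorical cross-entropy; returns per-epoch log.

        ``y`` holds integer class indices. Final-epoch weights are kept (no
        early stopping); the validation series is for HPO and reporting only.
        """
        schedule = schedule or TrainingSchedule()
        y = np.asarray(y, dtype=np.int64)
        n = y.shape[0]
        onehot = np.eye(self.n_classes)[y]
        rng = np.random.default_rng(seed)
        layers = self._all_layers()
        lr = self.spec.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        t = 0
        history = []
        for epoch in range(schedule.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, schedule.batch_size):
                idx = order[start:start + schedule.batch_size]
                batch = [X[idx] for X in Xs]
                logits = self._forward(batch, train=True, rng=rng)
                probs = softmax(logits)
                loss = -np.mean(np.log(np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, None)))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; the learning rate "
                        f"({lr:g}) is the usual culprit")
                epoch_loss += loss * len(idx)
                dlogits = (probs - onehot[idx]) / len(idx)
                self._backward(dlogits)
                t += 1
                for i, l in enumerate(layers):
                    mW, mb = m[i]
                    vW, vb = v[i]
                    mW[:] = beta1 * mW + (1 - beta1) * l.dW
                    mb[:] = beta1 * mb + (1 - beta1) * l.db
                    vW[:] = beta2 * vW + (1 - beta2) * l.dW ** 2
                    vb[:] = beta2 * vb + (1 - beta2) * l.db ** 2
                    bc1, bc2 = 1 - beta1 ** t, 1 - beta2 ** t
                    l.W -= lr * (mW / bc1) / (np.sqrt(vW / bc2) + eps)
                    l.b -= lr * (mb / bc1) / (np.sqrt(vb / bc2) + eps)
            entry = {"epoch": epoch, "train_loss": epoch_loss / n,
                     "train_acc": self.accuracy(Xs, y)}
            if Xs_val is not None and y_val is not None and len(y_val):
                entry["val_acc"] = self.accuracy(Xs_val, y_val)
            history.append(entry)
        return history

    # -- inference ---------------------------------------------------------

    def predict_proba(self, Xs: list[np.ndarray]) -> np.ndarray:
        return softmax(self._forward(Xs, train=False))

    def predict(self, Xs: list[np.ndarray]) -> np.ndarray:
        return self.predict_proba(Xs).argmax(axis=1)

    def predict_topk(self, Xs: list[np.ndarray], k: int) -> list[list[str]]:
        """Ranked top-k class names per row; ties broken by class index."""
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > self.n_classes:
            raise ValueError(f"k={k} exceeds {self.n_classes} classes")
        probs = self.predict_proba(Xs)
        order = np.argsort(-probs, axis=1, kind="stable")[:, :k]
        return [[self.class_names[j] for j in row] for row in order]

    def accuracy(self, Xs: list[np.ndarray], y: np.ndarray) -> float:
        return float(np.mean(self.predict(Xs) == np.asarray(y)))

    def input_gradients(self, xs: list[np.ndarray], class_idx: int,
                        mode: str = "logit") -> list[np.ndarray]:
        """Gradient of the class-``class_idx`` score w.r.t. each input block.

        ``mode='logit'`` differentiates the pre-softmax score (the default
        used for attribution); ``mode='prob'`` the softmax probability.
        """
        logits = self._forward(xs, train=False)
        seed_vec = np.zeros_like(logits)
        if mode == "logit":
            seed_vec[:, class_idx] = 1.0
        elif mode == "prob":
            p = softmax(logits)
            seed_vec = p[:, [class_idx]] * (np.eye(logits.shape[1])[class_idx] - p)
        else:
            raise ValueError(f"unknown gradient mode {mode!r}")
        return self._backward(seed_vec)


    # -- persistence -------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        """Write ``{prefix}.json`` (architecture) and ``{prefix}.npz`` (weights)."""
        import json
        from dataclasses import asdict

        meta = {
            "spec": {"architecture": self.spec.architecture,
                     "hyperparams": [asdict(h) for h in self.spec.hyperparams],
                     "feature_order": self.spec.feature_order},
            "input_dims": self.input_dims,
            "n_classes": self.n_classes,
            "class_names": self.class_names,
            "seed": self.seed,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        arrays = {}
        for i, layer in enumerate(self._all_layers()):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(f"{path_prefix}.npz", **arrays)

    @classmethod
    def load(cls, path_prefix: str) -> "IntegrationModel":
        import json

        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        spec = IntegrationSpec(
            meta["spec"]["architecture"],
            [Hyperparams(**h) for h in meta["spec"]["hyperparams"]],
            feature_order=meta["spec"]["feature_order"])
        model = cls(spec, meta["input_dims"], meta["n_classes"],
                    meta["class_names"], seed=meta["seed"])
        with np.load(f"{path_prefix}.npz") as blob:
            for i, layer in enumerate(model._all_layers()):
                layer.W = blob[f"W{i}"]
                layer.b = blob[f"b{i}"]
        return model


def build_model(spec: IntegrationSpec, input_dims: list[int], n_classes: int,
                class_names: list[str] | None = None, seed: int = 0) -> IntegrationModel:
    """Construct an untrained IntegrationModel; see IntegrationModel for wiring."""
    names = class_names if class_names is not None else [str(i) for i in range(n_classes)]
    return IntegrationModel(spec, input_dims, n_classes, names, seed=seed)
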