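"""Multichannel capsule classifier for lncRNA-protein interaction.

Each feature channel is passed through its own 5-layer fully connected
subnetwork (PReLU activations, dropout on hidden layers) ending in a
3-dimensional capsule U_i.  A learned 3x3 transformation matrix W_i maps
each capsule into a shared prediction space, the transformed capsules are
summed, S = sum_i W_i U_i, and the squashing nonlinearity

    V = (||S||^2 / (1 + ||S||^2)) * (S / ||S||)

compresses the summed capsule so its length ||V|| in [0, 1) is the
interaction score.  No dynamic routing is used: a binary problem needs a
single output capsule.  The W_i are the only trainable parameters of the
capsule stage -- 4 channels x 3x3 = 36 parameters.

Training minimizes the single-capsule margin loss from the capsule-network
literature, L = y max(0, m+ - ||V||)^2 + lambda (1-y) max(0, ||V|| - m-)^2
with m+ = 0.9, m- = 0.1, lambda = 0.5, by mini-batch Adam.  Class
imbalance is handled outside the model by EasyEnsemble: one member per
balanced negative subset, ensemble score = mean of member scores.

Implemented directly in NumPy with hand-written backpropagation; the whole
model is a few thousand parameters, so no autodiff framework is needed.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

N_SUBNET_LAYERS = 5
CAPSULE_DIM = 3


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults documented in the methods note)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 80
    dropout: float = 0.2
    weight_decay: float = 1e-4  # decoupled (AdamW-style), weight matrices only
    margin_pos: float = 0.9
    margin_neg: float = 0.1
    margin_lambda: float = 0.5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


def squash(s: np.ndarray) -> np.ndarray:
    """Capsule squashing: shrink short vectors toward 0, long toward
    length just below 1, preserving direction.  The zero vector maps to
    itself (the limit convention)."""
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    norm2 = np.sum(S * S, axis=1, keepdims=True)
    norm = np.sqrt(norm2)
    scale = np.where(norm > 0, norm2 / (1.0 + norm2) / np.where(norm > 0, norm, 1.0), 0.0)
    V = scale * S
    return V[0] if single else V


def classify(score: float, threshold: float = 0.5) -> str:
    """'interact' iff score strictly exceeds the threshold; the boundary
    score is assigned to no_interact."""
    return "interact" if score > threshold else "no_interact"


def count_capsule_params(n_channels: int, capsule_dim: int) -> int:
    """Trainable parameters of the capsule stage: one capsule_dim x
    capsule_dim transformation matrix per channel."""
    if n_channels < 1 or capsule_dim < 1:
        raise ValueError("n_channels and capsule_dim must be positive")
    return n_channels * capsule_dim**2


def default_hidden_widths(
    input_dim: int, output_dim: int = CAPSULE_DIM, cap: int = 32
) -> list[int]:
    """Geometric taper down to the capsule dimension over the four hidden
    layers of the 5-layer subnet, with the first hidden layer capped.

    The cap keeps subnet capacity matched to desk-scale training sets: an
    uncapped funnel from a 320-dim input memorizes a few thousand training
    pairs outright instead of learning the planted rule.
    """
    top = min(max(input_dim, output_dim), cap)
    widths = np.geomspace(top, output_dim, N_SUBNET_LAYERS)
    return [max(output_dim, int(round(w))) for w in widths[:-1]]


class CapsuleNet:
    """One ensemble member: per-channel subnets + capsule stage.

    Parameters
    ----------
    channel_dims:
        Ordered mapping channel name -> input dimension, e.g.
        ``{"SF": 320, "Mtf": 29, "PC": 100, "SS": 20}``.  Disabled
        channels are simply omitted (their subnet is closed).
    hidden_widths:
        Optional mapping channel -> list of 4 hidden widths; defaults to a
        geometric taper.
    dropout:
        Dropout rate on hidden-layer activations (train mode only).
    seed:
        Seed for weight initialization.
    """

    def __init__(
        self,
        channel_dims: dict[str, int],
        hidden_widths: dict[str, list[int]] | None = None,
        dropout: float = 0.2,
        seed: int = 0,
    ) -> None:
        if not channel_dims:
            raise ValueError("at least one channel is required")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.channel_dims = dict(channel_dims)
        self.dropout = float(dropout)
        self.hidden_widths = {
            c: list(
                (hidden_widths or {}).get(c) or default_hidden_widths(d)
            )
            for c, d in channel_dims.items()
        }
        for c, ws in self.hidden_widths.items():
            if len(ws) != N_SUBNET_LAYERS - 1:
                raise ValueError(
                    f"channel {c}: expected {N_SUBNET_LAYERS - 1} hidden widths"
                )
        rng = np.random.default_rng(seed)
        # subnets: 5 linear layers; PReLU (learnable scalar slope) after
        # layers 1-4, linear capsule output
        self.layers: dict[str, list[dict[str, np.ndarray]]] = {}
        for c, d in self.channel_dims.items():
            sizes = [d] + self.hidden_widths[c] + [CAPSULE_DIM]
            chain = []
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
                chain.append(
                    {
                        "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)),
                        "b": np.zeros(fan_out),
                        "a": np.array(0.25),  # PReLU slope (unused on last layer)
                    }
                )
            self.layers[c] = chain
        # capsule stage: the only trainable parameters of the second part
        self.capsule_W: dict[str, np.ndarray] = {
            c: np.eye(CAPSULE_DIM) + rng.normal(0.0, 0.1, (CAPSULE_DIM, CAPSULE_DIM))
            for c in self.channel_dims
        }
        # per-dimension input standardization (fit on the training set, not
        # trained): raw channels live on wildly different scales (motif
        # counts grow with sequence length) and would saturate the squash
        self.scaler: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def fit_scaler(self, X: dict[str, np.ndarray]) -> None:
        """Fit per-dimension mean/std standardization on training features."""
        self._check_input(X)
        self.scaler = {
            c: (
                X[c].mean(axis=0),
                np.maximum(X[c].std(axis=0), 1e-8),
            )
            for c in self.channel_dims
        }

    def _scale(self, X: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        if self.scaler is None:
            return X
        return {
            c: (np.asarray(X[c], dtype=float) - self.scaler[c][0]) / self.scaler[c][1]
            for c in self.channel_dims
        }

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for c, chain in self.layers.items():
            for i, layer in enumerate(chain):
                out.append((f"{c}/L{i}/W", layer["W"]))
                out.append((f"{c}/L{i}/b", layer["b"]))
                if i < N_SUBNET_LAYERS - 1:
                    out.append((f"{c}/L{i}/a", layer["a"]))
        for c in self.channel_dims:
            out.append((f"{c}/capsW", self.capsule_W[c]))
        return out

    @property
    def capsule_stage_parameter_count(self) -> int:
        return int(sum(W.size for W in self.capsule_W.values()))

    @property
    def n_parameters(self) -> int:
        return int(sum(arr.size for _, arr in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def _check_input(self, X: dict[str, np.ndarray]) -> None:
        for c, d in self.channel_dims.items():
            if c not in X:
                raise ValueError(f"missing feature channel {c!r}")
            if X[c].ndim != 2 or X[c].shape[1] != d:
                raise ValueError(
                    f"channel {c!r}: expected (*, {d}), got {X[c].shape}"
                )

    def forward(
        self,
        X: dict[str, np.ndarray],
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Scores ||V|| in [0, 1) for a batch; returns (scores, cache)."""
        self._check_input(X)
        if train_mode and self.dropout > 0 and rng is None:
            raise ValueError("train_mode with dropout requires an rng")
        X = self._scale(X)
        cache: dict = {"channels": {}}
        S = None
        for c in self.channel_dims:
            H = np.asarray(X[c], dtype=float)
            steps = []
            for i, layer in enumerate(self.layers[c]):
                Z = H @ layer["W"] + layer["b"]
                step = {"H_in": H, "Z": Z}
                if i < N_SUBNET_LAYERS - 1:
                    A = np.where(Z > 0, Z, layer["a"] * Z)
                    if train_mode and self.dropout > 0:
                        mask = (
                            rng.random(A.shape) >= self.dropout
                        ) / (1.0 - self.dropout)
                        A = A * mask
                        step["mask"] = mask
                    H = A
                else:
                    H = Z
                steps.append(step)
            U = H  # (B, 3) capsule
            Up = U @ self.capsule_W[c].T
            cache["channels"][c] = {"steps": steps, "U": U}
            S = Up if S is None else S + Up
        norm2 = np.sum(S * S, axis=1)
        scores = norm2 / (1.0 + norm2)
        cache["S"] = S
        cache["norm2"] = norm2
        return scores, cache

    def loss_and_grads(
        self,
        X: dict[str, np.ndarray],
        y: np.ndarray,
        config: TrainConfig,
        rng: np.random.Generator,
    ):
        """Margin loss and gradients for one mini-batch (train mode)."""
        y = np.asarray(y, dtype=float)
        scores, cache = self.forward(X, train_mode=True, rng=rng)
        B = len(y)
        pos_gap = np.maximum(0.0, config.margin_pos - scores)
        neg_gap = np.maximum(0.0, scores - config.margin_neg)
        loss = float(
            np.mean(y * pos_gap**2 + config.margin_lambda * (1 - y) * neg_gap**2)
        )
        dscore = (
            -2.0 * y * pos_gap + 2.0 * config.margin_lambda * (1 - y) * neg_gap
        ) / B
        # score = n2/(1+n2): d score / d S = 2 S / (1+n2)^2
        S = cache["S"]
        dS = (dscore * 2.0 / (1.0 + cache["norm2"]) ** 2)[:, None] * S
        grads: dict[str, np.ndarray] = {}
        for c in self.channel_dims:
            ch = cache["channels"][c]
            U = ch["U"]
            grads[f"{c}/capsW"] = dS.T @ U
            dH = dS @ self.capsule_W[c]
            for i in range(N_SUBNET_LAYERS - 1, -1, -1):
                step = ch["steps"][i]
                layer = self.layers[c][i]
                if i < N_SUBNET_LAYERS - 1:
                    dA = dH
                    if "mask" in step:
                        dA = dA * step["mask"]
                    Z = step["Z"]
                    neg = Z <= 0
                    grads[f"{c}/L{i}/a"] = np.array(np.sum(dA * np.where(neg, Z, 0.0)))
                    dZ = dA * np.where(neg, layer["a"], 1.0)
                else:
                    dZ = dH
                grads[f"{c}/L{i}/W"] = step["H_in"].T @ dZ
                grads[f"{c}/L{i}/b"] = dZ.sum(axis=0)
                dH = dZ @ layer["W"].T
        return loss, grads, scores

    def predict_scores(self, X: dict[str, np.ndarray]) -> np.ndarray:
        scores, _ = self.forward(X, train_mode=False)
        return scores


def train_one(
    model: CapsuleNet,
    X: dict[str, np.ndarray],
    y: np.ndarray,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> list[float]:
    """Train one member by mini-batch Adam on the margin loss.

    Returns the per-epoch mean loss trace.  Aborts with diagnostics on a
    non-finite loss.  Fully reproducible under ``seed`` (shuffling and
    dropout share one generator).
    """
    config = config or TrainConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if model.scaler is None:
        model.fit_scaler(X)
    rng = np.random.default_rng(seed)
    params = dict(model.parameters())
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    t = 0
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb = {c: X[c][idx] for c in model.channel_dims}
            loss, grads, _ = model.loss_and_grads(Xb, y[idx], config, rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {start}; "
                    "lower the learning rate or check the input features"
                )
            t += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - config.adam_beta2**t) / (1 - config.adam_beta1**t)
            )
            for k, p in params.items():
                g = grads[k]
                adam_m[k] = config.adam_beta1 * adam_m[k] + (1 - config.adam_beta1) * g
                adam_v[k] = config.adam_beta2 * adam_v[k] + (
                    1 - config.adam_beta2
                ) * g * g
                p -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + config.adam_eps)
                if config.weight_decay > 0 and k.endswith("W"):
                    p -= config.learning_rate * config.weight_decay * p
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


@dataclass
class EnsembleModel:
    """EasyEnsemble of capsule members; score = mean of member scores."""

    members: list[CapsuleNet]
    threshold: float = 0.5
    fingerprint: str = ""
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble requires at least one member")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def channel_dims(self) -> dict[str, int]:
        return self.members[0].channel_dims

    def predict_scores(self, X: dict[str, np.ndarray]) -> np.ndarray:
        return np.mean([m.predict_scores(X) for m in self.members], axis=0)

    def predict_labels(self, X: dict[str, np.ndarray]) -> list[str]:
        return [classify(s, self.threshold) for s in self.predict_scores(X)]

    # -- serialization ------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Single-file .npz container: all member weights + JSON metadata."""
        arrays = {}
        for i, member in enumerate(self.members):
            for name, arr in member.parameters():
                arrays[f"m{i}/{name}"] = arr
            if member.scaler is not None:
                for c, (mu, sigma) in member.scaler.items():
                    arrays[f"m{i}/scaler/{c}/mu"] = mu
                    arrays[f"m{i}/scaler/{c}/sigma"] = sigma
        meta = {
            "format_version": self.FORMAT_VERSION,
            "n_members": len(self.members),
            "channel_dims": self.channel_dims,
            "hidden_widths": self.members[0].hidden_widths,
            "dropout": self.members[0].dropout,
            "threshold": self.threshold,
            "fingerprint": self.fingerprint,
            "train_config": asdict(self.train_config),
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path, expected_fingerprint: str | None = None) -> "EnsembleModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["format_version"] != cls.FORMAT_VERSION:
                raise ValueError(
                    f"model format v{meta['format_version']} not supported"
                )
            if (
                expected_fingerprint is not None
                and meta["fingerprint"] != expected_fingerprint
            ):
                raise ValueError(
                    "feature-config fingerprint mismatch: model was trained "
                    f"under {meta['fingerprint']!r} but the current feature "
                    f"configuration is {expected_fingerprint!r}; refusing to "
                    "predict"
                )
            members = []
            for i in range(meta["n_members"]):
                member = CapsuleNet(
                    channel_dims=meta["channel_dims"],
                    hidden_widths=meta["hidden_widths"],
                    dropout=meta["dropout"],
                    seed=0,
                )
                for name, arr in member.parameters():
                    arr[...] = data[f"m{i}/{name}"]
                scaler = {}
                for c in meta["channel_dims"]:
                    key = f"m{i}/scaler/{c}/mu"
                    if key in data:
                        scaler[c] = (data[key], data[f"m{i}/scaler/{c}/sigma"])
                member.scaler = scaler or None
                members.append(member)
        return cls(
            members=members,
            threshold=meta["threshold"],
            fingerprint=meta["fingerprint"],
            train_config=TrainConfig(**meta["train_config"]),
        )


def train_ensemble(
    X_pos: dict[str, np.ndarray],
    X_neg_subsets: list[dict[str, np.ndarray]],
    config: TrainConfig | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    fingerprint: str = "",
) -> EnsembleModel:
    """EasyEnsemble training: one member per balanced negative subset,
    each trained on (all positives + that subset)."""
    if not X_neg_subsets:
        raise ValueError("at least one negative subset is required")
    config = config or TrainConfig()
    channel_dims = {c: X_pos[c].shape[1] for c in X_pos}
    n_pos = next(iter(X_pos.values())).shape[0]
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(X_neg_subsets))
    members = []
    for i, X_neg in enumerate(X_neg_subsets):
        n_neg = next(iter(X_neg.values())).shape[0]
        X = {c: np.vstack([X_pos[c], X_neg[c]]) for c in channel_dims}
        y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        member = CapsuleNet(
            channel_dims=channel_dims,
            dropout=config.dropout,
            seed=int(seeds[2 * i] % (2**31)),
        )
        train_one(member, X, y, config, seed=int(seeds[2 * i + 1] % (2**31)))
        members.append(member)
    return EnsembleModel(
        members=members,
        threshold=threshold,
        fingerprint=fingerprint,
        train_config=config,
    )
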