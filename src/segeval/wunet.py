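"""U-Net with learnable, prunable dense skip connections.

The backbone is a classic 2D U-Net: per-level double 3x3 conv + ReLU
blocks, 2x2 max-pool downsampling, bilinear upsampling, and the usual
level-matched encoder-to-decoder concatenation skips. On top of it,
every ordered pair of levels (i < j) *within* the encoder path and
*within* the decoder path gets an extra feed-forward connection, in the
dense-connectivity spirit: the source block's output is spatially
resampled to the target scale (average-pool down / bilinear up),
projected to the target's input channels with a 1x1 convolution, scaled
by a learnable gate sigmoid(w), and added to the target block's input.

After training, connections whose gate value is at or below a pruning
threshold tau are removed entirely; the classic skips are never gated
or pruned, so tau = 1 reduces the network exactly (bit for bit) to the
plain backbone.

Training minimises Dice loss + binary cross-entropy, keeps the
checkpoint with the lowest validation loss, and is fully deterministic
given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import autograd as ag
from .autograd import Tensor
from .geometry import Mask3D


@dataclass(frozen=True)
class WUNetConfig:
    """Architecture and pruning hyper-parameters.

    depth counts resolution levels (encoder blocks); input_size must be
    divisible by 2**(depth-1). base_channels doubles per level.
    """

    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 1
    prune_threshold: float = 0.05
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        f = 2 ** (self.depth - 1)
        h, w = self.input_size
        if h % f or w % f:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2**(depth-1)={f}"
            )

    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]


@dataclass
class ConnectionWeights:
    """Gate state of the extra dense skip connections.

    Keys are ('encoder'|'decoder', source_level, target_level) with
    source < target in path order. ``weights`` are the gate values
    sigmoid(raw); pruned connections contribute exactly 0 (they are
    skipped in the forward pass, not multiplied by zero).
    """

    weights: dict[tuple[str, int, int], float] = field(default_factory=dict)
    kept: dict[tuple[str, int, int], bool] = field(default_factory=dict)

    def n_connections(self) -> int:
        return len(self.weights)

    def kept_set(self) -> set[tuple[str, int, int]]:
        return {k for k, v in self.kept.items() if v}

    def to_json_dict(self) -> dict:
        return {
            "|".join(map(str, k)): {"weight": w, "kept": self.kept[k]}
            for k, w in self.weights.items()
        }


@dataclass
class TrainResult:
    """Outcome of a training run: loss history and best checkpoint info."""

    epochs: int
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    best_val_loss: float
    seed: int
    n_train: int
    n_val: int

    def summary(self) -> str:
        lines = [
            "Weighted-dense-skip U-Net training",
            f"  epochs:        {self.epochs}",
            f"  train/val:     {self.n_train}/{self.n_val} slices",
            f"  seed:          {self.seed}",
            f"  best epoch:    {self.best_epoch} (val loss {self.best_val_loss:.4f})",
            f"  final train loss: {self.train_losses[-1]:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return asdict(self)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class WUNet:
    """Weighted-dense-skip U-Net model (numpy, CPU).

    Parameters live in ``self.params`` (name -> Tensor); the extra
    connection gates in ``self.raw_gates``. Use :meth:`fit` to train,
    :meth:`prune` to threshold the gates, :meth:`predict_stack` for
    slice-wise inference into a :class:`Mask3D`.
    """

    def __init__(self, config: WUNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = config.channels()
        self.params: dict[str, Tensor] = {}
        self.raw_gates: dict[tuple[str, int, int], Tensor] = {}
        self.pruned: set[tuple[str, int, int]] = set()

        def conv_param(name: str, cout: int, cin: int, k: int) -> None:
            self.params[name + ".w"] = Tensor(
                _he_init(rng, (cout, cin, k, k), cin * k * k, dtype), requires_grad=True
            )
            self.params[name + ".b"] = Tensor(
                np.zeros(cout, dtype=dtype), requires_grad=True
            )

        # encoder blocks
        for i in range(config.depth):
            cin = config.in_channels if i == 0 else ch[i - 1]
            conv_param(f"enc{i}.conv1", ch[i], cin, 3)
            conv_param(f"enc{i}.conv2", ch[i], ch[i], 3)
        # decoder blocks, level l = depth-2 .. 0; input = concat(up(ch[l+1]), ch[l])
        for l in range(config.depth - 2, -1, -1):
            cin = ch[l + 1] + ch[l]
            conv_param(f"dec{l}.conv1", ch[l], cin, 3)
            conv_param(f"dec{l}.conv2", ch[l], ch[l], 3)
        conv_param("head", config.out_channels, ch[0], 1)

        # extra dense connections: encoder path and decoder path
        for i in range(config.depth):
            for j in range(i + 1, config.depth):
                # encoder: source block i output (ch[i]) -> block j input (ch[j-1])
                conv_param(f"enc_skip{i}_{j}.proj", ch[j - 1], ch[i], 1)
                self.raw_gates[("encoder", i, j)] = Tensor(
                    np.zeros((), dtype=dtype), requires_grad=True
                )
                # decoder: path nodes 0..depth-1; node 0 = bottleneck output
                # node t>0 = decoder block at level depth-1-t
                lt = config.depth - 1 - j  # target decoder level
                cs = ch[config.depth - 1 - i]  # source node channels
                ct = ch[lt + 1] + ch[lt]  # target concat input channels
                conv_param(f"dec_skip{i}_{j}.proj", ct, cs, 1)
                self.raw_gates[("decoder", i, j)] = Tensor(
                    np.zeros((), dtype=dtype), requires_grad=True
                )

    # -- architecture accessors ------------------------------------------

    def connection_weights(self) -> ConnectionWeights:
        cw = ConnectionWeights()
        for key, t in self.raw_gates.items():
            cw.weights[key] = float(1.0 / (1.0 + np.exp(-t.data)))
            cw.kept[key] = key not in self.pruned
        return cw

    def parameters(self) -> list[Tensor]:
        return list(self.params.values()) + [
            t for k, t in self.raw_gates.items() if k not in self.pruned
        ]

    # -- forward ----------------------------------------------------------

    def _conv(self, name: str, x: Tensor, padding: int) -> Tensor:
        return ag.conv2d(x, self.params[name + ".w"], self.params[name + ".b"], padding)

    def _block(self, name: str, x: Tensor) -> Tensor:
        x = ag.relu(self._conv(name + ".conv1", x, 1))
        return ag.relu(self._conv(name + ".conv2", x, 1))

    def _gated(self, kind: str, i: int, j: int, src: Tensor, resample) -> Tensor:
        name = ("enc_skip" if kind == "encoder" else "dec_skip") + f"{i}_{j}.proj"
        x = resample(src)
        x = self._conv(name, x, 0)
        return ag.scale(x, ag.sigmoid(self.raw_gates[(kind, i, j)]))

    def forward_logits(self, x: np.ndarray, backbone_only: bool = False) -> Tensor:
        """Logit map for a batch (N, C, H, W).

        With ``backbone_only=True`` every extra connection is skipped,
        regardless of the pruning mask — the plain U-Net forward pass.
        """
        cfg = self.config
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None]
        t = Tensor(x)

        def live(kind, i, j):
            return not backbone_only and (kind, i, j) not in self.pruned

        enc_out: list[Tensor] = []
        h = t
        for j in range(cfg.depth):
            if j > 0:
                h = ag.maxpool2x(enc_out[j - 1])
                for i in range(j):
                    if live("encoder", i, j):
                        extra = self._gated(
                            "encoder", i, j, enc_out[i],
                            lambda s, f=2 ** (j - i): ag.avgpool(s, f),
                        )
                        h = ag.add(h, extra)
            h = self._block(f"enc{j}", h)
            enc_out.append(h)

        # decoder path nodes: node 0 = bottleneck output
        nodes: list[Tensor] = [enc_out[-1]]
        d = enc_out[-1]
        for tnode in range(1, cfg.depth):
            l = cfg.depth - 1 - tnode  # resolution level of this decoder block
            up = ag.upsample2x_bilinear(d)
            h = ag.concat_channels(up, enc_out[l])
            for s in range(tnode):
                if live("decoder", s, tnode):
                    extra = self._gated(
                        "decoder", s, tnode, nodes[s],
                        lambda src, f=2 ** (tnode - s): ag.upsample_bilinear(src, f),
                    )
                    h = ag.add(h, extra)
            d = self._block(f"dec{l}", h)
            nodes.append(d)

        return self._conv("head", d, 0)

    def forward(self, x: np.ndarray, backbone_only: bool = False) -> np.ndarray:
        """Sigmoid probability map, values in (0, 1)."""
        from scipy.special import expit

        z = self.forward_logits(x, backbone_only=backbone_only)
        return expit(z.data)

    # -- training ---------------------------------------------------------

    def fit(
        self,
        dataset: Sequence[tuple[np.ndarray, np.ndarray]],
        epochs: int = 50,
        seed: int = 0,
        lr: float = 1e-3,
        batch_size: int = 4,
        val_fraction: float = 0.1,
        fine_tune_after_prune: bool = False,
    ) -> TrainResult:
        """Train on (image, mask) slice pairs; keep the lowest-val-loss
        checkpoint.

        The dataset is split train/val by a seeded shuffle (default 90:10,
        at least one validation slice). Loss is Dice + BCE with equal
        weights, optimised by Adam. Deterministic given ``seed``.
        """
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(dataset))
        n_val = max(1, int(round(val_fraction * len(dataset))))
        if n_val >= len(dataset):
            raise ValueError("dataset too small for a train/val split")
        val_idx, train_idx = order[:n_val], order[n_val:]

        def batch(idx):
            xs = np.stack([np.asarray(dataset[i][0], dtype=self.dtype) for i in idx])
            ys = np.stack([np.asarray(dataset[i][1], dtype=self.dtype) for i in idx])
            return xs[:, None], ys[:, None]

        opt = ag.Adam(self.parameters(), lr=lr)
        train_losses: list[float] = []
        val_losses: list[float] = []
        best_val = np.inf
        best_epoch = -1
        best_state: dict[str, np.ndarray] = {}

        for epoch in range(epochs):
            perm = rng.permutation(train_idx)
            losses = []
            for k in range(0, len(perm), batch_size):
                xb, yb = batch(perm[k : k + batch_size])
                loss = ag.dice_bce_loss(self.forward_logits(xb), yb)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            train_losses.append(float(np.mean(losses)))

            xv, yv = batch(val_idx)
            vloss = ag.dice_bce_loss(self.forward_logits(xv), yv).item()
            if np.isnan(vloss):
                raise RuntimeError(
                    f"validation loss became NaN at epoch {epoch}; "
                    f"train losses so far: {train_losses}"
                )
            val_losses.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_epoch = epoch
                best_state = self.state_dict()

        self.load_state_dict(best_state)
        return TrainResult(
            epochs=epochs,
            train_losses=train_losses,
            val_losses=val_losses,
            best_epoch=best_epoch,
            best_val_loss=float(best_val),
            seed=seed,
            n_train=len(train_idx),
            n_val=len(val_idx),
        )

    # -- pruning ----------------------------------------------------------

    def prune(self, tau: float | None = None) -> ConnectionWeights:
        """Remove extra connections whose gate sigmoid(raw) <= tau.

        Classic skips are untouched. tau=0 keeps everything (gates are
        strictly positive); tau=1 prunes every extra connection, making
        the forward pass identical to the plain backbone.
        """
        if tau is None:
            tau = self.config.prune_threshold
        if tau < 0:
            raise ValueError("tau must be >= 0")
        self.pruned = {
            k
            for k, t in self.raw_gates.items()
            if 1.0 / (1.0 + np.exp(-t.data)) <= tau
        }
        return self.connection_weights()

    def unprune(self) -> None:
        self.pruned = set()

    # -- inference --------------------------------------------------------

    def predict_stack(
        self,
        images: np.ndarray,
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        threshold: float = 0.5,
        largest_component: bool = True,
        batch_size: int = 8,
    ) -> Mask3D:
        """Slice-wise inference on a (nz, H, W) stack into a Mask3D.

        Probability maps are thresholded at 0.5 and, as post-processing,
        only the largest 3D connected component is kept (an empty
        prediction stays empty).
        """
        images = np.asarray(images, dtype=self.dtype)
        probs = np.concatenate(
            [
                self.forward(images[k : k + batch_size, None])[:, 0]
                for k in range(0, len(images), batch_size)
            ]
        )
        vox = (probs >= threshold).astype(np.uint8)
        if largest_component and vox.any():
            labels, n = ndimage.label(vox)
            if n > 1:
                sizes = ndimage.sum_labels(vox, labels, index=np.arange(1, n + 1))
                vox = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
        return Mask3D(vox, spacing, origin)

    # -- state ------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.params.items()}
        for key, t in self.raw_gates.items():
            state["gate|" + "|".join(map(str, key))] = t.data.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()
        for key, t in self.raw_gates.items():
            t.data = state["gate|" + "|".join(map(str, key))].copy()

    def save(self, path: str | Path) -> None:
        """Checkpoint: config + weights + pruning mask (npz + JSON header)."""
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "pruned": sorted("|".join(map(str, k)) for k in self.pruned),
        }
        arrays = self.state_dict()
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "WUNet":
        with np.load(Path(path), allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            cfg_d = meta["config"]
            cfg_d["input_size"] = tuple(cfg_d["input_size"])
            model = cls(WUNetConfig(**cfg_d))
            state = {k: f[k] for k in f.files if k != "__meta__"}
        model.load_state_dict(state)
        model.pruned = {
            (p.split("|")[0], int(p.split("|")[1]), int(p.split("|")[2]))
            for p in meta["pruned"]
        }
        return model
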