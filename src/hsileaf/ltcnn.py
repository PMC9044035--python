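"""The lightweight inception classifier: architecture, loss, training.

The network maps a 200 x 200 x L band-selected reflectance tile to one
of C species.  It has three parts:

* Part I (stem): 5x5/2 conv (64) + 3x3/2 max-pool + 3x3/1 conv (96) +
  3x3/2 max-pool, turning the input into 25 x 25 x 96 shallow features;
* Part II: three inception modules with concatenated output depths
  288 / 296 / 480.  The first two use a 3-path structure (1x1; 1x1->3x3;
  1x1->3x3->3x3, the stacked 3x3 pair standing in for a 5x5 at equal
  receptive field); the third uses 2 paths.  Modules 2 and 3 downsample
  by applying stride 2 on the final convolution of every path, giving
  the 25 -> 13 -> 7 progression under same padding;
* Part III: global average pooling, a 196-unit FC layer, 40% dropout,
  and a C-way softmax output.

Every convolution and the hidden FC layer are followed by ReLU; there is
no batch normalization; all conv/FC layers carry biases.  The loss is
cross-entropy in base-2 (bits), summed over the batch.  Training uses
Adam with an exponentially decayed learning rate (x0.9 every 5 epochs
from 1e-3), batch size 12, and random-crop plus random horizontal /
vertical flip augmentation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .band_selection import BandSelection, apply_selection
from .exceptions import ConstructionError
from .preprocess import DatasetManifest

LN2 = math.log(2.0)

# Inception path widths solved so that the full network with a 6-band
# input and 30 classes has exactly 1,388,950 trainable parameters (see
# resolve_inception_widths).  Paths are tuples of conv output widths in
# order; the last width of each path contributes to the module depth.
DEFAULT_INCEPTION: tuple[dict, ...] = (
    {"paths": ((64,), (175, 128), (16, 48, 96)), "stride": 1},
    {"paths": ((64,), (125, 136), (32, 64, 96)), "stride": 2},
    {"paths": ((160,), (192, 320)), "stride": 2},
)
TARGET_PARAMS_L6 = 1_388_950

# Stage-output trace for a 200 x 200 x L input (spatial, spatial, depth).
CANONICAL_STAGES = (
    ("conv1", (100, 100, 64)),
    ("pool1", (50, 50, 64)),
    ("conv2", (50, 50, 96)),
    ("pool2", (25, 25, 96)),
    ("inception1", (25, 25, 288)),
    ("inception2", (13, 13, 296)),
    ("inception3", (7, 7, 480)),
    ("gap", (1, 1, 480)),
    ("fc", (1, 1, 196)),
    ("output", (1, 1, 30)),
)


@dataclass
class LtCNNSpec:
    """Layer-by-layer description of the lightweight network."""

    in_bands: int = 6
    n_classes: int = 30
    input_size: int = 200
    stem_widths: tuple[int, int] = (64, 96)
    inception: tuple[dict, ...] = DEFAULT_INCEPTION
    fc_width: int = 196
    dropout: float = 0.40

    @property
    def output_depths(self) -> tuple[int, ...]:
        return tuple(sum(p[-1] for p in mod["paths"]) for mod in self.inception)

    @classmethod
    def reduced(
        cls,
        in_bands: int,
        n_classes: int,
        input_size: int = 64,
        width_scale: float = 0.25,
    ) -> "LtCNNSpec":
        """A width-scaled variant for desk-scale experiments.

        Same topology, every channel width multiplied by ``width_scale``
        (minimum 4), smaller input.  Used for smoke training where the
        full network would be needlessly slow on a CPU.
        """

        def s(w: int) -> int:
            return max(4, round(w * width_scale))

        inception = tuple(
            {"paths": tuple(tuple(s(w) for w in p) for p in mod["paths"]),
             "stride": mod["stride"]}
            for mod in DEFAULT_INCEPTION
        )
        return cls(
            in_bands=in_bands,
            n_classes=n_classes,
            input_size=input_size,
            stem_widths=(s(64), s(96)),
            inception=inception,
            fc_width=s(196),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "LtCNNSpec":
        d = json.loads(text)
        d["stem_widths"] = tuple(d["stem_widths"])
        d["inception"] = tuple(
            {"paths": tuple(tuple(p) for p in m["paths"]), "stride": m["stride"]}
            for m in d["inception"]
        )
        return cls(**d)


# ---------------------------------------------------------------------------
# Parameter arithmetic and the width solver
# ---------------------------------------------------------------------------

def _conv_params(k: int, cin: int, cout: int) -> int:
    return k * k * cin * cout + cout


def _module_params(cin: int, paths: tuple[tuple[int, ...], ...]) -> int:
    total = 0
    for path in paths:
        prev = cin
        for depth, w in enumerate(path):
            k = 1 if depth == 0 else 3
            total += _conv_params(k, prev, w)
            prev = w
    return total


def param_count(spec: LtCNNSpec) -> tuple[int, dict[str, int]]:
    """Analytic trainable-parameter count (weights + biases, no BN)."""
    parts: dict[str, int] = {}
    parts["conv1"] = _conv_params(5, spec.in_bands, spec.stem_widths[0])
    parts["conv2"] = _conv_params(3, spec.stem_widths[0], spec.stem_widths[1])
    cin = spec.stem_widths[1]
    for i, mod in enumerate(spec.inception, start=1):
        parts[f"inception{i}"] = _module_params(cin, mod["paths"])
        cin = sum(p[-1] for p in mod["paths"])
    parts["fc"] = cin * spec.fc_width + spec.fc_width
    parts["output"] = spec.fc_width * spec.n_classes + spec.n_classes
    return sum(parts.values()), parts


def _set_knobs(spec: LtCNNSpec, knobs: dict[tuple[int, int, int], int]) -> LtCNNSpec:
    """Return spec with bottleneck widths {(module, path, pos): w} replaced."""
    inception = []
    for mi, mod in enumerate(spec.inception):
        paths = [list(p) for p in mod["paths"]]
        for (m, p, pos), w in knobs.items():
            if m == mi:
                paths[p][pos] = w
        inception.append(
            {"paths": tuple(tuple(p) for p in paths), "stride": mod["stride"]}
        )
    return replace(spec, inception=tuple(inception))


@dataclass
class WidthSolution:
    spec: LtCNNSpec
    total_params: int
    target: int | None
    discrepancy: int  # |total - target|, 0 when exact


def resolve_inception_widths(
    spec: LtCNNSpec | None = None, target_params: int | None = None
) -> WidthSolution:
    """Resolve concrete inception path widths.

    Without a target, the packaged default widths are returned.  With a
    target, the solver searches the 1x1 bottleneck widths (which change
    the parameter count but not the module output depths) for an exact
    match of the full-network trainable parameter count; the search is
    deterministic and exhaustive over bounded ranges.  If no exact
    solution exists the nearest one is returned with its discrepancy.

    The free knobs are the reduce widths of path 2 in all three modules
    and of path 3 in modules 1-2; each enters the total linearly and
    independently, so the search solves a five-term linear Diophantine
    equation by nested enumeration with a divisibility test.
    """
    spec = spec or LtCNNSpec()
    if target_params is None:
        total, _ = param_count(spec)
        return WidthSolution(spec, total, None, 0)

    knob_keys = [(0, 1, 0), (1, 1, 0), (2, 1, 0), (0, 2, 0), (1, 2, 0)]
    base_spec = _set_knobs(spec, {k: 0 for k in knob_keys})
    base, _ = param_count(base_spec)
    steps = []
    for key in knob_keys:
        one, _ = param_count(_set_knobs(base_spec, {key: 1}))
        steps.append(one - base)
    a1, a2, a3, d1, d2 = steps  # per-unit costs of each knob

    # enumeration order: nearest to conventional (GoogLeNet-like) widths
    # first, so the first exact hit has sensible proportions
    def centered(lo: int, hi: int, center: int) -> list[int]:
        return sorted(range(lo, hi + 1), key=lambda v: (abs(v - center), v))

    x_lo, x_hi = 8, 256      # module-1 path-2 reduce
    d_order = centered(8, 128, 16)    # module-1 path-3 reduce
    e_order = centered(8, 128, 32)    # module-2 path-3 reduce
    z_order = centered(8, 512, 192)   # module-3 path-2 reduce
    y_order = centered(8, 256, 96)    # module-2 path-2 reduce

    best: tuple[int, dict] | None = None
    residual0 = target_params - base
    for d in d_order:
        for e in e_order:
            r1 = residual0 - d1 * d - d2 * e
            for z in z_order:
                r2 = r1 - a3 * z
                if r2 < a1 * x_lo + a2 * 8:
                    continue
                for y in y_order:
                    r3 = r2 - a2 * y
                    if r3 < a1 * x_lo:
                        continue
                    x, rem = divmod(r3, a1)
                    if x_lo <= x <= x_hi:
                        knobs = {
                            (0, 1, 0): x, (1, 1, 0): y, (2, 1, 0): z,
                            (0, 2, 0): d, (1, 2, 0): e,
                        }
                        if rem == 0:
                            solved = _set_knobs(spec, knobs)
                            total, _ = param_count(solved)
                            return WidthSolution(solved, total, target_params, 0)
                        if best is None or rem < best[0]:
                            best = (rem, knobs)
    if best is None:  # pragma: no cover
        raise RuntimeError("width search ranges exhausted without a candidate")
    solved = _set_knobs(spec, best[1])
    total, _ = param_count(solved)
    return WidthSolution(solved, total, target_params, abs(total - target_params))


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

class LtCNNModel:
    """A built, trainable network with its stage-output shape trace."""

    def __init__(self, spec: LtCNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w1, w2 = spec.stem_widths
        stem = [
            nn.Conv2D(spec.in_bands, w1, k=5, stride=2, rng=rng), nn.ReLU(),
            nn.MaxPool(3, 2),
            nn.Conv2D(w1, w2, k=3, stride=1, rng=rng), nn.ReLU(),
            nn.MaxPool(3, 2),
        ]
        modules = []
        cin = w2
        for mod in spec.inception:
            paths = []
            for path in mod["paths"]:
                layers: list[nn.Layer] = []
                prev = cin
                for depth, w in enumerate(path):
                    k = 1 if depth == 0 else 3
                    stride = mod["stride"] if depth == len(path) - 1 else 1
                    layers += [nn.Conv2D(prev, w, k=k, stride=stride, rng=rng),
                               nn.ReLU()]
                    prev = w
                paths.append(nn.Sequential(layers))
            modules.append(nn.Inception(paths))
            cin = sum(p[-1] for p in mod["paths"])
        head = [
            nn.GlobalAvgPool(),
            nn.Dense(cin, spec.fc_width, rng=rng), nn.ReLU(),
            nn.Dropout(spec.dropout),
            nn.Dense(spec.fc_width, spec.n_classes, rng=rng),
        ]
        self.net = nn.Sequential(stem + modules + head)
        self.shape_trace = self._trace()
        expected = shape_trace(spec)
        if self.shape_trace != expected:
            raise ConstructionError(
                f"built trace {self.shape_trace} != declared trace {expected}"
            )

    def _trace(self) -> list[tuple[str, tuple[int, int, int]]]:
        names = iter(
            ["conv1", "pool1", "conv2", "pool2", "inception1", "inception2",
             "inception3", "gap", "fc", "output"]
        )
        trace = []
        shape = (self.spec.input_size, self.spec.input_size, self.spec.in_bands)
        for layer in self.net.layers:
            shape = layer.out_shape(shape)
            if isinstance(layer, (nn.Conv2D, nn.MaxPool, nn.Inception,
                                  nn.GlobalAvgPool, nn.Dense)):
                trace.append((next(names), shape))
        return trace

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.net.params())

    def forward_logits(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        return self.net.forward(x.astype(np.float32), train=train, rng=rng)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward_logits(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward_logits(x, train=False).argmax(axis=1)

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        np.savez_compressed(path, spec=np.array(self.spec.to_json()), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LtCNNModel":
        with np.load(path) as z:
            spec = LtCNNSpec.from_json(str(z["spec"]))
            model = cls(spec)
            for i, p in enumerate(model.net.params()):
                p.value[...] = z[f"p{i}"]
        return model


def shape_trace(spec: LtCNNSpec) -> list[tuple[str, tuple[int, int, int]]]:
    """Analytic stage-output trace under same-padding ceil arithmetic."""

    def half(s: int) -> int:
        return math.ceil(s / 2)

    s = spec.input_size
    trace = []
    s = half(s); trace.append(("conv1", (s, s, spec.stem_widths[0])))
    s = half(s); trace.append(("pool1", (s, s, spec.stem_widths[0])))
    trace.append(("conv2", (s, s, spec.stem_widths[1])))
    s = half(s); trace.append(("pool2", (s, s, spec.stem_widths[1])))
    for i, (mod, depth) in enumerate(zip(spec.inception, spec.output_depths), 1):
        if mod["stride"] == 2:
            s = half(s)
        trace.append((f"inception{i}", (s, s, depth)))
    trace.append(("gap", (1, 1, spec.output_depths[-1])))
    trace.append(("fc", (1, 1, spec.fc_width)))
    trace.append(("output", (1, 1, spec.n_classes)))
    return trace


def build_model(spec: LtCNNSpec, seed: int = 0) -> LtCNNModel:
    """Build the network; fails loud if the shape trace is inconsistent."""
    return LtCNNModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# Loss, augmentation, schedule, training
# ---------------------------------------------------------------------------

def cross_entropy_loss(
    predictions: np.ndarray, targets: np.ndarray, clamp: float = 1e-12
) -> float:
    """Cross-entropy in bits, summed over the batch.

    ``predictions`` are per-row probability distributions; ``targets``
    are one-hot rows.  Zero predicted probability at a true class is
    clamped at ``clamp`` rather than returning inf.
    """
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("predictions and targets must share a shape")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("prediction rows must sum to 1")
    return float(-(y * np.log2(np.clip(p, clamp, None))).sum())


def augment(
    tile: np.ndarray, input_size: int, rng: np.random.Generator | None = None,
    train: bool = True,
) -> np.ndarray:
    """Random crop + independent horizontal/vertical flips.

    Evaluation mode (``train=False``) center-crops and never flips.
    """
    h, w = tile.shape[:2]
    if h < input_size or w < input_size:
        raise ValueError(
            f"tile {h}x{w} smaller than crop size {input_size}"
        )
    if train:
        if rng is None:
            raise ValueError("training-mode augmentation requires an rng")
        r0 = int(rng.integers(0, h - input_size + 1))
        c0 = int(rng.integers(0, w - input_size + 1))
        out = tile[r0 : r0 + input_size, c0 : c0 + input_size]
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
        return np.ascontiguousarray(out)
    r0 = (h - input_size) // 2
    c0 = (w - input_size) // 2
    return np.ascontiguousarray(
        tile[r0 : r0 + input_size, c0 : c0 + input_size]
    )


@dataclass
class TrainConfig:
    """Training protocol: Adam, exponential LR decay, crop/flip augment."""

    batch_size: int = 12
    epochs: int = 200
    lr0: float = 1e-3
    lr_decay: float = 0.9
    decay_every: int = 5
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.decay_every) <= 0:
            raise ValueError("batch_size, epochs, decay_every must be positive")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """lr0 * decay^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.lr_decay ** (epoch // config.decay_every)


def _load_split(
    manifest: DatasetManifest, selection: BandSelection | None, split: str
) -> tuple[list[np.ndarray], np.ndarray]:
    records = manifest.subset(split)
    if records.empty:
        raise ValueError(f"manifest has no '{split}' records; run split_dataset")
    tiles, labels = [], []
    for path, label in zip(records["path"], records["label"]):
        cube = manifest.load(path)
        if selection is not None:
            cube = apply_selection(cube, selection)
        tiles.append(cube.values.astype(np.float32))
        labels.append(int(label))
    return tiles, np.array(labels, dtype=int)


def train(
    manifest: DatasetManifest,
    selection: BandSelection | None,
    spec: LtCNNSpec,
    config: TrainConfig,
) -> tuple[LtCNNModel, dict]:
    """Train from scratch on the manifest's train split.

    Tiles are loaded once (band selection applied lazily per tile) and
    kept in memory; each step draws a fresh crop/flip.  Reflectance is
    already in [0, 1], so no further input standardization is applied.
    Returns the model and a history dict with per-epoch mean loss (bits
    per image) and learning rate.
    """
    rng = np.random.default_rng(config.seed)
    model = build_model(spec, seed=int(rng.integers(0, 2**31 - 1)))
    tiles, labels = _load_split(manifest, selection, "train")
    n = len(tiles)
    C = spec.n_classes
    opt = nn.Adam(model.net.params())
    history = {"epoch": [], "loss": [], "lr": []}
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        perm = rng.permutation(n)
        epoch_bits = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xs = [
                augment(tiles[i], spec.input_size, rng, train=config.augment)
                if config.augment
                else augment(tiles[i], spec.input_size, train=False)
                for i in idx
            ]
            x = np.stack(xs)
            y = np.zeros((len(idx), C), dtype=np.float32)
            y[np.arange(len(idx)), labels[idx]] = 1.0
            logits = model.forward_logits(x, train=True, rng=rng)
            p = nn.softmax(logits)
            batch_bits = cross_entropy_loss(p, y)
            if not np.isfinite(batch_bits):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: logits range "
                    f"[{logits.min()}, {logits.max()}]"
                )
            epoch_bits += batch_bits
            # d(loss)/d(logits) for base-2 cross-entropy over the batch sum
            dz = ((p - y) / LN2).astype(np.float32)
            opt.zero_grad()
            model.net.backward(dz)
            opt.step(lr)
        history["epoch"].append(epoch)
        history["loss"].append(epoch_bits / n)
        history["lr"].append(lr)
    return model, history


def predict_split(
    model: LtCNNModel,
    manifest: DatasetManifest,
    selection: BandSelection | None,
    split: str = "test",
    batch_size: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Center-crop predictions for a manifest split: (truth, predicted)."""
    tiles, labels = _load_split(manifest, selection, split)
    preds = []
    for start in range(0, len(tiles), batch_size):
        x = np.stack(
            [augment(t, model.spec.input_size, train=False)
             for t in tiles[start : start + batch_size]]
        )
        preds.append(model.predict(x))
    return labels, np.concatenate(preds)
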