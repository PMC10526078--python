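"""Six-layer fully-convolutional segmenter with weighted cross-entropy.

Layers 1-3: 3x3 same-padded convolution (in->53, then 53->53) + ReLU +
2x2/2 max-pooling (floor semantics on odd sizes).  Layers 4-5: 1x1
convolutions (53->53 with ReLU, then 53->2 with ReLU), acting as a
pixel-wise fully connected network.  Layer 6: bilinear upsampling of the
2-channel score map back to the input size.  The argmax over the two score
channels gives the segmentation, with ties resolved to non-ablated.

Training minimizes a weighted average cross-entropy (non-ablated weight 1,
ablated weight = non-ablated:ablated pixel ratio, unlabeled weight 0) with
the Adam optimizer.  The network and its backward pass are implemented in
NumPy; everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pals.core_io import (
    ABLATED,
    NON_ABLATED,
    STATE_MAX_NORMALIZED,
    Frame,
    LabelMask,
    SegmentationResult,
    ValidationError,
)
from pals.sampling import ClassWeights

HIDDEN_CHANNELS = 53
N_CLASSES = 2
MIN_INPUT_SIZE = 8  # three 2x pool stages must not collapse


@dataclass(frozen=True)
class CNNSpec:
    """Architecture parameters; only the input channel count varies."""

    in_channels: int
    hidden_channels: int = HIDDEN_CHANNELS
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValidationError("in_channels must be >= 1")


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 4
    weights: ClassWeights = field(default_factory=lambda: ClassWeights(w_ablated=1.0))
    seed: int = 0


# ---------------------------------------------------------------------------
# Layer primitives (channels-first float32 arrays)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C,H,W) -> (H*W, C*k*k) patch matrix for a same-size convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # windows: (C, H, W, k, k) -> (H, W, C, k, k) -> (H*W, C*k*k)
    c, h, w = windows.shape[:3]
    return np.ascontiguousarray(windows.transpose(1, 2, 0, 3, 4)).reshape(
        h * w, c * k * k
    )


class _Conv:
    """k x k convolution with 'same' zero padding (k odd).

    ``is_input_layer`` layers skip the (unused) gradient with respect to
    their input.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        is_input_layer: bool = False,
    ):
        fan_in = cin * k * k
        self.k = k
        self.pad = k // 2
        self.is_input_layer = is_input_layer
        self.W = (rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.full(cout, 0.01, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(
        self, x: np.ndarray, keep: bool, cols: np.ndarray | None = None
    ) -> np.ndarray:
        cout, cin, k, _ = self.W.shape
        h, w = x.shape[1:]
        if cols is None:
            if k == 1:
                cols = x.reshape(cin, h * w).T
            else:
                cols = _im2col(x, k, self.pad)
        out = cols @ self.W.reshape(cout, -1).T + self.b
        if keep:
            self._cols = cols
            self._shape = (h, w)
        return np.ascontiguousarray(out.T.reshape(cout, h, w))

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        cout, cin, k, _ = self.W.shape
        h, w = self._shape
        dflat = dout.reshape(cout, h * w).T  # (HW, cout)
        self.dW += (dflat.T @ self._cols).reshape(self.W.shape)
        self.db += dflat.sum(axis=0)
        if self.is_input_layer:
            return None
        if k == 1:
            dx = dflat @ self.W.reshape(cout, cin)
            return np.ascontiguousarray(dx.T.reshape(cin, h, w))
        # dx = convolution of dout with spatially flipped, transposed kernels
        w_rot = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, k, k)
        cols_back = _im2col(dout, k, self.pad)
        dx = cols_back @ w_rot.reshape(cin, -1).T
        return np.ascontiguousarray(dx.T.reshape(cin, h, w))

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if keep:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    """2x2 max-pooling with stride 2; odd trailing rows/columns dropped."""

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2]
        win = xc.reshape(c, h2, 2, w2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, h2, w2, 4
        )
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
        if keep:
            self._idx = idx
            self._in_shape = (c, h, w)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        h2, w2 = dout.shape[1:]
        dwin = np.zeros((c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=3)
        dx = np.zeros((c, h, w), dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2] = (
            dwin.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(
                c, 2 * h2, 2 * w2
            )
        )
        return dx


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation operator (half-pixel-center mapping)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(np.float32)
    rows = np.arange(n_out)
    np.add.at(m, (rows, i0), 1.0 - frac)
    np.add.at(m, (rows, i1), frac)
    return m


class _BilinearUp:
    """Bilinear upsampling to a fixed output size; a linear operator whose
    backward pass is its transpose."""

    def forward(self, x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
        h, w = x.shape[1:]
        self._rr = _interp_matrix(out_hw[0], h)
        self._rc = _interp_matrix(out_hw[1], w)
        return np.matmul(np.matmul(self._rr[None], x), self._rc.T[None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.matmul(np.matmul(self._rr.T[None], dout), self._rc[None])


# ---------------------------------------------------------------------------
# The segmenter
# ---------------------------------------------------------------------------

class CNNSegmenter:
    """The six-layer fully-convolutional pixel classifier."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.hidden_channels
        self.conv1 = _Conv(spec.in_channels, ch, 3, rng, is_input_layer=True)
        self.conv2 = _Conv(ch, ch, 3, rng)
        self.conv3 = _Conv(ch, ch, 3, rng)
        self.conv4 = _Conv(ch, ch, 1, rng)
        self.conv5 = _Conv(ch, spec.n_classes, 1, rng)
        self.relu = [_ReLU() for _ in range(5)]
        self.pool = [_MaxPool2() for _ in range(3)]
        self.up = _BilinearUp()
        self._convs = [self.conv1, self.conv2, self.conv3, self.conv4, self.conv5]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        """(C,H,W) float32 -> (2,H,W) score map."""
        c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValidationError(
                f"input has {c} channels, model expects {self.spec.in_channels}"
            )
        if h < MIN_INPUT_SIZE or w < MIN_INPUT_SIZE:
            raise ValidationError(
                f"input {h}x{w} too small; need at least "
                f"{MIN_INPUT_SIZE}x{MIN_INPUT_SIZE}"
            )
        out = x
        for i in range(3):
            out = self._convs[i].forward(out, keep)
            out = self.relu[i].forward(out, keep)
            out = self.pool[i].forward(out, keep)
        out = self.relu[3].forward(self.conv4.forward(out, keep), keep)
        out = self.relu[4].forward(self.conv5.forward(out, keep), keep)
        return self.up.forward(out, (h, w))

    def backward(self, dscores: np.ndarray) -> None:
        d = self.up.backward(dscores)
        d = self.conv5.backward(self.relu[4].backward(d))
        d = self.conv4.backward(self.relu[3].backward(d))
        for i in (2, 1, 0):
            d = self.pool[i].backward(d)
            d = self.relu[i].backward(d)
            d = self._convs[i].backward(d)

    def forward_logits(
        self, x: np.ndarray, keep: bool = False, cols1: np.ndarray | None = None
    ) -> np.ndarray:
        """Training-path forward: upsampled layer-5 scores WITHOUT the final
        ReLU.  Softmax cross-entropy on the post-ReLU scores is degenerate
        (both channels can die simultaneously, zeroing all gradients), so
        optimization uses the pre-activation scores; inference keeps the
        specified ReLU + upsample + argmax path.

        ``cols1`` optionally supplies the precomputed layer-1 patch matrix
        (it depends only on the input, so callers may cache it per frame).
        """
        out = self.conv1.forward(x, keep, cols=cols1)
        out = self.pool[0].forward(self.relu[0].forward(out, keep), keep)
        for i in (1, 2):
            out = self._convs[i].forward(out, keep)
            out = self.relu[i].forward(out, keep)
            out = self.pool[i].forward(out, keep)
        out = self.relu[3].forward(self.conv4.forward(out, keep), keep)
        out = self.conv5.forward(out, keep)
        return self.up.forward(out, (x.shape[1], x.shape[2]))

    def backward_logits(self, dscores: np.ndarray) -> None:
        d = self.up.backward(dscores)
        d = self.conv5.backward(d)
        d = self.conv4.backward(self.relu[3].backward(d))
        for i in (2, 1, 0):
            d = self.pool[i].backward(d)
            d = self.relu[i].backward(d)
            d = self._convs[i].backward(d)

    def zero_grad(self) -> None:
        for conv in self._convs:
            conv.dW[:] = 0.0
            conv.db[:] = 0.0

    @property
    def params(self):
        return [p for conv in self._convs for p in conv.params]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, wavelengths_nm=None) -> None:
        arrays = {}
        for i, conv in enumerate(self._convs):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        meta = {
            "in_channels": self.spec.in_channels,
            "hidden_channels": self.spec.hidden_channels,
            "n_classes": self.spec.n_classes,
            "wavelengths_nm": list(wavelengths_nm) if wavelengths_nm is not None else None,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["CNNSegmenter", list | None]:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(
                CNNSpec(
                    in_channels=meta["in_channels"],
                    hidden_channels=meta["hidden_channels"],
                    n_classes=meta["n_classes"],
                )
            )
            for i, conv in enumerate(model._convs):
                conv.W = data[f"W{i}"]
                conv.b = data[f"b{i}"]
                conv.dW = np.zeros_like(conv.W)
                conv.db = np.zeros_like(conv.b)
        return model, meta["wavelengths_nm"]


def build(spec: CNNSpec, seed: int = 0) -> CNNSegmenter:
    return CNNSegmenter(spec, seed=seed)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _weight_map(mask: LabelMask, weights: ClassWeights) -> np.ndarray:
    wmap = np.zeros(mask.codes.shape, dtype=np.float32)
    wmap[mask.codes == NON_ABLATED] = weights.w_nonablated
    wmap[mask.codes == ABLATED] = weights.w_ablated
    return wmap


def loss(scores: np.ndarray, mask: LabelMask, weights: ClassWeights) -> float:
    """Weighted average softmax cross-entropy over labeled pixels.

    ``scores`` is H x W x 2.  The normalizer is the sum of pixel weights, so
    an all-unlabeled mask yields zero loss.
    """
    value, _ = _loss_and_grad(
        np.ascontiguousarray(np.moveaxis(np.asarray(scores), 2, 0)), mask, weights
    )
    return value


def _loss_and_grad(
    scores_cf: np.ndarray, mask: LabelMask, weights: ClassWeights
) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(scores) for channels-first (2,H,W) scores."""
    if scores_cf.shape[1:] != mask.codes.shape:
        raise ValidationError("scores and mask must share H x W")
    wmap = _weight_map(mask, weights)
    total_w = float(wmap.sum())
    if total_w == 0.0:
        return 0.0, np.zeros_like(scores_cf)
    s = scores_cf - scores_cf.max(axis=0, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=0, keepdims=True)
    target = (mask.codes == ABLATED).astype(np.int64)
    logp = s - np.log(e.sum(axis=0, keepdims=True))
    picked = np.take_along_axis(logp, target[None], axis=0)[0]
    value = float(-(wmap * picked).sum() / total_w)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[None], 1.0, axis=0)
    grad = (wmap[None] * (p - onehot) / total_w).astype(np.float32)
    return value, grad


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)


def _frame_input(frame: Frame) -> np.ndarray:
    if frame.cube.state != STATE_MAX_NORMALIZED:
        raise ValidationError("CNN expects preprocessed (max-normalized) frames")
    return np.ascontiguousarray(
        np.moveaxis(frame.cube.intensities, 2, 0).astype(np.float32)
    )


def fit(
    model: CNNSegmenter, frames: list[Frame], config: TrainConfig
) -> list[float]:
    """Train in place; returns the per-epoch mean loss trace."""
    if not frames:
        raise ValidationError("fit requires at least one frame")
    channels = {f.cube.shape[2] for f in frames}
    if channels != {model.spec.in_channels}:
        raise ValidationError(
            f"frame channel counts {sorted(channels)} inconsistent with model "
            f"({model.spec.in_channels})"
        )
    inputs = [_frame_input(f) for f in frames]
    masks = [f.mask for f in frames]
    # Layer-1 patch matrices depend only on the inputs; cache them across
    # epochs when they fit comfortably in memory.
    cols_bytes = 4 * sum(
        x.shape[1] * x.shape[2] * x.shape[0] * 9 for x in inputs
    )
    cols1 = (
        [_im2col(x, 3, 1) for x in inputs] if cols_bytes < 1_500_000_000 else None
    )
    rng = np.random.default_rng(config.seed)
    optimizer = _Adam(model.params, lr=config.learning_rate)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(frames))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            model.zero_grad()
            batch_loss = 0.0
            for j in batch:
                scores = model.forward_logits(
                    inputs[j],
                    keep=True,
                    cols1=cols1[j] if cols1 is not None else None,
                )
                value, grad = _loss_and_grad(scores, masks[j], config.weights)
                model.backward_logits(grad / len(batch))
                batch_loss += value
            optimizer.step()
            epoch_losses.append(batch_loss / len(batch))
        trace.append(float(np.mean(epoch_losses)))
    return trace


def segment(model: CNNSegmenter, frame: Frame) -> SegmentationResult:
    """Score map + argmax decision (ties resolve to non-ablated)."""
    scores = model.forward(_frame_input(frame), keep=False)
    return SegmentationResult.from_scores(np.moveaxis(scores, 0, 2))
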