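"""Depthwise-separable convolutional classifier on spectral patches.

A separable convolution factorizes a standard convolution into a depthwise
step (each of the C input channels convolved independently with its own
K x K kernel, valid padding, no channel mixing) followed by a pointwise step
(a 1 x 1 convolution mixing the C channels into E outputs).  Per block this
costs C*K^2 + C*E parameters against C*E*K^2 for the standard layer — the
economy that makes training on high-band-count pixel patches cheap.

Both operators follow the index form

    O_c[i, j] = sum(I_c[i:i+K, j:j+K] * K_c)    (depthwise, cross-correlation)
    E_e[i, j] = sum_c  P[e, c] * O_c[i, j]      (pointwise)

and are implemented with plain numpy so they can be checked against
nested-loop oracles to machine precision.  The classifier stacks separable
blocks with ReLU, global average pooling and a dense softmax head, and is
trained with mini-batch SGD with momentum on a class-weighted cross-entropy;
forward, backward and the update rule are all written out here, so training
is bitwise-reproducible from a seed.

Spectral bands play the role of input channels: a sample is a ws x ws x B
patch presented to the network as B feature maps of size ws x ws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import HSCube, LabelMask, PipelineConfig
from .sscd import PixelSample

__all__ = [
    "FeatureMap",
    "SepConvParams",
    "ClassifierSpec",
    "TrainResult",
    "SCNNClassifier",
    "depthwise_conv",
    "pointwise_conv",
    "separable_block",
    "build_classifier",
    "train_classifier",
    "predict_map",
]


@dataclass
class FeatureMap:
    """A C x H x W stack of feature channels."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"feature map must be C x H x W; got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature map contains non-finite values")

    @property
    def channels(self) -> int:
        return self.data.shape[0]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, FeatureMap) else np.asarray(x, dtype=np.float64)


@dataclass
class SepConvParams:
    """Parameters of one separable block: C depthwise kernels + an E x C mix."""

    depthwise: np.ndarray  # (C, K, K)
    pointwise: np.ndarray  # (E, C)
    bias: np.ndarray | None = None  # (E,)

    def __post_init__(self) -> None:
        self.depthwise = np.asarray(self.depthwise, dtype=np.float64)
        self.pointwise = np.asarray(self.pointwise, dtype=np.float64)
        if self.depthwise.ndim != 3 or self.depthwise.shape[1] != self.depthwise.shape[2]:
            raise ValueError(f"depthwise must be (C, K, K); got {self.depthwise.shape}")
        if self.pointwise.ndim != 2:
            raise ValueError(f"pointwise must be (E, C); got {self.pointwise.shape}")
        if self.pointwise.shape[1] != self.depthwise.shape[0]:
            raise ValueError(
                f"pointwise expects {self.depthwise.shape[0]} channels; "
                f"got {self.pointwise.shape[1]}"
            )
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.pointwise.shape[0],):
                raise ValueError("bias length must equal E")

    @property
    def kernel_size(self) -> int:
        return self.depthwise.shape[1]

    @property
    def param_count(self) -> int:
        c, k, _ = self.depthwise.shape
        e = self.pointwise.shape[0]
        return c * k * k + c * e + (e if self.bias is not None else 0)

    @property
    def standard_conv_param_count(self) -> int:
        """Parameter count of the equivalent standard C->E, K x K convolution."""
        c, k, _ = self.depthwise.shape
        return c * self.pointwise.shape[0] * k * k


def depthwise_conv(input, kernels: np.ndarray) -> np.ndarray:
    """Per-channel valid cross-correlation; output (C, H-K+1, W-K+1)."""
    x = _as_array(input)
    kernels = np.asarray(kernels, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"input must be C x H x W; got {x.shape}")
    c, h, w = x.shape
    if kernels.shape[0] != c:
        raise ValueError(f"{kernels.shape[0]} kernels for {c} channels")
    k = kernels.shape[1]
    if kernels.shape[1] != kernels.shape[2]:
        raise ValueError(f"kernels must be square; got {kernels.shape}")
    if k > h or k > w:
        raise ValueError(f"kernel {k} exceeds spatial size {h}x{w}")
    windows = sliding_window_view(x, (k, k), axis=(1, 2))  # (C, H', W', K, K)
    return np.einsum("chwij,cij->chw", windows, kernels, optimize=True)


def pointwise_conv(input, kernels: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """1 x 1 convolution: at every pixel, the linear map kernels @ channel-vector."""
    x = _as_array(input)
    kernels = np.asarray(kernels, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"input must be C x H x W; got {x.shape}")
    if kernels.ndim != 2 or kernels.shape[1] != x.shape[0]:
        raise ValueError(
            f"kernels must be (E, {x.shape[0]}); got {kernels.shape}"
        )
    out = np.einsum("ec,chw->ehw", kernels, x, optimize=True)
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)[:, None, None]
    return out


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


_ACTIVATIONS = {"relu": _relu, "identity": lambda x: x}


def separable_block(input, params: SepConvParams, activation: str = "relu") -> np.ndarray:
    """activation(pointwise(depthwise(input))); output (E, H-K+1, W-K+1)."""
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    mid = depthwise_conv(input, params.depthwise)
    out = pointwise_conv(mid, params.pointwise, params.bias)
    return _ACTIVATIONS[activation](out)


@dataclass
class ClassifierSpec:
    """Architecture of the patch classifier.

    ``blocks`` is an ordered list of (kernel K, output channels E) separable
    blocks with the named activation between them; after the blocks a global
    average pool and a dense layer map to ``n_classes`` scores.  The spec is
    valid for an input patch only if each block's K fits the remaining
    spatial extent.
    """

    input_ws: int
    input_bands: int
    blocks: list[tuple[int, int]] = field(default_factory=lambda: [(3, 16), (3, 32)])
    activation: str = "relu"
    n_classes: int = 3

    def __post_init__(self) -> None:
        self.blocks = [(int(k), int(e)) for k, e in self.blocks]
        spatial = self.input_ws
        for k, e in self.blocks:
            if k < 1 or e < 1:
                raise ValueError(f"bad block ({k}, {e})")
            if k > spatial:
                raise ValueError(
                    f"block kernel {k} exceeds remaining spatial size {spatial}"
                )
            spatial -= k - 1
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @classmethod
    def for_patch(
        cls,
        ws: int,
        bands: int,
        block_channels: tuple[int, ...] = (16, 32),
        kernel: int = 3,
        n_classes: int = 3,
    ) -> "ClassifierSpec":
        """Default architecture, with kernels clipped to the patch size.

        At ws = 1 every block degenerates to a pointwise (1 x 1) layer, so the
        network classifies from the single-pixel spectrum alone — which keeps
        the whole window-size grid runnable.
        """
        blocks = []
        spatial = ws
        for e in block_channels:
            k = min(kernel, spatial)
            blocks.append((k, e))
            spatial -= k - 1
        return cls(input_ws=ws, input_bands=bands, blocks=blocks, n_classes=n_classes)

    def to_dict(self) -> dict:
        return {
            "input_ws": self.input_ws,
            "input_bands": self.input_bands,
            "blocks": [list(b) for b in self.blocks],
            "activation": self.activation,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        d = dict(d)
        d["blocks"] = [tuple(b) for b in d["blocks"]]
        return cls(**d)


@dataclass
class TrainResult:
    """Outcome of one training run: the fitted model plus its loss history."""

    model: "SCNNClassifier"
    loss_history: list[float]
    seed: int
    config: dict

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.loss_history):
            raise RuntimeError(
                f"training diverged: non-finite loss in history {self.loss_history}"
            )


class SCNNClassifier:
    """Separable-convolution patch classifier with numpy forward/backward."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: list[SepConvParams] = []
        c = spec.input_bands
        for k, e in spec.blocks:
            # He-style init scaled to the fan-in of each factor
            dw = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(c, k, k))
            pw = rng.normal(0.0, np.sqrt(2.0 / c), size=(e, c))
            self.params.append(SepConvParams(dw, pw, np.zeros(e)))
            c = e
        self.dense_w = rng.normal(0.0, np.sqrt(2.0 / c), size=(spec.n_classes, c))
        self.dense_b = np.zeros(spec.n_classes)
        # per-band input standardization, fitted on the training set
        self.input_mean = np.zeros(spec.input_bands)
        self.input_sd = np.ones(spec.input_bands)

    # ------------------------------------------------------------------
    # forward / backward on batches (N, B, ws, ws)
    # ------------------------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean[:, None, None]) / self.input_sd[:, None, None]

    def _forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Return class logits (N, n_classes); fills ``cache`` for backprop."""
        a = self._standardize(x)
        for p in self.params:
            k = p.kernel_size
            win = sliding_window_view(a, (k, k), axis=(2, 3))  # (N,C,H',W',K,K)
            mid = np.einsum("nchwij,cij->nchw", win, p.depthwise, optimize=True)
            z = np.einsum("ec,nchw->nehw", p.pointwise, mid, optimize=True)
            z += p.bias[:, None, None]
            out = _ACTIVATIONS[self.spec.activation](z)
            if cache is not None:
                cache.append((a, mid, z))
            a = out
        pooled = a.mean(axis=(2, 3))  # (N, E)
        logits = pooled @ self.dense_w.T + self.dense_b
        if cache is not None:
            cache.append((a, pooled))
        return logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def _backward(self, cache: list, dlogits: np.ndarray, grads: dict) -> None:
        a_last, pooled = cache[-1]
        grads["dense_w"] = dlogits.T @ pooled
        grads["dense_b"] = dlogits.sum(axis=0)
        dpooled = dlogits @ self.dense_w  # (N, E)
        _, _, hh, ww = a_last.shape
        da = np.broadcast_to(
            dpooled[:, :, None, None] / (hh * ww), a_last.shape
        ).copy()
        grads["blocks"] = [None] * len(self.params)
        for bi in range(len(self.params) - 1, -1, -1):
            a_in, mid, z = cache[bi]
            p = self.params[bi]
            if self.spec.activation == "relu":
                dz = da * (z > 0)
            else:
                dz = da
            dbias = dz.sum(axis=(0, 2, 3))
            dpw = np.einsum("nehw,nchw->ec", dz, mid, optimize=True)
            dmid = np.einsum("ec,nehw->nchw", p.pointwise, dz, optimize=True)
            k = p.kernel_size
            win_in = sliding_window_view(a_in, (k, k), axis=(2, 3))
            ddw = np.einsum("nchwij,nchw->cij", win_in, dmid, optimize=True)
            if bi > 0:
                pad = k - 1
                dmid_p = np.pad(dmid, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
                win_d = sliding_window_view(dmid_p, (k, k), axis=(2, 3))
                flipped = p.depthwise[:, ::-1, ::-1]
                da = np.einsum("nchwij,cij->nchw", win_d, flipped, optimize=True)
            grads["blocks"][bi] = (ddw, dpw, dbias)

    # ------------------------------------------------------------------
    # training / inference
    # ------------------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        config: PipelineConfig,
    ) -> TrainResult:
        """Mini-batch SGD with momentum on class-weighted cross-entropy.

        Class weights are inverse frequencies normalized to mean 1, so the
        dominant background class cannot drown the loss.  The per-epoch loss
        recorded is the weighted mean cross-entropy over the epoch.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if x.ndim != 4 or x.shape[0] == 0:
            raise ValueError("need a non-empty (N, B, ws, ws) sample array")
        if x.shape[0] != y.shape[0]:
            raise ValueError("sample/label count mismatch")
        self.input_mean = x.mean(axis=(0, 2, 3))
        self.input_sd = np.maximum(x.std(axis=(0, 2, 3)), 1e-8)
        counts = np.bincount(y, minlength=self.spec.n_classes).astype(np.float64)
        present = counts > 0
        weights = np.zeros_like(counts)
        weights[present] = 1.0 / counts[present]
        weights = np.where(present, weights / weights[present].mean(), 0.0)
        rng = np.random.default_rng(config.seed)
        velocity = {
            "dense_w": np.zeros_like(self.dense_w),
            "dense_b": np.zeros_like(self.dense_b),
            "blocks": [
                (np.zeros_like(p.depthwise), np.zeros_like(p.pointwise), np.zeros_like(p.bias))
                for p in self.params
            ],
        }
        n = x.shape[0]
        history: list[float] = []
        for _epoch in range(config.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            epoch_weight = 0.0
            for start in range(0, n, config.batch_size):
                idx = perm[start : start + config.batch_size]
                xb, yb = x[idx], y[idx]
                cache: list = []
                logits = self._forward(xb, cache)
                probs = self._softmax(logits)
                wb = weights[yb]
                eps = 1e-12
                losses = -np.log(probs[np.arange(len(yb)), yb] + eps)
                batch_w = wb.sum()
                epoch_loss += float((wb * losses).sum())
                epoch_weight += float(batch_w)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits *= (wb / max(batch_w, eps))[:, None]
                grads: dict = {}
                self._backward(cache, dlogits, grads)
                self._sgd_step(grads, velocity, config)
            history.append(epoch_loss / max(epoch_weight, 1e-12))
        return TrainResult(
            model=self, loss_history=history, seed=config.seed, config=config.to_dict()
        )

    def _sgd_step(self, grads: dict, velocity: dict, config: PipelineConfig) -> None:
        lr, mom = config.learning_rate, config.momentum
        velocity["dense_w"] = mom * velocity["dense_w"] - lr * grads["dense_w"]
        velocity["dense_b"] = mom * velocity["dense_b"] - lr * grads["dense_b"]
        self.dense_w += velocity["dense_w"]
        self.dense_b += velocity["dense_b"]
        for bi, p in enumerate(self.params):
            vdw, vpw, vb = velocity["blocks"][bi]
            ddw, dpw, dbias = grads["blocks"][bi]
            vdw = mom * vdw - lr * ddw
            vpw = mom * vpw - lr * dpw
            vb = mom * vb - lr * dbias
            velocity["blocks"][bi] = (vdw, vpw, vb)
            p.depthwise += vdw
            p.pointwise += vpw
            p.bias += vb

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class logits for a batch of (N, B, ws, ws) patches."""
        return self._forward(np.asarray(x, dtype=np.float64))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._softmax(self.forward(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {
            "dense_w": self.dense_w,
            "dense_b": self.dense_b,
            "input_mean": self.input_mean,
            "input_sd": self.input_sd,
        }
        for i, p in enumerate(self.params):
            arrays[f"dw{i}"] = p.depthwise
            arrays[f"pw{i}"] = p.pointwise
            arrays[f"bias{i}"] = p.bias
        meta = {"spec": self.spec.to_dict(), "seed": self.seed}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SCNNClassifier":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            model = cls(ClassifierSpec.from_dict(meta["spec"]), seed=meta["seed"])
            model.dense_w = npz["dense_w"]
            model.dense_b = npz["dense_b"]
            model.input_mean = npz["input_mean"]
            model.input_sd = npz["input_sd"]
            for i in range(len(model.params)):
                model.params[i] = SepConvParams(
                    npz[f"dw{i}"], npz[f"pw{i}"], npz[f"bias{i}"]
                )
        return model


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> SCNNClassifier:
    """Deterministically initialize a classifier from an architecture spec."""
    return SCNNClassifier(spec, seed=seed)


def samples_to_arrays(samples: list[PixelSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack PixelSamples into (N, B, ws, ws) patches and (N,) labels."""
    if not samples:
        raise ValueError("empty sample list")
    x = np.stack([s.patch.data.transpose(2, 0, 1) for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return x, y


def train_classifier(
    model: SCNNClassifier, samples: list[PixelSample], config: PipelineConfig
) -> TrainResult:
    """Train on a list of (possibly SSN-augmented) pixel samples."""
    x, y = samples_to_arrays(samples)
    return model.fit(x, y, config)


def predict_map(
    model: SCNNClassifier, cube: HSCube, ws: int, chunk: int = 2048
) -> tuple[LabelMask, np.ndarray]:
    """Classify every pixel of a cube; returns (mask, H x W x n_classes scores).

    Edge pixels are handled by replicate-padding the cube so each pixel has a
    full ws x ws patch; scores are softmax probabilities (each pixel's scores
    sum to 1) so threshold-free metrics like AUC can be computed downstream.
    """
    if cube.band_count != model.spec.input_bands:
        raise ValueError(
            f"cube has {cube.band_count} bands; model expects {model.spec.input_bands}"
        )
    if ws != model.spec.input_ws:
        raise ValueError(f"model expects ws={model.spec.input_ws}; got {ws}")
    h, w, b = cube.shape
    half = ws // 2
    padded = np.pad(cube.data, ((half, half), (half, half), (0, 0)), mode="edge")
    windows = sliding_window_view(padded, (ws, ws), axis=(0, 1))  # (H, W, B, ws, ws)
    patches = windows.reshape(h * w, b, ws, ws)
    scores = np.empty((h * w, model.spec.n_classes))
    for start in range(0, h * w, chunk):
        scores[start : start + chunk] = model.predict_proba(
            patches[start : start + chunk]
        )
    labels = scores.argmax(axis=1).reshape(h, w)
    return LabelMask(labels.astype(np.int64)), scores.reshape(h, w, model.spec.n_classes)
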