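"""Delta-DL: a compact AlexNet-style CNN over delta-images, exposing a
10-neuron fully-connected feature layer per view, plus Grad-CAM.

The network is implemented directly in NumPy (batched im2col convolutions
with explicit backpropagation), which keeps it small (a few conv blocks,
well under 200k parameters at the defaults), deterministic under a fixed
seed, and lets Grad-CAM reuse the same backward pass.  One network is
shared across the three body-axis views; the view identity enters as a
constant second input channel (x → 0, y → 0.5, z → 1).

Feature extraction reads the activations of the penultimate
fully-connected layer (width 10 by default), giving 30 delta-DL features
per subject at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .imagereg import AXES, DeltaImageSet

__all__ = [
    "NetworkSpec",
    "FeatureCNN",
    "DeepFeatureVector",
    "build_feature_cnn",
    "train",
    "extract_deep_features",
    "gradcam",
]

VIEW_TAGS = {"x": 0.0, "y": 0.5, "z": 1.0}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the delta-DL feature network.

    input_size : square input side in pixels.
    conv_channels : output channels of the successive 3×3 conv blocks,
        each followed by ReLU and 2×2 max-pooling.
    feature_layer_width : neurons in the fully-connected feature layer
        (the number of delta-DL features per view).
    n_classes : classification-head width.
    view_tag_channel : add a constant per-view channel so one shared
        network can serve the three views.
    """

    input_size: int = 64
    conv_channels: tuple[int, ...] = (8, 16, 32)
    feature_layer_width: int = 10
    n_classes: int = 2
    view_tag_channel: bool = True

    def __post_init__(self):
        size = self.input_size
        for _ in self.conv_channels:
            if size % 2 != 0:
                raise ValueError("input size must halve cleanly at every pool")
            size //= 2
        if size < 1:
            raise ValueError("too many conv blocks for this input size")


@dataclass
class DeepFeatureVector:
    """Concatenated per-view feature-layer activations (x, y, z order)."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite deep features")

    def __len__(self):
        return len(self.values)


# ---------------------------------------------------------------------------
# layers

class _Conv:
    """3×3 same-padding convolution."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)

    @property
    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x):
        self.x = x
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # B,C,H,W,3,3
        self.cols = cols
        return np.einsum("bchwij,ocij->bohw", cols, self.W, optimize=True) + self.b[None, :, None, None]

    def backward(self, g):
        self.gW = np.einsum("bchwij,bohw->ocij", self.cols, g, optimize=True)
        self.gb = g.sum(axis=(0, 2, 3))
        gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gcols = sliding_window_view(gp, (3, 3), axis=(2, 3))
        Wflip = self.W[:, :, ::-1, ::-1]
        return np.einsum("bohwij,ocij->bchw", gcols, Wflip, optimize=True)

    def step(self, lr, mom, vel):
        for name in ("W", "b"):
            v = vel.setdefault(id(self) * 2 + (name == "b"), 0.0)
            v = mom * v - lr * getattr(self, "g" + name)
            vel[id(self) * 2 + (name == "b")] = v
            setattr(self, name, getattr(self, name) + v)


class _ReLU:
    n_params = 0

    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask

    def step(self, lr, mom, vel):
        pass


class _Pool2:
    n_params = 0

    def forward(self, x):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self.mask = xr == out[:, :, :, None, :, None]
        self.shape = x.shape
        return out

    def backward(self, g):
        gr = g[:, :, :, None, :, None] * self.mask
        return gr.reshape(self.shape)

    def step(self, lr, mom, vel):
        pass


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW = self.x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def step(self, lr, mom, vel):
        for name in ("W", "b"):
            key = id(self) * 2 + (name == "b")
            v = vel.setdefault(key, 0.0)
            v = mom * v - lr * getattr(self, "g" + name)
            vel[key] = v
            setattr(self, name, getattr(self, name) + v)


class FeatureCNN:
    """Conv blocks → linear FC feature layer → 2-way classification head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c_in = 2 if spec.view_tag_channel else 1
        self.convs = []
        size = spec.input_size
        for c_out in spec.conv_channels:
            self.convs += [_Conv(c_in, c_out, rng), _ReLU(), _Pool2()]
            c_in = c_out
            size //= 2
        self.flat_dim = c_in * size * size
        self.fc_feat = _Dense(self.flat_dim, spec.feature_layer_width, rng)
        self.fc_out = _Dense(spec.feature_layer_width, spec.n_classes, rng)
        self._vel: dict = {}

    @property
    def n_params(self) -> int:
        layers = self.convs + [self.fc_feat, self.fc_out]
        return int(sum(l.n_params for l in layers))

    # ---- forward / backward -------------------------------------------
    def _prep(self, images, view_tag=None):
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != self.spec.input_size or x.shape[-2] != self.spec.input_size:
            raise ValueError(
                f"input size {x.shape[-2:]}, expected {self.spec.input_size}"
            )
        if self.spec.view_tag_channel and x.shape[1] == 1:
            if view_tag is None:
                tag = 0.0
            elif isinstance(view_tag, str):
                tag = VIEW_TAGS[view_tag]
            else:
                tag = float(view_tag)
            x = np.concatenate([x, np.full_like(x, tag)], axis=1)
        return x

    def forward(self, images, view_tag=None):
        """Logits (B, n_classes); caches activations for backward."""
        h = self._prep(images, view_tag)
        for layer in self.convs:
            h = layer.forward(h)
        self.conv_out = h  # final conv-block activations, for Grad-CAM
        self.batch = h.shape[0]
        h = h.reshape(self.batch, -1)
        # the feature layer is linear: its activations are the delta-DL
        # features, and gradients always reach the conv stack for Grad-CAM
        self.feats = self.fc_feat.forward(h)
        return self.fc_out.forward(self.feats)

    def backward(self, g_logits, to_conv_only=False):
        g = self.fc_out.backward(g_logits)
        g = self.fc_feat.backward(g)
        g = g.reshape(self.conv_out.shape)
        if to_conv_only:
            return g
        for layer in reversed(self.convs):
            g = layer.backward(g)
        return g

    def step(self, lr, momentum=0.9):
        for layer in self.convs + [self.fc_feat, self.fc_out]:
            layer.step(lr, momentum, self._vel)

    def predict_proba(self, images, view_tag=None):
        logits = self.forward(images, view_tag)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def features(self, images, view_tag=None):
        self.forward(images, view_tag)
        return self.feats.copy()


def build_feature_cnn(spec: NetworkSpec | None = None, seed: int = 0) -> FeatureCNN:
    """Construct the delta-DL network (feature layer width 10 by default)."""
    return FeatureCNN(spec or NetworkSpec(), seed=seed)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingCurves:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def train(
    network: FeatureCNN,
    delta_images: np.ndarray,
    labels: np.ndarray,
    view_tags=None,
    epochs: int = 20,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 32,
    seed: int = 0,
    class_weighted: bool = True,
) -> TrainingCurves:
    """Momentum-SGD training with softmax cross-entropy.

    ``delta_images``: (N, H, W) normalized delta-images; ``view_tags``: per
    sample view letter or tag value (defaults to the x tag).  Returns the
    per-epoch loss/accuracy curves.  Deterministic for a fixed seed.
    """
    x = np.asarray(delta_images, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    tags = np.zeros(len(y)) if view_tags is None else np.array(
        [VIEW_TAGS[t] if isinstance(t, str) else float(t) for t in view_tags]
    )
    weights = np.ones(network.spec.n_classes)
    if class_weighted:
        counts = np.bincount(y, minlength=network.spec.n_classes).astype(float)
        weights = np.where(counts > 0, len(y) / (len(classes) * np.maximum(counts, 1)), 0.0)
    rng = np.random.default_rng(seed)
    curves = TrainingCurves()
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        total_loss, correct = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = x[idx][:, None]
            if network.spec.view_tag_channel:
                xb = np.concatenate([xb, tags[idx][:, None, None, None]
                                     * np.ones_like(xb)], axis=1)
            logits = network.forward(xb)
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            p = e / e.sum(axis=1, keepdims=True)
            w = weights[y[idx]]
            total_loss += float(-(w * np.log(p[np.arange(len(idx)), y[idx]] + 1e-12)).sum())
            correct += int((p.argmax(axis=1) == y[idx]).sum())
            g = p.copy()
            g[np.arange(len(idx)), y[idx]] -= 1.0
            g *= (w / w.sum())[:, None]
            network.backward(g)
            network.step(lr, momentum)
        curves.loss.append(total_loss / n)
        curves.accuracy.append(correct / n)
    return curves


def extract_deep_features(network: FeatureCNN, views: DeltaImageSet | dict) -> DeepFeatureVector:
    """Concatenated feature-layer activations for the three views (length
    3 × feature_layer_width, i.e. 30 at defaults)."""
    imgs = views.images if isinstance(views, DeltaImageSet) else views
    feats = []
    for axis in AXES:
        f = network.features(imgs[axis][None], view_tag=axis)
        feats.append(f[0])
    sid = views.subject_id if isinstance(views, DeltaImageSet) else ""
    return DeepFeatureVector(np.concatenate(feats), subject_id=sid)


def gradcam(network: FeatureCNN, image: np.ndarray, target_class: int = 1,
            view_tag=None) -> np.ndarray:
    """Gradient-weighted class activation map over the final conv block.

    The class score is the discriminative logit margin (target logit minus
    the mean of the others, which for a 2-way head is the logit
    difference); channel weights are the spatial means of its gradient at
    the final conv block.  The ReLU'd weighted channel sum is upsampled to
    the input size and min–max normalized to [0, 1].  A constant map
    normalizes to zeros.
    """
    logits = network.forward(np.asarray(image, dtype=float)[None], view_tag=view_tag)
    n_cls = logits.shape[1]
    g = np.full_like(logits, -1.0 / max(n_cls - 1, 1))
    g[0, target_class] = 1.0
    g_conv = network.backward(g, to_conv_only=True)  # (1, C, h, w)
    acts = network.conv_out[0]
    w = g_conv[0].mean(axis=(1, 2))
    cam = np.maximum((w[:, None, None] * acts).sum(axis=0), 0.0)
    size = network.spec.input_size
    cam = resize(cam, (size, size), order=1, preserve_range=True, anti_aliasing=False)
    lo, hi = cam.min(), cam.max()
    if hi - lo <= 0:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)
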