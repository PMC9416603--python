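"""Single- and dual-stream convolutional feature extractors.

The recognition model is a small 2-D CNN per modality: the window (channels
x 600 samples) is treated as a one-plane image, passed through two valid
(no padding, stride 1) convolutions with ReLU and two non-overlapping max
poolings, and flattened:

    EMG branch  4x600 -> conv 1x101 (depth 16) -> pool 1x10
                      -> conv 3x11  (depth 8)  -> pool 2x2  -> 160
    IMU branch  3x600 -> conv 1x101 (depth 16) -> pool 1x10
                      -> conv 2x11  (depth 8)  -> pool 2x2  -> 160

The dual-stream model concatenates the two 160-vectors at a convergence
layer (320), maps them through a fully connected layer to 32, and applies a
softmax output over the four motion modes.  A single-stream model applies
one branch (or a 7x600 channel-stacked fused branch, flattening to 320)
followed by the same FC/softmax head.

After training, dropping the output layer turns the network into a feature
extractor: the default tap is the 32-unit FC output (``fc32``); the 320-unit
convergence-layer features (``fusion320``) are also exposed.

Everything is implemented directly on NumPy (im2col convolutions backed by
BLAS matmuls, explicit backprop, Adam), which keeps training on CPU fast and
bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import NotFittedError

N_EMG, N_IMU, WIN = 4, 3, 600
EMG_FLAT = N_EMG * WIN  # 2400; column layout of the 4200-vector window pair


# ---------------------------------------------------------------------------
# Architecture arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchSpec:
    """One convolutional branch, in the printed configuration by default."""

    in_channels: int = 4
    in_length: int = WIN
    conv1_kernel: tuple[int, int] = (1, 101)
    conv1_depth: int = 16
    pool1: tuple[int, int] = (1, 10)
    conv2_kernel: tuple[int, int] = (3, 11)
    conv2_depth: int = 8
    pool2: tuple[int, int] = (2, 2)
    padding: int = 0
    stride: int = 1


EMG_BRANCH = BranchSpec(in_channels=4, conv2_kernel=(3, 11))
IMU_BRANCH = BranchSpec(in_channels=3, conv2_kernel=(2, 11))
FUSED_BRANCH = BranchSpec(in_channels=7, conv2_kernel=(3, 11))


def output_shape(spec: BranchSpec) -> tuple[int, int, int, int]:
    """(height, width, depth, flattened) after conv1/pool1/conv2/pool2.

    Convolutions use the spec's padding and stride (default: valid, stride
    1); pooling is non-overlapping with floor division.  Raises if a kernel
    no longer fits its input at any stage.
    """
    h, w = spec.in_channels, spec.in_length

    def conv(h, w, kh, kw):
        h2 = (h + 2 * spec.padding - kh) // spec.stride + 1
        w2 = (w + 2 * spec.padding - kw) // spec.stride + 1
        if h2 < 1 or w2 < 1:
            raise ValueError(f"kernel ({kh}x{kw}) larger than input ({h}x{w})")
        return h2, w2

    def pool(h, w, ph, pw):
        h2, w2 = h // ph, w // pw
        if h2 < 1 or w2 < 1:
            raise ValueError(f"pool ({ph}x{pw}) larger than input ({h}x{w})")
        return h2, w2

    h, w = conv(h, w, *spec.conv1_kernel)
    h, w = pool(h, w, *spec.pool1)
    h, w = conv(h, w, *spec.conv2_kernel)
    h, w = pool(h, w, *spec.pool2)
    return h, w, spec.conv2_depth, h * w * spec.conv2_depth


# ---------------------------------------------------------------------------
# NumPy layers
# ---------------------------------------------------------------------------

def _conv_valid(x: np.ndarray, W: np.ndarray):
    """Valid stride-1 cross-correlation. x (B,Cin,H,W), W (Cout,Cin,kh,kw)."""
    kh, kw = W.shape[2], W.shape[3]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    B, Cin, Hp, Wp = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Hp * Wp, Cin * kh * kw)
    cols = np.ascontiguousarray(cols)
    out = cols @ W.reshape(W.shape[0], -1).T
    return out.reshape(B, Hp, Wp, W.shape[0]).transpose(0, 3, 1, 2), cols


class _Conv2D:
    def __init__(self, cin, cout, kh, kw, rng, first=False):
        fan_in = cin * kh * kw
        lim = np.sqrt(6.0 / fan_in)
        self.W = rng.uniform(-lim, lim, (cout, cin, kh, kw)).astype(np.float32)
        self.b = np.zeros(cout, np.float32)
        self.first = first  # first layer never needs an input gradient

    def forward(self, x, train):
        out, cols = _conv_valid(x, self.W)
        out += self.b[None, :, None, None]
        if train:
            self._cols = cols
        return out

    def backward(self, d):
        B, Cout, Hp, Wp = d.shape
        dflat = np.ascontiguousarray(d.transpose(0, 2, 3, 1)).reshape(-1, Cout)
        self.dW = (dflat.T @ self._cols).reshape(self.W.shape)
        self.db = dflat.sum(0)
        self._cols = None
        if self.first:
            return None
        kh, kw = self.W.shape[2], self.W.shape[3]
        dpad = np.pad(d, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        Wf = np.ascontiguousarray(self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx, _ = _conv_valid(dpad, Wf)
        return dx

    params = ("W", "b")


class _MaxPool:
    params = ()

    def __init__(self, ph, pw):
        self.ph, self.pw = ph, pw

    def _fold(self, x):
        B, C, H, W = x.shape
        Hp, Wp = H // self.ph, W // self.pw
        xt = x[:, :, : Hp * self.ph, : Wp * self.pw]
        return (xt.reshape(B, C, Hp, self.ph, Wp, self.pw)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, Hp, Wp, self.ph * self.pw))

    def forward(self, x, train):
        xr = self._fold(x)
        idx = xr.argmax(-1)
        out = np.take_along_axis(xr, idx[..., None], -1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return out

    def backward(self, d):
        B, C, H, W = self._xshape
        Hp, Wp = H // self.ph, W // self.pw
        dr = np.zeros((B, C, Hp, Wp, self.ph * self.pw), d.dtype)
        np.put_along_axis(dr, self._idx[..., None], d[..., None], -1)
        dx = np.zeros(self._xshape, d.dtype)
        dx[:, :, : Hp * self.ph, : Wp * self.pw] = (
            dr.reshape(B, C, Hp, Wp, self.ph, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Hp * self.ph, Wp * self.pw)
        )
        return dx


class _ReLU:
    params = ()

    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, d):
        return d * self._mask


class _Flatten:
    params = ()

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class _Dense:
    params = ("W", "b")

    def __init__(self, n_in, n_out, rng):
        lim = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-lim, lim, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, np.float32)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.dW = self._x.T @ d
        self.db = d.sum(0)
        self._x = None
        return d @ self.W.T


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, d):
        for lyr in reversed(self.layers):
            d = lyr.backward(d)
        return d


def _branch_layers(spec: BranchSpec, rng) -> list:
    if spec.padding or spec.stride != 1:
        raise ValueError("the network implements valid stride-1 convolutions")
    return [
        _Conv2D(1, spec.conv1_depth, *spec.conv1_kernel, rng, first=True),
        _ReLU(),
        _MaxPool(*spec.pool1),
        _Conv2D(spec.conv1_depth, spec.conv2_depth, *spec.conv2_kernel, rng),
        _ReLU(),
        _MaxPool(*spec.pool2),
        _Flatten(),
    ]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = [(lyr, p) for lyr in layers for p in lyr.params]
        self.m = [np.zeros_like(getattr(l, p)) for l, p in self.entries]
        self.v = [np.zeros_like(getattr(l, p)) for l, p in self.entries]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        corr1 = 1 - self.b1**self.t
        corr2 = 1 - self.b2**self.t
        for i, (lyr, p) in enumerate(self.entries):
            g = getattr(lyr, "d" + p).astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            upd = (self.lr * (self.m[i] / corr1)
                   / (np.sqrt(self.v[i] / corr2) + self.eps))
            setattr(lyr, p, getattr(lyr, p) - upd)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training regime: 64-window batches, learning rate 0.001, Adam,
    cross-entropy loss.  `epochs` counts full passes over the training set."""

    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 200
    seed: int = 0

    def as_kwargs(self) -> dict:
        return dict(batch_size=self.batch_size, lr=self.learning_rate,
                    epochs=self.epochs, random_state=self.seed)


class _BaseCNN(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Shared fit/predict/transform machinery for both architectures.

    X rows are flattened window pairs: 4200 columns laid out as the EMG
    block (4x600 row-major) followed by the IMU block (3x600), the layout
    produced by :meth:`gaitfuse.preprocess.WindowSet.as_matrix`.
    """

    def __init__(self, epochs=30, batch_size=64, lr=0.001, random_state=0,
                 tap="fc32", fc_relu=True):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state
        self.tap = tap
        self.fc_relu = fc_relu

    # -- input plumbing ----------------------------------------------------

    def _validate_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != EMG_FLAT + N_IMU * WIN:
            raise ValueError(
                f"X must be (n, {EMG_FLAT + N_IMU * WIN}) flattened window "
                "pairs (EMG 4x600 block then IMU 3x600 block)")
        return X

    def _blocks(self, X):
        emg = X[:, :EMG_FLAT].reshape(-1, 1, N_EMG, WIN)
        imu = X[:, EMG_FLAT:].reshape(-1, 1, N_IMU, WIN)
        return emg, imu

    def _standardize(self, X, fit=False):
        emg, imu = self._blocks(X)
        stacked = np.concatenate([emg[:, 0], imu[:, 0]], axis=1)  # (n,7,600)
        if fit:
            self.channel_mean_ = stacked.mean(axis=(0, 2))
            self.channel_std_ = stacked.std(axis=(0, 2)) + 1e-8
        stacked = ((stacked - self.channel_mean_[None, :, None])
                   / self.channel_std_[None, :, None])
        return (stacked[:, :N_EMG][:, None].reshape(-1, 1, N_EMG, WIN),
                stacked[:, N_EMG:][:, None].reshape(-1, 1, N_IMU, WIN))

    # -- subclass hooks ----------------------------------------------------

    def _build(self, rng):
        raise NotImplementedError

    def _forward(self, emg, imu, train=False, tap=None):
        raise NotImplementedError

    def _backward(self, d):
        raise NotImplementedError

    def _all_layers(self):
        raise NotImplementedError

    # -- training ----------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train with minibatch Adam on cross-entropy loss.

        validation_data, if given, is an (X_val, y_val) pair whose accuracy
        is logged per epoch in ``history_``.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != len(X) or len(X) == 0:
            raise ValueError("X and y must be non-empty and aligned")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least two classes")
        yi = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        emg, imu = self._standardize(X, fit=True)
        opt = _Adam(self._all_layers(), self.lr)

        n = len(X)
        bs = min(self.batch_size, n)
        self.history_ = {"loss": [], "accuracy": [], "val_accuracy": []}
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            tot_loss, tot_hit = 0.0, 0
            for s in range(0, n, bs):
                b = perm[s:s + bs]
                logits = self._forward(emg[b], imu[b], train=True)
                p = _softmax(logits)
                tot_loss += -np.sum(np.log(p[np.arange(len(b)), yi[b]] + 1e-12))
                tot_hit += int(np.sum(p.argmax(1) == yi[b]))
                d = p.copy()
                d[np.arange(len(b)), yi[b]] -= 1.0
                self._backward((d / len(b)).astype(np.float32))
                opt.step()
            self.history_["loss"].append(tot_loss / n)
            self.history_["accuracy"].append(tot_hit / n)
            if validation_data is not None:
                Xv, yv = validation_data
                self.history_["val_accuracy"].append(
                    float(np.mean(self.predict(Xv) == np.asarray(yv))))
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise NotFittedError("estimator has not been fitted")

    def _batched(self, X, tap, batch=256):
        self._check_fitted()
        X = self._validate_X(X)
        emg, imu = self._standardize(X)
        outs = [self._forward(emg[s:s + batch], imu[s:s + batch], tap=tap)
                for s in range(0, len(X), batch)]
        return np.concatenate(outs)

    def predict_proba(self, X):
        return _softmax(self._batched(X, tap=None))

    def predict(self, X):
        return self.classes_[self._batched(X, tap=None).argmax(1)]

    def transform(self, X, tap=None):
        """Extract features at the configured tap (output layer removed).

        ``fc32`` gives the 32-unit FC representation, ``fusion320`` the
        concatenated flattened convolutional features (320 for the
        dual-stream and fused single-stream models, 160 for a single
        branch).  Row order follows X.
        """
        tap = tap or self.tap
        if tap not in ("fc32", "fusion320"):
            raise ValueError("tap must be 'fc32' or 'fusion320'")
        return self._batched(X, tap=tap)


class DualStreamCNN(_BaseCNN):
    """Dual-stream recognition model and feature extractor.

    Two modality-specific convolutional branches are fused by concatenation
    (320), passed through a 32-unit FC layer and a 4-way softmax output.
    ``transform`` drops the output layer and returns the tap features.
    """

    def _build(self, rng):
        self.emg_layers_ = _branch_layers(EMG_BRANCH, rng)
        self.imu_layers_ = _branch_layers(IMU_BRANCH, rng)
        fused = output_shape(EMG_BRANCH)[3] + output_shape(IMU_BRANCH)[3]
        head = [_Dense(fused, 32, rng)]
        if self.fc_relu:
            head.append(_ReLU())
        self.head_layers_ = head
        self.out_layer_ = _Dense(32, len(self.classes_), rng)
        self._emg_seq = _Sequential(self.emg_layers_)
        self._imu_seq = _Sequential(self.imu_layers_)
        self._head_seq = _Sequential(self.head_layers_)

    def _all_layers(self):
        return (self.emg_layers_ + self.imu_layers_ + self.head_layers_
                + [self.out_layer_])

    def _forward(self, emg, imu, train=False, tap=None):
        fe = self._emg_seq.forward(emg, train)
        fi = self._imu_seq.forward(imu, train)
        fused = np.concatenate([fe, fi], axis=1)
        if tap == "fusion320":
            return fused
        self._fe_width = fe.shape[1]
        h = self._head_seq.forward(fused, train)
        if tap == "fc32":
            return h
        return self.out_layer_.forward(h, train)

    def _backward(self, d):
        d = self.out_layer_.backward(d)
        d = self._head_seq.backward(d)
        self._emg_seq.backward(d[:, : self._fe_width])
        self._imu_seq.backward(d[:, self._fe_width:])


class SingleStreamCNN(_BaseCNN):
    """Single-stream model over one modality or the channel-stacked fusion.

    ``modality`` selects the EMG branch (4x600), the IMU branch (3x600) or
    the fused 7x600 input (EMG rows stacked on IMU rows, second conv kernel
    3x11, flattening to 320).
    """

    def __init__(self, modality="emg", epochs=30, batch_size=64, lr=0.001,
                 random_state=0, tap="fc32", fc_relu=True):
        super().__init__(epochs=epochs, batch_size=batch_size, lr=lr,
                         random_state=random_state, tap=tap, fc_relu=fc_relu)
        self.modality = modality

    def _spec(self):
        try:
            return {"emg": EMG_BRANCH, "imu": IMU_BRANCH,
                    "fused": FUSED_BRANCH}[self.modality]
        except KeyError:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected emg/imu/fused"
            ) from None

    def _build(self, rng):
        spec = self._spec()
        self.branch_layers_ = _branch_layers(spec, rng)
        head = [_Dense(output_shape(spec)[3], 32, rng)]
        if self.fc_relu:
            head.append(_ReLU())
        self.head_layers_ = head
        self.out_layer_ = _Dense(32, len(self.classes_), rng)
        self._branch_seq = _Sequential(self.branch_layers_)
        self._head_seq = _Sequential(self.head_layers_)

    def _all_layers(self):
        return self.branch_layers_ + self.head_layers_ + [self.out_layer_]

    def _input(self, emg, imu):
        if self.modality == "emg":
            return emg
        if self.modality == "imu":
            return imu
        return np.concatenate([emg, imu], axis=2)  # (B,1,7,600)

    def _forward(self, emg, imu, train=False, tap=None):
        f = self._branch_seq.forward(self._input(emg, imu), train)
        if tap == "fusion320":
            return f
        h = self._head_seq.forward(f, train)
        if tap == "fc32":
            return h
        return self.out_layer_.forward(h, train)

    def _backward(self, d):
        d = self.out_layer_.backward(d)
        d = self._head_seq.backward(d)
        self._branch_seq.backward(d)


# ---------------------------------------------------------------------------
# Thin functional wrappers and checkpointing
# ---------------------------------------------------------------------------

def build_dual_stream(seed: int = 0, **kw) -> DualStreamCNN:
    return DualStreamCNN(random_state=seed, **kw)


def build_single_stream(modality: str = "emg", seed: int = 0,
                        **kw) -> SingleStreamCNN:
    return SingleStreamCNN(modality=modality, random_state=seed, **kw)


def train(model: _BaseCNN, ws, cfg: TrainConfig | None = None) -> _BaseCNN:
    """Fit a model on a WindowSet's train split, logging validation accuracy
    on its val split.  Returns the fitted model (the trained extractor)."""
    if cfg is not None:
        model.set_params(**cfg.as_kwargs())
    tr = ws.split_subset("train")
    va = ws.split_subset("val")
    if len(tr) == 0:
        raise ValueError("window set has no train split")
    val = (va.as_matrix(), va.labels) if len(va) else None
    return model.fit(tr.as_matrix(), tr.labels, validation_data=val)


def extract(model: _BaseCNN, ws, tap: str | None = None):
    """Extract tap features for every window pair of a WindowSet, as a
    :class:`gaitfuse.features.FeatureMatrix` in WindowSet order."""
    from .features import FeatureMatrix

    vals = model.transform(ws.as_matrix(), tap=tap)
    tapname = tap or model.tap
    names = [f"cnn:{tapname}:{i}" for i in range(vals.shape[1])]
    return FeatureMatrix(vals.astype(float), names, ws.labels)


def save_model(model: _BaseCNN, path) -> None:
    """Checkpoint a fitted model (architecture config + weights) to .npz."""
    model._check_fitted()
    arrays = {"channel_mean_": model.channel_mean_,
              "channel_std_": model.channel_std_,
              "classes_": model.classes_}
    for i, lyr in enumerate(model._all_layers()):
        for p in lyr.params:
            arrays[f"layer{i}_{p}"] = getattr(lyr, p)
    cfg = dict(model.get_params())
    cfg["__class__"] = type(model).__name__
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> _BaseCNN:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]))
        cls = {"DualStreamCNN": DualStreamCNN,
               "SingleStreamCNN": SingleStreamCNN}[cfg.pop("__class__")]
        model = cls(**cfg)
        model.classes_ = z["classes_"]
        model.channel_mean_ = z["channel_mean_"]
        model.channel_std_ = z["channel_std_"]
        model.n_features_in_ = EMG_FLAT + N_IMU * WIN
        model._build(np.random.default_rng(0))
        for i, lyr in enumerate(model._all_layers()):
            for p in lyr.params:
                setattr(lyr, p, z[f"layer{i}_{p}"])
    return model
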