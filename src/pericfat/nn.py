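"""Minimal 3D U-Net with hand-derived backpropagation on numpy.

Layers keep a single-use cache from the last forward pass; the training
loop is strictly sequential (forward, loss, backward, Adam step), so no
general autodiff graph is needed.  Convolutions are stride-1 "same"
convolutions evaluated as im2col windows contracted with the kernel via
BLAS (float32 throughout).  Downsampling is 2x2x2 max-pooling, upsampling
nearest-neighbour.  The bottleneck contains a 1x1x1 feature-reduction
convolution that halves the channel count before the decoder.

The architecture and training recipe (Dice loss, Adam, stepwise learning
rate decay every 100 epochs, per-sample augmentation, 70/30 train/tune
splits) follow the cascade configuration in :mod:`pericfat.locnet` and
:mod:`pericfat.segnet`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


# ---------------------------------------------------------------------------
# Layers


class Conv3d:
    """Stride-1 'same' 3D convolution, optionally followed by ReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, rng, relu: bool = True):
        fan_in = c_in * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.relu = relu
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = self._xp = self._pre = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    #: below this many spatial voxels an explicit im2col + GEMM beats the
    #: direct loop kernel (short rows defeat its vectorization)
    _GEMM_VOXELS = 10000

    def _pad(self, x):
        p = self.k // 2
        if p:
            return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        return np.ascontiguousarray(x)

    @staticmethod
    def _col_sample(xp_i, k):
        """im2col of one padded sample, laid out (Ci*k^3, D*H*W).

        The copy runs W-contiguously in the source, and the layout lets
        forward/backward GEMMs write channel-first outputs directly.
        """
        win = sliding_window_view(xp_i, (k, k, k), axis=(1, 2, 3))
        c = xp_i.shape[0]
        return np.ascontiguousarray(win.transpose(0, 4, 5, 6, 1, 2, 3)).reshape(
            c * k**3, -1
        )

    def forward(self, x, train: bool):
        from ._kernels import conv3d_forward

        xp = self._pad(x)
        n, _, d, h, w = x.shape
        co = self.w.shape[0]
        small = d * h * w <= self._GEMM_VOXELS
        out = np.empty((n, co, d, h, w), dtype=np.float32)
        if small:
            wm = self.w.reshape(co, -1)
            cols = []
            for i in range(n):
                col = self._col_sample(xp[i], self.k)
                out[i] = (wm @ col).reshape(co, d, h, w)
                if train:
                    cols.append(col)
            self._cols = cols if train else None
        else:
            conv3d_forward(xp, self.w, out)
            self._cols = None
        out += self.b.reshape(1, -1, 1, 1, 1)
        if self.relu:
            self._pre = out
            out = np.maximum(out, 0.0)
        if train:
            self._xp = xp
        return out

    def backward(self, g):
        from ._kernels import conv3d_forward

        if self.relu:
            g = np.where(self._pre > 0, g, 0.0).astype(np.float32)
        g = np.ascontiguousarray(g, dtype=np.float32)
        n, co, d, h, w = g.shape
        ci = self.w.shape[1]
        small = d * h * w <= self._GEMM_VOXELS
        if small and self._cols is not None:
            gw = np.zeros((co, ci * self.k**3), dtype=np.float32)
            for i in range(n):
                gw += g[i].reshape(co, -1) @ self._cols[i].T
            self.gw = gw.reshape(self.w.shape)
        else:
            from ._kernels import conv3d_wgrad

            self.gw = np.zeros_like(self.w)
            conv3d_wgrad(self._xp, g, self.gw)
        self.gb = g.sum(axis=(0, 2, 3, 4))
        # input gradient = 'same' conv of g with the flipped, transposed kernel
        wt = np.ascontiguousarray(
            self.w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )
        p = self.k // 2
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else g
        gx = np.empty((n, ci, d, h, w), dtype=np.float32)
        if small:
            wtm = wt.reshape(ci, -1)
            for i in range(n):
                gcol = self._col_sample(gp[i], self.k)
                gx[i] = (wtm @ gcol).reshape(ci, d, h, w)
        else:
            conv3d_forward(gp, wt, gx)
        self._xp = self._pre = self._cols = None
        return gx


class MaxPool2:
    """Non-overlapping 2x2x2 max pooling (even spatial dims required)."""

    params: list = []

    def forward(self, x, train: bool):
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.ascontiguousarray(xr.max(axis=-1))

    def backward(self, g):
        n, c, d, h, w = self._shape
        out = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(out, self._arg[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        out = out.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        self._arg = None
        return np.ascontiguousarray(out)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2x2 block."""

    params: list = []

    def forward(self, x, train: bool):
        return np.ascontiguousarray(
            x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        )

    def backward(self, g):
        n, c, d, h, w = g.shape
        gr = g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        return np.ascontiguousarray(gr.sum(axis=(3, 5, 7)))


class Dropout:
    def __init__(self, rate: float, rng):
        self.rate = rate
        self.rng = rng
        self._mask = None

    params: list = []

    def forward(self, x, train: bool):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        g = g * self._mask
        self._mask = None
        return g


# ---------------------------------------------------------------------------
# U-Net


class UNet3d:
    """Encoder-decoder with skip connections and a feature-reduced bottleneck.

    ``levels`` is the number of 2x down-sampling steps; spatial dims of the
    input must be divisible by 2**levels.
    """

    def __init__(
        self,
        levels: int = 4,
        base_filters: int = 8,
        dropout: float = 0.5,
        bottleneck_feature_reduction: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.enc: list[list[Conv3d]] = []
        c_in = 1
        for i in range(levels):
            f = base_filters * 2**i
            self.enc.append([Conv3d(c_in, f, 3, rng), Conv3d(f, f, 3, rng)])
            c_in = f
        fb = base_filters * 2**levels
        self.bott = [Conv3d(c_in, fb, 3, rng)]
        if bottleneck_feature_reduction:
            self.bott.append(Conv3d(fb, fb // 2, 1, rng))
            fb = fb // 2
        self.drop = Dropout(dropout, rng)
        self.pools = [MaxPool2() for _ in range(levels)]
        self.ups = [Upsample2() for _ in range(levels)]
        # decoder: upsample -> 1x1 channel-halving "up-convolution" -> concat
        # with the skip -> two 3x3x3 convs (keeps concat widths at 2f)
        self.upconvs: list[Conv3d] = []
        self.dec: list[list[Conv3d]] = []
        c_in = fb
        for i in reversed(range(levels)):
            f = base_filters * 2**i
            self.upconvs.append(Conv3d(c_in, f, 1, rng))
            self.dec.append([Conv3d(2 * f, f, 3, rng), Conv3d(f, f, 3, rng)])
            c_in = f
        self.head = Conv3d(c_in, 1, 1, rng, relu=False)
        # start from sparse foreground predictions: soft-Dice training from
        # a ~0.5 everywhere start is prone to collapsing into the
        # empty-prediction attractor (see train_unet)
        self.head.b[:] = -2.0

    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.bott
        for up, blk in zip(self.upconvs, self.dec):
            yield up
            yield from blk
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def forward(self, x, train: bool = False):
        """Return sigmoid foreground probabilities, shape (N,1,D,H,W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            for conv in blk:
                x = conv.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for conv in self.bott:
            x = conv.forward(x, train)
        x = self.drop.forward(x, train)
        self._skip_channels = []
        for blk, up, upconv, skip in zip(self.dec, self.ups, self.upconvs, reversed(skips)):
            x = up.forward(x, train)
            x = upconv.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for conv in blk:
                x = conv.forward(x, train)
        z = self.head.forward(x, train)
        self._p = 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))
        return self._p

    def backward(self, dloss_dp):
        g = (dloss_dp * self._p * (1.0 - self._p)).astype(np.float32)
        g = self.head.backward(g)
        skip_grads = []
        for blk, up, upconv, c_skip in zip(
            reversed(self.dec),
            reversed(self.ups),
            reversed(self.upconvs),
            reversed(self._skip_channels),
        ):
            for conv in reversed(blk):
                g = conv.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(upconv.backward(np.ascontiguousarray(g[:, c_skip:])))
        g = self.drop.backward(g)
        for conv in reversed(self.bott):
            g = conv.backward(g)
        # skip_grads was collected top-level first, i.e. ordered like self.enc
        for blk, pool, gs in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + gs
            for conv in reversed(blk):
                g = conv.backward(g)
        return g

    # -- weights I/O ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            out[f"w{i}"] = layer.w
            out[f"b{i}"] = layer.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            layer.w = np.asarray(state[f"w{i}"], dtype=np.float32)
            layer.b = np.asarray(state[f"b{i}"], dtype=np.float32)


# ---------------------------------------------------------------------------
# Loss, optimizer, augmentation, training loop


def dice_loss_grad(p, t, eps: float = 1.0):
    """Soft Dice loss (mean over batch) and its gradient wrt p."""
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    psum = p.sum(axis=axes)
    tsum = t.sum(axis=axes)
    denom = psum + tsum + eps
    dice = (2.0 * inter + eps) / denom
    loss = float(np.mean(1.0 - dice))
    n = p.shape[0]
    grad = -(2.0 * t * denom.reshape((-1,) + (1,) * (p.ndim - 1)) - (2.0 * inter + eps).reshape(
        (-1,) + (1,) * (p.ndim - 1)
    )) / (denom**2).reshape((-1,) + (1,) * (p.ndim - 1))
    return loss, (grad / n).astype(np.float32)


def soft_dice(p, t, eps: float = 1.0) -> float:
    axes = tuple(range(1, p.ndim))
    d = (2.0 * (p * t).sum(axis=axes) + eps) / (p.sum(axis=axes) + t.sum(axis=axes) + eps)
    return float(np.mean(d))


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def refresh(self, params):
        """Re-bind parameter/grad views after layers rewrote their .gw/.gb."""
        self.params = params


def augment_pair(img, mask, rng, translate_voxels: int, rotate_deg: float):
    """Random axial in-plane translation and small rotation about a random axis.

    ``img`` and ``mask`` are (D,H,W) arrays (image already normalized so the
    air background maps to 0).  Masks use nearest-neighbour interpolation.
    """
    out_i, out_m = img, mask
    if translate_voxels > 0:
        tx, ty = rng.integers(-translate_voxels, translate_voxels + 1, 2)
        out_i = ndimage.shift(out_i, (tx, ty, 0), order=0, mode="constant", cval=0.0)
        out_m = ndimage.shift(out_m, (tx, ty, 0), order=0, mode="constant", cval=0.0)
    if rotate_deg > 0:
        ang = rng.uniform(-rotate_deg, rotate_deg)
        axes = tuple(rng.choice(3, size=2, replace=False))
        out_i = ndimage.rotate(
            out_i, ang, axes=axes, reshape=False, order=1, mode="constant", cval=0.0
        )
        out_m = ndimage.rotate(
            out_m, ang, axes=axes, reshape=False, order=0, mode="constant", cval=0.0
        )
    return out_i.astype(np.float32), out_m.astype(np.float32)


@dataclass
class TrainLog:
    epochs: list
    lr: list
    train_loss: list
    tune_dice: list  # (epoch, dice) pairs
    split_history: list  # (epoch, train_ids, tune_ids)


def train_unet(
    model: UNet3d,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    *,
    epochs: int,
    batch_size: int,
    lr0: float,
    lr_decay_factor: float,
    lr_decay_every: int = 100,
    resplit_every: int | None = None,
    tune_frac: float = 0.3,
    translate_voxels: int = 0,
    rotate_deg: float = 0.0,
    seed: int = 0,
    eval_every: int = 10,
    max_grad_norm: float = 1.0,
) -> TrainLog:
    """Dice-loss training with Adam and stepwise learning-rate decay.

    Gradients are clipped to a global L2 norm of ``max_grad_norm`` before
    each step; soft-Dice training is otherwise prone to a collapse where
    one oversized update drives every logit negative (the empty-prediction
    attractor) and sigmoid saturation kills the gradient signal.

    A single 70/30 train/tune split is drawn up front; if ``resplit_every``
    is set the split is redrawn from the full pool every that many epochs
    (a rotation-style use of all data).  The split RNG stream is separate
    from the augmentation/dropout stream so split schedules are
    reproducible regardless of augmentation settings.
    """
    n = len(images)
    split_rng = np.random.default_rng((seed, 151))
    aug_rng = np.random.default_rng((seed, 7))
    order_rng = np.random.default_rng((seed, 11))

    def draw_split():
        perm = split_rng.permutation(n)
        n_tune = max(1, int(round(tune_frac * n))) if n > 1 else 0
        return sorted(perm[n_tune:]), sorted(perm[:n_tune])

    train_ids, tune_ids = draw_split()
    opt = Adam(model.parameters(), lr=lr0)
    log = TrainLog([], [], [], [], [(0, list(train_ids), list(tune_ids))])

    imgs = [np.asarray(x, dtype=np.float32) for x in images]
    msks = [np.asarray(y, dtype=np.float32) for y in masks]

    for epoch in range(epochs):
        if resplit_every and epoch > 0 and epoch % resplit_every == 0:
            train_ids, tune_ids = draw_split()
            log.split_history.append((epoch, list(train_ids), list(tune_ids)))
        lr = lr0 * lr_decay_factor ** (epoch // lr_decay_every)
        opt.lr = lr
        order = order_rng.permutation(train_ids)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, len(order), batch_size):
            ids = order[start : start + batch_size]
            xb, yb = [], []
            for i in ids:
                xi, yi = augment_pair(imgs[i], msks[i], aug_rng, translate_voxels, rotate_deg)
                xb.append(xi[None])
                yb.append(yi[None])
            x = np.stack(xb)
            y = np.stack(yb)
            p = model.forward(x, train=True)
            loss, grad = dice_loss_grad(p, y)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            model.backward(grad)
            params = model.parameters()
            if max_grad_norm is not None:
                gnorm = np.sqrt(sum(float(np.vdot(g_, g_)) for _, g_ in params))
                if gnorm > max_grad_norm:
                    scale = max_grad_norm / gnorm
                    for _, g_ in params:
                        g_ *= scale
            opt.refresh(params)
            opt.step()
            epoch_loss += loss
            nb += 1
        log.epochs.append(epoch)
        log.lr.append(lr)
        log.train_loss.append(epoch_loss / max(nb, 1))
        if tune_ids and (epoch % eval_every == 0 or epoch == epochs - 1):
            d = evaluate_dice(model, [imgs[i] for i in tune_ids], [msks[i] for i in tune_ids])
            log.tune_dice.append((epoch, d))
    return log


def evaluate_dice(model: UNet3d, images, masks) -> float:
    vals = []
    for x, y in zip(images, masks):
        p = model.forward(np.asarray(x, dtype=np.float32)[None, None])
        vals.append(soft_dice((p[0, 0] > 0.5).astype(np.float32), np.asarray(y, np.float32)))
    return float(np.mean(vals))


def lr_at_epoch(lr0: float, decay_factor: float, epoch: int, every: int = 100) -> float:
    """Stepwise schedule: lr0 * factor**(epoch // every)."""
    return lr0 * decay_factor ** (epoch // every)
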