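"""Neural-network building blocks (layers, LSTM, Adam) on the autodiff engine.

Shapes follow the usual conventions: dense layers act on ``(batch, features)``,
recurrent layers on python lists of per-timestep ``(batch, features)`` tensors.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, embedding_lookup, no_grad


class Module:
    """Base class: parameter registry and train/eval mode switching."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name, array):
        p = Tensor(array, requires_grad=True)
        self._params[name] = p
        return p

    def parameters(self):
        out = list(self._params.values())
        for c in self._children.values():
            out.extend(c.parameters())
        return out

    def named_parameters(self, prefix=""):
        out = []
        for k, p in self._params.items():
            out.append((prefix + k, p))
        for name, c in self._children.items():
            out.extend(c.named_parameters(prefix + name + "."))
        return out

    def train(self, mode=True):
        self.training = mode
        for c in self._children.values():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat serialization (weights + batchnorm running stats) ---------------
    def state_dict(self):
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, mod in self._iter_modules():
            if isinstance(mod, BatchNorm):
                state[name + "._running_mean"] = mod.running_mean.copy()
                state[name + "._running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k], dtype=np.float64)
        for name, mod in self._iter_modules():
            if isinstance(mod, BatchNorm):
                mod.running_mean = np.asarray(state[name + "._running_mean"])
                mod.running_var = np.asarray(state[name + "._running_var"])

    def _iter_modules(self, prefix=""):
        yield prefix[:-1] if prefix else "", self
        for name, c in self._children.items():
            yield from c._iter_modules(prefix + name + ".")


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class Dense(Module):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.W = self.add_param("W", _glorot(rng, n_in, n_out))
        self.b = self.add_param("b", np.zeros(n_out))

    def __call__(self, x):
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_tokens, dim, rng):
        super().__init__()
        self.W = self.add_param("W", rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, indices):
        return embedding_lookup(self.W, indices)


class BatchNorm(Module):
    """Batch normalization over the feature axis of (batch, features) inputs."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(n_features))
        self.beta = self.add_param("beta", np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                (self.running_var + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class GaussianNoise(Module):
    """Additive zero-mean Gaussian noise, active in training mode only."""

    def __init__(self, std, rng):
        super().__init__()
        self.std = std
        self.rng = rng

    def __call__(self, x):
        if not self.training or self.std == 0.0:
            return x
        return x + Tensor(self.rng.normal(0.0, self.std, size=x.shape))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_sequence(seq, Wx, Wh, b, h0, c0, reverse=False, mask=None):
    """Full LSTM sweep over a (T, B, E) sequence as one fused primitive.

    Returns a packed (T+1, B, H) tensor: rows 0..T-1 are the per-step hidden
    states (in input order, also for reverse sweeps), row T is the final cell
    state.  An optional (T, B) 0/1 `mask` freezes the state on padded steps,
    making the sweep exact for variable-length sequences regardless of how a
    batch is padded.  Forward and backward-through-time are hand-written
    numpy; the produced gradients are detached (first-order only), which is
    all the sequence models require, and removes per-timestep graph overhead.
    """
    T, B, E = seq.shape
    H = Wh.data.shape[0]
    xp = (seq.data.reshape(T * B, E) @ Wx.data + b.data).reshape(T, B, 4 * H)
    if mask is not None:
        mask = np.asarray(mask, dtype=np.float64).reshape(T, B, 1)
    hs = np.empty((T, B, H))
    ii, ff, gg, oo, tcs, cprev = (np.empty((T, B, H)) for _ in range(6))
    h, c = h0.data, c0.data
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        z = xp[t] + h @ Wh.data
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        cprev[t] = c
        c_cand = f * c + i * g
        tc = np.tanh(c_cand)
        h_cand = o * tc
        ii[t], ff[t], gg[t], oo[t], tcs[t] = i, f, g, o, tc
        if mask is None:
            h, c = h_cand, c_cand
        else:
            m = mask[t]
            h = m * h_cand + (1.0 - m) * h
            c = m * c_cand + (1.0 - m) * c
        hs[t] = h
    out = np.concatenate([hs, c[None]], axis=0)

    cache = {}

    def shared(gt):
        key = id(gt)
        if key not in cache:
            gd = gt.data
            gouts, gcT = gd[:T], gd[T]
            dz = np.empty((T, B, 4 * H))
            gh_next = np.zeros((B, H))
            gc_next = gcT.copy()
            for t in list(order)[::-1]:  # reverse of processing order
                gh = gouts[t] + gh_next
                gc = gc_next
                if mask is not None:
                    m = mask[t]
                    gh_carry = (1.0 - m) * gh
                    gc_carry = (1.0 - m) * gc
                    gh = m * gh
                    gc = m * gc
                i, f, g, o, tc = ii[t], ff[t], gg[t], oo[t], tcs[t]
                gct = gc + gh * o * (1.0 - tc * tc)
                dz[t, :, :H] = gct * g * i * (1.0 - i)
                dz[t, :, H : 2 * H] = gct * cprev[t] * f * (1.0 - f)
                dz[t, :, 2 * H : 3 * H] = gct * i * (1.0 - g * g)
                dz[t, :, 3 * H :] = gh * tc * o * (1.0 - o)
                gh_next = dz[t] @ Wh.data.T
                gc_next = gct * f
                if mask is not None:
                    gh_next = gh_next + gh_carry
                    gc_next = gc_next + gc_carry
            cache[key] = (dz, gh_next, gc_next)
        return cache[key]

    def grad_Wh(gt):
        dz = shared(gt)[0]
        # h_prev at step t is hs of the previously processed step
        acc = np.zeros_like(Wh.data)
        steps = list(order)
        for k, t in enumerate(steps):
            hp = h0.data if k == 0 else hs[steps[k - 1]]
            acc += hp.T @ dz[t]
        return Tensor(acc)

    vjps = (
        lambda gt: Tensor(
            (shared(gt)[0].reshape(T * B, 4 * H) @ Wx.data.T).reshape(T, B, E)
        ),
        lambda gt: Tensor(
            seq.data.reshape(T * B, E).T @ shared(gt)[0].reshape(T * B, 4 * H)
        ),
        grad_Wh,
        lambda gt: Tensor(shared(gt)[0].sum(axis=(0, 1))),
        lambda gt: Tensor(shared(gt)[1]),
        lambda gt: Tensor(shared(gt)[2]),
    )
    return Tensor._make(out, (seq, Wx, Wh, b, h0, c0), vjps)


def lstm_cell_fused(x, Wx, Wh, b, h, c):
    """One LSTM step as a single fused primitive returning [h_new | c_new].

    Like `lstm_step_fused` but also folds in the input projection; used by
    single-step autoregressive decoding.
    """
    H = Wh.data.shape[0]
    xd, hd, cd = x.data, h.data, c.data
    z = xd @ Wx.data + hd @ Wh.data + b.data
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H : 2 * H])
    g = np.tanh(z[:, 2 * H : 3 * H])
    o = _sigmoid(z[:, 3 * H :])
    c_new = f * cd + i * g
    tc = np.tanh(c_new)
    out = np.concatenate([o * tc, c_new], axis=1)

    cache = {}

    def shared(gt):
        key = id(gt)
        if key not in cache:
            gd = gt.data
            gh, gc = gd[:, :H], gd[:, H:]
            gct = gc + gh * o * (1.0 - tc * tc)
            dz = np.concatenate(
                [
                    gct * g * i * (1.0 - i),
                    gct * cd * f * (1.0 - f),
                    gct * i * (1.0 - g * g),
                    gh * tc * o * (1.0 - o),
                ],
                axis=1,
            )
            cache[key] = (dz, gct)
        return cache[key]

    vjps = (
        lambda gt: Tensor(shared(gt)[0] @ Wx.data.T),
        lambda gt: Tensor(xd.T @ shared(gt)[0]),
        lambda gt: Tensor(hd.T @ shared(gt)[0]),
        lambda gt: Tensor(shared(gt)[0].sum(axis=0)),
        lambda gt: Tensor(shared(gt)[0] @ Wh.data.T),
        lambda gt: Tensor(shared(gt)[1] * f),
    )
    return Tensor._make(out, (x, Wx, Wh, b, h, c), vjps)


class LSTMCell(Module):
    def __init__(self, n_in, n_units, rng):
        super().__init__()
        self.n_units = n_units
        self.Wx = self.add_param("Wx", _glorot(rng, n_in, 4 * n_units))
        self.Wh = self.add_param("Wh", _glorot(rng, n_units, 4 * n_units))
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self.b = self.add_param("b", b)

    def __call__(self, x, h, c):
        H = self.n_units
        hc = lstm_cell_fused(x, self.Wx, self.Wh, self.b, h, c)
        return hc[:, :H], hc[:, H:]

    def zero_state(self, batch):
        z = Tensor(np.zeros((batch, self.n_units)))
        return z, z


class LSTMLayer(Module):
    """Unidirectional LSTM over a stacked (T, B, n_in) sequence tensor."""

    def __init__(self, n_in, n_units, rng):
        super().__init__()
        self.n_in, self.n_units = n_in, n_units
        self.cell = LSTMCell(n_in, n_units, rng)

    def __call__(self, seq, init_state=None, reverse=False, mask=None):
        T, B = seq.shape[0], seq.shape[1]
        cell = self.cell
        h0, c0 = init_state if init_state is not None else cell.zero_state(B)
        packed = lstm_sequence(seq, cell.Wx, cell.Wh, cell.b, h0, c0,
                               reverse=reverse, mask=mask)
        outs = packed[:T]
        h_final = packed[0 if reverse else T - 1]
        c_final = packed[T]
        return outs, (h_final, c_final)


class BiLSTMLayer(Module):
    """Bidirectional LSTM; per-step outputs are [fwd, bwd] concatenations."""

    def __init__(self, n_in, n_units, rng):
        super().__init__()
        self.fwd = LSTMLayer(n_in, n_units, rng)
        self.bwd = LSTMLayer(n_in, n_units, rng)

    def __call__(self, seq, mask=None):
        outs_f, (hf, cf) = self.fwd(seq, mask=mask)
        outs_b, (hb, cb) = self.bwd(seq, reverse=True, mask=mask)
        outs = concat([outs_f, outs_b], axis=2)
        return outs, (hf, cf, hb, cb)


def softmax(x):
    m = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - m).exp()
    return e * e.sum(axis=-1, keepdims=True) ** -1.0


def cross_entropy_logits(logits, targets, mask=None):
    """Mean categorical cross-entropy from raw logits.

    logits: (batch, n_classes); targets: int array (batch,);
    mask: optional 0/1 array (batch,) excluding padded positions from the mean.
    """
    m = Tensor(logits.data.max(axis=-1, keepdims=True))
    shifted = logits - m
    logz = shifted.exp().sum(axis=-1, keepdims=True).log()
    picked = shifted[np.arange(len(targets)), targets]
    nll = (logz.reshape(-1) - picked)
    if mask is None:
        return nll.mean()
    w = Tensor(mask)
    return (nll * w).sum() * (1.0 / max(float(mask.sum()), 1.0))


class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
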