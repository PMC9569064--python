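"""Minimal reverse-mode autodiff on numpy arrays, plus the layers and the
optimizer used by the sequence models in this package.

Only the operations the models need are implemented.  All state lives in
plain ``numpy`` arrays; training is single-threaded and fully determined by
the seeds handed to the parameter initializers and the data shuffler.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "logsumexp",
    "Linear",
    "LSTMCell",
    "BiLSTM",
    "Adagrad",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._acc(g)
            other._acc(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._acc(g * other.data)
            other._acc(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            g = np.asarray(g)
            if a.ndim == 1 and b.ndim == 1:
                self._acc(g * b)
                other._acc(g * a)
            elif b.ndim == 1:
                self._acc(g[..., None] * b)
                other._acc(
                    (a.reshape(-1, a.shape[-1]) * g.reshape(-1, 1)).sum(axis=0)
                )
            elif a.ndim == 1:
                self._acc(b @ g)
                other._acc(np.outer(a, g))
            else:
                self._acc(g @ np.swapaxes(b, -1, -2))
                other._acc(np.swapaxes(a, -1, -2) @ g)

        return self._make(out_data, (self, other), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._acc(full)

        return self._make(out_data, (self,), backward)

    # -- nonlinearities and reductions ----------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._acc(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._acc(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._acc(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._acc(g * out_data)

        return self._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._acc(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._acc(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- backprop driver -------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        perm: set[int] = set()
        temp: list[tuple[Tensor, bool]] = [(self, False)]
        while temp:
            node, processed = temp.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in perm:
                continue
            perm.add(id(node))
            temp.append((node, True))
            for p in node._parents:
                if id(p) not in perm:
                    temp.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._acc(g[tuple(idx)])

    return tensors[0]._make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._acc(np.take(g, i, axis=axis))

    return tensors[0]._make(out_data, tuple(tensors), backward)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp reduction with softmax backward."""
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    exps = np.exp(x.data - m)
    sums = exps.sum(axis=axis, keepdims=True)
    out_data = np.log(sums) + m
    soft = exps / sums
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._acc(g * soft)

    return x._make(out_data, (x,), backward)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear:
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class LSTMCell:
    """Standard LSTM cell; gate order in the packed weights is i, f, g, o.

    The forget-gate bias is initialised to 1, the usual remedy for
    vanishing memory early in training.
    """

    def __init__(self, rng, d_in: int, d_hidden: int):
        self.h = d_hidden
        self.Wx = Tensor(glorot(rng, d_in, 4 * d_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, d_hidden, 4 * d_hidden), requires_grad=True)
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def step(self, x: Tensor, h: Tensor, c: Tensor):
        z = x @ self.Wx + h @ self.Wh + self.b
        H = self.h
        i = z[:, 0:H].sigmoid()
        f = z[:, H : 2 * H].sigmoid()
        g = z[:, 2 * H : 3 * H].tanh()
        o = z[:, 3 * H : 4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def parameters(self):
        return [self.Wx, self.Wh, self.b]


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_chain(x: Tensor, mask: np.ndarray, cell: LSTMCell,
               h0: Tensor, c0: Tensor, reverse: bool = False):
    """Run an LSTM over a padded batch as one fused autodiff op.

    Masked steps hold the previous state, so the held state after the
    loop is the state at each sequence's last real position (first real
    position for ``reverse``).  Backward is hand-written BPTT, which keeps
    the graph small and training fast.

    Returns (outputs (B, L, H), h_final, c_final).
    """
    B, L, D = x.shape
    H = cell.h
    Wx, Wh, b = cell.Wx, cell.Wh, cell.b
    order = range(L - 1, -1, -1) if reverse else range(L)

    xp = x.data
    h, c = h0.data, c0.data
    hs = np.empty((B, L, H))
    cache = {}
    h_prev = np.empty((B, L, H))
    c_prev = np.empty((B, L, H))
    gates = np.empty((B, L, 4 * H))
    tanh_c = np.empty((B, L, H))
    for t in order:
        m = mask[:, t : t + 1]
        h_prev[:, t], c_prev[:, t] = h, c
        z = xp[:, t] @ Wx.data + h @ Wh.data + b.data
        i = _sigmoid_np(z[:, :H])
        f = _sigmoid_np(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid_np(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        gates[:, t] = np.concatenate([i, f, g, o], axis=1)
        tanh_c[:, t] = tc
        hs[:, t] = h
    cache.update(h_prev=h_prev, c_prev=c_prev, gates=gates, tanh_c=tanh_c)
    h_final, c_final = h, c

    # pack (hs, h_final, c_final) into one node; callers slice it apart
    packed = np.concatenate([hs, h_final[:, None, :], c_final[:, None, :]], axis=1)
    parents = (x, Wx, Wh, b, h0, c0)

    def backward(grad):
        g_hs = grad[:, :L]
        dh_next = grad[:, L].copy()
        dc_next = grad[:, L + 1].copy()
        dx = np.zeros_like(xp)
        dWx = np.zeros_like(Wx.data)
        dWh = np.zeros_like(Wh.data)
        db = np.zeros_like(b.data)
        for t in reversed(list(order)):
            m = mask[:, t : t + 1]
            dh = g_hs[:, t] + dh_next
            dc = dc_next
            # un-blend the mask hold
            dh_new = m * dh
            dh_prev = (1.0 - m) * dh
            dc_new = m * dc
            dc_prev = (1.0 - m) * dc
            i = cache["gates"][:, t, :H]
            f = cache["gates"][:, t, H : 2 * H]
            gg = cache["gates"][:, t, 2 * H : 3 * H]
            o = cache["gates"][:, t, 3 * H :]
            tc = cache["tanh_c"][:, t]
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc**2)
            df = dc_new * cache["c_prev"][:, t]
            dc_prev = dc_prev + dc_new * f
            di = dc_new * gg
            dg = dc_new * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - gg**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dx[:, t] = dz @ Wx.data.T
            dWx += xp[:, t].T @ dz
            dWh += cache["h_prev"][:, t].T @ dz
            db += dz.sum(axis=0)
            dh_next = dh_prev + dz @ Wh.data.T
            dc_next = dc_prev
        x._acc(dx)
        Wx._acc(dWx)
        Wh._acc(dWh)
        b._acc(db)
        h0._acc(dh_next)
        c0._acc(dc_next)

    out = x._make(packed, parents, backward)
    return out[:, :L], out[:, L], out[:, L + 1]


class BiLSTM:
    """Bidirectional LSTM over a padded batch.

    ``__call__`` takes ``x`` of shape (B, L, D) and a float mask (B, L)
    with 1 at real positions.  Returns outputs (B, L, 2h) plus the final
    (h, c) states for each direction.
    """

    def __init__(self, rng, d_in: int, d_hidden: int):
        self.h = d_hidden
        self.fwd = LSTMCell(rng, d_in, d_hidden)
        self.bwd = LSTMCell(rng, d_in, d_hidden)

    def __call__(self, x: Tensor, mask: np.ndarray, init_state=None):
        B, _, _ = x.shape
        if init_state is None:
            zeros = Tensor(np.zeros((B, self.h)))
            hf0, cf0, hb0, cb0 = zeros, zeros, zeros, zeros
        else:
            hf0, cf0, hb0, cb0 = init_state
        fwd_hs, hf, cf = lstm_chain(x, mask, self.fwd, hf0, cf0, reverse=False)
        bwd_hs, hb, cb = lstm_chain(x, mask, self.bwd, hb0, cb0, reverse=True)
        outs = concat([fwd_hs, bwd_hs], axis=2)
        return outs, (hf, cf, hb, cb)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class Adagrad:
    """Adagrad with a stepped exponential learning-rate decay.

    The effective rate at update ``k`` is ``lr * decay_rate**(k // decay_steps)``.
    """

    def __init__(self, params, lr: float, decay_rate: float = 1.0,
                 decay_steps: int = 1, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.decay_rate = decay_rate
        self.decay_steps = max(1, int(decay_steps))
        self.eps = eps
        self.step_count = 0
        self._accum = [np.zeros_like(p.data) for p in self.params]

    @property
    def current_lr(self) -> float:
        return self.lr * self.decay_rate ** (self.step_count // self.decay_steps)

    def step(self):
        lr = self.current_lr
        for p, acc in zip(self.params, self._accum):
            if p.grad is None:
                continue
            acc += p.grad**2
            p.data -= lr * p.grad / (np.sqrt(acc) + self.eps)
        self.step_count += 1

    def zero_grad(self):
        for p in self.params:
            p.grad = None
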