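"""Neural layers: LSTM / BiLSTM, dropout, linear-chain CRF, AdaDelta.

Parameters are plain :class:`~kbrelex.autodiff.Tensor` objects collected in a
name -> tensor dictionary; initialization is Glorot-uniform from an explicit
``numpy.random.Generator`` so every run is reproducible from its seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

Array = np.ndarray


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Array:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def parameter(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    return Tensor(glorot(rng, shape), requires_grad=True)


def zeros_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def dropout(
    x: Tensor,
    p: float,
    rng: Optional[np.random.Generator],
    train: bool,
) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def lstm_parameters(
    rng: np.random.Generator, input_dim: int, hidden: int, prefix: str
) -> dict[str, Tensor]:
    """Weights for one direction; forget-gate bias initialized to 1."""
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0
    return {
        f"{prefix}.Wx": Tensor(glorot(rng, (input_dim, 4 * hidden)), requires_grad=True),
        f"{prefix}.Wh": Tensor(glorot(rng, (hidden, 4 * hidden)), requires_grad=True),
        f"{prefix}.b": Tensor(b, requires_grad=True),
    }


def lstm_run(
    params: dict[str, Tensor],
    prefix: str,
    xs: Sequence[Tensor],
    reverse: bool = False,
) -> list[Tensor]:
    """Run an LSTM over a list of (B, D) inputs; returns (B, H) states per step.

    Gate order in the fused weight matrix: input, forget, cell, output.
    """
    Wx, Wh, b = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"], params[f"{prefix}.b"]
    hidden = Wh.shape[0]
    batch = xs[0].shape[0]
    h = Tensor(np.zeros((batch, hidden)))
    c = Tensor(np.zeros((batch, hidden)))
    order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    out: list[Optional[Tensor]] = [None] * len(xs)
    for t in order:
        gates = xs[t] @ Wx + h @ Wh + b
        i = ad.sigmoid(gates[:, :hidden])
        f = ad.sigmoid(gates[:, hidden : 2 * hidden])
        g = ad.tanh(gates[:, 2 * hidden : 3 * hidden])
        o = ad.sigmoid(gates[:, 3 * hidden :])
        c = f * c + i * g
        h = o * ad.tanh(c)
        out[t] = h
    return out  # type: ignore[return-value]


def bilstm_parameters(
    rng: np.random.Generator, input_dim: int, hidden: int, prefix: str = "bilstm"
) -> dict[str, Tensor]:
    params = {}
    params.update(lstm_parameters(rng, input_dim, hidden, f"{prefix}.fwd"))
    params.update(lstm_parameters(rng, input_dim, hidden, f"{prefix}.bwd"))
    return params


def bilstm_run(
    params: dict[str, Tensor], xs: Sequence[Tensor], prefix: str = "bilstm"
) -> list[Tensor]:
    """Forward and backward passes concatenated per step: (B, 2*hidden)."""
    fwd = lstm_run(params, f"{prefix}.fwd", xs)
    bwd = lstm_run(params, f"{prefix}.bwd", xs, reverse=True)
    return [ad.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]


# ---------------------------------------------------------------------------
# Linear-chain CRF
# ---------------------------------------------------------------------------

def crf_parameters(num_tags: int) -> dict[str, Tensor]:
    return {
        "crf.trans": zeros_parameter((num_tags, num_tags)),
        "crf.start": zeros_parameter((num_tags,)),
        "crf.stop": zeros_parameter((num_tags,)),
    }


def crf_nll(
    params: dict[str, Tensor], emissions: Tensor, tags: Array
) -> Tensor:
    """Mean negative log-likelihood of gold tag paths.

    emissions: (B, T, K) tensor; tags: (B, T) integer array.  The path score
    is the sum of emissions along the path plus start/transition/stop scores;
    the partition function comes from the forward algorithm in log space.
    """
    trans, start, stop = (
        params["crf.trans"],
        params["crf.start"],
        params["crf.stop"],
    )
    tags = np.asarray(tags)
    batch, T, K = emissions.shape
    rows = np.arange(batch)

    gold = ad.gather(start, (tags[:, 0],))
    gold = gold + ad.gather(
        emissions,
        (rows[:, None], np.arange(T)[None, :], tags),
    ).sum(axis=1)
    if T > 1:
        gold = gold + ad.gather(trans, (tags[:, :-1], tags[:, 1:])).sum(axis=1)
    gold = gold + ad.gather(stop, (tags[:, -1],))

    alpha = start.reshape(1, K) + emissions[:, 0]
    for t in range(1, T):
        alpha = (
            ad.logsumexp(
                alpha.reshape(batch, K, 1) + trans.reshape(1, K, K), axis=1
            )
            + emissions[:, t]
        )
    logz = ad.logsumexp(alpha + stop.reshape(1, K), axis=1)
    return (logz - gold).mean()


def viterbi_decode(
    emissions: Array,
    trans: Array,
    start: Array,
    stop: Array,
) -> list[int]:
    """Exact argmax tag path for one sequence of (T, K) emission scores."""
    emissions = np.asarray(emissions, dtype=float)
    T, K = emissions.shape
    score = start + emissions[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        total = score[:, None] + trans  # (prev, next)
        back[t] = np.argmax(total, axis=0)
        score = total[back[t], np.arange(K)] + emissions[t]
    score = score + stop
    best = int(np.argmax(score))
    path = [best]
    for t in range(T - 1, 0, -1):
        best = int(back[t][best])
        path.append(best)
    return path[::-1]


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class AdaDelta:
    """AdaDelta with a learning-rate multiplier and per-minibatch L2.

    Keeps the usual running averages of squared gradients and squared
    updates (decay ``rho``, stabilizer ``eps``); the L2 term is added to the
    gradient of every parameter at each step.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1.0,
        rho: float = 0.95,
        eps: float = 1e-6,
        l2: float = 1e-5,
    ) -> None:
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.l2 = l2
        self._eg = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._ex = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.l2 * p.data
            eg = self._eg[name] = (
                self.rho * self._eg[name] + (1.0 - self.rho) * g * g
            )
            dx = -np.sqrt(self._ex[name] + self.eps) / np.sqrt(eg + self.eps) * g
            self._ex[name] = self.rho * self._ex[name] + (1.0 - self.rho) * dx * dx
            p.data = p.data + self.lr * dx

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
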