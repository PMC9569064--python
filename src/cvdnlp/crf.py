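"""Linear-chain CRF primitives.

A tag path ``y`` over ``n`` positions is scored as the sum of per-position
emission scores and adjacent-tag transition scores, augmented with
dedicated START and STOP states::

    s(X, y) = T[START, y_1] + sum_t P[t, y_t]
            + sum_t T[y_t, y_{t+1}] + T[y_n, STOP]

The transition matrix has shape (K+2, K+2) where the last two indices are
START and STOP.  Entries into START and out of STOP are structural and
never read by these routines.

These functions operate on single unbatched instances and are used for
decoding and as the reference route in tests; the batched training loss
with its analytic gradient lives alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "start_index",
    "stop_index",
    "structural_transitions",
    "path_score",
    "log_partition",
    "path_log_probability",
    "viterbi",
    "TagPath",
    "crf_nll_batch",
]


def start_index(num_tags: int) -> int:
    return num_tags


def stop_index(num_tags: int) -> int:
    return num_tags + 1


def structural_transitions(transitions: np.ndarray) -> np.ndarray:
    """Return a copy with -inf placed on the impossible structural moves
    (anything into START, anything out of STOP)."""
    K = transitions.shape[0] - 2
    out = transitions.astype(np.float64).copy()
    out[:, start_index(K)] = -np.inf
    out[stop_index(K), :] = -np.inf
    return out


def _check(emissions: np.ndarray, transitions: np.ndarray) -> int:
    emissions = np.asarray(emissions)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a non-empty (n, K) matrix")
    K = emissions.shape[1]
    if transitions.shape != (K + 2, K + 2):
        raise ValueError(
            f"transitions must have shape ({K + 2}, {K + 2}), got {transitions.shape}"
        )
    return K


def path_score(emissions: np.ndarray, transitions: np.ndarray, path) -> float:
    """Score of one tag path under the START/STOP augmentation."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    K = _check(emissions, transitions)
    path = np.asarray(path, dtype=np.intp)
    n = emissions.shape[0]
    if path.shape != (n,):
        raise ValueError(f"path length {path.shape} does not match sequence length {n}")
    score = transitions[start_index(K), path[0]]
    score += emissions[np.arange(n), path].sum()
    if n > 1:
        score += transitions[path[:-1], path[1:]].sum()
    score += transitions[path[-1], stop_index(K)]
    return float(score)


def log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all tag paths of exp(path score), by the forward
    recursion in log space."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    K = _check(emissions, transitions)
    n = emissions.shape[0]
    inner = transitions[:K, :K]
    alpha = transitions[start_index(K), :K] + emissions[0]
    for t in range(1, n):
        alpha = _lse(alpha[:, None] + inner, axis=0) + emissions[t]
    return float(_lse(alpha + transitions[:K, stop_index(K)], axis=0))


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    safe = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.exp(x - safe).sum(axis=axis)) + np.squeeze(safe, axis=axis)
    return np.where(np.isfinite(np.squeeze(m, axis=axis)), out, -np.inf)


def path_log_probability(emissions, transitions, path) -> float:
    """log p(y | X) = s(X, y) - log Z(X); always <= 0."""
    return path_score(emissions, transitions, path) - log_partition(
        emissions, transitions
    )


@dataclass(frozen=True)
class TagPath:
    tags: tuple
    score: float
    log_probability: float


def viterbi(emissions: np.ndarray, transitions: np.ndarray) -> TagPath:
    """Best-scoring tag path; ties resolved toward lower tag indices."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    K = _check(emissions, transitions)
    n = emissions.shape[0]
    inner = transitions[:K, :K]
    delta = transitions[start_index(K), :K] + emissions[0]
    pointers = np.empty((n, K), dtype=np.intp)
    for t in range(1, n):
        scores = delta[:, None] + inner  # (prev, cur)
        best_prev = np.argmax(scores, axis=0)  # argmax picks lowest index on ties
        pointers[t] = best_prev
        delta = scores[best_prev, np.arange(K)] + emissions[t]
    final = delta + transitions[:K, stop_index(K)]
    last = int(np.argmax(final))
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(pointers[t, path[-1]]))
    path.reverse()
    score = float(final[last])
    return TagPath(
        tags=tuple(path),
        score=score,
        log_probability=score - log_partition(emissions, transitions),
    )


# ---------------------------------------------------------------------------
# Batched training loss with analytic gradient (forward-backward marginals).
# ---------------------------------------------------------------------------


def crf_nll_batch(
    emissions: np.ndarray,
    transitions: np.ndarray,
    tags: np.ndarray,
    mask: np.ndarray,
):
    """Mean negative log-likelihood of gold tag paths over a padded batch.

    Parameters
    ----------
    emissions : (B, L, K) scores; padded positions are ignored via ``mask``.
    transitions : (K+2, K+2) with START=K, STOP=K+1.
    tags : (B, L) gold tag indices (arbitrary at padded positions).
    mask : (B, L) 1.0 at real positions; every row must start with 1.

    Returns
    -------
    (loss, d_emissions, d_transitions) — the scalar mean NLL and its
    gradients with respect to the emissions and the transition matrix.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    tags = np.asarray(tags, dtype=np.intp)
    mask = np.asarray(mask, dtype=np.float64)
    B, L, K = emissions.shape
    START, STOP = start_index(K), stop_index(K)
    inner = transitions[:K, :K]
    lengths = mask.sum(axis=1).astype(np.intp)
    if np.any(lengths < 1):
        raise ValueError("every sequence in the batch must have length >= 1")
    rows = np.arange(B)

    # ---- gold path scores and their gradient contributions ----
    gold = np.zeros(B)
    d_em = np.zeros_like(emissions)
    d_T = np.zeros_like(transitions)
    gold += transitions[START, tags[:, 0]]
    np.add.at(d_T, (START, tags[:, 0]), -1.0)
    for t in range(L):
        on = mask[:, t] > 0
        gold[on] += emissions[rows[on], t, tags[on, t]]
        np.add.at(d_em, (rows[on], t, tags[on, t]), -1.0)
        if t + 1 < L:
            nxt = mask[:, t + 1] > 0
            gold[nxt] += transitions[tags[nxt, t], tags[nxt, t + 1]]
            np.add.at(d_T, (tags[nxt, t], tags[nxt, t + 1]), -1.0)
    last_tags = tags[rows, lengths - 1]
    gold += transitions[last_tags, STOP]
    np.add.at(d_T, (last_tags, STOP), -1.0)

    # ---- forward pass (log alphas kept per step for the backward pass) ----
    alphas = np.empty((L, B, K))
    alpha = transitions[START, :K][None, :] + emissions[:, 0, :]
    alphas[0] = alpha
    for t in range(1, L):
        m = mask[:, t : t + 1]
        new = _lse3(alpha[:, :, None] + inner[None, :, :]) + emissions[:, t, :]
        alpha = m * new + (1.0 - m) * alpha
        alphas[t] = alpha
    log_z = _lse2(alpha + transitions[:K, STOP][None, :])

    # ---- backward pass and expected-count gradients ----
    beta = np.broadcast_to(transitions[:K, STOP][None, :], (B, K)).copy()
    betas = np.empty((L, B, K))
    for b in range(B):
        betas[lengths[b] - 1, b] = beta[b]
    for t in range(L - 2, -1, -1):
        m = (mask[:, t + 1] > 0)[:, None]
        new = _lse3(
            np.swapaxes(inner[None, :, :] + (emissions[:, t + 1, :] + betas[t + 1])[:, None, :], 1, 2)
        )
        beta = np.where(m, new, beta)
        betas[t] = beta
        # rows whose sequence ends at t keep beta = T[:, STOP]
        ended = lengths - 1 == t
        if ended.any():
            betas[t, ended] = transitions[:K, STOP][None, :]

    # unary marginals -> emission gradient; also START / STOP expectations
    for t in range(L):
        on = mask[:, t] > 0
        if not on.any():
            continue
        logm = alphas[t, on] + betas[t, on] - log_z[on, None]
        marg = np.exp(logm)
        d_em[on, t, :] += marg
    first_marg = np.exp(alphas[0] + betas[0] - log_z[:, None])
    d_T[START, :K] += first_marg.sum(axis=0)
    # d logZ / d T[k, STOP] is the softmax of the final scores, i.e. the
    # marginal of the last real position carrying tag k
    alpha_last = alphas[lengths - 1, rows]
    d_T[:K, STOP] += np.exp(
        alpha_last + transitions[:K, STOP][None, :] - log_z[:, None]
    ).sum(axis=0)

    # pairwise marginals -> inner transition gradient
    for t in range(L - 1):
        on = mask[:, t + 1] > 0
        if not on.any():
            continue
        logm = (
            alphas[t, on][:, :, None]
            + inner[None, :, :]
            + (emissions[on, t + 1, :] + betas[t + 1, on])[:, None, :]
            - log_z[on, None, None]
        )
        d_T[:K, :K] += np.exp(logm).sum(axis=0)

    loss = float(np.mean(log_z - gold))
    return loss, d_em / B, d_T / B


def _lse2(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    return np.log(np.exp(x - m).sum(axis=-1)) + m[..., 0]


def _lse3(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    return np.log(np.exp(x - m).sum(axis=1)) + m[:, 0, :]
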