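"""Linear-chain CRF over BIO label sequences.

The CRF scores a whole label path as ``start[y_0] + sum_t em[t, y_t] +
sum_t trans[y_{t-1}, y_t] + end[y_T]``.  Training minimises the negative
log-likelihood ``log Z - score(gold)``, where the normaliser ``log Z`` is
computed by the forward recursion in log space; prediction uses the Viterbi
dynamic programme to return the highest-scoring path.

BIO validity is enforced *structurally* with an additive constraint mask:
transitions into ``I-x`` from anything other than ``B-x``/``I-x`` (and
starts at ``I-x``) carry a large negative score that is excluded from
training updates, so a constrained CRF can never emit an invalid sequence.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .nn.autograd import DTYPE, Tensor

NEG = np.float32(-1e4)  # effectively forbidden; finite to keep float32 arithmetic clean


class CrfParameters:
    """Transition/start/end scores plus the (fixed) BIO constraint mask."""

    def __init__(self, labels: Sequence[str], seed: int = 0, constrain: bool = True):
        self.labels = tuple(labels)
        L = len(self.labels)
        rng = np.random.default_rng(seed)
        self.trans = Tensor(rng.normal(0.0, 0.02, (L, L)).astype(DTYPE))
        self.trans.requires_grad = True
        self.start = Tensor(rng.normal(0.0, 0.02, L).astype(DTYPE))
        self.start.requires_grad = True
        self.end = Tensor(rng.normal(0.0, 0.02, L).astype(DTYPE))
        self.end.requires_grad = True
        if constrain:
            self.trans_mask, self.start_mask = bio_constraint_masks(self.labels)
        else:
            self.trans_mask = np.zeros((L, L), dtype=DTYPE)
            self.start_mask = np.zeros(L, dtype=DTYPE)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def params(self, prefix: str = "crf.") -> dict[str, Tensor]:
        return {prefix + "trans": self.trans, prefix + "start": self.start,
                prefix + "end": self.end}

    def masked_trans(self) -> np.ndarray:
        return self.trans.data + self.trans_mask

    def masked_start(self) -> np.ndarray:
        return self.start.data + self.start_mask

    def allows(self, tag_ids: Sequence[int]) -> bool:
        if len(tag_ids) == 0:
            return False
        if self.start_mask[tag_ids[0]] < 0:
            return False
        return all(self.trans_mask[a, b] >= 0 for a, b in zip(tag_ids[:-1], tag_ids[1:]))


def bio_constraint_masks(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Additive masks forbidding ``O -> I-x``, ``B-y/I-y -> I-x`` (y != x) and start at ``I-x``."""
    L = len(labels)
    trans_mask = np.zeros((L, L), dtype=DTYPE)
    start_mask = np.zeros(L, dtype=DTYPE)
    for j, lj in enumerate(labels):
        if not lj.startswith("I-"):
            continue
        typ = lj[2:]
        start_mask[j] = NEG
        for i, li in enumerate(labels):
            if li not in (f"B-{typ}", f"I-{typ}"):
                trans_mask[i, j] = NEG
    return trans_mask, start_mask


def _as_batched(emissions) -> tuple[Tensor, bool]:
    t = emissions if isinstance(emissions, Tensor) else Tensor(np.asarray(emissions))
    if t.ndim == 2:
        return t.reshape(1, *t.shape), True
    if t.ndim == 3:
        return t, False
    raise ValueError("emissions must be (T,L) or (B,T,L)")


def crf_log_partition(emissions, crf: CrfParameters) -> Tensor:
    """log sum over all label paths of exp(path score), by the forward recursion.

    Accepts emissions of shape (T, L) -> scalar Tensor, or (B, T, L) for a
    batch of equal-length sequences -> (B,) Tensor.  Differentiable when
    ``emissions`` is a graph Tensor.
    """
    em, squeeze = _as_batched(emissions)
    B, T, L = em.shape
    if T < 1:
        raise ValueError("need at least one position")
    trans = (crf.trans + crf.trans_mask).reshape(1, L, L)
    alpha = em[:, 0, :] + (crf.start + crf.start_mask)  # (B,L)
    for t in range(1, T):
        step = alpha.reshape(B, L, 1) + trans + em[:, t, :].reshape(B, 1, L)
        alpha = step.logsumexp(axis=1)
    z = (alpha + crf.end).logsumexp(axis=1)  # (B,)
    return z.reshape(()) if squeeze else z


def crf_path_score(emissions, crf: CrfParameters, tags) -> Tensor:
    """Score of the given gold path(s); shapes follow :func:`crf_log_partition`."""
    em, squeeze = _as_batched(emissions)
    ids = np.asarray(tags, dtype=np.intp)
    if ids.ndim == 1:
        ids = ids[None, :]
    B, T, L = em.shape
    rows = np.arange(B)[:, None]
    cols = np.arange(T)[None, :]
    s = em[(rows, cols, ids)].sum(axis=1)
    s = s + crf.start[ids[:, 0]] + crf.end[ids[:, -1]]
    if T > 1:
        s = s + crf.trans[(ids[:, :-1], ids[:, 1:])].sum(axis=1)
    return s.reshape(()) if squeeze else s


def crf_nll(emissions, crf: CrfParameters, tags) -> Tensor:
    """Negative log-likelihood ``log Z - score(gold)``; always >= 0.

    Raises if the gold path violates the constraint mask (such a path has
    effectively zero probability under the constrained model).
    """
    ids = np.asarray(tags, dtype=np.intp)
    for row in ids.reshape(-1, ids.shape[-1]):
        if not crf.allows(row):
            raise ValueError(f"gold path {row.tolist()} violates the BIO constraint mask")
    return crf_log_partition(emissions, crf) - crf_path_score(emissions, crf, tags)


def viterbi_decode(emissions: np.ndarray, crf: CrfParameters) -> list[int]:
    """Maximum-score label path under the constraint mask (pure numpy).

    Ties are broken deterministically towards the lowest label index (numpy's
    argmax returns the first maximum).
    """
    em = emissions.data if isinstance(emissions, Tensor) else np.asarray(emissions)
    if em.ndim != 2 or em.shape[0] < 1:
        raise ValueError("emissions must be (T,L) with T >= 1")
    T, L = em.shape
    trans = crf.masked_trans()
    alpha = crf.masked_start() + em[0]
    back = np.zeros((T, L), dtype=np.intp)
    for t in range(1, T):
        scores = alpha[:, None] + trans  # (prev, next)
        back[t] = np.argmax(scores, axis=0)
        alpha = scores[back[t], np.arange(L)] + em[t]
    alpha = alpha + crf.end.data
    path = [int(np.argmax(alpha))]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t][path[-1]]))
    path.reverse()
    return path


def linear_decode(emissions: np.ndarray) -> list[int]:
    """Position-wise argmax (ties -> lowest label index); no sequence coupling."""
    em = emissions.data if isinstance(emissions, Tensor) else np.asarray(emissions, dtype=DTYPE)
    return [int(i) for i in np.argmax(em, axis=-1)]
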