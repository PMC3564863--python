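"""Gaussian-emission hidden Markov machinery for nanopore event analysis.

The model is the standard discrete-time HMM with K hidden states and a
Gaussian emission per state, parameterized exactly as the field writes it
for single-channel current records:

* ``pi`` — initial-state probabilities (probability that an event *begins*
  in a given state),
* ``A`` — K x K state-to-state transition probability matrix,
* ``q`` — per-state emission means in normalized current units (I/I0),
* ``b`` — per-state emission standard deviations (I/I0 units).

Provided here: exact scaled forward likelihood, Viterbi decoding with a
deterministic tie-break, multi-sequence Baum-Welch with selective parameter
freezing (needed for the voltage-specific refit, where only ``pi`` and ``A``
are re-estimated), and histogram-based construction of an initial model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "HmmModel",
    "FitResult",
    "ViterbiPath",
    "log_likelihood",
    "viterbi",
    "baum_welch",
    "initial_model_from_histogram",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: smallest admissible emission SD (I/I0 units); prevents variance collapse
#: on 1-2 point events during re-estimation.
B_FLOOR = 1e-4

_ATOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when an HmmModel violates its stochastic-matrix invariants."""


@dataclass
class HmmModel:
    """K-state Gaussian-emission HMM ``(pi, A, q, b)``.

    States are kept in canonical order: ascending by emission mean ``q``
    (low, mid, high for the three-state protein models).
    """

    pi: np.ndarray
    A: np.ndarray
    q: np.ndarray
    b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.b = np.asarray(self.b, dtype=float)

    @property
    def K(self) -> int:
        return self.q.shape[0]

    def validate(self) -> "HmmModel":
        K = self.K
        if self.pi.shape != (K,) or self.A.shape != (K, K) or self.b.shape != (K,):
            raise ModelValidationError("shape mismatch among pi, A, q, b")
        if not np.all(np.isfinite(self.pi)) or np.any(self.pi < 0):
            raise ModelValidationError("pi must be finite and nonnegative")
        if abs(self.pi.sum() - 1.0) > _ATOL:
            raise ModelValidationError("pi must sum to 1 within 1e-9")
        if np.any(self.A < 0) or not np.all(np.isfinite(self.A)):
            raise ModelValidationError("A must be finite and nonnegative")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > _ATOL):
            raise ModelValidationError("each row of A must sum to 1 within 1e-9")
        if np.any(self.b <= 0) or not np.all(np.isfinite(self.b)):
            raise ModelValidationError("all emission SDs b must be > 0")
        if not np.all(np.isfinite(self.q)):
            raise ModelValidationError("q must be finite")
        if np.any(np.diff(self.q) < 0):
            raise ModelValidationError("states must be sorted ascending by q")
        return self

    def canonicalized(self) -> "HmmModel":
        """Return an equivalent model with states sorted ascending by q."""
        order = np.argsort(self.q, kind="stable")
        return HmmModel(
            pi=self.pi[order],
            A=self.A[np.ix_(order, order)],
            q=self.q[order],
            b=self.b[order],
            label=self.label,
        )

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of A (principal left eigenvector)."""
        w, v = np.linalg.eig(self.A.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()

    # ---- JSON round trip (bit-exact via shortest-repr floats) ----

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "K": self.K,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            pi=np.array(d["pi"], dtype=float),
            A=np.array(d["A"], dtype=float),
            q=np.array(d["q"], dtype=float),
            b=np.array(d["b"], dtype=float),
            label=d.get("label", ""),
        )

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        d = self.to_dict()
        if meta:
            d["meta"] = meta
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "HmmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ViterbiPath:
    """Most probable hidden-state sequence for one event."""

    states: np.ndarray
    log_joint: float


@dataclass
class FitResult:
    """Outcome of a Baum-Welch fit."""

    model: HmmModel
    loglik_trajectory: np.ndarray
    n_iter: int
    converged: bool
    warnings: list = field(default_factory=list)


def _as_values(event) -> np.ndarray:
    """Accept an Event object (``.values``) or a bare array of I/I0 points."""
    values = getattr(event, "values", event)
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("event must be a non-empty 1-D sequence of I/I0 values")
    return x


def _log_emissions(x: np.ndarray, model: HmmModel) -> np.ndarray:
    """(T, K) Gaussian log-densities of each point under each state."""
    z = (x[:, None] - model.q[None, :]) / model.b[None, :]
    return -0.5 * z * z - np.log(model.b)[None, :] - 0.5 * _LOG_2PI


def _forward(x: np.ndarray, model: HmmModel):
    """Scaled forward pass.

    Returns ``(loglik, alpha_hat, log_b)`` where ``alpha_hat[t]`` is the
    forward variable normalized to sum to 1 at each step and the scale
    factors are accumulated in log space (textbook scaled recursion; stable
    for events up to 1e5 points).
    """
    T = x.shape[0]
    K = model.K
    logB = _log_emissions(x, model)
    # per-row max keeps the linear-domain emissions in range
    off = logB.max(axis=1)
    B = np.exp(logB - off[:, None])

    alpha = np.empty((T, K))
    loglik = 0.0
    a = model.pi * B[0]
    c = a.sum()
    if c <= 0.0 or not np.isfinite(c):
        raise FloatingPointError("forward pass underflow at t=0")
    alpha[0] = a / c
    loglik += np.log(c) + off[0]
    AT = model.A
    for t in range(1, T):
        a = (alpha[t - 1] @ AT) * B[t]
        c = a.sum()
        if c <= 0.0 or not np.isfinite(c):
            raise FloatingPointError(f"forward pass underflow at t={t}")
        alpha[t] = a / c
        loglik += np.log(c) + off[t]
    return loglik, alpha, logB


def log_likelihood(event, model: HmmModel) -> float:
    """Exact marginal log-likelihood ``log P(E | lambda)`` of an event.

    Computed with the per-step-scaled forward recursion; finite for all
    finite inputs and valid models.
    """
    model.validate()
    x = _as_values(event)
    loglik, _, _ = _forward(x, model)
    return float(loglik)


def viterbi(event, model: HmmModel) -> ViterbiPath:
    """Most likely state sequence (Viterbi path) of an event.

    Ties are broken toward the lowest state index at every backtrack step,
    so the decoded path is deterministic across platforms.  The returned
    ``log_joint`` is the log of the maximized joint probability and is
    always <= the marginal log-likelihood of the same event.
    """
    model.validate()
    x = _as_values(event)
    T = x.shape[0]
    K = model.K
    logB = _log_emissions(x, model)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
        logA = np.log(model.A)

    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]
        # argmax returns the first (lowest-index) maximizer
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]

    states = np.empty(T, dtype=np.intp)
    states[-1] = int(np.argmax(delta))
    log_joint = float(delta[states[-1]])
    for t in range(T - 1, 0, -1):
        states[t - 1] = psi[t, states[t]]
    return ViterbiPath(states=states, log_joint=log_joint)


def _event_list(events) -> list[np.ndarray]:
    seqs = [_as_values(e) for e in events]
    if not seqs:
        raise ValueError("at least one event is required")
    return seqs


def baum_welch(
    events: Sequence,
    init: HmmModel,
    *,
    update_pi: bool = True,
    update_A: bool = True,
    update_q: bool = True,
    update_b: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    b_floor: float = B_FLOOR,
) -> FitResult:
    """Multi-sequence Baum-Welch EM with selective parameter freezing.

    Each event is an independent sequence; ``pi`` is re-estimated from the
    per-event posteriors at t=0 (events are never concatenated, since pi is
    the probability that an *event* begins in a given state).  Only the
    flagged parameter blocks are updated; frozen blocks remain bit-identical
    to ``init``.  Iteration stops when the relative change in total
    log-likelihood drops below ``tol`` or at ``max_iter``.

    States starved of posterior mass (expected occupancy < 1e-12) keep
    their ``q``/``b`` for that iteration and a warning is recorded.

    The returned model is re-canonicalized (states sorted ascending by q,
    with ``pi`` and ``A`` permuted consistently).
    """
    init.validate()
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    seqs = _event_list(events)

    pi = init.pi.copy()
    A = init.A.copy()
    q = init.q.copy()
    b = init.b.copy()
    K = init.K
    warn_log: list[str] = []

    trajectory: list[float] = []
    prev_ll = -np.inf
    n_iter = 0
    converged = False

    for it in range(max_iter):
        model = HmmModel(pi=pi, A=A, q=q, b=b, label=init.label)
        total_ll = 0.0
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        gamma_acc = np.zeros(K)          # sum of posteriors over all t
        gamma_trans_acc = np.zeros(K)    # posteriors over t < T-1 (xi denominator)
        mean_acc = np.zeros(K)
        var_acc = np.zeros(K)

        for x in seqs:
            ll, alpha, logB = _forward(x, model)
            total_ll += ll
            T = x.shape[0]
            off = logB.max(axis=1)
            B = np.exp(logB - off[:, None])

            beta = np.empty((T, K))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                v = A @ (B[t + 1] * beta[t + 1])
                s = v.sum()
                beta[t] = v / s

            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)

            pi_acc += gamma[0]
            gamma_acc += gamma.sum(axis=0)
            if T > 1:
                gamma_trans_acc += gamma[:-1].sum(axis=0)
                # xi_t ∝ alpha_t[i] A[i,j] B[t+1,j] beta[t+1,j], vectorized over t
                m = alpha[:-1, :, None] * A[None, :, :] * (B[1:] * beta[1:])[:, None, :]
                m /= m.sum(axis=(1, 2), keepdims=True)
                xi_acc += m.sum(axis=0)
            mean_acc += gamma.T @ x
            var_acc += gamma.T @ (x * x)

        trajectory.append(total_ll)
        n_iter = it + 1

        rel = abs(total_ll - prev_ll) / max(1.0, abs(total_ll))
        if it > 0 and rel < tol:
            converged = True
            break
        prev_ll = total_ll

        starved = gamma_acc < 1e-12
        if np.any(starved) and (update_q or update_b):
            warn_log.append(
                f"iteration {it}: states {np.flatnonzero(starved).tolist()} "
                "starved of posterior mass; q,b frozen for this iteration"
            )

        if update_pi:
            pi = pi_acc / pi_acc.sum()
        if update_A:
            denom = np.where(gamma_trans_acc > 0, gamma_trans_acc, 1.0)
            A_new = xi_acc / denom[:, None]
            # rows with no observed transitions keep their previous values
            rowsum = A_new.sum(axis=1)
            dead = rowsum <= 0
            A_new[dead] = A[dead]
            A_new /= A_new.sum(axis=1, keepdims=True)
            A = A_new
        safe = ~starved
        if update_q:
            q = np.where(safe, mean_acc / np.where(safe, gamma_acc, 1.0), q)
        if update_b:
            ex2 = var_acc / np.where(safe, gamma_acc, 1.0)
            new_var = ex2 - (mean_acc / np.where(safe, gamma_acc, 1.0)) ** 2
            new_b = np.sqrt(np.maximum(new_var, b_floor**2))
            b = np.where(safe, new_b, b)

    fitted = HmmModel(pi=pi, A=A, q=q, b=b, label=init.label).canonicalized()
    if not (update_q or update_b):
        # frozen blocks must stay bit-identical: canonical order of q is
        # unchanged, so only pi/A could have been touched, and they were
        # permuted by the identity.
        fitted = HmmModel(pi=fitted.pi, A=fitted.A, q=init.q, b=init.b, label=init.label)
    for w in warn_log:
        warnings.warn(w, RuntimeWarning, stacklevel=2)
    return FitResult(
        model=fitted,
        loglik_trajectory=np.asarray(trajectory),
        n_iter=n_iter,
        converged=converged,
        warnings=warn_log,
    )


def initial_model_from_histogram(events, K: int, random_state: int = 0) -> HmmModel:
    """Initial model with ``q``/``b`` from a K-cluster 1-D partition of the
    pooled I/I0 points, uniform ``pi`` and uniform ``A``.

    This mirrors how the initial model is built in practice: state levels
    and noise widths are read off the event histogram, while the
    probabilities are assumed uninformative (an event is equally likely to
    begin in any state, and all transitions are equally likely).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    pooled = np.concatenate([_as_values(e) for e in events])
    if np.unique(pooled).size < K:
        raise ValueError(f"need at least {K} distinct pooled values for K={K}")

    if K == 1:
        q = np.array([pooled.mean()])
        b = np.array([max(pooled.std(), B_FLOOR)])
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=10, random_state=random_state)
        labels = km.fit_predict(pooled[:, None])
        centers = km.cluster_centers_.ravel()
        order = np.argsort(centers)
        q = centers[order]
        b = np.empty(K)
        for rank, cl in enumerate(order):
            pts = pooled[labels == cl]
            b[rank] = max(pts.std(), B_FLOOR)
    return HmmModel(
        pi=np.full(K, 1.0 / K),
        A=np.full((K, K), 1.0 / K),
        q=q,
        b=b,
        label=f"histogram-init K={K}",
    ).validate()
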