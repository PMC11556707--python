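"""Single-layer Kalman filter of pain perception.

The filter maintains a scalar belief about tissue damage.  The *prior mean*
``xbar_hat = A_hat * x_hat + B_hat . u (+ eps(0, Q))`` is the expected pain,
the *posterior mean* ``x_hat = xbar_hat + K (z - xbar_hat)`` is the perceived
pain, and the Kalman gain ``K = Pbar / (Pbar + R)`` sets how much the noisy
sensory input ``z`` corrects the expectation.

All operations broadcast over leading axes, so a whole batch of replicates
can be filtered with one call per step; the scalar dataclass API is a thin
veneer over the same kernels.

The paper-facing convention of sampling the process noise ``eps(0, Q)`` into
the prior *mean* (not only adding ``Q`` to the prior variance) is available
behind ``sample_process_noise``; with the flag off the filter is the textbook
deterministic recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ConfigurationError, DimensionError, FilterParams, StimulusSchedule

__all__ = [
    "FilterState",
    "PriorEstimate",
    "TrajectoryRecord",
    "process_noise_variance",
    "predict_state",
    "update_state",
    "steady_state_prior_variance",
    "run_filter",
]


@dataclass
class FilterState:
    """Posterior belief: perceived pain ``x_hat``, variance ``P``, step ``k``."""

    x_hat: float | np.ndarray = 0.0
    P: float | np.ndarray = 1.0e6
    k: int = 0


@dataclass
class PriorEstimate:
    """Prior belief: expected pain ``xbar_hat``, variance ``Pbar`` and the
    process-noise variance ``Q`` used at this step."""

    xbar_hat: float | np.ndarray
    Pbar: float | np.ndarray
    Q: float | np.ndarray


@dataclass
class TrajectoryRecord:
    """Per-step log of one (possibly batched) filter run.

    State arrays have shape ``(n_steps, ...)`` with the replicate batch in
    the trailing axes.  Hierarchical runs additionally fill the parameter
    fields (``p_hat`` etc.); they are ``None`` for single-layer runs.
    """

    x: np.ndarray
    z: np.ndarray
    xbar_hat: np.ndarray
    Pbar: np.ndarray
    K: np.ndarray
    x_hat: np.ndarray
    P: np.ndarray
    p_hat: Optional[np.ndarray] = None
    Pp_diag: Optional[np.ndarray] = None
    K_p: Optional[np.ndarray] = None
    e_hat: Optional[np.ndarray] = None
    R_p: Optional[np.ndarray] = None
    Hp: Optional[np.ndarray] = None
    Pp_final: Optional[np.ndarray] = None
    Pp_history: Optional[np.ndarray] = None

    def clipped(self, bounds=(0.0, 10.0)) -> np.ndarray:
        """Perceived pain clipped to the reporting scale (clipping is applied
        only when summarising, never inside the filter recursion)."""
        return np.clip(self.x_hat, *bounds)


# ---------------------------------------------------------------------------
# kernels (shared with the hierarchical filter to keep the degenerate case
# bit-identical)


def _dot_bu(B, u):
    return np.sum(np.asarray(B, dtype=float) * np.asarray(u, dtype=float), axis=-1)


def _predict_mean(A, B, x_hat, u, eps):
    return A * x_hat + _dot_bu(B, u) + eps


def _predict_var(A, P, Q):
    return A * A * P + Q


def _update(xbar, Pbar, z, R):
    K = Pbar / (Pbar + R)
    x_hat = xbar + K * (z - xbar)
    P = (1.0 - K) * Pbar
    return x_hat, P, K


# ---------------------------------------------------------------------------
# public operations


def process_noise_variance(params: FilterParams, u) -> float | np.ndarray:
    """``Q = Q0 + ||u||^2 * Qu`` -- control input inflates process noise."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != params.m:
        raise DimensionError(
            f"control input has length {u.shape[-1]}, expected m={params.m}"
        )
    norm_sq = np.sum(u * u, axis=-1)
    q = params.Q0 + norm_sq * params.Qu
    return float(q) if np.ndim(q) == 0 else q


def predict_state(
    state: FilterState,
    params: FilterParams,
    u,
    rng: np.random.Generator | None = None,
    sample_process_noise: bool = False,
) -> PriorEstimate:
    """Propagate the belief through the internal model.

    With ``sample_process_noise`` a draw from ``N(0, Q)`` is added to the
    prior mean (the stochastic-prior convention used in the simulation
    protocols); ``Q`` always enters the prior variance.
    """
    Q = process_noise_variance(params, u)
    if sample_process_noise:
        if rng is None:
            raise ConfigurationError("sample_process_noise=True requires an rng")
        eps = np.sqrt(Q) * rng.standard_normal(np.shape(state.x_hat))
    else:
        eps = 0.0
    xbar = _predict_mean(params.A_hat, params.b_vector, state.x_hat, u, eps)
    Pbar = _predict_var(params.A_hat, state.P, Q)
    return PriorEstimate(xbar_hat=xbar, Pbar=Pbar, Q=Q)


def update_state(prior: PriorEstimate, z, R) -> tuple[FilterState, float | np.ndarray]:
    """Fuse the prior with sensory input; returns the posterior and gain."""
    if np.any(np.asarray(R) <= 0):
        raise ConfigurationError("R must be > 0")
    x_hat, P, K = _update(prior.xbar_hat, prior.Pbar, z, R)
    return FilterState(x_hat=x_hat, P=P, k=0), K


def steady_state_prior_variance(A_hat, Q, R):
    """Positive fixed point of the scalar prior-variance recursion.

    Solves ``Pbar = A_hat^2 * R * Pbar / (Pbar + R) + Q``, i.e. the positive
    root of ``Pbar^2 + ((1 - A_hat^2) R - Q) Pbar - Q R = 0``; evaluated in a
    cancellation-safe form.  Serves as the convergence oracle for the
    iterated filter.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    Q = np.asarray(Q, dtype=float)
    R = np.asarray(R, dtype=float)
    b = (1.0 - A_hat * A_hat) * R - Q
    disc = np.sqrt(b * b + 4.0 * Q * R)
    root = np.where(b > 0, 2.0 * Q * R / (b + disc), 0.5 * (disc - b))
    return float(root) if root.ndim == 0 else root


def run_filter(
    params: FilterParams,
    schedule: StimulusSchedule,
    z: np.ndarray,
    rng: np.random.Generator | None = None,
    sample_process_noise: bool = True,
    x0: float = 0.0,
    P_init: float | None = None,
    x_true: np.ndarray | None = None,
) -> TrajectoryRecord:
    """Filter a batch of sensory-input trajectories through fixed parameters.

    Parameters
    ----------
    z
        Sensory input, shape ``(n_steps, n_rep)``.
    rng
        Process-noise stream; required when ``sample_process_noise``.
    """
    z = np.asarray(z, dtype=float)
    n, n_rep = z.shape
    if schedule.n_steps != n:
        raise DimensionError("schedule and z disagree on n_steps")
    b_vec = params.b_vector

    u = schedule.u
    norm_sq = np.sum(u * u, axis=-1)  # (n,) or (n, n_rep)
    Q = params.Q0 + norm_sq * params.Qu
    Q_col = Q if Q.ndim == 2 else Q[:, None]
    if sample_process_noise:
        if rng is None:
            raise ConfigurationError("sample_process_noise=True requires an rng")
        eps = np.sqrt(Q_col) * rng.standard_normal((n, n_rep))
    else:
        eps = np.zeros((n, n_rep))

    rec = TrajectoryRecord(
        x=np.zeros(n) if x_true is None else np.asarray(x_true, dtype=float),
        z=z,
        xbar_hat=np.empty((n, n_rep)),
        Pbar=np.empty((n, n_rep)),
        K=np.empty((n, n_rep)),
        x_hat=np.empty((n, n_rep)),
        P=np.empty((n, n_rep)),
    )

    x_hat = np.full(n_rep, float(x0))
    P = np.full(n_rep, params.P0 if P_init is None else float(P_init))
    for k in range(n):
        u_k = u[k]
        xbar = _predict_mean(params.A_hat, b_vec, x_hat, u_k, eps[k])
        Pbar = _predict_var(params.A_hat, P, Q_col[k] if Q.ndim == 2 else Q[k])
        x_hat, P, K = _update(xbar, Pbar, z[k], schedule.R[k])
        rec.xbar_hat[k] = xbar
        rec.Pbar[k] = Pbar
        rec.K[k] = K
        rec.x_hat[k] = x_hat
        rec.P[k] = P
    return rec
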