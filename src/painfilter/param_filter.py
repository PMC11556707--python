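"""Hierarchical layer: Kalman estimation of the internal-model parameters.

A second Kalman filter treats the internal-model parameter vector
``p_hat = [A_hat, b_1, ..., b_m]`` as a slowly drifting latent state and
updates it from the pain prediction error ``e_hat = x_hat - xbar_hat``
(perceived minus expected pain).  Two departures from the textbook dual
filter are deliberate:

* the prediction-error variance is ``R_p = P + Pbar``, the sum of the
  variances of the two estimates being differenced;
* the parameter-covariance update is scaled by the state gain ``K``:
  ``P_p = (I - K K_p H_p) Pbar_p``.  Without the scaling, ``P_p`` would
  collapse to zero as ``R -> inf`` -- i.e. the model would become certain of
  its internal parameters precisely when sensory input carries no
  information.  The unscaled variant remains available (``legacy=True``) for
  comparison.  The gain factor multiplies from the left: the subtrahend is
  then the symmetric Gram matrix ``K (Pbar_p Hp^T)(Pbar_p Hp^T)^T / S``,
  which keeps ``P_p`` positive semidefinite and reduces to the textbook
  covariance update at ``K = 1``.

The observation row ``H_p = (1 - K) [x_hat_prev, u]`` maps parameter space
to state space.  Because ``H_p`` at step ``k`` needs the gain of step ``k``,
the parameter-uncertainty term inside the state-prior variance uses the
``H_p`` computed at the end of the *previous* step (one-step lag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .params import ConfigurationError, DimensionError, FilterParams, StimulusSchedule
from .state_filter import (
    FilterState,
    PriorEstimate,
    TrajectoryRecord,
    _dot_bu,
    _predict_var,
    _update,
)

__all__ = [
    "ParamNoise",
    "ParamFilterState",
    "PredictionError",
    "predict_params",
    "compute_Hp",
    "update_params",
    "hier_predict_state",
    "hier_step",
    "run_hierarchical",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class ParamNoise:
    """Internal-model noise covariance (diagonal) and initial covariance.

    ``Q_p`` is diagonal because the persistence and the cue gains are taken
    as independent random variables.
    """

    Q_p: np.ndarray
    P_p0: np.ndarray

    def __post_init__(self):
        Q_p = np.asarray(self.Q_p, dtype=float)
        P_p0 = np.asarray(self.P_p0, dtype=float)
        if Q_p.ndim != 2 or Q_p.shape[0] != Q_p.shape[1]:
            raise DimensionError("Q_p must be a square matrix")
        off = Q_p - np.diag(np.diag(Q_p))
        if np.any(off != 0.0):
            raise ConfigurationError("Q_p must be diagonal")
        if np.any(np.diag(Q_p) < 0):
            raise ConfigurationError("Q_p diagonal entries must be non-negative")
        if P_p0.shape != Q_p.shape:
            raise DimensionError("P_p0 must match Q_p in shape")
        object.__setattr__(self, "Q_p", Q_p)
        object.__setattr__(self, "P_p0", P_p0)

    @property
    def dim(self) -> int:
        return self.Q_p.shape[0]

    @classmethod
    def defaults(cls, m: int = 1, q: float = 0.002**2, p0: float = 1.0e6) -> "ParamNoise":
        d = 1 + m
        return cls(Q_p=q * np.eye(d), P_p0=p0 * np.eye(d))


@dataclass
class ParamFilterState:
    """Internal-model estimate ``p_hat`` with covariance ``P_p`` at step ``k``."""

    p_hat: np.ndarray
    P_p: np.ndarray
    k: int = 0


class PredictionError(NamedTuple):
    """Pain prediction error and its variance ``R_p = P + Pbar``."""

    e_hat: float | np.ndarray
    R_p: float | np.ndarray


def _quad(Hp, M):
    """``Hp M Hp^T`` for row vectors with leading batch axes."""
    return np.einsum("...i,...ij,...j->...", Hp, M, Hp)


def _matvec(M, v):
    return np.einsum("...ij,...j->...i", M, v)


def predict_params(
    state: ParamFilterState,
    noise: ParamNoise,
    rng: np.random.Generator | None = None,
    sample_noise: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk prior for the parameters: ``pbar = p (+ eps)``,
    ``Pbar_p = P_p + Q_p``."""
    p_hat = np.asarray(state.p_hat, dtype=float)
    if sample_noise:
        if rng is None:
            raise ConfigurationError("sample_noise=True requires an rng")
        sd = np.sqrt(np.diag(noise.Q_p))
        pbar = p_hat + sd * rng.standard_normal(p_hat.shape)
    else:
        pbar = p_hat.copy()
    Pbar_p = np.asarray(state.P_p, dtype=float) + noise.Q_p
    return pbar, Pbar_p


def compute_Hp(K, x_hat_prev, u) -> np.ndarray:
    """Sensitivity of the posterior pain to the parameters:
    ``H_p = (1 - K) [x_hat_prev, u_1, ..., u_m]``."""
    K = np.asarray(K, dtype=float)
    x_prev = np.asarray(x_hat_prev, dtype=float)
    u = np.asarray(u, dtype=float)
    lead = np.broadcast_shapes(K.shape, x_prev.shape, u.shape[:-1])
    x_col = np.broadcast_to(x_prev, lead)[..., None]
    u_b = np.broadcast_to(u, lead + u.shape[-1:])
    return (1.0 - K)[..., None] * np.concatenate([x_col, u_b], axis=-1)


def update_params(
    pbar_hat,
    Pbar_p,
    Hp,
    err: PredictionError,
    K,
    legacy: bool = False,
) -> tuple[ParamFilterState, np.ndarray]:
    """Measurement update of the parameter filter from the prediction error.

    ``K_p = Pbar_p Hp^T / (Hp Pbar_p Hp^T + R_p)`` (a column vector: the
    innovation is scalar), ``p = pbar + K_p e``, and the covariance update
    ``P_p = Pbar_p (I - K K_p Hp)`` with the state gain ``K`` as scaling
    factor (``legacy=True`` drops the scaling).  The result is symmetrised
    to suppress floating-point asymmetry.
    """
    pbar_hat = np.asarray(pbar_hat, dtype=float)
    Pbar_p = np.asarray(Pbar_p, dtype=float)
    Hp = np.asarray(Hp, dtype=float)
    S = _quad(Hp, Pbar_p) + np.asarray(err.R_p, dtype=float)
    if np.any(S <= 0):
        raise ConfigurationError("innovation variance must be positive (zero Hp with R_p = 0?)")
    PH = _matvec(Pbar_p, Hp)
    K_p = PH / np.asarray(S)[..., None]
    p_hat = pbar_hat + K_p * np.asarray(err.e_hat, dtype=float)[..., None]
    scale = np.ones(()) if legacy else np.asarray(K, dtype=float)
    # (I - scale * K_p Hp) Pbar_p  ==  Pbar_p - scale * (PH PH^T) / S:
    # subtracting a scaled Gram matrix keeps P_p positive semidefinite.
    P_p = Pbar_p - (scale / np.asarray(S))[..., None, None] * np.einsum(
        "...i,...j->...ij", PH, PH
    )
    P_p = 0.5 * (P_p + np.swapaxes(P_p, -1, -2))
    return ParamFilterState(p_hat=p_hat, P_p=P_p, k=0), K_p


def hier_predict_state(
    state: FilterState,
    pstate: ParamFilterState,
    params: FilterParams,
    Hp_prev,
    u,
    rng: np.random.Generator | None = None,
    sample_process_noise: bool = False,
) -> PriorEstimate:
    """State prediction with time-varying parameters.

    The prior variance gains the parameter-uncertainty term
    ``Hp_prev P_p Hp_prev^T`` (lagged sensitivity row, see module docstring).
    ``params`` supplies the noise constants (``Q0 = 0.1^2`` in hierarchical
    mode); the dynamics come from ``pstate``.
    """
    u = np.asarray(u, dtype=float)
    p = np.asarray(pstate.p_hat, dtype=float)
    if u.shape[-1] != p.shape[-1] - 1:
        raise DimensionError("u length must be len(p_hat) - 1")
    A = p[..., 0]
    B = p[..., 1:]
    norm_sq = np.sum(u * u, axis=-1)
    Q = params.Q0 + norm_sq * params.Qu
    if sample_process_noise:
        if rng is None:
            raise ConfigurationError("sample_process_noise=True requires an rng")
        eps = np.sqrt(Q) * rng.standard_normal(np.shape(state.x_hat))
    else:
        eps = 0.0
    xbar = A * np.asarray(state.x_hat) + _dot_bu(B, u) + eps
    Pbar = _predict_var(A, np.asarray(state.P), Q) + _quad(
        np.asarray(Hp_prev, dtype=float), np.asarray(pstate.P_p, dtype=float)
    )
    return PriorEstimate(xbar_hat=xbar, Pbar=Pbar, Q=Q)


def hier_step(
    z,
    u,
    R,
    fstate: FilterState,
    pstate: ParamFilterState,
    params: FilterParams,
    noise: ParamNoise,
    Hp_prev,
    process_rng: np.random.Generator | None = None,
    param_rng: np.random.Generator | None = None,
    sample_process_noise: bool = False,
    sample_param_noise: bool = False,
    legacy: bool = False,
) -> tuple[FilterState, ParamFilterState, np.ndarray, dict]:
    """One full step of the hierarchical filter.

    Order of operations: parameter prior -> state prior (lagged ``H_p`` in
    the variance term) -> state update (yields ``K``) -> fresh ``H_p`` ->
    prediction error with ``R_p = P + Pbar`` -> parameter update.  The
    parameters consuming the step-``k`` error are in place before the
    step-``k+1`` state prediction.
    """
    pbar, Pbar_p = predict_params(pstate, noise, param_rng, sample_param_noise)
    prior = hier_predict_state(
        fstate,
        ParamFilterState(p_hat=pbar, P_p=Pbar_p, k=pstate.k),
        params,
        Hp_prev,
        u,
        process_rng,
        sample_process_noise,
    )
    if np.any(np.asarray(R) <= 0):
        raise ConfigurationError("R must be > 0")
    x_prev = np.asarray(fstate.x_hat)
    x_hat, P, K = _update(prior.xbar_hat, prior.Pbar, z, R)
    Hp = compute_Hp(K, x_prev, u)
    err = PredictionError(e_hat=x_hat - prior.xbar_hat, R_p=P + prior.Pbar)
    pstate_new, K_p = update_params(pbar, Pbar_p, Hp, err, K, legacy=legacy)
    pstate_new.k = pstate.k + 1
    fstate_new = FilterState(x_hat=x_hat, P=P, k=fstate.k + 1)
    row = {
        "xbar_hat": prior.xbar_hat,
        "Pbar": prior.Pbar,
        "K": K,
        "Hp": Hp,
        "e_hat": err.e_hat,
        "R_p": err.R_p,
        "K_p": K_p,
    }
    return fstate_new, pstate_new, Hp, row


def run_hierarchical(
    params: FilterParams,
    noise: ParamNoise,
    schedule: StimulusSchedule,
    z: np.ndarray,
    process_rng: np.random.Generator | None = None,
    param_rng: np.random.Generator | None = None,
    sample_process_noise: bool = True,
    sample_param_noise: bool = True,
    x0: float = 0.0,
    P_init: float | None = None,
    p0: np.ndarray | None = None,
    Pp_init: np.ndarray | None = None,
    legacy: bool = False,
    x_true: np.ndarray | None = None,
    store_Pp: bool = False,
) -> TrajectoryRecord:
    """Run the hierarchical filter over a batch of replicates.

    Parameters
    ----------
    z
        Sensory input, shape ``(n_steps, n_rep)``.
    p0
        Initial parameter vector, shape ``(d,)`` shared or ``(n_rep, d)``
        per replicate (e.g. per-individual cue gains); defaults to
        ``[A_hat, *B_hat]`` from ``params``.
    Pp_init
        Initial parameter covariance, ``(d, d)``; defaults to ``noise.P_p0``.
    """
    z = np.asarray(z, dtype=float)
    n, n_rep = z.shape
    if schedule.n_steps != n:
        raise DimensionError("schedule and z disagree on n_steps")
    d = noise.dim
    if d != schedule.m + 1:
        raise DimensionError("ParamNoise dimension must be 1 + m")

    if p0 is None:
        p0 = np.concatenate([[params.A_hat], params.b_vector])
    p_hat = np.broadcast_to(np.asarray(p0, dtype=float), (n_rep, d)).copy()
    Pp0 = noise.P_p0 if Pp_init is None else np.asarray(Pp_init, dtype=float)
    P_p = np.broadcast_to(Pp0, (n_rep, d, d)).copy()

    u = schedule.u  # (n, m) or (n, n_rep, m)
    norm_sq = np.sum(u * u, axis=-1)
    Q = params.Q0 + norm_sq * params.Qu
    Q_col = Q if Q.ndim == 2 else Q[:, None]
    if sample_process_noise:
        if process_rng is None:
            raise ConfigurationError("sample_process_noise=True requires process_rng")
        eps = np.sqrt(Q_col) * process_rng.standard_normal((n, n_rep))
    else:
        eps = np.zeros((n, n_rep))
    if sample_param_noise:
        if param_rng is None:
            raise ConfigurationError("sample_param_noise=True requires param_rng")
        sd = np.sqrt(np.diag(noise.Q_p))
        p_eps = sd * param_rng.standard_normal((n, n_rep, d))
    else:
        p_eps = np.zeros((n, n_rep, d))

    rec = TrajectoryRecord(
        x=np.zeros(n) if x_true is None else np.asarray(x_true, dtype=float),
        z=z,
        xbar_hat=np.empty((n, n_rep)),
        Pbar=np.empty((n, n_rep)),
        K=np.empty((n, n_rep)),
        x_hat=np.empty((n, n_rep)),
        P=np.empty((n, n_rep)),
        p_hat=np.empty((n, n_rep, d)),
        Pp_diag=np.empty((n, n_rep, d)),
        K_p=np.empty((n, n_rep, d)),
        e_hat=np.empty((n, n_rep)),
        R_p=np.empty((n, n_rep)),
        Hp=np.empty((n, n_rep, d)),
    )
    Pp_full = np.empty((n, n_rep, d, d)) if store_Pp else None

    x_hat = np.full(n_rep, float(x0))
    P = np.full(n_rep, params.P0 if P_init is None else float(P_init))
    Hp_lag = np.zeros((n_rep, d))
    Q_p = noise.Q_p
    for k in range(n):
        u_k = u[k]  # (m,) or (n_rep, m)
        # parameter prior
        pbar = p_hat + p_eps[k]
        Pbar_p = P_p + Q_p
        # state prior with lagged parameter-uncertainty term
        A = pbar[:, 0]
        B = pbar[:, 1:]
        xbar = A * x_hat + _dot_bu(B, u_k) + eps[k]
        Pbar = _predict_var(A, P, Q_col[k] if Q.ndim == 2 else Q[k]) + _quad(Hp_lag, Pbar_p)
        # state update
        x_prev = x_hat
        x_hat, P, K = _update(xbar, Pbar, z[k], schedule.R[k])
        # fresh sensitivity row, prediction error, parameter update
        Hp = compute_Hp(K, x_prev, u_k)
        e_hat = x_hat - xbar
        R_p = P + Pbar
        S = _quad(Hp, Pbar_p) + R_p
        PH = _matvec(Pbar_p, Hp)
        K_p = PH / S[..., None]
        p_hat = pbar + K_p * e_hat[..., None]
        scale = np.ones_like(K) if legacy else K
        P_p = Pbar_p - (scale / S)[..., None, None] * np.einsum(
            "...i,...j->...ij", PH, PH
        )
        P_p = 0.5 * (P_p + np.swapaxes(P_p, -1, -2))
        Hp_lag = Hp

        rec.xbar_hat[k] = xbar
        rec.Pbar[k] = Pbar
        rec.K[k] = K
        rec.x_hat[k] = x_hat
        rec.P[k] = P
        rec.p_hat[k] = p_hat
        rec.Pp_diag[k] = np.diagonal(P_p, axis1=-2, axis2=-1)
        rec.K_p[k] = K_p
        rec.e_hat[k] = e_hat
        rec.R_p[k] = R_p
        rec.Hp[k] = Hp
        if store_Pp:
            Pp_full[k] = P_p
    rec.Pp_final = P_p
    if store_Pp:
        rec.Pp_history = Pp_full
    return rec
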