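"""Parameter containers and validation for the pain-perception filters.

The perceiver is modelled as a Kalman filter tracking a scalar latent state
(actual or potential tissue damage) on the 11-point clinical pain scale.
``FilterParams`` holds the perceiver's *internal model*: the believed pain
persistence ``A_hat``, believed cue gains ``B_hat``, the observation map
``H``, sensory-noise variance ``R`` and the heteroscedastic process-noise
constants ``Q0``/``Qu``.  ``WorldParams`` holds the ground-truth dynamics
that generate tissue damage and sensory input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ConfigurationError",
    "DimensionError",
    "SchemaError",
    "FilterParams",
    "WorldParams",
    "StimulusSchedule",
    "single_layer_defaults",
    "hierarchical_defaults",
]


class ConfigurationError(ValueError):
    """A parameter value violates its admissible range."""


class DimensionError(ValueError):
    """Array shapes are not conformable (e.g. control-input length vs B_hat)."""


class SchemaError(ValueError):
    """A delimited-text table is missing required columns."""


@dataclass(frozen=True)
class FilterParams:
    """Internal-model and noise constants of the perception filter.

    Parameters
    ----------
    A_hat
        Believed pain-persistence coefficient.  ``0 < A_hat < 1`` means pain
        is expected to diminish on its own; ``A_hat > 1`` to worsen.
        Negative values are rejected.
    B_hat
        Believed gains of the control inputs (cues, context), length ``m``.
    H
        Observation mapping from state to sensory space (dimensionless 1).
    R
        Sensory-noise variance, in squared pain units.
    Q0, Qu
        Baseline and control-dependent process-noise variance: at each step
        the process noise has variance ``Q = Q0 + ||u||^2 * Qu``.
    P0
        Initial posterior variance.  The default ``1e6`` makes the first
        update essentially ignore the (arbitrary) initial posterior mean.
    """

    A_hat: float = 0.8
    B_hat: tuple = (0.6,)
    H: float = 1.0
    R: float = 0.8**2
    Q0: float = 0.4**2
    Qu: float = 0.4**2
    P0: float = 1.0e6

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.B_hat, dtype=float))
        if b.ndim != 1:
            raise DimensionError("B_hat must be a 1-D sequence of cue gains")
        object.__setattr__(self, "B_hat", tuple(float(v) for v in b))
        if not self.R > 0:
            raise ConfigurationError(f"R must be > 0, got {self.R}")
        if self.Q0 < 0 or self.Qu < 0:
            raise ConfigurationError("Q0 and Qu must be non-negative")
        if not self.P0 > 0:
            raise ConfigurationError(f"P0 must be > 0, got {self.P0}")
        if self.A_hat < 0:
            raise ConfigurationError(f"A_hat must be non-negative, got {self.A_hat}")

    @property
    def m(self) -> int:
        """Control-input dimensionality."""
        return len(self.B_hat)

    @property
    def b_vector(self) -> np.ndarray:
        return np.asarray(self.B_hat, dtype=float)

    def replace(self, **kw) -> "FilterParams":
        from dataclasses import replace

        return replace(self, **kw)


def single_layer_defaults(**overrides) -> FilterParams:
    """Default constants of the single-layer filter."""
    return FilterParams(**overrides)


def hierarchical_defaults(**overrides) -> FilterParams:
    """Default constants when the internal model is itself estimated.

    The hierarchical model accounts for internal-model uncertainty explicitly
    (through the parameter covariance), so the baseline process noise drops
    from 0.4^2 to 0.1^2.
    """
    overrides.setdefault("Q0", 0.1**2)
    return FilterParams(**overrides)


@dataclass(frozen=True)
class WorldParams:
    """Ground-truth tissue-damage dynamics and sensory truncation bounds.

    ``x(k) = A x(k-1) + B u_tilde(k)``, clipped to ``bounds``; sensory input
    is a truncated Gaussian ``z ~ N(H x, R)`` on ``bounds``.
    """

    A: float = 0.9
    B: float = 0.8
    H: float = 1.0
    bounds: tuple = (0.0, 10.0)

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo < hi:
            raise ConfigurationError(f"bounds must satisfy lo < hi, got {self.bounds}")


@dataclass
class StimulusSchedule:
    """Per-step world inputs driving a simulation.

    Attributes
    ----------
    u_tilde
        Tissue-damage drive, shape ``(n_steps,)``.
    u
        Control/cue input, shape ``(n_steps, m)`` shared across replicates or
        ``(n_steps, n_rep, m)`` when it varies per replicate/individual.
    R
        Sensory-noise variance per step, shape ``(n_steps,)``; a step change
        here is how nerve injury is modelled.
    injury_step
        Optional index where ``R`` changes, for annotation only.
    x_override
        Optional explicit true-state series, shape ``(n_steps,)`` or
        ``(n_steps, n_rep)``, bypassing the damage recursion.  Used by
        discrete-trial protocols that pin the sensory-input mean per trial.
    """

    u_tilde: np.ndarray
    u: np.ndarray
    R: np.ndarray
    injury_step: Optional[int] = None
    x_override: Optional[np.ndarray] = None

    def __post_init__(self):
        self.u_tilde = np.asarray(self.u_tilde, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.u_tilde.ndim != 1:
            raise DimensionError("u_tilde must be 1-D")
        n = self.u_tilde.shape[0]
        if self.u.ndim not in (2, 3) or self.u.shape[0] != n:
            raise DimensionError("u must have shape (n_steps, m) or (n_steps, n_rep, m)")
        if self.R.shape != (n,):
            raise DimensionError("R must have shape (n_steps,)")
        if np.any(self.R <= 0):
            raise ConfigurationError("all R entries must be > 0")
        if self.x_override is not None:
            self.x_override = np.asarray(self.x_override, dtype=float)
            if self.x_override.shape[0] != n:
                raise DimensionError("x_override must have n_steps rows")

    @property
    def n_steps(self) -> int:
        return self.u_tilde.shape[0]

    @property
    def m(self) -> int:
        return self.u.shape[-1]


def constant_schedule(
    n_steps: int,
    m: int = 1,
    R: float = 0.8**2,
    u_tilde: float = 0.0,
    u: float = 0.0,
) -> StimulusSchedule:
    """Schedule with constant inputs (convenience constructor)."""
    return StimulusSchedule(
        u_tilde=np.full(n_steps, float(u_tilde)),
        u=np.full((n_steps, m), float(u)),
        R=np.full(n_steps, float(R)),
    )
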