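"""Simulation protocols: placebo/nocebo, conditioning, chronic pain,
neuropathic-pain sweeps, pain-history risk factors and offset analgesia.

Each ``run_*`` function configures a stimulus schedule, draws sensory input
from the truncated-Gaussian world, runs the single-layer or hierarchical
filter over a batch of replicates (or simulated individuals) and aggregates
the trajectories.  Replicate-based protocols report per-step medians with
interquartile ranges; individual-based protocols report per-cell means with
standard errors -- the truncation of sensory input makes the distributions
asymmetric, which is why medians are the default summary.

Reproducibility contract: every scenario is a deterministic function of its
arguments and the seed.  Where a protocol has a relabelling symmetry (the
placebo and nocebo cues differ only in which gain distribution they carry),
random draws are keyed by the *condition* rather than by slot position, so
swapping the labels swaps the outputs exactly.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .param_filter import ParamNoise, run_hierarchical
from .params import (
    ConfigurationError,
    FilterParams,
    StimulusSchedule,
    WorldParams,
    hierarchical_defaults,
    single_layer_defaults,
)
from .rng import condition_stream, split_streams
from .state_filter import run_filter
from .world import generate_observations, sample_sensory, simulate_damage

__all__ = [
    "ScenarioConfig",
    "AggregateResult",
    "aggregate",
    "run_placebo_nocebo_single",
    "run_conditioning_hier",
    "run_chronic_pain",
    "run_uncued_injury",
    "run_neuropathic_single_sweep",
    "run_neuropathic_hier_sweep",
    "run_history_risk",
    "run_offset_analgesia",
    "run_scenario",
    "SCENARIOS",
]

SCALE = (0.0, 10.0)


# ---------------------------------------------------------------------------
# aggregation


def aggregate(trajectories, mode: str = "replicate") -> dict:
    """Summarise values over the last (replicate/individual) axis.

    ``replicate`` mode returns the median and the 25/75% quantiles
    (linear-interpolation convention); ``individual`` mode returns the mean
    and the standard error ``sd / sqrt(n)`` (ddof=1).
    """
    v = np.asarray(trajectories, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("aggregate needs at least 2 trajectories")
    if mode == "replicate":
        q25, med, q75 = np.percentile(v, [25.0, 50.0, 75.0], axis=-1)
        return {"median": med, "q25": q25, "q75": q75}
    if mode == "individual":
        n = v.shape[-1]
        return {"mean": v.mean(axis=-1), "se": v.std(axis=-1, ddof=1) / np.sqrt(n)}
    raise ValueError(f"unknown aggregation mode {mode!r}")


@dataclass
class AggregateResult:
    """Scenario output: long trajectory table, per-cell summary table, and a
    grab-bag of scenario-specific summary numbers."""

    name: str
    trajectories: Optional[pd.DataFrame] = None
    cells: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


def _truncated_draws(rng, mu, sd, shape, low=0.0, high=np.inf, max_rounds=1000):
    """Initial-parameter draws from N(mu, sd^2) truncated by resampling."""
    if sd == 0:
        return np.full(shape, float(mu))
    out = rng.normal(mu, sd, size=shape)
    for _ in range(max_rounds):
        bad = (out < low) | (out > high)
        if not bad.any():
            return out
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
    bad = (out < low) | (out > high)
    if bad.any():
        a, b = (low - mu) / sd, (high - mu) / sd
        out[bad] = stats.truncnorm(a, b, loc=mu, scale=sd).ppf(
            rng.uniform(size=int(bad.sum()))
        )
    return out


def _clip(a):
    return np.clip(a, *SCALE)


def _cell_stats(values):
    """Mean and SE across the last axis (individuals)."""
    v = np.asarray(values, dtype=float)
    return v.mean(axis=-1), v.std(axis=-1, ddof=1) / np.sqrt(v.shape[-1])


# ---------------------------------------------------------------------------
# placebo / nocebo with the single-layer filter (discrete test trials)


def run_placebo_nocebo_single(
    seed: int = 0,
    n_individuals: int = 28,
    n_repetitions: int = 1,
    n_trials_per_cell: int = 10,
    u_mag: float = 3.7,
    b_laws: Optional[dict] = None,
    x_levels: Optional[dict] = None,
    R: float = 0.8**2,
    Q0: float = 0.4**2,
    Qu: float = 0.4**2,
    sample_process_noise: bool = True,
) -> AggregateResult:
    """Cue-induced expectation effects on identical noxious stimuli.

    Test trials are discrete events (persistence ``A_hat = 0``); the two
    cues are orthogonal control inputs of identical magnitude ``u_mag`` whose
    gains differ per individual: ``b_cue ~ N(mu, sd^2)`` truncated at 0.
    Expected pain is the prior ``b_cue * u_mag`` and perceived pain fuses it
    with sensory input from the true stimulus level (which depends on the
    temperature only, never on the cue).
    """
    if b_laws is None:
        b_laws = {"placebo": (0.7, 0.5), "nocebo": (1.3, 0.5)}
    if x_levels is None:
        x_levels = {"low": 3.1, "high": 4.3}
    Q = Q0 + u_mag**2 * Qu
    Pbar = Q  # A_hat = 0 and fresh trials: prior variance is the process noise
    K = Pbar / (Pbar + R)

    shape = (n_repetitions, n_individuals)
    rows = []
    per_rep: dict = {}
    for cue, (mu, sd) in b_laws.items():
        b = _truncated_draws(condition_stream(seed, "b", mu, sd), mu, sd, shape, low=0.0)
        for temp, x in x_levels.items():
            g_z = condition_stream(seed, "z", mu, sd, float(x))
            z = sample_sensory(
                x, 1.0, R, g_z, bounds=SCALE,
                size=(n_repetitions, n_individuals, n_trials_per_cell),
            )
            if sample_process_noise:
                g_e = condition_stream(seed, "eps", mu, sd, float(x))
                eps = np.sqrt(Q) * g_e.standard_normal(z.shape)
            else:
                eps = np.zeros_like(z)
            xbar = b[..., None] * u_mag + eps
            xhat = xbar + K * (z - xbar)
            exp_ind = xbar.mean(axis=-1)  # per-individual cell mean, (rep, ind)
            per_ind = xhat.mean(axis=-1)
            e_mean, e_se = _cell_stats(exp_ind)
            p_mean, p_se = _cell_stats(per_ind)
            per_rep[(cue, temp)] = {
                "expected_mean": e_mean,
                "perceived_mean": p_mean,
            }
            rows.append(
                {
                    "cue": cue,
                    "temperature": temp,
                    "expected_mean": float(e_mean.mean()),
                    "expected_se": float(e_se.mean()),
                    "perceived_mean": float(p_mean.mean()),
                    "perceived_se": float(p_se.mean()),
                }
            )
    cells = pd.DataFrame(rows)
    extras = {
        "per_repetition": per_rep,
        "K": float(K),
        "prior_mean": {cue: mu * u_mag for cue, (mu, _) in b_laws.items()},
    }
    return AggregateResult(name="placebo_nocebo_single", cells=cells, extras=extras)


# ---------------------------------------------------------------------------
# classical conditioning with the hierarchical filter


def run_conditioning_hier(
    seed: int = 0,
    n_individuals: int = 28,
    n_repetitions: int = 1,
    n_conditioning: int = 120,
    n_test_per_cell: int = 10,
    u_mag: float = 3.7,
    z_low: float = 2.2,
    z_high: float = 5.2,
    b0_mean: float = 0.9,
    b0_sd: float = 0.8,
    x_levels: Optional[dict] = None,
    R: float = 0.8**2,
    q_p: float = 0.002**2,
    p_p0: float = 1.0,
    P_init: float = 1.0,
    sample_process_noise: bool = True,
    sample_param_noise: bool = True,
    freeze_params: bool = False,
) -> AggregateResult:
    """Cue gains acquired by pairing cues with low/high sensory input.

    120 conditioning trials pair the placebo cue with sensory input centred
    at ``z_low`` and the nocebo cue with ``z_high``; both cue gains start
    from the same law ``N(b0_mean, b0_sd^2)`` truncated at 0, so any later
    separation is produced by the parameter filter.  A 40-trial test phase
    (balanced cue x temperature factorial) follows, with stimuli at the
    placebo/nocebo protocol levels.  ``freeze_params`` zeroes the parameter
    noise and initial parameter covariance, pinning the gains (control).

    Initial uncertainties default to the settled-perceiver convention
    (``P = 1``, ``P_p = I``): simulated individuals arrive with a lifetime
    of calibrated perception and only the cue-gain *values* are fresh
    draws.  An uninformative parameter covariance would instead saturate
    the state gain through the parameter-uncertainty term in the prior
    variance, destroying the very observability (``H_p = (1-K)[x, u]``)
    that conditioning relies on.
    """
    if x_levels is None:
        x_levels = {"low": 3.1, "high": 4.3}
    B = n_repetitions * n_individuals
    streams = split_streams(seed)
    b0 = _truncated_draws(streams.individual, b0_mean, b0_sd, (B, 2), low=0.0)
    p0 = np.concatenate([np.zeros((B, 1)), b0], axis=1)  # discrete trials: A0 = 0

    half = n_conditioning // 2
    base = np.array([0] * half + [1] * (n_conditioning - half))
    cond_cue = np.empty((n_conditioning, B), dtype=int)
    for i in range(B):
        cond_cue[:, i] = streams.individual.permutation(base)

    temps = sorted(x_levels)
    test_cells = [(c, t) for c in (0, 1) for t in temps]
    test_plan = np.array([ci for ci, _ in enumerate(test_cells) for _ in range(n_test_per_cell)])
    n_test = test_plan.size
    test_idx = np.empty((n_test, B), dtype=int)
    for i in range(B):
        test_idx[:, i] = streams.individual.permutation(test_plan)

    n = n_conditioning + n_test
    u = np.zeros((n, B, 2))
    x_override = np.empty((n, B))
    cond_levels = np.array([z_low, z_high])
    for k in range(n_conditioning):
        u[k, np.arange(B), cond_cue[k]] = u_mag
        x_override[k] = cond_levels[cond_cue[k]]
    cell_cue = np.array([c for c, _ in test_cells])
    cell_x = np.array([x_levels[t] for _, t in test_cells])
    for j in range(n_test):
        k = n_conditioning + j
        cues = cell_cue[test_idx[j]]
        u[k, np.arange(B), cues] = u_mag
        x_override[k] = cell_x[test_idx[j]]

    schedule = StimulusSchedule(
        u_tilde=np.zeros(n), u=u, R=np.full(n, R), x_override=x_override
    )
    params = hierarchical_defaults(R=R, B_hat=(0.6, 0.6))
    if freeze_params:
        noise = ParamNoise(Q_p=np.zeros((3, 3)), P_p0=np.zeros((3, 3)))
    else:
        noise = ParamNoise.defaults(m=2, q=q_p, p0=p_p0)
    world = WorldParams(A=0.0, B=0.0)
    x, z = generate_observations(schedule, world, streams.sensory, B)
    rec = run_hierarchical(
        params, noise, schedule, z, streams.process, streams.param,
        sample_process_noise=sample_process_noise,
        sample_param_noise=sample_param_noise,
        p0=p0, P_init=P_init,
    )

    # gain trajectories over conditioning (median/IQR across individuals,
    # first repetition shown; per-repetition terminal stats kept in extras)
    b_traj = np.concatenate(
        [b0[None], rec.p_hat[: n_conditioning - 1, :, 1:]], axis=0
    ).reshape(n_conditioning, n_repetitions, n_individuals, 2)
    agg_p = aggregate(b_traj[:, 0, :, 0])
    agg_n = aggregate(b_traj[:, 0, :, 1])
    traj = pd.DataFrame(
        {
            "trial": np.arange(1, n_conditioning + 1),
            "b_placebo_median": agg_p["median"],
            "b_placebo_q25": agg_p["q25"],
            "b_placebo_q75": agg_p["q75"],
            "b_nocebo_median": agg_n["median"],
            "b_nocebo_q25": agg_n["q25"],
            "b_nocebo_q75": agg_n["q75"],
            "expected_placebo_median": agg_p["median"] * u_mag,
            "expected_nocebo_median": agg_n["median"] * u_mag,
        }
    )

    # gains produced by the full conditioning phase (after the last update)
    terminal = rec.p_hat[n_conditioning - 1, :, 1:].reshape(
        n_repetitions, n_individuals, 2
    )
    term_p = np.median(terminal[..., 0], axis=-1)
    term_n = np.median(terminal[..., 1], axis=-1)

    xbar = rec.xbar_hat[n_conditioning:].reshape(n_test, n_repetitions, n_individuals)
    xhat = rec.x_hat[n_conditioning:].reshape(n_test, n_repetitions, n_individuals)
    rows = []
    per_rep: dict = {}
    cue_names = {0: "placebo", 1: "nocebo"}
    for ci, (c, t) in enumerate(test_cells):
        mask = test_idx.reshape(n_test, n_repetitions, n_individuals) == ci
        n_in_cell = mask.sum(axis=0)  # == n_test_per_cell everywhere
        exp_ind = (xbar * mask).sum(axis=0) / n_in_cell
        per_ind = (xhat * mask).sum(axis=0) / n_in_cell
        e_mean, e_se = _cell_stats(exp_ind)
        p_mean, p_se = _cell_stats(per_ind)
        per_rep[(cue_names[c], t)] = {"expected_mean": e_mean, "perceived_mean": p_mean}
        rows.append(
            {
                "cue": cue_names[c],
                "temperature": t,
                "expected_mean": float(e_mean.mean()),
                "expected_se": float(e_se.mean()),
                "perceived_mean": float(p_mean.mean()),
                "perceived_se": float(p_se.mean()),
            }
        )
    extras = {
        "terminal_b_placebo_median": term_p,
        "terminal_b_nocebo_median": term_n,
        "separated": term_n > term_p,
        "per_repetition": per_rep,
    }
    return AggregateResult(
        name="conditioning_hier", trajectories=traj, cells=pd.DataFrame(rows), extras=extras
    )


# ---------------------------------------------------------------------------
# chronic pain (single layer, impulse damage, two sensory-noise levels)


def run_chronic_pain(
    seed: int = 0,
    n_replicates: int = 100,
    R_values: tuple = (0.8**2, 1.8**2),
    n_steps: int = 100,
    impulse_step: int = 20,
    impulse: float = 3.7,
    world_A: float = 0.9,
    world_B: float = 0.8,
    A_hat: float = 1.0,
    cued: bool = True,
    sample_process_noise: bool = True,
    recovery_threshold: float = 0.1,
) -> AggregateResult:
    """Pain outliving tissue damage when the internal model expects
    persistence (``A_hat = 1``) and sensory input is ambiguous.

    The world recovers geometrically (``A = 0.9``) after a single cued
    damage impulse; the filter is run for each sensory-noise level in
    ``R_values``.  ``cued=False`` removes the predictive control input (the
    unexpected-injury variant).
    """
    u_tilde = np.zeros(n_steps)
    u_tilde[impulse_step] = impulse
    u = np.zeros((n_steps, 1))
    if cued:
        u[impulse_step, 0] = impulse
    world = WorldParams(A=world_A, B=world_B)

    frames = []
    post_medians = {}
    for R in R_values:
        label = f"R={R:g}"
        params = single_layer_defaults(A_hat=A_hat, R=R)
        schedule = StimulusSchedule(u_tilde=u_tilde, u=u, R=np.full(n_steps, R))
        streams = split_streams(seed)
        x, z = generate_observations(schedule, world, streams.sensory, n_replicates)
        rec = run_filter(
            params, schedule, z, streams.process,
            sample_process_noise=sample_process_noise, x_true=x,
        )
        pain = aggregate(rec.clipped())
        expected = aggregate(_clip(rec.xbar_hat))
        frames.append(
            pd.DataFrame(
                {
                    "condition": label,
                    "step": np.arange(n_steps),
                    "x_true": x,
                    "pain_median": pain["median"],
                    "pain_q25": pain["q25"],
                    "pain_q75": pain["q75"],
                    "expected_median": expected["median"],
                }
            )
        )
        window = (x < recovery_threshold) & (np.arange(n_steps) > impulse_step)
        post_medians[label] = (
            float(np.median(rec.clipped()[window])) if window.any() else float("nan")
        )
    return AggregateResult(
        name="chronic_pain",
        trajectories=pd.concat(frames, ignore_index=True),
        extras={"post_recovery_median": post_medians},
    )


def run_uncued_injury(
    seed: int = 0,
    n_replicates: int = 100,
    R: float = 0.8**2,
    n_steps: int = 100,
    impulse_step: int = 20,
    impulse: float = 3.7,
    world_A: float = 0.9,
    world_B: float = 0.8,
    A_hat: float = 1.0,
    sample_process_noise: bool = True,
) -> AggregateResult:
    """Damage without a predictive cue: pain rises only once sensory input
    reports the injury, so the prior lags the stimulus."""
    res = run_chronic_pain(
        seed=seed,
        n_replicates=n_replicates,
        R_values=(R,),
        n_steps=n_steps,
        impulse_step=impulse_step,
        impulse=impulse,
        world_A=world_A,
        world_B=world_B,
        A_hat=A_hat,
        cued=False,
        sample_process_noise=sample_process_noise,
    )
    res.name = "uncued_injury"
    return res


# ---------------------------------------------------------------------------
# neuropathic pain: sensory-disruption sweeps


def run_neuropathic_single_sweep(
    seed: int = 0,
    n_replicates: int = 100,
    A_hat_values: tuple = (0.9, 1.0, 1.1),
    R_values: tuple = (0.8**2, 80.0**2, 800.0**2),
    baseline_steps: int = 200,
    post_steps: int = 300,
    baseline_R: float = 0.8**2,
    sample_process_noise: bool = True,
) -> AggregateResult:
    """Fixed-parameter filter under a step increase of sensory noise.

    No tissue damage at any time (``x = 0``); each cell runs a baseline
    period at the default ``R`` (so the posterior variance settles) followed
    by the disrupted period at the cell's ``R``.  With ``A_hat > 1`` and
    large ``R`` the prior dominates and pain escalates spontaneously.
    """
    n = baseline_steps + post_steps
    world = WorldParams(A=0.0, B=0.0)
    frames = []
    post_medians = {}
    for A_hat in A_hat_values:
        for R in R_values:
            label = f"A_hat={A_hat:g},R={R:g}"
            params = single_layer_defaults(A_hat=A_hat)
            R_sched = np.full(n, baseline_R)
            R_sched[baseline_steps:] = R
            schedule = StimulusSchedule(
                u_tilde=np.zeros(n), u=np.zeros((n, 1)), R=R_sched,
                injury_step=baseline_steps,
            )
            streams = split_streams(seed)
            x, z = generate_observations(schedule, world, streams.sensory, n_replicates)
            rec = run_filter(
                params, schedule, z, streams.process,
                sample_process_noise=sample_process_noise, x_true=x,
            )
            pain = aggregate(rec.clipped())
            frames.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "A_hat": A_hat,
                        "R": R,
                        "step": np.arange(n),
                        "pain_median": pain["median"],
                        "pain_q25": pain["q25"],
                        "pain_q75": pain["q75"],
                    }
                )
            )
            post_medians[label] = float(np.median(rec.clipped()[baseline_steps:]))
    return AggregateResult(
        name="neuropathic_single_sweep",
        trajectories=pd.concat(frames, ignore_index=True),
        extras={"post_injury_median": post_medians},
    )


def run_neuropathic_hier_sweep(
    seed: int = 0,
    n_replicates: int = 100,
    A0_values: tuple = (0.9, 1.0, 1.1),
    R_values: tuple = (0.8**2, 8.0**2, 80.0**2, 800.0**2),
    n_steps: int = 1000,
    B0: float = 0.6,
    P_init: float = 1.0,
    Pp_init_scale: float = 1.0,
    q_p: float = 0.002**2,
    sample_process_noise: bool = True,
    sample_param_noise: bool = True,
) -> AggregateResult:
    """Adaptive persistence after nerve injury.

    The run starts *at* the injury with settled uncertainties (``P = 1``,
    ``P_p = I`` by convention -- a baseline period cannot be used because it
    would itself move ``A_hat``).  With intermediate sensory noise the
    prediction errors drag ``A_hat`` toward 1 whatever its initial value;
    with extreme noise ``A_hat`` reduces to a random walk around its initial
    value with the internal-model noise variance.
    """
    world = WorldParams(A=0.0, B=0.0)
    noise = ParamNoise(Q_p=q_p * np.eye(2), P_p0=Pp_init_scale * np.eye(2))
    frames = []
    extras: dict = {"terminal_A_median": {}, "post_injury_pain_median": {}}
    for A0 in A0_values:
        for R in R_values:
            label = f"A0={A0:g},R={R:g}"
            params = hierarchical_defaults(R=R)
            schedule = StimulusSchedule(
                u_tilde=np.zeros(n_steps), u=np.zeros((n_steps, 1)),
                R=np.full(n_steps, R), injury_step=0,
            )
            streams = split_streams(seed)
            x, z = generate_observations(schedule, world, streams.sensory, n_replicates)
            rec = run_hierarchical(
                params, noise, schedule, z, streams.process, streams.param,
                sample_process_noise=sample_process_noise,
                sample_param_noise=sample_param_noise,
                x0=0.0, P_init=P_init, p0=np.array([A0, B0]), x_true=x,
            )
            pain = aggregate(rec.clipped())
            A_traj = aggregate(rec.p_hat[:, :, 0])
            frames.append(
                pd.DataFrame(
                    {
                        "condition": label,
                        "A0": A0,
                        "R": R,
                        "step": np.arange(n_steps),
                        "pain_median": pain["median"],
                        "pain_q25": pain["q25"],
                        "pain_q75": pain["q75"],
                        "A_median": A_traj["median"],
                        "A_q25": A_traj["q25"],
                        "A_q75": A_traj["q75"],
                    }
                )
            )
            extras["terminal_A_median"][label] = float(np.median(rec.p_hat[-1, :, 0]))
            extras["post_injury_pain_median"][label] = float(np.median(rec.clipped()))
    return AggregateResult(
        name="neuropathic_hier_sweep",
        trajectories=pd.concat(frames, ignore_index=True),
        extras=extras,
    )


# ---------------------------------------------------------------------------
# pain history as a risk factor for neuropathic pain


def run_history_risk(
    seed: int = 0,
    n_replicates: int = 100,
    histories: tuple = ((0.99, True), (0.90, True), (0.90, False)),
    baseline_steps: int = 3000,
    post_steps: int = 1000,
    impulse_every: int = 50,
    impulse: float = 3.7,
    world_B: float = 0.8,
    baseline_R: float = 0.8**2,
    injury_R: float = 800.0**2,
    window_frac: float = 0.25,
    q_p: float = 0.002**2,
    p_p0: float = 1.0,
    P_init: float = 1.0,
    sample_process_noise: bool = True,
    sample_param_noise: bool = True,
) -> AggregateResult:
    """How the dynamics of past pain shape the risk of neuropathic pain.

    Each history runs a long pre-injury period with the default parameters:
    the world recovers at rate ``A`` and (for stimulated histories) receives
    cued damage impulses every ``impulse_every`` steps, so the hierarchical
    filter learns a persistence estimate from the experienced decay
    episodes.  Nerve injury is a step of ``R`` to ``injury_R``; the summary
    statistic is the median perceived pain over the last ``window_frac`` of
    the post-injury period.
    """
    n = baseline_steps + post_steps
    frames = []
    extras: dict = {"terminal_A_median": {}, "post_injury_pain_median": {}}
    for A, stimulated in histories:
        label = f"A={A:g},{'stimuli' if stimulated else 'no_stimuli'}"
        u_tilde = np.zeros(n)
        u = np.zeros((n, 1))
        if stimulated:
            ks = np.arange(impulse_every, baseline_steps, impulse_every)
            u_tilde[ks] = impulse
            u[ks, 0] = impulse
        R_sched = np.full(n, baseline_R)
        R_sched[baseline_steps:] = injury_R
        schedule = StimulusSchedule(
            u_tilde=u_tilde, u=u, R=R_sched, injury_step=baseline_steps
        )
        world = WorldParams(A=A, B=world_B)
        params = hierarchical_defaults()
        noise = ParamNoise.defaults(m=1, q=q_p, p0=p_p0)
        streams = split_streams(seed)
        x, z = generate_observations(schedule, world, streams.sensory, n_replicates)
        rec = run_hierarchical(
            params, noise, schedule, z, streams.process, streams.param,
            sample_process_noise=sample_process_noise,
            sample_param_noise=sample_param_noise, P_init=P_init, x_true=x,
        )
        pain = aggregate(rec.clipped())
        A_traj = aggregate(rec.p_hat[:, :, 0])
        frames.append(
            pd.DataFrame(
                {
                    "condition": label,
                    "step": np.arange(n),
                    "x_true": x,
                    "pain_median": pain["median"],
                    "pain_q25": pain["q25"],
                    "pain_q75": pain["q75"],
                    "A_median": A_traj["median"],
                    "A_q25": A_traj["q25"],
                    "A_q75": A_traj["q75"],
                }
            )
        )
        extras["terminal_A_median"][label] = float(
            np.median(rec.p_hat[baseline_steps - 1, :, 0])
        )
        w0 = n - int(round(window_frac * post_steps))
        extras["post_injury_pain_median"][label] = float(np.median(rec.clipped()[w0:]))
    return AggregateResult(
        name="history_risk",
        trajectories=pd.concat(frames, ignore_index=True),
        extras=extras,
    )


# ---------------------------------------------------------------------------
# offset analgesia


def run_offset_analgesia(
    seed: int = 0,
    n_replicates: int = 100,
    n_repetitions: int = 1,
    t1: int = 49,
    t2: int = 49,
    t3_blocks: tuple = (25, 25, 25, 25),
    delta: int = 5,
    level_low: float = 3.1,
    level_high: float = 4.3,
    world_B: float = 0.8,
    R: float = 0.8**2,
    P_init: float = 1.0,
    Pp_init_scale: float = 1.0,
    q_p: float = 0.002**2,
    sample_process_noise: bool = True,
    sample_param_noise: bool = True,
) -> AggregateResult:
    """Disproportionate pain drop after a small stimulus-intensity decrease.

    Tissue damage is taken as linearly proportionate to the applied
    temperature, i.e. a step function through the T1 (low) / T2 (high) /
    T3 (low) intervals; there are no predictive cues (``u = 0``) and the
    internal model starts matched to the world (persistence 1 between
    temperature changes).  Perceived pain is summarised as the median of
    ``x_hat`` within each interval, omitting the first ``delta`` steps after
    every temperature ramp.  The control condition holds the low temperature
    throughout.
    """
    lengths = [t1, t2] + list(t3_blocks)
    names = ["T1", "T2"] + [f"T3_{j+1}" for j in range(len(t3_blocks))]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    n = int(bounds[-1])
    x_offset = np.concatenate(
        [np.full(t1, level_low), np.full(t2, level_high), np.full(sum(t3_blocks), level_low)]
    )
    x_control = np.full(n, level_low)
    # omit the delta steps after each ramp: onset, T1->T2 and T2->T3
    keep = {name: np.arange(bounds[i], bounds[i + 1]) for i, name in enumerate(names)}
    for name in ("T1", "T2", "T3_1"):
        keep[name] = keep[name][delta:]

    B = n_repetitions * n_replicates
    p0 = np.array([1.0, world_B])
    noise = ParamNoise(Q_p=q_p * np.eye(2), P_p0=Pp_init_scale * np.eye(2))
    params = hierarchical_defaults(R=R)
    world = WorldParams(A=1.0, B=world_B)

    rows = []
    frames = []
    per_rep: dict = {}
    for label, x_series in (("offset", x_offset), ("control", x_control)):
        schedule = StimulusSchedule(
            u_tilde=np.zeros(n), u=np.zeros((n, 1)), R=np.full(n, R),
            x_override=x_series,
        )
        streams = split_streams(seed)
        x, z = generate_observations(schedule, world, streams.sensory, B)
        rec = run_hierarchical(
            params, noise, schedule, z, streams.process, streams.param,
            sample_process_noise=sample_process_noise,
            sample_param_noise=sample_param_noise,
            x0=0.0, P_init=P_init, p0=p0, x_true=x,
        )
        xhat = rec.clipped().reshape(n, n_repetitions, n_replicates)
        pain = aggregate(xhat[:, 0, :])
        frames.append(
            pd.DataFrame(
                {
                    "condition": label,
                    "step": np.arange(n),
                    "x_true": x,
                    "pain_median": pain["median"],
                    "pain_q25": pain["q25"],
                    "pain_q75": pain["q75"],
                }
            )
        )
        per_rep[label] = {}
        for name in names:
            per_replicate_median = np.median(xhat[keep[name]], axis=0)  # (rep, n_repl)
            interval_median = np.median(per_replicate_median, axis=-1)  # (rep,)
            q25, q75 = np.percentile(per_replicate_median, [25, 75], axis=-1)
            per_rep[label][name] = interval_median
            rows.append(
                {
                    "condition": label,
                    "interval": name,
                    "median": float(interval_median[0]),
                    "q25": float(q25[0]),
                    "q75": float(q75[0]),
                }
            )
    cells = pd.DataFrame(rows)
    undershoot = per_rep["control"]["T3_1"] - per_rep["offset"]["T3_1"]
    return AggregateResult(
        name="offset_analgesia",
        trajectories=pd.concat(frames, ignore_index=True),
        cells=cells,
        extras={"per_repetition": per_rep, "undershoot": undershoot},
    )


# ---------------------------------------------------------------------------
# configuration / dispatch


SCENARIOS: dict[str, Callable] = {
    "placebo_nocebo_single": run_placebo_nocebo_single,
    "conditioning_hier": run_conditioning_hier,
    "chronic_pain": run_chronic_pain,
    "uncued_injury": run_uncued_injury,
    "neuropathic_single_sweep": run_neuropathic_single_sweep,
    "neuropathic_hier_sweep": run_neuropathic_hier_sweep,
    "history_risk": run_history_risk,
    "offset_analgesia": run_offset_analgesia,
}

SCENARIO_MODEL: dict[str, str] = {
    "placebo_nocebo_single": "single",
    "conditioning_hier": "hierarchical",
    "chronic_pain": "single",
    "uncued_injury": "single",
    "neuropathic_single_sweep": "single",
    "neuropathic_hier_sweep": "hierarchical",
    "history_risk": "hierarchical",
    "offset_analgesia": "hierarchical",
}


@dataclass
class ScenarioConfig:
    """Validated scenario request: which protocol, at what size, which seed,
    and any keyword overrides of the protocol's defaults."""

    name: str
    model: Optional[str] = None
    seed: int = 0
    n_replicates: Optional[int] = None
    n_individuals: Optional[int] = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.name!r}; choose from {sorted(SCENARIOS)}"
            )
        expected = SCENARIO_MODEL[self.name]
        if self.model is None:
            self.model = expected
        elif self.model != expected:
            raise ConfigurationError(
                f"scenario {self.name!r} uses the {expected!r} model, not {self.model!r}"
            )
        sig = inspect.signature(SCENARIOS[self.name])
        unknown = set(self.overrides) - set(sig.parameters)
        if unknown:
            raise ConfigurationError(
                f"unknown override(s) {sorted(unknown)} for scenario {self.name!r}"
            )
        for key in ("R", "baseline_R", "injury_R"):
            if key in self.overrides and not self.overrides[key] > 0:
                raise ConfigurationError(f"{key} must be > 0")
        for key in ("q_p", "p_p0", "Q0", "Qu"):
            if key in self.overrides and self.overrides[key] < 0:
                raise ConfigurationError(f"{key} must be non-negative")


def run_scenario(config: ScenarioConfig) -> AggregateResult:
    """Dispatch a validated config to its protocol function."""
    fn = SCENARIOS[config.name]
    sig = inspect.signature(fn)
    kwargs = dict(config.overrides)
    kwargs["seed"] = config.seed
    if config.n_replicates is not None and "n_replicates" in sig.parameters:
        kwargs["n_replicates"] = config.n_replicates
    if config.n_individuals is not None and "n_individuals" in sig.parameters:
        kwargs["n_individuals"] = config.n_individuals
    return fn(**kwargs)
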