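"""Kuramoto dynamics of the V1 sheet and session-level Arnold-tongue runs.

Each trial integrates

    dtheta_i/dt = omega_i + (1/N) * sum_j K_ij sin(theta_j - theta_i)

for one second from random initial phases. Synchrony is the magnitude r of
the Kuramoto order parameter, time-averaged over the second half of the
trial; pairwise phase-locking values (PLVs) over the same window feed the
Hebbian learning rule. Sessions sweep the (zeta, rho) condition grid over
blocks with a fresh stimulus and fresh initial phases per trial.

Numerics: integration is carried out in a frame co-rotating at each trial's
mean intrinsic frequency (an exact change of variables, since the coupling
depends only on phase differences); phases are rotated back afterwards. This
leaves r, PLV and instantaneous frequencies unchanged while letting the
adaptive integrator take much larger steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._rng import DEFAULT_SEED, PHASES, STIMULUS, child_rng
from .afferent_drive import DrivePipeline, FrequencyVector
from .cortical_sheet import CouplingMatrix, OscillatorSheet, build_sheet
from .stimuli import (
    AnnulusParams,
    StimulusCondition,
    build_condition_grid,
    generate_model_patch,
)
from .tongue_metrics import ArnoldTongue


@dataclass(frozen=True)
class TrialConfig:
    """Integration and readout settings for a single one-second trial."""

    duration: float = 1.0  # s, the stimulus monitoring interval
    dt: float = 0.001  # s, output grid
    subsample_points: int = 50  # PLV timepoints within the second half
    rtol: float = 1e-6
    atol: float = 1e-8
    sync_threshold: float = 0.5  # time-mean r defining a "synchronized state"

    def __post_init__(self):
        if self.duration <= 0 or not self.dt < self.duration:
            raise ValueError("require 0 < dt < duration")
        if self.subsample_points < 2:
            raise ValueError("need at least 2 PLV subsample points")


@dataclass
class PhaseTrajectory:
    """Time-resolved phases for one trial: theta has shape (T, N)."""

    times: np.ndarray
    theta: np.ndarray
    omega: np.ndarray


@dataclass
class SynchronySummary:
    r_mean: float
    psi: float
    per_block: np.ndarray | None = None


@dataclass
class RateReadouts:
    """Firing-rate proxies: figure mean rate vs feedforward background rate."""

    figure_rate: float
    background_rate_proxy: float
    rate_difference: float


@dataclass
class SessionResult:
    """Per-condition synchrony tongue plus trial-level records of a session."""

    tongue: ArnoldTongue
    records: pd.DataFrame  # session, block, zeta_level, rho_level, r_mean
    plv_trials: list | None = None  # (r_mean, PLV) pairs when collected
    q_weighted_sum: np.ndarray | None = None  # streaming Hebbian accumulators
    q_weight_total: float = 0.0


def _validate_K(K, N: int) -> np.ndarray:
    K = K.K if isinstance(K, CouplingMatrix) else np.asarray(K, dtype=float)
    if K.shape != (N, N):
        raise ValueError("coupling matrix shape does not match oscillator count")
    if not np.all(np.isfinite(K)):
        raise ValueError("coupling matrix contains non-finite entries")
    return K


def _integrate(theta0: np.ndarray, omega: np.ndarray, K: np.ndarray, config: TrialConfig):
    """Batched integration; theta0 and omega have shape (B, N)."""
    B, N = theta0.shape
    omega_bar = omega.mean(axis=1, keepdims=True)  # co-rotating frame per trial
    delta = omega - omega_bar
    t_eval = np.arange(0.0, config.duration + config.dt / 2.0, config.dt)

    def rhs(_t, y):
        phi = y.reshape(B, N)
        s, c = np.sin(phi), np.cos(phi)
        coupling = (c * (s @ K) - s * (c @ K)) / N  # K symmetric
        return (delta + coupling).ravel()

    sol = solve_ivp(
        rhs,
        (0.0, config.duration),
        theta0.ravel(),
        method="RK45",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failure: {sol.message}")
    phi = sol.y.T.reshape(len(t_eval), B, N)
    theta = phi + omega_bar[None, :, :] * t_eval[:, None, None]
    return t_eval, theta


def simulate_trial(
    omega: FrequencyVector | np.ndarray,
    K: CouplingMatrix | np.ndarray,
    config: TrialConfig | None = None,
    rng=None,
    theta0: np.ndarray | None = None,
) -> PhaseTrajectory:
    """Integrate one trial from uniform random initial phases."""
    config = config or TrialConfig()
    w = np.asarray(getattr(omega, "omega", omega), dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("omega contains non-finite entries")
    N = w.size
    Km = _validate_K(K, N)
    if theta0 is None:
        rng = np.random.default_rng(rng)
        theta0 = rng.uniform(0.0, 2.0 * np.pi, size=N)
    times, theta = _integrate(theta0[None, :], w[None, :], Km, config)
    return PhaseTrajectory(times=times, theta=theta[:, 0, :], omega=w)


def simulate_trials(
    omegas: np.ndarray,
    K: CouplingMatrix | np.ndarray,
    config: TrialConfig | None = None,
    theta0: np.ndarray | None = None,
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of trials sharing one coupling matrix.

    ``omegas`` has shape (B, N). Returns (times, theta) with theta of shape
    (T, B, N). Batching trials into one adaptive solve amortizes step-size
    control across a block's conditions.
    """
    config = config or TrialConfig()
    omegas = np.atleast_2d(np.asarray(omegas, dtype=float))
    if not np.all(np.isfinite(omegas)):
        raise ValueError("omegas contain non-finite entries")
    B, N = omegas.shape
    Km = _validate_K(K, N)
    if theta0 is None:
        rng = np.random.default_rng(rng)
        theta0 = rng.uniform(0.0, 2.0 * np.pi, size=(B, N))
    return _integrate(theta0, omegas, Km, config)


def order_parameter(phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kuramoto order parameter r e^{i psi} = mean_j e^{i theta_j}.

    Accepts a single phase vector or an array whose last axis indexes
    oscillators; returns (r, psi) with r in [0, 1] and psi in (-pi, pi].
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase vector")
    z = np.exp(1j * phases).mean(axis=-1)
    r, psi = np.abs(z), np.angle(z)
    if phases.ndim == 1:
        return float(r), float(psi)
    return r, psi


def _second_half(times: np.ndarray, duration: float) -> np.ndarray:
    return times > duration / 2.0


def trial_synchrony(traj: PhaseTrajectory, config: TrialConfig | None = None) -> SynchronySummary:
    """Time-average of r over the second half of the trial."""
    config = config or TrialConfig()
    mask = _second_half(traj.times, config.duration)
    r, psi = order_parameter(traj.theta[mask])
    return SynchronySummary(r_mean=float(r.mean()), psi=float(psi[-1]))


def pairwise_plv(traj: PhaseTrajectory, config: TrialConfig | None = None) -> np.ndarray:
    """Pairwise phase-locking values over the subsampled second half.

    PLV_ij = | mean_t exp(i (theta_i(t) - theta_j(t))) | over the second half
    of the trial subsampled to ``config.subsample_points`` timepoints.
    Symmetric with unit diagonal, entries in [0, 1].
    """
    config = config or TrialConfig()
    idx = np.where(_second_half(traj.times, config.duration))[0]
    sub = idx[np.linspace(0, len(idx) - 1, config.subsample_points).round().astype(int)]
    return _plv_from_phases(traj.theta[sub])


def _plv_from_phases(theta_sub: np.ndarray) -> np.ndarray:
    """PLV matrix from subsampled phases of shape (T_sub, N)."""
    Z = np.exp(1j * theta_sub)
    M = (Z.T.conj() @ Z) / theta_sub.shape[0]
    plv = np.abs(M.T)
    np.fill_diagonal(plv, 1.0)
    return np.minimum(plv, 1.0)


def instantaneous_frequency(traj: PhaseTrajectory) -> np.ndarray:
    """Finite-difference instantaneous frequency (Hz), shape (T-1, N).

    The instantaneous frequency dtheta/dt / 2pi serves as a proxy for the
    instantaneous population firing rate of each assembly.
    """
    dtheta = np.diff(traj.theta, axis=0)
    dt = np.diff(traj.times)[:, None]
    return dtheta / dt / (2.0 * np.pi)


def rate_readouts(
    traj: PhaseTrajectory, background_frequencies: FrequencyVector | np.ndarray
) -> RateReadouts:
    """Mean figure firing-rate proxy vs the feedforward background rate.

    The figure rate is the time- and population-mean instantaneous frequency;
    because the coupling term is antisymmetric under exchange of i and j, the
    population mean stays pinned to mean(nu) and is insensitive to coupling.
    The background proxy is the mean feedforward frequency of a maximum-
    heterogeneity (zeta = 1) patch, which the model does not simulate
    dynamically.
    """
    bg = np.asarray(getattr(background_frequencies, "nu", background_frequencies))
    fig_rate = float(instantaneous_frequency(traj).mean())
    bg_rate = float(bg.mean())
    return RateReadouts(
        figure_rate=fig_rate,
        background_rate_proxy=bg_rate,
        rate_difference=fig_rate - bg_rate,
    )


class SessionSimulator:
    """Runs sessions of the model over a condition grid with fresh stimuli.

    Holds the oscillator sheet, the cached afferent-drive pipeline, and the
    workflow seed. Every trial gets its own named random streams for the
    stimulus draw and the initial phases, keyed by (session, block,
    condition), so runs are reproducible and order-independent.
    """

    def __init__(
        self,
        sheet: OscillatorSheet | None = None,
        conditions: list[StimulusCondition] | None = None,
        trial_config: TrialConfig | None = None,
        annulus: AnnulusParams | None = None,
        seed: int = DEFAULT_SEED,
        deg_per_pixel: float = 1.0 / 20.0,
        drive_mode: str = "elements",
    ):
        self.sheet = sheet or build_sheet()
        self.conditions = conditions or build_condition_grid()
        self.trial_config = trial_config or TrialConfig()
        self.annulus = annulus or AnnulusParams()
        self.seed = seed
        self.deg_per_pixel = deg_per_pixel
        template = generate_model_patch(
            self.conditions[0], child_rng(seed, STIMULUS, 0, 0, 0),
            annulus=self.annulus, deg_per_pixel=deg_per_pixel,
        )
        self.drive = DrivePipeline(self.sheet, template, mode=drive_mode)

    def trial_frequencies(self, condition, session: int, block: int, cond_idx: int):
        rng = child_rng(self.seed, STIMULUS, session, block, cond_idx)
        patch = generate_model_patch(
            condition, rng, annulus=self.annulus, deg_per_pixel=self.deg_per_pixel,
            render=self.drive.mode == "pixels",
        )
        return self.drive.frequencies(patch)

    def initial_phases(self, session: int, block: int, cond_idx: int) -> np.ndarray:
        rng = child_rng(self.seed, PHASES, session, block, cond_idx)
        return rng.uniform(0.0, 2.0 * np.pi, size=self.sheet.N)

    def run_session(
        self,
        K: CouplingMatrix | np.ndarray,
        session: int = 1,
        blocks: int = 30,
        collect_plv: bool = False,
        plv_weight_fn=None,
    ) -> SessionResult:
        """Simulate ``blocks`` blocks, one trial per condition per block.

        Per-condition synchrony is averaged over blocks into an Arnold
        tongue. With ``collect_plv`` the (r_mean, PLV) pair of every trial is
        retained; with ``plv_weight_fn`` (a map r -> weight) the Hebbian
        experience accumulators are streamed instead, avoiding the PLV stack.
        """
        conds = self.conditions
        N = self.sheet.N
        Km = _validate_K(K, N)
        cfg = self.trial_config
        mask = None
        rows = []
        plv_trials = [] if collect_plv else None
        q_sum = np.zeros((N, N)) if plv_weight_fn is not None else None
        q_wtot = 0.0
        n_z = max(c.zeta_level for c in conds) + 1
        n_r = max(c.rho_level for c in conds) + 1
        acc = np.zeros((n_z, n_r))
        cnt = np.zeros((n_z, n_r))

        for block in range(1, blocks + 1):
            omegas = np.stack(
                [self.trial_frequencies(c, session, block, ci).omega for ci, c in enumerate(conds)]
            )
            theta0 = np.stack(
                [self.initial_phases(session, block, ci) for ci in range(len(conds))]
            )
            times, theta = simulate_trials(omegas, Km, cfg, theta0=theta0)
            if mask is None:
                mask = _second_half(times, cfg.duration)
                idx = np.where(mask)[0]
                sub = idx[
                    np.linspace(0, len(idx) - 1, cfg.subsample_points).round().astype(int)
                ]
            r_t, _ = order_parameter(theta[mask])  # (T_half, B)
            r_means = r_t.mean(axis=0)
            for ci, c in enumerate(conds):
                r_mean = float(r_means[ci])
                rows.append(
                    dict(
                        session=session, block=block,
                        zeta_level=c.zeta_level, rho_level=c.rho_level,
                        zeta=c.zeta, rho=c.rho, r_mean=r_mean,
                    )
                )
                acc[c.zeta_level, c.rho_level] += r_mean
                cnt[c.zeta_level, c.rho_level] += 1
                if collect_plv or plv_weight_fn is not None:
                    plv = _plv_from_phases(theta[sub, ci, :])
                    if collect_plv:
                        plv_trials.append((r_mean, plv.astype(np.float32)))
                    if plv_weight_fn is not None:
                        w = float(plv_weight_fn(r_mean))
                        q_sum += w * plv
                        q_wtot += w

        zeta_axis = np.array(sorted({c.zeta for c in conds}))
        rho_axis = np.array(sorted({c.rho for c in conds}))
        tongue = ArnoldTongue(
            values=acc / np.maximum(cnt, 1), zeta_axis=zeta_axis, rho_axis=rho_axis,
            kind="synchrony",
        )
        return SessionResult(
            tongue=tongue,
            records=pd.DataFrame(rows),
            plv_trials=plv_trials,
            q_weighted_sum=q_sum,
            q_weight_total=q_wtot,
        )
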