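"""Hebbian coupling plasticity and its estimation from behavior.

Between sessions the coupling matrix relaxes toward the experience of the
previous session:

    K^{s+1} = exp(-E) K^s + (1 - exp(-E)) * gamma * Q^s,

where Q^s collects pairwise phase-locking values accumulated over the
session's trials, each trial weighted by the probability that the model
responded correctly, P_c(r) = 1 / (1 + exp(-mu0 - mu1 r)). The psychometric
parameters (mu0, mu1) are fit to first-session behavior; the effective
learning rate E (the product of learning rate and consolidation time) is the
model's single free learning parameter, estimated by a coarse-to-fine grid
search maximizing the weighted Jaccard similarity between simulated
session-2 synchrony and observed session-2 performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cortical_sheet import CouplingMatrix
from .tongue_metrics import ArnoldTongue, minmax_normalize, weighted_jaccard


@dataclass(frozen=True)
class PsychometricParams:
    """Logistic link from synchrony r to probability correct."""

    mu0: float
    mu1: float
    se: tuple[float, float] | None = None  # standard errors when fitted


@dataclass(frozen=True)
class LearningConfig:
    """Coarse-to-fine grid search settings for the effective learning rate."""

    grid_levels: int = 5
    candidates_per_grid: int = 25
    e_min: float = 1e-3
    e_max: float = 10.0


@dataclass
class ExperienceMatrix:
    """Correctness-weighted mean PLV of one session; entries in [0, 1]."""

    session: int
    Q: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if np.any(Q < -1e-12) or np.any(Q > 1 + 1e-12):
            raise ValueError("experience entries must lie in [0, 1]")
        self.Q = np.clip(Q, 0.0, 1.0)


@dataclass
class LearningRateFit:
    E: float
    objective: float
    history: pd.DataFrame  # columns: level, E, objective


def prob_correct(r, params: PsychometricParams) -> np.ndarray | float:
    """P_c = 1 / (1 + exp(-mu0 - mu1 * r)); monotone in r when mu1 > 0."""
    r = np.asarray(r, dtype=float)
    p = 1.0 / (1.0 + np.exp(-params.mu0 - params.mu1 * r))
    return float(p) if p.ndim == 0 else p


def fit_psychometric(
    synchrony_tongue: ArnoldTongue,
    accuracy_tongue: ArnoldTongue,
    trial_counts: np.ndarray | int,
) -> PsychometricParams:
    """Binomial ML fit of (mu0, mu1) from matched synchrony/accuracy cells.

    Each condition contributes a binomial observation: ``trial_counts`` trials
    with per-condition accuracy, whose success probability is P_c evaluated at
    the simulated synchrony of that condition. Fit via logistic regression.
    """
    import statsmodels.api as sm

    if synchrony_tongue.values.shape != accuracy_tongue.values.shape:
        raise ValueError("tongues must share the same condition grid")
    r = synchrony_tongue.values.ravel()
    acc = accuracy_tongue.values.ravel()
    counts = np.broadcast_to(np.asarray(trial_counts, dtype=float), acc.shape).ravel()
    k = np.round(acc * counts)
    if k.sum() == 0 or (counts - k).sum() == 0:
        raise RuntimeError("degenerate accuracy: all responses identical")
    exog = sm.add_constant(r)
    model = sm.GLM(np.column_stack([k, counts - k]), exog, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as exc:  # noqa: BLE001 - surface as a fit failure
        raise RuntimeError(f"psychometric fit failed: {exc}") from exc
    mu0, mu1 = res.params
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e3:
        raise RuntimeError("psychometric fit diverged (perfect separation?)")
    se = tuple(float(s) for s in res.bse)
    return PsychometricParams(mu0=float(mu0), mu1=float(mu1), se=se)


def accumulate_experience(
    plv_per_trial, r_per_trial, params: PsychometricParams, session: int = 1
) -> ExperienceMatrix:
    """Weight-normalized mean of per-trial PLV matrices.

    Q = sum_t P_c(r_t) PLV_t / sum_t P_c(r_t). Normalizing by the weight sum
    keeps Q in [0, 1], which in turn bounds the learned coupling by gamma.
    """
    r = np.asarray(r_per_trial, dtype=float)
    if len(plv_per_trial) == 0 or len(plv_per_trial) != len(r):
        raise ValueError("need aligned, non-empty PLV and synchrony lists")
    w = np.asarray(prob_correct(r, params), dtype=float)
    if w.sum() <= 0:
        raise RuntimeError("all trial weights are zero")
    Q = np.zeros_like(np.asarray(plv_per_trial[0], dtype=float))
    for wi, plv in zip(w, plv_per_trial):
        Q += wi * np.asarray(plv, dtype=float)
    return ExperienceMatrix(session=session, Q=Q / w.sum())


def update_coupling(
    K_s: CouplingMatrix | np.ndarray,
    Q_s: ExperienceMatrix | np.ndarray,
    gamma: float,
    E: float,
) -> CouplingMatrix:
    """One between-session learning step (convex combination toward gamma*Q).

    E = 0 leaves K unchanged; E -> infinity drives K to gamma * Q, i.e.
    structural coupling approaches functional coupling. Entries stay in
    [0, gamma] for any number of sessions. The diagonal is kept at zero
    (self-coupling is inert in the dynamics).
    """
    if E < 0:
        raise ValueError("effective learning rate must be non-negative")
    session = K_s.session if isinstance(K_s, CouplingMatrix) else 0
    K = K_s.K if isinstance(K_s, CouplingMatrix) else np.asarray(K_s, dtype=float)
    Q = Q_s.Q if isinstance(Q_s, ExperienceMatrix) else np.asarray(Q_s, dtype=float)
    if K.shape != Q.shape:
        raise ValueError("K and Q shapes must match")
    decay = np.exp(-E)
    K_next = decay * K + (1.0 - decay) * gamma * Q
    np.fill_diagonal(K_next, 0.0)
    return CouplingMatrix(session=session + 1, K=K_next)


def learning_rate_objective(
    behavior_tongue: ArnoldTongue, synchrony_tongue: ArnoldTongue
) -> float:
    """Weighted Jaccard between min-max-normalized behavior and synchrony."""
    return weighted_jaccard(minmax_normalize(behavior_tongue), synchrony_tongue)


def estimate_learning_rate(
    session2_behavior_tongue: ArnoldTongue,
    simulate_session2,
    K1: CouplingMatrix | np.ndarray,
    Q1: ExperienceMatrix | np.ndarray,
    gamma: float,
    config: LearningConfig | None = None,
) -> LearningRateFit:
    """Coarse-to-fine search for the effective learning rate E.

    ``simulate_session2`` maps a candidate session-2 coupling matrix to a
    simulated synchrony tongue (injectable so tests can substitute a cheap
    surrogate). Five nested grids of 25 candidates each: the first is
    log-spaced over [e_min, e_max]; each refinement spans the interval
    between the neighbors of the previous optimum. Ties break toward the
    smallest E.
    """
    config = config or LearningConfig()
    cand = np.geomspace(config.e_min, config.e_max, config.candidates_per_grid)
    rows = []
    best_E, best_val = None, -np.inf
    for level in range(config.grid_levels):
        vals = np.empty(len(cand))
        for i, E in enumerate(cand):
            K2 = update_coupling(K1, Q1, gamma, float(E))
            tongue = simulate_session2(K2)
            vals[i] = learning_rate_objective(session2_behavior_tongue, tongue)
            rows.append(dict(level=level, E=float(E), objective=float(vals[i])))
        if not np.all(np.isfinite(vals)):
            raise RuntimeError("non-finite learning-rate objective")
        i_best = int(np.argmax(vals))  # argmax takes the first (smallest E) tie
        if vals[i_best] > best_val or (vals[i_best] == best_val and cand[i_best] < best_E):
            best_E, best_val = float(cand[i_best]), float(vals[i_best])
        lo = cand[max(i_best - 1, 0)]
        hi = cand[min(i_best + 1, len(cand) - 1)]
        cand = np.linspace(lo, hi, config.candidates_per_grid)
    return LearningRateFit(E=best_E, objective=best_val, history=pd.DataFrame(rows))


@dataclass
class LearningTrajectory:
    """State emitted by a multi-session learning run."""

    tongues: dict = field(default_factory=dict)  # session -> synchrony tongue
    couplings: dict = field(default_factory=dict)  # session -> CouplingMatrix
    experiences: dict = field(default_factory=dict)  # session -> ExperienceMatrix
    records: dict = field(default_factory=dict)  # session -> per-trial table


def simulate_learning(
    simulator,
    K1: CouplingMatrix,
    params: PsychometricParams,
    E: float,
    sessions: int = 8,
    blocks: int = 30,
    gamma: float | None = None,
    first_session_result=None,
) -> LearningTrajectory:
    """Run sessions 1..``sessions`` with between-session Hebbian updates.

    ``simulator`` is a :class:`~gammatongue.oscillator_dynamics.SessionSimulator`.
    Each session streams P_c-weighted PLV accumulation; afterwards the
    coupling is updated by :func:`update_coupling`. A precomputed session-1
    result (with streamed experience) can be passed to avoid re-simulation.
    The ninth (transfer) session is never simulated.
    """
    from .cortical_sheet import CouplingConfig

    gamma = gamma if gamma is not None else CouplingConfig().gamma
    weight_fn = lambda r: prob_correct(r, params)  # noqa: E731
    traj = LearningTrajectory()
    K = K1
    for s in range(1, sessions + 1):
        if s == 1 and first_session_result is not None:
            res = first_session_result
        else:
            res = simulator.run_session(K.K, session=s, blocks=blocks, plv_weight_fn=weight_fn)
        if res.q_weight_total <= 0:
            raise RuntimeError("all trial weights are zero")
        Q = ExperienceMatrix(session=s, Q=res.q_weighted_sum / res.q_weight_total)
        traj.tongues[s] = res.tongue
        traj.couplings[s] = K
        traj.experiences[s] = Q
        traj.records[s] = res.records
        if s < sessions:
            K = update_coupling(K, Q, gamma, E)
    return traj


def loo_cross_validate(
    accuracy_tongues_by_participant: dict,
    simulator,
    K1: CouplingMatrix,
    gamma: float,
    trial_counts: int = 30,
    blocks: int = 30,
    eval_blocks: int | None = None,
    sessions: int = 8,
    learning_config: LearningConfig | None = None,
):
    """Leave-one-participant-out protocol for model-based prediction.

    ``accuracy_tongues_by_participant`` maps participant id to a dict
    ``{session: accuracy ArnoldTongue}`` with sessions 1..``sessions``. For
    each fold, (mu0, mu1) and E are fit on the held-in participants' mean
    session-1 and session-2 tongues, the model then learns through sessions
    2..``sessions``, and the simulated tongues are returned for evaluation
    against the left-out participant (sessions 3+ only are untouched by
    fitting). Returns a dict: participant -> dict(E, params, tongues).
    """
    from .tongue_metrics import mean_tongue

    pids = sorted(accuracy_tongues_by_participant)
    if len(pids) < 2:
        raise ValueError("need at least 2 participants")
    for pid in pids:
        have = set(accuracy_tongues_by_participant[pid])
        if not set(range(1, sessions + 1)) <= have:
            raise ValueError(f"participant {pid} missing sessions")
    eval_blocks = eval_blocks or blocks

    # session-1 simulation is fold-independent (no learning): run once
    res1 = simulator.run_session(K1.K, session=1, blocks=blocks)
    folds = {}
    for left_out in pids:
        held_in = [p for p in pids if p != left_out]
        beh1 = mean_tongue([accuracy_tongues_by_participant[p][1] for p in held_in])
        beh2 = mean_tongue([accuracy_tongues_by_participant[p][2] for p in held_in])
        params = fit_psychometric(res1.tongue, beh1, trial_counts)
        weight_fn = lambda r: prob_correct(r, params)  # noqa: B023, E731
        res1w = simulator.run_session(
            K1.K, session=1, blocks=blocks, plv_weight_fn=weight_fn
        )
        Q1 = ExperienceMatrix(session=1, Q=res1w.q_weighted_sum / res1w.q_weight_total)

        def simulate_session2(K2, _sim=simulator, _blocks=eval_blocks):
            return _sim.run_session(K2.K, session=2, blocks=_blocks).tongue

        fit = estimate_learning_rate(
            beh2, simulate_session2, K1, Q1, gamma, learning_config
        )
        traj = simulate_learning(
            simulator, K1, params, fit.E, sessions=sessions, blocks=blocks,
            gamma=gamma, first_session_result=res1w,
        )
        folds[left_out] = dict(E=fit.E, params=params, tongues=traj.tongues)
    return folds
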