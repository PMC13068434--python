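"""Synthetic 2AFC behavioral cohorts with the structure the analysis assumes.

Generates per-trial figure-orientation discrimination data whose
per-condition accuracy is driven by model synchrony through the logistic
psychometric link, with subject-level heterogeneity (intercept offsets,
slope scales, lapse rates), session-over-session improvement inherited from
the model's learned synchrony tongues, and a transfer-session (session 9)
reset to session-1 synchrony, mimicking the retinotopic locality of
learning. This stands in for a human dataset so that psychometric fitting,
learning-rate estimation, cross-validation and noise-ceiling code are fully
testable; it is synthetic data, not a record of human performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import BEHAVIOR, DEFAULT_SEED, child_rng
from .plasticity import PsychometricParams, prob_correct
from .tongue_metrics import ArnoldTongue

REQUIRED_COLUMNS = (
    "participant", "session", "block", "zeta_level", "rho_level", "orientation", "correct",
)

N_SESSIONS = 9  # eight training sessions plus the transfer session


@dataclass(frozen=True)
class SubjectProfile:
    """Latent observer parameters of one synthetic participant."""

    participant: int
    mu0_offset: float
    mu1_scale: float
    E_subject: float
    lapse_rate: float


@dataclass(frozen=True)
class PopulationParams:
    """Population distributions the subject profiles are drawn from."""

    mu0: float = -1.0  # base intercept (log-odds); near-chance at r = 0
    mu1: float = 5.0  # base slope per unit synchrony
    mu0_offset_sd: float = 0.3  # normal intercept offsets
    mu1_scale_sd: float = 0.2  # log-normal slope scales
    E_population: float = 0.5  # effective learning rate behind the tongues
    E_sd_log: float = 0.2  # log-normal spread of recorded subject E
    lapse_max: float = 0.04  # uniform [0, lapse_max]


def sample_profiles(
    n_participants: int, population: PopulationParams | None = None, rng=None
) -> list[SubjectProfile]:
    population = population or PopulationParams()
    rng = np.random.default_rng(rng)
    profiles = []
    for p in range(1, n_participants + 1):
        profiles.append(
            SubjectProfile(
                participant=p,
                mu0_offset=float(rng.normal(0.0, population.mu0_offset_sd)),
                mu1_scale=float(rng.lognormal(0.0, population.mu1_scale_sd)),
                E_subject=float(
                    rng.lognormal(np.log(population.E_population), population.E_sd_log)
                ),
                lapse_rate=float(rng.uniform(0.0, population.lapse_max)),
            )
        )
    return profiles


def generate_participant(
    profile: SubjectProfile,
    model_tongues_by_session: dict,
    population: PopulationParams | None = None,
    blocks: int = 30,
    rng=None,
) -> pd.DataFrame:
    """Per-trial records for one participant across sessions 1-9.

    Sessions 1-8 use the corresponding model synchrony tongue; session 9 (the
    transfer session, figure at an untrained location) reuses the session-1
    tongue — learning is retinotopically local, so performance resets.
    Expected accuracy is (1 - lapse) * P_c floored at the 2AFC chance level
    0.5.
    """
    population = population or PopulationParams()
    missing = [s for s in range(1, 9) if s not in model_tongues_by_session]
    if missing:
        raise ValueError(f"missing model tongues for sessions {missing}")
    rng = np.random.default_rng(rng)
    params = PsychometricParams(
        mu0=population.mu0 + profile.mu0_offset,
        mu1=population.mu1 * profile.mu1_scale,
    )
    frames = []
    for session in range(1, N_SESSIONS + 1):
        tongue: ArnoldTongue = model_tongues_by_session[1 if session == 9 else session]
        n_z, n_r = tongue.values.shape
        p_cell = np.maximum(
            0.5, (1.0 - profile.lapse_rate) * prob_correct(tongue.values, params)
        ).ravel()
        n_cells = n_z * n_r
        p = np.tile(p_cell, blocks)
        iz, ir = np.divmod(np.arange(n_cells), n_r)
        frames.append(
            pd.DataFrame(
                dict(
                    participant=profile.participant,
                    session=session,
                    block=np.repeat(np.arange(1, blocks + 1), n_cells),
                    zeta_level=np.tile(iz + 1, blocks),
                    rho_level=np.tile(ir + 1, blocks),
                    orientation=np.where(
                        rng.random(blocks * n_cells) < 0.5, "V", "H"
                    ),
                    correct=(rng.random(blocks * n_cells) < p).astype(int),
                )
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(
    n_participants: int = 8,
    model_tongues_by_session: dict | None = None,
    population: PopulationParams | None = None,
    blocks: int = 30,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, list[SubjectProfile]]:
    """Generate a full synthetic cohort; reproducible from the seed.

    All participants' accuracies derive from the same session-wise model
    tongues (generated under the population's effective learning rate);
    subject heterogeneity enters through psychometric offsets, slope scales
    and lapses.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if model_tongues_by_session is None:
        raise ValueError("model tongues for sessions 1-8 are required")
    profiles = sample_profiles(n_participants, population, child_rng(seed, BEHAVIOR, 0))
    frames = [
        generate_participant(
            prof, model_tongues_by_session, population, blocks,
            child_rng(seed, BEHAVIOR, prof.participant),
        )
        for prof in profiles
    ]
    return pd.concat(frames, ignore_index=True), profiles


def load_behavior(path: str | Path) -> pd.DataFrame:
    """Read and validate a behavioral trial table (CSV).

    Requires the canonical columns; rejects out-of-range sessions, levels, or
    responses, reporting offending row indices.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    checks = {
        "session": df["session"].between(1, N_SESSIONS),
        "zeta_level": df["zeta_level"] >= 1,
        "rho_level": df["rho_level"] >= 1,
        "correct": df["correct"].isin((0, 1)),
        "block": df["block"] >= 1,
    }
    for col, ok in checks.items():
        if not ok.all():
            bad = list(df.index[~ok][:10])
            raise ValueError(f"invalid values in column '{col}' at rows {bad}")
    return df


def accuracy_tongues(
    df: pd.DataFrame,
    zeta_axis: np.ndarray,
    rho_axis: np.ndarray,
) -> dict:
    """Aggregate trials to per-participant, per-session accuracy tongues.

    Returns {participant: {session: ArnoldTongue}} with cell values equal to
    the mean of ``correct`` over that condition's trials.
    """
    out: dict = {}
    n_z, n_r = len(zeta_axis), len(rho_axis)
    grouped = df.groupby(["participant", "session", "zeta_level", "rho_level"])[
        "correct"
    ].mean()
    for (pid, session, iz, ir), acc in grouped.items():
        tongue = out.setdefault(pid, {}).get(session)
        if tongue is None:
            tongue = ArnoldTongue(
                values=np.full((n_z, n_r), np.nan),
                zeta_axis=zeta_axis,
                rho_axis=rho_axis,
                kind="accuracy",
            )
            out[pid][session] = tongue
        tongue.values[int(iz) - 1, int(ir) - 1] = acc
    return out
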