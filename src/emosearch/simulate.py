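"""Synthetic trial-level data for an emotional visual-search experiment.

Generates datasets with the statistical structure the downstream analysis
assumes: three age groups ("I", "V", "IX" grade), three display conditions
(angry target, happy target, target absent), reaction times drawn from
per-participant ex-Gaussian distributions, and yes/no detection responses
from an equal-variance signal-detection observer.

Default group-level parameters are posterior medians from a developmental
visual-search study of the anger superiority effect: ex-Gaussian (mu,
sigma, tau) per group x condition and sensitivity d' per group x emotion.
Exactly half of each participant's trials are target-absent, the present
half split equally between angry and happy targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exgauss import ExGaussianParams, sample_exgauss

__all__ = [
    "SimulationConfig",
    "DEFAULT_EXGAUSS_TRUTH",
    "DEFAULT_SDT_TRUTH",
    "generate_behavioral_dataset",
    "generate_rt_cells",
]

CONDITIONS = ("angry_target", "happy_target", "target_absent")
EMOTIONS = ("angry", "happy")
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "target_present",
    "response",
    "rt",
    "correct",
]

# Group-level ex-Gaussian truths (seconds) per (group, condition).
DEFAULT_EXGAUSS_TRUTH: dict[tuple[str, str], tuple[float, float, float]] = {
    ("I", "angry_target"): (3.21, 0.98, 1.52),
    ("I", "happy_target"): (3.35, 1.05, 1.41),
    ("I", "target_absent"): (3.33, 0.93, 1.55),
    ("V", "angry_target"): (2.65, 0.86, 1.26),
    ("V", "happy_target"): (2.71, 0.89, 1.21),
    ("V", "target_absent"): (2.72, 0.90, 1.25),
    ("IX", "angry_target"): (1.58, 0.51, 0.57),
    ("IX", "happy_target"): (1.81, 0.57, 0.50),
    ("IX", "target_absent"): (2.80, 0.42, 0.41),
}

# Group-level SDT truths (d', criterion) per (group, emotion).
DEFAULT_SDT_TRUTH: dict[tuple[str, str], tuple[float, float]] = {
    ("I", "angry"): (2.87, 0.0),
    ("I", "happy"): (2.32, 0.0),
    ("V", "angry"): (3.10, 0.0),
    ("V", "happy"): (2.74, 0.0),
    ("IX", "angry"): (2.91, 0.0),
    ("IX", "happy"): (2.51, 0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Design and generating parameters of a synthetic experiment.

    ``participant_sd_frac`` sets between-participant spread: participant
    mu is Normal(mu, frac*mu); sigma and tau are lognormal around the
    group value with log-SD = frac (positivity); SDT d is Normal(d,
    frac*d) and the decision threshold Normal around its group value
    with SD = frac (absolute, since criteria can be 0).
    """

    n_participants_per_group: int = 30
    n_trials_per_participant: int = 96
    group_labels: tuple[str, ...] = ("I", "V", "IX")
    exgauss_truth: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXGAUSS_TRUTH)
    )
    sdt_truth: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SDT_TRUTH)
    )
    participant_sd_frac: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants_per_group < 1:
            raise ValueError("n_participants_per_group must be positive")
        if self.n_trials_per_participant < 2 or self.n_trials_per_participant % 2:
            raise ValueError(
                "n_trials_per_participant must be even so exactly half the "
                "trials can be target-absent"
            )
        for g in self.group_labels:
            for cond in CONDITIONS:
                if (g, cond) not in self.exgauss_truth:
                    raise ValueError(f"exgauss_truth missing cell {(g, cond)}")
                mu, sigma, tau = self.exgauss_truth[(g, cond)]
                if mu <= 0 or sigma <= 0 or tau <= 0:
                    raise ValueError(f"non-positive ex-Gaussian parameter in cell {(g, cond)}")
            for emo in EMOTIONS:
                if (g, emo) not in self.sdt_truth:
                    raise ValueError(f"sdt_truth missing cell {(g, emo)}")
        if self.participant_sd_frac < 0:
            raise ValueError("participant_sd_frac must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _condition_counts(n_trials: int, participant_index: int) -> dict[str, int]:
    """Exact per-condition counts: n/2 absent, present half split angry/happy.

    When the present half is odd the extra trial goes to the angry target
    on even participant indices and to the happy target on odd ones, so
    the split is deterministic and balanced across participants.
    """
    n_absent = n_trials // 2
    n_present = n_trials - n_absent
    n_angry = n_present // 2
    n_happy = n_present // 2
    if n_present % 2:
        if participant_index % 2 == 0:
            n_angry += 1
        else:
            n_happy += 1
    return {"angry_target": n_angry, "happy_target": n_happy, "target_absent": n_absent}


def generate_rt_cells(
    n_participants: int,
    n_trials_per_cell: int,
    exgauss_truth: dict[str, tuple[float, float, float]],
    participant_sd_frac: float = 0.10,
    group: str = "I",
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """RT-only dataset with an exact per-cell trial count.

    Used for reaction-time parameter-recovery studies where the design is
    stated as trials per condition rather than as the behavioral task's
    half-absent split.  Participant-level parameters are drawn around the
    condition truths with the same conventions as the full generator
    (Normal on mu, lognormal on sigma and tau); every trial is marked
    correct so downstream correct-only filtering keeps all of them.
    """
    rng = np.random.default_rng(rng_seed)
    frac = participant_sd_frac
    rows = []
    for i in range(n_participants):
        pid = f"{group}_p{i:03d}"
        for cond, (mu, sigma, tau) in exgauss_truth.items():
            params = ExGaussianParams(
                mu=max(rng.normal(mu, frac * mu), 0.05) if frac > 0 else mu,
                sigma=sigma * np.exp(rng.normal(0, frac)) if frac > 0 else sigma,
                tau=tau * np.exp(rng.normal(0, frac)) if frac > 0 else tau,
            )
            rts = sample_exgauss(n_trials_per_cell, params, rng, positive_only=True)
            for rt in rts:
                rows.append(
                    dict(
                        participant_id=pid,
                        group=group,
                        condition=cond,
                        target_present=cond != "target_absent",
                        response="different",
                        rt=float(rt),
                        correct=True,
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_behavioral_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the full trial table for every participant.

    Per participant, latent ex-Gaussian parameters are drawn around the
    group truth for each condition, and a latent SDT observer (d' per
    emotion, one decision threshold) around the group truth.  RTs and
    responses are generated independently given the design: the RT
    generator and the detection observer are separate processes, fitted
    by separate models downstream.

    Responses use the equal-variance SDT observer: on target-present
    trials of emotion e the probability of responding "different" is
    Phi(d_e/2 - c_e); on target-absent trials it is Phi(-lambda) with
    lambda the participant's absolute threshold (the mean over emotions
    of d_e/2 + c_e, so each emotion's hit/false-alarm formulas hold).
    """
    rng = np.random.default_rng(config.rng_seed)
    frac = config.participant_sd_frac
    rows: list[dict] = []
    pidx = 0
    for group in config.group_labels:
        for _ in range(config.n_participants_per_group):
            pid = f"{group}_p{pidx:03d}"
            counts = _condition_counts(config.n_trials_per_participant, pidx)

            # latent observer
            d_i, lam_terms = {}, []
            for emo in EMOTIONS:
                d, c = config.sdt_truth[(group, emo)]
                d_i[emo] = rng.normal(d, frac * abs(d)) if frac > 0 else d
                lam_terms.append(c + d_i[emo] / 2.0)
            lam_i = float(np.mean(lam_terms))
            if frac > 0:
                lam_i = rng.normal(lam_i, frac)

            for cond in CONDITIONS:
                n = counts[cond]
                mu, sigma, tau = config.exgauss_truth[(group, cond)]
                params_i = ExGaussianParams(
                    mu=max(rng.normal(mu, frac * mu), 0.05) if frac > 0 else mu,
                    sigma=sigma * np.exp(rng.normal(0, frac)) if frac > 0 else sigma,
                    tau=tau * np.exp(rng.normal(0, frac)) if frac > 0 else tau,
                )
                rts = sample_exgauss(n, params_i, rng, positive_only=True)
                present = cond != "target_absent"
                if present:
                    emo = "angry" if cond == "angry_target" else "happy"
                    p_diff = float(ndtr(d_i[emo] - lam_i))
                else:
                    p_diff = float(ndtr(-lam_i))
                said_diff = rng.uniform(size=n) < p_diff
                for t in range(n):
                    resp = "different" if said_diff[t] else "same"
                    rows.append(
                        dict(
                            participant_id=pid,
                            group=group,
                            condition=cond,
                            target_present=present,
                            response=resp,
                            rt=float(rts[t]),
                            correct=bool(said_diff[t] == present),
                        )
                    )
            pidx += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
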