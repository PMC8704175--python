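"""Simulated blinded rater studies with known generative parameters.

Two generators mirror the structure of a two-session blinded contour
evaluation by a panel of clinicians:

* an ordinal scoring study — each contour carries a latent quality,
  each clinician a bias, and each (clinician, contour) pair correlated
  noise across the two sessions; the latent value is mapped to the
  0-3 rubric (rejected / major revision / minor revision / accepted)
  by fixed cutpoints;
* a contour Turing test — per (slice, clinician, session) Bernoulli
  judgement that the AI contour is the better one, with a Gaussian-
  copula session correlation and a random red/green blinding per slice
  and session.

Because the parameters are known, the aggregation statistics (means,
acceptability rates, kappa, McNemar, Mann-Whitney, positive rates) can
be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SESSIONS = ("week0", "week2")
ARMS = ("AI", "GT")
COLORS = ("red", "green")


@dataclass(frozen=True)
class RaterStudyConfig:
    """Generative parameters of the simulated study.

    Latent scale is the score scale: a contour of quality q rated by an
    unbiased clinician with no noise maps through the cutpoints
    (0.5, 1.5, 2.5) to round(q). Defaults emulate a panel of 10
    clinicians scoring 50 contours per arm twice, plus a 100-slice
    Turing test; the default arm qualities and positive probability sit
    in the regime reported for CTV auto-contouring panels (mean scores
    ~2.5-2.6, AI-better rates ~40%).
    """

    n_clinicians: int = 10
    n_contours_per_arm: int = 50
    latent_quality_mean_ai: float = 2.6
    latent_quality_mean_gt: float = 2.5
    quality_sd: float = 0.35
    clinician_bias_sd: float = 0.25
    residual_sd: float = 0.45
    session_correlation: float = 0.6
    score_cutpoints: tuple[float, float, float] = (0.5, 1.5, 2.5)
    n_slices: int = 100
    turing_positive_prob: float = 0.405
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.session_correlation <= 1:
            raise ValueError("session_correlation must be in [0, 1]")
        if not 0 <= self.turing_positive_prob <= 1:
            raise ValueError("turing_positive_prob must be in [0, 1]")
        c = self.score_cutpoints
        if not (c[0] < c[1] < c[2]):
            raise ValueError("score_cutpoints must be strictly increasing")
        if min(self.n_clinicians, self.n_contours_per_arm, self.n_slices) < 1:
            raise ValueError("counts must be positive")


def _ordinal(latent: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(cutpoints), latent, side="right").astype(int)


def simulate_scoring_study(config: RaterStudyConfig) -> pd.DataFrame:
    """Long-format score table: clinician_id, contour_id, session, arm, score.

    Latent rating of contour i by clinician c in session s:
    ``q_i + b_c + sqrt(rho)*u_ic + sqrt(1-rho)*e_ics`` with u, e
    standard-normal scaled to ``residual_sd`` — exact correlation rho
    between sessions on the latent scale, approximate after the ordinal
    cutpoints (documented behaviour).
    """
    rng = np.random.default_rng(config.seed)
    rho = config.session_correlation
    nc, ni = config.n_clinicians, config.n_contours_per_arm
    bias = rng.normal(0.0, config.clinician_bias_sd, nc)
    clin_ids = np.array([f"C{c:02d}" for c in range(nc)])
    frames = []
    for arm, qmean in (
        ("AI", config.latent_quality_mean_ai),
        ("GT", config.latent_quality_mean_gt),
    ):
        quality = rng.normal(qmean, config.quality_sd, ni)
        # shared and per-session components of the rating noise
        u = rng.standard_normal((nc, ni))
        e = rng.standard_normal((2, nc, ni))
        contour_ids = np.array([f"{arm}_{i:03d}" for i in range(ni)])
        for s_idx, session in enumerate(SESSIONS):
            noise = config.residual_sd * (
                np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e[s_idx]
            )
            latent = quality[None, :] + bias[:, None] + noise
            score = _ordinal(latent, config.score_cutpoints).clip(0, 3)
            frames.append(
                pd.DataFrame(
                    {
                        "clinician_id": np.repeat(clin_ids, ni),
                        "contour_id": np.tile(contour_ids, nc),
                        "session": session,
                        "arm": arm,
                        "score": score.reshape(-1),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_turing_study(config: RaterStudyConfig) -> pd.DataFrame:
    """Turing-test table: clinician_id, slice_id, session, chosen_color, ai_color.

    A judgement is positive (AI chosen) with probability
    ``turing_positive_prob``; the two sessions of one (clinician, slice)
    pair share a Gaussian-copula latent with correlation rho. Colors are
    re-randomized per slice and session, as the blinding protocol does.
    """
    rng = np.random.default_rng(config.seed + 1)
    rho = config.session_correlation
    nc, ns = config.n_clinicians, config.n_slices
    thr = stats.norm.ppf(config.turing_positive_prob)
    u = rng.standard_normal((nc, ns))
    e = rng.standard_normal((2, nc, ns))
    ai_color = rng.integers(0, 2, (2, ns))  # per session & slice
    colors = np.array(COLORS)
    clin_ids = np.array([f"C{c:02d}" for c in range(nc)])
    slice_ids = np.array([f"S{k:03d}" for k in range(ns)])
    frames = []
    for s_idx, session in enumerate(SESSIONS):
        z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e[s_idx]
        positive = z < thr
        ai = colors[ai_color[s_idx]]  # (ns,)
        other = colors[1 - ai_color[s_idx]]
        chosen = np.where(positive, ai[None, :], other[None, :])
        frames.append(
            pd.DataFrame(
                {
                    "clinician_id": np.repeat(clin_ids, ns),
                    "slice_id": np.tile(slice_ids, nc),
                    "session": session,
                    "chosen_color": chosen.reshape(-1),
                    "ai_color": np.tile(ai, nc),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
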