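"""Blinded clinical-evaluation protocol: bookkeeping and statistics.

Covers the analysis of a two-session blinded contour study:

* randomization/blinding schedules (presentation order re-randomized
  per session, random red/green color per slice);
* ordinal 0-3 scoring aggregation — per-clinician score distributions
  and means, pooled distributions, acceptability (score >= 2) and
  fully-acceptable (score = 3) rates, per-clinician AI-vs-GT
  Mann-Whitney comparisons;
* Turing-test aggregation — per-clinician positive rates (AI contour
  judged better), the mean positive rate, and the intelligence
  criterion (every clinician's rate at or above 30%);
* consistency between the two sessions — unweighted Cohen's kappa per
  clinician (kappa >= 0.2 read as acceptable consistency) and
  McNemar's test on the paired per-slice binary judgements.

Score and Turing tables are plain pandas DataFrames in the long formats
produced by :mod:`segeval.study_sim` (or read from CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import mann_whitney

SCORE_COLUMNS = ["clinician_id", "contour_id", "session", "arm", "score"]
TURING_COLUMNS = ["clinician_id", "slice_id", "session", "chosen_color", "ai_color"]
KAPPA_ACCEPTABLE = 0.2
DEFAULT_TURING_CRITERION = 0.30


def validate_score_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns {sorted(missing)}")
    if not df["score"].isin([0, 1, 2, 3]).all():
        raise ValueError("scores must be integers in {0, 1, 2, 3}")
    dup = df.duplicated(["clinician_id", "contour_id", "session"])
    if dup.any():
        raise ValueError("duplicate (clinician, contour, session) ratings")
    return df


def validate_turing_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(TURING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"turing table missing columns {sorted(missing)}")
    colors = set(df["chosen_color"]) | set(df["ai_color"])
    if not colors <= {"red", "green"}:
        raise ValueError(f"colors must be red/green, got {sorted(colors)}")
    dup = df.duplicated(["clinician_id", "slice_id", "session"])
    if dup.any():
        raise ValueError("duplicate (clinician, slice, session) responses")
    return df


# ---------------------------------------------------------------------------
# Randomization / blinding
# ---------------------------------------------------------------------------


def make_blinding_schedule(
    contour_ids: Sequence[str], slice_ids: Sequence[str], seed: int = 0
) -> dict:
    """Per-session presentation orders and per-slice color assignments.

    The presentation order is re-shuffled independently for the second
    session; each slice gets a fresh random color for the AI contour in
    each session. The returned key maps everything back to the truth and
    must stay with the statistician, not the raters.
    """
    if len(set(contour_ids)) != len(contour_ids):
        raise ValueError("duplicate contour ids")
    if len(set(slice_ids)) != len(slice_ids):
        raise ValueError("duplicate slice ids")
    rng = np.random.default_rng(seed)
    schedule: dict = {"seed": seed, "sessions": {}}
    for session in ("week0", "week2"):
        order = list(np.array(contour_ids)[rng.permutation(len(contour_ids))])
        colors = {
            sid: ("red" if rng.integers(0, 2) else "green") for sid in slice_ids
        }
        schedule["sessions"][session] = {
            "presentation_order": order,
            "ai_color": colors,
        }
    return schedule


# ---------------------------------------------------------------------------
# Clinicians' scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreSummary:
    """Aggregates of one scoring session (both arms)."""

    session: str
    per_clinician: dict  # clinician -> arm -> {counts, n, mean}
    per_clinician_p: dict  # clinician -> AI-vs-GT Mann-Whitney p
    pooled_counts: dict  # arm -> {score: count}
    pooled_percent: dict  # arm -> {score: % of ratings}
    overall_mean: dict  # arm -> unweighted mean of clinician means
    pooled_mean: dict  # arm -> rating-weighted mean
    acceptability_percent: dict  # arm -> % of ratings with score >= 2
    fully_acceptable_percent: dict  # arm -> % of ratings with score == 3
    missing_cells: list

    def to_dict(self) -> dict:
        return asdict(self)


def score_summary(table: pd.DataFrame, session: str) -> ScoreSummary:
    """Aggregate one session of an ordinal scoring study.

    Per-clinician mean = sum of scores / number rated; the overall mean
    per arm is the *unweighted mean of per-clinician means* (the
    convention of published panel tables), with the rating-weighted
    pooled mean also reported since the two differ when clinicians rate
    unequal numbers. Acceptability counts ratings with score >= 2.
    """
    df = validate_score_table(table)
    df = df[df["session"] == session]
    if df.empty:
        raise ValueError(f"no rows for session {session!r}")
    clinicians = sorted(df["clinician_id"].unique())

    per_clinician: dict = {}
    per_clinician_p: dict = {}
    missing = []
    for c in clinicians:
        per_clinician[c] = {}
        sub_c = df[df["clinician_id"] == c]
        for arm in ("AI", "GT"):
            sub = sub_c[sub_c["arm"] == arm]
            if sub.empty:
                missing.append({"clinician_id": c, "arm": arm, "session": session})
                continue
            counts = {s: int((sub["score"] == s).sum()) for s in range(4)}
            per_clinician[c][arm] = {
                "counts": counts,
                "n": int(len(sub)),
                "mean": float(sub["score"].mean()),
            }
        if "AI" in per_clinician[c] and "GT" in per_clinician[c]:
            ai = sub_c[sub_c["arm"] == "AI"]["score"].to_numpy()
            gt = sub_c[sub_c["arm"] == "GT"]["score"].to_numpy()
            per_clinician_p[c] = mann_whitney(ai, gt)["p_two_sided"]

    pooled_counts: dict = {}
    pooled_percent: dict = {}
    overall_mean: dict = {}
    pooled_mean: dict = {}
    acceptability: dict = {}
    fully: dict = {}
    for arm in ("AI", "GT"):
        counts = {
            s: sum(
                per_clinician[c][arm]["counts"][s]
                for c in clinicians
                if arm in per_clinician[c]
            )
            for s in range(4)
        }
        total = sum(counts.values())
        pooled_counts[arm] = counts
        pooled_percent[arm] = {
            s: 100.0 * v / total if total else float("nan") for s, v in counts.items()
        }
        means = [
            per_clinician[c][arm]["mean"] for c in clinicians if arm in per_clinician[c]
        ]
        overall_mean[arm] = float(np.mean(means)) if means else float("nan")
        pooled_mean[arm] = (
            sum(s * v for s, v in counts.items()) / total if total else float("nan")
        )
        acceptability[arm] = (
            100.0 * (counts[2] + counts[3]) / total if total else float("nan")
        )
        fully[arm] = 100.0 * counts[3] / total if total else float("nan")

    return ScoreSummary(
        session=session,
        per_clinician=per_clinician,
        per_clinician_p=per_clinician_p,
        pooled_counts=pooled_counts,
        pooled_percent=pooled_percent,
        overall_mean=overall_mean,
        pooled_mean=pooled_mean,
        acceptability_percent=acceptability,
        fully_acceptable_percent=fully,
        missing_cells=missing,
    )


# ---------------------------------------------------------------------------
# Consistency statistics
# ---------------------------------------------------------------------------


def cohen_kappa(
    scores_s1: Sequence[int],
    scores_s2: Sequence[int],
    labels: Sequence[int] = (0, 1, 2, 3),
    weights: str | None = None,
) -> float | None:
    """Cohen's kappa between paired ratings of the same items.

    Unweighted by default ('linear'/'quadratic' available). Returns
    None when kappa is undefined, i.e. the chance agreement is 1
    (no variation in either session).
    """
    s1 = np.asarray(scores_s1)
    s2 = np.asarray(scores_s2)
    if s1.shape != s2.shape or s1.size == 0:
        raise ValueError("need equal-length, non-empty paired ratings")
    labels = list(labels)
    p1 = np.array([(s1 == l).mean() for l in labels])
    p2 = np.array([(s2 == l).mean() for l in labels])
    pe = float(p1 @ p2)
    if pe >= 1.0 - 1e-12:
        return None
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(s1, s2, labels=labels, weights=weights))


def kappa_by_clinician(
    table: pd.DataFrame, arm: str | None = None
) -> dict[str, dict]:
    """Week0-vs-week2 kappa per clinician on contours rated both times."""
    df = validate_score_table(table)
    if arm is not None:
        df = df[df["arm"] == arm]
    out: dict[str, dict] = {}
    for c, sub in df.groupby("clinician_id"):
        wide = sub.pivot_table(
            index="contour_id", columns="session", values="score", aggfunc="first"
        ).dropna()
        if wide.shape[0] == 0 or wide.shape[1] < 2:
            out[str(c)] = {"kappa": None, "n": 0, "acceptable": None}
            continue
        k = cohen_kappa(wide["week0"].astype(int), wide["week2"].astype(int))
        out[str(c)] = {
            "kappa": k,
            "n": int(wide.shape[0]),
            "acceptable": (None if k is None else bool(k >= KAPPA_ACCEPTABLE)),
        }
    return out


def mcnemar_test(
    paired_binary_s1: Sequence[int], paired_binary_s2: Sequence[int]
) -> dict:
    """McNemar's test on paired binary outcomes from two sessions.

    Exact binomial when fewer than 25 discordant pairs, chi-square with
    continuity correction otherwise; no discordance gives p = 1.
    """
    b1 = np.asarray(paired_binary_s1).astype(bool)
    b2 = np.asarray(paired_binary_s2).astype(bool)
    if b1.shape != b2.shape or b1.size == 0:
        raise ValueError("need equal-length, non-empty paired outcomes")
    n01 = int((~b1 & b2).sum())
    n10 = int((b1 & ~b2).sum())
    table = [
        [int((b1 & b2).sum()), n01],
        [n10, int((~b1 & ~b2).sum())],
    ]
    if n01 + n10 == 0:
        return {"p": 1.0, "discordant": 0, "method": "degenerate", "table": table}
    from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

    exact = (n01 + n10) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return {
        "p": float(res.pvalue),
        "discordant": n01 + n10,
        "method": "exact-binomial" if exact else "chi2-corrected",
        "table": table,
    }


# ---------------------------------------------------------------------------
# Turing test
# ---------------------------------------------------------------------------


@dataclass
class TuringSummary:
    """Aggregates of one Turing-test session."""

    session: str
    criterion: float
    per_clinician: dict  # clinician -> {positive, n, rate}
    mean_positive_rate: float  # unweighted mean of clinician rates
    verdict_all_clinicians: bool  # every clinician's rate >= criterion
    verdict_mean_rate: bool  # mean rate >= criterion

    def to_dict(self) -> dict:
        return asdict(self)


def turing_summary(
    table: pd.DataFrame,
    session: str,
    criterion: float = DEFAULT_TURING_CRITERION,
) -> TuringSummary:
    """Positive rates and the intelligence verdict for one session.

    A response is positive when the chosen color is the AI contour's.
    The default verdict requires *every* clinician's rate to meet the
    criterion (a clinician at exactly the criterion counts as meeting
    it); the mean-rate rule is reported alongside.
    """
    df = validate_turing_table(table)
    df = df[df["session"] == session]
    if df.empty:
        raise ValueError(f"no rows for session {session!r}")
    pos = df["chosen_color"] == df["ai_color"]
    per: dict = {}
    for c, idx in df.groupby("clinician_id").groups.items():
        p = pos.loc[idx]
        per[str(c)] = {
            "positive": int(p.sum()),
            "n": int(len(p)),
            "rate": float(p.mean()),
        }
    rates = np.array([v["rate"] for v in per.values()])
    return TuringSummary(
        session=session,
        criterion=criterion,
        per_clinician=per,
        mean_positive_rate=float(rates.mean()),
        verdict_all_clinicians=bool(np.all(rates >= criterion)),
        verdict_mean_rate=bool(rates.mean() >= criterion),
    )


def per_slice_mean_score(table: pd.DataFrame, session: str) -> dict:
    """Mean positive judgement per slice across clinicians.

    A slice scored 0.3 was judged AI-better by 3 of 10 clinicians; the
    summary counts slices at or above 0.3 and 0.5.
    """
    df = validate_turing_table(table)
    df = df[df["session"] == session]
    if df.empty:
        raise ValueError(f"no rows for session {session!r}")
    pos = (df["chosen_color"] == df["ai_color"]).astype(float)
    means = pos.groupby(df["slice_id"]).mean()
    return {
        "per_slice": {str(k): float(v) for k, v in means.items()},
        "n_slices": int(means.size),
        "n_ge_03": int((means >= 0.3).sum()),
        "n_ge_05": int((means >= 0.5).sum()),
    }


def mcnemar_by_clinician(table: pd.DataFrame) -> dict[str, dict]:
    """Session-consistency McNemar test per clinician on paired slices."""
    df = validate_turing_table(table)
    pos = df.assign(positive=(df["chosen_color"] == df["ai_color"]).astype(int))
    out: dict[str, dict] = {}
    for c, sub in pos.groupby("clinician_id"):
        wide = sub.pivot_table(
            index="slice_id", columns="session", values="positive", aggfunc="first"
        ).dropna()
        if wide.shape[0] == 0 or wide.shape[1] < 2:
            out[str(c)] = {"p": None, "discordant": None, "method": "missing"}
            continue
        out[str(c)] = mcnemar_test(
            wide["week0"].astype(int), wide["week2"].astype(int)
        )
    return out


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Everything the two-session blinded evaluation produces."""

    scoring: dict  # session -> ScoreSummary
    turing: dict  # session -> TuringSummary
    kappa: dict  # clinician -> {kappa, n, acceptable}
    mcnemar: dict  # clinician -> {p, discordant, method}
    per_slice: dict  # session -> per-slice mean scores

    def to_dict(self) -> dict:
        return {
            "scoring": {s: v.to_dict() for s, v in self.scoring.items()},
            "turing": {s: v.to_dict() for s, v in self.turing.items()},
            "kappa": self.kappa,
            "mcnemar": self.mcnemar,
            "per_slice": self.per_slice,
        }


def build_study_report(
    score_table: pd.DataFrame | None,
    turing_table: pd.DataFrame | None,
    criterion: float = DEFAULT_TURING_CRITERION,
) -> StudyReport:
    """Aggregate a complete study (either table may be absent)."""
    scoring: dict = {}
    kappa: dict = {}
    if score_table is not None:
        for session in sorted(score_table["session"].unique()):
            scoring[session] = score_summary(score_table, session)
        kappa = kappa_by_clinician(score_table)
    turing: dict = {}
    mcn: dict = {}
    per_slice: dict = {}
    if turing_table is not None:
        for session in sorted(turing_table["session"].unique()):
            turing[session] = turing_summary(turing_table, session, criterion)
            per_slice[session] = per_slice_mean_score(turing_table, session)
        mcn = mcnemar_by_clinician(turing_table)
    return StudyReport(
        scoring=scoring, turing=turing, kappa=kappa, mcnemar=mcn, per_slice=per_slice
    )
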