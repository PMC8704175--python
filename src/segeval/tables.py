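"""Bundled reference tables from the published CTV-evaluation study.

Three small CSV fixtures ship with the package:

* ``validation_metrics.csv`` — per-patient DSC and 95HD (mm) of the
  clinical auto-segmentation model on the 20-patient validation cohort,
  split into the clinicians'-scoring group (patients 1-10) and the
  Turing-test group (patients 11-20);
* ``scoring_counts.csv`` — per-clinician counts of each 0-3 score for
  AI and reference (GT) contours, both sessions (50 ratings per
  clinician per arm per session);
* ``turing_counts.csv`` — per-clinician positive/negative judgement
  counts in the contour Turing test, both sessions (100 slices each).

Loaders return pandas DataFrames; helpers expand the count tables into
the long formats the :mod:`segeval.clinical` aggregations consume.

Known erratum, preserved as printed: the source table's Turing-group
95HD "mean 8.97" is inconsistent with its own ten listed values (whose
mean is 7.64); the whole-cohort mean 8.11 mm is consistent and is the
value this package reproduces.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__package__) / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as p:
        return pd.read_csv(p)


def load_validation_metrics() -> pd.DataFrame:
    """Per-patient DSC/95HD with a ``group`` column."""
    return _read("validation_metrics.csv")


def load_scoring_counts() -> pd.DataFrame:
    """Score-count table: session, clinician, arm, score, count."""
    return _read("scoring_counts.csv")


def load_turing_counts() -> pd.DataFrame:
    """Turing-test counts: session, clinician, positive, negative."""
    return _read("turing_counts.csv")


def scoring_counts_to_table(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand score counts into a long per-rating ScoreTable.

    Contour identities are synthetic (the published table aggregates
    them away), so session-pairing statistics such as kappa cannot be
    recomputed from this expansion — only distributions and means.
    """
    if counts is None:
        counts = load_scoring_counts()
    rows = []
    for (session, clinician, arm), sub in counts.groupby(
        ["session", "clinician", "arm"]
    ):
        i = 0
        for _, r in sub.sort_values("score").iterrows():
            for _ in range(int(r["count"])):
                rows.append(
                    (clinician, f"{arm}_{clinician}_{i:03d}", session, arm, int(r["score"]))
                )
                i += 1
    return pd.DataFrame(
        rows, columns=["clinician_id", "contour_id", "session", "arm", "score"]
    )


def turing_counts_to_table(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand Turing counts into a long per-response table.

    Slice identities and colors are synthetic (AI fixed to red): the
    published counts do not record which slices were positive, so paired
    McNemar statistics cannot be recomputed — only rates and verdicts.
    """
    if counts is None:
        counts = load_turing_counts()
    rows = []
    for _, r in counts.iterrows():
        n = int(r["positive"]) + int(r["negative"])
        for k in range(n):
            positive = k < int(r["positive"])
            rows.append(
                (
                    r["clinician"],
                    f"S{k:03d}",
                    r["session"],
                    "red" if positive else "green",
                    "red",
                )
            )
    return pd.DataFrame(
        rows,
        columns=["clinician_id", "slice_id", "session", "chosen_color", "ai_color"],
    )
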