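"""Cohort-level statistics linking the autoregulation index to outcomes.

The packaged cohort (25 neonatal/pediatric ECMO patients) carries, per
patient: demographics, ECMO type and duration, the intra-ECMO
autoregulation index (Pmean, %), the neuroimaging total score with
modality and timing, arterial blood-gas changes from the 24 h before ECMO
to the first 24 h on ECMO, and anticoagulation summaries (PTT, UH, INR)
over the whole run.

The primary cohort result is the Pearson correlation between the
autoregulation index and the neuroimaging score; univariate and
multivariate ordinary-least-squares regressions probe ECMO type/duration,
blood-gas deltas and anticoagulation as candidate drivers.  Analyses run
on the whole cohort and within the neonate (age <= 4 weeks) and child
subgroups, with no multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from .neuro import Category, categorize

__all__ = [
    "load_table",
    "load_cohort",
    "pearson",
    "fit_linear",
    "blood_gas_delta",
    "coag_summary",
    "category_counts",
    "cohort_report",
]

_TABLE_FILES = {
    "characteristics": "table1_characteristics.csv",
    "index_scores": "table2_index_scores.csv",
    "bloodgas": "table3_bloodgas.csv",
    "anticoag": "table4_anticoag.csv",
}


class CohortValidationWarning(UserWarning):
    """A packaged or user-supplied cohort row violates a sanity invariant."""


def load_table(name: str) -> pd.DataFrame:
    """Load one packaged cohort table by short name.

    Names: ``characteristics``, ``index_scores``, ``bloodgas``,
    ``anticoag``.
    """
    if name not in _TABLE_FILES:
        raise KeyError(f"unknown table {name!r}; choose from {sorted(_TABLE_FILES)}")
    ref = resources.files("autoregwtc.data").joinpath(_TABLE_FILES[name])
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def _validate_coag(df: pd.DataFrame) -> None:
    # a transcription typo in a source table (e.g. an impossible PTT
    # minimum) should warn, not abort: the value is carried verbatim
    for stem in ("ptt", "uh", "inr"):
        cols = [c for c in df.columns if c.startswith(stem)]
        if len(cols) != 3:
            continue
        lo, mid, hi = (df[c] for c in sorted(cols, key=lambda c: ("min" not in c, "mean" not in c)))
        bad = ~((lo <= mid) & (mid <= hi))
        for pid in df.loc[bad, "patient_id"]:
            warnings.warn(
                f"patient {pid}: {stem.upper()} min/mean/max not ordered "
                "(suspected transcription error, value kept verbatim)",
                CohortValidationWarning,
                stacklevel=3,
            )


def load_cohort(
    characteristics: pd.DataFrame | None = None,
    index_scores: pd.DataFrame | None = None,
    bloodgas: pd.DataFrame | None = None,
    anticoag: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge the four cohort tables into one record per patient.

    Any table not supplied falls back to the packaged one.  Coagulation
    triples are validated (min <= mean <= max) with warnings on violation.
    """
    characteristics = characteristics if characteristics is not None else load_table("characteristics")
    index_scores = index_scores if index_scores is not None else load_table("index_scores")
    bloodgas = bloodgas if bloodgas is not None else load_table("bloodgas")
    anticoag = anticoag if anticoag is not None else load_table("anticoag")
    _validate_coag(anticoag)
    df = characteristics.merge(
        index_scores.drop(columns=["age_group"], errors="ignore"), on="patient_id"
    )
    df = df.merge(bloodgas.drop(columns=["age_group"], errors="ignore"), on="patient_id")
    df = df.merge(anticoag.drop(columns=["age_group"], errors="ignore"), on="patient_id")
    df["category"] = [categorize(t).value for t in df["total_score"]]
    if (df["ecmo_duration_h"] <= 0).any():
        raise ValueError("ECMO duration must be positive")
    if ((df["autoreg_index_pct"] < 0) | (df["autoreg_index_pct"] > 100)).any():
        raise ValueError("autoregulation index must lie in [0, 100]")
    return df


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fit_linear(outcome, predictors, names: list[str] | None = None):
    """Ordinary least squares of ``outcome`` on ``predictors`` with intercept.

    Returns the fitted statsmodels results object (coefficients under
    ``.params``, two-sided t-test p-values under ``.pvalues``, ``.rsquared``).
    A rank-deficient design raises, naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    if x.shape[0] != y.size:
        raise ValueError("outcome and predictors have incompatible shapes")
    if y.size <= x.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    design = pd.DataFrame(x, columns=names)
    design = sm.add_constant(design)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for col in names:
            reduced = design.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                collinear.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return sm.OLS(y, design).fit()


def blood_gas_delta(pre_window, on_window, kind: str) -> float:
    """Blood-gas change from the 24 h pre-ECMO to the first 24 h on ECMO.

    For ``ph`` and ``pao2`` the delta is max(on) - min(pre); for ``pco2``
    it is min(on) - max(pre), so a washout drop comes out negative.
    """
    pre = np.asarray(pre_window, dtype=float)
    on = np.asarray(on_window, dtype=float)
    if pre.size == 0 or on.size == 0:
        raise ValueError("both measurement windows must be non-empty")
    kind = kind.lower()
    if kind in ("ph", "pao2"):
        return float(on.max() - pre.min())
    if kind == "pco2":
        return float(on.min() - pre.max())
    raise ValueError(f"unknown blood-gas kind {kind!r}")


def coag_summary(values) -> tuple[float, float, float]:
    """(min, mean, max) of repeated coagulation lab values over an ECMO run."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one lab value")
    return float(v.min()), float(v.mean()), float(v.max())


def category_counts(totals) -> dict[Category, int]:
    """Count patients per neuroimaging category from their total scores."""
    counts = {c: 0 for c in Category}
    for t in totals:
        counts[categorize(float(t))] += 1
    return counts


@dataclass
class GroupResult:
    group: str
    n: int
    r: float | None
    p: float | None
    counts: dict[str, int]


def cohort_report(df: pd.DataFrame | None = None, min_group: int = 3) -> dict:
    """Primary cohort analysis: correlation and counts, overall and by age group.

    Groups with fewer than ``min_group`` usable records are skipped with a
    warning.  Also runs the univariate regressions of the autoregulation
    index on ECMO duration and each blood-gas delta, and of the
    neuroimaging score on the anticoagulation summaries.
    """
    if df is None:
        df = load_cohort()
    out: dict = {"groups": {}, "regressions": {}}
    for group, sub in (
        ("cohort", df),
        ("neonates", df[df["age_group"] == "neonate"]),
        ("children", df[df["age_group"] == "child"]),
    ):
        if len(sub) < min_group:
            warnings.warn(f"group {group!r} has <{min_group} records; skipped")
            continue
        r, p = pearson(sub["autoreg_index_pct"], sub["total_score"])
        counts = category_counts(sub["total_score"])
        out["groups"][group] = {
            "n": int(len(sub)),
            "pearson_r": r,
            "p_value": p,
            "counts": {c.value: counts[c] for c in Category},
        }
    predictors = {
        "ecmo_duration_h": ("autoreg_index_pct", "ecmo_duration_h"),
        "delta_ph": ("autoreg_index_pct", "delta_ph"),
        "delta_pao2": ("autoreg_index_pct", "delta_pao2_mmhg"),
        "delta_pco2": ("autoreg_index_pct", "delta_pco2_mmhg"),
        "ptt_mean": ("total_score", "ptt_mean_s"),
        "uh_mean": ("total_score", "uh_mean_iu_ml"),
    }
    for label, (ycol, xcol) in predictors.items():
        if ycol not in df or xcol not in df or len(df) < 4:
            continue
        fit = fit_linear(df[ycol], df[[xcol]].to_numpy(), names=[xcol])
        out["regressions"][label] = {
            "outcome": ycol,
            "slope": float(fit.params[xcol]),
            "p_value": float(fit.pvalues[xcol]),
            "r_squared": float(fit.rsquared),
        }
    return out
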