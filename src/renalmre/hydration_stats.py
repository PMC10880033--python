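"""Cohort-level statistics: fasting vs hydration and left vs right.

The study design this reproduces: each subject is imaged fasting and after
a drinking challenge, left and right kidney separately; per (subject, side,
state, ROI) the median of each biomechanical parameter is one sample.
QA metrics are compared with paired t-tests; the skewed biomechanical
medians with Wilcoxon tests — signed-rank when the contrast is paired
(fasting vs hydrated within subject), rank-sum when it is not (ROI vs ROI
across the pooled sample).  Tied samples are excluded rather than
mid-ranked.  No multiple-testing correction is applied by default (a Holm
option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import DEFAULT_MODULI
from .physics import phase_angle, shear_speed_and_attenuation

PARAMETERS = ("gd_kpa", "gl_kpa", "cs_mps", "alpha_per_mm", "upsilon")


def stars(p: float) -> str:
    """Significance annotation: * <=0.05, ** <=0.01, *** <=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# elementary tests


def paired_t_test(x, y):
    """Two-sided paired t-test; returns (t, df, p).

    Pairs with missing values are dropped; fewer than 3 complete pairs is
    an error.  Zero-variance differences return p = 1 with a warning (t is
    0 for identical samples) instead of failing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        warnings.warn("zero-variance differences in paired t-test; p set to 1")
        t = 0.0 if np.mean(d) == 0 else float(np.sign(np.mean(d)) * np.inf)
        return t, n - 1, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)


def wilcoxon_signed_rank(x, y=None):
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences (ties) are excluded before ranking.  The exact null
    distribution is used for n <= 25 without tied magnitudes, the normal
    approximation otherwise.  Returns (W, n_used, p).
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[np.isfinite(d)]
    d = d[d != 0.0]  # ties excluded
    n = d.size
    if n == 0:
        raise ValueError("no untied pairs left after exclusions")
    method = "exact" if n <= 25 and np.unique(np.abs(d)).size == n else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())  # positive-rank-sum convention
    return w_plus, n, float(res.pvalue)


def rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on two groups.

    Observations whose value also occurs in the other group (cross-group
    ties) are excluded from both groups first.  Exact p for group sizes
    <= 25 without remaining ties.  Returns (U, (n1, n2), p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    tied = np.intersect1d(x, y)
    x = x[~np.isin(x, tied)]
    y = y[~np.isin(y, tied)]
    if x.size == 0 or y.size == 0:
        raise ValueError("a group is empty after tie exclusion")
    exact = (
        x.size <= 25
        and y.size <= 25
        and np.unique(np.concatenate([x, y])).size == x.size + y.size
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), (x.size, y.size), float(res.pvalue)


# ---------------------------------------------------------------------------
# study table and synthetic cohorts


REQUIRED_COLUMNS = ("subject", "side", "hydration_state", "roi", "parameter", "value")


def make_study_table(rows) -> pd.DataFrame:
    """Validated long-format study table of per-sample medians."""
    df = pd.DataFrame(rows)
    for c in REQUIRED_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"study table is missing column '{c}'")
    if "excluded" not in df.columns:
        df["excluded"] = False
    key = ["subject", "side", "hydration_state", "roi", "parameter"]
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (subject, side, state, roi, parameter) rows")
    return df


def _compartment_baselines(moduli=DEFAULT_MODULI) -> dict:
    out = {}
    for t in moduli:
        cs, al = shear_speed_and_attenuation(t.G_star_pa)
        out[t.label] = {
            "gd_kpa": t.G_d,
            "gl_kpa": t.G_l,
            "cs_mps": float(np.real(cs)),
            "alpha_per_mm": float(al),
            "upsilon": phase_angle(t.G_d, t.G_l),
        }
    return out


#: Between-subject and within-subject (repeat) SDs per parameter, set to
#: the dispersion scale of healthy-kidney medians at 50 Hz.
BETWEEN_SD = {"gd_kpa": 0.09, "gl_kpa": 0.09, "cs_mps": 0.08, "alpha_per_mm": 0.012, "upsilon": 0.03}
WITHIN_SD = {"gd_kpa": 0.025, "gl_kpa": 0.025, "cs_mps": 0.03, "alpha_per_mm": 0.008, "upsilon": 0.012}


def simulate_cohort(
    n_subjects: int = 10,
    effects: dict | None = None,
    seed: int = 0,
    rois=("cortex", "medulla", "sinus", "vessel"),
    parameters=PARAMETERS,
    sides=("left", "right"),
    moduli=DEFAULT_MODULI,
) -> pd.DataFrame:
    """Synthetic cohort of per-(subject, side, state, ROI) medians.

    Each sample is baseline + subject random effect (between-subject SD) +
    measurement noise (within-subject SD); ``effects`` maps
    ``(roi, parameter)`` to an additive hydration effect applied to the
    hydrated state, e.g. ``{("sinus", "gd_kpa"): -0.02}``.  A null cohort
    (no effects) is exchangeable between states by construction.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    base = _compartment_baselines(moduli)
    rows = []
    for s in range(1, n_subjects + 1):
        subj_shift = {p: rng.normal(0.0, BETWEEN_SD[p]) for p in parameters}
        for side in sides:
            side_shift = {p: rng.normal(0.0, 0.3 * BETWEEN_SD[p]) for p in parameters}
            for roi in rois:
                for p in parameters:
                    mu = base[roi][p] + subj_shift[p] + side_shift[p]
                    for state in ("fasting", "hydrated"):
                        v = mu + rng.normal(0.0, WITHIN_SD[p])
                        if state == "hydrated":
                            v += effects.get((roi, p), 0.0)
                        rows.append(
                            {
                                "subject": f"s{s:02d}",
                                "side": side,
                                "hydration_state": state,
                                "roi": roi,
                                "parameter": p,
                                "value": v,
                                "excluded": False,
                            }
                        )
    return make_study_table(rows)


# ---------------------------------------------------------------------------
# reports


def _active(table: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in table.columns:
        return table[~table["excluded"].astype(bool)]
    return table


def _paired_changes(df: pd.DataFrame) -> pd.DataFrame:
    wide = df.pivot_table(
        index=["subject", "side"], columns="hydration_state", values="value"
    )
    wide = wide.dropna()
    wide["change"] = wide["hydrated"] - wide["fasting"]
    return wide


def hydration_report(
    table: pd.DataFrame,
    rois=None,
    parameters=None,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Fasting-vs-hydrated contrast per (ROI, parameter).

    For every ROI and parameter the paired per-(subject, side) change
    (hydrated minus fasting) is summarized as median +/- SD and tested with
    the two-sided Wilcoxon signed-rank test (ties excluded).  Returns a
    table with columns (contrast, roi, parameter, n, estimate, sd, p,
    stars, significant).  ``holm`` applies a Holm step-down correction
    across the rows (off by default).
    """
    table = _active(make_study_table(table))
    states = set(table["hydration_state"])
    if not {"fasting", "hydrated"} <= states:
        raise ValueError("need both fasting and hydrated states")
    rois = rois or sorted(table["roi"].unique())
    parameters = parameters or [p for p in PARAMETERS if p in set(table["parameter"])]
    rows = []
    for roi in rois:
        for p in parameters:
            sub = table[(table["roi"] == roi) & (table["parameter"] == p)]
            if sub.empty:
                continue
            wide = _paired_changes(sub)
            ch = wide["change"].to_numpy()
            _, n_used, pval = wilcoxon_signed_rank(ch)
            rows.append(
                {
                    "contrast": "hydrated-fasting",
                    "roi": roi,
                    "parameter": p,
                    "n": int(len(ch)),
                    "estimate": float(np.median(ch)),
                    "sd": float(np.std(ch, ddof=1)) if len(ch) > 1 else 0.0,
                    "p": pval,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable (roi, parameter) cells in the table")
    if holm:
        out["p"] = _holm(out["p"].to_numpy())
    out["stars"] = [stars(p) for p in out["p"]]
    out["significant"] = out["p"] <= alpha
    return out


def roi_contrast_report(
    table: pd.DataFrame,
    pairs,
    parameters=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Unpaired ROI-vs-ROI contrasts on the pooled sample (rank-sum)."""
    table = _active(make_study_table(table))
    parameters = parameters or [p for p in PARAMETERS if p in set(table["parameter"])]
    rows = []
    for a, b in pairs:
        for p in parameters:
            xa = table[(table["roi"] == a) & (table["parameter"] == p)]["value"].to_numpy()
            xb = table[(table["roi"] == b) & (table["parameter"] == p)]["value"].to_numpy()
            if xa.size == 0 or xb.size == 0:
                raise ValueError(f"ROI pair ({a}, {b}) has an empty group")
            _, _, pval = rank_sum(xa, xb)
            rows.append(
                {
                    "contrast": f"{a}-{b}",
                    "parameter": p,
                    "n": int(xa.size + xb.size),
                    "estimate": float(np.median(xa) - np.median(xb)),
                    "p": pval,
                    "stars": stars(pval),
                    "significant": pval <= alpha,
                }
            )
    return pd.DataFrame(rows)


def hydration_difference_report(
    table: pd.DataFrame,
    pairs=(("cortex", "sinus"),),
    parameters=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hydration change of ROI-pair differences (e.g. cortex minus sinus).

    The per-sample quantity is the first-minus-second ROI difference; its
    hydrated-minus-fasting change is tested with the paired signed-rank
    test per parameter.
    """
    table = _active(make_study_table(table))
    parameters = parameters or [p for p in PARAMETERS if p in set(table["parameter"])]
    rows = []
    for a, b in pairs:
        for p in parameters:
            sub = table[table["parameter"] == p]
            wide = sub.pivot_table(
                index=["subject", "side", "hydration_state"], columns="roi", values="value"
            )
            if a not in wide.columns or b not in wide.columns:
                raise ValueError(f"ROI pair ({a}, {b}) missing from table")
            diff = (wide[a] - wide[b]).reset_index().rename(columns={0: "value"})
            diff.columns = ["subject", "side", "hydration_state", "value"]
            wide2 = _paired_changes(diff)
            ch = wide2["change"].to_numpy()
            _, _, pval = wilcoxon_signed_rank(ch)
            rows.append(
                {
                    "contrast": f"({a}-{b}) hydrated-fasting",
                    "parameter": p,
                    "n": int(len(ch)),
                    "estimate": float(np.median(ch)),
                    "sd": float(np.std(ch, ddof=1)) if len(ch) > 1 else 0.0,
                    "p": pval,
                    "stars": stars(pval),
                    "significant": pval <= alpha,
                }
            )
    return pd.DataFrame(rows)


def left_right_report(table: pd.DataFrame, parameters, alpha: float = 0.05) -> pd.DataFrame:
    """Left-vs-right paired t-tests (used for the QA metrics)."""
    table = _active(make_study_table(table))
    rows = []
    for p in parameters:
        sub = table[table["parameter"] == p]
        wide = sub.pivot_table(
            index=["subject", "hydration_state"], columns="side", values="value"
        ).dropna()
        t, df, pval = paired_t_test(wide["left"].to_numpy(), wide["right"].to_numpy())
        rows.append(
            {
                "contrast": "left-right",
                "parameter": p,
                "n": int(len(wide)) ,
                "estimate": float(np.mean(wide["left"] - wide["right"])),
                "t": t,
                "df": df,
                "p": pval,
                "stars": stars(pval),
                "significant": pval <= alpha,
            }
        )
    return pd.DataFrame(rows)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def type_one_error_rate(
    n_reps: int = 1000,
    n_subjects: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical false-positive rate of the hydration contrast under the null.

    Runs :func:`hydration_report` on ``n_reps`` effect-free cohorts (one
    ROI, one parameter, one side, ``n_subjects`` paired samples) and
    returns the fraction rejected at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cohort = simulate_cohort(
            n_subjects=n_subjects,
            effects=None,
            seed=int(rng.integers(0, 2**31 - 1)),
            rois=("sinus",),
            parameters=("gd_kpa",),
            sides=("left",),
        )
        rep = hydration_report(cohort, alpha=alpha)
        hits += int(rep["significant"].iloc[0])
    return hits / n_reps
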