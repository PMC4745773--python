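"""Biomarker-evaluation statistics, implemented from first principles.

Kaplan-Meier product-limit survival curves, the (Mantel-Cox) log-rank test
for two or more groups, median dichotomization of expression values,
immunohistochemistry (IHC) intensity scoring from integrated optical density
(IOD) measurements, a two-sided Fisher exact test for 2x2 tables, and ROC
curve construction with trapezoidal AUC and Youden-index cutoff selection.

These are the statistics a candidate marker is judged by once the
prioritization pipeline has nominated it: does high expression predict worse
survival (KM + log-rank on a median or staining split), does positivity
associate with clinical variables (Fisher/chi-square), and how well does the
circulating concentration separate cases from controls (ROC/AUC and the
sensitivity/specificity-optimal cutoff)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HIGHER = "higher_than_median"
LOWER = "lower_than_median"


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one group.

    Parameters
    ----------
    times
        Follow-up times (> 0); event or censoring time per subject.
    events
        1/True where death (event) was observed, 0/False for censoring.

    Returns a table with one row per distinct event time: ``time``,
    ``n_risk`` (subjects at risk just before the time), ``n_events``,
    ``n_censored`` (censorings at exactly that time, which leave the risk
    set after it), and the survival estimate ``survival``.  S(0) = 1 and the
    estimate is a right-continuous, non-increasing step function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group")
    if (times <= 0).any():
        raise ValueError("times must be > 0")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n_risk = times.size
    for t in np.unique(times):
        at_t = times == t
        d = int(np.sum(at_t & events))
        c = int(np.sum(at_t & ~events))
        if d > 0:
            s *= 1.0 - d / n_risk
            rows.append(
                {"time": t, "n_risk": n_risk, "n_events": d,
                 "n_censored": c, "survival": s}
            )
        n_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events",
                                       "n_censored", "survival"])


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a :func:`km_curve` table at time ``t`` (right-continuous)."""
    past = curve[curve["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(*groups) -> tuple[float, float, int]:
    """Mantel-Cox log-rank test across two or more groups.

    Each group is a ``(times, events)`` pair.  At every pooled event time the
    observed events per group are compared with the expectation under the
    null of identical hazards, conditioning on the risk sets; ties are
    handled by the hypergeometric variance and censorings at an event time
    leave the risk set after it (events processed first).

    Returns ``(chi2, p, df)`` with ``df = n_groups - 1``.  For two groups the
    statistic is the familiar scalar form sum(O-E)^2 summed over event times
    divided by the summed variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError("empty group")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    t_all = np.concatenate(times)
    e_all = np.concatenate(events)
    g_all = np.concatenate(labels)
    if not e_all.any():
        raise ValueError("no events observed in any group")

    k = len(groups)
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(t_all[e_all]):
        at_risk = t_all >= t
        n = int(at_risk.sum())
        d = int((e_all & (t_all == t)).sum())
        if n == 0 or d == 0:
            continue
        n_g = np.array([(at_risk & (g_all == g)).sum() for g in range(k)], float)
        d_g = np.array(
            [((e_all) & (t_all == t) & (g_all == g)).sum() for g in range(k)], float
        )
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1)
            cov += v * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[: k - 1]
    vmat = cov[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p, df


def dichotomize_by_median(values, tie_policy: str = "lower") -> np.ndarray:
    """Split subjects into higher- and lower-than-median groups.

    Values equal to the median go to the lower group by default
    (``tie_policy="lower"``); with ``tie_policy="exclude"`` they are labelled
    with the empty string and drop out of downstream comparisons.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    med = float(np.median(values))
    if np.all(values == med):
        warnings.warn("all values equal the median; every subject labelled lower",
                      stacklevel=2)
    if tie_policy == "lower":
        return np.where(values > med, HIGHER, LOWER)
    if tie_policy == "exclude":
        out = np.where(values > med, HIGHER, LOWER)
        return np.where(values == med, "", out)
    raise ValueError(f"unknown tie_policy {tie_policy!r}")


# ---------------------------------------------------------------------------
# IHC scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IhcScore:
    intensity: float  # mean of per-image IOD/area
    positive: bool


def ihc_score(iod, area, cutoff: float = 0.043) -> IhcScore:
    """Score one sample-region from its per-image IOD and area values.

    The intensity is the mean over images of IOD/area; the sample-region is
    called positive when intensity is strictly above ``cutoff`` (the default
    cutoff separates negative from positive staining in ranked samples).
    """
    iod = np.asarray(iod, dtype=float)
    area = np.asarray(area, dtype=float)
    if iod.size == 0 or iod.shape != area.shape:
        raise ValueError("need matching, non-empty IOD and area vectors")
    if (area <= 0).any():
        raise ValueError("area must be > 0 for every image")
    if (iod < 0).any():
        raise ValueError("IOD must be >= 0")
    intensity = float(np.mean(iod / area))
    return IhcScore(intensity=intensity, positive=intensity > cutoff)


def score_ihc_table(measurements: pd.DataFrame, cutoff: float = 0.043) -> pd.DataFrame:
    """Score every (sample, region) of an IHC measurement table.

    Columns: ``sample``, ``region``, ``iod``, ``area`` (one row per image).
    """
    rows = []
    for (sample, region), g in measurements.groupby(["sample", "region"]):
        sc = ihc_score(g["iod"], g["area"], cutoff=cutoff)
        rows.append(
            {"sample": sample, "region": region,
             "intensity": sc.intensity, "positive": sc.positive}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by hypergeometric enumeration.

    All tables with the observed margins are enumerated; the p value sums the
    probabilities of every table no more likely than the observed one (the
    usual two-sided convention), with a small relative tolerance against
    floating-point ties.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def association_test(table, min_expected: float = 5.0) -> dict:
    """Fisher's exact test or Pearson chi-square, chosen by expected counts.

    Fisher is used when any expected cell count is below ``min_expected``;
    otherwise the (uncorrected) chi-square test.
    """
    t = np.asarray(table, dtype=float)
    expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
    if (expected < min_expected).any():
        return {"method": "fisher", "p": fisher_exact_2x2(table)}
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return {"method": "chi2", "p": float(p), "chi2": float(chi2)}


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_points(concentrations, is_case) -> pd.DataFrame:
    """ROC curve over all observed cutoffs, cases assumed higher.

    Every observed concentration is swept as a threshold; a subject is
    called positive when its concentration is >= the threshold.  The table
    is ordered by increasing false-positive rate and includes the (0,0)
    (threshold above the maximum) and (1,1) endpoints.  Columns:
    ``threshold``, ``fpr`` (1 - specificity), ``tpr`` (sensitivity).

    A warning is emitted when the resulting AUC is below 0.5 (the marker
    discriminates in the opposite orientation).
    """
    conc = np.asarray(concentrations, dtype=float)
    case = np.asarray(is_case, dtype=bool)
    n_case = int(case.sum())
    n_ctrl = int((~case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need at least one case and one control")

    thresholds = np.unique(conc)[::-1]  # descending: (0,0) -> (1,1)
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in thresholds:
        called = conc >= thr
        rows.append(
            {
                "threshold": float(thr),
                "fpr": float((called & ~case).sum() / n_ctrl),
                "tpr": float((called & case).sum() / n_case),
            }
        )
    curve = pd.DataFrame(rows)
    if auc(curve) < 0.5:
        warnings.warn(
            "AUC < 0.5: marker appears lower in cases; consider flipping "
            "the orientation", stacklevel=2,
        )
    return curve


def auc(curve: pd.DataFrame) -> float:
    """Area under a :func:`roc_points` curve by the trapezoid rule.

    Equals the Mann-Whitney U statistic divided by ``n_case * n_control``,
    with half credit for concentration ties.
    """
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


def optimal_cutoff(curve: pd.DataFrame) -> dict:
    """Cutoff maximizing sensitivity + specificity (the Youden index).

    Ties are broken toward the lower cutoff.  Returns the cutoff
    concentration with its sensitivity and specificity (fractions in
    [0, 1]).
    """
    finite = curve[np.isfinite(curve["threshold"])]
    j = finite["tpr"] - finite["fpr"]
    best = j.max()
    winners = finite[np.isclose(j, best)]
    row = winners.loc[winners["threshold"].idxmin()]
    return {
        "cutoff": float(row["threshold"]),
        "sensitivity": float(row["tpr"]),
        "specificity": float(1.0 - row["fpr"]),
        "youden": float(best),
    }


def roc_analysis(concentrations, is_case) -> dict:
    """Full ROC summary: curve, AUC, and the Youden-optimal cutoff."""
    curve = roc_points(concentrations, is_case)
    return {"curve": curve, "auc": auc(curve), **optimal_cutoff(curve)}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["event"] = df["event"].astype(int).astype(bool)
    return df


def read_plasma(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_case"] = df["is_case"].astype(int).astype(bool)
    return df


def read_ihc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
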