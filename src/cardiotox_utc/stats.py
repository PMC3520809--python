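"""Statistical inference chain.

The longitudinal design is collapsed to one value per animal by per-animal
ordinary-least-squares slopes of each measurement against cumulative dose
("beta coefficients"), removing the repeated-measures dependence. Group
comparisons use Kruskal-Wallis; slope-collagen association uses Spearman
rank correlation; disease labelling uses a control-derived collagen
threshold (control mean + k*SD, k=2 by default); and biomarker accuracy
uses ROC analysis with the rank (Mann-Whitney) AUC estimator, a DeLong
confidence interval (seeded bootstrap as an option) and a Youden-J operating
cutoff with ties broken toward higher specificity. Sample SDs use the n-1
denominator throughout, and p-values are reported raw (no multiplicity
correction is applied, matching the source analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
    UndefinedCorrelationError,
)


@dataclass
class BetaCoefficient:
    """Per-animal OLS slope of one variable against cumulative dose."""

    animal_id: int | str
    variable: str
    slope: float
    intercept: float
    n_points: int


@dataclass
class ThresholdSpec:
    """Control-derived disease threshold: mean + k*SD of control values."""

    control_mean: float
    control_sd: float
    k: float
    threshold: float


@dataclass
class ROCResult:
    """ROC accuracy summary for one score against a binary disease label."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    n_pos: int
    n_neg: int


def per_animal_beta(
    doses: Sequence[float],
    values: Sequence[float],
    animal_id: int | str = "",
    variable: str = "",
) -> BetaCoefficient:
    """OLS slope of a measurement on cumulative dose for a single animal."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("need >= 2 paired (dose, value) points")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all doses identical; slope undefined")
    res = sps.linregress(x, y)
    return BetaCoefficient(
        animal_id=animal_id,
        variable=variable,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=int(x.size),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with g-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InputError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(flat).size == 1:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedCorrelationError("zero variance in a ranked vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def derive_threshold(control_values: Sequence[float], k: float = 2.0) -> ThresholdSpec:
    """Disease threshold from control collagen values: mean + k * sample SD."""
    vals = np.asarray(control_values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 control values for a threshold")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return ThresholdSpec(control_mean=mean, control_sd=sd, k=k, threshold=mean + k * sd)


# ---------------------------------------------------------------------------
# ROC machinery


def _check_binary(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InputError("both classes must be present")
    return labels, ~labels


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank (Mann-Whitney) AUC estimator with half-credit for ties."""
    s = np.asarray(scores, dtype=float)
    pos, neg = _check_binary(np.asarray(labels))
    ranks = sps.rankdata(s)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def delong_ci(
    scores: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> Tuple[float, float, float]:
    """AUC with DeLong variance-based confidence interval.

    Uses the structural components of the Mann-Whitney statistic:
    ``V10[i] = P(score_i > neg) + 0.5*P(score_i = neg)`` over negatives for
    each positive i (and symmetrically ``V01``), giving
    ``var(AUC) = S10/m + S01/n``.
    """
    s = np.asarray(scores, dtype=float)
    pos_mask, neg_mask = _check_binary(np.asarray(labels))
    x = s[pos_mask]
    y = s[neg_mask]
    m, n = x.size, y.size
    # pairwise comparison matrix with half-credit for ties
    diff = x[:, None] - y[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """Stratified percentile-bootstrap AUC confidence interval (seeded)."""
    s = np.asarray(scores, dtype=float)
    pos_mask, neg_mask = _check_binary(np.asarray(labels))
    x, y = s[pos_mask], s[neg_mask]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(x.size, bool), np.zeros(y.size, bool)])
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        aucs[b] = mann_whitney_auc(np.concatenate([xb, yb]), lab)
    auc = mann_whitney_auc(s, np.asarray(labels))
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(auc), float(lo), float(hi)


def cutoff_performance(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> Tuple[float, float]:
    """Sensitivity and specificity (%) calling disease when score >= cutoff."""
    if not np.isfinite(cutoff):
        raise InputError("cutoff must be finite")
    s = np.asarray(scores, dtype=float)
    pos, neg = _check_binary(np.asarray(labels))
    called = s >= cutoff
    sens = 100.0 * float((called & pos).sum()) / float(pos.sum())
    spec = 100.0 * float((~called & neg).sum()) / float(neg.sum())
    return sens, spec


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Operating cutoff maximizing Youden's J; ties go to higher specificity.

    Candidate cutoffs are the observed score values (plus one above the
    maximum); a higher cutoff never lowers specificity, so ties are broken
    toward the larger cutoff.
    """
    s = np.asarray(scores, dtype=float)
    _check_binary(np.asarray(labels))
    candidates = np.unique(s)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    best_cut, best_j = candidates[0], -np.inf
    for c in candidates:
        sens, spec = cutoff_performance(s, labels, c)
        j = sens + spec - 100.0
        if j > best_j or (j == best_j and c > best_cut):
            best_j, best_cut = j, c
    return float(best_cut)


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci: str = "delong",
    seed: int = 0,
) -> ROCResult:
    """Full ROC accuracy summary: AUC, CI, Youden cutoff and its operating point."""
    labels = np.asarray(labels, dtype=bool)
    if ci == "delong":
        auc, lo, hi = delong_ci(scores, labels)
    elif ci == "bootstrap":
        auc, lo, hi = bootstrap_ci(scores, labels, seed=seed)
    else:
        raise InputError(f"unknown CI method {ci!r}")
    cutoff = youden_cutoff(scores, labels)
    sens, spec = cutoff_performance(scores, labels, cutoff)
    return ROCResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        cutoff=cutoff,
        sensitivity_pct=sens,
        specificity_pct=spec,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


def categorical_test(table: np.ndarray) -> Tuple[str, float]:
    """Fisher's exact test for 2x2 tables, chi-square otherwise."""
    t = np.asarray(table, dtype=float)
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t)
        return "fisher", float(p)
    _, p, _, _ = sps.chi2_contingency(t)
    return "chi2", float(p)


# ---------------------------------------------------------------------------
# tabular summaries


def summarize_groups(
    records: pd.DataFrame,
    value_col: str = "value",
    variable_col: str = "variable",
    dose_col: str = "dose_mg_per_kg",
) -> pd.DataFrame:
    """Per-dose summary per variable: n, mean, SD and SE.

    Emits both the SD and the SE column so either reading of a printed
    "mean ± spread" table can be compared against. Groups of size one get a
    NaN spread (flagged by ``se`` being NaN).
    """
    rows = []
    for (var, dose), grp in records.groupby([variable_col, dose_col], sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "variable": var,
                "dose_mg_per_kg": dose,
                "n": n,
                "mean": float(vals.mean()),
                "sd": sd,
                "se": sd / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def betas_by_animal(
    records: pd.DataFrame,
    value_col: str = "value",
    variable_col: str = "variable",
    dose_col: str = "dose_mg_per_kg",
    id_col: str = "animal_id",
) -> pd.DataFrame:
    """Beta coefficients for every (animal, variable) with >= 2 distinct doses."""
    rows = []
    for (animal, var), grp in records.groupby([id_col, variable_col], sort=True):
        grp = grp.sort_values(dose_col)
        doses = grp[dose_col].to_numpy(dtype=float)
        if np.unique(doses).size < 2:
            continue
        beta = per_animal_beta(doses, grp[value_col].to_numpy(dtype=float), animal, var)
        rows.append(
            {
                "animal_id": animal,
                "variable": var,
                "slope": beta.slope,
                "intercept": beta.intercept,
                "n_points": beta.n_points,
            }
        )
    return pd.DataFrame(rows)
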