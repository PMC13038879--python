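"""Between-group statistics and clinical correlations.

Three separate test families, each with its own multiplicity handling:

* **Edges** — per (state, edge) two-sided Welch's t-test on Fisher-z
  connectivity (heteroscedasticity-robust), with Benjamini-Hochberg FDR
  applied once across the pooled family of all states' edges.
* **Temporal metrics** (FO, MDT, switching rate) — a normality gate
  (Shapiro-Wilk per group at alpha 0.05 plus median-centered Levene at
  alpha 0.05) chooses Student's t for normal homoscedastic data and
  two-sided tie-corrected Mann-Whitney U otherwise.  Per-state p-values
  are BH-adjusted within each metric family (m = K states), and because
  these state-wise tests are declared exploratory, raw p-values are
  reported alongside q.
* **Transitions** — per directed cell (i -> j, self-transitions included)
  the subject transition probabilities are variance-stabilized with the
  arcsine square-root transform, gated the same way, and BH-adjusted
  across all K^2 directed cells.

Every comparison reports two effect sizes: Cohen's d with the
equal-weight pooled SD, d = (mean_2 - mean_1) / sqrt((SD_1^2 + SD_2^2)/2),
and the rank-biserial correlation 1 - 2U/(n_1 n_2), with U counting
(group-1, group-2) pairs in which the group-1 value is larger (ties half)
— so both effects are positive when group 2 (patients) is larger.

Clinical correlations are patients-only, pairwise-complete, Pearson when
both variables pass Shapiro-Wilk and Spearman otherwise, reported
uncorrected and flagged exploratory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import StateFCEntry

logger = logging.getLogger(__name__)

ALPHA_GATE = 0.05


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, mapped
    back to input order and capped at 1.  NaN inputs propagate to NaN
    outputs (with a warning) and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    finite = np.isfinite(p)
    if not finite.all():
        logger.warning("bh_fdr: %d NaN p-value(s) propagated",
                       int((~finite).sum()))
    q = np.full_like(p, np.nan)
    if finite.any():
        sub = p[finite]
        if sub.min() < 0 or sub.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        q[finite] = multipletests(sub, method="fdr_bh")[1]
    return q


def cohen_d(group1: np.ndarray, group2: np.ndarray) -> float:
    """(mean_2 - mean_1) / sqrt((SD_1^2 + SD_2^2) / 2), sample SDs."""
    a, b = np.asarray(group1, float), np.asarray(group2, float)
    pooled = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
    if pooled == 0:
        return 0.0 if np.mean(b) == np.mean(a) else np.inf
    return float((b.mean() - a.mean()) / pooled)


def rank_biserial_from_u(u: float, n1: int, n2: int) -> float:
    """1 - 2U/(n1 n2); U counts group-1-larger pairs (ties half)."""
    return float(1.0 - 2.0 * u / (n1 * n2))


@dataclass
class GroupTestResult:
    family: str
    identifier: str
    test_used: str
    stat: float
    p: float
    q: float
    cohen_d: float
    rank_biserial: float
    n1: int
    n2: int


def _normal(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue >= ALPHA_GATE


def _gate(group1: np.ndarray, group2: np.ndarray) -> bool:
    """True -> Student's t applies (both normal, homoscedastic)."""
    if not (_normal(group1) and _normal(group2)):
        return False
    return sps.levene(group1, group2,
                      center="median").pvalue >= ALPHA_GATE


def compare_metric(group1: np.ndarray, group2: np.ndarray,
                   identifier: str,
                   family: str = "metric") -> GroupTestResult:
    """Normality-gated two-group comparison with both effect sizes.

    group1 is the reference arm (controls); group2 the patients, so
    positive effects mean patients are larger.  Missing values must be
    dropped by the caller.  q is filled in later by the family adjustment.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"{identifier}: need >= 3 values per group")
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if degenerate and a.mean() == b.mean():
        logger.warning("%s: zero variance in both groups", identifier)
    u = float(sps.mannwhitneyu(a, b, alternative="two-sided").statistic)
    if _gate(a, b):
        res = sps.ttest_ind(a, b, equal_var=True)
        test_used, stat, p = "student_t", float(res.statistic), \
            float(res.pvalue)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_used, stat, p = "mannwhitney_u", u, float(res.pvalue)
    return GroupTestResult(
        family=family, identifier=identifier, test_used=test_used,
        stat=stat, p=p, q=np.nan, cohen_d=cohen_d(a, b),
        rank_biserial=rank_biserial_from_u(u, len(a), len(b)),
        n1=len(a), n2=len(b))


def compare_metric_family(values_by_state: dict[str, tuple[np.ndarray,
                                                           np.ndarray]],
                          family: str) -> pd.DataFrame:
    """One comparison per state, BH-adjusted within the family (m = K)."""
    results = [compare_metric(a, b, identifier=name, family=family)
               for name, (a, b) in values_by_state.items()]
    df = pd.DataFrame([asdict(r) for r in results])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def edgewise_welch(entries: list[StateFCEntry], groups: dict[str, str],
                   n_states: int,
                   min_subjects: int = 2) -> pd.DataFrame:
    """Welch's t per (state, edge) with one pooled BH family.

    Only subjects with a present matrix (>= the frame threshold) in a
    state contribute to that state's tests.  A state with fewer than
    ``min_subjects`` present subjects in either group is skipped entirely
    (logged); its edges never enter the BH family.
    """
    frames = []
    for state in range(n_states):
        by_group: dict[str, list[np.ndarray]] = {"control": [],
                                                 "patient": []}
        for e in entries:
            if e.state == state and e.present:
                by_group[groups[e.subject_id]].append(e.matrix)
        n1, n2 = len(by_group["control"]), len(by_group["patient"])
        if n1 < min_subjects or n2 < min_subjects:
            logger.warning("state %d skipped in edge tests: %d control, "
                           "%d patient matrices", state + 1, n1, n2)
            continue
        n = by_group["control"][0].shape[0]
        iu, ju = np.triu_indices(n, k=1)
        a = np.stack(by_group["control"])[:, iu, ju]   # n1 x n_edges
        b = np.stack(by_group["patient"])[:, iu, ju]
        res = sps.ttest_ind(a, b, axis=0, equal_var=False)
        mean_diff = b.mean(axis=0) - a.mean(axis=0)
        pooled = np.sqrt((a.std(axis=0, ddof=1) ** 2
                          + b.std(axis=0, ddof=1) ** 2) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(pooled > 0, mean_diff / pooled, 0.0)
        frames.append(pd.DataFrame({
            "state": state + 1, "roi_i": iu + 1, "roi_j": ju + 1,
            "test": "welch_t", "stat": res.statistic, "p": res.pvalue,
            "cohen_d": d, "n1": n1, "n2": n2}))
    if not frames:
        return pd.DataFrame(columns=["state", "roi_i", "roi_j", "test",
                                     "stat", "p", "q", "cohen_d",
                                     "n1", "n2"])
    df = pd.concat(frames, ignore_index=True)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def arcsine_sqrt(p: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform for proportions, asin(sqrt(p))."""
    return np.arcsin(np.sqrt(np.clip(np.asarray(p, float), 0.0, 1.0)))


def compare_tpm(tpms_by_group: dict[str, list[tuple[np.ndarray,
                                                    np.ndarray]]],
                min_subjects: int = 2) -> pd.DataFrame:
    """Per directed cell (i -> j) group comparison of transition
    probabilities after arcsine square-root transformation.

    ``tpms_by_group[group]`` is a list of (tpm, empty_rows) pairs; a
    subject contributes cell (i, j) only when their row i had at least
    one outgoing transition.  BH runs across all tested directed cells.
    """
    k = tpms_by_group["control"][0][0].shape[0]
    rows = []
    for i in range(k):
        for j in range(k):
            vals = {}
            for g in ("control", "patient"):
                vals[g] = np.array([tpm[i, j]
                                    for tpm, empty in tpms_by_group[g]
                                    if not empty[i]])
            if len(vals["control"]) < max(min_subjects, 3) \
                    or len(vals["patient"]) < max(min_subjects, 3):
                logger.warning("transition %d->%d skipped: too few "
                               "subjects", i + 1, j + 1)
                continue
            a = arcsine_sqrt(vals["control"])
            b = arcsine_sqrt(vals["patient"])
            r = compare_metric(a, b, identifier=f"S{i + 1}->S{j + 1}",
                               family="transition")
            row = asdict(r)
            row["from_state"], row["to_state"] = i + 1, j + 1
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def clinical_correlations(metrics: pd.DataFrame, clinical: pd.DataFrame,
                          min_n: int = 3,
                          method: str = "auto") -> pd.DataFrame:
    """Exploratory metric x clinical correlations (patients only).

    Pairwise-complete observations; with ``method="auto"`` each pair
    uses Pearson when both variables pass Shapiro-Wilk at alpha 0.05 and
    Spearman otherwise; ``"pearson"``/``"spearman"`` force one
    estimator.  Two-sided uncorrected p.  Constant variables are skipped
    with a warning.
    """
    if method not in ("auto", "pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    common = metrics.index.intersection(clinical.index)
    met = metrics.loc[common]
    clin = clinical.loc[common]
    for mcol in met.columns:
        for ccol in clin.columns:
            pair = pd.concat([met[mcol], clin[ccol]], axis=1).dropna()
            if len(pair) < min_n:
                continue
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlation %s ~ %s skipped: constant "
                               "variable", mcol, ccol)
                continue
            if method == "auto":
                used = "pearson" if _normal(x) and _normal(y) \
                    else "spearman"
            else:
                used = method
            if used == "pearson":
                r, p = sps.pearsonr(x, y)
            else:
                r, p = sps.spearmanr(x, y)
            rows.append({"metric": mcol, "clinical": ccol,
                         "method": used, "r": float(r), "p": float(p),
                         "n": len(pair), "note": "exploratory"})
    return pd.DataFrame(rows)
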