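"""Group statistics for S vs AS descriptor comparisons.

The battery mirrors a standard two-group descriptor analysis with
unequal group sizes: Shapiro-Wilk and Levene assumption checks
(advisory), Welch's t-test with Welch-Satterthwaite degrees of freedom,
bias-corrected Hedges' g, univariate ROC analysis with the Youden
operating point, and Fleiss' kappa for rater-panel agreement.

Sign convention: t and g are computed as AS minus S, so descriptors
that are higher in the symmetric group yield negative values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .config import PipelineConfig
from .model import DegenerateDataError, RaterPanel, SymmetryLabel, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    descriptor_name: str
    t: float
    df: float
    p: float
    g: float
    shapiro_p_S: float | None
    shapiro_p_AS: float | None
    levene_p: float | None
    n_S: int
    n_AS: int
    significant: bool = False
    p_adjusted: float | None = None


@dataclass
class ROCResult:
    descriptor_name: str
    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    youden_threshold: float
    youden_j: float
    positive_class: str
    separability: float = 0.0  # max(auc, 1 - auc)


@dataclass
class KappaResult:
    kappa: float
    n_items: int
    n_raters: int
    n_categories: int


@dataclass
class GroupComparisonReport:
    exercise: str
    comparisons: list[GroupComparison]
    alpha: float = 0.05
    ranked_by_g: list[str] = field(default_factory=list)
    ranked_by_auc: list[str] = field(default_factory=list)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, df, two-sided p).

    t = (mean_a - mean_b) / sqrt(s²_a/n_a + s²_b/n_b), with degrees of
    freedom from the Welch-Satterthwaite equation and the p-value from
    Student's t distribution at that (real-valued) df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DegenerateDataError("Welch's t-test needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sea, seb = va / na, vb / nb
    se2 = sea + seb
    if se2 <= 0:
        raise DegenerateDataError("both groups have zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (sea**2 / (na - 1) + seb**2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def hedges_g(group_a, group_b) -> float:
    """Bias-corrected standardized mean difference (a minus b).

    g = J * (mean_a - mean_b) / s_pooled with the (n_a+n_b-2)-df pooled
    SD and small-sample correction J = 1 - 3 / (4(n_a+n_b-2) - 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DegenerateDataError("Hedges' g needs n >= 2 per group")
    dof = na + nb - 2
    s_pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof)
    if s_pooled <= 0:
        raise DegenerateDataError("zero pooled variance")
    correction = 1.0 - 3.0 / (4.0 * dof - 1.0)
    return float(correction * (a.mean() - b.mean()) / s_pooled)


def assumption_checks(
    group_a, group_b
) -> tuple[float | None, float | None, float | None]:
    """Shapiro-Wilk p per group and Levene p (median-centered).

    Advisory only: Welch's test is applied regardless. Degenerate groups
    (too small or constant) skip the corresponding check with a warning,
    returning None in its slot.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)

    def _shapiro(x) -> float | None:
        if x.size < 3 or np.ptp(x) == 0:
            logger.warning("Shapiro-Wilk skipped: group too small or constant")
            return None
        return float(sps.shapiro(x).pvalue)

    levene_p: float | None
    if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
        logger.warning("Levene test skipped: degenerate groups")
        levene_p = None
    else:
        levene_p = float(sps.levene(a, b, center="median").pvalue)
    return _shapiro(a), _shapiro(b), levene_p


def roc_analysis(
    scores, labels, positive_class: str = "S", descriptor_name: str = ""
) -> ROCResult:
    """Empirical ROC over all distinct thresholds with the Youden point.

    AUC is the trapezoid area, equal to the Mann-Whitney concordance
    probability with half-credit for ties. The operating point maximizes
    J = TPR - FPR; ties are broken toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([SymmetryLabel(l).value for l in labels], dtype=object)
    classes = set(labels.tolist())
    if len(classes) < 2:
        raise DegenerateDataError(f"ROC needs both classes, got only {sorted(classes)}")
    fpr, tpr, thresholds = roc_curve(labels, scores, pos_label=positive_class)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    # sklearn thresholds are decreasing; the last argmax is the lowest threshold
    ties = np.flatnonzero(j == best_j)
    best = int(ties[-1])
    return ROCResult(
        descriptor_name=descriptor_name,
        auc=auc,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        youden_threshold=float(thresholds[best]),
        youden_j=float(best_j),
        positive_class=positive_class,
        separability=float(max(auc, 1.0 - auc)),
    )


def fleiss_kappa(panel: RaterPanel) -> KappaResult:
    """Fleiss' chance-corrected agreement over a complete ratings matrix."""
    categories = sorted(set(map(str, panel.ratings.ravel())))
    counts = np.stack(
        [(panel.ratings == cat).sum(axis=1) for cat in categories], axis=1
    ).astype(float)
    n = panel.n_raters
    if panel.n_items < 2:
        raise DegenerateDataError("Fleiss' kappa needs >= 2 items")
    p_cat = counts.sum(axis=0) / (panel.n_items * n)
    p_expected = float(np.sum(p_cat**2))
    if p_expected >= 1.0:
        raise DegenerateDataError(
            "all ratings fall in one category: expected agreement is 1 and "
            "Fleiss' kappa is undefined"
        )
    p_item = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_observed = float(p_item.mean())
    kappa = (p_observed - p_expected) / (1.0 - p_expected)
    return KappaResult(float(kappa), panel.n_items, n, len(categories))


def majority_label(panel: RaterPanel) -> list[SymmetryLabel]:
    """Per-item label held by more than half of the raters (2/3 rule for 3)."""
    out = []
    half = panel.n_raters / 2.0
    for i, row in enumerate(panel.ratings):
        vals, counts = np.unique(row.astype(str), return_counts=True)
        top = counts.max()
        if top <= half:
            raise DegenerateDataError(
                f"item {panel.recording_ids[i]!r}: no label reaches a majority "
                f"({panel.n_raters} raters tied)"
            )
        out.append(SymmetryLabel(vals[counts.argmax()]))
    return out


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def compare_groups(
    table: pd.DataFrame,
    alpha: float = 0.05,
    config: PipelineConfig | None = None,
    exercise: str = "",
) -> tuple[GroupComparisonReport, list[ROCResult]]:
    """Full descriptor battery over a wide or long descriptor table.

    Accepts the long (recording x feature) descriptor table or the wide
    per-recording matrix; compares every ``<feature>_<stat>`` descriptor
    between the AS and S groups (Welch t, Hedges' g, assumption checks,
    significance at ``alpha``) and runs per-descriptor ROC analysis.
    Descriptors are ranked by |g| and by AUC of the configured positive
    class.
    """
    from .descriptors import descriptor_matrix

    config = config or PipelineConfig()
    if "feature" in table.columns:
        wide = descriptor_matrix(table)
    else:
        wide = table
    if "label" not in wide.columns or wide["label"].isna().any():
        raise ValidationError("descriptor table lacks S/AS labels for some recordings")
    labels = wide["label"].astype(str)
    present = set(labels)
    if present != {"S", "AS"}:
        raise DegenerateDataError(
            f"group comparison needs both S and AS labels, got {sorted(present)}"
        )
    s_mask = labels == "S"
    as_mask = labels == "AS"
    if s_mask.sum() < 2 or as_mask.sum() < 2:
        raise DegenerateDataError("each group needs n >= 2 recordings")

    comparisons: list[GroupComparison] = []
    rocs: list[ROCResult] = []
    desc_cols = [c for c in wide.columns if c != "label"]
    for col in desc_cols:
        s_vals = wide.loc[s_mask, col].to_numpy(dtype=float)
        as_vals = wide.loc[as_mask, col].to_numpy(dtype=float)
        all_vals = wide[col].to_numpy(dtype=float)
        # a descriptor constant up to floating rounding (e.g. the MAD of a
        # MAD-normalized series is identically 1) carries no information;
        # testing its epsilon-level noise would be meaningless
        constant = np.ptp(all_vals) <= 1e-9 * max(1.0, float(np.abs(all_vals).max()))
        sh_s, sh_as, lev = assumption_checks(s_vals, as_vals)
        try:
            if constant:
                raise DegenerateDataError(f"descriptor {col} is constant")
            t, df, p = welch_t_test(as_vals, s_vals)
            g = hedges_g(as_vals, s_vals)
        except DegenerateDataError:
            # e.g. the MAD of a MAD-normalized series is identically 1 in
            # every recording; report the descriptor but without a test
            logger.warning("descriptor %s has zero variance in both groups; "
                           "no test performed", col)
            t = df = p = g = float("nan")
        comparisons.append(
            GroupComparison(
                descriptor_name=col, t=t, df=df, p=p, g=g,
                shapiro_p_S=sh_s, shapiro_p_AS=sh_as, levene_p=lev,
                n_S=int(s_mask.sum()), n_AS=int(as_mask.sum()),
            )
        )
        rocs.append(
            roc_analysis(
                wide[col].to_numpy(dtype=float), labels.to_numpy(),
                config.roc_positive_class, col,
            )
        )
    if config.holm_correction:
        tested = [c for c in comparisons if np.isfinite(c.p)]
        adj = _holm([c.p for c in tested])
        for c, pa in zip(tested, adj):
            c.p_adjusted = pa
            c.significant = pa < alpha
    else:
        for c in comparisons:
            c.significant = bool(np.isfinite(c.p) and c.p < alpha)

    ranked_g = [c.descriptor_name for c in
                sorted(comparisons,
                       key=lambda c: -abs(c.g) if np.isfinite(c.g) else np.inf)]
    g_by_name = {c.descriptor_name: abs(c.g) if np.isfinite(c.g) else -np.inf
                 for c in comparisons}
    # AUC ties (common under perfect separation) break toward the larger
    # effect size, then lexicographically for determinism
    ranked_auc = [r.descriptor_name for r in
                  sorted(rocs, key=lambda r: (-r.auc, -g_by_name[r.descriptor_name],
                                              r.descriptor_name))]
    report = GroupComparisonReport(
        exercise=exercise, comparisons=comparisons, alpha=alpha,
        ranked_by_g=ranked_g, ranked_by_auc=ranked_auc,
    )
    return report, rocs
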