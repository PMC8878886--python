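"""Group-differentiation statistics.

Univariate region comparison with data-driven test selection (Student's t
for normal/equal-variance data, Welch for normal/unequal-variance,
Kruskal-Wallis otherwise), clinical-score associations (ANOVA or
Kruskal-Wallis across ordinal CDR groups; linear correlation for CDR-SoB and
MMSE), PCA on standardized region values, overall loading factors
(loading coefficient x mean/SD) with top/bottom-50% contributor selection,
unidirectional metabolite attribution, and ROC analysis of component scores.

P-values are reported raw (uncorrected); Benjamini-Hochberg adjustment is
available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .regions import RegionDefinition, RegionMatrix

__all__ = [
    "PCAResult",
    "ROCResult",
    "select_univariate_test",
    "univariate_compare",
    "clinical_association",
    "run_pca",
    "overall_loading_factors",
    "select_contributors",
    "unidirectional_metabolites",
    "roc_analysis",
]


# --------------------------------------------------------------------------
# univariate tests
# --------------------------------------------------------------------------

def select_univariate_test(group_a: np.ndarray, group_b: np.ndarray,
                           alpha: float = 0.05) -> str:
    """Choose the two-group test by the normality / equal-variance gates:
    Shapiro-Wilk on each group, then Brown-Forsythe, both at ``alpha``.

    Returns one of ``student_t``, ``welch``, ``kruskal_wallis``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    normal = True
    for g in (a, b):
        if np.ptp(g) == 0:  # constant sample: Shapiro undefined, treat as non-normal
            normal = False
            break
        if scipy.stats.shapiro(g).pvalue < alpha:
            normal = False
            break
    if not normal:
        return "kruskal_wallis"
    bf_p = scipy.stats.levene(a, b, center="median").pvalue
    return "student_t" if bf_p >= alpha else "welch"


def _run_test(name: str, a: np.ndarray, b: np.ndarray) -> float:
    if name == "student_t":
        return float(scipy.stats.ttest_ind(a, b, equal_var=True).pvalue)
    if name == "welch":
        return float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
    return float(scipy.stats.kruskal(a, b).pvalue)


def univariate_compare(matrix: RegionMatrix, labels: pd.Series,
                       alpha: float = 0.05,
                       bh_adjust: bool = False) -> pd.DataFrame:
    """Per-region two-group comparison, ordered by ascending p.

    ``labels`` maps sample_id -> group; exactly two groups must be present.
    Regions constant in both groups are flagged degenerate with p = 1.
    Returns a DataFrame with region_id, label, test_used, p_value (raw),
    group means and SEs, and optionally BH-adjusted q values.
    """
    ids = [s for s in matrix.sample_ids if s in labels.index]
    lab = labels.loc[ids]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    ga = [s for s in ids if lab[s] == groups[0]]
    gb = [s for s in ids if lab[s] == groups[1]]
    rows = []
    for r in matrix.regions:
        a = matrix.values.loc[ga, r.label].to_numpy()
        b = matrix.values.loc[gb, r.label].to_numpy()
        degenerate = (np.ptp(a) == 0) and (np.ptp(b) == 0)
        if degenerate:
            test, p = "degenerate", 1.0
        else:
            test = select_univariate_test(a, b, alpha)
            p = _run_test(test, a, b)
        rows.append({
            "region_id": r.region_id, "label": r.label, "test_used": test,
            "p_value": p, "degenerate": degenerate,
            f"mean_{groups[0]}": float(a.mean()),
            f"se_{groups[0]}": float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0,
            f"mean_{groups[1]}": float(b.mean()),
            f"se_{groups[1]}": float(b.std(ddof=1) / math.sqrt(b.size)) if b.size > 1 else 0.0,
        })
    out = pd.DataFrame(rows).sort_values("p_value", ignore_index=True)
    if bh_adjust:
        m = len(out)
        order = np.argsort(out["p_value"].to_numpy())
        q = np.empty(m)
        prev = 1.0
        for rank, i in list(enumerate(order))[::-1]:
            prev = min(prev, out["p_value"].iloc[i] * m / (rank + 1))
            q[i] = prev
        out["q_value"] = q
    return out


def clinical_association(matrix: RegionMatrix, metadata: pd.DataFrame,
                         score: str, alpha: float = 0.05) -> pd.DataFrame:
    """Associate each region with a clinical score over individual samples.

    ``cdr_global`` (ordinal): one-way ANOVA across score groups when every
    group passes Shapiro-Wilk normality at ``alpha`` (groups of n < 3 count
    as non-normal), else Kruskal-Wallis.  ``cdr_sob`` / ``mmse``
    (continuous): least-squares linear fit reporting slope, Pearson r and p.
    """
    if score not in ("cdr_global", "cdr_sob", "mmse"):
        raise ValueError(f"unknown clinical score {score!r}")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    ids = [s for s in matrix.sample_ids
           if s in meta.index and not meta.loc[s, "is_pooled"]]
    values = meta.loc[ids, score]
    ok = values.notna()
    if ok.mean() < 0.8:
        raise ValueError(f"score {score} present for under 80% of individuals")
    ids = [s for s in ids if ok[s]]
    values = values.loc[ids].astype(float)
    if values.nunique() < 2:
        raise ValueError(f"score {score} has fewer than 2 distinct levels")

    rows = []
    for r in matrix.regions:
        x = matrix.values.loc[ids, r.label].to_numpy()
        if score == "cdr_global":
            grouped = [x[(values == lv).to_numpy()] for lv in sorted(values.unique())]
            grouped = [g for g in grouped if g.size > 0]
            normal = all(g.size >= 3 and np.ptp(g) > 0
                         and scipy.stats.shapiro(g).pvalue >= alpha
                         for g in grouped)
            if all(np.ptp(g) == 0 for g in grouped) and len({g[0] for g in grouped}) == 1:
                rows.append({"region_id": r.region_id, "label": r.label,
                             "test_used": "anova", "p_value": 1.0,
                             "statistic": 0.0})
                continue
            if normal:
                res = scipy.stats.f_oneway(*grouped)
                test = "anova"
            else:
                res = scipy.stats.kruskal(*grouped)
                test = "kruskal_wallis"
            rows.append({"region_id": r.region_id, "label": r.label,
                         "test_used": test,
                         "p_value": float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
                         "statistic": float(res.statistic)})
        else:
            if np.ptp(x) == 0:
                rows.append({"region_id": r.region_id, "label": r.label,
                             "test_used": "linear", "slope": 0.0,
                             "pearson_r": 0.0, "p_value": 1.0})
                continue
            fit = scipy.stats.linregress(values.to_numpy(), x)
            rows.append({"region_id": r.region_id, "label": r.label,
                         "test_used": "linear", "slope": float(fit.slope),
                         "pearson_r": float(fit.rvalue),
                         "p_value": float(fit.pvalue)})
    return pd.DataFrame(rows).sort_values("p_value", ignore_index=True)


# --------------------------------------------------------------------------
# PCA and loading factors
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame                 # samples x components (PC1, PC2, ...)
    loading_coefficients: pd.DataFrame   # regions x components, orthonormal columns
    explained_variance_fraction: np.ndarray
    region_means: pd.Series              # standardization record
    region_sds: pd.Series


def run_pca(matrix: RegionMatrix, sample_ids: list[str] | None = None) -> PCAResult:
    """PCA of standardized region values (per-region z-scores).

    Components are computed by SVD of the z-scored matrix over the given
    samples (defaults to every row).  Loading signs are fixed so each
    component's largest-magnitude coefficient is positive.
    """
    ids = sample_ids if sample_ids is not None else matrix.sample_ids
    x = matrix.values.loc[ids]
    if len(ids) < 3 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 regions")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance region(s): {', '.join(zero.index)}; drop before PCA")
    z = (x - means) / sds
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    k = min(len(ids) - 1, x.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest |coefficient| positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(u * s, index=ids, columns=comp)
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=comp)
    explained = s ** 2 / (z.to_numpy() ** 2).sum()
    return PCAResult(scores=scores, loading_coefficients=loadings,
                     explained_variance_fraction=explained,
                     region_means=means, region_sds=sds)


def overall_loading_factors(pca: PCAResult, matrix: RegionMatrix,
                            component: int = 1,
                            individual_ids: list[str] | None = None
                            ) -> pd.DataFrame:
    """Overall loading factor per region: the loading coefficient times the
    ratio of the region's mean over its standard deviation (computed over
    individual samples on the normalized intensities)."""
    col = f"PC{component}"
    if col not in pca.loading_coefficients.columns:
        raise ValueError(f"component {component} not available")
    ids = individual_ids if individual_ids is not None else list(pca.scores.index)
    sub = matrix.values.loc[ids]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[(sd == 0)].tolist()
        raise ValueError(f"zero-variance region(s): {bad}")
    factor = pca.loading_coefficients[col] * mean / sd
    out = pd.DataFrame({
        "label": mean.index,
        "loading_coefficient": pca.loading_coefficients[col].to_numpy(),
        "region_mean": mean.to_numpy(),
        "region_sd": sd.to_numpy(),
        "overall_loading_factor": factor.to_numpy(),
    })
    out["region_id"] = np.arange(len(out))
    out["sign_class"] = np.where(out["overall_loading_factor"] > 0,
                                 "positive", "negative")
    out.loc[out["overall_loading_factor"] == 0, "sign_class"] = "zero"
    return out


def select_contributors(table: pd.DataFrame, fraction: float = 0.5
                        ) -> tuple[list[int], list[int]]:
    """Top ``fraction`` of positively contributing regions and bottom
    ``fraction`` of negatively contributing regions, by overall loading
    factor; counts are ceilings, ties break by region_id ascending, zero
    factors belong to neither set.  Returns (positive_ids, negative_ids)."""
    if table.empty:
        raise ValueError("empty loading-factor table")
    f = table["overall_loading_factor"]
    pos = table[f > 0].sort_values(["overall_loading_factor", "region_id"],
                                   ascending=[False, True])
    neg = table[f < 0].sort_values(["overall_loading_factor", "region_id"],
                                   ascending=[True, True])
    n_pos = math.ceil(fraction * len(pos))
    n_neg = math.ceil(fraction * len(neg))
    return (pos["region_id"].head(n_pos).tolist(),
            neg["region_id"].head(n_neg).tolist())


def unidirectional_metabolites(positive_regions: list[int],
                               negative_regions: list[int],
                               annotations: dict[int, tuple[str, ...]]
                               ) -> tuple[list[str], list[str]]:
    """Union the candidate metabolites of each region set and drop any
    metabolite appearing in both unions (it cannot be attributed a
    direction).  Returns the two unidirectional name lists, sorted.

    Which sign maps to AD is component-specific; the caller applies the
    polarity after comparing group score means.
    """
    pos_union = set()
    for rid in positive_regions:
        pos_union.update(annotations[rid])
    neg_union = set()
    for rid in negative_regions:
        neg_union.update(annotations[rid])
    both = pos_union & neg_union
    return sorted(pos_union - both), sorted(neg_union - both)


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    accuracy: float
    threshold: float
    curve: np.ndarray        # (n, 2) of (FPR, TPR), from (0,0) to (1,1)
    flipped: bool = False    # True when scores were negated to make AUC >= 0.5


def roc_analysis(scores: np.ndarray, labels: np.ndarray,
                 positive_label=None) -> ROCResult:
    """ROC curve over all thresholds; AUC by trapezoid; operating threshold
    maximizing Youden's J; accuracy at that threshold.

    Orientation is chosen so AUC >= 0.5 (recorded in ``flipped``): the
    positive class is called when the oriented score exceeds the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("ROC needs exactly two classes in labels")
    if positive_label is None:
        positive_label = classes[1]
    y = labels == positive_label
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    def curve_for(s):
        order = np.argsort(-s, kind="stable")
        tp = np.cumsum(y[order])
        fp = np.cumsum(~y[order])
        # collapse tied thresholds
        thr = s[order]
        last = np.r_[np.diff(thr) != 0, True]
        tpr = np.r_[0.0, tp[last] / n_pos]
        fpr = np.r_[0.0, fp[last] / n_neg]
        thresholds = np.r_[np.inf, thr[last]]
        return fpr, tpr, thresholds

    fpr, tpr, thresholds = curve_for(scores)
    auc = float(np.trapezoid(tpr, fpr))
    flipped = auc < 0.5
    if flipped:
        fpr, tpr, thresholds = curve_for(-scores)
        auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    j = int(np.argmax(youden))
    thr = float(thresholds[j])
    oriented = -scores if flipped else scores
    predicted_pos = oriented >= thr if np.isfinite(thr) else np.zeros_like(y)
    accuracy = float((predicted_pos == y).mean())
    return ROCResult(auc=auc, accuracy=accuracy,
                     threshold=float(-thr) if flipped else thr,
                     curve=np.column_stack([fpr, tpr]), flipped=flipped)
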