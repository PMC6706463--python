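"""Group statistics: ANOVA, chi-squared, Pearson correlations, ROI analysis.

The statistical workflow mirrors a standard three-group (HC / UHR / FES)
EEG study: one-way ANOVA with Bonferroni-corrected post-hoc unpaired
t-tests for continuous measures, Pearson chi-squared for contingency
tables, Pearson correlations with Bonferroni correction for
degree-versus-clinical-scale relations, and an electrode-wise ANOVA map
thresholded at p < 0.001 to define spatially connected regions of
interest (ROIs).

All tests are two-sided. ``anova_from_summary`` recomputes the omnibus F
from printed per-group means, SDs and ns — the verification surface for
published tables when raw data are unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import Montage


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus test result with optional pairwise Bonferroni post-hocs."""

    statistic_name: str  # "F" or "chi2"
    statistic: float
    df: tuple
    p: float
    posthoc: dict = field(default_factory=dict)  # (g1, g2) -> adjusted p

    def __post_init__(self):
        if np.isfinite(self.p) and not (0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "posthoc": {f"{a}|{b}": p for (a, b), p in self.posthoc.items()},
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between one variable pair."""

    pair: tuple
    r: float
    p: float
    n: int
    p_adjusted: float | None = None

    def __post_init__(self):
        if np.isfinite(self.r) and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")

    def as_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "p_adjusted": self.p_adjusted,
        }


@dataclass(frozen=True)
class ROISet:
    """Named, disjoint electrode subsets (ids are 1-based montage ids)."""

    rois: dict  # name -> tuple of electrode ids

    def __post_init__(self):
        seen = set()
        for name, ids in self.rois.items():
            s = set(ids)
            if seen & s:
                raise ValueError(f"ROI {name!r} overlaps another ROI")
            seen |= s

    def __iter__(self):
        return iter(self.rois.items())

    def __len__(self):
        return len(self.rois)


def default_rois() -> ROISet:
    """The three regions of interest of the reference high-density layout.

    ROI1: superior parietal; ROI2: right temporal; ROI3: occipital.
    Shipping these fixed electrode lists makes the ROI stage runnable
    without re-deriving a montage adjacency.
    """
    return ROISet(
        {
            "ROI1": (12, 13, 19, 20, 24),
            "ROI2": (96, 97, 98, 101, 102),
            "ROI3": (68, 69, 73, 74, 82, 88, 89),
        }
    )


def anova_oneway(groups: dict) -> GroupTestResult:
    """Classical one-way ANOVA over named groups of raw values."""
    names = list(groups)
    samples = [np.asarray(groups[g], float) for g in names]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df = (k - 1, n_total - k)
    within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if within == 0:
        grand = np.concatenate(samples).mean()
        if all(s.mean() == grand for s in samples):
            return GroupTestResult("F", 0.0, df, 1.0)
        warnings.warn("zero within-group variance with unequal means; F undefined")
        return GroupTestResult("F", float("inf"), df, 0.0)
    f, p = sps.f_oneway(*samples)
    return GroupTestResult("F", float(f), df, float(p))


def anova_from_summary(means, sds, ns) -> GroupTestResult:
    """One-way ANOVA from per-group means, standard deviations and sizes.

    SS_between = sum n_i (m_i - grand_mean)^2,
    SS_within  = sum (n_i - 1) s_i^2; F = MS_between / MS_within.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds, ns must have equal length")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    k, n_total = len(ns), int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df = (k - 1, n_total - k)
    if ss_within == 0:
        if ss_between == 0:
            return GroupTestResult("F", 0.0, df, 1.0)
        return GroupTestResult("F", float("inf"), df, 0.0)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, *df))
    return GroupTestResult("F", float(f), df, p)


def chi_square_contingency(table) -> GroupTestResult:
    """Pearson chi-squared on an observed count table (no Yates correction)."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    if (row_m == 0).any():
        raise ValueError(f"row {int(np.where(row_m == 0)[0][0])} has zero margin")
    if (col_m == 0).any():
        raise ValueError(f"column {int(np.where(col_m == 0)[0][0])} has zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return GroupTestResult("chi2", float(chi2), (dof,), float(p))


def posthoc_bonferroni(groups: dict, equal_var: bool = True) -> dict:
    """Pairwise two-sample t-tests, Bonferroni-adjusted over all pairs.

    Student (equal-variance) tests by default, matching classical ANOVA
    post-hocs; set equal_var=False for Welch.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(combinations(names, 2))
    m = len(pairs)
    out = {}
    for a, b in pairs:
        xa = np.asarray(groups[a], float)
        xb = np.asarray(groups[b], float)
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p = float(sps.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
        out[(a, b)] = min(1.0, m * p)
    return out


def pearson_correlation(x, y, pair=("x", "y"),
                        n_tests: int = 1) -> CorrelationResult:
    """Sample Pearson r with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        pair=tuple(pair),
        r=float(r),
        p=float(p),
        n=len(x),
        p_adjusted=min(1.0, n_tests * float(p)),
    )


def electrodewise_anova(degree_maps: dict) -> pd.DataFrame:
    """One-way ANOVA per electrode over per-subject degree maps by group.

    degree_maps maps group name -> (subjects, electrodes) array. Returns
    a DataFrame indexed by electrode position (0-based) with columns F
    and p. Selection for ROI definition is done downstream on raw p
    values (no multiple-testing correction at this stage).
    """
    arrays = {g: np.asarray(v, float) for g, v in degree_maps.items()}
    widths = {a.shape[1] for a in arrays.values()}
    if len(widths) != 1:
        raise ValueError("all groups must share one electrode set")
    n_el = widths.pop()
    f_map = np.full(n_el, np.nan)
    p_map = np.full(n_el, np.nan)
    failures = []
    for e in range(n_el):
        try:
            res = anova_oneway({g: a[:, e] for g, a in arrays.items()})
            f_map[e], p_map[e] = res.statistic, res.p
        except ValueError:
            failures.append(e)
    if failures:
        warnings.warn(f"ANOVA undefined for electrodes {failures}; left missing")
    return pd.DataFrame({"F": f_map, "p": p_map})


def define_rois(pmap, montage: Montage, alpha: float = 0.001) -> ROISet:
    """Group significant electrodes into spatially connected ROIs.

    Electrodes with p < alpha form the candidate set; connected
    components under the montage neighbour relation become ROIs, each
    named by the majority region label of its electrodes (suffixed when
    a label repeats).
    """
    pmap = np.asarray(pmap, float)
    if len(pmap) != montage.n_electrodes:
        raise ValueError("p map must cover every montage electrode")
    sig_ids = [montage.ids[k] for k in range(len(pmap)) if pmap[k] < alpha]
    if not sig_ids:
        warnings.warn(f"no electrode reaches p < {alpha}; empty ROI set")
        return ROISet({})
    sig = set(sig_ids)
    components, seen = [], set()
    for start in sig_ids:  # deterministic order
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for other in sig:
                if other not in seen and montage.are_neighbors(cur, other):
                    seen.add(other)
                    queue.append(other)
        components.append(sorted(comp))
    names: dict = {}
    counts: dict = {}
    for comp in components:
        labels = [montage.region_of(e) for e in comp]
        majority = max(sorted(set(labels)), key=labels.count)
        counts[majority] = counts.get(majority, 0) + 1
        name = majority if counts[majority] == 1 else f"{majority}_{counts[majority]}"
        names[name] = tuple(comp)
    return ROISet(names)


def roi_summary(profiles: dict, roiset: ROISet, cohort: pd.DataFrame,
                scales=("MCCB", "GAF")) -> dict:
    """Per-ROI group ANOVA and pooled degree-scale correlations.

    profiles maps subject_id -> SubjectNetworkProfile (its degree_auc is
    indexed by electrode position, 1-based id = position + 1). Per ROI,
    each subject's mean degree AUC over the ROI electrodes is compared
    across groups (ANOVA + Bonferroni post-hocs); pooled-subject Pearson
    correlations against each scale are Bonferroni-adjusted over the
    number of (ROI x scale) tests. Missing scale values are dropped
    pairwise-complete, with n reported.
    """
    cohort = cohort.set_index("subject_id")
    roi_means = {}
    for name, ids in roiset:
        vals = {}
        for sid, prof in profiles.items():
            idx = [eid - 1 for eid in ids]
            if max(idx) >= len(prof.degree_auc):
                raise ValueError(
                    f"ROI {name!r} references electrode {max(ids)} beyond "
                    f"the profile of subject {sid}"
                )
            vals[sid] = float(np.mean(prof.degree_auc[idx]))
        roi_means[name] = vals

    anovas = {}
    for name, vals in roi_means.items():
        by_group: dict = {}
        for sid, v in vals.items():
            by_group.setdefault(cohort.loc[sid, "group"], []).append(v)
        res = anova_oneway(by_group)
        res = GroupTestResult(
            res.statistic_name, res.statistic, res.df, res.p,
            posthoc=posthoc_bonferroni(by_group),
        )
        anovas[name] = res

    n_tests = max(1, len(roi_means) * len(scales))
    correlations = {}
    for name, vals in roi_means.items():
        for scale in scales:
            if scale not in cohort.columns:
                continue
            sids = [s for s in vals if np.isfinite(cohort.loc[s, scale])]
            x = np.array([vals[s] for s in sids])
            y = np.array([float(cohort.loc[s, scale]) for s in sids])
            try:
                correlations[(name, scale)] = pearson_correlation(
                    x, y, pair=(f"{name} mean degree", scale),
                    n_tests=n_tests,
                )
            except ValueError as exc:
                warnings.warn(
                    f"correlation of {name} degree with {scale} undefined: "
                    f"{exc}"
                )
                correlations[(name, scale)] = CorrelationResult(
                    pair=(f"{name} mean degree", scale),
                    r=float("nan"), p=float("nan"), n=len(x),
                    p_adjusted=float("nan"),
                )
    return {"roi_means": roi_means, "anova": anovas, "correlations": correlations}
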