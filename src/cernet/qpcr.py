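"""Relative-quantification qPCR statistics (the 2^-ΔΔCt layer).

ΔCt = Ct(target) - Ct(reference) per sample (technical replicates averaged
after Δ); ΔΔCt = mean ΔCt(group1) - mean ΔCt(group2); the fold change is
2^-ΔΔCt, reported both as the raw ratio and in the signed convention where a
ratio below 1 is written as the negative reciprocal (0.752 -> -1.33), so
|signed fold change| >= 1 always.

Test selection mirrors standard qPCR practice: Shapiro-Wilk on each group,
then an F-test of variances when both pass (Student vs Welch t), otherwise
Mann-Whitney U; more than two groups go to one-way ANOVA or Kruskal-Wallis.
ΔCt is inversely related to abundance, so correlations computed on ΔCts are
reported with both the ΔCt-space and expression-space sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import CorrelationResult, correlate
from .simulate import QpcrDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeResult",
    "TestDecision",
    "FractionationResult",
    "SilencingFilterResult",
    "delta_ct",
    "fold_change",
    "choose_test",
    "correlate_dcts",
    "categorical_association",
    "fractionation_percent",
    "silencing_efficiency_filter",
    "signed_fold_change",
]


def signed_fold_change(raw: float) -> float:
    """Raw ratio -> signed convention (>= 1 stays, < 1 becomes -1/raw)."""
    if raw <= 0:
        raise ValueError("raw fold change must be positive")
    if abs(raw - 1.0) < 1e-12:  # no change maps to +1, not -1/(1-eps)
        return 1.0
    return raw if raw >= 1 else -1.0 / raw


@dataclass(frozen=True)
class FoldChangeResult:
    target_id: str
    mean_ddct: float
    fold_change_raw: float
    fold_change_signed: float
    p: float | None
    test_used: str | None
    n_group1: int
    n_group2: int

    def __post_init__(self) -> None:
        if abs(self.fold_change_signed) < 1 - 1e-12:
            raise ValueError("|signed fold change| must be >= 1")


@dataclass(frozen=True)
class TestDecision:
    test_used: str       # student_t / welch_t / mann_whitney
    p: float
    statistic: float
    normal_x: bool
    normal_y: bool
    equal_variance: bool | None


def delta_ct(dataset: QpcrDataset) -> pd.DataFrame:
    """Per-(sample, target, group, timepoint) ΔCt, replicates averaged.

    Raises if any record lacks its reference measurement.
    """
    df = dataset.records
    if df["ct_reference"].isna().any():
        bad = df.loc[df["ct_reference"].isna(), "sample"].iloc[0]
        raise ValueError(f"missing reference Ct for sample {bad!r}")
    out = df.assign(dct=df["ct_target"] - df["ct_reference"])
    return (out.groupby(["sample", "group", "timepoint", "target"],
                        as_index=False)["dct"].mean())


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def _variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test for equality of variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    p = stats.f.sf(f, x.size - 1, y.size - 1)
    p = 2 * min(p, 1 - p)
    return float(min(1.0, p))


def choose_test(x, y, alpha_norm: float = 0.05) -> TestDecision:
    """Normality-driven two-sample test.

    Shapiro-Wilk on each group; both normal -> F-test of variances ->
    Student (equal) or Welch (unequal) t; any non-normal -> Mann-Whitney U.
    Groups of n < 3 cannot be normality-tested and fall back to
    Mann-Whitney with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        logger.warning("n < 3: defaulting to Mann-Whitney")
        normal_x = normal_y = False
    else:
        normal_x = _shapiro_normal(x, alpha_norm)
        normal_y = _shapiro_normal(y, alpha_norm)

    if normal_x and normal_y:
        equal_var = _variance_f_test(x, y) > alpha_norm
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        p = float(res.pvalue)
        if np.isnan(p):  # both groups constant and identical
            p = 1.0
        return TestDecision(name, p, float(res.statistic),
                            normal_x, normal_y, equal_var)
    if np.ptp(np.concatenate([x, y])) == 0:
        # every observation tied: no evidence of a shift
        return TestDecision("mann_whitney", 1.0, x.size * y.size / 2.0,
                            normal_x, normal_y, None)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestDecision("mann_whitney", float(res.pvalue),
                        float(res.statistic), normal_x, normal_y, None)


def fold_change(
    dataset: QpcrDataset,
    group1: str,
    group2: str,
    target: str | None = None,
    alpha_norm: float = 0.05,
) -> FoldChangeResult:
    """2^-ΔΔCt fold change of ``group1`` relative to ``group2``.

    The p-value comes from :func:`choose_test` on the per-sample ΔCt
    distributions; with fewer than two samples in a group the fold change is
    still computed but the p-value is unavailable.
    """
    dct = delta_ct(dataset)
    if target is None:
        targets = dct["target"].unique()
        if len(targets) != 1:
            raise ValueError("multiple targets present; pass target=")
        target = targets[0]
    dct = dct[dct["target"] == target]
    x = dct.loc[dct["group"] == group1, "dct"].to_numpy()
    y = dct.loc[dct["group"] == group2, "dct"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError(f"empty group among ({group1!r}, {group2!r})")
    ddct = float(x.mean() - y.mean())
    raw = float(2.0 ** (-ddct))
    if x.size < 2 or y.size < 2:
        p, test = None, None
    else:
        decision = choose_test(x, y, alpha_norm)
        p, test = decision.p, decision.test_used
    return FoldChangeResult(target, ddct, raw, signed_fold_change(raw),
                            p, test, int(x.size), int(y.size))


@dataclass(frozen=True)
class DctCorrelation:
    """Correlation computed on ΔCt vectors with explicit sign semantics."""

    result: CorrelationResult
    r_expression: float
    expression_sign_flipped: bool


def correlate_dcts(dct_a, dct_b, alpha_norm: float = 0.05,
                   b_is_dct: bool = True) -> DctCorrelation:
    """Correlate two paired ΔCt vectors, Pearson when both pass normality,
    Spearman otherwise.

    ΔCt is inversely related to abundance.  When both inputs are ΔCts the
    two sign flips cancel and the expression-space r equals the ΔCt-space r;
    when ``b_is_dct`` is False (ΔCt vs a plain covariate) the expression-
    space sign is flipped.
    """
    a = np.asarray(dct_a, dtype=float)
    b = np.asarray(dct_b, dtype=float)
    method = ("pearson"
              if _shapiro_normal(a, alpha_norm) and _shapiro_normal(b, alpha_norm)
              else "spearman")
    res = correlate(a, b, method=method)
    flipped = not b_is_dct
    return DctCorrelation(res, -res.r if flipped else res.r, flipped)


@dataclass(frozen=True)
class AssociationResult:
    test_used: str
    p: float
    statistic: float
    groups_used: tuple[str, ...]


def categorical_association(values: Mapping[str, Sequence[float]],
                            alpha_norm: float = 0.05) -> AssociationResult:
    """Association between expression and a categorical feature.

    ``values`` maps group label -> per-sample values.  Two groups go through
    :func:`choose_test`; more go to one-way ANOVA when all groups pass
    Shapiro-Wilk, else Kruskal-Wallis.  Singleton groups are dropped with a
    warning.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    dropped = [k for k, v in groups.items() if v.size < 2]
    for k in dropped:
        logger.warning("dropping singleton group %r", k)
        del groups[k]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups of size >= 2")
    labels = tuple(sorted(groups))
    arrays = [groups[k] for k in labels]
    if len(arrays) == 2:
        d = choose_test(arrays[0], arrays[1], alpha_norm)
        return AssociationResult(d.test_used, d.p, d.statistic, labels)
    if all(_shapiro_normal(a, alpha_norm) for a in arrays):
        res = stats.f_oneway(*arrays)
        return AssociationResult("anova", float(res.pvalue),
                                 float(res.statistic), labels)
    res = stats.kruskal(*arrays)
    return AssociationResult("kruskal_wallis", float(res.pvalue),
                             float(res.statistic), labels)


@dataclass(frozen=True)
class FractionationResult:
    transcript_id: str
    pct_nuclear: float
    pct_cytoplasmic: float

    def __post_init__(self) -> None:
        if abs(self.pct_nuclear + self.pct_cytoplasmic - 100.0) > 1e-9:
            raise ValueError("fraction percentages must sum to 100")


def fractionation_percent(ct_nuclear: float, ct_cytoplasmic: float,
                          transcript_id: str = "transcript") -> FractionationResult:
    """Nuclear/cytoplasmic split from fraction Cts: relative abundance
    2^-Ct per fraction, expressed as percentages of their sum."""
    for name, ct in (("nuclear", ct_nuclear), ("cytoplasmic", ct_cytoplasmic)):
        if ct is None or not np.isfinite(ct):
            raise ValueError(f"missing {name} fraction Ct")
    a_nuc = 2.0 ** (-float(ct_nuclear))
    a_cyt = 2.0 ** (-float(ct_cytoplasmic))
    pct_nuc = 100.0 * a_nuc / (a_nuc + a_cyt)
    return FractionationResult(transcript_id, pct_nuc, 100.0 - pct_nuc)


@dataclass(frozen=True)
class SilencingFilterResult:
    kept: Mapping[str, float]        # replicate -> efficiency
    removed: Mapping[str, float]
    status: str                      # "ok" or "all_removed"


def silencing_efficiency_filter(
    replicate_fold_changes: Mapping[str, float],
    min_efficiency: float = 0.75,
) -> SilencingFilterResult:
    """Drop replicates with knockdown efficiency below threshold.

    Input ratios are treated-vs-control expression ratios (2^-ΔΔCt);
    efficiency = 1 - ratio.  A replicate exactly at the threshold is kept.
    """
    kept, removed = {}, {}
    for rep, ratio in replicate_fold_changes.items():
        if ratio <= 0:
            raise ValueError(f"fold-change ratio must be positive ({rep})")
        eff = 1.0 - ratio
        (kept if eff >= min_efficiency else removed)[rep] = eff
    status = "ok" if kept else "all_removed"
    return SilencingFilterResult(kept, removed, status)
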