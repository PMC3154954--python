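"""Between-group comparison of variance structure.

Genome-wide comparisons use a two-sample Welch t-test on log2-transformed
CVs; compositional comparisons use a Pearson chi-square goodness-of-fit of
observed low:mid:high class counts against either the theoretical 25:50:25
pattern (generalized to the configured cutoffs) or the control group's
observed counts.  Multiple testing is handled by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variance import CVProfile, ConstraintClassification, classify_constraint

logger = logging.getLogger("varcon")


@dataclass
class CVComparison:
    """Welch t-test of log2 CV between two donor groups."""

    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    n_excluded_zero: int
    transform: str = "log2"


@dataclass
class ClassCountTest:
    """Chi-square goodness of fit of (low, mid, high) counts against a null."""

    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    null_kind: str  # proportions | control_counts
    statistic: float
    df: int
    p_value: float
    low_excess: float  # observed low minus expected low (sign = direction)


def logcv_ttest(profile: CVProfile, group_a: str, group_b: str, equal_var: bool = False) -> CVComparison:
    """Two-sample t-test (Welch by default) on log2 CV over the common universe.

    Genes with zero or undefined CV in either group are excluded (count
    recorded): the log of a zero CV is undefined.
    """
    for g in (group_a, group_b):
        if g not in profile.cv.columns:
            raise ValueError(f"group {g!r} not present in CV profile")
    a = profile.cv[group_a].to_numpy(dtype=float)
    b = profile.cv[group_b].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    n_excluded = int((~ok).sum())
    la, lb = np.log2(a[ok]), np.log2(b[ok])
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("fewer than 2 finite positive CVs in a group")
    t, p = stats.ttest_ind(la, lb, equal_var=equal_var)
    return CVComparison(group_a, group_b, float(t), float(p), len(la), len(lb), n_excluded)


def class_count_chisq(
    classification: ConstraintClassification,
    gene_set: list[str],
    group: str,
    null_kind: str = "proportions",
    control_counts: tuple[int, int, int] | None = None,
) -> ClassCountTest:
    """Chi-square goodness of fit of a gene set's class counts in one group.

    ``null_kind='proportions'`` expects the theoretical split implied by the
    classification cutoffs (25:50:25 at the defaults);
    ``null_kind='control_counts'`` rescales the control group's observed
    triple to the set size.  Pearson statistic, df = 2, no continuity
    correction.
    """
    observed = classification.class_counts(group, gene_set)
    total = sum(observed)
    if total == 0:
        raise ValueError("gene set has no classified genes in this group")
    if null_kind == "proportions":
        lo, hi = classification.low_pct, classification.high_pct
        props = np.array([lo, hi - lo, 100.0 - hi]) / 100.0
    elif null_kind == "control_counts":
        if control_counts is None or sum(control_counts) <= 0:
            raise ValueError("control_counts null requires a positive count triple")
        props = np.asarray(control_counts, dtype=float) / sum(control_counts)
    else:
        raise ValueError(f"unknown null_kind {null_kind!r}")
    expected = props * total
    if (expected < 1).any():
        raise ValueError(
            "an expected cell is < 1; use a larger gene set or an exact test"
        )
    statistic, p = stats.chisquare(observed, expected)
    return ClassCountTest(
        observed=observed,
        expected=tuple(float(e) for e in expected),
        null_kind=null_kind,
        statistic=float(statistic),
        df=2,
        p_value=float(p),
        low_excess=float(observed[0] - expected[0]),
    )


def cutoff_sensitivity(
    profile: CVProfile,
    gene_set: list[str],
    group: str,
    cutoffs: list[tuple[float, float]] = ((25.0, 75.0), (10.0, 90.0), (5.0, 95.0)),
    null_kind: str = "proportions",
    reference: str = "all_donors",
    control_label: str | None = None,
) -> pd.DataFrame:
    """Reclassify and re-test a gene set at each percentile cutoff pair.

    Confirms whether a compositional deviation persists when more stringent
    cutoffs define the constraint classes; the sign of the low-class excess
    is reported per cutoff.
    """
    rows = []
    for low_pct, high_pct in cutoffs:
        cls = classify_constraint(
            profile, low_pct=low_pct, high_pct=high_pct,
            reference=reference, control_label=control_label,
        )
        control_counts = (
            cls.class_counts(control_label) if null_kind == "control_counts" else None
        )
        test = class_count_chisq(cls, gene_set, group, null_kind, control_counts)
        rows.append(
            {
                "low_pct": low_pct,
                "high_pct": high_pct,
                "n_low": test.observed[0],
                "n_mid": test.observed[1],
                "n_high": test.observed[2],
                "statistic": test.statistic,
                "p_value": test.p_value,
                "low_excess": test.low_excess,
                "direction": int(np.sign(test.low_excess)),
            }
        )
    return pd.DataFrame(rows)


def mean_expression_ttest(
    norm_matrix: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> CVComparison:
    """Companion test: two-sample t-test on per-gene mean log2 expression.

    Used to verify that compositional variance differences are not driven by
    shifts in average expression between the groups.
    """
    means = {}
    for g in (group_a, group_b):
        samples = design.index[design["group_label"] == g]
        samples = [s for s in samples if s in norm_matrix.columns]
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
        means[g] = norm_matrix[samples].mean(axis=1).to_numpy()
    t, p = stats.ttest_ind(means[group_a], means[group_b], equal_var=equal_var)
    return CVComparison(
        group_a, group_b, float(t), float(p),
        len(means[group_a]), len(means[group_b]), 0, transform="mean_log2",
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
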