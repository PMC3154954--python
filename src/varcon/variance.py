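"""Coefficient-of-variation profiling and constraint classification.

The coefficient of variation of a gene in a donor group is its sample
standard deviation (n-1 denominator) across that group's samples divided by
its mean, computed by default on linear-scale intensities recovered from the
normalized log2 matrix.  Genes are classified as highly constrained (low
CV), mid-variability or lowly constrained (high CV) against the 25th/75th
percentiles of a reference genome-wide CV distribution — by default the one
pooled over all donors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import NormalizationResult

logger = logging.getLogger("varcon")

CLASSES = ("low", "mid", "high")
POOLED = "__all__"


@dataclass
class CVProfile:
    """Per-gene, per-group coefficients of variation.

    ``cv`` and ``mean_expr`` are gene x group; the pooled (all-donors)
    column is stored under :data:`POOLED`.  ``scale`` records whether CV
    was computed on linear or log2 values.  Undefined CVs (non-positive
    mean on the linear scale) are NaN.
    """

    cv: pd.DataFrame
    mean_expr: pd.DataFrame
    scale: str = "linear"
    group_by: str = "group_label"

    @property
    def groups(self) -> list[str]:
        return [c for c in self.cv.columns if c != POOLED]

    def pooled(self) -> pd.Series:
        return self.cv[POOLED]

    def n_undefined(self) -> int:
        return int(self.cv.isna().to_numpy().sum())


@dataclass
class ConstraintClassification:
    """Gene x group constraint labels at fixed percentile cutoffs.

    ``thresholds`` are the CV values at the (low_pct, high_pct) percentiles
    of the reference vector; a gene is low iff cv < threshold_low, high iff
    cv > threshold_high, mid otherwise (boundary-equal genes are mid, so the
    three classes partition the defined CVs).
    """

    labels: pd.DataFrame  # values in {low, mid, high} or NaN for undefined CV
    low_pct: float
    high_pct: float
    thresholds: tuple[float, float]
    reference: str = "all_donors"
    n_undefined: int = 0

    def class_counts(self, group: str, gene_set: list[str] | None = None) -> tuple[int, int, int]:
        """(n_low, n_mid, n_high) for a gene set (default: all genes) in a group."""
        col = self.labels[group]
        if gene_set is not None:
            missing = set(gene_set) - set(self.labels.index)
            if missing:
                raise KeyError(f"gene {sorted(missing)[0]!r} not in classified universe")
            col = col.loc[list(gene_set)]
        return tuple(int((col == c).sum()) for c in CLASSES)

    def genes_in_class(self, group: str, cls: str) -> set[str]:
        col = self.labels[group]
        return set(col.index[col == cls])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _cv_of_block(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CV and mean along axis 1; CV is NaN where the mean is <= 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv, mean


def compute_cv(
    norm: NormalizationResult,
    design: pd.DataFrame,
    group_by: str = "group_label",
    scale: str = "linear",
) -> CVProfile:
    """Per-gene CV within each group plus a pooled all-samples column.

    ``scale='linear'`` (default) back-transforms the log2 matrix before
    taking sd/mean; ``scale='log2'`` computes CV on the log2 values
    directly.  Every group must contribute at least 2 samples.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"unknown scale {scale!r}")
    if group_by not in design.columns:
        raise ValueError(f"design has no column {group_by!r}")
    mat = norm.linear() if scale == "linear" else norm.matrix
    mat = mat[design.index.intersection(mat.columns)]
    values = mat.to_numpy()

    cv_cols: dict[str, np.ndarray] = {}
    mean_cols: dict[str, np.ndarray] = {}
    col_pos = {s: i for i, s in enumerate(mat.columns)}
    for label, sub in design.groupby(group_by, sort=False):
        samples = [s for s in sub.index if s in col_pos]
        if len(samples) < 2:
            raise ValueError(f"group {label!r} has < 2 samples; CV undefined")
        block = values[:, [col_pos[s] for s in samples]]
        cv_cols[label], mean_cols[label] = _cv_of_block(block)
    cv_cols[POOLED], mean_cols[POOLED] = _cv_of_block(values)

    cv = pd.DataFrame(cv_cols, index=mat.index)
    mean_expr = pd.DataFrame(mean_cols, index=mat.index)
    n_undef = int(cv.isna().to_numpy().sum())
    if n_undef:
        logger.info("compute_cv: %d undefined CV entries (non-positive mean)", n_undef)
    return CVProfile(cv, mean_expr, scale=scale, group_by=group_by)


def percentile_thresholds(
    reference_cv: pd.Series | np.ndarray, low_pct: float, high_pct: float
) -> tuple[float, float]:
    """Linear-interpolation (type 7) percentiles of the finite reference CVs."""
    ref = np.asarray(reference_cv, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("reference CV vector has no finite values")
    lo, hi = np.percentile(ref, [low_pct, high_pct], method="linear")
    return float(lo), float(hi)


def classify_constraint(
    profile: CVProfile,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
    reference: str = "all_donors",
    control_label: str | None = None,
) -> ConstraintClassification:
    """Label every gene x group CV as low / mid / high constraint class.

    Thresholds are computed once from the reference vector — the pooled
    all-donors CV distribution (``reference='all_donors'``, the default) or
    the control group's own CVs (``reference='control_only'``) — then every
    group's CVs are compared against those fixed thresholds.
    """
    if not (0 < low_pct < high_pct < 100):
        raise ValueError("need 0 < low_pct < high_pct < 100")
    if reference == "all_donors":
        ref = profile.pooled()
    elif reference == "control_only":
        if control_label is None or control_label not in profile.cv.columns:
            raise ValueError("control_only reference requires a valid control_label")
        ref = profile.cv[control_label]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    t_low, t_high = percentile_thresholds(ref, low_pct, high_pct)

    arr = profile.cv[profile.groups + [POOLED]]
    labels = pd.DataFrame(
        np.where(
            arr.isna(), None, np.where(arr < t_low, "low", np.where(arr > t_high, "high", "mid"))
        ),
        index=arr.index,
        columns=arr.columns,
    )
    n_undef = int(arr.isna().to_numpy().sum())
    cls = ConstraintClassification(
        labels=labels,
        low_pct=low_pct,
        high_pct=high_pct,
        thresholds=(t_low, t_high),
        reference=reference,
        n_undefined=n_undef,
    )
    for g in profile.groups:
        logger.debug("class counts %s: %s", g, cls.class_counts(g))
    return cls


def strategy_concordance(
    classifications: dict[str, ConstraintClassification],
    cls: str,
    group: str = POOLED,
) -> pd.DataFrame:
    """Pairwise and overall Jaccard concordance (in %) of one constraint class.

    Mirrors comparing low- or high-variance gene sets across normalization
    strategies: pairwise concordance is 100*|A&B|/|A|B|union, the ``overall``
    row/column is 100*|intersection of all|/|union of all|.
    """
    if cls not in CLASSES:
        raise ValueError(f"class must be one of {CLASSES}")
    if len(classifications) < 2:
        raise ValueError("need at least two classifications to compare")
    names = list(classifications)
    universes = {name: set(c.labels.index) for name, c in classifications.items()}
    first = universes[names[0]]
    for name in names[1:]:
        if universes[name] != first:
            raise ValueError(f"classification {name!r} has a different gene universe")
    sets = {name: classifications[name].genes_in_class(group, cls) for name in names}

    def jaccard(a: set, b: set) -> float:
        union = a | b
        return 100.0 * len(a & b) / len(union) if union else 100.0

    table = pd.DataFrame(index=names + ["overall"], columns=names + ["overall"], dtype=float)
    for a in names:
        for b in names:
            table.loc[a, b] = jaccard(sets[a], sets[b])
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    overall = 100.0 * len(inter) / len(union) if union else 100.0
    table.loc["overall", :] = overall
    table.loc[:, "overall"] = overall
    return table
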