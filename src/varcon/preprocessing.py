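"""Detection filtering and the five normalization regimes.

All regimes log2-transform first (after flooring non-positive intensities at
a configurable small value).  Median normalization subtracts each sample's
median log2 value, computed either over all probes or over detected probes
only; quantile normalization replaces each sample's sorted values with
cross-sample rank means (ties receive the mean of their rank span); spline
normalization maps each sample's quantiles through a monotone smooth curve
anchored on the mean quantile profile.  Background correction is
deliberately absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .data_io import ExpressionBundle, ValidationError

logger = logging.getLogger("varcon")

STRATEGIES = (
    "log2",
    "log2_median_with_nondetected",
    "log2_median_detected_only",
    "log2_quantile",
    "log2_spline",
)


@dataclass
class NormalizationResult:
    """Log2-scale normalized matrix plus the parameters that produced it."""

    matrix: pd.DataFrame  # probe x sample, log2 scale
    strategy: str
    provenance: dict = field(default_factory=dict)

    @property
    def probes(self) -> pd.Index:
        return self.matrix.index

    def linear(self) -> pd.DataFrame:
        """Back-transform to linear-scale intensities."""
        return np.exp2(self.matrix)


# ---------------------------------------------------------------------------
# Detection filter
# ---------------------------------------------------------------------------


def detection_filter(
    bundle: ExpressionBundle,
    p_threshold: float = 0.01,
    fraction: float = 0.75,
    scope: str = "any_group",
) -> list[str] | dict[tuple[str, str], list[str]]:
    """Probes detected in at least ``fraction`` of a stratum's donors.

    A probe counts as detected for a donor when any of that donor's samples
    has detection p <= ``p_threshold``.  Strata are (group_label,
    cell_type) combinations.  ``scope='any_group'`` (default) returns the
    union over strata — a probe passes if it passes anywhere;
    ``scope='per_group'`` returns the per-stratum lists.
    """
    if not (0 < p_threshold <= 1) or not (0 < fraction <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if bundle.detection is None:
        raise ValidationError("bundle has no detection matrix; filter unavailable")
    if scope not in ("any_group", "per_group"):
        raise ValueError(f"unknown scope {scope!r}")

    design = bundle.design
    per_stratum: dict[tuple[str, str], list[str]] = {}
    for (grp, ct), sub in design.groupby(["group_label", "cell_type"], sort=False):
        if len(sub) == 0:
            raise ValidationError(f"empty design group ({grp}, {ct})")
        det = bundle.detection[sub.index]
        # detected per donor: min p over that donor's samples
        donor_min = det.T.groupby(sub["donor_id"]).min().T
        frac_detected = (donor_min <= p_threshold).mean(axis=1)
        passed = list(bundle.probes[frac_detected >= fraction])
        per_stratum[(grp, ct)] = passed
    if scope == "per_group":
        return per_stratum
    union: set[str] = set()
    for passed in per_stratum.values():
        union.update(passed)
    kept = [p for p in bundle.probes if p in union]  # preserve probe order
    logger.info("detection filter: %d / %d probes pass", len(kept), len(bundle.probes))
    return kept


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _to_log2(bundle: ExpressionBundle, floor: float | None) -> pd.DataFrame:
    if bundle.is_log2:
        return bundle.expression.astype(float)
    x = bundle.expression.astype(float)
    nonpos = (x.to_numpy() <= 0).any()
    if nonpos:
        if floor is None:
            raise ValidationError("non-positive intensities and no floor configured")
        x = x.clip(lower=floor)
    return np.log2(x)


def _quantile_normalize(log2x: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample rank-mean quantile normalization with tie averaging."""
    arr = log2x.to_numpy()
    n, m = arr.shape
    ref = np.mean(np.sort(arr, axis=0), axis=1)  # reference quantile profile
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = ref
        # ties: every member of a tie span gets the mean of ref over the span
        sorted_col = col[order]
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    mapped[order[start:end]] = ref[start:end].mean()
                start = end
        out[:, j] = mapped
    return pd.DataFrame(out, index=log2x.index, columns=log2x.columns)


def _spline_normalize(log2x: pd.DataFrame, n_anchors: int = 15) -> pd.DataFrame:
    """Monotone quantile-anchored spline mapping onto the mean quantile curve.

    Approximates robust spline normalization: each sample's anchor quantiles
    are mapped onto the corresponding reference (column-mean) quantiles with
    a monotone PCHIP curve, and all values pass through it.
    """
    arr = log2x.to_numpy()
    qs = np.linspace(0.0, 1.0, n_anchors)
    ref = np.quantile(np.sort(arr, axis=0).mean(axis=1), qs)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        x_anchor = np.quantile(arr[:, j], qs)
        keep = np.concatenate([[True], np.diff(x_anchor) > 1e-12])
        xa, ya = x_anchor[keep], ref[keep]
        if len(xa) < 2:  # (near-)constant sample: shift onto reference median
            out[:, j] = arr[:, j] - np.median(arr[:, j]) + np.median(ref)
            continue
        spline = PchipInterpolator(xa, ya, extrapolate=True)
        out[:, j] = spline(arr[:, j])
    return pd.DataFrame(out, index=log2x.index, columns=log2x.columns)


def normalize(
    bundle: ExpressionBundle,
    strategy: str = "log2_quantile",
    detected: list[str] | None = None,
    floor: float | None = 1.0,
) -> NormalizationResult:
    """Apply one of the five normalization regimes.

    ``detected`` restricts the output (and, for the detected-only median
    regime, the median computation) to the given probes; ``None`` keeps all
    probes except for the detected-only regime, which requires the list.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    log2x = _to_log2(bundle, floor)
    provenance: dict = {"strategy": strategy, "floor": floor, "n_probes_in": len(log2x)}

    if strategy == "log2":
        out = log2x
    elif strategy == "log2_median_with_nondetected":
        out = log2x - log2x.median(axis=0)
    elif strategy == "log2_median_detected_only":
        if not detected:
            raise ValidationError("detected probe list required for detected-only median")
        medians = log2x.loc[detected].median(axis=0)
        out = log2x - medians
    elif strategy == "log2_quantile":
        out = _quantile_normalize(log2x)
    else:  # log2_spline
        out = _spline_normalize(log2x)

    if detected is not None:
        out = out.loc[[p for p in out.index if p in set(detected)]]
    provenance["n_probes_out"] = len(out)
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError("normalization produced non-finite values")
    return NormalizationResult(out, strategy, provenance)
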