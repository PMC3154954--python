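"""Intra-individual versus inter-individual expression variance.

Technical (within-donor) variability is quantified as the mean CV across a
donor's replicate samples; biological (between-donor) variability as the
mean CV across donors of a group.  Because replicate counts and group sizes
differ, the between-donor side is additionally estimated on random subsets
of a fixed number of donors (one randomly chosen sample per donor),
matching the sample size of the within-donor estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import NormalizationResult
from .synthetic import substream
from .variance import _cv_of_block

logger = logging.getLogger("varcon")


@dataclass
class ReplicateVarianceSummary:
    """Within- vs between-donor CV summary.

    ``intra_cv_mean``: per replicated donor, the mean over genes of the CV
    across that donor's replicates.  ``inter_cv_mean``: per group, the mean
    gene CV across all donors (one sample per donor).  ``subsample_means``:
    per group, the distribution over random donor subsets of fixed size of
    the mean gene CV — the sample-size-matched control.
    """

    intra_cv_mean: pd.Series  # index: donor_id
    inter_cv_mean: pd.Series  # index: group label
    subsample_means: dict[str, np.ndarray]
    subset_size: int
    n_subsets: int
    seed: int
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    intra_mean: float = float("nan")
    inter_mean: float = float("nan")
    per_module_intra: pd.DataFrame | None = None


def _gene_cv_mean(values: np.ndarray) -> float:
    cv, _ = _cv_of_block(values)
    return float(np.nanmean(cv))


def intra_vs_inter(
    norm: NormalizationResult,
    design: pd.DataFrame,
    subset_size: int = 4,
    n_subsets: int = 100,
    seed: int = 0,
    modules: dict[str, list[str]] | None = None,
) -> ReplicateVarianceSummary:
    """Compare within-donor and between-donor mean CV.

    Within: every donor with >= 2 samples contributes the mean gene CV over
    its replicates.  Between: for each group with >= ``subset_size``
    donors, ``n_subsets`` random subsets of ``subset_size`` distinct donors
    are drawn (one randomly chosen sample per donor), each yielding a mean
    gene CV.  Each subset uses its own named substream, so raising
    ``n_subsets`` extends rather than reshuffles the draws.  The summary
    t-test (Welch) compares the per-donor within means against the pooled
    subset means.  ``modules`` adds a per-module within-donor CV table.
    """
    mat = np.exp2(norm.matrix)  # CV on linear-scale intensities
    mat = mat[[s for s in design.index if s in norm.matrix.columns]]
    design = design.loc[mat.columns]
    values = mat.to_numpy()
    col_pos = {s: i for i, s in enumerate(mat.columns)}

    # within-donor
    intra = {}
    replicated = []
    for donor, sub in design.groupby("donor_id", sort=False):
        if len(sub) >= 2:
            cols = [col_pos[s] for s in sub.index]
            intra[donor] = _gene_cv_mean(values[:, cols])
            replicated.append(donor)
    if not intra:
        raise ValueError("no donor has >= 2 replicate samples")
    intra_series = pd.Series(intra, name="intra_cv_mean")

    # between-donor, full and subsampled
    inter = {}
    subsample_means: dict[str, np.ndarray] = {}
    for group, sub in design.groupby("group_label", sort=False):
        donors = list(pd.unique(sub["donor_id"]))
        if len(donors) < subset_size:
            raise ValueError(
                f"group {group!r} has {len(donors)} donors < subset_size {subset_size}"
            )
        # full between-donor CV: one sample per donor (the first, deterministic)
        first_cols = [col_pos[sub.index[sub["donor_id"] == d][0]] for d in donors]
        inter[group] = _gene_cv_mean(values[:, first_cols])

        means = np.empty(n_subsets)
        for i in range(n_subsets):
            rng = substream(seed, f"replicates/{group}/subset{i}")
            chosen = rng.choice(len(donors), size=subset_size, replace=False)
            cols = []
            for di in chosen:
                donor_samples = list(sub.index[sub["donor_id"] == donors[di]])
                cols.append(col_pos[donor_samples[rng.integers(len(donor_samples))]])
            means[i] = _gene_cv_mean(values[:, cols])
        subsample_means[group] = means

    all_subsets = np.concatenate(list(subsample_means.values()))
    t, p = stats.ttest_ind(intra_series.to_numpy(), all_subsets, equal_var=False)

    per_module = None
    if modules:
        rows = {}
        for name, members in modules.items():
            keep = [g for g in members if g in mat.index]
            if not keep:
                continue
            row = {}
            for donor in replicated:
                cols = [col_pos[s] for s in design.index[design["donor_id"] == donor]]
                row[donor] = _gene_cv_mean(mat.loc[keep].to_numpy()[:, cols])
            rows[name] = row
        per_module = pd.DataFrame(rows).T

    return ReplicateVarianceSummary(
        intra_cv_mean=intra_series,
        inter_cv_mean=pd.Series(inter, name="inter_cv_mean"),
        subsample_means=subsample_means,
        subset_size=subset_size,
        n_subsets=n_subsets,
        seed=seed,
        t_statistic=float(t),
        p_value=float(p),
        intra_mean=float(intra_series.mean()),
        inter_mean=float(all_subsets.mean()),
        per_module_intra=per_module,
    )


def intersect_universes(probes_a: list[str], probes_b: list[str]) -> list[str]:
    """Probes common to two platform versions, in first-list order."""
    b = set(probes_b)
    return [p for p in probes_a if p in b]
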