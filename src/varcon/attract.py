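"""ANOVA-based core-pathway discovery with synexpression decomposition.

The procedure tests gene sets (e.g. KEGG pathways) for their ability to
distinguish phenotype classes: a one-way ANOVA F statistic is computed per
gene across the classes, each set's log-F values are compared against the
out-of-set background with a two-sample t-test, and BH-significant sets are
ranked by the number of detected probes they contain.  Significant sets are
then decomposed into synexpression groups — correlated subsets found by
average-linkage hierarchical clustering on 1 - Pearson correlation — which
can be expanded with any gene in the dataset whose profile tracks the group
mean.

The gene-set statistic (t-test on log F) and the informativeness floor
(mean within-cluster correlation to the cluster mean profile) are this
package's concrete, documented choices; each is isolated behind one
function so an alternative can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .compare import bh_adjust
from .data_io import GeneSetCollection
from .preprocessing import NormalizationResult

logger = logging.getLogger("varcon")

LOG_F_EPS = 1e-8  # admits F = 0 genes into the log-F comparison


# ---------------------------------------------------------------------------
# Per-gene ANOVA
# ---------------------------------------------------------------------------


def gene_fstat(norm: NormalizationResult, classes: pd.Series) -> pd.DataFrame:
    """One-way ANOVA F statistic per gene across phenotype classes.

    ``classes`` maps sample id -> class label and must cover >= 2 classes
    with >= 2 samples each.  Returns a gene-indexed frame with columns
    f_statistic, df_between, df_within, p_value.
    """
    classes = classes.loc[[s for s in norm.matrix.columns if s in classes.index]]
    labels = pd.unique(classes)
    if len(labels) < 2:
        raise ValueError("need >= 2 phenotype classes")
    mat = norm.matrix[classes.index].to_numpy()
    n_genes, n_samples = mat.shape

    grand_mean = mat.mean(axis=1)
    ss_between = np.zeros(n_genes)
    ss_within = np.zeros(n_genes)
    for label in labels:
        cols = np.flatnonzero((classes == label).to_numpy())
        if len(cols) < 2:
            raise ValueError(f"class {label!r} has < 2 samples")
        block = mat[:, cols]
        m = block.mean(axis=1)
        ss_between += len(cols) * (m - grand_mean) ** 2
        ss_within += ((block - m[:, None]) ** 2).sum(axis=1)

    df_between = len(labels) - 1
    df_within = n_samples - len(labels)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_within > 0, ms_between / ms_within, np.inf)
    p = stats.f.sf(f, df_between, df_within)
    return pd.DataFrame(
        {
            "f_statistic": f,
            "df_between": df_between,
            "df_within": df_within,
            "p_value": p,
        },
        index=norm.matrix.index,
    )


# ---------------------------------------------------------------------------
# Gene-set significance and ranking
# ---------------------------------------------------------------------------


def _set_statistic(log_f_in: np.ndarray, log_f_out: np.ndarray) -> tuple[float, float]:
    """Gene-set statistic: Welch t of in-set vs out-of-set log F."""
    if np.array_equal(log_f_in, log_f_out) or (log_f_in.std() == 0 and log_f_out.std() == 0
                                               and log_f_in.mean() == log_f_out.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(log_f_in, log_f_out, equal_var=False)
    return float(t), float(p)


def find_core_pathways(
    anova: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_size: int = 5,
) -> pd.DataFrame:
    """Rank gene sets by phenotype-discriminating power.

    Per set, the log F of in-set genes is compared to the out-of-set
    background (Welch t); p-values are BH-adjusted across sets; sets with
    adjusted p < alpha are retained and ranked descending by detected-probe
    count, ties broken by adjusted p then name.  Sets smaller than
    ``min_size`` after intersection with the ANOVA universe are skipped.
    """
    universe = set(anova.index)
    log_f = np.log(anova["f_statistic"].to_numpy() + LOG_F_EPS)
    log_f_by_gene = pd.Series(log_f, index=anova.index)

    rows = []
    for name in sets.names():
        members = [g for g in sets[name] if g in universe]
        if len(members) < min_size:
            logger.warning("set %r has %d detected probes (< %d); skipped", name, len(members), min_size)
            continue
        in_mask = log_f_by_gene.index.isin(members)
        t, p = _set_statistic(log_f_by_gene[in_mask].to_numpy(), log_f_by_gene[~in_mask].to_numpy())
        rows.append({"set_name": name, "t_statistic": t, "raw_p": p, "n_detected_probes": len(members)})
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "t_statistic", "raw_p", "adjusted_p", "n_detected_probes", "rank"]
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
    retained = table[table["adjusted_p"] < alpha].copy()
    retained = retained.sort_values(
        ["n_detected_probes", "adjusted_p", "set_name"], ascending=[False, True, True]
    ).reset_index(drop=True)
    retained["rank"] = np.arange(1, len(retained) + 1)
    return retained


# ---------------------------------------------------------------------------
# Synexpression decomposition
# ---------------------------------------------------------------------------


@dataclass
class SynexpressionGroup:
    """A correlated, phenotype-informative subset of a pathway.

    ``informativeness`` is the within-group mean squared error about the
    mean profile (lower = tighter); ``mean_within_corr`` the mean Pearson
    correlation of members to the mean profile.
    """

    members: list[str]
    mean_profile: pd.Series
    informativeness: float
    mean_within_corr: float
    expanded: list[str] = field(default_factory=list)


def _group_from_members(mat: pd.DataFrame, members: list[str]) -> SynexpressionGroup:
    block = mat.loc[members]
    mean_profile = block.mean(axis=0)
    mse = float(((block - mean_profile) ** 2).to_numpy().mean())
    mp = mean_profile.to_numpy()
    if np.std(mp) == 0:
        corr = 1.0
    else:
        cors = [
            1.0 if np.std(row) == 0 else float(np.corrcoef(row, mp)[0, 1])
            for row in block.to_numpy()
        ]
        corr = float(np.mean(cors))
    return SynexpressionGroup(list(members), mean_profile, mse, corr)


def synexpression_groups(
    norm: NormalizationResult,
    set_members: list[str],
    significant_genes: list[str],
    min_corr: float = 0.85,
    max_groups: int = 10,
) -> list[SynexpressionGroup]:
    """Decompose a pathway's significant genes into correlated subsets.

    Average-linkage hierarchical clustering on 1 - Pearson correlation; the
    dendrogram is cut at the smallest k such that every cluster's mean
    member-to-mean-profile correlation reaches ``min_corr`` (or at
    ``max_groups``).  Singleton clusters are dropped.  Fewer than 3
    eligible genes yields one trivial group with a warning.
    """
    eligible = [g for g in set_members if g in set(significant_genes) and g in norm.matrix.index]
    if not eligible:
        raise ValueError("no significant in-set genes to decompose")
    mat = norm.matrix
    if len(eligible) < 3:
        logger.warning("only %d eligible genes; returning a single trivial group", len(eligible))
        return [_group_from_members(mat, eligible)]

    block = mat.loc[eligible].to_numpy()
    # correlation distance; guard constant rows (zero variance -> r treated as 0)
    sd = block.std(axis=1)
    safe = np.where(sd[:, None] > 0, (block - block.mean(axis=1)[:, None]) / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
    corr = np.clip(safe @ safe.T / block.shape[1], -1.0, 1.0)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    link = linkage(np.maximum(dist[iu], 0.0), method="average")

    chosen: list[list[str]] | None = None
    for k in range(1, max_groups + 1):
        assignment = fcluster(link, t=k, criterion="maxclust")
        clusters = [
            [eligible[i] for i in np.flatnonzero(assignment == c)]
            for c in np.unique(assignment)
        ]
        groups = [_group_from_members(mat, members) for members in clusters]
        if all(g.mean_within_corr >= min_corr for g in groups):
            chosen = clusters
            break
    if chosen is None:
        assignment = fcluster(link, t=max_groups, criterion="maxclust")
        chosen = [
            [eligible[i] for i in np.flatnonzero(assignment == c)]
            for c in np.unique(assignment)
        ]
    result = [_group_from_members(mat, members) for members in chosen if len(members) > 1]
    if not result:  # everything singleton: fall back to one trivial group
        result = [_group_from_members(mat, eligible)]
    return result


def expand_synexpression(
    norm: NormalizationResult,
    group: SynexpressionGroup,
    universe: list[str] | None = None,
    corr_threshold: float = 0.85,
) -> list[str]:
    """Genes whose profile correlates with the group mean at or above threshold.

    The threshold applies to signed Pearson r against the group's mean
    profile; the result is the union of matches with the group members, in
    matrix order.  Lowering the threshold can only add genes.
    """
    if not group.members:
        raise ValueError("cannot expand an empty group")
    mat = norm.matrix if universe is None else norm.matrix.loc[[g for g in norm.matrix.index if g in set(universe)]]
    mp = group.mean_profile.loc[mat.columns].to_numpy()
    x = mat.to_numpy()
    mp_c = mp - mp.mean()
    mp_sd = mp_c.std()
    x_c = x - x.mean(axis=1, keepdims=True)
    x_sd = x_c.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(
            (x_sd > 0) & (mp_sd > 0),
            (x_c @ mp_c) / (len(mp) * x_sd * mp_sd),
            np.where((x_sd == 0) & (mp_sd == 0), 1.0, 0.0),
        )
    hits = set(mat.index[r >= corr_threshold]) | set(group.members)
    return [g for g in norm.matrix.index if g in hits]


def run_attract(
    norm: NormalizationResult,
    classes: pd.Series,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_corr: float = 0.85,
    max_groups: int = 10,
    corr_threshold: float = 0.85,
    min_size: int = 5,
) -> tuple[pd.DataFrame, dict[str, list[SynexpressionGroup]]]:
    """Full procedure: ANOVA -> set ranking -> decomposition -> expansion.

    Returns the ranked pathway table and, per retained set, its
    synexpression groups with expanded membership filled in.
    """
    anova = gene_fstat(norm, classes)
    table = find_core_pathways(anova, sets, alpha=alpha, min_size=min_size)
    significant = list(anova.index[bh_adjust(anova["p_value"].to_numpy()) < alpha])
    modules: dict[str, list[SynexpressionGroup]] = {}
    for name in table["set_name"]:
        members = sets[name]
        if not set(members) & set(significant):
            modules[name] = []
            continue
        groups = synexpression_groups(norm, members, significant, min_corr, max_groups)
        for g in groups:
            g.expanded = expand_synexpression(norm, g, corr_threshold=corr_threshold)
        modules[name] = groups
    return table, modules
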