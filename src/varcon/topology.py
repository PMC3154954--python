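"""Constraint class versus interaction-network connectivity.

For one donor group, each classified gene is mapped to its network node and
annotated with the node degree; per-class degree distributions are
summarized with Gaussian kernel density estimates (descriptive only) and
compared with a two-sample Kolmogorov-Smirnov test (primary) alongside a
chi-square on jointly binned counts, since published analyses of this kind
report both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import InteractionNetwork
from .variance import CVProfile, ConstraintClassification

logger = logging.getLogger("varcon")


@dataclass
class DegreeByClass:
    """Per-gene degree records and per-class degree vectors for one group."""

    records: pd.DataFrame  # columns: node, degree, constraint_class
    group: str
    kde: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    n_unmapped: int = 0

    def degrees(self, cls: str) -> np.ndarray:
        r = self.records
        return r.loc[r["constraint_class"] == cls, "degree"].to_numpy()


@dataclass
class DegreeComparison:
    class_a: str
    class_b: str
    ks_statistic: float
    ks_p: float
    chisq_statistic: float
    chisq_p: float
    chisq_df: int
    bins: np.ndarray


def ks_2sample(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sample KS statistic and p-value (exact for small samples).

    Thin, unrestricted wrapper used both here and by callers needing the
    bare statistic: D = sup_x |ECDF_a(x) - ECDF_b(x)|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = stats.ks_2samp(a, b, method=mode)
    return float(res.statistic), float(res.pvalue)


def degree_by_class(
    network: InteractionNetwork,
    classification: ConstraintClassification,
    group: str,
    kde_grid_size: int = 256,
) -> DegreeByClass:
    """Attach node degrees to each classified gene of one donor group.

    Genes without a mapped node in the graph are excluded and counted.
    A Gaussian KDE (Scott's reference-rule bandwidth) is fitted per class
    when the class has >= 2 distinct degree values; the curve is normalized
    to integrate to 1 on its grid.
    """
    labels = classification.labels[group]
    rows = []
    n_unmapped = 0
    for gene, cls in labels.items():
        if cls is None or (isinstance(cls, float) and np.isnan(cls)):
            continue
        deg = network.degree_of(gene)
        if deg is None:
            n_unmapped += 1
            continue
        rows.append({"probe_id": gene, "node": network.node_map.get(gene, gene), "degree": deg, "constraint_class": cls})
    if not rows:
        raise ValueError("node_map covers no classified gene")
    records = pd.DataFrame(rows).set_index("probe_id")
    dbc = DegreeByClass(records=records, group=group, n_unmapped=n_unmapped)

    for cls in records["constraint_class"].unique():
        deg = dbc.degrees(cls).astype(float)
        if len(deg) < 2 or np.all(deg == deg[0]):
            logger.warning("class %r: too few distinct degrees for a KDE; omitted", cls)
            continue
        kde = stats.gaussian_kde(deg)  # Scott's rule
        bw = kde.factor * deg.std(ddof=1)
        grid = np.linspace(deg.min() - 3 * bw, deg.max() + 3 * bw, kde_grid_size)
        density = kde(grid)
        density = density / np.trapezoid(density, grid)
        dbc.kde[cls] = (grid, density)
    return dbc


def _merged_quantile_bins(pooled: np.ndarray, n_a: int, n_b: int, n_bins: int) -> np.ndarray:
    """Quantile bin edges on the pooled sample, merged until expected >= 5."""
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
    edges[0], edges[-1] = -np.inf, np.inf
    while len(edges) > 2:
        counts = np.histogram(pooled, bins=edges)[0]
        frac = counts / counts.sum()
        exp_a, exp_b = frac * n_a, frac * n_b
        if (exp_a >= 5).all() and (exp_b >= 5).all():
            break
        i = int(np.argmin(np.minimum(exp_a, exp_b)))
        drop = i + 1 if i + 1 < len(edges) - 1 else i
        edges = np.delete(edges, drop)
    return edges


def compare_degree_distributions(
    dbc: DegreeByClass,
    class_a: str = "high",
    class_b: str = "low",
    n_bins: int | None = None,
) -> DegreeComparison:
    """KS (primary) and binned chi-square comparison of two class degree sets.

    Bins for the chi-square are pooled-sample quantile bins merged until
    every expected cell is >= 5; a single surviving bin is an error.  Both
    classes need >= 5 nodes.
    """
    a = dbc.degrees(class_a).astype(float)
    b = dbc.degrees(class_b).astype(float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("both classes need >= 5 nodes")
    ks_d, ks_p = ks_2sample(a, b)

    pooled = np.concatenate([a, b])
    if n_bins is None:
        n_bins = max(2, min(10, len(pooled) // 20))
    edges = _merged_quantile_bins(pooled, len(a), len(b), n_bins)
    if len(edges) <= 2:
        raise ValueError("degenerate binning: a single bin carries all degrees")
    obs = np.vstack([np.histogram(a, bins=edges)[0], np.histogram(b, bins=edges)[0]])
    chi2, chi_p, df, _ = stats.chi2_contingency(obs, correction=False)
    return DegreeComparison(
        class_a=class_a,
        class_b=class_b,
        ks_statistic=ks_d,
        ks_p=ks_p,
        chisq_statistic=float(chi2),
        chisq_p=float(chi_p),
        chisq_df=int(df),
        bins=edges,
    )


def degree_cv_correlation(
    dbc: DegreeByClass,
    profile: CVProfile,
    group: str,
    resolve: str = "min",
) -> tuple[float, float]:
    """Spearman rank correlation between node degree and gene CV in a group.

    Probes sharing one node are collapsed by the most-constrained CV
    (``resolve='min'``, default) or the mean (``resolve='mean'``).
    Returns (rho, p); a constant degree vector yields (nan, nan) with a
    warning, since rank correlation is undefined there.
    """
    if resolve not in ("min", "mean"):
        raise ValueError("resolve must be 'min' or 'mean'")
    recs = dbc.records.join(profile.cv[group].rename("cv"), how="inner").dropna(subset=["cv"])
    agg = recs.groupby("node").agg(degree=("degree", "first"), cv=("cv", resolve))
    if len(agg) < 10:
        raise ValueError("need >= 10 mapped genes for a rank correlation")
    if agg["degree"].nunique() == 1:
        logger.warning("constant degree vector; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(agg["degree"], agg["cv"])
    return float(rho), float(p)
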