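"""Synthetic expression data with the statistical structure the analysis assumes.

The generator emulates a patient-derived microarray study: log-normal baseline
intensities, per-gene dispersion drawn from a long-tailed (gamma) law,
group-specific variance scaling (a variance-deflated "SZ-like" group and a
variance-inflated "PD-like" group around a control group), pathway-targeted
mean shifts between cell types (the signal the ANOVA pathway discovery looks
for), donor-replicate structure, separable detection p-values, and an
interaction network whose node degree is negatively coupled to expression CV.

All randomness descends from one seed through named substreams, so adding a
stage never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionBundle, GeneSetCollection, InteractionNetwork
import networkx as nx

_LN2 = np.log(2.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named stage under one global seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One donor group: label, number of donors, and the multiplicative
    factor applied to every gene's log-scale dispersion in that group."""

    label: str
    n_donors: int
    variance_scale: float = 1.0


@dataclass(frozen=True)
class PathwaySpec:
    """A planted gene set: ``mean_shift`` (log2 units) separates cell types
    for its members; ``variance_scale_override`` additionally multiplies
    their dispersion in every group."""

    name: str
    size: int
    mean_shift: float = 0.0
    variance_scale_override: float | None = None


@dataclass(frozen=True)
class ReplicateSpec:
    """Donor-replicate structure: ``n_donors`` donors (allocated round-robin
    across groups) each contribute ``replicates_per_donor`` samples."""

    n_donors: int
    replicates_per_donor: int = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for :func:`generate_dataset`.

    Defaults mirror the emulated study: 11 control, 9 variance-deflated
    (SZ-like, scale 0.5) and 13 variance-inflated (PD-like, scale 1.6)
    donors; log2 intensities centred at 8 +/- 2; per-gene CVs gamma with
    mean 0.2 and shape 2 (``cv_shape=None`` makes dispersion homogeneous —
    the exchangeable null used for test calibration); donor effects carry
    ``donor_effect_fraction`` of each gene's total between-sample standard
    deviation, leaving replicates of one donor less variable than samples
    of distinct donors.
    """

    n_genes: int = 2000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("Control", 11, 1.0),
        GroupSpec("SZ", 9, 0.5),
        GroupSpec("PD", 13, 1.6),
    )
    n_celltypes: int = 1
    pathways: tuple[PathwaySpec, ...] = ()
    baseline_mean_log2: tuple[float, float] = (8.0, 2.0)  # (mean, sd)
    cv_mean: float = 0.2
    cv_shape: float | None = 2.0  # gamma shape; None => all genes share cv_mean
    donor_effect_fraction: float = 0.8
    replicate_spec: ReplicateSpec | None = None
    detection_noise: float = 0.02  # probability a (probe, sample) drops out
    frac_undetected: float = 0.0  # fraction of probes undetected in every sample
    degree_cv_coupling: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for g in self.groups:
            if g.variance_scale <= 0:
                raise ValueError(f"variance_scale must be > 0 in group {g.label!r}")
            if g.n_donors < 2:
                raise ValueError(f"group {g.label!r} needs >= 2 donors")
        if sum(p.size for p in self.pathways) > self.n_genes:
            raise ValueError("pathway sizes exceed n_genes")
        for p in self.pathways:
            if p.size > self.n_genes:
                raise ValueError(f"pathway {p.name!r} larger than n_genes")
        if self.replicate_spec is not None and self.replicate_spec.replicates_per_donor < 2:
            raise ValueError("replicates_per_donor must be >= 2")
        if not 0 <= self.frac_undetected < 1:
            raise ValueError("frac_undetected must be in [0, 1)")
        if not 0 <= self.donor_effect_fraction < 1:
            raise ValueError("donor_effect_fraction must be in [0, 1)")
        if not -1 <= self.degree_cv_coupling <= 1:
            raise ValueError("degree_cv_coupling must be in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests.

    ``base_cv`` is each gene's dispersion before group scaling; ``true_cv``
    the implied per-group CV of the linear-scale intensities; ``true_class``
    the constraint class implied by thresholding ``true_cv`` at the
    25th/75th percentiles of the base distribution.
    """

    base_cv: pd.Series
    true_cv: pd.DataFrame  # gene x group
    true_class: pd.DataFrame  # gene x group, {low, mid, high}
    pathway_members: dict[str, list[str]] = field(default_factory=dict)
    degree_cv_coupling: float = 0.0


def _sigma_log2(cv: np.ndarray) -> np.ndarray:
    """log2-scale sd of a log-normal with linear-scale coefficient of variation cv."""
    return np.sqrt(np.log1p(np.asarray(cv) ** 2)) / _LN2


def _cv_from_sigma_log2(sigma: np.ndarray) -> np.ndarray:
    return np.sqrt(np.expm1((np.asarray(sigma) * _LN2) ** 2))


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionBundle, GeneSetCollection, SyntheticTruth]:
    """Generate an expression bundle, its gene sets and the ground truth.

    Per gene g with baseline log2 mean mu_g and dispersion sigma_g, a sample
    of donor d in group k (variance scale s_k) has

        log2 intensity = mu_g + shift_g(cell type) + a_{g,d} + e,

    with donor effect a ~ N(0, (f * s_k * sigma_g)^2) and residual
    e ~ N(0, ((1 - f^2)^{1/2} * s_k * sigma_g)^2), f the donor-effect
    fraction; the total sd across independent donors is s_k * sigma_g, so
    the implied linear-scale CV is sqrt(exp((s_k sigma_g ln2)^2) - 1).
    Pathway members receive ``mean_shift`` in every cell type beyond the
    first.  Detection p-values are Uniform(0, 0.005) for expressed entries
    and Uniform(0.1, 1) for dropouts, cleanly separable around 0.01.
    """
    config.validate()
    rng_expr = substream(config.seed, "expression")
    rng_drop = substream(config.seed, "dropout")

    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="probe_id")

    mu = rng_expr.normal(*config.baseline_mean_log2, size=n)
    if config.cv_shape is None:
        base_cv = np.full(n, config.cv_mean)
    else:
        base_cv = rng_expr.gamma(config.cv_shape, config.cv_mean / config.cv_shape, size=n)
        base_cv = np.maximum(base_cv, 1e-4)
    sigma = _sigma_log2(base_cv)

    # pathway membership: disjoint blocks from the front of the gene index
    pathway_members: dict[str, list[str]] = {}
    shift = np.zeros(n)
    var_override = np.ones(n)
    cursor = 0
    for p in config.pathways:
        members = genes[cursor:cursor + p.size]
        cursor += p.size
        pathway_members[p.name] = list(members)
        idx = slice(cursor - p.size, cursor)
        shift[idx] = p.mean_shift
        if p.variance_scale_override is not None:
            var_override[idx] = p.variance_scale_override

    # sample design -----------------------------------------------------
    rep_quota: dict[str, int] = {g.label: 0 for g in config.groups}
    if config.replicate_spec is not None:
        labels = [g.label for g in config.groups]
        for i in range(config.replicate_spec.n_donors):
            rep_quota[labels[i % len(labels)]] += 1

    rows = []
    for g in config.groups:
        for j in range(g.n_donors):
            donor = f"{g.label}_d{j:02d}"
            n_reps = (
                config.replicate_spec.replicates_per_donor
                if config.replicate_spec is not None and j < rep_quota[g.label]
                else 1
            )
            for ct in range(config.n_celltypes):
                ct_label = f"ct{ct}"
                for r in range(n_reps):
                    rows.append(
                        {
                            "sample_id": f"{donor}_{ct_label}_r{r}",
                            "donor_id": donor,
                            "group_label": g.label,
                            "cell_type": ct_label,
                            "replicate_id": f"r{r}",
                        }
                    )
    design = pd.DataFrame(rows).set_index("sample_id")

    # intensities --------------------------------------------------------
    scale_by_group = {g.label: g.variance_scale for g in config.groups}
    f = config.donor_effect_fraction
    donor_ids = list(pd.unique(design["donor_id"]))
    donor_effects = {}
    for donor in donor_ids:
        s_k = scale_by_group[design.loc[design["donor_id"] == donor, "group_label"].iloc[0]]
        donor_effects[donor] = rng_expr.normal(0.0, 1.0, size=n) * (f * s_k * sigma * var_override)

    log2x = np.empty((n, len(design)))
    resid_frac = np.sqrt(1.0 - f * f)
    for j, (sample, row) in enumerate(design.iterrows()):
        s_k = scale_by_group[row["group_label"]]
        ct = int(row["cell_type"][2:])
        e = rng_expr.normal(0.0, 1.0, size=n) * (resid_frac * s_k * sigma * var_override)
        log2x[:, j] = mu + (shift if ct > 0 else 0.0) + donor_effects[row["donor_id"]] + e

    expression = pd.DataFrame(np.exp2(log2x), index=genes, columns=design.index)

    # detection p-values -------------------------------------------------
    dropout = rng_drop.random(expression.shape) < config.detection_noise
    det = rng_drop.uniform(0.0, 0.005, size=expression.shape)
    det[dropout] = rng_drop.uniform(0.1, 1.0, size=int(dropout.sum()))
    if config.frac_undetected > 0:
        # probes below background on the platform: undetected in every sample
        n_undet = int(round(config.frac_undetected * n))
        undet = rng_drop.choice(n, size=n_undet, replace=False)
        det[undet, :] = rng_drop.uniform(0.1, 1.0, size=(n_undet, det.shape[1]))
    detection = pd.DataFrame(det, index=genes, columns=design.index)

    bundle = ExpressionBundle(expression, detection, design)

    # ground truth -------------------------------------------------------
    true_cv = pd.DataFrame(
        {
            g.label: _cv_from_sigma_log2(g.variance_scale * sigma * var_override)
            for g in config.groups
        },
        index=genes,
    )
    lo, hi = np.percentile(base_cv, [25, 75])
    true_class = true_cv.apply(
        lambda col: np.where(col < lo, "low", np.where(col > hi, "high", "mid"))
    )
    truth = SyntheticTruth(
        base_cv=pd.Series(base_cv, index=genes, name="base_cv"),
        true_cv=true_cv,
        true_class=pd.DataFrame(true_class, index=genes, columns=true_cv.columns),
        pathway_members=pathway_members,
        degree_cv_coupling=config.degree_cv_coupling,
    )
    sets = GeneSetCollection(
        sets={k: list(v) for k, v in pathway_members.items()},
        descriptions={k: "synthetic pathway" for k in pathway_members},
        universe=list(genes),
        original_sizes={k: len(v) for k, v in pathway_members.items()},
    )
    return bundle, sets, truth


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def generate_network(
    truth: SyntheticTruth,
    coupling: float,
    n_extra_edges: int = 0,
    seed: int = 0,
    n_base_edges: int | None = None,
) -> InteractionNetwork:
    """Random interaction network whose degrees are rank-coupled to CV.

    Each gene becomes one node.  A latent propensity mixes the reversed CV
    rank (weight ``coupling``) with independent noise, and base edges are
    drawn with endpoint probabilities increasing in that propensity, so the
    Spearman correlation between degree and true CV approaches
    ``-coupling``.  ``n_extra_edges`` uniformly random edges are added on
    top.  Edge counts are exact; self-loops and duplicates are rejected.
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must be in [-1, 1]")
    rng = substream(seed, "network")
    genes = list(truth.base_cv.index)
    n = len(genes)
    if n_base_edges is None:
        n_base_edges = 2 * n

    cv_rank = pd.Series(truth.base_cv.to_numpy(), index=genes).rank().to_numpy()
    z_rank = -(cv_rank - cv_rank.mean()) / cv_rank.std()
    noise = rng.standard_normal(n)
    z = coupling * z_rank + np.sqrt(max(0.0, 1.0 - coupling**2)) * noise
    w = np.exp(1.5 * (z - z.max()))
    p = w / w.sum()

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    edges: set[tuple[int, int]] = set()

    def draw(m: int, probs: np.ndarray | None) -> None:
        attempts = 0
        while len(edges) < m and attempts < 200:
            need = m - len(edges)
            a = rng.choice(n, size=2 * need, p=probs)
            b = rng.choice(n, size=2 * need, p=probs)
            for i, j in zip(a, b):
                if i == j:
                    continue
                e = (min(i, j), max(i, j))
                if e not in edges:
                    edges.add(e)
                    if len(edges) >= m:
                        break
            attempts += 1

    draw(n_base_edges, p)
    draw(n_base_edges + n_extra_edges, None)
    graph.add_edges_from((genes[i], genes[j]) for i, j in edges)
    return InteractionNetwork(graph, node_map={g: g for g in genes})


def write_truth(truth: SyntheticTruth, out_dir) -> None:
    """Write truth tables as TSV next to the generated bundle."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = truth.true_cv.copy()
    tab.insert(0, "base_cv", truth.base_cv)
    tab.to_csv(out / "truth_cv.tsv", sep="\t")
    truth.true_class.to_csv(out / "truth_class.tsv", sep="\t")
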