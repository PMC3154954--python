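"""End-to-end orchestration from one YAML config.

Stage order: (simulate or load) -> detection filter -> normalization ->
CV profiling and constraint classification -> ANOVA pathway discovery ->
genome-wide and per-pathway group comparisons -> network topology ->
replicate variance -> enrichment.  Every stage writes TSV tables; a JSON
manifest records versions, seeds and parameters, and a Markdown summary
collects the headline numbers.  Identical config + seeds reproduce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attract import run_attract
from .compare import (
    class_count_chisq,
    cutoff_sensitivity,
    logcv_ttest,
    mean_expression_ttest,
)
from .data_io import (
    ExpressionBundle,
    GeneSetCollection,
    InteractionNetwork,
    read_annotations,
    read_expression_bundle,
    read_gene_sets,
    read_network,
    write_expression_bundle,
    write_gene_sets,
    write_network,
)
from .enrichment import enrich, unique_terms
from .preprocessing import detection_filter, normalize
from .replicates import intra_vs_inter
from .synthetic import (
    GroupSpec,
    PathwaySpec,
    ReplicateSpec,
    SyntheticConfig,
    generate_dataset,
    generate_network,
    write_truth,
)
from .topology import compare_degree_distributions, degree_by_class, degree_cv_correlation
from .variance import POOLED, classify_constraint, compute_cv

logger = logging.getLogger("varcon")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``inputs`` / ``simulate`` set."""

    out_dir: str = "varcon_out"
    inputs: dict | None = None  # expression/detection/design/gene_sets/network/annotations paths
    simulate: SyntheticConfig | None = None
    normalization: str = "log2_quantile"
    detection_p: float = 0.01
    detection_fraction: float = 0.75
    detection_scope: str = "any_group"
    control_label: str = "Control"
    classes_column: str = "cell_type"
    cutoffs: tuple[tuple[float, float], ...] = ((25.0, 75.0), (10.0, 90.0), (5.0, 95.0))
    alpha: float = 0.05
    min_corr: float = 0.85
    subset_size: int = 4
    n_subsets: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if "cutoffs" in raw:
            cfg.cutoffs = tuple(tuple(map(float, c)) for c in raw["cutoffs"])
        if sim is not None:
            groups = tuple(GroupSpec(**g) for g in sim.pop("groups", []))
            pathways = tuple(PathwaySpec(**p) for p in sim.pop("pathways", []))
            rep = sim.pop("replicate_spec", None)
            cfg.simulate = SyntheticConfig(
                groups=groups or SyntheticConfig.groups,
                pathways=pathways,
                replicate_spec=ReplicateSpec(**rep) if rep else None,
                **sim,
            )
        if (cfg.inputs is None) == (cfg.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
        return cfg


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    bundle = read_expression_bundle(
        paths["expression"], paths.get("detection"), paths["design"],
        is_log2=bool(paths.get("is_log2", False)),
    )
    sets = (
        read_gene_sets(paths["gene_sets"], list(bundle.probes))
        if paths.get("gene_sets")
        else None
    )
    network = read_network(paths["network"]) if paths.get("network") else None
    annotations = read_annotations(paths["annotations"]) if paths.get("annotations") else None
    return bundle, sets, None, network, annotations


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage failure aborts with the stage name in the raised error; the
    manifest written so far is marked incomplete.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "varcon_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "normalization": cfg.normalization,
            "detection_p": cfg.detection_p,
            "detection_fraction": cfg.detection_fraction,
            "cutoffs": [list(c) for c in cfg.cutoffs],
            "alpha": cfg.alpha,
            "control_label": cfg.control_label,
        },
        "stages": {},
        "complete": False,
    }
    summary_lines = ["# varcon run summary", ""]
    stage = "setup"
    try:
        t0 = time.time()
        # ------------------------------------------------ inputs / simulation
        stage = "inputs"
        truth = None
        annotations = None
        network = None
        if cfg.simulate is not None:
            sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed or cfg.seed)
            bundle, sets, truth = generate_dataset(sim)
            network = generate_network(truth, sim.degree_cv_coupling, seed=sim.seed)
            write_expression_bundle(bundle, out / "inputs")
            write_gene_sets(sets, out / "inputs" / "gene_sets.gmt")
            write_network(network, out / "inputs" / "network.tsv")
            write_truth(truth, out / "inputs")
            manifest["stages"]["inputs"] = {"mode": "simulate", "seed": sim.seed}
        else:
            bundle, sets, truth, network, annotations = _load_inputs(cfg)
            manifest["stages"]["inputs"] = {"mode": "files"}

        # ------------------------------------------------ detection filter
        stage = "detection_filter"
        if bundle.detection is not None:
            detected = detection_filter(
                bundle, cfg.detection_p, cfg.detection_fraction, cfg.detection_scope
            )
        else:
            detected = list(bundle.probes)
        manifest["stages"]["detection_filter"] = {
            "n_probes": len(bundle.probes), "n_detected": len(detected),
        }
        summary_lines.append(
            f"- detection filter: {len(detected)} / {len(bundle.probes)} probes pass"
        )

        # ------------------------------------------------ normalization
        stage = "normalization"
        norm = normalize(bundle, cfg.normalization, detected=detected)
        manifest["stages"]["normalization"] = norm.provenance
        norm.matrix.to_csv(out / "normalized.tsv", sep="\t")

        # ------------------------------------------------ CV + classification
        stage = "variance_constraint"
        profile = compute_cv(norm, bundle.design)
        low0, high0 = cfg.cutoffs[0]
        cls = classify_constraint(profile, low0, high0)
        profile.cv.to_csv(out / "cv.tsv", sep="\t")
        cls.labels.to_csv(out / "constraint_class.tsv", sep="\t")
        counts = {g: cls.class_counts(g) for g in profile.groups}
        manifest["stages"]["variance_constraint"] = {
            "thresholds": list(cls.thresholds),
            "class_counts": {g: list(c) for g, c in counts.items()},
            "n_undefined": cls.n_undefined,
        }
        for g, c in counts.items():
            summary_lines.append(f"- class counts {g} (low/mid/high): {c}")

        # ------------------------------------------------ attract
        stage = "attract"
        pathways = pd.DataFrame()
        modules: dict = {}
        if sets is not None and len(sets) and bundle.design[cfg.classes_column].nunique() >= 2:
            classes = bundle.design[cfg.classes_column]
            pathways, modules = run_attract(
                norm, classes, sets, alpha=cfg.alpha, min_corr=cfg.min_corr
            )
            pathways.to_csv(out / "core_pathways.tsv", sep="\t", index=False)
            with open(out / "synexpression.tsv", "w", encoding="utf-8") as fh:
                fh.write("set_name\tgroup_index\tn_members\tn_expanded\tmembers\n")
                for name, groups in modules.items():
                    for i, g in enumerate(groups):
                        fh.write(
                            f"{name}\t{i}\t{len(g.members)}\t{len(g.expanded)}\t"
                            + ",".join(g.members) + "\n"
                        )
            summary_lines.append(f"- core pathways retained: {len(pathways)}")
        manifest["stages"]["attract"] = {"n_retained": int(len(pathways))}

        # ------------------------------------------------ group comparisons
        stage = "group_comparison"
        comp_rows = []
        test_groups = [g for g in profile.groups if g != cfg.control_label]
        control_counts = counts.get(cfg.control_label)
        for g in test_groups:
            cvt = logcv_ttest(profile, g, cfg.control_label)
            mt = mean_expression_ttest(norm.matrix, bundle.design, g, cfg.control_label)
            genome = list(cls.labels.index[cls.labels[g].notna()])
            chi_prop = class_count_chisq(cls, genome, g, "proportions")
            chi_ctrl = (
                class_count_chisq(cls, genome, g, "control_counts", control_counts)
                if control_counts
                else None
            )
            comp_rows.append(
                {
                    "group": g,
                    "logcv_t": cvt.t_statistic,
                    "logcv_p": cvt.p_value,
                    "mean_expr_t": mt.t_statistic,
                    "mean_expr_p": mt.p_value,
                    "chisq_25_50_25": chi_prop.statistic,
                    "chisq_25_50_25_p": chi_prop.p_value,
                    "low_excess": chi_prop.low_excess,
                    "chisq_control": chi_ctrl.statistic if chi_ctrl else np.nan,
                    "chisq_control_p": chi_ctrl.p_value if chi_ctrl else np.nan,
                }
            )
            summary_lines.append(
                f"- {g} vs {cfg.control_label}: log2-CV t = {cvt.t_statistic:.2f} "
                f"(p = {cvt.p_value:.3g}), low-class excess = {chi_prop.low_excess:+.0f}"
            )
        genome_comparison = pd.DataFrame(comp_rows)
        genome_comparison.to_csv(out / "genome_comparison.tsv", sep="\t", index=False)

        # per-pathway composition + cutoff sensitivity for retained pathways
        path_rows = []
        for name in (pathways["set_name"] if len(pathways) else []):
            for g in profile.groups:
                members = [m for m in sets[name] if m in cls.labels.index]
                try:
                    t = class_count_chisq(cls, members, g, "proportions")
                except ValueError:
                    continue
                path_rows.append(
                    {
                        "set_name": name, "group": g,
                        "n_low": t.observed[0], "n_mid": t.observed[1], "n_high": t.observed[2],
                        "statistic": t.statistic, "p_value": t.p_value,
                    }
                )
        if path_rows:
            pd.DataFrame(path_rows).to_csv(out / "pathway_composition.tsv", sep="\t", index=False)
        if test_groups:
            genome = list(cls.labels.index[cls.labels[test_groups[0]].notna()])
            sens = cutoff_sensitivity(profile, genome, test_groups[0], cfg.cutoffs)
            sens.to_csv(out / "cutoff_sensitivity.tsv", sep="\t", index=False)
        manifest["stages"]["group_comparison"] = {"n_groups_tested": len(test_groups)}

        # ------------------------------------------------ network topology
        stage = "network_topology"
        if network is not None and network.n_nodes:
            topo_rows = []
            for g in profile.groups:
                try:
                    dbc = degree_by_class(network, cls, g)
                    comp = compare_degree_distributions(dbc, "high", "low")
                    rho, rho_p = degree_cv_correlation(dbc, profile, g)
                except ValueError as err:
                    logger.warning("topology skipped for %s: %s", g, err)
                    continue
                topo_rows.append(
                    {
                        "group": g,
                        "ks_statistic": comp.ks_statistic, "ks_p": comp.ks_p,
                        "chisq_statistic": comp.chisq_statistic, "chisq_p": comp.chisq_p,
                        "spearman_degree_cv": rho, "spearman_p": rho_p,
                        "n_unmapped": dbc.n_unmapped,
                    }
                )
                summary_lines.append(
                    f"- topology {g}: KS D = {comp.ks_statistic:.3f} (p = {comp.ks_p:.3g}), "
                    f"Spearman(degree, CV) = {rho:.3f}"
                )
            if topo_rows:
                pd.DataFrame(topo_rows).to_csv(out / "topology.tsv", sep="\t", index=False)
            manifest["stages"]["network_topology"] = {"n_groups": len(topo_rows)}

        # ------------------------------------------------ replicate variance
        stage = "replicate_variance"
        if (bundle.replicate_counts() >= 2).any():
            try:
                rep = intra_vs_inter(
                    norm, bundle.design, cfg.subset_size, cfg.n_subsets, cfg.seed,
                    modules={n: sets[n] for n in sets.names()} if sets else None,
                )
                rep.intra_cv_mean.to_csv(out / "intra_cv.tsv", sep="\t")
                manifest["stages"]["replicate_variance"] = {
                    "intra_mean": rep.intra_mean, "inter_mean": rep.inter_mean,
                    "p_value": rep.p_value,
                }
                summary_lines.append(
                    f"- intra-donor mean CV {rep.intra_mean:.4f} vs "
                    f"inter-donor {rep.inter_mean:.4f} (p = {rep.p_value:.3g})"
                )
            except ValueError as err:
                logger.warning("replicate variance skipped: %s", err)

        # ------------------------------------------------ enrichment
        stage = "enrichment"
        if annotations is not None and len(annotations):
            universe = [g for g in cls.labels.index]
            for g in profile.groups:
                high = sorted(cls.genes_in_class(g, "high"))
                low = sorted(cls.genes_in_class(g, "low"))
                if not high or not low:
                    continue
                eh = enrich(high, annotations, universe, cfg.alpha)
                el = enrich(low, annotations, universe, cfg.alpha)
                uh, ul = unique_terms(eh, el, cfg.alpha)
                uh.to_csv(out / f"enrichment_high_{g}.tsv", sep="\t", index=False)
                ul.to_csv(out / f"enrichment_low_{g}.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"done": True}

        manifest["complete"] = True
        manifest["elapsed_s"] = round(time.time() - t0, 3)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.md").write_text("\n".join(summary_lines) + "\n")
    logger.info("pipeline complete in %.1fs -> %s", manifest["elapsed_s"], out)
    return manifest
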