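"""End-to-end study orchestration.

One config drives the whole analysis: load (or simulate) the three omic
blocks, align samples, filter and normalize per omic, run diversity and
confounder screens, univariate + latent-variable marker discovery with VIP
fusion per omic, Frobenius-normalized multiblock integration, and the
per-group interkingdom networks.  The result is a JSON-serializable
:class:`StudyReport` plus TSV artifacts; identical config and seed give an
identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, differential, latent, multiblock, network
from .core_io import (
    AlignedStudy,
    FeatureTable,
    align_samples,
    read_feature_table,
    read_metadata,
)
from .preprocess import (
    DEFAULT_FILTERS,
    FilterRule,
    css_normalize,
    frobenius_normalize,
    log_transform,
    min_sample_depth,
    prevalence_abundance_filter,
    rarefy,
    relative_abundance,
)
from .synthetic import SyntheticConfig, generate_study

logger = logging.getLogger("triomix")

TAXA_OMICS = ("bacteria", "fungi")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with per-module defaults.

    Either ``tables`` (paths to bacteria/fungi/metabolite TSVs) plus
    ``metadata`` (CSV path), or ``simulate`` (a :class:`SyntheticConfig`).
    """

    tables: dict = field(default_factory=dict)     # omic -> path
    metadata: str | None = None
    simulate: SyntheticConfig | None = None
    filters: dict = field(default_factory=dict)    # omic -> FilterRule
    css: dict = field(default_factory=lambda: {"quantile": 0.5, "scale": 1000.0})
    rarefaction: dict = field(default_factory=lambda: {"depth": None})
    shannon_base: float = 2.0
    n_perm: int = 999
    n_comp: int = 2
    k_folds: int = 7
    vip_threshold: float = 1.0
    alpha: float = 0.05
    lefse: differential.LefseParams = field(default_factory=differential.LefseParams)
    network_alpha: float = 0.05
    confounder_vars: list = field(
        default_factory=lambda: [
            "gender", "age", "corticosteroid_therapy",
            "previous_therapy", "failure_previous_therapies",
        ]
    )
    median_split_vars: list = field(default_factory=lambda: ["age"])
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "simulate" in raw:
            cfg.simulate = SyntheticConfig(**(raw["simulate"] or {}))
        cfg.tables = dict(raw.get("tables", {}))
        cfg.metadata = raw.get("metadata")
        for omic, rule in (raw.get("filters") or {}).items():
            cfg.filters[omic] = FilterRule(**rule)
        for key in ("css", "rarefaction"):
            getattr(cfg, key).update(raw.get(key) or {})
        for key in (
            "shannon_base", "n_perm", "n_comp", "k_folds", "vip_threshold",
            "alpha", "network_alpha", "confounder_vars", "median_split_vars",
            "seed", "out_dir",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "lefse" in raw:
            cfg.lefse = differential.LefseParams(**raw["lefse"])
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            missing = [o for o in ("bacteria", "fungi", "metabolite") if o not in self.tables]
            for omic in missing:
                logger.info("pipeline runs without the %s block", omic)
            if len(self.tables) < 2:
                raise ValueError("need at least two omic tables (or simulate:)")
            if self.metadata is None:
                raise ValueError("metadata path required when tables are given")
            for omic, path in self.tables.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{omic} table not found: {path}")
            if not Path(self.metadata).exists():
                raise FileNotFoundError(f"metadata not found: {self.metadata}")


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """One reproducible integer sub-seed per stage from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(names, children)}


def load_study(config: PipelineConfig):
    if config.simulate is not None:
        return generate_study(config.simulate)
    value_kinds = {"bacteria": "count", "fungi": "count", "metabolite": "concentration"}
    blocks = {
        omic: read_feature_table(path, omic, value_kind=value_kinds[omic])
        for omic, path in config.tables.items()
    }
    metadata = read_metadata(config.metadata)
    return align_samples(blocks, metadata), None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the study report as a plain dict."""
    config.validate()
    seeds = _stage_seeds(
        config.seed, ["rarefy", "permanova", "lefse", "cv", "confounder"]
    )
    study, truth = load_study(config)
    groups = study.groups
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_samples": len(study.sample_ids),
            "groups": {g: int((groups == g).sum()) for g in np.unique(groups)},
            "simulated": config.simulate is not None,
        }
    }

    # ---- filtering -------------------------------------------------------
    filters = {**DEFAULT_FILTERS, **config.filters}
    filtered: dict[str, FeatureTable] = {}
    report["filtering"] = {}
    for name, block in study.blocks.items():
        kept = prevalence_abundance_filter(block, filters[name])
        filtered[name] = kept
        report["filtering"][name] = {
            "n_input": block.shape[0], "n_kept": kept.shape[0],
            "n_removed": block.shape[0] - kept.shape[0],
        }
    study = AlignedStudy(filtered, study.metadata, list(study.sample_ids))

    # ---- per-omic normalizations ----------------------------------------
    rel = {name: relative_abundance(b) for name, b in study.blocks.items()}
    css = {
        name: css_normalize(study.blocks[name], config.css["quantile"], config.css["scale"])
        for name in TAXA_OMICS if name in study.blocks
    }

    # ---- diversity -------------------------------------------------------
    report["diversity"] = {}
    for name in TAXA_OMICS:
        if name not in study.blocks:
            continue
        block = study.blocks[name]
        depth = config.rarefaction["depth"] or min_sample_depth(block)
        rare = rarefy(block, depth, seeds["rarefy"])
        h = diversity.shannon(rare, base=config.shannon_base)
        lab = study.metadata.loc[h.index, "group"].to_numpy()
        from scipy.stats import mannwhitneyu

        hx, hy = h[lab == "UC"], h[lab == "CTRL"]
        alpha_p = float(mannwhitneyu(hx, hy, alternative="two-sided").pvalue)
        dm = diversity.bray_curtis(rel[name])
        perma = diversity.permanova(dm, groups, config.n_perm, seeds["permanova"])
        intra = diversity.intragroup_distance_test(dm, groups)
        report["diversity"][name] = {
            "rarefaction_depth": depth,
            "shannon_mean": {g: float(h[lab == g].mean()) for g in ("UC", "CTRL")},
            "shannon_p": alpha_p,
            "permanova_F": perma.statistic,
            "permanova_p": perma.p_value,
            "intragroup_U": intra.statistic,
            "intragroup_p": intra.p_value,
            "intragroup_medians": intra.extras["medians"],
        }

    # ---- confounders -----------------------------------------------------
    confounders = differential.confounder_screen(
        study, config.confounder_vars, config.median_split_vars,
        alpha=config.alpha, n_perm=min(config.n_perm, 199), seed=seeds["confounder"],
    )
    report["confounders"] = confounders.to_dict(orient="records")

    # ---- per-omic differential + latent + fusion ------------------------
    report["omics"] = {}
    marker_tables: dict[str, pd.DataFrame] = {}
    for name, block in study.blocks.items():
        uni_table = rel[name] if name in TAXA_OMICS else block
        stats = differential.mann_whitney_screen(uni_table, groups, alpha=config.alpha)
        lefse_params = differential.LefseParams(
            **{**config.lefse.__dict__, "seed": seeds["lefse"]}
        )
        lda_scores = differential.lefse(rel[name], groups, lefse_params)

        if name in TAXA_OMICS:
            X = log_transform(css[name]).values.T
            scale_flag = False
        else:
            X = block.values.T
            scale_flag = True
        pca_model = latent.pca(X, config.n_comp)
        pls = latent.plsda(X, groups, config.n_comp, scale=scale_flag)
        vips = pd.Series(latent.vip(pls), index=block.feature_ids)
        cv = latent.cross_validate(
            X, groups, config.n_comp, k=config.k_folds, seed=seeds["cv"], scale=scale_flag
        )
        auroc, _ = latent.roc_auc(pls.predict(X), groups)
        markers = latent.fuse_markers(vips, stats, config.vip_threshold, config.alpha)
        marker_tables[name] = markers
        verdicts = markers["verdict"].to_numpy()
        report["omics"][name] = {
            "n_features": block.shape[0],
            "n_univariate_significant": int(stats["significant"].sum()),
            "n_lefse_significant": int(lda_scores["significant"].sum()) if len(lda_scores) else 0,
            "pca_explained_variance": [float(v) for v in pca_model.explained_variance_ratio],
            "plsda": {"rmse": cv.rmse, "r2": cv.r2, "q2": cv.q2, "auroc": auroc,
                      "n_comp": pls.n_comp},
            "markers": {
                "UC": sorted(markers.loc[verdicts == "UC-marker", "feature_id"]),
                "CTRL": sorted(markers.loc[verdicts == "CTRL-marker", "feature_id"]),
            },
        }

    # ---- multiblock integration -----------------------------------------
    frob = {name: frobenius_normalize(rel[name] if name in TAXA_OMICS else study.blocks[name])
            for name in study.blocks}
    mats = {name: t.values.T for name, t in frob.items()}
    cd = multiblock.comdim(mats, K=config.n_comp)
    mb = multiblock.mbpca(mats, n_comp=config.n_comp)
    mbp, mb_cv, mb_auroc = multiblock.mbplsda(
        mats, groups, config.n_comp, k_folds=config.k_folds, seed=seeds["cv"]
    )
    report["multiblock"] = {
        "block_names": list(mats),
        "comdim_saliences": cd.saliences.round(10).tolist(),
        "comdim_residual_fraction": cd.residual_fraction.round(10).tolist(),
        "mbpca_block_weights": mb.block_weights.round(10).tolist(),
        "mbpca_explained_block_variance": mb.explained_block_variance.round(10).tolist(),
        "mbplsda": {
            "block_importance": mbp.block_importance.round(10).tolist(),
            "rmse": mb_cv.rmse, "r2": mb_cv.r2, "q2": mb_cv.q2, "auroc": mb_auroc,
        },
    }

    # ---- interkingdom networks ------------------------------------------
    report["networks"] = {}
    nets = {}
    if all(name in study.blocks for name in TAXA_OMICS):
        for g in ("UC", "CTRL"):
            cols = [s for s, lab in zip(study.sample_ids, groups) if lab == g]
            edges = network.spearman_edges(
                rel["bacteria"].subset_samples(cols),
                rel["fungi"].subset_samples(cols),
                alpha=config.network_alpha,
            )
            net = network.build_network(edges)
            nets[g] = (edges, net)
            report["networks"][g] = net.metrics

    if truth is not None:
        report["truth_summary"] = {
            omic: {"n_planted": len(m)} for omic, m in truth.markers.items()
        }

    if config.out_dir:
        _write_artifacts(Path(config.out_dir), report, marker_tables, nets)
    return report


def _write_artifacts(out: Path, report: dict, marker_tables, nets) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    for name, markers in marker_tables.items():
        markers.to_csv(out / f"markers_{name}.tsv", sep="\t", index=False)
    for g, (edges, net) in nets.items():
        network.write_edges(edges, out / f"network_edges_{g}.tsv")
        if net.n_nodes:
            network.write_graphml(net, out / f"network_{g}.graphml")


def report_json(report: dict) -> str:
    """Stable serialization: sorted keys, no timestamps."""
    return json.dumps(report, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj)}")
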