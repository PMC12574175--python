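"""End-to-end orchestration: expression I/O → DE → integration →
network → biomarker, with re-entrant on-disk stage outputs and a run
manifest.

The two contrasts deliberately use different test engines: the
small-n cell-culture contrast (3D vs 2D) uses the moderated t, while the
tumor-vs-cell-line contrast uses per-feature Welch tests (unequal
variances, sentinel missingness).  Multiple-testing correction is
applied per contrast, never pooled across contrasts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .biomarker import evaluate_biomarkers
from .diffexp import (
    DESets,
    Thresholds,
    classify_de,
    fit_moderated_t,
    quantile_normalize,
    welch_de_table,
    write_de_table,
)
from .expression import (
    SENTINEL_NOT_DETECTED,
    ExpressionMatrix,
    SampleDesign,
    detection_filter,
    match_features_by_name,
    read_expression_table,
)
from .integrate import (
    inverse_pair_filter,
    load_interaction_table,
    ora_enrichment,
    pairs_to_frame,
    read_gmt,
    shared_direction_mirnas,
)
from .network import assemble_cerna, export_network, hub_ranking, network_counts
from .simulate import Scenario, ScenarioConfig, generate_scenario

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    scenario: ScenarioConfig | None = None
    input_paths: dict[str, str] = field(default_factory=dict)
    mirna_thresholds: Thresholds = field(default_factory=Thresholds)
    mrna_thresholds: Thresholds = field(default_factory=Thresholds)
    tumor_thresholds: Thresholds = field(default_factory=Thresholds)
    detection_min_level: float = 1.0
    sentinel: float = SENTINEL_NOT_DETECTED
    apply_quantile_normalization: bool = False
    pair_mode: str = "mir_down_mrna_up"

    def __post_init__(self) -> None:
        if (self.scenario is None) == (not self.input_paths):
            # exactly one of {real inputs, synthetic scenario} must be active
            if self.scenario is None:
                raise PipelineError("config needs either a scenario or input paths")
            raise PipelineError("config must use either a scenario or input paths, not both")

    def validate_inputs(self) -> None:
        for key, p in self.input_paths.items():
            if not Path(p).exists():
                raise PipelineError(f"input file for {key!r} does not exist: {p}")


@dataclass
class ResultBundle:
    config: PipelineConfig
    det_mirna_3d: pd.DataFrame
    sets_mirna_3d: DESets
    det_mrna_3d: pd.DataFrame
    sets_mrna_3d: DESets
    det_mirna_tumor: pd.DataFrame
    sets_mirna_tumor: DESets
    pairs: list
    concordance: pd.DataFrame
    network: object
    hubs: pd.DataFrame
    roc: pd.DataFrame
    enrichment: pd.DataFrame | None
    manifest: dict
    paths: dict[str, Path]


REQUIRED_INPUT_KEYS = (
    "mirna_3d", "design_3d", "mrna_3d", "mrna_design",
    "mirna_tumor", "tumor_design", "target_interactions", "sponge_interactions",
)


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    labels = dict(zip(df["sample"], df["group"]))
    groups: list[str] = []
    for g in labels.values():
        if g not in groups:
            groups.append(g)
    if len(groups) != 2:
        raise PipelineError(f"{path}: expected exactly two groups, got {groups}")
    return SampleDesign(labels=labels, groups=(groups[0], groups[1]))


def _load_inputs(cfg: PipelineConfig):
    if cfg.scenario is not None:
        sc = generate_scenario(cfg.scenario)
        return sc
    cfg.validate_inputs()
    missing = [k for k in REQUIRED_INPUT_KEYS if k not in cfg.input_paths]
    if missing:
        raise PipelineError(f"missing input paths: {missing}")
    p = cfg.input_paths
    mirna_3d = read_expression_table(p["mirna_3d"], sentinel=cfg.sentinel)
    mrna_3d = read_expression_table(p["mrna_3d"], sentinel=cfg.sentinel)
    mirna_tumor = read_expression_table(p["mirna_tumor"], sentinel=cfg.sentinel)
    gene_sets = read_gmt(p["gene_sets"]) if "gene_sets" in p else {}
    return Scenario(
        config=None,  # type: ignore[arg-type]
        mirna_3d=mirna_3d,
        design_3d=read_design(p["design_3d"]),
        mrna_3d=mrna_3d,
        mrna_design=read_design(p["mrna_design"]),
        mirna_tumor=mirna_tumor,
        tumor_design=read_design(p["tumor_design"]),
        target_interactions=load_interaction_table(p["target_interactions"]),
        sponge_interactions=load_interaction_table(p["sponge_interactions"]),
        gene_sets=gene_sets,
        truth=None,  # type: ignore[arg-type]
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    d = asdict(cfg)
    d.pop("outdir")  # hash the scientific config, not the output location
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Run every stage in order and write the report bundle to outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "load"

    def write_tsv(name: str, df: pd.DataFrame, **kw) -> None:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", float_format="%.10g", **kw)

    try:
        sc = _load_inputs(cfg)

        stage = "detection_filter"
        mirna_3d = detection_filter(sc.mirna_3d, cfg.detection_min_level)
        mrna_3d = detection_filter(sc.mrna_3d, cfg.detection_min_level)
        mirna_tumor = detection_filter(sc.mirna_tumor, cfg.detection_min_level)
        logger.info(
            "detection: miRNA-3D %d, mRNA-3D %d, miRNA-tumor %d features retained",
            mirna_3d.shape[0], mrna_3d.shape[0], mirna_tumor.shape[0],
        )

        if cfg.apply_quantile_normalization:
            stage = "quantile_normalize"
            mirna_3d = quantile_normalize(mirna_3d)
            mrna_3d = quantile_normalize(mrna_3d)

        stage = "diffexp_mirna_3d"
        det_mirna_3d, _ = fit_moderated_t(mirna_3d, sc.design_3d)
        sets_mirna_3d = classify_de(det_mirna_3d, cfg.mirna_thresholds)
        paths["de_mirna_3d"] = outdir / "de_mirna_3d.tsv"
        write_de_table(det_mirna_3d, paths["de_mirna_3d"])

        stage = "diffexp_mrna_3d"
        det_mrna_3d, _ = fit_moderated_t(mrna_3d, sc.mrna_design)
        sets_mrna_3d = classify_de(det_mrna_3d, cfg.mrna_thresholds)
        paths["de_mrna_3d"] = outdir / "de_mrna_3d.tsv"
        write_de_table(det_mrna_3d, paths["de_mrna_3d"])

        stage = "diffexp_mirna_tumor"
        det_tumor = welch_de_table(mirna_tumor, sc.tumor_design)
        sets_tumor = classify_de(det_tumor, cfg.tumor_thresholds)
        paths["de_mirna_tumor"] = outdir / "de_mirna_tumor.tsv"
        write_de_table(det_tumor, paths["de_mirna_tumor"])

        stage = "integration"
        pairs = inverse_pair_filter(
            sets_mirna_3d, sets_mrna_3d, sc.target_interactions, cfg.pair_mode
        )
        logger.info(
            "inverse pairs: %d (distinct miRNAs %d, distinct mRNAs %d)",
            len(pairs), len({p.mirna for p in pairs}), len({p.mrna for p in pairs}),
        )
        write_tsv("pairs", pairs_to_frame(pairs), index=False)

        mapping = match_features_by_name(det_mirna_3d.index, det_tumor.index)
        concordance = shared_direction_mirnas(
            det_mirna_3d, sets_mirna_3d, det_tumor, sets_tumor, mapping
        )
        write_tsv("concordance", concordance, index=False)

        stage = "cerna_network"
        down_pairs = [p for p in pairs if p.mirna_direction == "down"]
        net = assemble_cerna(concordance, down_pairs, sc.sponge_interactions)
        counts = network_counts(net)
        logger.info("ceRNA network: %s", counts)
        hubs = hub_ranking(net)
        write_tsv("hubs", hubs, index=False)
        for fmt, name in [("graphml", "network.graphml"), ("edge_tsv", "network_edges.tsv"),
                          ("json", "network.json")]:
            paths[name] = outdir / name
            export_network(net, paths[name], fmt)

        stage = "biomarker"
        hub_features = list(hubs["mirna"])
        if hub_features:
            roc = evaluate_biomarkers(mirna_tumor, sc.tumor_design, hub_features)
        else:
            roc = pd.DataFrame(
                columns=["auc", "reported_auc", "orientation", "n_pos", "n_neg"]
            ).rename_axis("feature")
        write_tsv("biomarker_auc", roc)

        stage = "enrichment"
        enrichment = None
        if sc.gene_sets:
            universe = set(det_mrna_3d.index)
            query = set(sets_mrna_3d.up) & universe
            enrichment = ora_enrichment(query, sc.gene_sets, universe)
            write_tsv("enrichment", enrichment, index=False)

        stage = "manifest"
        manifest = {
            "cernet_version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
            "counts": {
                "mirna_3d_up": len(sets_mirna_3d.up),
                "mirna_3d_down": len(sets_mirna_3d.down),
                "mrna_3d_up": len(sets_mrna_3d.up),
                "mrna_3d_down": len(sets_mrna_3d.down),
                "mirna_tumor_up": len(sets_tumor.up),
                "mirna_tumor_down": len(sets_tumor.down),
                "inverse_pairs": len(pairs),
                "concordant": int(len(concordance)),
                **counts,
            },
            "files": {name: _sha256(p) for name, p in sorted(paths.items())},
        }
        paths["manifest"] = outdir / "manifest.json"
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for p in paths.values():
            if p.exists():
                p.rename(failed / p.name)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return ResultBundle(
        config=cfg,
        det_mirna_3d=det_mirna_3d,
        sets_mirna_3d=sets_mirna_3d,
        det_mrna_3d=det_mrna_3d,
        sets_mrna_3d=sets_mrna_3d,
        det_mirna_tumor=det_tumor,
        sets_mirna_tumor=sets_tumor,
        pairs=pairs,
        concordance=concordance,
        network=net,
        hubs=hubs,
        roc=roc,
        enrichment=enrichment,
        manifest=manifest,
        paths=paths,
    )
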