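"""Ground-truthed synthetic data with the statistical structure the
pipeline assumes.

The generator emulates the study layout end to end, without downloads:

* an in-house miRNA cohort contrasting 3D spheroid vs 2D monolayer
  culture (biological triplicates, log2 intensities, Gaussian noise);
* a matching mRNA cohort for the same 3D-vs-2D contrast;
* an independent tumor-vs-cell-line miRNA cohort on its own platform,
  with "not detected" sentinel dropouts;
* interaction tables (miRNA→mRNA targets, lncRNA→miRNA sponges) holding
  the planted true pairs plus decoys among non-regulated features;
* a small synthetic gene-set collection for enrichment.

Planted structure: ``n_hubs`` miRNAs are down-regulated in both
contrasts, each with up-regulated mRNA targets and sponging lncRNAs; a
few concordant down-miRNAs deliberately lack sponges (they must drop out
of the assembled network); concordant up-miRNAs, single-context DE
features, and pure nulls round out the matrices.  Effect sizes default
to the log2FC ranges of the bundled published concordance panel (see
:mod:`cernet.reference`).  All randomness flows from one seed through
named substreams, so identical seeds give bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import SENTINEL_NOT_DETECTED, ExpressionMatrix, SampleDesign
from .integrate import make_interaction_table, write_interaction_table


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    # cohort geometry
    n_mirna: int = 300
    n_mrna: int = 500
    n_lncrna: int = 30
    n_per_group: int = 3  # biological triplicates per condition
    # noise / scale
    noise_sd: float = 0.3  # log2-scale Gaussian sigma
    baseline_range: tuple[float, float] = (6.0, 12.0)
    sentinel_rate: float = 0.02  # fraction of eligible tumor-cohort cells
    sentinel: float = SENTINEL_NOT_DETECTED
    # network plan
    n_hubs: int = 4
    targets_per_hub: tuple[int, ...] | int = 10
    sponges_per_hub: int = 3
    n_spongeless_down: int = 2  # concordant-down miRNAs without sponges
    targets_per_spongeless: int = 3
    n_up_concordant: int = 8
    # context-specific DE (concordance decoys)
    n_up_3d_only: int = 5
    n_down_3d_only: int = 5
    n_up_tumor_only: int = 5
    n_down_tumor_only: int = 5
    # name-matching decoys (features present in only one cohort)
    n_tumor_only_features: int = 10
    n_3d_only_features: int = 10
    # effect-size ranges (log2FC)
    hub_lfc_3d: tuple[float, float] = (-3.49, -1.11)
    hub_lfc_tumor: tuple[float, float] = (-4.58, -1.97)
    up_lfc_3d: tuple[float, float] = (1.10, 2.78)
    up_lfc_tumor: tuple[float, float] = (1.41, 4.82)
    context_only_lfc: float = 2.0
    mrna_up_lfc: tuple[float, float] = (1.5, 3.0)
    n_down_mrna: int = 20
    mrna_down_lfc: tuple[float, float] = (-3.0, -1.5)
    # interaction decoys
    decoy_interaction_rate: float = 0.2  # decoys ≈ rate · n_mirna
    n_decoy_sponges: int = 10
    # extra explicit plants on the 3D miRNA contrast: (feature_id, log2fc)
    planted_de: tuple[tuple[str, float], ...] = ()
    n_gene_sets: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_mrna", "n_lncrna", "n_per_group"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        for name in ("sentinel_rate", "decoy_interaction_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ScenarioError(f"{name} must lie in [0, 1]")
        if sum(self.hub_targets()) + self.n_spongeless_down * self.targets_per_spongeless > self.n_mrna:
            raise ScenarioError("planted target mRNAs exceed n_mrna")
        if self.n_hubs * self.sponges_per_hub > self.n_lncrna:
            raise ScenarioError("planted sponge lncRNAs exceed n_lncrna")

    def hub_targets(self) -> tuple[int, ...]:
        if isinstance(self.targets_per_hub, int):
            return (self.targets_per_hub,) * self.n_hubs
        if len(self.targets_per_hub) != self.n_hubs:
            raise ScenarioError("targets_per_hub length must equal n_hubs")
        return tuple(self.targets_per_hub)


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth the generated bundle encodes (σ=0 exact)."""

    mirna_up_3d: frozenset[str]
    mirna_down_3d: frozenset[str]
    mirna_up_tumor: frozenset[str]
    mirna_down_tumor: frozenset[str]
    mrna_up_3d: frozenset[str]
    mrna_down_3d: frozenset[str]
    concordant_up: frozenset[str]
    concordant_down: frozenset[str]
    hub_mirnas: frozenset[str]
    spongeless_down: frozenset[str]
    true_pairs: tuple[tuple[str, str], ...]  # mir-down/mRNA-up pairs in the table
    sponge_edges: tuple[tuple[str, str], ...]
    expected_counts: dict[str, int]
    n_sentinel_cells: int
    n_sentinel_eligible_cells: int


@dataclass
class Scenario:
    config: ScenarioConfig
    mirna_3d: ExpressionMatrix
    design_3d: SampleDesign
    mrna_3d: ExpressionMatrix
    mrna_design: SampleDesign
    mirna_tumor: ExpressionMatrix
    tumor_design: SampleDesign
    target_interactions: pd.DataFrame
    sponge_interactions: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: ScenarioTruth


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float], n: int) -> np.ndarray:
    lo, hi = min(lo_hi), max(lo_hi)
    return rng.uniform(lo, hi, size=n)


def _matrix(
    rng: np.random.Generator,
    features: list[str],
    baselines: np.ndarray,
    effects: dict[str, float],
    ref_label: str,
    alt_label: str,
    sample_prefixes: tuple[str, str],
    n_per_group: int,
    noise_sd: float,
    platform_tag: str,
) -> tuple[ExpressionMatrix, SampleDesign]:
    n = len(features)
    ref_cols = [f"{sample_prefixes[0]}_{i + 1}" for i in range(n_per_group)]
    alt_cols = [f"{sample_prefixes[1]}_{i + 1}" for i in range(n_per_group)]
    eff = np.array([effects.get(f, 0.0) for f in features])
    ref = baselines[:, None] + rng.normal(0.0, noise_sd, size=(n, n_per_group)) * (noise_sd > 0)
    alt = (baselines + eff)[:, None] + rng.normal(0.0, noise_sd, size=(n, n_per_group)) * (
        noise_sd > 0
    )
    values = pd.DataFrame(
        np.hstack([ref, alt]), index=features, columns=ref_cols + alt_cols
    )
    mask = pd.DataFrame(False, index=features, columns=values.columns)
    m = ExpressionMatrix(values, mask, scale="log2", platform_tag=platform_tag)
    design = SampleDesign(
        labels={**{c: ref_label for c in ref_cols}, **{c: alt_label for c in alt_cols}},
        groups=(ref_label, alt_label),
    )
    return m, design


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the full ground-truthed bundle for one seed."""
    root = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ["roles", "effects", "noise_3d", "noise_mrna", "noise_tumor", "sentinel", "interactions"],
            root.spawn(7),
        )
    }

    # ---- feature names and role assignment -------------------------------
    mirnas = [f"hsa-miR-sim-{i:04d}" for i in range(cfg.n_mirna)]
    mrnas = [f"MSIM{i:04d}" for i in range(cfg.n_mrna)]
    lncrnas = [f"LNC-SIM-{i:03d}" for i in range(cfg.n_lncrna)]

    order = list(streams["roles"].permutation(cfg.n_mirna))
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        if cursor + k > len(order):
            raise ScenarioError("not enough miRNAs for the planted roles")
        out = [mirnas[i] for i in order[cursor : cursor + k]]
        cursor += k
        return out

    hubs = take(cfg.n_hubs)
    spongeless = take(cfg.n_spongeless_down)
    up_conc = take(cfg.n_up_concordant)
    up_3d_only = take(cfg.n_up_3d_only)
    down_3d_only = take(cfg.n_down_3d_only)
    up_tumor_only = take(cfg.n_up_tumor_only)
    down_tumor_only = take(cfg.n_down_tumor_only)
    only_3d_features = take(cfg.n_3d_only_features)  # null features absent from tumor cohort
    planted_mirnas = set(hubs + spongeless + up_conc + up_3d_only + down_3d_only
                         + up_tumor_only + down_tumor_only)
    null_mirnas = [m for m in mirnas if m not in planted_mirnas and m not in only_3d_features]

    mrna_order = list(streams["roles"].permutation(cfg.n_mrna))
    mcursor = 0

    def take_mrna(k: int) -> list[str]:
        nonlocal mcursor
        out = [mrnas[i] for i in mrna_order[mcursor : mcursor + k]]
        mcursor += k
        return out

    hub_target_map = {h: take_mrna(k) for h, k in zip(hubs, cfg.hub_targets())}
    spongeless_target_map = {s: take_mrna(cfg.targets_per_spongeless) for s in spongeless}
    down_mrnas = take_mrna(cfg.n_down_mrna)
    up_mrnas = sorted({t for ts in hub_target_map.values() for t in ts}
                      | {t for ts in spongeless_target_map.values() for t in ts})
    null_mrnas = [g for g in mrnas if g not in set(up_mrnas) | set(down_mrnas)]

    lnc_order = list(streams["roles"].permutation(cfg.n_lncrna))
    sponge_map: dict[str, list[str]] = {}
    lcursor = 0
    for h in hubs:
        sponge_map[h] = [lncrnas[i] for i in lnc_order[lcursor : lcursor + cfg.sponges_per_hub]]
        lcursor += cfg.sponges_per_hub
    sponge_lncs = sorted({l for ls in sponge_map.values() for l in ls})

    # ---- effect sizes ----------------------------------------------------
    er = streams["effects"]
    eff_3d: dict[str, float] = {}
    eff_tumor: dict[str, float] = {}
    for m, v3, vt in zip(hubs + spongeless,
                         _uniform(er, cfg.hub_lfc_3d, len(hubs) + len(spongeless)),
                         _uniform(er, cfg.hub_lfc_tumor, len(hubs) + len(spongeless))):
        eff_3d[m], eff_tumor[m] = float(v3), float(vt)
    for m, v3, vt in zip(up_conc,
                         _uniform(er, cfg.up_lfc_3d, len(up_conc)),
                         _uniform(er, cfg.up_lfc_tumor, len(up_conc))):
        eff_3d[m], eff_tumor[m] = float(v3), float(vt)
    for m in up_3d_only:
        eff_3d[m] = cfg.context_only_lfc
    for m in down_3d_only:
        eff_3d[m] = -cfg.context_only_lfc
    for m in up_tumor_only:
        eff_tumor[m] = cfg.context_only_lfc
    for m in down_tumor_only:
        eff_tumor[m] = -cfg.context_only_lfc
    for fid, lfc in cfg.planted_de:
        if fid not in set(mirnas):
            raise ScenarioError(f"planted_de feature {fid!r} not among generated miRNAs")
        if fid in eff_3d:
            raise ScenarioError(f"planted_de feature {fid!r} already has a planted role")
        eff_3d[fid] = float(lfc)

    eff_mrna = {g: float(v) for g, v in zip(up_mrnas, _uniform(er, cfg.mrna_up_lfc, len(up_mrnas)))}
    eff_mrna.update(
        {g: float(v) for g, v in zip(down_mrnas, _uniform(er, cfg.mrna_down_lfc, len(down_mrnas)))}
    )

    # ---- matrices --------------------------------------------------------
    base_mirna = _uniform(er, cfg.baseline_range, cfg.n_mirna)
    base_mrna = _uniform(er, cfg.baseline_range, cfg.n_mrna)

    mirna_3d, design_3d = _matrix(
        streams["noise_3d"], mirnas, base_mirna, eff_3d, "2D", "3D",
        ("BT474_2D", "BT474_3D"), cfg.n_per_group, cfg.noise_sd, "sim-miRNA-array",
    )
    mrna_3d, mrna_design = _matrix(
        streams["noise_mrna"], mrnas, base_mrna, eff_mrna, "2D", "3D",
        ("mRNA_2D", "mRNA_3D"), cfg.n_per_group, cfg.noise_sd, "sim-mRNA-array",
    )

    tumor_features = [m for m in mirnas if m not in set(only_3d_features)]
    tumor_features += [f"hsa-miR-tum-{i:03d}" for i in range(cfg.n_tumor_only_features)]
    base_tumor = _uniform(er, cfg.baseline_range, len(tumor_features))
    mirna_tumor, tumor_design = _matrix(
        streams["noise_tumor"], tumor_features, base_tumor, eff_tumor, "2D", "tumor",
        ("BT474", "Tumor"), cfg.n_per_group, cfg.noise_sd, "sim-tumor-array",
    )

    # sentinel dropouts: only null (non-planted) tumor-cohort features are
    # eligible, so the detection filter's sentinel rule never removes a
    # planted signal and the σ=0 ground-truth contract holds.
    planted_tumor = {m for m in tumor_features if m in eff_tumor}
    eligible = [f for f in tumor_features if f not in planted_tumor]
    n_cols = mirna_tumor.shape[1]
    n_eligible_cells = len(eligible) * n_cols
    n_sent = 0
    if cfg.sentinel_rate > 0 and eligible:
        hits = streams["sentinel"].random((len(eligible), n_cols)) < cfg.sentinel_rate
        n_sent = int(hits.sum())
        vals = mirna_tumor.values
        sub = vals.loc[eligible].to_numpy()
        sub[hits] = cfg.sentinel
        vals.loc[eligible] = sub
    mirna_tumor = ExpressionMatrix(
        mirna_tumor.values, mirna_tumor.mask, "log2", "sim-tumor-array", cfg.sentinel
    ).apply_sentinel(cfg.sentinel)

    # ---- interaction tables ---------------------------------------------
    ir = streams["interactions"]
    sources = ("mirnet", "encori")
    evidences = ("predicted", "curated", "clip")

    def ev() -> tuple[str, str]:
        return str(ir.choice(evidences)), str(ir.choice(sources))

    target_rows = []
    true_pairs = []
    for h in hubs:
        for t in hub_target_map[h]:
            e, s = ev()
            target_rows.append((h, "miRNA", t, "mRNA", e, s))
            true_pairs.append((h, t))
    for sl in spongeless:
        for t in spongeless_target_map[sl]:
            e, s = ev()
            target_rows.append((sl, "miRNA", t, "mRNA", e, s))
            true_pairs.append((sl, t))
    # decoys: null-miRNA → (null|down) mRNA and planted-down-miRNA → null mRNA;
    # none of these can pass the inverse filter in either orientation.
    n_decoys = int(round(cfg.decoy_interaction_rate * cfg.n_mirna))
    for _ in range(n_decoys):
        if null_mirnas and ir.random() < 0.7:
            mir = str(ir.choice(null_mirnas))
            tgt = str(ir.choice(null_mrnas + down_mrnas))
        else:
            mir = str(ir.choice(hubs + spongeless))
            tgt = str(ir.choice(null_mrnas))
        e, s = ev()
        target_rows.append((mir, "miRNA", tgt, "mRNA", e, s))

    sponge_rows = []
    sponge_edges = []
    for h in hubs:
        for l in sponge_map[h]:
            e, s = ev()
            sponge_rows.append((l, "lncRNA", h, "miRNA", e, s))
            sponge_edges.append((l, h))
    decoy_lncs = [l for l in lncrnas if l not in set(sponge_lncs)]
    for _ in range(cfg.n_decoy_sponges):
        if not decoy_lncs or not null_mirnas:
            break
        e, s = ev()
        sponge_rows.append(
            (str(ir.choice(decoy_lncs)), "lncRNA", str(ir.choice(null_mirnas)), "miRNA", e, s)
        )

    target_interactions = make_interaction_table(target_rows)
    sponge_interactions = make_interaction_table(sponge_rows)

    # ---- synthetic gene sets --------------------------------------------
    gene_sets: dict[str, set[str]] = {"PLANTED_TARGET_PROGRAM": set(up_mrnas)}
    for i in range(cfg.n_gene_sets):
        size = int(ir.integers(10, 40))
        gene_sets[f"RANDOM_SET_{i:02d}"] = set(ir.choice(mrnas, size=size, replace=False))

    # ---- truth -----------------------------------------------------------
    extra_up = frozenset(f for f, l in cfg.planted_de if l > 0)
    extra_down = frozenset(f for f, l in cfg.planted_de if l < 0)
    truth = ScenarioTruth(
        mirna_up_3d=frozenset(up_conc + up_3d_only) | extra_up,
        mirna_down_3d=frozenset(hubs + spongeless + down_3d_only) | extra_down,
        mirna_up_tumor=frozenset(up_conc + up_tumor_only),
        mirna_down_tumor=frozenset(hubs + spongeless + down_tumor_only),
        mrna_up_3d=frozenset(up_mrnas),
        mrna_down_3d=frozenset(down_mrnas),
        concordant_up=frozenset(up_conc),
        concordant_down=frozenset(hubs + spongeless),
        hub_mirnas=frozenset(hubs),
        spongeless_down=frozenset(spongeless),
        true_pairs=tuple(sorted(true_pairs)),
        sponge_edges=tuple(sorted(sponge_edges)),
        expected_counts={
            "n_lncRNA": len(sponge_lncs),
            "n_miRNA": len(hubs),
            "n_mRNA": len({t for h in hubs for t in hub_target_map[h]}),
        },
        n_sentinel_cells=n_sent,
        n_sentinel_eligible_cells=n_eligible_cells,
    )

    return Scenario(
        config=cfg,
        mirna_3d=mirna_3d,
        design_3d=design_3d,
        mrna_3d=mrna_3d,
        mrna_design=mrna_design,
        mirna_tumor=mirna_tumor,
        tumor_design=tumor_design,
        target_interactions=target_interactions,
        sponge_interactions=sponge_interactions,
        gene_sets=gene_sets,
        truth=truth,
    )


def default_paper_scenario(seed: int = 0, noise_sd: float = 0.3) -> ScenarioConfig:
    """The reference scenario reproducing the published network shape.

    Four hub miRNAs down-regulated in both contexts whose target union is
    58 mRNAs and sponge union is 12 lncRNAs; six concordant down-miRNAs
    in total, of which two lack sponges and must drop out of the network;
    eight concordant up-miRNAs; triplicate samples per condition.  Hub
    effect sizes are drawn from the published panel's log2FC ranges
    ([−3.49, −1.11] for the 3D contrast, [−4.58, −1.97] in tumors).
    """
    return ScenarioConfig(
        n_mirna=300,
        n_mrna=500,
        n_lncrna=30,
        n_per_group=3,
        noise_sd=noise_sd,
        n_hubs=4,
        targets_per_hub=(15, 15, 14, 14),  # disjoint → union 58
        sponges_per_hub=3,  # disjoint → union 12
        n_spongeless_down=2,
        n_up_concordant=8,
        seed=seed,
    )


def two_group_config(
    n_features: int,
    n_planted: int,
    effect: float,
    noise_sd: float,
    n_per_group: int = 3,
    seed: int = 0,
) -> ScenarioConfig:
    """A minimal one-contrast scenario: n_planted features at ``effect``
    log2FC against pure nulls — used for power / FDR calibration checks."""
    planted = tuple((f"hsa-miR-sim-{i:04d}", effect) for i in range(n_planted))
    return ScenarioConfig(
        n_mirna=n_features,
        n_mrna=10,
        n_lncrna=2,
        n_per_group=n_per_group,
        noise_sd=noise_sd,
        n_hubs=0,
        targets_per_hub=(),
        sponges_per_hub=0,
        n_spongeless_down=0,
        targets_per_spongeless=0,
        n_up_concordant=0,
        n_up_3d_only=0,
        n_down_3d_only=0,
        n_up_tumor_only=0,
        n_down_tumor_only=0,
        n_tumor_only_features=0,
        n_3d_only_features=0,
        n_down_mrna=0,
        decoy_interaction_rate=0.0,
        n_decoy_sponges=0,
        sentinel_rate=0.0,
        planted_de=planted,
        n_gene_sets=0,
        seed=seed,
    )


def write_scenario(sc: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the same TSV dialects the readers consume."""
    from .expression import write_expression_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, m in [
        ("mirna_3d", sc.mirna_3d),
        ("mrna_3d", sc.mrna_3d),
        ("mirna_tumor", sc.mirna_tumor),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        write_expression_table(m, paths[name])
    for name, d in [
        ("design_3d", sc.design_3d),
        ("mrna_design", sc.mrna_design),
        ("tumor_design", sc.tumor_design),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        with open(paths[name], "w", encoding="utf-8") as fh:
            fh.write("sample\tgroup\n")
            for s, g in d.labels.items():
                fh.write(f"{s}\t{g}\n")
    paths["target_interactions"] = outdir / "target_interactions.tsv"
    write_interaction_table(sc.target_interactions, paths["target_interactions"])
    paths["sponge_interactions"] = outdir / "sponge_interactions.tsv"
    write_interaction_table(sc.sponge_interactions, paths["sponge_interactions"])
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        for sid in sorted(sc.gene_sets):
            members = "\t".join(sorted(sc.gene_sets[sid]))
            fh.write(f"{sid}\tsynthetic\t{members}\n")
    paths["truth"] = outdir / "truth.json"
    import json

    truth = sc.truth
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "mirna_up_3d": sorted(truth.mirna_up_3d),
                "mirna_down_3d": sorted(truth.mirna_down_3d),
                "mirna_up_tumor": sorted(truth.mirna_up_tumor),
                "mirna_down_tumor": sorted(truth.mirna_down_tumor),
                "mrna_up_3d": sorted(truth.mrna_up_3d),
                "mrna_down_3d": sorted(truth.mrna_down_3d),
                "concordant_up": sorted(truth.concordant_up),
                "concordant_down": sorted(truth.concordant_down),
                "hub_mirnas": sorted(truth.hub_mirnas),
                "spongeless_down": sorted(truth.spongeless_down),
                "true_pairs": [list(p) for p in truth.true_pairs],
                "sponge_edges": [list(p) for p in truth.sponge_edges],
                "expected_counts": truth.expected_counts,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
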