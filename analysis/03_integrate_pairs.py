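#!/usr/bin/env python
"""Directional integration and cross-cohort concordance.

Retains miRNA–mRNA pairs that are inversely regulated in the 3D-vs-2D
contrast (miRNA down, target mRNA up) and supported by interaction
evidence; intersects the 3D miRNA calls with the tumor cohort by name
to find direction-concordant miRNAs; runs hypergeometric ORA of the
up-regulated mRNAs against the bundled gene sets.  Writes
``results/integration/``.
"""

from pathlib import Path

from cernet.diffexp import classify_de, read_de_table
from cernet.expression import match_features_by_name
from cernet.integrate import (
    inverse_pair_filter,
    load_interaction_table,
    ora_enrichment,
    pairs_to_frame,
    read_gmt,
    shared_direction_mirnas,
)

REPO = Path(__file__).resolve().parents[1]
BUNDLE = REPO / "results" / "scenario"
DE = REPO / "results" / "de"
OUT = REPO / "results" / "integration"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    det_mirna = read_de_table(DE / "de_mirna_3d.tsv")
    det_mrna = read_de_table(DE / "de_mrna_3d.tsv")
    det_tumor = read_de_table(DE / "de_mirna_tumor.tsv")
    sets_mirna, sets_mrna, sets_tumor = map(classify_de, (det_mirna, det_mrna, det_tumor))

    interactions = load_interaction_table(BUNDLE / "target_interactions.tsv")
    pairs = inverse_pair_filter(sets_mirna, sets_mrna, interactions)
    pairs_to_frame(pairs).to_csv(OUT / "pairs.tsv", sep="\t", index=False)
    print(
        f"inverse pairs (miRNA down / mRNA up, evidence-supported): {len(pairs)} "
        f"over {len({p.mirna for p in pairs})} miRNAs and "
        f"{len({p.mrna for p in pairs})} mRNAs"
    )

    mapping = match_features_by_name(det_mirna.index, det_tumor.index)
    conc = shared_direction_mirnas(det_mirna, sets_mirna, det_tumor, sets_tumor, mapping)
    conc.to_csv(OUT / "concordance.tsv", sep="\t", index=False, float_format="%.10g")
    n_up = int((conc["direction"] == "up").sum())
    n_down = int((conc["direction"] == "down").sum())
    print(
        f"concordant miRNAs (same direction in 3D-vs-2D and tumors-vs-2D): "
        f"{len(conc)} ({n_up} up, {n_down} down)"
    )

    gene_sets = read_gmt(BUNDLE / "gene_sets.gmt")
    universe = set(det_mrna.index)
    enr = ora_enrichment(set(sets_mrna.up) & universe, gene_sets, universe)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    top = enr.sort_values("p").iloc[0]
    print(
        f"ORA over {len(gene_sets)} gene sets: top set {top['set_id']} "
        f"(overlap {top['overlap']}/{top['set_size']}, q={top['q']:.2e})"
    )


if __name__ == "__main__":
    main()
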