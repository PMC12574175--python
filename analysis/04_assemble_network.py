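#!/usr/bin/env python
"""Assemble the tripartite ceRNA network and rank hub miRNAs.

Concordant down-regulated miRNAs that have at least one evidence-backed
up-regulated target *and* at least one sponging lncRNA become the
network's miRNA layer; their targets and sponges form the mRNA and
lncRNA layers.  Exports GraphML / edge TSV / JSON plus the hub table
under ``results/network/``.
"""

from pathlib import Path

import pandas as pd

from cernet.integrate import DirectionalPair, load_interaction_table
from cernet.network import assemble_cerna, export_network, hub_ranking, network_counts

REPO = Path(__file__).resolve().parents[1]
BUNDLE = REPO / "results" / "scenario"
INT = REPO / "results" / "integration"
OUT = REPO / "results" / "network"


def load_pairs(path: Path) -> list[DirectionalPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        DirectionalPair(
            r.mirna, r.mrna, r.mirna_direction, r.mrna_direction,
            tuple(str(r.evidence).split(";")),
        )
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    conc = pd.read_csv(INT / "concordance.tsv", sep="\t")
    pairs = [p for p in load_pairs(INT / "pairs.tsv") if p.mirna_direction == "down"]
    sponges = load_interaction_table(BUNDLE / "sponge_interactions.tsv")

    net = assemble_cerna(conc, pairs, sponges)
    counts = network_counts(net)
    down = set(conc.loc[conc["direction"] == "down", "mirna"])
    in_net = {n for n, d in net.nodes(data=True) if d["cls"] == "miRNA"}
    print(
        f"ceRNA network: {counts['n_lncRNA']} lncRNAs -> {counts['n_miRNA']} miRNAs "
        f"-> {counts['n_mRNA']} mRNAs ({net.number_of_edges()} edges); "
        f"{len(down - in_net)} concordant-down miRNAs excluded for lacking sponges"
    )

    hubs = hub_ranking(net)
    hubs.to_csv(OUT / "hubs.tsv", sep="\t", index=False)
    print("hub ranking (degree):")
    print(hubs.to_string(index=False))

    for fmt, name in [("graphml", "network.graphml"), ("edge_tsv", "network_edges.tsv"),
                      ("json", "network.json")]:
        export_network(net, OUT / name, fmt)
    print(f"exports written to {OUT}")


if __name__ == "__main__":
    main()
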