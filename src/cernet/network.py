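"""Tripartite ceRNA network assembly, hub ranking, and export.

Under the competing-endogenous-RNA hypothesis, up-regulated lncRNAs
sponge down-regulated miRNAs, de-repressing the miRNAs' up-regulated
mRNA targets.  The assembled graph therefore has exactly two edge
kinds — sponge (lncRNA→miRNA) and regulation (miRNA→mRNA) — and a miRNA
enters the network only if it carries at least one of each (a concordant
down-miRNA with targets but no sponging lncRNA stays out).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .integrate import DirectionalPair

NODE_CLASSES = ("lncRNA", "miRNA", "mRNA")
EDGE_KINDS = ("sponge", "regulation")


class NetworkError(ValueError):
    pass


def assemble_cerna(
    concordance: pd.DataFrame,
    pairs: list[DirectionalPair],
    sponges: pd.DataFrame,
    require_sponge: bool = True,
) -> nx.DiGraph:
    """Assemble the lncRNA→miRNA→mRNA network.

    ``concordance`` is a cross-context concordance table (its ``down``
    rows seed the miRNA layer), ``pairs`` must come from the
    miRNA-down/mRNA-up filter, and ``sponges`` is an interaction table
    restricted to (or containing) lncRNA→miRNA rows.  Node attributes:
    ``cls`` and ``direction``; edge attributes: ``kind`` and
    ``evidence``.  The graph is simple; assembly is order-invariant.
    """
    if any(p.mirna_direction != "down" or p.mrna_direction != "up" for p in pairs):
        raise NetworkError("pairs must be in mir_down_mrna_up orientation")
    down_mirnas = set(concordance.loc[concordance["direction"] == "down", "mirna"])

    targets: dict[str, dict[str, tuple[str, ...]]] = {}
    for p in pairs:
        if p.mirna in down_mirnas:
            targets.setdefault(p.mirna, {})[p.mrna] = p.evidence

    sp = sponges[
        (sponges["regulator_class"] == "lncRNA") & (sponges["target_class"] == "miRNA")
    ]
    sponge_map: dict[str, dict[str, list[str]]] = {}
    for r in sp.itertuples(index=False):
        if r.target in down_mirnas:
            sponge_map.setdefault(r.target, {}).setdefault(r.regulator, []).append(
                f"{r.source}:{r.evidence}"
            )

    included = {m for m in down_mirnas if m in targets and (not require_sponge or m in sponge_map)}

    g = nx.DiGraph()
    for mir in sorted(included):
        g.add_node(mir, cls="miRNA", direction="down")
        for lnc in sorted(sponge_map.get(mir, {})):
            if lnc not in g:
                g.add_node(lnc, cls="lncRNA", direction="")
            g.add_edge(lnc, mir, kind="sponge",
                       evidence=";".join(sorted(sponge_map[mir][lnc])))
        for mrna in sorted(targets[mir]):
            if mrna not in g:
                g.add_node(mrna, cls="mRNA", direction="up")
            g.add_edge(mir, mrna, kind="regulation", evidence=";".join(targets[mir][mrna]))
    return g


def network_counts(g: nx.DiGraph) -> dict[str, int]:
    counts = {c: 0 for c in NODE_CLASSES}
    for _, d in g.nodes(data=True):
        counts[d["cls"]] += 1
    return {"n_lncRNA": counts["lncRNA"], "n_miRNA": counts["miRNA"], "n_mRNA": counts["mRNA"]}


def hub_ranking(g: nx.DiGraph) -> pd.DataFrame:
    """Rank miRNA nodes by unweighted degree.

    Columns: mirna, regulation_degree (outgoing regulation edges),
    sponge_degree (incoming sponge edges), total_degree; sorted by
    total_degree descending, ties by identifier ascending.
    """
    rows = []
    for n, d in g.nodes(data=True):
        if d["cls"] != "miRNA":
            continue
        reg = sum(1 for _, _, e in g.out_edges(n, data=True) if e["kind"] == "regulation")
        spo = sum(1 for _, _, e in g.in_edges(n, data=True) if e["kind"] == "sponge")
        rows.append((n, reg, spo, reg + spo))
    table = pd.DataFrame(rows, columns=["mirna", "regulation_degree", "sponge_degree", "total_degree"])
    return table.sort_values(
        ["total_degree", "mirna"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def export_network(g: nx.DiGraph, path: str | Path, fmt: str) -> None:
    """Write the network as graphml, edge_tsv, or json (node-link)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\tkind\ttarget\tevidence\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{d['kind']}\t{v}\t{d['evidence']}\n")
    elif fmt == "json":
        data = nx.node_link_data(g, edges="edges")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    else:
        raise NetworkError(f"unknown export format: {fmt!r}")


def import_network_json(path: str | Path) -> nx.DiGraph:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return nx.node_link_graph(data, directed=True, edges="edges")
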