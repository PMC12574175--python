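"""Interaction evidence, directional pair filtering, cross-context
concordance, and over-representation enrichment.

The biological logic: a miRNA represses its mRNA targets, so a genuine
regulatory pair in a two-condition contrast should show *inverse*
differential expression (miRNA down with target mRNA up, or the
reverse), and the pair must be supported by interaction evidence
(predicted / curated / CLIP) from target databases.  miRNAs whose
change replicates with the same sign in an independent tumor cohort are
the concordant candidates carried into the ceRNA network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DESets, bh_adjust
from .expression import FeatureMapping

REGULATOR_CLASSES = {"miRNA", "lncRNA"}
TARGET_CLASSES = {"mRNA", "miRNA"}
LEGAL_CLASS_PAIRS = {("miRNA", "mRNA"), ("lncRNA", "miRNA")}
EVIDENCE_LEVELS = {"predicted", "curated", "clip"}

INTERACTION_COLUMNS = [
    "regulator", "regulator_class", "target", "target_class", "evidence", "source",
]


class IntegrationError(ValueError):
    pass


@dataclass(frozen=True)
class DirectionalPair:
    """A database-supported miRNA–mRNA pair with opposite DE directions."""

    mirna: str
    mrna: str
    mirna_direction: str  # "up" | "down"
    mrna_direction: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mirna_direction == self.mrna_direction:
            raise IntegrationError("directions must be strictly opposite")


def _validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrationError(f"interaction table missing columns: {missing}")
    df = df[INTERACTION_COLUMNS].astype(str)
    bad_ev = sorted(set(df["evidence"]) - EVIDENCE_LEVELS)
    if bad_ev:
        raise IntegrationError(f"unknown evidence levels: {bad_ev}")
    pairs = list(zip(df["regulator_class"], df["target_class"]))
    for i, cp in enumerate(pairs):
        if cp not in LEGAL_CLASS_PAIRS:
            raise IntegrationError(
                f"illegal class pair {cp[0]}->{cp[1]} at row {i}: only "
                "miRNA->mRNA and lncRNA->miRNA are allowed"
            )
    # (regulator, target, source) rows unique after dedup
    return df.drop_duplicates(subset=["regulator", "target", "source"]).reset_index(drop=True)


def load_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read a typed regulator→target interaction TSV and validate it."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_interactions(df)


def make_interaction_table(rows: list[tuple[str, str, str, str, str, str]]) -> pd.DataFrame:
    """Build a validated interaction table from in-memory rows."""
    df = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
    return _validate_interactions(df)


def write_interaction_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def inverse_pair_filter(
    mirna_sets: DESets,
    mrna_sets: DESets,
    interactions: pd.DataFrame,
    mode: str = "mir_down_mrna_up",
) -> list[DirectionalPair]:
    """Retain miRNA–mRNA pairs with opposite DE directions and evidence.

    A pair is kept iff (i) the miRNA is in the required direction set,
    (ii) its mRNA target is in the opposite direction set, and (iii) the
    pair appears in the interaction table (evidence sources unioned).
    ``mode`` selects miRNA-down/mRNA-up, the reverse, or both (disjoint
    union).  Returned sorted by (miRNA, mRNA) for determinism.
    """
    if mode not in ("mir_down_mrna_up", "mir_up_mrna_down", "both"):
        raise IntegrationError(f"unknown mode: {mode!r}")
    reg = interactions[
        (interactions["regulator_class"] == "miRNA")
        & (interactions["target_class"] == "mRNA")
    ]
    evidence: dict[tuple[str, str], list[str]] = {}
    for r in reg.itertuples(index=False):
        evidence.setdefault((r.regulator, r.target), []).append(f"{r.source}:{r.evidence}")

    wanted: list[tuple[frozenset, frozenset, str, str]] = []
    if mode in ("mir_down_mrna_up", "both"):
        wanted.append((mirna_sets.down, mrna_sets.up, "down", "up"))
    if mode in ("mir_up_mrna_down", "both"):
        wanted.append((mirna_sets.up, mrna_sets.down, "up", "down"))

    out: list[DirectionalPair] = []
    for mir_set, mrna_set, mdir, tdir in wanted:
        for (mir, mrna), ev in evidence.items():
            if mir in mir_set and mrna in mrna_set:
                out.append(DirectionalPair(mir, mrna, mdir, tdir, tuple(sorted(ev))))
    out.sort(key=lambda p: (p.mirna, p.mrna))
    return out


def pairs_to_frame(pairs: list[DirectionalPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.mirna, p.mirna_direction, p.mrna, p.mrna_direction, ";".join(p.evidence))
            for p in pairs
        ],
        columns=["mirna", "mirna_direction", "mrna", "mrna_direction", "evidence"],
    )


def shared_direction_mirnas(
    det_a: pd.DataFrame,
    sets_a: DESets,
    det_b: pd.DataFrame,
    sets_b: DESets,
    mapping: FeatureMapping,
) -> pd.DataFrame:
    """Cross-context concordance table of same-direction significant miRNAs.

    A matched miRNA is retained iff it is significant (per each context's
    own thresholds) in *both* contexts with the same sign of log2FC.
    Columns: mirna, log2fc_context1, log2fc_context2, direction; sorted
    by log2fc_context1 ascending.
    """
    rows = []
    for id_a, id_b in mapping.pairs:
        in_a = "up" if id_a in sets_a.up else "down" if id_a in sets_a.down else None
        in_b = "up" if id_b in sets_b.up else "down" if id_b in sets_b.down else None
        if in_a is None or in_b is None or in_a != in_b:
            continue
        rows.append(
            (id_a, float(det_a.loc[id_a, "log2fc"]), float(det_b.loc[id_b, "log2fc"]), in_a)
        )
    table = pd.DataFrame(
        rows, columns=["mirna", "log2fc_context1", "log2fc_context2", "direction"]
    )
    return table.sort_values("log2fc_context1", kind="stable").reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis.

    For each set S (intersected with the universe), p = P[X >= overlap]
    where X ~ Hypergeom(N=|universe|, K=|S|, n=|query|); q by BH across
    the collection.  The query must lie within the universe.
    """
    if not universe:
        raise IntegrationError("empty universe")
    if not query <= universe:
        raise IntegrationError("query must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        k = len(query & members)
        # upper tail P[X >= k]; sf(k-1) == P[X > k-1]
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members), n_query))
        rows.append((set_id, k, len(members), n_query, n_universe, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=["set_id", "overlap", "set_size", "query_size", "universe_size", "p"],
    )
    table["q"] = bh_adjust(table["p"]) if len(table) else np.nan
    return table
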