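"""Published reference values bundled as analysis inputs.

``SHARED_MIRNA_PANEL`` is the published concordance panel for the BT-474
3D-vs-2D contrast against luminal-B breast tumors: the 14 miRNAs whose
differential expression replicates with the same sign in both contexts,
with their printed log2 fold changes.  It serves as a fixture input for
the concordance machinery (a printed table is data, and this one is
small enough to carry verbatim).

``REPORTED_COHORT_COUNTS`` and ``REPORTED_AUC`` are provenance anchors
only: full-cohort quantities from the original study that depend on the
deposited GEO accessions and interaction-database snapshots, which this
package does not download.  They are never computed and never compared
against pipeline output.
"""

from __future__ import annotations

import pandas as pd

from .diffexp import DESets, Thresholds
from .expression import FeatureMapping

#: (miRNA, log2FC 3D-vs-2D, log2FC tumors-vs-2D)
SHARED_MIRNA_PANEL: tuple[tuple[str, float, float], ...] = (
    ("hsa-miR-92a-3p", -3.49, -4.27),
    ("hsa-miR-378d", -2.52, -3.35),
    ("hsa-miR-130a-3p", -2.41, -3.71),
    ("hsa-miR-362-5p", -2.07, -2.12),
    ("hsa-miR-18a-5p", -1.13, -1.97),
    ("hsa-miR-539-3p", -1.11, -4.58),
    ("hsa-miR-4717-3p", 1.10, 1.41),
    ("hsa-miR-5196-5p", 1.36, 2.60),
    ("hsa-miR-4534", 1.37, 1.86),
    ("hsa-miR-1290", 1.73, 2.15),
    ("hsa-miR-3141", 1.73, 2.15),
    ("hsa-miR-4433-3p", 1.73, 4.82),
    ("hsa-miR-3911", 1.89, 3.87),
    ("hsa-miR-584-5p", 2.78, 4.35),
)

#: miRNA hubs of the published ceRNA network and their reported
#: normal-vs-tumor diagnostic AUCs (retrieved values; documentation only).
REPORTED_AUC: dict[str, float] = {
    "hsa-miR-92a-3p": 0.68,
    "hsa-miR-539-5p": 0.72,
    "hsa-miR-18a-5p": 0.74,
    "hsa-miR-130a-3p": 0.81,
}

#: Full-cohort counts from the original study.  These require the GEO
#: accessions and database snapshots and are not reproducible from the
#: bundled/synthetic inputs; carried as metadata, never recomputed.
REPORTED_COHORT_COUNTS: dict[str, int] = {
    "mirna_up_3d_vs_2d": 75,
    "mirna_down_3d_vs_2d": 82,
    "mirna_up_tumor_vs_2d": 43,
    "mirna_down_tumor_vs_2d": 186,
    "integrated_mrna_down_targets_of_up": 1175,
    "integrated_mrna_up_targets_of_down": 872,
}

#: Published network shape: 12 sponge lncRNAs, 4 hub miRNAs, 58 target mRNAs.
REPORTED_NETWORK_SHAPE: dict[str, int] = {"n_lncRNA": 12, "n_miRNA": 4, "n_mRNA": 58}


def panel_concordance_inputs(
    q: float = 0.01, thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, DESets, pd.DataFrame, DESets, FeatureMapping]:
    """Build minimal DE tables/sets for the two contexts from the panel.

    Every panel miRNA is marked significant (q set below alpha) in both
    contexts with its printed log2FC, so feeding the result to
    ``shared_direction_mirnas`` reconstructs the published table.
    """
    names = [r[0] for r in SHARED_MIRNA_PANEL]

    def det(col: int) -> pd.DataFrame:
        lfc = pd.Series([r[col] for r in SHARED_MIRNA_PANEL], index=names, dtype=float)
        return pd.DataFrame(
            {
                "log2fc": lfc,
                "fc_linear": 2.0**lfc,
                "p": q,
                "q": q,
            }
        )

    def sets(det_table: pd.DataFrame) -> DESets:
        up = frozenset(det_table.index[det_table["log2fc"] > 0])
        down = frozenset(det_table.index[det_table["log2fc"] < 0])
        return DESets(up, down, frozenset(), thresholds)

    det_3d, det_tumor = det(1), det(2)
    mapping = FeatureMapping(
        pairs=[(n, n) for n in names], unmatched_a=[], unmatched_b=[]
    )
    return det_3d, sets(det_3d), det_tumor, sets(det_tumor), mapping
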