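#!/usr/bin/env python
"""Differential expression for both contrasts of the scenario bundle.

Applies the detection filter (log2 signal > 1 in every sample, sentinel
cells disqualify), then runs the moderated t on the two 3D-vs-2D
cell-culture cohorts and per-feature Welch tests on the tumor-vs-2D
cohort; classifies features at FC > 1.5, BH q < 0.05.  Writes
``results/de/de_*.tsv``.
"""

from pathlib import Path

from cernet.diffexp import classify_de, fit_moderated_t, welch_de_table, write_de_table
from cernet.expression import detection_filter, read_expression_table
from cernet.pipeline import read_design

REPO = Path(__file__).resolve().parents[1]
BUNDLE = REPO / "results" / "scenario"
OUT = REPO / "results" / "de"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    jobs = [
        ("mirna_3d", "design_3d", "moderated"),
        ("mrna_3d", "mrna_design", "moderated"),
        ("mirna_tumor", "tumor_design", "welch"),
    ]
    for matrix_name, design_name, engine in jobs:
        m = read_expression_table(BUNDLE / f"{matrix_name}.tsv", sentinel=-9.969)
        design = read_design(BUNDLE / f"{design_name}.tsv")
        filtered = detection_filter(m, 1.0)
        if engine == "moderated":
            det, params = fit_moderated_t(filtered, design)
            extra = f"d0={params.d0:.2f}, s0^2={params.s0_sq:.4f}"
        else:
            det = welch_de_table(filtered, design)
            extra = "per-feature Welch"
        sets = classify_de(det)
        write_de_table(det, OUT / f"de_{matrix_name}.tsv")
        print(
            f"[{matrix_name}] {m.shape[0]} features, {filtered.shape[0]} detected; "
            f"{engine} ({extra}): {len(sets.up)} up / {len(sets.down)} down "
            f"at FC>1.5, q<0.05"
        )


if __name__ == "__main__":
    main()
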