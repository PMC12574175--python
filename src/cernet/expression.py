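"""Expression-matrix containers, readers, and sanitation policies.

Bulk microarray exports arrive as feature-by-sample tables on a log2
intensity scale, either as plain TSV or in the GEO series-matrix dialect
(metadata lines prefixed with ``!``, the numeric table delimited by
begin/end markers).  Agilent exports additionally use a sentinel value,
−9.969, to mean "not detected"; such cells are *not* measurements and are
masked at read time while the raw value is retained for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Agilent "not detected" placeholder used by the miRNA array exports.
SENTINEL_NOT_DETECTED = -9.969

_SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
_SERIES_MATRIX_END = "!series_matrix_table_end"


class ExpressionIOError(ValueError):
    """Raised for malformed expression tables or policy violations."""


@dataclass
class ExpressionMatrix:
    """Feature × sample expression values with a missingness mask.

    ``values`` holds every number as read, including sentinel cells;
    ``mask`` is True where a cell is missing/off-scale and must be
    excluded from every downstream mean, variance, or test.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    scale: Literal["log2", "linear"] = "log2"
    platform_tag: str = ""
    sentinel: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ExpressionIOError("values and mask dimensions disagree")
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ExpressionIOError("values and mask ids disagree")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            raise ExpressionIOError("duplicate sample ids")
        self.mask = self.mask.astype(bool)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> pd.DataFrame:
        """Values with masked cells replaced by NaN."""
        return self.values.where(~self.mask)

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        features = list(features)
        return ExpressionMatrix(
            values=self.values.loc[features].copy(),
            mask=self.mask.loc[features].copy(),
            scale=self.scale,
            platform_tag=self.platform_tag,
            sentinel=self.sentinel,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            values=self.values[samples].copy(),
            mask=self.mask[samples].copy(),
            scale=self.scale,
            platform_tag=self.platform_tag,
            sentinel=self.sentinel,
        )

    def apply_sentinel(self, sentinel: float) -> "ExpressionMatrix":
        """Mask every cell equal to ``sentinel`` (idempotent)."""
        mask = self.mask | (self.values == sentinel)
        return ExpressionMatrix(self.values.copy(), mask, self.scale, self.platform_tag, sentinel)


@dataclass
class SampleDesign:
    """Sample → group assignment with a designated reference group."""

    labels: dict[str, str]
    groups: tuple[str, str]  # (reference, alternative)

    def __post_init__(self) -> None:
        unknown = set(self.labels.values()) - set(self.groups)
        if unknown:
            raise ExpressionIOError(f"labels outside declared groups: {sorted(unknown)}")

    @property
    def reference(self) -> str:
        return self.groups[0]

    @property
    def alternative(self) -> str:
        return self.groups[1]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def check_covers(self, m: ExpressionMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.labels]
        if missing:
            raise ExpressionIOError(f"samples without a group label: {missing}")


@dataclass
class FeatureMapping:
    """1:1 name-based mapping between two datasets' feature ids."""

    pairs: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]
    policy: str = "trim-whitespace"

    @property
    def matched_a(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def matched_b(self) -> list[str]:
        return [b for _, b in self.pairs]


def _parse_number(token: str) -> float:
    # Unicode minus (U+2212) accepted as minus; decimal or scientific notation.
    return float(token.strip().replace("−", "-"))


def _rows_from_lines(
    lines: Iterable[str], dialect: str, path: str
) -> list[list[str]]:
    rows: list[tuple[int, list[str]]] = []
    in_table = dialect != "series_matrix"  # plain_tsv: whole file is the table
    has_markers = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if dialect == "series_matrix":
            stripped = line.strip()
            if stripped.lower() == _SERIES_MATRIX_BEGIN:
                in_table, has_markers = True, True
                continue
            if stripped.lower() == _SERIES_MATRIX_END:
                in_table = False
                continue
            if stripped.startswith("!"):
                continue
            if not in_table and has_markers:
                continue
        if not line.strip():
            continue
        rows.append((lineno, line.split("\t")))
    return rows


def read_expression_table(
    path: str | Path,
    dialect: Literal["plain_tsv", "series_matrix"] = "plain_tsv",
    *,
    sentinel: float | None = None,
    scale: Literal["log2", "linear"] = "log2",
    platform_tag: str = "",
    duplicate_policy: Literal["strict", "first_wins"] = "strict",
) -> ExpressionMatrix:
    """Read a feature × sample expression table.

    In the series-matrix dialect, lines starting with ``!`` are skipped
    and the table is delimited by the begin/end markers.  Cells exactly
    equal to ``sentinel`` are masked at read time; the value itself is
    retained for audit.
    """
    path = Path(path)
    if dialect not in ("plain_tsv", "series_matrix"):
        raise ExpressionIOError(f"unknown dialect: {dialect!r}")
    with open(path, encoding="utf-8") as fh:
        rows = _rows_from_lines(fh, dialect, str(path))
    if len(rows) < 2:
        raise ExpressionIOError(f"{path}: empty table (no data rows)")

    header_lineno, header = rows[0]
    sample_ids = [c.strip().strip('"') for c in header[1:]]
    if not sample_ids:
        raise ExpressionIOError(f"{path}: header row has no sample ids")
    n = len(sample_ids)

    feature_ids: list[str] = []
    seen: dict[str, int] = {}
    data: list[list[float]] = []
    for lineno, cells in rows[1:]:
        if len(cells) - 1 != n:
            raise ExpressionIOError(
                f"{path}: line {lineno}: expected {n} values, got {len(cells) - 1}"
            )
        fid = cells[0].strip().strip('"')
        if fid in seen:
            if duplicate_policy == "strict":
                raise ExpressionIOError(
                    f"{path}: line {lineno}: duplicate feature id {fid!r}"
                )
            continue  # first_wins
        try:
            values = [_parse_number(c) for c in cells[1:]]
        except ValueError as exc:
            raise ExpressionIOError(f"{path}: line {lineno}: {exc}") from exc
        seen[fid] = lineno
        feature_ids.append(fid)
        data.append(values)

    values = pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)
    mask = pd.DataFrame(False, index=feature_ids, columns=sample_ids)
    if sentinel is not None:
        mask = values == sentinel
    return ExpressionMatrix(values, mask, scale=scale, platform_tag=platform_tag, sentinel=sentinel)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the plain-TSV dialect; round-trips values and mask bit-exactly.

    Masked cells are written as their stored value (the sentinel), so
    re-reading with the same sentinel reproduces the mask.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in m.values.iterrows():
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row.to_numpy()) + "\n")


def detection_filter(
    m: ExpressionMatrix,
    min_level: float = 1.0,
    scope: Literal["all_samples", "any_group_mean"] = "all_samples",
    design: SampleDesign | None = None,
) -> ExpressionMatrix:
    """Restrict to features passing the detection policy (default RMA > 1).

    ``all_samples`` (default, strictest reading): every unmasked cell of
    the feature exceeds ``min_level`` *and* the feature has zero masked
    cells — a "not detected" sentinel cannot certify detection.
    ``any_group_mean``: at least one group's mean over unmasked cells
    exceeds ``min_level`` (requires ``design``).
    """
    if not np.isfinite(min_level):
        raise ExpressionIOError("min_level must be finite")
    if m.scale != "log2":
        raise ExpressionIOError("detection filter expects a log2-scale matrix")
    if scope == "all_samples":
        no_masked = ~m.mask.any(axis=1)
        above = (m.values > min_level).all(axis=1)
        keep = no_masked & above
    elif scope == "any_group_mean":
        if design is None:
            raise ExpressionIOError("any_group_mean scope requires a design")
        design.check_covers(m)
        vals = m.unmasked()
        keep = pd.Series(False, index=m.values.index)
        for g in design.groups:
            keep |= vals[design.samples_in(g)].mean(axis=1) > min_level
    else:
        raise ExpressionIOError(f"unknown scope: {scope!r}")
    kept = int(keep.sum())
    logger.info(
        "detection_filter(min_level=%s, scope=%s): kept %d / dropped %d features",
        min_level, scope, kept, len(keep) - kept,
    )
    return m.subset_features(m.values.index[keep])


def _normalize_name(name: str, policy: str) -> str:
    if policy == "trim-whitespace":
        return name.strip()
    if policy == "none":
        return name
    raise ExpressionIOError(f"unknown name-normalization policy: {policy!r}")


def match_features_by_name(
    a: ExpressionMatrix | Sequence[str],
    b: ExpressionMatrix | Sequence[str],
    policy: str = "trim-whitespace",
    strict: bool = True,
) -> FeatureMapping:
    """1:1 name matching across datasets (case-sensitive, no re-annotation).

    Default policy only trims surrounding whitespace: no case folding, no
    -5p/-3p arm inference, no probe collapsing.
    """
    ids_a = list(a.feature_ids) if isinstance(a, ExpressionMatrix) else list(a)
    ids_b = list(b.feature_ids) if isinstance(b, ExpressionMatrix) else list(b)

    def normed(ids: list[str], label: str) -> dict[str, str]:
        out: dict[str, str] = {}
        dups: list[str] = []
        for i in ids:
            key = _normalize_name(i, policy)
            if key in out:
                dups.append(key)
            else:
                out[key] = i
        if dups and strict:
            raise ExpressionIOError(
                f"duplicate post-normalization names in {label}: {sorted(set(dups))}"
            )
        return out

    na, nb = normed(ids_a, "A"), normed(ids_b, "B")
    common = [k for k in na if k in nb]
    pairs = [(na[k], nb[k]) for k in common]
    matched_a = {na[k] for k in common}
    matched_b = {nb[k] for k in common}
    return FeatureMapping(
        pairs=pairs,
        unmatched_a=[i for i in ids_a if i not in matched_a],
        unmatched_b=[i for i in ids_b if i not in matched_b],
        policy=policy,
    )
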