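"""Per-feature differential expression for two-condition contrasts.

Two engines are provided, mirroring how the two kinds of contrast are
analyzed in practice:

* :func:`fit_moderated_t` — the limma-style moderated t-statistic for
  small-n cell-culture contrasts (e.g. 3D vs 2D triplicates).  Each
  feature's residual variance s²_g (pooled across the two groups,
  d_g = n−2 df) is shrunk toward a prior variance s₀² estimated across
  all features by empirical Bayes.  The posterior variance

      s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

  replaces s²_g in the t-statistic, which then has d₀ + d_g degrees of
  freedom.  The hyperparameters (d₀, s₀²) are obtained by closed-form
  method-of-moments on log variances: if s²_g ~ s₀²·F(d_g, d₀), then
  e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s₀² + ψ(d₀/2)
  − log(d₀/2) and variance ψ′(d_g/2) + ψ′(d₀/2), so d₀ comes from a
  trigamma inversion and s₀² from the mean.

* :func:`welch_de_table` — per-feature two-sided Welch's t-test for the
  tumor-vs-cell-line contrast, where unequal variances and sentinel
  missingness make pooling inappropriate.

log₂ fold change is always the difference of group means on the log₂
scale (alternative − reference); linear fold change is 2^log₂FC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "mean_ref", "mean_alt", "log2fc", "fc_linear",
    "t", "df", "p", "q", "method", "n_ref", "n_alt",
]


class DiffExpError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """DE classification thresholds: linear FC cut and significance level."""

    fc_min: float = 1.5
    alpha: float = 0.05
    use_q: bool = True

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise DiffExpError("fc_min must exceed 1")
        if not 0 < self.alpha <= 1:
            raise DiffExpError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class DESets:
    """Partition of tested features into up / down / not-significant."""

    up: frozenset[str]
    down: frozenset[str]
    ns: frozenset[str]
    thresholds: Thresholds

    @property
    def tested(self) -> frozenset[str]:
        return self.up | self.down | self.ns


@dataclass
class EBayesParams:
    """Empirical-Bayes hyperparameters and per-feature variances."""

    d0: float  # prior degrees of freedom; np.inf allowed
    s0_sq: float  # prior variance
    s2: pd.Series  # per-feature residual variance s²_g
    df_resid: pd.Series  # per-feature residual df d_g

    def posterior_var(self) -> pd.Series:
        if np.isinf(self.d0):
            return pd.Series(self.s0_sq, index=self.s2.index)
        return (self.d0 * self.s0_sq + self.df_resid * self.s2) / (self.d0 + self.df_resid)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the mean reference quantile distribution.

    After normalization each column's sorted values equal the mean of the
    per-column sorted vectors; ties within a column receive the mean of
    their reference quantiles.  Requires a complete (unmasked) matrix.
    """
    if m.mask.to_numpy().any():
        raise DiffExpError(
            "quantile_normalize requires a complete matrix; "
            "take the complete-case submatrix first"
        )
    x = m.values.to_numpy(dtype=float)
    n_feat, n_samp = x.shape
    if n_feat == 1:
        out = np.full_like(x, x.mean())
    else:
        reference = np.sort(x, axis=0).mean(axis=1)
        out = np.empty_like(x)
        for j in range(n_samp):
            ranks = stats.rankdata(x[:, j], method="average")  # 1-based, .5 on ties
            out[:, j] = np.interp(ranks, np.arange(1, n_feat + 1), reference)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.mask.copy(), m.scale, m.platform_tag, m.sentinel)


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch's t-test of y vs x: t = (ȳ − x̄)/√(s²x/nx + s²y/ny).

    Zero variance on both sides with unequal means is perfect separation
    (t = ±inf, p = 0); with equal means the statistic is undefined and a
    ``DiffExpError('degenerate variance')`` is raised so callers can skip
    and log the feature.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DiffExpError("welch_test needs >=2 values per side")
    # constant samples must register exactly zero variance (mean
    # subtraction leaves ~1e-30 residues on identical floats)
    vx = 0.0 if (x == x[0]).all() else x.var(ddof=1)
    vy = 0.0 if (y == y[0]).all() else y.var(ddof=1)
    if vx == 0 and vy == 0:
        diff = y.mean() - x.mean()
        if diff == 0:
            raise DiffExpError("degenerate variance")
        return float(np.sign(diff) * np.inf), float(x.size + y.size - 2), 0.0
    if vx == 0 or vy == 0:
        # one constant sample: Welch formulas directly (scipy's moment
        # path warns about the degenerate side)
        se_sq = vx / x.size + vy / y.size
        t = (y.mean() - x.mean()) / np.sqrt(se_sq)
        df = se_sq**2 / (
            (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
        )
        return float(t), float(df), float(2 * stats.t.sf(abs(t), df))
    res = stats.ttest_ind(y, x, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (NaN-tolerant).

    q_(i) = min_{j>=i} p_(j)·m/j after sorting, mapped back to the input
    order and capped at 1; NaN entries stay NaN and do not count toward m.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise DiffExpError("p-values must lie in [0, 1]")
    if vals.size:
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of s² ~ s₀²·F(df, d₀) on the log scale.

    Returns (d0, s0_sq); d0 is np.inf when the observed spread of log
    variances is no larger than expected from the residual df alone.
    Non-positive variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if not ok.any():
        return np.inf, 0.0
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = ((e - emean) ** 2).sum() / (n - 1)
    evar -= special.polygamma(1, dfo / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def _group_arrays(
    m: ExpressionMatrix, design: SampleDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    design.check_covers(m)
    vals = m.unmasked()
    return vals[design.samples_in(design.reference)], vals[design.samples_in(design.alternative)]


def fit_moderated_t(
    m: ExpressionMatrix,
    design: SampleDesign,
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, EBayesParams]:
    """Moderated-t differential expression for a two-group design.

    Returns a DE table (one row per feature, columns :data:`DE_COLUMNS`)
    and the fitted :class:`EBayesParams`.  ``d0_override`` forces the
    prior df (0 recovers the ordinary two-sample t).  Features with fewer
    than two unmasked observations in either group are reported with NaN
    statistics and logged.
    """
    ref, alt = _group_arrays(m, design)
    if ref.shape[1] < 2 or alt.shape[1] < 2:
        raise DiffExpError("each group needs >=2 samples")

    n_ref = ref.notna().sum(axis=1)
    n_alt = alt.notna().sum(axis=1)
    mean_ref = ref.mean(axis=1)
    mean_alt = alt.mean(axis=1)
    ss = ref.sub(mean_ref, axis=0).pow(2).sum(axis=1) + alt.sub(mean_alt, axis=0).pow(2).sum(axis=1)
    df_resid = (n_ref + n_alt - 2).astype(float)
    testable = (n_ref >= 2) & (n_alt >= 2) & (df_resid > 0)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("fit_moderated_t: %d features lack >=2 obs per group; reported as NA", n_skipped)

    s2 = ss / df_resid
    s2[~testable] = np.nan

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_f_dist(s2[testable].to_numpy(), df_resid[testable].to_numpy())
        if d0 == 0:
            s0_sq = float(np.nan_to_num(s0_sq))
    else:
        d0, s0_sq = fit_f_dist(s2[testable].to_numpy(), df_resid[testable].to_numpy())

    params = EBayesParams(d0=d0, s0_sq=s0_sq, s2=s2, df_resid=df_resid)

    if d0 == 0:
        post_var = s2.copy()
        df_total = df_resid.astype(float)
    elif np.isinf(d0):
        post_var = pd.Series(s0_sq, index=s2.index).where(testable)
        df_total = pd.Series(np.inf, index=s2.index)
    else:
        post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    log2fc = mean_alt - mean_ref
    se = np.sqrt(post_var * (1.0 / n_ref + 1.0 / n_alt))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    # zero posterior variance: perfect separation if means differ, else no signal
    zero_se = testable & (se == 0)
    t[zero_se & (log2fc != 0)] = np.sign(log2fc) * np.inf
    t[zero_se & (log2fc == 0)] = 0.0

    p = pd.Series(np.nan, index=s2.index)
    finite_df = df_total.replace(np.inf, 1e12)
    tt = testable & t.notna()
    p[tt] = 2.0 * stats.t.sf(np.abs(t[tt]), finite_df[tt])
    p[tt & np.isinf(t)] = 0.0

    table = pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "log2fc": log2fc,
            "fc_linear": np.exp2(log2fc),
            "t": t,
            "df": df_total.where(tt),
            "p": p,
            "q": bh_adjust(p),
            "method": "moderated",
            "n_ref": n_ref,
            "n_alt": n_alt,
        }
    )
    table.index.name = "feature"
    return table, params


def welch_de_table(m: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-feature Welch DE table (two-sided), masked cells excluded.

    Features failing preconditions (<2 unmasked values per side, or
    degenerate variance) get NaN statistics rather than silent drops.
    """
    ref, alt = _group_arrays(m, design)
    rows = {}
    n_degenerate = 0
    for fid in m.feature_ids:
        x = ref.loc[fid].dropna().to_numpy()
        y = alt.loc[fid].dropna().to_numpy()
        mr = x.mean() if x.size else np.nan
        ma = y.mean() if y.size else np.nan
        lfc = ma - mr
        t = df = p = np.nan
        if x.size >= 2 and y.size >= 2:
            try:
                t, df, p = welch_test(x, y)
            except DiffExpError:
                n_degenerate += 1
        rows[fid] = (mr, ma, lfc, np.exp2(lfc), t, df, p, x.size, y.size)
    if n_degenerate:
        logger.info("welch_de_table: %d degenerate-variance features reported as NA", n_degenerate)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["mean_ref", "mean_alt", "log2fc", "fc_linear", "t", "df", "p", "n_ref", "n_alt"],
    )
    table["q"] = bh_adjust(table["p"])
    table["method"] = "welch"
    table = table[DE_COLUMNS]
    table.index.name = "feature"
    return table


def classify_de(det: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> DESets:
    """Partition features into up / down / ns at the given thresholds.

    up: fc_linear > fc_min and stat < alpha; down: fc_linear < 1/fc_min
    and stat < alpha (stat = q when use_q else p); comparisons strict;
    NaN statistics are never significant.
    """
    stat = det["q"] if thresholds.use_q else det["p"]
    sig = stat < thresholds.alpha  # NaN compares False
    up = det.index[sig & (det["fc_linear"] > thresholds.fc_min)]
    down = det.index[sig & (det["fc_linear"] < 1.0 / thresholds.fc_min)]
    ns = det.index.difference(up.union(down))
    return DESets(frozenset(up), frozenset(down), frozenset(ns), thresholds)


def cluster_features(m: ExpressionMatrix) -> tuple[list[str], np.ndarray | None]:
    """Agglomerative clustering of features (Euclidean, average linkage).

    Returns the deterministic leaf order and the scipy linkage matrix
    (None for <2 features).  Requires a complete submatrix.
    """
    if m.mask.to_numpy().any():
        raise DiffExpError("cluster_features requires a complete matrix")
    ids = m.feature_ids
    if len(ids) < 2:
        return list(ids), None
    link = hierarchy.linkage(m.values.to_numpy(), method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [ids[i] for i in order], link


def write_de_table(det: pd.DataFrame, path) -> None:
    out = det.copy()
    out.insert(3, "FC", out.pop("fc_linear"))
    out = out.rename(columns={"log2fc": "log2FC"})
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    """Load a DE table written by :func:`write_de_table` (re-entrant)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.rename(columns={"log2FC": "log2fc", "FC": "fc_linear"})
    return df[DE_COLUMNS]
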