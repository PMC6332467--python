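"""Exact contingency tests, residual post-hoc, ANOVA and Dunnett comparisons.

The case-control battery implemented here:

* Fisher's exact test for 2x2 tables, two-sided by the point-probability
  rule (sum the hypergeometric probabilities of all tables with the same
  margins that are no more probable than the observed one) — the convention
  of the major commercial statistics packages.
* The Fisher-Freeman-Halton generalization to r x c tables, by full
  enumeration of margin-fixed tables when their number is tractable and by
  Monte Carlo permutation sampling otherwise (add-one estimator, so the
  reported p is never zero, with its binomial standard error).
* Adjusted standardized residuals as a cell-level post-hoc for contingency
  tables, with two-sided normal p-values and per-cell phi effect sizes
  (phi = residual / sqrt(N)).
* One-way ANOVA from raw observations or directly from published
  (n, mean, sd) group summaries — the two routes agree exactly because the
  raw route reduces to the summary formulas.
* Dunnett's two-tailed many-to-one comparison against a single control
  group, with the family-wise adjusted p estimated by Monte Carlo over the
  joint null of the shared-control construction (which handles unbalanced
  group sizes naturally).
* Bonferroni adjustment.

All randomized procedures record their seed and replicate count in the
returned result object.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

FULL_ENUMERATION = "full-enumeration"
MONTE_CARLO = "monte-carlo"

# Relative tolerance (in log space) for the "no more probable than observed"
# comparison, guarding against floating-point misclassification of ties.
_LOG_TIE_TOL = 1e-9

_DEFAULT_MAX_ENUMERATION = 200_000
_DEFAULT_MC_REPLICATES = 100_000


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError(f"need at least a 2x2 table, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("grand total must be positive")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValueError("label lengths do not match table shape")

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[Sequence[int]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        counts = np.asarray(rows, dtype=np.int64)
        r, c = counts.shape
        return cls(
            counts,
            tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(r)),
            tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(c)),
        )

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


@dataclass(frozen=True)
class ExactTestResult:
    """Two-sided exact test result with computation metadata."""

    p_value: float
    method: str
    n_tables: int | None = None  # margin-fixed tables enumerated (exact path)
    replicates: int | None = None
    seed: int | None = None
    std_error: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class ResidualReport:
    """Cell-level adjusted standardized residual post-hoc for a table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame
    p_values: pd.DataFrame
    phi: pd.DataFrame
    n: int


@dataclass(frozen=True)
class AnovaResult:
    group_n: tuple[int, ...]
    group_mean: tuple[float, ...]
    group_sd: tuple[float, ...]
    f_statistic: float | None
    df_between: int
    df_within: int
    p_value: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class DunnettResult:
    """Many-to-one comparisons of treatment groups against one control."""

    comparisons: tuple[str, ...]
    t_statistics: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    std_errors: tuple[float, ...]
    lambdas: tuple[float, ...]  # n_i / (n_i + n_0); corr_ij = sqrt(l_i l_j)
    df: int
    mse: float
    method: str
    replicates: int
    seed: int


def _log_point_prob_const(row_totals: np.ndarray, col_totals: np.ndarray) -> float:
    n = row_totals.sum()
    return float(
        gammaln(row_totals + 1).sum() + gammaln(col_totals + 1).sum() - lgamma(n + 1)
    )


def _log_point_prob(counts: np.ndarray, const: float) -> float:
    return const - float(gammaln(counts + 1.0).sum())


def _count_tables(row_totals: np.ndarray, col_totals: np.ndarray, cap: int) -> int:
    """Count margin-fixed tables by bounded recursion; returns cap+1 if over."""
    r = len(row_totals)

    def rec(i: int, colrem: tuple[int, ...], budget: int) -> int:
        if i == r - 1:
            return 1 if sum(colrem) == row_totals[-1] else 0
        total = 0

        def fill(j: int, rowrem: int, crem: list[int]) -> int:
            nonlocal total
            if total > budget:
                return total
            if j == len(crem) - 1:
                if 0 <= rowrem <= crem[j]:
                    nxt = list(crem)
                    nxt[j] -= rowrem
                    total += rec(i + 1, tuple(nxt), budget - total)
                return total
            lo = max(0, rowrem - sum(crem[j + 1 :]))
            hi = min(rowrem, crem[j])
            for v in range(lo, hi + 1):
                nxt = list(crem)
                nxt[j] -= v
                fill(j + 1, rowrem - v, nxt)
                if total > budget:
                    return total
            return total

        return fill(0, int(row_totals[i]), list(colrem))

    return rec(0, tuple(int(c) for c in col_totals), cap)


def _enumerate_log_probs(
    row_totals: np.ndarray, col_totals: np.ndarray, const: float
) -> np.ndarray:
    """Log point probability of every margin-fixed table (recursive fill)."""
    r, c = len(row_totals), len(col_totals)
    out: list[float] = []
    lg = gammaln(np.arange(int(row_totals.sum()) + 2, dtype=float))

    def rec(i: int, colrem: list[int], acc_lg: float) -> None:
        if i == r - 1:
            if all(v >= 0 for v in colrem) and sum(colrem) == row_totals[-1]:
                out.append(const - acc_lg - sum(lg[v + 1] for v in colrem))
            return

        def fill(j: int, rowrem: int, crem: list[int], acc: float) -> None:
            if j == c - 1:
                if 0 <= rowrem <= crem[j]:
                    nxt = list(crem)
                    nxt[j] -= rowrem
                    rec(i + 1, nxt, acc + lg[rowrem + 1])
                return
            lo = max(0, rowrem - sum(crem[j + 1 :]))
            hi = min(rowrem, crem[j])
            for v in range(lo, hi + 1):
                nxt = list(crem)
                nxt[j] -= v
                fill(j + 1, rowrem - v, nxt, acc + lg[v + 1])

        fill(0, int(row_totals[i]), colrem, acc_lg)

    rec(0, [int(v) for v in col_totals], 0.0)
    return np.asarray(out)


def fisher_exact_2x2(table: ContingencyTable) -> ExactTestResult:
    """Two-sided Fisher's exact test for a 2x2 table (point-probability rule).

    The p-value is the sum of hypergeometric probabilities of every 2x2 table
    with the observed margins whose point probability does not exceed that of
    the observed table.  Computation is exact in log space.  A table with any
    zero margin is degenerate and returns p = 1 with a flag.
    """
    if table.counts.shape != (2, 2):
        raise ValueError(f"fisher_exact_2x2 needs a 2x2 table, got {table.counts.shape}")
    rt, ct = table.row_totals, table.col_totals
    if (rt == 0).any() or (ct == 0).any():
        return ExactTestResult(1.0, FULL_ENUMERATION, n_tables=1, degenerate=True)
    const = _log_point_prob_const(rt, ct)
    lp_obs = _log_point_prob(table.counts, const)
    lo = max(0, int(rt[0] - ct[1]))
    hi = min(int(rt[0]), int(ct[0]))
    a = np.arange(lo, hi + 1)
    cells = np.stack([a, rt[0] - a, ct[0] - a, rt[1] - ct[0] + a], axis=1)
    log_probs = const - gammaln(cells + 1.0).sum(axis=1)
    p = float(np.exp(log_probs[log_probs <= lp_obs + _LOG_TIE_TOL]).sum())
    return ExactTestResult(min(p, 1.0), FULL_ENUMERATION, n_tables=len(a))


def freeman_halton_exact(
    table: ContingencyTable,
    max_enumeration: int = _DEFAULT_MAX_ENUMERATION,
    mc_replicates: int = _DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> ExactTestResult:
    """Fisher-Freeman-Halton exact test for an r x c table.

    When the number of margin-fixed tables is at most ``max_enumeration`` the
    test is computed by full enumeration; otherwise the p-value is estimated
    by Monte Carlo sampling of margin-fixed tables (random pairing of row and
    column category labels, equivalent to sequential conditional
    hypergeometric filling), using the add-one estimator
    ``(1 + hits) / (1 + replicates)`` with its standard error.
    """
    if mc_replicates < 1000:
        raise ValueError(f"mc_replicates must be >= 1000, got {mc_replicates}")
    rt, ct = table.row_totals, table.col_totals
    keep_r, keep_c = rt > 0, ct > 0
    if (~keep_r).any() or (~keep_c).any():
        # Empty rows/columns carry no information; drop them for the test.
        sub = ContingencyTable(
            table.counts[np.ix_(keep_r, keep_c)],
            tuple(np.array(table.row_labels)[keep_r]),
            tuple(np.array(table.col_labels)[keep_c]),
        ) if keep_r.sum() >= 2 and keep_c.sum() >= 2 else None
        if sub is None:
            return ExactTestResult(1.0, FULL_ENUMERATION, n_tables=1, degenerate=True)
        return freeman_halton_exact(sub, max_enumeration, mc_replicates, seed)
    const = _log_point_prob_const(rt, ct)
    lp_obs = _log_point_prob(table.counts, const)
    n_tables = _count_tables(rt, ct, max_enumeration)
    if n_tables <= max_enumeration:
        log_probs = _enumerate_log_probs(rt, ct, const)
        p = float(np.exp(log_probs[log_probs <= lp_obs + _LOG_TIE_TOL]).sum())
        return ExactTestResult(min(p, 1.0), FULL_ENUMERATION, n_tables=int(n_tables))
    rng = np.random.default_rng(seed)
    r, c = table.counts.shape
    row_vec = np.repeat(np.arange(r, dtype=np.int32), rt)
    col_vec = np.repeat(np.arange(c, dtype=np.int32), ct)
    n = len(row_vec)
    hits = 0
    chunk = max(1, min(20_000, mc_replicates))
    done = 0
    while done < mc_replicates:
        b = min(chunk, mc_replicates - done)
        perm = rng.permuted(np.tile(row_vec, (b, 1)), axis=1)
        idx = perm * c + col_vec[None, :]
        offset = (np.arange(b, dtype=np.int64) * (r * c))[:, None]
        counts = np.bincount((idx + offset).ravel(), minlength=b * r * c).reshape(b, r * c)
        lp = const - gammaln(counts + 1.0).sum(axis=1)
        hits += int((lp <= lp_obs + _LOG_TIE_TOL).sum())
        done += b
    p_hat = (1 + hits) / (1 + mc_replicates)
    se = sqrt(p_hat * (1 - p_hat) / mc_replicates)
    return ExactTestResult(
        p_hat, MONTE_CARLO, replicates=mc_replicates, seed=seed, std_error=se
    )


def adjusted_residuals(table: ContingencyTable) -> ResidualReport:
    """Adjusted standardized residuals with normal p-values and phi per cell.

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - row_i/N)(1 - col_j/N)) with
    E_ij = row_i * col_j / N; each residual is approximately standard normal
    under independence.  phi_ij = r_ij / sqrt(N).  Cells in zero-total rows
    or columns are undefined (NaN).
    """
    O = table.counts.astype(float)
    n = table.total
    rt = table.row_totals.astype(float)
    ct = table.col_totals.astype(float)
    E = np.outer(rt, ct) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(E * (1 - rt[:, None] / n) * (1 - ct[None, :] / n))
        resid = np.where(denom > 0, (O - E) / denom, np.nan)
    pvals = 2 * sps.norm.sf(np.abs(resid))
    phi = resid / sqrt(n)
    idx, cols = list(table.row_labels), list(table.col_labels)
    return ResidualReport(
        observed=pd.DataFrame(O, index=idx, columns=cols),
        expected=pd.DataFrame(E, index=idx, columns=cols),
        residuals=pd.DataFrame(resid, index=idx, columns=cols),
        p_values=pd.DataFrame(pvals, index=idx, columns=cols),
        phi=pd.DataFrame(phi, index=idx, columns=cols),
        n=n,
    )


def anova_oneway_summary(
    n: Sequence[int], mean: Sequence[float], sd: Sequence[float]
) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    SSB = sum n_i (m_i - grand_mean)^2, SSW = sum (n_i - 1) s_i^2,
    F = (SSB / (k-1)) / (SSW / (N-k)).  If every group has zero variance and
    the means coincide, the test is degenerate (flagged; p undefined).
    """
    n = [int(v) for v in n]
    if not (len(n) == len(mean) == len(sd)):
        raise ValueError("n, mean and sd must have equal length")
    if len(n) < 2:
        raise ValueError("need at least two groups")
    if any(v < 2 for v in n):
        raise ValueError("each group needs n >= 2")
    if any(s < 0 for s in sd):
        raise ValueError("standard deviations must be non-negative")
    n_arr = np.asarray(n, dtype=float)
    m_arr = np.asarray(mean, dtype=float)
    s_arr = np.asarray(sd, dtype=float)
    total = n_arr.sum()
    k = len(n)
    grand = float((n_arr * m_arr).sum() / total)
    ssb = float((n_arr * (m_arr - grand) ** 2).sum())
    ssw = float(((n_arr - 1) * s_arr**2).sum())
    df_b, df_w = k - 1, int(total) - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(
                tuple(n), tuple(map(float, mean)), tuple(map(float, sd)),
                None, df_b, df_w, None, degenerate=True,
            )
        f = float("inf")
        p = 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        tuple(n), tuple(map(float, mean)), tuple(map(float, sd)), f, df_b, df_w, p
    )


def summarize_groups(
    groups: Sequence[Sequence[float]],
) -> tuple[list[int], list[float], list[float]]:
    """Per-group (n, mean, sample sd) summaries of raw observations."""
    n = [len(g) for g in groups]
    if any(v < 2 for v in n):
        raise ValueError("each group needs n >= 2")
    means = [float(np.mean(g)) for g in groups]
    sds = [float(np.std(g, ddof=1)) for g in groups]
    return n, means, sds


def anova_oneway_raw(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from raw observations (reduces to the summary form)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n, means, sds = summarize_groups(groups)
    return anova_oneway_summary(n, means, sds)


def _dunnett_null_max_abs_t(
    n_treat: Sequence[int],
    n_control: int,
    df: int,
    replicates: int,
    seed: int,
) -> np.ndarray:
    """Monte Carlo sample of max_j |T_j| under the joint Dunnett null.

    Shared-control construction: group means are independent normals scaled
    by 1/sqrt(n), the pooled variance estimate is a scaled chi-square with
    ``df`` degrees of freedom shared by all comparisons.
    """
    rng = np.random.default_rng(seed)
    k = len(n_treat)
    n_t = np.asarray(n_treat, dtype=float)
    z_t = rng.standard_normal((replicates, k)) / np.sqrt(n_t)
    z_0 = rng.standard_normal((replicates, 1)) / sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, size=(replicates, 1)) / df)
    t = (z_t - z_0) / (s * np.sqrt(1.0 / n_t + 1.0 / n_control))
    return np.abs(t).max(axis=1)


def dunnett_two_tailed(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    mc_replicates: int = _DEFAULT_MC_REPLICATES,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> DunnettResult:
    """Dunnett's two-tailed many-to-one comparison against one control group.

    t_i = (mean_i - mean_0) / sqrt(MSE (1/n_i + 1/n_0)) with MSE pooled over
    all groups (df = N - k).  The family-wise adjusted two-tailed p-value of
    comparison i is P(max_j |T_j| >= |t_i|) under the equicorrelated
    multivariate t null induced by the shared control (corr_ij =
    sqrt(lambda_i lambda_j), lambda_i = n_i/(n_i + n_0)), estimated by Monte
    Carlo with the add-one estimator.
    """
    if mc_replicates < 100_000:
        raise ValueError(f"mc_replicates must be >= 100000, got {mc_replicates}")
    if len(groups) < 2:
        raise ValueError("need a control and at least one treatment group")
    if not 0 <= control_index < len(groups):
        raise ValueError(f"control_index {control_index} out of range")
    n_all, means, _ = summarize_groups(groups)
    if n_all[control_index] < 2:
        raise ValueError("control group needs n >= 2")
    big_n, k = sum(n_all), len(groups)
    df = big_n - k
    sse = sum(
        float(np.sum((np.asarray(g, dtype=float) - m) ** 2)) for g, m in zip(groups, means)
    )
    mse = sse / df
    if mse == 0.0:
        raise ValueError("zero pooled variance: Dunnett statistics undefined")
    treat_idx = [i for i in range(k) if i != control_index]
    n0, m0 = n_all[control_index], means[control_index]
    t_stats = [
        (means[i] - m0) / sqrt(mse * (1.0 / n_all[i] + 1.0 / n0)) for i in treat_idx
    ]
    lambdas = [n_all[i] / (n_all[i] + n0) for i in treat_idx]
    max_abs = _dunnett_null_max_abs_t(
        [n_all[i] for i in treat_idx], n0, df, mc_replicates, seed
    )
    p_adj, ses = [], []
    for t in t_stats:
        hits = int((max_abs >= abs(t)).sum())
        p = (1 + hits) / (1 + mc_replicates)
        p_adj.append(p)
        ses.append(sqrt(p * (1 - p) / mc_replicates))
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    return DunnettResult(
        comparisons=tuple(labels[i] for i in treat_idx),
        t_statistics=tuple(t_stats),
        p_adjusted=tuple(p_adj),
        std_errors=tuple(ses),
        lambdas=tuple(lambdas),
        df=df,
        mse=mse,
        method=MONTE_CARLO,
        replicates=mc_replicates,
        seed=seed,
    )


def bonferroni_adjust(pvalues: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: min(1, p * m) for each p.

    ``m`` is the number of tests in the family and must be at least the
    number of p-values supplied.
    """
    pvalues = list(pvalues)
    if m < len(pvalues):
        raise ValueError(f"m={m} smaller than number of p-values ({len(pvalues)})")
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in pvalues]
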