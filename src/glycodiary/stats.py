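"""Matched-pair statistical protocol.

Continuous variables are routed by a Kolmogorov-Smirnov normality check
(estimated mean and SD; note this is anticonservative in the Lilliefors
sense, see the methods note) to either a paired t-test or the Wilcoxon
signed-rank test; food-group intakes always take the signed-rank route.
Categorical variables use Pearson's chi-square without continuity
correction. P <= alpha (default 0.05, inclusive) is flagged significant.

The signed-rank test is implemented here rather than delegated: zero
differences are dropped, ties receive mid-ranks, and the null distribution
is exact for n <= 25 non-zero differences (computed over doubled ranks by a
polynomial convolution, equivalent to enumerating all 2^n sign
assignments), with a tie-corrected normal approximation above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsConfig
from .errors import DegenerateDataError

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str                 # paired_t | wilcoxon | chi_square
    n_pairs: int
    statistic: float
    p_value: float
    route_reason: str         # normal | non-normal | categorical | forced
    t2dm_summary: str = ""
    nd_summary: str = ""
    family: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def route(values: np.ndarray, alpha: float = 0.05) -> tuple[str, str]:
    """Choose the paired test for a continuous variable.

    A KS test of the pooled values against a normal with the sample mean and
    SD; p > alpha routes to the paired t-test, otherwise to the signed-rank
    test. Constant variables route to the signed-rank test with a warning.

    Returns (test, reason).
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 3:
        raise DegenerateDataError(f"normality routing needs >= 3 values, got {len(values)}")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("constant variable routed to the signed-rank test", stacklevel=2)
        return "wilcoxon", "non-normal"
    p = sps.kstest(values, "norm", args=(values.mean(), sd)).pvalue
    if p > alpha:
        return "paired_t", "normal"
    return "wilcoxon", "non-normal"


def _signed_rank_p_exact(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank statistic over doubled ranks.

    ``ranks2`` are 2x the mid-ranks (integers); ``w2`` is 2x the observed
    positive-rank sum. The null distribution of W+ over all equiprobable
    sign assignments is built by convolution; p = 2 min(P(W<=w), P(W>=w)),
    capped at 1.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assign = counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum() / n_assign
    p_ge = counts[w2i:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None
) -> tuple[float, float, bool]:
    """Wilcoxon signed-rank test on paired samples (or differences).

    Returns (W+ statistic, two-sided p, degenerate flag). All-zero
    differences give the degenerate result (0, 1.0, True).
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, True
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _signed_rank_p_exact(np.round(2 * ranks), 2 * w_plus)
        return w_plus, p, False
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0, True
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, min(1.0, p), False


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; raises on zero variance of the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise DegenerateDataError("paired t-test needs >= 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise DegenerateDataError("paired t-test: zero variance of differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def chi_square(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square on an r x c contingency table (no continuity
    correction). Warns when any expected count is below 5.

    Returns (statistic, p, dof).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise DegenerateDataError("contingency table must be 2-D with counts >= 0")
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    table = table[np.ix_(rows, cols)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateDataError("degenerate contingency table margin")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square: expected count below 5", stacklevel=2)
    return float(stat), float(p), int(dof)


def _summ_mean_sd(v: np.ndarray) -> str:
    return f"{np.mean(v):.2f}+/-{np.std(v, ddof=1):.2f}"


def _summ_median_iqr(v: np.ndarray) -> str:
    return f"{np.median(v):.2f} ({np.quantile(v, 0.25):.2f}-{np.quantile(v, 0.75):.2f})"


def compare_paired(
    variable: str,
    t2dm: np.ndarray,
    nd: np.ndarray,
    family: str = "",
    config: StatsConfig | None = None,
    force_wilcoxon: bool = False,
) -> ComparisonResult:
    """Route and run the paired comparison for one variable.

    ``t2dm`` and ``nd`` are pair-aligned vectors; pairs with a missing value
    in either member are dropped (pairwise deletion).
    """
    config = config or StatsConfig()
    t2dm = np.asarray(t2dm, dtype=float)
    nd = np.asarray(nd, dtype=float)
    ok = ~(np.isnan(t2dm) | np.isnan(nd))
    t2dm, nd = t2dm[ok], nd[ok]
    if len(t2dm) == 0:
        raise DegenerateDataError(f"{variable}: no complete pairs")

    if force_wilcoxon:
        test, reason = "wilcoxon", "forced"
    else:
        pooled = np.concatenate([t2dm, nd]) if config.ks_scope == "pooled" else None
        if pooled is not None:
            test, reason = route(pooled, config.routing_alpha)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t1, _ = route(t2dm, config.routing_alpha)
                t2, _ = route(nd, config.routing_alpha)
            test = "paired_t" if t1 == t2 == "paired_t" else "wilcoxon"
            reason = "normal" if test == "paired_t" else "non-normal"

    degenerate = False
    if test == "paired_t":
        try:
            stat, p = paired_t(t2dm, nd)
        except DegenerateDataError:
            stat, p, degenerate = 0.0, 1.0, True
        t2dm_summary, nd_summary = _summ_mean_sd(t2dm), _summ_mean_sd(nd)
    else:
        stat, p, degenerate = wilcoxon_signed_rank(t2dm, nd)
        t2dm_summary, nd_summary = _summ_median_iqr(t2dm), _summ_median_iqr(nd)

    return ComparisonResult(
        variable=variable, test=test, n_pairs=int(len(t2dm)), statistic=stat,
        p_value=p, route_reason=reason, t2dm_summary=t2dm_summary,
        nd_summary=nd_summary, family=family, degenerate=degenerate,
    )


def compare_categorical(
    variable: str,
    t2dm_counts: dict[str, int],
    nd_counts: dict[str, int],
    family: str = "demographic",
) -> ComparisonResult:
    """Chi-square comparison of a categorical variable's arm distributions."""
    levels = sorted(set(t2dm_counts) | set(nd_counts))
    table = np.array(
        [[t2dm_counts.get(k, 0) for k in levels], [nd_counts.get(k, 0) for k in levels]]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p, _ = chi_square(table)
    n = int(min(sum(t2dm_counts.values()), sum(nd_counts.values())))
    return ComparisonResult(
        variable=variable, test="chi_square", n_pairs=n, statistic=stat,
        p_value=p, route_reason="categorical",
        t2dm_summary=str(dict(zip(levels, table[0].tolist()))),
        nd_summary=str(dict(zip(levels, table[1].tolist()))),
        family=family,
    )


def paired_frame(
    values: pd.DataFrame,
    profiles: pd.DataFrame,
    column: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair-align one per-participant column into (t2dm, nd) vectors.

    ``values`` must have a participant_id column. Pairs missing the value in
    either member are dropped by the comparison itself (emitted as NaN).
    """
    merged = values.merge(
        profiles[["participant_id", "pair_id", "arm"]], on="participant_id", how="right"
    )
    wide = merged.pivot(index="pair_id", columns="arm", values=column)
    if "T2DM" not in wide.columns or "ND" not in wide.columns:
        raise DegenerateDataError(f"{column}: both arms required for pairing")
    return wide["T2DM"].to_numpy(dtype=float), wide["ND"].to_numpy(dtype=float)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (reported alongside, never used for the primary flags)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def results_frame(results: list[ComparisonResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tabulate comparison results with BH column and significance flags."""
    df = pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "family": [r.family for r in results],
            "test": [r.test for r in results],
            "route_reason": [r.route_reason for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    df["p_bh"] = benjamini_hochberg(df["p_value"].to_numpy()) if len(df) else []
    df["significant"] = df["p_value"] <= alpha
    return df
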