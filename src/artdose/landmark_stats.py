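"""Motion and dose statistics: paired deltas, percentile summaries,
location/scale rank tests, correlations, ECDFs, percentile confidence
intervals and rank-vs-deviation fits.

Conventions (documented once, applied everywhere):

* all p-values are two-sided;
* zeros in the signed-rank test follow the Pratt convention (ranked with
  the rest, then dropped from the statistic); ties get midranks;
* percentiles are order statistics at index ``ceil(q * n)`` of the
  ascending sort, without interpolation — the same convention the DVH
  D_q metrics use;
* percentile confidence intervals default to binomial order-statistic
  inversion; a seeded bootstrap is available as an option;
* no multiple-testing correction is applied by default; Holm adjustment
  sits behind a flag.

Small-sample paths are exact (dynamic programming over the rank
permutation distribution); large samples fall back to the usual normal
approximations with tie corrections.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "delta_abs",
    "percentile_summary",
    "order_statistic_percentile",
    "signed_rank_test",
    "rank_sum_test",
    "scale_test",
    "correlations",
    "ecdf",
    "percentile_with_ci",
    "rank_adaptation_fit",
    "holm_adjust",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int
    estimate: float | None = None
    ci: tuple[float, float] | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# --------------------------------------------------------------------------
# Deviation tables
# --------------------------------------------------------------------------

def delta_abs(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row |inter| - |intra| delta; incomplete pairs dropped and counted."""
    required = {"inter_mm", "intra_mm"}
    if not required <= set(table.columns):
        raise ValueError("table must have inter_mm and intra_mm columns")
    complete = table.dropna(subset=["inter_mm", "intra_mm"]).copy()
    complete["delta_mm"] = complete["inter_mm"].abs() - complete["intra_mm"].abs()
    complete.attrs["n_dropped"] = len(table) - len(complete)
    return complete


def order_statistic_percentile(values: np.ndarray, q: float) -> float:
    """Ascending order statistic at index ceil(q*n); q in (0, 1]."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    k = int(np.ceil(q * v.size))
    return float(v[max(k, 1) - 1])


def percentile_summary(table: pd.DataFrame, q: float = 0.95,
                       columns: tuple[str, ...] = ("inter_mm", "intra_mm"),
                       min_rows: int = 20) -> pd.DataFrame:
    """Per-parameter q-th percentile of |deviation| plus the cross-parameter median.

    Emits a warning note when any parameter has fewer than ``min_rows`` rows.
    """
    if "parameter" not in table.columns:
        raise ValueError("table must carry a 'parameter' column")
    rows = []
    for param, sub in table.groupby("parameter"):
        row: dict = {"parameter": param, "n": len(sub)}
        for col in columns:
            vals = sub[col].dropna().to_numpy()
            if vals.size == 0:
                raise ValueError(f"parameter {param}: empty column {col}")
            row[f"{col}_p{int(q * 100)}"] = order_statistic_percentile(np.abs(vals), q)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("parameter")
    if (out["n"] < min_rows).any():
        out.attrs["warning"] = f"fewer than {min_rows} rows for some parameter"
    medians = {f"median_{c}": float(out[f"{c}_p{int(q * 100)}"].median())
               for c in columns}
    out.attrs.update(medians)
    return out


# --------------------------------------------------------------------------
# Exact rank-statistic machinery
# --------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _signed_rank_exact_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """Exact P(W <= w) and P(W >= w) for the signed-rank sum over random signs.

    ``ranks2`` are the (doubled, integer) ranks of the nonzero differences;
    ``w2`` the doubled observed positive-rank sum.  The null distribution is
    the generating polynomial product over independent fair signs.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = 0.5 * dist + 0.5 * shifted
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return cdf, sf


def signed_rank_test(x: np.ndarray, y: np.ndarray | None = None,
                     exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Pratt zero handling, midranks for ties.  Exact null for up to
    ``exact_max_n`` nonzero pairs, normal approximation with continuity and
    tie correction above.  Two-sided.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[~np.isnan(d)]
    n_all = d.size
    if n_all == 0:
        raise ValueError("no paired differences")
    ranks = _midranks(np.abs(d))          # Pratt: rank zeros with the rest ...
    nonzero = d != 0
    if not nonzero.any():
        return TestResult("signed_rank", np.nan, np.nan, n_all,
                          estimate=0.0, note="degenerate: all differences zero")
    ranks = ranks[nonzero]                 # ... then drop them from the sums
    signs = np.sign(d[nonzero])
    w_plus = float(ranks[signs > 0].sum())
    n = int(nonzero.sum())
    estimate = float(np.median(d))
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        cdf, sf = _signed_rank_exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult("signed_rank_exact", w_plus, p, n, estimate=estimate)
    mean = ranks.sum() / 2.0
    var = float((ranks ** 2).sum()) / 4.0  # midrank form; equals n(n+1)(2n+1)/24 untied
    cc = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - cc) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult("signed_rank_normal", w_plus, min(1.0, p), n, estimate=estimate)


def _subset_sum_distribution(scores2: np.ndarray, k: int) -> np.ndarray:
    """Counts of k-subsets of ``scores2`` (non-negative ints) by score sum."""
    total = int(scores2.sum())
    table = np.zeros((k + 1, total + 1))
    table[0, 0] = 1.0
    for s in scores2:
        for size in range(min(k, 1_000_000), 0, -1):
            table[size, s:] += table[size - 1, : total + 1 - s]
    return table[k]


def _two_sample_exact_p(scores2: np.ndarray, n_a: int, observed2: int) -> float:
    counts = _subset_sum_distribution(scores2, n_a)
    total = counts.sum()
    cdf = counts[: observed2 + 1].sum() / total
    sf = counts[observed2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def rank_sum_test(a: np.ndarray, b: np.ndarray, exact_max_min_n: int = 10,
                  exact_max_total: int = 30) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) location comparison.

    Exact permutation null (DP over rank subsets, midranks) when the smaller
    sample has at most ``exact_max_min_n`` values and the pooled size at most
    ``exact_max_total``; otherwise normal approximation with tie correction
    and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n_a].sum())
    n = n_a + n_b
    estimate = float(np.median(a) - np.median(b))
    if min(n_a, n_b) <= exact_max_min_n and n <= exact_max_total:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _two_sample_exact_p(ranks2, n_a, int(round(2 * w)))
        return TestResult("rank_sum_exact", w, p, n, estimate=estimate)
    mean = n_a * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    cc = 0.5 * np.sign(w - mean)
    z = (w - mean - cc) / np.sqrt(var)
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return TestResult("rank_sum_normal", w, p, n, estimate=estimate)


def _ansari_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    return np.minimum(ranks, n + 1 - ranks)


def _mood_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    return (ranks - (n + 1) / 2.0) ** 2


def scale_test(a: np.ndarray, b: np.ndarray, method: str = "ansari_bradley",
               center: bool = True, exact_max_total: int = 20) -> TestResult:
    """Two-sided rank dispersion test (Ansari-Bradley or Mood).

    Samples are median-centered first (both tests assume equal locations).
    Ansari-Bradley scores rank distance from the extremes; Mood scores the
    squared deviation of the rank from the mean rank.  Exact permutation
    null for pooled n up to ``exact_max_total``, else a normal approximation
    with the general linear-rank-statistic variance (tie-safe).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per sample")
    if center:
        a = a - np.median(a)
        b = b - np.median(b)
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    ranks = _midranks(pooled)
    if method == "ansari_bradley":
        scores = _ansari_scores(ranks, n)
        scale2 = 2
    elif method == "mood":
        scores = _mood_scores(ranks, n)
        scale2 = 4
    else:
        raise ValueError("method must be 'ansari_bradley' or 'mood'")
    note = None
    _, tie_counts = np.unique(pooled, return_counts=True)
    if (tie_counts > 1).sum() and (tie_counts[tie_counts > 1].sum() / n) > 0.5:
        note = "more than 50% of pooled values are tied"
    statistic = float(scores[:n_a].sum())
    if n <= exact_max_total:
        scores_i = np.round(scale2 * scores).astype(int)
        p = _two_sample_exact_p(scores_i, n_a, int(round(scale2 * statistic)))
        return TestResult(f"{method}_exact", statistic, p, n, note=note)
    mean = n_a * scores.mean()
    var = (n_a * (n - n_a) / (n * (n - 1))) * float(((scores - scores.mean()) ** 2).sum())
    z = (statistic - mean) / np.sqrt(var)
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return TestResult(f"{method}_normal", statistic, p, n, note=note)


# --------------------------------------------------------------------------
# Correlations, ECDF, percentile CI, fits
# --------------------------------------------------------------------------

def correlations(x: np.ndarray, y: np.ndarray, method: str = "pearson",
                 level: float = 0.95) -> TestResult:
    """Pearson or Spearman correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    if method == "spearman":
        x, y = _midranks(x), _midranks(y)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return TestResult(method, r, 0.0, n, estimate=r, ci=(r, r))
    tstat = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(tstat), n - 2))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zq = sps.norm.ppf(0.5 + level / 2)
    ci = (float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se)))
    return TestResult(method, r, p, n, estimate=r, ci=ci)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical distribution function: (sorted unique x, F(x)) step support.

    ``F(x)`` is the fraction of the sample <= x; evaluated at the maximum it
    equals 1.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    xs, counts = np.unique(v, return_counts=True)
    return xs, np.cumsum(counts) / v.size


def percentile_with_ci(values: np.ndarray, q: float = 0.025, level: float = 0.95,
                       method: str = "order_statistic", n_boot: int = 2000,
                       seed: int = 0) -> tuple[float, tuple[float, float], str]:
    """Order-statistic percentile with a confidence interval.

    Default CI by binomial order-statistic inversion (distribution-free);
    ``method='bootstrap'`` uses a seeded percentile bootstrap with
    ``n_boot`` resamples.  Returns (estimate, (lo, hi), note) where the note
    records the CI construction used.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 20:
        raise ValueError("need at least 20 values for a percentile CI")
    note = ""
    if q * n < 1:
        note = "q*n < 1: estimate falls back to the widest (first) order statistic; "
    estimate = order_statistic_percentile(v, q) if q * n >= 1 else float(v[0])
    if method == "order_statistic":
        alpha = 1 - level
        cdf = sps.binom.cdf(np.arange(n + 1), n, q)
        # 1-based order-statistic indices l, u with
        # P(x_(l) <= true quantile <= x_(u)) = cdf[u-1] - cdf[l-1] >= level
        lower_ok = np.nonzero(cdf[:-1] <= alpha / 2)[0]       # cdf[l-1] <= alpha/2
        if lower_ok.size:
            l = int(lower_ok[-1]) + 1
        else:
            l = 1
            note += ("lower CI bound clamped to the sample minimum "
                     "(nominal coverage not attainable at this q and n); ")
        upper_ok = np.nonzero(cdf >= 1 - alpha / 2)[0]        # cdf[u-1] >= 1 - alpha/2
        if upper_ok.size and upper_ok[0] + 1 <= n:
            u = int(upper_ok[0]) + 1
        else:
            u = n
            note += "upper CI bound clamped to the sample maximum; "
        ci = (float(v[l - 1]), float(v[u - 1]))
        note += "CI: binomial order-statistic inversion"
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            reps[i] = order_statistic_percentile(rng.choice(v, size=n, replace=True), q)
        ci = (float(np.quantile(reps, (1 - level) / 2)),
              float(np.quantile(reps, 0.5 + level / 2)))
        note += f"CI: seeded percentile bootstrap (B={n_boot})"
    else:
        raise ValueError("method must be 'order_statistic' or 'bootstrap'")
    return estimate, ci, note


def rank_adaptation_fit(eud_ranks: np.ndarray, deviation_mm: np.ndarray,
                        quadratic: bool = False) -> dict:
    """OLS of EUD rank (scaled to [0, 1]) on a landmark deviation.

    Returns coefficients, r-squared and the overall F-test p-value; with
    ``quadratic=True`` a squared-deviation term is added.  Both the linear
    and quadratic variants are legitimate readings of a 'linear quadratic
    fit'; callers decide which to report.
    """
    r = np.asarray(eud_ranks, dtype=float)
    d = np.asarray(deviation_mm, dtype=float)
    if r.min() < -1e-9 or r.max() > 1 + 1e-9:
        raise ValueError("ranks must be scaled to [0, 1]")
    n = r.size
    cols = [np.ones(n), d]
    if quadratic:
        cols.append(d ** 2)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    fitted = X @ beta
    ss_res = float(((r - fitted) ** 2).sum())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    k = X.shape[1] - 1
    if ss_res <= 1e-14 * max(ss_tot, 1.0):
        p = 0.0
        fstat = np.inf
    else:
        fstat = (r2 / k) / ((1 - r2) / (n - k - 1))
        p = float(sps.f.sf(fstat, k, n - k - 1))
    return {
        "intercept": float(beta[0]),
        "slope": float(beta[1]),
        "quadratic": float(beta[2]) if quadratic else None,
        "r_squared": r2,
        "f_statistic": float(fstat),
        "p_value": p,
        "n": n,
    }


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
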