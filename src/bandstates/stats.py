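"""Nonparametric pre/post statistics for microstate metrics.

The battery mirrors standard practice for within-subject stimulation
studies: Shapiro-Wilk to justify nonparametric testing, Wilcoxon
signed-rank two-tailed tests of pre versus each post session with
Benjamini-Hochberg FDR correction and rank-biserial effect sizes, and
Spearman correlations between baseline and change scores tested against
the mathematical-coupling null rather than zero.

The coupling issue: for a change score ``post - pre`` that contains the
baseline, ``corr(pre, post - pre)`` is negative even when pre and post are
unrelated beyond their shared test-retest coupling.  Under the null of no
true baseline-dependence with equal variances, its expected value is
``r0 = -sqrt((1 - rho) / 2)`` where ``rho = corr(pre, post)``; the observed
correlation is therefore compared to ``r0`` by a Fisher-z test instead of
to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "rank_biserial",
    "interpret_rb",
    "fdr_bh",
    "spearman",
    "CouplingTestResult",
    "coupling_null_test",
    "run_statistics",
]


def shapiro_wilk(x: np.ndarray) -> float:
    """Shapiro-Wilk normality p-value (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=np.float64)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined")
    return float(sps.shapiro(x).pvalue)


def _signed_midranks(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |diff| and their signs, zero differences dropped."""
    diff = diff[diff != 0]
    if len(diff) == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(diff))
    return ranks, np.sign(diff)


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed exact p for the signed-rank statistic via DP over 2^n signs.

    Mid-ranks are doubled to integers so ties are handled exactly; the
    distribution of ``2*W+`` over all sign assignments is built by dynamic
    programming in O(n * total).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         exact_max_n: int = 25) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test of paired samples.

    Zero differences are dropped (Wilcoxon's rule) and ties get mid-ranks.
    For ``n <= exact_max_n`` the p-value comes from the exact distribution
    over all 2^n sign assignments (computed by dynamic programming, so
    ties are exact too); larger samples use the normal approximation with
    tie correction.  Returns ``(p, W+)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = y - x
    ranks, signs = _signed_midranks(diff)
    w_plus = float(ranks[signs > 0].sum())
    n = len(ranks)
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4
        tie_counts = np.unique(ranks, return_counts=True)[1]
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - \
            ((tie_counts**3 - tie_counts).sum()) / 48
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2 * sps.norm.sf(abs(z)))
    return p, w_plus


def rank_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation (Kerby simple difference).

    ``rb = (favorable - unfavorable rank sum) / total rank sum`` over the
    nonzero differences, signed by the direction of ``y - x``.
    """
    diff = np.asarray(y, dtype=np.float64) - np.asarray(x, dtype=np.float64)
    ranks, signs = _signed_midranks(diff)
    total = ranks.sum()
    return float((ranks[signs > 0].sum() - ranks[signs < 0].sum()) / total)


def interpret_rb(rb: float) -> str:
    """Effect-size band for |rb|: small < 0.10 <= medium < 0.37 <= high."""
    a = abs(rb)
    if a < 0.10:
        return "small"
    if a < 0.37:
        return "medium"
    return "high"


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with p-value; exact by permutation for
    small n, t-approximation otherwise.  Returns ``(rho, p)``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    n = len(x)
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        import itertools

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = float(rx_c @ ry_c / denom)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rx_c[list(perm)] @ ry_c / denom)
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def _fisher_z(r: float) -> float:
    r = np.clip(r, -0.999999, 0.999999)
    return float(np.arctanh(r))


@dataclass
class CouplingTestResult:
    """Baseline-vs-change correlation tested against the coupling null."""

    r_pre_change: float
    r_pre_post: float
    null_value: float
    p_adjusted: float
    p_naive: float
    n: int


def coupling_null_test(pre: np.ndarray, post: np.ndarray) -> CouplingTestResult:
    """Test ``corr(pre, post - pre)`` against its coupling-expected value.

    The null hypothesis is pure mathematical coupling / regression to the
    mean: with test-retest correlation ``rho = corr(pre, post)`` and no
    true baseline-dependence of change (equal variances under the null),
    the expected baseline-change correlation is ``r0 = -sqrt((1-rho)/2)``.
    The observed Spearman ``corr(pre, post - pre)`` is compared with
    ``r0`` via a Fisher-z test with SE ``1/sqrt(n-3)``.  ``p_naive`` tests
    the same correlation against zero for comparison.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape or len(pre) < 5:
        raise ValueError("need paired samples with n >= 5")
    change = post - pre
    if np.ptp(pre) == 0 or np.ptp(change) == 0 or np.ptp(post) == 0:
        raise ValueError("zero variance in pre, post, or change")
    n = len(pre)
    r_pre_change, p_naive = spearman(pre, change)
    r_pre_post, _ = spearman(pre, post)
    r0 = -np.sqrt(max(0.0, (1.0 - r_pre_post) / 2.0))
    z = (_fisher_z(r_pre_change) - _fisher_z(r0)) * np.sqrt(n - 3)
    p_adj = float(2 * sps.norm.sf(abs(z)))
    return CouplingTestResult(
        r_pre_change=r_pre_change,
        r_pre_post=r_pre_post,
        null_value=float(r0),
        p_adjusted=p_adj,
        p_naive=p_naive,
        n=n,
    )


def run_statistics(
    metrics: pd.DataFrame,
    parameters: tuple[str, ...] = ("mean_duration", "occurrence"),
    q: float = 0.05,
    coupling_cells: list[dict] | None = None,
    pre_session: str = "pre",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full pre-versus-post statistical battery on a metrics table.

    For every (condition, band, parameter, state) the pre session is
    compared with each post session by a two-tailed Wilcoxon signed-rank
    test on the paired subject values (subjects missing either session are
    dropped from that contrast); rank-biserial effect sizes and per-session
    mean +/- SD are reported, and Benjamini-Hochberg FDR is applied within
    each (condition, band, parameter) family.  Only within-condition
    contrasts are computed.

    ``coupling_cells`` optionally lists cells (dicts with condition, band,
    state, parameter) for which baseline-versus-change Spearman
    correlations are tested against the coupling-corrected null, one test
    per post session.  Returns ``(comparisons, coupling_results)``.
    """
    required = {"subject", "condition", "session", "band", "state"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    sessions = [s for s in metrics["session"].unique() if s != pre_session]

    rows = []
    for (cond, band, state), cell in metrics.groupby(["condition", "band", "state"]):
        by_sess = {s: g.set_index("subject") for s, g in cell.groupby("session")}
        if pre_session not in by_sess:
            continue
        for param in parameters:
            for sess in sessions:
                if sess not in by_sess:
                    continue
                pre_g, post_g = by_sess[pre_session], by_sess[sess]
                common = pre_g.index.intersection(post_g.index)
                pre_v = pre_g.loc[common, param].to_numpy()
                post_v = post_g.loc[common, param].to_numpy()
                ok = np.isfinite(pre_v) & np.isfinite(post_v)
                pre_v, post_v = pre_v[ok], post_v[ok]
                if len(pre_v) < 5 or np.all(post_v == pre_v):
                    continue
                p, _w = wilcoxon_signed_rank(pre_v, post_v)
                rb = rank_biserial(pre_v, post_v)
                rows.append({
                    "condition": cond, "band": band, "state": state,
                    "parameter": param,
                    "contrast": f"{pre_session} vs {sess}",
                    "session": sess, "n": len(pre_v), "p": p, "rb": rb,
                    "rb_band": interpret_rb(rb),
                    "direction": "increase" if rb > 0 else "decrease",
                    "mean_pre": pre_v.mean(), "sd_pre": pre_v.std(ddof=1),
                    "mean_post": post_v.mean(), "sd_post": post_v.std(ddof=1),
                })
    comparisons = pd.DataFrame(rows)
    if not comparisons.empty:
        comparisons["p_fdr"] = np.nan
        comparisons["significant"] = False
        for _, idx in comparisons.groupby(
                ["condition", "band", "parameter"]).groups.items():
            p_adj, reject = fdr_bh(comparisons.loc[idx, "p"].to_numpy(), q=q)
            comparisons.loc[idx, "p_fdr"] = p_adj
            comparisons.loc[idx, "significant"] = reject

    coup_rows = []
    for cell_spec in coupling_cells or []:
        sel = metrics[
            (metrics["condition"] == cell_spec["condition"])
            & (metrics["band"] == cell_spec["band"])
            & (metrics["state"] == cell_spec["state"])
        ]
        param = cell_spec["parameter"]
        by_sess = {s: g.set_index("subject") for s, g in sel.groupby("session")}
        if pre_session not in by_sess:
            continue
        for sess in sessions:
            if sess not in by_sess:
                continue
            common = by_sess[pre_session].index.intersection(by_sess[sess].index)
            pre_v = by_sess[pre_session].loc[common, param].to_numpy()
            post_v = by_sess[sess].loc[common, param].to_numpy()
            try:
                res = coupling_null_test(pre_v, post_v)
            except ValueError:
                continue
            coup_rows.append({
                "condition": cell_spec["condition"], "band": cell_spec["band"],
                "state": cell_spec["state"], "parameter": param,
                "contrast": f"{pre_session} vs {sess}", "n": res.n,
                "r_pre_change": res.r_pre_change,
                "r_pre_post": res.r_pre_post,
                "null_value": res.null_value,
                "p_adjusted": res.p_adjusted, "p_naive": res.p_naive,
            })
    return comparisons, pd.DataFrame(coup_rows)
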