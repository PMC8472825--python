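"""Single-subject nonparametric inference.

Per subject, condition and baseline, ERD/ERS values are tested against a
zero median with one-sample Wilcoxon signed-rank tests, one per scalp
cluster; the two baselines are compared with paired Wilcoxon tests on the
same event epochs.  Each 7-cluster family is corrected with a step-up
false-coverage-rate adjustment (Benjamini-Hochberg type) and assessed at
alpha = 0.050.  A cluster counts as a significant desynchronization only
when its adjusted p is below alpha AND its median ERD is negative.

Exact p-values (enumeration of the signed-rank / rank-sum null) are used
for small samples without ties; otherwise the normal approximation with tie
and continuity corrections applies.  With epoch counts of at most ~25 per
condition, in-range tie-free cases are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import CLUSTERS, ConfigurationError, InsufficientDataError, PipelineConfig

__all__ = [
    "TestResult",
    "fcr_adjust",
    "one_sample_family",
    "paired_family",
    "rank_sum",
    "simulate_null_family_rate",
    "wilcoxon_one_sample",
    "wilcoxon_paired",
]


@dataclass
class TestResult:
    cluster: str
    statistic: float
    p_raw: float
    p_adjusted: float
    median: float
    iqr: float
    significant: bool


def _iqr(values: np.ndarray, method: str = "linear") -> float:
    q75, q25 = np.percentile(values, [75, 25], method=method)
    return float(q75 - q25)


def wilcoxon_one_sample(values, cfg: PipelineConfig | None = None) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against zero median.

    Zeros are dropped before ranking; the null distribution is exact
    (enumeration over sign assignments) when the post-removal n is at most
    ``cfg.exact_max_n`` and the absolute values are tie-free, otherwise the
    normal approximation with tie and continuity corrections is used.
    All-zero input is degenerate: returns (0.0, 1.0).
    """
    cfg = cfg or PipelineConfig()
    v = np.asarray(values, dtype=float)
    if cfg.zero_policy == "wilcox":
        v = v[v != 0]
    if len(v) == 0:
        return 0.0, 1.0
    if len(v) < 5:
        raise InsufficientDataError(f"signed-rank test needs n >= 5, have {len(v)}")
    tie_free = len(np.unique(np.abs(v))) == len(v)
    method = "exact" if (len(v) <= cfg.exact_max_n and tie_free) else "approx"
    res = sps.wilcoxon(v, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(a, b, cfg: PipelineConfig | None = None) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (signed-rank on a - b).

    Identical samples are degenerate: returns (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    return wilcoxon_one_sample(d, cfg)


def fcr_adjust(p_values, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Step-up adjusted p-values over one family (ascending sort,
    p_(i) * m / i with a running minimum from the top, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ConfigurationError("cannot adjust an empty family")
    cfg = cfg or PipelineConfig()
    return multipletests(p, alpha=cfg.alpha, method="fdr_bh")[1]


def rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for two independent
    groups; exact for min(n) <= 10 without ties, else normal approximation
    with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("rank-sum test needs >= 2 values per group")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cluster families
# ---------------------------------------------------------------------------


def one_sample_family(cluster_values: np.ndarray,
                      cfg: PipelineConfig | None = None) -> list[TestResult]:
    """One-sample tests over the 7 clusters of one (condition, baseline)
    family; ``cluster_values`` is (n_epochs, 7).  Significance requires an
    adjusted p below alpha and a negative median (desynchronization)."""
    cfg = cfg or PipelineConfig()
    arr = np.asarray(cluster_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(CLUSTERS):
        raise ConfigurationError("expected an (n_epochs, 7) cluster array")
    stats_p = [wilcoxon_one_sample(arr[:, c], cfg) for c in range(arr.shape[1])]
    p_adj = fcr_adjust([p for _, p in stats_p], cfg)
    out = []
    for c, cl in enumerate(CLUSTERS):
        med = float(np.median(arr[:, c]))
        out.append(
            TestResult(
                cluster=cl,
                statistic=stats_p[c][0],
                p_raw=stats_p[c][1],
                p_adjusted=float(p_adj[c]),
                median=med,
                iqr=_iqr(arr[:, c], cfg.iqr_method),
                significant=bool(p_adj[c] < cfg.alpha and med < 0),
            )
        )
    return out


def paired_family(values_a: np.ndarray, values_b: np.ndarray,
                  cfg: PipelineConfig | None = None) -> list[TestResult]:
    """Paired tests over the 7 clusters (same event epochs scored against
    the two baselines).  ``significant`` here means a significant
    difference between baselines (no sign requirement); ``median``/``iqr``
    describe the paired differences a - b."""
    cfg = cfg or PipelineConfig()
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != len(CLUSTERS):
        raise ConfigurationError("expected matching (n_epochs, 7) arrays")
    stats_p = [wilcoxon_paired(a[:, c], b[:, c], cfg) for c in range(a.shape[1])]
    p_adj = fcr_adjust([p for _, p in stats_p], cfg)
    out = []
    for c, cl in enumerate(CLUSTERS):
        d = a[:, c] - b[:, c]
        out.append(
            TestResult(
                cluster=cl,
                statistic=stats_p[c][0],
                p_raw=stats_p[c][1],
                p_adjusted=float(p_adj[c]),
                median=float(np.median(d)),
                iqr=_iqr(d, cfg.iqr_method),
                significant=bool(p_adj[c] < cfg.alpha),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo null calibration
# ---------------------------------------------------------------------------


def simulate_null_family_rate(
    n_families: int = 500,
    n_epochs: int = 15,
    cluster_rho: float = 0.5,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
) -> float:
    """Family-wise false-positive rate under the null.

    Simulates zero-median 7-cluster epoch samples with inter-cluster
    correlation ``cluster_rho`` (neighbouring clusters share channels'
    activity in real data), runs the one-sample family with adjustment and
    counts families with any adjusted p below alpha."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_families):
        common = rng.standard_normal((n_epochs, 1))
        indep = rng.standard_normal((n_epochs, len(CLUSTERS)))
        vals = np.sqrt(cluster_rho) * common + np.sqrt(1 - cluster_rho) * indep
        p = [wilcoxon_one_sample(vals[:, c], cfg)[1] for c in range(len(CLUSTERS))]
        if (fcr_adjust(p, cfg) < cfg.alpha).any():
            hits += 1
    return hits / n_families
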