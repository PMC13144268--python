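"""Image-quality metrics and their paired nonparametric statistics.

Per-slice PSNR and SSIM are computed against the long-time reference on
[0, 1] floating images (before any 8-bit quantisation).  Methods are then
compared with the Friedman omnibus test on within-slice ranks, followed by
Dunn z-tests of the reference method against each alternative with Holm
step-down correction — the comparison family is reference-vs-others, not
all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "MetricTable",
    "StatReport",
    "psnr",
    "ssim",
    "summarize",
    "friedman_test",
    "dunn_holm",
    "evaluate_stats",
]


def psnr(reference: np.ndarray, test: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(max_val^2 / MSE), in dB.

    Identical images have zero MSE and return +inf; ``summarize`` excludes
    such rows from means with a warning.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_val**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, max_val: float = 1.0) -> float:
    """Mean structural similarity with the canonical Gaussian window.

    11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, population local
    statistics, averaged over positions where the full window fits.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if min(reference.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            reference,
            test,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=max_val,
            use_sample_covariance=False,
        )
    )


class MetricTable:
    """Tidy per-slice metric rows (slice_id, method_id, psnr, ssim), fully paired."""

    COLUMNS = ["slice_id", "method_id", "psnr", "ssim"]

    def __init__(self, rows, methods=None, reference_method: str = "unet_l4") -> None:
        df = rows[self.COLUMNS].copy() if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows, columns=self.COLUMNS)
        if df.duplicated(["slice_id", "method_id"]).any():
            raise ValueError("every (slice, method) pair must appear exactly once")
        self.df = df.reset_index(drop=True)
        self.methods = list(methods) if methods is not None else list(pd.unique(df["method_id"]))
        self.reference_method = reference_method

    def pivot(self, metric: str) -> pd.DataFrame:
        """slices x methods matrix; raises if any cell is missing (paired design)."""
        wide = self.df.pivot(index="slice_id", columns="method_id", values=metric)
        wide = wide.reindex(columns=self.methods)
        if wide.isna().any().any():
            raise ValueError(f"missing (slice, method) cells for metric {metric!r}")
        return wide

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "MetricTable":
        return cls(pd.read_csv(path), **kw)


@dataclass
class StatReport:
    metric: str
    friedman_statistic: float
    friedman_p: float
    posthoc: list[dict] = field(default_factory=list)  # method_id, z, raw_p, holm_p
    summary: list[dict] = field(default_factory=list)  # method_id, mean, sd, n, n_infinite

    def to_frame(self) -> pd.DataFrame:
        summ = pd.DataFrame(self.summary).set_index("method_id")
        post = pd.DataFrame(self.posthoc).set_index("method_id") if self.posthoc else pd.DataFrame()
        return summ.join(post, how="left")


def summarize(table: MetricTable, metric: str) -> list[dict]:
    """Per-method mean and sample SD (n-1); infinite values excluded and counted."""
    if not len(table.df):
        raise ValueError("empty metric table")
    out = []
    for method in table.methods:
        vals = table.df.loc[table.df["method_id"] == method, metric].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_inf = int(len(vals) - len(finite))
        if n_inf:
            warnings.warn(f"{n_inf} infinite {metric} value(s) excluded for {method}")
        if len(finite) == 0:
            raise ValueError(f"no finite {metric} values for method {method}")
        sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
        out.append(
            {
                "method_id": method,
                "mean": float(np.mean(finite)),
                "sd": sd,
                "n": int(len(finite)),
                "n_infinite": n_inf,
                "sd_defined": len(finite) > 1,
            }
        )
    return out


def _within_slice_ranks(wide: pd.DataFrame) -> np.ndarray:
    data = wide.to_numpy(dtype=float)
    return np.apply_along_axis(stats.rankdata, 1, data)


def friedman_test(table: MetricTable, metric: str) -> tuple[float, float]:
    """Friedman chi-square on within-slice ranks, with tie correction.

    Statistic: (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C), where A is the
    sum of squared ranks and C = n k (k+1)^2 / 4; df = k - 1.
    """
    wide = table.pivot(metric)
    n, k = wide.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 methods and >= 2 slices")
    ranks = _within_slice_ranks(wide)
    rank_sums = ranks.sum(axis=0)
    A = float((ranks**2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    if A == C:  # every slice fully tied across methods
        return 0.0, 1.0
    statistic = (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / (A - C)
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p


def dunn_holm(table: MetricTable, metric: str, reference: str | None = None) -> list[dict]:
    """Dunn z-tests of the reference method vs each other method, Holm-adjusted.

    Pooled-rank formulation (Dunn 1964): all n*k observations are ranked
    together with average ranks for ties; z = (Rbar_ref - Rbar_m) / sqrt(
    (N(N+1)/12 - T) * 2/n ) with tie term T = sum(t^3 - t) / (12 (N-1)).
    Two-sided p-values; Holm step-down over the k-1 comparisons, capped at 1.
    """
    reference = reference or table.reference_method
    wide = table.pivot(metric)
    if reference not in wide.columns:
        raise ValueError(f"reference method {reference!r} not in table")
    n, k = wide.shape
    data = wide.to_numpy(dtype=float)
    pooled = stats.rankdata(data.ravel()).reshape(n, k)
    mean_ranks = pooled.mean(axis=0)
    N = n * k
    _, counts = np.unique(data.ravel(), return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (12.0 * (N - 1))
    var = (N * (N + 1) / 12.0 - tie_term) * (2.0 / n)
    ref_idx = list(wide.columns).index(reference)
    rows = []
    for j, method in enumerate(wide.columns):
        if method == reference:
            continue
        if var <= 0:  # fully degenerate data
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[ref_idx] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"method_id": method, "z": float(z), "raw_p": min(p, 1.0)})
    return _holm(rows)


def _holm(rows: list[dict]) -> list[dict]:
    """Holm step-down adjustment in place; preserves monotonicity, caps at 1."""
    m = len(rows)
    order = np.argsort([r["raw_p"] for r in rows], kind="stable")
    running = 0.0
    for rank, idx in enumerate(order):
        adj = (m - rank) * rows[idx]["raw_p"]
        running = max(running, adj)
        rows[idx]["holm_p"] = min(1.0, running)
    return rows


def evaluate_stats(table: MetricTable, metric: str, reference: str | None = None) -> StatReport:
    """Mean +/- SD summary, Friedman omnibus, and reference-vs-others Dunn-Holm."""
    statistic, p = friedman_test(table, metric)
    return StatReport(
        metric=metric,
        friedman_statistic=statistic,
        friedman_p=p,
        posthoc=dunn_holm(table, metric, reference=reference),
        summary=summarize(table, metric),
    )
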