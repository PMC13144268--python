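"""Reader-agreement statistics for the four-point striatal pattern scale.

Quadratic weighted Cohen's kappa measures chance-corrected agreement with a
gold standard, penalising disagreements by squared category distance on the
fixed 1..4 scale.  Reliability uses the intraclass correlation coefficient
in its two-way random-effects, absolute-agreement, single-measure form,
ICC(2,1) — across sessions for intra-rater and across observers for
inter-rater consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .phantom import ScoreTable

__all__ = [
    "AgreementResult",
    "weighted_kappa",
    "icc_single",
    "intra_rater_report",
    "inter_rater_report",
    "kappa_report",
]

K_CATEGORIES = 4


@dataclass(frozen=True)
class AgreementResult:
    kind: str  # weighted_kappa | icc_intra | icc_inter
    pair: tuple
    value: float
    n_items: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"agreement value {self.value} outside [-1, 1]")
        if self.n_items < 2:
            raise ValueError("need at least 2 items")


def weighted_kappa(scores_a, scores_b) -> float:
    """Quadratic weighted Cohen's kappa on the fixed 4-category ordinal scale.

    Weights w_ij = 1 - (i-j)^2 / (k-1)^2; kappa = (po_w - pe_w)/(1 - pe_w)
    with the expected matrix from marginal products.  All four categories
    are retained even if unobserved, so values are comparable across
    methods.  If both raters are constant and identical (pe_w = 1), kappa
    is defined as 1.
    """
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score lists must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired scores")
    if np.any((a < 1) | (a > 4) | (b < 1) | (b > 4)):
        raise ValueError("scores must be integers in 1..4")
    k = K_CATEGORIES
    obs = np.zeros((k, k), dtype=float)
    np.add.at(obs, (a - 1, b - 1), 1.0)
    obs /= obs.sum()
    idx = np.arange(k, dtype=float)
    w = 1.0 - (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    po = float((w * obs).sum())
    pe = float((w * expected).sum())
    if abs(1.0 - pe) < 1e-15:
        return 1.0  # both raters constant and equal: perfect (degenerate) agreement
    return (po - pe) / (1.0 - pe)


def icc_single(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an items x raters grid with no missing cells.
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an items x raters grid with >= 2 of each")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not allowed")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0.0:
        raise ValueError("zero total variance: ICC undefined for constant ratings")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def _pivot_scores(df: pd.DataFrame, index_cols, column_col, value_col="score") -> pd.DataFrame:
    wide = df.pivot_table(index=index_cols, columns=column_col, values=value_col, aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("raters/sessions do not cover a common item set")
    return wide


def intra_rater_report(scores: ScoreTable, method: str) -> list[AgreementResult]:
    """Per-reader ICC(2,1) between sessions 1 and 2 for one method."""
    df = scores.df[scores.df["method_id"] == method]
    if set(df["session"].unique()) != {1, 2}:
        raise ValueError(f"both sessions required for method {method!r}")
    results = []
    for reader, sub in df.groupby("reader_id", sort=True):
        wide = _pivot_scores(sub, ["case_id", "hemisphere"], "session")
        results.append(
            AgreementResult(
                kind="icc_intra",
                pair=(reader,),
                value=icc_single(wide.to_numpy()),
                n_items=len(wide),
            )
        )
    return results


def inter_rater_report(scores: ScoreTable, session: int = 1) -> list[AgreementResult]:
    """Pairwise reader ICC(2,1) pooling all methods' scores, plus their mean."""
    df = scores.df[scores.df["session"] == session]
    readers = sorted(df["reader_id"].unique())
    if len(readers) < 2:
        raise ValueError("need at least 2 readers")
    wide = _pivot_scores(df, ["case_id", "hemisphere", "method_id"], "reader_id")
    results = []
    for r1, r2 in combinations(readers, 2):
        results.append(
            AgreementResult(
                kind="icc_inter",
                pair=(r1, r2),
                value=icc_single(wide[[r1, r2]].to_numpy()),
                n_items=len(wide),
            )
        )
    mean_icc = float(np.mean([r.value for r in results]))
    results.append(
        AgreementResult(kind="icc_inter", pair=("average",), value=mean_icc, n_items=len(wide))
    )
    return results


def kappa_report(scores: ScoreTable, gold: ScoreTable, session: int = 1) -> pd.DataFrame:
    """Quadratic weighted kappa vs the gold standard, per reader per method.

    Returns a readers x methods frame with an 'average' row (arithmetic mean
    of the reader kappas per method).  The gold table must cover every
    (case, hemisphere) item that appears in ``scores``.
    """
    df = scores.df[scores.df["session"] == session]
    gold_map = gold.df.set_index(["case_id", "hemisphere"])["score"]
    if gold_map.index.duplicated().any():
        raise ValueError("gold standard has duplicate (case, hemisphere) items")
    items = set(map(tuple, df[["case_id", "hemisphere"]].drop_duplicates().to_numpy()))
    missing = items - set(gold_map.index)
    if missing:
        raise ValueError(f"items missing from gold standard: {sorted(missing)[:5]} ...")
    rows = {}
    for (reader, method), sub in df.groupby(["reader_id", "method_id"], sort=True):
        keys = list(zip(sub["case_id"], sub["hemisphere"]))
        rows.setdefault(reader, {})[method] = weighted_kappa(
            sub["score"].to_numpy(), gold_map.loc[keys].to_numpy()
        )
    table = pd.DataFrame(rows).T.sort_index()
    table.loc["average"] = table.mean(axis=0)
    table.index.name = "reader_id"
    return table
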