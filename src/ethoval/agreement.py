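"""Agreement statistics between sensor output and a gold standard.

At 1-min resolution the comparison is categorical: sensitivity (SE),
specificity (SP), balanced accuracy AC = (SE + SP)/2, prevalence
(TP + FN)/N, and the positive predictive value computed from SE, SP and
prevalence,

    PPV = SE * prev / (SE * prev + (1 - SP) * (1 - prev)),

which is algebraically identical to TP/(TP + FP) when all three inputs come
from the same confusion matrix. Lin's concordance correlation coefficient
(CCC) and Spearman's r_S are additionally computed on the 0/1 labels.
At 10-min resolution the comparison is numeric (minutes of behavior per
window): R², RMSE, CCC, r_S.

Undefined statistics (empty truth class, constant series, degenerate kappa
marginals) are reported as NaN, never coerced to zero, so degenerate strata
stay visible. All statistics use pairwise-complete rows only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .series import MergedDataset

__all__ = [
    "ConfusionCounts",
    "AgreementMetrics",
    "confusion",
    "se_sp_ac",
    "prevalence",
    "ppv",
    "lin_ccc",
    "spearman",
    "r_squared",
    "rmse",
    "cohen_kappa",
    "evaluate",
    "format_report",
]


class InsufficientDataError(ValueError):
    """Raised when no overlapping rows exist for a comparison."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """Four-way tally of aligned binary arrays; gold defines the truth axis."""
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape:
        raise ValueError("pred and gold must be aligned")
    ok = ~(np.isnan(pred) | np.isnan(gold))
    p, g = pred[ok].astype(bool), gold[ok].astype(bool)
    if p.size == 0:
        raise InsufficientDataError("no overlapping rows")
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def se_sp_ac(counts_or_se, sp: float | None = None) -> tuple[float, float, float]:
    """(SE, SP, AC) from a confusion matrix, or AC from given SE/SP fractions.

    ``se_sp_ac(counts)`` computes SE = TP/(TP+FN), SP = TN/(FP+TN) and their
    mean; ``se_sp_ac(se, sp)`` just returns the balanced accuracy triple for
    already-known fractions. An empty truth class yields NaN, not 0.
    """
    if sp is None:
        c: ConfusionCounts = counts_or_se
        se = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else math.nan
        sp = c.tn / (c.fp + c.tn) if c.fp + c.tn > 0 else math.nan
    else:
        se = float(counts_or_se)
    ac = (se + sp) / 2.0
    return se, sp, ac


def prevalence(counts: ConfusionCounts) -> float:
    """(TP + FN) / N — the gold-standard positive fraction."""
    if counts.n == 0:
        return math.nan
    return (counts.tp + counts.fn) / counts.n


def ppv(se: float, sp: float, prev: float) -> float:
    """Positive predictive value from SE, SP and prevalence.

    Equals TP/(TP+FP) exactly when the three inputs derive from one
    confusion matrix. Undefined (NaN) when the denominator vanishes.
    """
    for v in (se, sp, prev):
        if not math.isnan(v) and not 0 <= v <= 1:
            raise ValueError("SE, SP and prevalence must lie in [0, 1]")
    denom = se * prev + (1 - sp) * (1 - prev)
    if denom <= 0 or math.isnan(denom):
        return math.nan
    return se * prev / denom


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
    (1/N) moments. Penalizes deviation from the 45° line, so
    |CCC| <= |Pearson r|; CCC = 1 only for identical series. NaN when both
    series are constant at the same value's variance scale (undefined).
    """
    x, y = _pair(x, y)
    if x.size < 2:
        raise ValueError("CCC needs at least two paired observations")
    sx2 = np.var(x)
    sy2 = np.var(y)
    mdiff = x.mean() - y.mean()
    denom = sx2 + sy2 + mdiff**2
    if denom == 0:
        return math.nan
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / denom)


def spearman(x, y) -> float:
    x, y = _pair(x, y)
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def r_squared(x, y) -> float:
    """Squared Pearson correlation (identical to simple-regression R²)."""
    x, y = _pair(x, y)
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.pearsonr(x, y).statistic ** 2)


def rmse(x, y) -> float:
    x, y = _pair(x, y)
    if x.size == 0:
        raise InsufficientDataError("RMSE needs at least one pair")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def cohen_kappa(a, b) -> float:
    """Cohen's kappa for two label series; NaN when chance agreement is 1."""
    a, b = _pair(a, b)
    if a.size == 0:
        raise InsufficientDataError("kappa needs at least one pair")
    # degenerate marginals: p_e == 1 iff both raters are constant
    if np.all(a == a[0]) and np.all(b == b[0]):
        return math.nan
    return float(cohen_kappa_score(a, b))


@dataclass(frozen=True)
class AgreementMetrics:
    """One report row: sensor vs. gold at one resolution. NaN = undefined/NA."""

    source: str
    se: float = math.nan
    sp: float = math.nan
    ac: float = math.nan
    ppv: float = math.nan
    prevalence: float = math.nan
    ccc: float = math.nan
    r_s: float = math.nan
    kappa: float = math.nan
    r2: float = math.nan
    rmse: float = math.nan
    n: int = 0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _evaluate_pair_1min(name: str, pred: np.ndarray, gold: np.ndarray) -> AgreementMetrics:
    c = confusion(pred, gold)
    se, sp, ac = se_sp_ac(c)
    prev = prevalence(c)
    x, y = _pair(pred, gold)
    return AgreementMetrics(
        source=name,
        se=se,
        sp=sp,
        ac=ac,
        ppv=ppv(se, sp, prev) if not math.isnan(se) else math.nan,
        prevalence=prev,
        ccc=lin_ccc(x, y) if x.size >= 2 else math.nan,
        r_s=spearman(x, y),
        kappa=cohen_kappa(x, y),
        n=c.n,
    )


def _evaluate_pair_10min(name: str, pred: np.ndarray, gold: np.ndarray) -> AgreementMetrics:
    x, y = _pair(pred, gold)
    if x.size == 0:
        raise InsufficientDataError(f"no overlapping rows for {name}")
    return AgreementMetrics(
        source=name,
        ccc=lin_ccc(x, y) if x.size >= 2 else math.nan,
        r_s=spearman(x, y),
        r2=r_squared(x, y),
        rmse=rmse(x, y),
        n=int(x.size),
    )


def evaluate(
    merged: MergedDataset, gold: str, resolution: str | None = None
) -> pd.DataFrame:
    """Full agreement battery for every sensor column against ``gold``.

    1-min resolution runs the categorical battery (SE, SP, AC, PPV,
    prevalence, kappa) plus CCC and r_S on the binary labels; coarser
    resolutions run the numeric battery (R², RMSE, CCC, r_S). Each row
    reports the pairwise-complete N actually used.
    """
    resolution = resolution or merged.resolution
    if gold not in merged.data.columns:
        raise KeyError(f"gold column {gold!r} not in merged dataset")
    rows = []
    for name in merged.sources:
        if name == gold:
            continue
        sub = merged.data[[name, gold]].dropna()
        pred = sub[name].to_numpy(float)
        truth = sub[gold].to_numpy(float)
        if resolution == "1min":
            rows.append(_evaluate_pair_1min(name, pred, truth))
        else:
            rows.append(_evaluate_pair_10min(name, pred, truth))
    df = pd.DataFrame([r.as_dict() for r in rows]).set_index("source")
    return df


def _round_half_up(v: float, digits: int) -> float:
    if math.isnan(v):
        return math.nan
    q = 10**digits
    return math.floor(abs(v) * q + 0.5) / q * (1 if v >= 0 else -1)


def format_report(df: pd.DataFrame, resolution: str) -> str:
    """Aligned plain-text report; percentages to 1 dp, coefficients to 2 dp."""
    if resolution == "1min":
        cols = ["se", "sp", "ac", "ppv", "ccc", "r_s", "n"]
        header = ["System", "SE (%)", "SP (%)", "AC (%)", "PPV (%)", "CCC", "r_S", "N (min)"]
        pct = {"se", "sp", "ac", "ppv"}
    else:
        cols = ["r2", "rmse", "ccc", "r_s", "n"]
        header = ["System", "R2", "RMSE", "CCC", "r_S", "N"]
        pct = set()
    lines = []
    rows = [header]
    for name, row in df.iterrows():
        cells = [str(name)]
        for c in cols:
            v = row[c]
            if c == "n":
                cells.append(str(int(v)))
            elif c in pct:
                cells.append(f"{_round_half_up(100 * v, 1):.1f}" if not math.isnan(v) else "--")
            else:
                cells.append(f"{_round_half_up(v, 2):.2f}" if not math.isnan(v) else "--")
        rows.append(cells)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    for r in rows:
        lines.append("  ".join(cell.rjust(w) for cell, w in zip(r, widths)))
    return "\n".join(lines)
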