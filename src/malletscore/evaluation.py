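"""Agreement metrics between MMS score sets.

Two sets of per-trial grades (algorithm vs ground truth, manual vs ground
truth, algorithm vs manual, or rater vs rater) are compared with the Pearson
correlation coefficient (PCC) and the root-mean-square error (RMSE) in grade
units, each with a 95% confidence interval, plus a 5×5 truth × predicted
confusion matrix.

CI methods: the PCC interval uses the Fisher z transform
(tanh(atanh r ± 1.96 / sqrt(n − 3))) by default, with a seeded
nonparametric-bootstrap alternative; the RMSE interval uses a seeded
nonparametric bootstrap (10,000 resamples by default).  Reports from several
raters are averaged by taking the arithmetic mean of the point estimates; the
averaged report's CIs are recomputed as a t-interval across the rater point
estimates rather than averaging the per-rater intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, MalletScoreError

logger = logging.getLogger(__name__)

N_GRADES = 5


@dataclass
class ScoreSet:
    """trial_id → grade (1–5) mapping from one scorer."""

    scores: dict[str, int]
    rater: str = ""

    def __post_init__(self) -> None:
        bad = {t: g for t, g in self.scores.items()
               if g not in range(1, N_GRADES + 1)}
        if bad:
            raise MalletScoreError(f"grades must be 1..5; offending: {bad}")

    def exclude(self, trial_ids: Sequence[str]) -> "ScoreSet":
        drop = set(trial_ids)
        return ScoreSet({t: g for t, g in self.scores.items() if t not in drop},
                        self.rater)

    @classmethod
    def from_csv(cls, path: str | Path, rater: str = "",
                 trial_col: str = "trial_id",
                 grade_col: str = "grade") -> "ScoreSet":
        df = pd.read_csv(path)
        return cls(dict(zip(df[trial_col].astype(str), df[grade_col].astype(int))),
                   rater or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"trial_id": list(self.scores),
                      "grade": list(self.scores.values())}).to_csv(path,
                                                                   index=False)


def _paired(a: ScoreSet, b: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(set(a.scores) & set(b.scores))
    unpaired = (set(a.scores) | set(b.scores)) - set(common)
    if unpaired:
        logger.warning("dropping %d unpaired trial ids (e.g. %s)",
                       len(unpaired), sorted(unpaired)[:3])
    if not common:
        raise EmptyInputError(
            f"no paired trials between {a.rater!r} and {b.rater!r}")
    x = np.array([a.scores[t] for t in common], dtype=float)
    y = np.array([b.scores[t] for t in common], dtype=float)
    return x, y


def pcc_with_ci(a: ScoreSet, b: ScoreSet, confidence: float = 0.95,
                method: str = "fisher", n_boot: int = 10_000,
                seed: int = 0) -> tuple[float, float, float]:
    """Pearson r on paired grades with a 95% CI (Fisher z or bootstrap)."""
    x, y = _paired(a, b)
    if len(x) < 3:
        raise EmptyInputError("PCC needs at least 3 paired trials")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MalletScoreError(
            "correlation undefined: a score set has zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    z_crit = stats.norm.ppf(0.5 + confidence / 2.0)
    if method == "fisher":
        if abs(r) >= 1.0:
            return r, r, r
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(len(x) - 3)
        lo, hi = np.tanh(z - z_crit * se), np.tanh(z + z_crit * se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        xs, ys = x[idx], y[idx]
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        denom = np.sqrt((xs_c ** 2).sum(axis=1) * (ys_c ** 2).sum(axis=1))
        rs = np.divide((xs_c * ys_c).sum(axis=1), denom,
                       out=np.full(n_boot, np.nan), where=denom > 0)
        rs = rs[np.isfinite(rs)]
        alpha = 1.0 - confidence
        lo, hi = np.quantile(rs, [alpha / 2, 1 - alpha / 2])
    else:
        raise MalletScoreError(f"unknown CI method {method!r}")
    return r, float(lo), float(hi)


def rmse_with_ci(a: ScoreSet, b: ScoreSet, confidence: float = 0.95,
                 n_boot: int = 10_000, seed: int = 0
                 ) -> tuple[float, float, float]:
    """RMSE in grade units over paired trials, with a bootstrap 95% CI."""
    x, y = _paired(a, b)
    sq = (x - y) ** 2
    rmse = float(np.sqrt(sq.mean()))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(sq), size=(n_boot, len(sq)))
    boots = np.sqrt(sq[idx].mean(axis=1))
    alpha = 1.0 - confidence
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return rmse, float(lo), float(hi)


def confusion_matrix(truth: ScoreSet, pred: ScoreSet) -> np.ndarray:
    """5×5 counts[true − 1][predicted − 1] over paired trials."""
    x, y = _paired(truth, pred)
    counts = np.zeros((N_GRADES, N_GRADES), dtype=int)
    for t, p in zip(x.astype(int), y.astype(int)):
        counts[t - 1, p - 1] += 1
    return counts


def within_one_grade(confusion: np.ndarray) -> bool:
    """True when all confusion mass lies on or adjacent to the diagonal."""
    t, p = np.nonzero(confusion)
    return bool(np.all(np.abs(t - p) <= 1))


@dataclass
class AgreementReport:
    """PCC and RMSE (with 95% CIs) plus confusion counts for one comparison."""

    pcc: float
    pcc_ci: tuple[float, float]
    rmse: float
    rmse_ci: tuple[float, float]
    n: int
    confusion: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12:
            raise MalletScoreError(f"PCC {self.pcc} outside [-1, 1]")
        if self.rmse < 0:
            raise MalletScoreError("RMSE must be >= 0")
        if self.confusion is not None and self.confusion.sum() != self.n:
            raise MalletScoreError("confusion counts must sum to n")

    @property
    def within_one_grade(self) -> Optional[bool]:
        if self.confusion is None:
            return None
        return within_one_grade(self.confusion)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n": self.n,
            "pcc": round(self.pcc, 4),
            "pcc_ci95": [round(v, 4) for v in self.pcc_ci],
            "rmse": round(self.rmse, 4),
            "rmse_ci95": [round(v, 4) for v in self.rmse_ci],
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
            d["within_one_grade"] = self.within_one_grade
        return d


def agreement_report(truth: ScoreSet, pred: ScoreSet,
                     pcc_method: str = "fisher", n_boot: int = 10_000,
                     seed: int = 0, label: str = "") -> AgreementReport:
    """Full agreement report (PCC, RMSE, CIs, confusion) for one pair."""
    r, r_lo, r_hi = pcc_with_ci(truth, pred, method=pcc_method,
                                n_boot=n_boot, seed=seed)
    e, e_lo, e_hi = rmse_with_ci(truth, pred, n_boot=n_boot, seed=seed)
    conf = confusion_matrix(truth, pred)
    label = label or f"{truth.rater or 'a'} vs {pred.rater or 'b'}"
    return AgreementReport(r, (r_lo, r_hi), e, (e_lo, e_hi),
                           int(conf.sum()), conf, label)


def average_over_raters(reports: list[AgreementReport],
                        confidence: float = 0.95) -> AgreementReport:
    """Mean PCC/RMSE across rater reports; CIs are t-intervals across raters."""
    if not reports:
        raise EmptyInputError("cannot average an empty list of reports")
    if len(reports) == 1:
        return reports[0]
    pccs = np.array([r.pcc for r in reports])
    rmses = np.array([r.rmse for r in reports])

    def t_ci(v: np.ndarray) -> tuple[float, float]:
        m, se = v.mean(), stats.sem(v)
        if se == 0:
            return float(m), float(m)
        half = se * stats.t.ppf(0.5 + confidence / 2.0, len(v) - 1)
        return float(m - half), float(m + half)

    conf = None
    if all(r.confusion is not None for r in reports):
        conf = np.sum([r.confusion for r in reports], axis=0)
    n = int(conf.sum()) if conf is not None else reports[0].n
    return AgreementReport(float(pccs.mean()), t_ci(pccs),
                           float(rmses.mean()), t_ci(rmses), n, conf,
                           label=f"average of {len(reports)} raters")


def plot_confusion_heatmap(confusion: np.ndarray, path: str | Path,
                           title: str = "") -> None:
    """Write a truth × predicted grade heatmap to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    im = ax.imshow(confusion, cmap="Blues")
    labels = ["I", "II", "III", "IV", "V"]
    ax.set_xticks(range(N_GRADES), labels)
    ax.set_yticks(range(N_GRADES), labels)
    ax.set_xlabel("predicted grade")
    ax.set_ylabel("true grade")
    for i in range(N_GRADES):
        for j in range(N_GRADES):
            if confusion[i, j]:
                ax.text(j, i, str(confusion[i, j]), ha="center", va="center",
                        color="black")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
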