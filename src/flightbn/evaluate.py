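"""Calibration scores, threshold errors, the Type-II ROC and repeated CV.

Scores per case use the probability assigned to the *true* state, Pc:
logarithmic loss = mean(-ln Pc); quadratic (Brier) loss =
mean(1 - 2 Pc + sum_j Pj^2); spherical payoff = mean(Pc / sqrt(sum_j
Pj^2)); AUC by the rank (Mann-Whitney) statistic with tie correction; Gini
= 2 AUC - 1.

Classification uses a *no-flight threshold* tau: predict "no flight" iff
P(no flight) >= tau (ties predict no flight).  Type I error % = false
positives / actual negatives x 100; Type II % = false negatives / actual
positives x 100; total % = misclassifications / all cases x 100, so
total = (type1 * N_neg + type2 * N_pos) / N at every threshold.

Repeated k-fold cross-validation re-learns discretizations, TAN structure
and EM parameters on the training folds of every iteration, pools the
test-fold posteriors per iteration, and summarizes the per-threshold error
curves (grid 0..1 step 0.001) as mean/SD/min/max across iterations.  The
SD-distance diagnostic is (calibration - CV mean)/CV SD per threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import CaseFile

THRESHOLDS_REPORTED: tuple[float, ...] = (0.50, 0.90, 0.95, 0.99)
GRID: np.ndarray = np.round(np.arange(0, 1001) / 1000.0, 3)


@dataclass
class ScoredCases:
    """Per-case posterior P(flight = true) plus the truth flag."""

    p_flight: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.p_flight = np.asarray(self.p_flight, dtype=float)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.p_flight.shape != self.truth.shape:
            raise ValueError("length mismatch")
        if ((self.p_flight < 0) | (self.p_flight > 1)).any():
            raise ValueError("probabilities outside [0, 1]")


def calibration_metrics(sc: ScoredCases, log_base: str = "natural") -> dict:
    """The five calibration indices for binary scored cases."""
    p = sc.p_flight
    y = sc.truth
    pc = np.where(y, p, 1.0 - p)
    sumsq = p**2 + (1.0 - p) ** 2
    logf = np.log if log_base == "natural" else np.log2
    logloss = float(np.mean(-logf(np.clip(pc, 1e-300, None))))
    quadratic = float(np.mean(1.0 - 2.0 * pc + sumsq))
    spherical = float(np.mean(pc / np.sqrt(sumsq)))
    if y.all() or not y.any():
        raise ValueError("AUC undefined: need both classes present")
    ranks = rankdata(p)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    auc = float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
    gini = 2.0 * auc - 1.0
    return {
        "logarithmic_loss": logloss,
        "quadratic_loss": quadratic,
        "spherical_payoff": spherical,
        "gini": gini,
        "auc": auc,
    }


def confusion_at_threshold(sc: ScoredCases, tau: float) -> dict:
    """Type I / Type II / total error percentages at no-flight threshold tau."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    y = sc.truth
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0:
        raise ValueError("Type II undefined: no actual positives")
    predict_no_flight = (1.0 - sc.p_flight) >= tau
    fp = int((~predict_no_flight & ~y).sum())  # predicted flight, none occurred
    fn = int((predict_no_flight & y).sum())  # predicted no flight, flight occurred
    type1 = 100.0 * fp / n_neg if n_neg else float("nan")
    type2 = 100.0 * fn / n_pos
    total = 100.0 * (fp + fn) / len(y)
    return {"type1_pct": type1, "type2_pct": type2, "total_pct": total}


def error_curves(sc: ScoredCases, grid: np.ndarray = GRID) -> pd.DataFrame:
    """Vectorized per-threshold error table over a grid of tau.

    tau = 0 is included for grid completeness with the same decision rule
    (P(no flight) >= 0 always predicts no flight).
    """
    y = sc.truth
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    p_no = 1.0 - sc.p_flight
    grid = np.asarray(grid, dtype=float)
    # predict no flight iff p_no >= tau: count cases with p_no >= tau by class
    pos_sorted = np.sort(p_no[y])
    neg_sorted = np.sort(p_no[~y])
    fn = len(pos_sorted) - np.searchsorted(pos_sorted, grid, side="left")
    tn = len(neg_sorted) - np.searchsorted(neg_sorted, grid, side="left")
    fp = n_neg - tn
    type1 = 100.0 * fp / n_neg if n_neg else np.full_like(grid, np.nan)
    type2 = 100.0 * fn / n_pos if n_pos else np.full_like(grid, np.nan)
    total = 100.0 * (fp + fn) / len(y)
    return pd.DataFrame(
        {"threshold": grid, "type1_pct": type1, "type2_pct": type2, "total_pct": total}
    )


def type2_roc(sc: ScoredCases, grid: np.ndarray = GRID) -> pd.DataFrame:
    """Modified ROC: true-negative prediction rate vs Type II error per tau.

    As tau rises the classifier predicts "no flight" less readily, so
    Type I is non-decreasing and Type II non-increasing in tau.
    """
    grid = np.asarray(grid, dtype=float)
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("grid outside [0, 1]")
    curves = error_curves(sc, grid)
    curves["true_negative_rate_pct"] = 100.0 - curves["type1_pct"]
    return curves[["threshold", "type2_pct", "true_negative_rate_pct", "type1_pct", "total_pct"]]


@dataclass
class CVResult:
    """Per-threshold summary over CV iterations plus the calibration curve."""

    grid: np.ndarray
    stats: dict  # error type -> DataFrame(mean, sd, min, max) indexed by grid
    calibration: pd.DataFrame
    sd_distance: pd.DataFrame
    n_iterations: int
    k: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"threshold": self.grid})
        for err, df in self.stats.items():
            for col in ("mean", "sd", "min", "max"):
                out[f"{err}_{col}"] = df[col].to_numpy()
            out[f"{err}_calibration"] = self.calibration[err].to_numpy()
            out[f"{err}_sd_distance"] = self.sd_distance[err].to_numpy()
        return out


def sd_distance(calibration: pd.DataFrame, cv_mean: pd.DataFrame, cv_sd: pd.DataFrame) -> pd.DataFrame:
    """(calibration - CV mean)/CV SD; NaN where the SD is zero."""
    if not calibration.index.equals(cv_mean.index):
        raise ValueError("grid mismatch between calibration and CV curves")
    out = {}
    for col in calibration.columns:
        sd = cv_sd[col].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (calibration[col].to_numpy() - cv_mean[col].to_numpy()) / sd
        d = np.where(sd > 0, d, np.nan)
        out[col] = d
    return pd.DataFrame(out, index=calibration.index)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per case, positives and negatives spread evenly."""
    fold = np.empty(len(y), dtype=int)
    for cls in (True, False):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % k
    return fold


def repeated_kfold_cv(
    cf: CaseFile,
    species: str,
    k: int = 4,
    iterations: int = 100,
    seed: int = 0,
    covariates=None,
    stratified: bool = True,
    grid: np.ndarray = GRID,
    alpha: float = 1.0,
) -> CVResult:
    """Repeated k-fold CV with full re-learning per training split.

    Each iteration randomizes fold membership, and for each fold re-runs
    supervised MDL discretization, TAN structure learning and EM on the
    training cases only, then scores the held-out fold.  Test posteriors
    are pooled within an iteration before computing error curves.
    """
    from .model import learn_flight_bn, score_casefile

    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    y = cf.flight_flags(species).to_numpy()
    if y.sum() < k:
        raise ValueError("not enough positive hours to stratify folds")
    err_types = ("type1_pct", "type2_pct", "total_pct")
    per_iter = {e: np.empty((iterations, len(grid))) for e in err_types}
    for it in range(iterations):
        if stratified:
            fold = _stratified_folds(y, k, rng)
        else:
            fold = rng.permutation(np.arange(len(y)) % k)
            while any((y[fold == f].sum() == 0) for f in range(k)):
                import warnings

                warnings.warn("fold without positives; resampling")
                fold = rng.permutation(np.arange(len(y)) % k)
        p_all = np.empty(len(y))
        for f in range(k):
            train = fold != f
            model = learn_flight_bn(
                cf, species, subset=train, covariates=covariates, alpha=alpha
            )
            p_all[~train] = score_casefile(model, cf, subset=~train)
        sc = ScoredCases(p_all, y)
        curves = error_curves(sc, grid)
        for e in err_types:
            per_iter[e][it] = curves[e].to_numpy()
    # calibration: learn and score on the full case file
    model = learn_flight_bn(cf, species, covariates=covariates, alpha=alpha)
    p_cal = score_casefile(model, cf)
    cal_curves = error_curves(ScoredCases(p_cal, y), grid).set_index("threshold")
    cal = cal_curves[list(err_types)]
    stats = {}
    mean_df = {}
    sd_df = {}
    for e in err_types:
        m = per_iter[e]
        stats[e] = pd.DataFrame(
            {
                "mean": m.mean(axis=0),
                "sd": m.std(axis=0, ddof=1) if iterations > 1 else np.zeros(len(grid)),
                "min": m.min(axis=0),
                "max": m.max(axis=0),
            },
            index=pd.Index(grid, name="threshold"),
        )
        mean_df[e] = stats[e]["mean"]
        sd_df[e] = stats[e]["sd"]
    sdd = sd_distance(cal, pd.DataFrame(mean_df), pd.DataFrame(sd_df))
    return CVResult(
        grid=np.asarray(grid),
        stats=stats,
        calibration=cal,
        sd_distance=sdd,
        n_iterations=iterations,
        k=k,
        seed=seed,
    )


def evaluation_report(sc: ScoredCases, thresholds=THRESHOLDS_REPORTED, grid=GRID) -> dict:
    """Scores plus per-threshold errors, JSON-serializable."""
    report = {"scores": calibration_metrics(sc)}
    report["thresholds"] = {
        str(tau): confusion_at_threshold(sc, tau) for tau in thresholds
    }
    curves = error_curves(sc, grid)
    report["grid"] = {
        "threshold": curves["threshold"].tolist(),
        "type1_pct": curves["type1_pct"].tolist(),
        "type2_pct": curves["type2_pct"].tolist(),
        "total_pct": curves["total_pct"].tolist(),
    }
    return report
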