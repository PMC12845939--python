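"""Depressive-pattern screening: the 2-SD individual-baseline rule, the
logistic feature model, evaluation metrics and group statistics.

The rule classifier implements the screening criterion: a stimulus counts as
deviant when the baseline-relative z-scores of the core features (PDA, PDV,
FD) exceed 2 SD in the direction expected under depression (hyper-response to
negative stimuli, blunted or negative response to positive stimuli, longer
fixations for both); a participant is labelled depressive-pattern when at
least three of the six stimuli are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve, auc as sk_auc

__all__ = [
    "RuleConfig",
    "LogisticModel",
    "ConfusionMetrics",
    "GroupStats",
    "SeparationError",
    "DEFAULT_DIRECTIONS",
    "flag_stimulus",
    "classify_rule",
    "screen_participant",
    "logistic_score",
    "odds_ratio",
    "fit_logistic",
    "confusion_metrics",
    "threshold_sweep",
    "roc_auc",
    "group_stats",
]

LABEL_POSITIVE = "depressive-pattern"
LABEL_NEGATIVE = "non-depressive"

# valence -> feature -> expected deviation direction under depression
DEFAULT_DIRECTIONS: dict[str, dict[str, int]] = {
    "neg": {"PDA": +1, "PDV": +1, "FD": +1},
    "pos": {"PDA": -1, "PDV": -1, "FD": +1},
}


class SeparationError(RuntimeError):
    """Perfect separation in the logistic fit; a penalised fit is advised."""


@dataclass
class RuleConfig:
    k_sd: float = 2.0
    core_features: tuple[str, ...] = ("PDA", "PDV", "FD")
    mode: str = "majority"  # 'any' | 'majority' | 'all'
    min_flagged_stimuli: int = 3
    directions: dict = field(default_factory=lambda: {
        v: dict(d) for v, d in DEFAULT_DIRECTIONS.items()})

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.min_flagged_stimuli < 1:
            raise ValueError("min_flagged_stimuli must be >= 1")
        if self.mode not in ("any", "majority", "all"):
            raise ValueError("mode must be one of any/majority/all")


def flag_stimulus(z: dict[str, float], valence: str, cfg: RuleConfig | None = None
                  ) -> bool:
    """True when the stimulus deviates from baseline per the configured rule.

    A core feature is deviant iff its direction-gated z-score is >= k_sd
    (inclusive, per the "at least 2 SD" criterion); missing z-scores count as
    non-deviant.
    """
    cfg = cfg or RuleConfig()
    if valence not in cfg.directions:
        raise ValueError(f"unknown valence {valence!r}")
    dirs = cfg.directions[valence]
    n_dev = 0
    for f in cfg.core_features:
        zv = z.get(f, float("nan"))
        if not np.isfinite(zv):
            continue
        if dirs.get(f, +1) * zv >= cfg.k_sd:
            n_dev += 1
    k = len(cfg.core_features)
    need = {"any": 1, "majority": k // 2 + 1, "all": k}[cfg.mode]
    return n_dev >= need


def classify_rule(stimulus_flags: list[bool], cfg: RuleConfig | None = None) -> str:
    """Participant-level rule: depressive-pattern iff at least
    ``min_flagged_stimuli`` stimuli were flagged."""
    cfg = cfg or RuleConfig()
    if len(stimulus_flags) < cfg.min_flagged_stimuli:
        raise ValueError(
            f"need at least {cfg.min_flagged_stimuli} stimuli, "
            f"got {len(stimulus_flags)}")
    return LABEL_POSITIVE if sum(bool(f) for f in stimulus_flags) \
        >= cfg.min_flagged_stimuli else LABEL_NEGATIVE


def screen_participant(stimulus_z: list[tuple[dict[str, float], str]],
                       cfg: RuleConfig | None = None) -> tuple[str, list[bool]]:
    """Apply the rule to a list of (z-features, valence) stimulus records."""
    cfg = cfg or RuleConfig()
    flags = [flag_stimulus(z, val, cfg) for z, val in stimulus_z]
    return classify_rule(flags, cfg), flags


# ---------------------------------------------------------------------------
# logistic feature model
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Fitted (or user-set) logistic model for depressive status.

    Reported defaults for the printed slopes: 0.085 per % PDA to negative
    news, -0.11 per % pupil response to positive news, 0.007 per ms fixation
    duration.
    """

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    se: np.ndarray | None = None
    llf: float = float("nan")
    llnull: float = float("nan")
    lr_chi2: float = float("nan")
    lr_df: int = 0
    lr_pvalue: float = float("nan")
    nagelkerke_r2: float = float("nan")
    n_obs: int = 0
    fitted: bool = False

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite and complete")
        eta = self.intercept + X @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> pd.DataFrame:
        rows = {"intercept": (self.intercept, np.nan, np.nan)}
        for i, name in enumerate(self.feature_names):
            se = self.se[i] if self.se is not None else np.nan
            rows[name] = (self.coef[i], se, math.exp(self.coef[i]))
        return pd.DataFrame(rows, index=["beta", "SE", "OR"]).T


def logistic_score(model: LogisticModel, features) -> float:
    """Probability of depressive status for one feature vector."""
    return float(model.predict(np.asarray(features, dtype=float))[0])


def odds_ratio(beta: float) -> float:
    """Odds ratio per unit predictor increase, OR = e^beta."""
    return float(math.exp(beta))


def fit_logistic(X, y, feature_names: tuple[str, ...] | None = None,
                 freeze_coef: np.ndarray | None = None) -> LogisticModel:
    """Maximum-likelihood logistic fit (IRLS via statsmodels Logit).

    Reports the likelihood-ratio chi-square against the intercept-only model
    and Nagelkerke's R^2.  With ``freeze_coef`` the slopes are held at the
    supplied values and only the intercept is estimated (the printed model
    reports slopes but no intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(k))
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to fit")

    if freeze_coef is not None:
        freeze_coef = np.asarray(freeze_coef, dtype=float)
        offset = X @ freeze_coef
        res = sm.Logit(y, np.ones((n, 1)), offset=offset).fit(disp=0)
        intercept = float(res.params[0])
        coef = freeze_coef
        se = None
        llf = float(res.llf)
    else:
        design = sm.add_constant(X, has_constant="add")
        try:
            # bse triggers the Hessian inverse, which is singular under
            # (quasi-)separation, so it stays inside the guard
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            se = np.asarray(res.bse, dtype=float)[1:]
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(
                "perfect separation detected; consider a penalised fit"
            ) from exc
        if not res.mle_retvals.get("converged", True) or np.max(np.abs(params)) > 1e3:
            raise SeparationError(
                "logistic fit did not converge (likely separation); "
                "consider a penalised fit")
        intercept = float(params[0])
        coef = params[1:]
        llf = float(res.llf)

    ll0 = float(sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf)
    lr = 2.0 * (llf - ll0)
    r2 = _nagelkerke(ll0, llf, n)
    return LogisticModel(
        feature_names=feature_names, coef=np.asarray(coef, dtype=float),
        intercept=intercept, se=se, llf=llf, llnull=ll0,
        lr_chi2=float(max(lr, 0.0)), lr_df=k,
        lr_pvalue=float(sps.chi2.sf(max(lr, 0.0), k)),
        nagelkerke_r2=r2, n_obs=n, fitted=True)


def _nagelkerke(ll0: float, ll1: float, n: int) -> float:
    """Nagelkerke R^2 = [1 - exp((2/n)(ll0 - ll1))] / [1 - exp((2/n) ll0)]."""
    num = 1.0 - math.exp((2.0 / n) * (ll0 - ll1))
    den = 1.0 - math.exp((2.0 / n) * ll0)
    return float(num / den) if den != 0 else float("nan")


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def confusion_metrics(tn: int, fp: int, fn: int, tp: int) -> ConfusionMetrics:
    """Standard confusion-matrix metrics; undefined ratios (zero denominator)
    are reported as NaN rather than raising."""
    for v in (tn, fp, fn, tp):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    n = tn + fp + fn + tp
    if n == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num, den):
        return float(num / den) if den > 0 else float("nan")

    acc = ratio(tp + tn, n)
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else float("nan"))
    return ConfusionMetrics(tn=int(tn), fp=int(fp), fn=int(fn), tp=int(tp),
                            accuracy=acc, sensitivity=sens, specificity=spec,
                            precision=prec, f1=float(f1))


def threshold_sweep(probabilities, labels,
                    thresholds=(0.4, 0.5, 0.6)) -> pd.DataFrame:
    """Sensitivity/specificity per probability threshold (p >= t => positive)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    rows = []
    for t in thresholds:
        pred = (p >= t).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        m = confusion_metrics(tn, fp, fn, tp)
        rows.append({"threshold": t, "sensitivity": m.sensitivity,
                     "specificity": m.specificity, "accuracy": m.accuracy})
    return pd.DataFrame(rows)


def roc_auc(probabilities, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC.  Raises on single-class labels."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    fpr, tpr, _ = roc_curve(y, np.asarray(probabilities, dtype=float))
    return fpr, tpr, float(sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    t: float
    df: int
    p_value: float
    cohen_d: float
    mannwhitney_u: float
    mannwhitney_p: float
    normal_a: bool
    normal_b: bool


def group_stats(group_a, group_b, alpha: float = 0.05) -> GroupStats:
    """Two-sample comparison: pooled-variance t-test (df = nA + nB - 2),
    Cohen's d with pooled SD (sign follows mean(a) - mean(b)), Mann-Whitney U,
    and Shapiro-Wilk normality screening per group."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t_stat, p = sps.ttest_ind(a, b, equal_var=True)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    d = float((a.mean() - b.mean()) / math.sqrt(sp2)) if sp2 > 0 else float("nan")
    u_res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    sh_a = sps.shapiro(a).pvalue if 3 <= na <= 5000 else np.nan
    sh_b = sps.shapiro(b).pvalue if 3 <= nb <= 5000 else np.nan
    return GroupStats(t=float(t_stat), df=na + nb - 2, p_value=float(p),
                      cohen_d=d, mannwhitney_u=float(u_res.statistic),
                      mannwhitney_p=float(u_res.pvalue),
                      normal_a=bool(sh_a > alpha) if np.isfinite(sh_a) else True,
                      normal_b=bool(sh_b > alpha) if np.isfinite(sh_b) else True)
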