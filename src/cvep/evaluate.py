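"""Cross-validated accuracy curves and the statistical battery.

Accuracy is evaluated by 10-fold cross-validation over trials: with 10
trials per target, each fold holds out one trial per target, trains
templates/beamformers on the remaining 9 and tests the held-out trials
at every averaged-epoch count from 1 to 18.  The per-fold accuracies are
averaged, giving accuracy as a function of stimulation time.

Statistics mirror the study design: Wilcoxon signed-rank for accuracy
contrasts, paired t for the between-family fatigue contrast, one-way
repeated-measures ANOVA with Greenhouse-Geisser correction within each
family, and Bonferroni-corrected pairwise post hocs at alpha = 0.008.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .decode_cca import build_templates, identify_cca
from .decode_stb import build_beamformers, identify_stb
from .preproc import EpochArray

__all__ = [
    "AccuracyCurve",
    "StatTestResult",
    "printed_epoch_duration_s",
    "printed_time_grid",
    "kfold_accuracy",
    "wilcoxon_signed_rank",
    "paired_t",
    "rm_anova_gg",
    "bonferroni_posthoc",
    "compare_decoders",
]


def printed_epoch_duration_s(code_length_bits: int = 31, rate_hz: float = 90.0) -> float:
    """Epoch duration truncated to milliseconds (31 bits at 90 Hz -> 0.344 s)."""
    return math.floor(code_length_bits / rate_hz * 1000) / 1000


def printed_time_grid(
    epochs: np.ndarray | range = range(1, 19),
    code_length_bits: int = 31,
    rate_hz: float = 90.0,
) -> np.ndarray:
    """Stimulation-time column as conventionally printed.

    Multiples of the millisecond-truncated epoch duration, truncated to
    2 decimals — e.g. 1 -> 0.344, 10 -> 3.44, 18 -> 6.19 s.
    """
    per = printed_epoch_duration_s(code_length_bits, rate_hz)
    vals = np.array([math.floor(e * per * 100 + 1e-9) / 100 for e in epochs])
    vals[np.asarray(list(epochs)) == 1] = per
    return vals


@dataclass(frozen=True)
class AccuracyCurve:
    """Decoding accuracy (%) vs number of averaged epochs, per CV fold."""

    epochs_used: np.ndarray
    stimulation_time_s: np.ndarray
    fold_accuracies: np.ndarray  # folds x len(epochs_used), percent
    decoder: str = ""
    label: str = ""

    @property
    def mean(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.fold_accuracies.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epochs_used": self.epochs_used,
                "stimulation_time_s": self.stimulation_time_s,
                "accuracy_mean_pct": self.mean,
                "accuracy_sd_pct": self.sd,
            }
        )


@dataclass(frozen=True)
class StatTestResult:
    """A single hypothesis-test outcome with its correction context."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    correction: str = ""
    effect_direction: str = ""
    df: tuple[float, ...] = ()
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "correction": self.correction,
            "effect_direction": self.effect_direction,
            "df": list(self.df),
            **self.extra,
        }


def _stack_trials(trials: list[EpochArray]) -> np.ndarray:
    return np.stack([t.data for t in trials])


def kfold_accuracy(
    trials_per_target: dict[str, list[EpochArray]],
    decoder: str = "cca",
    k: int = 10,
    epochs_used: range | np.ndarray = range(1, 19),
    seed: int | None = None,
    shrinkage: float = 0.05,
    reg: float = 1e-8,
) -> AccuracyCurve:
    """K-fold cross-validated accuracy curve for one decoder.

    ``trials_per_target`` maps target label to its list of trial
    EpochArrays (same count per target, divisible by ``k``).  ``seed``
    shuffles the trial-to-fold assignment; ``None`` keeps trial order.
    """
    if decoder not in ("cca", "stb"):
        raise ValueError(f"unknown decoder {decoder!r}")
    labels = list(trials_per_target.keys())
    n_trials = len(next(iter(trials_per_target.values())))
    if any(len(v) != n_trials for v in trials_per_target.values()):
        raise ValueError("all targets must have the same number of trials")
    if k > n_trials or n_trials % k:
        raise ValueError(f"cannot split {n_trials} trials into {k} folds")
    fs = next(iter(trials_per_target.values()))[0].fs_hz
    order = np.arange(n_trials)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n_trials)
    folds = np.array_split(order, k)
    epochs_used = np.asarray(list(epochs_used), dtype=int)
    stacked = {lab: _stack_trials(trials_per_target[lab]) for lab in labels}

    acc = np.zeros((k, epochs_used.size))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        train = {
            lab: stacked[lab][train_idx].reshape(-1, *stacked[lab].shape[2:])
            for lab in labels
        }
        if decoder == "cca":
            model = build_templates(train, fs_hz=fs)
        else:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")  # expected h <= m*n warning at this scale
                model = build_beamformers(train, shrinkage=shrinkage, fs_hz=fs)
        correct = np.zeros(epochs_used.size)
        total = 0
        for true_i, lab in enumerate(labels, start=1):
            for ti in test_idx:
                trial = EpochArray(stacked[lab][ti], fs_hz=fs, target_label=lab)
                total += 1
                for j, r in enumerate(epochs_used):
                    if decoder == "cca":
                        pred, _ = identify_cca(trial, model, n_epochs_used=int(r), reg=reg)
                    else:
                        pred, _ = identify_stb(trial, model, n_epochs_used=int(r))
                    correct[j] += pred == true_i
        acc[f] = 100.0 * correct / total

    n0 = next(iter(trials_per_target.values()))[0].n_samples
    times = epochs_used * (n0 / fs)
    return AccuracyCurve(
        epochs_used=epochs_used,
        stimulation_time_s=times,
        fold_accuracies=acc,
        decoder=decoder,
    )


def wilcoxon_signed_rank(a, b, alpha: float = 0.05) -> StatTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original rule); p-values use
    exact enumeration for small tie-free samples and the tie-corrected
    normal approximation otherwise.  The reported statistic is the
    normal-approximation Z (negative when b > a on average), matching how
    such contrasts are conventionally tabulated; the signed-rank sum W is
    kept alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return StatTestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, alpha,
            effect_direction="none", extra={"degenerate": "all differences zero", "n": 0},
        )
    res = scipy.stats.wilcoxon(nz, alternative="two-sided", method="auto")
    approx = scipy.stats.wilcoxon(nz, alternative="two-sided", method="approx")
    z = float(approx.zstatistic)
    direction = "a>b" if np.median(nz) > 0 else "a<b"
    return StatTestResult(
        "wilcoxon_signed_rank",
        statistic=z,
        p_value=float(res.pvalue),
        alpha=alpha,
        effect_direction=direction,
        extra={"W": float(res.statistic), "n": int(nz.size)},
    )


def paired_t(a, b, alpha: float = 0.05) -> StatTestResult:
    """Classical paired t test (two-sided, df = n - 1).

    Zero-variance differences are flagged: identical samples give
    t = 0 / p = 1, a constant nonzero shift gives infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    n = d.size
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return StatTestResult(
                "paired_t", 0.0, 1.0, alpha, df=(n - 1,),
                extra={"degenerate": "zero difference variance, zero mean"},
            )
        return StatTestResult(
            "paired_t", math.inf if d.mean() > 0 else -math.inf, 0.0, alpha, df=(n - 1,),
            extra={"degenerate": "zero difference variance, nonzero mean"},
        )
    res = scipy.stats.ttest_rel(a, b)
    direction = "a>b" if d.mean() > 0 else "a<b"
    return StatTestResult(
        "paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        effect_direction=direction,
        df=(n - 1,),
    )


def rm_anova_gg(scores: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> StatTestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``scores`` is subjects x conditions (complete, no missing cells).
    Returns the F statistic with GG-corrected degrees of freedom and
    p-value, plus the epsilon estimate.
    """
    import pingouin as pg

    df = pd.DataFrame(np.asarray(scores, dtype=float)) if not isinstance(scores, pd.DataFrame) else scores
    if df.isna().any().any():
        raise ValueError("scores table must have no missing cells")
    n_sub, n_cond = df.shape
    if n_cond < 2 or n_sub < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    long = df.reset_index(drop=True).reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="score"
    )
    aov = pg.rm_anova(
        data=long, dv="score", within="condition", subject="subject", correction=True
    )
    row = aov.iloc[0]
    eps = float(row.get("eps", 1.0))
    p_gg = row.get("p_GG_corr", row.get("p-GG-corr", np.nan))
    p = float(p_gg) if np.isfinite(p_gg) else float(row["p_unc"])
    df1, df2 = float(row["ddof1"]) * eps, float(row["ddof2"]) * eps
    return StatTestResult(
        "rm_anova",
        statistic=float(row["F"]),
        p_value=p,
        alpha=alpha,
        correction="greenhouse-geisser",
        df=(df1, df2),
        extra={"epsilon": eps, "p_uncorrected": float(row["p_unc"])},
    )


def bonferroni_posthoc(
    scores: np.ndarray | pd.DataFrame, alpha: float = 0.008
) -> list[StatTestResult]:
    """Paired t for every condition pair, judged at the Bonferroni alpha.

    For 4 conditions this is the 6 pairwise contrasts at
    alpha = 0.05 / 6 ~= 0.008.
    """
    arr = np.asarray(scores, dtype=float)
    names = list(scores.columns) if isinstance(scores, pd.DataFrame) else [str(i + 1) for i in range(arr.shape[1])]
    out = []
    for i in range(arr.shape[1]):
        for j in range(i + 1, arr.shape[1]):
            res = paired_t(arr[:, i], arr[:, j], alpha=alpha)
            out.append(
                StatTestResult(
                    "paired_t",
                    statistic=res.statistic,
                    p_value=res.p_value,
                    alpha=alpha,
                    correction="bonferroni",
                    effect_direction=res.effect_direction,
                    df=res.df,
                    extra={**res.extra, "pair": (names[i], names[j])},
                )
            )
    return out


def compare_decoders(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    epochs_used: range | np.ndarray = range(1, 19),
    label_a: str = "CCA",
    label_b: str = "STB",
    code_length_bits: int = 31,
    rate_hz: float = 90.0,
) -> pd.DataFrame:
    """Per-stimulation-time Wilcoxon comparison of two decoders.

    ``curves_a``/``curves_b`` are subjects x len(epochs_used) accuracy
    matrices over matched subjects (or matched simulation seeds).  Emits
    one row per averaged-epoch count with the printed stimulation time,
    the signed-rank Z and the p-value.
    """
    A = np.atleast_2d(np.asarray(curves_a, dtype=float))
    B = np.atleast_2d(np.asarray(curves_b, dtype=float))
    epochs_used = np.asarray(list(epochs_used), dtype=int)
    if A.shape != B.shape or A.shape[1] != epochs_used.size:
        raise ValueError(
            f"curve matrices must share shape (subjects, {epochs_used.size}); "
            f"got {A.shape} and {B.shape}"
        )
    rows = []
    times = printed_time_grid(epochs_used, code_length_bits, rate_hz)
    for j, (e, t) in enumerate(zip(epochs_used, times)):
        res = wilcoxon_signed_rank(A[:, j], B[:, j])
        rows.append(
            {
                "epochs_used": int(e),
                "stimulation_time_s": t,
                "Z": res.statistic,
                "p_value": res.p_value,
                f"{label_a}_mean_pct": A[:, j].mean(),
                f"{label_b}_mean_pct": B[:, j].mean(),
            }
        )
    return pd.DataFrame(rows)
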