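"""Analysis stage: accuracy breakdowns, per-participant logistic
regressions, group tests, awareness (PDP/confidence) contrasts, and a
half-normal Bayes factor.

Scoring convention
------------------
Throughout, exclusion-phase responses are scored *as if under
inclusion instructions*: "correct"/"accuracy" always means the
grammatical member of the pair was chosen.  Above-chance grammatical
choice under exclusion -- where a participant is trying to pick the
ungrammatical item -- is the process-dissociation signature of
unconscious knowledge.

Regressions
-----------
Each participant's 132 choices (both phases pooled) are logistically
regressed on the pair's feature differences.  A small ridge penalty
(lambda = 1e-3 on the slopes, none on the intercept) keeps
coefficients finite under quasi-separation.  Group inference is a
one-sample t test of each coefficient against zero over participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

__all__ = [
    "accuracy_table",
    "participant_accuracy",
    "fit_participant_regression",
    "fit_all_participants",
    "group_coefficient_tests",
    "mixed_anova_2x2",
    "hochberg_correct",
    "pdp_confidence_analysis",
    "dienes_bf",
    "recovery_experiment",
]

RIDGE_LAMBDA = 1e-3


# ---------------------------------------------------------------------------
# Accuracy breakdowns
# ---------------------------------------------------------------------------

def participant_accuracy(
    records: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Per-participant grammatical-choice proportions, optionally
    within levels of trial-metadata columns."""
    keys = ["group", "variant", "participant"] + (by or [])
    out = (
        records.groupby(keys, dropna=False)["chose_grammatical"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    return out


def accuracy_table(records: pd.DataFrame) -> pd.DataFrame:
    """Cell means and standard errors of per-participant accuracy.

    Rows are group x phase; columns cover the grammatical-item
    breakdown (old/new), the ungrammatical breakdown (layer/random),
    violated layer, and locality.  Cells with no trials are missing
    (NaN), never zero.  Exclusion cells are grammatical-choice rates.
    """
    breakdowns = {
        "novelty": "gram_status",
        "violation": "ungram_status",
        "violated_layer": "violated_layer",
        "locality": "locality",
    }
    frames = []
    for name, col in breakdowns.items():
        acc = participant_accuracy(records, by=["phase", col])
        cell = (
            acc.groupby(["group", "variant", "phase", col])["accuracy"]
            .agg(mean="mean", se="sem", n="count")
            .reset_index()
            .rename(columns={col: "level"})
        )
        cell.insert(0, "breakdown", name)
        frames.append(cell)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Per-participant ridge logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    participant: str
    spec: str
    coefficients: pd.Series  # includes "intercept"
    converged: bool
    dropped: tuple[str, ...] = ()


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, bool]:
    """Penalised logistic MLE: minimise -loglik + lam/2 * ||w_slopes||^2.

    The first column of X must be the intercept column; it is not
    penalised.  Returns (coefficients, converged).
    """
    n, k = X.shape
    mask = np.ones(k)
    mask[0] = 0.0  # no penalty on the intercept

    def negloglik(w):
        z = X @ w
        # log(1 + exp(-z*s)) with s = +-1, stable form
        s = 2 * y - 1
        ll = np.logaddexp(0.0, -s * z).sum()
        return ll + 0.5 * lam * np.sum(mask * w * w)

    def grad(w):
        p = special.expit(X @ w)
        return X.T @ (p - y) + lam * mask * w

    lam_eff = lam
    for _ in range(4):  # escalate ridge if the optimiser fails
        res = optimize.minimize(
            negloglik,
            np.zeros(k),
            jac=grad,
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.success and np.all(np.isfinite(res.x)):
            return res.x, True
        lam_eff *= 10
        lam = lam_eff
    return res.x, False


def _firth_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Firth's bias-reduced logistic fit (Jeffreys-prior penalisation).

    Removes the O(1/n) away-from-zero bias of the plain MLE and keeps
    coefficients finite under separation, which matters for 132-trial
    per-participant fits where some predictors are informative on only
    a handful of pairs.  Columns are scaled to unit norm internally
    (the penalty is not scale-invariant in finite steps of the
    optimisation, and the raw predictors differ by orders of
    magnitude).
    """
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    n, k = Xs.shape
    w = np.zeros(k)
    for _ in range(max_iter):
        p = special.expit(Xs @ w)
        W = p * (1 - p)
        XtW = Xs.T * W
        info = XtW @ Xs
        try:
            inv_info = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            inv_info = np.linalg.inv(info + 1e-10 * np.eye(k))
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", Xs, inv_info, Xs) * W
        score = Xs.T @ (y - p + h * (0.5 - p))
        step = inv_info @ score
        # dampen absurd steps (flat directions early on)
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        w = w + step
        if np.linalg.norm(step) < tol:
            return w / scale, True
    return w / scale, False


def fit_participant_regression(
    records: pd.DataFrame,
    features: pd.DataFrame,
    spec: str = "chunk-rep",
    method: str = "firth",
    lam: float = RIDGE_LAMBDA,
) -> RegressionResult:
    """Fit one participant's choices on the pair feature differences.

    ``records`` must hold that participant's trials (both phases);
    the response is ``chose_grammatical``.  ``method`` selects the
    default bias-reduced Firth fit or a ridge-penalised MLE
    (``lam`` on the slopes, intercept unpenalised).  Constant feature
    columns are dropped (their coefficient is reported as NaN) rather
    than failing.
    """
    participant = str(records["participant"].iloc[0])
    X_df = features.loc[records["pair_id"]].reset_index(drop=True)
    y = records["chose_grammatical"].to_numpy(dtype=float)
    keep = [c for c in X_df.columns if X_df[c].nunique() > 1]
    dropped = tuple(c for c in X_df.columns if c not in keep)
    X = np.column_stack(
        [np.ones(len(X_df))] + [X_df[c].to_numpy(dtype=float) for c in keep]
    )
    if method == "firth":
        w, ok = _firth_logistic(X, y)
    elif method == "ridge":
        w, ok = _ridge_logistic(X, y, lam)
    else:
        raise ValueError(f"unknown method {method!r}")
    coefs = pd.Series(np.nan, index=["intercept", *X_df.columns], dtype=float)
    coefs["intercept"] = w[0]
    for name, val in zip(keep, w[1:]):
        coefs[name] = val
    return RegressionResult(
        participant=participant,
        spec=spec,
        coefficients=coefs,
        converged=ok,
        dropped=dropped,
    )


def fit_all_participants(
    records: pd.DataFrame, features: pd.DataFrame, spec: str = "chunk-rep"
) -> pd.DataFrame:
    """Coefficient frame: one row per participant, one column per
    predictor (plus intercept)."""
    rows = {}
    for pid, sub in records.groupby("participant", sort=True):
        res = fit_participant_regression(sub, features, spec)
        rows[pid] = res.coefficients
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant"
    return out


def group_coefficient_tests(coefficients: pd.DataFrame) -> pd.DataFrame:
    """One-sample t test of each coefficient against zero over
    participants, with dz effect size and a 95% CI of the mean."""
    if len(coefficients) < 2:
        raise ValueError("group tests need at least 2 participants")
    rows = []
    for col in coefficients.columns:
        x = coefficients[col].dropna().to_numpy()
        n = len(x)
        mean = x.mean()
        sd = x.std(ddof=1)
        se = sd / math.sqrt(n)
        if sd == 0:  # degenerate: identical coefficients
            t = 0.0 if mean == 0 else math.inf * np.sign(mean)
            p = 1.0 if mean == 0 else 0.0
        else:
            t, p = stats.ttest_1samp(x, 0.0)
        half = stats.t.ppf(0.975, n - 1) * se
        rows.append(
            {
                "predictor": col,
                "n": n,
                "mean": mean,
                "se": se,
                "t": float(t),
                "df": n - 1,
                "p": float(p),
                "dz": mean / sd if sd > 0 else np.nan,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# ANOVA, multiplicity, awareness analyses
# ---------------------------------------------------------------------------

def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "accuracy",
    within: str = "phase",
    between: str = "group",
    subject: str = "participant",
) -> pd.DataFrame:
    """2x2 mixed-design ANOVA (one within- and one between-participant
    factor) with partial eta squared, via pingouin."""
    import pingouin as pg

    for factor in (within, between):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    counts = data.groupby([subject, within], observed=True).size()
    if counts.min() < 1 or data.isna().any().any():
        raise ValueError("missing cells in the ANOVA design")
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    aov = aov.rename(
        columns={
            "Source": "effect",
            "p_unc": "p",
            "p-unc": "p",
            "np2": "partial_eta_sq",
        }
    )
    return aov[["effect", "F", "DF1", "DF2", "p", "partial_eta_sq"]]


def hochberg_correct(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Hochberg's step-up procedure: reject H(1)..H(k) for the largest
    k with p(k) <= alpha / (m - k + 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(p, alpha=alpha, method="simes-hochberg")
    return reject


def _two_sample(x, y):
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return np.nan, nx + ny - 2, np.nan, np.nan
    t, p = stats.ttest_ind(x, y)
    sp = math.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
        / (nx + ny - 2)
    )
    d = (np.mean(x) - np.mean(y)) / sp if sp > 0 else np.nan
    return float(t), nx + ny - 2, float(p), d


def _paired(x, y):
    diff = np.asarray(x) - np.asarray(y)
    n = len(diff)
    sd = diff.std(ddof=1) if n > 1 else 0.0
    if n < 2 or sd == 0:
        return np.nan, n - 1, np.nan, np.nan
    t, p = stats.ttest_rel(x, y)
    dz = diff.mean() / sd
    return float(t), n - 1, float(p), dz


def pdp_confidence_analysis(records: pd.DataFrame) -> pd.DataFrame:
    """The five awareness contrasts of the process-dissociation and
    confidence analyses.

    1. trained inclusion vs exclusion (paired): conscious control.
    2. trained exclusion vs control exclusion (two-sample): unconscious
       knowledge expressed against intent.
    3. guess-trial (confidence = 50) inclusion accuracy, trained vs
       control (two-sample): knowledge without awareness of knowing.
    4. confident (> 50) vs guess inclusion accuracy within trained
       (paired over participants with both bins).
    5. inclusion-exclusion difference, confident vs guess (paired over
       participants with both bins): awareness of control.

    Participants lacking a confidence bin are excluded from contrasts
    4-5 (and from 3 if they have no guess trials); accuracy is always
    the grammatical-choice rate.
    """
    acc = participant_accuracy(records, by=["phase"]).pivot_table(
        index=["group", "participant"], columns="phase", values="accuracy"
    )
    trained = acc.loc["trained"]
    control = acc.loc["control"]

    guessing = records.assign(
        bin=np.where(records["confidence"] <= 50, "guess", "confident")
    )
    bin_acc = (
        guessing.groupby(["group", "participant", "phase", "bin"])[
            "chose_grammatical"
        ]
        .mean()
        .unstack(["phase", "bin"])
    )

    rows = []

    t, df, p, d = _paired(trained["inclusion"], trained["exclusion"])
    rows.append(
        {
            "contrast": "trained inclusion vs exclusion",
            "mean_1": trained["inclusion"].mean(),
            "mean_2": trained["exclusion"].mean(),
            "t": t,
            "df": df,
            "p": p,
            "effect_size": d,
        }
    )

    t, df, p, d = _two_sample(trained["exclusion"], control["exclusion"])
    rows.append(
        {
            "contrast": "trained exclusion vs control exclusion",
            "mean_1": trained["exclusion"].mean(),
            "mean_2": control["exclusion"].mean(),
            "t": t,
            "df": df,
            "p": p,
            "effect_size": d,
        }
    )

    g_tr = bin_acc.loc["trained", ("inclusion", "guess")].dropna()
    g_co = bin_acc.loc["control", ("inclusion", "guess")].dropna()
    t, df, p, d = _two_sample(g_tr, g_co)
    rows.append(
        {
            "contrast": "guess-trial inclusion: trained vs control",
            "mean_1": g_tr.mean(),
            "mean_2": g_co.mean(),
            "t": t,
            "df": df,
            "p": p,
            "effect_size": d,
        }
    )

    tr = bin_acc.loc["trained"]
    both = tr[
        tr[("inclusion", "guess")].notna()
        & tr[("inclusion", "confident")].notna()
    ]
    t, df, p, d = _paired(
        both[("inclusion", "confident")], both[("inclusion", "guess")]
    )
    rows.append(
        {
            "contrast": "trained inclusion: confident vs guess",
            "mean_1": both[("inclusion", "confident")].mean(),
            "mean_2": both[("inclusion", "guess")].mean(),
            "t": t,
            "df": df,
            "p": p,
            "effect_size": d,
        }
    )

    need = [
        ("inclusion", "guess"),
        ("inclusion", "confident"),
        ("exclusion", "guess"),
        ("exclusion", "confident"),
    ]
    full = tr[tr[need].notna().all(axis=1)]
    diff_conf = full[("inclusion", "confident")] - full[("exclusion", "confident")]
    diff_guess = full[("inclusion", "guess")] - full[("exclusion", "guess")]
    t, df, p, d = _paired(diff_conf, diff_guess)
    rows.append(
        {
            "contrast": "inclusion-exclusion difference: confident vs guess",
            "mean_1": diff_conf.mean(),
            "mean_2": diff_guess.mean(),
            "t": t,
            "df": df,
            "p": p,
            "effect_size": d,
        }
    )
    return pd.DataFrame(rows).set_index("contrast")


# ---------------------------------------------------------------------------
# Bayes factor with a half-normal prior
# ---------------------------------------------------------------------------

def dienes_bf(mean: float, se: float, prior_sd: float) -> float:
    """Bayes factor (H1 over H0) for a normal estimate under a
    half-normal prediction.

    H0: the effect is 0; the data likelihood is Normal(mean; 0, se).
    H1: the effect theta is drawn from HalfNormal(prior_sd) on
    [0, inf); the marginal likelihood is the integral of
    Normal(mean; theta, se) against that prior.  Computed by adaptive
    quadrature to relative error < 1e-6.
    """
    if not (np.isfinite(mean) and np.isfinite(se) and np.isfinite(prior_sd)):
        raise ValueError("mean, se and prior_sd must be finite")
    if se <= 0 or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")

    # Substituting theta = prior_sd * u makes the prior factor an O(1)
    # standard half-normal, so the quadrature is well scaled for any
    # ratio of prior_sd to se.
    def integrand(u):
        return stats.norm.pdf(mean, loc=prior_sd * u, scale=se) * (
            2.0 * stats.norm.pdf(u)
        )

    upper = max(12.0, (abs(mean) + 8 * se) / prior_sd)
    upper = min(upper, 1e9)  # the half-normal factor kills the tail anyway
    likelihood_peak = abs(mean) / prior_sd
    likelihood_width = se / prior_sd
    points = sorted(
        {
            min(upper, max(p, 0.0))
            for p in (
                likelihood_peak,
                likelihood_peak + 8 * likelihood_width,
                10 * likelihood_width,
                1.0,
                8.0,
            )
        }
    )
    marginal, _ = integrate.quad(
        integrand,
        0.0,
        upper,
        points=points,
        epsabs=0.0,
        epsrel=1e-9,
        limit=400,
    )
    null = stats.norm.pdf(mean, loc=0.0, scale=se)
    return marginal / null


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------

def recovery_experiment(
    preset: str = "grammar-learner-implicit",
    variant: str = "centre-left",
    n_participants: int = 80,
    n_replicates: int = 200,
    seed: int = 0,
    stimulus_seed: int | None = None,
) -> pd.DataFrame:
    """End-to-end parameter recovery on synthetic groups.

    One stimulus design is built and held fixed; each replicate draws
    a fresh participant group from the preset, simulates both test
    phases, fits the per-participant regressions, and records the
    group mean and 95% CI per coefficient.  Reports per-coefficient
    bias, RMSE of the group mean, and CI coverage of the generating
    population mean.
    """
    from .features import CorpusStatistics, feature_matrix
    from .simulate import PRESETS, simulate_group
    from .stimuli import build_stimulus_set

    dist = PRESETS[preset] if isinstance(preset, str) else preset
    rng = np.random.default_rng(seed)
    design = build_stimulus_set(
        variant, stimulus_seed if stimulus_seed is not None else seed
    )
    stats_ = CorpusStatistics.from_corpus(design.training)
    fm = feature_matrix(design.pairs, stats_, "chunk-rep")

    truth = pd.Series(dist.mean)
    means, covered = [], []
    for _ in range(n_replicates):
        records = simulate_group(
            design, fm, n_participants, dist, rng, group="trained"
        )
        coefs = fit_all_participants(records, fm, "chunk-rep")
        g = group_coefficient_tests(coefs)
        means.append(g["mean"])
        covered.append(
            (g["ci_low"] <= truth.reindex(g.index))
            & (truth.reindex(g.index) <= g["ci_high"])
        )
    mean_df = pd.DataFrame(means)
    cover_df = pd.DataFrame(covered)
    out = pd.DataFrame(
        {
            "true": truth.reindex(mean_df.columns),
            "mean_estimate": mean_df.mean(),
            "bias": mean_df.mean() - truth.reindex(mean_df.columns),
            "rmse": np.sqrt(
                ((mean_df - truth.reindex(mean_df.columns)) ** 2).mean()
            ),
            "coverage": cover_df.mean(),
        }
    )
    out.index.name = "predictor"
    return out
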