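"""Repeatability and multimodel inference for maneuvering performance.

The analysis operates on bird-trial means of each performance metric.
Repeatability (the intraclass correlation coefficient, ICC) comes from
an intercept-only mixed model with a random intercept per bird:
ICC = sigma2_among / (sigma2_among + sigma2_residual), with confidence
intervals by parametric bootstrap.  Variation among individuals is then
related to burst muscle capacity and morphology with a set of eight
candidate mixed-effects models compared by AICc; supported models
(delta AICc < 2) are averaged with renormalized Akaike weights.

Burst muscle capacity enters as *residual* burst: the residual of load
lifted after regressing out wing aspect ratio and capture site, which
isolates muscle capacity from wing morphology.

Variance components for the ICC use restricted maximum likelihood;
model comparison refits by full maximum likelihood (AICc requires it).
Continuous predictors are z-scored before fitting, so the reported
coefficients are standardized betas; categorical terms stay as
indicator contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

logger = logging.getLogger("flightmaneuvers")

__all__ = [
    "trim_outliers",
    "trial_means",
    "repeatability",
    "RepeatabilityEstimate",
    "residual_burst",
    "aspect_ratio",
    "candidate_models",
    "fit_and_select",
    "ModelSupportSummary",
    "grubbs_outliers",
    "METRICS_WITH_DAYS_EFFECT",
]

#: metrics whose candidate models carry a days-post-capture fixed effect
METRICS_WITH_DAYS_EFFECT = frozenset(
    {"Vel_max", "AccHor_max", "DecHor_max", "Arc_vel_avg", "Arc_cent_max"}
)

CONTINUOUS_PREDICTORS = ("body_mass", "burst", "wing_length", "aspect_ratio", "days_post_capture")


def trim_outliers(values: np.ndarray, k: float = 5.0) -> tuple[np.ndarray, int]:
    """Drop values more than ``k`` SDs from the pooled mean (single pass).

    Guards the pooled metric samples against extreme tracking errors;
    with ``k = 5`` the removed fraction on clean data is negligible.
    Mean and SD are taken from the full input sample.  Returns the
    retained values and the number removed.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or not np.isfinite(k):
        return x, 0
    sd = x.std(ddof=1)
    if sd == 0:
        return x, 0
    keep = np.abs(x - x.mean()) <= k * sd
    return x[keep], int((~keep).sum())


def trial_means(
    maneuver_table: pd.DataFrame,
    metadata: pd.DataFrame,
    trim_sd: float = 5.0,
) -> pd.DataFrame:
    """Aggregate a long maneuver table to one record per bird-trial.

    ``maneuver_table`` is the long format written by the extraction
    stage (columns ``bird_id, trial_id, maneuver_class, metric,
    value``); ``metadata`` supplies per-trial covariates (``bird_id,
    trial_id, competitor, experiment, days_post_capture``).  Metric
    values are pooled per metric and trimmed at ``trim_sd`` SDs before
    averaging.  PRT_pct is the per-trial share of pitch-roll turns
    among complex turns (NaN when a trial has none).
    """
    df = maneuver_table.copy()
    records = metadata.drop_duplicates(["bird_id", "trial_id"]).set_index(
        ["bird_id", "trial_id"]
    )
    out = records.copy()
    for metric, sub in df.groupby("metric"):
        vals = sub["value"].to_numpy(dtype=float)
        kept, n_removed = trim_outliers(vals, trim_sd)
        if n_removed:
            logger.info("trimmed %d extreme values of %s", n_removed, metric)
            sd = np.nanstd(vals, ddof=1)
            mean = np.nanmean(vals)
            sub = sub[np.abs(sub["value"] - mean) <= trim_sd * sd]
        out[metric] = sub.groupby(["bird_id", "trial_id"])["value"].mean()
    counts = (
        df.drop_duplicates(["bird_id", "trial_id", "maneuver_class", "start_frame", "object_id"])
        if "start_frame" in df.columns and "object_id" in df.columns
        else df
    )
    complex_counts = (
        counts[counts["maneuver_class"].isin(["pitchRollTurn", "arcingTurn"])]
        .groupby(["bird_id", "trial_id", "maneuver_class"])
        .size()
        .unstack(fill_value=0)
    )
    if not complex_counts.empty:
        n_prt = complex_counts.get("pitchRollTurn", 0)
        n_arc = complex_counts.get("arcingTurn", 0)
        out["PRT_pct"] = n_prt / (n_prt + n_arc)
    else:
        out["PRT_pct"] = np.nan
    return out.reset_index()


@dataclass
class RepeatabilityEstimate:
    """ICC point estimate, bootstrap CI, and qualitative classification."""

    metric: str
    icc: float
    ci_low: float
    ci_high: float
    n_birds: int
    n_records: int
    among_variance: float
    residual_variance: float
    n_boot: int
    converged: bool = True

    @property
    def classification(self) -> str:
        """High > 0.70, moderate 0.40-0.70, low < 0.40; 'not repeatable'
        when the CI reaches zero."""
        if self.ci_low <= 1e-6:
            return "not repeatable"
        if self.icc > 0.70:
            return "high"
        if self.icc >= 0.40:
            return "moderate"
        return "low"


def _fit_intercept_only(y: np.ndarray, groups: np.ndarray) -> tuple[float, float, float, bool]:
    """(mu, sigma2_among, sigma2_resid, converged) by REML.

    The one-way random-intercept model admits a profiled REML criterion
    in the single variance ratio lambda = sigma2_among / sigma2_resid:
    given lambda, the GLS mean and the residual variance have closed
    forms, so the fit reduces to a bounded one-dimensional optimization.
    This is exact (no matrix optimizer to stall) and fast enough to
    refit thousands of parametric-bootstrap replicates.
    """
    y = np.asarray(y, dtype=float)
    _, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    n = len(y)
    means = np.bincount(inv, weights=y) / counts
    ssw = float(np.sum(y**2) - np.sum(counts * means**2))
    if np.var(y) < 1e-24:  # degenerate: a constant response
        return float(np.mean(y)), 0.0, 0.0, True

    def profile(lam: float) -> tuple[float, float, float]:
        """(criterion, mu, sigma2_resid) at a fixed variance ratio."""
        d = 1.0 + lam * counts
        w = counts / d
        mu = float(np.sum(w * means) / np.sum(w))
        q = ssw + float(np.sum(counts * (means - mu) ** 2 / d))
        s2e = max(q, 1e-300) / (n - 1)
        crit = (n - 1) * np.log(s2e) + float(np.sum(np.log(d))) + np.log(np.sum(w))
        return crit, mu, s2e

    res = minimize_scalar(
        lambda t: profile(np.exp(t))[0], bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    crit, mu, s2e = profile(lam)
    crit0, mu0, s2e0 = profile(0.0)
    if crit0 <= crit:  # boundary solution: no among-individual variance
        return mu0, 0.0, s2e0, True
    return mu, lam * s2e, s2e, bool(res.success)


def repeatability(
    records: pd.DataFrame,
    metric: str,
    n_boot: int = 5000,
    seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> RepeatabilityEstimate:
    """Repeatability of one metric across each bird's trials.

    Fits the intercept-only random-intercept model by REML and reports
    ICC = among / (among + residual) variance.  The CI is a percentile
    interval from a parametric bootstrap: ``n_boot`` datasets are
    simulated from the fitted model (new bird intercepts and residuals)
    and refit.  Requires repeated measures: at least two records for at
    least two birds.
    """
    sub = records[["bird_id", metric]].dropna()
    y = sub[metric].to_numpy(dtype=float)
    birds = sub["bird_id"].to_numpy()
    uniq, counts = np.unique(birds, return_counts=True)
    if len(uniq) < 2 or not np.any(counts >= 2):
        raise ValueError(
            f"repeatability of {metric} needs repeated measures of >= 2 birds"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, among, resid, converged = _fit_intercept_only(y, birds)
    total = among + resid
    icc = among / total if total > 0 else 0.0

    boot = np.empty(n_boot)
    bird_index = {b: i for i, b in enumerate(uniq)}
    idx = np.array([bird_index[b] for b in birds])
    sd_among, sd_resid = np.sqrt(among), np.sqrt(resid)
    for it in range(n_boot):
        b_star = rng.normal(0.0, sd_among, len(uniq))
        y_star = mu + b_star[idx] + rng.normal(0.0, sd_resid, len(y))
        _, a_s, r_s, _ = _fit_intercept_only(y_star, birds)
        boot[it] = a_s / (a_s + r_s) if a_s + r_s > 0 else 0.0
    alpha = 1.0 - ci_level
    if n_boot > 0:
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo, hi = np.nan, np.nan
    return RepeatabilityEstimate(
        metric=metric,
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        n_birds=len(uniq),
        n_records=len(y),
        among_variance=among,
        residual_variance=resid,
        n_boot=n_boot,
        converged=converged,
    )


def aspect_ratio(wing_length: float, wing_area: float) -> float:
    """Wing aspect ratio, AR = 4 L^2 / S (single-wing length and area)."""
    wing_length = np.asarray(wing_length, dtype=float)
    wing_area = np.asarray(wing_area, dtype=float)
    if np.any(wing_length <= 0) or np.any(wing_area <= 0):
        raise ValueError("wing length and area must be positive")
    return 4.0 * wing_length**2 / wing_area


def residual_burst(traits: pd.DataFrame, site_column: str = "experiment") -> np.ndarray:
    """Residual load-lifting capacity, controlling aspect ratio and site.

    Ordinary least squares of ``load_lifted`` on ``aspect_ratio`` plus
    site indicators; the residuals isolate burst muscle capacity from
    wing shape and between-site differences, and sum to zero within
    each site.
    """
    needed = {"load_lifted", "aspect_ratio", site_column}
    if not needed.issubset(traits.columns):
        raise ValueError(f"traits table must contain columns {sorted(needed)}")
    site = pd.get_dummies(traits[site_column], drop_first=True, dtype=float)
    X = np.column_stack(
        [np.ones(len(traits)), traits["aspect_ratio"].to_numpy(dtype=float), site.to_numpy()]
    )
    if len(traits) <= X.shape[1]:
        raise ValueError("fewer birds than regression parameters")
    y = traits["load_lifted"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class LMMFit:
    """Maximum-likelihood fit of a random-intercept linear mixed model."""

    fe_params: np.ndarray
    bse_fe: np.ndarray
    cov_re: float  # random-intercept variance
    scale: float  # residual variance
    llf: float
    converged: bool


def _fit_lmm_ml(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> LMMFit:
    """Fit y = X beta + b_group + e by maximum likelihood.

    With a single random intercept the covariance is sigma2_e (I + lambda
    Z Z'), so both the GLS estimate of beta and the profiled sigma2_e are
    closed forms in the variance ratio lambda; the fit is a bounded 1-D
    optimization over log lambda, using only per-group sums.  Exact and
    orders of magnitude faster than a general mixed-model optimizer.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    _, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group sums of rows of X and of y
    Sx = np.zeros((len(counts), p))
    for j in range(p):
        Sx[:, j] = np.bincount(inv, weights=X[:, j])
    Sy = np.bincount(inv, weights=y)

    def profile(lam: float):
        c = lam / (1.0 + lam * counts)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(A, b)
        q = yty - float(np.sum(c * Sy**2)) - 2.0 * float(beta @ b) + float(beta @ A @ beta)
        # q = (y - X beta)' Vtilde^-1 (y - X beta); guard rounding
        q = max(q, 1e-12 * (1.0 + yty))
        s2 = q / n
        dev = n * np.log(s2) + float(np.sum(np.log1p(lam * counts)))
        return dev, beta, s2, A

    res = minimize_scalar(
        lambda t: profile(np.exp(t))[0], bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    dev, beta, s2, A = profile(lam)
    dev0, beta0, s20, A0 = profile(0.0)
    if dev0 <= dev:
        lam, dev, beta, s2, A = 0.0, dev0, beta0, s20, A0
    llf = -0.5 * (n * np.log(2.0 * np.pi) + dev + n)
    cov_beta = s2 * np.linalg.inv(A)
    return LMMFit(
        fe_params=beta,
        bse_fe=np.sqrt(np.diag(cov_beta)),
        cov_re=lam * s2,
        scale=s2,
        llf=float(llf),
        converged=bool(res.success),
    )


#: the eight candidate fixed-effect structures; all non-null models also
#: include competitor presence, experiment, and body mass
CANDIDATE_MODELS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("wing size", ("wing_length",)),
    ("wing shape", ("aspect_ratio",)),
    ("wing size & shape", ("wing_length", "aspect_ratio")),
    ("burst", ("burst",)),
    ("burst & wing size", ("burst", "wing_length")),
    ("burst & wing shape", ("burst", "aspect_ratio")),
    ("burst, wing size & shape", ("burst", "wing_length", "aspect_ratio")),
    ("intercept-only", ()),
)


def candidate_models(metric: str) -> list[dict]:
    """The candidate model set for one performance metric.

    Each entry lists the fixed-effect columns (besides the intercept).
    Five metrics additionally carry days post-capture in every non-null
    model.  All models have a bird random intercept.
    """
    from .core_io import CLASS_METRICS

    known = {m for metrics in CLASS_METRICS.values() for m in metrics} | {"PRT_pct"}
    if metric not in known:
        raise ValueError(f"unknown performance metric {metric!r}")
    base = ["competitor", "body_mass"]
    if metric in METRICS_WITH_DAYS_EFFECT:
        base.append("days_post_capture")
    out = []
    for name, extra in CANDIDATE_MODELS:
        if name == "intercept-only":
            out.append({"name": name, "predictors": []})
        else:
            out.append({"name": name, "predictors": base + list(extra) + ["experiment"]})
    return out


@dataclass
class ModelSupportSummary:
    """AICc table plus averages over the supported model set."""

    metric: str
    table: pd.DataFrame
    coefficients: dict[str, dict[str, float]]
    relative_importance: dict[str, float]
    r2_marginal: float
    best_model: str
    support: list[str]
    random_intercept_variance: float
    residual_variance: float
    n_records: int
    dropped: list[str] = field(default_factory=list)


def _design_matrix(data: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for p in predictors:
        if p == "experiment":
            dummies = pd.get_dummies(data["experiment"], drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
                names.append(f"experiment[{c}]")
        else:
            cols.append(data[p].to_numpy(dtype=float))
            names.append(p)
    return np.column_stack(cols), names


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_and_select(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    metric: str,
    of_interest_exclude: tuple[str, ...] = ("experiment", "days_post_capture"),
) -> ModelSupportSummary:
    """Fit the candidate models for one metric and summarize support.

    Records are joined with bird traits, continuous predictors are
    z-scored (so coefficients are standardized betas), and each
    candidate is fit by maximum likelihood with a bird random intercept.
    Models within 2 AICc of the best form the support set; coefficients
    are averaged over the supported models containing them, weighted by
    renormalized Akaike weights, with unconditional (between-model)
    variance folded into the CIs.  Relative importance of a predictor is
    the summed weight of supported models containing it.  Marginal R^2
    is the variance of the fixed-effect predictions over the total
    (fixed + random intercept + residual) variance, computed with the
    nuisance effects (experiment, days post-capture) zeroed out.
    """
    data = records.merge(
        traits[["bird_id", "body_mass", "wing_length", "aspect_ratio", "residual_burst"]],
        on="bird_id",
        how="left",
    ).rename(columns={"residual_burst": "burst"})
    data = data.dropna(subset=[metric]).reset_index(drop=True)
    n = len(data)
    for p in CONTINUOUS_PREDICTORS:
        if p in data.columns:
            sd = data[p].std(ddof=1)
            data[p] = (data[p] - data[p].mean()) / (sd if sd > 0 else 1.0)
    y = data[metric].to_numpy(dtype=float)
    groups = data["bird_id"].to_numpy()

    fits = []
    dropped = []
    for spec in candidate_models(metric):
        X, names = _design_matrix(data, spec["predictors"])
        try:
            res = _fit_lmm_ml(y, X, groups)
        except np.linalg.LinAlgError as err:
            logger.warning("model %r dropped (singular fit): %s", spec["name"], err)
            dropped.append(spec["name"])
            continue
        k = X.shape[1] + 2  # fixed effects + random-intercept and residual variances
        fits.append(
            {
                "name": spec["name"],
                "names": names,
                "X": X,
                "res": res,
                "k": k,
                "llf": float(res.llf),
                "aicc": _aicc(float(res.llf), k, n),
            }
        )
    if not fits:
        raise RuntimeError(f"no candidate model for {metric} could be fit")

    best_aicc = min(f["aicc"] for f in fits)
    for f in fits:
        f["delta"] = f["aicc"] - best_aicc
    rel = np.array([np.exp(-0.5 * f["delta"]) for f in fits])
    weights = rel / rel.sum()
    for f, w in zip(fits, weights):
        f["weight"] = float(w)
        f["supported"] = f["delta"] < 2.0

    support = [f for f in fits if f["supported"]]
    w_support = np.array([f["weight"] for f in support])
    w_support = w_support / w_support.sum()
    for f, w in zip(support, w_support):
        f["w_renorm"] = float(w)

    # averaged standardized coefficients over the supported models
    coefficients: dict[str, dict[str, float]] = {}
    importance: dict[str, float] = {}
    all_names: list[str] = []
    for f in support:
        for name in f["names"]:
            if name not in all_names:
                all_names.append(name)
    for name in all_names:
        holders = [f for f in support if name in f["names"]]
        w = np.array([f["w_renorm"] for f in holders])
        w = w / w.sum()
        est = np.array([float(f["res"].fe_params[f["names"].index(name)]) for f in holders])
        var = np.array(
            [float(f["res"].bse_fe[f["names"].index(name)]) ** 2 for f in holders]
        )
        avg = float(np.sum(w * est))
        # unconditional variance: within-model plus between-model spread
        se = float(np.sqrt(np.sum(w * (var + (est - avg) ** 2))))
        coefficients[name] = {
            "estimate": avg,
            "se": se,
            "ci_low": avg - 1.96 * se,
            "ci_high": avg + 1.96 * se,
        }
        if name != "intercept":
            importance[name.split("[")[0]] = float(
                sum(f["w_renorm"] for f in holders)
            )

    # marginal R^2 restricted to the effects of interest
    r2_terms = []
    for f in support:
        params = np.array(f["res"].fe_params, dtype=float)
        zeroed = params.copy()
        for i, name in enumerate(f["names"]):
            base = name.split("[")[0]
            if base in of_interest_exclude or name == "intercept":
                zeroed[i] = 0.0
        pred = f["X"] @ zeroed
        var_f = float(np.var(pred))
        total = var_f + f["res"].cov_re + f["res"].scale
        r2_terms.append((f["w_renorm"], var_f / total if total > 0 else 0.0))
    r2_marginal = float(sum(w * r for w, r in r2_terms))

    best = min(fits, key=lambda f: f["aicc"])
    table = pd.DataFrame(
        {
            "model": [f["name"] for f in fits],
            "k": [f["k"] for f in fits],
            "loglik": [f["llf"] for f in fits],
            "AICc": [f["aicc"] for f in fits],
            "delta_AICc": [f["delta"] for f in fits],
            "weight": [f["weight"] for f in fits],
            "supported": [f["supported"] for f in fits],
        }
    ).sort_values("AICc", ignore_index=True)
    return ModelSupportSummary(
        metric=metric,
        table=table,
        coefficients=coefficients,
        relative_importance=importance,
        r2_marginal=r2_marginal,
        best_model=best["name"],
        support=[f["name"] for f in support],
        random_intercept_variance=best["res"].cov_re,
        residual_variance=float(best["res"].scale),
        n_records=n,
        dropped=dropped,
    )


def grubbs_outliers(values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, list[float]]:
    """Iterative two-sided Grubbs test for single outliers.

    Repeatedly tests the most extreme remaining value against the
    Grubbs critical value at level ``alpha`` and removes it while
    significant.  Returns a boolean outlier mask aligned with the input
    and the G statistics of the flagged values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    active = np.ones(x.size, dtype=bool)
    flagged: list[float] = []
    while active.sum() >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_rel = int(np.argmax(dev))
        g = dev[i_rel] / sd
        n = sub.size
        t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        if g <= g_crit:
            break
        idx = np.flatnonzero(active)[i_rel]
        active[idx] = False
        flagged.append(float(g))
    return ~active, flagged
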