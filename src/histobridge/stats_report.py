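"""Group-level inference for cohort histomorphometry tables.

Per parameter (and ROI and timepoint) a linear mixed model is fitted with
treatment as the fixed effect and animal ID as a random intercept — the
appropriate design when every animal carries several differently treated
defects. All pairwise treatment contrasts are tested with a single-step
Tukey-type adjustment: the adjusted p-value of a contrast is the probability
that the maximum absolute component of a multivariate t vector (with the
contrasts' estimated correlation) exceeds the observed |t|.

Estimation is REML via statsmodels MixedLM. When the animal variance
component collapses to zero (a singular fit), the model falls back to
ordinary least squares with a warning; in the balanced two-group case this
reduces the adjusted p exactly to the two-sample pooled t-test. Degrees of
freedom use a containment-style rule, df = N - rank(X) - (n_animals - 1),
tagged in the output so alternative conventions can be compared.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = [
    "ContrastResult",
    "MixedModelFit",
    "fit_mixed_model",
    "summarise",
    "simulate_cohort_values",
    "apply_exclusions",
    "plot_group_summary",
]


@dataclass
class ContrastResult:
    """One pairwise treatment contrast (first minus second)."""

    pair: tuple[str, str]
    estimate: float
    se: float
    df: float
    t: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    adjustment: str = "tukey-single-step"


@dataclass
class MixedModelFit:
    """Fitted per-parameter model: fixed effects, variance, contrasts."""

    parameter: Optional[str]
    roi: Optional[str]
    timepoint: Optional[int]
    group_means: dict[str, float]
    n_per_group: dict[str, int]
    animal_variance: float
    residual_variance: float
    contrasts: list[ContrastResult] = field(default_factory=list)
    method: str = "REML mixed model (random animal intercept)"
    df_method: str = "containment"
    fallback_ols: bool = False

    def contrast(self, a: str, b: str) -> ContrastResult:
        for c in self.contrasts:
            if c.pair == (a, b):
                return c
            if c.pair == (b, a):
                return ContrastResult(
                    pair=(a, b),
                    estimate=-c.estimate,
                    se=c.se,
                    df=c.df,
                    t=-c.t,
                    p_adjusted=c.p_adjusted,
                    ci_low=-c.ci_high,
                    ci_high=-c.ci_low,
                    adjustment=c.adjustment,
                )
        raise KeyError((a, b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": self.parameter,
                    "roi": self.roi,
                    "timepoint": self.timepoint,
                    "contrast": f"{c.pair[0]} - {c.pair[1]}",
                    "estimate": c.estimate,
                    "se": c.se,
                    "df": c.df,
                    "t": c.t,
                    "p_adjusted": c.p_adjusted,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "adjustment": c.adjustment,
                }
                for c in self.contrasts
            ]
        )


def _subset(
    table: pd.DataFrame,
    parameter: Optional[str],
    roi: Optional[str],
    timepoint: Optional[int],
) -> pd.DataFrame:
    df = table
    for col, val in (("parameter", parameter), ("roi", roi), ("timepoint", timepoint)):
        if val is not None:
            df = df[df[col] == val]
    df = df.dropna(subset=["value"])
    return df.copy()


def _tukey_p(t_obs: np.ndarray, corr: np.ndarray, df: float) -> np.ndarray:
    """Single-step adjusted p: P(max_k |T_k| >= |t|) for multivariate t."""
    k = corr.shape[0]
    out = np.empty(len(t_obs))
    # jitter the correlation toward PD if estimation made it singular
    corr = corr + 1e-10 * np.eye(k)
    rng = np.random.default_rng(0)  # fixed: QMC integration must be reproducible
    for i, t in enumerate(np.abs(t_obs)):
        if not np.isfinite(t):
            out[i] = np.nan
            continue
        if t == 0:
            out[i] = 1.0
            continue
        if k == 1:  # a single contrast: the exact two-sided t probability
            out[i] = float(2.0 * stats.t.sf(t, max(df, 1.0)))
            continue
        inside = stats.multivariate_t.cdf(
            np.full(k, t),
            shape=corr,
            df=max(df, 1.0),
            lower_limit=np.full(k, -t),
            allow_singular=True,
            random_state=rng,
        )
        out[i] = float(np.clip(1.0 - inside, 0.0, 1.0))
    return out


def fit_mixed_model(
    table: pd.DataFrame,
    parameter: Optional[str] = None,
    roi: Optional[str] = None,
    timepoint: Optional[int] = None,
) -> MixedModelFit:
    """Fit value ~ treatment with a random animal intercept; Tukey contrasts.

    ``table`` is a tidy cohort table with columns ``animal_id``,
    ``treatment``, ``value`` and optionally ``parameter``, ``roi``,
    ``timepoint`` used for sub-setting.
    """
    df = _subset(table, parameter, roi, timepoint)
    counts = df.groupby("treatment")["value"].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least two treatments with two observations each")
    treatments = sorted(df["treatment"].unique())
    df["treatment"] = pd.Categorical(df["treatment"], categories=treatments)

    n = len(df)
    n_animals = df["animal_id"].nunique()
    k = len(treatments)

    fallback = False
    animal_var = 0.0
    values_constant = df["value"].nunique() == 1
    if values_constant:
        # degenerate data: zero variance everywhere, no model to fit
        fallback = True
        beta = np.zeros(k)
        beta[:] = df["value"].iloc[0]
        cov = np.zeros((k, k))
        resid_var = 0.0
        dof = float(n - k)
        means = {t: float(df["value"].iloc[0]) for t in treatments}
    else:
        singleton_animals = df.groupby("animal_id").size().max() == 1
        if not singleton_animals:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = smf.mixedlm(
                    "value ~ C(treatment)", df, groups=df["animal_id"]
                ).fit(reml=True)
            animal_var = float(mixed.cov_re.iloc[0, 0])
        if (
            singleton_animals
            or animal_var < 1e-8 * max(mixed.scale, 1e-300)
            or n_animals < 2
        ):
            warnings.warn(
                "animal variance component is zero; falling back to a "
                "fixed-effects (OLS) model",
                stacklevel=2,
            )
            fallback = True
            ols = smf.ols("value ~ C(treatment)", df).fit()
            fe = ols.params
            fe_cov = ols.cov_params()
            resid_var = float(ols.mse_resid)
            dof = float(ols.df_resid)
            animal_var = 0.0
        else:
            fe = mixed.fe_params
            fe_cov = mixed.cov_params().iloc[: len(fe), : len(fe)]
            resid_var = float(mixed.scale)
            dof = float(max(1, n - k - (n_animals - 1)))
        # treatment means from the treatment-coded design
        design = np.zeros((k, len(fe)))
        design[:, 0] = 1.0
        names = list(fe.index)
        for j, t in enumerate(treatments[1:], start=1):
            col = f"C(treatment)[T.{t}]"
            design[j, names.index(col)] = 1.0
        beta = design @ np.asarray(fe)
        cov = design @ np.asarray(fe_cov) @ design.T
        means = {t: float(beta[j]) for j, t in enumerate(treatments)}

    pairs = list(itertools.combinations(range(k), 2))
    L = np.zeros((len(pairs), k))
    for m, (i, j) in enumerate(pairs):
        L[m, i] = 1.0
        L[m, j] = -1.0
    est = L @ beta
    vcv = L @ cov @ L.T
    se = np.sqrt(np.clip(np.diag(vcv), 0.0, None))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    if np.all(se > 0):
        dd = np.sqrt(np.outer(np.diag(vcv), np.diag(vcv)))
        corr = vcv / dd
        p_adj = _tukey_p(tvals, corr, dof)
    else:
        p_adj = np.where(est == 0.0, 1.0, 0.0)

    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    contrasts = [
        ContrastResult(
            pair=(treatments[i], treatments[j]),
            estimate=float(est[m]),
            se=float(se[m]),
            df=dof,
            t=float(tvals[m]),
            p_adjusted=float(p_adj[m]),
            ci_low=float(est[m] - tcrit * se[m]),
            ci_high=float(est[m] + tcrit * se[m]),
        )
        for m, (i, j) in enumerate(pairs)
    ]
    return MixedModelFit(
        parameter=parameter,
        roi=roi,
        timepoint=timepoint,
        group_means=means,
        n_per_group={t: int(counts.get(t, 0)) for t in treatments},
        animal_variance=animal_var,
        residual_variance=resid_var,
        contrasts=contrasts,
        method=(
            "OLS fixed-effects fallback" if fallback
            else "REML mixed model (random animal intercept)"
        ),
        df_method="residual" if fallback else "containment",
        fallback_ols=fallback,
    )


def summarise(
    table: pd.DataFrame,
    by: Sequence[str] = ("treatment", "timepoint", "roi", "parameter"),
) -> pd.DataFrame:
    """Descriptive per-group means and sds, rounded to 0.1.

    Single observations report a missing (NaN) sd, not 0.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    by = [c for c in by if c in table.columns]
    g = table.groupby(list(by), sort=True, observed=True)["value"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["mean"] = out["mean"].round(1)
    out["sd"] = out["sd"].round(1)
    return out


def apply_exclusions(
    table: pd.DataFrame, exclusions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded defects and keep the bookkeeping.

    ``exclusions`` columns: ``animal_id``, ``treatment``, ``timepoint`` and a
    ``reason``. Returns (filtered table, per-group analysis-n table).
    """
    keys = ["animal_id", "treatment", "timepoint"]
    merged = table.merge(
        exclusions[keys + ["reason"]], on=keys, how="left", validate="many_to_one"
    )
    kept = merged[merged["reason"].isna()].drop(columns="reason")
    n_table = (
        kept.groupby(["treatment", "timepoint"], observed=True)["animal_id"]
        .nunique()
        .rename("n_analysed")
        .reset_index()
    )
    return kept.reset_index(drop=True), n_table


def simulate_cohort_values(
    n_animals: int,
    groups: Sequence[str],
    group_offsets: Optional[dict[str, float]] = None,
    baseline: float = 50.0,
    animal_sd: float = 2.0,
    residual_sd: float = 2.0,
    seed: int = 0,
    parameter: str = "nBV_TV_pct",
    roi: str = "cortical",
    timepoint: int = 6,
) -> pd.DataFrame:
    """Numeric cohort simulation matching the phantom cohort's effect model.

    Each animal receives every group once; value = baseline + group offset +
    animal random intercept + residual noise. This is the distributional
    model `generate_cohort` realises through rendered phantoms, without the
    rendering, and is what power/coverage simulations run on.
    """
    rng = np.random.default_rng(seed)
    offsets = group_offsets or {}
    rows = []
    for i in range(n_animals):
        a = rng.normal(0.0, animal_sd)
        for g in groups:
            rows.append(
                {
                    "animal_id": f"sheep{i + 1:02d}",
                    "treatment": g,
                    "timepoint": timepoint,
                    "roi": roi,
                    "parameter": parameter,
                    "value": baseline
                    + offsets.get(g, 0.0)
                    + a
                    + rng.normal(0.0, residual_sd),
                }
            )
    return pd.DataFrame(rows)


def plot_group_summary(
    table: pd.DataFrame,
    parameter: str,
    roi: str,
    path: Optional[str] = None,
):
    """Grouped box plot of one parameter per treatment and timepoint."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _subset(table, parameter, roi, None)
    timepoints = sorted(df["timepoint"].unique())
    treatments = sorted(df["treatment"].unique())
    fig, axes = plt.subplots(
        1, len(timepoints), figsize=(4 * len(timepoints), 4), squeeze=False
    )
    for ax, tp in zip(axes[0], timepoints):
        sub = df[df["timepoint"] == tp]
        data = [sub[sub["treatment"] == t]["value"].to_numpy() for t in treatments]
        ax.boxplot(data, tick_labels=treatments)
        ax.set_title(f"{parameter} ({roi}), {tp} months")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
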