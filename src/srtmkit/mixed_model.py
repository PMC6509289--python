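"""Compound-symmetry linear mixed model for two-group repeated measures.

The design is the classic small-animal longitudinal layout: each animal is
imaged at every study day, animals are nested in treatment groups, and the
question is whether the *change over time* differs between groups.  The
model is

    value_{a,g,d} = mu_{g,d} + b_a + e_{a,g,d},
    b_a ~ N(0, sigma2_animal),  e ~ N(0, sigma2_resid),

i.e. a saturated group x time cell-mean fixed structure with a per-animal
random intercept.  A random intercept induces a compound-symmetry (CS)
within-animal covariance: equal correlation rho =
sigma2_animal / (sigma2_animal + sigma2_resid) between every pair of
time points.  Estimation is REML by default (ML available).

Contrasts use the fixed-effect covariance with a t reference on the
residual degrees of freedom n_obs - n_cells; this is a deliberate,
documented convention (software packages differ in their denominator-df
defaults).  Pairwise interaction contrasts — difference-in-differences of
cell means between two days and two groups — are the quantity behind a
"rebound" claim: a transient post-treatment rise in the treated group
only.  Raw p-values are reported; a Holm adjustment helper is provided
but not applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DesignError
from .longitudinal import validate_longitudinal

__all__ = [
    "MixedModelFit",
    "ContrastResult",
    "PowerResult",
    "fit_mixed_cs",
    "interaction_contrast",
    "groupwise_comparison",
    "all_pairwise_interaction_contrasts",
    "holm_adjust",
    "run_design_power",
]


@dataclass
class ContrastResult:
    estimate: float
    se: float
    stat: float
    df: float
    pvalue: float
    description: str

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "estimate": self.estimate,
            "se": self.se,
            "stat": self.stat,
            "df": self.df,
            "pvalue": self.pvalue,
        }


@dataclass
class MixedModelFit:
    """Fitted CS mixed model: cell means, their covariance, variance components."""

    cell_means: pd.Series  # indexed by (group, day)
    cov_cells: np.ndarray
    sigma2_animal: float
    sigma2_resid: float
    loglike: float
    reml: bool
    n_obs: int
    df_resid: float
    groups: Tuple[str, ...]
    days: Tuple[float, ...]
    balanced: bool
    converged: bool
    method: str  # "reml", "ml" or "degenerate"

    @property
    def rho(self) -> float:
        total = self.sigma2_animal + self.sigma2_resid
        return self.sigma2_animal / total if total > 0 else 0.0

    def cell_index(self, group, day) -> int:
        key = (group, day)
        labels = list(self.cell_means.index)
        if key not in labels:
            raise KeyError(f"no cell for group={group!r}, day={day!r}")
        return labels.index(key)

    def to_dict(self) -> dict:
        return {
            "cell_means": {f"{g}:{d}": float(v) for (g, d), v in self.cell_means.items()},
            "sigma2_animal": self.sigma2_animal,
            "sigma2_resid": self.sigma2_resid,
            "rho": self.rho,
            "loglike": self.loglike,
            "method": self.method,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "balanced": self.balanced,
            "converged": self.converged,
        }


def _check_design(table: pd.DataFrame) -> None:
    days = table["day"].unique()
    if len(days) < 2:
        raise DesignError("need at least 2 time points")
    per_group = table.groupby("group")["animal_id"].nunique()
    if len(per_group) < 1:
        raise DesignError("no groups in table")
    if (per_group < 2).any():
        bad = per_group[per_group < 2].index.tolist()
        raise DesignError(f"groups with fewer than 2 animals: {bad}")
    days_per_group = table.groupby("group")["day"].nunique()
    if (days_per_group < 2).any():
        bad = days_per_group[days_per_group < 2].index.tolist()
        raise DesignError(f"groups observed at a single time point: {bad}")


def fit_mixed_cs(table: pd.DataFrame, reml: bool = True) -> MixedModelFit:
    """REML fit of value ~ group x time cell means + per-animal random intercept.

    Balancedness is checked and reported, not required; missing cells are
    handled by the general mixed-model machinery.  Data whose within-cell
    residual variation is numerically zero (exact cell-mean tables, as
    produced by a zero-variance generator) short-circuit to the exact
    least-squares solution with zero variance components, which REML
    cannot profile.
    """
    validate_longitudinal(table)
    _check_design(table)
    table = table.sort_values(["group", "animal_id", "day"], kind="stable").reset_index(drop=True)
    groups = tuple(sorted(table["group"].unique()))
    days = tuple(sorted(table["day"].unique()))
    observed_cells = set(map(tuple, table[["group", "day"]].itertuples(index=False)))
    cells = [(g, d) for g in groups for d in days if (g, d) in observed_cells]
    index = pd.MultiIndex.from_tuples(cells, names=["group", "day"])

    counts = table.groupby(["group", "day"]).size()
    balanced = len(cells) == len(groups) * len(days) and counts.nunique() == 1

    y = table["value"].to_numpy(dtype=float)
    n_obs = y.size
    k = len(cells)
    exog = np.zeros((n_obs, k))
    col = {c: j for j, c in enumerate(cells)}
    for i, (g, d) in enumerate(zip(table["group"], table["day"])):
        exog[i, col[(g, d)]] = 1.0
    df_resid = float(n_obs - k)

    cell_avg = table.groupby(["group", "day"])["value"].mean()
    resid = y - np.array([cell_avg[(g, d)] for g, d in zip(table["group"], table["day"])])
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        # exact cell-mean data: variance components are zero by construction
        means = pd.Series([cell_avg[c] for c in cells], index=index, name="mean")
        return MixedModelFit(
            cell_means=means,
            cov_cells=np.zeros((k, k)),
            sigma2_animal=0.0,
            sigma2_resid=0.0,
            loglike=np.inf,
            reml=reml,
            n_obs=n_obs,
            df_resid=df_resid,
            groups=groups,
            days=days,
            balanced=bool(balanced),
            converged=True,
            method="degenerate",
        )

    from statsmodels.regression.mixed_linear_model import MixedLM

    model = MixedLM(y, exog, groups=table["animal_id"].to_numpy())
    res = None
    last_exc = None
    for method in (["bfgs"], ["cg"], ["powell"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method)
            break
        except np.linalg.LinAlgError as exc:  # optimiser walked into a singular V
            last_exc = exc
    if res is None:
        raise DesignError(f"mixed model estimation failed: {last_exc}")
    fe = np.asarray(res.fe_params, dtype=float)
    cov_fe = np.asarray(res.cov_params())[:k, :k]
    means = pd.Series(fe, index=index, name="mean")
    return MixedModelFit(
        cell_means=means,
        cov_cells=cov_fe,
        sigma2_animal=float(np.asarray(res.cov_re)[0, 0]),
        sigma2_resid=float(res.scale),
        loglike=float(res.llf),
        reml=reml,
        n_obs=n_obs,
        df_resid=df_resid,
        groups=groups,
        days=days,
        balanced=bool(balanced),
        converged=bool(res.converged),
        method="reml" if reml else "ml",
    )


def _contrast(fit: MixedModelFit, L: np.ndarray, description: str) -> ContrastResult:
    est = float(L @ fit.cell_means.to_numpy())
    var = float(L @ fit.cov_cells @ L)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        stat = np.inf if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        stat = est / se
        p = 2.0 * sps.t.sf(abs(stat), fit.df_resid)
    return ContrastResult(est, se, stat, fit.df_resid, float(p), description)


def interaction_contrast(
    fit: MixedModelFit, group_a, group_b, day_1, day_2
) -> ContrastResult:
    """Difference-in-differences (mu_a,d2 - mu_a,d1) - (mu_b,d2 - mu_b,d1).

    Two-sided t test on the residual degrees of freedom; a positive
    estimate means group_a's change from day_1 to day_2 exceeds
    group_b's.
    """
    L = np.zeros(len(fit.cell_means))
    L[fit.cell_index(group_a, day_2)] += 1.0
    L[fit.cell_index(group_a, day_1)] -= 1.0
    L[fit.cell_index(group_b, day_2)] -= 1.0
    L[fit.cell_index(group_b, day_1)] += 1.0
    return _contrast(
        fit, L, f"({group_a}: d{day_2}-d{day_1}) - ({group_b}: d{day_2}-d{day_1})"
    )


def groupwise_comparison(
    fit: MixedModelFit, day, group_a=None, group_b=None
) -> ContrastResult:
    """Between-group difference mu_a,day - mu_b,day at one time point."""
    if group_a is None or group_b is None:
        if len(fit.groups) != 2:
            raise KeyError("specify group_a and group_b for designs with != 2 groups")
        group_a, group_b = fit.groups
    L = np.zeros(len(fit.cell_means))
    L[fit.cell_index(group_a, day)] += 1.0
    L[fit.cell_index(group_b, day)] -= 1.0
    return _contrast(fit, L, f"{group_a} - {group_b} at day {day}")


def all_pairwise_interaction_contrasts(
    fit: MixedModelFit, group_a=None, group_b=None
) -> pd.DataFrame:
    """Interaction contrasts for every pair of study days, as a table."""
    if group_a is None or group_b is None:
        if len(fit.groups) != 2:
            raise KeyError("specify group_a and group_b for designs with != 2 groups")
        group_a, group_b = fit.groups
    rows = []
    for d1, d2 in combinations(fit.days, 2):
        c = interaction_contrast(fit, group_a, group_b, d1, d2)
        rows.append({"day_1": d1, "day_2": d2, **c.to_dict()})
    return pd.DataFrame(rows)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; raw p-values are the default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


@dataclass
class PowerResult:
    rejection_rate: float
    ci_low: float
    ci_high: float
    n_rejected: int
    n_replicates: int
    alpha: float
    mean_estimate: float

    def to_dict(self) -> dict:
        return {
            "rejection_rate": self.rejection_rate,
            "ci_99_low": self.ci_low,
            "ci_99_high": self.ci_high,
            "n_rejected": self.n_rejected,
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "mean_estimate": self.mean_estimate,
        }


def run_design_power(
    cell_means: dict,
    sigma_animal: float,
    sigma_resid: float,
    n_per_group: int = 4,
    n_replicates: int = 200,
    seed: int = 0,
    contrast: Tuple = None,
    alpha: float = 0.05,
    reml: bool = True,
) -> PowerResult:
    """Monte-Carlo rejection rate of an interaction contrast under a design.

    Simulates tables from the CS generator (``cell_means`` maps
    (group, day) to the cell mean), fits the mixed model and tests the
    requested contrast ``(group_a, group_b, day_1, day_2)`` at ``alpha``.
    With zero effect the rate estimates the type-I error; with an
    injected offset it estimates power.  Fully reproducible given
    ``seed``.  The 99% Clopper-Pearson interval bounds Monte-Carlo
    uncertainty.
    """
    if n_replicates < 1:
        raise DesignError("need at least one replicate")
    from .synthetic import make_longitudinal_dataset

    groups = sorted({g for g, _ in cell_means})
    days = sorted({d for _, d in cell_means})
    if contrast is None:
        if len(groups) != 2 or len(days) < 2:
            raise DesignError("default contrast needs 2 groups and >= 2 days")
        contrast = (groups[0], groups[1], days[0], days[1])
    ga, gb, d1, d2 = contrast
    rng = np.random.default_rng(seed)
    n_rej = 0
    estimates = np.empty(n_replicates)
    for r in range(n_replicates):
        table = make_longitudinal_dataset(
            cell_means=cell_means,
            n_per_group=n_per_group,
            sigma_animal=sigma_animal,
            sigma_resid=sigma_resid,
            seed=rng.integers(0, 2**31 - 1),
        )
        fit = fit_mixed_cs(table, reml=reml)
        c = interaction_contrast(fit, ga, gb, d1, d2)
        estimates[r] = c.estimate
        if c.pvalue < alpha:
            n_rej += 1
    rate = n_rej / n_replicates
    ci = sps.binomtest(n_rej, n_replicates).proportion_ci(confidence_level=0.99)
    return PowerResult(
        rejection_rate=rate,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_rejected=n_rej,
        n_replicates=n_replicates,
        alpha=alpha,
        mean_estimate=float(estimates.mean()),
    )
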