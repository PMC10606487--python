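"""Linkage tests on sib pairs.

The workhorse is Haseman-Elston regression: the squared within-pair
phenotype difference is regressed on the expected number of alleles shared
IBD at a marker; under linkage the slope is negative (sibs sharing more
alleles resemble each other more).  The same relationship is summarised as
a Pearson correlation with its exact t-transform p-value, optionally
adjusted for pair covariates (mean age, number of males) in a standardized
multiple regression, and complemented by a non-parametric allele-sharing
likelihood-ratio test with a permutation p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .ascertainment import classify_pair
from .models import (
    EdspError,
    IBDPosterior,
    MarkerMap,
    SIB_IBD_PRIOR,
    SelectionCriteria,
    SibPairRecord,
)

log = logging.getLogger(__name__)


class UndefinedCorrelationError(EdspError):
    """Correlation undefined because a variable is constant."""


@dataclass(frozen=True)
class HEResult:
    """Haseman-Elston regression output for one marker/phenotype."""

    n_pairs: int
    intercept: float
    slope: float
    slope_se: float
    t_stat: float
    p_one_sided: float      # H1: slope < 0
    pearson_r: float
    p_two_sided: float


@dataclass(frozen=True)
class AdjustedModelResult:
    """Standardized multiple regression (Table-3-style)."""

    terms: tuple[str, ...]
    betas: tuple[float, ...]
    p_values: tuple[float, ...]
    adjusted_r2: float
    n: int

    def beta(self, term: str) -> float:
        return self.betas[self.terms.index(term)]

    def p(self, term: str) -> float:
        return self.p_values[self.terms.index(term)]


@dataclass(frozen=True)
class SharingLRTResult:
    """Allele-sharing likelihood-ratio test at one marker."""

    z_hat: tuple[float, float, float]
    lr_stat: float
    p_perm: float
    n_perm: int
    seed: int
    n_pairs: int


def squared_trait_difference(pair: SibPairRecord, phenotype: str) -> float:
    """Squared sib difference of one phenotype (mmHg^2)."""
    return pair.squared_difference(phenotype)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform
    ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(abs(t), n - 2)


def pearson_linkage_test(y, x) -> tuple[float, float]:
    """Pearson correlation between squared differences and IBD sharing,
    with its two-sided t-based p-value."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n != len(x):
        raise ValueError("y and x must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: constant variable")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, pearson_p_from_r(r, n)


def haseman_elston(y, x) -> HEResult:
    """OLS of squared phenotype differences on expected IBD sharing.

    The one-sided p-value tests H1: slope < 0 on n-2 degrees of freedom;
    Pearson correlation output is embedded.  Using the sharing proportion
    (pihat) instead of the expected allele count rescales the slope by 2
    but leaves r, t and all p-values unchanged.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    r, p_two = pearson_linkage_test(y, x)
    n = len(y)
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if se == 0.0:  # perfect fit
        t_stat = -math.inf if slope < 0 else math.inf
        p_one = 0.0 if slope < 0 else 1.0
    else:
        t_stat = slope / se
        p_one = float(stats.t.cdf(t_stat, n - 2))
    return HEResult(n_pairs=n, intercept=float(fit.params[0]), slope=slope,
                    slope_se=se, t_stat=t_stat, p_one_sided=p_one,
                    pearson_r=r, p_two_sided=p_two)


_COLLINEARITY_COND_MAX = 1e8


def adjusted_regression(y, covariates: dict[str, Sequence[float]],
                        ) -> AdjustedModelResult:
    """Multiple OLS with z-scored response and predictors.

    ``covariates`` maps term name to values (the marker sharing variable
    plus confounders such as pair mean age and number of males); reports
    standardized betas, per-term p-values and the adjusted R^2.
    """
    y = np.asarray(y, dtype=float)
    terms = tuple(covariates)
    n = len(y)
    if n <= len(terms) + 1:
        raise ValueError("need n > number of terms + 1")
    cols = []
    for name in terms:
        v = np.asarray(covariates[name], dtype=float)
        if len(v) != n:
            raise ValueError(f"covariate {name!r} has wrong length")
        sd = v.std(ddof=1)
        if sd == 0.0:
            raise EdspError(f"collinear design: constant term {name!r}")
        cols.append((v - v.mean()) / sd)
    X = np.column_stack(cols)
    if np.linalg.cond(X.T @ X) > _COLLINEARITY_COND_MAX:
        raise EdspError(
            f"collinear design among terms {list(terms)}")
    sd_y = y.std(ddof=1)
    if sd_y == 0.0:
        raise EdspError("response is constant")
    yz = (y - y.mean()) / sd_y
    fit = sm.OLS(yz, sm.add_constant(X)).fit()
    return AdjustedModelResult(
        terms=terms,
        betas=tuple(float(b) for b in fit.params[1:]),
        p_values=tuple(float(p) for p in fit.pvalues[1:]),
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
    )


# --- allele-sharing likelihood-ratio test -----------------------------------


def _weights_from_posteriors(
        posteriors: Sequence[Optional[IBDPosterior]]) -> np.ndarray:
    rows = []
    for post in posteriors:
        if post is None:
            continue
        w = np.array([post.f0, post.f1, post.f2]) / np.asarray(SIB_IBD_PRIOR)
        rows.append(w / w.sum())
    return np.asarray(rows)


def _loglik(W: np.ndarray, z: np.ndarray) -> float:
    mix = W @ z
    if np.any(mix <= 0.0):
        return -np.inf
    return float(np.log(mix).sum())


def _em_mle(W: np.ndarray, max_iter: int = 5000, tol: float = 1e-13,
            ) -> np.ndarray:
    """Unconstrained simplex MLE of mixture weights by EM."""
    z = np.asarray(SIB_IBD_PRIOR, dtype=float)
    ll = _loglik(W, z)
    for _ in range(max_iter):
        resp = W * z
        resp /= resp.sum(axis=1, keepdims=True)
        z = resp.mean(axis=0)
        new_ll = _loglik(W, z)
        if new_ll - ll < tol:
            break
        ll = new_ll
    return z


def _constrained_mle(W: np.ndarray) -> np.ndarray:
    """Sharing-deficit MLE: z0 >= 1/4, z2 <= 1/4 on the simplex."""
    z = _em_mle(W)
    if z[0] >= 0.25 - 1e-12 and z[2] <= 0.25 + 1e-12:
        return z
    res = optimize.minimize(
        lambda v: -_loglik(W, np.clip(v, 1e-12, 1.0)),
        x0=np.array([0.5, 0.375, 0.125]),
        method="SLSQP",
        bounds=[(0.25, 1.0), (0.0, 1.0), (0.0, 0.25)],
        constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
    )
    return np.clip(res.x, 0.0, 1.0)


def _multinomial_lr(counts: np.ndarray, deficit: bool) -> np.ndarray:
    """LR statistics for fully informative permutation draws (vectorised
    over rows of IBD-state counts)."""
    counts = np.atleast_2d(counts).astype(float)
    n = counts.sum(axis=1, keepdims=True)
    prior = np.asarray(SIB_IBD_PRIOR)
    phat = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * np.log(phat / prior)
    stat = 2.0 * np.nansum(np.where(counts > 0, term, 0.0), axis=1)
    if deficit:
        bad = (phat[:, 0] < 0.25) | (phat[:, 2] > 0.25)
        for i in np.nonzero(bad)[0]:
            W = np.repeat(np.eye(3), counts[i].astype(int), axis=0)
            z = _constrained_mle(W)
            stat[i] = max(0.0, 2.0 * (_loglik(W, z)
                                      - _loglik(W, np.asarray(SIB_IBD_PRIOR))))
    return stat


def sharing_lrt(posteriors: Sequence[Optional[IBDPosterior]],
                direction: str = "any",
                n_perm: int = 1000,
                seed: int = 0) -> SharingLRTResult:
    """Non-parametric allele-sharing likelihood-ratio test at one marker.

    Each informative pair contributes prior-free likelihood weights
    ``w_k``; the sharing probabilities z are estimated by maximum
    likelihood over the simplex (``direction='deficit'`` constrains
    z0 >= 1/4 and z2 <= 1/4, the one-sided EDSP alternative).  The
    p-value is by permutation: each pair's weights are re-drawn under the
    null prior as fully informative IBD states.
    """
    if direction not in ("any", "deficit"):
        raise ValueError("direction must be 'any' or 'deficit'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    W = _weights_from_posteriors(posteriors)
    if len(W) < 2:
        raise EdspError("sharing_lrt needs >= 2 informative pairs")
    n_pairs = len(W)
    deficit = direction == "deficit"
    z_hat = _constrained_mle(W) if deficit else _em_mle(W)
    null = np.asarray(SIB_IBD_PRIOR)
    lr = max(0.0, 2.0 * (_loglik(W, z_hat) - _loglik(W, null)))

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_pairs, SIB_IBD_PRIOR, size=n_perm)
    perm_stats = _multinomial_lr(counts, deficit)
    p_perm = (1.0 + float(np.sum(perm_stats >= lr - 1e-12))) / (n_perm + 1.0)
    return SharingLRTResult(z_hat=tuple(float(v) for v in z_hat),
                            lr_stat=lr, p_perm=p_perm, n_perm=n_perm,
                            seed=seed, n_pairs=n_pairs)


# --- whole-panel analysis and cohort summary --------------------------------


def pair_covariates(pairs: Sequence[SibPairRecord]) -> pd.DataFrame:
    """Per-pair confounders: mean age and number of male sibs."""
    rows = []
    for pair in pairs:
        ages = [a for a in (pair.sib1.age, pair.sib2.age) if a is not None]
        rows.append({
            "family_id": pair.family_id,
            "mean_age": float(np.mean(ages)) if ages else np.nan,
            "n_males": sum(s.sex == "male" for s in (pair.sib1, pair.sib2)),
            "same_sex": pair.sib1.sex == pair.sib2.sex,
        })
    return pd.DataFrame(rows)


def linkage_table(pairs: Sequence[SibPairRecord], marker_map: MarkerMap,
                  phenotypes: Sequence[str] = ("sbp", "dbp", "pp"),
                  adjust: bool = True) -> pd.DataFrame:
    """Per-marker, per-phenotype linkage results.

    Requires ``pair_sharing_profile`` to have been run on every pair.
    Columns: marker, phenotype, n_pairs, r, p_two_sided, he_slope,
    he_slope_se, he_p_one_sided, p_bonferroni (emitted for reference,
    never used for gating), and when ``adjust`` is set the standardized
    covariate-adjusted terms (marker, mean age, number of males).
    """
    cov = pair_covariates(pairs)
    rows = []
    n_tests = len(marker_map) * len(phenotypes)
    for m_idx, marker in enumerate(marker_map):
        shared, keep = [], []
        for i, pair in enumerate(pairs):
            if pair.posteriors is None:
                raise EdspError("run pair_sharing_profile before linkage")
            post = pair.posteriors[m_idx]
            if post is None:
                continue
            shared.append(post.expected_shared)
            keep.append(i)
        for phenotype in phenotypes:
            x, y, idx = [], [], []
            for j, i in enumerate(keep):
                try:
                    d = pairs[i].squared_difference(phenotype)
                except EdspError:
                    continue
                x.append(shared[j])
                y.append(d)
                idx.append(i)
            row = {"marker": marker.name, "phenotype": phenotype,
                   "n_pairs": len(y)}
            try:
                he = haseman_elston(y, x)
                row.update(r=he.pearson_r, p_two_sided=he.p_two_sided,
                           he_slope=he.slope, he_slope_se=he.slope_se,
                           he_p_one_sided=he.p_one_sided,
                           p_bonferroni=min(1.0, he.p_two_sided * n_tests))
            except (UndefinedCorrelationError, ValueError) as exc:
                log.warning("%s/%s: %s", marker.name, phenotype, exc)
                row.update(r=np.nan, p_two_sided=np.nan, he_slope=np.nan,
                           he_slope_se=np.nan, he_p_one_sided=np.nan,
                           p_bonferroni=np.nan)
                rows.append(row)
                continue
            if adjust:
                sub = cov.iloc[idx]
                try:
                    adj = adjusted_regression(y, {
                        "marker": x,
                        "mean_age": sub["mean_age"].to_numpy(),
                        "n_males": sub["n_males"].to_numpy(),
                    })
                    row.update(
                        adj_beta_marker=adj.beta("marker"),
                        adj_p_marker=adj.p("marker"),
                        adj_beta_age=adj.beta("mean_age"),
                        adj_p_age=adj.p("mean_age"),
                        adj_beta_sex=adj.beta("n_males"),
                        adj_p_sex=adj.p("n_males"),
                        adj_r2=adj.adjusted_r2,
                    )
                except EdspError as exc:
                    log.warning("%s/%s adjusted model: %s",
                                marker.name, phenotype, exc)
            rows.append(row)
    return pd.DataFrame(rows)


_SUMMARY_ROWS = [
    ("age", "Age (years)"),
    ("height", "Height (m)"),
    ("weight", "Weight (kg)"),
    ("bmi", "Body mass index (kg/m^2)"),
    ("sbp", "Systolic blood pressure (mmHg)"),
    ("dbp", "Diastolic blood pressure (mmHg)"),
    ("pp", "Pulse pressure (mmHg)"),
]


def cohort_summary(pairs: Sequence[SibPairRecord],
                   extra: Optional[pd.DataFrame] = None,
                   criteria: SelectionCriteria = SelectionCriteria(),
                   ) -> pd.DataFrame:
    """Demographic/haemodynamic summary split by affected status.

    The affected sib of each pair is the higher-BP sib from the
    classification (computed with ``criteria`` when missing).  Extra
    per-individual variables (height, weight, bmi, ...) may be supplied
    as a DataFrame indexed by (family_id, individual_id).  Reports
    mean +/- SD per group and a Welch two-sample p-value per variable;
    SDs are missing for single-observation groups.
    """
    values: dict[str, dict[str, list[float]]] = {
        key: {"affected": [], "unaffected": []} for key, _ in _SUMMARY_ROWS}
    for pair in pairs:
        cls = pair.classification or classify_pair(pair.sib1, pair.sib2,
                                                   criteria)
        for sib in (pair.sib1, pair.sib2):
            group = ("affected" if sib.individual_id == cls.affected_sib
                     else "unaffected")
            for key, _ in _SUMMARY_ROWS:
                v = None
                if key in ("age", "sbp", "dbp", "pp"):
                    v = getattr(sib, key) if key != "pp" else sib.pp
                elif extra is not None and key in extra.columns:
                    try:
                        v = extra.loc[sib.key, key]
                    except KeyError:
                        v = None
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    values[key][group].append(float(v))

    rows = []
    for key, label in _SUMMARY_ROWS:
        aff = np.asarray(values[key]["affected"])
        unaff = np.asarray(values[key]["unaffected"])
        both = np.concatenate([aff, unaff])
        if both.size == 0:
            continue

        def _sd(v):
            return float(np.std(v, ddof=1)) if v.size > 1 else np.nan

        p = np.nan
        if aff.size > 1 and unaff.size > 1:
            p = float(stats.ttest_ind(aff, unaff, equal_var=False).pvalue)
        rows.append({
            "variable": label,
            "all_mean": float(both.mean()), "all_sd": _sd(both),
            "affected_mean": float(aff.mean()) if aff.size else np.nan,
            "affected_sd": _sd(aff),
            "unaffected_mean": float(unaff.mean()) if unaff.size else np.nan,
            "unaffected_sd": _sd(unaff),
            "p_welch": p,
        })
    return pd.DataFrame(rows)
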