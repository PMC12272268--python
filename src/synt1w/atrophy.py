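"""Longitudinal mixed-effects modeling of cord CSA trajectories.

Fits a linear mixed-effects model with vertebral level, linear and quadratic
time-since-enrollment terms and their interaction with group, an
age-by-time covariate and a scanner term as fixed effects, and per-subject
random intercept, time slope, quadratic term and level offsets.  Group
contrasts (patients - controls) of the linear atrophy rate, the quadratic
deceleration and the marginal CSA at chosen timepoints are derived from the
fixed-effect estimates and their covariance.

If the full random structure is singular on a given data set, the model is
refitted with a reduced structure (drop the quadratic random term, then the
level component, then the slope), and the structure actually used is
recorded on the fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryModelSpec",
    "TrajectoryFit",
    "Contrast",
    "fit_trajectory_model",
    "group_contrast",
    "marginal_csa",
]


@dataclass(frozen=True)
class TrajectoryModelSpec:
    """Fixed- and random-effect structure of the trajectory model."""

    include_quadratic: bool = True
    age_time_interaction: bool = True
    scanner_term: bool = True
    reml: bool = True
    random_structure: tuple[str, ...] = ("intercept", "time", "time2", "level")
    contrast_timepoints: tuple[float, ...] = (0.0, 24.0)


@dataclass
class TrajectoryFit:
    """A converged mixed-model fit plus the context needed for contrasts."""

    result: object  # statsmodels MixedLMResults
    spec: TrajectoryModelSpec
    formula: str
    random_structure_used: tuple[str, ...]
    groups: tuple[str, ...]
    levels: tuple[str, ...]
    mean_age: float
    time_range: tuple[float, float]
    converged: bool

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def cov_fe(self) -> pd.DataFrame:
        k = len(self.result.fe_params)
        cov = np.asarray(self.result.cov_params())[:k, :k]
        names = self.result.fe_params.index
        return pd.DataFrame(cov, index=names, columns=names)

    def group_rate(self, group: str) -> float:
        """Model-implied linear rate (mm^2/month) for one group."""
        c = self._rate_vector(group)
        return float(c @ self.fe_params.values)

    def _rate_vector(self, group: str) -> np.ndarray:
        names = list(self.fe_params.index)
        c = np.zeros(len(names))
        c[names.index("time")] = 1.0
        inter = f"C(group)[T.{group}]:time"
        if inter in names:
            c[names.index(inter)] = 1.0
        return c


@dataclass(frozen=True)
class Contrast:
    """A patients-minus-controls contrast with normal-approximation inference."""

    quantity: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    p_adjusted: float
    per_group: dict = field(default_factory=dict)


_RE_FALLBACKS = {
    ("intercept", "time", "time2", "level"): ("~time + time2", {"level": "0 + C(level)"}),
    ("intercept", "time", "time2"): ("~time + time2", None),
    ("intercept", "time", "level"): ("~time", {"level": "0 + C(level)"}),
    ("intercept", "time"): ("~time", None),
    ("intercept",): ("1", None),
}

_FALLBACK_ORDER = [
    ("intercept", "time", "time2", "level"),
    ("intercept", "time", "level"),
    ("intercept", "time"),
    ("intercept",),
]


def fit_trajectory_model(
    records: pd.DataFrame,
    spec: TrajectoryModelSpec | None = None,
    modality: str | None = None,
) -> TrajectoryFit:
    """Fit the trajectory model to long-format CSA records.

    ``records`` must contain the CSA record columns; if ``modality`` is
    given, rows are filtered to that modality first.  Age is mean-centered
    before entering the age-by-time interaction; time is months since
    enrollment, uncentered.  Estimation is REML by default.
    """
    spec = spec or TrajectoryModelSpec()
    df = records.copy()
    if modality is not None:
        df = df[df["modality"] == modality].copy()
    if df["group"].nunique() < 2:
        raise ValueError("need both groups present")
    if df["time_months"].nunique() < 3:
        raise ValueError("need >= 3 timepoints")
    if df["level"].nunique() < 2:
        raise ValueError("need >= 2 levels")

    df["time"] = df["time_months"].astype(float)
    df["time2"] = df["time"] ** 2
    mean_age = float(df.drop_duplicates("subject_id")["age_years"].mean()) if "age_years" in df else 0.0
    df["age_c"] = df.get("age_years", mean_age) - mean_age

    terms = ["C(level)", "C(group)*time"]
    if spec.include_quadratic:
        terms.append("C(group)*time2")
    if spec.age_time_interaction and "age_years" in df:
        terms.append("age_c:time")
    if spec.scanner_term and "scanner_id" in df and df["scanner_id"].nunique() > 1:
        terms.append("C(scanner_id)")
    formula = "csa_mm2 ~ " + " + ".join(terms)

    start = tuple(spec.random_structure)
    structures = [start] + [s for s in _FALLBACK_ORDER if _smaller(s, start)]
    last_exc: Exception | None = None
    for structure in structures:
        re_formula, vc_formula = _RE_FALLBACKS[structure]
        if "time2" in structure and not spec.include_quadratic:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    formula, df, groups=df["subject_id"],
                    re_formula=re_formula, vc_formula=vc_formula,
                )
                result = model.fit(reml=spec.reml, method=["lbfgs", "bfgs"], maxiter=500)
            if not result.converged:
                raise RuntimeError("optimizer did not converge")
            ses = result.bse_fe.values
            if not np.all(np.isfinite(ses)):
                raise RuntimeError("non-finite fixed-effect standard errors")
        except Exception as exc:  # singular covariance, convergence failure
            logger.info("random structure %s failed (%s); reducing", structure, exc)
            last_exc = exc
            continue
        if structure != start:
            logger.warning("random structure reduced from %s to %s", start, structure)
        return TrajectoryFit(
            result=result,
            spec=spec,
            formula=formula,
            random_structure_used=structure,
            groups=tuple(sorted(df["group"].unique())),
            levels=tuple(sorted(df["level"].unique())),
            mean_age=mean_age,
            time_range=(float(df["time"].min()), float(df["time"].max())),
            converged=True,
        )
    # Degenerate data (e.g. zero residual variance in noise-free simulations)
    # breaks the mixed-model likelihood; the fixed effects are still exactly
    # identified, so fall back to an ordinary least-squares fit.
    logger.warning("mixed model degenerate (%s); falling back to fixed-effects OLS", last_exc)
    ols_res = smf.ols(formula, df).fit()
    return TrajectoryFit(
        result=_OLSAdapter(ols_res),
        spec=spec,
        formula=formula,
        random_structure_used=(),
        groups=tuple(sorted(df["group"].unique())),
        levels=tuple(sorted(df["level"].unique())),
        mean_age=mean_age,
        time_range=(float(df["time"].min()), float(df["time"].max())),
        converged=True,
    )


class _OLSAdapter:
    """Expose an OLS result through the MixedLM fixed-effects accessors."""

    def __init__(self, res) -> None:
        self._res = res
        self.converged = True

    @property
    def fe_params(self):
        return self._res.params

    @property
    def bse_fe(self):
        return self._res.bse

    def cov_params(self):
        return self._res.cov_params()


def _smaller(a: tuple, b: tuple) -> bool:
    return set(a) < set(b)


def _design_row(fit: TrajectoryFit, group: str, t: float) -> np.ndarray:
    """Fixed-effect design row for one group at time t, averaged over levels,
    age at the cohort mean, scanner at the reference category."""
    names = list(fit.fe_params.index)
    x = np.zeros(len(names))
    n_levels = len(fit.levels)
    for i, name in enumerate(names):
        if name == "Intercept":
            x[i] = 1.0
        elif name.startswith("C(level)[T."):
            x[i] = 1.0 / n_levels  # average over levels (reference absorbed)
        elif name == f"C(group)[T.{group}]":
            x[i] = 1.0
        elif name == "time":
            x[i] = t
        elif name == "time2":
            x[i] = t * t
        elif name == f"C(group)[T.{group}]:time":
            x[i] = t
        elif name == f"C(group)[T.{group}]:time2":
            x[i] = t * t
        # age_c:time -> 0 at mean age; scanner dummies -> 0 at reference
    return x


def _contrast_vector(fit: TrajectoryFit, quantity: str, t: float | None) -> np.ndarray:
    names = list(fit.fe_params.index)
    ref, other = fit.groups[0], fit.groups[1]
    c = np.zeros(len(names))
    if quantity == "linear_rate":
        key = f"C(group)[T.{other}]:time"
    elif quantity == "quadratic":
        key = f"C(group)[T.{other}]:time2"
    elif quantity == "marginal_at_t":
        if t is None:
            raise ValueError("marginal_at_t requires t")
        return _design_row(fit, other, t) - _design_row(fit, ref, t)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    if key not in names:
        raise ValueError(f"quantity {quantity!r} absent from model ({key} not fitted)")
    c[names.index(key)] = 1.0
    return c


def group_contrast(
    fit: TrajectoryFit,
    quantities: str | list[str | tuple[str, float]],
    alpha: float = 0.05,
) -> list[Contrast]:
    """Patients-minus-controls contrasts with family-wise (Tukey-style) adjustment.

    ``quantities`` is one name or a list; ``"marginal_at_t"`` entries are
    given as ``("marginal_at_t", t)``.  The adjustment family is exactly the
    set requested in this call: adjusted p-values are computed from the
    joint normal distribution of the contrast z-statistics (for a single
    contrast the adjusted p equals the raw p).
    """
    if isinstance(quantities, str):
        quantities = [quantities]
    elif isinstance(quantities, tuple) and len(quantities) == 2 and isinstance(quantities[0], str):
        quantities = [quantities]
    specs: list[tuple[str, float | None]] = []
    for q in quantities:
        if isinstance(q, tuple):
            specs.append((q[0], float(q[1])))
        else:
            specs.append((q, None))

    beta = fit.fe_params.values
    cov = fit.cov_fe.values
    rows = np.vstack([_contrast_vector(fit, q, t) for q, t in specs])
    est = rows @ beta
    vmat = rows @ cov @ rows.T
    se = np.sqrt(np.diag(vmat))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))

    m = len(specs)
    if m == 1:
        p_adj = p_raw.copy()
    else:
        corr = vmat / np.outer(se, se)
        corr = (corr + corr.T) / 2.0 + 1e-12 * np.eye(m)
        mvn = stats.multivariate_normal(mean=np.zeros(m), cov=corr, seed=0, allow_singular=True)
        p_adj = np.empty(m)
        for i, zi in enumerate(z):
            c = abs(zi)
            inside = mvn.cdf(np.full(m, c), lower_limit=np.full(m, -c))
            p_adj[i] = min(1.0, max(p_raw[i], 1.0 - inside))

    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    out = []
    for i, (q, t) in enumerate(specs):
        per_group = {}
        if q == "marginal_at_t":
            for g in fit.groups:
                xg = _design_row(fit, g, t)
                eg = float(xg @ beta)
                sg = float(np.sqrt(xg @ cov @ xg))
                per_group[g] = (eg, eg - zcrit * sg, eg + zcrit * sg)
        elif q == "linear_rate":
            for g in fit.groups:
                per_group[g] = fit.group_rate(g)
        label = q if t is None else f"{q}({t})"
        out.append(
            Contrast(
                quantity=label,
                estimate=float(est[i]),
                se=float(se[i]),
                ci_lower=float(est[i] - zcrit * se[i]),
                ci_upper=float(est[i] + zcrit * se[i]),
                p_value=float(p_raw[i]),
                p_adjusted=float(p_adj[i]),
                per_group=per_group,
            )
        )
    return out


def marginal_csa(fit: TrajectoryFit, t: float, alpha: float = 0.05) -> dict[str, tuple[float, float, float]]:
    """Model-implied mean CSA per group at time ``t`` (est, CI lower, CI upper).

    Averaged over vertebral levels with age at the cohort mean and the
    reference scanner.  Warns when ``t`` lies outside the observed range.
    """
    lo, hi = fit.time_range
    if not lo <= t <= hi:
        warnings.warn(f"t={t} months extrapolates beyond observed range [{lo}, {hi}]")
    beta = fit.fe_params.values
    cov = fit.cov_fe.values
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    out = {}
    for g in fit.groups:
        x = _design_row(fit, g, t)
        e = float(x @ beta)
        s = float(np.sqrt(x @ cov @ x))
        out[g] = (e, e - zcrit * s, e + zcrit * s)
    return out
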