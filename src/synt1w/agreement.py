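"""Accuracy and precision statistics for paired CSA measurements.

Bland-Altman agreement (bias and 95% limits of agreement), a default-prior
(JZS) Bayesian two-sample t-test for comparing group biases, and
repeatability as the standard deviation across repeated measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special

__all__ = [
    "AgreementSummary",
    "RepeatabilitySummary",
    "bland_altman",
    "subject_mean_differences",
    "jzs_bayes_factor",
    "interpret_bf",
    "repeatability_sd",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary of method B against method A.

    Differences are ``B - A``; percentages are relative to the grand mean of
    the two per-method means.
    """

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class RepeatabilitySummary:
    per_subject_sd: pd.Series
    mean_sd: float
    sd_of_sd: float


def bland_altman(a, b) -> AgreementSummary:
    """Bias and limits of agreement of paired measurements ``b`` vs ``a``.

    bias = mean(b - a); LoA = bias +/- 1.96 * SD(b - a) with sample (n-1) SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    denom = 0.5 * (a.mean() + b.mean())
    pct = 100.0 / denom if denom != 0 else math.nan
    return AgreementSummary(
        n=a.size,
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        bias_pct=bias * pct,
        loa_lower_pct=lo * pct,
        loa_upper_pct=hi * pct,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def subject_mean_differences(
    records: pd.DataFrame,
    modality_a: str = "reference",
    modality_b: str = "synthetic",
) -> pd.DataFrame:
    """One agreement point per (subject, timepoint), averaged across levels.

    Returns a frame with columns ``subject_id, group, time_months, a, b``
    where ``a``/``b`` are the level-averaged CSA of each modality.
    """
    wide = (
        records.pivot_table(
            index=["subject_id", "group", "time_months"],
            columns="modality",
            values="csa_mm2",
            aggfunc="mean",
        )
        .dropna(subset=[modality_a, modality_b])
        .reset_index()
    )
    return wide.rename(columns={modality_a: "a", modality_b: "b"})


def _jzs_integrand(g: np.ndarray, t: float, N: float, nu: float, r: float) -> np.ndarray:
    """Integrand of the JZS alternative marginal likelihood over g (up to the
    shared null factor), with the Cauchy scale absorbed as N*r^2."""
    nr = N * r * r * g
    return (
        (1.0 + nr) ** -0.5
        * (1.0 + t * t / ((1.0 + nr) * nu)) ** (-(nu + 1.0) / 2.0)
        * (2.0 * math.pi) ** -0.5
        * g ** -1.5
        * np.exp(-1.0 / (2.0 * g))
    )


def jzs_bayes_factor(
    sample_a,
    sample_b,
    prior_scale: float = math.sqrt(2) / 2,
) -> float:
    """JZS (Cauchy-prior) Bayes factor BF10 for a two-sample t-test.

    The prior on the standardized effect size is Cauchy(0, ``prior_scale``);
    BF10 > 1 favors a group difference, BF10 < 1 the null.  Computed by
    numerical integration of the Zellner-Siow mixture over the prior
    variance g.  Scale-invariant: rescaling both samples leaves BF10
    unchanged.  Two zero-variance samples with equal means are degenerate
    and return BF10 = 0 with a warning.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    nu = n1 + n2 - 2
    N = n1 * n2 / (n1 + n2)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / nu
    if sp2 == 0:
        if x.mean() == y.mean():
            warnings.warn("degenerate samples: zero variance and equal means; BF10 -> 0")
            return 0.0
        return math.inf
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))

    null_like = (1.0 + t * t / nu) ** (-(nu + 1.0) / 2.0)
    alt_like, _ = integrate.quad(
        _jzs_integrand, 0.0, np.inf, args=(t, N, nu, prior_scale),
        limit=200, epsabs=1e-12, epsrel=1e-10,
    )
    return float(alt_like / null_like)


def interpret_bf(bf10: float) -> str:
    """Jeffreys-scale reading: >3 difference, <1/3 equivalence, else inconclusive."""
    if bf10 > 3.0:
        return "evidence for difference"
    if bf10 < 1.0 / 3.0:
        return "evidence for equivalence"
    return "inconclusive"


def repeatability_sd(
    records: pd.DataFrame,
    modality: str = "synthetic",
    group: str | None = "control",
    per_level: bool = True,
) -> RepeatabilitySummary:
    """Precision as the SD of repeated (over-time) measurements per subject.

    For each subject the sample SD of CSA across timepoints is computed
    (per level and then averaged across levels when ``per_level``, else on
    level-averaged CSA), and summarized as cohort mean +/- SD.  Subjects
    with fewer than 2 timepoints are excluded.
    """
    df = records[records["modality"] == modality]
    if group is not None:
        df = df[df["group"] == group]
    if df.empty:
        raise ValueError("no records after filtering")

    def _per_subject(sub: pd.DataFrame) -> float:
        if sub["time_months"].nunique() < 2:
            return math.nan
        if per_level:
            sds = sub.groupby("level")["csa_mm2"].std(ddof=1)
            return float(sds.mean())
        series = sub.groupby("time_months")["csa_mm2"].mean()
        return float(series.std(ddof=1))

    per_subj = df.groupby("subject_id").apply(_per_subject, include_groups=False).dropna()
    if per_subj.empty:
        raise ValueError("no subject has >= 2 timepoints")
    return RepeatabilitySummary(
        per_subject_sd=per_subj,
        mean_sd=float(per_subj.mean()),
        sd_of_sd=float(per_subj.std(ddof=1)) if per_subj.size > 1 else 0.0,
    )
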