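"""Phenotype genetics for multi-environment F2:3 family trials.

Variance components come from the balanced two-way (family x environment)
ANOVA expected-mean-squares method:

    sigma_eps^2 = MS_error
    sigma_ge^2  = (MS_GxE - MS_error) / r
    sigma_g^2   = (MS_G - MS_GxE) / (n r)

with n environments and r replicates; negative estimates are truncated at
zero (the raw values are retained for inspection). Heritabilities:

    H_B^2  = sigma_g^2  / (sigma_g^2 + sigma_ge^2/n + sigma_eps^2/(n r))
    H_GE^2 = (sigma_ge^2/n) / (same denominator)

The published form of the interaction heritability puts sigma_g^2/n in the
numerator, which is algebraically forced to H_B^2/n and contradicts the
reported estimates; the corrected numerator sigma_ge^2/n is the default and
the literal form is available with ``as_printed=True``.

Heterosis indices (percent): HI = F1/MP*100, RH = (F1-MP)/F1*100,
MH = (F1-MP)/MP*100, OH = (F1-PH)/PH*100, ARR = (F23-F1)/F1*100, with MP the
mid-parent mean and PH the better parent.

The deep-sowing rate of change defaults to RC = (T_deep/T_normal - 1)*100;
the literal published orientation (1 - T_normal/T_deep)*100 is available
with ``as_printed=True`` but does not reproduce the reported percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_eps2: float
    n_env: int
    n_rep: int
    raw_sigma_g2: float = None
    raw_sigma_ge2: float = None

    def __post_init__(self):
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_eps2) < 0:
            raise ValueError("variance components must be nonnegative after truncation")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")

    @property
    def denominator(self) -> float:
        return (
            self.sigma_g2
            + self.sigma_ge2 / self.n_env
            + self.sigma_eps2 / (self.n_env * self.n_rep)
        )


@dataclass(frozen=True)
class HeritabilityResult:
    H_B2: float
    H_GE2: float


@dataclass(frozen=True)
class HeterosisResult:
    HI: float
    RH: float
    MH: float
    OH: float
    ARR: float
    MP: float
    P_H: float


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    sd: float
    cv_percent: float
    skewness: float
    kurtosis: float     # excess kurtosis: 0 for a normal distribution
    minimum: float
    maximum: float
    normal_flag: bool   # |skewness| < 1 and |excess kurtosis| < 1


def check_balanced(table: pd.DataFrame) -> tuple[int, int, int]:
    """Validate a family x environment x replicate table; return (G, n, r)."""
    required = {"family", "environment", "replicate", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if not np.isfinite(table["value"].to_numpy(float)).all():
        raise ValueError("non-finite trait values in phenotype table")
    counts = table.groupby(["family", "environment"], sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicates per family x environment")
    n_fam = table["family"].nunique()
    n_env = table["environment"].nunique()
    if len(counts) != n_fam * n_env:
        raise ValueError("unbalanced design: missing family x environment cells")
    return n_fam, n_env, int(counts.iloc[0])


def estimate_variance_components(table: pd.DataFrame) -> VarianceComponents:
    """Two-way ANOVA expected-mean-squares estimates from a balanced table."""
    g, n, r = check_balanced(table)
    if g < 2 or n < 2 or r < 2:
        raise ValueError("need >= 2 families, >= 2 environments, >= 2 replicates")
    y = table["value"].to_numpy(float)
    grand = y.mean()
    cell = table.groupby(["family", "environment"], sort=False)["value"].mean()
    fam = table.groupby("family", sort=False)["value"].mean()
    env = table.groupby("environment", sort=False)["value"].mean()

    ss_g = n * r * ((fam - grand) ** 2).sum()
    ss_e = g * r * ((env - grand) ** 2).sum()
    cell_df = cell.reset_index()
    cell_df["fam_mean"] = cell_df["family"].map(fam)
    cell_df["env_mean"] = cell_df["environment"].map(env)
    ss_ge = r * (
        (cell_df["value"] - cell_df["fam_mean"] - cell_df["env_mean"] + grand) ** 2
    ).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_g - ss_e - ss_ge

    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (n - 1))
    ms_err = ss_err / (g * n * (r - 1))

    raw_ge = (ms_ge - ms_err) / r
    raw_g = (ms_g - ms_ge) / (n * r)
    return VarianceComponents(
        sigma_g2=max(raw_g, 0.0),
        sigma_ge2=max(raw_ge, 0.0),
        sigma_eps2=ms_err,
        n_env=n,
        n_rep=r,
        raw_sigma_g2=raw_g,
        raw_sigma_ge2=raw_ge,
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    denom = vc.denominator
    if denom <= 0:
        raise ValueError("all variance components are zero: heritability undefined")
    return vc.sigma_g2 / denom


def ge_heritability(vc: VarianceComponents, as_printed: bool = False) -> float:
    """Interaction heritability; ``as_printed`` uses the literal sigma_g^2/n numerator."""
    denom = vc.denominator
    if denom <= 0:
        raise ValueError("all variance components are zero: heritability undefined")
    num = vc.sigma_g2 / vc.n_env if as_printed else vc.sigma_ge2 / vc.n_env
    return num / denom


def heritability(vc: VarianceComponents) -> HeritabilityResult:
    return HeritabilityResult(broad_sense_heritability(vc), ge_heritability(vc))


def heterosis(p1_mean: float, p2_mean: float, f1_mean: float,
              f23_mean: float) -> HeterosisResult:
    if min(p1_mean, p2_mean, f1_mean) <= 0:
        raise ValueError("parental and F1 means must be positive")
    mp = (p1_mean + p2_mean) / 2.0
    ph = max(p1_mean, p2_mean)
    return HeterosisResult(
        HI=f1_mean / mp * 100.0,
        RH=(f1_mean - mp) / f1_mean * 100.0,
        MH=(f1_mean - mp) / mp * 100.0,
        OH=(f1_mean - ph) / ph * 100.0,
        ARR=(f23_mean - f1_mean) / f1_mean * 100.0,
        MP=mp,
        P_H=ph,
    )


def rate_of_change(mean_normal: float, mean_deep: float, as_printed: bool = False) -> float:
    """Percent change of the trait under deep sowing relative to normal depth."""
    if as_printed:
        if mean_deep == 0:
            raise ValueError("zero deep-sowing mean")
        return (1.0 - mean_normal / mean_deep) * 100.0
    if mean_normal == 0:
        raise ValueError("zero normal-depth mean")
    return (mean_deep / mean_normal - 1.0) * 100.0


def describe_distribution(values) -> DistributionSummary:
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        # Degenerate sample: flat distribution treated as trivially "normal".
        return DistributionSummary(mean, 0.0, 0.0, 0.0, 0.0, mean, mean, True)
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    cv = 100.0 * sd / mean if mean > 0 else math.nan
    return DistributionSummary(
        mean=mean, sd=sd, cv_percent=cv, skewness=skew, kurtosis=kurt,
        minimum=float(x.min()), maximum=float(x.max()),
        normal_flag=abs(skew) < 1.0 and abs(kurt) < 1.0,
    )


def relative_expression_ddct(
    ct_target_test: float, ct_ref_test: float,
    ct_target_cal: float, ct_ref_cal: float,
) -> float:
    """Relative qRT-PCR expression by the 2^-ddCt method."""
    for v in (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)


def family_means(table: pd.DataFrame, environment: str) -> pd.Series:
    """Per-family mean trait value in one environment (sorted by family id)."""
    sub = table[table["environment"] == environment]
    if sub.empty:
        raise ValueError(f"no records for environment {environment!r}")
    return sub.groupby("family")["value"].mean().sort_index()


def environment_report(table: pd.DataFrame) -> dict:
    """Components, heritabilities, and per-environment distribution summaries.

    With fewer than two environments or replicates the ANOVA decomposition is
    not estimable; components and heritabilities are reported as None."""
    _, n_env, n_rep = check_balanced(table)
    if n_env >= 2 and n_rep >= 2:
        vc = estimate_variance_components(table)
        h = heritability(vc)
    else:
        vc = h = None
    per_env = {}
    for env in dict.fromkeys(table["environment"]):
        means = family_means(table, env)
        s = describe_distribution(means.to_numpy())
        per_env[str(env)] = s.__dict__ if not hasattr(s, "_asdict") else s._asdict()
    return {
        "variance_components": None
        if vc is None
        else {
            "sigma_g2": vc.sigma_g2,
            "sigma_ge2": vc.sigma_ge2,
            "sigma_eps2": vc.sigma_eps2,
            "n_env": vc.n_env,
            "n_rep": vc.n_rep,
        },
        "heritability": None if h is None else {"H_B2": h.H_B2, "H_GE2": h.H_GE2},
        "distributions": {
            env: {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                  for k, v in d.items()}
            for env, d in per_env.items()
        },
    }


def _warn_unbalanced(msg: str) -> None:  # hook for CLI logging
    warnings.warn(msg, stacklevel=2)
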