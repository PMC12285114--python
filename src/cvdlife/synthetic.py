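"""Synthetic cohort and genetics generators with known ground truth.

The cohort generator draws three-state (CVD-free -> CVD -> dead, plus
CVD-free -> dead) event histories from Gompertz baseline hazards times
group-specific hazard ratios, emulating a prospective biobank of adults
aged 30-79 followed for roughly a decade.  Because the generative
hazards are known in closed form, a continuous-time Kolmogorov-forward
oracle (`true_life_expectancy`) provides exact group life expectancies
against which the discrete life-table engine and the full estimation
pipeline can be validated.

The genetics generator produces binomial genotype dosages, sparse-normal
trait architectures with cross-trait correlation, and noisy GWAS summary
statistics for trans-ancestry or European/East-Asian pairs, so the
meta-score construction can be exercised end to end with a known
liability model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TrueLifeExpectancy",
    "simulate_cohort",
    "true_life_expectancy",
    "gompertz_rate",
    "simulate_genetics",
    "simulate_ld_panel",
    "simulate_liability_outcome",
]


def gompertz_rate(age, a: float, b: float):
    """Hazard ``a * exp(b * age)`` (per year) at the given age(s)."""
    return a * np.exp(b * np.asarray(age, dtype=float))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the women of a Chinese biobank testing set:
    ~70k adults entering uniformly over ages 30-79, administratively
    censored 10-14 years after entry, with a 20/60/20 genetic-risk
    split and transition hazard ratios matching the fitted Cox models
    (incidence 1.20/1.63, non-CVD death 1.01/1.11, post-CVD death
    1.07/1.25 for intermediate/high vs low risk).  Baseline Gompertz
    parameters give a crude CVD incidence near 0.026/year at the
    mid-follow-up mean age, i.e. roughly 28% of the cohort developing
    CVD over follow-up.

    ``baseline_hazards`` maps transition id (1: free->CVD, 2: free->
    non-CVD death, 3: CVD->death) to Gompertz ``(a, b)`` with hazard
    ``a*exp(b*age)``.  ``true_hr`` maps transition id to per-group
    multipliers aligned with ``group_labels`` (reference first, HR 1).
    """

    n: int = 70_000
    seed: int = 0
    entry_age_range: tuple[float, float] = (30.0, 79.0)
    sex_ratio_male: float = 0.402
    group_name: str = "genetic_risk"
    group_labels: tuple[str, ...] = ("low", "intermediate", "high")
    group_prevalence: tuple[float, ...] = (0.2, 0.6, 0.2)
    baseline_hazards: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {
            1: (3.0e-4, 0.070),
            2: (1.2e-5, 0.095),
            3: (2.0e-4, 0.085),
        }
    )
    true_hr: Mapping[int, tuple[float, ...]] = field(
        default_factory=lambda: {
            1: (1.0, 1.20, 1.63),
            2: (1.0, 1.01, 1.11),
            3: (1.0, 1.07, 1.25),
        }
    )
    followup_years: tuple[float, float] = (10.0, 14.0)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if len(self.group_prevalence) != len(self.group_labels):
            raise ValueError("group_prevalence must align with group_labels")
        if abs(sum(self.group_prevalence) - 1.0) > 1e-9:
            raise ValueError("group_prevalence must sum to 1")
        for t in (1, 2, 3):
            a, b = self.baseline_hazards[t]
            if a < 0:
                raise ValueError(f"baseline hazard a for transition {t} negative")
            hrs = self.true_hr[t]
            if len(hrs) != len(self.group_labels):
                raise ValueError(f"true_hr[{t}] must align with group_labels")
            if any(h <= 0 for h in hrs):
                raise ValueError("hazard ratios must be positive")
            if abs(hrs[0] - 1.0) > 1e-12:
                raise ValueError("reference group must have HR 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _gompertz_sample(u, entry_age, a, b, hr):
    """Inverse-CDF residual event time from `entry_age` under hazard
    ``a*hr*exp(b*age)``; returns +inf where the rate is zero."""
    u = np.asarray(u, dtype=float)
    entry_age = np.asarray(entry_age, dtype=float)
    rate0 = a * hr
    out = np.full(np.broadcast(u, entry_age).shape, np.inf)
    rate0 = np.broadcast_to(np.asarray(rate0, dtype=float), out.shape)
    ok = rate0 > 0
    e = -np.log(u)  # standard exponential
    if b == 0.0:
        out[ok] = e[ok] / rate0[ok]
    else:
        # H(t) = (a*hr/b) * (exp(b*(x0+t)) - exp(b*x0)) = e
        ebx = np.exp(b * entry_age)
        out[ok] = np.log(ebx[ok] + b * e[ok] / rate0[ok]) / b - entry_age[ok]
    return out


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a cohort of three-state event histories.

    Each individual's uniforms occupy one row of a single seeded draw
    matrix, so individual *i*'s history is identical for any cohort
    size ``>= i`` under the same seed.

    Returns a cohort table with one row per individual: ``id, sex,
    entry_age, <group_name>, cov1, age_cvd, age_death, censor_age,
    event_cvd, event_death`` where ``censor_age`` is the administrative
    censoring age and the event ages are NaN when unobserved.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    u = rng.uniform(size=(cfg.n, 8))

    lo, hi = cfg.entry_age_range
    entry = lo + (hi - lo) * u[:, 0]
    sex = np.where(u[:, 1] < cfg.sex_ratio_male, "male", "female")
    cum = np.cumsum(cfg.group_prevalence)
    group_idx = np.searchsorted(cum, u[:, 2], side="left").clip(0, len(cum) - 1)
    f_lo, f_hi = cfg.followup_years
    censor = entry + f_lo + (f_hi - f_lo) * u[:, 3]
    cov1 = (u[:, 7] < 0.5).astype(int)

    a1, b1 = cfg.baseline_hazards[1]
    a2, b2 = cfg.baseline_hazards[2]
    a3, b3 = cfg.baseline_hazards[3]
    hr1 = np.asarray(cfg.true_hr[1])[group_idx]
    hr2 = np.asarray(cfg.true_hr[2])[group_idx]
    hr3 = np.asarray(cfg.true_hr[3])[group_idx]

    t_cvd = _gompertz_sample(u[:, 4], entry, a1, b1, hr1)
    t_dead = _gompertz_sample(u[:, 5], entry, a2, b2, hr2)

    age_cvd_latent = entry + t_cvd
    age_dead_latent = entry + t_dead

    cvd_first = (age_cvd_latent < age_dead_latent) & (age_cvd_latent < censor)
    noncvd_death = (~cvd_first) & (age_dead_latent <= censor)

    age_cvd = np.where(cvd_first, age_cvd_latent, np.nan)
    age_death = np.where(noncvd_death, age_dead_latent, np.nan)

    # post-CVD survival, Markov in current age
    if cvd_first.any():
        onset = age_cvd_latent[cvd_first]
        t3 = _gompertz_sample(u[cvd_first, 6], onset, a3, b3, hr3[cvd_first])
        d3 = onset + t3
        observed = d3 <= censor[cvd_first]
        deaths = np.where(observed, d3, np.nan)
        tmp = age_death.copy()
        tmp[cvd_first] = deaths
        age_death = tmp

    event_cvd = ~np.isnan(age_cvd)
    event_death = ~np.isnan(age_death)

    return pd.DataFrame(
        {
            "id": np.arange(cfg.n),
            "sex": sex,
            "entry_age": entry,
            cfg.group_name: np.asarray(cfg.group_labels, dtype=object)[group_idx],
            "cov1": cov1,
            "age_cvd": age_cvd,
            "age_death": age_death,
            "censor_age": censor,
            "event_cvd": event_cvd.astype(int),
            "event_death": event_death.astype(int),
        }
    )


@dataclass(frozen=True)
class TrueLifeExpectancy:
    """Oracle life expectancies for one risk group (years in 40-90)."""

    group: str
    total_le: float
    cvd_free_le: float
    le_with_cvd: float
    proportion_cvd_free: float
    index_age: float
    end_age: float
    step: float


def true_life_expectancy(
    config: SimulationConfig,
    group: str,
    index_age: float = 40.0,
    end_age: float = 90.0,
    step: float = 0.01,
) -> TrueLifeExpectancy:
    """Integrate the Kolmogorov forward equations for one group.

    From ``P_free(index_age) = 1`` the occupancy probabilities evolve as

        dP_free/dx = -(lam1(x) + lam2(x)) P_free
        dP_cvd/dx  =  lam1(x) P_free - lam3(x) P_cvd

    with the group's hazards ``lam_i(x) = a_i exp(b_i x) HR_{i,g}``.
    Life expectancies are the integrals of the occupancies over
    ``[index_age, end_age]``, computed with classical fixed-step RK4 by
    carrying the integrals as extra state components (so they converge
    at the same fourth order as the occupancies).
    """
    if step > 0.1:
        raise ValueError("step must be <= 0.1 year")
    g = config.group_labels.index(group)
    pars = []
    for t in (1, 2, 3):
        a, b = config.baseline_hazards[t]
        pars.append((a * config.true_hr[t][g], b))

    def deriv(x, y):
        p_free, p_cvd = y[0], y[1]
        l1 = pars[0][0] * np.exp(pars[0][1] * x)
        l2 = pars[1][0] * np.exp(pars[1][1] * x)
        l3 = pars[2][0] * np.exp(pars[2][1] * x)
        return np.array(
            [-(l1 + l2) * p_free, l1 * p_free - l3 * p_cvd, p_free, p_cvd]
        )

    n_steps = int(round((end_age - index_age) / step))
    h = (end_age - index_age) / n_steps
    y = np.array([1.0, 0.0, 0.0, 0.0])
    x = index_age
    for _ in range(n_steps):
        k1 = deriv(x, y)
        k2 = deriv(x + h / 2, y + h / 2 * k1)
        k3 = deriv(x + h / 2, y + h / 2 * k2)
        k4 = deriv(x + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        x += h

    le_free, le_cvd = float(y[2]), float(y[3])
    total = le_free + le_cvd
    return TrueLifeExpectancy(
        group=group,
        total_le=total,
        cvd_free_le=le_free,
        le_with_cvd=le_cvd,
        proportion_cvd_free=le_free / total if total > 0 else float("nan"),
        index_age=index_age,
        end_age=end_age,
        step=h,
    )


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------

_UNAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                      ("C", "A"), ("G", "T"), ("C", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _variant_metadata(rng, m, frac_ambiguous, spacing_bp=10_000):
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=m)
    alleles = [_UNAMBIGUOUS_PAIRS[i] for i in pair_idx]
    n_amb = int(round(frac_ambiguous * m))
    if n_amb:
        amb_pos = rng.choice(m, size=n_amb, replace=False)
        for j, k in enumerate(amb_pos):
            alleles[k] = _AMBIGUOUS_PAIRS[j % len(_AMBIGUOUS_PAIRS)]
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": spacing_bp * (1 + np.arange(m)),
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
        }
    )


def simulate_ld_panel(
    n: int,
    m: int,
    seed: int,
    block_size: int = 5,
    within_r: float = 0.7,
    freq_range: tuple[float, float] = (0.1, 0.5),
    spacing_bp: int = 10_000,
):
    """Genotype panel with block-exchangeable LD.

    Latent Gaussians share a per-block factor with loading
    ``sqrt(within_r)`` and are thresholded to dosages 0/1/2 at the
    Hardy-Weinberg quantiles of each variant's allele frequency, giving
    within-block dosage correlations near ``within_r`` and independence
    across blocks.  Returns ``(dosages, variants)``.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=m)
    n_blocks = int(np.ceil(m / block_size))
    factor = np.repeat(rng.normal(size=(n, n_blocks)), block_size, axis=1)[:, :m]
    z = np.sqrt(within_r) * factor + np.sqrt(1 - within_r) * rng.normal(size=(n, m))
    # threshold to genotypes at HWE quantiles: P(0)=(1-p)^2, P(0 or 1)=1-p^2
    from scipy.stats import norm

    q0 = norm.ppf((1 - freqs) ** 2)
    q1 = norm.ppf(1 - freqs**2)
    dos = (z > q0).astype(float) + (z > q1)
    variants = _variant_metadata(rng, m, frac_ambiguous=0.0, spacing_bp=spacing_bp)
    return dos, variants


def simulate_genetics(
    n: int,
    m_variants: int,
    n_traits: int,
    seed: int,
    architecture: Mapping | None = None,
):
    """Genotypes, trait architectures, and noisy GWAS summaries.

    Architecture keys (defaults in parentheses): ``prop_causal`` (0.2),
    ``h2`` (0.3) per-trait genetic variance on a unit-variance liability
    scale, ``cross_trait_corr`` (0.4) correlation of causal effects
    across traits, ``gwas_n`` (200_000) sample size governing summary
    noise, ``ancestry_attenuation`` (0.8) correlation between European
    and East-Asian true effects, ``n_trans_traits`` (half) number of
    traits reported as a single trans-ancestry GWAS, ``frac_ambiguous``
    (0.0) strand-ambiguous variants in the panel.

    Returns ``(dosages, variants, summaries, true_weights)`` where
    ``summaries`` maps trait -> {ancestry: DataFrame} in the GWAS
    summary layout (`variant_id chrom pos effect_allele other_allele
    beta p eaf`) and ``true_weights`` is the (m, T) matrix of true
    per-allele effects (EUR/trans scale).
    """
    if m_variants < 50:
        raise ValueError("m_variants must be >= 50")
    arch = {
        "prop_causal": 0.2,
        "h2": 0.3,
        "cross_trait_corr": 0.4,
        "gwas_n": 200_000,
        "ancestry_attenuation": 0.8,
        "n_trans_traits": n_traits // 2,
        "frac_ambiguous": 0.0,
    }
    if architecture:
        unknown = set(architecture) - set(arch)
        if unknown:
            raise ValueError(f"unknown architecture keys: {sorted(unknown)}")
        arch.update(architecture)

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.5, size=m_variants)
    dosages = rng.binomial(2, freqs, size=(n, m_variants)).astype(float)
    variants = _variant_metadata(rng, m_variants, arch["frac_ambiguous"])
    variants["eaf"] = freqs

    m, T = m_variants, n_traits
    rho = arch["cross_trait_corr"]
    causal = rng.uniform(size=m) < arch["prop_causal"]
    shared = rng.normal(size=m)
    W = np.zeros((m, T))
    for t in range(T):
        raw = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=m)
        w = np.where(causal, raw, 0.0)
        var_g = np.sum(w**2 * 2 * freqs * (1 - freqs))
        if var_g > 0:
            w = w * np.sqrt(arch["h2"] / var_g)
        W[:, t] = w

    att = arch["ancestry_attenuation"]
    se = 1.0 / np.sqrt(arch["gwas_n"] * 2 * freqs * (1 - freqs))

    def summary(true_w):
        from scipy.stats import norm

        beta_hat = true_w + rng.normal(scale=se)
        z = beta_hat / se
        p = np.clip(2 * norm.sf(np.abs(z)), 1e-300, 1.0)
        return pd.DataFrame(
            {
                "variant_id": variants["variant_id"],
                "chrom": variants["chrom"],
                "pos": variants["pos"],
                "effect_allele": variants["allele1"],
                "other_allele": variants["allele2"],
                "beta": beta_hat,
                "p": p,
                "eaf": freqs,
            }
        )

    summaries: dict[str, dict[str, pd.DataFrame]] = {}
    n_trans = int(arch["n_trans_traits"])
    for t in range(T):
        trait = f"trait{t + 1}"
        if t < n_trans:
            summaries[trait] = {"trans": summary(W[:, t])}
        else:
            w_scale = np.std(W[:, t]) if np.std(W[:, t]) > 0 else 1.0
            indep = rng.normal(scale=w_scale, size=m) * causal
            w_eas = att * W[:, t] + np.sqrt(max(0.0, 1 - att**2)) * indep
            summaries[trait] = {"EUR": summary(W[:, t]), "EAS": summary(w_eas)}

    return dosages, variants, summaries, W


def simulate_liability_outcome(
    dosages: np.ndarray,
    true_weights: np.ndarray,
    trait_effects: Sequence[float],
    seed: int,
    prevalence: float = 0.25,
):
    """Binary outcome from a logistic liability over trait genetic values.

    ``trait_effects`` are log-odds per SD of each trait's genetic value;
    the intercept is set so the expected case fraction is `prevalence`.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    gvals = dosages @ true_weights
    sd = gvals.std(axis=0)
    sd[sd == 0] = 1.0
    z = (gvals - gvals.mean(axis=0)) / sd
    lin = z @ np.asarray(trait_effects, dtype=float)

    def mean_p(b0):
        return expit(b0 + lin).mean() - prevalence

    b0 = brentq(mean_p, -20, 20)
    return (rng.uniform(size=len(lin)) < expit(b0 + lin)).astype(int)
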