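"""Synthetic worlds and imperfect observations for end-to-end testing.

``generate_world`` draws a fully known truth — exposures, covariates, and
the latent pregnancy-risk / abortion-propensity surfaces — from exactly
the generative process the inference module assumes (hierarchical country
baselines inside modeling groups, covariate effects on standardized
covariates, first-order random walks over periods).  ``generate_observations``
then degrades the truth into the datum taxonomy the classifiers expect:
complete and incomplete registries, surveys of women under-reporting by a
regional inflation factor, AICM studies decomposed into complications and
multipliers, and intention surveys with varying scope, instrument,
microdata access and recall windows.

All randomness flows from a single seed through per-country
``SeedSequence`` spawn keys, so enlarging the world leaves previously
generated countries untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import accounting
from .accounting import (
    GROUPS,
    DEFAULT_PERIODS,
    ExposureSurface,
    RateSurface,
    compute_accounts,
    indicator_table,
    PERIOD_WIDTH,
)
from .abortion_data import AbortionDatum
from .intention_data import BirthRecord, IntentionDatum
from .inference import ModelConfig, Posterior, softplus, default_priors

__all__ = [
    "SyntheticWorldConfig",
    "ObservationProcessConfig",
    "WorldTruth",
    "generate_world",
    "generate_observations",
    "recovery_report",
]

F = len(GROUPS)

#: Candidate covariates; only the first two carry true effects by default.
COVARIATE_NAMES = (
    "gdp_per_capita",
    "legal_abortion_status",
    "hdi",
    "female_literacy",
    "gender_inequality_index",
    "urban_population",
)


@dataclass
class SyntheticWorldConfig:
    seed: int  # mandatory: no implicit randomness
    n_regions: int = 4
    countries_per_region: int = 5
    periods: tuple = DEFAULT_PERIODS
    group_mean_log_omega: tuple = tuple(default_priors()["world_mean_om"])
    group_mean_logit_alpha: tuple = tuple(default_priors()["world_mean_al"])
    sigma_world: float = 0.3  # spread of true world means around the defaults
    sigma_group: float = 0.15
    sigma_country: float = 0.2
    sigma_rw: float = 0.05
    beta_omega: tuple = (-0.10, 0.0)  # effects of the first two covariates
    beta_alpha: tuple = (0.0, 0.25)
    inflation_factors: tuple = (1.25, 1.5, 2.0, 2.5)  # cycled over regions
    recall_bias: tuple = (0.10, 0.20, 0.30, 0.15)  # logit shift, cycled
    mean_women: float = 1.0e6
    women_spread: float = 0.3  # lognormal SD of country size
    growth_per_period: float = 0.01
    births_noise_cv: float = 0.02  # UNPD birth estimates are not exact

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.sigma_group, self.sigma_country) <= 0 or self.sigma_rw < 0:
            raise ValueError("hierarchy SDs must be positive")


@dataclass
class ObservationProcessConfig:
    seed: int
    regime_proportions: dict = field(default_factory=lambda: {
        "complete_registry": 0.2,
        "incomplete_registry": 0.2,
        "survey_with_underreporting": 0.2,
        "aicm_setting": 0.2,
        "none": 0.2,
    })
    pair_survey_with_registry: bool = True  # underpins regional inflation info
    registry_noise_sd: float = 0.05  # log scale
    survey_noise_sd: float = 0.10  # log scale
    incomplete_fraction: float = 0.70
    spontaneous_prob: float = 0.25
    subgroup_prob: float = 0.3
    non_national_prob: float = 0.15
    special_population_prob: float = 0.04
    modified_aicm_prob: float = 0.3
    modified_aicm_missing: tuple = (0.05, 0.35)  # share of abortions missed
    spontaneous_capture: tuple = (0.2, 0.8)  # facility share of miscarriages
    aicm_complications_noise_sd: float = 0.08
    # realized counterparts of the model's labeled error components
    nonsampling_sd: float = 0.05
    non_probability_sd: float = 0.20
    subgroup_sd: float = 0.15
    multiplier_noise_sd: float = 0.20
    legal_count_noise_sd: float = 0.10
    intention_coverage: float = 0.8
    intention_se: float = 1.5  # sampling SE in percentage points
    scope_proportions: dict = field(default_factory=lambda: {
        "all_women": 0.6, "ever_married": 0.2, "currently_married": 0.2,
    })
    microdata_prob: float = 0.7
    recall_prob: float = 0.3
    lmup_prob: float = 0.10
    antenatal_prob: float = 0.05
    marital_history_prob: float = 0.8

    def __post_init__(self) -> None:
        total = sum(self.regime_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("regime proportions must sum to 1")
        total = sum(self.scope_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("scope proportions must sum to 1")


@dataclass
class WorldTruth:
    config: SyntheticWorldConfig
    exposure: ExposureSurface
    covariates: pd.DataFrame
    rates: RateSurface
    accounts: accounting.PregnancyAccounts
    regions: dict  # country -> region label
    modeling_groups: dict  # country -> modeling-group label
    params: dict  # true hyperparameters keyed by name

    def model_config(self, covariates: Optional[list] = None, **kwargs) -> ModelConfig:
        return ModelConfig(
            modeling_groups=dict(self.modeling_groups),
            regions=dict(self.regions),
            covariates=list(
                COVARIATE_NAMES[:2] if covariates is None else covariates
            ),
            **kwargs,
        )

    def indicator_truth(self) -> dict:
        return indicator_table(self.accounts, self.exposure.total_women)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_world(cfg: SyntheticWorldConfig) -> WorldTruth:
    R, ncr = cfg.n_regions, cfg.countries_per_region
    C = R * ncr
    T = len(cfg.periods)
    countries = [f"C{r:02d}{i:02d}" for r in range(R) for i in range(ncr)]
    region_of = {
        c: f"R{r:02d}" for r, block in enumerate(range(0, C, ncr))
        for c in countries[block:block + ncr]
    }
    region_labels = sorted(set(region_of.values()))
    # modeling groups coincide with regions here; the model treats them
    # as separate configuration
    modeling_groups = dict(region_of)

    hyper = _rng(cfg.seed, 0)
    # world means drawn around the configured defaults, matching the
    # model's top-level prior (simulation-based-calibration consistency)
    m_om = np.asarray(cfg.group_mean_log_omega, dtype=float) \
        + cfg.sigma_world * hyper.standard_normal(F)
    m_al = np.asarray(cfg.group_mean_logit_alpha, dtype=float) \
        + cfg.sigma_world * hyper.standard_normal(F)
    group_mean_om = np.empty((F, R))
    group_mean_al = np.empty((F, R))
    for r in range(R):  # per-region streams: stable under adding regions
        grng = _rng(cfg.seed, 5, r)
        group_mean_om[:, r] = m_om + cfg.sigma_group * grng.standard_normal(F)
        group_mean_al[:, r] = m_al + cfg.sigma_group * grng.standard_normal(F)

    K = len(COVARIATE_NAMES)
    Xraw = np.zeros((K, C, T))
    base_om = np.zeros((F, C))
    base_al = np.zeros((F, C))
    rw_om = np.zeros((C, T))
    rw_al = np.zeros((C, T))
    women = np.zeros((F, C, T))
    for ci, c in enumerate(countries):
        # stream keyed by (region, within-region index): enlarging the world
        # leaves existing countries' draws untouched
        rng = _rng(cfg.seed, 1, ci // ncr, ci % ncr)
        g = region_labels.index(region_of[c])
        base_om[:, ci] = group_mean_om[:, g] + cfg.sigma_country * rng.standard_normal(F)
        base_al[:, ci] = group_mean_al[:, g] + cfg.sigma_country * rng.standard_normal(F)
        rw_om[ci, 1:] = np.cumsum(cfg.sigma_rw * rng.standard_normal(T - 1))
        rw_al[ci, 1:] = np.cumsum(cfg.sigma_rw * rng.standard_normal(T - 1))
        # covariates: slowly drifting country series; legal status constant
        level = rng.standard_normal(K)
        trend = 0.2 * rng.standard_normal(K)
        for k in range(K):
            Xraw[k, ci, :] = level[k] + trend[k] * np.linspace(0, 1, T)
        Xraw[1, ci, :] = float(rng.random() < 0.5)  # legal_abortion_status
        total = cfg.mean_women * np.exp(cfg.women_spread * rng.standard_normal())
        married = 0.60 + 0.1 * rng.random()
        shares_m = np.array([0.12, 0.55, 0.33])
        shares_u = np.array([0.10, 0.35, 0.55])
        share = np.concatenate([married * shares_m, (1 - married) * shares_u])
        growth = (1 + cfg.growth_per_period) ** np.arange(T)
        women[:, ci, :] = share[:, None] * total * growth[None, :]

    # true effects act on theoretically standardized covariates (unit-scale
    # by construction), so a country's truth never depends on which other
    # countries are in the run; the model's empirical standardization
    # agrees up to O(1/sqrt(C)) wobble
    Xstd = Xraw.copy()
    Xstd[1] = 2.0 * Xraw[1] - 1.0  # Bernoulli(1/2) -> +-1

    beta_om = np.zeros(K)
    beta_al = np.zeros(K)
    beta_om[: len(cfg.beta_omega)] = cfg.beta_omega
    beta_al[: len(cfg.beta_alpha)] = cfg.beta_alpha

    L = base_om[:, :, None] + np.einsum("k,kct->ct", beta_om, Xstd)[None] + rw_om[None]
    A = base_al[:, :, None] + np.einsum("k,kct->ct", beta_al, Xstd)[None] + rw_al[None]
    rates = RateSurface(omega=np.exp(L), alpha=expit(A))

    exposure = ExposureSurface(
        countries=countries, periods=list(cfg.periods), women=women,
        births=np.zeros((C, T)),
    )
    accounts = compute_accounts(exposure, rates)
    # UNPD-style births input: the implied truth, observed with a small CV
    noise = np.empty((C, T))
    for ci in range(C):
        noise[ci] = _rng(cfg.seed, 2, ci // ncr, ci % ncr).standard_normal(T)
    exposure.births = accounts.births_implied * (1.0 + cfg.births_noise_cv * noise)

    cov_rows = []
    for ci, c in enumerate(countries):
        for ti, p in enumerate(cfg.periods):
            cov_rows.append((c, p, *Xraw[:, ci, ti]))
    covariates = pd.DataFrame(
        cov_rows, columns=["country", "period_start", *COVARIATE_NAMES]
    )

    inflation = {
        r: cfg.inflation_factors[i % len(cfg.inflation_factors)]
        for i, r in enumerate(region_labels)
    }
    recall = {
        r: cfg.recall_bias[i % len(cfg.recall_bias)]
        for i, r in enumerate(region_labels)
    }
    params = {
        "group_mean_om": group_mean_om,  # (F, R) in region_labels order
        "group_mean_al": group_mean_al,
        "country_base_om": base_om,
        "country_base_al": base_al,
        "beta_om": beta_om[:2],
        "beta_al": beta_al[:2],
        "inflation_factors": inflation,
        "recall_bias": recall,
        "region_labels": region_labels,
    }
    return WorldTruth(
        config=cfg, exposure=exposure, covariates=covariates, rates=rates,
        accounts=accounts, regions=region_of, modeling_groups=modeling_groups,
        params=params,
    )


# ---------------------------------------------------------------------------
# Observation process


_REGIMES = (
    "complete_registry",
    "incomplete_registry",
    "survey_with_underreporting",
    "aicm_setting",
    "none",
)


def _assign_regimes(cfg: ObservationProcessConfig, n: int) -> list[str]:
    """Deterministic largest-remainder assignment within a region block."""
    quotas = {k: cfg.regime_proportions.get(k, 0.0) * n for k in _REGIMES}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    rem = n - sum(counts.values())
    order = sorted(_REGIMES, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    out = []
    for k in _REGIMES:
        out.extend([k] * counts[k])
    return out[:n]


def generate_observations(
    truth: WorldTruth, cfg: ObservationProcessConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade the truth into raw abortion and intention datum tables."""
    world = truth.config
    countries = truth.exposure.countries
    periods = truth.exposure.periods
    ncr = world.countries_per_region
    psi_annual = truth.accounts.Psi / PERIOD_WIDTH
    births_annual = truth.accounts.births_implied / PERIOD_WIDTH
    ind = truth.indicator_truth()
    pu_births = ind["pct_births_unintended"]
    pu_pregs = ind["pct_pregnancies_unintended"]

    # marital percent intended from the accounts directly
    married_int = [i for i, g in enumerate(GROUPS)
                   if g.marital_status == "married" and g.need_status == "no_need"]
    married_all = [i for i, g in enumerate(GROUPS) if g.marital_status == "married"]
    b_f = truth.accounts.births_f
    pct_marital_int = (
        100.0 * b_f[married_int].sum(axis=0) / b_f[married_all].sum(axis=0)
    )

    regimes: dict[str, str] = {}
    for block in range(0, len(countries), ncr):
        names = countries[block:block + ncr]
        for c, reg in zip(names, _assign_regimes(cfg, len(names))):
            regimes[c] = reg

    ab_rows: list[AbortionDatum] = []
    int_rows: list[IntentionDatum] = []
    for ci, c in enumerate(countries):
        region = truth.regions[c]
        infl = truth.params["inflation_factors"][region]
        recall_shift = truth.params["recall_bias"][region]
        rng = _rng(cfg.seed, 10, ci // ncr, ci % ncr)
        regime = regimes[c]
        for ti, p in enumerate(periods):
            a_true = psi_annual[ci, ti]
            b_true = births_annual[ci, ti]
            did = f"{c}-{p}"

            def noisy(x, sd):
                return float(x * np.exp(sd * rng.standard_normal()))

            special = rng.random() < cfg.special_population_prob
            if regime in ("complete_registry", "incomplete_registry"):
                frac = 1.0 if regime == "complete_registry" else cfg.incomplete_fraction
                count = noisy(a_true * frac, cfg.registry_noise_sd)
                datum = AbortionDatum(
                    country=c, period=p, source="official_statistic",
                    reported_count=count, live_births=b_true,
                    special_population=special, datum_id=f"ab-{did}",
                    region=region,
                )
                if regime == "incomplete_registry":
                    # rotate the mechanism that reveals incompleteness
                    mech = ti % 4
                    if mech == 0:
                        datum.legal_broadly_available = False
                    elif mech == 1:
                        datum.acknowledged_completeness = cfg.incomplete_fraction
                    elif mech == 2:
                        datum.informal_sector_substantial = True
                    else:
                        datum.implausible_per_review = True
                elif rng.random() < cfg.spontaneous_prob:
                    # registries see only a fraction of spontaneous losses,
                    # so the pregnancy-identity revision over-subtracts:
                    # the revised count is a genuine minimum for induced
                    # abortions and the raw count a genuine maximum
                    datum.includes_spontaneous = True
                    capture = rng.uniform(*cfg.spontaneous_capture)
                    datum.reported_count = noisy(
                        a_true + capture * (a_true / 10 + b_true / 5),
                        cfg.registry_noise_sd,
                    )
                ab_rows.append(datum)
            # the survey/registry coincidence that identifies a regional
            # inflation factor does not exist everywhere: the last region
            # goes without, so its surveys inform the model as minimums
            paired_region = (ci // ncr) < (len(countries) // ncr) - 1
            if regime == "survey_with_underreporting" or (
                regime == "complete_registry" and cfg.pair_survey_with_registry
                and paired_region
            ):
                # realize every error component the classifier will assign
                national = rng.random() > cfg.non_national_prob
                subgroup = rng.random() < cfg.subgroup_prob
                sd2 = cfg.survey_noise_sd ** 2 + cfg.nonsampling_sd ** 2
                if not national:
                    sd2 += cfg.non_probability_sd ** 2
                if subgroup:
                    sd2 += cfg.subgroup_sd ** 2
                count = noisy(a_true / infl, np.sqrt(sd2))
                ab_rows.append(AbortionDatum(
                    country=c, period=p, source="published_study",
                    method="womens_reports", reported_count=count,
                    live_births=b_true,
                    special_population=rng.random() < cfg.special_population_prob,
                    national_probability_sample=national,
                    subgroup_breakdown=subgroup,
                    sampling_variance=cfg.survey_noise_sd ** 2,
                    datum_id=f"sv-{did}", region=region,
                ))
            if regime == "aicm_setting":
                mult_true = float(rng.uniform(3.0, 6.0))
                comp = a_true / mult_true * np.exp(
                    cfg.aicm_complications_noise_sd * rng.standard_normal()
                )
                # the multiplier is itself estimated from a provider survey
                mult = mult_true * float(
                    np.exp(cfg.multiplier_noise_sd * rng.standard_normal())
                )
                national = rng.random() > cfg.non_national_prob
                if not national:
                    comp *= float(
                        np.exp(cfg.non_probability_sd * rng.standard_normal())
                    )
                modified = rng.random() < cfg.modified_aicm_prob
                # modified AICM settings still miss part of the informal
                # sector, which is why such datums are treated as minimums
                miss = rng.uniform(*cfg.modified_aicm_missing) if modified else 0.0
                legal = (
                    float(0.3 * a_true * (1 - miss)
                          * np.exp(cfg.legal_count_noise_sd
                                   * rng.standard_normal()))
                    if modified else None
                )
                est_comp = comp * ((0.7 * (1 - miss)) if modified else 1.0)
                ab_rows.append(AbortionDatum(
                    country=c, period=p, source="published_study",
                    method="aicm", reported_count=np.nan, live_births=b_true,
                    special_population=special,
                    national_probability_sample=national,
                    aicm_complications_treated=float(est_comp),
                    aicm_total_complications=float(est_comp * 1.25),
                    aicm_multiplier=mult, aicm_legal_abortions=legal,
                    datum_id=f"ab-{did}", region=region,
                ))

            # intention surveys, independent of the abortion regime
            if rng.random() < cfg.intention_coverage:
                scope = rng.choice(
                    list(cfg.scope_proportions),
                    p=list(cfg.scope_proportions.values()),
                )
                microdata = rng.random() < cfg.microdata_prob
                recall = rng.random() < cfg.recall_prob
                antenatal = rng.random() < cfg.antenatal_prob
                lmup = rng.random() < cfg.lmup_prob
                denominator = "pregnancies" if (
                    not antenatal and rng.random() < 0.2
                ) else "births"
                pu_true = pu_pregs[ci, ti] if denominator == "pregnancies" \
                    else pu_births[ci, ti]
                if antenatal:
                    pu_true = pu_births[ci, ti]
                national = rng.random() > cfg.non_national_prob
                logit = np.log(pu_true / (100 - pu_true))
                if recall and not microdata:
                    logit -= recall_shift  # long recall inflates "intended"
                se_logit = cfg.intention_se / (pu_true * (100 - pu_true) / 100)
                sd2 = se_logit ** 2 + cfg.nonsampling_sd ** 2
                if not national:
                    sd2 += cfg.non_probability_sd ** 2
                pu_obs = 100 * expit(
                    logit + np.sqrt(sd2) * rng.standard_normal()
                )
                pm_true = pct_marital_int[ci, ti]
                se_logit_m = cfg.intention_se / (
                    pm_true * (100 - pm_true) / 100
                )
                sd2_m = (se_logit_m ** 2 + cfg.nonsampling_sd ** 2
                         + cfg.subgroup_sd ** 2)
                if not national:
                    sd2_m += cfg.non_probability_sd ** 2
                pm_obs = float(100 * expit(
                    np.log(pm_true / (100 - pm_true))
                    + np.sqrt(sd2_m) * rng.standard_normal()
                ))
                datum = IntentionDatum(
                    country=c, period=p, percent_unintended=float(pu_obs),
                    scope=str(scope), denominator=denominator,
                    special_population=rng.random() < cfg.special_population_prob,
                    national_probability_sample=national,
                    microdata_available=microdata,
                    sampling_error=cfg.intention_se if microdata else None,
                    recall_over_one_year=recall,
                    antenatal_clinic_sample=antenatal,
                    marital_history_available=rng.random() < cfg.marital_history_prob,
                    recent_birth_restriction=rng.random() < 0.5,
                    percent_marital_intended=pm_obs,
                    datum_id=f"in-{did}", region=region,
                )
                if scope == "currently_married":
                    # the survey measures unintendedness among married women
                    pmu = 100.0 - pm_obs
                    datum.percent_unintended = float(np.clip(pmu, 1, 99))
                if lmup and scope == "all_women":
                    datum.instrument = "lmup"
                    amb = float(rng.uniform(5, 15))
                    unw = float(np.clip(pu_obs - amb / 2, 0.5, 98 - amb))
                    datum.lmup_unwanted = unw
                    datum.lmup_ambivalent = amb
                    datum.lmup_planned = 100.0 - unw - amb
                if not datum.marital_history_available:
                    # enough records that the interval midpoint's sampling
                    # noise matches the survey-scale sampling error
                    datum.birth_records = _toy_records(
                        rng, pm_true, n=400, ambiguous_frac=0.15
                    )
                int_rows.append(datum)

    ab_frame = pd.DataFrame([vars(d) for d in ab_rows])
    int_frame = pd.DataFrame([vars(d) for d in int_rows])
    return ab_frame, int_frame


def _toy_records(rng, pct_intended: float, n: int, ambiguous_frac: float):
    records = []
    for _ in range(n):
        intended = bool(rng.random() < pct_intended / 100.0)
        u = rng.random()
        if u < 0.15:  # premarital birth
            records.append(BirthRecord(2000.0, 2005.0, True, intended))
        elif u < 0.15 + ambiguous_frac:  # no longer in first union
            records.append(BirthRecord(2008.0, 2005.0, False, intended))
        else:
            records.append(BirthRecord(2008.0, 2005.0, True, intended))
    return records


# ---------------------------------------------------------------------------
# Recovery metrics


def recovery_report(truth: WorldTruth, posterior: Posterior) -> pd.DataFrame:
    """RMSE, bias and 95% coverage per parameter family.

    Rows are individual parameters; aggregate per family with groupby.
    """
    model = posterior.model
    rows = []

    def add(family, name, true_value, draws):
        lo, md, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        rows.append({
            "family": family, "parameter": name, "truth": float(true_value),
            "median": float(md), "lower95": float(lo), "upper95": float(hi),
            "error": float(md - true_value),
            "covered": bool(lo <= true_value <= hi),
        })

    # group-level means (model group labels == generator region labels)
    region_labels = truth.params["region_labels"]
    for s, key in (("om", "group_mean_om"), ("al", "group_mean_al")):
        draws = posterior.get(f"group_mean_{s}")  # (n, F, G)
        for gi, glabel in enumerate(model.group_labels):
            ri = region_labels.index(glabel)
            for fi in range(F):
                add(f"group_mean_{s}", f"{glabel}/f{fi}",
                    truth.params[key][fi, ri], draws[:, fi, gi])

    for s, key in (("om", "beta_om"), ("al", "beta_al")):
        if model.K:
            draws = posterior.get(f"beta_{s}")
            for k in range(min(model.K, len(truth.params[key]))):
                add(f"beta_{s}", model.config.covariates[k],
                    truth.params[key][k], draws[:, k])

    infl_draws = posterior.inflation_factor_draws()
    for ri, r in enumerate(model.region_labels):
        add("inflation_factor", r,
            truth.params["inflation_factors"][r], infl_draws[:, ri])
    rho_draws = posterior.get("rho")
    for ri, r in enumerate(model.region_labels):
        add("recall_bias", r, truth.params["recall_bias"][r], rho_draws[:, ri])

    # latent surfaces on the natural scale
    omega_draws, alpha_draws = posterior.rate_draws()
    idx = [(fi, ci, ti) for fi in range(F)
           for ci in range(0, model.C, max(1, model.C // 5))
           for ti in range(0, model.T, 2)]
    for fi, ci, ti in idx:
        add("alpha", f"f{fi}/c{ci}/t{ti}", truth.rates.alpha[fi, ci, ti],
            alpha_draws[:, fi, ci, ti])
        add("omega", f"f{fi}/c{ci}/t{ti}", truth.rates.omega[fi, ci, ti],
            omega_draws[:, fi, ci, ti])
    return pd.DataFrame(rows)
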