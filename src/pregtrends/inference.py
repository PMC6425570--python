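"""Bayesian hierarchical time-series model for pregnancy and abortion rates.

The latent state is a pair of surfaces over (group f, country c, period t):
``log omega_fct`` (pregnancy risk) and ``logit alpha_fct`` (propensity of a
pregnancy to end in induced abortion).  Each surface decomposes as

    country baseline (per group)  +  covariate term  +  random walk in t,

with country baselines pooled hierarchically inside modeling groups and
modeling-group means pooled toward world means.  Survey under-reporting is
captured by regional inflation factors (>= 1 on the natural scale) and
long-recall response bias by regional intercepts, both with hierarchical
priors.  UNPD live births enter as a high-precision Gaussian likelihood on
the implied birth count.

Classified observations contribute Gaussian terms (points, possibly
right-truncated for AICM complication counts) or soft-bound terms
(Gaussian-CDF likelihoods for minimum / maximum / interval data) on the
transformed scale, with variance equal to the sum of their labeled error
components.

Fitting is by penalized maximum a posteriori with an analytic gradient,
followed by a Laplace (Gaussian) approximation for posterior draws;
preconditioned HMC and adaptive Metropolis samplers seeded from the
Laplace factor are available for verification, with split-chain
R-hat / ESS diagnostics.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, linalg
from scipy.special import log_ndtr, expit

from . import accounting
from .accounting import (
    GROUPS,
    ExposureSurface,
    RateSurface,
    PERIOD_WIDTH,
    compute_accounts,
    indicator_table,
    INDICATORS,
)
from .observations import ClassifiedObservation, INDICATOR_SCALES

__all__ = [
    "ModelConfig",
    "PregnancyModel",
    "Posterior",
    "build_model",
    "fit",
    "loglik_point",
    "loglik_bound",
    "apply_inflation",
    "validate_holdout",
    "select_covariates",
    "aggregate",
]

F = len(GROUPS)
_UNINTENDED_IDX = np.array(
    [i for i, g in enumerate(GROUPS) if g.need_status != "no_need"]
)
_INTENDED_IDX = np.array(
    [i for i, g in enumerate(GROUPS) if g.need_status == "no_need"]
)
_MARRIED_UNINT_IDX = np.array(
    [i for i, g in enumerate(GROUPS)
     if g.marital_status == "married" and g.need_status != "no_need"]
)
_MARRIED_INT_IDX = np.array(
    [i for i, g in enumerate(GROUPS)
     if g.marital_status == "married" and g.need_status == "no_need"]
)

_LOGIT_CLIP = (0.2, 99.8)  # percent clip before logit transform

_SURFACES = ("om", "al")


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


# ---------------------------------------------------------------------------
# Configuration


def default_priors() -> dict:
    """Weakly informative defaults; all tunables live here, none hard-coded
    in the density."""
    return {
        # world means of log pregnancy risk per group (per woman-year);
        # unmarried no-need women are largely sexually inactive, keeping
        # nonmarital births mostly unintended (the ordering the
        # currently-married bound rule assumes)
        "world_mean_om": [np.log(r) for r in (0.20, 0.05, 0.15, 0.12, 0.04, 0.01)],
        # world means of logit abortion propensity per group: unintended
        # pregnancies are aborted more often when unmarried
        "world_mean_al": [_logit(p) for p in (0.30, 0.40, 0.04, 0.60, 0.70, 0.10)],
        "world_mean_sd": 0.3,
        "beta_sd": 1.0,
        "sigma_group_scale": 0.3,  # half-normal scales
        "sigma_country_scale": 0.3,
        "sigma_rw_scale": 0.1,
        "zeta0": -0.7,  # softplus(-0.7) ~ log 1.5 inflation
        "mu_zeta_sd": 1.0,
        "sigma_zeta": 0.5,
        "mu_rho_sd": 0.5,
        "sigma_rho": 0.2,
    }


def default_error_components() -> dict:
    """Default additive variances on the transformed (log / logit) scale."""
    return {
        "sampling": 0.01,
        "non_probability": 0.04,
        "subgroup": 0.0225,
        "multiplier": 0.04,
        "complications": 0.01,
        "legal_count": 0.01,
        "nonsampling_default": 0.0025,
    }


@dataclass
class ModelConfig:
    modeling_groups: dict  # country -> modeling-group label
    regions: dict  # country -> region label
    covariates: list = dc_field(default_factory=list)  # covariate column names
    priors: dict = dc_field(default_factory=default_priors)
    error_components: dict = dc_field(default_factory=default_error_components)
    bound_softness: float = 0.1  # base soft-bound SD on the transformed scale
    births_cv: float = 0.02  # coefficient of variation of the births likelihood
    sampler: dict = dc_field(
        default_factory=lambda: {"method": "laplace", "chains": 4,
                                 "draws": 500, "seed": 0, "tune": 500}
    )
    suppress_width_ratio: Optional[float] = None  # country-suppression rule

    def __post_init__(self) -> None:
        pri = default_priors()
        pri.update(self.priors)
        self.priors = pri
        err = default_error_components()
        err.update(self.error_components)
        self.error_components = err

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# Likelihood primitives (transformed scale)


def _phi_over_Phi(u):
    """phi(u)/Phi(u), numerically stable for very negative u."""
    u = np.asarray(u, dtype=float)
    log_pdf = -0.5 * u * u - 0.5 * np.log(2 * np.pi)
    return np.exp(log_pdf - log_ndtr(u))


def loglik_point(
    y: float,
    latent: float,
    variance: float,
    truncation: Optional[float] = None,
    truncation_sd: Optional[float] = None,
) -> float:
    """Gaussian point-observation log density on the transformed scale.

    When ``truncation`` is given the observation error is right-truncated
    (AICM complication counts cannot exceed the total complication count),
    i.e. the density is renormalized by Phi((truncation - latent)/sd).
    """
    ll, _ = _point_ll_grad(y, latent, variance, truncation, truncation_sd)
    return float(ll)


def _point_ll_grad(y, latent, variance, truncation=None, truncation_sd=None):
    if variance <= 0:
        raise ValueError("point observation requires positive total variance")
    resid = latent - y
    ll = -0.5 * resid * resid / variance - 0.5 * np.log(2 * np.pi * variance)
    grad = -resid / variance
    if truncation is not None:
        tsd = truncation_sd if truncation_sd is not None else np.sqrt(variance)
        # renormalize: observation error cannot exceed the right bound
        u = (truncation - latent) / tsd
        ll -= log_ndtr(u)
        grad += _phi_over_Phi(u) / tsd
    return ll, grad


def loglik_bound(
    bound: str,
    value: float,
    latent: float,
    softness: float,
    value_high: Optional[float] = None,
) -> float:
    """Soft-bound log likelihood: ``log Phi((latent - value)/s)`` for a
    minimum, mirrored for a maximum, and a difference of Phi terms for an
    interval.  The hard-bound (censoring) likelihood is the s -> 0 limit."""
    ll, _ = _bound_ll_grad(bound, value, latent, softness, value_high)
    return float(ll)


def _bound_ll_grad(bound, value, latent, softness, value_high=None):
    s = softness
    if s <= 0:
        raise ValueError("bound softness must be positive")
    if bound == "minimum":
        u = (latent - value) / s
        return log_ndtr(u), _phi_over_Phi(u) / s
    if bound == "maximum":
        u = (value - latent) / s
        return log_ndtr(u), -_phi_over_Phi(u) / s
    if bound == "interval":
        if value_high is None or value > value_high:
            raise ValueError("interval requires low <= high")
        u = (latent - value) / s
        v = (latent - value_high) / s
        # log(Phi(u) - Phi(v)); switch to the survival branch when both
        # arguments sit in the upper tail, where Phi saturates
        if u + v <= 0:
            la, lb = log_ndtr(u), log_ndtr(v)  # la >= lb
        else:
            la, lb = log_ndtr(-v), log_ndtr(-u)  # Phi(u)-Phi(v) = Phic(v)-Phic(u)
        diff = la + np.log1p(-np.exp(np.minimum(lb - la, -1e-12)))
        log_pu = -0.5 * u * u - 0.5 * np.log(2 * np.pi)
        log_pv = -0.5 * v * v - 0.5 * np.log(2 * np.pi)
        grad = (np.exp(log_pu - diff) - np.exp(log_pv - diff)) / s
        return diff, grad
    raise ValueError(f"unknown bound type {bound!r}")


def apply_inflation(observed_expectation: float, factor: float) -> float:
    """Expected observed value of a survey linked to an inflation factor:
    the latent quantity divided by the factor (factor >= 1 under-reports)."""
    if factor <= 0:
        raise ValueError("inflation factor must be positive")
    return observed_expectation / factor


def softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# Model


@dataclass
class _ObsTerm:
    """Preprocessed observation: everything the density needs."""

    ci: int
    ti: int
    indicator: str
    bound: str
    y: float
    y_high: Optional[float]
    variance: float
    softness: float
    truncation: Optional[float]
    truncation_sd: Optional[float]
    inflate_region: Optional[int]
    recall_region: Optional[int]
    source: ClassifiedObservation


class PregnancyModel:
    """Joint density over the latent parameters given classified data."""

    def __init__(
        self,
        observations: Sequence[ClassifiedObservation],
        exposure: ExposureSurface,
        covariates: Optional[pd.DataFrame],
        config: ModelConfig,
    ):
        self.config = config
        self.exposure = exposure
        self.countries = list(exposure.countries)
        self.periods = list(exposure.periods)
        self.C = len(self.countries)
        self.T = len(self.periods)
        self.K = len(config.covariates)
        self._cidx = {c: i for i, c in enumerate(self.countries)}
        self._tidx = {p: i for i, p in enumerate(self.periods)}

        missing = [c for c in self.countries if c not in config.modeling_groups]
        if missing:
            raise ValueError(f"countries without modeling group: {missing}")
        missing = [c for c in self.countries if c not in config.regions]
        if missing:
            raise ValueError(f"countries without region: {missing}")
        self.group_labels = sorted(set(config.modeling_groups[c] for c in self.countries))
        self.region_labels = sorted(set(config.regions[c] for c in self.countries))
        self.G = len(self.group_labels)
        self.R = len(self.region_labels)
        self._gofc = np.array(
            [self.group_labels.index(config.modeling_groups[c]) for c in self.countries]
        )
        self._rofc = np.array(
            [self.region_labels.index(config.regions[c]) for c in self.countries]
        )

        self.X = self._standardized_covariates(covariates)  # (K, C, T)
        self.obs_terms = [self._prepare(o) for o in observations if not o.excluded]
        self._layout()

    # -- construction helpers ------------------------------------------------

    def _standardized_covariates(self, covariates) -> np.ndarray:
        K = self.K
        X = np.zeros((K, self.C, self.T))
        if K == 0:
            return X
        if covariates is None:
            raise ValueError("config names covariates but no covariate table given")
        tbl = covariates.set_index(["country", "period_start"])
        for k, name in enumerate(self.config.covariates):
            if name not in tbl.columns:
                raise ValueError(f"covariate {name!r} missing from table")
            for ci, c in enumerate(self.countries):
                for ti, p in enumerate(self.periods):
                    X[k, ci, ti] = tbl.loc[(c, p), name]
        # standardize to mean 0, SD 1 within the run
        flat = X.reshape(K, -1)
        mean = flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return ((flat - mean) / sd).reshape(K, self.C, self.T)

    def _transform(self, obs: ClassifiedObservation, x: float) -> float:
        if INDICATOR_SCALES[obs.indicator] == "log":
            if x <= 0:
                x = 0.5  # zero counts: half-count continuity guard
            return float(np.log(x))
        p = float(np.clip(x, *_LOGIT_CLIP)) / 100.0
        return float(np.log(p) - np.log1p(-p))

    def _prepare(self, obs: ClassifiedObservation) -> _ObsTerm:
        if obs.indicator not in INDICATOR_SCALES:
            raise ValueError(f"observation on unknown indicator {obs.indicator!r}")
        if obs.country not in self._cidx:
            raise ValueError(f"observation references unknown country {obs.country!r}")
        if obs.period not in self._tidx:
            raise ValueError(f"observation references unknown period {obs.period}")
        comp = self.config.error_components
        variance = 0.0
        for label, v in obs.error_components.items():
            variance += comp[label] if v is None else float(v)
        y = self._transform(obs, obs.value)
        y_high = (
            self._transform(obs, obs.value_high) if obs.value_high is not None else None
        )
        trunc = trunc_sd = None
        if obs.truncation is not None and obs.bound == "point":
            # right-truncated observation error (AICM complications): the
            # renormalizer must use the same SD as the density, or the
            # joint density becomes unbounded in the latent rate
            trunc = self._transform(obs, obs.truncation)
            trunc_sd = float(np.sqrt(variance))
        softness = float(np.sqrt(self.config.bound_softness ** 2 + variance))
        inflate = recall = None
        if obs.inflation_link == "regional_inflation_factor":
            region = obs.region or self.config.regions.get(obs.country)
            if region is None:
                raise ValueError(
                    f"inflation link set but region unknown for {obs.country}"
                )
            inflate = self.region_labels.index(region)
        if obs.recall_bias_flag:
            region = obs.region or self.config.regions[obs.country]
            recall = self.region_labels.index(region)
        if obs.bound == "point" and variance <= 0:
            raise ValueError("point observation with nonpositive total variance")
        return _ObsTerm(
            ci=self._cidx[obs.country],
            ti=self._tidx[obs.period],
            indicator=obs.indicator,
            bound=obs.bound,
            y=y,
            y_high=y_high,
            variance=variance,
            softness=softness,
            truncation=trunc,
            truncation_sd=trunc_sd,
            inflate_region=inflate,
            recall_region=recall,
            source=obs,
        )

    def _layout(self) -> None:
        """Assign slices of the flat parameter vector.

        The hierarchy is non-centered: country baselines, modeling-group
        means and random-walk states are stored as standard-normal
        deviates scaled by their (estimated) SDs, which keeps the
        posterior geometry well conditioned.
        """
        self.slices: dict[str, tuple[slice, tuple]] = {}
        pos = 0

        def add(name, shape):
            nonlocal pos
            n = int(np.prod(shape)) if shape else 1
            self.slices[name] = (slice(pos, pos + n), shape)
            pos += n

        for s in _SURFACES:
            add(f"world_mean_{s}", (F,))
            add(f"raw_group_{s}", (F, self.G))
            add(f"raw_country_{s}", (F, self.C))
            add(f"beta_{s}", (self.K,))
            add(f"raw_rw_{s}", (self.C, self.T - 1))
            add(f"lsg_{s}", ())
            add(f"lsc_{s}", ())
            add(f"lsr_{s}", ())
        add("zeta", (self.R,))
        add("mu_zeta", ())
        add("rho", (self.R,))
        add("mu_rho", ())
        self.n_params = pos

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        """Raw or derived parameter block; supports a leading draws axis.

        Derived names: ``group_mean_om/al`` and ``country_base_om/al``.
        """
        if name.startswith(("group_mean_", "country_base_")):
            return self._derived(theta, name)
        sl, shape = self.slices[name]
        block = theta[..., sl]
        return block.reshape(theta.shape[:-1] + shape) if shape else block[..., 0]

    def _derived(self, theta: np.ndarray, name: str) -> np.ndarray:
        s = name.rsplit("_", 1)[1]
        wm = self.get(theta, f"world_mean_{s}")
        sg = np.exp(self.get(theta, f"lsg_{s}"))
        gm = wm[..., :, None] + sg[..., None, None] * self.get(theta, f"raw_group_{s}")
        if name.startswith("group_mean_"):
            return gm
        sc = np.exp(self.get(theta, f"lsc_{s}"))
        return gm[..., :, self._gofc] + sc[..., None, None] * self.get(
            theta, f"raw_country_{s}"
        )

    def initial_point(self) -> np.ndarray:
        pri = self.config.priors
        theta = np.zeros(self.n_params)
        for s in _SURFACES:
            m0 = np.asarray(pri[f"world_mean_{s}"], dtype=float)
            theta[self.slices[f"world_mean_{s}"][0]] = m0
            for nm, key in (
                (f"lsg_{s}", "sigma_group_scale"),
                (f"lsc_{s}", "sigma_country_scale"),
                (f"lsr_{s}", "sigma_rw_scale"),
            ):
                theta[self.slices[nm][0]] = np.log(pri[key] / 2.0)
        theta[self.slices["zeta"][0]] = pri["zeta0"]
        theta[self.slices["mu_zeta"][0]] = pri["zeta0"]
        return theta

    # -- surfaces ------------------------------------------------------------

    def surfaces(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(log omega, logit alpha), each shaped (F, C, T).

        Supports a leading draws dimension on theta.
        """
        out = []
        for s in _SURFACES:
            base = self.get(theta, f"country_base_{s}")  # (..., F, C) derived
            beta = self.get(theta, f"beta_{s}")  # (..., K)
            raw = self.get(theta, f"raw_rw_{s}")  # (..., C, T-1)
            sr = np.exp(self.get(theta, f"lsr_{s}"))
            L = np.repeat(base[..., :, :, None], self.T, axis=-1).astype(float)
            if self.K:
                L = L + np.einsum("...k,kct->...ct", beta, self.X)[..., None, :, :]
            inc = np.asarray(sr)[..., None, None] * raw
            states = np.concatenate(
                [np.zeros(inc.shape[:-1] + (1,)), np.cumsum(inc, axis=-1)], axis=-1
            )  # (..., C, T)
            L = L + states[..., None, :, :]
            out.append(np.clip(L, -40.0, 30.0))
        return out[0], out[1]

    def rate_surface(self, theta: np.ndarray) -> RateSurface:
        L, A = self.surfaces(theta)
        return RateSurface(omega=np.exp(L), alpha=expit(A))

    # -- log posterior and gradient ------------------------------------------

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(all="ignore"):
            lp, grad = self._logp_grad_impl(theta)
        if not (np.isfinite(lp) and np.isfinite(grad).all()):
            # infeasible excursion during a line search: reject the point
            return -1e15, np.zeros_like(theta)
        return lp, grad

    def _forward(self, theta: np.ndarray) -> dict:
        """Forward pass with intermediates kept for backprop."""
        inter = {}
        for s in _SURFACES:
            wm = self.get(theta, f"world_mean_{s}")
            raw_g = self.get(theta, f"raw_group_{s}")
            raw_c = self.get(theta, f"raw_country_{s}")
            raw_i = self.get(theta, f"raw_rw_{s}")
            sg = float(np.exp(np.clip(self.get(theta, f"lsg_{s}"), -30, 30)))
            sc = float(np.exp(np.clip(self.get(theta, f"lsc_{s}"), -30, 30)))
            sr = float(np.exp(np.clip(self.get(theta, f"lsr_{s}"), -30, 30)))
            gm = wm[:, None] + sg * raw_g
            cb = gm[:, self._gofc] + sc * raw_c
            states = np.concatenate(
                [np.zeros((self.C, 1)), np.cumsum(sr * raw_i, axis=1)], axis=1
            )
            S = np.repeat(cb[:, :, None], self.T, axis=2)
            if self.K:
                beta = self.get(theta, f"beta_{s}")
                S = S + np.einsum("k,kct->ct", beta, self.X)[None]
            S = S + states[None]
            # keep exp() finite on line-search excursions; the optimum is
            # far inside the clip range (mask makes the gradient exact)
            mask = (S > -40.0) & (S < 30.0)
            S = np.clip(S, -40.0, 30.0)
            inter[s] = dict(raw_g=raw_g, raw_c=raw_c, raw_i=raw_i, sg=sg,
                            sc=sc, sr=sr, states=states, surface=S, mask=mask)
        return inter

    def _logp_grad_impl(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.config
        grad = np.zeros_like(theta)
        lp = 0.0

        inter = self._forward(theta)
        L, A = inter["om"]["surface"], inter["al"]["surface"]
        omega = np.exp(L)
        alpha = expit(A)
        w = self.exposure.women
        O = PERIOD_WIDTH * w * omega  # Omega^f
        P = O * alpha  # Psi^f
        dP_dA = P * (1.0 - alpha)
        b = (O - 1.1 * P) / 1.2  # implied births per group
        db_dA = -(1.1 / 1.2) * dP_dA

        dL = np.zeros_like(L)
        dA = np.zeros_like(A)

        # births likelihood: UNPD births vs implied, Gaussian with CV
        B = self.exposure.births
        sd = np.maximum(cfg.births_cv * B, 1e-6)
        btot = b.sum(axis=0)
        r = (B - btot) / sd
        lp += -0.5 * float((r * r).sum())
        g = r / sd  # d lp / d btot
        dL += g[None, :, :] * b
        dA += g[None, :, :] * db_dA

        # observation terms
        for term in self.obs_terms:
            ci, ti = term.ci, term.ti
            Oc, Pc, ac, bc = O[:, ci, ti], P[:, ci, ti], alpha[:, ci, ti], b[:, ci, ti]
            theta_val, dl, da = self._indicator_theta(term.indicator, Oc, Pc, ac, bc, ci, ti)
            if theta_val is None:  # degenerate cell, penalty applied in helper
                continue
            shift = 0.0
            if term.inflate_region is not None:
                zeta_r = self.get(theta, "zeta")[term.inflate_region]
                shift += softplus(zeta_r)
            if term.recall_region is not None:
                rho_r = self.get(theta, "rho")[term.recall_region]
                shift += rho_r
            tv = theta_val - shift
            if term.bound == "point":
                ll, dll = _point_ll_grad(
                    term.y, tv, term.variance, term.truncation, term.truncation_sd
                )
            else:
                ll, dll = _bound_ll_grad(
                    term.bound, term.y, tv, term.softness, term.y_high
                )
            lp += float(ll)
            dL[:, ci, ti] += dll * dl
            dA[:, ci, ti] += dll * da
            if term.inflate_region is not None:
                sl = self.slices["zeta"][0]
                grad[sl.start + term.inflate_region] += -dll * expit(zeta_r)
            if term.recall_region is not None:
                sl = self.slices["rho"][0]
                grad[sl.start + term.recall_region] += -dll

        # guard: implied births are nonnegative iff alpha <= 1/1.1; penalize
        # the per-pregnancy (scale-free) violation smoothly
        viol = np.minimum((1.0 - 1.1 * alpha) / 1.2, 0.0)
        if viol.any():
            kappa = 1e4
            lp += -kappa * float((viol * viol).sum())
            # d viol / d A = -(1.1/1.2) alpha (1 - alpha) where viol < 0
            dA += np.where(
                viol < 0,
                -2 * kappa * viol * (-(1.1 / 1.2)) * alpha * (1 - alpha),
                0.0,
            )

        # backprop surfaces to parameters
        for s, dS in (("om", dL), ("al", dA)):
            iv = inter[s]
            dS = dS * iv["mask"]  # clipped cells are locally flat
            dcb = dS.sum(axis=2)  # (F, C)
            grad[self.slices[f"world_mean_{s}"][0]] += dcb.sum(axis=1)
            dgm = np.zeros((F, self.G))
            np.add.at(dgm.T, self._gofc, dcb.T)
            grad[self.slices[f"raw_group_{s}"][0]] += (iv["sg"] * dgm).ravel()
            grad[self.slices[f"lsg_{s}"][0]] += iv["sg"] * float(
                (dgm * iv["raw_g"]).sum()
            )
            grad[self.slices[f"raw_country_{s}"][0]] += (iv["sc"] * dcb).ravel()
            grad[self.slices[f"lsc_{s}"][0]] += iv["sc"] * float(
                (dcb * iv["raw_c"]).sum()
            )
            if self.K:
                grad[self.slices[f"beta_{s}"][0]] += np.einsum(
                    "fct,kct->k", dS, self.X
                )
            dstates = dS.sum(axis=0)  # (C, T)
            rev = np.cumsum(dstates[:, ::-1], axis=1)[:, ::-1]  # sum over t >= k
            grad[self.slices[f"raw_rw_{s}"][0]] += (iv["sr"] * rev[:, 1:]).ravel()
            grad[self.slices[f"lsr_{s}"][0]] += float(
                (dstates * iv["states"]).sum()
            )

        # priors
        lp += self._priors(theta, grad)
        return lp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    def _indicator_theta(self, ind, Oc, Pc, ac, bc, ci, ti):
        """Transformed model value for one observation and its partials
        w.r.t. log omega and logit alpha for the six groups at that cell."""
        if ind in ("abortion_count", "abortion_rate"):
            tot = Pc.sum()
            theta = np.log(tot / PERIOD_WIDTH)
            if ind == "abortion_rate":
                theta += np.log(1000.0) - np.log(self.exposure.total_women[ci, ti])
            dl = Pc / tot
            da = Pc * (1.0 - ac) / tot
            return theta, dl, da
        if ind == "pct_pregnancies_unintended":
            part = Oc[_UNINTENDED_IDX].sum()
            other = Oc[_INTENDED_IDX].sum()
            theta = np.log(part) - np.log(other)
            dl = np.zeros(F)
            dl[_UNINTENDED_IDX] = Oc[_UNINTENDED_IDX] / part
            dl[_INTENDED_IDX] = -Oc[_INTENDED_IDX] / other
            return theta, dl, np.zeros(F)
        if ind in ("pct_births_unintended", "pct_marital_births_intended"):
            if ind == "pct_births_unintended":
                part_idx, other_idx = _UNINTENDED_IDX, _INTENDED_IDX
            else:
                part_idx, other_idx = _MARRIED_INT_IDX, _MARRIED_UNINT_IDX
            part = bc[part_idx].sum()
            other = bc[other_idx].sum()
            if part <= 0 or other <= 0:
                return None, None, None  # penalty term handles this region
            theta = np.log(part) - np.log(other)
            dl = np.zeros(F)
            da = np.zeros(F)
            db_dA = -(1.1 / 1.2) * Pc * (1.0 - ac)
            dl[part_idx] = bc[part_idx] / part
            da[part_idx] = db_dA[part_idx] / part
            dl[other_idx] = -bc[other_idx] / other
            da[other_idx] = -db_dA[other_idx] / other
            return theta, dl, da
        raise ValueError(f"unknown indicator {ind!r}")

    def indicator_gradient(self, theta: np.ndarray, term: "_ObsTerm"):
        """Expected-observation value on the transformed scale (including
        inflation / recall shifts) and its exact gradient w.r.t. the full
        parameter vector; the delta method uses this with the Laplace
        covariance to get posterior variances of predicted observations."""
        inter = self._forward(theta)
        L, A = inter["om"]["surface"], inter["al"]["surface"]
        omega, alpha = np.exp(L), expit(A)
        O = PERIOD_WIDTH * self.exposure.women * omega
        P = O * alpha
        b = (O - 1.1 * P) / 1.2
        ci, ti = term.ci, term.ti
        tv, dl, da = self._indicator_theta(
            term.indicator, O[:, ci, ti], P[:, ci, ti], alpha[:, ci, ti],
            b[:, ci, ti], ci, ti,
        )
        grad = np.zeros(self.n_params)
        if tv is None:
            return float("nan"), grad
        g = self._gofc[ci]
        for s, dvec in (("om", dl), ("al", da)):
            iv = inter[s]
            dv = dvec * iv["mask"][:, ci, ti]
            sl = self.slices[f"world_mean_{s}"][0]
            grad[sl.start:sl.stop] += dv
            sl = self.slices[f"raw_group_{s}"][0]
            grad[sl.start + np.arange(F) * self.G + g] += iv["sg"] * dv
            grad[self.slices[f"lsg_{s}"][0]] += iv["sg"] * float(
                (dv * iv["raw_g"][:, g]).sum()
            )
            sl = self.slices[f"raw_country_{s}"][0]
            grad[sl.start + np.arange(F) * self.C + ci] += iv["sc"] * dv
            grad[self.slices[f"lsc_{s}"][0]] += iv["sc"] * float(
                (dv * iv["raw_c"][:, ci]).sum()
            )
            if self.K:
                sl = self.slices[f"beta_{s}"][0]
                grad[sl.start:sl.stop] += float(dv.sum()) * self.X[:, ci, ti]
            dtot = float(dv.sum())
            if ti >= 1:
                sl = self.slices[f"raw_rw_{s}"][0]
                start = sl.start + ci * (self.T - 1)
                grad[start:start + ti] += iv["sr"] * dtot
            grad[self.slices[f"lsr_{s}"][0]] += dtot * iv["states"][ci, ti]
        shift = 0.0
        if term.inflate_region is not None:
            zeta_r = self.get(theta, "zeta")[term.inflate_region]
            shift += softplus(zeta_r)
            grad[self.slices["zeta"][0].start + term.inflate_region] -= expit(zeta_r)
        if term.recall_region is not None:
            shift += self.get(theta, "rho")[term.recall_region]
            grad[self.slices["rho"][0].start + term.recall_region] -= 1.0
        return float(tv - shift), grad

    def _priors(self, theta: np.ndarray, grad: np.ndarray) -> float:
        pri = self.config.priors
        lp = 0.0

        def gaussian(name, mean, sd):
            # mean may be a scalar or an array matching the flattened block
            nonlocal lp
            sl, _shape = self.slices[name]
            x = theta[sl]
            m = np.asarray(mean, dtype=float).ravel()
            dev = (x - m) / sd ** 2
            lp += -0.5 * float((((x - m) / sd) ** 2).sum()) - x.size * np.log(sd)
            grad[sl] += -dev
            return dev

        for s in _SURFACES:
            m0 = np.asarray(pri[f"world_mean_{s}"], dtype=float)
            gaussian(f"world_mean_{s}", m0, pri["world_mean_sd"])
            # non-centered deviates are standard normal a priori
            for nm in (f"raw_group_{s}", f"raw_country_{s}", f"raw_rw_{s}"):
                gaussian(nm, 0.0, 1.0)
            if self.K:
                gaussian(f"beta_{s}", 0.0, pri["beta_sd"])
            # half-normal priors on the SDs (with log-parametrization Jacobian)
            for nm, scale in (
                (f"lsg_{s}", pri["sigma_group_scale"]),
                (f"lsc_{s}", pri["sigma_country_scale"]),
                (f"lsr_{s}", pri["sigma_rw_scale"]),
            ):
                ls = float(np.clip(theta[self.slices[nm][0]][0], -30, 30))
                sig = float(np.exp(ls))
                lp += -0.5 * sig ** 2 / scale ** 2 + ls
                grad[self.slices[nm][0]] += -(sig ** 2) / scale ** 2 + 1.0

        mu_zeta = self.get(theta, "mu_zeta")
        gaussian("zeta", mu_zeta, pri["sigma_zeta"])
        zeta = self.get(theta, "zeta")
        dev = (zeta - mu_zeta) / pri["sigma_zeta"] ** 2
        grad[self.slices["mu_zeta"][0]] += dev.sum()
        gaussian("mu_zeta", pri["zeta0"], pri["mu_zeta_sd"])

        mu_rho = self.get(theta, "mu_rho")
        gaussian("rho", mu_rho, pri["sigma_rho"])
        rho = self.get(theta, "rho")
        dev = (rho - mu_rho) / pri["sigma_rho"] ** 2
        grad[self.slices["mu_rho"][0]] += dev.sum()
        gaussian("mu_rho", 0.0, pri["mu_rho_sd"])
        return lp

    def inflation_factors(self, theta: np.ndarray) -> np.ndarray:
        """Regional inflation factors on the natural scale (>= 1)."""
        return np.exp(softplus(self.get(theta, "zeta")))


def build_model(
    observations: Sequence[ClassifiedObservation],
    exposure: ExposureSurface,
    config: ModelConfig,
    covariates: Optional[pd.DataFrame] = None,
) -> PregnancyModel:
    return PregnancyModel(observations, exposure, covariates, config)


# ---------------------------------------------------------------------------
# Posterior


@dataclass
class Posterior:
    model: PregnancyModel
    draws: np.ndarray  # (n_draws, n_params)
    map_point: np.ndarray
    diagnostics: dict
    cov_factor: Optional[np.ndarray] = None  # Laplace scale: cov = S S'

    def get(self, name: str) -> np.ndarray:
        return self.model.get(self.draws, name)

    def rate_draws(self) -> tuple[np.ndarray, np.ndarray]:
        """(omega, alpha) draws shaped (n_draws, F, C, T)."""
        L, A = self.model.surfaces(self.draws)
        return np.exp(L), expit(A)

    def account_draws(self) -> dict[str, np.ndarray]:
        """Per-draw group pregnancy/abortion/birth counts (n, F, C, T)."""
        omega, alpha = self.rate_draws()
        w = self.model.exposure.women
        O = PERIOD_WIDTH * w * omega
        P = O * alpha
        b = (O - 1.1 * P) / 1.2
        return {"pregnancies": O, "abortions": P, "births": b}

    def inflation_factor_draws(self) -> np.ndarray:
        return np.exp(softplus(self.get("zeta")))

    def indicator_draws(self, level: str = "country") -> dict:
        return aggregate(self, level)

    def indicator_summary(self, level: str = "country") -> pd.DataFrame:
        """Reported indicators: MAP-anchored point with draw-based intervals.

        Sums of group counts are convex in the latent log rates, so naive
        Gaussian-draw medians drift above the mode along weakly identified
        directions even when the data pin the total; quantiles are
        therefore recentered at the mode-derived value.
        """
        draws = aggregate(self, level)
        modes = aggregate(self, level, draws=self.map_point[None, :])
        rows = []
        for (unit, period), table in draws.items():
            for ind in INDICATORS:
                point = float(modes[(unit, period)][ind][0])
                med, lo80, hi80, lo95, hi95 = np.nanquantile(
                    table[ind], [0.5, 0.1, 0.9, 0.025, 0.975]
                )
                shift = point - med
                rows.append((unit, period, ind, point, lo80 + shift,
                             hi80 + shift, lo95 + shift, hi95 + shift))
        return pd.DataFrame(
            rows,
            columns=["unit", "period_start", "indicator", "point",
                     "lower80", "upper80", "lower95", "upper95"],
        )


def _fd_hessian(model: PregnancyModel, x: np.ndarray, h: float = 1e-5,
                central: bool = True) -> np.ndarray:
    """Hessian of -logp via finite differences of the analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    if central:
        for j in range(n):
            tp = x.copy(); tp[j] += h
            tm = x.copy(); tm[j] -= h
            H[:, j] = -(model.logp_grad(tp)[1] - model.logp_grad(tm)[1]) / (2 * h)
    else:
        g0 = model.logp_grad(x)[1]
        for j in range(n):
            tp = x.copy(); tp[j] += h
            H[:, j] = -(model.logp_grad(tp)[1] - g0) / h
    return 0.5 * (H + H.T)


def _newton_polish(model, x, lp, g, gtol=1e-2, max_iter=60):
    """Damped Newton ascent to a genuine mode; L-BFGS alone stalls in the
    strongly anisotropic valley carved by the births constraint."""
    lam = 1e-6
    for _ in range(max_iter):
        if float(np.abs(g).max()) < gtol:
            break
        H = _fd_hessian(model, x, central=False)
        p = None
        for _try in range(25):
            try:
                c = linalg.cho_factor(H + lam * np.eye(x.size))
                p = linalg.cho_solve(c, g)
                break
            except linalg.LinAlgError:
                lam *= 10.0
        if p is None:
            break
        t, ok, gp = 1.0, False, float(g @ p)
        for _ls in range(50):
            lp_new, g_new = model.logp_grad(x + t * p)
            if lp_new > lp + 1e-4 * t * gp:
                ok = True
                break
            t *= 0.5
        if not ok:
            lam *= 10.0
            continue
        x, lp, g = x + t * p, lp_new, g_new
        lam = max(lam * 0.3, 1e-9)
    return x, lp, g


def _laplace(model: PregnancyModel, draws: int, seed: int):
    x = model.initial_point()
    neg = lambda t: tuple(-v for v in model.logp_grad(t))
    target_cv = model.config.births_cv
    # continuation: the births constraint is loosened then tightened, which
    # walks the optimizer down the constraint valley instead of across it
    ladder = sorted({max(target_cv, c) for c in (1.0, 0.1)} | {target_cv},
                    reverse=True)
    res = None
    try:
        for cv in ladder:
            model.config.births_cv = cv
            res = optimize.minimize(
                neg, x, jac=True, method="L-BFGS-B",
                options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-14,
                         "gtol": 1e-9},
            )
            x = res.x
    finally:
        model.config.births_cv = target_cv
    lp, g = model.logp_grad(x)
    mode, lp, g = _newton_polish(model, x, lp, g)
    gmax = float(np.abs(g).max())
    converged = gmax < 0.1
    if not converged:
        warnings.warn(f"MAP search did not reach a stationary point "
                      f"(max |grad| = {gmax:.3g})")
    H = _fd_hessian(model, mode)
    # eigenvalue factorization: floor only numerically degenerate directions
    # so weakly identified parameters keep their (wide) posterior variance
    evals, vecs = linalg.eigh(H)
    floor = max(1e-10 * float(evals.max()), 1e-8)
    n_floored = int((evals < floor).sum())
    if n_floored:
        warnings.warn(f"{n_floored} Hessian directions at or below zero "
                      "curvature were floored; intervals there are caps")
        converged = False
    evals = np.maximum(evals, floor)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((draws, model.n_params))
    samples = (mode[:, None] + (vecs / np.sqrt(evals)) @ z.T).T
    scale = vecs / np.sqrt(evals)  # cov = scale @ scale.T
    diag = {
        "method": "laplace",
        "converged": bool(converged),
        "optimizer_message": str(res.message),
        "max_grad": gmax,
        "neg_logp": float(-lp),
        "floored_directions": n_floored,
        "rhat_max": None,
        "ess_min": None,
    }
    return samples, mode, scale, diag


def _hmc(model, draws, warmup, chains, seed, mode, scale_mat, max_leapfrog=16):
    """Hamiltonian Monte Carlo in the Laplace-whitened space.

    Positions are x = mode + S u with S the Laplace covariance factor, so
    an identity mass matrix and O(1) step sizes work; step size is tuned
    by dual averaging to ~0.8 acceptance during warmup.
    """
    import arviz as az

    n = model.n_params
    S = scale_mat

    def logp_grad_u(u):
        lp, g = model.logp_grad(mode + S @ u)
        return lp, S.T @ g

    rng = np.random.default_rng(seed)
    all_chains = np.empty((chains, draws, n))
    accept_rates = []
    for ch in range(chains):
        crng = np.random.default_rng(rng.integers(2 ** 31))
        u = 0.05 * crng.standard_normal(n)
        lp, g = logp_grad_u(u)
        eps, mu = 0.2, np.log(10 * 0.2)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa, target = 0.05, 10.0, 0.75, 0.8
        n_accept = 0
        for it in range(warmup + draws):
            p0 = crng.standard_normal(n)
            u_new, g_new, p = u, g, p0.copy()
            lf = int(crng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
            p = p + 0.5 * eps * g_new
            for step in range(lf):
                u_new = u_new + eps * p
                lp_new, g_new = logp_grad_u(u_new)
                if step < lf - 1:
                    p = p + eps * g_new
            p = p + 0.5 * eps * g_new
            h0 = lp - 0.5 * float(p0 @ p0)
            h1 = lp_new - 0.5 * float(p @ p)
            log_alpha = min(0.0, h1 - h0) if np.isfinite(h1) else -np.inf
            if np.log(crng.random()) < log_alpha:
                u, lp, g = u_new, lp_new, g_new
                if it >= warmup:
                    n_accept += 1
            if it < warmup:
                # dual averaging (Nesterov) on log step size
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (
                    target - np.exp(min(0.0, log_alpha))
                ) / (m + t0)
                log_eps = mu - np.sqrt(m) / gamma * h_bar
                w = m ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if it == warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                all_chains[ch, it - warmup] = mode + S @ u
        accept_rates.append(n_accept / draws)
    flat = all_chains.reshape(-1, n)
    diag = {"method": "hmc", "acceptance": accept_rates,
            "step_size": float(eps)}
    try:
        ds = az.convert_to_dataset(all_chains if chains > 1 else
                                   all_chains.reshape(2, draws // 2, n))
        diag["rhat_max"] = float(np.nanmax(az.rhat(ds)["x"].values))
        diag["ess_min"] = float(np.nanmin(az.ess(ds)["x"].values))
        diag["converged"] = diag["rhat_max"] < 1.2
    except Exception:  # diagnostics should never kill a run
        diag["rhat_max"] = None
        diag["ess_min"] = None
        diag["converged"] = min(accept_rates) > 0.5
    if not diag["converged"]:
        warnings.warn(
            f"HMC diagnostics weak (rhat_max={diag.get('rhat_max')}, "
            f"acceptance={accept_rates})"
        )
    return flat, diag


def _metropolis(model, draws, chains, tune, seed, mode, scale_mat):
    """Adaptive Metropolis with a Laplace-preconditioned proposal."""
    import arviz as az

    n = model.n_params
    scale = 2.38 / np.sqrt(n)
    rng = np.random.default_rng(seed)
    all_chains = np.empty((chains, draws, n))
    accept = np.zeros(chains)
    for ch in range(chains):
        crng = np.random.default_rng(rng.integers(2 ** 31))
        x = mode + 0.1 * (scale_mat @ crng.standard_normal(n))
        lp, _ = model.logp_grad(x)
        s = scale
        for i in range(tune + draws):
            step = s * (scale_mat @ crng.standard_normal(n))
            prop = x + step
            lp_p, _ = model.logp_grad(prop)
            if np.log(crng.random()) < lp_p - lp:
                x, lp = prop, lp_p
                acc = 1.0
            else:
                acc = 0.0
            if i < tune:
                s *= np.exp(0.5 * (acc - 0.234) / np.sqrt(1 + i))
            else:
                all_chains[ch, i - tune] = x
                accept[ch] += acc
    accept /= draws
    idata = az.convert_to_dataset(all_chains[:, :, :])
    rhat = az.rhat(idata)["x"].values
    ess = az.ess(idata)["x"].values
    diag = {
        "method": "metropolis",
        "converged": bool(np.nanmax(rhat) < 1.1),
        "acceptance": accept.tolist(),
        "rhat_max": float(np.nanmax(rhat)),
        "ess_min": float(np.nanmin(ess)),
    }
    if not diag["converged"]:
        warnings.warn(
            f"Metropolis chains not converged: max R-hat {diag['rhat_max']:.3f}"
        )
    return all_chains.reshape(-1, n), diag


def fit(model: PregnancyModel, config: Optional[ModelConfig] = None) -> Posterior:
    """Fit the model and return posterior draws with diagnostics.

    Seeded runs are bit-for-bit reproducible for identical settings.
    """
    cfg = (config or model.config).sampler
    method = cfg.get("method", "laplace")
    draws = int(cfg.get("draws", 500))
    seed = int(cfg.get("seed", 0))
    samples, mode, scale, diag = _laplace(model, draws, seed)
    if method == "hmc":
        chains = int(cfg.get("chains", 2))
        warmup = int(cfg.get("tune", 200))
        per_chain = max(2, draws // chains)
        samples, mdiag = _hmc(model, per_chain, warmup, chains, seed, mode, scale)
        base_converged = diag["converged"]
        diag.update(mdiag)
        diag["converged"] = bool(base_converged and mdiag["converged"])
    elif method == "metropolis":
        chains = int(cfg.get("chains", 4))
        tune = int(cfg.get("tune", 500))
        per_chain = max(1, draws // chains)
        samples, mdiag = _metropolis(model, per_chain, chains, tune, seed, mode, scale)
        diag.update(mdiag)
    elif method != "laplace":
        raise ValueError(f"unknown sampler method {method!r}")
    return Posterior(model=model, draws=samples, map_point=mode,
                     diagnostics=diag, cov_factor=scale)


# ---------------------------------------------------------------------------
# Aggregation


def aggregate(posterior: Posterior, level: str = "country",
              draws: Optional[np.ndarray] = None) -> dict:
    """Indicator draws per (unit, period), pooling counts before deriving
    rates and percentages (never averaging ratios).

    Returns {(unit_label, period_start): {indicator: draws array}}.
    ``draws`` overrides the posterior draws (e.g. the MAP as a single row).
    """
    model = posterior.model
    if draws is None:
        acc = posterior.account_draws()
    else:
        omega, alpha = model.surfaces(draws)
        omega, alpha = np.exp(omega), expit(alpha)
        O_ = PERIOD_WIDTH * model.exposure.women * omega
        P_ = O_ * alpha
        acc = {"pregnancies": O_, "abortions": P_,
               "births": (O_ - 1.1 * P_) / 1.2}
    O, P, b = acc["pregnancies"], acc["abortions"], acc["births"]
    women = model.exposure.total_women  # (C, T)

    if level == "country":
        units = {c: [i] for i, c in enumerate(model.countries)}
    elif level == "region":
        units = {
            r: [i for i, c in enumerate(model.countries)
                if model.config.regions[c] == r]
            for r in model.region_labels
        }
    elif level == "global":
        units = {"global": list(range(len(model.countries)))}
    else:
        raise ValueError(f"unknown aggregation level {level!r}")

    out = {}
    for unit, idx in units.items():
        if not idx:
            raise ValueError(f"no countries in aggregation unit {unit!r}")
        Ou = O[:, :, idx, :].sum(axis=2)  # (n, F, T)
        Pu = P[:, :, idx, :].sum(axis=2)
        bu = b[:, :, idx, :].sum(axis=2)
        wu = women[idx, :].sum(axis=0)  # (T,)
        M = Pu.sum(axis=1) / 10.0 + bu.sum(axis=1) / 5.0
        Osum, Psum, bsum = Ou.sum(axis=1), Pu.sum(axis=1), bu.sum(axis=1)
        O_un = Ou[:, _UNINTENDED_IDX].sum(axis=1)
        O_in = Ou[:, _INTENDED_IDX].sum(axis=1)
        P_un = Pu[:, _UNINTENDED_IDX].sum(axis=1)
        b_un = bu[:, _UNINTENDED_IDX].sum(axis=1)
        b_in = bu[:, _INTENDED_IDX].sum(axis=1)
        per_kw = 1000.0 / (wu * PERIOD_WIDTH)
        for ti, period in enumerate(model.periods):
            table = {
                "pregnancy_rate": Osum[:, ti] * per_kw[ti],
                "unintended_pregnancy_rate": O_un[:, ti] * per_kw[ti],
                "intended_pregnancy_rate": O_in[:, ti] * per_kw[ti],
                "pct_pregnancies_unintended": 100 * O_un[:, ti] / Osum[:, ti],
                "pct_pregnancies_intended": 100 * O_in[:, ti] / Osum[:, ti],
                "abortion_rate": Psum[:, ti] * per_kw[ti],
                "pct_pregnancies_abortion": 100 * Psum[:, ti] / Osum[:, ti],
                "pct_unintended_pregnancies_abortion":
                    100 * P_un[:, ti] / O_un[:, ti],
                "unintended_birth_rate": b_un[:, ti] * per_kw[ti],
                "intended_birth_rate": b_in[:, ti] * per_kw[ti],
                "pct_births_unintended": 100 * b_un[:, ti] / bsum[:, ti],
                "pct_births_intended": 100 * b_in[:, ti] / bsum[:, ti],
                "miscarriage_rate": M[:, ti] * per_kw[ti],
                "pct_pregnancies_miscarriage": 100 * M[:, ti] / Osum[:, ti],
                "_counts": {
                    "pregnancies": Osum[:, ti],
                    "abortions": Psum[:, ti],
                    "births": bsum[:, ti],
                    "miscarriages": M[:, ti],
                },
            }
            out[(unit, period)] = table
    return out


# ---------------------------------------------------------------------------
# Validation and covariate selection


def validate_holdout(
    observations: Sequence[ClassifiedObservation],
    exposure: ExposureSurface,
    config: ModelConfig,
    scheme: str = "random_subset",
    fraction_or_country=0.2,
    seed: int = 0,
    covariates: Optional[pd.DataFrame] = None,
    full_posterior: Optional[Posterior] = None,
) -> dict:
    """Refit excluding data and score the held-out observations.

    Returns per-datum transformed-scale errors and empirical coverage of
    the 80%/95% predictive intervals (point observations only; bounds have
    no point prediction to score), plus summary bias/RMSE.  For
    ``leave_country_out`` the summary additionally compares that country's
    posterior interval widths against the full-data fit.
    """
    active = [o for o in observations if not o.excluded]
    rng = np.random.default_rng(seed)
    if scheme == "random_subset":
        frac = float(fraction_or_country)
        n_hold = int(round(frac * len(active)))
        if n_hold == 0:
            return {"metrics": pd.DataFrame(), "summary": {"n": 0}}
        idx = rng.choice(len(active), size=n_hold, replace=False)
        held = [active[i] for i in sorted(idx)]
        kept = [o for i, o in enumerate(active) if i not in set(idx)]
    elif scheme == "leave_country_out":
        country = str(fraction_or_country)
        held = [o for o in active if o.country == country]
        kept = [o for o in active if o.country != country]
    else:
        raise ValueError(f"unknown holdout scheme {scheme!r}")

    model = build_model(kept, exposure, config, covariates)
    # a modeling group can lose all its data: it falls back to its
    # hierarchical prior; warn so the run log records it
    groups_with_data = {config.modeling_groups[o.country] for o in kept}
    empty = set(model.group_labels) - groups_with_data
    if empty:
        warnings.warn(f"holdout emptied modeling groups {sorted(empty)}; "
                      "they fall back to the hierarchical prior")
    posterior = fit(model)
    held_terms = [model._prepare(o) for o in held]

    # delta-method predictive: value at the mode, variance from the exact
    # indicator gradient through the Laplace covariance plus the datum's
    # own error variance (naive draw quantiles through the count sums are
    # inflated by the convexity of exp along weakly identified directions)
    rows = []
    z80, z95 = 1.2815515655446004, 1.959963984540054
    for term in held_terms:
        if term.bound != "point":
            continue
        tv, grad = model.indicator_gradient(posterior.map_point, term)
        if not np.isfinite(tv):
            continue
        v_post = float(((posterior.cov_factor.T @ grad) ** 2).sum())
        sd = np.sqrt(v_post + term.variance)
        err = float(tv - term.y)
        rows.append({
            "country": term.source.country,
            "period": term.source.period,
            "indicator": term.indicator,
            "error": err,
            "predictive_sd": float(sd),
            "covered80": bool(abs(err) <= z80 * sd),
            "covered95": bool(abs(err) <= z95 * sd),
        })
    metrics = pd.DataFrame(rows)
    summary = {"n": len(metrics), "scheme": scheme}
    if len(metrics):
        summary.update({
            "rmse": float(np.sqrt((metrics["error"] ** 2).mean())),
            "median_bias": float(metrics["error"].median()),
            "coverage80": float(metrics["covered80"].mean()),
            "coverage95": float(metrics["covered95"].mean()),
        })
    out = {"metrics": metrics, "summary": summary}

    if scheme == "leave_country_out":
        if full_posterior is not None:
            full_post = full_posterior
        else:
            full_post = fit(build_model(active, exposure, config, covariates))
        ci = model._cidx[str(fraction_or_country)]
        widths = []
        for post, tag in ((full_post, "full"), (posterior, "holdout")):
            # widths on the logit scale: a pure information measure, not
            # confounded by where in (0,1) the propensity happens to sit
            L, A = post.model.surfaces(post.draws)
            a_draws = A[:, :, ci, :]
            w95 = np.quantile(a_draws, 0.975, axis=0) - np.quantile(
                a_draws, 0.025, axis=0
            )
            widths.append(float(w95.mean()))
        out["summary"]["width_full"] = widths[0]
        out["summary"]["width_holdout"] = widths[1]
        out["posterior_full"] = full_post
        out["posterior_holdout"] = posterior
    return out


def select_covariates(
    candidates: Sequence[str],
    observations: Sequence[ClassifiedObservation],
    exposure: ExposureSurface,
    config: ModelConfig,
    covariates: pd.DataFrame,
    seed: int = 0,
    max_subset_size: int = 2,
    fraction: float = 0.2,
) -> pd.DataFrame:
    """Rank covariate subsets by holdout error and bias.

    Ties (within numerical tolerance) break toward fewer covariates; a
    collinearity warning with the condition number is emitted when the
    candidate matrix is ill-conditioned.
    """
    from itertools import combinations

    if candidates:
        mat = covariates[list(candidates)].to_numpy(dtype=float)
        mat = (mat - mat.mean(axis=0)) / np.where(mat.std(axis=0) == 0, 1, mat.std(axis=0))
        cond = float(np.linalg.cond(mat))
        if cond > 30:
            warnings.warn(f"candidate covariates are collinear: condition "
                          f"number {cond:.1f}")
    subsets = [()]
    for k in range(1, min(max_subset_size, len(candidates)) + 1):
        subsets.extend(combinations(candidates, k))
    rows = []
    for sub in subsets:
        cfg = config.copy()
        cfg.covariates = list(sub)
        res = validate_holdout(
            observations, exposure, cfg, "random_subset", fraction, seed,
            covariates,
        )
        s = res["summary"]
        rows.append({
            "subset": ",".join(sub) if sub else "(none)",
            "n_covariates": len(sub),
            "rmse": s.get("rmse", np.nan),
            "abs_bias": abs(s.get("median_bias", np.nan)),
            "n_holdout": s.get("n", 0),
        })
    table = pd.DataFrame(rows)
    table["score"] = table["rmse"] + table["abs_bias"]
    table = table.sort_values(
        ["score", "n_covariates"], kind="stable"
    ).reset_index(drop=True)
    return table
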