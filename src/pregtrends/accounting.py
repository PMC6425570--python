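"""Deterministic demographic accounting of pregnancies and their outcomes.

Women of reproductive age (15-49) are partitioned into six population
groups -- the cross of marital status (married, unmarried; "married"
includes cohabiting unions) and contraceptive-need status (unmet need,
using contraception, no need).  Each group ``f`` in country ``c`` and
five-year period ``t`` has an exposure ``w_fct`` (women), a pregnancy
risk ``omega_fct`` (pregnancies per woman-year) and a propensity
``alpha_fct`` that a pregnancy ends in induced abortion.  Group
pregnancies are ``Omega^f = w * omega * period_width`` and group
abortions ``Psi^f = Omega^f * alpha``.

Miscarriages (spontaneous losses after 5 weeks, incl. stillbirths) are
imputed from gestational-age life tables as one per ten abortions plus
one per five live births, which gives the closed accounting identity

    pregnancies = 1.2 * births + 1.1 * abortions
                = births + abortions + miscarriages(abortions, births).

Pregnancies in the no-need groups are intended by construction; those in
the unmet-need and using-contraception groups are unintended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "PopulationGroup",
    "GROUPS",
    "DEFAULT_INTENTION_MAP",
    "UNINTENDED_SOURCE",
    "INTENDED_SOURCE",
    "ExposureSurface",
    "RateSurface",
    "PregnancyAccounts",
    "group_pregnancies",
    "total_abortions",
    "miscarriages",
    "pregnancy_identity",
    "compute_accounts",
    "intention_split",
    "indicator_table",
    "INDICATORS",
    "PERIOD_WIDTH",
    "DEFAULT_PERIODS",
]

PERIOD_WIDTH = 5.0
#: Five-year period start years covering 1990-2019.
DEFAULT_PERIODS: tuple[int, ...] = (1990, 1995, 2000, 2005, 2010, 2015)

MARITAL_STATUSES = ("married", "unmarried")
NEED_STATUSES = ("unmet_need", "using_contraception", "no_need")


@dataclass(frozen=True, order=True)
class PopulationGroup:
    """One of the six marital-status x contraceptive-need cells."""

    marital_status: str
    need_status: str

    def __post_init__(self) -> None:
        if self.marital_status not in MARITAL_STATUSES:
            raise ValueError(f"unknown marital status {self.marital_status!r}")
        if self.need_status not in NEED_STATUSES:
            raise ValueError(f"unknown need status {self.need_status!r}")

    @property
    def label(self) -> str:
        return f"{self.marital_status}/{self.need_status}"


#: Stable, ordered enumeration of the six groups (index f).
GROUPS: tuple[PopulationGroup, ...] = tuple(
    PopulationGroup(m, n) for m in MARITAL_STATUSES for n in NEED_STATUSES
)

#: Intention source per group: pregnancies to women with unmet need or
#: using contraception are unintended; no-need pregnancies are intended.
DEFAULT_INTENTION_MAP: dict[PopulationGroup, str] = {
    g: ("intended" if g.need_status == "no_need" else "unintended") for g in GROUPS
}

UNINTENDED_SOURCE = tuple(g for g in GROUPS if DEFAULT_INTENTION_MAP[g] == "unintended")
INTENDED_SOURCE = tuple(g for g in GROUPS if DEFAULT_INTENTION_MAP[g] == "intended")


def group_index(group: PopulationGroup) -> int:
    return GROUPS.index(group)


# ---------------------------------------------------------------------------
# Surfaces


@dataclass
class ExposureSurface:
    """Women counts ``w_fct`` and UNPD-style live births ``B_ct``.

    ``women`` has shape (6, n_countries, n_periods); ``births`` has shape
    (n_countries, n_periods) and holds live births per five-year period.
    """

    countries: list[str]
    periods: list[int]
    women: np.ndarray
    births: np.ndarray

    def __post_init__(self) -> None:
        self.women = np.asarray(self.women, dtype=float)
        self.births = np.asarray(self.births, dtype=float)
        expected = (len(GROUPS), len(self.countries), len(self.periods))
        if self.women.shape != expected:
            raise ValueError(f"women has shape {self.women.shape}, expected {expected}")
        if self.births.shape != expected[1:]:
            raise ValueError(
                f"births has shape {self.births.shape}, expected {expected[1:]}"
            )
        if (self.women < 0).any() or (self.births < 0).any():
            raise ValueError("exposure counts must be nonnegative")

    @property
    def total_women(self) -> np.ndarray:
        """Women of reproductive age per (country, period)."""
        return self.women.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi, g in enumerate(GROUPS):
            for ci, c in enumerate(self.countries):
                for ti, p in enumerate(self.periods):
                    rows.append(
                        (c, p, g.marital_status, g.need_status, self.women[fi, ci, ti])
                    )
        return pd.DataFrame(
            rows, columns=["country", "period_start", "group_marital", "group_need", "women"]
        )

    def births_frame(self) -> pd.DataFrame:
        rows = [
            (c, p, self.births[ci, ti])
            for ci, c in enumerate(self.countries)
            for ti, p in enumerate(self.periods)
        ]
        return pd.DataFrame(rows, columns=["country", "period_start", "live_births"])

    @classmethod
    def from_frames(
        cls, women: pd.DataFrame, births: pd.DataFrame
    ) -> "ExposureSurface":
        countries = sorted(women["country"].unique())
        periods = sorted(int(p) for p in women["period_start"].unique())
        w = np.zeros((len(GROUPS), len(countries), len(periods)))
        cidx = {c: i for i, c in enumerate(countries)}
        tidx = {p: i for i, p in enumerate(periods)}
        gidx = {(g.marital_status, g.need_status): i for i, g in enumerate(GROUPS)}
        for row in women.itertuples(index=False):
            key = (row.group_marital, row.group_need)
            if key not in gidx:
                raise ValueError(f"unknown population group {key}")
            w[gidx[key], cidx[row.country], tidx[int(row.period_start)]] = row.women
        b = np.zeros((len(countries), len(periods)))
        for row in births.itertuples(index=False):
            b[cidx[row.country], tidx[int(row.period_start)]] = row.live_births
        return cls(countries=countries, periods=periods, women=w, births=b)


@dataclass
class RateSurface:
    """Latent pregnancy risk ``omega`` (per woman-year) and abortion
    propensity ``alpha`` (probability a pregnancy ends in induced abortion),
    both indexed (group, country, period)."""

    omega: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.omega.shape != self.alpha.shape:
            raise ValueError("omega and alpha shapes differ")
        if (self.omega <= 0).any():
            raise ValueError("omega must be strictly positive")
        if (self.alpha <= 0).any() or (self.alpha >= 1).any():
            raise ValueError("alpha must lie strictly in (0, 1)")


@dataclass
class PregnancyAccounts:
    """Expected pregnancy outcomes per (country, period).

    All per-group arrays have shape (6, C, T); totals have shape (C, T).
    Counts are real-valued expectations over a five-year period.
    """

    omega_f: np.ndarray  # Omega^f_ct, pregnancies per group
    psi_f: np.ndarray  # Psi^f_ct, abortions per group
    births_f: np.ndarray  # implied live births per group
    Omega: np.ndarray = field(init=False)
    Psi: np.ndarray = field(init=False)
    births_implied: np.ndarray = field(init=False)
    miscarriages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Omega = self.omega_f.sum(axis=0)
        self.Psi = self.psi_f.sum(axis=0)
        self.births_implied = self.births_f.sum(axis=0)
        self.miscarriages = miscarriages(self.Psi, self.births_implied)

    @property
    def miscarriages_f(self) -> np.ndarray:
        return miscarriages(self.psi_f, self.births_f)


# ---------------------------------------------------------------------------
# Core operations


def group_pregnancies(
    exposure: ExposureSurface | np.ndarray,
    rates: RateSurface,
    period_width: float = PERIOD_WIDTH,
) -> np.ndarray:
    """Pregnancies per group: ``Omega^f_ct = w_fct * omega_fct * width``."""
    w = exposure.women if isinstance(exposure, ExposureSurface) else np.asarray(exposure)
    if w.shape != rates.omega.shape:
        raise ValueError(
            f"exposure shape {w.shape} does not match rate shape {rates.omega.shape}"
        )
    return w * rates.omega * period_width


def total_abortions(
    exposure: ExposureSurface | np.ndarray,
    rates: RateSurface,
    period_width: float = PERIOD_WIDTH,
) -> np.ndarray:
    """Abortions per (c, t): ``Psi_ct = sum_f w_fct omega_fct alpha_fct``."""
    return (group_pregnancies(exposure, rates, period_width) * rates.alpha).sum(axis=0)


def miscarriages(abortions, live_births):
    """Miscarriage count: one per ten abortions plus one per five births."""
    abortions = np.asarray(abortions, dtype=float)
    live_births = np.asarray(live_births, dtype=float)
    if (abortions < 0).any() or (live_births < 0).any():
        raise ValueError("counts must be nonnegative")
    return abortions / 10.0 + live_births / 5.0


def pregnancy_identity(live_births, abortions):
    """Total pregnancies from births and induced abortions:
    ``1.2 * births + 1.1 * abortions``.

    Equals births + abortions + miscarriages(abortions, births) exactly.
    """
    live_births = np.asarray(live_births, dtype=float)
    abortions = np.asarray(abortions, dtype=float)
    if (live_births < 0).any() or (abortions < 0).any():
        raise ValueError("counts must be nonnegative")
    out = 1.2 * live_births + 1.1 * abortions
    return out.item() if out.ndim == 0 else out


def implied_births(omega_f: np.ndarray, psi_f: np.ndarray) -> np.ndarray:
    """Live births implied by pregnancies and abortions at group level.

    Solves Omega = 1.2 b + 1.1 a for b, making conservation
    (Omega = b + a + miscarriages) exact within every group.
    """
    return (omega_f - 1.1 * psi_f) / 1.2


def compute_accounts(
    exposure: ExposureSurface | np.ndarray,
    rates: RateSurface,
    period_width: float = PERIOD_WIDTH,
) -> PregnancyAccounts:
    omega_f = group_pregnancies(exposure, rates, period_width)
    psi_f = omega_f * rates.alpha
    return PregnancyAccounts(
        omega_f=omega_f, psi_f=psi_f, births_f=implied_births(omega_f, psi_f)
    )


def _source_masks(
    group_map: dict[PopulationGroup, str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    gm = DEFAULT_INTENTION_MAP if group_map is None else group_map
    missing = [g for g in GROUPS if g not in gm]
    if missing:
        raise ValueError(f"intention map is missing groups: {missing}")
    bad = {v for v in gm.values()} - {"intended", "unintended"}
    if bad:
        raise ValueError(f"intention map has unknown classes: {bad}")
    intended = np.array([gm[g] == "intended" for g in GROUPS])
    return intended, ~intended


def intention_split(
    accounts: PregnancyAccounts,
    group_map: dict[PopulationGroup, str] | None = None,
) -> dict[str, np.ndarray]:
    """Split pregnancies, births and abortions by intention source group."""
    intended, unintended = _source_masks(group_map)
    return {
        "pregnancies_intended": accounts.omega_f[intended].sum(axis=0),
        "pregnancies_unintended": accounts.omega_f[unintended].sum(axis=0),
        "births_intended": accounts.births_f[intended].sum(axis=0),
        "births_unintended": accounts.births_f[unintended].sum(axis=0),
        "abortions_intended_source": accounts.psi_f[intended].sum(axis=0),
        "abortions_unintended_source": accounts.psi_f[unintended].sum(axis=0),
    }


#: Published indicator list: rates are per 1,000 women aged 15-49 per year.
INDICATORS: tuple[str, ...] = (
    "pregnancy_rate",
    "unintended_pregnancy_rate",
    "intended_pregnancy_rate",
    "pct_pregnancies_unintended",
    "pct_pregnancies_intended",
    "abortion_rate",
    "pct_pregnancies_abortion",
    "pct_unintended_pregnancies_abortion",
    "unintended_birth_rate",
    "intended_birth_rate",
    "pct_births_unintended",
    "pct_births_intended",
    "miscarriage_rate",
    "pct_pregnancies_miscarriage",
)


def indicator_table(
    accounts: PregnancyAccounts,
    women,
    group_map: dict[PopulationGroup, str] | None = None,
    period_width: float = PERIOD_WIDTH,
) -> dict[str, np.ndarray]:
    """Compute the published indicator set from accounts.

    ``women`` is the count of women aged 15-49 per (c, t).  Rates are
    annualized per 1,000 women; percentages are out of the relevant total.
    The percent of *unintended* pregnancies ending in abortion uses
    unintended-source groups only, in numerator and denominator.
    """
    women = np.asarray(women, dtype=float)
    if (women <= 0).any():
        raise ValueError("women must be strictly positive")
    split = intention_split(accounts, group_map)
    per_kw = 1000.0 / (women * period_width)
    out = {
        "pregnancy_rate": accounts.Omega * per_kw,
        "unintended_pregnancy_rate": split["pregnancies_unintended"] * per_kw,
        "intended_pregnancy_rate": split["pregnancies_intended"] * per_kw,
        "pct_pregnancies_unintended": 100.0
        * split["pregnancies_unintended"]
        / accounts.Omega,
        "pct_pregnancies_intended": 100.0
        * split["pregnancies_intended"]
        / accounts.Omega,
        "abortion_rate": accounts.Psi * per_kw,
        "pct_pregnancies_abortion": 100.0 * accounts.Psi / accounts.Omega,
        "pct_unintended_pregnancies_abortion": 100.0
        * split["abortions_unintended_source"]
        / split["pregnancies_unintended"],
        "unintended_birth_rate": split["births_unintended"] * per_kw,
        "intended_birth_rate": split["births_intended"] * per_kw,
        "pct_births_unintended": 100.0
        * split["births_unintended"]
        / accounts.births_implied,
        "pct_births_intended": 100.0
        * split["births_intended"]
        / accounts.births_implied,
        "miscarriage_rate": accounts.miscarriages * per_kw,
        "pct_pregnancies_miscarriage": 100.0 * accounts.miscarriages / accounts.Omega,
    }
    assert tuple(out) == INDICATORS
    return out
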