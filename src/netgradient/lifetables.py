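"""Expected (background) mortality tables and deprivation-stratified variants.

Background mortality ``hP`` is the all-cause hazard of the matched general
population, read from a life table by single year of age, calendar year, sex
and region, and optionally by deprivation quintile.  Rates are hazards per
person-year, piecewise constant within 1-year age x 1-year period cells
(Lexis squares).  Ages and years outside the declared ranges are clamped to
the nearest edge cell, the standard practice in relative-survival work which
keeps very old patients in the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError

__all__ = [
    "LifeTable",
    "RateRatioTable",
    "lookup_expected_hazard",
    "expected_hazard_along_followup",
    "cumulative_expected_hazard",
    "build_deprivation_lifetables",
    "make_gompertz_lifetable",
]


@dataclass
class LifeTable:
    """Dense background-mortality table.

    ``rates`` has shape ``(n_ages, n_years, n_sexes, n_regions)`` or, for a
    deprivation-stratified table, ``(..., 5)`` with quintile as the last axis
    (quintile 1 = least deprived at index 0).
    """

    rates: np.ndarray
    age_min: int
    year_min: int
    sexes: tuple = ("male", "female")
    regions: tuple = ("R1",)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0) or not np.all(np.isfinite(self.rates)):
            raise ValidationError("life-table rates must be finite and >= 0")
        if self.has_quintiles and self.rates.shape[-1] != 5:
            raise ValidationError("quintile dimension must be complete (all 5)")
        self._sex_index = {s: i for i, s in enumerate(self.sexes)}
        self._region_index = {r: i for i, r in enumerate(self.regions)}

    @property
    def has_quintiles(self) -> bool:
        return self.rates.ndim == 5

    @property
    def age_max(self) -> int:
        return self.age_min + self.rates.shape[0] - 1

    @property
    def year_max(self) -> int:
        return self.year_min + self.rates.shape[1] - 1

    # -- indexing helpers ---------------------------------------------------
    def sex_idx(self, sex):
        try:
            if np.isscalar(sex):
                return self._sex_index[sex]
            return np.array([self._sex_index[s] for s in sex])
        except KeyError as e:
            raise CoverageError(f"sex stratum {e} not in life table {self.sexes}")

    def region_idx(self, region):
        try:
            if np.isscalar(region):
                return self._region_index[region]
            return np.array([self._region_index[r] for r in region])
        except KeyError as e:
            raise CoverageError(f"region stratum {e} not in life table {self.regions}")

    def lookup(self, age, year, sex, region, quintile=None):
        """Rate per person-year at floored age/year, clamped to table edges."""
        ai = np.clip(np.floor(age).astype(int) - self.age_min, 0, self.rates.shape[0] - 1)
        yi = np.clip(np.floor(year).astype(int) - self.year_min, 0, self.rates.shape[1] - 1)
        si = self.sex_idx(sex)
        ri = self.region_idx(region)
        if self.has_quintiles:
            if quintile is None:
                raise CoverageError("table is deprivation-stratified; quintile required")
            qi = np.asarray(quintile, dtype=int) - 1
            if np.any((qi < 0) | (qi > 4)):
                raise CoverageError("quintile must be in 1..5")
            return self.rates[ai, yi, si, ri, qi]
        return self.rates[ai, yi, si, ri]

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.age_min, self.age_max + 1)
        years = np.arange(self.year_min, self.year_max + 1)
        dims = [ages, years, list(self.sexes), list(self.regions)]
        names = ["age", "year", "sex", "region"]
        if self.has_quintiles:
            dims.append([1, 2, 3, 4, 5])
            names.append("quintile")
        idx = pd.MultiIndex.from_product(dims, names=names)
        return pd.DataFrame({"rate": self.rates.ravel()}, index=idx).reset_index()

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        has_q = "quintile" in df.columns
        ages = np.sort(df["age"].unique())
        years = np.sort(df["year"].unique())
        sexes = tuple(pd.unique(df["sex"]))
        regions = tuple(pd.unique(df["region"]))
        shape = [len(ages), len(years), len(sexes), len(regions)]
        if has_q:
            shape.append(5)
        expected = int(np.prod(shape))
        if len(df) != expected:
            raise ValidationError(
                f"life table not dense: {len(df)} rows, expected {expected}"
            )
        if not (np.array_equal(ages, np.arange(ages[0], ages[-1] + 1))
                and np.array_equal(years, np.arange(years[0], years[-1] + 1))):
            raise ValidationError("age/year grids must be contiguous integers")
        sort_cols = ["age", "year", "sex", "region"] + (["quintile"] if has_q else [])
        key = df.copy()
        key["sex"] = pd.Categorical(key["sex"], categories=sexes, ordered=True)
        key["region"] = pd.Categorical(key["region"], categories=regions, ordered=True)
        key = key.sort_values(sort_cols, kind="mergesort")
        rates = key["rate"].to_numpy().reshape(shape)
        return cls(rates, int(ages[0]), int(years[0]), sexes, regions)

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class RateRatioTable:
    """Multiplicative mortality rate ratios by deprivation quintile.

    ``ratios[k-1]`` multiplies the base rate for quintile ``k``.  The
    reference quintile need not have ratio 1 (the gradients published for
    income quintiles are expressed relative to the population mean).
    """

    ratios: np.ndarray = field(default_factory=lambda: np.array([0.70, 0.85, 1.00, 1.20, 1.45]))

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (5,):
            raise ValidationError("need exactly 5 quintile rate ratios")
        if np.any(self.ratios <= 0):
            raise ValidationError("rate ratios must be > 0")


def lookup_expected_hazard(lifetable: LifeTable, age, year, sex, region, quintile=None):
    """Expected hazard per person-year for given strata (floored, edge-clamped)."""
    return lifetable.lookup(age, year, sex, region, quintile)


def expected_hazard_along_followup(record, lifetable: LifeTable, t):
    """hP at follow-up time ``t`` (years) for one cohort record.

    The attained age is ``age_at_diagnosis + t`` and the calendar year is the
    time-updated decimal year of diagnosis plus ``t``; both are floored to the
    table's Lexis cell.  ``record`` is any mapping with fields ``age``,
    ``diag_year_frac``, ``sex``, ``region`` (and ``edi_q`` for a stratified
    table).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("follow-up time must be >= 0")
    q = record["edi_q"] if lifetable.has_quintiles else None
    return lifetable.lookup(
        record["age"] + t, record["diag_year_frac"] + t, record["sex"], record["region"], q
    )


def _breakpoints(age, year_frac, t_max):
    """Times in (0, t_max) where the Lexis cell changes (birthday / 1 January)."""
    bps = []
    for start in (age, year_frac):
        first = np.ceil(start) - start
        if first == 0.0:
            first = 1.0
        b = np.arange(first, t_max, 1.0)
        bps.append(b)
    out = np.unique(np.concatenate(bps))
    return out[(out > 0) & (out < t_max)]


def cumulative_expected_hazard(record, lifetable: LifeTable, times):
    """Exact integral of the piecewise-constant hP over [0, t] for each t.

    Returns an array matching ``times``.  Used for Pohar-Perme weights
    ``1/S_P(t)`` and for analytic censoring-fraction checks.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    t_max = float(times.max()) if times.size else 0.0
    if t_max == 0.0:
        return np.zeros_like(times)
    bps = _breakpoints(record["age"], record["diag_year_frac"], t_max)
    edges = np.concatenate([[0.0], bps, [t_max]])
    mids = 0.5 * (edges[:-1] + edges[1:])
    rates = expected_hazard_along_followup(record, lifetable, mids)
    cum_at_edges = np.concatenate([[0.0], np.cumsum(rates * np.diff(edges))])
    # piecewise linear in t, exact for piecewise-constant rates
    return np.interp(times, edges, cum_at_edges)


def build_deprivation_lifetables(
    lifetable: LifeTable, rr: RateRatioTable, renormalize: bool = False
) -> LifeTable:
    """Stratify a base table by deprivation quintile via multiplicative ratios.

    ``rate(q) = base * ratio(q)``; with ``renormalize=True`` the ratios are
    first rescaled so the equal-weight mean over quintiles equals the base
    rate in every cell, preserving overall population mortality.
    """
    if lifetable.has_quintiles:
        raise ValidationError("base table already has a quintile dimension")
    ratios = rr.ratios
    if renormalize:
        ratios = ratios / ratios.mean()
    rates = lifetable.rates[..., None] * ratios
    return LifeTable(rates, lifetable.age_min, lifetable.year_min,
                     lifetable.sexes, lifetable.regions)


def make_gompertz_lifetable(
    age_range=(0, 110),
    year_range=(2000, 2020),
    sexes=("male", "female"),
    regions=("R1", "R2"),
    level={"male": 2.0e-5, "female": 1.1e-5},
    slope=0.10,
    year_trend=-0.01,
    region_factors=None,
) -> LifeTable:
    """Synthetic national life table with Gompertz age dependence.

    Defaults are calibrated so that all-cause mortality around ages 70-80
    is of the order observed in the French general population during the
    2000s (e.g. male hazard ~0.02/yr at 70); a mild negative calendar trend
    emulates secular mortality improvement.
    """
    ages = np.arange(age_range[0], age_range[1] + 1)
    years = np.arange(year_range[0], year_range[1] + 1)
    if region_factors is None:
        region_factors = {r: 1.0 + 0.05 * i for i, r in enumerate(regions)}
    rates = np.empty((len(ages), len(years), len(sexes), len(regions)))
    for si, sex in enumerate(sexes):
        base = level[sex] * np.exp(slope * ages)
        for yi, year in enumerate(years):
            trend = np.exp(year_trend * (year - 2010))
            for ri, reg in enumerate(regions):
                rates[:, yi, si, ri] = base * trend * region_factors[reg]
    return LifeTable(np.minimum(rates, 1.5), age_range[0], year_range[0],
                     tuple(sexes), tuple(regions))
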