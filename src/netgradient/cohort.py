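"""Synthetic registry-like cohorts with known excess-hazard truth.

The generator emulates the structure of a French cancer-registry extract:
patients diagnosed in a fixed window (default 1 Jan 2006 - 31 Dec 2009),
followed until death or an administrative cutoff (default 30 June 2013) with
a small random loss to follow-up (~2%), a continuous area-deprivation score
(EDI-like, right-skewed on roughly [-16, 56] with median -0.9), national
deprivation quintiles, and survival times driven by the total hazard

    h(t) = hE(t, a, EDI) + hP(a + t, year, sex, region)

so that every downstream estimator can be checked by parameter recovery.
Event times are drawn by numerical inversion of the cumulative total hazard
on a daily grid with linear interpolation.  Zero survival times receive the
registry convention of 0.5 day.  All times are in years of 365.25 days.

The EDI stand-in is a shifted log-normal, ``-16 + LogNormal(log 15.1, 0.25)``,
whose median is -0.9 and whose quintile medians (about -5.0, -2.7, -0.9,
1.2, 4.8) are close to the published national values; the true within-area
distribution is unknown, so this is a calibration, not an estimate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError
from .lifetables import LifeTable

__all__ = [
    "ScenarioConfig",
    "Cohort",
    "generate_cohort",
    "apply_zero_time_rule",
    "assign_quintiles",
    "national_quintile_cuts",
    "true_log_ehr",
    "expected_censoring_fraction",
]

DAY = 1.0 / 365.25
GRID_STEP = DAY  # inversion grid step, years

EDI_SHIFT = -16.0
EDI_MU = float(np.log(15.1))
EDI_SIGMA = 0.25


def date_to_year_frac(d) -> float:
    """Decimal calendar year: year + day offset / 365.25 (package convention)."""
    if isinstance(d, str):
        d = dt.date.fromisoformat(d)
    return d.year + (d - dt.date(d.year, 1, 1)).days / 365.25


@dataclass
class ScenarioConfig:
    """Generative truth for one synthetic cohort."""

    n_subjects: int = 2000
    seed: int = 0
    diagnosis_window: tuple = ("2006-01-01", "2009-12-31")
    admin_censor_date: str = "2013-06-30"
    loss_to_followup_rate: float = 0.02
    age_distribution: tuple = (70.0, 10.0, 30.0, 95.0)  # mean, sd, min, max
    sex_ratio: float = 0.55  # proportion male
    edi_distribution: dict = field(default_factory=lambda: {
        "shift": EDI_SHIFT, "mu": EDI_MU, "sigma": EDI_SIGMA})
    effect_kind: str = "proportional"  # null | proportional | time_dependent
    beta_edi: float = 0.024
    td_shape: dict = field(default_factory=lambda: {"type": "exp_decay", "decay": 1.0})
    baseline_excess_hazard: dict = field(default_factory=lambda: {
        "dist": "weibull", "shape": 0.9, "scale": 11.0, "log_age_slope": 0.02})
    region_codes: tuple = ("R1", "R2")

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValidationError("n_subjects must be > 0")
        if not 0.0 <= self.loss_to_followup_rate < 1.0:
            raise ValidationError("loss_to_followup_rate must be in [0, 1)")
        w0, w1 = (date_to_year_frac(d) for d in self.diagnosis_window)
        if not (w0 < w1 <= date_to_year_frac(self.admin_censor_date)):
            raise ValidationError("need window start < end <= admin censor date")
        if self.effect_kind not in ("null", "proportional", "time_dependent"):
            raise ValidationError(f"unknown effect_kind {self.effect_kind!r}")

    # -- truth --------------------------------------------------------------
    def baseline_hazard(self, t):
        b = self.baseline_excess_hazard
        if b.get("dist", "weibull") != "weibull":
            raise ValidationError("only weibull baselines are implemented")
        k, s = b["shape"], b["scale"]
        t = np.maximum(np.asarray(t, dtype=float), 1e-8)
        return (k / s) * (t / s) ** (k - 1.0)

    def edi_coefficient(self, t):
        """beta(t): log-EHR per EDI unit at follow-up time t."""
        t = np.asarray(t, dtype=float)
        if self.effect_kind == "null":
            return np.zeros_like(t)
        if self.effect_kind == "proportional":
            return np.full_like(t, self.beta_edi)
        if self.td_shape.get("type", "exp_decay") != "exp_decay":
            raise ValidationError("only exp_decay time-dependence is implemented")
        return self.beta_edi * np.exp(-self.td_shape["decay"] * t)

    def excess_hazard(self, t, age, edi):
        """True hE(t, a, EDI) of the scenario."""
        slope = self.baseline_excess_hazard.get("log_age_slope", 0.0)
        return self.baseline_hazard(t) * np.exp(
            slope * (np.asarray(age, float) - 70.0)
            + self.edi_coefficient(t) * np.asarray(edi, float))

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["diagnosis_window"] = list(d["diagnosis_window"])
        d["region_codes"] = list(d["region_codes"])
        s = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_yaml(cls, source) -> "ScenarioConfig":
        if isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        for key in ("diagnosis_window", "region_codes", "age_distribution"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def true_log_ehr(config: ScenarioConfig, t, edi1, edi0) -> np.ndarray:
    """True log excess-hazard ratio between two EDI values at time t."""
    return config.edi_coefficient(t) * (edi1 - edi0)


def national_quintile_cuts(edi_distribution=None) -> np.ndarray:
    """Quintile boundaries of the synthetic national EDI law (analytic)."""
    d = edi_distribution or {"shift": EDI_SHIFT, "mu": EDI_MU, "sigma": EDI_SIGMA}
    q = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
    return d["shift"] + np.exp(d["mu"] + d["sigma"] * q)


def assign_quintiles(edi_values, boundaries) -> np.ndarray:
    """Quintile labels 1..5 from 4 increasing cuts (half-open, lower-closed)."""
    b = np.asarray(boundaries, dtype=float)
    if b.shape != (4,) or np.any(np.diff(b) <= 0):
        raise ValidationError("boundaries must be 4 strictly increasing cut points")
    return np.searchsorted(b, np.asarray(edi_values, dtype=float), side="right") + 1


def apply_zero_time_rule(df: pd.DataFrame) -> pd.DataFrame:
    """Assign 0.5 day to zero survival times (registry convention)."""
    if np.any(df["time_years"] < 0):
        raise ValidationError("negative follow-up time")
    out = df.copy()
    out.loc[out["time_years"] == 0.0, "time_years"] = 0.5 * DAY
    return out


@dataclass
class Cohort:
    """A cohort table plus the national quintile cuts used to label it."""

    df: pd.DataFrame
    quintile_cuts: np.ndarray
    config: ScenarioConfig | None = None

    def __len__(self):
        return len(self.df)

    def write_csv(self, path):
        with open(path, "w") as fh:
            fh.write("# edi_quintile_cuts: "
                     + ",".join(f"{c:.10g}" for c in self.quintile_cuts) + "\n")
            cols = ["id", "age", "sex", "diag_date", "time_years", "event",
                    "edi", "edi_q", "region"]
            self.df[cols].to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "Cohort":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# edi_quintile_cuts:"):
                raise ValidationError("cohort CSV missing quintile-cuts header")
            cuts = np.array([float(x) for x in first.split(":", 1)[1].split(",")])
            df = pd.read_csv(fh, float_precision="round_trip")
        df["diag_year_frac"] = [date_to_year_frac(d) for d in df["diag_date"]]
        return cls(df, cuts)


def _total_hazard_grid(config, ages, year_fracs, sexes, regions, edis, quints,
                       lifetable: LifeTable, t_max: float, offset: float = 0.0):
    """hE + hP on a daily grid over [offset, offset + t_max], shape (n, G)."""
    grid = np.arange(0.0, t_max + GRID_STEP, GRID_STEP)
    n = ages.size
    tt = offset + grid[None, :]
    he = config.excess_hazard(tt, ages[:, None], edis[:, None])
    q = quints if lifetable.has_quintiles else None
    si = lifetable.sex_idx(list(sexes))
    ri = lifetable.region_idx(list(regions))
    ai = np.clip(np.floor(ages[:, None] + tt).astype(int) - lifetable.age_min,
                 0, lifetable.rates.shape[0] - 1)
    yi = np.clip(np.floor(year_fracs[:, None] + tt).astype(int) - lifetable.year_min,
                 0, lifetable.rates.shape[1] - 1)
    if lifetable.has_quintiles:
        hp = lifetable.rates[ai, yi, si[:, None], ri[:, None], (q - 1)[:, None]]
    else:
        hp = lifetable.rates[ai, yi, si[:, None], ri[:, None]]
    return grid, he + hp


def _invert_event_times(config, ages, year_fracs, sexes, regions, edis, quints,
                        lifetable, t_max, targets, segment_years=10.0):
    """Invert the cumulative total hazard at exponential targets.

    Works in follow-up segments so long horizons never materialize a huge
    grid; subjects whose target is reached inside a segment are resolved by
    linear interpolation of the trapezoid cumulative hazard.
    """
    n = ages.size
    t_event = np.full(n, np.inf)
    remaining = np.arange(n)
    consumed = np.zeros(n)
    t0 = 0.0
    while remaining.size and t0 < t_max:
        t1 = min(t0 + segment_years, t_max)
        r = remaining
        grid, h = _total_hazard_grid(
            config, ages[r], year_fracs[r] - 0.0, sexes[r], regions[r],
            edis[r], quints[r], lifetable, t1 - t0, offset=t0)
        cum = np.concatenate(
            [np.zeros((r.size, 1)),
             np.cumsum(0.5 * (h[:, 1:] + h[:, :-1]) * np.diff(grid)[None, :],
                       axis=1)], axis=1)
        tgt = targets[r] - consumed[r]
        idx = np.array([np.searchsorted(cum[i], tgt[i]) for i in range(r.size)])
        inside = idx < grid.size
        ii = np.where(inside)[0]
        j = idx[ii]
        c0, c1 = cum[ii, j - 1], cum[ii, j]
        frac = np.where(c1 > c0, (tgt[ii] - c0) / np.maximum(c1 - c0, 1e-300), 0.0)
        t_event[r[ii]] = t0 + grid[j - 1] + frac * (grid[j] - grid[j - 1])
        consumed[r] += cum[:, -1]
        remaining = r[~inside]
        t0 = t1
    return t_event


def generate_cohort(config: ScenarioConfig, lifetable: LifeTable) -> Cohort:
    """Simulate one registry-like cohort (deterministic given config.seed).

    Event times come from inversion of the cumulative total hazard on a
    daily grid; censoring is administrative at the study cutoff plus an
    independent uniform loss-to-follow-up for the configured fraction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    mean, sd, lo, hi = config.age_distribution
    ages = stats.truncnorm.rvs((lo - mean) / sd, (hi - mean) / sd,
                               loc=mean, scale=sd, size=n, random_state=rng)
    sexes = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    regions = np.asarray(config.region_codes)[
        rng.integers(0, len(config.region_codes), size=n)]
    d = config.edi_distribution
    edis = d["shift"] + np.exp(rng.normal(d["mu"], d["sigma"], size=n))
    cuts = national_quintile_cuts(d)
    quints = assign_quintiles(edis, cuts)

    w0 = dt.date.fromisoformat(config.diagnosis_window[0])
    w1 = dt.date.fromisoformat(config.diagnosis_window[1])
    offsets = rng.integers(0, (w1 - w0).days + 1, size=n)
    diag_dates = np.array([w0 + dt.timedelta(days=int(o)) for o in offsets])
    year_fracs = np.array([date_to_year_frac(dd) for dd in diag_dates])
    admin = date_to_year_frac(config.admin_censor_date)
    t_admin = admin - year_fracs

    # range coverage check before building the hazard grid
    max_age = ages.max() + t_admin.max()
    if lifetable.age_max < 105 and max_age > lifetable.age_max + 5:
        raise ValidationError(
            f"life table ends at age {lifetable.age_max}, cohort reaches {max_age:.0f}")

    targets = rng.exponential(size=n)
    t_event = _invert_event_times(config, ages, year_fracs, sexes, regions,
                                  edis, quints, lifetable,
                                  float(t_admin.max()), targets)

    censor = t_admin.copy()
    ltf = rng.random(n) < config.loss_to_followup_rate
    u = rng.random(n)
    censor[ltf] = np.minimum(censor[ltf], u[ltf] * t_admin[ltf])
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    df = pd.DataFrame({
        "id": np.arange(n),
        "age": ages,
        "sex": sexes,
        "diag_date": [dd.isoformat() for dd in diag_dates],
        "diag_year_frac": year_fracs,
        "time_years": time,
        "event": event,
        "edi": edis,
        "edi_q": quints,
        "region": regions,
    })
    df = apply_zero_time_rule(df)
    return Cohort(df, cuts, config)


def expected_censoring_fraction(config: ScenarioConfig, lifetable: LifeTable,
                                n_mc: int = 4000, seed: int = 12345) -> float:
    """Analytic (numerically integrated) censoring probability of the scenario.

    Averages, over a deterministic Monte-Carlo draw of covariates,
    ``(1-p) S(t_adm) + p/t_adm * int_0^{t_adm} S(u) du`` where S is the
    survival function of the total hazard; independent of the cohort draw.
    """
    probe = ScenarioConfig(**{**asdict(config), "n_subjects": n_mc, "seed": seed,
                              "diagnosis_window": tuple(config.diagnosis_window),
                              "region_codes": tuple(config.region_codes)})
    rng = np.random.default_rng(seed)
    n = n_mc
    mean, sd, lo, hi = probe.age_distribution
    ages = stats.truncnorm.rvs((lo - mean) / sd, (hi - mean) / sd,
                               loc=mean, scale=sd, size=n, random_state=rng)
    sexes = np.where(rng.random(n) < probe.sex_ratio, "male", "female")
    regions = np.asarray(probe.region_codes)[rng.integers(0, len(probe.region_codes), n)]
    d = probe.edi_distribution
    edis = d["shift"] + np.exp(rng.normal(d["mu"], d["sigma"], size=n))
    quints = assign_quintiles(edis, national_quintile_cuts(d))
    w0 = dt.date.fromisoformat(probe.diagnosis_window[0])
    w1 = dt.date.fromisoformat(probe.diagnosis_window[1])
    offsets = rng.integers(0, (w1 - w0).days + 1, size=n)
    year_fracs = np.array([date_to_year_frac(w0 + dt.timedelta(days=int(o)))
                           for o in offsets])
    admin = date_to_year_frac(probe.admin_censor_date)
    t_admin = admin - year_fracs
    grid, h = _total_hazard_grid(probe, ages, year_fracs, sexes, regions,
                                 edis, quints, lifetable, float(t_admin.max()))
    cum = np.concatenate([np.zeros((n, 1)),
                          np.cumsum(0.5 * (h[:, 1:] + h[:, :-1])
                                    * np.diff(grid)[None, :], axis=1)], axis=1)
    S = np.exp(-cum)
    p = probe.loss_to_followup_rate
    out = np.empty(n)
    for i in range(n):
        gi = grid <= t_admin[i]
        s_adm = np.interp(t_admin[i], grid, S[i])
        integral = np.trapezoid(np.append(S[i, gi], s_adm),
                                np.append(grid[gi], t_admin[i]))
        out[i] = (1.0 - p) * s_adm + p * integral / t_admin[i]
    return float(out.mean())
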