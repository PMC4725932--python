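"""Age-stage cohort life tables and population growth parameters.

A cohort of individually-reared aphids, censused daily from birth to death,
yields the age-specific survival rate ``l_x`` (fraction of the initial cohort
alive at age ``x`` days), the age-specific fecundity ``m_x`` (mean offspring
per surviving individual at age ``x``), and the age-stage occupancy matrix
``s_xj`` (fraction of the initial cohort alive and in stage ``j`` at age
``x``).  From these the classical population parameters follow:

* net reproductive rate  ``R0 = Σ_x l_x m_x``  (mean lifetime offspring),
* intrinsic rate of increase ``r`` solving the Euler–Lotka equation
  ``Σ_x exp(-r (x+1)) l_x m_x = 1``,
* finite rate of increase ``λ = exp(r)``,
* mean generation time ``T = ln(R0) / r``.

Conventions (stated here because the field's software rarely prints them):
age 0 is the day of birth; ``death_age`` is the last day alive, so total
longevity is ``death_age + 1`` days; the adult period includes the entry day;
the Euler–Lotka exponent is ``x + 1`` (ages indexed from 0), with the bare-``x``
convention available via ``exponent_offset=0``.

Standard errors of every parameter come from bootstrap resampling of
individuals with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("N1", "N2", "N3", "N4", "Adult")
ADULT = "Adult"

__all__ = [
    "STAGES",
    "IndividualRecord",
    "Cohort",
    "DemographySchedules",
    "StagePeriods",
    "PopulationParameters",
    "build_schedules",
    "net_reproductive_rate",
    "solve_intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "stage_period_stats",
    "bootstrap_population_parameters",
    "life_table_report",
]


@dataclass(frozen=True)
class IndividualRecord:
    """Daily life history of one individual.

    Parameters
    ----------
    individual_id : opaque label, unique within a cohort.
    stage_entry_age : mapping from stage label (subset of ``STAGES``, always
        including ``"N1"`` at age 0) to the age in days of the first day spent
        in that stage.
    death_age : age in days of the last day alive.
    daily_offspring : offspring produced on each day of life, indexed by age;
        length ``death_age + 1``.
    """

    individual_id: str
    stage_entry_age: Mapping[str, int]
    death_age: int
    daily_offspring: tuple[int, ...]

    def __post_init__(self) -> None:
        entries = dict(self.stage_entry_age)
        unknown = set(entries) - set(STAGES)
        if unknown:
            raise ValueError(f"{self.individual_id}: unknown stages {sorted(unknown)}")
        if entries.get("N1") != 0:
            raise ValueError(f"{self.individual_id}: N1 entry age must be 0")
        if self.death_age < 0:
            raise ValueError(f"{self.individual_id}: negative death_age")
        prev = -1
        for stage in STAGES:
            if stage in entries:
                age = int(entries[stage])
                if age < prev:
                    raise ValueError(
                        f"{self.individual_id}: stage entry ages must be nondecreasing along {STAGES}"
                    )
                if age > self.death_age:
                    raise ValueError(
                        f"{self.individual_id}: {stage} entry after death_age"
                    )
                prev = age
        if len(self.daily_offspring) != self.death_age + 1:
            raise ValueError(
                f"{self.individual_id}: daily_offspring length "
                f"{len(self.daily_offspring)} != death_age + 1 = {self.death_age + 1}"
            )
        if any(o < 0 for o in self.daily_offspring):
            raise ValueError(f"{self.individual_id}: negative offspring count")
        adult_entry = entries.get(ADULT)
        first_repro = next(
            (a for a, o in enumerate(self.daily_offspring) if o > 0), None
        )
        if first_repro is not None and (adult_entry is None or first_repro < adult_entry):
            raise ValueError(
                f"{self.individual_id}: offspring recorded at age {first_repro} "
                "before adult entry"
            )
        object.__setattr__(self, "stage_entry_age", entries)
        object.__setattr__(self, "daily_offspring", tuple(int(o) for o in self.daily_offspring))

    @property
    def adult_entry_age(self) -> int | None:
        return self.stage_entry_age.get(ADULT)

    def stage_at(self, age: int) -> str:
        """Stage occupied at a given age (last stage entered by that age)."""
        if age < 0 or age > self.death_age:
            raise ValueError("age outside lifespan")
        current = "N1"
        for stage in STAGES:
            entry = self.stage_entry_age.get(stage)
            if entry is not None and entry <= age:
                current = stage
        return current


@dataclass(frozen=True)
class Cohort:
    """A set of individually-followed life histories on one host plant."""

    records: tuple[IndividualRecord, ...]
    host_label: str = ""
    census_interval: int = 1  # days; daily census is the only supported design

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty cohort")
        if self.census_interval != 1:
            raise ValueError("census_interval is fixed at 1 day")
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual_id in cohort")
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DemographySchedules:
    """Age-indexed survival, fecundity and stage-occupancy schedules."""

    max_age: int
    l_x: np.ndarray  # survival fraction, shape (max_age + 1,)
    m_x: np.ndarray  # per-capita daily fecundity among survivors
    s_xj: np.ndarray  # age × stage occupancy fractions, shape (max_age + 1, len(STAGES))

    def __post_init__(self) -> None:
        l = np.asarray(self.l_x, dtype=float)
        m = np.asarray(self.m_x, dtype=float)
        s = np.asarray(self.s_xj, dtype=float)
        if l.shape != (self.max_age + 1,) or m.shape != l.shape:
            raise ValueError("l_x/m_x length must be max_age + 1")
        if l[0] != 1.0:
            raise ValueError("l_0 must be 1")
        if np.any(np.diff(l) > 1e-12) or np.any(l < 0) or np.any(l > 1):
            raise ValueError("l_x must be non-increasing within [0, 1]")
        if np.any(m < 0):
            raise ValueError("m_x must be nonnegative")
        if np.any(m[l == 0] != 0):
            raise ValueError("m_x must be 0 where no individual is alive")
        if s.shape != (self.max_age + 1, len(STAGES)):
            raise ValueError("s_xj shape mismatch")
        if np.max(np.abs(s.sum(axis=1) - l)) > 1e-12:
            raise ValueError("stage occupancies must sum to l_x at every age")
        object.__setattr__(self, "l_x", l)
        object.__setattr__(self, "m_x", m)
        object.__setattr__(self, "s_xj", s)


@dataclass(frozen=True)
class StagePeriods:
    """Mean developmental periods, with the number of individuals behind each."""

    nymph_period: float  # days from birth to adult entry, among adults
    adult_period: float  # days from adult entry to death inclusive, among adults
    total_longevity: float  # death_age + 1, all individuals
    n_adults: int
    n: int


@dataclass(frozen=True)
class PopulationParameters:
    """Point estimates and bootstrap standard errors of population parameters.

    Point estimates come from the original cohort; SEs are standard deviations
    over bootstrap resamples.  Resamples with zero total offspring leave ``r``
    undefined and are dropped from the r/λ/T summaries; their count is kept in
    ``n_degenerate``.
    """

    R0: float
    r: float
    lambda_: float
    T: float
    nymph_period: float
    adult_period: float
    total_longevity: float
    se_R0: float
    se_r: float
    se_lambda: float
    se_T: float
    se_nymph_period: float
    se_adult_period: float
    se_total_longevity: float
    B: int
    seed: int
    n_degenerate: int = 0
    bootstrap_means: Mapping[str, float] = field(default_factory=dict)
    host_label: str = ""


# ---------------------------------------------------------------------------
# schedules


class _CohortArrays:
    """Columnar view of a cohort for fast (re)computation of schedules."""

    def __init__(self, cohort: Cohort):
        n = len(cohort)
        self.n = n
        self.max_age = max(r.death_age for r in cohort.records)
        A = self.max_age + 1
        self.death_age = np.array([r.death_age for r in cohort.records], dtype=np.int64)
        self.adult_entry = np.array(
            [r.adult_entry_age if r.adult_entry_age is not None else -1 for r in cohort.records],
            dtype=np.int64,
        )
        self.offspring = np.zeros((n, A), dtype=np.int64)
        # stage index occupied at each age; -1 = dead
        self.stage_idx = np.full((n, A), -1, dtype=np.int8)
        for i, rec in enumerate(cohort.records):
            self.offspring[i, : rec.death_age + 1] = rec.daily_offspring
            entries = sorted(
                ((age, STAGES.index(s)) for s, age in rec.stage_entry_age.items()),
            )
            for (age, j), nxt in zip(entries, entries[1:] + [(rec.death_age + 1, None)]):
                self.stage_idx[i, age : nxt[0]] = j

    def schedules(self, idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(l_x, m_x, s_xj) for the full cohort or a resample index vector."""
        death = self.death_age if idx is None else self.death_age[idx]
        off = self.offspring if idx is None else self.offspring[idx]
        n = len(death)
        A = self.max_age + 1
        alive = np.cumsum(np.bincount(death, minlength=A)[::-1])[::-1]
        l_x = alive / n
        total_off = off.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m_x = np.where(alive > 0, total_off / np.maximum(alive, 1), 0.0)
        stage = self.stage_idx if idx is None else self.stage_idx[idx]
        s_xj = np.zeros((A, len(STAGES)))
        for j in range(len(STAGES)):
            s_xj[:, j] = (stage == j).sum(axis=0) / n
        return l_x, m_x, s_xj

    def periods(self, idx: np.ndarray | None = None) -> StagePeriods:
        death = self.death_age if idx is None else self.death_age[idx]
        adult = self.adult_entry if idx is None else self.adult_entry[idx]
        is_adult = adult >= 0
        n_ad = int(is_adult.sum())
        if n_ad:
            nymph = float(adult[is_adult].mean())
            adult_p = float((death[is_adult] - adult[is_adult] + 1).mean())
        else:
            nymph = math.nan
            adult_p = math.nan
        return StagePeriods(
            nymph_period=nymph,
            adult_period=adult_p,
            total_longevity=float((death + 1).mean()),
            n_adults=n_ad,
            n=len(death),
        )


def build_schedules(cohort: Cohort) -> DemographySchedules:
    """Compute l_x, m_x and s_xj from daily individual records.

    ``l_x`` is the fraction of the initial cohort alive at age ``x``; ``m_x``
    is total offspring produced at age ``x`` divided by the number alive then
    (0 when none are alive); ``s_xj`` counts survivors by developmental stage.
    """
    arrays = _CohortArrays(cohort)
    l_x, m_x, s_xj = arrays.schedules()
    return DemographySchedules(max_age=arrays.max_age, l_x=l_x, m_x=m_x, s_xj=s_xj)


# ---------------------------------------------------------------------------
# population parameters


def net_reproductive_rate(sched: DemographySchedules) -> float:
    """R0 = Σ_x l_x m_x — mean lifetime offspring per initial individual."""
    return float(np.dot(sched.l_x, sched.m_x))


def _euler_lotka_residual(r: float, ages: np.ndarray, phi: np.ndarray) -> float:
    return float(np.exp(-r * ages) @ phi) - 1.0


def solve_intrinsic_rate(
    sched: DemographySchedules,
    *,
    exponent_offset: int = 1,
    r_tol: float = 1e-12,
    residual_tol: float = 1e-10,
) -> float:
    """Solve the Euler–Lotka equation Σ exp(-r (x + offset)) l_x m_x = 1 for r.

    Uses bisection on the (strictly decreasing) left-hand side, starting from
    the bracket [-1, 2] day⁻¹ and doubling its ends until the residual changes
    sign.  ``exponent_offset=1`` is the ages-from-0 convention used throughout;
    ``exponent_offset=0`` gives the bare-x alternative.
    """
    phi = sched.l_x * sched.m_x
    if phi.sum() <= 0:
        raise ValueError("no reproduction, r undefined")
    ages = np.arange(sched.max_age + 1, dtype=float) + exponent_offset
    lo, hi = -1.0, 2.0
    f_lo = _euler_lotka_residual(lo, ages, phi)
    f_hi = _euler_lotka_residual(hi, ages, phi)
    for _ in range(60):
        if f_lo > 0 >= f_hi:
            break
        if f_lo <= 0:
            lo *= 2.0
            f_lo = _euler_lotka_residual(lo, ages, phi)
        if f_hi > 0:
            hi *= 2.0
            f_hi = _euler_lotka_residual(hi, ages, phi)
    else:
        raise ValueError("could not bracket the Euler-Lotka root")
    while hi - lo > r_tol:
        mid = 0.5 * (lo + hi)
        if _euler_lotka_residual(mid, ages, phi) > 0:
            lo = mid
        else:
            hi = mid
    r = 0.5 * (lo + hi)
    if abs(_euler_lotka_residual(r, ages, phi)) > residual_tol:
        raise ValueError("Euler-Lotka residual did not converge")
    return r


def finite_rate(r: float) -> float:
    """Finite rate of increase λ = e^r (per-day population multiplier)."""
    if not math.isfinite(r):
        raise ValueError("r must be finite")
    return math.exp(r)


def mean_generation_time(R0: float, r: float) -> float:
    """Mean generation time T = ln(R0)/r (days)."""
    if R0 <= 0:
        raise ValueError("T requires R0 > 0")
    if r == 0:
        raise ValueError("T undefined at replacement (r = 0)")
    return math.log(R0) / r


def stage_period_stats(cohort: Cohort) -> StagePeriods:
    """Mean nymph/adult periods (among individuals reaching adulthood) and
    total longevity (all individuals)."""
    return _CohortArrays(cohort).periods()


def _parameters_from_arrays(
    arrays: _CohortArrays, idx: np.ndarray | None, exponent_offset: int
) -> dict[str, float]:
    l_x, m_x, _ = arrays.schedules(idx)
    phi = l_x * m_x
    R0 = float(phi.sum())
    out: dict[str, float] = {"R0": R0}
    if R0 > 0:
        ages = np.arange(arrays.max_age + 1, dtype=float) + exponent_offset
        lo, hi = -1.0, 2.0
        f_lo = _euler_lotka_residual(lo, ages, phi)
        f_hi = _euler_lotka_residual(hi, ages, phi)
        for _ in range(60):
            if f_lo > 0 >= f_hi:
                break
            if f_lo <= 0:
                lo *= 2.0
                f_lo = _euler_lotka_residual(lo, ages, phi)
            if f_hi > 0:
                hi *= 2.0
                f_hi = _euler_lotka_residual(hi, ages, phi)
        while hi - lo > 1e-12:
            mid = 0.5 * (lo + hi)
            if _euler_lotka_residual(mid, ages, phi) > 0:
                lo = mid
            else:
                hi = mid
        r = 0.5 * (lo + hi)
        out["r"] = r
        out["lambda"] = math.exp(r)
        out["T"] = math.log(R0) / r if R0 != 1.0 and r != 0 else math.nan
    else:
        out["r"] = math.nan
        out["lambda"] = math.nan
        out["T"] = math.nan
    periods = arrays.periods(idx)
    out["nymph_period"] = periods.nymph_period
    out["adult_period"] = periods.adult_period
    out["total_longevity"] = periods.total_longevity
    return out


def bootstrap_population_parameters(
    cohort: Cohort,
    B: int = 10_000,
    seed: int = 0,
    *,
    exponent_offset: int = 1,
) -> PopulationParameters:
    """Point estimates (original cohort) plus bootstrap SEs of all parameters.

    ``B`` resamples of ``n`` individuals are drawn with replacement; every
    parameter is recomputed per resample and the SE is the standard deviation
    over valid resamples.  Resamples with zero total offspring (possible under
    high mortality) are dropped from the r/λ/T summaries and counted in
    ``n_degenerate``.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    arrays = _CohortArrays(cohort)
    point = _parameters_from_arrays(arrays, None, exponent_offset)
    rng = np.random.default_rng(seed)
    n = arrays.n
    keys = ("R0", "r", "lambda", "T", "nymph_period", "adult_period", "total_longevity")
    samples: dict[str, list[float]] = {k: [] for k in keys}
    n_degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        est = _parameters_from_arrays(arrays, idx, exponent_offset)
        if math.isnan(est["r"]):
            n_degenerate += 1
        for k in keys:
            samples[k].append(est[k])
    if n_degenerate == B:
        raise ValueError("all bootstrap resamples degenerate (no offspring)")

    def _se(values: list[float]) -> float:
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            return math.nan
        return float(arr.std(ddof=1))

    def _mean(values: list[float]) -> float:
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        return float(arr.mean()) if len(arr) else math.nan

    return PopulationParameters(
        R0=point["R0"],
        r=point["r"],
        lambda_=point["lambda"],
        T=point["T"],
        nymph_period=point["nymph_period"],
        adult_period=point["adult_period"],
        total_longevity=point["total_longevity"],
        se_R0=_se(samples["R0"]),
        se_r=_se(samples["r"]),
        se_lambda=_se(samples["lambda"]),
        se_T=_se(samples["T"]),
        se_nymph_period=_se(samples["nymph_period"]),
        se_adult_period=_se(samples["adult_period"]),
        se_total_longevity=_se(samples["total_longevity"]),
        B=B,
        seed=seed,
        n_degenerate=n_degenerate,
        bootstrap_means={k: _mean(v) for k, v in samples.items()},
        host_label=cohort.host_label,
    )


# ---------------------------------------------------------------------------
# reporting

_REPORT_ROWS = [
    ("Net reproductive rate, R0 (offspring)", "R0", "se_R0", 1),
    ("Intrinsic rate of increase, r (day^-1)", "r", "se_r", 2),
    ("Finite rate of increase, lambda (day^-1)", "lambda_", "se_lambda", 2),
    ("Mean generation time, T (day)", "T", "se_T", 1),
    ("Nymph period (day)", "nymph_period", "se_nymph_period", 1),
    ("Adult period (day)", "adult_period", "se_adult_period", 1),
    ("Total longevity (day)", "total_longevity", "se_total_longevity", 1),
]


def life_table_report(parameters: Sequence[PopulationParameters]) -> pd.DataFrame:
    """Mean ± SE comparison table, one column per cohort, fixed row order."""
    if not parameters:
        raise ValueError("need at least one PopulationParameters")
    columns = {}
    for i, p in enumerate(parameters):
        label = p.host_label or f"cohort_{i + 1}"
        cells = []
        for _, attr, se_attr, nd in _REPORT_ROWS:
            val = getattr(p, attr)
            se = getattr(p, se_attr)
            if math.isnan(val):
                cells.append("undefined")
            else:
                cells.append(f"{val:.{nd}f} ± {se:.{nd + 1}f}")
        columns[label] = cells
    return pd.DataFrame(columns, index=[row[0] for row in _REPORT_ROWS])


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=True)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
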