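"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the three kinds of raw data behind a host-plant
fitness study that are rarely published alongside it:

* daily life-history records of an individually-reared parthenogenetic aphid
  cohort (stage-structured development, stage-dependent daily survival, an
  age-dependent fecundity curve),
* 5-hour EPG recordings as Markovian waveform sequences with log-normal dwell
  times,
* pooled-library RNA-seq count vectors (Poisson sampling around gene-level
  proportions, a designated DE subset at known fold change) plus GO-style
  annotations with designated over-represented terms.

Each generator is deterministic under its seed and returns the ground truth
next to the data, so estimator recovery can be measured exactly.  For the
cohort generator the truth (expected ``l_x``/``m_x``/``s_xj`` schedules and
the intrinsic rate they imply) is computed by an exact dynamic program over
(stage, days-remaining) states that mirrors the sampling scheme — not by
averaging simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import CountMatrix
from .epg import DEFAULT_DURATION_S, WAVEFORM_CODES, EPGRecording, WaveformInterval
from .lifetable import (
    STAGES,
    Cohort,
    DemographySchedules,
    IndividualRecord,
    solve_intrinsic_rate,
)

__all__ = [
    "CohortSimSpec",
    "CohortTruth",
    "simulate_cohort",
    "CountSimSpec",
    "simulate_counts",
    "EPGSimSpec",
    "simulate_epg",
    "simulate_annotation",
]

MAX_AGE_CAP = 200  # days; bounds every cohort simulation

_NYMPH_STAGES = STAGES[:-1]


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortSimSpec:
    """Life-history generator parameters.

    Defaults mimic a thriving pea-aphid colony on a favorable host: a nymph
    period around 7.5 days split over four instars, high nymphal survival, a
    mean adult span of roughly 2.5 weeks, and a triangular fecundity profile
    peaking a week after the adult molt — which together imply R0 ≈ 100
    lifetime offspring and an intrinsic rate of increase near 0.38 day⁻¹.

    * ``stage_gamma``: (shape, scale) of the gamma whose rounded value (min 1)
      is the stage duration in days, per nymphal instar N1..N4.
    * ``survival_nymph`` / ``survival_adult``: daily probability of surviving
      to the next day while in a nymphal / adult stage.
    * ``f_max`` offspring·day⁻¹ at the fecundity peak, ``peak_age`` days after
      adult molt, linear ramp to zero over ``width`` days on either side; an
      optional ``second_peak`` (f_max, peak_age, width) adds a second ramp.
    """

    n: int = 80
    stage_gamma: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {s: (9.0, 0.21) for s in _NYMPH_STAGES}
    )
    survival_nymph: float = 0.99
    survival_adult: float = 0.94
    f_max: float = 14.0
    peak_age: float = 7.0
    width: float = 14.0
    second_peak: tuple[float, float, float] | None = None
    max_age: int = MAX_AGE_CAP

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for stage in _NYMPH_STAGES:
            if stage not in self.stage_gamma:
                raise ValueError(f"missing stage duration parameters for {stage}")
            shape, scale = self.stage_gamma[stage]
            if shape <= 0 or scale <= 0:
                raise ValueError("gamma shape/scale must be positive")
        for q in (self.survival_nymph, self.survival_adult):
            if not 0 < q <= 1:
                raise ValueError("daily survival must lie in (0, 1]")
        if self.f_max < 0 or self.width <= 0:
            raise ValueError("f_max must be >= 0 and width > 0")
        if not 1 <= self.max_age <= MAX_AGE_CAP:
            raise ValueError(f"max_age must lie in [1, {MAX_AGE_CAP}]")

    def fecundity(self, adult_age: float) -> float:
        """Expected offspring per day at a given adult age (days since molt)."""
        f = self.f_max * max(0.0, 1.0 - abs(adult_age - self.peak_age) / self.width)
        if self.second_peak is not None:
            f2, p2, w2 = self.second_peak
            f += f2 * max(0.0, 1.0 - abs(adult_age - p2) / w2)
        return f

    def duration_pmf(self, stage: str, tail_tol: float = 1e-12) -> np.ndarray:
        """Exact pmf of the discretized stage duration max(1, round(Gamma)).

        Entry ``k`` (1-based; index 0 unused) is P(duration = k) =
        F(k+0.5) - F(k-0.5) for k >= 2 and F(1.5) for k = 1, truncated where
        the survivor function drops below ``tail_tol``.
        """
        shape, scale = self.stage_gamma[stage]
        dist = stats.gamma(shape, scale=scale)
        kmax = max(2, int(math.ceil(dist.isf(tail_tol))) + 1)
        edges = np.arange(1, kmax + 1) + 0.5
        cdf = dist.cdf(edges)
        pmf = np.empty(kmax + 1)
        pmf[0] = 0.0
        pmf[1] = cdf[0]
        pmf[2:] = np.diff(cdf)
        pmf[kmax] += dist.sf(edges[-1])  # fold the far tail into the last bin
        return pmf


@dataclass(frozen=True)
class CohortTruth:
    """Analytic expectations implied by a CohortSimSpec."""

    schedules: DemographySchedules
    R0: float
    r: float | None  # None when the spec implies no reproduction


def _expected_schedules(spec: CohortSimSpec) -> DemographySchedules:
    """Exact expected l_x, m_x, s_xj via DP over (stage, days-remaining)."""
    A = spec.max_age + 1
    pmfs = [spec.duration_pmf(s) for s in _NYMPH_STAGES]
    n_stages = len(_NYMPH_STAGES)
    # nymph[i] = mass vector over days-remaining (index = days left incl. today)
    nymph = [np.zeros(len(p)) for p in pmfs]
    nymph[0] = pmfs[0].copy()
    adult = np.zeros(A + 1)  # index = adult age (days since molt)
    l_x = np.zeros(A)
    m_num = np.zeros(A)
    s_xj = np.zeros((A, len(STAGES)))
    fec = np.array([spec.fecundity(a) for a in range(A + 1)])
    for x in range(A):
        for i in range(n_stages):
            s_xj[x, i] = nymph[i].sum()
        s_xj[x, n_stages] = adult.sum()
        l_x[x] = s_xj[x].sum()
        m_num[x] = float(adult @ fec)
        # survive the day, then advance stage clocks
        q_n, q_a = spec.survival_nymph, spec.survival_adult
        new_nymph = [np.zeros_like(v) for v in nymph]
        adult_in = 0.0
        for i in range(n_stages):
            v = nymph[i] * q_n
            new_nymph[i][1:-1] += v[2:]  # one fewer day remaining in stage
            molting = v[1]  # last day in stage: molt tomorrow
            if i + 1 < n_stages:
                new_nymph[i + 1] += molting * pmfs[i + 1]
            else:
                adult_in = molting
        new_adult = np.zeros_like(adult)
        new_adult[1:] = adult[:-1] * q_a
        new_adult[0] = adult_in
        nymph = new_nymph
        adult = new_adult
    with np.errstate(invalid="ignore", divide="ignore"):
        m_x = np.where(l_x > 0, m_num / np.maximum(l_x, 1e-300), 0.0)
    # the pmfs sum to 1 only to float precision: pin the known exact values
    l_x[0] = 1.0
    l_x = np.minimum.accumulate(np.clip(l_x, 0.0, 1.0))
    return DemographySchedules(max_age=spec.max_age, l_x=l_x, m_x=m_x, s_xj=s_xj)


def simulate_cohort(spec: CohortSimSpec, seed: int = 0) -> tuple[Cohort, CohortTruth]:
    """Draw a cohort of daily life histories and return it with its truth.

    Per individual: four instar durations are drawn as max(1, round(Gamma)),
    each day alive survives to the next with the stage's daily probability
    (capped at ``max_age``), and each adult day produces Poisson offspring
    with mean given by the triangular fecundity profile.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(spec.n):
        durs = [
            max(1, int(round(rng.gamma(*spec.stage_gamma[s])))) for s in _NYMPH_STAGES
        ]
        molt_ages = np.cumsum(durs)  # entry ages of N2, N3, N4, Adult
        entries = {"N1": 0}
        offspring = []
        age = 0
        while True:
            for j, stage in enumerate(STAGES[1:]):
                if age == (molt_ages[j] if j < len(molt_ages) else -1):
                    entries[stage] = age
            is_adult = age >= molt_ages[-1]
            if is_adult:
                offspring.append(int(rng.poisson(spec.fecundity(age - molt_ages[-1]))))
            else:
                offspring.append(0)
            q = spec.survival_adult if is_adult else spec.survival_nymph
            if age >= spec.max_age or rng.random() >= q:
                break
            age += 1
        entries = {s: int(a) for s, a in entries.items() if a <= age}
        records.append(
            IndividualRecord(
                individual_id=f"ind{i:04d}",
                stage_entry_age=entries,
                death_age=age,
                daily_offspring=tuple(offspring),
            )
        )
    cohort = Cohort(records=tuple(records), host_label="synthetic")
    sched = _expected_schedules(spec)
    R0 = float(np.dot(sched.l_x, sched.m_x))
    r_true = solve_intrinsic_rate(sched) if R0 > 0 else None
    return cohort, CohortTruth(schedules=sched, R0=R0, r=r_true)


# ---------------------------------------------------------------------------
# counts


@dataclass(frozen=True)
class CountSimSpec:
    """Pooled-library count generator parameters.

    Gene-level mean proportions are log-normal; counts per sample are Poisson
    with mean proportion × library size (the sampling model the exact
    replicate-free test assumes); a designated fraction of genes has its
    proportion multiplied by ``fold_change`` (or its inverse, per
    ``up_fraction``) in sample B.  Proportions are not renormalized after the
    fold changes — the resulting composition shift is what TMM corrects.
    """

    n_genes: int = 5000
    length_log_mean: float = math.log(1500.0)
    length_log_sigma: float = 0.5
    expr_log_mean: float = 0.0
    expr_log_sigma: float = 1.5
    library_sizes: tuple[float, float] = (1e7, 1e7)
    de_fraction: float = 0.04
    fold_change: float = 4.0
    up_fraction: float = 0.5
    negative_binomial_dispersion: float | None = None  # optional NB robustness mode

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(N <= 0 for N in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if not 0 <= self.up_fraction <= 1:
            raise ValueError("up_fraction must lie in [0, 1]")


def simulate_counts(
    spec: CountSimSpec, seed: int = 0
) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-sample count matrix plus a per-gene truth table.

    The truth table has columns ``is_de``, ``direction`` ("up" means higher
    in sample B) and ``true_fc`` (B over A, always the spec's fold change or
    its inverse for DE genes, 1 otherwise).
    """
    rng = np.random.default_rng(seed)
    g = spec.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(g)], name="gene_id")
    lengths = np.maximum(
        100.0, np.round(rng.lognormal(spec.length_log_mean, spec.length_log_sigma, g))
    )
    base = rng.lognormal(spec.expr_log_mean, spec.expr_log_sigma, g)
    prop = base / base.sum()
    n_de = int(round(spec.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    up = rng.random(n_de) < spec.up_fraction
    fc = np.ones(g)
    fc[de_idx[up]] = spec.fold_change
    fc[de_idx[~up]] = 1.0 / spec.fold_change
    NA, NB = spec.library_sizes
    mean_a = prop * NA
    mean_b = prop * fc * NB
    if spec.negative_binomial_dispersion is None:
        counts_a = rng.poisson(mean_a)
        counts_b = rng.poisson(mean_b)
    else:
        disp = spec.negative_binomial_dispersion
        size = 1.0 / disp
        counts_a = rng.negative_binomial(size, size / (size + mean_a))
        counts_b = rng.negative_binomial(size, size / (size + mean_b))
    counts = pd.DataFrame({"A": counts_a, "B": counts_b}, index=gene_ids)
    matrix = CountMatrix(counts=counts, gene_length_bp=pd.Series(lengths, index=gene_ids))
    direction = np.full(g, "ns", dtype=object)
    direction[de_idx[up]] = "up"
    direction[de_idx[~up]] = "down"
    truth = pd.DataFrame(
        {"is_de": fc != 1.0, "direction": direction, "true_fc": fc}, index=gene_ids
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# EPG


@dataclass(frozen=True)
class EPGSimSpec:
    """Markov-renewal EPG recording generator.

    A recording is an alternating sequence of waveform states with log-normal
    dwell times, truncated at the recording length; intervals tile the
    session, so time ratios sum to 1 by construction.  Defaults sketch a
    successfully feeding aphid: short non-probing bouts, pathway probing,
    then long passive phloem ingestion (E2).
    """

    transition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "np": {"C": 1.0},
            "C": {"np": 0.3, "E1": 0.5, "F": 0.1, "G": 0.1},
            "E1": {"E2": 0.8, "C": 0.2},
            "E2": {"C": 0.6, "np": 0.4},
            "F": {"C": 1.0},
            "G": {"C": 1.0},
        }
    )
    dwell_log_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "np": math.log(300.0),
            "C": math.log(600.0),
            "E1": math.log(120.0),
            "E2": math.log(2500.0),
            "F": math.log(400.0),
            "G": math.log(500.0),
        }
    )
    dwell_log_sigma: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.6 for c in WAVEFORM_CODES}
    )
    initial_state: str = "np"
    duration_s: float = DEFAULT_DURATION_S
    n_recordings: int = 30
    group_label: str = "synthetic"

    def __post_init__(self) -> None:
        for state, row in self.transition.items():
            if state not in WAVEFORM_CODES:
                raise ValueError(f"unknown state {state!r}")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition row for {state!r} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError("transition probabilities must be nonnegative")
        for code in set().union(self.transition, *map(dict, self.transition.values())):
            if code in self.dwell_log_mean and not math.isfinite(self.dwell_log_mean[code]):
                raise ValueError(f"dwell mean for {code!r} must be finite")
        if self.duration_s <= 0 or self.n_recordings < 1:
            raise ValueError("duration and n_recordings must be positive")


def simulate_epg(spec: EPGSimSpec, seed: int = 0) -> list[EPGRecording]:
    """Draw ``n_recordings`` gap-free recordings from a Markov-renewal spec."""
    rng = np.random.default_rng(seed)
    recordings = []
    for i in range(spec.n_recordings):
        t = 0.0
        state = spec.initial_state
        intervals = []
        while t < spec.duration_s:
            mu = spec.dwell_log_mean[state]
            sigma = spec.dwell_log_sigma[state]
            dwell = float(rng.lognormal(mu, sigma))
            if dwell <= 0:
                raise ValueError(f"zero dwell drawn in state {state!r}")
            end = min(t + dwell, spec.duration_s)
            intervals.append(WaveformInterval(code=state, start_s=t, end_s=end))
            t = end
            row = spec.transition.get(state)
            if not row:
                if t < spec.duration_s:
                    raise ValueError(f"absorbing state {state!r} with no transitions")
                break
            codes = list(row)
            state = codes[int(rng.choice(len(codes), p=[row[c] for c in codes]))]
        recordings.append(
            EPGRecording(
                recording_id=f"{spec.group_label}_rec{i:03d}",
                group_label=spec.group_label,
                intervals=tuple(intervals),
                duration_s=spec.duration_s,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    gene_ids: Sequence[str],
    n_terms: int,
    genes_per_term: float,
    spiked_terms: Sequence[str] | int,
    spike_odds: float,
    de_truth: Sequence[str],
    seed: int = 0,
) -> tuple[dict[str, frozenset], list[str]]:
    """Random gene→term annotation with designated over-represented terms.

    Every term annotates each gene independently with base probability
    ``genes_per_term / n_genes``; for spiked terms the probability among
    true-DE genes is raised to the stated odds ratio.  Returns the annotation
    map and the list of spiked term ids.
    """
    if spike_odds <= 0:
        raise ValueError("spike_odds must be positive")
    gene_ids = list(gene_ids)
    de_set = set(de_truth)
    if not de_set <= set(gene_ids):
        raise ValueError("de_truth genes must be a subset of gene_ids")
    rng = np.random.default_rng(seed)
    terms = [f"TERM:{i:04d}" for i in range(n_terms)]
    if isinstance(spiked_terms, int):
        if spiked_terms > n_terms:
            raise ValueError("more spiked terms than terms")
        spiked = terms[:spiked_terms]
    else:
        spiked = list(spiked_terms)
        if not set(spiked) <= set(terms):
            raise ValueError("spiked terms must be among the generated terms")
    p = genes_per_term / len(gene_ids)
    if not 0 < p < 1:
        raise ValueError("genes_per_term implies a probability outside (0, 1)")
    p_spiked = spike_odds * p / (1 - p + spike_odds * p)
    annotations: dict[str, set[str]] = {g: set() for g in gene_ids}
    is_de = np.array([g in de_set for g in gene_ids])
    for term in terms:
        probs = np.where(is_de & (term in spiked), p_spiked, p)
        hit = rng.random(len(gene_ids)) < probs
        for g in np.array(gene_ids)[hit]:
            annotations[g].add(term)
    return {g: frozenset(t) for g, t in annotations.items()}, spiked
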