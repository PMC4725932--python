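"""Replicate-free differential expression between pooled RNA-seq libraries.

Each condition is a single pooled library (hundreds of dissected salivary
glands), so no within-condition variance is available and the classical
replicate-aware models do not apply.  The pipeline here is the standard one
for that design:

* RPKM (reads per kb of gene model per million mapped reads) for abundance,
* TMM (trimmed mean of M-values) scaling factors to remove composition bias
  between libraries,
* the Audic–Claverie exact test: conditional on the total ``x + y``, the count
  in one library is binomial/negative-binomial under Poisson sampling, giving
  an exact p-value for a between-library difference without replicates,
* Benjamini–Hochberg FDR adjustment across tested genes,
* calling: a gene is "up"/"down" only when the normalized expression ratio is
  ≥ 2 (either direction) AND the adjusted p-value is below the threshold
  (default 0.001),
* direction-aware set/Venn partitioning across 2–3 contrasts.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "DESetComparison",
    "rpkm",
    "tmm_factors",
    "ac_pvalue",
    "bh_adjust",
    "de_contrast",
    "venn_partition",
]


@dataclass(frozen=True)
class CountMatrix:
    """Gene × sample read counts with gene lengths.

    ``counts`` is an integer DataFrame indexed by gene id with one column per
    sample; ``gene_length_bp`` is indexed identically.  Library size N is the
    column sum.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        lengths = self.gene_length_bp.reindex(counts.index)
        if counts.empty:
            raise ValueError("empty count matrix")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][:5].tolist()
            raise ValueError(f"missing gene lengths, e.g. {missing}")
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("library sizes must be positive")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_length_bp", lengths.astype(float))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM scaling factors; effective library size = N · f."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        f = self.factors.astype(float)
        if (f <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = float(np.log(f).mean())
        if abs(log_gm) > 1e-12:
            raise ValueError("TMM factors must have geometric mean 1")
        object.__setattr__(self, "factors", f)

    def effective_library_sizes(self, matrix: CountMatrix) -> pd.Series:
        return matrix.library_sizes * self.factors


def rpkm(
    count: float | np.ndarray, length_bp: float | np.ndarray, library_size: float
) -> float | np.ndarray:
    """RPKM = 1e9 · count / (library_size · length_bp)."""
    if np.any(np.asarray(length_bp) <= 0):
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return 1e9 * np.asarray(count, dtype=float) / (library_size * np.asarray(length_bp, dtype=float))


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
    min_genes: int,
) -> float:
    """log2 TMM factor of one sample against the reference.

    Genes with a zero count in either library are dropped; the M (log-ratio)
    distribution is trimmed by ``logratio_trim`` from each tail and the A
    (mean log-abundance) distribution by ``sum_trim`` from each tail; the
    factor is the precision-weighted mean of the surviving M values, weights
    from the delta-method binomial variance.
    """
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = M.size
    rank_M = stats.rankdata(M)
    rank_A = stats.rankdata(A)
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    keep_trim = (rank_M >= lo_m) & (rank_M <= hi_m) & (rank_A >= lo_a) & (rank_A <= hi_a)
    if keep_trim.sum() < min_genes:
        warnings.warn(
            f"only {int(keep_trim.sum())} genes survive the TMM trim; "
            "falling back to an untrimmed weighted mean",
            stacklevel=3,
        )
        keep_trim = np.ones(n, dtype=bool)
    with np.errstate(divide="ignore"):
        f = float(np.sum(M[keep_trim] / w[keep_trim]) / np.sum(1.0 / w[keep_trim]))
    if not math.isfinite(f):
        f = 0.0
    return f


def tmm_factors(
    matrix: CountMatrix,
    ref_sample: str | None = None,
    *,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    min_genes: int = 20,
) -> NormalizationFactors:
    """TMM scaling factors for every sample of a count matrix.

    The reference is the sample whose upper-quartile count proportion is
    closest to the mean upper-quartile proportion, unless given.  Factors are
    rescaled to geometric mean 1, so effective library sizes keep the overall
    sequencing depth scale.
    """
    samples = matrix.sample_ids
    if len(samples) < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = matrix.counts.to_numpy(dtype=float)
    lib = matrix.library_sizes.to_numpy(dtype=float)
    if ref_sample is None:
        q75 = np.quantile(counts / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
        ref_sample = samples[ref_idx]
    elif ref_sample in samples:
        ref_idx = samples.index(ref_sample)
    else:
        raise ValueError(f"unknown reference sample {ref_sample!r}")
    ref = counts[:, ref_idx]
    log2f = np.zeros(len(samples))
    for s in range(len(samples)):
        if s == ref_idx:
            continue
        log2f[s] = _tmm_pair_factor(
            counts[:, s], ref, lib[s], lib[ref_idx], logratio_trim, sum_trim, min_genes
        )
    factors = 2.0 ** (log2f - log2f.mean())  # geometric mean 1
    return NormalizationFactors(
        factors=pd.Series(factors, index=samples), reference_sample=ref_sample
    )


# ---------------------------------------------------------------------------
# Audic-Claverie exact test


def _ac_onesided_tails(
    x: np.ndarray, y: np.ndarray, N1: float, N2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lower (Y ≤ y) and upper (Y ≥ y) tail probabilities of the AC model.

    Conditional on observing x in library 1, the count in library 2 follows a
    negative-binomial with x+1 "successes" and success probability
    N1/(N1+N2):  p(y|x) = C(x+y, y) (N2/N1)^y / (1+N2/N1)^(x+y+1).
    scipy's nbinom evaluates both tails in a numerically stable way.
    """
    q = N1 / (N1 + N2)
    lower = stats.nbinom.cdf(y, x + 1, q)
    upper = stats.nbinom.sf(y - 1, x + 1, q)
    return lower, upper


def ac_pvalue(
    x: int | np.ndarray, y: int | np.ndarray, N1: float, N2: float
) -> float | np.ndarray:
    """Two-sided Audic–Claverie p-value for counts x (library 1) vs y (library 2).

    The one-sided tail is accumulated from y outward in the direction away
    from the conditional expectation x·N2/N1; the two-sided p doubles the
    smaller tail, capped at 1.  Accepts scalars or aligned arrays.
    """
    x_arr = np.asarray(x)
    y_arr = np.asarray(y)
    if not (np.all(x_arr == np.floor(x_arr)) and np.all(y_arr == np.floor(y_arr))):
        raise ValueError("counts must be integers")
    if np.any(x_arr < 0) or np.any(y_arr < 0):
        raise ValueError("counts must be nonnegative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    x_arr = x_arr.astype(np.int64)
    y_arr = y_arr.astype(np.int64)
    lower, upper = _ac_onesided_tails(x_arr, y_arr, float(N1), float(N2))
    expect = x_arr * (N2 / N1)
    tail = np.where(y_arr > expect, upper, np.where(y_arr < expect, lower, np.minimum(lower, upper)))
    p = np.minimum(1.0, 2.0 * tail)
    if np.isscalar(x) and np.isscalar(y):
        return float(p)
    return p


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contrasts and calling


def de_contrast(
    matrix: CountMatrix,
    sample_a: str,
    sample_b: str,
    factors: NormalizationFactors | None = None,
    *,
    ratio_threshold: float = 2.0,
    alpha: float = 0.001,
    ratio_on: str = "cpm",
    secretory: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene differential-expression table for sample_b vs sample_a.

    Normalized abundance is counts-per-million on the effective (TMM-scaled)
    library size; the expression ratio uses a 0.5 pseudocount on normalized
    CPM (or RPKM with ``ratio_on="rpkm"``); the Audic–Claverie test runs on
    raw counts with effective library sizes; BH adjusts across tested genes;
    genes with zero counts in both samples are excluded from testing.
    Calls: "up"/"down" when ratio ≥ ``ratio_threshold`` in either direction
    AND adjusted p < ``alpha``, else "ns".
    """
    if sample_a == sample_b:
        raise ValueError("contrast requires two distinct samples")
    for s in (sample_a, sample_b):
        if s not in matrix.sample_ids:
            raise ValueError(f"sample {s!r} not in matrix")
    if ratio_on not in {"cpm", "rpkm"}:
        raise ValueError("ratio_on must be 'cpm' or 'rpkm'")
    if factors is None:
        factors = tmm_factors(matrix)
    eff = factors.effective_library_sizes(matrix)
    n1, n2 = float(eff[sample_a]), float(eff[sample_b])
    x = matrix.counts[sample_a].to_numpy()
    y = matrix.counts[sample_b].to_numpy()
    cpm_a = x / n1 * 1e6
    cpm_b = y / n2 * 1e6
    if ratio_on == "cpm":
        ratio = (cpm_b + 0.5) / (cpm_a + 0.5)
    else:
        lengths = matrix.gene_length_bp.to_numpy()
        ratio = (rpkm(y, lengths, n2) + 0.5) / (rpkm(x, lengths, n1) + 0.5)

    tested = (x + y) > 0
    p = np.full(len(x), np.nan)
    p[tested] = ac_pvalue(x[tested], y[tested], n1, n2)
    p_adj = np.full(len(x), np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p[tested])

    call = np.full(len(x), "ns", dtype=object)
    sig = tested & (p_adj < alpha)
    call[sig & (ratio >= ratio_threshold)] = "up"
    call[sig & (ratio <= 1.0 / ratio_threshold)] = "down"

    out = pd.DataFrame(
        {
            "count_a": x,
            "count_b": y,
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "ratio": ratio,
            "p_value": p,
            "p_adjusted": p_adj,
            "tested": tested,
            "call": call,
        },
        index=matrix.gene_ids,
    )
    out.attrs["contrast"] = (sample_a, sample_b)
    if secretory is not None:
        out["secretory_flag"] = pd.Series(secretory).reindex(out.index).fillna(0).astype(int)
    return out


@dataclass(frozen=True)
class DESetComparison:
    """Venn-style partition of called genes across 2-3 contrasts."""

    contrasts: tuple[str, ...]
    up_sets: Mapping[str, frozenset]
    down_sets: Mapping[str, frozenset]
    partition: Mapping[frozenset, int]  # region (subset of contrast names) -> count
    common_up: frozenset
    common_down: frozenset
    commonly_varied: frozenset

    def partition_table(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "count": v}
            for k, v in sorted(self.partition.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "contrasts": list(self.contrasts),
            "partition": {"&".join(sorted(k)): v for k, v in self.partition.items()},
            "common_up": sorted(self.common_up),
            "common_down": sorted(self.common_down),
            "commonly_varied": sorted(self.commonly_varied),
        }


def venn_partition(results: Mapping[str, pd.DataFrame]) -> DESetComparison:
    """Direction-aware set comparison of 2-3 DE contrasts.

    Each value may be a de_contrast table (the "call" column is used) or any
    object with ``up``/``down`` attributes of gene sets.  The partition maps
    every non-empty combination of contrasts to the number of called genes
    exclusive to exactly that combination.
    """
    if not 2 <= len(results) <= 3:
        raise ValueError("venn_partition supports 2 or 3 contrasts")
    up_sets: dict[str, frozenset] = {}
    down_sets: dict[str, frozenset] = {}
    for name, res in results.items():
        if isinstance(res, pd.DataFrame):
            up_sets[name] = frozenset(res.index[res["call"] == "up"])
            down_sets[name] = frozenset(res.index[res["call"] == "down"])
        else:
            up_sets[name] = frozenset(res.up)
            down_sets[name] = frozenset(res.down)
    called = {name: up_sets[name] | down_sets[name] for name in results}
    names = tuple(results)
    partition: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = frozenset(combo)
            genes = set.intersection(*(set(called[c]) for c in combo))
            for other in names:
                if other not in inside:
                    genes -= called[other]
            partition[inside] = len(genes)
    return DESetComparison(
        contrasts=names,
        up_sets=up_sets,
        down_sets=down_sets,
        partition=partition,
        common_up=frozenset.intersection(*up_sets.values()),
        common_down=frozenset.intersection(*down_sets.values()),
        commonly_varied=frozenset(set.intersection(*(set(v) for v in called.values()))),
    )
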