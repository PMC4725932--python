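"""Electrical penetration graph (EPG) waveform summaries and group comparisons.

An EPG recording annotates a fixed-length session (default 5 h = 18,000 s) of
aphid probing behavior with timed waveform events: np (non-probing),
C (pathway/probing), E1 (watery salivation into phloem), E2 (passive phloem
ingestion), F (derailed stylet mechanics) and G (xylem drinking).

The analyses here are the ones a feeding-behavior study reports:

* per-recording *time ratios* — time spent in each waveform divided by the
  nominal recording length (unannotated time is reported separately, never
  redistributed);
* group mean ± SEM summaries of those ratios;
* group comparisons per waveform — Welch's t-test for two groups, one-way
  ANOVA with Tukey HSD compact-letter display for several;
* the *attainment matrix*: the fraction of recordings per group that reach a
  waveform at least once (did the individual get as far as phloem ingestion?).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WAVEFORM_CODES: tuple[str, ...] = ("np", "C", "E1", "E2", "F", "G")
DEFAULT_DURATION_S = 18_000.0  # 5 h

__all__ = [
    "WAVEFORM_CODES",
    "DEFAULT_DURATION_S",
    "WaveformInterval",
    "EPGRecording",
    "time_ratios",
    "group_summary",
    "compare_groups",
    "attainment_matrix",
    "significance_stars",
]


@dataclass(frozen=True)
class WaveformInterval:
    code: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"interval must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EPGRecording:
    recording_id: str
    group_label: str
    intervals: tuple[WaveformInterval, ...]
    duration_s: float = DEFAULT_DURATION_S
    allow_extra_codes: bool = False

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.start_s))
        for iv in ivs:
            if iv.code not in WAVEFORM_CODES and not self.allow_extra_codes:
                raise ValueError(
                    f"{self.recording_id}: unknown waveform code {iv.code!r} "
                    f"(expected one of {WAVEFORM_CODES})"
                )
            if iv.end_s > self.duration_s:
                raise ValueError(
                    f"{self.recording_id}: interval [{iv.start_s}, {iv.end_s}] "
                    f"exceeds recording duration {self.duration_s}"
                )
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"{self.recording_id}: overlapping intervals "
                    f"{a.code}[{a.start_s}, {a.end_s}] and {b.code}[{b.start_s}, {b.end_s}]"
                )
        object.__setattr__(self, "intervals", ivs)


def time_ratios(recording: EPGRecording, *, exact: bool = False) -> dict[str, float]:
    """Time spent in each waveform divided by the nominal recording length.

    The denominator is always ``recording.duration_s`` (the study design fixes
    the session length), so incomplete annotation shows up in the
    ``"unannotated"`` entry rather than inflating the waveform ratios.
    With ``exact=True`` ratios are returned as ``fractions.Fraction`` so that
    the identity Σ ratios + unannotated = 1 holds exactly.
    """
    codes = list(WAVEFORM_CODES)
    for iv in recording.intervals:
        if iv.code not in codes:
            codes.append(iv.code)
    dur = Fraction(recording.duration_s)
    totals = {code: Fraction(0) for code in codes}
    for iv in recording.intervals:
        totals[iv.code] += Fraction(iv.end_s) - Fraction(iv.start_s)
    ratios = {code: totals[code] / dur for code in codes}
    ratios["unannotated"] = 1 - sum(ratios.values())
    if exact:
        return ratios
    return {code: float(v) for code, v in ratios.items()}


def group_summary(recordings: Iterable[EPGRecording]) -> pd.DataFrame:
    """Mean ± SEM time ratio per (group, waveform).

    SEM = sd/√n with ddof 1; a single-recording group gets SEM = NaN (flagged
    by ``n = 1``) rather than a silent zero.
    """
    rows = []
    for rec in recordings:
        ratios = time_ratios(rec)
        for code in WAVEFORM_CODES:
            rows.append({"group": rec.group_label, "waveform": code, "ratio": ratios[code]})
    if not rows:
        raise ValueError("no recordings")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "waveform"], sort=False)["ratio"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["group", "waveform", "mean", "sem", "n"]]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _ratio_table(recordings: Sequence[EPGRecording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        r = time_ratios(rec)
        rows.append(
            {"recording_id": rec.recording_id, "group": rec.group_label}
            | {code: r[code] for code in WAVEFORM_CODES}
        )
    return pd.DataFrame(rows)


def _compact_letter_display(
    groups: Sequence[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Columns (letter
    classes) start as one class containing every group; each significant pair
    splits the classes containing both members; subset classes are absorbed.
    """
    classes: list[set[str]] = [set(groups)]
    for a, b in sorted(significant_pairs):
        new_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb classes contained in another
        classes = [
            cls
            for i, cls in enumerate(new_classes)
            if cls and not any(i != j and cls < other for j, other in enumerate(new_classes))
        ]
        # drop exact duplicates
        unique: list[set[str]] = []
        for cls in classes:
            if cls not in unique:
                unique.append(cls)
        classes = unique
    # letter assignment in group order of first appearance
    letters = "abcdefghijklmnopqrstuvwxyz"
    order = {g: i for i, g in enumerate(groups)}
    classes.sort(key=lambda cls: min(order[g] for g in cls))
    out = {g: "" for g in groups}
    for letter, cls in zip(letters, classes):
        for g in groups:
            if g in cls:
                out[g] += letter
    return out


def compare_groups(
    recordings: Sequence[EPGRecording],
    mode: str,
    *,
    equal_var: bool = False,
    posthoc_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-waveform group comparison of time ratios.

    ``mode="pairwise"`` runs a two-sample t-test (Welch by default; Student's
    with ``equal_var=True``) and reports t, df, p and significance stars.
    ``mode="multigroup"`` runs one-way ANOVA plus a Tukey HSD all-pairs
    post-hoc at ``posthoc_alpha``, summarised as a compact letter display.
    Waveforms with zero variance in every group are reported with NaN
    statistics rather than raising.
    """
    if mode not in {"pairwise", "multigroup"}:
        raise ValueError("mode must be 'pairwise' or 'multigroup'")
    table = _ratio_table(recordings)
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    if mode == "pairwise" and len(groups) != 2:
        raise ValueError(f"pairwise mode needs exactly 2 groups, got {len(groups)}")

    rows = []
    for code in WAVEFORM_CODES:
        samples = [table.loc[table["group"] == g, code].to_numpy() for g in groups]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples if len(s)}) == 1:
            rows.append(
                {"waveform": code, "statistic": math.nan, "df": math.nan, "p": math.nan,
                 "note": "zero variance in all groups; test undefined"}
            )
            continue
        if mode == "pairwise":
            res = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
            rows.append(
                {"waveform": code, "statistic": float(res.statistic),
                 "df": float(res.df), "p": float(res.pvalue),
                 "stars": significance_stars(float(res.pvalue)), "note": ""}
            )
        else:
            f_res = stats.f_oneway(*samples)
            tukey = stats.tukey_hsd(*samples)
            sig = set()
            for i, j in itertools.combinations(range(len(groups)), 2):
                if tukey.pvalue[i, j] < posthoc_alpha:
                    sig.add(tuple(sorted((groups[i], groups[j]))))
            letters = _compact_letter_display(groups, sig)
            rows.append(
                {"waveform": code, "statistic": float(f_res.statistic),
                 "df": (len(groups) - 1, sum(len(s) for s in samples) - len(groups)),
                 "p": float(f_res.pvalue),
                 "letters": ";".join(f"{g}={letters[g]}" for g in groups), "note": ""}
            )
    return pd.DataFrame(rows)


def attainment_matrix(recordings: Iterable[EPGRecording]) -> pd.DataFrame:
    """Fraction of recordings per group containing ≥ 1 interval of each code.

    This is the "how far along the feeding sequence did individuals get"
    summary: a value of 1.0 under E2 means every individual reached passive
    phloem ingestion.  Columns are ordered along the feeding sequence
    np → C → E1 → E2, then F, G.
    """
    per_group: dict[str, list[EPGRecording]] = {}
    for rec in recordings:
        per_group.setdefault(rec.group_label, []).append(rec)
    if not per_group:
        raise ValueError("no recordings")
    order = ("np", "C", "E1", "E2", "F", "G")
    data = {}
    for group, recs in per_group.items():
        n = len(recs)
        data[group] = [
            sum(1 for r in recs if any(iv.code == code for iv in r.intervals)) / n
            for code in order
        ]
    return pd.DataFrame(data, index=list(order)).T
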