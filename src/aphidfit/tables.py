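"""Delimited-text readers and writers for every pipeline input.

All inputs are plain delimited text (comma or tab, auto-detected).  Readers
validate the schema up front and attach 1-based line numbers to every error
so a malformed row can be found in an editor.  Formats:

* cohort life histories — long format, one row per individual per day:
  ``individual_id, age_day, stage, offspring, alive`` (alive ∈ {0, 1});
* EPG intervals — ``recording_id, group, waveform, start_s, end_s``;
* counts — ``gene_id, length_bp`` then one integer column per sample;
* annotation sidecar — ``gene_id, secretory, go_terms`` (pipe-separated) or
  plain two-column ``gene_id, term_id`` pairs.
"""

from __future__ import annotations

import csv
from typing import Mapping

import numpy as np
import pandas as pd

from .de import CountMatrix
from .epg import DEFAULT_DURATION_S, EPGRecording, WaveformInterval
from .lifetable import STAGES, Cohort, IndividualRecord

__all__ = [
    "read_table",
    "read_cohort",
    "write_cohort",
    "read_epg",
    "write_epg",
    "read_counts",
    "write_counts",
    "read_annotation_sidecar",
    "read_gene_term_pairs",
]


class TableFormatError(ValueError):
    """A schema or value problem in a delimited input file."""


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def read_table(path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a delimited file and validate it against a column schema.

    ``schema`` maps required column names to int, float or str.  Errors name
    the offending column and the 1-based file line (header is line 1).
    Extra columns are preserved untouched.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    for col, typ in schema.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise TableFormatError(
                f"{path}: line {line}: column {col!r} has non-numeric value "
                f"{df[col][bad].iloc[0]!r}"
            )
        if typ is int:
            frac = converted.dropna() % 1 != 0
            if frac.any():
                line = int(frac[frac].index[0]) + 2
                raise TableFormatError(
                    f"{path}: line {line}: column {col!r} must be integer"
                )
            df[col] = converted.astype("Int64")
        else:
            # numpy's strtod is correctly rounded; pd.to_numeric is not
            df[col] = df[col].to_numpy(dtype=str).astype(float)
    return df


# ---------------------------------------------------------------------------
# cohort


_COHORT_SCHEMA = {
    "individual_id": str,
    "age_day": int,
    "stage": str,
    "offspring": int,
    "alive": int,
}


def read_cohort(path, host_label: str | None = None) -> Cohort:
    """Assemble a Cohort from a long-format daily census file.

    For each individual the rows must cover ages 0..death contiguously with
    ``alive = 1``; a trailing ``alive = 0`` row is tolerated and ignored.
    Stage entry ages are the first day each stage is recorded.
    """
    df = read_table(path, _COHORT_SCHEMA)
    if host_label is None:
        host_label = str(df["host"].iloc[0]) if "host" in df.columns else ""
    records = []
    for ind_id, sub in df.groupby("individual_id", sort=False):
        sub = sub.sort_values("age_day")
        alive = sub[sub["alive"] == 1]
        if alive.empty:
            raise TableFormatError(
                f"{path}: individual {ind_id!r} has no alive rows"
            )
        ages = alive["age_day"].to_numpy(dtype=int)
        if ages[0] != 0 or not np.array_equal(ages, np.arange(len(ages))):
            raise TableFormatError(
                f"{path}: individual {ind_id!r}: alive rows must cover ages 0..death "
                "contiguously"
            )
        death_age = int(ages[-1])
        entries: dict[str, int] = {}
        for age, stage in zip(ages, alive["stage"]):
            if stage not in STAGES:
                line = int(sub.index[sub["age_day"] == age][0]) + 2
                raise TableFormatError(
                    f"{path}: line {line}: unknown stage {stage!r}"
                )
            entries.setdefault(stage, int(age))
        try:
            rec = IndividualRecord(
                individual_id=str(ind_id),
                stage_entry_age=entries,
                death_age=death_age,
                daily_offspring=tuple(int(o) for o in alive["offspring"]),
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: individual {ind_id!r}: {exc}") from exc
        records.append(rec)
    return Cohort(records=tuple(records), host_label=host_label)


def write_cohort(cohort: Cohort, path) -> None:
    rows = []
    for rec in cohort.records:
        for age in range(rec.death_age + 1):
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "age_day": age,
                    "stage": rec.stage_at(age),
                    "offspring": rec.daily_offspring[age],
                    "alive": 1,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EPG


_EPG_SCHEMA = {
    "recording_id": str,
    "group": str,
    "waveform": str,
    "start_s": float,
    "end_s": float,
}


def read_epg(
    path, duration_s: float = DEFAULT_DURATION_S, allow_extra_codes: bool = False
) -> list[EPGRecording]:
    df = read_table(path, _EPG_SCHEMA)
    recordings = []
    for (rec_id, group), sub in df.groupby(["recording_id", "group"], sort=False):
        intervals = tuple(
            WaveformInterval(code=row.waveform, start_s=row.start_s, end_s=row.end_s)
            for row in sub.itertuples()
        )
        recordings.append(
            EPGRecording(
                recording_id=str(rec_id),
                group_label=str(group),
                intervals=intervals,
                duration_s=duration_s,
                allow_extra_codes=allow_extra_codes,
            )
        )
    return recordings


def write_epg(recordings, path) -> None:
    rows = [
        {
            "recording_id": rec.recording_id,
            "group": rec.group_label,
            "waveform": iv.code,
            "start_s": iv.start_s,
            "end_s": iv.end_s,
        }
        for rec in recordings
        for iv in rec.intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts and annotation


def read_counts(path) -> CountMatrix:
    """Count matrix file: gene_id, length_bp, then one column per sample."""
    df = read_table(path, {"gene_id": str, "length_bp": float})
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length_bp")]
    if not sample_cols:
        raise TableFormatError(f"{path}: no sample columns found")
    dup = df["gene_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise TableFormatError(f"{path}: line {line}: duplicate gene_id")
    counts = df[sample_cols].apply(pd.to_numeric)
    bad = counts.isna().any(axis=1) | (counts % 1 != 0).any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise TableFormatError(f"{path}: line {line}: counts must be integers")
    counts = counts.astype(np.int64)
    counts.index = pd.Index(df["gene_id"], name="gene_id")
    lengths = pd.Series(df["length_bp"].to_numpy(), index=counts.index)
    return CountMatrix(counts=counts, gene_length_bp=lengths)


def write_counts(matrix: CountMatrix, path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length_bp", matrix.gene_length_bp)
    out.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_annotation_sidecar(path) -> tuple[pd.Series, dict[str, frozenset]]:
    """Sidecar with columns gene_id, secretory (0/1), go_terms (pipe-separated).

    Returns the secretory flag series and a gene → term-set map.
    """
    df = read_table(path, {"gene_id": str, "secretory": int})
    secretory = pd.Series(
        df["secretory"].to_numpy(dtype=int), index=pd.Index(df["gene_id"], name="gene_id")
    )
    terms: dict[str, frozenset] = {}
    go_col = df["go_terms"] if "go_terms" in df.columns else pd.Series("", index=df.index)
    for gene, cell in zip(df["gene_id"], go_col):
        terms[gene] = frozenset(t for t in str(cell).split("|") if t)
    return secretory, terms


def read_gene_term_pairs(path) -> dict[str, frozenset]:
    """Two-column annotation: gene_id, term_id (one pair per line)."""
    df = read_table(path, {"gene_id": str, "term_id": str})
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in out.items()}
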