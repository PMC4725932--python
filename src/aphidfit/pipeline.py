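"""Run configuration, manifests and the end-to-end pipeline driver.

``run_pipeline`` executes any subset of the analysis stages on file inputs,
writes versioned outputs into one directory, and records a machine-readable
manifest (inputs, parameters, seed, sha256 checksums of every file read and
written) so a run can be reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import de, enrich, epg, lifetable, tables

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_STAGES = ("lifetable", "epg", "de", "enrich")


@dataclass(frozen=True)
class RunConfig:
    """What to run, on which files, with which thresholds.

    Thresholds: ``ratio_threshold`` ≥ 1 and ``alpha`` ∈ (0, 1) gate DE calls;
    ``bootstrap_B`` ≥ 2 resamples; ``posthoc_alpha`` ∈ (0, 1) for the EPG
    letter display; ``enrichment_level`` (optional) cuts GO results at one
    ontology level.  The seed is recorded in every output.
    """

    stages: tuple[str, ...]
    out_dir: str
    seed: int = 0
    cohort_path: str | None = None
    epg_path: str | None = None
    epg_mode: str = "multigroup"
    counts_path: str | None = None
    annotation_path: str | None = None
    contrasts: tuple[tuple[str, str], ...] = ()
    gene_list_path: str | None = None
    obo_path: str | None = None
    ratio_threshold: float = 2.0
    alpha: float = 0.001
    bootstrap_B: int = 10_000
    posthoc_alpha: float = 0.05
    enrichment_level: int | None = None
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; expected {_KNOWN_STAGES}")
        if self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be >= 1")
        if not 0 < self.alpha < 1 or not 0 < self.posthoc_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.bootstrap_B < 2:
            raise ValueError("bootstrap_B must be >= 2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the manifest dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not config.stages:
        warnings.warn("empty stage list: nothing to run", stacklevel=2)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    def register_input(path) -> Path:
        p = Path(path)
        inputs[str(p)] = _sha256(p)
        return p

    def write_json(name: str, payload) -> None:
        p = out_dir / name
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        outputs[name] = _sha256(p)

    def write_tsv(name: str, frame: pd.DataFrame, **kw) -> None:
        p = out_dir / name
        frame.to_csv(p, sep="\t", **kw)
        outputs[name] = _sha256(p)

    for stage in config.stages:
        try:
            if stage == "lifetable":
                cohort = tables.read_cohort(register_input(config.cohort_path))
                params = lifetable.bootstrap_population_parameters(
                    cohort, B=config.bootstrap_B, seed=config.seed
                )
                sched = lifetable.build_schedules(cohort)
                write_tsv(
                    "lifetable_schedules.tsv",
                    pd.DataFrame(
                        {"age": range(sched.max_age + 1), "l_x": sched.l_x, "m_x": sched.m_x}
                    ),
                    index=False,
                )
                write_tsv("lifetable_report.tsv", lifetable.life_table_report([params]))
                payload = {
                    k: v
                    for k, v in asdict(params).items()
                    if k != "bootstrap_means"
                }
                write_json("lifetable_parameters.json", payload)
            elif stage == "epg":
                recordings = tables.read_epg(register_input(config.epg_path))
                write_tsv("epg_summary.tsv", epg.group_summary(recordings), index=False)
                write_tsv(
                    "epg_tests.tsv",
                    epg.compare_groups(
                        recordings, config.epg_mode, posthoc_alpha=config.posthoc_alpha
                    ),
                    index=False,
                )
                write_tsv("epg_attainment.tsv", epg.attainment_matrix(recordings))
            elif stage == "de":
                matrix = tables.read_counts(register_input(config.counts_path))
                secretory = None
                if config.annotation_path:
                    secretory, _ = tables.read_annotation_sidecar(
                        register_input(config.annotation_path)
                    )
                factors = de.tmm_factors(matrix)
                results = {}
                for a, b in config.contrasts:
                    res = de.de_contrast(
                        matrix,
                        a,
                        b,
                        factors,
                        ratio_threshold=config.ratio_threshold,
                        alpha=config.alpha,
                        secretory=secretory,
                    )
                    name = f"de_{a}_vs_{b}.tsv"
                    write_tsv(name, res)
                    results[f"{a}:{b}"] = res
                if 2 <= len(results) <= 3:
                    write_json(
                        "de_set_comparison.json", de.venn_partition(results).to_dict()
                    )
                # when a truth sidecar sits next to the counts file, score calls
                truth_path = Path(config.counts_path).with_name("truth.de.tsv")
                if truth_path.exists():
                    truth = pd.read_csv(register_input(truth_path), sep="\t", index_col=0)
                    evaluation = {}
                    for name, res in results.items():
                        called = res.index[res["call"] != "ns"]
                        is_de = truth["is_de"].reindex(res.index).fillna(False)
                        evaluation[name] = {
                            "n_called": int(len(called)),
                            "n_true_de": int(is_de.sum()),
                            "recall": (
                                float(is_de[called].sum() / is_de.sum())
                                if is_de.sum()
                                else None
                            ),
                            "false_calls": int((~is_de[called]).sum()),
                        }
                    write_json("de_truth_evaluation.json", evaluation)
            elif stage == "enrich":
                _, annotations = tables.read_annotation_sidecar(
                    register_input(config.annotation_path)
                )
                gene_list = [
                    line.strip()
                    for line in open(register_input(config.gene_list_path))
                    if line.strip()
                ]
                names = None
                levels = None
                if config.obo_path:
                    ontology = enrich.load_obo(register_input(config.obo_path))
                    annotations = enrich.propagate_annotations(annotations, ontology)
                    names = ontology.names
                    levels = enrich.term_levels(ontology)
                rows = enrich.enrich(
                    gene_list, annotations.keys(), annotations, term_names=names
                )
                if config.enrichment_level is not None and levels is not None:
                    rows = enrich.level_filter(rows, levels, config.enrichment_level)
                write_tsv("enrichment.tsv", rows, index=False)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
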