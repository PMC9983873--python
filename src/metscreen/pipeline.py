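"""End-to-end pipeline: simulate -> normalize -> filter -> recurrence ->
enrichment -> clinical statistics, with a reproducible run manifest.

`run_all` is the library entry point; the command-line interface in
:mod:`metscreen.cli` is a thin wrapper around it.  All stage outputs are
new files inside the run directory; a ``manifest.json`` records the
configuration and a SHA-256 hash of every input and output, so two runs
with the same configuration and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import case_filter, clinical_stats, enrichment, io_model, recurrence
from .case_filter import FilterThresholds
from .io_model import GeneSetCollection, ValidationError
from .recurrence import RecurrenceParams
from .synthetic_data import (
    ClinicalSimConfig,
    SimulationConfig,
    simulate_clinical,
    simulate_trios,
    write_truth_table,
)

logger = logging.getLogger("metscreen")

STAGES = ("io", "simulate", "normalize", "filter", "recurrence",
          "enrichment", "clinical")
STAGE_EXIT_CODES = {name: 10 + i for i, name in enumerate(STAGES)}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit codes."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything `run_all` needs; loadable from a YAML mapping."""

    outdir: str = "metscreen_run"
    seed: int = 0
    simulate: bool = True
    counts: bool = True  # apply CPM normalization before filtering
    matrix_path: str | None = None
    annot_path: str | None = None
    gene_sets_path: str | None = None
    n_random_sets: int = 5  # decoy sets added when simulating gene sets
    random_set_size: int = 100
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    recurrence: RecurrenceParams = field(default_factory=RecurrenceParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clinical: ClinicalSimConfig = field(default_factory=ClinicalSimConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub_cls in (
            ("thresholds", FilterThresholds),
            ("recurrence", RecurrenceParams),
            ("simulation", SimulationConfig),
            ("clinical", ClinicalSimConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if "libsize_range" in sub:
                    sub["libsize_range"] = tuple(sub["libsize_range"])
                kwargs[key] = sub_cls(**sub)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)


def stage_seed(seed: int, stage_index: int) -> int:
    """Fan one global seed out to independent, reproducible stage seeds."""
    ss = np.random.SeedSequence(seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_to_jsonable(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        return obj

    return convert(cfg)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path

    # --- simulate or load -------------------------------------------------
    truth = None
    if config.simulate:
        try:
            sim_cfg = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, 1)
            )
            matrix, annot, truth = simulate_trios(sim_cfg)
            matrix_path = outdir / "matrix.tsv"
            annot_path = outdir / "annotation.tsv"
            io_model.write_expression_table(matrix, matrix_path)
            io_model.write_sample_annotation(annot, annot_path)
            write_truth_table(truth, outdir / "truth.tsv")
            emit("matrix", matrix_path)
            emit("annotation", annot_path)
            emit("truth", outdir / "truth.tsv")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("simulate", exc) from exc
    else:
        try:
            if not config.matrix_path or not config.annot_path:
                raise ValidationError(
                    "matrix_path and annot_path are required when simulate=false"
                )
            matrix = io_model.read_expression_table(config.matrix_path)
            annot = io_model.read_sample_annotation(config.annot_path)
            inputs[config.matrix_path] = _sha256(Path(config.matrix_path))
            inputs[config.annot_path] = _sha256(Path(config.annot_path))
        except Exception as exc:  # noqa: BLE001
            raise StageError("io", exc) from exc

    # --- normalize --------------------------------------------------------
    try:
        trios = io_model.assemble_trios(matrix, annot)
        norm = io_model.cpm_normalize(matrix) if config.counts else matrix
        norm_path = outdir / "matrix_cpm.tsv"
        io_model.write_expression_table(norm, norm_path)
        emit("matrix_cpm", norm_path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("normalize", exc) from exc

    # --- per-case filter --------------------------------------------------
    try:
        calls = case_filter.call_all(norm, trios, config.thresholds)
        calls_path = outdir / "calls.tsv"
        case_filter.write_call_matrix(calls, calls_path)
        emit("calls", calls_path)
        for path in case_filter.write_case_gene_lists(calls, outdir / "case_lists"):
            emit(f"case_lists/{path.name}", path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc

    # --- recurrence -------------------------------------------------------
    try:
        table = recurrence.count_recurrence(
            calls, norm, trios, pseudocount=config.thresholds.pseudocount
        )
        recurrence.write_recurrence_table(table, outdir / "recurrence.tsv")
        emit("recurrence", outdir / "recurrence.tsv")
        up = recurrence.select_recurrent(table, config.recurrence, "up")
        down = recurrence.select_recurrent(table, config.recurrence, "down")
        lead_up, lead_down = recurrence.leading_genes(table, config.recurrence)
        for name, genes in (
            ("selected_up", up),
            ("selected_down", down),
            ("leading_up", lead_up),
            ("leading_down", lead_down),
        ):
            path = outdir / f"{name}.txt"
            path.write_text("".join(g + "\n" for g in genes), encoding="utf-8")
            emit(name, path)
        if len(calls.columns) <= recurrence.MAX_VENN_CASES:
            venn = recurrence.venn_summary(calls, "up")
            venn.to_csv(outdir / "venn_up.tsv", sep="\t", index=False)
            emit("venn_up", outdir / "venn_up.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("recurrence", exc) from exc

    # --- enrichment -------------------------------------------------------
    try:
        evaluable = (calls != case_filter.CALL_NOT_EVALUABLE).any(axis=1)
        universe = list(calls.index[evaluable])
        if config.gene_sets_path:
            sets = io_model.read_gene_sets(config.gene_sets_path)
            inputs[config.gene_sets_path] = _sha256(Path(config.gene_sets_path))
        elif truth is not None:
            sets = _truth_gene_sets(truth, universe, config)
            io_model.write_gene_sets(sets, outdir / "gene_sets.gmt")
            emit("gene_sets", outdir / "gene_sets.gmt")
        else:
            sets = None
        if sets is not None:
            selected = [g for g in up if g in set(universe)]
            enr = enrichment.enrich_collection(selected, sets, universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")
            emit("enrichment", outdir / "enrichment.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", exc) from exc

    # --- clinical statistics ---------------------------------------------
    try:
        if config.simulate:
            clin_cfg = dataclasses.replace(
                config.clinical, seed=stage_seed(config.seed, 2)
            )
            marker = lead_up[0] if lead_up else None
            ihc, surv, ln, patients = simulate_clinical(clin_cfg, truth, marker)
            io_model.write_ihc_table(ihc, outdir / "ihc.tsv")
            io_model.write_survival_table(surv, outdir / "survival.tsv")
            io_model.write_ln_table(ln, outdir / "ln_counts.tsv")
            for name in ("ihc", "survival", "ln_counts"):
                emit(name, outdir / f"{name}.tsv")
            summary = clinical_summary(ihc, surv, ln)
            with open(outdir / "clinical_summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
                fh.write("\n")
            emit("clinical_summary", outdir / "clinical_summary.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("clinical", exc) from exc

    manifest = {
        "config": _config_to_jsonable(config),
        "inputs": inputs,
        "outputs": {
            name: _sha256(path) for name, path in sorted(outputs.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return manifest


def _truth_gene_sets(
    truth, universe: list[str], config: PipelineConfig
) -> GeneSetCollection:
    """Demo gene sets for simulated runs: the two spiked sets plus decoys."""
    sets = GeneSetCollection()
    in_universe = set(universe)
    sets.add(
        "spiked_up",
        [g for g in truth.genes_with_label("up_spiked") if g in in_universe],
        "genes simulated with the up effect",
    )
    sets.add(
        "spiked_down",
        [g for g in truth.genes_with_label("down_spiked") if g in in_universe],
        "genes simulated with the down effect",
    )
    rng = np.random.default_rng(stage_seed(config.seed, 3))
    size = min(config.random_set_size, len(universe))
    for i in range(config.n_random_sets):
        members = rng.choice(universe, size=size, replace=False)
        sets.add(f"random_{i + 1}", list(members), "uniformly drawn decoy set")
    return sets


def clinical_summary(ihc, surv, ln) -> dict:
    """Headline clinical statistics for a run, as plain JSON-able values."""
    primary = [r.score for r in ihc if r.tissue == "primary"]
    ln_met = [r.score for r in ihc if r.tissue == "ln_met"]
    u, p_ihc = clinical_stats.mann_whitney(ln_met, primary, mode="asymptotic")
    groups = sorted({r.group for r in surv})
    out: dict = {
        "ihc_mann_whitney_U": u,
        "ihc_mann_whitney_p": p_ihc,
        "ihc_bins": clinical_stats.ihc_bin_table(ihc)
        .to_dict(orient="records"),
    }
    if len(groups) == 2:
        a = [r for r in surv if r.group == groups[0]]
        b = [r for r in surv if r.group == groups[1]]
        stat, p = clinical_stats.logrank_test(a, b)
        out["logrank_groups"] = groups
        out["logrank_statistic"] = stat
        out["logrank_p"] = p
    ratio_groups = pd.Series(
        [clinical_stats.ln_ratio_group(r) for r in ln]
    ).value_counts()
    out["ln_ratio_groups"] = {k: int(v) for k, v in ratio_groups.items()}
    return out
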