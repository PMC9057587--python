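"""End-to-end orchestration: simulate -> count -> enrich -> filter -> evaluate.

One config (YAML-friendly nested dict) drives every stage; a single
top-level seed fans out to per-stage seeds through a fixed splitting
rule so each stage is independently reproducible.  All outputs are TSV
or FASTA/FASTQ text with deterministic content: the same config and
seed produce byte-identical artifacts.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from displaymap import counts as counts_mod
from displaymap import enrichment as enrich_mod
from displaymap import simulate as sim_mod
from displaymap import structure as struct_mod
from displaymap.reference import ReferenceConstruct, default_construct, read_reference_fasta

logger = logging.getLogger(__name__)

#: stage ids for the seed-splitting rule (never reorder: part of the contract)
_STAGE_IDS = {
    "mutagenesis": 1,
    "selection": 2,
    "sequencing_selected": 3,
    "sequencing_unselected": 4,
    "annotation": 5,
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "displaymap_out",
    "reference": {"fasta": None},
    "simulate": {
        "n_clones": 50000,
        "lambda_nt": 2.0,
        "epitope_positions": [62, 75, 83, 96, 104],
        "decoy_buried": [],
        "decoy_disulfide": [],
        "q_effect": 0.8,
        "p_hit": 0.9,
        "p_bg": 0.005,
        "rounds": 2,
        "target_size": None,
        "coverage": 200.0,
        "read_length": 150,
        "error_rate": 0.001,
    },
    "reads": {"selected": None, "unselected": None},
    "counts": {
        "anchor_k": counts_mod.DEFAULT_ANCHOR_K,
        "max_mismatch": counts_mod.DEFAULT_MAX_MISMATCH,
        "min_coverage": counts_mod.DEFAULT_MIN_COVERAGE,
        "search_rc": False,
    },
    "enrichment": {"threshold": 2.0, "pseudocount": 0.0},
    "filter": {
        "annotation": None,
        "structure": None,
        "chain": "A",
        "rsa_min": struct_mod.DEFAULT_RSA_MIN,
        "drop_unannotated": False,
    },
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed.

    Uses numpy's SeedSequence over (seed, stage id); the same run seed
    always yields the same per-stage seeds, and distinct stages get
    decorrelated streams.
    """
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


def _merge_validate(defaults: dict, given: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {path}{key} must be a mapping")
            merged[key] = _merge_validate(defaults[key], value, f"{path}{key}.")
        else:
            merged[key] = value
    return merged


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    data: dict[str, Any]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        cfg = _merge_validate(DEFAULT_CONFIG, raw)
        have_sim = raw.get("simulate") is not None and "simulate" in raw
        have_reads = cfg["reads"]["selected"] is not None
        if have_reads and cfg["reads"]["unselected"] is None:
            raise ConfigError("reads.unselected is required when reads.selected is given")
        if not have_reads and not have_sim:
            # default simulation block is acceptable; nothing to check
            pass
        if have_reads and cfg["reference"]["fasta"] is None:
            raise ConfigError("reference.fasta is required when supplying real reads")
        sim = cfg["simulate"]
        if sim["target_size"] is None:
            sim["target_size"] = sim["n_clones"]
        cls._check_numeric(cfg)
        return cls(data=cfg)

    @staticmethod
    def _check_numeric(cfg: dict[str, Any]) -> None:
        sim = cfg["simulate"]
        if sim["n_clones"] < 1:
            raise ConfigError("simulate.n_clones must be >= 1")
        if not 0 <= sim["p_bg"] <= sim["p_hit"] <= 1:
            raise ConfigError("require 0 <= p_bg <= p_hit <= 1")
        if cfg["enrichment"]["pseudocount"] < 0:
            raise ConfigError("enrichment.pseudocount must be >= 0")
        if not 0 <= cfg["filter"]["rsa_min"] <= 1:
            raise ConfigError("filter.rsa_min must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def evaluate_recovery(called: set[int], truth: set[int]) -> dict[str, Any]:
    """Set-overlap recovery metrics of a call set against planted truth.

    Precision is 1.0 when both sets are empty and 0.0 (flagged) when
    calls are empty but truth is not.
    """
    called, truth = set(called), set(truth)
    tp = len(called & truth)
    sensitivity = tp / len(truth) if truth else 1.0
    flagged = False
    if called:
        precision = tp / len(called)
    elif not truth:
        precision = 1.0
    else:
        precision = 0.0
        flagged = True
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_called": len(called),
        "n_truth": len(truth),
        "flagged": flagged,
    }


@dataclass
class PipelineResult:
    """In-memory view of a pipeline run plus the artifact directory."""

    outdir: Path
    ref: ReferenceConstruct
    counts: dict[str, pd.DataFrame]
    enrichment: pd.DataFrame
    called: set[int]
    filtered: pd.DataFrame
    epitope: set[int]
    truth: sim_mod.GroundTruth | None
    recovery_prefilter: dict | None
    recovery_postfilter: dict | None


def _log_params(lines: list[str], section: str, params: dict[str, Any]) -> None:
    for key in sorted(params):
        lines.append(f"{section}.{key} = {params[key]!r}")


def run_pipeline(config: RunConfig | dict) -> PipelineResult:
    """Execute all stages under one config and write artifacts to outdir."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config.data
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log_lines: list[str] = [f"seed = {seed}"]

    # --- reference -------------------------------------------------------
    if cfg["reference"]["fasta"]:
        ref = read_reference_fasta(cfg["reference"]["fasta"])
    else:
        ref = default_construct()
    ref.to_fasta(outdir / "reference.fasta")
    log_lines.append(f"reference = {ref.name} ({len(ref)} aa, "
                     f"{ref.first_residue}..{ref.first_residue + len(ref) - 1})")

    truth: sim_mod.GroundTruth | None = None
    annotation_path = cfg["filter"]["annotation"]
    simulated = cfg["reads"]["selected"] is None
    if simulated:
        sim = cfg["simulate"]
        _log_params(log_lines, "simulate", sim)
        epitopes = frozenset(int(p) for p in sim["epitope_positions"])
        decoys = frozenset(int(p) for p in sim["decoy_buried"]) | frozenset(
            int(p) for p in sim["decoy_disulfide"]
        )
        params = sim_mod.SelectionParams(
            epitope_positions=epitopes | decoys,
            q_effect=sim["q_effect"],
            p_hit=sim["p_hit"],
            p_bg=sim["p_bg"],
            rounds=sim["rounds"],
        )
        library = sim_mod.mutagenize_library(
            ref, sim["n_clones"], sim["lambda_nt"], stage_seed(seed, "mutagenesis")
        )
        selected = sim_mod.select_library(
            library, params, sim["target_size"], stage_seed(seed, "selection")
        )
        reads = {}
        for lib_name, lib, stage in (
            ("selected", selected, "sequencing_selected"),
            ("unselected", library, "sequencing_unselected"),
        ):
            records = sim_mod.sequence_library(
                lib, ref, sim["coverage"], sim["read_length"], sim["error_rate"],
                stage_seed(seed, stage),
            )
            path = outdir / f"{lib_name}.fastq"
            sim_mod.write_fastq(records, path)
            reads[lib_name] = path
            log_lines.append(f"sequenced {lib_name}: {len(records)} reads -> {path.name}")
        truth = sim_mod.GroundTruth(
            epitope_positions=epitopes,
            q_effect=sim["q_effect"],
            p_hit=sim["p_hit"],
            p_bg=sim["p_bg"],
            rounds=sim["rounds"],
            lambda_nt=sim["lambda_nt"],
            seed=seed,
        )
        sim_mod.write_truth(truth, outdir / "truth.tsv")
        if cfg["filter"]["annotation"] is None and cfg["filter"]["structure"] is None:
            # synthetic annotation: every construct cysteine sits in a
            # (synthetic) disulfide; decoy_buried positions get low RSA
            cys = {ref.index_to_native(i) for i, aa in enumerate(ref.aa_seq) if aa == "C"}
            bad_ss = frozenset(int(p) for p in sim["decoy_disulfide"]) - cys
            if bad_ss:
                raise ConfigError(
                    f"decoy_disulfide positions {sorted(bad_ss)} are not cysteines"
                )
            ann_path = outdir / "annotation.tsv"
            sim_mod.write_annotation(
                ref, ann_path,
                disulfide_positions=cys,
                buried_positions=[int(p) for p in sim["decoy_buried"]],
                seed=stage_seed(seed, "annotation"),
            )
            annotation_path = str(ann_path)
            log_lines.append(f"synthetic annotation -> {ann_path.name}")
    else:
        reads = {"selected": Path(cfg["reads"]["selected"]),
                 "unselected": Path(cfg["reads"]["unselected"])}

    # --- counting --------------------------------------------------------
    cc = cfg["counts"]
    _log_params(log_lines, "counts", cc)
    tables: dict[str, pd.DataFrame] = {}
    for lib_name, path in reads.items():
        table, aux, stats = counts_mod.count_reads(
            counts_mod.read_fastq(path), ref, lib_name,
            k=cc["anchor_k"], max_mismatch=cc["max_mismatch"],
            min_coverage=cc["min_coverage"], search_rc=cc["search_rc"],
        )
        tables[lib_name] = table
        counts_mod.write_counts(table, outdir / f"counts_{lib_name}.tsv",
                                metadata={"library": lib_name, **stats})
        aux.to_csv(outdir / f"substitutions_{lib_name}.tsv", sep="\t", index=False)
        log_lines.append(f"counts {lib_name}: {stats}")

    # --- enrichment ------------------------------------------------------
    ec = cfg["enrichment"]
    _log_params(log_lines, "enrichment", ec)
    fm = enrich_mod.build_frequency_matrix(
        tables.values(), reference="unselected", pseudocount=ec["pseudocount"]
    )
    etable = enrich_mod.enrichment_table(fm, threshold=ec["threshold"])
    enrich_mod.write_enrichment(etable, outdir / "enrichment.tsv",
                                metadata={"threshold": ec["threshold"],
                                          "reference": "unselected"})
    sel_rows = etable[etable["library"] == "selected"]
    called = set(sel_rows.loc[sel_rows["called"], "position"].astype(int))
    # the within-sample median call is primary; log how the unselected-
    # reference reading would differ, for auditability
    alt_called = set(
        sel_rows.loc[sel_rows["ref_delta"] >= ec["threshold"], "position"].astype(int)
    )
    log_lines.append(f"called (within-sample median): {sorted(called)}")
    log_lines.append(
        f"call discrepancy vs reference-ratio reading: "
        f"median-only={sorted(called - alt_called)} ref-only={sorted(alt_called - called)}"
    )

    # --- structural filter ----------------------------------------------
    fc = cfg["filter"]
    _log_params(log_lines, "filter", fc)
    if annotation_path:
        annotation = struct_mod.read_annotation_table(annotation_path)
    elif fc["structure"]:
        annotation = struct_mod.annotate_structure(ref, fc["structure"], fc["chain"])
    else:
        raise ConfigError("filter stage needs an annotation table or a structure")
    scores = sel_rows.set_index("position")["e_log2"]
    filtered = struct_mod.filter_epitope(
        called, annotation, scores=scores,
        rsa_min=fc["rsa_min"], drop_unannotated=fc["drop_unannotated"],
    )
    filtered.to_csv(outdir / "epitope.tsv", sep="\t", index=False, float_format="%.10g")
    epitope = struct_mod.epitope_set(filtered)
    log_lines.append(f"epitope set after structural filter: {sorted(epitope)}")

    # --- recovery --------------------------------------------------------
    recovery_pre = recovery_post = None
    if truth is not None:
        recovery_pre = evaluate_recovery(called, truth.epitope_positions)
        recovery_post = evaluate_recovery(epitope, truth.epitope_positions)
        report = pd.DataFrame(
            [
                {"stage": "pre_filter", **recovery_pre},
                {"stage": "post_filter", **recovery_post},
            ]
        )
        report.to_csv(outdir / "recovery.tsv", sep="\t", index=False, float_format="%.10g")
        log_lines.append(f"recovery pre-filter: {recovery_pre}")
        log_lines.append(f"recovery post-filter: {recovery_post}")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        outdir=outdir,
        ref=ref,
        counts=tables,
        enrichment=etable,
        called=called,
        filtered=filtered,
        epitope=epitope,
        truth=truth,
        recovery_prefilter=recovery_pre,
        recovery_postfilter=recovery_post,
    )
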