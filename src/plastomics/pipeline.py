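"""End-to-end pipeline: simulate -> partition -> classify -> detect
inversions -> PCR screen -> map characters, with per-stage seeds derived
stably from one run seed so the report is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .assays import DEFAULT_ASSAYS
from .character_mapping import CharacterMatrix, assess_synapomorphy
from .errors import PlastomicsError
from .gene_status import Thresholds, classify_locus, extract_locus, survey_gene
from .insilico_pcr import (
    PcrParams,
    genera_without_any_inversion,
    run_panel_screen,
)
from .io import load_tree
from .quadripartite import genome_summary, partition_genome
from .rearrangement import (
    infer_inversion_events,
    lcb_decomposition,
    shared_gene_order,
)
from .synth import (
    DEFAULT_PANEL,
    INV50,
    MutationSpec,
    apply_inversion,
    build_panel,
    default_gene_catalog,
    generate_plastome,
    mutate_gene,
    regions_for_profile,
)

logger = logging.getLogger(__name__)

#: 16-taxon screening phylogeny with the derived-state taxa monophyletic.
PANEL_TREE_MONOPHYLETIC = (
    "((('Cladrastis wilsonii','Styphnolobium japonicum'),"
    "'Camoensia brevicalyx'),"
    "((('Crotalaria capensis','Lupinus luteus'),"
    "('Bolusanthus speciosus','Dicraeopetalum mahafaliense')),"
    "(('Anagyris foetida',('Baptisia australis',"
    "('Piptanthus nepalensis','Thermopsis fabacea'))),"
    "('Euchresta japonica',('Maackia fauriei',"
    "('Salweenia bouffordiana',"
    "('Sophora koreensis','Sophora flavescens')))))));"
)

#: Alternative arrangement nesting Bolusanthus/Dicraeopetalum inside the
#: derived clade (renders the 24-kb character non-synapomorphic).
PANEL_TREE_NESTED_CONFLICT = (
    "((('Cladrastis wilsonii','Styphnolobium japonicum'),"
    "'Camoensia brevicalyx'),"
    "(('Crotalaria capensis','Lupinus luteus'),"
    "(('Anagyris foetida',('Baptisia australis',"
    "('Piptanthus nepalensis','Thermopsis fabacea'))),"
    "(('Bolusanthus speciosus','Dicraeopetalum mahafaliense'),"
    "('Euchresta japonica',('Maackia fauriei',"
    "('Salweenia bouffordiana',"
    "('Sophora koreensis','Sophora flavescens'))))))));"
)

STAGES = (
    "simulate", "partition", "classify_gene", "detect_inversions",
    "pcr_screen", "map_character",
)


@dataclass
class RunConfig:
    seed: int = 0
    profile: str = "mini"
    stages: tuple[str, ...] = STAGES
    truncation_threshold: float = 0.5
    min_ir_len: int = 1000
    pcr: PcrParams = field(default_factory=PcrParams)
    tree: str = PANEL_TREE_MONOPHYLETIC

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(
            self.seed, spawn_key=(STAGES.index(stage),)
        )
        return int(ss.generate_state(1)[0])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; returns a JSON-serializable report."""
    report: dict = {
        "plastomics_version": __version__,
        "config": {
            "seed": config.seed,
            "profile": config.profile,
            "stages": list(config.stages),
            "truncation_threshold": config.truncation_threshold,
            "min_ir_len": config.min_ir_len,
            "pcr": dataclasses.asdict(config.pcr),
        },
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            report["stages"][stage] = {"status": "skipped"}
            continue
        missing = [
            d for d in _DEPS.get(stage, ())
            if report["stages"].get(d, {}).get("status") != "ok"
        ]
        if missing:
            report["stages"][stage] = {
                "status": "skipped",
                "reason": f"dependencies not satisfied: {missing}",
            }
            continue
        try:
            logger.info("stage %s (seed %d)", stage, config.stage_seed(stage))
            report["stages"][stage] = _RUNNERS[stage](config, state)
            report["stages"][stage]["status"] = "ok"
        except PlastomicsError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
    return report


def _min_ir_len(config: RunConfig) -> int:
    if config.profile == "mini":
        return min(config.min_ir_len, 500)
    return config.min_ir_len


def _run_simulate(config: RunConfig, state: dict) -> dict:
    seed = config.stage_seed("simulate")
    catalog = default_gene_catalog(config.profile)
    regions = regions_for_profile(config.profile)
    reference = generate_plastome(catalog, regions, seed=seed)
    reference.id = "reference-ancestral"
    panel = build_panel(DEFAULT_PANEL, seed=seed, profile=config.profile,
                        catalog=catalog)
    mutants = {}
    for label, spec in (
        ("frameshift", MutationSpec("FRAMESHIFT_INSERTION", motif="AAAC",
                                    exon=2)),
        ("truncation", MutationSpec("EXON_TRUNCATION")),
        ("deletion", MutationSpec("WHOLE_GENE_DELETION")),
        ("start_codon", MutationSpec("START_CODON_MUTATION")),
    ):
        mutants[label] = mutate_gene(reference, "rps16", spec, seed=seed)
        mutants[label].id = f"mutant-{label}"
    state.update(
        catalog=catalog, regions=regions, reference=reference,
        panel=panel, mutants=mutants,
    )
    return {
        "n_panel_records": len(panel),
        "genome_length": len(reference),
        "n_mutants": len(mutants),
        "seed": seed,
    }


def _run_partition(config: RunConfig, state: dict) -> dict:
    record = dict(state["panel"])["Maackia fauriei"]
    part = partition_genome(record, _min_ir_len(config))
    summary = genome_summary(record, part)
    state["partition"] = part
    return {
        "taxon": record.id,
        "lengths": {
            "total": summary.total_bp,
            "lsc": summary.lsc_len,
            "ssc": summary.ssc_len,
            "ir": summary.ir_len,
        },
        "gc_pct": round(summary.gc_pct, 1),
        "at_pct": round(summary.at_pct, 1),
        "coding_cds_pct": round(summary.coding_cds_pct, 1),
        "coding_cds_rna_pct": round(summary.coding_cds_rna_pct, 1),
        "feature_counts": {
            "unique": summary.n_features_unique,
            "with_ir_duplicates": summary.n_features_with_ir_duplicates,
            "unique_cds": summary.n_unique_cds,
            "unique_trna": summary.n_unique_trna,
            "unique_rrna": summary.n_unique_rrna,
        },
    }


def _run_classify(config: RunConfig, state: dict) -> dict:
    reference = state["reference"]
    ref_locus = extract_locus(reference, "rps16")
    thresholds = Thresholds(
        truncation_coverage=config.truncation_threshold
    )
    records = [("intact", reference)] + sorted(state["mutants"].items())
    reports, tally = survey_gene(records, "rps16", ref_locus, thresholds)
    return {
        "gene": "rps16",
        "categories": {
            taxon: rep.category for taxon, rep in reports.items()
        },
        "evidence": {
            taxon: rep.evidence for taxon, rep in reports.items()
        },
        "tally": dict(tally),
    }


def _run_detect(config: RunConfig, state: dict) -> dict:
    reference = state["reference"]
    panel = dict(state["panel"])
    min_ir = _min_ir_len(config)
    # four-way comparison: no inversion / 50 / 50+36 / 50+36+24
    fifty, _ = apply_inversion(reference, INV50)
    fifty.id = "50kb-only"
    four = {
        "no inversion": reference,
        "50kb": fifty,
        "50+36": panel["Lupinus luteus"],
        "50+36+24": panel["Maackia fauriei"],
    }
    perms = [
        shared_gene_order(rec, reference, min_ir_len=min_ir)
        for rec in four.values()
    ]
    blocks = lcb_decomposition(perms)
    maackia_perm = shared_gene_order(
        panel["Maackia fauriei"], reference, min_ir_len=min_ir
    )
    events = infer_inversion_events(
        maackia_perm, record=panel["Maackia fauriei"], bfs_limit=0
    )
    state["screen_events"] = events
    return {
        "n_lcbs": len(blocks),
        "events": [
            {
                "name": e.name,
                "size_bp": e.size,
                "left": e.left_label,
                "right": e.right_label,
                "mediating_repeat": e.mediating_repeat,
                "flags": list(e.flags),
            }
            for e in events
        ],
    }


def _run_screen(config: RunConfig, state: dict) -> dict:
    tribes = {t.taxon: t.tribe for t in DEFAULT_PANEL.taxa}
    result = run_panel_screen(
        state["panel"], DEFAULT_ASSAYS, config.pcr, tribes
    )
    state["screen_result"] = result
    return {
        "calls": {
            taxon: row.to_dict() for taxon, row in result.calls.iterrows()
        },
        "genera_with_inversion": result.genus_tally,
        "tribes_with_inversion": result.tribe_tally,
        "genera_without_any_inversion": genera_without_any_inversion(result),
    }


def _run_map(config: RunConfig, state: dict) -> dict:
    tree = load_tree(config.tree)
    calls = state["screen_result"].calls
    data = {
        taxon: {
            inv: {"PRESENT": "1", "ABSENT": "0"}.get(v, "?")
            for inv, v in row.items()
        }
        for taxon, row in calls.iterrows()
    }
    matrix = CharacterMatrix.from_dict(data)
    out = {}
    for inv in calls.columns:
        rep = assess_synapomorphy(tree, matrix, inv)
        out[inv] = {
            "min_changes": rep.changes,
            "single_origin": rep.single_origin,
            "clade": sorted(rep.clade),
            "conflicting_taxa": list(rep.conflicting_taxa),
        }
    return {"characters": out}


_DEPS = {
    "partition": ("simulate",),
    "classify_gene": ("simulate",),
    "detect_inversions": ("simulate",),
    "pcr_screen": ("simulate",),
    "map_character": ("simulate", "pcr_screen"),
}

_RUNNERS = {
    "simulate": _run_simulate,
    "partition": _run_partition,
    "classify_gene": _run_classify,
    "detect_inversions": _run_detect,
    "pcr_screen": _run_screen,
    "map_character": _run_map,
}


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_text(report: dict) -> str:
    lines = [f"plastomics run report (seed {report['config']['seed']}, "
             f"profile {report['config']['profile']})"]
    for stage, body in report["stages"].items():
        lines.append(f"\n== {stage}: {body.get('status')}")
        for k, v in body.items():
            if k == "status":
                continue
            lines.append(f"  {k}: {v}")
    return "\n".join(lines)
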