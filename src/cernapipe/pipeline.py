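"""End-to-end orchestration of the ceRNA discovery workflow.

Stage order (fixed, even where stages commute): per-tissue differential
expression at the focal stage -> tissue-specific DE sets -> lncRNA
candidate filtering -> target assignment (cis, trans, seed) -> DE/target
overlap -> trend-model triple assembly -> co-expression modules on the
focal tissue's stage series (normal condition) -> hub-based
prioritization.  When a planted-truth record is available the report
includes exact-match precision/recall and a per-stage attrition table for
every missed triple.

All tabular outputs are TSV with a header; the report is JSON.  The run is
a pure function of (inputs, configuration): a rerun writes byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cernapipe import cerna, coexpr, diffexpr, lncfilter, targets
from cernapipe.cerna import CeRNATriple
from cernapipe.simulate import SimulatedDataset, PlantedTruth

logger = logging.getLogger("cernapipe")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_dataset", "score_recovery"]

ASSAYS = ("mrna", "lncrna", "mirna")


@dataclass
class PipelineConfig:
    counts: dict[str, str] = field(default_factory=dict)  # assay -> TSV path
    gtf: str = ""
    transcripts_fasta: str = ""
    mirna_fasta: str = ""
    design: str = ""
    truth: str | None = None
    outdir: str = "cernapipe_out"
    focal_tissue: str = "skin"
    focal_stage: str = "E41"
    reference_condition: str = "normal"
    de: diffexpr.DEThresholds = field(default_factory=diffexpr.DEThresholds)
    lnc: lncfilter.LncFilterParams = field(default_factory=lncfilter.LncFilterParams)
    targets: targets.TargetParams = field(default_factory=targets.TargetParams)
    coexpr: coexpr.CoexprParams = field(default_factory=coexpr.CoexprParams)
    require_lnc_mrna_edge: bool = False
    allowlist: list[str] | None = None  # optional curated gene allowlist

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("counts", "gtf", "transcripts_fasta", "mirna_fasta", "design",
                    "truth", "outdir", "focal_tissue", "focal_stage",
                    "reference_condition", "require_lnc_mrna_edge", "allowlist"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "de" in raw:
            cfg.de = diffexpr.DEThresholds(**raw["de"])
        if "lnc" in raw:
            cfg.lnc = lncfilter.LncFilterParams(**raw["lnc"])
        if "targets" in raw:
            cfg.targets = targets.TargetParams(**raw["targets"])
        if "coexpr" in raw:
            cfg.coexpr = coexpr.CoexprParams(**raw["coexpr"])
        return cfg


@dataclass
class PipelineResult:
    de_tables: dict[tuple[str, str], pd.DataFrame]
    specific: dict[str, dict[str, str]]
    lnc_filter: pd.DataFrame
    edges: dict[str, list[targets.InteractionEdge]]
    overlap: dict[str, dict[str, list[str]]]
    triples: list[CeRNATriple]
    coexpr_result: coexpr.CoexpressionResult | None
    final: list[CeRNATriple]
    recovery: dict | None
    stage_counts: dict[str, int]


def score_recovery(candidates: list[CeRNATriple] | list[tuple], truth: PlantedTruth) -> dict:
    """Exact-match triple precision/recall plus confusion lists.

    Precision is reported as None (NA) when there are no candidates.
    """
    cand = {
        t.key() if isinstance(t, CeRNATriple) else tuple(t) for t in candidates
    }
    true = {(t["lncrna"], t["mirna"], t["mrna"]) for t in truth.triples}
    tp = sorted(cand & true)
    fp = sorted(cand - true)
    fn = sorted(true - cand)
    return {
        "n_candidates": len(cand),
        "n_truth": len(true),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "precision": (len(tp) / len(cand)) if cand else None,
        "recall": (len(tp) / len(true)) if true else None,
    }


def _attrition(
    truth: PlantedTruth,
    final_keys: set[tuple[str, str, str]],
    candidate_pass: set[str],
    de_calls: dict[str, dict[str, str]],
    specific: dict[str, dict[str, str]],
    seed_keys_lnc: set[tuple[str, str]],
    seed_keys_mrna: set[tuple[str, str]],
    hub_union: set[str],
    focal_tissue: str,
) -> dict[str, list]:
    """First stage at which each missed truth triple was lost."""
    stages: dict[str, list] = {
        "recovered": [],
        "lncrna_filter": [],
        "de_call": [],
        "tissue_specificity": [],
        "seed_edge": [],
        "module_hub": [],
        "other": [],
    }
    sig = cerna.TREND_MODELS
    for trip in truth.triples:
        key = (trip["lncrna"], trip["mirna"], trip["mrna"])
        if key in final_keys:
            stages["recovered"].append(key)
            continue
        l, m, g = key
        want = sig[trip["model"]]
        if l not in candidate_pass:
            stages["lncrna_filter"].append(key)
        elif (
            de_calls[focal_tissue].get(l) != want[0]
            or de_calls[focal_tissue].get(m) != want[1]
            or de_calls[focal_tissue].get(g) != want[2]
        ):
            stages["de_call"].append(key)
        elif any(f not in specific[a] for f, a in ((l, "lncrna"), (m, "mirna"), (g, "mrna"))):
            stages["tissue_specificity"].append(key)
        elif (m, l) not in seed_keys_lnc or (m, g) not in seed_keys_mrna:
            stages["seed_edge"].append(key)
        elif g not in hub_union:
            stages["module_hub"].append(key)
        else:
            stages["other"].append(key)
    return stages


def _utr_sites_only(
    edges: list[targets.InteractionEdge],
    cds_of: dict[str, tuple[int, int]],
) -> list[targets.InteractionEdge]:
    """Keep only seed sites lying fully outside the target's CDS span."""
    out = []
    for e in edges:
        cds = cds_of.get(e.target)
        if cds is None:
            out.append(e)
            continue
        sites = tuple(s for s in e.sites if s[1] <= cds[0] or s[0] >= cds[1])
        if sites:
            out.append(
                targets.InteractionEdge(e.regulator, e.target, e.mode, float(len(sites)), sites)
            )
    return out


def run_pipeline_dataset(
    dataset: SimulatedDataset, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full workflow on an in-memory dataset."""
    cfg = config or PipelineConfig()
    design = dataset.design.set_index("sample")
    annotation = dataset.annotation
    focal_tissue, focal_stage = cfg.focal_tissue, cfg.focal_stage
    if focal_tissue not in set(design["tissue"]) or focal_stage not in set(design["stage"]):
        raise ValueError("focal tissue/stage missing from the design table")

    tissues = [t for t in dict.fromkeys(design["tissue"])]
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    de_calls_by_assay: dict[str, dict[str, dict[str, str]]] = {a: {} for a in ASSAYS}
    for assay in ASSAYS:
        counts = dataset.counts[assay]
        for tissue in tissues:
            samples = design.index[
                (design["tissue"] == tissue) & (design["stage"] == focal_stage)
            ].intersection(counts.columns)
            if len(samples) == 0:
                continue
            sub = counts[samples]
            groups = design.loc[samples, "condition"]
            table = diffexpr.run_de(sub, groups, cfg.reference_condition, cfg.de)
            de_tables[(assay, tissue)] = table
            de_calls_by_assay[assay][tissue] = diffexpr.de_sets(table)
            logger.info(
                "DE %s/%s: %d features, %d called",
                assay, tissue, len(table), len(de_calls_by_assay[assay][tissue]),
            )

    specific = {
        assay: cerna.tissue_specific_sets(de_calls_by_assay[assay], focal_tissue)
        for assay in ASSAYS
    }

    # lncRNA candidate filter
    lnc_frame = annotation.frame("lncRNA")
    lnc_counts = dataset.counts["lncrna"]
    mrna_counts = dataset.counts["mrna"]
    shared = lnc_counts.columns
    libsizes = lnc_counts.sum(axis=0) + mrna_counts.reindex(columns=shared).fillna(0).sum(axis=0)
    lengths = lnc_frame["length"]
    fpkm = lncfilter.compute_fpkm(lnc_counts.loc[lnc_frame.index], lengths, libsizes)
    coverage = lncfilter.coverage_proxy(
        lnc_counts.loc[lnc_frame.index], lengths, cfg.lnc.read_length
    )
    coding = lncfilter.coding_votes(
        {tid: dataset.sequences[tid] for tid in lnc_frame.index}, cutoff=cfg.lnc.coding_cutoff
    )
    lnc_filter = lncfilter.filter_lncrna_candidates(lnc_frame, fpkm, coverage, coding, cfg.lnc)
    candidate_pass = set(lnc_filter.index[lnc_filter["pass"]])
    specific_lnc = {f: d for f, d in specific["lncrna"].items() if f in candidate_pass}

    # target edges
    mrna_frame = annotation.frame("protein_coding")
    cis = targets.cis_targets(
        lnc_frame.loc[sorted(candidate_pass)][["chrom", "start", "end"]],
        mrna_frame[["chrom", "start", "end"]],
        cfg.targets,
    )
    factors_all = diffexpr.size_factors(mrna_counts[shared])
    lnc_factors = diffexpr.size_factors(lnc_counts)
    lnc_expr = coexpr.vst_transform(lnc_counts.loc[sorted(candidate_pass)], lnc_factors)
    mrna_expr = coexpr.vst_transform(mrna_counts[shared], factors_all)
    trans = targets.trans_targets(lnc_expr, mrna_expr, cfg.targets)
    mir_seqs = dataset.mirna_sequences
    seed_mrna = targets.seed_targets(
        mir_seqs, {tid: dataset.sequences[tid] for tid in mrna_frame.index}, cfg.targets
    )
    # functional miRNA sites sit in the UTRs (5' or 3'); discard CDS hits
    cds_of = {
        tid: t.cds for tid, t in annotation.transcripts.items() if t.cds is not None
    }
    seed_mrna = _utr_sites_only(seed_mrna, cds_of)
    seed_lnc = targets.seed_targets(
        mir_seqs, {tid: dataset.sequences[tid] for tid in sorted(candidate_pass)}, cfg.targets
    )
    edges = {"cis": cis, "trans": trans, "seed_mrna": seed_mrna, "seed_lnc": seed_lnc}

    # DE/target overlap
    de_lnc_edges = [e for e in cis + trans if e.regulator in specific_lnc]
    de_mir_edges = [e for e in seed_mrna if e.regulator in specific["mirna"]]
    specific_mrna = specific["mrna"]
    if cfg.allowlist is not None:
        specific_mrna = {f: d for f, d in specific_mrna.items() if f in set(cfg.allowlist)}
    overlap = cerna.overlap_targets(specific_mrna, de_lnc_edges, de_mir_edges)

    # trend-model triples
    triples = cerna.assemble_triples(
        specific_lnc,
        specific["mirna"],
        specific_mrna,
        seed_lnc,
        seed_mrna,
        cis + trans,
        require_lnc_mrna_edge=cfg.require_lnc_mrna_edge,
    )

    # co-expression on the focal tissue's stage series, reference condition
    series = design.index[
        (design["tissue"] == focal_tissue)
        & (design["condition"] == cfg.reference_condition)
    ].intersection(dataset.counts["mrna"].columns)
    series_counts = dataset.counts["mrna"][series]
    series_factors = diffexpr.size_factors(series_counts)
    cx = coexpr.run_coexpr(
        series_counts, series_factors, design.loc[series, "stage"], cfg.coexpr
    )

    mt_p = {int(m): cx.module_trait_p.loc[m].to_dict() for m in cx.module_trait_p.index}
    final = cerna.prioritize(triples, mt_p, cx.hub_sets, focal_stage, cfg.coexpr.module_p_threshold)

    significant = {
        m for m, pv in mt_p.items() if pv.get(focal_stage, 1.0) < cfg.coexpr.module_p_threshold
    }
    hub_union: set[str] = set()
    for m in significant:
        hub_union.update(cx.hub_sets.get(m, set()))

    recovery = None
    if dataset.truth is not None:
        recovery = score_recovery(final, dataset.truth)
        recovery["attrition"] = _attrition(
            dataset.truth,
            {t.key() for t in final},
            candidate_pass,
            de_calls_by_assay_flat(de_calls_by_assay),
            specific,
            {(e.regulator, e.target) for e in seed_lnc},
            {(e.regulator, e.target) for e in seed_mrna},
            hub_union,
            focal_tissue,
        )

    stage_counts = {
        "de_mrna_focal": len(de_calls_by_assay["mrna"].get(focal_tissue, {})),
        "de_lncrna_focal": len(de_calls_by_assay["lncrna"].get(focal_tissue, {})),
        "de_mirna_focal": len(de_calls_by_assay["mirna"].get(focal_tissue, {})),
        "specific_mrna": len(specific["mrna"]),
        "specific_lncrna": len(specific["lncrna"]),
        "specific_mirna": len(specific["mirna"]),
        "lnc_candidates": len(candidate_pass),
        "overlap_genes": len(overlap),
        "triples": len(triples),
        "modules": len(cx.hub_sets),
        "significant_modules": len(significant),
        "final_triples": len(final),
    }
    return PipelineResult(
        de_tables, specific, lnc_filter, edges, overlap, triples, cx, final,
        recovery, stage_counts,
    )


def de_calls_by_assay_flat(
    de_calls_by_assay: dict[str, dict[str, dict[str, str]]]
) -> dict[str, dict[str, str]]:
    """Merge per-assay tissue maps into one map tissue -> {feature: dir}."""
    tissues: dict[str, dict[str, str]] = {}
    for assay_map in de_calls_by_assay.values():
        for tissue, features in assay_map.items():
            tissues.setdefault(tissue, {}).update(features)
    return tissues


def _triples_frame(triples: list[CeRNATriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna": t.lncrna,
                "mirna": t.mirna,
                "mrna": t.mrna,
                "model": t.model,
                "lnc_mir_sites": int(t.lnc_mir_edge.evidence) if t.lnc_mir_edge else 0,
                "mir_mrna_sites": int(t.mir_mrna_edge.evidence) if t.mir_mrna_edge else 0,
                "lnc_mrna_mode": t.lnc_mrna_edge.mode if t.lnc_mrna_edge else "",
            }
            for t in triples
        ],
        columns=["lncrna", "mirna", "mrna", "model", "lnc_mir_sites", "mir_mrna_sites", "lnc_mrna_mode"],
    )


def write_report(result: PipelineResult, outdir: str | Path) -> Path:
    """Write every intermediate table plus a JSON report; returns report path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (assay, tissue), table in result.de_tables.items():
        table.to_csv(out / f"de_{assay}_{tissue}.tsv", sep="\t", index_label="feature_id")
    result.lnc_filter.to_csv(out / "lncrna_candidates.tsv", sep="\t", index_label="transcript_id")
    edge_rows = []
    for mode, edges in result.edges.items():
        for e in edges:
            edge_rows.append(
                {
                    "regulator": e.regulator,
                    "target": e.target,
                    "mode": e.mode,
                    "evidence": e.evidence,
                    "sites": ";".join(f"{s}-{t}" for s, t in e.sites),
                }
            )
    pd.DataFrame(edge_rows, columns=["regulator", "target", "mode", "evidence", "sites"]).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    _triples_frame(result.triples).to_csv(out / "triples.tsv", sep="\t", index=False)
    _triples_frame(result.final).to_csv(out / "final_triples.tsv", sep="\t", index=False)
    if result.coexpr_result is not None:
        cx = result.coexpr_result
        cx.labels.to_csv(out / "module_labels.tsv", sep="\t", index_label="gene_id")
        cx.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        cx.module_trait_p.to_csv(out / "module_trait_p.tsv", sep="\t")
    report = {
        "stage_counts": result.stage_counts,
        "final_triples": [list(t.key()) + [t.model] for t in result.final],
        "recovery": result.recovery,
    }
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs per the config, run, write outputs."""
    from cernapipe import io as cio
    from cernapipe.simulate import SimulationParams

    for key in ("gtf", "transcripts_fasta", "mirna_fasta", "design"):
        p = getattr(config, key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config path {key!r} does not exist: {p}")
    annotation = cio.read_gtf(config.gtf)
    sequences = cio.read_fasta(config.transcripts_fasta)
    mirna_sequences = cio.read_fasta(config.mirna_fasta)
    counts = {assay: cio.read_counts(path) for assay, path in config.counts.items()}
    design = cio.read_design(config.design)
    truth = cio.read_truth(config.truth) if config.truth else None
    dataset = SimulatedDataset(
        params=SimulationParams(),
        annotation=annotation,
        sequences=sequences,
        mirna_sequences=mirna_sequences,
        counts=counts,
        design=design,
        truth=truth,
    )
    result = run_pipeline_dataset(dataset, config)
    write_report(result, config.outdir)
    return result
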