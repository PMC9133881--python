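"""Planted-truth simulator for the ceRNA discovery pipeline.

Generates, as a pure function of (parameters, seed): a transcript
annotation (mRNA / lncRNA / miRNA with exon structure and genomic
placement enabling 100 kb cis pairs), transcript and miRNA sequences with
embedded miRNA seed sites, negative-binomial count matrices for a
2-condition x multi-tissue x multi-stage design with replicates, a sample
design table, and a truth record of everything planted:

* tissue-specific DE features with signed directions (log2 shift applied in
  the hairless condition of the given tissue at the focal stage);
* ceRNA triples obeying the two sponge trend models, whose three members
  are DE in the focal tissue with trend-consistent signs and whose seed
  sites are embedded by construction;
* latent-factor co-expression modules, each tied to one developmental
  stage through a mean shift of the shared factor;
* decoy "lncRNAs" violating exactly one candidate filter each (short,
  mono-exonic, coding-ORF-bearing, or silent/unexpressed);
* designated cis pairs placed within the 100 kb window; all other
  neighbours are spaced farther apart.

Counts follow NB(mean, dispersion) with log2-uniform base means, per-sample
library-size offsets spanning at least 2-fold, and gene-wise mean shifts on
the log2 scale for every planted effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cernapipe.lncfilter import orf_coding_score
from cernapipe.targets import TargetParams, mirna_seed

__all__ = [
    "SimulationParams",
    "PlantedTruth",
    "TranscriptModel",
    "AnnotationSet",
    "SimulatedDataset",
    "generate_annotation",
    "generate_sequences",
    "simulate_counts",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
NONCODING_ORF_MARGIN = 0.4  # max longest-ORF fraction for a planted true lncRNA


@dataclass(frozen=True)
class SimulationParams:
    n_mrna: int = 2000
    n_lnc: int = 100
    n_mir: int = 50
    tissues: tuple[str, ...] = ("skin", "heart", "liver", "lung", "kidney")
    stages: tuple[str, ...] = ("E39", "E41", "E45", "E52", "E60")
    focal_tissue: str = "skin"
    focal_stage: str = "E41"
    n_reps: int = 3
    nb_mean_log_range: tuple[float, float] = (3.3, 10.0)  # log2 scale
    dispersion: float = 0.05
    de_fraction: float = 0.05
    de_lfc: float = 2.0
    n_triples: int = 10
    module_sizes: tuple[int, ...] = (60, 50, 40)
    decoy_fraction: float = 0.24  # split evenly across the four decoy classes
    # per-sample factor noise is kept small relative to de_lfc so the
    # module structure cannot mask the planted DE effect on shared genes
    factor_sd: float = 0.3  # latent module factor noise, log2 scale
    stage_shift: float = 2.0  # factor mean shift at the module's stage, log2
    mrna_utr_len: int = 150  # each of 5' and 3'
    mrna_cds_len: int = 300
    lnc_len: int = 300
    mir_len: int = 22
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.de_lfc <= 0:
            raise ValueError("de_lfc must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.focal_tissue not in self.tissues:
            raise ValueError("focal_tissue must be one of tissues")
        if self.focal_stage not in self.stages:
            raise ValueError("focal_stage must be one of stages")
        if self.n_triples > min(self.n_mrna, self.n_lnc, self.n_mir):
            raise ValueError("n_triples exceeds the available feature count")
        needed = sum(self.module_sizes) + self.n_triples
        if needed > self.n_mrna:
            raise ValueError(
                f"module_sizes plus triples need {needed} mRNAs but only "
                f"{self.n_mrna} are simulated"
            )


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str
    exons: list[tuple[int, int]]
    biotype: str  # protein_coding | lncRNA | miRNA
    cds: tuple[int, int] | None = None  # transcript-relative, 0-based half-open

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class AnnotationSet:
    transcripts: dict[str, TranscriptModel]
    chrom_lengths: dict[str, int]

    def frame(self, biotype: str | None = None) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "length": t.length,
                "n_exons": len(t.exons),
                "biotype": t.biotype,
            }
            for t in self.transcripts.values()
            if biotype is None or t.biotype == biotype
        ]
        return pd.DataFrame(rows).set_index("transcript_id")


@dataclass
class PlantedTruth:
    de_features: dict[str, dict[str, str]]  # tissue -> {feature: up|down}
    triples: list[dict[str, str]]  # lncrna, mirna, mrna, model
    modules: dict[str, dict]  # module -> {"genes": [...], "stage": str}
    cis_pairs: list[dict]  # {"lncrna", "gene", "gap"}
    lnc_candidates: list[str]  # true lncRNAs surviving every filter
    decoys: dict[str, str]  # lncRNA id -> decoy class

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        return cls(**json.loads(text))


@dataclass
class SimulatedDataset:
    params: SimulationParams
    annotation: AnnotationSet
    sequences: dict[str, str]  # transcript sequences (DNA alphabet)
    mirna_sequences: dict[str, str]  # mature miRNA sequences (RNA alphabet)
    counts: dict[str, pd.DataFrame]  # assay -> features x samples
    design: pd.DataFrame  # sample, condition, tissue, stage, replicate
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# annotation + truth planning


def _feature_ids(params: SimulationParams) -> tuple[list[str], list[str], list[str]]:
    mrna = [f"MRNA{i:05d}" for i in range(1, params.n_mrna + 1)]
    lnc = [f"LNC{i:04d}" for i in range(1, params.n_lnc + 1)]
    mir = [f"MIR{i:03d}" for i in range(1, params.n_mir + 1)]
    return mrna, lnc, mir


def _plan_truth(params: SimulationParams, rng: np.random.Generator) -> PlantedTruth:
    mrna_ids, lnc_ids, mir_ids = _feature_ids(params)

    # decoys: four classes, each an equal share of decoy_fraction of n_lnc
    per_class = int(round(params.decoy_fraction * params.n_lnc / 4))
    classes = ("short", "monoexonic", "coding", "silent")
    decoys: dict[str, str] = {}
    pool = list(lnc_ids)
    for cls in classes:
        for _ in range(per_class):
            decoys[pool.pop()] = cls  # take from the tail; sponges come from the head
    true_lnc = [l for l in lnc_ids if l not in decoys]
    if len(true_lnc) < params.n_triples:
        raise ValueError("not enough non-decoy lncRNAs for the requested triples")

    # triples: distinct members, alternating trend models
    trip_lnc = true_lnc[: params.n_triples]
    trip_mir = mir_ids[: params.n_triples]
    trip_mrna = mrna_ids[: params.n_triples]
    models = ["model1" if i % 2 == 0 else "model2" for i in range(params.n_triples)]
    triples = [
        {"lncrna": l, "mirna": m, "mrna": g, "model": mod}
        for l, m, g, mod in zip(trip_lnc, trip_mir, trip_mrna, models)
    ]

    # modules: the first module is tied to the focal stage and receives every
    # triple mRNA; remaining modules are tied to other stages round-robin
    other_stages = [s for s in params.stages if s != params.focal_stage]
    module_stage = {
        f"module_{i + 1}": (params.focal_stage if i == 0 else other_stages[(i - 1) % len(other_stages)])
        for i in range(len(params.module_sizes))
    }
    non_triple_mrna = [g for g in mrna_ids if g not in set(trip_mrna)]
    filler_pool = list(rng.permutation(non_triple_mrna))
    modules: dict[str, dict] = {}
    for i, size in enumerate(params.module_sizes):
        name = f"module_{i + 1}"
        if i == 0:
            fill = [filler_pool.pop() for _ in range(max(0, size - len(trip_mrna)))]
            genes = sorted(trip_mrna + fill)
        else:
            genes = sorted(filler_pool.pop() for _ in range(size))
        modules[name] = {"genes": genes, "stage": module_stage[name]}
    module_genes = {g for m in modules.values() for g in m["genes"]}

    # DE planting per tissue.  Triple members anchor the focal tissue with
    # trend-consistent signs; module filler genes are never DE in the focal
    # tissue (stage-driven co-expression, not condition response); triple
    # members are excluded from every other tissue so they stay
    # tissue-specific.
    de_features: dict[str, dict[str, str]] = {t: {} for t in params.tissues}
    n_de_mrna = int(round(params.de_fraction * params.n_mrna))
    n_de_lnc = int(round(params.de_fraction * params.n_lnc))
    n_de_mir = max(1, int(round(params.de_fraction * params.n_mir)))
    trip_members = set(trip_lnc) | set(trip_mir) | set(trip_mrna)

    for t in params.tissues:
        focal = t == params.focal_tissue
        if focal:
            for trip in triples:
                sig = {"model1": ("down", "up", "down"), "model2": ("up", "down", "up")}[
                    trip["model"]
                ]
                de_features[t][trip["lncrna"]] = sig[0]
                de_features[t][trip["mirna"]] = sig[1]
                de_features[t][trip["mrna"]] = sig[2]
            candidates = [
                g for g in non_triple_mrna if g not in module_genes
            ]
            extra = rng.choice(candidates, size=max(0, n_de_mrna - params.n_triples), replace=False)
            for g in extra:
                de_features[t][g] = "up" if rng.random() < 0.5 else "down"
            # skin-specific DE lncRNAs are exactly the planted sponges
        else:
            g_pool = [g for g in mrna_ids if g not in trip_members]
            for g in rng.choice(g_pool, size=n_de_mrna, replace=False):
                de_features[t][g] = "up" if rng.random() < 0.5 else "down"
            l_pool = [l for l in true_lnc if l not in trip_members]
            for l in rng.choice(l_pool, size=min(n_de_lnc, len(l_pool)), replace=False):
                de_features[t][l] = "up" if rng.random() < 0.5 else "down"
            m_pool = [m for m in mir_ids if m not in trip_members]
            for m in rng.choice(m_pool, size=min(n_de_mir, len(m_pool)), replace=False):
                de_features[t][m] = "up" if rng.random() < 0.5 else "down"

    # cis pairs: the first half of the triples are co-located sponge/target
    n_cis = params.n_triples // 2
    cis_pairs = [
        {"lncrna": triples[i]["lncrna"], "gene": triples[i]["mrna"], "gap": None}
        for i in range(n_cis)
    ]

    return PlantedTruth(
        de_features=de_features,
        triples=triples,
        modules=modules,
        cis_pairs=cis_pairs,
        lnc_candidates=sorted(true_lnc),
        decoys=decoys,
    )


def generate_annotation(
    params: SimulationParams, max_retries: int = 100
) -> tuple[AnnotationSet, PlantedTruth]:
    """Place every feature on chromosomes and plan the planted truth.

    Designated cis pairs are placed with a transcript-boundary gap of
    20-80 kb; all other neighbouring features are spaced 150-250 kb apart so
    that only planted pairs fall inside the 100 kb window.
    """
    ss = np.random.SeedSequence([params.seed, 101])
    rng = np.random.default_rng(ss)
    truth = _plan_truth(params, rng)
    mrna_ids, lnc_ids, mir_ids = _feature_ids(params)

    cis_partner = {p["lncrna"]: p["gene"] for p in truth.cis_pairs}
    cis_lnc_of_gene = {g: l for l, g in cis_partner.items()}

    # placement units: a cis-paired mRNA drags its lncRNA right behind it
    units: list[list[str]] = []
    for g in mrna_ids:
        unit = [g]
        if g in cis_lnc_of_gene:
            unit.append(cis_lnc_of_gene[g])
        units.append(unit)
    units.extend([l] for l in lnc_ids if l not in cis_partner)
    units.extend([m] for m in mir_ids)

    n_chrom = 10
    chroms = [f"chr{i}" for i in range(1, n_chrom + 1)]
    cursors = {c: 10_000 for c in chroms}
    transcripts: dict[str, TranscriptModel] = {}

    def _spans(feature: str) -> tuple[list[int], int]:
        """Exon lengths and intron length for a feature id."""
        if feature.startswith("MRNA"):
            total = 2 * params.mrna_utr_len + params.mrna_cds_len
            per = total // 3
            return [per, per, total - 2 * per], 800
        if feature.startswith("MIR"):
            return [params.mir_len], 0
        cls = truth.decoys.get(feature)
        if cls == "short":
            return [75, 75], 600
        if cls == "monoexonic":
            return [params.lnc_len], 0
        half = params.lnc_len // 2
        return [half, params.lnc_len - half], 600

    for i, unit in enumerate(units):
        chrom = chroms[i % n_chrom]
        for j, feature in enumerate(unit):
            if j == 0:
                gap = int(rng.integers(150_000, 250_000))
            else:  # cis partner: inside the window
                gap = int(rng.integers(20_000, 80_000))
            start = cursors[chrom] + gap
            exon_lens, intron = _spans(feature)
            exons = []
            pos = start
            for k, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                pos += el
                if k < len(exon_lens) - 1:
                    pos += intron
            end = exons[-1][1]
            biotype = (
                "protein_coding"
                if feature.startswith("MRNA")
                else "miRNA" if feature.startswith("MIR") else "lncRNA"
            )
            strand = "+" if rng.random() < 0.5 else "-"
            cds = (
                (params.mrna_utr_len, params.mrna_utr_len + params.mrna_cds_len)
                if biotype == "protein_coding"
                else None
            )
            transcripts[feature] = TranscriptModel(
                transcript_id=feature,
                gene_id=feature,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
                biotype=biotype,
                cds=cds,
            )
            cursors[chrom] = end

    for pair in truth.cis_pairs:
        l, g = transcripts[pair["lncrna"]], transcripts[pair["gene"]]
        if l.chrom != g.chrom:
            raise RuntimeError("cis pair placement failed: partners on different chromosomes")
        gap = max(0, l.start - g.end, g.start - l.end)
        if gap > 100_000:
            raise RuntimeError(
                f"cis pair placement failed: gap {gap} bp exceeds the 100 kb window"
            )
        pair["gap"] = int(gap)

    chrom_lengths = {c: cursors[c] + 10_000 for c in chroms}
    return AnnotationSet(transcripts, chrom_lengths), truth


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    """ATG + random non-stop codons + stop, exactly n_nt long (n_nt % 3 == 0)."""
    n_codons = n_nt // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + _STOPS[rng.integers(0, 3)]


def _embed(seq: str, site: str, pos: int) -> str:
    return seq[:pos] + site + seq[pos + len(site) :]


def _rc(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def generate_sequences(
    annotation: AnnotationSet,
    truth: PlantedTruth,
    seed: int,
    params: SimulationParams | None = None,
    max_retries: int = 50,
) -> tuple[dict[str, str], dict[str, str]]:
    """Transcript (DNA) and miRNA (RNA) sequences with planted seed sites.

    For every planted triple the exact reverse complement of the miRNA seed
    (positions 2-8) is embedded in the target mRNA's UTR (5' or 3', chosen
    at random) and in the sponge lncRNA; background sequence is uniform over
    {A,C,G,T} with no deliberate sites.  True lncRNAs are resampled until
    their longest-ORF fraction stays below 0.4 so that, by construction,
    they survive the coding-potential filter; the ``coding`` decoy class is
    built as one open reading frame end-to-end.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    mir_ids = sorted(t for t in annotation.transcripts if t.startswith("MIR"))
    mirna_seqs_dna = {m: _random_seq(rng, params.mir_len) for m in mir_ids}
    if params.mir_len < 8:
        raise ValueError("miRNA length leaves a seed region shorter than 7 nt")
    tp = TargetParams()
    site_of_mir = {m: _rc(mirna_seed(s, tp)) for m, s in mirna_seqs_dna.items()}

    sponge_site: dict[str, str] = {}
    target_site: dict[str, str] = {}
    for trip in truth.triples:
        sponge_site[trip["lncrna"]] = site_of_mir[trip["mirna"]]
        target_site[trip["mrna"]] = site_of_mir[trip["mirna"]]
    # truth must control every site among planted members: a chance
    # occurrence of another planted miRNA's seed in a sponge or target
    # would be a real, undeclared interaction and make the truth ambiguous
    planted_sites = {site_of_mir[t["mirna"]] for t in truth.triples}

    def _foreign_site(seq: str, own: str | None) -> bool:
        return any(s in seq for s in planted_sites if s != own)

    sequences: dict[str, str] = {}
    for tid, t in annotation.transcripts.items():
        n = t.length
        if t.biotype == "miRNA":
            sequences[tid] = mirna_seqs_dna[tid]
        elif t.biotype == "protein_coding":
            site = target_site.get(tid)
            for attempt in range(max_retries):
                utr5 = _random_seq(rng, params.mrna_utr_len)
                cds = _random_cds(rng, params.mrna_cds_len)
                utr3 = _random_seq(rng, params.mrna_utr_len)
                if site is not None:
                    pos = int(rng.integers(0, params.mrna_utr_len - len(site)))
                    if rng.random() < 0.5:
                        utr5 = _embed(utr5, site, pos)
                    else:
                        utr3 = _embed(utr3, site, pos)
                    if not _foreign_site(utr5 + utr3, site):
                        break
                else:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a UTR for {tid} free of other planted "
                    f"seed sites in {max_retries} tries"
                )
            sequences[tid] = utr5 + cds + utr3
        else:  # lncRNA classes
            cls = truth.decoys.get(tid)
            if cls == "coding":
                n_cds = (n // 3) * 3
                seq = _random_cds(rng, n_cds) + _random_seq(rng, n - n_cds)
                sequences[tid] = seq
                continue
            site = sponge_site.get(tid)
            for attempt in range(max_retries):
                seq = _random_seq(rng, n)
                if site is not None:
                    pos = int(rng.integers(0, n - len(site)))
                    seq = _embed(seq, site, pos)
                    if _foreign_site(seq, site):
                        continue
                score, orf = orf_coding_score(seq)
                if orf / n < NONCODING_ORF_MARGIN:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a non-coding sequence for {tid} in "
                    f"{max_retries} tries (longest-ORF fraction < {NONCODING_ORF_MARGIN})"
                )
            sequences[tid] = seq

    mirna_rna = {m: s.replace("T", "U") for m, s in mirna_seqs_dna.items()}
    return sequences, mirna_rna


# ---------------------------------------------------------------------------
# counts


def _sample_table(params: SimulationParams) -> pd.DataFrame:
    rows = []
    for tissue in params.tissues:
        for cond in ("normal", "hairless"):
            for rep in range(1, params.n_reps + 1):
                rows.append((f"{tissue}_{params.focal_stage}_{cond}_{rep}", cond, tissue, params.focal_stage, rep))
    for stage in params.stages:
        if stage == params.focal_stage:
            continue
        for cond in ("normal", "hairless"):
            for rep in range(1, params.n_reps + 1):
                rows.append((f"{params.focal_tissue}_{stage}_{cond}_{rep}", cond, params.focal_tissue, stage, rep))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "tissue", "stage", "replicate"]
    ).set_index("sample")


def simulate_counts(
    annotation: AnnotationSet, truth: PlantedTruth, params: SimulationParams
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """NB count matrices per assay plus the sample design table.

    The mRNA assay covers the focal stage in every tissue plus the focal
    tissue's full stage series; the lncRNA and miRNA assays cover the focal
    stage only (matching the sequencing design the pipeline expects).
    Planted DE features have their log2 mean shifted by +-de_lfc in the
    hairless condition of their tissue at the focal stage; module genes
    share a latent per-sample factor (in the focal tissue, both conditions)
    whose mean is shifted at the module's associated stage; library-size
    offsets span at least 2-fold across samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 303]))
    design = _sample_table(params)
    focal_mask = design["stage"] == params.focal_stage
    mrna_ids, lnc_ids, mir_ids = _feature_ids(params)

    lo, hi = params.nb_mean_log_range
    if hi <= lo:
        raise ValueError("nb_mean_log_range must be increasing")
    mid = (lo + hi) / 2.0

    trip_mrnas = {trip["mrna"] for trip in truth.triples}
    planted = {g for trip in truth.triples for g in (trip["lncrna"], trip["mirna"], trip["mrna"])}
    module_of_gene: dict[str, str] = {}
    loading: dict[str, float] = {}
    for name, mod in truth.modules.items():
        for g in mod["genes"]:
            module_of_gene[g] = name
            planted.add(g)
    base: dict[str, float] = {}
    for fid in mrna_ids + lnc_ids + mir_ids:
        if fid in planted:
            base[fid] = float(rng.uniform(mid, hi))
        else:
            base[fid] = float(rng.uniform(lo, hi))
        if fid in module_of_gene:
            # triple mRNAs are planted as hub members: their loading must
            # keep kME safely above the hub threshold despite sampling noise
            if fid in trip_mrnas:
                loading[fid] = float(rng.uniform(1.2, 1.5))
            else:
                loading[fid] = float(rng.uniform(0.8, 1.2))
    for fid, cls in truth.decoys.items():
        if cls == "silent":
            base[fid] = -np.inf  # zero mean -> all-zero counts

    # latent module factors: one value per (module, focal-tissue sample)
    focal_tissue_samples = design.index[design["tissue"] == params.focal_tissue]
    factor: dict[str, pd.Series] = {}
    for name, mod in truth.modules.items():
        shift = (design.loc[focal_tissue_samples, "stage"] == mod["stage"]) * params.stage_shift
        noise = rng.normal(0.0, params.factor_sd, size=len(focal_tissue_samples))
        factor[name] = shift + noise

    # library offsets: exact >= 2-fold spread, shuffled deterministically
    all_samples = design.index
    offsets = np.linspace(-0.5, 0.5, num=len(all_samples))
    rng.shuffle(offsets)
    lib_offset = pd.Series(offsets, index=all_samples)

    de_shift = params.de_lfc  # log2 units

    def _matrix(ids: list[str], samples: pd.Index) -> pd.DataFrame:
        sub = design.loc[samples]
        logmu = np.zeros((len(ids), len(samples)))
        for i, fid in enumerate(ids):
            logmu[i, :] = base[fid] + lib_offset.loc[samples].to_numpy()
            mod = module_of_gene.get(fid)
            if mod is not None:
                f = factor[mod].reindex(samples).fillna(0.0).to_numpy()
                logmu[i, :] += loading[fid] * f
        for j, (sample, row) in enumerate(sub.iterrows()):
            if row["stage"] != params.focal_stage or row["condition"] != "hairless":
                continue
            tissue_de = truth.de_features.get(row["tissue"], {})
            for i, fid in enumerate(ids):
                d = tissue_de.get(fid)
                if d == "up":
                    logmu[i, j] += de_shift
                elif d == "down":
                    logmu[i, j] -= de_shift
        mu = np.power(2.0, logmu)
        mu = np.where(np.isfinite(mu), mu, 0.0)
        if (mu < 0).any():
            raise ValueError("negative NB means are not permitted")
        if (mu > 2**53).any():
            raise ValueError("NB means overflow safe integer range")
        n_param = 1.0 / params.dispersion
        p_param = np.where(mu > 0, n_param / (n_param + mu), 1.0)
        counts = rng.negative_binomial(n_param, p_param)
        counts = np.where(mu > 0, counts, 0)
        return pd.DataFrame(counts, index=ids, columns=samples)

    mrna_samples = design.index
    ncrna_samples = design.index[focal_mask]
    counts = {
        "mrna": _matrix(mrna_ids, mrna_samples),
        "lncrna": _matrix(lnc_ids, ncrna_samples),
        "mirna": _matrix(mir_ids, ncrna_samples),
    }
    return counts, design.reset_index()


def simulate_dataset(params: SimulationParams = SimulationParams()) -> SimulatedDataset:
    """Full deterministic dataset: annotation, sequences, counts, truth."""
    annotation, truth = generate_annotation(params)
    sequences, mirna_rna = generate_sequences(annotation, truth, params.seed, params)
    counts, design = simulate_counts(annotation, truth, params)
    return SimulatedDataset(params, annotation, sequences, mirna_rna, counts, design, truth)


# ---------------------------------------------------------------------------
# writers (GTF 1-based inclusive, FASTA, TSV, truth JSON)


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    lines = []
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{t.biotype}";'
        )
        if t.cds is not None:
            # transcript-relative CDS span, 1-based inclusive
            attrs += f' cds_start "{t.cds[0] + 1}"; cds_end "{t.cds[1]}";'
        lines.append(
            "\t".join(
                [t.chrom, "cernapipe", "transcript", str(t.start + 1), str(t.end), ".", t.strand, ".", attrs]
            )
        )
        for s, e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, "cernapipe", "exon", str(s + 1), str(e), ".", t.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(sequences):
            fh.write(f">{tid}\n")
            seq = sequences[tid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write GTF, FASTAs, per-assay counts TSV, design TSV and truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["gtf"] = out / "annotation.gtf"
    write_gtf(dataset.annotation, paths["gtf"])
    paths["transcripts_fasta"] = out / "transcripts.fa"
    write_fasta(dataset.sequences, paths["transcripts_fasta"])
    paths["mirna_fasta"] = out / "mirnas.fa"
    write_fasta(dataset.mirna_sequences, paths["mirna_fasta"])
    for assay, mat in dataset.counts.items():
        p = out / f"counts_{assay}.tsv"
        mat.to_csv(p, sep="\t", index_label="feature_id")
        paths[f"counts_{assay}"] = p
    paths["design"] = out / "design.tsv"
    dataset.design.to_csv(paths["design"], sep="\t", index=False)
    paths["truth"] = out / "truth.json"
    Path(paths["truth"]).write_text(dataset.truth.to_json())
    return paths
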