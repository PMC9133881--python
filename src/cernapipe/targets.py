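"""Regulator->target edge assignment.

Three edge modes are supported, mirroring how lncRNA and miRNA targets are
nominated in multi-omic ceRNA studies:

* ``cis``  — a lncRNA and a gene on the same chromosome whose transcript
  boundaries lie within a window (100 kb by default); the genomic gap is the
  evidence.
* ``trans`` — expression profiles with |Pearson r| >= 0.95 by default; the
  signed correlation is the evidence.
* ``seed`` — the exact reverse complement of the miRNA seed (nucleotides
  2-8) occurring at least once in the target sequence; all site positions
  (0-based, half-open on the target) are the evidence.

``intersect_predictors`` keeps only edges present in every predictor's edge
set, preserving the multi-tool-overlap semantics used to prune seed-based
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "InteractionEdge",
    "TargetParams",
    "cis_targets",
    "trans_targets",
    "seed_targets",
    "intersect_predictors",
    "mirna_seed",
    "interval_gap",
]


@dataclass(frozen=True)
class TargetParams:
    cis_window: int = 100_000
    r_threshold: float = 0.95
    seed_start: int = 2  # 1-based miRNA position, inclusive
    seed_end: int = 8  # 1-based miRNA position, inclusive

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if self.seed_end - self.seed_start + 1 < 7:
            raise ValueError("seed region must span at least 7 nt")


@dataclass(frozen=True)
class InteractionEdge:
    """Typed regulator->target edge with its evidence."""

    regulator: str
    target: str
    mode: str  # cis | trans | seed
    evidence: float  # genomic gap (bp) | Pearson r | site count
    sites: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def key(self) -> tuple[str, str]:
        return (self.regulator, self.target)


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two 0-based half-open intervals (0 if overlapping)."""
    if end_a <= start_a or end_b <= start_b:
        raise ValueError("malformed interval: end must exceed start")
    return max(0, start_b - end_a, start_a - end_b)


def cis_targets(
    lnc_annotations: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    params: TargetParams = TargetParams(),
) -> list[InteractionEdge]:
    """Genomic-proximity edges: same chromosome, boundary gap <= window.

    Both inputs are DataFrames indexed by feature id with columns ``chrom``,
    ``start``, ``end`` (0-based half-open).  Strand is ignored; the gap is
    measured between the closest transcript boundaries.  The scan is sorted
    per chromosome, so the cost is near-linear after sorting.
    """
    for name, df in (("lnc", lnc_annotations), ("gene", gene_annotations)):
        if (df["end"] <= df["start"]).any():
            raise ValueError(f"malformed interval in {name} annotations")
    edges: list[InteractionEdge] = []
    genes_by_chrom = {
        chrom: sub.sort_values("start") for chrom, sub in gene_annotations.groupby("chrom")
    }
    for lnc_id, lnc in lnc_annotations.sort_values(["chrom", "start"]).iterrows():
        genes = genes_by_chrom.get(lnc["chrom"])
        if genes is None:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        mask = (starts <= lnc["end"] + params.cis_window) & (
            ends >= lnc["start"] - params.cis_window
        )
        for gene_id, g in genes[mask].iterrows():
            gap = interval_gap(lnc["start"], lnc["end"], g["start"], g["end"])
            if gap <= params.cis_window:
                edges.append(InteractionEdge(lnc_id, gene_id, "cis", float(gap)))
    return edges


def trans_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    params: TargetParams = TargetParams(),
) -> list[InteractionEdge]:
    """Co-expression edges: |Pearson r| >= threshold on log-scale profiles.

    Zero-variance profiles yield no edges (r undefined) with a warning.
    """
    if lnc_expr.shape[1] < 3:
        raise ValueError("need at least 3 paired samples")
    if list(lnc_expr.columns) != list(gene_expr.columns):
        gene_expr = gene_expr[lnc_expr.columns]
    lx = lnc_expr.to_numpy(dtype=float)
    gx = gene_expr.to_numpy(dtype=float)
    lsd = lx.std(axis=1)
    gsd = gx.std(axis=1)
    if (lsd == 0).any() or (gsd == 0).any():
        warnings.warn("zero-variance expression profiles excluded (r undefined)")
    lz = (lx - lx.mean(axis=1, keepdims=True)) / np.where(lsd == 0, np.nan, lsd)[:, None]
    gz = (gx - gx.mean(axis=1, keepdims=True)) / np.where(gsd == 0, np.nan, gsd)[:, None]
    r = lz @ gz.T / lx.shape[1]
    edges = []
    hits = np.argwhere(np.abs(np.nan_to_num(r)) >= params.r_threshold)
    for i, j in hits:
        edges.append(
            InteractionEdge(
                str(lnc_expr.index[i]), str(gene_expr.index[j]), "trans", float(r[i, j])
            )
        )
    return edges


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def mirna_seed(mirna_seq: str, params: TargetParams = TargetParams()) -> str:
    """Extract the seed (positions 2-8, 1-based inclusive, by default)."""
    seq = _normalize(mirna_seq)
    if len(seq) < params.seed_end:
        raise ValueError(
            f"miRNA of length {len(seq)} is shorter than the seed span "
            f"(positions {params.seed_start}-{params.seed_end})"
        )
    return seq[params.seed_start - 1 : params.seed_end]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def seed_targets(
    mirna_seqs: dict[str, str],
    target_seqs: dict[str, str],
    params: TargetParams = TargetParams(),
) -> list[InteractionEdge]:
    """Seed-match edges: exact reverse complement of the miRNA seed in the target.

    Matching is alphabet-normalized (U -> T, case-insensitive); overlapping
    occurrences all count, and every site is reported as a 0-based half-open
    interval on the target.
    """
    edges = []
    seeds = {
        mid: str(Seq(mirna_seed(seq, params)).reverse_complement())
        for mid, seq in mirna_seqs.items()
    }
    for tid, tseq in target_seqs.items():
        if not tseq:
            raise ValueError(f"empty target sequence for {tid}")
        norm = _normalize(tseq)
        for mid, site in seeds.items():
            positions = _find_all(norm, site)
            if positions:
                edges.append(
                    InteractionEdge(
                        mid,
                        tid,
                        "seed",
                        float(len(positions)),
                        tuple((p, p + len(site)) for p in positions),
                    )
                )
    return edges


def intersect_predictors(edge_sets: list[list[InteractionEdge]]) -> list[InteractionEdge]:
    """Edges whose (regulator, target) pair appears in every predictor set.

    Evidence from the first set is kept; evidence from the other sets is
    attached via the returned edges' order-stable merge (sites unioned).
    """
    if not edge_sets:
        raise ValueError("need at least one edge set")
    keysets = [{e.key() for e in s} for s in edge_sets]
    common = set.intersection(*keysets)
    by_key: dict[tuple[str, str], InteractionEdge] = {}
    for s in edge_sets:
        for e in s:
            if e.key() in common:
                if e.key() not in by_key:
                    by_key[e.key()] = e
                else:
                    prev = by_key[e.key()]
                    merged_sites = tuple(sorted(set(prev.sites) | set(e.sites)))
                    by_key[e.key()] = InteractionEdge(
                        prev.regulator, prev.target, prev.mode, prev.evidence, merged_sites
                    )
    return [by_key[k] for k in sorted(by_key)]
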