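"""Standard-format I/O: GTF, FASTA, counts/design TSV, truth JSON.

GTF coordinates are 1-based inclusive on disk and converted to 0-based
half-open in memory; parsing goes through :mod:`gffutils`.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from cernapipe.simulate import AnnotationSet, PlantedTruth, TranscriptModel

__all__ = [
    "read_gtf",
    "read_fasta",
    "read_counts",
    "read_design",
    "read_truth",
]


def read_gtf(path: str | Path) -> AnnotationSet:
    """Load transcript models (with exons and biotype) from a GTF file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, TranscriptModel] = {}
    chrom_max: dict[str, int] = {}
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["transcript_id"][0]
        cds = None
        if "cds_start" in feat.attributes and "cds_end" in feat.attributes:
            cds = (int(feat.attributes["cds_start"][0]) - 1, int(feat.attributes["cds_end"][0]))
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=feat.attributes["gene_id"][0],
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
            exons=[],
            biotype=feat.attributes.get("gene_biotype", ["unknown"])[0],
            cds=cds,
        )
        chrom_max[feat.seqid] = max(chrom_max.get(feat.seqid, 0), feat.end)
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        transcripts[tid].exons.append((feat.start - 1, feat.end))
    for t in transcripts.values():
        t.exons.sort()
    return AnnotationSet(transcripts, {c: m + 10_000 for c, m in chrom_max.items()})


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth(path: str | Path) -> PlantedTruth:
    return PlantedTruth.from_json(Path(path).read_text())
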