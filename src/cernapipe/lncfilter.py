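"""lncRNA candidate selection.

Transcripts survive as lncRNA candidates only if they clear, in order:

1. transcript length >= 200 nt and exon number >= 2;
2. FPKM > 0.5 in at least one sample;
3. minimal read coverage >= 3 in at least one sample (proxied by
   ``count * read_length / transcript_length``);
4. not carrying a known protein-coding annotation;
5. a consensus non-coding vote across registered coding-potential scorers.

The external coding-potential tools used in practice (alignment- and
profile-based classifiers) are replaced by a pluggable scorer contract with
one built-in open-reading-frame scorer: the logistic of the longest-ORF
fraction of the transcript.  A transcript is non-coding iff *all* registered
scorers vote non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LncFilterParams",
    "compute_fpkm",
    "orf_coding_score",
    "coding_votes",
    "filter_lncrna_candidates",
]

# rejection reasons in the printed order of the filter rules
REASONS = ("length", "exon number", "FPKM", "coverage", "known coding annotation", "coding potential")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class LncFilterParams:
    min_length: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.5
    min_coverage: float = 3.0
    read_length: int = 150
    coding_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_exons, self.min_fpkm, self.min_coverage) <= 0:
            raise ValueError("all thresholds must be strictly positive")


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm = count / (length/1e3) / (library_size/1e6)``.
    """
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    if np.isnan(lens).any() or (lens <= 0).any():
        raise ValueError("every transcript needs a positive length")
    libs = library_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(libs).any() or (libs <= 0).any():
        raise ValueError("every sample needs a positive library size")
    x = counts.to_numpy(dtype=float)
    fpkm = x / (lens[:, None] / 1e3) / (libs[None, :] / 1e6)
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def longest_orf_length(sequence: str) -> int:
    """Longest ATG->stop open reading frame over the 3 forward frames (nt).

    The length includes start and stop codons; an ORF must terminate at an
    in-frame stop codon within the sequence.
    """
    seq = sequence.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        start = None
        for idx, codon in enumerate(codons):
            if start is None and codon == "ATG":
                start = idx
            elif start is not None and codon in STOP_CODONS:
                best = max(best, (idx - start + 1) * 3)
                start = None
    return best


def orf_coding_score(sequence: str, steepness: float = 10.0, midpoint: float = 0.5) -> tuple[float, int]:
    """Coding-potential score in [0, 1] plus the longest ORF length.

    The score is a logistic function of the longest-ORF fraction of the
    transcript, monotone in that fraction; transcripts whose longest ORF
    covers more than ``midpoint`` of the sequence score above 0.5.

    Raises
    ------
    ValueError
        If more than 10% of bases are ambiguous (not A/C/G/T/U).
    """
    seq = sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    n_ambig = sum(1 for b in seq if b not in "ACGT")
    if n_ambig > 0.1 * len(seq):
        raise ValueError(
            f"{n_ambig}/{len(seq)} ambiguous bases exceed the 10% tolerance"
        )
    orf = longest_orf_length(seq)
    frac = orf / len(seq)
    score = 1.0 / (1.0 + np.exp(-steepness * (frac - midpoint)))
    return float(score), orf


def coding_votes(
    sequences: Mapping[str, str],
    scorers: Sequence[Callable[[str], tuple[float, int]]] | None = None,
    cutoff: float = 0.5,
) -> pd.Series:
    """Consensus coding call per transcript over pluggable scorers.

    A transcript is voted *coding* (True) if any scorer's score reaches
    ``cutoff``; it is non-coding only when all scorers agree it is.
    """
    if scorers is None:
        scorers = [orf_coding_score]
    votes = {}
    for tid, seq in sequences.items():
        votes[tid] = any(scorer(seq)[0] >= cutoff for scorer in scorers)
    return pd.Series(votes, name="coding")


def filter_lncrna_candidates(
    transcripts: pd.DataFrame,
    fpkm: pd.DataFrame,
    coverage: pd.DataFrame,
    coding: pd.Series,
    params: LncFilterParams = LncFilterParams(),
) -> pd.DataFrame:
    """Apply the five candidate-selection rules to every transcript.

    Parameters
    ----------
    transcripts:
        DataFrame indexed by transcript id with columns ``length``,
        ``n_exons`` and ``biotype`` (a biotype of ``protein_coding`` marks a
        known non-lncRNA annotation).
    fpkm, coverage:
        Per-sample matrices; the FPKM and coverage rules require the
        threshold to hold in at least one sample.
    coding:
        Boolean consensus coding call per transcript (True = coding).

    Returns
    -------
    DataFrame indexed like ``transcripts`` with boolean ``pass`` and a
    ``reason`` column recording the first failing rule in the printed order
    (empty string for passing transcripts).
    """
    ids = transcripts.index
    for name, table in (("fpkm", fpkm), ("coverage", coverage)):
        missing = ids.difference(table.index)
        if len(missing):
            raise ValueError(f"transcripts missing from {name}: {list(missing)[:5]}")
    missing = ids.difference(coding.index)
    if len(missing):
        raise ValueError(f"transcripts missing from coding calls: {list(missing)[:5]}")

    length_ok = transcripts["length"] >= params.min_length
    exons_ok = transcripts["n_exons"] >= params.min_exons
    fpkm_ok = (fpkm.loc[ids] > params.min_fpkm).any(axis=1)
    cov_ok = (coverage.loc[ids] >= params.min_coverage).any(axis=1)
    not_annotated_coding = transcripts["biotype"] != "protein_coding"
    noncoding_ok = ~coding.loc[ids].astype(bool)

    rules = [
        ("length", length_ok),
        ("exon number", exons_ok),
        ("FPKM", fpkm_ok),
        ("coverage", cov_ok),
        ("known coding annotation", not_annotated_coding),
        ("coding potential", noncoding_ok),
    ]
    passed = pd.Series(True, index=ids)
    reason = pd.Series("", index=ids)
    for label, ok in rules:
        newly_failed = passed & ~ok
        reason[newly_failed] = label
        passed &= ok
    return pd.DataFrame({"pass": passed, "reason": reason})


def coverage_proxy(
    counts: pd.DataFrame, lengths: pd.Series, read_length: int = 150
) -> pd.DataFrame:
    """Mean per-base read depth proxied by ``count * read_length / length``."""
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    if (lens <= 0).any():
        raise ValueError("every transcript needs a positive length")
    return counts.mul(read_length).div(lens, axis=0)
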