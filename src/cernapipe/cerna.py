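"""Tissue-specificity logic and trend-model ceRNA triple assembly.

A competing-endogenous-RNA triple (lncRNA, miRNA, mRNA) is emitted when the
lncRNA and the mRNA both carry a seed site for the miRNA and the three
differential-expression directions follow one of the two sponge-consistent
trend models:

* model1: lncRNA down | miRNA up   | mRNA down
* model2: lncRNA up   | miRNA down | mRNA up

Candidates are then prioritized by requiring the mRNA to be a hub gene of a
co-expression module significantly associated (p < 0.05) with the focal
developmental stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from cernapipe.targets import InteractionEdge

__all__ = [
    "CeRNATriple",
    "TREND_MODELS",
    "tissue_specific_sets",
    "overlap_targets",
    "assemble_triples",
    "prioritize",
]

# direction signature (lncRNA, miRNA, mRNA) per trend model
TREND_MODELS: dict[str, tuple[str, str, str]] = {
    "model1": ("down", "up", "down"),
    "model2": ("up", "down", "up"),
}


@dataclass(frozen=True)
class CeRNATriple:
    lncrna: str
    mirna: str
    mrna: str
    model: str
    lnc_mir_edge: InteractionEdge | None = None
    mir_mrna_edge: InteractionEdge | None = None
    lnc_mrna_edge: InteractionEdge | None = None

    def key(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


def tissue_specific_sets(
    de_sets: Mapping[str, Mapping[str, str]], focal: str
) -> dict[str, str]:
    """Features DE in the focal tissue and in no other tissue.

    ``de_sets`` maps tissue -> {feature: 'up'|'down'}.  Exclusion is
    direction-agnostic: a feature DE up in the focal tissue and down
    elsewhere is still excluded.
    """
    if not de_sets:
        raise ValueError("empty DE map")
    if focal not in de_sets:
        raise ValueError(f"focal tissue {focal!r} missing from DE map")
    other = set()
    for tissue, features in de_sets.items():
        if tissue != focal:
            other.update(features)
    return {f: d for f, d in de_sets[focal].items() if f not in other}


def overlap_targets(
    specific_de_mrna: Iterable[str],
    lnc_edges: Iterable[InteractionEdge],
    mir_edges: Iterable[InteractionEdge],
) -> dict[str, dict[str, list[str]]]:
    """Genes supported by all three evidence streams, with provenance.

    Returns ``{gene: {"lncrna": [regulators], "mirna": [regulators]}}`` for
    genes that are focal-tissue-specific DE *and* targeted by at least one
    lncRNA *and* at least one miRNA.
    """
    lnc_by_gene: dict[str, list[str]] = {}
    for e in lnc_edges:
        lnc_by_gene.setdefault(e.target, []).append(e.regulator)
    mir_by_gene: dict[str, list[str]] = {}
    for e in mir_edges:
        mir_by_gene.setdefault(e.target, []).append(e.regulator)
    out = {}
    for gene in sorted(set(specific_de_mrna) & set(lnc_by_gene) & set(mir_by_gene)):
        out[gene] = {
            "lncrna": sorted(set(lnc_by_gene[gene])),
            "mirna": sorted(set(mir_by_gene[gene])),
        }
    return out


def assemble_triples(
    lnc_de: Mapping[str, str],
    mir_de: Mapping[str, str],
    mrna_de: Mapping[str, str],
    lnc_mir_edges: Iterable[InteractionEdge],
    mir_mrna_edges: Iterable[InteractionEdge],
    lnc_mrna_edges: Iterable[InteractionEdge] = (),
    require_lnc_mrna_edge: bool = False,
) -> list[CeRNATriple]:
    """Enumerate trend-consistent triples supported by both seed edges.

    ``lnc_mir_edges`` carry the miRNA as regulator and the lncRNA (sponge)
    as target; ``mir_mrna_edges`` the miRNA as regulator and the mRNA as
    target.  A direct lncRNA->mRNA (cis/trans) edge is recorded when
    available and required only in strict mode
    (``require_lnc_mrna_edge=True``).  Output is deduplicated and sorted by
    (lncRNA, miRNA, mRNA); any member with no DE direction is silently
    skipped.
    """
    lnc_by_mir: dict[str, dict[str, InteractionEdge]] = {}
    for e in lnc_mir_edges:
        if e.regulator in mir_de and e.target in lnc_de:
            lnc_by_mir.setdefault(e.regulator, {})[e.target] = e
    mrna_by_mir: dict[str, dict[str, InteractionEdge]] = {}
    for e in mir_mrna_edges:
        if e.regulator in mir_de and e.target in mrna_de:
            mrna_by_mir.setdefault(e.regulator, {})[e.target] = e
    direct = {(e.regulator, e.target): e for e in lnc_mrna_edges}

    seen: dict[tuple[str, str, str], CeRNATriple] = {}
    for mir, lncs in lnc_by_mir.items():
        mrnas = mrna_by_mir.get(mir)
        if not mrnas:
            continue
        for lnc, le in lncs.items():
            for mrna, me in mrnas.items():
                signature = (lnc_de[lnc], mir_de[mir], mrna_de[mrna])
                model = next(
                    (name for name, sig in TREND_MODELS.items() if sig == signature),
                    None,
                )
                if model is None:
                    continue
                de = direct.get((lnc, mrna))
                if require_lnc_mrna_edge and de is None:
                    continue
                key = (lnc, mir, mrna)
                if key not in seen:
                    seen[key] = CeRNATriple(lnc, mir, mrna, model, le, me, de)
    return [seen[k] for k in sorted(seen)]


def prioritize(
    triples: Iterable[CeRNATriple],
    module_trait_p: Mapping[int, Mapping[str, float]],
    hub_sets: Mapping[int, set[str]],
    focal_stage: str,
    p_threshold: float = 0.05,
) -> list[CeRNATriple]:
    """Retain triples whose mRNA is a hub of a focal-stage-significant module.

    ``module_trait_p`` maps module label -> {stage: p-value}; a module is
    significant when its focal-stage p-value is strictly below
    ``p_threshold``.  Emits a warning and returns an empty list when no
    module is significant.
    """
    significant = {
        m for m, pvals in module_trait_p.items() if pvals.get(focal_stage, 1.0) < p_threshold
    }
    if not significant:
        warnings.warn(f"no module significantly associated with {focal_stage}")
        return []
    hubs = set()
    for m in significant:
        hubs.update(hub_sets.get(m, set()))
    return [t for t in triples if t.mrna in hubs]
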