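"""HEG labelling: external gene lists, plus an optional CAI classifier.

The analysis consumes externally predicted highly expressed genes (HEG);
the codon adaptation index (CAI) scorer exists so the full pipeline can run
on data with no external list (e.g. synthetic genomes).  File labels always
override CAI classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from ._genetics import codon_family, iter_codons, sense_codons
from .seqio import GeneRecord, GenomeDataset

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


class HegListError(ValueError):
    pass


def read_heg_ids(path) -> list[str]:
    """Read a HEG list: one gene_id per line, '#' starts a comment."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids


def load_heg_list(path, dataset: GenomeDataset) -> GenomeDataset:
    """Flag the dataset's genes named in the list; mutates and returns it.

    Zero matches is an error (almost always an ID-scheme mismatch);
    unmatched IDs are reported as a warning.
    """
    ids = read_heg_ids(path)
    known = {g.gene_id for g in dataset.genes}
    matched = set(ids) & known
    if not matched:
        raise HegListError(
            f"no gene in {dataset.genome_id!r} matches the HEG list {path} "
            f"({len(ids)} ids read); check the gene-id scheme"
        )
    missing = sorted(set(ids) - known)
    if missing:
        log.warning("HEG list %s: %d ids not in dataset: %s", path, len(missing), missing)
    for g in dataset.genes:
        g.is_heg = g.gene_id in matched
    return dataset


@dataclass
class CaiWeights:
    """Relative-adaptiveness weights; family-maximal codons have weight 1."""

    w: dict[str, float]
    reference_size: int


def cai_weights(reference_genes: list[GeneRecord], genetic_code_id: int = 11) -> CaiWeights:
    """Codon weights from a reference set (typically ribosomal proteins).

    w(c) = count(c) / max count within c's synonymous family; unobserved
    codons receive a 0.5 pseudo-count so no weight is zero.  Stop codons
    are excluded.
    """
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    counts = {c: 0.0 for c in sense_codons(genetic_code_id)}
    for g in reference_genes:
        for codon in iter_codons(g.cds[:-3] if g.valid else g.cds):
            if codon in counts:
                counts[codon] += 1
    for c in counts:
        if counts[c] == 0:
            counts[c] = PSEUDOCOUNT
    fam = codon_family(genetic_code_id)
    w = {c: counts[c] / max(counts[m] for m in fam[c]) for c in counts}
    return CaiWeights(w=w, reference_size=len(reference_genes))


def cai_score(gene: GeneRecord, weights: CaiWeights, genetic_code_id: int = 11) -> float:
    """Geometric mean of weights over the gene's scorable codons.

    The stop codon and single-codon families (ATG, TGG in table 11) are
    excluded, the standard convention.  Computed in log space.
    """
    fam = codon_family(genetic_code_id)
    body = gene.cds[:-3] if gene.stop_codon != "ABSENT" else gene.cds
    logs = [
        math.log(weights.w[c])
        for c in iter_codons(body)
        if c in fam and len(fam[c]) > 1
    ]
    if not logs:
        raise ValueError(f"gene {gene.gene_id!r} has no scorable codons")
    return math.exp(sum(logs) / len(logs))


def classify_heg_by_cai(
    dataset: GenomeDataset,
    quantile: float = 0.95,
    weights: CaiWeights | None = None,
) -> GenomeDataset:
    """Flag the top (1-quantile) fraction of valid genes by CAI as HEG.

    Without explicit weights the whole valid gene set serves as its own
    reference — a self-referential but common fallback when no curated
    reference (e.g. ribosomal proteins) is available.  Exactly
    round(n*(1-quantile)) genes are flagged; ties break by gene_id.
    """
    valid = [g for g in dataset.genes if g.valid]
    if not valid:
        raise ValueError("no valid genes to classify")
    if weights is None:
        weights = cai_weights(valid, dataset.genetic_code_id)
    scored = sorted(
        ((cai_score(g, weights, dataset.genetic_code_id), g) for g in valid),
        key=lambda t: (-t[0], t[1].gene_id),
    )
    k = len(valid) if quantile <= 0 else int(round(len(valid) * (1 - quantile)))
    top = {g.gene_id for _, g in scored[:k]}
    for g in dataset.genes:
        g.is_heg = g.gene_id in top
    return dataset


def cai_table(dataset: GenomeDataset, weights: CaiWeights) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g.gene_id,
            "cai": cai_score(g, weights, dataset.genetic_code_id),
            "is_heg": g.is_heg,
        }
        for g in dataset.genes
        if g.valid
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cai", "is_heg"])
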