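"""Stop-codon usage tables, GC content and whole-codon usage per gene class.

Gene classes: ALL (every valid gene), HEG (highly expressed genes, flagged
externally or by CAI), LEG (the valid complement of HEG).  Codon labels are
reported in the RNA alphabet; internal sequences stay DNA.
"""

from __future__ import annotations

import decimal
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._genetics import ALL_CODONS, iter_codons, to_rna, RNA_STOPS
from .seqio import Contig, GeneRecord, GenomeDataset

GENE_CLASSES = ("ALL", "HEG", "LEG")


class UndefinedGCError(ValueError):
    pass


def _in_class(gene: GeneRecord, gene_class: str) -> bool:
    if gene_class == "ALL":
        return True
    if gene_class == "HEG":
        return gene.is_heg
    if gene_class == "LEG":
        return not gene.is_heg
    raise ValueError(f"unknown gene class {gene_class!r}")


@dataclass
class StopUsageTable:
    """Counts and frequencies of the three stop codons for one gene class."""

    genome_id: str
    gene_class: str
    counts: dict[str, int]  # RNA labels UAA/UAG/UGA

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float] | None:
        """Relative frequencies, or None for an empty class (not zeros)."""
        t = self.total
        if t == 0:
            return None
        return {c: n / t for c, n in self.counts.items()}


def genome_gc(contigs) -> float:
    """Genome GC fraction over unambiguous bases; N excluded entirely."""
    if isinstance(contigs, Contig):
        contigs = [contigs]
    gc = at = 0
    for contig in contigs:
        c = Counter(contig.sequence)
        gc += c["G"] + c["C"]
        at += c["A"] + c["T"]
    if gc + at == 0:
        raise UndefinedGCError("no unambiguous bases; GC content undefined")
    return gc / (gc + at)


def cds_gc(genes: list[GeneRecord], gene_class: str = "ALL") -> float:
    """GC of concatenated valid CDS of one class (sensitivity companion to genome_gc)."""
    seqs = [g.cds for g in genes if g.valid and _in_class(g, gene_class)]
    if not seqs:
        raise UndefinedGCError(f"no valid genes in class {gene_class}")
    return genome_gc(Contig("_cds", "".join(seqs)))


def count_stop_codons(
    genes: list[GeneRecord], gene_class: str = "ALL", genome_id: str = ""
) -> StopUsageTable:
    """Tally terminal stop codons over the valid genes of one class."""
    counts = {c: 0 for c in RNA_STOPS}
    for g in genes:
        if g.valid and _in_class(g, gene_class):
            counts[to_rna(g.stop_codon)] += 1
    return StopUsageTable(genome_id, gene_class, counts)


def stop_percentages(table, decimals: int = 1) -> dict[str, float]:
    """Percentages (100*freq) rounded half-up to `decimals` places.

    Accepts a StopUsageTable or a raw counts mapping.  Rounding half-up
    happens only here, at the reporting layer; everything upstream keeps
    full precision.
    """
    counts = table.counts if isinstance(table, StopUsageTable) else dict(table)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot form percentages of an empty table")
    q = decimal.Decimal(1).scaleb(-decimals)
    out = {}
    for codon, n in counts.items():
        pct = decimal.Decimal(n) * 100 / decimal.Decimal(total)
        out[codon] = float(pct.quantize(q, rounding=decimal.ROUND_HALF_UP))
    return out


@dataclass
class CodonUsageTable:
    """In-frame triplet counts over whole CDS, stop position included."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        t = self.total
        return {c: (n / t if t else 0.0) for c, n in self.counts.items()}

    def ratio(self, codon_a: str, codon_b: str) -> float:
        """count(a)/count(b), e.g. the AGG:CGC rare-arginine contrast."""
        b = self.counts[codon_b.upper().replace("U", "T")]
        if b == 0:
            raise ZeroDivisionError(f"codon {codon_b} unobserved")
        return self.counts[codon_a.upper().replace("U", "T")] / b

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        return CodonUsageTable({c: self.counts[c] + other.counts[c] for c in ALL_CODONS})


def codon_usage(genes: list[GeneRecord], gene_class: str = "ALL") -> CodonUsageTable:
    """Codon usage over all in-frame positions of the valid genes of a class."""
    counts = Counter()
    for g in genes:
        if g.valid and _in_class(g, gene_class):
            counts.update(iter_codons(g.cds))
    table = CodonUsageTable()
    for c in ALL_CODONS:
        table.counts[c] = counts.get(c, 0)
    return table


@dataclass
class GenomeSummary:
    """One genome's GC and per-class stop usage, the unit of cohort analyses."""

    genome_id: str
    gc: float
    n_genes_all: int
    n_genes_heg: int
    tables: dict[str, StopUsageTable]

    @property
    def uag_fraction_heg(self) -> float | None:
        f = self.tables["HEG"].freqs
        return None if f is None else f["UAG"]

    def stop_freq(self, gene_class: str, codon: str) -> float | None:
        f = self.tables[gene_class].freqs
        return None if f is None else f[codon]


def summarize_genome(dataset: GenomeDataset) -> GenomeSummary:
    tables = {
        cls: count_stop_codons(dataset.genes, cls, dataset.genome_id)
        for cls in GENE_CLASSES
    }
    valid = [g for g in dataset.genes if g.valid]
    return GenomeSummary(
        genome_id=dataset.genome_id,
        gc=genome_gc(list(dataset.contigs.values())),
        n_genes_all=len(valid),
        n_genes_heg=sum(g.is_heg for g in valid),
        tables=tables,
    )


def stop_usage_frame(summaries: list[GenomeSummary]) -> pd.DataFrame:
    """Long-format stop usage table, one row per genome x gene class."""
    rows = []
    for s in summaries:
        for cls in GENE_CLASSES:
            t = s.tables[cls]
            f = t.freqs
            rows.append(
                {
                    "genome_id": s.genome_id,
                    "gene_class": cls,
                    "UAA_count": t.counts["UAA"],
                    "UAG_count": t.counts["UAG"],
                    "UGA_count": t.counts["UGA"],
                    "total": t.total,
                    "UAA_freq": f["UAA"] if f else float("nan"),
                    "UAG_freq": f["UAG"] if f else float("nan"),
                    "UGA_freq": f["UGA"] if f else float("nan"),
                    "gc": s.gc,
                }
            )
    return pd.DataFrame(rows)
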