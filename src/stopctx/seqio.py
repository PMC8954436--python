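"""Genome/annotation input and strand-aware CDS + 3' context extraction.

Coordinates are GFF3-style throughout: 1-based, inclusive on both ends.
The stop codon occupies positions +1..+3 of the termination window and the
first downstream base is +4; ``GeneRecord.downstream`` starts at +4 in the
gene-sense orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator

from ._genetics import clean_sequence, revcomp, stop_codons

log = logging.getLogger(__name__)

ABSENT = "ABSENT"

#: Default downstream window: 10 codons past the stop, enough for the
#: extended preference scan.
DEFAULT_CONTEXT_LEN = 30


class FastaFormatError(ValueError):
    pass


class GffFormatError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass
class Contig:
    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"contig {self.contig_id!r} has empty sequence")
        self.sequence = clean_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds: str
    stop_codon: str  # TAA/TAG/TGA or ABSENT (DNA alphabet internally)
    downstream: str
    is_heg: bool = False
    valid: bool = False
    reason: str = "ok"
    downstream_overlaps_cds: bool = False


@dataclass
class GenomeDataset:
    genome_id: str
    contigs: dict[str, Contig]
    genes: list[GeneRecord] = field(default_factory=list)
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene_ids in genome {self.genome_id!r}")
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise ValueError(
                    f"gene {g.gene_id!r} references unknown contig {g.contig_id!r}"
                )


def read_fasta(path, circular: bool = False) -> list[Contig]:
    """Read a (multi-)FASTA file into Contig records.

    The contig_id is the header token before the first whitespace; lowercase
    sequence is accepted and uppercased; non-ACGT IUPAC codes fold to N.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate contig_id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, str(rec.seq), circular=circular))
    if not contigs:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return contigs


@dataclass(frozen=True)
class CdsFeature:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str


def read_gff_cds(path, contigs) -> tuple[list[CdsFeature], dict[str, str]]:
    """Collect single-segment CDS features from a GFF3 file.

    Returns ``(features, rejected)`` where *rejected* maps gene_id -> reason.
    Multi-segment CDS (the same ID on several rows) are rejected: the scope
    is prokaryotic, unspliced coding sequences.  Gene ids come from the
    ``ID=`` attribute, falling back to ``locus_tag=``.
    """
    known = {c.contig_id for c in contigs} if not isinstance(contigs, dict) else set(contigs)
    rows: dict[str, list[CdsFeature]] = {}
    rejected: dict[str, str] = {}
    unknown_contigs: list[str] = []
    anon = 0
    for feat in DataIterator(str(path)):
        if feat.featuretype != "CDS":
            continue
        if feat.start is None or feat.end is None or feat.start > feat.end:
            raise GffFormatError(f"CDS with start > end at {feat.seqid}:{feat.start}-{feat.end}")
        attrs = feat.attributes
        if "ID" in attrs:
            gid = attrs["ID"][0]
        elif "locus_tag" in attrs:
            gid = attrs["locus_tag"][0]
        else:
            anon += 1
            gid = f"__anon{anon}"
            rejected[gid] = "no_id"
            continue
        if feat.seqid not in known:
            unknown_contigs.append(gid)
            continue
        if feat.strand not in {"+", "-"}:
            rejected[gid] = "no_strand"
            continue
        if feat.frame not in (".", "0", None):
            log.warning("CDS %s has nonzero phase %s; treated as phase 0", gid, feat.frame)
        rows.setdefault(gid, []).append(
            CdsFeature(gid, feat.seqid, int(feat.start), int(feat.end), feat.strand)
        )
    if unknown_contigs:
        raise GffFormatError(
            "CDS features reference unknown contigs: " + ", ".join(sorted(unknown_contigs))
        )
    features: list[CdsFeature] = []
    for gid, segs in rows.items():
        if len(segs) > 1:
            rejected[gid] = "multi-segment"
            log.warning("CDS %s rejected: multi-segment (%d rows)", gid, len(segs))
        else:
            features.append(segs[0])
    return features, rejected


def extract_cds_and_context(
    contig: Contig, start: int, end: int, strand: str,
    context_len: int = DEFAULT_CONTEXT_LEN,
) -> tuple[str, str]:
    """Extract the gene-sense CDS and its 3' downstream context.

    On the + strand the downstream window is the ``context_len`` bases after
    *end*; on the - strand it is the reverse complement of the bases before
    *start*.  Circular contigs wrap; linear contigs truncate at the edge, so
    the returned downstream may be shorter than ``context_len``.
    """
    seq = contig.sequence
    L = len(seq)
    if not (1 <= start <= end <= L):
        raise CoordinateError(
            f"coordinates {start}-{end} out of range for contig "
            f"{contig.contig_id!r} (length {L})"
        )
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    cds_fwd = seq[start - 1 : end]
    # On a circular contig the window wraps but never re-reads past one turn.
    eff_len = min(context_len, L) if contig.circular else context_len
    if strand == "+":
        if contig.circular:
            ds = "".join(seq[(end + i) % L] for i in range(eff_len))
        else:
            ds = seq[end : end + eff_len]
        return cds_fwd, ds
    if contig.circular:
        window = "".join(seq[(start - 1 - eff_len + i) % L] for i in range(eff_len))
    else:
        window = seq[max(0, start - 1 - eff_len) : start - 1]
    return revcomp(cds_fwd), revcomp(window)


def validate_cds(cds: str, genetic_code_id: int = 11) -> tuple[bool, str, str]:
    """Classify a CDS as valid/invalid for stop-codon statistics.

    Returns ``(valid, reason, stop_codon_or_ABSENT)`` with reason in
    {ok, length, internal_stop, no_stop, ambiguous}.  Validation is total:
    every input yields exactly one verdict, never an exception.
    """
    stops = set(stop_codons(genetic_code_id))
    if len(cds) < 6 or len(cds) % 3 != 0:
        return False, "length", ABSENT
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in stops:
            return False, "internal_stop", ABSENT
    last = cds[-3:]
    if "N" in last:
        return False, "ambiguous", ABSENT
    if last not in stops:
        return False, "no_stop", ABSENT
    return True, "ok", last


def _downstream_interval(feat: CdsFeature, context_len: int, L: int, circular: bool):
    """Genomic (start, end) 1-based intervals covered by the downstream window."""
    if feat.strand == "+":
        lo, hi = feat.end + 1, feat.end + context_len
    else:
        lo, hi = feat.start - context_len, feat.start - 1
    if circular:
        lo = (lo - 1) % L + 1
        hi = (hi - 1) % L + 1
        if lo <= hi:
            return [(lo, hi)]
        return [(lo, L), (1, hi)]
    return [(max(1, lo), min(L, hi))]


def assemble_dataset(
    genome_id: str,
    contigs: list[Contig],
    features: list[CdsFeature],
    context_len: int = DEFAULT_CONTEXT_LEN,
    genetic_code_id: int = 11,
) -> GenomeDataset:
    """Build a GenomeDataset: extract, validate and flag every CDS feature.

    Genes whose downstream window overlaps another annotated CDS are kept
    (flagged via ``downstream_overlaps_cds``) so callers can filter
    optionally.
    """
    cmap = {c.contig_id: c for c in contigs}
    by_contig: dict[str, list[CdsFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig_id, []).append(f)
    genes: list[GeneRecord] = []
    for f in features:
        contig = cmap[f.contig_id]
        cds, ds = extract_cds_and_context(contig, f.start, f.end, f.strand, context_len)
        valid, reason, stop = validate_cds(cds, genetic_code_id)
        ivs = _downstream_interval(f, context_len, len(contig), contig.circular)
        overlap = any(
            o is not f and iv[0] <= o.end and o.start <= iv[1]
            for o in by_contig[f.contig_id]
            for iv in ivs
        )
        genes.append(
            GeneRecord(
                gene_id=f.gene_id,
                genome_id=genome_id,
                contig_id=f.contig_id,
                start=f.start,
                end=f.end,
                strand=f.strand,
                cds=cds,
                stop_codon=stop,
                downstream=ds,
                valid=valid,
                reason=reason,
                downstream_overlaps_cds=overlap,
            )
        )
    return GenomeDataset(genome_id, cmap, genes, genetic_code_id)


def load_genome(
    fasta_path,
    gff_path,
    genome_id: str | None = None,
    circular: bool = False,
    context_len: int = DEFAULT_CONTEXT_LEN,
    genetic_code_id: int = 11,
) -> GenomeDataset:
    """Convenience loader: FASTA + GFF3 -> GenomeDataset."""
    contigs = read_fasta(fasta_path, circular=circular)
    features, rejected = read_gff_cds(gff_path, contigs)
    if rejected:
        log.info("%d CDS rejected at GFF stage: %s", len(rejected), rejected)
    gid = genome_id if genome_id is not None else contigs[0].contig_id
    return assemble_dataset(gid, contigs, features, context_len, genetic_code_id)


def qc_table(dataset: GenomeDataset) -> pd.DataFrame:
    """Per-gene QC table (TSV-ready)."""
    from ._genetics import to_rna

    rows = [
        {
            "gene_id": g.gene_id,
            "valid": g.valid,
            "reason": g.reason,
            "stop_codon": to_rna(g.stop_codon) if g.stop_codon != ABSENT else ABSENT,
            "context_len_obtained": len(g.downstream),
            "overlap_flag": g.downstream_overlaps_cds,
        }
        for g in dataset.genes
    ]
    return pd.DataFrame(rows, columns=[
        "gene_id", "valid", "reason", "stop_codon",
        "context_len_obtained", "overlap_flag",
    ])
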