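"""3' stop-codon context statistics.

Position convention (the main off-by-three hazard, stated once and used
everywhere): the stop codon occupies positions +1..+3, the first downstream
base is +4, and "+456" denotes the first full downstream codon.  A gene's
``downstream`` string therefore starts at +4, so downstream index ``i``
(0-based) is genomic position ``+4 + i``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._genetics import ALL_CODONS, BASES, DNA_STOPS, to_rna
from .codonstats import GenomeSummary, _in_class
from .seqio import GeneRecord

#: Chance expectation for any particular downstream codon (Fig-3-style
#: reports render this as 2% at integer rounding).
CHANCE_EXPECTATION = 1 / 64

RNA_BASES = ("A", "C", "G", "U")


def gc_bin(gc: float, low: float = 0.40, high: float = 0.60) -> str:
    """GC stratum: LOW < 40%, MID = [40%, 60%], HIGH > 60%.

    Boundary genomes fall in MID so the three bins partition [0, 1].
    """
    if not 0 <= gc <= 1:
        raise ValueError(f"gc must be a fraction in [0,1], got {gc}")
    if gc < low:
        return "LOW"
    if gc <= high:
        return "MID"
    return "HIGH"


@dataclass
class ContextProfile:
    """Per-position downstream nucleotide frequencies for one stratum."""

    stratum: tuple
    position: int  # genomic offset, +4 onward
    freq: dict[str, float]  # RNA alphabet
    n: int


def position_profile(genes: list[GeneRecord], position: int, stratum=()) -> ContextProfile | None:
    """Nucleotide frequencies at one downstream position (+4 onward).

    Genes whose context truncates before the position, or carry N there,
    do not contribute.  Returns None when no gene contributes.
    """
    if position < 4:
        raise ValueError("downstream positions start at +4")
    i = position - 4
    counts = Counter(
        g.downstream[i] for g in genes if len(g.downstream) > i and g.downstream[i] in BASES
    )
    n = sum(counts.values())
    if n == 0:
        return None
    return ContextProfile(
        stratum=stratum,
        position=position,
        freq={to_rna(b): counts[b] / n for b in BASES},
        n=n,
    )


def plus4_profile(genes: list[GeneRecord], stratum=()) -> ContextProfile | None:
    """The +4 (first downstream) nucleotide distribution."""
    return position_profile(genes, 4, stratum)


def context_profiles(
    genes: list[GeneRecord], positions=range(4, 34), stratum=()
) -> list[ContextProfile]:
    out = []
    for pos in positions:
        p = position_profile(genes, pos, stratum)
        if p is not None:
            out.append(p)
    return out


@dataclass
class DownstreamCodonTable:
    """Distribution of the first downstream (+4..+6) codon for one stratum."""

    stratum: tuple
    counts: dict[str, int]  # DNA keys, all 64 codons
    n: int
    chance_expectation: float = CHANCE_EXPECTATION

    @property
    def freqs(self) -> dict[str, float]:
        return {c: (v / self.n if self.n else 0.0) for c, v in self.counts.items()}

    @property
    def codons_at_or_above_chance(self) -> list[str]:
        """RNA labels of codons at or above 1/64, most frequent first."""
        f = self.freqs
        hits = [(c, x) for c, x in f.items() if x >= self.chance_expectation]
        hits.sort(key=lambda t: (-t[1], t[0]))
        return [to_rna(c) for c, _ in hits]

    @property
    def unn_fraction(self) -> float:
        """Aggregate frequency of UNN triplets (first downstream base U)."""
        if self.n == 0:
            return 0.0
        return sum(v for c, v in self.counts.items() if c[0] == "T") / self.n


def first_downstream_codon(gene: GeneRecord) -> str | None:
    """The +4..+6 triplet, or None if truncated or ambiguous."""
    t = gene.downstream[:3]
    if len(t) < 3 or "N" in t:
        return None
    return t


def downstream_codon_freq(genes: list[GeneRecord], stratum=()) -> DownstreamCodonTable:
    """Count the +4..+6 codon across genes with >=3 unambiguous downstream bases."""
    counts = {c: 0 for c in ALL_CODONS}
    n = 0
    for g in genes:
        t = first_downstream_codon(g)
        if t is not None:
            counts[t] += 1
            n += 1
    return DownstreamCodonTable(stratum, counts, n)


@dataclass
class TandemStopResult:
    stratum: tuple
    fraction: float
    n: int
    by_primary_stop: dict[str, float]  # RNA primary stop -> tandem fraction
    by_primary_n: dict[str, int]


def tandem_stop_fraction(genes: list[GeneRecord], stratum=()) -> TandemStopResult:
    """Fraction of genes with a second in-frame stop at +4..+6.

    The breakdown by primary stop identity makes the amber-followed-by-stop
    pattern (as in E. coli atpE and sucB) directly visible.
    """
    tandem = {s: 0 for s in DNA_STOPS}
    totals = {s: 0 for s in DNA_STOPS}
    for g in genes:
        t = first_downstream_codon(g)
        if t is None or g.stop_codon not in totals:
            continue
        totals[g.stop_codon] += 1
        if t in DNA_STOPS:
            tandem[g.stop_codon] += 1
    n = sum(totals.values())
    frac = sum(tandem.values()) / n if n else 0.0
    return TandemStopResult(
        stratum=stratum,
        fraction=frac,
        n=n,
        by_primary_stop={
            to_rna(s): (tandem[s] / totals[s] if totals[s] else float("nan"))
            for s in DNA_STOPS
        },
        by_primary_n={to_rna(s): totals[s] for s in DNA_STOPS},
    )


def extended_preference_scan(
    genes: list[GeneRecord],
    stratum=(),
    n_codons: int = 10,
    threshold: float = 0.15,
) -> pd.DataFrame:
    """Per-position preference over the first ``n_codons`` downstream codons.

    The preference statistic is the maximum base frequency minus the uniform
    expectation 0.25; a position is flagged "preferred" when it exceeds
    ``threshold``.  Genes with truncated context contribute to the leading
    positions they cover.
    """
    rows = []
    for slot in range(1, n_codons + 1):
        for k in range(3):
            pos = 4 + 3 * (slot - 1) + k
            p = position_profile(genes, pos, stratum)
            if p is None:
                continue
            top = max(p.freq, key=lambda b: (p.freq[b], b))
            pref = p.freq[top] - 0.25
            rows.append(
                {
                    "slot": slot,
                    "position": pos,
                    **{b: p.freq[b] for b in RNA_BASES},
                    "n": p.n,
                    "top_base": top,
                    "preference": pref,
                    "preferred": pref > threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["slot", "position", *RNA_BASES, "n", "top_base", "preference", "preferred"],
    )


def uag_heg_screen(summaries: list[GenomeSummary], threshold: float = 0.15) -> list[str]:
    """Genomes whose HEG UAG fraction strictly exceeds ``threshold``.

    Sorted by descending fraction (ties by genome_id).  Genomes with an
    empty HEG class are skipped.
    """
    hits = []
    for s in summaries:
        f = s.uag_fraction_heg
        if f is not None and f > threshold:
            hits.append((s.genome_id, f))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in hits]


def select_stratum(
    genes: list[GeneRecord],
    gene_class: str = "ALL",
    stop: str | None = None,
    min_downstream: int = 0,
) -> list[GeneRecord]:
    """Filter valid genes by class and (optionally) primary stop codon.

    ``stop`` accepts RNA or DNA spelling.
    """
    want = stop.replace("U", "T") if stop else None
    return [
        g
        for g in genes
        if g.valid
        and _in_class(g, gene_class)
        and (want is None or g.stop_codon == want)
        and len(g.downstream) >= min_downstream
    ]
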