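"""Cohort-level orchestration: load data, run every stage, emit TSV tables.

This is the library behind the command line: each function takes loaded
``GenomeDataset`` objects and returns pandas DataFrames shaped like the
published tables (stop usage, +4 profiles by GC bin, downstream codons vs
the 1/64 chance line, tandem stops, the extended preference scan, the
UAG-rich genome screen, GC correlations and +4 letter groups).  All codon
and base labels in the emitted tables use the RNA alphabet.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ._genetics import RNA_STOPS, to_rna
from . import codonstats, context, stats
from .codonstats import GenomeSummary, summarize_genome
from .heg import load_heg_list
from .seqio import GenomeDataset, load_genome, qc_table

log = logging.getLogger(__name__)

GC_BIN_ORDER = ("LOW", "MID", "HIGH")


def load_cohort(data_dir, context_len: int | None = None) -> list[GenomeDataset]:
    """Load a cohort directory written by the simulator (manifest.json layout).

    Each manifest entry names a FASTA, a GFF3 and an optional HEG list;
    ``context_len`` defaults to the manifest's value.
    """
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    ctx = context_len if context_len is not None else manifest.get("context_len", 30)
    datasets = []
    for entry in manifest["genomes"]:
        ds = load_genome(
            data_dir / entry["fasta"],
            data_dir / entry["gff"],
            genome_id=entry["genome_id"],
            circular=entry.get("circular", False),
            context_len=ctx,
        )
        if entry.get("heg_list"):
            load_heg_list(data_dir / entry["heg_list"], ds)
        datasets.append(ds)
    return datasets


def summaries_of(datasets: list[GenomeDataset]) -> list[GenomeSummary]:
    return [summarize_genome(ds) for ds in datasets]


def stop_usage_table(datasets, summaries=None) -> pd.DataFrame:
    summaries = summaries or summaries_of(datasets)
    return codonstats.stop_usage_frame(summaries)


def genome_summary_table(datasets, summaries=None, decimals: int = 1) -> pd.DataFrame:
    """One row per genome: GC, gene counts, per-class UAG percentage."""
    summaries = summaries or summaries_of(datasets)
    rows = []
    for s in summaries:
        row = {
            "genome_id": s.genome_id,
            "gc": s.gc,
            "gc_bin": context.gc_bin(s.gc),
            "n_genes_all": s.n_genes_all,
            "n_genes_heg": s.n_genes_heg,
        }
        for cls in ("ALL", "HEG"):
            t = s.tables[cls]
            if t.total:
                for codon, pct in codonstats.stop_percentages(t, decimals).items():
                    row[f"{cls}_{codon}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def qc_tables(datasets) -> pd.DataFrame:
    frames = []
    for ds in datasets:
        q = qc_table(ds)
        q.insert(0, "genome_id", ds.genome_id)
        frames.append(q)
    return pd.concat(frames, ignore_index=True)


def _strata(datasets, summaries, gene_classes=("ALL", "HEG", "LEG")):
    """Yield (gene_class, gc_bin, stop_rna, genes, genome_id) per genome."""
    for ds, s in zip(datasets, summaries):
        b = context.gc_bin(s.gc)
        for cls in gene_classes:
            for stop in RNA_STOPS:
                genes = context.select_stratum(ds.genes, cls, stop)
                yield cls, b, stop, genes, ds.genome_id


def plus4_table(datasets, summaries=None) -> pd.DataFrame:
    """Per (genome, gene_class, stop) +4..+33 nucleotide profile rows."""
    summaries = summaries or summaries_of(datasets)
    rows = []
    for cls, b, stop, genes, gid in _strata(datasets, summaries):
        for p in context.context_profiles(genes):
            rows.append(
                {
                    "genome_id": gid,
                    "gene_class": cls,
                    "gc_bin": b,
                    "stop_codon": stop,
                    "position": p.position,
                    **p.freq,
                    "n": p.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genome_id", "gene_class", "gc_bin", "stop_codon", "position",
                 "A", "C", "G", "U", "n"],
    )


def _pooled_bins(datasets, summaries, gene_classes=("ALL", "HEG", "LEG")):
    pools: dict[tuple, list] = {}
    for ds, s in zip(datasets, summaries):
        b = context.gc_bin(s.gc)
        for cls in gene_classes:
            pools.setdefault((cls, b), []).extend(
                context.select_stratum(ds.genes, cls)
            )
    return pools


def downstream_codon_table(datasets, summaries=None) -> pd.DataFrame:
    """64-row downstream (+456) codon table per (gene_class, gc_bin) pool."""
    summaries = summaries or summaries_of(datasets)
    rows = []
    for (cls, b), genes in sorted(_pooled_bins(datasets, summaries).items()):
        t = context.downstream_codon_freq(genes, stratum=(cls, b))
        freqs = t.freqs
        above = set(t.codons_at_or_above_chance)
        for codon in sorted(t.counts):
            rna = to_rna(codon)
            rows.append(
                {
                    "gene_class": cls,
                    "gc_bin": b,
                    "codon": rna,
                    "count": t.counts[codon],
                    "freq": freqs[codon],
                    "at_or_above_chance": rna in above,
                    "chance_expectation": t.chance_expectation,
                    "n": t.n,
                    "unn_fraction": t.unn_fraction,
                }
            )
    return pd.DataFrame(rows)


def tandem_table(datasets, summaries=None) -> pd.DataFrame:
    summaries = summaries or summaries_of(datasets)
    rows = []
    for (cls, b), genes in sorted(_pooled_bins(datasets, summaries).items()):
        t = context.tandem_stop_fraction(genes, stratum=(cls, b))
        row = {"gene_class": cls, "gc_bin": b, "tandem_fraction": t.fraction, "n": t.n}
        for s in RNA_STOPS:
            row[f"after_{s}"] = t.by_primary_stop[s]
            row[f"after_{s}_n"] = t.by_primary_n[s]
        rows.append(row)
    return pd.DataFrame(rows)


def extended_scan_table(
    datasets, summaries=None, n_codons: int = 10, threshold: float = 0.15
) -> pd.DataFrame:
    """Extended 10-codon preference scan per (gene_class, gc_bin, stop)."""
    summaries = summaries or summaries_of(datasets)
    pools: dict[tuple, list] = {}
    for ds, s in zip(datasets, summaries):
        b = context.gc_bin(s.gc)
        for cls in ("ALL", "HEG"):
            for stop in RNA_STOPS:
                pools.setdefault((cls, b, stop), []).extend(
                    context.select_stratum(ds.genes, cls, stop)
                )
    frames = []
    for (cls, b, stop), genes in sorted(pools.items()):
        if not genes:
            continue
        df = context.extended_preference_scan(
            genes, stratum=(cls, b, stop), n_codons=n_codons, threshold=threshold
        )
        df.insert(0, "stop_codon", stop)
        df.insert(0, "gc_bin", b)
        df.insert(0, "gene_class", cls)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def uag_screen_table(summaries, threshold: float = 0.15) -> pd.DataFrame:
    hits = context.uag_heg_screen(summaries, threshold)
    frac = {s.genome_id: s.uag_fraction_heg for s in summaries}
    return pd.DataFrame(
        [{"genome_id": g, "heg_uag_fraction": frac[g], "threshold": threshold} for g in hits]
    )


def per_genome_plus4_freqs(datasets, summaries, gene_class: str, stop: str):
    """Rows of per-genome +4 base frequencies for one (class, stop) pair,
    keyed by the genome's GC bin — the observation unit of the group test."""
    out: dict[str, list] = {}
    for ds, s in zip(datasets, summaries):
        genes = context.select_stratum(ds.genes, gene_class, stop)
        p = context.plus4_profile(genes)
        if p is None:
            continue
        out.setdefault(context.gc_bin(s.gc), []).append(p.freq)
    return {b: pd.DataFrame(rows) for b, rows in out.items()}


def grouping_table(
    datasets, summaries=None, alpha: float = 0.01,
    gene_classes=("ALL", "HEG"), welch: bool = False, holm: bool = False,
) -> pd.DataFrame:
    """Compact-letter groups of +4 nucleotides per (class, gc_bin, stop)."""
    summaries = summaries or summaries_of(datasets)
    rows = []
    for cls in gene_classes:
        for stop in RNA_STOPS:
            by_bin = per_genome_plus4_freqs(datasets, summaries, cls, stop)
            for b, df in sorted(by_bin.items()):
                ga = stats.group_nucleotides(
                    df, alpha=alpha, stratum=(cls, b, stop), welch=welch, holm=holm
                )
                if ga is None:
                    continue
                for base in sorted(ga.labels):
                    rows.append(
                        {
                            "gene_class": cls,
                            "gc_bin": b,
                            "stop_codon": stop,
                            "nucleotide": base,
                            "mean_freq": ga.means[base],
                            "letter": ga.labels[base],
                            "n_genomes": len(df),
                        }
                    )
    return pd.DataFrame(rows)


def correlation_table(datasets, summaries=None, gene_classes=("HEG", "ALL")) -> pd.DataFrame:
    summaries = summaries or summaries_of(datasets)
    frames = []
    for cls in gene_classes:
        res = stats.gc_stop_correlation(summaries, cls)
        frames.append(stats.correlation_frame(res, cls))
    return pd.concat(frames, ignore_index=True)


def write_report(datasets, out_dir, alpha: float = 0.01,
                 uag_threshold: float = 0.15, scan_threshold: float = 0.15,
                 decimals: int = 1) -> dict[str, Path]:
    """Run every stage and write the TSV bundle; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = summaries_of(datasets)
    tables = {
        "stop_usage": stop_usage_table(datasets, summaries),
        "genome_summary": genome_summary_table(datasets, summaries, decimals),
        "qc": qc_tables(datasets),
        "plus4_profile": plus4_table(datasets, summaries),
        "downstream_codons": downstream_codon_table(datasets, summaries),
        "tandem_stops": tandem_table(datasets, summaries),
        "extended_scan": extended_scan_table(datasets, summaries, threshold=scan_threshold),
        "uag_screen": uag_screen_table(summaries, uag_threshold),
        "plus4_groups": grouping_table(datasets, summaries, alpha=alpha),
    }
    try:
        tables["correlations"] = correlation_table(datasets, summaries)
    except (ValueError, stats.ZeroVarianceError) as e:
        log.warning("correlation stage skipped: %s", e)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
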