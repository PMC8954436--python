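"""Synthetic prokaryotic genomes with known stop-usage and context truth.

The generator emits FASTA + GFF3 + HEG list + a JSON truth record so that
every downstream statistic has a parameter-recovery test.  It emulates the
structure of a cohort of genomes under translational selection: multinomial
stop choice per gene class (HEG vs LEG), optionally linear-in-GC stop
probabilities (UGA rising and UAA falling with GC), a position +4 base
distribution per stop codon, an i.i.d. or codon-wise downstream model, and
a controllable tandem-stop rate.

Reproducibility: one root seed; the stream for genome *i* is
``numpy.random.default_rng([seed, i])``, so cohorts are reproducible
independent of generation order.

Layout: one contig per genome; genes are placed non-overlapping with the
planted downstream window occupying the spacer next to each gene (after the
gene on +, reverse-complemented before it on -), so re-extraction returns
the planted strings exactly.  Circular contigs are rotated so the origin
falls inside the downstream window of one forward-strand gene, exercising
the wrap-around path of the extractor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._genetics import BASES, DNA_STOPS, revcomp, sense_codons
from .seqio import CdsFeature, Contig, GenomeDataset, assemble_dataset

_SENSE = sense_codons(11)
_SENSE_ARR = np.array(_SENSE)
_GC_PER_CODON = np.array([sum(b in "GC" for b in c) for c in _SENSE], dtype=float)


class SizingError(ValueError):
    pass


@dataclass
class StopModel:
    """Stop-codon probabilities, possibly linear in genome GC.

    ``coeffs`` maps each DNA stop codon to (intercept, slope); the triple
    evaluated at a GC value is clipped at zero and renormalized to sum 1.
    A fixed multinomial is the slope-0 special case.
    """

    coeffs: dict[str, tuple[float, float]]

    @classmethod
    def fixed(cls, p_taa: float, p_tag: float, p_tga: float) -> "StopModel":
        return cls({"TAA": (p_taa, 0.0), "TAG": (p_tag, 0.0), "TGA": (p_tga, 0.0)})

    def probs(self, gc: float) -> np.ndarray:
        p = np.array([max(0.0, a + b * gc) for a, b in (self.coeffs[s] for s in DNA_STOPS)])
        t = p.sum()
        if t <= 0:
            raise ValueError(f"stop model degenerate at gc={gc}")
        return p / t


@dataclass
class DownstreamModel:
    """Model for downstream bases past +4.

    kind="iid": bases are i.i.d. from ``base_probs`` (A,C,G,T order), or
    from the genome background distribution when ``base_probs`` is None;
    the +4 base itself comes from the per-stop ``plus4_dist``.

    kind="codons": each downstream slot is a whole codon drawn from
    ``slot_codon_probs`` (a mapping codon->prob, re-used for every slot, or
    a list of per-slot mappings); the per-stop +4 distribution is ignored
    since the slot-1 codon determines +4.
    """

    kind: str = "iid"
    base_probs: tuple[float, float, float, float] | None = None
    slot_codon_probs: dict[str, float] | list[dict[str, float]] | None = None

    def validate(self, n_slots: int) -> None:
        if self.kind not in {"iid", "codons"}:
            raise ValueError(f"unknown downstream model kind {self.kind!r}")
        if self.kind == "iid" and self.base_probs is not None:
            _check_probs(dict(zip(BASES, self.base_probs)), "downstream base_probs")
        if self.kind == "codons":
            if self.slot_codon_probs is None:
                raise ValueError("codons model needs slot_codon_probs")
            dists = self.slot_codon_probs
            for d in dists if isinstance(dists, list) else [dists]:
                _check_probs(d, "slot codon distribution")


def _check_probs(d: dict, what: str) -> None:
    if abs(sum(d.values()) - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {sum(d.values())!r})")
    if any(v < 0 for v in d.values()):
        raise ValueError(f"{what} has negative entries")


def _default_stop_models() -> dict[str, StopModel]:
    # HEG: strong GC gradient on UAA/UGA, flat scarce UAG — the pattern the
    # cohort figures show.  LEG: the same gradient, attenuated, with UAG at
    # the ~7-8% whole-genome level seen in E. coli.
    return {
        "HEG": StopModel({"TAA": (0.80, -0.60), "TAG": (0.10, 0.0), "TGA": (0.10, 0.60)}),
        "LEG": StopModel({"TAA": (0.85, -0.42), "TAG": (0.08, 0.0), "TGA": (0.07, 0.42)}),
    }


def _default_plus4() -> dict[str, dict[str, float]]:
    # U-dominant +4 after every stop, the nearly universal HEG pattern.
    d = {"A": 0.20, "C": 0.15, "G": 0.15, "T": 0.50}
    return {s: dict(d) for s in DNA_STOPS}


@dataclass
class SimulationConfig:
    """Generative parameters; defaults state a 60-genome GC-gradient cohort
    spanning 30-70% GC with 300 HEG and 300 LEG per genome."""

    seed: int = 0
    n_genomes: int = 60
    genes_per_genome: int = 600
    heg_fraction: float = 0.5
    gc_targets: tuple[float, float] | list[float] = (0.30, 0.70)
    stop_probs: dict[str, StopModel] = field(default_factory=_default_stop_models)
    plus4_dist: dict[str, dict[str, float]] = field(default_factory=_default_plus4)
    downstream_model: DownstreamModel = field(default_factory=DownstreamModel)
    tandem_rate: float = 0.0
    context_len: int = 30
    circular_fraction: float = 0.5
    reverse_strand_fraction: float = 0.5
    gene_length_codons: tuple[int, int] = (60, 300)
    spacer_len: tuple[int, int] = (20, 60)
    max_contig_len: int | None = None

    def validate(self) -> None:
        for name, v in [("heg_fraction", self.heg_fraction),
                        ("tandem_rate", self.tandem_rate),
                        ("circular_fraction", self.circular_fraction),
                        ("reverse_strand_fraction", self.reverse_strand_fraction)]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_genomes < 1 or self.genes_per_genome < 1:
            raise ValueError("need at least one genome and one gene")
        for cls in ("HEG", "LEG"):
            if cls not in self.stop_probs:
                raise ValueError(f"stop_probs missing class {cls}")
        for s, d in self.plus4_dist.items():
            _check_probs(d, f"plus4_dist[{s}]")
        self.downstream_model.validate(self.context_len // 3)
        if isinstance(self.gc_targets, (list, np.ndarray)):
            if len(self.gc_targets) != self.n_genomes:
                raise ValueError("per-genome gc_targets must have n_genomes entries")

    def gc_target(self, genome_index: int) -> float:
        if isinstance(self.gc_targets, (list, np.ndarray)):
            return float(self.gc_targets[genome_index])
        lo, hi = self.gc_targets
        if self.n_genomes == 1:
            return (lo + hi) / 2
        return lo + (hi - lo) * genome_index / (self.n_genomes - 1)


def body_codon_probs(target_gc: float) -> np.ndarray:
    """Sense-codon distribution whose expected GC equals ``target_gc``.

    Codons get product-of-bases probabilities with a single GC dial theta,
    renormalized over the 61 sense codons; theta is solved so that the
    expected per-base GC of a drawn codon matches the target (excluding the
    stop codons skews GC slightly, hence the solve instead of theta=target).
    """

    def expected_gc(theta: float) -> float:
        w = theta ** _GC_PER_CODON * (1 - theta) ** (3 - _GC_PER_CODON)
        w = w / w.sum()
        return float((w * _GC_PER_CODON).sum() / 3)

    if not 0.02 < target_gc < 0.98:
        raise ValueError(f"GC target {target_gc} unreachable for coding sequence")
    theta = brentq(lambda t: expected_gc(t) - target_gc, 1e-6, 1 - 1e-6, xtol=1e-12)
    w = theta ** _GC_PER_CODON * (1 - theta) ** (3 - _GC_PER_CODON)
    return w / w.sum()


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


_BASE_ARR = np.array(list(BASES))


def _draw_bases(rng, n: int, p: np.ndarray) -> str:
    return "".join(_BASE_ARR[rng.choice(4, size=n, p=p)]) if n else ""


def _draw_downstream(rng, cfg: SimulationConfig, stop: str, bg: np.ndarray) -> str:
    m = cfg.downstream_model
    L = cfg.context_len
    if m.kind == "codons":
        dists = m.slot_codon_probs
        n_slots = math.ceil(L / 3)
        out = []
        for slot in range(n_slots):
            d = dists[slot % len(dists)] if isinstance(dists, list) else dists
            codons = sorted(d)
            probs = np.array([d[c] for c in codons])
            out.append(codons[rng.choice(len(codons), p=probs)])
        return "".join(out)[:L]
    p4d = cfg.plus4_dist[stop]
    p4 = _BASE_ARR[rng.choice(4, p=np.array([p4d[b] for b in BASES]))]
    rest_p = np.asarray(m.base_probs) if m.base_probs is not None else bg
    return p4 + _draw_bases(rng, L - 1, rest_p)


def simulate_genome(cfg: SimulationConfig, genome_index: int) -> tuple[GenomeDataset, dict]:
    """Generate one genome; returns the (re-extracted) dataset and its truth.

    The returned dataset is produced by running the extractor over the
    generated contig, so it is exactly what an analysis of the emitted
    files would see.  Deterministic for a fixed (seed, genome_index).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, genome_index])
    genome_id = f"synth{genome_index:03d}"
    gc = cfg.gc_target(genome_index)
    body_p = body_codon_probs(gc)
    bg = _base_probs(gc)
    n = cfg.genes_per_genome
    ctx = cfg.context_len

    n_heg = int(round(cfg.heg_fraction * n))
    heg_mask = np.zeros(n, dtype=bool)
    heg_mask[rng.permutation(n)[:n_heg]] = True
    strands = np.where(rng.random(n) < cfg.reverse_strand_fraction, "-", "+")
    lengths = rng.integers(cfg.gene_length_codons[0], cfg.gene_length_codons[1] + 1, size=n)

    # one vectorized draw for every body codon in the genome
    total = int(lengths.sum())
    big = "".join(_SENSE_ARR[rng.choice(len(_SENSE), size=total, p=body_p)])
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    probs_by_class = {
        "HEG": cfg.stop_probs["HEG"].probs(gc),
        "LEG": cfg.stop_probs["LEG"].probs(gc),
    }

    parts: list[str] = []
    cursor = 0

    def emit(s: str) -> None:
        nonlocal cursor
        parts.append(s)
        cursor += len(s)

    emit(_draw_bases(rng, int(rng.integers(*cfg.spacer_len)), bg))
    genes_truth = []
    features = []
    for i in range(n):
        cls = "HEG" if heg_mask[i] else "LEG"
        stop = DNA_STOPS[rng.choice(3, p=probs_by_class[cls])]
        body = big[3 * offsets[i] : 3 * offsets[i + 1]]
        cds = "ATG" + body + stop
        ds = _draw_downstream(rng, cfg, stop, bg)
        tandem = bool(rng.random() < cfg.tandem_rate)
        if tandem:
            ds = DNA_STOPS[rng.choice(3)] + ds[3:]
        strand = str(strands[i])
        if strand == "-":
            emit(revcomp(ds))
        start = cursor + 1
        emit(cds if strand == "+" else revcomp(cds))
        end = cursor
        if strand == "+":
            emit(ds)
        emit(_draw_bases(rng, int(rng.integers(*cfg.spacer_len)), bg))
        gid = f"{genome_id}_g{i:04d}"
        genes_truth.append(
            {
                "gene_id": gid,
                "gene_class": cls,
                "strand": strand,
                "start": start,
                "end": end,
                "stop_codon": stop,
                "plus4": ds[0],
                "downstream": ds,
                "tandem": tandem,
            }
        )
        features.append(CdsFeature(gid, genome_id, start, end, strand))

    seq = "".join(parts)
    circular = bool(rng.random() < cfg.circular_fraction)
    rotation = 0
    if circular:
        plus_idx = [i for i in range(n) if genes_truth[i]["strand"] == "+"]
        if plus_idx:
            j = int(plus_idx[rng.choice(len(plus_idx))])
            k = int(rng.integers(1, ctx))  # origin inside gene j's downstream
            rotation = genes_truth[j]["end"] + k
            seq = seq[rotation:] + seq[:rotation]
            L = len(seq)
            for t, f in zip(genes_truth, list(features)):
                ns = t["start"] - rotation
                ne = t["end"] - rotation
                ns += L if ns < 1 else 0
                ne += L if ne < 1 else 0
                t["start"], t["end"] = ns, ne
            features = [
                CdsFeature(t["gene_id"], genome_id, t["start"], t["end"], t["strand"])
                for t in genes_truth
            ]
    if cfg.max_contig_len is not None and len(seq) > cfg.max_contig_len:
        raise SizingError(
            f"genome {genome_id}: {n} genes need {len(seq)} nt "
            f"> max_contig_len {cfg.max_contig_len}"
        )

    contig = Contig(genome_id, seq, circular=circular)
    dataset = assemble_dataset(genome_id, [contig], features, context_len=ctx)
    heg_ids = {t["gene_id"] for t, h in zip(genes_truth, heg_mask) if h}
    for g in dataset.genes:
        g.is_heg = g.gene_id in heg_ids

    from .codonstats import genome_gc  # avoid import cycle at module load

    truth = {
        "genome_id": genome_id,
        "genome_index": genome_index,
        "gc_target": gc,
        "gc_realized": genome_gc(contig),
        "circular": circular,
        "rotation": rotation,
        "contig_len": len(seq),
        "genes": genes_truth,
        "config": _config_echo(cfg),
    }
    return dataset, truth


def _config_echo(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["stop_probs"] = {k: v["coeffs"] for k, v in d["stop_probs"].items()}
    return d


def simulate_cohort(cfg: SimulationConfig) -> list[tuple[GenomeDataset, dict]]:
    """All genomes of the configured cohort, index order."""
    cfg.validate()
    return [simulate_genome(cfg, i) for i in range(cfg.n_genomes)]


def simulate_gc_gradient_cohort(cfg: SimulationConfig) -> list[tuple[GenomeDataset, dict]]:
    """A cohort spanning the configured GC range, evenly spaced.

    Requires a (lo, hi) range and at least 10 genomes so the gradient is
    identifiable; realized genome GC lands within 0.02 of each target.
    """
    if isinstance(cfg.gc_targets, (list, np.ndarray)):
        raise ValueError("gradient cohort needs a (lo, hi) gc range")
    if cfg.n_genomes < 10:
        raise ValueError("gradient cohort needs n_genomes >= 10")
    return simulate_cohort(cfg)


def simulate_null_plus4_strata(
    n_strata: int,
    n_genomes: int = 30,
    genes_per_genome: int = 200,
    seed: int = 0,
    compositional: bool = False,
) -> list:
    """Per-genome +4 frequency tables with NO true nucleotide differences.

    Default null: each nucleotide's per-genome frequency is an independent
    binomial(genes, 1/4) proportion, matching the independence assumption
    of the pairwise t-tests this null calibrates.  ``compositional=True``
    instead draws all four frequencies from one multinomial per genome
    (frequencies then sum to 1 and are negatively correlated, as in real
    +4 data); the pairwise t is mildly anti-conservative on that null —
    see the methods documentation.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 7919])
    out = []
    for _ in range(n_strata):
        if compositional:
            counts = rng.multinomial(genes_per_genome, [0.25] * 4, size=n_genomes)
        else:
            counts = rng.binomial(genes_per_genome, 0.25, size=(n_genomes, 4))
        out.append(pd.DataFrame(counts / genes_per_genome, columns=["A", "C", "G", "U"]))
    return out


# ---------------------------------------------------------------------------
# file emission

def write_genome(dataset: GenomeDataset, truth: dict, outdir) -> dict:
    """Write FASTA, GFF3, HEG list and truth JSON for one genome.

    Returns a manifest entry with the relative file names.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = dataset.genome_id
    fasta = outdir / f"{gid}.fna"
    gff = outdir / f"{gid}.gff3"
    heg = outdir / f"{gid}.heg.txt"
    tjson = outdir / f"{gid}.truth.json"
    with open(fasta, "w") as fh:
        for c in dataset.contigs.values():
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in dataset.genes:
            fh.write(
                f"{g.contig_id}\tstopctx_sim\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )
    with open(heg, "w") as fh:
        fh.write("# simulated highly expressed genes\n")
        for g in dataset.genes:
            if g.is_heg:
                fh.write(g.gene_id + "\n")
    with open(tjson, "w") as fh:
        json.dump(truth, fh, indent=None)
    circ = next(iter(dataset.contigs.values())).circular
    return {
        "genome_id": gid,
        "fasta": fasta.name,
        "gff": gff.name,
        "heg_list": heg.name,
        "truth": tjson.name,
        "circular": circ,
    }


def write_cohort(cfg: SimulationConfig, outdir) -> Path:
    """Simulate and write a whole cohort plus a manifest.json; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for dataset, truth in simulate_cohort(cfg):
        entries.append(write_genome(dataset, truth, outdir))
    manifest = {"context_len": cfg.context_len, "genomes": entries}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
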