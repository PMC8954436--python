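"""Downstream-context statistics: +4 profiles, +456 codons, tandem stops."""

import math

import numpy as np
import pytest

from stopctx.codonstats import GenomeSummary, StopUsageTable
from stopctx.context import (
    CHANCE_EXPECTATION,
    downstream_codon_freq,
    extended_preference_scan,
    gc_bin,
    plus4_profile,
    select_stratum,
    tandem_stop_fraction,
    uag_heg_screen,
)
from stopctx.seqio import GeneRecord
from stopctx.synthetic_data import (
    DownstreamModel,
    SimulationConfig,
    StopModel,
    simulate_genome,
)


def gene(downstream, stop="TAA", gene_id="g", is_heg=False):
    cds = "ATGAAA" + stop
    return GeneRecord(
        gene_id=gene_id, genome_id="G", contig_id="c", start=1, end=len(cds),
        strand="+", cds=cds, stop_codon=stop, downstream=downstream,
        is_heg=is_heg, valid=True, reason="ok",
    )


# -- GC bins -----------------------------------------------------------------

@pytest.mark.parametrize(
    "gc, b",
    [
        (0.3354, "LOW"),   # S. aureus-like
        (0.5193, "MID"),   # E. coli K-12-like
        (0.6714, "HIGH"),  # P. aeruginosa-like
        (0.40, "MID"), (0.60, "MID"),  # boundaries partition into MID
        (0.0, "LOW"), (1.0, "HIGH"),
    ],
)
def test_gc_bin(gc, b):
    assert gc_bin(gc) == b


def test_gc_bin_rejects_percent_scale():
    with pytest.raises(ValueError):
        gc_bin(51.93)


# -- +4 profile --------------------------------------------------------------

def test_plus4_two_genes():
    p = plus4_profile([gene("TGGG"), gene("AGGG")])
    assert p.freq == {"U": 0.5, "A": 0.5, "C": 0.0, "G": 0.0}
    assert p.n == 2


def test_plus4_unit_mass_n1():
    p = plus4_profile([gene("CAA")])
    assert p.freq["C"] == 1.0 and p.n == 1


def test_plus4_empty_and_ambiguous():
    assert plus4_profile([]) is None
    assert plus4_profile([gene("NAA")]) is None


def test_plus4_planted_recovery():
    """Planted +4 distribution (U .7, A/C/G .1) recovered within 3 SE, n=2000."""
    rng = np.random.default_rng(5)
    bases, probs = ["T", "A", "C", "G"], [0.7, 0.1, 0.1, 0.1]
    genes = [gene(bases[i] + "AA") for i in rng.choice(4, size=2000, p=probs)]
    p = plus4_profile(genes)
    for b_rna, want in zip(["U", "A", "C", "G"], probs):
        se = math.sqrt(want * (1 - want) / 2000)
        assert abs(p.freq[b_rna] - want) <= 3 * se


# -- downstream codon table --------------------------------------------------

def test_chance_expectation_constant():
    assert CHANCE_EXPECTATION == 1 / 64


def test_downstream_codons_all_ttt():
    t = downstream_codon_freq([gene("TTTA"), gene("TTT")])
    assert t.freqs["TTT"] == 1.0
    assert t.unn_fraction == 1.0
    assert t.codons_at_or_above_chance == ["UUU"]


def test_downstream_codons_uniform_within_3se():
    rng = np.random.default_rng(12)
    bases = np.array(list("ACGT"))
    n = 8000
    genes = [gene("".join(bases[rng.integers(0, 4, 3)])) for _ in range(n)]
    t = downstream_codon_freq(genes)
    se = math.sqrt((1 / 64) * (63 / 64) / n)
    for c, f in t.freqs.items():
        assert abs(f - 1 / 64) <= 3 * se + 1e-12, c


def test_downstream_codons_skip_truncated_and_ambiguous():
    t = downstream_codon_freq([gene("TT"), gene("TNT"), gene("GGG")])
    assert t.n == 1 and t.counts["GGG"] == 1


def test_plus4_marginalization_invariant():
    """+4 profile equals the first-base marginal of the codon table on the
    subset of genes with a full +456 triplet."""
    rng = np.random.default_rng(21)
    bases = np.array(list("ACGT"))
    genes = [gene("".join(bases[rng.integers(0, 4, 5)])) for _ in range(400)]
    sub = [g for g in genes if len(g.downstream) >= 3]
    t = downstream_codon_freq(sub)
    p = plus4_profile(sub)
    for b, rna in zip("ACGT", "ACGU"):
        marg = sum(v for c, v in t.freqs.items() if c[0] == b)
        assert p.freq[rna] == pytest.approx(marg)


# -- tandem stops ------------------------------------------------------------

def test_tandem_all_taa():
    t = tandem_stop_fraction([gene("TAAG"), gene("TAAC")])
    assert t.fraction == 1.0
    assert t.by_primary_stop["UAA"] == 1.0


def test_tandem_matches_codon_table_stop_mass():
    rng = np.random.default_rng(31)
    bases = np.array(list("ACGT"))
    genes = [gene("".join(bases[rng.integers(0, 4, 3)])) for _ in range(2000)]
    t = tandem_stop_fraction(genes)
    dt = downstream_codon_freq(genes)
    stop_mass = dt.freqs["TAA"] + dt.freqs["TAG"] + dt.freqs["TGA"]
    assert t.fraction == pytest.approx(stop_mass)


def test_tandem_sense_only_downstream_is_zero():
    """A generator cohort whose downstream codons exclude stops yields 0."""
    from stopctx._genetics import sense_codons

    sense = sense_codons(11)
    model = DownstreamModel(kind="codons", slot_codon_probs={c: 1 / 61 for c in sense})
    cfg = SimulationConfig(
        seed=3, n_genomes=1, genes_per_genome=300, gc_targets=[0.5],
        gene_length_codons=(5, 15), tandem_rate=0.0, downstream_model=model,
    )
    ds, _ = simulate_genome(cfg, 0)
    assert tandem_stop_fraction(select_stratum(ds.genes, "ALL")).fraction == 0.0


def test_tandem_planted_rate_recovery():
    """Planted tandem rate 0.10 recovered within 3 binomial SE at n=3000."""
    cfg = SimulationConfig(
        seed=9, n_genomes=1, genes_per_genome=3000, gc_targets=[0.5],
        gene_length_codons=(5, 15), tandem_rate=0.10,
    )
    ds, truth = simulate_genome(cfg, 0)
    t = tandem_stop_fraction(select_stratum(ds.genes, "ALL"))
    # non-tandem genes can still draw a stop triplet by chance; compare to
    # the realized planted fraction instead of the nominal rate alone
    planted = sum(g["tandem"] for g in truth["genes"]) / 3000
    assert abs(planted - 0.10) <= 3 * math.sqrt(0.1 * 0.9 / 3000)
    assert t.fraction >= planted - 1e-12  # chance tandems only add


# -- extended preference scan ------------------------------------------------

def test_scan_uniform_no_preference():
    rng = np.random.default_rng(41)
    bases = np.array(list("ACGT"))
    n = 5000
    genes = [gene("".join(bases[rng.integers(0, 4, 30)])) for _ in range(n)]
    df = extended_preference_scan(genes)
    assert set(df["slot"]) == set(range(1, 11))
    se = math.sqrt(0.25 * 0.75 / n)
    assert (df["preference"].abs() <= 3 * se).all()
    assert not df["preferred"].any()


def test_scan_planted_motif():
    genes = [gene("TTT" + "ACGT" * 7) for _ in range(50)]
    df = extended_preference_scan(genes)
    slot1 = df[df.slot == 1]
    assert (slot1["preference"] == 0.75).all()
    assert (slot1["top_base"] == "U").all()
    assert slot1["preferred"].all()


def test_scan_n1_matches_plus4():
    rng = np.random.default_rng(51)
    bases = np.array(list("ACGT"))
    genes = [gene("".join(bases[rng.integers(0, 4, 6)])) for _ in range(300)]
    df = extended_preference_scan(genes, n_codons=1)
    p4 = plus4_profile(genes)
    row = df[df.position == 4].iloc[0]
    for b in "ACGU":
        assert row[b] == pytest.approx(p4.freq[b])


# -- UAG screen --------------------------------------------------------------

def summary(gid, heg_counts, gc=0.5):
    t = StopUsageTable(gid, "HEG", heg_counts)
    return GenomeSummary(gid, gc, sum(heg_counts.values()), t.total,
                         {"ALL": t, "HEG": t, "LEG": t})


def test_uag_screen_threshold_strict():
    s_in = summary("in", {"UAG": 4, "UAA": 16, "UGA": 5})      # 16% > 15%
    s_out = summary("out", {"UAG": 2, "UAA": 223, "UGA": 30})  # E. coli-like 0.8%
    s_edge = summary("edge", {"UAG": 3, "UAA": 14, "UGA": 3})  # exactly 15%
    assert uag_heg_screen([s_out, s_in, s_edge]) == ["in"]


def test_uag_screen_planted_cohort():
    """Exactly the genomes generated with amber-rich HEG pass the screen."""
    rich = StopModel.fixed(0.6, 0.3, 0.1)
    poor = StopModel.fixed(0.8, 0.05, 0.15)
    summaries, want = [], []
    for i in range(50):
        is_rich = i % 7 == 0  # 8 planted
        cfg = SimulationConfig(
            seed=60 + i, n_genomes=1, genes_per_genome=300, gc_targets=[0.5],
            gene_length_codons=(5, 15), heg_fraction=0.5,
            stop_probs={"HEG": rich if is_rich else poor, "LEG": poor},
        )
        ds, truth = simulate_genome(cfg, 0)
        from stopctx.codonstats import summarize_genome

        s = summarize_genome(ds)
        s.genome_id = f"G{i:02d}"
        summaries.append(s)
        if is_rich:
            want.append(s.genome_id)
    assert sorted(uag_heg_screen(summaries)) == sorted(want)
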