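"""CDS extraction, annotation parsing and validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stopctx.seqio import (
    ABSENT,
    Contig,
    CoordinateError,
    FastaFormatError,
    GffFormatError,
    extract_cds_and_context,
    read_fasta,
    read_gff_cds,
    validate_cds,
)

# -- independent oracles -----------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def circular_slice_oracle(seq: str, positions_1based) -> str:
    """Character-by-character circular indexing."""
    L = len(seq)
    return "".join(seq[(p - 1) % L] for p in positions_1based)


# -- FASTA -------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, contig_id, seq",
    [
        (">c1\nACGT\n", "c1", "ACGT"),
        (">c1\nacg\nt\n", "c1", "ACGT"),  # line wrap + case fold
        (">c1 desc words\nAC\n", "c1", "AC"),  # header tokenization
        (">c1\nACRYSW\n", "c1", "ACNNNN"),  # IUPAC ambiguity folds to N
    ],
)
def test_read_fasta_single(tmp_path, text, contig_id, seq):
    p = tmp_path / "a.fa"
    p.write_text(text)
    (c,) = read_fasta(p)
    assert (c.contig_id, c.sequence) == (contig_id, seq)


def test_read_fasta_errors(tmp_path):
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(FastaFormatError):
        read_fasta(empty)
    dup = tmp_path / "dup.fa"
    dup.write_text(">c1\nAC\n>c1\nGT\n")
    with pytest.raises(FastaFormatError, match="duplicate"):
        read_fasta(dup)


# -- GFF3 --------------------------------------------------------------------

CONTIGS = [Contig("c1", "A" * 50)]


def _gff(tmp_path, body):
    p = tmp_path / "a.gff3"
    p.write_text("##gff-version 3\n" + body)
    return p


def test_gff_basic_row(tmp_path):
    p = _gff(tmp_path, "c1\t.\tCDS\t4\t12\t.\t+\t0\tID=g1\n")
    feats, rejected = read_gff_cds(p, CONTIGS)
    assert not rejected
    f = feats[0]
    assert (f.gene_id, f.contig_id, f.start, f.end, f.strand) == ("g1", "c1", 4, 12, "+")


def test_gff_multisegment_rejected(tmp_path):
    p = _gff(
        tmp_path,
        "c1\t.\tCDS\t4\t12\t.\t+\t0\tID=g2\n"
        "c1\t.\tCDS\t20\t28\t.\t+\t0\tID=g2\n"
        "c1\t.\tCDS\t30\t38\t.\t-\t0\tID=g3\n",
    )
    feats, rejected = read_gff_cds(p, CONTIGS)
    assert rejected == {"g2": "multi-segment"}
    assert [f.gene_id for f in feats] == ["g3"]


def test_gff_locus_tag_fallback(tmp_path):
    p = _gff(tmp_path, "c1\t.\tCDS\t4\t12\t.\t+\t0\tlocus_tag=lt9\n")
    feats, _ = read_gff_cds(p, CONTIGS)
    assert feats[0].gene_id == "lt9"


def test_gff_id_precedence_over_locus_tag(tmp_path):
    p = _gff(tmp_path, "c1\t.\tCDS\t4\t12\t.\t+\t0\tID=gid;locus_tag=lt\n")
    feats, _ = read_gff_cds(p, CONTIGS)
    assert feats[0].gene_id == "gid"


def test_gff_unknown_contig_error(tmp_path):
    p = _gff(tmp_path, "cX\t.\tCDS\t4\t12\t.\t+\t0\tID=g1\n")
    with pytest.raises(GffFormatError, match="g1"):
        read_gff_cds(p, CONTIGS)


def test_gff_start_after_end_error(tmp_path):
    p = _gff(tmp_path, "c1\t.\tCDS\t12\t4\t.\t+\t0\tID=g1\n")
    with pytest.raises(GffFormatError):
        read_gff_cds(p, CONTIGS)


# -- extraction --------------------------------------------------------------

def test_extract_plus_strand_linear():
    c = Contig("c", "AAATGACCCTAAGTTT")
    cds, ds = extract_cds_and_context(c, 3, 12, "+", context_len=4)
    assert cds == "ATGACCCTAA"
    assert ds == "GTTT"


def test_extract_minus_strand_truncates_at_edge():
    c = Contig("c", "AAATGACCCTAAGTTT")
    cds, ds = extract_cds_and_context(c, 3, 12, "-", context_len=4)
    assert cds == revcomp_oracle("ATGACCCTAA") == "TTAGGGTCAT"
    # upstream window start-4..start-1 truncates to positions 1..2 ("AA")
    assert ds == revcomp_oracle("AA") == "TT"


def test_extract_circular_wraps():
    c = Contig("c", "TAAAC", circular=True)
    cds, ds = extract_cds_and_context(c, 1, 3, "+", context_len=4)
    assert cds == "TAA"
    assert ds == circular_slice_oracle(c.sequence, [4, 5, 6, 7]) == "ACTA"


def test_extract_out_of_range():
    c = Contig("c", "ACGTACGT")
    with pytest.raises(CoordinateError):
        extract_cds_and_context(c, 5, 9, "+")


def test_extract_random_placements_roundtrip():
    """Planting a CDS+context at random and re-extracting returns it exactly,
    on both strands, linear and circular: 1000 placements."""
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        L = int(rng.integers(60, 200))
        seq = "".join(bases[rng.integers(0, 4, size=L)])
        glen = int(rng.integers(2, 10)) * 3
        ctx = int(rng.integers(0, 12))
        circular = bool(rng.integers(0, 2))
        strand = "+-"[rng.integers(0, 2)]
        start = int(rng.integers(1, L - glen + 2))
        end = start + glen - 1
        c = Contig("c", seq, circular=circular)
        cds, ds = extract_cds_and_context(c, start, end, strand, ctx)
        if strand == "+":
            want_cds = seq[start - 1 : end]
            want_ds_pos = range(end + 1, end + 1 + ctx)
        else:
            want_cds = revcomp_oracle(seq[start - 1 : end])
            want_ds_pos = range(start - ctx, start)
        if circular:
            want_ds = circular_slice_oracle(seq, want_ds_pos)
        else:
            want_ds = "".join(seq[p - 1] for p in want_ds_pos if 1 <= p <= L)
        if strand == "-":
            want_ds = revcomp_oracle(want_ds)
        assert cds == want_cds
        assert ds == want_ds


def test_strand_symmetry():
    """Reverse-complementing the contig and mirroring coordinates leaves
    cds and downstream unchanged."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for circular in (False, True):
        L = 300
        seq = "".join(bases[rng.integers(0, 4, size=L)])
        c = Contig("c", seq, circular=circular)
        c_rc = Contig("c_rc", revcomp_oracle(seq), circular=circular)
        for _ in range(50):
            glen = int(rng.integers(2, 20)) * 3
            start = int(rng.integers(1, L - glen + 2))
            end = start + glen - 1
            strand = "+-"[rng.integers(0, 2)]
            mirrored = (L - end + 1, L - start + 1, "-" if strand == "+" else "+")
            assert extract_cds_and_context(c, start, end, strand, 11) == \
                extract_cds_and_context(c_rc, *mirrored, 11)


# -- validation --------------------------------------------------------------

@pytest.mark.parametrize(
    "cds, valid, reason, stop",
    [
        ("ATGTAA", True, "ok", "TAA"),
        ("ATGAAATAG", True, "ok", "TAG"),
        ("ATGTGAAAATAA", False, "internal_stop", ABSENT),
        ("ATGAAA", False, "no_stop", ABSENT),
        ("ATGTA", False, "length", ABSENT),
        ("TAA", False, "length", ABSENT),
        ("ATGAAATAAA", False, "length", ABSENT),  # not divisible by 3
        ("ATGAAATNA", False, "ambiguous", ABSENT),
        ("ATGNNNTGA", True, "ok", "TGA"),  # internal N is not a stop
    ],
)
def test_validate_cds(cds, valid, reason, stop):
    assert validate_cds(cds) == (valid, reason, stop)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=30))
def test_validation_total(cds):
    """Every CDS yields exactly one verdict; valid implies the invariants."""
    valid, reason, stop = validate_cds(cds)
    assert reason in {"ok", "length", "internal_stop", "no_stop", "ambiguous"}
    assert valid == (reason == "ok")
    if valid:
        assert len(cds) % 3 == 0 and len(cds) >= 6
        assert cds[-3:] == stop and stop in {"TAA", "TAG", "TGA"}
    else:
        assert stop == ABSENT
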