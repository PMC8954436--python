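"""Statistical layer: GC/stop-frequency correlations and +4 group tests.

Two conventions are fixed here.  The correlation is the plain Pearson
product-moment coefficient with the usual t-transform p-value (n-2 df).
The group test is a pooled-variance (Student, not Welch) two-sample t-test
at a bare alpha with no multiple-testing correction by default; Welch and
Holm variants are available behind flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._genetics import RNA_STOPS

log = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Raised when a correlation is undefined because an input is constant."""


@dataclass
class CorrelationResult:
    stop_codon: str
    r: float
    n: int
    p_value: float


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: constant input vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def gc_stop_correlation(
    summaries, gene_class: str = "HEG"
) -> dict[str, CorrelationResult]:
    """Correlate each stop codon's class-level frequency with genome GC.

    Genomes with an empty class are dropped.  Defaults to HEG, the class
    shown in cohort-level figures; pass "ALL" or "LEG" for the others.
    """
    pts = [
        (s.gc, s.tables[gene_class].freqs)
        for s in summaries
        if s.tables[gene_class].freqs is not None
    ]
    if len(pts) < 3:
        raise ValueError(f"need >=3 genomes with non-empty {gene_class} class")
    gc = [p[0] for p in pts]
    out = {}
    for codon in RNA_STOPS:
        freqs = [p[1][codon] for p in pts]
        r, p = pearson(gc, freqs)
        out[codon] = CorrelationResult(codon, r, len(pts), p)
    return out


def student_t(sample_a, sample_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-sided t-test, pooled variance by default.

    Degenerate conventions: both samples constant with equal means -> (0, 1);
    zero pooled variance with unequal means -> (signed inf, 0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupAssignment:
    """Compact-letter display over the four +4 nucleotides in one stratum.

    Nucleotides share a letter iff every pair inside that letter is
    non-significant; a pair sharing no letter tested significant.
    """

    stratum: tuple
    labels: dict[str, str]
    means: dict[str, float]
    p_values: dict[tuple[str, str], float]

    @property
    def n_groups(self) -> int:
        return len(set("".join(self.labels.values())))


def _holm(pvals: dict, alpha: float) -> dict:
    """Holm step-down adjusted p-values."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[k] = running
    return adj


def group_nucleotides(
    per_genome_freqs: pd.DataFrame,
    alpha: float = 0.01,
    stratum=(),
    welch: bool = False,
    holm: bool = False,
) -> GroupAssignment | None:
    """Assign compact-letter groups to nucleotides from per-genome frequencies.

    ``per_genome_freqs`` has one row per genome and one column per
    nucleotide (A,C,G,U); the observation unit is the genome, matching
    cohort-level figures.  All six pairwise Student t-tests are run at the
    stated alpha; letters are the maximal mutually-non-significant sets,
    ordered by descending group mean (ties alphabetical), so the
    GroupAssignment invariants hold exactly even when non-significance is
    non-transitive.

    Returns None (with a warning) when fewer than two genomes are present.
    """
    cols = sorted(per_genome_freqs.columns)
    if len(per_genome_freqs) < 2:
        log.warning("stratum %s: <2 genomes, no grouping", stratum)
        return None
    means = {c: float(per_genome_freqs[c].mean()) for c in cols}
    pvals = {}
    for a, b in combinations(cols, 2):
        _, p = student_t(per_genome_freqs[a], per_genome_freqs[b], welch=welch)
        pvals[(a, b)] = p
    if holm:
        pvals = _holm(pvals, alpha)

    def nonsig(a: str, b: str) -> bool:
        return pvals[(a, b) if (a, b) in pvals else (b, a)] >= alpha

    # Maximal cliques of the non-significance graph (4 nodes: enumerate).
    cliques = []
    nodes = cols
    for mask in range(1, 1 << len(nodes)):
        members = [nodes[i] for i in range(len(nodes)) if mask >> i & 1]
        if all(nonsig(a, b) for a, b in combinations(members, 2)):
            cliques.append(set(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    maximal.sort(key=lambda c: (-max(means[m] for m in c), min(c)))
    labels = {c: "" for c in cols}
    for letter, clique in zip("abcdefghij", maximal):
        for m in sorted(clique):
            labels[m] += letter
    return GroupAssignment(stratum=stratum, labels=labels, means=means, p_values=pvals)


def correlation_frame(results: dict[str, CorrelationResult], gene_class: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stop_codon": c,
                "gene_class": gene_class,
                "n": r.n,
                "r": r.r,
                "p": r.p_value,
            }
            for c, r in results.items()
        ]
    )
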