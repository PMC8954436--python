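import json
from pathlib import Path

import pytest

from stopctx.report import load_cohort
from stopctx.synthetic_data import SimulationConfig, write_cohort


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory) -> Path:
    """A 6-genome synthetic cohort spanning the GC gradient, on disk."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(
        seed=424242,
        n_genomes=6,
        genes_per_genome=80,
        gc_targets=(0.30, 0.70),
        gene_length_codons=(30, 80),
        tandem_rate=0.05,
    )
    write_cohort(cfg, out)
    return out


@pytest.fixture(scope="session")
def small_cohort(small_cohort_dir):
    return load_cohort(small_cohort_dir)


@pytest.fixture(scope="session")
def small_cohort_truth(small_cohort_dir):
    truths = []
    for f in sorted(small_cohort_dir.glob("*.truth.json")):
        with open(f) as fh:
            truths.append(json.load(fh))
    return truths
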