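import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mxefold.genome import GeneModelSet, GenomicInterval, Transcript
from mxefold.simulate import SyntheticCohortSpec, emit_cohort


@pytest.fixture(scope="session")
def uni_cohort():
    """Small unidirectional cohort shared across tests (read-only)."""
    return emit_cohort(
        SyntheticCohortSpec(n_positive=8, n_null=8, seed=11)
    )


@pytest.fixture(scope="session")
def bi_cohort():
    return emit_cohort(
        SyntheticCohortSpec(n_positive=8, n_null=8, seed=12,
                            mode="bidirectional")
    )


@pytest.fixture()
def toy_models():
    """Two transcripts sharing flanking exons with distinct middle exons:
    the canonical two-exon MXE topology."""
    mk = lambda s, e: GenomicInterval("chr1", s, e, "+")
    t1 = Transcript("t1", "gA", (mk(100, 200), mk(300, 400), mk(700, 800)))
    t2 = Transcript("t2", "gA", (mk(100, 200), mk(500, 600), mk(700, 800)))
    models = GeneModelSet()
    models.add(t1)
    models.add(t2)
    return models


def random_toy_models(rng: np.random.Generator) -> GeneModelSet:
    """A random small single-gene annotation for oracle comparisons."""
    models = GeneModelSet()
    n_transcripts = int(rng.integers(2, 5))
    for k in range(n_transcripts):
        n_exons = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(np.arange(1, 60), size=2 * n_exons,
                                    replace=False))
        exons = tuple(
            GenomicInterval("chr1", int(bounds[2 * i]), int(bounds[2 * i + 1]),
                            "+")
            for i in range(n_exons)
        )
        models.add(Transcript(f"t{k}", "g", exons))
    return models
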