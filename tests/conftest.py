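import math

import numpy as np
import pandas as pd
import pytest

from stic_atlas import preprocess as pp
from stic_atlas.genome import toy_genome
from stic_atlas.synthetic import (
    SynthConfig,
    generate_cohort,
    generate_loci,
    generate_reference_panel,
)


def small_config(**overrides) -> SynthConfig:
    """A fast, reduced cohort for unit tests (structure intact, sizes small)."""
    defaults = dict(
        n_patients_per_subtype={s: 3 for s in
                                ("dormant", "mixed", "immunoreactive", "proliferative")},
        n_aois_per_patient=3,
        n_nft=6, n_hgsc=4, n_meso=4, n_stromal=0,
        n_genes=400, n_signature_per_subtype=20,
        n_loci=2000, depth=100_000,
        seed=11,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    return pp.remove_batch_effects(pp.variance_stabilize(small_cohort.expression))


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def dna_world(genome):
    """Shared loci, weights and a 30-member euploid panel for DNA tests."""
    ss = np.random.SeedSequence(42)
    s_loci, s_w, s_panel = ss.spawn(3)
    loci = generate_loci(genome, 8000, s_loci)
    weights = np.exp(np.random.default_rng(s_w).normal(0, 1, len(loci)))
    panel = generate_reference_panel(
        genome, n=30, depth=300_000, seed=s_panel, loci=loci, weights=weights
    )
    return {"loci": loci, "weights": weights, "panel": panel, "genome": genome}


@pytest.fixture()
def aoi_matrix_factory():
    """Build a minimal AOIMatrix from a values array."""

    def build(values, transformed=False, batches=None, diagnosis="STIC"):
        values = np.asarray(values, dtype=float)
        genes = [f"g{i}" for i in range(values.shape[0])]
        aois = [f"a{j}" for j in range(values.shape[1])]
        meta = pd.DataFrame(
            {
                "compartment": "epithelial",
                "diagnosis": diagnosis,
                "batch": batches if batches is not None else "run1",
                "patient": aois,
            },
            index=aois,
        )
        return pp.AOIMatrix(pd.DataFrame(values, index=genes, columns=aois),
                            meta, transformed=transformed)

    return build
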