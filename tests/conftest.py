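import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ibdnet.io import GeneSetDB, GenotypeMatrix, SnpMeta, build_interaction_table

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix():
    """3 affected (CD) + 2 controls (HC), 2 SNPs, no missing calls."""
    snps = [
        SnpMeta("rs1", "1", "GENEA", "A", "G"),
        SnpMeta("rs2", "2", "GENEB", "C", "T"),
    ]
    calls = np.array([[2, 1], [1, 0], [0, 1], [0, 2], [0, 0]], dtype=np.int8)
    samples = ["s1", "s2", "s3", "s4", "s5"]
    groups = {"s1": "CD", "s2": "CD", "s3": "CD", "s4": "HC", "s5": "HC"}
    return GenotypeMatrix(samples=samples, groups=groups, snps=snps, calls=calls)


def interactions_from_tuples(tuples):
    df = pd.DataFrame(tuples, columns=["protein_a", "protein_b", "combined_score"])
    return build_interaction_table(df)


@pytest.fixture
def small_db():
    return GeneSetDB(
        sets={
            "PW1": ("alpha", ["g1", "g2", "g3", "g4"]),
            "PW2": ("beta", ["g3", "g4", "g5", "g6"]),
            "PW3": ("gamma", ["g7", "g8"]),
        }
    )
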