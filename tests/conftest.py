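import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

MUTATION_HEADER = (
    "sample_id\tprotein_id\tposition\tref_aa\talt_aa\tmutation_class\tsomatic_status"
)


def records_to_tsv(records) -> str:
    rows = [MUTATION_HEADER]
    for r in records:
        rows.append(
            f"{r.sample_id}\t{r.protein_id}\t{r.position}\t{r.ref_aa}\t{r.alt_aa}"
            f"\t{r.mutation_class}\t{r.somatic_status}"
        )
    return "\n".join(rows) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(20140326)


@pytest.fixture
def simple_pdb_text():
    """Three CA records for chain A at residues 1, 2, 3."""
    return (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00\n"
        "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00\n"
        "ATOM      3  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00\n"
        "END\n"
    )
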