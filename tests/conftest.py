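import json
import pathlib

import pytest

from cvperm.config import parse_descriptor
from cvperm.synthdata import SyntheticSpec, generate

REPO = pathlib.Path(__file__).resolve().parent.parent
DESCRIPTOR_DIR = REPO / "examples" / "descriptors"


def make_descriptor(
    B=20,
    per_task=1,
    k=50,
    alpha=1e-4,
    with_covariates=True,
    grid=None,
    pipeline=None,
    **extra,
):
    """Build a small valid descriptor JSON and parse it."""
    doc = {
        "with_covariates": with_covariates,
        "n_permutations": B,
        "permutations_per_task": per_task,
        "pipeline": pipeline
        or [
            {"name": "kbest", "component_ref": "select_k_best", "parameters": {"k": k}},
            {"name": "ridge", "component_ref": "ridge", "parameters": {"alpha": alpha}},
        ],
    }
    if grid is not None:
        doc["grid"] = {"axes": grid}
    doc.update(extra)
    return parse_descriptor(json.dumps(doc))


@pytest.fixture(scope="session")
def descriptor_dir():
    return DESCRIPTOR_DIR


@pytest.fixture(scope="session")
def small_cohort():
    """100 subjects x 200 SNPs, 2 correlated phenotypes, planted g2=0.5."""
    return generate(
        SyntheticSpec(
            n_subjects=100,
            n_snps=200,
            n_phenotypes=2,
            n_causal_snps=5,
            genetic_variance_fraction=0.5,
            missing_rate=0.02,
            seed=11,
        )
    )
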