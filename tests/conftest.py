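import json
import os

import pytest

from altorf.fixtures import FixtureSpec, generate_fixture
from altorf.pipeline import RunConfig, run_pipeline


def fixture_config(d: str, out_dir: str, **overrides) -> RunConfig:
    kwargs = dict(
        genome=os.path.join(d, "genome.fa"),
        gff=os.path.join(d, "annotation.gff3"),
        ref_proteome=os.path.join(d, "ref_proteome.fa"),
        psm=os.path.join(d, "psms.tsv"),
        ribo=os.path.join(d, "ribo.tsv"),
        disorder=os.path.join(d, "disorder.tsv"),
        slims=os.path.join(d, "slims.tsv"),
        structure=os.path.join(d, "structure.tsv"),
        expression=os.path.join(d, "expression.tsv"),
        vcf=os.path.join(d, "variants.vcf"),
        out_dir=out_dir,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def mini_fixture(tmp_path_factory):
    """Small seeded mini-genome (9 genes) shared across unit tests."""
    d = tmp_path_factory.mktemp("mini_fx")
    truth = generate_fixture(FixtureSpec(seed=11, n_genes=9), str(d))
    return str(d), truth


@pytest.fixture(scope="session")
def mini_result(mini_fixture, tmp_path_factory):
    d, truth = mini_fixture
    out = tmp_path_factory.mktemp("mini_out")
    res = run_pipeline(fixture_config(d, str(out)))
    return res, truth


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """Default-scale fixture (75 genes, ≥200 planted ORFs) for acceptance."""
    d = tmp_path_factory.mktemp("study_fx")
    truth = generate_fixture(FixtureSpec(seed=5), str(d))
    return str(d), truth


@pytest.fixture(scope="session")
def study_result(study_fixture, tmp_path_factory):
    d, truth = study_fixture
    out = tmp_path_factory.mktemp("study_out")
    res = run_pipeline(fixture_config(d, str(out)))
    return res, truth, str(out)


def load_truth(d: str) -> dict:
    with open(os.path.join(d, "truth.json")) as fh:
        return json.load(fh)
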