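"""Shared test fixtures: one deterministic synthetic bundle plus the trained
artifacts derived from it, built once per session."""

from __future__ import annotations

import pytest

from scaffoldmine import domains, fixtures, ordering, pipeline, screening, substrates
from scaffoldmine.aligners import PrealignedAligner

SEED = 7


@pytest.fixture(scope="session")
def bundle():
    return fixtures.generate_fixtures(SEED)


@pytest.fixture(scope="session")
def profiles(bundle):
    built = domains.build_profiles(bundle.labeled_domains, PrealignedAligner())
    return domains.calibrate_thresholds(built, bundle.labeled_domains)


@pytest.fixture(scope="session")
def substrate_model(bundle):
    aln = substrates.AlignedSequenceSet.from_labeled(
        bundle.substrate_sequences, bundle.substrate_labels, PrealignedAligner()
    )
    return substrates.train(aln, substrates.BEST_PARAMS_A, seed=SEED)


@pytest.fixture(scope="session")
def screening_db(bundle):
    return screening.ingest({"fixture": bundle.library})


@pytest.fixture(scope="session")
def config(bundle, profiles, substrate_model, screening_db):
    return pipeline.PipelineConfig(
        profiles=profiles,
        refdb=ordering.ReferenceBlockDB([("ref0", bundle.reference_domain_string)]),
        substrate_models={"A": substrate_model},
        screening_db=screening_db,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    bundle.write(d)
    return d


@pytest.fixture(scope="session")
def genome_results(fixture_dir, config):
    return pipeline.run(fixture_dir / "genome.gbk", config)


@pytest.fixture(scope="session")
def shuffled_results(fixture_dir, config):
    return pipeline.run(fixture_dir / "genome_shuffled.gbk", config)
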