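import pytest

from sompkit.cli import bundle_config
from sompkit.io_tables import PeptideEvidence
from sompkit.pipeline import run_curation
from sompkit.synthetic import headline_bundle


def make_evidence(
    accession="P1",
    peptide="MKLVNTTR",
    spectra=1,
    significant=True,
    score=100.0,
    method="CF2",
    solubility="ISOM",
):
    return PeptideEvidence(
        protein_accession=accession,
        peptide=peptide,
        spectra_count=spectra,
        significant=significant,
        score=score,
        method=method,
        solubility=solubility,
    )


@pytest.fixture(scope="session")
def headline_bundle_fixture(tmp_path_factory):
    """The headline-structure synthetic bundle, generated once per session."""
    out = tmp_path_factory.mktemp("headline_bundle_fixture")
    return headline_bundle(11, out)


@pytest.fixture(scope="session")
def headline_run(headline_bundle_fixture, tmp_path_factory):
    """Full pipeline run on the headline-structure bundle."""
    out = tmp_path_factory.mktemp("headline_run")
    return run_curation(bundle_config(headline_bundle_fixture.out_dir), out_dir=out)
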