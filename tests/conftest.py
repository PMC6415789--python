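import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sipscreen import FractionMeta, SipCountTable

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


MOTHUR_FIXTURE = (
    "label\tGroup\tnumOtus\tOtu001\tOtu002\n"
    "0.03\tS1\t2\t10\t90\n"
    "0.03\tS2\t2\t30\t70\n"
)

TSV_FIXTURE = "otu\tS1\tS2\nOtu001\t10\t30\nOtu002\t90\t70\n"

TAXONOMY_FIXTURE = (
    "OTU\tSize\tTaxonomy\n"
    "Otu001\t120\tBacteria(100);Bacteroidetes(98);Flavobacteriia(97);\n"
    "Otu002\t80\tBacteria(100);Proteobacteria(99);Alphaproteobacteria(95);"
    "Rhodospirillales(90);\n"
)


@pytest.fixture
def mothur_file(tmp_path):
    p = tmp_path / "counts.shared"
    p.write_text(MOTHUR_FIXTURE)
    return p


@pytest.fixture
def tsv_file(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text(TSV_FIXTURE)
    return p


@pytest.fixture
def taxonomy_file(tmp_path):
    p = tmp_path / "cons.taxonomy"
    p.write_text(TAXONOMY_FIXTURE)
    return p


def four_sample_meta(treatment="starch"):
    return {
        "C12_light": FractionMeta("C12", "light", treatment, 1.700),
        "C12_heavy": FractionMeta("C12", "heavy", treatment, 1.725),
        "C13_light": FractionMeta("C13", "light", treatment, 1.700),
        "C13_heavy": FractionMeta("C13", "heavy", treatment, 1.725),
    }


def toy_experiment_table(c12=(10, 10), c13=(30, 10), totals=(100, 100, 100, 100)):
    """Two-taxon table; focal taxon Otu001 has (heavy, light) counts c12/c13."""
    counts = np.array(
        [
            [c12[1], c12[0], c13[1], c13[0]],  # focal: light, heavy per isotope
            [
                totals[0] - c12[1],
                totals[1] - c12[0],
                totals[2] - c13[1],
                totals[3] - c13[0],
            ],
        ],
        dtype=np.int64,
    )
    return SipCountTable(
        otu_ids=["Otu001", "Otu002"],
        sample_ids=["C12_light", "C12_heavy", "C13_light", "C13_heavy"],
        counts=counts,
        meta=four_sample_meta(),
    )


@pytest.fixture
def toy_table():
    return toy_experiment_table()
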