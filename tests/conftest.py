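import datetime

import pytest

from ngsqr import GeneratorConfig, generate, make_record
from ngsqr.examples import example_resource as _example_resource


@pytest.fixture()
def example_doc():
    """The worked-example MolecularSequence in the legacy dialect."""
    return _example_resource()


@pytest.fixture(scope="session")
def dataset():
    """A full-size synthetic dataset (n=1000, fixed seed)."""
    return generate(GeneratorConfig(n=1000, seed=1234))


@pytest.fixture(scope="session")
def small_dataset():
    return generate(GeneratorConfig(n=60, seed=7))


@pytest.fixture()
def full_record():
    """A record with every documented element populated."""
    return make_record({
        "record_id": "FULL-1",
        "patient_ref": "Patient/P1",
        "sample_prep.sequencing_type": "targeted_panel",
        "sample_prep.target_gene": ["TP53", "EGFR"],
        "sample_prep.specimen_type": "ffpe",
        "sample_prep.sampling_date": datetime.date(2019, 5, 4),
        "dna_extraction.extraction_kit": "qiagen allprep DNA/RNA mini kit",
        "dna_extraction.od_260_280": 1.9,
        "dna_extraction.od_260_230": 2.0,
        "dna_extraction.dna_median_size": 2500.0,
        "library.input_amount": 200.0,
        "library.input_size": 300.0,
        "library.construction_kit": "agilent sureselect XT HS",
        "sequencing.instrument": "Illumina HiSeq 2500",
        "sequencing.read_length": 150,
        "sequencing.direction": "paired",
        "sequencing.running_mode": "high output",
        "sequencing.error_rate": 0.7,
        "sequencing.pct_q30": 91.5,
        "processing.total_reads": 38000000,
        "processing.mean_coverage": 750.5,
        "processing.uniformity": 94.2,
        "processing.on_target_rate": 64.0,
        "processing.q30": 90.1,
        "processing.pr_score": 95.0,
        "processing.mapping_algorithm": "BWA-MEM",
        "processing.alignment_software": "bwa 0.7.17",
        "processing.variant_calling_software": "GATK Mutect2",
        "processing.quality_score": 55.0,
        "processing.allelic_read_percentage": 31.0,
        "processing.germline_filter_criteria": "population AF > 0.01 excluded",
        "processing.reference_database": "GRCh37",
    })
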