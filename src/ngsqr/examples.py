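"""A small worked example: one MolecularSequence resource in the legacy
('paper') dialect, as an originating laboratory system would emit it.

Only the DNA-extraction stage is populated: extraction kit, the two
spectrophotometric purity ratios, and the median fragment size (60 kb —
an intact, non-degraded specimen).  Note the non-standard ``"units"``
sibling key on ``dnaIntegrity``, which is what the legacy ('paper')
dialect exists to reproduce.
"""

from __future__ import annotations

import copy

# The dnaExtraction sub-tree exactly as the legacy system lays it out.
EXAMPLE_DNA_EXTRACTION = {
    "url": "dnaExtraction",
    "extension": [
        {"url": "dnaExtractionKit",
         "valueString": "qiagen allprep DNA/RNA mini kit"},
        {"url": "dnaPurity",
         "extension": [
             {"url": "od260280", "valueDecimal": 2.1},
             {"url": "od260230", "valueDecimal": 2.3},
         ]},
        {"url": "dnaIntegrity", "units": "bp", "valueDecimal": 60000},
    ],
}

EXAMPLE_RESOURCE = {
    "resourceType": "MolecularSequence",
    "identifier": [{"value": "example-1"}],
    "extension": [
        {
            "url": "http://example.org/fhir/StructureDefinition/QcMetrics",
            "extension": [copy.deepcopy(EXAMPLE_DNA_EXTRACTION)],
        }
    ],
}


def example_resource() -> dict:
    """A fresh deep copy, safe to mutate."""
    return copy.deepcopy(EXAMPLE_RESOURCE)
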