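"""Registry of NGS quality-control data elements.

Every QC data element exchanged by this package is declared here exactly
once: its dotted record path (``stage.field``), its position in the
QcMetrics extension tree (a chain of extension urls), its semantic type,
its unit (if any) and its value-range constraint.  The domain model, the
FHIR codec, the profile emitter, the validator, the statistics layer and
the synthetic generator are all driven off this table, which keeps the
flat-record view and the FHIR view of an element permanently in sync.

The elements cover the four stages of a clinical NGS workflow: sample
preparation, library preparation (DNA extraction + library construction),
sequencing, and data processing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple

QC_METRICS_URL = "http://example.org/fhir/StructureDefinition/QcMetrics"


class SequencingType(str, enum.Enum):
    TARGETED_PANEL = "targeted_panel"
    WES = "wes"
    WGS = "wgs"
    OTHER = "other"


class SpecimenType(str, enum.Enum):
    FFPE = "ffpe"
    FRESH_CELL = "fresh_cell"
    CELL_LINE = "cell_line"
    BLOOD = "blood"
    OTHER = "other"


class ReadDirection(str, enum.Enum):
    SINGLE = "single"
    PAIRED = "paired"


class Kind(str, enum.Enum):
    """Semantic type of an element's value."""

    STRING = "string"
    CODE = "code"
    DECIMAL = "decimal"
    INTEGER = "integer"
    DATE = "date"
    GENE_LIST = "gene_list"  # repeated string (0..*)


@dataclass(frozen=True)
class Range:
    """Closed/open numeric bounds; ``None`` means unbounded on that side."""

    lo: Optional[float] = None
    hi: Optional[float] = None
    lo_open: bool = False
    hi_open: bool = False

    def check(self, v: float) -> bool:
        if self.lo is not None and (v < self.lo or (self.lo_open and v == self.lo)):
            return False
        if self.hi is not None and (v > self.hi or (self.hi_open and v == self.hi)):
            return False
        return True

    def describe(self) -> str:
        lo = "(-inf" if self.lo is None else ("(" if self.lo_open else "[") + repr(self.lo)
        hi = "inf)" if self.hi is None else repr(self.hi) + (")" if self.hi_open else "]")
        return f"{lo}, {hi}"


PCT = Range(0.0, 100.0)
POSITIVE = Range(0.0, None, lo_open=True)
NON_NEGATIVE = Range(0.0, None)
OD_RATIO = Range(0.0, 10.0, lo_open=True, hi_open=True)


@dataclass(frozen=True)
class Element:
    path: str                       # dotted record path, e.g. "dna_extraction.od_260_280"
    fhir_path: Tuple[str, ...]      # url chain under QcMetrics, e.g. ("dnaExtraction", "dnaPurity", "od260280")
    kind: Kind
    unit: Optional[str] = None      # UCUM-ish unit string carried on the wire
    range: Optional[Range] = None
    enum: Optional[type] = None     # for Kind.CODE
    short: str = ""                 # human description, used in the StructureDefinition

    @property
    def stage(self) -> str:
        return self.path.split(".", 1)[0]

    @property
    def field_name(self) -> str:
        return self.path.split(".", 1)[1]

    @property
    def url(self) -> str:
        return self.fhir_path[-1]

    @property
    def numeric(self) -> bool:
        return self.kind in (Kind.DECIMAL, Kind.INTEGER)


ELEMENTS: Tuple[Element, ...] = (
    # -- sample preparation ------------------------------------------------
    Element("sample_prep.sequencing_type", ("samplePreparation", "sequencingType"),
            Kind.CODE, enum=SequencingType, short="Type of sequencing assay"),
    Element("sample_prep.target_gene", ("samplePreparation", "targetGene"),
            Kind.GENE_LIST, short="Gene symbols covered by the panel"),
    Element("sample_prep.specimen_type", ("samplePreparation", "specimenType"),
            Kind.CODE, enum=SpecimenType, short="Specimen preservation / origin"),
    Element("sample_prep.sampling_date", ("samplePreparation", "samplingDate"),
            Kind.DATE, short="Date the specimen was sampled"),
    # -- library preparation: DNA extraction -------------------------------
    Element("dna_extraction.extraction_kit", ("dnaExtraction", "dnaExtractionKit"),
            Kind.STRING, short="DNA extraction kit"),
    Element("dna_extraction.od_260_280", ("dnaExtraction", "dnaPurity", "od260280"),
            Kind.DECIMAL, range=OD_RATIO, short="DNA purity: OD 260/280 absorbance ratio"),
    Element("dna_extraction.od_260_230", ("dnaExtraction", "dnaPurity", "od260230"),
            Kind.DECIMAL, range=OD_RATIO, short="DNA purity: OD 260/230 absorbance ratio"),
    Element("dna_extraction.dna_median_size", ("dnaExtraction", "dnaIntegrity"),
            Kind.DECIMAL, unit="bp", range=POSITIVE,
            short="DNA integrity: median fragment size"),
    # -- library preparation: library construction -------------------------
    Element("library.input_amount", ("libraryConstruction", "libraryInputAmount"),
            Kind.DECIMAL, unit="ng", range=POSITIVE, short="Library input amount"),
    Element("library.input_size", ("libraryConstruction", "libraryInputSize"),
            Kind.DECIMAL, unit="bp", range=POSITIVE, short="Library input size"),
    Element("library.construction_kit", ("libraryConstruction", "libraryConstructionKit"),
            Kind.STRING, short="Library construction kit"),
    # -- sequencing --------------------------------------------------------
    Element("sequencing.instrument", ("sequencing", "sequencingInstrument"),
            Kind.STRING, short="Sequencing instrument"),
    Element("sequencing.read_length", ("sequencing", "readLength"),
            Kind.INTEGER, unit="bp", range=Range(1, None), short="Read length"),
    Element("sequencing.direction", ("sequencing", "sequencingDirection"),
            Kind.CODE, enum=ReadDirection, short="Single- or paired-end sequencing"),
    Element("sequencing.running_mode", ("sequencing", "runningMode"),
            Kind.STRING, short="Instrument running mode"),
    Element("sequencing.error_rate", ("sequencing", "errorRate"),
            Kind.DECIMAL, unit="%", range=PCT, short="Run error rate"),
    Element("sequencing.pct_q30", ("sequencing", "percentQ30"),
            Kind.DECIMAL, unit="%", range=PCT,
            short="Percent of bases with quality above Q30 (run-level)"),
    # -- data processing ---------------------------------------------------
    Element("processing.total_reads", ("dataProcessing", "totalReads"),
            Kind.INTEGER, range=NON_NEGATIVE, short="Total sequenced reads"),
    Element("processing.mean_coverage", ("dataProcessing", "meanCoverage"),
            Kind.DECIMAL, unit="x", range=NON_NEGATIVE, short="Mean target coverage"),
    Element("processing.uniformity", ("dataProcessing", "uniformity"),
            Kind.DECIMAL, unit="%", range=PCT, short="Coverage uniformity"),
    Element("processing.on_target_rate", ("dataProcessing", "onTargetRate"),
            Kind.DECIMAL, unit="%", range=PCT, short="Fraction of reads on target"),
    Element("processing.q30", ("dataProcessing", "q30"),
            Kind.DECIMAL, unit="%", range=PCT,
            short="Percent of bases above Q30 (pipeline-level)"),
    Element("processing.pr_score", ("dataProcessing", "prScore"),
            Kind.DECIMAL, unit="%", range=PCT, short="Pass-rate (PR) score"),
    Element("processing.mapping_algorithm", ("dataProcessing", "mappingAlgorithm"),
            Kind.STRING, short="Read mapping algorithm"),
    Element("processing.alignment_software", ("dataProcessing", "alignmentSoftware"),
            Kind.STRING, short="Sequence alignment software"),
    Element("processing.variant_calling_software", ("dataProcessing", "variantCallingSoftware"),
            Kind.STRING, short="Variant calling software"),
    Element("processing.quality_score", ("dataProcessing", "qualityScore"),
            Kind.DECIMAL, range=NON_NEGATIVE, short="Variant quality score"),
    Element("processing.allelic_read_percentage", ("dataProcessing", "allelicReadPercentage"),
            Kind.DECIMAL, unit="%", range=PCT, short="Allelic read percentage"),
    Element("processing.germline_filter_criteria", ("dataProcessing", "germlineFilterCriteria"),
            Kind.STRING, short="Germline variant filter criteria"),
    Element("processing.reference_database", ("dataProcessing", "referenceDatabase"),
            Kind.STRING, short="Reference database"),
)

# Stage url on the wire, in emission order.
STAGE_URLS = {
    "sample_prep": "samplePreparation",
    "dna_extraction": "dnaExtraction",
    "library": "libraryConstruction",
    "sequencing": "sequencing",
    "processing": "dataProcessing",
}
STAGES = tuple(STAGE_URLS)

BY_PATH = {e.path: e for e in ELEMENTS}
BY_FHIR_PATH = {e.fhir_path: e for e in ELEMENTS}

# Identifier paths handled outside the extension tree.
ID_PATHS = ("record_id", "patient_ref")
ALL_PATHS = ID_PATHS + tuple(e.path for e in ELEMENTS)

NUMERIC_PATHS = tuple(e.path for e in ELEMENTS if e.numeric)

assert len(set(ALL_PATHS)) == len(ALL_PATHS)
assert len(ELEMENTS) >= 28
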