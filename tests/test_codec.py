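import copy
import json

import pytest

from ngsqr import (
    CodecError,
    Dialect,
    EncodeValidationError,
    decode,
    detect_dialect,
    emit_profile,
    from_fhir,
    make_record,
    profile_leaf_urls,
    to_fhir,
    validate_resource,
)
from ngsqr.examples import EXAMPLE_DNA_EXTRACTION


class TestWorkedExample:
    def test_parse_yields_the_documented_values(self, example_doc):
        r = from_fhir(example_doc)
        assert r.dna_extraction.od_260_280 == 2.1
        assert r.dna_extraction.od_260_230 == 2.3
        assert r.dna_extraction.dna_median_size == 60000.0
        assert r.dna_extraction.extraction_kit == "qiagen allprep DNA/RNA mini kit"

    def test_paper_dialect_reencoding_reproduces_the_subtree(self, example_doc):
        doc = to_fhir(from_fhir(example_doc), Dialect.PAPER)
        subtree = doc["extension"][0]["extension"][0]
        assert subtree == EXAMPLE_DNA_EXTRACTION
        # byte-compatible after identical serialization
        assert json.dumps(subtree) == json.dumps(EXAMPLE_DNA_EXTRACTION)

    def test_example_validates_clean_in_paper_dialect(self, example_doc):
        assert validate_resource(example_doc, Dialect.PAPER).ok


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_identity_over_synthetic_records(self, dataset, dialect):
        for r in dataset.records[:250]:
            assert from_fhir(to_fhir(r, dialect), dialect) == r

    def test_cross_dialect_consistency(self, small_dataset):
        for r in small_dataset.records:
            assert (from_fhir(to_fhir(r, Dialect.PAPER))
                    == from_fhir(to_fhir(r, Dialect.STRICT_FHIR)))

    def test_auto_detect_per_dialect(self, full_record):
        assert detect_dialect(to_fhir(full_record, Dialect.PAPER)) == Dialect.PAPER
        assert detect_dialect(
            to_fhir(full_record, Dialect.STRICT_FHIR)) == Dialect.STRICT_FHIR

    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_no_nulls_and_no_empty_extension_arrays(self, small_dataset, dialect):
        def walk(obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    assert v is not None
                    if k == "extension":
                        assert v != []
                    walk(v)
            elif isinstance(obj, list):
                for v in obj:
                    walk(v)
        for r in small_dataset.records[:20]:
            walk(to_fhir(r, dialect))

    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_encoded_resources_validate_clean(self, small_dataset, dialect):
        for r in small_dataset.records[:20]:
            assert validate_resource(to_fhir(r, dialect), dialect).ok


class TestEncodeEdgeCases:
    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_empty_record_has_identifier_and_no_extension(self, dialect):
        doc = to_fhir(make_record({"record_id": "S2"}), dialect)
        assert doc["identifier"] == [{"value": "S2"}]
        assert "extension" not in doc

    def test_invalid_record_is_refused_with_report(self):
        bad = make_record({"record_id": "S1", "sequencing.pct_q30": 101})
        with pytest.raises(EncodeValidationError) as exc:
            to_fhir(bad)
        assert any(i.path == "sequencing.pct_q30" for i in exc.value.report.errors)

    def test_integral_decimals_serialize_without_trailing_zero(self, example_doc):
        doc = to_fhir(from_fhir(example_doc), Dialect.PAPER)
        text = json.dumps(doc)
        assert '"valueDecimal": 60000' in text and "60000.0" not in text


class TestDecodeEdgeCases:
    def test_wrong_resource_type_is_fatal(self):
        with pytest.raises(CodecError, match="Observation"):
            from_fhir({"resourceType": "Observation", "identifier": [{"value": "x"}]})

    def test_units_plus_value_quantity_is_ambiguous(self, example_doc):
        leaf = example_doc["extension"][0]["extension"][0]["extension"][2]
        assert leaf["url"] == "dnaIntegrity"
        leaf["valueQuantity"] = {"value": 60000, "unit": "bp"}
        del leaf["valueDecimal"]
        with pytest.raises(CodecError, match="dnaIntegrity"):
            from_fhir(example_doc)

    def test_unknown_subextensions_collected_not_fatal(self, example_doc):
        example_doc["extension"][0]["extension"][0]["extension"].append(
            {"url": "labTemperature", "valueDecimal": 23.5})
        result = decode(example_doc)
        assert result.ignored == ["dnaExtraction.labTemperature"]
        assert result.record.dna_extraction.od_260_280 == 2.1

    def test_string_encoded_numbers_are_coerced(self, example_doc):
        leaf = example_doc["extension"][0]["extension"][0]["extension"][1]["extension"][0]
        leaf["valueString"] = "2.1"
        del leaf["valueDecimal"]
        assert from_fhir(example_doc).dna_extraction.od_260_280 == 2.1


class TestValidateResource:
    def test_wrong_value_type_key_is_an_error(self, example_doc):
        doc = to_fhir(from_fhir(example_doc), Dialect.STRICT_FHIR)
        leaf = doc["extension"][0]["extension"][0]["extension"][1]["extension"][0]
        assert leaf["url"] == "od260280"
        leaf["valueString"] = str(leaf.pop("valueDecimal"))
        report = validate_resource(doc, Dialect.STRICT_FHIR)
        errors = [i for i in report.errors if i.code == "wrong-value-type"]
        assert len(errors) == 1
        assert errors[0].path.endswith("od260280")

    def test_unknown_subextension_is_a_warning_only(self, example_doc):
        example_doc["extension"][0]["extension"][0]["extension"].append(
            {"url": "labTemperature", "valueDecimal": 23.5})
        report = validate_resource(example_doc)
        assert report.ok
        assert any(i.code == "unknown-extension" and "labTemperature" in i.path
                   for i in report.warnings)

    def test_units_sibling_rejected_in_strict_dialect(self, example_doc):
        report = validate_resource(example_doc, Dialect.STRICT_FHIR)
        assert any(i.code == "units-key-not-fhir" for i in report.errors)

    def test_out_of_range_value_surfaces_at_record_path(self, full_record):
        doc = to_fhir(full_record, Dialect.STRICT_FHIR)
        doc["extension"][0]["extension"][3]["extension"][4]["valueQuantity"]["value"] = 150
        report = validate_resource(doc, Dialect.STRICT_FHIR)
        assert any(i.path == "sequencing.error_rate" and i.code == "out-of-range"
                   for i in report.errors)


class TestProfile:
    def test_is_a_constraint_on_molecular_sequence(self):
        prof = emit_profile()
        assert prof["resourceType"] == "StructureDefinition"
        assert prof["type"] == "MolecularSequence"
        assert prof["derivation"] == "constraint"

    def test_contains_every_documented_leaf(self, full_record):
        prof = emit_profile()
        leaves = profile_leaf_urls(prof)
        assert len(leaves) >= 28

        def emitted_leaf_urls(doc):
            urls = set()
            def walk(nodes):
                for n in nodes:
                    if "extension" in n:
                        walk(n["extension"])
                    else:
                        urls.add(n["url"])
            walk(doc["extension"][0]["extension"])
            return urls

        for dialect in Dialect:
            emitted = emitted_leaf_urls(to_fhir(full_record, dialect))
            assert emitted <= leaves

    def test_deterministic_across_calls(self):
        assert json.dumps(emit_profile()) == json.dumps(emit_profile())

    def test_gene_list_is_repeatable(self):
        el = [e for e in emit_profile()["differential"]["element"]
              if e.get("sliceName") == "targetGene"]
        assert el[0]["max"] == "*"
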