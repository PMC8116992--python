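"""Seeded generator of specimen-stratified synthetic NGS QC datasets.

Emulates the kind of accumulated QC table a clinical targeted cancer
panel produces over several years of operation: roughly a thousand
samples, mostly FFPE tissue with smaller fresh-cell and cell-line
fractions, where fresh-cell specimens show systematically better quality
than FFPE across DNA integrity, Q30, coverage, uniformity, on-target
rate and pass-rate score (and a lower error rate), because formalin
fixation degrades and crosslinks DNA.

All default distribution parameters are invented synthetic constants
chosen to be realistic for deep targeted panel sequencing; none are
measurements from any real pipeline.  They are fully overridable via
:class:`GeneratorConfig`.

Determinism: records are drawn from one PCG64 stream per record, seeded
by ``SeedSequence((master_seed, record_index))``, so the same config and
seed reproduce the dataset byte-for-byte, independent of generation
order.  Specimen-type counts come from largest-remainder apportionment
of the mix proportions, making the per-facet tallies exact rather than
stochastic — they double as ground truth for count-conservation tests.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .elements import BY_PATH, Kind, SpecimenType
from .model import QcRecord, make_record

__all__ = [
    "MetricSpec", "SpecimenProfile", "GeneratorConfig", "GeneratedDataset",
    "default_profiles", "generate", "corrupt", "MUTATION_CLASSES",
]


@dataclass(frozen=True)
class MetricSpec:
    """Distribution of one numeric metric within one specimen type.

    family ``normal``: value ~ N(loc, scale); ``lognormal``: exp(N(log
    loc, scale)) so ``loc`` is the median; ``beta_scaled``: lo + (hi −
    lo)·Beta(loc, scale).  Values are rejection-sampled into [lo, hi]
    (clipped after 100 draws, which in practice never triggers with the
    shipped parameters).
    """

    family: str  # "normal" | "lognormal" | "beta_scaled"
    loc: float
    scale: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.family not in ("normal", "lognormal", "beta_scaled"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.lo > self.hi:
            raise ValueError("truncation lo must be <= hi")

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "beta_scaled":
            return self.lo + (self.hi - self.lo) * rng.beta(self.loc, self.scale)
        for _ in range(100):
            if self.family == "normal":
                v = rng.normal(self.loc, self.scale)
            else:
                v = math.exp(rng.normal(math.log(self.loc), self.scale))
            if self.lo <= v <= self.hi:
                return v
        return min(max(v, self.lo), self.hi)


@dataclass(frozen=True)
class SpecimenProfile:
    specimen_type: SpecimenType
    metrics: Dict[str, MetricSpec]
    missingness: Dict[str, float]
    pools: Dict[str, Sequence[Tuple[str, float]]]

    def __post_init__(self):
        for path, spec in self.metrics.items():
            el = BY_PATH[path]
            if el.range is not None:
                if not (el.range.check(spec.lo) or spec.lo == el.range.lo):
                    raise ValueError(f"{path}: truncation lo outside metric domain")
                if not (el.range.check(spec.hi) or spec.hi == el.range.hi):
                    raise ValueError(f"{path}: truncation hi outside metric domain")
        for path, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{path}: missingness rate outside [0,1]")


# Metrics where larger is better; used by tests and docs to phrase the
# FFPE-vs-fresh ordering property.  error_rate is the lower-is-better one.
QUALITY_INCREASING = (
    "dna_extraction.dna_median_size",
    "sequencing.pct_q30",
    "processing.mean_coverage",
    "processing.uniformity",
    "processing.on_target_rate",
    "processing.pr_score",
)

_SHARED_POOLS: Dict[str, Sequence[Tuple[str, float]]] = {
    "library.construction_kit": (
        ("agilent sureselect XT HS", 0.7), ("illumina truseq nano", 0.3)),
    "sequencing.instrument": (
        ("Illumina HiSeq 2500", 0.6), ("Illumina NextSeq 550", 0.4)),
    "sequencing.running_mode": (("high output", 0.7), ("rapid run", 0.3)),
    "processing.mapping_algorithm": (("BWA-MEM", 0.9), ("Bowtie2", 0.1)),
    "processing.alignment_software": (("bwa 0.7.17", 0.9), ("bowtie2 2.4.1", 0.1)),
    "processing.variant_calling_software": (
        ("GATK Mutect2", 0.6), ("VarDict", 0.4)),
    "processing.germline_filter_criteria": (
        ("population AF > 0.01 excluded", 1.0),),
    "processing.reference_database": (("GRCh37", 0.8), ("GRCh38", 0.2)),
}

_GENE_POOL = ("TP53", "EGFR", "KRAS", "BRAF", "PIK3CA", "ALK", "BRCA1",
              "BRCA2", "MET", "ERBB2", "PTEN", "RET")

# Baseline missingness for the optional wet-lab measurements.
_MISSINGNESS = {
    "dna_extraction.od_260_230": 0.05,
    "dna_extraction.od_260_280": 0.02,
    "dna_extraction.dna_median_size": 0.03,
    "library.input_amount": 0.02,
    "library.input_size": 0.02,
    "processing.quality_score": 0.05,
    "processing.allelic_read_percentage": 0.05,
}


def _profile(specimen: SpecimenType, *, median_size, error_rate, pct_q30,
             coverage, uniformity, on_target, pr_score, q30,
             extraction_pool) -> SpecimenProfile:
    metrics = {
        "dna_extraction.od_260_280": MetricSpec("normal", 1.87, 0.07, 1.2, 2.4),
        "dna_extraction.od_260_230": MetricSpec("normal", 2.05, 0.25, 0.5, 3.0),
        "dna_extraction.dna_median_size": median_size,
        "library.input_amount": MetricSpec("normal", 250.0, 60.0, 10.0, 600.0),
        "library.input_size": MetricSpec("normal", 290.0, 35.0, 100.0, 500.0),
        "sequencing.error_rate": error_rate,
        "sequencing.pct_q30": pct_q30,
        "processing.total_reads": MetricSpec("lognormal", 4.0e7, 0.35, 1e6, 5e8),
        "processing.mean_coverage": coverage,
        "processing.uniformity": uniformity,
        "processing.on_target_rate": on_target,
        "processing.q30": q30,
        "processing.pr_score": pr_score,
        "processing.quality_score": MetricSpec("normal", 60.0, 15.0, 0.0, 120.0),
        "processing.allelic_read_percentage":
            MetricSpec("beta_scaled", 2.0, 4.0, 0.0, 100.0),
    }
    pools = dict(_SHARED_POOLS)
    pools["dna_extraction.extraction_kit"] = extraction_pool
    return SpecimenProfile(specimen_type=specimen, metrics=metrics,
                           missingness=dict(_MISSINGNESS), pools=pools)


def default_profiles() -> Dict[SpecimenType, SpecimenProfile]:
    """Three shipped profiles (ffpe, fresh_cell, cell_line).

    Location parameters are ordered so that, in expectation, fresh-cell
    quality exceeds cell-line quality which exceeds FFPE quality for
    every quality-increasing metric, and the reverse for error rate —
    the qualitative pattern formalin fixation produces.  The constants
    are synthetic (illustrative, not fitted to any real dataset).
    """
    ffpe_kit = (("qiagen allprep DNA/RNA FFPE kit", 0.6),
                ("promega maxwell RSC DNA FFPE kit", 0.4))
    fresh_kit = (("qiagen allprep DNA/RNA mini kit", 0.7),
                 ("qiagen DNeasy blood & tissue kit", 0.3))
    return {
        SpecimenType.FFPE: _profile(
            SpecimenType.FFPE,
            median_size=MetricSpec("lognormal", 3000.0, 0.45, 100.0, 2e5),
            error_rate=MetricSpec("normal", 0.85, 0.20, 0.0, 100.0),
            pct_q30=MetricSpec("normal", 88.0, 3.5, 0.0, 100.0),
            coverage=MetricSpec("normal", 620.0, 140.0, 0.0, 3000.0),
            uniformity=MetricSpec("beta_scaled", 18.0, 1.6, 0.0, 100.0),
            on_target=MetricSpec("normal", 62.0, 6.0, 0.0, 100.0),
            pr_score=MetricSpec("normal", 90.0, 4.5, 0.0, 100.0),
            q30=MetricSpec("normal", 87.0, 3.5, 0.0, 100.0),
            extraction_pool=ffpe_kit),
        SpecimenType.FRESH_CELL: _profile(
            SpecimenType.FRESH_CELL,
            median_size=MetricSpec("lognormal", 50000.0, 0.30, 1000.0, 5e5),
            error_rate=MetricSpec("normal", 0.50, 0.12, 0.0, 100.0),
            pct_q30=MetricSpec("normal", 93.5, 1.8, 0.0, 100.0),
            coverage=MetricSpec("normal", 900.0, 150.0, 0.0, 3000.0),
            uniformity=MetricSpec("beta_scaled", 55.0, 2.2, 0.0, 100.0),
            on_target=MetricSpec("normal", 71.0, 4.5, 0.0, 100.0),
            pr_score=MetricSpec("normal", 97.0, 1.8, 0.0, 100.0),
            q30=MetricSpec("normal", 92.5, 2.0, 0.0, 100.0),
            extraction_pool=fresh_kit),
        SpecimenType.CELL_LINE: _profile(
            SpecimenType.CELL_LINE,
            median_size=MetricSpec("lognormal", 45000.0, 0.32, 1000.0, 5e5),
            error_rate=MetricSpec("normal", 0.55, 0.13, 0.0, 100.0),
            pct_q30=MetricSpec("normal", 92.5, 2.0, 0.0, 100.0),
            coverage=MetricSpec("normal", 860.0, 150.0, 0.0, 3000.0),
            uniformity=MetricSpec("beta_scaled", 45.0, 2.2, 0.0, 100.0),
            on_target=MetricSpec("normal", 69.0, 5.0, 0.0, 100.0),
            pr_score=MetricSpec("normal", 96.0, 2.0, 0.0, 100.0),
            q30=MetricSpec("normal", 91.5, 2.2, 0.0, 100.0),
            extraction_pool=fresh_kit),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 1000
    mix: Dict[SpecimenType, float] = field(default_factory=lambda: {
        SpecimenType.FFPE: 0.6,
        SpecimenType.FRESH_CELL: 0.3,
        SpecimenType.CELL_LINE: 0.1,
    })
    seed: int = 0
    year_range: Tuple[int, int] = (2014, 2020)
    profiles: Optional[Dict[SpecimenType, SpecimenProfile]] = None

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must be <= end")


@dataclass
class GeneratedDataset:
    records: List[QcRecord]
    tallies: Dict[str, Dict]


def apportion(n: int, mix: Dict, keys: Sequence) -> Dict:
    """Largest-remainder apportionment of n among the mix's keys.

    Deterministic: remainders are broken by larger fractional part, then
    by position in ``keys``."""
    quotas = {k: n * mix[k] for k in keys}
    counts = {k: int(math.floor(quotas[k])) for k in keys}
    short = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), keys.index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


def _pick(rng: np.random.Generator, pool: Sequence[Tuple[str, float]]) -> str:
    values = [v for v, _ in pool]
    weights = np.array([w for _, w in pool], dtype=float)
    return values[rng.choice(len(values), p=weights / weights.sum())]


def _one_record(index: int, specimen: SpecimenType, profile: SpecimenProfile,
                config: GeneratorConfig) -> QcRecord:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, index)))
    flat: Dict[str, object] = {
        "record_id": f"CS-{index + 1:05d}",
        "patient_ref": f"Patient/P{10000 + index}",
        "sample_prep.sequencing_type": "targeted_panel",
        "sample_prep.specimen_type": specimen.value,
    }
    y0, y1 = config.year_range
    start = _dt.date(y0, 1, 1)
    span = (_dt.date(y1, 12, 31) - start).days + 1
    flat["sample_prep.sampling_date"] = (
        start + _dt.timedelta(days=int(rng.integers(span)))).isoformat()
    n_genes = int(rng.integers(3, 9))
    genes = list(rng.choice(len(_GENE_POOL), size=n_genes, replace=False))
    flat["sample_prep.target_gene"] = [_GENE_POOL[g] for g in sorted(genes)]
    flat["sequencing.read_length"] = int(rng.choice([100, 150], p=[0.3, 0.7]))
    flat["sequencing.direction"] = "paired" if rng.random() < 0.95 else "single"
    for path, pool in profile.pools.items():
        flat[path] = _pick(rng, pool)
    for path, spec in profile.metrics.items():
        value = spec.draw(rng)
        if rng.random() < profile.missingness.get(path, 0.0):
            continue
        if BY_PATH[path].kind == Kind.INTEGER:
            value = int(round(value))
        else:
            value = round(float(value), 4)
        flat[path] = value
    return make_record(flat)


def generate(config: GeneratorConfig = GeneratorConfig()) -> GeneratedDataset:
    """Generate exactly ``config.n`` records plus exact per-facet tallies.

    Identical (config, seed) → identical output.  Every generated record
    validates with no errors by construction (all draws are truncated to
    their metric's domain).
    """
    profiles = config.profiles or default_profiles()
    counts = apportion(config.n, config.mix, list(config.mix))
    assignment: List[SpecimenType] = []
    for k in config.mix:
        assignment.extend([k] * counts[k])
    records = [_one_record(i, specimen, profiles[specimen], config)
               for i, specimen in enumerate(assignment)]
    tallies: Dict[str, Dict] = {
        "total": config.n,
        "specimen_type": {},
        "sequencing_type": {},
        "year": {},
    }
    for r in records:
        sp = r.sample_prep
        for facet, value in (
                ("specimen_type", sp.specimen_type.value),
                ("sequencing_type", sp.sequencing_type.value),
                ("year", sp.sampling_date.year)):
            tallies[facet][value] = tallies[facet].get(value, 0) + 1
    return GeneratedDataset(records=records, tallies=tallies)


# ---------------------------------------------------------------------------
# Negative-test fixture injection

@dataclass(frozen=True)
class Mutation:
    cls: str
    count: int = 1
    path: Optional[str] = None  # override the class's default target path


# class name -> (level, default path)
MUTATION_CLASSES = {
    "out_of_range_percentage": ("record", "sequencing.pct_q30"),
    "negative_size": ("record", "dna_extraction.dna_median_size"),
    "wrong_value_type": ("resource", "dna_extraction.od_260_280"),
    "unknown_subextension": ("resource", None),
}


def _find_leaf(doc: dict, fhir_path: Tuple[str, ...]) -> Optional[dict]:
    for ext in doc.get("extension", []):
        nodes = ext.get("extension", [])
        node = None
        for url in fhir_path:
            node = next((c for c in nodes if c.get("url") == url), None)
            if node is None:
                break
            nodes = node.get("extension", [])
        if node is not None:
            return node
    return None


def corrupt(items: Sequence, mutation_spec: Sequence[Mutation], seed: int):
    """Inject documented violation classes into a seeded random subset.

    ``items`` are QcRecords for record-level classes (out-of-range
    percentage, negative size) or encoded resource documents for
    post-encoding classes (wrong value-type key, unknown sub-extension).
    Returns ``(mutated_items, injected)`` where ``injected`` lists
    ``(record_id, path, class)`` for assertion; an empty spec is the
    identity.
    """
    import copy

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    items = [i.model_copy(deep=True) if isinstance(i, QcRecord)
             else copy.deepcopy(i) for i in items]
    injected: List[Tuple[str, str, str]] = []
    for mut in mutation_spec:
        if mut.cls not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {mut.cls!r}")
        level, default_path = MUTATION_CLASSES[mut.cls]
        path = mut.path or default_path
        if level == "record":
            eligible = [i for i, it in enumerate(items) if isinstance(it, QcRecord)]
        else:
            eligible = [i for i, it in enumerate(items) if isinstance(it, dict)]
        if mut.cls == "wrong_value_type":
            eligible = [i for i in eligible
                        if _find_leaf(items[i], BY_PATH[path].fhir_path)]
        if len(eligible) < mut.count:
            raise ValueError(
                f"{mut.cls}: only {len(eligible)} eligible items for count {mut.count}")
        chosen = rng.choice(len(eligible), size=mut.count, replace=False)
        for ci in sorted(int(c) for c in chosen):
            idx = eligible[ci]
            item = items[idx]
            if mut.cls == "out_of_range_percentage":
                stage, name = path.split(".", 1)
                setattr(getattr(item, stage), name,
                        float(100.0 + rng.uniform(1.0, 50.0)))
                injected.append((item.record_id, path, mut.cls))
            elif mut.cls == "negative_size":
                stage, name = path.split(".", 1)
                setattr(getattr(item, stage), name,
                        -float(rng.uniform(1.0, 1000.0)))
                injected.append((item.record_id, path, mut.cls))
            elif mut.cls == "wrong_value_type":
                leaf = _find_leaf(item, BY_PATH[path].fhir_path)
                for key in ("valueDecimal", "valueInteger"):
                    if key in leaf:
                        leaf["valueString"] = str(leaf.pop(key))
                        break
                injected.append((_doc_id(item), path, mut.cls))
            else:  # unknown_subextension
                target = _find_leaf(item, ("dataProcessing",)) or \
                    item["extension"][0]["extension"][0]
                target.setdefault("extension", []).append(
                    {"url": "labTemperature", "valueDecimal": 23.5})
                injected.append((_doc_id(item),
                                 target.get("url", "") + ".labTemperature", mut.cls))
    return items, injected


def _doc_id(doc: dict) -> str:
    for ident in doc.get("identifier", []):
        if ident.get("value"):
            return str(ident["value"])
    return str(doc.get("id", ""))
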