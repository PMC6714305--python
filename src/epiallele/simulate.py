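"""Synthetic deep-bisulfite-sequencing cohorts with known ground truth.

Each simulated sample is a mixture of two cell compartments: germ cells
(proportion ``f``) and somatic cells (``1 - f``). Every sequenced read is one
allele. An allele is epiallele-coherent: a single Bernoulli draw with the
compartment's methylated-allele probability sets *all* CpGs of the read
identically (the all-red / all-blue rows of single-allele methylation plots);
per-CpG noise arises only downstream from incomplete bisulfite conversion and
sequencing error.

Methylated-allele probabilities by imprint class and compartment:

====================  =====================  =====
class                 soma                   germ
====================  =====================  =====
germ_marker           1.0                    0.0
maternal_imprint      0.5                    0.0
paternal_imprint      0.5                    1.0
x_inactivation        1.0 (46,XY) / 0.5      0.0
                      (46,XX or 47,XXY)
====================  =====================  =====

Imprinting epimutations are injected as an additive shift ``e`` on the germ
compartment's probability at a chosen locus, clamped to [0, 1].

Bisulfite chemistry: an unmethylated C reads as T with probability
``conversion_rate`` (else it stays C, inappropriate non-conversion); a
methylated CpG C stays C with probability ``conversion_rate`` (else it reads
T). Sequencing error substitutes any base uniformly with one of the other
three. Substitution-only (no indels, no homopolymer artifacts); constant
quality strings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import AmpliconLocus

GROUPS = ("normal", "KS")
FRACTIONS = ("SN", "AT", "blood", "sperm", "SCO")
KARYOTYPES = ("46,XY", "46,XX", "47,XXY")

_BASE_PROB = {
    #  class              soma (by karyotype)            germ
    "germ_marker": (lambda k: 1.0, 0.0),
    "maternal_imprint": (lambda k: 0.5, 0.0),
    "paternal_imprint": (lambda k: 0.5, 1.0),
    "x_inactivation": (lambda k: 1.0 if k == "46,XY" else 0.5, 0.0),
}


def allele_methylated_probability(
    imprint_class: str, compartment: str, karyotype: str, epimutation: float = 0.0
) -> float:
    """Population methylated-allele probability for one compartment."""
    soma_fn, germ_p = _BASE_PROB[imprint_class]
    if compartment == "soma":
        if epimutation != 0.0:
            raise ValueError("epimutations act on the germ compartment only")
        return soma_fn(karyotype)
    if compartment != "germ":
        raise ValueError(f"unknown compartment {compartment!r}")
    return float(np.clip(germ_p + epimutation, 0.0, 1.0))


def expected_mean_methylation(
    imprint_class: str, karyotype: str, germ_fraction: float, epimutation: float = 0.0
) -> float:
    """Analytic population mean methylation (%) of a mixture, noise-free."""
    p_soma = allele_methylated_probability(imprint_class, "soma", karyotype)
    p_germ = allele_methylated_probability(
        imprint_class, "germ", karyotype, epimutation
    )
    return 100.0 * ((1.0 - germ_fraction) * p_soma + germ_fraction * p_germ)


def allele_methylation_profile(
    locus: AmpliconLocus,
    compartment: str,
    karyotype: str,
    epimutation: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one allele: a per-CpG boolean vector, identical at all CpGs."""
    rng = np.random.default_rng() if rng is None else rng
    p = allele_methylated_probability(
        locus.imprint_class, compartment, karyotype, epimutation
    )
    methylated = bool(rng.random() < p)
    return np.full(locus.n_cpgs, methylated, dtype=bool)


@dataclass
class SampleSpec:
    """Ground-truth description of one simulated sample."""

    sample_id: str
    group: str = "normal"
    fraction: str = "SN"
    karyotype: str = "46,XY"
    germ_fraction: float = 0.0
    n_reads_per_locus: int = 500
    conversion_rate: float = 0.995
    seq_error_rate: float = 0.002
    epimutations: dict[str, float] = field(default_factory=dict)
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.karyotype not in KARYOTYPES:
            raise ValueError(f"unknown karyotype {self.karyotype!r}")
        for name, value in (
            ("germ_fraction", self.germ_fraction),
            ("conversion_rate", self.conversion_rate),
            ("seq_error_rate", self.seq_error_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.fraction in ("SCO", "blood") and self.germ_fraction != 0.0:
            raise ValueError(f"{self.fraction} fractions must have germ_fraction=0")
        if self.fraction == "sperm" and self.germ_fraction != 1.0:
            raise ValueError("sperm samples must have germ_fraction=1")
        for magnitude in self.epimutations.values():
            if not -1.0 <= magnitude <= 1.0:
                raise ValueError("epimutation magnitude outside [-1, 1]")
        if self.n_reads_per_locus <= 0:
            raise ValueError("n_reads_per_locus must be positive")
        if self.patient_id is None:
            self.patient_id = self.sample_id

    @property
    def purity_gated(self) -> bool:
        # only normal-group SN fractions are subject to the 4% marker gate;
        # KS SN fractions are enrichment-only and bypass it
        return self.group == "normal" and self.fraction == "SN"


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    out = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE_OF.items():
        lut[ord(base)] = code
    return lut[out]


def bisulfite_convert_batch(
    locus: AmpliconLocus,
    allele_methylated: np.ndarray,
    conversion_rate: float,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized bisulfite conversion + sequencing error for a read batch.

    ``allele_methylated`` is a boolean vector, one entry per read (alleles are
    all-or-none across CpGs). Returns an (n_reads, length) uint8 base-code
    matrix (A=0, C=1, G=2, T=3).
    """
    n = allele_methylated.size
    ref = _encode(locus.reference)
    reads = np.tile(ref, (n, 1))
    noncpg = np.asarray(locus.non_cpg_c_positions, dtype=np.intp)
    cpg = np.asarray(locus.cpg_positions, dtype=np.intp)
    # non-CpG Cs: always unmethylated; convert to T with p = conversion_rate
    conv = rng.random((n, noncpg.size)) < conversion_rate
    block = reads[:, noncpg]
    block[conv] = 3  # T
    reads[:, noncpg] = block
    # CpG Cs: unmethylated allele -> T with p = conversion; methylated allele
    # -> stays C with p = conversion (failure emits the opposite letter)
    conv = rng.random((n, cpg.size)) < conversion_rate
    to_t = conv ^ allele_methylated[:, None]
    block = reads[:, cpg]
    block[to_t] = 3
    reads[:, cpg] = block
    # uniform substitution error
    if seq_error_rate > 0:
        err = rng.random(reads.shape) < seq_error_rate
        offsets = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
        reads[err] = (reads[err] + offsets[err]) % 4
    return reads


def bisulfite_convert(
    reference: str,
    allele_methylation: np.ndarray,
    conversion_rate: float,
    seq_error_rate: float,
    rng: np.random.Generator,
    cpg_positions=None,
    non_cpg_c_positions=None,
    locus: AmpliconLocus | None = None,
) -> str:
    """Simulate one bisulfite read from one allele; returns a DNA string."""
    if locus is None:
        locus = AmpliconLocus(
            name="_anon",
            imprint_class="germ_marker",
            reference=reference,
            cpg_positions=tuple(cpg_positions),
            non_cpg_c_positions=tuple(non_cpg_c_positions),
        )
    allele = np.asarray(allele_methylation, dtype=bool)
    if allele.size != locus.n_cpgs:
        raise ValueError("allele methylation length != number of CpGs")
    ref = _encode(locus.reference)
    reads = np.tile(ref, (1, 1))
    noncpg = np.asarray(locus.non_cpg_c_positions, dtype=np.intp)
    cpg = np.asarray(locus.cpg_positions, dtype=np.intp)
    conv = rng.random(noncpg.size) < conversion_rate
    reads[0, noncpg[conv]] = 3
    conv = rng.random(cpg.size) < conversion_rate
    to_t = conv ^ allele
    reads[0, cpg[to_t]] = 3
    if seq_error_rate > 0:
        err = rng.random(reads.shape[1]) < seq_error_rate
        offsets = rng.integers(1, 4, size=reads.shape[1], dtype=np.uint8)
        reads[0, err] = (reads[0, err] + offsets[err]) % 4
    return "".join("ACGT"[c] for c in reads[0])


@dataclass
class SampleReads:
    """In-memory reads for one sample, grouped by locus."""

    sample_id: str
    reads: dict[str, list[tuple[str, str]]]  # locus -> [(read_id, sequence)]


def simulate_sample(
    panel: list[AmpliconLocus],
    spec: SampleSpec,
    rng: np.random.Generator,
) -> tuple[SampleReads, pd.DataFrame]:
    """Simulate all reads of one sample; returns reads plus truth records."""
    by_locus: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for locus in panel:
        n = spec.n_reads_per_locus
        is_germ = rng.random(n) < spec.germ_fraction
        e = spec.epimutations.get(locus.name, 0.0)
        p_germ = allele_methylated_probability(
            locus.imprint_class, "germ", spec.karyotype, e
        )
        p_soma = allele_methylated_probability(
            locus.imprint_class, "soma", spec.karyotype
        )
        p = np.where(is_germ, p_germ, p_soma)
        methylated = rng.random(n) < p
        codes = bisulfite_convert_batch(
            locus, methylated, spec.conversion_rate, spec.seq_error_rate, rng
        )
        lut = np.array(list("ACGT"))
        seqs = ["".join(row) for row in lut[codes]]
        ids = [f"{spec.sample_id}|{locus.name}|{i:05d}" for i in range(n)]
        by_locus[locus.name] = list(zip(ids, seqs))
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample_id": spec.sample_id,
                    "locus": locus.name,
                    "read_id": ids,
                    "compartment": np.where(is_germ, "germ", "soma"),
                    "allele_methylated": methylated,
                    "allele_methylated_sites": [
                        ",".join("1" if methylated[i] else "0" for _ in locus.cpg_positions)
                        for i in range(n)
                    ],
                }
            )
        )
    return SampleReads(spec.sample_id, by_locus), pd.concat(truth_rows, ignore_index=True)


def sample_sheet(specs: list[SampleSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in specs],
            "patient_id": [s.patient_id for s in specs],
            "group": [s.group for s in specs],
            "fraction": [s.fraction for s in specs],
            "karyotype": [s.karyotype for s in specs],
            "purity_gated": [s.purity_gated for s in specs],
        }
    )


def write_fastq(reads: SampleReads, path) -> None:
    """Write one sample's reads as 4-line FASTQ (constant quality)."""
    records = []
    for locus_reads in reads.reads.values():
        for read_id, seq in locus_reads:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def simulate_cohort(
    panel: list[AmpliconLocus],
    sample_specs: list[SampleSpec],
    rng_seed: int | np.random.SeedSequence,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, SampleReads], pd.DataFrame, pd.DataFrame]:
    """Simulate a whole cohort, optionally writing FASTQ + TSV artifacts.

    Returns ``(reads_by_sample, truth_table, sample_sheet)``; fully
    reproducible from the seed (byte-identical FASTQ on re-run).
    """
    ids = [s.sample_id for s in sample_specs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = ss.spawn(len(sample_specs))
    all_reads: dict[str, SampleReads] = {}
    truths = []
    for spec, child in zip(sample_specs, children):
        reads, truth = simulate_sample(panel, spec, np.random.default_rng(child))
        all_reads[spec.sample_id] = reads
        truths.append(truth)
    truth_table = pd.concat(truths, ignore_index=True)
    sheet = sample_sheet(sample_specs)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "fastq").mkdir(parents=True, exist_ok=True)
        for sid, reads in all_reads.items():
            write_fastq(reads, out / "fastq" / f"{sid}.fastq")
        truth_table.to_csv(out / "truth.tsv", sep="\t", index=False)
        sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    return all_reads, truth_table, sheet
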