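"""Amplicon locus panel: targeted regions, their CpG maps, and imprint classes.

A locus panel describes the bisulfite amplicons under study: for each target
region, the unconverted genomic top-strand sequence, the offsets of the CpG
cytosines whose methylation is read out, and the offsets of non-CpG cytosines
used to estimate the per-read bisulfite conversion rate. Each locus carries an
imprint class that fixes the expected allele methylation of the germ and
somatic compartments:

- ``germ_marker``   — promoter methylated in soma, unmethylated in germ cells
                      (FGFR3, VASA/DDX4, RHOXF1);
- ``maternal_imprint`` — ~50% methylated alleles in soma, unmethylated in the
                      male germline (MEST, LIT1; the assayed MEG3 region loses
                      methylation in germ cells and is modeled here too);
- ``paternal_imprint`` — ~50% methylated alleles in soma, fully methylated in
                      the male germline (H19);
- ``x_inactivation`` — XIST promoter: fully methylated in 46,XY soma, ~50% in
                      46,XX / 47,XXY soma, unmethylated in the male germline.

The synthetic panel generator invents stand-in sequences with a controlled CpG
layout; it does not reproduce the real assay coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IMPRINT_CLASSES = (
    "paternal_imprint",
    "maternal_imprint",
    "germ_marker",
    "x_inactivation",
)

#: default 8-locus panel: name -> imprint class
DEFAULT_PANEL_CLASSES: dict[str, str] = {
    "H19": "paternal_imprint",
    # the assayed MEG3 region behaves germ-unmethylated (decrease expected in
    # germ-cell fractions), so it is modeled with the maternal-type class
    "MEG3": "maternal_imprint",
    "MEST": "maternal_imprint",
    "LIT1": "maternal_imprint",
    "FGFR3": "germ_marker",
    "DDX4": "germ_marker",
    "RHOXF1": "germ_marker",
    "XIST": "x_inactivation",
}


class PanelSizingError(ValueError):
    """Amplicon too short to host the requested number of CpGs."""


@dataclass(frozen=True)
class AmpliconLocus:
    """One targeted amplicon region (0-based offsets internally)."""

    name: str
    imprint_class: str
    reference: str
    cpg_positions: tuple[int, ...]
    non_cpg_c_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.imprint_class not in IMPRINT_CLASSES:
            raise ValueError(f"unknown imprint class {self.imprint_class!r}")
        ref = self.reference
        for p in self.cpg_positions:
            if not (0 <= p < len(ref) - 1 and ref[p] == "C" and ref[p + 1] == "G"):
                raise ValueError(f"{self.name}: offset {p} is not a CpG cytosine")
        for p in self.non_cpg_c_positions:
            if not (0 <= p < len(ref) and ref[p] == "C"):
                raise ValueError(f"{self.name}: offset {p} is not a cytosine")
            if p + 1 < len(ref) and ref[p + 1] == "G":
                raise ValueError(f"{self.name}: offset {p} is a CpG, not a non-CpG C")
        for positions, label in (
            (self.cpg_positions, "cpg_positions"),
            (self.non_cpg_c_positions, "non_cpg_c_positions"),
        ):
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"{self.name}: {label} not strictly increasing")
        if set(self.cpg_positions) & set(self.non_cpg_c_positions):
            raise ValueError(f"{self.name}: CpG and non-CpG C offsets overlap")
        if len(self.cpg_positions) < 5:
            raise ValueError(f"{self.name}: need >=5 CpGs")
        if len(self.non_cpg_c_positions) < 5:
            raise ValueError(f"{self.name}: need >=5 non-CpG Cs")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def length(self) -> int:
        return len(self.reference)


def _make_reference(
    n_cpgs: int, length: int, rng: np.random.Generator
) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
    """Build one synthetic amplicon with an exactly controlled CpG layout.

    The backbone is drawn from {A,G,T}; CpG dinucleotides are planted on a
    spaced grid so they never collide, and non-CpG cytosines are planted at
    positions whose successor is never G. No accidental CpGs can arise.
    """
    # grid of candidate CpG start slots, spaced >=3 so CG pairs never touch
    slots = np.arange(2, length - 2, 3)
    if n_cpgs < 5:
        raise PanelSizingError("need at least 5 CpGs per locus")
    if length < 4 * n_cpgs or len(slots) < n_cpgs:
        raise PanelSizingError(
            f"amplicon length {length} too small for {n_cpgs} CpGs"
        )
    seq = rng.choice(np.frombuffer(b"AGT", dtype="S1"), size=length).astype("U1")
    cpg = np.sort(rng.choice(slots, size=n_cpgs, replace=False))
    for p in cpg:
        seq[p] = "C"
        seq[p + 1] = "G"
    # plant a non-CpG C immediately before each of the first few CpGs
    # ("CCG": first C is followed by C, hence non-CpG); always fits
    n_noncpg = max(5, n_cpgs // 2)
    noncpg = [int(p) - 1 for p in cpg[:n_noncpg]]
    for q in noncpg:
        seq[q] = "C"
    # sprinkle extra non-CpG Cs at free positions not followed by G
    taken = set(int(p) for p in cpg) | set(int(p) + 1 for p in cpg) | set(noncpg)
    free = [
        q
        for q in range(length - 1)
        if q not in taken and q + 1 not in taken and seq[q + 1] != "G"
    ]
    n_extra = min(len(free) // 10, n_cpgs)
    if n_extra:
        for q in rng.choice(np.array(free), size=n_extra, replace=False):
            seq[int(q)] = "C"
            noncpg.append(int(q))
    return "".join(seq), tuple(int(p) for p in cpg), tuple(sorted(noncpg))


def make_locus_panel(
    n_cpgs_per_locus: int = 10,
    amplicon_length: int = 200,
    rng_seed: int | np.random.SeedSequence = 0,
) -> list[AmpliconLocus]:
    """Generate the synthetic 8-locus panel, deterministic under the seed."""
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = ss.spawn(len(DEFAULT_PANEL_CLASSES))
    panel = []
    for (name, klass), child in zip(DEFAULT_PANEL_CLASSES.items(), children):
        rng = np.random.default_rng(child)
        ref, cpg, noncpg = _make_reference(n_cpgs_per_locus, amplicon_length, rng)
        panel.append(
            AmpliconLocus(
                name=name,
                imprint_class=klass,
                reference=ref,
                cpg_positions=cpg,
                non_cpg_c_positions=noncpg,
            )
        )
    return panel


def write_panel(panel: list[AmpliconLocus], tsv_path, fasta_path) -> None:
    """Write the panel table (TSV, 0-based offsets) and reference FASTA."""
    rows = [
        {
            "name": loc.name,
            "imprint_class": loc.imprint_class,
            "cpg_positions": ",".join(map(str, loc.cpg_positions)),
            "non_cpg_c_positions": ",".join(map(str, loc.non_cpg_c_positions)),
        }
        for loc in panel
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    records = [
        SeqRecord(Seq(loc.reference), id=loc.name, description=loc.imprint_class)
        for loc in panel
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_panel(tsv_path, fasta_path) -> list[AmpliconLocus]:
    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(tsv_path, sep="\t")
    panel = []
    for row in table.itertuples(index=False):
        if row.name not in refs:
            raise FileNotFoundError(
                f"locus {row.name} in {tsv_path} missing from {fasta_path}"
            )
        panel.append(
            AmpliconLocus(
                name=row.name,
                imprint_class=row.imprint_class,
                reference=refs[row.name],
                cpg_positions=tuple(
                    int(x) for x in str(row.cpg_positions).split(",")
                ),
                non_cpg_c_positions=tuple(
                    int(x) for x in str(row.non_cpg_c_positions).split(",")
                ),
            )
        )
    return panel
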