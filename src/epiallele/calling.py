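"""Read-level methylation calling for deep bisulfite sequencing amplicons.

This stage turns raw amplicon reads into per-allele methylation patterns:
demultiplex barcoded reads, align each read
against its locus reference with the bisulfite-asymmetric aligner, call the
per-CpG pattern (M/U/N) of every read, estimate each read's bisulfite
conversion rate from non-CpG cytosines, filter on conversion and alignment
coverage, and summarize each sample x locus into mean methylation and
read-class (fully methylated / fully unmethylated / mosaic) proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Alignment, Scoring, align_bisulfite
from .panel import AmpliconLocus

CALL_M, CALL_U, CALL_N = "M", "U", "N"


@dataclass
class ReadPattern:
    """Per-read CpG methylation calls: one 'line' of a single-allele plot."""

    read_id: str
    locus: str
    orientation: str
    calls: str  # one of M/U/N per CpG of the locus
    conversion_rate_read: float | None
    aligned_fraction: float
    pass_qc: bool = False
    fail_reason: str = ""

    @property
    def m_fraction(self) -> float | None:
        """Fraction of M among non-N calls; None if every call is N."""
        informative = len(self.calls) - self.calls.count(CALL_N)
        if informative == 0:
            return None
        return self.calls.count(CALL_M) / informative


@dataclass
class LocusSummary:
    """Per sample x locus aggregate over passing reads."""

    sample_id: str
    locus: str
    n_reads_pass: int
    mean_methylation: float  # percent, mean over reads of per-read M fraction
    p_unmeth: float
    p_meth: float
    p_mosaic: float
    # class-conditional mean methylation (%), used by the bootstrap; NaN if
    # the class is empty
    mean_meth_unmeth: float = float("nan")
    mean_meth_meth: float = float("nan")
    mean_meth_mosaic: float = float("nan")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads,
    barcode_table: dict[str, str],
    max_mismatches: int = 1,
):
    """Assign reads to samples by their MID (multiplex identifier) prefix.

    ``reads`` is an iterable of ``(read_id, sequence)``. Every read is
    assigned to the unique MID within ``max_mismatches`` of its prefix (the
    MID, and nothing else, is trimmed), or to the unassigned bin. Returns
    ``(per_sample, unassigned)``.
    """
    mids = list(barcode_table)
    if len({len(m) for m in mids}) > 1:
        raise ValueError("all MIDs must have equal length")
    for a, b in combinations(mids, 2):
        if hamming(a, b) <= 2 * max_mismatches:
            raise ValueError(
                f"MIDs {a!r} and {b!r} are within 2*max_mismatches; "
                "assignment would be ambiguous"
            )
    k = len(mids[0])
    per_sample: dict[str, list[tuple[str, str]]] = {
        sample: [] for sample in barcode_table.values()
    }
    unassigned: list[tuple[str, str]] = []
    for read_id, seq in reads:
        prefix = seq[:k].upper()
        hit = None
        if len(prefix) == k:
            for mid in mids:
                if hamming(prefix, mid.upper()) <= max_mismatches:
                    hit = mid
                    break
        if hit is None:
            unassigned.append((read_id, seq))
        else:
            per_sample[barcode_table[hit]].append((read_id, seq[k:]))
    return per_sample, unassigned


def call_read_pattern(alignment: Alignment, locus: AmpliconLocus) -> ReadPattern:
    """Derive the per-CpG M/U/N calls and QC metrics from one alignment."""
    ref2read = alignment.ref_to_read
    read = alignment.aligned_read
    calls = []
    for p in locus.cpg_positions:
        k = ref2read[p]
        if k < 0:
            calls.append(CALL_N)
            continue
        base = read[k]
        calls.append(CALL_M if base == "C" else CALL_U if base == "T" else CALL_N)
    n_aligned_c = 0
    n_converted = 0
    for p in locus.non_cpg_c_positions:
        k = ref2read[p]
        if k >= 0:
            n_aligned_c += 1
            if read[k] == "T":
                n_converted += 1
    conversion = n_converted / n_aligned_c if n_aligned_c else None
    aligned_fraction = float(np.count_nonzero(ref2read >= 0)) / locus.length
    return ReadPattern(
        read_id="",
        locus=locus.name,
        orientation=alignment.orientation,
        calls="".join(calls),
        conversion_rate_read=conversion,
        aligned_fraction=aligned_fraction,
    )


def call_reads(
    reads,
    locus: AmpliconLocus,
    scoring: Scoring = Scoring(),
    band: int | None = 16,
) -> list[ReadPattern]:
    """Align and call every ``(read_id, sequence)`` against one locus."""
    patterns = []
    for read_id, seq in reads:
        aln = align_bisulfite(seq, locus, scoring=scoring, band=band)
        pattern = call_read_pattern(aln, locus)
        pattern.read_id = read_id
        patterns.append(pattern)
    return patterns


def filter_reads(
    patterns: list[ReadPattern],
    min_conversion: float = 0.95,
    min_aligned: float = 0.8,
) -> tuple[list[ReadPattern], dict]:
    """QC-gate read patterns; returns passing patterns and a filter report."""
    for name, value in (("min_conversion", min_conversion), ("min_aligned", min_aligned)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    passing = []
    report = {
        "n_input": len(patterns),
        "n_pass": 0,
        "fail_aligned": 0,
        "fail_no_conversion_estimate": 0,
        "fail_conversion": 0,
    }
    for p in patterns:
        if p.aligned_fraction < min_aligned:
            p.pass_qc, p.fail_reason = False, "aligned"
            report["fail_aligned"] += 1
        elif p.conversion_rate_read is None:
            p.pass_qc, p.fail_reason = False, "no_conversion_estimate"
            report["fail_no_conversion_estimate"] += 1
        elif p.conversion_rate_read < min_conversion:
            p.pass_qc, p.fail_reason = False, "conversion"
            report["fail_conversion"] += 1
        else:
            p.pass_qc, p.fail_reason = True, ""
            report["n_pass"] += 1
            passing.append(p)
    return passing, report


def classify_read(pattern: ReadPattern, read_class_max_minor: float = 0.1) -> str | None:
    """'unmeth' / 'meth' / 'mosaic' by the minor-call threshold; None if no calls."""
    mf = pattern.m_fraction
    if mf is None:
        return None
    if mf <= read_class_max_minor:
        return "unmeth"
    if mf >= 1.0 - read_class_max_minor:
        return "meth"
    return "mosaic"


def summarize_locus(
    patterns: list[ReadPattern],
    sample_id: str,
    locus: str | None = None,
    read_class_max_minor: float = 0.1,
) -> LocusSummary | None:
    """Aggregate passing reads of one sample x locus; None if no usable read.

    A read counts as unmethylated if its M fraction (over non-N calls) is at
    most ``read_class_max_minor``, methylated if at least 1 - that, and mosaic
    otherwise. Zero passing reads yield an explicit missing summary (None),
    never a fabricated 0%.
    """
    usable = [p for p in patterns if p.pass_qc and p.m_fraction is not None]
    if not usable:
        return None
    if locus is None:
        locus = usable[0].locus
    mfracs = np.array([p.m_fraction for p in usable])
    classes = np.array([classify_read(p, read_class_max_minor) for p in usable])
    n = len(usable)

    def class_stats(name):
        sel = mfracs[classes == name]
        return sel.size / n, 100.0 * sel.mean() if sel.size else float("nan")

    p_u, m_u = class_stats("unmeth")
    p_m, m_m = class_stats("meth")
    p_x, m_x = class_stats("mosaic")
    return LocusSummary(
        sample_id=sample_id,
        locus=locus,
        n_reads_pass=n,
        mean_methylation=100.0 * float(mfracs.mean()),
        p_unmeth=p_u,
        p_meth=p_m,
        p_mosaic=p_x,
        mean_meth_unmeth=m_u,
        mean_meth_meth=m_m,
        mean_meth_mosaic=m_x,
    )


def export_pattern_matrix(patterns: list[ReadPattern], path, locus: AmpliconLocus) -> None:
    """Write the read x CpG matrix (rows sorted by descending M fraction).

    Columns are labeled with 1-based CpG cytosine positions; cells are M/U/N.
    """
    path = Path(path)
    header = ["read_id"] + [f"CpG_{p + 1}" for p in locus.cpg_positions]
    rows = sorted(
        patterns,
        key=lambda p: (-(p.m_fraction if p.m_fraction is not None else -1.0), p.read_id),
    )
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for p in rows:
                fh.write("\t".join([p.read_id, *p.calls]) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing pattern matrix to {path}: {exc}") from exc
    if not patterns:
        warnings.warn(f"no read patterns; wrote header-only matrix to {path}")


def summaries_to_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def frame_to_summaries(frame: pd.DataFrame) -> list[LocusSummary]:
    return [LocusSummary(**row) for row in frame.to_dict("records")]


def call_sample(
    reads_by_locus: dict[str, list[tuple[str, str]]],
    panel: list[AmpliconLocus],
    sample_id: str,
    min_conversion: float = 0.95,
    min_aligned: float = 0.8,
    read_class_max_minor: float = 0.1,
    scoring: Scoring = Scoring(),
    band: int | None = 16,
):
    """Run call -> filter -> summarize for every locus of one sample.

    Returns ``(summaries, patterns_by_locus, filter_reports)``.
    """
    by_name = {loc.name: loc for loc in panel}
    summaries: list[LocusSummary] = []
    patterns_by_locus: dict[str, list[ReadPattern]] = {}
    reports: dict[str, dict] = {}
    for locus_name, reads in reads_by_locus.items():
        locus = by_name[locus_name]
        patterns = call_reads(reads, locus, scoring=scoring, band=band)
        passing, report = filter_reads(patterns, min_conversion, min_aligned)
        patterns_by_locus[locus_name] = patterns
        reports[locus_name] = report
        summary = summarize_locus(
            passing, sample_id, locus_name, read_class_max_minor
        )
        if summary is not None:
            summaries.append(summary)
    return summaries, patterns_by_locus, reports


def group_reads_by_locus(
    reads: list[tuple[str, str]], locus_names: list[str]
) -> dict[str, list[tuple[str, str]]]:
    """Group reads whose ids encode the locus (``sample|locus|index``)."""
    known = set(locus_names)
    grouped: dict[str, list[tuple[str, str]]] = {name: [] for name in locus_names}
    for read_id, seq in reads:
        parts = read_id.split("|")
        if len(parts) >= 2 and parts[1] in known:
            grouped[parts[1]].append((read_id, seq))
    return grouped
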