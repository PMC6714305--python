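"""End-to-end pipeline: simulate -> call -> gate -> estimate -> assess -> stats.

A single seed in the run configuration fans out to per-stage child seeds by
stable derivation (`numpy.random.SeedSequence.spawn`), so each stage is
independently reproducible. Re-running an identical configuration reproduces
byte-identical TSV outputs; the manifest records the configuration hash and a
checksum of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, mixture, simulate, stats
from .panel import make_locus_panel, write_panel
from .simulate import SampleSpec

log = logging.getLogger("epiallele")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 1
    out_dir: str = "runs/demo"
    # panel
    n_cpgs_per_locus: int = 10
    amplicon_length: int = 200
    # noise defaults applied to cohort specs that do not override them
    conversion_rate: float = 0.995
    seq_error_rate: float = 0.002
    n_reads_per_locus: int = 500
    # thresholds
    min_conversion: float = 0.95
    min_aligned: float = 0.8
    read_class_max_minor: float = 0.1
    purity_threshold: float = 4.0
    tolerance_delta: float = 10.0
    n_bootstrap: int = 1000
    band: int = 16
    # cohort: list of SampleSpec field dicts
    cohort: list = field(default_factory=list)

    def specs(self) -> list[SampleSpec]:
        specs = []
        for entry in self.cohort:
            entry = dict(entry)
            entry.setdefault("n_reads_per_locus", self.n_reads_per_locus)
            entry.setdefault("conversion_rate", self.conversion_rate)
            entry.setdefault("seq_error_rate", self.seq_error_rate)
            specs.append(SampleSpec(**entry))
        return specs

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir is a storage location, not part of the scientific config
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _spec_dict(sample_id, patient_id, group, fraction, karyotype, f, **extra):
    d = {
        "sample_id": sample_id,
        "patient_id": patient_id,
        "group": group,
        "fraction": fraction,
        "karyotype": karyotype,
        "germ_fraction": f,
    }
    d.update(extra)
    return d


def make_demo_cohort(seed: int = 1, n_reads_per_locus: int = 500,
                     out_dir: str = "runs/demo") -> RunConfig:
    """The demonstration cohort mirroring the study's group sizes.

    Normal group: five SN, four AT, three SCO, five blood, six sperm. KS
    group: seven blood, three SN + three AT from KS+ patients (47,XXY, with
    germ cells), three AT from KS- patients. The three KS+ patients carry the
    three distinct germ-compartment anomalies (H19 loses its germline
    methylation; MEG3 gains methylation; MEST sits at the somatic level, so
    its germ alleles produce no shift); LIT1 is intact in all of them.
    """
    cohort: list[dict] = []
    # differential plating of normal tissue yields highly pure SN fractions
    # (the retained ones sit well below the 4% DDX4 gate)
    sn_f = [1.0, 0.995, 0.99, 0.99, 0.985]
    at_f = [0.05, 0.08, 0.03, 0.10]
    for i, f in enumerate(sn_f, 1):
        cohort.append(_spec_dict(f"N{i}_SN", f"N{i}", "normal", "SN", "46,XY", f))
    for i, f in enumerate(at_f, 1):
        cohort.append(_spec_dict(f"N{i}_AT", f"N{i}", "normal", "AT", "46,XY", f))
    for i in range(1, 4):
        cohort.append(_spec_dict(f"SCO{i}_AT", f"SCO{i}", "normal", "SCO", "46,XY", 0.0))
    for i in range(1, 6):
        cohort.append(_spec_dict(f"B{i}", f"B{i}", "normal", "blood", "46,XY", 0.0))
    for i in range(1, 7):
        cohort.append(_spec_dict(f"SP{i}", f"SP{i}", "normal", "sperm", "46,XY", 1.0))
    for i in range(1, 8):
        cohort.append(_spec_dict(f"KSB{i}", f"KSB{i}", "KS", "blood", "47,XXY", 0.0))
    ks_sn_f = [0.6, 0.5, 0.7]
    ks_at_f = [0.03, 0.05, 0.02]
    anomalies = [{"H19": -1.0}, {"MEG3": 1.0}, {"MEST": 0.5}]
    for i, (fsn, fat, anomaly) in enumerate(zip(ks_sn_f, ks_at_f, anomalies), 1):
        cohort.append(
            _spec_dict(f"KS{i}_SN", f"KS{i}", "KS", "SN", "47,XXY", fsn,
                       epimutations=anomaly)
        )
        cohort.append(
            _spec_dict(f"KS{i}_AT", f"KS{i}", "KS", "AT", "47,XXY", fat,
                       epimutations=anomaly)
        )
    for i in range(1, 4):
        cohort.append(_spec_dict(f"KSm{i}_AT", f"KSm{i}", "KS", "AT", "47,XXY", 0.0))
    return RunConfig(seed=seed, out_dir=out_dir,
                     n_reads_per_locus=n_reads_per_locus, cohort=cohort)


def paired_patient_specs(
    patient_id: str,
    group: str = "normal",
    karyotype: str = "46,XY",
    f_AT: float = 0.05,
    f_SN: float = 0.98,
    n_reads_per_locus: int = 500,
    epimutations: dict[str, float] | None = None,
    **noise,
) -> list[SampleSpec]:
    """Convenience: one patient's AT/SN pair with shared ground truth."""
    epim = epimutations or {}
    common = dict(group=group, karyotype=karyotype,
                  n_reads_per_locus=n_reads_per_locus, epimutations=epim, **noise)
    return [
        SampleSpec(sample_id=f"{patient_id}_AT", patient_id=patient_id,
                   fraction="AT", germ_fraction=f_AT, **common),
        SampleSpec(sample_id=f"{patient_id}_SN", patient_id=patient_id,
                   fraction="SN", germ_fraction=f_SN, **common),
    ]


def analyze_cohort(
    panel,
    reads_by_sample,
    sheet: pd.DataFrame,
    config: RunConfig,
    rng_seed,
):
    """Call, gate, estimate and assess an in-memory cohort.

    Returns a dict with summaries, filter reports, gate report, fraction
    estimates, assessments, skipped assessments and the cohort report.
    """
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    seed_estimates, seed_assess = ss.spawn(2)
    locus_names = [loc.name for loc in panel]

    summaries: list[calling.LocusSummary] = []
    patterns_all: dict[str, dict] = {}
    filter_reports: dict[str, dict] = {}
    for sid in sheet["sample_id"]:
        reads = reads_by_sample[sid]
        by_locus = reads.reads if isinstance(reads, simulate.SampleReads) else reads
        s, patterns, reports = calling.call_sample(
            by_locus, panel, sid,
            min_conversion=config.min_conversion,
            min_aligned=config.min_aligned,
            read_class_max_minor=config.read_class_max_minor,
            band=config.band,
        )
        summaries.extend(s)
        patterns_all[sid] = patterns
        filter_reports[sid] = reports

    included, excluded, gate_report = mixture.purity_gate(
        summaries, sheet, threshold=config.purity_threshold
    )
    excluded_set = set(excluded)

    estimates: dict[str, mixture.FractionEstimate] = {}
    est_children = iter(seed_estimates.spawn(len(sheet)))
    for sid in sheet["sample_id"]:
        child = next(est_children)
        sample_summaries = [s for s in summaries if s.sample_id == sid]
        est = mixture.estimate_germ_fraction(
            sample_summaries, n_bootstrap=config.n_bootstrap, rng_seed=child
        )
        if est is not None:
            estimates[sid] = est

    # assess patients that have both an AT and a (gate-surviving) SN fraction
    assessments: list[mixture.ShiftAssessment] = []
    skipped: list[dict] = []
    patients = sheet.drop_duplicates("patient_id")
    assess_children = iter(seed_assess.spawn(len(patients)))
    for row in patients.itertuples(index=False):
        child = next(assess_children)
        sub = sheet[sheet["patient_id"] == row.patient_id]
        at_ids = set(sub.loc[sub["fraction"] == "AT", "sample_id"])
        sn_ids = set(sub.loc[sub["fraction"] == "SN", "sample_id"]) - excluded_set
        if not at_ids or not sn_ids:
            continue
        a, s = mixture.assess_patient(
            row.patient_id,
            panel,
            [x for x in summaries if x.sample_id in at_ids],
            [x for x in summaries if x.sample_id in sn_ids],
            estimates,
            karyotype=row.karyotype,
            tolerance_delta=config.tolerance_delta,
            n_bootstrap=config.n_bootstrap,
            rng_seed=child,
        )
        assessments.extend(a)
        skipped.extend(s)

    report = mixture.cohort_report(assessments, estimates, summaries, sheet)
    return {
        "summaries": summaries,
        "patterns": patterns_all,
        "filter_reports": filter_reports,
        "gate_report": gate_report,
        "gate_included": included,
        "gate_excluded": excluded,
        "estimates": estimates,
        "assessments": assessments,
        "skipped_assessments": skipped,
        "cohort_report": report,
    }


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages into ``config.out_dir``; returns the run directory."""
    specs = config.specs()
    if not specs:
        raise ValueError("configuration defines an empty cohort")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "init"
    try:
        ss = np.random.SeedSequence(config.seed)
        seed_panel, seed_cohort, seed_analysis = ss.spawn(3)

        stage = "panel"
        panel = make_locus_panel(
            config.n_cpgs_per_locus, config.amplicon_length, rng_seed=seed_panel
        )
        write_panel(panel, out / "panel.tsv", out / "reference.fa")
        log.info("panel: %d loci", len(panel))

        stage = "simulate"
        reads_by_sample, truth, sheet = simulate.simulate_cohort(
            panel, specs, rng_seed=seed_cohort, out_dir=out
        )
        log.info("simulate: %d samples", len(specs))

        stage = "analyze"
        result = analyze_cohort(panel, reads_by_sample, sheet, config, seed_analysis)
        _write_tsv(calling.summaries_to_frame(result["summaries"]), out / "summaries.tsv")
        with open(out / "filter_report.json", "w") as fh:
            json.dump(result["filter_reports"], fh, indent=2, sort_keys=True)
        with open(out / "purity_gate.json", "w") as fh:
            json.dump(result["gate_report"], fh, indent=2, sort_keys=True)
        patterns_dir = out / "patterns"
        patterns_dir.mkdir(exist_ok=True)
        by_name = {loc.name: loc for loc in panel}
        for sid, by_locus in result["patterns"].items():
            for locus_name, patterns in by_locus.items():
                calling.export_pattern_matrix(
                    patterns, patterns_dir / f"{sid}.{locus_name}.tsv", by_name[locus_name]
                )
        est_rows = [
            {
                "sample_id": sid,
                "f_hat": e.f_hat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_reads_used": e.n_reads_used,
                **{f"f_{k}": v for k, v in e.per_locus_f.items()},
            }
            for sid, e in result["estimates"].items()
        ]
        _write_tsv(pd.DataFrame(est_rows), out / "fraction_estimates.tsv")
        _write_tsv(
            pd.DataFrame([vars(a) for a in result["assessments"]]),
            out / "assessments.tsv",
        )
        with open(out / "cohort_report.json", "w") as fh:
            json.dump(result["cohort_report"], fh, indent=2, sort_keys=True)
        _write_tsv(
            pd.DataFrame(result["cohort_report"]["paired_plot_data"]),
            out / "paired_plot_data.tsv",
        )

        stage = "stats"
        summaries_frame = calling.summaries_to_frame(result["summaries"])
        comparisons = []
        gated_out = set(result["gate_excluded"])
        kept = summaries_frame[~summaries_frame["sample_id"].isin(gated_out)]
        normal_sheet = sheet[sheet["group"] == "normal"]
        for loc in panel:
            try:
                comparisons.append(
                    stats.compare_locus(kept, normal_sheet, loc.name,
                                        group_by="fraction")
                )
            except ValueError as exc:
                log.info("stats: skipping %s (%s)", loc.name, exc)
        _write_tsv(stats.comparisons_to_frame(comparisons), out / "group_stats.tsv")
        _write_tsv(stats.pairwise_to_frame(comparisons), out / "pairwise_p.tsv")

        stage = "manifest"
        config.to_yaml(out / "config.yaml")
        artifacts = sorted(
            p.relative_to(out).as_posix()
            for p in out.rglob("*")
            if p.is_file() and p.name not in ("run.log", "manifest.json")
        )
        manifest = {
            "config_hash": config.config_hash(),
            "artifacts": {
                a: hashlib.sha256((out / a).read_bytes()).hexdigest()
                for a in artifacts
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("run complete: %s", out)
        return out
    except Exception as exc:
        log.exception("pipeline failed at stage %r; partial outputs kept in %s",
                      stage, out)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
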