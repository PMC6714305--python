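"""Germ/soma mixture inference and imprinting-aberration flagging.

The testicular cell fractions are two-compartment mixtures of germ cells
(proportion ``f``) and somatic cells. Three inferences are implemented:

1. **Purity gate** — germ-cell-enriched SN fractions from normozoospermic
   donors are excluded when the germ-marker VASA/DDX4 shows mean methylation
   above 4% (somatic contamination). KS SN fractions bypass the gate: for
   these patients only enrichment, not purification, is achievable.

2. **Germ-cell fraction estimation** — germ-marker loci are fully methylated
   in soma and fully unmethylated in germ cells, so the proportion of
   unmethylated reads estimates ``f`` directly. The point estimate is the
   read-count-weighted mean over the germ-marker loci; uncertainty comes from
   a seeded nonparametric bootstrap over reads (resampling read classes).

3. **Expected-shift model and aberration flags** — for a patient with a
   somatic-rich AT fraction and a germ-cell-enriched SN fraction, the somatic
   reference level ``s`` is recovered from the AT measurement by inverting the
   mixture, ``s = (m_AT - f_AT * g) / (1 - f_AT)`` with ``g`` the germ-line
   level of the locus class (0 or 100%), and the SN methylation expected under
   intact imprinting is ``m_expected = (1 - f_SN) * s + f_SN * g``. Deviations
   are flagged by three explicit rules (wrong_direction, no_shift, magnitude)
   that correspond one-to-one to the qualitative anomaly types seen in KS
   germ-cell fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import LocusSummary

GERM_MARKER_LOCI = ("FGFR3", "DDX4", "RHOXF1")

#: germ-line reference methylation level (%) by locus class
GERM_LEVEL = {
    "maternal_imprint": 0.0,
    "germ_marker": 0.0,
    "x_inactivation": 0.0,
    "paternal_imprint": 100.0,
}


def expected_sign(locus_class: str) -> str:
    """Expected direction of the AT -> SN methylation shift: 'down' or 'up'."""
    return "up" if locus_class == "paternal_imprint" else "down"


@dataclass
class FractionEstimate:
    """Estimated germ-cell fraction of one sample, with bootstrap CI."""

    sample_id: str
    f_hat: float
    per_locus_f: dict[str, float]
    ci_low: float
    ci_high: float
    n_reads_used: int


@dataclass
class ShiftAssessment:
    """Observed vs expected AT -> SN methylation shift at one locus."""

    patient_id: str
    locus: str
    m_AT: float
    m_SN: float
    f_hat: float  # f of the SN fraction
    expected_sign: str
    m_expected: float
    delta: float  # m_SN - m_expected
    aberrant: bool
    reason: str


def purity_gate(
    summaries: list[LocusSummary],
    sheet: pd.DataFrame,
    marker: str = "DDX4",
    threshold: float = 4.0,
) -> tuple[list[str], list[str], dict]:
    """Apply the germ-marker purity gate to the purity-gated samples.

    A gated sample is excluded iff its marker mean methylation is strictly
    above ``threshold`` percent (a sample at exactly the threshold is kept).
    Gated samples without a marker summary are flagged unevaluable rather
    than silently included. Returns ``(included, excluded, report)`` over the
    gated samples only.
    """
    marker_meth = {
        s.sample_id: s.mean_methylation for s in summaries if s.locus == marker
    }
    gated = sheet.loc[sheet["purity_gated"], "sample_id"].tolist()
    included, excluded, unevaluable = [], [], []
    values = {}
    for sid in gated:
        if sid not in marker_meth:
            unevaluable.append(sid)
            continue
        values[sid] = marker_meth[sid]
        (excluded if marker_meth[sid] > threshold else included).append(sid)
    report = {
        "marker": marker,
        "threshold_percent": threshold,
        "included": {sid: values[sid] for sid in included},
        "excluded": {sid: values[sid] for sid in excluded},
        "unevaluable": unevaluable,
    }
    return included, excluded, report


def _bootstrap_class_counts(
    rng: np.random.Generator, n: int, probs: np.ndarray, n_bootstrap: int
) -> np.ndarray:
    """(n_bootstrap, 3) multinomial resamples of read-class counts."""
    return rng.multinomial(n, probs, size=n_bootstrap)


def estimate_germ_fraction(
    summaries: list[LocusSummary],
    germ_marker_loci=GERM_MARKER_LOCI,
    n_bootstrap: int = 1000,
    rng_seed: int | np.random.SeedSequence = 0,
) -> FractionEstimate | None:
    """Estimate a sample's germ-cell fraction from germ-marker loci.

    Per-locus f is the proportion of (fully) unmethylated reads; the point
    estimate is the read-count-weighted mean; the 95% CI is a percentile
    bootstrap over read classes. Returns None (explicit missing state) if no
    germ-marker locus has passing reads.
    """
    markers = [s for s in summaries if s.locus in germ_marker_loci]
    if not markers:
        return None
    sample_ids = {s.sample_id for s in markers}
    if len(sample_ids) != 1:
        raise ValueError("summaries must come from a single sample")
    n_total = sum(s.n_reads_pass for s in markers)
    f_hat = sum(s.p_unmeth * s.n_reads_pass for s in markers) / n_total
    rng = np.random.default_rng(rng_seed)
    boot_unmeth = np.zeros(n_bootstrap)
    for s in markers:
        probs = np.clip([s.p_unmeth, s.p_meth, s.p_mosaic], 0.0, None)
        probs = probs / probs.sum()
        counts = _bootstrap_class_counts(rng, s.n_reads_pass, probs, n_bootstrap)
        boot_unmeth += counts[:, 0]
    boot_f = boot_unmeth / n_total
    ci_low, ci_high = np.percentile(boot_f, [2.5, 97.5])
    return FractionEstimate(
        sample_id=markers[0].sample_id,
        f_hat=float(f_hat),
        per_locus_f={s.locus: float(s.p_unmeth) for s in markers},
        ci_low=float(min(ci_low, f_hat)),
        ci_high=float(max(ci_high, f_hat)),
        n_reads_used=n_total,
    )


def expected_methylation(
    locus_class: str,
    karyotype: str,
    m_AT: float,
    f_AT: float,
    f_SN: float,
) -> float:
    """Expected SN methylation (%) under intact imprinting.

    The somatic reference level is inferred from the patient's own AT
    fraction by inverting the mixture (absorbing residual germ cells in AT);
    the karyotype enters only through the measured m_AT.
    """
    if not 0.0 <= f_AT < 1.0:
        raise ValueError("f_AT must lie in [0, 1); the soma reference is "
                         "undefined for a pure germ AT fraction")
    if not f_AT <= f_SN <= 1.0:
        raise ValueError("require f_AT <= f_SN <= 1")
    g = GERM_LEVEL[locus_class]
    s = (m_AT - f_AT * g) / (1.0 - f_AT)
    return float(np.clip((1.0 - f_SN) * s + f_SN * g, 0.0, 100.0))


def _bootstrap_mean_meth(
    rng: np.random.Generator, summary: LocusSummary, n_bootstrap: int
) -> np.ndarray:
    """Bootstrap distribution of a sample's mean methylation (%).

    Read classes are resampled multinomially; within-class mean methylation
    is held at its observed value (within-class spread is negligible for
    near-binary epialleles).
    """
    probs = np.clip(
        [summary.p_unmeth, summary.p_meth, summary.p_mosaic], 0.0, None
    )
    probs = probs / probs.sum()
    means = np.array(
        [summary.mean_meth_unmeth, summary.mean_meth_meth, summary.mean_meth_mosaic]
    )
    means = np.where(probs > 0, means, 0.0)  # empty classes never drawn
    counts = rng.multinomial(summary.n_reads_pass, probs, size=n_bootstrap)
    return counts @ means / summary.n_reads_pass


def assess_shift(
    patient_id: str,
    locus_class: str,
    at_summary: LocusSummary,
    sn_summary: LocusSummary,
    f_AT: float,
    f_SN: float,
    karyotype: str = "47,XXY",
    tolerance_delta: float = 10.0,
    n_bootstrap: int = 1000,
    rng_seed: int | np.random.SeedSequence = 0,
) -> ShiftAssessment:
    """Flag a locus whose AT -> SN shift deviates from the mixture model.

    Rules, tried in order (first hit wins):

    - ``wrong_direction`` — the observed shift is real (outside the bootstrap
      95% null width) and opposes the expected direction while the expected
      magnitude exceeds ``tolerance_delta``;
    - ``no_shift`` — the observed shift is within the bootstrap 95% null
      width of zero while the expected magnitude exceeds ``tolerance_delta``;
    - ``magnitude`` — |m_SN - m_expected| exceeds ``tolerance_delta`` and the
      SN bootstrap CI excludes m_expected.
    """
    m_at = at_summary.mean_methylation
    m_sn = sn_summary.mean_methylation
    m_exp = expected_methylation(locus_class, karyotype, m_at, f_AT, f_SN)
    sign = expected_sign(locus_class)
    delta = m_sn - m_exp
    expected_shift = m_exp - m_at
    observed_shift = m_sn - m_at

    rng = np.random.default_rng(rng_seed)
    boot_at = _bootstrap_mean_meth(rng, at_summary, n_bootstrap)
    boot_sn = _bootstrap_mean_meth(rng, sn_summary, n_bootstrap)
    null_width = float(
        np.percentile(np.abs((boot_sn - boot_at) - observed_shift), 95.0)
    )
    sn_lo, sn_hi = np.percentile(boot_sn, [2.5, 97.5])

    aberrant, reason = False, ""
    opposes = (sign == "up" and observed_shift < 0) or (
        sign == "down" and observed_shift > 0
    )
    if (
        opposes
        and abs(observed_shift) > null_width
        and abs(expected_shift) > tolerance_delta
    ):
        aberrant, reason = True, "wrong_direction"
    elif abs(observed_shift) <= null_width and abs(expected_shift) > tolerance_delta:
        aberrant, reason = True, "no_shift"
    elif abs(delta) > tolerance_delta and not (sn_lo <= m_exp <= sn_hi):
        aberrant, reason = True, "magnitude"
    return ShiftAssessment(
        patient_id=patient_id,
        locus=at_summary.locus,
        m_AT=float(m_at),
        m_SN=float(m_sn),
        f_hat=float(f_SN),
        expected_sign=sign,
        m_expected=float(m_exp),
        delta=float(delta),
        aberrant=aberrant,
        reason=reason,
    )


def assess_patient(
    patient_id: str,
    panel,
    at_summaries: list[LocusSummary],
    sn_summaries: list[LocusSummary],
    estimates: dict[str, FractionEstimate],
    karyotype: str,
    tolerance_delta: float = 10.0,
    n_bootstrap: int = 1000,
    rng_seed: int | np.random.SeedSequence = 0,
) -> tuple[list[ShiftAssessment], list[dict]]:
    """Assess every non-marker locus of one AT/SN patient pair.

    Loci that cannot be assessed (missing pair member, missing f estimates,
    f_AT > f_SN) are skipped with a logged reason. Returns
    ``(assessments, skipped)``.
    """
    at_by_locus = {s.locus: s for s in at_summaries}
    sn_by_locus = {s.locus: s for s in sn_summaries}
    at_ids = {s.sample_id for s in at_summaries}
    sn_ids = {s.sample_id for s in sn_summaries}
    skipped: list[dict] = []

    def skip(locus, why):
        skipped.append({"patient_id": patient_id, "locus": locus, "reason": why})

    def first_estimate(ids):
        for sid in ids:
            if sid in estimates:
                return estimates[sid]
        return None

    est_at = first_estimate(at_ids)
    est_sn = first_estimate(sn_ids)
    non_marker = [loc for loc in panel if loc.imprint_class != "germ_marker"]
    if est_at is None or est_sn is None:
        for loc in non_marker:
            skip(loc.name, "missing_fraction_estimate")
        return [], skipped
    f_at, f_sn = est_at.f_hat, est_sn.f_hat
    assessments = []
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = iter(ss.spawn(len(non_marker)))
    for loc in non_marker:
        child = next(children)
        if loc.name not in at_by_locus or loc.name not in sn_by_locus:
            skip(loc.name, "missing_pair_member")
            continue
        if not (0.0 <= f_at < 1.0 and f_at <= f_sn <= 1.0):
            skip(loc.name, "fraction_estimates_inconsistent")
            continue
        assessments.append(
            assess_shift(
                patient_id,
                loc.imprint_class,
                at_by_locus[loc.name],
                sn_by_locus[loc.name],
                f_at,
                f_sn,
                karyotype=karyotype,
                tolerance_delta=tolerance_delta,
                n_bootstrap=n_bootstrap,
                rng_seed=child,
            )
        )
    return assessments, skipped


def cohort_report(
    assessments: list[ShiftAssessment],
    estimates: dict[str, FractionEstimate],
    summaries: list[LocusSummary],
    sheet: pd.DataFrame,
) -> dict:
    """Structured cohort summary: flags per patient/locus, per-group counts,
    and paired AT -> SN line-plot data."""
    if not assessments:
        assessment_table = pd.DataFrame(
            columns=[
                "patient_id", "locus", "m_AT", "m_SN", "f_hat", "expected_sign",
                "m_expected", "delta", "aberrant", "reason",
            ]
        )
    else:
        assessment_table = pd.DataFrame([vars(a) for a in assessments])
    group_of_patient = dict(zip(sheet["patient_id"], sheet["group"]))
    flags = assessment_table[assessment_table.get("aberrant", pd.Series(dtype=bool)) == True]  # noqa: E712
    per_group: dict[str, int] = {}
    for pid in flags.get("patient_id", []):
        g = group_of_patient.get(pid, "?")
        per_group[g] = per_group.get(g, 0) + 1
    # paired line-plot rows: one per patient x locus with both fractions
    meth = pd.DataFrame([vars(s) for s in summaries]) if summaries else pd.DataFrame()
    plot_rows = []
    if not meth.empty:
        merged = meth.merge(
            sheet[["sample_id", "patient_id", "fraction", "group"]], on="sample_id"
        )
        pairs = merged[merged["fraction"].isin(["AT", "SN"])]
        wide = pairs.pivot_table(
            index=["patient_id", "group", "locus"],
            columns="fraction",
            values="mean_methylation",
        ).reset_index()
        if {"AT", "SN"} <= set(wide.columns):
            wide = wide.dropna(subset=["AT", "SN"])
            plot_rows = wide.rename(columns={"AT": "m_AT", "SN": "m_SN"}).to_dict(
                "records"
            )
    return {
        "n_patients_assessed": int(assessment_table["patient_id"].nunique())
        if not assessment_table.empty
        else 0,
        "n_aberrant": int(len(flags)),
        "aberrant_by_group": per_group,
        "aberrant_pairs": [
            {"patient_id": r.patient_id, "locus": r.locus, "reason": r.reason}
            for r in flags.itertuples(index=False)
        ]
        if not flags.empty
        else [],
        "assessments": assessment_table.to_dict("records"),
        "fraction_estimates": {
            sid: {
                "f_hat": est.f_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_reads_used": est.n_reads_used,
                "per_locus_f": est.per_locus_f,
            }
            for sid, est in estimates.items()
        },
        "paired_plot_data": plot_rows,
    }
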