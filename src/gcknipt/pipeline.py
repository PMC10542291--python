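"""End-to-end orchestration: files in, genotype calls, QC outcomes and the
diagnostic-accuracy and feasibility reports out.

Input dialects (UTF-8 CSV, header row, ISO-8601 dates, decimal gestational
weeks):

* ``samples.csv`` — one row per maternal cfDNA sample: pregnancy_id,
  sample_id, date_received, ga_weeks, assay_available, assay_specific,
  assay_preexisting, var_pos, var_tot, wt_pos, wt_tot, ff_method,
  ff_ch1_pos, ff_ch1_tot, ff_ch2_pos, ff_ch2_tot [, date_reported].
  Channel 1 of the fetal-fraction assay is the fetus-specific target
  (ZFY or the paternal SNP allele), channel 2 the reference (ZFX or the
  shared allele).
* ``scans.csv`` — pregnancy_id, ga_weeks, ac_mm.
* ``confirmed.csv`` — pregnancy_id, genotype (the reference standard).
* ``growth_standard.json`` — see :mod:`gcknipt.growth`.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._exceptions import EmptyStudyError, GckNiptError, InvalidInputError
from .accuracy import (
    PairedPredictions,
    accuracy_measures,
    bootstrap_auc_compare,
    build_contingency,
    generalized_score_compare,
    mcnemar_compare,
    roc_curve,
    youden_optimal_threshold,
)
from .ddpcr import (
    DropletCounts,
    InferenceSettings,
    call_genotype,
    fetal_fraction_from_snp,
    fetal_fraction_from_xy,
    genotype_posterior,
)
from .feasibility import TurnaroundRecord, turnaround_summary
from .growth import (
    Scan,
    ac_percentile,
    classify_by_ac,
    load_growth_standard,
    select_scan,
)
from .qc import Outcome, SampleRecord, apply_sample_qc, classify_pregnancy_outcome

__all__ = ["StudyConfig", "process_samples", "run_accuracy_study", "run_feasibility_study"]


@dataclass
class StudyConfig:
    """Paths, thresholds and statistics settings for one study run."""

    samples: Path
    scans: Path | None = None
    confirmed: Path | None = None
    growth_standard: Path | None = None
    outdir: Path = Path("results")
    conf_level: float = 0.95
    ac_thresholds: tuple[int, int] = (75, 90)
    n_boot: int = 2000
    seed: int = 0
    prior_nm: float = 0.5
    mcnemar_exact_cutoff: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("samples", "scans", "confirmed", "growth_standard", "outdir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        if "ac_thresholds" in raw:
            raw["ac_thresholds"] = tuple(raw["ac_thresholds"])
        return cls(**raw)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def _load_sample_records(path: Path, settings: InferenceSettings, prior_nm: float):
    """Parse samples.csv, run fetal-fraction estimation and the genotype
    caller on every analysable sample.  Returns (records by pregnancy,
    per-sample call rows, exclusion rows)."""
    df = pd.read_csv(path, dtype={"pregnancy_id": str, "sample_id": str})
    if df.empty:
        raise EmptyStudyError(f"{path}: no samples")
    by_pregnancy: dict[str, list[SampleRecord]] = {}
    call_rows = []
    exclusions = []
    for _, row in df.iterrows():
        pid, sid = row["pregnancy_id"], row["sample_id"]
        assay_available = _parse_bool(row["assay_available"])
        ff = None
        posterior = None
        reason = None
        if assay_available:
            try:
                ch1 = DropletCounts("ff_ch1", int(row["ff_ch1_pos"]), int(row["ff_ch1_tot"]))
                ch2 = DropletCounts("ff_ch2", int(row["ff_ch2_pos"]), int(row["ff_ch2_tot"]))
                if str(row["ff_method"]).strip().upper() == "XY":
                    ff = fetal_fraction_from_xy(ch1, ch2)
                else:
                    ff = fetal_fraction_from_snp(ch1, ch2)
                var = DropletCounts("variant", int(row["var_pos"]), int(row["var_tot"]))
                wt = DropletCounts("wildtype", int(row["wt_pos"]), int(row["wt_tot"]))
                posterior = genotype_posterior(var, wt, ff, prior_nm=prior_nm, settings=settings)
            except GckNiptError as exc:
                reason = f"assay_error:{type(exc).__name__}"
        date_reported = None
        if "date_reported" in row and isinstance(row["date_reported"], str) and row["date_reported"]:
            date_reported = dt.date.fromisoformat(row["date_reported"])
        rec = SampleRecord(
            pregnancy_id=pid,
            sample_id=sid,
            date_received=dt.date.fromisoformat(str(row["date_received"])),
            ga_at_receipt=float(row["ga_weeks"]),
            assay_available=assay_available,
            assay_specific=_parse_bool(row.get("assay_specific", True)),
            assay_preexisting=_parse_bool(row.get("assay_preexisting", False)),
            ff=ff,
            posterior=posterior,
            date_reported=date_reported,
        )
        by_pregnancy.setdefault(pid, []).append(rec)
        qc = apply_sample_qc(rec) if (ff is not None or not rec.assay_specific) else None
        call = call_genotype(posterior) if posterior is not None else None
        call_rows.append(
            {
                "pregnancy_id": pid,
                "sample_id": sid,
                "fetal_fraction": ff.f if ff else None,
                "ff_method": ff.method if ff else None,
                "paternal_allele_droplets": ff.paternal_allele_droplets if ff else None,
                "qc_passed": qc.passed if qc else False,
                "qc_failures": ";".join(f.value for f in qc.failures) if qc else "",
                "p_het": posterior.p_het if posterior else None,
                "call": call.call if call else "",
            }
        )
        if reason:
            exclusions.append({"pregnancy_id": pid, "sample_id": sid, "reason": reason})
    return by_pregnancy, pd.DataFrame(call_rows), exclusions


def process_samples(cfg: StudyConfig, settings: InferenceSettings | None = None):
    """Run QC + calling on every sample and classify every pregnancy.

    Returns (calls DataFrame, outcomes DataFrame, by_pregnancy records,
    exclusion rows)."""
    settings = settings or InferenceSettings(seed=cfg.seed)
    by_pregnancy, calls, exclusions = _load_sample_records(
        cfg.samples, settings, cfg.prior_nm
    )
    outcome_rows = []
    for pid in sorted(by_pregnancy):
        oc = classify_pregnancy_outcome(by_pregnancy[pid])
        outcome_rows.append(
            {
                "pregnancy_id": pid,
                "outcome": oc.outcome.value,
                "reported_sample_id": oc.reported_sample_id or "",
                "ga_at_report": oc.ga_at_report,
                "turnaround_weeks": oc.turnaround_weeks,
            }
        )
    return calls, pd.DataFrame(outcome_rows), by_pregnancy, exclusions


def _measures_dict(t, conf):
    m = accuracy_measures(t, conf)
    out = {}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        p = getattr(m, name)
        out[name] = {
            "estimate": p.estimate,
            "ci": [p.low, p.high],
            "rounded_pct": p.rounded_pct,
            "k": p.k,
            "n": p.n,
        }
    return out


def run_accuracy_study(
    cfg: StudyConfig, settings: InferenceSettings | None = None
) -> dict:
    """The paired diagnostic-accuracy analysis: NIPT vs ultrasound AC.

    Eligible pregnancies need a conclusive NIPT call, a scan in the
    26-30-week window and a confirmed genotype; everything else is
    excluded with a logged reason.  Produces contingency tables, accuracy
    measures with exact CIs, McNemar and generalized-score comparisons,
    paired ROC/AUC with a bootstrap comparison and the Youden-optimal AC
    percentile threshold.
    """
    if cfg.scans is None or cfg.confirmed is None or cfg.growth_standard is None:
        raise InvalidInputError("accuracy study needs scans, confirmed and growth_standard paths")
    calls, outcomes, by_pregnancy, exclusions = process_samples(cfg, settings)
    std = load_growth_standard(cfg.growth_standard)
    scans_df = pd.read_csv(cfg.scans, dtype={"pregnancy_id": str})
    confirmed_df = pd.read_csv(cfg.confirmed, dtype={"pregnancy_id": str})
    confirmed = dict(zip(confirmed_df["pregnancy_id"], confirmed_df["genotype"]))

    rows = []
    for pid in sorted(by_pregnancy):
        reported = outcomes.loc[outcomes["pregnancy_id"] == pid].iloc[0]
        if reported["outcome"] != Outcome.REPORTED.value:
            exclusions.append(
                {"pregnancy_id": pid, "sample_id": "", "reason": "no_conclusive_nipt"}
            )
            continue
        sid = reported["reported_sample_id"]
        call_row = calls.loc[calls["sample_id"] == sid].iloc[0]
        pscans = [
            Scan(pregnancy_id=pid, ga=float(r["ga_weeks"]), ac_mm=float(r["ac_mm"]))
            for _, r in scans_df.loc[scans_df["pregnancy_id"] == pid].iterrows()
        ]
        try:
            scan = select_scan(pscans)
        except GckNiptError:
            exclusions.append(
                {"pregnancy_id": pid, "sample_id": sid, "reason": "no_eligible_scan"}
            )
            continue
        if pid not in confirmed:
            exclusions.append(
                {"pregnancy_id": pid, "sample_id": sid, "reason": "no_confirmed_genotype"}
            )
            continue
        pct = ac_percentile(scan.ac_mm, scan.ga, std)
        rows.append(
            {
                "pregnancy_id": pid,
                "nipt_call": call_row["call"],
                "p_het": float(call_row["p_het"]),
                "ac_percentile": pct,
                "confirmed": confirmed[pid],
            }
        )
    if not rows:
        raise EmptyStudyError("no pregnancy eligible for the accuracy study")

    eligible = pd.DataFrame(rows)
    truth = list(eligible["confirmed"])
    nipt_pred = list(eligible["nipt_call"])
    report: dict = {"n_eligible": len(eligible), "tests": {}, "comparisons": {}}

    t_nipt = build_contingency(nipt_pred, truth)
    report["tests"]["nipt"] = {
        "table": {"tp": t_nipt.tp, "fp": t_nipt.fp, "fn": t_nipt.fn, "tn": t_nipt.tn},
        "concordant": t_nipt.concordant,
        "measures": _measures_dict(t_nipt, cfg.conf_level),
    }
    ac_preds = {}
    for thr in cfg.ac_thresholds:
        pred = [classify_by_ac(p, thr).predicted for p in eligible["ac_percentile"]]
        ac_preds[thr] = pred
        t = build_contingency(pred, truth)
        report["tests"][f"ac{thr}"] = {
            "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
            "concordant": t.concordant,
            "measures": _measures_dict(t, cfg.conf_level),
        }

    for thr in cfg.ac_thresholds:
        paired = PairedPredictions(
            truth=tuple(truth), test_a=tuple(nipt_pred), test_b=tuple(ac_preds[thr])
        )
        mc_sens = mcnemar_compare(paired, "diseased", cfg.mcnemar_exact_cutoff)
        mc_spec = mcnemar_compare(paired, "nondiseased", cfg.mcnemar_exact_cutoff)
        gs = generalized_score_compare(paired)
        report["comparisons"][f"nipt_vs_ac{thr}"] = {
            "mcnemar_sensitivity": {
                "statistic": mc_sens.statistic, "p_value": mc_sens.p_value,
                "b": mc_sens.b, "c": mc_sens.c, "method": mc_sens.method,
            },
            "mcnemar_specificity": {
                "statistic": mc_spec.statistic, "p_value": mc_spec.p_value,
                "b": mc_spec.b, "c": mc_spec.c, "method": mc_spec.method,
            },
            "generalized_score_ppv": {
                "statistic": gs["ppv"].statistic, "p_value": gs["ppv"].p_value,
                "ppv_nipt": gs["ppv"].value_a, "ppv_ac": gs["ppv"].value_b,
                "defined": gs["ppv"].defined,
            },
            "generalized_score_npv": {
                "statistic": gs["npv"].statistic, "p_value": gs["npv"].p_value,
                "npv_nipt": gs["npv"].value_a, "npv_ac": gs["npv"].value_b,
                "defined": gs["npv"].defined,
            },
        }

    # ROC on the continuous scores: NIPT posterior, and negated AC
    # percentile (lower percentile = more likely N/M)
    nipt_scores = list(eligible["p_het"])
    ac_scores = [-p for p in eligible["ac_percentile"]]
    roc_nipt = roc_curve(nipt_scores, truth)
    roc_ac = roc_curve(ac_scores, truth)
    boot = bootstrap_auc_compare(
        nipt_scores, ac_scores, truth, n_boot=cfg.n_boot, seed=cfg.seed
    )
    youden_score, degenerate = youden_optimal_threshold(roc_ac)
    report["roc"] = {
        "auc_nipt": roc_nipt.auc,
        "auc_ac": roc_ac.auc,
        "delta_auc": boot.delta_auc,
        "bootstrap_p_value": boot.p_value,
        "n_boot": boot.n_boot,
        "youden_ac_percentile": None if degenerate else -youden_score,
    }
    report["_roc_curves"] = {
        "nipt": {"fpr": list(roc_nipt.fpr), "tpr": list(roc_nipt.tpr),
                 "thresholds": list(roc_nipt.thresholds)},
        "ac": {"fpr": list(roc_ac.fpr), "tpr": list(roc_ac.tpr),
               "thresholds": list(roc_ac.thresholds)},
    }
    report["exclusions"] = exclusions
    return report


def run_feasibility_study(
    cfg: StudyConfig, settings: InferenceSettings | None = None
) -> dict:
    """The prospective feasibility analysis: reporting outcomes, turnaround
    and gestational-age-at-report summaries and group comparisons."""
    calls, outcomes, by_pregnancy, exclusions = process_samples(cfg, settings)
    records = []
    for pid in sorted(by_pregnancy):
        samples = sorted(by_pregnancy[pid], key=lambda s: (s.date_received, s.sample_id))
        oc = classify_pregnancy_outcome(samples)
        if oc.outcome is Outcome.REPORTED and oc.turnaround_weeks is None:
            exclusions.append(
                {"pregnancy_id": pid, "sample_id": oc.reported_sample_id,
                 "reason": "missing_report_date"}
            )
            continue
        records.append(
            TurnaroundRecord(
                pregnancy_id=pid,
                ga_first_sample=samples[0].ga_at_receipt,
                outcome=oc,
                ga_at_report=oc.ga_at_report,
                turnaround_weeks=oc.turnaround_weeks,
                n_samples=len(samples),
                assay_preexisting=any(s.assay_preexisting for s in samples),
            )
        )
    summary = turnaround_summary(records)
    report = {
        "n_pregnancies": summary.n_pregnancies,
        "n_reported": summary.n_reported,
        "outcome_counts": summary.outcome_counts,
        "turnaround_weeks": summary.turnaround,
        "ga_at_report": summary.ga_at_report,
        "early_referral": summary.early_referral,
        "by_n_samples": {
            "n_single": summary.by_n_samples.n_a,
            "n_multiple": summary.by_n_samples.n_b,
            "single": summary.by_n_samples.summary_a,
            "multiple": summary.by_n_samples.summary_b,
            "statistic": summary.by_n_samples.statistic,
            "p_value": summary.by_n_samples.p_value,
        },
        "by_assay_preexisting": {
            "n_preexisting": summary.by_assay_preexisting.n_a,
            "n_new": summary.by_assay_preexisting.n_b,
            "preexisting": summary.by_assay_preexisting.summary_a,
            "new": summary.by_assay_preexisting.summary_b,
            "statistic": summary.by_assay_preexisting.statistic,
            "p_value": summary.by_assay_preexisting.p_value,
        },
        "spearman_ga_vs_turnaround": summary.spearman_ga_vs_turnaround,
        "exclusions": exclusions,
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report deterministically (sorted keys, fixed float repr)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
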