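"""Sample-level quality control and pregnancy-level reporting outcomes.

A ddPCR result is analysable only if the assay is specific for the
maternal variant, the fetal fraction exceeds 2% and the fetus-specific
(paternal) allele was seen in more than 10 droplets — all strict
inequalities.  A pregnancy is "reported" from the earliest sample that
passes QC and yields a conclusive call; failed or inconclusive first
samples trigger a repeat-sample request, modelled here simply as a later
sample record.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field

from ._exceptions import IncompleteRecordError, InvalidInputError, InvalidRecordError
from .ddpcr import FetalFractionEstimate, GenotypePosterior, call_genotype

__all__ = [
    "MIN_FETAL_FRACTION",
    "MIN_PATERNAL_DROPLETS",
    "QCFailure",
    "QCResult",
    "SampleRecord",
    "PregnancyReportOutcome",
    "apply_sample_qc",
    "select_reportable_sample",
    "classify_pregnancy_outcome",
]

# strict thresholds: a sample at exactly these values fails
MIN_FETAL_FRACTION = 0.02
MIN_PATERNAL_DROPLETS = 10


class QCFailure(str, enum.Enum):
    ASSAY_NONSPECIFIC = "assay_nonspecific"
    LOW_FETAL_FRACTION = "low_fetal_fraction"
    LOW_PATERNAL_DROPLETS = "low_paternal_droplets"


@dataclass(frozen=True)
class QCResult:
    passed: bool
    failures: tuple[QCFailure, ...]


@dataclass
class SampleRecord:
    """One maternal cfDNA sample with its assay results.

    ``date_reported`` is the date the genotype report was issued from this
    sample (None if the sample never produced a report).
    """

    pregnancy_id: str
    sample_id: str
    date_received: dt.date
    ga_at_receipt: float
    assay_available: bool = True
    assay_specific: bool = True
    assay_preexisting: bool = False
    ff: FetalFractionEstimate | None = None
    posterior: GenotypePosterior | None = None
    date_reported: dt.date | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ga_at_receipt < 45.0:
            raise InvalidInputError(
                f"gestational age at receipt must be in (0, 45), got {self.ga_at_receipt}"
            )


class Outcome(str, enum.Enum):
    REPORTED = "reported"
    NO_ASSAY = "no_assay"
    QC_FAIL_NO_REPEAT = "qc_fail_no_repeat"
    BELOW_THRESHOLD_NO_REPEAT = "below_threshold_no_repeat"


@dataclass(frozen=True)
class PregnancyReportOutcome:
    outcome: Outcome
    reported_sample_id: str | None = None
    ga_at_report: float | None = None
    turnaround_weeks: int | None = None


def apply_sample_qc(s: SampleRecord) -> QCResult:
    """Run all three QC gates on a sample and report every failure.

    Fetal fraction must be strictly greater than 2% and the paternal
    allele must be seen in strictly more than 10 droplets.
    """
    failures: list[QCFailure] = []
    if not s.assay_specific:
        failures.append(QCFailure.ASSAY_NONSPECIFIC)
    if s.ff is None:
        if s.assay_specific:
            raise IncompleteRecordError(
                f"sample {s.sample_id}: fetal-fraction estimate required for QC"
            )
    else:
        if s.ff.f <= MIN_FETAL_FRACTION:
            failures.append(QCFailure.LOW_FETAL_FRACTION)
        if s.ff.paternal_allele_droplets <= MIN_PATERNAL_DROPLETS:
            failures.append(QCFailure.LOW_PATERNAL_DROPLETS)
    return QCResult(passed=not failures, failures=tuple(failures))


def _is_reportable(s: SampleRecord) -> bool:
    if s.posterior is None:
        return False
    if not apply_sample_qc(s).passed:
        return False
    return call_genotype(s.posterior).call != "inconclusive"


def select_reportable_sample(samples: list[SampleRecord]) -> SampleRecord | None:
    """Earliest sample (by receipt date) passing QC with a conclusive call.

    When more than one sample was tested, the study reports from the
    earliest sample with a reportable result.
    """
    if not samples:
        raise InvalidInputError("no samples supplied")
    ordered = sorted(samples, key=lambda s: (s.date_received, s.sample_id))
    for s in ordered:
        if _is_reportable(s):
            return s
    return None


def classify_pregnancy_outcome(
    samples: list[SampleRecord], repeats_received: bool | None = None
) -> PregnancyReportOutcome:
    """Assign the single reporting outcome of a pregnancy.

    Mirrors the feasibility flow chart: no assay designable; reported
    (earliest reportable sample); all samples failed QC with no further
    sample; or QC passed but no call reached the reporting threshold and
    no further sample arrived.  Turnaround is whole weeks (floor of
    days/7) from receipt of the first sample to report issue.
    """
    if not samples:
        raise InvalidInputError("no samples supplied")
    if repeats_received is None:
        repeats_received = len(samples) > 1
    if not any(s.assay_available for s in samples):
        if any(s.posterior is not None for s in samples):
            raise InvalidRecordError(
                f"pregnancy {samples[0].pregnancy_id}: posterior present without assay"
            )
        return PregnancyReportOutcome(outcome=Outcome.NO_ASSAY)

    ordered = sorted(samples, key=lambda s: (s.date_received, s.sample_id))
    first = ordered[0]
    chosen = select_reportable_sample(ordered)
    if chosen is not None:
        if chosen.date_reported is not None:
            days = (chosen.date_reported - first.date_received).days
            turnaround = days // 7
            ga_at_report = chosen.ga_at_receipt + (
                (chosen.date_reported - chosen.date_received).days / 7.0
            )
        else:
            turnaround = None
            ga_at_report = None
        return PregnancyReportOutcome(
            outcome=Outcome.REPORTED,
            reported_sample_id=chosen.sample_id,
            ga_at_report=ga_at_report,
            turnaround_weeks=turnaround,
        )
    analysable = [s for s in ordered if s.posterior is not None or s.ff is not None]
    any_qc_pass = any(apply_sample_qc(s).passed for s in analysable) if analysable else False
    if any_qc_pass:
        return PregnancyReportOutcome(outcome=Outcome.BELOW_THRESHOLD_NO_REPEAT)
    return PregnancyReportOutcome(outcome=Outcome.QC_FAIL_NO_REPEAT)
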