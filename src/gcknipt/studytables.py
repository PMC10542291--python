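"""Published contingency tables and cohort flow counts of the GCK-MODY NIPT
diagnostic-accuracy and feasibility study, packaged as analysis fixtures.

The individual-level study data are not public; these aggregate counts are
the printed results and serve as reference inputs for reproducing the
accuracy statistics.
"""

from __future__ import annotations

from .accuracy import TwoByTwo

__all__ = [
    "NIPT_TABLE",
    "AC75_TABLE",
    "AC90_TABLE",
    "FEASIBILITY_FLOW",
    "paired_labels",
]

# Predicted-vs-confirmed fetal genotype, positive class = N/M, n = 38.
# NIPT call at the >=0.95 / <=0.05 posterior thresholds:
NIPT_TABLE = TwoByTwo(tp=15, fp=1, fn=0, tn=22)
# Abdominal circumference < 75th percentile at the 28-week scan:
AC75_TABLE = TwoByTwo(tp=8, fp=9, fn=7, tn=14)
# Abdominal circumference < 90th percentile:
AC90_TABLE = TwoByTwo(tp=13, fp=12, fn=2, tn=11)

# Feasibility cohort flow: 43 consecutive pregnancies.
FEASIBILITY_FLOW = {
    "reported": 38,
    "no_assay": 1,
    "qc_fail_no_repeat": 1,
    "below_threshold_no_repeat": 3,
}


def paired_labels(t: TwoByTwo) -> tuple[list[str], list[str]]:
    """Expand a contingency table into aligned (predicted, confirmed) label
    lists, ordered tp, fp, fn, tn."""
    predicted = ["NM"] * (t.tp + t.fp) + ["NN"] * (t.fn + t.tn)
    confirmed = (
        ["NM"] * t.tp + ["NN"] * t.fp + ["NM"] * t.fn + ["NN"] * t.tn
    )
    return predicted, confirmed
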