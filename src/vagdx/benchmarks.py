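"""Reference confusion counts from the clinical validation of this protocol.

The clinical cohort behind the patellofemoral VAG protocol is not publicly
deposited, but the per-group classification counts of its six reported
networks are.  They serve as worked-example inputs: every derived metric
(per-group percentages, overall accuracy, F1, MCC) can be recomputed from
these integers and tied bit-for-bit to the evaluation module.

Counts are (HC total, HC correct, OA total, OA correct); variant I = open
kinetic chain, II = closed, III = both chains stacked.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts

REFERENCE_COUNTS: dict[str, dict] = {
    "MLP 9-40-2":  {"variant": "I",   "hc_total": 45, "hc_correct": 43,
                    "oa_total": 23, "oa_correct": 18},
    "RBF 9-35-2":  {"variant": "I",   "hc_total": 45, "hc_correct": 44,
                    "oa_total": 23, "oa_correct": 23},
    "MLP 10-16-2": {"variant": "II",  "hc_total": 45, "hc_correct": 44,
                    "oa_total": 23, "oa_correct": 23},
    "RBF 10-40-2": {"variant": "II",  "hc_total": 45, "hc_correct": 43,
                    "oa_total": 23, "oa_correct": 23},
    "MLP 8-3-2":   {"variant": "III", "hc_total": 89, "hc_correct": 88,
                    "oa_total": 47, "oa_correct": 45},
    "RBF 8-14-2":  {"variant": "III", "hc_total": 89, "hc_correct": 85,
                    "oa_total": 47, "oa_correct": 40},
}


def reference_confusion(name: str) -> ConfusionCounts:
    """Confusion counts for a reference network, OA as the positive class."""
    c = REFERENCE_COUNTS[name]
    return ConfusionCounts(
        tp=c["oa_correct"],
        fn=c["oa_total"] - c["oa_correct"],
        tn=c["hc_correct"],
        fp=c["hc_total"] - c["hc_correct"],
    )
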