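"""Published operating points of the original clinical evaluation.

The decision pipeline implemented here was designed around a clinical
study of 152 eyes (44 no-surgery / 61 levator resection / 47 frontalis
suspension) whose patient data are not publicly deposited.  The study's
reported test-set indicators per task and feature scheme are kept here
as a reference for display and for internal-consistency checks (e.g.
that the F1 cells equal the harmonic mean of the printed precision and
recall); they are *not* reproducible from synthetic cohorts and this
package never claims to re-derive them.
"""

from __future__ import annotations

#: task -> scheme -> metric -> reported value
REFERENCE_OPERATING_POINTS: dict[str, dict[str, dict[str, float]]] = {
    "diagnosis": {
        "3d": {"acc": 0.8478, "auc": 0.833, "f1": 0.8889, "precision": 0.9032, "recall": 0.8750},
        "2d": {"acc": 0.8043, "auc": 0.759, "f1": 0.8615, "precision": 0.8485, "recall": 0.8750},
        "both": {"acc": 0.8261, "auc": 0.795, "f1": 0.8824, "precision": 0.8333, "recall": 0.9375},
    },
    "plan": {
        "3d": {"acc": 0.8182, "auc": 0.817, "f1": 0.8333, "precision": 0.8333, "recall": 0.8333},
        "2d": {"acc": 0.8182, "auc": 0.773, "f1": 0.7000, "precision": 0.7778, "recall": 0.6364},
        "both": {"acc": 0.8182, "auc": 0.833, "f1": 0.8000, "precision": 1.0000, "recall": 0.6667},
    },
}

#: class sizes of the reference cohort (no surgery, resection, suspension)
REFERENCE_CLASS_COUNTS: tuple[int, int, int] = (44, 61, 47)
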