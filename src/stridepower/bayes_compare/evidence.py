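"""Jeffreys evidence scale for Bayes factors (Lee & Wagenmakers wording)."""

from __future__ import annotations

from ..grf_pipeline import ValidationError

_LABELS = (
    (100.0, "extreme"),
    (30.0, "very strong"),
    (10.0, "strong"),
    (3.0, "moderate"),
    (1.0, "anecdotal"),
)


def classify_bf(bf10: float) -> str:
    """Verbal evidence category for a Bayes factor BF10.

    BF10 >= 100, 30-100, 10-30, 3-10 and 1-3 read as extreme, very strong,
    strong, moderate and anecdotal evidence for H1; exactly 1 is no
    evidence either way; below 1 the inverse scale applies in favour of H0.
    """
    if not bf10 > 0:
        raise ValidationError("Bayes factor must be positive")
    if bf10 == 1.0:
        return "no evidence"
    if bf10 > 1.0:
        value, hypothesis = bf10, "H1"
    else:
        value, hypothesis = 1.0 / bf10, "H0"
    for cut, label in _LABELS:
        if value >= cut:
            return f"{label} evidence for {hypothesis}"
    return f"anecdotal evidence for {hypothesis}"
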