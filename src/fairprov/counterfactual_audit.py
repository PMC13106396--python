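"""Counterfactual gender-flip analysis of borderline predictions.

For test cases whose predicted probability lies within a margin of the 0.5
decision threshold, the gender bit is inverted (in both directions — female
to male and male to female), every other feature left untouched, and the case
re-scored. The fraction of boundary cases whose predicted class changes
measures gender's direct influence on borderline decisions. Gender enters
models unstandardized, so the flip is a pure bit inversion with no
re-scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CounterfactualResult", "boundary_cases", "gender_flip_audit"]


@dataclass
class CounterfactualResult:
    """Per-case flip records plus the aggregate flip fraction."""

    threshold: float
    margin: float
    n_boundary: int
    n_flipped: int
    cases: list[dict]

    @property
    def flip_fraction(self) -> float:
        return self.n_flipped / self.n_boundary if self.n_boundary else 0.0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "margin": self.margin,
            "n_boundary": self.n_boundary,
            "n_flipped": self.n_flipped,
            "flip_fraction": self.flip_fraction,
            "cases": self.cases,
        }


def boundary_cases(model, table: pd.DataFrame, margin: float = 0.15,
                   threshold: float = 0.5) -> list[str]:
    """Patient ids with predicted probability in [threshold-margin, threshold+margin].

    Bounds are inclusive; an empty result is allowed.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    prob = model.predict_proba(table)
    # endpoint form keeps the decimal bounds (e.g. [0.35, 0.65]) inclusive
    # under binary floating point, where |0.35 - 0.5| > 0.15
    mask = (prob >= threshold - margin) & (prob <= threshold + margin)
    return [str(p) for p in table.loc[mask, "patient_id"]]


def gender_flip_audit(model, table: pd.DataFrame, case_ids: list[str] | None = None,
                      margin: float = 0.15, threshold: float = 0.5) -> CounterfactualResult:
    """Invert the gender bit of every boundary case and record class changes.

    Refuses models fitted without gender (there is no gender pathway to
    audit; use the feature-exclusion ablation for those).
    """
    if "gender" not in model.feature_names:
        raise ValueError("model has no 'gender' input feature; cannot flip gender")
    if case_ids is None:
        case_ids = boundary_cases(model, table, margin, threshold)
    sub = table.set_index("patient_id", drop=False).loc[list(case_ids)]
    orig_prob = model.predict_proba(sub)
    flipped = sub.copy()
    flipped["gender"] = 1 - flipped["gender"].to_numpy()
    flip_prob = model.predict_proba(flipped)
    orig_cls = (orig_prob >= threshold).astype(int)
    flip_cls = (flip_prob >= threshold).astype(int)
    cases = [
        {
            "patient_id": str(pid),
            "original_gender": int(g),
            "original_probability": float(p0),
            "flipped_probability": float(p1),
            "original_class": int(c0),
            "flipped_class": int(c1),
            "changed": bool(c0 != c1),
        }
        for pid, g, p0, p1, c0, c1 in zip(
            sub["patient_id"], sub["gender"], orig_prob, flip_prob, orig_cls, flip_cls
        )
    ]
    return CounterfactualResult(
        threshold=threshold,
        margin=margin,
        n_boundary=len(cases),
        n_flipped=int(sum(c["changed"] for c in cases)),
        cases=cases,
    )
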