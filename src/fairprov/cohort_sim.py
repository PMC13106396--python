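"""Synthetic patient cohorts with a controllable injected gender bias.

The simulator emulates a 30-day hospital readmission cohort: four clinical
features (age, BMI, comorbidity status, gender) and a binary outcome drawn
from a logistic data-generating process. A negative gender coefficient
(``beta_gender``, male = 1) injects a known disparity — male patients get a
systematically lower readmission probability than otherwise-identical female
patients — giving downstream fairness audits a ground truth to recover.

Continuous features are z-scored over the full generated cohort before the
outcome is drawn, and models are fit on the same standardized columns, so the
generating coefficients are on the per-SD scale a fitted logistic model should
recover at large n.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .seeding import substream

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "Cohort",
    "SplitIndices",
    "CohortParseError",
    "generate_cohort",
    "stratified_split",
    "write_cohort",
    "read_cohort",
]

#: Column order of the cohort table (and its CSV serialization).
COHORT_COLUMNS = (
    "patient_id",
    "age",
    "bmi",
    "comorbidity",
    "gender",
    "age_std",
    "bmi_std",
    "outcome",
)


class CohortParseError(ValueError):
    """Raised when a cohort CSV cannot be parsed."""


class CohortSpec(BaseModel):
    """Parameters of the logistic data-generating process.

    Coefficients are log-odds: per standard deviation for the standardized
    continuous features (age, BMI), per unit for the binary ones. The default
    ``beta_gender = -0.30`` is the moderate injected disparity used throughout
    the main audit; the sensitivity sweep varies it.
    """

    n_patients: int = Field(1000, ge=1)
    intercept: float = -1.0
    beta_age: float = 0.50
    beta_bmi: float = 0.40
    beta_comorbidity: float = 1.00
    beta_gender: float = -0.30
    age_range: tuple[float, float] = (20.0, 85.0)
    bmi_mean: float = 27.0
    bmi_sd: float = Field(5.0, gt=0)
    bmi_clip: tuple[float, float] = (16.0, 45.0)
    comorbidity_prevalence: float = Field(0.35, ge=0.0, le=1.0)
    male_fraction: float = Field(0.5, ge=0.0, le=1.0)
    seed: int = 42

    @model_validator(mode="after")
    def _check_ranges(self) -> "CohortSpec":
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range: low bound must be below high bound")
        if not self.bmi_clip[0] < self.bmi_clip[1]:
            raise ValueError("bmi_clip: low bound must be below high bound")
        return self


@dataclass
class Cohort:
    """A simulated patient table plus its generation metadata.

    ``table`` columns follow :data:`COHORT_COLUMNS`; ``standardization``
    records the moments (mean, sample SD) used to z-score age and BMI so the
    raw columns can be reproduced from the standardized ones and vice versa.
    """

    table: pd.DataFrame
    spec: CohortSpec
    standardization: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    def view(self, patient_ids: Sequence[str]) -> pd.DataFrame:
        """Rows for the given patient ids, in the given order."""
        sub = self.table.set_index("patient_id").loc[list(patient_ids)]
        return sub.reset_index()


@dataclass(frozen=True)
class SplitIndices:
    """A disjoint train/test partition of patient ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    stratify_on: str
    test_fraction: float
    seed: int


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the logistic data-generating process.

    Age is uniform on ``age_range``; BMI is Gaussian(``bmi_mean``,
    ``bmi_sd``) clipped to ``bmi_clip``; comorbidity and gender are Bernoulli.
    Age and BMI are z-scored over the generated sample (sample SD, ddof=1),
    the linear predictor is assembled from the spec coefficients on the
    standardized scale, and the outcome is a Bernoulli draw at
    ``sigmoid(lp)``. Fully reproducible from ``spec.seed`` via named
    substreams ("features", "outcome").
    """
    if not isinstance(spec, CohortSpec):
        spec = CohortSpec.model_validate(spec)
    n = spec.n_patients
    rng_feat = substream(spec.seed, "features")
    rng_out = substream(spec.seed, "outcome")

    age = rng_feat.uniform(spec.age_range[0], spec.age_range[1], n)
    bmi = np.clip(rng_feat.normal(spec.bmi_mean, spec.bmi_sd, n), *spec.bmi_clip)
    comorbidity = (rng_feat.random(n) < spec.comorbidity_prevalence).astype(np.int64)
    gender = (rng_feat.random(n) < spec.male_fraction).astype(np.int64)

    moments = {}
    std_cols = {}
    for name, values in (("age", age), ("bmi", bmi)):
        mean = float(values.mean())
        # Degenerate n=1 cohorts standardize to 0 rather than dividing by 0.
        sd = float(values.std(ddof=1)) if n > 1 else 1.0
        if sd == 0.0:
            sd = 1.0
        moments[name] = {"mean": mean, "sd": sd}
        std_cols[name + "_std"] = (values - mean) / sd

    lp = (
        spec.intercept
        + spec.beta_age * std_cols["age_std"]
        + spec.beta_bmi * std_cols["bmi_std"]
        + spec.beta_comorbidity * comorbidity
        + spec.beta_gender * gender
    )
    outcome = (rng_out.random(n) < _sigmoid(lp)).astype(np.int64)

    width = max(4, len(str(n)))
    patient_id = [f"P{i + 1:0{width}d}" for i in range(n)]

    table = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age": age,
            "bmi": bmi,
            "comorbidity": comorbidity,
            "gender": gender,
            "age_std": std_cols["age_std"],
            "bmi_std": std_cols["bmi_std"],
            "outcome": outcome,
        }
    )
    logger.debug(
        "generated cohort: n=%d seed=%d prevalence=%.3f", n, spec.seed, outcome.mean()
    )
    return Cohort(table=table, spec=spec, standardization=moments)


def stratified_split(
    cohort: Cohort, test_fraction: float, seed: int, stratify_on: str = "outcome"
) -> SplitIndices:
    """Outcome-stratified train/test partition with largest-remainder rounding.

    Each stratum contributes ``test_fraction`` of its members to the test
    side, rounded jointly by the largest-remainder rule so the total test size
    is ``round(test_fraction * n)``. Deterministic given ``seed`` (its own
    "split" substream shuffles within strata).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be strictly between 0 and 1")
    table = cohort.table
    if stratify_on not in table.columns:
        raise ValueError(f"stratification column {stratify_on!r} not in cohort")
    classes = table[stratify_on].unique()
    if len(classes) < 2:
        raise ValueError(f"cannot stratify: only one {stratify_on} class present")
    counts = table[stratify_on].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cannot stratify: class(es) {bad} have fewer than 2 members")

    n = len(table)
    total_test = int(math.floor(test_fraction * n + 0.5))
    if total_test == 0 or total_test == n:
        raise ValueError("test_fraction leaves train or test empty for this cohort")

    # Largest-remainder apportionment of the test quota across strata.
    ordered = sorted(classes.tolist())
    quotas = {c: test_fraction * int(counts[c]) for c in ordered}
    base = {c: int(math.floor(quotas[c])) for c in ordered}
    leftover = total_test - sum(base.values())
    by_remainder = sorted(ordered, key=lambda c: (-(quotas[c] - base[c]), c))
    for c in by_remainder[:leftover]:
        base[c] += 1

    rng = substream(seed, "split")
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in ordered:
        ids = table.loc[table[stratify_on] == c, "patient_id"].to_numpy()
        perm = rng.permutation(len(ids))
        k = base[c]
        test_ids.extend(ids[perm[:k]])
        train_ids.extend(ids[perm[k:]])
    return SplitIndices(
        train_ids=tuple(sorted(train_ids)),
        test_ids=tuple(sorted(test_ids)),
        stratify_on=stratify_on,
        test_fraction=test_fraction,
        seed=seed,
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as CSV plus a ``<path>.meta.json`` sidecar.

    Integers are written exactly; reals with 12 significant digits (the
    round-trip guarantee of :func:`read_cohort`).
    """
    path = Path(path)
    cohort.table.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "spec": cohort.spec.model_dump(),
        "seed": cohort.spec.seed,
        "standardization": cohort.standardization,
        "columns": list(COHORT_COLUMNS),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


_INT_COLUMNS = ("comorbidity", "gender", "outcome")
_REAL_COLUMNS = ("age", "bmi", "age_std", "bmi_std")


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises :class:`CohortParseError` naming the missing column or the 1-based
    data row of the first non-numeric cell.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise CohortParseError(f"cannot parse {path}: {exc}") from exc
    for col in COHORT_COLUMNS:
        if col not in raw.columns:
            raise CohortParseError(f"missing required column {col!r}")
    table = pd.DataFrame({"patient_id": raw["patient_id"].astype(str)})
    for col in COHORT_COLUMNS[1:]:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or converted.isna().any():
            row = int(np.where(converted.isna())[0][0]) + 1
            raise CohortParseError(f"non-numeric value in column {col!r} at data row {row}")
        table[col] = converted.astype(np.int64 if col in _INT_COLUMNS else np.float64)

    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        spec = CohortSpec.model_validate(meta["spec"])
        standardization = meta.get("standardization", {})
    else:
        spec = CohortSpec(n_patients=len(table))
        standardization = {
            c: {"mean": float(table[c].mean()), "sd": float(table[c].std(ddof=1))}
            for c in ("age", "bmi")
        }
    return Cohort(table=table, spec=spec, standardization=standardization)
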