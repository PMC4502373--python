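"""Breed stature summaries and contrasting large/small cohort construction.

Country-replicated wither-height records (FAO DAD-IS style: one row per
breed and country with average male and female heights in cm) are reduced
to a single stature value per breed, and breeds are classified into
contrasting cohorts by a stringent quartile rule:

* the country value is the mean of the male and female averages;
* the breed value is the single country value, or the median across
  countries when a breed is reported by several;
* a breed is **large** when its value lies strictly above the overall upper
  quartile (and, when multi-country, its own lower quartile lies strictly
  above the overall median); **small** symmetrically below; otherwise
  **medium**.

Quartiles use linear interpolation between order statistics (the common
"type 7" rule); the convention is recorded in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("csskit")

QUANTILE_RULE = "linear"  # numpy's interpolated (type 7) empirical quantile


class CohortError(ValueError):
    """Raised for unusable phenotype tables or degenerate cohorts."""


@dataclass
class BreedSummary:
    breed: str
    n_countries: int
    country_values_cm: list
    breed_value_cm: float
    breed_q1_cm: float
    breed_q3_cm: float


@dataclass
class CohortAssignment:
    overall_q1_cm: float
    overall_median_cm: float
    overall_q3_cm: float
    classes: dict  # breed -> large | medium | small
    summaries: dict = field(default_factory=dict)  # breed -> BreedSummary

    def breeds_in(self, cls: str) -> list:
        return [b for b, c in self.classes.items() if c == cls]

    def separation_cm(self) -> float:
        """min(large breed values) − max(small breed values)."""
        large = [self.summaries[b].breed_value_cm for b in self.breeds_in("large")]
        small = [self.summaries[b].breed_value_cm for b in self.breeds_in("small")]
        if not large or not small:
            raise CohortError("separation undefined: an extreme cohort is empty")
        return float(min(large) - max(small))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for breed, cls in self.classes.items():
            s = self.summaries[breed]
            rows.append(
                (breed, s.n_countries, s.breed_value_cm, s.breed_q1_cm,
                 s.breed_q3_cm, cls)
            )
        return pd.DataFrame(
            rows,
            columns=["breed", "n_countries", "breed_value_cm", "q1_cm", "q3_cm",
                     "stature_class"],
        )


def summarize_breeds(table: pd.DataFrame) -> list[BreedSummary]:
    """Collapse a (breed, country, male_cm, female_cm) table per breed.

    Rows with a missing male or female value are dropped with a log record.
    """
    required = {"breed", "country", "male_cm", "female_cm"}
    if table is None or len(table) == 0:
        raise CohortError("phenotype table is empty")
    if not required.issubset(table.columns):
        raise CohortError(f"phenotype table needs columns {sorted(required)}")
    if table.duplicated(subset=["breed", "country"]).any():
        raise CohortError("duplicate (breed, country) rows in phenotype table")
    ok = table["male_cm"].notna() & table["female_cm"].notna()
    if (~ok).any():
        log.info("dropping %d phenotype rows with missing heights", int((~ok).sum()))
    table = table[ok]
    if len(table) == 0:
        raise CohortError("no complete phenotype rows")

    out = []
    for breed, grp in table.groupby("breed", sort=True):
        values = ((grp["male_cm"] + grp["female_cm"]) / 2.0).to_numpy(float)
        value = float(values[0]) if len(values) == 1 else float(np.median(values))
        out.append(
            BreedSummary(
                breed=breed,
                n_countries=len(values),
                country_values_cm=[float(v) for v in values],
                breed_value_cm=value,
                breed_q1_cm=float(np.quantile(values, 0.25, method=QUANTILE_RULE)),
                breed_q3_cm=float(np.quantile(values, 0.75, method=QUANTILE_RULE)),
            )
        )
    return out


def classify_cohorts(summaries: list[BreedSummary]) -> CohortAssignment:
    """Apply the stringent quartile rule over all breed values."""
    if len(summaries) < 4:
        raise CohortError("need at least 4 breeds for quartile classification")
    values = np.array([s.breed_value_cm for s in summaries], float)
    q1 = float(np.quantile(values, 0.25, method=QUANTILE_RULE))
    med = float(np.quantile(values, 0.50, method=QUANTILE_RULE))
    q3 = float(np.quantile(values, 0.75, method=QUANTILE_RULE))

    classes = {}
    for s in summaries:
        cls = "medium"
        if s.breed_value_cm > q3 and (s.n_countries < 2 or s.breed_q1_cm > med):
            cls = "large"
        elif s.breed_value_cm < q1 and (s.n_countries < 2 or s.breed_q3_cm < med):
            cls = "small"
        classes[s.breed] = cls
    return CohortAssignment(
        overall_q1_cm=q1,
        overall_median_cm=med,
        overall_q3_cm=q3,
        classes=classes,
        summaries={s.breed: s for s in summaries},
    )


def cohort_samples(assignment: CohortAssignment, panel) -> tuple[list, list]:
    """Genotyped sample ids of the large and small cohorts.

    Breeds genotyped but absent from the phenotype classification are
    treated as medium (and logged); medium samples are excluded.
    """
    large, small = [], []
    unknown = set()
    for sid, breed in zip(panel.samples["sample_id"], panel.samples["breed"]):
        cls = assignment.classes.get(breed)
        if cls is None:
            unknown.add(breed)
            continue
        if cls == "large":
            large.append(sid)
        elif cls == "small":
            small.append(sid)
    if unknown:
        log.info("breeds without phenotype classification treated as medium: %s",
                 sorted(unknown))
    if not large or not small:
        raise CohortError(
            "a contrasting cohort has zero genotyped samples "
            f"(large={len(large)}, small={len(small)})"
        )
    return large, small
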