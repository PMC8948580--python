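"""Tissue-provenance arithmetic from parabiosis and photoconversion assays.

Parabiosis joins two congenically marked mice (CD45.1/CD45.2) so they share
a blood circulation.  The partner-derived fraction of a tissue population,
normalised to the partner-derived fraction in blood, estimates how much of
that population was recruited from the circulation:

    recruitment% = 100 * tissue_chimerism / blood_chimerism

Per-mouse recruitment percentages are averaged (unweighted mean of ratios),
and the mean is combined with steady-state and post-injury cell counts:
the accumulated count is post - steady, the recruited count is the mean
recruitment applied to the accumulation, and the recruited fraction of the
total pool is recruited / post.  Intermediates are carried at full
precision; display values are rounded half-up to one decimal, and the
recruited count is rounded to the nearest cell before the final fraction —
the order that reproduces the published worked chain
(100/35.7*30.9 = 86.6; 78.6% of 5355 -> 4209; 4209/5375 = 78.3%).

Photoconversion (KikGR) tags cells in one lymph node; the migration ratio
of an organ is its photoconverted-cell fraction divided by the fraction in
a nondraining lymph node, which measures systemic circulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tregprov")

__all__ = [
    "ParabiosisMouse",
    "RecruitmentEstimate",
    "PhotoconversionSample",
    "round_half_up",
    "normalize_recruitment",
    "recruitment_chain",
    "estimate_recruitment",
    "bootstrap_recruitment_ci",
    "migration_ratio",
    "read_cohort_csv",
    "read_photoconversion_csv",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), not banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class ParabiosisMouse:
    """Chimerism measurements for one parabiont, in percent."""

    mouse_id: str
    blood_chimerism_pct: float
    tissue_chimerism_pct: float

    def __post_init__(self):
        if not self.blood_chimerism_pct > 0:
            raise ValueError(
                f"{self.mouse_id}: blood chimerism must be > 0 "
                f"(got {self.blood_chimerism_pct})"
            )
        if self.tissue_chimerism_pct < 0:
            raise ValueError(f"{self.mouse_id}: tissue chimerism must be >= 0")


@dataclass(slots=True)
class RecruitmentEstimate:
    """Full provenance of the recruitment calculation.

    The three headline percentages are deliberately kept distinct: the mean
    per-mouse recruitment (share of *new* cells that are blood-derived), the
    recruited fraction of the *accumulation*, and the recruited fraction of
    the *total* post-injury pool.
    """

    per_mouse_recruitment_pct: list[float]
    mean_recruitment_pct: float
    steady_state_count: int
    post_injury_count: int
    accumulated_count: int
    recruited_count: int
    recruited_fraction_of_total_pct: float
    over_100_flags: list[bool] = field(default_factory=list)

    def display(self) -> dict:
        """Rounded human-readable summary (full precision lives on the fields)."""
        return {
            "per_mouse_recruitment_pct": [round_half_up(v) for v in self.per_mouse_recruitment_pct],
            "mean_recruitment_pct": round_half_up(self.mean_recruitment_pct),
            "steady_state_count": self.steady_state_count,
            "post_injury_count": self.post_injury_count,
            "accumulated_count": self.accumulated_count,
            "recruited_count": self.recruited_count,
            "recruited_fraction_of_total_pct": round_half_up(self.recruited_fraction_of_total_pct),
        }

    def to_dict(self) -> dict:
        return {
            "per_mouse_recruitment_pct": self.per_mouse_recruitment_pct,
            "mean_recruitment_pct": self.mean_recruitment_pct,
            "steady_state_count": self.steady_state_count,
            "post_injury_count": self.post_injury_count,
            "accumulated_count": self.accumulated_count,
            "recruited_count": self.recruited_count,
            "recruited_fraction_of_total_pct": self.recruited_fraction_of_total_pct,
            "over_100_flags": self.over_100_flags,
            "display": self.display(),
        }


@dataclass(frozen=True, slots=True)
class PhotoconversionSample:
    organ: str
    phc_fraction: float
    is_nondraining_reference: bool = False

    def __post_init__(self):
        if not 0 <= self.phc_fraction <= 1:
            raise ValueError(f"{self.organ}: phc_fraction must be in [0, 1]")


def normalize_recruitment(blood_pct: float, tissue_pct: float) -> float:
    """Tissue chimerism normalised to blood chimerism, in percent.

    Values above 100% are returned unclipped (a warning is logged);
    truncating them would bias a cohort mean downward.
    """
    if not blood_pct > 0:
        raise ValueError(f"blood chimerism must be > 0, got {blood_pct}")
    if tissue_pct < 0:
        raise ValueError(f"tissue chimerism must be >= 0, got {tissue_pct}")
    value = 100.0 * tissue_pct / blood_pct
    if value > 100.0:
        logger.warning(
            "normalized recruitment %.1f%% exceeds 100%% (blood %.3g, tissue %.3g)",
            value, blood_pct, tissue_pct,
        )
    return value


def recruitment_chain(
    mean_recruitment_pct: float, steady_state_count: int, post_injury_count: int
) -> RecruitmentEstimate:
    """Combine a mean recruitment percentage with cell counts.

    accumulated = post - steady; recruited = round(mean% of accumulated);
    fraction of total = 100 * recruited / post.
    """
    if steady_state_count < 0:
        raise ValueError("steady-state count must be >= 0")
    if post_injury_count < steady_state_count:
        raise ValueError(
            f"post-injury count ({post_injury_count}) below steady state "
            f"({steady_state_count})"
        )
    if post_injury_count <= 0:
        raise ValueError("post-injury count must be positive")
    accumulated = post_injury_count - steady_state_count
    recruited = int(round_half_up(mean_recruitment_pct / 100.0 * accumulated, 0))
    fraction_total = 100.0 * recruited / post_injury_count
    return RecruitmentEstimate(
        per_mouse_recruitment_pct=[],
        mean_recruitment_pct=mean_recruitment_pct,
        steady_state_count=steady_state_count,
        post_injury_count=post_injury_count,
        accumulated_count=accumulated,
        recruited_count=recruited,
        recruited_fraction_of_total_pct=fraction_total,
    )


def estimate_recruitment(
    cohort: Sequence[ParabiosisMouse],
    steady_state_count: int,
    post_injury_count: int,
    *,
    weighted: bool = False,
) -> RecruitmentEstimate:
    """Per-mouse normalisation, cohort mean, and the count chain.

    The cohort mean is the unweighted mean of per-mouse normalised values
    (mean of ratios, never ratio of means).  ``weighted=True`` instead
    weights each mouse by its blood chimerism, an optional alternative.
    """
    if not cohort:
        raise ValueError("empty parabiosis cohort")
    per_mouse = [
        normalize_recruitment(m.blood_chimerism_pct, m.tissue_chimerism_pct)
        for m in cohort
    ]
    if weighted:
        w = np.array([m.blood_chimerism_pct for m in cohort])
        mean_pct = float(np.average(per_mouse, weights=w))
    else:
        mean_pct = float(np.mean(per_mouse))
    est = recruitment_chain(mean_pct, steady_state_count, post_injury_count)
    est.per_mouse_recruitment_pct = per_mouse
    est.over_100_flags = [v > 100.0 for v in per_mouse]
    return est


def bootstrap_recruitment_ci(
    cohort: Sequence[ParabiosisMouse],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI (resampling mice) for the cohort mean."""
    if not cohort:
        raise ValueError("empty parabiosis cohort")
    per_mouse = np.array(
        [normalize_recruitment(m.blood_chimerism_pct, m.tissue_chimerism_pct) for m in cohort]
    )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(per_mouse), size=(n_boot, len(per_mouse)))
    means = per_mouse[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def migration_ratio(samples: Sequence[PhotoconversionSample]) -> pd.DataFrame:
    """Photoconverted fractions normalised to the nondraining-LN reference.

    Exactly one sample must be flagged as the nondraining reference and it
    must have a positive fraction; its own ratio is 1 by construction.
    """
    refs = [s for s in samples if s.is_nondraining_reference]
    if len(refs) != 1:
        raise ValueError(
            f"exactly one nondraining reference organ required, got {len(refs)}"
        )
    ref = refs[0]
    if not ref.phc_fraction > 0:
        raise ValueError(f"reference organ {ref.organ} has zero photoconverted fraction")
    rows = [
        {
            "organ": s.organ,
            "phc_fraction": s.phc_fraction,
            "migration_ratio": s.phc_fraction / ref.phc_fraction,
            "is_reference": s.is_nondraining_reference,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["organ", "phc_fraction", "migration_ratio", "is_reference"])


def read_cohort_csv(path) -> list[ParabiosisMouse]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["mouse_id", "blood_chimerism_pct", "tissue_chimerism_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return [
        ParabiosisMouse(str(r.mouse_id), float(r.blood_chimerism_pct), float(r.tissue_chimerism_pct))
        for r in df.itertuples(index=False)
    ]


def read_photoconversion_csv(path) -> list[PhotoconversionSample]:
    df = pd.read_csv(path)
    required = ["organ", "phc_fraction", "is_nondraining_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    def as_bool(v) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return str(v).strip().lower() in ("true", "t", "1", "yes")

    return [
        PhotoconversionSample(
            str(r.organ), float(r.phc_fraction), as_bool(r.is_nondraining_reference)
        )
        for r in df.itertuples(index=False)
    ]
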