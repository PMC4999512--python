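"""Species-level comparative table for helper-effort analyses.

Builds the analysis table consumed by the PGLS machinery: a standardized
measure of helper effort (helper provisioning rate as a percentage of a
sex-ratio-weighted parental benchmark), mean helper-brood kinship from
pedigree class mixtures, the ecological predictors, and the
inclusion/exclusion filters (extra-pair paternity threshold, conservative
re-analysis flags).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProvisioningInput",
    "PedigreeComposition",
    "SpeciesRecord",
    "parental_benchmark",
    "helper_effort",
    "mean_kinship",
    "transform_response",
    "apply_filters",
    "standardize_predictors",
    "read_species_csv",
    "write_species_csv",
    "write_exclusion_log",
    "PREDICTOR_COLUMNS",
]

#: Predictor columns, in the order they enter the design matrix.
PREDICTOR_COLUMNS = ("kinship_r", "sexratio_pct_male", "group_size", "pct_nests_helped")

#: Extra-pair paternity threshold (%) above which the parental benchmark
#: (parents assumed related to the brood at r = 0.5) is considered invalid.
DEFAULT_EPP_THRESHOLD = 20.0

#: EPP band (%) additionally excluded in the conservative re-analysis.
CONSERVATIVE_EPP_BAND = (10.0, 20.0)


@dataclass(frozen=True)
class ProvisioningInput:
    """Raw per-species provisioning rates (feeds/hour) in helped groups.

    Rates are assumed already corrected, within the source study, to the
    average helped-group size and brood size at a standard nestling age;
    such corrections are provenance of the inputs, not recomputed here.
    At least one of ``helper_rate_pooled`` or both sex-specific helper
    rates must be present.
    """

    species_id: str
    breeder_male_rate: float
    breeder_female_rate: float
    prop_male_helpers: float
    helper_rate_pooled: float | None = None
    helper_rate_male: float | None = None
    helper_rate_female: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("breeder_male_rate", "breeder_female_rate",
                     "helper_rate_pooled", "helper_rate_male", "helper_rate_female"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v):
                raise ValueError(f"{self.species_id}: {name} is not finite")
            if v < 0:
                raise ValueError(f"{self.species_id}: {name} is negative ({v})")
        if not 0.0 <= self.prop_male_helpers <= 1.0:
            raise ValueError(
                f"{self.species_id}: prop_male_helpers must be in [0, 1], "
                f"got {self.prop_male_helpers}")
        if self.helper_rate_pooled is None and (
                self.helper_rate_male is None or self.helper_rate_female is None):
            raise ValueError(
                f"{self.species_id}: need helper_rate_pooled or both "
                "sex-specific helper rates")


@dataclass(frozen=True)
class PedigreeComposition:
    """Mixture of pedigree classes among a species' helpers.

    ``classes`` is a sequence of ``(r, proportion)`` pairs, e.g. full
    siblings (r=0.5), half siblings (r=0.25), unrelated (r=0). Proportions
    must sum to one.
    """

    species_id: str
    classes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple((float(r), float(p)) for r, p in self.classes))
        for r, p in self.classes:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{self.species_id}: relatedness {r} outside [0, 1]")
            if p < 0:
                raise ValueError(f"{self.species_id}: negative class proportion {p}")
        total = sum(p for _, p in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.species_id}: pedigree class proportions sum to {total}, not 1")


@dataclass
class SpeciesRecord:
    """One species' derived response, predictors and exclusion metadata."""

    species_id: str
    effort_pct: float
    kinship_r: float
    sexratio_pct_male: float
    group_size: float
    pct_nests_helped: float
    quality: int
    epp_rate: float | None = None   # None = unknown
    conservative_flag: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.quality not in (1, 2, 3):
            raise ValueError(f"{self.species_id}: quality must be 1, 2 or 3, got {self.quality}")
        if not self.effort_pct > 0:
            raise ValueError(f"{self.species_id}: effort_pct must be > 0 (log response)")
        if not 0.0 <= self.kinship_r <= 1.0:
            raise ValueError(f"{self.species_id}: kinship_r outside [0, 1]")
        if not 0.0 <= self.sexratio_pct_male <= 100.0:
            raise ValueError(f"{self.species_id}: sexratio_pct_male outside [0, 100]")
        if self.group_size < 2:
            raise ValueError(f"{self.species_id}: group_size < 2 in helped groups")
        if not 0.0 < self.pct_nests_helped <= 100.0:
            raise ValueError(f"{self.species_id}: pct_nests_helped outside (0, 100]")
        if self.epp_rate is not None and not 0.0 <= self.epp_rate <= 100.0:
            raise ValueError(f"{self.species_id}: epp_rate outside [0, 100]")


def parental_benchmark(p: ProvisioningInput) -> float:
    """Sex-ratio-weighted parental provisioning rate (feeds/hour).

    With a fraction ``s`` of helpers male, the benchmark is
    ``s * breeder_male_rate + (1 - s) * breeder_female_rate``: helpers'
    effort is judged against the breeder of their own sex, so a 70% male
    helper force weights the benchmark 70:30 toward the male breeder.
    """
    s = p.prop_male_helpers
    return s * p.breeder_male_rate + (1.0 - s) * p.breeder_female_rate


def helper_effort(p: ProvisioningInput) -> float:
    """Helper provisioning rate as a percentage of the parental benchmark.

    A helper visiting at the breeders' rate scores 100%, at half their rate
    50%; values above 100% are legitimate (helpers outworking breeders).
    When only sex-specific helper rates are available they are pooled with
    the same sex-ratio weights as the parental benchmark.
    """
    bench = parental_benchmark(p)
    if bench <= 0:
        raise ValueError(
            f"{p.species_id}: parental benchmark is {bench}; helper effort undefined")
    if p.helper_rate_pooled is not None:
        rate = p.helper_rate_pooled
    else:
        s = p.prop_male_helpers
        rate = s * p.helper_rate_male + (1.0 - s) * p.helper_rate_female
    return 100.0 * rate / bench


def mean_kinship(c: PedigreeComposition) -> float:
    """Mean helper-brood relatedness: proportion-weighted mixture over classes."""
    return float(sum(p * r for r, p in c.classes))


def transform_response(effort_pct: float) -> float:
    """Natural log of helper effort (%), the model response."""
    arr = np.asarray(effort_pct, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("helper effort must be > 0 to take logs")
    out = np.log(arr)
    return float(out) if out.ndim == 0 else out


@dataclass
class FilterResult:
    records: list[SpeciesRecord]
    exclusions: list[dict] = field(default_factory=list)


def apply_filters(
    records: Sequence[SpeciesRecord],
    mode: str = "full",
    epp_threshold_full: float = DEFAULT_EPP_THRESHOLD,
    named_exclusions: Iterable[str] | None = None,
) -> FilterResult:
    """Apply the inclusion rules and return survivors plus an exclusion log.

    ``full`` mode drops species whose known extra-pair paternity rate
    exceeds ``epp_threshold_full`` (species with unknown EPP are retained
    but logged). ``conservative`` mode additionally drops species carrying
    a per-record conservative flag (juvenile helpers, multi-nest
    provisioning, paternity-linked helping, single-group data) and those
    in the 10-20% EPP band. ``named_exclusions`` drops listed species by
    name; unknown names warn rather than fail.
    """
    if mode not in ("full", "conservative"):
        raise ValueError(f"mode must be 'full' or 'conservative', got {mode!r}")
    named = set(named_exclusions or ())
    known_ids = {r.species_id for r in records}
    for name in sorted(named - known_ids):
        warnings.warn(f"named exclusion {name!r} not present in the record set",
                      stacklevel=2)

    kept: list[SpeciesRecord] = []
    log: list[dict] = []
    lo, hi = CONSERVATIVE_EPP_BAND
    for rec in records:
        if rec.species_id in named:
            log.append({"species_id": rec.species_id, "mode": mode,
                        "rule": "named_exclusion", "reason": "listed by caller"})
            continue
        if rec.epp_rate is not None and rec.epp_rate > epp_threshold_full:
            log.append({"species_id": rec.species_id, "mode": mode,
                        "rule": "epp_above_threshold",
                        "reason": f"EPP {rec.epp_rate}% > {epp_threshold_full}%"})
            continue
        if rec.epp_rate is None:
            log.append({"species_id": rec.species_id, "mode": mode,
                        "rule": "epp_unknown_retained",
                        "reason": "EPP unknown; retained and flagged"})
        if mode == "conservative":
            if rec.conservative_flag:
                log.append({"species_id": rec.species_id, "mode": mode,
                            "rule": "conservative_flag",
                            "reason": rec.reason or "flagged for conservative exclusion"})
                continue
            if rec.epp_rate is not None and lo <= rec.epp_rate <= hi:
                log.append({"species_id": rec.species_id, "mode": mode,
                            "rule": "epp_band",
                            "reason": f"EPP {rec.epp_rate}% in [{lo}, {hi}]%"})
                continue
        kept.append(rec)
    return FilterResult(records=kept, exclusions=log)


@dataclass
class Standardization:
    """Design matrix with z-scored predictors plus back-transform metadata."""

    X: np.ndarray                 # n x (1 + k), first column the intercept
    columns: tuple[str, ...]      # including "intercept"
    means: np.ndarray             # predictor means, length k
    sds: np.ndarray               # predictor sample SDs (ddof=1), length k

    def unstandardize_beta(self, beta_std: np.ndarray, sd_y: float = 1.0) -> np.ndarray:
        """Map coefficients from the z-scored scale back to raw units.

        ``beta_raw_j = sd_y * beta_std_j / sd_x_j`` for slopes; the raw
        intercept is recovered so the fitted line passes through the means.
        """
        beta_std = np.asarray(beta_std, dtype=float)
        slopes = sd_y * beta_std[1:] / self.sds
        intercept = sd_y * beta_std[0] - np.sum(slopes * self.means)
        return np.concatenate([[intercept], slopes])


def standardize_predictors(
    records: Sequence[SpeciesRecord],
    columns: Sequence[str] = PREDICTOR_COLUMNS,
) -> Standardization:
    """z-score each predictor (sample SD) and prepend an intercept column."""
    if len(records) < 3:
        raise ValueError("need at least 3 records to standardize predictors")
    raw = np.array([[getattr(r, c) for c in columns] for r in records], dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    for j, c in enumerate(columns):
        if sds[j] == 0 or not np.isfinite(sds[j]):
            raise ValueError(f"predictor {c!r} has zero variance; cannot z-score")
    Z = (raw - means) / sds
    X = np.column_stack([np.ones(len(records)), Z])
    return Standardization(X=X, columns=("intercept", *columns), means=means, sds=sds)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["species_id", "effort_pct", "kinship_r", "sexratio_pct_male",
               "group_size", "pct_nests_helped", "quality", "epp_rate",
               "conservative_flag", "reason"]


def read_species_csv(path) -> list[SpeciesRecord]:
    """Read the species table (UTF-8 CSV, empty cell = missing EPP)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c not in ("reason",)]
    if missing:
        raise ValueError(f"species CSV missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        epp = getattr(row, "epp_rate")
        epp = None if pd.isna(epp) else float(epp)
        reason = getattr(row, "reason", "")
        reason = "" if (isinstance(reason, float) and math.isnan(reason)) else str(reason)
        flag = getattr(row, "conservative_flag", False)
        records.append(SpeciesRecord(
            species_id=str(row.species_id),
            effort_pct=float(row.effort_pct),
            kinship_r=float(row.kinship_r),
            sexratio_pct_male=float(row.sexratio_pct_male),
            group_size=float(row.group_size),
            pct_nests_helped=float(row.pct_nests_helped),
            quality=int(row.quality),
            epp_rate=epp,
            conservative_flag=bool(flag) and not pd.isna(flag),
            reason=reason,
        ))
    return records


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in CSV_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_species_csv(records: Sequence[SpeciesRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_exclusion_log(exclusions: Sequence[dict], path) -> None:
    """Write the exclusion log as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in exclusions:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
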