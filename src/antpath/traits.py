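"""Species-level social-trait curation.

Implements the aggregation and recoding rules for the five colony traits:
number of physical worker castes (1-4), colony size, effective queen mating
frequency, number of queens per colony, and the coefficient of variation of
worker head width.  Repeated observations are aggregated per species
(harmonic mean for mating frequency, sample-size-weighted arithmetic mean
for colony size, pooled CV for head widths), species with derived life
histories are excluded, and analysis tables are produced on transformed
scales (log10 for the three size-like traits, square root for the CV).

Input format: a tidy UTF-8 CSV/TSV with one row per species-observation.

Column dictionary
-----------------
species, genus                   text; ``species`` is the binomial
n_castes                         integer 1-4 (may repeat across rows)
colony_size                      workers per colony for one estimate
colony_size_sample_n             colonies behind that estimate (optional)
mating_frequency                 effective queen mating frequency (>= 1)
queen_number                     queens per colony (>= 1)
mating_category                  monandry | facultative_polyandry | obligate_polyandry
queen_category                   monogyny | facultative_polygyny | obligate_polygyny
head_width_mm                    one worker head width per row
supercolonial, social_parasite, thelytokous, gamergate,
hybrid_caste_determination       exclusion flags (0/1); temporary social
                                 parasites are NOT flagged and stay in
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraitRecord",
    "CasteAnnotation",
    "aggregate_mating_frequency",
    "aggregate_colony_size",
    "worker_size_cv",
    "apply_caste_criteria",
    "apply_exclusions",
    "transform_traits",
    "binarize_traits",
    "collapse_categories",
    "load_species_table",
    "records_to_species_frame",
    "build_analysis_table",
]

EXCLUSION_FLAGS = (
    "supercolonial",
    "social_parasite",
    "thelytokous",
    "gamergate",
    "hybrid_caste_determination",
)
MATING_CATEGORIES = ("monandry", "facultative_polyandry", "obligate_polyandry")
QUEEN_CATEGORIES = ("monogyny", "facultative_polygyny", "obligate_polygyny")


class TraitValidationError(ValueError):
    pass


@dataclass
class CasteAnnotation:
    """Morphometric / literature evidence behind a caste count."""

    size_variation: str | None = None          # "limited" | "present"
    scaling: str | None = None                 # "monophasic_allometric" | "non_allometric"
    n_scaling_relationships: int | None = None
    literature_caste_count: int | None = None


@dataclass
class SpeciesTraitRecord:
    """One species' raw and derived social traits."""

    species_name: str
    genus: str = ""
    n_castes: int | None = None
    colony_size_estimates: list[tuple[float, int | None]] = field(default_factory=list)
    mating_frequency_observations: list[float] = field(default_factory=list)
    queen_number_observations: list[float] = field(default_factory=list)
    mating_category: str | None = None
    queen_category: str | None = None
    head_widths_mm: list[float] = field(default_factory=list)
    exclusion_flags: set[str] = field(default_factory=set)
    caste_annotation: CasteAnnotation | None = None

    def validate(self) -> None:
        if self.n_castes is not None and self.n_castes not in (1, 2, 3, 4):
            raise TraitValidationError(
                f"{self.species_name}: n_castes must be 1-4, got {self.n_castes}"
            )
        for w, n in self.colony_size_estimates:
            if w <= 0:
                raise TraitValidationError(f"{self.species_name}: colony size {w} <= 0")
            if n is not None and n <= 0:
                raise TraitValidationError(f"{self.species_name}: sample size {n} <= 0")
        for x in self.mating_frequency_observations:
            if x < 1:
                raise TraitValidationError(
                    f"{self.species_name}: mating frequency {x} < 1"
                )
        for x in self.queen_number_observations:
            if x < 1:
                raise TraitValidationError(f"{self.species_name}: queen number {x} < 1")
        for x in self.head_widths_mm:
            if x <= 0:
                raise TraitValidationError(f"{self.species_name}: head width {x} <= 0")
        if self.mating_category is not None and self.mating_category not in MATING_CATEGORIES:
            raise TraitValidationError(
                f"{self.species_name}: unknown mating category {self.mating_category!r}"
            )
        if self.queen_category is not None and self.queen_category not in QUEEN_CATEGORIES:
            raise TraitValidationError(
                f"{self.species_name}: unknown queen category {self.queen_category!r}"
            )
        if not self.exclusion_flags <= set(EXCLUSION_FLAGS):
            raise TraitValidationError(
                f"{self.species_name}: unknown exclusion flags "
                f"{self.exclusion_flags - set(EXCLUSION_FLAGS)}"
            )


# -- aggregation ops -------------------------------------------------------

def aggregate_mating_frequency(observations: Sequence[float]) -> float:
    """Harmonic mean of effective mating frequencies.

    The harmonic mean weights low frequencies more, mirroring their larger
    effect on within-colony relatedness.  Empty input -> NaN; values below 1
    are invalid (an effective frequency cannot be below one mate).
    """
    if len(observations) == 0:
        return math.nan
    obs = np.asarray(observations, dtype=float)
    if np.any(obs < 1):
        raise TraitValidationError("mating frequencies must be >= 1")
    return float(len(obs) / np.sum(1.0 / obs))


def aggregate_colony_size(estimates: Sequence[tuple[float, int | None]]) -> float:
    """Arithmetic mean colony size weighted by sample size.

    Estimates lacking a sample size contribute with weight one.
    """
    if len(estimates) == 0:
        return math.nan
    sizes = np.array([w for w, _ in estimates], dtype=float)
    if np.any(sizes <= 0):
        raise TraitValidationError("colony sizes must be positive")
    weights = np.array([1.0 if n is None or (isinstance(n, float) and math.isnan(n)) else float(n)
                        for _, n in estimates])
    if np.any(weights <= 0):
        raise TraitValidationError("sample sizes must be positive")
    return float(np.sum(sizes * weights) / np.sum(weights))


def worker_size_cv(head_widths_mm: Sequence[float], ddof: int = 1) -> float:
    """Coefficient of variation of worker head width (sd / mean).

    Uses the sample standard deviation (``ddof=1``) by default.  Fewer than
    two measurements -> NaN (a CV is then undefined).
    """
    if len(head_widths_mm) < 2:
        return math.nan
    x = np.asarray(head_widths_mm, dtype=float)
    if np.any(x <= 0):
        raise TraitValidationError("head widths must be positive")
    return float(np.std(x, ddof=ddof) / np.mean(x))


def apply_caste_criteria(annotation: CasteAnnotation) -> int:
    """Number of physical worker castes implied by morphometric evidence.

    Limited size variation or monophasic allometric scaling -> one caste;
    non-allometric scaling -> the number of distinct scaling relationships;
    no morphometrics -> the direct literature count.
    """
    a = annotation
    if a.size_variation == "limited" or a.scaling == "monophasic_allometric":
        if a.n_scaling_relationships is not None and a.n_scaling_relationships > 1:
            raise TraitValidationError(
                "contradictory annotation: limited variation / monophasic scaling "
                f"with {a.n_scaling_relationships} scaling relationships"
            )
        return 1
    if a.scaling == "non_allometric":
        if a.n_scaling_relationships is None:
            raise TraitValidationError(
                "non-allometric scaling requires n_scaling_relationships"
            )
        return int(a.n_scaling_relationships)
    if a.literature_caste_count is not None:
        return int(a.literature_caste_count)
    raise TraitValidationError("caste annotation carries no usable evidence")


def apply_exclusions(
    records: Iterable[SpeciesTraitRecord],
) -> tuple[list[SpeciesTraitRecord], list[SpeciesTraitRecord]]:
    """Drop species with derived life histories.

    Supercolonial, socially parasitic (other than temporary parasites, which
    are never flagged), thelytokous, gamergate-reproducing and
    hybrid-caste-determined species leave the analysis set.
    """
    retained, excluded = [], []
    for rec in records:
        (excluded if rec.exclusion_flags else retained).append(rec)
    return retained, excluded


def collapse_categories(category: str, scheme: str = "three_level") -> str:
    """Recode a mating/queen category.

    ``three_level`` is the identity; ``obligate_binary`` collapses monandry
    with facultative polyandry (and monogyny with facultative polygyny) into
    ``not_obligate`` versus ``obligate``.
    """
    if category in MATING_CATEGORIES or category in QUEEN_CATEGORIES:
        if scheme == "three_level":
            return category
        if scheme == "obligate_binary":
            return "obligate" if category.startswith("obligate") else "not_obligate"
        raise ValueError(f"unknown scheme {scheme!r}")
    raise ValueError(f"unknown category {category!r}")


# -- table-level ops -------------------------------------------------------

def records_to_species_frame(records: Iterable[SpeciesTraitRecord]) -> pd.DataFrame:
    """One aggregated row per species, with provenance counts."""
    rows = []
    seen: set[str] = set()
    for rec in records:
        rec.validate()
        if rec.species_name in seen:
            raise TraitValidationError(f"duplicate species {rec.species_name!r}")
        seen.add(rec.species_name)
        rows.append(
            {
                "species": rec.species_name,
                "genus": rec.genus,
                "castes": rec.n_castes if rec.n_castes is not None else (
                    apply_caste_criteria(rec.caste_annotation)
                    if rec.caste_annotation is not None
                    else np.nan
                ),
                "colony_size": aggregate_colony_size(rec.colony_size_estimates),
                "mating_frequency": aggregate_mating_frequency(
                    rec.mating_frequency_observations
                ),
                "queen_number": (
                    float(np.mean(rec.queen_number_observations))
                    if rec.queen_number_observations
                    else np.nan
                ),
                "worker_cv": worker_size_cv(rec.head_widths_mm),
                "mating_category": rec.mating_category,
                "queen_category": rec.queen_category,
                "n_colony_size_obs": len(rec.colony_size_estimates),
                "n_mating_obs": len(rec.mating_frequency_observations),
                "n_queen_obs": len(rec.queen_number_observations),
                "n_head_widths": len(rec.head_widths_mm),
            }
        )
    return pd.DataFrame(rows)


def transform_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Analysis scales: log10 size-like traits, square-root CV."""
    out = table.copy()
    for col, new in [
        ("colony_size", "log10_colony_size"),
        ("mating_frequency", "log10_mating_frequency"),
        ("queen_number", "log10_queen_number"),
    ]:
        if col in out:
            vals = out[col].astype(float)
            if (vals <= 0).any():
                raise TraitValidationError(f"non-positive {col} cannot be log10-transformed")
            out[new] = np.log10(vals)
    if "worker_cv" in out:
        if (out["worker_cv"] < 0).any():
            raise TraitValidationError("negative CV")
        out["sqrt_worker_cv"] = np.sqrt(out["worker_cv"].astype(float))
    if "castes" in out:
        out["castes_binary"] = np.where(
            out["castes"].isna(), None, np.where(out["castes"] > 1, "multiple", "single")
        )
    return out


def binarize_traits(
    table: pd.DataFrame,
    colony_rule: str = "median",
    mating_threshold: float = 2.0,
) -> pd.DataFrame:
    """Two-class codings for the transition-rate stage.

    Colony sizes at or below the threshold (the median by default, or the
    40th/60th percentile under ``q40``/``q60``) are ``small``; mating
    frequencies at or below ``mating_threshold`` (2 mates) are ``low``.
    Thresholds are computed on the species present in ``table`` (the subset
    entering the analysis), with ties going to the lower class.
    """
    out = table.copy()
    quant = {"median": 0.5, "q40": 0.4, "q60": 0.6}
    if colony_rule not in quant:
        raise ValueError(f"unknown colony rule {colony_rule!r}")
    if "colony_size" in out:
        sizes = out["colony_size"].astype(float)
        if sizes.notna().sum() == 0:
            raise TraitValidationError("colony size entirely missing")
        thr = float(np.nanquantile(sizes, quant[colony_rule]))
        out["colony_size_class"] = np.where(
            sizes.isna(), None, np.where(sizes > thr, "large", "small")
        )
        out.attrs["colony_size_threshold"] = thr
        out.attrs["colony_rule"] = colony_rule
    if "mating_frequency" in out:
        mf = out["mating_frequency"].astype(float)
        out["mating_class"] = np.where(
            mf.isna(), None, np.where(mf > mating_threshold, "high", "low")
        )
        out.attrs["mating_threshold"] = float(mating_threshold)
    for cat_col, out_col in [
        ("mating_category", "obligate_polyandry_binary"),
        ("queen_category", "obligate_polygyny_binary"),
    ]:
        if cat_col in out:
            out[out_col] = [
                None if c is None or (isinstance(c, float) and math.isnan(c))
                else collapse_categories(c, "obligate_binary")
                for c in out[cat_col]
            ]
    return out


def build_analysis_table(
    records: Iterable[SpeciesTraitRecord],
    colony_rule: str = "median",
    mating_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full curation: validate, exclude, aggregate, transform, binarise.

    Returns ``(analysis_table, excluded_table)``.  Missing data stay as NaN:
    each downstream analysis takes its own maximal complete-case subset.
    """
    retained, excluded = apply_exclusions(list(records))
    table = records_to_species_frame(retained)
    table = transform_traits(table)
    table = binarize_traits(table, colony_rule=colony_rule, mating_threshold=mating_threshold)
    excl = records_to_species_frame(excluded) if excluded else pd.DataFrame()
    return table, excl


def load_species_table(source) -> list[SpeciesTraitRecord]:
    """Read the tidy observation-level CSV/TSV into species records.

    ``source`` is a path or a DataFrame following the module's column
    dictionary; rows sharing a ``species`` value are one species' repeated
    observations.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep)
    if "species" not in df.columns:
        raise TraitValidationError("input must carry a 'species' column")
    records = []
    for species, grp in df.groupby("species", sort=True):
        rec = SpeciesTraitRecord(species_name=str(species))
        if "genus" in grp and grp["genus"].notna().any():
            rec.genus = str(grp["genus"].dropna().iloc[0])
        elif " " in str(species):
            rec.genus = str(species).split()[0]
        if "n_castes" in grp and grp["n_castes"].notna().any():
            rec.n_castes = int(grp["n_castes"].dropna().iloc[0])
        if "colony_size" in grp:
            for _, row in grp.iterrows():
                w = row.get("colony_size")
                if pd.notna(w):
                    n = row.get("colony_size_sample_n")
                    rec.colony_size_estimates.append(
                        (float(w), int(n) if pd.notna(n) else None)
                    )
        for col, target in [
            ("mating_frequency", rec.mating_frequency_observations),
            ("queen_number", rec.queen_number_observations),
            ("head_width_mm", rec.head_widths_mm),
        ]:
            if col in grp:
                target.extend(float(v) for v in grp[col].dropna())
        if "mating_category" in grp and grp["mating_category"].notna().any():
            rec.mating_category = str(grp["mating_category"].dropna().iloc[0])
        if "queen_category" in grp and grp["queen_category"].notna().any():
            rec.queen_category = str(grp["queen_category"].dropna().iloc[0])
        for flag in EXCLUSION_FLAGS:
            if flag in grp and grp[flag].fillna(0).astype(float).any():
                rec.exclusion_flags.add(flag)
        rec.validate()
        records.append(rec)
    return records
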