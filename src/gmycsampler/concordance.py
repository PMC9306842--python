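"""Score a GMYC species partition against user-predefined groups.

Scoring unit is the GMYC species.  A multi-sample species containing two
or more user groups is a merge (``n``); type II when at least one of the
constituent groups has exactly one sample in the analyzed dataset.  A
multi-sample species pure for one group is a split (``y``) when the group
also occurs in another species, else an exact match (``y``).  A
single-sample species is always scored ``singleton`` — even when it
perfectly recovers a one-sample user group.

All percentages and ratios are carried at full precision; rounding to the
reported precision (half-up) happens only at output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .data_io import GroupMap, check_tip_match
from .gmyc_model import SpeciesPartition

__all__ = [
    "SpeciesClassification",
    "MatchRow",
    "MergeRecord",
    "RunMetrics",
    "classify_species",
    "percentage_match",
    "splitting_ratio",
    "singleton_percentage",
    "per_group_split_factor",
    "run_metrics",
    "exact_match_scores",
    "round_half_up",
]

CATEGORIES = ("merge_I", "merge_II", "split", "exact", "singleton")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of the reports)."""
    if math.isnan(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
    return out


@dataclass(frozen=True)
class SpeciesClassification:
    """Category and match flag of one GMYC species."""

    species_id: int
    members: frozenset[str]
    groups_present: frozenset[str]
    category: str
    match_flag: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class MatchRow:
    """One row of the per-sample summary table."""

    sample_name: str
    gmyc_species_id: int
    user_group: str
    match_flag: str


@dataclass(frozen=True)
class MergeRecord:
    species_id: int
    groups: frozenset[str]
    merge_type: str  # "I" or "II"


@dataclass(frozen=True)
class RunMetrics:
    """All per-run concordance statistics."""

    y_count: int
    n_count: int
    singleton_count: int
    m_incl: float
    m_excl: float  # NaN when y + n == 0
    sr_incl: float
    sr_excl: float
    singleton_pct: float
    merges: tuple[MergeRecord, ...]
    exact_groups: frozenset[str]
    split_factors: dict[str, int]
    split_factors_excl_singletons: dict[str, int]
    exact_match_incidence: float
    n_species: int
    n_groups: int
    match_table: tuple[MatchRow, ...]

    def __post_init__(self) -> None:
        if self.y_count + self.n_count + self.singleton_count != self.n_species:
            raise ValueError("y + n + singletons must equal the species count")


def classify_species(
    partition: SpeciesPartition, groups: GroupMap
) -> list[SpeciesClassification]:
    """Classify each GMYC species against the predefined groups."""
    check_tip_match(partition.tips, groups)
    # Group sizes within the analyzed dataset (after any subsampling).
    dataset_group_size: dict[str, int] = {}
    group_occurrence: dict[str, int] = {}  # species containing >=1 sample of g
    for members in partition.species:
        present = {groups.group_of(n) for n in members}
        for g in present:
            group_occurrence[g] = group_occurrence.get(g, 0) + 1
        for n in members:
            g = groups.group_of(n)
            dataset_group_size[g] = dataset_group_size.get(g, 0) + 1

    out: list[SpeciesClassification] = []
    for sid, members in zip(partition.ids, partition.species):
        present = frozenset(groups.group_of(n) for n in members)
        if len(members) == 1:
            category, flag = "singleton", "singleton"
        elif len(present) >= 2:
            has_dataset_singleton = any(
                dataset_group_size[g] == 1 for g in present
            )
            category = "merge_II" if has_dataset_singleton else "merge_I"
            flag = "n"
        else:
            (g,) = present
            category = "split" if group_occurrence[g] > 1 else "exact"
            flag = "y"
        out.append(
            SpeciesClassification(
                species_id=sid,
                members=members,
                groups_present=present,
                category=category,
                match_flag=flag,
            )
        )
    return out


def percentage_match(
    y: int, n: int, s: int, include_singletons: bool
) -> float:
    """Overall percentage match.

    Including singletons: ``100 * (y + s) / (y + n + s)``; excluding:
    ``100 * y / (y + n)`` (NaN with a warning when ``y + n == 0``).
    """
    if include_singletons:
        total = y + n + s
        if total < 1:
            raise ValueError("need at least one scored species")
        return 100.0 * (y + s) / total
    if y + n == 0:
        warnings.warn("percentage match excluding singletons is undefined "
                      "(no non-singleton species)")
        return float("nan")
    return 100.0 * y / (y + n)


def splitting_ratio(
    n_species: int, n_singletons: int, n_groups: int, include_singletons: bool
) -> float:
    """GMYC species count over user-group count (optionally less singletons)."""
    if n_groups < 1:
        raise ValueError("need at least one user-defined group")
    if n_singletons > n_species:
        raise ValueError("more singletons than species")
    numerator = n_species if include_singletons else n_species - n_singletons
    return numerator / n_groups


def singleton_percentage(n_singletons: int, n_species: int) -> float:
    """Percentage of GMYC species that are singletons."""
    if n_species < 1:
        raise ValueError("need at least one species")
    return 100.0 * n_singletons / n_species


def per_group_split_factor(
    partition: SpeciesPartition,
    groups: GroupMap,
    *,
    include_singleton_species: bool = True,
) -> dict[str, int]:
    """Number of distinct GMYC species containing each group.

    A factor of 2 means the group was split over two species (oversplit by
    a factor of 2).  Singleton species count toward the factor by default.
    """
    check_tip_match(partition.tips, groups)
    factors: dict[str, int] = {}
    for members in partition.species:
        if not include_singleton_species and len(members) == 1:
            continue
        for g in {groups.group_of(n) for n in members}:
            factors[g] = factors.get(g, 0) + 1
    return factors


def run_metrics(partition: SpeciesPartition, groups: GroupMap) -> RunMetrics:
    """Aggregate the classification of one GMYC run into all metrics."""
    classifications = classify_species(partition, groups)
    y = sum(1 for c in classifications if c.match_flag == "y")
    n = sum(1 for c in classifications if c.match_flag == "n")
    s = sum(1 for c in classifications if c.match_flag == "singleton")
    groups_in_dataset = frozenset(
        groups.group_of(name) for name in partition.tips
    )
    n_groups = len(groups_in_dataset)
    merges = tuple(
        MergeRecord(
            species_id=c.species_id,
            groups=c.groups_present,
            merge_type="II" if c.category == "merge_II" else "I",
        )
        for c in classifications
        if c.category in ("merge_I", "merge_II")
    )
    exact_groups = frozenset(
        g for c in classifications if c.category == "exact" for g in c.groups_present
    )
    match_table = tuple(
        MatchRow(
            sample_name=name,
            gmyc_species_id=c.species_id,
            user_group=groups.group_of(name),
            match_flag=c.match_flag,
        )
        for c in classifications
        for name in sorted(c.members)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_excl = percentage_match(y, n, s, include_singletons=False)
    if y + n == 0:
        warnings.warn("all species are singletons: m_excl undefined")
    return RunMetrics(
        y_count=y,
        n_count=n,
        singleton_count=s,
        m_incl=percentage_match(y, n, s, include_singletons=True),
        m_excl=m_excl,
        sr_incl=splitting_ratio(partition.n_species, s, n_groups, True),
        sr_excl=splitting_ratio(partition.n_species, s, n_groups, False),
        singleton_pct=singleton_percentage(s, partition.n_species),
        merges=merges,
        exact_groups=exact_groups,
        split_factors=per_group_split_factor(partition, groups),
        split_factors_excl_singletons=per_group_split_factor(
            partition, groups, include_singleton_species=False
        ),
        exact_match_incidence=100.0 * len(exact_groups) / n_groups,
        n_species=partition.n_species,
        n_groups=n_groups,
        match_table=match_table,
    )


def exact_match_scores(
    runs: list[RunMetrics], all_groups: frozenset[str] | set[str]
) -> dict[str, float]:
    """Per-group percentage of runs in which the group was an exact match."""
    if not runs:
        raise ValueError("need at least one run")
    return {
        g: 100.0 * sum(1 for r in runs if g in r.exact_groups) / len(runs)
        for g in sorted(all_groups)
    }
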