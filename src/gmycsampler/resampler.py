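"""Random subsampling of alignments without replacement.

Subset size is the ceiling of ``fraction * n_records`` (50% of 500 gives
exactly 250 and at least one record is always kept).  With
``ensure_representation`` enabled, a two-phase draw first picks one
uniform representative for every group present in the source and then
fills the remaining slots uniformly from the rest.  Per-replicate random
streams are derived deterministically from ``(base_seed, replicate_index)``
so the same configuration always yields byte-identical outputs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .data_io import Alignment, GroupMap, write_alignment

__all__ = ["ResampleConfig", "ReplicateSet", "draw_subsample", "generate_replicates"]

MANIFEST_NAME = "resample_manifest.csv"


@dataclass(frozen=True)
class ResampleConfig:
    fraction: float
    n_replicates: int
    base_seed: int
    ensure_representation: bool = False
    group_map: GroupMap | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.ensure_representation and self.group_map is None:
            raise ValueError("ensure_representation requires a group_map")


@dataclass(frozen=True)
class ReplicateSet:
    replicates: tuple[Alignment, ...]
    seeds: tuple[int, ...]
    provenance: dict


def subset_size(fraction: float, n_records: int) -> int:
    return math.ceil(fraction * n_records)


def _replicate_rng(base_seed: int, replicate_index: int) -> np.random.Generator:
    # Derivation is part of the reproducibility contract: spawn-free,
    # order-independent streams keyed on (base_seed, replicate_index).
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(replicate_index,))
    )


def draw_subsample(
    aln: Alignment, cfg: ResampleConfig, replicate_index: int
) -> Alignment:
    """Draw one replicate: distinct records, uniform, without replacement.

    Output record order matches the source alignment.
    """
    if not (0 <= replicate_index < cfg.n_replicates):
        raise ValueError(
            f"replicate_index {replicate_index} outside [0, {cfg.n_replicates})"
        )
    target = subset_size(cfg.fraction, aln.n_records)
    rng = _replicate_rng(cfg.base_seed, replicate_index)
    names = list(aln.names)

    if cfg.ensure_representation:
        assert cfg.group_map is not None
        by_group: dict[str, list[str]] = {}
        for name in names:
            by_group.setdefault(cfg.group_map.group_of(name), []).append(name)
        if target < len(by_group):
            raise ValueError(
                f"cannot represent {len(by_group)} groups with "
                f"{target} records"
            )
        chosen: set[str] = set()
        for group in sorted(by_group):
            members = by_group[group]
            chosen.add(members[int(rng.integers(len(members)))])
        pool = [n for n in names if n not in chosen]
        extra = target - len(chosen)
        if extra > 0:
            chosen.update(rng.choice(pool, size=extra, replace=False).tolist())
    else:
        chosen = set(rng.choice(names, size=target, replace=False).tolist())

    return aln.subset(chosen)


def generate_replicates(
    aln: Alignment, cfg: ResampleConfig, out_dir: str | Path
) -> ReplicateSet:
    """Write ``n_replicates`` subsampled FASTA files plus a manifest.

    File names are ``subset_{fraction}_{rep:03d}.fasta``.  The manifest
    records fraction, per-replicate seeds and the source checksum; it
    contains nothing run-dependent, so identical configurations produce
    byte-identical directories.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    source_checksum = aln.sha256()
    replicates: list[Alignment] = []
    seeds: list[int] = []
    rows: list[dict] = []
    for rep in range(cfg.n_replicates):
        sub = draw_subsample(aln, cfg, rep)
        fname = f"subset_{cfg.fraction:g}_{rep:03d}.fasta"
        write_alignment(sub, out_dir / fname)
        seed = int(
            np.random.SeedSequence(
                entropy=cfg.base_seed, spawn_key=(rep,)
            ).generate_state(1)[0]
        )
        replicates.append(sub)
        seeds.append(seed)
        rows.append(
            {
                "file": fname,
                "fraction": cfg.fraction,
                "replicate": rep,
                "base_seed": cfg.base_seed,
                "stream_seed": seed,
                "n_records": sub.n_records,
                "source_sha256": source_checksum,
            }
        )
    with open(out_dir / MANIFEST_NAME, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    provenance = {
        "fraction": cfg.fraction,
        "base_seed": cfg.base_seed,
        "source_sha256": source_checksum,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return ReplicateSet(
        replicates=tuple(replicates), seeds=tuple(seeds), provenance=provenance
    )
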