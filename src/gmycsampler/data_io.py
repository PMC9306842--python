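"""Input/output for alignments, ultrametric trees and group tables.

This module also derives the branching-event schedule (ordered inter-node
waiting times with per-interval lineage bookkeeping) that the GMYC
likelihood consumes.

Conventions
-----------
* Node heights are measured from the tips (tips at height 0, root at
  ``depth``); every time threshold is expressed on this scale.
* Trees must be rooted and binary.  Ultrametricity is checked within a
  relative tolerance and tip heights are snapped to exactly 0.
* Sequence names are matched to tree tip labels on the first
  whitespace-delimited token of the FASTA description line.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DataError",
    "AlignmentError",
    "ValidationError",
    "EmptyInputError",
    "UltrametricityError",
    "Alignment",
    "GroupMap",
    "TreeNode",
    "UltrametricTree",
    "BranchingEvent",
    "BranchingSchedule",
    "read_alignment",
    "write_alignment",
    "read_trees",
    "read_group_map",
    "write_group_map",
    "check_tip_match",
    "branching_events",
]

#: IUPAC nucleotide one-letter codes plus gap characters.
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")
GAP_CHARS = frozenset("-.")

#: Default relative ultrametricity tolerance (fraction of tree depth).
DEFAULT_ULTRAMETRIC_TOL = 1e-6

#: Relative jitter applied to tied node heights (fraction of tree depth).
TIE_JITTER = 1e-9


class DataError(ValueError):
    """Base class for all input-validation failures."""


class AlignmentError(DataError):
    """Malformed alignment (unequal lengths, bad characters, ...)."""


class ValidationError(DataError):
    """Schema/consistency violation (duplicate names, missing columns)."""


class EmptyInputError(DataError):
    """A file that parsed to zero records."""


class UltrametricityError(DataError):
    """A tree whose tips are not equidistant from the root."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """An aligned set of named nucleotide sequences.

    Parameters
    ----------
    records
        Ordered ``(name, sequence)`` pairs.  Names must be unique, all
        sequences must have equal, positive length and use IUPAC
        nucleotide codes (plus ``-``/``.`` gaps).
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no records")
        names = [name for name, _ in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate sequence names: {sorted(dupes)}"
            )
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if 0 in lengths:
            raise AlignmentError("sequences have zero length")
        allowed = IUPAC_NUCLEOTIDES | GAP_CHARS
        for name, seq in self.records:
            bad = set(seq.upper()) - allowed
            if bad:
                raise AlignmentError(
                    f"record {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)

    def subset(self, names: Iterable[str]) -> "Alignment":
        """Return a new alignment with ``names`` in source record order."""
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise ValidationError(f"names not in alignment: {sorted(missing)}")
        return Alignment(
            tuple((n, s) for n, s in self.records if n in wanted)
        )

    def sha256(self) -> str:
        h = hashlib.sha256()
        for name, seq in self.records:
            h.update(name.encode())
            h.update(b"\0")
            h.update(seq.encode())
            h.update(b"\n")
        return h.hexdigest()


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment.

    Record names are the first whitespace-delimited token of each
    description line.  Raises :class:`EmptyInputError` on an empty file
    and :class:`AlignmentError`/:class:`ValidationError` on invalid
    content.
    """
    path = Path(path)
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment(tuple(records))


def write_alignment(aln: Alignment, path: str | Path, *, width: int = 0) -> None:
    """Write ``aln`` to FASTA.  ``width=0`` keeps each sequence on one line."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Group map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupMap:
    """Mapping of sample name to a predefined group label."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, label in self.entries.items():
            if not label:
                raise ValidationError(f"empty group label for sample {name!r}")

    def groups(self) -> frozenset[str]:
        return frozenset(self.entries.values())

    def group_of(self, name: str) -> str:
        return self.entries[name]

    def members(self, label: str) -> frozenset[str]:
        return frozenset(n for n, g in self.entries.items() if g == label)

    def restrict(self, names: Iterable[str]) -> "GroupMap":
        """Restrict the map to ``names`` (e.g. after subsampling)."""
        names = set(names)
        missing = names - set(self.entries)
        if missing:
            raise ValidationError(
                f"samples missing from group map: {sorted(missing)}"
            )
        return GroupMap({n: g for n, g in self.entries.items() if n in names})

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)


def read_group_map(path: str | Path) -> GroupMap:
    """Read a two-column CSV (``sample_name,group``; header mandatory).

    Labels are kept verbatim apart from stripping surrounding whitespace.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyInputError(f"empty CSV file: {path}")
        cols = [c.strip() for c in reader.fieldnames]
        for required in ("sample_name", "group"):
            if required not in cols:
                raise ValidationError(
                    f"missing required column {required!r} in {path} "
                    f"(found {cols})"
                )
        entries: dict[str, str] = {}
        for row in reader:
            row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
            name, label = row["sample_name"], row["group"]
            if name in entries:
                raise ValidationError(f"duplicated sample_name {name!r}")
            entries[name] = label
    if not entries:
        raise EmptyInputError(f"no rows in group map {path}")
    return GroupMap(entries)


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_name", "group"])
        for name in sorted(groups):
            writer.writerow([name, groups.group_of(name)])


def check_tip_match(tip_labels: Iterable[str], groups: GroupMap) -> None:
    """Fail fast if tree tips and group-map samples do not line up."""
    tips = set(tip_labels)
    samples = set(groups)
    missing = sorted(tips - samples)
    if missing:
        raise ValidationError(
            f"tree tips absent from group map: {missing}"
        )


# ---------------------------------------------------------------------------
# Ultrametric trees
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of an ultrametric tree (height above the tips)."""

    __slots__ = ("label", "height", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        height: float = 0.0,
        children: Sequence["TreeNode"] = (),
    ) -> None:
        self.label = label
        self.height = float(height)
        self.children: list[TreeNode] = list(children)
        self.parent: TreeNode | None = None
        for child in self.children:
            child.parent = self

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tip_set(self) -> frozenset[str]:
        return frozenset(
            n.label for n in self.preorder() if n.is_tip  # type: ignore[misc]
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"tip {self.label!r}" if self.is_tip else f"{len(self.children)}-child"
        return f"<TreeNode {kind} h={self.height:.4g}>"


class UltrametricTree:
    """A rooted binary ultrametric tree with tip labels and node heights."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(
        cls,
        dtree: dendropy.Tree,
        *,
        tolerance: float = DEFAULT_ULTRAMETRIC_TOL,
        source: str = "<tree>",
    ) -> "UltrametricTree":
        """Convert a dendropy tree, validating ultrametricity.

        ``tolerance`` is relative to tree depth; tips within tolerance are
        snapped to height exactly 0.
        """
        seed = dtree.seed_node
        if len(seed.child_nodes()) != 2:
            raise ValidationError(
                f"{source}: tree is unrooted or non-binary at the root "
                f"({len(seed.child_nodes())} children)"
            )
        # Distances from the root along branch lengths.
        dist: dict[dendropy.Node, float] = {seed: 0.0}
        for node in dtree.preorder_node_iter():
            if node is seed:
                continue
            edge = node.edge.length if node.edge.length is not None else 0.0
            if edge < 0:
                raise ValidationError(f"{source}: negative branch length")
            dist[node] = dist[node.parent_node] + edge
        leaves = dtree.leaf_node_iter()
        tip_dists = {lf: dist[lf] for lf in leaves}
        depth = max(tip_dists.values())
        if depth <= 0:
            raise ValidationError(f"{source}: tree has zero depth")
        worst_lf, worst_dev = max(
            ((lf, abs(d - depth)) for lf, d in tip_dists.items()),
            key=lambda t: t[1],
        )
        if worst_dev > tolerance * depth:
            raise UltrametricityError(
                f"{source}: tree is not ultrametric; worst tip "
                f"{worst_lf.taxon.label if worst_lf.taxon else '?'!r} deviates "
                f"by {worst_dev:.6g} (depth {depth:.6g}, tolerance "
                f"{tolerance * depth:.6g})"
            )

        def build(dnode: dendropy.Node) -> TreeNode:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else None
                if label is None:
                    raise ValidationError(f"{source}: unlabeled tip")
                return TreeNode(label=str(label), height=0.0)
            kids = [build(c) for c in dnode.child_nodes()]
            if len(kids) != 2:
                raise ValidationError(
                    f"{source}: non-binary internal node "
                    f"({len(kids)} children)"
                )
            return TreeNode(height=depth - dist[dnode], children=kids)

        return cls(build(seed))

    @classmethod
    def from_newick(
        cls, newick: str, *, tolerance: float = DEFAULT_ULTRAMETRIC_TOL
    ) -> "UltrametricTree":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls.from_dendropy(dtree, tolerance=tolerance)

    # -- validation / properties -------------------------------------------

    def _validate(self) -> None:
        tips = self.tips()
        if len(tips) < 2:
            raise ValidationError("tree needs at least 2 tips")
        labels = [t.label for t in tips]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels")
        for node in self.root.preorder():
            if node.is_tip:
                if abs(node.height) > 0:
                    raise UltrametricityError(
                        f"tip {node.label!r} not at height 0"
                    )
            else:
                for child in node.children:
                    if node.height < child.height:
                        raise ValidationError(
                            "internal node below its child (negative branch)"
                        )

    def tips(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tips())  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def depth(self) -> float:
        return self.root.height

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if not n.is_tip]

    # -- operations ---------------------------------------------------------

    def newick(self, *, precision: int = 17) -> str:
        """Serialize to newick with branch lengths at full float precision."""

        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                body = _quote_label(node.label)  # type: ignore[arg-type]
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return body
            blen = node.parent.height - node.height
            return f"{body}:{blen:.{precision}g}"

        return fmt(self.root) + ";"

    def restrict_to(self, names: Iterable[str]) -> "UltrametricTree":
        """Prune the tree to ``names``, suppressing unifurcations.

        Node heights are preserved, so the result stays ultrametric on the
        same time scale (the root may become younger).
        """
        wanted = set(names)
        missing = wanted - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        if len(wanted) < 2:
            raise ValidationError("cannot restrict a tree to fewer than 2 tips")

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                if node.label in wanted:
                    return TreeNode(label=node.label, height=0.0)
                return None
            kept = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            return TreeNode(height=node.height, children=kept)

        new_root = prune(self.root)
        assert new_root is not None and not new_root.is_tip
        return UltrametricTree(new_root)

    def mrca(self, names: Iterable[str]) -> TreeNode:
        wanted = frozenset(names)
        node = self.root
        while True:
            nxt = [c for c in node.children if wanted <= c.tip_set()]
            if not nxt:
                return node
            node = nxt[0]


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t()[]{}:;,='\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_trees(
    path: str | Path,
    format: str = "newick",
    *,
    tolerance: float = DEFAULT_ULTRAMETRIC_TOL,
    all_trees: bool = False,
) -> list[UltrametricTree]:
    """Read ultrametric trees from a newick or NEXUS file.

    NEXUS translate tables are honored.  By default only the first tree of
    a multi-tree file is returned (MCC files contain one tree); pass
    ``all_trees=True`` for every tree.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    path = Path(path)
    tree_list = dendropy.TreeList.get(
        path=str(path),
        schema=format,
        rooting="force-rooted",
        preserve_underscores=True,
    )
    if not tree_list:
        raise EmptyInputError(f"no trees in {path}")
    dtrees = list(tree_list) if all_trees else [tree_list[0]]
    return [
        UltrametricTree.from_dendropy(
            dt, tolerance=tolerance, source=f"{path}[{i}]"
        )
        for i, dt in enumerate(dtrees)
    ]


# ---------------------------------------------------------------------------
# Branching schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchingEvent:
    """One branching event and the lineage state of the interval below it.

    The interval associated with an event spans from the next (younger)
    event height, or the tips, up to the event's own height; ``waiting_time``
    is its duration and the lineage counts describe the tree inside it.
    """

    height: float
    waiting_time: float
    n_lineages: int
    #: Species-tree lineage count in the interval (None when unclassified).
    k: int | None = None
    #: Within-species lineage counts >= 2 in the interval, sorted.
    coal_counts: tuple[int, ...] = ()
    #: True for diversification events (height > threshold); None when
    #: the schedule is unclassified.
    is_diversification: bool | None = None


@dataclass(frozen=True)
class BranchingSchedule:
    """Root-to-tips ordered branching events of an ultrametric tree."""

    events: tuple[BranchingEvent, ...]
    depth: float
    n_tips: int
    threshold: float | None = None

    @property
    def classified(self) -> bool:
        return self.threshold is not None

    @property
    def n_events(self) -> int:
        return len(self.events)


def _sorted_internal_nodes(tree: UltrametricTree) -> list[tuple[TreeNode, float]]:
    """Internal nodes ordered root->tips with deterministic tie handling.

    Ties (and zero-length internal branches) are resolved by sorting on
    (height desc, smallest descendant tip label, subtree size desc) and
    then clamping heights to be strictly decreasing by a tiny jitter, so
    every waiting time is strictly positive and event order reproducible.
    """
    meta: list[tuple[TreeNode, float, str, int]] = []
    for node in tree.internal_nodes():
        tipset = node.tip_set()
        meta.append((node, node.height, min(tipset), len(tipset)))
    meta.sort(key=lambda t: (-t[1], t[2], -t[3]))
    delta = TIE_JITTER * tree.depth
    out: list[tuple[TreeNode, float]] = []
    prev = None
    for node, height, _, _ in meta:
        if prev is not None and height >= prev:
            height = prev - delta
        out.append((node, height))
        prev = height
    if out and out[-1][1] <= 0:
        raise ValidationError("tree has too many tied node heights to jitter")
    return out


def branching_events(
    tree: UltrametricTree, threshold: float | None = None
) -> BranchingSchedule:
    """Derive the branching-event schedule of ``tree``.

    With ``threshold`` given, each event is labeled diversification
    (height > threshold) or coalescent (height <= threshold), and the
    per-interval lineage state (``k`` species-tree lineages, within-species
    counts ``n_j``) is computed under the species assignment induced by the
    threshold.  With ``threshold=None`` a single-class schedule (total
    lineage count per interval) is returned.
    """
    depth = tree.depth
    if threshold is not None and not (0.0 <= threshold <= depth * (1 + 1e-12)):
        raise ValueError(
            f"threshold {threshold} outside [0, {depth}]"
        )
    ordered = _sorted_internal_nodes(tree)

    rep_tip: dict[int, str] = {}
    species_of_tip: dict[str, int] = {}
    single_species: dict[int, int | None] = {}
    if threshold is not None:
        # Species are maximal subtrees whose root height <= threshold; a
        # node subtends a single species iff it is a tip or its height is
        # <= threshold.  Identify each species by its smallest tip label.
        from .gmyc_model import threshold_partition  # local import, no cycle at runtime

        partition = threshold_partition(tree, threshold)
        for sid, members in enumerate(partition.species):
            for name in members:
                species_of_tip[name] = sid
        for node in tree.root.preorder():
            if node.is_tip:
                single_species[id(node)] = species_of_tip[node.label]  # type: ignore[index]
            elif node.height <= threshold:
                any_tip = min(node.tip_set())
                single_species[id(node)] = species_of_tip[any_tip]
            else:
                single_species[id(node)] = None

    events: list[BranchingEvent] = []
    # Sweep root->tips replacing each expanded node by its children.
    n_per_species: dict[int, int] = {}
    k = 1
    n_active = 0

    def add_edge(node: TreeNode) -> None:
        nonlocal n_active
        n_active += 1
        if threshold is None:
            return
        sid = single_species[id(node)]
        if sid is not None:
            n_per_species[sid] = n_per_species.get(sid, 0) + 1

    def remove_edge(node: TreeNode) -> None:
        nonlocal n_active
        n_active -= 1
        if threshold is None:
            return
        sid = single_species[id(node)]
        if sid is not None:
            n_per_species[sid] -= 1
            if not n_per_species[sid]:
                del n_per_species[sid]

    heights = [h for _, h in ordered]
    for idx, (node, height) in enumerate(ordered):
        if node.parent is not None:
            remove_edge(node)
        for child in node.children:
            add_edge(child)
        is_div: bool | None = None
        kk: int | None = None
        coal_counts: tuple[int, ...] = ()
        if threshold is not None:
            is_div = height > threshold
            if is_div:
                k += 1
            kk = k
            coal_counts = tuple(sorted(v for v in n_per_species.values() if v >= 2))
        next_height = heights[idx + 1] if idx + 1 < len(ordered) else 0.0
        events.append(
            BranchingEvent(
                height=height,
                waiting_time=height - next_height,
                n_lineages=n_active,
                k=kk,
                coal_counts=coal_counts,
                is_diversification=is_div,
            )
        )
    assert n_active == tree.n_tips
    return BranchingSchedule(
        events=tuple(events),
        depth=depth,
        n_tips=tree.n_tips,
        threshold=threshold,
    )
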