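"""Synthetic ground-truth inputs: Yule species trees, coalescent-within-
species gene trees, JC69 sequences, and a byte-stable worked-example
fixture with an imposed six-species delimitation over eight user groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import msprime
import numpy as np

from .data_io import Alignment, GroupMap, TreeNode, UltrametricTree
from .gmyc_model import SpeciesPartition, threshold_partition

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_species_tree",
    "simulate_gene_tree",
    "simulate_sequences",
    "simulate_truth_set",
    "figure1_fixture",
    "FIXTURE_THRESHOLD",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a coalescent-within-Yule simulation."""

    n_species: int
    speciation_rate: float = 1.0
    samples_per_species: int | Sequence[int] = 2
    #: Expected within-species pairwise coalescence depth, relative to the
    #: species-tree depth.  Small values give deep interspecific and
    #: shallow intraspecific branching.
    coalescent_scale: float = 0.05
    seed: int = 0
    sequence_length: int | None = None
    mutation_rate: float | None = None
    #: When set, species trees are redrawn (deterministically) until the
    #: youngest species divergence is at least this multiple of the
    #: expected within-species pairwise coalescence depth, enforcing the
    #: deep-interspecific / shallow-intraspecific regime.
    min_species_separation: float | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.speciation_rate <= 0 or self.coalescent_scale <= 0:
            raise ValueError("rates must be positive")
        samples = self.samples_list()
        if len(samples) != self.n_species or any(s < 1 for s in samples):
            raise ValueError("samples_per_species must be >= 1 per species")

    def samples_list(self) -> list[int]:
        if isinstance(self.samples_per_species, int):
            return [self.samples_per_species] * self.n_species
        return list(self.samples_per_species)


@dataclass(frozen=True)
class TruthSet:
    """A simulated gene tree with its true species labels."""

    tree: UltrametricTree
    groups: GroupMap
    true_partition: SpeciesPartition

    def __post_init__(self) -> None:
        by_label = SpeciesPartition.from_labels(dict(self.groups.entries))
        if by_label != self.true_partition:
            raise ValueError("group labels do not match the true partition")


def _species_label(i: int) -> str:
    return f"sp{i + 1}"


def simulate_species_tree(
    n_species: int, speciation_rate: float, seed: int
) -> UltrametricTree:
    """Simulate a pure-birth (Yule) species tree with ``n_species`` tips.

    Inter-event durations with ``k`` lineages are Exp(k * rate), including
    a final Exp(n * rate) stretch after the last split, so the expected
    root depth is ``sum_{k=2..n} 1/(k * rate)``.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    if n_species == 1:
        # Degenerate single-tip tree; bypasses the >= 2 tips validation.
        tree = object.__new__(UltrametricTree)
        tree.root = TreeNode(label=_species_label(0), height=0.0)
        return tree
    waits = {k: rng.exponential(1.0 / (k * speciation_rate)) for k in range(2, n_species + 1)}
    # Height of the event that creates k+1 lineages is sum of waits j>k.
    event_height = {}
    acc = 0.0
    for k in range(n_species, 1, -1):
        acc += waits[k]
        event_height[k] = acc  # event where k-1 -> k lineages
    # Forward construction: split a uniformly chosen extant lineage.
    tips = [TreeNode(label=_species_label(0))]
    pending: list[TreeNode] = list(tips)
    nodes_at: list[tuple[float, TreeNode]] = []
    label_counter = 1
    for k in range(2, n_species + 1):
        idx = int(rng.integers(len(pending)))
        node = pending[idx]
        left = TreeNode(label=node.label)
        right = TreeNode(label=_species_label(label_counter))
        label_counter += 1
        node.label = None
        node.children = [left, right]
        left.parent = node
        right.parent = node
        node.height = event_height[k]
        pending[idx] = left
        pending.append(right)
    root = pending[0]
    while root.parent is not None:
        root = root.parent
    return UltrametricTree(root)


def _msprime_demography(
    species_tree: UltrametricTree, pop_size: float
) -> msprime.Demography:
    if species_tree.n_tips == 1:  # pragma: no cover - handled by caller
        raise ValueError("demography needs >= 2 species")
    newick = species_tree.newick()
    return msprime.Demography.from_species_tree(newick, initial_size=pop_size)


def simulate_gene_tree(
    species_tree: UltrametricTree,
    samples_per_species: int | Sequence[int],
    coalescent_scale: float,
    seed: int,
) -> TruthSet:
    """Simulate a gene tree embedded in ``species_tree``.

    Within each species a Kingman coalescent runs at a population size of
    ``coalescent_scale * depth`` (so the expected within-species pairwise
    coalescence time is that fraction of the species-tree depth); lineages
    not coalesced by a speciation node continue in the ancestral
    population.  Tip ``i`` of species ``sp`` is named ``"{sp}_{i}"``.
    """
    labels = list(species_tree.tip_labels)
    n_species = len(labels)
    if isinstance(samples_per_species, int):
        samples = {lab: samples_per_species for lab in labels}
    else:
        if len(samples_per_species) != n_species:
            raise ValueError("need one sample count per species")
        samples = dict(zip(labels, samples_per_species))
    depth = species_tree.depth if n_species > 1 else 1.0
    pop_size = coalescent_scale * depth

    msp_seed = (int(seed) % (2**31 - 2)) + 1
    if n_species == 1:
        ts = msprime.sim_ancestry(
            samples=sum(samples.values()),
            population_size=pop_size,
            ploidy=1,
            random_seed=msp_seed,
        )
        pop_of_node = {u: labels[0] for u in ts.samples()}
    else:
        demography = _msprime_demography(species_tree, pop_size)
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            ploidy=1,
            random_seed=msp_seed,
        )
        pop_names = {p.id: p.name for p in demography.populations}
        pop_of_node = {
            u: pop_names[ts.node(u).population] for u in ts.samples()
        }

    tree = ts.first()
    counters: dict[str, int] = {}
    names: dict[int, str] = {}
    for u in ts.samples():
        sp = pop_of_node[u]
        counters[sp] = counters.get(sp, 0) + 1
        names[u] = f"{sp}_{counters[sp]}"

    def build(u: int) -> TreeNode:
        kids = tree.children(u)
        if not kids:
            return TreeNode(label=names[u], height=0.0)
        return TreeNode(
            height=tree.time(u), children=[build(c) for c in kids]
        )

    gene_tree = UltrametricTree(build(tree.root))
    entries = {names[u]: pop_of_node[u] for u in ts.samples()}
    groups = GroupMap(entries)
    return TruthSet(
        tree=gene_tree,
        groups=groups,
        true_partition=SpeciesPartition.from_labels(entries),
    )


def simulate_truth_set(config: SimulationConfig) -> TruthSet:
    """Species tree + gene tree from one config.

    With ``min_species_separation`` set, species trees are redrawn with
    derived seeds until the youngest interspecific divergence exceeds the
    required multiple of the expected intraspecific pairwise depth.
    """
    attempt = 0
    while True:
        species_tree = simulate_species_tree(
            config.n_species,
            config.speciation_rate,
            config.seed + 100_003 * attempt,
        )
        if config.min_species_separation is None or config.n_species < 2:
            break
        min_split = min(n.height for n in species_tree.internal_nodes())
        pairwise_depth = config.coalescent_scale * species_tree.depth
        if min_split >= config.min_species_separation * pairwise_depth:
            break
        attempt += 1
        if attempt > 1000:
            raise RuntimeError(
                "could not satisfy min_species_separation in 1000 draws; "
                "lower coalescent_scale or the separation factor"
            )
    return simulate_gene_tree(
        species_tree,
        config.samples_list(),
        config.coalescent_scale,
        config.seed + 1,
    )


# ---------------------------------------------------------------------------
# JC69 sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_sequences(
    tree: UltrametricTree, length: int, mutation_rate: float, seed: int
) -> Alignment:
    """Evolve JC69 sequences along ``tree``; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    root_state = rng.integers(4, size=length)
    records: list[tuple[str, str]] = []

    def evolve(state: np.ndarray, node: TreeNode) -> None:
        if node.is_tip:
            records.append((node.label, "".join(_BASES[state])))  # type: ignore[arg-type]
            return
        for child in node.children:
            t = node.height - child.height
            p_change = 0.75 * (1.0 - np.exp(-4.0 * mutation_rate * t / 3.0))
            child_state = state.copy()
            hit = rng.random(length) < p_change
            if hit.any():
                # A changed site takes one of the three other bases uniformly.
                child_state[hit] = (
                    state[hit] + rng.integers(1, 4, size=int(hit.sum()))
                ) % 4
            evolve(child_state, child)

    evolve(root_state, tree.root)  # records accumulate in tip preorder
    return Alignment(tuple(records))


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

#: Threshold at which the fixture tree reproduces the imposed partition.
FIXTURE_THRESHOLD = 1.0


def _cherry(a: str, b: str, height: float) -> TreeNode:
    return TreeNode(height=height, children=[TreeNode(label=a), TreeNode(label=b)])


def figure1_fixture() -> tuple[TruthSet, SpeciesPartition]:
    """A 16-tip, 8-group worked example with a designed 6-species outcome.

    Groups (true labels): sp1, sp2, sp3, spY with 2 samples each; spA with
    4; spZ with 2; spB and spW singletons.  The imposed partition (the
    tree's threshold partition at :data:`FIXTURE_THRESHOLD`) has six
    species: sp1+sp2+sp3 merged, spA split in two, spZ exact, spB a
    singleton, and spY+spW merged (spW being a dataset singleton).
    Byte-stable across runs.
    """
    c_sp1 = _cherry("sp1_1", "sp1_2", 0.10)
    c_sp2 = _cherry("sp2_1", "sp2_2", 0.12)
    c_sp3 = _cherry("sp3_1", "sp3_2", 0.14)
    merge1 = TreeNode(
        height=0.50,
        children=[TreeNode(height=0.30, children=[c_sp1, c_sp2]), c_sp3],
    )
    c_spa1 = _cherry("spA_1", "spA_2", 0.16)
    c_spa2 = _cherry("spA_3", "spA_4", 0.18)
    c_spz = _cherry("spZ_1", "spZ_2", 0.20)
    c_spy = _cherry("spY_1", "spY_2", 0.22)
    merge2 = TreeNode(height=0.55, children=[c_spy, TreeNode(label="spW_1")])
    spa_join = TreeNode(height=1.5, children=[c_spa1, c_spa2])
    right_mid = TreeNode(height=2.0, children=[spa_join, c_spz])
    left = TreeNode(height=2.5, children=[merge1, right_mid])
    right = TreeNode(height=3.0, children=[merge2, TreeNode(label="spB_1")])
    root = TreeNode(height=3.5, children=[left, right])
    tree = UltrametricTree(root)

    entries = {name: name.rsplit("_", 1)[0] for name in tree.tip_labels}
    groups = GroupMap(entries)
    truth = TruthSet(
        tree=tree,
        groups=groups,
        true_partition=SpeciesPartition.from_labels(entries),
    )
    imposed = threshold_partition(tree, FIXTURE_THRESHOLD)
    return truth, imposed
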