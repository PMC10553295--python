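"""Synthetic aligned protein sets with known ancestry.

Sequences are simulated along a user-supplied rooted tree whose branch
lengths are interpreted as exact point-substitution counts: a uniform-random
ancestor is drawn at the root, each branch applies its stated number of
substitutions at uniformly chosen positions (the replacement residue always
differs from the old one), and gap ('-') / missing ('?') symbols are sprinkled
onto the leaves at fixed per-site rates, emulating post-alignment artifacts.

Counting substitutions per branch (rather than using a stochastic rate model)
keeps divergence under exact control, which is what downstream recovery tests
need.  No attempt is made at a realistic substitution process (JTT/WAG) or at
indel evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .encoding import GAP, MISSING, STANDARD_AMINO_ACIDS, AlignedProteinSet

__all__ = ["SimulationSpec", "simulate_alignment", "worked_example_set",
           "THREE_CLADE_TREE"]

#: A six-taxon, three-clade topology with well-separated divergence levels:
#: within-clade branches carry few substitutions, between-clade many.  Counts
#: are sized for a 400-column ancestor; the stationary Hamming distance has
#: substantial sampling spread per substitution count on short lattices, and
#: at 400 columns the inter-clade separation comfortably exceeds that spread.
THREE_CLADE_TREE = "(((A:12,B:12):80,(C:12,D:12):80):80,(E:12,F:12):160);"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated alignment.

    ``tree`` is a rooted Newick string whose branch lengths are nonnegative
    integer substitution counts; leaf labels become taxon labels.
    """

    tree: str = THREE_CLADE_TREE
    ancestor_length: int = 400
    deletion_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        for name in ("deletion_rate", "missing_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.deletion_rate + self.missing_rate >= 1:
            raise ValueError("deletion_rate + missing_rate must be < 1")

    def true_tree(self) -> dendropy.Tree:
        tree = dendropy.Tree.get(data=self.tree, schema="newick")
        if len(tree.leaf_nodes()) < 2:
            raise ValueError("tree must have at least two leaves")
        return tree


def _mutate(seq: np.ndarray, count: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``count`` point substitutions at uniform positions (new != old)."""
    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    seq = seq.copy()
    for _ in range(count):
        pos = int(rng.integers(seq.size))
        choices = alphabet[alphabet != seq[pos]]
        seq[pos] = rng.choice(choices)
    return seq


def simulate_alignment(spec: SimulationSpec) -> AlignedProteinSet:
    """Simulate an aligned protein set along ``spec.tree``.

    Fully reproducible from ``spec.seed``.  Leaf order follows the Newick
    leaf order.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.true_tree()
    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    ancestor = rng.choice(alphabet, size=spec.ancestor_length)

    states: dict[int, np.ndarray] = {id(tree.seed_node): ancestor}
    labels, seqs = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        count = int(round(node.edge.length or 0))
        if count < 0:
            raise ValueError("negative substitution count on a branch")
        states[id(node)] = _mutate(states[id(node.parent_node)], count, rng)
        if node.is_leaf():
            seq = states[id(node)].copy()
            u = rng.random(seq.size)
            seq[u < spec.deletion_rate] = GAP
            mask = (u >= spec.deletion_rate) & (
                u < spec.deletion_rate + spec.missing_rate
            )
            seq[mask] = MISSING
            labels.append(node.taxon.label.replace(" ", "_"))
            seqs.append("".join(seq))
    return AlignedProteinSet(tuple(labels), tuple(seqs))


def worked_example_set() -> AlignedProteinSet:
    """A fixed six-taxon, 20-column alignment used in docs and regression tests.

    Generated once with ``simulate_alignment(SimulationSpec(
    tree="(((A:3,B:3):20,(C:3,D:3):20):20,(E:3,F:3):40);",
    ancestor_length=20, seed=42))`` and frozen, so it is stable across
    versions; two gap sites and one missing site were then added by hand to
    exercise the full alphabet.
    """
    records = [
        ("A", "CGQTQPGYTEDPDLQRAGLL"),
        ("B", "GGQTQPGYTEDPDLQTCHLL"),
        ("C", "SCKRKQYWWQFYHKHKPTT-"),
        ("D", "CDKRKLYWWVFYHLHKPTTC"),
        ("E", "FTLVTGYPDMAYMSVSVE?R"),
        ("F", "FTLVTGYPKAAMMSVSVEG-"),
    ]
    return AlignedProteinSet.from_records(records)
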