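"""Hamming-distance trajectories and pairwise distance matrices.

Two automata evolved from different protein encodings are compared row by
row: at step t the normalised Hamming distance is

    D_H(t) = (1/M) * sum_i |a_i^t - b_i^t|,

the fraction of cells that differ.  Under rule 84 the trajectory quickly
reaches a plateau; its tail average is the Stationary Hamming Distance (SHD),
the dissimilarity used to fill the pairwise matrix.  The classical p-distance
(proportion of differing residues under pairwise deletion of gap/missing
sites) is provided as the comparison baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ca_engine import (
    DEFAULT_RULE,
    DEFAULT_STEPS,
    AutomatonImage,
    RuleTable,
    evolve,
    rule_from_number,
)
from .encoding import (
    GAP,
    MISSING,
    STANDARD_AMINO_ACIDS,
    AlignedProteinSet,
    CodeTable,
    encode_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HammingTrajectory",
    "DistanceMatrix",
    "hamming_trajectory",
    "stationary_value",
    "pairwise_shd_matrix",
    "p_distance_matrix",
    "DEFAULT_WINDOW",
    "DEFAULT_TOL",
]

DEFAULT_WINDOW = 100
DEFAULT_TOL = 0.01


class ComparabilityError(ValueError):
    """Two objects cannot be compared (mismatched size, steps or labels)."""


@dataclass(frozen=True)
class HammingTrajectory:
    """D_H(t) for t = 0..T between two automata, with its stationary summary.

    ``shd`` is the arithmetic mean of the final ``window`` values;
    ``saturated`` records whether the tail standard deviation is within
    tolerance of a flat plateau.
    """

    values: np.ndarray = field(repr=False)
    window: int
    shd: float
    saturated: bool

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)

    @property
    def n_steps(self) -> int:
        return self.values.size - 1

    def write_tsv(self, path: str | Path) -> None:
        """Write (t, D_H) pairs for plateau plots."""
        with open(path, "w") as fh:
            fh.write("t\tD_H\n")
            for t, v in enumerate(self.values):
                fh.write(f"{t}\t{v:.10g}\n")


def stationary_value(
    values: np.ndarray, window: int = DEFAULT_WINDOW, tol: float = DEFAULT_TOL
) -> tuple[float, bool]:
    """Tail summary of a trajectory.

    Returns ``(shd, saturated)`` where ``shd`` is the mean of the final
    ``window`` values and ``saturated`` is true when their standard deviation
    is at most ``tol``.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be positive, got {window}")
    if window > values.size:
        raise ValueError(
            f"window {window} exceeds trajectory length {values.size}"
        )
    if tol < 0:
        raise ValueError(f"tol must be nonnegative, got {tol}")
    tail = values[-window:]
    return float(tail.mean()), bool(tail.std() <= tol)


def hamming_trajectory(
    image_a: AutomatonImage,
    image_b: AutomatonImage,
    window: int = DEFAULT_WINDOW,
    tol: float = DEFAULT_TOL,
) -> HammingTrajectory:
    """Per-step normalised Hamming distance between two automaton images."""
    if image_a.rows.shape != image_b.rows.shape:
        raise ComparabilityError(
            f"image shapes differ: {image_a.rows.shape} vs {image_b.rows.shape}"
        )
    if image_a.rule_number != image_b.rule_number:
        raise ComparabilityError(
            f"images evolved under different rules: "
            f"{image_a.rule_number} vs {image_b.rule_number}"
        )
    diffs = image_a.rows != image_b.rows
    values = diffs.mean(axis=1)
    shd, saturated = stationary_value(values, window=window, tol=tol)
    return HammingTrajectory(values, window=window, shd=shd, saturated=saturated)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal, entries in [0,1]."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    metric_name: str = "shd"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if n < 2:
            raise ValueError("a distance matrix needs at least two taxa")
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        if np.isnan(vals).any():
            raise ValueError("matrix contains NaN entries")
        if not np.allclose(vals, vals.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0):
            raise ValueError("matrix diagonal is not zero")
        if vals.min() < -1e-12:
            raise ValueError("negative matrix entries")
        # both sequence metrics are fractions of sites/cells
        if self.metric_name in ("shd", "p-distance") and vals.max() > 1 + 1e-12:
            raise ValueError(f"{self.metric_name} entries outside [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangular entries in scipy's condensed order."""
        iu = np.triu_indices(self.n_taxa, k=1)
        return self.values[iu]

    def reorder(self, labels: tuple[str, ...] | list[str]) -> "DistanceMatrix":
        """Return the same matrix with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            tuple(labels), self.values[np.ix_(idx, idx)], self.metric_name
        )

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance-matrix format: count line, then label + row."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa}\n")
            for label, row in zip(self.labels, self.values):
                cells = "  ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label:<12s}  {cells}\n")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path: str | Path, metric_name: str = "shd") -> "DistanceMatrix":
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
        return cls(tuple(labels), np.array(rows), metric_name)

    @classmethod
    def read_tsv(cls, path: str | Path, metric_name: str = "shd") -> "DistanceMatrix":
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        labels = tuple(lines[0].split("\t")[1:])
        rows = [[float(x) for x in l.split("\t")[1:]] for l in lines[1:]]
        return cls(labels, np.array(rows), metric_name)


def _evolved_images(
    aln: AlignedProteinSet,
    table: CodeTable | None,
    rule: RuleTable | int,
    steps: int,
) -> list[AutomatonImage]:
    if isinstance(rule, (int, np.integer)):
        rule = rule_from_number(rule)
    table = table or CodeTable.default()
    return [evolve(encode_sequence(seq, table), rule, steps) for _, seq in aln]


def pairwise_shd_matrix(
    aln: AlignedProteinSet,
    table: CodeTable | None = None,
    rule: RuleTable | int = DEFAULT_RULE,
    steps: int = DEFAULT_STEPS,
    window: int = DEFAULT_WINDOW,
    tol: float = DEFAULT_TOL,
) -> DistanceMatrix:
    """Stationary Hamming distance between every pair of taxa.

    Each taxon's sequence is encoded and evolved once; each unordered pair is
    compared once and mirrored.  Pairs whose trajectory has not plateaued
    (tail standard deviation above ``tol``) are logged, not rejected.
    """
    if window > steps + 1:
        raise ValueError(f"window {window} exceeds trajectory length {steps + 1}")
    images = _evolved_images(aln, table, rule, steps)
    n = aln.n_taxa
    values = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            traj = hamming_trajectory(images[j], images[k], window=window, tol=tol)
            values[j, k] = values[k, j] = traj.shd
            if not traj.saturated:
                logger.warning(
                    "trajectory %s vs %s not saturated (tail std above %g)",
                    aln.labels[j], aln.labels[k], tol,
                )
    return DistanceMatrix(tuple(aln.labels), values, "shd")


def p_distance_matrix(
    aln: AlignedProteinSet, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Proportion of differing residues between every pair of sequences.

    Sites where either sequence carries a non-standard symbol (gap '-',
    missing '?', or an ambiguity code) are excluded.  ``deletion`` chooses
    the exclusion mode: ``"pairwise"`` drops such sites per pair (the usual
    default), ``"complete"`` drops any column containing one anywhere.
    A pair with no comparable sites gets distance 0 with a warning.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    seqs = np.array([list(s) for _, s in aln])
    ordinary = np.isin(seqs, list(STANDARD_AMINO_ACIDS))
    if deletion == "complete":
        keep = ordinary.all(axis=0)
        seqs = seqs[:, keep]
        ordinary = ordinary[:, keep]
    n = aln.n_taxa
    values = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            both = ordinary[j] & ordinary[k]
            n_sites = int(both.sum())
            if n_sites == 0:
                logger.warning(
                    "no comparable sites between %s and %s; p-distance set to 0",
                    aln.labels[j], aln.labels[k],
                )
                continue
            diffs = int((seqs[j, both] != seqs[k, both]).sum())
            values[j, k] = values[k, j] = diffs / n_sites
    return DistanceMatrix(tuple(aln.labels), values, "p-distance")
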