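"""End-to-end run: encode -> evolve -> distance matrices -> dendrograms -> report.

`run` ties the stages together for one aligned FASTA input and writes an
artifact bundle (distance matrices in PHYLIP and TSV form, Newick trees, all
pairwise Hamming trajectories, an optional per-taxon automaton raster, and a
summary report).  All computation happens before any file is written, so a
failing stage leaves no partial matrix files behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import clustering, distance
from .ca_engine import DEFAULT_RULE, DEFAULT_STEPS, evolve, render_image, rule_from_number
from .distance import DEFAULT_TOL, DEFAULT_WINDOW, hamming_trajectory
from .encoding import AlignedProteinSet, CodeTable, encode_sequence, load_code_table, read_aligned_fasta

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; defaults are rule 84 and T = 500."""

    input: str | Path = ""
    rule_number: int = DEFAULT_RULE
    steps: int = DEFAULT_STEPS
    window: int = DEFAULT_WINDOW
    tol: float = DEFAULT_TOL
    metric: str = "both"          # "shd" | "p" | "both"
    code_table: str | Path | None = None
    out_dir: str | Path = "capdist_out"
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.metric not in ("shd", "p", "both"):
            raise ValueError(f"metric must be 'shd', 'p' or 'both', got {self.metric!r}")


def run(config: RunConfig, aln: AlignedProteinSet | None = None) -> dict:
    """Execute the full pipeline; returns a summary dict (also written as JSON).

    ``aln`` may be supplied directly (e.g. a simulated set); otherwise
    ``config.input`` is read as aligned FASTA.
    """
    if aln is None:
        aln = read_aligned_fasta(config.input)
    table = load_code_table(config.code_table)
    rule = rule_from_number(config.rule_number)

    summary: dict = {
        "n_taxa": aln.n_taxa,
        "n_positions": aln.n_positions,
        "automaton_cells": table.width * aln.n_positions,
        "rule": rule.rule_number,
        "steps": config.steps,
        "metric": config.metric,
    }

    artifacts: list[tuple[Path, object]] = []   # (relative path, writer payload)
    out = Path(config.out_dir)

    matrices: dict[str, distance.DistanceMatrix] = {}
    trees: dict[str, clustering.Dendrogram] = {}
    trajectories = None

    if config.metric in ("shd", "both"):
        images = [
            evolve(encode_sequence(seq, table), rule, config.steps)
            for _, seq in aln
        ]
        import numpy as np

        n = aln.n_taxa
        values = np.zeros((n, n))
        trajectories = {}
        for j in range(n):
            for k in range(j + 1, n):
                traj = hamming_trajectory(
                    images[j], images[k], window=config.window, tol=config.tol
                )
                values[j, k] = values[k, j] = traj.shd
                trajectories[(aln.labels[j], aln.labels[k])] = traj
                if not traj.saturated:
                    logger.warning(
                        "pair %s/%s not saturated", aln.labels[j], aln.labels[k]
                    )
        matrices["shd"] = distance.DistanceMatrix(tuple(aln.labels), values, "shd")
        if config.write_images:
            for label, img in zip(aln.labels, images):
                artifacts.append((Path(f"{label}.pgm"), img))
    if config.metric in ("p", "both"):
        matrices["p-distance"] = distance.p_distance_matrix(aln)

    for name, mat in matrices.items():
        trees[name] = clustering.upgma(mat)

    if len(trees) == 2:
        r = clustering.cophenetic_correlation(trees["shd"], trees["p-distance"])
        summary["cophenetic_correlation"] = r

    # --- all computation done; write the bundle ---
    out.mkdir(parents=True, exist_ok=True)
    stem = {"shd": "shd", "p-distance": "pdist"}
    for name, mat in matrices.items():
        mat.write_phylip(out / f"{stem[name]}.phylip")
        mat.write_tsv(out / f"{stem[name]}.tsv")
        (out / f"{stem[name]}.nwk").write_text(
            clustering.to_newick(trees[name]) + "\n"
        )
    if trajectories is not None:
        with open(out / "trajectories.tsv", "w") as fh:
            fh.write("taxon_a\ttaxon_b\tt\tD_H\n")
            for (la, lb), traj in trajectories.items():
                for t, v in enumerate(traj.values):
                    fh.write(f"{la}\t{lb}\t{t}\t{v:.10g}\n")
    for rel, img in artifacts:
        render_image(img, out / rel)
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("wrote artifact bundle to %s", out)
    return summary
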