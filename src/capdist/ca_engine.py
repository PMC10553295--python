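"""Elementary cellular automata with periodic boundaries.

One-dimensional lattices of two-state cells evolve under one of the 256
elementary rules.  A rule maps each (left, center, right) neighborhood triple
to the cell's next state; rules are numbered by the standard Wolfram
convention, where bit k of the rule number is the output for the triple whose
3-bit value is k.  The lattice wraps: c_0 == c_M and c_{M+1} == c_1.

Rule 84 (the default throughout this package) has the closed form
``next = (left OR center) AND NOT right``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RuleTable", "AutomatonImage", "rule_from_number", "step", "evolve",
           "render_image", "read_pgm", "DEFAULT_RULE", "DEFAULT_STEPS"]

DEFAULT_RULE = 84
DEFAULT_STEPS = 500


@dataclass(frozen=True)
class RuleTable:
    """Lookup table of an elementary rule in Wolfram numbering."""

    rule_number: int
    #: outputs[k] is the next state for the neighborhood triple with value
    #: k = 4*left + 2*center + right.
    outputs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.rule_number <= 255:
            raise ValueError(f"rule number {self.rule_number} outside [0, 255]")
        out = np.asarray(self.outputs, dtype=np.uint8)
        if out.shape != (8,) or set(np.unique(out)) - {0, 1}:
            raise ValueError("outputs must be 8 bits")
        object.__setattr__(self, "outputs", out)
        rebuilt = int(sum(int(b) << k for k, b in enumerate(out)))
        if rebuilt != self.rule_number:
            raise ValueError(
                f"outputs encode rule {rebuilt}, not {self.rule_number}"
            )

    def __getitem__(self, triple: tuple[int, int, int]) -> int:
        left, center, right = triple
        return int(self.outputs[4 * left + 2 * center + right])


def rule_from_number(n: int) -> RuleTable:
    """Build the lookup table for elementary rule ``n`` (0..255)."""
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ValueError(f"rule number must be an integer, got {n!r}")
    if not 0 <= n <= 255:
        raise ValueError(f"rule number {n} outside [0, 255]")
    outputs = np.array([(n >> k) & 1 for k in range(8)], dtype=np.uint8)
    return RuleTable(int(n), outputs)


@dataclass(frozen=True)
class AutomatonImage:
    """Space-time diagram of an automaton: rows are time steps, columns cells.

    ``rows[0]`` is the initial state; ``rows[t]`` is the state after t
    synchronous updates under ``rule_number`` with periodic boundaries.
    """

    rows: np.ndarray = field(repr=False)
    rule_number: int
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        rows = np.ascontiguousarray(self.rows, dtype=np.uint8)
        if rows.ndim != 2 or rows.shape[0] < 1 or rows.shape[1] < 1:
            raise ValueError("image must be a non-empty 2-D bit matrix")
        object.__setattr__(self, "rows", rows)
        if self.boundary != "periodic":
            raise ValueError("only periodic boundaries are supported")

    @property
    def n_steps(self) -> int:
        """T: number of evolution steps (rows minus the initial row)."""
        return self.rows.shape[0] - 1

    @property
    def n_cells(self) -> int:
        """M: lattice width."""
        return self.rows.shape[1]


def step(state: np.ndarray, rule: RuleTable) -> np.ndarray:
    """Apply one synchronous update with periodic wrap-around."""
    state = np.asarray(state, dtype=np.uint8)
    if state.ndim != 1 or state.size < 1:
        raise ValueError("state must be a non-empty 1-D bit vector")
    left = np.roll(state, 1)
    right = np.roll(state, -1)
    return rule.outputs[4 * left + 2 * state + right]


def evolve(initial: np.ndarray, rule: RuleTable | int = DEFAULT_RULE,
           steps: int = DEFAULT_STEPS) -> AutomatonImage:
    """Evolve ``initial`` for ``steps`` updates, keeping every intermediate row.

    The result has ``steps + 1`` rows; row 0 is the initial state itself.
    """
    if isinstance(rule, (int, np.integer)):
        rule = rule_from_number(rule)
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    state = np.asarray(initial, dtype=np.uint8)
    if state.ndim != 1 or state.size < 1:
        raise ValueError("initial state must be a non-empty 1-D bit vector")
    rows = np.empty((steps + 1, state.size), dtype=np.uint8)
    rows[0] = state
    for t in range(1, steps + 1):
        rows[t] = step(rows[t - 1], rule)
    return AutomatonImage(rows, rule.rule_number)


def render_image(image: AutomatonImage, path: str | Path) -> None:
    """Write the space-time diagram as a raster file.

    1-bits render dark, 0-bits light; time runs downward with row 0 on top.
    ``.pgm``/``.pbm`` paths get a plain (P1) bitmap, bit-exact and
    re-readable with :func:`read_pgm`; ``.png`` uses Pillow if available.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        # PNG: 0 -> white (255), 1 -> black (0)
        arr = ((1 - image.rows) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
        return
    h, w = image.rows.shape
    lines = ["P1", f"{w} {h}"]
    lines.extend(" ".join(str(int(b)) for b in row) for row in image.rows)
    path.write_text("\n".join(lines) + "\n")


def read_pgm(path: str | Path) -> np.ndarray:
    """Read a plain P1 bitmap written by :func:`render_image` back to bits."""
    tokens = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path}: not a plain P1 bitmap")
    w, h = int(tokens[1]), int(tokens[2])
    bits = np.array([int(t) for t in tokens[3 : 3 + w * h]], dtype=np.uint8)
    if bits.size != w * h:
        raise ValueError(f"{path}: expected {w * h} bits, found {bits.size}")
    return bits.reshape(h, w)
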