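"""Sudoku task engine: generation, carving, entry validation, voice tokens.

Puzzles are produced by a randomized backtracking fill of a valid 9x9 grid
followed by carving: removing exactly 35 (easy), 45 (medium) or 55 (hard)
cells while preserving a *unique* completion, verified by an exhaustive
solution counter.  During play, entries are validated against the
precomputed solution: correct entries lock their cell, wrong entries are
flagged (shown red in the original interface) and increment the error
counter; each wrong entry counts, including repeats.

Number input by voice accepts exactly the nine digit words per language -
English "one".."nine" and Romanian "unu".."noua" (with diacritics) - and
silently ignores every other token.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import numpy as np

from .metrics import SessionEvent

__all__ = [
    "DIFFICULTY_REMOVALS",
    "Puzzle",
    "GameState",
    "CommandVocabulary",
    "VOCABULARIES",
    "PuzzleGenerationError",
    "InvalidEntryError",
    "generate_solution",
    "count_solutions",
    "carve_puzzle",
    "validate_entry",
    "parse_voice_token",
    "countdown_sequence",
    "is_valid_solution",
]

#: cells removed per difficulty level
DIFFICULTY_REMOVALS = {"easy": 35, "medium": 45, "hard": 55}

_CARVE_MAX_ATTEMPTS = 100


class PuzzleGenerationError(RuntimeError):
    """Raised when no unique-solution carving is found within the retry cap."""


class InvalidEntryError(ValueError):
    """Raised for entries on given/locked cells or out-of-range values."""


def _box(r: int, c: int) -> int:
    return (r // 3) * 3 + c // 3


def is_valid_solution(grid) -> bool:
    """True iff every row, column and 3x3 box contains 1-9 exactly once."""
    g = np.asarray(grid, dtype=int)
    if g.shape != (9, 9):
        return False
    full = set(range(1, 10))
    for i in range(9):
        if set(g[i, :]) != full or set(g[:, i]) != full:
            return False
    for br in range(0, 9, 3):
        for bc in range(0, 9, 3):
            if set(g[br : br + 3, bc : bc + 3].ravel()) != full:
                return False
    return True


def generate_solution(seed: int) -> np.ndarray:
    """Complete valid solution grid via randomized backtracking fill."""
    rnd = random.Random(seed)
    grid = [[0] * 9 for _ in range(9)]
    rows = [0] * 9
    cols = [0] * 9
    boxes = [0] * 9

    def fill(pos: int) -> bool:
        if pos == 81:
            return True
        r, c = divmod(pos, 9)
        b = _box(r, c)
        used = rows[r] | cols[c] | boxes[b]
        digits = [d for d in range(1, 10) if not used & (1 << d)]
        rnd.shuffle(digits)
        for d in digits:
            bit = 1 << d
            grid[r][c] = d
            rows[r] |= bit
            cols[c] |= bit
            boxes[b] |= bit
            if fill(pos + 1):
                return True
            grid[r][c] = 0
            rows[r] ^= bit
            cols[c] ^= bit
            boxes[b] ^= bit
        return False

    fill(0)
    return np.array(grid, dtype=int)


def count_solutions(grid, limit: int = 2) -> int:
    """Exhaustive backtracking count of completions, early-exiting at
    ``limit`` (fewest-candidates cell first)."""
    g = np.asarray(grid, dtype=int).tolist()
    rows = [0] * 9
    cols = [0] * 9
    boxes = [0] * 9
    empties = []
    for r in range(9):
        for c in range(9):
            d = g[r][c]
            if d:
                bit = 1 << d
                rows[r] |= bit
                cols[c] |= bit
                boxes[_box(r, c)] |= bit
            else:
                empties.append((r, c))

    count = 0

    def solve(remaining: list) -> None:
        nonlocal count
        if count >= limit:
            return
        if not remaining:
            count += 1
            return
        # most-constrained cell first
        best_i, best_opts = -1, None
        for i, (r, c) in enumerate(remaining):
            used = rows[r] | cols[c] | boxes[_box(r, c)]
            opts = [d for d in range(1, 10) if not used & (1 << d)]
            if best_opts is None or len(opts) < len(best_opts):
                best_i, best_opts = i, opts
                if len(opts) <= 1:
                    break
        if not best_opts:
            return
        r, c = remaining[best_i]
        rest = remaining[:best_i] + remaining[best_i + 1 :]
        b = _box(r, c)
        for d in best_opts:
            bit = 1 << d
            rows[r] |= bit
            cols[c] |= bit
            boxes[b] |= bit
            solve(rest)
            rows[r] ^= bit
            cols[c] ^= bit
            boxes[b] ^= bit
            if count >= limit:
                return

    solve(empties)
    return count


@dataclass
class Puzzle:
    """A carved puzzle: complete solution, givens mask, and provenance."""

    solution: np.ndarray
    givens: np.ndarray
    difficulty: str
    removals: int
    seed: int

    def __post_init__(self) -> None:
        self.solution = np.asarray(self.solution, dtype=int)
        self.givens = np.asarray(self.givens, dtype=int)

    def empty_cells(self) -> list[tuple[int, int]]:
        return [(int(r), int(c)) for r, c in zip(*np.nonzero(self.givens == 0))]

    def to_string(self) -> str:
        """81-character row-major digit string, 0 for blanks."""
        return "".join(str(d) for d in self.givens.ravel())

    def to_json(self) -> str:
        return json.dumps(
            {
                "difficulty": self.difficulty,
                "seed": self.seed,
                "removals": self.removals,
                "givens": self.to_string(),
                "solution": "".join(str(d) for d in self.solution.ravel()),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Puzzle":
        d = json.loads(text)
        to_grid = lambda s: np.array([int(ch) for ch in s], dtype=int).reshape(9, 9)  # noqa: E731
        return cls(
            solution=to_grid(d["solution"]),
            givens=to_grid(d["givens"]),
            difficulty=d["difficulty"],
            removals=int(d["removals"]),
            seed=int(d["seed"]),
        )


def _sub_seed(seed: int, attempt: int) -> int:
    return int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0])


def carve_puzzle(solution, difficulty: str, seed: int) -> Puzzle:
    """Remove exactly the difficulty's cell count, keeping the solution unique.

    Cells are visited in a seeded random order and removed greedily whenever
    the exhaustive counter still finds a single completion (once a removal
    breaks uniqueness it stays broken, so one pass per order suffices).
    Orders that fall short trigger a reshuffle from an internal sub-seed, up
    to a hard cap of 100 attempts.
    """
    solution = np.asarray(solution, dtype=int)
    if not is_valid_solution(solution):
        raise ValueError("carve_puzzle requires a complete valid solution grid")
    if difficulty not in DIFFICULTY_REMOVALS:
        raise ValueError(
            f"unknown difficulty {difficulty!r}; choose from {sorted(DIFFICULTY_REMOVALS)}"
        )
    target = DIFFICULTY_REMOVALS[difficulty]
    for attempt in range(_CARVE_MAX_ATTEMPTS):
        rnd = random.Random(_sub_seed(seed, attempt))
        order = [(r, c) for r in range(9) for c in range(9)]
        rnd.shuffle(order)
        g = solution.copy()
        removed = 0
        for r, c in order:
            if removed == target:
                break
            v = g[r, c]
            g[r, c] = 0
            if count_solutions(g, limit=2) == 1:
                removed += 1
            else:
                g[r, c] = v
        if removed == target:
            return Puzzle(
                solution=solution,
                givens=g,
                difficulty=difficulty,
                removals=target,
                seed=seed,
            )
    raise PuzzleGenerationError(
        f"no unique {difficulty} carving found in {_CARVE_MAX_ATTEMPTS} attempts"
    )


def make_puzzle(difficulty: str, seed: int) -> Puzzle:
    """Convenience: generate a solution and carve it, both from ``seed``."""
    return carve_puzzle(generate_solution(seed), difficulty, seed)


@dataclass
class GameState:
    """Mutable play state over one puzzle.

    ``entries`` records the last entered digit and its correctness per
    cell; locked cells hold their (correct) value and reject further
    entries; ``n_errors`` counts every incorrect entry event.
    """

    puzzle: Puzzle
    entries: dict = field(default_factory=dict)
    locked: set = field(default_factory=set)
    selected: tuple[int, int] | None = None
    n_errors: int = 0

    def select(self, row: int, col: int) -> None:
        self.selected = (int(row), int(col))

    @property
    def is_complete(self) -> bool:
        return len(self.locked) == len(self.puzzle.empty_cells())

    def enter(self, row: int, col: int, value: int) -> bool:
        """Validate one entry; returns the correctness flag."""
        cell = (int(row), int(col))
        if not (1 <= value <= 9):
            raise InvalidEntryError(f"value {value} outside 1-9")
        if self.puzzle.givens[cell] != 0:
            raise InvalidEntryError(f"cell {cell} is a given")
        if cell in self.locked:
            raise InvalidEntryError(f"cell {cell} is already locked")
        correct = int(self.puzzle.solution[cell]) == int(value)
        self.entries[cell] = (int(value), correct)
        if correct:
            self.locked.add(cell)
        else:
            self.n_errors += 1
        return correct


def validate_entry(state: GameState, row: int, col: int, value: int) -> GameState:
    """Functional wrapper over :meth:`GameState.enter` (mutates and returns
    the state, for pipeline-style use)."""
    state.enter(row, col, value)
    return state


@dataclass(frozen=True)
class CommandVocabulary:
    """Digit-word vocabulary for one language; exactly nine accepted words."""

    language: str
    words: dict

    def __post_init__(self) -> None:
        if len(self.words) != 9 or set(self.words.values()) != set(range(1, 10)):
            raise ValueError("vocabulary must map exactly nine words onto 1-9")


VOCABULARIES = {
    "en": CommandVocabulary(
        "en",
        {
            "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
            "six": 6, "seven": 7, "eight": 8, "nine": 9,
        },
    ),
    "ro": CommandVocabulary(
        "ro",
        {
            "unu": 1, "doi": 2, "trei": 3, "patru": 4, "cinci": 5,
            "șase": 6, "șapte": 7, "opt": 8, "nouă": 9,
        },
    ),
}


def parse_voice_token(token: str, vocab: CommandVocabulary) -> int | None:
    """Map a spoken token to its digit, or ``None`` (ignored) for anything
    outside the nine-word vocabulary.  Never raises on arbitrary input."""
    if not isinstance(token, str):
        return None
    return vocab.words.get(token.strip().lower())


def countdown_sequence(spacing_s: float = 1.0, t0: float = 0.0) -> list[SessionEvent]:
    """The "3, 2, 1, Start" cue sequence as timestamped events (rhythmic
    auditory cueing to mitigate freezing episodes)."""
    cues = ["3", "2", "1", "Start"]
    return [
        SessionEvent(t=t0 + i * spacing_s, type="countdown", value=cue)
        for i, cue in enumerate(cues)
    ]
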