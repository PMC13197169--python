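"""Tower of London state space, solver, and problem-bank generation.

The task uses three pegs with capacities 3, 2 and 1 and three colored
balls.  A move transfers the top ball of one peg onto another peg with
free capacity.  Problems are start/goal pairs; the bank generator emits
families of structurally distinct problems expressed in all six color
permutations, each verified to have a unique optimal solution.
"""

from __future__ import annotations

import itertools
import json
import random
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

CAPACITIES: tuple[int, int, int] = (3, 2, 1)
COLORS: tuple[str, str, str] = ("R", "G", "B")


class InvalidStateError(ValueError):
    """Raised when a peg configuration violates the task rules."""


class IllegalMoveError(ValueError):
    """Raised when a move cannot be applied to a state."""


@dataclass(frozen=True, order=True)
class TolState:
    """Ordered ball stacks on the three pegs, bottom to top."""

    pegs: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.pegs) != 3:
            raise InvalidStateError("exactly three pegs required")
        balls = [b for peg in self.pegs for b in peg]
        if sorted(balls) != sorted(COLORS):
            raise InvalidStateError(
                f"state must contain each of {COLORS} exactly once, got {balls}"
            )
        for k, (peg, cap) in enumerate(zip(self.pegs, CAPACITIES), start=1):
            if len(peg) > cap:
                raise InvalidStateError(
                    f"peg {k} holds {len(peg)} balls, capacity is {cap}"
                )

    @classmethod
    def from_lists(cls, pegs: Sequence[Sequence[str]]) -> "TolState":
        return cls(tuple(tuple(p) for p in pegs))  # type: ignore[arg-type]

    def relabel(self, mapping: dict[str, str]) -> "TolState":
        """Apply a color bijection to every ball."""
        return TolState(tuple(tuple(mapping[b] for b in peg) for peg in self.pegs))  # type: ignore[arg-type]

    def serialize(self) -> str:
        """Canonical text form: pegs 1-3, bottom to top, '|' separated."""
        return "|".join("".join(peg) for peg in self.pegs)

    @classmethod
    def deserialize(cls, text: str) -> "TolState":
        return cls.from_lists([list(part) for part in text.split("|")])


@dataclass(frozen=True, order=True)
class TolMove:
    """Move the top ball of ``source_peg`` onto ``dest_peg`` (1-based)."""

    source_peg: int
    dest_peg: int

    def __post_init__(self) -> None:
        if not (1 <= self.source_peg <= 3 and 1 <= self.dest_peg <= 3):
            raise IllegalMoveError("peg indices must be 1-3")
        if self.source_peg == self.dest_peg:
            raise IllegalMoveError("source and destination pegs must differ")

    @property
    def inverse(self) -> "TolMove":
        return TolMove(self.dest_peg, self.source_peg)


@dataclass(frozen=True)
class TolProblem:
    """A start/goal pair with verified solution structure."""

    start: TolState
    goal: TolState
    optimal_length: int
    n_optimal_paths: int
    family_id: int = 0
    color_permutation: int = 1

    @property
    def unique(self) -> bool:
        return self.n_optimal_paths == 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "start": [list(p) for p in self.start.pegs],
                "goal": [list(p) for p in self.goal.pegs],
                "optimal_length": self.optimal_length,
                "n_optimal_paths": self.n_optimal_paths,
                "family_id": self.family_id,
                "color_permutation": self.color_permutation,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "TolProblem":
        d = json.loads(line)
        return cls(
            start=TolState.from_lists(d["start"]),
            goal=TolState.from_lists(d["goal"]),
            optimal_length=d["optimal_length"],
            n_optimal_paths=d["n_optimal_paths"],
            family_id=d["family_id"],
            color_permutation=d["color_permutation"],
        )


def legal_moves(state: TolState) -> list[TolMove]:
    """All moves legal in ``state``, sorted by (source, dest)."""
    moves = []
    for src in range(1, 4):
        if not state.pegs[src - 1]:
            continue
        for dst in range(1, 4):
            if dst == src:
                continue
            if len(state.pegs[dst - 1]) < CAPACITIES[dst - 1]:
                moves.append(TolMove(src, dst))
    return sorted(moves)


def apply_move(state: TolState, move: TolMove) -> TolState:
    """Apply ``move`` to ``state``; the top ball of the source peg moves."""
    src, dst = move.source_peg - 1, move.dest_peg - 1
    if not state.pegs[src]:
        raise IllegalMoveError(f"source peg {move.source_peg} is empty")
    if len(state.pegs[dst]) >= CAPACITIES[dst]:
        raise IllegalMoveError(f"destination peg {move.dest_peg} is at capacity")
    pegs = [list(p) for p in state.pegs]
    ball = pegs[src].pop()
    pegs[dst].append(ball)
    return TolState.from_lists(pegs)


def enumerate_states() -> list[TolState]:
    """Every valid state, in canonical (sorted) order.

    There are 6 occupancy distributions (n1<=3, n2<=2, n3<=1, sum 3)
    times 3! ball orderings = 36 states.
    """
    states = []
    for perm in itertools.permutations(COLORS):
        for n1 in range(0, 4):
            for n2 in range(0, 3):
                n3 = 3 - n1 - n2
                if not 0 <= n3 <= 1:
                    continue
                pegs = (perm[:n1], perm[n1 : n1 + n2], perm[n1 + n2 :])
                states.append(TolState(pegs))
    return sorted(set(states))


def shortest_paths(
    start: TolState, goal: TolState
) -> tuple[int, list[tuple[TolMove, ...]]]:
    """Minimal move count and ALL minimal move sequences, BFS over the move graph.

    Paths are returned in lexicographic move order.
    """
    if start == goal:
        return 0, [()]
    # BFS layer by layer, keeping every minimal predecessor.
    dist: dict[TolState, int] = {start: 0}
    preds: dict[TolState, list[tuple[TolState, TolMove]]] = {start: []}
    frontier = deque([start])
    found_at: int | None = None
    while frontier:
        state = frontier.popleft()
        d = dist[state]
        if found_at is not None and d >= found_at:
            break
        for move in legal_moves(state):
            nxt = apply_move(state, move)
            nd = d + 1
            if nxt not in dist:
                dist[nxt] = nd
                preds[nxt] = [(state, move)]
                frontier.append(nxt)
                if nxt == goal:
                    found_at = nd
            elif dist[nxt] == nd:
                preds[nxt].append((state, move))

    def unwind(state: TolState) -> list[tuple[TolMove, ...]]:
        if state == start:
            return [()]
        paths = []
        for prev, move in preds[state]:
            for prefix in unwind(prev):
                paths.append(prefix + (move,))
        return paths

    return dist[goal], sorted(unwind(goal))


def bfs_distances(start: TolState) -> dict[TolState, int]:
    """Distance from ``start`` to every reachable state."""
    dist = {start: 0}
    frontier = deque([start])
    while frontier:
        state = frontier.popleft()
        for move in legal_moves(state):
            nxt = apply_move(state, move)
            if nxt not in dist:
                dist[nxt] = dist[state] + 1
                frontier.append(nxt)
    return dist


def classify_problem(start: TolState, goal: TolState) -> TolProblem:
    """Solve a start/goal pair and record its solution structure."""
    if start == goal:
        raise ValueError("start and goal must differ")
    length, paths = shortest_paths(start, goal)
    return TolProblem(
        start=start,
        goal=goal,
        optimal_length=length,
        n_optimal_paths=len(paths),
    )


def color_permutations() -> list[dict[str, str]]:
    """The six color bijections, in a fixed deterministic order."""
    return [
        dict(zip(COLORS, perm)) for perm in sorted(itertools.permutations(COLORS))
    ]


def _family_key(start: TolState, goal: TolState) -> str:
    """Canonical form of a start/goal pair under color relabeling."""
    return min(
        start.relabel(m).serialize() + ">" + goal.relabel(m).serialize()
        for m in color_permutations()
    )


def generate_problem_bank(
    n_families: int = 12,
    n_permutations: int = 6,
    length_quota: dict[int, int] | None = None,
    seed: int = 0,
) -> list[TolProblem]:
    """Sample structurally distinct problem families and expand by color permutation.

    Each family is a start/goal pair (up to color relabeling) with a unique
    optimal solution whose length matches the quota.  With the defaults
    (12 families x 6 permutations, half length-2 and half length-4) the bank
    holds 72 problems.
    """
    if length_quota is None:
        length_quota = {2: n_families // 2, 4: n_families - n_families // 2}
    if sum(length_quota.values()) != n_families:
        raise ValueError("length quota must sum to n_families")
    if n_permutations > 6:
        raise ValueError("at most 6 color permutations exist")

    states = enumerate_states()
    # Group candidate pairs by family (equivalence class under relabeling).
    families_by_length: dict[int, dict[str, tuple[TolState, TolState]]] = {
        ln: {} for ln in length_quota
    }
    for start in states:
        dist = bfs_distances(start)
        for goal in states:
            if goal == start:
                continue
            ln = dist[goal]
            if ln not in length_quota:
                continue
            key = _family_key(start, goal)
            if key in families_by_length[ln]:
                continue
            prob = classify_problem(start, goal)
            if prob.unique:
                families_by_length[ln][key] = (start, goal)

    rng = random.Random(seed)
    bank: list[TolProblem] = []
    family_id = 0
    for ln in sorted(length_quota):
        want = length_quota[ln]
        candidates = sorted(families_by_length[ln])
        if len(candidates) < want:
            raise ValueError(
                f"only {len(candidates)} unique-optimal families of length {ln}, "
                f"quota asks for {want}"
            )
        for key in rng.sample(candidates, want):
            family_id += 1
            start, goal = families_by_length[ln][key]
            for perm_idx, mapping in enumerate(
                color_permutations()[:n_permutations], start=1
            ):
                prob = classify_problem(start.relabel(mapping), goal.relabel(mapping))
                bank.append(
                    TolProblem(
                        start=prob.start,
                        goal=prob.goal,
                        optimal_length=prob.optimal_length,
                        n_optimal_paths=prob.n_optimal_paths,
                        family_id=family_id,
                        color_permutation=perm_idx,
                    )
                )
    return bank


def schedule_blocks(
    bank: Sequence[TolProblem], n_blocks: int = 6, seed: int = 0
) -> list[list[TolProblem]]:
    """Split a bank into blocks so that no block repeats a family.

    Problems from the same family are placed in different blocks (one color
    permutation of each family per block when counts allow); order within a
    block is shuffled deterministically.
    """
    by_family: dict[int, list[TolProblem]] = {}
    for prob in bank:
        by_family.setdefault(prob.family_id, []).append(prob)
    for fam, probs in by_family.items():
        if len(probs) > n_blocks:
            raise ValueError(
                f"family {fam} has {len(probs)} problems but only {n_blocks} blocks"
            )
    rng = random.Random(seed)
    blocks: list[list[TolProblem]] = [[] for _ in range(n_blocks)]
    for fam in sorted(by_family):
        probs = sorted(by_family[fam], key=lambda p: p.color_permutation)
        slots = rng.sample(range(n_blocks), len(probs))
        for prob, slot in zip(probs, slots):
            blocks[slot].append(prob)
    for block in blocks:
        rng.shuffle(block)
    return blocks


def write_bank(bank: Iterable[TolProblem], path) -> None:
    with open(path, "w") as fh:
        for prob in bank:
            fh.write(prob.to_json() + "\n")


def read_bank(path) -> list[TolProblem]:
    with open(path) as fh:
        return [TolProblem.from_json(line) for line in fh if line.strip()]
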