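"""Exact model of the three-bead Tower of London planning task.

Three beads (R, G, B) sit on three posts of capacities 3, 2 and 1. A move
transfers the top bead of one post onto another post with free capacity.
A problem presents a start and a goal configuration; the participant must
report the minimum number of moves (1-5) needed to transform one into the
other. The full state space has 36 configurations and is small enough to
solve exactly by breadth-first search; all-pairs distances are precomputed
and cached.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "CAPACITIES",
    "BEADS",
    "ToLState",
    "ToLProblem",
    "TrialResponse",
    "enumerate_states",
    "legal_moves",
    "min_moves",
    "generate_problem_set",
    "score_responses",
    "trials_to_tsv",
    "trials_from_tsv",
]

CAPACITIES = (3, 2, 1)
BEADS = ("R", "G", "B")


@dataclass(frozen=True)
class ToLState:
    """One bead configuration: three stacks, bottom-to-top order."""

    posts: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        beads = [b for post in self.posts for b in post]
        if sorted(beads) != sorted(BEADS):
            raise ValueError(f"state must contain exactly the beads {BEADS}: {self.posts}")
        for i, post in enumerate(self.posts):
            if len(post) > CAPACITIES[i]:
                raise ValueError(
                    f"post {i + 1} holds {len(post)} beads, capacity {CAPACITIES[i]}"
                )

    def serialize(self) -> str:
        """Unique canonical text form, e.g. ``RG|B|`` (posts separated by |)."""
        return "|".join("".join(post) for post in self.posts)

    @classmethod
    def deserialize(cls, text: str) -> "ToLState":
        parts = text.split("|")
        if len(parts) != 3:
            raise ValueError(f"expected 3 posts in serialized state: {text!r}")
        return cls(tuple(tuple(p) for p in parts))  # type: ignore[arg-type]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.serialize()


@dataclass(frozen=True)
class ToLProblem:
    """A start/goal pair whose difficulty is the exact minimum move count."""

    start: ToLState
    goal: ToLState
    min_moves: int

    def __post_init__(self) -> None:
        if self.start == self.goal:
            raise ValueError("start and goal must differ")
        true = min_moves(self.start, self.goal)
        if true != self.min_moves:
            raise ValueError(f"labeled min_moves {self.min_moves} != BFS distance {true}")
        if not 1 <= self.min_moves <= 5:
            raise ValueError("difficulty level must be in 1..5")


@dataclass(frozen=True)
class TrialResponse:
    """One scored trial: the presented problem, the answer and the RT."""

    problem: ToLProblem
    answered_moves: int
    rt_s: float

    def __post_init__(self) -> None:
        if self.rt_s <= 0:
            raise ValueError("reaction time must be positive")

    @property
    def correct(self) -> bool:
        return self.answered_moves == self.problem.min_moves


@lru_cache(maxsize=1)
def enumerate_states() -> frozenset[ToLState]:
    """All 36 admissible configurations of 3 distinct beads on posts (3,2,1)."""
    occupancies = [
        occ
        for occ in itertools.product(range(4), range(3), range(2))
        if sum(occ) == 3
    ]
    states = []
    for occ in occupancies:
        for order in itertools.permutations(BEADS):
            it = iter(order)
            posts = tuple(tuple(itertools.islice(it, k)) for k in occ)
            states.append(ToLState(posts))  # type: ignore[arg-type]
    return frozenset(states)


def legal_moves(state: ToLState) -> list[ToLState]:
    """Successors reachable by moving one top bead to a post with free space."""
    out = []
    for src in range(3):
        if not state.posts[src]:
            continue
        for dst in range(3):
            if dst == src or len(state.posts[dst]) >= CAPACITIES[dst]:
                continue
            posts = [list(p) for p in state.posts]
            bead = posts[src].pop()
            posts[dst].append(bead)
            out.append(ToLState(tuple(tuple(p) for p in posts)))  # type: ignore[arg-type]
    return out


@lru_cache(maxsize=1)
def _all_pairs_distances() -> dict[ToLState, dict[ToLState, int]]:
    """BFS from every state over the 36-state move graph (cached)."""
    dist: dict[ToLState, dict[ToLState, int]] = {}
    for source in enumerate_states():
        d = {source: 0}
        queue = deque([source])
        while queue:
            s = queue.popleft()
            for t in legal_moves(s):
                if t not in d:
                    d[t] = d[s] + 1
                    queue.append(t)
        dist[source] = d
    return dist


def min_moves(start: ToLState, goal: ToLState) -> int:
    """Length of the shortest legal-move path between two configurations."""
    return _all_pairs_distances()[start][goal]


@lru_cache(maxsize=16)
def _pairs_at_distance(level: int) -> tuple[tuple[ToLState, ToLState], ...]:
    dist = _all_pairs_distances()
    states = sorted(enumerate_states(), key=lambda s: s.serialize())
    return tuple((a, b) for a in states for b in states if dist[a][b] == level)


def generate_problem_set(
    n_per_level: int, seed: int, levels: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> list[ToLProblem]:
    """Sample ``n_per_level`` distinct problems at each difficulty level.

    Sampling is uniform over all (start, goal) pairs at the requested BFS
    distance, without replacement within a set; fully reproducible by seed.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    problems: list[ToLProblem] = []
    for level in levels:
        pairs = _pairs_at_distance(level)
        if n_per_level > len(pairs):
            raise ValueError(
                f"level {level}: requested {n_per_level} problems but only "
                f"{len(pairs)} distinct (start, goal) pairs exist"
            )
        idx = rng.choice(len(pairs), size=n_per_level, replace=False)
        problems.extend(
            ToLProblem(start=pairs[i][0], goal=pairs[i][1], min_moves=level)
            for i in idx
        )
    return problems


def score_responses(
    trials: list[TrialResponse], levels: frozenset[int] | set[int] = frozenset({1, 2, 3, 4, 5})
) -> tuple[float, float]:
    """Accuracy (%) and mean RT (s) over correct trials, restricted to levels.

    The level restriction supports the post-hoc reanalysis that keeps only the
    demanding 4- and 5-move trials. Raises if the restriction leaves no trials,
    and if no trial in the subset is correct (mean RT would be undefined).
    """
    subset = [t for t in trials if t.problem.min_moves in levels]
    if not subset:
        raise ValueError(f"no trials at levels {sorted(levels)}")
    n_correct = sum(t.correct for t in subset)
    accuracy = 100.0 * n_correct / len(subset)
    if n_correct == 0:
        raise ValueError(
            f"no correct trials at levels {sorted(levels)}: mean RT undefined"
        )
    mean_rt = float(np.mean([t.rt_s for t in subset if t.correct]))
    return accuracy, mean_rt


def trials_to_tsv(trials: list[TrialResponse]) -> str:
    """Serialize trials as TSV: start, goal, level, answer, RT (seconds)."""
    lines = ["start\tgoal\tlevel\tanswered_moves\trt_s"]
    for t in trials:
        lines.append(
            f"{t.problem.start.serialize()}\t{t.problem.goal.serialize()}\t"
            f"{t.problem.min_moves}\t{t.answered_moves}\t{t.rt_s:.6f}"
        )
    return "\n".join(lines) + "\n"


def trials_from_tsv(text: str) -> list[TrialResponse]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    trials = []
    for ln in lines[1:]:
        start, goal, level, answer, rt = ln.split("\t")
        problem = ToLProblem(
            start=ToLState.deserialize(start),
            goal=ToLState.deserialize(goal),
            min_moves=int(level),
        )
        trials.append(TrialResponse(problem, int(answer), float(rt)))
    return trials
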