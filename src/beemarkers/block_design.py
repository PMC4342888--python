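"""Randomized incomplete block design for triplex isotopic labeling.

Each colony contributes three replicate antennal samples; samples are
grouped into blocks of three, one block per LC-MS/MS run, with the three
dimethyl labels (light/medium/heavy) distinguishing the samples within a
block.  The design must satisfy:

* every block holds exactly three samples with three distinct labels;
* every colony appears in exactly three blocks, once per replicate, using
  each label exactly once across its replicates;
* no block holds two samples from the same colony;
* no block holds two colonies from the same population of origin.

Among feasible designs we minimize the sampling variance of the estimated
hygienic-behavior (HB) effect in the block-adjusted linear model, i.e. the
inverse of the block-centered sum of squares of the HB covariate over all
sample slots.  Spreading dissimilar HB values within blocks maximizes the
power to detect expression-HB associations.  The literal alternative of
minimizing the within-block variance of HB is available via
``criterion="within_block_variance"``.

The optimizer is a random feasible start plus pairwise same-label slot-swap
hill climbing, repeated over ``n_restarts`` restarts (greedy; instances of
one-to-two hundred colonies do not need more).  Labels are attached to a
feasible colony-block incidence by peeling perfect matchings off the
3-regular colony-block bipartite graph (Koenig's theorem guarantees three),
so label balance holds by construction and swaps exchange same-label slots
only.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .types import LABELS, BlockAssignment, BlockSlot, ColonyRecord


class InfeasibleDesignError(ValueError):
    """The design constraints cannot be satisfied for these colonies."""


# ---------------------------------------------------------------------------
# feasibility and incidence construction
# ---------------------------------------------------------------------------


def _check_feasibility(colonies: Sequence[ColonyRecord], relax_population: bool) -> None:
    n = len(colonies)
    if n < 3:
        raise InfeasibleDesignError(f"need at least 3 colonies, got {n}")
    ids = [c.colony_id for c in colonies]
    if len(set(ids)) != n:
        raise InfeasibleDesignError("duplicate colony_id in input")
    if relax_population:
        return
    pops: dict[str, int] = {}
    for c in colonies:
        pops[c.population] = pops.get(c.population, 0) + 1
    if len(pops) < 3:
        raise InfeasibleDesignError(
            f"only {len(pops)} distinct populations; 3 are required unless the "
            "population constraint is relaxed"
        )
    # Each colony fills 3 of the 3n/3 = n block slots reserved one-per-block
    # for its population, so a population may hold at most n/3 colonies.
    for pop, k in pops.items():
        if 3 * k > n:
            raise InfeasibleDesignError(
                f"population {pop!r} has {k} of {n} colonies (> one third): "
                "cannot avoid same-population block collisions"
            )


def _random_incidence(
    colonies: Sequence[ColonyRecord],
    rng: np.random.Generator,
    relax_population: bool,
    max_repair: int = 200_000,
) -> list[list[int]]:
    """Random feasible colony-block incidence: n blocks x 3 colony indices.

    Starts from a random placement of the 3n samples and repairs constraint
    violations (same colony or same population twice in a block) by swapping
    offending samples with randomly chosen ones in other blocks.
    """
    n = len(colonies)
    pop = [c.population for c in colonies]
    samples = np.repeat(np.arange(n), 3)
    rng.shuffle(samples)
    blocks = samples.reshape(n, 3)

    def violations(b: int) -> int:
        cols = blocks[b]
        v = 3 - len(set(cols.tolist()))
        if not relax_population:
            ps = [pop[c] for c in cols]
            v += 3 - len(set(ps))
        return v

    bad = {b for b in range(n) if violations(b) > 0}
    attempts = 0
    while bad and attempts < max_repair:
        attempts += 1
        b = rng.choice(sorted(bad))
        i = int(rng.integers(3))
        b2 = int(rng.integers(n))
        if b2 == b:
            continue
        j = int(rng.integers(3))
        before = violations(b) + violations(b2)
        blocks[b, i], blocks[b2, j] = blocks[b2, j], blocks[b, i]
        after = violations(b) + violations(b2)
        if after > before:
            blocks[b, i], blocks[b2, j] = blocks[b2, j], blocks[b, i]
        else:
            for bb in (b, b2):
                if violations(bb) > 0:
                    bad.add(bb)
                else:
                    bad.discard(bb)
    if bad:
        raise InfeasibleDesignError(
            "could not construct a feasible random incidence (repair budget "
            "exhausted); constraints may be near-infeasible"
        )
    return [sorted(blocks[b].tolist()) for b in range(n)]


def _color_labels(incidence: list[list[int]], n_colonies: int) -> dict[tuple[int, int], str]:
    """Assign labels to (block, colony) pairs via bipartite matching peeling.

    The colony-block incidence graph is 3-regular bipartite, hence the union
    of three perfect matchings; each matching gets one label, giving every
    block and every colony each label exactly once.
    """
    edges = {(b, c) for b, cols in enumerate(incidence) for c in cols}
    coloring: dict[tuple[int, int], str] = {}
    remaining = set(edges)
    for label in LABELS[:2]:
        g = nx.Graph()
        bnodes = [("b", b) for b in range(len(incidence))]
        cnodes = [("c", c) for c in range(n_colonies)]
        g.add_nodes_from(bnodes, bipartite=0)
        g.add_nodes_from(cnodes, bipartite=1)
        g.add_edges_from((("b", b), ("c", c)) for b, c in sorted(remaining))
        match = nx.bipartite.hopcroft_karp_matching(g, top_nodes=bnodes)
        for b in range(len(incidence)):
            node = match.get(("b", b))
            if node is None:
                raise RuntimeError("matching peel failed on regular bipartite graph")
            edge = (b, node[1])
            coloring[edge] = label
            remaining.discard(edge)
    for b, c in remaining:
        coloring[(b, c)] = LABELS[2]
    return coloring


def _assignment_from_incidence(
    incidence: list[list[int]],
    colonies: Sequence[ColonyRecord],
    seed: Optional[int] = None,
) -> BlockAssignment:
    """Attach labels and replicate indices to a colony-block incidence.

    Replicates follow a fixed Latin rotation: a colony's light sample is
    replicate 0, medium 1, heavy 2.
    """
    coloring = _color_labels(incidence, len(colonies))
    label_rank = {lab: r for r, lab in enumerate(LABELS)}
    blocks = []
    for b, cols in enumerate(incidence):
        slots = []
        for c in cols:
            lab = coloring[(b, c)]
            slots.append(BlockSlot(colonies[c].colony_id, label_rank[lab], lab))
        slots.sort(key=lambda s: label_rank[s.label])
        blocks.append(slots)
    return BlockAssignment(blocks=blocks, seed=seed)


# ---------------------------------------------------------------------------
# design criterion
# ---------------------------------------------------------------------------


def _block_centered_ssx(incidence: list[list[int]], x: np.ndarray) -> float:
    vals = x[np.asarray(incidence)]  # n_blocks x 3
    centered = vals - vals.mean(axis=1, keepdims=True)
    return float((centered**2).sum())


def design_information(
    assignment: BlockAssignment,
    colonies: Sequence[ColonyRecord],
    hb_variable: str = "r24",
) -> float:
    """Sampling variance of the HB-effect estimator under the block-adjusted model.

    Equals ``1 / SSX`` where SSX is the block-centered sum of squares of the
    HB covariate over all sample slots (the residual sum of squares of the
    covariate after projection on block indicators).  Lower is better.
    Returns +inf with a warning when the covariate has no within-block
    variation anywhere, in which case the HB effect is inestimable.
    """
    idx = {c.colony_id: i for i, c in enumerate(colonies)}
    x = np.array([getattr(c, hb_variable) for c in colonies], dtype=float)
    incidence = [[idx[s.colony_id] for s in block] for block in assignment.blocks]
    ssx = _block_centered_ssx(incidence, x)
    if ssx <= 1e-12:
        warnings.warn(
            "no within-block variation in the HB covariate; effect inestimable",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return 1.0 / ssx


def _objective(incidence: list[list[int]], x: np.ndarray, criterion: str) -> float:
    ssx = _block_centered_ssx(incidence, x)
    if criterion == "effect_variance":
        return 1.0 / ssx if ssx > 1e-12 else float("inf")
    if criterion == "within_block_variance":
        # literal reading: minimize the spread of HB within blocks
        return ssx
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def _local_search(
    incidence: list[list[int]],
    x: np.ndarray,
    pop: list[str],
    criterion: str,
    rng: np.random.Generator,
    relax_population: bool,
    max_sweeps: int = 60,
) -> tuple[list[list[int]], float]:
    """Greedy hill climbing over same-position colony swaps between blocks.

    Swapping the slot at position k of two blocks exchanges two same-label
    samples, so label balance and replicate structure survive every move.
    Only improving moves are accepted; sweeps repeat until no move improves.
    """
    inc = [list(b) for b in incidence]
    n = len(inc)

    def block_obj(cols: list[int]) -> float:
        v = x[cols]
        m = v.mean()
        return float(((v - m) ** 2).sum())

    ssx_blocks = [block_obj(b) for b in inc]
    sign = -1.0 if criterion == "effect_variance" else 1.0
    # maximize SSX for effect_variance, minimize for within_block_variance

    def feasible(cols: list[int]) -> bool:
        if len(set(cols)) != 3:
            return False
        if not relax_population:
            if len({pop[c] for c in cols}) != 3:
                return False
        return True

    improved = True
    sweeps = 0
    pairs = list(itertools.combinations(range(n), 2))
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        order = rng.permutation(len(pairs))
        for pi in order:
            b1, b2 = pairs[pi]
            for k1 in range(3):
                for k2 in range(3):
                    c1, c2 = inc[b1][k1], inc[b2][k2]
                    if c1 == c2:
                        continue
                    new1 = inc[b1][:k1] + [c2] + inc[b1][k1 + 1 :]
                    new2 = inc[b2][:k2] + [c1] + inc[b2][k2 + 1 :]
                    if not (feasible(new1) and feasible(new2)):
                        continue
                    delta = (
                        block_obj(new1)
                        + block_obj(new2)
                        - ssx_blocks[b1]
                        - ssx_blocks[b2]
                    )
                    if sign * delta < -1e-13:
                        inc[b1], inc[b2] = new1, new2
                        ssx_blocks[b1] = block_obj(new1)
                        ssx_blocks[b2] = block_obj(new2)
                        improved = True
    return [sorted(b) for b in inc], _objective(inc, x, criterion)


def build_design(
    colonies: Sequence[ColonyRecord],
    hb_variable: str = "r24",
    n_restarts: int = 10,
    seed: int = 0,
    criterion: str = "effect_variance",
    relax_population: bool = False,
) -> BlockAssignment:
    """Construct an optimized constraint-satisfying triplex block design.

    Runs ``n_restarts`` random feasible initializations, hill-climbs each by
    same-label slot swaps, and returns the best design found.  Ties between
    equal-objective designs break on the lexicographic block signature so the
    result is a deterministic function of the inputs and ``seed``.

    Raises :class:`InfeasibleDesignError` when the constraints cannot hold,
    naming the violated constraint.
    """
    _check_feasibility(colonies, relax_population)
    x = np.array([getattr(c, hb_variable) for c in colonies], dtype=float)
    pop = [c.population for c in colonies]
    ss = np.random.SeedSequence(seed)
    best: tuple[float, list[tuple[int, ...]], list[list[int]]] | None = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        inc0 = _random_incidence(colonies, rng, relax_population)
        inc, obj = _local_search(inc0, x, pop, criterion, rng, relax_population)
        signature = sorted(tuple(b) for b in inc)
        if best is None or (obj, signature) < best[:2]:
            best = (obj, signature, [list(b) for b in sorted(inc)])
    assert best is not None
    obj, _, inc = best
    assignment = _assignment_from_incidence(inc, colonies, seed=seed)
    assignment.objective_value = obj
    return assignment


def random_design(
    colonies: Sequence[ColonyRecord],
    seed: int = 0,
    relax_population: bool = False,
) -> BlockAssignment:
    """A single random feasible design (no optimization); useful as a baseline."""
    _check_feasibility(colonies, relax_population)
    rng = np.random.default_rng(seed)
    inc = _random_incidence(colonies, rng, relax_population)
    assignment = _assignment_from_incidence(inc, colonies, seed=seed)
    x = np.array([getattr(c, "r24") for c in colonies], dtype=float)
    assignment.objective_value = _objective(inc, x, "effect_variance")
    return assignment


# ---------------------------------------------------------------------------
# validation and enumeration
# ---------------------------------------------------------------------------


def validate_design(
    assignment: BlockAssignment,
    colonies: Sequence[ColonyRecord],
    relax_population: bool = False,
) -> dict:
    """Check every design invariant; report pass/fail with offending blocks.

    Pure report: nothing is mutated and no exception is raised for failures.
    """
    pops = {c.colony_id: c.population for c in colonies}
    report: dict[str, dict] = {}

    def check(name: str, offenders: list) -> None:
        report[name] = {"passed": not offenders, "offending_blocks": offenders}

    bad_size = [b for b, blk in enumerate(assignment.blocks) if len(blk) != 3]
    check("block_size_3", bad_size)
    bad_labels = [
        b
        for b, blk in enumerate(assignment.blocks)
        if sorted(s.label for s in blk) != sorted(LABELS)
    ]
    check("distinct_labels_per_block", bad_labels)
    bad_dup = [
        b
        for b, blk in enumerate(assignment.blocks)
        if len({s.colony_id for s in blk}) != len(blk)
    ]
    check("no_colony_repeat_in_block", bad_dup)
    bad_pop = [
        b
        for b, blk in enumerate(assignment.blocks)
        if len({pops.get(s.colony_id) for s in blk}) != len(blk)
    ]
    check("no_population_repeat_in_block", [] if relax_population else bad_pop)

    per_colony: dict[str, list[tuple[int, int, str]]] = {}
    for b, blk in enumerate(assignment.blocks):
        for s in blk:
            per_colony.setdefault(s.colony_id, []).append((b, s.replicate, s.label))
    bad_colonies = []
    for cid in pops:
        entries = per_colony.get(cid, [])
        ok = (
            len(entries) == 3
            and len({e[0] for e in entries}) == 3
            and sorted(e[1] for e in entries) == [0, 1, 2]
            and sorted(e[2] for e in entries) == sorted(LABELS)
        )
        if not ok:
            bad_colonies.append(cid)
    report["colony_three_blocks_all_labels"] = {
        "passed": not bad_colonies,
        "offending_colonies": bad_colonies,
    }
    unknown = [cid for cid in per_colony if cid not in pops]
    report["all_colonies_known"] = {"passed": not unknown, "offending_colonies": unknown}
    report["all_passed"] = all(
        v["passed"] for k, v in report.items() if isinstance(v, dict)
    )
    return report


def enumerate_optimal(
    colonies: Sequence[ColonyRecord],
    hb_variable: str = "r24",
    criterion: str = "effect_variance",
    relax_population: bool = False,
    max_colonies: int = 6,
) -> tuple[float, list[list[int]]]:
    """Exhaustively enumerate feasible colony-block incidences; return the optimum.

    The criterion depends only on which colonies share blocks, so label
    assignments need not be enumerated.  Intended for instances of at most
    ``max_colonies`` colonies.
    """
    n = len(colonies)
    if n > max_colonies:
        raise ValueError(f"enumeration limited to {max_colonies} colonies, got {n}")
    _check_feasibility(colonies, relax_population)
    x = np.array([getattr(c, hb_variable) for c in colonies], dtype=float)
    pop = [c.population for c in colonies]
    triples = [
        t
        for t in itertools.combinations(range(n), 3)
        if relax_population or len({pop[c] for c in t}) == 3
    ]
    best_obj = float("inf") if criterion == "effect_variance" else float("inf")
    best_inc: list[list[int]] | None = None

    deg = [0] * n

    def rec(chosen: list[int], start: int, remaining: int) -> None:
        nonlocal best_obj, best_inc
        if remaining == 0:
            if all(d == 3 for d in deg):
                inc = [list(triples[i]) for i in chosen]
                obj = _objective(inc, x, criterion)
                if obj < best_obj:
                    best_obj = obj
                    best_inc = inc
            return
        for i in range(start, len(triples)):
            t = triples[i]
            if any(deg[c] >= 3 for c in t):
                continue
            for c in t:
                deg[c] += 1
            chosen.append(i)
            rec(chosen, i, remaining - 1)  # blocks unordered: multiset of triples
            chosen.pop()
            for c in t:
                deg[c] -= 1

    rec([], 0, n)
    if best_inc is None:
        raise InfeasibleDesignError("no feasible incidence exists")
    return best_obj, best_inc
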