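"""Constraint-based causal discovery: PC algorithm with Fisher-z tests.

The implementation is self-contained and deliberately order-independent:

* conditional independence is decided by the Fisher-z test of a vanishing
  partial correlation (the standard test for multivariate-Gaussian data);
* the skeleton phase is the *stable* PC variant -- adjacency sets are
  frozen at the start of every depth, so the result does not depend on
  the order in which edges are visited;
* unshielded triples x - z - y with z outside the recorded separating set
  become v-structures x -> z <- y; conflicting orientation demands revert
  the edge to undirected (a completed graph cannot carry bidirected
  edges), with a logged warning;
* Meek's rules R1-R4 are applied to a fixed point, yielding a CPDAG.

Two exact graph oracles back the tests: :func:`d_separated` (reachability
on the moralized ancestral subgraph) and :func:`cpdag_of` (the
Markov-equivalence class representative of a DAG).  :func:`oracle_pc`
runs the identical PC machinery with d-separation in place of the data
test, which on a faithful input must reproduce :func:`cpdag_of` exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
from scipy.stats import norm

from .cohort_model import CohortTable
from .errors import InsufficientSampleError, NumericalError, ValidationError
from .synthetic_data import Dag

logger = logging.getLogger(__name__)

Pair = frozenset


@dataclass
class Cpdag:
    """Mixed graph: undirected pairs plus an acyclic set of directed edges."""

    nodes: tuple[str, ...]
    undirected: set[frozenset] = field(default_factory=set)
    directed: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.undirected = {frozenset(p) for p in self.undirected}
        self.directed = {tuple(e) for e in self.directed}
        self.validate()

    def validate(self) -> None:
        known = set(self.nodes)
        for p in self.undirected:
            if len(p) != 2 or not p <= known:
                raise ValidationError(f"bad undirected pair {set(p)}")
        dir_pairs = {frozenset(e) for e in self.directed}
        for a, b in self.directed:
            if a == b or a not in known or b not in known:
                raise ValidationError(f"bad directed edge ({a!r}, {b!r})")
            if (b, a) in self.directed:
                raise ValidationError(f"edge {a!r}-{b!r} directed both ways")
        if dir_pairs & self.undirected:
            raise ValidationError("a pair appears both directed and undirected")
        g = nx.DiGraph(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("directed part contains a cycle")

    # -- queries ------------------------------------------------------------
    def skeleton_pairs(self) -> set[frozenset]:
        return self.undirected | {frozenset(e) for e in self.directed}

    def is_adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.undirected or (a, b) in self.directed \
            or (b, a) in self.directed

    def neighbors(self, node: str) -> set[str]:
        out = {next(iter(p - {node})) for p in self.undirected if node in p}
        out |= {b for a, b in self.directed if a == node}
        out |= {a for a, b in self.directed if b == node}
        return out

    def copy(self) -> "Cpdag":
        return Cpdag(self.nodes, set(self.undirected), set(self.directed))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cpdag):
            return NotImplemented
        return (set(self.nodes) == set(other.nodes)
                and self.undirected == other.undirected
                and self.directed == other.directed)

    # -- serialization ------------------------------------------------------
    def to_edge_records(self) -> list[dict]:
        rows = [{"source": a, "target": b, "kind": "directed"}
                for a, b in sorted(self.directed)]
        rows += [{"source": a, "target": b, "kind": "undirected"}
                 for a, b in sorted(tuple(sorted(p)) for p in self.undirected)]
        return sorted(rows, key=lambda r: (r["source"], r["target"]))

    def write_tsv(self, path: str | Path) -> None:
        lines = ["source\ttarget\tkind"]
        lines += [f"{r['source']}\t{r['target']}\t{r['kind']}"
                  for r in self.to_edge_records()]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in sorted(self.directed):
            g.add_edge(a, b, kind="directed")
        for p in sorted(self.undirected, key=sorted):
            a, b = sorted(p)
            g.add_edge(a, b, kind="undirected")
        nx.write_graphml(g, path)


class SepsetMap:
    """Separating set recorded for each removed pair, keyed unordered."""

    def __init__(self) -> None:
        self._d: dict[frozenset, frozenset] = {}

    def set(self, x: str, y: str, S: Iterable[str]) -> None:
        S = frozenset(S)
        if x in S or y in S:
            raise ValidationError("conditioning set may not contain an endpoint")
        self._d[frozenset((x, y))] = S

    def get(self, x: str, y: str) -> frozenset | None:
        return self._d.get(frozenset((x, y)))

    def __len__(self) -> int:
        return len(self._d)

    def items(self):
        return self._d.items()


@dataclass(frozen=True)
class CiDecision:
    """Outcome of one Fisher-z conditional-independence test."""

    r: float
    z: float
    stat: float
    p: float
    independent: bool


def partial_correlation(corr: np.ndarray, x: int, y: int, S: Iterable[int]) -> float:
    """Partial correlation of variables x, y given S, from a correlation matrix.

    Computed by the precision-matrix formula on the submatrix over
    {x, y} | S; closed forms handle |S| <= 1 (the vast majority of PC's
    queries).  The result is symmetric in x, y and invariant to the order
    of S.
    """
    S = sorted(set(S))
    if x in S or y in S or x == y:
        raise ValidationError("x, y must be distinct and outside S")
    if not S:
        return float(corr[x, y])
    if len(S) == 1:
        z = S[0]
        rxy, rxz, ryz = corr[x, y], corr[x, z], corr[y, z]
        den = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
        if den <= 0:
            raise NumericalError(f"degenerate conditioning on {S}")
        return float((rxy - rxz * ryz) / np.sqrt(den))
    idx = [x, y, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise NumericalError(f"singular submatrix for conditioning set {S}") from None
    den = prec[0, 0] * prec[1, 1]
    if den <= 0:
        raise NumericalError(f"non-PD submatrix for conditioning set {S}")
    r = float(-prec[0, 1] / np.sqrt(den))
    return float(np.clip(r, -1.0, 1.0))


def fisher_z_test(r: float, n: int, s: int, alpha: float) -> CiDecision:
    """Test rho = 0 from a sample partial correlation r with |S| = s.

    z = atanh(r); the statistic sqrt(n - s - 3) * |z| is approximately
    standard normal under independence, giving the two-sided p-value
    p = 2 * (1 - Phi(stat)).  Independence is declared when p > alpha.
    """
    dof = n - s - 3
    if dof < 1:
        raise InsufficientSampleError(
            f"n = {n} too small for conditioning-set size {s}"
        )
    r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    z = float(np.arctanh(r))
    stat = float(np.sqrt(dof) * abs(z))
    p = float(2.0 * norm.sf(stat))
    return CiDecision(r=r, z=z, stat=stat, p=p, independent=p > alpha)


# ---------------------------------------------------------------------------
# PC skeleton (stable variant) over an abstract independence callable
# ---------------------------------------------------------------------------

def _skeleton_core(
    names: tuple[str, ...],
    indep: Callable[[int, int, tuple[int, ...]], bool],
    max_depth: int | None = None,
) -> tuple[Cpdag, SepsetMap]:
    """Order-independent skeleton phase of PC.

    Starts from the complete graph; at depth l every still-adjacent pair
    (x, y) is tested against all size-l subsets of adj(x) \\ {y} and of
    adj(y) \\ {x}, with adjacency sets frozen at the start of the depth.
    Candidate subsets are enumerated in lexicographic order of node
    *name*, so the first separating set recorded -- and hence the final
    orientation -- is invariant under column permutations of the input.
    """
    n = len(names)
    rank = {i: names[i] for i in range(n)}  # sort key: node name
    adj: list[set[int]] = [set(range(n)) - {i} for i in range(n)]
    seps = SepsetMap()
    depth = 0
    while True:
        pairs = sorted(
            ((x, y) for x in range(n) for y in adj[x] if rank[x] < rank[y]),
            key=lambda p: (rank[p[0]], rank[p[1]]),
        )
        # classical stop rule: some adjacency set must still be large enough
        if not any(len(adj[a]) - 1 >= depth for a, b in pairs for a, b in ((a, b), (b, a))):
            break
        if max_depth is not None and depth > max_depth:
            logger.warning(
                "PC skeleton depth capped at %d by sample size", max_depth
            )
            break
        frozen = [sorted(s, key=rank.get) for s in adj]
        for x, y in pairs:
            removed = False
            tested: set[tuple[int, ...]] = set()
            for a, b in ((x, y), (y, x)):
                cand = [v for v in frozen[a] if v != b]
                if len(cand) < depth:
                    continue
                for S in combinations(cand, depth):
                    if S in tested:
                        continue
                    tested.add(S)
                    if indep(x, y, S):
                        adj[x].discard(y)
                        adj[y].discard(x)
                        seps.set(names[x], names[y], (names[v] for v in S))
                        removed = True
                        break
                if removed:
                    break
        depth += 1
    und = {frozenset((names[x], names[y]))
           for x in range(n) for y in adj[x] if x < y}
    return Cpdag(names, und, set()), seps


def pc_skeleton(table: CohortTable, alpha: float) -> tuple[Cpdag, SepsetMap]:
    """Stable PC skeleton on a complete cohort table via Fisher-z tests.

    The conditioning-set depth is capped at n - 4 so the Fisher-z degrees
    of freedom stay positive (with a logged warning when the cap binds).
    """
    if np.isnan(table.values).any():
        raise ValidationError("table has missing values; impute first")
    if table.n_cols < 2:
        raise ValidationError("need at least 2 columns")
    n = table.n_rows
    corr = np.corrcoef(table.values.T)

    def indep(x: int, y: int, S: tuple[int, ...]) -> bool:
        r = partial_correlation(corr, x, y, S)
        return fisher_z_test(r, n, len(S), alpha).independent

    return _skeleton_core(table.roster.names, indep, max_depth=n - 4)


def orient_v_structures(skeleton: Cpdag, sepsets: SepsetMap) -> Cpdag:
    """Orient unshielded triples x - z - y with z outside sepset(x, y).

    All orientation demands are collected first; an edge demanded in both
    directions by different triples is a conflict and stays undirected
    (logged).
    """
    if skeleton.directed:
        raise ValidationError("skeleton must be undirected-only")
    demands: set[tuple[str, str]] = set()
    for z in sorted(skeleton.nodes):
        nbrs = sorted(skeleton.neighbors(z))
        for x, y in combinations(nbrs, 2):
            if skeleton.is_adjacent(x, y):
                continue
            S = sepsets.get(x, y)
            if S is None or z in S:
                continue
            demands.add((x, z))
            demands.add((y, z))
    conflicts = {frozenset(e) for e in demands if (e[1], e[0]) in demands}
    for pair in conflicts:
        logger.info("conflicting v-structure orientations on %s; kept undirected",
                    sorted(pair))
    out = skeleton.copy()
    for a, b in sorted(demands):
        pair = frozenset((a, b))
        if pair in conflicts:
            continue
        if _reaches(out.directed, b, a):
            # a finite-sample artifact: the demanded arrow would close a
            # directed cycle; treat like a conflict and keep the edge undirected
            logger.info("v-structure orientation %s -> %s would create a cycle; "
                        "kept undirected", a, b)
            continue
        out.undirected.discard(pair)
        out.directed.add((a, b))
    out.validate()
    return out


def _reaches(directed: set[tuple[str, str]], src: str, dst: str) -> bool:
    """True if dst is reachable from src along directed edges."""
    succ: dict[str, list[str]] = {}
    for a, b in directed:
        succ.setdefault(a, []).append(b)
    seen = {src}
    stack = [src]
    while stack:
        cur = stack.pop()
        for nxt in succ.get(cur, ()):
            if nxt == dst:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _meek_pass(g: Cpdag) -> bool:
    """One sweep of Meek rules R1-R4; returns True if something oriented."""
    changed = False
    for pair in sorted(g.undirected, key=sorted):
        a, b = sorted(pair)
        for a, b in ((a, b), (b, a)):
            if frozenset((a, b)) not in g.undirected:
                break
            oriented = False
            # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
            for c, a2 in g.directed:
                if a2 == a and not g.is_adjacent(c, b):
                    oriented = True
                    break
            # R2: a -> c -> b and a - b  =>  a -> b
            if not oriented:
                for a2, c in g.directed:
                    if a2 == a and (c, b) in g.directed:
                        oriented = True
                        break
            # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
            if not oriented:
                und_nbrs = [next(iter(p - {a})) for p in g.undirected if a in p]
                into_b = [c for c in und_nbrs if (c, b) in g.directed]
                for c, d in combinations(sorted(into_b), 2):
                    if not g.is_adjacent(c, d):
                        oriented = True
                        break
            # R4: a - c (or a -> c), c -> d -> b, c and b non-adjacent => a -> b
            if not oriented:
                for c, d in g.directed:
                    if (d, b) in g.directed and not g.is_adjacent(c, b) and (
                        frozenset((a, c)) in g.undirected or (a, c) in g.directed
                    ):
                        oriented = True
                        break
            if oriented:
                if _reaches(g.directed, b, a):
                    logger.info("Meek orientation %s -> %s would create a cycle; "
                                "kept undirected", a, b)
                    continue
                g.undirected.discard(frozenset((a, b)))
                g.directed.add((a, b))
                changed = True
                break
    return changed


def meek_closure(pdag: Cpdag) -> Cpdag:
    """Apply Meek rules R1-R4 to a fixed point (idempotent)."""
    g = pdag.copy()
    while _meek_pass(g):
        pass
    g.validate()
    return g


def run_pc(table: CohortTable, alpha: float) -> Cpdag:
    """Full PC: stable skeleton, v-structure orientation, Meek closure."""
    skel, seps = pc_skeleton(table, alpha)
    return meek_closure(orient_v_structures(skel, seps))


# ---------------------------------------------------------------------------
# exact graph oracles (testing aids, independent of any data)
# ---------------------------------------------------------------------------

def d_separated(dag: Dag, x: str, y: str, S: Iterable[str]) -> bool:
    """Exact d-separation of x and y given S in a DAG.

    Implemented by reachability on the moralized ancestral subgraph:
    restrict to ancestors of {x, y} | S, marry co-parents, drop edge
    directions, delete S, and check whether x still reaches y.
    """
    S = set(S)
    known = set(dag.nodes)
    for node in {x, y} | S:
        if node not in known:
            raise ValidationError(f"unknown node {node!r}")
    if x == y or x in S or y in S:
        raise ValidationError("x, y must be distinct and outside S")
    relevant = {x, y} | S
    anc = set(relevant)
    for node in relevant:
        anc |= dag.ancestors(node)
    moral: dict[str, set[str]] = {n: set() for n in anc}
    sub_edges = [(a, b) for a, b in dag.edges if a in anc and b in anc]
    for a, b in sub_edges:
        moral[a].add(b)
        moral[b].add(a)
    children: dict[str, list[str]] = {n: [] for n in anc}
    for a, b in sub_edges:
        children[b].append(a)
    for b, parents in children.items():
        for p, q in combinations(parents, 2):
            moral[p].add(q)
            moral[q].add(p)
    # BFS from x avoiding S
    seen = {x}
    stack = [x]
    while stack:
        cur = stack.pop()
        for nxt in moral[cur]:
            if nxt in S or nxt in seen:
                continue
            if nxt == y:
                return False
            seen.add(nxt)
            stack.append(nxt)
    return True


def cpdag_of(dag: Dag) -> Cpdag:
    """Exact CPDAG of a DAG: skeleton + v-structures, then Meek closure."""
    directed: set[tuple[str, str]] = set()
    for z in dag.nodes:
        for x, y in combinations(sorted(dag.parents(z)), 2):
            if not dag.is_adjacent(x, y):
                directed.add((x, z))
                directed.add((y, z))
    und = {frozenset(e) for e in dag.edges} - {frozenset(e) for e in directed}
    return meek_closure(Cpdag(dag.nodes, und, directed))


def oracle_pc(dag: Dag) -> Cpdag:
    """PC with the CI test replaced by exact d-separation.

    On any DAG this must coincide with :func:`cpdag_of`; the identity is
    the central correctness check for the PC machinery.
    """
    names = dag.nodes

    def indep(x: int, y: int, S: tuple[int, ...]) -> bool:
        return d_separated(dag, names[x], names[y], {names[v] for v in S})

    skel, seps = _skeleton_core(names, indep)
    return meek_closure(orient_v_structures(skel, seps))
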