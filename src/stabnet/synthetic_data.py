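"""Ground-truth structural equation models and synthetic cohort generation.

The package's analysis target is a cohort whose participant-level data
are not publicly deposited, so everything is validated against simulated
cohorts with a *known* generating structure.  This module provides:

* :class:`Dag` / :class:`SemSpec` -- a labeled acyclic graph with linear
  edge weights, per-node Gaussian noise scales, and per-node observation
  transforms (identity, or ``exp`` for skewed cytokine-like marginals);
* :func:`simulate_cohort` -- ancestral sampling of the latent linear-
  Gaussian system plus roster-driven observation mapping (bounded ordinal
  questionnaire totals, thresholded binary/categorical variables) and
  MCAR/MAR missingness injection;
* :func:`paper_like_sem` -- a fixed-topology model over the default
  roster emulating the published cluster structure (outcomes centred on
  fatigue, inflammatory-marker paths CRP -> sCD14 and IL-1b -> IL-6 ->
  TNF-a, psychosocial paths, isolated sex and severity);
* :func:`make_retention_fixture` -- a 303-row cohort of which exactly 68
  rows lack all four outcomes, reproducing the study's retention
  arithmetic (235 retained, 77.6%).

Dependence is defined on the latent Gaussian scale: children regress on
their parents' *latent* values, and the observation mapping (exp,
rounding, clamping, thresholding) is applied afterwards per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort_model import CohortTable, RosterEntry, VariableRoster
from .errors import ValidationError

__all__ = [
    "Dag",
    "SemSpec",
    "MissingnessSpec",
    "default_roster",
    "paper_like_sem",
    "simulate_cohort",
    "make_retention_fixture",
    "implied_covariance",
    "standardize_noise",
    "random_dag",
    "random_sem",
    "chain_sem",
    "collider_sem",
    "MARKER_NAMES",
    "OUTCOME_NAMES",
]

OUTCOME_NAMES = (
    "fatigue",
    "concentration",
    "depressive_symptoms",
    "physical_functioning",
)

MARKER_NAMES = (
    "CRP", "sCD14", "sCD163", "TNFa", "IP10", "MCP1",
    "IL1b", "IL2", "IL6", "IL10", "IL13", "IL17A",
)


@dataclass(frozen=True)
class Dag:
    """Labeled directed acyclic graph."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node names")
        known = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in known or b not in known:
                raise ValidationError(f"edge ({a!r}, {b!r}) references unknown node")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(a for a in self.nodes if (a, node) in self.edges)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(b for b in self.nodes if (node, b) in self.edges)

    def topological_order(self) -> tuple[str, ...]:
        """Kahn's algorithm with node-order tie-breaking (deterministic)."""
        indeg = {n: 0 for n in self.nodes}
        for _, b in self.edges:
            indeg[b] += 1
        placed: set[str] = set()
        order: list[str] = []
        while len(order) < len(self.nodes):
            # first node (in declaration order) with no unplaced parents
            nxt = next((n for n in self.nodes if n not in placed and indeg[n] == 0), None)
            if nxt is None:
                raise ValidationError("graph contains a directed cycle")
            order.append(nxt)
            placed.add(nxt)
            for c in self.children(nxt):
                indeg[c] -= 1
        return tuple(order)

    def ancestors(self, node: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents(node))
        while stack:
            a = stack.pop()
            if a not in out:
                out.add(a)
                stack.extend(self.parents(a))
        return out

    def is_adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges


@dataclass(frozen=True)
class MissingnessSpec:
    """Missingness mechanism injected by the simulator.

    ``MCAR`` blanks eligible cells independently at ``rate``; ``MAR``
    makes the per-row missingness probability increase with the (latent,
    standardized) value of ``driver`` through a logistic link with the
    given ``slope``.  Covariate columns and the driver itself are never
    blanked, so the mechanism stays missing-at-random given observed data.
    """

    mechanism: str = "MCAR"
    rate: float = 0.1
    driver: str | None = None
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate < 1.0:
            raise ValidationError("rate must lie in [0, 1)")
        if self.mechanism == "MAR" and not self.driver:
            raise ValidationError("MAR requires a driver variable")


@dataclass(frozen=True)
class SemSpec:
    """Linear-Gaussian SEM: weighted DAG + noise scales + observation hints.

    ``transform`` maps a node to ``"identity"`` or ``"exp"`` (log-normal
    marginal); ``cutpoints`` gives cumulative probabilities at which a
    latent is cut into integer levels for binary/categorical nodes.
    """

    dag: Dag
    weights: Mapping[tuple[str, str], float]
    noise_scale: Mapping[str, float]
    transform: Mapping[str, str] = field(default_factory=dict)
    cutpoints: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        object.__setattr__(self, "noise_scale", dict(self.noise_scale))
        object.__setattr__(self, "transform", dict(self.transform))
        object.__setattr__(self, "cutpoints",
                           {k: tuple(v) for k, v in dict(self.cutpoints).items()})
        if set(self.weights) != set(self.dag.edges):
            raise ValidationError("weights must be defined exactly on dag.edges")
        if set(self.noise_scale) != set(self.dag.nodes):
            raise ValidationError("noise_scale must be defined exactly on dag.nodes")
        for node, s in self.noise_scale.items():
            if not s > 0:
                raise ValidationError(f"noise scale for {node!r} must be positive")
        for node, t in self.transform.items():
            if t not in ("identity", "exp"):
                raise ValidationError(f"unknown transform {t!r} for {node!r}")


def standardize_noise(
    dag: Dag, weights: Mapping[tuple[str, str], float], floor: float = 0.1
) -> dict[str, float]:
    """Noise scales giving each latent unit variance (when attainable).

    Walking the DAG in topological order, the implied covariance among
    already-processed nodes is accumulated and each node's noise variance
    is set to ``1 - Var(weighted parent sum)``, floored at ``floor`` so
    heavily-loaded nodes stay well-defined (their variance then slightly
    exceeds one).
    """
    order = dag.topological_order()
    pos = {n: i for i, n in enumerate(order)}
    k = len(order)
    cov = np.zeros((k, k))
    noise: dict[str, float] = {}
    for n in order:
        i = pos[n]
        ps = dag.parents(n)
        if ps:
            pidx = [pos[p] for p in ps]
            w = np.array([weights[(p, n)] for p in ps])
            q = float(w @ cov[np.ix_(pidx, pidx)] @ w)
            cross = cov[:, pidx] @ w  # cov(n, earlier nodes)
        else:
            q = 0.0
            cross = np.zeros(k)
        nv = max(1.0 - q, floor)
        cov[i, :] = cross
        cov[:, i] = cross
        cov[i, i] = q + nv
        noise[n] = float(np.sqrt(nv))
    return noise


def implied_covariance(sem: SemSpec) -> tuple[tuple[str, ...], np.ndarray]:
    """Closed-form latent covariance (I - W')^-1 D (I - W')^-T."""
    nodes = sem.dag.nodes
    k = len(nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((k, k))
    for (a, b), w in sem.weights.items():
        W[pos[a], pos[b]] = w
    D = np.diag([sem.noise_scale[n] ** 2 for n in nodes])
    M = np.linalg.inv(np.eye(k) - W.T)
    return nodes, M @ D @ M.T


def _standardized(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def _observe(entry: RosterEntry, latent: np.ndarray, sem: SemSpec) -> np.ndarray:
    """Map a latent column to its observed scale, per roster metadata."""
    name = entry.name
    if sem.transform.get(name) == "exp":
        obs = np.exp(latent)
        if entry.bounds is not None:
            obs = np.clip(obs, *entry.bounds)
        return obs
    cuts = sem.cutpoints.get(name)
    if cuts is None and entry.scale in ("binary", "categorical"):
        # equiprobable levels by default
        if entry.levels is not None:
            n_levels = len(entry.levels)
        elif entry.scale == "binary":
            n_levels = 2
        elif entry.bounds is not None:
            n_levels = int(round(entry.bounds[1] - entry.bounds[0])) + 1
        else:
            n_levels = 2
        cuts = tuple((i + 1) / n_levels for i in range(n_levels - 1))
    if cuts is not None:
        z = _standardized(latent)
        thresholds = norm.ppf(np.asarray(cuts))
        return np.searchsorted(thresholds, z, side="right").astype(float)
    if entry.bounds is not None:
        lo, hi = entry.bounds
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        z = _standardized(latent)
        obs = mid + z * half / 3.0  # +/- 3 sd spans the instrument range
        if entry.scale == "ordinal":
            obs = np.round(obs)
        return np.clip(obs, lo, hi)
    return latent


def simulate_cohort(
    sem: SemSpec,
    roster: VariableRoster,
    n: int,
    seed: int,
    missing: MissingnessSpec | None = None,
) -> CohortTable:
    """Ancestral sampling of a SEM into a roster-shaped cohort table.

    Roster columns absent from the SEM are independent standard normal
    latents.  Missingness (if requested) is injected into outcome and
    putative columns only; baseline covariates stay complete, mirroring
    registry-style cohorts where attrition hits follow-up questionnaires.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    missing_nodes = set(sem.dag.nodes) - set(roster.names)
    if missing_nodes:
        raise ValidationError(f"roster lacks SEM nodes {sorted(missing_nodes)}")
    rng = np.random.default_rng(seed)
    latents: dict[str, np.ndarray] = {}
    for node in sem.dag.topological_order():
        eps = rng.normal(0.0, sem.noise_scale[node], size=n)
        total = eps
        for p in sem.dag.parents(node):
            total = total + sem.weights[(p, node)] * latents[p]
        latents[node] = total
    for name in roster.names:
        if name not in latents:
            latents[name] = rng.normal(0.0, 1.0, size=n)

    values = np.column_stack([_observe(e, latents[e.name], sem) for e in roster])

    if missing is not None and missing.rate > 0:
        if missing.mechanism == "MAR":
            if missing.driver not in roster:
                raise ValidationError(f"MAR driver {missing.driver!r} not in roster")
            drive = _standardized(latents[missing.driver])
            p_row = expit(logit(missing.rate) + missing.slope * drive)
        else:
            p_row = np.full(n, missing.rate)
        for j, e in enumerate(roster):
            if e.role == "covariate" or e.name == missing.driver:
                continue
            blank = rng.random(n) < p_row
            values[blank, j] = np.nan

    ids = tuple(f"P{i:04d}" for i in range(1, n + 1))
    return CohortTable(values=values, roster=roster, participant_ids=ids)


# ---------------------------------------------------------------------------
# default roster and the study-like fixed-topology SEM
# ---------------------------------------------------------------------------

def default_roster() -> VariableRoster:
    """Roster of the emulated cohort: 4 outcomes, 22+4 putative columns
    (five CERQ subscales prior to factor combination), 6 baseline covariates.

    Months and score ranges follow the instruments' published layouts
    (CIS fatigue 8-56, CIS concentration 5-35, PHQ-9 0-27, SF-36 physical
    functioning 0-100, B-IPQ 0-80, BRS 1-5, CBRSQ subscales, CERQ
    subscales 2-10, DJGLS 0-6, NLE count 0-9).
    """
    e = RosterEntry
    entries = [
        # outcomes, month 24
        e("fatigue", "outcome", "ordinal", 24, (8, 56)),
        e("concentration", "outcome", "ordinal", 24, (5, 35)),
        e("depressive_symptoms", "outcome", "ordinal", 24, (0, 27)),
        e("physical_functioning", "outcome", "ordinal", 24, (0, 100)),
        # inflammatory markers, month 3 (skewed, unbounded above)
        *[e(m, "putative", "continuous", 3) for m in MARKER_NAMES],
        # psychological / social scales
        e("illness_perceptions", "putative", "ordinal", 12, (0, 80)),
        e("resilience", "putative", "continuous", 6, (1, 5)),
        e("fear_avoidance", "putative", "ordinal", 3, (0, 24)),
        e("damage_beliefs", "putative", "ordinal", 3, (0, 20)),
        e("all_or_nothing", "putative", "ordinal", 3, (0, 20)),
        e("cerq_acceptance", "putative", "ordinal", 6, (2, 10), "CERQ"),
        e("cerq_positive_refocusing", "putative", "ordinal", 6, (2, 10), "CERQ"),
        e("cerq_refocus_planning", "putative", "ordinal", 6, (2, 10), "CERQ"),
        e("cerq_positive_reappraisal", "putative", "ordinal", 6, (2, 10), "CERQ"),
        e("cerq_perspective", "putative", "ordinal", 6, (2, 10), "CERQ"),
        e("loneliness", "putative", "ordinal", 3, (0, 6)),
        e("negative_life_events", "putative", "ordinal", 1, (0, 9)),
        e("severity", "putative", "ordinal", 0, (0, 3),
          levels=("mild", "moderate", "severe", "critical")),
        e("sex", "putative", "binary", 0, (0, 1), levels=("male", "female")),
        # baseline covariates
        e("age", "covariate", "continuous", 0, (16, 85)),
        e("bmi", "covariate", "continuous", 0, (15, 45)),
        e("smoking", "covariate", "categorical", 0,
          levels=("never", "ex", "current")),
        e("migration_background", "covariate", "categorical", 0,
          levels=("dutch", "other_hic", "lmic")),
        e("education", "covariate", "ordinal", 0, (0, 3),
          levels=("none", "school", "vocational", "university")),
        e("comorbidities", "covariate", "ordinal", 0, (0, 2)),
    ]
    return VariableRoster(tuple(entries))


#: fixed ground-truth topology (parent, child, sign); magnitudes come from the seed
_PAPER_EDGES: tuple[tuple[str, str, float], ...] = (
    # outcome cluster centred on fatigue
    ("depressive_symptoms", "fatigue", +1),
    ("fatigue", "concentration", +1),
    ("fatigue", "physical_functioning", -1),
    # direct psychosocial paths into the outcomes
    ("loneliness", "depressive_symptoms", +1),
    ("illness_perceptions", "concentration", +1),
    ("fear_avoidance", "physical_functioning", -1),
    ("resilience", "loneliness", -1),
    ("all_or_nothing", "illness_perceptions", +1),
    # inflammatory-marker cluster
    ("CRP", "sCD14", +1),
    ("IL1b", "IL6", +1),
    ("IL6", "TNFa", +1),
    ("IL6", "IL10", +1),
    ("IP10", "MCP1", +1),
    ("IL2", "IL13", +1),
    ("IL13", "IL17A", +1),
    ("sCD163", "CRP", +1),
    # markers touch the psychosocial side only through negative life events
    ("IP10", "negative_life_events", -1),
    # coping subscales share the resilience signal (combined by factor analysis)
    ("resilience", "cerq_acceptance", +1),
    ("resilience", "cerq_positive_refocusing", +1),
    ("resilience", "cerq_refocus_planning", +1),
    ("resilience", "cerq_positive_reappraisal", +1),
    ("resilience", "cerq_perspective", +1),
    # baseline covariates feed several network variables (adjusted away later)
    ("age", "physical_functioning", -1),
    ("age", "CRP", +1),
    ("bmi", "CRP", +1),
    ("bmi", "IL6", +1),
    ("smoking", "IL6", +1),
    ("education", "illness_perceptions", -1),
    ("comorbidities", "fatigue", +1),
    ("migration_background", "loneliness", +1),
)


def paper_like_sem(seed: int) -> tuple[SemSpec, VariableRoster]:
    """Fixed-topology SEM emulating the published cluster structure.

    The topology never varies with the seed; only the edge-weight
    magnitudes do, drawn uniformly from |w| in [0.3, 0.6] on standardized
    latent scales.  ``sex`` and ``severity`` are present but isolated.
    """
    roster = default_roster()
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.3, 0.6, size=len(_PAPER_EDGES))
    weights = {(a, b): float(s * m) for (a, b, s), m in zip(_PAPER_EDGES, mags)}
    dag = Dag(roster.names, frozenset(weights))
    noise = standardize_noise(dag, weights)
    transform = {m: "exp" for m in MARKER_NAMES}
    cutpoints = {
        "sex": (0.5,),
        "severity": (0.55, 0.80, 0.92),
        "smoking": (0.55, 0.80),
        "migration_background": (0.65, 0.85),
        "education": (0.05, 0.40, 0.70),
        "comorbidities": (0.60, 0.85),
    }
    return SemSpec(dag, weights, noise, transform, cutpoints), roster


def paper_like_missingness() -> MissingnessSpec:
    """Default attrition model: MAR at 5% driven by depressive symptoms."""
    return MissingnessSpec("MAR", 0.05, "depressive_symptoms", 1.0)


def make_retention_fixture(seed: int) -> CohortTable:
    """Cohort of 303 rows of which exactly 68 lack all four outcomes.

    Emulates loss to follow-up at the month-24 visit: a complete-case
    filter on the outcomes retains exactly 235 participants (77.6%).
    Putative columns additionally carry light MCAR missingness so the
    imputation stage has work to do on the retained rows.
    """
    sem, roster = paper_like_sem(seed)
    seeds = np.random.SeedSequence([int(seed) % (2**31), 7]).generate_state(2)
    table = simulate_cohort(sem, roster, 303, int(seeds[0]), missing=None)
    rng = np.random.default_rng(int(seeds[1]))
    values = table.values.copy()
    out_idx = [roster.index(v) for v in OUTCOME_NAMES]
    lost = rng.choice(303, size=68, replace=False)
    values[np.ix_(lost, out_idx)] = np.nan
    putative_idx = [j for j, e in enumerate(roster)
                    if e.role == "putative" and e.name not in ("sex", "severity")]
    blank = rng.random((303, len(putative_idx))) < 0.03
    for k, j in enumerate(putative_idx):
        values[blank[:, k], j] = np.nan
    return table.with_values(values)


# ---------------------------------------------------------------------------
# small fixtures and random SEMs for tests and calibration studies
# ---------------------------------------------------------------------------

def _plain_roster(names: Sequence[str]) -> VariableRoster:
    return VariableRoster(tuple(
        RosterEntry(n, "putative", "continuous", 0) for n in names
    ))


def chain_sem() -> tuple[SemSpec, VariableRoster]:
    """X -> Y -> Z with standardized weights 0.8 (corr(X, Z) = 0.64)."""
    dag = Dag(("X", "Y", "Z"), frozenset({("X", "Y"), ("Y", "Z")}))
    weights = {("X", "Y"): 0.8, ("Y", "Z"): 0.8}
    return SemSpec(dag, weights, standardize_noise(dag, weights)), _plain_roster("XYZ")


def collider_sem(weight: float = 0.6) -> tuple[SemSpec, VariableRoster]:
    """A -> C <- B: the one 3-node structure PC can fully orient."""
    dag = Dag(("A", "B", "C"), frozenset({("A", "C"), ("B", "C")}))
    weights = {("A", "C"): weight, ("B", "C"): weight}
    return SemSpec(dag, weights, standardize_noise(dag, weights)), _plain_roster("ABC")


def random_dag(n_nodes: int, edge_prob: float, seed: int) -> Dag:
    """Erdos-Renyi DAG: random topological order, independent edges."""
    rng = np.random.default_rng(seed)
    names = tuple(f"X{i:02d}" for i in range(1, n_nodes + 1))
    order = rng.permutation(n_nodes)
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.add((names[order[i]], names[order[j]]))
    return Dag(names, frozenset(edges))


def random_sem(
    dag: Dag,
    seed: int,
    weight_range: tuple[float, float] = (0.4, 0.8),
    negative_fraction: float = 0.0,
) -> SemSpec:
    """Random weights of given magnitude on a DAG, noise standardized."""
    rng = np.random.default_rng(seed)
    lo, hi = weight_range
    weights = {}
    for e in sorted(dag.edges):
        w = float(rng.uniform(lo, hi))
        if rng.random() < negative_fraction:
            w = -w
        weights[e] = w
    return SemSpec(dag, weights, standardize_noise(dag, weights))


def sem_roster(sem: SemSpec) -> VariableRoster:
    """Continuous putative roster matching a SEM's node set."""
    return _plain_roster(sem.dag.nodes)


def truth_edges_tsv(sem: SemSpec) -> str:
    """Ground-truth edge list as TSV text (parent, child, weight)."""
    lines = ["parent\tchild\tweight"]
    for (a, b) in sorted(sem.dag.edges):
        lines.append(f"{a}\t{b}\t{sem.weights[(a, b)]!r}")
    return "\n".join(lines) + "\n"
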