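"""Bootstrap edge-stability aggregation over repeated PC runs.

The headline procedure: draw B bootstrap replicates of the cohort, push
each through impute -> factor-combine -> covariate-adjust -> PC, count
for every variable pair the fraction of replicate CPDAGs in which it is
adjacent (irrespective of direction), retain pairs at or above the
stability threshold (default 0.5, a majority decision), grade them
low / moderate / high, attach correlation signs from one completed copy
of the full data, and separately count per-direction orientation
frequencies to flag "causal" links at the same threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._version import __version__
from .cohort_model import CohortTable, VariableRoster
from .causal_graph import Cpdag, run_pc
from .errors import ConfigError, PipelineError, StabnetError
from .preprocess import (
    ImputeConfig,
    apply_factor,
    bootstrap_resample,
    fit_factor,
    mice_impute,
    residualize,
)

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("low", "moderate", "high")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the bootstrap-stability run.

    ``B`` bootstrap replicates (the published analysis used 500);
    ``threshold`` is both the adjacency-retention and the orientation
    threshold (0.5 = majority); ``alpha`` is the Fisher-z level inside
    PC; ``covariates=None`` means "all covariate-role columns in the
    roster".  Factor groups absent from a roster are skipped with a
    warning so one default configuration serves plain fixtures too.
    """

    B: int = 500
    threshold: float = 0.5
    alpha: float = 0.05
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    factor_groups: tuple[str, ...] = ("CERQ",)
    covariates: tuple[str, ...] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_groups", tuple(self.factor_groups))
        if self.covariates is not None:
            object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigError("threshold must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factor_groups"] = list(self.factor_groups)
        d["covariates"] = list(self.covariates) if self.covariates is not None else None
        return d


@dataclass
class StabilityNetwork:
    """Final artifact of a bootstrap-stability run."""

    nodes: tuple[str, ...]
    adjacency_freq: dict[frozenset, float]
    retained: set[frozenset]
    category: dict[frozenset, str]
    sign: dict[frozenset, str]
    orientation_freq: dict[tuple[str, str], float]
    causal: set[tuple[str, str]]
    B: int
    n_failed: int
    config: PipelineConfig
    replicate_edge_counts: tuple[int, ...] = ()
    failures: tuple[str, ...] = ()


def classify_stability(freq: float, threshold: float) -> str:
    """Grade a bootstrap frequency: excluded / low / moderate / high.

    Below the retention threshold a link is excluded; up to 80% it has
    low stability, up to 97% moderate, above 97% high.
    """
    if not 0.0 <= freq <= 1.0:
        raise ConfigError(f"frequency {freq} outside [0, 1]")
    if freq < threshold:
        return "excluded"
    if freq <= 0.80:
        return "low"
    if freq <= 0.97:
        return "moderate"
    return "high"


def _replicate_seeds(master_seed: int, index: int) -> tuple[int, int]:
    """Independent (resample, impute) seeds for one replicate, hashed
    from the master seed and the replicate index."""
    ss = np.random.SeedSequence([int(master_seed) % (2**31), int(index)])
    s1, s2 = ss.generate_state(2)
    return int(s1) % (2**31), int(s2) % (2**31)


def resolve_covariates(roster: VariableRoster, config: PipelineConfig) -> tuple[str, ...]:
    if config.covariates is not None:
        return config.covariates
    return roster.by_role("covariate")


def prepare_table(
    table: CohortTable,
    config: PipelineConfig,
    impute_seed: int,
    resample_seed: int | None = None,
) -> CohortTable:
    """One pass of the per-replicate preparation chain.

    With ``resample_seed=None`` the chain runs on the table as given
    (used for the sign matrix); otherwise it starts from a bootstrap
    resample.
    """
    t = table if resample_seed is None else bootstrap_resample(table, resample_seed)
    t = mice_impute(t, dataclasses.replace(config.impute, seed=impute_seed))
    for group in config.factor_groups:
        members = t.roster.group_members(group)
        if not members:
            logger.warning("factor group %r has no members in roster; skipped", group)
            continue
        model = fit_factor(t, group)
        t = apply_factor(t, model)
    return residualize(t, resolve_covariates(table.roster, config))


def network_node_names(roster: VariableRoster, config: PipelineConfig) -> tuple[str, ...]:
    """Node set of the final network implied by roster + config.

    Covariate-role columns are always dropped by residualization; group
    members collapse to one node named after the group.
    """
    grouped: list[str] = []
    names: list[str] = []
    for e in roster:
        if e.role == "covariate":
            continue
        if e.group in config.factor_groups and roster.group_members(e.group):
            if e.group not in grouped:
                grouped.append(e.group)
                names.append(e.group)
            continue
        names.append(e.name)
    return tuple(names)


def run_pipeline(table: CohortTable, config: PipelineConfig) -> StabilityNetwork:
    """B replicates of resample -> impute -> factor -> adjust -> PC,
    aggregated into per-pair adjacency and per-direction orientation
    frequencies.

    A replicate that raises a package error is logged and excluded from
    both numerator and denominator; the run aborts once failures exceed
    5% of B.
    """
    adj_counts: Counter = Counter()
    ori_counts: Counter = Counter()
    edge_counts: list[int] = []
    failures: list[str] = []
    max_failures = 0.05 * config.B
    for b in range(config.B):
        resample_seed, impute_seed = _replicate_seeds(config.master_seed, b)
        try:
            prepared = prepare_table(table, config, impute_seed, resample_seed)
            graph = run_pc(prepared, config.alpha)
        except StabnetError as exc:
            failures.append(f"replicate {b}: {exc}")
            logger.warning("replicate %d failed: %s", b, exc)
            if len(failures) > max_failures:
                raise PipelineError(
                    f"{len(failures)} of {b + 1} replicates failed "
                    f"(> 5% of B = {config.B}); last error: {exc}"
                ) from exc
            continue
        for pair in graph.skeleton_pairs():
            adj_counts[pair] += 1
        for edge in graph.directed:
            ori_counts[edge] += 1
        edge_counts.append(len(graph.skeleton_pairs()))
        logger.info("replicate %d: %d adjacent pairs", b, edge_counts[-1])
    n_ok = config.B - len(failures)
    if n_ok == 0:
        raise PipelineError("all replicates failed")
    adjacency_freq = {p: c / n_ok for p, c in adj_counts.items()}
    orientation_freq = {e: c / n_ok for e, c in ori_counts.items()}
    retained = {p for p, f in adjacency_freq.items() if f >= config.threshold}
    category = {p: classify_stability(adjacency_freq[p], config.threshold)
                for p in retained}
    causal = {e for e, f in orientation_freq.items()
              if f >= config.threshold and frozenset(e) in retained}
    nodes = network_node_names(table.roster, config)
    return StabilityNetwork(
        nodes=nodes,
        adjacency_freq=adjacency_freq,
        retained=retained,
        category=category,
        sign={},
        orientation_freq=orientation_freq,
        causal=causal,
        B=config.B,
        n_failed=len(failures),
        config=config,
        replicate_edge_counts=tuple(edge_counts),
        failures=tuple(failures),
    )


def assign_signs(
    network: StabilityNetwork, table: CohortTable, config: PipelineConfig
) -> StabilityNetwork:
    """Attach correlation signs to the retained links.

    Signs come from the Pearson correlation matrix of ONE completed and
    residualized copy of the full (non-bootstrapped) table, seeded by the
    master seed.  A link with exactly zero correlation is assigned
    positive with a logged warning.
    """
    prepared = prepare_table(table, config, impute_seed=config.master_seed)
    corr = np.corrcoef(prepared.values.T)
    idx = {n: i for i, n in enumerate(prepared.roster.names)}
    signs: dict[frozenset, str] = {}
    for pair in network.retained:
        a, b = sorted(pair)
        r = corr[idx[a], idx[b]]
        if r == 0.0:
            logger.warning("zero correlation for link %s-%s; sign set positive", a, b)
        signs[pair] = "positive" if r >= 0 else "negative"
    return dataclasses.replace(network, sign=signs)


def summarize(network: StabilityNetwork) -> dict:
    """Counts of retained links (overall and per category), causal links,
    and isolated nodes."""
    by_cat = {c: 0 for c in CATEGORY_ORDER}
    for c in network.category.values():
        by_cat[c] += 1
    linked = {n for p in network.retained for n in p}
    return {
        "n_stable_links": len(network.retained),
        "by_category": by_cat,
        "n_causal_links": len(network.causal),
        "causal_links": sorted(list(e) for e in network.causal),
        "isolated_nodes": sorted(set(network.nodes) - linked),
        "B": network.B,
        "n_failed_replicates": network.n_failed,
    }


# ---------------------------------------------------------------------------
# run-directory serialization
# ---------------------------------------------------------------------------

def edge_table_lines(network: StabilityNetwork) -> list[str]:
    """Deterministic TSV lines for the retained links."""
    header = ("source\ttarget\tkind\tadjacency_freq\tcategory\tsign"
              "\torientation_freq_ab\torientation_freq_ba")
    lines = [header]
    for pair in sorted(network.retained, key=sorted):
        a, b = sorted(pair)
        if (b, a) in network.causal and (a, b) not in network.causal:
            a, b = b, a
        kind = "directed" if (a, b) in network.causal else "undirected"
        lines.append("\t".join([
            a, b, kind,
            f"{network.adjacency_freq[pair]:.6f}",
            network.category[pair],
            network.sign.get(pair, ""),
            f"{network.orientation_freq.get((a, b), 0.0):.6f}",
            f"{network.orientation_freq.get((b, a), 0.0):.6f}",
        ]))
    return lines


def save_run(network: StabilityNetwork, out_dir: str | Path,
             provenance_extra: Mapping | None = None) -> None:
    """Write network_edges.tsv, network.graphml, summary.json,
    provenance.json and replicates.log into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "network_edges.tsv").write_text("\n".join(edge_table_lines(network)) + "\n")

    graph = Cpdag(
        network.nodes,
        undirected={p for p in network.retained
                    if not ({tuple(sorted(p)), tuple(sorted(p))[::-1]} & network.causal)},
        directed={e for e in network.causal},
    )
    graph.write_graphml(out / "network.graphml")

    (out / "summary.json").write_text(
        json.dumps(summarize(network), indent=2, sort_keys=True) + "\n"
    )
    provenance = {
        "tool": "stabnet",
        "version": __version__,
        "config": network.config.to_dict(),
        "B": network.B,
        "n_failed_replicates": network.n_failed,
        "replicate_edge_counts": list(network.replicate_edge_counts),
        "numpy_version": np.__version__,
    }
    if provenance_extra:
        provenance.update(dict(provenance_extra))
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    log_lines = [f"replicate {i}: {c} adjacent pairs"
                 for i, c in enumerate(network.replicate_edge_counts)]
    log_lines += list(network.failures)
    (out / "replicates.log").write_text("\n".join(log_lines) + "\n")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {"B", "threshold", "alpha", "impute", "factor_groups",
             "covariates", "master_seed"}
    extra = set(raw) - known
    if extra:
        raise ConfigError(f"unknown config keys {sorted(extra)}")
    impute_raw = raw.get("impute", {}) or {}
    if not isinstance(impute_raw, dict):
        raise ConfigError("impute must be a mapping")
    impute_known = {"iterations", "method", "donors", "seed"}
    impute_extra = set(impute_raw) - impute_known
    if impute_extra:
        raise ConfigError(f"unknown impute keys {sorted(impute_extra)}")
    try:
        impute = ImputeConfig(**impute_raw)
        return PipelineConfig(
            B=int(raw.get("B", 500)),
            threshold=float(raw.get("threshold", 0.5)),
            alpha=float(raw.get("alpha", 0.05)),
            impute=impute,
            factor_groups=tuple(raw.get("factor_groups", ("CERQ",))),
            covariates=tuple(raw["covariates"]) if raw.get("covariates") is not None
            else None,
            master_seed=int(raw.get("master_seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    except StabnetError:
        raise
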