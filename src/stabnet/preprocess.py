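"""Per-bootstrap preparation chain: resample, impute, factor-combine, adjust.

The order mirrors the analysis flowchart the pipeline implements:
bootstrap resampling sits outermost, chained-equation imputation runs
inside each replicate, related questionnaire subscales are collapsed to
a single maximum-likelihood factor score, and finally every analysis
variable is residualized on the baseline covariates (which are then
dropped from the table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.decomposition import FactorAnalysis

from .cohort_model import CohortTable, RosterEntry, VariableRoster
from .errors import (
    CollinearityError,
    FitError,
    IdentifiabilityError,
    NumericalError,
    SchemaError,
    UnimputableError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_HEYWOOD_EPS = 1e-6


@dataclass(frozen=True)
class ImputeConfig:
    """Chained-equations settings.

    ``pmm`` (predictive mean matching, the default) copies values from
    the ``donors`` observed rows whose regression predictions are nearest
    the missing cell's prediction, so bounded and integer-coded columns
    never receive out-of-range values.  ``normal`` draws from the linear
    model's residual distribution and is intended for continuous tables
    (imputed values are clipped into roster bounds when present).
    """

    iterations: int = 10
    method: str = "pmm"
    donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.donors < 1:
            raise ValidationError("donors must be >= 1")
        if self.method not in ("pmm", "normal"):
            raise ValidationError(f"unknown imputation method {self.method!r}")


@dataclass(frozen=True)
class FactorModel:
    """One-factor maximum-likelihood model over a subscale family."""

    member_names: tuple[str, ...]
    loadings: tuple[float, ...]
    uniquenesses: tuple[float, ...]
    score_method: str = "regression"
    group: str = ""
    month: int = 0


def bootstrap_resample(table: CohortTable, seed: int) -> CohortTable:
    """Draw n rows with replacement from the n input rows (seeded)."""
    n = table.n_rows
    if n == 0:
        raise ValidationError("cannot resample an empty table")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n)
    return table.with_values(
        table.values[idx],
        participant_ids=[table.participant_ids[i] for i in idx],
    )


def mice_impute(table: CohortTable, config: ImputeConfig) -> CohortTable:
    """Multiple imputation by chained equations, one completed dataset.

    Incomplete variables are visited in order of ascending missingness;
    each is regressed (least squares, with intercept) on all other
    columns of the current completed matrix.  Initial fill is a seeded
    random draw from each variable's observed values.  Observed cells are
    never altered.
    """
    mask = table.missing_mask
    if not mask.any():
        return table
    if table.n_cols < 2:
        raise ValidationError("imputation requires at least 2 columns")
    all_missing = [table.roster.names[j] for j in range(table.n_cols)
                   if mask[:, j].all()]
    if all_missing:
        raise UnimputableError(
            f"column(s) with no observed values: {all_missing}"
        )

    rng = np.random.default_rng(config.seed)
    vals = table.values.copy()
    n, p = vals.shape
    incomplete = [j for j in range(p) if mask[:, j].any()]
    # initial fill: random draws from the observed distribution
    for j in incomplete:
        obs = vals[~mask[:, j], j]
        miss = mask[:, j]
        vals[miss, j] = rng.choice(obs, size=int(miss.sum()), replace=True)
    # visit order: ascending missingness, ties by column index
    order = sorted(incomplete, key=lambda j: (int(mask[:, j].sum()), j))

    others = {j: [k for k in range(p) if k != j] for j in incomplete}
    for _ in range(config.iterations):
        for j in order:
            miss = mask[:, j]
            X = np.column_stack([np.ones(n), vals[:, others[j]]])
            beta, *_ = np.linalg.lstsq(X[~miss], vals[~miss, j], rcond=None)
            pred = X @ beta
            if config.method == "pmm":
                pred_obs = pred[~miss]
                pred_mis = pred[miss]
                obs_vals = vals[~miss, j]
                k = min(config.donors, obs_vals.size)
                dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
                nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = rng.integers(0, k, size=nearest.shape[0])
                vals[miss, j] = obs_vals[nearest[np.arange(len(pick)), pick]]
            else:
                resid = vals[~miss, j] - pred[~miss]
                sigma = resid.std(ddof=1) if resid.size > 1 else 0.0
                draw = pred[miss] + rng.normal(0.0, sigma, size=int(miss.sum()))
                bounds = table.roster.entries[j].bounds
                if bounds is not None:
                    draw = np.clip(draw, *bounds)
                vals[miss, j] = draw
    return table.with_values(vals)


def fit_factor(table: CohortTable, group: str) -> FactorModel:
    """One-factor maximum-likelihood fit on a subscale family.

    Members are standardized before fitting, so loadings are on the
    correlation metric (factanal-style).  Loadings are sign-normalized so
    their sum is non-negative.  A uniqueness collapsing to zero (Heywood
    case) is logged and clamped.
    """
    members = table.roster.group_members(group)
    if len(members) < 3:
        raise IdentifiabilityError(
            f"group {group!r} has {len(members)} members; a 1-factor model needs >= 3"
        )
    cols = [table.roster.index(m) for m in members]
    X = table.values[:, cols]
    if np.isnan(X).any():
        raise ValidationError(f"group {group!r} has missing values; impute first")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        flat = [m for m, s in zip(members, sd) if s == 0]
        raise FitError(f"constant member column(s) {flat} in group {group!r}")
    Z = (X - X.mean(axis=0)) / sd
    max_iter = 2000
    fa = FactorAnalysis(n_components=1, max_iter=max_iter, tol=1e-4,
                        svd_method="lapack")
    fa.fit(Z)
    if fa.n_iter_ >= max_iter:
        raise FitError(
            f"1-factor fit for group {group!r} did not converge in {max_iter} iterations"
        )
    loadings = fa.components_[0].astype(float)
    if loadings.sum() < 0:
        loadings = -loadings
    uniq = fa.noise_variance_.astype(float)
    if (uniq <= _HEYWOOD_EPS).any():
        heywood = [m for m, u in zip(members, uniq) if u <= _HEYWOOD_EPS]
        logger.warning("Heywood case in group %r: uniqueness ~ 0 for %s",
                       group, heywood)
        uniq = np.maximum(uniq, _HEYWOOD_EPS)
    month = table.roster[members[0]].month
    return FactorModel(
        member_names=tuple(members),
        loadings=tuple(loadings),
        uniquenesses=tuple(uniq),
        group=group,
        month=month,
    )


def apply_factor(table: CohortTable, model: FactorModel) -> CohortTable:
    """Replace the member columns by one regression-method factor score.

    For standardized members z with loadings L and uniquenesses Psi the
    regression (Thomson) score is  f = L' (L L' + diag(Psi))^-1 z ; it has
    mean zero and variance at most one (shrinkage toward the prior).
    The new column is named after the group and keeps the group tag.
    """
    missing = [m for m in model.member_names if m not in table.roster]
    if missing:
        raise SchemaError(f"member column(s) {missing} absent from table")
    cols = [table.roster.index(m) for m in model.member_names]
    X = table.values[:, cols]
    if np.isnan(X).any():
        raise ValidationError("factor members have missing values; impute first")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    L = np.asarray(model.loadings)
    psi = np.asarray(model.uniquenesses)
    sigma = np.outer(L, L) + np.diag(psi)
    w = np.linalg.solve(sigma, L)
    scores = Z @ w

    name = model.group or "+".join(model.member_names)
    first = min(cols)
    entry = RosterEntry(name=name, role="putative", scale="continuous",
                        month=model.month, group=model.group or None)
    keep = [j for j in range(table.n_cols) if j not in cols]
    new_entries: list[RosterEntry] = []
    new_cols: list[np.ndarray] = []
    inserted = False
    for j in keep:
        if j > first and not inserted:
            new_entries.append(entry)
            new_cols.append(scores)
            inserted = True
        new_entries.append(table.roster.entries[j])
        new_cols.append(table.values[:, j])
    if not inserted:
        new_entries.append(entry)
        new_cols.append(scores)
    return CohortTable(
        values=np.column_stack(new_cols),
        roster=VariableRoster(tuple(new_entries)),
        participant_ids=table.participant_ids,
    )


def _covariate_design(table: CohortTable, covariate_names: Sequence[str]
                      ) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate contrast matrix (categoricals -> indicators)."""
    n = table.n_rows
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for name in covariate_names:
        entry = table.roster[name]
        x = table.column(name)
        if np.isnan(x).any():
            raise ValidationError(f"covariate {name!r} has missing values; impute first")
        if entry.scale == "categorical":
            levels = np.unique(x)
            for lv in levels[1:]:  # reference = first observed level
                cols.append((x == lv).astype(float))
                names.append(f"{name}=={lv:g}")
        else:
            cols.append(x)
            names.append(name)
    return np.column_stack(cols), names


def residualize(table: CohortTable, covariate_names: Sequence[str]) -> CohortTable:
    """Replace each analysis column by its standardized covariate residual.

    Every outcome/putative column is regressed on an intercept plus the
    covariate contrasts; the residual, scaled to unit variance, replaces
    it.  Covariate columns are dropped from the output, and roster bounds
    are cleared (residuals live on an unbounded standardized scale).
    """
    for name in covariate_names:
        if table.roster[name].role != "covariate":
            raise SchemaError(f"{name!r} does not have the covariate role")
    X, design_names = _covariate_design(table, covariate_names)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dependent = [design_names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise CollinearityError(
            f"rank-deficient covariate design; dependent columns: {dependent}"
        )
    keep = [j for j, e in enumerate(table.roster) if e.role != "covariate"]
    if np.isnan(table.values[:, keep]).any():
        raise ValidationError("table has missing values; impute first")
    Y = table.values[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    flat = [table.roster.entries[keep[k]].name for k in range(len(keep)) if sd[k] == 0]
    if flat:
        raise NumericalError(f"zero residual variance for {flat}")
    resid = resid / sd
    entries = tuple(
        replace(table.roster.entries[j], bounds=None, scale="continuous")
        for j in keep
    )
    return CohortTable(
        values=resid,
        roster=VariableRoster(entries),
        participant_ids=table.participant_ids,
    )
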