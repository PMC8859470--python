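"""Factorial sweeps and regression-tree / random-forest importance analysis.

The designer expands Cartesian parameter grids into replicated design points
with deterministic per-point seeds, the sweeps measure structural
(spectral radius, diameter) or dynamical (mean infections per horizon)
outputs, and the importance fits attribute the measured output to the swept
parameters via normalized impurity decrease.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor, export_text

from .graph_model import MPSNParams, PathwayLabel, assemble, validate_params
from .spread_sim import InfectivitySchedule, SpreadParams, run_ensemble
from .structure import diameter, layer_adjacency, spectral_radius, union_adjacency

__all__ = [
    "DesignPoint",
    "ImportanceResult",
    "factorial_design",
    "structural_sweep",
    "dynamics_sweep",
    "fit_importance",
    "robustness_scan",
    "TABLE1_GRIDS",
    "TABLE3_NETWORK_GRIDS",
    "TABLE3_SPREAD_GRID",
]

# Published experiment grids (64 x 64 lattice).
TABLE1_GRIDS = {
    "n": [4096],
    "k": [4, 16, 64],
    "r": [1, 1.5, 2, 2.5, 3, 3.5, 4],
    "s": [4, 16, 64],
    "template": ["complete", "star"],
    "epsilon": [0.1, 0.5, 1, 5, 10],
}

TABLE3_NETWORK_GRIDS = {
    "n": [4096],
    "k": [16],
    "r": [1, 2, 3],
    "s": [4, 16],
    "template": ["complete"],
    "epsilon": [0.1, 1, 10],
}

TABLE3_SPREAD_GRID = {
    "alpha_s": [0, 0.001, 0.005, 0.01, 0.015],
    "alpha_l": [0, 0.001, 0.005, 0.01, 0.015],
    "alpha_ld": [0, 0.001, 0.005, 0.01, 0.015],
    "horizons": (6, 12, 18, 24),
}


@dataclass(frozen=True)
class DesignPoint:
    """One valid parameter combination plus replicate index and derived seed."""

    n: int
    k: int
    r: float
    s: int
    template: str
    epsilon: float
    replicate: int
    rng_seed: int

    def to_params(self) -> MPSNParams:
        return MPSNParams(
            n=self.n,
            r=self.r,
            k=self.k,
            s=self.s,
            template_kind=self.template,
            epsilon=self.epsilon,
            rng_seed=self.rng_seed,
        )


def _point_seed(master_seed: int, point_index: int, replicate: int) -> int:
    return int(np.random.SeedSequence([master_seed, point_index, replicate]).generate_state(1)[0])


def factorial_design(
    grids: dict,
    n_replicates: int = 10,
    master_seed: int = 0,
) -> list[DesignPoint]:
    """Cartesian product of the grids, validity-filtered, replicated, seeded.

    The design is a deterministic function of ``(grids, n_replicates,
    master_seed)`` including every per-point seed.
    """
    keys = ("n", "k", "r", "s", "template", "epsilon")
    values = [grids[key] for key in keys]
    points: list[DesignPoint] = []
    index = 0
    for combo in itertools.product(*values):
        n, k, r, s, template, epsilon = combo
        p = MPSNParams(n=n, r=r, k=k, s=s, template_kind=template, epsilon=epsilon)
        if not validate_params(p).valid:
            continue
        for rep in range(n_replicates):
            points.append(
                DesignPoint(
                    n=n,
                    k=k,
                    r=r,
                    s=s,
                    template=template,
                    epsilon=epsilon,
                    replicate=rep,
                    rng_seed=_point_seed(master_seed, index, rep),
                )
            )
        index += 1
    if not points:
        raise ValueError("no valid design points after filtering")
    return points


def structural_sweep(design: list[DesignPoint], ld_variant: str = "definitional") -> pd.DataFrame:
    """Spectral radius (union + layers) and diameter for every design point.

    Per-point failures are recorded in the ``error`` column and the sweep
    continues.
    """
    rows = []
    for point in design:
        row = asdict(point)
        try:
            g = assemble(point.to_params(), ld_variant=ld_variant)
            row["lambda1"] = spectral_radius(union_adjacency(g))
            row["lambda1_s"] = spectral_radius(layer_adjacency(g, PathwayLabel.S))
            row["lambda1_l"] = spectral_radius(layer_adjacency(g, PathwayLabel.L))
            row["lambda1_ld"] = spectral_radius(layer_adjacency(g, PathwayLabel.LD))
            row["diam"] = diameter(g).value
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - sweep must be resumable
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def dynamics_sweep(
    design: list[DesignPoint],
    spread_grid: dict | None = None,
    n_runs: int = 100,
    ld_variant: str = "definitional",
    schedule: InfectivitySchedule | None = None,
    seed_fraction: float = 0.05,
    latency: int = 0,
) -> pd.DataFrame:
    """Mean infections per horizon for every (network point, alpha combination).

    One output row per (design point, alpha triple, horizon); the ensemble
    mean over ``n_runs`` runs is the observed variable.
    """
    spread_grid = spread_grid or TABLE3_SPREAD_GRID
    horizons = tuple(spread_grid.get("horizons", (6, 12, 18, 24)))
    alpha_combos = list(
        itertools.product(spread_grid["alpha_s"], spread_grid["alpha_l"], spread_grid["alpha_ld"])
    )
    rows = []
    for point in design:
        base = asdict(point)
        try:
            g = assemble(point.to_params(), ld_variant=ld_variant)
        except Exception as exc:  # noqa: BLE001
            base["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(base)
            continue
        for a_s, a_l, a_ld in alpha_combos:
            params = SpreadParams(
                alpha_s=a_s,
                alpha_l=a_l,
                alpha_ld=a_ld,
                latency=latency,
                seed_fraction=seed_fraction,
                horizons=horizons,
                rng_seed=point.rng_seed,
            )
            summary = run_ensemble(g, params, schedule, n_runs=n_runs)
            for horizon, mean in zip(summary.horizons, summary.means):
                rows.append(
                    {
                        **base,
                        "alpha_s": a_s,
                        "alpha_l": a_l,
                        "alpha_ld": a_ld,
                        "T": horizon,
                        "mean_infected": float(mean),
                        "error": "",
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class ImportanceResult:
    """Normalized impurity importances of design parameters for one target."""

    method: str
    target: str
    hyperparams: dict
    importances: dict[str, float]
    ranks: dict[str, int]  # 1 = most important
    tree_text: str | None = None
    degenerate: bool = False

    def top(self, m: int = 1) -> set[str]:
        return {f for f, rank in self.ranks.items() if rank <= m}


def _encode_features(df: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    x = df[features].copy()
    categorical = [c for c in x.columns if x[c].dtype == object]
    if categorical:
        x = pd.get_dummies(x, columns=categorical)
    return x.astype(float)


def fit_importance(
    df: pd.DataFrame,
    features: list[str],
    target: str,
    method: str = "random_forest",
    rng_seed: int = 0,
    **hyperparams,
) -> ImportanceResult:
    """Fit a regression tree or forest and report normalized importances.

    A constant target yields a flagged degenerate result with all-zero
    importances rather than an exception.
    """
    if len(df) < 20:
        raise ValueError("need at least 20 rows to fit an importance model")
    x = _encode_features(df, features)
    y = df[target].to_numpy(dtype=float)
    # canonical row order: bootstrap draws then depend only on content, not
    # on the order rows arrived in
    order = np.lexsort(tuple(x[c].to_numpy() for c in x.columns) + (y,))
    x = x.iloc[order].reset_index(drop=True)
    y = y[order]

    if np.ptp(y) == 0:
        importances = {c: 0.0 for c in x.columns}
        ranks = {c: i + 1 for i, c in enumerate(x.columns)}
        return ImportanceResult(
            method=method,
            target=target,
            hyperparams=dict(hyperparams),
            importances=importances,
            ranks=ranks,
            degenerate=True,
        )

    tree_text = None
    if method == "cart":
        params = {"max_depth": 3, **hyperparams}
        model = DecisionTreeRegressor(random_state=rng_seed, **params)
        model.fit(x, y)
        tree_text = export_text(model, feature_names=list(x.columns))
    elif method == "random_forest":
        params = {"n_estimators": 500, **hyperparams}
        model = RandomForestRegressor(random_state=rng_seed, n_jobs=1, **params)
        model.fit(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")

    raw = model.feature_importances_
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    importances = dict(zip(x.columns, map(float, norm)))
    order = sorted(importances, key=importances.get, reverse=True)
    ranks = {feature: i + 1 for i, feature in enumerate(order)}
    return ImportanceResult(
        method=method,
        target=target,
        hyperparams=params,
        importances=importances,
        ranks=ranks,
        tree_text=tree_text,
    )


@dataclass
class RobustnessScan:
    results: list[ImportanceResult]
    top1_stable: bool
    top1_features: set[str] = field(default_factory=set)


def robustness_scan(
    df: pd.DataFrame,
    features: list[str],
    target: str,
    hyperparam_grid: list[dict] | None = None,
    method: str = "random_forest",
    rng_seed: int = 0,
) -> RobustnessScan:
    """One importance fit per hyperparameter cell plus a top-1 stability flag."""
    hyperparam_grid = hyperparam_grid or [
        {"n_estimators": 100},
        {"n_estimators": 300},
        {"n_estimators": 500},
        {"n_estimators": 300, "min_samples_split": 10},
    ]
    results = [
        fit_importance(df, features, target, method=method, rng_seed=rng_seed, **cell)
        for cell in hyperparam_grid
    ]
    tops = {next(iter(res.top(1))) for res in results}
    return RobustnessScan(results=results, top1_stable=len(tops) == 1, top1_features=tops)
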