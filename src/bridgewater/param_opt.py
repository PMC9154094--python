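"""Seedable hyperparameter search for the placement cutoffs.

The objective mirrors how the cutoffs were originally tuned: run
placement on training complexes stripped of their waters and measure,
for every native bridging water, the distance to the nearest placed
water oxygen. Natives left without any placed water receive a finite
penalty distance (10 Å by default) so the objective stays defined when a
parameter set places nothing. Lower is better; false positives are not
penalized.

Random search is the built-in backend — it needs nothing beyond numpy
and is exactly reproducible from the seed. A Tree-of-Parzen-Estimators
backend is available when ``hyperopt`` is installed (``strategy="tpe"``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BridgewaterError, NoTrainingDataError
from .evaluation import EvalParams, find_native_waters, score_saturation
from .placement import PlacementParams, place_waters
from .structio import InterfaceComplex, strip_waters

__all__ = ["SearchSpace", "OptTrial", "objective", "search", "trials_table"]


@dataclass(frozen=True)
class SearchSpace:
    """Bounds per tunable dimension; grid_spacing is a discrete choice."""

    clash_dist: tuple[float, float] = (1.5, 3.0)
    cluster_dist: tuple[float, float] = (1.0, 3.0)
    hbond_max: tuple[float, float] = (2.5, 4.0)
    grid_spacing: tuple[float, ...] = (0.5, 1.0)

    def __post_init__(self) -> None:
        for name in ("clash_dist", "cluster_dist", "hbond_max"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
        if not self.grid_spacing:
            raise ValueError("grid_spacing choices must be non-empty")

    def sample(self, rng: np.random.Generator,
               base: PlacementParams = PlacementParams()) -> PlacementParams:
        """Draw one parameter set: uniform per continuous dimension."""
        return dataclasses.replace(
            base,
            clash_dist=float(rng.uniform(*self.clash_dist)),
            cluster_dist=float(rng.uniform(*self.cluster_dist)),
            hbond_max=float(rng.uniform(*self.hbond_max)),
            grid_spacing=float(self.grid_spacing[rng.integers(len(self.grid_spacing))]),
        )


@dataclass
class OptTrial:
    index: int
    params: PlacementParams
    objective: float


def objective(
    complexes: Sequence[InterfaceComplex],
    params: PlacementParams,
    eval_params: EvalParams = EvalParams(),
    penalty: float = 10.0,
) -> float:
    """Mean over complexes of the mean per-native nearest-water distance (Å).

    Waters are stripped before placement; the stripped-out bridging
    waters are the ground truth. A native with no placed water within
    reach (placement produced nothing) contributes ``penalty``.
    """
    if not complexes:
        raise NoTrainingDataError("no training data")
    per_complex: list[float] = []
    for cx in complexes:
        bridging, _ = find_native_waters(cx, eval_params)
        if not bridging:
            raise BridgewaterError(
                f"training complex {cx.source_id!r} has no bridging waters")
        placed = place_waters(strip_waters(cx), params)
        report = score_saturation(bridging, placed, eval_params)
        dists = [min(d, penalty) if math.isfinite(d) else penalty
                 for _, d in report.per_native_nearest]
        per_complex.append(float(np.mean(dists)))
    return float(np.mean(per_complex))


def search(
    space: SearchSpace,
    complexes: Sequence[InterfaceComplex],
    n_trials: int,
    seed: int,
    strategy: str = "random",
    *,
    base: PlacementParams = PlacementParams(),
    eval_params: EvalParams = EvalParams(),
    penalty: float = 10.0,
) -> tuple[PlacementParams, list[OptTrial]]:
    """Minimize the objective over the space; reproducible from the seed.

    Returns the best parameter set (argmin; ties go to the earliest
    trial) and the full trial log.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not complexes:
        raise NoTrainingDataError("no training data")

    if strategy == "random":
        rng = np.random.default_rng(seed)
        trials: list[OptTrial] = []
        for i in range(n_trials):
            params = space.sample(rng, base)
            val = objective(complexes, params, eval_params, penalty)
            trials.append(OptTrial(index=i, params=params, objective=val))
    elif strategy == "tpe":
        trials = _tpe_search(space, complexes, n_trials, seed, base,
                             eval_params, penalty)
    else:
        raise ValueError(f"unknown strategy {strategy!r} (use 'random' or 'tpe')")

    best = min(trials, key=lambda t: (t.objective, t.index))
    return best.params, trials


def _tpe_search(space, complexes, n_trials, seed, base, eval_params,
                penalty) -> list[OptTrial]:
    try:
        from hyperopt import Trials, fmin, hp, tpe
    except ImportError as exc:  # pragma: no cover - optional extra
        raise BridgewaterError(
            "strategy='tpe' requires the optional 'hyperopt' dependency "
            "(pip install bridgewater[tpe]); the built-in 'random' strategy "
            "has no extra requirements") from exc

    hp_space = {
        "clash_dist": hp.uniform("clash_dist", *space.clash_dist),
        "cluster_dist": hp.uniform("cluster_dist", *space.cluster_dist),
        "hbond_max": hp.uniform("hbond_max", *space.hbond_max),
        "grid_spacing": hp.choice("grid_spacing", list(space.grid_spacing)),
    }
    log: list[OptTrial] = []

    def _loss(kw):
        params = dataclasses.replace(base, **kw)
        val = objective(complexes, params, eval_params, penalty)
        log.append(OptTrial(index=len(log), params=params, objective=val))
        return val

    fmin(_loss, hp_space, algo=tpe.suggest, max_evals=n_trials,
         trials=Trials(), rstate=np.random.default_rng(seed),
         show_progressbar=False)
    return log


def trials_table(trials: Sequence[OptTrial]) -> pd.DataFrame:
    """Trial log as a DataFrame (one row per trial, TSV-friendly)."""
    return pd.DataFrame([
        {
            "trial": t.index,
            "objective": t.objective,
            "clash_dist": t.params.clash_dist,
            "cluster_dist": t.params.cluster_dist,
            "merge_dist": t.params.merge_dist,
            "hbond_max": t.params.hbond_max,
            "grid_spacing": t.params.grid_spacing,
        }
        for t in trials
    ])
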