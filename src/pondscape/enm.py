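"""Ensemble ecological niche modelling (ENM).

The model relates species presence records to gridded environmental
covariates through an ensemble of presence / pseudo-absence classifiers.
The workflow: spatial thinning of presences, repeated pseudo-absence (PA)
sampling (uniform or "disk" sampling excluding a radius around presences),
class weighting so presences and PAs carry equal total weight, repeated
stratified 70/30 train/evaluation splits, per-run evaluation by AUC-ROC
and the True Skill Statistic (TSS), and a TSS-gated ensemble: runs with
TSS above a cutoff (default 0.7) are averaged into the ensemble mean
suitability surface, with a per-cell coefficient of variation (CV,
population sd / mean) as the uncertainty surface.

Learners are pluggable through a registry; a linear-logistic family and a
tree-ensemble family ship by default.  :class:`EnsembleNicheModel` /
:class:`EnsembleNicheResults` expose the statsmodels-style model/results
split; the module-level functions are the individual pipeline operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .raster import GridRaster

__all__ = [
    "OccurrenceSet",
    "ModelRun",
    "EnsembleModel",
    "EnsembleNicheModel",
    "EnsembleNicheResults",
    "thin_occurrences",
    "sample_pseudo_absences",
    "compute_weights",
    "split_train_eval",
    "auc_roc",
    "tss",
    "fit_single_model",
    "permutation_importance",
    "select_variables",
    "build_ensemble",
    "count_model_runs",
    "enumerate_run_specs",
    "response_curve",
    "register_learner",
    "predict_surface",
]


class EmptyEnsembleError(RuntimeError):
    """No model run passed the TSS cutoff."""


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceSet:
    """Presence points of one species, planar metre coordinates (n, 2)."""

    species_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.points.shape[0]


def thin_occurrences(occ: OccurrenceSet, min_dist: float = 50.0) -> OccurrenceSet:
    """Greedy spatial thinning in input order.

    A point is kept iff no previously kept point lies within ``min_dist``
    metres; order is preserved.  Removes duplicate coordinates for any
    min_dist >= 0.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    kept: list[np.ndarray] = []
    for p in occ.points:
        if all(np.hypot(*(p - q)) > min_dist for q in kept):
            kept.append(p)
    pts = np.array(kept) if kept else np.empty((0, 2))
    return OccurrenceSet(occ.species_id, pts)


def sample_pseudo_absences(
    frame: GridRaster,
    occ: OccurrenceSet,
    n: int,
    n_sets: int = 1,
    method: str = "random",
    min_dist: float = 50.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Draw ``n_sets`` independent sets of ``n`` pseudo-absence points.

    Points are cell centers drawn uniformly without replacement within a
    set from the eligible cells: all non-nodata cells (``method="random"``)
    or, for the disk method, the non-nodata cells whose center lies
    strictly farther than ``min_dist`` from every presence.
    """
    if method not in ("random", "disk"):
        raise ValueError(f"unknown PA method {method!r}")
    xs, ys = frame.cell_centers()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    eligible = frame.valid_mask().ravel()
    if method == "disk" and len(occ) > 0:
        d, _ = cKDTree(occ.points).query(centers)
        eligible = eligible & (d > min_dist)
    idx_pool = np.nonzero(eligible)[0]
    if idx_pool.size < n:
        raise ValueError(
            f"only {idx_pool.size} eligible cells for {n} pseudo-absences"
        )
    sets = []
    for child in np.random.SeedSequence([int(seed), 53]).spawn(n_sets):
        rng = np.random.default_rng(child)
        chosen = rng.choice(idx_pool, size=n, replace=False)
        sets.append(centers[chosen])
    return sets


def compute_weights(n_presence: int, n_pa: int) -> tuple[float, float]:
    """Per-point weights giving presences and PAs equal total weight.

    Presence weight 1; PA weight n_presence / n_pa, so that
    ``n_presence * w_p == n_pa * w_pa`` exactly.
    """
    if n_presence <= 0 or n_pa <= 0:
        raise ValueError("both class counts must be positive")
    return 1.0, n_presence / n_pa


def split_train_eval(
    labels: np.ndarray, fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train_idx, eval_idx).

    Per class, round(fraction * n_class) points go to training.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 67]))
    train_parts, eval_parts = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 points")
        idx = rng.permutation(idx)
        n_train = int(np.floor(fraction * idx.size + 0.5))
        train_parts.append(idx[:n_train])
        eval_parts.append(idx[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(eval_parts))


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------


def auc_roc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def tss(scores, labels) -> tuple[float, float]:
    """True Skill Statistic and its optimising threshold.

    Maximises sensitivity + specificity - 1 over the distinct score
    values as candidate thresholds (rule: score >= threshold -> presence);
    ties on TSS are broken by the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("TSS undefined with a single class")
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    thresholds = np.unique(scores)
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg, thresholds, side="left") / neg.size
    values = sens + spec - 1.0
    best = int(np.argmax(values))  # first max = lowest threshold
    return float(values[best]), float(thresholds[best])


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

_LEARNERS: dict[str, Callable[[int], object]] = {}


def register_learner(learner_id: str, factory: Callable[[int], object]) -> None:
    """Register a learner family: factory(seed) -> sklearn-style classifier."""
    _LEARNERS[learner_id] = factory


# unpenalised MLE: duplicating points is then exactly equivalent to doubling weights
register_learner(
    "logistic",
    lambda seed: LogisticRegression(C=np.inf, max_iter=2000, solver="lbfgs"),
)
register_learner(
    "rf",
    lambda seed: RandomForestClassifier(
        n_estimators=100, min_samples_leaf=5, random_state=seed, n_jobs=1
    ),
)


@dataclass
class ModelRun:
    """One fitted member of the ensemble, with its evaluation scores."""

    learner_id: str
    pa_set_index: int
    run_index: int
    predictor: object
    var_names: tuple[str, ...]
    tss: float = np.nan
    auc: float = np.nan
    tss_threshold: float = np.nan

    def predict(self, X) -> np.ndarray:
        """Suitability probability in [0, 1] for rows of covariates."""
        X = np.asarray(X, dtype=float)
        p = self.predictor.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


def fit_single_model(
    learner_id: str,
    X,
    y,
    weights,
    seed: int = 0,
    var_names: Sequence[str] | None = None,
    pa_set_index: int = 0,
    run_index: int = 0,
) -> ModelRun:
    """Fit one registered learner honouring per-point weights."""
    if learner_id not in _LEARNERS:
        raise KeyError(f"unknown learner {learner_id!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("at least one covariate required")
    est = _LEARNERS[learner_id](int(seed))
    est.fit(X, y, sample_weight=np.asarray(weights, dtype=float))
    names = tuple(var_names) if var_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    return ModelRun(learner_id, pa_set_index, run_index, est, names)


def permutation_importance(
    run: ModelRun, X, variable: int | str, n_perm: int = 5, seed: int = 0
) -> float:
    """Ensemble-SDM permutation importance: mean over permutations of 1 - Pearson r
    between predictions on original data and on data with one variable
    shuffled.  Constant predictions give 0 by convention."""
    X = np.asarray(X, dtype=float)
    j = run.var_names.index(variable) if isinstance(variable, str) else int(variable)
    base = run.predict(X)
    if np.std(base) == 0:
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 79]))
    vals = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        perm = run.predict(Xp)
        if np.std(perm) == 0:
            vals.append(1.0 if np.std(base) > 0 else 0.0)
            continue
        r = np.corrcoef(base, perm)[0, 1]
        vals.append(1.0 - r)
    return float(np.clip(np.mean(vals), 0.0, None))


def select_variables(
    candidates: pd.DataFrame,
    importances: Mapping[str, float],
    corr_threshold: float = 0.7,
) -> list[str]:
    """Collinearity-aware variable selection.

    Variables are clustered by single linkage on 1 - |Pearson r| with
    cluster radius 1 - corr_threshold (so any pair with |r| >=
    corr_threshold ends up together); within each cluster the variable
    with the highest importance is retained.  Output preserves the input
    column order.
    """
    names = list(candidates.columns)
    if len(names) == 1:
        return names
    corr = candidates.corr().to_numpy()
    corr = np.where(np.isfinite(corr), corr, 0.0)  # constant columns correlate with nothing
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="single")
    clusters = fcluster(Z, t=1.0 - corr_threshold, criterion="distance")
    keep: set[str] = set()
    for cl in np.unique(clusters):
        members = [names[i] for i in np.nonzero(clusters == cl)[0]]
        keep.add(max(members, key=lambda v: importances.get(v, 0.0)))
    return [v for v in names if v in keep]


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------


def predict_surface(run: ModelRun, covariates: Mapping[str, GridRaster]) -> GridRaster:
    """Apply a fitted run to covariate rasters; nodata propagates."""
    frame = covariates[run.var_names[0]]
    stack = np.column_stack(
        [covariates[name].values.ravel() for name in run.var_names]
    )
    valid = np.all(np.isfinite(stack), axis=1)
    out = np.full(stack.shape[0], np.nan)
    if valid.any():
        out[valid] = run.predict(stack[valid])
    return frame.with_values(out.reshape(frame.shape))


@dataclass
class EnsembleModel:
    """TSS-gated ensemble: mean suitability and CV uncertainty surfaces."""

    members: list[ModelRun]
    tss_cutoff: float
    mean_surface: GridRaster
    cv_surface: GridRaster

    @property
    def passing_members(self) -> list[ModelRun]:
        return [m for m in self.members if m.tss > self.tss_cutoff]

    def project(self, covariates: Mapping[str, GridRaster]) -> tuple[GridRaster, GridRaster]:
        """Mean and CV surfaces of the passing members on new covariates
        (e.g. a future climate scenario)."""
        return _mean_cv([predict_surface(m, covariates) for m in self.passing_members])


def _mean_cv(surfaces: list[GridRaster]) -> tuple[GridRaster, GridRaster]:
    stack = np.stack([s.values for s in surfaces])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    cv = np.where(np.isfinite(mean), cv, np.nan)
    frame = surfaces[0]
    return frame.with_values(mean), frame.with_values(cv)


def build_ensemble(
    runs: list[ModelRun],
    covariates: Mapping[str, GridRaster] | None = None,
    tss_cutoff: float = 0.7,
    surfaces: list[GridRaster] | None = None,
) -> EnsembleModel:
    """Average the runs with TSS above the cutoff into an ensemble.

    Member surfaces are predicted from ``covariates`` unless precomputed
    ``surfaces`` (aligned with ``runs``) are supplied.  CV is population
    sd / mean per cell, 0 where the mean is 0.
    """
    passing = [i for i, r in enumerate(runs) if r.tss > tss_cutoff]
    if not passing:
        raise EmptyEnsembleError(f"no run has TSS > {tss_cutoff}")
    if surfaces is None:
        if covariates is None:
            raise ValueError("either covariates or surfaces must be given")
        surfaces = [predict_surface(runs[i], covariates) for i in passing]
    else:
        surfaces = [surfaces[i] for i in passing]
    mean, cv = _mean_cv(surfaces)
    return EnsembleModel(list(runs), tss_cutoff, mean, cv)


def count_model_runs(n_learners: int, n_pa_sets: int, n_runs: int) -> int:
    """Total single-model runs: learners x PA sets x repeat runs."""
    if min(n_learners, n_pa_sets, n_runs) < 1:
        raise ValueError("all counts must be positive")
    return n_learners * n_pa_sets * n_runs


def enumerate_run_specs(
    learner_ids: Sequence[str], n_pa_sets: int, n_runs: int
) -> list[tuple[str, int, int]]:
    """All (learner_id, pa_set, run) triples the pipeline will fit."""
    return [
        (lid, p, r)
        for lid in learner_ids
        for p in range(n_pa_sets)
        for r in range(n_runs)
    ]


def response_curve(
    ensemble: EnsembleModel,
    train_data: pd.DataFrame,
    variable: str,
    n_points: int = 25,
) -> pd.DataFrame:
    """Evaluation-strip response curve of the ensemble mean.

    One variable is swept over its observed range; the others are held at
    their training medians.  Returns columns (value, mean_prediction).
    """
    if variable not in train_data.columns:
        raise KeyError(f"unknown variable {variable!r}")
    members = ensemble.passing_members
    grid = np.linspace(train_data[variable].min(), train_data[variable].max(), n_points)
    medians = train_data.median()
    rows = []
    for v in grid:
        point = medians.copy()
        point[variable] = v
        X = point[list(members[0].var_names)].to_numpy(dtype=float)[None, :]
        preds = [m.predict(X)[0] for m in members]
        rows.append((v, float(np.mean(preds))))
    return pd.DataFrame(rows, columns=["value", "mean_prediction"])


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class EnsembleNicheModel:
    """Ensemble niche model for one species on a covariate stack.

    Parameters
    ----------
    covariates : mapping of name -> GridRaster
        Environmental covariates on a common frame.
    occurrences : OccurrenceSet
        Presence points in the frame's coordinate system.
    learners : sequence of registered learner ids.
    n_pa, n_pa_sets : pseudo-absences per set and number of sets.
    n_runs : repeat train/eval splits per (learner, PA set).
    pa_method : "random" or "disk"; ``pa_min_dist`` applies to "disk".
    thin_dist : spatial thinning radius in metres (None disables).
    tss_cutoff : ensembling gate on evaluation TSS.
    split_fraction : training share of each stratified split.
    seed : master seed; all randomness derives from it.
    """

    def __init__(
        self,
        covariates: Mapping[str, GridRaster],
        occurrences: OccurrenceSet,
        *,
        learners: Sequence[str] = ("logistic", "rf"),
        n_pa: int = 300,
        n_pa_sets: int = 2,
        n_runs: int = 2,
        pa_method: str = "random",
        pa_min_dist: float = 50.0,
        thin_dist: float | None = None,
        tss_cutoff: float = 0.7,
        split_fraction: float = 0.7,
        seed: int = 0,
    ) -> None:
        self.covariates = dict(covariates)
        self.var_names = tuple(self.covariates)
        self.frame = next(iter(self.covariates.values()))
        for ras in self.covariates.values():
            self.frame.require_same_frame(ras)
        self.occurrences = (
            thin_occurrences(occurrences, thin_dist) if thin_dist else occurrences
        )
        self.learners = tuple(learners)
        self.n_pa = n_pa
        self.n_pa_sets = n_pa_sets
        self.n_runs = n_runs
        self.pa_method = pa_method
        self.pa_min_dist = pa_min_dist
        self.tss_cutoff = tss_cutoff
        self.split_fraction = split_fraction
        self.seed = int(seed)

    def _design(self, points: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.covariates[name].sample(points) for name in self.var_names]
        )

    def fit(self) -> "EnsembleNicheResults":
        occ = self.occurrences
        if len(occ) == 0:
            raise ValueError("no presence points")
        pa_sets = sample_pseudo_absences(
            self.frame,
            occ,
            self.n_pa,
            n_sets=self.n_pa_sets,
            method=self.pa_method,
            min_dist=self.pa_min_dist,
            seed=self.seed,
        )
        X_pres = self._design(occ.points)
        w_p, w_pa = compute_weights(len(occ), self.n_pa)
        runs: list[ModelRun] = []
        train_frames: list[pd.DataFrame] = []
        specs = enumerate_run_specs(self.learners, self.n_pa_sets, self.n_runs)
        for k, (learner_id, pa_idx, run_idx) in enumerate(specs):
            X_pa = self._design(pa_sets[pa_idx])
            X = np.vstack([X_pres, X_pa])
            y = np.concatenate([np.ones(len(occ)), np.zeros(self.n_pa)]).astype(int)
            w = np.concatenate([np.full(len(occ), w_p), np.full(self.n_pa, w_pa)])
            tr, ev = split_train_eval(
                y, self.split_fraction, seed=self.seed * 100003 + k
            )
            run = fit_single_model(
                learner_id,
                X[tr],
                y[tr],
                w[tr],
                seed=self.seed * 9176 + k,
                var_names=self.var_names,
                pa_set_index=pa_idx,
                run_index=run_idx,
            )
            scores = run.predict(X[ev])
            run.auc = auc_roc(scores, y[ev])
            run.tss, run.tss_threshold = tss(scores, y[ev])
            runs.append(run)
            if learner_id == self.learners[0] and run_idx == 0:
                train_frames.append(pd.DataFrame(X[tr], columns=self.var_names))
        ensemble = build_ensemble(runs, self.covariates, tss_cutoff=self.tss_cutoff)
        train_data = pd.concat(train_frames, ignore_index=True)
        return EnsembleNicheResults(self, ensemble, train_data)


@dataclass
class EnsembleNicheResults:
    """Fitted ensemble: member scores, surfaces, diagnostics."""

    model: EnsembleNicheModel
    ensemble: EnsembleModel
    train_data: pd.DataFrame

    @property
    def mean_surface(self) -> GridRaster:
        return self.ensemble.mean_surface

    @property
    def cv_surface(self) -> GridRaster:
        return self.ensemble.cv_surface

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-run evaluation ledger (learner, pa_set, run, tss, auc)."""
        return pd.DataFrame(
            [
                {
                    "learner": r.learner_id,
                    "pa_set": r.pa_set_index,
                    "run": r.run_index,
                    "tss": r.tss,
                    "auc": r.auc,
                    "passed": r.tss > self.ensemble.tss_cutoff,
                }
                for r in self.ensemble.members
            ]
        )

    def project(self, covariates: Mapping[str, GridRaster]):
        """(mean, cv) surfaces of the ensemble on new covariates."""
        return self.ensemble.project(covariates)

    def response_curve(self, variable: str, n_points: int = 25) -> pd.DataFrame:
        return response_curve(self.ensemble, self.train_data, variable, n_points)

    def variable_importance(self, n_perm: int = 3, seed: int = 0) -> pd.Series:
        """Mean permutation importance per variable across passing runs."""
        X = self.train_data.to_numpy(dtype=float)
        out = {}
        for v in self.model.var_names:
            vals = [
                permutation_importance(r, X, v, n_perm=n_perm, seed=seed)
                for r in self.ensemble.passing_members
            ]
            out[v] = float(np.mean(vals))
        return pd.Series(out, name="importance")

    def plot_response_curves(self, variables=None, n_points: int = 25, axes=None):
        """Evaluation-strip response curves, one panel per variable.

        Returns the matplotlib figure; ``variables`` defaults to every
        model covariate.
        """
        import matplotlib.pyplot as plt

        variables = list(variables) if variables is not None else list(self.model.var_names)
        if axes is None:
            fig, axes = plt.subplots(1, len(variables), figsize=(3.2 * len(variables), 3), squeeze=False)
            axes = axes[0]
        else:
            fig = axes[0].figure
        for ax, var in zip(axes, variables):
            df = self.response_curve(var, n_points=n_points)
            ax.plot(df["value"], df["mean_prediction"])
            ax.set_xlabel(var)
            ax.set_ylim(0, 1)
        axes[0].set_ylabel("ensemble mean suitability")
        fig.tight_layout()
        return fig

    def summary(self) -> str:
        m = self.metrics
        passing = m[m["passed"]]
        lines = [
            "Ensemble niche model results",
            "=" * 60,
            f"species:            {self.model.occurrences.species_id}",
            f"presences:          {len(self.model.occurrences)}",
            f"learners:           {', '.join(self.model.learners)}",
            f"model runs:         {len(m)} "
            f"({len(self.model.learners)} learners x {self.model.n_pa_sets} PA sets"
            f" x {self.model.n_runs} runs)",
            f"TSS cutoff:         {self.ensemble.tss_cutoff}",
            f"runs in ensemble:   {len(passing)}",
            f"mean TSS (passing): {passing['tss'].mean():.3f}",
            f"mean AUC (passing): {passing['auc'].mean():.3f}",
            "-" * 60,
            m.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)
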