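"""Random-forest δ³⁴S isoscape regression.

The site-averaged δ³⁴S compilation is regressed on environmental covariates
(sea-salt and dust aerosol deposition, gravity anomaly, soil and climate
grids) with a random forest. Candidate covariates go through a two-stage
selection in the VSURF style: variables are first ranked by out-of-bag
permutation importance averaged over several forests and the clearly
uninformative tail is eliminated; survivors are then added greedily in rank
order, each addition kept only if it lowers the out-of-bag RMSE. Model skill
is reported from repeated cross-validation, and the fitted forest is
evaluated over a covariate stack to produce the isoscape mean grid, with a
constant RMSE as its uncertainty surface.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``transform``, ``get_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import RepeatedKFold, ShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .grids import CovariateStack, Isoscape, RasterGrid

try:  # exact bootstrap-index recipe used inside sklearn's forests
    import inspect as _inspect

    from sklearn.ensemble._forest import (
        _generate_sample_indices as _sk_gen_indices,
    )

    if "sample_weight" in _inspect.signature(_sk_gen_indices).parameters:
        def _sk_sample_indices(random_state, n_samples, n_samples_bootstrap):
            return _sk_gen_indices(random_state, n_samples,
                                   n_samples_bootstrap, None)
    else:  # older signature
        _sk_sample_indices = _sk_gen_indices
except ImportError:  # pragma: no cover - fallback mirrors the same recipe
    from sklearn.utils import check_random_state

    def _sk_sample_indices(random_state, n_samples, n_samples_bootstrap):
        rng = check_random_state(random_state)
        return rng.randint(0, n_samples, n_samples_bootstrap).astype(np.int32)


def _resolve_max_features(max_features, p: int):
    """The 'p/3 rounded' convention for regression forests."""
    if max_features == "third":
        return max(1, round(p / 3))
    return max_features


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


@dataclass
class RegressionDataset:
    """Aligned regression matrix: one row per site, covariates + response."""

    X: pd.DataFrame
    y: np.ndarray
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if self.X.isna().any().any():
            raise ValueError("X contains invalid (NaN) covariate entries; "
                             "drop those rows before modelling")

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)


def build_regression_dataset(sites, covariate_matrix: pd.DataFrame,
                             variables: list[str] | None = None) -> RegressionDataset:
    """Join site averages with extracted covariates, dropping invalid rows.

    ``sites`` is a collection of SiteAverage; ``covariate_matrix`` is the
    output of :func:`isoprov.grids.extract_at_points` (indexed by site_id).
    Rows with any invalid covariate entry are dropped.
    """
    variables = variables or [c for c in covariate_matrix.columns
                              if c not in ("x", "y")]
    rows, ys, ids = [], [], []
    for s in sites:
        if s.site_id not in covariate_matrix.index:
            continue
        row = covariate_matrix.loc[s.site_id, variables]
        if row.isna().any():
            continue
        rows.append(row.astype(float))
        ys.append(s.mean_d34S)
        ids.append(s.site_id)
    X = pd.DataFrame(rows, columns=variables).reset_index(drop=True)
    return RegressionDataset(X=X, y=np.array(ys), site_ids=ids)


class RandomForestIsoscape(RegressorMixin, BaseEstimator):
    """Random-forest regressor with out-of-bag diagnostics for isoscapes.

    Parameters
    ----------
    n_trees : int, default 500
        Ensemble size.
    max_features : "third" or int or float, default "third"
        Features tried per split; "third" is max(1, round(p/3)).
    min_leaf : int, default 5
        Minimum samples per leaf.
    random_state : int or None
        Seed; fits are deterministic given a seed.

    Attributes
    ----------
    forest_ : fitted ``RandomForestRegressor`` (with OOB predictions).
    oob_prediction_, oob_rmse_ : out-of-bag predictions and their RMSE.
    y_min_, y_max_ : training response range; forest predictions are means
        of training values and therefore stay inside this range.
    """

    def __init__(self, n_trees: int = 500, max_features="third",
                 min_leaf: int = 5, random_state: int | None = None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, float)
        if len(X) < self.min_leaf:
            raise ValueError(
                f"need at least min_leaf={self.min_leaf} rows, got {len(X)}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=_resolve_max_features(self.max_features, X.shape[1]),
            min_samples_leaf=self.min_leaf,
            bootstrap=True, oob_score=True, n_jobs=1,
            random_state=self.random_state,
        ).fit(X.to_numpy(), y)
        self._X_train = X.to_numpy()
        self._y_train = y
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        self.oob_prediction_ = self.forest_.oob_prediction_
        self.oob_rmse_ = float(np.sqrt(np.mean((y - self.oob_prediction_) ** 2)))
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X[list(self.feature_names_in_)]
        return self.forest_.predict(X.to_numpy())

    # -- out-of-bag machinery -------------------------------------------

    def _oob_index_sets(self) -> list[np.ndarray]:
        """Per-tree arrays of sample indices left out of the bootstrap."""
        n = len(self._y_train)
        out = []
        for tree in self.forest_.estimators_:
            inbag = _sk_sample_indices(tree.random_state, n, n)
            mask = np.ones(n, bool)
            mask[inbag] = False
            out.append(np.flatnonzero(mask))
        return out

    def oob_prediction_reconstructed(self) -> np.ndarray:
        """OOB predictions rebuilt from per-tree index sets.

        Exists to validate the index reconstruction against the forest's
        own ``oob_prediction_``.
        """
        check_is_fitted(self, "forest_")
        n = len(self._y_train)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.forest_.estimators_, self._oob_index_sets()):
            if oob.size:
                total[oob] += tree.predict(self._X_train[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore"):
            return total / count

    def permutation_importance_oob(self, n_repeats: int = 1,
                                   random_state: int | None = None) -> pd.DataFrame:
        """Permutation importance measured on each tree's OOB samples.

        For every tree, each variable is permuted within the tree's
        out-of-bag sample and the increase in squared error over the
        unpermuted OOB error is recorded. Returns a table sorted by mean
        increase in MSE, with the standard error of the per-tree increases
        (``se``): an uninformative variable has mean ~ 0 within a few se.
        """
        check_is_fitted(self, "forest_")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        p = self.n_features_in_
        increases: list[list[float]] = [[] for _ in range(p)]
        for tree, oob in zip(self.forest_.estimators_, self._oob_index_sets()):
            if oob.size < 2:
                continue
            Xo = self._X_train[oob]
            yo = self._y_train[oob]
            base = np.mean((yo - tree.predict(Xo)) ** 2)
            for j in range(p):
                acc = 0.0
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, j] = rng.permutation(Xp[:, j])
                    acc += np.mean((yo - tree.predict(Xp)) ** 2) - base
                increases[j].append(acc / n_repeats)
        rows = []
        for j, name in enumerate(self.feature_names_in_):
            arr = np.asarray(increases[j])
            rows.append({"variable": name,
                         "importance": float(arr.mean()),
                         "se": float(arr.std(ddof=1) / np.sqrt(arr.size))})
        return (pd.DataFrame(rows)
                .sort_values("importance", ascending=False)
                .reset_index(drop=True))

    def impurity_importance(self) -> pd.DataFrame:
        """Mean-decrease-in-impurity importance (secondary diagnostic)."""
        check_is_fitted(self, "forest_")
        return (pd.DataFrame({"variable": self.feature_names_in_,
                              "importance": self.forest_.feature_importances_})
                .sort_values("importance", ascending=False)
                .reset_index(drop=True))

    def partial_dependence(self, X, variable: str, grid) -> pd.DataFrame:
        """Mean prediction as ``variable`` is swept over ``grid`` values."""
        check_is_fitted(self, "forest_")
        X = _as_frame(X)
        if variable not in X.columns:
            raise ValueError(f"unknown variable {variable!r}")
        rows = []
        for v in np.asarray(grid, float):
            Xm = X.copy()
            Xm[variable] = v
            rows.append((v, float(self.predict(Xm).mean())))
        return pd.DataFrame(rows, columns=["value", "mean_prediction"])

    def predict_isoscape(self, stack: CovariateStack,
                         constant_rmse: float, system: str = "S",
                         note: str = "") -> Isoscape:
        """Evaluate the forest over a covariate stack.

        The mean grid is the per-cell forest prediction; the SD grid is the
        constant RMSE everywhere valid; a cell is nodata wherever any
        required covariate layer is nodata.
        """
        check_is_fitted(self, "forest_")
        missing = [v for v in self.feature_names_in_ if v not in stack]
        if missing:
            raise ValueError(f"covariate stack is missing layer(s): {missing}")
        names = list(self.feature_names_in_)
        valid = stack.combined_valid_mask(names)
        M = stack.as_matrix(names).to_numpy()
        flat_valid = valid.ravel()
        mean = np.full(stack.spec.shape, np.nan).ravel()
        if flat_valid.any():
            mean[flat_valid] = self.forest_.predict(M[flat_valid])
        mean = mean.reshape(stack.spec.shape)
        grid = RasterGrid(stack.spec, mean, ~valid, f"{system}_mean")
        return Isoscape(system=system, mean=grid, sd=float(constant_rmse),
                        note=note or "forest prediction; constant-RMSE sd")


class RFVariableSelector(SelectorMixin, BaseEstimator):
    """Two-stage random-forest variable selection (ranking then addition).

    Stage 1 ranks variables by OOB permutation importance averaged over
    ``n_rank_forests`` independently seeded forests and eliminates those
    whose mean importance falls below ``importance_sd_multiplier`` times the
    SD of the importances in the lower half of the ranking (the noise tail).
    Stage 2 walks the survivors in rank order and keeps an addition only if
    it lowers the out-of-bag RMSE by more than ``addition_tolerance``
    relative to the best model so far; the baseline is the RMSE of
    predicting the response mean, so a dataset with no usable signal selects
    nothing.

    Attributes
    ----------
    ranked_variables_ : list of (name, mean importance), descending.
    elimination_threshold_ : stage-1 cutoff in importance units.
    selected_variables_ : ordered accepted subset.
    oob_path_ : list of (variable_added, oob_rmse) for accepted additions.
    """

    def __init__(self, n_rank_forests: int = 10,
                 importance_sd_multiplier: float = 1.0,
                 addition_tolerance: float = 0.0,
                 n_trees: int = 500, max_features="third", min_leaf: int = 5,
                 random_state: int | None = None):
        self.n_rank_forests = n_rank_forests
        self.importance_sd_multiplier = importance_sd_multiplier
        self.addition_tolerance = addition_tolerance
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, float)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 candidate variables")
        if len(X) < 20:
            raise ValueError("need at least 20 rows for variable selection")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.n_rank_forests + X.shape[1] + 1) % (2 ** 31)

        # stage 1: rank by mean OOB permutation importance
        imp = np.zeros(X.shape[1])
        for k in range(self.n_rank_forests):
            f = RandomForestIsoscape(self.n_trees, self.max_features,
                                     self.min_leaf, int(seeds[k])).fit(X, y)
            tab = f.permutation_importance_oob().set_index("variable")
            imp += tab.loc[list(self.feature_names_in_), "importance"].to_numpy()
        imp /= self.n_rank_forests
        order = np.argsort(-imp)
        self.ranked_variables_ = [(str(self.feature_names_in_[i]), float(imp[i]))
                                  for i in order]
        tail = imp[order][max(2, len(order) // 2):]
        if tail.size < 2:
            tail = imp[order][-2:]
        self.elimination_threshold_ = float(
            self.importance_sd_multiplier * np.std(tail, ddof=1))
        survivors = [name for name, v in self.ranked_variables_
                     if v > self.elimination_threshold_]
        if not survivors:
            raise ValueError(
                "all variables eliminated at the ranking stage; consider "
                "lowering importance_sd_multiplier")

        # stage 2: greedy addition in rank order against OOB RMSE
        best_rmse = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
        selected: list[str] = []
        self.oob_path_: list[tuple[str, float]] = []
        for j, name in enumerate(survivors):
            cand = selected + [name]
            f = RandomForestIsoscape(
                self.n_trees, self.max_features, self.min_leaf,
                int(seeds[self.n_rank_forests + j])).fit(X[cand], y)
            if best_rmse - f.oob_rmse_ > self.addition_tolerance:
                selected.append(name)
                best_rmse = f.oob_rmse_
                self.oob_path_.append((name, f.oob_rmse_))
        self.selected_variables_ = selected
        self.support_mask_ = np.isin(self.feature_names_in_, selected)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_


@dataclass
class CVReport:
    """Repeated cross-validation summary for the isoscape regression."""

    scheme: dict
    fold_rmse: list[float]
    fold_r2: list[float]
    observed: np.ndarray
    predicted: np.ndarray
    rmse: float
    r2: float
    residual_shapiro_w: float
    residual_shapiro_p: float

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.predicted

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "rmse": self.rmse, "r2": self.r2,
                "fold_rmse": self.fold_rmse, "fold_r2": self.fold_r2,
                "residual_shapiro_w": self.residual_shapiro_w,
                "residual_shapiro_p": self.residual_shapiro_p}


def cross_validate(ds: RegressionDataset, variables: list[str] | None = None,
                   folds: int = 10, repeats: int = 5,
                   train_fraction: float | None = 0.8,
                   seed: int | None = None,
                   model_params: dict | None = None) -> CVReport:
    """Repeated cross-validation of the forest regression.

    With ``train_fraction`` set (default 0.8), ``folds x repeats`` random
    splits hold out ``1 - train_fraction`` of the sites each; with
    ``train_fraction=None`` a classic repeated k-fold is used. RMSE and R^2
    are computed on the held-out predictions pooled over all splits — never
    on training folds.
    """
    variables = variables or ds.variables
    X = ds.X[variables]
    y = ds.y
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds the {len(y)} available rows")
    if train_fraction is None:
        splitter = RepeatedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
        scheme = {"k": folds, "repeats": repeats, "train_fraction": None}
    else:
        splitter = ShuffleSplit(n_splits=folds * repeats,
                                test_size=1.0 - train_fraction,
                                random_state=seed)
        scheme = {"k": folds, "repeats": repeats,
                  "train_fraction": train_fraction}
    params = model_params or {}
    obs_all, pred_all, fold_rmse, fold_r2 = [], [], [], []
    for i, (tr, te) in enumerate(splitter.split(X)):
        m = RandomForestIsoscape(random_state=None if seed is None
                                 else (seed + i) % (2 ** 31), **params)
        m.fit(X.iloc[tr], y[tr])
        pred = m.predict(X.iloc[te])
        obs = y[te]
        fold_rmse.append(float(np.sqrt(np.mean((obs - pred) ** 2))))
        sst = np.sum((obs - obs.mean()) ** 2)
        fold_r2.append(float(1 - np.sum((obs - pred) ** 2) / sst) if sst > 0
                       else float("nan"))
        obs_all.append(obs)
        pred_all.append(pred)
    observed = np.concatenate(obs_all)
    predicted = np.concatenate(pred_all)
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    sst = np.sum((observed - observed.mean()) ** 2)
    r2 = float(1 - np.sum((observed - predicted) ** 2) / sst)
    resid = observed - predicted
    # Shapiro-Wilk is defined for n <= 5000; subsample deterministically above
    if resid.size > 5000:
        resid_s = resid[np.linspace(0, resid.size - 1, 5000).astype(int)]
    else:
        resid_s = resid
    w, p = stats.shapiro(resid_s)
    return CVReport(scheme=scheme, fold_rmse=fold_rmse, fold_r2=fold_r2,
                    observed=observed, predicted=predicted, rmse=rmse, r2=r2,
                    residual_shapiro_w=float(w), residual_shapiro_p=float(p))


# -- thin functional wrappers ------------------------------------------------

def select_variables(ds: RegressionDataset, n_rank_forests: int = 10,
                     importance_sd_multiplier: float = 1.0,
                     addition_tolerance: float = 0.0,
                     seed: int | None = None,
                     model_params: dict | None = None) -> RFVariableSelector:
    params = model_params or {}
    sel = RFVariableSelector(n_rank_forests=n_rank_forests,
                             importance_sd_multiplier=importance_sd_multiplier,
                             addition_tolerance=addition_tolerance,
                             random_state=seed, **params)
    return sel.fit(ds.X, ds.y)


def fit_forest(ds: RegressionDataset, variables: list[str] | None = None,
               n_trees: int = 500, max_features="third", min_leaf: int = 5,
               seed: int | None = None) -> RandomForestIsoscape:
    variables = variables or ds.variables
    unknown = set(variables) - set(ds.variables)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")
    return RandomForestIsoscape(n_trees, max_features, min_leaf,
                                seed).fit(ds.X[variables], ds.y)
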