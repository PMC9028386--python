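"""Repeated LASSO-logistic cross-validation for the binary ISUP endpoint.

The estimator follows a statsmodels-like shape: :class:`LassoLogisticCV` is
built from a feature table and labels (``from_dataframe``), ``fit(seed)``
runs the full stochastic cross-validation and returns a
:class:`RepeatedCVResults` carrying per-iteration train/test AUCs, selected
feature sets, aggregates and a ``summary()`` table.

One iteration:

1. stratified lesion-level split into training (2/3) and test (1/3);
2. training-set median imputation and standardization (test data is
   transformed with the training statistics — no leakage);
3. an L1-penalized logistic regression path of 100 log-spaced penalties
   from lambda_max (the smallest penalty zeroing every coefficient) down
   four decades; the penalty minimizing mean held-out binomial deviance
   over stratified internal 3-fold CV is chosen, ties going to the
   sparser (larger) penalty, and the model is refit on the full training
   set;
4. train and test AUCs are recorded (Mann-Whitney formulation, ties 1/2);
   an all-zero (intercept-only) model is legitimate and scores 0.5.

This is repeated ``n_repeats`` times (default 30); the model quality is the
arithmetic mean AUC over iterations, the "best" iteration the one with
maximal test AUC (ties broken by train AUC then iteration index), and the
per-feature selection frequency the fraction of iterations with a nonzero
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ModelConfig",
    "LassoLogisticCV",
    "RepeatedCVResults",
    "ModelSuite",
    "SuiteResults",
    "roc_auc",
    "roc_points",
    "split_train_test",
    "fit_lasso_logistic",
    "run_repeated_cv",
    "build_model_suite",
]


# ---------------------------------------------------------------------------
# primitives


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with ties 1/2.

    Identical to the trapezoidal area under the empirical ROC curve.
    Raises if only one class is present. Constant scores give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve coordinates (FPR, TPR) at every threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n1 = max(int(y.sum()), 1)
    n0 = max(int((1 - y).sum()), 1)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    keep = np.r_[np.diff(s) != 0, True]  # one point per distinct threshold
    fpr = np.r_[0.0, fp[keep] / n0]
    tpr = np.r_[0.0, tp[keep] / n1]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def split_train_test(labels, train_fraction: float = 2.0 / 3.0, rng=None):
    """Stratified index split; |train| = round(train_fraction * n).

    Per-class training counts are the rounded per-class shares, adjusted
    (largest classes first) so the total matches and every class keeps at
    least one lesion on each side. Classes with fewer than 2 members make
    stratification impossible and raise.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = labels.size
    n_train = int(round(train_fraction * n))
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"class(es) {bad.tolist()} have < 2 lesions; stratified split impossible")
    take = np.clip(np.rint(train_fraction * counts).astype(int), 1, counts - 1)
    # repair the total while respecting the 1..count-1 bounds
    order = np.argsort(-counts)
    while take.sum() != n_train:
        step = 1 if take.sum() < n_train else -1
        moved = False
        for c in order:
            if 1 <= take[c] + step <= counts[c] - 1:
                take[c] += step
                moved = True
                break
        if not moved:  # bounds make the target unreachable; accept closest
            break
    train_idx, test_idx = [], []
    for c, t in zip(classes, take):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        train_idx.append(idx[:t])
        test_idx.append(idx[t:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment spreading each class round-robin over k folds."""
    fold = np.empty(y.size, dtype=int)
    start = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        fold[idx] = (np.arange(idx.size) + start) % k
        start += idx.size  # stagger classes so folds stay balanced
    return fold


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Single L1-logistic fit at penalty lam (objective sum of deviances / n
    + lam * ||beta||_1); returns (coefficients, intercept)."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    C = 1.0 / (lam * X.shape[0])
    est = LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        intercept_scaling=100.0,  # keeps the intercept effectively unpenalized
        max_iter=500,
        tol=1e-8,
        random_state=0,
    )
    with warnings.catch_warnings():
        # the nearly-unpenalized end of the path on separable data cannot
        # converge to a finite optimum; the clipped solution is fine
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est.coef_[0].copy(), float(est.intercept_[0])


def _deviance(scores: np.ndarray, y: np.ndarray) -> float:
    from scipy.special import expit

    p = np.clip(expit(scores), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty path from lambda_max (all coefficients zero) down."""
    ybar = y.mean()
    lam_max = float(np.max(np.abs(X.T @ (y - ybar))) / X.shape[0])
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambdas)


def fit_lasso_logistic(
    X_train: np.ndarray,
    y_train: np.ndarray,
    inner_folds: int = 3,
    n_lambdas: int = 100,
    decades: float = 4.0,
    rng=None,
) -> dict:
    """LASSO-logistic fit with the penalty chosen by internal stratified
    k-fold CV minimizing mean held-out binomial deviance.

    Expects standardized, imputed features. Returns a dict with ``coef``,
    ``intercept``, ``lambda_``, ``selected`` (boolean array) and the CV
    deviance path.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train).astype(int)
    path = lambda_path(X_train, y_train, n_lambdas, decades)
    folds = _stratified_folds(y_train, inner_folds, rng)
    dev = np.zeros((inner_folds, path.size))
    for f in range(inner_folds):
        tr, va = folds != f, folds == f
        if len(np.unique(y_train[tr])) < 2:  # cannot happen with >=2 per class, but be safe
            dev[f] = np.nan
            continue
        for j, lam in enumerate(path):
            coef, b0 = _fit_l1(X_train[tr], y_train[tr], lam)
            dev[f, j] = _deviance(X_train[va] @ coef + b0, y_train[va])
    mean_dev = np.nanmean(dev, axis=0)
    best_j = int(np.argmin(mean_dev))  # first minimum = largest (sparsest) lambda
    lam_star = float(path[best_j])
    coef, b0 = _fit_l1(X_train, y_train, lam_star)
    return {
        "coef": coef,
        "intercept": b0,
        "lambda_": lam_star,
        "selected": np.abs(coef) > 1e-8,
        "cv_deviance": mean_dev,
        "lambda_path": path,
    }


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class ModelConfig:
    """Cross-validation settings for one model configuration."""

    config_id: str = "model"
    n_repeats: int = 30
    train_fraction: float = 2.0 / 3.0
    inner_folds: int = 3
    n_lambdas: int = 100
    lambda_decades: float = 4.0
    #: split at the lesion level (default) or grouped by patient
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1 or self.inner_folds < 2:
            raise ValueError("need n_repeats >= 1 and inner_folds >= 2")


class LassoLogisticCV:
    """Repeated LASSO-logistic CV model for a lesion feature table.

    Parameters
    ----------
    X : DataFrame
        Lesions x features; missing values allowed (median-imputed per
        training set).
    y : array-like
        Binary labels aligned with ``X`` rows (1 = ISUP 2+).
    config : ModelConfig
    groups : array-like, optional
        Patient ids per lesion; used only with ``config.group_by_patient``.
    """

    def __init__(self, X: pd.DataFrame, y, config: ModelConfig | None = None, groups=None):
        self.X = pd.DataFrame(X).astype(float)
        self.y = np.asarray(y).astype(int)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y length mismatch")
        if self.X.shape[0] == 0 or self.X.shape[1] == 0:
            raise ValueError("empty feature table")
        self.config = config or ModelConfig()
        self.groups = None if groups is None else np.asarray(groups)
        self.feature_names = list(self.X.columns)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        feature_cols: list[str] | None = None,
        group_col: str | None = None,
        config: ModelConfig | None = None,
    ) -> "LassoLogisticCV":
        if feature_cols is None:
            drop = {label_col} | ({group_col} if group_col else set())
            feature_cols = [c for c in df.columns if c not in drop and pd.api.types.is_numeric_dtype(df[c])]
        groups = df[group_col].to_numpy() if group_col else None
        return cls(df[feature_cols], df[label_col].to_numpy(), config=config, groups=groups)

    # -- splitting -----------------------------------------------------

    def _split(self, rng: np.random.Generator):
        if self.config.group_by_patient and self.groups is not None:
            return self._grouped_split(rng)
        return split_train_test(self.y, self.config.train_fraction, rng)

    def _grouped_split(self, rng: np.random.Generator, max_tries: int = 200):
        """Patient-grouped split: whole patients go to one side; retried
        until both classes appear on both sides."""
        patients = np.unique(self.groups)
        n_train = int(round(self.config.train_fraction * self.y.size))
        for _ in range(max_tries):
            perm = patients[rng.permutation(patients.size)]
            train_p, count = [], 0
            for p in perm:
                if count >= n_train:
                    break
                train_p.append(p)
                count += int(np.sum(self.groups == p))
            tr = np.flatnonzero(np.isin(self.groups, train_p))
            te = np.flatnonzero(~np.isin(self.groups, train_p))
            if te.size and len(np.unique(self.y[tr])) == 2 and len(np.unique(self.y[te])) == 2:
                return np.sort(tr), np.sort(te)
        raise ValueError("could not find a patient-grouped split with both classes on both sides")

    # -- fitting -------------------------------------------------------

    def fit(self, seed: int = 0) -> "RepeatedCVResults":
        cfg = self.config
        root = np.random.SeedSequence(seed)
        iter_seeds = root.spawn(cfg.n_repeats)
        Xall = self.X.to_numpy(dtype=float)
        records = []
        selections = np.zeros((cfg.n_repeats, len(self.feature_names)), dtype=bool)
        roc_store = {}
        for it in range(cfg.n_repeats):
            rng = np.random.default_rng(iter_seeds[it])
            try:
                tr, te = self._split(rng)
            except ValueError as err:
                raise ValueError(f"iteration {it}: {err}") from err
            Xtr, Xte = Xall[tr], Xall[te]
            ytr, yte = self.y[tr], self.y[te]
            # training-set medians and moments only: the test set is
            # transformed, never consulted
            med = np.nanmedian(Xtr, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            Xtr = np.where(np.isfinite(Xtr), Xtr, med)
            Xte = np.where(np.isfinite(Xte), Xte, med)
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
            fitres = fit_lasso_logistic(
                Xtr, ytr, cfg.inner_folds, cfg.n_lambdas, cfg.lambda_decades, rng
            )
            s_tr = Xtr @ fitres["coef"] + fitres["intercept"]
            s_te = Xte @ fitres["coef"] + fitres["intercept"]
            try:
                auc_tr = roc_auc(s_tr, ytr)
                auc_te = roc_auc(s_te, yte)
            except ValueError as err:
                raise ValueError(f"iteration {it}: {err}") from err
            selections[it] = fitres["selected"]
            records.append(
                dict(
                    iteration=it,
                    train_auc=auc_tr,
                    test_auc=auc_te,
                    lambda_=fitres["lambda_"],
                    n_selected=int(fitres["selected"].sum()),
                    selected=tuple(np.array(self.feature_names)[fitres["selected"]]),
                )
            )
            roc_store[it] = (
                roc_points(s_tr, ytr),
                roc_points(s_te, yte),
            )
        iterations = pd.DataFrame(records)
        freq = pd.Series(selections.mean(axis=0), index=self.feature_names, name="selection_frequency")
        return RepeatedCVResults(
            model=self,
            config=cfg,
            seed=seed,
            iterations=iterations,
            selection_frequencies=freq.sort_values(ascending=False, kind="stable"),
            _roc=roc_store,
        )


@dataclass
class RepeatedCVResults:
    """Results of a repeated LASSO-logistic cross-validation."""

    model: LassoLogisticCV
    config: ModelConfig
    seed: int
    iterations: pd.DataFrame
    selection_frequencies: pd.Series
    _roc: dict = field(default_factory=dict, repr=False)

    @property
    def n_lesions(self) -> int:
        return self.model.y.size

    @property
    def mean_train_auc(self) -> float:
        return float(self.iterations["train_auc"].mean())

    @property
    def mean_test_auc(self) -> float:
        return float(self.iterations["test_auc"].mean())

    @property
    def best_iteration(self) -> int:
        """Iteration with maximal test AUC; ties broken by train AUC, then index."""
        df = self.iterations
        order = df.sort_values(
            ["test_auc", "train_auc", "iteration"], ascending=[False, False, True], kind="stable"
        )
        return int(order.iloc[0]["iteration"])

    @property
    def best_train_auc(self) -> float:
        return float(self.iterations.loc[self.iterations["iteration"] == self.best_iteration, "train_auc"].iloc[0])

    @property
    def best_test_auc(self) -> float:
        return float(self.iterations.loc[self.iterations["iteration"] == self.best_iteration, "test_auc"].iloc[0])

    def best_roc(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(train, test) ROC coordinates of the best iteration."""
        return self._roc[self.best_iteration]

    def summary_row(self) -> dict:
        return dict(
            model_type=self.config.config_id,
            n_lesions=self.n_lesions,
            train_mean_auc=round(self.mean_train_auc, 3),
            test_mean_auc=round(self.mean_test_auc, 3),
            train_best_auc=round(self.best_train_auc, 3),
            test_best_auc=round(self.best_test_auc, 3),
        )

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Repeated LASSO-logistic CV -- {self.config.config_id}",
            f"  lesions: {self.n_lesions}   repeats: {self.config.n_repeats}   "
            f"train fraction: {self.config.train_fraction:.2f}   seed: {self.seed}",
            f"  mean AUC   train {self.mean_train_auc:.3f}   test {self.mean_test_auc:.3f}",
            f"  best AUC   train {self.best_train_auc:.3f}   test {self.best_test_auc:.3f}"
            f"   (iteration {self.best_iteration})",
            f"  top features by selection frequency:",
        ]
        for name, f in self.selection_frequencies.head(top).items():
            lines.append(f"    {f:5.2f}  {name}")
        return "\n".join(lines)


def run_repeated_cv(
    features: pd.DataFrame,
    labels,
    config: ModelConfig | None = None,
    seed: int = 0,
    groups=None,
) -> RepeatedCVResults:
    """Functional wrapper: build a :class:`LassoLogisticCV` and fit it."""
    return LassoLogisticCV(features, labels, config=config, groups=groups).fit(seed)


# ---------------------------------------------------------------------------
# the five model configurations


MODEL_IDS = ("a", "b", "c", "d", "e")
MODEL_NAMES = {
    "a": "PET",
    "b": "MRI",
    "c": "PET (MRI-visible)",
    "d": "MRI (PET-visible)",
    "e": "MRI+PET",
}


class ModelSuite:
    """The five model configurations on one cohort.

    (a) all PET-visible lesions, PET features; (b) all MRI-visible lesions,
    MRI features; (c) paired lesions, PET features; (d) paired lesions, MRI
    features; (e) paired lesions, both feature sets concatenated with
    modality prefixes.

    Feature tables are lesion-indexed wide DataFrames already restricted to
    the stability-filtered feature set; ``labels`` maps every lesion or
    pair index to its binary endpoint.
    """

    def __init__(
        self,
        pet_features: pd.DataFrame,
        mri_features: pd.DataFrame,
        paired_pet_features: pd.DataFrame,
        paired_mri_features: pd.DataFrame,
        labels: pd.Series,
        config: ModelConfig | None = None,
        groups: pd.Series | None = None,
    ):
        self.tables = {}
        base = config or ModelConfig()
        self._configs = {}
        paired_pet = paired_pet_features.add_prefix("pet.") if not paired_pet_features.empty else paired_pet_features
        paired_mri = paired_mri_features.add_prefix("mri.") if not paired_mri_features.empty else paired_mri_features
        combined = (
            paired_pet.join(paired_mri, how="inner")
            if not (paired_pet.empty or paired_mri.empty)
            else pd.DataFrame()
        )
        self.tables = {
            "a": pet_features.add_prefix("pet."),
            "b": mri_features.add_prefix("mri."),
            "c": paired_pet,
            "d": paired_mri,
            "e": combined,
        }
        for mid in MODEL_IDS:
            cfg = ModelConfig(**{**base.__dict__, "config_id": MODEL_NAMES[mid]})
            self._configs[mid] = cfg
        self.labels = labels
        self.groups = groups

    def fit(self, seed: int = 0) -> "SuiteResults":
        root = np.random.SeedSequence(seed)
        seeds = {mid: int(s.generate_state(1)[0] % (2**31)) for mid, s in zip(MODEL_IDS, root.spawn(len(MODEL_IDS)))}
        results: dict[str, RepeatedCVResults] = {}
        skipped: dict[str, str] = {}
        for mid in MODEL_IDS:
            table = self.tables[mid]
            if table.empty:
                skipped[mid] = "no lesions (empty feature table)"
                continue
            idx = table.index.intersection(self.labels.index)
            y = self.labels.loc[idx]
            if idx.empty:
                skipped[mid] = "no labeled lesions"
                continue
            if y.nunique() < 2 or y.value_counts().min() < 2:
                skipped[mid] = "fewer than 2 lesions in a class; stratified CV impossible"
                continue
            groups = self.groups.loc[idx].to_numpy() if self.groups is not None else None
            model = LassoLogisticCV(table.loc[idx], y.to_numpy(), config=self._configs[mid], groups=groups)
            results[mid] = model.fit(seeds[mid])
        return SuiteResults(results=results, skipped=skipped)


@dataclass
class SuiteResults:
    results: dict[str, RepeatedCVResults]
    skipped: dict[str, str]

    def summary_frame(self) -> pd.DataFrame:
        rows = [self.results[mid].summary_row() for mid in MODEL_IDS if mid in self.results]
        return pd.DataFrame(
            rows,
            columns=["model_type", "n_lesions", "train_mean_auc", "test_mean_auc", "train_best_auc", "test_best_auc"],
        )

    def summary(self) -> str:
        parts = [self.summary_frame().to_string(index=False)]
        for mid, reason in self.skipped.items():
            parts.append(f"model ({mid}) skipped: {reason}")
        return "\n".join(parts)


def build_model_suite(
    pet_features: pd.DataFrame,
    mri_features: pd.DataFrame,
    paired_pet_features: pd.DataFrame,
    paired_mri_features: pd.DataFrame,
    labels: pd.Series,
    config: ModelConfig | None = None,
    seed: int = 0,
    groups: pd.Series | None = None,
) -> SuiteResults:
    """Fit all five model configurations; returns results plus skip reasons."""
    suite = ModelSuite(
        pet_features, mri_features, paired_pet_features, paired_mri_features,
        labels, config=config, groups=groups,
    )
    return suite.fit(seed)
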