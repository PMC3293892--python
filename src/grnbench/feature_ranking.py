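"""Feature weighting, entropy-based recursive elimination, bootstrap, SAM.

Four multivariate weighting engines produce a non-negative relevance weight
per feature:

* LSVM    — absolute hyperplane coefficients of a linear soft-margin SVM;
* GSVM    — Gaussian-kernel SVM with the kernel-RFE criterion: the change in
            the margin objective when one feature is removed from the kernel;
* SRDA    — absolute coefficients of a spectral-regression discriminant
            (a ridge-regularized least-squares fit to the centered class
            indicator, solved in the dual);
* IRELIEF — iterative Relief: margin-based weights from probabilistic
            nearest hits/misses under a weighted L1 metric, iterated to a
            fixed point.

Rankings come from the Entropy-based Recursive Feature Elimination (ERFE)
schema: at each round the engine is refit on the surviving features and the
entropy of the normalized weight histogram decides how aggressively to
discard — when weights are concentrated (low entropy) the whole lowest
weight bin goes at once, otherwise a fixed fraction of the worst features.
Eliminated features fill the ranking from the bottom.

The Monte Carlo bootstrap schema wraps tuning + ranking in B external
stratified train/test splits (test data never touches tuning or ranking)
and aggregates per-split rankings by mean rank; the model size is the
minimizer of the split-averaged test error curve.

SAM is the univariate baseline: a moderated t statistic with a fudge
constant s0 chosen to stabilize its coefficient of variation, a permutation
null pooled across genes, and selection at an estimated false discovery
rate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .list_metrics import ConfusionCounts, RankedList, mcc

__all__ = [
    "MethodSpec",
    "RankingRun",
    "BootstrapSchema",
    "SamResult",
    "ErfeConfig",
    "default_method",
    "tune_hyperparams",
    "weight_features",
    "erfe_rank",
    "error_curve",
    "bootstrap_rank",
    "single_rank",
    "choose_n_features",
    "sam_test",
    "size_grid",
]

METHOD_NAMES = ("LSVM", "GSVM", "SRDA", "IRELIEF")


@dataclass(frozen=True)
class MethodSpec:
    """A weighting engine plus its (possibly tuned) hyperparameters.

    ``c`` is the SVM regularization, ``sigma`` the kernel bandwidth (GSVM,
    I-Relief) expressed in units of the median pairwise training distance,
    ``alpha`` the SRDA ridge penalty.  ``grid`` maps hyperparameter names to
    candidate values; tuning records the chosen point in the plain fields.
    """

    name: str
    c: float = 1.0
    sigma: float = 1.0
    alpha: float = 1.0
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.name!r}")


def default_method(name: str) -> MethodSpec:
    grids = {
        "LSVM": {"c": (0.1, 1.0, 10.0, 100.0)},
        "GSVM": {"c": (0.1, 1.0, 10.0), "sigma": (0.25, 0.5, 1.0, 2.0, 4.0)},
        "SRDA": {"alpha": (0.01, 0.1, 1.0, 10.0, 100.0)},
        "IRELIEF": {"sigma": (0.25, 0.5, 1.0, 2.0, 4.0)},
    }
    return MethodSpec(name=name, grid=grids[name])


@dataclass
class RankingRun:
    """Outcome of one ranking experiment on one dataset."""

    ranking: RankedList  # full permutation of feature indices, best first
    weights: np.ndarray  # aggregate relevance per feature (universe order)
    error_curve: dict  # model size -> error estimate
    n_star: int
    selected: frozenset
    method: MethodSpec
    mcc_value: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_star not in self.error_curve:
            raise ValueError("n_star must be a key of the error curve")
        if self.selected != frozenset(self.ranking.ids[: self.n_star]):
            raise ValueError("selected set must equal the top-n_star of the list")


@dataclass(frozen=True)
class BootstrapSchema:
    B: int = 100
    inner_folds: int = 3
    test_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ErfeConfig:
    bins: int = 10
    entropy_fraction: float = 0.5  # threshold = fraction * log(bins)
    fallback_fraction: float = 0.2


# ---------------------------------------------------------------------------
# Weighting engines
# ---------------------------------------------------------------------------
# All engines and classifiers standardize features with statistics of the
# data they are fitted on: gene-wise error variances are strongly
# heterogeneous (lognormal), and margin/distance-based methods would
# otherwise be dominated by the noisiest genes.

def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


class _Standardized:
    """Wrap a classifier with train-fitted feature standardization."""

    def __init__(self, base):
        self.base = base

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        self.base.fit((X - self.mu_) / self.sd_, y)
        return self

    def predict(self, X):
        return self.base.predict((np.asarray(X, dtype=float) - self.mu_) / self.sd_)


def _median_pairwise_l2(X: np.ndarray) -> float:
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(X), k=1)
    med = float(np.sqrt(np.median(d2[iu]))) if iu[0].size else 1.0
    return med if med > 0 else 1.0


def _median_pairwise_l1(X: np.ndarray) -> float:
    d = np.sum(np.abs(X[:, None, :] - X[None, :, :]), axis=-1)
    iu = np.triu_indices(len(X), k=1)
    med = float(np.median(d[iu])) if iu[0].size else 1.0
    return med if med > 0 else 1.0


def _lsvm_weights(X: np.ndarray, y: np.ndarray, spec: MethodSpec) -> np.ndarray:
    clf = SVC(kernel="linear", C=spec.c)
    clf.fit(X, y)
    return np.abs(clf.coef_.ravel())


def _gsvm_weights(X: np.ndarray, y: np.ndarray, spec: MethodSpec) -> np.ndarray:
    """Kernel-RFE criterion: |W^2 - W^2_(-f)| with the fitted dual weights."""
    sigma = spec.sigma * _median_pairwise_l2(X)
    gamma = 1.0 / (2.0 * sigma * sigma)
    clf = SVC(kernel="rbf", C=spec.c, gamma=gamma)
    clf.fit(X, y)
    sv = X[clf.support_]
    coef = clf.dual_coef_.ravel()  # alpha_i * y_i
    A = np.outer(coef, coef)
    diff = sv[:, None, :] - sv[None, :, :]  # (n_sv, n_sv, p)
    d2 = diff**2
    K = np.exp(-gamma * d2.sum(axis=-1))
    M = A * K
    # removing feature f multiplies K elementwise by exp(gamma * d2[..., f])
    crit = np.abs(
        np.einsum("ij,ijf->f", M, np.exp(gamma * d2)) - M.sum()
    )
    return crit


def _srda_weights(X: np.ndarray, y: np.ndarray, spec: MethodSpec) -> np.ndarray:
    w = _srda_coef(X, y, spec.alpha)
    return np.abs(w)


def _srda_coef(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge fit of the centered class indicator, solved in the dual."""
    Xc = X - X.mean(axis=0)
    t = np.where(y == 1, 1.0, -1.0)
    t = t - t.mean()
    n = len(y)
    G = Xc @ Xc.T + alpha * np.eye(n)
    a = np.linalg.solve(G, t)
    return Xc.T @ a


def _irelief_weights(
    X: np.ndarray,
    y: np.ndarray,
    spec: MethodSpec,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterative Relief weights: non-negative, unit-sum fixed point."""
    n, p = X.shape
    d = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, p)
    sigma = spec.sigma * _median_pairwise_l1(X)
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    diff_cls = y[:, None] != y[None, :]
    w = np.full(p, 1.0 / p)
    for _ in range(max_iter):
        D = d @ w  # weighted L1 distances (n, n)
        f = np.exp(-D / sigma)
        nu = np.zeros(p)
        for i in range(n):
            h_mask, m_mask = same[i], diff_cls[i]
            if not h_mask.any() or not m_mask.any():
                continue
            ph = f[i] * h_mask
            pm = f[i] * m_mask
            hs, ms = ph.sum(), pm.sum()
            if hs <= 0 or ms <= 0:
                continue
            nu += (pm / ms - ph / hs) @ d[i]
        w_new = np.maximum(nu, 0.0)
        s = w_new.sum()
        w_new = np.full(p, 1.0 / p) if s <= 0 else w_new / s
        delta = float(np.linalg.norm(w_new - w))
        w = w_new
        if delta < tol:
            break
    return w


_ENGINES = {
    "LSVM": _lsvm_weights,
    "GSVM": _gsvm_weights,
    "SRDA": _srda_weights,
    "IRELIEF": _irelief_weights,
}


def weight_features(spec: MethodSpec, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Non-negative relevance weight per feature (X is samples x features)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes to weight features")
    return _ENGINES[spec.name](_standardize(X), y, spec)


# ---------------------------------------------------------------------------
# Classifiers (for error curves / MCC)
# ---------------------------------------------------------------------------

class _SRDAClassifier:
    """Nearest-class-mean classifier in the SRDA projection."""

    def __init__(self, alpha: float):
        self.alpha = alpha

    def fit(self, X, y):
        self.w_ = _srda_coef(np.asarray(X, float), np.asarray(y), self.alpha)
        z = X @ self.w_
        self.mid_ = 0.5 * (z[y == 1].mean() + z[y == 0].mean())
        self.sign_ = 1.0 if z[y == 1].mean() >= z[y == 0].mean() else -1.0
        return self

    def predict(self, X):
        z = X @ self.w_
        return (self.sign_ * (z - self.mid_) > 0).astype(int)


def _classifier(spec: MethodSpec, X_train: np.ndarray):
    if spec.name in ("LSVM", "IRELIEF"):
        return _Standardized(SVC(kernel="linear", C=spec.c))
    if spec.name == "GSVM":
        sigma = spec.sigma * _median_pairwise_l2(_standardize(X_train))
        return _Standardized(
            SVC(kernel="rbf", C=spec.c, gamma=1.0 / (2.0 * sigma * sigma))
        )
    return _Standardized(_SRDAClassifier(spec.alpha))


def _cv_error(spec: MethodSpec, X: np.ndarray, y: np.ndarray, folds: int, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        clf = _classifier(spec, X[tr])
        clf.fit(X[tr], y[tr])
        errs.append(float(np.mean(clf.predict(X[te]) != y[te])))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

def tune_hyperparams(
    spec: MethodSpec, X: np.ndarray, y: np.ndarray, seed: int | None = None
) -> MethodSpec:
    """3-fold CV over the spec's grid, no feature ranking involved.

    Ties break toward the strongest regularization: smallest c, largest
    sigma, largest alpha.  I-Relief's bandwidth is scored by the error of a
    linear SVM on features rescaled by the I-Relief weights at that
    bandwidth (the classifier itself has no sigma).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to tune")
    if not spec.grid:
        return spec

    names = sorted(spec.grid)
    values = [spec.grid[k] for k in names]
    best: tuple | None = None
    best_spec = spec
    rng_seed = 0 if seed is None else int(seed) % (2**31)

    import itertools

    for combo in itertools.product(*values):
        cand = replace(spec, **dict(zip(names, combo)))
        if cand.name == "IRELIEF":
            err = _irelief_tune_error(cand, X, y, rng_seed)
        else:
            err = _cv_error(cand, X, y, 3, rng_seed)
        # tie-break key: error, then larger c is worse, smaller sigma worse,
        # smaller alpha worse
        key = (err, cand.c, -cand.sigma, -cand.alpha)
        if best is None or key < best:
            best = key
            best_spec = cand
    return best_spec


def _irelief_tune_error(spec: MethodSpec, X, y, seed) -> float:
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        w = _irelief_weights(_standardize(X[tr]), y[tr], spec)
        clf = _Standardized(SVC(kernel="linear", C=spec.c))
        clf.fit(X[tr] * w, y[tr])
        errs.append(float(np.mean(clf.predict(X[te] * w) != y[te])))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# ERFE
# ---------------------------------------------------------------------------

def _weight_entropy(w: np.ndarray, bins: int) -> tuple[float, np.ndarray]:
    """Entropy of the weight histogram plus the bin index of each feature."""
    wmax = float(w.max())
    if wmax <= 0:
        return np.log(bins), np.zeros(len(w), dtype=int)
    edges = np.linspace(0.0, wmax, bins + 1)
    idx = np.clip(np.searchsorted(edges, w, side="right") - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    q = counts[counts > 0] / len(w)
    return float(-np.sum(q * np.log(q))), idx


def erfe_order(
    spec: MethodSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: ErfeConfig = ErfeConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Full elimination order (best first) and final per-feature weights.

    Returns (ranking over original column indices, last-seen weight of each
    feature at its elimination round).
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < 2:
        return np.arange(p), np.ones(p)
    active = np.arange(p)
    worst_first: list[int] = []
    last_weight = np.zeros(p)
    threshold = config.entropy_fraction * np.log(config.bins)
    while len(active) > 1:
        w = weight_features(spec, X[:, active], y)
        s = w.sum()
        wn = w / s if s > 0 else np.full(len(w), 1.0 / len(w))
        last_weight[active] = wn
        H, bin_idx = _weight_entropy(wn, config.bins)
        if H < threshold:
            lowest = int(bin_idx.min())
            drop_mask = bin_idx == lowest
        else:
            k = max(1, int(np.floor(config.fallback_fraction * len(active))))
            order = np.argsort(wn, kind="stable")
            drop_mask = np.zeros(len(active), dtype=bool)
            drop_mask[order[:k]] = True
        if drop_mask.all():  # never eliminate the whole active set at once
            drop_mask[int(np.argmax(wn))] = False
        dropped = active[drop_mask]
        # within a batch, worse weights occupy worse ranks
        batch_order = dropped[np.argsort(wn[drop_mask], kind="stable")]
        worst_first.extend(batch_order.tolist())
        active = active[~drop_mask]
    if len(active) == 1:
        last_weight[active] = max(1.0, last_weight.max())
        worst_first.extend(active.tolist())
    ranking = np.asarray(worst_first[::-1], dtype=int)
    return ranking, last_weight


def size_grid(p: int) -> list[int]:
    """Geometric ladder of candidate model sizes: powers of two plus p."""
    sizes = []
    k = 1
    while k < p:
        sizes.append(k)
        k *= 2
    sizes.append(p)
    return sizes


def error_curve(
    ranking: np.ndarray,
    spec: MethodSpec,
    X: np.ndarray,
    y: np.ndarray,
    sizes: list[int],
    folds: int = 3,
    seed: int | None = None,
) -> dict[int, float]:
    """Internal stratified-CV misclassification at each candidate size."""
    curve = {}
    seed = 0 if seed is None else int(seed) % (2**31)
    for n in sizes:
        cols = ranking[:n]
        curve[n] = _cv_error(spec, X[:, cols], y, folds, seed)
    return curve


def choose_n_features(curve: dict[int, float]) -> int:
    """Size minimizing the error estimate; ties go to the smallest size."""
    if not curve:
        raise ValueError("empty error curve")
    return min(curve, key=lambda n: (curve[n], n))


def erfe_rank(
    spec: MethodSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    config: ErfeConfig = ErfeConfig(),
    tune: bool = True,
) -> RankingRun:
    """Single-run ERFE: tune, rank, estimate the error curve by internal CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if tune:
        spec = tune_hyperparams(spec, X, y, seed)
    ranking, weights = erfe_order(spec, X, y, config)
    sizes = size_grid(X.shape[1])
    curve = error_curve(ranking, spec, X, y, sizes, seed=seed)
    n_star = choose_n_features(curve)
    return RankingRun(
        ranking=RankedList(tuple(int(i) for i in ranking), p=X.shape[1]),
        weights=weights,
        error_curve=curve,
        n_star=n_star,
        selected=frozenset(int(i) for i in ranking[:n_star]),
        method=spec,
        seed=seed,
    )


def single_rank(
    spec: MethodSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    config: ErfeConfig = ErfeConfig(),
    folds: int = 3,
) -> RankingRun:
    """Single cross-validation mode: one honest stratified CV loop.

    The reported ranking is fit on the whole dataset; the error curve is
    selection-bias-free: within each CV fold the tuned engine re-ranks the
    training part only, and per-size classifiers trained on that fold's
    ranking are scored on the held-out part.  The chosen size n* minimizes
    the fold-averaged error; the MCC is computed from the summed held-out
    confusion counts at n*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    spec = tune_hyperparams(spec, X, y, seed)
    ranking, weights = erfe_order(spec, X, y, config)
    sizes = size_grid(X.shape[1])
    base = 0 if seed is None else int(seed) % (2**31)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=base)
    err_sum = {n: 0.0 for n in sizes}
    conf = {n: [0, 0, 0, 0] for n in sizes}
    for tr, te in skf.split(X, y):
        fold_ranking, _ = erfe_order(spec, X[tr], y[tr], config)
        for n in sizes:
            cols = fold_ranking[:n]
            clf = _classifier(spec, X[tr][:, cols])
            clf.fit(X[tr][:, cols], y[tr])
            pred = clf.predict(X[te][:, cols])
            err_sum[n] += float(np.mean(pred != y[te]))
            conf[n][0] += int(np.sum((pred == 1) & (y[te] == 1)))
            conf[n][1] += int(np.sum((pred == 0) & (y[te] == 0)))
            conf[n][2] += int(np.sum((pred == 1) & (y[te] == 0)))
            conf[n][3] += int(np.sum((pred == 0) & (y[te] == 1)))
    curve = {n: err_sum[n] / folds for n in sizes}
    n_star = choose_n_features(curve)
    tp, tn, fp, fn = conf[n_star]
    return RankingRun(
        ranking=RankedList(tuple(int(i) for i in ranking), p=X.shape[1]),
        weights=weights,
        error_curve=curve,
        n_star=n_star,
        selected=frozenset(int(i) for i in ranking[:n_star]),
        method=spec,
        mcc_value=mcc(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Monte Carlo bootstrap schema
# ---------------------------------------------------------------------------

def _stratified_split(
    y: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        n_test = min(n_test, len(idx) - 2)  # keep >= 2 per class in train
        test.extend(idx[:n_test].tolist())
        train.extend(idx[n_test:].tolist())
    return np.asarray(sorted(train)), np.asarray(sorted(test))


def bootstrap_rank(
    spec: MethodSpec,
    X: np.ndarray,
    y: np.ndarray,
    schema: BootstrapSchema,
    seed: int | None = None,
    config: ErfeConfig = ErfeConfig(),
) -> RankingRun:
    """B external train/test splits; aggregate ranking by mean rank.

    Tuning and ERFE see only each split's training part; the held-out part
    supplies the error curve (and confusion counts for the MCC at the
    chosen size).  The aggregate list sorts features by mean rank across
    splits, ties broken by mean weight; the aggregate error curve is the
    split-mean test error and n* its minimizer.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    sizes = size_grid(p)
    rank_sum = np.zeros(p)
    weight_sum = np.zeros(p)
    err_sum = {n: 0.0 for n in sizes}
    conf = {n: [0, 0, 0, 0] for n in sizes}  # tp, tn, fp, fn
    tuned_last = spec
    attempts = 0
    b = 0
    while b < schema.B:
        if attempts > 10 * schema.B:
            raise RuntimeError("could not draw enough two-class training splits")
        attempts += 1
        tr, te = _stratified_split(y, schema.test_fraction, rng)
        if len(np.unique(y[tr])) < 2:
            continue
        split_seed = int(rng.integers(2**31))
        tuned = tune_hyperparams(spec, X[tr], y[tr], split_seed)
        ranking, weights = erfe_order(tuned, X[tr], y[tr], config)
        pos = np.empty(p)
        pos[ranking] = np.arange(1, p + 1)
        rank_sum += pos
        weight_sum += weights
        for n in sizes:
            cols = ranking[:n]
            clf = _classifier(tuned, X[tr][:, cols])
            clf.fit(X[tr][:, cols], y[tr])
            pred = clf.predict(X[te][:, cols])
            err_sum[n] += float(np.mean(pred != y[te]))
            conf[n][0] += int(np.sum((pred == 1) & (y[te] == 1)))
            conf[n][1] += int(np.sum((pred == 0) & (y[te] == 0)))
            conf[n][2] += int(np.sum((pred == 1) & (y[te] == 0)))
            conf[n][3] += int(np.sum((pred == 0) & (y[te] == 1)))
        tuned_last = tuned
        b += 1
    mean_rank = rank_sum / schema.B
    mean_weight = weight_sum / schema.B
    order = sorted(range(p), key=lambda f: (mean_rank[f], -mean_weight[f], f))
    curve = {n: err_sum[n] / schema.B for n in sizes}
    n_star = choose_n_features(curve)
    tp, tn, fp, fn = conf[n_star]
    return RankingRun(
        ranking=RankedList(tuple(order), p=p),
        weights=mean_weight,
        error_curve=curve,
        n_star=n_star,
        selected=frozenset(order[:n_star]),
        method=tuned_last,
        mcc_value=mcc(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    d: np.ndarray  # moderated statistic per gene
    s0: float
    p_values: np.ndarray
    q_values: np.ndarray
    selected: frozenset
    order: np.ndarray  # gene indices by increasing p-value (best first)
    fdr: float


def _group_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (mean difference, pooled standard error) for samples x genes X."""
    g1, g0 = X[y == 1], X[y == 0]
    n1, n0 = len(g1), len(g0)
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    pooled = ss / (n1 + n0 - 2)
    se = np.sqrt((1.0 / n1 + 1.0 / n0) * pooled)
    return m1 - m0, se


def _choose_s0(diff: np.ndarray, se: np.ndarray) -> float:
    """Fudge constant minimizing the coefficient of variation of |d| across
    windows of the standard-error distribution (percentile grid 0..100)."""
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(se, percentiles)
    # windows of se for the cv computation
    qs = np.percentile(se, np.arange(0, 101, 10))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = diff / (se + s0)
        mads = []
        for lo, hi in zip(qs[:-1], qs[1:]):
            m = (se >= lo) & (se <= hi)
            if m.sum() >= 3:
                vals = d[m]
                mads.append(np.median(np.abs(vals - np.median(vals))) / 0.64)
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(
    y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    n = len(y)
    n1 = int(np.sum(y == 1))
    from math import comb

    if comb(n, n1) <= n_perm:
        perms = []
        for pos in combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(pos)] = 1
            perms.append(lab)
        return perms
    return [rng.permutation(y) for _ in range(n_perm)]


def sam_test(
    X: np.ndarray,
    y: np.ndarray,
    fdr: float = 0.05,
    n_perm: int = 200,
    seed: int | None = None,
    s0: float | None = None,
) -> SamResult:
    """Moderated-t selection with a permutation null pooled across genes.

    ``X`` is samples x genes.  Genes are ranked by permutation p-value
    (equivalently by |d|, since the null is pooled across genes); q-values
    come from the Benjamini-Hochberg step-up on the pooled permutation
    p-values, and selection keeps genes with q <= ``fdr``.  (Estimating the
    per-cutoff FDR as the median null exceedance count over the observed
    count mis-calibrates at the top of the list: the observed maximum is
    exchangeable with the per-permutation maxima, so the strongest gene
    would be "confirmed" by half the permutations even under a global
    null.)
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for the SAM test")
    rng = np.random.default_rng(seed)
    diff, se = _group_stats(X, y)
    if s0 is None:
        s0 = _choose_s0(diff, se)
    d = diff / (se + s0)
    abs_d = np.abs(d)
    p = X.shape[1]

    perms = _label_permutations(y, n_perm, rng)
    null = np.empty((len(perms), p))
    for k, lab in enumerate(perms):
        pdiff, pse = _group_stats(X, lab)
        null[k] = np.abs(pdiff / (pse + s0))

    # pooled permutation p-values (+1 smoothing)
    flat = np.sort(null.ravel())
    exceed = flat.size - np.searchsorted(flat, abs_d, side="left")
    p_values = (1.0 + exceed) / (1.0 + flat.size)

    order = np.lexsort((np.arange(p), -abs_d))  # best (largest |d|) first
    # Benjamini-Hochberg step-up on the pooled permutation p-values
    p_sorted = p_values[order]
    k_arr = np.arange(1, p + 1)
    q_sorted = np.minimum.accumulate((p_sorted * p / k_arr)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q_values = np.empty(p)
    q_values[order] = q_sorted

    passing = np.flatnonzero(q_sorted <= fdr)
    selected = frozenset(int(g) for g in order[: passing[-1] + 1]) if passing.size else frozenset()
    return SamResult(
        d=d,
        s0=float(s0),
        p_values=p_values,
        q_values=q_values,
        selected=selected,
        order=order,
        fdr=fdr,
    )
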