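"""Tiered minimal-signature feature selection.

The selector wraps three binary classifiers (PLS-DA, random forest, linear
SVM) in rounds of: stratified bootstrap train/test splits, per-classifier
feature-importance ranking, a within-test-set permutation relevance test, and
a half-interval (binary) search for the smallest relevant prefix of the
ranking.  The dataset is then restricted to the selected features and the
round repeats until the selection is stable or ``max_rounds`` is reached.

A candidate feature set is *relevant* when predictions made after randomly
permuting the test-set intensities of all other features remain significantly
more accurate than the no-information (majority-class) rate — a one-sided
binomial test at ``alpha`` pooled over the bootstrap test sets.  With
``alpha = 1`` every candidate passes (degenerate bound); an uninformative
table passes nothing, so the null selection is empty.

Tier semantics per classifier: **S** — selected in every round including the
final one; **A** — selected in every round except the final; **E** — selected
in at least one earlier round only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .preprocess import FeatureTable
from .pls import _nipals, _vip_scores

__all__ = [
    "CLASSIFIERS",
    "SelectorConfig",
    "TierResult",
    "stratified_bootstrap_split",
    "importance_rank",
    "relevance_test",
    "half_interval_search",
    "select_signature",
    "signature_performance",
]

CLASSIFIERS = ("plsda", "random_forest", "svm")
_EPS = 1e-12


@dataclass
class SelectorConfig:
    classifiers: tuple[str, ...] = CLASSIFIERS
    n_boot: int = 50
    test_fraction: float = 0.2
    alpha: float = 0.05
    max_rounds: int = 10
    seed: int = 0
    rf_estimators: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 0.5:
            raise ValueError("test_fraction must be in (0, 0.5)")
        if self.n_boot < 10:
            raise ValueError("n_boot must be >= 10")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


@dataclass
class TierResult:
    """Per-classifier feature tiers and per-round bookkeeping."""

    tiers: dict[str, dict[str, str]]
    rounds_run: dict[str, int]
    selections: dict[str, list[list[str]]]
    accuracy: dict[str, list[float]]

    def tier_set(self, classifier: str, tier: str) -> set[str]:
        return {f for f, t in self.tiers[classifier].items() if t == tier}

    def union(self, tiers=("S", "A")) -> set[str]:
        """Features in any of the given tiers for any classifier."""
        out: set[str] = set()
        for clf in self.tiers:
            for t in tiers:
                out |= self.tier_set(clf, t)
        return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def stratified_bootstrap_split(
    y, test_fraction: float, rng: np.random.Generator, max_tries: int = 100
):
    """Bootstrap training set with class proportions preserved; test = OOB.

    The training set is drawn with replacement per class (so the class ratio
    matches the data within one sample); the test set is the out-of-bag
    remainder, subsampled to ``test_fraction`` of the data if larger.  Both
    sets are guaranteed to contain both classes.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    n = len(y)
    target = max(2, round(test_fraction * n))
    for _ in range(max_tries):
        train = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=int(k), replace=True)
            for c, k in zip(classes, counts)
        ])
        oob = np.setdiff1d(np.arange(n), train)
        if len(oob) < 2 or len(np.unique(y[oob])) < 2:
            continue
        if len(oob) > target:
            keep = []
            for c in classes:
                members = oob[y[oob] == c]
                frac = len(members) / len(oob)
                k = max(1, round(frac * target))
                keep.append(rng.choice(members, size=min(k, len(members)), replace=False))
            oob = np.sort(np.concatenate(keep))
        return np.sort(train), oob
    raise RuntimeError("could not draw a split with both classes out-of-bag")


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class _Fitted:
    """Uniform adapter: predict(X) -> 0/1 labels, plus feature importances."""

    def __init__(self, predict, importance):
        self.predict = predict
        self.importance = importance


def _fit_classifier(name: str, X: np.ndarray, y01: np.ndarray, rng, cfg) -> _Fitted:
    n, p = X.shape
    if len(np.unique(y01)) < 2 or n < 4:
        raise ValueError("degenerate training set")
    if name == "plsda":
        yc = y01 - y01.mean()
        n_comp = max(1, min(2, n - 2, p))
        W, P, T, C, _, _ = _nipals(X, yc, n_comp, 200, 1e-10)
        Wstar = W @ np.linalg.inv(P.T @ W)
        B = Wstar @ C
        y_mean = y01.mean()

        def predict(Xn, B=B, y_mean=y_mean):
            return (Xn @ B + y_mean >= 0.5).astype(int)

        return _Fitted(predict, _vip_scores(W, T, C))
    if name == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=cfg.rf_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(X, y01)
        return _Fitted(lambda Xn: clf.predict(Xn), clf.feature_importances_)
    if name == "svm":
        clf = SVC(kernel="linear", C=1.0).fit(X, y01)
        return _Fitted(lambda Xn: clf.predict(Xn), np.abs(clf.coef_[0]))
    raise ValueError(f"unknown classifier {name!r}")


def importance_rank(
    classifier: str, X: np.ndarray, y, features: list[str],
    rng: np.random.Generator | None = None,
    config: SelectorConfig | None = None,
) -> list[str]:
    """Feature names in decreasing importance (VIP / impurity decrease /
    \\|linear-SVM weight\\|), deterministic name tie-break."""
    cfg = config or SelectorConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    y01 = _to_binary(y)
    fitted = _fit_classifier(classifier, np.asarray(X, float), y01, rng, cfg)
    imp = fitted.importance
    order = sorted(range(len(features)), key=lambda j: (-imp[j], features[j]))
    return [features[j] for j in order]


def _to_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return np.array([classes.index(v) for v in y], dtype=int)


# ---------------------------------------------------------------------------
# relevance testing and half-interval search
# ---------------------------------------------------------------------------

def relevance_test(
    model, X_test: np.ndarray, y_test: np.ndarray,
    candidate_idx, alpha: float, rng: np.random.Generator,
) -> bool:
    """Is the candidate feature set sufficient for above-chance prediction?

    All non-candidate columns of the test matrix are permuted within-column;
    the candidate passes when the resulting accuracy is significantly above
    the majority-class rate (one-sided binomial, level ``alpha``).
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    n, p = X_test.shape
    if n < 5:
        raise ValueError("test set must have at least 5 samples")
    cand = np.zeros(p, dtype=bool)
    cand[list(candidate_idx)] = True
    Xp = X_test.copy()
    for j in np.flatnonzero(~cand):
        Xp[:, j] = Xp[rng.permutation(n), j]
    pred = model.predict(Xp)
    k = int((pred == y_test).sum())
    p0 = max(np.mean(y_test == c) for c in np.unique(y_test))
    pval = stats.binom.sf(k - 1, n, p0)
    return bool(pval < alpha)


def half_interval_search(ranked: list, oracle) -> list:
    """Smallest prefix of ``ranked`` passing ``oracle`` (binary search).

    Under a monotone oracle this equals the exhaustive prefix scan while
    using at most ceil(log2(p)) + 1 oracle calls.  The candidate found by
    the search is verified before being returned; [] when nothing passes.
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    cache: dict[int, bool] = {}

    def _probe(k: int) -> bool:
        if k not in cache:
            cache[k] = bool(oracle(list(ranked[:k])))
        return cache[k]

    lo, hi = 1, len(ranked)
    while lo < hi:
        mid = (lo + hi) // 2
        if _probe(mid):
            hi = mid
        else:
            lo = mid + 1
    return list(ranked[:lo]) if _probe(lo) else []


# ---------------------------------------------------------------------------
# the iterated selector
# ---------------------------------------------------------------------------

def _majority_correct(votes: np.ndarray, appearances: np.ndarray) -> int:
    """Samples whose out-of-bag majority-vote prediction is correct (strict)."""
    seen = appearances > 0
    return int((votes[seen] > appearances[seen] / 2).sum())


def _run_round(X, y01, features, clf_name, cfg, rng, n_candidates=None):
    """One selection round; returns (selected features, intact OOB accuracy).

    Accuracy is aggregated per *sample* (majority vote over the bootstrap
    test sets it appears in) so the binomial relevance tests count
    independent units rather than correlated pooled predictions.  A prefix
    is selected when its permuted-complement accuracy is (a) significantly
    above the majority-class rate and (b) not significantly below the intact
    accuracy, both one-sided at the Bonferroni-corrected per-probe level.
    """
    n, p = X.shape
    splits = [
        stratified_bootstrap_split(y01, cfg.test_fraction, rng)
        for _ in range(cfg.n_boot)
    ]
    rank_sum = np.zeros(p)
    models, tests, perms = [], [], []
    appearances = np.zeros(n)
    intact_votes = np.zeros(n)
    for tr, te in splits:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd < _EPS] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        m = _fit_classifier(clf_name, Xtr, y01[tr], rng, cfg)
        imp = m.importance
        order = sorted(range(p), key=lambda j: (-imp[j], features[j]))
        ranks = np.empty(p)
        ranks[order] = np.arange(p)
        rank_sum += ranks
        pred = m.predict(Xte)
        appearances[te] += 1
        intact_votes[te] += pred == y01[te]
        models.append(m)
        tests.append((te, Xte, y01[te]))
        # fixed per-bootstrap column permutations keep the relevance oracle a
        # deterministic function of the candidate set
        perms.append(np.argsort(rng.random((len(te), p)), axis=0))

    order = sorted(range(p), key=lambda j: (rank_sum[j], features[j]))
    ranked = [features[j] for j in order]
    name_to_col = {f: j for j, f in enumerate(features)}
    seen = appearances > 0
    n_eff = int(seen.sum())
    pos = int((y01[seen] == 1).sum())
    p0 = max(pos, n_eff - pos) / n_eff
    intact_correct = _majority_correct(intact_votes, appearances)
    acc_intact = intact_correct / n_eff
    # the tested prefix is the top of an importance ranking over the round's
    # candidate features, so the null of the chance test is a maximum over
    # many spuriously correlated features; Bonferroni-correct the level by
    # the number of candidates the selection started from (restriction does
    # not refresh the data the maximum was selected on, so the original
    # count is carried through later rounds)
    alpha_eff = cfg.alpha / (n_candidates or p)

    def oracle(prefix: list) -> bool:
        cand = np.zeros(p, dtype=bool)
        cand[[name_to_col[f] for f in prefix]] = True
        votes = np.zeros(n)
        for m, (te, Xte, yte), perm in zip(models, tests, perms):
            Xp = np.take_along_axis(Xte, perm, axis=0)
            Xp[:, cand] = Xte[:, cand]
            votes[te] += m.predict(Xp) == yte
        correct = _majority_correct(votes, appearances)
        above_chance = stats.binom.sf(correct - 1, n_eff, p0) < alpha_eff
        no_drop = stats.binom.cdf(correct, n_eff, acc_intact) >= cfg.alpha
        return bool(above_chance and no_drop)

    selected = half_interval_search(ranked, oracle)
    return sorted(selected), acc_intact


def select_signature(table: FeatureTable, config: SelectorConfig | None = None) -> TierResult:
    """Run the iterated bootstrap selector for every configured classifier."""
    cfg = config or SelectorConfig()
    if table.n_samples < 10:
        raise ValueError("selector needs at least 10 samples")
    X_full = np.asarray(table.X, dtype=float)
    y01 = _to_binary(table.y)
    seed_seq = np.random.SeedSequence(cfg.seed)
    children = seed_seq.spawn(len(CLASSIFIERS))

    tiers: dict[str, dict[str, str]] = {}
    rounds_run: dict[str, int] = {}
    selections: dict[str, list[list[str]]] = {}
    accuracy: dict[str, list[float]] = {}
    for ci, clf_name in enumerate(CLASSIFIERS):
        if clf_name not in cfg.classifiers:
            continue
        rng = np.random.default_rng(children[ci])
        features = list(table.features)
        sels: list[list[str]] = []
        accs: list[float] = []
        for _ in range(cfg.max_rounds):
            cols = [table.features.index(f) for f in features]
            sel, acc = _run_round(X_full[:, cols], y01, features, clf_name,
                                  cfg, rng, n_candidates=table.n_features)
            sels.append(sel)
            accs.append(acc)
            if not sel:
                break
            if len(sels) >= 2 and sel == sels[-2]:
                break
            features = sel

        tier_map = {f: "none" for f in table.features}
        nonempty = [set(s) for s in sels if s]
        final = set(sels[-1]) if sels else set()
        if final and len(nonempty) == len(sels):
            s_tier = set.intersection(*nonempty)
        else:
            s_tier = set()
        if len(sels) >= 2:
            earlier = [set(s) for s in sels[:-1]]
            a_tier = (set.intersection(*earlier) - final) if all(earlier) else set()
        else:
            a_tier = set()
        ever = set().union(*[set(s) for s in sels]) if sels else set()
        for f in ever - s_tier - a_tier:
            tier_map[f] = "E"
        for f in a_tier:
            tier_map[f] = "A"
        for f in s_tier:
            tier_map[f] = "S"
        tiers[clf_name] = tier_map
        rounds_run[clf_name] = len(sels)
        selections[clf_name] = sels
        accuracy[clf_name] = accs
    return TierResult(tiers, rounds_run, selections, accuracy)


# ---------------------------------------------------------------------------
# performance of a fixed signature
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV in percent; NaN where undefined."""
    def _ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def signature_performance(
    table: FeatureTable,
    signature: list[str],
    config: SelectorConfig | None = None,
    classifier: str = "plsda",
    pos_label=None,
) -> dict:
    """Bootstrap test-set performance of a fixed feature signature.

    Refits the classifier on bootstrap training sets restricted to the
    signature and averages sensitivity/specificity/PPV/NPV over the test
    sets; splits where a metric's denominator is empty are excluded from
    that metric's mean and counted in ``n_undefined``.
    """
    if not signature:
        raise ValueError("signature is empty")
    cfg = config or SelectorConfig()
    sub = table.select(signature)
    X = np.asarray(sub.X, dtype=float)
    y01 = _to_binary(sub.y)
    classes = sorted(set(np.asarray(sub.y).tolist()))
    pos = classes.index(pos_label) if pos_label is not None else 0
    rng = np.random.default_rng(cfg.seed)
    metrics = {k: [] for k in ("sensitivity", "specificity", "ppv", "npv")}
    for _ in range(cfg.n_boot):
        tr, te = stratified_bootstrap_split(y01, cfg.test_fraction, rng)
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd < _EPS] = 1.0
        m = _fit_classifier(classifier, (X[tr] - mu) / sd, y01[tr], rng, cfg)
        pred = m.predict((X[te] - mu) / sd)
        yte = y01[te]
        tp = int(((pred == pos) & (yte == pos)).sum())
        fn = int(((pred != pos) & (yte == pos)).sum())
        tn = int(((pred != pos) & (yte != pos)).sum())
        fp = int(((pred == pos) & (yte != pos)).sum())
        for k, v in confusion_metrics(tp, fn, tn, fp).items():
            metrics[k].append(v)
    out = {}
    n_undef = {}
    for k, vals in metrics.items():
        arr = np.asarray(vals)
        defined = arr[~np.isnan(arr)]
        out[k] = float(defined.mean()) if len(defined) else float("nan")
        n_undef[k] = int(np.isnan(arr).sum())
    out["n_undefined"] = n_undef
    return out
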