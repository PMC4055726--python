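"""Binary classification trees (CART) with Gini growing, weakest-link
cost-complexity pruning, repeated 10-fold cross-validation, 1-SE selection,
and classification metrics.

Conventions, all deterministic:

* numeric splits: ``value < threshold`` goes left; thresholds are midpoints
  between consecutive distinct sorted values;
* categorical splits: the left branch takes an explicit category subset;
  candidate subsets are the nonempty proper subsets that exclude the highest
  observed category (each two-way partition enumerated once), in ascending
  bitmask order;
* ties in Gini improvement are broken by earlier variable in declared column
  order, then by smaller threshold (numeric) or earlier subset (categorical);
* splits must improve the Gini criterion by more than ``MIN_IMPROVEMENT``
  (guards float noise around structurally tied partitions);
* leaf prediction is the majority class, ties predicting class 0 (absent);
* risks in the pruning path and CV are *relative*: misclassification risk
  divided by the root (majority-class) risk, so the root scores 1.

The pruning path follows the standard cost-complexity construction: the
first recorded subtree is the smallest subtree with the full tree's training
risk (splits with zero risk gain collapse at alpha 0), and alphas strictly
increase down to the root.  Cross-validation evaluates each fold's tree at
the geometric means of consecutive master-path alphas, and the standard
error of the cross-validated relative error follows the per-case-loss
convention of rpart: ``sqrt(mean((L - mean L)^2) / n) / root_risk`` for the
0/1 case losses L.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_IMPROVEMENT = 1e-9


@dataclass
class CartParams:
    """Growth controls (defaults follow the classic recursive-partitioning
    tool: a node needs min_split cases to be split, children keep at least
    min_leaf cases, and depth is capped at max_depth)."""

    min_split: int = 20
    min_leaf: int = 7
    max_depth: int = 30


@dataclass
class SplitRule:
    variable: str
    kind: str  # numeric | categorical
    threshold: float | None = None
    left_categories: frozenset | None = None

    def describe(self) -> str:
        if self.kind == "numeric":
            return f"{self.variable} >= {self.threshold:g} -> right"
        cats = ",".join(str(c) for c in sorted(self.left_categories))
        return f"{self.variable} in {{{cats}}} -> left"


@dataclass
class TreeNode:
    node_id: int
    n: int
    class_counts: tuple[int, int]  # (n_absent, n_present)
    depth: int
    split: SplitRule | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    improvement: float = 0.0  # n * (gini - weighted child gini), count units
    collapse_alpha: float = np.inf  # complexity at which this node becomes a leaf

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def predicted_class(self) -> int:
        n0, n1 = self.class_counts
        return 1 if n1 > n0 else 0

    @property
    def risk(self) -> int:
        """Misclassification count if this node predicts its majority class."""
        return min(self.class_counts)


@dataclass
class ClassificationTree:
    root: TreeNode
    params: CartParams
    columns: list[str]
    categorical: dict[str, list]  # variable -> ordered category levels
    n: int
    root_risk: int  # misclassification count of the majority-class predictor
    pruning_sequence: list[tuple[float, int, float]] = field(default_factory=list)
    # modal-tree metadata, populated by modal_optimal_tree
    modal_size: int | None = None
    size_counts: dict[int, int] | None = None
    first_split_counts: dict[str, int] | None = None

    def n_leaves(self, alpha: float = -1.0) -> int:
        return _count_leaves(self.root, alpha)

    def split_variables(self, alpha: float = -1.0) -> list[str]:
        """Variables used by splits of the subtree at complexity ``alpha``
        (default: the tree as stored), in preorder."""
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf or node.collapse_alpha <= alpha:
                return
            out.append(node.split.variable)
            walk(node.children[0])
            walk(node.children[1])

        walk(self.root)
        return out


@dataclass
class CVResult:
    sizes: np.ndarray  # candidate n_leaves, decreasing alpha order reversed
    alphas: np.ndarray
    rel_errors: np.ndarray  # training relative error per candidate
    xerrors: np.ndarray
    xstds: np.ndarray
    k: int
    seed: int


@dataclass
class ModelEvaluation:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def misclassification(self) -> float:
        return (self.fn + self.fp) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def misclassification_pct(self) -> int:
        # display rounding, half up
        return int(np.floor(100 * self.misclassification + 0.5))

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def gini(class_counts) -> float:
    """Gini impurity 1 - sum(p_i^2); in [0, 0.5] for two classes."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValueError(f"class counts must be non-negative and not all zero: {class_counts}")
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


def _impurity_n(n0, n1):
    """n * gini in count units; vectorized over arrays of counts."""
    n = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n - (n0 * n0 + n1 * n1) / n
    return np.where(n > 0, out, 0.0)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


class _Design:
    """Column store: numeric columns as float arrays, categorical columns as
    integer codes over sorted observed levels."""

    def __init__(self, X: pd.DataFrame, categorical: tuple[str, ...]):
        self.columns = list(X.columns)
        self.categorical: dict[str, list] = {}
        self.data: dict[str, np.ndarray] = {}
        for col in self.columns:
            vals = X[col].to_numpy()
            if col in categorical:
                levels = sorted(pd.unique(vals).tolist())
                self.categorical[col] = levels
                lookup = {v: i for i, v in enumerate(levels)}
                self.data[col] = np.array([lookup[v] for v in vals], dtype=np.int64)
            else:
                arr = np.asarray(vals, dtype=float)
                if np.any(~np.isfinite(arr)):
                    raise ValueError(f"column {col!r} contains missing or non-finite values")
                self.data[col] = arr

    @property
    def n(self) -> int:
        return len(next(iter(self.data.values())))


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------


def _best_split(design: _Design, y: np.ndarray, idx: np.ndarray, min_leaf: int):
    """Best (rule, improvement, left_mask) at a node, or None."""
    n = idx.size
    n1 = int(y[idx].sum())
    n0 = n - n1
    parent_imp = float(_impurity_n(n0, n1))
    best = None
    best_gain = MIN_IMPROVEMENT
    for col in design.columns:
        vals = design.data[col][idx]
        yy = y[idx]
        if col in design.categorical:
            levels = design.categorical[col]
            k = len(levels)
            obs = np.unique(vals)
            if obs.size < 2:
                continue
            cnt1 = np.bincount(vals[yy == 1], minlength=k).astype(float)
            cnt = np.bincount(vals, minlength=k).astype(float)
            obs_list = [int(c) for c in obs]
            m = len(obs_list)
            for bits in range(1, 1 << (m - 1)):
                left = [obs_list[j] for j in range(m - 1) if bits >> j & 1]
                ln = sum(cnt[c] for c in left)
                ln1 = sum(cnt1[c] for c in left)
                rn = n - ln
                rn1 = n1 - ln1
                if ln < min_leaf or rn < min_leaf:
                    continue
                gain = parent_imp - float(
                    _impurity_n(ln - ln1, ln1) + _impurity_n(rn - rn1, rn1)
                )
                if gain > best_gain:
                    best_gain = gain
                    left_set = frozenset(levels[c] for c in left)
                    rule = SplitRule(col, "categorical", left_categories=left_set)
                    best = (rule, gain, np.isin(vals, left))
        else:
            order = np.argsort(vals, kind="stable")
            sv = vals[order]
            sy = yy[order]
            c1 = np.cumsum(sy)
            pos = np.arange(1, n)
            distinct = sv[1:] > sv[:-1]
            ok = distinct & (pos >= min_leaf) & (n - pos >= min_leaf)
            if not ok.any():
                continue
            ln = pos[ok].astype(float)
            ln1 = c1[:-1][ok].astype(float)
            rn = n - ln
            rn1 = n1 - ln1
            gains = parent_imp - (
                _impurity_n(ln - ln1, ln1) + _impurity_n(rn - rn1, rn1)
            )
            j = int(np.argmax(gains))
            if gains[j] > best_gain:
                best_gain = float(gains[j])
                i = pos[ok][j]
                thr = (sv[i - 1] + sv[i]) / 2.0
                rule = SplitRule(col, "numeric", threshold=float(thr))
                best = (rule, best_gain, vals < thr)
    return best


def grow_tree(
    X: pd.DataFrame,
    y,
    params: CartParams | None = None,
    categorical: tuple[str, ...] = (),
) -> ClassificationTree:
    """Grow a binary classification tree by recursive best-first Gini splits."""
    params = params or CartParams()
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("response must be binary 0/1")
    y = y.astype(np.int64)
    design = _Design(X, tuple(categorical))
    if design.n != y.size:
        raise ValueError("X and y length mismatch")
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        nid = counter[0]
        counter[0] += 1
        n1 = int(y[idx].sum())
        n0 = idx.size - n1
        node = TreeNode(nid, idx.size, (n0, n1), depth)
        if (
            depth >= params.max_depth
            or idx.size < params.min_split
            or n0 == 0
            or n1 == 0
        ):
            return node
        found = _best_split(design, y, idx, params.min_leaf)
        if found is None:
            return node
        rule, gain, left_mask = found
        node.split = rule
        node.improvement = gain
        node.children = (
            build(idx[left_mask], depth + 1),
            build(idx[~left_mask], depth + 1),
        )
        return node

    root = build(np.arange(design.n), 0)
    tree = ClassificationTree(
        root=root,
        params=params,
        columns=design.columns,
        categorical=design.categorical,
        n=design.n,
        root_risk=min(root.class_counts),
    )
    tree.pruning_sequence = prune_path(tree)
    return tree


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _count_leaves(node: TreeNode, alpha: float) -> int:
    if node.is_leaf or node.collapse_alpha <= alpha:
        return 1
    return _count_leaves(node.children[0], alpha) + _count_leaves(node.children[1], alpha)


def _subtree_risk(node: TreeNode, alpha: float) -> int:
    if node.is_leaf or node.collapse_alpha <= alpha:
        return node.risk
    return _subtree_risk(node.children[0], alpha) + _subtree_risk(node.children[1], alpha)


def prune_path(tree: ClassificationTree) -> list[tuple[float, int, float]]:
    """Weakest-link cost-complexity pruning path.

    Annotates every internal node with the complexity at which it collapses
    and returns the nested sequence as ``(alpha, n_leaves, relative training
    error)`` with strictly increasing alpha and strictly decreasing leaves,
    ending at the root.  Risks are scaled by the root risk.
    """
    root = tree.root
    r_root = tree.root_risk
    scale = float(r_root) if r_root > 0 else 1.0

    # reset annotations (path may be recomputed)
    def reset(node: TreeNode) -> None:
        node.collapse_alpha = np.inf
        if not node.is_leaf:
            reset(node.children[0])
            reset(node.children[1])

    reset(root)
    if root.is_leaf:
        return [(0.0, 1, root.risk / scale)]

    def internal_nodes(node: TreeNode, live: list) -> None:
        if node.is_leaf or node.collapse_alpha != np.inf:
            return
        live.append(node)
        internal_nodes(node.children[0], live)
        internal_nodes(node.children[1], live)

    # collapse zero-gain splits first: the recorded "full" tree is the
    # smallest subtree attaining the full tree's training risk
    while True:
        live: list[TreeNode] = []
        internal_nodes(root, live)
        if not live:
            break
        gs = [
            ((t.risk - _subtree_risk(t, 0.0)) / scale) / (_count_leaves(t, 0.0) - 1)
            for t in live
        ]
        if min(gs) > 1e-12:
            break
        for t, g in zip(live, gs):
            if g <= 1e-12:
                t.collapse_alpha = 0.0

    sequence = [(0.0, _count_leaves(root, 0.0), _subtree_risk(root, 0.0) / scale)]
    while _count_leaves(root, sequence[-1][0]) > 1:
        alpha_prev = sequence[-1][0]
        live = []
        internal_nodes(root, live)
        if not live:
            break
        gs = []
        for t in live:
            leaves = _count_leaves(t, alpha_prev)
            if leaves <= 1:
                gs.append(np.inf)
                continue
            g = ((t.risk - _subtree_risk(t, alpha_prev)) / scale) / (leaves - 1)
            gs.append(g)
        gmin = min(gs)
        for t, g in zip(live, gs):
            if g <= gmin + 1e-12:
                t.collapse_alpha = gmin
        sequence.append(
            (float(gmin), _count_leaves(root, gmin), _subtree_risk(root, gmin) / scale)
        )
    return sequence


def prune_to(tree: ClassificationTree, alpha: float) -> ClassificationTree:
    """Deep copy of the subtree optimal at complexity ``alpha``."""

    def clone(node: TreeNode) -> TreeNode:
        if node.is_leaf or node.collapse_alpha <= alpha:
            return TreeNode(node.node_id, node.n, node.class_counts, node.depth)
        c = TreeNode(
            node.node_id,
            node.n,
            node.class_counts,
            node.depth,
            split=node.split,
            improvement=node.improvement,
            collapse_alpha=node.collapse_alpha,
        )
        c.children = (clone(node.children[0]), clone(node.children[1]))
        return c

    pruned = ClassificationTree(
        root=clone(tree.root),
        params=tree.params,
        columns=tree.columns,
        categorical=tree.categorical,
        n=tree.n,
        root_risk=tree.root_risk,
        pruning_sequence=[e for e in tree.pruning_sequence if e[0] >= alpha] or tree.pruning_sequence[-1:],
    )
    return pruned


def prune_to_size(tree: ClassificationTree, size: int) -> ClassificationTree:
    """Prune to the path subtree with exactly ``size`` leaves."""
    for alpha, n_leaves, _ in tree.pruning_sequence:
        if n_leaves == size:
            return prune_to(tree, alpha)
    raise ValueError(
        f"no subtree with {size} leaves in the pruning sequence "
        f"(available sizes: {[s for _, s, _ in tree.pruning_sequence]})"
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _encode(tree: ClassificationTree, X: pd.DataFrame) -> dict[str, np.ndarray]:
    cols = {}
    for col in tree.columns:
        if col not in X.columns:
            raise ValueError(f"missing predictor column {col!r}")
        vals = X[col].to_numpy()
        if col in tree.categorical:
            levels = tree.categorical[col]
            lookup = {v: i for i, v in enumerate(levels)}
            unseen = [v for v in pd.unique(vals) if v not in lookup]
            if unseen:
                raise ValueError(
                    f"unseen categories {unseen} for variable {col!r}"
                )
            cols[col] = np.array([lookup[v] for v in vals], dtype=np.int64)
        else:
            cols[col] = np.asarray(vals, dtype=float)
    return cols


def predict(tree: ClassificationTree, X: pd.DataFrame, alpha: float = -1.0) -> np.ndarray:
    """Route cases through the tree (optionally its subtree at ``alpha``)
    and return the leaf majority class per case."""
    cols = _encode(tree, X)
    n = len(X)
    out = np.zeros(n, dtype=np.int64)

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf or node.collapse_alpha <= alpha:
            out[idx] = node.predicted_class
            return
        rule = node.split
        vals = cols[rule.variable][idx]
        if rule.kind == "numeric":
            left = vals < rule.threshold
        else:
            left_codes = np.array(
                [i for i, lv in enumerate(tree.categorical[rule.variable]) if lv in rule.left_categories]
            )
            left = np.isin(vals, left_codes)
        walk(node.children[0], idx[left])
        walk(node.children[1], idx[~left])

    walk(tree.root, np.arange(n))
    return out


def evaluate(pred_or_tree, y_true, X: pd.DataFrame | None = None) -> ModelEvaluation:
    """Confusion counts and metrics; accepts predicted labels or a tree + X."""
    if isinstance(pred_or_tree, ClassificationTree):
        if X is None:
            raise ValueError("evaluating a tree requires the feature table X")
        y_pred = predict(pred_or_tree, X)
    else:
        y_pred = np.asarray(pred_or_tree)
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("cannot evaluate on empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch between predictions and truth")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    return ModelEvaluation(tp, fn, tn, fp)


# ---------------------------------------------------------------------------
# cross-validation, 1-SE selection, modal tree
# ---------------------------------------------------------------------------


def _eval_alphas(alphas: np.ndarray) -> np.ndarray:
    """Geometric means of consecutive path alphas; the last alpha is its own
    evaluation point."""
    if alphas.size == 1:
        return alphas.copy()
    mids = np.sqrt(alphas[:-1] * alphas[1:])
    return np.concatenate([mids, alphas[-1:]])


def cross_validate(
    X: pd.DataFrame,
    y,
    params: CartParams | None = None,
    k: int = 10,
    seed: int = 0,
    categorical: tuple[str, ...] = (),
) -> CVResult:
    """k-fold cross-validated relative errors along the master pruning path.

    Folds are a seeded uniform (non-stratified) partition.  Each fold's tree
    is evaluated at the geometric-mean alphas of the master path; xerror is
    the pooled held-out misclassification divided by the root risk of the
    full data, with a per-case-loss standard error.
    """
    params = params or CartParams()
    y = np.asarray(y).astype(np.int64)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    master = grow_tree(X, y, params, categorical)
    path = master.pruning_sequence
    alphas = np.array([a for a, _, _ in path])
    sizes = np.array([s for _, s, _ in path])
    rel_errors = np.array([e for _, _, e in path])
    evals = _eval_alphas(alphas)
    root_rate = master.root_risk / n if master.root_risk > 0 else 1.0

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    fold_of[perm] = np.arange(n) % k

    loss = np.zeros((n, evals.size))
    for fold in range(k):
        test = fold_of == fold
        Xtr = X.loc[~test].reset_index(drop=True)
        ytr = y[~test]
        Xte = X.loc[test].reset_index(drop=True)
        fold_tree = grow_tree(Xtr, ytr, params, categorical)
        for j, a in enumerate(evals):
            pred = predict(fold_tree, Xte, alpha=a)
            loss[test, j] = (pred != y[test]).astype(float)

    mean_loss = loss.mean(axis=0)
    xerrors = mean_loss / root_rate
    xstds = np.sqrt(((loss - mean_loss) ** 2).mean(axis=0) / n) / root_rate
    return CVResult(sizes, alphas, rel_errors, xerrors, xstds, k, seed)


def select_1se(cv: CVResult) -> tuple[float, int]:
    """1-SE rule: smallest tree whose xerror is within one standard error of
    the minimum; returns (alpha, size)."""
    i_min = int(np.argmin(cv.xerrors))
    bound = cv.xerrors[i_min] + cv.xstds[i_min]
    ok = cv.xerrors <= bound
    # path is ordered by increasing alpha = decreasing size
    candidates = [(cv.sizes[i], cv.alphas[i]) for i in range(cv.sizes.size) if ok[i]]
    size = min(s for s, _ in candidates)
    alpha = max(a for s, a in candidates if s == size)
    return float(alpha), int(size)


def modal_optimal_tree(
    X: pd.DataFrame,
    y,
    params: CartParams | None = None,
    n_repeats: int = 50,
    base_seed: int = 0,
    k: int = 10,
    categorical: tuple[str, ...] = (),
) -> ClassificationTree:
    """Repeat cross-validation ``n_repeats`` times (seeds base_seed ...),
    select a tree size by the 1-SE rule each time, take the modal size (ties
    to the smaller size), and return the full-data tree pruned to it."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    params = params or CartParams()
    master = grow_tree(X, np.asarray(y), params, categorical)
    selected = []
    for r in range(n_repeats):
        cv = cross_validate(X, y, params, k=k, seed=base_seed + r, categorical=categorical)
        _, size = select_1se(cv)
        selected.append(size)
    counts = Counter(selected)
    top = max(counts.values())
    modal_size = min(s for s, c in counts.items() if c == top)
    tree = prune_to_size(master, modal_size)
    tree.modal_size = modal_size
    tree.size_counts = dict(sorted(counts.items()))
    firsts = Counter(
        tuple(prune_to_size(master, s).split_variables()[:1]) for s in selected
    )
    tree.first_split_counts = {
        (k2[0] if k2 else "<root>"): v for k2, v in firsts.items()
    }
    return tree
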