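"""Stage-3: CART integration of the composite biomarker with primary-care
diagnosis and certainty.

A classification tree over four complete features — composite biomarker
(0/1), biomarker frequency (0-6), primary-care (EAE Hub) diagnosis
(0 = nonautism, 1 = autism) and dichotomized certainty (0 = uncertain,
1 = certain) — is grown by greedy binary recursive partitioning on Gini
impurity (entropy available), best-gain-first, stopping after a fixed
split budget.  Terminal nodes carry a three-way clinical decision:
*autism* (diagnose), *nonautism* (rule out), or *refer* for specialist
evaluation.  The decision policy is explicit configuration rather than a
purity rule: the published assignment refers one terminal whose purity
matches another terminal that is decided, a clinical judgment no
threshold reproduces.

:func:`published_tree` returns the study's reported tree with its
node-by-node class counts, and :func:`evaluate_decided` scores any
tree/policy over the decided (non-referred) cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import AccuracyStats, Confusion2x2, accuracy_stats
from .screen import roc_auc

__all__ = [
    "TreeNode",
    "CVReport",
    "FEATURES",
    "fit_cart",
    "published_tree",
    "PUBLISHED_POLICY",
    "evaluate_decided",
    "predict_terminal",
    "cross_validate",
    "tree_to_dict",
    "tree_from_dict",
    "render_tree_text",
    "tree_to_dot",
]

#: Candidate split variables, in tie-breaking priority order.
FEATURES = ["composite", "frequency", "eae_dx", "certainty"]

DECISIONS = ("autism", "nonautism", "refer")


@dataclass
class TreeNode:
    """A node of a binary classification tree.

    Internal nodes hold ``split_variable`` and ``threshold`` (cases with
    ``value <= threshold`` go left); terminals hold an optional
    ``decision``.  ``counts`` is ``(n_autism, n_nonautism)`` of the
    training (or stored) cases reaching the node.
    """

    node_id: int
    counts: tuple
    split_variable: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    decision: str | None = None

    @property
    def is_terminal(self) -> bool:
        return self.split_variable is None

    @property
    def n(self) -> int:
        return int(self.counts[0] + self.counts[1])

    @property
    def p_autism(self) -> float:
        return self.counts[0] / self.n if self.n else float("nan")

    def terminals(self) -> list["TreeNode"]:
        if self.is_terminal:
            return [self]
        return self.left.terminals() + self.right.terminals()

    def structure(self):
        """Hashable structure signature (splits only, no counts)."""
        if self.is_terminal:
            return ("leaf",)
        return (self.split_variable, float(self.threshold),
                self.left.structure(), self.right.structure())


def _impurity(n_a: int, n_n: int, criterion: str) -> float:
    n = n_a + n_n
    if n == 0:
        return 0.0
    p = n_a / n
    if criterion == "gini":
        return 2 * p * (1 - p)
    if criterion == "entropy":
        if p in (0.0, 1.0):
            return 0.0
        return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    raise ValueError(f"unknown criterion {criterion!r}")


def _best_split(X: pd.DataFrame, y: np.ndarray, idx: np.ndarray,
                criterion: str, min_node: int):
    """Best (gain, variable, threshold) for the cases in ``idx``.

    Ties break on the fixed feature order, then the lower threshold.
    """
    y_sub = y[idx]
    n = len(idx)
    parent = _impurity(int(y_sub.sum()), int(n - y_sub.sum()), criterion)
    best = (0.0, None, None)
    for var in FEATURES:
        v = X[var].to_numpy()[idx]
        for thr in np.unique(v)[:-1]:  # candidate thresholds between levels
            left = v <= thr
            nl = int(left.sum())
            nr = n - nl
            if nl < min_node or nr < min_node:
                continue
            la = int(y_sub[left].sum())
            ra = int(y_sub.sum()) - la
            child = (nl * _impurity(la, nl - la, criterion)
                     + nr * _impurity(ra, nr - ra, criterion)) / n
            gain = parent - child
            if gain > best[0] + 1e-12:
                best = (gain, var, float(thr))
    return best


def fit_cart(
    X: pd.DataFrame,
    y,
    max_splits: int = 5,
    min_node: int = 5,
    min_gain: float = 0.005,
    criterion: str = "gini",
) -> TreeNode:
    """Grow a classification tree by greedy best-gain-first partitioning.

    ``X`` must contain the four complete feature columns; ``y`` is 1 for
    reference-standard autism.  At each step the frontier leaf whose
    best split yields the largest impurity decrease is split, until
    ``max_splits`` splits have been made or no split improves impurity
    by at least ``min_gain``.  Deterministic given the data: ties break
    on the fixed feature order then the lower threshold.  A single-class
    sample yields a root-only tree.
    """
    for f in FEATURES:
        if f not in X.columns:
            raise ValueError(f"missing feature column {f!r}")
        if X[f].isna().any():
            raise ValueError(f"feature {f!r} has missing values")
    y = np.asarray(y).astype(int)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")

    next_id = [1]

    def make_node(idx):
        node = TreeNode(
            node_id=next_id[0],
            counts=(int(y[idx].sum()), int(len(idx) - y[idx].sum())),
        )
        next_id[0] += 1
        return node

    all_idx = np.arange(len(y))
    root = make_node(all_idx)
    # frontier: list of (node, idx, best_split)
    frontier = [(root, all_idx, _best_split(X, y, all_idx, criterion, min_node))]
    n_splits = 0
    while n_splits < max_splits and frontier:
        # pick the frontier leaf with the largest achievable gain
        frontier.sort(key=lambda e: (-e[2][0], e[0].node_id))
        node, idx, (gain, var, thr) = frontier.pop(0)
        if var is None or gain < min_gain:
            break
        v = X[var].to_numpy()[idx]
        li = idx[v <= thr]
        ri = idx[v > thr]
        node.split_variable = var
        node.threshold = thr
        node.left = make_node(li)
        node.right = make_node(ri)
        frontier.append((node.left, li, _best_split(X, y, li, criterion, min_node)))
        frontier.append((node.right, ri, _best_split(X, y, ri, criterion, min_node)))
        n_splits += 1
    return root


def predict_terminal(tree: TreeNode, case: dict) -> TreeNode:
    """Route one case (a mapping of feature -> value) to its terminal."""
    node = tree
    while not node.is_terminal:
        v = case[node.split_variable]
        node = node.left if v <= node.threshold else node.right
    return node


def majority_policy(tree: TreeNode) -> dict:
    """Default decision policy: each terminal takes its majority class."""
    return {
        t.node_id: ("autism" if t.p_autism >= 0.5 else "nonautism")
        for t in tree.terminals()
    }


def published_tree() -> TreeNode:
    """The study's reported decision tree with its printed class counts.

    Structure (node numbers as printed): the root splits on the
    composite biomarker.  The biomarker-positive branch (node 3, 79/10)
    splits on EAE Hub diagnosis — EAE-autism cases are node 6 (57/0);
    EAE-nonautism cases (node 7, 22/10) split on biomarker frequency
    > 1 (node 10, 10/0) and then on certainty (node 12 uncertain, 9/1;
    node 13 certain, 3/9).  The biomarker-negative branch (node 2,
    23/34) splits on EAE Hub diagnosis — EAE-nonautism cases are node 5
    (9/26); EAE-autism cases (node 4, 14/8) split on certainty (node 8
    uncertain, 2/5; node 9 certain, 12/3).

    Counts are ``(n_autism, n_nonautism)``.
    """
    n13 = TreeNode(13, (3, 9))
    n12 = TreeNode(12, (9, 1))
    n11 = TreeNode(11, (12, 10), "certainty", 0.5, left=n12, right=n13)
    n10 = TreeNode(10, (10, 0))
    n7 = TreeNode(7, (22, 10), "frequency", 1.5, left=n11, right=n10)
    n6 = TreeNode(6, (57, 0))
    n3 = TreeNode(3, (79, 10), "eae_dx", 0.5, left=n7, right=n6)
    n9 = TreeNode(9, (12, 3))
    n8 = TreeNode(8, (2, 5))
    n4 = TreeNode(4, (14, 8), "certainty", 0.5, left=n8, right=n9)
    n5 = TreeNode(5, (9, 26))
    n2 = TreeNode(2, (23, 34), "eae_dx", 0.5, left=n5, right=n4)
    root = TreeNode(1, (102, 44), "composite", 0.5, left=n2, right=n3)
    return root


#: Published terminal decisions: diagnose nodes 6, 9, 10, 12; rule out
#: node 5; refer nodes 8 and 13.
PUBLISHED_POLICY = {
    6: "autism",
    10: "autism",
    12: "autism",
    9: "autism",
    5: "nonautism",
    8: "refer",
    13: "refer",
}


def evaluate_decided(
    tree: TreeNode,
    policy: dict,
    cases: pd.DataFrame | None = None,
    outcome=None,
    ci_method: str = "wilson",
) -> tuple[AccuracyStats, int]:
    """Accuracy over decided cases; referred cases are excluded.

    With ``cases=None`` the stored node counts are scored (the published
    worked example); otherwise each case is routed through the tree and
    scored against ``outcome`` (1 = reference autism).  Returns
    ``(AccuracyStats, n_referred)``.
    """
    missing = [t.node_id for t in tree.terminals() if t.node_id not in policy]
    if missing:
        raise ValueError(f"policy lacks decisions for terminals {missing}")
    tp = fp = fn = tn = referred = 0
    if cases is None:
        for t in tree.terminals():
            n_a, n_n = t.counts
            d = policy[t.node_id]
            if d == "autism":
                tp += n_a
                fp += n_n
            elif d == "nonautism":
                fn += n_a
                tn += n_n
            else:
                referred += n_a + n_n
    else:
        y = np.asarray(outcome).astype(bool)
        for i, (_, case) in enumerate(cases.iterrows()):
            d = policy[predict_terminal(tree, case).node_id]
            if d == "refer":
                referred += 1
            elif d == "autism":
                tp += int(y[i])
                fp += int(not y[i])
            else:
                fn += int(y[i])
                tn += int(not y[i])
    table = Confusion2x2(tp=tp, fp=fp, fn=fn, tn=tn, referred=referred)
    if table.n == 0:
        stats = AccuracyStats(*(float("nan"),) * 5, (float("nan"),) * 2, 0, 0)
        return stats, referred
    return accuracy_stats(table, ci_method=ci_method), referred


@dataclass
class CVReport:
    """Stratified k-fold cross-validation of the fitted tree."""

    fold_structures: list = field(default_factory=list)
    train_auc: list = field(default_factory=list)
    valid_auc: list = field(default_factory=list)
    modal_structure_count: int = 0
    seed: int | None = None

    @property
    def mean_valid_auc(self) -> float:
        return float(np.mean(self.valid_auc)) if self.valid_auc else float("nan")

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_auc)) if self.train_auc else float("nan")


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    folds = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f)) for f in folds]


def _posterior_scores(tree: TreeNode, X: pd.DataFrame) -> np.ndarray:
    return np.array(
        [predict_terminal(tree, case).p_autism for _, case in X.iterrows()]
    )


def cross_validate(
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    max_refolds: int = 20,
    **fit_kwargs,
) -> CVReport:
    """Stratified k-fold CV: per-fold tree structure and train/valid AUC.

    Validation AUC scores held-out cases by the terminal-node autism
    posterior of the fold's training tree.  If a fold ends up missing a
    class (tiny samples), the partition is redrawn with a new seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y).astype(int)
    report = CVReport(seed=seed)
    for attempt in range(max_refolds):
        rng = np.random.default_rng(seed + attempt)
        folds = _stratified_folds(y, k, rng)
        if all(len(np.unique(y[f])) == 2 for f in folds):
            break
    else:
        raise ValueError("could not stratify folds with both classes")
    for fold in folds:
        train = np.setdiff1d(np.arange(len(y)), fold)
        tree = fit_cart(X.iloc[train].reset_index(drop=True), y[train], **fit_kwargs)
        report.fold_structures.append(tree.structure())
        report.train_auc.append(
            roc_auc(_posterior_scores(tree, X.iloc[train]), y[train])
        )
        report.valid_auc.append(
            roc_auc(_posterior_scores(tree, X.iloc[fold]), y[fold])
        )
    counts = {}
    for s in report.fold_structures:
        counts[s] = counts.get(s, 0) + 1
    report.modal_structure_count = max(counts.values())
    return report


def tree_to_dict(node: TreeNode, policy: dict | None = None) -> dict:
    d = {
        "node_id": node.node_id,
        "n_autism": int(node.counts[0]),
        "n_nonautism": int(node.counts[1]),
    }
    if node.is_terminal:
        dec = node.decision or (policy or {}).get(node.node_id)
        d["decision"] = dec
    else:
        d["split_variable"] = node.split_variable
        d["threshold"] = node.threshold
        d["left"] = tree_to_dict(node.left, policy)
        d["right"] = tree_to_dict(node.right, policy)
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        node_id=d["node_id"],
        counts=(d["n_autism"], d["n_nonautism"]),
        decision=d.get("decision"),
    )
    if "split_variable" in d:
        node.split_variable = d["split_variable"]
        node.threshold = d["threshold"]
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node


def tree_to_json(node: TreeNode, policy: dict | None = None, **kwargs) -> str:
    return json.dumps(tree_to_dict(node, policy), **kwargs)


def render_tree_text(node: TreeNode, policy: dict | None = None, indent: str = "") -> str:
    """Indented text rendering of a tree (and optional decisions)."""
    n_a, n_n = node.counts
    head = f"node {node.node_id}: autism={n_a} nonautism={n_n}"
    if node.is_terminal:
        dec = node.decision or (policy or {}).get(node.node_id)
        head += f" -> {dec}" if dec else ""
        return indent + head + "\n"
    out = indent + head + f" | split {node.split_variable} <= {node.threshold:g}\n"
    out += render_tree_text(node.left, policy, indent + "  ")
    out += render_tree_text(node.right, policy, indent + "  ")
    return out


def tree_to_dot(node: TreeNode, policy: dict | None = None) -> str:
    """Graphviz DOT rendering."""
    lines = ["digraph cart {", "  node [shape=box];"]

    def walk(n):
        n_a, n_n = n.counts
        label = f"node {n.node_id}\\nautism={n_a} nonautism={n_n}"
        if n.is_terminal:
            dec = n.decision or (policy or {}).get(n.node_id)
            if dec:
                label += f"\\ndecision: {dec}"
        else:
            label += f"\\n{n.split_variable} <= {n.threshold:g}?"
        lines.append(f'  n{n.node_id} [label="{label}"];')
        if not n.is_terminal:
            lines.append(f"  n{n.node_id} -> n{n.left.node_id} [label=yes];")
            lines.append(f"  n{n.node_id} -> n{n.right.node_id} [label=no];")
            walk(n.left)
            walk(n.right)

    walk(node)
    lines.append("}")
    return "\n".join(lines)
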