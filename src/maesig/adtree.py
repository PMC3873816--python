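"""Boosted alternating decision tree (ADTree) for MAE/BAE classification.

An ADTree is a sum-of-paths model: prediction nodes carry real values, and an
instance's margin is the root value plus the values of every prediction node
it traverses, following *all* paths whose decision conditions hold.  Training
follows Freund & Mason's boosting scheme: each iteration scans every existing
prediction node as a precondition, every feature, and every threshold midway
between consecutive distinct observed values, and installs the rule with the
smallest Z-score

    Z = 2[sqrt(W+(true) W-(true)) + sqrt(W+(false) W-(false))] + W(not reached)

where W+/W- are the boosting weights of positive (MAE) and negative (BAE)
instances.  Cost-sensitive "Precision" training multiplies the initial BAE
weights by the false-positive penalty ratio, pushing the decision boundary
away from the biallelic cluster.

A positive margin calls MAE; the decision boundary sits at margin 0 with no
probability calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EPSILON = 1.0  # smoothing inside prediction-value logs

POSITIVE_LABEL = "MAE"
NEGATIVE_LABEL = "BAE"


@dataclass(frozen=True)
class Rule:
    """One boosting rule: a decision node with its two prediction values.

    `precondition_node` indexes the prediction node an instance must reach;
    node 0 is the root, and rule k contributes nodes 2k+1 (condition true)
    and 2k+2 (condition false).  The condition is `x[feature] > threshold`.
    """

    precondition_node: int
    feature: str
    threshold: float
    value_true: float
    value_false: float


@dataclass
class ADTreeModel:
    root_value: float
    rules: list[Rule]
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def n_nodes(self) -> int:
        return 1 + 2 * len(self.rules)

    # -- prediction ---------------------------------------------------------

    def margins(self, X: pd.DataFrame, impute: str | None = None) -> np.ndarray:
        """Margins for a feature matrix (rows = instances).

        Missing feature values raise by default; `impute="median"` substitutes
        the training medians stored in the model metadata.
        """
        cols = []
        for f in self.feature_names:
            if f not in X.columns:
                raise ValueError(f"feature {f!r} absent from input matrix")
            col = X[f].to_numpy(dtype=float)
            if np.isnan(col).any():
                if impute == "median":
                    med = self.metadata.get("feature_medians", {}).get(f)
                    if med is None:
                        raise ValueError(f"no stored median to impute feature {f!r}")
                    col = np.where(np.isnan(col), med, col)
                else:
                    raise ValueError(
                        f"missing values in feature {f!r}; pass impute='median' to fill"
                    )
            cols.append(col)
        Xa = np.column_stack(cols) if cols else np.empty((len(X), 0))
        fidx = {f: i for i, f in enumerate(self.feature_names)}

        n = Xa.shape[0]
        margins = np.full(n, self.root_value, dtype=float)
        reach: dict[int, np.ndarray] = {0: np.ones(n, dtype=bool)}
        for k, rule in enumerate(self.rules):
            pre = reach[rule.precondition_node]
            cond = Xa[:, fidx[rule.feature]] > rule.threshold
            t_mask = pre & cond
            f_mask = pre & ~cond
            margins += np.where(t_mask, rule.value_true, 0.0)
            margins += np.where(f_mask, rule.value_false, 0.0)
            reach[2 * k + 1] = t_mask
            reach[2 * k + 2] = f_mask
        return margins

    def predict_margin(self, x: Mapping[str, float]) -> float:
        """Margin of a single instance (dict of feature -> value)."""
        row = pd.DataFrame([dict(x)])
        return float(self.margins(row)[0])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "maesig-adtree",
            "version": 1,
            "root_value": self.root_value,
            "rules": [
                {
                    "precondition_node": r.precondition_node,
                    "feature": r.feature,
                    "threshold": r.threshold,
                    "value_true": r.value_true,
                    "value_false": r.value_false,
                }
                for r in self.rules
            ],
            "feature_names": self.feature_names,
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ADTreeModel":
        if d.get("format") != "maesig-adtree":
            raise ValueError("not a maesig ADTree model file")
        return cls(
            root_value=float(d["root_value"]),
            rules=[Rule(**r) for r in d["rules"]],
            feature_names=list(d["feature_names"]),
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ADTreeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainingSet:
    """Labeled feature matrix; instances with missing values in the used
    features are dropped (and counted) before training."""

    X: pd.DataFrame
    y: np.ndarray  # +1 = MAE, -1 = BAE
    n_dropped_missing: int = 0

    @classmethod
    def from_labels(
        cls,
        features: pd.DataFrame,
        labels: Mapping[str, str],
        feature_names: Sequence[str] | None = None,
    ) -> "TrainingSet":
        feature_names = list(feature_names or features.columns)
        ids = [g for g in features.index if g in labels]
        sub = features.loc[ids, feature_names]
        complete = sub.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        sub = sub[complete]
        y = np.array([1 if labels[g] == POSITIVE_LABEL else -1 for g in sub.index])
        return cls(sub, y, n_dropped)

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class ClassifierReport:
    """Pooled and per-repeat cross-validation performance for the MAE class."""

    tp: int
    fp: int
    fn: int
    tn: int
    per_repeat_f: list[float]
    seeds: list[int]
    n_folds: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    @property
    def f_sd(self) -> float:
        return float(np.std(self.per_repeat_f, ddof=1)) if len(self.per_repeat_f) > 1 else 0.0


def _prediction_values(wp: float, wn: float) -> float:
    return 0.5 * math.log((wp + EPSILON) / (wn + EPSILON))


def train_adtree(
    data: TrainingSet,
    iterations: int = 10,
    cost_ratio: float = 1.0,
    seed: int = 0,
) -> ADTreeModel:
    """Boost an alternating decision tree for `iterations` rounds.

    `cost_ratio` multiplies the initial weight of every BAE instance,
    penalizing false positives (1.0 = "Neutral", 8.0 = "Precision").
    Training is deterministic; `seed` is recorded in the model metadata for
    provenance only.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be > 0")
    y = data.y
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("need at least one instance of each class")
    feature_names = list(data.X.columns)
    Xa = data.X.to_numpy(dtype=float)
    if np.isnan(Xa).any():
        raise ValueError("training matrix contains missing values; drop them first")
    n = Xa.shape[0]

    w = np.ones(n, dtype=float)
    w[y == -1] *= cost_ratio

    wp, wn = w[y == 1].sum(), w[y == -1].sum()
    root_value = 0.5 * math.log(wp / wn)
    w = w * np.exp(-y * root_value)

    # per-feature sort orders, shared across iterations
    orders = [np.argsort(Xa[:, j], kind="stable") for j in range(Xa.shape[1])]

    rules: list[Rule] = []
    reach: dict[int, np.ndarray] = {0: np.ones(n, dtype=bool)}
    total_w = float(w.sum())

    for _ in range(iterations):
        best = None  # (Z, node, j, threshold, a, b, t_mask, f_mask)
        for node in sorted(reach):
            pre = reach[node]
            if not pre.any():
                continue
            w_outside = total_w - float(w[pre].sum())
            for j in range(Xa.shape[1]):
                order = orders[j]
                sel = order[pre[order]]  # subset indices sorted by feature j
                v = Xa[sel, j]
                if v.size < 2 or v[0] == v[-1]:
                    continue
                wp_s = np.where(y[sel] == 1, w[sel], 0.0)
                wn_s = np.where(y[sel] == -1, w[sel], 0.0)
                cp = np.cumsum(wp_s)
                cn = np.cumsum(wn_s)
                # boundaries between distinct consecutive values
                distinct = np.nonzero(v[1:] != v[:-1])[0]  # split after index k
                thr = (v[distinct] + v[distinct + 1]) / 2.0
                wp_false = cp[distinct]
                wn_false = cn[distinct]
                wp_true = cp[-1] - wp_false
                wn_true = cn[-1] - wn_false
                z = (
                    2.0
                    * (np.sqrt(wp_true * wn_true) + np.sqrt(wp_false * wn_false))
                    + w_outside
                )
                k = int(np.argmin(z))  # first minimum -> smallest threshold on ties
                if best is None or z[k] < best[0]:
                    a = _prediction_values(float(wp_true[k]), float(wn_true[k]))
                    b = _prediction_values(float(wp_false[k]), float(wn_false[k]))
                    best = (float(z[k]), node, j, float(thr[k]), a, b)
        if best is None:
            break  # no splittable precondition subset remains
        _, node, j, threshold, a, b = best
        pre = reach[node]
        cond = Xa[:, j] > threshold
        t_mask = pre & cond
        f_mask = pre & ~cond
        w[t_mask] *= np.exp(-y[t_mask] * a)
        w[f_mask] *= np.exp(-y[f_mask] * b)
        total_w = float(w.sum())
        k_rule = len(rules)
        rules.append(Rule(node, feature_names[j], threshold, a, b))
        reach[2 * k_rule + 1] = t_mask
        reach[2 * k_rule + 2] = f_mask

    medians = {f: float(np.median(Xa[:, j])) for j, f in enumerate(feature_names)}
    return ADTreeModel(
        root_value=root_value,
        rules=rules,
        feature_names=feature_names,
        metadata={
            "iterations": iterations,
            "cost_ratio": cost_ratio,
            "seed": seed,
            "n_train": n,
            "n_dropped_missing": data.n_dropped_missing,
            "feature_medians": medians,
        },
    )


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index arrays for stratified K-fold assignment."""
    assignment = np.empty(len(y), dtype=int)
    for cls in (1, -1):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < folds:
            raise ValueError(
                f"class {cls:+d} has {len(idx)} instances, fewer than {folds} folds"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.nonzero(assignment == k)[0] for k in range(folds)]


def cross_validate(
    data: TrainingSet,
    folds: int = 10,
    repeats: int = 10,
    iterations: int = 10,
    cost_ratio: float = 1.0,
    seed: int = 0,
) -> ClassifierReport:
    """Repeated stratified K-fold cross-validation, pooling confusion counts.

    The training set is shuffled into `folds` stratified subsets `repeats`
    times with distinct seeded shuffles; each fold serves once as the test
    set.  The report pools TP/FP/FN/TN over all folds of all repeats and
    records the per-repeat F-measure spread.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    tp = fp = fn = tn = 0
    per_repeat_f = []
    seeds = [seed + r for r in range(repeats)]
    for rseed in seeds:
        rng = np.random.default_rng(rseed)
        r_tp = r_fp = r_fn = r_tn = 0
        for test_idx in _stratified_folds(data.y, folds, rng):
            train_mask = np.ones(len(data), dtype=bool)
            train_mask[test_idx] = False
            train = TrainingSet(data.X.iloc[train_mask], data.y[train_mask])
            model = train_adtree(train, iterations, cost_ratio, seed=rseed)
            pred = model.margins(data.X.iloc[test_idx]) > 0
            truth = data.y[test_idx] == 1
            r_tp += int((pred & truth).sum())
            r_fp += int((pred & ~truth).sum())
            r_fn += int((~pred & truth).sum())
            r_tn += int((~pred & ~truth).sum())
        tp, fp, fn, tn = tp + r_tp, fp + r_fp, fn + r_fn, tn + r_tn
        p = r_tp / (r_tp + r_fp) if r_tp + r_fp else 0.0
        r = r_tp / (r_tp + r_fn) if r_tp + r_fn else 0.0
        per_repeat_f.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    return ClassifierReport(tp, fp, fn, tn, per_repeat_f, seeds, folds)


def rank_features_info_gain(
    data: TrainingSet, bins: int = 10
) -> list[tuple[str, float]]:
    """Rank features by information gain of the class given an
    equal-frequency discretization; ties broken by feature name."""
    if len(data) < 2:
        raise ValueError("need at least 2 instances")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    y01 = (data.y == 1).astype(int)
    h_class = _entropy(np.bincount(y01, minlength=2))
    gains = []
    for f in data.X.columns:
        x = data.X[f].to_numpy(dtype=float)
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
        bin_idx = np.searchsorted(edges, x, side="left")
        h_cond = 0.0
        for b in np.unique(bin_idx):
            mask = bin_idx == b
            h_cond += mask.mean() * _entropy(np.bincount(y01[mask], minlength=2))
        gains.append((f, h_class - h_cond))
    gains.sort(key=lambda t: (-t[1], t[0]))
    return gains


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def forward_select(
    data: TrainingSet,
    ranked: Sequence[str],
    tolerance: float = 0.01,
    folds: int = 10,
    repeats: int = 2,
    iterations: int = 10,
    cost_ratio: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Add features in rank order until cross-validated F-measure stops
    improving by at least `tolerance` (strictly, when tolerance is 0)."""
    if not ranked:
        raise ValueError("ranked feature list is empty")
    selected = [ranked[0]]
    best_f = cross_validate(
        TrainingSet(data.X[selected], data.y),
        folds,
        repeats,
        iterations,
        cost_ratio,
        seed,
    ).f_measure
    for f in ranked[1:]:
        trial = selected + [f]
        trial_f = cross_validate(
            TrainingSet(data.X[trial], data.y),
            folds,
            repeats,
            iterations,
            cost_ratio,
            seed,
        ).f_measure
        gain = trial_f - best_f
        if gain > tolerance or (tolerance > 0 and math.isclose(gain, tolerance)):
            selected, best_f = trial, trial_f
        else:
            break
    return selected


def predict_genome(
    model: ADTreeModel,
    features: pd.DataFrame,
    expression: Mapping[str, float],
    min_rpkm: float = 0.1,
) -> pd.DataFrame:
    """Call MAE/BAE for every gene with evidence of transcription.

    Genes with RPKM below `min_rpkm` are labeled silent and excluded from
    calls; genes without an RPKM entry or with missing feature data get
    call "NA".  Expressed genes are called MAE when the margin is positive.
    """
    rows = []
    have = features[model.feature_names].notna().all(axis=1)
    margins = pd.Series(np.nan, index=features.index, dtype=float)
    if have.any():
        margins[have] = model.margins(features.loc[have, model.feature_names])
    for gene in features.index:
        rpkm = expression.get(gene)
        margin = float(margins[gene])
        if rpkm is None or not have[gene]:
            call, expressed = "NA", rpkm is not None and rpkm >= min_rpkm
        elif rpkm < min_rpkm:
            call, expressed = "silent", False
        else:
            call, expressed = ("MAE" if margin > 0 else "BAE"), True
        rows.append(
            {"gene_id": gene, "margin": margin, "call": call, "expressed": expressed}
        )
    return pd.DataFrame(rows).set_index("gene_id")
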