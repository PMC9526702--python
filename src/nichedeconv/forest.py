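"""Random-forest niche classification and composition estimation.

A forest of 200 Gini decision trees is trained on niche-labelled reference
regions.  Tree growth is effectively unlimited in depth but a node stops
splitting once its majority class reaches ``purity_stop`` (default 95%) of
the node — implemented as an exact truncation of fully grown scikit-learn
trees: because greedy tree induction chooses each split only from the data
reaching that node, cutting the tree at the first node whose majority-class
fraction meets the threshold yields the identical model to stopping growth
there.

Each tree casts one hard vote per sample; the fraction of trees voting for
each niche is the sample's estimated niche composition (a point on the
4-simplex — votes partition the forest, so no renormalization is needed),
and the niche with the greatest vote fraction is the sample's dominant
"…-like signature", ties broken by the canonical order LE < IT < CT < MVP <
PAN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .matrix import ProteinMatrix
from .niches import NICHES
from .synthetic import BulkCohort, ReferenceAtlas


@dataclass
class ForestConfig:
    """Forest hyperparameters.

    ``purity_stop`` is the node-purity stopping rule: a node is a leaf once
    its majority class accounts for at least this fraction of the node.
    ``split_by='region'`` keeps technical duplicates of one microdissected
    region in the same fold of the train/test split (no leakage);
    ``split_by='sample'`` splits individual columns.
    """

    n_trees: int = 200
    purity_stop: float = 0.95
    max_depth: int | None = None
    features_per_split: str | int = "sqrt"
    bootstrap: bool = True
    train_frac: float = 0.8
    split_by: str = "region"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.purity_stop <= 1):
            raise ValueError("purity_stop must lie in (0.5, 1]")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.split_by not in ("region", "sample"):
            raise ValueError("split_by must be 'region' or 'sample'")


@dataclass
class NicheComposition:
    """Per-sample niche probability vector and dominant-niche call."""

    sample_id: str
    probs: np.ndarray  # 5-vector in canonical niche order
    dominant: str

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(NICHES),):
            raise ValueError("probs must be a 5-vector in canonical niche order")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")


@dataclass
class EvalReport:
    """Held-out evaluation: confusion matrix and one-vs-rest ROC AUCs."""

    confusion: pd.DataFrame  # rows = true niche, cols = predicted niche
    auc: float  # macro average over classes
    per_class_auc: pd.Series


def stratified_split(
    labels: pd.Series,
    train_frac: float = 0.8,
    seed: int = 0,
    region_of_sample: pd.Series | None = None,
) -> tuple[list[str], list[str]]:
    """Split samples into train/test, stratified by niche.

    Per niche, ``ceil(train_frac * n)`` units go to training.  When
    ``region_of_sample`` is given the unit is the region: duplicates of one
    region always land in the same fold.
    """
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    if region_of_sample is not None:
        region_of_sample = pd.Series(region_of_sample).loc[labels.index]
        unit_label = labels.groupby(region_of_sample).first()
        members = {r: list(idx) for r, idx in labels.groupby(region_of_sample).groups.items()}
    else:
        unit_label = labels
        members = {s: [s] for s in labels.index}

    train: list[str] = []
    test: list[str] = []
    for niche in NICHES:
        units = sorted(unit_label.index[unit_label == niche])
        if len(units) < 2:
            raise ValueError(f"niche {niche!r} has fewer than 2 units to split")
        n_train = int(np.ceil(train_frac * len(units)))
        perm = rng.permutation(len(units))
        for k, u in enumerate(np.array(units, dtype=object)[perm]):
            (train if k < n_train else test).extend(members[u])
    return train, test


def _tree_arrays(tree: DecisionTreeClassifier, purity_stop: float) -> dict:
    """Extract per-node arrays plus the purity-truncation leaf mask."""
    t = tree.tree_
    counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
    frac = counts.max(axis=1) / counts.sum(axis=1)
    is_leaf = t.children_left == -1
    eff_leaf = is_leaf | (frac >= purity_stop)
    # node vote in canonical class order, first-max tie-break
    canon = np.zeros((t.node_count, len(NICHES)))
    canon[:, tree.classes_.astype(int)] = counts
    vote = np.argmax(canon, axis=1)
    return {
        "left": t.children_left.copy(),
        "right": t.children_right.copy(),
        "feature": t.feature.copy(),
        "threshold": t.threshold.copy(),
        "eff_leaf": eff_leaf,
        "vote": vote,
    }


@dataclass
class ForestModel:
    """Trained niche forest: per-tree node arrays plus the feature list."""

    trees: list[dict]
    feature_names: list[str]
    purity_stop: float
    config: ForestConfig = field(default_factory=ForestConfig)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _descend(self, tree: dict, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = np.flatnonzero(~tree["eff_leaf"][node])
        while active.size:
            nz = node[active]
            go_left = X[active, tree["feature"][nz]] <= tree["threshold"][nz]
            node[active] = np.where(go_left, tree["left"][nz], tree["right"][nz])
            active = active[~tree["eff_leaf"][node[active]]]
        return node

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Vote fractions per sample (rows = samples, cols = canonical niches)."""
        if list(X.columns) != self.feature_names:
            raise ValueError("feature mismatch: restrict/reorder to the model's features")
        xv = np.ascontiguousarray(X.to_numpy(dtype=np.float64))
        votes = np.zeros((xv.shape[0], len(NICHES)))
        for tree in self.trees:
            node = self._descend(tree, xv)
            v = tree["vote"][node]
            votes[np.arange(xv.shape[0]), v] += 1
        return votes / self.n_trees

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([NICHES[i] for i in np.argmax(probs, axis=1)])

    def tree_depths(self) -> np.ndarray:
        """Effective depth of each tree after purity truncation."""
        depths = []
        for tree in self.trees:
            depth = np.zeros(len(tree["left"]), dtype=int)
            maxd = 0
            stack = [(0, 0)]
            while stack:
                node, d = stack.pop()
                depth[node] = d
                if tree["eff_leaf"][node]:
                    maxd = max(maxd, d)
                else:
                    stack.append((tree["left"][node], d + 1))
                    stack.append((tree["right"][node], d + 1))
            depths.append(maxd)
        return np.array(depths)

    # -- serialization (versioned JSON bundle) -------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "n_trees": self.n_trees,
            "purity_stop": self.purity_stop,
            "classes": list(NICHES),
            "n_features": len(self.feature_names),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (directory / "features.json").write_text(json.dumps(self.feature_names))
        trees = [
            {k: np.asarray(v).tolist() for k, v in t.items()} for t in self.trees
        ]
        (directory / "trees.json").write_text(json.dumps(trees))

    @classmethod
    def load(cls, directory: str | Path) -> "ForestModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("format_version") != 1:
            raise ValueError("unsupported model bundle version")
        features = json.loads((directory / "features.json").read_text())
        raw = json.loads((directory / "trees.json").read_text())
        trees = []
        for t in raw:
            trees.append(
                {
                    "left": np.asarray(t["left"], dtype=np.int64),
                    "right": np.asarray(t["right"], dtype=np.int64),
                    "feature": np.asarray(t["feature"], dtype=np.int64),
                    "threshold": np.asarray(t["threshold"], dtype=np.float64),
                    "eff_leaf": np.asarray(t["eff_leaf"], dtype=bool),
                    "vote": np.asarray(t["vote"], dtype=np.int64),
                }
            )
        return cls(trees=trees, feature_names=features, purity_stop=manifest["purity_stop"])


def train_random_forest(
    reference: ReferenceAtlas, config: ForestConfig | None = None
) -> ForestModel:
    """Grow the niche forest on a fully imputed reference atlas.

    Bootstrap resamples per tree, Gini splits over sqrt(p) candidate features,
    purity-stopped at ``config.purity_stop``.
    """
    config = config or ForestConfig()
    matrix = reference.matrix
    if matrix.has_missing():
        raise ValueError("training matrix has missing values: impute first")
    X = matrix.values.T.to_numpy(dtype=np.float64)
    y = reference.niche_of_sample.loc[matrix.sample_ids].map(
        {n: i for i, n in enumerate(NICHES)}
    ).to_numpy()
    n = X.shape[0]

    rng = np.random.default_rng(config.seed)
    trees: list[dict] = []
    for _ in range(config.n_trees):
        if config.bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_depth=config.max_depth,
            max_features=config.features_per_split,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(X[idx], y[idx])
        trees.append(_tree_arrays(clf, config.purity_stop))
    return ForestModel(
        trees=trees,
        feature_names=list(matrix.protein_ids),
        purity_stop=config.purity_stop,
        config=config,
    )


def evaluate_forest(model: ForestModel, test: ReferenceAtlas) -> EvalReport:
    """Confusion matrix from dominant-label calls and macro one-vs-rest AUC."""
    labels = test.niche_of_sample.loc[test.matrix.sample_ids]
    unseen = set(labels.unique()) - set(NICHES)
    if unseen:
        raise ValueError(f"unseen class labels in test set: {sorted(unseen)}")
    X = test.matrix.values.T
    probs = model.predict_proba(X)
    pred = np.array([NICHES[i] for i in np.argmax(probs, axis=1)])

    confusion = pd.DataFrame(0, index=list(NICHES), columns=list(NICHES))
    for t, p in zip(labels, pred):
        confusion.loc[t, p] += 1

    per_class = {}
    for i, niche in enumerate(NICHES):
        y_bin = (labels == niche).to_numpy().astype(int)
        if y_bin.min() == y_bin.max():
            per_class[niche] = np.nan
        else:
            per_class[niche] = roc_auc_score(y_bin, probs[:, i])
    per_class = pd.Series(per_class)
    return EvalReport(
        confusion=confusion,
        auc=float(per_class.dropna().mean()),
        per_class_auc=per_class,
    )


def predict_niche_composition(
    model: ForestModel,
    bulk: BulkCohort | ProteinMatrix,
    require_zscored: bool = False,
) -> list[NicheComposition]:
    """Estimate each bulk sample's niche composition from forest vote fractions.

    The bulk matrix must be restricted to the model's feature list (use
    ``intersect_features``) and should be z-scored per sample; a non-z-scored
    input warns by default and raises when ``require_zscored`` is set.
    """
    matrix = bulk.matrix if isinstance(bulk, BulkCohort) else bulk
    if matrix.scale_tag != "zscored":
        msg = f"bulk matrix scale_tag is {matrix.scale_tag!r}, expected 'zscored'"
        if require_zscored:
            raise ValueError(msg)
        warnings.warn(msg)
    probs = model.predict_proba(matrix.values.T)
    comps = []
    for sid, p in zip(matrix.sample_ids, probs):
        comps.append(
            NicheComposition(sample_id=sid, probs=p, dominant=NICHES[int(np.argmax(p))])
        )
    return comps


def composition_table(comps: list[NicheComposition]) -> pd.DataFrame:
    """Long-format (sample, niche, probability, dominant flag) table."""
    rows = []
    for c in comps:
        for niche, p in zip(NICHES, c.probs):
            rows.append(
                {
                    "sample": c.sample_id,
                    "niche": niche,
                    "probability": p,
                    "dominant": niche == c.dominant,
                }
            )
    return pd.DataFrame(rows)
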