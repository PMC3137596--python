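"""Per-motif SVM models over the MDD decomposition.

Training builds the MDD tree on the positive windows, then fits one
RBF-kernel SVM per leaf on the leaf's positives plus ratio-matched negative
windows sampled from the shared negative pool.  To avoid skew from any one
draw, several negative sets are sampled per leaf and cross-validation is
repeated on each; the deployed leaf model is refit once on a seed-fixed
sample with the winning hyper-parameters.  Prediction routes each query
window down the tree to its leaf and applies that leaf's SVM.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .encoding import (
    AAindexEntry,
    MotifPattern,
    PositionalWeightMatrix,
    WindowVectorizer,
)
from .evaluation import MetricsReport, cross_validate
from .mdd import (
    AAGroupScheme,
    MDDConfig,
    MDDTree,
    mdd_cluster,
    route,
    tree_from_json,
    tree_to_json,
)
from .sequence_io import ProteinRecord, SequenceWindow, SiteDataset, extract_window

#: Negative:positive ratio of the reference training corpus (2728 / 586).
DEFAULT_NEGATIVE_RATIO = 2728 / 586

# LibSVM-practice grids: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3, step x4.
DEFAULT_COST_GRID = tuple(float(2.0**p) for p in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**p) for p in range(-15, 4, 2))


@dataclass
class SVMConfig:
    """RBF-SVM hyper-parameter search space and decision threshold."""

    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("hyper-parameter grids must be non-empty")


def sample_negatives(
    negatives: Sequence[SequenceWindow],
    leaf_size: int,
    ratio: float,
    seed: int,
    rounds: int = 10,
) -> list[list[SequenceWindow]]:
    """Draw ``rounds`` negative subsets of ``round(ratio * leaf_size)``.

    Subsets are drawn without replacement within a round and are fully
    reproducible from ``(seed, round index)``.  If the pool is smaller than
    the requested size, the whole pool is used with a warning.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    size = int(round(ratio * leaf_size))
    pool = list(negatives)
    if size > len(pool):
        import warnings

        warnings.warn(
            f"negative pool ({len(pool)}) smaller than requested sample "
            f"({size}); using the whole pool",
            stacklevel=2,
        )
        size = len(pool)
    subsets = []
    for r in range(rounds):
        rng = np.random.default_rng((seed, r))
        idx = rng.choice(len(pool), size=size, replace=False)
        subsets.append([pool[i] for i in sorted(idx)])
    return subsets


@dataclass
class LeafModel:
    """A fitted leaf: vectorizer (with the leaf PWM), SVM, and CV history."""

    leaf_id: int
    vectorizer: WindowVectorizer
    classifier: SVC
    best_params: dict
    negative_seed: int
    cv_reports: list[MetricsReport] = field(default_factory=list)

    @property
    def cv_accuracy(self) -> float:
        if not self.cv_reports:
            return float("nan")
        return float(np.mean([r.Acc for r in self.cv_reports]))


def _make_pipeline(
    features: tuple[str, ...],
    aaindex: Mapping[str, AAindexEntry] | None,
    motif_patterns: Sequence[MotifPattern] | None,
    C: float,
    gamma: float,
) -> Pipeline:
    return Pipeline(
        [
            (
                "vec",
                WindowVectorizer(
                    features=features,
                    aaindex=aaindex,
                    motif_patterns=motif_patterns,
                ),
            ),
            ("svc", SVC(kernel="rbf", C=C, gamma=gamma)),
        ]
    )


def train_leaf(
    positives: Sequence[SequenceWindow],
    negative_subsets: Sequence[Sequence[SequenceWindow]],
    leaf_id: int = 0,
    features: tuple[str, ...] = ("AA_PWM", "AAC"),
    svm_cfg: SVMConfig | None = None,
    k: int = 5,
    seed: int = 0,
    aaindex: Mapping[str, AAindexEntry] | None = None,
    motif_patterns: Sequence[MotifPattern] | None = None,
) -> LeafModel:
    """Train one leaf model with repeated negative resampling.

    For each negative subset (round), hyper-parameters are grid-searched by
    k-fold CV accuracy and the pooled CV report at the winning parameters is
    recorded.  The deployed classifier is refit on the leaf positives plus
    the first subset using the configuration that won the most rounds.
    The leaf PWM is always fitted on positive training folds only (the
    vectorizer sits inside the CV pipeline), so no evaluation fold leaks
    into the encoding.
    """
    svm_cfg = svm_cfg or SVMConfig()
    if k > len(positives):
        import warnings

        warnings.warn(
            f"leaf has only {len(positives)} positives; reducing k from "
            f"{k} to {len(positives)}",
            stacklevel=2,
        )
        k = max(2, len(positives))
    param_votes: Counter = Counter()
    cv_reports: list[MetricsReport] = []
    single_combo = len(svm_cfg.cost_grid) == 1 and len(svm_cfg.gamma_grid) == 1
    for r, subset in enumerate(negative_subsets):
        X = list(positives) + list(subset)
        y = np.array([1] * len(positives) + [0] * len(subset))
        if single_combo:
            best = {
                "svc__C": svm_cfg.cost_grid[0],
                "svc__gamma": svm_cfg.gamma_grid[0],
            }
        else:
            pipe = _make_pipeline(
                features, aaindex, motif_patterns, 1.0, "scale"
            )
            gs = GridSearchCV(
                pipe,
                {
                    "svc__C": list(svm_cfg.cost_grid),
                    "svc__gamma": list(svm_cfg.gamma_grid),
                },
                cv=StratifiedKFold(k, shuffle=True, random_state=seed + r),
                scoring="accuracy",
                refit=False,
                n_jobs=1,
            )
            gs.fit(X, y)
            best = gs.best_params_
        param_votes[(best["svc__C"], best["svc__gamma"])] += 1

        def trainer(train_windows, train_labels, _best=best):
            pipe = _make_pipeline(
                features,
                aaindex,
                motif_patterns,
                _best["svc__C"],
                _best["svc__gamma"],
            )
            pipe.fit(train_windows, train_labels)
            return pipe.predict

        pooled, _ = cross_validate(X, y, trainer, k=k, seed=seed + r)
        cv_reports.append(pooled)
    (best_C, best_gamma), _ = param_votes.most_common(1)[0]
    final_X = list(positives) + list(negative_subsets[0])
    final_y = np.array(
        [1] * len(positives) + [0] * len(negative_subsets[0])
    )
    final_pipe = _make_pipeline(
        features, aaindex, motif_patterns, best_C, best_gamma
    )
    final_pipe.fit(final_X, final_y)
    return LeafModel(
        leaf_id=leaf_id,
        vectorizer=final_pipe.named_steps["vec"],
        classifier=final_pipe.named_steps["svc"],
        best_params={"C": best_C, "gamma": best_gamma},
        negative_seed=seed,
        cv_reports=cv_reports,
    )


class SnoSiteClassifier(BaseEstimator, ClassifierMixin):
    """MDD-clustered per-motif SVM classifier for cysteine modification sites.

    Parameters
    ----------
    features : tuple of str
        Feature blocks for the leaf vectorizers; default PWM + composition.
    max_cluster_size, chi2_threshold, min_leaf_size
        MDD stopping parameters (see :class:`~snopred.mdd.MDDConfig`).
    negative_ratio : float or None
        Negatives sampled per leaf positive; None uses the ratio observed
        in the training data.
    rounds : int
        Negative resampling rounds per leaf.
    cost_grid, gamma_grid : tuple of float
        RBF-SVM search grids (single-element grids skip the search).
    decision_threshold : float
        SVM decision-value cutoff for a positive call.
    cv_folds : int
        Folds for the per-round cross-validation inside training.
    random_state : int
        Seed for negative sampling and fold shuffling.

    Attributes
    ----------
    tree_ : MDDTree
        The fitted decomposition of the positive windows.
    leaf_models_ : dict mapping leaf id -> LeafModel
    cv_accuracy_ : float
        Size-weighted mean of per-leaf CV accuracies (over rounds).
    """

    def __init__(
        self,
        features: tuple[str, ...] = ("AA_PWM", "AAC"),
        max_cluster_size: int = 100,
        chi2_threshold: float = 34.3,
        min_leaf_size: int = 15,
        negative_ratio: float | None = None,
        rounds: int = 10,
        cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
        gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
        decision_threshold: float = 0.0,
        cv_folds: int = 5,
        random_state: int = 0,
        scheme: AAGroupScheme | None = None,
        aaindex: Mapping[str, AAindexEntry] | None = None,
        motif_patterns: Sequence[MotifPattern] | None = None,
    ) -> None:
        self.features = features
        self.max_cluster_size = max_cluster_size
        self.chi2_threshold = chi2_threshold
        self.min_leaf_size = min_leaf_size
        self.negative_ratio = negative_ratio
        self.rounds = rounds
        self.cost_grid = cost_grid
        self.gamma_grid = gamma_grid
        self.decision_threshold = decision_threshold
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.scheme = scheme
        self.aaindex = aaindex
        self.motif_patterns = motif_patterns

    # -- fitting ----------------------------------------------------------

    def fit(
        self, X: Sequence[SequenceWindow], y: Sequence[int]
    ) -> "SnoSiteClassifier":
        y = np.asarray(y)
        positives = [w for w, label in zip(X, y) if label == 1]
        negatives = [w for w, label in zip(X, y) if label == 0]
        if not positives or not negatives:
            raise ValueError("both classes must be present for training")
        self.n_ = positives[0].n
        ratio = (
            self.negative_ratio
            if self.negative_ratio is not None
            else len(negatives) / len(positives)
        )
        cfg = MDDConfig(
            max_cluster_size=self.max_cluster_size,
            chi2_threshold=self.chi2_threshold,
            min_leaf_size=self.min_leaf_size,
        )
        self.tree_ = mdd_cluster(positives, scheme=self.scheme, cfg=cfg)
        svm_cfg = SVMConfig(
            cost_grid=tuple(self.cost_grid),
            gamma_grid=tuple(self.gamma_grid),
            decision_threshold=self.decision_threshold,
        )
        self.leaf_models_ = {}
        for leaf in self.tree_.leaves():
            subsets = sample_negatives(
                negatives,
                leaf_size=len(leaf.members),
                ratio=ratio,
                seed=self.random_state * 1000 + leaf.leaf_id,
                rounds=self.rounds,
            )
            self.leaf_models_[leaf.leaf_id] = train_leaf(
                leaf.members,
                subsets,
                leaf_id=leaf.leaf_id,
                features=tuple(self.features),
                svm_cfg=svm_cfg,
                k=self.cv_folds,
                seed=self.random_state,
                aaindex=self.aaindex,
                motif_patterns=self.motif_patterns,
            )
        sizes = np.array(
            [len(leaf.members) for leaf in self.tree_.leaves()]
        )
        accs = np.array(
            [
                self.leaf_models_[leaf.leaf_id].cv_accuracy
                for leaf in self.tree_.leaves()
            ]
        )
        self.cv_accuracy_ = (
            float(np.average(accs, weights=sizes))
            if not np.isnan(accs).all()
            else float("nan")
        )
        self.classes_ = np.array([0, 1])
        return self

    def fit_dataset(self, dataset: SiteDataset) -> "SnoSiteClassifier":
        """Fit from a :class:`SiteDataset` (positives + negatives)."""
        X = list(dataset.positives) + list(dataset.negatives)
        y = [1] * len(dataset.positives) + [0] * len(dataset.negatives)
        return self.fit(X, y)

    # -- prediction -------------------------------------------------------

    def _leaf_for(self, window: SequenceWindow) -> LeafModel:
        return self.leaf_models_[route(window, self.tree_)]

    def decision_function(
        self, X: Sequence[SequenceWindow]
    ) -> np.ndarray:
        scores = np.empty(len(X))
        for i, w in enumerate(X):
            lm = self._leaf_for(w)
            vec = lm.vectorizer.transform([w])
            scores[i] = lm.classifier.decision_function(vec)[0]
        return scores

    def predict(self, X: Sequence[SequenceWindow]) -> np.ndarray:
        return (
            self.decision_function(X) > self.decision_threshold
        ).astype(int)

    def predict_proteins(
        self, proteins: Sequence[ProteinRecord]
    ) -> pd.DataFrame:
        """Score every cysteine of the given proteins.

        Returns one row per cysteine: protein id, 1-based position, the
        window string, the matched motif leaf id, the SVM decision value,
        and the binary call.
        """
        rows = []
        for prot in proteins:
            for pos in prot.cysteine_positions():
                w = extract_window(prot, pos, self.n_)
                leaf_id = route(w, self.tree_)
                lm = self.leaf_models_[leaf_id]
                score = float(
                    lm.classifier.decision_function(
                        lm.vectorizer.transform([w])
                    )[0]
                )
                rows.append(
                    {
                        "protein_id": prot.id,
                        "position": pos,
                        "window": w.residues,
                        "leaf_id": leaf_id,
                        "score": score,
                        "call": int(score > self.decision_threshold),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id",
                "position",
                "window",
                "leaf_id",
                "score",
                "call",
            ],
        )

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the model archive: tree JSON, per-leaf PWM TSV + SVM blob,
        and the configuration snapshot."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tree.json").write_text(tree_to_json(self.tree_))
        snapshot = {
            "n": self.n_,
            "features": list(self.features),
            "max_cluster_size": self.max_cluster_size,
            "chi2_threshold": self.chi2_threshold,
            "min_leaf_size": self.min_leaf_size,
            "decision_threshold": self.decision_threshold,
            "random_state": self.random_state,
        }
        (directory / "config.json").write_text(
            json.dumps(snapshot, indent=2, sort_keys=True)
        )
        for leaf_id, lm in self.leaf_models_.items():
            leaf_dir = directory / f"leaf_{leaf_id:03d}"
            leaf_dir.mkdir(exist_ok=True)
            if lm.vectorizer.pwm_ is not None:
                lm.vectorizer.pwm_.to_frame().to_csv(
                    leaf_dir / "pwm.tsv", sep="\t"
                )
                (leaf_dir / "pwm_count.txt").write_text(
                    str(lm.vectorizer.pwm_.source_count)
                )
            joblib.dump(lm.classifier, leaf_dir / "svm.joblib")
            (leaf_dir / "leaf.json").write_text(
                json.dumps(
                    {
                        "leaf_id": leaf_id,
                        "best_params": lm.best_params,
                        "negative_seed": lm.negative_seed,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )

    @classmethod
    def load(cls, directory: str | Path) -> "SnoSiteClassifier":
        directory = Path(directory)
        snapshot = json.loads((directory / "config.json").read_text())
        model = cls(
            features=tuple(snapshot["features"]),
            max_cluster_size=snapshot["max_cluster_size"],
            chi2_threshold=snapshot["chi2_threshold"],
            min_leaf_size=snapshot["min_leaf_size"],
            decision_threshold=snapshot["decision_threshold"],
            random_state=snapshot["random_state"],
        )
        model.n_ = snapshot["n"]
        model.tree_ = tree_from_json((directory / "tree.json").read_text())
        model.leaf_models_ = {}
        for leaf_dir in sorted(directory.glob("leaf_*")):
            meta = json.loads((leaf_dir / "leaf.json").read_text())
            vec = WindowVectorizer(features=tuple(snapshot["features"]))
            pwm_path = leaf_dir / "pwm.tsv"
            if pwm_path.exists():
                frame = pd.read_csv(
                    pwm_path, sep="\t", index_col=0,
                    float_precision="round_trip",
                )
                count = int((leaf_dir / "pwm_count.txt").read_text())
                vec.pwm_ = PositionalWeightMatrix.from_frame(frame, count)
            else:
                vec.pwm_ = None
            model.leaf_models_[meta["leaf_id"]] = LeafModel(
                leaf_id=meta["leaf_id"],
                vectorizer=vec,
                classifier=joblib.load(leaf_dir / "svm.joblib"),
                best_params=meta["best_params"],
                negative_seed=meta["negative_seed"],
            )
        model.classes_ = np.array([0, 1])
        return model


def train_snosite(
    dataset: SiteDataset, **params
) -> SnoSiteClassifier:
    """Convenience wrapper: fit a :class:`SnoSiteClassifier` on a dataset."""
    return SnoSiteClassifier(**params).fit_dataset(dataset)
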