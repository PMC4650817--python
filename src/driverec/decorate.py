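"""DECORATE meta-learning and the four-committee averaged ensemble.

DECORATE (Diverse Ensemble Creation by Oppositional Relabeling of Artificial
Training Examples) grows a committee of base learners one member at a time.
Each iteration draws artificial examples from a per-attribute Gaussian
approximation of the training-data distribution, labels them *against* the
current committee's predictions (class probability inversely proportional to
the committee's posterior), trains a candidate member on the original plus
artificial data, and keeps it only if the committee's error on the original
data does not increase. The oppositional labels force diversity; the
acceptance test keeps the committee honest.

The driver/passenger ensemble trains one DECORATE committee for each of four
base learners — Gaussian naive Bayes, a Platt-calibrated linear SVM (an
SMO-style support vector classifier), an information-gain decision tree
(C4.5-style) and a small random forest — and averages their posterior
probabilities into a single driver score ``Prb``. A gene is called a driver
when ``Prb`` exceeds 0.5; a tie at exactly 0.5 is called passenger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "DecorateParams",
    "DecorateCommittee",
    "EnsembleModel",
    "BASE_LEARNER_IDS",
    "train_decorate",
    "train_ensemble",
    "committee_posterior",
    "ensemble_posterior",
    "classify",
]

#: fixed order of the four base learners behind the ensemble
BASE_LEARNER_IDS = ("naive_bayes", "linear_svm", "decision_tree", "random_forest")

DRIVER = 1
PASSENGER = 0

#: floor on committee class posteriors in the oppositional-label inverse rule
LABEL_EPS = 1e-3

_MAX_SEED = 2**31 - 1


@dataclass
class DecorateParams:
    """DECORATE build parameters.

    artificial_size : number of artificial examples per iteration, as a
        fraction of the original training-set size (1.0 doubles the data).
    desired_size : target committee size (members, including the first).
    num_iterations : maximum candidate-generation iterations; the build may
        stop earlier when the committee reaches ``desired_size``.
    seed : master RNG seed; every random draw descends from it.
    """

    artificial_size: float = 1.0
    desired_size: int = 15
    num_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.artificial_size <= 0:
            raise ValueError("artificial_size must be > 0")
        if self.desired_size < 1:
            raise ValueError("desired_size must be >= 1")
        if self.num_iterations < 0:
            raise ValueError("num_iterations must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DecorateParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


class PlattLinearSVM:
    """Linear support-vector classifier with Platt-calibrated probabilities.

    Fits a hard linear SVM, then a one-dimensional logistic sigmoid mapping
    its decision values to class probabilities — the classic recipe used by
    SMO-style implementations to emit posteriors.
    """

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state
        self._svm: SVC | None = None
        self._sigmoid: LogisticRegression | None = None

    def fit(self, X, y):
        self._svm = SVC(kernel="linear", random_state=self.random_state)
        self._svm.fit(X, y)
        d = self._svm.decision_function(X).reshape(-1, 1)
        self._sigmoid = LogisticRegression(C=1e3)
        self._sigmoid.fit(d, y)
        self.classes_ = self._sigmoid.classes_
        return self

    def predict_proba(self, X):
        d = self._svm.decision_function(X).reshape(-1, 1)
        return self._sigmoid.predict_proba(d)

    def predict(self, X):
        return self._svm.predict(X)


def make_base_learner(base_learner_id: str, random_state: int | None = None):
    """Instantiate a fresh base learner by id."""
    if base_learner_id == "naive_bayes":
        return GaussianNB()
    if base_learner_id == "linear_svm":
        return PlattLinearSVM(random_state=random_state)
    if base_learner_id == "decision_tree":
        return DecisionTreeClassifier(criterion="entropy", random_state=random_state)
    if base_learner_id == "random_forest":
        # 10 trees: the classic Weka RandomForest default, and ample for
        # 10-dimensional inputs with ~100 training points
        return RandomForestClassifier(n_estimators=10, random_state=random_state)
    raise ValueError(
        f"unknown base learner {base_learner_id!r}; expected one of "
        f"{BASE_LEARNER_IDS}"
    )


@dataclass
class DecorateCommittee:
    """A trained DECORATE committee for one base learner."""

    base_learner_id: str
    members: list = field(default_factory=list)
    training_error_history: list[float] = field(default_factory=list)
    classes_: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Uniform average of member class-probability outputs."""
        if not self.members:
            raise RuntimeError("committee has no trained members")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        probs = self.members[0].predict_proba(X)
        for m in self.members[1:]:
            probs = probs + m.predict_proba(X)
        return probs / len(self.members)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the driver class."""
        probs = self.predict_proba(X)
        driver_col = int(np.where(self.classes_ == DRIVER)[0][0])
        return probs[:, driver_col]


def _validate_training_data(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")


def _committee_error(prob_sum: np.ndarray, n_members: int, y: np.ndarray,
                     classes: np.ndarray) -> float:
    """0/1 error of the averaged committee on labels *y* (tie -> passenger)."""
    driver_col = int(np.where(classes == DRIVER)[0][0])
    prb = prob_sum[:, driver_col] / n_members
    pred = np.where(prb > 0.5, DRIVER, PASSENGER)
    return float(np.mean(pred != y))


def n_artificial(artificial_size: float, n: int) -> int:
    """Artificial examples per iteration: ceil(artificial_size * n)."""
    return int(np.ceil(artificial_size * n))


def train_decorate(
    X: np.ndarray,
    y: np.ndarray,
    params: DecorateParams,
    base_learner_id: str,
    rng: np.random.Generator | None = None,
) -> DecorateCommittee:
    """Build a DECORATE committee on labeled feature rows.

    ``y`` uses 1 for drivers and 0 for passengers. The committee keeps at
    most ``params.desired_size`` members; candidates that raise the
    committee's 0/1 error on the original training data are discarded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _validate_training_data(X, y)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = len(y)
    mu = X.mean(axis=0)
    sigma = np.maximum(X.std(axis=0), 1e-9)
    n_art = n_artificial(params.artificial_size, n)

    first = make_base_learner(base_learner_id, int(rng.integers(_MAX_SEED)))
    first.fit(X, y)
    classes = np.asarray(first.classes_)
    members = [first]
    prob_sum = first.predict_proba(X).copy()
    error = _committee_error(prob_sum, 1, y, classes)
    history = [error]

    iterations = 0
    while len(members) < params.desired_size and iterations < params.num_iterations:
        iterations += 1
        # artificial examples from the per-attribute Gaussian approximation
        X_art = rng.normal(loc=mu, scale=sigma, size=(n_art, X.shape[1]))
        # oppositional labels: p(class) inversely proportional to the
        # committee's posterior, floored to avoid division blow-up
        comm_probs = np.zeros((n_art, len(classes)))
        for m in members:
            comm_probs += m.predict_proba(X_art)
        comm_probs /= len(members)
        inv = 1.0 / np.maximum(comm_probs, LABEL_EPS)
        inv /= inv.sum(axis=1, keepdims=True)
        y_art = np.array(
            [classes[rng.choice(len(classes), p=row)] for row in inv], dtype=int
        )

        candidate = make_base_learner(base_learner_id, int(rng.integers(_MAX_SEED)))
        candidate.fit(np.vstack([X, X_art]), np.concatenate([y, y_art]))
        cand_probs = candidate.predict_proba(X)
        new_error = _committee_error(
            prob_sum + cand_probs, len(members) + 1, y, classes
        )
        if new_error <= error:
            members.append(candidate)
            prob_sum += cand_probs
            error = new_error
            history.append(error)

    return DecorateCommittee(
        base_learner_id=base_learner_id,
        members=members,
        training_error_history=history,
        classes_=classes,
    )


@dataclass
class EnsembleModel:
    """Four DECORATE committees, one per base learner, averaged at predict."""

    committees: list[DecorateCommittee]

    def __post_init__(self) -> None:
        if len(self.committees) != 4:
            raise RuntimeError(
                f"ensemble requires exactly 4 committees, got {len(self.committees)}"
            )

    def posterior(self, X: np.ndarray) -> np.ndarray:
        return ensemble_posterior(self, X)


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    params: DecorateParams,
    base_learner_ids: Sequence[str] = BASE_LEARNER_IDS,
) -> EnsembleModel:
    """Train the four-committee ensemble; all randomness flows from
    ``params.seed`` through one generator."""
    rng = np.random.default_rng(params.seed)
    committees = [
        train_decorate(X, y, params, learner_id, rng=rng)
        for learner_id in base_learner_ids
    ]
    return EnsembleModel(committees=committees)


def committee_posterior(committee: DecorateCommittee, x: np.ndarray) -> float:
    """Driver-class posterior of one committee for a single feature vector."""
    return float(committee.posterior(np.atleast_2d(x))[0])


def ensemble_posterior(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Prb: uniform mean of the four committees' driver posteriors."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    out = np.zeros(len(X))
    for committee in model.committees:
        out += committee.posterior(X)
    return out / len(model.committees)


def classify(prb: np.ndarray | float) -> np.ndarray:
    """Driver iff Prb > 0.5 (a tie at the boundary is called passenger)."""
    return np.where(np.asarray(prb) > 0.5, DRIVER, PASSENGER)


# -- persistence -----------------------------------------------------------

ARCHIVE_VERSION = 1


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist a trained ensemble to a versioned joblib archive."""
    import joblib

    joblib.dump({"version": ARCHIVE_VERSION, "model": model}, path)


def load_model(path: str | Path) -> EnsembleModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('version')}")
    return payload["model"]
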