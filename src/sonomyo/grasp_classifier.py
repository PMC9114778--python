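"""Shrinkage-LDA grasp classification and cross-condition accuracy matrices.

Per-frame grasp decoding uses linear discriminant analysis on the 14,000
raw pixel features of a downscaled frame.  With only a few hundred training
frames the pooled within-class covariance is badly rank-deficient, so it is
shrunk toward a scaled identity,

    Sigma_lambda = (1 - lambda) * Sigma_pooled
                   + lambda * (tr(Sigma_pooled) / p) * I,

with lambda either fixed or chosen by the Ledoit-Wolf analytic rule.  The
discriminant solve exploits the low rank of Sigma_pooled through the
Woodbury identity, so fitting never forms a p x p matrix; the result is
exact, identical to the dense solve where that is feasible.

Training strategies mirror the acquisition protocol: one classifier per
static arm position or dynamic movement pattern, plus pooled "ALL"
classifiers over the 7 positions or 4 patterns, and a continuous-dynamic
classifier trained on the single 20-s sweep.  The cross-condition accuracy
matrix (train condition x test condition) separates intra-condition
accuracy (diagonal) from inter-condition generalization (off-diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import Frame, vectorize
from .synthgen import (
    DYNAMIC_PATTERNS,
    STATIC_POSITIONS,
    AcquisitionRecord,
    GraspLabel,
    Load,
    Mode,
)

CLASS_ORDER: tuple[GraspLabel, ...] = (
    GraspLabel.REST,
    GraspLabel.TRIPOD,
    GraspLabel.POINT,
)


# ---------------------------------------------------------------------------
# Training strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingStrategy:
    """Which conditions contribute training frames.

    ``kind`` is one of ``static_single``, ``static_all``, ``dynamic_single``,
    ``dynamic_all``, ``continuous_dynamic``; single-condition strategies
    carry the position or pattern name in ``condition``.
    """

    kind: str
    condition: str | None = None

    _KINDS = (
        "static_single",
        "static_all",
        "dynamic_single",
        "dynamic_all",
        "continuous_dynamic",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "static_single" and self.condition not in STATIC_POSITIONS:
            raise ValueError("static_single needs a valid position")
        if self.kind == "dynamic_single" and self.condition not in DYNAMIC_PATTERNS:
            raise ValueError("dynamic_single needs a valid pattern")
        if self.kind.endswith("_all") or self.kind == "continuous_dynamic":
            if self.condition is not None:
                raise ValueError(f"{self.kind} takes no condition")

    def selects(self, record: AcquisitionRecord) -> bool:
        mode = record.arm_condition.mode
        if self.kind == "static_single":
            return mode is Mode.STATIC and record.arm_condition.key == self.condition
        if self.kind == "static_all":
            return mode is Mode.STATIC
        if self.kind == "dynamic_single":
            return mode is Mode.DYNAMIC and record.arm_condition.key == self.condition
        if self.kind == "dynamic_all":
            return mode is Mode.DYNAMIC
        return mode is Mode.CONTINUOUS_DYNAMIC

    @property
    def label(self) -> str:
        if self.condition is not None:
            return self.condition
        return {"static_all": "ALL", "dynamic_all": "ALL",
                "continuous_dynamic": "Continuous Dynamic"}[self.kind]


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitAssignment:
    """Per condition-cell choice of which of the two repeats trains.

    ``train_repeat`` maps each (grasp, condition, load) cell to 1 or 2;
    the other repeat tests.  Train and test are disjoint and together
    exhaust the session.
    """

    train_repeat: dict[tuple[GraspLabel, str, Load], int]
    seed: int

    def is_train(self, record: AcquisitionRecord) -> bool:
        key = (record.grasp, record.arm_condition.key, record.load.value)
        return record.repeat_index == self.train_repeat[key]


def split_repeats(session: list[AcquisitionRecord], seed: int) -> SplitAssignment:
    """Randomly assign, per condition cell, one repeat to training and the
    other to testing (a fair coin per cell, deterministic in ``seed``).

    Raises
    ------
    ValueError
        If any cell does not hold exactly the repeats {1, 2}, naming it.
    """
    cells: dict[tuple[GraspLabel, str, Load], set[int]] = {}
    for rec in session:
        key = (rec.grasp, rec.arm_condition.key, rec.load.value)
        cells.setdefault(key, set()).add(rec.repeat_index)
    for key, reps in cells.items():
        if reps != {1, 2}:
            raise ValueError(
                f"cell (grasp={key[0].name}, condition={key[1]!r}, "
                f"load={key[2].value}) has repeats {sorted(reps)}, expected both 1 and 2"
            )
    rng = np.random.default_rng(seed)
    assignment = {}
    for key in sorted(cells, key=lambda k: (int(k[0]), k[1], k[2].value)):
        assignment[key] = int(rng.integers(1, 3))
    return SplitAssignment(train_repeat=assignment, seed=seed)


def assemble_training_set(
    records: list[AcquisitionRecord],
    strategy: TrainingStrategy,
    load: Load,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorize the frames of every record matching ``strategy`` and
    ``load``, in record order then time order.

    Returns ``(features, labels)`` with features ``(n_frames, 14000)`` in
    [0, 1] and integer grasp labels.
    """
    selected = [
        r for r in records if r.load.value is load and strategy.selects(r)
    ]
    if not selected:
        raise ValueError(
            f"no records match strategy {strategy.label!r} under load {load.value}"
        )
    X = np.concatenate(
        [np.stack([vectorize(f) for f in r.frames]) for r in selected]
    )
    y = np.concatenate(
        [np.full(r.n_frames, int(r.grasp), dtype=int) for r in selected]
    )
    return X, y


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _ledoit_wolf_lambda(Xc: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity toward (tr(S)/p) I, computed from the
    Gram matrix of the centered data so no p x p matrix is formed.

    S is the (biased, /n) covariance of the centered rows Xc.
    """
    n, p = Xc.shape
    G = Xc @ Xc.T  # (n, n)
    tr_S = float(np.trace(G)) / n
    mu = tr_S / p
    tr_S2 = float(np.sum(G * G)) / n**2
    d2 = tr_S2 / p - mu**2  # ||S - mu I||_F^2 / p
    if d2 <= 0:
        return 1.0
    sq_norms = np.einsum("ij,ij->i", Xc, Xc)
    # (1/n^2) sum_i ||x_i x_i^T - S||_F^2 / p, expanded via the Gram matrix
    b2_bar = (float(np.sum(sq_norms**2)) / n**2 - tr_S2 / n) / p
    b2 = min(max(b2_bar, 0.0), d2)
    return float(b2 / d2)


@dataclass
class GraspClassifier:
    """Fitted shrinkage-LDA model over vectorized frames.

    The decision rule is the argmax over classes of the linear score
    ``x @ coef_[k] + intercept_[k]`` with ``coef_[k] = Sigma_lambda^{-1} mu_k``
    and ``intercept_[k] = -mu_k @ coef_[k] / 2 + log pi_k``; ties go to the
    earlier class in ``class_order`` (REST < TRIPOD < POINT).
    """

    class_order: tuple[GraspLabel, ...]
    means: np.ndarray          # (K, p)
    priors: np.ndarray         # (K,)
    shrinkage: float
    coef_: np.ndarray = field(repr=False)   # (K, p)
    intercept_: np.ndarray = field(repr=False)  # (K,)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"expected {self.means.shape[1]} features, got {X.shape[1]}"
            )
        return X @ self.coef_.T + self.intercept_

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        idx = np.argmax(scores, axis=1)  # argmax takes the first max: tie rule
        return np.array([int(self.class_order[i]) for i in idx])

    def predict(self, frame: Frame) -> GraspLabel:
        """Predict the grasp for a single frame."""
        x = vectorize(frame)
        return GraspLabel(int(self.predict_features(x[None, :])[0]))


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    shrinkage: float | str = "auto",
) -> GraspClassifier:
    """Fit the shrinkage-regularized LDA classifier.

    Parameters
    ----------
    features
        ``(n, p)`` matrix of feature vectors.
    labels
        Integer grasp labels (values of :class:`GraspLabel`).
    shrinkage
        lambda in [0, 1], or ``"auto"`` for the Ledoit-Wolf analytic rule
        on the pooled within-class scatter.

    Raises
    ------
    ValueError
        If fewer than two classes are present, any class has fewer than
        two samples, or lambda is outside [0, 1] (lambda = 0 additionally
        requires the pooled covariance to be nonsingular, i.e. enough
        samples for the dimension).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, p) with one label per row")
    classes = [c for c in CLASS_ORDER if int(c) in set(y.tolist())]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit LDA")
    counts = {c: int(np.sum(y == int(c))) for c in classes}
    for c, cnt in counts.items():
        if cnt < 2:
            raise ValueError(f"class {c.name} has {cnt} sample(s); need >= 2")

    n, p = X.shape
    K = len(classes)
    means = np.stack([X[y == int(c)].mean(axis=0) for c in classes])
    priors = np.array([counts[c] / n for c in classes])

    # centered within-class residuals; pooled covariance S = Xc^T Xc / (n - K)
    Xc = X.copy()
    for i, c in enumerate(classes):
        Xc[y == int(c)] -= means[i]
    dof = n - K

    if shrinkage == "auto":
        lam = _ledoit_wolf_lambda(Xc)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")

    tr_S = float(np.einsum("ij,ij->", Xc, Xc)) / dof
    nu = tr_S / p  # shrinkage target scale tr(S)/p
    if nu == 0.0:
        # zero within-class scatter: any isotropic scale gives the same
        # nearest-mean rule, so use a unit target instead of a singular one
        nu = 1.0
    alpha = lam * nu  # isotropic part of Sigma_lambda

    if lam == 1.0:
        coef = means / alpha
    elif p <= max(n, 512):
        S = (Xc.T @ Xc) / dof
        sigma = (1.0 - lam) * S + alpha * np.eye(p)
        coef = np.linalg.solve(sigma, means.T).T
    else:
        if alpha <= 0:
            raise ValueError(
                "shrinkage 0 with p >> n leaves the covariance singular; "
                "use shrinkage > 0 or 'auto'"
            )
        # Woodbury: Sigma = alpha I + B^T B with B = sqrt((1-lam)/dof) Xc
        B = np.sqrt((1.0 - lam) / dof) * Xc  # (n, p)
        core = alpha * np.eye(n) + B @ B.T   # (n, n)
        Bm = B @ means.T                     # (n, K)
        coef = (means.T / alpha - B.T @ np.linalg.solve(core, Bm) / alpha).T

    intercept = -0.5 * np.einsum("kp,kp->k", means, coef) + np.log(priors)
    return GraspClassifier(
        class_order=tuple(classes),
        means=means,
        priors=priors,
        shrinkage=lam,
        coef_=coef,
        intercept_=intercept,
    )


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def classification_accuracy(predictions, truths) -> float:
    """Percent of frames whose predicted grasp matches the true grasp."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape:
        raise ValueError("predictions and truths must have equal length")
    if pred.size == 0:
        raise ValueError("cannot score an empty prediction list")
    return 100.0 * float(np.mean(pred == true))


@dataclass
class AccuracyMatrix:
    """Train-strategy x test-condition accuracy grid (percent).

    Static sessions give an 8 x 7 grid (7 single positions + ALL by 7 test
    positions); dynamic sessions give 5 x 4.  Row order matches
    ``row_labels``; the final row is the pooled ALL classifier.  The
    diagonal of the single-condition rows holds intra-condition accuracy,
    the off-diagonal inter-condition accuracy.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    load: Load
    arm_side: str = "RIGHT"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape must match labels")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("accuracies must lie in [0, 100]")
        self.values = v

    @property
    def diagonal_mean(self) -> float:
        """Mean intra-condition accuracy over single-condition rows."""
        k = len(self.col_labels)
        return float(np.mean(np.diag(self.values[:k, :k])))

    @property
    def offdiagonal_mean(self) -> float:
        """Mean inter-condition accuracy over single-condition rows."""
        k = len(self.col_labels)
        sub = self.values[:k, :k]
        mask = ~np.eye(k, dtype=bool)
        return float(np.mean(sub[mask]))

    @property
    def all_row_mean(self) -> float:
        """Mean accuracy of the pooled ALL classifier across test conditions."""
        return float(np.mean(self.values[-1]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )


def strategies_for(mode: Mode) -> list[TrainingStrategy]:
    if mode is Mode.STATIC:
        return [TrainingStrategy("static_single", p) for p in STATIC_POSITIONS] + [
            TrainingStrategy("static_all")
        ]
    if mode is Mode.DYNAMIC:
        return [TrainingStrategy("dynamic_single", p) for p in DYNAMIC_PATTERNS] + [
            TrainingStrategy("dynamic_all")
        ]
    return [TrainingStrategy("continuous_dynamic")]


def cross_condition_matrix(
    session: list[AcquisitionRecord],
    load: Load,
    mode: Mode,
    split: SplitAssignment,
    shrinkage: float | str = "auto",
) -> AccuracyMatrix:
    """Train one classifier per condition (plus pooled ALL) on the training
    repeats and score each on every condition's test repeats."""
    if mode is Mode.STATIC:
        conditions = STATIC_POSITIONS
    elif mode is Mode.DYNAMIC:
        conditions = DYNAMIC_PATTERNS
    else:
        raise ValueError("cross-condition matrices are defined for STATIC/DYNAMIC")
    train_records = [r for r in session if split.is_train(r)]
    test_records = [r for r in session if not split.is_train(r)]

    test_sets = {}
    for cond in conditions:
        sel = [
            r
            for r in test_records
            if r.load.value is load and r.arm_condition.key == cond
        ]
        if not sel:
            raise ValueError(f"no test records for condition {cond!r}")
        Xt = np.concatenate(
            [np.stack([vectorize(f) for f in r.frames]) for r in sel]
        )
        yt = np.concatenate([np.full(r.n_frames, int(r.grasp)) for r in sel])
        test_sets[cond] = (Xt, yt)

    strategies = strategies_for(mode)
    rows = []
    for strat in strategies:
        X, y = assemble_training_set(train_records, strat, load)
        clf = fit_lda(X, y, shrinkage)
        rows.append(
            [
                classification_accuracy(clf.predict_features(Xt), yt)
                for cond, (Xt, yt) in ((c, test_sets[c]) for c in conditions)
            ]
        )
    return AccuracyMatrix(
        values=np.array(rows),
        row_labels=tuple(s.label for s in strategies),
        col_labels=tuple(conditions),
        load=load,
        arm_side=session[0].arm_side if session else "RIGHT",
    )
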