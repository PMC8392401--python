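"""Margin classification: ROC construction, cut-off selection, the
two-criteria sequential decision protocol, quadrant assignment and
diagnostic evaluation.

A specimen is *positive* (tumour-containing, classes M and T) or *negative*
(healthy, class H). Single-criterion rules:

* Ratio rule — positive iff Ratio > 2.19 (high is positive);
* 2R1 rule  — positive iff 2R1 <= 24.0 s^-1 (low is positive).

The sequential protocol applies one rule decisively outside a borderline
band and defers band specimens to the other quantifier:

* ratio-first — Ratio > 2.19 positive, Ratio < 1.95 negative, and for
  1.95 <= Ratio <= 2.19 an extra 0.39 MHz acquisition decides by the 2R1
  rule;
* 2R1-first  — 2R1 <= 24.0 positive, 2R1 > 26.5 negative, and for
  24.0 < 2R1 <= 26.5 the Ratio rule decides.

The shipped cut-offs (2.19, 24.0) and band limits (1.95, 26.5 s^-1) are the
protocol constants derived on the original 104-specimen cohort; on new data
they can be re-selected from a ROC sweep (:func:`best_cutoff`, or
``SequentialCutoffClassifier(select_cutoffs=True)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import MissingMeasurementError
from .quantifiers import QuantifierSet

POSITIVE, NEGATIVE = "positive", "negative"

#: Class-label -> binary outcome: healthy specimens are negative, any tumour
#: content (mixed or tumour) is positive.
CLASS_TO_OUTCOME = {"H": NEGATIVE, "M": POSITIVE, "T": POSITIVE}


def outcome_from_class(true_class: str) -> str:
    """Map an H/M/T histology label to the binary margin outcome."""
    try:
        return CLASS_TO_OUTCOME[true_class]
    except KeyError:
        raise ValueError(f"unknown class label: {true_class!r}") from None


@dataclass(frozen=True)
class CutoffProtocol:
    """Cut-offs, borderline band limits and criterion order of the protocol."""

    ratio_cutoff: float = 2.19
    ratio_band_low: float = 1.95
    two_r1_cutoff: float = 24.0
    two_r1_band_high: float = 26.5
    order: str = "ratio_first"

    def __post_init__(self):
        if self.ratio_band_low > self.ratio_cutoff:
            raise ValueError("ratio_band_low must not exceed ratio_cutoff")
        if self.two_r1_cutoff > self.two_r1_band_high:
            raise ValueError("two_r1_cutoff must not exceed two_r1_band_high")
        if self.order not in ("ratio_first", "two_r1_first"):
            raise ValueError(f"unknown order: {self.order!r}")


@dataclass(frozen=True)
class Decision:
    """One classification outcome with its decision path and quadrant."""

    sample_id: str
    predicted: str  # positive / negative
    path: str  # first_criterion / second_criterion
    quadrant: str | None = None  # I..IV when both quantifiers are known


@dataclass(frozen=True)
class ROCCurve:
    """A threshold sweep: sensitivity vs 1-specificity with trapezoid AUC.

    ``orientation`` records which direction of the score counts as positive;
    thresholds are placed at midpoints between adjacent unique scores (with
    infinite sentinels) so ties never sit on a threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    orientation: str
    auc: float


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts with the three headline rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def roc_curve(scores, labels, orientation: str = "high_is_positive") -> ROCCurve:
    """ROC sweep over the unique score values.

    ``labels`` are ``positive``/``negative`` (H/M/T class labels are also
    accepted and mapped through :func:`outcome_from_class`). The AUC is the
    trapezoid area, which equals the concordance (Mann-Whitney) statistic
    with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    lab = [l if l in (POSITIVE, NEGATIVE) else outcome_from_class(l) for l in labels]
    y = np.asarray([1 if l == POSITIVE else 0 for l in lab])
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    if orientation not in ("high_is_positive", "low_is_positive"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    internal = s if orientation == "high_is_positive" else -s

    order = np.argsort(-internal, kind="mergesort")
    si, yi = internal[order], y[order]
    # last index of each unique value in the descending sweep
    boundary = np.flatnonzero(np.append(np.diff(si) != 0, True))
    tp = np.cumsum(yi)[boundary]
    fp = np.cumsum(1 - yi)[boundary]
    sens = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    uniq_desc = si[boundary]
    mids = (uniq_desc[:-1] + uniq_desc[1:]) / 2.0
    thr_internal = np.concatenate([[np.inf], mids, [-np.inf]])
    thresholds = thr_internal if orientation == "high_is_positive" else -thr_internal
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds, sens, fpr, orientation, auc)


def best_cutoff(roc: ROCCurve, criterion: str = "youden") -> float:
    """Threshold optimizing a ROC criterion.

    ``youden`` maximizes sensitivity + specificity - 1;
    ``closest_to_perfect`` minimizes the distance to the (0, 1) corner;
    ``equal_error_rate`` minimizes |sensitivity - specificity|. Ties break
    toward higher sensitivity, then higher specificity.
    """
    sens, fpr = roc.sensitivity, roc.one_minus_specificity
    if criterion == "youden":
        objective = -(sens - fpr)
    elif criterion == "closest_to_perfect":
        objective = (1 - sens) ** 2 + fpr**2
    elif criterion == "equal_error_rate":
        objective = np.abs(sens - (1 - fpr))
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    # lexicographic: objective asc, then sensitivity desc, then specificity desc
    idx = sorted(range(len(objective)), key=lambda i: (objective[i], -sens[i], fpr[i]))[0]
    return float(roc.thresholds[idx])


def classify_single(q: QuantifierSet, protocol: CutoffProtocol, which: str) -> Decision:
    """Single-criterion decision.

    Ratio rule: positive iff ratio > cutoff (the cutoff itself is negative).
    2R1 rule: positive iff two_r1 <= cutoff (the cutoff itself is positive).
    """
    if which == "ratio":
        predicted = POSITIVE if q.ratio > protocol.ratio_cutoff else NEGATIVE
    elif which == "two_r1":
        if q.two_r1 is None:
            raise MissingMeasurementError(
                f"sample '{q.sample_id}': 2R1 required but the 0.39 MHz acquisition is missing"
            )
        predicted = POSITIVE if q.two_r1 <= protocol.two_r1_cutoff else NEGATIVE
    else:
        raise ValueError(f"unknown quantifier: {which!r}")
    quadrant = assign_quadrant(q, protocol) if q.two_r1 is not None else None
    return Decision(q.sample_id, predicted, "first_criterion", quadrant)


def classify_sequential(q: QuantifierSet, protocol: CutoffProtocol | None = None) -> Decision:
    """Two-criteria sequential decision in the protocol's configured order.

    Specimens decided outside the borderline band carry
    ``path='first_criterion'``; band specimens are decided by the other
    quantifier (``path='second_criterion'``) and raise
    :class:`MissingMeasurementError` if it was never measured — the signal
    that the extra acquisition must be performed.
    """
    protocol = protocol or CutoffProtocol()
    if protocol.order == "ratio_first":
        # a zero-width band (band_low == cutoff) disables deferral entirely,
        # collapsing the sequential rule onto the Ratio-only rule
        in_band = (
            protocol.ratio_band_low < protocol.ratio_cutoff
            and protocol.ratio_band_low <= q.ratio <= protocol.ratio_cutoff
        )
        if q.ratio > protocol.ratio_cutoff:
            predicted, path = POSITIVE, "first_criterion"
        elif not in_band:
            predicted, path = NEGATIVE, "first_criterion"
        else:
            if q.two_r1 is None:
                raise MissingMeasurementError(
                    f"sample '{q.sample_id}': Ratio {q.ratio:.3f} is borderline "
                    f"[{protocol.ratio_band_low}, {protocol.ratio_cutoff}]; "
                    "an R1 acquisition at 0.39 MHz is required"
                )
            predicted = POSITIVE if q.two_r1 <= protocol.two_r1_cutoff else NEGATIVE
            path = "second_criterion"
    else:  # two_r1_first
        if q.two_r1 is None:
            raise MissingMeasurementError(
                f"sample '{q.sample_id}': 2R1-first protocol requires the 0.39 MHz acquisition"
            )
        if q.two_r1 <= protocol.two_r1_cutoff:
            predicted, path = POSITIVE, "first_criterion"
        elif q.two_r1 > protocol.two_r1_band_high:
            predicted, path = NEGATIVE, "first_criterion"
        else:
            predicted = POSITIVE if q.ratio > protocol.ratio_cutoff else NEGATIVE
            path = "second_criterion"
    quadrant = assign_quadrant(q, protocol) if q.two_r1 is not None else None
    return Decision(q.sample_id, predicted, path, quadrant)


def assign_quadrant(q: QuantifierSet, protocol: CutoffProtocol | None = None) -> str:
    """Quadrant of the (2R1, Ratio) plane under the two cut-offs.

    I: Ratio above its cut-off and 2R1 at or below its cut-off (both rules
    positive — tumour-like); II: Ratio above, 2R1 above; III: Ratio at or
    below, 2R1 above (both rules negative — healthy-like); IV: Ratio at or
    below, 2R1 at or below. Boundary membership follows the single-criterion
    conventions (Ratio positive strictly above, 2R1 positive at <=).
    """
    protocol = protocol or CutoffProtocol()
    if q.two_r1 is None:
        raise MissingMeasurementError(
            f"sample '{q.sample_id}': quadrant assignment needs both quantifiers"
        )
    ratio_pos = q.ratio > protocol.ratio_cutoff
    two_r1_pos = q.two_r1 <= protocol.two_r1_cutoff
    if ratio_pos and two_r1_pos:
        return "I"
    if ratio_pos and not two_r1_pos:
        return "II"
    if not ratio_pos and not two_r1_pos:
        return "III"
    return "IV"


def evaluate(decisions, truth) -> ConfusionSummary:
    """Confusion counts of a decision list against H/M/T ground truth.

    H is negative; M and T are positive. ``truth`` may also contain
    ``positive``/``negative`` directly.
    """
    if len(decisions) != len(truth):
        raise ValueError("decisions and truth must be aligned lists of equal length")
    tp = fp = tn = fn = 0
    for d, t in zip(decisions, truth):
        actual = t if t in (POSITIVE, NEGATIVE) else outcome_from_class(t)
        pred = d.predicted if isinstance(d, Decision) else d
        if actual == POSITIVE:
            if pred == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if pred == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionSummary:
    """Build a :class:`ConfusionSummary` directly from counts."""
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


class SequentialCutoffClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn estimator wrapping the sequential two-cutoff protocol.

    ``X`` has two columns, ``[ratio, two_r1]``; ``two_r1`` may be NaN for
    specimens on which only the two-field Ratio acquisition was run (allowed
    as long as they fall outside the borderline band). ``y`` is binary; the
    label named by ``pos_label`` is the tumour-containing class.

    By default the protocol constants are used unchanged and ``fit`` only
    validates the data and records the classes. With ``select_cutoffs=True``
    the two cut-offs are re-selected on the training data from ROC sweeps
    (criterion ``selection_criterion``), keeping the band half-widths at
    their configured offsets from the cut-offs.

    Examples
    --------
    >>> import numpy as np
    >>> clf = SequentialCutoffClassifier(pos_label=1)
    >>> X = np.array([[3.4, 12.0], [1.8, 35.0], [2.0, 20.0]])
    >>> clf.fit(X, [1, 0, 1]).predict(X).tolist()
    [1, 0, 1]
    """

    def __init__(
        self,
        ratio_cutoff: float = 2.19,
        ratio_band_low: float = 1.95,
        two_r1_cutoff: float = 24.0,
        two_r1_band_high: float = 26.5,
        order: str = "ratio_first",
        select_cutoffs: bool = False,
        selection_criterion: str = "youden",
        pos_label=POSITIVE,
    ):
        self.ratio_cutoff = ratio_cutoff
        self.ratio_band_low = ratio_band_low
        self.two_r1_cutoff = two_r1_cutoff
        self.two_r1_band_high = two_r1_band_high
        self.order = order
        self.select_cutoffs = select_cutoffs
        self.selection_criterion = selection_criterion
        self.pos_label = pos_label

    def _check_X(self, X):
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly 2 columns: [ratio, two_r1]")
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("y must contain exactly two classes")
        if self.pos_label not in self.classes_:
            raise ValueError(f"pos_label {self.pos_label!r} not found in y")
        self.n_features_in_ = 2
        ratio_cut, two_r1_cut = self.ratio_cutoff, self.two_r1_cutoff
        if self.select_cutoffs:
            labels = [POSITIVE if v == self.pos_label else NEGATIVE for v in y]
            ratio_cut = best_cutoff(
                roc_curve(X[:, 0], labels, "high_is_positive"), self.selection_criterion
            )
            two_r1 = X[:, 1]
            if np.isnan(two_r1).any():
                raise ValueError("select_cutoffs=True requires complete 2R1 measurements")
            two_r1_cut = best_cutoff(
                roc_curve(two_r1, labels, "low_is_positive"), self.selection_criterion
            )
        self.protocol_ = CutoffProtocol(
            ratio_cutoff=ratio_cut,
            ratio_band_low=ratio_cut - (self.ratio_cutoff - self.ratio_band_low),
            two_r1_cutoff=two_r1_cut,
            two_r1_band_high=two_r1_cut + (self.two_r1_band_high - self.two_r1_cutoff),
            order=self.order,
        )
        return self

    def _decisions(self, X) -> list[Decision]:
        check_is_fitted(self, "protocol_")
        X = self._check_X(X)
        out = []
        for i, (ratio, two_r1) in enumerate(X):
            q = QuantifierSet(
                sample_id=str(i), ratio=float(ratio),
                two_r1=None if np.isnan(two_r1) else float(two_r1),
            )
            out.append(classify_sequential(q, self.protocol_))
        return out

    def predict(self, X):
        neg = self.classes_[self.classes_ != self.pos_label][0]
        return np.asarray(
            [self.pos_label if d.predicted == POSITIVE else neg for d in self._decisions(X)]
        )

    def decision_path_labels(self, X):
        """Which criterion decided each specimen (first/second)."""
        return np.asarray([d.path for d in self._decisions(X)])

    def predict_quadrant(self, X):
        """Quadrant (I-IV) for each specimen; requires both quantifiers."""
        check_is_fitted(self, "protocol_")
        X = self._check_X(X)
        return np.asarray(
            [
                assign_quadrant(
                    QuantifierSet(str(i), float(r), float(t)), self.protocol_
                )
                for i, (r, t) in enumerate(X)
            ]
        )
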