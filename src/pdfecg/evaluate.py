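"""Agreement statistics and the diagnosis-classification experiment.

Validation of digitized interval measurements against reference values uses
Bland-Altman limits of agreement (bias +- 1.96 SD of the pairwise
differences) and the Pearson product-moment correlation with a two-sided
t-test of r = 0 at alpha = 0.05.

Classification follows a 100-run stratified patient-leave-out protocol: each
run holds out exactly one patient per diagnosis class (all of that patient's
ECGs go to the test set together), fits a fresh RBF-kernel SVM (C = 1) on
the remainder with train-only feature standardisation, and accumulates the
test confusion across runs.  One-vs-rest ROC AUC comes from pooled decision
scores and calibration curves from pooled Platt probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from pdfecg.errors import (
    DegenerateInputError,
    PairingError,
    ShapeError,
    StratificationError,
)

__all__ = [
    "AgreementResult",
    "SplitPlan",
    "EvalResult",
    "bland_altman",
    "pearson_test",
    "make_split_plan",
    "aligned_features",
    "train_eval",
    "metrics_from_confusion",
]


def aligned_features(records, reference_lead: str = "II", decimate: int = 4,
                     window_ms: float | None = 700.0) -> np.ndarray:
    """R-aligned, concatenated 12-lead feature vectors for a cohort.

    R peaks are detected once per record on the reference lead; all twelve
    leads of a record are then shifted by the same amount (they are
    synchronous), so the QRS complexes line up across the whole cohort.

    ``window_ms`` crops each aligned lead to a window centred on the common
    R column before concatenation, so the classifier sees the synchronized
    beat's morphology rather than the spacing of neighbouring beats (which
    would make heart rate the dominant feature).  ``None`` keeps the full
    strip.  ``decimate`` keeps every k-th sample, which leaves QRS
    morphology intact at 500 Hz while shrinking the feature dimension.
    Row order follows ``records``.
    """
    from pdfecg.align import align_on_r
    from pdfecg.calibrate import LEAD_ORDER
    from pdfecg.fiducials import detect_r_peaks

    records = list(records)
    r_sets = [detect_r_peaks(rec.leads[reference_lead]) for rec in records]
    blocks = []
    for name in LEAD_ORDER:
        aligned = align_on_r([rec.leads[name] for rec in records], r_sets,
                             source_ids=[str(i) for i in range(len(records))])
        m = aligned.matrix
        if window_ms is not None:
            half = int(round(window_ms / 2000.0 * records[0].fs))
            lo = max(aligned.reference_index - half, 0)
            hi = min(aligned.reference_index + half, m.shape[1])
            m = m[:, lo:hi]
        blocks.append(m[:, ::decimate])
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# agreement statistics

@dataclass(frozen=True)
class AgreementResult:
    means: np.ndarray
    diffs: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    p_two_sided: float

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement between two paired measurement series.

    diffs are ``x - y``; bias is their mean; the limits of agreement are
    bias +- 1.96 * SD(diffs, ddof=1).  Pearson r and its two-sided p value
    for the pairing are included for the usual companion report.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired inputs must match: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise PairingError("need at least 3 pairs")
    means = (x + y) / 2.0
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    try:
        r, p = pearson_test(x, y)[:2]
    except DegenerateInputError:
        r, p = float("nan"), float("nan")
    return AgreementResult(means, diffs, bias, bias - 1.96 * sd, bias + 1.96 * sd, r, p)


def pearson_test(x, y, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Pearson r with a two-sided significance test of H0: r = 0.

    The test statistic is ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of
    freedom.  Returns ``(r, p, reject_null)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired inputs must match: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise PairingError("need at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    r = float((xc * yc).sum() / denom)
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sstats.t.sf(abs(t), df=n - 2))
    return r, p, p < alpha


# ---------------------------------------------------------------------------
# stratified patient-leave-out split plan

@dataclass(frozen=True)
class SplitPlan:
    """100-run plan: per run, test = exactly one patient per class."""

    runs: tuple                  # ((train_patients, test_patients), ...)
    classes: tuple
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def make_split_plan(patient_labels: dict, n_runs: int = 100, seed: int = 0
                    ) -> SplitPlan:
    """Draw ``n_runs`` train/test patient splits, one held-out patient per class.

    ``patient_labels`` maps patient id -> class label.  Reproducible from
    ``seed``; a class with fewer than two patients cannot both train and
    test and raises :class:`StratificationError`.
    """
    classes = tuple(sorted(set(patient_labels.values())))
    by_class = {c: sorted(p for p, l in patient_labels.items() if l == c)
                for c in classes}
    for c, members in by_class.items():
        if len(members) < 2:
            raise StratificationError(f"class {c!r} has {len(members)} patient(s)")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        test = tuple(members[rng.integers(len(members))]
                     for members in by_class.values())
        train = tuple(p for p in sorted(patient_labels) if p not in test)
        runs.append((train, test))
    return SplitPlan(tuple(runs), classes, seed)


# ---------------------------------------------------------------------------
# SVM experiment

@dataclass
class EvalResult:
    classes: tuple
    confusion: np.ndarray            # (K, K) counts, rows = true class
    per_class: dict                  # class -> {precision, sensitivity, specificity, f1}
    auc_ovr: dict                    # class -> one-vs-rest AUC averaged over runs
    calibration: dict                # class -> {bin_centers, observed, counts}
    auc_ovr_pooled: dict = field(default_factory=dict)  # AUC on pooled scores
    n_runs: int = 0
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "auc_ovr": self.auc_ovr,
            "n_runs": self.n_runs,
        }


def shuffled_label_null(features, labels, patients, plan: SplitPlan,
                        n_shuffles: int = 20, runs_per_shuffle: int = 10,
                        seed: int = 0, C: float = 1.0) -> dict:
    """Chance-level reference: mean one-vs-rest AUC under label permutation.

    A single permutation of the per-ECG labels retains chance correlations
    with the cohort's patient-cluster structure, so its AUC scatters around
    0.5; averaging several independent permutations (each over a fresh slice
    of the split plan) gives the concentrated chance-level estimate a random
    predictor should match.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    sums = {c: 0.0 for c in plan.classes}
    counts = {c: 0 for c in plan.classes}
    for k in range(n_shuffles):
        ylab = rng.permutation(labels)
        sub = SplitPlan(plan.runs[k * runs_per_shuffle:(k + 1) * runs_per_shuffle]
                        or plan.runs[:runs_per_shuffle], plan.classes, plan.seed)
        res = train_eval(features, ylab, patients, sub, C=C, probability=False)
        for c in plan.classes:
            if np.isfinite(res.auc_ovr[c]):
                sums[c] += res.auc_ovr[c]
                counts[c] += 1
    return {c: sums[c] / max(counts[c], 1) for c in plan.classes}


def metrics_from_confusion(confusion) -> dict:
    """One-vs-rest precision/sensitivity/specificity/F1 per class.

    Rows are true classes, columns predicted.  A zero denominator yields 0
    for that metric with a note under ``"_flags"``.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ShapeError(f"confusion matrix must be square, got {c.shape}")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
        raise ShapeError("confusion matrix must hold non-negative counts")
    k = c.shape[0]
    total = c.sum()
    out: dict = {"_flags": []}
    for i in range(k):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp

        def safe(num, den, name):
            if den == 0:
                out["_flags"].append(f"class {i}: zero denominator for {name}")
                return 0.0
            return float(num / den)

        precision = safe(tp, tp + fp, "precision")
        sensitivity = safe(tp, tp + fn, "sensitivity")
        specificity = safe(tn, tn + fp, "specificity")
        if precision + sensitivity == 0:
            out["_flags"].append(f"class {i}: zero denominator for f1")
            f1 = 0.0
        else:
            f1 = 2 * precision * sensitivity / (precision + sensitivity)
        out[i] = {"precision": precision, "sensitivity": sensitivity,
                  "specificity": specificity, "f1": f1}
    return out


def train_eval(features, labels, patients, plan: SplitPlan,
               C: float = 1.0, gamma="scale", calibration_bins: int = 10,
               probability: bool = True) -> EvalResult:
    """Run the full patient-leave-out SVM experiment.

    ``features`` is (n_ecgs, d); ``labels`` and ``patients`` give each ECG's
    class and owning patient.  Per run the classifier is fitted from scratch
    on the training ECGs (z-scored with train-only statistics) and evaluated
    on every ECG of the held-out patients.  Patient-level leakage is asserted
    on every run, never assumed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    pats = np.asarray(patients)
    if not (X.shape[0] == y.size == pats.size):
        raise PairingError("features, labels and patients must align")

    classes = plan.classes
    k = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    pooled_scores, pooled_probs, pooled_true = [], [], []
    run_aucs: dict = {c: [] for c in classes}

    for train_p, test_p in plan.runs:
        train_set, test_set = set(train_p), set(test_p)
        if train_set & test_set:
            raise StratificationError("patient appears in both train and test")
        train_mask = np.isin(pats, list(train_set))
        test_mask = np.isin(pats, list(test_set))
        assert not np.any(train_mask & test_mask)

        mu = X[train_mask].mean(axis=0)
        sd = X[train_mask].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train_mask] - mu) / sd
        Xte = (X[test_mask] - mu) / sd

        with warnings.catch_warnings():
            # scikit-learn 1.9 deprecates SVC(probability=True) in favour of
            # CalibratedClassifierCV; Platt scaling inside SVC is what we want
            warnings.simplefilter("ignore", FutureWarning)
            clf = SVC(C=C, kernel="rbf", gamma=gamma, probability=probability,
                      random_state=0, decision_function_shape="ovr")
            clf.fit(Xtr, y[train_mask])
        pred = clf.predict(Xte)
        for t, p in zip(y[test_mask], pred):
            confusion[cls_index[t], cls_index[p]] += 1
        scores = clf.decision_function(Xte)
        if scores.ndim == 1:    # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        # decision_function columns follow clf.classes_; re-order to plan order
        order = [list(clf.classes_).index(c) for c in classes if c in clf.classes_]
        full = np.full((scores.shape[0], k), -np.inf)
        for j, oc in zip(range(len(order)), order):
            full[:, cls_index[clf.classes_[oc]]] = scores[:, oc]
        pooled_scores.append(full)
        for c in classes:
            binary = (y[test_mask] == c).astype(int)
            if 0 < binary.sum() < binary.size:
                run_aucs[c].append(roc_auc_score(binary, full[:, cls_index[c]]))
        if probability:
            probs = clf.predict_proba(Xte)
            pfull = np.zeros((probs.shape[0], k))
            for j, c in enumerate(clf.classes_):
                pfull[:, cls_index[c]] = probs[:, j]
            pooled_probs.append(pfull)
        pooled_true.append(y[test_mask])

    scores = np.vstack(pooled_scores)
    true = np.concatenate(pooled_true)
    # primary AUC: mean of per-run one-vs-rest AUCs (rank-based within each
    # run, so per-run score offsets cannot masquerade as discrimination);
    # pooled-score AUC kept as a secondary view
    auc = {c: (float(np.mean(run_aucs[c])) if run_aucs[c] else float("nan"))
           for c in classes}
    auc_pooled = {}
    for c in classes:
        binary = (true == c).astype(int)
        if binary.min() == binary.max():
            auc_pooled[c] = float("nan")
        else:
            auc_pooled[c] = float(roc_auc_score(binary, scores[:, cls_index[c]]))

    calibration = {}
    if probability and pooled_probs:
        probs = np.vstack(pooled_probs)
        edges = np.linspace(0.0, 1.0, calibration_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for c in classes:
            p = probs[:, cls_index[c]]
            obs = np.full(calibration_bins, np.nan)
            cnt = np.zeros(calibration_bins, dtype=int)
            which = np.clip(np.digitize(p, edges) - 1, 0, calibration_bins - 1)
            for b in range(calibration_bins):
                m = which == b
                cnt[b] = m.sum()
                if cnt[b]:
                    obs[b] = float((true[m] == c).mean())
            calibration[c] = {"bin_centers": centers.tolist(),
                              "observed": obs.tolist(),
                              "counts": cnt.tolist()}

    metrics = metrics_from_confusion(confusion)
    flags = {"metric_flags": metrics.pop("_flags")}
    per_class = {classes[i]: metrics[i] for i in range(k)}
    return EvalResult(classes, confusion, per_class, auc, calibration,
                      auc_ovr_pooled=auc_pooled, n_runs=plan.n_runs, flags=flags)
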