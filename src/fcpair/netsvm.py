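"""Network-level classification of medication state from connectivity.

The 325 unique connections among the 26 ROIs are partitioned into six
subnetwork masks — the three within-network blocks (cerebellum, basal
ganglia + thalamus, motor cortex; hemispheres merged) and the three
between-network blocks.  Per mask, each scan's connection values form a
feature vector; features are standardised, linearly decorrelated by
principal components, and classified by a soft-margin linear support
vector machine (medicated vs drug-naive).  Evaluation uses
leave-one-subject-out cross-validation (both scans of one patient held out
per fold; standardisation and projection fit on the training folds only).
Significance comes from refitting the full cross-validation under label
permutations: the observed accuracy must exceed the 97.5th percentile of
the permutation null.  Across the six masks the permutation p-values are
FDR adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .flperm import fdr_adjust

__all__ = [
    "SubnetworkMask",
    "build_masks",
    "extract_features",
    "reduce_dimensionality",
    "SubnetworkSVM",
    "ClassificationResult",
    "compute_metrics",
    "fdr_across_models",
    "correlate_scores_with_clinical",
    "classify_all_masks",
]

POSITIVE = "levodopa"
NEGATIVE = "de_novo"


@dataclass(frozen=True)
class SubnetworkMask:
    """Edge indices (into the row-major upper triangle) of one mask."""

    name: str
    network_a: str
    network_b: str
    edge_indices: tuple

    @property
    def within(self) -> bool:
        return self.network_a == self.network_b

    @property
    def n_edges(self) -> int:
        return len(self.edge_indices)


_SHORT = {"cerebellum": "CBL", "basal_ganglia": "BG", "motor_cortex": "MC"}


def build_masks(roi_labels, network_of) -> list[SubnetworkMask]:
    """The six within/between subnetwork masks partitioning all edges.

    Edge order inside each mask follows the row-major upper-triangle
    ordering of the ROI label sequence, so feature vectors are reproducible
    across scans by construction.
    """
    missing = [l for l in roi_labels if l not in network_of]
    if missing:
        raise ValueError(f"ROI(s) without a network assignment: {missing}")
    nets = []
    for l in roi_labels:
        if network_of[l] not in nets:
            nets.append(network_of[l])
    n = len(roi_labels)
    iu = np.triu_indices(n, 1)
    edge_nets = [
        tuple(sorted((network_of[roi_labels[i]], network_of[roi_labels[j]])))
        for i, j in zip(*iu)
    ]
    masks = []
    pairs = [(a, a) for a in nets] + [
        (a, b) for i, a in enumerate(nets) for b in nets[i + 1 :]
    ]
    for a, b in pairs:
        key = tuple(sorted((a, b)))
        idx = tuple(e for e, en in enumerate(edge_nets) if en == key)
        masks.append(
            SubnetworkMask(
                name=f"{_SHORT.get(a, a)}x{_SHORT.get(b, b)}",
                network_a=a, network_b=b, edge_indices=idx,
            )
        )
    return masks


def extract_features(fc, mask: SubnetworkMask) -> np.ndarray:
    """Gather one scan's connection values for a mask."""
    tri = fc.upper_triangle()
    idx = np.asarray(mask.edge_indices, int)
    if idx.size and idx.max() >= tri.size:
        raise ValueError("mask indices exceed the connectivity edge count")
    return tri[idx]


def reduce_dimensionality(train_matrix: np.ndarray, n_components: int):
    """Standardise then project onto leading principal components.

    Fits the scaler and the eigendecomposition of the training covariance;
    returns ``(transform, transformed_train)`` where ``transform`` maps
    held-out samples into the same component space.
    """
    train_matrix = np.asarray(train_matrix, float)
    n_obs, n_feat = train_matrix.shape
    if n_obs < 2:
        raise ValueError("need at least 2 training samples")
    k = min(n_components, n_feat, n_obs - 1)
    if k < 1:
        raise ValueError("retained component count must be >= 1")
    scaler = StandardScaler().fit(train_matrix)
    pca = PCA(n_components=k, svd_solver="full").fit(scaler.transform(train_matrix))

    def transform(x):
        return pca.transform(scaler.transform(np.atleast_2d(np.asarray(x, float))))

    return transform, transform(train_matrix)


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Accuracy, sensitivity and specificity with the medicated state positive."""
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("empty confusion table")
    out = {"accuracy": (tp + tn) / total}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
    out["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    return out


def fdr_across_models(p_values, alpha: float = 0.05):
    """BH adjustment of the per-mask permutation p-values."""
    return fdr_adjust(p_values, alpha=alpha)


class SubnetworkSVM:
    """Linear maximum-margin classifier of medication state for one mask.

    Parameters
    ----------
    features : array, samples x features
        One row per scan (two rows per subject).
    labels : sequence of {"de_novo", "levodopa"}
    subject_ids : sequence
        Subject of each row; every subject must contribute exactly 2 rows.
    within_network : bool
        Component-retention rule: all features for within-network masks,
        ``n_features - 1`` (capped at the training-sample rank) for
        between-network masks.
    C : float
        Soft-margin box constraint of the hinge objective.
    transform_scope : {"fold", "global"}
        Whether standardisation + projection are fit inside each training
        fold (default, leakage-free) or once on all samples.
    """

    def __init__(self, features, labels, subject_ids, mask_name="mask",
                 within_network=True, C=1.0, transform_scope="fold"):
        X = np.asarray(features, float)
        y = np.asarray([1 if l == POSITIVE else 0 for l in labels], int)
        lab = np.asarray(labels, object)
        if not set(lab) <= {POSITIVE, NEGATIVE}:
            raise ValueError(f"labels must be {NEGATIVE!r} or {POSITIVE!r}")
        sids = np.asarray(subject_ids, object)
        if X.shape[0] != y.size or sids.size != y.size:
            raise ValueError("features, labels and subject_ids disagree on length")
        counts = pd.Series(sids).value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise ValueError(
                f"every subject needs exactly 2 samples; offending: {list(bad.index)}"
            )
        if transform_scope not in ("fold", "global"):
            raise ValueError("transform_scope must be 'fold' or 'global'")
        self.X, self.y, self.sids = X, y, sids
        self.mask_name = mask_name
        self.within_network = within_network
        self.C = C
        self.transform_scope = transform_scope
        self._folds = None

    # -- fold machinery -----------------------------------------------------

    def _n_components(self, n_train: int) -> int:
        p = self.X.shape[1]
        want = p if self.within_network else max(p - 1, 1)
        return min(want, p, n_train - 1)

    def _prepare_folds(self):
        """Cache per-fold transformed features (label-independent)."""
        if self._folds is not None:
            return self._folds
        subjects = sorted(set(self.sids))
        folds = []
        if self.transform_scope == "global":
            k = self._n_components(self.X.shape[0])
            transform, _ = reduce_dimensionality(self.X, k)
            Xt = transform(self.X)
            for s in subjects:
                te = np.flatnonzero(self.sids == s)
                tr = np.flatnonzero(self.sids != s)
                folds.append((tr, te, Xt[tr], Xt[te]))
        else:
            for s in subjects:
                te = np.flatnonzero(self.sids == s)
                tr = np.flatnonzero(self.sids != s)
                k = self._n_components(tr.size)
                transform, Xtr = reduce_dimensionality(self.X[tr], k)
                folds.append((tr, te, Xtr, transform(self.X[te])))
        self._folds = folds
        return folds

    def _loocv(self, y, collect_scores=False):
        """Pooled held-out predictions (and scores) for a label vector."""
        preds = np.empty(y.size, int)
        scores = np.empty(y.size, float) if collect_scores else None
        for tr, te, Xtr, Xte in self._prepare_folds():
            ytr = y[tr]
            if ytr.min() == ytr.max():  # degenerate permuted fold
                preds[te] = ytr[0]
                if collect_scores:
                    scores[te] = 0.0
                continue
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(Xtr, ytr)
            if collect_scores:
                s = clf.decision_function(Xte)
                scores[te] = s
                preds[te] = (s > 0).astype(int)
            else:
                preds[te] = clf.predict(Xte)
        return preds, scores

    # -- public API ---------------------------------------------------------

    def fit(self, n_perm: int = 10000, seed: int | None = 0,
            perm_scheme: str = "free", alpha_percentile: float = 97.5
            ) -> "ClassificationResult":
        """Cross-validate, then build the label-permutation accuracy null."""
        if perm_scheme not in ("free", "within_subject"):
            raise ValueError("perm_scheme must be 'free' or 'within_subject'")
        low_perm_warning = None
        if n_perm < 100:
            low_perm_warning = (
                f"n_perm={n_perm} is too small for stable permutation p-values"
            )
            warnings.warn(low_perm_warning, stacklevel=2)
        preds, scores = self._loocv(self.y, collect_scores=True)
        tp = int(np.sum((preds == 1) & (self.y == 1)))
        tn = int(np.sum((preds == 0) & (self.y == 0)))
        fp = int(np.sum((preds == 1) & (self.y == 0)))
        fn = int(np.sum((preds == 0) & (self.y == 1)))
        metrics = compute_metrics(tp, fp, tn, fn)
        auc = float(roc_auc_score(self.y, scores))

        rng = np.random.default_rng(seed)
        null_acc = np.empty(n_perm)
        n = self.y.size
        subjects = sorted(set(self.sids))
        for j in range(n_perm):
            if perm_scheme == "free":
                yp = self.y[rng.permutation(n)]
            else:
                yp = self.y.copy()
                for s in subjects:
                    if rng.random() < 0.5:
                        idx = np.flatnonzero(self.sids == s)
                        yp[idx] = yp[idx[::-1]]
            pj, _ = self._loocv(yp)
            null_acc[j] = np.mean(pj == yp)
        p_raw = (1.0 + np.sum(null_acc >= metrics["accuracy"])) / (n_perm + 1.0)
        threshold = float(np.percentile(null_acc, alpha_percentile))
        return ClassificationResult(
            mask_name=self.mask_name,
            accuracy=metrics["accuracy"],
            sensitivity=metrics["sensitivity"],
            specificity=metrics["specificity"],
            auc=auc,
            confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
            decision_scores=scores,
            labels=self.y.copy(),
            subject_ids=self.sids.copy(),
            p_raw=float(p_raw),
            null_accuracies=null_acc,
            null_percentile_threshold=threshold,
            significant=metrics["accuracy"] > threshold,
            n_perm=n_perm,
            seed=seed,
            warnings=[w for w in [low_perm_warning] if w],
        )


@dataclass
class ClassificationResult:
    """Cross-validated metrics and the permutation null for one mask."""

    mask_name: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: dict
    decision_scores: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    p_raw: float
    null_accuracies: np.ndarray
    null_percentile_threshold: float
    significant: bool
    n_perm: int
    seed: int | None
    p_fdr: float | None = None
    warnings: list = field(default_factory=list)

    def subject_scores(self) -> pd.Series:
        """Mean held-out decision score per subject (medicated minus naive)."""
        df = pd.DataFrame(
            {"sid": self.subject_ids, "y": self.labels, "score": self.decision_scores}
        )
        pos = df[df.y == 1].set_index("sid").score
        return pos.sort_index()

    def roc_points(self) -> pd.DataFrame:
        from sklearn.metrics import roc_curve

        fpr, tpr, thr = roc_curve(self.labels, self.decision_scores)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    def summary(self) -> str:
        c = self.confusion
        return "\n".join(
            [
                f"Subnetwork SVM: {self.mask_name}",
                f"  accuracy={self.accuracy:.2f} sensitivity={self.sensitivity:.2f} "
                f"specificity={self.specificity:.2f} AUC={self.auc:.2f}",
                f"  confusion TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']}",
                f"  permutation p={self.p_raw:.4g} "
                f"(null 97.5th pct accuracy={self.null_percentile_threshold:.3f}; "
                f"{'significant' if self.significant else 'not significant'}; "
                f"n_perm={self.n_perm})",
            ]
        )


def correlate_scores_with_clinical(decision_scores: pd.Series,
                                   clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-subject SVM scores with clinical measures.

    ``clinical`` is indexed by subject id with one numeric column per
    measure.  Constant columns are reported with NaN correlation.
    """
    common = decision_scores.index.intersection(clinical.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched subjects")
    s = decision_scores.loc[common].to_numpy(float)
    rows = []
    for col in clinical.columns:
        v = clinical.loc[common, col].to_numpy(float)
        ok = np.isfinite(v) & np.isfinite(s)
        if ok.sum() < 3 or np.ptp(v[ok]) == 0 or np.ptp(s[ok]) == 0:
            rows.append({"measure": col, "r": np.nan, "p": np.nan,
                         "n": int(ok.sum()), "note": "undefined (constant input)"})
            continue
        r, p = stats.pearsonr(s[ok], v[ok])
        rows.append({"measure": col, "r": float(r), "p": float(p),
                     "n": int(ok.sum()), "note": ""})
    return pd.DataFrame(rows)


def classify_all_masks(fc_by_subject: dict, network_of: dict,
                       n_perm: int = 10000, seed: int | None = 0,
                       C: float = 1.0) -> tuple[pd.DataFrame, dict]:
    """Run all six subnetwork classifiers and FDR-adjust their p-values.

    ``fc_by_subject`` maps subject id -> {condition: ConnectivityMatrix}.
    Returns a summary table shaped like a classification-metrics table plus
    the per-mask :class:`ClassificationResult` objects.
    """
    sids_sorted = sorted(fc_by_subject)
    any_fc = fc_by_subject[sids_sorted[0]][POSITIVE]
    masks = build_masks(any_fc.roi_labels, network_of)
    rows_X = {m.name: [] for m in masks}
    labels, subject_ids = [], []
    for sid in sids_sorted:
        for cond in (NEGATIVE, POSITIVE):
            fc = fc_by_subject[sid][cond]
            for m in masks:
                rows_X[m.name].append(extract_features(fc, m))
            labels.append(cond)
            subject_ids.append(sid)
    results = {}
    seed_seq = np.random.SeedSequence(seed)
    for m, child in zip(masks, seed_seq.spawn(len(masks))):
        model = SubnetworkSVM(
            np.asarray(rows_X[m.name]), labels, subject_ids,
            mask_name=m.name, within_network=m.within, C=C,
        )
        results[m.name] = model.fit(
            n_perm=n_perm, seed=int(child.generate_state(1)[0] % (2**31)),
        )
    p_fdr, _ = fdr_across_models([results[m.name].p_raw for m in masks])
    for m, p in zip(masks, p_fdr):
        results[m.name].p_fdr = float(p)
    table = pd.DataFrame(
        [
            {
                "mask": m.name,
                "accuracy": results[m.name].accuracy,
                "p_raw": results[m.name].p_raw,
                "p_fdr": results[m.name].p_fdr,
                "auc": results[m.name].auc,
                "sensitivity": results[m.name].sensitivity,
                "specificity": results[m.name].specificity,
                "significant": results[m.name].significant,
            }
            for m in masks
        ]
    )
    return table, results
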