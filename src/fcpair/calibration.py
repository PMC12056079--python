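"""Monte-Carlo calibration studies of the pipeline on synthetic cohorts.

These routines regenerate cohorts from the synthetic generator, push them
through the full analysis path, and measure operating characteristics: the
type-I error of the edge-wise permutation GLM, the false-positive rate of
the classifier's permutation rule, the multivariate/univariate dissociation
at the reference effect magnitude, and the recovery of an injected
centrality hub.  They exist so that calibration claims are recomputed, not
asserted.
"""

from __future__ import annotations

import numpy as np

from .cohort import CONDITIONS, CohortConfig, generate_roi_cohort, generate_voxel_cohort
from .ecm import ECMAnalysis
from .flperm import FreedmanLaneGLM, paired_contrast
from .netsvm import SubnetworkSVM, build_masks, extract_features
from .preprocess import compute_fc, run_first_level

__all__ = [
    "cohort_connectivity",
    "mask_features",
    "fl_type1_error",
    "dissociation_rates",
    "svm_null_false_positive_rate",
    "hub_recovery_rate",
]


def cohort_connectivity(cohort) -> dict:
    """Preprocess every scan of an ROI cohort into connectivity matrices."""
    fc_by = {}
    for s in cohort.subjects:
        fc_by[s.subject_id] = {}
        for cond in CONDITIONS:
            scan = cohort.scans[(s.subject_id, cond)]
            cleaned = run_first_level(scan, "roi_fc")
            fc_by[s.subject_id][cond] = compute_fc(
                cleaned, scan.channel_labels, cohort.network_of,
                cohort.hemisphere_of,
            )
    return fc_by


def mask_features(fc_by_subject, cohort, mask_name: str):
    """Feature matrix, labels and subject ids for one subnetwork mask."""
    masks = build_masks(cohort.roi_labels, cohort.network_of)
    mask = next(m for m in masks if m.name == mask_name)
    X, labels, sids = [], [], []
    for sid in sorted(fc_by_subject):
        for cond in CONDITIONS:
            X.append(extract_features(fc_by_subject[sid][cond], mask))
            labels.append(cond)
            sids.append(sid)
    return np.asarray(X), labels, np.asarray(sids), mask


def fl_type1_error(
    n_replicates: int = 50,
    n_subjects: int = 29,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean per-edge rejection rate of the permutation GLM on null cohorts."""
    rates = []
    for rep in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, seed=seed + rep,
                           effect_mode="null")
        cohort = generate_roi_cohort(cfg)
        contrasts = paired_contrast(cohort_connectivity(cohort))
        res = FreedmanLaneGLM(contrasts, cohort.covariates()).fit(
            n_perm=n_perm, seed=seed + rep, alpha=alpha
        )
        rates.append(float(np.mean(res.p_raw <= alpha)))
    return float(np.mean(rates))


def dissociation_rates(
    n_replicates: int = 20,
    n_subjects: int = 29,
    svm_n_perm: int = 500,
    fl_n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Multivariate detection vs univariate null at the reference magnitude.

    Per replicate cohort with the distributed cerebellum x basal-ganglia
    effect: does the CBLxBG classifier beat its permutation 97.5th
    percentile, and does the edge-wise FDR stage reject zero edges?
    """
    sig, zero_fdr, accs = [], [], []
    for rep in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, seed=seed + rep,
                           effect_mode="distributed")
        cohort = generate_roi_cohort(cfg)
        fc_by = cohort_connectivity(cohort)
        fl = FreedmanLaneGLM(
            paired_contrast(fc_by), cohort.covariates()
        ).fit(n_perm=fl_n_perm, seed=seed + rep)
        zero_fdr.append(fl.n_rejections == 0)
        X, labels, sids, mask = mask_features(fc_by, cohort, "CBLxBG")
        res = SubnetworkSVM(
            X, labels, sids, mask_name=mask.name, within_network=False
        ).fit(n_perm=svm_n_perm, seed=seed + rep)
        sig.append(bool(res.significant))
        accs.append(res.accuracy)
    return {
        "classifier_significant_rate": float(np.mean(sig)),
        "fdr_zero_edge_rate": float(np.mean(zero_fdr)),
        "mean_accuracy": float(np.mean(accs)),
    }


def svm_null_false_positive_rate(
    n_replicates: int = 200,
    n_subjects: int = 10,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """False-positive rate of the 97.5th-percentile rule on null cohorts."""
    import warnings

    hits = []
    for rep in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, seed=seed + rep,
                           effect_mode="null")
        cohort = generate_roi_cohort(cfg)
        fc_by = cohort_connectivity(cohort)
        X, labels, sids, mask = mask_features(fc_by, cohort, "CBLxBG")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = SubnetworkSVM(
                X, labels, sids, mask_name=mask.name, within_network=False
            ).fit(n_perm=n_perm, seed=seed + rep)
        hits.append(bool(res.significant))
    return float(np.mean(hits))


def hub_recovery_rate(
    n_replicates: int = 20,
    n_subjects: int = 20,
    seed: int = 0,
) -> float:
    """Fraction of cohorts recovering the hub as a significant positive cluster."""
    hits = []
    for rep in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, seed=seed + rep)
        cohort = generate_voxel_cohort(cfg)
        res = ECMAnalysis(cohort, min_participants=15).fit()
        table = res.cluster_table
        hub = cohort.truth["hub_parcel"]
        parcels = next(iter(cohort.scans.values())).grid.parcels
        found = False
        for ci, cl in enumerate(res.clusters):
            row = table.iloc[ci]
            if not (row["significant"] and row["direction"] == "positive"):
                continue
            in_hub = np.mean(parcels[cl["voxels"]] == hub)
            if in_hub > 0.5:
                found = True
        hits.append(found)
    return float(np.mean(hits))
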