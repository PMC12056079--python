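"""Synthetic paired-condition cohorts for the connectivity pipeline.

Each simulated patient contributes two resting-state scans — one drug-naive
("de_novo") and one after sustained medication ("levodopa") — drawn from a
subject-specific latent covariance over the 26 bilateral ROIs of the motor
cortico-striato-thalamo-cerebellar system.  The latent covariance has the
qualitative block pattern of real regional connectivity: strong coupling
within the cortical motor network, moderate coupling within the cerebellum
and within the basal ganglia + thalamus, elevated homotopic
(interhemispheric) coupling, and weak cross-network coherence.

The medication effect is, by construction, a *distributed* covariance shift:
a fixed low-rank (rank 3) random pattern on one cross-network block (by
default cerebellum x basal ganglia), scaled so that each individual edge
moves by much less than its own sampling noise.  A multivariate read-out of
the whole block can therefore separate the conditions while no single edge
does — the dissociation the downstream analyses are designed to detect.
Nuisance structure (linear drift, six autocorrelated motion parameters,
common white-matter and CSF signals) is mixed into the observed series and
provided as regressors, giving the denoising stages real work to do.

A voxel-level variant lays parcels on a 3D lattice, gives one "hub" parcel
extra shared signal in the medicated condition (raising its eigenvector
centrality), and masks a posterior slab of the grid in a configurable
fraction of subjects to emulate incomplete posterior-cerebellum coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rois
from .ecm import VoxelGrid, VoxelScan
from .preprocess import ScanTimeSeries

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "PairedCohort",
    "generate_roi_cohort",
    "generate_voxel_cohort",
    "write_roi_cohort",
    "write_voxel_cohort",
    "read_voxel_cohort",
    "read_scan_tsv",
]

CONDITIONS = ("de_novo", "levodopa")

#: Reference per-cohort scale of the distributed covariance shift.  At this
#: value the per-edge correlation shifts average well under the ~0.1 SD of a
#: paired edge contrast (univariate tests stay null after FDR) while the
#: 64-edge pattern as a whole separates the conditions for the classifier.
REFERENCE_EFFECT_MAGNITUDE = 0.025

_CLINICAL_RANGES = {
    "updrs1": (0, 52),
    "updrs2": (0, 52),
    "updrs3": (0, 132),
    "tremor": (0, 40),
    "rigidity": (0, 44),
    "gait": (0, 20),
    "moca": (0, 30),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one paired cohort.

    ``network_sizes`` must sum to ``n_rois``; ``effect_block`` names the
    network pair carrying the covariance shift; amplitudes are in units of
    the unit-variance latent signal SD.
    """

    n_subjects: int = 29
    n_frames: int = 210
    tr_seconds: float = 2.4
    n_rois: int = 26
    network_sizes: tuple = (8, 8, 10)
    effect_block: tuple = (rois.CEREBELLUM, rois.BASAL_GANGLIA)
    effect_magnitude: float = REFERENCE_EFFECT_MAGNITUDE
    effect_mode: str = "distributed"
    drift_amplitude: float = 0.4
    motion_amplitude: float = 0.3
    wm_amplitude: float = 0.5
    csf_amplitude: float = 0.4
    subject_variability: float = 0.04
    clinical_effect_correlation: float = 0.0
    grid_shape: tuple = (12, 12, 12)
    coverage_deficit_fraction: float = 0.3
    hub_effect: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if sum(self.network_sizes) != self.n_rois:
            raise ValueError(
                f"network_sizes {self.network_sizes} must sum to n_rois={self.n_rois}"
            )
        if self.effect_mode not in ("distributed", "single_edge", "null"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        pair = tuple(sorted(self.effect_block))
        known = {tuple(sorted(p)) for p in _network_pairs()}
        if pair not in known:
            raise ValueError(
                f"effect_block {self.effect_block!r} does not name a known "
                f"network pair; choose from {sorted(known)}"
            )
        if not 0.0 <= self.coverage_deficit_fraction <= 1.0:
            raise ValueError("coverage_deficit_fraction must lie in [0, 1]")
        if self.n_subjects < 1 or self.n_frames < 8:
            raise ValueError("need at least 1 subject and 8 frames")


def _network_pairs():
    nets = rois.NETWORKS
    pairs = [(n, n) for n in nets]
    pairs += [(a, b) for i, a in enumerate(nets) for b in nets[i + 1 :]]
    return pairs


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    gender: int  # 0 female, 1 male
    disease_duration: dict  # condition -> months
    treatment_duration_months: float
    clinical: dict  # condition -> {measure: int score}


@dataclass
class PairedCohort:
    """Paired scans plus covariates, clinical scores and generative truth."""

    subjects: list
    scans: dict  # (subject_id, condition) -> ScanTimeSeries | VoxelScan
    truth: dict = field(default_factory=dict)
    roi_labels: tuple = ()
    network_of: dict = field(default_factory=dict)
    hemisphere_of: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.subjects:
            for cond in CONDITIONS:
                if (s.subject_id, cond) not in self.scans:
                    raise ValueError(
                        f"subject {s.subject_id} lacks a {cond} scan"
                    )

    @property
    def subject_ids(self):
        return sorted(s.subject_id for s in self.subjects)

    def covariates(self) -> pd.DataFrame:
        """Nuisance covariate table: duration change, baseline age, gender."""
        rows = []
        for s in sorted(self.subjects, key=lambda s: s.subject_id):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "delta_disease_duration": s.disease_duration["levodopa"]
                    - s.disease_duration["de_novo"],
                    "age": s.age,
                    "gender": s.gender,
                }
            )
        return pd.DataFrame(rows).set_index("subject_id")

    def clinical_table(self) -> pd.DataFrame:
        rows = []
        for s in sorted(self.subjects, key=lambda s: s.subject_id):
            for cond in CONDITIONS:
                row = {"subject_id": s.subject_id, "condition": cond,
                       "age": s.age, "gender": s.gender,
                       "disease_duration_months": s.disease_duration[cond],
                       "treatment_duration_months": (
                           s.treatment_duration_months if cond == "levodopa" else 0.0)}
                row.update(s.clinical[cond])
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent covariance construction

_WITHIN = {rois.CEREBELLUM: 0.35, rois.BASAL_GANGLIA: 0.35, rois.MOTOR_CORTEX: 0.55}
_BETWEEN = 0.10
_HOMOTOPIC_BONUS = 0.20


def _base_correlation(labels, network_of, hemisphere_of) -> np.ndarray:
    n = len(labels)
    c = np.full((n, n), _BETWEEN)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if network_of[a] == network_of[b]:
                c[i, j] = _WITHIN[network_of[a]]
            if a[2:] == b[2:] and a != b:  # homotopic pair (same base region)
                c[i, j] += _HOMOTOPIC_BONUS
    np.fill_diagonal(c, 1.0)
    return c


def _nearest_spd(c: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues from below and restore the unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.maximum(w, floor)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def _effect_pattern(rng, labels, network_of, block, rank: int = 3) -> np.ndarray:
    """Fixed low-rank shift pattern confined to one cross-network block.

    Root-mean-square of the block entries is normalised to 1 so that
    ``effect_magnitude`` is the per-edge RMS correlation shift.
    """
    n = len(labels)
    idx_a = [i for i, l in enumerate(labels) if network_of[l] == block[0]]
    idx_b = [i for i, l in enumerate(labels) if network_of[l] == block[1]]
    if block[0] == block[1]:
        u = rng.standard_normal((len(idx_a), rank))
        sub = u @ u.T
        np.fill_diagonal(sub, 0.0)
        pattern = np.zeros((n, n))
        pattern[np.ix_(idx_a, idx_a)] = sub
    else:
        u = rng.standard_normal((len(idx_a), rank))
        v = rng.standard_normal((len(idx_b), rank))
        sub = u @ v.T
        pattern = np.zeros((n, n))
        pattern[np.ix_(idx_a, idx_b)] = sub
        pattern[np.ix_(idx_b, idx_a)] = sub.T
    iu = np.triu_indices(n, 1)
    nz = pattern[iu][pattern[iu] != 0]
    pattern /= np.sqrt(np.mean(nz**2))
    return pattern


def _single_edge_pattern(labels, network_of, block) -> np.ndarray:
    n = len(labels)
    i = next(i for i, l in enumerate(labels) if network_of[l] == block[0])
    j = next(j for j, l in enumerate(labels)
             if network_of[l] == block[1] and j != i)
    pattern = np.zeros((n, n))
    pattern[i, j] = pattern[j, i] = 1.0
    return pattern


# ---------------------------------------------------------------------------
# nuisance signals


def _ar1(rng, n, rho=0.9):
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def _slow_signal(rng, n, n_harmonics=4):
    """Low-frequency common signal: random low-order Fourier series."""
    t = np.arange(n) / n
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        a, b = rng.standard_normal(2)
        x += a * np.sin(2 * np.pi * k * t) + b * np.cos(2 * np.pi * k * t)
    return x / max(x.std(), 1e-12)


def _simulate_scan(rng, cov, cfg: CohortConfig, n_channels: int):
    """Latent signal from ``cov`` plus drift/motion/WM/CSF contamination."""
    T = cfg.n_frames
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n_channels))
    latent = rng.standard_normal((T, n_channels)) @ L.T
    drift = (np.arange(T) / T - 0.5)[:, None] * (
        cfg.drift_amplitude * rng.uniform(0.5, 1.5, n_channels)
    )[None, :]
    motion = np.column_stack([_ar1(rng, T) for _ in range(6)])
    motion_loadings = rng.standard_normal((6, n_channels)) * cfg.motion_amplitude / np.sqrt(6)
    # tissue signals are distinct physiological sources: decorrelate them
    # from motion within the scan so stepwise nuisance regression is coherent
    basis = np.column_stack([np.ones(T), motion])
    q, _ = np.linalg.qr(basis)
    def _ortho(x):
        x = x - q @ (q.T @ x)
        return x / max(x.std(), 1e-12)
    wm = _ortho(_slow_signal(rng, T))
    csf = _ortho(_slow_signal(rng, T))
    wm_load = rng.uniform(0.5, 1.5, n_channels) * cfg.wm_amplitude
    csf_load = rng.uniform(0.5, 1.5, n_channels) * cfg.csf_amplitude
    data = (
        latent
        + drift
        + motion @ motion_loadings
        + wm[:, None] * wm_load[None, :]
        + csf[:, None] * csf_load[None, :]
    )
    return data, motion, wm, csf


# ---------------------------------------------------------------------------
# clinical covariates


def _clip_int(rng_val, lo, hi):
    return int(np.clip(round(rng_val), lo, hi))


def _simulate_subject_record(rng, sid: str, effect_scale: float,
                             cfg: CohortConfig) -> SubjectRecord:
    age = float(np.round(rng.uniform(45, 75), 1))
    gender = int(rng.random() < 18 / 29)
    dd_denovo = float(np.round(rng.uniform(6, 30), 1))
    gap = float(np.round(rng.uniform(24, 48), 1))
    treatment = float(np.round(rng.uniform(12, 44), 1))
    clin = {}
    base3 = rng.normal(17, 6)
    for cond in CONDITIONS:
        shift = rng.normal(0, 3)
        if cond == "levodopa" and cfg.clinical_effect_correlation != 0:
            shift += cfg.clinical_effect_correlation * 10.0 * (effect_scale - 1.0)
        u3 = base3 + shift
        clin[cond] = {
            "updrs1": _clip_int(rng.normal(2, 1.5), *_CLINICAL_RANGES["updrs1"]),
            "updrs2": _clip_int(rng.normal(6, 3), *_CLINICAL_RANGES["updrs2"]),
            "updrs3": _clip_int(u3, *_CLINICAL_RANGES["updrs3"]),
            "tremor": _clip_int(rng.normal(1.5, 1.5), *_CLINICAL_RANGES["tremor"]),
            "rigidity": _clip_int(rng.normal(4, 2), *_CLINICAL_RANGES["rigidity"]),
            "gait": _clip_int(rng.normal(1, 1), *_CLINICAL_RANGES["gait"]),
            "moca": _clip_int(rng.normal(28, 1.5), *_CLINICAL_RANGES["moca"]),
        }
    return SubjectRecord(
        subject_id=sid,
        age=age,
        gender=gender,
        disease_duration={"de_novo": dd_denovo, "levodopa": dd_denovo + gap},
        treatment_duration_months=treatment,
        clinical=clin,
    )


# ---------------------------------------------------------------------------
# public generators


def generate_roi_cohort(config: CohortConfig) -> PairedCohort:
    """Simulate a paired ROI-level cohort under the configured effect."""
    cfg = config
    labels, network_of, hemisphere_of = rois.default_roi_set()
    if len(labels) != cfg.n_rois:
        raise ValueError("custom ROI counts are not supported by the bundled atlas")
    rng = np.random.default_rng(cfg.seed)
    base = _base_correlation(labels, network_of, hemisphere_of)
    block = tuple(cfg.effect_block)
    if cfg.effect_mode == "distributed":
        pattern = _effect_pattern(rng, labels, network_of, block)
    elif cfg.effect_mode == "single_edge":
        pattern = _single_edge_pattern(labels, network_of, block)
    else:
        pattern = np.zeros((cfg.n_rois, cfg.n_rois))
    magnitude = cfg.effect_magnitude if cfg.effect_mode != "null" else 0.0

    subjects, scans = [], {}
    for s in range(cfg.n_subjects):
        sid = f"S{s:03d}"
        subj_pert = rng.standard_normal((cfg.n_rois, cfg.n_rois))
        subj_pert = (subj_pert + subj_pert.T) / 2.0
        np.fill_diagonal(subj_pert, 0.0)
        cov_base = _nearest_spd(base + cfg.subject_variability * subj_pert)
        effect_scale = max(0.0, rng.normal(1.0, 0.25))
        record = _simulate_subject_record(rng, sid, effect_scale, cfg)
        subjects.append(record)
        for cond in CONDITIONS:
            cov = cov_base
            if cond == "levodopa" and magnitude != 0.0:
                cov = _nearest_spd(cov_base + magnitude * effect_scale * pattern)
            data, motion, wm, csf = _simulate_scan(rng, cov, cfg, cfg.n_rois)
            scans[(sid, cond)] = ScanTimeSeries(
                data=data, channel_labels=labels, motion=motion,
                wm=wm, csf=csf, tr_seconds=cfg.tr_seconds,
            )

    iu = np.triu_indices(cfg.n_rois, 1)
    shifted = magnitude * pattern
    truth = {
        "effect_mode": cfg.effect_mode,
        "effect_block": list(block),
        "effect_magnitude": magnitude,
        "shifted_edges": [
            [labels[i], labels[j], float(shifted[i, j])]
            for i, j in zip(*iu)
            if shifted[i, j] != 0.0
        ],
    }
    return PairedCohort(
        subjects=subjects, scans=scans, truth=truth,
        roi_labels=labels, network_of=network_of, hemisphere_of=hemisphere_of,
    )


def _default_parcels(shape) -> np.ndarray:
    """Split the grid into a 3x3x3 arrangement of box parcels."""
    edges = [np.linspace(0, s, 4).astype(int) for s in shape]
    parcels = np.zeros(shape, int)
    lab = 0
    for a in range(3):
        for b in range(3):
            for c in range(3):
                parcels[
                    edges[0][a]:edges[0][a + 1],
                    edges[1][b]:edges[1][b + 1],
                    edges[2][c]:edges[2][c + 1],
                ] = lab
                lab += 1
    return parcels.ravel()


HUB_PARCEL = 13  # centre box of the 3x3x3 parcel arrangement


def generate_voxel_cohort(config: CohortConfig) -> PairedCohort:
    """Simulate a paired voxel-grid cohort with a medication-sensitive hub.

    Every voxel mixes a global signal, a parcel-common signal and its own
    noise.  In the medicated condition the centre ("hub") parcel receives an
    increased global-signal loading, which raises the centrality of its
    voxels.  A posterior slab (low second coordinate) is masked out for a
    ``coverage_deficit_fraction`` of subjects, in both of their scans.
    """
    cfg = config
    if any(s < 4 for s in cfg.grid_shape):
        raise ValueError("every grid dimension must be >= 4")
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.grid_shape)
    n_vox = int(np.prod(shape))
    parcels = _default_parcels(shape)
    n_parcels = parcels.max() + 1
    T = cfg.n_frames

    # posterior slab: lowest quarter of the j axis (at least 2 planes)
    jj = np.unravel_index(np.arange(n_vox), shape)[1]
    slab_depth = max(2, shape[1] // 4)
    slab = jj < slab_depth

    subjects, scans = [], {}
    for s in range(cfg.n_subjects):
        sid = f"S{s:03d}"
        missing = rng.random() < cfg.coverage_deficit_fraction
        coverage = np.ones(n_vox, bool)
        if missing:
            coverage[slab] = False
        record = _simulate_subject_record(rng, sid, 1.0, cfg)
        subjects.append(record)
        for cond in CONDITIONS:
            global_sig = rng.standard_normal(T)
            parcel_sig = rng.standard_normal((T, n_parcels))
            noise = rng.standard_normal((T, n_vox))
            g_load = np.full(n_vox, 0.5)
            if cond == "levodopa" and cfg.hub_effect != 0.0:
                g_load[parcels == HUB_PARCEL] += cfg.hub_effect
            data = (
                g_load[None, :] * global_sig[:, None]
                + 0.6 * parcel_sig[:, parcels]
                + noise
            )
            motion = np.column_stack([_ar1(rng, T) for _ in range(6)])
            data += motion @ (
                rng.standard_normal((6, n_vox)) * cfg.motion_amplitude / np.sqrt(6)
            )
            wm = _slow_signal(rng, T)
            csf = _slow_signal(rng, T)
            data += wm[:, None] * cfg.wm_amplitude + csf[:, None] * cfg.csf_amplitude
            grid = VoxelGrid(shape=shape, coverage=coverage, parcels=parcels)
            scans[(sid, cond)] = VoxelScan(
                data=data, grid=grid, motion=motion, wm=wm, csf=csf,
                tr_seconds=cfg.tr_seconds,
            )

    truth = {
        "effect_mode": "hub" if cfg.hub_effect else "null",
        "hub_parcel": HUB_PARCEL,
        "hub_effect": cfg.hub_effect,
        "slab_voxels": int(slab.sum()),
    }
    return PairedCohort(subjects=subjects, scans=scans, truth=truth)


# ---------------------------------------------------------------------------
# on-disk interchange


def write_roi_cohort(cohort: PairedCohort, outdir) -> None:
    """One TSV per scan, a clinical table TSV and a truth-record JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sid, cond), scan in sorted(cohort.scans.items()):
        df = pd.DataFrame(scan.data, columns=list(scan.channel_labels))
        for k in range(6):
            df[f"motion_{k + 1}"] = scan.motion[:, k]
        df["wm"] = scan.wm
        df["csf"] = scan.csf
        df.to_csv(outdir / f"{sid}_{cond}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    cohort.clinical_table().to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2)


def write_voxel_cohort(cohort: PairedCohort, outdir) -> None:
    """Compressed array bundle (.npz) plus a JSON sidecar for a voxel cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays, meta = {}, {"subjects": [], "conditions": list(CONDITIONS)}
    grid = None
    for (sid, cond), scan in sorted(cohort.scans.items()):
        key = f"{sid}_{cond}"
        arrays[f"data_{key}"] = scan.data.astype(np.float32)
        arrays[f"coverage_{key}"] = scan.grid.coverage
        arrays[f"motion_{key}"] = scan.motion
        arrays[f"wm_{key}"] = scan.wm
        arrays[f"csf_{key}"] = scan.csf
        grid = scan.grid
        if sid not in meta["subjects"]:
            meta["subjects"].append(sid)
    arrays["parcels"] = grid.parcels
    np.savez_compressed(outdir / "voxel_cohort.npz", **arrays)
    meta.update(
        {
            "grid_shape": list(grid.shape),
            "tr_seconds": next(iter(cohort.scans.values())).tr_seconds,
            "truth": cohort.truth,
        }
    )
    with open(outdir / "voxel_cohort.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_voxel_cohort(outdir) -> PairedCohort:
    """Read a voxel cohort bundle written by :func:`write_voxel_cohort`."""
    outdir = Path(outdir)
    bundle = np.load(outdir / "voxel_cohort.npz")
    with open(outdir / "voxel_cohort.json") as fh:
        meta = json.load(fh)
    shape = tuple(meta["grid_shape"])
    parcels = bundle["parcels"]
    scans, subjects = {}, []
    for sid in meta["subjects"]:
        subjects.append(
            SubjectRecord(
                subject_id=sid, age=0.0, gender=0,
                disease_duration={"de_novo": 0.0, "levodopa": 0.0},
                treatment_duration_months=0.0,
                clinical={c: {} for c in CONDITIONS},
            )
        )
        for cond in CONDITIONS:
            key = f"{sid}_{cond}"
            grid = VoxelGrid(shape=shape, coverage=bundle[f"coverage_{key}"],
                             parcels=parcels)
            scans[(sid, cond)] = VoxelScan(
                data=bundle[f"data_{key}"].astype(float), grid=grid,
                motion=bundle[f"motion_{key}"], wm=bundle[f"wm_{key}"],
                csf=bundle[f"csf_{key}"], tr_seconds=meta["tr_seconds"],
            )
    return PairedCohort(subjects=subjects, scans=scans, truth=meta.get("truth", {}))


def read_scan_tsv(path, tr_seconds: float) -> ScanTimeSeries:
    """Read a scan TSV written by :func:`write_roi_cohort`."""
    df = pd.read_csv(path, sep="\t")
    motion_cols = [f"motion_{k + 1}" for k in range(6)]
    channels = [c for c in df.columns if c not in motion_cols + ["wm", "csf"]]
    return ScanTimeSeries(
        data=df[channels].to_numpy(),
        channel_labels=tuple(channels),
        motion=df[motion_cols].to_numpy(),
        wm=df["wm"].to_numpy(),
        csf=df["csf"].to_numpy(),
        tr_seconds=tr_seconds,
    )
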