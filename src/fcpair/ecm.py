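"""Voxel-wise eigenvector centrality mapping and cluster-level inference.

Eigenvector centrality (EC) scores each voxel by the leading eigenvector of
the voxel-by-voxel similarity matrix, where similarity is the absolute
Pearson correlation between cleaned time series.  Because the similarity
matrix is non-negative, the Perron-Frobenius theorem guarantees a
non-negative leading eigenvector, computed here by power iteration with a
deterministic uniform positive start.  Paired EC difference maps
(medicated minus drug-naive) are thresholded by per-voxel subject coverage,
tested voxel-wise with a one-sample t-test, grouped into connected
suprathreshold clusters, and tested again at the cluster level with
Benjamini-Hochberg FDR control.

For large grids the similarity matrix is never held in memory: the power
iteration recomputes it in row chunks.  Below a configurable voxel count
the matrix is materialised once, which is algebraically identical and much
faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VoxelGrid",
    "VoxelScan",
    "ECMap",
    "smooth_grid",
    "compute_ec",
    "delta_ec",
    "coverage_threshold",
    "voxelwise_one_sample_t",
    "extract_clusters",
    "cluster_level_test",
    "correlate_delta_ec_with_clinical",
    "correlate_scores",
    "export_nifti",
    "ECMAnalysis",
    "ECMResults",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a voxel scan: 3D shape, coverage and parcel labels.

    Voxels are indexed linearly in C order; ``coverage`` marks the voxels
    actually acquired in the scan and ``parcels`` carries an integer parcel
    label per voxel (-1 for unlabelled).
    """

    shape: tuple
    coverage: np.ndarray
    parcels: np.ndarray

    def __post_init__(self):
        n = int(np.prod(self.shape))
        cov = np.asarray(self.coverage, dtype=bool).ravel()
        par = np.asarray(self.parcels, dtype=int).ravel()
        if cov.shape[0] != n or par.shape[0] != n:
            raise ValueError("coverage/parcels must have one entry per voxel")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "coverage", cov)
        object.__setattr__(self, "parcels", par)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def unravel(self, linear_idx):
        return np.unravel_index(linear_idx, self.shape)


@dataclass(frozen=True)
class VoxelScan:
    """A voxel-level scan: frames x voxels data plus nuisance regressors."""

    data: np.ndarray
    grid: VoxelGrid
    motion: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.shape[1] != self.grid.n_voxels:
            raise ValueError("data channel count must equal grid voxel count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ECMap:
    """Per-voxel eigenvector centrality with its computation record."""

    ec: np.ndarray
    eigenvalue: float
    n_iterations: int
    converged: bool
    excluded_voxels: np.ndarray = field(default_factory=lambda: np.array([], int))


def smooth_grid(
    data: np.ndarray,
    shape: tuple,
    coverage: np.ndarray | None = None,
    fwhm_mm: float = 5.0,
    voxel_size_mm: float = 3.0,
) -> np.ndarray:
    """Per-frame 3D Gaussian smoothing within the coverage mask.

    The kernel is renormalised at mask edges (smoothing of masked data
    divided by the smoothed mask) so that a constant field stays constant.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    data = np.asarray(data, dtype=float)
    n = int(np.prod(shape))
    if data.shape[1] != n:
        raise ValueError("data columns must match the grid voxel count")
    if fwhm_mm == 0:
        return data.copy()
    sigma = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    mask = np.ones(n, bool) if coverage is None else np.asarray(coverage, bool).ravel()
    mask3 = mask.reshape(shape).astype(float)
    weight = ndimage.gaussian_filter(mask3, sigma, mode="constant")
    out = np.zeros_like(data)
    for t in range(data.shape[0]):
        frame = np.where(mask, data[t], 0.0).reshape(shape)
        sm = ndimage.gaussian_filter(frame, sigma, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            frame_out = np.where(weight > 0, sm / weight, 0.0)
        out[t] = np.where(mask, frame_out.ravel(), 0.0)
    return out


def _abs_corr_matvec(U: np.ndarray, v: np.ndarray, chunk_rows: int) -> np.ndarray:
    """|U^T U| @ v computed in row chunks of the similarity matrix."""
    n = U.shape[1]
    out = np.empty(n, dtype=U.dtype)
    for start in range(0, n, chunk_rows):
        stop = min(start + chunk_rows, n)
        rows = U[:, start:stop].T @ U
        np.abs(rows, out=rows)
        out[start:stop] = rows @ v
    return out


def compute_ec(
    series: np.ndarray,
    coverage: np.ndarray | None = None,
    chunk_rows: int = 512,
    dense_voxel_limit: int = 8192,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> ECMap:
    """Eigenvector centrality of the absolute-correlation voxel graph.

    ``series`` is frames x voxels (cleaned, any affine scaling is
    immaterial).  Voxels outside ``coverage`` or with zero temporal variance
    are excluded from the graph; their EC is NaN.  The returned EC vector is
    non-negative over the graph and has unit Euclidean norm.
    """
    series = np.asarray(series, dtype=float)
    n_total = series.shape[1]
    mask = np.ones(n_total, bool) if coverage is None else np.asarray(coverage, bool).ravel()
    sd = series.std(axis=0)
    excluded = np.flatnonzero(mask & (sd == 0))
    if excluded.size:
        warnings.warn(
            f"excluding {excluded.size} zero-variance voxel(s) from the EC graph",
            stacklevel=2,
        )
    good = mask & (sd > 0)
    idx = np.flatnonzero(good)
    if idx.size < 2:
        raise ValueError("need at least 2 usable in-coverage voxels")
    # double precision below 1e4 voxels, single above (memory/throughput)
    dtype = np.float64 if idx.size < 10_000 else np.float32
    X = series[:, idx].astype(dtype)
    X = X - X.mean(axis=0)
    X /= np.linalg.norm(X, axis=0)  # now corr = X.T @ X, unit diagonal

    n = idx.size
    v = np.full(n, 1.0 / np.sqrt(n), dtype=dtype)
    dense = None
    if n <= dense_voxel_limit:
        dense = np.abs(X.T @ X)
    lam = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = dense @ v if dense is not None else _abs_corr_matvec(X, v, chunk_rows)
        lam = float(v @ w)
        resid = float(np.linalg.norm(w - lam * v))
        v = w / np.linalg.norm(w)
        if resid <= tol * max(lam, 1.0):
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"EC power iteration did not converge in {max_iter} iterations "
            f"(relative residual {resid / max(lam, 1.0):.3e})"
        )
    ec = np.full(n_total, np.nan)
    ec[idx] = np.abs(v.astype(float))  # Perron vector; abs guards roundoff signs
    ec[idx] /= np.linalg.norm(ec[idx])
    return ECMap(
        ec=ec,
        eigenvalue=lam,
        n_iterations=it,
        converged=converged,
        excluded_voxels=excluded,
    )


def delta_ec(ec_ldopa: np.ndarray, ec_denovo: np.ndarray) -> np.ndarray:
    """Per-voxel EC difference, defined only where both maps are defined."""
    ec_ldopa = np.asarray(ec_ldopa, float)
    ec_denovo = np.asarray(ec_denovo, float)
    if ec_ldopa.shape != ec_denovo.shape:
        raise ValueError("EC map shapes do not match")
    return ec_ldopa - ec_denovo  # NaN propagates where either is missing


def coverage_threshold(delta_maps: np.ndarray, min_participants: int = 15) -> np.ndarray:
    """Keep voxels whose EC difference is defined for enough subjects."""
    delta_maps = np.asarray(delta_maps, float)
    counts = np.sum(~np.isnan(delta_maps), axis=0)
    return counts >= min_participants


def voxelwise_one_sample_t(
    delta_maps: np.ndarray, mask: np.ndarray, min_subjects: int = 3
):
    """Two-sided one-sample t-test of the EC difference against zero.

    Each voxel uses only the subjects that cover it.  Returns
    ``(t_map, p_map, zero_variance_flags)``; voxels outside the mask or
    with fewer than ``min_subjects`` covering subjects are NaN.
    """
    delta_maps = np.asarray(delta_maps, float)
    n_vox = delta_maps.shape[1]
    t_map = np.full(n_vox, np.nan)
    p_map = np.full(n_vox, np.nan)
    flags = np.zeros(n_vox, bool)
    valid = ~np.isnan(delta_maps)
    counts = valid.sum(axis=0)
    use = np.asarray(mask, bool) & (counts >= min_subjects)
    # nan-aware per-voxel moments (vectorised)
    d = np.where(valid, delta_maps, 0.0)
    n = counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = d.sum(axis=0) / n
        ss = ((d - np.where(valid, m, 0.0)) ** 2 * valid).sum(axis=0)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    zero_var = use & (sd == 0)
    flags[zero_var] = True
    t_map[zero_var] = 0.0
    p_map[zero_var] = 1.0
    ok = use & (sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ok = m[ok] / (sd[ok] / np.sqrt(n[ok]))
    t_map[ok] = t_ok
    p_map[ok] = 2.0 * stats.t.sf(np.abs(t_ok), n[ok] - 1)
    return t_map, p_map, flags


_STRUCTURES = {6: (3, 1), 18: (3, 2), 26: (3, 3)}


def extract_clusters(
    p_map: np.ndarray,
    t_map: np.ndarray,
    mask: np.ndarray,
    shape: tuple,
    p_thresh: float = 0.005,
    min_size: int = 10,
    connectivity: int = 26,
    strict_size: bool = True,
) -> list[dict]:
    """Connected suprathreshold components of consistent effect sign.

    A cluster is a connected set (26-neighbourhood by default) of in-mask
    voxels with p <= ``p_thresh`` and a common t sign.  Components of size
    strictly greater than ``min_size`` are retained (set
    ``strict_size=False`` for a >= rule).  Returns a list of dicts with
    ``voxels`` (linear indices), ``size`` and ``direction``.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must be in (0, 1)")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(*_STRUCTURES[connectivity])
    p_map = np.asarray(p_map, float)
    t_map = np.asarray(t_map, float)
    mask = np.asarray(mask, bool)
    supra = mask & np.isfinite(p_map) & np.isfinite(t_map) & (p_map <= p_thresh)
    clusters = []
    for direction, sign_ok in (("positive", t_map > 0), ("negative", t_map < 0)):
        sel = (supra & sign_ok).reshape(shape)
        labels, n_lab = ndimage.label(sel, structure=structure)
        labels = labels.ravel()
        for lab in range(1, n_lab + 1):
            voxels = np.flatnonzero(labels == lab)
            size = voxels.size
            keep = size > min_size if strict_size else size >= min_size
            if keep:
                clusters.append(
                    {"voxels": voxels, "size": int(size), "direction": direction}
                )
    clusters.sort(key=lambda c: (-c["size"], int(c["voxels"][0])))
    return clusters


def _subject_cluster_means(delta_maps: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Per-subject mean EC difference over a cluster's covered voxels."""
    sub = delta_maps[:, voxels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(sub, axis=1)
    return means[~np.isnan(means)]


def cluster_level_test(
    clusters: list[dict], delta_maps: np.ndarray, alpha: float = 0.005
) -> pd.DataFrame:
    """One-sample t-test per cluster with BH-FDR across clusters.

    For each cluster the subject-wise mean EC difference over the cluster's
    voxels is tested against zero.  The table reports mean and SD of those
    subject means (raw scale; rendering multiplies by 10^3), the cluster t,
    raw and FDR-adjusted p, and a significance flag at ``alpha``.
    """
    rows = []
    for ci, cl in enumerate(clusters):
        means = _subject_cluster_means(np.asarray(delta_maps, float), cl["voxels"])
        t, p = stats.ttest_1samp(means, 0.0)
        rows.append(
            {
                "cluster": ci,
                "direction": cl["direction"],
                "n_voxels": cl["size"],
                "mean_delta_ec": float(np.mean(means)),
                "sd_delta_ec": float(np.std(means, ddof=1)),
                "t": float(t),
                "p_raw": float(p),
                "n_subjects": means.size,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster", "direction", "n_voxels", "mean_delta_ec",
            "sd_delta_ec", "t", "p_raw", "n_subjects",
        ],
    )
    if len(table):
        rej, p_fdr, *_ = multipletests(table["p_raw"], alpha=alpha, method="fdr_bh")
        table["p_fdr"] = p_fdr
        table["significant"] = rej
    else:
        table["p_fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def _pearson_map(delta_maps: np.ndarray, score: np.ndarray, mask: np.ndarray,
                 min_subjects: int = 3):
    """Per-voxel Pearson correlation of EC difference with a score change."""
    delta_maps = np.asarray(delta_maps, float)
    score = np.asarray(score, float)
    n_vox = delta_maps.shape[1]
    r_map = np.full(n_vox, np.nan)
    p_map = np.full(n_vox, np.nan)
    valid = ~np.isnan(delta_maps)
    counts = valid.sum(axis=0)
    use = np.asarray(mask, bool) & (counts >= min_subjects)
    s = score[:, None] * np.ones(n_vox)[None, :]
    d = np.where(valid, delta_maps, 0.0)
    sv = np.where(valid, s, 0.0)
    n = counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        md = d.sum(axis=0) / n
        ms = sv.sum(axis=0) / n
        dc = (d - md) * valid
        sc = (sv - ms) * valid
        num = (dc * sc).sum(axis=0)
        den = np.sqrt((dc**2).sum(axis=0) * (sc**2).sum(axis=0))
        r = np.where(den > 0, num / den, np.nan)
    r = np.clip(r, -1.0, 1.0)
    r_map[use] = r[use]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
    p_map[use] = p[use]
    return r_map, p_map


def correlate_delta_ec_with_clinical(
    delta_maps: np.ndarray,
    delta_score: np.ndarray,
    mask: np.ndarray,
    shape: tuple,
    p_thresh: float = 0.005,
    min_size: int = 10,
    connectivity: int = 26,
    alpha: float = 0.005,
):
    """Voxel-wise EC-difference vs clinical-change correlation with clusters.

    Returns ``(r_map, p_map, cluster_table)``.  Clusters are extracted from
    the correlation p-map (sign given by r) and, at the cluster level, the
    subject-mean EC difference over the cluster is correlated with the score
    change; cluster p-values are BH-FDR adjusted.
    """
    delta_score = np.asarray(delta_score, float)
    if np.ptp(delta_score) == 0:
        raise ValueError("clinical score change is constant; correlation undefined")
    r_map, p_map = _pearson_map(delta_maps, delta_score, mask)
    clusters = extract_clusters(
        p_map, r_map, mask, shape, p_thresh=p_thresh, min_size=min_size,
        connectivity=connectivity,
    )
    rows = []
    for ci, cl in enumerate(clusters):
        sub = np.asarray(delta_maps, float)[:, cl["voxels"]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(sub, axis=1)
        ok = ~np.isnan(means)
        r, p = stats.pearsonr(means[ok], delta_score[ok])
        rows.append(
            {
                "cluster": ci,
                "direction": cl["direction"],
                "n_voxels": cl["size"],
                "r": float(r),
                "p_raw": float(p),
                "n_subjects": int(ok.sum()),
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster", "direction", "n_voxels", "r", "p_raw", "n_subjects"]
    )
    if len(table):
        rej, p_fdr, *_ = multipletests(table["p_raw"], alpha=alpha, method="fdr_bh")
        table["p_fdr"] = p_fdr
        table["significant"] = rej
    else:
        table["p_fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return r_map, p_map, table


def export_nifti(values: np.ndarray, shape: tuple, path,
                 voxel_size_mm: float = 3.0) -> None:
    """Write a per-voxel map (or frames x voxels series) as a NIfTI-1 volume.

    Requires nibabel (optional dependency).  NaNs are preserved; the affine
    is a plain isotropic scaling, as the synthetic grids carry no anatomy.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - import guard
        raise ImportError("NIfTI export requires the optional nibabel dependency") from exc
    values = np.asarray(values, dtype=np.float32)
    if values.ndim == 1:
        vol = values.reshape(shape)
    elif values.ndim == 2:
        vol = np.moveaxis(values.reshape((values.shape[0],) + tuple(shape)), 0, -1)
    else:
        raise ValueError("values must be a per-voxel vector or frames x voxels")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def correlate_scores(score_a, score_b):
    """Plain Pearson correlation between two clinical change scores."""
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 matched score pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant score vector; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


class ECMAnalysis:
    """Group EC-difference analysis of a paired voxel cohort.

    Parameters
    ----------
    cohort : PairedCohort
        A voxel-level paired cohort (scans are :class:`VoxelScan`).
    min_participants : int
        Per-voxel subject coverage threshold.
    p_thresh, min_size, connectivity, alpha
        Voxel-level threshold, cluster-size rule, cluster neighbourhood and
        cluster-level FDR alpha.
    """

    def __init__(
        self,
        cohort,
        min_participants: int = 15,
        p_thresh: float = 0.005,
        min_size: int = 10,
        connectivity: int = 26,
        alpha: float = 0.005,
        smooth_fwhm_mm: float = 0.0,
        voxel_size_mm: float = 3.0,
        discard_frames: int = 4,
        dense_voxel_limit: int = 8192,
        chunk_rows: int = 512,
    ):
        self.cohort = cohort
        self.min_participants = min_participants
        self.p_thresh = p_thresh
        self.min_size = min_size
        self.connectivity = connectivity
        self.alpha = alpha
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.voxel_size_mm = voxel_size_mm
        self.discard_frames = discard_frames
        self.dense_voxel_limit = dense_voxel_limit
        self.chunk_rows = chunk_rows

    def _clean(self, scan: VoxelScan) -> np.ndarray:
        from .preprocess import regress_out, standardize, temporal_filter

        k = self.discard_frames
        data = scan.data[k:]
        motion = scan.motion[k:]
        wm = scan.wm[k:]
        csf = scan.csf[k:]
        cov = scan.grid.coverage
        if self.smooth_fwhm_mm > 0:
            data = smooth_grid(
                data, scan.grid.shape, cov,
                fwhm_mm=self.smooth_fwhm_mm, voxel_size_mm=self.voxel_size_mm,
            )
        sub = data[:, cov]
        sub = regress_out(sub, motion)
        sub = regress_out(sub, np.column_stack([wm, csf]))
        sub = temporal_filter(sub, scan.tr_seconds, low_cut_hz=0.01, high_cut_hz=0.20)
        sub = standardize(sub)
        out = np.zeros_like(data)
        out[:, cov] = sub
        return out

    def fit(self) -> "ECMResults":
        """Run the full EC-difference pipeline and return its results."""
        subject_ids = sorted(s.subject_id for s in self.cohort.subjects)
        deltas = []
        grid0 = None
        for sid in subject_ids:
            scans = {c: self.cohort.scans[(sid, c)] for c in ("de_novo", "levodopa")}
            ecs = {}
            for cond, scan in scans.items():
                if grid0 is None:
                    grid0 = scan.grid
                cleaned = self._clean(scan)
                ecs[cond] = compute_ec(
                    cleaned,
                    coverage=scan.grid.coverage,
                    dense_voxel_limit=self.dense_voxel_limit,
                    chunk_rows=self.chunk_rows,
                ).ec
            deltas.append(delta_ec(ecs["levodopa"], ecs["de_novo"]))
        delta_maps = np.asarray(deltas)
        mask = coverage_threshold(delta_maps, self.min_participants)
        t_map, p_map, flags = voxelwise_one_sample_t(delta_maps, mask)
        clusters = extract_clusters(
            p_map, t_map, mask, grid0.shape,
            p_thresh=self.p_thresh, min_size=self.min_size,
            connectivity=self.connectivity,
        )
        table = cluster_level_test(clusters, delta_maps, alpha=self.alpha)
        return ECMResults(
            analysis=self,
            subject_ids=subject_ids,
            delta_maps=delta_maps,
            mask=mask,
            t_map=t_map,
            p_map=p_map,
            zero_variance_flags=flags,
            clusters=clusters,
            cluster_table=table,
            grid_shape=grid0.shape,
        )


@dataclass
class ECMResults:
    """EC-difference maps, voxel statistics and the cluster table."""

    analysis: ECMAnalysis
    subject_ids: list
    delta_maps: np.ndarray
    mask: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    zero_variance_flags: np.ndarray
    clusters: list
    cluster_table: pd.DataFrame
    grid_shape: tuple

    def correlate_with_clinical(self, delta_score: np.ndarray):
        """Voxel-wise correlation of the EC difference with a score change."""
        a = self.analysis
        return correlate_delta_ec_with_clinical(
            self.delta_maps, delta_score, self.mask, self.grid_shape,
            p_thresh=a.p_thresh, min_size=a.min_size,
            connectivity=a.connectivity, alpha=a.alpha,
        )

    def summary(self) -> str:
        lines = [
            "Eigenvector centrality difference analysis",
            f"  subjects: {len(self.subject_ids)}  grid: {self.grid_shape}",
            f"  voxels in analysis mask: {int(self.mask.sum())}",
            f"  clusters (>{self.analysis.min_size} voxels at "
            f"p<={self.analysis.p_thresh}): {len(self.cluster_table)}",
        ]
        if len(self.cluster_table):
            lines.append(self.cluster_table.to_string(index=False))
        return "\n".join(lines)
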