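"""First-level denoising of resting-state time series and ROI connectivity.

The first-level stream mirrors a standard seed-based pipeline: discard the
initial frames acquired before magnetisation reaches steady state, high-pass
filter (0.01 Hz), regress out the six rigid-body motion parameters, regress
out the mean white-matter and CSF signals, low-pass filter (0.20 Hz), then
mean-centre and standardise before computing the pairwise Pearson
correlation matrix between regional time series.  A second variant used for
eigenvector-centrality mapping replaces the separate high-/low-pass pair by
one 0.01-0.2 Hz band-pass applied after nuisance regression.

All filters are zero-phase (forward-backward) second-order Butterworth
filters, one per cutoff, so the frequency response is the squared magnitude
of the underlying second-order prototype and can be checked analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "ScanTimeSeries",
    "ConnectivityMatrix",
    "discard_initial_frames",
    "temporal_filter",
    "regress_out",
    "standardize",
    "run_first_level",
    "compute_fc",
]


@dataclass(frozen=True)
class ScanTimeSeries:
    """One scan: channel time series plus the nuisance regressors.

    ``data`` holds frames x channels (ROI or voxel signals); ``motion`` the
    frames x 6 rigid-body parameters; ``wm`` / ``csf`` the mean white-matter
    and CSF signals, one value per frame.
    """

    data: np.ndarray
    channel_labels: tuple
    motion: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "motion", np.asarray(self.motion, dtype=float))
        object.__setattr__(self, "wm", np.asarray(self.wm, dtype=float).ravel())
        object.__setattr__(self, "csf", np.asarray(self.csf, dtype=float).ravel())
        n = data.shape[0]
        if self.motion.shape != (n, 6):
            raise ValueError(
                f"motion must be (n_frames, 6) = ({n}, 6); got {self.motion.shape}"
            )
        if self.wm.shape[0] != n or self.csf.shape[0] != n:
            raise ValueError("wm/csf length must equal the data frame count")
        if not np.isfinite(data).all():
            raise ValueError("time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix over labelled ROIs."""

    values: np.ndarray
    roi_labels: tuple
    network_of: dict
    hemisphere_of: dict

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        r = len(self.roi_labels)
        if v.shape != (r, r):
            raise ValueError(f"values must be {r}x{r}; got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("connectivity matrix must have unit diagonal")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def upper_triangle(self) -> np.ndarray:
        """Vectorised strict upper triangle (row-major edge order)."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


def discard_initial_frames(scan: ScanTimeSeries, k: int = 4) -> ScanTimeSeries:
    """Drop the first ``k`` frames from the data and every regressor."""
    if not 0 <= k < scan.n_frames:
        raise ValueError(
            f"cannot discard {k} frames from a {scan.n_frames}-frame scan"
        )
    return replace(
        scan,
        data=scan.data[k:],
        motion=scan.motion[k:],
        wm=scan.wm[k:],
        csf=scan.csf[k:],
    )


def _butter_sos(cutoff_hz: float, tr_seconds: float, btype: str):
    nyquist = 0.5 / tr_seconds
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist:.4g}) Hz"
        )
    return signal.butter(2, cutoff_hz / nyquist, btype=btype, output="sos")


def temporal_filter(
    series: np.ndarray,
    tr_seconds: float,
    low_cut_hz: float | None = None,
    high_cut_hz: float | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth filtering along the frame axis.

    ``low_cut_hz`` sets a high-pass edge (removes slow drift and the DC
    component); ``high_cut_hz`` sets a low-pass edge.  Passing both gives a
    band-pass realised as the cascade of the two second-order sections.
    """
    series = np.asarray(series, dtype=float)
    if low_cut_hz is None and high_cut_hz is None:
        return series.copy()
    if low_cut_hz is not None and high_cut_hz is not None:
        if low_cut_hz >= high_cut_hz:
            raise ValueError("low_cut_hz must be below high_cut_hz")
    out = series
    if low_cut_hz is not None:
        out = out - out.mean(axis=0, keepdims=True)  # explicit DC removal
        out = signal.sosfiltfilt(_butter_sos(low_cut_hz, tr_seconds, "highpass"), out, axis=0)
    if high_cut_hz is not None:
        out = signal.sosfiltfilt(_butter_sos(high_cut_hz, tr_seconds, "lowpass"), out, axis=0)
    return out


def regress_out(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualise each column of ``series`` on ``regressors`` plus intercept.

    Residuals are orthogonal to every regressor column (and mean-free) to
    numerical precision.  A rank-deficient design is rejected with the
    offending columns named.
    """
    series = np.asarray(series, dtype=float)
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    n = series.shape[0]
    if regressors.shape[0] != n:
        raise ValueError("regressors must have the same frame count as the series")
    design = np.column_stack([np.ones(n), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _rank_deficient_columns(design)
        raise ValueError(
            "rank-deficient nuisance design; offending columns (0=intercept): "
            f"{bad}"
        )
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def _rank_deficient_columns(design: np.ndarray) -> list[int]:
    """Columns that add no rank when appended left to right."""
    bad = []
    rank = 0
    for j in range(design.shape[1]):
        new = np.linalg.matrix_rank(design[:, : j + 1])
        if new == rank:
            bad.append(j)
        rank = new
    return bad


def standardize(series: np.ndarray) -> np.ndarray:
    """Mean-centre and scale every channel to unit sample (n-1) SD."""
    series = np.asarray(series, dtype=float)
    two_d = series.ndim == 2
    mat = series if two_d else series[:, None]
    sd = mat.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) at index {zero.tolist()}")
    out = (mat - mat.mean(axis=0)) / sd
    return out if two_d else out.ravel()


def run_first_level(
    scan: ScanTimeSeries,
    pipeline: str = "roi_fc",
    discard_frames: int = 4,
    low_cut_hz: float = 0.01,
    high_cut_hz: float = 0.20,
) -> np.ndarray:
    """Apply the full per-scan denoising sequence and return cleaned series.

    ``roi_fc``: discard -> high-pass -> motion regression -> WM/CSF
    regression -> low-pass -> standardise.  ``ecm``: discard -> motion
    regression -> WM/CSF regression -> band-pass -> standardise.
    """
    if pipeline not in ("roi_fc", "ecm"):
        raise ValueError(f"unknown pipeline {pipeline!r}")
    scan = discard_initial_frames(scan, discard_frames)
    data = scan.data
    tr = scan.tr_seconds
    if pipeline == "roi_fc":
        data = temporal_filter(data, tr, low_cut_hz=low_cut_hz)
        data = regress_out(data, scan.motion)
        data = regress_out(data, np.column_stack([scan.wm, scan.csf]))
        data = temporal_filter(data, tr, high_cut_hz=high_cut_hz)
    else:
        data = regress_out(data, scan.motion)
        data = regress_out(data, np.column_stack([scan.wm, scan.csf]))
        data = temporal_filter(data, tr, low_cut_hz=low_cut_hz, high_cut_hz=high_cut_hz)
    return standardize(data)


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher z-transform of a correlation matrix's off-diagonal entries.

    The diagonal is left at zero (arctanh(1) is infinite and carries no
    information).  Downstream analyses consume raw r by default; this
    transform is provided for variance-stabilised workflows.
    """
    values = np.asarray(values, dtype=float)
    out = np.arctanh(np.clip(values, -1 + 1e-15, 1 - 1e-15))
    if out.ndim == 2 and out.shape[0] == out.shape[1]:
        np.fill_diagonal(out, 0.0)
    return out


def compute_fc(
    series: np.ndarray,
    labels,
    networks: dict | None = None,
    hemispheres: dict | None = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation matrix of the channel time series."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 frames to correlate")
    if series.shape[1] != len(labels):
        raise ValueError("label count must match channel count")
    sd = series.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant channel(s) at index {zero.tolist()}")
    r = np.corrcoef(series, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r,
        roi_labels=tuple(labels),
        network_of=dict(networks or {}),
        hemisphere_of=dict(hemispheres or {}),
    )
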