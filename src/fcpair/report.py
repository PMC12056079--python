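"""Result-table rendering and run manifests.

Rendering conventions follow the field's reporting habits: classification
metrics to 2 decimal places, cluster-level mean EC differences multiplied
by 10^3, and significance stars (* p<0.05, ** p<0.01, *** p<0.001).
Manifests record the configuration, seeds and a SHA-256 digest of every
output file so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

__all__ = [
    "significance_stars",
    "render_classification_table",
    "render_cluster_table",
    "RunManifest",
]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_classification_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classification summary with 2-dp metrics and significance stars."""
    out = pd.DataFrame()
    out["Pairs"] = table["mask"]
    out["SVM Accuracy"] = table["accuracy"].map("{:.2f}".format)
    out["P value"] = [
        f"{p:.4g}{significance_stars(p)}" for p in table["p_raw"]
    ]
    out["FDR-corrected p value"] = [
        f"{p:.4g}{significance_stars(p)}" for p in table["p_fdr"]
    ]
    out["AUC"] = table["auc"].map("{:.2f}".format)
    out["Sensitivity"] = table["sensitivity"].map("{:.2f}".format)
    out["Specificity"] = table["specificity"].map("{:.2f}".format)
    return out


def render_cluster_table(table: pd.DataFrame) -> pd.DataFrame:
    """Cluster summary with mean EC differences in units of 10^-3."""
    out = pd.DataFrame()
    if len(table) == 0:
        return pd.DataFrame(
            columns=["Cluster", "Average dEC (x10^3)", "t", "FDR p", "Number of voxels"]
        )
    out["Cluster"] = table["cluster"]
    out["Average dEC (x10^3)"] = [
        f"{1e3 * m:.2f} ± {1e3 * s:.2f}"
        for m, s in zip(table["mean_delta_ec"], table["sd_delta_ec"])
    ]
    out["t"] = [f"{t:.2f}{significance_stars(p)}"
                for t, p in zip(table["t"], table["p_fdr"])]
    out["FDR p"] = table["p_fdr"].map("{:.4g}".format)
    out["Number of voxels"] = table["n_voxels"]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Records config, seeds and output digests for one pipeline run."""

    def __init__(self, config: dict, seed: int | None):
        self.data = {
            "config": config,
            "seed": seed,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {},
            "outputs": {},
            "warnings": [],
        }

    def record_stage(self, name: str, **info):
        self.data["stages"][name] = info

    def record_output(self, path):
        path = Path(path)
        self.data["outputs"][path.name] = _sha256(path)

    def warn(self, message: str):
        self.data["warnings"].append(message)

    def write(self, path):
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)
        return path
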