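"""The bilateral motor cortico-striatal-thalamo-cerebellar ROI inventory.

Three subnetworks, hemispheres instantiated left/right:

* cerebellum (8): lobules I-IV, V, VI and Crus I per hemisphere (the lobules
  above the horizontal fissure, i.e. those with reliable field-of-view
  coverage);
* basal ganglia + thalamus (8): thalamus, caudate nucleus, putamen and
  globus pallidus per hemisphere;
* motor cortex (10): precentral gyrus, inferior and superior precentral
  sulci, caudal superior frontal gyrus (SMA) and caudal middle frontal
  gyrus (premotor) per hemisphere.
"""

from __future__ import annotations

CEREBELLUM = "cerebellum"
BASAL_GANGLIA = "basal_ganglia"
MOTOR_CORTEX = "motor_cortex"

NETWORKS = (CEREBELLUM, BASAL_GANGLIA, MOTOR_CORTEX)

_BASE_ROIS = {
    CEREBELLUM: ("CBL_I_IV", "CBL_V", "CBL_VI", "CBL_CrusI"),
    BASAL_GANGLIA: ("Tha", "Cdn", "Pu", "GP"),
    MOTOR_CORTEX: ("PreCG", "InfPreCS", "SupPreCS", "SFGcau", "MFGcau"),
}


def default_roi_set():
    """Bilateral ROI labels with their network and hemisphere maps.

    Returns ``(labels, network_of, hemisphere_of)`` with labels ordered
    cerebellum, basal ganglia, motor cortex; left before right within each
    base region.
    """
    labels: list[str] = []
    network_of: dict[str, str] = {}
    hemisphere_of: dict[str, str] = {}
    for network in NETWORKS:
        for base in _BASE_ROIS[network]:
            for hemi in ("L", "R"):
                label = f"{hemi}_{base}"
                labels.append(label)
                network_of[label] = network
                hemisphere_of[label] = hemi
    return tuple(labels), network_of, hemisphere_of


def network_sizes() -> dict[str, int]:
    return {net: 2 * len(_BASE_ROIS[net]) for net in NETWORKS}
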