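"""Atlas loading: AAL-style label tables with network assignments.

The package ships the standard 116-region AAL name table and an editable
ROI-to-network mapping covering the seven canonical resting-state networks
(basal ganglia, central executive, default mode, motor, salience, visual,
auditory).  Cerebellar and vermis regions are excluded from analysis,
leaving the first 90 cerebral ROIs; ROIs without a network assignment
contribute only between-network edges to the contrast metrics.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Parcellation

__all__ = ["aal_label_table", "aal_network_table", "load_atlas", "EXCLUDED_PREFIXES"]

EXCLUDED_PREFIXES = ("Cerebelum", "Vermis")


def _data_path(name: str):
    return resources.files("denoisebench").joinpath("data", name)


def aal_label_table() -> pd.DataFrame:
    """The shipped AAL-116 index/name table."""
    with resources.as_file(_data_path("aal116_labels.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def aal_network_table() -> pd.DataFrame:
    """The shipped (editable) ROI-name to resting-state-network mapping."""
    with resources.as_file(_data_path("aal_networks.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_atlas(
    label_map: np.ndarray | str | Path,
    name_table: pd.DataFrame | None = None,
    network_table: pd.DataFrame | None = None,
    exclude_prefixes: tuple[str, ...] = EXCLUDED_PREFIXES,
) -> Parcellation:
    """Build a :class:`Parcellation` from an integer label image and tables.

    ``label_map`` may be a 3D integer array or a path to a label NIfTI.
    Labels whose names start with an excluded prefix (cerebellum, vermis)
    are dropped; with the standard AAL table exactly 90 ROIs remain.  Any
    label present in the image but absent from the name table is an error.
    """
    if name_table is None:
        name_table = aal_label_table()
    if network_table is None:
        network_table = aal_network_table()
    if isinstance(label_map, (str, Path)):
        from .fileio import read_label_map

        labels = read_label_map(label_map)
    else:
        labels = np.asarray(label_map).astype(int)

    names = dict(zip(name_table["index"].astype(int), name_table["name"]))
    present = sorted(set(int(v) for v in np.unique(labels)) - {0})
    unnamed = [v for v in present if v not in names]
    if unnamed:
        raise ValueError(f"label values without names in the table: {unnamed}")

    excluded_ids = {
        idx for idx, name in names.items() if name.startswith(exclude_prefixes)
    }
    out_labels = labels.copy()
    for idx in excluded_ids:
        out_labels[out_labels == idx] = 0

    kept = {idx: names[idx] for idx in present if idx not in excluded_ids}
    net_map = dict(zip(network_table["name"], network_table["network"]))
    network_of = {idx: net_map.get(name) for idx, name in kept.items()}
    return Parcellation(labels=out_labels, roi_names=kept, network_of=network_of)
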