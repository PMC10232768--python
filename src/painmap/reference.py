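"""Reported reference values from the trigeminal-neuralgia percept-fMRI study.

Small TSVs shipped with the package hold the study's printed result tables
for the full 39-patient cohort: the signed correlation cluster tables, the
pooled decoder confusion matrices, and the cross-method consensus flags.
They serve as worked-example inputs for the table-level operations
(consensus logic, region unions, volume arithmetic, pooled accuracy) — the
raw patient fMRI itself is not distributable.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "reported_clusters", "reported_consensus_flags", "reported_confusion",
    "reported_region_sets", "reported_cluster_regions", "VOXEL_MM3",
]

# 3 mm isotropic analysis grid: the cluster tables' mm^3/voxel ratio.
VOXEL_MM3 = 27.0


def _read(name: str) -> pd.DataFrame:
    with resources.files("painmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reported_clusters(sign: str) -> pd.DataFrame:
    """Published cluster table for 'positive' or 'negative' correlations."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    return _read(f"reported_clusters_{sign}.tsv")


def reported_cluster_regions(sign: str) -> set[str]:
    return set(reported_clusters(sign)["region"])


def reported_consensus_flags() -> pd.DataFrame:
    """Region x method identification flags of the published consensus table."""
    return _read("reported_consensus_flags.tsv")


def reported_region_sets() -> tuple[set[str], set[str], set[str]]:
    """The three methods' identified-region sets implied by the flags."""
    df = reported_consensus_flags()
    return (set(df.loc[df["correlation"] == 1, "region"]),
            set(df.loc[df["cnn"] == 1, "region"]),
            set(df.loc[df["gcnn"] == 1, "region"]))


def reported_confusion(method: str) -> np.ndarray:
    """Pooled 2x2 confusion counts (rows true low/high, cols predicted)."""
    df = _read("reported_confusion.tsv").set_index("method")
    if method not in df.index:
        raise ValueError(f"unknown method {method!r}")
    r = df.loc[method]
    return np.array([[r["true_low_pred_low"], r["true_low_pred_high"]],
                     [r["true_high_pred_low"], r["true_high_pred_high"]]],
                    dtype=int)
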