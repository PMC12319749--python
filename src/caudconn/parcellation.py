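"""Voxel-wise winner-take-all parcellation of striatal voxels.

Each striatal voxel is correlated with every cortical voxel (Fisher
z-transformed), maps are averaged within groups, and the voxel is assigned
the cortical network most frequently represented among its k most
correlated cortical voxels (k = 25 by default).  Allocation fractions and
cross-group label-overlap tables summarise age-group differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bold import BoldRun, mask_to_indices

logger = logging.getLogger(__name__)

TOP_K = 25
CLIP_R = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z = atanh(r), with |r| clipped to 1 - 1e-7 before transform."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    return np.arctanh(np.clip(r, -CLIP_R, CLIP_R))


@dataclass
class VoxelZMap:
    """Fisher-z correlations, rows = striatal voxels, cols = cortical voxels."""

    z: np.ndarray
    striatal_voxels: np.ndarray  # (Ns, 3)
    cortical_voxels: np.ndarray  # (Nc, 3)
    tag: str = ""
    zero_variance_rows: list = field(default_factory=list)
    zero_variance_cols: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.z.shape != (len(self.striatal_voxels), len(self.cortical_voxels)):
            raise ValueError("z shape must match voxel index tables")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z map contains non-finite entries")

    def same_space(self, other: "VoxelZMap") -> bool:
        return (
            self.z.shape == other.z.shape
            and np.array_equal(self.striatal_voxels, other.striatal_voxels)
            and np.array_equal(self.cortical_voxels, other.cortical_voxels)
        )


def voxelwise_zmap(
    bold: BoldRun,
    striatal_mask: np.ndarray,
    cortical_mask: np.ndarray,
    tag: str = "",
) -> VoxelZMap:
    """Pearson correlation of every striatal voxel with every cortical voxel
    over all retained volumes, Fisher z-transformed.

    Zero-variance voxels contribute z = 0 and are logged.
    """
    striatal_mask = np.asarray(striatal_mask, dtype=bool)
    cortical_mask = np.asarray(cortical_mask, dtype=bool)
    if np.any(striatal_mask & cortical_mask):
        raise ValueError("striatal and cortical masks must be disjoint")
    s = bold.timeseries(striatal_mask).astype(float)
    c = bold.timeseries(cortical_mask).astype(float)

    def standardize(x):
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        zero = sd == 0
        sd[zero] = 1.0
        return x / sd[:, None], np.flatnonzero(zero)

    s_std, s_zero = standardize(s)
    c_std, c_zero = standardize(c)
    if len(s_zero) or len(c_zero):
        logger.warning(
            "zero-variance voxels assigned z=0: %d striatal, %d cortical",
            len(s_zero), len(c_zero),
        )
    r = (s_std @ c_std.T) / s.shape[1]
    z = fisher_z(np.clip(r, -1.0, 1.0))
    z[s_zero, :] = 0.0
    z[:, c_zero] = 0.0
    return VoxelZMap(
        z=z,
        striatal_voxels=mask_to_indices(striatal_mask),
        cortical_voxels=mask_to_indices(cortical_mask),
        tag=tag,
        zero_variance_rows=list(s_zero),
        zero_variance_cols=list(c_zero),
    )


def group_average(zmaps: list[VoxelZMap], tag: str = "") -> VoxelZMap:
    """Element-wise mean of per-subject z maps over identical voxel spaces."""
    if not zmaps:
        raise ValueError("no z maps to average")
    first = zmaps[0]
    for m in zmaps[1:]:
        if not first.same_space(m):
            raise ValueError("z maps are not in the same voxel space")
    return VoxelZMap(
        z=np.mean([m.z for m in zmaps], axis=0),
        striatal_voxels=first.striatal_voxels,
        cortical_voxels=first.cortical_voxels,
        tag=tag,
    )


@dataclass
class ParcellationMap:
    """Per-striatal-voxel winning network with vote diagnostics."""

    labels: np.ndarray  # (Ns,) winning network label
    votes: np.ndarray  # (Ns, n_networks) counts over the top-k voxels
    margin: np.ndarray  # top vote - runner-up vote
    striatal_voxels: np.ndarray
    network_labels: np.ndarray  # label values indexing the vote columns
    k: int
    tie_log: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.striatal_voxels, columns=["i", "j", "k_idx"])
        df["label"] = self.labels
        for col, lab in enumerate(self.network_labels):
            df[f"votes_net{lab}"] = self.votes[:, col]
        df["margin"] = self.margin
        return df


def winner_take_all(
    group_map: VoxelZMap,
    cortical_labels: np.ndarray,
    k: int = TOP_K,
    tie_rule: str = "summed-z",
) -> ParcellationMap:
    """Assign each striatal voxel the modal network among its top-k cortical
    voxels by group-mean z.

    Ties at the k-th ranked z are broken by ascending cortical voxel index
    (stable sort); ties between networks by the larger summed z over that
    network's voxels within the top-k, then by the lower label index.  All
    tie decisions are logged on the returned map.
    """
    labels3d = np.asarray(cortical_labels)
    cv = group_map.cortical_voxels
    cort_lab = labels3d[cv[:, 0], cv[:, 1], cv[:, 2]].astype(int)
    if np.any(cort_lab <= 0):
        raise ValueError("every cortical voxel must carry a nonzero network label")
    if k > len(cort_lab):
        raise ValueError(f"k={k} exceeds cortical voxel count {len(cort_lab)}")
    if tie_rule not in ("summed-z", "lowest-label"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")

    networks = np.unique(cort_lab)
    n_net = len(networks)
    net_col = {lab: i for i, lab in enumerate(networks)}

    n_vox = group_map.z.shape[0]
    votes = np.zeros((n_vox, n_net), dtype=int)
    win = np.zeros(n_vox, dtype=int)
    margin = np.zeros(n_vox, dtype=int)
    tie_log: list[dict] = []

    for v in range(n_vox):
        row = group_map.z[v]
        order = np.argsort(-row, kind="stable")
        top = order[:k]
        if k < len(row) and row[order[k - 1]] == row[order[k]]:
            tie_log.append({"voxel": v, "kind": "kth-rank-tie"})
        top_labels = cort_lab[top]
        counts = np.zeros(n_net, dtype=int)
        for lab in top_labels:
            counts[net_col[lab]] += 1
        votes[v] = counts
        best = counts.max()
        cand = np.flatnonzero(counts == best)
        if len(cand) > 1:
            if tie_rule == "summed-z":
                sums = np.array(
                    [row[top[top_labels == networks[c]]].sum() for c in cand]
                )
                cand = cand[np.flatnonzero(sums == sums.max())]
            tie_log.append(
                {"voxel": v, "kind": "network-vote-tie",
                 "candidates": [int(networks[c]) for c in cand]}
            )
        win[v] = networks[cand[0]]  # lowest label index among remaining ties
        sorted_counts = np.sort(counts)[::-1]
        margin[v] = sorted_counts[0] - (sorted_counts[1] if n_net > 1 else 0)

    return ParcellationMap(
        labels=win, votes=votes, margin=margin,
        striatal_voxels=group_map.striatal_voxels,
        network_labels=networks, k=k, tie_log=tie_log,
    )


def allocation_fractions(pmap: ParcellationMap) -> pd.Series:
    """Percentage of striatal voxels assigned to each network (sums to 100)."""
    if len(pmap.labels) == 0:
        raise ValueError("empty parcellation map")
    counts = pd.Series(0, index=pd.Index(pmap.network_labels, name="network"), dtype=float)
    uniq, n = np.unique(pmap.labels, return_counts=True)
    counts.loc[uniq] = n
    return 100.0 * counts / len(pmap.labels)


def label_overlap(
    reference: ParcellationMap, comparison: ParcellationMap, network: int
) -> dict:
    """Retention and redistribution of a reference network's voxels.

    Over voxels labelled ``network`` in the reference map: ``retention_pct``
    is the share keeping that label in the comparison map; redistribution
    gives the share captured by each competing network.  When the network is
    absent from the reference, the result is flagged undefined rather than 0.
    """
    if not np.array_equal(reference.striatal_voxels, comparison.striatal_voxels):
        raise ValueError("maps are not in the same voxel space")
    sel = reference.labels == network
    if not np.any(sel):
        return {"defined": False, "network": int(network),
                "retention_pct": None, "redistribution_pct": {}}
    comp = comparison.labels[sel]
    total = len(comp)
    retention = 100.0 * np.sum(comp == network) / total
    redis = {
        int(lab): 100.0 * np.sum(comp == lab) / total
        for lab in np.unique(comp)
        if lab != network
    }
    return {"defined": True, "network": int(network),
            "retention_pct": retention, "redistribution_pct": redis}
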