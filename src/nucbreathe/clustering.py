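"""Conformational clustering and DNA <-> tail co-occupancy.

Frames are superposed on a reference over the histone-core heavy atoms,
a coordinate subset (DNA arm, H3, or H2A-without-N-tail) is flattened into a
feature vector per frame, and k-means (k = 8 by default) partitions the
frames.  Cluster labels are ranked by size (1 = largest).  Cross-tabulating
the DNA partition against a tail partition gives, for each DNA cluster, the
percentage of its frames found in each tail-configuration cluster -- the
matrix that links DNA opening to tail release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .geometry import superpose
from .structure_io import NucleosomeIndex, SelectionError, Trajectory


class ClusteringError(Exception):
    pass


#: DNA backbone heavy-atom names (sugar-phosphate) for all-atom structures;
#: generator pseudo-beads use a subset of these names, so the same filter
#: applies to both.
DNA_BACKBONE_NAMES = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
    "O5*", "C5*", "C4*", "O4*", "C3*", "O3*", "C2*", "C1*",
}


@dataclass
class ClusterModel:
    """Size-ranked k-means partition of one coordinate subset."""

    k: int
    assignment: np.ndarray              # per-frame labels 1..k, 1 = largest
    centroids: np.ndarray
    sizes: np.ndarray
    seed: int
    selection_tag: str
    inertia: float = np.nan

    def __post_init__(self) -> None:
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(1, self.k + 1)):
            raise ClusteringError("labels must be dense 1..k")
        if int(self.sizes.sum()) != self.assignment.size:
            raise ClusteringError("cluster sizes must sum to n_frames")

    @property
    def n_frames(self) -> int:
        return self.assignment.size


def build_feature_matrix(traj: Trajectory, nuc: NucleosomeIndex,
                         selection_tag: str,
                         reference: np.ndarray | None = None,
                         opening_arm: str = "3p") -> np.ndarray:
    """(n_frames, 3*n_sel) matrix of superposed, flattened coordinates.

    Selections by tag: ``dna`` = backbone heavy atoms of the inner gyre plus
    the opening arm's outer gyre (the quiet arm is left out), ``h3`` = entire
    H3 chains, ``h2ac`` = H2A chains excluding the N-terminal tail.  Each
    frame is first least-squares fitted to the reference (default: frame 0)
    over the histone-core heavy atoms.
    """
    structure = nuc.structure
    if selection_tag == "dna":
        ann = nuc.annotation
        bp = np.concatenate([ann.inner_gyre,
                             ann.outer_gyre_3p if opening_arm == "3p"
                             else ann.outer_gyre_5p])
        atoms = nuc.bp_atoms(bp)
        atoms = atoms[np.isin(structure.atom_names[atoms],
                              list(DNA_BACKBONE_NAMES))]
    elif selection_tag == "h3":
        atoms = nuc.histone_atoms("H3")
    elif selection_tag == "h2ac":
        n_tails = [t.name for t in nuc.annotation.tails
                   if t.name.startswith("H2AN")]
        atoms = nuc.histone_atoms("H2A", exclude_tails=tuple(n_tails))
    else:
        raise SelectionError(f"unknown selection tag {selection_tag!r}")
    if atoms.size == 0:
        raise SelectionError(f"selection {selection_tag!r} is empty")

    fit_sel = nuc.histone_core_atoms()
    ref = traj.coords[0] if reference is None else np.asarray(reference)
    X = np.empty((traj.n_frames, atoms.size * 3))
    for f in range(traj.n_frames):
        transform, _ = superpose(traj.coords[f], ref, fit_sel)
        X[f] = transform.apply(traj.coords[f][atoms]).ravel()
    return X


def kmeans_cluster(matrix: np.ndarray, k: int = 8, seed: int = 0,
                   n_init: int = 10, max_iter: int = 500,
                   selection_tag: str = "dna") -> ClusterModel:
    """k-means++ clustering of the feature matrix, size-ranked labels."""
    matrix = np.asarray(matrix)
    if matrix.shape[0] < k:
        raise ClusteringError(
            f"{matrix.shape[0]} frames cannot support k={k} clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=1e-6, random_state=seed)
    raw = km.fit_predict(matrix)
    model = ClusterModel(
        k=k,
        assignment=raw + 1,
        centroids=km.cluster_centers_,
        sizes=np.bincount(raw, minlength=k),
        seed=seed,
        selection_tag=selection_tag,
        inertia=float(km.inertia_),
    )
    return rank_clusters(model)


def rank_clusters(model: ClusterModel) -> ClusterModel:
    """Relabel so sizes are non-increasing; ties keep lowest original label."""
    order = np.lexsort((np.arange(model.k), -model.sizes))  # stable by size
    relabel = np.empty(model.k, dtype=int)
    relabel[order] = np.arange(1, model.k + 1)
    return ClusterModel(
        k=model.k,
        assignment=relabel[model.assignment - 1],
        centroids=model.centroids[order],
        sizes=model.sizes[order],
        seed=model.seed,
        selection_tag=model.selection_tag,
        inertia=model.inertia,
    )


def cross_tabulate(dna_model: ClusterModel,
                   tail_model: ClusterModel) -> pd.DataFrame:
    """Row-normalized contingency matrix in percent.

    Entry (i, j) = 100 * |{frames: dna=i and tail=j}| / |{frames: dna=i}|;
    every row sums to 100.
    """
    if dna_model.n_frames != tail_model.n_frames:
        raise ClusteringError("cluster assignments cover different frames")
    tab = pd.crosstab(pd.Series(dna_model.assignment, name="dna_cluster"),
                      pd.Series(tail_model.assignment, name="tail_cluster"))
    tab = tab.reindex(index=np.arange(1, dna_model.k + 1),
                      columns=np.arange(1, tail_model.k + 1), fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def map_clusters_to_gamma(model: ClusterModel, observables: pd.DataFrame,
                          arm: str) -> pd.DataFrame:
    """Per-cluster mean (gamma1, gamma2) and size, for centroid overlays.

    ``observables`` must carry one row per clustered frame (same order).
    Clusters whose member frames all have undefined angles get NaN means.
    """
    if len(observables) != model.n_frames:
        raise ClusteringError(
            "observables and cluster assignment cover different frames")
    g1 = observables[f"gamma1_{arm}"].to_numpy(dtype=float)
    g2 = observables[f"gamma2_{arm}"].to_numpy(dtype=float)
    rows = []
    for c in range(1, model.k + 1):
        member = model.assignment == c
        with np.errstate(invalid="ignore"):
            m1 = np.nanmean(g1[member]) if np.isfinite(g1[member]).any() else np.nan
            m2 = np.nanmean(g2[member]) if np.isfinite(g2[member]).any() else np.nan
        rows.append((c, m1, m2, int(member.sum())))
    return pd.DataFrame(rows, columns=["cluster", "mean_gamma1",
                                       "mean_gamma2", "size"])


@dataclass
class SummaryRow:
    """Two-sided percentile summary of one observable series."""

    label: str
    p_lo: float
    p_hi: float
    lo: float = 5.0
    hi: float = 95.0

    def __post_init__(self) -> None:
        if self.p_lo > self.p_hi:
            raise ClusteringError("lower percentile exceeds upper percentile")


def percentile_summary(series: np.ndarray | pd.Series, label: str = "",
                       lo: float = 5.0, hi: float = 95.0) -> SummaryRow:
    """Linear-interpolation percentiles at ``lo`` and ``hi`` (default 5/95)."""
    values = np.asarray(series, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot summarize an empty series")
    p_lo, p_hi = np.percentile(values, [lo, hi], method="linear")
    return SummaryRow(label=label, p_lo=float(p_lo), p_hi=float(p_hi),
                      lo=lo, hi=hi)
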