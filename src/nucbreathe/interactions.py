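"""Histone-DNA interaction measures.

Implements the contact count N_C (non-hydrogen atom pairs closer than a
cutoff, 4.5 A by default) and the inverse-power weighted mean distance

    d[n] = ( (1/(N1*N2)) * sum_ij (1/||d_ij||)^n )^(-1/n)

between two atom groups, where n is an even positive integer.  d[10] tracks
the mean separation (delta); d[100] approaches the minimal pairwise distance
(delta_min) and is the per-residue "minimal distance" used in the heatmaps.
The naive sum overflows for n = 100, so the minimum distance is factored out
first: every term (d_min/d_ij)^n lies in (0, 1].

Per-tail configuration descriptors combine delta to the adjacent L-DNA,
delta to the same-side dyad segment, contact counts to the inner and outer
DNA gyres, and the tail's radius of gyration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import compute_rg
from .structure_io import NucleosomeIndex, SelectionError, Trajectory


class SingularDistanceError(Exception):
    """Two selected atoms coincide; inverse-power distance is undefined."""


@dataclass
class ContactSpec:
    """Contact definition: strict distance cutoff over heavy-atom pairs."""

    cutoff: float = 4.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass
class WeightedDistanceSpec:
    """Exponent of the inverse-power weighted mean distance (even, >= 2)."""

    n: int = 10

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2:
            raise ValueError("exponent n must be an even integer >= 2")


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def count_contacts(coords: np.ndarray, sel_a: np.ndarray, sel_b: np.ndarray,
                   spec: ContactSpec | None = None) -> int:
    """Number of (a in A, b in B) pairs with |r_a - r_b| < cutoff (strict).

    Selections must be disjoint, non-empty atom index arrays; the caller is
    responsible for restricting them to heavy atoms (NucleosomeIndex
    selections already are).
    """
    spec = spec or ContactSpec()
    sel_a, sel_b = np.asarray(sel_a), np.asarray(sel_b)
    if sel_a.size == 0 or sel_b.size == 0:
        raise SelectionError("contact selections must be non-empty")
    if np.intersect1d(sel_a, sel_b).size:
        raise SelectionError("contact selections must be disjoint")
    a, b = np.asarray(coords)[sel_a], np.asarray(coords)[sel_b]
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    # count_neighbors uses <=; enforce the strict inequality by removing
    # pairs at exactly the cutoff (measure zero, but contract is strict)
    total = int(tree_a.count_neighbors(tree_b, spec.cutoff))
    pairs = tree_a.query_ball_tree(tree_b, spec.cutoff)
    exact = 0
    for i, js in enumerate(pairs):
        if js:
            d = np.linalg.norm(b[js] - a[i], axis=1)
            exact += int(np.sum(d == spec.cutoff))
    return total - exact


def weighted_mean_distance(coords: np.ndarray, sel_a: np.ndarray,
                           sel_b: np.ndarray,
                           spec: WeightedDistanceSpec | None = None) -> float:
    """Inverse-power weighted mean distance d[n] between two groups (A).

    Numerically stable for n = 100 across distances spanning orders of
    magnitude; always >= the true minimum pairwise distance.
    """
    spec = spec or WeightedDistanceSpec()
    sel_a, sel_b = np.asarray(sel_a), np.asarray(sel_b)
    if sel_a.size == 0 or sel_b.size == 0:
        raise SelectionError("weighted-distance selections must be non-empty")
    coords = np.asarray(coords)
    d = cdist(coords[sel_a], coords[sel_b])
    dmin = d.min()
    if dmin <= 0.0:
        raise SingularDistanceError("coincident atoms between the two groups")
    ratio = dmin / d                       # in (0, 1]
    mean_pow = np.mean(ratio ** spec.n)    # (1/(N1 N2)) sum (dmin/dij)^n
    return float(dmin * mean_pow ** (-1.0 / spec.n))


# ---------------------------------------------------------------------------
# Tail configuration series
# ---------------------------------------------------------------------------

def tail_configuration_series(traj: Trajectory, nuc: NucleosomeIndex,
                              tail: str, stride: int = 1,
                              contact_spec: ContactSpec | None = None
                              ) -> pd.DataFrame:
    """Per-frame tail descriptors: delta to L-DNA and dyad segment (n=10),
    contacts to inner/outer gyres, and tail Rg.

    Columns: frame, time_ps, delta_ldna, delta_dyad, nc_inner, nc_outer,
    tail_rg.  Raises :class:`SelectionError` for an absent tail.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ann = nuc.annotation
    tdef = ann.tail(tail)  # raises SelectionError if unknown
    tail_atoms = nuc.tail_atoms(tail)
    arm = tdef.arm
    ldna_atoms = nuc.bp_atoms(ann.ldna(arm))
    dyad_atoms = nuc.bp_atoms(ann.dyad_segment(arm))
    inner_atoms = nuc.gyre_atoms("inner")
    outer_atoms = nuc.gyre_atoms("outer")
    wspec = WeightedDistanceSpec(10)
    cspec = contact_spec or ContactSpec()
    masses = nuc.structure.masses

    rows = []
    for f in range(0, traj.n_frames, stride):
        c = traj.coords[f]
        rows.append((
            f, f * traj.frame_interval,
            weighted_mean_distance(c, tail_atoms, ldna_atoms, wspec),
            weighted_mean_distance(c, tail_atoms, dyad_atoms, wspec),
            count_contacts(c, tail_atoms, inner_atoms, cspec),
            count_contacts(c, tail_atoms, outer_atoms, cspec),
            compute_rg(c, tail_atoms, masses),
        ))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "delta_ldna",
                                       "delta_dyad", "nc_inner", "nc_outer",
                                       "tail_rg"])


# ---------------------------------------------------------------------------
# Per-residue minimal-distance profiles
# ---------------------------------------------------------------------------

#: Epigenetically relevant H3-tail residues grouped by position along the
#: tail: the tip, the two center groups, and the anchor that pins the L-DNA
#: to the inner gyre.
H3_RESIDUE_GROUPS: dict[str, tuple[str, ...]] = {
    "tip": ("R2", "K4"),
    "center-tip": ("R8", "K9", "K14"),
    "center-anchor": ("R26", "K27"),
    "anchor": ("K36", "K37", "R40", "R42"),
}

_ONE_LETTER = {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
               "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
               "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
               "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}


def _resolve_residue_label(nuc: NucleosomeIndex, chain_id: str,
                           label: str) -> np.ndarray:
    """Atom indices for a label like 'K36' (one-letter code + resid)."""
    code, num = label[0].upper(), label[1:]
    if not num.isdigit():
        raise SelectionError(f"malformed residue label {label!r}")
    resid = int(num)
    atoms = nuc.residue_atoms(chain_id, resid)
    resname = str(nuc.structure.residue_names[atoms[0]]).upper()
    expected = _ONE_LETTER.get(resname)
    if expected is not None and expected != code:
        raise SelectionError(
            f"residue {chain_id}:{resid} is {resname}, not {code!r} "
            f"as label {label!r} claims")
    return atoms


def residue_distance_profile(traj: Trajectory, nuc: NucleosomeIndex,
                             tail: str, gyre: str,
                             residues: dict[str, tuple[str, ...]] | None = None,
                             stride: int = 1) -> pd.DataFrame:
    """Per-residue minimal distance (d[100]) to a DNA gyre, long format.

    ``residues`` maps group name -> residue labels within the tail's chain;
    defaults to :data:`H3_RESIDUE_GROUPS`.  Columns: frame, time_ps, residue,
    group, gyre, delta_min.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    tdef = nuc.annotation.tail(tail)
    groups = residues or H3_RESIDUE_GROUPS
    resolved = []
    for group, labels in groups.items():
        for label in labels:
            resolved.append(
                (label, group, _resolve_residue_label(nuc, tdef.chain_id, label)))
    gyre_atoms = nuc.gyre_atoms(gyre)
    wspec = WeightedDistanceSpec(100)

    rows = []
    for f in range(0, traj.n_frames, stride):
        c = traj.coords[f]
        for label, group, atoms in resolved:
            rows.append((f, f * traj.frame_interval, label, group, gyre,
                         weighted_mean_distance(c, atoms, gyre_atoms, wspec)))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "residue", "group",
                                       "gyre", "delta_min"])


def cluster_median_heatmap(profile: pd.DataFrame,
                           assignment: np.ndarray | dict[int, int]
                           ) -> pd.DataFrame:
    """Median delta_min per (residue, cluster): the heatmap matrix.

    ``assignment`` maps frame index -> cluster label and must cover every
    frame present in the profile.  Clusters with no sampled frames produce
    NaN entries (flagged missing, never zero).
    """
    prof = profile.copy()
    if isinstance(assignment, dict):
        prof["cluster"] = prof["frame"].map(assignment)
    else:
        assignment = np.asarray(assignment)
        if prof["frame"].max() >= assignment.size:
            raise ValueError("assignment does not cover all profiled frames")
        prof["cluster"] = assignment[prof["frame"].to_numpy()]
    if prof["cluster"].isna().any():
        raise ValueError("assignment does not cover all profiled frames")
    residues = list(dict.fromkeys(prof["residue"]))  # preserve profile order
    mat = prof.pivot_table(index="residue", columns="cluster",
                           values="delta_min", aggfunc="median")
    all_clusters = sorted(set(np.unique(list(assignment.values())
                                        if isinstance(assignment, dict)
                                        else assignment)))
    mat = mat.reindex(index=residues, columns=all_clusters)
    return mat
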