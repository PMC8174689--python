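"""Breathing geometry: superposition, dyad frame, opening angles, Rg.

The dyad-centered coordinate system has its origin on the central base pair.
X points from the centroid of the inner-gyre DNA to the dyad (the dyad axis),
the superhelical axis S is the normal of the best-fit plane through the
inner-gyre base-pair centers (sign fixed by the DNA winding direction),
Y = normalize(X x S) and Z = X x Y.  The XY plane is then the nucleosome disc
plane; gamma1 measures out-of-plane (XZ) and gamma2 in-plane (XY) opening of
a linker arm.

Sign convention: gamma1 = atan2(v.X, v.Z) (right-handed about +Y) and
gamma2 = atan2(-v.X, v.Y) (right-handed about +Z) for an arm unit vector v.
gamma1 grows as the arm tilts toward +X, gamma2 as it tilts toward -X: the
two angles describe opening in opposite X directions, which is why a motion
that opens one arm in one plane reads as closing in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import NucleosomeIndex, SelectionError, Trajectory


class GeometryError(Exception):
    """Degenerate geometric construction (collinear fit, undefined plane...)."""


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch least squares)
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """x -> x @ rotation.T + translation"""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimizing the RMSD over the
    selected atoms, and that minimized RMSD (Angstrom).  Raises
    :class:`GeometryError` for fewer than 3 atoms or a collinear selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        selection = np.asarray(selection)
        sel_m, sel_r = mobile[selection], reference[selection]
    if sel_m.shape != sel_r.shape:
        raise GeometryError("selection does not map 1:1 between structures")
    n = sel_m.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    cm, cr = sel_m.mean(axis=0), sel_r.mean(axis=0)
    a, b = sel_r - cr, sel_m - cm
    sv = np.linalg.svd(b, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("collinear selection: rotation is underdetermined")
    rot, rssd = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = float(rssd / np.sqrt(n))
    return RigidTransform(rotation=R, translation=t), rmsd


# ---------------------------------------------------------------------------
# Dyad frame
# ---------------------------------------------------------------------------

@dataclass
class DyadFrame:
    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.X, self.Y, self.Z):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise GeometryError("dyad frame axes must be unit vectors")
        if (abs(self.X @ self.Y) > 1e-9 or abs(self.X @ self.Z) > 1e-9
                or abs(self.Y @ self.Z) > 1e-9):
            raise GeometryError("dyad frame axes must be orthogonal")
        if np.linalg.norm(np.cross(self.X, self.Y) - self.Z) > 1e-9:
            raise GeometryError("dyad frame must be right-handed (Z = X x Y)")

    def to_local(self, v: np.ndarray) -> np.ndarray:
        """Components of a (free) vector in the frame axes."""
        return np.array([v @ self.X, v @ self.Y, v @ self.Z])


def frame_from_bp_centers(centers: np.ndarray, inner_bp: np.ndarray,
                          dyad_bp: int,
                          s_reference: np.ndarray | None = None) -> DyadFrame:
    """Build the dyad frame from base-pair center positions.

    ``centers`` is (L, 3); ``inner_bp`` holds 1-based inner-gyre bp indices;
    ``dyad_bp`` the 1-based dyad index.  The sign of the superhelical axis is
    fixed by the DNA winding direction (or by ``s_reference`` if given), which
    keeps the frame continuous across trajectory frames.
    """
    centers = np.asarray(centers, dtype=float)
    origin = centers[dyad_bp - 1]
    inner = centers[np.asarray(inner_bp) - 1]
    ctr = inner.mean(axis=0)
    x = origin - ctr
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise GeometryError("dyad coincides with inner-gyre centroid")
    X = x / nx

    pts = inner - ctr
    _, sv, vt = np.linalg.svd(pts, full_matrices=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("inner-gyre bp centers are collinear; plane "
                            "normal is undefined")
    S = vt[2]
    if s_reference is not None:
        if S @ np.asarray(s_reference) < 0:
            S = -S
    else:
        # winding direction: sum of consecutive cross products about centroid
        w = np.cross(pts[:-1], pts[1:]).sum(axis=0)
        if S @ w < 0:
            S = -S
    y = np.cross(X, S)
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise GeometryError("dyad axis is parallel to the superhelical axis")
    Y = y / ny
    Z = np.cross(X, Y)
    return DyadFrame(origin=origin, X=X, Y=Y, Z=Z)


def build_dyad_frame(coords: np.ndarray, nuc: NucleosomeIndex,
                     s_reference: np.ndarray | None = None) -> DyadFrame:
    """Dyad frame of one trajectory frame (see module docstring for axes)."""
    ann = nuc.annotation
    centers = nuc.bp_centers(np.asarray(coords, dtype=float))
    return frame_from_bp_centers(centers, ann.inner_gyre, ann.dyad_bp,
                                 s_reference=s_reference)


# ---------------------------------------------------------------------------
# Arm vectors and opening angles
# ---------------------------------------------------------------------------

def arm_vector(coords: np.ndarray, nuc: NucleosomeIndex, arm: str,
               mode: str = "tls") -> np.ndarray:
    """Unit direction of an L-DNA arm, oriented inner (hinge side) -> terminal.

    ``mode="tls"`` fits a total-least-squares line through the arm bp centers;
    ``mode="endpoints"`` uses the normalized difference of the two end centers.
    """
    ann = nuc.annotation
    bp = ann.arm_range(arm)  # ordered inner -> terminal
    centers = nuc.bp_centers(np.asarray(coords, dtype=float))[bp - 1]
    span = centers[-1] - centers[0]
    nspan = np.linalg.norm(span)
    if nspan < 1e-9:
        raise GeometryError(f"arm {arm}: coincident bp centers")
    if mode == "endpoints" or len(centers) == 2:
        return span / nspan
    pts = centers - centers.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    d = vt[0]
    if d @ span < 0:
        d = -d
    return d / np.linalg.norm(d)


def compute_gamma(coords: np.ndarray, nuc: NucleosomeIndex,
                  dyad_frame: DyadFrame, arm: str,
                  arm_mode: str = "tls") -> tuple[float, float]:
    """Opening angles (gamma1, gamma2) in degrees for one arm.

    gamma1: signed angle (right-handed about +Y) between the XZ-projection of
    the arm vector and Z; gamma2: signed angle (right-handed about +Z)
    between the XY-projection and Y.  A degenerate projection (norm < 1e-9)
    yields NaN for that component rather than a fabricated value.
    """
    v = arm_vector(coords, nuc, arm, mode=arm_mode)
    vx, vy, vz = dyad_frame.to_local(v)
    g1 = np.degrees(np.arctan2(vx, vz)) if np.hypot(vx, vz) >= 1e-9 else np.nan
    g2 = np.degrees(np.arctan2(-vx, vy)) if np.hypot(vx, vy) >= 1e-9 else np.nan
    return float(g1), float(g2)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def compute_rg(coords: np.ndarray, selection: np.ndarray | None = None,
               masses: np.ndarray | None = None,
               mass_weighted: bool = True) -> float:
    """Radius of gyration sqrt(sum w |r - rbar|^2 / sum w) in Angstrom."""
    coords = np.asarray(coords, dtype=float)
    if selection is not None:
        selection = np.asarray(selection)
        if selection.size == 0:
            raise SelectionError("empty selection for radius of gyration")
        coords = coords[selection]
        if masses is not None:
            masses = np.asarray(masses)[selection] if np.asarray(masses).ndim else masses
    if coords.shape[0] == 0:
        raise SelectionError("empty selection for radius of gyration")
    if mass_weighted and masses is not None:
        w = np.asarray(masses, dtype=float)
    else:
        w = np.ones(coords.shape[0])
    ctr = (coords * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((coords - ctr) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


# ---------------------------------------------------------------------------
# Per-frame observable series
# ---------------------------------------------------------------------------

def breathing_series(traj: Trajectory, nuc: NucleosomeIndex,
                     stride: int = 1, mass_weighted: bool = True,
                     arm_mode: str = "tls") -> pd.DataFrame:
    """Per-frame gamma1/gamma2 for both arms and DNA Rg.

    Columns: frame, time_ps, gamma1_3p, gamma2_3p, gamma1_5p, gamma2_5p, rg.
    The superhelical-axis sign is carried from frame to frame for continuity.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    dna = nuc.dna_heavy_atoms()
    masses = nuc.structure.masses
    rows = []
    s_ref = None
    for f in range(0, traj.n_frames, stride):
        coords = traj.coords[f]
        frame = build_dyad_frame(coords, nuc, s_reference=s_ref)
        s_ref = _s_axis(frame)
        g1_3, g2_3 = compute_gamma(coords, nuc, frame, "3p", arm_mode)
        g1_5, g2_5 = compute_gamma(coords, nuc, frame, "5p", arm_mode)
        rg = compute_rg(coords, dna, masses, mass_weighted)
        rows.append((f, f * traj.frame_interval, g1_3, g2_3, g1_5, g2_5, rg))
    return pd.DataFrame(rows, columns=["frame", "time_ps", "gamma1_3p",
                                       "gamma2_3p", "gamma1_5p", "gamma2_5p",
                                       "rg"])


def _s_axis(frame: DyadFrame) -> np.ndarray:
    """Recover the superhelical axis direction S from the frame axes.

    Y = normalize(X x S) implies S lies in the plane orthogonal to Y;
    the component used for sign continuity is simply -Z projected back,
    i.e. S ~ cross(Y, X) up to the in-plane part -- for sign continuity only
    the hemisphere matters, so cross(Y, X) suffices.
    """
    return np.cross(frame.Y, frame.X)


# ---------------------------------------------------------------------------
# 2D gamma histograms
# ---------------------------------------------------------------------------

@dataclass
class GammaHistogram2D:
    """2D (gamma1, gamma2) occupancy histogram of one arm.

    ``occupied_area`` is the number of bins holding at least
    ``occupancy_min`` frames times the bin area (deg^2) -- the "area of the
    histogram" used to compare how much angle space an ensemble visits.
    """

    bin_width: float
    edges1: np.ndarray
    edges2: np.ndarray
    counts: np.ndarray
    occupancy_min: int
    occupied_area: float = field(init=False)
    mode_bin: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        occupied = int((self.counts >= self.occupancy_min).sum())
        self.occupied_area = occupied * self.bin_width ** 2
        i, j = np.unravel_index(int(np.argmax(self.counts)), self.counts.shape)
        self.mode_bin = (
            float(0.5 * (self.edges1[i] + self.edges1[i + 1])),
            float(0.5 * (self.edges2[j] + self.edges2[j + 1])),
        )

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def summary(self) -> dict:
        return {
            "bin_width_deg": self.bin_width,
            "n_frames": self.n_frames,
            "occupied_area_deg2": self.occupied_area,
            "mode_bin_deg": list(self.mode_bin),
        }


def gamma_histogram2d(series: pd.DataFrame, arm: str,
                      bin_width: float = 2.5,
                      occupancy_min: int = 1) -> GammaHistogram2D:
    """Bin the (gamma1, gamma2) angles of one arm on a grid aligned at
    multiples of ``bin_width``.  NaN (undefined-angle) frames are dropped."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    g1 = np.asarray(series[f"gamma1_{arm}"], dtype=float)
    g2 = np.asarray(series[f"gamma2_{arm}"], dtype=float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[ok], g2[ok]
    if g1.size == 0:
        raise ValueError("no frames with defined angles")

    def edges(vals: np.ndarray) -> np.ndarray:
        lo = np.floor(vals.min() / bin_width) * bin_width
        hi = np.ceil(vals.max() / bin_width) * bin_width
        if hi <= lo + 0.5 * bin_width:
            hi = lo + bin_width
        return np.arange(lo, hi + 0.5 * bin_width, bin_width)

    e1, e2 = edges(g1), edges(g2)
    counts, _, _ = np.histogram2d(g1, g2, bins=[e1, e2])
    return GammaHistogram2D(bin_width=float(bin_width), edges1=e1, edges2=e2,
                            counts=counts.astype(int),
                            occupancy_min=int(occupancy_min))
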