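"""Idealized nucleosome structures and breathing trajectories with ground truth.

The generator lays the DNA of a nucleosome on a superhelix (147 bp core by
default) with two straight B-DNA-like linker arms (11 bp each), a histone
"octamer" reduced to a ring of pseudo-atom beads split across eight chains,
and one disordered-tail bead chain per histone.  Motion is prescribed, not
simulated: each frame rigidly rotates a linker+outer-gyre arm about its hinge
by requested out-of-plane / in-plane angles, repositions tails according to a
mode schedule (bridging both gyres, collapsed on the dyad, or detached), and
adds Gaussian positional jitter.  The true per-frame opening angles, tail
modes and the dyad frame are returned as :class:`GroundTruth`, which is what
makes every downstream analysis stage testable without MD data.

Geometric defaults (superhelix radius 41.9 A, pitch 25.9 A/turn, 1.65 turns,
3.3 A rise per linker bp) are chosen to resemble canonical nucleosome
dimensions; they are generator parameters, nothing more.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DyadFrame, frame_from_bp_centers
from .structure_io import (NucleosomeAnnotation, NucleosomeIndex,
                           SelectionError, StructureModel, Trajectory,
                           annotate_nucleosome, element_mass)


class ParameterError(Exception):
    """Invalid generator specification or schedule."""


TAIL_MODES = ("bridge", "dyad_collapsed", "detached", "absent")

# human H3 residues 1-45; gives the tail beads real residue identities so the
# epigenetic-residue groups (R2, K4, ... R42) resolve by label
_H3_TAIL_SEQ = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGT"
_AA3 = {"A": "ALA", "R": "ARG", "T": "THR", "K": "LYS", "Q": "GLN",
        "S": "SER", "G": "GLY", "P": "PRO", "L": "LEU", "V": "VAL",
        "H": "HIS", "Y": "TYR"}

_DNA_BEAD_NAMES = ("C1'", "C2'", "C3'", "C4'", "C5'")


@dataclass
class TailSpec:
    length: int
    mode: str = "bridge"


def default_tails() -> dict[str, TailSpec]:
    return {
        "H3_3p": TailSpec(45, "bridge"),
        "H3_5p": TailSpec(45, "bridge"),
        "H4_3p": TailSpec(32, "dyad_collapsed"),
        "H4_5p": TailSpec(32, "dyad_collapsed"),
        "H2AC_3p": TailSpec(11, "bridge"),
        "H2AC_5p": TailSpec(11, "bridge"),
        "H2B_3p": TailSpec(33, "dyad_collapsed"),
        "H2B_5p": TailSpec(33, "dyad_collapsed"),
    }


@dataclass
class SyntheticSpec:
    """Parameters of the idealized nucleosome generator."""

    core_bp: int = 147
    linker_bp: int = 11
    superhelix_radius: float = 41.9      # A
    superhelix_pitch: float = 25.9       # A per superhelical turn
    wrap_turns: float = 1.65
    rise_per_bp: float = 3.3             # A, straight linker segments
    beads_per_nucleotide: int = 1
    core_ring_beads: int = 160
    core_ring_radius: float = 30.0       # A
    strand_half_offset: float = 5.0      # A, half the C1'-C1' separation
    arm_elevation_deg: float = 30.0      # closed-arm direction in the YZ plane
    detached_distance: float = 130.0     # A, detached-tail offset along -X
                                         # (the DNA ring's far edge sits
                                         # ~2R from the dyad on that side)
    jitter_sigma: float = 0.3            # A
    tails: dict[str, TailSpec] = field(default_factory=default_tails)
    seed: int = 0

    def validate(self) -> None:
        pos = {"core_bp": self.core_bp, "linker_bp": self.linker_bp,
               "superhelix_radius": self.superhelix_radius,
               "superhelix_pitch": self.superhelix_pitch,
               "wrap_turns": self.wrap_turns, "rise_per_bp": self.rise_per_bp,
               "beads_per_nucleotide": self.beads_per_nucleotide,
               "core_ring_beads": self.core_ring_beads,
               "core_ring_radius": self.core_ring_radius,
               "strand_half_offset": self.strand_half_offset}
        for name, v in pos.items():
            if v <= 0:
                raise ParameterError(f"{name} must be positive, got {v}")
        if self.beads_per_nucleotide > len(_DNA_BEAD_NAMES):
            raise ParameterError("at most 5 beads per nucleotide supported")
        if self.jitter_sigma < 0:
            raise ParameterError("jitter_sigma must be >= 0")
        for name, t in self.tails.items():
            if t.mode not in TAIL_MODES:
                raise ParameterError(f"tail {name}: unknown mode {t.mode!r}")
            if t.length <= 0:
                raise ParameterError(f"tail {name}: length must be positive")

    @property
    def n_bp(self) -> int:
        return self.core_bp + 2 * self.linker_bp

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tails"] = {k: {"length": t.length, "mode": t.mode}
                      for k, t in self.tails.items()}
        return d


@dataclass
class GroundTruth:
    """True per-frame angles and tail modes of a generated trajectory."""

    spec: dict
    seed: int
    frame_origin: np.ndarray
    frame_X: np.ndarray
    frame_Y: np.ndarray
    frame_Z: np.ndarray
    gamma: dict[str, np.ndarray]        # arm -> (n_frames, 2) degrees
    tail_modes: dict[str, list[str]]    # tail -> per-frame mode

    @property
    def n_frames(self) -> int:
        return next(iter(self.gamma.values())).shape[0]

    def dyad_frame(self) -> DyadFrame:
        return DyadFrame(origin=self.frame_origin, X=self.frame_X,
                         Y=self.frame_Y, Z=self.frame_Z)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec,
            "seed": self.seed,
            "frame": {"origin": self.frame_origin.tolist(),
                      "X": self.frame_X.tolist(), "Y": self.frame_Y.tolist(),
                      "Z": self.frame_Z.tolist()},
            "gamma": {k: v.tolist() for k, v in self.gamma.items()},
            "tail_modes": self.tail_modes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(spec=d["spec"], seed=d["seed"],
                   frame_origin=np.array(d["frame"]["origin"]),
                   frame_X=np.array(d["frame"]["X"]),
                   frame_Y=np.array(d["frame"]["Y"]),
                   frame_Z=np.array(d["frame"]["Z"]),
                   gamma={k: np.array(v) for k, v in d["gamma"].items()},
                   tail_modes=d["tail_modes"])


# ---------------------------------------------------------------------------
# Closed-structure construction
# ---------------------------------------------------------------------------

_HISTONE_CHAINS = [
    # chain, histone type, tail name, tail residues at N-terminus?
    ("A", "H3", "H3_3p", True),
    ("B", "H3", "H3_5p", True),
    ("C", "H4", "H4_3p", True),
    ("D", "H4", "H4_5p", True),
    ("E", "H2A", "H2AC_3p", False),
    ("F", "H2A", "H2AC_5p", False),
    ("G", "H2B", "H2B_3p", True),
    ("H", "H2B", "H2B_5p", True),
]


class _Blueprint:
    """Closed-state coordinates plus every index needed to animate them."""

    def __init__(self, spec: SyntheticSpec) -> None:
        spec.validate()
        self.spec = spec
        L = spec.n_bp
        nb = spec.beads_per_nucleotide
        R, pitch = spec.superhelix_radius, spec.superhelix_pitch

        # --- base-pair centers, tangents, strand offsets -------------------
        centers = np.zeros((L, 3))
        tangents = np.zeros((L, 3))
        offs = np.zeros((L, 3))
        core_lo = spec.linker_bp + 1              # first core bp (1-based)
        core_hi = spec.linker_bp + spec.core_bp   # last core bp
        jmid = (spec.core_bp - 1) / 2.0
        for j in range(spec.core_bp):
            phi = (j - jmid) / (spec.core_bp - 1) * spec.wrap_turns * 2 * np.pi
            c, s = np.cos(phi), np.sin(phi)
            i = core_lo + j - 1
            centers[i] = (R * c, R * s, pitch * phi / (2 * np.pi))
            t = np.array([-R * s, R * c, pitch / (2 * np.pi)])
            tangents[i] = t / np.linalg.norm(t)
            u = np.cross(tangents[i], np.array([c, s, 0.0]))
            offs[i] = u / np.linalg.norm(u)

        # dyad frame from the core-only centers (linkers are outside the
        # inner gyre, so they do not enter the frame construction)
        outer = 40 if L >= 82 else max(1, L // 4)
        inner_bp = np.arange(outer + 1, L - outer + 1)
        dyad_bp = (L + 1) // 2
        self.frame = frame_from_bp_centers(centers, inner_bp, dyad_bp)
        self.inner_bp, self.outer_bp_count, self.dyad_bp = inner_bp, outer, dyad_bp

        # closed linker arms: straight, along a direction with zero X
        # component in the dyad frame, so both opening angles are 0 by
        # construction
        th = np.radians(spec.arm_elevation_deg)
        u0 = np.sin(th) * self.frame.Y + np.cos(th) * self.frame.Z
        self.u0 = u0 / np.linalg.norm(u0)
        for k in range(1, spec.linker_bp + 1):
            # 3' arm extends from the last core bp
            i3 = core_hi + k - 1
            centers[i3] = centers[core_hi - 1] + k * spec.rise_per_bp * self.u0
            tangents[i3] = self.u0
            offs[i3] = offs[core_hi - 1]
            # 5' arm extends from the first core bp
            i5 = core_lo - k - 1
            centers[i5] = centers[core_lo - 1] + k * spec.rise_per_bp * self.u0
            tangents[i5] = self.u0
            offs[i5] = offs[core_lo - 1]
        self.bp_centers0 = centers

        # --- assemble atom arrays ------------------------------------------
        names, resnames, resids, chains, elements = [], [], [], [], []
        xyz: list[np.ndarray] = []

        def add(name, resname, resid, chain, pos, element="C"):
            names.append(name); resnames.append(resname); resids.append(resid)
            chains.append(chain); elements.append(element)
            xyz.append(np.asarray(pos, dtype=float))

        h = spec.strand_half_offset
        # sense strand (chain I): residue i == bp i
        self.sense_beads = np.zeros((L, nb), dtype=int)
        for i in range(L):
            base = centers[i] + h * offs[i]
            for k in range(nb):
                self.sense_beads[i, k] = len(xyz)
                add(_DNA_BEAD_NAMES[k], "DA", i + 1, "I",
                    base + 0.8 * k * tangents[i])
        # antisense strand (chain J): residue r pairs bp L+1-r
        self.anti_beads = np.zeros((L, nb), dtype=int)
        for r in range(1, L + 1):
            i = L - r  # 0-based bp index of the partner
            base = centers[i] - h * offs[i]
            for k in range(nb):
                self.anti_beads[i, k] = len(xyz)
                add(_DNA_BEAD_NAMES[k], "DT", r, "J",
                    base + 0.8 * k * tangents[i])

        # histone core ring, split over the eight chains
        n_ring = spec.core_ring_beads - spec.core_ring_beads % 8
        per_chain = n_ring // 8
        ring_pos = [
            spec.core_ring_radius * np.array([np.cos(a), np.sin(a), 0.0])
            for a in np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
        ]
        self.tail_atoms: dict[str, np.ndarray] = {}
        self.tail_chain: dict[str, str] = {}
        self.tail_ranges: dict[str, tuple[int, int]] = {}
        ring_cursor = 0
        for ci, (chain, htype, tail_name, n_term) in enumerate(_HISTONE_CHAINS):
            tail = spec.tails.get(tail_name)
            tlen = tail.length if tail and tail.mode != "absent" else 0
            if htype == "H2A":
                ring_start, tail_start = 19, 119
            else:
                ring_start = tlen + 1 if n_term else 1
                tail_start = 1
            tail_idx = []

            def add_tail_beads():
                for m in range(tlen):
                    if htype == "H3" and m < len(_H3_TAIL_SEQ):
                        resname = _AA3[_H3_TAIL_SEQ[m]]
                    else:
                        resname = "GLY"
                    tail_idx.append(len(xyz))
                    add("CA", resname, tail_start + m, chain, np.zeros(3))

            if n_term and tlen:
                add_tail_beads()
            for p in range(per_chain):
                add("CA", "ALA", ring_start + p, chain, ring_pos[ring_cursor])
                ring_cursor += 1
            if not n_term and tlen:  # H2A C-terminal tail
                add_tail_beads()
            if tlen:
                self.tail_atoms[tail_name] = np.array(tail_idx)
                self.tail_chain[tail_name] = chain
                self.tail_ranges[tail_name] = (tail_start, tail_start + tlen - 1)

        elements = np.array(elements)
        self.structure_arrays = dict(
            atom_names=np.array(names),
            residue_names=np.array(resnames),
            residue_indices=np.array(resids, dtype=int),
            chain_ids=np.array(chains),
            elements=elements,
            masses=np.array([element_mass(e) for e in elements]),
        )
        self.closed = np.array(xyz)
        self.n_atoms = len(xyz)

        # --- arm bookkeeping ------------------------------------------------
        nbp_out = self.outer_bp_count
        self.arm_bp = {
            "5p": np.arange(1, nbp_out + 1),
            "3p": np.arange(L - nbp_out + 1, L + 1),
        }
        self.hinge_bp = {"5p": nbp_out, "3p": L - nbp_out + 1}
        self.arm_atoms = {
            arm: np.concatenate(
                [self.sense_beads[bp - 1].ravel() for bp in bps]
                + [self.anti_beads[bp - 1].ravel() for bp in bps])
            for arm, bps in self.arm_bp.items()
        }
        self.hinge_point = {
            arm: self.bp_centers0[self.hinge_bp[arm] - 1].copy()
            for arm in ("3p", "5p")
        }

        # tail placement targets (bp indices)
        self.bridge_outer_bp = {"5p": nbp_out // 2, "3p": L - nbp_out // 2 + 1}
        self.bridge_inner_bp = {}
        for arm in ("3p", "5p"):
            tgt = self.bp_centers0[self.bridge_outer_bp[arm] - 1]
            d = np.linalg.norm(
                self.bp_centers0[self.inner_bp - 1] - tgt, axis=1)
            self.bridge_inner_bp[arm] = int(self.inner_bp[np.argmin(d)])
        half = 4
        self.dyad_segment = {
            "5p": np.arange(dyad_bp - half, dyad_bp + 1),
            "3p": np.arange(dyad_bp, dyad_bp + half + 1),
        }
        self.dna_bead_idx = np.concatenate(
            [self.sense_beads.ravel(), self.anti_beads.ravel()])
        self.ldna_bp = np.concatenate(
            [np.arange(1, 16), np.arange(L - 14, L + 1)])
        self.ldna_beads = np.concatenate(
            [self.sense_beads[self.ldna_bp - 1].ravel(),
             self.anti_beads[self.ldna_bp - 1].ravel()])

    # -- per-frame assembly ------------------------------------------------
    def frame_coords(self, angles: dict[str, tuple[float, float]],
                     modes: dict[str, str]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Closed coords -> rotated arms -> repositioned tails (no jitter).

        Returns the coordinates and the true arm directions after rotation.
        """
        coords = self.closed.copy()
        fr = self.frame
        true_dirs = {}
        for arm in ("3p", "5p"):
            a_out, a_in = angles.get(arm, (0.0, 0.0))
            # positive out-of-plane tilts the arm toward +X (gamma1 = +a),
            # positive in-plane toward -X (gamma2 = +a): the two angles open
            # in opposite X directions, mirroring their sign conventions
            Rm = (_axis_rotation(fr.Z, np.radians(a_in))
                  @ _axis_rotation(fr.Y, np.radians(a_out)))
            true_dirs[arm] = Rm @ self.u0
            if abs(a_out) < 1e-12 and abs(a_in) < 1e-12:
                continue
            idx = self.arm_atoms[arm]
            p = self.hinge_point[arm]
            coords[idx] = (coords[idx] - p) @ Rm.T + p

        for tail_name, mode in modes.items():
            if mode == "absent":
                continue
            idx = self.tail_atoms.get(tail_name)
            if idx is None:
                continue
            arm = "3p" if tail_name.endswith("3p") else "5p"
            coords[idx] = self._place_tail(coords, tail_name, idx, arm, mode)
        return coords, true_dirs

    def _place_tail(self, coords: np.ndarray, tail_name: str,
                    idx: np.ndarray, arm: str, mode: str) -> np.ndarray:
        spec, fr = self.spec, self.frame
        n = idx.size
        t_order = list(self.tail_atoms)
        t_idx = t_order.index(tail_name)
        if mode == "bridge":
            p_out = coords[self.sense_beads[self.bridge_outer_bp[arm] - 1, 0]]
            p_in = coords[self.sense_beads[self.bridge_inner_bp[arm] - 1, 0]]
            d = p_in - p_out
            nd = np.linalg.norm(d)
            if nd < 6.0:
                raise ParameterError("bridge targets too close for placement")
            u = d / nd
            a, b = p_out + 1.5 * u, p_in - 1.5 * u
            w = np.linspace(0.0, 1.0, n)[:, None]
            return a + w * (b - a)
        if mode == "dyad_collapsed":
            seg = self.dyad_segment[arm]
            S = np.cross(fr.Y, fr.X)
            psi = np.radians(-40 + 25 * (t_idx % 8))
            off = 2.5 * (np.cos(psi) * fr.X + np.sin(psi) * S)
            pos = np.empty((n, 3))
            for m in range(n):
                bead = self.sense_beads[seg[m % seg.size] - 1, 0]
                pos[m] = coords[bead] + off + (m // seg.size) * 0.6 * fr.X
            return pos
        if mode == "detached":
            S = np.cross(fr.Y, fr.X)
            center = (fr.origin - spec.detached_distance * fr.X
                      + (t_idx - 3.5) * 8.0 * S)
            # beads march further away from the nucleosome, never toward it
            pos = center - np.arange(n)[:, None] * 1.0 * fr.X
            return pos
        raise ParameterError(f"unknown tail mode {mode!r}")


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about an arbitrary unit axis (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * K
            + (1 - np.cos(angle_rad)) * (K @ K))


def _gamma_of(v: np.ndarray, fr: DyadFrame) -> tuple[float, float]:
    vx, vy, vz = fr.to_local(v)
    return (float(np.degrees(np.arctan2(vx, vz))),
            float(np.degrees(np.arctan2(-vx, vy))))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def make_ideal_nucleosome(spec: SyntheticSpec | None = None
                          ) -> tuple[StructureModel, GroundTruth]:
    """Closed, jitter-free idealized nucleosome with its ground-truth frame."""
    spec = spec or SyntheticSpec()
    bp = _Blueprint(spec)
    modes = {k: t.mode for k, t in spec.tails.items()}
    coords, dirs = bp.frame_coords({}, modes)
    structure = StructureModel(coords=coords[None], **bp.structure_arrays)
    fr = bp.frame
    gamma = {arm: np.array([_gamma_of(dirs[arm], fr)]) for arm in ("3p", "5p")}
    truth = GroundTruth(spec=spec.to_dict(), seed=spec.seed,
                        frame_origin=fr.origin, frame_X=fr.X, frame_Y=fr.Y,
                        frame_Z=fr.Z, gamma=gamma,
                        tail_modes={k: [m] for k, m in modes.items()})
    return structure, truth


def make_breathing_trajectory(
        spec: SyntheticSpec | None = None,
        angle_series: dict[str, np.ndarray] | None = None,
        tail_schedule: dict[str, list[str]] | None = None,
        seed: int | None = None,
        frame_interval: float = 20.0,
) -> tuple[Trajectory, GroundTruth]:
    """Prescribed-motion trajectory with per-frame ground truth.

    ``angle_series`` maps arm ("3p"/"5p") to an (n_frames, 2) array of
    (out-of-plane, in-plane) angles in degrees, each within (-90, 90);
    ``tail_schedule`` maps tail name to a per-frame list of modes.  Tails not
    scheduled keep their spec mode; arms without a series stay closed.
    """
    spec = spec or SyntheticSpec()
    bp = _Blueprint(spec)
    if not angle_series:
        raise ParameterError("angle_series must prescribe at least one arm")
    n_frames = None
    for arm, arr in angle_series.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ParameterError(f"angle series for arm {arm} must be (n, 2)")
        if np.any(np.abs(arr) >= 90.0):
            raise ParameterError("prescribed angles must lie in (-90, 90)")
        if n_frames is None:
            n_frames = arr.shape[0]
        elif arr.shape[0] != n_frames:
            raise ParameterError("angle series lengths differ between arms")
        angle_series[arm] = arr
    base_modes = {k: t.mode for k, t in spec.tails.items()}
    schedule: dict[str, list[str]] = {}
    for name, mode in base_modes.items():
        seq = (tail_schedule or {}).get(name)
        if seq is None:
            seq = [mode] * n_frames
        if len(seq) != n_frames:
            raise ParameterError(
                f"tail schedule for {name} has {len(seq)} entries, "
                f"expected {n_frames}")
        if mode == "absent" and any(m != "absent" for m in seq):
            raise ParameterError(f"tail {name} is absent; cannot schedule it")
        if mode != "absent" and any(m == "absent" for m in seq):
            raise ParameterError(
                f"tail {name} exists; 'absent' cannot appear in its schedule")
        for m in seq:
            if m not in TAIL_MODES:
                raise ParameterError(f"unknown tail mode {m!r} in schedule")
        schedule[name] = list(seq)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = np.empty((n_frames, bp.n_atoms, 3))
    gamma = {arm: np.zeros((n_frames, 2)) for arm in ("3p", "5p")}
    for f in range(n_frames):
        angles = {arm: tuple(arr[f]) for arm, arr in angle_series.items()}
        modes = {name: seq[f] for name, seq in schedule.items()}
        coords, dirs = bp.frame_coords(angles, modes)
        _check_tail_clearance(bp, coords, modes)
        for arm in ("3p", "5p"):
            gamma[arm][f] = _gamma_of(dirs[arm], bp.frame)
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma,
                                         size=coords.shape)
        frames[f] = coords

    topo = StructureModel(coords=bp.closed[None], **bp.structure_arrays)
    traj = Trajectory(topology=topo, coords=frames,
                      frame_interval=frame_interval)
    fr = bp.frame
    truth = GroundTruth(spec=spec.to_dict(),
                        seed=int(spec.seed if seed is None else seed),
                        frame_origin=fr.origin, frame_X=fr.X, frame_Y=fr.Y,
                        frame_Z=fr.Z, gamma=gamma, tail_modes=schedule)
    return traj, truth


def _check_tail_clearance(bp: _Blueprint, coords: np.ndarray,
                          modes: dict[str, str]) -> None:
    """Assert the mode guarantees before jitter is applied."""
    dna = coords[bp.dna_bead_idx]
    ldna = coords[bp.ldna_beads]
    for name, mode in modes.items():
        idx = bp.tail_atoms.get(name)
        if idx is None:
            continue
        tail = coords[idx]
        if mode == "detached":
            dmin = _min_dist(tail, dna)
            if dmin < 12.0:
                raise ParameterError(
                    f"detached tail {name} only {dmin:.1f} A from DNA")
        elif mode == "dyad_collapsed":
            dmin = _min_dist(tail, ldna)
            if dmin < 9.0:
                raise ParameterError(
                    f"dyad-collapsed tail {name} only {dmin:.1f} A from L-DNA")


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.min(d))


def tailless_variant(structure: StructureModel,
                     annotation: NucleosomeAnnotation) -> StructureModel:
    """Remove every atom of every annotated tail residue (idempotent)."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    for t in annotation.tails:
        lo, hi = t.residue_range
        mask &= ~((structure.chain_ids == t.chain_id)
                  & (structure.residue_indices >= lo)
                  & (structure.residue_indices <= hi))
    return structure.subset(np.flatnonzero(mask))


def synthetic_profile(spec: SyntheticSpec | None = None,
                      include_tails: bool = True) -> dict:
    """Annotation config matching the generator's chain/residue layout."""
    spec = spec or SyntheticSpec()
    bp = _Blueprint(spec)
    histones = {}
    for chain, htype, tail_name, _ in _HISTONE_CHAINS:
        tails = []
        if include_tails and tail_name in bp.tail_ranges:
            arm = "3p" if tail_name.endswith("3p") else "5p"
            lo, hi = bp.tail_ranges[tail_name]
            tails.append({"name": tail_name, "range": [lo, hi], "arm": arm})
        histones[chain] = {"type": htype, "tails": tails}
    return {
        "name": "synthetic" if include_tails else "synthetic-tailless",
        "dna_chains": ["I", "J"],
        "dyad_bp": bp.dyad_bp,
        "arm_bp": spec.linker_bp,
        "histones": histones,
    }


def annotate_synthetic(structure: StructureModel,
                       spec: SyntheticSpec | None = None) -> NucleosomeIndex:
    """Convenience: annotation + atom index for a generated structure."""
    spec = spec or SyntheticSpec()
    ann = annotate_nucleosome(structure, synthetic_profile(spec))
    return NucleosomeIndex(structure, ann)


# ---------------------------------------------------------------------------
# Canned experiment: tail release coupled to arm opening
# ---------------------------------------------------------------------------

def coupled_opening_scenario(
        n_frames: int = 240, switch_frame: int = 120, lag: int = 12,
        open_angles: tuple[float, float] = (35.0, 35.0),
        arm: str = "3p", seed: int = 0,
        spec: SyntheticSpec | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Trajectory where H3/H2AC tail detachment precedes arm opening.

    The tails on the opening arm switch from bridging to detached at
    ``switch_frame - lag``; the arm opens (step to ``open_angles``) at
    ``switch_frame``.  This is the mechanism probe used to check that the
    cluster cross-tabulation recovers the coupling between tail release and
    DNA opening.
    """
    if not 0 < switch_frame < n_frames:
        raise ParameterError("switch_frame must lie inside the trajectory")
    if not 0 <= lag <= switch_frame:
        raise ParameterError("lag must be within [0, switch_frame]")
    spec = spec or SyntheticSpec(seed=seed)
    angles = np.zeros((n_frames, 2))
    angles[switch_frame:] = open_angles
    series = {arm: angles, ("5p" if arm == "3p" else "3p"): np.zeros((n_frames, 2))}
    release = switch_frame - lag
    schedule = {}
    for name in (f"H3_{arm}", f"H2AC_{arm}"):
        schedule[name] = ["bridge"] * release + ["detached"] * (n_frames - release)
    return make_breathing_trajectory(spec, series, schedule, seed=seed)
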