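"""Structure/trajectory I/O and nucleosome role annotation.

Containers are thin numpy-backed records.  PDB files are read and written
through :mod:`biotite`; DCD trajectories through :mod:`MDAnalysis`.  The
:class:`NucleosomeAnnotation` maps chains, residues and base pairs onto the
roles every downstream stage consumes: histone core vs. tail, inner vs. outer
DNA gyre, linker DNA (L-DNA), and the dyad reference segments.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class StructureIOError(Exception):
    """Unreadable or empty structure/trajectory file."""


class TopologyError(Exception):
    """Trajectory does not match its topology."""


class AnnotationError(Exception):
    """Inconsistent nucleosome annotation."""


class SelectionError(Exception):
    """An atom selection resolved to nothing (or to something invalid)."""


# ---------------------------------------------------------------------------
# Element and mass inference
# ---------------------------------------------------------------------------

# Names that are genuinely two-letter elements when they appear verbatim as a
# full atom name (ions, metals).  "CA" in a protein residue is C-alpha, not
# calcium, so the table is only consulted for residues that look like ions.
_TWO_LETTER = {
    "CL": "Cl", "BR": "Br", "NA": "Na", "MG": "Mg", "ZN": "Zn",
    "FE": "Fe", "MN": "Mn", "CU": "Cu", "NI": "Ni", "CO": "Co",
}
_ION_RESIDUES = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "NI", "CO",
                 "CA", "K", "CAL", "SOD", "POT", "CLA"}

_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "Cl": 35.45, "Mg": 24.305, "K": 39.098,
    "Ca": 40.078, "Zn": 65.38, "Fe": 55.845, "Mn": 54.938,
}


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the element from an atom name (for PDBs lacking element columns).

    Rule: first alphabetic character of the atom name, with a two-letter
    override for ion-like residues.
    """
    name = atom_name.strip().upper()
    if residue_name.strip().upper() in _ION_RESIDUES and name in _TWO_LETTER:
        return _TWO_LETTER[name]
    if name in _TWO_LETTER and not any(ch.isdigit() for ch in name):
        # bare ion record without residue context (e.g. atom "CL" in "CL")
        pass
    for ch in name:
        if ch.isalpha():
            return ch.upper() if len(ch) == 1 else ch
    raise StructureIOError(f"cannot infer element for atom name {atom_name!r}")


def element_mass(element: str) -> float:
    el = element.capitalize() if len(element) > 1 else element.upper()
    return _MASS.get(el, 12.011)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """A molecular structure: per-atom annotations plus one or more models.

    ``coords`` has shape ``(n_models, n_atoms, 3)`` in Angstrom.  Residue
    indices are 1-based within each chain and non-decreasing.
    """

    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_indices: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if not np.all(np.isfinite(self.coords)):
            raise StructureIOError("non-finite coordinates in structure")
        for cid in np.unique(self.chain_ids):
            resids = self.residue_indices[self.chain_ids == cid]
            if np.any(np.diff(resids) < 0):
                raise StructureIOError(
                    f"residue indices decrease within chain {cid!r}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def coordinates(self) -> np.ndarray:
        """Coordinates of the first model, shape (n_atoms, 3)."""
        return self.coords[0]

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return np.array([e.upper() != "H" for e in self.elements])

    def atom_indices(self, chain_id: str,
                     residue_range: tuple[int, int] | None = None) -> np.ndarray:
        mask = self.chain_ids == chain_id
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self.residue_indices >= lo) & (self.residue_indices <= hi)
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))

    def subset(self, indices: np.ndarray) -> "StructureModel":
        indices = np.asarray(indices)
        return StructureModel(
            atom_names=self.atom_names[indices],
            residue_names=self.residue_names[indices],
            residue_indices=self.residue_indices[indices],
            chain_ids=self.chain_ids[indices],
            elements=self.elements[indices],
            masses=self.masses[indices],
            coords=self.coords[:, indices],
        )


@dataclass
class Trajectory:
    """Frames sharing the topology's atom count and ordering.

    ``coords``: (n_frames, n_atoms, 3) in Angstrom; ``frame_interval`` in ps.
    """

    topology: StructureModel
    coords: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}")
        if self.frame_interval <= 0:
            raise TopologyError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# PDB read/write (biotite)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read a (possibly multi-model) PDB file into a :class:`StructureModel`."""
    if format.lower() != "pdb":
        raise StructureIOError(f"unsupported structure format {format!r}")
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
    except (OSError, ValueError) as exc:
        raise StructureIOError(f"cannot read PDB file {path}: {exc}") from exc
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises several types on bad records
        raise StructureIOError(f"cannot parse PDB file {path}: {exc}") from exc
    arr0 = stack[0] if stack.stack_depth() else None
    if arr0 is None or stack.array_length() == 0:
        raise StructureIOError(f"no ATOM records in {path}")

    elements = []
    for name, res, el in zip(arr0.atom_name, arr0.res_name, arr0.element):
        el = el.strip()
        elements.append(el.capitalize() if el else infer_element(name, res))
    elements = np.array(elements)
    return StructureModel(
        atom_names=np.array(arr0.atom_name),
        residue_names=np.array(arr0.res_name),
        residue_indices=np.array(arr0.res_id, dtype=int),
        chain_ids=np.array(arr0.chain_id),
        elements=elements,
        masses=np.array([element_mass(e) for e in elements]),
        coords=np.array(stack.coord, dtype=float),
    )


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write all models of a structure to a PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_atoms
    stack = struc.AtomArrayStack(structure.n_models, n)
    stack.coord = np.asarray(structure.coords, dtype=np.float32)
    stack.chain_id = structure.chain_ids.astype("U4")
    stack.res_id = structure.residue_indices.astype(int)
    stack.res_name = structure.residue_names.astype("U5")
    stack.atom_name = structure.atom_names.astype("U6")
    stack.element = np.array([e.upper() for e in structure.elements], dtype="U2")
    stack.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    try:
        pdb.write(str(path))
    except OSError as exc:
        raise StructureIOError(f"cannot write PDB file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Trajectory read/write (MDAnalysis for DCD; multi-model PDB fallback)
# ---------------------------------------------------------------------------

def read_trajectory(topology: StructureModel, path: str | Path,
                    format: str = "dcd", frame_interval: float = 1.0) -> Trajectory:
    """Read a DCD (or multi-model PDB) trajectory against a topology."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "dcd":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            try:
                u.load_new(str(path))
            except (OSError, ValueError) as exc:
                if "number of atoms" in str(exc).lower():
                    raise TopologyError(str(exc)) from exc
                raise StructureIOError(f"cannot read DCD {path}: {exc}") from exc
            if u.trajectory.n_atoms != topology.n_atoms:
                raise TopologyError(
                    f"DCD has {u.trajectory.n_atoms} atoms, topology has "
                    f"{topology.n_atoms}")
            frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                              dtype=float)
    elif fmt in ("pdb", "multimodel-pdb"):
        model = read_structure(path)
        if model.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"PDB has {model.n_atoms} atoms, topology has {topology.n_atoms}")
        frames = model.coords
    else:
        raise StructureIOError(f"unsupported trajectory format {format!r}")
    return Trajectory(topology=topology, coords=frames,
                      frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "dcd") -> None:
    path = Path(path)
    fmt = format.lower()
    if fmt == "dcd":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.coordinates.DCD.DCDWriter(str(path),
                                               traj.topology.n_atoms) as w:
                u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
                for frame in traj.coords:
                    u.atoms.positions = frame.astype(np.float32)
                    w.write(u.atoms)
    elif fmt in ("pdb", "multimodel-pdb"):
        write_structure(traj.topology.with_coords(traj.coords), path)
    else:
        raise StructureIOError(f"unsupported trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Observable series CSV
# ---------------------------------------------------------------------------

def write_series_csv(series: pd.DataFrame, path: str | Path) -> None:
    """Write a per-frame observable table (one row per frame) to CSV.

    Values are written at full precision (lossless round trip well beyond
    6 significant digits).
    """
    if series is None or len(series) == 0:
        raise ValueError("cannot write an empty observable series")
    try:
        series.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise StructureIOError(f"cannot write CSV {path}: {exc}") from exc


def read_series_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise StructureIOError(f"cannot read CSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Species profiles and annotation
# ---------------------------------------------------------------------------

def get_species_profile(name: str) -> dict:
    """Load a shipped tail-definition profile ('human', 'drosophila', 'tailless')."""
    res = importlib.resources.files("nucbreathe") / "profiles" / f"{name}.yaml"
    if not res.is_file():
        raise AnnotationError(f"unknown species profile {name!r}")
    return yaml.safe_load(res.read_text())


@dataclass
class TailDef:
    """One histone tail: owning chain, residue range (inclusive), arm side."""

    name: str
    chain_id: str
    residue_range: tuple[int, int]
    arm: str  # "3p" or "5p"


@dataclass
class NucleosomeAnnotation:
    """Role map for one nucleosome.

    Base pairs are indexed 1..L along the sense strand 5'->3'; the antisense
    residue of bp *i* is residue ``L+1-i`` of the complementary chain.  The
    outer gyres are the terminal ``outer_bp`` (default 40) base pairs at each
    end, the inner gyre is everything in between; the L-DNA reference segments
    are the terminal ``ldna_bp`` (default 15) base pairs; each side's dyad
    segment is the dyad bp plus ``dyad_half`` (default 4) bp toward that arm.
    """

    species_profile: str
    sense_chain: str
    anti_chain: str
    n_bp: int
    dyad_bp: int
    histone_chains: dict[str, str]          # chain id -> histone type
    tails: list[TailDef]
    outer_bp: int = 40
    ldna_bp: int = 15
    dyad_half: int = 4
    arm_bp: int = 15                        # bp per arm used for v3/v5

    # --- derived bp index sets (1-based, inclusive ranges) ---
    def _validate(self) -> None:
        if self.n_bp < 2 * self.outer_bp + 2:
            raise AnnotationError(
                f"{self.n_bp} bp too short for two {self.outer_bp} bp outer gyres")
        if abs(self.dyad_bp - (self.n_bp + 1) / 2) > 1.0:
            raise AnnotationError(
                f"dyad bp {self.dyad_bp} is not within 1 bp of the midpoint "
                f"of {self.n_bp} bp")
        if self.arm_bp < 2:
            raise AnnotationError("arm definition needs at least 2 bp")

    def __post_init__(self) -> None:
        self._validate()

    @property
    def outer_gyre_5p(self) -> np.ndarray:
        return np.arange(1, self.outer_bp + 1)

    @property
    def outer_gyre_3p(self) -> np.ndarray:
        return np.arange(self.n_bp - self.outer_bp + 1, self.n_bp + 1)

    @property
    def outer_gyres(self) -> np.ndarray:
        return np.concatenate([self.outer_gyre_5p, self.outer_gyre_3p])

    @property
    def inner_gyre(self) -> np.ndarray:
        return np.arange(self.outer_bp + 1, self.n_bp - self.outer_bp + 1)

    @property
    def ldna_5p(self) -> np.ndarray:
        return np.arange(1, self.ldna_bp + 1)

    @property
    def ldna_3p(self) -> np.ndarray:
        return np.arange(self.n_bp - self.ldna_bp + 1, self.n_bp + 1)

    @property
    def dyad_segment_5p(self) -> np.ndarray:
        return np.arange(self.dyad_bp - self.dyad_half, self.dyad_bp + 1)

    @property
    def dyad_segment_3p(self) -> np.ndarray:
        return np.arange(self.dyad_bp, self.dyad_bp + self.dyad_half + 1)

    @property
    def arm_range_5p(self) -> np.ndarray:
        """bp of the 5' arm, ordered inner (hinge side) -> terminal."""
        return np.arange(self.arm_bp, 0, -1)

    @property
    def arm_range_3p(self) -> np.ndarray:
        return np.arange(self.n_bp - self.arm_bp + 1, self.n_bp + 1)

    def ldna(self, arm: str) -> np.ndarray:
        return self.ldna_3p if arm == "3p" else self.ldna_5p

    def dyad_segment(self, arm: str) -> np.ndarray:
        return self.dyad_segment_3p if arm == "3p" else self.dyad_segment_5p

    def arm_range(self, arm: str) -> np.ndarray:
        if arm not in ("3p", "5p"):
            raise AnnotationError(f"unknown arm {arm!r}")
        return self.arm_range_3p if arm == "3p" else self.arm_range_5p

    def tail(self, name: str) -> TailDef:
        for t in self.tails:
            if t.name == name:
                return t
        raise SelectionError(f"no tail named {name!r} in annotation "
                             f"(have {[t.name for t in self.tails]})")

    @property
    def tail_names(self) -> list[str]:
        return [t.name for t in self.tails]


def annotate_nucleosome(structure: StructureModel, profile: dict) -> NucleosomeAnnotation:
    """Build a :class:`NucleosomeAnnotation` from a structure and a config.

    ``profile`` keys: ``name``, ``dna_chains`` (sense, antisense),
    ``histones`` mapping chain id -> ``{type, tails: [{name, range, arm}]}``,
    optional ``dyad_bp``, ``outer_bp``, ``ldna_bp``, ``dyad_half``, ``arm_bp``.
    Tail residue ranges may be given directly or come from a species profile
    via ``species`` ("human"/"drosophila"/"tailless").
    """
    dna = profile.get("dna_chains")
    if not dna or len(dna) != 2:
        raise AnnotationError("profile must name exactly two DNA chains")
    sense, anti = dna
    n_sense = len(np.unique(structure.residue_indices[structure.chain_ids == sense]))
    n_anti = len(np.unique(structure.residue_indices[structure.chain_ids == anti]))
    if n_sense == 0:
        raise AnnotationError(f"DNA chain {sense!r} not found in structure")
    if n_sense != n_anti:
        raise AnnotationError(
            f"DNA strands have unequal lengths ({n_sense} vs {n_anti})")
    n_bp = int(profile.get("n_bp", n_sense))
    if n_bp != n_sense:
        raise AnnotationError(
            f"profile says {n_bp} bp but structure has {n_sense}")

    dyad_bp = int(profile.get("dyad_bp", (n_bp + 1) // 2))

    species = profile.get("species")
    species_tails = None
    if species:
        species_tails = get_species_profile(species).get("tails", {})

    histone_chains: dict[str, str] = {}
    tails: list[TailDef] = []
    for chain_id, info in (profile.get("histones") or {}).items():
        htype = info["type"]
        histone_chains[chain_id] = htype
        chain_resids = structure.residue_indices[structure.chain_ids == chain_id]
        if chain_resids.size == 0:
            raise AnnotationError(f"histone chain {chain_id!r} not in structure")
        lo, hi = int(chain_resids.min()), int(chain_resids.max())
        tail_specs = info.get("tails")
        if tail_specs is None and species_tails is not None:
            arm = info.get("arm", "3p")
            tail_specs = [
                {"name": f"{tag}_{arm}", "range": rng, "arm": arm}
                for tag, rng in _species_tail_specs(htype, species_tails)
            ]
        for t in tail_specs or []:
            s, e = int(t["range"][0]), int(t["range"][1])
            if s < lo or e > hi:
                raise AnnotationError(
                    f"tail {t.get('name')} range {s}-{e} outside chain "
                    f"{chain_id!r} span {lo}-{hi}")
            tails.append(TailDef(name=t["name"], chain_id=chain_id,
                                 residue_range=(s, e), arm=t.get("arm", "3p")))

    return NucleosomeAnnotation(
        species_profile=profile.get("name", species or "custom"),
        sense_chain=sense,
        anti_chain=anti,
        n_bp=n_bp,
        dyad_bp=dyad_bp,
        histone_chains=histone_chains,
        tails=tails,
        outer_bp=int(profile.get("outer_bp", 40)),
        ldna_bp=int(profile.get("ldna_bp", 15)),
        dyad_half=int(profile.get("dyad_half", 4)),
        arm_bp=int(profile.get("arm_bp", 15)),
    )


def _species_tail_specs(htype: str, species_tails: dict) -> list[tuple[str, list]]:
    out = []
    for entry in species_tails.get(htype, []):
        out.append((entry["tag"], entry["range"]))
    return out


# ---------------------------------------------------------------------------
# Atom-level index resolution
# ---------------------------------------------------------------------------

class NucleosomeIndex:
    """Precomputed atom-index views of a structure under an annotation.

    Resolves base-pair index sets to atom indices, picks the C1'-equivalent
    reference atom of every nucleotide, and exposes the heavy-atom selections
    the geometry/interaction stages operate on.
    """

    _REF_NAMES = ("C1'", "C1*", "CA")

    def __init__(self, structure: StructureModel,
                 annotation: NucleosomeAnnotation) -> None:
        self.structure = structure
        self.annotation = annotation
        L = annotation.n_bp

        self._sense_res_atoms: dict[int, np.ndarray] = {}
        self._anti_res_atoms: dict[int, np.ndarray] = {}
        for cid, store in ((annotation.sense_chain, self._sense_res_atoms),
                           (annotation.anti_chain, self._anti_res_atoms)):
            mask = structure.chain_ids == cid
            idx = np.flatnonzero(mask)
            for r in np.unique(structure.residue_indices[mask]):
                store[int(r)] = idx[structure.residue_indices[mask] == r]

        def ref_atom(atoms: np.ndarray) -> int:
            names = structure.atom_names[atoms]
            for ref in self._REF_NAMES:
                hit = np.flatnonzero(names == ref)
                if hit.size:
                    return int(atoms[hit[0]])
            return int(atoms[0])

        # bp i (1..L): sense residue i, antisense residue L+1-i
        self.bp_ref_sense = np.array(
            [ref_atom(self._sense_res_atoms[i]) for i in range(1, L + 1)])
        self.bp_ref_anti = np.array(
            [ref_atom(self._anti_res_atoms[L + 1 - i]) for i in range(1, L + 1)])
        self._bp_atoms = [
            np.concatenate([self._sense_res_atoms[i],
                            self._anti_res_atoms[L + 1 - i]])
            for i in range(1, L + 1)
        ]
        self._heavy = structure.heavy_mask()

    # --- base-pair resolution ------------------------------------------------
    def bp_centers(self, coords: np.ndarray) -> np.ndarray:
        """(L, 3) midpoints of the C1'-equivalent atoms of every base pair."""
        return 0.5 * (coords[self.bp_ref_sense] + coords[self.bp_ref_anti])

    def bp_atoms(self, bp_indices: np.ndarray, heavy_only: bool = True) -> np.ndarray:
        """All atom indices of the given (1-based) base pairs."""
        atoms = np.concatenate([self._bp_atoms[i - 1] for i in np.atleast_1d(bp_indices)])
        if heavy_only:
            atoms = atoms[self._heavy[atoms]]
        if atoms.size == 0:
            raise SelectionError("base-pair selection resolved to zero heavy atoms")
        return atoms

    # --- common selections ---------------------------------------------------
    @property
    def dna_atoms(self) -> np.ndarray:
        return np.flatnonzero(
            (self.structure.chain_ids == self.annotation.sense_chain)
            | (self.structure.chain_ids == self.annotation.anti_chain))

    def dna_heavy_atoms(self) -> np.ndarray:
        atoms = self.dna_atoms
        return atoms[self._heavy[atoms]]

    def tail_atoms(self, tail_name: str, heavy_only: bool = True) -> np.ndarray:
        t = self.annotation.tail(tail_name)
        atoms = self.structure.atom_indices(t.chain_id, t.residue_range)
        if heavy_only and atoms.size:
            atoms = atoms[self._heavy[atoms]]
        if atoms.size == 0:
            raise SelectionError(
                f"tail {tail_name!r} resolves to zero atoms (tail-less structure?)")
        return atoms

    def residue_atoms(self, chain_id: str, resid: int,
                      heavy_only: bool = True) -> np.ndarray:
        atoms = self.structure.atom_indices(chain_id, (resid, resid))
        if heavy_only and atoms.size:
            atoms = atoms[self._heavy[atoms]]
        if atoms.size == 0:
            raise SelectionError(f"residue {chain_id}:{resid} has no atoms")
        return atoms

    def histone_core_atoms(self, heavy_only: bool = True) -> np.ndarray:
        """Histone atoms minus every annotated tail residue."""
        ann = self.annotation
        mask = np.isin(self.structure.chain_ids, list(ann.histone_chains))
        for t in ann.tails:
            lo, hi = t.residue_range
            mask &= ~((self.structure.chain_ids == t.chain_id)
                      & (self.structure.residue_indices >= lo)
                      & (self.structure.residue_indices <= hi))
        atoms = np.flatnonzero(mask)
        if heavy_only:
            atoms = atoms[self._heavy[atoms]]
        if atoms.size == 0:
            raise SelectionError("histone-core selection is empty")
        return atoms

    def histone_atoms(self, htype: str, exclude_tails: tuple[str, ...] = (),
                      heavy_only: bool = True) -> np.ndarray:
        ann = self.annotation
        chains = [c for c, t in ann.histone_chains.items() if t == htype]
        if not chains:
            raise SelectionError(f"no {htype} chains in annotation")
        mask = np.isin(self.structure.chain_ids, chains)
        for tname in exclude_tails:
            t = ann.tail(tname)
            lo, hi = t.residue_range
            mask &= ~((self.structure.chain_ids == t.chain_id)
                      & (self.structure.residue_indices >= lo)
                      & (self.structure.residue_indices <= hi))
        atoms = np.flatnonzero(mask)
        if heavy_only:
            atoms = atoms[self._heavy[atoms]]
        return atoms

    def gyre_atoms(self, gyre: str) -> np.ndarray:
        ann = self.annotation
        if gyre == "inner":
            return self.bp_atoms(ann.inner_gyre)
        if gyre == "outer":
            return self.bp_atoms(ann.outer_gyres)
        if gyre == "outer_3p":
            return self.bp_atoms(ann.outer_gyre_3p)
        if gyre == "outer_5p":
            return self.bp_atoms(ann.outer_gyre_5p)
        raise SelectionError(f"unknown gyre {gyre!r}")
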