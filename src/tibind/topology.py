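"""System topology, trajectory frames, and rule-based atom classification.

Internal units are nm (lengths) and ps (times).  Atom indices are 0-based;
peptide residue numbering is 1-based in reports, matching the position
labels used for hexapeptide motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

# one/three letter codes for the six residues of the RKLPDA multiset
ONE_TO_THREE = {"R": "ARG", "K": "LYS", "L": "LEU", "P": "PRO", "D": "ASP", "A": "ALA"}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "NA": 22.990, "CL": 35.45, "TI": 47.867, "K": 39.098, "MG": 24.305,
}

# heavy-atom topology per residue: atom names and intra-residue bonds.
# Backbone N-CA-C(=O); sidechain rooted at CB.  The C-terminal residue
# additionally carries OXT (deprotonated carboxylate; zwitterionic peptide).
RESIDUE_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
}

RESIDUE_BONDS = {
    "ALA": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")],
    "ARG": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASP": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "OD1"), ("CG", "OD2")],
    "LEU": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "PRO": [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "CD"), ("CD", "N")],
}

# sidechain donor/acceptor atoms the RDF notation distinguishes
SIDECHAIN_N = {"ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"]}
SIDECHAIN_O = {"ASP": ["OD1", "OD2"]}

CTERM_O_NAMES = ("O", "OXT", "OT1", "OT2", "OC1", "OC2")

DEFAULT_SEGMENT_MAP = {
    # residue name -> segment
    "ARG": "peptide", "LYS": "peptide", "LEU": "peptide", "PRO": "peptide",
    "ASP": "peptide", "ALA": "peptide",
    "TIO": "surface", "TIA": "surface", "SLB": "surface", "SUR": "surface",
    "NA": "ion", "NA+": "ion", "SOD": "ion", "CL": "ion", "CL-": "ion", "CLA": "ion",
    "SOL": "solvent", "WAT": "solvent", "HOH": "solvent", "TIP3": "solvent",
}


def infer_element(name: str, segment: str) -> str:
    """Element symbol from an atom name given its segment context."""
    n = name.strip().upper()
    if segment == "surface":
        if n.startswith("TI"):
            return "TI"
        if n.startswith("O"):
            return "O"
        if n.startswith("H"):
            return "H"
        raise ValueError(f"cannot infer element for surface atom {name!r}")
    if segment == "ion":
        if n.startswith("NA") or n.startswith("SOD"):
            return "NA"
        if n.startswith("CL"):
            return "CL"
        raise ValueError(f"cannot infer element for ion {name!r}")
    # peptide / solvent: first alphabetic character (CA is a carbon here)
    for ch in n:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element for atom {name!r}")


@dataclass
class SystemTopology:
    """Static description of the simulated system's atoms."""

    names: list[str]
    resnames: list[str]
    resids: np.ndarray          # per-atom residue index, 1-based within segment
    segments: list[str]         # peptide | surface | solvent | ion
    elements: list[str]
    masses: np.ndarray          # amu
    charges: np.ndarray | None = None
    peptide_sequence: str | None = None
    box_hint: np.ndarray | None = None  # nm, orthorhombic edges

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("resnames", "segments", "elements"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length mismatch")
        self.resids = np.asarray(self.resids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.resids.shape != (n,) or self.masses.shape != (n,):
            raise ValueError("resids/masses length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def segment_indices(self, segment: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.segments) == segment)

    @property
    def peptide_indices(self) -> np.ndarray:
        return self.segment_indices("peptide")

    def peptide_residue_numbers(self) -> np.ndarray:
        """1-based residue positions of the peptide atoms, renumbered 1..6."""
        pep = self.peptide_indices
        if pep.size == 0:
            return np.array([], dtype=int)
        raw = self.resids[pep]
        uniq = sorted(dict.fromkeys(raw.tolist()))
        remap = {r: i + 1 for i, r in enumerate(uniq)}
        return np.array([remap[r] for r in raw], dtype=int)


@dataclass
class TrajectoryFrame:
    """One trajectory frame: time (ps), orthorhombic box (nm), coords (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")


@dataclass
class ClassifyParams:
    layer_tolerance: float = 0.05   # nm, z-window defining the outermost Ti layer
    oh_bond_cutoff: float = 0.12    # nm, O-H bond detection for hydroxyls
    exposure_depth: float = 0.25    # nm, z-depth from the outer Ti plane for OB


@dataclass
class AtomClasses:
    """Index sets the analyses consume, derived from topology + geometry."""

    TI: np.ndarray
    TI_TOP: np.ndarray
    TI_BOTTOM: np.ndarray
    OB: np.ndarray
    OF: np.ndarray
    HF: np.ndarray
    peptide_CA: dict          # residue position (1-based) -> atom index
    NTERM_N: int
    CTERM_O: np.ndarray
    sidechain_N: dict         # residue position -> index array
    sidechain_O: dict
    peptide_O: np.ndarray     # every peptide oxygen (backbone + carboxyl + sidechain)
    NA: np.ndarray
    CL: np.ndarray
    water_O: np.ndarray


def _min_image_dz(dz: np.ndarray, lz: float) -> np.ndarray:
    return dz - lz * np.round(dz / lz)


def min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return d - box * np.round(d / box)


def classify_atoms(topology: SystemTopology, frame: TrajectoryFrame,
                   params: ClassifyParams | None = None) -> AtomClasses:
    """Geometric atom classification for slab + peptide + ion systems.

    Surface classes are assigned from z-layering and bond cutoffs rather
    than atom names: the outermost Ti layers bound the slab, hydroxyl
    oxygens (OF) are surface O within the O-H bond cutoff of a surface H,
    and bridging oxygens (OB) are the remaining exposed-face O within
    ``exposure_depth`` of an outer Ti plane.
    """
    params = params or ClassifyParams()
    segs = np.asarray(topology.segments)
    elems = np.asarray(topology.elements)
    z = frame.coords[:, 2]

    surf = segs == "surface"
    ti = np.flatnonzero(surf & (elems == "TI"))
    if ti.size == 0:
        raise ValueError("no Ti atoms in the surface segment")
    z_ti = z[ti]
    ti_top = ti[z_ti >= z_ti.max() - params.layer_tolerance]
    ti_bottom = ti[z_ti <= z_ti.min() + params.layer_tolerance]
    plane_top = z[ti_top].mean()
    plane_bottom = z[ti_bottom].mean()

    surf_o = np.flatnonzero(surf & (elems == "O"))
    surf_h = np.flatnonzero(surf & (elems == "H"))
    if surf_o.size and surf_h.size:
        d = frame.coords[surf_o][:, None, :] - frame.coords[surf_h][None, :, :]
        d = min_image(d, frame.box)
        dist = np.linalg.norm(d, axis=-1)
        has_h = (dist <= params.oh_bond_cutoff).any(axis=1)
        of = surf_o[has_h]
        hf = surf_h[(dist <= params.oh_bond_cutoff).any(axis=0)]
    else:
        of = np.array([], dtype=int)
        hf = np.array([], dtype=int)

    non_of = np.setdiff1d(surf_o, of)
    exposed = (z[non_of] >= plane_top - params.exposure_depth) | \
              (z[non_of] <= plane_bottom + params.exposure_depth)
    ob = non_of[exposed]

    # peptide roles
    pep = topology.peptide_indices
    if pep.size == 0:
        raise ValueError("no peptide segment in topology")
    pos = topology.peptide_residue_numbers()
    n_res = int(pos.max())
    if n_res != 6:
        raise ValueError(f"peptide has {n_res} residues, expected 6")
    names = np.asarray(topology.names)

    ca: dict[int, int] = {}
    side_n: dict[int, np.ndarray] = {}
    side_o: dict[int, np.ndarray] = {}
    for r in range(1, n_res + 1):
        ratoms = pep[pos == r]
        rnames = names[ratoms]
        ca_idx = ratoms[rnames == "CA"]
        if ca_idx.size != 1:
            raise ValueError(f"peptide residue {r} has {ca_idx.size} CA atoms")
        ca[r] = int(ca_idx[0])
        resname = topology.resnames[ratoms[0]]
        sn = SIDECHAIN_N.get(resname, [])
        so = SIDECHAIN_O.get(resname, [])
        side_n[r] = ratoms[np.isin(rnames, sn)]
        side_o[r] = ratoms[np.isin(rnames, so)]

    first = pep[pos == 1]
    nterm = first[names[first] == "N"]
    if nterm.size != 1:
        raise ValueError("could not identify the N-terminal backbone N")
    last = pep[pos == n_res]
    cterm_o = last[np.isin(names[last], CTERM_O_NAMES)]

    pep_o = pep[np.asarray([e == "O" for e in elems[pep]])]

    ions = segs == "ion"
    na = np.flatnonzero(ions & (elems == "NA"))
    cl = np.flatnonzero(ions & (elems == "CL"))
    wat_o = np.flatnonzero((segs == "solvent") & (elems == "O"))

    return AtomClasses(TI=ti, TI_TOP=ti_top, TI_BOTTOM=ti_bottom, OB=ob, OF=of,
                       HF=hf, peptide_CA=ca, NTERM_N=int(nterm[0]), CTERM_O=cterm_o,
                       sidechain_N=side_n, sidechain_O=side_o, peptide_O=pep_o,
                       NA=na, CL=cl, water_O=wat_o)


def peptide_bond_list(topology: SystemTopology) -> list[tuple[int, int]]:
    """Heavy-atom bond list of the peptide from the residue templates.

    Intra-residue bonds follow ``RESIDUE_BONDS``; residues are linked by
    C(i)-N(i+1) peptide bonds; the C-terminal carboxylate O (OXT) bonds to C.
    """
    pep = topology.peptide_indices
    pos = topology.peptide_residue_numbers()
    names = np.asarray(topology.names)
    bonds: list[tuple[int, int]] = []
    n_res = int(pos.max()) if pos.size else 0
    by_res = {}
    for r in range(1, n_res + 1):
        ratoms = pep[pos == r]
        by_res[r] = {str(names[a]): int(a) for a in ratoms}
    for r in range(1, n_res + 1):
        resname = topology.resnames[pep[pos == r][0]]
        amap = by_res[r]
        for a, b in RESIDUE_BONDS[resname]:
            if a in amap and b in amap:
                bonds.append((amap[a], amap[b]))
        for oxt in ("OXT", "OT2", "OC2"):
            if oxt in amap and "C" in amap:
                bonds.append((amap["C"], amap[oxt]))
        if r < n_res and "C" in amap and "N" in by_res[r + 1]:
            bonds.append((amap["C"], by_res[r + 1]["N"]))
    return bonds
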