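"""Synthetic slab/peptide/ion systems with planted ground truth.

The generator emulates the statistical structure of the adsorption
trajectories so that every analysis stage can be validated against known
truth without any external data:

* a hydroxylated anatase (101) slab (typed TI / lattice O / OF / HF);
* a six-residue zwitterionic peptide whose conformation in each frame is
  drawn from rigid all-heavy-atom templates with prescribed end-to-end
  distances, plus isotropic jitter;
* two-state (bound/unbound) surface-separation dynamics from a discrete
  Markov chain, the SSD imposed exactly by translating the peptide's
  centre of mass above a randomly chosen slab face;
* planted anchor contacts (a basic sidechain N at an exact distance from
  a hydroxyl O) and planted bridging Na+ satisfying the dual 3 A
  criterion, with decoy ions kept at least 0.5 nm from both surface and
  peptide oxygens.

Frames are emitted with periodic wrapping applied, so the unwrapping step
of the analysis pipeline is always exercised.  No solvent coordinates are
generated (water plays no role in the geometric analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .surface import SlabModel, build_anatase_slab, hydroxylate, slab_to_topology
from .topology import (ELEMENT_MASSES, ONE_TO_THREE, RESIDUE_ATOMS,
                       AtomClasses, ClassifyParams, SystemTopology,
                       TrajectoryFrame, classify_atoms, min_image)

CA_CA = 0.38          # nm, virtual C-alpha spacing of the idealised backbone
_BB_OFF = 0.125       # nm, N/C placement along the chain tangent
_CO_OFF = 0.122       # nm, carbonyl O offset
_SC_STEP = 0.13       # nm, sidechain chain-atom step
_BR_ALONG = 0.08      # nm, branch-atom offsets
_BR_PERP = 0.11

_SIDECHAIN_CHAIN = {"ARG": ["CB", "CG", "CD", "NE", "CZ"],
                    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
                    "LEU": ["CB", "CG"], "ASP": ["CB", "CG"],
                    "ALA": ["CB"], "PRO": []}
_SIDECHAIN_BRANCH = {"ARG": {"NH1": ("CZ", 1), "NH2": ("CZ", -1)},
                     "LEU": {"CD1": ("CG", 1), "CD2": ("CG", -1)},
                     "ASP": {"OD1": ("CG", 1), "OD2": ("CG", -1)},
                     "LYS": {}, "ALA": {}, "PRO": {}}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic adsorption trajectory."""

    sequence: str = "RKLPDA"
    n_frames: int = 2000
    frame_dt: float = 10.0           # ps
    box_z: float = 8.0               # nm (lateral box comes from the slab)
    slab_n1: int = 3
    slab_n2: int = 7
    slab_layers: int = 2
    hydroxyl_fraction: float = 0.3
    p_bind: float = 0.08             # unbound -> bound per frame
    p_unbind: float = 0.02           # bound -> unbound per frame
    ssd_bound_mean: float = 0.7      # nm, truncated normal on (0, 1)
    ssd_bound_sd: float = 0.1
    bound_threshold: float = 1.0     # nm, upper truncation of the bound state
    template_eeds: tuple = (0.65, 1.40)   # nm, compact / extended conformers
    bound_weights: tuple = (0.7, 0.3)
    unbound_weights: tuple = (0.0, 1.0)
    jitter_sigma: float = 0.01       # nm, isotropic per-atom noise
    n_na: int = 6
    n_cl: int = 2
    p_bridge: float = 0.9            # chance a bound frame carries a bridging Na+
    contact_distance: float = 0.28   # nm, planted anchor-N to OF distance
    bridge_distance: float = 0.23    # nm, planted Na+ to peptide-O distance
    decoy_clearance: float = 0.5     # nm, decoy ions stay this far from O atoms

    def __post_init__(self) -> None:
        for p in (self.p_bind, self.p_unbind, self.p_bridge,
                  self.hydroxyl_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability/fraction out of [0, 1]: {p}")
        if not (0 < self.ssd_bound_mean < self.bound_threshold):
            raise ValueError("bound-state SSD mean must lie inside (0, threshold)")
        if len(self.template_eeds) != len(self.bound_weights) or \
           len(self.template_eeds) != len(self.unbound_weights):
            raise ValueError("one weight per conformer template required")

    @property
    def stationary_bound_probability(self) -> float:
        if self.p_bind + self.p_unbind == 0:
            return 1.0
        return self.p_bind / (self.p_bind + self.p_unbind)


@dataclass
class GroundTruth:
    """Frame-by-frame planted truth for a generated trajectory."""

    states: np.ndarray              # bool, True = bound
    stationary_bound_probability: float
    conformer_ids: np.ndarray
    true_ssd: np.ndarray            # nm
    template_eeds: np.ndarray
    template_rmsd: np.ndarray       # pairwise heavy-atom RMSD of the templates
    bridge_na: list = field(default_factory=list)    # per frame: planted Na indices
    contact_planted: np.ndarray | None = None
    contact_partner: np.ndarray | None = None        # OF atom index, -1 if none
    bridge_partner: np.ndarray | None = None         # peptide O index, -1 if none
    anchor_atom: int | None = None
    contact_distance: float | None = None
    bridge_distance: float | None = None
    seed: int | None = None


def _arc_angle(eed: float, n: int = 6) -> float:
    """Arc step angle giving chord(1 step) = CA_CA and chord(n-1) = eed."""
    if not (0 < eed < (n - 1) * CA_CA):
        raise ValueError(f"end-to-end target {eed} outside (0, {(n - 1) * CA_CA})")
    span = n - 1

    def f(phi):
        return CA_CA * math.sin(span * phi / 2) / math.sin(phi / 2) - eed

    lo, hi = 1e-9, 2 * math.pi / span - 1e-9
    if f(lo) < 0:  # fully extended: straight chain
        return 0.0
    return brentq(f, lo, hi, xtol=1e-14)


def build_conformer(sequence: str, eed: float,
                    anchor_down: bool = True) -> tuple[list, list, np.ndarray, dict]:
    """Idealised all-heavy-atom hexapeptide geometry with an exact EED.

    C-alpha atoms sit on a circular arc in the xy-plane with 0.38 nm
    virtual bonds; sidechains splay radially outward, except the anchor
    residue (first R, else first K) and the first D, which point along -z
    so that their terminal N / O atoms can reach the surface.  Returns
    (names, resnames_per_atom, coords, meta) with meta giving the peptide-
    local indices of the anchor N and per-residue atom spans.
    """
    seq = sequence.upper()
    n = len(seq)
    phi = _arc_angle(eed, n)
    if phi == 0.0:
        ca = np.array([[i * CA_CA, 0.0, 0.0] for i in range(n)])
        radial = np.array([[0.0, 1.0, 0.0]] * n)
        tangent = np.array([[1.0, 0.0, 0.0]] * n)
    else:
        radius = CA_CA / (2 * math.sin(phi / 2))
        theta = np.arange(n) * phi
        ca = radius * np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
        radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
        tangent = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros(n)])

    chord = np.zeros((n, 3))
    chord[:-1] = ca[1:] - ca[:-1]
    chord[:-1] /= np.linalg.norm(chord[:-1], axis=1)[:, None]
    chord[-1] = chord[-2]

    anchor_res = None
    for letter in ("R", "K"):
        if letter in seq:
            anchor_res = seq.index(letter)
            break
    down = set()
    if anchor_down and anchor_res is not None:
        down.add(anchor_res)
    if "D" in seq:
        down.add(seq.index("D"))

    names, resnames, coords = [], [], []
    meta = {"anchor_atom": None, "residue_spans": []}
    zhat = np.array([0.0, 0.0, 1.0])
    for i, letter in enumerate(seq):
        res = ONE_TO_THREE[letter]
        t = tangent[i]
        s_dir = -zhat if i in down else radial[i]
        b_dir = t if i in down else zhat
        # N and C sit on the chord towards the neighbouring CA so that the
        # inter-residue C-N bond is exactly CA_CA - 2*_BB_OFF = 0.13 nm
        pos: dict[str, np.ndarray] = {"CA": ca[i]}
        pos["N"] = ca[i] - _BB_OFF * (chord[i - 1] if i > 0 else chord[0])
        pos["C"] = ca[i] + _BB_OFF * (chord[i] if i < n - 1 else chord[n - 2])
        pos["O"] = pos["C"] + _CO_OFF * zhat
        if res == "PRO":
            pos["CB"] = ca[i] + 0.12 * s_dir
            pos["CD"] = pos["N"] + 0.12 * s_dir
            pos["CG"] = 0.5 * (pos["CB"] + pos["CD"]) + 0.10 * s_dir
        else:
            prev = ca[i]
            for j, at in enumerate(_SIDECHAIN_CHAIN[res]):
                wob = 0.02 * b_dir * (1 if j % 2 else -1)
                prev = prev + _SC_STEP * s_dir + wob
                pos[at] = prev
            for at, (parent, sign) in _SIDECHAIN_BRANCH[res].items():
                pos[at] = pos[parent] + _BR_ALONG * s_dir + sign * _BR_PERP * b_dir
        atom_order = list(RESIDUE_ATOMS[res])
        if i == n - 1:
            pos["OXT"] = pos["C"] - _CO_OFF * zhat
            atom_order.append("OXT")
        start = len(names)
        for at in atom_order:
            names.append(at)
            resnames.append(res)
            coords.append(pos[at])
        meta["residue_spans"].append((start, len(names)))
        if i == anchor_res:
            anchor_name = "NH1" if res == "ARG" else "NZ"
            meta["anchor_atom"] = start + atom_order.index(anchor_name)
    if meta["anchor_atom"] is None:
        meta["anchor_atom"] = 0  # fall back to the N-terminal backbone N
    return names, resnames, np.asarray(coords), meta


def generate_synthetic_system(spec: SyntheticSpec, seed: int
                              ) -> tuple[SystemTopology, SlabModel, AtomClasses, dict]:
    """Assemble the static system: slab + peptide + ions.

    Returns the topology, the hydroxylated slab, the (static) atom classes
    and a layout dict used by :func:`generate_trajectory`.  Deterministic
    given the seed.
    """
    slab = build_anatase_slab(spec.slab_n1, spec.slab_n2, spec.slab_layers)
    slab = hydroxylate(slab, spec.hydroxyl_fraction, seed=seed)
    z_offset = 0.3  # lift the slab so the lower-face hydroxyls stay in the box
    if spec.box_z < slab.thickness + 2.0 * z_offset + 2.0:
        raise ValueError(f"box_z {spec.box_z} nm too small for a "
                         f"{slab.thickness:.2f} nm slab plus solvent region")

    surf_topo, surf_frame = slab_to_topology(slab, z_offset=z_offset)
    templates = [build_conformer(spec.sequence, e) for e in spec.template_eeds]
    names0, resnames0, _, meta0 = templates[0]

    names = list(surf_topo.names)
    resnames = list(surf_topo.resnames)
    resids = list(surf_topo.resids)
    segments = list(surf_topo.segments)
    elements = list(surf_topo.elements)

    n_surface = len(names)
    pep_res0 = np.array([r for i, (a, b) in enumerate(meta0["residue_spans"])
                         for r in [i] * (b - a)])
    for k, (nm, rn) in enumerate(zip(names0, resnames0)):
        names.append(nm)
        resnames.append(rn)
        resids.append(2 + int(pep_res0[k]))
        segments.append("peptide")
        elements.append(nm[0])
    next_resid = 2 + len(spec.sequence)
    for _ in range(spec.n_na):
        names.append("NA"); resnames.append("NA"); resids.append(next_resid)
        segments.append("ion"); elements.append("NA"); next_resid += 1
    for _ in range(spec.n_cl):
        names.append("CL"); resnames.append("CL"); resids.append(next_resid)
        segments.append("ion"); elements.append("CL"); next_resid += 1

    topo = SystemTopology(names=names, resnames=resnames,
                          resids=np.asarray(resids), segments=segments,
                          elements=elements,
                          masses=np.array([ELEMENT_MASSES[e] for e in elements]),
                          peptide_sequence=spec.sequence.upper(),
                          box_hint=np.array([slab.lx, slab.ly, spec.box_z]))

    # provisional frame (peptide mid-box) to derive the static atom classes
    box = np.array([slab.lx, slab.ly, spec.box_z])
    coords = np.zeros((topo.n_atoms, 3))
    coords[:n_surface] = surf_frame.coords
    _, _, tcoords, _ = templates[0]
    mid = np.array([slab.lx / 2, slab.ly / 2, spec.box_z - 1.5])
    pep_slice = slice(n_surface, n_surface + len(names0))
    coords[pep_slice] = tcoords - tcoords.mean(axis=0) + mid
    coords[n_surface + len(names0):] = mid + [0.5, 0.5, 0.5]
    frame0 = TrajectoryFrame(time=0.0, box=box, coords=coords)
    classes = classify_atoms(topo, frame0, ClassifyParams())

    layout = {"n_surface": n_surface, "pep_slice": pep_slice,
              "na_slice": slice(n_surface + len(names0),
                                n_surface + len(names0) + spec.n_na),
              "cl_slice": slice(n_surface + len(names0) + spec.n_na, topo.n_atoms),
              "surface_coords": surf_frame.coords, "box": box,
              "templates": templates, "z_offset": z_offset}
    return topo, slab, classes, layout


def _template_rmsd_matrix(templates) -> np.ndarray:
    from .clustering import kabsch_rmsd
    n = len(templates)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_rmsd(templates[i][2], templates[j][2])
    return m


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_trajectory(spec: SyntheticSpec, seed: int
                        ) -> tuple[SystemTopology, list[TrajectoryFrame], GroundTruth]:
    """Sample a wrapped synthetic trajectory with planted ground truth.

    Per frame the Markov state selects the SSD distribution and conformer
    weights; the peptide (jittered, z-rotated, optionally mirrored to the
    lower face) is translated so its mass-weighted COM sits exactly at the
    sampled SSD above the chosen face.  In bound frames the anchor N is
    placed at the exact planted contact distance from a hydroxyl O when
    geometrically feasible, and with probability ``p_bridge`` one Na+ is
    planted to satisfy the dual bridging criterion; every other ion is a
    decoy kept clear of all oxygens.
    """
    rng = np.random.default_rng(seed)
    topo, slab, classes, layout = generate_synthetic_system(
        spec, seed=int(rng.integers(2 ** 31 - 1)))
    box = layout["box"]
    lz = float(box[2])
    surface = layout["surface_coords"]
    pep_slice = layout["pep_slice"]
    na_slice = layout["na_slice"]
    cl_slice = layout["cl_slice"]
    templates = layout["templates"]
    masses = topo.masses[pep_slice]

    plane_top = surface[classes.TI_TOP, 2].mean()
    plane_bot = surface[classes.TI_BOTTOM, 2].mean()
    surf_o_idx = np.concatenate([classes.OB, classes.OF])
    of_pos = surface[classes.OF] if classes.OF.size else np.empty((0, 3))
    surf_o_pos = surface[surf_o_idx]
    pep_elems = np.asarray(topo.elements)[pep_slice.start:pep_slice.stop]
    pep_o_local = np.flatnonzero(pep_elems == "O")
    anchor_local = templates[0][3]["anchor_atom"]

    max_ssd = 0.5 * (lz - (plane_top - plane_bot))
    unbound_lo = spec.bound_threshold + 0.05
    unbound_hi = max_ssd - 0.15
    if unbound_hi <= unbound_lo:
        raise ValueError("box too small for an unbound SSD range above the threshold")
    a = (0.0 - spec.ssd_bound_mean) / spec.ssd_bound_sd
    b = (spec.bound_threshold - spec.ssd_bound_mean) / spec.ssd_bound_sd

    p_stat = spec.stationary_bound_probability
    state = bool(rng.random() < p_stat)
    states = np.empty(spec.n_frames, dtype=bool)
    conf_ids = np.empty(spec.n_frames, dtype=int)
    true_ssd = np.empty(spec.n_frames)
    contact_planted = np.zeros(spec.n_frames, dtype=bool)
    contact_partner = np.full(spec.n_frames, -1, dtype=int)
    bridge_partner = np.full(spec.n_frames, -1, dtype=int)
    bridges: list[np.ndarray] = []
    frames: list[TrajectoryFrame] = []

    n_templates = len(templates)
    for f in range(spec.n_frames):
        states[f] = state
        weights = np.asarray(spec.bound_weights if state else spec.unbound_weights,
                             dtype=float)
        cid = int(rng.choice(n_templates, p=weights / weights.sum()))
        conf_ids[f] = cid
        coords_p = templates[cid][2].copy()
        if spec.jitter_sigma > 0:
            coords_p = coords_p + rng.normal(0.0, spec.jitter_sigma, coords_p.shape)
        coords_p = coords_p @ _rot_z(rng.uniform(0.0, 2 * math.pi)).T

        face = 1 if rng.random() < 0.5 else -1
        if face < 0:
            # approach the lower face by a proper 180-degree rotation about x
            # (a z-mirror would be an improper transform: Kabsch superposition
            # rightly cannot map mirror images onto each other)
            coords_p[:, 1:] *= -1.0
        if state:
            ssd = float(truncnorm.rvs(a, b, loc=spec.ssd_bound_mean,
                                      scale=spec.ssd_bound_sd, random_state=rng))
        else:
            ssd = float(rng.uniform(unbound_lo, unbound_hi))
        true_ssd[f] = ssd
        plane = plane_top if face > 0 else plane_bot
        com = np.average(coords_p, axis=0, weights=masses)
        target_z = plane + face * ssd
        coords_p += np.array([0.0, 0.0, target_z]) - [0.0, 0.0, com[2]]

        placed = False
        if state and of_pos.size:
            # faces are distinguished by which side of the slab the OF sits on
            on_face = of_pos[:, 2] > plane_top if face > 0 else of_pos[:, 2] < plane_bot
            cand = np.flatnonzero(on_face)
            if cand.size:
                of_choice = int(rng.choice(cand))
                of_atom = of_pos[of_choice]
                dz = coords_p[anchor_local, 2] - of_atom[2]
                if abs(dz) < spec.contact_distance - 1e-3:
                    rho = math.sqrt(spec.contact_distance ** 2 - dz ** 2)
                    az = rng.uniform(0.0, 2 * math.pi)
                    target_xy = of_atom[:2] + rho * np.array([math.cos(az), math.sin(az)])
                    coords_p[:, :2] += target_xy - coords_p[anchor_local, :2]
                    placed = True
                    contact_partner[f] = int(classes.OF[of_choice])
        if not placed:
            shift = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1])])
            coords_p[:, :2] += shift - coords_p[:, :2].mean(axis=0)
        contact_planted[f] = placed

        ions = np.empty((spec.n_na + spec.n_cl, 3))
        planted_na: list[int] = []
        start_ion = 0
        if state and spec.n_na > 0 and rng.random() < spec.p_bridge:
            pep_o_pos = coords_p[pep_o_local]
            k_low = int(np.argmin(face * pep_o_pos[:, 2]))
            low = pep_o_pos[k_low]
            d = min_image(surf_o_pos - low, box)
            j = int(np.argmin(np.linalg.norm(d, axis=1)))
            dist = float(np.linalg.norm(d[j]))
            if dist <= 0.3 + spec.bridge_distance - 0.01:
                ions[0] = low + d[j] / dist * spec.bridge_distance
                planted_na.append(int(na_slice.start))
                bridge_partner[f] = int(pep_slice.start + pep_o_local[k_low])
                start_ion = 1
        # decoy ions: in the water region, clear of all surface and peptide O
        avoid = np.vstack([surf_o_pos, coords_p[pep_o_local]])
        for k in range(start_ion, spec.n_na + spec.n_cl):
            for attempt in range(200):
                pos = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                                plane_top + rng.uniform(1.2, lz - (plane_top - plane_bot) - 2.4)])
                dmin = np.linalg.norm(min_image(avoid - pos, box), axis=1).min()
                if dmin >= spec.decoy_clearance:
                    ions[k] = pos
                    break
            else:
                raise RuntimeError("could not place a decoy ion clear of oxygens")
        bridges.append(np.asarray(planted_na, dtype=int))

        coords = np.empty((topo.n_atoms, 3))
        coords[:layout["n_surface"]] = surface
        coords[pep_slice] = coords_p
        coords[na_slice] = ions[:spec.n_na]
        coords[cl_slice] = ions[spec.n_na:]
        coords %= box  # emit wrapped
        frames.append(TrajectoryFrame(time=f * spec.frame_dt, box=box.copy(),
                                      coords=coords))
        # Markov step for the next frame
        if state:
            state = rng.random() >= spec.p_unbind
        else:
            state = rng.random() < spec.p_bind

    truth = GroundTruth(states=states, stationary_bound_probability=p_stat,
                        conformer_ids=conf_ids, true_ssd=true_ssd,
                        template_eeds=np.asarray(spec.template_eeds),
                        template_rmsd=_template_rmsd_matrix(templates),
                        bridge_na=bridges, contact_planted=contact_planted,
                        contact_partner=contact_partner,
                        bridge_partner=bridge_partner,
                        anchor_atom=pep_slice.start + anchor_local,
                        contact_distance=spec.contact_distance,
                        bridge_distance=spec.bridge_distance, seed=seed)
    return topo, frames, truth


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-serialisable ground-truth sidecar."""
    return {"states": truth.states.astype(int).tolist(),
            "stationary_bound_probability": truth.stationary_bound_probability,
            "conformer_ids": truth.conformer_ids.tolist(),
            "true_ssd": truth.true_ssd.tolist(),
            "template_eeds": truth.template_eeds.tolist(),
            "template_rmsd": truth.template_rmsd.tolist(),
            "bridge_na": [b.tolist() for b in truth.bridge_na],
            "contact_planted": truth.contact_planted.astype(int).tolist(),
            "contact_partner": truth.contact_partner.tolist(),
            "bridge_partner": truth.bridge_partner.tolist(),
            "anchor_atom": truth.anchor_atom,
            "contact_distance": truth.contact_distance,
            "bridge_distance": truth.bridge_distance,
            "seed": truth.seed}
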