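"""Radial distribution functions between peptide atoms and surface oxygens.

Selections follow the field's notation for the hexapeptide/anatase system:
nitrogen atoms of basic residues (ARG, LYS) and the N-terminal amine,
oxygens of ASP and the C-terminal carboxylate, C-alpha for the apolar
residues, against the two surface oxygen types — bridging oxygens (OB) and
hydroxyl oxygens (OF).  The conditional RDF restricts the reference set to
"surface" Na+ ions satisfying a dual distance criterion: within 3 A of a
surface oxygen (OB or OF) and simultaneously within 3 A of any peptide
oxygen — the geometry of an ion bridging peptide and surface.

Normalisation uses the whole-box density of the B selection (GROMACS
convention).  In slab geometry the density is inhomogeneous, so peak
heights are convention-dependent; peak positions are not, and raw pair
counts are retained so any alternative normalisation can be applied
post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .topology import AtomClasses, SystemTopology, TrajectoryFrame, min_image


@dataclass
class RDFResult:
    bin_edges: np.ndarray        # nm, uniform
    g: np.ndarray
    counts: np.ndarray           # raw in-range pair counts per bin (integers)
    frames_used: int
    mean_n_a: float
    n_b: int
    normalization: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


class SelectionError(ValueError):
    pass


def resolve_selection(expr: str, topology: SystemTopology,
                      classes: AtomClasses) -> np.ndarray:
    """Resolve a textual atom selection to a sorted index array.

    Grammar (whitespace-separated, case-insensitive keywords)::

        surface OB | surface OF
        NA | CL | water-O | peptide-O
        NTERM-N | CTERM-O
        sidechain-N [pos I | res X[,Y..]]
        sidechain-O [pos I | res X[,Y..]]
        CA          [pos I | res X[,Y..]]

    ``pos`` qualifiers are 1-based sequence positions; ``res`` qualifiers
    select positions whose residue one-letter code is in the given set.
    """
    tokens = expr.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    head = tokens[0].upper()

    def _positions(kind_map: dict) -> list[int]:
        if len(tokens) == 1:
            return sorted(kind_map)
        qual = tokens[1].lower()
        if qual == "pos":
            if len(tokens) < 3:
                raise SelectionError(f"token 3: expected a position after 'pos' in {expr!r}")
            try:
                p = int(tokens[2])
            except ValueError:
                raise SelectionError(f"token 3: bad position {tokens[2]!r}") from None
            if p not in kind_map:
                raise SelectionError(f"position {p} outside peptide (1..{max(kind_map)})")
            return [p]
        if qual == "res":
            if len(tokens) < 3:
                raise SelectionError(f"token 3: expected residue letters after 'res' in {expr!r}")
            letters = {c.strip().upper() for c in tokens[2].split(",") if c.strip()}
            seq = topology.peptide_sequence or ""
            return [p for p in sorted(kind_map) if p <= len(seq) and seq[p - 1] in letters]
        raise SelectionError(f"token 2: unknown qualifier {tokens[1]!r} in {expr!r}")

    if head == "SURFACE":
        if len(tokens) < 2 or tokens[1].upper() not in ("OB", "OF"):
            raise SelectionError(f"token 2: expected OB or OF after 'surface' in {expr!r}")
        return np.sort(classes.OB if tokens[1].upper() == "OB" else classes.OF)
    if head == "NA":
        return np.sort(classes.NA)
    if head == "CL":
        return np.sort(classes.CL)
    if head == "WATER-O":
        return np.sort(classes.water_O)
    if head == "PEPTIDE-O":
        return np.sort(classes.peptide_O)
    if head == "NTERM-N":
        return np.array([classes.NTERM_N])
    if head == "CTERM-O":
        return np.sort(classes.CTERM_O)
    if head == "SIDECHAIN-N":
        pos = _positions(classes.sidechain_N)
        return np.sort(np.concatenate([classes.sidechain_N[p] for p in pos])
                       if pos else np.array([], dtype=int))
    if head == "SIDECHAIN-O":
        pos = _positions(classes.sidechain_O)
        return np.sort(np.concatenate([classes.sidechain_O[p] for p in pos])
                       if pos else np.array([], dtype=int))
    if head == "CA":
        pos = _positions(classes.peptide_CA)
        return np.array(sorted(classes.peptide_CA[p] for p in pos), dtype=int)
    raise SelectionError(f"token 1: unknown selection token {tokens[0]!r}")


def _pair_distances(coords: np.ndarray, box: np.ndarray,
                    sel_a: np.ndarray, sel_b: np.ndarray) -> np.ndarray:
    d = coords[sel_a][:, None, :] - coords[sel_b][None, :, :]
    d = min_image(d, box)
    dist = np.linalg.norm(d, axis=-1)
    same = sel_a[:, None] == sel_b[None, :]
    return dist[~same]


def _rdf_accumulate(frames: Iterable[TrajectoryFrame],
                    a_sets: Callable[[int, TrajectoryFrame], np.ndarray],
                    sel_b: np.ndarray, r_max: float, bin_width: float):
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, edges[-1] + bin_width)
    counts = np.zeros(len(edges) - 1)
    denom = np.zeros(len(edges) - 1)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_frames = 0
    sum_na = 0
    per_frame = []  # (counts_t, n_a, rho_b) for frame-mean normalisation
    for i, fr in enumerate(frames):
        if r_max >= 0.5 * fr.box.min():
            raise ValueError(f"r_max {r_max} nm exceeds half the smallest box edge "
                             f"({0.5 * fr.box.min():.3f} nm)")
        sel_a = np.asarray(a_sets(i, fr), dtype=int)
        n_frames += 1
        sum_na += sel_a.size
        rho_b = sel_b.size / float(np.prod(fr.box))
        if sel_a.size:
            dist = _pair_distances(fr.coords, fr.box, sel_a, sel_b)
            c_t, _ = np.histogram(dist, bins=edges)
        else:
            c_t = np.zeros(len(edges) - 1)
        counts += c_t
        denom += sel_a.size * shell * rho_b
        per_frame.append((c_t, sel_a.size, rho_b))
    if n_frames == 0:
        raise ValueError("no frames supplied")
    return edges, counts, denom, shell, n_frames, sum_na, per_frame


def compute_rdf(frames: Sequence[TrajectoryFrame], sel_a: np.ndarray,
                sel_b: np.ndarray, r_max: float = 1.2,
                bin_width: float = 0.002) -> RDFResult:
    """g(r) between two fixed atom selections, averaged over frames.

    Minimum-image distances in an orthorhombic box; identical atom indices
    appearing in both selections are excluded pairwise.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    edges, counts, denom, _, n_frames, sum_na, _ = _rdf_accumulate(
        frames, lambda i, fr: sel_a, sel_b, r_max, bin_width)
    g = np.divide(counts, denom, out=np.zeros_like(counts), where=denom > 0)
    return RDFResult(bin_edges=edges, g=g, counts=counts.astype(int),
                     frames_used=n_frames, mean_n_a=sum_na / n_frames,
                     n_b=int(sel_b.size),
                     normalization="whole-box density of B (GROMACS convention)")


def first_peak(rdf: RDFResult, window_max: float = 0.4) -> tuple[float, float, bool]:
    """Location and height of the g(r) maximum within (0, window_max].

    Returns (r_peak, g_peak, outside_flag); the flag is set when the
    global maximum over the full binned range lies beyond the window —
    i.e. there is no genuine short-range peak.
    """
    centers = rdf.bin_centers
    if window_max > rdf.bin_edges[-1] + 1e-12:
        raise ValueError(f"window_max {window_max} beyond binned range "
                         f"{rdf.bin_edges[-1]:.3f}")
    if not np.any(rdf.g > 0):
        raise ValueError("all-zero g(r): nothing to locate")
    inside = centers <= window_max
    i_in = int(np.argmax(np.where(inside, rdf.g, -np.inf)))
    i_all = int(np.argmax(rdf.g))
    flag = not inside[i_all]
    return float(centers[i_in]), float(rdf.g[i_in]), flag


def bridging_na_filter(frame: TrajectoryFrame, classes: AtomClasses,
                       d_surface: float = 0.3, d_peptide: float = 0.3) -> np.ndarray:
    """Na+ ions simultaneously near the surface and near a peptide oxygen.

    An ion qualifies when its minimum-image distance to at least one
    surface oxygen (OB or OF) is <= ``d_surface`` AND to at least one
    peptide oxygen (backbone carbonyl, carboxylate or sidechain O) is
    <= ``d_peptide`` — both 0.3 nm (3 A) by default.
    """
    na = classes.NA
    if na.size == 0:
        return np.array([], dtype=int)
    surf_o = np.concatenate([classes.OB, classes.OF])
    pep_o = classes.peptide_O
    if surf_o.size == 0 or pep_o.size == 0:
        return np.array([], dtype=int)
    d_s = np.linalg.norm(min_image(frame.coords[na][:, None, :]
                                   - frame.coords[surf_o][None, :, :], frame.box), axis=-1)
    d_p = np.linalg.norm(min_image(frame.coords[na][:, None, :]
                                   - frame.coords[pep_o][None, :, :], frame.box), axis=-1)
    ok = (d_s.min(axis=1) <= d_surface) & (d_p.min(axis=1) <= d_peptide)
    return na[ok]


def conditional_rdf(frames: Sequence[TrajectoryFrame], classes: AtomClasses,
                    sel_b: np.ndarray, r_max: float = 1.2, bin_width: float = 0.002,
                    d_surface: float = 0.3, d_peptide: float = 0.3,
                    mode: str = "framewise") -> RDFResult:
    """RDF from bridging Na+ (dual 3 A criterion, re-evaluated every frame) to B.

    ``mode='framewise'`` (default): counts are pooled and normalised by the
    summed per-frame filtered ion count, so frames with an empty filter
    contribute zero counts and zero reference particles.  With a filter
    that accepts every ion in every frame this is bin-for-bin identical to
    :func:`compute_rdf` on the full Na+ set.  ``mode='frame_mean'`` instead
    averages the per-frame normalised g(r) over frames with a non-empty
    filter.
    """
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_b.size == 0:
        raise ValueError("empty selection")
    if mode not in ("framewise", "frame_mean"):
        raise ValueError(f"unknown normalisation mode {mode!r}")

    def a_sets(i, fr):
        return bridging_na_filter(fr, classes, d_surface, d_peptide)

    edges, counts, denom, shell, n_frames, sum_na, per_frame = _rdf_accumulate(
        frames, a_sets, sel_b, r_max, bin_width)
    if mode == "framewise":
        g = np.divide(counts, denom, out=np.zeros_like(counts), where=denom > 0)
    else:
        gs = [c / (na * shell * rho) for c, na, rho in per_frame if na > 0]
        g = np.mean(gs, axis=0) if gs else np.zeros(len(edges) - 1)
    return RDFResult(bin_edges=edges, g=g, counts=counts.astype(int),
                     frames_used=n_frames, mean_n_a=sum_na / n_frames,
                     n_b=int(sel_b.size),
                     normalization=f"conditional ({mode}), dual "
                                   f"{d_surface * 10:.0f}/{d_peptide * 10:.0f} A filter")


def write_rdf(result: RDFResult, path, label_a: str = "A", label_b: str = "B") -> None:
    """Two-column (r_nm, g) whitespace table with an xvg-style comment header."""
    with open(path, "w") as fh:
        fh.write(f"# RDF {label_a} - {label_b}\n")
        fh.write(f"# frames = {result.frames_used}, mean |A| = {result.mean_n_a:.3f}, "
                 f"|B| = {result.n_b}\n")
        fh.write(f"# normalization: {result.normalization}\n")
        fh.write("# r_nm  g\n")
        for r, g in zip(result.bin_centers, result.g):
            fh.write(f"{r:10.5f} {g:14.6f}\n")
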