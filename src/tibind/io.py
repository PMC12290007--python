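"""Readers and writers for structures and trajectories.

GRO files (single and multi-frame) are handled natively — the format is
fixed-column and GROMACS-heritage multi-frame GRO is not covered by the
trajectory libraries for slabs with non-standard atom naming.  PDB files
and XTC/DCD trajectories go through MDAnalysis.  All coordinates are
converted to nm at the boundary (PDB/MDAnalysis are Angstrom-native).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .topology import (DEFAULT_SEGMENT_MAP, ELEMENT_MASSES, THREE_TO_ONE,
                       SystemTopology, TrajectoryFrame, infer_element)

_ANGSTROM = 0.1  # nm per Angstrom


def _build_topology(names, resnames, resids, segment_map=None, box_hint=None):
    segment_map = {**DEFAULT_SEGMENT_MAP, **(segment_map or {})}
    segments, elements, masses = [], [], []
    for name, resname in zip(names, resnames):
        key = resname.strip().upper()
        if key not in segment_map:
            raise ValueError(f"unknown residue name {resname!r}: supply a segment mapping")
        seg = segment_map[key]
        el = infer_element(name, seg)
        if el not in ELEMENT_MASSES:
            raise ValueError(f"no mass for element {el!r} (atom {name!r})")
        segments.append(seg)
        elements.append(el)
        masses.append(ELEMENT_MASSES[el])

    seq = None
    pep = [i for i, s in enumerate(segments) if s == "peptide"]
    if pep:
        seen: dict[int, str] = {}
        for i in pep:
            seen.setdefault(int(resids[i]), resnames[i].strip().upper())
        seq = "".join(THREE_TO_ONE.get(rn, "X") for _, rn in sorted(seen.items()))

    return SystemTopology(names=list(names), resnames=[r.strip().upper() for r in resnames],
                          resids=np.asarray(resids, dtype=int), segments=segments,
                          elements=elements, masses=np.asarray(masses),
                          peptide_sequence=seq, box_hint=box_hint)


def _require_orthorhombic(dimensions, where: str):
    """MDAnalysis-style [lx, ly, lz, alpha, beta, gamma] -> nm edge lengths."""
    if dimensions is None:
        raise ValueError(f"{where}: no box information")
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError(f"{where}: triclinic box not supported (angles {dims[3:]})")
    return dims[:3] * _ANGSTROM


# ---------------------------------------------------------------- GRO native

def _parse_gro_block(lines, lineno0):
    """Parse one GRO frame starting at lines[0]; returns (frame_data, consumed)."""
    title = lines[0]
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            pass
    try:
        natoms = int(lines[1].strip())
    except (IndexError, ValueError) as exc:
        raise ValueError(f"line {lineno0 + 2}: malformed GRO atom-count record") from exc
    if len(lines) < natoms + 3:
        raise EOFError(f"line {lineno0 + 1}: truncated GRO frame (need {natoms} atoms)")
    resids, resnames, names, coords = [], [], [], np.empty((natoms, 3))
    for i in range(natoms):
        ln = lines[2 + i]
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            coords[i] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"line {lineno0 + 3 + i}: malformed GRO atom record: {ln!r}") from exc
    boxfields = lines[2 + natoms].split()
    if len(boxfields) < 3:
        raise ValueError(f"line {lineno0 + 3 + natoms}: malformed GRO box record")
    box = np.array([float(v) for v in boxfields[:3]])
    if len(boxfields) > 3 and any(abs(float(v)) > 1e-9 for v in boxfields[3:]):
        raise ValueError(f"line {lineno0 + 3 + natoms}: triclinic GRO box not supported")
    return (time, resids, resnames, names, coords, box), natoms + 3


def read_gro_frames(path) -> Iterator[tuple]:
    """Yield raw parsed frames from a (possibly multi-frame) GRO file."""
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        data, consumed = _parse_gro_block(lines[pos:], pos)
        yield data
        pos += consumed
        while pos < len(lines) and not lines[pos].strip():
            pos += 1


def write_gro(path, topology: SystemTopology, frames: Iterable[TrajectoryFrame],
              title: str = "tibind system") -> None:
    """Write frames as (multi-frame) GRO.  Coordinates already in nm."""
    with open(path, "w") as fh:
        for fr in ([frames] if isinstance(frames, TrajectoryFrame) else frames):
            if fr.coords.shape[0] != topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
            fh.write(f"{title} t= {fr.time:.4f}\n{topology.n_atoms}\n")
            for i in range(topology.n_atoms):
                resid = int(topology.resids[i]) % 100000
                fh.write(f"{resid:5d}{topology.resnames[i]:<5.5s}"
                         f"{topology.names[i]:>5.5s}{(i + 1) % 100000:5d}"
                         f"{fr.coords[i, 0]:8.3f}{fr.coords[i, 1]:8.3f}{fr.coords[i, 2]:8.3f}\n")
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def read_segment_map(path) -> dict:
    """Plain-text residue-name -> segment overrides, one mapping per line.

    Lines are ``RESNAME segment`` (whitespace-separated); ``#`` comments and
    blank lines are ignored.  Valid segments: peptide, surface, solvent, ion.
    """
    mapping = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        s = ln.split("#")[0].strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != 2 or parts[1] not in ("peptide", "surface", "solvent", "ion"):
            raise ValueError(f"{path}:{lineno}: expected 'RESNAME segment', got {ln!r}")
        mapping[parts[0].upper()] = parts[1]
    return mapping


# ------------------------------------------------------------- structures

def load_structure(path, fmt: str | None = None, segment_map=None
                   ) -> tuple[SystemTopology, TrajectoryFrame]:
    """Load a PDB or GRO structure into (topology, first frame), nm units."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "GRO":
        try:
            data = next(iter(read_gro_frames(path)))
        except StopIteration:
            raise ValueError(f"{path}: empty GRO file") from None
        time, resids, resnames, names, coords, box = data
        topo = _build_topology(names, resnames, resids, segment_map, box_hint=box)
        return topo, TrajectoryFrame(time=time, box=box, coords=coords)
    if fmt == "PDB":
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        box = _require_orthorhombic(u.dimensions, str(path)) if u.dimensions is not None \
            else np.array([1.0, 1.0, 1.0])
        topo = _build_topology([a.name for a in u.atoms],
                               [a.resname for a in u.atoms],
                               [a.resid for a in u.atoms], segment_map, box_hint=box)
        coords = u.atoms.positions * _ANGSTROM
        return topo, TrajectoryFrame(time=0.0, box=box, coords=coords)
    raise ValueError(f"unsupported structure format {fmt!r}")


def write_structure(path, topology: SystemTopology, frame: TrajectoryFrame) -> None:
    """Write a single structure as GRO or PDB (by extension)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").upper()
    if fmt == "GRO":
        write_gro(path, topology, [frame])
        return
    if fmt == "PDB":
        import MDAnalysis as mda
        n = topology.n_atoms
        u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                               trajectory=True)
        u.add_TopologyAttr("names", topology.names)
        u.add_TopologyAttr("resnames", topology.resnames)
        u.add_TopologyAttr("resids", topology.resids)
        u.atoms.positions = frame.coords / _ANGSTROM
        u.dimensions = np.concatenate([frame.box / _ANGSTROM, [90.0, 90.0, 90.0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))
        return
    raise ValueError(f"unsupported structure format {fmt!r}")


# ------------------------------------------------------------ trajectories

def load_trajectory(path, topology: SystemTopology, fmt: str | None = None,
                    stride: int = 1, time_range: tuple[float, float] | None = None
                    ) -> Iterator[TrajectoryFrame]:
    """Iterate frames of an XTC/DCD/multi-GRO trajectory in time order.

    ``stride`` keeps every stride-th frame (counted before time filtering);
    ``time_range`` is a closed [t0, t1] window in ps (t1 may be ``inf``).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    t0, t1 = time_range if time_range is not None else (-np.inf, np.inf)

    if fmt == "GRO":
        for i, data in enumerate(_iter_gro_tolerant(path)):
            time, _, _, _, coords, box = data
            if i % stride or not (t0 <= time <= t1):
                continue
            if coords.shape[0] != topology.n_atoms:
                raise ValueError(f"{path}: frame has {coords.shape[0]} atoms, "
                                 f"topology has {topology.n_atoms}")
            yield TrajectoryFrame(time=time, box=box, coords=coords)
        return

    if fmt in ("XTC", "DCD"):
        if fmt == "XTC":
            from MDAnalysis.coordinates.XTC import XTCReader as Reader
        else:
            from MDAnalysis.coordinates.DCD import DCDReader as Reader
        reader = Reader(str(path))
        try:
            if reader.n_atoms != topology.n_atoms:
                raise ValueError(f"{path}: trajectory has {reader.n_atoms} atoms, "
                                 f"topology has {topology.n_atoms}")
            n_bad = 0
            for i, ts in enumerate(_iter_reader_tolerant(reader)):
                if i % stride or not (t0 <= ts.time <= t1):
                    continue
                box = _require_orthorhombic(ts.dimensions, str(path))
                yield TrajectoryFrame(time=float(ts.time), box=box,
                                      coords=ts.positions * _ANGSTROM)
        finally:
            reader.close()
        return

    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _iter_gro_tolerant(path):
    gen = read_gro_frames(path)
    n = 0
    while True:
        try:
            data = next(gen)
        except StopIteration:
            return
        except EOFError as exc:
            warnings.warn(f"{path}: stopping after {n} complete frames: {exc}")
            return
        n += 1
        yield data


def _iter_reader_tolerant(reader):
    it = iter(reader)
    n = 0
    while True:
        try:
            ts = next(it)
        except StopIteration:
            return
        except (EOFError, IOError, OSError) as exc:
            warnings.warn(f"stopping after {n} complete frames: {exc}")
            return
        n += 1
        yield ts


def write_xtc(path, topology: SystemTopology, frames: Iterable[TrajectoryFrame]) -> None:
    """Write frames to XTC (GROMACS compressed trajectory) via MDAnalysis."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.XTC import XTCWriter

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    with XTCWriter(str(path), n_atoms=topology.n_atoms) as w:
        for fr in frames:
            if fr.coords.shape[0] != topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
            u.atoms.positions = fr.coords / _ANGSTROM
            u.trajectory.ts.time = fr.time
            u.dimensions = np.concatenate([fr.box / _ANGSTROM, [90.0, 90.0, 90.0]])
            w.write(u.atoms)


def write_series_tsv(path, times, ssd, eed) -> None:
    """Per-frame series as 3-column TSV: time_ps, ssd_nm, eed_nm."""
    arr = np.column_stack([times, ssd, eed])
    header = "time_ps\tssd_nm\teed_nm"
    np.savetxt(path, arr, delimiter="\t", header=header, comments="", fmt="%.6g")


def read_series_tsv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a 3-column (time, SSD, EED) series; header and comments ignored.

    This is the layout of the per-peptide SSD/EED series files produced by common MD post-processing, so
    ranking can be reproduced directly from such files.
    """
    rows = []
    for ln in Path(path).read_text().splitlines():
        s = ln.strip()
        if not s or s.startswith(("#", "@")):
            continue
        parts = s.replace(",", "\t").split()
        try:
            rows.append([float(v) for v in parts[:3]])
        except ValueError:
            continue  # header line
    if not rows:
        raise ValueError(f"{path}: no numeric rows")
    arr = np.asarray(rows)
    if arr.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (time, ssd, eed)")
    return arr[:, 0], arr[:, 1], arr[:, 2]
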