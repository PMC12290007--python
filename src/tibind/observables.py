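"""Per-frame adsorption observables and binding-state statistics.

Two scalar observables drive the whole analysis:

* SSD — surface separation distance: the z-distance from the peptide's
  mass-weighted centre of mass to the mean plane of the outermost Ti layer,
  minimised over the two (identical) slab faces under periodic boundaries.
* EED — end-to-end distance between the C-alpha atoms of residues 1 and 6.

A frame is adsorbed (bound) when SSD < 1 nm; the per-sequence binding
fraction is the percentage of bound frames over the production window, and
the EED is summarised separately over bound (EED_a) and unbound (EED_d)
frames.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .topology import (AtomClasses, ClassifyParams, SystemTopology,
                       TrajectoryFrame, classify_atoms, min_image,
                       peptide_bond_list)


@dataclass
class AnalysisParams:
    bound_threshold: float = 1.0        # nm; bound means SSD strictly below this
    layer_tolerance: float = 0.05       # nm; outer Ti layer window
    production_start: float = 0.0       # ps; frames before this are dropped
    min_dwell_frames: int = 1           # debounce: merge shorter runs (1 = off)
    strong_binder_percent: float = 50.0
    cluster_series_percent: float = 90.0
    population_sd: bool = True          # population (N) rather than sample (N-1) SDs

    def __post_init__(self) -> None:
        if self.bound_threshold <= 0:
            raise ValueError("bound_threshold must be positive")
        for p in (self.strong_binder_percent, self.cluster_series_percent):
            if not (0 < p <= 100):
                raise ValueError("percent parameters must be in (0, 100]")


@dataclass
class BindingProfile:
    """Per-frame SSD/EED series with derived binding statistics."""

    times: np.ndarray      # ps
    ssd: np.ndarray        # nm
    eed: np.ndarray        # nm
    bound: np.ndarray      # bool
    percent_bound: float
    eed_a: float | None    # mean EED over bound frames (None if never bound)
    std_a: float | None
    eed_d: float | None
    std_d: float | None
    events: list = field(default_factory=list)  # (t_start, t_end, "bound"/"unbound")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def unwrap_peptide(frame: TrajectoryFrame, topology: SystemTopology,
                   bonds: list[tuple[int, int]] | None = None,
                   max_bond: float = 0.25) -> np.ndarray:
    """Make the peptide whole across periodic boundaries.

    Atoms are placed at the minimum-image position relative to a traversal
    of the peptide bond graph rooted at its first atom; all other segments
    are returned untouched.  A post-unwrap bond longer than ``max_bond``
    (nm) means the molecule cannot be reconnected and raises.
    """
    coords = frame.coords.copy()
    pep = topology.peptide_indices
    if pep.size == 0:
        raise ValueError("no peptide atoms to unwrap")
    bonds = bonds if bonds is not None else peptide_bond_list(topology)
    adj: dict[int, list[int]] = {int(i): [] for i in pep}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)

    root = int(pep[0])
    seen = {root}
    queue = deque([root])
    while queue:
        a = queue.popleft()
        for b in adj[a]:
            if b in seen:
                continue
            d = min_image(coords[b] - coords[a], frame.box)
            coords[b] = coords[a] + d
            seen.add(b)
            queue.append(b)
    if len(seen) != pep.size:
        missing = sorted(set(map(int, pep)) - seen)
        raise ValueError(f"peptide bond graph is disconnected; unreached atoms {missing}")
    for a, b in bonds:
        blen = float(np.linalg.norm(coords[b] - coords[a]))
        if blen > max_bond:
            raise ValueError(f"broken peptide after unwrap: bond {a}-{b} = {blen:.3f} nm")
    return coords


def _peptide_com_z(coords: np.ndarray, topology: SystemTopology) -> float:
    pep = topology.peptide_indices
    w = topology.masses[pep]
    return float(np.average(coords[pep, 2], weights=w))


def compute_ssd(frame: TrajectoryFrame, classes: AtomClasses,
                topology: SystemTopology, coords: np.ndarray | None = None) -> float:
    """Surface separation distance (nm) for one frame.

    ``coords`` may supply pre-unwrapped coordinates; the periodic z-distance
    is taken to each face's outer-Ti mean plane and the smaller one returned.
    """
    if classes.TI_TOP.size == 0 or classes.TI_BOTTOM.size == 0:
        raise ValueError("empty outer Ti layer")
    coords = frame.coords if coords is None else coords
    com_z = _peptide_com_z(coords, topology)
    lz = frame.box[2]
    dists = []
    for layer in (classes.TI_TOP, classes.TI_BOTTOM):
        plane = float(frame.coords[layer, 2].mean())
        dz = com_z - plane
        dz -= lz * round(dz / lz)
        dists.append(abs(dz))
    return min(dists)


def compute_eed(frame: TrajectoryFrame, classes: AtomClasses,
                coords: np.ndarray | None = None) -> float:
    """End-to-end distance (nm): C-alpha of residue 1 to C-alpha of residue 6."""
    positions = sorted(classes.peptide_CA)
    if not positions:
        raise ValueError("no C-alpha atoms identified")
    coords = frame.coords if coords is None else coords
    a = classes.peptide_CA[positions[0]]
    b = classes.peptide_CA[positions[-1]]
    return float(np.linalg.norm(coords[b] - coords[a]))


def _debounce(bound: np.ndarray, min_dwell: int) -> np.ndarray:
    """Merge state runs shorter than ``min_dwell`` frames into the surrounding state."""
    if min_dwell <= 1 or bound.size == 0:
        return bound
    out = bound.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(out)
        for i, (start, stop, state) in enumerate(runs):
            if stop - start < min_dwell and 0 < i:  # keep the leading run as-is
                out[start:stop] = not state
                changed = True
                break
    return out


def _runs(bound: np.ndarray) -> list[tuple[int, int, bool]]:
    """Consecutive constant-state runs as (start, stop, state) with stop exclusive."""
    runs = []
    start = 0
    for i in range(1, len(bound) + 1):
        if i == len(bound) or bound[i] != bound[start]:
            runs.append((start, i, bool(bound[start])))
            start = i
    return runs


def _state_stats(values: np.ndarray, mask: np.ndarray, population: bool):
    if not mask.any():
        return None, None
    v = values[mask]
    ddof = 0 if population else 1
    sd = float(v.std(ddof=ddof)) if v.size > ddof else 0.0
    return float(v.mean()), sd


def binding_profile(frames: Iterable[TrajectoryFrame], topology: SystemTopology,
                    params: AnalysisParams | None = None,
                    classes: AtomClasses | None = None) -> BindingProfile:
    """Compute the SSD/EED series and binding statistics over a trajectory."""
    params = params or AnalysisParams()
    bonds = peptide_bond_list(topology)
    times, ssds, eeds = [], [], []
    for frame in frames:
        if frame.time < params.production_start:
            continue
        if classes is None:
            classes = classify_atoms(topology, frame,
                                     ClassifyParams(layer_tolerance=params.layer_tolerance))
        coords = unwrap_peptide(frame, topology, bonds=bonds)
        times.append(frame.time)
        ssds.append(compute_ssd(frame, classes, topology, coords=coords))
        eeds.append(compute_eed(frame, classes, coords=coords))
    if not times:
        raise ValueError("no frames in the production window")

    times = np.asarray(times)
    ssd = np.asarray(ssds)
    eed = np.asarray(eeds)
    bound = ssd < params.bound_threshold
    bound = _debounce(bound, params.min_dwell_frames)

    percent = 100.0 * bound.sum() / bound.size
    eed_a, std_a = _state_stats(eed, bound, params.population_sd)
    eed_d, std_d = _state_stats(eed, ~bound, params.population_sd)
    events = [(float(times[s]), float(times[e - 1]), "bound" if st else "unbound")
              for s, e, st in _runs(bound)]
    return BindingProfile(times=times, ssd=ssd, eed=eed, bound=bound,
                          percent_bound=percent, eed_a=eed_a, std_a=std_a,
                          eed_d=eed_d, std_d=std_d, events=events)


def profile_from_series(times, ssd, eed, params: AnalysisParams | None = None
                        ) -> BindingProfile:
    """Binding profile directly from a precomputed (time, SSD, EED) series.

    This is the entry point for deposited per-peptide series files: the
    bound/unbound classification and all derived statistics are identical
    to the trajectory path.
    """
    params = params or AnalysisParams()
    times = np.asarray(times, dtype=float)
    ssd = np.asarray(ssd, dtype=float)
    eed = np.asarray(eed, dtype=float)
    keep = times >= params.production_start
    if not keep.any():
        raise ValueError("no frames in the production window")
    times, ssd, eed = times[keep], ssd[keep], eed[keep]
    bound = _debounce(ssd < params.bound_threshold, params.min_dwell_frames)
    percent = 100.0 * bound.sum() / bound.size
    eed_a, std_a = _state_stats(eed, bound, params.population_sd)
    eed_d, std_d = _state_stats(eed, ~bound, params.population_sd)
    events = [(float(times[s]), float(times[e - 1]), "bound" if st else "unbound")
              for s, e, st in _runs(bound)]
    return BindingProfile(times=times, ssd=ssd, eed=eed, bound=bound,
                          percent_bound=percent, eed_a=eed_a, std_a=std_a,
                          eed_d=eed_d, std_d=std_d, events=events)


def rank_peptides(profiles: Mapping[str, BindingProfile]) -> pd.DataFrame:
    """Binding-potency ranking table.

    Rows (label, percent_bound, eed_a, std_a, eed_d, std_d) sorted by
    percent_bound descending, ties alphabetical.  Values are kept at full
    precision; round at the report layer.
    """
    if not profiles:
        raise ValueError("no profiles to rank")
    rows = [{"sequence": label, "percent_bound": p.percent_bound,
             "eed_a": p.eed_a, "std_a": p.std_a, "eed_d": p.eed_d, "std_d": p.std_d}
            for label, p in profiles.items()]
    df = pd.DataFrame(rows)
    df = df.sort_values(["percent_bound", "sequence"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def write_ranking_tsv(df: pd.DataFrame, path) -> None:
    """Ranking table as TSV with 2-decimal report rounding; absent values '-'."""
    out = df.copy()
    for col in ("percent_bound", "eed_a", "std_a", "eed_d", "std_d"):
        out[col] = out[col].map(lambda v: "-" if v is None or pd.isna(v) else f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)
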