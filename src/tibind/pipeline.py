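"""End-to-end orchestration: trajectory -> binding profile -> clusters -> RDFs.

A run reproduces the standard report artifacts for one system (per-frame
series, ranking row, cluster summary, RDF curves, conditional Na+ RDF) from
either real trajectory files or the synthetic generator, and a batch run
reproduces the ranking table, strong-binder subset and motif tables from a
directory of per-peptide SSD/EED series.  Every run writes a JSON manifest
echoing all parameters and the SHA-256 of each output, so identical inputs
and seed give byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .clustering import (cluster_summary, gromos_cluster, peptide_heavy_selection,
                         rmsd_matrix, write_assignments_tsv)
from .observables import (AnalysisParams, binding_profile, profile_from_series,
                          rank_peptides, write_ranking_tsv)
from .rdf import compute_rdf, conditional_rdf, first_peak, resolve_selection, write_rdf
from .sequences import (DedupPolicy, MotifMode, PositionScope, SequenceLibrary,
                        motif_pair_counts, motif_triplet_counts,
                        positional_motif_counts, select_by_rank, write_motif_table)
from .topology import ClassifyParams, classify_atoms

log = logging.getLogger("tibind.pipeline")


@dataclass
class PipelineConfig:
    output_dir: str = "tibind_out"
    seed: int = 0
    # input: either files ...
    topology_path: str | None = None
    trajectory_path: str | None = None
    # ... or a synthetic spec (dict of SyntheticSpec fields)
    synthetic: dict | None = None
    stride: int = 1
    cluster_stride: int = 1
    cluster_cutoff: float = 0.15        # nm, RMSD cutoff of the GROMOS clustering
    rdf_selections: list = field(default_factory=lambda: ["sidechain-N", "NTERM-N",
                                                          "CTERM-O"])
    rdf_targets: list = field(default_factory=lambda: ["surface OF", "surface OB"])
    conditional_target: str = "peptide-O"
    rdf_r_max: float = 1.2
    rdf_bin_width: float = 0.002
    analysis: dict = field(default_factory=dict)   # AnalysisParams overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_frames(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        from .synthetic import SyntheticSpec, generate_trajectory
        spec = SyntheticSpec(**cfg.synthetic)
        topo, frames, _ = generate_trajectory(spec, seed=cfg.seed)
        return topo, frames[::cfg.stride]
    if not cfg.topology_path or not cfg.trajectory_path:
        raise ValueError("config needs topology_path + trajectory_path or a "
                         "'synthetic' block")
    topo, _ = tio.load_structure(cfg.topology_path)
    frames = list(tio.load_trajectory(cfg.trajectory_path, topo, stride=cfg.stride))
    if not frames:
        raise ValueError(f"no frames read from {cfg.trajectory_path}")
    return topo, frames


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run observables -> clustering -> RDFs -> conditional RDF for one system.

    Clustering runs only when the peptide is bound more than the
    strong-binder threshold of the analysis parameters; a 0%-bound run
    skips it with a logged reason.  Returns the manifest dict.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = AnalysisParams(**cfg.analysis)
    manifest: dict = {"seed": cfg.seed, "params": vars(params).copy(),
                      "config": {k: v for k, v in vars(cfg).items()},
                      "stages": {}, "outputs": {}}

    def _stage(name):
        log.info("stage %s", name)

    try:
        _stage("load")
        topo, frames = _load_frames(cfg)
        manifest["stages"]["load"] = {"n_frames": len(frames),
                                      "n_atoms": topo.n_atoms,
                                      "sequence": topo.peptide_sequence}

        _stage("observables")
        classes = classify_atoms(topo, frames[0],
                                 ClassifyParams(layer_tolerance=params.layer_tolerance))
        profile = binding_profile(frames, topo, params, classes=classes)
        tio.write_series_tsv(out / "series.tsv", profile.times, profile.ssd,
                             profile.eed)
        manifest["stages"]["observables"] = {
            "percent_bound": profile.percent_bound, "eed_a": profile.eed_a,
            "std_a": profile.std_a, "eed_d": profile.eed_d, "std_d": profile.std_d,
            "n_events": len(profile.events)}

        _stage("clustering")
        if profile.percent_bound > params.strong_binder_percent and \
                int(profile.bound.sum()) >= 2:
            from .clustering import extract_bound_frames
            bound_frames, bound_idx = extract_bound_frames(frames, profile)
            sel = peptide_heavy_selection(topo)
            mat, kept = rmsd_matrix(bound_frames, sel, stride=cfg.cluster_stride,
                                    topology=topo)
            result = gromos_cluster(mat, cfg.cluster_cutoff,
                                    frame_ids=bound_idx[kept])
            write_assignments_tsv(result, profile, out / "clusters.tsv")
            summary = cluster_summary(result, profile)
            summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False,
                           float_format="%.4f")
            # representative (centroid) structures of the reported clusters
            pos_of_id = {int(fid): p for p, fid in enumerate(bound_idx)}
            for cid, cen in enumerate(result.centroids, start=1):
                if result.populations[cid - 1] <= 10.0:
                    continue
                rep_frame = bound_frames[pos_of_id[int(result.frame_ids[cen])]]
                tio.write_structure(out / f"cluster{cid}_representative.pdb",
                                    topo, rep_frame)
            manifest["stages"]["clustering"] = {
                "n_clusters": result.n_clusters,
                "populations": result.populations.tolist(),
                "cutoff_nm": cfg.cluster_cutoff, "frames_clustered": len(kept)}
        else:
            reason = (f"percent_bound {profile.percent_bound:.2f} <= "
                      f"{params.strong_binder_percent}")
            log.info("clustering skipped: %s", reason)
            manifest["stages"]["clustering"] = {"skipped": reason}

        _stage("rdf")
        rdf_info = {}
        for sel_expr in cfg.rdf_selections:
            sel_a = resolve_selection(sel_expr, topo, classes)
            if sel_a.size == 0:
                rdf_info[sel_expr] = {"skipped": "empty selection"}
                continue
            for tgt_expr in cfg.rdf_targets:
                sel_b = resolve_selection(tgt_expr, topo, classes)
                if sel_b.size == 0:
                    continue
                r = compute_rdf(frames, sel_a, sel_b, r_max=cfg.rdf_r_max,
                                bin_width=cfg.rdf_bin_width)
                fname = f"rdf_{sel_expr.replace(' ', '_')}__{tgt_expr.replace(' ', '_')}.tsv"
                write_rdf(r, out / fname, label_a=sel_expr, label_b=tgt_expr)
                try:
                    r_pk, g_pk, outside = first_peak(r)
                    rdf_info[fname] = {"r_peak_nm": r_pk, "g_peak": g_pk,
                                       "peak_outside_window": outside}
                except ValueError:
                    rdf_info[fname] = {"r_peak_nm": None}
        manifest["stages"]["rdf"] = rdf_info

        _stage("conditional_rdf")
        if classes.NA.size:
            sel_b = resolve_selection(cfg.conditional_target, topo, classes)
            c = conditional_rdf(frames, classes, sel_b, r_max=cfg.rdf_r_max,
                                bin_width=cfg.rdf_bin_width)
            write_rdf(c, out / "rdf_conditional_na.tsv", label_a="bridging NA",
                      label_b=cfg.conditional_target)
            manifest["stages"]["conditional_rdf"] = {
                "mean_bridging_na": c.mean_n_a,
                "r_peak_nm": first_peak(c)[0] if np.any(c.g > 0) else None}
        else:
            manifest["stages"]["conditional_rdf"] = {"skipped": "no Na+ ions"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str)
                                       + "\n")
    return manifest


def batch_rank(series_dir, output_dir, threshold_percent: float = 50.0,
               params: AnalysisParams | None = None) -> dict:
    """Ranking + strong-binder subset + motif tables from per-peptide series.

    ``series_dir`` holds one 3-column (time, SSD, EED) file per peptide,
    named ``<SEQUENCE>.tsv`` (any extension); this is the layout per-peptide
    SSD/EED series archives map onto.  Missing/unreadable files
    are listed and skipped with a warning.
    """
    params = params or AnalysisParams()
    series_dir = Path(series_dir)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = {}
    skipped = []
    for path in sorted(series_dir.iterdir()):
        if not path.is_file():
            continue
        label = path.stem.upper()
        try:
            t, ssd, eed = tio.read_series_tsv(path)
            profiles[label] = profile_from_series(t, ssd, eed, params)
        except (ValueError, OSError) as exc:
            skipped.append(path.name)
            log.warning("skipping %s: %s", path.name, exc)
    if not profiles:
        raise ValueError(f"no readable series in {series_dir}")

    ranking = rank_peptides(profiles)
    write_ranking_tsv(ranking, out / "ranking.tsv")

    library = SequenceLibrary(list(ranking["sequence"]), dedup_policy=DedupPolicy.none,
                              provenance={"source": str(series_dir)})
    fractions = {row.sequence: row.percent_bound for row in ranking.itertuples()}
    strong = select_by_rank(library, fractions, threshold_percent)
    strong.write(out / "strong_binders.txt")

    motif_outputs = {
        "pairs_ordered_all.tsv":
            motif_pair_counts(strong, MotifMode.ordered, PositionScope.all),
        "pairs_agnostic_all.tsv":
            motif_pair_counts(strong, MotifMode.order_agnostic, PositionScope.all),
        "pairs_interior.tsv":
            motif_pair_counts(strong, MotifMode.ordered, PositionScope.interior_2_5),
        "pairs_nterm.tsv":
            motif_pair_counts(strong, MotifMode.ordered, PositionScope.nterm_1_2),
        "pairs_cterm.tsv":
            motif_pair_counts(strong, MotifMode.ordered, PositionScope.cterm_5_6),
        "triplets_all.tsv": motif_triplet_counts(strong),
        "pairs_positional.tsv": positional_motif_counts(strong, k=2),
        "triplets_positional.tsv": positional_motif_counts(strong, k=3),
    }
    for name, rows in motif_outputs.items():
        write_motif_table(rows, out / name)

    manifest = {"n_series": len(profiles), "skipped": skipped,
                "threshold_percent": threshold_percent,
                "n_strong_binders": len(strong),
                "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
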