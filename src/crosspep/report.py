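"""End-to-end orchestration and summary reports.

``run_pipeline`` executes feature matching -> marker screening -> sequenced
marker QC -> orthology -> protease tallies for one configuration and writes
every stage output plus a JSON run manifest. ``overlap_report`` computes the
early/late marker-panel intersection (Venn counts).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .featmatch import PeakFeature, ToleranceModel, cluster_features, detection_frequencies, normalize_amplitudes
from .markers import call_markers, frequency_filter
from .orthology import (
    MappedMarker,
    OrthologMap,
    compare_panels,
    map_markers,
    select_top_markers,
)
from .proteases import load_motif_db, tallies_to_frame, tally_activity
from .seqqc import markers_from_panel, qc_marker

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage label."""


@dataclass
class RunConfig:
    """Paths and parameters for an end-to-end run."""

    output_dir: str
    peak_lists: List[str] = field(default_factory=list)
    group_map: Optional[str] = None
    case_group: str = "case"
    control_group: str = "control"
    standard_masses: List[float] = field(default_factory=list)
    rat_panel: Optional[str] = None
    human_panel: Optional[str] = None
    rat_fasta: Optional[str] = None
    human_fasta: Optional[str] = None
    ortholog_map: Optional[str] = None
    motif_db: Optional[str] = None
    protein_filter: Optional[str] = None
    alpha: float = 0.05
    frequency_threshold: float = 0.70
    top_n: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must lie in [0, 1]")
        for name in (
            "group_map", "rat_panel", "human_panel", "rat_fasta",
            "human_fasta", "ortholog_map", "motif_db",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config field {name}: no such file {path!r}")
        for path in self.peak_lists:
            if not Path(path).exists():
                raise FileNotFoundError(f"config field peak_lists: no such file {path!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _features_from_frame(df: pd.DataFrame) -> List[PeakFeature]:
    return [
        PeakFeature(
            sample_id=str(r.sample_id),
            mass=float(r.mass_da),
            migration_time=float(r.migration_min),
            amplitude=float(r.amplitude),
        )
        for r in df.itertuples(index=False)
    ]


def _marker_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "frequency_case": f"{r.frequency_case:.4f}",
                "frequency_control": f"{r.frequency_control:.4f}",
                "p_raw": f"{r.p_raw:.6g}",
                "p_adjusted": f"{r.p_adjusted:.6g}",
                "mean_amp_case": f"{r.mean_amp_case:.2f}",
                "mean_amp_control": f"{r.mean_amp_control:.2f}",
                "regulation": r.regulation or "none",
                "significant": r.significant,
            }
            for r in results
        ]
    )


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all configured stages; returns the run manifest.

    Stages whose inputs are not configured are skipped and noted in the
    manifest. On a stage failure the files already written by that stage are
    renamed with a ``.partial`` suffix and a stage-labeled error is raised.
    Re-running with an identical config gives byte-identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "parameters": {
            "alpha": config.alpha,
            "frequency_threshold": config.frequency_threshold,
            "top_n": config.top_n,
            "seed": config.seed,
        },
        "stages": {},
    }
    stage_files: List[Path] = []

    def _run_stage(name, fn):
        stage_files.clear()
        try:
            info = fn()
        except Exception as exc:
            for f in stage_files:
                if f.exists():
                    f.rename(f.with_suffix(f.suffix + ".partial"))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = info

    def _out(name: str) -> Path:
        p = out / name
        stage_files.append(p)
        return p

    markers_results = []
    rat_mapped: List[MappedMarker] = []
    human_mapped: List[MappedMarker] = []

    def stage_featmatch():
        if not config.peak_lists or config.group_map is None:
            return {"skipped": True}
        frames = [cio.read_peak_list(p) for p in config.peak_lists]
        features = _features_from_frame(pd.concat(frames, ignore_index=True))
        groups = cio.read_group_map(config.group_map)
        excluded: List[str] = []
        if config.standard_masses:
            features, excluded = normalize_amplitudes(
                features, config.standard_masses
            )
            groups = {s: g for s, g in groups.items() if s not in excluded}
        consensus = cluster_features(features, ToleranceModel(), groups=groups)
        cio.write_consensus_matrix(consensus, _out("consensus_matrix.tsv"))
        manifest["consensus"] = consensus  # handed to the next stage
        manifest["groups"] = groups
        return {
            "n_features": len(features),
            "n_samples_excluded": len(excluded),
            "n_consensus_peptides": len(consensus),
        }

    def stage_markers():
        consensus = manifest.pop("consensus", None)
        groups = manifest.pop("groups", None)
        if consensus is None:
            return {"skipped": True}
        retained = frequency_filter(
            consensus,
            config.case_group,
            config.control_group,
            threshold=config.frequency_threshold,
        )
        results = call_markers(
            retained,
            groups,
            config.case_group,
            config.control_group,
            alpha=config.alpha,
        )
        markers_results.extend(results)
        _marker_table(results).to_csv(
            _out("marker_results.tsv"), sep="\t", index=False
        )
        return {
            "n_after_frequency_filter": len(retained),
            "n_tested": len(results),
            "n_significant": sum(r.significant for r in results),
        }

    def stage_seqqc():
        if config.rat_panel is None or config.rat_fasta is None:
            return {"skipped": True}
        panel = cio.read_panel(config.rat_panel)
        proteins = cio.read_fasta(config.rat_fasta)
        markers = markers_from_panel(panel, species="rat")
        records = []
        for m in markers:
            try:
                rec = qc_marker(m, proteins)
                records.append(
                    {
                        "sequence": m.sequence,
                        "protein_id": m.protein_id,
                        "coordinates_ok": rec.coordinates_ok,
                        "n_occurrences": len(rec.occurrences),
                        "passed": rec.passed,
                    }
                )
            except Exception:
                records.append(
                    {
                        "sequence": m.sequence,
                        "protein_id": m.protein_id,
                        "coordinates_ok": False,
                        "n_occurrences": 0,
                        "passed": False,
                    }
                )
        pd.DataFrame(records).to_csv(_out("qc_report.tsv"), sep="\t", index=False)
        mapped, failed = map_markers(markers, proteins)
        rat_mapped.extend(mapped)
        return {
            "n_markers": len(markers),
            "n_mapped": len(mapped),
            "n_failed": len(failed),
        }

    def stage_orthology():
        if (
            not rat_mapped
            or config.human_panel is None
            or config.human_fasta is None
            or config.ortholog_map is None
        ):
            return {"skipped": True}
        panel = cio.read_panel(config.human_panel)
        proteins = cio.read_fasta(config.human_fasta)
        markers = markers_from_panel(panel, species="human")
        top = select_top_markers(markers, n=config.top_n)
        mapped, _ = map_markers(top, proteins)
        human_mapped.extend(mapped)
        omap = OrthologMap(cio.read_ortholog_map(config.ortholog_map))
        comparison = compare_panels(rat_mapped, human_mapped, omap)
        pd.DataFrame(
            [
                {
                    "rat_sequence": m.rat_marker.marker.sequence,
                    "human_sequence": m.human_marker.marker.sequence,
                    "tier": m.tier,
                    "protein": m.rat_marker.marker.protein_name,
                    "regulation": m.rat_marker.regulation,
                }
                for m in comparison.matches
            ],
            columns=["rat_sequence", "human_sequence", "tier", "protein", "regulation"],
        ).to_csv(_out("orthology_matches.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {"species": k[0], "protein": k[1], "n_up": v[0], "n_down": v[1]}
                for k, v in sorted(comparison.regulation_summary.items())
            ]
        ).to_csv(_out("regulation_summary.tsv"), sep="\t", index=False)
        return {"tier_counts": comparison.tier_counts}

    def stage_proteases():
        if not rat_mapped:
            return {"skipped": True}
        db = load_motif_db(config.motif_db)
        tallies, provenance = tally_activity(
            rat_mapped, db, protein_filter=config.protein_filter
        )
        tallies_to_frame(tallies).to_csv(
            _out("protease_tallies.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "marker": p.marker_sequence,
                    "terminus": p.terminus,
                    "context6": p.context6,
                    "regulation": p.regulation,
                    "proteases": ",".join(p.proteases),
                    "groups": ",".join(p.groups),
                    "mismatches": p.mismatches,
                }
                for p in provenance
            ],
            columns=[
                "marker", "terminus", "context6", "regulation",
                "proteases", "groups", "mismatches",
            ],
        ).to_csv(_out("protease_provenance.tsv"), sep="\t", index=False)
        return {
            "n_groups": len(tallies),
            "directions": {g: t.direction for g, t in sorted(tallies.items())},
        }

    _run_stage("featmatch", stage_featmatch)
    _run_stage("markers", stage_markers)
    _run_stage("seqqc", stage_seqqc)
    _run_stage("orthology", stage_orthology)
    _run_stage("proteases", stage_proteases)

    manifest.pop("consensus", None)
    manifest.pop("groups", None)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@dataclass
class OverlapReport:
    n_early: int
    n_late: int
    n_shared: int
    shared_sequences: List[str]

    @property
    def pct_early_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_early if self.n_early else 0.0


def overlap_report(
    early_panel: pd.DataFrame,
    late_panel: pd.DataFrame,
    modification_sensitive: bool = True,
) -> OverlapReport:
    """Early/late marker-panel intersection by sequence identity.

    By default modification-coded sequences must match exactly (modification
    variants are separate markers); ``modification_sensitive=False`` folds
    the sequences to uppercase first.
    """
    def key(seq: str) -> str:
        return seq if modification_sensitive else seq.upper()

    early = {key(s) for s in early_panel["sequence"]}
    late = {key(s) for s in late_panel["sequence"]}
    shared = sorted(early & late)
    return OverlapReport(
        n_early=len(early),
        n_late=len(late),
        n_shared=len(shared),
        shared_sequences=shared,
    )


def recompute_published_counts(
    late_rat_panel: pd.DataFrame,
    early_rat_panel: pd.DataFrame,
    human_ckd_panel: pd.DataFrame,
    human_cvd_panel: pd.DataFrame,
    rat_proteins: Dict[str, str],
    human_proteins: Dict[str, str],
    ortholog_pairs: Sequence[Tuple[str, str, int]],
    collagen_name: str = "COL1A1",
    top_n: int = 50,
) -> Dict:
    """Recompute the headline summary counts from supplied marker tables.

    Deterministic table computations: orthology tier counts of the late rat
    panel against the top-N human CKD and CVD markers, per-species collagen
    regulation splits, the early/late overlap, and the grouped protease
    tallies for collagen fragments.
    """
    omap = OrthologMap(list(ortholog_pairs))
    db = load_motif_db()

    late_markers = markers_from_panel(late_rat_panel, species="rat")
    rat_mapped, _ = map_markers(late_markers, rat_proteins)

    result: Dict = {}
    for label, human_panel in (("ckd", human_ckd_panel), ("cvd", human_cvd_panel)):
        markers = markers_from_panel(human_panel, species="human")
        top = select_top_markers(markers, n=top_n)
        mapped, _ = map_markers(top, human_proteins)
        comparison = compare_panels(rat_mapped, mapped, omap)
        result[f"tier_counts_{label}"] = comparison.tier_counts
        up = sum(
            1
            for m in mapped
            if m.marker.protein_name == collagen_name and m.regulation == "up"
        )
        down = sum(
            1
            for m in mapped
            if m.marker.protein_name == collagen_name and m.regulation == "down"
        )
        result[f"{label}_{collagen_name}_up_down"] = (up, down)

    rat_up = sum(
        1
        for m in rat_mapped
        if m.marker.protein_name == collagen_name and m.regulation == "up"
    )
    rat_total = sum(
        1 for m in rat_mapped if m.marker.protein_name == collagen_name
    )
    result[f"rat_{collagen_name}_up_total"] = (rat_up, rat_total)

    overlap = overlap_report(early_rat_panel, late_rat_panel)
    result["early_late_overlap"] = overlap.n_shared
    result["n_early"] = overlap.n_early

    tallies, _ = tally_activity(rat_mapped, db, protein_filter=collagen_name)
    result["rat_protease_tallies"] = {
        g: (t.n_sites_up, t.n_sites_down) for g, t in sorted(tallies.items())
    }
    return result
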