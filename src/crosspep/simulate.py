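"""Synthetic two-species case/control peptide studies.

Collagen-like reference proteins carry planted cleavage motifs at known cut
positions; fragments are cut exactly at those motif midpoints, so the
re-extracted terminal contexts equal the planted motifs. Per-sample
amplitudes are log-normal around group means (cases scaled by planted fold
changes, or by the case:control cleavage-rate ratio of the terminal motif
groups), modulated by a Poisson cleavage-count factor; detection is logistic
in log-amplitude; measured mass and migration time carry Gaussian noise.
Ground truth is a sidecar never read by the analysis stages.
"""

from __future__ import annotations

import ast
import math
import os
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as cio
from .markers import bh_adjust, ranksum_test
from .proteases import default_grouping, load_motif_db
from .seqqc import MigrationModel, count_basic_residues, theoretical_mass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# collagen-flavoured composition: glycine/proline/alanine-rich background
_AA_WEIGHTS = np.array(
    [0.04, 0.005, 0.04, 0.05, 0.02, 0.26, 0.01, 0.02, 0.04, 0.03,
     0.01, 0.02, 0.20, 0.04, 0.05, 0.05, 0.03, 0.03, 0.005, 0.03]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

MIN_SITE_GAP = 6  # motifs occupy 6 residues around the cut; no overlap allowed


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_case: int = 10
    n_control: int = 7
    n_proteins: int = 2
    protein_length: int = 600
    planted_fold_changes: Tuple[float, ...] = (4.0, 4.0, 0.25)
    planted_protease_weights: Mapping[str, float] = field(
        default_factory=lambda: {"ADAMTS5": 4.0}
    )
    amplitude_noise_sigma: float = 0.5  # natural-log scale SD
    detection_midpoint: float = math.log(50.0)  # ln(amplitude) at 50% detection
    detection_slope: float = 2.0
    mass_error_ppm_sigma: float = 10.0
    mt_error_min_sigma: float = 0.3
    species: Tuple[str, ...] = ("rat", "human")
    ortholog_mutation_rate: float = 0.0
    cut_spacing_min: int = 15
    cut_spacing_max: int = 35
    sites_per_protein: Optional[int] = None
    explicit_sites: Optional[Tuple[Tuple[int, int, str], ...]] = None
    motifs: Optional[Tuple[str, ...]] = None  # default: all bundled motifs
    base_amplitude_mu: float = math.log(2000.0)
    base_amplitude_sigma: float = 0.8
    cleavage_count_scale: int = 200
    standard_masses: Tuple[float, ...] = (1046.54, 2191.07, 3016.49)
    standard_amplitude: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_proteins", "protein_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if any(f <= 0 for f in self.planted_fold_changes):
            raise ConfigurationError("fold changes must be positive")
        if any(w <= 0 for w in self.planted_protease_weights.values()):
            raise ConfigurationError("protease weights must be positive")
        for name in (
            "amplitude_noise_sigma",
            "mass_error_ppm_sigma",
            "mt_error_min_sigma",
            "base_amplitude_sigma",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.cut_spacing_min < MIN_SITE_GAP + 4:
            raise ConfigurationError("cut spacing too small to host distinct motifs")
        if self.cut_spacing_max < self.cut_spacing_min:
            raise ConfigurationError("cut_spacing_max < cut_spacing_min")

    def to_file(self, path: str | os.PathLike) -> None:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, Mapping):
                value = dict(value)
            lines.append(f"{f.name}: {value!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "SimulationConfig":
        kwargs = {}
        names = {f.name for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            if key not in names:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)


@dataclass(frozen=True)
class CutSite:
    protein_index: int
    position: int  # 1-based: scissile bond between residue `position` and +1
    motif: str  # 6-residue context written into the protein


@dataclass(frozen=True)
class FragmentTruth:
    fragment_id: str
    protein_index: int
    start: int  # 1-based inclusive
    stop: int
    n_motif: str
    c_motif: str
    fold_change: float
    planted: bool

    @property
    def regulation(self) -> Optional[str]:
        if self.fold_change > 1:
            return "up"
        if self.fold_change < 1:
            return "down"
        return None


def _motif_pool(config: SimulationConfig) -> List[str]:
    if config.motifs is not None:
        pool = list(config.motifs)
    else:
        pool = load_motif_db().contexts
    for m in pool:
        if len(m) != 6:
            raise ConfigurationError(f"motif {m!r} is not 6 residues")
    return pool


def _plan_sites(config: SimulationConfig, rng: np.random.Generator) -> List[CutSite]:
    length = config.protein_length
    if config.explicit_sites is not None:
        sites = sorted(config.explicit_sites)
        by_protein: Dict[int, List[int]] = {}
        for idx, pos, motif in sites:
            if not 0 <= idx < config.n_proteins:
                raise ConfigurationError(f"site protein index {idx} out of range")
            if not 3 <= pos <= length - 3:
                raise ConfigurationError(
                    f"cut position {pos} does not fit a 6-residue motif "
                    f"in a {length}-residue protein"
                )
            if len(motif) != 6:
                raise ConfigurationError(f"motif {motif!r} is not 6 residues")
            by_protein.setdefault(idx, []).append(pos)
        for positions in by_protein.values():
            gaps = np.diff(sorted(positions))
            if len(gaps) and gaps.min() < MIN_SITE_GAP:
                raise ConfigurationError("planted motifs overlap")
        return [CutSite(i, p, m) for i, p, m in sites]

    pool = _motif_pool(config)
    capacity = (length - MIN_SITE_GAP) // config.cut_spacing_min
    n_sites = config.sites_per_protein
    if n_sites is not None and n_sites > capacity:
        raise ConfigurationError(
            f"{n_sites} motifs do not fit in a {length}-residue protein "
            f"at spacing >= {config.cut_spacing_min}"
        )
    sites: List[CutSite] = []
    for idx in range(config.n_proteins):
        positions: List[int] = []
        pos = int(rng.integers(config.cut_spacing_min, config.cut_spacing_max + 1))
        while pos <= length - 3 and (n_sites is None or len(positions) < n_sites):
            positions.append(pos)
            pos += int(rng.integers(config.cut_spacing_min, config.cut_spacing_max + 1))
        if n_sites is not None and len(positions) < n_sites:
            raise ConfigurationError(
                f"could not place {n_sites} motifs in a {length}-residue protein"
            )
        for p in positions:
            motif = pool[int(rng.integers(len(pool)))]
            sites.append(CutSite(idx, p, motif))
    return sites


def generate_references(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[str], List[CutSite]]:
    """Random collagen-like proteins with planted motif contexts.

    Returns (protein sequences, planted cut sites); protein ``i`` hosts a cut
    between residues ``position`` and ``position+1`` whose surrounding six
    residues spell the planted motif.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites = _plan_sites(config, rng)
    proteins: List[str] = []
    for idx in range(config.n_proteins):
        residues = list(
            rng.choice(list(AMINO_ACIDS), size=config.protein_length, p=_AA_WEIGHTS)
        )
        for site in sites:
            if site.protein_index == idx:
                residues[site.position - 3 : site.position + 3] = list(site.motif)
        proteins.append("".join(residues))
    return proteins, sites


def _motif_weight(motif: str, weights: Mapping[str, float]) -> float:
    """Case:control rate ratio of a motif via its protease groups (geo-mean)."""
    entry = load_motif_db().get(motif)
    if entry is None:
        return 1.0
    groups = sorted({default_grouping(p) for p in entry.proteases})
    w = [float(weights.get(g, 1.0)) for g in groups]
    return float(np.exp(np.mean(np.log(w))))


def simulate_fragments(
    proteins: Sequence[str],
    sites: Sequence[CutSite],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[FragmentTruth]:
    """Cut fragments between consecutive planted sites of each protein.

    Fragment fold change = sqrt(w_N * w_C) over its two terminal motifs'
    case:control cleavage-rate ratios; a subset of fragments is overridden
    with the configured planted fold changes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    by_protein: Dict[int, List[CutSite]] = {}
    for site in sites:
        by_protein.setdefault(site.protein_index, []).append(site)
    fragments: List[FragmentTruth] = []
    for idx in sorted(by_protein):
        ordered = sorted(by_protein[idx], key=lambda s: s.position)
        for left, right in zip(ordered, ordered[1:]):
            start, stop = left.position + 1, right.position
            w = math.sqrt(
                _motif_weight(left.motif, config.planted_protease_weights)
                * _motif_weight(right.motif, config.planted_protease_weights)
            )
            fragments.append(
                FragmentTruth(
                    fragment_id=f"F{len(fragments):03d}",
                    protein_index=idx,
                    start=start,
                    stop=stop,
                    n_motif=left.motif,
                    c_motif=right.motif,
                    fold_change=w,
                    planted=False,
                )
            )
    n_planted = min(len(config.planted_fold_changes), len(fragments))
    if n_planted:
        chosen = rng.choice(len(fragments), size=n_planted, replace=False)
        for slot, fold in zip(sorted(int(c) for c in chosen),
                              config.planted_fold_changes):
            fragments[slot] = replace(
                fragments[slot], fold_change=float(fold), planted=True
            )
    return fragments


def fragment_sequence(fragment: FragmentTruth, proteins: Sequence[str]) -> str:
    return proteins[fragment.protein_index][fragment.start - 1 : fragment.stop]


@dataclass
class SpeciesStudy:
    species: str
    proteins: Dict[str, str]  # protein_id -> sequence
    protein_names: Dict[str, str]  # protein_id -> shared cross-species name
    fragments: List[FragmentTruth]
    peak_lists: pd.DataFrame  # concatenated per-sample rows
    panel: pd.DataFrame
    groups: Dict[str, str]  # sample_id -> "case" / "control"
    amplitudes: pd.DataFrame  # fragments x samples, 0 = not detected


def _protein_id(species: str, index: int) -> str:
    return f"{species}_P{index:02d}"


def _protein_name(index: int) -> str:
    return f"COLSIM{index:02d}"


def simulate_samples(
    proteins: Sequence[str],
    fragments: Sequence[FragmentTruth],
    config: SimulationConfig,
    species: str,
    rng: Optional[np.random.Generator] = None,
    migration_model: Optional[MigrationModel] = None,
) -> SpeciesStudy:
    """Simulate one species' cohort: peak lists, amplitudes and panel table."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    model = migration_model or MigrationModel()
    samples = [f"{species}_case_{i + 1:02d}" for i in range(config.n_case)] + [
        f"{species}_control_{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = {
        s: ("case" if "_case_" in s else "control") for s in samples
    }
    k_scale = config.cleavage_count_scale

    seqs = [fragment_sequence(f, proteins) for f in fragments]
    theo_mass = np.array([theoretical_mass(s) for s in seqs])
    base_time = np.array(
        [model.predict(count_basic_residues(s)) for s in seqs]
    )
    base_amp = np.exp(
        rng.normal(config.base_amplitude_mu, config.base_amplitude_sigma,
                   size=len(fragments))
    )

    amp = np.zeros((len(fragments), len(samples)))
    peak_rows: List[dict] = []
    for j, sample in enumerate(samples):
        is_case = groups[sample] == "case"
        for i, frag in enumerate(fragments):
            lam = k_scale * (frag.fold_change if is_case else 1.0)
            count = rng.poisson(lam)
            if count == 0:
                continue
            amplitude = (
                base_amp[i]
                * (count / k_scale)
                * math.exp(rng.normal(0.0, config.amplitude_noise_sigma))
            )
            p_detect = expit(
                config.detection_slope
                * (math.log(amplitude) - config.detection_midpoint)
            )
            if rng.random() >= p_detect:
                continue
            amp[i, j] = amplitude
            mass = theo_mass[i] * (
                1.0 + rng.normal(0.0, config.mass_error_ppm_sigma) * 1e-6
            )
            mtime = base_time[i] + rng.normal(0.0, config.mt_error_min_sigma)
            peak_rows.append(
                {
                    "sample_id": sample,
                    "mass_da": mass,
                    "migration_min": max(mtime, 1.0),
                    "amplitude": amplitude,
                }
            )
        # internal standards, always present
        for k, std_mass in enumerate(config.standard_masses):
            amplitude = config.standard_amplitude * math.exp(
                rng.normal(0.0, config.amplitude_noise_sigma)
            )
            mass = std_mass * (
                1.0 + rng.normal(0.0, config.mass_error_ppm_sigma) * 1e-6
            )
            peak_rows.append(
                {
                    "sample_id": sample,
                    "mass_da": mass,
                    "migration_min": 22.0 + 6.0 * k
                    + rng.normal(0.0, config.mt_error_min_sigma),
                    "amplitude": amplitude,
                }
            )

    peak_lists = pd.DataFrame(peak_rows, columns=cio.PEAK_COLUMNS)
    amplitudes = pd.DataFrame(
        amp, index=[f.fragment_id for f in fragments], columns=samples
    )

    # Sequenced panel: empirical statistics computed from the simulated cohort
    case_cols = [s for s in samples if groups[s] == "case"]
    ctrl_cols = [s for s in samples if groups[s] == "control"]
    p_raw = [
        ranksum_test(amplitudes.loc[f.fragment_id, case_cols].to_numpy(),
                     amplitudes.loc[f.fragment_id, ctrl_cols].to_numpy())
        for f in fragments
    ]
    p_adj = bh_adjust(p_raw)
    rows = []
    for f, seq, p in zip(fragments, seqs, p_adj):
        mc = float(amplitudes.loc[f.fragment_id, case_cols].mean())
        mctl = float(amplitudes.loc[f.fragment_id, ctrl_cols].mean())
        if mc == mctl:
            regulation = "none"
        else:
            regulation = "up" if mc > mctl else "down"
        rows.append(
            {
                "sequence": seq,
                "protein_name": _protein_name(f.protein_index),
                "start": f.start,
                "stop": f.stop,
                "p_adjusted": float(p),
                "mean_amp_case": mc,
                "mean_amp_control": mctl,
                "regulation": regulation,
                "protein_id": _protein_id(species, f.protein_index),
            }
        )
    panel = pd.DataFrame(rows, columns=cio.PANEL_COLUMNS + ["protein_id"])

    protein_ids = {
        _protein_id(species, i): p for i, p in enumerate(proteins)
    }
    protein_names = {
        _protein_id(species, i): _protein_name(i) for i in range(len(proteins))
    }
    return SpeciesStudy(
        species=species,
        proteins=protein_ids,
        protein_names=protein_names,
        fragments=list(fragments),
        peak_lists=peak_lists,
        panel=panel,
        groups=groups,
        amplitudes=amplitudes,
    )


@dataclass
class SimulationTruth:
    planted_markers: pd.DataFrame  # sequence, species, fold, regulation, ...
    protease_directions: Dict[str, str]
    fragment_map: pd.DataFrame  # fragment -> (protein, start, stop, motifs)


@dataclass
class Study:
    config: SimulationConfig
    species_studies: Dict[str, SpeciesStudy]
    ortholog_pairs: List[Tuple[str, str, int]]
    truth: SimulationTruth

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_file(out / "config.txt")
        for species, study in self.species_studies.items():
            cio.write_fasta(study.proteins, out / f"{species}_proteins.fasta")
            cio.write_peak_list(study.peak_lists, out / f"{species}_peaks.tsv")
            cio.write_panel(study.panel, out / f"{species}_panel.tsv")
            cio.write_group_map(study.groups, out / f"{species}_groups.tsv")
        cio.write_ortholog_map(self.ortholog_pairs, out / "ortholog_map.tsv")
        self.truth.planted_markers.to_csv(
            out / "truth_planted_markers.tsv", sep="\t", index=False
        )
        self.truth.fragment_map.to_csv(
            out / "truth_fragment_map.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.truth.protease_directions.items()),
            columns=["protease_group", "direction"],
        ).to_csv(out / "truth_protease_directions.tsv", sep="\t", index=False)


def _mutate_outside_motifs(
    protein: str,
    sites: Sequence[CutSite],
    protein_index: int,
    rate: float,
    rng: np.random.Generator,
) -> str:
    if rate <= 0:
        return protein
    protected = set()
    for site in sites:
        if site.protein_index == protein_index:
            protected.update(range(site.position - 3, site.position + 3))
    residues = list(protein)
    for i in range(len(residues)):
        if i in protected:
            continue
        if rng.random() < rate:
            residues[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(residues)


def simulate_study(config: SimulationConfig) -> Study:
    """Run the full two-species generator for one configuration.

    A fixed seed gives byte-identical study directories.
    """
    rng = np.random.default_rng(config.seed)
    proteins, sites = generate_references(config, rng)
    fragments = simulate_fragments(proteins, sites, config, rng)

    species_studies: Dict[str, SpeciesStudy] = {}
    planted_rows = []
    fragment_rows = []
    for species in config.species:
        if species == config.species[0]:
            sp_proteins = list(proteins)
        else:
            sp_proteins = [
                _mutate_outside_motifs(
                    p, sites, i, config.ortholog_mutation_rate, rng
                )
                for i, p in enumerate(proteins)
            ]
        study = simulate_samples(sp_proteins, fragments, config, species, rng)
        species_studies[species] = study
        for f in fragments:
            seq = fragment_sequence(f, sp_proteins)
            fragment_rows.append(
                {
                    "fragment_id": f.fragment_id,
                    "species": species,
                    "protein_id": _protein_id(species, f.protein_index),
                    "start": f.start,
                    "stop": f.stop,
                    "n_motif": f.n_motif,
                    "c_motif": f.c_motif,
                    "fold_change": f.fold_change,
                    "planted": f.planted,
                }
            )
            if f.planted:
                planted_rows.append(
                    {
                        "sequence": seq,
                        "species": species,
                        "fold_change": f.fold_change,
                        "regulation": f.regulation,
                        "fragment_id": f.fragment_id,
                    }
                )

    directions = {}
    for group, w in config.planted_protease_weights.items():
        directions[group] = (
            "increased" if w > 1 else "decreased" if w < 1 else "unclear"
        )
    truth = SimulationTruth(
        planted_markers=pd.DataFrame(
            planted_rows,
            columns=["sequence", "species", "fold_change", "regulation", "fragment_id"],
        ),
        protease_directions=directions,
        fragment_map=pd.DataFrame(
            fragment_rows,
            columns=[
                "fragment_id", "species", "protein_id", "start", "stop",
                "n_motif", "c_motif", "fold_change", "planted",
            ],
        ),
    )
    pairs = []
    if len(config.species) >= 2:
        first, second = config.species[0], config.species[1]
        pairs = [
            (_protein_id(first, i), _protein_id(second, i), 0)
            for i in range(config.n_proteins)
        ]
    return Study(
        config=config,
        species_studies=species_studies,
        ortholog_pairs=pairs,
        truth=truth,
    )
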