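"""CE-MS feature matching: tolerance windows, normalization, consensus clustering.

Per-sample peak features (neutral mass, normalized migration time, amplitude)
are aligned across samples into consensus peptides using mass- and
time-dependent tolerance windows: +/-50 ppm below 4 kDa ramping linearly to
+/-150 ppm at 6 kDa, and +/-1 min at 19 min ramping linearly to +/-2.5 min at
50 min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

MASS_MIN_DA = 800.0
MASS_MAX_DA = 25000.0


@dataclass(frozen=True)
class PeakFeature:
    """One detected polypeptide in one sample."""

    sample_id: str
    mass: float  # neutral deconvoluted mass, Da
    migration_time: float  # normalized CE migration time, min
    amplitude: float  # normalized signal intensity, >= 0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.migration_time <= 0:
            raise ValueError(
                f"migration_time must be positive, got {self.migration_time}"
            )
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def in_analyzed_range(self) -> bool:
        return MASS_MIN_DA <= self.mass <= MASS_MAX_DA


@dataclass(frozen=True)
class ToleranceModel:
    """Piecewise-linear clustering tolerance windows.

    Mass: flat ``ppm_low`` below ``mass_lo``, linear ramp to ``ppm_high`` at
    ``mass_hi``, flat above. Time: flat ``time_low`` up to ``time_lo`` minutes,
    linear ramp to ``time_high`` at ``time_hi``, flat beyond.
    """

    mass_lo: float = 4000.0
    mass_hi: float = 6000.0
    ppm_low: float = 50.0
    ppm_high: float = 150.0
    time_lo: float = 19.0
    time_hi: float = 50.0
    time_low: float = 1.0
    time_high: float = 2.5

    def mass_tolerance(self, mass: float) -> float:
        """ppm half-window at the given mass."""
        if mass <= 0:
            raise ValueError(f"mass must be positive, got {mass}")
        return float(
            np.interp(mass, [self.mass_lo, self.mass_hi], [self.ppm_low, self.ppm_high])
        )

    def time_tolerance(self, migration_time: float) -> float:
        """minutes half-window at the given migration time."""
        if migration_time <= 0:
            raise ValueError(f"migration_time must be positive, got {migration_time}")
        return float(
            np.interp(
                migration_time,
                [self.time_lo, self.time_hi],
                [self.time_low, self.time_high],
            )
        )

    def mass_window_da(self, mass: float) -> float:
        return mass * self.mass_tolerance(mass) * 1e-6


@dataclass
class ConsensusPeptide:
    """A cross-sample cluster of peak features treated as one molecule."""

    cluster_id: int
    mass: float  # representative (running mean of members)
    migration_time: float
    amplitudes: Dict[str, float] = field(default_factory=dict)  # per sample
    frequencies: Dict[str, float] = field(default_factory=dict)  # per group

    @property
    def n_samples(self) -> int:
        return len(self.amplitudes)


class _Cluster:
    __slots__ = ("members", "sum_mass", "sum_time")

    def __init__(self, feature: PeakFeature) -> None:
        self.members: Dict[str, PeakFeature] = {feature.sample_id: feature}
        self.sum_mass = feature.mass
        self.sum_time = feature.migration_time

    @property
    def mass(self) -> float:
        return self.sum_mass / len(self.members)

    @property
    def migration_time(self) -> float:
        return self.sum_time / len(self.members)

    def add(self, feature: PeakFeature) -> None:
        self.members[feature.sample_id] = feature
        self.sum_mass += feature.mass
        self.sum_time += feature.migration_time

    def remove(self, sample_id: str) -> PeakFeature:
        feature = self.members.pop(sample_id)
        self.sum_mass -= feature.mass
        self.sum_time -= feature.migration_time
        return feature


def _distance(
    feature: PeakFeature, cluster: _Cluster, tol: ToleranceModel
) -> Optional[float]:
    """Normalized window distance, or None if outside the window."""
    rep_mass = cluster.mass
    rep_time = cluster.migration_time
    mass_win = tol.mass_window_da(rep_mass)
    time_win = tol.time_tolerance(rep_time)
    dm = abs(feature.mass - rep_mass) / mass_win
    dt = abs(feature.migration_time - rep_time) / time_win
    if dm <= 1.0 and dt <= 1.0:
        return dm + dt
    return None


def normalize_amplitudes(
    features: Sequence[PeakFeature],
    standard_masses: Sequence[float],
    tolerance: ToleranceModel | None = None,
    reference_level: float | None = None,
) -> Tuple[List[PeakFeature], List[str]]:
    """Scale each sample's amplitudes to the internal-standard reference level.

    The per-sample scale factor is ``reference_level / median(matched standard
    amplitudes)``; when ``reference_level`` is None it defaults to the median
    across samples of those per-sample medians. Samples in which no standard
    is matched are excluded from clustering and reported.

    Returns (normalized features, excluded sample ids).
    """
    tol = tolerance or ToleranceModel()
    by_sample: Dict[str, List[PeakFeature]] = {}
    for f in features:
        by_sample.setdefault(f.sample_id, []).append(f)

    medians: Dict[str, float] = {}
    excluded: List[str] = []
    for sample_id, feats in by_sample.items():
        matched = [
            f.amplitude
            for f in feats
            for m in standard_masses
            if abs(f.mass - m) <= tol.mass_window_da(m)
        ]
        if not matched:
            excluded.append(sample_id)
            logger.warning(
                "sample %s: no internal standard matched; excluded from clustering",
                sample_id,
            )
            continue
        medians[sample_id] = float(np.median(matched))

    if not medians:
        return [], excluded
    ref = reference_level if reference_level is not None else float(
        np.median(list(medians.values()))
    )

    normalized: List[PeakFeature] = []
    for sample_id, feats in by_sample.items():
        if sample_id in medians:
            scale = ref / medians[sample_id]
            normalized.extend(
                PeakFeature(f.sample_id, f.mass, f.migration_time, f.amplitude * scale)
                for f in feats
            )
    return normalized, excluded


def cluster_features(
    features: Iterable[PeakFeature],
    tolerance: ToleranceModel | None = None,
    groups: Mapping[str, str] | None = None,
) -> List[ConsensusPeptide]:
    """Greedy incremental clustering of features into consensus peptides.

    Features are visited in order of descending amplitude. Each joins the
    nearest existing cluster whose representative lies within both tolerance
    windows (distance = |dmass|/mass_window + |dtime|/time_window); otherwise
    it founds a new cluster. A cluster holds at most one feature per sample:
    on collision the nearer feature keeps the slot and the loser founds a new
    cluster. Features outside the analyzed 0.8-25 kDa range are dropped.
    """
    tol = tolerance or ToleranceModel()
    feats = [f for f in features if f.in_analyzed_range()]
    order = sorted(
        feats, key=lambda f: (-f.amplitude, f.mass, f.migration_time, f.sample_id)
    )

    clusters: List[_Cluster] = []
    for feature in order:
        best: Optional[_Cluster] = None
        best_d = np.inf
        for cluster in clusters:
            d = _distance(feature, cluster, tol)
            if d is not None and d < best_d:
                best, best_d = cluster, d
        if best is None:
            clusters.append(_Cluster(feature))
            continue
        incumbent = best.members.get(feature.sample_id)
        if incumbent is None:
            best.add(feature)
        else:
            d_inc = _distance(incumbent, best, tol)
            if d_inc is not None and d_inc <= best_d:
                clusters.append(_Cluster(feature))  # loser founds a new cluster
            else:
                best.remove(feature.sample_id)
                best.add(feature)
                clusters.append(_Cluster(incumbent))

    out: List[ConsensusPeptide] = []
    for i, cluster in enumerate(clusters):
        cp = ConsensusPeptide(
            cluster_id=i,
            mass=cluster.mass,
            migration_time=cluster.migration_time,
            amplitudes={s: f.amplitude for s, f in sorted(cluster.members.items())},
        )
        if groups is not None:
            cp.frequencies = detection_frequencies(cp.amplitudes, groups)
        out.append(cp)
    return out


def detection_frequencies(
    amplitudes: Mapping[str, float], groups: Mapping[str, str]
) -> Dict[str, float]:
    """Per-group fraction of samples in which the peptide was detected."""
    sizes: Dict[str, int] = {}
    for g in groups.values():
        sizes[g] = sizes.get(g, 0) + 1
    hits: Dict[str, int] = {g: 0 for g in sizes}
    for sample_id in amplitudes:
        g = groups.get(sample_id)
        if g is not None:
            hits[g] += 1
    return {g: hits[g] / sizes[g] for g in sizes}


def within_window(
    feature_mass: float,
    feature_time: float,
    rep_mass: float,
    rep_time: float,
    tolerance: ToleranceModel | None = None,
) -> bool:
    """Post-hoc membership check against a cluster representative."""
    tol = tolerance or ToleranceModel()
    return (
        abs(feature_mass - rep_mass) <= tol.mass_window_da(rep_mass)
        and abs(feature_time - rep_time) <= tol.time_tolerance(rep_time)
    )
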