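"""Sequenced-marker quality control and precursor mapping.

Sequences use the modification coding of the marker tables: uppercase letters
are the 20 standard residues; lowercase ``p`` = hydroxyproline, ``k`` =
hydroxylysine, ``m`` = oxidized methionine (each +15.994915 Da on the parent
residue). QC applies the post-identification filters only: theoretical
monoisotopic mass within +/-80 ppm of the measured mass, and predicted CE
migration time (from the basic-residue count at pH 2) within +/-2 min of the
observed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

# Monoisotopic residue masses (peptide-bond residues, Da).
RESIDUE_MASS: Dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.010565
HYDROXYL_MASS = 15.994915  # +O: hydroxylation / methionine oxidation

#: modification code -> parent residue
MODIFICATION_CODES: Dict[str, str] = {"p": "P", "k": "K", "m": "M"}

MASS_PPM_LIMIT = 80.0
MIGRATION_WINDOW_MIN = 2.0

BASIC_RESIDUES = frozenset("KRH")


class AlphabetError(ValueError):
    """Raised for a residue symbol outside the supported alphabet."""


@dataclass(frozen=True)
class SequencedMarker:
    """A differential peptide from a sequenced marker panel."""

    sequence: str  # modification-coded
    protein_id: str
    protein_name: str
    start: int  # 1-based inclusive on the precursor
    stop: int
    species: str = ""
    regulation: Optional[str] = None  # "up" / "down" / None
    p_adjusted: float = float("nan")
    mean_amp_case: float = float("nan")
    mean_amp_control: float = float("nan")

    def plain_sequence(self) -> str:
        return self.sequence.upper()

    def validate_coordinates(self, protein: str) -> bool:
        if self.stop < self.start:
            return False
        if self.stop - self.start + 1 != len(self.sequence):
            return False
        return protein[self.start - 1 : self.stop].upper() == self.plain_sequence()


def theoretical_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a modification-coded peptide sequence."""
    if not sequence:
        raise AlphabetError("empty sequence")
    mass = WATER_MASS
    for ch in sequence:
        if ch in RESIDUE_MASS:
            mass += RESIDUE_MASS[ch]
        elif ch in MODIFICATION_CODES:
            mass += RESIDUE_MASS[MODIFICATION_CODES[ch]] + HYDROXYL_MASS
        else:
            raise AlphabetError(f"unknown residue symbol {ch!r}")
    return mass


def mass_deviation_check(
    measured: float, theoretical: float, limit: float = MASS_PPM_LIMIT
) -> Tuple[bool, float]:
    """(pass, ppm) where ppm = 1e6 * (measured - theoretical) / theoretical."""
    if measured <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    ppm = 1e6 * (measured - theoretical) / theoretical
    return abs(ppm) < limit, ppm


def count_basic_residues(sequence: str) -> int:
    return sum(1 for ch in sequence.upper() if ch in BASIC_RESIDUES)


# Invented calibration consistent with "more charge at pH 2 -> earlier
# migration"; the real predictor is not published, so the table is injectable.
DEFAULT_CALIBRATION: Dict[int, float] = {
    0: 40.0,
    1: 35.0,
    2: 30.5,
    3: 26.5,
    4: 23.0,
    5: 20.0,
    6: 18.0,
}


@dataclass(frozen=True)
class MigrationModel:
    """Basic-residue-count -> expected CE migration time calibration."""

    calibration: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION)
    )
    window: float = MIGRATION_WINDOW_MIN

    def __post_init__(self) -> None:
        if not self.calibration:
            raise ValueError("empty migration calibration table")
        counts = sorted(self.calibration)
        times = [self.calibration[c] for c in counts]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("expected migration time must strictly decrease with charge")

    def predict(self, n_basic: int) -> float:
        counts = sorted(self.calibration)
        times = [self.calibration[c] for c in counts]
        return float(np.interp(n_basic, counts, times))  # clamped at the ends

    def check(self, observed: float, n_basic: int) -> Tuple[bool, float]:
        """(pass, deviation) against the +/- window."""
        dev = observed - self.predict(n_basic)
        return abs(dev) < self.window, dev


def predict_migration_time(sequence: str, model: MigrationModel | None = None) -> float:
    model = model or MigrationModel()
    return model.predict(count_basic_residues(sequence))


@dataclass(frozen=True)
class Occurrence:
    start: int  # 1-based inclusive
    stop: int
    n_flank: str  # up to 3 protein residues before start
    c_flank: str  # up to 3 protein residues after stop


class MappingError(ValueError):
    """Peptide not found in its stated precursor."""


def map_peptide(sequence: str, protein: str) -> List[Occurrence]:
    """All occurrences of the (case-folded) peptide in the precursor.

    Collagens are repetitive: every occurrence is returned, with up to three
    flanking protein residues on each side (shorter at the termini).
    """
    pep = sequence.upper()
    prot = protein.upper()
    if not pep:
        raise MappingError("empty peptide")
    hits: List[Occurrence] = []
    idx = prot.find(pep)
    while idx != -1:
        start = idx + 1
        stop = idx + len(pep)
        hits.append(
            Occurrence(
                start=start,
                stop=stop,
                n_flank=prot[max(0, idx - 3) : idx],
                c_flank=prot[stop : stop + 3],
            )
        )
        idx = prot.find(pep, idx + 1)
    if not hits:
        raise MappingError(f"peptide {sequence!r} not found in precursor")
    return hits


@dataclass
class QCRecord:
    marker: SequencedMarker
    coordinates_ok: bool
    occurrences: List[Occurrence]
    ppm: Optional[float] = None
    mass_ok: Optional[bool] = None
    time_deviation: Optional[float] = None
    time_ok: Optional[bool] = None

    @property
    def passed(self) -> bool:
        checks = [self.coordinates_ok, bool(self.occurrences)]
        if self.mass_ok is not None:
            checks.append(self.mass_ok)
        if self.time_ok is not None:
            checks.append(self.time_ok)
        return all(checks)


def qc_marker(
    marker: SequencedMarker,
    proteins: Mapping[str, str],
    measured_mass: Optional[float] = None,
    measured_time: Optional[float] = None,
    migration_model: MigrationModel | None = None,
    ppm_limit: float = MASS_PPM_LIMIT,
) -> QCRecord:
    """Run the post-identification QC filters on one sequenced marker.

    Mapping and coordinate validation always run; the mass and migration
    checks run only when measured values are supplied (the marker tables do
    not carry them).
    """
    protein = proteins.get(marker.protein_id)
    if protein is None:
        raise MappingError(f"no precursor sequence for {marker.protein_id!r}")
    try:
        occurrences = map_peptide(marker.sequence, protein)
    except MappingError:
        occurrences = []
    record = QCRecord(
        marker=marker,
        coordinates_ok=marker.validate_coordinates(protein),
        occurrences=occurrences,
    )
    if measured_mass is not None:
        record.mass_ok, record.ppm = mass_deviation_check(
            measured_mass, theoretical_mass(marker.sequence), limit=ppm_limit
        )
    if measured_time is not None:
        model = migration_model or MigrationModel()
        record.time_ok, record.time_deviation = model.check(
            measured_time, count_basic_residues(marker.sequence)
        )
    return record


def markers_from_panel(df, species: str = "") -> List[SequencedMarker]:
    """Build SequencedMarker objects from a panel DataFrame (io.read_panel)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SequencedMarker(
                sequence=str(row.sequence),
                protein_id=str(getattr(row, "protein_id", row.protein_name)),
                protein_name=str(row.protein_name),
                start=int(row.start),
                stop=int(row.stop),
                species=species,
                regulation=(
                    str(row.regulation) if row.regulation in ("up", "down") else None
                ),
                p_adjusted=float(row.p_adjusted),
                mean_amp_case=float(row.mean_amp_case),
                mean_amp_control=float(row.mean_amp_control),
            )
        )
    return out
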