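"""Cleavage-site protease inference.

Six-residue terminal cleavage contexts of mapped marker fragments are matched
against a local motif database (a bundled transcription of the curated
MEROPS/CutDB cleavage sites, extensible by the user): strict = exact string
equality, relaxed = Hamming distance up to 2. Matched sites are tallied per
protease group on the up- versus down-regulated side to infer the direction
of protease activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .orthology import MappedMarker
from .seqqc import RESIDUE_MASS

logger = logging.getLogger(__name__)

CONTEXT_LENGTH = 6
RELAXED_MAX_MISMATCHES = 2

VALID_SOURCES = {"CutDB", "MEROPS", "custom"}


@dataclass(frozen=True)
class ProteaseMotif:
    context6: str  # 3 residues before + 3 after the scissile bond
    proteases: Tuple[str, ...]
    source: str = "custom"
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.context6) != CONTEXT_LENGTH:
            raise ValueError(f"motif must be 6 residues, got {self.context6!r}")
        if any(ch not in RESIDUE_MASS for ch in self.context6):
            raise ValueError(f"non-residue character in motif {self.context6!r}")
        if not self.proteases:
            raise ValueError(f"motif {self.context6} has no proteases")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


class MotifDB:
    """Cleavage-motif collection indexed for exact lookup and mismatch scan."""

    def __init__(self, motifs: Iterable[ProteaseMotif]):
        merged: Dict[str, ProteaseMotif] = {}
        for m in motifs:
            if m.context6 in merged:
                prev = merged[m.context6]
                proteases = tuple(
                    sorted(set(prev.proteases) | set(m.proteases))
                )
                merged[m.context6] = ProteaseMotif(
                    m.context6, proteases, prev.source, prev.notes
                )
            else:
                merged[m.context6] = m
        self._motifs: Dict[str, ProteaseMotif] = merged

    def __len__(self) -> int:
        return len(self._motifs)

    def __iter__(self):
        return iter(self._motifs.values())

    def get(self, context6: str) -> Optional[ProteaseMotif]:
        return self._motifs.get(context6)

    @property
    def contexts(self) -> List[str]:
        return sorted(self._motifs)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@lru_cache(maxsize=1)
def _bundled_table() -> pd.DataFrame:
    with resources.as_file(
        resources.files("crosspep.data") / "cleavage_motifs.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t")


def load_motif_db(path: Optional[str] = None) -> MotifDB:
    """Load a motif table (context6, proteases, source, notes).

    With no path, the bundled table transcribed row-by-row from the curated
    COL1A1 cleavage-site list is used.
    """
    df = _bundled_table() if path is None else pd.read_csv(path, sep="\t")
    required = {"context6", "proteases"}
    if not required.issubset(df.columns):
        raise ValueError(f"motif table needs columns {sorted(required)}")
    motifs: List[ProteaseMotif] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        context = str(row.context6).strip()
        proteases = tuple(
            p.strip() for p in str(row.proteases).split(",") if p.strip()
        )
        source = str(getattr(row, "source", "custom") or "custom")
        notes = getattr(row, "notes", "")
        notes = "" if pd.isna(notes) else str(notes)
        try:
            motifs.append(ProteaseMotif(context, proteases, source, notes))
        except ValueError as exc:
            raise ValueError(f"motif table row {i}: {exc}") from exc
    return MotifDB(motifs)


@dataclass(frozen=True)
class MotifMatch:
    motif: ProteaseMotif
    mismatches: int

    @property
    def mode(self) -> str:
        return "strict" if self.mismatches == 0 else "relaxed"


def match_site(
    context6: str, db: MotifDB, max_mismatches: int = 0
) -> List[MotifMatch]:
    """Motifs matching a complete 6-residue context.

    ``max_mismatches=0`` is the strict search (exact equality); up to 2
    mismatches is the relaxed search. Results sort by mismatch count, then
    motif string.
    """
    if len(context6) != CONTEXT_LENGTH:
        raise ValueError(f"context must be 6 residues, got {context6!r}")
    context = context6.upper()
    matches = [
        MotifMatch(m, _hamming(context, m.context6))
        for m in db
        if _hamming(context, m.context6) <= max_mismatches
    ]
    matches.sort(key=lambda m: (m.mismatches, m.motif.context6))
    return matches


def default_grouping(protease: str) -> str:
    """Collapse protease names into the reported activity families."""
    if protease.startswith("MMP"):
        return "MMP"
    if protease in ("CTSK", "F2"):
        return "CTSK/F2"
    return protease


@dataclass
class ActivityTally:
    protease_group: str
    n_sites_up: int = 0
    n_sites_down: int = 0

    @property
    def direction(self) -> str:
        if self.n_sites_up > self.n_sites_down:
            return "increased"
        if self.n_sites_up < self.n_sites_down:
            return "decreased"
        return "unclear"


@dataclass(frozen=True)
class SiteProvenance:
    marker_sequence: str
    terminus: str  # "N" or "C"
    context6: str
    regulation: str
    proteases: Tuple[str, ...]
    groups: Tuple[str, ...]
    mismatches: int


def tally_activity(
    markers: Sequence[MappedMarker],
    db: MotifDB,
    protein_filter: Optional[str] = None,
    grouping=default_grouping,
    relaxed_max: int = RELAXED_MAX_MISMATCHES,
) -> Tuple[Dict[str, ActivityTally], List[SiteProvenance]]:
    """Tally matched cleavage sites per protease group by fragment regulation.

    For every regulated marker (optionally restricted to one precursor name)
    both terminal contexts are matched strictly first, falling back to the
    relaxed scan; incomplete contexts from protein termini are skipped.
    Identical context strings arising from repeat occurrences of one marker
    count once; a site matching motifs of several groups increments each.
    """
    if protein_filter is not None:
        markers = [
            m for m in markers if m.marker.protein_name == protein_filter
        ]
    if not markers:
        logger.warning("no markers to tally (filter=%r)", protein_filter)

    tallies: Dict[str, ActivityTally] = {}
    provenance: List[SiteProvenance] = []
    for m in markers:
        if m.regulation not in ("up", "down"):
            continue
        sites: List[Tuple[str, str]] = []  # (terminus, context)
        seen: Set[Tuple[str, str]] = set()
        for ctx in [m.context] + m.all_contexts:
            for terminus, context, complete in (
                ("N", ctx.n_context, ctx.n_complete),
                ("C", ctx.c_context, ctx.c_complete),
            ):
                if not complete:
                    continue
                key = (terminus, context)
                if key in seen:
                    continue
                seen.add(key)
                sites.append((terminus, context))
        for terminus, context in sites:
            matches = match_site(context, db, max_mismatches=0)
            if not matches:
                matches = match_site(context, db, max_mismatches=relaxed_max)
            if not matches:
                continue
            proteases = sorted({p for mm in matches for p in mm.motif.proteases})
            groups = sorted({grouping(p) for p in proteases})
            mismatches = min(mm.mismatches for mm in matches)
            for group in groups:
                tally = tallies.setdefault(group, ActivityTally(group))
                if m.regulation == "up":
                    tally.n_sites_up += 1
                else:
                    tally.n_sites_down += 1
            provenance.append(
                SiteProvenance(
                    marker_sequence=m.marker.sequence,
                    terminus=terminus,
                    context6=context,
                    regulation=m.regulation,
                    proteases=tuple(proteases),
                    groups=tuple(groups),
                    mismatches=mismatches,
                )
            )
    return tallies, provenance


def tallies_to_frame(tallies: Mapping[str, ActivityTally]) -> pd.DataFrame:
    rows = [
        {
            "protease_group": t.protease_group,
            "n_sites_up": t.n_sites_up,
            "n_sites_down": t.n_sites_down,
            "direction": t.direction,
        }
        for t in sorted(tallies.values(), key=lambda t: t.protease_group)
    ]
    return pd.DataFrame(
        rows, columns=["protease_group", "n_sites_up", "n_sites_down", "direction"]
    )
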