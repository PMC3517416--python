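"""Cross-species marker orthology.

Rat/human marker pairs from declared ortholog precursors are classified into
three tiers: (1) identical fragment — both cleavage sites and the peptide
sequence identical; (2) one identical cleavage site; (3) same protein region,
overlapping by at least two residues. A pair is only a match when both markers
are regulated in the same direction; the highest satisfied tier is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .seqqc import MappingError, SequencedMarker, map_peptide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleavageContexts:
    """Six-residue N- and C-terminal cleavage contexts of a mapped fragment."""

    n_context: str  # 3 protein residues before start + first 3 peptide residues
    c_context: str  # last 3 peptide residues + 3 protein residues after stop
    n_complete: bool
    c_complete: bool


def cleavage_contexts(protein: str, start: int, stop: int) -> CleavageContexts:
    """Extract both terminal contexts for a fragment at 1-based (start, stop).

    Contexts shorter than six residues (fragment at a protein terminus, or a
    peptide shorter than three residues) are flagged incomplete; a length-3
    peptide serves both context halves.
    """
    if not (1 <= start <= stop <= len(protein)):
        raise ValueError(f"coordinates ({start}, {stop}) outside protein")
    prot = protein.upper()
    pep = prot[start - 1 : stop]
    n_before = prot[max(0, start - 4) : start - 1]
    c_after = prot[stop : stop + 3]
    n_context = n_before + pep[:3]
    c_context = pep[-3:] + c_after
    return CleavageContexts(
        n_context=n_context,
        c_context=c_context,
        n_complete=len(n_context) == 6,
        c_complete=len(c_context) == 6,
    )


@dataclass
class MappedMarker:
    """A sequenced marker bound to its precursor with extracted contexts."""

    marker: SequencedMarker
    context: CleavageContexts  # at the stated coordinates
    all_contexts: List[CleavageContexts] = field(default_factory=list)
    # deduplicated at the context-string level across repeat occurrences

    @property
    def regulation(self) -> Optional[str]:
        return self.marker.regulation

    @property
    def protein_id(self) -> str:
        return self.marker.protein_id


def map_markers(
    markers: Sequence[SequencedMarker], proteins: Mapping[str, str]
) -> Tuple[List[MappedMarker], List[SequencedMarker]]:
    """Bind markers to precursors; unmappable markers are returned separately."""
    mapped: List[MappedMarker] = []
    failed: List[SequencedMarker] = []
    for m in markers:
        protein = proteins.get(m.protein_id)
        if protein is None or not m.validate_coordinates(protein):
            logger.warning("marker %s: cannot map to %s", m.sequence, m.protein_id)
            failed.append(m)
            continue
        try:
            occurrences = map_peptide(m.sequence, protein)
        except MappingError:
            failed.append(m)
            continue
        seen: Dict[Tuple[str, str], CleavageContexts] = {}
        for occ in occurrences:
            ctx = cleavage_contexts(protein, occ.start, occ.stop)
            seen.setdefault((ctx.n_context, ctx.c_context), ctx)
        primary = cleavage_contexts(protein, m.start, m.stop)
        mapped.append(
            MappedMarker(marker=m, context=primary, all_contexts=list(seen.values()))
        )
    return mapped, failed


class OrthologMap:
    """Declared rat<->human precursor pairs with optional coordinate offsets."""

    def __init__(self, pairs: Sequence[Tuple[str, str, int]]):
        self._by_rat: Dict[str, Tuple[str, int]] = {}
        self._by_human: Dict[str, Tuple[str, int]] = {}
        for rat_id, human_id, offset in pairs:
            if rat_id in self._by_rat or human_id in self._by_human:
                raise ValueError(f"protein in more than one ortholog pair: {rat_id}/{human_id}")
            self._by_rat[rat_id] = (human_id, int(offset))
            self._by_human[human_id] = (rat_id, int(offset))

    def human_for(self, rat_id: str) -> Optional[Tuple[str, int]]:
        return self._by_rat.get(rat_id)

    @classmethod
    def identity(cls, protein_ids: Sequence[str]) -> "OrthologMap":
        return cls([(p, p, 0) for p in protein_ids])


def tier_match(
    rat: MappedMarker, human: MappedMarker, ortholog_map: OrthologMap
) -> Optional[int]:
    """Highest orthology tier satisfied by the pair, or None.

    Requires a declared ortholog precursor pair and identical regulation.
    Tier 1: both contexts and the uppercased sequence identical. Tier 2: at
    least one identical context (a tier-1 pair also satisfies this; the
    higher tier is reported). Tier 3: coordinate intervals, after the
    per-pair offset applied to the rat fragment, overlap by >= 2 residues.
    """
    if rat.regulation is None or human.regulation is None:
        return None
    if rat.regulation != human.regulation:
        return None
    pair = ortholog_map.human_for(rat.protein_id)
    if pair is None or pair[0] != human.protein_id:
        logger.debug(
            "no ortholog pairing %s -> %s", rat.protein_id, human.protein_id
        )
        return None
    offset = pair[1]

    n_same = rat.context.n_context == human.context.n_context
    c_same = rat.context.c_context == human.context.c_context
    if (
        n_same
        and c_same
        and rat.marker.plain_sequence() == human.marker.plain_sequence()
    ):
        return 1
    if n_same or c_same:
        return 2
    r_start, r_stop = rat.marker.start + offset, rat.marker.stop + offset
    overlap = min(r_stop, human.marker.stop) - max(r_start, human.marker.start) + 1
    if overlap >= 2:
        return 3
    return None


@dataclass(frozen=True)
class OrthologyMatch:
    rat_marker: MappedMarker
    human_marker: MappedMarker
    tier: int
    regulation_agreement: bool = True


@dataclass
class PanelComparison:
    tier_counts: Dict[int, int]
    matches: List[OrthologyMatch]
    regulation_summary: Dict[Tuple[str, str], Tuple[int, int]]
    # (species, protein_name) -> (n up, n down)


def _regulation_summary(
    markers: Sequence[MappedMarker], species: str
) -> Dict[Tuple[str, str], Tuple[int, int]]:
    summary: Dict[Tuple[str, str], List[int]] = {}
    for m in markers:
        key = (species, m.marker.protein_name)
        tally = summary.setdefault(key, [0, 0])
        if m.regulation == "up":
            tally[0] += 1
        elif m.regulation == "down":
            tally[1] += 1
    return {k: (v[0], v[1]) for k, v in summary.items()}


def compare_panels(
    rat_panel: Sequence[MappedMarker],
    human_panel: Sequence[MappedMarker],
    ortholog_map: OrthologMap,
) -> PanelComparison:
    """Best-match tier classification of a rat panel against a human panel.

    Each rat marker contributes at most one match: its highest-tier human
    partner, ties broken by the lower human adjusted p-value and then the
    human sequence. Tier counts are therefore disjoint.
    """
    matches: List[OrthologyMatch] = []
    for rat in rat_panel:
        candidates: List[Tuple[int, float, str, MappedMarker]] = []
        for hum in human_panel:
            tier = tier_match(rat, hum, ortholog_map)
            if tier is not None:
                p = hum.marker.p_adjusted
                candidates.append(
                    (tier, p if not math.isnan(p) else math.inf, hum.marker.sequence, hum)
                )
        if candidates:
            # tier 1 is the most stringent, so the numerically lowest wins
            best = min(candidates, key=lambda c: (c[0], c[1], c[2]))
            matches.append(
                OrthologyMatch(rat_marker=rat, human_marker=best[3], tier=best[0])
            )
    counts = {1: 0, 2: 0, 3: 0}
    for m in matches:
        counts[m.tier] += 1
    summary = _regulation_summary(rat_panel, "rat")
    summary.update(_regulation_summary(human_panel, "human"))
    return PanelComparison(tier_counts=counts, matches=matches, regulation_summary=summary)


def _fold_magnitude(marker: SequencedMarker) -> float:
    case, control = marker.mean_amp_case, marker.mean_amp_control
    if case <= 0 or control <= 0 or math.isnan(case) or math.isnan(control):
        return math.inf
    return abs(math.log(case / control))


def select_top_markers(
    panel: Sequence[SequencedMarker], n: int = 50
) -> List[SequencedMarker]:
    """The n most significant markers (lowest adjusted p), deterministically.

    Ties are broken by the larger absolute log fold change, then by sequence.
    """
    if n > len(panel):
        logger.warning("requested top %d of a panel of %d; returning all", n, len(panel))
    ranked = sorted(
        panel,
        key=lambda m: (
            m.p_adjusted if not math.isnan(m.p_adjusted) else math.inf,
            -_fold_magnitude(m),
            m.sequence,
        ),
    )
    return ranked[:n]
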