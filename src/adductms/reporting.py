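"""Fragment maps, region classification and residue-occurrence histograms.

These summaries turn a ranked match list into binding-site evidence:

* a *fragment map* draws every identified cleavage product as a bar over the
  sequence, split into platinated (>= 1 metal adduct) and metal-free tracks;
* *region classification* buckets fragments into 5'-end (a/b/c/d series, or
  peptide a/b), 3'-end (w/x/y/z, or peptide y) and Middle (internal)
  classes and reports percentage abundances separately for the platinated
  and unplatinated evidence sets;
* a *residue histogram* counts, per sequence position, how many matched
  fragments cover it, again split by platination.

Classification follows fragment topology (which terminus the fragment
retains), not fixed position windows.  By default each unique fragment
(aggregated over charge states and adduct stoichiometries) is counted once;
``count_all=True`` counts every matched ion instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .matching import MatchResult
from .polymers import OligoSequence, PeptideSequence

__all__ = [
    "MapTrack",
    "FragmentMap",
    "RegionSummary",
    "build_fragment_map",
    "classify_regions",
    "residue_histogram",
    "histogram_to_tsv",
    "map_to_svg",
]

_REGIONS = ("5'-end", "3'-end", "Middle")


def _region_of(result: MatchResult) -> Optional[str]:
    kind = result.species.fragment.kind
    if kind == "terminal5":
        return "5'-end"
    if kind == "terminal3":
        return "3'-end"
    if kind == "internal":
        return "Middle"
    return None  # precursors carry no localization information


@dataclass(frozen=True)
class MapTrack:
    """One unique fragment drawn on the map (aggregated over ion species)."""

    label: str
    group: str  # terminal5 | terminal3 | internal
    start: int
    end: int
    platinated: bool
    mean_similarity: float
    n_matches: int


@dataclass(frozen=True)
class FragmentMap:
    sequence: str
    name: str
    tracks: Tuple[MapTrack, ...]
    platinated_counts: np.ndarray  # per position, unique fragments covering it
    unplatinated_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "name": self.name,
            "tracks": [
                {
                    "label": t.label,
                    "group": t.group,
                    "start": t.start,
                    "end": t.end,
                    "platinated": t.platinated,
                    "mean_similarity": round(t.mean_similarity, 4),
                    "n_matches": t.n_matches,
                }
                for t in self.tracks
            ],
            "platinated_counts": self.platinated_counts.tolist(),
            "unplatinated_counts": self.unplatinated_counts.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_fragment_map(
    results: Sequence[MatchResult],
    sequence: OligoSequence | PeptideSequence,
) -> FragmentMap:
    """Aggregate matches into map tracks and per-position coverage counts.

    All matches must reference ``sequence``; precursor matches are ignored
    (they cover everything and localize nothing).  Matches of the same
    fragment at different charge states or adduct stoichiometries collapse
    into one track per (fragment label, platinated flag) with the mean
    similarity across its ions.
    """
    n = len(sequence)
    groups: Dict[Tuple[str, bool], List[MatchResult]] = {}
    for r in results:
        frag = r.species.fragment
        if frag.parent != sequence:
            raise ValueError(
                f"match {r.label} references {frag.parent.name!r}, "
                f"not {sequence.name!r}"
            )
        if frag.kind == "precursor":
            continue
        groups.setdefault((frag.label, r.species.is_platinated), []).append(r)
    tracks = []
    for (label, platinated), members in groups.items():
        frag = members[0].species.fragment
        tracks.append(
            MapTrack(
                label=label,
                group=frag.kind,
                start=frag.start,
                end=frag.end,
                platinated=platinated,
                mean_similarity=float(np.mean([m.similarity for m in members])),
                n_matches=len(members),
            )
        )
    tracks.sort(key=lambda t: (t.platinated, t.group, t.start, t.end, t.label))
    plat = np.zeros(n, dtype=int)
    unplat = np.zeros(n, dtype=int)
    for t in tracks:
        target = plat if t.platinated else unplat
        target[t.start - 1 : t.end] += 1
    return FragmentMap(
        sequence=sequence.residues,
        name=sequence.name,
        tracks=tuple(tracks),
        platinated_counts=plat,
        unplatinated_counts=unplat,
    )


@dataclass(frozen=True)
class RegionSummary:
    region: str
    platinated_pct: float
    unplatinated_pct: float
    platinated_count: int
    unplatinated_count: int
    platinated_empty: bool = False
    unplatinated_empty: bool = False


def classify_regions(
    results: Sequence[MatchResult], count_all: bool = False
) -> List[RegionSummary]:
    """5'-end / 3'-end / Middle percentage abundances per evidence set.

    Percentages are computed separately over the platinated and the
    unplatinated matches and sum to 100 within each non-empty set.  An empty
    evidence set reports 0% with its ``*_empty`` flag raised.  Unique
    fragments are counted by default; ``count_all=True`` counts every ion.
    """
    counts = {(region, flag): 0 for region in _REGIONS for flag in (True, False)}
    seen = set()
    for r in results:
        region = _region_of(r)
        if region is None:
            continue
        platinated = r.species.is_platinated
        if not count_all:
            key = (r.species.fragment.label, platinated)
            if key in seen:
                continue
            seen.add(key)
        counts[(region, platinated)] += 1
    totals = {
        flag: sum(counts[(region, flag)] for region in _REGIONS)
        for flag in (True, False)
    }
    out = []
    for region in _REGIONS:
        pct = {}
        for flag in (True, False):
            pct[flag] = (
                100.0 * counts[(region, flag)] / totals[flag] if totals[flag] else 0.0
            )
        out.append(
            RegionSummary(
                region=region,
                platinated_pct=pct[True],
                unplatinated_pct=pct[False],
                platinated_count=counts[(region, True)],
                unplatinated_count=counts[(region, False)],
                platinated_empty=totals[True] == 0,
                unplatinated_empty=totals[False] == 0,
            )
        )
    return out


def residue_histogram(
    results: Sequence[MatchResult],
    sequence: OligoSequence | PeptideSequence,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position (platinated, unplatinated) coverage counts over matches.

    Every terminal or internal match increments each position its fragment
    covers; precursor matches are excluded.  The histogram total therefore
    equals the sum of covered-interval lengths over counted matches.
    """
    n = len(sequence)
    plat = np.zeros(n, dtype=int)
    unplat = np.zeros(n, dtype=int)
    for r in results:
        frag = r.species.fragment
        if frag.parent != sequence:
            raise ValueError(f"match {r.label} references a different sequence")
        if frag.kind == "precursor":
            continue
        target = plat if r.species.is_platinated else unplat
        target[frag.start - 1 : frag.end] += 1
    return plat, unplat


def histogram_to_tsv(
    sequence: OligoSequence | PeptideSequence,
    platinated: np.ndarray,
    unplatinated: np.ndarray,
) -> str:
    lines = ["position\tresidue\tplatinated\tunplatinated"]
    for pos in range(1, len(sequence) + 1):
        lines.append(
            f"{pos}\t{sequence[pos]}\t{platinated[pos - 1]}\t{unplatinated[pos - 1]}"
        )
    return "\n".join(lines) + "\n"


_GROUP_COLOR = {"terminal5": "#1f77b4", "terminal3": "#d62728", "internal": "#2ca02c"}


def map_to_svg(fmap: FragmentMap, similarity_cutoff: float = 0.9) -> str:
    """Render a fragment map as standalone SVG.

    5'-terminal fragments are blue, 3'-terminal red, internal green; bars at
    mean similarity >= ``similarity_cutoff`` are drawn solid, weaker evidence
    is drawn faded.  Platinated tracks appear below the sequence ruler,
    metal-free tracks above it.
    """
    n = len(fmap.sequence)
    cell = 28
    row_h = 14
    left, top = 60, 30
    plat_tracks = [t for t in fmap.tracks if t.platinated]
    free_tracks = [t for t in fmap.tracks if not t.platinated]
    height = top + row_h * (len(free_tracks) + len(plat_tracks) + 6)
    width = left + cell * n + 120
    svg = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace" font-size="12">',
        f'<text x="{left}" y="{top - 12}" font-weight="bold">{fmap.name}</text>',
    ]

    def bars(tracks: Sequence[MapTrack], y0: int, heading: str) -> int:
        svg.append(f'<text x="4" y="{y0 + 10}" font-size="10">{heading}</text>')
        y = y0 + row_h
        for t in tracks:
            x = left + (t.start - 1) * cell
            w = (t.end - t.start + 1) * cell - 4
            color = _GROUP_COLOR.get(t.group, "#555555")
            opacity = 1.0 if t.mean_similarity >= similarity_cutoff else 0.35
            svg.append(
                f'<rect x="{x}" y="{y}" width="{w}" height="{row_h - 4}" '
                f'fill="{color}" fill-opacity="{opacity}"/>'
            )
            svg.append(
                f'<text x="{x + w + 6}" y="{y + row_h - 6}" font-size="9">'
                f"{t.label} ({t.mean_similarity:.2f})</text>"
            )
            y += row_h
        return y

    y = bars(free_tracks, top, "metal-free fragments")
    y += row_h // 2
    for pos, letter in enumerate(fmap.sequence, start=1):
        x = left + (pos - 1) * cell + cell // 2
        svg.append(f'<text x="{x}" y="{y + 12}" text-anchor="middle">{letter}</text>')
        svg.append(
            f'<text x="{x}" y="{y + 24}" text-anchor="middle" font-size="8" '
            f'fill="#888">{pos}</text>'
        )
    y += 2 * row_h
    bars(plat_tracks, y, "platinated fragments")
    svg.append("</svg>")
    return "\n".join(svg)
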