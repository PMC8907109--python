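"""Spectrum reading, envelope-to-peak alignment and similarity scoring.

A theoretical isotopologue envelope is aligned to a centroided spectrum by
assigning each isotopologue (most abundant first) the nearest unused peak
within a ppm tolerance; unmatched isotopologues contribute zero intensity.
Both the theoretical and the matched experimental intensity vectors are
normalized to unit sum over the envelope support and scored with the
total-variation overlap

    score = 1 - 1/2 * sum_k | I_theo,k - I_exp,k |

which is bounded in [0, 1], invariant to uniform intensity scaling and equal
to 1 exactly when the envelope shapes agree.  Cosine similarity on the same
aligned vectors is available as an alternative metric.  A species counts as
matched only if its principal (most abundant) isotopologue found a peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import IsotopePattern
from .ions import IonSpecies

__all__ = [
    "PeakList",
    "PeakListError",
    "MatchResult",
    "read_peaklist",
    "similarity",
    "match_spectrum",
    "matches_to_tsv",
    "matches_to_json",
]


class PeakListError(ValueError):
    """Raised for malformed or empty spectrum files (reports line numbers)."""


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: strictly m/z-sorted peaks with intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: Optional[str] = None
    precursor_mz: Optional[float] = None
    isolation_width: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise PeakListError("mz and intensity must be 1-D and equal length")
        if len(self.mz) == 0:
            raise PeakListError("empty spectrum")
        if np.any(self.mz <= 0):
            raise PeakListError("all m/z values must be positive")
        if np.any(self.intensity < 0):
            raise PeakListError("intensities must be non-negative")
        if np.any(np.diff(self.mz) <= 0):
            raise PeakListError("peaks must be strictly sorted by m/z")

    def __len__(self) -> int:
        return len(self.mz)

    @classmethod
    def from_arrays(
        cls, mz: Sequence[float], intensity: Sequence[float], **kwargs
    ) -> "PeakList":
        """Build a PeakList, sorting and merging exact-duplicate m/z values."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        if len(mz) > 1:
            dup = np.concatenate([[False], np.diff(mz) == 0])
            if dup.any():
                keep = ~dup
                idx = np.cumsum(keep) - 1
                summed = np.zeros(keep.sum())
                np.add.at(summed, idx, intensity)
                mz, intensity = mz[keep], summed
        return cls(mz, intensity, **kwargs)


def _read_txt(path: Path) -> PeakList:
    mz, intensity = [], []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise PeakListError(f"{path}: line {lineno}: expected 'm/z intensity'")
            try:
                mz.append(float(fields[0]))
                intensity.append(float(fields[1]))
            except ValueError:
                raise PeakListError(
                    f"{path}: line {lineno}: cannot parse {line!r}"
                ) from None
    if not mz:
        raise PeakListError(f"{path}: empty spectrum")
    return PeakList.from_arrays(mz, intensity)


def _read_mgf(path: Path, index: int) -> PeakList:
    from pyteomics import mgf

    with mgf.MGF(str(path)) as reader:
        for i, spectrum in enumerate(reader):
            if i == index:
                params = spectrum.get("params", {})
                pepmass = params.get("pepmass")
                precursor = float(pepmass[0]) if pepmass else None
                charge = params.get("charge")
                polarity = None
                if charge:
                    polarity = "neg" if int(charge[0]) < 0 else "pos"
                if len(spectrum["m/z array"]) == 0:
                    raise PeakListError(f"{path}: spectrum {index} is empty")
                return PeakList.from_arrays(
                    spectrum["m/z array"],
                    spectrum["intensity array"],
                    precursor_mz=precursor,
                    polarity=polarity,
                )
    raise PeakListError(f"{path}: no MGF spectrum at index {index}")


def read_peaklist(path: str | Path, format: Optional[str] = None, index: int = 0) -> PeakList:
    """Read a centroided spectrum from a two-column txt file or an MGF.

    ``format`` is inferred from the extension when omitted.  txt files are
    whitespace-delimited (m/z, intensity) with ``#`` comment lines; for MGF,
    ``index`` selects the BEGIN/END IONS block (first by default).
    """
    path = Path(path)
    if format is None:
        format = "mgf" if path.suffix.lower() == ".mgf" else "txt"
    if format == "txt":
        return _read_txt(path)
    if format == "mgf":
        return _read_mgf(path, index)
    raise ValueError(f"unknown spectrum format {format!r}")


def _assign_peaks(
    envelope: IsotopePattern, peaks: PeakList, ppm_tol: float
) -> np.ndarray:
    """Greedy nearest-peak assignment, most abundant isotopologue first.

    Returns an array of peak indices per isotopologue (-1 = unmatched); each
    peak is used at most once within one envelope.
    """
    assignment = np.full(len(envelope), -1, dtype=int)
    used: set = set()
    order = np.argsort(envelope.abundances)[::-1]
    for iso in order:
        mz = envelope.masses[iso]
        tol = mz * ppm_tol * 1e-6
        lo = np.searchsorted(peaks.mz, mz - tol, side="left")
        hi = np.searchsorted(peaks.mz, mz + tol, side="right")
        best, best_dist = -1, np.inf
        for idx in range(lo, hi):
            if idx in used:
                continue
            dist = abs(peaks.mz[idx] - mz)
            if dist < best_dist:
                best, best_dist = idx, dist
        if best >= 0:
            assignment[iso] = best
            used.add(best)
    return assignment


def similarity(
    envelope: IsotopePattern,
    peaks: PeakList,
    ppm_tol: float = 5.0,
    metric: str = "tv",
) -> float:
    """Envelope/spectrum similarity in [0, 1] (see module docstring)."""
    score, _assignment = _score(envelope, peaks, ppm_tol, metric)
    return score


def _score(
    envelope: IsotopePattern, peaks: PeakList, ppm_tol: float, metric: str
) -> Tuple[float, np.ndarray]:
    if metric not in ("tv", "cosine"):
        raise ValueError(f"unknown similarity metric {metric!r}")
    assignment = _assign_peaks(envelope, peaks, ppm_tol)
    theo = envelope.abundances / envelope.abundances.sum()
    exp = np.where(assignment >= 0, peaks.intensity[np.clip(assignment, 0, None)], 0.0)
    if exp.sum() == 0:
        return 0.0, assignment
    exp = exp / exp.sum()
    if metric == "tv":
        score = 1.0 - 0.5 * float(np.abs(theo - exp).sum())
    else:
        score = float(np.dot(theo, exp) / (np.linalg.norm(theo) * np.linalg.norm(exp)))
    return float(np.clip(score, 0.0, 1.0)), assignment


@dataclass(frozen=True)
class MatchResult:
    """One ion-species-to-spectrum assignment."""

    species: IonSpecies
    similarity: float
    observed_mz: float
    ppm_error: float
    matched_pairs: Tuple[Tuple[int, int], ...]  # (isotopologue idx, peak idx)
    isobar_group: int = -1

    @property
    def label(self) -> str:
        return self.species.label


def match_spectrum(
    species: Sequence[IonSpecies],
    peaks: PeakList,
    ppm_tol: float = 5.0,
    min_similarity: float = 0.75,
    prune: float = 1e-3,
    metric: str = "tv",
    min_relative_intensity: float = 0.0,
) -> List[MatchResult]:
    """Score every candidate species against a spectrum and rank the matches.

    A species is reported when its principal isotopologue found a peak and
    its similarity is >= ``min_similarity`` (0.75 default for MS/MS work,
    0.90 is the usual survey-mode setting).  Results are sorted by
    similarity descending then |ppm| ascending.  Species whose principal m/z
    values lie within ``ppm_tol`` of each other share an ``isobar_group``
    id, so isobaric ambiguity is reported rather than silently resolved.
    ``min_relative_intensity`` optionally drops peaks below that fraction of
    the base peak before matching.
    """
    if min_relative_intensity > 0:
        keep = peaks.intensity >= min_relative_intensity * peaks.intensity.max()
        if not keep.any():
            return []
        peaks = PeakList(
            peaks.mz[keep], peaks.intensity[keep],
            polarity=peaks.polarity, precursor_mz=peaks.precursor_mz,
        )
    results: List[MatchResult] = []
    for sp in species:
        envelope = sp.envelope(prune=prune)
        score, assignment = _score(envelope, peaks, ppm_tol, metric)
        principal = envelope.principal_index
        if assignment[principal] < 0 or score < min_similarity:
            continue
        obs = float(peaks.mz[assignment[principal]])
        theo = float(envelope.masses[principal])
        pairs = tuple(
            (int(i), int(p)) for i, p in enumerate(assignment) if p >= 0
        )
        results.append(
            MatchResult(
                species=sp,
                similarity=score,
                observed_mz=obs,
                ppm_error=(obs - theo) / theo * 1e6,
                matched_pairs=pairs,
            )
        )
    results.sort(key=lambda r: (-r.similarity, abs(r.ppm_error), r.label))
    return _assign_isobar_groups(results, ppm_tol)


def _assign_isobar_groups(
    results: List[MatchResult], ppm_tol: float
) -> List[MatchResult]:
    """Chain species whose principal m/z values fall within ppm_tol."""
    if not results:
        return results
    order = sorted(range(len(results)), key=lambda i: results[i].species.mz)
    group_of = {}
    group = 0
    prev_mz = None
    for rank, i in enumerate(order):
        mz = results[i].species.mz
        if prev_mz is not None and (mz - prev_mz) / prev_mz * 1e6 > ppm_tol:
            group += 1
        group_of[i] = group
        prev_mz = mz
    return [
        MatchResult(
            species=r.species,
            similarity=r.similarity,
            observed_mz=r.observed_mz,
            ppm_error=r.ppm_error,
            matched_pairs=r.matched_pairs,
            isobar_group=group_of[i],
        )
        for i, r in enumerate(results)
    ]


def matches_to_tsv(results: Sequence[MatchResult]) -> str:
    lines = ["label\tformula\tz\ttheoretical_mz\tobserved_mz\tppm\tsimilarity\tisobar_group"]
    for r in results:
        lines.append(
            f"{r.label}\t{r.species.total_formula.hill()}\t{r.species.z:+d}\t"
            f"{r.species.mz:.4f}\t{r.observed_mz:.4f}\t{r.ppm_error:.2f}\t"
            f"{r.similarity:.4f}\t{r.isobar_group}"
        )
    return "\n".join(lines) + "\n"


def matches_to_json(results: Sequence[MatchResult]) -> str:
    records = [
        {
            "label": r.label,
            "fragment": r.species.fragment.label,
            "kind": r.species.fragment.kind,
            "formula": r.species.total_formula.hill(),
            "z": r.species.z,
            "theoretical_mz": round(r.species.mz, 6),
            "observed_mz": round(r.observed_mz, 6),
            "ppm": round(r.ppm_error, 3),
            "similarity": round(r.similarity, 4),
            "platinated": r.species.is_platinated,
            "isobar_group": r.isobar_group,
        }
        for r in results
    ]
    return json.dumps(records, indent=2)
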