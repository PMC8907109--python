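"""Seeded generator of synthetic isotopically resolved centroid spectra.

No raw spectra from platination experiments are publicly deposited, so the
test surface for the matcher and the reporting layer is synthetic: planted
ion species are rendered as their isotopologue envelopes with multiplicative
(ppm-scale) m/z jitter and log-normal intensity noise, on top of uniformly
placed decoy peaks with exponentially distributed intensities.  A fixed seed
makes the full output deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ions import IonSpecies
from .matching import PeakList

__all__ = [
    "PlantedSpecies",
    "SimulationConfig",
    "simulate_spectrum",
    "write_txt",
    "write_mgf",
]


@dataclass(frozen=True)
class PlantedSpecies:
    species: IonSpecies
    abundance: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic spectrum.

    ``mz_jitter_ppm`` is the 1-sigma multiplicative mass error (Orbitrap
    calibration jitter is ~1-2 ppm); ``intensity_sigma`` the log-normal
    sigma of multiplicative intensity noise; decoys are uniform in m/z and
    exponential in intensity.
    """

    planted: Tuple[PlantedSpecies, ...] = ()
    mz_jitter_ppm: float = 0.0
    intensity_sigma: float = 0.0
    n_decoys: int = 0
    decoy_mz_range: Tuple[float, float] = (200.0, 2000.0)
    decoy_intensity_scale: float = 0.05
    base_intensity: float = 1000.0
    envelope_prune: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_jitter_ppm < 0 or self.intensity_sigma < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not self.planted and self.n_decoys == 0:
            raise ValueError("need at least one planted species or decoy peak")


def simulate_spectrum(cfg: SimulationConfig) -> PeakList:
    """Render the configured species and decoys into a centroided PeakList."""
    rng = np.random.default_rng(cfg.seed)
    mz_out: List[float] = []
    intensity_out: List[float] = []
    for plant in cfg.planted:
        envelope = plant.species.envelope(prune=cfg.envelope_prune)
        for mz, abundance in zip(envelope.masses, envelope.abundances):
            jittered = mz * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6)
            intensity = (
                cfg.base_intensity
                * plant.abundance
                * abundance
                * float(np.exp(rng.normal(0.0, cfg.intensity_sigma)))
            )
            mz_out.append(jittered)
            intensity_out.append(intensity)
    if cfg.n_decoys:
        lo, hi = cfg.decoy_mz_range
        decoy_mz = rng.uniform(lo, hi, size=cfg.n_decoys)
        decoy_intensity = (
            cfg.base_intensity
            * cfg.decoy_intensity_scale
            * rng.exponential(1.0, size=cfg.n_decoys)
        )
        mz_out.extend(decoy_mz.tolist())
        intensity_out.extend(decoy_intensity.tolist())
    return PeakList.from_arrays(mz_out, intensity_out)


def write_txt(peaks: PeakList, path: str | Path) -> None:
    """Write the two-column txt dialect the reader consumes.

    Values are written with ``repr`` so a read-back round-trips
    bit-identically.
    """
    with open(path, "w") as handle:
        handle.write("# m/z\tintensity\n")
        for mz, intensity in zip(peaks.mz, peaks.intensity):
            handle.write(f"{float(mz)!r}\t{float(intensity)!r}\n")


def write_mgf(
    peaks: PeakList, path: str | Path, title: str = "synthetic spectrum"
) -> None:
    from pyteomics import mgf

    params = {"title": title}
    if peaks.precursor_mz is not None:
        params["pepmass"] = peaks.precursor_mz
    mgf.write(
        [{"m/z array": peaks.mz, "intensity array": peaks.intensity, "params": params}],
        output=str(path),
        file_mode="w",
    )
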