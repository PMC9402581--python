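"""Photosynthesis-irradiance scoring of fluence-rate volumes.

Gross photosynthesis is approximated per tissue voxel with the peaked P-E
relation

    P(E) = P_max * (E / E_opt) * exp(1 - E / E_opt)

which rises linearly at low fluence rate E, peaks at ``P_max`` when
``E = E_opt`` and declines beyond it (photoinhibition).  E at a voxel is
the incident downwelling irradiance ``E0`` times the relative fluence rate
``phi`` from transport; E, E0 and E_opt share units (µmol photons m⁻² s⁻¹),
so the relation is scale-consistent and the scores remain relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import TISSUE, LabelVolume
from .mc import FluenceVolume


class PEError(ValueError):
    """Invalid P-E parameters or inputs."""


@dataclass(frozen=True)
class PEParams:
    """One symbiont photo-physiology: maximum rate and optimal fluence rate."""

    P_max: float
    E_opt: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.P_max <= 0:
            raise PEError("P_max must be > 0")
        if self.E_opt <= 0:
            raise PEError("E_opt must be > 0")


@dataclass
class PhotosynthesisField:
    """Per-tissue-voxel scores plus the tissue-voxel-normalized summary."""

    scores: np.ndarray        # 1-D, one entry per tissue voxel
    summary: float            # mean score per tissue voxel
    n_tissue_voxels: int
    incident_irradiance: float
    pe: PEParams
    meta: dict = field(default_factory=dict)


def load_default_pe(path: str | Path | None = None) -> dict[str, PEParams]:
    """Load the shipped shallow/mesophotic P-E fixture sets."""
    if path is None:
        path = Path(__file__).parent / "data" / "pe.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    return {
        name: PEParams(P_max=raw[name]["P_max"], E_opt=raw[name]["E_opt"], label=name)
        for name in ("shallow", "mesophotic")
    }


def load_default_irradiances(path: str | Path | None = None) -> dict[str, float]:
    if path is None:
        path = Path(__file__).parent / "data" / "pe.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    return {k: float(v) for k, v in raw["irradiance"].items()}


def pe_score(E, pe: PEParams):
    """Evaluate the P-E relation at fluence rate(s) ``E`` (same units as E_opt)."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise PEError("fluence rate E must be >= 0")
    x = E / pe.E_opt
    out = pe.P_max * x * np.exp(1.0 - x)
    return float(out) if out.ndim == 0 else out


def score_volume(
    fluence: FluenceVolume,
    volume: LabelVolume,
    pe: PEParams,
    E0: float,
) -> PhotosynthesisField:
    """Score every tissue voxel at E = E0 * phi and summarize per tissue voxel."""
    if fluence.phi.shape != volume.labels.shape:
        raise PEError(
            f"grid mismatch: fluence {fluence.phi.shape} vs labels {volume.labels.shape}"
        )
    if E0 <= 0:
        raise PEError("incident irradiance E0 must be > 0")
    mask = volume.labels == TISSUE
    n = int(mask.sum())
    if n == 0:
        raise PEError("volume contains no tissue voxels")
    scores = pe_score(E0 * fluence.phi[mask], pe)
    return PhotosynthesisField(
        scores=scores,
        summary=float(scores.mean()),
        n_tissue_voxels=n,
        incident_irradiance=E0,
        pe=pe,
        meta={"seed": fluence.seed, "n_photons": fluence.n_photons},
    )
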