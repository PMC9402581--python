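"""Voxel Monte Carlo photon transport for three-phase coral tiles.

Photon packets are launched as a collimated beam (normal incidence, +z,
uniform over the top face), propagate with exponentially sampled optical
depth through the voxel grid (partial steps across media boundaries),
deposit the fraction ``mua/mut`` of their weight at each interaction and
scatter through the Henyey-Greenstein phase function with uniform azimuth.
Low-weight packets play Russian roulette.  Relative fluence rate (phi, in
multiples of the incident irradiance) is accumulated with a track-length
estimator by default, so a non-interacting medium yields phi = 1 in the
beam; an absorbed-weight estimator is available where mua > 0.

Randomness is counter-based: each photon owns a stream keyed by
``(seed, photon index)``, so runs are reproducible and independent of any
batching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from numba import njit

from .geometry import TISSUE, WATER, GeometryError, LabelVolume

CM_TO_MM = 0.1  # coefficients are configured in cm^-1, transport runs in mm


class TransportError(ValueError):
    """Invalid optical properties or transport configuration."""


@dataclass(frozen=True)
class MediumOptics:
    """Absorption/scattering of one medium, cm^-1; g is the HG anisotropy."""

    mua: float
    mus: float
    g: float

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise TransportError("mua and mus must be >= 0")
        if not -1 < self.g < 1:
            raise TransportError("g must lie in (-1, 1)")

    @classmethod
    def from_reduced(cls, mua: float, mus_prime: float, g: float) -> "MediumOptics":
        """Build from reduced scattering mus' = mus (1 - g)."""
        if not -1 < g < 1:
            raise TransportError("g must lie in (-1, 1)")
        return cls(mua=mua, mus=mus_prime / (1.0 - g), g=g)

    @property
    def mus_prime(self) -> float:
        return self.mus * (1.0 - self.g)


@dataclass(frozen=True)
class OpticalProperties:
    """Per-phase optics for water (0), tissue (1) and skeleton (2)."""

    water: MediumOptics
    tissue: MediumOptics
    skeleton: MediumOptics

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        media = (self.water, self.tissue, self.skeleton)
        mua = np.array([m.mua for m in media]) * CM_TO_MM
        mus = np.array([m.mus for m in media]) * CM_TO_MM
        g = np.array([m.g for m in media])
        return mua, mus, g


@dataclass(frozen=True)
class TransportConfig:
    n_photons: int = 1_000_000
    seed: int = 0
    lateral_boundary: str = "periodic"  # or "absorbing"
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    estimator: str = "path_length"  # or "absorbed_weight"

    def __post_init__(self) -> None:
        if self.n_photons < 1_000:
            raise TransportError("n_photons must be >= 1000")
        if not 0 < self.roulette_threshold < 1:
            raise TransportError("roulette_threshold must be in (0, 1)")
        if not 0 < self.roulette_survival < 1:
            raise TransportError("roulette_survival must be in (0, 1)")
        if self.lateral_boundary not in ("periodic", "absorbing"):
            raise TransportError("lateral_boundary must be 'periodic' or 'absorbing'")
        if self.estimator not in ("path_length", "absorbed_weight"):
            raise TransportError("estimator must be 'path_length' or 'absorbed_weight'")


@dataclass
class FluenceVolume:
    """Relative fluence rate phi per voxel plus the energy ledger.

    All ledger entries are fractions of the launched weight.  ``roulette_net``
    is the (zero-mean) weight created minus destroyed by Russian roulette;
    launched = absorbed + escaped + roulette_net to float precision.
    """

    phi: np.ndarray
    resolution: float
    escaped_top: float
    escaped_other: float
    absorbed: dict[str, float]
    roulette_net: float
    n_photons: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def absorbed_total(self) -> float:
        return float(sum(self.absorbed.values()))

    def energy_balance(self) -> float:
        """launched - (absorbed + escaped + roulette_net), as a fraction."""
        return 1.0 - (self.escaped_top + self.escaped_other + self.absorbed_total + self.roulette_net)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.phi.astype(np.float32), photometric="minisblack")
        sidecar = {
            "resolution_mm": self.resolution,
            "normalization": "phi = 1 equals incident collimated irradiance",
            "escaped_top": self.escaped_top,
            "escaped_other": self.escaped_other,
            "absorbed": self.absorbed,
            "roulette_net": self.roulette_net,
            "n_photons": self.n_photons,
            "seed": self.seed,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def sample_hg(g: float, u: float | np.ndarray) -> float | np.ndarray:
    """Inverse-CDF sample of the HG scattering cosine for uniform u in [0, 1].

    For g = 0 the phase function is isotropic and cos(theta) = 2u - 1.
    """
    if not -1 < g < 1:
        raise TransportError("g must lie in (-1, 1)")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise TransportError("u must lie in [0, 1]")
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
        out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# numba kernel

@njit(inline="always", cache=True)
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31)), x


@njit(inline="always", cache=True)
def _rand(state):
    # xorshift64* on a per-photon state; returns double in [0, 1)
    x = state
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    out = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return (out >> np.uint64(11)) * (1.0 / 9007199254740992.0), x


@njit(cache=True)
def _transport_kernel(
    labels, mua, mus, g, res, n_photons, seed, periodic,
    roul_threshold, roul_survival, use_track_length,
    phi, absorbed_vox,
):
    nz, ny, nx = labels.shape
    Lx = nx * res
    Ly = ny * res
    Lz = nz * res
    escaped_top = 0.0
    escaped_other = 0.0
    absorbed = np.zeros(3)
    roulette_net = 0.0
    EPS = 1e-12

    for ip in range(n_photons):
        # counter-based stream: state seeded from (seed, photon index)
        key = (np.uint64(seed) << np.uint64(32)) ^ np.uint64(ip)
        state, _ = _splitmix64(key)
        if state == np.uint64(0):
            state = np.uint64(0x9E3779B97F4A7C15)

        u0, state = _rand(state)
        u1, state = _rand(state)
        x = u0 * Lx
        y = u1 * Ly
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        alive = True

        u2, state = _rand(state)
        tau = -np.log(1.0 - u2 + EPS)

        while alive:
            ix = int(x / res)
            iy = int(y / res)
            iz = int(z / res)
            if ix < 0:
                ix = 0
            elif ix >= nx:
                ix = nx - 1
            if iy < 0:
                iy = 0
            elif iy >= ny:
                iy = ny - 1
            if iz < 0:
                iz = 0
            elif iz >= nz:
                iz = nz - 1

            m = labels[iz, iy, ix]
            mut = mua[m] + mus[m]

            # distance to the nearest voxel face along the direction of travel
            if ux > EPS:
                tx = ((ix + 1) * res - x) / ux
            elif ux < -EPS:
                tx = (ix * res - x) / ux
            else:
                tx = 1e30
            if uy > EPS:
                ty = ((iy + 1) * res - y) / uy
            elif uy < -EPS:
                ty = (iy * res - y) / uy
            else:
                ty = 1e30
            if uz > EPS:
                tz = ((iz + 1) * res - z) / uz
            elif uz < -EPS:
                tz = (iz * res - z) / uz
            else:
                tz = 1e30
            t_bound = min(tx, min(ty, tz))
            if t_bound < 0.0:
                t_bound = 0.0

            if mut * t_bound >= tau and mut > 0.0:
                # interaction inside this voxel
                d = tau / mut
                if use_track_length:
                    phi[iz, iy, ix] += w * d
                x += ux * d
                y += uy * d
                z += uz * d
                dep = w * mua[m] / mut
                absorbed[m] += dep
                if not use_track_length:
                    absorbed_vox[iz, iy, ix] += dep
                w -= dep
                # scatter: HG polar angle, uniform azimuth
                ug, state = _rand(state)
                gm = g[m]
                if gm == 0.0:
                    ct = 2.0 * ug - 1.0
                else:
                    frac = (1.0 - gm * gm) / (1.0 - gm + 2.0 * gm * ug)
                    ct = (1.0 + gm * gm - frac * frac) / (2.0 * gm)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                st = np.sqrt(max(0.0, 1.0 - ct * ct))
                up, state = _rand(state)
                phi_a = 2.0 * np.pi * up
                cp = np.cos(phi_a)
                sp = np.sin(phi_a)
                if abs(uz) > 0.99999:
                    nux = st * cp
                    nuy = st * sp
                    nuz = ct if uz > 0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
                ut, state = _rand(state)
                tau = -np.log(1.0 - ut + EPS)
                # Russian roulette
                if w < roul_threshold:
                    ur, state = _rand(state)
                    if ur < roul_survival:
                        gain = w * (1.0 / roul_survival - 1.0)
                        roulette_net -= gain
                        w /= roul_survival
                    else:
                        roulette_net += w
                        alive = False
                continue

            # free flight to the voxel boundary
            d = t_bound + 1e-9  # nudge across the face
            if use_track_length:
                seg = min(d, t_bound)
                phi[iz, iy, ix] += w * seg
            tau -= mut * d
            if tau < 0.0:
                tau = 0.0
            x += ux * d
            y += uy * d
            z += uz * d

            if z < 0.0:
                escaped_top += w
                alive = False
            elif z >= Lz:
                escaped_other += w  # absorbing bottom plane
                alive = False
            elif x < 0.0 or x >= Lx or y < 0.0 or y >= Ly:
                if periodic:
                    x = x % Lx
                    y = y % Ly
                else:
                    escaped_other += w
                    alive = False

    return escaped_top, escaped_other, absorbed, roulette_net


def run_mc(
    volume: LabelVolume,
    optics: OpticalProperties,
    config: TransportConfig,
) -> FluenceVolume:
    """Run photon transport on a label volume and return the fluence field.

    phi is normalized so that a non-interacting medium yields phi = 1
    everywhere in the collimated beam.
    """
    labels = volume.labels
    mua, mus, g = optics.as_arrays()
    nz, ny, nx = labels.shape
    res = volume.resolution

    phi = np.zeros((nz, ny, nx), dtype=np.float64)
    absorbed_vox = np.zeros((1, 1, 1), dtype=np.float64)
    use_track = config.estimator == "path_length"
    if not use_track:
        if np.any(mua[np.unique(labels)] <= 0):
            raise TransportError("absorbed_weight estimator requires mua > 0 in every present medium")
        absorbed_vox = np.zeros((nz, ny, nx), dtype=np.float64)

    esc_top, esc_other, absorbed, roulette_net = _transport_kernel(
        labels, mua, mus, g, res,
        config.n_photons, config.seed, config.lateral_boundary == "periodic",
        config.roulette_threshold, config.roulette_survival, use_track,
        phi, absorbed_vox,
    )

    n = config.n_photons
    area = nx * ny * res * res
    vvox = res**3
    if use_track:
        # track length per voxel / (voxel volume) / incident photon areal density
        phi *= area / (n * vvox)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            mua_vox = mua[labels]
            phi = np.where(mua_vox > 0, absorbed_vox * area / (n * vvox) / np.where(mua_vox > 0, mua_vox, 1.0), 0.0)

    return FluenceVolume(
        phi=phi,
        resolution=res,
        escaped_top=esc_top / n,
        escaped_other=esc_other / n,
        absorbed={
            "water": absorbed[0] / n,
            "tissue": absorbed[1] / n,
            "skeleton": absorbed[2] / n,
        },
        roulette_net=roulette_net / n,
        n_photons=n,
        seed=config.seed,
        meta={"estimator": config.estimator, "lateral_boundary": config.lateral_boundary},
    )


def surface_escape_profile(fluence: FluenceVolume, volume: LabelVolume) -> np.ndarray:
    """phi in the first water voxel above the local tissue-water interface.

    Returns a 2D map with the lateral grid dimensions.  Columns whose
    surface sits at the grid top report the surface voxel itself.
    """
    if fluence.phi.shape != volume.labels.shape:
        raise TransportError("fluence and label volume grids do not match")
    hidx = volume.surface_height_index()
    above = np.maximum(hidx - 1, 0)
    ny, nx = hidx.shape
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    return fluence.phi[above, iy, ix]


def mean_tissue_phi(fluence: FluenceVolume, volume: LabelVolume) -> float:
    """Mean relative fluence rate over tissue voxels."""
    mask = volume.labels == TISSUE
    if not mask.any():
        raise GeometryError("volume contains no tissue voxels")
    return float(fluence.phi[mask].mean())
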