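"""Brute-force 1-D layered-slab photon transport reference.

Deliberately independent of the package's voxel kernel: continuous-space
propagation through horizontally infinite layers, per-photon Python loop,
numpy RNG.  Used only as a cross-check oracle on depth-resolved fluence.
"""

import numpy as np


def run_reference_slab(layers, z_max, n_bins, n_photons, seed,
                       roulette_threshold=1e-4, roulette_survival=0.1):
    """Track-length fluence estimate on z bins for a layered medium.

    ``layers`` is a list of (z_top, z_bottom, mua, mus, g) in mm / mm^-1.
    Photons start at z=0 going down; top boundary escapes, z >= z_max is
    absorbed.  Returns phi normalized to incident irradiance.
    """
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, z_max, n_bins + 1)
    dz = edges[1] - edges[0]
    track = np.zeros(n_bins)

    def props(z):
        for zt, zb, mua, mus, g in layers:
            if zt <= z < zb:
                return mua, mus, g, zb, zt
        return 0.0, 0.0, 0.0, z_max, 0.0

    for _ in range(n_photons):
        z = 0.0
        uz = 1.0
        ux = uy = 0.0
        w = 1.0
        tau = -np.log(1.0 - rng.random())
        while True:
            mua, mus, g, zb, zt = props(z)
            mut = mua + mus
            # distance along flight to the layer boundary in the z direction
            if uz > 1e-12:
                d_bound = (zb - z) / uz
            elif uz < -1e-12:
                d_bound = (zt - z) / uz
            else:
                d_bound = 1e9
            d_int = tau / mut if mut > 0 else np.inf
            d = min(d_bound + 1e-9, d_int)
            # tally track length into z bins crossed by this segment
            z2 = z + uz * d
            lo, hi = sorted((z, z2))
            i0 = max(0, int(lo / dz))
            i1 = min(n_bins - 1, int(hi / dz))
            if abs(uz) > 1e-12:
                for i in range(i0, i1 + 1):
                    overlap = min(hi, edges[i + 1]) - max(lo, edges[i])
                    if overlap > 0:
                        track[i] += w * overlap / abs(uz)
            else:
                if 0 <= i0 < n_bins:
                    track[i0] += w * d
            if d == d_int:
                tau = 0.0
            else:
                tau -= mut * d
            z = z2
            if z < 0.0 or z >= z_max:
                break
            if d == d_int:
                # interaction: absorb a weight fraction, then HG scatter
                w *= mus / mut
                ct = _hg(g, rng.random())
                st = np.sqrt(max(0.0, 1.0 - ct * ct))
                phi = 2 * np.pi * rng.random()
                if abs(uz) > 0.99999:
                    ux, uy, uz = st * np.cos(phi), st * np.sin(phi), ct * np.sign(uz)
                else:
                    den = np.sqrt(1 - uz * uz)
                    nx = st * (ux * uz * np.cos(phi) - uy * np.sin(phi)) / den + ux * ct
                    ny = st * (uy * uz * np.cos(phi) + ux * np.sin(phi)) / den + uy * ct
                    nz = -st * np.cos(phi) * den + uz * ct
                    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
                    ux, uy, uz = nx / norm, ny / norm, nz / norm
                tau = -np.log(1.0 - rng.random())
                if w < roulette_threshold:
                    if rng.random() < roulette_survival:
                        w /= roulette_survival
                    else:
                        break
    return track / n_photons / dz


def _hg(g, u):
    if g == 0:
        return 2 * u - 1
    frac = (1 - g * g) / (1 - g + 2 * g * u)
    return float(np.clip((1 + g * g - frac * frac) / (2 * g), -1, 1))
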