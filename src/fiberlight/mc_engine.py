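"""Voxel Monte-Carlo photon transport in homogeneous scattering tissue.

The transport scheme is the classical hop-drop-spin random walk with
absorption weighting and Russian roulette:

* **hop** — free path sampled from the Beer-Lambert distribution,
  ``s = −ln(u)/μ_t``;
* **drop** — at each interaction a fraction ``μ_a/μ_t`` of the packet weight
  is deposited in the enclosing voxel, the remainder survives;
* **spin** — a new direction is drawn from the Henyey-Greenstein phase
  function (polar) and a uniform azimuth;
* packets falling below a weight floor play Russian roulette (survival
  probability ``p``; survivors are re-weighted by ``1/p``), which keeps the
  estimator unbiased while bounding the walk length.

Photons leaving the grid are tallied as escaped; the tissue is treated as an
infinite homogeneous medium within the grid (no refractive-index mismatch at
the grid faces — the source sits millimetres deep in tissue).

Fluence is recovered from absorbed energy: in a voxel of volume ``V`` the
fluence rate is ``Φ = E_dep / (μ_a · V)`` per launched packet, and is then
rescaled by the disc area ``π r²`` so that the map is expressed in multiples
of the source exit intensity ``I₀ = P/(π r²)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from fiberlight.optics import FluenceMap, OpticalProperties, Photon, SourceSpec, VoxelGrid

__all__ = [
    "sample_free_path",
    "sample_hg_cosine",
    "launch_photon",
    "propagate",
    "run_mc",
    "ROULETTE_WEIGHT",
    "ROULETTE_SURVIVAL",
]

#: default Russian-roulette weight floor and survival probability
ROULETTE_WEIGHT = 1e-4
ROULETTE_SURVIVAL = 0.1


# ---------------------------------------------------------------------------
# elementary samplers (thin, array-friendly wrappers used by tests and by the
# Python-level API; the jitted kernel re-implements them scalar-inline)
# ---------------------------------------------------------------------------

def sample_free_path(mu_t: float, u):
    """Free path length (mm) for total attenuation ``mu_t`` and uniform variate ``u``.

    ``s = −ln(u)/μ_t`` with ``u`` in (0, 1]; the mean path is ``1/μ_t``.
    """
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must lie in (0, 1]")
    out = -np.log(u) / mu_t
    return float(out) if out.ndim == 0 else out

def sample_hg_cosine(g: float, u):
    """Cosine of the Henyey-Greenstein scattering angle by inverse CDF.

    For ``g = 0`` the phase function is isotropic and ``cosθ = 2u − 1``;
    otherwise the standard closed form

    ``cosθ = (1 + g² − ((1 − g²)/(1 − g + 2gu))²) / (2g)``

    is used.  The first moment of the sampled cosine equals ``g``.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must satisfy -1 < g < 1")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
        out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def launch_photon(source: SourceSpec, rng: np.random.Generator) -> Photon:
    """Draw one photon from a disc source: uniform over the disc, uniform in
    solid angle within the emission cone, weight 1."""
    e1, e2 = source.basis()
    n = np.asarray(source.normal)
    r = source.radius * math.sqrt(rng.random())
    psi = 2.0 * math.pi * rng.random()
    pos = np.asarray(source.center) + r * (math.cos(psi) * e1 + math.sin(psi) * e2)
    cos_min = math.cos(source.half_angle)
    cos_a = 1.0 - rng.random() * (1.0 - cos_min)
    sin_a = math.sqrt(max(0.0, 1.0 - cos_a * cos_a))
    phi = 2.0 * math.pi * rng.random()
    direction = cos_a * n + sin_a * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return Photon(position=pos, direction=direction, weight=1.0)


# ---------------------------------------------------------------------------
# jitted transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _propagate_one(x, y, z, ux, uy, uz, w,
                   mu_a, mu_s, g,
                   ox, oy, oz, inv_vox, nx, ny, nz,
                   tally, w_min, p_surv, rng):
    """Transport one packet to termination.

    Returns (deposited, escaped, killed, boosted): weight absorbed in the
    grid, weight carried out of the grid, weight destroyed by roulette, and
    weight created by roulette re-weighting.  The per-packet balance is
    ``deposited + escaped + killed − boosted = w_launched`` exactly.
    """
    mu_t = mu_a + mu_s
    frac_a = mu_a / mu_t
    deposited = 0.0
    escaped = 0.0
    killed = 0.0
    boosted = 0.0
    while True:
        # hop
        u = 1.0 - rng.random()          # in (0, 1]
        s = -math.log(u) / mu_t
        x += s * ux
        y += s * uy
        z += s * uz
        i = int((x - ox) * inv_vox)
        j = int((y - oy) * inv_vox)
        k = int((z - oz) * inv_vox)
        if x < ox or y < oy or z < oz or i >= nx or j >= ny or k >= nz:
            escaped += w
            break
        # drop
        dep = w * frac_a
        tally[i, j, k] += dep
        deposited += dep
        w -= dep
        if w <= 0.0:
            break
        # roulette
        if w < w_min:
            if rng.random() < p_surv:
                boosted += w * (1.0 / p_surv - 1.0)
                w /= p_surv
            else:
                killed += w
                break
        # spin
        if g == 0.0:
            cost = 2.0 * rng.random() - 1.0
        else:
            frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * rng.random())
            cost = (1.0 + g * g - frac * frac) / (2.0 * g)
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
        sint = math.sqrt(1.0 - cost * cost)
        # uniform azimuth via rejection on the unit circle (no cos/sin calls)
        while True:
            v1 = 2.0 * rng.random() - 1.0
            v2 = 2.0 * rng.random() - 1.0
            r2 = v1 * v1 + v2 * v2
            if 0.0 < r2 <= 1.0:
                break
        inv_r2 = 1.0 / r2
        cosp = (v1 * v1 - v2 * v2) * inv_r2
        sinp = 2.0 * v1 * v2 * inv_r2
        if abs(uz) > 0.99999:
            ux = sint * cosp
            uy = sint * sinp
            uz = cost if uz > 0.0 else -cost
        else:
            den = math.sqrt(1.0 - uz * uz)
            inv_den = 1.0 / den
            tx = sint * (ux * uz * cosp - uy * sinp) * inv_den + ux * cost
            ty = sint * (uy * uz * cosp + ux * sinp) * inv_den + uy * cost
            tz = -sint * cosp * den + uz * cost
            ux = tx
            uy = ty
            uz = tz
    return deposited, escaped, killed, boosted


@njit(cache=True, fastmath=True)
def _run_kernel(n_photons,
                cx, cy, cz, nx0, ny0, nz0, e1x, e1y, e1z, e2x, e2y, e2z,
                radius, cos_min,
                mu_a, mu_s, g,
                ox, oy, oz, inv_vox, nx, ny, nz,
                tally, w_min, p_surv, rng):
    deposited = 0.0
    escaped = 0.0
    killed = 0.0
    boosted = 0.0
    for _ in range(n_photons):
        # launch: uniform over disc, uniform solid angle in cone
        r = radius * math.sqrt(rng.random())
        psi = 2.0 * math.pi * rng.random()
        cpsi = math.cos(psi)
        spsi = math.sin(psi)
        x = cx + r * (cpsi * e1x + spsi * e2x)
        y = cy + r * (cpsi * e1y + spsi * e2y)
        z = cz + r * (cpsi * e1z + spsi * e2z)
        cos_a = 1.0 - rng.random() * (1.0 - cos_min)
        sin_a = math.sqrt(max(0.0, 1.0 - cos_a * cos_a))
        phi = 2.0 * math.pi * rng.random()
        cphi = math.cos(phi)
        sphi = math.sin(phi)
        ux = cos_a * nx0 + sin_a * (cphi * e1x + sphi * e2x)
        uy = cos_a * ny0 + sin_a * (cphi * e1y + sphi * e2y)
        uz = cos_a * nz0 + sin_a * (cphi * e1z + sphi * e2z)
        d, e, kk, b = _propagate_one(x, y, z, ux, uy, uz, 1.0,
                                     mu_a, mu_s, g,
                                     ox, oy, oz, inv_vox, nx, ny, nz,
                                     tally, w_min, p_surv, rng)
        deposited += d
        escaped += e
        killed += kk
        boosted += b
    return deposited, escaped, killed, boosted


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def propagate(photon: Photon, grid: VoxelGrid, props: OpticalProperties,
              deposit: np.ndarray, rng: np.random.Generator,
              roulette_weight: float = ROULETTE_WEIGHT,
              roulette_survival: float = ROULETTE_SURVIVAL) -> dict:
    """Transport a single photon packet to termination.

    ``deposit`` is a float64 array of the grid's shape into which absorbed
    weight is accumulated in place.  Set ``roulette_weight=0`` to disable
    Russian roulette (the walk then ends only by escape or full absorption).

    Returns a record with the weight ledger; by construction
    ``deposited + escaped + killed − boosted`` equals the launched weight.
    """
    if not grid.contains(photon.position):
        raise ValueError("photon must start inside the grid")
    if deposit.shape != tuple(grid.shape):
        raise ValueError("deposit array shape must match grid shape")
    x, y, z = (float(v) for v in photon.position)
    ux, uy, uz = (float(v) for v in photon.direction)
    d, e, k, b = _propagate_one(
        x, y, z, ux, uy, uz, float(photon.weight),
        props.mu_a, props.mu_s, props.g,
        grid.origin[0], grid.origin[1], grid.origin[2],
        1.0 / grid.voxel_size, grid.shape[0], grid.shape[1], grid.shape[2],
        deposit, roulette_weight, roulette_survival, rng,
    )
    return {"deposited": d, "escaped": e, "killed": k, "boosted": b,
            "launched": float(photon.weight)}


def run_mc(source: SourceSpec, grid: VoxelGrid, props: OpticalProperties,
           n_photons: int, seed: int,
           roulette_weight: float = ROULETTE_WEIGHT,
           roulette_survival: float = ROULETTE_SURVIVAL) -> FluenceMap:
    """Run a full Monte-Carlo simulation and return the normalized fluence map.

    The absorbed-energy estimator requires ``mu_a > 0``; per-voxel fluence is
    ``E_dep/(μ_a·V·N)`` rescaled by the disc area so the map is in units of
    the source exit intensity I₀.  The result is deterministic for a given
    ``(seed, n_photons)`` pair.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if props.mu_a <= 0:
        raise ValueError(
            "run_mc uses an absorbed-energy fluence estimator and does not "
            "support a non-absorbing medium (mu_a = 0)"
        )
    rng = np.random.default_rng(seed)
    tally = np.zeros(grid.shape, dtype=np.float64)
    e1, e2 = source.basis()
    n = np.asarray(source.normal)
    d, e, k, b = _run_kernel(
        int(n_photons),
        source.center[0], source.center[1], source.center[2],
        n[0], n[1], n[2], e1[0], e1[1], e1[2], e2[0], e2[1], e2[2],
        source.radius, math.cos(source.half_angle),
        props.mu_a, props.mu_s, props.g,
        grid.origin[0], grid.origin[1], grid.origin[2],
        1.0 / grid.voxel_size, grid.shape[0], grid.shape[1], grid.shape[2],
        tally, roulette_weight, roulette_survival, rng,
    )
    values = tally * (source.area / (props.mu_a * grid.voxel_volume * n_photons))
    meta = {
        "deposited": d, "escaped": e, "killed": k, "boosted": b,
        "launched": float(n_photons),
        "source_radius_mm": source.radius,
        "mu_a": props.mu_a, "mu_s": props.mu_s, "g": props.g, "n": props.n,
    }
    return FluenceMap(grid=grid, values=values, n_photons=int(n_photons),
                      seed=int(seed), meta=meta)
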