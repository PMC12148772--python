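"""Numba-compiled photon transport kernel.

One kernel call transports one batch of histories through the voxel grid
with analog sampling: exact voxel-boundary ray tracing, interaction type
chosen from per-material partial-coefficient fractions, photoelectric
absorption, free-electron Klein-Nishina incoherent scattering with local
deposition of the electron energy (collision-KERMA scoring), Thomson
coherent redirection, and local deposition at the transport cutoff.
With ``scatter_on = False`` every interaction instead deposits
``E * muen/mu`` and terminates, which makes the expected score equal the
primary collision-KERMA closed form (used as a deterministic oracle).

All energies in keV, lengths in cm.
"""
import numpy as np
from numba import njit

MEC2 = 510.998950
_BIG = 1e30


@njit(cache=False, inline="always")
def _sample_kn(e):
    """Klein-Nishina sample: returns (eps = E'/E, cos_theta)."""
    a = e / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = eps0 ** np.random.random()
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        if sin2 < 0.0:
            sin2 = 0.0
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if np.random.random() <= g:
            return eps, 1.0 - t


@njit(cache=False, inline="always")
def _sample_thomson():
    """cos_theta from the Thomson angular law (1 + cos^2)."""
    while True:
        c = 2.0 * np.random.random() - 1.0
        if np.random.random() * 2.0 <= 1.0 + c * c:
            return c


@njit(cache=False, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    if abs(uz) < 0.999999:
        den = np.sqrt(1.0 - uz * uz)
        vx = ux * cost + sint * (ux * uz * cphi - uy * sphi) / den
        vy = uy * cost + sint * (uy * uz * cphi + ux * sphi) / den
        vz = uz * cost - sint * den * cphi
    else:
        vx = sint * cphi
        vy = sint * sphi
        vz = cost if uz > 0.0 else -cost
    n = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / n, vy / n, vz / n


@njit(cache=False)
def run_batch(seed, n_hist,
              cdf, edges,
              ssd, field_r, cx, cy,
              mat, den, dx, dy, dz,
              e0, de, mu_rho, f_pe, f_pe_inc, muen_over_mu,
              cutoff, scatter_on, rayleigh_on,
              edep):
    """Transport ``n_hist`` photons; accumulate deposited energy per voxel.

    Returns (emitted, escaped, discarded) energy totals in keV.
    """
    np.random.seed(seed)
    nx, ny, nz = mat.shape
    xmax = nx * dx
    ymax = ny * dy
    zmax = nz * dz
    ne = mu_rho.shape[1]
    emitted = 0.0
    escaped = 0.0
    discarded = 0.0

    for _ in range(n_hist):
        # energy from the binned spectrum (uniform within the bin)
        u = np.random.random()
        b = np.searchsorted(cdf, u)
        if b >= len(cdf):
            b = len(cdf) - 1
        e = edges[b] + np.random.random() * (edges[b + 1] - edges[b])
        emitted += e

        # direction: source on the axis at z=-ssd aiming at a uniform
        # point of the surface field circle
        r = field_r * np.sqrt(np.random.random())
        ang = 2.0 * np.pi * np.random.random()
        px = cx + r * np.cos(ang)
        py = cy + r * np.sin(ang)
        norm = np.sqrt((px - cx) ** 2 + (py - cy) ** 2 + ssd * ssd)
        ux = (px - cx) / norm
        uy = (py - cy) / norm
        uz = ssd / norm
        x = px
        y = py
        z = 0.0
        i = int(x / dx)
        j = int(y / dy)
        k = 0
        if i < 0 or i >= nx or j < 0 or j >= ny:
            escaped += e
            continue

        alive = True
        while alive:
            ie = int((e - e0) / de + 0.5)
            if ie < 0:
                ie = 0
            elif ie >= ne:
                ie = ne - 1

            tau = -np.log(1.0 - np.random.random())
            # --- ray trace to the interaction point ------------------
            while True:
                m = mat[i, j, k]
                mu = mu_rho[m, ie] * den[i, j, k]
                if ux > 0.0:
                    tx = ((i + 1) * dx - x) / ux
                elif ux < 0.0:
                    tx = (i * dx - x) / ux
                else:
                    tx = _BIG
                if uy > 0.0:
                    ty = ((j + 1) * dy - y) / uy
                elif uy < 0.0:
                    ty = (j * dy - y) / uy
                else:
                    ty = _BIG
                if uz > 0.0:
                    tz = ((k + 1) * dz - z) / uz
                elif uz < 0.0:
                    tz = (k * dz - z) / uz
                else:
                    tz = _BIG
                tmin = tx
                axis = 0
                if ty < tmin:
                    tmin = ty
                    axis = 1
                if tz < tmin:
                    tmin = tz
                    axis = 2
                if tmin < 0.0:
                    tmin = 0.0
                if mu * tmin >= tau:
                    s = tau / mu
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    interacted = True
                    break
                tau -= mu * tmin
                x += tmin * ux
                y += tmin * uy
                z += tmin * uz
                if axis == 0:
                    if ux > 0.0:
                        i += 1
                        x = i * dx
                    else:
                        x = i * dx
                        i -= 1
                elif axis == 1:
                    if uy > 0.0:
                        j += 1
                        y = j * dy
                    else:
                        y = j * dy
                        j -= 1
                else:
                    if uz > 0.0:
                        k += 1
                        z = k * dz
                    else:
                        z = k * dz
                        k -= 1
                if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                    escaped += e
                    interacted = False
                    break
            if not interacted:
                break

            # --- interaction -----------------------------------------
            m = mat[i, j, k]
            if not scatter_on:
                edep[i, j, k] += e * muen_over_mu[m, ie]
                discarded += e * (1.0 - muen_over_mu[m, ie])
                break

            u = np.random.random()
            if u < f_pe[m, ie]:
                edep[i, j, k] += e
                break
            elif u < f_pe_inc[m, ie]:
                eps, cost = _sample_kn(e)
                edep[i, j, k] += e * (1.0 - eps)
                e = e * eps
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
                if e < cutoff:
                    edep[i, j, k] += e
                    break
            else:
                if rayleigh_on:
                    cost = _sample_thomson()
                    phi = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
                # with coherent scattering disabled the event is a
                # delta interaction: the photon continues unchanged,
                # equivalent to removing the coherent cross section

    return emitted, escaped, discarded


@njit(cache=False)
def kn_samples(seed, n, e):
    """n Klein-Nishina (eps, cos_theta) samples at energy e (test oracle)."""
    np.random.seed(seed)
    out = np.empty((n, 2))
    for i in range(n):
        eps, cost = _sample_kn(e)
        out[i, 0] = eps
        out[i, 1] = cost
    return out
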