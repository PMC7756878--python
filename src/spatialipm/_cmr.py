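"""Packed encounter arrays and fast mark-resight likelihood kernels.

Two likelihood paths are provided:

* :func:`nonspatial_loglik` -- the exact marginal forward algorithm over the
  three hidden states with spatially constant detection.

* :func:`spatial_loglik` -- the spatial marginal likelihood.  Latent
  locations in unobserved years are integrated out with a fixed set of
  common-random-number particles: each alive state carries a particle cloud
  seeded at the last sighting and propagated by the site-fidelity /
  Student-T mixture.  "Not seen" years contribute the cloud-averaged
  probability of non-detection (including the mass outside the study area,
  where detection is zero); re-sighting years contribute the kernel density
  of the observed location under the cloud, with the exact-stay atom handled
  separately (a breeder re-sighted at precisely its previous site is a
  site-fidelity event).  Because the particle base draws are fixed across
  parameter evaluations, the approximate likelihood is a smooth function of
  the parameters and can be explored by Metropolis-Hastings.

Within a multi-year gap the kernel scale of a cloud follows the cloud's own
habitat state; the first step after a sighting of known habitat uses the
known origin habitat exactly.  The residual approximation (ignoring habitat
switching part-way through a gap) is second order in the switch
probabilities psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["PackedEncounters", "pack_encounters", "spatial_loglik", "nonspatial_loglik"]


@dataclass
class PackedEncounters:
    """Flat-array view of a set of encounter histories (one sex)."""

    first: np.ndarray  # (n,) first occasion index
    mark_fl: np.ndarray  # (n,) 1 if marked as fledgling
    mark_hab: np.ndarray  # (n,) habitat at first capture
    events: np.ndarray  # (n, T) codes 0-4; 0 before marking
    ox: np.ndarray  # (n, T) sighting x (NaN when unseen)
    oy: np.ndarray
    n_years: int

    @property
    def n_individuals(self) -> int:
        return int(self.first.size)

    def particle_draws(self, n_particles: int, seed) -> tuple[np.ndarray, np.ndarray]:
        """Fixed standard-T(5) steps and stay-gate uniforms for the spatial
        marginal likelihood (common random numbers across evaluations)."""
        rng = np.random.default_rng(seed)
        n, t = self.events.shape
        tsteps = rng.standard_t(5.0, size=(n, t, n_particles, 2)).astype(np.float32)
        ustay = rng.random(size=(n, t, n_particles)).astype(np.float32)
        return tsteps, ustay


def pack_encounters(df, years) -> PackedEncounters:
    """Pack a validated wide encounter table into contiguous arrays."""
    years = np.asarray(years)
    t = years.size
    n = len(df)
    first = (df["mark_year"].to_numpy() - years[0]).astype(np.int64)
    mark_fl = (df["mark_age"] == "fledgling").to_numpy().astype(np.int64)
    mark_hab = (df["mark_habitat"] == "Tall").to_numpy().astype(np.int64)
    events = np.zeros((n, t), dtype=np.int64)
    ox = np.full((n, t), np.nan)
    oy = np.full((n, t), np.nan)
    for k, yr in enumerate(years):
        events[:, k] = df[f"event_{yr}"].to_numpy()
        ox[:, k] = df[f"x_{yr}"].to_numpy()
        oy[:, k] = df[f"y_{yr}"].to_numpy()
    return PackedEncounters(
        first=first,
        mark_fl=mark_fl,
        mark_hab=mark_hab,
        events=events,
        ox=ox,
        oy=oy,
        n_years=t,
    )


@njit(cache=True)
def _t_logconst(df: float) -> float:
    return (
        math.lgamma(0.5 * (df + 1.0))
        - math.lgamma(0.5 * df)
        - 0.5 * math.log(df * math.pi)
    )


@njit(cache=True)
def _zone(x, y, trect, crect):
    """0 = core, 1 = peripheral, 2 = outside."""
    if crect[0] <= x <= crect[1] and crect[2] <= y <= crect[3]:
        return 0
    if trect[0] <= x <= trect[1] and trect[2] <= y <= trect[3]:
        return 1
    return 2


@njit(cache=True, fastmath=True)
def spatial_loglik(
    first,
    mark_fl,
    mark_hab,
    events,
    ox,
    oy,
    tsteps,
    ustay,
    phi,  # (T, 2 ages, 2 habitats): survival for transition t -> t+1
    psi,  # (2 ages, 2 habitats)
    sigma,  # (2 ages, 2 habitats)
    pstay,  # (2 habitats), breeders only
    df,
    pz,  # (2,) detection in (core, peripheral)
    cz,  # (2,) habitat determination in (core, peripheral)
    trect,
    crect,
):
    n, T = events.shape
    P = tsteps.shape[2]
    tconst = _t_logconst(df)
    half = 0.5 * (df + 1.0)
    norm2d = 2.0 * tconst
    total = 0.0
    # particle clouds per alive state; collapse onto the anchor is lazy
    # (gap == 0 means both clouds sit exactly at the anchor)
    pos = np.empty((2, P, 2), dtype=np.float32)
    atom = np.empty((2, P), dtype=np.uint8)
    dens = np.empty(2)
    e_alive = np.empty(2)
    for i in range(n):
        a0 = first[i]
        if a0 >= T - 1:
            continue
        ax = ox[i, a0]
        ay = oy[i, a0]
        a_s = 1.0 if mark_hab[i] == 0 else 0.0
        a_t = 1.0 - a_s
        a_d = 0.0
        gap = 0
        orig_hab = mark_hab[i]
        ll = 0.0
        for k in range(a0 + 1, T):
            tprev = k - 1
            age = 0 if (mark_fl[i] == 1 and tprev == a0) else 1
            phi_s = phi[tprev, age, 0]
            phi_t = phi[tprev, age, 1]
            psi_s = psi[age, 0]
            psi_t = psi[age, 1]
            n_s = a_s * phi_s * (1.0 - psi_s) + a_t * phi_t * psi_t
            n_t = a_s * phi_s * psi_s + a_t * phi_t * (1.0 - psi_t)
            n_d = a_d + a_s * (1.0 - phi_s) + a_t * (1.0 - phi_t)
            ev = events[i, k]
            if ev == 4:
                t0f = np.float32(trect[0])
                t1f = np.float32(trect[1])
                t2f = np.float32(trect[2])
                t3f = np.float32(trect[3])
                c0f = np.float32(crect[0])
                c1f = np.float32(crect[1])
                c2f = np.float32(crect[2])
                c3f = np.float32(crect[3])
                for h in range(2):
                    if gap == 0 and orig_hab >= 0:
                        sig = sigma[age, orig_hab]
                        ps = pstay[orig_hab] if age == 1 else 0.0
                    else:
                        sig = sigma[age, h]
                        ps = pstay[h] if age == 1 else 0.0
                    # fledglings always move: an impossible stay threshold
                    psf = np.float32(ps) if age == 1 else np.float32(-1.0)
                    sigf = np.float32(sig)
                    axf = np.float32(ax)
                    ayf = np.float32(ay)
                    c_out = 0
                    c_core = 0
                    if gap == 0:
                        for p in range(P):
                            mv = ustay[i, k, p] >= psf
                            f = np.float32(1.0) if mv else np.float32(0.0)
                            px = axf + f * sigf * tsteps[i, k, p, 0]
                            py = ayf + f * sigf * tsteps[i, k, p, 1]
                            pos[h, p, 0] = px
                            pos[h, p, 1] = py
                            atom[h, p] = np.uint8(0) if mv else np.uint8(1)
                            in_core = (
                                (px >= c0f) and (px <= c1f) and (py >= c2f) and (py <= c3f)
                            )
                            in_tot = (
                                (px >= t0f) and (px <= t1f) and (py >= t2f) and (py <= t3f)
                            )
                            c_core += 1 if in_core else 0
                            c_out += 0 if in_tot else 1
                    else:
                        for p in range(P):
                            mv = ustay[i, k, p] >= psf
                            f = np.float32(1.0) if mv else np.float32(0.0)
                            px = pos[h, p, 0] + f * sigf * tsteps[i, k, p, 0]
                            py = pos[h, p, 1] + f * sigf * tsteps[i, k, p, 1]
                            pos[h, p, 0] = px
                            pos[h, p, 1] = py
                            if mv:
                                atom[h, p] = np.uint8(0)
                            in_core = (
                                (px >= c0f) and (px <= c1f) and (py >= c2f) and (py <= c3f)
                            )
                            in_tot = (
                                (px >= t0f) and (px <= t1f) and (py >= t2f) and (py <= t3f)
                            )
                            c_core += 1 if in_core else 0
                            c_out += 0 if in_tot else 1
                    c_per = P - c_core - c_out
                    e_alive[h] = (
                        c_out / P
                        + (c_core / P) * (1.0 - pz[0])
                        + (c_per / P) * (1.0 - pz[1])
                    )
                gap += 1
                e_s = e_alive[0]
                e_t = e_alive[1]
                e_d = 1.0
            else:
                gx = ox[i, k]
                gy = oy[i, k]
                z = _zone(gx, gy, trect, crect)
                if z == 2:
                    # a sighting outside the total area has probability zero
                    ll = -np.inf
                    break
                pdet = pz[z]
                cdet = cz[z]
                same = abs(gx - ax) < 1e-9 and abs(gy - ay) < 1e-9
                for h in range(2):
                    if gap == 0 and orig_hab >= 0:
                        sig = sigma[age, orig_hab]
                        ps = pstay[orig_hab] if age == 1 else 0.0
                    else:
                        sig = sigma[age, h]
                        ps = pstay[h] if age == 1 else 0.0
                    if age == 1 and same and ps > 0.0:
                        if gap == 0:
                            dens[h] = ps
                        else:
                            na = 0
                            for p in range(P):
                                na += atom[h, p]
                            dens[h] = ps * na / P
                    elif gap == 0:
                        # single known origin: exact kernel density
                        dx = (gx - ax) / sig
                        dy = (gy - ay) / sig
                        lg = (
                            norm2d
                            - half * math.log1p(dx * dx / df)
                            - half * math.log1p(dy * dy / df)
                        )
                        dens[h] = (1.0 - ps) * math.exp(lg) / (sig * sig)
                    else:
                        s = 0.0
                        for p in range(P):
                            dx = (gx - pos[h, p, 0]) / sig
                            dy = (gy - pos[h, p, 1]) / sig
                            lg = (
                                norm2d
                                - half * math.log1p(dx * dx / df)
                                - half * math.log1p(dy * dy / df)
                            )
                            s += math.exp(lg)
                        dens[h] = (1.0 - ps) * s / (P * sig * sig)
                if ev == 1:
                    e_s = dens[0] * pdet * cdet
                    e_t = 0.0
                elif ev == 2:
                    e_s = 0.0
                    e_t = dens[1] * pdet * cdet
                else:
                    e_s = dens[0] * pdet * (1.0 - cdet)
                    e_t = dens[1] * pdet * (1.0 - cdet)
                e_d = 0.0
                # collapse clouds onto the sighting (lazily via gap = 0)
                ax = gx
                ay = gy
                gap = 0
                orig_hab = 0 if ev == 1 else (1 if ev == 2 else -1)
            a_s = n_s * e_s
            a_t = n_t * e_t
            a_d = n_d * e_d
            tot = a_s + a_t + a_d
            if tot <= 0.0 or not np.isfinite(tot):
                ll = -np.inf
                break
            ll += math.log(tot)
            a_s /= tot
            a_t /= tot
            a_d /= tot
        total += ll
        if not np.isfinite(total):
            return -np.inf
    return total


@njit(cache=True)
def nonspatial_loglik(
    first,
    mark_fl,
    mark_hab,
    events,
    phi,  # (T, 2, 2)
    psi,  # (2, 2)
    p,
    c,
):
    n, T = events.shape
    total = 0.0
    for i in range(n):
        a0 = first[i]
        if a0 >= T - 1:
            continue
        a_s = 1.0 if mark_hab[i] == 0 else 0.0
        a_t = 1.0 - a_s
        a_d = 0.0
        ll = 0.0
        for k in range(a0 + 1, T):
            tprev = k - 1
            age = 0 if (mark_fl[i] == 1 and tprev == a0) else 1
            phi_s = phi[tprev, age, 0]
            phi_t = phi[tprev, age, 1]
            psi_s = psi[age, 0]
            psi_t = psi[age, 1]
            n_s = a_s * phi_s * (1.0 - psi_s) + a_t * phi_t * psi_t
            n_t = a_s * phi_s * psi_s + a_t * phi_t * (1.0 - psi_t)
            n_d = a_d + a_s * (1.0 - phi_s) + a_t * (1.0 - phi_t)
            ev = events[i, k]
            if ev == 1:
                a_s = n_s * p * c
                a_t = 0.0
                a_d = 0.0
            elif ev == 2:
                a_s = 0.0
                a_t = n_t * p * c
                a_d = 0.0
            elif ev == 3:
                a_s = n_s * p * (1.0 - c)
                a_t = n_t * p * (1.0 - c)
                a_d = 0.0
            else:
                a_s = n_s * (1.0 - p)
                a_t = n_t * (1.0 - p)
                a_d = n_d
            tot = a_s + a_t + a_d
            if tot <= 0.0:
                return -np.inf
            ll += math.log(tot)
            a_s /= tot
            a_t /= tot
            a_d /= tot
        total += ll
    return total
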