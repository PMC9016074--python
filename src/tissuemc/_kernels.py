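"""Numba transport kernels for the layered and voxel Monte Carlo engines.

Packets are propagated sequentially from a single RNG stream, so a run is
bit-reproducible given (seed, config).  Accumulation is double precision
with 64-bit counters.  Two RNGs are available inside the kernels:

* kind 0 — xoshiro256** (the high-quality default), and
* kind 1 — a clone of ``ran3`` (the subtractive lagged-Fibonacci generator
  of Numerical Recipes in C), shipped for bias studies.

The scalar output slots of a run are listed in the ``S_*`` constants.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# scalar output slots
S_SPECULAR = 0
S_R_TOTAL = 1
S_T_TOTAL = 2
S_A_INTERIOR = 3
S_A_SURFACE = 4
S_KILLED = 5
S_R_SUMSQ = 6
S_T_SUMSQ = 7
S_RAD_TOP_DISC = 8
S_RAD_TOP_OVER = 9
S_RAD_BOT_DISC = 10
S_RAD_BOT_OVER = 11
S_CART_DISC = 12
S_CART_OVER = 13
S_FIB_DISC = 14
S_TRACE_DROPPED = 15
S_LATERAL = 16
N_SCALARS = 20

# terminal kinds in trace records
TERM_DIED = 0
TERM_TOP = 1
TERM_BOTTOM = 2
TERM_OVERFLOW = 3
TERM_KILLED = 4

# source kinds
SRC_PENCIL = 0
SRC_ISOTROPIC = 1
SRC_GAUSSIAN = 2
SRC_UNIFORM = 3
SRC_FIBER = 4
SRC_RECT = 5

# stepping methods (voxel engine)
STEP_AW = 0
STEP_AR = 1
STEP_MBL = 2

_INV_2_53 = 1.0 / 9007199254740992.0
_MBIG = 1000000000

# guard against pathological non-terminating packets (perfect mirrors etc.)
_MAX_EVENTS = 50_000_000


# ---------------------------------------------------------------------------
# RNG
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rnd(kind, su, ma, st):
    """Uniform deviate on [0, 1) from the selected generator state."""
    if kind == 0:
        # xoshiro256**
        x = su[1] * np.uint64(5)
        res = ((x << np.uint64(7)) | (x >> np.uint64(57))) * np.uint64(9)
        t = su[1] << np.uint64(17)
        su[2] ^= su[0]
        su[3] ^= su[1]
        su[1] ^= su[2]
        su[0] ^= su[3]
        su[2] ^= t
        su[3] = (su[3] << np.uint64(45)) | (su[3] >> np.uint64(19))
        return float(res >> np.uint64(11)) * _INV_2_53
    else:
        # ran3 (Numerical Recipes subtractive generator)
        inext = st[0] + 1
        if inext == 56:
            inext = 1
        inextp = st[1] + 1
        if inextp == 56:
            inextp = 1
        mj = ma[inext] - ma[inextp]
        if mj < 0:
            mj += _MBIG
        ma[inext] = mj
        st[0] = inext
        st[1] = inextp
        return mj * (1.0 / _MBIG)


@njit(cache=True)
def draw_uniform(kind, su, ma, st, out):
    for i in range(out.size):
        out[i] = _rnd(kind, su, ma, st)


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _fresnel_k(n1, n2, ci):
    """Unpolarized Fresnel; returns (reflectance, cos_t); cos_t = -1 on TIR."""
    if n1 == n2:
        return 0.0, ci
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0, -1.0
    ct = np.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    """MCML direction update: deflect by acos(ct) with azimuth phi."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = st * cp
        nuy = st * sp
        nuz = ct if uz >= 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nuz = -den * st * cp + uz * ct
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, inline="always")
def _lut_sample(row, xi):
    n = row.size
    pos = xi * (n - 1)
    i = int(pos)
    if i > n - 2:
        i = n - 2
    f = pos - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit(cache=True, inline="always")
def _bin_index(edges, v):
    """Half-open bins [e_i, e_{i+1}); the last bin is upper-inclusive.
    Returns -1 outside the edge span."""
    n = edges.size - 1
    if v < edges[0] or v > edges[n]:
        return -1
    if v == edges[n]:
        return n - 1
    lo = 0
    hi = n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if v < edges[mid]:
            hi = mid
        else:
            lo = mid
    return lo


@njit(cache=True, inline="always")
def _fluence_deposit(fl_grid, x, y, z, w,
                     fx0, fy0, fz0, fdx, fdy, fdz, fnx, fny, fnz):
    ix = int(np.floor((x - fx0) / fdx))
    iy = int(np.floor((y - fy0) / fdy))
    iz = int(np.floor((z - fz0) / fdz))
    if 0 <= ix < fnx and 0 <= iy < fny and 0 <= iz < fnz:
        fl_grid[(ix * fny + iy) * fnz + iz] += w


# ---------------------------------------------------------------------------
# layered engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_layered_kernel(
    n_packets,
    # regions 0..L+1 (0 and L+1 are bounding media)
    mua, mus, nn, ztop, zbot, luts,
    # source
    src_kind, src_p,
    # surface layout (fiber probe); zero fibers + lay_on=0 means none
    lay_on, lay_tip_r2, lay_refl, lay_n_out, lay_lambert,
    lay_fx, lay_fy, lay_rcore2, lay_ncore, lay_cosmin,
    # detectors
    top_on, redges_top, cosmin_top,
    bot_on, redges_bot, cosmin_bot,
    cart_on, cxedges, cax_x, cax_z, c_cosmin,
    fd_on, fd_x, fd_y, fd_r2, fd_cosmin,
    # fluence / energy-deposition grid
    fl_on, fx0, fy0, fz0, fdx, fdy, fdz, fnx, fny, fnz, fl_grid,
    # trace
    tr_on, tr_cap, tr_ev, tr_nev, tr_term,
    # control
    split_bnd, roul_on, roul_thresh, roul_m,
    rng_kind, su, ma3, st3,
    # outputs
    out, rad_top, rad_bot, cart, fd_w,
):
    n_regions = mua.size
    last_int = n_regions - 2
    for ip in range(n_packets):
        # ---------------- launch ----------------
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        reg = 1
        if src_kind == SRC_PENCIL:
            rf, _ct = _fresnel_k(nn[0], nn[1], 1.0)
            out[S_SPECULAR] += rf
            w = 1.0 - rf
        elif src_kind == SRC_GAUSSIAN:
            # Box-Muller
            u1 = _rnd(rng_kind, su, ma3, st3)
            u2 = _rnd(rng_kind, su, ma3, st3)
            rr = np.sqrt(-2.0 * np.log(1.0 - u1))
            x = src_p[0] * rr * np.cos(2.0 * np.pi * u2)
            y = src_p[0] * rr * np.sin(2.0 * np.pi * u2)
            rf, _ct = _fresnel_k(nn[0], nn[1], 1.0)
            out[S_SPECULAR] += rf
            w = 1.0 - rf
        elif src_kind == SRC_UNIFORM:
            rr = src_p[0] * np.sqrt(_rnd(rng_kind, su, ma3, st3))
            aa = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            x = rr * np.cos(aa)
            y = rr * np.sin(aa)
            rf, _ct = _fresnel_k(nn[0], nn[1], 1.0)
            out[S_SPECULAR] += rf
            w = 1.0 - rf
        elif src_kind == SRC_RECT:
            x = (_rnd(rng_kind, su, ma3, st3) - 0.5) * src_p[0]
            y = (_rnd(rng_kind, su, ma3, st3) - 0.5) * src_p[1]
            rf, _ct = _fresnel_k(nn[0], nn[1], 1.0)
            out[S_SPECULAR] += rf
            w = 1.0 - rf
        elif src_kind == SRC_ISOTROPIC:
            x = src_p[0]
            y = src_p[1]
            z = src_p[2]
            uz = 2.0 * _rnd(rng_kind, su, ma3, st3) - 1.0
            aa = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            ss = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = ss * np.cos(aa)
            uy = ss * np.sin(aa)
            reg = 1
            while reg < n_regions - 1 and z >= zbot[reg]:
                reg += 1
        elif src_kind == SRC_FIBER:
            rr = src_p[0] * np.sqrt(_rnd(rng_kind, su, ma3, st3))
            aa = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            x = src_p[3] + rr * np.cos(aa)
            y = src_p[4] + rr * np.sin(aa)
            # uniform over solid angle of the in-core cone
            ct = 1.0 - _rnd(rng_kind, su, ma3, st3) * (1.0 - src_p[2])
            stt = np.sqrt(max(0.0, 1.0 - ct * ct))
            bb = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            n_core = src_p[1]
            rf, ctt = _fresnel_k(n_core, nn[1], ct)
            out[S_SPECULAR] += rf
            w = 1.0 - rf
            if ctt < 0.0:
                ctt = ct
            scale = n_core / nn[1]
            ux = stt * np.cos(bb) * scale
            uy = stt * np.sin(bb) * scale
            uz = ctt
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

        wr = 0.0
        wt = 0.0
        alive = True
        tr_over = False
        nev = 0
        term_kind = TERM_DIED
        if tr_on:
            tr_ev[ip, 0, 0] = x
            tr_ev[ip, 0, 1] = y
            tr_ev[ip, 0, 2] = z
            tr_ev[ip, 0, 3] = ux
            tr_ev[ip, 0, 4] = uy
            tr_ev[ip, 0, 5] = uz
            tr_ev[ip, 0, 6] = w
            nev = 1
        n_steps = 0

        while alive:
            n_steps += 1
            if n_steps > _MAX_EVENTS:
                out[S_KILLED] += w
                term_kind = TERM_KILLED
                break
            sdim = -np.log(1.0 - _rnd(rng_kind, su, ma3, st3))
            # ------- hop, possibly across boundaries -------
            interacted = False
            while True:
                mt = mua[reg] + mus[reg]
                s = sdim / mt if mt > 0.0 else np.inf
                if uz > 0.0:
                    db = (zbot[reg] - z) / uz
                elif uz < 0.0:
                    db = (ztop[reg] - z) / uz
                else:
                    db = np.inf
                if db < 0.0:
                    db = 0.0
                if s < db:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    interacted = True
                    break
                if db == np.inf:
                    # clear infinite medium moving laterally: degenerate
                    out[S_KILLED] += w
                    alive = False
                    term_kind = TERM_KILLED
                    break
                x += ux * db
                y += uy * db
                z += uz * db
                if mt > 0.0:
                    sdim -= db * mt
                    if sdim < 0.0:
                        sdim = 0.0
                going_up = uz < 0.0
                nxt = reg - 1 if going_up else reg + 1
                ci = -uz if going_up else uz
                if ci > 1.0:
                    ci = 1.0
                if nxt == 0:
                    # ---- top surface ----
                    z = 0.0
                    handled = False
                    if lay_on == 1:
                        infib = -1
                        for f in range(lay_fx.size):
                            ddx = x - lay_fx[f]
                            ddy = y - lay_fy[f]
                            if ddx * ddx + ddy * ddy <= lay_rcore2[f]:
                                infib = f
                                break
                        if infib >= 0:
                            rf, ct = _fresnel_k(nn[reg], lay_ncore[infib], ci)
                            if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                                uz = -uz
                            else:
                                scale = nn[reg] / lay_ncore[infib]
                                uxo = ux * scale
                                uyo = uy * scale
                                uzo = -ct
                                norm = np.sqrt(uxo * uxo + uyo * uyo + uzo * uzo)
                                uxo /= norm
                                uyo /= norm
                                uzo /= norm
                                out[S_R_TOTAL] += w
                                wr += w
                                if ct >= lay_cosmin[infib]:
                                    fd_w[infib] += w
                                else:
                                    out[S_FIB_DISC] += w
                                if top_on == 1:
                                    r = np.sqrt(x * x + y * y)
                                    if ct >= cosmin_top:
                                        bi = _bin_index(redges_top, r)
                                        if bi >= 0:
                                            rad_top[bi] += w
                                        else:
                                            out[S_RAD_TOP_OVER] += w
                                    else:
                                        out[S_RAD_TOP_DISC] += w
                                ux = uxo
                                uy = uyo
                                uz = uzo
                                alive = False
                                term_kind = TERM_TOP
                            handled = True
                        elif x * x + y * y <= lay_tip_r2:
                            # metal housing
                            out[S_A_SURFACE] += w * (1.0 - lay_refl)
                            w *= lay_refl
                            if w <= 0.0:
                                alive = False
                                term_kind = TERM_DIED
                            elif lay_lambert == 1:
                                czz = np.sqrt(_rnd(rng_kind, su, ma3, st3))
                                szz = np.sqrt(max(0.0, 1.0 - czz * czz))
                                aa = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
                                ux = szz * np.cos(aa)
                                uy = szz * np.sin(aa)
                                uz = czz
                            else:
                                uz = -uz
                            handled = True
                    if not handled:
                        n_out = lay_n_out if lay_on == 1 else nn[0]
                        rf, ct = _fresnel_k(nn[reg], n_out, ci)
                        w_esc = 0.0
                        if split_bnd == 1 and ct >= 0.0:
                            w_esc = w * (1.0 - rf)
                            w *= rf
                            uz = -uz
                            if w <= 0.0:
                                alive = False
                                term_kind = TERM_TOP
                        else:
                            if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                                uz = -uz
                            else:
                                w_esc = w
                                alive = False
                                term_kind = TERM_TOP
                        if w_esc > 0.0:
                            scale = nn[reg] / n_out
                            uxo = ux * scale
                            uyo = uy * scale
                            uzo = -ct
                            norm = np.sqrt(uxo * uxo + uyo * uyo + uzo * uzo)
                            uxo /= norm
                            uyo /= norm
                            uzo /= norm
                            out[S_R_TOTAL] += w_esc
                            wr += w_esc
                            if top_on == 1:
                                r = np.sqrt(x * x + y * y)
                                if ct >= cosmin_top:
                                    bi = _bin_index(redges_top, r)
                                    if bi >= 0:
                                        rad_top[bi] += w_esc
                                    else:
                                        out[S_RAD_TOP_OVER] += w_esc
                                else:
                                    out[S_RAD_TOP_DISC] += w_esc
                            if cart_on == 1:
                                ca = uxo * cax_x + uzo * cax_z
                                if ca >= c_cosmin:
                                    bi = _bin_index(cxedges, x)
                                    if bi >= 0:
                                        cart[bi] += w_esc
                                    else:
                                        out[S_CART_OVER] += w_esc
                                else:
                                    out[S_CART_DISC] += w_esc
                            if fd_on == 1:
                                for f in range(fd_x.size):
                                    ddx = x - fd_x[f]
                                    ddy = y - fd_y[f]
                                    if ddx * ddx + ddy * ddy <= fd_r2[f]:
                                        if ct >= fd_cosmin[f]:
                                            fd_w[f] += w_esc
                                        else:
                                            out[S_FIB_DISC] += w_esc
                                        break
                            if not alive:
                                ux = uxo
                                uy = uyo
                                uz = uzo
                elif nxt == n_regions - 1:
                    # ---- bottom surface ----
                    z = zbot[reg]
                    rf, ct = _fresnel_k(nn[reg], nn[nxt], ci)
                    w_esc = 0.0
                    if split_bnd == 1 and ct >= 0.0:
                        w_esc = w * (1.0 - rf)
                        w *= rf
                        uz = -uz
                        if w <= 0.0:
                            alive = False
                            term_kind = TERM_BOTTOM
                    else:
                        if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                            uz = -uz
                        else:
                            w_esc = w
                            alive = False
                            term_kind = TERM_BOTTOM
                    if w_esc > 0.0:
                        scale = nn[reg] / nn[nxt]
                        uxo = ux * scale
                        uyo = uy * scale
                        uzo = ct
                        norm = np.sqrt(uxo * uxo + uyo * uyo + uzo * uzo)
                        uxo /= norm
                        uyo /= norm
                        uzo /= norm
                        out[S_T_TOTAL] += w_esc
                        wt += w_esc
                        if bot_on == 1:
                            r = np.sqrt(x * x + y * y)
                            if ct >= cosmin_bot:
                                bi = _bin_index(redges_bot, r)
                                if bi >= 0:
                                    rad_bot[bi] += w_esc
                                else:
                                    out[S_RAD_BOT_OVER] += w_esc
                            else:
                                out[S_RAD_BOT_DISC] += w_esc
                        if not alive:
                            ux = uxo
                            uy = uyo
                            uz = uzo
                else:
                    # ---- interior interface ----
                    z = ztop[reg] if going_up else zbot[reg]
                    rf, ct = _fresnel_k(nn[reg], nn[nxt], ci)
                    if ct < 0.0 or (rf > 0.0 and _rnd(rng_kind, su, ma3, st3) < rf):
                        uz = -uz
                    else:
                        if nn[reg] != nn[nxt]:
                            scale = nn[reg] / nn[nxt]
                            ux *= scale
                            uy *= scale
                            uz = -ct if going_up else ct
                            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                            ux /= norm
                            uy /= norm
                            uz /= norm
                        reg = nxt
                if not alive:
                    break
                if tr_on:
                    if nev < tr_cap:
                        tr_ev[ip, nev, 0] = x
                        tr_ev[ip, nev, 1] = y
                        tr_ev[ip, nev, 2] = z
                        tr_ev[ip, nev, 3] = ux
                        tr_ev[ip, nev, 4] = uy
                        tr_ev[ip, nev, 5] = uz
                        tr_ev[ip, nev, 6] = w
                        nev += 1
                    else:
                        tr_over = True
            if not alive:
                break
            if not interacted:
                continue
            # ------- drop (AW) -------
            mt = mua[reg] + mus[reg]
            dep = w * (mua[reg] / mt)
            out[S_A_INTERIOR] += dep
            if fl_on == 1 and dep > 0.0:
                _fluence_deposit(fl_grid, x, y, z, dep,
                                 fx0, fy0, fz0, fdx, fdy, fdz, fnx, fny, fnz)
            w -= dep
            # ------- spin -------
            ct = _lut_sample(luts[reg], _rnd(rng_kind, su, ma3, st3))
            phi = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            ux, uy, uz = _spin(ux, uy, uz, ct, phi)
            if tr_on:
                if nev < tr_cap:
                    tr_ev[ip, nev, 0] = x
                    tr_ev[ip, nev, 1] = y
                    tr_ev[ip, nev, 2] = z
                    tr_ev[ip, nev, 3] = ux
                    tr_ev[ip, nev, 4] = uy
                    tr_ev[ip, nev, 5] = uz
                    tr_ev[ip, nev, 6] = w
                    nev += 1
                else:
                    tr_over = True
            # ------- roulette -------
            if w < roul_thresh:
                if roul_on == 0:
                    # disabled: deposit the residual and terminate (keeps the
                    # energy balance exact)
                    out[S_A_INTERIOR] += w
                    if fl_on == 1:
                        _fluence_deposit(fl_grid, x, y, z, w,
                                         fx0, fy0, fz0, fdx, fdy, fdz,
                                         fnx, fny, fnz)
                    w = 0.0
                    alive = False
                    term_kind = TERM_DIED
                elif _rnd(rng_kind, su, ma3, st3) * roul_m < 1.0:
                    w *= roul_m
                else:
                    out[S_KILLED] += w
                    alive = False
                    term_kind = TERM_DIED

        out[S_R_SUMSQ] += wr * wr
        out[S_T_SUMSQ] += wt * wt
        if tr_on:
            if tr_over:
                out[S_TRACE_DROPPED] += 1.0
                term_kind = TERM_OVERFLOW
            else:
                # terminal event (exit or death position)
                if nev < tr_cap:
                    tr_ev[ip, nev, 0] = x
                    tr_ev[ip, nev, 1] = y
                    tr_ev[ip, nev, 2] = z
                    tr_ev[ip, nev, 3] = ux
                    tr_ev[ip, nev, 4] = uy
                    tr_ev[ip, nev, 5] = uz
                    tr_ev[ip, nev, 6] = w
                    nev += 1
                else:
                    tr_over = True
                    out[S_TRACE_DROPPED] += 1.0
                    term_kind = TERM_OVERFLOW
            tr_nev[ip] = nev
            tr_term[ip, 0] = x
            tr_term[ip, 1] = y
            tr_term[ip, 2] = z
            tr_term[ip, 3] = ux
            tr_term[ip, 4] = uy
            tr_term[ip, 5] = uz
            tr_term[ip, 6] = w
            tr_term[ip, 7] = term_kind


# ---------------------------------------------------------------------------
# voxel engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_voxel_kernel(
    n_packets,
    # volume: labels flat (C order over (nx,ny,nz)); material tables
    labels, vnx, vny, vnz, vx0, vy0, vz0, vdx, vdy, vdz,
    m_mua, m_mus, m_nn, m_luts,
    n_above, n_below,
    # source
    src_kind, src_p,
    # detectors (top/bottom radial, cartesian-x)
    top_on, redges_top, cosmin_top,
    bot_on, redges_bot, cosmin_bot,
    cart_on, cxedges, cax_x, cax_z, c_cosmin,
    # deposition grid (independent of the sample grid)
    fl_on, fx0, fy0, fz0, fdx, fdy, fdz, fnx, fny, fnz, fl_grid,
    # control
    stepping, split_bnd, roul_on, roul_thresh, roul_m,
    rng_kind, su, ma3, st3,
    # outputs
    out, rad_top, rad_bot, cart,
):
    for ip in range(n_packets):
        # ---------------- launch ----------------
        x = 0.0
        y = 0.0
        z = vz0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        if src_kind == SRC_GAUSSIAN:
            u1 = _rnd(rng_kind, su, ma3, st3)
            u2 = _rnd(rng_kind, su, ma3, st3)
            rr = np.sqrt(-2.0 * np.log(1.0 - u1))
            x = src_p[0] * rr * np.cos(2.0 * np.pi * u2)
            y = src_p[0] * rr * np.sin(2.0 * np.pi * u2)
        elif src_kind == SRC_UNIFORM:
            rr = src_p[0] * np.sqrt(_rnd(rng_kind, su, ma3, st3))
            aa = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            x = rr * np.cos(aa)
            y = rr * np.sin(aa)
        elif src_kind == SRC_RECT:
            x = (_rnd(rng_kind, su, ma3, st3) - 0.5) * src_p[0]
            y = (_rnd(rng_kind, su, ma3, st3) - 0.5) * src_p[1]
        elif src_kind == SRC_ISOTROPIC:
            x = src_p[0]
            y = src_p[1]
            z = src_p[2]
            uz = 2.0 * _rnd(rng_kind, su, ma3, st3) - 1.0
            aa = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
            ss = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = ss * np.cos(aa)
            uy = ss * np.sin(aa)
        ix = int(np.floor((x - vx0) / vdx))
        iy = int(np.floor((y - vy0) / vdy))
        iz = int(np.floor((z - vz0) / vdz))
        if iz < 0:
            iz = 0
        if ix < 0 or ix >= vnx or iy < 0 or iy >= vny or iz >= vnz:
            out[S_LATERAL] += 1.0
            continue
        lab = labels[(ix * vny + iy) * vnz + iz]
        if src_kind != SRC_ISOTROPIC:
            rf, _ct = _fresnel_k(n_above, m_nn[lab], 1.0)
            out[S_SPECULAR] += rf
            w = 1.0 - rf

        wr = 0.0
        wt = 0.0
        alive = True
        n_steps = 0
        while alive:
            n_steps += 1
            if n_steps > _MAX_EVENTS:
                out[S_KILLED] += w
                break
            sdim = -np.log(1.0 - _rnd(rng_kind, su, ma3, st3))
            while True:
                cmua = m_mua[lab]
                cmus = m_mus[lab]
                cn = m_nn[lab]
                mu_step = cmus if stepping == STEP_MBL else cmua + cmus
                s = sdim / mu_step if mu_step > 0.0 else np.inf
                # distances to the three candidate faces
                if ux > 0.0:
                    tx = (vx0 + (ix + 1) * vdx - x) / ux
                elif ux < 0.0:
                    tx = (vx0 + ix * vdx - x) / ux
                else:
                    tx = np.inf
                if uy > 0.0:
                    ty = (vy0 + (iy + 1) * vdy - y) / uy
                elif uy < 0.0:
                    ty = (vy0 + iy * vdy - y) / uy
                else:
                    ty = np.inf
                if uz > 0.0:
                    tz = (vz0 + (iz + 1) * vdz - z) / uz
                elif uz < 0.0:
                    tz = (vz0 + iz * vdz - z) / uz
                else:
                    tz = np.inf
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
                if s < tmin:
                    # interaction inside the current voxel
                    if stepping == STEP_MBL and cmua > 0.0:
                        surv = w * np.exp(-cmua * s)
                        dep = w - surv
                        out[S_A_INTERIOR] += dep
                        if fl_on == 1:
                            _fluence_deposit(
                                fl_grid,
                                x + 0.5 * s * ux, y + 0.5 * s * uy,
                                z + 0.5 * s * uz, dep,
                                fx0, fy0, fz0, fdx, fdy, fdz, fnx, fny, fnz)
                        w = surv
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    break
                # move to the face
                if stepping == STEP_MBL and cmua > 0.0 and tmin > 0.0:
                    surv = w * np.exp(-cmua * tmin)
                    dep = w - surv
                    out[S_A_INTERIOR] += dep
                    if fl_on == 1:
                        _fluence_deposit(
                            fl_grid,
                            x + 0.5 * tmin * ux, y + 0.5 * tmin * uy,
                            z + 0.5 * tmin * uz, dep,
                            fx0, fy0, fz0, fdx, fdy, fdz, fnx, fny, fnz)
                    w = surv
                x += ux * tmin
                y += uy * tmin
                z += uz * tmin
                if mu_step > 0.0:
                    sdim -= tmin * mu_step
                    if sdim < 0.0:
                        sdim = 0.0
                # snap the crossed coordinate onto the face and find neighbor
                if axis == 0:
                    jx = ix + 1 if ux > 0.0 else ix - 1
                    x = vx0 + (ix + 1) * vdx if ux > 0.0 else vx0 + ix * vdx
                    if jx < 0 or jx >= vnx:
                        out[S_LATERAL] += w
                        alive = False
                        break
                    nlab = labels[(jx * vny + iy) * vnz + iz]
                    if m_nn[nlab] != cn:
                        ci = abs(ux)
                        rf, ct = _fresnel_k(cn, m_nn[nlab], ci)
                        if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                            ux = -ux
                        else:
                            scale = cn / m_nn[nlab]
                            uy *= scale
                            uz *= scale
                            ux = ct if ux > 0.0 else -ct
                            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                            ux /= norm
                            uy /= norm
                            uz /= norm
                            ix = jx
                            lab = nlab
                    else:
                        ix = jx
                        lab = nlab
                elif axis == 1:
                    jy = iy + 1 if uy > 0.0 else iy - 1
                    y = vy0 + (iy + 1) * vdy if uy > 0.0 else vy0 + iy * vdy
                    if jy < 0 or jy >= vny:
                        out[S_LATERAL] += w
                        alive = False
                        break
                    nlab = labels[(ix * vny + jy) * vnz + iz]
                    if m_nn[nlab] != cn:
                        ci = abs(uy)
                        rf, ct = _fresnel_k(cn, m_nn[nlab], ci)
                        if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                            uy = -uy
                        else:
                            scale = cn / m_nn[nlab]
                            ux *= scale
                            uz *= scale
                            uy = ct if uy > 0.0 else -ct
                            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                            ux /= norm
                            uy /= norm
                            uz /= norm
                            iy = jy
                            lab = nlab
                    else:
                        iy = jy
                        lab = nlab
                else:
                    jz = iz + 1 if uz > 0.0 else iz - 1
                    z = vz0 + (iz + 1) * vdz if uz > 0.0 else vz0 + iz * vdz
                    if jz < 0 or jz >= vnz:
                        # top or bottom sample boundary
                        going_up = uz < 0.0
                        n_out = n_above if going_up else n_below
                        ci = abs(uz)
                        if ci > 1.0:
                            ci = 1.0
                        rf, ct = _fresnel_k(cn, n_out, ci)
                        w_esc = 0.0
                        if split_bnd == 1 and ct >= 0.0:
                            w_esc = w * (1.0 - rf)
                            w *= rf
                            uz = -uz
                            if w <= 0.0:
                                alive = False
                        else:
                            if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                                uz = -uz
                            else:
                                w_esc = w
                                alive = False
                        if w_esc > 0.0:
                            scale = cn / n_out
                            uxo = ux * scale
                            uyo = uy * scale
                            uzo = -ct if going_up else ct
                            norm = np.sqrt(uxo * uxo + uyo * uyo + uzo * uzo)
                            uxo /= norm
                            uyo /= norm
                            uzo /= norm
                            if going_up:
                                out[S_R_TOTAL] += w_esc
                                wr += w_esc
                                if top_on == 1:
                                    r = np.sqrt(x * x + y * y)
                                    if ct >= cosmin_top:
                                        bi = _bin_index(redges_top, r)
                                        if bi >= 0:
                                            rad_top[bi] += w_esc
                                        else:
                                            out[S_RAD_TOP_OVER] += w_esc
                                    else:
                                        out[S_RAD_TOP_DISC] += w_esc
                                if cart_on == 1:
                                    ca = uxo * cax_x + uzo * cax_z
                                    if ca >= c_cosmin:
                                        bi = _bin_index(cxedges, x)
                                        if bi >= 0:
                                            cart[bi] += w_esc
                                        else:
                                            out[S_CART_OVER] += w_esc
                                    else:
                                        out[S_CART_DISC] += w_esc
                            else:
                                out[S_T_TOTAL] += w_esc
                                wt += w_esc
                                if bot_on == 1:
                                    r = np.sqrt(x * x + y * y)
                                    if ct >= cosmin_bot:
                                        bi = _bin_index(redges_bot, r)
                                        if bi >= 0:
                                            rad_bot[bi] += w_esc
                                        else:
                                            out[S_RAD_BOT_OVER] += w_esc
                                    else:
                                        out[S_RAD_BOT_DISC] += w_esc
                        if not alive:
                            break
                    else:
                        nlab = labels[(ix * vny + iy) * vnz + jz]
                        if m_nn[nlab] != cn:
                            ci = abs(uz)
                            rf, ct = _fresnel_k(cn, m_nn[nlab], ci)
                            if ct < 0.0 or _rnd(rng_kind, su, ma3, st3) < rf:
                                uz = -uz
                            else:
                                scale = cn / m_nn[nlab]
                                ux *= scale
                                uy *= scale
                                uz = ct if uz > 0.0 else -ct
                                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                                ux /= norm
                                uy /= norm
                                uz /= norm
                                iz = jz
                                lab = nlab
                        else:
                            iz = jz
                            lab = nlab
            if not alive:
                break
            # ------- interaction -------
            cmua = m_mua[lab]
            cmus = m_mus[lab]
            mt = cmua + cmus
            if mt <= 0.0:
                # clear voxel but the dimensionless step ran out (cannot
                # happen: mu_step == 0 gives infinite geometric steps)
                continue
            if stepping == STEP_AW:
                dep = w * (cmua / mt)
                out[S_A_INTERIOR] += dep
                if fl_on == 1 and dep > 0.0:
                    _fluence_deposit(fl_grid, x, y, z, dep,
                                     fx0, fy0, fz0, fdx, fdy, fdz,
                                     fnx, fny, fnz)
                w -= dep
            elif stepping == STEP_AR:
                if _rnd(rng_kind, su, ma3, st3) < cmua / mt:
                    out[S_A_INTERIOR] += w
                    if fl_on == 1:
                        _fluence_deposit(fl_grid, x, y, z, w,
                                         fx0, fy0, fz0, fdx, fdy, fdz,
                                         fnx, fny, fnz)
                    w = 0.0
                    break
            # MBL: absorption already handled along the path
            if cmus > 0.0:
                ct = _lut_sample(m_luts[lab], _rnd(rng_kind, su, ma3, st3))
                phi = 2.0 * np.pi * _rnd(rng_kind, su, ma3, st3)
                ux, uy, uz = _spin(ux, uy, uz, ct, phi)
            # ------- roulette -------
            if w < roul_thresh:
                if roul_on == 0:
                    out[S_A_INTERIOR] += w
                    if fl_on == 1 and w > 0.0:
                        _fluence_deposit(fl_grid, x, y, z, w,
                                         fx0, fy0, fz0, fdx, fdy, fdz,
                                         fnx, fny, fnz)
                    w = 0.0
                    break
                elif _rnd(rng_kind, su, ma3, st3) * roul_m < 1.0:
                    w *= roul_m
                else:
                    out[S_KILLED] += w
                    break
        out[S_R_SUMSQ] += wr * wr
        out[S_T_SUMSQ] += wt * wt


# ---------------------------------------------------------------------------
# sampling-volume voxelization
# ---------------------------------------------------------------------------

@njit(cache=True)
def sv_accumulate(events, n_events, term_w, selected,
                  gx0, gy0, gz0, gdx, gdy, gdz, gnx, gny, gnz, grid):
    """Accumulate path-length × terminal-weight of the selected packets.

    ``events`` is the (packets, capacity, 7) trace array; consecutive event
    positions form segments which are clipped to the grid box and walked
    voxel by voxel.  Returns the total accumulated path×weight (equals the
    grid sum up to roundoff).
    """
    x1g = gx0 + gnx * gdx
    y1g = gy0 + gny * gdy
    z1g = gz0 + gnz * gdz
    total = 0.0
    for si in range(selected.size):
        ip = selected[si]
        wterm = term_w[ip]
        if wterm <= 0.0:
            continue
        ne = n_events[ip]
        for k in range(ne - 1):
            # promote the float32 storage to float64 before any arithmetic
            ax = np.float64(events[ip, k, 0])
            ay = np.float64(events[ip, k, 1])
            az = np.float64(events[ip, k, 2])
            bx = np.float64(events[ip, k + 1, 0])
            by = np.float64(events[ip, k + 1, 1])
            bz = np.float64(events[ip, k + 1, 2])
            dx = bx - ax
            dy = by - ay
            dz = bz - az
            seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
            if seg_len <= 0.0:
                continue
            # clip the parametric segment t in [0,1] to the grid box
            t0 = 0.0
            t1 = 1.0
            if dx != 0.0:
                ta = (gx0 - ax) / dx
                tb = (x1g - ax) / dx
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
            elif ax < gx0 or ax >= x1g:
                continue
            if dy != 0.0:
                ta = (gy0 - ay) / dy
                tb = (y1g - ay) / dy
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
            elif ay < gy0 or ay >= y1g:
                continue
            if dz != 0.0:
                ta = (gz0 - az) / dz
                tb = (z1g - az) / dz
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
            elif az < gz0 or az >= z1g:
                continue
            if t1 <= t0:
                continue
            # walk voxels from t0 to t1; each iteration advances t exactly
            # to the next face parameter, so the per-voxel lengths
            # telescope to (t1 - t0)·seg_len without truncation loss
            eps = 1e-12
            t = t0
            while t < t1:
                px = ax + (t + eps) * dx
                py = ay + (t + eps) * dy
                pz = az + (t + eps) * dz
                ix = int(np.floor((px - gx0) / gdx))
                iy = int(np.floor((py - gy0) / gdy))
                iz = int(np.floor((pz - gz0) / gdz))
                if ix < 0:
                    ix = 0
                if iy < 0:
                    iy = 0
                if iz < 0:
                    iz = 0
                if ix >= gnx:
                    ix = gnx - 1
                if iy >= gny:
                    iy = gny - 1
                if iz >= gnz:
                    iz = gnz - 1
                # parametric exit from this voxel
                tn = t1
                if dx > 0.0:
                    tt = (gx0 + (ix + 1) * gdx - ax) / dx
                    if tt < tn:
                        tn = tt
                elif dx < 0.0:
                    tt = (gx0 + ix * gdx - ax) / dx
                    if tt < tn:
                        tn = tt
                if dy > 0.0:
                    tt = (gy0 + (iy + 1) * gdy - ay) / dy
                    if tt < tn:
                        tn = tt
                elif dy < 0.0:
                    tt = (gy0 + iy * gdy - ay) / dy
                    if tt < tn:
                        tn = tt
                if dz > 0.0:
                    tt = (gz0 + (iz + 1) * gdz - az) / dz
                    if tt < tn:
                        tn = tt
                elif dz < 0.0:
                    tt = (gz0 + iz * gdz - az) / dz
                    if tt < tn:
                        tn = tt
                if tn > t1:
                    tn = t1
                if tn <= t:
                    tn = t1 if t + 10.0 * eps > t1 else t + 10.0 * eps
                dl = (tn - t) * seg_len * wterm
                grid[(ix * gny + iy) * gnz + iz] += dl
                total += dl
                t = tn
    return total
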