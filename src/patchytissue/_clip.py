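"""Low-level periodic Voronoi kernels.

A cell's Voronoi polyhedron is built by successive half-space clipping of a
bounding cube (the bisectors with the cell's own axial periodic images) against
the perpendicular bisector planes of nearby generating points, nearest first.
Clipping stops once the next bisector is farther than twice the current
circumradius, which makes the construction exact.

Two candidate tiers are used:

* tier 1 — minimum-image displacements only; exact whenever the finished cell's
  circumradius ``d_max`` satisfies ``2 d_max <= R`` (the candidate radius) and
  ``d_max <= L/4`` (no alternate periodic image can then contribute a facet);
* tier 2 — all 27 periodic images of every point; exact for ``d_max <= 3L/4``.

Configurations violating even tier 2 (near-empty boxes) are handled by the
pure-Python image construction in :mod:`patchytissue.geometry`.

All functions here are :func:`numba.njit`-compiled and operate on flat numpy
arrays; they are internal API.
"""

import numba as nb
import numpy as np

MAXF = 160   # max faces per polyhedron
MAXFV = 64   # max vertices per face
MAXN = 96    # max distinct neighbors per cell
MAXCAND = 16384
MAXAFF = 512  # max cells affected by one multi-cell move

OK = 0
ERR_TIER2 = 1        # tier-2 exactness check failed (pathologically sparse)
ERR_OVERFLOW = 2     # static buffer overflow (should not happen)

FACET_AREA_MIN = 1e-9  # µm²; smaller shared facets are numerical slivers


@nb.njit(cache=False)
def _clip_by_plane(fv, fnv, fpid, nf, px, py, pz, h, pid, eps, tmp, sbuf,
                   cap, d2max):
    """Clip the face soup by the half-space ``p·x <= h``.

    Returns ``(nf, changed, d2max, err)``.  ``fv`` holds face vertices in
    coordinates relative to the cell's generating point; faces are kept
    outward-oriented.  ``cap``, ``tmp`` and ``sbuf`` are scratch buffers.
    """
    # single pass: signed distances of every vertex, and cut detection
    any_out = False
    for f in range(nf):
        for v in range(fnv[f]):
            s = fv[f, v, 0] * px + fv[f, v, 1] * py + fv[f, v, 2] * pz - h
            sbuf[f, v] = s
            if s > eps:
                any_out = True
    if not any_out:
        return nf, False, d2max, OK

    ncap = 0
    g = 0  # write cursor for surviving faces
    for f in range(nf):
        nv = fnv[f]
        n_out = 0
        n_in = 0
        for v in range(nv):
            s = sbuf[f, v]
            tmp[v] = s
            if s > eps:
                n_out += 1
            elif s < -eps:
                n_in += 1
        if n_out == 0:
            # fully kept; on-plane vertices join the cap ring
            if n_in < nv:
                for v in range(nv):
                    if tmp[v] >= -eps:
                        if ncap >= cap.shape[0]:
                            return nf, False, d2max, ERR_OVERFLOW
                        cap[ncap, 0] = fv[f, v, 0]
                        cap[ncap, 1] = fv[f, v, 1]
                        cap[ncap, 2] = fv[f, v, 2]
                        ncap += 1
            if g != f:
                for v in range(nv):
                    fv[g, v, 0] = fv[f, v, 0]
                    fv[g, v, 1] = fv[f, v, 1]
                    fv[g, v, 2] = fv[f, v, 2]
                fnv[g] = nv
                fpid[g] = fpid[f]
            g += 1
            continue
        if n_in == 0:
            # fully removed (outside, or degenerate all-on face)
            continue
        # mixed: Sutherland-Hodgman walk, on-vertices treated as inside
        nw = 0
        for v in range(nv):
            w = v + 1
            if w == nv:
                w = 0
            sa = tmp[v]
            sb = tmp[w]
            if sa <= eps:
                fv[g + MAXF, nw, 0] = fv[f, v, 0]  # stage into scratch face row
                fv[g + MAXF, nw, 1] = fv[f, v, 1]
                fv[g + MAXF, nw, 2] = fv[f, v, 2]
                nw += 1
                if sa >= -eps:
                    if ncap >= cap.shape[0]:
                        return nf, False, d2max, ERR_OVERFLOW
                    cap[ncap, 0] = fv[f, v, 0]
                    cap[ncap, 1] = fv[f, v, 1]
                    cap[ncap, 2] = fv[f, v, 2]
                    ncap += 1
            if (sa < -eps and sb > eps) or (sa > eps and sb < -eps):
                t = sa / (sa - sb)
                ix = fv[f, v, 0] + t * (fv[f, w, 0] - fv[f, v, 0])
                iy = fv[f, v, 1] + t * (fv[f, w, 1] - fv[f, v, 1])
                iz = fv[f, v, 2] + t * (fv[f, w, 2] - fv[f, v, 2])
                if nw >= MAXFV:
                    return nf, False, d2max, ERR_OVERFLOW
                fv[g + MAXF, nw, 0] = ix
                fv[g + MAXF, nw, 1] = iy
                fv[g + MAXF, nw, 2] = iz
                nw += 1
                if ncap >= cap.shape[0]:
                    return nf, False, d2max, ERR_OVERFLOW
                cap[ncap, 0] = ix
                cap[ncap, 1] = iy
                cap[ncap, 2] = iz
                ncap += 1
            if nw >= MAXFV:
                return nf, False, d2max, ERR_OVERFLOW
        if nw >= 3:
            for v in range(nw):
                fv[g, v, 0] = fv[g + MAXF, v, 0]
                fv[g, v, 1] = fv[g + MAXF, v, 1]
                fv[g, v, 2] = fv[g + MAXF, v, 2]
            fnv[g] = nw
            fpid[g] = fpid[f]
            g += 1
    nf = g

    # build the cap face on the cutting plane
    if ncap >= 3:
        # local orthonormal basis (e1, e2) in the plane
        ax = abs(px)
        ay = abs(py)
        az = abs(pz)
        if ax <= ay and ax <= az:
            ux, uy, uz = 1.0, 0.0, 0.0
        elif ay <= az:
            ux, uy, uz = 0.0, 1.0, 0.0
        else:
            ux, uy, uz = 0.0, 0.0, 1.0
        d = ux * px + uy * py + uz * pz
        e1x = ux - d * px
        e1y = uy - d * py
        e1z = uz - d * pz
        nrm = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= nrm
        e1y /= nrm
        e1z /= nrm
        e2x = py * e1z - pz * e1y
        e2y = pz * e1x - px * e1z
        e2z = px * e1y - py * e1x
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for i in range(ncap):
            cx += cap[i, 0]
            cy += cap[i, 1]
            cz += cap[i, 2]
        cx /= ncap
        cy /= ncap
        cz /= ncap
        ang = tmp  # reuse scratch
        for i in range(ncap):
            rx = cap[i, 0] - cx
            ry = cap[i, 1] - cy
            rz = cap[i, 2] - cz
            u = rx * e1x + ry * e1y + rz * e1z
            v = rx * e2x + ry * e2y + rz * e2z
            ang[i] = np.arctan2(v, u)
        # insertion sort by angle
        for i in range(1, ncap):
            a = ang[i]
            x0 = cap[i, 0]
            y0 = cap[i, 1]
            z0 = cap[i, 2]
            j = i - 1
            while j >= 0 and ang[j] > a:
                ang[j + 1] = ang[j]
                cap[j + 1, 0] = cap[j, 0]
                cap[j + 1, 1] = cap[j, 1]
                cap[j + 1, 2] = cap[j, 2]
                j -= 1
            ang[j + 1] = a
            cap[j + 1, 0] = x0
            cap[j + 1, 1] = y0
            cap[j + 1, 2] = z0
        # dedup consecutive points (wrap-around included)
        if nf >= MAXF:
            return nf, False, d2max, ERR_OVERFLOW
        nw = 0
        eps2 = eps * eps
        for i in range(ncap):
            keep = True
            if nw > 0:
                dx = cap[i, 0] - fv[nf, nw - 1, 0]
                dy = cap[i, 1] - fv[nf, nw - 1, 1]
                dz = cap[i, 2] - fv[nf, nw - 1, 2]
                if dx * dx + dy * dy + dz * dz < eps2:
                    keep = False
            if keep and nw < MAXFV:
                fv[nf, nw, 0] = cap[i, 0]
                fv[nf, nw, 1] = cap[i, 1]
                fv[nf, nw, 2] = cap[i, 2]
                nw += 1
        if nw >= 2:
            dx = cap[0, 0] - fv[nf, nw - 1, 0]
            dy = cap[0, 1] - fv[nf, nw - 1, 1]
            dz = cap[0, 2] - fv[nf, nw - 1, 2]
            if dx * dx + dy * dy + dz * dz < eps2:
                nw -= 1
        if nw >= 3:
            fnv[nf] = nw
            fpid[nf] = pid
            nf += 1

    # refresh circumradius
    d2 = 0.0
    for f in range(nf):
        for v in range(fnv[f]):
            r2 = (fv[f, v, 0] * fv[f, v, 0] + fv[f, v, 1] * fv[f, v, 1]
                  + fv[f, v, 2] * fv[f, v, 2])
            if r2 > d2:
                d2 = r2
    return nf, True, d2, OK


@nb.njit(cache=False)
def _init_cube(fv, fnv, fpid, half):
    """Bounding cube from the six axial self-image bisectors (pid = -1)."""
    # faces: +x, -x, +y, -y, +z, -z; outward-oriented vertex loops
    sgn = np.array([1.0, -1.0])
    nf = 0
    for axis in range(3):
        for si in range(2):
            s = sgn[si]
            a1 = (axis + 1) % 3
            a2 = (axis + 2) % 3
            if s < 0.0:
                a1, a2 = a2, a1
            corners = np.empty((4, 2))
            corners[0, 0] = -half
            corners[0, 1] = -half
            corners[1, 0] = half
            corners[1, 1] = -half
            corners[2, 0] = half
            corners[2, 1] = half
            corners[3, 0] = -half
            corners[3, 1] = half
            for v in range(4):
                fv[nf, v, axis] = s * half
                fv[nf, v, a1] = corners[v, 0]
                fv[nf, v, a2] = corners[v, 1]
            fnv[nf] = 4
            fpid[nf] = -1
            nf += 1
    return nf


@nb.njit(cache=False)
def _clip_cell(cdx, cdy, cdz, cd, ncand, L, fv, fnv, fpid, tmp, sbuf,
               cap, cand_area):
    """Clip the bounding cube against sorted candidate bisectors.

    Fills ``cand_area`` with the facet area produced by each candidate plane
    and returns ``(volume, surface_area, self_area, d_max, err)``; ``self_area``
    is the area shared with the cell's own periodic images (cube faces).
    """
    eps = 1e-9 * L
    nf = _init_cube(fv, fnv, fpid, 0.5 * L)
    d2max = 0.75 * L * L  # cube corner
    for c in range(ncand):
        if 0.25 * cd[c] * cd[c] > d2max:
            break
        inv = 1.0 / cd[c]
        nf, _, d2max, err = _clip_by_plane(
            fv, fnv, fpid, nf, cdx[c] * inv, cdy[c] * inv, cdz[c] * inv,
            0.5 * cd[c], c, eps, tmp, sbuf, cap, d2max)
        if err != OK:
            return 0.0, 0.0, 0.0, 0.0, err
        if nf < 4:
            return 0.0, 0.0, 0.0, 0.0, ERR_OVERFLOW

    for c in range(ncand):
        cand_area[c] = 0.0
    self_area = 0.0
    vol = 0.0
    sarea = 0.0
    for f in range(nf):
        nv = fnv[f]
        # face area via polygon cross-product sum; volume via fan tetrahedra
        axx = 0.0
        ayy = 0.0
        azz = 0.0
        vf = 0.0
        for v in range(nv):
            w = v + 1
            if w == nv:
                w = 0
            axx += fv[f, v, 1] * fv[f, w, 2] - fv[f, v, 2] * fv[f, w, 1]
            ayy += fv[f, v, 2] * fv[f, w, 0] - fv[f, v, 0] * fv[f, w, 2]
            azz += fv[f, v, 0] * fv[f, w, 1] - fv[f, v, 1] * fv[f, w, 0]
        for v in range(1, nv - 1):
            vf += (fv[f, 0, 0] * (fv[f, v, 1] * fv[f, v + 1, 2]
                                  - fv[f, v, 2] * fv[f, v + 1, 1])
                   + fv[f, 0, 1] * (fv[f, v, 2] * fv[f, v + 1, 0]
                                    - fv[f, v, 0] * fv[f, v + 1, 2])
                   + fv[f, 0, 2] * (fv[f, v, 0] * fv[f, v + 1, 1]
                                    - fv[f, v, 1] * fv[f, v + 1, 0]))
        area = 0.5 * np.sqrt(axx * axx + ayy * ayy + azz * azz)
        vol += vf / 6.0
        sarea += area
        pid = fpid[f]
        if pid >= 0:
            cand_area[pid] += area
        else:
            self_area += area
    return vol, sarea, self_area, np.sqrt(d2max), OK


@nb.njit(cache=False)
def _cands_minimage(pos, i, L, R, cdx, cdy, cdz, cd, cid):
    n = pos.shape[0]
    m = 0
    R2 = R * R
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < R2:
            if m >= cdx.shape[0]:
                return -1
            cdx[m] = dx
            cdy[m] = dy
            cdz[m] = dz
            cd[m] = np.sqrt(d2)
            cid[m] = j
            m += 1
    # insertion sort ascending by distance
    for a in range(1, m):
        vx = cdx[a]
        vy = cdy[a]
        vz = cdz[a]
        vd = cd[a]
        vi = cid[a]
        b = a - 1
        while b >= 0 and cd[b] > vd:
            cdx[b + 1] = cdx[b]
            cdy[b + 1] = cdy[b]
            cdz[b + 1] = cdz[b]
            cd[b + 1] = cd[b]
            cid[b + 1] = cid[b]
            b -= 1
        cdx[b + 1] = vx
        cdy[b + 1] = vy
        cdz[b + 1] = vz
        cd[b + 1] = vd
        cid[b + 1] = vi
    return m


@nb.njit(cache=False)
def _cands_images(pos, i, L, R, cdx, cdy, cdz, cd, cid):
    """Periodic images of every point within radius R (own images included).

    Covers all 27 images when ``R >= 2.61 L``; used for boxes small relative
    to the cell spacing, where several images of the same point can
    contribute facets.  Candidates are returned sorted by distance.
    """
    n = pos.shape[0]
    m = 0
    R2 = R * R
    for j in range(n):
        bx = pos[j, 0] - pos[i, 0]
        by = pos[j, 1] - pos[i, 1]
        bz = pos[j, 2] - pos[i, 2]
        for ox in range(-1, 2):
            dx = bx + ox * L
            if dx * dx > R2:
                continue
            for oy in range(-1, 2):
                dy = by + oy * L
                d2xy = dx * dx + dy * dy
                if d2xy > R2:
                    continue
                for oz in range(-1, 2):
                    if j == i and ox == 0 and oy == 0 and oz == 0:
                        continue
                    dz = bz + oz * L
                    d2 = d2xy + dz * dz
                    if d2 > R2:
                        continue
                    if m >= cdx.shape[0]:
                        return -1
                    cdx[m] = dx
                    cdy[m] = dy
                    cdz[m] = dz
                    cd[m] = np.sqrt(d2)
                    cid[m] = j
                    m += 1
    for a in range(1, m):
        vx = cdx[a]
        vy = cdy[a]
        vz = cdz[a]
        vd = cd[a]
        vi = cid[a]
        b = a - 1
        while b >= 0 and cd[b] > vd:
            cdx[b + 1] = cdx[b]
            cdy[b + 1] = cdy[b]
            cdz[b + 1] = cdz[b]
            cd[b + 1] = cd[b]
            cid[b + 1] = cid[b]
            b -= 1
        cdx[b + 1] = vx
        cdy[b + 1] = vy
        cdz[b + 1] = vz
        cd[b + 1] = vd
        cid[b + 1] = vi
    return m


@nb.njit(cache=False)
def _cell_geometry(pos, i, L, R0, fv, fnv, fpid, tmp, sbuf, cap,
                   cdx, cdy, cdz, cd, cid, cand_area,
                   nbr_row, nbra_row):
    """Full periodic Voronoi geometry of one cell.

    Returns ``(volume, surface_area, n_neighbors, d_max, err)`` and fills the
    neighbor id/area rows, one entry per facet: under periodic boundaries the
    same neighbor may contribute several distinct facets (one per image plane)
    and each is listed separately.  Self-image contact (facets against the
    cell's own periodic images) is recorded as a single entry under the cell's
    own id.
    """
    # min-image candidates suffice while d_max <= L/4; small boxes (the
    # candidate radius hits the L/2 cap) start directly with explicit images
    use_images = R0 >= 0.499 * L
    R = R0 if use_images else min(R0, 0.5 * L)
    vol = 0.0
    sarea = 0.0
    self_area = 0.0
    dmax = 0.0
    m = 0
    while True:
        if use_images:
            m = _cands_images(pos, i, L, R, cdx, cdy, cdz, cd, cid)
        else:
            m = _cands_minimage(pos, i, L, R, cdx, cdy, cdz, cd, cid)
        if m < 0:
            return 0.0, 0.0, 0, 0.0, ERR_OVERFLOW
        vol, sarea, self_area, dmax, err = _clip_cell(
            cdx, cdy, cdz, cd, m, L, fv, fnv, fpid, tmp, sbuf, cap, cand_area)
        if err != OK:
            return 0.0, 0.0, 0, 0.0, err
        if use_images:
            if 2.0 * dmax <= R:
                if dmax > 0.75 * L:
                    return 0.0, 0.0, 0, 0.0, ERR_TIER2
                break
            if R >= 2.61 * L:
                # every {-1,0,1} image already included
                if dmax > 0.75 * L:
                    return 0.0, 0.0, 0, 0.0, ERR_TIER2
                break
            R = min(1.6 * R, 2.61 * L)
        else:
            if 2.0 * dmax <= R and dmax <= 0.25 * L:
                break
            if R < 0.5 * L:
                R = min(1.6 * R, 0.5 * L)
            else:
                use_images = True
                R = max(2.2 * dmax + 1.0, 0.7 * L)

    nn = 0
    if self_area > FACET_AREA_MIN:
        nbr_row[nn] = i
        nbra_row[nn] = self_area
        nn += 1
    for c in range(m):
        a = cand_area[c]
        if a <= FACET_AREA_MIN:
            continue
        if nn >= nbr_row.shape[0]:
            return 0.0, 0.0, 0, 0.0, ERR_OVERFLOW
        nbr_row[nn] = cid[c]
        nbra_row[nn] = a
        nn += 1
    return vol, sarea, nn, dmax, OK


@nb.njit(cache=False)
def update_cells(pos, L, R0, idxs, vol, sarea, nbr, nbrn, nbra, dmax_arr):
    """Recompute geometry rows for the cells in ``idxs`` (in place)."""
    fv = np.empty((2 * MAXF, MAXFV, 3))
    fnv = np.empty(MAXF, np.int64)
    fpid = np.empty(MAXF, np.int64)
    tmp = np.empty(MAXCAND)
    sbuf = np.empty((MAXF, MAXFV))
    cap = np.empty((4 * MAXFV, 3))
    cdx = np.empty(MAXCAND)
    cdy = np.empty(MAXCAND)
    cdz = np.empty(MAXCAND)
    cd = np.empty(MAXCAND)
    cid = np.empty(MAXCAND, np.int64)
    cand_area = np.empty(MAXCAND)
    for q in range(idxs.shape[0]):
        i = idxs[q]
        v, s, nn, dm, err = _cell_geometry(
            pos, i, L, R0, fv, fnv, fpid, tmp, sbuf, cap,
            cdx, cdy, cdz, cd, cid, cand_area, nbr[i], nbra[i])
        if err != OK:
            return err
        vol[i] = v
        sarea[i] = s
        nbrn[i] = nn
        dmax_arr[i] = dm
    return OK


@nb.njit(cache=False)
def _cell_U(k, A, V, adh_sum, A0, V0, gs, lam):
    dA = A - A0
    return 0.5 * k * dA * dA / A0 - 0.5 * gs * adh_sum - lam * np.log(V / V0)


@nb.njit(cache=False)
def _adh_sum(nbra_row, nn):
    s = 0.0
    for q in range(nn):
        s += nbra_row[q]
    return s


@nb.njit(cache=False)
def recompute_energies(stiff, vol, sarea, nbra, nbrn, A0, V0, gs, lam, U):
    n = stiff.shape[0]
    tot = 0.0
    for i in range(n):
        U[i] = _cell_U(stiff[i], sarea[i], vol[i], _adh_sum(nbra[i], nbrn[i]),
                       A0, V0, gs, lam)
        tot += U[i]
    return tot


@nb.njit(cache=False)
def try_move(pos, stiff, L, R0, A0, V0, gs, lam,
             vol, sarea, nbr, nbrn, nbra, dmax_arr, U,
             ids, newpos,
             alist, tvol, tsarea, tnbr, tnbrn, tnbra, tdmax, tU, inA,
             fv, fnv, fpid, tmp, sbuf, cap, cdx, cdy, cdz, cd, cid, cand_area):
    """Evaluate the energy change of moving ``ids`` to ``newpos``.

    Positions are modified in place to the proposed configuration; geometry
    caches are untouched (results staged in the ``t*`` buffers).  Returns
    ``(delta_U, n_affected, err)``.  Caller must either commit via
    :func:`commit_move` or restore positions.
    """
    nm = ids.shape[0]
    na = 0
    for q in range(nm):
        i = ids[q]
        if inA[i] == 0:
            inA[i] = 1
            alist[na] = i
            na += 1
        for p in range(nbrn[i]):
            j = nbr[i, p]
            if inA[j] == 0:
                inA[j] = 1
                alist[na] = j
                na += 1
    for q in range(nm):
        i = ids[q]
        pos[i, 0] = newpos[q, 0] % L
        pos[i, 1] = newpos[q, 1] % L
        pos[i, 2] = newpos[q, 2] % L

    # moved cells first, to discover their post-move neighborhoods
    for q in range(nm):
        i = ids[q]
        Ri = min(0.5 * L, max(2.2 * dmax_arr[i] + 1.0, 0.6 * R0))
        v, s, nn, dm, err = _cell_geometry(
            pos, i, L, Ri, fv, fnv, fpid, tmp, sbuf, cap,
            cdx, cdy, cdz, cd, cid, cand_area, tnbr[q], tnbra[q])
        if err != OK:
            return 0.0, na, err
        tvol[q] = v
        tsarea[q] = s
        tnbrn[q] = nn
        tdmax[q] = dm
        for p in range(nn):
            j = tnbr[q, p]
            if inA[j] == 0:
                inA[j] = 1
                if na >= alist.shape[0]:
                    return 0.0, na, ERR_OVERFLOW
                alist[na] = j
                na += 1
    # remaining affected cells
    slot = nm
    for q in range(na):
        i = alist[q]
        moved = False
        for p in range(nm):
            if ids[p] == i:
                moved = True
                break
        if moved:
            continue
        if slot >= tvol.shape[0]:
            return 0.0, na, ERR_OVERFLOW
        Ri = min(0.5 * L, max(2.2 * dmax_arr[i] + 1.0, 0.6 * R0))
        v, s, nn, dm, err = _cell_geometry(
            pos, i, L, Ri, fv, fnv, fpid, tmp, sbuf, cap,
            cdx, cdy, cdz, cd, cid, cand_area, tnbr[slot], tnbra[slot])
        if err != OK:
            return 0.0, na, err
        tvol[slot] = v
        tsarea[slot] = s
        tnbrn[slot] = nn
        tdmax[slot] = dm
        # record which cell this slot belongs to, reusing alist tail mapping
        alist[MAXAFF + slot] = i
        slot += 1

    delta = 0.0
    for q in range(nm):
        i = ids[q]
        tU[q] = _cell_U(stiff[i], tsarea[q], tvol[q],
                        _adh_sum(tnbra[q], tnbrn[q]), A0, V0, gs, lam)
        delta += tU[q] - U[i]
    for q in range(nm, slot):
        i = alist[MAXAFF + q]
        tU[q] = _cell_U(stiff[i], tsarea[q], tvol[q],
                        _adh_sum(tnbra[q], tnbrn[q]), A0, V0, gs, lam)
        delta += tU[q] - U[i]
    # stash slot count in alist header area
    alist[2 * MAXAFF] = slot
    return delta, na, OK


@nb.njit(cache=False)
def commit_move(ids, alist, na,
                vol, sarea, nbr, nbrn, nbra, dmax_arr, U,
                tvol, tsarea, tnbr, tnbrn, tnbra, tdmax, tU):
    nm = ids.shape[0]
    slot = alist[2 * MAXAFF]
    for q in range(nm):
        i = ids[q]
        vol[i] = tvol[q]
        sarea[i] = tsarea[q]
        nbrn[i] = tnbrn[q]
        dmax_arr[i] = tdmax[q]
        U[i] = tU[q]
        for p in range(tnbrn[q]):
            nbr[i, p] = tnbr[q, p]
            nbra[i, p] = tnbra[q, p]
    for q in range(nm, slot):
        i = alist[MAXAFF + q]
        vol[i] = tvol[q]
        sarea[i] = tsarea[q]
        nbrn[i] = tnbrn[q]
        dmax_arr[i] = tdmax[q]
        U[i] = tU[q]
        for p in range(tnbrn[q]):
            nbr[i, p] = tnbr[q, p]
            nbra[i, p] = tnbra[q, p]


@nb.njit(cache=False)
def clear_affected(alist, na, inA):
    for q in range(na):
        inA[alist[q]] = 0


@nb.njit(cache=False)
def relax_chunk(pos, stiff, L, R0, A0, V0, gs, lam, kbt,
                vol, sarea, nbr, nbrn, nbra, dmax_arr, U, total_energy,
                move_ids, dirs, mags, urand, jitter):
    """Run one chunk of Metropolis iterations in place.

    Randomness is supplied pre-drawn: per iteration, ``move_ids`` (cells to
    move), ``dirs`` (unit directions), ``mags`` (exponential step lengths),
    ``urand`` (acceptance uniform), ``jitter`` (collision rescue offsets).
    Returns ``(total_energy, energy_sum_over_iterations, n_accepted, err)``.
    """
    niter = move_ids.shape[0]
    nm = move_ids.shape[1]
    n = pos.shape[0]
    fv = np.empty((2 * MAXF, MAXFV, 3))
    fnv = np.empty(MAXF, np.int64)
    fpid = np.empty(MAXF, np.int64)
    tmp = np.empty(MAXCAND)
    sbuf = np.empty((MAXF, MAXFV))
    cap = np.empty((4 * MAXFV, 3))
    cdx = np.empty(MAXCAND)
    cdy = np.empty(MAXCAND)
    cdz = np.empty(MAXCAND)
    cd = np.empty(MAXCAND)
    cid = np.empty(MAXCAND, np.int64)
    cand_area = np.empty(MAXCAND)
    inA = np.zeros(n, np.uint8)
    alist = np.empty(2 * MAXAFF + 1, np.int64)
    tvol = np.empty(MAXAFF)
    tsarea = np.empty(MAXAFF)
    tnbr = np.empty((MAXAFF, MAXN), np.int64)
    tnbrn = np.empty(MAXAFF, np.int64)
    tnbra = np.empty((MAXAFF, MAXN))
    tdmax = np.empty(MAXAFF)
    tU = np.empty(MAXAFF)
    oldpos = np.empty((nm, 3))
    newpos = np.empty((nm, 3))
    ids = np.empty(nm, np.int64)
    nacc = 0
    esum = 0.0
    for it in range(niter):
        for q in range(nm):
            ids[q] = move_ids[it, q]
            oldpos[q, 0] = pos[ids[q], 0]
            oldpos[q, 1] = pos[ids[q], 1]
            oldpos[q, 2] = pos[ids[q], 2]
            for c in range(3):
                newpos[q, c] = (oldpos[q, c]
                                + dirs[it, q, c] * mags[it, q]) % L
        # coincidence guard: re-jitter once, else reject outright
        reject = False
        for q in range(nm):
            tries = 0
            while tries < 2:
                collide = False
                for j in range(n):
                    if j == ids[q]:
                        continue
                    dx = pos[j, 0] - newpos[q, 0]
                    dy = pos[j, 1] - newpos[q, 1]
                    dz = pos[j, 2] - newpos[q, 2]
                    dx -= L * np.rint(dx / L)
                    dy -= L * np.rint(dy / L)
                    dz -= L * np.rint(dz / L)
                    if dx * dx + dy * dy + dz * dz < 1e-12:
                        collide = True
                        break
                if not collide:
                    break
                for c in range(3):
                    newpos[q, c] = (newpos[q, c]
                                    + jitter[it, q, c] * 1e-3) % L
                tries += 1
            if tries == 2:
                reject = True
                break
        if reject:
            esum += total_energy
            continue
        delta, na, err = try_move(
            pos, stiff, L, R0, A0, V0, gs, lam,
            vol, sarea, nbr, nbrn, nbra, dmax_arr, U,
            ids, newpos,
            alist, tvol, tsarea, tnbr, tnbrn, tnbra, tdmax, tU, inA,
            fv, fnv, fpid, tmp, sbuf, cap, cdx, cdy, cdz, cd, cid, cand_area)
        if err != OK:
            return total_energy, esum, nacc, err
        accept = delta <= 0.0 or urand[it] < np.exp(-delta / kbt)
        if accept:
            commit_move(ids, alist, na, vol, sarea, nbr, nbrn, nbra,
                        dmax_arr, U, tvol, tsarea, tnbr, tnbrn, tnbra,
                        tdmax, tU)
            total_energy += delta
            nacc += 1
        else:
            for q in range(nm):
                pos[ids[q], 0] = oldpos[q, 0]
                pos[ids[q], 1] = oldpos[q, 1]
                pos[ids[q], 2] = oldpos[q, 2]
        clear_affected(alist, na, inA)
        esum += total_energy
    return total_energy, esum, nacc, OK
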