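"""Numba inner loops for the cellular Potts engine and the diffusion solver.

Everything here operates on plain numpy arrays owned by
:class:`ncstream.state.SimulationState`. Cell labels index the per-cell arrays
directly (label 0 is medium and is kept as a zeroed slot). All stochastic
draws use numba's internal RNG, seeded once per simulation via
:func:`seed_rng`; the draw order is fixed and documented per kernel so that a
run is bit-reproducible for a given seed.

Conventions
-----------
* lattice ``sigma`` has shape ``(width, height)``; x is the AP axis, y the DV
  axis with y increasing ventrally (NC cells start at low y).
* copy-attempt sources and contact-energy bonds both use the 8-site Moore
  neighborhood; neighbors outside the closed lattice contribute no bond.
* the acceptance rule is ``p = min(1, exp(W - dH))`` with no temperature.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Moore neighborhood (8 sites)
_DX8 = np.array([1, -1, 0, 0, 1, 1, -1, -1], dtype=np.int64)
_DY8 = np.array([0, 0, 1, -1, 1, -1, 1, -1], dtype=np.int64)
# forward half of the Moore neighborhood: each unordered site pair once
_FDX = np.array([1, 0, 1, 1], dtype=np.int64)
_FDY = np.array([0, 1, 1, -1], dtype=np.int64)

#: per-cell list capacity for contacts / links / CIL partners
MAX_DEG = 24


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (separate from numpy's Python-level RNG)."""
    np.random.seed(seed)


# ----------------------------------------------------------------------
# energy change and work bias of a single copy attempt
# ----------------------------------------------------------------------

@njit(cache=True)
def delta_h_site(sigma, area, cell_type, J, lam_V, V_T, rx, ry, x):
    """Incremental dH for overwriting sigma[rx, ry] with label x.

    Only the two affected cells' volume terms and the Moore-neighborhood
    bonds of the target site change.
    """
    old = sigma[rx, ry]
    dh = 0.0
    if x > 0:
        v = float(area[x])
        dh += lam_V * ((v + 1.0 - V_T) ** 2 - (v - V_T) ** 2)
    if old > 0:
        v = float(area[old])
        dh += lam_V * ((v - 1.0 - V_T) ** 2 - (v - V_T) ** 2)
    w, h = sigma.shape
    for k in range(8):
        nx = rx + _DX8[k]
        ny = ry + _DY8[k]
        if nx < 0 or nx >= w or ny < 0 or ny >= h:
            continue
        s = sigma[nx, ny]
        if s != x:
            dh += J[cell_type[x], cell_type[s]]
        if s != old:
            dh -= J[cell_type[old], cell_type[s]]
    return dh


@njit(cache=True)
def work_bias_site(sigma, area, sum_x, sum_y, cell_type, pol,
                   link_list, link_cnt, conc,
                   lam_chem, lam_P, lam_M, d0, halo,
                   rx, ry, spx, spy, x, pol_mode):
    """Work bias W of overwriting sigma[rx, ry] with label x.

    Terms: extension-only chemotaxis (only when a cell extends into a medium
    site; never at contact sites or for retraction), persistent-adhesion
    springs, and polarized motility. Spring and polarity terms are evaluated
    for both cells whose centroid the copy would move; medium contributes
    nothing. ``spx, spy`` locate the copy source (ignored for retraction).
    """
    old = sigma[rx, ry]
    wb = 0.0
    if old == 0 and x > 0:
        t = cell_type[x]
        for s in range(3):
            ls = lam_chem[t, s]
            if ls != 0.0:
                wb += ls * (conc[s, rx + halo, ry + halo]
                            - conc[s, spx + halo, spy + halo])
    # dr of a cell is the copy displacement vector (source -> target site,
    # lattice scale): the gaining cell advances along it and the losing cell
    # is displaced along it. For a retraction the losing cell recoils away
    # from the removed site (unit vector from site toward its centroid).
    for which in range(2):
        if which == 0:
            i = x
            if i == 0:
                continue
            v = float(area[i])
            cx = sum_x[i] / v
            cy = sum_y[i] / v
            dcx = float(rx - spx)
            dcy = float(ry - spy)
        else:
            i = old
            if i == 0:
                continue
            v = float(area[i])
            if v <= 1.0:
                continue
            cx = sum_x[i] / v
            cy = sum_y[i] / v
            if x > 0:
                dcx = float(rx - spx)
                dcy = float(ry - spy)
            else:
                dcx = cx - rx
                dcy = cy - ry
                dn = math.sqrt(dcx * dcx + dcy * dcy)
                if dn > 1e-12:
                    dcx /= dn
                    dcy /= dn
        # persistent-adhesion springs toward/away from linked partners
        fx = 0.0
        fy = 0.0
        for kk in range(link_cnt[i]):
            j = link_list[i, kk]
            vj = float(area[j])
            rijx = sum_x[j] / vj - cx
            rijy = sum_y[j] / vj - cy
            dist = math.sqrt(rijx * rijx + rijy * rijy)
            if dist > 1e-12:
                f = lam_M[cell_type[i], cell_type[j]] * (dist - d0) / dist
                fx += f * rijx
                fy += f * rijy
        wb += fx * dcx + fy * dcy
        # polarized motility along the unit polarity vector
        px = pol[i, 0]
        py = pol[i, 1]
        pn = math.sqrt(px * px + py * py)
        if pn > 1e-12:
            proj = dcx * px + dcy * py
            if pol_mode == 0:
                proj /= pn          # unit polarity: full lambda_P always
            elif pol_mode == 2:
                if pn > 1.0:
                    proj /= pn      # saturated: proportional below |p| = 1
            wb += lam_P[cell_type[i]] * proj
    return wb


@njit(cache=True)
def run_attempts(sigma, area, sum_x, sum_y, cell_type, pol,
                 link_list, link_cnt, conc,
                 lam_chem, lam_P, lam_M, J, lam_V, V_T, d0,
                 p_retract, halo, temperature, pol_mode):
    """One MCS worth of copy attempts (N = lattice site count).

    Draw order per attempt: target x, target y, retraction uniform,
    [neighbor index], acceptance uniform. Attempts whose source falls outside
    the closed lattice, no-op copies, and attempts that would annihilate a
    cell's last site consume no acceptance draw. Returns
    (accepted, retraction_attempts).
    """
    w, h = sigma.shape
    n = w * h
    accepted = 0
    retractions = 0
    for _ in range(n):
        rx = np.random.randint(0, w)
        ry = np.random.randint(0, h)
        if np.random.random() < p_retract:
            x = 0
            spx = -1
            spy = -1
            retractions += 1
        else:
            k = np.random.randint(0, 8)
            spx = rx + _DX8[k]
            spy = ry + _DY8[k]
            if spx < 0 or spx >= w or spy < 0 or spy >= h:
                continue
            x = sigma[spx, spy]
        old = sigma[rx, ry]
        if x == old:
            continue
        if old > 0 and area[old] <= 1:
            continue  # cells never vanish
        dh = delta_h_site(sigma, area, cell_type, J, lam_V, V_T, rx, ry, x)
        wb = work_bias_site(sigma, area, sum_x, sum_y, cell_type, pol,
                            link_list, link_cnt, conc,
                            lam_chem, lam_P, lam_M, d0, halo,
                            rx, ry, spx, spy, x, pol_mode)
        arg = (wb - dh) / temperature
        u = np.random.random()
        if arg >= 0.0 or u < math.exp(arg):
            sigma[rx, ry] = x
            if x > 0:
                area[x] += 1
                sum_x[x] += rx
                sum_y[x] += ry
            if old > 0:
                area[old] -= 1
                sum_x[old] -= rx
                sum_y[old] -= ry
            accepted += 1
    return accepted, retractions


# ----------------------------------------------------------------------
# contacts
# ----------------------------------------------------------------------

@njit(cache=True)
def _list_has(lst, cnt, i, val):
    for t in range(cnt[i]):
        if lst[i, t] == val:
            return True
    return False


@njit(cache=True)
def _list_add(lst, cnt, i, val):
    if cnt[i] < lst.shape[1]:
        lst[i, cnt[i]] = val
        cnt[i] += 1


@njit(cache=True)
def compute_contacts(sigma, contact_list, contact_cnt):
    """Fill per-cell contact lists from 8-neighborhood lattice adjacency."""
    contact_cnt[:] = 0
    w, h = sigma.shape
    for xx in range(w):
        for yy in range(h):
            a = sigma[xx, yy]
            if a == 0:
                continue
            for k in range(4):
                nx = xx + _FDX[k]
                ny = yy + _FDY[k]
                if nx < 0 or nx >= w or ny < 0 or ny >= h:
                    continue
                b = sigma[nx, ny]
                if b == 0 or b == a:
                    continue
                if not _list_has(contact_list, contact_cnt, a, b):
                    _list_add(contact_list, contact_cnt, a, b)
                    _list_add(contact_list, contact_cnt, b, a)


# ----------------------------------------------------------------------
# persistent adhesion links
# ----------------------------------------------------------------------

@njit(cache=True)
def _unlink(link_list, link_cnt, i, j):
    for t in range(link_cnt[i]):
        if link_list[i, t] == j:
            link_list[i, t] = link_list[i, link_cnt[i] - 1]
            link_cnt[i] -= 1
            break


@njit(cache=True)
def update_links(n_cells, area, sum_x, sum_y,
                 contact_list, contact_cnt, link_list, link_cnt,
                 p_form, d0, break_divisor):
    """Link maintenance for one MCS.

    Existing links first (ascending cell id, list order): a pair that lost
    lattice contact is unlinked deterministically; otherwise it breaks with
    probability clamp((|r_ij| - d0) / divisor, 0, 1). Then contacting
    unlinked pairs form a link with probability ``p_form``. Returns
    (formed, broken).
    """
    broken = 0
    formed = 0
    for i in range(1, n_cells + 1):
        t = 0
        while t < link_cnt[i]:
            j = link_list[i, t]
            if j < i:
                t += 1
                continue
            if not _list_has(contact_list, contact_cnt, i, j):
                _unlink(link_list, link_cnt, i, j)
                _unlink(link_list, link_cnt, j, i)
                broken += 1
                continue
            dx = sum_x[j] / area[j] - sum_x[i] / area[i]
            dy = sum_y[j] / area[j] - sum_y[i] / area[i]
            dist = math.sqrt(dx * dx + dy * dy)
            p_break = (dist - d0) / break_divisor
            if p_break > 0.0 and np.random.random() < min(p_break, 1.0):
                _unlink(link_list, link_cnt, i, j)
                _unlink(link_list, link_cnt, j, i)
                broken += 1
                continue
            t += 1
    for i in range(1, n_cells + 1):
        for t in range(contact_cnt[i]):
            j = contact_list[i, t]
            if j < i:
                continue
            if _list_has(link_list, link_cnt, i, j):
                continue
            if np.random.random() < p_form:
                _list_add(link_list, link_cnt, i, j)
                _list_add(link_list, link_cnt, j, i)
                formed += 1
    return formed, broken


# ----------------------------------------------------------------------
# contact inhibition of locomotion
# ----------------------------------------------------------------------

@njit(cache=True)
def update_cil(n_cells, cell_type,
               contact_list, contact_cnt, prev_contact_list, prev_contact_cnt,
               cil_list, cil_cnt, p_cil):
    """CIL switching for one MCS.

    Stale trigger partners (contact lost) are pruned first; then, for each
    *new* eligible contact pair (at least one NC cell; placode-placode never
    triggers), each participant independently enters/extends its CIL state
    with its own type's p(CIL). Draw order: ascending lower cell id, contact
    list order, lower-id participant first. Returns (entries, exits).
    """
    entries = 0
    exits = 0
    for i in range(1, n_cells + 1):
        was_active = cil_cnt[i] > 0
        t = 0
        while t < cil_cnt[i]:
            j = cil_list[i, t]
            if not _list_has(contact_list, contact_cnt, i, j):
                cil_list[i, t] = cil_list[i, cil_cnt[i] - 1]
                cil_cnt[i] -= 1
            else:
                t += 1
        if was_active and cil_cnt[i] == 0:
            exits += 1
    for i in range(1, n_cells + 1):
        for t in range(contact_cnt[i]):
            j = contact_list[i, t]
            if j < i:
                continue
            if cell_type[i] != 1 and cell_type[j] != 1:
                continue  # placode-placode contacts never trigger CIL
            if _list_has(prev_contact_list, prev_contact_cnt, i, j):
                continue  # drawn once per new contact event
            if np.random.random() < p_cil[cell_type[i]]:
                if not _list_has(cil_list, cil_cnt, i, j):
                    if cil_cnt[i] == 0:
                        entries += 1
                    _list_add(cil_list, cil_cnt, i, j)
            if np.random.random() < p_cil[cell_type[j]]:
                if not _list_has(cil_list, cil_cnt, j, i):
                    if cil_cnt[j] == 0:
                        entries += 1
                    _list_add(cil_list, cil_cnt, j, i)
    return entries, exits


# ----------------------------------------------------------------------
# polarity
# ----------------------------------------------------------------------

@njit(cache=True)
def update_polarity(n_cells, area, sum_x, sum_y, prev_cx, prev_cy,
                    cell_type, pol, disp, contact_list, contact_cnt,
                    cil_cnt, dP_free, dP_contact, lam_CIL):
    """Polarity persistence update p <- (1 - dP) p + dr for every cell.

    dr is the centroid displacement over the last MCS; dP depends on cell
    type and contact status. Cells in CIL state additionally subtract
    lam_CIL times the normalized sum of vectors toward all current contact
    partners. Also records dr into ``disp`` and refreshes the previous
    centroid cache. Deterministic.
    """
    for i in range(1, n_cells + 1):
        if area[i] <= 0:
            continue
        cx = sum_x[i] / area[i]
        cy = sum_y[i] / area[i]
        dx = cx - prev_cx[i]
        dy = cy - prev_cy[i]
        t = cell_type[i]
        dP = dP_contact[t] if contact_cnt[i] > 0 else dP_free[t]
        px = (1.0 - dP) * pol[i, 0] + dx
        py = (1.0 - dP) * pol[i, 1] + dy
        if cil_cnt[i] > 0:
            sx = 0.0
            sy = 0.0
            for k in range(contact_cnt[i]):
                j = contact_list[i, k]
                sx += sum_x[j] / area[j] - cx
                sy += sum_y[j] / area[j] - cy
            norm = math.sqrt(sx * sx + sy * sy)
            if norm > 1e-12:
                px -= lam_CIL * sx / norm
                py -= lam_CIL * sy / norm
        pol[i, 0] = px
        pol[i, 1] = py
        disp[i, 0] = dx
        disp[i, 1] = dy
        prev_cx[i] = cx
        prev_cy[i] = cy


# ----------------------------------------------------------------------
# reaction-diffusion
# ----------------------------------------------------------------------

@njit(cache=True)
def build_source(sigma, cell_type, rates, halo, src):
    """Per-site net source of one substance on the halo-extended grid.

    ``rates`` maps cell-type index -> rate (negative = uptake); the halo
    carries no sources. ``src`` is zeroed and filled in place.
    """
    src[:, :] = 0.0
    w, h = sigma.shape
    for xx in range(w):
        for yy in range(h):
            t = cell_type[sigma[xx, yy]]
            if t > 0:
                src[xx + halo, yy + halo] = rates[t]


@njit(cache=True, fastmath=True)
def step_field(c, src, D, delta, nsub, capacity):
    """Advance one field by one MCS via ``nsub`` explicit forward-Euler
    substeps of dc/dt = D lap(c) - delta c + S(c).

    ``src`` holds per-site rates: a positive rate ``s`` secretes toward the
    local carrying capacity (term ``s * (1 - c)``, so concentrations are
    occupancy fractions in [0, 1]); a negative rate ``-u`` is proportional
    uptake (term ``-u * c``, which cannot overdraw). Diffusion and decay
    are explicit; the secretion/uptake terms are taken semi-implicitly
    (their rates can exceed the explicit stability bound). 5-point
    Laplacian on unit spacing; zero-flux (reflecting) outer boundary;
    concentrations clamped at zero as a numerical guard.
    """
    w, h = c.shape
    dt = 1.0 / nsub
    buf = np.empty_like(c)
    a = c
    b = buf
    in_c = True
    for _ in range(nsub):
        for i in range(w):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < w - 1 else w - 1
            for j in range(h):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < h - 1 else h - 1
                cc = a[i, j]
                lap = a[im, j] + a[ip, j] + a[i, jm] + a[i, jp] - 4.0 * cc
                r = src[i, j]
                s = r if r > 0.0 else 0.0
                u = -r if r < 0.0 else 0.0
                val = ((cc * (1.0 - delta * dt) + dt * (D * lap + s))
                       / (1.0 + dt * (s / capacity + u)))
                b[i, j] = val if val > 0.0 else 0.0
        tmp = a
        a = b
        b = tmp
        in_c = not in_c
    if not in_c:
        c[:, :] = a


# ----------------------------------------------------------------------
# EMT insertion of new NC cells at the dorsal edge
# ----------------------------------------------------------------------

@njit(cache=True)
def emt_insert(sigma, area, sum_x, sum_y, prev_cx, prev_cy, cell_type,
               pol, disp, n_cells, patch_w, patch_h):
    """Insert new NC cells into dorsal-edge gaps.

    Scans the top strip (y in [0, patch_h)) left to right; every all-medium
    rectangle of patch_w x patch_h sites becomes one new NC cell (fresh
    max+1 id, zero polarity, no links, no CIL). Deterministic. Returns the
    updated cell count.
    """
    w, _ = sigma.shape
    xx = 0
    while xx + patch_w <= w:
        empty = True
        for ix in range(xx, xx + patch_w):
            for iy in range(patch_h):
                if sigma[ix, iy] != 0:
                    empty = False
                    break
            if not empty:
                break
        if not empty:
            xx += 1
            continue
        n_cells += 1
        cid = n_cells
        cell_type[cid] = 1
        area[cid] = patch_w * patch_h
        sx = 0.0
        sy = 0.0
        for ix in range(xx, xx + patch_w):
            for iy in range(patch_h):
                sigma[ix, iy] = cid
                sx += ix
                sy += iy
        sum_x[cid] = sx
        sum_y[cid] = sy
        prev_cx[cid] = sx / area[cid]
        prev_cy[cid] = sy / area[cid]
        pol[cid, 0] = 0.0
        pol[cid, 1] = 0.0
        disp[cid, 0] = 0.0
        disp[cid, 1] = 0.0
        xx += patch_w
    return n_cells
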