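"""Numba kernel for the disk-migration loop.

One iteration: every disk with at least one overlapping neighbour (centre
distance below the sum of effective radii, effective radius = packed radius +
delta/2) moves away from its overlappers with speed ``v_rep``; every other
disk drifts toward the attraction centre with speed ``v_att``.  Displacements
are computed synchronously from the pre-step configuration.

Neighbour search uses a uniform cell grid with cell size equal to the largest
effective diameter, rebuilt every iteration from the current bounding box.
Overlapping neighbours are accumulated in ascending index order so that the
kernel is bit-for-bit identical to the O(N^2) reference implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12  # norm floor for degenerate directions


@njit(cache=True)
def _velocities(pos, eff_r, cx, cy, v_att, v_rep, cell, head, nxt, ncx, ncy, x0, y0, vel, neigh):
    n = pos.shape[0]
    for k in range(n):
        xk = pos[k, 0]
        yk = pos[k, 1]
        gx = int((xk - x0) / cell)
        gy = int((yk - y0) / cell)
        m = 0
        for ix in range(max(gx - 1, 0), min(gx + 2, ncx)):
            for iy in range(max(gy - 1, 0), min(gy + 2, ncy)):
                j = head[ix * ncy + iy]
                while j >= 0:
                    if j != k:
                        dx = xk - pos[j, 0]
                        dy = yk - pos[j, 1]
                        if np.sqrt(dx * dx + dy * dy) < eff_r[k] + eff_r[j]:
                            neigh[m] = j
                            m += 1
                    j = nxt[j]
        if m == 0:
            dx = cx - xk
            dy = cy - yk
            nrm = np.sqrt(dx * dx + dy * dy)
            if nrm > _EPS:
                vel[k, 0] = v_att * dx / nrm
                vel[k, 1] = v_att * dy / nrm
            else:
                vel[k, 0] = 0.0
                vel[k, 1] = 0.0
        else:
            # ascending index order for reproducible summation
            for a in range(1, m):
                key = neigh[a]
                b = a - 1
                while b >= 0 and neigh[b] > key:
                    neigh[b + 1] = neigh[b]
                    b -= 1
                neigh[b + 1] = key
            sx = 0.0
            sy = 0.0
            for a in range(m):
                j = neigh[a]
                dx = xk - pos[j, 0]
                dy = yk - pos[j, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if d > _EPS:
                    sx += dx / d
                    sy += dy / d
            nrm = np.sqrt(sx * sx + sy * sy)
            if nrm > _EPS:
                vel[k, 0] = v_rep * sx / nrm
                vel[k, 1] = v_rep * sy / nrm
            else:
                vel[k, 0] = 0.0
                vel[k, 1] = 0.0


@njit(cache=True)
def migrate(pos, eff_r, cx, cy, v_att, v_rep, n_iter):
    """Advance the packing ``n_iter`` iterations in place."""
    n = pos.shape[0]
    cell = 0.0
    for k in range(n):
        if 2.0 * eff_r[k] > cell:
            cell = 2.0 * eff_r[k]
    vel = np.empty((n, 2))
    neigh = np.empty(n, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    for _ in range(n_iter):
        x0 = pos[0, 0]
        y0 = pos[0, 1]
        x1 = x0
        y1 = y0
        for k in range(1, n):
            if pos[k, 0] < x0:
                x0 = pos[k, 0]
            elif pos[k, 0] > x1:
                x1 = pos[k, 0]
            if pos[k, 1] < y0:
                y0 = pos[k, 1]
            elif pos[k, 1] > y1:
                y1 = pos[k, 1]
        ncx = int((x1 - x0) / cell) + 1
        ncy = int((y1 - y0) / cell) + 1
        head = np.full(ncx * ncy, -1, dtype=np.int64)
        # linked cell list; later-inserted disks sit at the head, which does
        # not matter because neighbours are re-sorted before accumulation
        for k in range(n):
            c = int((pos[k, 0] - x0) / cell) * ncy + int((pos[k, 1] - y0) / cell)
            nxt[k] = head[c]
            head[c] = k
        _velocities(pos, eff_r, cx, cy, v_att, v_rep, cell, head, nxt, ncx, ncy, x0, y0, vel, neigh)
        for k in range(n):
            pos[k, 0] += vel[k, 0]
            pos[k, 1] += vel[k, 1]
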