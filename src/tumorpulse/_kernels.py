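"""Numba inner loops: counter-based RNG, tridiagonal diffusion, receptor RK4,
continuous-time Boolean updates (Gillespie), division draws and cell mechanics.

All stochastic kernels draw from a stateless counter RNG (splitmix64 finalizer
over key + counter): every cell owns a key derived from (simulation seed,
cell id, purpose), so adding or removing cells never perturbs the draws of
the others.
"""

import numpy as np
from numba import njit

_PHI = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)

# purpose tags for per-cell RNG keys
PUR_CTMC = np.uint64(0x1234F00D)
PUR_CYCLE = np.uint64(0x5678BEEF)


@njit(cache=True, inline="always")
def _finalize(z):
    z = (z ^ (z >> np.uint64(30))) * _C1
    z = (z ^ (z >> np.uint64(27))) * _C2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rand(key, counter):
    """Uniform double in (0, 1) for (key, counter); strictly positive."""
    v = _finalize(key + (counter + np.uint64(1)) * _PHI)
    return (np.float64(v >> np.uint64(11)) + 0.5) * (2.0 ** -53)


@njit(cache=True)
def make_keys(seed, ids, purpose):
    """Derive one uint64 key per cell id for a purpose tag."""
    base = _finalize(np.uint64(seed) * _PHI ^ purpose)
    out = np.empty(ids.shape[0], np.uint64)
    for i in range(ids.shape[0]):
        out[i] = _finalize(base + np.uint64(ids[i]) * _PHI)
    return out


# ---------------------------------------------------------------------------
# diffusion: backward-Euler step along axis 0 with no-flux (Neumann) ends
# ---------------------------------------------------------------------------

@njit(cache=True)
def thomas_axis0(c, a):
    """Solve (I - a*L1d) x = c in place along axis 0 of a 2-D array.

    L1d is the standard 1-D Laplacian stencil with reflecting ends; a is the
    dimensionless diffusion number D*dt/h^2. Coefficients are identical for
    every column, so the forward-elimination factors are precomputed once.
    """
    n, m = c.shape
    if n == 1 or a == 0.0:
        return
    cp = np.empty(n, np.float64)
    inv = np.empty(n, np.float64)
    b0 = 1.0 + a
    inv[0] = 1.0 / b0
    cp[0] = -a * inv[0]
    for i in range(1, n):
        b = 1.0 + a if i == n - 1 else 1.0 + 2.0 * a
        denom = b + a * cp[i - 1]
        inv[i] = 1.0 / denom
        cp[i] = -a * inv[i]
    for j in range(m):
        c[0, j] = c[0, j] * inv[0]
    for i in range(1, n):
        for j in range(m):
            c[i, j] = (c[i, j] + a * c[i - 1, j]) * inv[i]
    for i in range(n - 2, -1, -1):
        for j in range(m):
            c[i, j] = c[i, j] - cp[i] * c[i + 1, j]


# ---------------------------------------------------------------------------
# receptor kinetics: mass-action binding / endocytosis / recycling, RK4
# ---------------------------------------------------------------------------

@njit(cache=True)
def receptor_rk4(re, res, ris, kb, ke, kr, tnf, dt, max_h):
    """Advance every cell's receptor pools by dt at fixed local TNF.

    Classic RK4 with substeps of at most max_h minutes.  Returns the amount
    of ligand internalized-and-degraded per cell (receptor units), the time
    integral of k_endo * Re* accumulated with the same RK4 weights.
    """
    n = re.shape[0]
    consumed = np.zeros(n, np.float64)
    nsub = int(np.ceil(dt / max_h))
    if nsub < 1:
        nsub = 1
    h = dt / nsub
    for i in range(n):
        x0, x1, x2 = re[i], res[i], ris[i]
        b, e, r = kb[i] * tnf[i], ke[i], kr[i]
        acc = 0.0
        for _ in range(nsub):
            k1_0 = -b * x0 + r * x2
            k1_1 = b * x0 - e * x1
            k1_2 = e * x1 - r * x2
            k1_c = e * x1
            y0 = x0 + 0.5 * h * k1_0
            y1 = x1 + 0.5 * h * k1_1
            y2 = x2 + 0.5 * h * k1_2
            k2_0 = -b * y0 + r * y2
            k2_1 = b * y0 - e * y1
            k2_2 = e * y1 - r * y2
            k2_c = e * y1
            y0 = x0 + 0.5 * h * k2_0
            y1 = x1 + 0.5 * h * k2_1
            y2 = x2 + 0.5 * h * k2_2
            k3_0 = -b * y0 + r * y2
            k3_1 = b * y0 - e * y1
            k3_2 = e * y1 - r * y2
            k3_c = e * y1
            y0 = x0 + h * k3_0
            y1 = x1 + h * k3_1
            y2 = x2 + h * k3_2
            k4_0 = -b * y0 + r * y2
            k4_1 = b * y0 - e * y1
            k4_2 = e * y1 - r * y2
            k4_c = e * y1
            x0 += h / 6.0 * (k1_0 + 2 * k2_0 + 2 * k3_0 + k4_0)
            x1 += h / 6.0 * (k1_1 + 2 * k2_1 + 2 * k3_1 + k4_1)
            x2 += h / 6.0 * (k1_2 + 2 * k2_2 + 2 * k3_2 + k4_2)
            acc += h / 6.0 * (k1_c + 2 * k2_c + 2 * k3_c + k4_c)
        re[i], res[i], ris[i] = x0, x1, x2
        consumed[i] = acc
    return consumed


@njit(cache=True)
def receptor_euler(re0, res0, ris0, kb, ke, kr, tnf, dt, h):
    """Explicit-Euler reference trajectory for one cell (oracle for tests)."""
    nsub = int(np.round(dt / h))
    x0, x1, x2 = re0, res0, ris0
    b = kb * tnf
    for _ in range(nsub):
        d0 = -b * x0 + kr * x2
        d1 = b * x0 - ke * x1
        d2 = ke * x1 - kr * x2
        x0 += h * d0
        x1 += h * d1
        x2 += h * d2
    return x0, x1, x2


# ---------------------------------------------------------------------------
# continuous-time stochastic Boolean network (direct-method Gillespie)
# ---------------------------------------------------------------------------

# logic bytecode opcodes (RPN)
OP_NODE = 0
OP_CONST = 1
OP_NOT = 2
OP_AND = 3
OP_OR = 4


@njit(cache=True, inline="always")
def _eval_logic(code, arg, lo, hi, vals, row):
    sp = 0
    stack = np.empty(32, np.uint8)
    for k in range(lo, hi):
        op = code[k]
        if op == 0:
            stack[sp] = vals[row, arg[k]]
            sp += 1
        elif op == 1:
            stack[sp] = np.uint8(arg[k])
            sp += 1
        elif op == 2:
            stack[sp - 1] = np.uint8(1) - stack[sp - 1]
        elif op == 3:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] & stack[sp]
        else:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] | stack[sp]
    return stack[0]


@njit(cache=True)
def gillespie_window(vals, is_input, rate_up, rate_down, code, arg, starts,
                     ends, dt, keys, counters):
    """Advance each row of `vals` by dt of CTMC time (asynchronous flips).

    A node whose logic value disagrees with its current value is unstable and
    flips with the corresponding up/down rate; waiting times are exponential
    (direct method).  Counters are advanced in place.
    """
    ncell, nn = vals.shape
    rates = np.empty(nn, np.float64)
    for c in range(ncell):
        t = 0.0
        key = keys[c]
        cnt = counters[c]
        while True:
            total = 0.0
            for i in range(nn):
                r = 0.0
                if not is_input[i]:
                    target = _eval_logic(code, arg, starts[i], ends[i], vals, c)
                    cur = vals[c, i]
                    if target > cur:
                        r = rate_up[i]
                    elif target < cur:
                        r = rate_down[i]
                rates[i] = r
                total += r
            if total <= 0.0:
                break
            u1 = _rand(key, cnt)
            cnt += np.uint64(1)
            t -= np.log(u1) / total
            if t > dt:
                break
            u2 = _rand(key, cnt) * total
            cnt += np.uint64(1)
            acc = 0.0
            pick = nn - 1
            for i in range(nn):
                acc += rates[i]
                if u2 <= acc:
                    pick = i
                    break
            vals[c, pick] = np.uint8(1) - vals[c, pick]
        counters[c] = cnt


# ---------------------------------------------------------------------------
# cell cycle: per-window division draws
# ---------------------------------------------------------------------------

@njit(cache=True)
def division_draws(eligible, p_div, keys, counters):
    """Bernoulli division draw plus two direction uniforms per dividing cell.

    eligible: uint8 mask (alive and proliferative).  Returns (divide mask,
    u_theta, u_z) with the direction uniforms only meaningful where the mask
    is set.  Counters advance by 1 for every eligible cell and by 2 more for
    each division, so non-dividing cells' future draws are unaffected.
    """
    n = eligible.shape[0]
    div = np.zeros(n, np.uint8)
    u1 = np.zeros(n, np.float64)
    u2 = np.zeros(n, np.float64)
    for i in range(n):
        if eligible[i] == 0:
            continue
        cnt = counters[i]
        u = _rand(keys[i], cnt)
        cnt += np.uint64(1)
        if u < p_div:
            div[i] = 1
            u1[i] = _rand(keys[i], cnt)
            cnt += np.uint64(1)
            u2[i] = _rand(keys[i], cnt)
            cnt += np.uint64(1)
        counters[i] = cnt
    return div, u1, u2


# ---------------------------------------------------------------------------
# mechanics: pairwise quadratic repulsion with uniform spatial hashing
# ---------------------------------------------------------------------------

@njit(cache=True)
def mechanics_steps(pos, radius, active, dims, k_rep, dt, nsteps):
    """Overdamped relaxation: repulsive force k*(1 - d/(ri+rj))^2 for d < ri+rj.

    Neighbour search uses a uniform grid with bin size 2*max(radius).
    Returns False if a non-finite force appears (caller aborts).
    """
    n = pos.shape[0]
    idx = np.empty(n, np.int64)
    na = 0
    rmax = 0.0
    for i in range(n):
        if active[i]:
            idx[na] = i
            na += 1
            if radius[i] > rmax:
                rmax = radius[i]
    if na < 2:
        return True
    bin_sz = 2.0 * rmax
    for _ in range(nsteps):
        # bounding box of active cells
        lo = np.empty(3, np.float64)
        for d in range(3):
            lo[d] = pos[idx[0], d]
        for a in range(na):
            i = idx[a]
            for d in range(3):
                if pos[i, d] < lo[d]:
                    lo[d] = pos[i, d]
        nbx = np.ones(3, np.int64)
        for d in range(dims):
            span = 0.0
            for a in range(na):
                v = pos[idx[a], d] - lo[d]
                if v > span:
                    span = v
            nbx[d] = int(span / bin_sz) + 1
        nbins = nbx[0] * nbx[1] * nbx[2]
        binof = np.empty(na, np.int64)
        count = np.zeros(nbins + 1, np.int64)
        for a in range(na):
            i = idx[a]
            bx = int((pos[i, 0] - lo[0]) / bin_sz)
            by = int((pos[i, 1] - lo[1]) / bin_sz) if dims > 1 else 0
            bz = int((pos[i, 2] - lo[2]) / bin_sz) if dims > 2 else 0
            b = (bz * nbx[1] + by) * nbx[0] + bx
            binof[a] = b
            count[b + 1] += 1
        for b in range(nbins):
            count[b + 1] += count[b]
        order = np.empty(na, np.int64)
        fill = count[:nbins].copy()
        for a in range(na):
            b = binof[a]
            order[fill[b]] = idx[a]
            fill[b] += 1
        disp = np.zeros((n, 3), np.float64)
        for a in range(na):
            i = idx[a]
            bx = int((pos[i, 0] - lo[0]) / bin_sz)
            by = int((pos[i, 1] - lo[1]) / bin_sz) if dims > 1 else 0
            bz = int((pos[i, 2] - lo[2]) / bin_sz) if dims > 2 else 0
            for dz in range(-1, 2):
                cz = bz + dz
                if cz < 0 or cz >= nbx[2]:
                    continue
                for dy in range(-1, 2):
                    cy = by + dy
                    if cy < 0 or cy >= nbx[1]:
                        continue
                    for dx in range(-1, 2):
                        cx = bx + dx
                        if cx < 0 or cx >= nbx[0]:
                            continue
                        b = (cz * nbx[1] + cy) * nbx[0] + cx
                        for q in range(count[b], count[b + 1]):
                            j = order[q]
                            if j <= i:
                                continue
                            rx = pos[i, 0] - pos[j, 0]
                            ry = pos[i, 1] - pos[j, 1]
                            rz = pos[i, 2] - pos[j, 2]
                            d2 = rx * rx + ry * ry + rz * rz
                            rsum = radius[i] + radius[j]
                            if d2 >= rsum * rsum or d2 == 0.0:
                                continue
                            dist = np.sqrt(d2)
                            ov = 1.0 - dist / rsum
                            f = k_rep * ov * ov / dist
                            disp[i, 0] += f * rx
                            disp[i, 1] += f * ry
                            disp[i, 2] += f * rz
                            disp[j, 0] -= f * rx
                            disp[j, 1] -= f * ry
                            disp[j, 2] -= f * rz
        for a in range(na):
            i = idx[a]
            for d in range(dims):
                step = disp[i, d] * dt
                if not np.isfinite(step):
                    return False
                pos[i, d] += step
    return True
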