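"""JIT-compiled numerical core for the ARMS-within-Gibbs sampler.

Everything here operates on plain float arrays so it can be compiled with
numba.  The envelope machinery (piecewise-linear hull on the log scale,
piecewise-exponential masses and inverse-CDF sampling) is shared between the
generic Python-level API in :mod:`ncrm.sampler` and the monolithic
:func:`gibbs_chain` driver used for trial simulation.

Hull convention: on the segment between abscissae ``x_i`` and ``x_{i+1}`` the
log envelope is ``max(l_{i,i+1}, min(l_{i-1,i}, l_{i+1,i+2}))`` where
``l_{jk}`` is the chord through the log-target values at abscissae j and k.
An undefined chord is dropped from the max/min; if every chord in the
expression is undefined the hull is 0.  The two exterior segments (between the
support boundary and the outermost abscissae) extend the adjacent chord.
"""

import math

import numpy as np
from numba import njit

# per-segment piece budget: a segment's hull is max/min of <=3 lines, so at
# most 3 interior breakpoints -> 4 linear pieces
_PIECES_PER_SEG = 4


@njit(cache=True)
def norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


@njit(cache=True)
def gamma_vec(dvals, S, alpha, mu, sigma, out):
    """Dirichlet increment weights alpha * (F0(d_i) - F0(d_{i-1})), i=1..S+1."""
    prev = 0.0
    for i in range(S):
        cur = norm_cdf((dvals[i] - mu) / sigma)
        out[i] = alpha * (cur - prev)
        prev = cur
    out[S] = alpha * (1.0 - prev)


@njit(cache=True)
def logtarget_p(x, y, n, g_lo, g_hi, plo, phi):
    """Full-conditional log density of one toxicity probability (kernel)."""
    if x <= plo or x >= phi:
        return -np.inf
    v = (g_lo - 1.0) * math.log(x - plo) + (g_hi - 1.0) * math.log(phi - x)
    if y > 0:
        v += y * math.log(x)
    if n - y > 0:
        v += (n - y) * math.log(1.0 - x)
    return v


@njit(cache=True)
def _chord(xs, lv, i, x):
    """Line through (xs[i], lv[i]) and (xs[i+1], lv[i+1])."""
    slope = (lv[i + 1] - lv[i]) / (xs[i + 1] - xs[i])
    return lv[i] + slope * (x - xs[i])


@njit(cache=True)
def _hull_seg(xs, lv, m, s, x):
    """Hull value on segment s (-1 = left exterior, m-1 = right exterior)."""
    defA = 0 <= s <= m - 2
    defB = 0 <= s - 1 <= m - 2
    defC = 0 <= s + 1 <= m - 2
    if defB and defC:
        inner = min(_chord(xs, lv, s - 1, x), _chord(xs, lv, s + 1, x))
        inner_def = True
    elif defB:
        inner = _chord(xs, lv, s - 1, x)
        inner_def = True
    elif defC:
        inner = _chord(xs, lv, s + 1, x)
        inner_def = True
    else:
        inner = 0.0
        inner_def = False
    if defA:
        a_val = _chord(xs, lv, s, x)
        if inner_def:
            return max(a_val, inner)
        return a_val
    if inner_def:
        return inner
    return 0.0


@njit(cache=True)
def hull_eval(xs, lv, m, lo, hi, x):
    """Evaluate the piecewise-linear log envelope anywhere on [lo, hi]."""
    if m == 1:
        return lv[0]
    if x < xs[0]:
        s = -1
    elif x >= xs[m - 1]:
        s = m - 1
    else:
        s = 0
        for i in range(m - 1):
            if xs[i] <= x < xs[i + 1]:
                s = i
                break
    return _hull_seg(xs, lv, m, s, x)


@njit(cache=True)
def _logmass_linear(ha, hb, length):
    """log integral of exp(linear) over an interval of given length."""
    t = hb - ha
    if t > 30.0:
        f = t - math.log(t)
    elif t < -30.0:
        f = -math.log(-t)
    elif abs(t) < 1e-9:
        f = 0.5 * t
    else:
        f = math.log(math.expm1(t) / t)
    return ha + math.log(length) + f


@njit(cache=True)
def build_pieces(xs, lv, m, lo, hi, pa, pb, pha, phb, plm):
    """Decompose the envelope into linear pieces with log masses.

    Fills the preallocated piece arrays (endpoints ``pa, pb``, hull values
    ``pha, phb``, log masses ``plm``) and returns the number of pieces.
    Caller must size the arrays to at least ``4 * (m + 2)``.
    """
    np_out = 0
    brk = np.empty(5)
    for s in range(-1, m):
        if s == -1:
            a = lo
            b = xs[0] if m >= 1 else hi
        elif s == m - 1:
            a = xs[m - 1]
            b = hi
        else:
            a = xs[s]
            b = xs[s + 1]
        if b <= a:
            continue
        # candidate breakpoints: pairwise intersections of the (defined)
        # chords entering this segment's max/min expression
        nb = 0
        brk[nb] = a
        nb += 1
        for c1 in range(s - 1, s + 1):
            for c2 in range(c1 + 1, s + 2):
                if 0 <= c1 <= m - 2 and 0 <= c2 <= m - 2:
                    s1 = (lv[c1 + 1] - lv[c1]) / (xs[c1 + 1] - xs[c1])
                    s2 = (lv[c2 + 1] - lv[c2]) / (xs[c2 + 1] - xs[c2])
                    ds = s1 - s2
                    if ds != 0.0:
                        # intersection of the two lines
                        b1 = lv[c1] - s1 * xs[c1]
                        b2 = lv[c2] - s2 * xs[c2]
                        xint = (b2 - b1) / ds
                        if a < xint < b:
                            brk[nb] = xint
                            nb += 1
        brk[nb] = b
        nb += 1
        # insertion sort of the interior breakpoints
        for ii in range(1, nb):
            key = brk[ii]
            jj = ii - 1
            while jj >= 0 and brk[jj] > key:
                brk[jj + 1] = brk[jj]
                jj -= 1
            brk[jj + 1] = key
        for ii in range(nb - 1):
            a2 = brk[ii]
            b2 = brk[ii + 1]
            if b2 <= a2:
                continue
            ha = _hull_seg(xs, lv, m, s, a2)
            hb = _hull_seg(xs, lv, m, s, b2)
            pa[np_out] = a2
            pb[np_out] = b2
            pha[np_out] = ha
            phb[np_out] = hb
            plm[np_out] = _logmass_linear(ha, hb, b2 - a2)
            np_out += 1
    return np_out


@njit(cache=True)
def total_logmass(plm, npieces):
    mx = -np.inf
    for i in range(npieces):
        if plm[i] > mx:
            mx = plm[i]
    if mx == -np.inf:
        return -np.inf
    acc = 0.0
    for i in range(npieces):
        acc += math.exp(plm[i] - mx)
    return mx + math.log(acc)


@njit(cache=True)
def sample_pieces(pa, pb, pha, phb, plm, npieces, u_seg, u_pos):
    """Inverse-CDF draw from the piecewise-exponential envelope density.

    ``u_seg`` selects the piece through the normalised masses, ``u_pos`` the
    position within the piece (both uniforms on (0,1)).
    """
    tot = total_logmass(plm, npieces)
    acc = 0.0
    k = npieces - 1
    for i in range(npieces):
        acc += math.exp(plm[i] - tot)
        if u_seg <= acc:
            k = i
            break
    a = pa[k]
    b = pb[k]
    length = b - a
    t = phb[k] - pha[k]
    if abs(t) < 1e-9:
        return a + u_pos * length
    if t > 0.0:
        # x = b + (L/t) * log(u + (1-u) e^{-t}), stable for large t
        return b + (length / t) * math.log(u_pos + (1.0 - u_pos) * math.exp(-t))
    return a + (length / t) * math.log1p(u_pos * math.expm1(t))


@njit(cache=True)
def arms_draw_p(y, n, g_lo, g_hi, plo, phi, prev, n0_init, max_rejects):
    """One ARMS transition targeting the full conditional of one p_i.

    Rejection sampling from the piecewise-exponential envelope with adaptive
    refinement (each rejected proposal becomes a new abscissa), followed by
    the Metropolis correction; returns the new state (the accepted proposal
    or ``prev``).  Raises if the rejection loop exceeds ``max_rejects``.
    """
    cap = n0_init + max_rejects + 2
    xs = np.empty(cap)
    lv = np.empty(cap)
    m = n0_init
    span = phi - plo
    for i in range(m):
        xs[i] = plo + span * (i + 1.0) / (m + 1.0)
        lv[i] = logtarget_p(xs[i], y, n, g_lo, g_hi, plo, phi)
    pcap = _PIECES_PER_SEG * (cap + 2)
    pa = np.empty(pcap)
    pb = np.empty(pcap)
    pha = np.empty(pcap)
    phb = np.empty(pcap)
    plm = np.empty(pcap)
    x_star = prev
    h_star = 0.0
    lt_star = -np.inf
    accepted = False
    for _ in range(max_rejects):
        npieces = build_pieces(xs, lv, m, plo, phi, pa, pb, pha, phb, plm)
        u_seg = np.random.random()
        u_pos = np.random.random()
        x = sample_pieces(pa, pb, pha, phb, plm, npieces, u_seg, u_pos)
        # keep proposals strictly interior
        if x <= plo or x >= phi:
            continue
        h = hull_eval(xs, lv, m, plo, phi, x)
        lt = logtarget_p(x, y, n, g_lo, g_hi, plo, phi)
        u = np.random.random()
        if math.log(u) <= lt - h:
            x_star = x
            h_star = h
            lt_star = lt
            accepted = True
            break
        # squeeze failed: refine the envelope with the rejected point
        pos = m
        for i in range(m):
            if x < xs[i]:
                pos = i
                break
        for i in range(m, pos, -1):
            xs[i] = xs[i - 1]
            lv[i] = lv[i - 1]
        xs[pos] = x
        lv[pos] = lt
        m += 1
    if not accepted:
        raise RuntimeError("ARMS rejection loop exceeded max_rejects")
    # Metropolis correction on the final envelope
    lt_prev = logtarget_p(prev, y, n, g_lo, g_hi, plo, phi)
    h_prev = hull_eval(xs, lv, m, plo, phi, prev)
    num = lt_star + min(lt_prev, h_prev)
    den = lt_prev + min(lt_star, h_star)
    log_acc = num - den
    if log_acc >= 0.0 or math.log(np.random.random()) <= log_acc:
        return x_star
    return prev


@njit(cache=True)
def alpha_logkernel(alpha, w, loginc, S, a, b):
    """Full-conditional log kernel of the DP precision at fixed base weights w."""
    v = math.lgamma(alpha) + (a - 1.0) * math.log(alpha) - b * alpha
    for i in range(S + 1):
        g = alpha * w[i]
        v += -math.lgamma(g) + (g - 1.0) * loginc[i]
    return v


@njit(cache=True)
def _base_increments(dvals, S, mu, sigma, out):
    prev = 0.0
    for i in range(S):
        cur = norm_cdf((dvals[i] - mu) / sigma)
        out[i] = cur - prev
        prev = cur
    out[S] = 1.0 - prev


@njit(cache=True)
def _dirichlet_logkernel(gam, loginc, S):
    v = 0.0
    for i in range(S + 1):
        v += -math.lgamma(gam[i]) + (gam[i] - 1.0) * loginc[i]
    return v


@njit(cache=True)
def _loginc_from_p(p, S, out):
    prev = 0.0
    for i in range(S):
        out[i] = math.log(p[i] - prev)
        prev = p[i]
    out[S] = math.log(1.0 - prev)


@njit(cache=True)
def gibbs_chain(y, n, S, dvals, alpha0, mu0, sigma0, a, b,
                update_hyper, joint_grid, mu_grid, sigma_grid,
                p_init, n_burnin, n_keep, n0_init, max_rejects, seed):
    """Run the full ARMS-within-Gibbs chain and return retained draws.

    Cyclic updates per iteration: (optionally) an independence-Metropolis step
    for alpha with a U(1, 20) proposal, a categorical draw for (mu, sigma) on
    the discrete grid (joint over the product grid, or sequential mu-then-sigma
    when ``joint_grid`` is False), then one ARMS transition per tried dose on
    the ordered full conditionals.

    Returns ``(p_out, alpha_out, mu_out, sigma_out)`` with ``n_keep`` rows.
    """
    np.random.seed(seed)
    p = p_init.copy()
    alpha = alpha0
    mu = mu0
    sigma = sigma0
    w = np.empty(S + 1)
    gam = np.empty(S + 1)
    loginc = np.empty(S + 1)
    _base_increments(dvals, S, mu, sigma, w)
    for i in range(S + 1):
        gam[i] = alpha * w[i]
    nmu = mu_grid.shape[0]
    nsig = sigma_grid.shape[0]
    logw_joint = np.empty(nmu * nsig)
    logw_axis = np.empty(max(nmu, nsig))
    wtmp = np.empty(S + 1)
    p_out = np.empty((n_keep, S))
    alpha_out = np.empty(n_keep)
    mu_out = np.empty(n_keep)
    sigma_out = np.empty(n_keep)
    for it in range(n_burnin + n_keep):
        if update_hyper:
            _loginc_from_p(p, S, loginc)
            # --- independence MH for alpha, proposal U(1, 20)
            alpha_prop = 1.0 + 19.0 * np.random.random()
            cur = alpha_logkernel(alpha, w, loginc, S, a, b)
            prop = alpha_logkernel(alpha_prop, w, loginc, S, a, b)
            if prop - cur >= 0.0 or math.log(np.random.random()) <= prop - cur:
                alpha = alpha_prop
            # --- (mu, sigma) on the discrete grid
            if joint_grid:
                mx = -np.inf
                for im in range(nmu):
                    for isg in range(nsig):
                        _base_increments(dvals, S, mu_grid[im], sigma_grid[isg], wtmp)
                        for q in range(S + 1):
                            wtmp[q] *= alpha
                        v = _dirichlet_logkernel(wtmp, loginc, S)
                        logw_joint[im * nsig + isg] = v
                        if v > mx:
                            mx = v
                tot = 0.0
                for q in range(nmu * nsig):
                    tot += math.exp(logw_joint[q] - mx)
                u = np.random.random() * tot
                acc = 0.0
                pick = nmu * nsig - 1
                for q in range(nmu * nsig):
                    acc += math.exp(logw_joint[q] - mx)
                    if u <= acc:
                        pick = q
                        break
                mu = mu_grid[pick // nsig]
                sigma = sigma_grid[pick % nsig]
            else:
                # mu given sigma
                mx = -np.inf
                for im in range(nmu):
                    _base_increments(dvals, S, mu_grid[im], sigma, wtmp)
                    for q in range(S + 1):
                        wtmp[q] *= alpha
                    v = _dirichlet_logkernel(wtmp, loginc, S)
                    logw_axis[im] = v
                    if v > mx:
                        mx = v
                tot = 0.0
                for im in range(nmu):
                    tot += math.exp(logw_axis[im] - mx)
                u = np.random.random() * tot
                acc = 0.0
                pick = nmu - 1
                for im in range(nmu):
                    acc += math.exp(logw_axis[im] - mx)
                    if u <= acc:
                        pick = im
                        break
                mu = mu_grid[pick]
                # sigma given the new mu
                mx = -np.inf
                for isg in range(nsig):
                    _base_increments(dvals, S, mu, sigma_grid[isg], wtmp)
                    for q in range(S + 1):
                        wtmp[q] *= alpha
                    v = _dirichlet_logkernel(wtmp, loginc, S)
                    logw_axis[isg] = v
                    if v > mx:
                        mx = v
                tot = 0.0
                for isg in range(nsig):
                    tot += math.exp(logw_axis[isg] - mx)
                u = np.random.random() * tot
                acc = 0.0
                pick = nsig - 1
                for isg in range(nsig):
                    acc += math.exp(logw_axis[isg] - mx)
                    if u <= acc:
                        pick = isg
                        break
                sigma = sigma_grid[pick]
            _base_increments(dvals, S, mu, sigma, w)
            for q in range(S + 1):
                gam[q] = alpha * w[q]
        # --- ARMS update of each ordered toxicity probability
        for i in range(S):
            plo = p[i - 1] if i > 0 else 0.0
            phi = p[i + 1] if i < S - 1 else 1.0
            p[i] = arms_draw_p(float(y[i]), float(n[i]), gam[i], gam[i + 1],
                               plo, phi, p[i], n0_init, max_rejects)
        if it >= n_burnin:
            k = it - n_burnin
            for i in range(S):
                p_out[k, i] = p[i]
            alpha_out[k] = alpha
            mu_out[k] = mu
            sigma_out[k] = sigma
    return p_out, alpha_out, mu_out, sigma_out
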