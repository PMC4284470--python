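"""JIT-compiled inner loop of the extended Gillespie algorithm.

Everything here operates on flat arrays prepared by
:mod:`protocell.kinetics`.  The direct method is exact even though the
internal volume varies, because the volume changes only at discrete events
(lipid-growth firings) and all geometry-dependent propensities are
recomputed after every firing.

Channel kinds:
  0  unimolecular            a = k * x[r1]
  1  bimolecular             a = k * g(r1) * g(r2) / V   (g = count, or
                             ext_conc * V for buffered species;
                             k * x (x-1) / V for identical tracked pair)
  2  container growth        a = sum_i kcont_i x_i / g_gran ; firing adds
                             g_gran lipids to C
  3  transport in  (Fick)    a = k * A        (k = D_i * [M_i^out])
  4  transport out (Fick)    a = k * x[r1] * A / V   (k = D_i)

Status codes returned: 0 horizon reached, 1 division threshold C >= theta,
2 event cap hit, 3 total propensity zero (time jumped to horizon),
4 internal consistency failure (negative count).
"""

import math

import numpy as np
from numba import njit

PI = math.pi


@njit(cache=True)
def _geometry(C, delta, rho):
    arg = C / (PI * rho * delta**3) - 1.0 / 3.0
    r = 0.5 * delta * (math.sqrt(arg) - 1.0)
    if r < 0.0:
        r = 0.0
    V = (4.0 / 3.0) * PI * r**3
    A = 4.0 * PI * r**2
    return V, A


@njit(cache=True)
def ssa_core(
    counts,        # int64[n_species], modified in place
    C0, t0,
    kind, kvec, r1, r2,                    # channel tables
    eff_ptr, eff_idx, eff_delta,           # CSR effects
    buffered, ext,                         # per-species
    kcont_idx, kcont_val, g_gran,          # growth channel
    delta, rho,
    theta_stop,                            # <= 0 disables division stop
    t_end, max_events, seed,
    record_every,                          # 0 -> endpoints only
    rec_t, rec_C, rec_counts,              # preallocated buffers
):
    np.random.seed(seed)
    n_ch = kind.shape[0]
    a = np.zeros(n_ch)
    C = C0
    t = t0
    V, A = _geometry(C, delta, rho)
    n_events = 0
    n_rec = 0
    status = 0

    # record initial point
    if rec_t.shape[0] > 0:
        rec_t[0] = t
        rec_C[0] = C
        rec_counts[0, :] = counts
        n_rec = 1

    while True:
        a0 = 0.0
        for j in range(n_ch):
            kj = kind[j]
            if kj == 0:
                aj = kvec[j] * counts[r1[j]]
            elif kj == 1:
                i1 = r1[j]
                i2 = r2[j]
                if i1 == i2 and not buffered[i1]:
                    x = counts[i1]
                    aj = kvec[j] * x * (x - 1) / V if V > 0.0 else 0.0
                else:
                    g1 = ext[i1] * V if buffered[i1] else counts[i1]
                    g2 = ext[i2] * V if buffered[i2] else counts[i2]
                    aj = kvec[j] * g1 * g2 / V if V > 0.0 else 0.0
            elif kj == 2:
                s = 0.0
                for m in range(kcont_idx.shape[0]):
                    s += kcont_val[m] * counts[kcont_idx[m]]
                aj = s / g_gran
            elif kj == 3:
                aj = kvec[j] * A
            else:  # 4
                aj = kvec[j] * counts[r1[j]] * A / V if V > 0.0 else 0.0
            if aj < 0.0:
                aj = 0.0
            a[j] = aj
            a0 += aj

        if a0 <= 0.0:
            t = t_end
            status = 3
            break

        u = np.random.random()
        tau = -math.log(1.0 - u) / a0
        if t + tau > t_end:
            t = t_end
            status = 0
            break
        t += tau

        target = np.random.random() * a0
        acc = 0.0
        j = n_ch - 1
        for jj in range(n_ch):
            acc += a[jj]
            if acc >= target:
                j = jj
                break

        if kind[j] == 2:
            C += g_gran
            V, A = _geometry(C, delta, rho)
        else:
            for m in range(eff_ptr[j], eff_ptr[j + 1]):
                counts[eff_idx[m]] += eff_delta[m]
                if counts[eff_idx[m]] < 0:
                    status = 4
                    return C, t, n_events, n_rec, status

        n_events += 1
        if record_every > 0 and n_events % record_every == 0:
            if n_rec < rec_t.shape[0]:
                rec_t[n_rec] = t
                rec_C[n_rec] = C
                rec_counts[n_rec, :] = counts
                n_rec += 1

        if theta_stop > 0.0 and C >= theta_stop:
            status = 1
            break
        if n_events >= max_events:
            status = 2
            break

    # record final point
    if rec_t.shape[0] > n_rec:
        rec_t[n_rec] = t
        rec_C[n_rec] = C
        rec_counts[n_rec, :] = counts
        n_rec += 1

    return C, t, n_events, n_rec, status
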