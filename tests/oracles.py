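"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the Hessian oracle
differentiates the pairwise spring potential numerically, the segment
oracle rescans every window pair with numpy's corrcoef, and the counting
oracles re-enumerate triples (plain loop, and the row-replication matrix
formulation)."""

import numpy as np


def anm_potential(ref, pos, pairs, gamma):
    """Pairwise spring energy (γ/2)·Σ_{springs} (d_ij − d⁰_ij)²."""
    v = 0.0
    for i, j in pairs:
        d0 = np.linalg.norm(ref[i] - ref[j])
        d = np.linalg.norm(pos[i] - pos[j])
        v += 0.5 * gamma * (d - d0) ** 2
    return v


def finite_difference_hessian(ref, pairs, gamma, h=1e-4):
    """Central second differences of the spring potential at equilibrium."""
    ref = np.asarray(ref, dtype=float)
    n3 = ref.size
    flat0 = ref.ravel()

    def v(flat):
        return anm_potential(ref, flat.reshape(-1, 3), pairs, gamma)

    out = np.zeros((n3, n3))
    for a in range(n3):
        for b in range(a, n3):
            qpp = flat0.copy(); qpp[a] += h; qpp[b] += h
            qpm = flat0.copy(); qpm[a] += h; qpm[b] -= h
            qmp = flat0.copy(); qmp[a] -= h; qmp[b] += h
            qmm = flat0.copy(); qmm[a] -= h; qmm[b] -= h
            out[a, b] = out[b, a] = (v(qpp) - v(qpm) - v(qmp) + v(qmm)) / (4 * h * h)
    return out


def brute_force_segment(f1, f2, lam):
    """Exhaustive (i, j) rescan with a fresh correlation per window.

    Same tie rule as the implementation: a later window must beat the
    incumbent by more than 1e-12 in |c|, so the first (smallest i, then
    smallest j) of any mathematically tied group is kept.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    best = None
    for i in range(len(f1) - lam + 1):
        for j in range(len(f2) - lam + 1):
            x = f1[i : i + lam]
            y = f2[j : j + lam]
            if x.std() == 0.0 or y.std() == 0.0:
                c = 0.0
            else:
                c = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
            if best is None or abs(c) > abs(best[2]) + 1e-12:
                best = (i, j, c)
    return best


def triple_loop_counts(L1, Z1, L2, Z2):
    """Nine cooperativity counts by naive enumeration of all triples."""
    n_rows, n_modes = L1.shape
    c = dict(s1=0, s2=0, d=0, s1_pos=0, s1_neg=0, s2_pos=0, s2_neg=0,
             d_pos=0, d_neg=0)
    for m1 in range(n_rows):
        for m2 in range(n_rows):
            for n in range(n_modes):
                a, b = L1[m1, n], L2[m2, n]
                if a and not b:
                    c["s1"] += 1
                    c["s1_pos" if Z1[m1, n] else "s1_neg"] += 1
                if b and not a:
                    c["s2"] += 1
                    c["s2_pos" if Z2[m2, n] else "s2_neg"] += 1
                if a and b:
                    c["d"] += 1
                    c["d_pos" if Z1[m1, n] == Z2[m2, n] else "d_neg"] += 1
    return c


def row_replication_counts(L1, Z1, L2, Z2):
    """Counting via row expansion: each row of pair 1's matrices is tiled to
    the full matrix shape and combined elementwise with pair 2's matrices."""
    n_rows = L1.shape[0]
    c = dict(s1=0, s2=0, d=0, s1_pos=0, s1_neg=0, s2_pos=0, s2_neg=0,
             d_pos=0, d_neg=0)
    for m in range(n_rows):
        l1m = np.tile(L1[m], (n_rows, 1))
        z1m = np.tile(Z1[m], (n_rows, 1))
        only1 = l1m & ~L2
        only2 = ~l1m & L2
        both = l1m & L2
        c["s1"] += int(only1.sum())
        c["s2"] += int(only2.sum())
        c["d"] += int(both.sum())
        c["s1_pos"] += int((only1 & z1m).sum())
        c["s1_neg"] += int((only1 & ~z1m).sum())
        c["s2_pos"] += int((only2 & Z2).sum())
        c["s2_neg"] += int((only2 & ~Z2).sum())
        c["d_pos"] += int((both & (z1m == Z2)).sum())
        c["d_neg"] += int((both & (z1m != Z2)).sum())
    return c
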