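"""Independent brute-force oracles, written from the definitions.

These deliberately avoid the library's code paths (scipy peak routines,
vectorised run-length logic): strict local-maximum scans, explicit
prominence/width walks, and per-sample loops for behavior segmentation.
"""

from __future__ import annotations

import numpy as np


def brute_force_detect(dff, frame_rate, k_sd=5.0, min_width_s=0.140,
                       smooth_window_s=0.150):
    """Exhaustive transient scan. Returns sorted peak indices."""
    x = np.asarray(dff, dtype=float)
    n = x.size
    mu = float(np.median(x))
    sigma = float(1.4826 * np.median(np.abs(x - mu)))
    height_thr = mu + k_sd * sigma
    prom_thr = k_sd * sigma

    candidates = []
    for i in range(1, n - 1):
        if not (x[i - 1] < x[i] > x[i + 1]):
            continue
        if x[i] < height_thr:
            continue
        # left base: minimum between the peak and the next higher point/edge
        j = i
        lmin, lidx = x[i], i
        while j > 0 and x[j - 1] <= x[i]:
            j -= 1
            if x[j] < lmin:
                lmin, lidx = x[j], j
        j = i
        rmin, ridx = x[i], i
        while j < n - 1 and x[j + 1] <= x[i]:
            j += 1
            if x[j] < rmin:
                rmin, ridx = x[j], j
        prom = x[i] - max(lmin, rmin)
        if prom < prom_thr:
            continue
        # width at half prominence, linear interpolation, clipped at bases
        h = x[i] - 0.5 * prom
        j = i
        while j > lidx and x[j] > h:
            j -= 1
        lip = float(j)
        if x[j] < h:
            lip = j + (h - x[j]) / (x[j + 1] - x[j])
        j = i
        while j < ridx and x[j] > h:
            j += 1
        rip = float(j)
        if x[j] < h:
            rip = j - (h - x[j]) / (x[j - 1] - x[j])
        if (rip - lip) / frame_rate < min_width_s:
            continue
        candidates.append(i)

    # merge peaks closer than one smoothing window: larger wins, ties earlier
    w = int(np.floor(smooth_window_s * frame_rate + 0.5))
    order = sorted(candidates, key=lambda p: (-x[p], p))
    kept = []
    for p in order:
        if all(abs(p - q) >= w for q in kept):
            kept.append(p)
    return np.array(sorted(kept), dtype=int)


def brute_force_immobility(vel, frame_rate, immobile_speed=0.2, guard_s=0.5,
                           min_s=4.0):
    """Per-sample run scan for immobility intervals. Returns [(s, e), ...]."""
    v = np.asarray(vel, dtype=float)
    n = v.size
    g = int(round(guard_s * frame_rate))
    out = []
    i = 0
    while i < n:
        if abs(v[i]) < immobile_speed:
            j = i
            while j < n and abs(v[j]) < immobile_speed:
                j += 1
            a = i + g if i > 0 else i
            b = j - g if j < n else j
            if b - a >= min_s * frame_rate:
                out.append((a / frame_rate, b / frame_rate))
            i = j
        else:
            i += 1
    return out


def brute_force_bouts(vel, frame_rate, immobility, bout_speed=0.4, min_s=4.0,
                      flank_s=4.0, gap_tol_s=1.0, onset_k_sd=2.0):
    """Per-sample bout scan with the same qualification and refinement rules.

    Returns [(onset_s, offset_s, cand_start_s, cand_end_s), ...].
    """
    v = np.asarray(vel, dtype=float)
    n = v.size
    fr = frame_rate
    imm_samples = []
    for (s, e) in immobility:
        imm_samples.extend(v[int(round(s * fr)):int(round(e * fr))])
    if not imm_samples:
        return []
    mean_imm = float(np.mean(imm_samples))
    sd_imm = float(np.std(imm_samples))

    def exceeds(i):
        return abs(v[i] - mean_imm) > onset_k_sd * sd_imm

    out = []
    i = 0
    while i < n:
        if abs(v[i]) > bout_speed:
            j = i
            while j < n and abs(v[j]) > bout_speed:
                j += 1
            if j - i >= min_s * fr:
                t0, t1 = i / fr, j / fr
                prev = [k for k, (s, e) in enumerate(immobility) if e <= t0 + 1e-9]
                nxt = [k for k, (s, e) in enumerate(immobility) if s >= t1 - 1e-9]
                ok = bool(prev) and bool(nxt)
                if ok:
                    ps, pe = immobility[prev[-1]]
                    ns, ne = immobility[nxt[0]]
                    ok = (t0 - pe <= gap_tol_s and ns - t1 <= gap_tol_s
                          and pe - ps >= flank_s and ne - ns >= flank_s)
                if ok:
                    lo = int(round(pe * fr))
                    a = i
                    if exceeds(a):
                        while a - 1 >= lo and exceeds(a - 1):
                            a -= 1
                    hi = int(round(ns * fr))
                    b = j - 1
                    if exceeds(b):
                        while b + 1 < min(hi, n) and exceeds(b + 1):
                            b += 1
                    out.append((a / fr, (b + 1) / fr, t0, t1))
            i = j
        else:
            i += 1
    return out


def sort_percentile(x, q):
    """Percentile by explicit sort + linear interpolation (numpy 'linear')."""
    s = np.sort(np.asarray(x, dtype=float))
    rank = q / 100.0 * (s.size - 1)
    lo = int(np.floor(rank))
    hi = min(lo + 1, s.size - 1)
    return s[lo] + (rank - lo) * (s[hi] - s[lo])


def mannwhitney_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration (no ties)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n1 = len(a)
    obs = sum(1 for x in a for y in b if x > y)
    n2 = len(b)
    mean_u = n1 * n2 / 2.0
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        grp = pooled[list(comb)]
        rest = np.delete(pooled, list(comb))
        u = sum(1 for x in grp for y in rest if x > y)
        if abs(u - mean_u) >= abs(obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_exact_p(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    from itertools import product

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_pos = ranks[d > 0].sum()
    total_w = ranks.sum()
    w_obs = min(w_pos, total_w - w_pos)
    count = 0
    n_assign = 0
    for signs in product([0, 1], repeat=d.size):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total_w - w) <= w_obs + 1e-12:
            count += 1
        n_assign += 1
    return count / n_assign
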