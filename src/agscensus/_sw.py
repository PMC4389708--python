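"""Numba kernels for the seeded translated search.

Two kernels do the heavy lifting:

``scan_candidates``
    walks a sorted array of packed seed keys (read, frame, target, diagonal)
    and emits one candidate per (read, frame, target) that satisfies the
    two-hit rule (two exact k-mer seeds on the same diagonal; a single seed
    suffices for frames whose peptide is too short to expect two).

``banded_sw_batch``
    runs a banded Smith-Waterman with affine gaps and full traceback for each
    candidate, restricted to a diagonal band around the seed diagonals, and
    returns the local-alignment statistics needed downstream (raw score,
    query/target spans, alignment columns, identities).

The gap model is Gotoh-style: a gap of length g costs open + g * extend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**6)


@njit(cache=True)
def scan_candidates(keys, diag_span, n_targets, need_two):
    """Collapse sorted seed keys into candidate (read, frame, target) triples.

    keys are sorted int64 values: ((read*6 + frame)*n_targets + target) *
    diag_span + shifted_diagonal.  Returns candidate arrays plus the min/max
    seed diagonal (shifted) per candidate, and the candidate count.
    """
    n = keys.shape[0]
    # worst case: one candidate per distinct group
    cand_read = np.empty(n, dtype=np.int32)
    cand_frame = np.empty(n, dtype=np.int8)
    cand_target = np.empty(n, dtype=np.int32)
    cand_dlo = np.empty(n, dtype=np.int32)
    cand_dhi = np.empty(n, dtype=np.int32)
    out = 0
    i = 0
    while i < n:
        g = keys[i] // diag_span
        j = i
        best_run = 0
        run = 0
        prev_key = np.int64(-1)
        dlo = np.int64(diag_span)
        dhi = np.int64(-1)
        while j < n and keys[j] // diag_span == g:
            d = keys[j] % diag_span
            if d < dlo:
                dlo = d
            if d > dhi:
                dhi = d
            if keys[j] == prev_key:
                run += 1
            else:
                run = 1
                prev_key = keys[j]
            if run > best_run:
                best_run = run
            j += 1
        target = g % n_targets
        rf = g // n_targets
        frame = rf % 6
        read = rf // 6
        required = 1 if need_two[frame] == 0 else 2
        if best_run >= required:
            cand_read[out] = read
            cand_frame[out] = frame
            cand_target[out] = target
            cand_dlo[out] = dlo
            cand_dhi[out] = dhi
            out += 1
        i = j
    return (
        cand_read[:out],
        cand_frame[:out],
        cand_target[:out],
        cand_dlo[:out],
        cand_dhi[:out],
    )


@njit(cache=True)
def _sw_one(q, m, t, tl, d0, d1, submat, oc, ge, H_prev, F_prev, H_cur, F_cur, tb):
    """Banded affine Smith-Waterman for one query/target pair.

    Cell (i, j) aligns q[i] with t[j]; only diagonals d = i - j within
    [d0, d1] are evaluated.  tb holds packed traceback: bits 0-1 = H source
    (0 stop, 1 diag, 2 from E, 3 from F), bit 2 = E opened, bit 3 = F opened.
    Returns (score, qstart, qend, tstart, tend, columns, identities).
    """
    W = d1 - d0 + 1
    for w in range(W):
        H_prev[w] = 0
        F_prev[w] = NEG
    best = 0
    bi = -1
    bw = -1
    for i in range(m):
        jhi = i - d0
        jlo = i - d1
        E = NEG
        for w in range(W):
            j = jlo + w
            if j < 0 or j >= tl:
                H_cur[w] = NEG
                F_cur[w] = NEG
                tb[i * W + w] = 0
                E = NEG
                continue
            # F: gap consuming q[i]; previous row same j is w+1 there
            fopen = 0
            F = NEG
            if w + 1 < W:
                hp = H_prev[w + 1]
                fp = F_prev[w + 1]
                a = hp - oc if hp > NEG // 2 else NEG
                b = fp - ge if fp > NEG // 2 else NEG
                if a >= b:
                    F = a
                    fopen = 1
                else:
                    F = b
            # E: gap consuming t[j]; same row previous w
            eopen = 0
            if w > 0:
                hl = H_cur[w - 1]
                a = hl - oc if hl > NEG // 2 else NEG
                b = E - ge if E > NEG // 2 else NEG
                if a >= b:
                    E = a
                    eopen = 1
                else:
                    E = b
            else:
                E = NEG
            # H
            diagv = NEG
            if i == 0 or j == 0:
                diagv = submat[q[i], t[j]]
            else:
                hp = H_prev[w]
                if hp > NEG // 2:
                    diagv = hp + submat[q[i], t[j]]
            h = 0
            src = 0
            if diagv > h:
                h = diagv
                src = 1
            if E > h:
                h = E
                src = 2
            if F > h:
                h = F
                src = 3
            H_cur[w] = h
            F_cur[w] = F
            tb[i * W + w] = src | (eopen << 2) | (fopen << 3)
            if h > best:
                best = h
                bi = i
                bw = w
        for w in range(W):
            H_prev[w] = H_cur[w]
            F_prev[w] = F_cur[w]
    if best <= 0:
        return 0, 0, -1, 0, -1, 0, 0
    # traceback
    i = bi
    w = bw
    j = i - d1 + w
    qend = bi
    tend = j
    qstart = bi
    tstart = j
    cols = 0
    ident = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if i < 0 or j < 0:
            break
        b = tb[i * W + w]
        if state == 0:
            src = b & 3
            if src == 0:
                break
            elif src == 1:
                cols += 1
                if q[i] == t[j]:
                    ident += 1
                qstart = i
                tstart = j
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap column consuming t[j]
            cols += 1
            tstart = j
            opened = b & 4
            j -= 1
            w -= 1
            if opened:
                state = 0
        else:  # gap column consuming q[i]
            cols += 1
            qstart = i
            opened = b & 8
            i -= 1
            w += 1
            if opened:
                state = 0
    return best, qstart, qend, tstart, tend, cols, ident


@njit(cache=True)
def banded_sw_batch(
    pep,  # (n_reads, 6, pmax) int8 peptide codes, X-padded
    plen,  # (6,) peptide length per frame
    t_flat,  # concatenated target codes
    t_off,  # (n_targets+1,) offsets
    cand_read,
    cand_frame,
    cand_target,
    cand_dlo,
    cand_dhi,
    diag_off,
    pad,
    submat,
    gap_open,
    gap_extend,
):
    nc = cand_read.shape[0]
    score = np.zeros(nc, dtype=np.int32)
    qstart = np.zeros(nc, dtype=np.int32)
    qend = np.zeros(nc, dtype=np.int32)
    tstart = np.zeros(nc, dtype=np.int32)
    tend = np.zeros(nc, dtype=np.int32)
    cols = np.zeros(nc, dtype=np.int32)
    ident = np.zeros(nc, dtype=np.int32)
    oc = gap_open + gap_extend
    pmax = pep.shape[2]
    # shared workspaces sized for the widest possible band (seeds may sit on
    # distant diagonals of one target, so bound by full query + target extent)
    tmax = 0
    for k in range(t_off.shape[0] - 1):
        tl = t_off[k + 1] - t_off[k]
        if tl > tmax:
            tmax = tl
    maxW = pmax + tmax + 2 * int(pad) + 2
    H_prev = np.zeros(maxW, dtype=np.int32)
    F_prev = np.zeros(maxW, dtype=np.int32)
    H_cur = np.zeros(maxW, dtype=np.int32)
    F_cur = np.zeros(maxW, dtype=np.int32)
    tb = np.zeros(pmax * maxW, dtype=np.uint8)
    for c in range(nc):
        f = cand_frame[c]
        m = plen[f]
        t0 = t_off[cand_target[c]]
        tl = t_off[cand_target[c] + 1] - t0
        d0 = cand_dlo[c] - diag_off - pad
        d1 = cand_dhi[c] - diag_off + pad
        if d0 < -(tl - 1):
            d0 = -(tl - 1)
        if d1 > m - 1:
            d1 = m - 1
        if d1 < d0:
            continue
        q = pep[cand_read[c], f]
        s, qs, qe, ts, te, co, idn = _sw_one(
            q, m, t_flat[t0 : t0 + tl], tl, d0, d1, submat, oc, gap_extend,
            H_prev, F_prev, H_cur, F_cur, tb,
        )
        score[c] = s
        qstart[c] = qs
        qend[c] = qe
        tstart[c] = ts
        tend[c] = te
        cols[c] = co
        ident[c] = idn
    return score, qstart, qend, tstart, tend, cols, ident
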