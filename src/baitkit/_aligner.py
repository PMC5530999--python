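"""Compiled affine-gap alignment kernels.

Two dynamic programmes back the whole toolkit:

* :func:`sw_local` — exact local (Smith–Waterman) alignment with affine
  gaps, optionally restricted to a diagonal band.  With the band fully
  open it is the exact aligner used as the ground-truth oracle; with a
  narrow band it is the extension stage of the seeded homology search.
* :func:`nw_global` — global (Needleman–Wunsch) alignment with penalised
  end gaps, used for the percent-identity filter.

A gap of length L costs ``gap_open + L * gap_extend``.  Ambiguity codes
(including N) never match anything, not even themselves: identity is
computed conservatively over unambiguous bases only.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

# A,C,G,T -> 0..3; every ambiguity code gets a distinct non-matching code.
_CODE = {
    "A": 0, "C": 1, "G": 2, "T": 3, "U": 3,
    "N": 4, "R": 5, "Y": 6, "S": 7, "W": 8, "K": 9, "M": 10,
    "B": 11, "D": 12, "H": 13, "V": 14,
}
_LUT = np.full(256, 15, dtype=np.uint8)
for _ch, _c in _CODE.items():
    _LUT[ord(_ch)] = _c
    _LUT[ord(_ch.lower())] = _c


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes for the kernels."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, go, ge, dlo, dhi):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pH = np.zeros((n + 1, m + 1), dtype=np.int8)
    pE = np.zeros((n + 1, m + 1), dtype=np.int8)
    pF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            # gap consuming b[j-1] (gap in query)
            eo = H[i, j - 1] - go - ge
            ee = E[i, j - 1] - ge
            if eo >= ee:
                E[i, j] = eo
                pE[i, j] = 1
            else:
                E[i, j] = ee
                pE[i, j] = 0
            # gap consuming a[i-1] (gap in subject)
            fo = H[i - 1, j] - go - ge
            fe = F[i - 1, j] - ge
            if fo >= fe:
                F[i, j] = fo
                pF[i, j] = 1
            else:
                F[i, j] = fe
                pF[i, j] = 0
            ca = a[i - 1]
            cb = b[j - 1]
            if ca == cb and ca < 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, j - 1] + sub
            val = 0
            ptr = 0
            if diag > val:
                val = diag
                ptr = 1
            if E[i, j] > val:
                val = E[i, j]
                ptr = 2
            if F[i, j] > val:
                val = F[i, j]
                ptr = 3
            H[i, j] = val
            pH[i, j] = ptr
            if val > best:
                best = val
                bi = i
                bj = j
    return H, pH, pE, pF, best, bi, bj


def _sw_traceback(a, b, pH, pE, pF, bi, bj):
    """Walk the pointer matrices from the best cell; also report the
    gapless runs of the alignment as ``(q_start, q_end, diagonal)`` with
    ``diagonal = s - q`` (needed for exact spliced-mapping refinement)."""
    i = bi
    j = bj
    aln_len = 0
    matches = 0
    gapopens = 0
    state = 0  # 0=H, 1=E, 2=F
    segments: list[tuple[int, int, int]] = []
    run_end = -1

    def close_run():
        nonlocal run_end
        if run_end != -1:
            segments.append((i, run_end, j - i))
            run_end = -1

    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                close_run()
                break
            if p == 1:
                if run_end == -1:
                    run_end = i
                aln_len += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                close_run()
                state = 1
            else:
                close_run()
                state = 2
        elif state == 1:
            aln_len += 1
            opened = pE[i, j]
            j -= 1
            if opened == 1:
                gapopens += 1
                state = 0
        else:
            aln_len += 1
            opened = pF[i, j]
            i -= 1
            if opened == 1:
                gapopens += 1
                state = 0
    segments.reverse()
    return i, j, aln_len, matches, gapopens, segments


def sw_local(
    a: np.ndarray,
    b: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    dlo: int | None = None,
    dhi: int | None = None,
):
    """Exact affine local alignment of code arrays ``a`` (query) vs ``b``.

    ``dlo``/``dhi`` restrict the alignment to diagonals ``j - i`` within
    the band (sequence coordinates); ``None`` leaves the band fully open.
    Returns ``None`` when the optimal score is <= 0, otherwise a tuple
    ``(score, q_start, q_end, s_start, s_end, aln_len, matches, gapopens,
    segments)`` where ``segments`` lists the gapless runs of the optimal
    alignment as ``(q_start, q_end, s - q diagonal)``.  Ties between
    equal-scoring cells resolve to the smallest query end coordinate,
    then subject end coordinate.
    """
    if dlo is None:
        dlo = -a.shape[0]
    if dhi is None:
        dhi = b.shape[0]
    H, pH, pE, pF, best, bi, bj = _sw_fill(
        a, b, match, mismatch, gap_open, gap_extend, dlo, dhi
    )
    if best <= 0:
        return None
    qs, ss, aln_len, matches, gapopens, segments = _sw_traceback(
        a, b, pH, pE, pF, bi, bj
    )
    return best, qs, bi, ss, bj, aln_len, matches, gapopens, segments


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, go, ge):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    pH = np.zeros((n + 1, m + 1), dtype=np.int8)
    pE = np.zeros((n + 1, m + 1), dtype=np.int8)
    pF = np.zeros((n + 1, m + 1), dtype=np.int8)
    for j in range(1, m + 1):
        E[0, j] = -(go + ge * j)
        H[0, j] = E[0, j]
        pH[0, j] = 2
        pE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -(go + ge * i)
        H[i, 0] = F[i, 0]
        pH[i, 0] = 3
        pF[i, 0] = 1 if i == 1 else 0
        for j in range(1, m + 1):
            eo = H[i, j - 1] - go - ge
            ee = E[i, j - 1] - ge
            if eo >= ee:
                E[i, j] = eo
                pE[i, j] = 1
            else:
                E[i, j] = ee
                pE[i, j] = 0
            fo = H[i - 1, j] - go - ge
            fe = F[i - 1, j] - ge
            if fo >= fe:
                F[i, j] = fo
                pF[i, j] = 1
            else:
                F[i, j] = fe
                pF[i, j] = 0
            ca = a[i - 1]
            cb = b[j - 1]
            if ca == cb and ca < 4:
                sub = match
            else:
                sub = mismatch
            val = H[i - 1, j - 1] + sub
            ptr = 1
            if E[i, j] > val:
                val = E[i, j]
                ptr = 2
            if F[i, j] > val:
                val = F[i, j]
                ptr = 3
            H[i, j] = val
            pH[i, j] = ptr
    return H, pH, pE, pF


@njit(cache=True)
def _nw_traceback(a, b, pH, pE, pF):  # pragma: no cover
    i = a.shape[0]
    j = b.shape[0]
    aln_len = 0
    matches = 0
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 1:
                aln_len += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            opened = pE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            aln_len += 1
            opened = pF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return aln_len, matches


def nw_global(
    a: np.ndarray,
    b: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
):
    """Exact affine global alignment with penalised end gaps.

    Returns ``(score, aln_len, matches)``.
    """
    H, pH, pE, pF = _nw_fill(a, b, match, mismatch, gap_open, gap_extend)
    aln_len, matches = _nw_traceback(a, b, pH, pE, pF)
    return int(H[a.shape[0], b.shape[0]]), aln_len, matches
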