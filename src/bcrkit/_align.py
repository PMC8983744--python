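"""Ungapped local alignment kernels.

Segment assignment uses exact ungapped local alignment (match +1,
mismatch -1, no gaps): the best-scoring contiguous run on any diagonal of
the germline x read comparison matrix.  This is deliberately simple —
deterministic, exhaustively testable, and adequate for substitution-only
(SHM) divergence; indels are out of scope.

The batch kernel scans one read against many germline segments with a
numba-compiled maximum-subarray (Kadane) pass per diagonal;
:func:`best_local` is the plain-Python reference implementation of the
same scan.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENCODE = np.full(256, 200, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes (other characters never match)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@njit(cache=False)
def _batch_kernel(germ_mat, germ_lens, read, out):  # pragma: no cover - numba
    k = germ_mat.shape[0]
    n = read.shape[0]
    for s in range(k):
        m = germ_lens[s]
        best = 0
        bg0 = bg1 = br0 = br1 = 0
        for d in range(-(m - 1), n):
            i0 = -d if d < 0 else 0
            i1 = m if m < n - d else n - d
            run = 0
            run_start = i0
            for i in range(i0, i1):
                if germ_mat[s, i] == read[i + d]:
                    val = 1
                else:
                    val = -1
                if run <= 0:
                    run = val
                    run_start = i
                else:
                    run += val
                if run > best:
                    best = run
                    bg0 = run_start
                    bg1 = i + 1
                    br0 = bg0 + d
                    br1 = bg1 + d
        out[s, 0] = best
        out[s, 1] = bg0
        out[s, 2] = bg1
        out[s, 3] = br0
        out[s, 4] = br1
        out[s, 5] = (best + (bg1 - bg0)) // 2


def batch_best_local(
    germ_mat: np.ndarray, germ_lens: np.ndarray, read: np.ndarray
) -> list[tuple[int, int, int, int, int, int]]:
    """Best ungapped local alignment of each germline row against the read.

    ``germ_mat`` is (k, m_max) uint8, rows padded with a non-matching
    sentinel.  Returns one ``(score, g_start, g_end, r_start, r_end,
    n_matches)`` tuple per row, with 0-based half-open intervals.  Ties
    break to the first maximum in (diagonal, end-position) order, so the
    result is deterministic.
    """
    k = germ_mat.shape[0]
    if k == 0 or read.shape[0] == 0:
        return [(0, 0, 0, 0, 0, 0)] * k
    out = np.zeros((k, 6), dtype=np.int64)
    _batch_kernel(germ_mat, germ_lens.astype(np.int64), read, out)
    return [tuple(int(x) for x in row) for row in out]


def best_local(germ: np.ndarray, read: np.ndarray) -> tuple[int, int, int, int, int, int]:
    """Plain-Python reference for the batch kernel (one germline row).

    Same scoring and tie-break order; used as an independent check and
    for tiny inputs.
    """
    m, n = germ.shape[0], read.shape[0]
    best = (0, 0, 0, 0, 0, 0)
    if m == 0 or n == 0:
        return best
    best_score = 0
    for d in range(-(m - 1), n):
        i0 = max(0, -d)
        i1 = min(m, n - d)
        run = 0
        run_start = i0
        for i in range(i0, i1):
            val = 1 if germ[i] == read[i + d] else -1
            if run <= 0:
                run = val
                run_start = i
            else:
                run += val
            if run > best_score:
                best_score = run
                g0, g1 = run_start, i + 1
                n_matches = (run + (g1 - g0)) // 2
                best = (run, g0, g1, g0 + d, g1 + d, n_matches)
    return best


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Length and 0-based start positions of the longest common substring.

    Ties resolved by earliest start in ``a``, then earliest in ``b``.
    """
    if not a or not b:
        return 0, 0, 0
    best_len, best_a, best_b = 0, 0, 0
    prev = [0] * (len(b) + 1)
    for i, ca in enumerate(a):
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b):
            if ca == cb:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best_len:
                    best_len = cur[j + 1]
                    best_a = i + 1 - best_len
                    best_b = j + 1 - best_len
        prev = cur
    return best_len, best_a, best_b
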