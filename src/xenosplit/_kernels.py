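"""Fused inner-loop kernels for k-mer membership lookup and read assignment.

These are optional accelerations: every caller has an equivalent pure-NumPy
path, and the kernels are exercised against it in the tests.  When numba is
not installed the module exposes ``HAVE_NUMBA = False`` and callers fall
back transparently.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        return deco


@njit(cache=True)
def _bisect(table: np.ndarray, q: np.uint64) -> int:
    lo, hi = 0, table.shape[0]
    while lo < hi:
        mid = (lo + hi) >> 1
        if table[mid] < q:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def rolling_canonical_kmers(rows: np.ndarray, k: int):
    """Canonical k-mer codes and validity for equal-length encoded reads."""
    n, length = rows.shape
    nwin = length - k + 1
    km = np.zeros((n, nwin), np.uint64)
    valid = np.zeros((n, nwin), np.bool_)
    mask = np.uint64((np.uint64(1) << np.uint64(2 * k)) - np.uint64(1))
    shift_top = np.uint64(2 * (k - 1))
    for i in range(n):
        fwd = np.uint64(0)
        rc = np.uint64(0)
        last_bad = -k - 1  # position of the most recent invalid base
        for j in range(length):
            c = rows[i, j]
            if c == 255:
                last_bad = j
                c_ = np.uint64(0)
            else:
                c_ = np.uint64(c)
            fwd = ((fwd << np.uint64(2)) | c_) & mask
            rc = (rc >> np.uint64(2)) | ((np.uint64(3) - c_) << shift_top)
            if j >= k - 1:
                w = j - k + 1
                if last_bad < w:  # window positions w..j free of invalid bases
                    valid[i, w] = True
                    km[i, w] = fwd if fwd < rc else rc
    return km, valid


@njit(cache=True)
def classify_counts(
    table_codes: np.ndarray,
    table_labels: np.ndarray,
    km: np.ndarray,
    valid: np.ndarray,
):
    """Per-read (h, m, b, u) counts via binary search in the merged table."""
    n, w = km.shape
    size = table_codes.shape[0]
    h = np.zeros(n, np.int32)
    m = np.zeros(n, np.int32)
    b = np.zeros(n, np.int32)
    u = np.zeros(n, np.int32)
    for i in range(n):
        for j in range(w):
            if not valid[i, j]:
                continue
            q = km[i, j]
            lo = _bisect(table_codes, q)
            if lo < size and table_codes[lo] == q:
                lab = table_labels[lo]
                if lab == 0:
                    h[i] += 1
                elif lab == 1:
                    m[i] += 1
                else:
                    b[i] += 1
            else:
                u[i] += 1
    return h, m, b, u


@njit(cache=True)
def assign_single_owner(
    codes: np.ndarray,
    owners: np.ndarray,
    km: np.ndarray,
    valid: np.ndarray,
):
    """Assign reads whose found k-mers all belong to one gene.

    Returns ``(gene_index, needs_slow)``; rows touching a shared k-mer or
    more than one owner are flagged for the general scoring path.
    """
    n, w = km.shape
    size = codes.shape[0]
    out = np.full(n, -1, np.int32)
    needs_slow = np.zeros(n, np.uint8)
    for i in range(n):
        first = -1
        multi = False
        shared = False
        for j in range(w):
            if not valid[i, j]:
                continue
            q = km[i, j]
            lo = _bisect(codes, q)
            if lo < size and codes[lo] == q:
                o = owners[lo]
                if o == -2:
                    shared = True
                elif first == -1:
                    first = o
                elif o != first:
                    multi = True
        if shared or multi:
            needs_slow[i] = 1
        else:
            out[i] = first
    return out, needs_slow
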