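"""Numba kernels for modification-aware semi-global alignment.

Unit-cost edit distance (match 0, mismatch/insertion/deletion 1) of a read
against a reference, with the read aligned end-to-end and both reference
ends free.  Reference positions carrying modified nucleotides match any read
base at zero cost: reverse transcriptase misreads modified bases, so a
mismatch there carries no signal.

Bases are encoded A=0 C=1 G=2 T=3 N=4; any other character also maps to 4.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = np.int32(1 << 20)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def semiglobal_dp(read, ref, mask, cutoff):  # pragma: no cover - jitted
    """Best semi-global alignment of ``read`` within ``ref``.

    Returns ``(errors, end)`` where ``end`` is the 1-based reference column
    of the alignment end (largest such column among co-optimal ends, i.e.
    the end closest to the reference 3' terminus).  With ``cutoff >= 0`` the
    DP is abandoned as soon as no cell of a row is <= cutoff, returning
    ``(cutoff + 1, -1)``.
    """
    m = read.shape[0]
    n = ref.shape[0]
    prev = np.empty(n + 1, dtype=np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        prev[j] = 0
    for i in range(1, m + 1):
        cur[0] = i
        rowmin = np.int32(i)
        rb = read[i - 1]
        for j in range(1, n + 1):
            cost = 0 if (mask[j - 1] or ref[j - 1] == rb) else 1
            v = prev[j - 1] + cost
            t = prev[j] + 1
            if t < v:
                v = t
            t = cur[j - 1] + 1
            if t < v:
                v = t
            cur[j] = v
            if v < rowmin:
                rowmin = v
        if cutoff >= 0 and rowmin > cutoff:
            return cutoff + 1, -1
        tmp = prev
        prev = cur
        cur = tmp
    best = prev[0]
    end = 0
    for j in range(1, n + 1):
        if prev[j] <= best:
            best = prev[j]
            end = j
    return best, end


@njit(cache=True)
def assign_batch(
    reads, read_lens, refs, ref_lens, masks, max_errors
):  # pragma: no cover - jitted
    """Best reference per read under (fewest errors, lowest ref index).

    ``refs``/``masks`` must be ordered by the caller's tie-break (species id
    ascending); a later reference wins only with strictly fewer errors.
    Returns arrays ``(ref_idx, errors, end)`` with ``ref_idx = -1`` for
    unassigned reads (no alignment within ``max_errors``).
    """
    n_reads = reads.shape[0]
    n_refs = refs.shape[0]
    out_ref = np.full(n_reads, -1, dtype=np.int32)
    out_err = np.full(n_reads, max_errors + 1, dtype=np.int32)
    out_end = np.full(n_reads, -1, dtype=np.int32)
    for r in range(n_reads):
        m = read_lens[r]
        read = reads[r, :m]
        best = max_errors + 1
        for k in range(n_refs):
            n = ref_lens[k]
            if m > n + max_errors:
                continue  # read cannot fit with <= max_errors insertions
            cutoff = best - 1  # later refs must strictly improve
            err, end = semiglobal_dp(read, refs[k, :n], masks[k, :n], cutoff)
            if err < best:
                best = err
                out_ref[r] = k
                out_err[r] = err
                out_end[r] = end
                if best == 0:
                    break
        if out_ref[r] >= 0:
            # offset relative to this reference
            out_end[r] = ref_lens[out_ref[r]] - out_end[r]
    return out_ref, out_err, out_end
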