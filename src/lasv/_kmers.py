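"""Packed k-mer counting kernels.

(k+1)-mers up to 56 bases are packed 2 bits/base into a pair of integers
(``hi`` = leading bases beyond 28, ``lo`` = trailing 28 bases) and counted
in a numba typed dict; 'N'-separated buffers reset the rolling window at
read boundaries.  The long-read kernel counts the number of *distinct
reads* containing each k-mer, which the solidity rule needs.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

_key_type = types.UniTuple(types.int64, 2)
_val_type = types.int64


def encode_buffer(sequences: list[str]) -> np.ndarray:
    """2-bit codes of 'N'-joined sequences; 255 marks boundaries."""
    if not sequences:
        return np.empty(0, dtype=np.uint8)
    joined = "N".join(sequences).encode()
    return _LUT[np.frombuffer(joined, dtype=np.uint8)]


@njit(cache=True)
def _count_kernel(codes, km):  # pragma: no cover - exercised via build_graph
    d = Dict.empty(_key_type, _val_type)
    lo_len = min(km, 28)
    hi_len = km - lo_len
    lo_mask = (1 << (2 * lo_len)) - 1
    hi_mask = (1 << (2 * hi_len)) - 1 if hi_len else 0
    lo_shift = 2 * lo_len - 2
    hi = 0
    lo = 0
    w = 0
    for i in range(codes.shape[0]):
        c = codes[i]
        if c > 3:
            hi = 0
            lo = 0
            w = 0
            continue
        if hi_len:
            hi = ((hi << 2) | (lo >> lo_shift)) & hi_mask
        lo = ((lo << 2) | c) & lo_mask
        w += 1
        if w >= km:
            key = (hi, lo)
            d[key] = d.get(key, 0) + 1
    return d


@njit(cache=True)
def _count_per_read_kernel(codes, km):  # pragma: no cover
    """Counts of distinct reads containing each k-mer (value packs
    last-seen read id in the high bits).  The buffer interleaves each read
    with its reverse complement, so a read id covers two 'N'-separated
    chunks."""
    d = Dict.empty(_key_type, _val_type)
    lo_len = min(km, 28)
    hi_len = km - lo_len
    lo_mask = (1 << (2 * lo_len)) - 1
    hi_mask = (1 << (2 * hi_len)) - 1 if hi_len else 0
    lo_shift = 2 * lo_len - 2
    hi = 0
    lo = 0
    w = 0
    nsep = 0
    rid = 0
    for i in range(codes.shape[0]):
        c = codes[i]
        if c > 3:
            hi = 0
            lo = 0
            w = 0
            nsep += 1
            rid = nsep >> 1
            continue
        if hi_len:
            hi = ((hi << 2) | (lo >> lo_shift)) & hi_mask
        lo = ((lo << 2) | c) & lo_mask
        w += 1
        if w >= km:
            key = (hi, lo)
            if key in d:
                val = d[key]
                if (val >> 32) != rid:
                    d[key] = (rid << 32) | ((val & 0xFFFFFFFF) + 1)
            else:
                d[key] = (rid << 32) | 1
    return d


@njit(cache=True)
def _solidify_kernel(short_d, long_d, threshold):  # pragma: no cover
    """Apply the solidity rule and emit packed arrays (his, los, covs)."""
    n = 0
    for key, sc in short_d.items():
        lc = (long_d.get(key, 0)) & 0xFFFFFFFF
        if sc >= threshold or (sc >= 1 and lc >= 1):
            n += 1
    for key, val in long_d.items():
        if key not in short_d and (val & 0xFFFFFFFF) >= 2:
            n += 1
    his = np.empty(n, dtype=np.int64)
    los = np.empty(n, dtype=np.int64)
    covs = np.empty(n, dtype=np.int64)
    i = 0
    for key, sc in short_d.items():
        lc = (long_d.get(key, 0)) & 0xFFFFFFFF
        if sc >= threshold or (sc >= 1 and lc >= 1):
            his[i] = key[0]
            los[i] = key[1]
            covs[i] = sc + lc
            i += 1
    for key, val in long_d.items():
        if key not in short_d:
            lc = val & 0xFFFFFFFF
            if lc >= 2:
                his[i] = key[0]
                los[i] = key[1]
                covs[i] = lc
                i += 1
    return his, los, covs


@njit(cache=True)
def _pack_kernel(codes, km, n):  # pragma: no cover
    """Pack each 'N'-separated chunk of exactly ``km`` bases."""
    his = np.empty(n, dtype=np.int64)
    los = np.empty(n, dtype=np.int64)
    lo_len = min(km, 28)
    hi_len = km - lo_len
    lo_mask = (1 << (2 * lo_len)) - 1
    hi_mask = (1 << (2 * hi_len)) - 1 if hi_len else 0
    lo_shift = 2 * lo_len - 2
    hi = 0
    lo = 0
    w = 0
    idx = 0
    for i in range(codes.shape[0]):
        c = codes[i]
        if c > 3:
            hi = 0
            lo = 0
            w = 0
            continue
        if hi_len:
            hi = ((hi << 2) | (lo >> lo_shift)) & hi_mask
        lo = ((lo << 2) | c) & lo_mask
        w += 1
        if w == km:
            his[idx] = hi
            los[idx] = lo
            idx += 1
            w = 0
            hi = 0
            lo = 0
    return his[:idx], los[:idx]


def pack_kmers(kmers: list[str], km: int):
    """Pack equal-length k-mer strings into (his, los) arrays."""
    if not kmers:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    return _pack_kernel(encode_buffer(kmers), km, len(kmers))


def decode_nodes(his: np.ndarray, los: np.ndarray, length: int) -> list[str]:
    """Decode packed nodes of ``length`` bases (node convention: last
    min(length, 28) bases in ``lo``, remainder in ``hi``)."""
    return decode_kmers(his, los, length)


_EMPTY_CODES = np.empty(0, dtype=np.uint8)


def count_solid_kmers(short_seqs: list[str], long_seqs: list[str],
                      km: int, threshold: int):
    """Count (k+1)-mers of both read sets and apply the solidity rule.

    Returns (his, los, covs) packed arrays.  Caller supplies sequences for
    both strands explicitly (counting is strand-naive).
    """
    if km > 56:
        raise ValueError("k-mers longer than 55 are not supported")
    short_d = _count_kernel(encode_buffer(short_seqs), km)
    long_d = _count_per_read_kernel(
        encode_buffer(long_seqs) if long_seqs else _EMPTY_CODES, km)
    return _solidify_kernel(short_d, long_d, threshold)


def decode_kmers(his: np.ndarray, los: np.ndarray, km: int) -> list[str]:
    """Unpack integer k-mers back into strings (vectorized)."""
    n = len(his)
    if n == 0:
        return []
    lo_len = min(km, 28)
    hi_len = km - lo_len
    out = np.empty((n, km), dtype=np.uint8)
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)
    for j in range(hi_len):
        shift = 2 * (hi_len - 1 - j)
        out[:, j] = chars[(his >> shift) & 3]
    for j in range(lo_len):
        shift = 2 * (lo_len - 1 - j)
        out[:, hi_len + j] = chars[(los >> shift) & 3]
    blob = out.tobytes().decode()
    return [blob[i * km:(i + 1) * km] for i in range(n)]
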