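"""Chunked numeric kernels for large int8 genotype matrices.

Genotype matrices are stored as allele counts in int8. Naive numpy ops would
upcast the whole matrix to float64 at once; these helpers stream over row
blocks to keep peak memory proportional to the block size. Matrix products
run in float32 (per-entry magnitudes are tiny and results feed standardized
statistics, so sgemm precision is ample) and accumulate into float64.
"""

from __future__ import annotations

import numpy as np

try:  # optional single-pass kernels; the numpy path is equivalent
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

# rows per block; 8192 x 5000 float32 is ~160 MB transient at most
_BLOCK = 8192


def chunked_dot(geno: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """``geno @ weights`` for a 1-D or 2-D weight array."""
    n = geno.shape[0]
    w = np.asarray(weights, dtype=np.float32)
    out = np.empty((n,) + w.shape[1:], dtype=np.float64)
    for lo in range(0, n, _BLOCK):
        hi = min(lo + _BLOCK, n)
        out[lo:hi] = geno[lo:hi].astype(np.float32, copy=False) @ w
    return out


def chunked_crossprod(geno: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column cross product ``geno.T @ y`` (one value per SNP)."""
    n, m = geno.shape
    out = np.zeros(m, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    for lo in range(0, n, _BLOCK):
        hi = min(lo + _BLOCK, n)
        out += geno[lo:hi].astype(np.float64, copy=False).T @ yv[lo:hi]
    return out


def column_moments(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP sum and sum of squares, exact integer accumulation."""
    s = geno.sum(axis=0, dtype=np.int64).astype(np.float64)
    # entries are in {0,1,2} so the square fits comfortably in int8
    ss = (geno * geno).sum(axis=0, dtype=np.int64).astype(np.float64)
    return s, ss


if HAVE_NUMBA:

    @numba.njit(cache=False)
    def _binom2_kernel(t2, t12, u, out):  # pragma: no cover - jitted
        n, m = u.shape
        for i in range(n):
            for j in range(m):
                v = np.int32(u[i, j])
                out[i, j] = (1 if v < t2[j] else 0) + \
                    (1 if v < t12[j] else 0)


def binomial2(p: np.ndarray, n_rows: int, rng: np.random.Generator,
              use_numba: bool | None = None) -> np.ndarray:
    """Draw an (n_rows, len(p)) int8 matrix of binomial(2, p_j) counts.

    Uses a single uniform per entry: with thresholds p^2 and 1 - (1-p)^2
    the count 2/1/0 probabilities are p^2, 2p(1-p), (1-p)^2. The uniform is
    a 16-bit integer, which quantizes each probability to the nearest
    1/65536 — far below sampling noise at any simulated scale.
    """
    p = np.asarray(p, dtype=np.float64)
    scale = 65536.0
    t2 = np.rint(p * p * scale).astype(np.int32)          # P(count = 2)
    t12 = np.rint((2.0 * p - p * p) * scale).astype(np.int32)  # P(>= 1)
    m = p.shape[0]
    u = rng.integers(0, 65536, size=(n_rows, m), dtype=np.uint16)
    out = np.empty((n_rows, m), dtype=np.int8)
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba:
        _binom2_kernel(t2, t12, u, out)
        return out
    for lo in range(0, n_rows, _BLOCK):
        hi = min(lo + _BLOCK, n_rows)
        ui = u[lo:hi].astype(np.int32, copy=False)
        # view as int8 before adding: bool + bool is a logical OR in numpy
        np.add((ui < t2).view(np.int8), (ui < t12).view(np.int8),
               out=out[lo:hi])
    return out


if HAVE_NUMBA:

    @numba.njit(cache=False)
    def _mendel_kernel(geno, father_pos, mother_pos, k, bits, children,
                       psum, need_psum):  # pragma: no cover - jitted
        n_couples = father_pos.shape[0]
        m = geno.shape[1]
        for c in range(n_couples):
            fi = father_pos[c]
            mi = mother_pos[c]
            for j in range(k):
                r = c * k + j
                for s in range(m):
                    gf = geno[fi, s]
                    gm = geno[mi, s]
                    b = bits[r, s]
                    children[r, s] = ((gf >> 1) + ((gf & 1) & (b & 1))
                                      + (gm >> 1) + ((gm & 1) & ((b >> 1) & 1)))
                    if need_psum:
                        psum[r, s] = gf + gm


def mendelian_children(geno: np.ndarray, father_pos: np.ndarray,
                       mother_pos: np.ndarray, n_children_per_couple: int,
                       rng: np.random.Generator, need_psum: bool = True,
                       use_numba: bool | None = None,
                       ) -> tuple[np.ndarray, np.ndarray | None]:
    """Sample children's allele counts and the parental genotype sums.

    At every SNP each parent transmits one of their two alleles uniformly
    at random, independently across SNPs and children: a homozygote
    transmits its allele with certainty, a heterozygote transmits a fair
    random bit (two bits of one random byte cover both parents). Children
    of couple c occupy rows ``c * k .. c * k + k - 1`` of the output.
    """
    n_couples = father_pos.shape[0]
    m = geno.shape[1]
    k = n_children_per_couple
    n_children = n_couples * k
    fpos = np.ascontiguousarray(father_pos, dtype=np.int64)
    mpos = np.ascontiguousarray(mother_pos, dtype=np.int64)
    bits = rng.integers(0, 256, size=(n_children, m), dtype=np.uint8)
    children = np.empty((n_children, m), dtype=np.int8)
    psum = np.empty((n_children, m), dtype=np.int8) if need_psum else None
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba:
        dummy = psum if need_psum else children
        _mendel_kernel(geno, fpos, mpos, k, bits, children, dummy,
                       need_psum)
        return children, psum
    block = max(_BLOCK // max(k, 1), 1)
    b8 = bits.view(np.int8)
    for lo in range(0, n_couples, block):
        hi = min(lo + block, n_couples)
        gf = np.repeat(geno[fpos[lo:hi]], k, axis=0)
        gm = np.repeat(geno[mpos[lo:hi]], k, axis=0)
        sl = slice(lo * k, hi * k)
        b = b8[sl]
        tf = (gf >> 1) + ((gf & 1) & (b & 1))
        tm = (gm >> 1) + ((gm & 1) & ((b >> 1) & 1))
        np.add(tf, tm, out=children[sl], casting="unsafe")
        if need_psum:
            np.add(gf, gm, out=psum[sl])
    return children, psum
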