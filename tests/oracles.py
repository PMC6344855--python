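"""Independent brute-force oracles for the scan phases.

These implement the scoring rules as literal loops over every window and
every occurrence, with no rolling state, and are deliberately kept free of
any code shared with the package implementation.
"""

from __future__ import annotations

import numpy as np


def _occurrences(text: str, pattern: str, start: int, end: int) -> list[int]:
    """All occurrence start positions of ``pattern`` in ``text[start:end]``."""
    out = []
    i = text.find(pattern, start, end)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1, end)
    return out


def bruteforce_scores(seq: str, k: int, w: int, ambiguous: str) -> np.ndarray:
    """Literal double-loop cumulative k-mer scorer (phase 1)."""
    L = len(seq)
    w = min(w, L)
    c = np.zeros(L, dtype=np.int64)
    for i in range(L - w + 1):
        kmer = seq[i:i + k]
        if ambiguous in kmer:
            continue
        occ = _occurrences(seq, kmer, i, i + w)
        if len(occ) < 2:
            continue
        n = len(occ)
        for j in range(i, i + k):
            c[j] += n
        for p in occ[1:]:
            for j in range(p, p + k):
                c[j] += 1
    return c


def bruteforce_ppm(seq: str, hrr_start: int, hrr_end: int, k: int, m: int,
                   ambiguous: str) -> tuple[np.ndarray, int]:
    """Literal pair-distance enumerator (phase 2).

    Returns (matrix, region_offset); matrix row index equals pair distance.
    """
    lo = max(0, hrr_start - m)
    hi = min(len(seq), hrr_end + m)
    region = seq[lo:hi]
    R = len(region)
    h = max(min(hrr_end - hrr_start, R), k)
    d_max = R // 2
    matrix = np.zeros((d_max + 1, R), dtype=np.int64)
    for i in range(R - k + 1):
        kmer = region[i:i + k]
        if ambiguous in kmer:
            continue
        window_end = min(i + h, R)
        occ = _occurrences(region, kmer, i, window_end)
        if len(occ) < 2:
            continue
        n = len(occ)
        for idx in range(len(occ) - 1):
            p, q = occ[idx], occ[idx + 1]
            dist = q - p
            if dist > d_max:
                continue
            value = n if idx == 0 else 1
            for col in set(range(p, p + k)) | set(range(q, q + k)):
                matrix[dist, col] += value
    return matrix, lo


def circular_longest_true_run(flags: list[bool]) -> tuple[int, int]:
    """Longest run of True on a ring by trying every start position."""
    n = len(flags)
    best_start, best_len = 0, 0
    for start in range(n):
        length = 0
        while length < n and flags[(start + length) % n]:
            length += 1
        if length > best_len:
            best_start, best_len = start, length
    return best_start, best_len
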