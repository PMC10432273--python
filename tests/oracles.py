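"""Independent brute-force oracles used to cross-check the implementation.

Kept deliberately naive (full-matrix DP, explicit codon table, transitive
closure) and free of any fzkit alignment/clustering code.
"""

from __future__ import annotations

import numpy as np

# standard genetic code, written out explicitly (independent of Biopython)
_T = "TCAG"
_AA = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AA[16 * i + 4 * j + k]
               for i, a in enumerate(_T)
               for j, b in enumerate(_T)
               for k, c in enumerate(_T)}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_oracle(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3].upper()
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frames_oracle(seq: str) -> dict[int, str]:
    seq = seq.upper()
    rc = "".join(_RC.get(b, "N") for b in reversed(seq))
    frames = {}
    for off in range(3):
        frames[off + 1] = translate_oracle(seq[off:])
        frames[-(off + 1)] = translate_oracle(rc[off:])
    return frames


def gotoh_local(a: str, b: str, score_fn, gap_open: float,
                gap_extend: float) -> float:
    """Best local alignment score; a gap of length k costs
    gap_open + (k-1)*gap_extend (matching the package's aligner setup)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + score_fn(ai, b[j - 1]),
                          E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def nt_score(x: str, y: str) -> float:
    return 1.0 if (x == y and x != "N") else -2.0


def aggregate_oracle(hits, max_gap: int) -> list[frozenset]:
    """Transitive closure of 'same contig and interval gap < max_gap'."""
    n = len(hits)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            hi, hj = hits[i], hits[j]
            if hi.contig_id != hj.contig_id:
                continue
            gap = max(hi.start, hj.start) - min(hi.end, hj.end)
            if gap < max_gap:
                adj[i][j] = True
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if seen[k]:
                continue
            seen[k] = True
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and not seen[j])
        comps.append(frozenset(comp))
    return comps
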