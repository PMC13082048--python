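"""Independent affine-gap Smith-Waterman scoring oracle for tests.

Plain Gotoh dynamic programming, written from the recurrences (no reuse of
the package's alignment route).  Gap convention matches the scoring used
throughout: the first gapped position costs ``gap_open`` and every further
position ``gap_extend``.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def gotoh_local_score(
    query: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -0.5,
) -> float:
    """Best local alignment score by explicit Gotoh DP (scalar reference)."""
    m, n = len(query), len(reference)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming reference
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming query
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if query[i - 1] == reference[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def gotoh_local_scores_batch(
    query: str,
    refs: np.ndarray,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -0.5,
) -> np.ndarray:
    """Gotoh local scores of one query against a stack of equal-length
    references (integer-encoded array of shape (n_refs, L)); vectorised over
    the reference axis."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    n_refs, L = refs.shape
    m = q.size
    H = np.zeros((n_refs, L + 1))
    best = np.zeros(n_refs)
    for i in range(1, m + 1):
        H_prev = H
        H = np.zeros((n_refs, L + 1))
        E = np.full(n_refs, NEG)
        F_col = np.full((n_refs, L + 1), NEG)
        # F needs the whole previous row; carry it as a matrix instead
        if i == 1:
            F_prev = np.full((n_refs, L + 1), NEG)
        else:
            F_prev = F_matrix  # noqa: F821  (assigned at the end of the loop)
        F_matrix = np.full((n_refs, L + 1), NEG)
        for j in range(1, L + 1):
            E = np.maximum(H[:, j - 1] + gap_open, E + gap_extend)
            F_matrix[:, j] = np.maximum(
                H_prev[:, j] + gap_open, F_prev[:, j] + gap_extend
            )
            s = np.where(refs[:, j - 1] == q[i - 1], match, mismatch)
            H[:, j] = np.maximum.reduce(
                [np.zeros(n_refs), H_prev[:, j - 1] + s, E, F_matrix[:, j]]
            )
        best = np.maximum(best, H[:, 1:].max(axis=1))
    return best


def enumerate_sequences(alphabet: str, max_len: int) -> list[str]:
    """All non-empty sequences over ``alphabet`` up to ``max_len``."""
    out: list[str] = []
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + c for s in frontier for c in alphabet]
        out.extend(frontier)
    return out


def encode(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into a uint8 array."""
    return np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
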