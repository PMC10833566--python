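"""Independent oracles used by the test suite.

Each function here recomputes a quantity by brute force or closed form,
deliberately sharing no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_scan(matrix: np.ndarray, sequence: str, both_strands: bool = True):
    """Enumerate every window (and strand) and return (score, start, strand).

    Ties: highest score, then leftmost start, then forward strand.  N bases
    contribute 0.
    """
    L = matrix.shape[0]
    idx = {b: i for i, b in enumerate(BASES)}

    def win_score(s: str) -> float:
        total = 0.0
        for j, c in enumerate(s):
            if c != "N":
                total += matrix[j, idx[c]]
        return total

    best = None
    for start in range(len(sequence) - L + 1):
        w = sequence[start : start + L]
        cands = [(win_score(w), start, 0)]
        if both_strands:
            cands.append((win_score(rc(w)), start, 1))
        for score, st, strand in cands:
            key = (score, -st, -strand)
            if best is None or key > best[0]:
                best = (key, score, st, strand)
    return best[1], best[2], ("forward" if best[3] == 0 else "reverse")


def pair_count_auroc(scores, labels) -> float:
    """AUROC by exhaustive pair counting with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def unrolled_shape_vector(sequence: str, lut: dict, parameter_is_intra: bool):
    """Hand-unrolled sliding-pentamer profile with explicit two-term averages."""
    L = len(sequence)
    pent = [lut[sequence[p : p + 5]] for p in range(L - 4)]
    if parameter_is_intra:
        return np.array(pent)
    values = []
    for step in range(1, L - 2):  # covered steps
        contribs = []
        for p in (step - 2, step - 1):
            if 0 <= p <= L - 5:
                contribs.append(pent[p])
        values.append(sum(contribs) / len(contribs))
    return np.array(values)


def closed_form_lda(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm pooled-covariance discriminant direction Sigma^-1 (mu1 - mu0)."""
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    d0 = X[y == 0] - mu0
    d1 = X[y == 1] - mu1
    sw = (d0.T @ d0 + d1.T @ d1) / (len(y) - 2)
    w = np.linalg.solve(sw, mu1 - mu0)
    w = w / np.linalg.norm(w)
    if w @ mu1 < w @ mu0:
        w = -w
    return w


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))
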