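"""Independent oracles and fixture builders shared across the test suite.

The oracles deliberately use the dumbest correct algorithm (per-base
expansion, full enumeration, dense grid search) so they stay independent of
the implementation paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

from endofilter.io import ReadAlignment

BASES = "ACGT"


# ---------------------------------------------------------------------------
# CIGAR offset oracle


def offset_oracle(read: ReadAlignment, ref_pos: int):
    """Expand the alignment into explicit (ref, query) pairs and look up."""
    pairs, deleted = {}, set()
    q, r = 0, read.ref_start
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                pairs[r + i] = q + i
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            deleted.update(range(r, r + n))
            r += n
    if ref_pos in pairs:
        return pairs[ref_pos]
    if ref_pos in deleted:
        return None
    raise ValueError(f"{ref_pos} outside aligned span")


def random_read(rng: np.random.Generator, ref_start: int | None = None) -> ReadAlignment:
    """A structurally valid read with a fuzzed CIGAR (clips, indels, skips)."""
    ops: list[tuple[str, int]] = []
    if rng.random() < 0.2:
        ops.append(("H", int(rng.integers(1, 6))))
    if rng.random() < 0.3:
        ops.append(("S", int(rng.integers(1, 9))))
    n_blocks = int(rng.integers(1, 6))
    for i in range(n_blocks):
        m_op = "M" if rng.random() < 0.7 else ("=" if rng.random() < 0.5 else "X")
        ops.append((m_op, int(rng.integers(1, 13))))
        if i < n_blocks - 1:
            ops.append((str(rng.choice(["I", "D", "N"])), int(rng.integers(1, 7))))
    if rng.random() < 0.3:
        ops.append(("S", int(rng.integers(1, 9))))
    if rng.random() < 0.2:
        ops.append(("H", int(rng.integers(1, 6))))
    qlen = sum(n for op, n in ops if op in "MIS=X")
    seq = "".join(rng.choice(list(BASES), size=qlen))
    start = int(rng.integers(0, 500)) if ref_start is None else ref_start
    return ReadAlignment(seq, start, tuple(ops))


# ---------------------------------------------------------------------------
# KS permutation oracle


def _ks_D_fraction(x, y) -> Fraction:
    n1, n2 = len(x), len(y)
    values = sorted(set(x) | set(y))
    best = Fraction(0)
    for v in values:
        f1 = Fraction(sum(1 for a in x if a <= v), n1)
        f2 = Fraction(sum(1 for b in y if b <= v), n2)
        best = max(best, abs(f1 - f2))
    return best


def ks_permutation_oracle(x, y) -> float:
    """P(D* >= D_obs) by enumerating every label assignment of the pooled
    sample, with exact rational arithmetic."""
    pooled = list(x) + list(y)
    n1 = len(x)
    d_obs = _ks_D_fraction(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if _ks_D_fraction(xs, ys) >= d_obs:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# palindrome arm oracle


def arm_oracle(seq: str, mode: str = "revcomp", max_arm: int | None = None) -> int:
    """Largest k verified by explicitly testing every k."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    c = len(seq) // 2
    limit = c if max_arm is None else min(max_arm, c)
    best = 0
    for k in range(1, limit + 1):
        ok = True
        for i in range(1, k + 1):
            l, r = seq[c - i], seq[c + i]
            if l not in comp or r not in comp:
                ok = False
                break
            if mode == "revcomp" and comp[l] != r:
                ok = False
                break
            if mode == "mirror" and l != r:
                ok = False
                break
        if ok:
            best = k
    return best


# ---------------------------------------------------------------------------
# threshold sweep oracle


def threshold_sweep_oracle(probs, y):
    """Best (sens+spec, t) by brute force over every distinct probability,
    ties to the largest threshold."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    results = []
    for t in np.unique(probs):
        pred = probs >= t
        sens = pred[y == 1].mean()
        spec = (~pred)[y == 0].mean()
        results.append((sens + spec, t))
    best_j = max(j for j, _ in results)
    best_t = max(t for j, t in results if abs(j - best_j) <= 1e-12)
    return best_j, best_t


# ---------------------------------------------------------------------------
# simplex grid oracle


def simplex_grid_min(P: np.ndarray, f: np.ndarray, step: float = 0.001):
    """Dense grid search over the 2-simplex (3 signatures) for the least-squares
    refit objective; returns (best objective, best w)."""
    assert P.shape[1] == 3
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best_obj, best_w = np.inf, None
    chunk = []
    for w1 in ticks:
        w2s = ticks[ticks <= 1.0 - w1 + step / 2]
        W = np.column_stack([np.full(len(w2s), w1), w2s, 1.0 - w1 - w2s])
        W[:, 2] = np.clip(W[:, 2], 0.0, None)
        R = P @ W.T - f[:, None]
        objs = (R * R).sum(axis=0)
        i = int(np.argmin(objs))
        if objs[i] < best_obj:
            best_obj, best_w = float(objs[i]), W[i]
    return best_obj, best_w
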