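"""Per-variant read-level evidence.

Three features drive artifact detection downstream: the in-read offset of the
variant on every covering read (obtained by walking the CIGAR), a two-sample
Kolmogorov-Smirnov test for positional bias of variant-supporting versus
wildtype-supporting reads, and the fraction of variant-supporting reads that
carry a soft clip.

The KS p-value is computed exactly (conditional on the pooled offsets, i.e.
the label-permutation null, which remains exact under ties) whenever
``n_alt * n_ref`` is small, and by the asymptotic two-sided distribution
otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .io import ReadAlignment, VariantCall

Transform = Literal["raw_offset", "distance_to_nearest_end"]

#: Above this product of sample sizes the asymptotic KS distribution is used.
EXACT_KS_LIMIT = 10_000


class UncallableVariantError(ValueError):
    """No variant-supporting reads cover the site in this alignment file."""


@dataclass
class VariantReadEvidence:
    """Offsets and soft-clip counts for one variant.

    Offsets are 0-based query positions of the variant (anchor) base, in query
    orientation; parallel lists record each read's length so the
    distance-to-nearest-end transform can fold per read.
    """

    variant: VariantCall
    alt_offsets: list[int] = field(default_factory=list)
    ref_offsets: list[int] = field(default_factory=list)
    alt_read_lens: list[int] = field(default_factory=list)
    ref_read_lens: list[int] = field(default_factory=list)
    n_alt_softclipped: int = 0

    @property
    def n_alt(self) -> int:
        return len(self.alt_offsets)

    @property
    def n_ref(self) -> int:
        return len(self.ref_offsets)

    @property
    def read_len(self) -> int:
        """Nominal read length: the maximum seen."""
        lens = self.alt_read_lens + self.ref_read_lens
        return max(lens) if lens else 0


@dataclass(frozen=True)
class PositionalBiasResult:
    ks_p: float
    ks_D: float
    evaluable: bool
    n_alt: int = 0
    n_ref: int = 0


# ---------------------------------------------------------------------------
# CIGAR walking


def query_offset(read: ReadAlignment, ref_pos_0based: int) -> int | None:
    """Query index aligned to a reference position, or None inside a deletion.

    Walks the CIGAR left to right keeping a (query, reference) cursor pair:
    M/=/X advance both, I and S advance the query only, D and N advance the
    reference only, H advances neither.
    """
    if ref_pos_0based < read.ref_start:
        raise ValueError(
            f"position {ref_pos_0based} before aligned span starting {read.ref_start}"
        )
    q, r = 0, read.ref_start
    for op, n in read.cigar:
        if op in "M=X":
            if r <= ref_pos_0based < r + n:
                return q + (ref_pos_0based - r)
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            if r <= ref_pos_0based < r + n:
                return None
            r += n
        # H, P: no cursor movement
    raise ValueError(f"position {ref_pos_0based} beyond aligned span ending {r}")


def _op_after_anchor(read: ReadAlignment, ref_pos_0based: int) -> tuple[int | None, str | None, int]:
    """(query offset of anchor, CIGAR op immediately after the anchor, its length).

    The "op after" is the op that starts exactly one base past the anchor in
    the walk — the op an inserted or deleted segment would occupy.
    """
    q, r = 0, read.ref_start
    cig = read.cigar
    for i, (op, n) in enumerate(cig):
        if op in "M=X":
            if r <= ref_pos_0based < r + n:
                off = q + (ref_pos_0based - r)
                if ref_pos_0based == r + n - 1 and i + 1 < len(cig):
                    nxt_op, nxt_n = cig[i + 1]
                    return off, nxt_op, nxt_n
                return off, op, n  # next base continues inside the same match block
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            if r <= ref_pos_0based < r + n:
                return None, None, 0
            r += n
    return None, None, 0


def classify_read_allele(read: ReadAlignment, variant: VariantCall) -> str:
    """``"alt"``, ``"ref"`` or ``"other"`` for one covering read.

    SNV: compare the query base at the variant's query offset. Insertion: alt
    iff an I op of the inserted length immediately follows the anchor base;
    deletion: alt iff a D op of the deleted length immediately follows the
    anchor. Reads where the anchor falls in a deletion are "other".
    """
    pos0 = variant.pos0
    if variant.vtype == "SNV":
        off = query_offset(read, pos0)
        if off is None:
            return "other"
        base = read.query_seq[off].upper()
        if base == variant.alt:
            return "alt"
        if base == variant.ref:
            return "ref"
        return "other"

    off, nxt_op, nxt_n = _op_after_anchor(read, pos0)
    if off is None:
        return "other"
    if variant.vtype == "insertion":
        ins_len = len(variant.alt) - len(variant.ref)
        if nxt_op == "I" and nxt_n == ins_len:
            return "alt"
        return "ref" if nxt_op in "M=X" else "other"
    # deletion
    del_len = len(variant.ref) - len(variant.alt)
    if nxt_op == "D" and nxt_n == del_len:
        return "alt"
    return "ref" if nxt_op in "M=X" else "other"


def collect_evidence(
    reads: Sequence[ReadAlignment], variant: VariantCall, *, min_clip: int = 1
) -> VariantReadEvidence:
    """Aggregate offsets and soft-clip counts over the covering reads.

    Raises :class:`UncallableVariantError` when no read supports the alternate
    allele (the variant cannot be assessed in this alignment file).
    """
    ev = VariantReadEvidence(variant)
    for read in reads:
        allele = classify_read_allele(read, variant)
        if allele == "other":
            continue
        off = query_offset(read, variant.pos0)
        if off is None:
            continue
        if allele == "alt":
            ev.alt_offsets.append(off)
            ev.alt_read_lens.append(read.read_len)
            if read.has_soft_clip(min_clip):
                ev.n_alt_softclipped += 1
        else:
            ev.ref_offsets.append(off)
            ev.ref_read_lens.append(read.read_len)
    if ev.n_alt == 0:
        raise UncallableVariantError(
            f"no alt-supporting reads for {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}"
        )
    return ev


# ---------------------------------------------------------------------------
# positional bias (two-sample KS)


def _transform_offsets(offsets: Sequence[int], read_lens: Sequence[int], transform: Transform):
    if transform == "raw_offset":
        return list(offsets)
    if transform == "distance_to_nearest_end":
        return [min(o, L - 1 - o) for o, L in zip(offsets, read_lens)]
    raise ValueError(f"unknown transform {transform!r}")


def _ks_D_int(x: Sequence[float], y: Sequence[float]) -> tuple[int, list[tuple[int, int]]]:
    """Integer-scaled KS statistic and tie-group counts.

    D = D_int / (n_x * n_y) where D_int = max over pooled values of
    |cum_x * n_y - cum_y * n_x|. Exact under ties (the ECDF difference is
    evaluated at tie-group boundaries).
    """
    n1, n2 = len(x), len(y)
    cx, cy = Counter(x), Counter(y)
    groups = [(cx[v], cy[v]) for v in sorted(set(x) | set(y))]
    d = a = r = 0
    for ga, gr in groups:
        a += ga
        r += gr
        d = max(d, abs(a * n2 - r * n1))
    return d, groups


def exact_ks_permutation_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided KS p-value under the label-permutation null.

    Counts, by dynamic programming over tie groups with exact integer
    arithmetic, the number of re-labelings of the pooled sample whose KS
    statistic is at least the observed one; equals full enumeration of all
    C(n1+n2, n1) label assignments.
    """
    n1, n2 = len(x), len(y)
    d_obs, groups = _ks_D_int(x, y)
    if d_obs == 0:
        return 1.0
    # count labelings with max statistic STRICTLY below d_obs
    ways: dict[int, int] = {0: 1}
    cum = 0
    for ga, gr in groups:
        m = ga + gr
        cum += m
        new: dict[int, int] = {}
        for a0, w in ways.items():
            for k in range(m + 1):
                a = a0 + k
                if a > n1 or cum - a > n2:
                    continue
                if abs(a * n2 - (cum - a) * n1) >= d_obs:
                    continue
                new[a] = new.get(a, 0) + w * comb(m, k)
        ways = new
    strict = ways.get(n1, 0)
    total = comb(n1 + n2, n1)
    return float(1 - Fraction(strict, total))


def positional_bias(
    evidence: VariantReadEvidence,
    transform: Transform = "distance_to_nearest_end",
    *,
    min_n: int = 3,
    exact_limit: int = EXACT_KS_LIMIT,
) -> PositionalBiasResult:
    """Two-sample two-sided KS test of alt vs ref in-read positions.

    When either sample has fewer than ``min_n`` observations the variant is
    not evaluable and p = 1 by convention (no evidence of bias). The default
    transform folds offsets to the distance from the nearest read end, because
    the fragmentation artifact concentrates near either edge symmetrically.
    """
    xa = _transform_offsets(evidence.alt_offsets, evidence.alt_read_lens, transform)
    xr = _transform_offsets(evidence.ref_offsets, evidence.ref_read_lens, transform)
    n1, n2 = len(xa), len(xr)
    if min(n1, n2) < min_n:
        return PositionalBiasResult(1.0, 0.0, False, n1, n2)
    d_int, _ = _ks_D_int(xa, xr)
    d = d_int / (n1 * n2)
    if n1 * n2 <= exact_limit:
        p = exact_ks_permutation_pvalue(xa, xr)
    else:
        p = float(stats.ks_2samp(xa, xr, alternative="two-sided", method="asymp").pvalue)
    return PositionalBiasResult(min(p, 1.0), d, True, n1, n2)


def soft_clip_ratio(evidence: VariantReadEvidence) -> float:
    """Fraction of alt-supporting reads bearing a soft clip."""
    if evidence.n_alt == 0:
        raise UncallableVariantError("soft_clip_ratio undefined with no alt reads")
    return evidence.n_alt_softclipped / evidence.n_alt


def offset_histogram(
    evidence: VariantReadEvidence, bin_width: int = 5, transform: Transform = "raw_offset"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts of alt and ref offsets in consecutive ``bin_width``-base bins.

    Returns (bin_edges, alt_counts, ref_counts); edges span the nominal read
    length.
    """
    read_len = max(evidence.read_len, bin_width)
    edges = np.arange(0, read_len + bin_width, bin_width)
    xa = _transform_offsets(evidence.alt_offsets, evidence.alt_read_lens, transform)
    xr = _transform_offsets(evidence.ref_offsets, evidence.ref_read_lens, transform)
    alt_counts, _ = np.histogram(xa, bins=edges)
    ref_counts, _ = np.histogram(xr, bins=edges)
    return edges, alt_counts, ref_counts
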