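"""SNV-centered palindrome (SCP) detection.

An SCP is the maximal odd-length palindromic reference context centered on a
variant: the k bases 3' of the variant are the reverse complement of the k
bases 5' of it, with the variant base itself free at the center (a hairpin
with the variant in the loop). Reported length is 2k+1; contexts whose
maximal arm is shorter than ``min_arm`` are reported as length 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .evidence import query_offset
from .io import ReadAlignment, ReferenceWindow, VariantCall, fetch_reference_window

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

Mode = Literal["revcomp", "mirror"]

DEFAULT_MIN_ARM = 2
DEFAULT_MAX_ARM = 20


@dataclass(frozen=True)
class ScpResult:
    variant: VariantCall | None
    arm_len: int
    scp_len: int
    arm_seq: str
    mode: Mode


def scp_length(
    window: ReferenceWindow,
    mode: Mode = "revcomp",
    min_arm: int = DEFAULT_MIN_ARM,
    max_arm: int | None = None,
    variant: VariantCall | None = None,
) -> ScpResult:
    """Maximal palindromic arm around the window center.

    ``arm_len`` is the largest k such that for every i in 1..k the base at
    center-i pairs with the base at center+i (complementary in revcomp mode,
    equal in mirror mode). Any N stops extension; the center base is ignored.
    """
    seq = window.seq.upper()
    if len(seq) % 2 == 0:
        raise ValueError("window must have odd length (centered on the variant base)")
    c = len(seq) // 2
    limit = c if max_arm is None else min(max_arm, c)
    k = 0
    for i in range(1, limit + 1):
        left, right = seq[c - i], seq[c + i]
        if left not in _COMP or right not in _COMP:
            break
        if mode == "revcomp":
            if _COMP[left] != right:
                break
        elif mode == "mirror":
            if left != right:
                break
        else:
            raise ValueError(f"unknown mode {mode!r}")
        k = i
    scp_len = 2 * k + 1 if k >= min_arm else 0
    return ScpResult(variant, k, scp_len, seq[c - k : c], mode)


def scp_for_variant(
    variant: VariantCall,
    fasta: str | Path,
    mode: Mode = "revcomp",
    min_arm: int = DEFAULT_MIN_ARM,
    max_arm: int = DEFAULT_MAX_ARM,
) -> ScpResult:
    """SCP of one call; indels are length 0 by contract (SCPs are SNV-centered)."""
    if variant.vtype != "SNV":
        return ScpResult(variant, 0, 0, "", mode)
    window = fetch_reference_window(fasta, variant.chrom, variant.pos, max_arm)
    return scp_length(window, mode=mode, min_arm=min_arm, max_arm=max_arm, variant=variant)


def scp_spectrum(
    variants: Iterable[VariantCall],
    fasta: str | Path,
    mode: Mode = "revcomp",
    min_arm: int = DEFAULT_MIN_ARM,
    max_arm: int = DEFAULT_MAX_ARM,
) -> dict[int, int]:
    """Histogram of SCP lengths (0, 5, 7, 9, ...); counts sum to the input size."""
    counts: Counter[int] = Counter()
    for v in variants:
        counts[scp_for_variant(v, fasta, mode, min_arm, max_arm).scp_len] += 1
    return dict(counts)


def scp_read_nesting(
    reads: Sequence[ReadAlignment],
    variant: VariantCall,
    scp: ScpResult,
    margin: int = 30,
) -> float:
    """Fraction of alt reads whose full palindrome span sits within ``margin``
    bases of a read edge.

    For each alt-supporting read the in-read span of the palindrome
    [center-k, center+k] is located via the CIGAR; reads in which the span is
    not fully aligned (an end falls in a deletion or off the aligned span) are
    excluded from the denominator.
    """
    from .evidence import classify_read_allele

    if scp.scp_len <= 0:
        raise ValueError("scp_read_nesting requires scp_len > 0")
    k = scp.arm_len
    pos0 = variant.pos0
    nested = evaluable = 0
    for read in reads:
        if classify_read_allele(read, variant) != "alt":
            continue
        try:
            o5 = query_offset(read, pos0 - k)
            o3 = query_offset(read, pos0 + k)
        except ValueError:
            continue  # span extends past the aligned portion
        if o5 is None or o3 is None:
            continue
        evaluable += 1
        L = read.read_len
        if o3 < margin or o5 > L - 1 - margin:
            nested += 1
    return nested / evaluable if evaluable else float("nan")


def scp_recurrence_table(scps_by_sample: Mapping[str, Sequence[ScpResult]]) -> pd.DataFrame:
    """Distinct palindromes (by reference arm sequence and length) counted once
    versus recurrently across samples.

    Returns one row per (scp_len, arm_seq) with the number of samples it was
    seen in; only reportable SCPs (scp_len > 0) are tabulated. The reference
    arm sequence identifies the palindrome, so the same hairpin hit in several
    samples collapses to one row.
    """
    seen: dict[tuple[int, str], set[str]] = {}
    for sample, scps in scps_by_sample.items():
        for s in scps:
            if s.scp_len > 0:
                seen.setdefault((s.scp_len, s.arm_seq), set()).add(sample)
    rows = [
        {"scp_len": ln, "arm_seq": arm, "n_samples": len(samples), "recurrent": len(samples) > 1}
        for (ln, arm), samples in sorted(seen.items())
    ]
    return pd.DataFrame(rows, columns=["scp_len", "arm_seq", "n_samples", "recurrent"])
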