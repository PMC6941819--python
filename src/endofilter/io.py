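"""Readers and writers for the formats the filtering pipeline touches.

Variant call tables (VCF or 5-column TSV), aligned reads (SAM/BAM), reference
FASTA windows, genuine-variant whitelists and signature-probability matrices
are converted into a small internal data model with fixed coordinate
conventions:

* ``VariantCall.pos`` is 1-based, as printed in VCF/TSV.
* ``ReadAlignment.ref_start`` and ``ReferenceWindow.start`` are 0-based, as in
  BAM; positions are converted once on input and once on output, so all CIGAR
  arithmetic happens in 0-based space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: CIGAR operations that consume query bases.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("MDN=X")

_CIGAR_CODES = "MIDNSHP=X"  # pysam integer op codes, in order


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedInputError(ValueError):
    """A record in an input file violates the format contract."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV or indel.

    The identity key used throughout the pipeline (recurrence counting,
    whitelist matching) is the 4-tuple ``(chrom, pos, ref, alt)`` — identical
    genomic coordinate and altered nucleotides.
    """

    chrom: str
    pos: int  # 1-based; for indels the leftmost anchor base, as in VCF
    ref: str
    alt: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise MalformedInputError("ref and alt must be non-empty")
        if set(self.ref) - VALID_BASES or set(self.alt) - VALID_BASES:
            raise MalformedInputError(
                f"alleles must be over ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise MalformedInputError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise MalformedInputError(f"pos must be >= 1, got {self.pos}")

    @property
    def vtype(self) -> str:
        """``"SNV"``, ``"insertion"`` or ``"deletion"``."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based position of the variant (anchor) base."""
        return self.pos - 1


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read: sequence, 0-based mapped start, and CIGAR.

    The CIGAR is an ordered list of ``(op, length)`` with op one of
    M/I/D/N/S/H/=/X. Invariants checked on construction: query-consuming op
    lengths sum to the query length, soft clips only at the ends (inside any
    hard clips), all lengths positive.
    """

    query_seq: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    is_mapped: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cigar", tuple((op, int(n)) for op, n in self.cigar))
        qlen = 0
        for op, n in self.cigar:
            if op not in "MIDNSHP=X":
                raise MalformedInputError(f"unknown CIGAR op {op!r}")
            if n <= 0:
                raise MalformedInputError("CIGAR lengths must be positive")
            if op in QUERY_OPS:
                qlen += n
        if self.is_mapped and qlen != len(self.query_seq):
            raise MalformedInputError(
                f"CIGAR consumes {qlen} query bases but read has {len(self.query_seq)}"
            )
        inner = [op for op, _ in self.cigar if op != "H"]
        for i, op in enumerate(inner):
            if op == "S" and i not in (0, len(inner) - 1):
                raise MalformedInputError("soft clip not at read end")

    @property
    def read_len(self) -> int:
        return len(self.query_seq)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_OPS)

    def has_soft_clip(self, min_clip: int = 1) -> bool:
        return any(op == "S" and n >= min_clip for op, n in self.cigar)

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "ReadAlignment":
        cigar = tuple((_CIGAR_CODES[op], n) for op, n in (rec.cigartuples or ()))
        return cls(
            query_seq=rec.query_sequence or "",
            ref_start=rec.reference_start,
            cigar=cigar,
            is_mapped=not rec.is_unmapped,
            name=rec.query_name or "",
        )


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence, 0-based inclusive start, uppercased."""

    chrom: str
    start: int
    seq: str
    truncated: bool = False  # True when the window ran off a contig end (N-padded)

    @property
    def center(self) -> int:
        return len(self.seq) // 2


@dataclass
class SignatureMatrix:
    """96-class substitution-probability profiles for K signatures.

    ``profiles`` is a (96, K) array; each column is nonnegative and sums to 1.
    ``contexts`` are the 96 labels in the canonical order produced by
    :func:`endofilter.signatures.sbs96_contexts`.
    """

    contexts: list[str]
    names: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if len(self.contexts) != 96 or self.profiles.shape[0] != 96:
            raise MalformedInputError("signature matrix must have exactly 96 context rows")
        if len(set(self.contexts)) != 96:
            raise MalformedInputError("context labels must be unique")
        if self.profiles.shape[1] != len(self.names):
            raise MalformedInputError("profile columns must match signature names")
        if (self.profiles < -1e-12).any():
            raise MalformedInputError("signature probabilities must be nonnegative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise MalformedInputError(f"signature profiles must sum to 1, got {sums}")

    @property
    def n_signatures(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# variant call tables


def _parse_tsv_calls(path: Path, sample_id: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise MalformedInputError(
                    f"{path}:{lineno}: expected >=4 columns (chrom pos ref alt), got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise MalformedInputError(f"{path}:{lineno}: non-integer position {pos_s!r}") from exc
            try:
                calls.append(VariantCall(chrom, pos, ref.upper(), alt.upper(), sample_id))
            except MalformedInputError as exc:
                raise MalformedInputError(f"{path}:{lineno}: {exc}") from exc
    return calls


def _parse_vcf_calls(path: Path, sample_id: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None or set(alt.upper()) - VALID_BASES:
                    continue  # symbolic / spanning-deletion alleles are not point calls
                calls.append(
                    VariantCall(rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), sample_id)
                )
    return calls


def read_variant_calls(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read a per-sample somatic call table (VCF, or TSV: chrom pos ref alt [type]).

    Multi-allelic VCF rows are split into one call per alternate allele;
    positions stay 1-based. An empty file yields an empty list with a logged
    warning; a malformed row raises :class:`MalformedInputError` naming the
    line.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        calls = _parse_vcf_calls(path, sample_id)
    else:
        with open(path) as fh:
            head = fh.read(16)
        if head.startswith("##fileformat=VCF"):
            calls = _parse_vcf_calls(path, sample_id)
        else:
            calls = _parse_tsv_calls(path, sample_id)
    if not calls:
        logger.warning("no variant calls parsed from %s", path)
    return calls


def write_variant_calls(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as the 5-column TSV accepted back by :func:`read_variant_calls`."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\ttype\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.vtype}\n")


# ---------------------------------------------------------------------------
# aligned reads


def fetch_reads_at(
    path: str | Path,
    chrom: str,
    pos_1based: int,
    *,
    min_mapq: int = 0,
    keep_duplicates: bool = False,
) -> list[ReadAlignment]:
    """Mapped, primary, non-duplicate reads whose aligned span covers a position.

    Coverage means the reference-consuming CIGAR span contains ``pos``;
    soft/hard clipped overlap does not count. BAM requires an index; plain SAM
    is scanned linearly (fine for the synthetic fixtures this package tests
    with).
    """
    path = Path(path)
    pos0 = pos_1based - 1
    out: list[ReadAlignment] = []
    is_sam = path.suffix == ".sam"
    mode = "r" if is_sam else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        if chrom not in af.references:
            raise MalformedInputError(f"contig {chrom!r} not in header of {path}")
        if is_sam:
            it = af.fetch(until_eof=True)
        else:
            try:
                it = af.fetch(chrom, pos0, pos0 + 1)
            except ValueError as exc:
                raise MalformedInputError(f"{path}: missing index ({exc})") from exc
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate and not keep_duplicates:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if is_sam and (rec.reference_name != chrom):
                continue
            if not (rec.reference_start <= pos0 < rec.reference_end):
                continue
            out.append(ReadAlignment.from_pysam(rec))
    return out


# ---------------------------------------------------------------------------
# reference


def fetch_reference_window(
    fasta: str | Path, chrom: str, center_pos_1based: int, flank: int
) -> ReferenceWindow:
    """A window of ``2*flank + 1`` reference bases centered on a variant base.

    Windows that run past a contig end are padded with N and flagged
    ``truncated``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    with pysam.FastaFile(str(fasta)) as fa:
        if chrom not in fa.references:
            raise MalformedInputError(f"contig {chrom!r} not in {fasta}")
        clen = fa.get_reference_length(chrom)
        center0 = center_pos_1based - 1
        lo, hi = center0 - flank, center0 + flank + 1
        seq = fa.fetch(chrom, max(lo, 0), min(hi, clen)).upper()
    left_pad = max(0, -lo)
    right_pad = max(0, hi - clen)
    if left_pad or right_pad:
        seq = "N" * left_pad + seq + "N" * right_pad
    return ReferenceWindow(chrom, lo, seq, truncated=bool(left_pad or right_pad))


# ---------------------------------------------------------------------------
# whitelist and signature matrix


def read_whitelist(path: str | Path) -> frozenset[tuple[str, int, str, str]]:
    """Known-genuine variant keys (chrom, pos, ref, alt) from a TSV."""
    keys = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise MalformedInputError(f"{path}:{lineno}: expected 4 columns")
            chrom, pos_s, ref, alt = fields[:4]
            keys.add((chrom, int(pos_s), ref.upper(), alt.upper()))
    return frozenset(keys)


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Signature matrix TSV: header of signature names, first column of 96
    context labels (``A[C>A]A`` style). Rows may come in any order; they are
    reindexed to the canonical SBS96 order."""
    from .signatures import sbs96_contexts

    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    canonical = sbs96_contexts()
    missing = set(canonical) - set(df.index)
    if missing:
        raise MalformedInputError(f"{path}: missing contexts, e.g. {sorted(missing)[:3]}")
    df = df.loc[canonical]
    return SignatureMatrix(canonical, list(df.columns), df.to_numpy(dtype=float))


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.profiles, index=matrix.contexts, columns=matrix.names).to_csv(
        path, sep="\t", index_label="context"
    )


def write_fasta(path: str | Path, records: dict[str, str], line_width: int = 60) -> None:
    """Write contigs to FASTA and create the .fai index."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    pysam.faidx(str(path))
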