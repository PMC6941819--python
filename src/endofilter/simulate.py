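"""Synthetic test bed for the whole pipeline.

Emulates the conditions under which endonuclease-fragmentation artifacts
arise: a reference with embedded hairpin palindromes; aligned reads carrying
artifact SNVs at palindrome centers 10-15 bases from a read edge with
elevated soft clipping; genuine SNVs at uniform in-read positions; per-sample
call tables whose artifact sites recur across the cohort; and 96-class
mutation spectra drawn from known signature mixtures. Every downstream module
is testable against the recorded ground truth without any external download.

All randomness flows from a single integer seed through numpy Generators, so
output is byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .io import SignatureMatrix, VariantCall, write_fasta, write_variant_calls
from .signatures import BASES, SUBSTITUTIONS, _context_index, sbs96_contexts

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Knobs of the simulator; defaults mirror the magnitudes the artifact
    shows in enzymatically fragmented libraries (offsets 10-15 bases from a
    read edge, ~50% vs ~5% soft-clip rates, 100-base reads)."""

    seed: int = 0
    chrom: str = "chr1"
    ref_len: int = 200_000
    n_palindromes: int = 300
    scp_len_min: int = 5  # odd total palindrome lengths, arms 2k+1
    scp_len_max: int = 21
    n_samples: int = 3
    n_artifact: int = 200  # shared artifact site pool size
    n_genuine: int = 50  # private genuine variants per sample
    artifact_edge_window: tuple[int, int] = (10, 15)
    artifact_softclip_prob: float = 0.5
    genuine_softclip_prob: float = 0.05
    artifact_recurrence_prob: float = 0.9  # chance each sample carries a pooled artifact site
    read_len: int = 100
    depth: int = 50
    vaf: float = 0.5
    seq_error_rate: float = 0.001
    noise_mixture: tuple[float, ...] = (0.9, 0.0, 0.1)
    genuine_mixture: tuple[float, ...] = (0.0, 0.7, 0.3)

    def __post_init__(self) -> None:
        for p in (
            self.artifact_softclip_prob,
            self.genuine_softclip_prob,
            self.artifact_recurrence_prob,
            self.vaf,
            self.seq_error_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.scp_len_min % 2 == 0 or self.scp_len_max % 2 == 0 or self.scp_len_min < 5:
            raise ValueError("SCP lengths must be odd and >= 5 (arms 2k+1, k >= 2)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_palindromes < self.n_artifact:
            raise ValueError("need at least as many palindromes as artifact sites")
        lo, hi = self.artifact_edge_window
        if not (0 < lo <= hi < self.read_len // 2):
            raise ValueError("artifact edge window must fit in half a read")


@dataclass
class SimulatedCohort:
    """Everything one simulation produced, with paths to the on-disk files."""

    config: SimulationConfig
    fasta: Path
    registry: pd.DataFrame  # palindrome centers (0-based) and arm lengths
    bam_paths: list[Path]
    call_table_paths: list[Path]
    call_tables: list[list[VariantCall]]
    truth: pd.DataFrame  # sample_id, chrom, pos, ref, alt, label, arm
    sample_ids: list[str]


def default_signature_matrix() -> SignatureMatrix:
    """Three synthetic profiles: an artifact-like "noise" signature spread over
    C>A and T>G classes, a "genuine" signature over C>T, and a flat background.
    Full column rank, so mixtures are identifiable."""
    contexts = sbs96_contexts()
    K = 3
    profiles = np.zeros((96, K))
    for i, c in enumerate(contexts):
        sub = c[2:5]
        if sub in ("C>A", "T>G"):
            profiles[i, 0] = 1.0
        if sub == "C>T":
            profiles[i, 1] = 1.0
        profiles[i, 2] = 1.0
    profiles /= profiles.sum(axis=0)
    return SignatureMatrix(contexts, ["SigNoise", "SigGenuine", "SigFlat"], profiles)


# ---------------------------------------------------------------------------
# reference


def simulate_reference(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, pd.DataFrame]:
    """Uniform-random reference with non-overlapping hairpin insertions.

    Each hairpin is written as (arm, free center base, reverse-complement
    arm); the registry records 0-based centers and constructed arm lengths.
    Writes ``reference.fa`` (+ .fai) under ``out_dir``.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq = rng.choice(list(BASES), size=config.ref_len)

    arms = [(L - 1) // 2 for L in range(config.scp_len_min, config.scp_len_max + 1, 2)]
    max_arm = max(arms)
    margin = config.read_len + max_arm + 5
    if config.ref_len < 2 * margin + config.n_palindromes * (2 * max_arm + 20):
        raise ValueError("palindromes do not fit in ref_len")

    centers: list[int] = []
    ks: list[int] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < config.n_palindromes:
        attempts += 1
        if attempts > 100 * config.n_palindromes:
            raise ValueError("palindromes do not fit in ref_len")
        c = int(rng.integers(margin, config.ref_len - margin))
        k = int(rng.choice(arms))
        lo, hi = c - k - 5, c + k + 5
        if any(lo < h and l < hi for l, h in occupied):
            continue
        occupied.append((lo, hi))
        for i in range(1, k + 1):
            seq[c + i] = _COMP[str(seq[c - i])]
        centers.append(c)
        ks.append(k)

    fasta = out_dir / "reference.fa"
    write_fasta(fasta, {config.chrom: "".join(seq)})
    registry = pd.DataFrame({"center0": centers, "arm": ks})
    registry["scp_len"] = 2 * registry["arm"] + 1
    registry = registry.sort_values("center0", ignore_index=True)
    registry.to_csv(out_dir / "palindromes.tsv", sep="\t", index=False)
    return fasta, registry


# ---------------------------------------------------------------------------
# alt-allele selection conditioned on context


def _draw_alt(rng: np.random.Generator, trinuc: str, probs96: np.ndarray) -> str:
    """Alternate allele at a site, sampled from a 96-class mixture restricted
    to the three classes the local context allows."""
    idx = _context_index()
    ref = trinuc[1]
    flipped = ref in "AG"
    if flipped:
        trinuc = "".join(_COMP[b] for b in reversed(trinuc))
        ref = trinuc[1]
    cands, weights = [], []
    for alt in BASES:
        if alt == ref:
            continue
        cands.append(alt)
        weights.append(probs96[idx[f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"]])
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(3)
    alt = cands[int(rng.choice(3, p=weights / weights.sum()))]
    return _COMP[alt] if flipped else alt


# ---------------------------------------------------------------------------
# reads


def _apply_errors(rng: np.random.Generator, bases: list[str], rate: float, skip: int) -> None:
    if rate <= 0:
        return
    n_err = rng.binomial(len(bases), rate)
    for pos in rng.integers(0, len(bases), size=n_err):
        if pos == skip:
            continue
        bases[pos] = _COMP[bases[pos]] if bases[pos] in _COMP else bases[pos]


def _build_read(
    rng: np.random.Generator,
    ref_seq: str,
    pos0: int,
    offset: int,
    read_len: int,
    alt_base: str | None,
    clip_side: str | None,
    clip_len: int,
    err_rate: float,
) -> tuple[int, str, list[tuple[int, int]]]:
    """One read covering pos0 with the variant base at query index ``offset``.

    Returns (ref_start, query sequence, pysam cigartuples). Soft-clipped bases
    are random (they fail to align by construction).
    """
    if clip_side == "left":
        aligned = read_len - clip_len
        ref_start = pos0 - (offset - clip_len)
        body = list(ref_seq[ref_start : ref_start + aligned])
        clip = [str(b) for b in rng.choice(list(BASES), size=clip_len)]
        bases = clip + body
        cigar = [(4, clip_len), (0, aligned)]
    elif clip_side == "right":
        aligned = read_len - clip_len
        ref_start = pos0 - offset
        body = list(ref_seq[ref_start : ref_start + aligned])
        clip = [str(b) for b in rng.choice(list(BASES), size=clip_len)]
        bases = body + clip
        cigar = [(0, aligned), (4, clip_len)]
    else:
        ref_start = pos0 - offset
        bases = list(ref_seq[ref_start : ref_start + read_len])
        cigar = [(0, read_len)]
    _apply_errors(rng, bases, err_rate, offset)
    if alt_base is not None:
        bases[offset] = alt_base
    else:
        bases[offset] = ref_seq[pos0]  # wildtype reads always show the reference base
    return ref_start, "".join(bases), cigar


def _artifact_offset_and_clip(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[int, str | None, int]:
    lo, hi = cfg.artifact_edge_window
    d = int(rng.integers(lo, hi + 1))
    side = "left" if rng.random() < 0.5 else "right"
    offset = d if side == "left" else cfg.read_len - 1 - d
    if rng.random() < cfg.artifact_softclip_prob:
        s = int(rng.integers(4, min(9, d + 1)))
        return offset, side, s
    return offset, None, 0


def _genuine_offset_and_clip(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[int, str | None, int]:
    offset = int(rng.integers(0, cfg.read_len))
    if rng.random() < cfg.genuine_softclip_prob:
        s = int(rng.integers(4, 9))
        feasible = []
        if offset >= s:
            feasible.append("left")
        if offset < cfg.read_len - s:
            feasible.append("right")
        if feasible:
            return offset, feasible[int(rng.integers(len(feasible)))], s
    return offset, None, 0


def simulate_reads(
    config: SimulationConfig,
    fasta: str | Path,
    registry: pd.DataFrame,
    out_dir: str | Path,
) -> SimulatedCohort:
    """Per-sample coordinate-sorted BAMs (+ index), call tables and truth.

    Artifact SNVs sit at palindrome centers drawn from a shared pool that each
    sample carries with ``artifact_recurrence_prob``; their alt reads place
    the variant 10-15 bases from a read edge and are soft-clipped at the
    proximal end with ``artifact_softclip_prob``. Genuine SNVs are private per
    sample with uniform in-read placement.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with pysam.FastaFile(str(fasta)) as fa:
        ref_seq = fa.fetch(cfg.chrom).upper()

    matrix = default_signature_matrix()
    noise_probs = matrix.profiles @ np.asarray(cfg.noise_mixture)
    genuine_probs = matrix.profiles @ np.asarray(cfg.genuine_mixture)

    # shared artifact site pool: palindrome centers, alt drawn once per site
    pool_rows = registry.iloc[
        rng.choice(len(registry), size=cfg.n_artifact, replace=False)
    ]
    artifact_sites = []
    for _, row in pool_rows.iterrows():
        c = int(row.center0)
        trinuc = ref_seq[c - 1 : c + 2]
        alt = _draw_alt(rng, trinuc, noise_probs)
        artifact_sites.append((c, ref_seq[c], alt, int(row.arm)))

    forbidden = set()
    for c, *_ in artifact_sites:
        forbidden.update(range(c - 30, c + 31))

    sample_ids = [f"S{i + 1}" for i in range(cfg.n_samples)]
    bam_paths: list[Path] = []
    table_paths: list[Path] = []
    call_tables: list[list[VariantCall]] = []
    truth_rows: list[dict] = []

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": cfg.ref_len}],
    }

    for si, sid in enumerate(sample_ids):
        srng = np.random.default_rng([cfg.seed, 2, si])
        sites: list[tuple[int, str, str, str, int]] = []  # pos0, ref, alt, label, arm
        for c, rb, ab, arm in artifact_sites:
            if srng.random() < cfg.artifact_recurrence_prob:
                sites.append((c, rb, ab, "artifact", arm))
        taken = {s[0] for s in sites}
        margin = cfg.read_len + 5
        while sum(1 for s in sites if s[3] == "genuine") < cfg.n_genuine:
            p = int(srng.integers(margin, cfg.ref_len - margin))
            if p in taken or p in forbidden or "N" in ref_seq[p - 1 : p + 2]:
                continue
            alt = _draw_alt(srng, ref_seq[p - 1 : p + 2], genuine_probs)
            sites.append((p, ref_seq[p], alt, "genuine", 0))
            taken.add(p)

        segments: list[tuple[int, str, list[tuple[int, int]], str]] = []
        calls: list[VariantCall] = []
        for pos0, rb, ab, label, arm in sorted(sites):
            n_alt = max(1, int(srng.binomial(cfg.depth, cfg.vaf)))
            n_ref = cfg.depth - n_alt
            for j in range(n_alt):
                if label == "artifact":
                    offset, side, s = _artifact_offset_and_clip(srng, cfg)
                else:
                    offset, side, s = _genuine_offset_and_clip(srng, cfg)
                start, q, cig = _build_read(
                    srng, ref_seq, pos0, offset, cfg.read_len, ab, side, s, cfg.seq_error_rate
                )
                segments.append((start, q, cig, f"{sid}_v{pos0}_a{j}"))
            for j in range(n_ref):
                offset = int(srng.integers(0, cfg.read_len))
                start, q, cig = _build_read(
                    srng, ref_seq, pos0, offset, cfg.read_len, None, None, 0, cfg.seq_error_rate
                )
                segments.append((start, q, cig, f"{sid}_v{pos0}_r{j}"))
            calls.append(VariantCall(cfg.chrom, pos0 + 1, rb, ab, sid))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "chrom": cfg.chrom,
                    "pos": pos0 + 1,
                    "ref": rb,
                    "alt": ab,
                    "label": label,
                    "arm": arm,
                }
            )

        bam_path = out_dir / f"{sid}.bam"
        segments.sort(key=lambda t: (t[0], t[3]))
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for start, q, cig, name in segments:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = q
                a.flag = 0
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = cig
                a.query_qualities = pysam.qualitystring_to_array("I" * len(q))
                bam.write(a)
        pysam.index(str(bam_path))
        table_path = out_dir / f"{sid}.calls.tsv"
        write_variant_calls(calls, table_path)
        bam_paths.append(bam_path)
        table_paths.append(table_path)
        call_tables.append(calls)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return SimulatedCohort(
        cfg, Path(fasta), registry, bam_paths, table_paths, call_tables, truth, sample_ids
    )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Reference + reads + call tables in one call."""
    fasta, registry = simulate_reference(config, out_dir)
    return simulate_reads(config, fasta, registry, out_dir)


# ---------------------------------------------------------------------------
# spectra


def simulate_spectra(
    matrix: SignatureMatrix,
    weights: np.ndarray,
    n_mutations: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Multinomial draw of ``n_mutations`` 96-class counts from a signature
    mixture. Weights must lie on the simplex."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be nonnegative and sum to 1")
    probs = matrix.profiles @ w
    return rng.multinomial(n_mutations, probs).astype(float)
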