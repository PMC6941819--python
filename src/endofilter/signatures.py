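"""96-class trinucleotide mutation spectra and signature refitting.

A sample's SNVs are binned into the 96 classes ``X[R>A]Y`` (pyrimidine
reference R, flanking bases X/Y), and the resulting frequency vector f is
decomposed over fixed signature profiles P by solving

    minimize  || f - P w ||^2   subject to   w >= 0,  sum(w) = 1.

The solution is found with SLSQP and then polished with an exact active-set
step (equality-constrained least squares on the support via the KKT system),
so noise-free mixtures are recovered to machine-level accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ReferenceWindow, SignatureMatrix, VariantCall, fetch_reference_window, revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AmbiguousContextError(ValueError):
    """The trinucleotide context contains N; the variant cannot be classified."""


@lru_cache(maxsize=1)
def sbs96_contexts() -> list[str]:
    """The 96 class labels in canonical order (by substitution, then flanks)."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


@lru_cache(maxsize=1)
def _context_index() -> dict[str, int]:
    return {c: i for i, c in enumerate(sbs96_contexts())}


def trinucleotide_class(window: ReferenceWindow, ref: str, alt: str) -> str:
    """Strand-normalized 96-class label for an SNV with a flank-1 window.

    If the reference base is a purine the trinucleotide is reverse
    complemented and both alleles complemented, so the reported reference base
    is always a pyrimidine.
    """
    seq = window.seq.upper()
    if len(seq) != 3:
        raise ValueError("trinucleotide classification needs a flank-1 (3-base) window")
    if "N" in seq:
        raise AmbiguousContextError(f"N in context {seq}")
    if seq[1] != ref.upper():
        raise ValueError(f"window center {seq[1]} does not match ref allele {ref}")
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        seq = revcomp(seq)
        ref, alt = _COMP[ref], _COMP[alt]
    label = f"{seq[0]}[{ref}>{alt}]{seq[2]}"
    if label not in _context_index():
        raise ValueError(f"not a valid substitution class: {label}")
    return label


@dataclass
class MutationSpectrum:
    """Counts over the 96 substitution classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 classes")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def total_snvs(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.total_snvs
        if total == 0:
            raise ValueError("empty spectrum has no frequencies")
        return self.counts / total

    @classmethod
    def from_variants(
        cls, variants: Iterable[VariantCall], fasta: str | Path
    ) -> tuple["MutationSpectrum", int]:
        """Spectrum from SNV calls against a reference; returns the spectrum and
        the number of variants excluded (indels, ambiguous contexts)."""
        counts = np.zeros(96)
        excluded = 0
        idx = _context_index()
        for v in variants:
            if v.vtype != "SNV":
                excluded += 1
                continue
            window = fetch_reference_window(fasta, v.chrom, v.pos, 1)
            try:
                counts[idx[trinucleotide_class(window, v.ref, v.alt)]] += 1
            except AmbiguousContextError:
                excluded += 1
        return cls(counts), excluded


@dataclass
class SignatureExposures:
    weights: np.ndarray
    residual: float
    names: list[str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.names)


def _active_set_polish(P: np.ndarray, f: np.ndarray, w0: np.ndarray) -> np.ndarray:
    """Exact simplex-constrained least squares by active-set refinement.

    Starting from the SLSQP support, repeatedly solves the KKT system of the
    equality-constrained problem restricted to the working set, dropping
    negative coordinates and adding coordinates whose reduced gradient is
    negative, until the KKT conditions hold.
    """
    K = P.shape[1]
    support = set(np.nonzero(w0 > 1e-9)[0]) or {int(np.argmin(((P - f[:, None]) ** 2).sum(0)))}
    for _ in range(4 * K + 10):
        S = sorted(support)
        Ps = P[:, S]
        G = Ps.T @ Ps
        m = len(S)
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = 2.0 * G
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        rhs = np.concatenate([2.0 * Ps.T @ f, [1.0]])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        ws, lam = sol[:m], sol[m]
        if (ws < -1e-12).any():
            support.discard(S[int(np.argmin(ws))])
            continue
        w = np.zeros(K)
        w[S] = np.clip(ws, 0.0, None)
        g = 2.0 * P.T @ (P @ w - f)  # gradient; on the support g_i = lambda
        reduced = g - lam
        outside = [i for i in range(K) if i not in support]
        if outside:
            j = min(outside, key=lambda i: reduced[i])
            if reduced[j] < -1e-10:
                support.add(j)
                continue
        return w / w.sum()
    return w / w.sum()


def refit_exposures(
    spectrum: MutationSpectrum | np.ndarray, matrix: SignatureMatrix
) -> SignatureExposures:
    """Nonnegative, sum-to-one signature exposures minimizing the squared
    distance between spectrum frequencies and the profile mixture.

    Exposures depend only on frequencies, not on the total count. Raises on an
    empty spectrum.
    """
    if isinstance(spectrum, MutationSpectrum):
        f = spectrum.frequencies
    else:
        arr = np.asarray(spectrum, dtype=float)
        if arr.sum() <= 0:
            raise ValueError("empty spectrum has no frequencies")
        f = arr / arr.sum()
    P = matrix.profiles
    K = matrix.n_signatures

    def obj(w):
        r = P @ w - f
        return float(r @ r)

    def jac(w):
        return 2.0 * P.T @ (P @ w - f)

    res = minimize(
        obj,
        np.full(K, 1.0 / K),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(K)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    w = _active_set_polish(P, f, w)
    return SignatureExposures(w, obj(w), list(matrix.names))


def kkt_residual(w: np.ndarray, matrix: SignatureMatrix, f: np.ndarray) -> float:
    """Maximum violation of the KKT conditions at w (0 at the exact optimum)."""
    P = matrix.profiles
    g = 2.0 * P.T @ (P @ w - f)
    on = w > 1e-9
    lam = g[on].mean() if on.any() else g.min()
    viol = [abs(w.sum() - 1.0), float(max(0.0, -(w.min())))]
    if on.any():
        viol.append(float(np.abs(g[on] - lam).max()))
    if (~on).any():
        viol.append(float(max(0.0, lam - g[~on].min())))
    return max(viol)


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Transformer mapping 96-class spectra to signature exposures.

    ``transform`` accepts an array of shape (n_samples, 96) of counts or
    frequencies and returns the (n_samples, K) exposure matrix; each row is
    nonnegative and sums to 1.
    """

    def __init__(self, matrix: SignatureMatrix | None = None):
        self.matrix = matrix

    def fit(self, X=None, y=None):
        if self.matrix is None:
            raise ValueError("a SignatureMatrix is required")
        self.matrix_ = self.matrix
        self.n_features_in_ = 96
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "matrix_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 96:
            raise ValueError("expected spectra with 96 classes")
        return np.vstack([refit_exposures(row, self.matrix_).weights for row in X])


def spectrum_heatmap_table(
    spectra: dict[str, MutationSpectrum | np.ndarray], matrix: SignatureMatrix
) -> pd.DataFrame:
    """Per-sample exposure table (rows: samples, columns: signatures; rows sum to 1)."""
    rows = {name: refit_exposures(s, matrix).weights for name, s in spectra.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.names)


def plot_exposure_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    """Render an exposure table as a heatmap image (samples x signatures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * table.shape[1]), max(2, 0.4 * table.shape[0])))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="exposure")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
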