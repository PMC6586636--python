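"""Mutation spectra, affected/unaffected splitting, spectrum tests and
signature refitting.

Substitutions are strand-collapsed onto the six base-pair classes
(G:C>T:A, G:C>C:G, G:C>A:T, A:T>T:A, A:T>G:C, A:T>C:G); trinucleotide
contexts are collapsed onto the 96 pyrimidine-centered types used by COSMIC
signature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammaln

__all__ = [
    "CLASSES6",
    "CONTEXTS96",
    "classify_substitution",
    "build_spectrum",
    "split_affected",
    "spectrum_difference_test",
    "SignatureExposure",
    "refit_signatures",
]

CLASSES6 = ("G:C>T:A", "G:C>C:G", "G:C>A:T", "A:T>T:A", "A:T>G:C", "A:T>C:G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# pyrimidine-strand substitution -> base-pair class
_PYR_TO_CLASS = {
    ("C", "A"): "G:C>T:A",
    ("C", "G"): "G:C>C:G",
    ("C", "T"): "G:C>A:T",
    ("T", "A"): "A:T>T:A",
    ("T", "C"): "A:T>G:C",
    ("T", "G"): "A:T>C:G",
}

CONTEXTS96 = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))
    for five, three in product("ACGT", repeat=2)
)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def classify_substitution(
    ref: str, alt: str, context: Optional[str] = None
) -> Tuple[str, Optional[str]]:
    """Strand-collapsed class (and 96-type context label) for a substitution.

    ``context``, if given, is the reference trinucleotide centered on the
    variant; it is reverse-complemented together with the alleles when the
    reference base is a purine so that the returned context is
    pyrimidine-centered (e.g. ``A[C>A]A``).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"alleles must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    ctx = None if context is None else context.upper()
    if ctx is not None:
        if len(ctx) != 3 or any(b not in _COMP for b in ctx):
            raise ValueError(f"context must be a 3-mer over ACGT, got {context!r}")
        if ctx[1] != ref:
            raise ValueError("context center must equal the reference allele")
    if ref in ("G", "A"):  # collapse onto the pyrimidine strand
        ref, alt = _COMP[ref], _COMP[alt]
        if ctx is not None:
            ctx = _revcomp(ctx)
    cls = _PYR_TO_CLASS[(ref, alt)]
    label = None if ctx is None else f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
    return cls, label


def build_spectrum(
    variants: pd.DataFrame, contexts: bool = False
) -> pd.Series:
    """Count a variant table (columns ref, alt[, context]) into a spectrum.

    Returns a Series over the six classes, or over the 96 context types when
    ``contexts=True`` (requires a ``context`` column).
    """
    if contexts:
        idx = pd.Series(0, index=list(CONTEXTS96), dtype=int)
        for _, row in variants.iterrows():
            _, label = classify_substitution(row["ref"], row["alt"], row["context"])
            idx[label] += 1
        return idx
    idx = pd.Series(0, index=list(CLASSES6), dtype=int)
    for _, row in variants.iterrows():
        cls, _ = classify_substitution(row["ref"], row["alt"])
        idx[cls] += 1
    return idx


def split_affected(
    counts: pd.Series, groups: pd.Series, exposed_group: str = "BaP"
) -> pd.Series:
    """Label offspring as affected when their total mutation count strictly
    exceeds the exposed group's mean count.

    ``counts`` is indexed by offspring id; ``groups`` maps offspring id to
    group label. Offspring exactly at the mean are unaffected (strict >).
    """
    exposed = counts[groups[counts.index] == exposed_group]
    if exposed.empty:
        raise ValueError(f"no offspring in exposed group {exposed_group!r}")
    threshold = exposed.mean()
    return counts > threshold


def _log_table_prob(x1: np.ndarray, col_sums: np.ndarray, r1: int) -> np.ndarray:
    """log P(row1 = x1 | margins) under the multivariate hypergeometric."""
    x1 = np.atleast_2d(x1)
    n = int(col_sums.sum())
    lp = np.sum(
        gammaln(col_sums + 1) - gammaln(x1 + 1) - gammaln(col_sums - x1 + 1),
        axis=1,
    )
    lp -= gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
    return lp


def _count_tables(col_sums: Sequence[int], r1: int) -> int:
    """Number of 2xC tables with the given margins (DP convolution)."""
    counts = np.zeros(r1 + 1, dtype=np.int64)
    counts[0] = 1
    for c in col_sums:
        new = np.zeros_like(counts)
        for x in range(min(c, r1) + 1):
            new[x:] += counts[: r1 + 1 - x]
        counts = np.minimum(new, 10**15)  # saturate; only the magnitude matters
    return int(counts[r1])


def spectrum_difference_test(
    table_a: Sequence[int],
    table_b: Sequence[int],
    max_exact_tables: int = 200_000,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> Tuple[float, str]:
    """Fisher-style exact test for a 2xC spectrum contingency table.

    The p-value is the probability, under the margin-fixed multivariate
    hypergeometric null, of tables at most as probable as the observed one
    (the standard two-sided exact criterion; it is invariant to swapping the
    two groups). Enumeration is used when the number of margin-compatible
    tables is small enough, otherwise a seeded Monte-Carlo estimate with
    ``n_monte_carlo`` draws. Columns with zero margin are dropped; a
    zero-margin row yields P = 1 with a warning.

    Returns ``(p, method)`` with method in {"exact", "monte_carlo"}.
    """
    a = np.asarray(table_a, dtype=np.int64)
    b = np.asarray(table_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("the two spectra must be equal-length 1-D count vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    if not keep.all():
        a, b = a[keep], b[keep]
    if a.sum() == 0 or b.sum() == 0:
        warnings.warn("a group has zero total count; test degenerate, P = 1")
        return 1.0, "exact"
    col_sums = a + b
    r1 = int(a.sum())
    lp_obs = float(_log_table_prob(a, col_sums, r1)[0])
    tol = 1e-9

    if _count_tables(col_sums, r1) <= max_exact_tables:
        total = 0.0
        stack = [(0, r1, 0.0)]
        # enumerate row-1 cell values column by column, accumulating log-prob
        logs = [
            np.array([
                gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
                for x in range(c + 1)
            ])
            for c in col_sums
        ]
        n = int(col_sums.sum())
        base = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
        suffix_max = np.concatenate([np.cumsum(col_sums[::-1])[::-1], [0]])
        C = len(col_sums)

        def rec(j: int, remaining: int, acc: float):
            nonlocal total
            if j == C:
                if remaining == 0 and acc - base <= lp_obs + tol:
                    total += np.exp(acc - base)
                return
            if remaining > suffix_max[j]:
                return
            for x in range(min(int(col_sums[j]), remaining) + 1):
                rec(j + 1, remaining - x, acc + float(logs[j][x]))

        rec(0, r1, 0.0)
        return min(1.0, float(total)), "exact"

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_sums, r1, size=n_monte_carlo)
    lp = _log_table_prob(draws, col_sums, r1)
    hits = int(np.sum(lp <= lp_obs + tol))
    return (hits + 1) / (n_monte_carlo + 1), "monte_carlo"


@dataclass
class SignatureExposure:
    """Normalized signature weights with the reconstruction residual."""

    weights: pd.Series
    residual: float  # cosine distance between spectrum and reconstruction

    def __post_init__(self):
        if (self.weights < -1e-12).any():
            raise ValueError("weights must be non-negative")
        if not (-1e-6 <= self.residual <= 1.0 + 1e-6):
            raise ValueError("residual must lie in [0, 1]")


def refit_signatures(
    spectrum: pd.Series,
    signatures: pd.DataFrame,
    weight_floor: float = 0.06,
) -> SignatureExposure:
    """Refit a 96-context spectrum against a signature matrix.

    Non-negative least squares on the normalized spectrum, followed by the
    refitting convention of zeroing weights below ``weight_floor`` and
    renormalizing to sum 1. The residual is the cosine distance between the
    input spectrum and its reconstruction from the final weights.
    Deterministic given its inputs.
    """
    s = spectrum.reindex(signatures.index).astype(float)
    if s.isna().any():
        raise ValueError("spectrum index must match the signature matrix rows")
    total = s.sum()
    if total <= 0:
        raise ValueError("spectrum has zero total count")
    s_norm = (s / total).to_numpy()
    sig = signatures.to_numpy(dtype=float)
    sig = sig / sig.sum(axis=0, keepdims=True)
    w, _ = nnls(sig, s_norm)
    if w.sum() <= 0:
        raise ValueError("refit degenerate: all signature weights zero")
    w = w / w.sum()
    w[w < weight_floor] = 0.0
    if w.sum() <= 0:  # every weight fell below the floor; keep the largest
        w = np.zeros_like(w)
    else:
        w = w / w.sum()
    recon = sig @ w
    denom = np.linalg.norm(recon) * np.linalg.norm(s_norm)
    cosine = float(recon @ s_norm / denom) if denom > 0 else 0.0
    residual = min(1.0, max(0.0, 1.0 - cosine))
    return SignatureExposure(
        weights=pd.Series(w, index=signatures.columns), residual=residual
    )
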