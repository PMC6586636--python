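"""Spectrum classes, affected split, exact spectrum test, signature refit."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mutgen.spectra import (CLASSES6, CONTEXTS96, build_spectrum,
                            classify_substitution, refit_signatures,
                            split_affected, spectrum_difference_test)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def test_strand_collapse_definition():
    assert classify_substitution("G", "T")[0] == "G:C>T:A"
    assert classify_substitution("C", "A")[0] == "G:C>T:A"


def test_all_twelve_substitutions_map_two_to_one():
    hits = {}
    for ref, alt in permutations("ACGT", 2):
        cls, _ = classify_substitution(ref, alt)
        hits.setdefault(cls, []).append((ref, alt))
    assert set(hits) == set(CLASSES6)
    assert all(len(v) == 2 for v in hits.values())


def test_context_collapses_to_pyrimidine_center():
    _, label = classify_substitution("G", "T", context="AGA")
    assert label == "T[C>A]T"  # reverse complement of A G A
    _, same = classify_substitution("C", "A", context="TCT")
    assert same == label


def test_invalid_substitutions_rejected():
    with pytest.raises(ValueError):
        classify_substitution("G", "G")
    with pytest.raises(ValueError):
        classify_substitution("N", "T")
    with pytest.raises(ValueError):
        classify_substitution("G", "T", context="ACA")  # center mismatch


def test_spectrum_invariant_under_reverse_complement():
    rng = np.random.default_rng(5)
    refs = rng.choice(list("ACGT"), 60)
    alts = [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    variants = pd.DataFrame(dict(ref=refs, alt=alts))
    flipped = pd.DataFrame(dict(ref=[_COMP[r] for r in refs],
                                alt=[_COMP[a] for a in alts]))
    pd.testing.assert_series_equal(build_spectrum(variants), build_spectrum(flipped))


def test_context_marginals_sum_to_six_classes():
    rng = np.random.default_rng(8)
    rows = []
    for _ in range(80):
        ref = rng.choice(list("ACGT"))
        alt = rng.choice([b for b in "ACGT" if b != ref])
        ctx = rng.choice(list("ACGT")) + ref + rng.choice(list("ACGT"))
        rows.append(dict(ref=ref, alt=alt, context=ctx))
    variants = pd.DataFrame(rows)
    s96 = build_spectrum(variants, contexts=True)
    s6 = build_spectrum(variants)
    # each block of 16 contexts belongs to one pyrimidine substitution
    blocks = {CONTEXTS96[i * 16][1:6]: s96.iloc[i * 16:(i + 1) * 16].sum() for i in range(6)}
    mapping = {"[C>A]": "G:C>T:A", "[C>G]": "G:C>C:G", "[C>T]": "G:C>A:T",
               "[T>A]": "A:T>T:A", "[T>C]": "A:T>G:C", "[T>G]": "A:T>C:G"}
    for block, total in blocks.items():
        assert total == s6[mapping[block]]


def test_split_affected_strict_mean_boundary():
    counts = pd.Series({"a": 10, "b": 10, "c": 10})
    groups = pd.Series({"a": "BaP", "b": "BaP", "c": "control"})
    assert not split_affected(counts, groups).any()  # all exactly at the mean


def test_split_affected_bimodal():
    counts = pd.Series({f"m{i}": (30 if i < 4 else 5) for i in range(12)})
    groups = pd.Series({f"m{i}": "BaP" for i in range(12)})
    labels = split_affected(counts, groups)
    assert set(labels[labels].index) == {f"m{i}" for i in range(4)}


def test_identical_spectra_give_p_one():
    p, method = spectrum_difference_test([4, 2, 6, 1, 3, 4], [4, 2, 6, 1, 3, 4])
    assert p == pytest.approx(1.0, abs=1e-9)


def test_spectrum_test_symmetric_in_groups():
    a, b = [5, 1, 7, 2, 0, 4], [1, 6, 2, 3, 2, 1]
    assert spectrum_difference_test(a, b)[0] == pytest.approx(
        spectrum_difference_test(b, a)[0], abs=1e-12
    )


def test_two_class_table_reduces_to_fisher_exact():
    from scipy.stats import fisher_exact

    p, method = spectrum_difference_test([5, 15], [12, 3])
    assert method == "exact"
    assert p == pytest.approx(fisher_exact([[5, 15], [12, 3]])[1], rel=1e-9)


def test_exact_matches_brute_force_enumeration():
    """Total-20 2x6 table: p equals full enumeration over fixed margins."""
    from itertools import product as iproduct
    from math import comb

    a = np.array([3, 1, 2, 0, 2, 2])
    b = np.array([1, 2, 0, 3, 1, 3])
    cols = a + b
    r1, n = a.sum(), (a + b).sum()

    def prob(x):
        return np.prod([comb(c, xi) for c, xi in zip(cols, x)]) / comb(n, r1)

    p_obs = prob(a)
    total = 0.0
    for x in iproduct(*[range(c + 1) for c in cols]):
        if sum(x) == r1 and prob(x) <= p_obs * (1 + 1e-9):
            total += prob(x)
    p, method = spectrum_difference_test(a, b)
    assert method == "exact"
    assert p == pytest.approx(total, rel=1e-9)


def test_monte_carlo_agrees_with_exact():
    a, b = [5, 3, 2, 4, 1, 5], [2, 6, 1, 3, 4, 4]
    p_exact, _ = spectrum_difference_test(a, b)
    p_mc, method = spectrum_difference_test(a, b, max_exact_tables=1, seed=123)
    assert method == "monte_carlo"
    assert p_mc == pytest.approx(p_exact, abs=0.01)


def test_pure_signature_refits_to_weight_one(signature_pair):
    spectrum = signature_pair["S1"] * 500
    exposure = refit_signatures(spectrum, signature_pair)
    assert exposure.weights["S1"] == pytest.approx(1.0)
    assert exposure.residual == pytest.approx(0.0, abs=1e-9)


def test_mixture_recovered_within_tolerance(signature_pair):
    rng = np.random.default_rng(17)
    mix = 0.6 * signature_pair["S1"] + 0.4 * signature_pair["S2"]
    draws = rng.multinomial(500, mix / mix.sum())
    exposure = refit_signatures(pd.Series(draws, index=signature_pair.index),
                                signature_pair)
    assert exposure.weights["S1"] == pytest.approx(0.6, abs=0.05)
    assert exposure.weights["S2"] == pytest.approx(0.4, abs=0.05)


def test_orthogonal_signatures_split_exactly():
    sig = pd.DataFrame(0.0, index=list(CONTEXTS96), columns=["A", "B"])
    sig.iloc[:48, 0] = 1 / 48
    sig.iloc[48:, 1] = 1 / 48
    spectrum = pd.Series(0.0, index=list(CONTEXTS96))
    spectrum.iloc[:48] = 0.7 * 300 / 48
    spectrum.iloc[48:] = 0.3 * 300 / 48
    exposure = refit_signatures(spectrum, sig)
    assert exposure.weights["A"] == pytest.approx(0.7, abs=1e-9)
    assert exposure.residual == pytest.approx(0.0, abs=1e-9)


def test_weight_floor_zeroes_small_exposures(signature_pair):
    mix = 0.97 * signature_pair["S1"] + 0.03 * signature_pair["S2"]
    exposure = refit_signatures(mix * 1000, signature_pair)
    assert exposure.weights["S2"] == 0.0
    assert exposure.weights.sum() == pytest.approx(1.0)


def test_zero_spectrum_rejected(signature_pair):
    with pytest.raises(ValueError):
        refit_signatures(pd.Series(0.0, index=signature_pair.index), signature_pair)
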