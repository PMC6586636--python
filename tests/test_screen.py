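"""Mendelian-violation discovery and the filter cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from mutgen.intervals import IntervalSet
from mutgen.screen import (AnimalSite, ScreenConfig, SiteObservation,
                           apply_filter_cascade, find_mendelian_violations,
                           screen_quintet, strand_bias_p)
from mutgen.simulate import SimulationConfig, simulate_quintet


def make_sites(records):
    """records: list of (animal, depth, alt_depth) for a single site."""
    rows = []
    for animal, depth, alt in records:
        rows.append(dict(site_id="s1", chrom="chr1", pos=100, ref="G", alt="T",
                         animal=animal, depth=depth, alt_depth=alt,
                         fwd_ref=(depth - alt) // 2, rev_ref=(depth - alt + 1) // 2,
                         fwd_alt=alt // 2, rev_alt=(alt + 1) // 2, mq0_fraction=0.0))
    return pd.DataFrame(rows)


def test_offspring_alt_with_ref_parents_is_candidate():
    sites = make_sites([("sire", 30, 0), ("dam", 30, 0), ("offspring_1", 30, 15)])
    out = find_mendelian_violations(sites)
    assert len(out) == 1 and out.iloc[0]["animal"] == "offspring_1"


def test_het_parent_blocks_candidate():
    sites = make_sites([("sire", 30, 0), ("dam", 30, 15), ("offspring_1", 30, 15)])
    assert find_mendelian_violations(sites).empty


def test_simulated_de_novo_recovered_exactly(de_novo_quintet):
    sites, truth = de_novo_quintet
    out = find_mendelian_violations(sites)
    assert set(zip(out["site_id"], out["animal"])) == set(
        zip(truth["site_id"], truth["carriers"])
    )


def test_clean_simulation_yields_zero_candidates():
    cfg = SimulationConfig(seed=3, n_sites=300, error_rate=0.0)
    sites, _ = simulate_quintet(cfg)
    assert find_mendelian_violations(sites).empty


def _obs(child=("offspring_1", 30, 9), sire=(30, 1), dam=(25, 0), mq0=0.05,
         strand=None):
    name, cd, ca = child
    fwd_alt = ca // 2 if strand is None else strand[0]
    rev_alt = ca - fwd_alt
    records = {
        "sire": AnimalSite(depth=sire[0], alt_depth=sire[1], mq0_fraction=mq0,
                           fwd_ref=(sire[0] - sire[1]) // 2,
                           rev_ref=sire[0] - sire[1] - (sire[0] - sire[1]) // 2,
                           fwd_alt=sire[1], rev_alt=0),
        "dam": AnimalSite(depth=dam[0], alt_depth=dam[1], mq0_fraction=mq0,
                          fwd_ref=(dam[0] - dam[1]) // 2,
                          rev_ref=dam[0] - dam[1] - (dam[0] - dam[1]) // 2,
                          fwd_alt=dam[1], rev_alt=0),
        name: AnimalSite(depth=cd, alt_depth=ca, mq0_fraction=mq0,
                         fwd_ref=(cd - ca) // 2, rev_ref=cd - ca - (cd - ca) // 2,
                         fwd_alt=fwd_alt, rev_alt=rev_alt),
    }
    return SiteObservation(chrom="chr1", pos=500, ref="G", alt="T", records=records)


def test_cascade_passes_study_thresholds():
    # parents 1/30 and 0/25 (< 5%), offspring 9/30 = 0.30 (> 25%), depths >= 7,
    # MQ0 0.05, balanced strands, outside the mask
    verdict = apply_filter_cascade(_obs(), "offspring_1")
    assert verdict.overall and all(verdict.flags.values())


def test_cascade_depth_six_fails_depth_flag_only():
    verdict = apply_filter_cascade(_obs(dam=(6, 0)), "offspring_1")
    assert not verdict.flags["depth"] and not verdict.overall
    assert verdict.flags["parent_vaf"] and verdict.flags["offspring_vaf"]


def test_cascade_offspring_vaf_boundary_is_strict():
    # VAF exactly 0.25 fails the strict > 0.25 rule
    verdict = apply_filter_cascade(_obs(child=("offspring_1", 32, 8)), "offspring_1")
    assert not verdict.flags["offspring_vaf"]


def test_cascade_repeat_mask_and_mq0():
    mask = IntervalSet([("chr1", 400, 600)])
    verdict = apply_filter_cascade(_obs(), "offspring_1", repeat_mask=mask)
    assert not verdict.flags["repeat_region"]
    verdict = apply_filter_cascade(_obs(mq0=0.2), "offspring_1")
    assert not verdict.flags["mq0"]


def test_cascade_extreme_strand_bias_fails():
    verdict = apply_filter_cascade(_obs(child=("offspring_1", 30, 10), strand=(10,)),
                                   "offspring_1")
    assert not verdict.flags["strand_bias"]


def test_cascade_flags_are_independent_of_order():
    v = apply_filter_cascade(_obs(dam=(6, 0), mq0=0.3), "offspring_1")
    # both independent criteria fail simultaneously
    assert not v.flags["depth"] and not v.flags["mq0"]
    assert v.flags["strand_bias"]


def test_strand_bias_balanced_table_is_one():
    assert strand_bias_p(10, 10, 5, 5) == 1.0
    assert strand_bias_p(0, 0, 0, 0) == 1.0


def test_strand_bias_matches_enumeration_oracle():
    fr, rr, fa, ra = 10, 0, 0, 10
    row1, row2 = fr + rr, fa + ra
    col1 = fr + fa
    n = row1 + row2
    p_obs = (math.comb(row1, fr) * math.comb(row2, fa)) / math.comb(n, col1)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        p = (math.comb(row1, x) * math.comb(row2, col1 - x)) / math.comb(n, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    assert strand_bias_p(fr, rr, fa, ra) == pytest.approx(total, abs=1e-12)


def test_screen_matches_naive_loop_oracle(de_novo_quintet):
    sites, _ = de_novo_quintet
    cfg = ScreenConfig()
    result = screen_quintet(sites)

    # naive site-by-site reimplementation of candidate discovery + cascade
    naive = 0
    for _, block in sites.groupby("site_id"):
        rec = block.set_index("animal")
        parent_clear = all(
            rec.loc[p, "alt_depth"] / rec.loc[p, "depth"] < cfg.genotype_vaf
            for p in ("sire", "dam")
        )
        if not parent_clear:
            continue
        for child in [a for a in rec.index if a.startswith("offspring")]:
            if rec.loc[child, "alt_depth"] < cfg.min_alt_reads:
                continue
            ok = (
                all(rec.loc[p, "alt_depth"] / rec.loc[p, "depth"] < cfg.parent_vaf_max
                    for p in ("sire", "dam"))
                and rec.loc[child, "alt_depth"] / rec.loc[child, "depth"] > cfg.offspring_vaf_min
                and (rec["mq0_fraction"] <= cfg.mq0_max).all()
                and (rec["depth"] >= cfg.min_depth).all()
                and strand_bias_p(rec.loc[child, "fwd_ref"], rec.loc[child, "rev_ref"],
                                  rec.loc[child, "fwd_alt"], rec.loc[child, "rev_alt"])
                > cfg.strand_p_min
            )
            naive += ok
    assert int(result["pass_all"].sum()) == naive


def test_animal_site_invariants():
    with pytest.raises(ValueError):
        AnimalSite(depth=10, alt_depth=11)
    with pytest.raises(ValueError):
        AnimalSite(depth=10, alt_depth=4, fwd_alt=1, rev_alt=1)
    assert AnimalSite(depth=0, alt_depth=0).vaf == 0.0
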