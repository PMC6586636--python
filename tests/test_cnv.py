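"""CNV segmentation (vs brute-force oracle), recurrence, status and
frequencies."""

import numpy as np
import pandas as pd
import pytest

from mutgen.cnv import (CnvCall, CnvConfig, assign_cnv_status, cnv_frequencies,
                        filter_recurrent, normalize_probes, segment_cnvs)


def series(values, chrom="chr1", spacing=3000):
    return pd.DataFrame(dict(chrom=chrom, pos=np.arange(1, len(values) + 1) * spacing,
                             log2=values))


def test_five_probe_duplication_called():
    calls = segment_cnvs(series([0, 0.61, 0.61, 0.61, 0.61, 0.61, 0]))
    assert len(calls) == 1
    c = calls[0]
    assert c.kind == "duplication" and c.n_probes == 5
    assert c.mean_log2 == pytest.approx(0.61)


def test_four_probe_run_not_called():
    assert segment_cnvs(series([0, 0.9, 0.9, 0.9, 0.9, 0])) == []


def test_all_zero_series_no_calls():
    assert segment_cnvs(series([0.0] * 50)) == []


def test_run_broken_by_single_low_probe_not_bridged():
    vals = [0.6] * 4 + [0.1] + [0.6] * 4
    assert segment_cnvs(series(vals)) == []


def test_sign_change_splits_runs():
    vals = [0.6] * 5 + [-0.9] * 5
    calls = segment_cnvs(series(vals))
    assert [c.kind for c in calls] == ["duplication", "deletion"]


def test_sex_chromosomes_excluded():
    assert segment_cnvs(series([0.9] * 8, chrom="chrX")) == []


def test_segmentation_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(300):
        n = int(rng.integers(10, 120))
        vals = rng.normal(0, 0.35, size=n)
        # sprinkle genuine runs
        if rng.random() < 0.5:
            start = int(rng.integers(0, max(1, n - 7)))
            vals[start:start + 7] = rng.normal(0.7, 0.1, size=min(7, n - start))
        calls = segment_cnvs(series(list(vals)))
        expected = []
        run_start = None
        sign = 0
        for i, v in enumerate(list(vals) + [0.0]):
            s = 1 if v > 0.4 else (-1 if v < -0.4 else 0)
            if s != sign:
                if sign != 0 and i - run_start >= 5:
                    expected.append((run_start, i - 1, sign))
                run_start = i if s != 0 else None
                sign = s
        got = [((c.start // 3000) - 1, (c.end // 3000) - 1,
                1 if c.kind == "duplication" else -1) for c in calls]
        assert got == expected


def test_mosaic_below_threshold_never_called():
    # closed form: a mosaic duplication at fraction f has log2((2+f)/2);
    # any f with that value <= 0.4 leaves every probe sub-threshold
    for f in (0.2, 0.4, 0.5, 0.63):
        value = float(np.log2((2 + f) / 2))
        assert value <= 0.4
        assert segment_cnvs(series([value] * 60)) == []


def test_recurrent_calls_removed_singletons_kept():
    mk = lambda animal, start: CnvCall(animal=animal, chrom="chr1", start=start,
                                       end=start + 14000, kind="duplication",
                                       mean_log2=0.6, n_probes=5)
    shared = [mk("a1", 30000), mk("a2", 30000), mk("a3", 31000)]
    single = mk("a4", 500000)
    kept = filter_recurrent(shared + [single])
    assert [c.animal for c in kept] == ["a4"]
    assert single.recurrence == 1


def test_recurrence_matches_pairwise_overlap_oracle():
    rng = np.random.default_rng(3)
    calls = []
    for i in range(40):
        start = int(rng.integers(1, 2_000_000))
        length = int(rng.integers(15_000, 120_000))
        calls.append(CnvCall(animal=f"a{rng.integers(0, 12)}", chrom=f"chr{rng.integers(1, 4)}",
                             start=start, end=start + length, kind="duplication",
                             mean_log2=0.6, n_probes=5))
    kept = filter_recurrent(calls)

    def overlap(a, b):
        if a.chrom != b.chrom:
            return 0.0
        ov = min(a.end, b.end) - max(a.start, b.start) + 1
        return 0.0 if ov <= 0 else min(ov / a.length, ov / b.length)

    expected = [c for c in calls
                if not any(o.animal != c.animal and overlap(c, o) >= 0.5 for o in calls)]
    assert [id(c) for c in kept] == [id(c) for c in expected]


def _call(kind="duplication", mean_log2=0.61):
    return CnvCall(animal="a1", chrom="chr1", start=30000, end=60000, kind=kind,
                   mean_log2=mean_log2, n_probes=10)


def test_status_de_novo_multi_tissue():
    status = assign_cnv_status(_call(), {"liver": 3.0, "spleen": 2.9, "brain": 3.1},
                               sire_copy_number=2.0, dam_copy_number=2.0)
    assert status == "de_novo"


def test_status_small_change_is_false_positive():
    status = assign_cnv_status(_call(), {"liver": 2.3, "spleen": 2.25, "brain": 2.3},
                               sire_copy_number=2.0, dam_copy_number=2.0)
    assert status == "false_positive"


def test_status_parent_carrier_is_inherited():
    status = assign_cnv_status(_call(), {"liver": 3.0, "spleen": 3.0},
                               sire_copy_number=3.0, dam_copy_number=2.0)
    assert status == "inherited"


def test_status_shallow_deletion_is_somatic():
    call = _call(kind="deletion", mean_log2=-0.6)
    status = assign_cnv_status(call, {"liver": 1.2, "spleen": 1.3, "brain": 1.25},
                               sire_copy_number=2.0, dam_copy_number=2.0)
    assert status == "putative_somatic"  # mean log2 above the -0.75 cut


def test_status_deep_deletion_is_de_novo():
    call = _call(kind="deletion", mean_log2=-0.95)
    status = assign_cnv_status(call, {"liver": 1.0, "spleen": 1.1, "brain": 1.0},
                               sire_copy_number=2.0, dam_copy_number=2.0)
    assert status == "de_novo"


def test_status_single_tissue_is_somatic():
    status = assign_cnv_status(_call(), {"liver": 3.0, "spleen": 2.1, "brain": 2.0},
                               sire_copy_number=2.0, dam_copy_number=2.0)
    assert status == "putative_somatic"


def test_status_sibling_sharing_is_germline_mosaic():
    status = assign_cnv_status(_call(), {"liver": 3.0, "spleen": 3.0},
                               sire_copy_number=2.0, dam_copy_number=2.0,
                               shared_with_sibling_same_sire=True)
    assert status == "germline_mosaic"


def test_status_requires_parental_copy_numbers():
    with pytest.raises(ValueError):
        assign_cnv_status(_call(), {"liver": 3.0}, sire_copy_number=None,
                          dam_copy_number=2.0)


def test_frequencies_with_event_merge():
    calls = []
    # 3 deletion events in control, dup pair sharing one event in treated
    for i in range(3):
        calls.append(CnvCall(animal=f"c{i}", chrom=f"chr{i + 1}", start=1000,
                             end=20000, kind="deletion", mean_log2=-0.9, n_probes=6))
    for chrom in ("chr4", "chr10"):
        calls.append(CnvCall(animal="t0", chrom=chrom, start=1000, end=20000,
                             kind="duplication", mean_log2=0.6, n_probes=6,
                             event_id="pair1"))
    group_of = {f"c{i}": "control" for i in range(3)} | {"t0": "bap"}
    sizes = {"control": 171, "bap": 181}
    dels = cnv_frequencies(calls, group_of, sizes, control="control",
                           kind="deletion", direction="less")
    dups = cnv_frequencies(calls, group_of, sizes, control="control",
                           kind="duplication", direction="greater")
    by = {c.group: c for c in dels}
    assert by["control"].count == 3
    assert round(by["control"].rate * 100, 1) == 1.8
    dup_by = {c.group: c for c in dups}
    assert dup_by["bap"].count == 1  # two calls, one mutational event


def test_normalize_equal_channels_all_zero():
    rng = np.random.default_rng(1)
    base = rng.uniform(100, 5000, 500)
    df = pd.DataFrame(dict(chrom="chr1", pos=np.arange(1, 501) * 3000,
                           ch_test=base, ch_ref=base))
    out = normalize_probes(df)
    assert np.allclose(out["log2"], 0.0, atol=1e-12)


def test_normalize_removes_multiplicative_bias():
    rng = np.random.default_rng(2)
    base = rng.uniform(100, 10000, 800)
    df = pd.DataFrame(dict(chrom="chr1", pos=np.arange(1, 801) * 3000,
                           ch_test=base * 1.9, ch_ref=base))
    out = normalize_probes(df)
    assert np.median(np.abs(out["log2"])) < 0.01


def test_normalize_removes_intensity_trend():
    rng = np.random.default_rng(4)
    base = np.sort(rng.uniform(100, 10000, 1000))
    bias = 1.0 + 0.3 * np.log10(base / 100)  # monotone intensity-dependent bias
    df = pd.DataFrame(dict(chrom="chr1", pos=np.arange(1, 1001) * 3000,
                           ch_test=base * bias, ch_ref=base))
    out = normalize_probes(df)
    a = 0.5 * np.log2(df["ch_test"] * df["ch_ref"])
    slope = np.polyfit(a, out["log2"], 1)[0]
    assert abs(slope) < 0.01


def test_normalize_refuses_tiny_arrays():
    df = pd.DataFrame(dict(chrom="chr1", pos=np.arange(1, 50) * 3000,
                           ch_test=np.ones(49), ch_ref=np.ones(49)))
    with pytest.raises(ValueError, match="100"):
        normalize_probes(df)
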