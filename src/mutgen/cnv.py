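"""aCGH CNV calling: normalization, segmentation, recurrence filtering,
status assignment and group frequencies.

A CNV is called from offspring-vs-parents log2 ratios when at least five
*consecutive* probes each individually exceed |log2| > 0.4 (every probe
altered, not just the run mean; runs are not bridged across a sub-threshold
probe). De novo status additionally requires qPCR-style copy-number support
in multiple germ layers, parents at two copies, and - for deletions - a mean
log2 below -0.75 (shallower deletions are post-fertilization somatic
events). Only autosomal calls are made, and calls recurring across animals
(reciprocal overlap >= 0.5) are removed as likely multi-allelic inherited
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intervals import is_autosome
from .rates import RateComparison, rate_and_ratio
from .stats import fisher_one_tailed, sidak_stepdown

__all__ = [
    "CnvConfig",
    "CnvCall",
    "normalize_probes",
    "segment_cnvs",
    "filter_recurrent",
    "assign_cnv_status",
    "cnv_frequencies",
]

CNV_STATUSES = ("de_novo", "inherited", "germline_mosaic", "putative_somatic", "false_positive")


@dataclass(frozen=True)
class CnvConfig:
    log2_threshold: float = 0.4       # |log2| each probe must exceed
    min_probes: int = 5               # consecutive altered probes per call
    deletion_log2_max: float = -0.75  # de novo deletions must be below this
    cn_change_min: float = 0.5        # qPCR copy change for a real event
    min_tissues: int = 2              # germ layers with the change for de novo
    reciprocal_overlap: float = 0.5   # recurrence criterion across animals


@dataclass
class CnvCall:
    """One segmented CNV for one animal."""

    animal: str
    chrom: str
    start: int            # first probe position (1-based)
    end: int              # last probe position
    kind: str             # "duplication" | "deletion"
    mean_log2: float
    n_probes: int
    status: Optional[str] = None
    recurrence: int = 1
    event_id: Optional[str] = None  # shared by calls from one mutational event
    notes: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("duplication", "deletion"):
            raise ValueError(f"kind must be duplication/deletion, got {self.kind!r}")
        if self.status is not None and self.status not in CNV_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_probes(raw: pd.DataFrame, lowess_frac: float = 0.3) -> pd.DataFrame:
    """Two-channel intensities -> normalized log2 ratio series.

    ``raw`` needs columns chrom, pos, ch_test, ch_ref (background-subtracted
    test/reference channel intensities) and optionally a boolean ``uniform``
    column; non-uniform probes are dropped. The log2 ratio is corrected for
    intensity-dependent trend with a lowess fit of M = log2(test/ref) on
    A = mean log intensity, then median-centered per array.
    """
    required = {"chrom", "pos", "ch_test", "ch_ref"}
    if not required.issubset(raw.columns):
        raise ValueError(f"missing columns {required - set(raw.columns)}")
    df = raw.copy()
    if "uniform" in df.columns:
        df = df[df["uniform"].astype(bool)]
    if len(df) < 100:
        raise ValueError("need >= 100 uniform probes to fit the intensity trend")
    if (df["ch_test"] <= 0).any() or (df["ch_ref"] <= 0).any():
        raise ValueError("channel intensities must be positive after background subtraction")
    m = np.log2(df["ch_test"].to_numpy() / df["ch_ref"].to_numpy())
    a = 0.5 * np.log2(df["ch_test"].to_numpy() * df["ch_ref"].to_numpy())
    trend = sm.nonparametric.lowess(m, a, frac=lowess_frac, return_sorted=False)
    log2 = m - trend
    log2 = log2 - np.median(log2)
    out = df[["chrom", "pos"]].copy()
    out["log2"] = log2
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def segment_cnvs(
    probes: pd.DataFrame,
    animal: str = "offspring",
    config: CnvConfig = CnvConfig(),
    autosomes_only: bool = True,
) -> List[CnvCall]:
    """Maximal runs of >= 5 consecutive same-sign probes beyond |0.4|.

    ``probes`` needs columns chrom, pos, log2 with strictly increasing
    positions per chromosome. One call per run; the call's type follows the
    sign and its mean log2 is the run mean.
    """
    required = {"chrom", "pos", "log2"}
    if not required.issubset(probes.columns):
        raise ValueError(f"missing columns {required - set(probes.columns)}")
    calls: List[CnvCall] = []
    for chrom, sub in probes.groupby("chrom", sort=True):
        if autosomes_only and not is_autosome(str(chrom)):
            continue
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"probe positions must be strictly increasing on {chrom}")
        log2 = sub["log2"].to_numpy()
        if not np.all(np.isfinite(log2)):
            raise ValueError("log2 values must be finite")
        sign = np.where(log2 > config.log2_threshold, 1, np.where(log2 < -config.log2_threshold, -1, 0))
        i = 0
        n = len(sign)
        while i < n:
            if sign[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and sign[j + 1] == sign[i]:
                j += 1
            run_len = j - i + 1
            if run_len >= config.min_probes:
                seg = log2[i : j + 1]
                calls.append(
                    CnvCall(
                        animal=animal, chrom=str(chrom), start=int(pos[i]), end=int(pos[j]),
                        kind="duplication" if sign[i] > 0 else "deletion",
                        mean_log2=float(seg.mean()), n_probes=run_len,
                    )
                )
            i = j + 1
    return calls


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def filter_recurrent(
    calls: Sequence[CnvCall], config: CnvConfig = CnvConfig()
) -> List[CnvCall]:
    """Keep only CNVs observed in a single animal.

    Two calls in *different* animals match when their reciprocal overlap is
    >= 0.5; any call with a match is removed (likely multi-allelic inherited
    variation). Each retained call's ``recurrence`` stays 1; removed calls
    are simply dropped.
    """
    keep: List[CnvCall] = []
    for i, c in enumerate(calls):
        rec = 1
        for j, other in enumerate(calls):
            if i == j or other.animal == c.animal:
                continue
            if _reciprocal_overlap(c, other) >= config.reciprocal_overlap:
                rec += 1
        c.recurrence = rec
        if rec == 1:
            keep.append(c)
    return keep


def assign_cnv_status(
    call: CnvCall,
    carrier_copy_numbers: Dict[str, float],
    sire_copy_number: Optional[float],
    dam_copy_number: Optional[float],
    shared_with_sibling_same_sire: bool = False,
    config: CnvConfig = CnvConfig(),
) -> str:
    """Validation status for one CNV from per-tissue copy numbers.

    ``carrier_copy_numbers`` maps germ-layer tissues (e.g. liver, spleen,
    brain) to qPCR copy-number estimates for the carrier. Rules, in order:
    a carrier parent makes the call inherited; sibling sharing within one
    sire (parents negative) makes it germline mosaic; a maximum carrier copy
    change < 0.5 is a false positive; a change confined to fewer than two
    germ layers, or a deletion with mean log2 >= -0.75, is a putative
    post-fertilization somatic event; otherwise the CNV is de novo. Missing
    parental copy numbers leave the status undecidable (ValueError).
    """
    if sire_copy_number is None or dam_copy_number is None:
        call.notes.append("parental copy numbers missing; status undecidable")
        raise ValueError("parental copy numbers required to assign status")
    direction = 1.0 if call.kind == "duplication" else -1.0
    for parent_cn in (sire_copy_number, dam_copy_number):
        if direction * (parent_cn - 2.0) >= config.cn_change_min:
            return "inherited"
    if shared_with_sibling_same_sire:
        return "germline_mosaic"
    changes = {t: direction * (cn - 2.0) for t, cn in carrier_copy_numbers.items()}
    if not changes or max(changes.values()) < config.cn_change_min:
        return "false_positive"
    n_supporting = sum(ch >= config.cn_change_min for ch in changes.values())
    if n_supporting < config.min_tissues:
        return "putative_somatic"
    if call.kind == "deletion" and call.mean_log2 >= config.deletion_log2_max:
        return "putative_somatic"
    return "de_novo"


def cnv_frequencies(
    calls: Sequence[CnvCall],
    group_of_animal: Dict[str, str],
    group_sizes: Dict[str, int],
    control: str,
    kind: str,
    direction: str,
    adjust_groups: Optional[Sequence[str]] = None,
) -> List[RateComparison]:
    """Per-group CNV event frequencies with Fisher and Sidak statistics.

    Multiple calls sharing an ``event_id`` within one animal count as a
    single mutational event. ``direction`` is the one-tailed Fisher
    alternative for treated-vs-control ("greater" when an increase is the
    hypothesis, e.g. duplications; "less" for deletions). The Holm-Sidak
    step-down (non-monotonized) runs over ``adjust_groups`` (default: every
    non-control group, in ``group_sizes`` order).
    """
    events: Dict[str, set] = {g: set() for g in group_sizes}
    for c in calls:
        if c.kind != kind:
            continue
        group = group_of_animal[c.animal]
        key = (c.animal, c.event_id if c.event_id is not None else (c.chrom, c.start, c.end))
        events[group].add(key)
    counts = {g: (len(events[g]), group_sizes[g]) for g in group_sizes}
    comparisons = rate_and_ratio(counts, control=control, ci_method="wald")
    x2, n2 = counts[control]
    for rc in comparisons:
        if rc.group == control:
            continue
        rc.p_value = fisher_one_tailed(rc.count, rc.n_offspring, x2, n2, direction=direction)
    if adjust_groups is None:
        adjust_groups = [g for g in group_sizes if g != control]
    by_group = {rc.group: rc for rc in comparisons}
    ps = [by_group[g].p_value for g in adjust_groups]
    if ps:
        adj = sidak_stepdown(ps, monotonize=False)
        for g, a in zip(adjust_groups, adj):
            by_group[g].p_adjusted = float(a)
    return comparisons
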