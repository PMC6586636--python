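"""Mendelian-violation discovery and the filter cascade.

Candidate discovery flags offspring-site pairs where the offspring carries an
allele absent from both parental genotypes; the cascade then applies the
study's five discovery filters independently (parental VAF < 5% in *each*
parent, offspring VAF > 25%, MQ0 fraction <= 0.1, depth >= 7 in every animal,
two-sided Fisher strand-bias P > 0.05) plus a repeat-mask exclusion. VAF is
alt_depth / depth (total read depth at the site).

Site tables are tidy pandas DataFrames with one row per (site, animal); the
per-animal records are assumed to have been computed over reads overlapping
pos +/- 10 bp of the putative variant (a precondition on input generation,
not re-checked here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "AnimalSite",
    "SiteObservation",
    "FilterVerdict",
    "find_mendelian_violations",
    "apply_filter_cascade",
    "strand_bias_p",
    "screen_quintet",
]

PARENTS = ("sire", "dam")

SITE_COLUMNS = [
    "site_id", "chrom", "pos", "ref", "alt", "animal", "depth", "alt_depth",
    "fwd_ref", "rev_ref", "fwd_alt", "rev_alt", "mq0_fraction",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Discovery filter thresholds (defaults are the study's values)."""

    parent_vaf_max: float = 0.05     # strict: parent VAF must be < this
    offspring_vaf_min: float = 0.25  # strict: offspring VAF must be > this
    mq0_max: float = 0.10            # inclusive: MQ0 fraction <= this
    min_depth: int = 7               # inclusive: depth >= this in all animals
    strand_p_min: float = 0.05       # strict: strand-bias P must be > this
    min_alt_reads: int = 3           # candidate calling: alt reads in offspring
    genotype_vaf: float = 0.20       # allele counted as present in a genotype


@dataclass
class AnimalSite:
    """Per-animal allelic evidence at one genomic site."""

    depth: int
    alt_depth: int
    mq0_fraction: float = 0.0
    fwd_ref: int = 0
    rev_ref: int = 0
    fwd_alt: int = 0
    rev_alt: int = 0

    def __post_init__(self):
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError("need 0 <= alt_depth <= depth")
        if not 0.0 <= self.mq0_fraction <= 1.0:
            raise ValueError("mq0_fraction must lie in [0, 1]")
        if self.fwd_alt + self.rev_alt != self.alt_depth:
            raise ValueError("strand alt counts must sum to alt_depth")

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth > 0 else 0.0


@dataclass
class SiteObservation:
    """One candidate site with records for every family member."""

    chrom: str
    pos: int
    ref: str
    alt: str
    records: Dict[str, AnimalSite]

    def vaf(self, animal: str) -> float:
        return self.records[animal].vaf


@dataclass
class FilterVerdict:
    """Per-criterion pass/fail flags; overall pass iff all criteria pass."""

    flags: Dict[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.flags.values())


def strand_bias_p(fwd_ref: int, rev_ref: int, fwd_alt: int, rev_alt: int) -> float:
    """Two-sided Fisher exact P for the 2x2 strand-by-allele table.

    The two-sided P sums the probabilities of all tables (with the observed
    margins) whose probability does not exceed the observed table's. An
    all-zero table returns 1.0 by convention.
    """
    counts = (fwd_ref, rev_ref, fwd_alt, rev_alt)
    if any(c < 0 for c in counts):
        raise ValueError("strand counts must be non-negative")
    if sum(counts) == 0:
        return 1.0
    res = sps.fisher_exact([[fwd_ref, rev_ref], [fwd_alt, rev_alt]], alternative="two-sided")
    return float(res.pvalue)


def find_mendelian_violations(
    sites: pd.DataFrame,
    parents: Sequence[str] = PARENTS,
    offspring: Optional[Sequence[str]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Offspring-site pairs whose alt allele is absent from both parents.

    An allele is "present" in a genotype when its VAF >= ``genotype_vaf``;
    a candidate needs >= ``min_alt_reads`` supporting reads in the offspring.
    Sites missing a parent record are skipped with a logged warning.

    Returns a DataFrame with columns site_id, chrom, pos, ref, alt, animal
    (the violating offspring) and offspring_vaf.
    """
    required = {"site_id", "animal", "depth", "alt_depth"}
    if not required.issubset(sites.columns):
        raise ValueError(f"site table missing columns {required - set(sites.columns)}")
    depth = sites.pivot_table(index="site_id", columns="animal", values="depth", aggfunc="first")
    alt = sites.pivot_table(index="site_id", columns="animal", values="alt_depth", aggfunc="first")
    missing_parent = [p for p in parents if p not in depth.columns]
    if missing_parent:
        raise ValueError(f"no records at all for parent(s) {missing_parent}")
    if offspring is None:
        offspring = [a for a in depth.columns if a not in parents]

    parent_ok = pd.Series(True, index=depth.index)
    for p in parents:
        obs = depth[p].notna()
        if not obs.all():
            logger.warning("skipping %d sites with missing %s record", (~obs).sum(), p)
        with np.errstate(invalid="ignore", divide="ignore"):
            pvaf = alt[p] / depth[p]
        parent_ok &= obs & (pvaf.fillna(1.0) < config.genotype_vaf)

    meta = sites.drop_duplicates("site_id").set_index("site_id")[["chrom", "pos", "ref", "alt"]]
    rows = []
    for child in offspring:
        if child not in depth.columns:
            continue
        d = depth[child]
        a = alt[child]
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = (a / d).fillna(0.0)
        hit = parent_ok & d.notna() & (a >= config.min_alt_reads)
        for site_id in depth.index[hit]:
            m = meta.loc[site_id]
            rows.append(
                dict(site_id=site_id, chrom=m["chrom"], pos=int(m["pos"]), ref=m["ref"],
                     alt=m["alt"], animal=child, offspring_vaf=float(vaf.loc[site_id]))
            )
    out = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "ref", "alt", "animal", "offspring_vaf"])
    return out.sort_values(["site_id", "animal"]).reset_index(drop=True)


def apply_filter_cascade(
    obs: SiteObservation,
    offspring: str,
    repeat_mask: Optional[IntervalSet] = None,
    parents: Sequence[str] = PARENTS,
    config: ScreenConfig = ScreenConfig(),
) -> FilterVerdict:
    """Evaluate every discovery criterion independently for one candidate.

    Flags: ``parent_vaf`` (< 5% in each parent), ``offspring_vaf`` (> 25% in
    the violating offspring), ``mq0`` (<= 0.1 in every animal), ``depth``
    (>= 7 in every animal; zero depth fails here, never divides), the
    ``strand_bias`` Fisher test on the offspring's strand counts (P > 0.05),
    and ``repeat_region`` (position outside the mask).
    """
    child = obs.records[offspring]
    verdict = FilterVerdict()
    verdict.flags["parent_vaf"] = all(
        obs.records[p].depth > 0 and obs.records[p].vaf < config.parent_vaf_max for p in parents
    )
    verdict.flags["offspring_vaf"] = child.depth > 0 and child.vaf > config.offspring_vaf_min
    verdict.flags["mq0"] = all(r.mq0_fraction <= config.mq0_max for r in obs.records.values())
    verdict.flags["depth"] = all(r.depth >= config.min_depth for r in obs.records.values())
    verdict.flags["strand_bias"] = (
        strand_bias_p(child.fwd_ref, child.rev_ref, child.fwd_alt, child.rev_alt)
        > config.strand_p_min
    )
    verdict.flags["repeat_region"] = not (
        repeat_mask is not None and repeat_mask.contains(obs.chrom, obs.pos)
    )
    return verdict


def site_observation(sites: pd.DataFrame, site_id) -> SiteObservation:
    """Assemble a :class:`SiteObservation` for one site from a tidy table."""
    block = sites[sites["site_id"] == site_id]
    if block.empty:
        raise KeyError(f"site {site_id!r} not in table")
    first = block.iloc[0]
    records = {}
    for _, row in block.iterrows():
        records[row["animal"]] = AnimalSite(
            depth=int(row["depth"]), alt_depth=int(row["alt_depth"]),
            mq0_fraction=float(row.get("mq0_fraction", 0.0)),
            fwd_ref=int(row.get("fwd_ref", 0)), rev_ref=int(row.get("rev_ref", 0)),
            fwd_alt=int(row.get("fwd_alt", 0)), rev_alt=int(row.get("rev_alt", 0)),
        )
    return SiteObservation(chrom=str(first["chrom"]), pos=int(first["pos"]),
                           ref=str(first["ref"]), alt=str(first["alt"]), records=records)


def screen_quintet(
    sites: pd.DataFrame,
    repeat_mask: Optional[IntervalSet] = None,
    parents: Sequence[str] = PARENTS,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Full discovery screen: Mendelian violations + filter cascade.

    Returns the candidate table with one boolean ``pass_<criterion>`` column
    per filter flag and a ``pass_all`` column.
    """
    candidates = find_mendelian_violations(sites, parents=parents, config=config)
    flag_names = ["parent_vaf", "offspring_vaf", "mq0", "depth", "strand_bias", "repeat_region"]
    flag_rows = []
    for _, cand in candidates.iterrows():
        obs = site_observation(sites, cand["site_id"])
        verdict = apply_filter_cascade(obs, cand["animal"], repeat_mask, parents, config)
        flag_rows.append([verdict.flags[f] for f in flag_names] + [verdict.overall])
    flags = pd.DataFrame(
        flag_rows, columns=[f"pass_{f}" for f in flag_names] + ["pass_all"],
        index=candidates.index,
    )
    return pd.concat([candidates, flags], axis=1)
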