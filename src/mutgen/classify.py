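"""Origin classification of validated variants from deep re-sequencing VAFs.

After targeted re-sequencing (depth >= 20 expected in every family member),
each candidate receives exactly one origin class from a decision tree over
the family's validation VAFs:

* parent VAF >= 0.35                -> inherited
* parent VAF in [0.05, 0.35)        -> somatic mosaic in that parent
* shared by >= 2 siblings,
  parents below the somatic floor   -> parental germline mosaic
* single carrier, VAF >= 0.39       -> de novo (fixed in the gamete)
* single carrier, VAF in [0.10,0.39)-> early embryonic (post-zygotic mosaic)
* VAF < 0.10                        -> false positive

Only the 0.39 de novo/embryonic cut comes from the study's stated validation
rule; the remaining cutoffs (0.35, 0.05, 0.10, min_links 3) are package
defaults exposed in :class:`ClassifyConfig`.

Embryonic events are assigned a mutant-cell count under the three-cell
founder model: three cells of the 64-cell embryo found the animal, i.e. six
haploid genomes, so a mosaic arising in 1, 2 or 3 of those cells is expected
at VAF 1/6, 2/6 or 3/6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from scipy import stats as sps

__all__ = [
    "ClassifyConfig",
    "ClassifiedVariant",
    "classify_origin",
    "embryonic_cell_count",
    "phase_parental_origin",
    "detect_clustered_mutations",
    "MutationCluster",
]

ORIGIN_CLASSES = (
    "de_novo", "embryonic", "germline_mosaic", "somatic_mosaic_parent",
    "inherited", "false_positive",
)

_LINEAGE_FRACTIONS = (1.0 / 6.0, 2.0 / 6.0, 3.0 / 6.0)


@dataclass(frozen=True)
class ClassifyConfig:
    inherited_vaf: float = 0.35       # parent at/above this is a constitutive carrier
    somatic_floor: float = 0.05       # parent in [floor, inherited) is a somatic mosaic
    fp_floor: float = 0.10            # offspring below this is a false positive
    de_novo_vaf: float = 0.39         # offspring at/above this is de novo
    sibling_carrier_vaf: float = 0.20 # sibling counted as sharing the variant
    min_links: int = 3                # phased reads required to call parental origin
    min_validation_depth: int = 20    # re-sequencing contract


@dataclass
class ClassifiedVariant:
    """A validated mutation with its origin call."""

    origin_class: str
    offspring_vaf: float
    carrier_offspring: Tuple[str, ...] = ()
    embryonic_cell_count: Optional[int] = None
    parental_origin: str = "unknown"
    caveats: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.origin_class not in ORIGIN_CLASSES:
            raise ValueError(f"unknown origin class {self.origin_class!r}")
        if (self.embryonic_cell_count is not None) != (self.origin_class == "embryonic"):
            raise ValueError("embryonic_cell_count present iff origin_class == 'embryonic'")


def embryonic_cell_count(vaf: float) -> int:
    """Mutant founder cells (1-3) nearest to a mosaic VAF; ties go lower.

    Under the three-cell founder model the expected VAFs are 1/6, 2/6 and
    3/6; a VAF equidistant between two fractions (e.g. 0.25) takes the lower
    cell count.
    """
    if not 0 < vaf <= 0.6:
        raise ValueError(f"embryonic VAF must lie in (0, 0.6], got {vaf}")
    dists = [abs(vaf - f) for f in _LINEAGE_FRACTIONS]
    best = min(dists)
    for i, d in enumerate(dists):  # first (lowest count) at the minimum wins ties
        if d <= best + 1e-12:
            return i + 1
    raise AssertionError("unreachable")


def classify_origin(
    offspring_vaf: float,
    sire_vaf: float,
    dam_vaf: float,
    sibling_vafs: Optional[Sequence[float]] = None,
    offspring: str = "offspring",
    depths: Optional[Dict[str, int]] = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> ClassifiedVariant:
    """Assign exactly one origin class from validation VAFs.

    ``sibling_vafs=None`` means the siblings were not re-sequenced: the
    germline-mosaic branch is then undecidable and the result carries a
    ``siblings_unobserved`` caveat.
    """
    caveats: List[str] = []
    if depths is not None:
        low = [a for a, d in depths.items() if d < config.min_validation_depth]
        if low:
            caveats.append(f"validation depth < {config.min_validation_depth}: {','.join(sorted(low))}")

    parent_vaf = max(sire_vaf, dam_vaf)
    cls: str
    cell_count: Optional[int] = None
    carriers: Tuple[str, ...] = (offspring,)

    if parent_vaf >= config.inherited_vaf:
        cls = "inherited"
    elif parent_vaf >= config.somatic_floor:
        cls = "somatic_mosaic_parent"
    else:
        shared = 0
        if sibling_vafs is None:
            caveats.append("siblings_unobserved")
        else:
            shared = sum(v >= config.sibling_carrier_vaf for v in sibling_vafs)
        if shared >= 1:
            cls = "germline_mosaic"
            carriers = (offspring,) + tuple(f"sibling_{i + 1}" for i in range(shared))
        elif offspring_vaf >= config.de_novo_vaf:
            cls = "de_novo"
        elif offspring_vaf >= config.fp_floor:
            cls = "embryonic"
            cell_count = embryonic_cell_count(offspring_vaf)
        else:
            cls = "false_positive"
            carriers = ()
    return ClassifiedVariant(
        origin_class=cls, offspring_vaf=offspring_vaf, carrier_offspring=carriers,
        embryonic_cell_count=cell_count, caveats=caveats,
    )


def phase_parental_origin(
    sire_links: int,
    dam_links: int,
    min_links: int = 3,
) -> Tuple[str, List[str]]:
    """Parental origin from read linkage to strain-informative markers.

    A mutation is called paternal when >= ``min_links`` mutant reads link to
    the sire haplotype and none conflict (symmetrically maternal); anything
    else is unknown, with a ``conflicting_links`` caveat when reads link both
    ways.
    """
    if sire_links < 0 or dam_links < 0:
        raise ValueError("link counts must be non-negative")
    caveats: List[str] = []
    if sire_links > 0 and dam_links > 0:
        caveats.append("conflicting_links")
        return "unknown", caveats
    if sire_links >= min_links and dam_links == 0:
        return "paternal", caveats
    if dam_links >= min_links and sire_links == 0:
        return "maternal", caveats
    return "unknown", caveats


@dataclass
class MutationCluster:
    animal: str
    chrom: str
    positions: Tuple[int, ...]
    span_bp: int
    p_uniform: float

    @property
    def size(self) -> int:
        return len(self.positions)


def detect_clustered_mutations(
    variants: pd.DataFrame,
    window_bp: int,
    genome_bp: float,
) -> List[MutationCluster]:
    """Maximal same-animal runs of variants with consecutive gaps <= window.

    ``variants`` needs columns animal, chrom, pos. Each cluster is annotated
    with an approximate probability of arising under uniform placement of
    that animal's n genome-wide variants: for a cluster of k variants,
    p ~= n * P(Binomial(n-1, window_bp / genome_bp) >= k-1), the expected
    number of variants anchoring such a window (a union-bound style figure of
    merit, not an exact test).
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    clusters: List[MutationCluster] = []
    for animal, sub in variants.groupby("animal"):
        n = len(sub)
        if n < 2:
            continue
        p_in = min(1.0, window_bp / genome_bp)
        for chrom, per_chrom in sub.groupby("chrom"):
            pos = np.sort(per_chrom["pos"].to_numpy())
            if len(pos) < 2:
                continue
            run = [int(pos[0])]
            for p in pos[1:]:
                if p - run[-1] <= window_bp:
                    run.append(int(p))
                else:
                    if len(run) >= 2:
                        clusters.append(_make_cluster(animal, chrom, run, n, p_in))
                    run = [int(p)]
            if len(run) >= 2:
                clusters.append(_make_cluster(animal, chrom, run, n, p_in))
    return clusters


def _make_cluster(animal, chrom, run, n, p_in) -> MutationCluster:
    k = len(run)
    p = min(1.0, n * float(sps.binom.sf(k - 2, n - 1, p_in)))
    return MutationCluster(
        animal=str(animal), chrom=str(chrom), positions=tuple(run),
        span_bp=run[-1] - run[0], p_uniform=p,
    )
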