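"""Synthetic family quintets, aCGH probe series and breakpoint junctions.

The generator emulates the study design: a family quintet (sire, dam and
three offspring) sequenced to ~31x mean autosomal coverage, with injected
mutations at their lineage-model allele fractions (de novo at VAF 0.5,
early-embryonic mosaics at 1/6, 2/6 or 3/6, parental germline mosaics shared
between siblings, sub-heterozygous parental somatic mosaics and inherited
heterozygous variants); probe-level aCGH series at ~3 kb spacing carrying
duplications (log2 3/2), heterozygous deletions (log2 1/2) and attenuated
mosaic CNVs (log2((2 +/- f)/2)); and rearrangement junction sequences with
0-6 bp of exact microhomology.

Every simulation is a pure function of its seed: identical configs produce
byte-identical outputs. Depths are Poisson around the mean (the standard
shotgun approximation), alt reads are binomial at the carrier's true VAF
folded with the per-base error rate, strand counts split 50/50 binomially
unless a bias is requested, and each alt read at a mutation site links to
the phase of the nearest informative marker with probability ``link_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .breakpoints import JunctionEvidence

__all__ = [
    "InjectionSpec",
    "AcghCnvSpec",
    "AcghConfig",
    "SimulationConfig",
    "simulate_quintet",
    "simulate_acgh",
    "simulate_junction",
]

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))  # mouse autosomes
CHROM_LEN = 120_000_000  # uniform toy chromosome length, bp

_EMBRYONIC_VAFS = (1.0 / 6.0, 2.0 / 6.0, 3.0 / 6.0)
INJECTION_KINDS = (
    "de_novo", "embryonic", "germline_mosaic_parent", "somatic_mosaic_parent", "inherited",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class InjectionSpec:
    """One mutation to inject into a quintet.

    ``carriers`` are offspring ids (two or more siblings for a parental
    germline mosaic); ``true_vaf`` defaults to the kind's lineage value
    (0.5 for de novo / germline-mosaic carriers / inherited). For a parental
    somatic mosaic, ``parent_vaf`` is the sub-heterozygous fraction in the
    carrier parent's tissue while the offspring carries the variant at 0.5.
    """

    kind: str
    carriers: Tuple[str, ...] = ("offspring_1",)
    true_vaf: float = 0.5
    parental_origin: str = "paternal"
    parent_vaf: float = 0.20  # somatic_mosaic_parent only

    def __post_init__(self):
        if self.kind not in INJECTION_KINDS:
            raise ValueError(f"unknown injection kind {self.kind!r}")
        if self.kind == "embryonic":
            if not any(abs(self.true_vaf - v) < 1e-9 for v in _EMBRYONIC_VAFS):
                raise ValueError("embryonic true_vaf must be one of 1/6, 2/6, 3/6")
        if self.kind == "germline_mosaic_parent" and len(self.carriers) < 2:
            raise ValueError("germline mosaic needs >= 2 sibling carriers")
        if self.parental_origin not in ("paternal", "maternal"):
            raise ValueError("parental_origin must be paternal or maternal")


@dataclass(frozen=True)
class AcghCnvSpec:
    """One CNV to inject into an offspring's probe series."""

    animal: str
    chrom: str
    start: int        # bp of first affected probe region
    length: int       # bp
    kind: str         # duplication | deletion | mosaic_duplication | mosaic_deletion
    fraction: float = 1.0  # mosaic cell fraction; 1.0 = constitutive
    event_id: Optional[str] = None

    @property
    def copies_log2(self) -> float:
        """Expected log2 ratio: log2((2 + f*dcopy)/2)."""
        dcopy = {"duplication": 1.0, "mosaic_duplication": 1.0,
                 "deletion": -1.0, "mosaic_deletion": -1.0}[self.kind]
        return float(np.log2((2.0 + self.fraction * dcopy) / 2.0))


@dataclass(frozen=True)
class AcghConfig:
    probe_spacing: int = 3000   # bp between probes (study average ~3 kb)
    n_probes: int = 2000        # probes per simulated chromosome
    noise_sd: float = 0.15      # per-probe Gaussian log2 noise
    cnvs: Tuple[AcghCnvSpec, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated quintet."""

    seed: int = 0
    n_offspring: int = 3
    mean_depth: float = 31.0          # study's ~31x autosomal coverage
    error_rate: float = 1e-3          # per-base miscall probability
    n_sites: int = 1000               # background (non-injected) sites
    informative_marker_rate: float = 0.01  # background sites carrying strain alleles
    injected: Tuple[InjectionSpec, ...] = ()
    link_rate: float = 0.8            # alt read phased to nearest marker
    mislink_rate: float = 0.0         # alt read linking to the wrong haplotype
    strand_bias: float = 0.5          # P(alt read on forward strand)
    mq0_contam_rate: float = 0.0      # sites given an elevated MQ0 fraction
    validation_depth: int = 300       # targeted re-sequencing depth
    acgh: AcghConfig = AcghConfig()

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.n_offspring < 1:
            raise ValueError("need at least one offspring")

    @property
    def offspring(self) -> Tuple[str, ...]:
        return tuple(f"offspring_{i + 1}" for i in range(self.n_offspring))

    @property
    def animals(self) -> Tuple[str, ...]:
        return ("sire", "dam") + self.offspring


def _true_vafs(spec: InjectionSpec, animals: Sequence[str]) -> Dict[str, float]:
    """Per-animal true allele fraction for one injection."""
    vafs = {a: 0.0 for a in animals}
    if spec.kind == "de_novo":
        for c in spec.carriers:
            vafs[c] = spec.true_vaf
    elif spec.kind == "embryonic":
        for c in spec.carriers:
            vafs[c] = spec.true_vaf
    elif spec.kind == "germline_mosaic_parent":
        for c in spec.carriers:
            vafs[c] = 0.5  # carriers inherit a full heterozygous allele
    elif spec.kind == "somatic_mosaic_parent":
        parent = "sire" if spec.parental_origin == "paternal" else "dam"
        vafs[parent] = spec.parent_vaf
        for c in spec.carriers:
            vafs[c] = 0.5
    elif spec.kind == "inherited":
        parent = "sire" if spec.parental_origin == "paternal" else "dam"
        vafs[parent] = 0.5
        for c in spec.carriers:
            vafs[c] = 0.5
    return vafs


def simulate_quintet(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-site allelic depths for one family quintet.

    Returns ``(sites, truth)``. ``sites`` is a tidy frame with one row per
    (site, animal): site_id, chrom, pos, ref, alt, context, is_marker,
    animal, depth, alt_depth, fwd_ref/rev_ref/fwd_alt/rev_alt, mq0_fraction,
    sire_links, dam_links, validation_depth, validation_alt. ``truth``
    records every injection (site_id, kind, true_vaf, carriers,
    parental_origin, cell_count).

    Validation columns re-draw the same true VAFs at ``validation_depth``,
    emulating the targeted re-sequencing arm of the study.
    """
    rng = np.random.default_rng(config.seed)
    animals = config.animals
    bad = [c for spec in config.injected for c in spec.carriers if c not in animals]
    if bad:
        raise ValueError(f"carriers not in quintet: {sorted(set(bad))}")

    n_inj = len(config.injected)
    n_total = config.n_sites + n_inj
    chroms = rng.choice(np.array(AUTOSOMES), size=n_total)
    pos = rng.integers(1, CHROM_LEN + 1, size=n_total)
    # avoid duplicate (chrom, pos) collisions deterministically
    seen = set()
    for i in range(n_total):
        while (chroms[i], pos[i]) in seen:
            pos[i] = rng.integers(1, CHROM_LEN + 1)
        seen.add((chroms[i], int(pos[i])))
    refs = _BASES[rng.integers(0, 4, size=n_total)]
    alt_shift = rng.integers(1, 4, size=n_total)
    alts = _BASES[(np.searchsorted(_BASES, refs) + alt_shift) % 4]
    flank5 = _BASES[rng.integers(0, 4, size=n_total)]
    flank3 = _BASES[rng.integers(0, 4, size=n_total)]
    contexts = np.char.add(np.char.add(flank5, refs), flank3)

    is_marker = np.zeros(n_total, dtype=bool)
    bg = np.arange(n_inj, n_total)
    n_markers = int(round(config.informative_marker_rate * config.n_sites))
    if n_markers:
        marker_idx = rng.choice(bg, size=n_markers, replace=False)
        is_marker[marker_idx] = True

    mq0 = np.zeros(n_total)
    if config.mq0_contam_rate > 0:
        contam = rng.random(n_total) < config.mq0_contam_rate
        mq0[contam] = rng.uniform(0.1, 0.5, size=contam.sum())

    # per-animal true VAF matrix
    vaf = np.zeros((n_total, len(animals)))
    truth_rows = []
    for i, spec in enumerate(config.injected):
        tv = _true_vafs(spec, animals)
        for j, a in enumerate(animals):
            vaf[i, j] = tv[a]
        truth_rows.append(
            dict(
                site_id=f"site_{i:06d}", chrom=chroms[i], pos=int(pos[i]),
                ref=refs[i], alt=alts[i], kind=spec.kind, true_vaf=spec.true_vaf,
                carriers=",".join(spec.carriers), parental_origin=spec.parental_origin,
                cell_count=(int(round(spec.true_vaf * 6)) if spec.kind == "embryonic" else pd.NA),
            )
        )
    # marker sites: sire heterozygous for the strain-informative allele
    sire_col = animals.index("sire")
    vaf[is_marker, sire_col] = 0.5

    err = config.error_rate
    p_alt = vaf * (1.0 - err) + (1.0 - vaf) * err

    depth = rng.poisson(config.mean_depth, size=(n_total, len(animals)))
    alt_depth = rng.binomial(depth, p_alt)
    fwd_alt = rng.binomial(alt_depth, config.strand_bias)
    ref_depth = depth - alt_depth
    fwd_ref = rng.binomial(ref_depth, 0.5)

    vdep = rng.poisson(config.validation_depth, size=(n_total, len(animals)))
    valt = rng.binomial(vdep, p_alt)

    # read-backed phasing links for injected sites
    sire_links = np.zeros((n_total, len(animals)), dtype=np.int64)
    dam_links = np.zeros_like(sire_links)
    for i, spec in enumerate(config.injected):
        for c in spec.carriers:
            j = animals.index(c)
            linked = rng.binomial(alt_depth[i, j], config.link_rate)
            wrong = rng.binomial(linked, config.mislink_rate)
            right = linked - wrong
            if spec.parental_origin == "paternal":
                sire_links[i, j], dam_links[i, j] = right, wrong
            else:
                dam_links[i, j], sire_links[i, j] = right, wrong

    site_ids = np.array([f"site_{i:06d}" for i in range(n_total)])
    frames = []
    for j, animal in enumerate(animals):
        frames.append(
            pd.DataFrame(
                dict(
                    site_id=site_ids, chrom=chroms, pos=pos, ref=refs, alt=alts,
                    context=contexts, is_marker=is_marker, animal=animal,
                    depth=depth[:, j], alt_depth=alt_depth[:, j],
                    fwd_ref=fwd_ref[:, j], rev_ref=ref_depth[:, j] - fwd_ref[:, j],
                    fwd_alt=fwd_alt[:, j], rev_alt=alt_depth[:, j] - fwd_alt[:, j],
                    mq0_fraction=mq0,
                    sire_links=sire_links[:, j], dam_links=dam_links[:, j],
                    validation_depth=vdep[:, j], validation_alt=valt[:, j],
                )
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["site_id", "animal"]).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["site_id", "chrom", "pos", "ref", "alt", "kind", "true_vaf",
                 "carriers", "parental_origin", "cell_count"],
    )
    return sites, truth


def simulate_acgh(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-offspring aCGH probe series with injected CNVs.

    Probes sit every ``probe_spacing`` bp; log2 = log2(copy/2) inside an
    injected CNV plus Gaussian noise, noise only elsewhere. A duplication
    adds one copy (log2 1.5 ~ 0.585), a heterozygous deletion removes one
    (log2 0.5 = -1), and a mosaic event in cell fraction f is attenuated to
    log2((2 +/- f)/2) - a half-mosaic duplication (f = 0.5) sits at
    log2(1.25) ~ 0.322, below the 0.4 calling threshold, so such events
    evade detection by design.

    Returns ``(probes, truth)``: probes tidy over (animal, chrom, pos,
    log2); truth lists each injected CNV with its expected log2 and probe
    count. Overlapping CNVs on one animal's chromosome are a configuration
    error; every CNV must span at least one probe spacing.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent stream from the quintet
    ac = config.acgh
    by_animal_chrom: Dict[Tuple[str, str], List[AcghCnvSpec]] = {}
    for spec in ac.cnvs:
        if spec.length < ac.probe_spacing:
            raise ValueError("CNV length must be >= probe spacing")
        key = (spec.animal, spec.chrom)
        for other in by_animal_chrom.get(key, []):
            if spec.start <= other.start + other.length - 1 and other.start <= spec.start + spec.length - 1:
                raise ValueError(f"overlapping injected CNVs on {key}")
        by_animal_chrom.setdefault(key, []).append(spec)

    animals = sorted({s.animal for s in ac.cnvs}) or list(config.offspring)
    chroms_needed = sorted({s.chrom for s in ac.cnvs}) or ["chr1"]
    positions = np.arange(1, ac.n_probes + 1) * ac.probe_spacing
    frames = []
    truth_rows = []
    for animal in animals:
        for chrom in chroms_needed:
            log2 = rng.normal(0.0, ac.noise_sd, size=ac.n_probes)
            for spec in by_animal_chrom.get((animal, chrom), []):
                inside = (positions >= spec.start) & (positions <= spec.start + spec.length - 1)
                log2[inside] += spec.copies_log2
                truth_rows.append(
                    dict(animal=animal, chrom=chrom, start=int(spec.start),
                         end=int(spec.start + spec.length - 1), kind=spec.kind,
                         fraction=spec.fraction, expected_log2=spec.copies_log2,
                         n_probes=int(inside.sum()), event_id=spec.event_id)
                )
            frames.append(pd.DataFrame(dict(animal=animal, chrom=chrom, pos=positions, log2=log2)))
    probes = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["animal", "chrom", "start", "end", "kind", "fraction",
                 "expected_log2", "n_probes", "event_id"],
    )
    return probes, truth


def simulate_junction(
    mh_len: int,
    event: str = "insertional",
    seed: int = 0,
    flank_len: int = 50,
    insert_len: int = 0,
) -> JunctionEvidence:
    """Generate a breakpoint junction with known microhomology.

    The donor and acceptor flanks share exactly ``mh_len`` identical bases
    at the join (microhomology), and the junction read carries them once.
    ``insert_len`` > 0 instead produces a blunt junction with inserted
    bases (mutually exclusive with microhomology). ``event`` selects the
    structural context: "tandem" (same-chromosome head-to-tail),
    "insertional" (different chromosomes), "deletion", or "inverted".
    """
    if not 0 <= mh_len <= 6:
        raise ValueError("microhomology length must lie in 0..6")
    if mh_len > flank_len:
        raise ValueError("microhomology cannot exceed the flank length")
    if mh_len and insert_len:
        raise ValueError("microhomology and inserted bases are mutually exclusive")
    if event not in ("tandem", "insertional", "deletion", "inverted"):
        raise ValueError(f"unknown event type {event!r}")
    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return "".join(_BASES[rng.integers(0, 4, size=n)])

    donor = rand_seq(flank_len)
    rest = rand_seq(flank_len - mh_len)
    # the first mh_len acceptor bases are the homologous bases shared with
    # the donor end; the junction length then pins the overlap exactly
    acceptor = donor[-mh_len:] + rest if mh_len else rest
    inserted = rand_seq(insert_len) if insert_len else ""
    junction = donor + inserted + acceptor[mh_len:]

    if event == "insertional":
        donor_chrom, acceptor_chrom = "chr16", "chr2"
    elif event == "inverted":
        donor_chrom = acceptor_chrom = "chr5"
    else:
        donor_chrom = acceptor_chrom = "chr10"
    return JunctionEvidence(
        donor_flank=donor, acceptor_flank=acceptor, junction=junction,
        donor_chrom=donor_chrom, donor_pos=int(rng.integers(1, CHROM_LEN)),
        acceptor_chrom=acceptor_chrom, acceptor_pos=int(rng.integers(1, CHROM_LEN)),
        orientation="inverted" if event == "inverted" else "head_to_tail",
        inserted=inserted, mh_len=mh_len,
    )
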