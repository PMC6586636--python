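"""CNV breakpoint characterization: microhomology, structural class and
parental origin.

A rearrangement junction joins a donor segment (sequence retained up to the
donor breakpoint) to an acceptor segment (sequence retained from the
acceptor breakpoint on). Microhomology is the maximal *exact* overlap shared
by both parental sequences at the join - the hallmark of
microhomology-mediated break-induced replication (MMBIR), which produced the
1-6 bp homologies seen at heritable CNV junctions. Inserted bases and
microhomology are mutually exclusive at a single junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "JunctionEvidence",
    "MicrohomologyResult",
    "microhomology_length",
    "classify_structure",
    "cnv_parental_origin",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


@dataclass
class JunctionEvidence:
    """Split-read evidence for one rearrangement junction.

    ``donor_flank`` ends at the donor breakpoint (including any homologous
    bases); ``acceptor_flank`` starts at the acceptor breakpoint (also
    including them). ``junction`` is the observed split-read sequence across
    the join. ``orientation`` is the discordant-pair orientation
    ("head_to_tail" or "inverted").
    """

    donor_flank: str
    acceptor_flank: str
    junction: str
    donor_chrom: str = "chrUn"
    donor_pos: int = 0
    acceptor_chrom: str = "chrUn"
    acceptor_pos: int = 0
    orientation: str = "head_to_tail"
    inserted: str = ""
    mh_len: Optional[int] = None  # ground truth when simulated
    acceptor_ambiguous: bool = False  # acceptor maps to multiple loci (repeats)


@dataclass
class MicrohomologyResult:
    length: int
    inserted: str
    aligned: bool
    caveats: List[str] = field(default_factory=list)


def microhomology_length(
    donor_flank: str, acceptor_flank: str, junction: str
) -> MicrohomologyResult:
    """Microhomology (bp) at a junction, or the inserted bases if any.

    The junction must decompose as ``donor_flank + acceptor_flank`` with the
    shared overlap written once (microhomology >= 0), or as
    ``donor_flank + inserted + acceptor_flank`` (blunt join with templated /
    untemplated insertion). The overlap length is fixed by the sequence
    lengths and verified base-by-base: the overlapping bases must be
    identical in both parental flanks and in the junction read. A junction
    that does not decompose returns ``aligned=False`` with an
    ``alignment_error`` caveat. Symmetric under exchanging donor and
    acceptor roles (with reverse complement).
    """
    d, a, j = donor_flank.upper(), acceptor_flank.upper(), junction.upper()
    if not d or not a or not j:
        raise ValueError("flanks and junction must be non-empty")
    overlap = len(d) + len(a) - len(j)
    bad = MicrohomologyResult(0, "", False, ["alignment_error"])
    if overlap > min(len(d), len(a)):
        return bad
    if overlap >= 0:
        if j != d + a[overlap:]:
            return bad
        if overlap > 0 and d[-overlap:] != a[:overlap]:
            return bad
        return MicrohomologyResult(length=overlap, inserted="", aligned=True)
    ins_len = -overlap
    if not (j.startswith(d) and j.endswith(a)):
        return bad
    inserted = j[len(d) : len(d) + ins_len]
    return MicrohomologyResult(length=0, inserted=inserted, aligned=True)


def classify_structure(
    call_kind: str,
    junctions: Sequence[JunctionEvidence],
    min_insert_complex: int = 10,
) -> Tuple[str, List[str]]:
    """Structural class of a CNV from its junction evidence.

    A same-chromosome head-to-tail join is a tandem duplication (or a simple
    deletion when the call is a loss); a join onto a different chromosome or
    locus is an insertional duplication; inverted discordant-pair
    orientation or an inserted fragment >= ``min_insert_complex`` bp marks a
    complex event. Junctions disagreeing with each other fall back to
    complex with a caveat. Invariant to reverse-complementing all junction
    sequences (orientation and loci carry the structural information).
    """
    if not junctions:
        raise ValueError("need >= 1 junction per call")
    caveats: List[str] = []
    votes = []
    for jn in junctions:
        if jn.orientation == "inverted" or len(jn.inserted) >= min_insert_complex:
            votes.append("complex")
        elif jn.donor_chrom != jn.acceptor_chrom:
            votes.append("insertional")
        else:
            votes.append("deletion" if call_kind == "deletion" else "tandem_duplication")
        if jn.acceptor_ambiguous:
            caveats.append("acceptor_ambiguous")
    if "complex" in votes:
        if len(set(votes)) > 1:
            caveats.append("inconsistent_junctions")
        return "complex", caveats
    if len(set(votes)) > 1:
        caveats.append("inconsistent_junctions")
        return "complex", caveats
    return votes[0], caveats


def cnv_parental_origin(
    sire_allele_reads: int,
    total_reads: int,
    n_informative_sites: int,
    kind: str = "duplication",
    min_sites: int = 5,
    bayes_factor: float = 1.0,
) -> Tuple[str, Dict[str, float]]:
    """Parental origin of a CNV from strain-informative allele fractions.

    For a heterozygous duplication the duplicated haplotype's alleles rise
    to an expected fraction of 2/3 (the other parent's fall to 1/3); for a
    deletion the deleted haplotype's alleles drop out. The call is a
    binomial likelihood comparison among {paternal, maternal, no-change}
    hypotheses on the pooled sire-allele count: the parent whose allele is
    enriched is called when its hypothesis beats the runner-up by at least
    ``bayes_factor`` (default 1, i.e. a maximum-likelihood decision; raise
    it for a conservative caller). Fewer than ``min_sites`` informative
    sites, a balanced fraction, or insufficient evidence returns "unknown".
    """
    if not 0 <= sire_allele_reads <= total_reads:
        raise ValueError("need 0 <= sire_allele_reads <= total_reads")
    if n_informative_sites < min_sites or total_reads == 0:
        return "unknown", {}
    if kind == "duplication":
        hyps = {"paternal": 2.0 / 3.0, "maternal": 1.0 / 3.0, "none": 0.5}
    elif kind == "deletion":
        # losing the paternal allele leaves (almost) only maternal reads
        eps = 0.02  # residual mismapping / noise
        hyps = {"paternal": eps, "maternal": 1.0 - eps, "none": 0.5}
    else:
        raise ValueError(f"kind must be duplication/deletion, got {kind!r}")
    logl = {
        h: float(sps.binom.logpmf(sire_allele_reads, total_reads, p))
        for h, p in hyps.items()
    }
    ranked = sorted(logl.items(), key=lambda kv: kv[1], reverse=True)
    best, second = ranked[0], ranked[1]
    if best[1] - second[1] < np.log(bayes_factor) - 1e-12 or best[0] == "none":
        return "unknown", logl
    if best[1] == second[1]:  # exact likelihood tie: no decision
        return "unknown", logl
    return best[0], logl
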