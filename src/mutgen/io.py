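"""Standard-format IO: VCF v4.2, BED, TSV site/probe tables, FASTA.

Internal coordinates are 1-based inclusive everywhere; BED (0-based
half-open) is converted at this boundary and nowhere else. VCF is written as
v4.2 text with per-animal DP/AD plus strand (ADF/ADR) and MQ0 fraction
(MQ0F) FORMAT fields and read back through pysam.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import IntervalSet
from .simulate import AUTOSOMES, CHROM_LEN

__all__ = [
    "read_intervals",
    "write_bed",
    "read_variants",
    "write_site_vcf",
    "write_site_tsv",
    "read_site_tsv",
    "write_probes_tsv",
    "read_probes_tsv",
    "write_fasta",
    "read_fasta",
    "write_json_report",
]

_VCF_SITE_COLUMNS = [
    "site_id", "chrom", "pos", "ref", "alt", "animal", "depth", "alt_depth",
    "fwd_ref", "rev_ref", "fwd_alt", "rev_alt", "mq0_fraction",
]


# -- BED ------------------------------------------------------------------

def read_intervals(path) -> IntervalSet:
    """Read a BED file (0-based half-open) into a 1-based inclusive set."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED start {start} >= end {end}")
            intervals.append((chrom, start + 1, end))  # to 1-based inclusive
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path, name: Optional[str] = None) -> None:
    """Write 1-based inclusive intervals back out as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            row = [chrom, str(start - 1), str(end)]
            if name:
                row.append(name)
            fh.write("\t".join(row) + "\n")


# -- site tables ----------------------------------------------------------

def write_site_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_site_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "animal": str})


def write_site_vcf(sites: pd.DataFrame, path, contig_len: int = CHROM_LEN) -> None:
    """Write a tidy site table as VCF v4.2 with DP/AD/ADF/ADR/MQ0F FORMAT."""
    animals = sorted(sites["animal"].unique())
    header = [
        "##fileformat=VCFv4.2",
        "##source=mutgen",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (unphased, from VAF)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand allelic depths">',
        '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand allelic depths">',
        '##FORMAT=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of MQ0 reads">',
    ]
    chroms = sorted(sites["chrom"].unique(), key=lambda c: (len(c), c))
    for c in chroms:
        header.append(f"##contig=<ID={c},length={contig_len}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(animals))

    def gt(vaf: float) -> str:
        if vaf >= 0.8:
            return "1/1"
        if vaf >= 0.2:
            return "0/1"
        return "0/0"

    lines = []
    meta_cols = ["chrom", "pos", "ref", "alt"]
    for site_id, block in sites.groupby("site_id", sort=True):
        first = block.iloc[0]
        recs = block.set_index("animal")
        fields = []
        for a in animals:
            if a not in recs.index:
                fields.append("./.:.:.:.:.:.")
                continue
            r = recs.loc[a]
            dp, ad = int(r["depth"]), int(r["alt_depth"])
            vaf = ad / dp if dp else 0.0
            fields.append(
                f"{gt(vaf)}:{dp}:{dp - ad},{ad}:{int(r['fwd_ref'])},{int(r['fwd_alt'])}:"
                f"{int(r['rev_ref'])},{int(r['rev_alt'])}:{float(r['mq0_fraction']):.4g}"
            )
        lines.append(
            f"{first['chrom']}\t{int(first['pos'])}\t{site_id}\t{first['ref']}\t{first['alt']}"
            f"\t.\t.\t.\tGT:DP:AD:ADF:ADR:MQ0F\t" + "\t".join(fields)
        )
    # VCF records must be coordinate-sorted within each contig block
    lines.sort(key=lambda l: ((len(l.split("\t")[0]), l.split("\t")[0]), int(l.split("\t")[1])))
    Path(path).write_text("\n".join(header + lines) + "\n")


def read_variants(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a VCF or TSV site table into the tidy per-(site, animal) frame.

    ``fmt`` is inferred from the suffix when omitted. Coordinates come back
    1-based inclusive; VCF FORMAT DP/AD map to depth/alt_depth, ADF/ADR to
    the strand counts and MQ0F to the MQ0 fraction.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "tsv":
        return read_site_tsv(path)
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for lineno, rec in enumerate(vf.fetch() if vf.index else vf):
            if not rec.alts:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} has no ALT")
            site_id = rec.id or f"{rec.chrom}:{rec.pos}"
            for animal in rec.samples:
                s = rec.samples[animal]
                if s.get("DP") is None:
                    continue
                ad = s.get("AD") or (0, 0)
                adf = s.get("ADF") or (0, 0)
                adr = s.get("ADR") or (0, 0)
                rows.append(
                    dict(
                        site_id=site_id, chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                        alt=rec.alts[0], animal=animal, depth=int(s["DP"]),
                        alt_depth=int(ad[1]), fwd_ref=int(adf[0]), fwd_alt=int(adf[1]),
                        rev_ref=int(adr[0]), rev_alt=int(adr[1]),
                        mq0_fraction=float(s.get("MQ0F") or 0.0),
                    )
                )
    df = pd.DataFrame(rows, columns=_VCF_SITE_COLUMNS)
    return df.sort_values(["site_id", "animal"]).reset_index(drop=True)


# -- probes / FASTA / reports --------------------------------------------

def write_probes_tsv(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json_report(report: dict, path, seed: Optional[int] = None) -> None:
    """Write a JSON report stamped with the seed and a config hash for provenance."""
    payload = dict(report)
    if seed is not None:
        payload["_provenance"] = {
            "seed": seed,
            "report_hash": hashlib.sha256(
                json.dumps(report, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
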