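"""End-to-end pipeline driver: simulate -> screen -> classify -> rates ->
spectra -> CNV -> breakpoints -> report.

Runs the whole analysis on synthetic cohorts whose defaults mirror the study
design (two sequenced families per exposure group at ~31x, aCGH cohorts of
171/83/98 offspring), and emits a frequency-table-style report together with
truth-vs-called confusion matrices. Deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import classify as clf
from . import io as mio
from .breakpoints import classify_structure, cnv_parental_origin, microhomology_length
from .cnv import CnvCall, assign_cnv_status, cnv_frequencies, filter_recurrent, segment_cnvs
from .config import PipelineConfig
from .rates import mutation_frequency, rate_and_ratio
from .screen import screen_quintet
from .simulate import (AUTOSOMES, AcghCnvSpec, AcghConfig, InjectionSpec,
                       SimulationConfig, simulate_acgh, simulate_junction)
from .spectra import build_spectrum, spectrum_difference_test, split_affected
from .stats import gee_poisson, sidak_stepdown
from .simulate import simulate_quintet

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_family_injections", "classify_candidates"]

_EMBRYONIC_CHOICES = (1.0 / 6.0, 2.0 / 6.0, 3.0 / 6.0)


def simulate_family_injections(
    n_offspring: int,
    de_novo_mean: float,
    embryonic_mean: float,
    paternal_fraction: float,
    rng: np.random.Generator,
) -> Tuple[InjectionSpec, ...]:
    """Draw per-offspring Poisson mutation loads as injection specs."""
    specs: List[InjectionSpec] = []
    for j in range(1, n_offspring + 1):
        child = f"offspring_{j}"
        for _ in range(rng.poisson(de_novo_mean)):
            origin = "paternal" if rng.random() < paternal_fraction else "maternal"
            specs.append(InjectionSpec(kind="de_novo", carriers=(child,), true_vaf=0.5,
                                       parental_origin=origin))
        for _ in range(rng.poisson(embryonic_mean)):
            vaf = _EMBRYONIC_CHOICES[rng.integers(0, 3)]
            origin = "paternal" if rng.random() < paternal_fraction else "maternal"
            specs.append(InjectionSpec(kind="embryonic", carriers=(child,), true_vaf=vaf,
                                       parental_origin=origin))
    return tuple(specs)


def classify_candidates(
    sites: pd.DataFrame,
    screened: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Validation-stage origin classification of screen survivors.

    Uses the simulated deep re-sequencing columns (validation_alt /
    validation_depth) as the cross-platform validation VAFs and the
    read-linkage counts for parental phasing.
    """
    survivors = screened[screened["pass_all"]]
    vdep = sites.pivot_table(index="site_id", columns="animal", values="validation_depth", aggfunc="first")
    valt = sites.pivot_table(index="site_id", columns="animal", values="validation_alt", aggfunc="first")
    vvaf = valt / vdep.where(vdep > 0)
    links = sites.set_index(["site_id", "animal"])[["sire_links", "dam_links"]]
    meta = sites.drop_duplicates("site_id").set_index("site_id")

    offspring = [a for a in vdep.columns if a.startswith("offspring")]
    rows = []
    for _, cand in survivors.iterrows():
        sid, child = cand["site_id"], cand["animal"]
        sibs = [a for a in offspring if a != child]
        result = clf.classify_origin(
            offspring_vaf=float(vvaf.loc[sid, child]),
            sire_vaf=float(vvaf.loc[sid, "sire"]),
            dam_vaf=float(vvaf.loc[sid, "dam"]),
            sibling_vafs=[float(vvaf.loc[sid, s]) for s in sibs],
            offspring=child,
            depths={a: int(vdep.loc[sid, a]) for a in vdep.columns},
            config=cfg.classify,
        )
        lk = links.loc[(sid, child)]
        origin, _ = clf.phase_parental_origin(
            int(lk["sire_links"]), int(lk["dam_links"]), min_links=cfg.classify.min_links
        )
        m = meta.loc[sid]
        rows.append(
            dict(site_id=sid, chrom=m["chrom"], pos=int(m["pos"]), ref=m["ref"], alt=m["alt"],
                 context=m["context"], animal=child, origin_class=result.origin_class,
                 validation_vaf=result.offspring_vaf,
                 embryonic_cell_count=result.embryonic_cell_count, parental_origin=origin)
        )
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "ref", "alt", "context", "animal",
                       "origin_class", "validation_vaf", "embryonic_cell_count", "parental_origin"],
    )


def _confusion(truth: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """Truth kind vs pipeline call for every injected site (one row per site)."""
    called = (classified.drop_duplicates(["family", "site_id"])
              .set_index(["family", "site_id"])["origin_class"])
    rows = []
    for _, t in truth.iterrows():
        rows.append(dict(kind=t["kind"], true_vaf=t["true_vaf"],
                         called=called.get((t["family"], t["site_id"]), "missed")))
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    return df.groupby(["kind", "called"]).size().unstack(fill_value=0)


def _snv_arm(cfg: PipelineConfig, rng: np.random.Generator):
    """Simulate, screen and classify every family; per-offspring counts."""
    count_rows, classified_frames, truth_frames = [], [], []
    for group, gcfg in cfg.groups.items():
        for fi, n_off in enumerate(gcfg.families):
            fam_rng = np.random.default_rng(rng.integers(2**31))
            injections = simulate_family_injections(
                n_off, gcfg.de_novo_mean, gcfg.embryonic_mean, cfg.paternal_fraction, fam_rng
            )
            sim = SimulationConfig(
                seed=int(fam_rng.integers(2**31)), n_offspring=n_off,
                mean_depth=cfg.mean_depth, error_rate=cfg.error_rate,
                n_sites=cfg.n_background_sites, injected=injections,
                validation_depth=cfg.validation_depth,
            )
            sites, truth = simulate_quintet(sim)
            screened = screen_quintet(sites, config=cfg.screen)
            classified = classify_candidates(sites, screened, cfg)
            fam = f"{group}.family{fi + 1}"
            classified = classified.assign(group=group, family=fam)
            truth = truth.assign(group=group, family=fam)
            classified_frames.append(classified)
            truth_frames.append(truth)
            per_child = classified.groupby(["animal", "origin_class"]).size().unstack(fill_value=0)
            for j in range(1, n_off + 1):
                child = f"offspring_{j}"
                dn = int(per_child.get("de_novo", pd.Series(dtype=int)).get(child, 0))
                em = int(per_child.get("embryonic", pd.Series(dtype=int)).get(child, 0))
                count_rows.append(dict(group=group, family=fam, offspring=f"{fam}.{child}",
                                       de_novo=dn, embryonic=em, total=dn + em))
    counts = pd.DataFrame(count_rows)
    classified_all = pd.concat(classified_frames, ignore_index=True)
    truth_all = pd.concat(truth_frames, ignore_index=True)
    return counts, classified_all, truth_all


def _rate_tables(counts: pd.DataFrame, cfg: PipelineConfig) -> Dict[str, dict]:
    """Frequency-table-style rates, ratios, GEE contrasts and adjustments."""
    control = cfg.control_group
    bap_groups = [g for g in cfg.groups if g != control]
    out: Dict[str, dict] = {}
    for mtype in ("de_novo", "embryonic", "total"):
        group_counts = {g: (int(counts.loc[counts["group"] == g, mtype].sum()),
                            int((counts["group"] == g).sum()))
                        for g in cfg.groups}
        group_counts["all_bap"] = (
            sum(group_counts[g][0] for g in bap_groups),
            sum(group_counts[g][1] for g in bap_groups),
        )
        comparisons = rate_and_ratio(group_counts, control=control, ci_method="poisson")
        gee_ps, labels = [], []
        for contrast in bap_groups + ["all_bap"]:
            mask = counts["group"].isin([control, contrast] if contrast != "all_bap"
                                        else [control] + bap_groups)
            sub = counts[mask]
            try:
                res = gee_poisson(sub[mtype], sub["group"] != control, sub["family"])
                gee_ps.append(res.p_value)
            except ValueError as exc:
                logger.warning("GEE degenerate for %s/%s: %s", mtype, contrast, exc)
                gee_ps.append(1.0)
            labels.append(contrast)
        adj = sidak_stepdown(gee_ps, monotonize=False)
        stats_by_group = dict(zip(labels, zip(gee_ps, adj)))
        table = []
        for rc in comparisons:
            p, padj = stats_by_group.get(rc.group, (None, None))
            table.append(dict(group=rc.group, n_offspring=rc.n_offspring, count=rc.count,
                              rate=rc.rate, ci=(rc.ci_low, rc.ci_high),
                              ratio_to_control=rc.ratio_to_control,
                              p_gee=p, p_adjusted=(None if padj is None else float(padj))))
        out[mtype] = dict(rows=table)
    return out


def _acgh_arm(cfg: PipelineConfig, rng: np.random.Generator):
    """Cohort-scale aCGH simulation, segmentation, status and frequencies."""
    calls: List[CnvCall] = []
    truth_frames = []
    group_of_animal: Dict[str, str] = {}
    group_sizes: Dict[str, int] = {}
    chrom_cycle = list(AUTOSOMES[1:])
    locus = 0
    for group, gcfg in cfg.groups.items():
        group_sizes[group] = gcfg.acgh_offspring
        specs_by_animal: Dict[str, List[AcghCnvSpec]] = {}

        def place(animal: str, kind: str, fraction: float = 1.0, event_id=None,
                  chrom: Optional[str] = None):
            nonlocal locus
            if event_id is None:
                # one id per injected event so that segments fragmented by
                # probe noise still count as a single mutational event
                event_id = f"{group}.ev{locus}"
            chrom = chrom or chrom_cycle[locus % len(chrom_cycle)]
            span = cfg.probes_per_chrom * 3000
            max_start = span - cfg.cnv_length_bp - 6000
            if max_start < 3000:
                raise ValueError("probe series too short for the configured CNV length")
            start = 3000 + (300_000 + (locus % 7) * 900_000) % max_start
            locus += 1
            specs_by_animal.setdefault(animal, []).append(
                AcghCnvSpec(animal=animal, chrom=chrom, start=start,
                            length=cfg.cnv_length_bp, kind=kind, fraction=fraction,
                            event_id=event_id)
            )

        idx = 0
        for _ in range(gcfg.acgh_deletions):
            place(f"{group}.a{idx}", "deletion"); idx += 1
        for _ in range(gcfg.acgh_duplications):
            place(f"{group}.a{idx}", "duplication"); idx += 1
        for p in range(gcfg.acgh_insertional_pairs):
            animal = f"{group}.a{idx}"; idx += 1
            eid = f"{group}.pair{p}"
            place(animal, "duplication", event_id=eid, chrom="chr4")
            place(animal, "duplication", event_id=eid, chrom="chr10")
        # one attenuated mosaic duplication per group: its mean log2
        # (~0.29) sits below the 0.4 calling threshold and its copy change
        # (0.45) below the 0.5 qPCR cut, so it should evade detection
        place(f"{group}.a{idx}", "mosaic_duplication", fraction=0.45); idx += 1

        for i in range(gcfg.acgh_offspring):
            animal = f"{group}.a{i}"
            group_of_animal[animal] = group
            sim = SimulationConfig(
                seed=int(rng.integers(2**31)),
                acgh=AcghConfig(noise_sd=cfg.probe_noise_sd, n_probes=cfg.probes_per_chrom,
                                cnvs=tuple(specs_by_animal.get(animal, ()))),
            )
            probes, truth = simulate_acgh(sim)
            if not truth.empty:
                truth_frames.append(truth.assign(group=group))
            for _, series in probes.groupby("animal"):
                calls.extend(segment_cnvs(series, animal=animal, config=cfg.cnv))
    truth_all = (pd.concat(truth_frames, ignore_index=True)
                 if truth_frames else pd.DataFrame())
    unique_calls = filter_recurrent(calls, cfg.cnv)

    qc_rng = np.random.default_rng(rng.integers(2**31))
    de_novo_calls: List[CnvCall] = []
    status_rows = []
    for call in unique_calls:
        match = None
        if not truth_all.empty:
            m = truth_all[(truth_all["animal"] == call.animal) & (truth_all["chrom"] == call.chrom)
                          & (truth_all["start"] <= call.end) & (truth_all["end"] >= call.start)]
            if len(m):
                match = m.iloc[0]
        if match is not None:
            dcopy = 1.0 if "duplication" in match["kind"] else -1.0
            cn = 2.0 + match["fraction"] * dcopy
            call.event_id = match["event_id"]
        else:
            cn = 2.0
        tissues = {t: cn + float(qc_rng.normal(0, 0.05)) for t in ("liver", "spleen", "brain")}
        status = assign_cnv_status(call, tissues, sire_copy_number=2.0, dam_copy_number=2.0,
                                   config=cfg.cnv)
        call.status = status
        status_rows.append(dict(animal=call.animal, chrom=call.chrom, start=call.start,
                                end=call.end, kind=call.kind, mean_log2=call.mean_log2,
                                n_probes=call.n_probes, status=status, event_id=call.event_id))
        if status == "de_novo":
            de_novo_calls.append(call)

    freq = {}
    for kind, direction in (("duplication", "greater"), ("deletion", "less")):
        comps = cnv_frequencies(de_novo_calls, group_of_animal, group_sizes,
                                control=cfg.control_group, kind=kind, direction=direction)
        freq[kind] = [dict(group=rc.group, n=rc.n_offspring, events=rc.count,
                           frequency=rc.rate, ci=(rc.ci_low, rc.ci_high),
                           ratio_to_control=rc.ratio_to_control, p_fisher=rc.p_value,
                           p_adjusted=rc.p_adjusted, notes=rc.notes) for rc in comps]
    return pd.DataFrame(status_rows), de_novo_calls, freq, truth_all


def _breakpoint_arm(de_novo_calls: List[CnvCall], cfg: PipelineConfig,
                    rng: np.random.Generator) -> List[dict]:
    """Junction characterization for each de novo duplication event."""
    rows = []
    seen_events = set()
    for call in de_novo_calls:
        if call.kind != "duplication":
            continue
        key = (call.animal, call.event_id or (call.chrom, call.start))
        if key in seen_events:
            continue
        seen_events.add(key)
        mh_true = int(rng.integers(1, 7))
        event = "insertional" if call.event_id else "tandem"
        jn = simulate_junction(mh_true, event=event, seed=int(rng.integers(2**31)),
                               flank_len=cfg.junction_flank)
        mh = microhomology_length(jn.donor_flank, jn.acceptor_flank, jn.junction)
        structure, _ = classify_structure("duplication", [jn])
        paternal = rng.random() < cfg.paternal_fraction
        n_reads = 120
        k = int(rng.binomial(n_reads, 2.0 / 3.0 if paternal else 1.0 / 3.0))
        origin, _ = cnv_parental_origin(k, n_reads, n_informative_sites=8, kind="duplication")
        rows.append(dict(animal=call.animal, chrom=call.chrom, start=call.start,
                         mh_true=mh_true, mh_detected=mh.length, structure=structure,
                         origin_true=("paternal" if paternal else "maternal"),
                         origin_called=origin))
    return rows


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the report dict (also written as ``report.json``). Identical
    configs produce identical reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    counts, classified, truth = _snv_arm(cfg, rng)
    confusion = _confusion(truth, classified)
    rate_tables = _rate_tables(counts, cfg)

    control_dn = int(counts.loc[counts["group"] == cfg.control_group, "de_novo"].sum())
    n_control = int((counts["group"] == cfg.control_group).sum())
    dn_freq = mutation_frequency(control_dn, 2 * cfg.genome_bp, n_control)

    # spectra: affected split against the exposed-group mean, then the
    # affected-vs-rest spectrum contrast
    groups_by_child = counts.set_index("offspring")["group"]
    is_bap = groups_by_child != cfg.control_group
    merged_groups = groups_by_child.where(~is_bap, "BaP")
    totals = counts.set_index("offspring")["total"]
    affected = split_affected(totals, merged_groups, exposed_group="BaP")
    classified = classified.assign(offspring=classified["family"] + "." + classified["animal"])
    snvs = classified[(classified["ref"].str.len() == 1) & (classified["alt"].str.len() == 1)
                      & classified["origin_class"].isin(["de_novo", "embryonic"])]
    affected_ids = set(affected.index[affected & is_bap])
    spec_a = build_spectrum(snvs[snvs["offspring"].isin(affected_ids)])
    spec_b = build_spectrum(snvs[~snvs["offspring"].isin(affected_ids)])
    p_spec, method = spectrum_difference_test(spec_a.to_numpy(), spec_b.to_numpy(),
                                              seed=int(rng.integers(2**31)))
    clusters = clf.detect_clustered_mutations(
        snvs.drop(columns="animal").rename(columns={"offspring": "animal"}),
        window_bp=500_000, genome_bp=cfg.genome_bp)

    cnv_table, de_novo_calls, cnv_freq, _ = _acgh_arm(cfg, rng)
    junctions = _breakpoint_arm(de_novo_calls, cfg, rng)

    report = {
        "seed": cfg.seed,
        "snv": {
            "per_offspring_counts": counts.to_dict(orient="records"),
            "rate_tables": rate_tables,
            "control_de_novo_frequency_per_nt": dn_freq,
            "confusion": confusion.to_dict() if not confusion.empty else {},
            "spectrum": {
                "affected": spec_a.to_dict(), "unaffected_plus_controls": spec_b.to_dict(),
                "fisher_p": p_spec, "method": method,
                "n_affected_offspring": int(sum(a in affected_ids for a in totals.index)),
            },
            "clusters": [dataclasses.asdict(c) for c in clusters],
        },
        "cnv": {"frequencies": cnv_freq, "n_calls": int(len(cnv_table))},
        "breakpoints": junctions,
    }
    classified.to_csv(out / "classified_variants.tsv", sep="\t", index=False)
    counts.to_csv(out / "per_offspring_counts.tsv", sep="\t", index=False)
    cnv_table.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
    mio.write_json_report(report, out / "report.json", seed=cfg.seed)
    return report
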