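"""End-to-end orchestration: simulate -> assign -> quantify -> peaks/sites ->
motifs -> age -> express -> report.

Each stage writes its outputs as plain-text tables under the run directory
and the final report joins the headline statistics with truth-vs-estimate
recovery metrics.  One seed governs every stage through named substreams, so
identical config + seed gives identical outputs (the report's timestamp
field aside).
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, dataio
from .ages import SpeciesLadder, assign_age, age_peak_relationships, compare_age_distributions
from .assign import count_by_gene, loci_from_snp_table
from .expression import (
    correlation_by_stratum,
    nuclear_index,
    pair_correlations,
    rpkm,
    stratified_wilcoxon,
)
from .motifs import (
    MotifSite,
    alignment_from_gapped,
    classify_motif_changes,
    divergence_level_correlation,
    global_align,
    scan_drach,
    sequence_divergence,
    strand_bias_test,
)
from .quant import call_peaks, call_sites, levels_table
from .simulate import CohortBundle, SimulationConfig, generate_cohort, simulate_reads

REPORT_SCHEMA_VERSION = 1


def log(stage: str, msg: str) -> None:
    print(f"[pseudom6a:{stage}] {msg}", file=sys.stderr)


def load_config(path: str | Path | None, seed: int | None = None) -> SimulationConfig:
    """Read a YAML config into a SimulationConfig; unknown keys are rejected.

    ``seed`` (e.g. from the command line) overrides the config's seed.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("seq_length_range", "rate_spread", "cognate_level_beta"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = SimulationConfig(**data)
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    schema_version: int
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    headline: dict[str, Any] = field(default_factory=dict)
    recovery: dict[str, Any] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_assign(bundle: CohortBundle, out: Path, max_pairs: int = 25) -> pd.DataFrame:
    """Strict vs lenient read assignment on simulated reads of known origin.

    Assignment is run per homologous pair (the pseudogene and its cognate are
    the near-identical loci among which reads cross-map; unrelated pairs
    share no homology).  ``max_pairs`` caps the stage's problem size.
    """
    cfg = bundle.config
    rng = cfg.rng("reads")
    snp_rows = [
        (g, pos, ref, alt) for g, lst in bundle.snps.items() for pos, ref, alt in lst
    ]
    snp_df = pd.DataFrame(snp_rows, columns=["locus", "position", "ref", "alt"])
    rows = []
    for pair in bundle.pairs[:max_pairs]:
        seqs = {
            pair.pseudogene_id: bundle.sequences[pair.pseudogene_id],
            pair.cognate_id: bundle.sequences[pair.cognate_id],
        }
        loci = loci_from_snp_table(seqs, snp_df)
        reads = simulate_reads(seqs, bundle.snps, cfg.read_length, cfg.reads_per_gene, rng)
        for policy, k in (("strict", None), ("lenient", 3)):
            counts, conf = count_by_gene(reads, loci, lenient_k=k)
            cross = 0
            if conf is not None:
                wrong = conf[
                    (conf["true_origin"] != conf["assigned"])
                    & (~conf["assigned"].str.startswith("*"))
                ]
                cross = int(wrong["reads"].sum())
            for r in counts.itertuples(index=False):
                rows.append(
                    (
                        pair.pseudogene_id,
                        policy,
                        r.locus_id,
                        r.unique_reads,
                        counts.attrs["ambiguous"],
                        counts.attrs["unassigned"],
                        cross,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "policy",
            "locus_id",
            "unique_reads",
            "ambiguous",
            "unassigned",
            "cross_assigned",
        ],
    )
    dataio.write_tsv(df, out / "assignment_counts.tsv")
    return df


def stage_quantify(bundle: CohortBundle, out: Path) -> pd.DataFrame:
    fc = pd.DataFrame(
        [(g, *c) for g, c in bundle.fraction_counts.items()],
        columns=["gene_id", "input_count", "eluate_count", "supernatant_count"],
    )
    levels = levels_table(fc, min_informative=bundle.config.min_informative)
    dataio.write_tsv(levels, out / "levels.tsv")
    return levels


def stage_peaks_sites(
    bundle: CohortBundle, out: Path
) -> tuple[dict[str, list], dict[str, list[MotifSite]]]:
    peaks_by_gene: dict[str, list] = {}
    sites_by_gene: dict[str, list[MotifSite]] = {}
    for gid, (rip, inp) in bundle.coverages.items():
        peaks = call_peaks(rip, inp, gene_id=gid)
        peaks_by_gene[gid] = peaks
        sites_by_gene[gid] = call_sites(bundle.sequences[gid], peaks, gene_id=gid)
    dataio.write_bed6(
        (
            (p.gene_id, p.start, p.end, p.gene_id, p.intensity, "+")
            for peaks in peaks_by_gene.values()
            for p in peaks
        ),
        out / "peaks.bed",
    )
    dataio.write_bed6(
        (
            (s.gene_id, s.pos, s.pos + 1, f"{s.gene_id}:{s.pos}", 0.0, "+")
            for sites in sites_by_gene.values()
            for s in sites
        ),
        out / "sites.bed",
    )
    return peaks_by_gene, sites_by_gene


def stage_motifs(
    bundle: CohortBundle,
    peaks_by_gene: dict[str, list],
    levels: pd.DataFrame,
    out: Path,
) -> dict[str, Any]:
    """Alignment, motif gain/loss on both strands, strand-bias chi-square,
    and the divergence-level correlation per pseudogene class."""
    level_map = dict(zip(levels["gene_id"], levels["level"]))
    rows = []
    n_gain = {"sense": 0, "antisense": 0}
    n_tot = 0
    for pair in bundle.pairs:
        pg, cg = pair.pseudogene_id, pair.cognate_id
        pseq, cseq = bundle.sequences[pg], bundle.sequences[cg]
        if len(pseq) == len(cseq):
            aln = alignment_from_gapped(pg, pseq, cseq)  # substitution-only birth
        else:
            aln = global_align(pseq, cseq, pair_id=pg)
        ppeaks = [(p.start, p.end) for p in peaks_by_gene.get(pg, [])]
        cpeaks = [(p.start, p.end) for p in peaks_by_gene.get(cg, [])]
        div = sequence_divergence(aln)
        recs = {}
        for strand in ("sense", "antisense"):
            rec = classify_motif_changes(aln, ppeaks, cpeaks, strand)
            recs[strand] = rec
            if rec.gained >= 1:
                n_gain[strand] += 1
        n_tot += 1
        rows.append(
            (
                pg,
                pair.klass,
                div,
                level_map.get(pg, np.nan),
                recs["sense"].gained,
                recs["sense"].lost,
                recs["sense"].shared,
                recs["antisense"].gained,
                recs["antisense"].lost,
                recs["antisense"].shared,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "class",
            "divergence",
            "pseudo_level",
            "sense_gained",
            "sense_lost",
            "sense_shared",
            "antisense_gained",
            "antisense_lost",
            "antisense_shared",
        ],
    )
    dataio.write_tsv(df, out / "motif_changes.tsv")
    sb = strand_bias_test(n_gain["sense"], n_tot, n_gain["antisense"], n_tot)
    result: dict[str, Any] = {
        "strand_bias": {
            "sense_gaining": n_gain["sense"],
            "antisense_gaining": n_gain["antisense"],
            "n_pairs": n_tot,
            "chi2_yates": sb.chi2_yates,
            "p_yates": sb.p_yates,
            "chi2": sb.chi2,
            "p": sb.p,
        },
        "divergence_level": {},
    }
    for klass in ("processed", "unprocessed"):
        sub = df[(df["class"] == klass) & df["pseudo_level"].notna()]
        if len(sub) >= 3 and sub["divergence"].std() > 0 and sub["pseudo_level"].std() > 0:
            r, p = divergence_level_correlation(sub["divergence"], sub["pseudo_level"])
            result["divergence_level"][klass] = {"r": r, "p": p, "n": len(sub)}
    return result


def stage_age(
    bundle: CohortBundle,
    peaks_by_gene: dict[str, list],
    sites_by_gene: dict[str, list[MotifSite]],
    out: Path,
) -> dict[str, Any]:
    """Phylostratigraphic ages of in-peak m6A sites vs out-of-peak DRACH
    controls, plus age/peak relationships."""
    ladder = SpeciesLadder(list(bundle.config.tree))
    m6a_ages: list[int] = []
    control_ages: list[int] = []
    all_ages: list[int] = []
    all_member: list[bool] = []
    all_intensity: list[float] = []
    rows = []
    for pair in bundle.pairs:
        pg = pair.pseudogene_id
        focal = bundle.sequences[pg]
        alignments = {
            sp: alignment_from_gapped(f"{pg}|{sp}", focal, seq)
            for sp, seq in bundle.orthologs[pg].items()
        }
        in_peak_pos = {s.pos for s in sites_by_gene.get(pg, [])}
        peak_at = {}
        for p in peaks_by_gene.get(pg, []):
            for x in range(p.start, p.end):
                peak_at[x] = p.intensity
        for site in scan_drach(focal, "sense", gene_id=pg):
            aa = assign_age(site, alignments, ladder)
            member = site.pos in in_peak_pos
            (m6a_ages if member else control_ages).append(aa.age_stratum)
            all_ages.append(aa.age_stratum)
            all_member.append(member)
            all_intensity.append(peak_at.get(site.pos, 0.0))
            rows.append((pg, site.pos, aa.age_stratum, member))
    dataio.write_tsv(
        pd.DataFrame(rows, columns=["gene_id", "pos", "age_stratum", "in_peak"]),
        out / "site_ages.tsv",
    )
    result: dict[str, Any] = {
        "n_m6a_sites": len(m6a_ages),
        "n_control_sites": len(control_ages),
    }
    if len(m6a_ages) >= 3 and len(control_ages) >= 3:
        stat, p, table = compare_age_distributions(m6a_ages, control_ages)
        dataio.write_tsv(table, out / "age_distributions.tsv")
        result["age_test"] = {"statistic": stat, "p": p}
    prop_table, (rho, rho_p) = age_peak_relationships(
        all_ages, all_member, all_intensity, ladder.n_strata
    )
    dataio.write_tsv(prop_table, out / "age_peak_proportions.tsv")
    result["in_peak_by_stratum"] = {
        int(r.stratum): (None if np.isnan(r.in_peak_proportion) else float(r.in_peak_proportion))
        for r in prop_table.itertuples(index=False)
    }
    result["age_intensity_spearman"] = {"rho": rho, "p": rho_p}
    return result


def stage_express(
    bundle: CohortBundle, levels: pd.DataFrame, out: Path
) -> dict[str, Any]:
    """m6A-stratified expression, nuclear-index and pair-correlation tests."""
    cat_map = dict(zip(levels["gene_id"], levels["category"]))
    klass_map = {p.pseudogene_id: p.klass for p in bundle.pairs}
    lengths = {g: len(s) for g, s in bundle.sequences.items()}

    # total expression from LAIC input counts, as RPKM
    lib = sum(c[0] for c in bundle.fraction_counts.values())
    expr = {
        g: rpkm(bundle.fraction_counts[g][0], lengths[g], lib)
        for g in bundle.fraction_counts
    }
    nidx = {
        g: nuclear_index(nuc, cyt)
        for g, (nuc, cyt) in bundle.compartment_expression.items()
    }
    cyto = {g: cyt for g, (nuc, cyt) in bundle.compartment_expression.items()}
    nuc = {g: n for g, (n, _) in bundle.compartment_expression.items()}

    result: dict[str, Any] = {}
    for name, values in (
        ("expression", expr),
        ("nuclear_index", nidx),
        ("cytosolic", cyto),
        ("nuclear", nuc),
    ):
        for klass in ("processed", "unprocessed"):
            genes = {g: v for g, v in values.items() if klass_map.get(g) == klass}
            tests, ecdfs = stratified_wilcoxon(genes, cat_map)
            dataio.write_tsv(tests, out / f"wilcoxon_{name}_{klass}.tsv")
            for r in tests.itertuples(index=False):
                if not r.skipped:
                    result[f"{name}_{klass}_{r.stratum_a}_vs_{r.stratum_b}"] = {
                        "p": float(r.p),
                        "median_shift": float(r.median_shift),
                    }

    pairs3 = [(p.pseudogene_id, p.pseudogene_id, p.cognate_id) for p in bundle.pairs]
    corr = pair_correlations(bundle.population_expression, pairs3)
    dataio.write_tsv(corr.drop(columns=["testable"]), out / "pair_correlations.tsv")
    n_sig = int(corr["significant"].sum())
    n_test = int(corr["testable"].sum())
    pos_frac = (
        float((corr.loc[corr["significant"], "r"] > 0).mean()) if n_sig else float("nan")
    )
    result["pair_correlations"] = {
        "n_significant": n_sig,
        "n_testable": n_test,
        "positive_fraction_of_significant": pos_frac,
    }
    strat = correlation_by_stratum(corr, cat_map, klass_map)
    for klass, (tests, _) in strat.items():
        dataio.write_tsv(tests, out / f"wilcoxon_correlation_{klass}.tsv")
        for r in tests.itertuples(index=False):
            if not r.skipped:
                result[f"correlation_{klass}_{r.stratum_a}_vs_{r.stratum_b}"] = {
                    "p": float(r.p),
                    "median_shift": float(r.median_shift),
                }
    return result


def _recovery_metrics(bundle: CohortBundle, levels: pd.DataFrame) -> dict[str, Any]:
    true_levels = bundle.truth["true_levels"]
    est = levels.dropna(subset=["level"])
    diffs = [
        float(r.level) - true_levels[r.gene_id]
        for r in est.itertuples(index=False)
        if r.gene_id in true_levels
    ]
    diffs = np.asarray(diffs)
    return {
        "n_genes_with_level": int(est.shape[0]),
        "level_bias": float(diffs.mean()) if diffs.size else float("nan"),
        "level_rmse": float(np.sqrt((diffs**2).mean())) if diffs.size else float("nan"),
    }


def run_pipeline(
    config: SimulationConfig | str | Path | None,
    outdir: str | Path,
    seed: int | None = None,
) -> RunReport:
    """Execute every stage in dependency order and write the joined report."""
    if not isinstance(config, SimulationConfig):
        config = load_config(config, seed=seed)
    elif seed is not None:
        config.seed = seed
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    report = RunReport(
        schema_version=REPORT_SCHEMA_VERSION,
        config=asdict(config),
        seed=config.seed,
        meta={
            "package_version": __version__,
            "generated_at": datetime.now(timezone.utc).isoformat(),
        },
    )

    log("simulate", f"generating cohort of {config.n_pairs} pairs (seed {config.seed})")
    bundle = generate_cohort(config)
    bundle.write(out / "cohort")
    report.outputs["cohort"] = str(out / "cohort")

    log("assign", "strict vs lenient read assignment")
    assign_df = stage_assign(bundle, out)
    report.outputs["assignment"] = str(out / "assignment_counts.tsv")
    strict = assign_df[assign_df["policy"] == "strict"]
    lenient = assign_df[assign_df["policy"] == "lenient"]
    report.headline["assignment"] = {
        "strict_cross_assigned": int(strict.groupby("pair_id")["cross_assigned"].first().sum()),
        "lenient_cross_assigned": int(lenient.groupby("pair_id")["cross_assigned"].first().sum()),
    }

    log("quantify", "LAIC-seq m6A levels")
    levels = stage_quantify(bundle, out)
    report.outputs["levels"] = str(out / "levels.tsv")

    log("peaks", "peak and site calling")
    peaks_by_gene, sites_by_gene = stage_peaks_sites(bundle, out)
    report.outputs["peaks"] = str(out / "peaks.bed")
    report.outputs["sites"] = str(out / "sites.bed")

    log("motifs", "motif gain/loss and strand bias")
    report.headline["motifs"] = stage_motifs(bundle, peaks_by_gene, levels, out)
    report.outputs["motif_changes"] = str(out / "motif_changes.tsv")

    log("age", "phylostratigraphic site ages")
    report.headline["age"] = stage_age(bundle, peaks_by_gene, sites_by_gene, out)
    report.outputs["site_ages"] = str(out / "site_ages.tsv")

    log("express", "stratified expression statistics")
    report.headline["expression"] = stage_express(bundle, levels, out)
    report.outputs["pair_correlations"] = str(out / "pair_correlations.tsv")

    report.recovery = _recovery_metrics(bundle, levels)
    dataio.write_json(report.to_dict(), out / "report.json")
    log("report", f"written to {out / 'report.json'}")
    return report
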