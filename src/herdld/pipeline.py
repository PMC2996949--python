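"""End-to-end pipeline driver: simulate -> qc -> phase -> ld -> decay ->
scan -> bias -> xchrom, with every stage parameter in one declarative
config and all outputs written as tab-separated text.

Stage defaults encode the standard study settings: MAF >= 0.05, <= 10%
missing, the 0-40 kb ... >100 Mb decay bins with 1,000 bootstrap samples,
2 Mb windows overlapping by 1.9 Mb with a 20-pair minimum, a 10 Mb
misplacement flag distance, 200 subsample replicates and alpha = 0.01 for
the parental contrast.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias, decay, genio, genome_scan, ldcore, phasing, qc, simdata, xchrom

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "enabled": True,
        "n_autosomes": 3, "markers_per_chrom": 120, "mean_spacing_bp": 66_000,
        "include_x": True, "x_markers": 80, "x_mean_spacing_bp": 215_000,
        "par_fraction": 0.15,
        "n_founder_haplotypes": 200, "n_generations": 100, "pop_size": 100,
        "cm_per_mb": 1.25, "n_sires": 20, "progeny_per_sire": 10,
        "n_misplaced": 0, "min_displacement_bp": 10_000_000,
        "mendel_rate": 0.0, "missing_rate": 0.0,
    },
    "input": {"ped": None, "map": None, "pedigree": None, "genes_bed": None},
    "qc": {"maf_min": 0.05, "max_missing": 0.10, "mendel_correct": True},
    "phase": {"use_truth": True, "maternal_only": True},
    "ld": {"max_distance_bp": None},
    "decay": {"n_boot": 1000},
    "scan": {"window": 2_000_000, "step": 100_000, "pair_min": 200_000,
             "pair_max": 600_000, "min_pairs": 20,
             "flag_distance": 10_000_000},
    "bias": {"sizes": [22, 55, 111, 222, 444, 665, "all"], "n_rep": 200,
             "maf_group_width": 0.05, "alpha": 0.01,
             "max_pairs_per_range": 2000},
    "xchrom": {"min_run": 5},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def merge_config(user: dict | None) -> dict:
    """Overlay a user config on the defaults; unknown keys are rejected."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, val in (user or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key: {key}")
        if isinstance(cfg[key], dict):
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise ValueError(f"unknown config key: {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: dict | None, outdir) -> Path:
    """Run the configured stages, writing every table under ``outdir``.

    A stage failure aborts with the stage name; outputs of completed
    stages are retained.
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log: list[str] = [f"seed={seed}", f"config={json.dumps(cfg, default=str)}"]

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - abort with stage name
                (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
                raise PipelineError(name, e) from e
        return deco

    # --- simulate / load -------------------------------------------------
    @stage("simulate")
    def study():
        sim = cfg["simulate"]
        if sim["enabled"]:
            snp_map = simdata.synthetic_snp_map(
                n_autosomes=sim["n_autosomes"],
                markers_per_chrom=sim["markers_per_chrom"],
                mean_spacing_bp=sim["mean_spacing_bp"],
                include_x=sim["include_x"], x_markers=sim["x_markers"],
                x_mean_spacing_bp=sim["x_mean_spacing_bp"],
                par_fraction=sim["par_fraction"], seed=seed)
            sc = simdata.SimConfig(
                snp_map=snp_map,
                n_founder_haplotypes=sim["n_founder_haplotypes"],
                n_generations=sim["n_generations"], pop_size=sim["pop_size"],
                cm_per_mb=sim["cm_per_mb"], n_sires=sim["n_sires"],
                progeny_per_sire=sim["progeny_per_sire"], seed=seed)
            founders = simdata.simulate_founders(sc)
            pop = simdata.evolve_population(founders, sc)
            st = simdata.make_halfsib_study(pop, sc)
            if (sim["n_misplaced"] or sim["mendel_rate"] or sim["missing_rate"]):
                st, ledger = simdata.inject_artifacts(
                    st, sim["n_misplaced"], sim["min_displacement_bp"],
                    sim["mendel_rate"], sim["missing_rate"], seed)
                genio.write_ledger(ledger, outdir / "truth_ledger.tsv")
            genio.write_study(st, outdir / "study")
            if st.truth is not None:
                genio.write_haplotypes(st.truth.panel, st.snp_map,
                                       outdir / "study.truth.hap")
            log.append(f"simulate: {st.n_animals} animals x {st.n_markers} markers")
            return st
        inp = cfg["input"]
        st = genio.read_study(inp["ped"], inp["map"], inp["pedigree"])
        log.append(f"load: {st.n_animals} animals x {st.n_markers} markers")
        return st

    # --- qc ---------------------------------------------------------------
    @stage("qc")
    def qc_result():
        st, report = qc.filter_snps(study, cfg["qc"]["maf_min"],
                                    cfg["qc"]["max_missing"])
        st, flagged = qc.mendelian_check(st, correct=cfg["qc"]["mendel_correct"])
        report.n_mendel_corrected = len(flagged)
        _write(pd.DataFrame([{
            "n_input": report.n_input,
            "n_removed_location": report.n_removed_location,
            "n_removed_maf": report.n_removed_maf,
            "n_removed_missing": report.n_removed_missing,
            "n_kept": report.n_kept,
            "n_mendel_corrected": report.n_mendel_corrected,
            "maf_before": report.maf_before, "maf_after": report.maf_after,
        }]), outdir / "qc_report.tsv")
        log.append(f"qc: kept {report.n_kept}/{report.n_input} markers, "
                   f"{len(flagged)} Mendelian corrections")
        return st

    # --- phase ------------------------------------------------------------
    @stage("phase")
    def panel():
        st = qc_result
        if cfg["phase"]["use_truth"] and st.truth is not None:
            pnl = st.truth.panel
            log.append("phase: simulator truth")
        else:
            pnl = phasing.phase_by_family_rules(st)
            log.append("phase: family rules")
        if cfg["phase"]["maternal_only"]:
            maternal, _ = phasing.split_parental(pnl)
            return maternal
        return pnl

    st = qc_result
    snp_map = st.snp_map

    # --- ld / decay ---------------------------------------------------------
    @stage("ld")
    def tables():
        adj = ldcore.pairwise_ld(panel, snp_map, scope="adjacent")
        syn = ldcore.pairwise_ld(panel, snp_map, scope="syntenic",
                                 max_distance_bp=cfg["ld"]["max_distance_bp"])
        genio.write_ld_table(adj, outdir / "ld_adjacent.tsv")
        genio.write_ld_table(syn, outdir / "ld_syntenic.tsv")
        log.append(f"ld: {len(adj)} adjacent, {len(syn)} syntenic pairs")
        return adj, syn

    adjacent_table, syntenic_table = tables

    @stage("decay")
    def decay_table():
        d = decay.decay_summary(syntenic_table, n_boot=cfg["decay"]["n_boot"],
                                seed=seed)
        _write(d, outdir / "decay.tsv")
        return d

    # --- scan ---------------------------------------------------------------
    @stage("scan")
    def scan_out():
        sc = cfg["scan"]
        windows = genome_scan.sliding_window_ld(
            panel, snp_map, window=sc["window"], step=sc["step"],
            pair_min=sc["pair_min"], pair_max=sc["pair_max"],
            min_pairs=sc["min_pairs"])
        _write(windows, outdir / "windows.tsv")
        calls = genome_scan.detect_misplaced(panel, snp_map,
                                             flag_distance=sc["flag_distance"])
        for call in calls:
            genome_scan.relocate_misplaced(panel, snp_map, call)
        _write(pd.DataFrame([vars(c) for c in calls]) if calls
               else pd.DataFrame(columns=["marker_id"]),
               outdir / "misplaced.tsv")
        log.append(f"scan: {len(windows)} windows, {len(calls)} misplaced calls")
        genes_bed = cfg["input"]["genes_bed"]
        if genes_bed:
            genes = genio.read_gene_bed(genes_bed)
            labeled = genome_scan.classify_gene_context(snp_map, genes,
                                                        syntenic_table)
            _write(genome_scan.gene_context_summary(labeled),
                   outdir / "gene_context.tsv")
        return windows, calls

    # --- bias -----------------------------------------------------------------
    @stage("bias")
    def bias_out():
        bc = cfg["bias"]
        sizes = [s for s in bc["sizes"]
                 if s == "all" or int(s) <= len(pd.unique(panel.carrier))]
        sub = bias.subsample_experiment(
            panel, snp_map, sizes=sizes, n_rep=bc["n_rep"], seed=seed,
            max_pairs_per_range=bc["max_pairs_per_range"])
        _write(sub, outdir / "bias_subsample.tsv")
        resid = bias.residual_ld_by_maf(syntenic_table,
                                        maf_group_width=bc["maf_group_width"])
        _write(resid, outdir / "bias_residual_maf.tsv")
        if st.truth is not None:
            maternal, paternal = phasing.split_parental(st.truth.panel)
            ptab, frac = bias.compare_parental_freqs(
                maternal, paternal, snp_map, alpha=bc["alpha"],
                scope="adjacent")
            _write(ptab, outdir / "bias_parental.tsv")
            log.append(f"bias: parental flagged fraction {frac:.4f}")
        return sub, resid

    # --- xchrom ------------------------------------------------------------
    @stage("xchrom")
    def x_out():
        from .containers import X_CHROM
        if not (snp_map.chrom == X_CHROM).any():
            log.append("xchrom: no X markers, skipped")
            return None
        boundary = xchrom.find_par_boundary(st, min_run=cfg["xchrom"]["min_run"])
        _write(boundary.evidence, outdir / "xchrom_evidence.tsv")
        _write(pd.DataFrame([{
            "boundary_pos": boundary.boundary_pos,
            "n_x_specific": boundary.n_x_specific, "n_par": boundary.n_par,
            "min_run": boundary.min_run}]), outdir / "xchrom_boundary.tsv")
        strat = xchrom.stratify_x_ld(panel, snp_map, boundary)
        for region, res in strat.items():
            if res["summary"] is not None:
                _write(res["summary"], outdir / f"xchrom_{region}_summary.tsv")
        log.append(f"xchrom: boundary={boundary.boundary_pos}")
        return boundary

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return outdir
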