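"""End-to-end driver chaining QC, diversity, ROH, LD/Ne and selection scans.

The configuration is a plain mapping (or YAML file) whose stage sections
mirror the analysis defaults: QC thresholds, ROH parameters, F_ST window
200 kb / step 60 kb with the top 0.1% ZF_ST rule, XP-EHH with P < 0.001, and
the >= 2 methods / >= 2 comparisons consensus rule.  Every output TSV carries
a provenance header with the stage parameters; the run is deterministic for
a given config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import diversity as div
from . import ld_ne, qc_filters, regions, roh, selection_scan, structure
from .genotype_io import (
    read_plink_text,
    read_vcf_phased,
    write_bed,
    write_plink_text,
    write_vcf_phased,
)
from .synthetic_data import SimConfig, SweepSpec, inject_sweep, simulate_divergent_pops

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _write_tsv(df, path: Path, stage: str, params: dict) -> None:
    header = "# ovisweep stage=%s %s\n" % (
        stage,
        " ".join(f"{k}={v}" for k, v in sorted(params.items())),
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, seed: int, out_dir) -> dict:
    """Run simulate/load -> QC -> diversity -> ROH -> LD/Ne -> scans -> consensus.

    Returns a manifest dict (also written to ``out_dir/manifest.json``)
    listing parameters and per-stage outputs.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "stages": {}}

    # ---- input ---------------------------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sweep_cfg = sim_kwargs.pop("sweep", None)
        sim = SimConfig(rng_seed=int(seed), **sim_kwargs)
        ds, hs, truth = simulate_divergent_pops(sim)
        if sweep_cfg:
            hs = inject_sweep(hs, SweepSpec(**sweep_cfg), rng_seed=int(seed) + 1)
            ds = hs.to_genotype_dataset()
        write_plink_text(ds, out / "sim.ped", out / "sim.map")
        write_vcf_phased(hs, out / "sim.vcf")
        manifest["stages"]["simulate"] = {
            "n_samples": ds.n_samples,
            "n_variants": ds.n_variants,
            "sweep": sweep_cfg,
        }
    elif "input" in cfg:
        inp = cfg["input"]
        if "ped" not in inp or "map" not in inp:
            raise ConfigError("input section requires keys 'ped' and 'map'")
        ds = read_plink_text(inp["ped"], inp["map"])
        hs = read_vcf_phased(inp["vcf"]) if "vcf" in inp else None
        if "groups" in inp:
            lab = yaml.safe_load(open(inp["groups"])) if isinstance(inp["groups"], str) \
                else inp["groups"]
            missing = [s for s in ds.sample_ids if s not in lab]
            if missing:
                raise ConfigError(f"group labels missing for samples: {missing[:5]}")
            ds.population_labels = [lab[s] for s in ds.sample_ids]
        if hs is not None:
            by_id = dict(zip(ds.sample_ids, ds.population_labels))
            hs.population_labels = [by_id.get(s, ".") for s in hs.sample_ids]
    else:
        raise ConfigError("config requires a 'simulate' or 'input' section")

    pops = list(dict.fromkeys(ds.population_labels))
    comparisons = cfg.get("comparisons") or [
        [a, b] for i, a in enumerate(pops) for b in pops[i + 1:]
    ]
    for a, b in comparisons:
        if a not in pops or b not in pops:
            raise ConfigError(f"comparison ({a}, {b}) names unknown population labels")

    # ---- QC ------------------------------------------------------------
    th = qc_filters.QcThresholds(**cfg.get("qc", {}))
    ds_qc, qc_report = qc_filters.apply_qc(ds, th)
    manifest["stages"]["qc"] = {
        "n_samples": ds_qc.n_samples,
        "n_variants": ds_qc.n_variants,
        "variants_removed": qc_report["variants"],
        "relatedness_removed": qc_report["relatedness_removed"],
    }
    if hs is not None:
        keep = [j for j, v in enumerate(hs.variant_ids) if v in set(ds_qc.variant_ids)]
        hs_pos = hs.pos_bp[keep]
        import dataclasses

        hs = dataclasses.replace(
            hs,
            variant_ids=[hs.variant_ids[j] for j in keep],
            chrom=hs.chrom[keep],
            pos_bp=hs_pos,
            haplotypes=hs.haplotypes[:, keep],
            map_cm=None if hs.map_cm is None else np.asarray(hs.map_cm)[keep],
        )

    # ---- diversity & structure ----------------------------------------
    rep = div.het_stats(ds_qc)
    _write_tsv(rep.per_population, out / "diversity.tsv", "diversity", {})
    n_perm = int(cfg.get("fst_permutations", 0))
    fst_mat = div.fst_matrix(ds_qc, n_perm=n_perm, seed=int(seed))
    _write_tsv(fst_mat.reset_index(), out / "fst_matrix.tsv", "fst_matrix",
               {"n_perm": n_perm})
    ds_pruned, _removed = qc_filters.ld_prune(ds_qc, th.ld_window_kb, th.ld_step_kb,
                                              th.ld_r2_max)
    pca_res = structure.pca(ds_pruned, k=min(10, ds_pruned.n_samples - 1))
    _write_tsv(pca_res.coordinates, out / "pca.tsv", "pca", {"scaling": "patterson"})
    if len(pops) >= 3:
        (out / "nj.nwk").write_text(structure.nj_tree(fst_mat) + "\n")

    # ---- ROH -----------------------------------------------------------
    roh_params = roh.RohParams(**cfg.get("roh", {}))
    segments = roh.detect_roh(ds_qc, roh_params)
    froh_df = roh.froh(segments, ds_qc.sample_ids)
    _write_tsv(froh_df, out / "froh.tsv", "roh",
               {"min_length_bp": roh_params.min_length_bp})
    island_sets = {}
    by_pop = ds_qc.samples_by_population()
    for p in pops:
        members = [ds_qc.sample_ids[i] for i in by_pop[p]]
        if len(members) >= 2:
            island_sets[p] = roh.roh_islands(
                segments, members, ds_qc, tags={f"comparison={p}"}
            )
    tagged: list = []
    for p, islands in island_sets.items():
        others = [iv for q, ivs in island_sets.items() if q != p for iv in ivs]
        tagged.extend(roh.private_islands(islands, others))
    write_bed(tagged, out / "roh_islands_private.bed")
    manifest["stages"]["roh"] = {
        "n_segments": len(segments),
        "n_private_islands": len(tagged),
    }

    # ---- LD / Ne -------------------------------------------------------
    ld_cfg = cfg.get("ld_ne", {})
    pairs = ld_ne.pairwise_r2(ds_qc, max_dist_bp=float(ld_cfg.get("max_dist_bp", 5e6)),
                              thin_step=int(ld_cfg.get("thin_step", 1)))
    edges = np.linspace(0, float(ld_cfg.get("max_dist_bp", 5e6)), 26)
    _write_tsv(ld_ne.ld_decay(pairs, edges), out / "ld_decay.tsv", "ld_decay", ld_cfg)
    t_grid = ld_cfg.get("t_grid", [10, 20, 50, 100, 200, 500, 1000])
    _write_tsv(ld_ne.ne_trajectory(pairs, t_grid), out / "ne_trajectory.tsv",
               "ne_trajectory", ld_cfg)

    # ---- selection scans ----------------------------------------------
    scan_cfg = cfg.get("fst_scan", {})
    xp_cfg = cfg.get("xpehh", {})
    for a, b in comparisons:
        comp = f"{a}_vs_{b}"
        try:
            scan = selection_scan.window_fst_scan(
                ds_qc, a, b,
                window_bp=int(scan_cfg.get("window_bp", 200_000)),
                step_bp=int(scan_cfg.get("step_bp", 60_000)),
                min_snps=int(scan_cfg.get("min_snps", 3)),
            )
        except ValueError as exc:
            logger.warning("F_ST scan skipped for %s: %s", comp, exc)
        else:
            _write_tsv(scan.windows, out / f"fst_scan_{comp}.tsv", "fst_scan",
                       {"comparison": comp, "mu": scan.mu_fst, "sigma": scan.sigma_fst})
            tagged.extend(scan.candidate_intervals(tags={f"comparison={comp}"}))
        if hs is not None:
            hap_pops = np.array(hs.haplotype_population_labels(), dtype=object)
            import dataclasses

            def _sub(pop):
                rows = np.flatnonzero(hap_pops == pop)
                samp = [s for s, p in zip(hs.sample_ids, hs.population_labels) if p == pop]
                return dataclasses.replace(
                    hs, sample_ids=samp, population_labels=[pop] * len(samp),
                    haplotypes=hs.haplotypes[rows],
                )
            records = selection_scan.xpehh_scan(
                _sub(a), _sub(b),
                p_threshold=float(xp_cfg.get("p_threshold", 0.001)),
            )
            _write_tsv(records.drop(columns=["defined"]),
                       out / f"xpehh_{comp}.tsv", "xpehh", {"comparison": comp})
            tagged.extend(
                selection_scan.significant_regions(
                    records,
                    merge_gap_bp=int(xp_cfg.get("merge_gap_bp", 200_000)),
                    tags={f"comparison={comp}"},
                )
            )

    # ---- consensus -----------------------------------------------------
    cons_cfg = cfg.get("consensus", {})
    consensus = regions.consensus_candidates(
        [iv for iv in tagged if any(t.startswith("method=") for t in iv.tags)],
        min_methods=int(cons_cfg.get("min_methods", 2)),
        min_comparisons=int(cons_cfg.get("min_comparisons", 2)),
    )
    _write_tsv(consensus, out / "consensus.tsv", "consensus", cons_cfg)
    manifest["stages"]["consensus"] = {"n_loci": int(len(consensus))}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
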