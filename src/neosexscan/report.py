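"""End-to-end pipeline: simulate or load a study, run every scan, and
emit deterministic result tables plus a run manifest.

The pipeline stages are: data (simulate or read inputs), coverage
(degeneration detection from sex-differential depth), divergence
(heterozygosity scans, X/Y SNP classification, fusion gradient),
codonevol (branch-specific omega and per-SNP effects) and expression
(biased-gene calling and chromosome enrichment).  A stage failure is
recorded in the manifest and does not abort the remaining stages.  The
manifest carries the configuration hash, the seed, per-stage counts and
SHA-256 digests of every output file, so a run can be verified and
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codonevol, coverage_analysis, divergence, expression as expr
from .io_formats import (
    SampleSheet, read_coverage, read_gene_models, read_genotypes,
    read_sample_sheet,
)
from .simgenome import SimulationConfig, simulate_dataset

log = logging.getLogger("neosexscan")

__all__ = ["RunManifest", "run_pipeline", "load_config"]

SEED_MODULUS = 2 ** 31


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # name -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _canonical_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _derived_seed(base: int, stage: str) -> int:
    """Stage seed derived from the base seed; stable across runs and
    independent between stages."""
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % SEED_MODULUS


def load_config(path) -> dict:
    """Load a YAML (or JSON) pipeline configuration."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _write_tsv(df: pd.DataFrame, out_dir: str, name: str,
               manifest: RunManifest) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.outputs[name] = _file_digest(path)
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_data(config: dict, seed: int):
    """Either simulate a dataset or load user inputs.

    Returns (sheet, matrix, genes, tracks, expression dict or None,
    chrom_lengths, counts)."""
    if "inputs" in config:
        inp = config["inputs"]
        sheet = read_sample_sheet(inp["samples"])
        matrix = read_genotypes(inp["vcf"], sheet)
        genes = (read_gene_models(inp["gff"], inp["fasta"])
                 if "gff" in inp and "fasta" in inp else [])
        tracks = {sid: read_coverage(os.path.join(inp["coverage_dir"],
                                                  f"{sid}.bedgraph"),
                                     sample_id=sid)
                  for sid in sheet.sample_ids} if "coverage_dir" in inp else {}
        em = None
        if "expression" in inp:
            em = expr.read_expression(inp["expression"], inp["probe_map"],
                                      inp["array_map"])
        lengths = {c: max(t.chrom_length(c) for t in tracks.values())
                   for c in next(iter(tracks.values())).chroms} if tracks else {
            c: int(matrix.pos[matrix.sites_on(c)].max())
            for c in np.unique(matrix.chrom)}
        counts = {"n_sites": matrix.n_sites, "n_genes": len(genes),
                  "n_samples": len(sheet.sample_ids), "source": "inputs"}
        return sheet, matrix, genes, tracks, em, lengths, counts, None

    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs["seed"] = _derived_seed(seed, "simulate")
    cfg = SimulationConfig(**sim_kwargs)
    ds = simulate_dataset(cfg)
    em = expr.ExpressionMatrix(signals=ds.expression["signals"],
                               probe_map=ds.expression["probe_map"],
                               array_map=ds.expression["array_map"])
    counts = {"n_sites": ds.matrix.n_sites, "n_genes": len(ds.gene_models),
              "n_samples": len(ds.sample_sheet.sample_ids),
              "source": "simulated"}
    return (ds.sample_sheet, ds.matrix, ds.gene_models, ds.coverage, em,
            cfg.chrom_plan(), counts, cfg)


def _split_chroms(config: dict, lengths: dict, sim_cfg) -> tuple[list, list]:
    """(candidate sex chromosomes, autosomes)."""
    if "candidates" in config:
        cands = list(config["candidates"])
    elif sim_cfg is not None:
        cands = [sim_cfg.neo_chrom, sim_cfg.anc_chrom]
    else:
        cands = []
    autos = [c for c in lengths if c not in cands]
    return cands, autos


def _stage_coverage(tracks, sheet: SampleSheet, candidates, autosomes,
                    out_dir, manifest) -> dict:
    norm = {sid: coverage_analysis.normalize_coverage(t)
            for sid, t in tracks.items()}
    rows = []
    sex_of = dict(zip(sheet.frame["sample_id"], sheet.frame["sex"]))
    for sid, t in norm.items():
        means = coverage_analysis.chromosome_mean_coverage(t)
        for _, r in means.iterrows():
            rows.append((sid, sex_of[sid], r["chrom"], r["mean"]))
    summaries = pd.DataFrame(rows, columns=["sample_id", "sex", "chrom", "mean"])
    per_sample, reports = coverage_analysis.detect_degeneration(
        summaries, candidates, autosomes)
    _write_tsv(summaries, out_dir, "coverage_chromosome_means.tsv", manifest)
    _write_tsv(per_sample, out_dir, "coverage_grubbs_tests.tsv", manifest)

    males = sheet.select(sex="male")
    females = sheet.select(sex="female")
    if males and females:
        win = coverage_analysis.sex_coverage_windows(norm[males[0]],
                                                     norm[females[0]])
        _write_tsv(win, out_dir, "coverage_sex_windows.tsv", manifest)
    return {
        "degenerate": sorted(c for c, r in reports.items() if r.degenerate),
        "n_candidates": len(candidates),
        "n_tests": int(len(per_sample)),
    }


def _stage_divergence(matrix, tracks, sheet: SampleSheet, lengths,
                      candidates, autosomes, roles, out_dir, manifest,
                      mask_preset: str = "strict") -> tuple[dict, pd.DataFrame]:
    mask = None
    if tracks:
        lo, hi = divergence.MASK_PRESETS[mask_preset]
        mask = divergence.build_site_mask(list(tracks.values()), lo, hi)

    xy = divergence.classify_xy_snps(matrix, roles, mask=mask)
    _write_tsv(xy, out_dir, "xy_snp_classes.tsv", manifest)
    species = divergence.classify_species_sites(
        matrix, roles["focal_females"], roles["other_females"], mask=mask)
    _write_tsv(species, out_dir, "species_site_classes.tsv", manifest)

    fm0 = roles["focal_males"][0]
    het_sum = divergence.chromosome_het_summary(matrix, fm0, mask, lengths)
    _write_tsv(het_sum, out_dir, "het_chromosome_summary.tsv", manifest)
    outliers = divergence.chromosome_outlier_tests(
        het_sum.set_index("chrom")["value"], candidates, autosomes)
    _write_tsv(outliers, out_dir, "het_outlier_tests.tsv", manifest)
    windows = divergence.het_windows(matrix, fm0, mask, lengths)
    _write_tsv(windows, out_dir, "het_windows.tsv", manifest)

    info = {"n_x_specific": int((xy["category"] == "X_specific").sum()),
            "n_y_specific": int((xy["category"] == "Y_specific").sum()),
            "n_shared": int((xy["category"] == "shared").sum()),
            "n_fixed_diff": int(species["fixed_diff"].sum()),
            "het_outliers": outliers.loc[outliers["significant"],
                                         "candidate"].tolist()}

    # fusion gradient on the first candidate with X-Y divergent sites
    for cand in candidates:
        sub = xy[(xy["chrom"] == cand)
                 & xy["category"].isin(["X_specific", "Y_specific"])]
        if len(sub) < 20 or cand not in lengths:
            continue
        fit = divergence.fusion_gradient(sub["pos"].to_numpy(), 1,
                                         lengths[cand], chrom=cand, mask=mask)
        info["gradient"] = {"chrom": cand, "beta": fit.beta,
                            "se_beta": fit.se_beta, "p_beta": fit.p_beta,
                            "separation": fit.separation}
        break
    return info, xy


def _stage_codonevol(matrix, genes, sheet: SampleSheet, xy: pd.DataFrame,
                     candidates, seed, out_dir, manifest) -> dict:
    focal_m = sheet.select("focal", "male")
    sister = sheet.select("sister")
    outgroup = sheet.select("outgroup")
    info: dict = {}

    # per-SNP effect by X/Y category
    effects = codonevol.annotate_snp_effects_bulk(matrix, genes)
    eff = xy.copy()
    eff["effect"] = effects
    _write_tsv(eff, out_dir, "snp_effects.tsv", manifest)
    info["nonsyn_fraction"] = codonevol.nonsyn_fraction_by_category(
        eff["category"], eff["effect"])

    # branch-specific omega on candidate-chromosome genes
    if focal_m and sister and outgroup:
        results, rows = [], []
        for i, g in enumerate(g for g in genes if g.chrom in candidates):
            gseed = _derived_seed(seed, f"gene:{g.gene_id}")
            try:
                f = codonevol.consensus_haploid(matrix, focal_m[0], g, gseed)
                s = codonevol.consensus_haploid(matrix, sister[0], g,
                                                gseed + 1)
                o = codonevol.consensus_haploid(matrix, outgroup[0], g,
                                                gseed + 2)
            except codonevol.GeneExcluded as exc:
                log.info("%s", exc)
                continue
            r = codonevol.branch_specific_omega(f, s, o)
            results.append(r)
            rows.append((g.gene_id, g.chrom, r.omega_focal,
                         r.omega_background, r.nd_focal, r.sd_focal,
                         r.nd_background, r.sd_background))
        if results:
            w1, w0 = codonevol.pooled_branch_omega(results)
            info["omega_focal"] = w1
            info["omega_background"] = w0
            info["n_genes_tested"] = len(results)
            _write_tsv(pd.DataFrame(rows, columns=[
                "gene_id", "chrom", "omega_focal", "omega_background",
                "nd_focal", "sd_focal", "nd_background", "sd_background"]),
                out_dir, "branch_omega.tsv", manifest)
    return info


def _stage_expression(em, matrix, sheet: SampleSheet, genes, candidates,
                      autosomes, lengths, out_dir, manifest) -> dict:
    norm = expr.normalize_expression(em)
    males = norm.arrays(species="focal", sex="male", tissue="brain")
    females = norm.arrays(species="focal", sex="female", tissue="brain")
    calls = expr.call_biased_genes(norm, {"male": males, "female": females})
    _write_tsv(calls, out_dir, "expression_sex_bias.tsv", manifest)

    gene_chrom = (norm.probe_map.drop_duplicates("gene_id")
                  .set_index("gene_id")["chrom"])
    info: dict = {"n_biased": int(calls["flagged"].sum()),
                  "n_genes": int(len(calls)),
                  "n_unstable_probes": norm.n_unstable_probes}
    try:
        props, outliers = expr.chromosome_enrichment(
            calls, gene_chrom, candidates, autosomes)
        _write_tsv(props, out_dir, "expression_enrichment.tsv", manifest)
        info["enriched"] = [o.label for o in outliers
                            if o.label in candidates]
    except ValueError as exc:
        info["enrichment_skipped"] = str(exc)

    focal_males = sheet.select("focal", "male")
    gene_info = norm.probe_map.drop_duplicates("gene_id")[
        ["gene_id", "chrom", "tss", "strand"]]
    sex_effect = calls.set_index("gene")["effect"].dropna()
    for cand in candidates:
        if (gene_info["chrom"] == cand).sum() >= 3 and focal_males:
            info["cis_correlation"] = expr.cis_het_correlation(
                sex_effect, matrix, focal_males, gene_info, cand)
            info["cis_chrom"] = cand
            break
    return info


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str, out_dir: str,
                 seed: int | None = None) -> RunManifest:
    """Run every stage over a simulated or user-supplied study.

    ``config`` is a mapping (or path to a YAML file) with optional keys
    ``simulate`` (SimulationConfig overrides), ``inputs`` (paths to VCF,
    sample sheet, coverage, gene models, expression), ``candidates``
    (candidate sex chromosomes) and ``seed``.  Outputs are written under
    ``out_dir``; the returned manifest is also written as
    ``manifest.json``.  Identical config + seed give byte-identical
    outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    if not 0 <= seed < SEED_MODULUS:
        raise ValueError(f"seed must be in [0, {SEED_MODULUS})")
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config_hash=_canonical_hash(config), seed=seed)

    def run_stage(name: str, fn, *args):
        try:
            out = fn(*args)
            info = out[0] if isinstance(out, tuple) else out
            manifest.stages[name] = {"status": "ok",
                                     **(info if isinstance(info, dict) else {})}
            return out
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            log.debug("%s", traceback.format_exc())
            manifest.stages[name] = {"status": "failed",
                                     "error": f"{type(exc).__name__}: {exc}"}
            return None

    data = run_stage("data", _stage_data, config, seed)
    if data is None:
        _finish(manifest, out_dir)
        return manifest
    sheet, matrix, genes, tracks, em, lengths, counts, sim_cfg = data
    manifest.stages["data"] = {"status": "ok", **counts}
    candidates, autosomes = _split_chroms(config, lengths, sim_cfg)

    roles = (sim_cfg.roles() if sim_cfg is not None else {
        "focal_males": sheet.select("focal", "male"),
        "focal_females": sheet.select("focal", "female"),
        "other_females": sheet.select("sister", "female"),
    })

    if tracks:
        run_stage("coverage", _stage_coverage, tracks, sheet, candidates,
                  autosomes, out_dir, manifest)
    xy = None
    div = run_stage("divergence", _stage_divergence, matrix, tracks, sheet,
                    lengths, candidates, autosomes, roles, out_dir, manifest,
                    config.get("mask_preset", "strict"))
    if div is not None:
        xy = div[1]
    if genes and xy is not None:
        run_stage("codonevol", _stage_codonevol, matrix, genes, sheet, xy,
                  candidates, seed, out_dir, manifest)
    if em is not None:
        run_stage("expression", _stage_expression, em, matrix, sheet, genes,
                  candidates, autosomes, lengths, out_dir, manifest)
    _finish(manifest, out_dir)
    return manifest


def _finish(manifest: RunManifest, out_dir: str) -> None:
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        fh.write(manifest.to_json() + "\n")
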