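"""Pipeline orchestration: simulate -> classify -> events -> DE -> usage ->
meta -> sectors -> motility from one config, with a reproducible manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    core_model,
    diffexpr,
    isoform_usage,
    motility,
    proteomics_meta,
    splice_events,
    structural_classify,
    synthetic_data,
)

logger = logging.getLogger("isoformshift")

STAGES = ("simulate", "classify", "events", "de", "usage", "meta", "sectors", "motility")

#: downstream dependencies used to halt dependents after a failure
_DEPS = {
    "classify": ("simulate",),
    "events": ("simulate", "classify"),
    "de": ("simulate",),
    "usage": ("simulate", "de"),
    "meta": (),
    "sectors": ("de", "meta"),
    "motility": (),
}

DEFAULT_CONFIG = {
    "outdir": "isoformshift_run",
    "stages": {s: True for s in STAGES},
    "seeds": {s: 7 + i for i, s in enumerate(STAGES)},
    "simulate": {"n_genes": 60, "n_observed": 120},
    "de": {"permutations": 100, "alpha_target": 0.05, "fold_change_guide": 1.0},
    "usage": {},
    "meta": {},
    "motility": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages in config: {sorted(unknown)}")
    for stage, enabled in cfg["stages"].items():
        if not enabled:
            continue
        for dep in _DEPS.get(stage, ()):
            if not cfg["stages"].get(dep, False):
                raise ValueError(
                    f"stage '{stage}' is enabled but its dependency '{dep}' is disabled"
                )
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: dict) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    cfg = validate_config(config)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"stages": {}, "config": cfg}
    state: dict = {}
    failed: set[str] = set()

    def record(stage: str, outputs: list[str], params: dict, seed: int, t0: float):
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
            "parameters": params,
            "seed": seed,
            "seconds": round(time.time() - t0, 3),
        }

    for stage in STAGES:
        if not cfg["stages"].get(stage, False):
            manifest["stages"][stage] = {"status": "disabled"}
            continue
        if any(d in failed for d in _DEPS.get(stage, ())):
            manifest["stages"][stage] = {"status": "skipped_failed_dependency"}
            logger.error("stage %s skipped: upstream failure", stage)
            failed.add(stage)
            continue
        seed = int(cfg["seeds"][stage])
        t0 = time.time()
        try:
            outputs = _run_stage(stage, cfg, state, seed, outdir)
            record(stage, outputs, cfg.get(stage, {}), seed, t0)
            logger.info("stage %s done in %.1fs", stage, time.time() - t0)
        except Exception as exc:  # halt downstream dependents only
            failed.add(stage)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            logger.exception("stage %s failed", stage)
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stage(stage: str, cfg: dict, state: dict, seed: int, outdir: str) -> list[str]:
    if stage == "simulate":
        scfg = cfg["simulate"]
        ann = synthetic_data.make_annotation(scfg["n_genes"], seed=seed)
        mix = {
            "exact_copy": 0.3,
            "truncation": 0.15,
            "exon_skip": 0.15,
            "intron_retain": 0.1,
            "alt_donor": 0.1,
            "alt_acceptor": 0.1,
            "antisense_copy": 0.05,
            "intergenic_fragment": 0.05,
        }
        obs, truth = synthetic_data.perturb_transcripts(
            ann, mix, n=scfg["n_observed"], seed=seed + 1
        )
        design = synthetic_data.CohortDesign(seed=seed + 2)
        cm = synthetic_data.simulate_counts(ann, design, seed=seed + 3)
        prot = synthetic_data.simulate_proteomics(
            synthetic_data.ProteomicsStudySpec(), seed=seed + 4
        )
        vel = synthetic_data.simulate_motility(
            synthetic_data.MotilitySpec(), seed=seed + 5
        )
        state.update(ann=ann, obs=obs, truth=truth, cm=cm, prot=prot, vel=vel)
        paths = []
        p = os.path.join(outdir, "reference.gtf")
        core_model.write_transcripts(list(ann), p)
        paths.append(p)
        p = os.path.join(outdir, "observed.gtf")
        core_model.write_transcripts(obs, p)
        paths.append(p)
        p = os.path.join(outdir, "counts.tsv")
        cm.counts.to_csv(p, sep="\t")
        paths.append(p)
        p = os.path.join(outdir, "metadata.tsv")
        cm.metadata.to_csv(p, sep="\t")
        paths.append(p)
        p = os.path.join(outdir, "motility.tsv")
        vel.to_csv(p, sep="\t", index=False)
        paths.append(p)
        return paths
    if stage == "classify":
        table, summary = structural_classify.classify_batch(state["obs"], state["ann"])
        state["calls"] = table
        p1 = os.path.join(outdir, "calls.tsv")
        table.to_csv(p1, sep="\t", index=False)
        p2 = os.path.join(outdir, "class_length_summary.tsv")
        summary.to_csv(p2, sep="\t")
        return [p1, p2]
    if stage == "events":
        calls = state["calls"]
        assigned = calls.dropna(subset=["matched_gene_id"])
        gene_of = dict(zip(assigned["transcript_id"], assigned["matched_gene_id"]))
        novel = set(
            calls.loc[~calls["category"].isin(["FSM", "ISM"]), "transcript_id"]
        )
        evs = splice_events.enumerate_events(
            state["ann"], state["obs"], gene_of, novel
        )
        p1 = os.path.join(outdir, "events.tsv")
        splice_events.events_table(evs).to_csv(p1, sep="\t", index=False)
        p2 = os.path.join(outdir, "event_counts.tsv")
        splice_events.count_by_type(evs).to_csv(p2, sep="\t")
        return [p1, p2]
    if stage == "de":
        dcfg = cfg["de"]
        cm = state["cm"]
        s = diffexpr.size_factors(cm.counts)
        alpha = diffexpr.estimate_dispersions(cm.counts, s)
        X, names = diffexpr.design_matrix(
            cm.metadata, contrast_groups=("DCM", "ICM")
        )
        res = diffexpr.nb_wald(cm.counts, s, alpha, X, contrast=1)
        calib = diffexpr.permutation_cutoff(
            cm.counts,
            s,
            alpha,
            cm.metadata,
            {"contrast_groups": ("DCM", "ICM")},
            B=dcfg["permutations"],
            seed=seed,
            target=dcfg["alpha_target"],
        )
        res = diffexpr.flag_significant(res, calib)
        state["de"] = res
        state["calib"] = calib
        p1 = os.path.join(outdir, "de_transcripts.tsv")
        res.to_csv(p1, sep="\t")
        p2 = os.path.join(outdir, "de_calibration.json")
        with open(p2, "w") as fh:
            json.dump(
                {
                    "B": calib.B,
                    "alpha_star": calib.alpha_star,
                    "min_p": calib.min_p.tolist(),
                    "seed": calib.seed,
                    "fold_change_guide": dcfg["fold_change_guide"],
                },
                fh,
                indent=2,
            )
        return [p1, p2]
    if stage == "usage":
        cm = state["cm"]
        gene_map = pd.Series(
            {t.transcript_id: t.gene_id for t in state["ann"]}, name="gene_id"
        ).reindex(cm.counts.index)
        groups = np.where(cm.metadata["condition"] == "CTRL", "CTRL", "HF")
        usage = isoform_usage.usage_table(cm.counts, gene_map, groups)
        switches = isoform_usage.detect_opposing(
            state["de"], gene_map, alpha_star=state["calib"].alpha_star
        )
        p1 = os.path.join(outdir, "usage.tsv")
        usage.to_csv(p1, sep="\t")
        p2 = os.path.join(outdir, "switches.tsv")
        switches.to_csv(p2, sep="\t")
        return [p1, p2]
    if stage == "meta":
        effects_by_gene: dict[str, list] = {}
        for sid, study in state["prot"].items():
            gene_tab = proteomics_meta.aggregate_protein_groups(
                study["intensities"], study["group_map"]
            )
            for eff in proteomics_meta.study_effect(
                gene_tab, study["covariates"], study_id=sid
            ):
                effects_by_gene.setdefault(eff.gene, []).append(eff)
        rows = []
        for gene, effs in sorted(effects_by_gene.items()):
            if len(effs) < 2:
                continue
            m = proteomics_meta.meta_re(effs)
            rows.append(
                {
                    "gene": gene,
                    "k": m.k,
                    "log2FoldChange": m.mu,
                    "se": m.se,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "pvalue": m.pvalue,
                    "Q": m.Q,
                    "tau2": m.tau2,
                    "I2": m.I2,
                    "percent_change": proteomics_meta.percent_change(m.mu),
                }
            )
        meta_tab = pd.DataFrame(rows).set_index("gene")
        state["meta"] = meta_tab
        p1 = os.path.join(outdir, "meta.tsv")
        meta_tab.to_csv(p1, sep="\t")
        return [p1]
    if stage == "sectors":
        de = state["de"]
        gene_map = pd.Series(
            {t.transcript_id: t.gene_id for t in state["ann"]}
        ).reindex(de.index)
        rna = de.assign(gene=gene_map).groupby("gene").agg(
            log2FoldChange=("log2FoldChange", "mean"),
            significant=("significant", "any"),
        )
        prot = state["meta"].assign(significant=state["meta"]["pvalue"] < 0.05)[
            ["log2FoldChange", "significant"]
        ]
        table, summary = proteomics_meta.nine_sector(rna, prot)
        p1 = os.path.join(outdir, "sectors.tsv")
        table.to_csv(p1, sep="\t")
        p2 = os.path.join(outdir, "sector_summary.json")
        with open(p2, "w") as fh:
            json.dump(summary, fh, indent=2)
        return [p1, p2]
    if stage == "motility":
        fit = motility.fit_hill(state["vel"])
        p1 = os.path.join(outdir, "motility_fit.json")
        with open(p1, "w") as fh:
            json.dump(
                {
                    "v_max": fit.v_max,
                    "v_min": fit.v_min,
                    "pCa50": fit.pca50,
                    "n_H": fit.n_h,
                    "R2": fit.r_squared,
                },
                fh,
                indent=2,
            )
        p2 = os.path.join(outdir, "motility_means.tsv")
        fit.means.to_csv(p2, sep="\t")
        return [p1, p2]
    raise ValueError(f"unknown stage {stage}")
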