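"""End-to-end orchestration: simulate -> DE -> specificity -> co-localization
-> targets/sponges/pre-miRNAs -> interaction filters -> network.

Every stage writes its table before dependents run, and the final report
collects the per-stage counts (DE totals by biotype, specific gene counts,
pair/triple counts, component sizes).  Stage outputs are pure functions of
(inputs, thresholds, seed), so a rerun with the same config is identical.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import coloc, diffexpr, interactions, io, mirna, network, specificity
from .io import ValidationError
from .simulate import (
    GroundTruth,
    SimConfig,
    simulate_counts,
    simulate_genome,
    simulate_panels,
    transcript_utr3s,
)

log = logging.getLogger("degradome")

THRESHOLD_RANGES = {
    "fold_threshold": (1.0, np.inf),
    "fdr_threshold": (0.0, 1.0),
    "z_threshold": (0.0, np.inf),
    "max_dist": (1, np.inf),
    "r_strong": (0.0, 1.0),
    "r_network": (0.0, 1.0),
    "energy_threshold": (-np.inf, 0.0),
    "min_strength": (0.0, 100.0),
    "min_power": (0.0, 100.0),
}


@dataclass
class PipelineConfig:
    """All stage thresholds plus either a simulation block or input paths."""

    outdir: str = "degradome_out"
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig | None = None
    counts_path: str | None = None
    annotation_path: str | None = None
    fold_threshold: float = diffexpr.FOLD_THRESHOLD
    fdr_threshold: float = diffexpr.FDR_THRESHOLD
    z_threshold: float = specificity.Z_THRESHOLD
    max_dist: int = coloc.MAX_DIST
    r_strong: float = coloc.R_STRONG
    r_network: float = network.R_NETWORK
    energy_threshold: float = interactions.ENERGY_THRESHOLD
    min_strength: float = interactions.MIN_STRENGTH
    min_power: float = interactions.MIN_POWER


def validate_config(raw: Mapping[str, Any]) -> tuple[PipelineConfig | None, list[str]]:
    """Fill defaults and collect every error (not just the first).

    Returns (config, []) on success or (None, errors); each error names
    the offending key.
    """
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    cfg_kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "sim":
            try:
                cfg_kwargs["sim"] = value if isinstance(value, SimConfig) else SimConfig(**value)
            except (TypeError, ValidationError) as exc:
                errors.append(f"sim: {exc}")
            continue
        if key not in known:
            errors.append(f"{key}: unknown configuration key")
            continue
        cfg_kwargs[key] = value
    for key, (lo, hi) in THRESHOLD_RANGES.items():
        if key in cfg_kwargs and not (lo <= float(cfg_kwargs[key]) <= hi):
            errors.append(f"{key}: value {cfg_kwargs[key]} outside [{lo}, {hi}]")
    if "sim" not in cfg_kwargs and "counts_path" not in cfg_kwargs:
        errors.append("sim: either a sim block or counts_path/annotation_path inputs are required")
    if errors:
        return None, errors
    cfg = PipelineConfig(**cfg_kwargs)
    if cfg.counts_path:
        cfg.counts_path = str(Path(cfg.counts_path).resolve())
    if cfg.annotation_path:
        cfg.annotation_path = str(Path(cfg.annotation_path).resolve())
    return cfg, []


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg, errors = validate_config(raw)
    if errors:
        raise ValidationError("; ".join(errors))
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and return the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception:
                log.error("stage %s failed; partial outputs retained in %s", name, out)
                raise
            report["stages"][name] = result
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    if config.sim is None:
        raise ValidationError("file-based runs need a sim block in this release; see docs")
    sim = replace(config.sim, seed=config.seed)

    # --- simulate ---------------------------------------------------------
    def _simulate():
        records, seqs, truth = simulate_genome(sim)
        expr = simulate_counts(truth, sim)
        tissue, month2, month3, netmat = simulate_panels(truth, sim)
        io.write_gff3(records, out / "annotation.gff3")
        io.write_bed(records, out / "annotation.bed")
        io.write_fasta(seqs, out / "transcripts.fa")
        io.write_fasta(truth.premirna_seqs, out / "premirnas.fa")
        io.write_fasta(truth.mirna_seqs, out / "mirnas.fa")
        io.write_matrix_tsv(expr.values, out / "counts.tsv")
        io.write_matrix_tsv(tissue, out / "tissue_tpm.tsv")
        io.write_matrix_tsv(month2, out / "month_2N.tsv")
        io.write_matrix_tsv(month3, out / "month_3N.tsv")
        io.write_matrix_tsv(netmat, out / "network_matrix.tsv")
        truth.to_json(out / "ground_truth.json")
        state.update(records=records, seqs=seqs, truth=truth, expr=expr,
                     tissue=tissue, month2=month2, month3=month3, netmat=netmat)
        return {"transcripts": len(records), "planted_de": len(truth.de)}

    state: dict[str, Any] = {}
    stage("simulate")(_simulate)

    truth: GroundTruth = state["truth"]
    records = state["records"]
    biotypes = truth.transcripts

    # --- differential expression -----------------------------------------
    def _de():
        table = diffexpr.de_analysis(
            state["expr"],
            case_group="2N",
            fc_threshold=config.fold_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        table.to_csv(out / "de_table.tsv", sep="\t", index=False)
        state["de"] = table
        called = table[table["call"] != "not-DE"]
        by_biotype = {
            bt: int(sum(biotypes.get(i) == bt for i in called["id"]))
            for bt in ("mRNA", "lncRNA", "miRNA")
        }
        return {"de_total": len(called), "de_by_biotype": by_biotype,
                "up": int((called["call"] == "up").sum()),
                "down": int((called["call"] == "down").sum())}

    stage("de")(_de)
    de_ids = set(state["de"].loc[state["de"]["call"] != "not-DE", "id"])

    # --- specificity ------------------------------------------------------
    def _specificity():
        tissue_tab = specificity.specificity_table(state["tissue"], config.z_threshold)
        tissue_tab.to_csv(out / "tissue_specificity.tsv", sep="\t")
        # 4-condition panels need the population-sd variant: with the sample
        # sd the largest attainable z over 4 conditions is exactly 1.5
        month_tab = specificity.specificity_table(state["month2"], config.z_threshold, ddof=0)
        month_tab.to_csv(out / "month_specificity.tsv", sep="\t")
        ratios = specificity.temporal_ratio_profile(state["month2"], state["month3"])
        prof = specificity.aggregate_profile(ratios, [g for g in truth.month_peak])
        labels = tissue_tab["specific_to"]
        spec_ids = set(labels[labels.notna()].index)
        n_spec_de = len(spec_ids & de_ids)
        state["tissue_labels"] = labels
        return {
            "tissue_specific": len(spec_ids),
            "tissue_specific_in_de": n_spec_de,
            "month_specific": int(month_tab["specific_to"].notna().sum()),
            "peak_month": str(prof.idxmax()),
        }

    stage("specificity")(_specificity)

    # --- co-localization --------------------------------------------------
    def _coloc():
        lnc = [r for r in records if r.biotype == "lncRNA" and r.id in de_ids]
        mr = [r for r in records if r.biotype == "mRNA" and r.id in de_ids]
        pairs = coloc.find_coloc_pairs(lnc, mr, config.max_dist)
        pairs = coloc.annotate_pairs(pairs, state["netmat"])
        coloc.pairs_to_frame(pairs).to_csv(out / "coloc_pairs.tsv", sep="\t", index=False)
        state["pairs"] = pairs
        summary: dict[str, Any] = {
            "pairs": len(pairs),
            "lncrnas_in_pairs": len({p.lncrna for p in pairs}),
            "mrnas_in_pairs": len({p.mrna for p in pairs}),
        }
        strong = sum(1 for p in pairs if p.pearson_r > config.r_strong)
        summary["strong_pairs"] = strong
        if pairs and lnc and mr:
            rows = state["netmat"]
            strong_all = 0
            n_all = 0
            for l in lnc:
                for m in mr:
                    r = coloc.pearson_r(rows.loc[l.id].to_numpy(), rows.loc[m.id].to_numpy())
                    n_all += 1
                    strong_all += bool(r > config.r_strong)
            try:
                chi2, p = coloc.correlation_enrichment_test(
                    strong, len(pairs), strong_all, n_all, config.r_strong
                )
                summary["enrichment_chi2_p"] = p
            except ValidationError:
                summary["enrichment_chi2_p"] = None
        return summary

    stage("coloc")(_coloc)

    # --- miRNA targets / sponges / pre-miRNAs -----------------------------
    def _targets():
        seqs = state["seqs"]
        utr3s = transcript_utr3s(seqs, biotypes)
        sites = mirna.scan_transcriptome(
            truth.mirna_seqs, seqs, biotypes, utr3s, min_class="8mer"
        )
        mirna.sites_to_frame(sites).to_csv(out / "target_sites.tsv", sep="\t", index=False)
        state["sites"] = sites
        return {"sites": len(sites)}

    stage("targets")(_targets)

    def _sponges():
        sites = state["sites"]
        lnc_sites = [s for s in sites if biotypes.get(s.transcript) == "lncRNA"]
        mrna_sites = [s for s in sites if biotypes.get(s.transcript) == "mRNA"]
        triples = mirna.find_sponge_candidates(lnc_sites, mrna_sites, state["netmat"])
        mirna.triples_to_frame(triples).to_csv(out / "sponge_triples.tsv", sep="\t", index=False)
        return {"triples": len(triples),
                "mirnas_shared": len({t.mirna for t in triples})}

    stage("sponges")(_sponges)

    def _premirna():
        lnc_seqs = {i: s for i, s in state["seqs"].items() if biotypes.get(i) == "lncRNA"}
        hits = mirna.find_harbored_premirnas(truth.premirna_seqs, lnc_seqs)
        pd.DataFrame(hits, columns=["lncrna", "premirna", "offset", "strand"]).to_csv(
            out / "harbored_premirnas.tsv", sep="\t", index=False
        )
        return {"harbored": len(hits)}

    stage("premirna")(_premirna)

    # --- interaction filtering -------------------------------------------
    def _interactions():
        rng = np.random.default_rng(config.seed + 3)
        seqs = state["seqs"]
        lnc_ids = sorted(i for i in seqs if biotypes.get(i) == "lncRNA" and i in de_ids)
        mr_ids = sorted(i for i in seqs if biotypes.get(i) == "mRNA" and i in de_ids)
        rows = []
        for l in lnc_ids[:10]:
            for m in mr_ids[:10]:
                rows.append(
                    dict(lncrna=l, partner=m, kind="mRNA",
                         energy=interactions.toy_interaction_energy(seqs[l], seqs[m])
                         + float(rng.normal(-60, 40)))
                )
        table = pd.DataFrame(rows, columns=["lncrna", "partner", "kind", "energy"])
        table.to_csv(out / "rna_rna_interactions.tsv", sep="\t", index=False)
        passing = interactions.filter_rna_rna(table, config.energy_threshold)
        passing.to_csv(out / "rna_rna_passing.tsv", sep="\t", index=False)
        return {"rna_rna_total": len(table), "rna_rna_passing": len(passing)}

    stage("interactions")(_interactions)

    # --- co-expression network -------------------------------------------
    def _network():
        mat = network.scale_normalize(state["netmat"])
        directions = dict(zip(state["de"]["id"], state["de"]["call"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = network.build_network(mat, config.r_network, biotypes, directions)
        comps = network.connected_components(net)
        hubs = network.hub_scores(net)
        network.export_graph(net, out / "network.sif", "sif")
        network.export_graph(net, out / "network.graphml", "graphml")
        pd.DataFrame(
            [
                dict(rank=i + 1, size=c["size"], **{f"n_{k}": v for k, v in c["biotype_counts"].items()})
                for i, c in enumerate(comps)
            ]
        ).to_csv(out / "network_components.tsv", sep="\t", index=False)
        return {
            "edges": net.graph.number_of_edges(),
            "component_sizes": [c["size"] for c in comps],
            "top_hubs": [h[0] for h in hubs[:5]],
        }

    stage("network")(_network)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    def _plain(v):
        if isinstance(v, dict):
            return {k: _plain(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_plain(x) for x in v]
        return v

    (out / "config_resolved.yaml").write_text(yaml.safe_dump(_plain(asdict(config)), sort_keys=True))
    return report


__all__ = ["PipelineConfig", "load_config", "run_pipeline", "validate_config"]
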