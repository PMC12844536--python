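"""Pipeline orchestration.

Runs the stages in dependency order on a dataset bundle (in memory from
the generator, or loaded from files): normalization, confounded-cluster
detection and batch residualization, differential testing, DAR/DEG
classification, H3K27ac activity classification, variant-zone
integration, correlation linking, motif preparation, footprint scoring
and AC-footprint concordance. Outputs are plain DataFrames collected in
a report bundle with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import counts as cmod
from . import footprints as fmod
from . import linking as lmod
from . import motifs as mmod
from . import variants as vmod
from .intervals import classify_activity, sample_random_regions
from .simulate import SimData

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_dataset", "run_pipeline"]

ALL_STAGES = [
    "normalize", "batch", "differential", "classify", "activity",
    "variant_integration", "linking", "motifs", "footprints", "ac",
]


@dataclass
class RunConfig:
    """Thresholds and toggles for one pipeline run."""

    seed: int = 0
    dar_fdr: float = 0.01
    dar_min_abs_log2fc: float = float(np.log2(1.5))
    deg_fdr: float = 0.05
    corr_p: float = 0.05
    scan_p: float = 1e-4
    ic_min: float = 0.75
    similarity_min: float = 0.95
    min_mean_logcpm: float = -3.0
    activity_flank_bp: int = 1000
    peak_zone_center: int = 25
    fp_zone_center: int = 10
    zone_flank: int = 250
    link_window: int = 1_000_000
    rolling_window: int = 501
    rolling_step: int = 100
    background_per_feature: int = 10
    stages: list = field(default_factory=lambda: list(ALL_STAGES))

    def validate(self) -> None:
        for name in ("dar_fdr", "deg_fdr", "corr_p", "scan_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_dataset(indir: str | Path) -> SimData:
    """Load a dataset bundle written by SimData.write (or same layout)."""
    from .simulate import SimConfig

    indir = Path(indir)
    genome_str = sio.read_fasta(indir / "genome.fa")
    code = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    genome = {
        c: code[np.frombuffer(s.encode(), dtype=np.uint8)]
        for c, s in genome_str.items()
    }
    peaks = sio.read_bed(indir / "peaks.bed").rename(columns={"id": "feature_id"})
    with open(indir / "truth.json") as fh:
        truth = json.load(fh)
    cfg_path = indir / "sim_config.json"
    cfg = SimConfig(**json.load(open(cfg_path))) if cfg_path.exists() else SimConfig()
    fp = pd.read_csv(indir / "footprints.tsv", sep="\t", keep_default_na=False)
    fp["variant_id"] = fp["variant_id"].replace("", np.nan)
    return SimData(
        config=cfg,
        chrom_sizes=sio.read_chrom_sizes(indir / "chrom.sizes"),
        genome=genome,
        peaks=peaks,
        h3k27ac=sio.read_bed(indir / "h3k27ac.bed"),
        variants=sio.read_vcf_snvs(indir / "variants.vcf"),
        atac_counts=sio.read_counts(indir / "atac_counts.tsv"),
        rna_counts=sio.read_counts(indir / "rna_counts.tsv"),
        samples=sio.read_sample_sheet(indir / "samples.tsv"),
        tss=sio.read_tss_table(indir / "tss.tsv"),
        motifs=mmod.read_motifs_meme(indir / "motifs.meme"),
        footprints=fp,
        cut_profiles=pd.read_csv(indir / "cut_profiles.tsv", sep="\t"),
        depth_factors={},
        offset_map=sio.read_offset_map(indir / "offset_map.tsv"),
        truth=truth,
    )


def _stage(cfg: RunConfig, name: str) -> bool:
    return name in cfg.stages


def run_pipeline(
    data: SimData, config: RunConfig | None = None, outdir: str | Path | None = None
) -> dict:
    """Execute the analysis stages and return a report bundle dict.

    The bundle maps stage-output names to DataFrames plus a ``manifest``
    with config, seed, and row counts; with ``outdir`` set every table is
    also written as TSV.
    """
    cfg = config or RunConfig()
    cfg.validate()
    t0 = time.time()
    out: dict = {}
    peaks = data.peaks.copy()
    peaks["id"] = peaks["feature_id"]

    # ---- normalize ---------------------------------------------------
    if _stage(cfg, "normalize"):
        atac_logcpm = cmod.normalize_logcpm(data.atac_counts)
        rna_logcpm = cmod.normalize_logcpm(data.rna_counts)
        kept = cmod.filter_features(atac_logcpm, cfg.min_mean_logcpm)
        logger.info("peak filter: %d of %d retained", len(kept), len(atac_logcpm))
        atac_logcpm = atac_logcpm.loc[kept]
        out["atac_logcpm"] = atac_logcpm
        out["rna_logcpm"] = rna_logcpm
        out["retained_peaks"] = pd.DataFrame({"feature_id": kept})

    # ---- batch -------------------------------------------------------
    if _stage(cfg, "batch"):
        labels, cluster_diff = cmod.detect_confounded_cluster(
            out["atac_logcpm"], data.samples, seed=cfg.seed
        )
        out["batch_labels"] = labels.rename_axis("sample_id").reset_index()
        out["cluster_diff_atac"] = cluster_diff
        if (labels == 2).sum() >= 2:
            out["cluster_diff_rna"] = cmod._two_group_moderated(
                out["rna_logcpm"],
                out["rna_logcpm"].columns[labels == 2],
                out["rna_logcpm"].columns[labels == 1],
                comparison="cluster2_vs_1",
            )
        else:
            out["cluster_diff_rna"] = pd.DataFrame()
        atac_bc = cmod.residualize_batch(out["atac_logcpm"], labels, data.samples)
        rna_bc = cmod.residualize_batch(out["rna_logcpm"], labels, data.samples)
        out["atac_corrected"] = atac_bc
        out["rna_corrected"] = rna_bc
    else:
        out["atac_corrected"] = out.get("atac_logcpm")
        out["rna_corrected"] = out.get("rna_logcpm")

    # ---- differential ------------------------------------------------
    if _stage(cfg, "differential"):
        out["atac_diff"] = {
            cmp_: cmod.differential_test(out["atac_corrected"], data.samples, cmp_)
            for cmp_ in cmod.COMPARISONS
        }
        out["rna_diff"] = {
            cmp_: cmod.differential_test(out["rna_corrected"], data.samples, cmp_)
            for cmp_ in cmod.COMPARISONS
        }

    # ---- classify ----------------------------------------------------
    if _stage(cfg, "classify"):
        out["dar_classes"] = cmod.classify_dars(
            out["atac_diff"]["strain_chow"],
            out["atac_diff"]["strain_HFD"],
            fdr_max=cfg.dar_fdr,
            min_abs_log2fc=cfg.dar_min_abs_log2fc,
        )
        out["deg_classes"] = cmod.classify_degs(
            out["rna_diff"], fdr_max=cfg.deg_fdr
        )

    # ---- activity ----------------------------------------------------
    if _stage(cfg, "activity"):
        act = classify_activity(peaks, data.h3k27ac, cfg.activity_flank_bp)
        out["activity"] = pd.DataFrame(
            {"feature_id": peaks["feature_id"], "activity": act.to_numpy()}
        )

    # ---- variant integration -----------------------------------------
    if _stage(cfg, "variant_integration"):
        nv = pd.DataFrame(
            {"feature_id": peaks["feature_id"],
             "n_variants": vmod.count_variants_in_peaks(peaks, data.variants)}
        )
        peak_table = out["dar_classes"].merge(
            peaks[["feature_id", "chrom", "start", "end"]], on="feature_id"
        ).merge(nv, on="feature_id")
        out["peak_table"] = peak_table
        out["fdr_windows"] = vmod.variant_fraction_by_fdr_window(peak_table)
        out["class_variant_enrichment"] = vmod.class_variant_enrichment(peak_table)
        zone_rows = []
        for cls in ("Common", "Chow", "HFD", "NonDAR"):
            feats = peak_table[peak_table["dar_class"] == cls]
            if len(feats) == 0:
                continue
            bg = sample_random_regions(
                feats, cfg.background_per_feature, data.chrom_sizes,
                rng_seed=cfg.seed + 1,
            )
            for z in vmod.zone_enrichment(
                feats, data.variants, bg,
                center_halfwidth=cfg.peak_zone_center,
                flank_outer=cfg.zone_flank, feature_set=cls,
            ):
                zone_rows.append(
                    {"feature_set": cls, "zone": z.zone,
                     "observed": z.observed_variants,
                     "background": z.background_variants,
                     "odds_ratio": z.result.odds_ratio, "p": z.result.p_value}
                )
        out["zone_enrichment"] = pd.DataFrame(zone_rows)
        out["density_profiles"] = vmod.variant_density_profile(
            peak_table, data.variants,
            classes=peak_table["dar_class"],
            halfwidth=cfg.zone_flank,
        )

    # ---- linking -----------------------------------------------------
    if _stage(cfg, "linking"):
        dars = out["peak_table"][
            out["peak_table"]["dar_class"] != "NonDAR"
        ].reset_index(drop=True)
        pairs = lmod.link_dar_pairs(
            dars, out["atac_corrected"], max_distance=cfg.link_window,
            p_max=cfg.corr_p,
        )
        out["dar_pairs"] = pairs
        out["rolling_curves"] = lmod.rolling_correlation_curve(
            pairs[pairs["p"] < cfg.corr_p],
            window=cfg.rolling_window, step=cfg.rolling_step,
        )
        summary, links = lmod.link_dars_to_degs(
            out["deg_classes"], data.tss, dars,
            out["rna_corrected"], out["atac_corrected"],
            p_max=cfg.corr_p,
        )
        out["deg_dar_fractions"] = summary
        out["gene_dar_links"] = links
        strata = out["activity"].merge(
            out["peak_table"][["feature_id", "n_variants"]], on="feature_id"
        )
        strata["has_variant"] = strata["n_variants"] >= 1
        counts_pg, tests = lmod.cumulative_dar_counts(
            out["deg_classes"], data.tss, dars,
            window=cfg.link_window,
            strata=strata[["feature_id", "activity", "has_variant"]],
        )
        out["cumulative_dar_counts"] = counts_pg
        out["cumulative_dar_tests"] = tests
        rep = out["rna_diff"]["strain_chow"]
        out["nearest_feature_bins"] = lmod.nearest_feature_stats(
            out["deg_classes"], rep, data.tss, dars
        )

    # ---- motifs ------------------------------------------------------
    if _stage(cfg, "motifs"):
        merged, member_map = mmod.filter_and_merge(
            data.motifs, ic_min=cfg.ic_min, similarity_min=cfg.similarity_min
        )
        out["merged_motifs"] = merged
        out["motif_members"] = pd.DataFrame(
            [
                {"merged_id": k, "member_id": m}
                for k, v in member_map.items() for m in v
            ]
        )
        out["score_distributions"] = {
            m.motif_id: mmod.score_distribution(m) for m in data.motifs
        }

    # ---- footprints --------------------------------------------------
    if _stage(cfg, "footprints"):
        totals = data.cut_profiles.groupby("group")["count"].sum()
        depth = (totals / totals.mean()).to_dict()
        scored = fmod.score_profiles(data.cut_profiles, depth_factors=depth)
        out["footprint_scores"] = scored
        bound = fmod.call_bound(scored, seed=cfg.seed)
        out["bound_calls"] = bound
        wide = scored.pivot(index="footprint_id", columns="group", values="score")
        sites = data.footprints.copy()
        sites["score_diff"] = [
            fmod.strain_score_difference(wide.loc[f].to_dict())
            for f in sites["footprint_id"]
        ]
        bound_any = bound.groupby("footprint_id")["bound"].any()
        sites["bound_any"] = sites["footprint_id"].map(bound_any)
        for g in wide.columns:
            sites[f"score_{g}"] = sites["footprint_id"].map(wide[g])
        out["footprint_sites"] = sites

    # ---- ac ----------------------------------------------------------
    if _stage(cfg, "ac"):
        sites = out["footprint_sites"].copy()
        motif_by_id = {m.motif_id: m for m in data.motifs}
        var_by_id = data.variants.set_index("variant_id")
        eff_rows = []
        dists = out.get("score_distributions") or {
            m.motif_id: mmod.score_distribution(m) for m in data.motifs
        }
        with_var = sites[sites["variant_id"].notna() & (sites["variant_id"] != "")]
        for row in with_var.itertuples():
            m = motif_by_id[row.motif_id]
            v = var_by_id.loc[row.variant_id]
            L = m.length
            codes = data.genome[v["chrom"]][
                v["pos"] - (L - 1) : v["pos"] + L
            ]
            ref_seq = "".join(mmod.BASES[c] for c in codes)
            voff = L - 1
            if ref_seq[voff] != v["ref_allele"]:
                raise ValueError(
                    f"genome/VCF mismatch at {row.variant_id}"
                )
            alt_seq = (
                ref_seq[:voff] + v["alt_allele"] + ref_seq[voff + 1 :]
            )
            eff = mmod.allelic_score(
                m, ref_seq, alt_seq, variant_id=row.variant_id,
                dist=dists[m.motif_id], p_max=cfg.scan_p,
            )
            eff_rows.append(
                {"variant_id": eff.variant_id, "motif_id": eff.motif_id,
                 "tf_name": eff.tf_name, "ref_score": eff.best_ref_score,
                 "alt_score": eff.best_alt_score,
                 "scaled_delta": eff.scaled_delta,
                 "strength": eff.strength, "significant": eff.significant}
            )
        effects = pd.DataFrame(eff_rows)
        out["allelic_effects"] = effects
        sites["overlapping_variant"] = sites["variant_id"].where(
            sites["variant_id"].notna() & (sites["variant_id"] != "")
        )
        if len(effects):
            sites["ac_flag"] = fmod.detect_ac_footprints(sites, effects)
            emap = effects.set_index(["variant_id", "motif_id"])
            keys = list(zip(sites["overlapping_variant"], sites["motif_id"]))
            sites["scaled_delta"] = [
                emap.at[k, "scaled_delta"] if k in emap.index else np.nan
                for k in keys
            ]
            sites["strength"] = [
                emap.at[k, "strength"] if k in emap.index else "none"
                for k in keys
            ]
        else:
            sites["ac_flag"] = False
            sites["scaled_delta"] = np.nan
            sites["strength"] = "none"
        cls_map = out["dar_classes"].set_index("feature_id")["dar_class"]
        sites["dar_class"] = sites["nfr_id"].map(cls_map)
        out["footprint_sites"] = sites
        out["ac_analysis"] = fmod.ac_enrichment_by_class(
            sites.dropna(subset=["dar_class"])
        )
        out["tf_stats"] = fmod.tf_level_stats(sites, out["dar_classes"])
        # variant enrichment at footprint centers
        bg = sample_random_regions(
            sites, cfg.background_per_feature, data.chrom_sizes,
            rng_seed=cfg.seed + 2,
        )
        fp_zone = vmod.zone_enrichment(
            sites, data.variants, bg,
            center_halfwidth=cfg.fp_zone_center,
            flank_outer=cfg.zone_flank, feature_set="footprints",
        )
        out["footprint_zone_enrichment"] = pd.DataFrame(
            [
                {"zone": z.zone, "observed": z.observed_variants,
                 "background": z.background_variants,
                 "odds_ratio": z.result.odds_ratio, "p": z.result.p_value}
                for z in fp_zone
            ]
        )

    out["manifest"] = _manifest(cfg, out, t0)
    if outdir is not None:
        _write_bundle(out, Path(outdir))
    return out


def _manifest(cfg: RunConfig, out: dict, t0: float) -> dict:
    counts = {
        k: int(len(v)) for k, v in out.items() if isinstance(v, pd.DataFrame)
    }
    h = hashlib.sha256()
    for k in sorted(counts):
        v = out[k]
        h.update(k.encode())
        h.update(v.to_csv(index=False).encode())
    return {
        "config": {k: (v if not isinstance(v, list) else list(v))
                   for k, v in asdict(cfg).items()},
        "row_counts": counts,
        "output_hash": h.hexdigest(),
        "elapsed_s": round(time.time() - t0, 2),
    }


def _write_bundle(out: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for k, v in out.items():
        if isinstance(v, pd.DataFrame):
            v.to_csv(outdir / f"{k}.tsv", sep="\t", index=not isinstance(
                v.index, pd.RangeIndex))
        elif isinstance(v, dict) and k in ("atac_diff", "rna_diff"):
            for cmp_, df in v.items():
                df.to_csv(outdir / f"{k}_{cmp_}.tsv", sep="\t", index=False)
        elif isinstance(v, dict) and k == "ac_analysis":
            for name, df in v.items():
                df.to_csv(outdir / f"ac_{name}.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(out["manifest"], fh, indent=1, sort_keys=True)
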