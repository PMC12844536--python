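"""Seeded two-strain x two-diet synthetic dataset with full ground truth.

The generator emulates the statistical structure of a bulk ATAC-seq +
RNA-seq comparison of two inbred mouse strains (B6 reference, 129
alternate) on two diets: strain-specific accessibility driven by SNVs at
peak centers, near-zero diet effects on chromatin, a contaminating
cell-type sample cluster, H3K27ac intervals flanking active peaks,
expression coupled to nearby accessibility, and Tn5 cut-site profiles
whose footprint depth follows a logistic function of the strain allele's
motif score. Every planted label is recorded in a truth object so each
pipeline stage can be scored for recovery.

All randomness flows from a single seed; identical seeds give identical
outputs, byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .intervals import OffsetMap
from .motifs import BASES, PWMotif, write_motifs_meme, score_distribution

__all__ = ["SimConfig", "SimData", "generate", "truth_report"]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults are the conditions the pipeline is validated under: 6
    replicates per strain x diet group (5 for 129/HFD), NB dispersion
    0.1, variant-driven strain DARs at |log2fc| = 1.5, center-variant
    fractions 0.8/0.6/0.4 for Common/Chow/HFD DARs, and a 7-sample
    contaminating cluster shifted 2 log2 units on a marker set.
    """

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 12_000_000
    # peaks
    n_peaks: int = 2000
    peak_width_min: int = 200
    peak_width_max: int = 400
    n_decoy_peaks: int = 50
    decoy_mean: float = 0.01
    # DAR structure
    n_common_dar: int = 180
    n_chow_dar: int = 140
    n_hfd_dar: int = 100
    strain_lfc: float = 1.5
    variant_center_frac: dict = field(
        default_factory=lambda: {
            "Common": 0.8, "Chow": 0.6, "HFD": 0.4, "NonDAR": 0.12,
        }
    )
    center_variant_halfwidth: int = 25
    background_snv_per_bp: float = 1.0 / 3000.0
    # counts
    dispersion: float = 0.1
    baseline_shape: float = 2.0
    baseline_mean: float = 3000.0
    lib_factor_min: float = 0.7
    lib_factor_max: float = 1.3
    samples_per_group: int = 6
    short_group: str = "S129:HFD"   # this group gets one fewer replicate
    # contamination batch
    n_contam_samples: int = 7
    contam_shift: float = 2.0
    n_marker_genes: int = 100
    n_marker_peaks: int = 500
    marker_baseline_scale: float = 0.25   # marker features are depleted
    marker_search_bp: int = 8000          # in the host tissue's baseline
    # activity
    active_frac_dar: float = 0.7
    active_frac_nondar: float = 0.5
    h3k27ac_gap: int = 200
    h3k27ac_width: int = 500
    # genes
    n_genes: int = 600
    n_strain_deg: int = 60
    n_diet_deg: int = 40
    n_dietstrain_deg: int = 40
    gene_lfc: float = 1.5
    diet_lfc: float = 1.2
    linked_frac: float = 0.6
    linked_noise_sd: float = 0.2
    n_unexpressed: int = 20
    # co-accessibility
    coacc_spacing: int = 200_000
    coacc_scale: int = 100_000
    coacc_sd: float = 0.25
    coacc_max_load: float = 0.6
    # motifs / footprints
    n_fp_concordant: int = 120
    n_fp_discordant: int = 40
    n_fp_strong: int = 60
    n_fp_neutral: int = 60
    n_fp_graded: int = 220
    occ_slope: float = 10.0
    occ_x0: float = 0.75
    cut_base_rate: float = 30.0
    cut_depth_frac: float = 0.8
    profile_flank: int = 30
    group_depth_min: float = 0.85
    group_depth_max: float = 1.15

    def validate(self) -> None:
        n_special = (
            self.n_common_dar + self.n_chow_dar + self.n_hfd_dar
            + self.n_decoy_peaks
        )
        if n_special >= self.n_peaks:
            raise ValueError("DAR + decoy counts exceed n_peaks")
        per_chrom = self.n_peaks // self.n_chroms + 1
        if per_chrom * (self.peak_width_max + 2100) > self.chrom_length:
            raise ValueError("too many peaks for the genome size")
        for v in self.variant_center_frac.values():
            if not 0 <= v <= 1:
                raise ValueError("variant_center_frac out of [0,1]")


@dataclass
class SimData:
    """Generated dataset bundle plus ground truth."""

    config: SimConfig
    chrom_sizes: dict
    genome: dict                 # chrom -> np.uint8 codes 0..3
    peaks: pd.DataFrame          # feature_id chrom start end
    h3k27ac: pd.DataFrame
    variants: pd.DataFrame
    atac_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    samples: pd.DataFrame
    tss: pd.DataFrame
    motifs: list
    footprints: pd.DataFrame     # footprint_id chrom start end motif_id tf_name nfr_id variant_id
    cut_profiles: pd.DataFrame   # footprint_id offset count group
    depth_factors: dict
    offset_map: OffsetMap
    truth: dict

    def genome_sequences(self) -> dict[str, str]:
        return {c: _ASCII[v].tobytes().decode() for c, v in self.genome.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pk = self.peaks.rename(columns={"feature_id": "id"})
        sio.write_bed(pk, outdir / "peaks.bed")
        sio.write_bed(self.h3k27ac, outdir / "h3k27ac.bed")
        sio.write_vcf_snvs(self.variants, outdir / "variants.vcf")
        sio.write_counts(self.atac_counts, outdir / "atac_counts.tsv")
        sio.write_counts(self.rna_counts, outdir / "rna_counts.tsv")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
        write_motifs_meme(self.motifs, outdir / "motifs.meme")
        fp = self.footprints.rename(columns={"footprint_id": "id"})
        sio.write_bed(fp, outdir / "footprints.bed")
        self.footprints.to_csv(outdir / "footprints.tsv", sep="\t", index=False)
        self.cut_profiles.to_csv(outdir / "cut_profiles.tsv", sep="\t", index=False)
        sio.write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")
        sio.write_offset_map(self.offset_map, outdir / "offset_map.tsv")
        sio.write_fasta(self.genome_sequences(), outdir / "genome.fa")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _build_motifs(rng: np.random.Generator) -> tuple[list[PWMotif], dict]:
    """Fixed-architecture motif set: 3 core, 2 short-strong, 2 neutral.

    Core motifs (L=8, every position 0.94-dominant) give weak-class but
    significant single-base effects; short-strong motifs (L=4, two
    informative positions) give strong-class effects that never reach the
    scan p threshold; neutral motifs (L=8 with two split positions) give
    near-zero deltas between their two top bases.
    """

    def column(dom: int, p_dom: float) -> np.ndarray:
        col = np.full(4, (1 - p_dom) / 3)
        col[dom] = p_dom
        return col

    motifs: list[PWMotif] = []
    meta: dict[str, dict] = {}
    for k in range(3):
        doms = rng.integers(0, 4, size=8)
        mat = np.stack([column(d, 0.94) for d in doms])
        mid = f"core{k}"
        motifs.append(PWMotif(mid, f"TFcore{k}", mat))
        meta[mid] = {"kind": "core", "flip_positions": list(range(8))}
    for k in range(2):
        doms = rng.integers(0, 4, size=2)
        mat = np.vstack(
            [column(doms[0], 0.94), np.full(4, 0.25),
             column(doms[1], 0.94), np.full(4, 0.25)]
        )
        mid = f"strong{k}"
        motifs.append(PWMotif(mid, f"TFstrong{k}", mat))
        meta[mid] = {"kind": "strong", "flip_positions": [0, 2]}
    for k in range(2):
        doms = rng.integers(0, 4, size=8)
        mat = np.stack([column(d, 0.94) for d in doms])
        split_pos = [2, 5]
        for sp in split_pos:
            top = doms[sp]
            second = int(rng.choice([b for b in range(4) if b != top]))
            col = np.full(4, 0.03)
            col[top] = 0.50
            col[second] = 0.44
            mat[sp] = col
        mid = f"neutral{k}"
        motifs.append(PWMotif(mid, f"TFneutral{k}", mat))
        meta[mid] = {"kind": "neutral", "flip_positions": split_pos}
    return motifs, meta


def generate(config: SimConfig | None = None) -> SimData:
    """Generate the full dataset bundle with ground truth."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_length for c in chroms}
    genome = {
        c: rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
        for c in chroms
    }

    # ---- samples -----------------------------------------------------
    groups = ["B6:chow", "B6:HFD", "S129:chow", "S129:HFD"]
    sample_rows = []
    for g in groups:
        strain, diet = g.split(":")
        n = cfg.samples_per_group - (1 if g == cfg.short_group else 0)
        for i in range(n):
            sample_rows.append(
                {"sample_id": f"{strain}_{diet}_{i + 1}",
                 "strain": strain, "diet": diet}
            )
    samples = pd.DataFrame(sample_rows)
    n_samples = len(samples)
    # contamination samples spread over groups (2/2/2/1 by default sizes)
    contam_per_group = {}
    remaining = cfg.n_contam_samples
    for g in groups:
        take = min(2, remaining)
        contam_per_group[g] = take
        remaining -= take
    contam_ids = []
    for g, k in contam_per_group.items():
        strain, diet = g.split(":")
        pool = samples.loc[
            (samples["strain"] == strain) & (samples["diet"] == diet),
            "sample_id",
        ].tolist()
        contam_ids.extend(pool[:k])
    contam_mask = samples["sample_id"].isin(contam_ids).to_numpy()

    # ---- peak placement ---------------------------------------------
    per_chrom = int(np.ceil(cfg.n_peaks / cfg.n_chroms))
    slot = cfg.chrom_length // per_chrom
    peak_rows = []
    pid = 0
    for c in chroms:
        for s in range(per_chrom):
            if pid >= cfg.n_peaks:
                break
            w = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
            lo = s * slot
            # trailing buffer keeps a peak's H3K27ac mark out of the
            # activity flank of the next slot's peak
            start = int(rng.integers(lo + 50, lo + slot - w - 2000))
            peak_rows.append(
                {"feature_id": f"peak_{pid:05d}", "chrom": c,
                 "start": start, "end": start + w}
            )
            pid += 1
    peaks = pd.DataFrame(peak_rows)
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    n_peaks = len(peaks)

    # ---- class assignment -------------------------------------------
    # DARs cluster spatially: peaks near a sampled set of domain anchors
    # are preferentially differential, giving DEG neighborhoods a higher
    # DAR density than the genome average
    n_dar_total = cfg.n_common_dar + cfg.n_chow_dar + cfg.n_hfd_dar
    n_anchors = max(4, n_dar_total // 35)
    anchor_idx = rng.choice(n_peaks, size=n_anchors, replace=False)
    anchor_pos = {
        c: np.sort(centers[anchor_idx][peaks["chrom"].to_numpy()[anchor_idx] == c])
        for c in chroms
    }
    weight = np.empty(n_peaks)
    for i in range(n_peaks):
        pos = anchor_pos[peaks.at[i, "chrom"]]
        if len(pos) == 0:
            weight[i] = 0.1
            continue
        dmin = np.abs(pos - centers[i]).min()
        weight[i] = 0.1 + np.exp(-dmin / 150_000)
    order = rng.choice(
        n_peaks, size=n_peaks, replace=False, p=weight / weight.sum()
    )
    dar_class = np.full(n_peaks, "NonDAR", dtype=object)
    i0 = 0
    for cls, n in (("Common", cfg.n_common_dar), ("Chow", cfg.n_chow_dar),
                   ("HFD", cfg.n_hfd_dar)):
        dar_class[order[i0 : i0 + n]] = cls
        i0 += n
    decoy = np.zeros(n_peaks, dtype=bool)
    decoy[order[i0 : i0 + cfg.n_decoy_peaks]] = True
    i0 += cfg.n_decoy_peaks

    # effect sign per DAR: spatially coherent (nearby DARs in the same
    # regulatory domain tend to shift the same way), decaying with the
    # co-accessibility kernel scale; pioneer loci overwritten below
    domain_grid = {
        c: np.arange(cfg.coacc_spacing // 2, cfg.chrom_length,
                     cfg.coacc_spacing)
        for c in chroms
    }
    domain_sign = {
        c: rng.choice([-1.0, 1.0], size=len(v))
        for c, v in domain_grid.items()
    }
    eff_sign = np.empty(n_peaks)
    for i in range(n_peaks):
        c = peaks.at[i, "chrom"]
        grid = domain_grid[c]
        j = int(np.argmin(np.abs(grid - centers[i])))
        dist = abs(int(grid[j]) - int(centers[i]))
        p_same = 0.5 + 0.5 * np.exp(-dist / cfg.coacc_scale)
        if rng.random() < p_same:
            eff_sign[i] = domain_sign[c][j]
        else:
            eff_sign[i] = rng.choice([-1.0, 1.0])

    # activity
    is_dar = np.isin(dar_class, ["Common", "Chow", "HFD"])
    p_active = np.where(is_dar, cfg.active_frac_dar, cfg.active_frac_nondar)
    active = (rng.random(n_peaks) < p_active) & ~decoy

    # center-variant designation per class
    has_center_variant = np.zeros(n_peaks, dtype=bool)
    for cls, frac in cfg.variant_center_frac.items():
        idx = np.where((dar_class == cls) & ~decoy)[0]
        k = int(round(frac * len(idx)))
        chosen = rng.choice(idx, size=k, replace=False)
        has_center_variant[chosen] = True

    # ---- motifs and footprint sites ---------------------------------
    motifs, motif_meta = _build_motifs(rng)
    by_kind: dict[str, list[PWMotif]] = {"core": [], "strong": [], "neutral": []}
    for m in motifs:
        by_kind[motif_meta[m.motif_id]["kind"]].append(m)

    def scaled_score(m: PWMotif, seq_codes: np.ndarray) -> float:
        lo = m.log_odds()
        s = float(lo[np.arange(m.length), seq_codes].sum())
        smin, smax = m.score_range()
        return (s - smin) / (smax - smin)

    cv_pool = {
        cls: list(np.where(has_center_variant & (dar_class == cls))[0])
        for cls in ("Common", "Chow", "HFD", "NonDAR")
    }
    for pool in cv_pool.values():
        rng.shuffle(pool)

    fp_specs = []  # (category, host_idx, motif)
    def take_hosts(cls: str, n: int) -> list[int]:
        got = [cv_pool[cls].pop() for _ in range(min(n, len(cv_pool[cls])))]
        return got

    n_conc_common = int(round(cfg.n_fp_concordant * 0.9))
    hosts = take_hosts("Common", n_conc_common)
    hosts += take_hosts("Chow", cfg.n_fp_concordant - len(hosts))
    for h in hosts:
        fp_specs.append(("concordant", h, by_kind["core"][int(rng.integers(3))]))
    # discordant loci concentrated in two TFs so at least one TF keeps a
    # >= 90% concordant variant set
    for h in take_hosts("NonDAR", cfg.n_fp_discordant):
        fp_specs.append(("discordant", h, by_kind["core"][1 + int(rng.integers(2))]))
    for h in take_hosts("NonDAR", cfg.n_fp_strong):
        fp_specs.append(("strong", h, by_kind["strong"][int(rng.integers(2))]))
    for h in take_hosts("NonDAR", cfg.n_fp_neutral):
        fp_specs.append(("neutral", h, by_kind["neutral"][int(rng.integers(2))]))

    fp_hosts_used = {h for _, h, _ in fp_specs}
    # graded occupancy, no variant; core motif 0 ('pioneer') binds only DARs
    dar_pool = [
        i for i in np.where(is_dar)[0] if i not in fp_hosts_used
    ]
    non_pool = [
        i for i in range(n_peaks)
        if not decoy[i] and i not in fp_hosts_used and i not in dar_pool
    ]
    rng.shuffle(dar_pool)
    rng.shuffle(non_pool)
    n_pioneer = min(cfg.n_fp_graded // 4, len(dar_pool))
    for _ in range(n_pioneer):
        fp_specs.append(("graded", dar_pool.pop(), by_kind["core"][0]))
    for _ in range(cfg.n_fp_graded - n_pioneer):
        if not non_pool:
            break
        fp_specs.append(
            ("graded", non_pool.pop(),
             by_kind["core"][1 + int(rng.integers(2))])
        )

    # realize footprint sites: plant instance sequences, variants, occupancy
    variant_rows = []
    fp_rows = []
    fp_truth = {}
    peak_variants: dict[int, list[str]] = {}
    vid_counter = 0
    k_choices = np.array([0, 1, 2, 4, 5])
    k_probs = np.array([0.35, 0.15, 0.10, 0.15, 0.25])
    for fp_i, (cat, host, m) in enumerate(fp_specs):
        L = m.length
        chrom = peaks.at[host, "chrom"]
        center = int(centers[host])
        cons = m.prob_matrix.argmax(axis=1).astype(np.uint8)
        inst = cons.copy()
        occ_pair = None  # (occ_b6, occ_129)
        var_id = None
        delta_sign = 0
        if cat == "graded":
            k = int(rng.choice(k_choices, p=k_probs))
            if k:
                pos = rng.choice(L, size=min(k, L), replace=False)
                for p in pos:
                    inst[p] = (inst[p] + 1 + rng.integers(3)) % 4
            mstart = center - L // 2
            genome[chrom][mstart : mstart + L] = inst
            s = scaled_score(m, inst)
            occ = float(_logistic(cfg.occ_slope * (s - cfg.occ_x0)))
            occ_pair = (occ, occ)
        else:
            flips = motif_meta[m.motif_id]["flip_positions"]
            j = int(rng.choice(flips))
            voff = int(rng.integers(-10, 11))   # variant near peak center
            vpos = center + voff
            mstart = vpos - j
            if m.motif_id.startswith("neutral"):
                col = m.prob_matrix[j]
                top2 = np.argsort(col)[::-1][:2]
                strong_b, weak_b = int(top2[0]), int(top2[1])
            else:
                strong_b = int(cons[j])
                weak_b = int(np.argmin(m.prob_matrix[j]))
            alt_gets_strong = bool(rng.random() < 0.5)
            ref_base = weak_b if alt_gets_strong else strong_b
            alt_base = strong_b if alt_gets_strong else weak_b
            inst[j] = ref_base
            genome[chrom][mstart : mstart + L] = inst
            ref_inst = inst.copy()
            alt_inst = inst.copy()
            alt_inst[j] = alt_base
            s_ref = scaled_score(m, ref_inst)
            s_alt = scaled_score(m, alt_inst)
            delta_sign = int(np.sign(s_alt - s_ref))
            occ_ref = float(_logistic(cfg.occ_slope * (s_ref - cfg.occ_x0)))
            occ_alt = float(_logistic(cfg.occ_slope * (s_alt - cfg.occ_x0)))
            if cat == "discordant":
                occ_pair = (occ_alt, occ_ref)  # occupancy swapped vs motif
            else:
                occ_pair = (occ_ref, occ_alt)
            var_id = f"var_{vid_counter:05d}"
            vid_counter += 1
            variant_rows.append(
                {"chrom": chrom, "pos": vpos,
                 "ref_allele": BASES[ref_base], "alt_allele": BASES[alt_base],
                 "variant_id": var_id}
            )
            peak_variants.setdefault(host, []).append(var_id)
            # pioneer coupling: peak strain effect follows the motif delta
            if cat == "concordant" and delta_sign != 0:
                eff_sign[host] = float(delta_sign)
        fid = f"fp_{fp_i:04d}"
        fp_rows.append(
            {"footprint_id": fid, "chrom": chrom, "start": int(mstart),
             "end": int(mstart + L), "motif_id": m.motif_id,
             "tf_name": m.tf_name,
             "nfr_id": peaks.at[host, "feature_id"],
             "variant_id": var_id if var_id else ""}
        )
        fp_truth[fid] = {
            "category": cat,
            "host": peaks.at[host, "feature_id"],
            "motif_id": m.motif_id,
            "variant_id": var_id,
            "occ_b6": occ_pair[0],
            "occ_129": occ_pair[1],
            "delta_sign": delta_sign,
            "bound_b6": occ_pair[0] >= 0.5,
            "bound_129": occ_pair[1] >= 0.5,
        }
    footprints = pd.DataFrame(fp_rows)

    # ---- remaining center variants + background SNVs -----------------
    for cls in ("Common", "Chow", "HFD", "NonDAR"):
        for host in cv_pool[cls]:
            c = peaks.at[host, "chrom"]
            vpos = int(
                centers[host]
                + rng.integers(-cfg.center_variant_halfwidth,
                               cfg.center_variant_halfwidth + 1)
            )
            ref_base = int(genome[c][vpos])
            alt_base = (ref_base + 1 + int(rng.integers(3))) % 4
            var_id = f"var_{vid_counter:05d}"
            vid_counter += 1
            variant_rows.append(
                {"chrom": c, "pos": vpos, "ref_allele": BASES[ref_base],
                 "alt_allele": BASES[alt_base], "variant_id": var_id}
            )
            peak_variants.setdefault(host, []).append(var_id)
    n_bg = rng.poisson(cfg.background_snv_per_bp * cfg.chrom_length * cfg.n_chroms)
    for _ in range(n_bg):
        c = chroms[int(rng.integers(cfg.n_chroms))]
        vpos = int(rng.integers(0, cfg.chrom_length))
        ref_base = int(genome[c][vpos])
        alt_base = (ref_base + 1 + int(rng.integers(3))) % 4
        variant_rows.append(
            {"chrom": c, "pos": vpos, "ref_allele": BASES[ref_base],
             "alt_allele": BASES[alt_base],
             "variant_id": f"var_{vid_counter:05d}"}
        )
        vid_counter += 1
    variants = pd.DataFrame(variant_rows).sort_values(
        ["chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- H3K27ac flanking Active peaks -------------------------------
    h3_rows = []
    for i in np.where(active)[0]:
        start = int(peaks.at[i, "end"]) + cfg.h3k27ac_gap
        h3_rows.append(
            {"chrom": peaks.at[i, "chrom"], "start": start,
             "end": start + cfg.h3k27ac_width, "id": f"h3k_{i:05d}"}
        )
    h3k27ac = pd.DataFrame(h3_rows)

    # ---- genes --------------------------------------------------------
    gene_order = rng.permutation(cfg.n_genes)
    deg_class = np.full(cfg.n_genes, "NonDEG", dtype=object)
    g0 = 0
    for cls, n in (("Strain", cfg.n_strain_deg), ("Diet", cfg.n_diet_deg),
                   ("DietStrain", cfg.n_dietstrain_deg)):
        deg_class[gene_order[g0 : g0 + n]] = cls
        g0 += n
    marker_gene = np.zeros(cfg.n_genes, dtype=bool)
    nondeg_idx = gene_order[g0:]
    marker_gene[nondeg_idx[: cfg.n_marker_genes]] = True
    unexpressed = np.zeros(cfg.n_genes, dtype=bool)
    unexpressed[nondeg_idx[cfg.n_marker_genes :
                           cfg.n_marker_genes + cfg.n_unexpressed]] = True

    # positions: linked Strain-DEGs sit at Common-DAR promoters
    # linked genes take the densest-neighborhood Common-DARs first
    common_idx = sorted(
        np.where(dar_class == "Common")[0], key=lambda i: (weight[i], -i)
    )
    gene_chrom = np.empty(cfg.n_genes, dtype=object)
    gene_tss = np.zeros(cfg.n_genes, dtype=int)
    gene_strand = rng.choice(["+", "-"], size=cfg.n_genes)
    linked_peak = np.full(cfg.n_genes, None, dtype=object)
    strain_idx = np.where(deg_class == "Strain")[0]
    n_linked = int(round(cfg.linked_frac * len(strain_idx)))
    for gi in strain_idx[:n_linked]:
        if not common_idx:
            break
        p = common_idx.pop()
        gene_chrom[gi] = peaks.at[p, "chrom"]
        gene_tss[gi] = int(centers[p] + rng.integers(-500, 501))
        linked_peak[gi] = p
    # unlinked strain-dependent DEGs still live near DARs (DAR-dense
    # neighborhoods around strain-specific expression)
    dar_idx_all = np.where(is_dar)[0]
    for gi in range(cfg.n_genes):
        if gene_chrom[gi] is not None:
            continue
        if deg_class[gi] in ("Strain", "DietStrain") and len(dar_idx_all):
            # near a DAR-domain anchor, so the 1 Mb neighborhood is
            # DAR-dense relative to a uniformly placed gene
            a = int(anchor_idx[int(rng.integers(len(anchor_idx)))])
            gene_chrom[gi] = peaks.at[a, "chrom"]
            gene_tss[gi] = int(
                np.clip(centers[a] + rng.integers(-150_000, 150_001),
                        1000, cfg.chrom_length - 1000)
            )
        else:
            gene_chrom[gi] = chroms[int(rng.integers(cfg.n_chroms))]
            gene_tss[gi] = int(rng.integers(1000, cfg.chrom_length - 1000))
    gene_ids = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    tss = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": gene_chrom, "tss_pos": gene_tss,
         "strand": gene_strand, "expressed": ~unexpressed}
    )

    # marker peaks: the contaminating cell type's accessibility program.
    # Peaks near marker-gene TSS are markers (so cluster-differential
    # peaks map to marker genes by nearest TSS), topped up with further
    # NonDAR peaks to the full program size so the contamination axis
    # dominates the sample covariance the way a cell-type admixture does.
    marker_peak = np.zeros(n_peaks, dtype=bool)
    for gi in np.where(marker_gene)[0]:
        m = (
            (peaks["chrom"] == gene_chrom[gi]).to_numpy()
            & (np.abs(centers - gene_tss[gi]) <= cfg.marker_search_bp)
            & (dar_class == "NonDAR") & ~decoy
        )
        cand = np.where(m)[0][:2]
        marker_peak[cand] = True
    fill_pool = np.where(
        (dar_class == "NonDAR") & ~decoy & ~marker_peak & ~has_center_variant
    )[0]
    fill_pool = np.array([i for i in fill_pool if i not in fp_hosts_used])
    n_fill = max(0, cfg.n_marker_peaks - int(marker_peak.sum()))
    if n_fill and len(fill_pool):
        marker_peak[rng.choice(fill_pool, size=min(n_fill, len(fill_pool)),
                               replace=False)] = True

    # ---- ATAC counts --------------------------------------------------
    strain_arr = samples["strain"].to_numpy()
    diet_arr = samples["diet"].to_numpy()
    is_129 = strain_arr == "S129"
    is_hfd = diet_arr == "HFD"
    lib = rng.uniform(cfg.lib_factor_min, cfg.lib_factor_max, size=n_samples)

    E = np.zeros((n_peaks, n_samples))
    # strain effects by class (applied to 129 samples in the relevant diets)
    for cls, diets in (("Common", (False, True)), ("Chow", (False,)),
                       ("HFD", (True,))):
        rows = np.where(dar_class == cls)[0]
        for hf in diets:
            cols = np.where(is_129 & (is_hfd == hf))[0]
            E[np.ix_(rows, cols)] += (
                eff_sign[rows, None] * cfg.strain_lfc
            )
    # contamination shift on marker peaks
    E[np.ix_(np.where(marker_peak)[0], np.where(contam_mask)[0])] += cfg.contam_shift
    # co-accessibility latent factors
    factor_pos = {
        c: np.arange(cfg.coacc_spacing // 2, cfg.chrom_length,
                     cfg.coacc_spacing)
        for c in chroms
    }
    n_factors = sum(len(v) for v in factor_pos.values())
    F = rng.normal(0, cfg.coacc_sd, size=(n_factors, n_samples))
    f_index = {}
    k = 0
    for c in chroms:
        for p in factor_pos[c]:
            f_index[(c, int(p))] = k
            k += 1
    for i in range(n_peaks):
        c = peaks.at[i, "chrom"]
        pos = factor_pos[c]
        j = int(np.argmin(np.abs(pos - centers[i])))
        dist = abs(int(pos[j]) - int(centers[i]))
        w = cfg.coacc_max_load * np.exp(-dist / cfg.coacc_scale)
        E[i, :] += w * F[f_index[(c, int(pos[j]))], :]
    # linked-pair shared noise
    link_noise = {}
    for gi in np.where(linked_peak != None)[0]:  # noqa: E711
        z = rng.normal(0, cfg.linked_noise_sd, size=n_samples)
        link_noise[gi] = z
        E[int(linked_peak[gi]), :] += z

    baseline = rng.gamma(
        cfg.baseline_shape, cfg.baseline_mean / cfg.baseline_shape,
        size=n_peaks,
    )
    baseline[marker_peak] *= cfg.marker_baseline_scale
    baseline[decoy] = cfg.decoy_mean
    log2mu = np.log2(baseline)[:, None] + E + np.log2(lib)[None, :]
    mu = np.power(2.0, log2mu)
    r = 1.0 / cfg.dispersion
    atac = rng.poisson(rng.gamma(r, mu / r)).astype(np.int64)
    atac_counts = pd.DataFrame(
        atac, index=peaks["feature_id"], columns=samples["sample_id"]
    )

    # ---- RNA counts ---------------------------------------------------
    Eg = np.zeros((cfg.n_genes, n_samples))
    gene_sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    s_rows = np.where(np.isin(deg_class, ["Strain", "DietStrain"]))[0]
    Eg[np.ix_(s_rows, np.where(is_129)[0])] += (
        gene_sign[s_rows, None] * cfg.gene_lfc
    )
    d_rows = np.where(np.isin(deg_class, ["Diet", "DietStrain"]))[0]
    Eg[np.ix_(d_rows, np.where(is_hfd)[0])] += (
        gene_sign[d_rows, None] * cfg.diet_lfc
    )
    Eg[np.ix_(np.where(marker_gene)[0], np.where(contam_mask)[0])] += cfg.contam_shift
    for gi, z in link_noise.items():
        # linked genes track their promoter peak's accessibility; sign
        # follows the peak effect so expression and accessibility correlate
        p = int(linked_peak[gi])
        Eg[gi, :] += z
        Eg[gi, is_129] += eff_sign[p] * cfg.gene_lfc - gene_sign[gi] * cfg.gene_lfc
        gene_sign[gi] = eff_sign[p]
    baseline_g = rng.gamma(
        cfg.baseline_shape, cfg.baseline_mean / cfg.baseline_shape,
        size=cfg.n_genes,
    )
    baseline_g[marker_gene] *= cfg.marker_baseline_scale
    baseline_g[unexpressed] = 0.5
    log2mug = np.log2(baseline_g)[:, None] + Eg + np.log2(lib)[None, :]
    mug = np.power(2.0, log2mug)
    rna = rng.poisson(rng.gamma(r, mug / r)).astype(np.int64)
    rna_counts = pd.DataFrame(
        rna, index=pd.Index(gene_ids, name="feature_id"),
        columns=samples["sample_id"],
    )

    # ---- cut-site profiles -------------------------------------------
    W = cfg.profile_flank
    offs = np.arange(-W, W + 1)
    center_mask = np.abs(offs) <= 10
    depth = {
        g: float(rng.uniform(cfg.group_depth_min, cfg.group_depth_max))
        for g in groups
    }
    prof_rows = []
    for fid in footprints["footprint_id"]:
        t = fp_truth[fid]
        for g in groups:
            strain = g.split(":")[0]
            occ = t["occ_129"] if strain == "S129" else t["occ_b6"]
            lam = cfg.cut_base_rate * depth[g] * np.where(
                center_mask, 1.0 - cfg.cut_depth_frac * occ, 1.0
            )
            counts = rng.poisson(lam)
            prof_rows.append(
                pd.DataFrame(
                    {"footprint_id": fid, "offset": offs, "count": counts,
                     "group": g}
                )
            )
    cut_profiles = pd.concat(prof_rows, ignore_index=True)

    # ---- truth ---------------------------------------------------------
    truth = {
        "peaks": {
            peaks.at[i, "feature_id"]: {
                "dar_class": str(dar_class[i]),
                "activity": "Active" if active[i] else "NonActive",
                "has_center_variant": bool(has_center_variant[i]),
                "variant_ids": peak_variants.get(i, []),
                "marker": bool(marker_peak[i]),
                "decoy": bool(decoy[i]),
                "effect_sign": float(eff_sign[i]) if is_dar[i] else 0.0,
            }
            for i in range(n_peaks)
        },
        "genes": {
            gene_ids[i]: {
                "deg_class": str(deg_class[i]),
                "marker": bool(marker_gene[i]),
                "expressed": bool(~unexpressed[i]),
                "linked_peak": (
                    peaks.at[int(linked_peak[i]), "feature_id"]
                    if linked_peak[i] is not None else None
                ),
            }
            for i in range(cfg.n_genes)
        },
        "footprints": fp_truth,
        "contamination_samples": sorted(contam_ids),
        "groups": groups,
    }

    return SimData(
        config=cfg,
        chrom_sizes=chrom_sizes,
        genome=genome,
        peaks=peaks,
        h3k27ac=h3k27ac,
        variants=variants,
        atac_counts=atac_counts,
        rna_counts=rna_counts,
        samples=samples,
        tss=tss,
        motifs=motifs,
        footprints=footprints,
        cut_profiles=cut_profiles,
        depth_factors=depth,
        offset_map=OffsetMap.identity(chrom_sizes),
        truth=truth,
    )


def truth_report(truth: dict, outputs: dict) -> dict:
    """Recovery metrics of pipeline outputs against planted truth.

    ``outputs`` may contain 'dar_classes' (feature_id, dar_class),
    'deg_classes', 'activity' (feature_id, activity), 'bound'
    (footprint_id, bound_any), 'ac_flags' (footprint_id, ac_flag).
    Sensitivity = recovered / planted; fdr = false / called, per class.
    """
    report: dict = {}
    if "dar_classes" in outputs:
        pred = outputs["dar_classes"].set_index("feature_id")["dar_class"]
        rows = {}
        for cls in ("Common", "Chow", "HFD", "NonDAR"):
            planted = [
                f for f, t in truth["peaks"].items()
                if t["dar_class"] == cls and f in pred.index
            ]
            called = pred.index[(pred == cls)]
            tp = sum(pred.get(f) == cls for f in planted)
            rows[cls] = {
                "n_planted": len(planted),
                "n_called": int(len(called)),
                "sensitivity": tp / len(planted) if planted else float("nan"),
                "fdr": (
                    1 - sum(
                        truth["peaks"].get(f, {}).get("dar_class") == cls
                        for f in called
                    ) / len(called)
                    if len(called) else float("nan")
                ),
            }
        report["dar"] = rows
    if "deg_classes" in outputs:
        pred = outputs["deg_classes"].set_index("feature_id")["deg_class"]
        rows = {}
        for cls in ("Strain", "Diet", "DietStrain", "NonDEG"):
            planted = [
                g for g, t in truth["genes"].items()
                if t["deg_class"] == cls and g in pred.index
            ]
            called = pred.index[pred == cls]
            tp = sum(pred.get(g) == cls for g in planted)
            rows[cls] = {
                "n_planted": len(planted),
                "n_called": int(len(called)),
                "sensitivity": tp / len(planted) if planted else float("nan"),
            }
        report["deg"] = rows
    if "activity" in outputs:
        pred = outputs["activity"].set_index("feature_id")["activity"]
        agree = [
            pred.get(f) == t["activity"]
            for f, t in truth["peaks"].items() if f in pred.index
        ]
        report["activity_accuracy"] = float(np.mean(agree))
    if "bound" in outputs:
        pred = outputs["bound"].set_index("footprint_id")["bound_any"]
        t_bound = {
            f: (t["bound_b6"] or t["bound_129"])
            for f, t in truth["footprints"].items() if f in pred.index
        }
        inter = sum(1 for f, b in t_bound.items() if b and pred.get(f))
        union = sum(1 for f, b in t_bound.items() if b or pred.get(f))
        report["bound_jaccard"] = inter / union if union else float("nan")
    if "ac_flags" in outputs:
        pred = outputs["ac_flags"].set_index("footprint_id")["ac_flag"]
        for cat in ("concordant", "discordant"):
            ids = [
                f for f, t in truth["footprints"].items()
                if t["category"] == cat and f in pred.index
            ]
            if ids:
                report[f"ac_rate_{cat}"] = float(
                    np.mean([bool(pred.get(f)) for f in ids])
                )
    return report
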