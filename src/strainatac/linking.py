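"""Peak-peak co-accessibility and peak-gene correlation linking.

DAR pairs within a distance cap are correlated across all samples on the
batch-corrected logCPM layer; rolling mean-correlation curves resolve the
distance dependence. DAR-DEG linking correlates gene expression with the
accessibility of every DAR whose center lies in cumulative windows around
the gene's most-active TSS, and summarizes per DEG class as the fraction
of genes with at least one significantly positively correlating DAR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import ContingencyTable, bh_fdr, fisher_exact, spearman_matrix, wilcoxon_rank_sum

__all__ = [
    "DEFAULT_WINDOWS",
    "link_dar_pairs",
    "rolling_correlation_curve",
    "link_dars_to_degs",
    "cumulative_dar_counts",
    "nearest_feature_stats",
]

#: cumulative TSS windows (bp); 'promoter' is +-2 kb
DEFAULT_WINDOWS: dict[str, int] = {
    "promoter": 2_000,
    "10k": 10_000,
    "50k": 50_000,
    "100k": 100_000,
    "500k": 500_000,
    "1M": 1_000_000,
}


def link_dar_pairs(
    dars: pd.DataFrame,
    counts: pd.DataFrame,
    max_distance: int = 1_000_000,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """All same-chromosome DAR pairs within the distance cap, correlated.

    ``dars`` needs feature_id/chrom/start/end plus n_variants (for the
    variant_combo stratification); ``counts`` is the batch-corrected
    logCPM layer indexed by feature_id. Distance is center-to-center,
    inclusive cap. Spearman across all samples; significant_positive iff
    p < ``p_max`` and rho > 0. Pair ids are canonically ordered
    id_a < id_b.
    """
    if counts.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    d = dars.copy()
    d["center"] = (d["start"] + d["end"]) // 2
    has_var = (
        d.set_index("feature_id")["n_variants"] >= 1
        if "n_variants" in d.columns
        else pd.Series(False, index=d["feature_id"])
    )
    rows_a, rows_b, dist = [], [], []
    for chrom, grp in d.groupby("chrom", sort=True):
        grp = grp.sort_values(["center", "feature_id"], kind="mergesort")
        ids = grp["feature_id"].to_numpy()
        c = grp["center"].to_numpy()
        hi_all = np.searchsorted(c, c + max_distance, "right")
        for i in range(len(c)):
            for j in range(i + 1, hi_all[i]):
                a, b = sorted((ids[i], ids[j]))
                rows_a.append(a)
                rows_b.append(b)
                dist.append(int(abs(c[j] - c[i])))
    if not rows_a:
        return pd.DataFrame(
            columns=["id_a", "id_b", "distance", "rho", "p",
                     "significant_positive", "variant_combo"]
        )
    X = counts.loc[rows_a].to_numpy(dtype=float)
    Y = counts.loc[rows_b].to_numpy(dtype=float)
    rho, p = spearman_matrix(X, Y)
    va = has_var.loc[rows_a].to_numpy()
    vb = has_var.loc[rows_b].to_numpy()
    combo = np.where(va & vb, "both", np.where(va | vb, "one", "neither"))
    out = pd.DataFrame(
        {
            "id_a": rows_a,
            "id_b": rows_b,
            "distance": dist,
            "rho": rho,
            "p": p,
            "significant_positive": (p < p_max) & (rho > 0),
            "variant_combo": combo,
        }
    )
    return out.sort_values(
        ["distance", "id_a", "id_b"], kind="mergesort"
    ).reset_index(drop=True)


def rolling_correlation_curve(
    pairs: pd.DataFrame,
    window: int = 501,
    step: int = 100,
    by_combo: bool = True,
) -> pd.DataFrame:
    """Rolling mean correlation against distance for significant pairs.

    Pairs (already restricted to the significant set by the caller, per
    convention the p < 0.05 pairs) are sorted by distance; each curve
    point is the mean rho over ``window`` consecutive pairs at the
    window-center distance, advancing by ``step`` pairs. Curves are
    computed per variant_combo when available.
    """
    if window % 2 == 0:
        raise ValueError("window size must be odd")
    groups = (
        pairs.groupby("variant_combo", sort=True)
        if by_combo and "variant_combo" in pairs.columns
        else [("all", pairs)]
    )
    frames = []
    for combo, grp in groups:
        grp = grp.sort_values(["distance", "id_a", "id_b"], kind="mergesort")
        rho = grp["rho"].to_numpy()
        distv = grp["distance"].to_numpy()
        if len(grp) < window:
            warnings.warn(
                f"variant_combo {combo!r}: {len(grp)} pairs < window {window}"
            )
            continue
        xs, ys = [], []
        for i in range(0, len(grp) - window + 1, step):
            xs.append(float(distv[i + window // 2]))
            ys.append(float(rho[i : i + window].mean()))
        frames.append(
            pd.DataFrame(
                {"distance": xs, "mean_rho": ys, "variant_combo": combo,
                 "window": window, "step": step}
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["distance", "mean_rho", "variant_combo", "window", "step"]
        )
    return pd.concat(frames, ignore_index=True)


def _gene_dar_correlations(
    genes: pd.DataFrame,
    dars: pd.DataFrame,
    gene_counts: pd.DataFrame,
    peak_counts: pd.DataFrame,
    max_distance: int,
) -> pd.DataFrame:
    """All (gene, DAR) pairs with |center - tss| <= max_distance, correlated."""
    d = dars.copy()
    d["center"] = (d["start"] + d["end"]) // 2
    g_ids, p_ids, dist = [], [], []
    for chrom, dg in d.groupby("chrom", sort=True):
        dg = dg.sort_values(["center", "feature_id"], kind="mergesort")
        centers = dg["center"].to_numpy()
        pids = dg["feature_id"].to_numpy()
        gg = genes[genes["chrom"] == chrom]
        for tss, gid in zip(gg["tss_pos"].to_numpy(), gg["gene_id"].to_numpy()):
            lo = np.searchsorted(centers, tss - max_distance, "left")
            hi = np.searchsorted(centers, tss + max_distance, "right")
            for k in range(lo, hi):
                g_ids.append(gid)
                p_ids.append(pids[k])
                dist.append(int(abs(centers[k] - tss)))
    if not g_ids:
        return pd.DataFrame(columns=["gene_id", "peak_id", "distance", "rho", "p"])
    common = [c for c in gene_counts.columns if c in peak_counts.columns]
    X = gene_counts.loc[g_ids, common].to_numpy(dtype=float)
    Y = peak_counts.loc[p_ids, common].to_numpy(dtype=float)
    rho, p = spearman_matrix(X, Y)
    return pd.DataFrame(
        {"gene_id": g_ids, "peak_id": p_ids, "distance": dist,
         "rho": rho, "p": p}
    )


def link_dars_to_degs(
    deg_classes: pd.DataFrame,
    tss_table: pd.DataFrame,
    dars: pd.DataFrame,
    gene_counts: pd.DataFrame,
    peak_counts: pd.DataFrame,
    windows: dict[str, int] = DEFAULT_WINDOWS,
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of genes with a correlating DAR, per class and window.

    For each expressed gene with a selected TSS, every DAR whose center
    lies within the cumulative window around the TSS is correlated
    (Spearman, batch-corrected logCPM of gene expression vs peak
    accessibility across shared samples). A DAR qualifies when p < p_max
    and rho > 0. Per DEG class and window: the fraction of genes with
    >= 1 qualifying DAR, plus a Fisher test of that indicator against the
    NonDEG class. Returns (summary frame, per-pair link table).
    """
    genes = tss_table[tss_table.get("expressed", True)].merge(
        deg_classes[["feature_id", "deg_class"]],
        left_on="gene_id", right_on="feature_id", how="inner",
    )
    dropped = len(deg_classes) - len(genes)
    if dropped > 0:
        warnings.warn(f"{dropped} genes without expressed TSS excluded")
    max_w = max(windows.values())
    links = _gene_dar_correlations(
        genes, dars, gene_counts, peak_counts, max_w
    )
    links["qualifying"] = (links["p"] < p_max) & (links["rho"] > 0)
    cls_of = genes.set_index("gene_id")["deg_class"]
    rows = []
    qual = links[links["qualifying"]]
    # per window: genes with >= 1 qualifying DAR within the window
    per_gene_min = qual.groupby("gene_id")["distance"].min()
    for wname, wsize in sorted(windows.items(), key=lambda kv: kv[1]):
        has = genes["gene_id"].map(
            lambda g: per_gene_min.get(g, np.inf) <= wsize
        )
        non_mask = cls_of.loc[genes["gene_id"]].to_numpy() == "NonDEG"
        non_has = has.to_numpy()[non_mask]
        for cls in ("NonDEG", "Diet", "DietStrain", "Strain"):
            m = cls_of.loc[genes["gene_id"]].to_numpy() == cls
            if not m.any():
                continue
            h = has.to_numpy()[m]
            t = ContingencyTable(
                a=int(h.sum()), b=int((~h).sum()),
                c=int(non_has.sum()), d=int((~non_has).sum()),
            )
            r = fisher_exact(t)
            rows.append(
                {"deg_class": cls, "window": wname, "window_bp": wsize,
                 "fraction": float(h.mean()), "n_genes": int(m.sum()),
                 "odds_ratio": r.odds_ratio, "p_vs_nondeg": r.p_value}
            )
    return pd.DataFrame(rows), links


def cumulative_dar_counts(
    deg_classes: pd.DataFrame,
    tss_table: pd.DataFrame,
    dars: pd.DataFrame,
    window: int = 1_000_000,
    strata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene DAR counts in the TSS window, compared across DEG classes.

    Counts DARs whose center lies within ``window`` of the gene's TSS,
    optionally stratified by the DAR's activity class and variant overlap
    (``strata`` maps feature_id -> activity, has_variant). Each DEG class
    is compared to NonDEG with a Wilcoxon rank-sum and effect size r.
    Returns (per-gene counts, per-class test table).
    """
    genes = tss_table[tss_table.get("expressed", True)].merge(
        deg_classes[["feature_id", "deg_class"]],
        left_on="gene_id", right_on="feature_id", how="inner",
    )
    d = dars.copy()
    d["center"] = (d["start"] + d["end"]) // 2
    if strata is not None:
        d = d.merge(strata, on="feature_id", how="left")
    per_gene = []
    for chrom, dg in d.groupby("chrom", sort=True):
        dg = dg.sort_values("center", kind="mergesort")
        centers = dg["center"].to_numpy()
        gg = genes[genes["chrom"] == chrom]
        for tss, gid, cls in zip(
            gg["tss_pos"].to_numpy(), gg["gene_id"].to_numpy(),
            gg["deg_class"].to_numpy(),
        ):
            lo = np.searchsorted(centers, tss - window, "left")
            hi = np.searchsorted(centers, tss + window, "right")
            rec = {"gene_id": gid, "deg_class": cls, "n_dars": hi - lo}
            if strata is not None and hi > lo:
                sub = dg.iloc[lo:hi]
                for act in ("Active", "NonActive"):
                    for hv, tag in ((True, "var"), (False, "novar")):
                        rec[f"n_{act}_{tag}"] = int(
                            ((sub["activity"] == act)
                             & (sub["has_variant"] == hv)).sum()
                        )
            per_gene.append(rec)
    counts = pd.DataFrame(per_gene)
    # genes on chromosomes without DARs still count zero
    missing = set(genes["gene_id"]) - set(counts.get("gene_id", []))
    if missing:
        extra = genes[genes["gene_id"].isin(missing)][["gene_id", "deg_class"]]
        extra = extra.assign(n_dars=0)
        counts = pd.concat([counts, extra], ignore_index=True).fillna(0)
    tests = []
    non = counts.loc[counts["deg_class"] == "NonDEG", "n_dars"].to_numpy()
    for cls in ("Diet", "DietStrain", "Strain"):
        x = counts.loc[counts["deg_class"] == cls, "n_dars"].to_numpy()
        if len(x) == 0 or len(non) == 0:
            continue
        u, p, r = wilcoxon_rank_sum(x, non)
        tests.append(
            {"deg_class": cls, "U": u, "p": p, "effect_r": r,
             "median": float(np.median(x)),
             "median_nondeg": float(np.median(non))}
        )
    return counts, pd.DataFrame(tests)


def nearest_feature_stats(
    deg_classes: pd.DataFrame,
    results: pd.DataFrame,
    tss_table: pd.DataFrame,
    dars: pd.DataFrame,
    bins: dict[str, int] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """|log2fc| of genes stratified by nearest-DAR distance bin.

    Each expressed gene gets the distance to the nearest DAR center; genes
    are binned by the smallest cumulative window containing that distance
    and each bin's |log2fc| (from ``results``, the gene-level differential
    table with a representative log2fc per gene) is compared to the
    outermost bin by Wilcoxon. Genes on chromosomes without DARs are
    excluded.
    """
    genes = tss_table[tss_table.get("expressed", True)].merge(
        deg_classes[["feature_id", "deg_class"]],
        left_on="gene_id", right_on="feature_id", how="inner",
    )
    lfc = results.set_index("feature_id")["log2fc"].abs()
    d = dars.copy()
    d["center"] = (d["start"] + d["end"]) // 2
    rows = []
    for chrom, dg in d.groupby("chrom", sort=True):
        centers = np.sort(dg["center"].to_numpy())
        gg = genes[genes["chrom"] == chrom]
        for tss, gid in zip(gg["tss_pos"].to_numpy(), gg["gene_id"].to_numpy()):
            i = np.searchsorted(centers, tss)
            cand = [j for j in (i - 1, i) if 0 <= j < len(centers)]
            if not cand:
                continue
            dist = min(abs(int(tss) - int(centers[j])) for j in cand)
            rows.append({"gene_id": gid, "nearest_dar_distance": dist})
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    ordered = sorted(bins.items(), key=lambda kv: kv[1])

    def to_bin(dist: int) -> str:
        for name, size in ordered:
            if dist <= size:
                return name
        return "beyond"

    df["bin"] = df["nearest_dar_distance"].map(to_bin)
    df["abs_log2fc"] = df["gene_id"].map(lfc)
    df = df.dropna(subset=["abs_log2fc"])
    outer_name = ordered[-1][0]
    ref = df.loc[df["bin"] == outer_name, "abs_log2fc"].to_numpy()
    out = []
    for name, _ in ordered:
        x = df.loc[df["bin"] == name, "abs_log2fc"].to_numpy()
        if len(x) == 0:
            continue
        rec = {"bin": name, "n": len(x), "median_abs_log2fc": float(np.median(x))}
        if name != outer_name and len(ref) > 0 and len(x) > 0:
            _, p, r = wilcoxon_rank_sum(x, ref)
            rec["p_vs_outer"] = p
            rec["effect_r"] = r
        out.append(rec)
    return pd.DataFrame(out)
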