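"""TF footprint scoring and strain concordance.

A footprint site is a motif-anchored interval inside an NFR. Its score on
a cut-site profile is the flank-minus-center mean of depth-normalized Tn5
cut counts: occupied sites deplete cuts at the center, so deeper
footprints score higher. Per-group scores feed a 2-means bound/unbound
call, strain score differences take the diet-matched pair with maximal
absolute difference, and AC-footprints are sites where a significantly
altered motif's allelic score and the strain footprint-score difference
agree in sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .stats import (
    ContingencyTable,
    EnrichmentResult,
    bh_fdr,
    fisher_exact,
    spearman,
    wilcoxon_rank_sum,
)

__all__ = [
    "GROUPS",
    "footprint_score",
    "call_bound",
    "strain_score_difference",
    "detect_ac_footprints",
    "ac_enrichment_by_class",
    "tf_level_stats",
]

#: the four strain x diet groups
GROUPS = ["B6:chow", "B6:HFD", "S129:chow", "S129:HFD"]


def footprint_score(
    counts: np.ndarray,
    depth_factor: float = 1.0,
    center_halfwidth: int = 10,
    flank_extent: int = 30,
) -> tuple[float, bool]:
    """Flank-minus-center score of one cut-site profile.

    ``counts`` covers offsets -W..+W (length 2W+1, W = flank_extent).
    After dividing by ``depth_factor``, the score is the mean over flank
    offsets ([-W, -w-1] u [w+1, W]) minus the mean over center offsets
    ([-w, w]). Returns (score, low_coverage_flag).
    """
    w, W = center_halfwidth, flank_extent
    if not (W > w >= 1):
        raise ValueError("need flank_extent > center_halfwidth >= 1")
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] != 2 * W + 1:
        raise ValueError(f"profile must have length {2 * W + 1}")
    if counts.sum() == 0:
        return 0.0, True
    x = counts / depth_factor
    offs = np.arange(-W, W + 1)
    center = np.abs(offs) <= w
    score = float(x[~center].mean() - x[center].mean())
    return score, False


def score_profiles(
    profiles: pd.DataFrame,
    depth_factors: dict[str, float] | None = None,
    center_halfwidth: int = 10,
    flank_extent: int = 30,
) -> pd.DataFrame:
    """Score a long-format cut-profile table.

    ``profiles`` has columns footprint_id, offset, count, group (or
    sample_id). Returns one row per (footprint_id, group) with columns
    score, low_coverage.
    """
    key = "group" if "group" in profiles.columns else "sample_id"
    W = flank_extent
    rows = []
    for (fid, grp), sub in profiles.groupby(["footprint_id", key], sort=True):
        vec = np.zeros(2 * W + 1)
        offs = sub["offset"].to_numpy()
        ok = np.abs(offs) <= W
        vec[offs[ok] + W] = sub["count"].to_numpy()[ok]
        depth = depth_factors.get(grp, 1.0) if depth_factors else 1.0
        s, low = footprint_score(vec, depth, center_halfwidth, flank_extent)
        rows.append(
            {"footprint_id": fid, key: grp, "score": s, "low_coverage": low}
        )
    return pd.DataFrame(rows)


def call_bound(scores: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-means bound/unbound call per group.

    ``scores`` has columns footprint_id, group, score; for each group with
    >= 20 sites the score distribution is split by seeded 2-means and the
    upper cluster is called bound. Degenerate distributions yield all
    unbound. Adds columns bound (bool) and threshold (group split point).
    """
    out = scores.copy()
    out["bound"] = False
    out["threshold"] = np.nan
    for grp, sub in scores.groupby("group", sort=True):
        if len(sub) < 20:
            raise ValueError(f"group {grp}: need >= 20 sites to call bound")
        x = sub["score"].to_numpy()
        if np.allclose(x, x[0]):
            warnings.warn(f"group {grp}: degenerate scores, all unbound")
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(
            x.reshape(-1, 1)
        )
        hi = int(np.argmax(km.cluster_centers_.ravel()))
        bound = km.labels_ == hi
        thr = (x[bound].min() + x[~bound].max()) / 2
        out.loc[sub.index, "bound"] = bound
        out.loc[sub.index, "threshold"] = thr
    return out


def strain_score_difference(group_scores: dict[str, float]) -> float:
    """Signed 129-minus-B6 score difference, diet-matched, max |.|.

    Over diets where both strains have a score, the difference whose
    absolute value is largest is returned (sign preserved). NaN when a
    strain is missing entirely.
    """
    diffs = []
    for diet in ("chow", "HFD"):
        a = group_scores.get(f"S129:{diet}")
        b = group_scores.get(f"B6:{diet}")
        if a is not None and b is not None:
            diffs.append(a - b)
    if not diffs:
        return float("nan")
    return max(diffs, key=abs)


def detect_ac_footprints(
    sites: pd.DataFrame, allelic_effects: pd.DataFrame
) -> pd.Series:
    """Flag AC-footprints: concordant motif and footprint changes.

    A site with an overlapping variant is an AC-footprint when the
    (variant, motif) allelic effect is significant and sign(scaled_delta)
    equals sign(score_diff), both nonzero. Sites whose variant/motif pair
    is missing from the effects table raise.
    """
    eff = allelic_effects.set_index(["variant_id", "motif_id"])
    flags = np.zeros(len(sites), dtype=bool)
    for i, row in enumerate(sites.itertuples()):
        vid = getattr(row, "overlapping_variant", None)
        if vid is None or (isinstance(vid, float) and np.isnan(vid)):
            continue
        key = (vid, row.motif_id)
        if key not in eff.index:
            raise KeyError(
                f"site {row.footprint_id}: no allelic effect for {key}"
            )
        e = eff.loc[key]
        sd = float(row.score_diff)
        delta = float(e["scaled_delta"])
        flags[i] = (
            bool(e["significant"])
            and sd != 0
            and delta != 0
            and np.sign(delta) == np.sign(sd)
        )
    return pd.Series(flags, index=sites.index, name="ac_flag")


def ac_enrichment_by_class(sites: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """AC-footprint enrichment, correlation and strength stratification.

    ``sites`` needs columns dar_class, ac_flag, score_diff, scaled_delta,
    strength. Produces per DAR class (vs NonDAR, non-AC background) the
    Fisher 2x2 of AC x class; the per-class Spearman of score_diff against
    scaled_delta; and Wilcoxon comparisons of |score_diff| between motif
    strength classes.
    """
    non = sites[sites["dar_class"] == "NonDAR"]
    enr_rows = []
    for cls in ("Common", "Chow", "HFD"):
        sub = sites[sites["dar_class"] == cls]
        if len(sub) == 0:
            continue
        t = ContingencyTable(
            a=int(sub["ac_flag"].sum()),
            b=int((~sub["ac_flag"]).sum()),
            c=int(non["ac_flag"].sum()),
            d=int((~non["ac_flag"]).sum()),
        )
        r = fisher_exact(t)
        enr_rows.append(
            {"dar_class": cls, "odds_ratio": r.odds_ratio, "p": r.p_value,
             "ci_low": r.ci_low, "ci_high": r.ci_high,
             "n_ac": t.a, "n_non_ac": t.b}
        )
    enrichment = pd.DataFrame(enr_rows)
    if len(enrichment):
        enrichment["q"] = bh_fdr(enrichment["p"].to_numpy())

    corr_rows = []
    for cls, sub in sites.groupby("dar_class", sort=True):
        sub = sub.dropna(subset=["score_diff", "scaled_delta"])
        if len(sub) < 3:
            continue
        c = spearman(sub["score_diff"].to_numpy(), sub["scaled_delta"].to_numpy())
        corr_rows.append(
            {"dar_class": cls, "rho": c.rho, "p": c.p_value, "n": c.n}
        )
    correlation = pd.DataFrame(corr_rows)

    strength_rows = []
    by_strength = {
        s: sub["score_diff"].abs().to_numpy()
        for s, sub in sites.groupby("strength", sort=True)
    }
    for a, b in (("strong", "neutral"), ("strong", "weak"), ("weak", "neutral")):
        if a in by_strength and b in by_strength and len(by_strength[a]) and len(by_strength[b]):
            u, p, r = wilcoxon_rank_sum(by_strength[a], by_strength[b])
            strength_rows.append(
                {"stronger": a, "weaker": b, "U": u, "p": p, "effect_r": r,
                 "median_diff": float(np.median(by_strength[a]) - np.median(by_strength[b]))}
            )
    strength = pd.DataFrame(strength_rows)
    return {"enrichment": enrichment, "correlation": correlation,
            "strength": strength}


def tf_level_stats(
    sites: pd.DataFrame,
    nfr_classes: pd.DataFrame,
    min_sites: int = 5,
    ac_fraction_rule: float = 0.9,
) -> pd.DataFrame:
    """Per-TF occupancy and AC statistics.

    ``sites`` has tf_name, nfr_id, bound_any (bound in >= 1 group),
    ac_flag, overlapping_variant; ``nfr_classes`` maps nfr_id ->
    dar_class. Occupancy enrichment restricts to NFRs hosting at least one
    footprint site: per TF, Fisher of (NFR hosts a bound footprint of this
    TF) x (DAR vs NonDAR). Also per-TF AC 2x2 vs other TFs and the
    fraction of the TF's motif-altering variants with AC-footprints, with
    the >= ``ac_fraction_rule`` reporting flag. TFs under ``min_sites``
    sites carry low_count=True and are excluded from headline lists.
    """
    cls_map = nfr_classes.set_index("feature_id")["dar_class"]
    sites = sites.copy()
    sites["dar_class"] = sites["nfr_id"].map(cls_map)
    sites["is_dar"] = sites["dar_class"].isin(["Common", "Chow", "HFD"])
    host_nfrs = sites["nfr_id"].unique()
    host_is_dar = cls_map.loc[host_nfrs].isin(["Common", "Chow", "HFD"])
    n_dar_hosts = int(host_is_dar.sum())
    n_non_hosts = int((~host_is_dar).sum())
    rows = []
    for tf, sub in sites.groupby("tf_name", sort=True):
        bound = sub[sub["bound_any"]]
        tf_dar_hosts = bound.loc[bound["is_dar"], "nfr_id"].nunique()
        tf_non_hosts = bound.loc[~bound["is_dar"], "nfr_id"].nunique()
        occ = fisher_exact(
            ContingencyTable(
                a=tf_dar_hosts,
                b=max(n_dar_hosts - tf_dar_hosts, 0),
                c=tf_non_hosts,
                d=max(n_non_hosts - tf_non_hosts, 0),
            )
        )
        others = sites[sites["tf_name"] != tf]
        ac = fisher_exact(
            ContingencyTable(
                a=int(sub["ac_flag"].sum()),
                b=int((~sub["ac_flag"]).sum()),
                c=int(others["ac_flag"].sum()),
                d=int((~others["ac_flag"]).sum()),
            )
        )
        with_var = sub[sub["overlapping_variant"].notna()]
        frac = (
            float(with_var["ac_flag"].mean()) if len(with_var) else float("nan")
        )
        rows.append(
            {
                "tf_name": tf,
                "n_sites": len(sub),
                "occupancy_dar_fraction": (
                    tf_dar_hosts / n_dar_hosts if n_dar_hosts else np.nan
                ),
                "occupancy_nondar_fraction": (
                    tf_non_hosts / n_non_hosts if n_non_hosts else np.nan
                ),
                "occupancy_or": occ.odds_ratio,
                "occupancy_p": occ.p_value,
                "ac_or": ac.odds_ratio,
                "ac_p": ac.p_value,
                "ac_variant_fraction": frac,
                "passes_ac_rule": bool(frac >= ac_fraction_rule)
                if not np.isnan(frac)
                else False,
                "low_count": len(sub) < min_sites,
            }
        )
    return pd.DataFrame(rows)
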