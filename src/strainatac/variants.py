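"""Variant-peak overlap statistics.

FDR-ordered variant-fraction windows, pairwise class-wise variant
enrichment, center-vs-flank zone enrichment against a width-matched
random-region background, and kernel-density positional profiles of
variants around feature centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyTable, EnrichmentResult, bh_fdr, fisher_exact

__all__ = [
    "count_variants_in_peaks",
    "variant_fraction_by_fdr_window",
    "class_variant_enrichment",
    "zone_enrichment",
    "variant_density_profile",
]


def count_variants_in_peaks(
    peaks: pd.DataFrame, variants: pd.DataFrame
) -> pd.Series:
    """Number of variants with position in [start, end) per peak."""
    counts = np.zeros(len(peaks), dtype=int)
    for chrom, vg in variants.groupby("chrom", sort=False):
        pos = np.sort(vg["pos"].to_numpy())
        m = (peaks["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        lo = np.searchsorted(pos, peaks.loc[m, "start"].to_numpy(), "left")
        hi = np.searchsorted(pos, peaks.loc[m, "end"].to_numpy(), "left")
        counts[m] = hi - lo
    return pd.Series(counts, index=peaks.index, name="n_variants")


def variant_offsets(
    features: pd.DataFrame, variants: pd.DataFrame, halfwidth: int
) -> np.ndarray:
    """Signed offsets of variants from feature centers, within +-halfwidth.

    A variant near two features contributes one offset per feature.
    """
    offs = []
    centers_all = ((features["start"] + features["end"]) // 2).to_numpy()
    for chrom, vg in variants.groupby("chrom", sort=False):
        pos = np.sort(vg["pos"].to_numpy())
        m = (features["chrom"] == chrom).to_numpy()
        for c in centers_all[m]:
            lo = np.searchsorted(pos, c - halfwidth, "left")
            hi = np.searchsorted(pos, c + halfwidth, "right")
            offs.append(pos[lo:hi] - c)
    if not offs:
        return np.empty(0, dtype=int)
    return np.concatenate(offs)


def variant_fraction_by_fdr_window(
    peaks: pd.DataFrame, window: int = 100
) -> pd.DataFrame:
    """Fraction of peaks containing >= 1 variant, in FDR-ordered windows.

    Peaks are sorted ascending by ``representative_fdr`` (the more
    significant of the underlying strain comparisons) and cut into
    consecutive windows of ``window`` peaks (last may be smaller).
    """
    s = peaks.sort_values(
        ["representative_fdr", "feature_id"], kind="mergesort"
    )
    has = (s["n_variants"] >= 1).to_numpy()
    fdr = s["representative_fdr"].to_numpy()
    rows = []
    for i in range(0, len(s), window):
        chunk = has[i : i + window]
        rows.append(
            {
                "window_index": i // window,
                "n_peaks": len(chunk),
                "fraction_with_variant": float(chunk.mean()),
                "median_fdr": float(np.median(fdr[i : i + window])),
            }
        )
    return pd.DataFrame(rows)


def class_variant_enrichment(classes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fisher enrichment of with-variant peaks between classes.

    ``classes`` needs dar_class and n_variants. For every ordered class
    pair (A, B): 2x2 of membership x has-variant, OR > 1 meaning A is more
    variant-associated than B. BH across pairs.
    """
    rows = []
    names = [c for c in ("Common", "Chow", "HFD", "NonDAR")
             if (classes["dar_class"] == c).any()]
    empty = set(("Common", "Chow", "HFD", "NonDAR")) - set(names)
    if empty:
        warnings.warn(f"empty DAR classes skipped: {sorted(empty)}")
    for a in names:
        for b in names:
            if a == b:
                continue
            A = classes[classes["dar_class"] == a]
            B = classes[classes["dar_class"] == b]
            t = ContingencyTable(
                a=int((A["n_variants"] >= 1).sum()),
                b=int((A["n_variants"] == 0).sum()),
                c=int((B["n_variants"] >= 1).sum()),
                d=int((B["n_variants"] == 0).sum()),
            )
            r = fisher_exact(t)
            rows.append(
                {"class_a": a, "class_b": b, "odds_ratio": r.odds_ratio,
                 "p": r.p_value, "ci_low": r.ci_low, "ci_high": r.ci_high}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class ZoneEnrichment:
    feature_set: str
    zone: str
    center_halfwidth: int
    flank_outer: int
    observed_variants: int
    background_variants: int
    result: EnrichmentResult


def zone_enrichment(
    features: pd.DataFrame,
    variants: pd.DataFrame,
    background_regions: pd.DataFrame,
    center_halfwidth: int = 25,
    flank_outer: int = 250,
    feature_set: str = "features",
) -> list[ZoneEnrichment]:
    """Center/flank variant enrichment vs a random-region background.

    Offsets are measured from feature (and background-region) centers.
    The center zone is |offset| <= center_halfwidth, the flank zone
    center_halfwidth < |offset| <= flank_outer. Each zone's Fisher table
    compares variant base pairs against non-variant base pairs, feature
    vs background, using zone bp totals as denominators (the zones have
    unequal widths, so bp-level rates keep them comparable).
    """
    if len(background_regions) < len(features):
        raise ValueError("background must be at least as large as features")
    zones = {
        "center": lambda d: np.abs(d) <= center_halfwidth,
        "flank": lambda d: (np.abs(d) > center_halfwidth)
        & (np.abs(d) <= flank_outer),
    }
    zone_bp = {
        "center": 2 * center_halfwidth + 1,
        "flank": 2 * (flank_outer - center_halfwidth),
    }
    obs = variant_offsets(features, variants, flank_outer)
    bg = variant_offsets(background_regions, variants, flank_outer)
    out = []
    for zone, member in zones.items():
        n_obs = int(member(obs).sum())
        n_bg = int(member(bg).sum())
        feat_bp = zone_bp[zone] * len(features)
        bg_bp = zone_bp[zone] * len(background_regions)
        t = ContingencyTable(
            a=n_obs, b=feat_bp - n_obs, c=n_bg, d=bg_bp - n_bg
        )
        out.append(
            ZoneEnrichment(
                feature_set=feature_set,
                zone=zone,
                center_halfwidth=center_halfwidth,
                flank_outer=flank_outer,
                observed_variants=n_obs,
                background_variants=n_bg,
                result=fisher_exact(t),
            )
        )
    return out


def variant_density_profile(
    features: pd.DataFrame,
    variants: pd.DataFrame,
    classes: pd.Series | None = None,
    halfwidth: int = 250,
    bandwidth: float = 10.0,
) -> pd.DataFrame:
    """Gaussian-kernel density of variant offsets from feature centers.

    One profile per class (or a single 'all' class), evaluated on integer
    offsets -halfwidth..+halfwidth and normalized to integrate to 1 over
    that support. Classes with no variants in range get a flat zero
    profile.
    """
    if not (halfwidth > bandwidth > 0):
        raise ValueError("need halfwidth > bandwidth > 0")
    grid = np.arange(-halfwidth, halfwidth + 1)
    if classes is None:
        classes = pd.Series("all", index=features.index)
    frames = []
    for cls in sorted(classes.unique()):
        sub = features[classes == cls]
        offs = variant_offsets(sub, variants, halfwidth)
        if len(offs) == 0:
            dens = np.zeros(len(grid))
        else:
            diff = grid[:, None] - offs[None, :]
            k = np.exp(-0.5 * (diff / bandwidth) ** 2)
            dens = k.sum(axis=1)
            dens = dens / np.trapezoid(dens, grid)
        frames.append(
            pd.DataFrame({"offset": grid, "density": dens, "class": cls})
        )
    return pd.concat(frames, ignore_index=True)
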