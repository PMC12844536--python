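"""Count normalization, batch handling, differential testing and the
DAR/DEG class taxonomies.

The differential engine is a moderated group-mean contrast on
(batch-corrected) logCPM: a per-feature cell-means OLS over the strain x
diet design, residual variance pooled across all groups and shrunk
toward the global mean variance with prior weight ``d0 = 4``. The classification layer on top — which comparisons a feature
is significant in, and the Common/Chow/HFD and NonDEG/Diet/Diet+strain/
Strain taxonomies — is the scientific logic this package exists for and
is engine-agnostic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "normalize_logcpm",
    "filter_features",
    "detect_confounded_cluster",
    "residualize_batch",
    "differential_test",
    "classify_dars",
    "classify_degs",
]

#: comparison name -> ((strain, diet) numerator group, denominator group)
#: or strain/diet contrast. log2fc is 129 vs B6 (strain) or HFD vs chow (diet).
COMPARISONS: dict[str, dict[str, str]] = {
    "strain_chow": {"fix": "diet", "at": "chow", "vary": "strain",
                    "num": "S129", "den": "B6"},
    "strain_HFD": {"fix": "diet", "at": "HFD", "vary": "strain",
                   "num": "S129", "den": "B6"},
    "diet_B6": {"fix": "strain", "at": "B6", "vary": "diet",
                "num": "HFD", "den": "chow"},
    "diet_129": {"fix": "strain", "at": "S129", "vary": "diet",
                 "num": "HFD", "den": "chow"},
}


def normalize_logcpm(raw_counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    logCPM_ij = log2((count_ij + prior) / (libsize_j + 2 * prior) * 1e6).
    """
    counts = raw_counts.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = raw_counts.columns[libsize <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    cpm = (counts + prior_count) / (libsize + 2 * prior_count) * 1e6
    return pd.DataFrame(
        np.log2(cpm), index=raw_counts.index, columns=raw_counts.columns
    )


def filter_features(logcpm: pd.DataFrame, min_mean_logcpm: float = -3.0) -> pd.Index:
    """Features whose mean logCPM across all samples exceeds the threshold."""
    keep = logcpm.mean(axis=1) > min_mean_logcpm
    return logcpm.index[keep]


def detect_confounded_cluster(
    logcpm: pd.DataFrame,
    samples: pd.DataFrame,
    n_pcs: int = 10,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Find a 2-means sample cluster on top principal components.

    Features are standardized, PCA reduces to ``n_pcs`` components, and
    2-means splits the samples. The smaller cluster is labelled 2 (the
    candidate contaminating cell-type batch). Returns (labels indexed by
    sample_id, cluster-2-vs-1 differential features) for downstream
    marker-gene enrichment.
    """
    if logcpm.shape[1] < 4:
        raise ValueError("need at least 4 samples for cluster detection")
    X = logcpm.to_numpy(dtype=float).T  # samples x features
    sd = X.std(axis=0)
    if np.all(sd == 0):
        warnings.warn("degenerate matrix: single cluster")
        labels = pd.Series(1, index=logcpm.columns, name="batch_cluster")
        return labels, pd.DataFrame()
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    k = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    pcs = PCA(n_components=k, random_state=seed).fit_transform(Z)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pcs)
    raw = km.labels_
    # smaller cluster -> 2; ties -> cluster containing first sample -> 1
    n1 = (raw == 0).sum()
    n2 = (raw == 1).sum()
    if n1 == n2:
        small = 1 - raw[0]
    else:
        small = 0 if n1 < n2 else 1
    labels = pd.Series(
        np.where(raw == small, 2, 1), index=logcpm.columns, name="batch_cluster"
    )
    diff = _two_group_moderated(
        logcpm,
        logcpm.columns[labels == 2],
        logcpm.columns[labels == 1],
        comparison="cluster2_vs_1",
    )
    return labels, diff


def residualize_batch(
    logcpm: pd.DataFrame, batch_labels: pd.Series, samples: pd.DataFrame
) -> pd.DataFrame:
    """Remove the batch-cluster effect while preserving group means.

    Per feature, the batch indicator is centered within each strain x diet
    group, its least-squares coefficient estimated jointly with the group
    means, and only the centered-batch term subtracted. Group means are
    therefore preserved exactly; a batch perfectly confounded with a group
    term leaves nothing to estimate and raises.
    """
    samples = samples.set_index("sample_id").loc[logcpm.columns]
    batch = batch_labels.loc[logcpm.columns].to_numpy()
    b = (batch == 2).astype(float)
    group = (samples["strain"] + ":" + samples["diet"]).to_numpy()
    b_centered = b.copy()
    for g in np.unique(group):
        m = group == g
        b_centered[m] = b[m] - b[m].mean()
    if np.allclose(b_centered, 0):
        if b.std() == 0:
            return logcpm.copy()
        raise ValueError(
            "batch cluster exactly confounded with strain x diet groups; "
            "redesign required"
        )
    # group cell-means + centered batch; solve per feature in one lstsq
    G = pd.get_dummies(pd.Series(group)).to_numpy(dtype=float)
    X = np.column_stack([G, b_centered])
    Y = logcpm.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    corrected = Y - np.outer(b_centered, beta[-1, :])
    return pd.DataFrame(corrected.T, index=logcpm.index, columns=logcpm.columns)


def _two_group_moderated(
    data: pd.DataFrame,
    group_a: pd.Index,
    group_b: pd.Index,
    comparison: str,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Moderated two-group t on logCPM-scale data. log2fc = mean_a - mean_b."""
    A = data[list(group_a)].to_numpy(dtype=float)
    B = data[list(group_b)].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"comparison {comparison}: need >= 2 samples per side")
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    df_resid = na + nb - 2
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    s2_prior = float(s2.mean()) if len(s2) else 0.0
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_mod * (1 / na + 1 / nb))
    lfc = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2 * sps.t.sf(np.abs(t), df=prior_df + df_resid)
    out = pd.DataFrame(
        {
            "feature_id": data.index,
            "comparison": comparison,
            "log2fc": lfc,
            "p": np.minimum(p, 1.0),
        }
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def differential_test(
    data: pd.DataFrame,
    samples: pd.DataFrame,
    comparison: str,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-feature differential test for one named comparison.

    ``data`` is the batch-corrected logCPM layer restricted to retained
    features. Comparisons: strain_chow / strain_HFD (129 vs B6 within
    diet), diet_B6 / diet_129 (HFD vs chow within strain).

    The model is a cell-means OLS over all strain x diet groups; the
    comparison is the contrast between its two groups, with the residual
    variance pooled across all groups (as one linear model over the full
    design would give) and shrunk toward the global mean variance with
    prior weight ``prior_df``. BH-FDR is computed within the comparison.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    cdef = COMPARISONS[comparison]
    sheet = samples.set_index("sample_id").loc[data.columns]
    group = (sheet["strain"] + ":" + sheet["diet"]).to_numpy()
    X = data.to_numpy(dtype=float)
    uniq, inv = np.unique(group, return_inverse=True)
    n_per = np.bincount(inv)
    if (n_per < 2).any():
        raise ValueError(f"comparison {comparison}: need >= 2 samples per group")
    # residuals around group means, pooled over all groups
    means = np.zeros((X.shape[0], len(uniq)))
    for g in range(len(uniq)):
        means[:, g] = X[:, inv == g].mean(axis=1)
    resid = X - means[:, inv]
    df_resid = X.shape[1] - len(uniq)
    s2 = (resid**2).sum(axis=1) / df_resid
    s2_prior = float(s2.mean()) if len(s2) else 0.0
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    num_g = f"{cdef['num']}:{cdef['at']}" if cdef["vary"] == "strain" else \
        f"{cdef['at']}:{cdef['num']}"
    den_g = f"{cdef['den']}:{cdef['at']}" if cdef["vary"] == "strain" else \
        f"{cdef['at']}:{cdef['den']}"
    gi = {g: k for k, g in enumerate(uniq)}
    if num_g not in gi or den_g not in gi:
        raise ValueError(f"comparison {comparison}: groups missing from design")
    lfc = means[:, gi[num_g]] - means[:, gi[den_g]]
    se = np.sqrt(s2_mod * (1 / n_per[gi[num_g]] + 1 / n_per[gi[den_g]]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2 * sps.t.sf(np.abs(t), df=prior_df + df_resid)
    out = pd.DataFrame(
        {
            "feature_id": data.index,
            "comparison": comparison,
            "log2fc": lfc,
            "p": np.minimum(p, 1.0),
        }
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def classify_dars(
    results_strain_chow: pd.DataFrame,
    results_strain_hfd: pd.DataFrame,
    fdr_max: float = 0.01,
    min_abs_log2fc: float = math.log2(1.5),
) -> pd.DataFrame:
    """DAR taxonomy from the two strain comparisons.

    A peak is a DAR in a comparison when fdr < fdr_max AND |log2fc| >
    min_abs_log2fc. Common = DAR on both diets, Chow/HFD = DAR on that diet
    only, else NonDAR. representative_fdr is the smaller of the two FDRs
    (the more significant underlying comparison).
    """
    chow = results_strain_chow.set_index("feature_id")
    hfd = results_strain_hfd.set_index("feature_id")
    if set(chow.index) != set(hfd.index):
        raise ValueError("strain comparisons cover different feature sets")
    hfd = hfd.loc[chow.index]
    in_chow = (chow["fdr"] < fdr_max) & (chow["log2fc"].abs() > min_abs_log2fc)
    in_hfd = (hfd["fdr"] < fdr_max) & (hfd["log2fc"].abs() > min_abs_log2fc)
    cls = np.where(
        in_chow & in_hfd, "Common",
        np.where(in_chow, "Chow", np.where(in_hfd, "HFD", "NonDAR")),
    )
    return pd.DataFrame(
        {
            "feature_id": chow.index,
            "dar_class": cls,
            "representative_fdr": np.minimum(
                chow["fdr"].to_numpy(), hfd["fdr"].to_numpy()
            ),
            "log2fc_chow": chow["log2fc"].to_numpy(),
            "log2fc_hfd": hfd["log2fc"].to_numpy(),
        }
    ).reset_index(drop=True)


def classify_degs(
    results: dict[str, pd.DataFrame], fdr_max: float = 0.05
) -> pd.DataFrame:
    """DEG taxonomy over the four comparisons.

    DEG-in-comparison iff fdr < fdr_max. Classes: Strain = DEG in both
    strain comparisons; Diet = DEG only in >= 1 diet comparison;
    Diet+strain = DEG in >= 1 diet and >= 1 strain comparison; NonDEG
    otherwise. Precedence DietStrain > Strain > Diet.
    """
    missing = set(COMPARISONS) - set(results)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    frames = {k: v.set_index("feature_id") for k, v in results.items()}
    idx = frames["strain_chow"].index
    for k, f in frames.items():
        if set(f.index) != set(idx):
            raise ValueError(f"comparison {k} covers different features")
        frames[k] = f.loc[idx]
    sig = {k: (frames[k]["fdr"] < fdr_max).to_numpy() for k in frames}
    any_strain = sig["strain_chow"] | sig["strain_HFD"]
    both_strain = sig["strain_chow"] & sig["strain_HFD"]
    any_diet = sig["diet_B6"] | sig["diet_129"]
    cls = np.where(
        any_diet & any_strain, "DietStrain",
        np.where(both_strain, "Strain", np.where(any_diet, "Diet", "NonDEG")),
    )
    rep = np.min(
        np.column_stack([frames[k]["fdr"].to_numpy() for k in COMPARISONS]),
        axis=1,
    )
    return pd.DataFrame(
        {"feature_id": idx, "deg_class": cls, "representative_fdr": rep}
    ).reset_index(drop=True)
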