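"""PWM motif machinery.

Information content and IC-based filtering, similarity merging, exact
log-odds score distributions on a discretized lattice (for p-value
thresholds at arbitrary tails), sequence scanning, and allelic ref-vs-alt
scoring of single-nucleotide variants with strength classes.

Scores are log2 odds of the pseudocount-regularized position
probabilities against a background (uniform by default). The exact score
distribution is built by position-wise convolution of the per-base score
masses under the background, so tail probabilities are exact up to the
lattice granularity.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "PWMotif",
    "ScoreDistribution",
    "AllelicMotifEffect",
    "information_content",
    "filter_and_merge",
    "score_distribution",
    "scan_sequence",
    "allelic_score",
    "read_motifs_jaspar",
    "read_motifs_meme",
    "write_motifs_meme",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on index encoding


@dataclass
class PWMotif:
    """Position probability matrix with background and pseudocount.

    ``prob_matrix`` is L x 4 (A, C, G, T) of base probabilities; the
    log-odds used everywhere regularizes with ``pseudocount`` mass split
    by the background before taking log2 ratios.
    """

    motif_id: str
    tf_name: str
    prob_matrix: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.prob_matrix = np.asarray(self.prob_matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.prob_matrix.ndim != 2 or self.prob_matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: prob_matrix must be L x 4")
        if self.prob_matrix.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        rows = self.prob_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return int(self.prob_matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        """L x 4 log2-odds matrix of regularized probabilities vs background."""
        reg = (self.prob_matrix + self.pseudocount * self.background) / (
            1.0 + self.pseudocount
        )
        return np.log2(reg / self.background)

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds()
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.prob_matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWMotif":
        return PWMotif(
            motif_id=self.motif_id,
            tf_name=self.tf_name,
            prob_matrix=self.prob_matrix[::-1, _COMPLEMENT],
            pseudocount=self.pseudocount,
            background=self.background.copy(),
        )


@dataclass
class ScoreDistribution:
    """Exact discretized distribution of the background log-odds score."""

    granularity: float
    offset: int          # lattice index of score 0
    pmf: np.ndarray      # probability mass per lattice point
    n_positions: int = 0  # motif length; bounds the rounding overshoot

    def survival(self, score: float) -> float:
        """P(score_random >= score) under the background model.

        The query score is snapped to the nearest lattice point. A
        continuous score can exceed the lattice maximum by at most
        n_positions * granularity / 2 through rounding; such scores get
        the top point's mass, anything further above gets 0.
        """
        idx = int(round(score / self.granularity)) + self.offset
        if idx <= 0:
            return 1.0
        if idx >= len(self.pmf):
            max_score = (len(self.pmf) - 1 - self.offset) * self.granularity
            overshoot = self.n_positions * self.granularity / 2 + 1e-9
            if score <= max_score + overshoot:
                idx = len(self.pmf) - 1
            else:
                return 0.0
        return float(self.pmf[idx:].sum())

    def threshold(self, p: float) -> float:
        """Smallest lattice score s with P(score >= s) <= p."""
        sf = np.concatenate([np.cumsum(self.pmf[::-1])[::-1], [0.0]])
        idx = int(np.argmax(sf <= p))
        return (idx - self.offset) * self.granularity


def information_content(pwm: PWMotif) -> tuple[np.ndarray, float]:
    """Per-position IC in bits (uniform background) and its average.

    IC_pos = 2 + sum_b p_b log2 p_b with 0*log(0) = 0; computed on the raw
    probability matrix.
    """
    p = pwm.prob_matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return ic, float(ic.mean())


def _aligned_similarity(a: np.ndarray, b: np.ndarray, min_overlap: int = 4):
    """Best Pearson correlation over alignment offsets (one orientation).

    Returns (similarity, offset) where offset is b's start relative to a's.
    """
    La, Lb = a.shape[0], b.shape[0]
    best = (-2.0, 0)
    for off in range(-(Lb - min_overlap), La - min_overlap + 1):
        a_lo, a_hi = max(0, off), min(La, off + Lb)
        if a_hi - a_lo < min_overlap:
            continue
        av = a[a_lo:a_hi].ravel()
        bv = b[a_lo - off : a_hi - off].ravel()
        sa, sb = av.std(), bv.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.corrcoef(av, bv)[0, 1])
        if r > best[0]:
            best = (r, off)
    return best


def motif_similarity(a: PWMotif, b: PWMotif, min_overlap: int = 4):
    """Max Pearson column correlation over offsets and both orientations.

    Returns (similarity, offset, orientation) with orientation in {+1, -1}
    for b as given or reverse-complemented.
    """
    fwd = _aligned_similarity(a.prob_matrix, b.prob_matrix, min_overlap)
    rev = _aligned_similarity(
        a.prob_matrix, b.reverse_complement().prob_matrix, min_overlap
    )
    if fwd[0] >= rev[0]:
        return fwd[0], fwd[1], 1
    return rev[0], rev[1], -1


def filter_and_merge(
    pwms: Sequence[PWMotif],
    ic_min: float = 0.75,
    similarity_min: float = 0.95,
) -> tuple[list[PWMotif], dict[str, list[str]]]:
    """Discard low-information motifs, then merge near-duplicates.

    Motifs with average IC <= ``ic_min`` are dropped. Remaining motifs are
    single-linkage clustered at pairwise similarity >= ``similarity_min``
    (max column Pearson over offsets and orientations, >= 4 overlapping
    columns). Each cluster's merged PWM averages the members' aligned
    columns (background-padded over the union extent), anchored on the
    longest member (ties -> smaller motif_id). Returns the merged motifs
    and a member map {merged_id: [member ids]} forming a partition.
    """
    kept = [m for m in pwms if information_content(m)[1] > ic_min]
    if not kept:
        raise ValueError("no motifs survive the IC filter")
    n = len(kept)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    align: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sim, off, ori = motif_similarity(kept[i], kept[j])
            if sim >= similarity_min:
                parent[find(i)] = find(j)
                align[(i, j)] = (off, ori)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    merged: list[PWMotif] = []
    member_map: dict[str, list[str]] = {}
    for members in clusters.values():
        members = sorted(
            members, key=lambda i: (-kept[i].length, kept[i].motif_id)
        )
        anchor = kept[members[0]]
        if len(members) == 1:
            merged.append(anchor)
            member_map[anchor.motif_id] = [anchor.motif_id]
            continue
        # align every member to the anchor (direct pairwise alignment)
        placed: list[tuple[int, np.ndarray]] = [(0, anchor.prob_matrix)]
        for i in members[1:]:
            m = kept[i]
            sim, off, ori = motif_similarity(anchor, m)
            mat = (
                m.prob_matrix if ori == 1
                else m.reverse_complement().prob_matrix
            )
            placed.append((off, mat))
        lo = min(off for off, _ in placed)
        hi = max(off + mat.shape[0] for off, mat in placed)
        L = hi - lo
        acc = np.zeros((L, 4))
        for off, mat in placed:
            padded = np.tile(anchor.background, (L, 1))
            padded[off - lo : off - lo + mat.shape[0]] = mat
            acc += padded
        acc /= len(placed)
        acc /= acc.sum(axis=1, keepdims=True)
        mid = f"merged_{anchor.motif_id}"
        merged.append(
            PWMotif(
                motif_id=mid,
                tf_name="/".join(sorted(kept[i].tf_name for i in members)),
                prob_matrix=acc,
                pseudocount=anchor.pseudocount,
                background=anchor.background.copy(),
            )
        )
        member_map[mid] = sorted(kept[i].motif_id for i in members)
    order = np.argsort([m.motif_id for m in merged])
    merged = [merged[i] for i in order]
    return merged, member_map


def score_distribution(pwm: PWMotif, granularity: float = 0.01) -> ScoreDistribution:
    """Exact background distribution of the motif log-odds score.

    Per-position base scores are rounded to the lattice and convolved
    across positions with background base weights; the total rounding
    error is bounded by L * granularity / 2.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    lo = pwm.log_odds()
    lattice = np.rint(lo / granularity).astype(int)
    mins = lattice.min(axis=1)
    maxs = lattice.max(axis=1)
    total_min, total_max = int(mins.sum()), int(maxs.sum())
    pmf = np.array([1.0])
    cur_min = 0
    for i in range(pwm.length):
        span = maxs[i] - mins[i]
        step = np.zeros(span + 1)
        for b in range(4):
            step[lattice[i, b] - mins[i]] += pwm.background[b]
        pmf = np.convolve(pmf, step)
        cur_min += mins[i]
    assert cur_min == total_min and len(pmf) == total_max - total_min + 1
    offset = -total_min  # index of lattice score 0
    return ScoreDistribution(
        granularity=granularity, offset=offset, pmf=pmf,
        n_positions=pwm.length,
    )


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (incl. N) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(lo: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Scores of all length-L windows; NaN where a window contains N."""
    L = lo.shape[0]
    nwin = len(enc) - L + 1
    if nwin <= 0:
        return np.empty(0)
    scores = np.zeros(nwin)
    valid = np.ones(nwin, dtype=bool)
    for i in range(L):
        col = enc[i : i + nwin]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, lo[i, np.clip(col, 0, 3)], 0.0)
    scores[~valid] = np.nan
    return scores


def scan_sequence(
    pwm: PWMotif,
    sequence: str,
    p_max: float = 1e-4,
    dist: ScoreDistribution | None = None,
) -> pd.DataFrame:
    """Both-strand motif hits above the exact p-value threshold.

    Windows containing N are skipped. Returns (position, strand, score, p)
    with position the 0-based window start on the forward sequence.
    """
    if len(sequence) < pwm.length:
        return pd.DataFrame(columns=["position", "strand", "score", "p"])
    if dist is None:
        dist = score_distribution(pwm)
    thr = dist.threshold(p_max)
    enc = encode_sequence(sequence)
    rows = []
    for strand, motif in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(motif.log_odds(), enc)
        # compare on the lattice so continuous rounding cannot drop a hit
        # sitting exactly at the threshold
        cand = np.where(~np.isnan(scores)
                        & (scores >= thr - dist.granularity / 2))[0]
        for pos in cand:
            s = float(scores[pos])
            p = dist.survival(s)
            if p <= p_max:
                rows.append(
                    {"position": int(pos), "strand": strand, "score": s,
                     "p": p}
                )
    out = pd.DataFrame(rows, columns=["position", "strand", "score", "p"])
    return out.sort_values(
        ["position", "strand"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class AllelicMotifEffect:
    """Best-window ref vs alt motif scores at a variant."""

    variant_id: str
    motif_id: str
    tf_name: str
    best_ref_score: float
    best_alt_score: float
    scaled_ref: float
    scaled_alt: float
    scaled_delta: float
    strength: str       # strong | weak | neutral
    significant: bool


def allelic_score(
    pwm: PWMotif,
    ref_window_sequence: str,
    alt_window_sequence: str,
    variant_id: str = "",
    variant_offset: int | None = None,
    dist: ScoreDistribution | None = None,
    p_max: float = 1e-4,
    neutral_max: float = 0.1,
    strong_min: float = 0.4,
) -> AllelicMotifEffect:
    """Score a single-nucleotide variant's effect on a motif.

    The two windows must be equal length and differ at exactly one base
    (the variant). For each allele the best log-odds score over all
    motif-length windows covering the variant position, on both strands,
    is taken; scores are min-max scaled by the PWM's achievable range and
    the effect is scaled_alt - scaled_ref. ``significant`` requires the
    better allele's exact p to reach ``p_max``. Strength: neutral when
    |delta| <= neutral_max, strong when |delta| >= strong_min, else weak.
    """
    if len(ref_window_sequence) != len(alt_window_sequence):
        raise ValueError("ref/alt windows must be equal length")
    diff = [
        i for i, (a, b) in enumerate(zip(ref_window_sequence, alt_window_sequence))
        if a != b
    ]
    if len(diff) != 1:
        raise ValueError(
            f"windows must differ at exactly one base (got {len(diff)})"
        )
    vpos = diff[0]
    if variant_offset is not None and variant_offset != vpos:
        raise ValueError("declared variant_offset does not match sequences")
    L = pwm.length
    if dist is None:
        dist = score_distribution(pwm)
    s_min, s_max = pwm.score_range()
    lo_f = pwm.log_odds()
    lo_r = pwm.reverse_complement().log_odds()

    def best(seq: str) -> float:
        enc = encode_sequence(seq)
        out = -np.inf
        for lo in (lo_f, lo_r):
            scores = _window_scores(lo, enc)
            # keep windows covering the variant position
            starts = np.arange(len(scores))
            cover = (starts <= vpos) & (vpos < starts + L)
            vals = scores[cover]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                out = max(out, float(vals.max()))
        return out

    ref_s = best(ref_window_sequence)
    alt_s = best(alt_window_sequence)
    scaled_ref = (ref_s - s_min) / (s_max - s_min)
    scaled_alt = (alt_s - s_min) / (s_max - s_min)
    delta = scaled_alt - scaled_ref
    p_best = min(dist.survival(ref_s), dist.survival(alt_s))
    if abs(delta) <= neutral_max:
        strength = "neutral"
    elif abs(delta) >= strong_min:
        strength = "strong"
    else:
        strength = "weak"
    return AllelicMotifEffect(
        variant_id=variant_id,
        motif_id=pwm.motif_id,
        tf_name=pwm.tf_name,
        best_ref_score=ref_s,
        best_alt_score=alt_s,
        scaled_ref=scaled_ref,
        scaled_alt=scaled_alt,
        scaled_delta=delta,
        strength=strength,
        significant=bool(p_best <= p_max),
    )


# ---------------------------------------------------------------------------
# format I/O (Biopython-backed)

def _from_bio(m, pseudocount: float = 0.8) -> PWMotif:
    counts = np.array([m.counts[b] for b in BASES], dtype=float).T
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PWMotif(
        motif_id=getattr(m, "matrix_id", None) or m.name,
        tf_name=m.name or "unknown",
        prob_matrix=probs,
        pseudocount=pseudocount,
    )


def read_motifs_jaspar(path: str | Path) -> list[PWMotif]:
    with open(path) as fh:
        return [_from_bio(m) for m in bio_motifs.parse(fh, "jaspar")]


def read_motifs_meme(path: str | Path) -> list[PWMotif]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = [_from_bio(m) for m in parsed]
    # Biopython's minimal parser drops the alternate (TF) name; recover
    # it from the MOTIF header lines
    alt_names = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("MOTIF"):
                parts = line.split()
                alt_names.append(parts[2] if len(parts) > 2 else parts[1])
    for pwm, alt in zip(out, alt_names):
        pwm.tf_name = alt
    return out


def write_motifs_meme(pwms: Iterable[PWMotif], path: str | Path) -> None:
    """MEME minimal-format writer."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for m in pwms:
            fh.write(f"MOTIF {m.motif_id} {m.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m.prob_matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
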