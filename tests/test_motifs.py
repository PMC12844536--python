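"""Motif engine: information content, merging, exact score
distributions against exhaustive enumeration, scanning, allelic scoring."""

import itertools

import numpy as np
import pytest
from scipy.stats import poisson

from strainatac import (
    PWMotif,
    allelic_score,
    filter_and_merge,
    information_content,
    scan_sequence,
    score_distribution,
)
from strainatac.motifs import BASES, motif_similarity


def pwm_from_rows(rows, motif_id="m", tf="tf"):
    return PWMotif(motif_id, tf, np.array(rows, dtype=float))


def random_pwm(rng, L, motif_id="m", conc=0.3):
    mat = rng.dirichlet(np.full(4, conc), size=L)
    return PWMotif(motif_id, motif_id, mat)


def consensus_pwm(L=8, p=0.94, motif_id="cons"):
    mat = np.full((L, 4), (1 - p) / 3)
    mat[np.arange(L), np.arange(L) % 4] = p
    return PWMotif(motif_id, motif_id, mat)


class TestInformationContent:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1, 0, 0, 0], 2.0),
            ([0.5, 0.5, 0, 0], 1.0),
        ],
    )
    def test_single_column_values(self, column, expected):
        mat = [column] * 4  # minimum length 4
        _, avg = information_content(pwm_from_rows(mat))
        assert avg == pytest.approx(expected)


class TestFilterAndMerge:
    def test_identical_motifs_merge(self):
        rng = np.random.default_rng(0)
        a = random_pwm(rng, 8, "A")
        b = PWMotif("B", "B", a.prob_matrix.copy())
        merged, members = filter_and_merge([a, b], ic_min=0.0)
        assert len(merged) == 1
        assert sorted(next(iter(members.values()))) == ["A", "B"]

    def test_reverse_complement_merges(self):
        rng = np.random.default_rng(1)
        a = random_pwm(rng, 8, "A")
        rc = a.reverse_complement()
        b = PWMotif("B", "B", rc.prob_matrix)
        sim, off, ori = motif_similarity(a, b)
        assert sim == pytest.approx(1.0) and ori == -1
        merged, _ = filter_and_merge([a, b], ic_min=0.0)
        assert len(merged) == 1

    def test_low_ic_discarded(self):
        flat = pwm_from_rows([[0.25] * 4] * 6, "flat")
        sharp = consensus_pwm(motif_id="sharp")
        merged, members = filter_and_merge([flat, sharp], ic_min=0.75)
        assert [m.motif_id for m in merged] == ["sharp"]
        with pytest.raises(ValueError):
            filter_and_merge([flat], ic_min=0.75)

    def test_member_map_is_partition(self):
        rng = np.random.default_rng(2)
        pwms = [random_pwm(rng, int(rng.integers(6, 10)), f"m{i}")
                for i in range(10)]
        pwms.append(PWMotif("m0copy", "t", pwms[0].prob_matrix.copy()))
        merged, members = filter_and_merge(pwms, ic_min=0.0)
        surviving = sorted(itertools.chain.from_iterable(members.values()))
        assert surviving == sorted(p.motif_id for p in pwms)

    def test_cluster_assignment_matches_similarity_oracle(self):
        rng = np.random.default_rng(3)
        pwms = [random_pwm(rng, 7, f"m{i}") for i in range(10)]
        pwms[5] = PWMotif("m5", "m5", pwms[2].prob_matrix.copy())
        merged, members = filter_and_merge(pwms, ic_min=0.0)

        # independent oracle: brute-force pairwise similarity + union-find
        def oracle_sim(a, b):
            best = -2
            for mats in ((a.prob_matrix, b.prob_matrix),
                         (a.prob_matrix, b.reverse_complement().prob_matrix)):
                A, B = mats
                for off in range(-(B.shape[0] - 4), A.shape[0] - 4 + 1):
                    lo, hi = max(0, off), min(A.shape[0], off + B.shape[0])
                    if hi - lo < 4:
                        continue
                    av = A[lo:hi].ravel()
                    bv = B[lo - off : hi - off].ravel()
                    if av.std() == 0 or bv.std() == 0:
                        continue
                    best = max(best, np.corrcoef(av, bv)[0, 1])
            return best

        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(p.motif_id for p in pwms)
        for i in range(10):
            for j in range(i + 1, 10):
                if oracle_sim(pwms[i], pwms[j]) >= 0.95:
                    g.add_edge(pwms[i].motif_id, pwms[j].motif_id)
        oracle_clusters = sorted(
            sorted(c) for c in nx.connected_components(g)
        )
        got_clusters = sorted(sorted(v) for v in members.values())
        assert got_clusters == oracle_clusters


class TestScoreDistribution:
    def test_masses_sum_to_one(self):
        rng = np.random.default_rng(4)
        d = score_distribution(random_pwm(rng, 6, "m"))
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exhaustive_enumeration_small_motifs(self):
        rng = np.random.default_rng(5)
        for L in (4, 5, 6):
            pwm = random_pwm(rng, L, f"m{L}")
            dist = score_distribution(pwm)
            lo = pwm.log_odds()
            scores = np.zeros(4**L)
            for k, seq in enumerate(itertools.product(range(4), repeat=L)):
                scores[k] = lo[np.arange(L), list(seq)].sum()
            for q in (0.5, 0.0, -2.0, 5.0):
                exact = (scores >= q - L * 0.01).mean()
                exact_lo = (scores >= q + L * 0.01).mean()
                got = dist.survival(q)
                assert exact_lo - 1e-12 <= got <= exact + 1e-12

    def test_threshold_monotone_in_p(self):
        rng = np.random.default_rng(6)
        dist = score_distribution(random_pwm(rng, 8, "m"))
        thresholds = [dist.threshold(p) for p in (1e-5, 1e-4, 1e-3, 1e-2)]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_bad_granularity_rejected(self):
        with pytest.raises(ValueError):
            score_distribution(consensus_pwm(), granularity=0)


class TestScanSequence:
    def test_consensus_hit_maximal(self):
        pwm = consensus_pwm()
        seq = "TTTTT" + pwm.consensus() + "TTTTT"
        hits = scan_sequence(pwm, seq, p_max=1e-3)
        plus = hits[hits["strand"] == "+"]
        assert 5 in plus["position"].tolist()
        best = plus.set_index("position").loc[5, "score"]
        assert best == pytest.approx(pwm.score_range()[1])

    def test_strand_symmetry(self):
        pwm = consensus_pwm()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        fwd = "AAAA" + pwm.consensus() + "CCCC"
        rev = "".join(comp[b] for b in reversed(fwd))
        h_f = scan_sequence(pwm, fwd, p_max=1e-3)
        h_r = scan_sequence(pwm, rev, p_max=1e-3)
        assert len(h_f) == len(h_r)
        assert sorted(h_f["score"]) == pytest.approx(sorted(h_r["score"]))

    def test_n_windows_skipped(self):
        pwm = consensus_pwm()
        seq = pwm.consensus()[:4] + "N" + pwm.consensus()[5:]
        assert len(scan_sequence(pwm, seq, p_max=0.5)) == 0

    def test_null_hit_rate_poisson(self):
        rng = np.random.default_rng(7)
        pwm = random_pwm(rng, 10, "m", conc=1.0)
        dist = score_distribution(pwm)
        thr = dist.threshold(1e-4)
        p_eff = dist.survival(thr)  # lattice tail at the chosen cutoff
        seq = "".join(rng.choice(list(BASES), size=10_000))
        hits = scan_sequence(pwm, seq, p_max=1e-4, dist=dist)
        lam = 2 * (10_000 - pwm.length + 1) * p_eff
        lo, hi = poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(hits) <= hi

    def test_short_sequence_empty(self):
        assert len(scan_sequence(consensus_pwm(), "ACG")) == 0


class TestAllelicScore:
    def window_pair(self, pwm, j, ref_base, alt_base, rng):
        """ref/alt windows: consensus instance embedded in random context,
        variant at motif position j."""
        L = pwm.length
        inst = list(pwm.consensus())
        inst[j] = ref_base
        left = "".join(rng.choice(list(BASES), size=L - 1))
        right = "".join(rng.choice(list(BASES), size=L - 1))
        ref = left + "".join(inst) + right
        vpos = len(left) + j
        alt = ref[:vpos] + alt_base + ref[vpos + 1 :]
        return ref, alt

    def test_consensus_disruption_strongly_negative(self):
        rng = np.random.default_rng(8)
        pwm = consensus_pwm()
        cons = pwm.consensus()
        worst = BASES[int(pwm.prob_matrix[3].argmin())]
        ref, alt = self.window_pair(pwm, 3, cons[3], worst, rng)
        eff = allelic_score(pwm, ref, alt, "v")
        assert eff.scaled_delta < -0.1
        assert eff.significant  # consensus allele reaches the threshold

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng, 8, "m")
        ref, alt = self.window_pair(pwm, 2, "A", "G", rng)
        fwd = allelic_score(pwm, ref, alt, "v")
        rev = allelic_score(pwm, alt, ref, "v")
        assert fwd.scaled_delta == pytest.approx(-rev.scaled_delta, abs=1e-12)

    def test_equal_windows_rejected(self):
        pwm = consensus_pwm()
        seq = "A" * (2 * pwm.length - 1)
        with pytest.raises(ValueError):
            allelic_score(pwm, seq, seq, "v")

    def test_best_window_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(10)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for case in range(100):
            L = int(rng.integers(5, 10))
            pwm = random_pwm(rng, L, f"m{case}")
            seq = "".join(rng.choice(list(BASES), size=2 * L - 1))
            vpos = L - 1
            alt_base = rng.choice([b for b in BASES if b != seq[vpos]])
            alt = seq[:vpos] + alt_base + seq[vpos + 1 :]
            eff = allelic_score(pwm, seq, alt, f"v{case}")

            def oracle_best(s):
                lo_f = pwm.log_odds()
                best = -np.inf
                rc = "".join(comp[b] for b in reversed(s))
                for track in (s, rc):
                    for start in range(len(track) - L + 1):
                        # window must cover the variant on the forward axis
                        fstart = (
                            start if track is s
                            else len(s) - (start + L)
                        )
                        if not (fstart <= vpos < fstart + L):
                            continue
                        win = track[start : start + L]
                        sc = sum(
                            lo_f[i, BASES.index(win[i])] for i in range(L)
                        )
                        best = max(best, sc)
                return best

            assert eff.best_ref_score == pytest.approx(oracle_best(seq))
            assert eff.best_alt_score == pytest.approx(oracle_best(alt))

    def test_strength_labels_consistent_with_scaled_delta(self, run):
        eff = run["allelic_effects"]
        d = eff["scaled_delta"].abs()
        assert (eff.loc[d <= 0.1, "strength"] == "neutral").all()
        assert (eff.loc[d >= 0.4, "strength"] == "strong").all()
        mid = (d > 0.1) & (d < 0.4)
        assert (eff.loc[mid, "strength"] == "weak").all()
        # the generator plants all three regimes
        assert set(eff["strength"]) == {"neutral", "weak", "strong"}
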