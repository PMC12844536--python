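"""Allelic motif scoring with exact PWM score distributions.

Builds a sharp 8-bp motif, computes the exact background distribution
of its log-odds score (so p-values are exact, not sampled), scans a
sequence containing the consensus, and scores a variant that swaps the
consensus base at position 3 for the worst base — the motifbreakR-style
ref-vs-alt comparison.
"""

import numpy as np

from strainatac import PWMotif, allelic_score, scan_sequence, score_distribution
from strainatac.motifs import BASES, information_content

rng = np.random.default_rng(0)
mat = np.full((8, 4), 0.02)
mat[np.arange(8), rng.integers(0, 4, 8)] = 0.94
pwm = PWMotif("demo", "DemoTF", mat)
_, avg_ic = information_content(pwm)
print(f"motif {pwm.consensus()}, average IC {avg_ic:.2f} bits "
      f"(> 0.75 so it survives the reliability filter)")

dist = score_distribution(pwm)
print(f"score threshold at p=1e-4: {dist.threshold(1e-4):.2f} bits")

seq = "ACGTGGTT" + pwm.consensus() + "TTACGGAA"
hits = scan_sequence(pwm, seq, p_max=1e-4)
print(f"scan finds {len(hits)} hit(s); best p = {hits['p'].min():.2e}")

j = 3
worst = BASES[int(pwm.prob_matrix[j].argmin())]
vpos = 8 + j  # variant position inside the embedded consensus
alt = seq[:vpos] + worst + seq[vpos + 1:]
ref_win = seq[vpos - 7: vpos + 8]
alt_win = alt[vpos - 7: vpos + 8]
eff = allelic_score(pwm, ref_win, alt_win, "rs_demo")
print(f"ref score {eff.best_ref_score:.2f}, alt score "
      f"{eff.best_alt_score:.2f}, scaled delta {eff.scaled_delta:+.3f} "
      f"({eff.strength}), significant={eff.significant}")
# a negative scaled delta means the alternate allele weakens the site;
# significance requires the better allele to pass the 1e-4 scan threshold
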