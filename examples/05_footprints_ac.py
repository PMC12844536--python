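"""Footprint scoring and AC-footprint concordance.

Scores Tn5 cut-site profiles with the flank-minus-center statistic,
calls bound sites per group by 2-means, takes the diet-matched strain
score difference, and flags AC-footprints: sites where a significantly
altered motif's allelic score and the strain footprint change agree in
sign. The enrichment of AC-footprints in Common-DARs is the pipeline's
central readout.
"""

from strainatac import RunConfig, SimConfig, generate, run_pipeline

data = generate(SimConfig(seed=1))
out = run_pipeline(data, RunConfig(seed=1))

sites = out["footprint_sites"]
print(f"{len(sites)} footprint sites; "
      f"{int(sites['bound_any'].sum())} bound in >= 1 group; "
      f"{int(sites['ac_flag'].sum())} AC-footprints")

enr = out["ac_analysis"]["enrichment"].set_index("dar_class")
row = enr.loc["Common"]
print(f"AC enrichment in Common-DARs vs non-DARs: OR {row['odds_ratio']:.1f} "
      f"(95% CI {row['ci_low']:.1f}-{row['ci_high']:.1f}), p {row['p']:.1e}")

corr = out["ac_analysis"]["correlation"].set_index("dar_class")
print(f"footprint-difference vs allelic-score Spearman (Common): "
      f"rho {corr.loc['Common', 'rho']:.2f}, p {corr.loc['Common', 'p']:.1e}")

st = out["ac_analysis"]["strength"].set_index(["stronger", "weaker"])
row = st.loc[("strong", "neutral")]
print(f"|score diff| strong vs neutral motifs: Wilcoxon p {row['p']:.1e}, "
      f"effect r {row['effect_r']:.2f}")

tf = out["tf_stats"]
passing = tf[tf["passes_ac_rule"] & ~tf["low_count"]]["tf_name"].tolist()
print(f"TFs with >= 90% of motif-altering variants showing AC-footprints: "
      f"{passing}")
# concordance concentrated in DARs, and per-TF concordance near 1 for
# pioneer-like factors, is the genetic-variation-drives-binding signal
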