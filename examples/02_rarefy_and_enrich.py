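"""Metadata-category enrichment on a rarefied synthetic survey.

Generates a 200-sample survey in which feature F0001 is planted to be
present in 90% of host_a samples but only 10% of the rest, rarefies to
a common depth, and runs both enrichment tests for every value of the
host field. The planted category should dominate both tests.
"""

from ampliquery import (
    PlantedEffect,
    enriched_subset,
    enumerate_enrichment,
    generate_survey,
    rarefy,
)

effect = PlantedEffect(
    "F0001", "host", "host_a", p_in=0.9, p_out=0.1,
    mean_freq_in=0.05, mean_freq_out=0.01,
)
table, metadata, _ = generate_survey(
    n_samples=200, n_features=300, effects=[effect], seed=7
)
rare = rarefy(table, depth=2000, seed=7)

results = enumerate_enrichment(rare, metadata, "F0001", ["host"], alpha=0.1)
print("field=host, feature=F0001  (N samples, O present, T with value, K overlap)")
print(f"{'value':<10}{'test':<10}{'p':>12}{'q':>12}  N   O   T   K")
for r in results:
    s = r.summary
    print(
        f"{r.value:<10}{r.test:<10}{r.p_value:>12.3g}{r.q_value:>12.3g}"
        f"{s.N:>4}{s.O_s:>4}{s.T_v:>4}{s.K_vs:>4}"
    )

flagged = enriched_subset(results, alpha=0.1)
print("\nenriched at BH q <= 0.1:", [(r.value, r.test) for r in flagged])
print(
    "Both the presence/absence binomial test and the frequency-aware "
    "ranksum test single out the planted host_a association."
)
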