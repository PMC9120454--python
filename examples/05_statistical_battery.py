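"""The statistical battery: gram ratios, model selection, rank tests, PERMANOVA.

Simulates replicate mock-community samples in which gram-positive
species are systematically over-represented, then asks the questions
the battery answers: what is the gram ratio vs expectation, which
genome property predicts abundance bias, which clades differ between
groups, and does any design factor explain the between-sample distances?
"""

import numpy as np
import pandas as pd

from gutbench import (
    CommunitySpec,
    dissimilarity_matrix,
    gram_ratio,
    make_community,
    pairwise_clade_tests,
    permanova,
    simulate_observed_profile,
    ProfileNoiseSpec,
    top_down_select,
)

community = make_community(CommunitySpec(seed=8))
rng = np.random.default_rng(8)

# gram-positive over-representation grows with homogenisation time
profiles, groups = [], {}
for minutes, boost in (("10min", 1.1), ("15min", 1.4), ("20min", 1.8)):
    for rep in range(3):
        prof = simulate_observed_profile(
            community, ProfileNoiseSpec(abundance_cv=0.05, seed=int(rng.integers(2**31))),
            sample_id=f"{minutes}-r{rep}",
        )
        entries = dict(prof.entries)
        for t in entries:
            if community.annotation(t).gram == "positive":
                entries[t] *= boost
        total = sum(entries.values())
        prof.entries = {t: 100 * a / total for t, a in entries.items()}
        profiles.append(prof)
        groups[prof.sample_id] = minutes

print("gram-positive/gram-negative abundance ratios:")
for prof in profiles[::3]:
    r = gram_ratio(prof, community)
    print(f"  {prof.sample_id:10s} observed {r.observed_ratio:.3f}  (expected {r.expected_ratio:.3f})")

# which genome property predicts the per-species abundance deviation?
taxa = sorted(community.entries, key=lambda t: t.key)
median_abund = [float(np.median([p.entries.get(t, 0.0) for p in profiles])) for t in taxa]
design = pd.DataFrame(
    {
        "gram_indicator": [1.0 if community.annotation(t).gram == "positive" else 0.0 for t in taxa],
        "genome_length": [community.annotation(t).genome_length for t in taxa],
        "gc_content": [community.annotation(t).gc_content for t in taxa],
    }
)
fit = top_down_select(median_abund, design, alpha=0.05)
print()
print(f"top-down linear model retained: {fit.retained_terms}")
print(f"  dropped in order: {fit.elimination_trace}")
for term in fit.retained_terms:
    print(f"  {term}: coefficient {fit.coefficients[term]:.4f}, p = {fit.p_values[term]:.4g}")

# per-clade pairwise Wilcoxon with FDR correction
table = pairwise_clade_tests(profiles, groups).rows
print()
print(f"pairwise Wilcoxon tests: {len(table)} comparisons, "
      f"smallest adjusted p = {table['p_adjusted'].min():.3f}")
print("(with 3 replicates per group the exact two-sided p cannot go below 0.1,")
print(" so no single clade clears the FDR threshold despite the planted shift)")

# does homogenisation time explain the distance structure?
dm = dissimilarity_matrix(profiles)
factors = pd.DataFrame({"sample_id": list(groups), "time": list(groups.values())})
res = permanova(dm, factors, "time", n_permutations=999, seed=8)
t = res.terms[0]
print()
print(f"PERMANOVA on homogenisation time: F = {t.f:.3f}, R2 = {t.r2:.3f}, p = {t.p:.3f}")
print()
print("The retained gram indicator and the significant PERMANOVA term both")
print("point at the planted effect: gram status drives the abundance bias and")
print("homogenisation time structures the between-sample dissimilarities.")
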