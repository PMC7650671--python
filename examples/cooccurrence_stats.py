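"""Co-occurrence statistics with automatic test selection.

Reproduces the published pairwise association p-values from the
published cross-tables, then runs the same machinery on a simulated
cohort.  The selection rule: plain chi-square when every expected count
is >= 5, Yates-corrected when >= 3, Fisher exact otherwise.
"""

import palinsig as ps

printed = {
    ("GPR126", "PLEKHS1"): [[45, 28], [11, 19]],
    ("PLEKHS1", "Intron ADM"): [[70, 21], [3, 9]],
    ("Intron ADM", "Chr15:96"): [[88, 7], [3, 5]],
    ("GPR126", "Chr15:96"): [[55, 40], [1, 7]],
    ("PLEKHS1", "Chr15:96"): [[70, 25], [3, 5]],
}

print("published cross-tables, recomputed:")
for (a, b), table in printed.items():
    res = ps.select_and_run_test(table)
    print(f"  {a:11s} x {b:11s} min_E={res.min_expected:5.2f} "
          f"{res.test_used:10s} p={res.p_value:.4f}")

print("\nsimulated cohort (103 tumors, latent-factor dependence, OR target 10):")
table, samples, truth = ps.simulate_cohort(ps.CohortSimSpec(seed=3))
matrix, _ = ps.build_matrix(table, ps.default_registry(), samples)
pairs = ps.pairwise_cooccurrence(
    matrix, ["GPR126", "PLEKHS1", "Intron ADM", "Chr7:11", "Chr15:96"])
for row in pairs.itertuples():
    print(f"  {row.locus_a:11s} x {row.locus_b:11s} "
          f"M/M={row.a_m_b_m:3d} {row.test_used:10s} p={row.p_value:.4f}")

print("\nSmall p-values mean mutations at the two loci co-occur more often "
      "than independence allows — the behavior a shared instability "
      "mechanism produces (and the generator plants via one latent factor).")
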