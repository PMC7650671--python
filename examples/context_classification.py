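"""Classify core-motif mutations by trinucleotide context.

The two recurrently mutated TGAACA positions behave differently under
pyrimidine normalization: the offset-1 G>A becomes C>T at TCA (the
optimal APOBEC deaminase substrate), while the offset-4 C>T sits in ACA
(not a TpC context).
"""

import pandas as pd

import palinsig as ps

arm = "CATTGGCGA"
body = "GG" + arm + "TGAACA" + ps.reverse_complement(arm) + "GG"
seq = ps.ReferenceSequence("chrT", body)
core0 = 11  # 0-based core start

muts = pd.DataFrame([
    {"sample_id": "T1", "chrom": "chrT", "pos": core0 + 2, "ref": "G", "alt": "A"},
    {"sample_id": "T2", "chrom": "chrT", "pos": core0 + 5, "ref": "C", "alt": "T"},
])
table, summary = ps.classify_cohort(muts, {"chrT": seq})

print(table[["pos", "substitution", "trinucleotide", "apobec_class"]].to_string(index=False))
print(f"\nfraction C>T after normalization: {summary['fraction_c_to_t']:.0%}")
print(f"fraction in TCN (APOBEC-compatible) contexts: "
      f"{summary['fraction_apobec_compatible']:.0%}")
print("\nBoth calls are C>T on the pyrimidine strand; only the offset-1 "
      "call sits in the TCA context that APOBEC3 enzymes prefer.")
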