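"""Discovery mode: find candidate cores around a called variant.

Given a +/-30 bp window with the alternate allele substituted in, every
5-8 bp sub-pattern covering the variant is tried as a candidate core;
those flanked by maximal arms of at least 8 bp on each side survive,
unless the pattern or an arm is a homopolymer.
"""

import palinsig as ps

arm = "GATCCGTA"  # 8 bp, mixed content
construct = arm + "TGAACA" + ps.reverse_complement(arm)
# variant (the mutated core G, offset 1) placed at window offset 30
left = 30 - (len(arm) + 1)
window = "C" * left + construct + "C" * (61 - left - len(construct))

candidates = ps.scan_variant_window(window, variant_offset=30, min_arm=8)
print(f"window of {len(window)} bp, variant at offset 30")
print(f"{'start':>5s} {'len':>3s} {'arm':>3s}  pattern")
for c in candidates:
    pat = window[c.core_start_in_window:c.core_end_in_window]
    print(f"{c.core_start_in_window:5d} {c.core_len:3d} {c.arm_length:3d}  {pat}")

print("\nEach row is a candidate core containing the variant with perfect "
      "inverted-repeat arms >= 8 bp — the construct class the genome-wide "
      "scan then searches for at fixed core.")
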