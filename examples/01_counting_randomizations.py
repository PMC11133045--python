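"""How many admissible randomizations does a changing criterion design have?

Under phase change moment (PCM) randomization the admissible set is all
compositions of the series length into bounded phase lengths; under blocked
alternating criterion (BAC) randomization it is 2**B within-block orders.
The count caps the smallest attainable p-value at 1/count, so it decides
whether a design can reject at alpha = .05 at all.
"""

from ccdrand import PCMDesign, count_randomizations, enumerate_compositions

designs = [
    ("37 measurements, 10 phases, min 3", PCMDesign(37, 10, 3)),
    ("20 measurements, 4 phases, min 3", PCMDesign(20, 4, 3)),
    ("15 measurements, 4 phases, 3..6", PCMDesign(15, 4, 3, 6)),
    ("30 measurements, 5 phases, min 3", PCMDesign(30, 5, 3)),
]
for label, design in designs:
    count = count_randomizations(design)
    print(f"PCM  {label:38s} -> {count:>7,} randomizations (min p = {1 / count:.2g})")

for n_blocks in (2, 4, 5):
    label = f"{2 * n_blocks} phases in {n_blocks} blocks of two"
    print(f"BAC  {label:38s} -> {2**n_blocks:>7,} randomizations (min p = {2**-n_blocks:.2g})")

print()
comps = enumerate_compositions(PCMDesign(15, 4, 3, 6))
print(f"the {len(comps)} compositions of 15 into 4 phases of length 3..6,")
print(f"lexicographic: first {comps[0]}, last {comps[-1]}")
print("a BAC design needs at least 5 blocks (10 phases) for min p <= .05;")
print("a PCM design gets there with just 15 measurements in 4 phases.")
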