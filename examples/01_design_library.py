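"""Design a sequence-tagged repair-template library for an E-box locus.

Walks through the library math: how many distinguishable tags exist at each
Hamming distance from the reference flank, how many mutations a synthesized
oligo is expected to carry under the doped-synthesis model, and what the
resulting 100-nt templates look like.
"""

import numpy as np

from cge import (
    CodonTagSpec,
    enumerate_codon_tags,
    enumerate_tags,
    expected_base_matrix,
    mutation_count_distribution,
    sample_template,
    translate,
)
from cge.simulate import demo_locus

design = demo_locus(seed=7)
print(f"locus {design.locus_name}: {design.original_seq} -> {design.mutant_seq}")
print(f"reference flank (5 nt each side of the variant): {design.reference_flank}")

# Tag space: 10 positions x 3 alternative bases.
for k in range(4):
    print(f"tags at Hamming distance {k}: {len(enumerate_tags(design.reference_flank, k))}")

# Each flank position mutates with probability 0.24 (8% per alternative base),
# so most synthesized oligos carry 2-3 tag mutations.
pmf = mutation_count_distribution(design.tag_scheme)
print(f"P(2 or 3 mutations) = {pmf[2] + pmf[3]:.4f}")
print(f"P(at most 5 mutations) = {pmf[:6].sum():.4f}")
print(f"P(no mutations, i.e. tag identical to wild type) = {pmf[0]:.4f}")

# Expected base composition per flank position (rows A, C, G, T).
pwm = expected_base_matrix(design.reference_flank, design.tag_scheme)
np.set_printoptions(precision=2, suppress=True)
print("expected base matrix:\n", pwm)

# Sample a small oligo library: each template is 42-nt arm + tagged flank +
# variant + tagged flank + 42-nt arm = 100 nt.
rng = np.random.default_rng(42)
for i in range(3):
    for variant in ("original", "mutant"):
        t = sample_template(design, variant, rng)
        print(f"oligo {i} ({variant}, {len(t)} nt): {t}")

# Coding-region alternative: synonymous degenerate-codon tags. The control
# swap GTTAGC -> GTAAGT keeps the Val-Ser protein sequence.
spec = CodonTagSpec(
    coding_context="ATGGTTAGCGGTACCAAA",
    variant_start=3,
    experimental_variants=(("control", "GTAAGT"),),
    degenerate_positions=(11, 14),
)
assert translate("GTTAGC") == translate("GTAAGT") == "VS"
tags = enumerate_codon_tags(spec)
print(f"codon-tag library size for 2 degenerate third positions: {len(tags)}")
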