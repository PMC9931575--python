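"""Design of sequence-tagged HDR repair-template libraries.

Competitive genome editing (CGE) repairs a Cas9 cut with a pool of
single-stranded oligos carrying (i) an experimental variant — either the
original genomic sequence, reconstituting wild type, or a designed mutation
such as the E-box CACGTG replaced by TATTTA — and (ii) a near-silent
sequence tag written into the nucleotides flanking the variant. Each of the
ten flank positions (five per side) is mutated independently with
probability 0.24, i.e. 0.08 for each of the three non-consensus bases.
The tag identifies the cell lineage founded by each repair event, so the
pool of edited cells carries thousands of internal replicates.

For coding targets the tag is instead built from synonymous substitutions
at degenerate codon positions so that the protein sequence is untouched.

This module holds the design records and the exact combinatorics of the
tag space: enumeration of tags at a given Hamming distance, the binomial
distribution of mutation counts per oligo, the expected per-position base
composition (a position weight matrix), template sampling, and exhaustive
enumeration of degenerate-codon tag libraries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_SET = frozenset(BASES)
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class DesignError(ValueError):
    """A locus or codon-tag design violates its own geometry or chemistry."""


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - _BASE_SET:
        raise DesignError(f"{what} must be a non-empty string over ACGT, got {seq!r}")
    return seq


@dataclass(frozen=True)
class TagScheme:
    """Stochastic flank-mutation scheme for non-coding sequence tags.

    Each of ``n_positions`` flank nucleotides is mutated independently with
    probability ``per_position_mut_prob``; conditional on mutation, the three
    alternative bases are equally likely (``per_base_prob`` each).
    """

    n_positions: int = 10
    per_position_mut_prob: float = 0.24
    per_base_prob: float = 0.08

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise DesignError("n_positions must be >= 1")
        if not 0.0 < self.per_position_mut_prob < 1.0:
            raise DesignError("per_position_mut_prob must lie in (0, 1)")
        if abs(self.per_position_mut_prob - 3.0 * self.per_base_prob) > 1e-12:
            raise DesignError(
                "per_position_mut_prob must equal 3 x per_base_prob "
                f"({self.per_position_mut_prob} != 3*{self.per_base_prob})"
            )


@dataclass(frozen=True)
class LocusDesign:
    """Everything needed to build and recognise templates for one locus.

    ``amplicon_ref`` is the unedited PCR product; ``original_seq`` must occur
    at ``variant_start`` (0-based) and is swapped for ``mutant_seq`` in the
    mutant templates. The tag region is the ``flank_len`` nucleotides on each
    side of the variant; homology arms of ``homology_arm_len`` extend beyond
    the tag region in the synthesised oligo.
    """

    locus_name: str
    amplicon_ref: str
    variant_start: int
    original_seq: str
    mutant_seq: str
    prefix_len: int = 20
    flank_len: int = 5
    homology_arm_len: int = 42
    tag_scheme: TagScheme = field(default_factory=TagScheme)
    flank_mask: tuple[int, ...] = ()  # 0-based tag positions excluded from mutation

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicon_ref", _check_dna(self.amplicon_ref, "amplicon_ref"))
        object.__setattr__(self, "original_seq", _check_dna(self.original_seq, "original_seq"))
        object.__setattr__(self, "mutant_seq", _check_dna(self.mutant_seq, "mutant_seq"))
        if len(self.original_seq) != len(self.mutant_seq):
            raise DesignError(
                f"{self.locus_name}: original_seq and mutant_seq lengths differ "
                f"({len(self.original_seq)} vs {len(self.mutant_seq)})"
            )
        if self.original_seq == self.mutant_seq:
            raise DesignError(f"{self.locus_name}: original and mutant variants are identical")
        v0, v1 = self.variant_start, self.variant_start + len(self.original_seq)
        if self.amplicon_ref[v0:v1] != self.original_seq:
            raise DesignError(
                f"{self.locus_name}: original_seq not found at variant_start {v0}"
            )
        if v0 - self.flank_len - self.homology_arm_len < 0 or v1 + self.flank_len + self.homology_arm_len > len(self.amplicon_ref):
            raise DesignError(
                f"{self.locus_name}: flanks/homology arms extend past the amplicon ends"
            )
        if self.prefix_len > len(self.amplicon_ref):
            raise DesignError(f"{self.locus_name}: prefix_len exceeds amplicon length")
        if self.tag_scheme.n_positions != 2 * self.flank_len:
            raise DesignError(
                f"{self.locus_name}: tag scheme covers {self.tag_scheme.n_positions} "
                f"positions but the flanks provide {2 * self.flank_len}"
            )
        if any(p < 0 or p >= 2 * self.flank_len for p in self.flank_mask):
            raise DesignError(f"{self.locus_name}: flank_mask positions out of range")

    @property
    def prefix(self) -> str:
        """Locus-assignment prefix: the first ``prefix_len`` nt of the amplicon."""
        return self.amplicon_ref[: self.prefix_len]

    @property
    def variant_end(self) -> int:
        return self.variant_start + len(self.original_seq)

    @property
    def reference_flank(self) -> str:
        """The unmutated 5'+3' flank concatenated 5'->3' (the zero-mutation tag)."""
        a = self.amplicon_ref
        return (
            a[self.variant_start - self.flank_len : self.variant_start]
            + a[self.variant_end : self.variant_end + self.flank_len]
        )

    @property
    def template_len(self) -> int:
        return 2 * self.homology_arm_len + 2 * self.flank_len + len(self.original_seq)

    def center(self, variant_label: str) -> str:
        if variant_label == "original":
            return self.original_seq
        if variant_label == "mutant":
            return self.mutant_seq
        raise ValueError(f"variant_label must be 'original' or 'mutant', got {variant_label!r}")


def enumerate_tags(reference_flank: str, k: int) -> list[str]:
    """All distinct tags at Hamming distance exactly ``k`` from the reference.

    The count is C(n, k) * 3^k for an n-nt flank: choose the mutated
    positions, then one of three alternative bases at each. For the 10-nt
    CGE tag region this gives 1, 30, 405 and 3,240 tags at k = 0..3.
    """
    reference_flank = _check_dna(reference_flank, "reference_flank")
    n = len(reference_flank)
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    out: list[str] = []
    for positions in itertools.combinations(range(n), k):
        alternatives = [[b for b in BASES if b != reference_flank[p]] for p in positions]
        for choice in itertools.product(*alternatives):
            tag = list(reference_flank)
            for p, b in zip(positions, choice):
                tag[p] = b
            out.append("".join(tag))
    assert len(out) == comb(n, k) * 3**k
    return out


def mutation_count_distribution(scheme: TagScheme) -> np.ndarray:
    """Binomial pmf of the number of mutated tag positions per oligo.

    Entry k is C(n, k) p^k (1-p)^(n-k) with n = ``n_positions`` and
    p = ``per_position_mut_prob``. Under the default 10/0.24 scheme, 2-3
    mutations cover ~53% of oligos and 0-5 mutations cover 98.4%.
    """
    n, p = scheme.n_positions, scheme.per_position_mut_prob
    k = np.arange(n + 1)
    pmf = np.array([comb(n, int(j)) for j in k], dtype=float) * p**k * (1 - p) ** (n - k)
    assert abs(pmf.sum() - 1.0) < 1e-12
    return pmf


def expected_base_matrix(reference_flank: str, scheme: TagScheme) -> np.ndarray:
    """Expected base frequencies of sampled tags: a 4 x n matrix (rows ACGT).

    At every position the consensus base keeps probability 1 - p and each
    alternative gets p/3; this is the position weight matrix of the designed
    library (0.76 / 0.08 under the default scheme).
    """
    reference_flank = _check_dna(reference_flank, "reference_flank")
    if len(reference_flank) != scheme.n_positions:
        raise ValueError("reference_flank length must equal scheme.n_positions")
    p = scheme.per_position_mut_prob
    mat = np.full((4, scheme.n_positions), p / 3.0)
    for j, base in enumerate(reference_flank):
        mat[_BASE_INDEX[base], j] = 1.0 - p
    assert np.allclose(mat.sum(axis=0), 1.0)
    return mat


def sample_tag(design: LocusDesign, rng: np.random.Generator) -> str:
    """Draw one tag from the flank-mutation model (masked positions kept intact)."""
    ref = design.reference_flank
    p = design.tag_scheme.per_position_mut_prob
    tag = list(ref)
    for i in range(len(ref)):
        if i in design.flank_mask:
            continue
        if rng.random() < p:
            tag[i] = rng.choice([b for b in BASES if b != ref[i]])
    return "".join(tag)


def assemble_template(design: LocusDesign, variant_label: str, tag: str) -> str:
    """Build the single-stranded oligo: arm + tagged flank + variant + tagged flank + arm."""
    if len(tag) != 2 * design.flank_len:
        raise ValueError(f"tag must be {2 * design.flank_len} nt, got {len(tag)}")
    a = design.amplicon_ref
    f, arm = design.flank_len, design.homology_arm_len
    left_arm = a[design.variant_start - f - arm : design.variant_start - f]
    right_arm = a[design.variant_end + f : design.variant_end + f + arm]
    return left_arm + tag[:f] + design.center(variant_label) + tag[f:] + right_arm


def sample_template(
    design: LocusDesign, variant_label: str, rng_seed: int | np.random.Generator
) -> str:
    """Sample one full-length template with a stochastically mutated tag.

    Deterministic given the seed. Default E-box geometry (42-nt arms, 5-nt
    flanks, 6-nt variant) yields a 100-nt oligo.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return assemble_template(design, variant_label, sample_tag(design, rng))


@dataclass(frozen=True)
class CodonTagSpec:
    """Degenerate-codon tag design for a coding-region target.

    ``coding_context`` is in frame; ``experimental_variants`` replace the
    region [variant_start, variant_start + replacement length); tags come
    from randomizing ``degenerate_positions`` (typically third codon
    positions) over their synonymous alternatives.
    """

    coding_context: str
    variant_start: int
    experimental_variants: tuple[tuple[str, str], ...]
    degenerate_positions: tuple[int, ...] = ()
    splice_exclusion: tuple[int, int] | None = None  # user-declared [start, end) to avoid

    def __post_init__(self) -> None:
        object.__setattr__(self, "coding_context", _check_dna(self.coding_context, "coding_context"))
        if len(self.coding_context) % 3:
            raise DesignError("coding_context must be a whole number of codons")
        if not self.experimental_variants:
            raise DesignError("at least one experimental variant is required")
        lens = {len(rep) for _, rep in self.experimental_variants}
        if len(lens) != 1:
            raise DesignError("all experimental variants must have equal length")
        (vlen,) = lens
        if self.variant_start < 0 or self.variant_start + vlen > len(self.coding_context):
            raise DesignError("variant region falls outside coding_context")
        vregion = range(self.variant_start, self.variant_start + vlen)
        for pos in self.degenerate_positions:
            if pos < 0 or pos >= len(self.coding_context):
                raise DesignError(f"degenerate position {pos} outside coding_context")
            if pos in vregion:
                raise DesignError(
                    f"degenerate position {pos} overlaps the experimental-variant region"
                )
            if not synonymous_alternatives(self.coding_context, pos):
                raise DesignError(
                    f"position {pos}: no synonymous alternative exists; randomizing it "
                    "would change the encoded amino acid"
                )
        if self.splice_exclusion is not None:
            lo, hi = self.splice_exclusion
            inside = [p for p in self.degenerate_positions if lo <= p < hi]
            if inside:
                warnings.warn(
                    f"degenerate positions {inside} fall inside the declared splice "
                    "exclusion interval; review the design",
                    stacklevel=2,
                )


def translate(dna: str) -> str:
    """Standard nuclear-code translation (thin wrapper for a uniform import)."""
    return str(Seq(dna).translate())


def synonymous_alternatives(coding: str, pos: int) -> list[str]:
    """Non-reference bases at ``pos`` that leave the encoded codon synonymous."""
    codon_start = 3 * (pos // 3)
    codon = coding[codon_start : codon_start + 3]
    aa = translate(codon)
    offset = pos - codon_start
    out = []
    for b in BASES:
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1 :]
        if translate(alt) == aa:
            out.append(b)
    return out


def enumerate_codon_tags(spec: CodonTagSpec) -> list[tuple[str, str]]:
    """All (variant_label, sequence) combinations of the degenerate positions.

    Output size is |variants| x product of per-position synonymous-base
    counts (reference base included). Every emitted sequence translates to
    the protein of its experimental variant.
    """
    per_pos_choices: list[list[str]] = []
    for pos in sorted(spec.degenerate_positions):
        codon_start = 3 * (pos // 3)
        ref_base = spec.coding_context[pos]
        per_pos_choices.append([ref_base] + synonymous_alternatives(spec.coding_context, pos))
    positions = sorted(spec.degenerate_positions)

    out: list[tuple[str, str]] = []
    for label, replacement in spec.experimental_variants:
        base_seq = (
            spec.coding_context[: spec.variant_start]
            + replacement
            + spec.coding_context[spec.variant_start + len(replacement) :]
        )
        expected_protein = translate(base_seq)
        for combo in itertools.product(*per_pos_choices) if positions else [()]:
            seq = list(base_seq)
            for pos, b in zip(positions, combo):
                seq[pos] = b
            tagged = "".join(seq)
            if translate(tagged) != expected_protein:  # defence in depth
                raise DesignError(
                    f"degenerate combination at {positions} altered the protein"
                )
            out.append((label, tagged))
    return out
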