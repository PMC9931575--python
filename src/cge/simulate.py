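"""Synthetic competitive-genome-editing experiments with full ground truth.

The generative model follows the assay: a pool of cells is transfected;
each cell independently ends up unedited (WT), precision-repaired from the
template library (HDR, split 1:1 between the original-variant and
mutant-variant templates, each repair drawing a fresh sequence tag from the
binomial flank-mutation model), or repaired by end joining (NHEJ, modelled
as a small deletion at the cut site). Cells founding the same (variant,
tag) combination pool into one lineage. Lineages then grow independently
and exponentially, with a per-day log-growth deficit (or advantage)
attached to mutant-variant lineages and optional Gaussian per-lineage rate
noise. Amplicon sequencing of a sample is a multinomial draw of reads from
the lineage abundances at that day, followed by iid per-base substitution
errors.

The headline generative identity: with per-day effect delta measured
between baseline day b and endpoint day e, the downstream median log2 fold
change converges to (e - b) * delta / ln 2 as lineage count grows.

`simulate_count_tables` is a count-level fast path (no read sequences, no
sequencing error) for statistical calibration at many-locus scale.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .design import BASES, LocusDesign, TagScheme
from .extract import TagCountTable

_ALTS = {b: [c for c in BASES if c != b] for b in BASES}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated locus experiment."""

    design: LocusDesign
    n_cells_transfected: int = 30_000
    outcome_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)  # (WT, HDR, NHEJ)
    fitness_effect: float = 0.0  # per-day log-growth difference, mutant vs original
    baseline_day: float = 2.0
    endpoint_day: float = 8.0
    read_depths: dict = field(
        default_factory=lambda: {"baseline": 1_000_000, "endpoint": 1_000_000}
    )
    seq_error_rate: float = 0.001
    base_growth_rate: float = 0.0
    lineage_rate_sd: float = 0.05  # per-day Gaussian rate noise, per lineage
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.outcome_probs) - 1.0) > 1e-9 or min(self.outcome_probs) < 0:
            raise ValueError("outcome_probs must be non-negative and sum to 1")
        if self.endpoint_day <= self.baseline_day:
            raise ValueError("endpoint_day must exceed baseline_day")
        if any(d <= 0 for d in self.read_depths.values()):
            raise ValueError("read depths must be positive")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must lie in [0, 1)")


@dataclass
class Lineage:
    """One independently growing cell lineage and its amplicon allele."""

    lineage_id: int
    category: str  # WT | HDR_original | HDR_mutant | NHEJ
    variant: str | None  # original | mutant | None
    tag: str | None
    founders: int
    growth_rate: float
    template: str


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated reads."""

    lineages: list[Lineage]
    abundances: dict  # day label -> np.ndarray over lineages
    read_counts: dict  # sample label -> np.ndarray over lineages
    outcome_counts: dict  # category -> founding cell count
    config_echo: dict

    def expected_log2fc(self, cfg: SimConfig) -> float:
        """The generative identity for the downstream median log2 fold change."""
        return (cfg.endpoint_day - cfg.baseline_day) * cfg.fitness_effect / np.log(2)


def _sample_tags(design: LocusDesign, n: int, rng: np.random.Generator) -> list[str]:
    """Vectorized draw of n tags from the binomial flank-mutation model."""
    ref = design.reference_flank
    L = len(ref)
    p = design.tag_scheme.per_position_mut_prob
    mut = rng.random((n, L)) < p
    if design.flank_mask:
        mut[:, list(design.flank_mask)] = False
    which = rng.integers(0, 3, size=(n, L))
    tags = []
    ref_list = list(ref)
    for i in range(n):
        row = mut[i]
        if not row.any():
            tags.append(ref)
            continue
        t = ref_list.copy()
        for j in np.flatnonzero(row):
            t[j] = _ALTS[ref[j]][which[i, j]]
        tags.append("".join(t))
    return tags


def _hdr_template_in_amplicon(design: LocusDesign, variant: str, tag: str) -> str:
    """The full amplicon sequence carried by an HDR-repaired chromosome."""
    a = design.amplicon_ref
    f = design.flank_len
    return (
        a[: design.variant_start - f]
        + tag[:f]
        + design.center(variant)
        + tag[f:]
        + a[design.variant_end + f :]
    )


def _nhej_allele(design: LocusDesign, deletion_len: int) -> str:
    """Placeholder end-joining allele: deletion centred on the cut site.

    Not a biological indel spectrum — just enough structure that the read
    matches neither the wild-type nor any template pattern.
    """
    cut = design.variant_start + len(design.original_seq) // 2
    start = max(0, cut - deletion_len // 2)
    return design.amplicon_ref[:start] + design.amplicon_ref[start + deletion_len :]


def found_lineages(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[Lineage], dict]:
    """Draw per-cell editing outcomes and pool cells into lineages."""
    n_wt, n_hdr, n_nhej = rng.multinomial(cfg.n_cells_transfected, cfg.outcome_probs)
    design = cfg.design
    lineages: list[Lineage] = []
    next_id = 0

    def rate(is_mutant: bool) -> float:
        r = cfg.base_growth_rate + (cfg.fitness_effect if is_mutant else 0.0)
        if cfg.lineage_rate_sd > 0:
            r += rng.normal(0.0, cfg.lineage_rate_sd)
        return r

    if n_wt:
        lineages.append(
            Lineage(next_id, "WT", None, None, int(n_wt), rate(False), design.amplicon_ref)
        )
        next_id += 1

    # HDR: 1:1 template mixture, one fresh tag per repair event
    n_mut = rng.binomial(n_hdr, 0.5)
    for variant, n_cells in (("original", n_hdr - n_mut), ("mutant", n_mut)):
        pooled = Counter(_sample_tags(design, int(n_cells), rng))
        for tag, founders in sorted(pooled.items()):
            lineages.append(
                Lineage(
                    next_id,
                    f"HDR_{variant}",
                    variant,
                    tag,
                    founders,
                    rate(variant == "mutant"),
                    _hdr_template_in_amplicon(design, variant, tag),
                )
            )
            next_id += 1

    for _ in range(int(n_nhej)):
        dlen = int(rng.integers(1, 11))
        lineages.append(
            Lineage(next_id, "NHEJ", None, None, 1, rate(False), _nhej_allele(design, dlen))
        )
        next_id += 1

    outcome_counts = {"WT": int(n_wt), "HDR": int(n_hdr), "NHEJ": int(n_nhej)}
    return lineages, outcome_counts


def _abundances(lineages: list[Lineage], day: float) -> np.ndarray:
    founders = np.array([l.founders for l in lineages], dtype=float)
    rates = np.array([l.growth_rate for l in lineages])
    return founders * np.exp(rates * day)


def _emit_reads(
    lineages: list[Lineage],
    counts: np.ndarray,
    sample: str,
    error_rate: float,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Per-lineage read copies with iid substitution errors.

    Error model: the number of errors per read is Binomial(L, rate) with
    distinct uniform positions — exactly the iid per-base Bernoulli model.
    """
    reads: list[tuple[str, str]] = []
    for lin, n in zip(lineages, counts):
        n = int(n)
        if n == 0:
            continue
        template = lin.template
        L = len(template)
        seqs = [template] * n
        if error_rate > 0:
            ks = rng.binomial(L, error_rate, size=n)
            for i in np.flatnonzero(ks):
                pos = rng.choice(L, size=int(ks[i]), replace=False)
                s = list(seqs[i])
                for j in pos:
                    s[j] = _ALTS[s[j]][rng.integers(0, 3)]
                seqs[i] = "".join(s)
        reads.extend(
            (f"{sample}|lin{lin.lineage_id}|r{i}", s) for i, s in enumerate(seqs)
        )
    return reads


def _write_fastq(path: Path, reads: list[tuple[str, str]]) -> None:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _config_echo(cfg: SimConfig) -> dict:
    echo = asdict(cfg)
    echo["design"] = {
        "locus_name": cfg.design.locus_name,
        "amplicon_ref": cfg.design.amplicon_ref,
        "variant_start": cfg.design.variant_start,
        "original_seq": cfg.design.original_seq,
        "mutant_seq": cfg.design.mutant_seq,
    }
    return echo


@dataclass
class SimResult:
    samples: dict  # sample label -> list[(read_id, sequence)]
    truth: SimTruth


def simulate_experiment(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Full fitness experiment: baseline and endpoint FASTQ samples + truth.

    Deterministic given ``cfg.rng_seed``. With ``outdir`` set, writes one
    FASTQ per sample, a truth TSV and a JSON config echo.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lineages, outcome_counts = found_lineages(cfg, rng)
    day_of = {"baseline": cfg.baseline_day, "endpoint": cfg.endpoint_day}
    abundances = {s: _abundances(lineages, d) for s, d in day_of.items()}

    samples: dict[str, list[tuple[str, str]]] = {}
    read_counts: dict[str, np.ndarray] = {}
    for sample, depth in cfg.read_depths.items():
        ab = abundances[sample]
        counts = rng.multinomial(int(depth), ab / ab.sum())
        read_counts[sample] = counts
        samples[sample] = _emit_reads(lineages, counts, sample, cfg.seq_error_rate, rng)

    truth = SimTruth(lineages, abundances, read_counts, outcome_counts, _config_echo(cfg))
    result = SimResult(samples, truth)
    if outdir is not None:
        write_sim_output(result, outdir)
    return result


def simulate_chip(
    cfg: SimConfig, binding_fold_change: float, outdir: str | Path | None = None
) -> SimResult:
    """ChIP experiment: input drawn from abundances, IP with mutant alleles
    re-weighted by ``binding_fold_change`` (0.25 = four-fold binding loss).

    Read depths are taken from ``cfg.read_depths`` keys 'input' and 'ip'
    (falling back to 'baseline'/'endpoint' depths if absent); both samples
    reflect the cell population at ``cfg.baseline_day``.
    """
    if binding_fold_change <= 0:
        raise ValueError("binding_fold_change must be positive")
    rng = np.random.default_rng(cfg.rng_seed)
    lineages, outcome_counts = found_lineages(cfg, rng)
    ab = _abundances(lineages, cfg.baseline_day)
    is_mut = np.array([l.category == "HDR_mutant" for l in lineages])
    ip_weights = ab * np.where(is_mut, binding_fold_change, 1.0)

    depths = {
        "input": cfg.read_depths.get("input", cfg.read_depths.get("baseline")),
        "ip": cfg.read_depths.get("ip", cfg.read_depths.get("endpoint")),
    }
    samples: dict[str, list[tuple[str, str]]] = {}
    read_counts: dict[str, np.ndarray] = {}
    for sample, weights in (("input", ab), ("ip", ip_weights)):
        depth = int(depths[sample])
        counts = rng.multinomial(depth, weights / weights.sum())
        read_counts[sample] = counts
        samples[sample] = _emit_reads(lineages, counts, sample, cfg.seq_error_rate, rng)

    truth = SimTruth(
        lineages, {"input": ab, "ip": ip_weights}, read_counts, outcome_counts,
        {**_config_echo(cfg), "binding_fold_change": binding_fold_change},
    )
    result = SimResult(samples, truth)
    if outdir is not None:
        write_sim_output(result, outdir)
    return result


def simulate_count_tables(
    cfg: SimConfig,
) -> tuple[TagCountTable, TagCountTable, SimTruth]:
    """Count-level fast path: tag count tables without read sequences.

    Identical lineage and multinomial sampling model, but reads are never
    materialised and sequencing error is not applied; intended for
    statistical calibration across many simulated loci.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lineages, outcome_counts = found_lineages(cfg, rng)
    day_of = {"baseline": cfg.baseline_day, "endpoint": cfg.endpoint_day}
    abundances = {s: _abundances(lineages, d) for s, d in day_of.items()}

    tables = {}
    read_counts = {}
    for sample in ("baseline", "endpoint"):
        depth = int(cfg.read_depths[sample])
        ab = abundances[sample]
        counts = rng.multinomial(depth, ab / ab.sum())
        read_counts[sample] = counts
        table = TagCountTable(sample_id=sample, locus_name=cfg.design.locus_name)
        table.total_reads_assigned = depth
        for lin, n in zip(lineages, counts):
            if lin.variant is not None and n > 0:
                table.counts[(lin.variant, lin.tag)] += int(n)
        tables[sample] = table

    truth = SimTruth(lineages, abundances, read_counts, outcome_counts, _config_echo(cfg))
    return tables["baseline"], tables["endpoint"], truth


def write_sim_output(result: SimResult, outdir: str | Path, gzip_fastq: bool = False) -> dict:
    """Write per-sample FASTQ, a lineage truth TSV and the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    for sample, reads in result.samples.items():
        p = outdir / f"{sample}{suffix}"
        _write_fastq(p, reads)
        paths[sample] = str(p)

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        samples = list(result.truth.read_counts)
        header = ["lineage_id", "category", "variant", "tag", "founders", "growth_rate"]
        header += [f"abundance_{s}" for s in result.truth.abundances]
        header += [f"reads_{s}" for s in samples]
        fh.write("\t".join(header) + "\n")
        for i, lin in enumerate(result.truth.lineages):
            row = [
                str(lin.lineage_id), lin.category, lin.variant or ".", lin.tag or ".",
                str(lin.founders), f"{lin.growth_rate:.6g}",
            ]
            row += [f"{result.truth.abundances[s][i]:.6g}" for s in result.truth.abundances]
            row += [str(int(result.truth.read_counts[s][i])) for s in samples]
            fh.write("\t".join(row) + "\n")
    paths["truth"] = str(truth_path)

    echo_path = outdir / "sim_config.json"
    with open(echo_path, "w") as fh:
        json.dump(result.truth.config_echo, fh, indent=2, default=str)
    paths["config"] = str(echo_path)
    return paths


def demo_locus(
    locus_name: str = "EBOX_DEMO",
    seed: int = 7,
    amplicon_len: int = 150,
    variant_start: int = 72,
    original_seq: str = "CACGTG",
    mutant_seq: str = "TATTTA",
    scheme: TagScheme | None = None,
) -> LocusDesign:
    """A synthetic E-box-style locus for examples and simulations.

    Draws a random amplicon that contains the original variant exactly once
    and the mutant variant not at all, so window extraction is unambiguous.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        arr = rng.integers(0, 4, size=amplicon_len)
        amplicon = "".join(BASES[i] for i in arr)
        amplicon = (
            amplicon[:variant_start]
            + original_seq
            + amplicon[variant_start + len(original_seq) :]
        )
        if amplicon.count(original_seq) == 1 and mutant_seq not in amplicon:
            return LocusDesign(
                locus_name=locus_name,
                amplicon_ref=amplicon,
                variant_start=variant_start,
                original_seq=original_seq,
                mutant_seq=mutant_seq,
                tag_scheme=scheme or TagScheme(),
            )
    raise RuntimeError("could not draw an unambiguous amplicon")
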