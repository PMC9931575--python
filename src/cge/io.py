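"""Config parsing, tabular output, run manifests, and the canonical pipelines.

A single YAML config describes the loci (amplicon, variant pair, tag
scheme) and the analysis thresholds; the two canonical pipelines bind the
stages together: fitness (count -> efficiency -> pair -> test -> bin) and
ChIP (count -> pair on input filter -> test). Every output directory gets
a manifest with the config hash, input checksums and per-stage row counts
so results stay traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .design import DesignError, LocusDesign, TagScheme
from .efficiency import efficiency_from_table
from .extract import (
    MAX_SUBS_EFFICIENCY,
    ConfigError,
    TagCountTable,
    count_tags,
    hamming,
    validate_designs,
)
from .stats import (
    DEFAULT_TAG_MUTATION_FILTER,
    DEFAULT_THRESHOLDS,
    chip_enrichment,
    fitness_test,
    internal_replicate_fitness,
    pair_lineages,
)

try:
    __version__ = version("cge")
except PackageNotFoundError:  # running from a source tree
    __version__ = "unknown"


@dataclass
class AnalysisSettings:
    """Thresholds of the paired analysis, with the assay defaults."""

    min_baseline_count: int = DEFAULT_THRESHOLDS["ebox"]
    min_input_count: int = DEFAULT_THRESHOLDS["chip_input"]
    tag_mutation_filter: tuple[int, ...] = DEFAULT_TAG_MUTATION_FILTER
    max_subs_pair: int = 2
    max_subs_efficiency: int = MAX_SUBS_EFFICIENCY
    binning_scheme: str = "first_position_parity"


@dataclass
class RunManifest:
    config_path: str
    config_sha256: str
    tool_version: str
    inputs: dict = field(default_factory=dict)  # path -> sha256
    seeds: dict = field(default_factory=dict)
    stage_rows: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _design_from_dict(d: dict) -> LocusDesign:
    scheme = TagScheme(**d["tag_scheme"]) if "tag_scheme" in d else TagScheme()
    kwargs = {k: v for k, v in d.items() if k != "tag_scheme"}
    if "flank_mask" in kwargs:
        kwargs["flank_mask"] = tuple(kwargs["flank_mask"])
    return LocusDesign(tag_scheme=scheme, **kwargs)


def validate_config(config_path: str | Path) -> tuple[list[LocusDesign], AnalysisSettings]:
    """Load and validate a YAML config; raise ConfigError listing all faults."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "loci" not in raw:
        raise ConfigError(f"{config_path}: config must contain a 'loci' list")
    designs, errors = [], []
    for entry in raw["loci"]:
        try:
            designs.append(_design_from_dict(entry))
        except (DesignError, TypeError, KeyError) as exc:
            errors.append(f"{entry.get('locus_name', '?')}: {exc}")
    if not errors:
        try:
            validate_designs(designs)
        except ConfigError as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))

    analysis = raw.get("analysis", {})
    if "tag_mutation_filter" in analysis:
        analysis["tag_mutation_filter"] = tuple(analysis["tag_mutation_filter"])
    return designs, AnalysisSettings(**analysis)


def counts_to_frame(tables: Sequence[TagCountTable], designs: Sequence[LocusDesign]) -> pd.DataFrame:
    """Flatten count tables to the long TSV layout (one row per variant/tag)."""
    flank = {d.locus_name: d.reference_flank for d in designs}
    rows = []
    for t in tables:
        for (variant, tag), count in sorted(t.counts.items()):
            rows.append(
                {
                    "sample": t.sample_id,
                    "locus": t.locus_name,
                    "variant": variant,
                    "tag": tag,
                    "n_mutations": hamming(tag, flank[t.locus_name]),
                    "count": count,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample", "locus", "variant", "tag", "n_mutations", "count"]
    )


def frame_to_tables(frame: pd.DataFrame) -> dict[tuple[str, str], TagCountTable]:
    """Rebuild count tables from the long TSV layout, keyed (sample, locus)."""
    tables: dict[tuple[str, str], TagCountTable] = {}
    for row in frame.itertuples():
        key = (row.sample, row.locus)
        if key not in tables:
            tables[key] = TagCountTable(sample_id=row.sample, locus_name=row.locus)
        t = tables[key]
        t.counts[(row.variant, row.tag)] += int(row.count)
        t.total_reads_assigned += int(row.count)
    return tables


def pairs_to_frame(records) -> pd.DataFrame:
    cols = [
        "locus", "tag", "n_flank_mutations",
        "count_orig_baseline", "count_mut_baseline",
        "count_orig_endpoint", "count_mut_endpoint", "log2fc",
    ]
    rows = [
        {
            "locus": r.locus_name, "tag": r.tag, "n_flank_mutations": r.n_flank_mutations,
            "count_orig_baseline": r.count_orig_baseline,
            "count_mut_baseline": r.count_mut_baseline,
            "count_orig_endpoint": r.count_orig_endpoint,
            "count_mut_endpoint": r.count_mut_endpoint,
            "log2fc": r.log2fc,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


def results_to_frame(results) -> pd.DataFrame:
    cols = ["locus", "group", "n_pairs", "median_log2fc", "p_value", "ci_low", "ci_high"]
    rows = [
        {
            "locus": r.locus_name, "group": r.group_label or "all", "n_pairs": r.n_pairs,
            "median_log2fc": r.median_log2fc, "p_value": r.p_value,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)


def _start_manifest(config_path, fastq_map) -> RunManifest:
    return RunManifest(
        config_path=str(config_path),
        config_sha256=_sha256(config_path),
        tool_version=__version__,
        inputs={role: _sha256(p) for role, p in fastq_map.items()},
    )


def run_fitness_pipeline(
    config_path: str | Path, fastq_map: dict[str, str], out_dir: str | Path
) -> pd.DataFrame:
    """count -> efficiency -> pair -> test -> bin, for every configured locus.

    ``fastq_map`` must provide the roles 'baseline' and 'endpoint' (day-2
    and day-8 gDNA). Writes counts.tsv, efficiency.tsv, pairs.tsv,
    summary.tsv, rejects.json and manifest.json; returns the summary frame.
    """
    for role in ("baseline", "endpoint"):
        if role not in fastq_map:
            raise ConfigError(f"fastq_map is missing the required sample role {role!r}")
    designs, settings = validate_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _start_manifest(config_path, fastq_map)

    tables: dict[str, dict[str, TagCountTable]] = {}
    for role in ("baseline", "endpoint"):
        tables[role] = count_tags(
            fastq_map[role], designs, sample_id=role, max_subs=settings.max_subs_efficiency
        )

    all_tables = [t for role in tables for t in tables[role].values()]
    counts = counts_to_frame(all_tables, designs)
    counts.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
    manifest.stage_rows["counts"] = len(counts)

    rejects = {
        f"{role}:{locus}": dict(t.reject_reasons)
        for role in tables
        for locus, t in tables[role].items()
    }
    with open(out_dir / "rejects.json", "w") as fh:
        json.dump(rejects, fh, indent=2)

    eff_rows, pair_frames, results = [], [], []
    for d in designs:
        for role in ("baseline", "endpoint"):
            eff_rows.append(efficiency_from_table(tables[role][d.locus_name], d).as_dict())
        records = pair_lineages(
            baseline=tables["baseline"][d.locus_name],
            endpoint=tables["endpoint"][d.locus_name],
            reference_flank=d.reference_flank,
            min_baseline_count=settings.min_baseline_count,
            tag_mutation_filter=settings.tag_mutation_filter,
        )
        pair_frames.append(pairs_to_frame(records))
        if records:
            results.append(
                fitness_test(
                    records,
                    filter_settings={
                        "min_baseline_count": settings.min_baseline_count,
                        "tag_mutation_filter": settings.tag_mutation_filter,
                    },
                    ci=True,
                )
            )
            results.extend(
                internal_replicate_fitness(records, settings.binning_scheme).values()
            )

    pd.DataFrame(eff_rows).to_csv(out_dir / "efficiency.tsv", sep="\t", index=False)
    pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames else pairs_to_frame([])
    pairs.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    summary = results_to_frame(results)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    manifest.stage_rows.update(
        {"efficiency": len(eff_rows), "pairs": len(pairs), "summary": len(summary)}
    )
    manifest.write(out_dir / "manifest.json")
    return summary


def run_chip_pipeline(
    config_path: str | Path, fastq_map: dict[str, str], out_dir: str | Path
) -> pd.DataFrame:
    """count -> pair (input filter) -> test for IP vs input samples."""
    for role in ("input", "ip"):
        if role not in fastq_map:
            raise ConfigError(f"fastq_map is missing the required sample role {role!r}")
    designs, settings = validate_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _start_manifest(config_path, fastq_map)

    tables = {
        role: count_tags(
            fastq_map[role], designs, sample_id=role, max_subs=settings.max_subs_efficiency
        )
        for role in ("input", "ip")
    }
    all_tables = [t for role in tables for t in tables[role].values()]
    counts = counts_to_frame(all_tables, designs)
    counts.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
    manifest.stage_rows["counts"] = len(counts)

    pair_frames, results = [], []
    for d in designs:
        records, result = chip_enrichment(
            ip=tables["ip"][d.locus_name],
            input_table=tables["input"][d.locus_name],
            reference_flank=d.reference_flank,
            min_input_count=settings.min_input_count,
            tag_mutation_filter=settings.tag_mutation_filter,
        )
        pair_frames.append(pairs_to_frame(records))
        results.append(result)

    pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames else pairs_to_frame([])
    pairs.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    summary = results_to_frame(results)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    manifest.stage_rows.update({"pairs": len(pairs), "summary": len(summary)})
    manifest.write(out_dir / "manifest.json")
    return summary
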