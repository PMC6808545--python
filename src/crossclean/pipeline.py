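"""End-to-end orchestration: pair screen -> thresholds -> classification ->
SSU validation -> completeness QC, with a reproducible run manifest.

Each stage is a pure function over files the previous stage (or the user)
wrote; no stage mutates its inputs, so reruns are idempotent.  The manifest
records every parameter, the SHA-256 digest of every input, and every file
written — rerunning with identical inputs yields identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import classify as _classify
from . import completeness as _completeness
from . import pairs as _pairs
from . import ssu as _ssu
from . import threshold as _threshold
from .formats import read_fasta, read_newick, read_sample_table, parse_tabular_hits, write_fasta

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A run configuration references missing inputs or bad parameters."""


def screen_scenario(
    samples,
    phylo,
    pair_hits,
    research_hits,
    libraries,
    *,
    bin_width: float = 1.0,
    min_peak_support: int = 5,
    smooth_window: int = 1,
    max_branches: int = 2,
    close_branches: int = 2,
    n_top: int = 3,
) -> dict:
    """Run the contamination screen on in-memory inputs.

    ``pair_hits`` maps :class:`~crossclean.pairs.PairKey` to that pair's hit
    rows; ``libraries`` maps library code to its transcript records.  Returns
    the per-stage results (eligible/excluded pairs, per-pair thresholds,
    candidates, per-library verdicts, summaries, matrix, pair list) without
    touching the filesystem — the same computation :func:`run_pipeline`
    performs over files.
    """
    eligible, excluded = _pairs.eligible_pairs(samples, phylo, max_branches)
    thresholds: dict = {}
    candidates: list[_threshold.Candidate] = []
    for pair in eligible:
        hits = pair_hits.get(pair, [])
        matches = _threshold.select_best_matches(hits, pair)
        hist = _threshold.build_histogram(matches, bin_width, pair=pair)
        th = _threshold.find_cutoff(hist, min_peak_support, smooth_window)
        thresholds[pair] = (th, len(matches))
        candidates.extend(_threshold.call_candidates(matches, th))
    verdict_map = _classify.classify_candidates(
        candidates, research_hits, samples, phylo,
        close_branches=close_branches, n_top=n_top,
    )
    verdicts_by_library = {
        code: _classify.assign_verdicts(
            records, {sid: v for sid, v in verdict_map.items() if v.sample == code}
        )
        for code, records in libraries.items()
    }
    summaries, matrix, pair_list = _classify.summarize_libraries(verdicts_by_library)
    return {
        "eligible_pairs": eligible,
        "excluded_pairs": excluded,
        "thresholds": thresholds,
        "candidates": candidates,
        "verdicts": verdicts_by_library,
        "summaries": summaries,
        "matrix": matrix,
        "pair_list": pair_list,
    }


@dataclass
class RunConfig:
    """Paths and parameters for one full pipeline run."""

    sample_table: Path
    outdir: Path
    tree: Path | None = None
    fasta_dir: Path | None = None
    hits_dir: Path | None = None
    research_hits: Path | None = None
    ssu_hits: Path | None = None
    ssu_lineage: Path | None = None
    ceg_counts: Path | None = None
    busco_summary: Path | None = None
    # threshold parameters
    bin_width: float = 1.0
    min_peak_support: int = 5
    smooth_window: int = 1
    # exclusion parameters
    max_branches: int = 2
    close_branches: int = 2
    n_top: int = 3
    # SSU parameters
    ssu_min_len: int = _ssu.DEFAULT_MIN_LEN
    ssu_max_evalue: float = _ssu.DEFAULT_MAX_EVALUE

    def __post_init__(self) -> None:
        for name in (
            "sample_table", "outdir", "tree", "fasta_dir", "hits_dir", "research_hits",
            "ssu_hits", "ssu_lineage", "ceg_counts", "busco_summary",
        ):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))

    def validate(self) -> None:
        """Fail fast, before any compute, on missing inputs."""
        for name in (
            "sample_table", "tree", "fasta_dir", "hits_dir", "research_hits",
            "ssu_hits", "ssu_lineage", "ceg_counts", "busco_summary",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input {name} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dictionary.

    Stages whose inputs are not configured are skipped.  Any stage error
    propagates with the stage name attached.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()
        },
        "inputs": {},
        "outputs": [],
    }

    def record_input(name: str, path: Path | None) -> None:
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def record_output(path: Path) -> None:
        manifest["outputs"].append(str(path))

    samples = read_sample_table(cfg.sample_table)
    record_input("sample_table", cfg.sample_table)
    phylo = None
    if cfg.tree is not None:
        phylo = read_newick(cfg.tree)
        record_input("tree", cfg.tree)

    results: dict = {"samples": samples}

    # ---- stage: pair screen -------------------------------------------------
    eligible, excluded = _pairs.eligible_pairs(samples, phylo, cfg.max_branches)
    excluded_path = outdir / "excluded_pairs.tsv"
    _pairs.write_excluded_pairs(excluded, excluded_path)
    record_output(excluded_path)
    results["eligible_pairs"] = eligible
    results["excluded_pairs"] = excluded

    # ---- stage: identity thresholds ----------------------------------------
    all_candidates: list[_threshold.Candidate] = []
    thresholds: list[tuple[_threshold.Threshold, int]] = []
    if cfg.hits_dir is not None:
        hist_dir = outdir / "histograms"
        hist_dir.mkdir(exist_ok=True)
        for pair in eligible:
            hits_path = Path(cfg.hits_dir) / f"{pair.a}__{pair.b}.tsv"
            if not hits_path.exists():
                logger.warning("no hit table for eligible pair %s-%s; skipped", pair.a, pair.b)
                continue
            record_input(f"hits:{pair.a}__{pair.b}", hits_path)
            hits = parse_tabular_hits(hits_path)
            matches = _threshold.select_best_matches(hits, pair)
            hist = _threshold.build_histogram(matches, cfg.bin_width, pair=pair)
            th = _threshold.find_cutoff(hist, cfg.min_peak_support, cfg.smooth_window)
            logger.info(
                "pair %s-%s: %d matches, status=%s cutoff=%s",
                pair.a, pair.b, len(matches), th.status, th.cutoff,
            )
            hist_path = hist_dir / f"{pair.a}__{pair.b}.hist.tsv"
            _threshold.write_histogram(hist, hist_path)
            record_output(hist_path)
            thresholds.append((th, len(matches)))
            all_candidates.extend(_threshold.call_candidates(matches, th))
        th_path = outdir / "thresholds.tsv"
        _threshold.write_threshold_report(thresholds, th_path)
        record_output(th_path)
    results["thresholds"] = thresholds
    results["candidates"] = all_candidates

    # ---- stage: classification + library splitting --------------------------
    if cfg.research_hits is not None and cfg.fasta_dir is not None:
        record_input("research_hits", cfg.research_hits)
        research = parse_tabular_hits(cfg.research_hits)
        verdict_map = _classify.classify_candidates(
            all_candidates, research, samples, phylo,
            close_branches=cfg.close_branches, n_top=cfg.n_top,
        )
        verdicts_by_library: dict[str, list] = {}
        split_dir = outdir / "split"
        split_dir.mkdir(exist_ok=True)
        for code in sorted(samples):
            fasta_path = Path(cfg.fasta_dir) / f"{code}.fasta"
            if not fasta_path.exists():
                logger.warning("no FASTA for library %s; skipped", code)
                continue
            record_input(f"fasta:{code}", fasta_path)
            records = read_fasta(fasta_path)
            own = {sid: v for sid, v in verdict_map.items() if v.sample == code}
            verdicts = _classify.assign_verdicts(records, own)
            verdicts_by_library[code] = verdicts
            clean, contam = _classify.split_library(records, verdicts)
            clean_path = split_dir / f"{code}.clean.fasta"
            contam_path = split_dir / f"{code}.contam.fasta"
            write_fasta(clean, clean_path)
            write_fasta(contam, contam_path)
            record_output(clean_path)
            record_output(contam_path)
        summaries, matrix, pair_list = _classify.summarize_libraries(verdicts_by_library)
        _classify.write_summary(summaries, outdir / "contamination_summary.tsv")
        _classify.write_pair_list(pair_list, outdir / "contaminant_pairs.tsv")
        _classify.write_matrix(matrix, outdir / "contamination_matrix.tsv")
        for name in ("contamination_summary.tsv", "contaminant_pairs.tsv", "contamination_matrix.tsv"):
            record_output(outdir / name)
        results["verdicts"] = verdicts_by_library
        results["summaries"] = summaries
        results["matrix"] = matrix
        results["pair_list"] = pair_list

    # ---- stage: SSU validation ----------------------------------------------
    if cfg.ssu_hits is not None and cfg.ssu_lineage is not None:
        record_input("ssu_hits", cfg.ssu_hits)
        record_input("ssu_lineage", cfg.ssu_lineage)
        lineages = _ssu.read_ref_lineages(cfg.ssu_lineage)
        raw = parse_tabular_hits(cfg.ssu_hits)
        annotated = _ssu.annotate_ssu_hits(raw, lineages)
        kept = _ssu.filter_ssu_hits(annotated, cfg.ssu_min_len, cfg.ssu_max_evalue)
        assignments = _ssu.assign_scaffolds(kept)
        validations = _ssu.validate_all(samples, assignments)
        sample_report = outdir / "ssu_validation.tsv"
        scaffold_report = outdir / "ssu_scaffolds.tsv"
        _ssu.write_validation_reports(validations, assignments, sample_report, scaffold_report)
        record_output(sample_report)
        record_output(scaffold_report)
        results["ssu_validations"] = validations

    # ---- stage: completeness QC ---------------------------------------------
    if cfg.ceg_counts is not None or cfg.busco_summary is not None:
        ceg_records = []
        busco_records = []
        if cfg.ceg_counts is not None:
            record_input("ceg_counts", cfg.ceg_counts)
            ceg_records = _completeness.read_ceg_counts(cfg.ceg_counts)
        if cfg.busco_summary is not None:
            record_input("busco_summary", cfg.busco_summary)
            busco_records = _completeness.read_busco_summary(cfg.busco_summary)
        table = _completeness.completeness_tables(ceg_records, busco_records)
        table_path = outdir / "completeness_percentiles.tsv"
        _completeness.write_completeness_table(table, table_path)
        record_output(table_path)
        results["completeness_table"] = table

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
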