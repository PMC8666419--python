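"""End-to-end orchestration: ingest -> binning -> consensus -> rates -> stats.

A run is described by a :class:`RunConfig` mapping condition labels
(1G+/1G-/uG+/uG- in the flight study) to replicate SAM files plus the
reference layout and all thresholds. Every threshold defaults to the
assay's value and is recorded, together with per-stage exclusion counts,
in the run manifest; a fixed seed governs the only stochastic step
(12-read subsampling for P_E) so reruns are byte-identical.
"""

from __future__ import annotations

import json
import time
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import build_bins, filter_bins, rebin_singletons
from .consensus import CallConfig, call_bin_errors
from .ingest import TemplateSpec, read_pairs
from .rates import (
    apply_oxidation_filter,
    context_rates,
    indel_rates,
    locus_totals,
    moving_average,
    per_locus_rates,
)
from .simulate import CONDITION_PRESETS, SimConfig, simulate_library
from .stats import (
    ComparisonResult,
    StatError,
    compare_conditions,
    condition_matrix,
    impute_and_median,
)

#: contrasts of interest: microgravity vs earth gravity, per enzyme variant
DEFAULT_CONTRASTS = (("1G+", "uG+"), ("1G-", "uG-"))


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    reference_fasta: str
    sam_files: dict[str, list[str]]  # condition -> replicate SAM paths
    primer_length: int = 24
    umi_length: int = 20
    window_length: int = 175
    pe_threshold: float = 1e-5
    min_reads_per_strand: int = 6
    min_bin_pairs: int = 6
    rebin_destination_min: int = 5
    strand_ratio_bounds: tuple[float, float] = (1.0 / 3.0, 3.0)
    ca_threshold: float = 5e-4
    context_window: int = 25
    max_pe_reads: int = 12
    template_forward: bool = True
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "strand_ratio_bounds" in data:
            data["strand_ratio_bounds"] = tuple(data["strand_ratio_bounds"])
        return cls(**data)

    def thresholds(self) -> dict:
        d = asdict(self)
        for k in ("reference_fasta", "sam_files", "out_dir"):
            d.pop(k)
        return d


@dataclass
class PipelineResult:
    """Bundle of every table the run produces, plus the manifest."""

    locus_table: pd.DataFrame  # oxidation-filtered per-locus rates
    raw_locus_table: pd.DataFrame  # pre-filter rates
    excluded_loci: dict[str, list[int]]
    comparisons: list[ComparisonResult]
    context2: pd.DataFrame
    context3: pd.DataFrame
    indel_table: pd.DataFrame
    profiles: dict[str, pd.DataFrame]  # condition -> moving-average profile
    gc_correlation: dict[str, float]
    manifest: dict
    calls: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


def _load_reference(path: str) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single reference sequence in {path}")
    return str(records[0].seq).upper()


def process_replicate(
    sam_path: str,
    spec: TemplateSpec,
    config: RunConfig,
    condition: str,
    replicate: str,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Ingest one SAM file and produce its call and rate tables."""
    obs = read_pairs(sam_path, spec, template_forward=config.template_forward)
    bins = build_bins(obs)
    bins, rebin_stats = rebin_singletons(obs, bins, destination_min=config.rebin_destination_min)
    bins, filter_stats = filter_bins(
        bins, min_pairs=config.min_bin_pairs, ratio_bounds=config.strand_ratio_bounds
    )
    call_cfg = CallConfig(
        pe_threshold=config.pe_threshold,
        min_reads_per_strand=config.min_reads_per_strand,
        max_pe_reads=config.max_pe_reads,
    )
    calls, call_stats = call_bin_errors(obs, bins, call_cfg, seed=np.random.default_rng(seed))
    table = per_locus_rates(calls, spec.window_length, condition, replicate)
    # read accounting: every SAM record is either part of a used pair or
    # tallied under exactly one exclusion reason
    accounted = 2 * obs.n_pairs + sum(obs.exclusions.values())
    stats = {
        "n_records": obs.n_records,
        "n_pairs_used": obs.n_pairs,
        "ingest_exclusions": dict(obs.exclusions),
        "accounting_balanced": accounted == obs.n_records,
        "rebin": dict(rebin_stats),
        "bin_filter": dict(filter_stats),
        "calls": dict(call_stats),
    }
    if not stats["accounting_balanced"]:
        raise RuntimeError(
            f"read accounting mismatch in {sam_path}: {accounted} != {obs.n_records}"
        )
    return calls, table, stats


def run(config: RunConfig, keep_calls: bool = False) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the result bundle."""
    t0 = time.time()
    reference = _load_reference(config.reference_fasta)
    spec = TemplateSpec.from_layout(
        reference, config.primer_length, config.umi_length, config.window_length
    )
    window_seq = reference[spec.window[0] : spec.window[1]]

    tables = []
    stage_stats: dict[str, dict] = {}
    all_calls: dict[tuple[str, str], pd.DataFrame] = {}
    rep_index = 0
    for condition, paths in config.sam_files.items():
        for r, sam_path in enumerate(paths):
            replicate = f"rep{r + 1}"
            calls, table, stats = process_replicate(
                sam_path, spec, config, condition, replicate, seed=[config.seed, rep_index]
            )
            rep_index += 1
            tables.append(table)
            stage_stats[f"{condition}/{replicate}"] = stats
            if keep_calls:
                all_calls[(condition, replicate)] = calls
    raw_table = pd.concat(tables, ignore_index=True)
    locus_table, excluded = apply_oxidation_filter(raw_table, config.ca_threshold)

    totals = locus_totals(locus_table, "substitution")
    matrices = {c: condition_matrix(totals, c) for c in config.sam_files}
    comparisons: list[ComparisonResult] = []
    for cx, cy in DEFAULT_CONTRASTS:
        if cx in matrices and cy in matrices:
            for paired in (True, False):
                try:
                    comparisons.append(compare_conditions(matrices[cx], matrices[cy], paired))
                except StatError:
                    pass

    profiles, gc_corr = {}, {}
    for cond, cm in matrices.items():
        med = impute_and_median(cm).medians
        vec = np.zeros(spec.window_length)
        vec[med.index.to_numpy()] = med.to_numpy()
        if spec.window_length >= config.context_window:
            prof, r = moving_average(vec, window_seq, config.context_window)
            profiles[cond] = prof
            gc_corr[cond] = r

    result = PipelineResult(
        locus_table=locus_table,
        raw_locus_table=raw_table,
        excluded_loci=excluded,
        comparisons=comparisons,
        context2=context_rates(locus_table, window_seq, 2),
        context3=context_rates(locus_table, window_seq, 3),
        indel_table=indel_rates(locus_table, window_seq),
        profiles=profiles,
        gc_correlation=gc_corr,
        manifest={
            "version": __version__,
            "seed": config.seed,
            "thresholds": config.thresholds(),
            "stages": stage_stats,
            "excluded_oxidation_loci": excluded,
            "runtime_s": round(time.time() - t0, 2),
        },
        calls=all_calls,
    )
    if config.out_dir:
        write_bundle(result, config.out_dir)
    return result


def comparisons_frame(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_x": [c.condition_x for c in comparisons],
            "condition_y": [c.condition_y for c in comparisons],
            "test": [c.test for c in comparisons],
            "n": [c.n for c in comparisons],
            "p": [c.p for c in comparisons],
            "mean_fold": [c.fold.mean_ratio for c in comparisons],
            "median_fold": [c.fold.median_ratio for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )


def write_bundle(result: PipelineResult, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.locus_table.to_csv(out / "locus_rates.tsv", sep="\t", index=False)
    result.raw_locus_table.to_csv(out / "locus_rates_unfiltered.tsv", sep="\t", index=False)
    comparisons_frame(result.comparisons).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    result.context2.to_csv(out / "dinucleotide_rates.tsv", sep="\t", index=False)
    result.context3.to_csv(out / "trinucleotide_rates.tsv", sep="\t", index=False)
    result.indel_table.to_csv(out / "indel_rates.tsv", sep="\t", index=False)
    for cond, prof in result.profiles.items():
        safe = cond.replace("+", "plus").replace("-", "minus")
        prof.to_csv(out / f"window_profile_{safe}.tsv", sep="\t", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(result.manifest)), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# simulation-driven study construction and self-test


def simulate_study(
    template: str,
    out_dir: str,
    conditions: dict[str, dict] | None = None,
    n_replicates: int = 3,
    n_molecules: int = 2000,
    seed: int = 0,
    **common,
) -> tuple[RunConfig, dict[tuple[str, str], "object"]]:
    """Simulate a multi-condition study and write its SAM/FASTA inputs.

    ``conditions`` maps condition labels to SimConfig overrides (rates,
    hotspots, ...); by default the four flight-study conditions with their
    preset rates are generated. Returns a ready RunConfig plus the truth
    tables keyed by (condition, replicate).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if conditions is None:
        conditions = {c: dict(p) for c, p in CONDITION_PRESETS.items()}
    sam_files: dict[str, list[str]] = {}
    truths = {}
    base = np.random.SeedSequence(seed)
    sub_seeds = iter(base.generate_state(len(conditions) * n_replicates * 4))
    ref_path = str(out / "reference.fasta")
    lib = None
    for cond, overrides in conditions.items():
        paths = []
        for r in range(n_replicates):
            cfg = SimConfig(
                template=template,
                n_molecules=n_molecules,
                condition=cond,
                seed=int(next(sub_seeds) % (2**31)),
                **{**common, **overrides},
            )
            lib = simulate_library(cfg)
            safe = cond.replace("+", "plus").replace("-", "minus")
            sam_path = str(out / f"{safe}_rep{r + 1}.sam")
            lib.write_sam(sam_path)
            paths.append(sam_path)
            truths[(cond, f"rep{r + 1}")] = lib.truth
        sam_files[cond] = paths
    lib.write_reference_fasta(ref_path)
    cfg = RunConfig(reference_fasta=ref_path, sam_files=sam_files, seed=seed)
    return cfg, truths


def truth_window_rate(truth, window: tuple[int, int], kind: str = "substitution") -> float:
    """Injected events per molecule-locus inside the analysis window."""
    w0, w1 = window
    events = truth.events
    if len(events) == 0:
        in_window = events
    else:
        in_window = events[
            (events["kind"] == kind) & (events["locus"] >= w0) & (events["locus"] < w1)
        ]
    covered = np.minimum(truth.molecules["product_length"].to_numpy(), w1) - w0
    covered = int(np.clip(covered, 0, None).sum())
    return len(in_window) / covered if covered else 0.0


def observed_rate(table: pd.DataFrame, condition: str, kinds: str = "substitution") -> tuple[float, int]:
    """Pooled rate over all replicates of one condition: summed expected
    errors of the event family / summed bin-locus coverage."""
    from .rates import DELETION_TYPES, INSERTION_TYPES, SUBSTITUTION_TYPES

    members = {
        "substitution": SUBSTITUTION_TYPES,
        "deletion": DELETION_TYPES,
        "insertion": INSERTION_TYPES,
    }[kinds]
    sub = table[table["condition"] == condition]
    cov = int(sub.groupby(["replicate", "locus"], observed=True)["coverage"].first().sum())
    s = float(sub[sub["type"].isin(members)]["sum_expected"].sum())
    return (s / cov if cov else float("nan")), cov


def selftest(
    seed: int = 0,
    n_molecules: int = 20000,
    out_dir: str | None = None,
    template: str | None = None,
    n_replicates: int = 3,
) -> dict:
    """Simulate the four study conditions at their preset rates and check
    that the pipeline recovers the injected substitution rates within
    3 Poisson standard deviations. Failures are reported, not raised."""
    import tempfile

    from ._template import DEFAULT_TEMPLATE

    template = template or DEFAULT_TEMPLATE
    with tempfile.TemporaryDirectory() as tmp:
        workdir = out_dir or tmp
        cfg, truths = simulate_study(
            template,
            workdir,
            n_replicates=n_replicates,
            n_molecules=n_molecules,
            seed=seed,
            product_length_mean=240.0,
            product_length_sd=8.0,
        )
        result = run(cfg)
        window = (
            cfg.primer_length + cfg.umi_length,
            cfg.primer_length + cfg.umi_length + cfg.window_length,
        )
        report: dict = {"conditions": {}, "passed": True, "manifest": result.manifest}
        for cond in cfg.sam_files:
            est, cov = observed_rate(result.locus_table, cond)
            injected = float(
                np.mean(
                    [
                        truth_window_rate(truths[(cond, f"rep{r + 1}")], window)
                        for r in range(n_replicates)
                    ]
                )
            )
            tol = 3.0 * np.sqrt(max(injected * cov, 1.0)) / cov if cov else float("inf")
            ok = abs(est - injected) <= tol
            report["conditions"][cond] = {
                "recovered_rate": est,
                "injected_rate": injected,
                "tolerance_3sd": float(tol),
                "n_bin_loci": cov,
                "ok": bool(ok),
            }
            report["passed"] &= ok
    return report
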