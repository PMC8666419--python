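"""Aggregation of error calls into rate tables.

The unit of observation is the molecule (one qualifying bin-locus
comparison), so every rate is a sum of expected errors |e - P_E| divided
by the number of qualifying comparisons at the locus. Tables are tidy
DataFrames carrying condition and replicate labels so the statistics
layer can pivot them; loci are 0-based within the analysis window.

The oxidation filter removes loci whose pooled C->A substitution rate
reaches the cutoff (5e-4 by default): oxidative 8-oxoguanine damage on the
polymerized strand shows up as C->A in reference orientation and would
otherwise masquerade as polymerase error at susceptible loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consensus import TYPE_LABELS

SUBSTITUTION_TYPES = [t for t in TYPE_LABELS if ">" in t]
DELETION_TYPES = [t for t in TYPE_LABELS if t.startswith("del:")]
INSERTION_TYPES = [t for t in TYPE_LABELS if t.startswith("ins:")]

PURINES = frozenset("AG")


def per_locus_rates(
    calls: pd.DataFrame,
    window_length: int,
    condition: str = "",
    replicate: str = "",
) -> pd.DataFrame:
    """Dense per-(locus, error type) rate table for one replicate.

    rate(locus, type) = sum of expected errors of that type / coverage,
    where coverage counts every qualifying base comparison at the locus
    (insertion calls are extra events at their anchor and do not add
    coverage). Loci with zero coverage are omitted.
    """
    base_calls = calls[~calls["is_insertion"]]
    coverage = np.zeros(window_length, dtype=np.int64)
    cov_counts = base_calls.groupby("locus", observed=True).size()
    coverage[cov_counts.index.to_numpy()] = cov_counts.to_numpy()

    sums = (
        calls[calls["type"] != "none"]
        .groupby(["locus", "type"], observed=False)["expected_error"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=[t for t in TYPE_LABELS if t != "none"], fill_value=0.0)
    )
    loci = np.nonzero(coverage)[0]
    sums = sums.reindex(index=loci, fill_value=0.0)
    tidy = sums.stack().rename("sum_expected").reset_index()
    tidy.columns = ["locus", "type", "sum_expected"]
    tidy["coverage"] = coverage[tidy["locus"].to_numpy()]
    tidy["rate"] = tidy["sum_expected"] / tidy["coverage"]
    tidy.insert(0, "replicate", replicate)
    tidy.insert(0, "condition", condition)
    return tidy


def locus_totals(table: pd.DataFrame, kinds: str = "substitution") -> pd.DataFrame:
    """Per-locus total rate over one event family, keeping labels."""
    members = {
        "substitution": SUBSTITUTION_TYPES,
        "deletion": DELETION_TYPES,
        "insertion": INSERTION_TYPES,
    }[kinds]
    sub = table[table["type"].isin(members)]
    out = (
        sub.groupby(["condition", "replicate", "locus"], observed=True)
        .agg(rate=("rate", "sum"), coverage=("coverage", "first"))
        .reset_index()
    )
    return out


def apply_oxidation_filter(
    table: pd.DataFrame,
    threshold: float = 5e-4,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Exclude C->A-inflated loci, per condition, pooled over replicates.

    A locus is excluded for a condition when its pooled C->A rate
    (summed expected errors / summed coverage across the condition's
    replicates) is >= ``threshold``. Returns the filtered table and the
    excluded loci per condition.
    """
    excluded: dict[str, list[int]] = {}
    keep_parts = []
    for cond, sub in table.groupby("condition", observed=True):
        ca = sub[sub["type"] == "C>A"].groupby("locus", observed=True).agg(
            s=("sum_expected", "sum"), c=("coverage", "sum")
        )
        bad = ca.index[(ca["s"] / ca["c"]) >= threshold].tolist()
        excluded[cond] = sorted(bad)
        keep_parts.append(sub[~sub["locus"].isin(bad)])
    return pd.concat(keep_parts, ignore_index=True) if keep_parts else table, excluded


def context_rates(table: pd.DataFrame, window_seq: str, k: int) -> pd.DataFrame:
    """Substitution rates grouped by k-nucleotide template context.

    Each k-mer occurrence starting at window locus l contributes the sum
    of the k per-locus total substitution rates (occurrences truncated by
    the window edge, or touching an excluded locus, are skipped). The
    anchor convention is "k-mer beginning at the locus", matching grouping
    by the identity of the first template base.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = locus_totals(table, "substitution")
    parts = []
    for (cond, rep), sub in totals.groupby(["condition", "replicate"], observed=True):
        rate_by_locus = dict(zip(sub["locus"], sub["rate"]))
        rows = []
        for start in range(len(window_seq) - k + 1):
            loci = range(start, start + k)
            if any(l not in rate_by_locus for l in loci):
                continue
            rows.append(
                (cond, rep, start, window_seq[start : start + k], sum(rate_by_locus[l] for l in loci))
            )
        parts.append(
            pd.DataFrame(rows, columns=["condition", "replicate", "start", "kmer", "rate"])
        )
    return pd.concat(parts, ignore_index=True)


def moving_average(
    rates: np.ndarray,
    window_seq: str,
    window: int = 25,
) -> tuple[pd.DataFrame, float]:
    """Sliding-window (step 1) mean error rate and its GC anticorrelation.

    ``rates`` is the per-locus rate vector aligned to ``window_seq``.
    Returns the window profile (start, mean rate, GC fraction) and the
    Pearson correlation between window means and window GC; NaN when
    either series has zero variance.
    """
    rates = np.asarray(rates, dtype=float)
    if window > len(rates) or len(rates) != len(window_seq):
        raise ValueError("window longer than region or misaligned sequence")
    kernel = np.ones(window) / window
    means = np.convolve(rates, kernel, mode="valid")
    is_gc = np.array([ch in "GC" for ch in window_seq], dtype=float)
    gc = np.convolve(is_gc, kernel, mode="valid")
    profile = pd.DataFrame(
        {"start": np.arange(len(means)), "mean_rate": means, "gc": gc}
    )
    if np.ptp(means) == 0 or np.ptp(gc) == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(means, gc)[0])
    return profile, r


def indel_rates(table: pd.DataFrame, window_seq: str) -> pd.DataFrame:
    """Deletion/insertion rates by event, base identity and 5' neighbour.

    Deletions of the base at locus l take window_seq[l-1] as the preceding
    nucleotide (locus 0 is skipped: its neighbour lies in the UMI);
    insertions after locus l take window_seq[l]. Rates are summed expected
    errors over summed coverage of the contributing loci.
    """
    rows = []
    for (cond, rep), sub in table.groupby(["condition", "replicate"], observed=True):
        cov = dict(zip(sub["locus"], sub["coverage"]))
        for event, types in (("deletion", DELETION_TYPES), ("insertion", INSERTION_TYPES)):
            ev = sub[sub["type"].isin(types)]
            for base in "ACGT":
                t = f"del:{base}" if event == "deletion" else f"ins:{base}"
                evb = ev[ev["type"] == t]
                by_prec: dict[str, list[float]] = {}
                cov_prec: dict[str, int] = {}
                for locus, s in zip(evb["locus"], evb["sum_expected"]):
                    if event == "deletion":
                        if locus == 0:
                            continue
                        prec = window_seq[locus - 1]
                    else:
                        prec = window_seq[locus]
                    by_prec.setdefault(prec, []).append(s)
                # coverage per preceding-nucleotide class: all loci of the
                # window whose event would carry that context and that base
                for locus in cov:
                    if event == "deletion":
                        if locus == 0 or window_seq[locus] != base:
                            continue
                        prec = window_seq[locus - 1]
                    else:
                        prec = window_seq[locus]
                    cov_prec[prec] = cov_prec.get(prec, 0) + cov[locus]
                for prec in sorted(set(by_prec) | set(cov_prec)):
                    s = float(np.sum(by_prec.get(prec, [])))
                    c = cov_prec.get(prec, 0)
                    rows.append(
                        (
                            cond,
                            rep,
                            event,
                            base,
                            prec,
                            "purine" if base in PURINES else "pyrimidine",
                            s,
                            c,
                            s / c if c else np.nan,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "replicate",
            "event",
            "base",
            "preceding",
            "base_class",
            "sum_expected",
            "coverage",
            "rate",
        ],
    )
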