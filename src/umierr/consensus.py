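"""Per-bin consensus calling and false-consensus probability.

For each retained UMI bin and each analysis-window locus, the template and
polymerized read stacks are collapsed to strict-majority consensus symbols
(base, or DEL for a deleted position); an error is called when the two
consensuses differ. Every call carries a false-consensus probability P_E:
the probability that incorrectly-called reads form a strict majority of
the stack, where read j is individually correct with probability
c_j = (1 - b_j)(1 - q_j) (b_j: probability the read is mis-binned via a
misread UMI; q_j = 10^(-Q_j/10): base-call error probability). Reads that
agree with the consensus are incorrect with probability 1 - c_j, reads
that disagree with probability c_j, and P_E sums the probability mass of
all majority-incorrect scenarios (a Poisson-binomial tail). Stacks deeper
than 12 reads are subsampled to 12 for the P_E computation only.

A call is retained when the combined two-strand probability
1 - (1 - P_E,t)(1 - P_E,p) is at or below the configured threshold
(1e-5 by default), and contributes the expected error |e - P_E|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codes import BASES, DEL, NOCOV, SYMBOLS, phred_to_prob
from .binning import UmiBin
from .ingest import PairObservations

# error-type labels: 0 none, 1-12 substitutions, 13-16 deletions, 17-20 insertions
TYPE_LABELS = ["none"]
_SUB_CODE = np.zeros((5, 5), dtype=np.int8)
for _x in range(4):
    for _y in range(4):
        if _x != _y:
            _SUB_CODE[_x, _y] = len(TYPE_LABELS)
            TYPE_LABELS.append(f"{BASES[_x]}>{BASES[_y]}")
for _x in range(4):
    _SUB_CODE[_x, DEL] = len(TYPE_LABELS)
    TYPE_LABELS.append(f"del:{BASES[_x]}")
_INS_CODE_BASE = len(TYPE_LABELS)
TYPE_LABELS += [f"ins:{b}" for b in BASES]


@dataclass
class CallConfig:
    """Thresholds governing error calling (defaults follow the assay)."""

    pe_threshold: float = 1e-5
    min_reads_per_strand: int = 6
    max_pe_reads: int = 12
    chunk_bins: int = 1024


@dataclass
class LocusStack:
    """Base observations of one strand class at one locus of one bin."""

    bases: np.ndarray  # int8 symbol codes (0-3 bases, 4 DEL)
    q: np.ndarray  # per-read base-call error probabilities
    b: np.ndarray  # per-read UMI mis-binning probabilities

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=np.int8)
        self.q = np.asarray(self.q, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.bases) == len(self.q) == len(self.b)):
            raise ValueError("stack vectors must have equal length")
        for v in (self.q, self.b):
            if ((v < 0) | (v > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ErrorCall:
    """Outcome of one bin-locus template/polymerized comparison."""

    bin_id: int
    locus: int
    e: int
    error_type: str
    p_e: float
    expected_error: float
    template_base: str
    polymerized_base: str
    depth_template: int
    depth_polymerized: int


def consensus_base(stack: LocusStack) -> int | None:
    """Strict-majority symbol (> m/2) or None when no symbol dominates."""
    if stack.m == 0:
        raise ValueError("empty stack")
    counts = np.bincount(stack.bases, minlength=5)
    top = int(counts.argmax())
    if 2 * counts[top] > stack.m:
        return top
    return None


def _majority_tail(p_incorrect: np.ndarray, threshold: float) -> float:
    """P(#incorrect > threshold) for independent Bernoulli(p_j) reads."""
    m = len(p_incorrect)
    dist = np.zeros(m + 1)
    dist[0] = 1.0
    for j, pj in enumerate(p_incorrect):
        dist[1 : j + 2] = dist[1 : j + 2] * (1 - pj) + dist[: j + 1] * pj
        dist[0] *= 1 - pj
    return float(dist[np.arange(m + 1) > threshold].sum())


def false_consensus_prob(
    stack: LocusStack,
    seed: int | np.random.Generator = 0,
    max_reads: int = 12,
    literal: bool = False,
) -> float:
    """Probability that the stack's strict-majority consensus is wrong.

    When the stack holds more than ``max_reads`` reads, a seeded uniform
    subsample of ``max_reads`` is used. With ``literal=True`` the
    alternative reading of the scenario sum is computed instead — the
    probability that *correct* calls form the majority — which is ~1 for
    clean stacks and is kept only for comparison.
    """
    cons = consensus_base(stack)
    if cons is None:
        raise ValueError("stack has no strict-majority consensus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e = (stack.bases != cons).astype(float)
    c = (1.0 - stack.b) * (1.0 - stack.q)
    m = stack.m
    if m > max_reads:
        idx = np.sort(rng.choice(m, size=max_reads, replace=False))
        e, c = e[idx], c[idx]
        m = max_reads
    p_incorrect = np.where(e == 1, c, 1.0 - c)
    if literal:
        return _majority_tail(1.0 - p_incorrect, m / 2.0)
    return _majority_tail(p_incorrect, m / 2.0)


def template_read_valid_mask(obs: PairObservations) -> np.ndarray:
    """True for pairs usable as template-strand evidence.

    A template read stack must match the pre-defined template sequence, so
    template pairs showing any mismatch, deletion or insertion inside the
    analysis window are excluded. Polymerized pairs are always True here.
    """
    refw = obs.spec.window_codes()
    mismatch = (obs.bases != refw[None, :]) & (obs.bases != NOCOV)
    bad = mismatch.any(axis=1)
    for i, ins in enumerate(obs.insertions):
        if ins:
            bad[i] = True
    return obs.strand_is_poly | ~bad


def validate_template_reads(b: UmiBin, obs: PairObservations) -> tuple[UmiBin, int]:
    """Drop template pairs that mismatch the reference inside the window.

    Returns the filtered bin and the number of excluded pairs; raises when
    no template pair survives (the bin is unusable).
    """
    valid = template_read_valid_mask(obs)
    keep = [i for i in b.members if valid[i]]
    n_excl = len(b.members) - len(keep)
    out = UmiBin(bin_id=b.bin_id, umi=b.umi, members=keep)
    poly = obs.strand_is_poly[keep]
    out.n_polymerized = int(poly.sum())
    out.n_template = len(keep) - out.n_polymerized
    if out.n_template == 0:
        raise ValueError(f"bin {b.bin_id} left without template reads")
    return out, n_excl


def call_errors(
    template_stack: LocusStack,
    polymerized_stack: LocusStack,
    bin_id: int = 0,
    locus: int = 0,
    config: CallConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> ErrorCall | None:
    """Compare the two strand consensuses at one locus of one bin.

    Returns None (the locus is skipped for this bin) when either stack is
    shallower than the per-strand minimum, lacks a strict consensus, or
    the combined P_E exceeds the retention threshold.
    """
    cfg = config or CallConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if template_stack.m < cfg.min_reads_per_strand or polymerized_stack.m < cfg.min_reads_per_strand:
        return None
    ct = consensus_base(template_stack)
    cp = consensus_base(polymerized_stack)
    if ct is None or cp is None:
        return None
    p_t = false_consensus_prob(template_stack, rng, cfg.max_pe_reads)
    p_p = false_consensus_prob(polymerized_stack, rng, cfg.max_pe_reads)
    p_e = 1.0 - (1.0 - p_t) * (1.0 - p_p)
    if p_e > cfg.pe_threshold:
        return None
    e = int(ct != cp)
    label = TYPE_LABELS[_SUB_CODE[ct, cp]] if ct != cp else "none"
    return ErrorCall(
        bin_id=bin_id,
        locus=locus,
        e=e,
        error_type=label,
        p_e=p_e,
        expected_error=abs(e - p_e),
        template_base=SYMBOLS[ct],
        polymerized_base=SYMBOLS[cp],
        depth_template=template_stack.m,
        depth_polymerized=polymerized_stack.m,
    )


def _stack_tensors(obs, members_by_bin, width):
    """Padded (bins x reads x loci) tensors for one strand of a bin chunk."""
    nb = len(members_by_bin)
    kmax = max((len(m) for m in members_by_bin), default=1)
    kmax = max(kmax, 1)
    bases = np.full((nb, kmax, width), NOCOV, dtype=np.int8)
    quals = np.zeros((nb, kmax, width), dtype=np.int8)
    bprob = np.zeros((nb, kmax), dtype=np.float64)
    for i, mem in enumerate(members_by_bin):
        if mem:
            bases[i, : len(mem)] = obs.bases[mem]
            quals[i, : len(mem)] = obs.quals[mem]
            bprob[i, : len(mem)] = obs.b[mem]
    return bases, quals, bprob


def _chunk_consensus(bases, quals, bprob, cfg, rng):
    """Consensus, depth and P_E for every (bin, locus) of one strand chunk."""
    covered = bases != NOCOV
    m = covered.sum(axis=1)  # (nb, W)
    counts = np.stack([((bases == s) & covered).sum(axis=1) for s in range(5)], axis=1)
    cons = counts.argmax(axis=1).astype(np.int8)  # (nb, W)
    top = counts.max(axis=1)
    strict = 2 * top > m  # no-call where False (including m == 0)

    e = (bases != cons[:, None, :]) & covered
    q = phred_to_prob(quals)
    c = (1.0 - bprob[:, :, None]) * (1.0 - q)
    p_inc = np.where(e, c, 1.0 - c)
    p_inc[~covered] = 0.0

    m_eff = np.minimum(m, cfg.max_pe_reads)
    if (m > cfg.max_pe_reads).any():
        # seeded uniform subsample of max_pe_reads reads per deep stack:
        # rank covered reads by a random key and keep the smallest ranks
        key = rng.random(bases.shape)
        key[~covered] = 2.0
        rank = np.argsort(np.argsort(key, axis=1, kind="stable"), axis=1, kind="stable")
        p_inc[rank >= cfg.max_pe_reads] = 0.0

    kmax = bases.shape[1]
    dist = np.zeros((bases.shape[0], kmax + 1, bases.shape[2]))
    dist[:, 0, :] = 1.0
    for j in range(kmax):
        pj = p_inc[:, j, :][:, None, :]
        old = dist
        dist = old * (1.0 - pj)
        dist[:, 1:, :] += old[:, :-1, :] * pj
    ks = np.arange(kmax + 1)
    majority = ks[None, :, None] > m_eff[:, None, :] / 2.0
    p_e = (dist * majority).sum(axis=1)
    return cons, strict, m, p_e


def _insertion_calls(obs, b, t_members, p_members, cfg, rng, refw):
    """Strict-majority insertion calls for one bin (sparse, python path)."""
    anchors = set()
    for i in p_members:
        anchors.update(obs.insertions[i].keys())
    out = []
    for anchor in sorted(anchors):
        if anchor + 1 >= obs.bases.shape[1]:
            continue
        rows = []
        for strand, members in (("t", t_members), ("p", p_members)):
            status, qv, bv = [], [], []
            for i in members:
                ins = obs.insertions[i].get(anchor)
                if ins is not None:
                    status.append(1)
                    qv.append(ins[1])
                    bv.append(obs.b[i])
                elif obs.bases[i, anchor] != NOCOV and obs.bases[i, anchor + 1] != NOCOV:
                    status.append(0)
                    qv.append(obs.quals[i, anchor])
                    bv.append(obs.b[i])
            rows.append((np.array(status), np.array(qv, dtype=float), np.array(bv)))
        (st_t, q_t, b_t), (st_p, q_p, b_p) = rows
        if len(st_t) < cfg.min_reads_per_strand or len(st_p) < cfg.min_reads_per_strand:
            continue
        if st_t.sum() * 2 >= len(st_t):  # template must call "no insertion"
            continue
        n_present = int(st_p.sum())
        if 2 * n_present <= len(st_p):
            continue  # polymerized consensus: no insertion -> nothing to call
        p_parts = []
        for st, qs, bs in ((st_t, q_t, b_t), (st_p, q_p, b_p)):
            cons_status = 1 if 2 * st.sum() > len(st) else 0
            e = (st != cons_status).astype(float)
            c = (1.0 - bs) * (1.0 - phred_to_prob(qs))
            p_incor = np.where(e == 1, c, 1.0 - c)
            mm = len(st)
            if mm > cfg.max_pe_reads:
                idx = np.sort(rng.choice(mm, cfg.max_pe_reads, replace=False))
                p_incor = p_incor[idx]
                mm = cfg.max_pe_reads
            p_parts.append(_majority_tail(p_incor, mm / 2.0))
        p_e = 1.0 - (1.0 - p_parts[0]) * (1.0 - p_parts[1])
        if p_e > cfg.pe_threshold:
            continue
        # inserted base: majority among present reads
        bases_present = [
            obs.insertions[i][anchor][0] for i in p_members if anchor in obs.insertions[i]
        ]
        base = int(np.bincount(bases_present, minlength=4).argmax())
        out.append(
            (b.bin_id, anchor, 1, _INS_CODE_BASE + base, p_e, 1.0 - p_e, len(st_t), len(st_p), 1)
        )
    return out


def call_bin_errors(
    obs: PairObservations,
    bins: list[UmiBin],
    config: CallConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, Counter]:
    """Error calls for every qualifying (bin, locus) of the analysis window.

    Returns the flat call table (one row per retained comparison, plus
    insertion rows flagged ``is_insertion``) and per-stage exclusion
    counts. Column ``locus`` is 0-based within the analysis window.
    """
    cfg = config or CallConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats: Counter = Counter()
    width = obs.spec.window_length
    refw = obs.spec.window_codes()

    valid = template_read_valid_mask(obs)
    usable: list[tuple[UmiBin, list[int], list[int]]] = []
    for b in bins:
        t_mem = [i for i in b.members if not obs.strand_is_poly[i] and valid[i]]
        p_mem = [i for i in b.members if obs.strand_is_poly[i]]
        stats["template_reads_excluded"] += (b.size - len(p_mem)) - len(t_mem)
        if not t_mem:
            stats["bins_without_valid_template"] += 1
            continue
        usable.append((b, t_mem, p_mem))

    frames = []
    for start in range(0, len(usable), cfg.chunk_bins):
        chunk = usable[start : start + cfg.chunk_bins]
        bin_ids = np.array([b.bin_id for b, _, _ in chunk])
        res = {}
        for strand, idx in (("t", 1), ("p", 2)):
            members = [mem[idx] for mem in [(None, t, p) for _, t, p in chunk]]
            bases, quals, bprob = _stack_tensors(obs, members, width)
            res[strand] = _chunk_consensus(bases, quals, bprob, cfg, rng)
        cons_t, strict_t, m_t, pe_t = res["t"]
        cons_p, strict_p, m_p, pe_p = res["p"]

        deep = (m_t >= cfg.min_reads_per_strand) & (m_p >= cfg.min_reads_per_strand)
        callable_ = deep & strict_t & strict_p
        stats["locus_skipped_depth"] += int((~deep).sum())
        stats["locus_skipped_no_consensus"] += int((deep & ~callable_).sum())
        p_e = 1.0 - (1.0 - pe_t) * (1.0 - pe_p)
        retained = callable_ & (p_e <= cfg.pe_threshold)
        stats["locus_skipped_pe_threshold"] += int((callable_ & ~retained).sum())

        bi, li = np.nonzero(retained)
        e = (cons_t[bi, li] != cons_p[bi, li]).astype(np.int8)
        tcode = _SUB_CODE[cons_t[bi, li], cons_p[bi, li]]
        tcode[e == 0] = 0
        pe_sel = p_e[bi, li]
        frames.append(
            pd.DataFrame(
                {
                    "bin_id": bin_ids[bi],
                    "locus": li.astype(np.int32),
                    "e": e,
                    "type_code": tcode,
                    "p_e": pe_sel,
                    "expected_error": np.abs(e - pe_sel),
                    "depth_template": m_t[bi, li].astype(np.int32),
                    "depth_polymerized": m_p[bi, li].astype(np.int32),
                    "is_insertion": np.zeros(len(bi), dtype=bool),
                }
            )
        )

        ins_rows = []
        for b, t_mem, p_mem in chunk:
            if any(obs.insertions[i] for i in p_mem):
                ins_rows.extend(_insertion_calls(obs, b, t_mem, p_mem, cfg, rng, refw))
        if ins_rows:
            arr = np.array(ins_rows, dtype=float)
            frames.append(
                pd.DataFrame(
                    {
                        "bin_id": arr[:, 0].astype(np.int64),
                        "locus": arr[:, 1].astype(np.int32),
                        "e": arr[:, 2].astype(np.int8),
                        "type_code": arr[:, 3].astype(np.int8),
                        "p_e": arr[:, 4],
                        "expected_error": arr[:, 5],
                        "depth_template": arr[:, 6].astype(np.int32),
                        "depth_polymerized": arr[:, 7].astype(np.int32),
                        "is_insertion": arr[:, 8].astype(bool),
                    }
                )
            )

    if frames:
        calls = pd.concat(frames, ignore_index=True)
    else:
        calls = pd.DataFrame(
            {
                "bin_id": pd.Series(dtype=np.int64),
                "locus": pd.Series(dtype=np.int32),
                "e": pd.Series(dtype=np.int8),
                "type_code": pd.Series(dtype=np.int8),
                "p_e": pd.Series(dtype=float),
                "expected_error": pd.Series(dtype=float),
                "depth_template": pd.Series(dtype=np.int32),
                "depth_polymerized": pd.Series(dtype=np.int32),
                "is_insertion": pd.Series(dtype=bool),
            }
        )
    calls["type"] = pd.Categorical.from_codes(calls["type_code"], categories=TYPE_LABELS)
    stats["calls_retained"] = len(calls)
    return calls, stats
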