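"""SAM ingest: strand classification, UMI extraction, window observations.

Each properly-paired read mate-pair represents one strand of one original
duplex: the synthetic template strand or the newly polymerized strand.
With the reference written in template orientation, template-strand pairs
align with their first-in-pair read forward and polymerized-strand pairs
with it reverse-complemented; the convention is configurable because it is
a property of the library layout, not of the method.

For every usable pair the reader extracts (i) the 20-nt UMI with its
misidentification probability P = 1 - prod(1 - 10^(-Qi/10)) and (ii) the
base observed at every analysis-window position, with its Phred score.
Deleted reference positions are recorded with a dedicated DEL symbol and
insertions are kept as sparse (anchor locus, base, quality) observations.
All coordinates are 0-based half-open; reads whose pair cannot be used are
excluded and tallied by reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._codes import NOCOV, _ENCODE, decode, phred_to_prob

TEMPLATE = "template"
POLYMERIZED = "polymerized"


class UmiExtractionError(ValueError):
    """Alignment does not usably cover the UMI interval."""


@dataclass(frozen=True)
class TemplateSpec:
    """Reference layout: primer site, UMI, and analysis window.

    The analysis window is the stretch of reference positions immediately
    following the UMI over which errors are called (175 by default — the
    region with dependable coverage given ~200-bp products).
    """

    reference: str
    primer: tuple[int, int]
    umi: tuple[int, int]
    window: tuple[int, int]

    def __post_init__(self) -> None:
        p, u, w = self.primer, self.umi, self.window
        if not (0 <= p[0] < p[1] <= u[0] < u[1] <= w[0] < w[1]):
            raise ValueError("intervals must be ordered primer -> UMI -> window and disjoint")
        if w[1] > len(self.reference):
            raise ValueError("analysis window extends past the reference")

    @classmethod
    def from_layout(
        cls,
        reference: str,
        primer_length: int = 24,
        umi_length: int = 20,
        window_length: int = 175,
    ) -> "TemplateSpec":
        u0 = primer_length
        u1 = u0 + umi_length
        return cls(reference.upper(), (0, primer_length), (u0, u1), (u1, u1 + window_length))

    @property
    def umi_length(self) -> int:
        return self.umi[1] - self.umi[0]

    @property
    def window_length(self) -> int:
        return self.window[1] - self.window[0]

    def window_codes(self) -> np.ndarray:
        from ._codes import encode

        return encode(self.reference[self.window[0] : self.window[1]])


@dataclass(frozen=True)
class UmiObservation:
    """A pair's observed UMI with its per-base scores and misid probability."""

    umi: str
    scores: np.ndarray
    p: float


def umi_misid_prob(scores, umi_length: int = 20) -> float:
    """Probability that at least one UMI base was miscalled:
    P = 1 - prod_i (1 - 10^(-Q_i/10))."""
    q = np.asarray(scores, dtype=float)
    if q.shape != (umi_length,):
        raise ValueError(f"expected {umi_length} scores, got {q.shape}")
    if (q < 0).any():
        raise ValueError("Phred scores must be >= 0")
    return float(1.0 - np.prod(1.0 - phred_to_prob(q)))


def classify_pair(
    r1: pysam.AlignedSegment,
    r2: pysam.AlignedSegment,
    template_forward: bool = True,
) -> tuple[str | None, str]:
    """Classify a mate-pair as template- or polymerized-strand.

    Returns (strand class, "ok") for a usable pair, else (None, reason).
    A usable pair is mapped, primary, and aligned in opposite orientations;
    the first-in-pair orientation decides the strand class.
    """
    for r in (r1, r2):
        if r.is_unmapped or r.mate_is_unmapped:
            return None, "unmapped"
        if r.is_secondary or r.is_supplementary:
            return None, "secondary"
    if r1.is_reverse == r2.is_reverse:
        return None, "discordant"
    first = r1 if r1.is_read1 else r2
    forward = not first.is_reverse
    if forward == template_forward:
        return TEMPLATE, "ok"
    return POLYMERIZED, "ok"


def _aligned_query_index(read: pysam.AlignedSegment, ref_lo: int, ref_hi: int):
    """Map reference positions [ref_lo, ref_hi) to query indices.

    Returns (qidx, has_indel): qidx[i] is the query offset observing
    ref_lo + i, or -1 for a deletion; positions outside the alignment stay
    -2. Soft-clipped bases never contribute.
    """
    span = ref_hi - ref_lo
    qidx = np.full(span, -2, dtype=np.int64)
    has_indel = False
    rpos = read.reference_start
    qpos = 0
    for op, n in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            lo = max(rpos, ref_lo)
            hi = min(rpos + n, ref_hi)
            if lo < hi:
                qidx[lo - ref_lo : hi - ref_lo] = qpos + (lo - rpos) + np.arange(hi - lo)
            rpos += n
            qpos += n
        elif op == 2:  # D
            lo = max(rpos, ref_lo)
            hi = min(rpos + n, ref_hi)
            if lo < hi:
                qidx[lo - ref_lo : hi - ref_lo] = -1
                has_indel = True
            rpos += n
        elif op == 1:  # I
            if ref_lo <= rpos - 1 < ref_hi:
                has_indel = True
            qpos += n
        elif op == 4:  # S
            qpos += n
        elif op == 3:  # N
            rpos += n
        # H/P consume nothing relevant
    return qidx, has_indel


def extract_umi(read: pysam.AlignedSegment, spec: TemplateSpec) -> UmiObservation:
    """The read bases aligned to the UMI interval, with their scores.

    Raises :class:`UmiExtractionError` when the alignment does not span the
    interval or has a deletion inside it.
    """
    lo, hi = spec.umi
    qidx, _ = _aligned_query_index(read, lo, hi)
    if (qidx < 0).any():
        raise UmiExtractionError(
            f"read {read.query_name} does not cleanly cover the UMI interval"
        )
    seq = np.frombuffer(read.query_sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[seq[qidx]]
    scores = np.asarray(read.query_qualities, dtype=np.int64)[qidx]
    return UmiObservation(decode(codes), scores, umi_misid_prob(scores, spec.umi_length))


@dataclass
class PairObservations:
    """Columnar per-pair observations over the analysis window."""

    spec: TemplateSpec
    umi_strings: list[str]
    strand_is_poly: np.ndarray  # bool (n,)
    b: np.ndarray  # (n,) UMI misidentification probability
    bases: np.ndarray  # (n, W) int8: 0-3 bases, 4 DEL, 5 not covered
    quals: np.ndarray  # (n, W) int8 Phred scores (0 where not covered)
    insertions: list[dict[int, tuple[int, int]]]  # per pair: anchor -> (base, Q)
    qnames: list[str]
    exclusions: Counter = field(default_factory=Counter)
    n_records: int = 0  # SAM records seen, for read accounting

    @property
    def n_pairs(self) -> int:
        return len(self.umi_strings)


def _read_window_obs(read: pysam.AlignedSegment, spec: TemplateSpec):
    """(bases, quals, insertions) for one read over the analysis window."""
    w0, w1 = spec.window
    span = w1 - w0
    bases = np.full(span, NOCOV, dtype=np.int8)
    quals = np.zeros(span, dtype=np.int8)
    ins: dict[int, tuple[int, int]] = {}
    if read.reference_start >= w1 or read.reference_end <= w0:
        return bases, quals, ins
    seq = np.frombuffer(read.query_sequence.encode("ascii"), dtype=np.uint8)
    q = np.asarray(read.query_qualities, dtype=np.int8)
    cigt = read.cigartuples
    if len(cigt) == 1 and cigt[0][0] in (0, 7, 8):
        # dominant fast path: a single match run
        rpos = read.reference_start
        lo, hi = max(rpos, w0), min(rpos + cigt[0][1], w1)
        if lo < hi:
            bases[lo - w0 : hi - w0] = _ENCODE[seq[lo - rpos : hi - rpos]]
            quals[lo - w0 : hi - w0] = q[lo - rpos : hi - rpos]
        return bases, quals, ins
    qidx, _ = _aligned_query_index(read, w0, w1)
    covered = qidx >= 0
    bases[covered] = _ENCODE[seq[qidx[covered]]]
    quals[covered] = q[qidx[covered]]
    bases[qidx == -1] = 4  # DEL
    # insertions anchored to the preceding reference position; deleted
    # positions have no base call of their own, so they borrow the quality
    # of the preceding (else following) read base
    rpos = read.reference_start
    qpos = 0
    for op, n in cigt:
        if op in (0, 7, 8):
            rpos += n
            qpos += n
        elif op == 2:
            lo, hi = max(rpos, w0), min(rpos + n, w1)
            if lo < hi:
                flank = q[qpos - 1] if qpos > 0 else q[min(qpos, len(q) - 1)]
                quals[lo - w0 : hi - w0] = flank
            rpos += n
        elif op == 1:
            anchor = rpos - 1
            if w0 <= anchor < w1 - 1 and n == 1:
                ins[anchor - w0] = (int(_ENCODE[seq[qpos]]), int(q[qpos]))
            qpos += n
        elif op == 4:
            qpos += n
        elif op == 3:
            rpos += n
    return bases, quals, ins


def read_pairs(
    sam_path: str,
    spec: TemplateSpec,
    template_forward: bool = True,
) -> PairObservations:
    """Parse a SAM/BAM file into per-pair window observations.

    Pairs are classified by orientation, their UMI is taken from whichever
    mate covers the UMI interval (first-in-pair preferred), and mate
    observations are merged with first-in-pair priority where they overlap.
    """
    exclusions: Counter = Counter()
    umi_strings: list[str] = []
    strand: list[bool] = []
    bvals: list[float] = []
    bases_rows: list[np.ndarray] = []
    quals_rows: list[np.ndarray] = []
    ins_rows: list[dict[int, tuple[int, int]]] = []
    qnames: list[str] = []

    pending: dict[str, pysam.AlignedSegment] = {}
    n_records = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for read in fh:
            n_records += 1
            if read.is_secondary or read.is_supplementary:
                exclusions["secondary"] += 1
                continue
            if read.is_unmapped:
                exclusions["unmapped"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            cls, reason = classify_pair(r1, r2, template_forward)
            if cls is None:
                exclusions[reason] += 2
                continue
            try:
                obs = extract_umi(r1, spec)
            except UmiExtractionError:
                try:
                    obs = extract_umi(r2, spec)
                except UmiExtractionError:
                    exclusions["umi_not_covered"] += 2
                    continue
            b1, q1, i1 = _read_window_obs(r1, spec)
            b2, q2, i2 = _read_window_obs(r2, spec)
            use2 = (b1 == NOCOV) & (b2 != NOCOV)
            b1[use2] = b2[use2]
            q1[use2] = q2[use2]
            merged_ins = dict(i2)
            merged_ins.update(i1)
            umi_strings.append(obs.umi)
            strand.append(cls == POLYMERIZED)
            bvals.append(obs.p)
            bases_rows.append(b1)
            quals_rows.append(q1)
            ins_rows.append(merged_ins)
            qnames.append(r1.query_name)
    if pending:
        exclusions["mate_missing"] += len(pending)
    if n_records == 0:
        raise ValueError(f"no reads in {sam_path}")

    span = spec.window_length
    return PairObservations(
        spec=spec,
        umi_strings=umi_strings,
        strand_is_poly=np.array(strand, dtype=bool),
        b=np.array(bvals, dtype=np.float64),
        bases=np.vstack(bases_rows) if bases_rows else np.empty((0, span), dtype=np.int8),
        quals=np.vstack(quals_rows) if quals_rows else np.empty((0, span), dtype=np.int8),
        insertions=ins_rows,
        qnames=qnames,
        exclusions=exclusions,
        n_records=n_records,
    )
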