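"""Candidate single-stranded template generation and secondary-structure screening.

A usable polymerisation template must avoid internal repeats and
reverse-complementary stretches that could fold into secondary structure or
misprime. The screen enforces two nested constraints: no shared (direct or
reverse-complement) stretch longer than ``max_match_long`` nucleotides with
both copies inside any ``window_long``-bp window, and none longer than
``max_match_short`` within any ``window_short``-bp window. Candidates are
additionally held to a target G+C fraction. Thermodynamic folding-energy
ranking is deliberately left to external tools; the hook here is purely
combinatorial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codes import encode, revcomp


@dataclass(frozen=True)
class ConstraintSpec:
    """Repeat/reverse-complementarity limits for template screening.

    A stretch of length L shared between two positions violates the screen
    when L exceeds the applicable limit and a sub-stretch of length
    ``limit + 1`` fits, at both of its occurrences, inside a single window
    of the applicable size.
    """

    max_match_long: int = 7
    window_long: int = 100
    max_match_short: int = 5
    window_short: int = 25
    gc_target: float = 0.50
    gc_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.max_match_short > self.max_match_long:
            raise ValueError("max_match_short must be <= max_match_long")
        if self.window_short > self.window_long:
            raise ValueError("window_short must be <= window_long")


@dataclass(frozen=True)
class Violation:
    """One maximal shared stretch that breaches a constraint."""

    kind: str  # "repeat" (direct) or "revcomp"
    pos_a: int
    pos_b: int
    length: int
    limit: str  # "short" or "long": tightest constraint breached

    def as_row(self) -> tuple:
        return (self.kind, self.pos_a, self.pos_b, self.length, self.limit)


@dataclass
class TemplateCandidate:
    sequence: str
    gc: float
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def gc_content(seq: str) -> float:
    codes = encode(seq)
    return float(np.mean((codes == 1) | (codes == 2)))


def _maximal_direct_matches(s: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal (i, j, L) with i < j, s[i:i+L] == s[j:j+L], L >= k."""
    n = len(s)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    out = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                # extend to the maximal match containing this seed
                a, b = i, j
                while a > 0 and b > 0 and s[a - 1] == s[b - 1]:
                    a -= 1
                    b -= 1
                length = k + (i - a)
                while a + length < n and b + length < n and s[a + length] == s[b + length]:
                    length += 1
                out.add((a, b, length))
    return sorted(out)


def _maximal_revcomp_matches(s: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal (i, j, L) with i <= j, s[i:i+L] == revcomp(s[j:j+L]).

    The pair is symmetric, so only i <= j is reported; the degenerate
    self-pair of a palindromic stretch (i == j) is included once.
    """
    n = len(s)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    out = set()
    for j in range(n - k + 1):
        kmer_rc = revcomp(s[j : j + k])
        for i in index.get(kmer_rc, ()):
            # maximal extension: growing right at i consumes left at j
            a, b = i, j  # a: left end of i-side, b: left end of j-side
            length = k
            while a + length < n and b > 0 and s[a + length] == comp[s[b - 1]]:
                length += 1
                b -= 1
            while a > 0 and b + length < n and s[a - 1] == comp[s[b + length]]:
                a -= 1
                length += 1
            lo, hi = min(a, b), max(a, b)
            out.add((lo, hi, length))
    return sorted(out)


def _breached_limit(i: int, j: int, length: int, kind: str, spec: ConstraintSpec) -> str | None:
    """Tightest constraint breached by a maximal match, or None."""
    for label, lmax, w in (
        ("short", spec.max_match_short, spec.window_short),
        ("long", spec.max_match_long, spec.window_long),
    ):
        lmin = lmax + 1
        if length < lmin:
            continue
        # check every sub-stretch of the minimal violating length
        for o in range(length - lmin + 1):
            if kind == "repeat":
                start_a, start_b = i + o, j + o
            else:
                # a sub-stretch at offset o on the i side pairs with the
                # mirrored offset on the j side
                start_a, start_b = i + o, j + (length - lmin - o)
            span = max(start_a, start_b) + lmin - min(start_a, start_b)
            if span <= w:
                return label
    return None


def screen_candidate(seq: str, spec: ConstraintSpec | None = None) -> list[Violation]:
    """Return every constraint violation in ``seq``, ordered by position."""
    spec = spec or ConstraintSpec()
    encode(seq)  # validates alphabet
    seed = spec.max_match_short + 1
    violations = []
    for kind, finder in (("repeat", _maximal_direct_matches), ("revcomp", _maximal_revcomp_matches)):
        for i, j, length in finder(seq, seed):
            limit = _breached_limit(i, j, length, kind, spec)
            if limit is not None:
                violations.append(Violation(kind, i, j, length, limit))
    violations.sort(key=lambda v: (v.pos_a, v.pos_b, v.kind, v.length))
    return violations


def _random_sequence(length: int, gc_target: float, rng: np.random.Generator) -> list[str]:
    n_gc = int(round(length * gc_target))
    bases = [rng.choice(["G", "C"]) for _ in range(n_gc)]
    bases += [rng.choice(["A", "T"]) for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return bases


def generate_candidates(
    n: int,
    length: int,
    spec: ConstraintSpec | None = None,
    seed: int = 0,
    max_tries: int = 200,
    repair_steps: int = 2000,
) -> list[TemplateCandidate]:
    """Generate ``n`` screened candidates of the requested length.

    Each attempt draws a composition-constrained random sequence and then
    hill-climbs: a base inside a violating stretch is swapped within its
    G/C or A/T class (preserving the G+C fraction exactly) and the swap is
    kept when the violation count does not increase. Raises RuntimeError
    when the retry budget is exhausted, which signals constraints that are
    unsatisfiable (or nearly so) at the requested length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or ConstraintSpec()
    rng = np.random.default_rng(seed)
    swap = {"A": "T", "T": "A", "G": "C", "C": "G"}
    out: list[TemplateCandidate] = []
    tries = 0
    while len(out) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not generate {n} passing candidates of length {length} "
                f"within {max_tries} attempts; constraints may be unsatisfiable"
            )
        tries += 1
        bases = _random_sequence(length, spec.gc_target, rng)
        seq = "".join(bases)
        violations = screen_candidate(seq, spec)
        for _ in range(repair_steps):
            if not violations:
                break
            v = violations[int(rng.integers(len(violations)))]
            side = int(rng.integers(2))
            start = v.pos_a if side == 0 else v.pos_b
            pos = start + int(rng.integers(v.length))
            trial = bases.copy()
            trial[pos] = swap[trial[pos]]
            trial_seq = "".join(trial)
            trial_violations = screen_candidate(trial_seq, spec)
            if len(trial_violations) <= len(violations):
                bases, seq, violations = trial, trial_seq, trial_violations
        gc = gc_content(seq)
        if not violations and abs(gc - spec.gc_target) <= spec.gc_tolerance + 1e-12:
            out.append(TemplateCandidate(seq, gc, violations))
    return out


def write_candidates_fasta(candidates: list[TemplateCandidate], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=f"candidate_{i}", description=f"gc={c.gc:.4f}")
        for i, c in enumerate(candidates)
    ]
    SeqIO.write(records, path, "fasta")


def write_violation_table(violations: list[Violation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tpos_a\tpos_b\tlength\tlimit\n")
        for v in violations:
            fh.write("\t".join(str(x) for x in v.as_row()) + "\n")
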