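"""Synthetic UMI-tagged amplicon libraries with a known error ground truth.

The generator emulates the polymerase-fidelity assay: each simulated
molecule is a single-stranded template carrying a random UMI downstream of
the primer site, copied once by a polymerase that commits substitution,
deletion and insertion errors at configurable per-base rates. The
resulting duplex (template strand + polymerized strand) is then "sequenced"
as a stack of paired-end reads per strand, each read carrying independent
Phred-scored sequencer miscalls. Oxidative G->T damage can be injected at
hotspot loci on the polymerized strand after polymerization, where it shows
up as C->A in reference orientation — an artifact, not a polymerase error,
and therefore absent from the polymerase truth table.

Outputs are aligned SAM records (the primary downstream path), raw FASTQ,
and a tab-separated truth table; identical seed and config give
byte-identical files.

Coordinate convention: the reference FASTA is the template strand written
in the direction of synthesis, so the primer site, the UMI and the analysis
window appear at ascending coordinates and polymerized-strand reads align
as reverse complements.
"""

from __future__ import annotations

import array
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from ._codes import A, C, DEL, SYMBOLS, complement_codes, decode, encode

_CHUNK = 2048  # fixed internal chunk size; part of the determinism contract

#: Median overall rates for the four study conditions: earth gravity (1G)
#: and parabolic-flight microgravity (uG), each with the proofreading
#: (exo+) and proofreading-deficient (exo-) Klenow fragment. Microgravity
#: rates apply the observed fold changes (1.1x substitutions exo+, 2.4x
#: exo-; 1.1x/1.5x deletions) to the earth-gravity baselines.
CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "1G+": {"substitution_rate": 2.07e-5, "deletion_rate": 2.82e-6},
    "uG+": {"substitution_rate": 2.28e-5, "deletion_rate": 3.10e-6},
    "1G-": {"substitution_rate": 3.68e-5, "deletion_rate": 3.16e-6},
    "uG-": {"substitution_rate": 8.83e-5, "deletion_rate": 4.74e-6},
}


def uniform_substitution_matrix(rate: float) -> np.ndarray:
    """4x4 matrix with total per-base substitution probability ``rate``,
    split uniformly over the three alternative bases."""
    m = np.full((4, 4), rate / 3.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing library (one replicate)."""

    template: str
    n_molecules: int
    umi_length: int = 20
    primer_length: int = 24
    product_length_mean: float = 200.0
    product_length_sd: float = 10.0
    depth_min: int = 6  # reads per molecule per strand, uniform inclusive
    depth_max: int = 14
    substitution_rate: float | np.ndarray = 0.0  # scalar or 4x4 matrix
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    oxo_hotspots: tuple[int, ...] = ()  # reference loci (must be C) damaged on the polymerized strand
    oxo_rate: float = 0.0
    phred_mean: float = 30.0
    phred_sd: float = 3.0
    read_length: int = 150
    reference_name: str = "template"
    condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = self.template.upper()
        self._template_codes = encode(self.template)
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        if len(self.template) < self.primer_length + self.umi_length + 1:
            raise ValueError("template shorter than primer site + UMI")
        m = self.substitution_matrix
        for name, r in (
            ("substitution", float(m.sum(axis=1).max())),
            ("deletion", self.deletion_rate),
            ("insertion", self.insertion_rate),
            ("oxidative damage", self.oxo_rate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} rate outside [0, 1]")
        for locus in self.oxo_hotspots:
            if self._template_codes[locus] != C:
                raise ValueError(
                    f"oxidative hotspot {locus} is not a C in the reference "
                    "(G on the polymerized strand)"
                )

    @property
    def substitution_matrix(self) -> np.ndarray:
        if np.isscalar(self.substitution_rate):
            return uniform_substitution_matrix(float(self.substitution_rate))
        m = np.array(self.substitution_rate, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("substitution rate must be a scalar or 4x4 matrix")
        m = m.copy()
        np.fill_diagonal(m, 0.0)
        return m

    @property
    def umi_start(self) -> int:
        return self.primer_length

    @property
    def umi_end(self) -> int:
        return self.primer_length + self.umi_length

    def rates_dict(self) -> dict[str, float]:
        return {
            "substitution_rate": float(self.substitution_matrix.sum(axis=1).mean()),
            "deletion_rate": float(self.deletion_rate),
            "insertion_rate": float(self.insertion_rate),
            "oxo_rate": float(self.oxo_rate),
        }


@dataclass
class TruthTable:
    """Ground truth: one row per molecule, one row per injected event.

    ``events`` holds polymerase errors only; oxidative damage is recorded
    separately in ``oxidation`` because it is an artifact of sample
    handling, not of polymerization.
    """

    molecules: pd.DataFrame  # molecule, umi, product_length, depth_template, depth_polymerized
    events: pd.DataFrame  # molecule, kind, locus, ref_base, alt_base
    oxidation: pd.DataFrame  # molecule, locus, ref_base, obs_base
    rates: dict[str, float] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# molecules\n")
            self.molecules.to_csv(fh, sep="\t", index=False)
            fh.write("# events\n")
            self.events.to_csv(fh, sep="\t", index=False)
            fh.write("# oxidation\n")
            self.oxidation.to_csv(fh, sep="\t", index=False)


def inject_oxidative_damage(
    strands: list[str],
    hotspots: tuple[int, ...] | list[int],
    per_strand_rate: float,
    rng: np.random.Generator | int = 0,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Convert G->T at hotspot loci of each strand with the given probability.

    ``strands`` are sequences in their own 5'->3' orientation and every
    hotspot locus must carry a G. Returns the damaged strands and the list
    of (strand index, locus) conversions, so callers can keep the events
    out of any polymerase truth table.
    """
    if not 0.0 <= per_strand_rate <= 1.0:
        raise ValueError("per_strand_rate outside [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for s in strands:
        for locus in hotspots:
            if s[locus] != "G":
                raise ValueError(f"hotspot locus {locus} is not a G")
    out, events = [], []
    for i, s in enumerate(strands):
        arr = list(s)
        for locus in hotspots:
            if rng.random() < per_strand_rate:
                arr[locus] = "T"
                events.append((i, locus))
        out.append("".join(arr))
    return out, events


class SimulatedLibrary:
    """Product of :func:`simulate_library`: truth plus deterministic writers.

    Molecule-level randomness (UMIs, product lengths, polymerase events,
    depths, oxidative damage) is drawn once at construction; read-level
    sequencer noise is regenerated from a derived seed inside each writer,
    so repeated or interleaved calls to :meth:`write_sam` and
    :meth:`write_fastq` describe exactly the same reads.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        n = cfg.n_molecules
        ref = cfg._template_codes
        tlen = len(ref)

        self.umis = rng.integers(0, 4, size=(n, cfg.umi_length), dtype=np.int8)
        lo = min(cfg.read_length, tlen)
        lengths = np.rint(rng.normal(cfg.product_length_mean, cfg.product_length_sd, n))
        self.lengths = np.clip(lengths, max(lo, cfg.umi_end + 1), tlen).astype(np.int64)
        self.depth_t = rng.integers(cfg.depth_min, cfg.depth_max + 1, n)
        self.depth_p = rng.integers(cfg.depth_min, cfg.depth_max + 1, n)

        lmax = int(self.lengths.max())
        # polymerized strand in reference orientation; the template strand is
        # the reference with the molecule's UMI substituted in. The UMI is
        # written before polymerase events are drawn: the UMI is itself
        # copied during polymerization and can acquire errors.
        poly = np.tile(ref[:lmax], (n, 1))
        poly[:, cfg.umi_start : cfg.umi_end] = self.umis
        covered = np.arange(lmax)[None, :] < self.lengths[:, None]
        synthesized = covered & (np.arange(lmax)[None, :] >= cfg.primer_length)

        events = {"molecule": [], "kind": [], "locus": [], "ref_base": [], "alt_base": []}

        # substitutions: event probability by template base, target drawn from
        # the conditional row of the rate matrix
        m = cfg.substitution_matrix
        row_tot = m.sum(axis=1)
        if row_tot.any():
            p_event = row_tot[poly]
            hit = (rng.random(poly.shape) < p_event) & synthesized
            mi, li = np.nonzero(hit)
            refb = poly[mi, li]
            cond = m[refb] / row_tot[refb][:, None]
            u = rng.random(len(mi))
            alt = (np.cumsum(cond, axis=1) < u[:, None]).sum(axis=1).astype(np.int8)
            poly[mi, li] = alt
            events["molecule"].extend(mi.tolist())
            events["kind"].extend(["substitution"] * len(mi))
            events["locus"].extend(li.tolist())
            events["ref_base"].extend(decode(refb))
            events["alt_base"].extend(decode(alt))

        if cfg.deletion_rate > 0:
            hit = (rng.random(poly.shape) < cfg.deletion_rate) & synthesized & (poly != DEL)
            mi, li = np.nonzero(hit)
            events["molecule"].extend(mi.tolist())
            events["kind"].extend(["deletion"] * len(mi))
            events["locus"].extend(li.tolist())
            events["ref_base"].extend(decode(poly[mi, li]) if len(li) else [])
            events["alt_base"].extend(["-"] * len(mi))
            poly[mi, li] = DEL

        self.insertions: dict[int, list[tuple[int, int]]] = {}
        if cfg.insertion_rate > 0:
            # insertion of a random base after the hit locus
            hit = (rng.random(poly.shape) < cfg.insertion_rate) & synthesized
            hit[:, -1] = False  # need a following position inside the product
            hit &= np.arange(lmax)[None, :] + 1 < self.lengths[:, None]
            mi, li = np.nonzero(hit)
            ins_base = rng.integers(0, 4, len(mi), dtype=np.int8)
            for mol, locus, b in zip(mi.tolist(), li.tolist(), ins_base.tolist()):
                self.insertions.setdefault(mol, []).append((locus, b))
            events["molecule"].extend(mi.tolist())
            events["kind"].extend(["insertion"] * len(mi))
            events["locus"].extend(li.tolist())
            events["ref_base"].extend(decode(poly[mi, li]) if len(li) else [])
            events["alt_base"].extend(decode(ins_base) if len(mi) else [])

        oxo = {"molecule": [], "locus": [], "ref_base": [], "obs_base": []}
        if cfg.oxo_rate > 0 and cfg.oxo_hotspots:
            # post-polymerization G->T on the polymerized strand: in reference
            # orientation the strand reads C at the hotspot and the damage is
            # observed as C->A
            for locus in cfg.oxo_hotspots:
                hit = (rng.random(n) < cfg.oxo_rate) & (self.lengths > locus) & (poly[:, locus] == C)
                mi = np.nonzero(hit)[0]
                poly[mi, locus] = A
                oxo["molecule"].extend(mi.tolist())
                oxo["locus"].extend([locus] * len(mi))
                oxo["ref_base"].extend(["C"] * len(mi))
                oxo["obs_base"].extend(["A"] * len(mi))

        self._poly = poly
        self._template_row = ref[:lmax]

        ev = pd.DataFrame(events)
        # events drawn per error process; order rows by molecule then locus
        if len(ev):
            ev = ev.sort_values(["molecule", "locus", "kind"], kind="stable").reset_index(drop=True)
        self.truth = TruthTable(
            molecules=pd.DataFrame(
                {
                    "molecule": np.arange(n),
                    "umi": [decode(u) for u in self.umis],
                    "product_length": self.lengths,
                    "depth_template": self.depth_t,
                    "depth_polymerized": self.depth_p,
                }
            ),
            events=ev,
            oxidation=pd.DataFrame(oxo),
            rates=cfg.rates_dict(),
        )

    def molecule_strands(self, i: int) -> tuple[str, str]:
        """(template strand, polymerized strand) of molecule ``i``, both in
        reference orientation; deleted bases are dropped, inserted bases
        included. With all error rates zero the two strings are equal,
        i.e. the physical polymerized strand is the exact reverse
        complement of its template."""
        cfg = self.config
        L = int(self.lengths[i])
        tmpl = self._template_row[:L].copy()
        tmpl[cfg.umi_start : cfg.umi_end] = self.umis[i]
        poly_codes = self._poly[i, :L]
        ins = dict()
        for anchor, base in self.insertions.get(i, []):
            ins[anchor] = base
        out = []
        for pos in range(L):
            if poly_codes[pos] != DEL:
                out.append(SYMBOLS[poly_codes[pos]])
            if pos in ins:
                out.append(SYMBOLS[ins[pos]])
        return decode(tmpl), "".join(out)

    # -- read streaming -------------------------------------------------

    def _iter_batches(self):
        """Yield deterministic batches of noisy read pairs.

        Each batch covers the pairs of one strand class for the molecules of
        one product length within one fixed-size molecule chunk; iteration
        order and random draw order depend only on config + seed.
        """
        cfg = self.config
        noise_rng = np.random.default_rng([cfg.seed, 1])
        for start in range(0, cfg.n_molecules, _CHUNK):
            mols = np.arange(start, min(start + _CHUNK, cfg.n_molecules))
            for length in np.unique(self.lengths[mols]):
                sel = mols[self.lengths[mols] == length]
                width = min(cfg.read_length, int(length))
                r2_start = int(length) - width
                for strand, depths in (("template", self.depth_t), ("polymerized", self.depth_p)):
                    pair_mols = np.repeat(sel, depths[sel])
                    pair_idx = np.concatenate([np.arange(d) for d in depths[sel]])
                    if strand == "template":
                        r1 = np.tile(self._template_row[:width], (len(pair_mols), 1))
                        r2 = np.tile(self._template_row[r2_start : r2_start + width], (len(pair_mols), 1))
                        # template reads carry the molecule's UMI, not the
                        # reference placeholder bases
                        for arr, off in ((r1, 0), (r2, r2_start)):
                            lo = max(cfg.umi_start, off)
                            hi = min(cfg.umi_end, off + width)
                            if lo < hi:
                                arr[:, lo - off : hi - off] = self.umis[
                                    pair_mols, lo - cfg.umi_start : hi - cfg.umi_start
                                ]
                    else:
                        r1 = self._poly[pair_mols, :width].copy()
                        r2 = self._poly[pair_mols, r2_start : r2_start + width].copy()
                    r1, q1 = self._apply_noise(r1, noise_rng)
                    r2, q2 = self._apply_noise(r2, noise_rng)
                    yield {
                        "mols": pair_mols,
                        "pair_idx": pair_idx,
                        "strand": strand,
                        "length": int(length),
                        "tail_start": r2_start,
                        "head": r1,
                        "head_q": q1,
                        "tail": r2,
                        "tail_q": q2,
                    }

    def _apply_noise(self, bases: np.ndarray, rng: np.random.Generator):
        cfg = self.config
        q = np.clip(
            np.rint(rng.normal(cfg.phred_mean, cfg.phred_sd, bases.shape)), 2, 41
        ).astype(np.int8)
        perr = np.power(10.0, -q / 10.0)
        miscall = (rng.random(bases.shape) < perr) & (bases < DEL)
        shift = rng.integers(1, 4, bases.shape, dtype=np.int8)
        bases = np.where(miscall, (bases + shift) % 4, bases).astype(np.int8)
        return bases, q

    def _read_fields(self, batch, row: int, slot: str, ins_rng):
        """SEQ codes, qual array and CIGAR for one read (reference orientation).

        ``slot`` selects the fragment end: "head" covers the reference
        interval starting at 0, "tail" the interval ending at the product
        length."""
        cfg = self.config
        bases = (batch["head"] if slot == "head" else batch["tail"])[row]
        quals = (batch["head_q"] if slot == "head" else batch["tail_q"])[row]
        start = 0 if slot == "head" else batch["tail_start"]
        mol = int(batch["mols"][row])
        ins_here = []
        if batch["strand"] == "polymerized" and mol in self.insertions:
            end = start + len(bases)
            ins_here = [
                (anchor, b)
                for anchor, b in self.insertions[mol]
                if start <= anchor and anchor + 1 < end
            ]
        has_del = bool((bases == DEL).any())
        if not has_del and not ins_here:
            return bases, quals, f"{len(bases)}M"
        seq_parts, qual_parts, cigar = [], [], []
        ins_at = {anchor - start: b for anchor, b in ins_here}

        def emit(op, n):
            if n:
                if cigar and cigar[-1][0] == op:
                    cigar[-1][1] += n
                else:
                    cigar.append([op, n])

        run = 0
        for off in range(len(bases)):
            if bases[off] == DEL:
                emit("M", run)
                run = 0
                emit("D", 1)
            else:
                seq_parts.append(bases[off])
                qual_parts.append(quals[off])
                run += 1
            if off in ins_at:
                emit("M", run)
                run = 0
                emit("I", 1)
                seq_parts.append(ins_at[off])
                qual_parts.append(int(np.clip(np.rint(ins_rng.normal(cfg.phred_mean, cfg.phred_sd)), 2, 41)))
        emit("M", run)
        seq = np.array(seq_parts, dtype=np.int8)
        qual = np.array(qual_parts, dtype=np.int8)
        return seq, qual, "".join(f"{n}{op}" for op, n in cigar)

    def sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": self.config.reference_name, "LN": len(self.config.template)}],
            }
        )

    def sam_records(self, header: pysam.AlignmentHeader | None = None):
        """Yield aligned read pairs as pysam records (template pairs align
        forward-first, polymerized pairs reverse-first)."""
        cfg = self.config
        header = header or self.sam_header()
        ins_rng = np.random.default_rng([cfg.seed, 2])
        for batch in self._iter_batches():
            strand_tag = "t" if batch["strand"] == "template" else "p"
            length, tail_start = batch["length"], batch["tail_start"]
            if strand_tag == "t":
                # template-strand pair: first-in-pair reads the fragment head
                # forward, the mate reads the tail reverse
                plan = ((99, 0, "head"), (147, tail_start, "tail"))
            else:
                # polymerized-strand pair: first-in-pair starts at the strand's
                # 5' end, which maps to the reference tail, aligned reverse
                plan = ((83, tail_start, "tail"), (163, 0, "head"))
            for row in range(len(batch["mols"])):
                qname = f"m{batch['mols'][row]:08d}{strand_tag}{batch['pair_idx'][row]:02d}"
                for k, (flag, rpos, slot) in enumerate(plan):
                    seq, qual, cigar = self._read_fields(batch, row, slot, ins_rng)
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = qname
                    rec.flag = flag
                    rec.reference_id = 0
                    rec.reference_start = rpos
                    rec.mapping_quality = 42
                    rec.cigarstring = cigar
                    rec.query_sequence = decode(seq)
                    rec.query_qualities = array.array(
                        "B", np.asarray(qual, dtype=np.uint8).tobytes()
                    )
                    rec.next_reference_id = 0
                    rec.next_reference_start = plan[1 - k][1]
                    rec.template_length = length if flag in (99, 163) else -length
                    yield rec

    def write_sam(self, path: str) -> None:
        header = self.sam_header()
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for rec in self.sam_records(header):
                out.write(rec)

    def fastq_records(self):
        """Yield (qname, r1_seq, r1_qual, r2_seq, r2_qual) in sequencing
        orientation (reverse-aligned reads are reverse-complemented)."""
        cfg = self.config
        ins_rng = np.random.default_rng([cfg.seed, 2])
        for batch in self._iter_batches():
            strand_tag = "t" if batch["strand"] == "template" else "p"
            # read1/read2 slot and orientation mirror the SAM layout
            plan = ((False, "head"), (True, "tail")) if strand_tag == "t" else ((True, "tail"), (False, "head"))
            for row in range(len(batch["mols"])):
                qname = f"m{batch['mols'][row]:08d}{strand_tag}{batch['pair_idx'][row]:02d}"
                fields = []
                for rev, slot in plan:
                    seq, qual, _ = self._read_fields(batch, row, slot, ins_rng)
                    if rev:
                        seq = complement_codes(seq)[::-1]
                        qual = qual[::-1]
                    fields.append(decode(seq))
                    fields.append((np.asarray(qual, dtype=np.uint8) + 33).tobytes().decode("ascii"))
                yield (qname, *fields)

    def write_fastq(self, r1_path: str, r2_path: str) -> None:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for qname, s1, q1, s2, q2 in self.fastq_records():
                f1.write(f"@{qname}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{qname}/2\n{s2}\n+\n{q2}\n")

    def write_reference_fasta(self, path: str) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        SeqIO.write(
            [SeqRecord(Seq(self.config.template), id=self.config.reference_name, description="")],
            path,
            "fasta",
        )


def simulate_library(config: SimConfig) -> SimulatedLibrary:
    """Simulate one library; see :class:`SimulatedLibrary` for outputs."""
    return SimulatedLibrary(config)
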