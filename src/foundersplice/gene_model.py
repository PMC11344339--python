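"""Transcript gene models, coding (c.) coordinates and an HGVS c. parser.

The coordinate backbone for all splice arithmetic in this package.  A
:class:`TranscriptModel` is an ordered list of genomic exon intervals
(1-based, closed) in transcription direction, with the CDS located in
spliced-transcript coordinates.  Coding positions follow HGVS: ``c.1`` is
the A of the start codon, ``c.N+k`` is ``k`` bases into the intron
downstream of the donor after coding base ``N``, and ``c.N-k`` is ``k``
bases upstream of the acceptor before coding base ``N``.

Only the HGVS c. dialect needed for small gene-panel variant tables is
supported: substitution, deletion, duplication, insertion and delins,
with optional intron offsets.  Anything else (inversions, alleles,
uncertain positions) raises :class:`UnsupportedHGVSError` rather than
misparsing silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CodingCoordinate",
    "VariantDescriptor",
    "TranscriptModel",
    "SpliceRegion",
    "HGVSParseError",
    "UnsupportedHGVSError",
    "parse_hgvs_c",
    "format_hgvs_c",
    "read_exon_table",
    "write_exon_table",
    "read_gff3",
    "load_fasta",
]


class HGVSParseError(ValueError):
    """Malformed HGVS c. string; the message names the offending token."""


class UnsupportedHGVSError(HGVSParseError):
    """Syntactically valid HGVS that uses a construct outside the supported dialect."""


@dataclass(frozen=True, order=False)
class CodingCoordinate:
    """A position in HGVS c. space: coding base plus signed intron offset.

    ``intron_offset`` is 0 for exonic positions, +n for the n-th base of
    the downstream intron (after a donor), -n for the n-th base before an
    acceptor.
    """

    base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise ValueError(f"c. base must be >= 1 (5'UTR positions unsupported), got {self.base}")

    def __str__(self) -> str:
        if self.intron_offset > 0:
            return f"{self.base}+{self.intron_offset}"
        if self.intron_offset < 0:
            return f"{self.base}{self.intron_offset}"
        return str(self.base)

    def sort_key(self) -> tuple[int, int]:
        # transcript order: base first, then offset (−k before the exonic base, +k after)
        return (self.base, self.intron_offset)


_VALID_KINDS = ("substitution", "deletion", "duplication", "insertion", "delins")


@dataclass(frozen=True)
class VariantDescriptor:
    """A parsed HGVS c. variant: kind, coordinate span and alleles."""

    kind: str
    start: CodingCoordinate
    end: CodingCoordinate
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.start.sort_key() > self.end.sort_key():
            raise ValueError(f"start {self.start} after end {self.end}")
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution requires single-base ref and alt")
            if self.start != self.end:
                raise ValueError("substitution must be a single position")
        if self.kind in ("insertion", "delins") and not self.alt_allele:
            raise ValueError(f"{self.kind} requires a non-empty alt allele")

    def to_hgvs(self) -> str:
        return format_hgvs_c(self)


_COORD_RE = r"(\d+)(?:([+-])(\d+))?"
_HGVS_RE = re.compile(
    rf"^c\.{_COORD_RE}(?:_{_COORD_RE})?(.*)$"
)
_UNSUPPORTED_TAILS = re.compile(r"^(inv|con|\[|\(|=)")


def _coord(base: str, sign: str | None, off: str | None) -> CodingCoordinate:
    offset = 0
    if sign is not None:
        offset = int(off) * (1 if sign == "+" else -1)
    return CodingCoordinate(int(base), offset)


def parse_hgvs_c(text: str) -> VariantDescriptor:
    """Parse an HGVS c. string of the supported dialect into a :class:`VariantDescriptor`.

    Supported kinds: substitution (``c.2052+3G>T``), deletion
    (``c.8440_8447del``), duplication (``c.7833_7837dup``), insertion
    (``c.100_101insAT``) and delins (``c.198_200delinsCC``).  The parse
    round-trips: ``format_hgvs_c(parse_hgvs_c(s)) == s`` up to whitespace
    and redundant deleted-sequence suffixes.
    """
    s = "".join(text.split())        # tables sometimes break strings with spaces
    if not s.startswith("c."):
        raise HGVSParseError(f"expected a 'c.' prefix in {text!r}")
    if s[2:3] in ("[", "("):
        raise UnsupportedHGVSError(f"allele/uncertainty notation is unsupported: {text!r}")
    m = _HGVS_RE.match(s)
    if not m:
        raise HGVSParseError(f"cannot parse coordinate in {text!r}")
    b1, s1, o1, b2, s2, o2, tail = m.groups()
    start = _coord(b1, s1, o1)
    end = _coord(b2, s2, o2) if b2 is not None else start
    if start.sort_key() > end.sort_key():
        raise HGVSParseError(f"start after end in {text!r}")
    has_range = b2 is not None

    if _UNSUPPORTED_TAILS.match(tail):
        raise UnsupportedHGVSError(f"unsupported HGVS construct {tail!r} in {text!r}")

    m_sub = re.fullmatch(r"([ACGTacgt])>([ACGTacgt])", tail)
    if m_sub:
        if has_range:
            raise UnsupportedHGVSError(f"ranged substitution is unsupported: {text!r}")
        return VariantDescriptor("substitution", start, end,
                                 m_sub.group(1).upper(), m_sub.group(2).upper())

    m_delins = re.fullmatch(r"del(?:([ACGTacgt]+))?ins([ACGTacgt]+)", tail)
    if m_delins:
        ref = (m_delins.group(1) or "").upper()
        return VariantDescriptor("delins", start, end, ref, m_delins.group(2).upper())

    m_del = re.fullmatch(r"del(?:([ACGTacgt]+))?", tail)
    if m_del:
        return VariantDescriptor("deletion", start, end, (m_del.group(1) or "").upper(), "")

    m_dup = re.fullmatch(r"dup(?:([ACGTacgt]+))?", tail)
    if m_dup:
        return VariantDescriptor("duplication", start, end, (m_dup.group(1) or "").upper(), "")

    m_ins = re.fullmatch(r"ins([ACGTacgt]+)", tail)
    if m_ins:
        if not has_range:
            raise HGVSParseError(f"insertion requires a flanking range: {text!r}")
        if not (end.base == start.base + 1 and start.intron_offset == 0 == end.intron_offset) and \
           not (end.base == start.base and end.intron_offset == start.intron_offset + 1):
            raise HGVSParseError(f"insertion flanks must be adjacent positions: {text!r}")
        return VariantDescriptor("insertion", start, end, "", m_ins.group(1).upper())

    if tail == "":
        raise HGVSParseError(f"missing variant operation after coordinate in {text!r}")
    raise UnsupportedHGVSError(f"unsupported or malformed token {tail!r} in {text!r}")


def format_hgvs_c(v: VariantDescriptor) -> str:
    """Serialize a :class:`VariantDescriptor` back to canonical HGVS c. form."""
    span = str(v.start) if v.start == v.end else f"{v.start}_{v.end}"
    if v.kind == "substitution":
        return f"c.{span}{v.ref_allele}>{v.alt_allele}"
    if v.kind == "deletion":
        return f"c.{span}del"
    if v.kind == "duplication":
        return f"c.{span}dup"
    if v.kind == "insertion":
        return f"c.{span}ins{v.alt_allele}"
    if v.kind == "delins":
        return f"c.{span}delins{v.alt_allele}"
    raise ValueError(v.kind)


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons, strand, CDS bounds, optional sequence.

    Parameters
    ----------
    exons
        Genomic intervals, 1-based closed, each as ``(start, end)`` with
        ``start <= end``, ordered in transcription direction (genomically
        decreasing for minus-strand transcripts).
    cds_start_tx, cds_end_tx
        1-based positions of the first and last CDS base in
        spliced-transcript coordinates.
    sequence
        Optional nucleotide string, either the genomic sequence covering
        all exons (``sequence_kind="genomic"``, anchored at
        ``sequence_start``) or the already-spliced mRNA
        (``sequence_kind="spliced"``).
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_tx: int
    cds_end_tx: int
    sequence: str | None = None
    sequence_kind: str = "genomic"
    sequence_start: int = 1
    check_cds_frame: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        if len(exons) < 1:
            raise ValueError("at least one exon required")
        for s, e in exons:
            if e < s:
                raise ValueError(f"exon interval ({s},{e}) reversed or zero length")
        starts = [s for s, _ in exons]
        if self.strand == "+":
            ok = all(exons[i][1] < exons[i + 1][0] for i in range(len(exons) - 1))
        else:
            ok = all(exons[i + 1][1] < exons[i][0] for i in range(len(exons) - 1))
        if not ok:
            raise ValueError("exons must be non-overlapping and ordered in transcription direction")
        L = self.spliced_length
        if not (1 <= self.cds_start_tx < self.cds_end_tx <= L):
            raise ValueError(
                f"CDS bounds ({self.cds_start_tx},{self.cds_end_tx}) outside spliced length {L}")
        if self.check_cds_frame and (self.cds_end_tx - self.cds_start_tx + 1) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if self.sequence_kind not in ("genomic", "spliced"):
            raise ValueError(f"sequence_kind must be 'genomic' or 'spliced'")
        del starts

    # -- basic geometry -----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exon_length(self, ordinal: int) -> int:
        s, e = self.exons[self._check_ordinal(ordinal) - 1]
        return e - s + 1

    def intron_length(self, ordinal: int) -> int:
        """Length of the intron following exon ``ordinal`` (1-based)."""
        if not 1 <= ordinal <= self.n_exons - 1:
            raise IndexError(f"intron {ordinal} does not exist (exons: {self.n_exons})")
        a, b = self.exons[ordinal - 1], self.exons[ordinal]
        if self.strand == "+":
            return b[0] - a[1] - 1
        return a[0] - b[1] - 1

    def _check_ordinal(self, ordinal: int) -> int:
        if not 1 <= ordinal <= self.n_exons:
            raise IndexError(f"exon {ordinal} does not exist (exons: {self.n_exons})")
        return ordinal

    def exon_tx_span(self, ordinal: int) -> tuple[int, int]:
        """Spliced-transcript (tx) coordinates covered by exon ``ordinal``, 1-based closed."""
        self._check_ordinal(ordinal)
        off = 0
        for i, (s, e) in enumerate(self.exons, start=1):
            ln = e - s + 1
            if i == ordinal:
                return off + 1, off + ln
            off += ln
        raise AssertionError

    def junction_tx_positions(self) -> list[int]:
        """tx coordinate of the last base of each exon except the final one."""
        out, off = [], 0
        for s, e in self.exons[:-1]:
            off += e - s + 1
            out.append(off)
        return out

    # -- coordinate mapping --------------------------------------------------

    def tx_to_genomic(self, tx: int) -> int:
        if not 1 <= tx <= self.spliced_length:
            raise ValueError(f"tx position {tx} outside transcript (length {self.spliced_length})")
        off = 0
        for s, e in self.exons:
            ln = e - s + 1
            if tx <= off + ln:
                k = tx - off - 1
                return s + k if self.strand == "+" else e - k
            off += ln
        raise AssertionError

    def genomic_to_tx(self, g: int) -> int:
        off = 0
        for s, e in self.exons:
            if s <= g <= e:
                k = g - s if self.strand == "+" else e - g
                return off + k + 1
            off += e - s + 1
        raise ValueError(f"genomic position {g} is not exonic in {self.id}")

    def c_to_tx(self, c: CodingCoordinate) -> int:
        """tx coordinate of the exonic anchor of ``c`` (offset ignored)."""
        tx = c.base + self.cds_start_tx - 1
        if not 1 <= tx <= self.spliced_length:
            raise ValueError(f"c.{c} beyond transcript extent of {self.id}")
        return tx

    def tx_to_c(self, tx: int) -> CodingCoordinate:
        base = tx - self.cds_start_tx + 1
        if base < 1:
            raise ValueError(f"tx {tx} is upstream of the CDS start (5'UTR c. numbering unsupported)")
        return CodingCoordinate(base)

    def c_to_genomic(self, c: CodingCoordinate) -> tuple[str, int]:
        """Map a c. coordinate (with intron offset) to ``(chrom, genomic position)``.

        Strand-aware; intronic offsets must anchor at the appropriate
        exon boundary and lie within the intron.
        """
        tx = self.c_to_tx(c)
        if c.intron_offset == 0:
            return self.chrom, self.tx_to_genomic(tx)
        spans = [self.exon_tx_span(i) for i in range(1, self.n_exons + 1)]
        if c.intron_offset > 0:
            donors = {sp[1]: i for i, sp in enumerate(spans, start=1)}
            if tx not in donors or donors[tx] == self.n_exons:
                raise ValueError(f"c.{c}: +offset must anchor at the last base of a non-final exon")
            intron = donors[tx]
            if c.intron_offset > self.intron_length(intron):
                raise ValueError(f"c.{c}: offset exceeds intron {intron} length")
            g = self.tx_to_genomic(tx)
            step = 1 if self.strand == "+" else -1
            return self.chrom, g + step * c.intron_offset
        acceptors = {sp[0]: i for i, sp in enumerate(spans, start=1)}
        if tx not in acceptors or acceptors[tx] == 1:
            raise ValueError(f"c.{c}: -offset must anchor at the first base of a non-first exon")
        intron = acceptors[tx] - 1
        if -c.intron_offset > self.intron_length(intron):
            raise ValueError(f"c.{c}: offset exceeds intron {intron} length")
        g = self.tx_to_genomic(tx)
        step = 1 if self.strand == "+" else -1
        return self.chrom, g + step * c.intron_offset

    def genomic_to_c(self, g: int, chrom: str | None = None) -> CodingCoordinate:
        """Inverse of :meth:`c_to_genomic`; intronic positions use the HGVS
        nearest-boundary convention (first half of the intron anchors to
        the donor, second half to the acceptor, midpoint to the donor)."""
        if chrom is not None and chrom != self.chrom:
            raise ValueError(f"{chrom} does not match transcript chromosome {self.chrom}")
        try:
            tx = self.genomic_to_tx(g)
        except ValueError:
            return self._intronic_genomic_to_c(g)
        return self.tx_to_c(tx)

    def _intronic_genomic_to_c(self, g: int) -> CodingCoordinate:
        for i in range(1, self.n_exons):
            up, down = self.exons[i - 1], self.exons[i]
            if self.strand == "+":
                lo, hi = up[1] + 1, down[0] - 1
                inside = lo <= g <= hi
                d_donor = g - up[1]
                d_accept = down[0] - g
            else:
                lo, hi = down[1] + 1, up[0] - 1
                inside = lo <= g <= hi
                d_donor = up[0] - g
                d_accept = g - down[1]
            if inside:
                donor_tx = self.exon_tx_span(i)[1]
                accept_tx = self.exon_tx_span(i + 1)[0]
                if d_donor <= d_accept:
                    return CodingCoordinate(self.tx_to_c(donor_tx).base, +d_donor)
                return CodingCoordinate(self.tx_to_c(accept_tx).base, -d_accept)
        raise ValueError(f"genomic position {g} outside transcript {self.id} extent")

    # -- sequence ------------------------------------------------------------

    def with_sequence(self, sequence: str, kind: str = "genomic", start: int = 1) -> "TranscriptModel":
        return replace(self, sequence=sequence, sequence_kind=kind, sequence_start=start)

    def exon_genomic_seq(self, ordinal: int) -> str:
        """Genomic-strand (plus-strand) sequence of exon ``ordinal``."""
        if self.sequence is None or self.sequence_kind != "genomic":
            raise ValueError(f"transcript {self.id} carries no genomic sequence")
        s, e = self.exons[self._check_ordinal(ordinal) - 1]
        i, j = s - self.sequence_start, e - self.sequence_start + 1
        if i < 0 or j > len(self.sequence):
            raise ValueError(f"exon {ordinal} extends beyond the attached sequence")
        return self.sequence[i:j]

    def intron_genomic_seq(self, ordinal: int) -> str:
        """Plus-strand genomic sequence of the intron following exon ``ordinal``."""
        if self.sequence is None or self.sequence_kind != "genomic":
            raise ValueError(f"transcript {self.id} carries no genomic sequence")
        a, b = self.exons[ordinal - 1], self.exons[ordinal]
        lo = (a[1] + 1, b[0] - 1) if self.strand == "+" else (b[1] + 1, a[0] - 1)
        i, j = lo[0] - self.sequence_start, lo[1] - self.sequence_start + 1
        return self.sequence[i:j]

    def spliced_mrna(self) -> str:
        """Spliced mRNA in transcription orientation (see :func:`build_spliced_mrna`)."""
        return build_spliced_mrna(self)

    def cds(self) -> str:
        mrna = self.spliced_mrna()
        return mrna[self.cds_start_tx - 1:self.cds_end_tx]


def build_spliced_mrna(model: TranscriptModel) -> str:
    """Concatenate exon sequences in transcription order.

    Minus-strand exon slices are reverse-complemented; the result length
    always equals the sum of exon lengths.
    """
    if model.sequence is None:
        raise ValueError(f"transcript {model.id} carries no sequence")
    if model.sequence_kind == "spliced":
        if len(model.sequence) != model.spliced_length:
            raise ValueError("spliced sequence length does not match exon lengths")
        return model.sequence.upper()
    parts = []
    for i in range(1, model.n_exons + 1):
        seg = model.exon_genomic_seq(i)
        if model.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    return "".join(parts).upper()


# ---------------------------------------------------------------------------
# Splice-region classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceRegion:
    """Where a variant falls relative to exon/intron architecture."""

    label: str
    exon: int | None = None
    intron: int | None = None
    offset: int = 0


# boundaries follow common annotation practice: the canonical dinucleotides,
# an extended donor region out to +6, an acceptor region out to the branch
# point neighbourhood (−3..−12), and a 3-nt exonic shoulder at junctions.
DONOR_REGION_MAX = 6
ACCEPTOR_REGION_MAX = 12
EXONIC_JUNCTION_SHOULDER = 3


def classify_splice_region(model: TranscriptModel, v: VariantDescriptor) -> SpliceRegion:
    """Classify a variant's start position relative to the model's splice sites.

    Exon/intron ordinals are 1-based in transcription order (exon 1 =
    first transcribed exon; intron ``i`` follows exon ``i``).
    """
    c = v.start
    tx = model.c_to_tx(c)
    spans = [model.exon_tx_span(i) for i in range(1, model.n_exons + 1)]
    if c.intron_offset > 0:
        donors = {sp[1]: i for i, sp in enumerate(spans, start=1)}
        if tx not in donors or donors[tx] == model.n_exons:
            raise ValueError(f"c.{c} does not anchor at a donor site of {model.id}")
        intron = donors[tx]
        if c.intron_offset > model.intron_length(intron):
            raise ValueError(f"c.{c} beyond intron {intron} extent")
        off = c.intron_offset
        if off <= 2:
            return SpliceRegion("canonical_donor", intron=intron, offset=off)
        if off <= DONOR_REGION_MAX:
            return SpliceRegion("donor_region", intron=intron, offset=off)
        return SpliceRegion("deep_intronic", intron=intron, offset=off)
    if c.intron_offset < 0:
        acceptors = {sp[0]: i for i, sp in enumerate(spans, start=1)}
        if tx not in acceptors or acceptors[tx] == 1:
            raise ValueError(f"c.{c} does not anchor at an acceptor site of {model.id}")
        intron = acceptors[tx] - 1
        if -c.intron_offset > model.intron_length(intron):
            raise ValueError(f"c.{c} beyond intron {intron} extent")
        off = c.intron_offset
        if off >= -2:
            return SpliceRegion("canonical_acceptor", intron=intron, offset=off)
        if off >= -ACCEPTOR_REGION_MAX:
            return SpliceRegion("acceptor_region", intron=intron, offset=off)
        return SpliceRegion("deep_intronic", intron=intron, offset=off)
    # exonic
    for i, (lo, hi) in enumerate(spans, start=1):
        if lo <= tx <= hi:
            d_left = tx - lo if i > 1 else None
            d_right = hi - tx if i < model.n_exons else None
            dists = [d for d in (d_left, d_right) if d is not None]
            if dists and min(dists) < EXONIC_JUNCTION_SHOULDER:
                return SpliceRegion("exonic_near_junction", exon=i)
            return SpliceRegion("exonic_internal", exon=i)
    raise ValueError(f"c.{c} outside transcript {model.id}")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_EXON_TABLE_COLUMNS = ["transcript_id", "chrom", "strand", "exon_number", "start", "end"]


def read_exon_table(path, cds: Mapping[str, tuple[int, int]] | None = None) -> dict[str, TranscriptModel]:
    """Read transcripts from a tab-delimited exon table.

    Required columns: ``transcript_id, chrom, strand, exon_number, start,
    end``; optional columns ``cds_start_tx, cds_end_tx`` (constant per
    transcript) or a ``cds`` mapping override.  Returns models without
    sequence (attach with :meth:`TranscriptModel.with_sequence`).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"exon table missing columns: {missing}")
    models: dict[str, TranscriptModel] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("exon_number")
        exons = tuple(zip(grp["start"].astype(int), grp["end"].astype(int)))
        strand = str(grp["strand"].iloc[0])
        chrom = str(grp["chrom"].iloc[0])
        if cds and tid in cds:
            c1, c2 = cds[tid]
        elif {"cds_start_tx", "cds_end_tx"} <= set(df.columns):
            c1, c2 = int(grp["cds_start_tx"].iloc[0]), int(grp["cds_end_tx"].iloc[0])
        else:
            c1, c2 = 1, sum(e - s + 1 for s, e in exons)
        models[str(tid)] = TranscriptModel(str(tid), chrom, strand, exons, c1, c2,
                                           check_cds_frame=False)
    return models


def write_exon_table(models: Iterable[TranscriptModel], path) -> None:
    import pandas as pd

    rows = []
    for m in models:
        for i, (s, e) in enumerate(m.exons, start=1):
            rows.append({"transcript_id": m.id, "chrom": m.chrom, "strand": m.strand,
                         "exon_number": i, "start": s, "end": e,
                         "cds_start_tx": m.cds_start_tx, "cds_end_tx": m.cds_end_tx})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gff3(path, transcript_id: str | None = None) -> dict[str, TranscriptModel]:
    """Read exon/CDS features from a GFF3 file into transcript models.

    Uses an in-memory gffutils database; exons are grouped by their
    ``Parent`` attribute.  CDS bounds are converted to spliced-transcript
    coordinates.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        parents = feat.attributes.get("Parent", [feat.id])
        for p in parents:
            if transcript_id is not None and p != transcript_id:
                continue
            meta[p] = (feat.seqid, feat.strand)
            (exons if feat.featuretype == "exon" else cds).setdefault(p, []).append(
                (feat.start, feat.end))
    models = {}
    for tid, ex in exons.items():
        chrom, strand = meta[tid]
        ex = sorted(ex, reverse=(strand == "-"))
        tmp = TranscriptModel(tid, chrom, strand, tuple(ex), 1,
                              sum(e - s + 1 for s, e in ex), check_cds_frame=False)
        if tid in cds:
            gpos = sorted(p for s, e in cds[tid] for p in (s, e))
            tx_bounds = sorted(tmp.genomic_to_tx(g) for g in (gpos[0], gpos[-1]))
            tmp = replace(tmp, cds_start_tx=tx_bounds[0], cds_end_tx=tx_bounds[1])
        models[tid] = tmp
    return models


def load_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
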