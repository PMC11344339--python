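"""Consequences of aberrant splicing: mRNA delta, reading frame, premature
termination, protein-level HGVS, NMD prediction and RT-PCR amplicon sizes.

Events are *declared* outcomes (exon skip, partial intron retention via a
cryptic acceptor/donor, exonic truncation via an ectopic acceptor), as
established experimentally by RT-PCR — this module does not score splice
sites.  Each event is applied to a :class:`~foundersplice.gene_model.TranscriptModel`
to produce the altered mRNA, and the altered open reading frame is
translated to classify the protein consequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_model import TranscriptModel, VariantDescriptor

__all__ = [
    "SpliceEvent",
    "AlteredTranscript",
    "ProteinConsequence",
    "PrimerPair",
    "AmpliconCall",
    "apply_splice_event",
    "apply_variant_to_transcript",
    "frame_consequence",
    "translate_consequence",
    "predict_nmd",
    "predict_amplicon_sizes",
    "gel_match",
    "find_ag_dinucleotides",
    "consequence_report",
    "NMD_JUNCTION_RULE_NT",
]

EVENT_KINDS = (
    "exon_skip",
    "partial_intron_retention_3prime",
    "partial_intron_retention_5prime",
    "exonic_acceptor_truncation",
)

#: distance (nt) upstream of the last exon–exon junction beyond which a
#: premature termination codon is predicted to trigger NMD (50–55-nt rule).
NMD_JUNCTION_RULE_NT = 55


@dataclass(frozen=True)
class SpliceEvent:
    """A declared aberrant-splicing outcome.

    ``target`` is the 1-based exon ordinal for ``exon_skip`` /
    ``exonic_acceptor_truncation`` and the 1-based intron ordinal for the
    retention kinds.  ``length_nt`` is the exon length (skip), the
    retained intronic length (retention), or the removed exonic length
    (truncation).
    """

    kind: str
    target: int
    length_nt: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown splice event kind {self.kind!r}")
        if self.length_nt is not None and self.length_nt < 1:
            raise ValueError("length_nt must be >= 1")


@dataclass(frozen=True)
class AlteredTranscript:
    """The mRNA produced by a splice event (or small variant) plus bookkeeping.

    ``junction_tx_pos`` is the transcript coordinate (in the *wild-type*
    mRNA) of the alteration's 5'-most changed base; ``junctions`` are the
    exon–exon junction positions of the *altered* mRNA (tx coordinate of
    the last base of each non-final exon), needed for the NMD rule.
    """

    mrna: str
    delta_nt: int
    junction_tx_pos: int
    event: SpliceEvent | None = None
    variant: VariantDescriptor | None = None
    junctions: tuple[int, ...] = ()
    cds_start_tx: int = 1


@dataclass(frozen=True)
class ProteinConsequence:
    frame_class: str                # {in_frame, frameshift}
    kind: str                       # inframe_insertion/-deletion, frameshift_with_PTC, nonsense, missense, no_change, no_ORF, no_stop
    hgvs_p: str
    novel_aa_count: int = 0
    aa_delta: int = 0
    nmd_predicted: bool = False
    ptc_tx_pos: int | None = None   # tx coordinate (altered mRNA) of the stop codon's first base


@dataclass(frozen=True)
class PrimerPair:
    """cDNA primer footprint, as tx coordinates on the wild-type transcript."""

    forward_tx_start: int
    reverse_tx_end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.forward_tx_start < self.reverse_tx_end:
            raise ValueError("forward primer must lie upstream of reverse primer")
        if self.forward_tx_start < 1:
            raise ValueError("primer coordinates are 1-based tx positions")


@dataclass(frozen=True)
class AmpliconCall:
    allele: str
    size_nt: int | None
    primer_lost: bool = False


# ---------------------------------------------------------------------------
# Applying events
# ---------------------------------------------------------------------------

def _tx_oriented_intron(model: TranscriptModel, intron: int) -> str:
    seg = model.intron_genomic_seq(intron)
    if model.strand == "-":
        seg = str(Seq(seg).reverse_complement())
    return seg.upper()


def apply_splice_event(model: TranscriptModel, event: SpliceEvent) -> AlteredTranscript:
    """Produce the altered mRNA for a declared splice event.

    The altered mRNA is the wild-type spliced mRNA with exactly the
    event's bases removed or inserted at the corresponding junction;
    ``delta_nt`` is negative for skips/truncations and positive for
    retentions.
    """
    mrna = model.spliced_mrna()
    wt_junctions = model.junction_tx_positions()

    if event.kind == "exon_skip":
        k = event.target
        exon_len = model.exon_length(k)
        if event.length_nt is not None and event.length_nt != exon_len:
            raise ValueError(
                f"exon {k} is {exon_len} nt but event declares {event.length_nt} nt")
        lo, hi = model.exon_tx_span(k)
        altered = mrna[:lo - 1] + mrna[hi:]
        delta = -exon_len
        junctions = []
        skipped_junction = hi if k < model.n_exons else None
        for j in wt_junctions:
            if j == skipped_junction:
                continue
            if k < model.n_exons and j == lo - 1:
                junctions.append(j)           # fused (k-1)/(k+1) junction
            elif j > hi:
                junctions.append(j + delta)
            elif j < lo:
                junctions.append(j)
        # skipping the final exon removes the last junction entirely
        return AlteredTranscript(altered, delta, lo, event=event,
                                 junctions=tuple(sorted(set(junctions))),
                                 cds_start_tx=_shift_cds_start(model, lo, hi, delta))

    if event.kind in ("partial_intron_retention_3prime", "partial_intron_retention_5prime"):
        k = event.target
        if not 1 <= k <= model.n_exons - 1:
            raise ValueError(f"intron {k} does not exist in {model.id}")
        if event.length_nt is None:
            raise ValueError("retention events require length_nt")
        r = event.length_nt
        if r > model.intron_length(k):
            raise ValueError(f"retention of {r} nt exceeds intron {k} "
                             f"({model.intron_length(k)} nt)")
        intron_seq = _tx_oriented_intron(model, k)
        retained = intron_seq[-r:] if event.kind.endswith("3prime") else intron_seq[:r]
        j = model.exon_tx_span(k)[1]          # junction after exon k
        altered = mrna[:j] + retained + mrna[j:]
        if event.kind.endswith("3prime"):
            # cryptic acceptor: retained block splices onto exon k+1
            junctions = [x if x <= j else x + r for x in wt_junctions]
        else:
            # cryptic donor: retained block extends exon k
            junctions = [x + r if x >= j else x for x in wt_junctions]
        return AlteredTranscript(altered, r, j + 1, event=event,
                                 junctions=tuple(junctions),
                                 cds_start_tx=_shift_cds_start(model, j + 1, j, r))

    if event.kind == "exonic_acceptor_truncation":
        k = event.target
        lo, hi = model.exon_tx_span(k)
        if event.length_nt is None:
            raise ValueError("truncation events require length_nt")
        d = event.length_nt
        if d >= model.exon_length(k):
            raise ValueError(f"truncation of {d} nt consumes exon {k} entirely; use exon_skip")
        altered = mrna[:lo - 1] + mrna[lo - 1 + d:]
        junctions = [x if x < lo else x - d for x in wt_junctions]
        return AlteredTranscript(altered, -d, lo, event=event,
                                 junctions=tuple(junctions),
                                 cds_start_tx=_shift_cds_start(model, lo, lo + d - 1, -d))

    raise ValueError(event.kind)


def _shift_cds_start(model: TranscriptModel, block_start: int, block_end: int,
                     delta: int) -> int:
    """CDS start tx position in the altered mRNA (start codon assumed intact)."""
    s = model.cds_start_tx
    if block_end < s and delta < 0:
        return s + delta
    if block_start <= s and delta > 0:
        return s + delta
    return s


def apply_variant_to_transcript(model: TranscriptModel, v: VariantDescriptor) -> AlteredTranscript:
    """Apply a small exonic variant (sub/del/dup/ins/delins) to the spliced mRNA.

    Intronic coordinates are rejected — splice-site variants act through a
    declared :class:`SpliceEvent`, not through direct sequence edit.
    """
    if v.start.intron_offset != 0 or v.end.intron_offset != 0:
        raise ValueError("intronic variant: model its experimentally determined "
                         "splice outcome as a SpliceEvent instead")
    mrna = model.spliced_mrna()
    a = model.c_to_tx(v.start)
    b = model.c_to_tx(v.end)
    ref = mrna[a - 1:b]
    if v.ref_allele and v.ref_allele != ref:
        raise ValueError(f"reference mismatch at c.{v.start}: model has {ref}, "
                         f"variant declares {v.ref_allele}")
    if v.kind == "substitution":
        altered = mrna[:a - 1] + v.alt_allele + mrna[a:]
    elif v.kind == "deletion":
        altered = mrna[:a - 1] + mrna[b:]
    elif v.kind == "duplication":
        altered = mrna[:b] + ref + mrna[b:]
    elif v.kind == "insertion":
        altered = mrna[:a] + v.alt_allele + mrna[a:]
    elif v.kind == "delins":
        altered = mrna[:a - 1] + v.alt_allele + mrna[b:]
    else:  # pragma: no cover
        raise ValueError(v.kind)
    delta = len(altered) - len(mrna)
    junctions = [j + delta if j >= b else j for j in model.junction_tx_positions()]
    return AlteredTranscript(altered, delta, a, variant=v,
                             junctions=tuple(junctions),
                             cds_start_tx=_shift_cds_start(model, a, b, delta))


# ---------------------------------------------------------------------------
# Frame and protein consequence
# ---------------------------------------------------------------------------

def frame_consequence(delta_nt: int) -> tuple[str, int | None]:
    """Classify a length change: ``(frame_class, aa_delta)``.

    In frame iff ``delta_nt`` is a multiple of 3, in which case
    ``aa_delta = delta_nt / 3``; otherwise ``("frameshift", None)``.
    """
    if delta_nt % 3 == 0:
        return "in_frame", delta_nt // 3
    return "frameshift", None


def _translate(seq: str) -> str:
    trimmed = seq[:len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def _protein_to_stop(seq: str) -> tuple[str, bool]:
    """Translate to the first stop; returns (protein, stop_found)."""
    aa = _translate(seq)
    idx = aa.find("*")
    if idx == -1:
        return aa, False
    return aa[:idx], True


def _aa3(a: str) -> str:
    return "Ter" if a == "*" else seq3(a)


def translate_consequence(altered: AlteredTranscript, model: TranscriptModel,
                          nmd_threshold: int = NMD_JUNCTION_RULE_NT) -> ProteinConsequence:
    """Translate the altered open reading frame and classify the outcome.

    Translation starts at the original start codon (shifted by any
    upstream length change) and runs to the first stop with the standard
    genetic code.  Frameshifts report the count of novel residues before
    the premature stop and an HGVS ``p.Xaa###Yaafs*N`` string where N
    counts the stop (``N = novel_aa_count + 1``); direct stop gains
    report ``p.Xaa###*``.  NMD is called with the last-junction rule.
    """
    wt_cds = model.cds()
    wt_prot, _ = _protein_to_stop(wt_cds)

    s = altered.cds_start_tx
    if s < 1 or s + 2 > len(altered.mrna) or \
            altered.mrna[s - 1:s + 2] != model.spliced_mrna()[model.cds_start_tx - 1:model.cds_start_tx + 2]:
        return ProteinConsequence("in_frame", "no_ORF", "p.?", nmd_predicted=False)
    alt_prot, stop_found = _protein_to_stop(altered.mrna[s - 1:])

    frame_class, aa_delta = frame_consequence(altered.delta_nt)
    ptc_tx = (s + 3 * len(alt_prot)) if stop_found else None

    if alt_prot == wt_prot:
        return ProteinConsequence(frame_class, "no_change", "p.(=)",
                                  aa_delta=0, ptc_tx_pos=ptc_tx)

    # first differing residue
    n = min(len(wt_prot), len(alt_prot))
    i = next((k for k in range(n) if wt_prot[k] != alt_prot[k]), n)

    nmd = predict_nmd(ptc_tx, altered.junctions, nmd_threshold) if stop_found else False

    if frame_class == "frameshift":
        if not stop_found:
            return ProteinConsequence("frameshift", "no_stop",
                                      f"p.{_aa3(wt_prot[i])}{i + 1}fs*?",
                                      novel_aa_count=len(alt_prot) - i,
                                      nmd_predicted=False)
        if i >= len(alt_prot):
            # shifted frame stops at the first changed codon
            hgvs = f"p.{_aa3(wt_prot[i])}{i + 1}*"
            return ProteinConsequence("frameshift", "frameshift_with_PTC", hgvs,
                                      novel_aa_count=0, nmd_predicted=nmd,
                                      ptc_tx_pos=ptc_tx)
        novel = len(alt_prot) - i
        hgvs = f"p.{_aa3(wt_prot[i])}{i + 1}{_aa3(alt_prot[i])}fs*{novel + 1}"
        return ProteinConsequence("frameshift", "frameshift_with_PTC", hgvs,
                                  novel_aa_count=novel, nmd_predicted=nmd,
                                  ptc_tx_pos=ptc_tx)

    # in-frame outcomes
    assert aa_delta is not None
    expected_len = len(wt_prot) + aa_delta
    if len(alt_prot) != expected_len:
        # an in-frame change that nonetheless introduced (or removed) a stop
        if len(alt_prot) < expected_len:
            kind = "nonsense"
            ref_aa = wt_prot[i] if i < len(wt_prot) else "?"
            hgvs = f"p.{_aa3(ref_aa)}{i + 1}*" if i == len(alt_prot) else f"p.{_aa3(ref_aa)}{i + 1}Ter"
            return ProteinConsequence("in_frame", kind, hgvs, aa_delta=len(alt_prot) - len(wt_prot),
                                      nmd_predicted=nmd, ptc_tx_pos=ptc_tx)
        return ProteinConsequence("in_frame", "no_stop", "p.?",
                                  aa_delta=len(alt_prot) - len(wt_prot))

    if aa_delta == 0:
        # same length, ≥1 residue changed
        if i == len(alt_prot):  # only the stop moved — not expected here
            return ProteinConsequence("in_frame", "no_change", "p.(=)", ptc_tx_pos=ptc_tx)
        if alt_prot[i:] == "" or len(alt_prot) == i:
            pass
        hgvs = f"p.{_aa3(wt_prot[i])}{i + 1}{_aa3(alt_prot[i])}"
        return ProteinConsequence("in_frame", "missense", hgvs, aa_delta=0,
                                  ptc_tx_pos=ptc_tx)

    # common prefix/suffix delimit the inserted or deleted residue run
    p = i
    smax = min(len(wt_prot), len(alt_prot)) - p
    sfx = 0
    while sfx < smax and wt_prot[len(wt_prot) - 1 - sfx] == alt_prot[len(alt_prot) - 1 - sfx]:
        sfx += 1
    if aa_delta < 0:
        d1, d2 = p + 1, len(wt_prot) - sfx
        if d1 == d2:
            hgvs = f"p.{_aa3(wt_prot[d1 - 1])}{d1}del"
        else:
            hgvs = f"p.{_aa3(wt_prot[d1 - 1])}{d1}_{_aa3(wt_prot[d2 - 1])}{d2}del"
        return ProteinConsequence("in_frame", "inframe_deletion", hgvs,
                                  aa_delta=aa_delta, nmd_predicted=False,
                                  ptc_tx_pos=ptc_tx)
    ins_run = alt_prot[p:len(alt_prot) - sfx]
    left, right = p, p + 1
    ins3 = "".join(_aa3(a) for a in ins_run)
    la = _aa3(wt_prot[left - 1]) if left >= 1 else "?"
    ra = _aa3(wt_prot[right - 1]) if right <= len(wt_prot) else "Ter"
    hgvs = f"p.{la}{left}_{ra}{right}ins{ins3}"
    return ProteinConsequence("in_frame", "inframe_insertion", hgvs,
                              aa_delta=aa_delta, nmd_predicted=False,
                              ptc_tx_pos=ptc_tx)


def predict_nmd(ptc_tx_pos: int | None, junctions: Sequence[int],
                threshold: int = NMD_JUNCTION_RULE_NT) -> bool:
    """Last-junction rule: NMD predicted iff the premature stop starts more
    than ``threshold`` nt upstream of the last exon–exon junction.

    ``ptc_tx_pos`` is the tx coordinate (altered mRNA) of the stop
    codon's first base; single-exon transcripts (no junctions) never
    trigger NMD.
    """
    if ptc_tx_pos is None or not junctions:
        return False
    return (max(junctions) - ptc_tx_pos) > threshold


# ---------------------------------------------------------------------------
# RT-PCR amplicons
# ---------------------------------------------------------------------------

def _event_removed_tx_interval(model: TranscriptModel, event: SpliceEvent) -> tuple[int, int] | None:
    """WT tx interval removed by the event (None for pure insertions)."""
    if event.kind == "exon_skip":
        return model.exon_tx_span(event.target)
    if event.kind == "exonic_acceptor_truncation":
        lo, _ = model.exon_tx_span(event.target)
        return lo, lo + (event.length_nt or 0) - 1
    return None


def predict_amplicon_sizes(model: TranscriptModel, primers: PrimerPair,
                           events: Sequence[SpliceEvent]) -> list[AmpliconCall]:
    """Predicted RT-PCR band sizes for the wild-type allele and each event allele.

    Wild-type size is ``reverse_tx_end − forward_tx_start + 1``; each
    surviving mutant allele adds the event's ``delta_nt``.  An allele
    whose primer site is removed by the event is reported as
    ``primer_lost`` with no size.  Results are sorted descending by size.
    """
    if primers.reverse_tx_end > model.spliced_length:
        raise ValueError("reverse primer beyond transcript end")
    wt_size = primers.reverse_tx_end - primers.forward_tx_start + 1
    calls = [AmpliconCall("WT", wt_size)]
    for ev in events:
        altered = apply_splice_event(model, ev)
        removed = _event_removed_tx_interval(model, ev)
        lost = False
        if removed is not None:
            lo, hi = removed
            lost = (lo <= primers.forward_tx_start <= hi) or (lo <= primers.reverse_tx_end <= hi)
        label = ev.label or f"{ev.kind}:{ev.target}"
        if lost:
            calls.append(AmpliconCall(label, None, primer_lost=True))
        else:
            calls.append(AmpliconCall(label, wt_size + altered.delta_nt))
    calls.sort(key=lambda c: (-(c.size_nt if c.size_nt is not None else -1)))
    return calls


def gel_match(predicted_nt: int, observed_nt: float, tol: float = 0.10) -> bool:
    """Reconcile an exact predicted size with an approximate gel estimate (±10% default)."""
    return abs(predicted_nt - observed_nt) <= tol * predicted_nt


def find_ag_dinucleotides(model: TranscriptModel, intron: int, window: int = 60) -> list[int]:
    """Exploration helper: AG dinucleotides within ``window`` nt of the 3' end
    of an intron (transcription orientation), as distances upstream of the
    canonical acceptor's AG.  Not a splice-site strength model."""
    seq = _tx_oriented_intron(model, intron)
    tail = seq[-window:]
    hits = []
    for k in range(len(tail) - 1):
        if tail[k:k + 2] == "AG":
            hits.append(len(tail) - k - 2)   # 0 = the canonical AG itself
    return sorted(hits)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def consequence_report(model: TranscriptModel, events: Sequence[SpliceEvent],
                       primers: PrimerPair | None = None,
                       nmd_threshold: int = NMD_JUNCTION_RULE_NT):
    """One row per event: delta, frame class, protein HGVS, NMD call and
    amplicon size — as a pandas DataFrame (write with ``to_csv(sep='\\t')``
    or ``to_json``)."""
    import pandas as pd

    amplicons = {}
    if primers is not None:
        for call in predict_amplicon_sizes(model, primers, events):
            amplicons[call.allele] = call
    rows = []
    for ev in events:
        alt = apply_splice_event(model, ev)
        cons = translate_consequence(alt, model, nmd_threshold=nmd_threshold)
        label = ev.label or f"{ev.kind}:{ev.target}"
        row = {
            "transcript_id": model.id,
            "event": label,
            "kind": ev.kind,
            "target": ev.target,
            "delta_nt": alt.delta_nt,
            "frame_class": cons.frame_class,
            "consequence": cons.kind,
            "hgvs_p": cons.hgvs_p,
            "novel_aa_count": cons.novel_aa_count,
            "aa_delta": cons.aa_delta,
            "nmd_predicted": cons.nmd_predicted,
        }
        if primers is not None:
            call = amplicons.get(label)
            row["amplicon_nt"] = call.size_nt if call else None
            row["primer_lost"] = call.primer_lost if call else None
            row["wt_amplicon_nt"] = amplicons["WT"].size_nt
        rows.append(row)
    return pd.DataFrame(rows)
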