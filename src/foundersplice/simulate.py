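"""Seeded synthetic-data generators with constructed ground truth.

Every generator pairs its output with a truth record derived by direct
construction or by an independent naive code path (a hand-written codon
table and per-SNP loops), never by the engines under test.  All output is
bit-reproducible under a fixed seed.

Three worlds are emulated:

* transcripts with planted splice alterations whose protein consequence
  is engineered (e.g. a frameshift meeting a stop after exactly k novel
  residues);
* SNP-array cohorts with a planted founder segment shared identical-by-
  descent among a subset of carriers (one shared haplotype, Hardy–
  Weinberg elsewhere, no recombination or LD model);
* annotated variant tables exercising every shortlist filter clause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gene_model import TranscriptModel
from .ibd import MISSING, GenotypePanel
from .splice import SpliceEvent

__all__ = [
    "TranscriptTruth",
    "SyntheticTranscriptFixture",
    "SyntheticCohortFixture",
    "gen_transcript_fixture",
    "gen_cohort_fixture",
    "gen_variant_table",
    "naive_translate",
    "CODON_TABLE",
    "write_pedmap",
]

# ---------------------------------------------------------------------------
# Naive translation machinery (the independent oracle path)
# ---------------------------------------------------------------------------

_B = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_B) for j, b in enumerate(_B) for k, c in enumerate(_B)
}
NONSTOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_COMP = str.maketrans("ACGT", "TGCA")


def naive_translate(seq: str) -> tuple[str, bool]:
    """Codon-by-codon translation to the first stop: (protein, stop_found)."""
    prot = []
    for k in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[k:k + 3]]
        if aa == "*":
            return "".join(prot), True
        prot.append(aa)
    return "".join(prot), False


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _first_diff(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for k in range(n):
        if a[k] != b[k]:
            return k
    return n


# ---------------------------------------------------------------------------
# Transcript fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptTruth:
    """Constructed expectation for one planted splice event."""

    label: str
    delta_nt: int
    frame_class: str
    aa_delta: int | None
    novel_aa_count: int
    stop_found: bool
    first_diff_pos: int | None      # 1-based residue of the first change
    wt_aa: str | None
    alt_aa: str | None              # residue replacing it (None if stop right there)
    ptc_tx_pos: int | None          # altered-mRNA tx coordinate of the stop codon start
    nmd_predicted: bool
    altered_mrna: str


@dataclass(frozen=True)
class SyntheticTranscriptFixture:
    model: TranscriptModel
    events: tuple[SpliceEvent, ...]
    truth: Mapping[str, TranscriptTruth]
    wt_mrna: str
    wt_protein: str


def _naive_apply(wt: str, ev: SpliceEvent, exon_spans: list[tuple[int, int]],
                 retained: str | None) -> tuple[str, int, list[int]]:
    """Independent event application: (altered mRNA, junction J 1-based, junctions)."""
    wt_junctions = [sp[1] for sp in exon_spans[:-1]]
    if ev.kind == "exon_skip":
        lo, hi = exon_spans[ev.target - 1]
        altered = wt[:lo - 1] + wt[hi:]
        L = hi - lo + 1
        junc = []
        for j in wt_junctions:
            if j == hi:
                continue
            junc.append(j - L if j > hi else j)
        return altered, lo, sorted(set(junc))
    if ev.kind == "exonic_acceptor_truncation":
        lo, hi = exon_spans[ev.target - 1]
        d = ev.length_nt or 0
        altered = wt[:lo - 1] + wt[lo - 1 + d:]
        junc = [j - d if j >= lo else j for j in wt_junctions]
        return altered, lo, junc
    j = exon_spans[ev.target - 1][1]
    r = len(retained or "")
    altered = wt[:j] + (retained or "") + wt[j:]
    if ev.kind == "partial_intron_retention_3prime":
        junc = [x if x <= j else x + r for x in wt_junctions]
    else:
        junc = [x + r if x >= j else x for x in wt_junctions]
    return altered, j + 1, junc


def _altered_pos_source(u0: int, ev: SpliceEvent, exon_spans, retained_len: int):
    """Map a 0-based altered-mRNA position to ('wt', idx0) or ('ret', idx0)."""
    if ev.kind == "exon_skip":
        lo, hi = exon_spans[ev.target - 1]
        return ("wt", u0) if u0 < lo - 1 else ("wt", u0 + (hi - lo + 1))
    if ev.kind == "exonic_acceptor_truncation":
        lo, _ = exon_spans[ev.target - 1]
        return ("wt", u0) if u0 < lo - 1 else ("wt", u0 + (ev.length_nt or 0))
    j = exon_spans[ev.target - 1][1]
    if u0 < j:
        return ("wt", u0)
    if u0 < j + retained_len:
        return ("ret", u0 - j)
    return ("wt", u0 - retained_len)


def _truth_from_altered(label: str, wt: str, altered: str, junctions: list[int],
                        nmd_threshold: int = 55) -> TranscriptTruth:
    wt_prot, _ = naive_translate(wt)
    alt_prot, stop = naive_translate(altered)
    delta = len(altered) - len(wt)
    in_frame = delta % 3 == 0
    frame_class = "in_frame" if in_frame else "frameshift"
    aa_delta = (len(alt_prot) - len(wt_prot)) if in_frame else None
    i = _first_diff(wt_prot, alt_prot)
    changed = alt_prot != wt_prot
    first_pos = i + 1 if changed else None
    wt_aa = wt_prot[i] if changed and i < len(wt_prot) else None
    alt_aa = alt_prot[i] if changed and i < len(alt_prot) else None
    novel = (len(alt_prot) - i) if (changed and not in_frame) else 0
    ptc = 3 * len(alt_prot) + 1 if stop else None
    # a natural-terminus stop sits downstream of every junction, so the
    # last-junction rule alone is the truth here
    nmd = bool(stop and junctions and (max(junctions) - ptc) > nmd_threshold)
    return TranscriptTruth(label, delta, frame_class, aa_delta, novel, stop,
                           first_pos, wt_aa, alt_aa, ptc, nmd, altered)


def gen_transcript_fixture(seed: int = 0, n_exons: int = 10,
                           exon_length_range: tuple[int, int] = (90, 210),
                           events: Sequence[Mapping] = (),
                           strand: str = "+",
                           planted_codons: Mapping[int, str] | None = None,
                           intron_length_range: tuple[int, int] = (80, 200),
                           gene_start: int = 5001,
                           transcript_id: str | None = None,
                           max_tries: int = 500) -> SyntheticTranscriptFixture:
    """Generate a transcript with planted splice events of known consequence.

    Each element of ``events`` is a dict:
    ``{"kind": ..., "target": ..., "length_nt": ..., "novel_aa": k}`` —
    ``length_nt`` forces the target exon length for skips; ``novel_aa``
    engineers the downstream sequence so a frameshift meets its premature
    stop after exactly k novel residues.  The whole transcript is coding
    (CDS = tx positions 1..L) and terminates in TAA.  Raises if the
    requested consequence cannot be engineered (e.g. stop unreachable).
    """
    rng = np.random.default_rng(seed)
    specs = [dict(s) for s in events]
    lo_len, hi_len = exon_length_range
    exon_lens = rng.integers(lo_len, hi_len + 1, n_exons)
    for s in specs:
        if s["kind"] == "exon_skip" and s.get("length_nt"):
            if not 1 <= s["target"] <= n_exons:
                raise ValueError(f"exon {s['target']} outside 1..{n_exons}")
            exon_lens[s["target"] - 1] = s["length_nt"]
        if s["kind"] in ("exon_skip", "exonic_acceptor_truncation") and s["target"] >= n_exons:
            raise ValueError("planted deletion events must leave downstream exons "
                             "for the shifted reading frame")
    exon_lens[-1] += (3 - int(exon_lens.sum()) % 3) % 3
    total = int(exon_lens.sum())
    n_codons = total // 3
    spans, off = [], 0
    for ln in exon_lens:
        spans.append((off + 1, off + int(ln)))
        off += int(ln)

    frozen_codons = dict(planted_codons or {})
    for cpos, codon in frozen_codons.items():
        if not 1 <= cpos < n_codons:
            raise ValueError(f"planted codon {cpos} outside coding range")

    intron_lens = rng.integers(*intron_length_range, size=n_exons - 1) \
        if n_exons > 1 else np.zeros(0, int)
    for s in specs:
        if s["kind"].startswith("partial_intron_retention"):
            t, r = s["target"], s["length_nt"]
            if not 1 <= t <= n_exons - 1:
                raise ValueError(f"intron {t} outside 1..{n_exons - 1}")
            intron_lens[t - 1] = max(int(intron_lens[t - 1]), r + 12)

    for attempt in range(max_tries):
        codons = list(rng.choice(NONSTOP_CODONS, n_codons - 1)) + ["TAA"]
        for cpos, codon in frozen_codons.items():
            codons[cpos - 1] = codon.upper()
        wt = list("".join(codons))
        retained: dict[int, list[str]] = {}
        for s in specs:
            if s["kind"].startswith("partial_intron_retention"):
                r = s["length_nt"]
                seq = list(rng.choice(list("ACGT"), r))
                if s["kind"].endswith("3prime"):
                    seq[-2:] = ["A", "G"]
                else:
                    seq[:2] = ["G", "T"]
                retained[s["target"]] = seq

        if _engineer_events(wt, spans, specs, retained, frozen_codons, rng):
            truths = _verify_all(wt, spans, specs, retained)
            if truths is not None:
                return _assemble_fixture(seed, "".join(wt), spans, specs, retained,
                                         intron_lens, strand, gene_start,
                                         transcript_id, truths, rng)
    raise ValueError("could not engineer the requested splice consequences "
                     f"in {max_tries} attempts (stop unreachable or conflicting spec)")


def _event_obj(s: Mapping, spans) -> SpliceEvent:
    length = s.get("length_nt")
    if s["kind"] == "exon_skip" and length is None:
        lo, hi = spans[s["target"] - 1]
        length = hi - lo + 1
    return SpliceEvent(s["kind"], s["target"], length, label=s.get("label", ""))


def _engineer_events(wt: list, spans, specs, retained, frozen_codons, rng) -> bool:
    """Patch stop codons so each event with a requested ``novel_aa`` count
    terminates there; returns False if this randomization cannot host it."""
    frozen_wt = set()
    for cpos in frozen_codons:
        frozen_wt.update(range(3 * (cpos - 1), 3 * cpos))
    frozen_wt.update(range(len(wt) - 3, len(wt)))      # terminal stop
    for s in specs:
        k = s.get("novel_aa")
        if k is None:
            continue
        ev = _event_obj(s, spans)
        ret = "".join(retained.get(ev.target, [])) if ev.kind.startswith("partial") else None
        altered, _, _ = _naive_apply("".join(wt), ev, spans, ret)
        if (len("".join(wt)) - len(altered)) % 3 == 0:
            raise ValueError("novel_aa engineering requires a frameshifting event")
        wt_prot, _ = naive_translate("".join(wt))
        alt_prot, _ = naive_translate(altered)
        i = _first_diff(wt_prot, alt_prot)
        c_star = i + k
        if 3 * c_star + 3 > len(altered):
            raise ValueError(f"stop after {k} novel residues unreachable "
                             "(transcript too short downstream)")
        rlen = len(ret) if ret is not None else 0
        targets = [_altered_pos_source(u, ev, spans, rlen)
                   for u in range(3 * c_star, 3 * c_star + 3)]
        # the stop must land strictly downstream of the junction's fixed prefix
        j_anchor = spans[ev.target - 1][0] - 1 if ev.kind in (
            "exon_skip", "exonic_acceptor_truncation") else spans[ev.target - 1][1]
        for kind, idx in targets:
            if kind == "wt" and (idx in frozen_wt or idx < j_anchor):
                return False
            if kind == "ret" and ret is not None and (
                    idx >= rlen - 2 and "".join(retained[ev.target][-2:]) == "AG") and \
                    s["kind"].endswith("3prime") and idx >= rlen - 2:
                return False
            if kind == "ret" and s["kind"].endswith("5prime") and idx < 2:
                return False
        for base, (kind, idx) in zip("TAA", targets):
            if kind == "wt":
                wt[idx] = base
            else:
                retained[ev.target][idx] = base
    return True


def _verify_all(wt: list, spans, specs, retained):
    """Recompute every event's truth after patching; None on any violation."""
    wt_s = "".join(wt)
    wt_prot, wt_stop = naive_translate(wt_s)
    if not wt_stop or len(wt_prot) != len(wt_s) // 3 - 1:
        return None                                    # premature stop leaked into WT frame
    truths = {}
    for s in specs:
        ev = _event_obj(s, spans)
        ret = "".join(retained.get(ev.target, [])) if ev.kind.startswith("partial") else None
        altered, _, junctions = _naive_apply(wt_s, ev, spans, ret)
        label = s.get("label") or f"{ev.kind}:{ev.target}"
        t = _truth_from_altered(label, wt_s, altered, junctions)
        k = s.get("novel_aa")
        if k is not None and (not t.stop_found or t.novel_aa_count != k):
            return None
        if k is None and t.frame_class == "in_frame":
            expected = len(wt_prot) + (t.delta_nt // 3)
            alt_prot, _ = naive_translate(altered)
            if len(alt_prot) != expected:               # in-frame event hit a chance stop
                return None
        truths[label] = t
    return truths


def _assemble_fixture(seed, wt: str, spans, specs, retained, intron_lens,
                      strand, gene_start, transcript_id, truths, rng):
    n_exons = len(spans)
    exon_seqs = [wt[a - 1:b] for a, b in spans]
    intron_seqs = []
    for t in range(1, n_exons):
        L = int(intron_lens[t - 1])
        body = "".join(rng.choice(list("ACGT"), L - 4))
        seq = "GT" + body + "AG"
        if t in retained:
            ret = "".join(retained[t])
            spec_kind = next(s["kind"] for s in specs
                             if s["kind"].startswith("partial") and s["target"] == t)
            if spec_kind.endswith("3prime"):
                seq = "GT" + body[:L - 2 - len(ret)] + ret
            else:
                seq = ret + body[:L - 2 - len(ret)] + "AG"
            if len(seq) != L:
                seq = seq[:L] if len(seq) > L else seq + "C" * (L - len(seq))
        intron_seqs.append(seq)
    sense_parts = []
    for i in range(n_exons):
        sense_parts.append(exon_seqs[i])
        if i < n_exons - 1:
            sense_parts.append(intron_seqs[i])
    sense = "".join(sense_parts)
    # genomic exon coordinates along the sense concatenation
    sense_spans, off = [], 0
    for i in range(n_exons):
        sense_spans.append((off + 1, off + len(exon_seqs[i])))
        off += len(exon_seqs[i])
        if i < n_exons - 1:
            off += len(intron_seqs[i])
    if strand == "+":
        genomic = sense
        exons = tuple((gene_start + a - 1, gene_start + b - 1) for a, b in sense_spans)
    else:
        genomic = _revcomp(sense)
        L = len(sense)
        exons = tuple((gene_start + L - b, gene_start + L - a) for a, b in sense_spans)
    model = TranscriptModel(transcript_id or f"SYNT{seed:04d}", "chrS", strand, exons,
                            1, len(wt), sequence=genomic, sequence_start=gene_start)
    # independent reconstruction check of the assembly
    rebuilt = []
    for a, b in exons:
        seg = genomic[a - gene_start:b - gene_start + 1]
        rebuilt.append(_revcomp(seg) if strand == "-" else seg)
    if "".join(rebuilt) != wt:
        raise AssertionError("fixture assembly failed its self-check")
    wt_prot, _ = naive_translate(wt)
    events = tuple(_event_obj(s, spans) for s in specs)
    return SyntheticTranscriptFixture(model, events, truths, wt, wt_prot)


# ---------------------------------------------------------------------------
# Cohort fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortFixture:
    panel: GenotypePanel
    truth: Mapping


def gen_cohort_fixture(seed: int = 0, n_samples: int = 100, n_chrom: int = 22,
                       snps_per_chrom: int = 5000,
                       beta: tuple[float, float] = (2.0, 2.0),
                       freq_clip: tuple[float, float] = (0.05, 0.95),
                       mean_spacing_bp: int = 22727,
                       founder: Mapping | None = None,
                       relatives: Sequence[tuple[str, int, int]] = (),
                       missing_rate: float = 0.0) -> SyntheticCohortFixture:
    """Simulate an array-style SNP cohort, optionally with a planted founder segment.

    Allele frequencies are Beta(2,2) clipped to [0.05, 0.95]; genotypes
    are independent Hardy–Weinberg draws except where structure is
    planted.  ``founder`` is e.g. ``{"n_carriers": 4, "segment_snps": 275,
    "chrom": "chr1"}``: the chosen carriers receive one shared identical
    haplotype across a contiguous segment centred mid-chromosome (their
    second haplotype stays independent).  ``relatives`` plants
    ``("parent_offspring", i, j)`` or ``("identical", i, j)`` pairs by
    sample index.  SNP spacing is uniform jitter (±50%) around
    ``mean_spacing_bp``, whose default makes 275 SNPs span ≈ 6.25 Mb.
    """
    rng = np.random.default_rng(seed)
    n_snps = n_chrom * snps_per_chrom
    chrom = np.repeat([f"chr{i + 1}" for i in range(n_chrom)], snps_per_chrom).astype(object)
    spacing = rng.uniform(0.5, 1.5, n_snps) * mean_spacing_bp
    pos = np.empty(n_snps, dtype=np.int64)
    for c in range(n_chrom):
        sl = slice(c * snps_per_chrom, (c + 1) * snps_per_chrom)
        pos[sl] = 10_000 + np.cumsum(spacing[sl]).astype(np.int64)
    freqs = np.clip(rng.beta(*beta, size=n_snps), *freq_clip)
    h1 = (rng.random((n_samples, n_snps)) < freqs).astype(np.int8)
    h2 = (rng.random((n_samples, n_snps)) < freqs).astype(np.int8)

    truth: dict = {"relatives": list(relatives), "founder": None}
    samples = [f"S{i:03d}" for i in range(n_samples)]

    if founder is not None:
        k = int(founder.get("n_carriers", 4))
        if k > n_samples:
            raise ValueError("n_carriers exceeds n_samples")
        seg = int(founder.get("segment_snps", 275))
        fchrom = founder.get("chrom") or "chr1"
        ci = [f"chr{i + 1}" for i in range(n_chrom)].index(fchrom)
        base = ci * snps_per_chrom
        center = base + snps_per_chrom // 2
        lo = center - seg // 2
        hi = lo + seg - 1
        if lo < base or hi >= base + snps_per_chrom:
            raise ValueError("founder segment does not fit within one chromosome")
        carriers = np.sort(rng.choice(n_samples, size=k, replace=False))
        founder_hap = (rng.random(seg) < freqs[lo:hi + 1]).astype(np.int8)
        copies = int(founder.get("copies", 1))
        for s in carriers:
            h1[s, lo:hi + 1] = founder_hap
            if copies == 2:
                h2[s, lo:hi + 1] = founder_hap
        truth["founder"] = {
            "carriers": [samples[s] for s in carriers],
            "chrom": fchrom,
            "index_pos": int(pos[center]),
            "index_snp": int(center),
            "segment_snps": seg,
            "segment_global": (int(lo), int(hi)),
            "span_mb": float(pos[hi] - pos[lo]) / 1e6,
            "copies": copies,
        }

    for kind, a, b in relatives:
        if kind == "identical":
            h1[b] = h1[a]
            h2[b] = h2[a]
        elif kind == "parent_offspring":
            pick = rng.random(n_snps) < 0.5
            h1[b] = np.where(pick, h1[a], h2[a])
            h2[b] = (rng.random(n_snps) < freqs).astype(np.int8)
        else:
            raise ValueError(f"unknown relationship {kind!r}")

    geno = (h1 + h2).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING
    ids = [f"rs{c}_{i}" for c, i in zip(chrom, pos)]
    panel = GenotypePanel(samples, chrom, pos, ids, geno)
    truth["freqs"] = freqs
    return SyntheticCohortFixture(panel, truth)


def write_pedmap(panel: GenotypePanel, prefix) -> None:
    """Write the panel as text PED/MAP (alleles A/B, missing = 0)."""
    with open(f"{prefix}.map", "w") as fh:
        for c, i, p in zip(panel.chrom, panel.ids, panel.pos):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    code = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for s, row in zip(panel.samples, panel.genotypes):
            gts = " ".join(code[int(g)] for g in row)
            fh.write(f"FAM {s} 0 0 0 -9 {gts}\n")


# ---------------------------------------------------------------------------
# Annotated variant tables
# ---------------------------------------------------------------------------

_CLAUSES = ("genotype_quality", "depth_snp", "depth_indel", "gnomad_af", "cadd",
            "clinvar", "consequence")


def _independent_label(rec: Mapping) -> bool:
    """Straightforward restatement of the shortlist rule, used only for truth."""
    gq = rec["genotype_quality"] > 20
    dp = rec["depth"] > (5 if rec["variant_class"] == "SNP" else 10)
    af = rec["gnomad_af"] is None or rec["gnomad_af"] < 0.01
    cadd = rec["cadd"] is None or rec["cadd"] > 20
    clin = rec["clinvar"] not in ("Benign", "Likely_benign")
    altering = {"missense", "stop_gained", "frameshift", "inframe_deletion",
                "inframe_insertion", "start_lost", "stop_lost", "splice_donor",
                "splice_acceptor", "splice_region"}
    cons = bool(set(rec["consequences"].split(",")) & altering)
    if not cons and rec.get("splice_score") is not None:
        cons = rec["splice_score"] > 0.5
    return gq and dp and af and cadd and clin and cons


def _base_passing_record(rng, variant_class="SNP") -> dict:
    return {
        "chrom": f"chr{int(rng.integers(1, 23))}",
        "pos": int(rng.integers(10_000, 50_000_000)),
        "ref": "C", "alt": "T" if variant_class == "SNP" else "TAG",
        "variant_class": variant_class,
        "genotype_quality": float(rng.uniform(30, 60)),
        "depth": float(rng.uniform(15, 40)),
        "gnomad_af": float(rng.uniform(1e-6, 5e-3)),
        "cadd": float(rng.uniform(22, 40)),
        "clinvar": "VUS",
        "consequences": "missense",
        "splice_score": None,
    }


def gen_variant_table(seed: int = 0, n_records: int = 0, plan: str = "one_hot"):
    """Annotated variant table plus independently computed pass/fail labels.

    The ``one_hot`` plan emits, for each of the 7 filter clauses, one
    record failing exactly that clause, plus one record passing all
    clauses; ``n_records`` extra records are drawn at random across the
    clause boundaries.  Returns ``(DataFrame, labels)`` where labels come
    from a direct restatement of the rule, not from the filter engine.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    if plan == "one_hot":
        rows.append(_base_passing_record(rng))
        fail_specs = {
            "genotype_quality": {"genotype_quality": float(rng.uniform(0, 20))},
            "depth_snp": {"depth": float(rng.uniform(0, 5))},
            "depth_indel": {"variant_class": "InDel", "ref": "CAT", "alt": "C",
                            "depth": float(rng.uniform(6, 10)),
                            "consequences": "frameshift"},
            "gnomad_af": {"gnomad_af": float(rng.uniform(0.02, 0.5))},
            "cadd": {"cadd": float(rng.uniform(0, 19))},
            "clinvar": {"clinvar": "Benign"},
            "consequence": {"consequences": "synonymous,intronic"},
        }
        for clause, patch in fail_specs.items():
            rec = _base_passing_record(rng)
            rec.update(patch)
            rows.append(rec)
    elif plan != "random":
        raise ValueError(f"unknown plan {plan!r}")

    clinvar_pool = ["VUS", "Likely_pathogenic", "Pathogenic", "Conflicting",
                    "Benign", "Likely_benign", None]
    cons_pool = ["missense", "stop_gained", "frameshift", "splice_donor",
                 "splice_region", "synonymous", "intronic"]
    for _ in range(n_records):
        vclass = "SNP" if rng.random() < 0.7 else "InDel"
        rec = _base_passing_record(rng, vclass)
        rec["genotype_quality"] = float(rng.uniform(0, 60))
        rec["depth"] = float(rng.uniform(0, 40))
        rec["gnomad_af"] = None if rng.random() < 0.25 else float(10 ** rng.uniform(-6, -0.8))
        rec["cadd"] = None if rng.random() < 0.2 else float(rng.uniform(0, 45))
        rec["clinvar"] = clinvar_pool[int(rng.integers(len(clinvar_pool)))]
        n_cons = int(rng.integers(1, 3))
        rec["consequences"] = ",".join(
            sorted(rng.choice(cons_pool, size=n_cons, replace=False)))
        rec["splice_score"] = float(rng.uniform(0, 1)) if rng.random() < 0.3 else None
        rows.append(rec)

    labels = np.array([_independent_label(r) for r in rows], dtype=bool)
    columns = ["chrom", "pos", "ref", "alt", "variant_class", "genotype_quality",
               "depth", "gnomad_af", "cadd", "clinvar", "consequences", "splice_score"]
    df = pd.DataFrame(rows, columns=columns)
    return df, labels
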