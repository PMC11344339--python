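"""Pre-curation variant filtering and trio-based phasing/zygosity checks.

The filter reproduces a typical gene-panel shortlisting rule applied
before expert curation: genotype quality > 20; depth > 5 for SNPs and
> 10 for InDels; gnomAD allele frequency < 0.01; CADD > 20; ClinVar
classification not Benign/Likely benign; and at least one
protein-altering or splice-altering consequence.  Absent gnomAD/CADD
annotations pass their clause by default (novel variants must survive),
with a strict mode to fail them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotatedVariantRecord",
    "FilterConfig",
    "FilterReport",
    "TrioGenotypes",
    "passes_filters",
    "filter_table",
    "phase_by_parents",
    "inheritance_model_check",
    "PROTEIN_ALTERING",
    "SPLICE_ALTERING",
]

PROTEIN_ALTERING = frozenset({
    "missense", "stop_gained", "stop_lost", "start_lost", "frameshift",
    "inframe_deletion", "inframe_insertion", "nonsense", "protein_altering",
})
SPLICE_ALTERING = frozenset({
    "splice_donor", "splice_acceptor", "splice_region", "splice_donor_region",
    "splice_polypyrimidine_tract",
})
_BENIGN = frozenset({"Benign", "Likely_benign"})
_CLINVAR_LEVELS = frozenset({"Benign", "Likely_benign", "VUS", "Likely_pathogenic",
                             "Pathogenic", "Conflicting"})


@dataclass(frozen=True)
class AnnotatedVariantRecord:
    """One annotated variant call, as produced by an upstream annotation pipeline."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str                       # SNP | InDel
    genotype_quality: float
    depth: float
    gnomad_af: float | None = None
    cadd: float | None = None
    clinvar: str | None = None               # Benign/…/Conflicting or None
    consequences: frozenset = frozenset()
    splice_score: float | None = None        # e.g. a precomputed SpliceAI delta
    acmg: str = ""                           # free-text pass-through, not computed

    def __post_init__(self) -> None:
        if self.variant_class not in ("SNP", "InDel"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.depth < 0 or self.genotype_quality < 0:
            raise ValueError("depth and genotype_quality must be >= 0")
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError("gnomad_af must lie in [0,1]")
        if self.clinvar is not None and self.clinvar not in _CLINVAR_LEVELS:
            raise ValueError(f"unknown ClinVar classification {self.clinvar!r}")
        object.__setattr__(self, "consequences", frozenset(self.consequences))


@dataclass(frozen=True)
class FilterConfig:
    min_gq: float = 20.0
    min_dp_snp: float = 5.0
    min_dp_indel: float = 10.0
    max_gnomad_af: float = 0.01
    min_cadd: float = 20.0
    absent_af_passes: bool = True
    absent_cadd_passes: bool = True
    splice_score_cutoff: float | None = 0.5   # records above it count as splice-altering


@dataclass(frozen=True)
class FilterReport:
    passed: bool
    clauses: Mapping[str, bool]

    def failing_clauses(self) -> list[str]:
        return [k for k, ok in self.clauses.items() if not ok]


def passes_filters(rec: AnnotatedVariantRecord,
                   config: FilterConfig = FilterConfig()) -> FilterReport:
    """Apply the shortlisting filter; returns the verdict with a per-clause report.

    All clauses use strict inequalities (quality *greater than* 20 etc.).
    The consequence clause passes if any consequence label is
    protein-altering or splice-altering, or if a supplied splice score
    exceeds the configured cutoff.
    """
    gq_ok = rec.genotype_quality > config.min_gq
    dp_min = config.min_dp_snp if rec.variant_class == "SNP" else config.min_dp_indel
    dp_ok = rec.depth > dp_min
    if rec.gnomad_af is None:
        af_ok = config.absent_af_passes
    else:
        af_ok = rec.gnomad_af < config.max_gnomad_af
    if rec.cadd is None:
        cadd_ok = config.absent_cadd_passes
    else:
        cadd_ok = rec.cadd > config.min_cadd
    clinvar_ok = rec.clinvar not in _BENIGN        # Conflicting and absent are retained
    cons_ok = bool(rec.consequences & (PROTEIN_ALTERING | SPLICE_ALTERING))
    if not cons_ok and rec.splice_score is not None and config.splice_score_cutoff is not None:
        cons_ok = rec.splice_score > config.splice_score_cutoff
    clauses = {
        "genotype_quality": gq_ok,
        "depth": dp_ok,
        "gnomad_af": af_ok,
        "cadd": cadd_ok,
        "clinvar": clinvar_ok,
        "consequence": cons_ok,
    }
    return FilterReport(all(clauses.values()), clauses)


def record_from_row(row: Mapping) -> AnnotatedVariantRecord:
    """Build a record from a TSV row (pandas Series or dict)."""
    import pandas as pd

    def _num(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v in ("", "NA", "N/A", "."):
            return None
        return float(v)

    cons = row.get("consequences", "")
    if isinstance(cons, str):
        cons = frozenset(c.strip() for c in cons.replace("&", ",").split(",") if c.strip())
    clinvar = row.get("clinvar")
    if clinvar in ("", "NA", "N/A", ".", None) or (isinstance(clinvar, float) and pd.isna(clinvar)):
        clinvar = None
    return AnnotatedVariantRecord(
        chrom=str(row["chrom"]), pos=int(row["pos"]), ref=str(row["ref"]),
        alt=str(row["alt"]), variant_class=str(row["variant_class"]),
        genotype_quality=float(row["genotype_quality"]), depth=float(row["depth"]),
        gnomad_af=_num("gnomad_af"), cadd=_num("cadd"), clinvar=clinvar,
        consequences=cons, splice_score=_num("splice_score"),
        acmg=str(row.get("acmg", "") or ""))


def filter_table(df, config: FilterConfig = FilterConfig()):
    """Apply :func:`passes_filters` to an annotated variant table.

    Returns a copy with ``filter_pass`` (bool) and ``filter_audit`` (a
    semicolon-joined list of failing clauses, empty on pass).
    """
    out = df.copy()
    passes, audits = [], []
    for _, row in df.iterrows():
        rep = passes_filters(record_from_row(row), config)
        passes.append(rep.passed)
        audits.append(";".join(rep.failing_clauses()))
    out["filter_pass"] = passes
    out["filter_audit"] = audits
    return out


# ---------------------------------------------------------------------------
# Trio phasing and inheritance models
# ---------------------------------------------------------------------------

_GT_VALUES = ("ref", "het", "hom_alt", "hemi", "missing")


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotype calls for a proband and (optionally typed) parents.

    ``calls`` maps a variant key to ``(proband, mother, father)`` calls
    from {ref, het, hom_alt, hemi, missing}.  ``chromosome_context`` is
    "autosome" or "X"; hemizygous calls are only legal for male probands
    on X (or Y).
    """

    calls: Mapping[str, tuple[str, str, str]]
    proband_sex: str = "unknown"              # male | female | unknown
    chromosome_context: str = "autosome"      # autosome | X

    def __post_init__(self) -> None:
        for key, (p, m, f) in self.calls.items():
            for g in (p, m, f):
                if g not in _GT_VALUES:
                    raise ValueError(f"unknown genotype call {g!r} for {key}")
            if p == "hemi" and not (self.chromosome_context == "X" and
                                    self.proband_sex == "male"):
                raise ValueError(f"hemizygous proband call at {key} requires a male "
                                 "proband on X")

    def proband(self, key: str) -> str:
        return self.calls[key][0]

    def mother(self, key: str) -> str:
        return self.calls[key][1]

    def father(self, key: str) -> str:
        return self.calls[key][2]


def _carries(call: str) -> bool | None:
    """Does this parent carry the alternate allele?  None when untyped."""
    if call == "missing":
        return None
    return call in ("het", "hom_alt", "hemi")


def phase_by_parents(trio: TrioGenotypes, v1: str, v2: str) -> str:
    """Phase two heterozygous proband variants from parental carriage.

    ``in_trans`` iff one variant traces exclusively to the mother and the
    other exclusively to the father; ``in_cis`` iff both trace
    exclusively to the same parent; anything else (missing parent,
    a parent carrying both, apparent de novo) is ``ambiguous``.
    Symmetric in (v1, v2).
    """
    for v in (v1, v2):
        if trio.proband(v) != "het":
            raise ValueError(f"phasing requires the proband to be heterozygous at {v}")
    m1, f1 = _carries(trio.mother(v1)), _carries(trio.father(v1))
    m2, f2 = _carries(trio.mother(v2)), _carries(trio.father(v2))
    if None in (m1, f1, m2, f2):
        return "ambiguous"
    def origin(m, f):
        if m and not f:
            return "mat"
        if f and not m:
            return "pat"
        return None   # both, or neither (de novo)
    o1, o2 = origin(m1, f1), origin(m2, f2)
    if o1 is None or o2 is None:
        return "ambiguous"
    return "in_trans" if o1 != o2 else "in_cis"


def inheritance_model_check(trio: TrioGenotypes, variants: Sequence[str]) -> str:
    """Classify the inheritance pattern supported by the trio genotypes.

    Returns ``AR_hom`` (proband homozygous, typed parents het),
    ``XL_hemizygous`` (male proband hemizygous on X with carrier mother),
    ``AR_comp_het`` (two heterozygous variants phased in trans), or
    ``inconsistent`` (Mendelian violation or nothing supported).
    """
    if len(variants) == 1:
        v = variants[0]
        p = trio.proband(v)
        m, f = trio.mother(v), trio.father(v)
        if p == "hom_alt":
            for parent in (m, f):
                if parent == "ref":
                    return "inconsistent"
            return "AR_hom"
        if p == "hemi" and trio.chromosome_context == "X":
            if m in ("het", "hom_alt", "missing") and f != "hom_alt":
                return "XL_hemizygous"
            return "inconsistent"
        return "inconsistent"
    if len(variants) == 2:
        try:
            phase = phase_by_parents(trio, variants[0], variants[1])
        except ValueError:
            return "inconsistent"
        return "AR_comp_het" if phase == "in_trans" else "inconsistent"
    raise ValueError("inheritance_model_check expects 1 or 2 variants")
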