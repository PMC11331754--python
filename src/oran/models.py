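"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; the VCF
reader converts from the 1-based VCF convention at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

SUBGROUPS = ("WNT", "SHH", "Group3", "Group4")

MUTATION_CATEGORIES = ("SNV", "indel")
ANTIGEN_CATEGORIES = ("SNV", "indel", "fusion", "TAA")


class OranError(Exception):
    """Base class for pipeline errors."""


class ReferenceMismatchError(OranError):
    """A variant's REF allele disagrees with the genome sequence."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, to_stop: bool = True) -> str:
    """Translate a CDS with the standard genetic code.

    ``to_stop=True`` stops at the first stop codon (terminal stop symbol is
    never included).  Trailing nucleotides that do not fill a codon are
    ignored (relevant for frameshifted sequences).
    """
    usable = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:usable]).translate())
    if to_stop:
        stop = aa.find("*")
        if stop != -1:
            aa = aa[:stop]
    return aa


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    subgroup: str
    sex: str = "unknown"
    age_years: float | None = None
    vital_status: str = "unknown"
    os_days: float | None = None
    pfs_days: float | None = None
    hla_class_i: tuple[str, ...] = ()
    hla_class_ii: tuple[str, ...] = ()

    def __post_init__(self):
        if self.subgroup not in SUBGROUPS:
            raise ValueError(
                f"unknown subgroup {self.subgroup!r}; allowed: {', '.join(SUBGROUPS)}"
            )


@dataclass
class TranscriptModel:
    """Strand-aware CDS model.

    ``cds_segments`` are stored in *transcription* order (for '-' strand
    genes: descending genomic coordinate), each 0-based half-open on the
    forward genomic strand.  ``segment_seqs`` holds the forward-strand genome
    sequence of each segment; the spliced, strand-corrected CDS and protein
    are derived from them.  The CDS is expected to include the stop codon.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    segment_seqs: tuple[str, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for (s, e), seq in zip(self.cds_segments, self.segment_seqs):
            if e - s != len(seq):
                raise ValueError(
                    f"{self.transcript_id}: segment [{s},{e}) length does not "
                    f"match its sequence ({len(seq)} nt)"
                )
        self.segment_seqs = tuple(s.upper() for s in self.segment_seqs)

    @property
    def cds_sequence(self) -> str:
        if self.strand == "+":
            return "".join(self.segment_seqs)
        return "".join(revcomp(s) for s in self.segment_seqs)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def partial(self) -> bool:
        return self.cds_length % 3 != 0

    @property
    def ambiguous(self) -> bool:
        return any("N" in s for s in self.segment_seqs)

    @property
    def protein(self) -> str:
        """Protein without the terminal stop symbol ('' if partial)."""
        if self.partial:
            return ""
        return translate_cds(self.cds_sequence, to_stop=True)

    @property
    def internal_stop(self) -> bool:
        if self.partial:
            return False
        full = translate_cds(self.cds_sequence, to_stop=False)
        return "*" in full[:-1]

    @property
    def usable(self) -> bool:
        """Eligible for peptide operations."""
        return not (self.partial or self.ambiguous or self.internal_stop)


@dataclass(frozen=True)
class Variant:
    patient_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    rna_vaf: float

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.rna_vaf <= 1.0:
            raise ValueError(f"rna_vaf {self.rna_vaf} outside [0, 1]")

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt):
            return "insertion"
        if len(self.ref) > len(self.alt):
            return "deletion"
        raise ValueError("MNV records must be skipped at ingest")

    @property
    def category(self) -> str:
        return "SNV" if self.vtype == "SNV" else "indel"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class FusionEvent:
    patient_id: str
    left_gene: str
    left_transcript: str
    left_breakpoint: int  # 1-based CDS coordinate: last retained base
    right_gene: str
    right_transcript: str
    right_breakpoint: int  # 1-based CDS coordinate: first retained base
    junction_reads: int = 0

    def __post_init__(self):
        if self.left_gene == self.right_gene:
            raise ValueError("self-fusion (left_gene == right_gene)")
        if self.left_breakpoint < 1 or self.right_breakpoint < 1:
            raise ValueError("CDS breakpoints are 1-based and must be >= 1")

    @property
    def id(self) -> str:
        return (
            f"{self.left_gene}--{self.right_gene}:"
            f"{self.left_breakpoint}-{self.right_breakpoint}"
        )

    @property
    def gene_pair(self) -> str:
        """Unordered gene-symbol pair used as landscape antigen identity."""
        return "--".join(sorted((self.left_gene, self.right_gene)))


class ExpressionMatrix:
    """A TPM table (features x samples) with a transcript->gene map.

    Thin wrapper around a pandas DataFrame so that validation and the
    gene-level summation rule live in one place.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        level: str,
        feature_map: Mapping[str, tuple[str, str]] | None = None,
    ):
        if level not in ("transcript", "gene"):
            raise ValueError("level must be 'transcript' or 'gene'")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups}")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative TPM values are not allowed")
        if level == "transcript":
            if feature_map is None:
                raise ValueError("transcript-level matrix requires a feature_map")
            missing = [t for t in values.index if t not in feature_map]
            if missing:
                raise ValueError(f"transcripts missing gene mapping: {missing}")
        self.values = values.astype(float)
        self.level = level
        self.feature_map = dict(feature_map) if feature_map else {}

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_level(self) -> "ExpressionMatrix":
        """Gene TPM = sum of its transcript TPMs (identity at gene level)."""
        if self.level == "gene":
            return self
        gene_ids = pd.Series(
            {t: self.feature_map[t][0] for t in self.values.index}
        )
        summed = self.values.groupby(gene_ids).sum()
        return ExpressionMatrix(summed, "gene")

    def gene_symbols(self) -> dict[str, str]:
        return {g: sym for g, sym in self.feature_map.values()}


@dataclass
class MutantProteinPair:
    variant_id: str
    transcript_id: str
    ref_protein: str
    mut_protein: str
    altered_span: tuple[int, int]  # 0-based [start, end) on mut_protein
    consequence: str  # synonymous|missense|inframe_ins|inframe_del|frameshift|stop_gain|stop_loss


@dataclass
class FusionProtein:
    fusion_id: str
    protein: str
    junction_index: int  # first residue using any right-partner nucleotide
    frame: str  # in_frame | frameshift
    novel_span: tuple[int, int]
    left_protein: str = ""
    right_protein: str = ""
    truncated_before_junction: bool = False


@dataclass
class EpitopeCandidate:
    patient_id: str
    peptide: str
    mhc_class: str  # "I" | "II"
    allele: str
    ic50_nM: float
    category: str  # SNV | indel | fusion | TAA
    source_id: str
    gene_symbol: str
    rna_vaf: float | None = None  # mutations only
    expression_tpm: float = 0.0
    novel: bool | None = None

    def __post_init__(self):
        self.peptide = self.peptide.upper()
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"mhc_class must be I or II, got {self.mhc_class}")
        if self.ic50_nM <= 0:
            raise ValueError("ic50_nM must be positive")
        if self.category not in ANTIGEN_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class AntigenCall:
    """One immunogenic mutation / fusion / TAA for one patient and MHC class.

    A source harbouring several passing epitopes is still a single antigen.
    """

    patient_id: str
    mhc_class: str
    category: str
    source_id: str
    gene_symbol: str
    n_epitopes: int
    best_ic50_nM: float

    def __post_init__(self):
        if self.n_epitopes < 1:
            raise ValueError("an antigen call requires >= 1 epitope")


def dedupe_alleles(alleles: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for a in alleles:
        a = a.strip()
        if a and a not in seen:
            seen[a] = None
    return tuple(seen)
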