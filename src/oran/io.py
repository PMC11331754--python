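"""Readers and writers for every external format the pipeline touches.

TSV dialects are documented next to each reader; VCF is read with pysam,
GTF with gffutils, FASTA with pyfaidx / Biopython.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from pyfaidx import Fasta

from .models import (
    AntigenCall,
    EpitopeCandidate,
    ExpressionMatrix,
    FusionEvent,
    OranError,
    PatientRecord,
    TranscriptModel,
    Variant,
    dedupe_alleles,
)

log = logging.getLogger("oran")

_MANIFEST_COLUMNS = [
    "patient_id",
    "subgroup",
    "sex",
    "age",
    "vital_status",
    "os_days",
    "pfs_days",
    "hla_i",
    "hla_ii",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan", "."):
        return None
    return float(s)


def read_cohort_manifest(path: str | Path) -> list[PatientRecord]:
    """Read the cohort manifest TSV (one row per patient).

    Columns: patient_id, subgroup, sex, age, vital_status, os_days,
    pfs_days, hla_i (semicolon-joined class-I alleles), hla_ii.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise OranError(f"manifest missing mandatory column(s): {', '.join(missing)}")
    dup = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dup:
        raise OranError(f"duplicate patient_id(s) in manifest: {', '.join(dup)}")
    records = []
    for _, row in df.iterrows():
        vital = str(row["vital_status"]).strip()
        if vital not in ("alive", "deceased"):
            vital = "unknown"
        sex = str(row["sex"]).strip()
        if sex not in ("M", "F"):
            sex = "unknown"
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                subgroup=str(row["subgroup"]).strip(),
                sex=sex,
                age_years=_opt_float(row["age"]),
                vital_status=vital,
                os_days=_opt_float(row["os_days"]),
                pfs_days=_opt_float(row["pfs_days"]),
                hla_class_i=dedupe_alleles(str(row["hla_i"] or "").split(";")),
                hla_class_ii=dedupe_alleles(str(row["hla_ii"] or "").split(";")),
            )
        )
    return records


def write_cohort_manifest(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "subgroup": r.subgroup,
                "sex": r.sex,
                "age": "" if r.age_years is None else r.age_years,
                "vital_status": r.vital_status,
                "os_days": "" if r.os_days is None else r.os_days,
                "pfs_days": "" if r.pfs_days is None else r.pfs_days,
                "hla_i": ";".join(r.hla_class_i),
                "hla_ii": ";".join(r.hla_class_ii),
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcript_models(
    gtf_path: str | Path, genome_fasta_path: str | Path
) -> list[TranscriptModel]:
    """Build strand-aware transcript models from GTF CDS features + genome.

    The CDS (including the stop codon) is spliced strand-aware; models whose
    total CDS length is not divisible by 3 are flagged partial, models with
    internal stops or ambiguous bases are flagged and excluded from peptide
    operations via ``TranscriptModel.usable``.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genome = Fasta(str(genome_fasta_path), as_raw=True, sequence_always_upper=True)
    by_tx: dict[str, list[gffutils.Feature]] = {}
    for feat in db.features_of_type("CDS"):
        tx = feat.attributes["transcript_id"][0]
        by_tx.setdefault(tx, []).append(feat)
    models = []
    for tx_id in sorted(by_tx):
        feats = sorted(by_tx[tx_id], key=lambda f: f.start)
        chrom = feats[0].seqid
        if chrom not in genome:
            raise OranError(f"{tx_id}: CDS references absent contig {chrom!r}")
        strand = feats[0].strand
        segments = tuple((f.start - 1, f.end) for f in feats)  # GTF is 1-based inclusive
        if strand == "-":
            segments = tuple(reversed(segments))
        seqs = tuple(str(genome[chrom][s:e]) for s, e in segments)
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=feats[0].attributes["gene_id"][0],
            gene_symbol=feats[0].attributes.get("gene_name", [feats[0].attributes["gene_id"][0]])[0],
            chrom=chrom,
            strand=strand,
            cds_segments=segments,
            segment_seqs=seqs,
        )
        if model.partial:
            log.warning("%s: CDS length %d not divisible by 3; flagged partial", tx_id, model.cds_length)
        elif model.internal_stop:
            log.warning("%s: internal stop codon; excluded from peptide ops", tx_id)
        elif model.ambiguous:
            log.warning("%s: ambiguous nucleotides in CDS; excluded", tx_id)
        models.append(model)
    return models


def read_vcf(path: str | Path, patient_id: str, vaf_key: str = "RVAF") -> list[Variant]:
    """Read somatic SNV/indel calls from a VCF 4.1 file.

    RNA-VAF is taken from INFO key ``vaf_key``.  MNVs (len(ref)==len(alt)>1)
    are skipped with a warning, as are records without a VAF.
    """
    variants: list[Variant] = []
    n_mnv = n_novaf = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == len(alt) > 1:
                    n_mnv += 1
                    continue
                if vaf_key not in rec.info:
                    n_novaf += 1
                    continue
                vaf = rec.info[vaf_key]
                if isinstance(vaf, tuple):
                    vaf = vaf[0]
                vaf = round(float(vaf), 6)  # htslib stores INFO floats as float32
                variants.append(
                    Variant(
                        patient_id=patient_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        rna_vaf=float(vaf),
                    )
                )
    if n_mnv:
        log.warning("%s: skipped %d MNV record(s)", path, n_mnv)
    if n_novaf:
        log.warning("%s: skipped %d record(s) lacking INFO/%s", path, n_novaf, vaf_key)
    return variants


def write_vcf(variants: Iterable[Variant], path: str | Path, contigs: Iterable[str] = ()) -> None:
    """Write a minimal VCF 4.1 with the RVAF INFO key."""
    lines = [
        "##fileformat=VCFv4.1",
        '##INFO=<ID=RVAF,Number=1,Type=Float,Description="RNA variant allele fraction">',
    ]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tRVAF={v.rna_vaf:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_table(path: str | Path, level: str) -> ExpressionMatrix:
    """Read a TPM table.

    Transcript level: columns transcript_id, gene_id, gene_symbol, then one
    column per sample.  Gene level: columns gene_id then samples.
    """
    df = pd.read_csv(path, sep="\t")
    if level == "transcript":
        meta_cols = ["transcript_id", "gene_id", "gene_symbol"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise OranError(f"expression table missing column(s): {', '.join(missing)}")
        feature_map = {
            r.transcript_id: (r.gene_id, r.gene_symbol) for r in df.itertuples()
        }
        values = df.set_index("transcript_id").drop(columns=["gene_id", "gene_symbol"])
        return ExpressionMatrix(values, "transcript", feature_map)
    if "gene_id" not in df.columns:
        raise OranError("gene-level expression table must have a gene_id column")
    return ExpressionMatrix(df.set_index("gene_id"), "gene")


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    if matrix.level == "transcript":
        df.insert(0, "gene_symbol", [matrix.feature_map[t][1] for t in df.index])
        df.insert(0, "gene_id", [matrix.feature_map[t][0] for t in df.index])
        df.index.name = "transcript_id"
    else:
        df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


_FUSION_COLUMNS = [
    "fusion_name",
    "junction_reads",
    "left_gene",
    "left_transcript",
    "left_cds_break",
    "right_gene",
    "right_transcript",
    "right_cds_break",
]


def read_fusion_calls(path: str | Path, patient_id: str) -> list[FusionEvent]:
    """Read fusion calls (STAR-Fusion-style TSV dialect, CDS breakpoints)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise OranError(f"fusion table missing column(s): {', '.join(missing)}")
    events = []
    for row in df.itertuples():
        if row.left_gene == row.right_gene:
            log.warning("%s: skipped self-fusion of %s", path, row.left_gene)
            continue
        try:
            reads = int(row.junction_reads)
        except (TypeError, ValueError):
            raise OranError(
                f"{path}: junction_reads {row.junction_reads!r} is not an integer"
            ) from None
        events.append(
            FusionEvent(
                patient_id=patient_id,
                left_gene=row.left_gene,
                left_transcript=row.left_transcript,
                left_breakpoint=int(row.left_cds_break),
                right_gene=row.right_gene,
                right_transcript=row.right_transcript,
                right_breakpoint=int(row.right_cds_break),
                junction_reads=reads,
            )
        )
    return events


def write_fusion_calls(events: Iterable[FusionEvent], path: str | Path) -> None:
    rows = [
        {
            "fusion_name": f"{e.left_gene}--{e.right_gene}",
            "junction_reads": e.junction_reads,
            "left_gene": e.left_gene,
            "left_transcript": e.left_transcript,
            "left_cds_break": e.left_breakpoint,
            "right_gene": e.right_gene,
            "right_transcript": e.right_transcript,
            "right_cds_break": e.right_breakpoint,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_proteome(path: str | Path, require_gene: bool = False) -> list[tuple[str, str, str]]:
    """Read a proteome FASTA with the ``>prot_id gene=SYMBOL`` header dialect.

    Returns (protein_id, gene_symbol, sequence) tuples; gene_symbol is ''
    when the tag is absent (an error if ``require_gene``).
    """
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = ""
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        if require_gene and not gene:
            raise OranError(
                f"proteome entry {rec.id!r} lacks a gene=<symbol> tag (required for TAA mode)"
            )
        entries.append((rec.id, gene, str(rec.seq).upper()))
    return entries


def read_ms_peptides(path: str | Path) -> pd.DataFrame:
    """Read MS-identified peptides: columns patient_id, peptide, probability."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("patient_id", "peptide", "probability") if c not in df.columns]
    if missing:
        raise OranError(f"MS peptide table missing column(s): {', '.join(missing)}")
    df["peptide"] = df["peptide"].str.upper()
    return df


EPITOPE_REPORT_COLUMNS = [
    "patient_id",
    "mhc_class",
    "category",
    "source_id",
    "gene_symbol",
    "peptide",
    "allele",
    "ic50_nM",
    "novel",
]

ANTIGEN_REPORT_COLUMNS = [
    "patient_id",
    "mhc_class",
    "category",
    "source_id",
    "gene_symbol",
    "n_epitopes",
    "best_ic50_nM",
]


def epitopes_to_frame(epitopes: Iterable[EpitopeCandidate]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "mhc_class": e.mhc_class,
            "category": e.category,
            "source_id": e.source_id,
            "gene_symbol": e.gene_symbol,
            "peptide": e.peptide,
            "allele": e.allele,
            "ic50_nM": round(e.ic50_nM, 4),
            "novel": bool(e.novel) if e.novel is not None else True,
        }
        for e in epitopes
    ]
    df = pd.DataFrame(rows, columns=EPITOPE_REPORT_COLUMNS)
    return df.sort_values(
        ["patient_id", "category", "gene_symbol", "peptide", "allele"]
    ).reset_index(drop=True)


def calls_to_frame(calls: Iterable[AntigenCall]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "mhc_class": c.mhc_class,
            "category": c.category,
            "source_id": c.source_id,
            "gene_symbol": c.gene_symbol,
            "n_epitopes": c.n_epitopes,
            "best_ic50_nM": round(c.best_ic50_nM, 4),
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=ANTIGEN_REPORT_COLUMNS)
    return df.sort_values(
        ["patient_id", "category", "gene_symbol", "source_id", "mhc_class"]
    ).reset_index(drop=True)


def frame_to_calls(df: pd.DataFrame) -> list[AntigenCall]:
    return [
        AntigenCall(
            patient_id=r.patient_id,
            mhc_class=r.mhc_class,
            category=r.category,
            source_id=r.source_id,
            gene_symbol=r.gene_symbol,
            n_epitopes=int(r.n_epitopes),
            best_ic50_nM=float(r.best_ic50_nM),
        )
        for r in df.itertuples()
    ]


def write_antigen_report(
    calls: Iterable[AntigenCall],
    epitopes: Iterable[EpitopeCandidate],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the epitope-level and antigen-level TSVs with deterministic order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epitope_path = out / "epitopes.tsv"
    antigen_path = out / "antigens.tsv"
    epitopes_to_frame(epitopes).to_csv(epitope_path, sep="\t", index=False)
    calls_to_frame(calls).to_csv(antigen_path, sep="\t", index=False)
    return epitope_path, antigen_path
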