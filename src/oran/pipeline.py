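"""End-to-end orchestration: inputs -> epitopes -> antigen calls.

Each antigen class runs the same skeleton: enumerate candidate peptides,
score them against the patient's HLA alleles, apply the strict filter
cascade, screen for proteome novelty, then aggregate passing epitopes into
one antigen call per (patient, MHC class, source).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .binding import (
    AffinityBackend,
    ProteomeIndex,
    filter_epitopes,
    make_backend,
    novelty_filter,
    predict_affinity,
)
from .config import PipelineConfig
from .fusions import build_fusion_protein, extract_fusion_peptides
from .io import (
    read_cohort_manifest,
    read_expression_table,
    read_fusion_calls,
    read_ms_peptides,
    read_proteome,
    read_transcript_models,
    read_vcf,
    write_antigen_report,
)
from .models import (
    AntigenCall,
    EpitopeCandidate,
    ExpressionMatrix,
    FusionEvent,
    OranError,
    PatientRecord,
    TranscriptModel,
    Variant,
)
from .taa import (
    NormalPanelStats,
    TAACategory,
    classify_taa_category,
    compute_normal_stats,
    enumerate_tag_peptides,
    identify_tags,
)
from .variants import call_neoantigens, mutation_peptides_for_variant

log = logging.getLogger("oran")


@dataclass
class PipelineInputs:
    patients: list[PatientRecord]
    transcripts: list[TranscriptModel]
    proteome: list[tuple[str, str, str]]
    panel: ExpressionMatrix
    organ_map: dict[str, str]
    tumor_expr: ExpressionMatrix
    variants: dict[str, list[Variant]]
    fusions: dict[str, list[FusionEvent]]
    ms_peptides: pd.DataFrame | None = None


def load_inputs(input_dir: str | Path) -> PipelineInputs:
    """Load the standard input layout (as emitted by the simulator)."""
    d = Path(input_dir)
    patients = read_cohort_manifest(d / "manifest.tsv")
    transcripts = read_transcript_models(d / "annotation.gtf", d / "genome.fa")
    proteome = read_proteome(d / "proteome.fa")
    panel = read_expression_table(d / "normal_panel.tsv", "gene")
    organ_map = dict(
        pd.read_csv(d / "organ_map.tsv", sep="\t").itertuples(index=False, name=None)
    )
    tumor = read_expression_table(d / "tumor_expression.tsv", "transcript")
    variants = {}
    fusions = {}
    for p in patients:
        vcf_path = d / "vcf" / f"{p.patient_id}.vcf"
        variants[p.patient_id] = read_vcf(vcf_path, p.patient_id) if vcf_path.exists() else []
        fus_path = d / "fusions" / f"{p.patient_id}.tsv"
        fusions[p.patient_id] = (
            read_fusion_calls(fus_path, p.patient_id) if fus_path.exists() else []
        )
    ms_path = d / "ms_peptides.tsv"
    ms = read_ms_peptides(ms_path) if ms_path.exists() else None
    return PipelineInputs(
        patients=patients,
        transcripts=transcripts,
        proteome=proteome,
        panel=panel,
        organ_map=organ_map,
        tumor_expr=tumor,
        variants=variants,
        fusions=fusions,
        ms_peptides=ms,
    )


def inputs_from_cohort(cohort) -> PipelineInputs:
    """Adapt an in-memory synthetic cohort bundle."""
    return PipelineInputs(
        patients=cohort.patients,
        transcripts=cohort.transcripts,
        proteome=cohort.proteome,
        panel=cohort.panel,
        organ_map=cohort.organ_map,
        tumor_expr=cohort.tumor_expr,
        variants=cohort.variants,
        fusions=cohort.fusions,
        ms_peptides=cohort.ms_peptides,
    )


@dataclass
class PipelineResult:
    epitopes: list[EpitopeCandidate]
    calls: list[AntigenCall]
    tag_records: list = field(default_factory=list)
    taa_categories: dict[str, TAACategory] = field(default_factory=dict)
    normal_stats: NormalPanelStats | None = None

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        write_antigen_report(self.calls, self.epitopes, out)
        if self.tag_records:
            pd.DataFrame(
                [
                    {
                        "patient_id": t.patient_id,
                        "gene_id": t.gene_id,
                        "gene_symbol": t.gene_symbol,
                        "tumor_gene_tpm": round(t.tumor_gene_tpm, 4),
                        "top_transcript_id": t.top_transcript_id,
                        "top_transcript_tpm": round(t.top_transcript_tpm, 4),
                        "normal_max": round(t.normal_max, 4),
                        "qualifies": t.qualifies,
                        "unverified_normal": t.unverified_normal,
                    }
                    for t in self.tag_records
                    if t.qualifies
                ]
            ).sort_values(["patient_id", "gene_id"]).to_csv(
                out / "tags.tsv", sep="\t", index=False
            )
        if self.taa_categories:
            pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "category": c.category,
                        "testis_hi": round(c.testis_hi, 4),
                        "fetal_hi": round(c.fetal_hi, 4),
                    }
                    for _g, c in sorted(self.taa_categories.items())
                ]
            ).to_csv(out / "taa_categories.tsv", sep="\t", index=False)
        return out


class AntigenPipeline:
    """Runs the antigen-discovery stages over a cohort."""

    def __init__(
        self,
        inputs: PipelineInputs,
        config: PipelineConfig | None = None,
        predictor: str | AffinityBackend = "surrogate",
    ):
        self.inputs = inputs
        self.config = config or PipelineConfig()
        self.backend = (
            predictor
            if not isinstance(predictor, str)
            else make_backend(predictor, self.config.surrogate_salt)
        )
        self.proteome_index = ProteomeIndex(inputs.proteome)
        self.tx_by_id = {t.transcript_id: t for t in inputs.transcripts}
        self.gene_tpm = inputs.tumor_expr.gene_level().values

    # ------------------------------------------------------------------ #
    def _alleles(self, patient: PatientRecord, mhc_class: str) -> tuple[str, ...]:
        return patient.hla_class_i if mhc_class == "I" else patient.hla_class_ii

    def _expressed_overlapping_transcripts(
        self, variant: Variant, patient_id: str
    ) -> list[TranscriptModel]:
        out = []
        col = self.inputs.tumor_expr.values[patient_id]
        for tx in self.inputs.transcripts:
            if tx.chrom != variant.chrom or not tx.usable:
                continue
            if not any(s <= variant.pos0 < e for s, e in tx.cds_segments):
                continue
            tpm = float(col.get(tx.transcript_id, 0.0))
            if tpm > self.config.tpm_min:
                out.append(tx)
        return sorted(out, key=lambda t: t.transcript_id)

    def run_mutations(self, mhc_classes: tuple[str, ...] = ("I", "II")) -> list[EpitopeCandidate]:
        passing: list[EpitopeCandidate] = []
        for patient in self.inputs.patients:
            for variant in self.inputs.variants.get(patient.patient_id, []):
                txs = self._expressed_overlapping_transcripts(variant, patient.patient_id)
                if not txs:
                    continue
                gene_tpm = max(
                    float(self.gene_tpm.loc[t.gene_id, patient.patient_id]) for t in txs
                )
                gene_symbol = txs[0].gene_symbol
                for mhc_class in mhc_classes:
                    peptides = mutation_peptides_for_variant(
                        variant, txs, mhc_class, self.config
                    )
                    if not peptides:
                        continue
                    candidates = predict_affinity(
                        peptides,
                        self._alleles(patient, mhc_class),
                        self.backend,
                        patient_id=patient.patient_id,
                        mhc_class=mhc_class,
                        category=variant.category,
                        source_id=variant.id,
                        gene_symbol=gene_symbol,
                        rna_vaf=variant.rna_vaf,
                        expression_tpm=gene_tpm,
                    )
                    kept = filter_epitopes(candidates, self.config)
                    passing.extend(novelty_filter(kept, self.proteome_index, "neoantigen"))
        return passing

    def run_fusions(self, mhc_classes: tuple[str, ...] = ("I", "II")) -> list[EpitopeCandidate]:
        passing: list[EpitopeCandidate] = []
        for patient in self.inputs.patients:
            col = self.gene_tpm[patient.patient_id]
            for event in self.inputs.fusions.get(patient.patient_id, []):
                fp = build_fusion_protein(event, self.tx_by_id)
                left_gene = self.tx_by_id[event.left_transcript].gene_id
                right_gene = self.tx_by_id[event.right_transcript].gene_id
                tpm = min(float(col.get(left_gene, 0.0)), float(col.get(right_gene, 0.0)))
                for mhc_class in mhc_classes:
                    peptides = extract_fusion_peptides(fp, mhc_class, self.config)
                    if not peptides:
                        continue
                    candidates = predict_affinity(
                        peptides,
                        self._alleles(patient, mhc_class),
                        self.backend,
                        patient_id=patient.patient_id,
                        mhc_class=mhc_class,
                        category="fusion",
                        source_id=event.id,
                        gene_symbol=f"{event.left_gene}--{event.right_gene}",
                        expression_tpm=tpm,
                    )
                    kept = filter_epitopes(candidates, self.config)
                    passing.extend(novelty_filter(kept, self.proteome_index, "neoantigen"))
        return passing

    def run_taas(
        self, mhc_classes: tuple[str, ...] = ("I", "II")
    ) -> tuple[list[EpitopeCandidate], list, NormalPanelStats]:
        stats = compute_normal_stats(self.inputs.panel, self.inputs.organ_map)
        passing: list[EpitopeCandidate] = []
        all_tags = []
        for patient in self.inputs.patients:
            records = identify_tags(
                self.inputs.tumor_expr, stats, patient.patient_id, self.config
            )
            all_tags.extend(records)
            for tag in records:
                if not tag.qualifies:
                    continue
                for mhc_class in mhc_classes:
                    peptides = enumerate_tag_peptides(
                        tag,
                        self.inputs.transcripts,
                        self.inputs.tumor_expr,
                        mhc_class,
                        self.config,
                    )
                    if not peptides:
                        continue
                    candidates = predict_affinity(
                        peptides,
                        self._alleles(patient, mhc_class),
                        self.backend,
                        patient_id=patient.patient_id,
                        mhc_class=mhc_class,
                        category="TAA",
                        source_id=tag.gene_id,
                        gene_symbol=tag.gene_symbol,
                        expression_tpm=tag.tumor_gene_tpm,
                    )
                    kept = filter_epitopes(candidates, self.config)
                    passing.extend(novelty_filter(kept, self.proteome_index, "TAA"))
        return passing, all_tags, stats

    def run(
        self,
        categories: tuple[str, ...] = ("mutation", "fusion", "TAA"),
        mhc_classes: tuple[str, ...] = ("I", "II"),
    ) -> PipelineResult:
        epitopes: list[EpitopeCandidate] = []
        tag_records: list = []
        taa_categories: dict[str, TAACategory] = {}
        stats = None
        if "mutation" in categories:
            epitopes.extend(self.run_mutations(mhc_classes))
        if "fusion" in categories:
            epitopes.extend(self.run_fusions(mhc_classes))
        if "TAA" in categories:
            taa_epitopes, tag_records, stats = self.run_taas(mhc_classes)
            epitopes.extend(taa_epitopes)
            immunogenic_genes = sorted(
                {e.source_id for e in taa_epitopes}
            )
            taa_categories = {
                g: classify_taa_category(g, stats, self.config) for g in immunogenic_genes
            }
        calls = call_neoantigens(epitopes)
        return PipelineResult(
            epitopes=epitopes,
            calls=calls,
            tag_records=tag_records,
            taa_categories=taa_categories,
            normal_stats=stats,
        )


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    predictor: str | AffinityBackend = "surrogate",
    categories: tuple[str, ...] = ("mutation", "fusion", "TAA"),
) -> PipelineResult:
    """Convenience wrapper: build the pipeline and run all stages."""
    return AntigenPipeline(inputs, config, predictor).run(categories)
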