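"""Tumor-associated gene (TAG) discovery from expression outliers.

A gene qualifies as a TAG in a patient when its normal-tissue ceiling
(the max over organs of mu + 2*sigma of panel TPM, testis and fetal
cerebellum held out) is below 1 TPM while in the tumor both the gene TPM
(sum over isoforms) and the top isoform TPM exceed 1.  Immunogenic TAGs
(TAAs) are classified cancer-testis (CTA) when also expressed in adult
testis, oncofetal when shared with fetal cerebellum instead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .models import ExpressionMatrix, OranError, TranscriptModel
from .peptides import all_kmers

log = logging.getLogger("oran")

HELD_OUT_ORGANS = ("testis", "fetal_cerebellum")


@dataclass
class NormalPanelStats:
    """Per-gene, per-organ mu / sigma / hi = mu + 2*sigma summaries.

    ``normal_max`` is the max of ``hi`` across the included organ panel;
    testis and fetal cerebellum are held out and kept separately for
    CTA / oncofetal classification.
    """

    mu: pd.DataFrame  # genes x organs (included panel only)
    sigma: pd.DataFrame
    hi: pd.DataFrame
    normal_max: pd.Series  # per gene
    testis_hi: pd.Series
    fetal_hi: pd.Series

    def normal_max_for(self, gene_id: str) -> float:
        if gene_id in self.normal_max.index:
            return float(self.normal_max[gene_id])
        log.warning("gene %s absent from normal panel; normal_max defaults to 0", gene_id)
        return 0.0

    def held_out_hi(self, gene_id: str) -> tuple[float, float]:
        testis = float(self.testis_hi.get(gene_id, 0.0))
        fetal = float(self.fetal_hi.get(gene_id, 0.0))
        return testis, fetal


@dataclass
class TAGRecord:
    patient_id: str
    gene_id: str
    gene_symbol: str
    tumor_gene_tpm: float
    top_transcript_id: str
    top_transcript_tpm: float
    normal_max: float
    qualifies: bool
    unverified_normal: bool = False


@dataclass(frozen=True)
class TAACategory:
    gene_id: str
    category: str  # CTA | oncofetal | other
    testis_hi: float
    fetal_hi: float


def compute_normal_stats(
    panel: ExpressionMatrix, organ_labels: Mapping[str, str]
) -> NormalPanelStats:
    """Summarise the normal panel at gene level.

    sigma is the sample standard deviation (n-1 denominator); single-sample
    organs get sigma = 0 with a logged caveat.  Organs named "testis" and
    "fetal_cerebellum" are routed to the held-out statistics.
    """
    gene = panel.gene_level()
    unlabelled = [s for s in gene.samples if s not in organ_labels]
    if unlabelled:
        raise OranError(f"unlabelled panel sample(s): {', '.join(unlabelled)}")
    organs = pd.Series({s: organ_labels[s] for s in gene.samples})
    grouped = gene.values.T.groupby(organs)
    mu = grouped.mean().T
    sigma = grouped.std(ddof=1).fillna(0.0).T
    for organ, n in grouped.size().items():
        if n == 1:
            log.warning("organ %r has a single sample; sigma set to 0", organ)
    hi = mu + 2.0 * sigma
    included = [o for o in hi.columns if o not in HELD_OUT_ORGANS]
    if not included:
        raise OranError("normal panel has no organs beyond the held-out pair")
    return NormalPanelStats(
        mu=mu[included],
        sigma=sigma[included],
        hi=hi[included],
        normal_max=hi[included].max(axis=1),
        testis_hi=hi["testis"] if "testis" in hi.columns else pd.Series(dtype=float),
        fetal_hi=hi["fetal_cerebellum"]
        if "fetal_cerebellum" in hi.columns
        else pd.Series(dtype=float),
    )


def identify_tags(
    tumor_expr: ExpressionMatrix,
    stats: NormalPanelStats,
    patient_id: str,
    config: PipelineConfig,
) -> list[TAGRecord]:
    """Apply the three TAG rules to one patient column.

    qualifies = normal_max < 1 (strict) AND gene TPM > 1 (strict) AND top
    isoform TPM > 1 (strict); ties always disqualify.  Returns a record for
    every gene (the qualifying subset is ``[r for r in out if r.qualifies]``).
    """
    if tumor_expr.level != "transcript":
        raise OranError("identify_tags requires a transcript-level tumor matrix")
    if patient_id not in tumor_expr.values.columns:
        raise OranError(f"patient {patient_id!r} absent from tumor expression matrix")
    col = tumor_expr.values[patient_id].to_dict()
    by_gene: dict[str, list[str]] = {}
    for tx in tumor_expr.values.index:
        by_gene.setdefault(tumor_expr.feature_map[tx][0], []).append(tx)
    known_genes = set(stats.normal_max.index)
    records = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        tpms = [float(col[t]) for t in txs]
        top_tpm = max(tpms)
        top_tx = txs[tpms.index(top_tpm)]
        unverified = gene_id not in known_genes
        normal_max = stats.normal_max_for(gene_id)
        gene_tpm = float(sum(tpms))
        qualifies = (
            normal_max < config.normal_max_lt
            and gene_tpm > config.tpm_min
            and top_tpm > config.tpm_min
        )
        records.append(
            TAGRecord(
                patient_id=patient_id,
                gene_id=gene_id,
                gene_symbol=tumor_expr.feature_map[txs[0]][1],
                tumor_gene_tpm=gene_tpm,
                top_transcript_id=top_tx,
                top_transcript_tpm=top_tpm,
                normal_max=normal_max,
                qualifies=qualifies,
                unverified_normal=unverified,
            )
        )
    return records


def enumerate_tag_peptides(
    tag: TAGRecord,
    transcripts: Sequence[TranscriptModel],
    tumor_expr: ExpressionMatrix,
    mhc_class: str,
    config: PipelineConfig,
) -> set[tuple[str, int]]:
    """All k-mers (class I: 9-12; class II: 15) over every expressed
    isoform's protein, deduplicated across isoforms."""
    if not tag.qualifies:
        return set()
    col = tumor_expr.values[tag.patient_id]
    lengths = config.lengths_for(mhc_class, "TAA")
    peptides: set[tuple[str, int]] = set()
    n_coding = 0
    for tx in transcripts:
        if tx.gene_id != tag.gene_id or not tx.usable:
            continue
        if tx.transcript_id in col.index and col[tx.transcript_id] <= config.tpm_min:
            continue
        n_coding += 1
        for k in lengths:
            peptides |= all_kmers(tx.protein, k)
    if n_coding == 0:
        log.warning("TAG %s has no expressed non-partial coding transcript", tag.gene_id)
    return peptides


def classify_taa_category(
    gene_id: str, stats: NormalPanelStats, config: PipelineConfig
) -> TAACategory:
    """CTA if testis hi > 1 TPM; else oncofetal if fetal hi > 1; else other."""
    testis, fetal = stats.held_out_hi(gene_id)
    if testis > config.tpm_min:
        category = "CTA"
    elif fetal > config.tpm_min:
        category = "oncofetal"
    else:
        category = "other"
    return TAACategory(gene_id=gene_id, category=category, testis_hi=testis, fetal_hi=fetal)
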