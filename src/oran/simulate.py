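"""Synthetic cohort generator with planted ground truth.

Generates an internally consistent bundle — genome + transcript models +
proteome, a 29-organ normal panel with held-out testis and fetal
cerebellum, and a tumor cohort (variants, fusions, expression, HLA,
survival, MS peptides) — in which tumor-associated genes, non-synonymous
variants and fusions are planted with margins well clear of every strict
threshold, so recovery by the pipeline is exactly determined.

A single seed drives a hierarchy of RNG streams (reference / panel /
cohort), so the same seed always yields byte-identical files.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import (
    write_cohort_manifest,
    write_expression_table,
    write_fusion_calls,
    write_vcf,
)
from .models import (
    ExpressionMatrix,
    FusionEvent,
    PatientRecord,
    SUBGROUPS,
    TranscriptModel,
    Variant,
    revcomp,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
)
_CODON_AA = {c: str(Seq(c).translate()) for c in _NON_STOP_CODONS}
_SYNONYMS: dict[str, list[str]] = {}
for _c, _aa in _CODON_AA.items():
    _SYNONYMS.setdefault(_aa, []).append(_c)

_HLA_I_POOL = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*04:01",
    "HLA-C*07:01",
)
_HLA_II_POOL = (
    "HLA-DRB1*07:01",
    "HLA-DRB1*15:01",
    "HLA-DQB1*06:02",
    "HLA-DPB1*04:01",
)


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort."""

    rng_seed: int = 0
    n_genes: int = 200
    n_transcripts_per_gene: int = 2  # second isoform where exon structure allows
    n_organs: int = 29  # included panel; testis + fetal cerebellum added on top
    samples_per_organ: int = 3
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"WNT": 3, "SHH": 7, "Group3": 6, "Group4": 8}
    )
    n_tag_pool: int = 30
    n_cta_pool: int = 8
    n_fetal_pool: int = 4
    n_planted_tags_per_patient: int = 3
    n_variants_per_patient: int = 8
    frac_synonymous: float = 0.2
    frac_frameshift: float = 0.2
    n_low_vaf_decoys_per_patient: int = 1
    n_fusions_total: int = 6
    vaf_low: float = 0.7
    vaf_high: float = 0.95
    normal_hi_margin: float = 0.5  # planted TAG mu+2sigma stays below this
    tumor_tpm_floor: float = 2.0  # planted top-isoform TPM stays above this
    survival_correlation: float = 0.0
    n_ms_patients: int = 4

    def __post_init__(self):
        if any(v < 0 for v in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be >= 0")
        if self.n_cta_pool + self.n_fetal_pool > self.n_tag_pool:
            raise ValueError("CTA + fetal pools exceed the TAG pool")


@dataclass
class TruthManifest:
    """Planted ground truth per patient."""

    tags: dict[str, list[str]]  # patient -> gene ids
    variants: dict[str, list[str]]  # patient -> non-synonymous variant ids
    fusions: dict[str, list[str]]  # patient -> fusion ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.tags):
            rows.append(
                {
                    "patient_id": pid,
                    "planted_tags": ";".join(self.tags[pid]),
                    "planted_variants": ";".join(self.variants.get(pid, [])),
                    "planted_fusions": ";".join(self.fusions.get(pid, [])),
                }
            )
        return pd.DataFrame(
            rows, columns=["patient_id", "planted_tags", "planted_variants", "planted_fusions"]
        )


@dataclass
class _GeneInfo:
    gene_id: str
    symbol: str
    transcripts: list[TranscriptModel]


@dataclass
class SyntheticCohort:
    params: SimParams
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    gtf_lines: list[str]
    proteome: list[tuple[str, str, str]]  # (tx_id, gene_symbol, protein)
    panel: ExpressionMatrix
    organ_map: dict[str, str]
    tag_pool: list[str]
    cta_pool: list[str]
    fetal_pool: list[str]
    patients: list[PatientRecord]
    tumor_expr: ExpressionMatrix
    variants: dict[str, list[Variant]]
    fusions: dict[str, list[FusionEvent]]
    ms_peptides: pd.DataFrame
    truth: TruthManifest

    def transcripts_by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts}

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        (out / "annotation.gtf").write_text("\n".join(self.gtf_lines) + "\n")
        with open(out / "proteome.fa", "w") as fh:
            for tx_id, gene, protein in self.proteome:
                fh.write(f">{tx_id} gene={gene}\n{protein}\n")
        write_cohort_manifest(self.patients, out / "manifest.tsv")
        write_expression_table(self.panel, out / "normal_panel.tsv")
        pd.DataFrame(
            sorted(self.organ_map.items()), columns=["sample", "organ"]
        ).to_csv(out / "organ_map.tsv", sep="\t", index=False)
        write_expression_table(self.tumor_expr, out / "tumor_expression.tsv")
        (out / "vcf").mkdir(exist_ok=True)
        (out / "fusions").mkdir(exist_ok=True)
        for p in self.patients:
            write_vcf(
                self.variants.get(p.patient_id, []),
                out / "vcf" / f"{p.patient_id}.vcf",
                contigs=sorted(self.genome),
            )
            write_fusion_calls(
                self.fusions.get(p.patient_id, []),
                out / "fusions" / f"{p.patient_id}.tsv",
            )
        self.ms_peptides.to_csv(out / "ms_peptides.tsv", sep="\t", index=False)
        self.truth.to_frame().to_csv(out / "truth_manifest.tsv", sep="\t", index=False)
        return out


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _make_gene(
    rng: np.random.Generator, gene_idx: int, chrom: str, cursor: int, params: SimParams
) -> tuple[_GeneInfo, str, int]:
    """Build one gene locus; returns (gene info, genomic sequence appended
    at ``cursor``, new cursor)."""
    gene_id = f"SIMG{gene_idx:04d}"
    symbol = f"GENE{gene_idx:04d}"
    n_codons = int(rng.integers(60, 150))
    codons = (
        ["ATG"]
        + [str(rng.choice(_NON_STOP_CODONS)) for _ in range(n_codons - 2)]
        + [str(rng.choice(_STOPS))]
    )
    cds = "".join(codons)
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 4))
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(10, len(cds) - 10), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0] + [int(c) for c in cuts] + [len(cds)]
    pieces = [cds[bounds[i] : bounds[i + 1]] for i in range(n_exons)]  # transcription order

    locus_parts: list[str] = [_rand_seq(rng, int(rng.integers(60, 150)))]
    cursor += len(locus_parts[0])
    genomic_pieces = pieces if strand == "+" else [revcomp(p) for p in reversed(pieces)]
    intervals: list[tuple[int, int]] = []
    for j, gp in enumerate(genomic_pieces):
        if j > 0:
            intron = _rand_seq(rng, int(rng.integers(30, 80)))
            locus_parts.append(intron)
            cursor += len(intron)
        intervals.append((cursor, cursor + len(gp)))
        locus_parts.append(gp)
        cursor += len(gp)
    if strand == "-":
        intervals = list(reversed(intervals))  # back to transcription order
    seg_seqs = tuple(
        p if strand == "+" else revcomp(p) for p in pieces
    )  # forward-strand sequence per transcription-order segment

    tx1 = TranscriptModel(
        transcript_id=f"SIMT{gene_idx:04d}.1",
        gene_id=gene_id,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        cds_segments=tuple(intervals),
        segment_seqs=seg_seqs,
    )
    transcripts = [tx1]

    if params.n_transcripts_per_gene >= 2:
        tx2 = _make_second_isoform(rng, tx1, bounds, gene_idx)
        if tx2 is not None:
            transcripts.append(tx2)
    return _GeneInfo(gene_id, symbol, transcripts), "".join(locus_parts), cursor


def _make_second_isoform(
    rng: np.random.Generator,
    tx1: TranscriptModel,
    cds_bounds: list[int],
    gene_idx: int,
) -> TranscriptModel | None:
    """Second isoform: a codon-aligned internal excision inside one exon."""
    cds_len = sum(e - s for s, e in tx1.cds_segments)
    for seg_i in range(len(tx1.cds_segments)):
        c_start, c_end = cds_bounds[seg_i], cds_bounds[seg_i + 1]
        # codon-aligned excision candidates fully inside this exon,
        # excluding the first and last codon of the whole CDS
        lo = max(((c_start + 2) // 3) * 3, 3)
        hi = min((c_end // 3) * 3, cds_len - 3)
        if hi - lo < 45:
            continue
        exc_len = 30
        start_choices = np.arange(lo, hi - exc_len + 1, 3)
        exc_start = int(rng.choice(start_choices))
        exc_end = exc_start + exc_len
        s, e = tx1.cds_segments[seg_i]
        if tx1.strand == "+":
            g_lo = s + (exc_start - c_start)
            g_hi = s + (exc_end - c_start)
        else:
            g_hi = e - (exc_start - c_start)
            g_lo = e - (exc_end - c_start)
        new_segments: list[tuple[int, int]] = []
        new_seqs: list[str] = []
        for j, ((ss, se), seq) in enumerate(zip(tx1.cds_segments, tx1.segment_seqs)):
            if j != seg_i:
                new_segments.append((ss, se))
                new_seqs.append(seq)
                continue
            first = (ss, g_lo)
            second = (g_hi, se)
            pair = [
                ((a, b), seq[a - ss : b - ss]) for a, b in (first, second) if b > a
            ]
            if tx1.strand == "-":
                pair = list(reversed(pair))  # keep transcription order
            for (a, b), sq in pair:
                new_segments.append((a, b))
                new_seqs.append(sq)
        return TranscriptModel(
            transcript_id=f"SIMT{gene_idx:04d}.2",
            gene_id=tx1.gene_id,
            gene_symbol=tx1.gene_symbol,
            chrom=tx1.chrom,
            strand=tx1.strand,
            cds_segments=tuple(new_segments),
            segment_seqs=tuple(new_seqs),
        )
    return None


def _gtf_lines(transcripts: list[TranscriptModel]) -> list[str]:
    lines = []
    for tx in transcripts:
        cum = 0
        rows = []
        for (s, e) in tx.cds_segments:  # transcription order
            frame = (3 - cum % 3) % 3
            rows.append((s, e, frame))
            cum += e - s
        for s, e, frame in sorted(rows):  # GTF rows in genomic order
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_symbol}";'
            )
            lines.append(
                f"{tx.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t{frame}\t{attrs}"
            )
    return lines


def generate_reference(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TranscriptModel], list[str], list[tuple[str, str, str]]]:
    """Genome FASTA content, transcript models, GTF lines and proteome."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(3)[0])
    chroms = [f"chr{i}" for i in (1, 2, 3, 4)]
    chrom_seqs: dict[str, list[str]] = {c: [] for c in chroms}
    cursors = {c: 0 for c in chroms}
    transcripts: list[TranscriptModel] = []
    for gi in range(params.n_genes):
        chrom = chroms[gi % len(chroms)]
        info, locus_seq, new_cursor = _make_gene(rng, gi, chrom, cursors[chrom], params)
        chrom_seqs[chrom].append(locus_seq)
        cursors[chrom] = new_cursor
        transcripts.extend(info.transcripts)
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    proteome = [(t.transcript_id, t.gene_symbol, t.protein) for t in transcripts]
    return genome, transcripts, _gtf_lines(transcripts), proteome


def generate_normal_panel(
    params: SimParams,
    gene_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, dict[str, str], list[str], list[str], list[str]]:
    """Gene-level normal panel + organ map + (TAG, CTA, fetal) pools.

    Background genes get TPM >= 1.2 in every included organ (so they can
    never pass the mu+2sigma < 1 gate); TAG-pool genes stay under the
    planted margin; CTA-pool genes light up in testis, fetal-pool genes in
    fetal cerebellum.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(3)[1])
    pool_idx = rng.choice(len(gene_ids), size=params.n_tag_pool, replace=False)
    tag_pool = sorted(gene_ids[i] for i in pool_idx)
    cta_pool = tag_pool[: params.n_cta_pool]
    fetal_pool = tag_pool[params.n_cta_pool : params.n_cta_pool + params.n_fetal_pool]
    organs = [f"organ{i:02d}" for i in range(1, params.n_organs + 1)] + [
        "testis",
        "fetal_cerebellum",
    ]
    samples = [f"{o}_s{j}" for o in organs for j in range(1, params.samples_per_organ + 1)]
    organ_map = {s: s.rsplit("_s", 1)[0] for s in samples}
    base = 1.5 + rng.lognormal(0.0, 0.4, size=len(gene_ids))
    values = base[:, None] * rng.uniform(0.8, 1.2, size=(len(gene_ids), len(samples)))
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    tag_set = set(tag_pool)
    low = lambda n: rng.uniform(0.0, 0.1, size=n)  # noqa: E731
    for g in gene_ids:
        if g not in tag_set:
            continue
        df.loc[g, :] = low(len(samples))
        testis_cols = [s for s in samples if organ_map[s] == "testis"]
        fetal_cols = [s for s in samples if organ_map[s] == "fetal_cerebellum"]
        if g in cta_pool:
            df.loc[g, testis_cols] = rng.uniform(3.0, 8.0, size=len(testis_cols))
        if g in fetal_pool:
            df.loc[g, fetal_cols] = rng.uniform(3.0, 8.0, size=len(fetal_cols))
    df = df.round(4)
    return ExpressionMatrix(df, "gene"), organ_map, tag_pool, cta_pool, fetal_pool


def _codon_genomic_positions(
    tx: TranscriptModel, codon_idx: int
) -> list[tuple[int, int]] | None:
    """Forward-strand genomic positions of the codon's 3 bases, with their
    segment index — or None if the codon spans a splice boundary."""
    cds_positions = range(codon_idx * 3, codon_idx * 3 + 3)
    out = []
    for cpos in cds_positions:
        cum = 0
        hit = None
        for si, (s, e) in enumerate(tx.cds_segments):
            seg_len = e - s
            if cum <= cpos < cum + seg_len:
                off = cpos - cum
                gpos = (s + off) if tx.strand == "+" else (e - 1 - off)
                hit = (si, gpos)
                break
            cum += seg_len
        if hit is None:
            return None
        out.append(hit)
    if len({si for si, _ in out}) != 1:
        return None
    return out


def _plant_snv(
    rng: np.random.Generator, tx: TranscriptModel, patient_id: str, want_synonymous: bool, vaf: float
) -> Variant | None:
    """Plant an SNV in a random interior codon of ``tx``."""
    cds = tx.cds_sequence
    n_codons = len(cds) // 3
    for _ in range(40):
        ci = int(rng.integers(2, n_codons - 2))
        placed = _codon_genomic_positions(tx, ci)
        if placed is None:
            continue
        codon = cds[ci * 3 : ci * 3 + 3]
        aa = _CODON_AA.get(codon)
        if aa is None:
            continue
        if want_synonymous:
            alts = [
                c
                for c in _SYNONYMS[aa]
                if c != codon and sum(a != b for a, b in zip(c, codon)) == 1
            ]
        else:
            alts = [
                c
                for c in _NON_STOP_CODONS
                if _CODON_AA[c] != aa and sum(a != b for a, b in zip(c, codon)) == 1
            ]
        if not alts:
            continue
        new_codon = str(alts[int(rng.integers(len(alts)))])
        base_idx = next(i for i in range(3) if new_codon[i] != codon[i])
        _si, gpos = placed[base_idx]
        ref_cds, alt_cds = codon[base_idx], new_codon[base_idx]
        if tx.strand == "-":
            ref_fwd, alt_fwd = revcomp(ref_cds), revcomp(alt_cds)
        else:
            ref_fwd, alt_fwd = ref_cds, alt_cds
        return Variant(
            patient_id=patient_id,
            chrom=tx.chrom,
            pos=gpos + 1,
            ref=ref_fwd,
            alt=alt_fwd,
            rna_vaf=round(float(vaf), 4),
        )
    return None


def _plant_frameshift(
    rng: np.random.Generator, tx: TranscriptModel, patient_id: str, vaf: float
) -> Variant | None:
    """Plant a 1-nt deletion (anchored, VCF-style) inside one CDS segment."""
    cds_len = tx.cds_length
    n_codons = cds_len // 3
    for _ in range(40):
        ci = int(rng.integers(3, n_codons - 3))
        placed = _codon_genomic_positions(tx, ci)
        if placed is None:
            continue
        si, _ = placed[0]
        s, e = tx.cds_segments[si]
        gpositions = sorted(g for _x, g in placed)
        anchor = gpositions[0] - 1  # base preceding the first deleted base
        if anchor < s:
            continue
        seg_seq = tx.segment_seqs[si]
        ref = seg_seq[anchor - s : anchor - s + 2]
        v = Variant(
            patient_id=patient_id,
            chrom=tx.chrom,
            pos=anchor + 1,
            ref=ref,
            alt=ref[0],
            rna_vaf=round(float(vaf), 4),
        )
        # a shifted frame that stops immediately leaves no novel residue;
        # only plant frameshifts that actually alter the protein
        from .models import translate_cds
        from .variants import apply_variant_to_cds

        mut = translate_cds(apply_variant_to_cds(v, tx))
        ref_protein = tx.protein
        prefix = 0
        while prefix < min(len(mut), len(ref_protein)) and mut[prefix] == ref_protein[prefix]:
            prefix += 1
        if len(mut) > prefix:
            return v
    return None


def generate_tumor_cohort(
    params: SimParams,
    transcripts: list[TranscriptModel],
    tag_pool: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[
    list[PatientRecord],
    ExpressionMatrix,
    dict[str, list[Variant]],
    dict[str, list[FusionEvent]],
    pd.DataFrame,
    TruthManifest,
]:
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(3)[2])
    patient_ids = []
    subgroup_of = {}
    i = 1
    for sg in SUBGROUPS:
        for _ in range(params.cohort_sizes.get(sg, 0)):
            pid = f"MB{i:03d}"
            patient_ids.append(pid)
            subgroup_of[pid] = sg
            i += 1

    tx_by_id = {t.transcript_id: t for t in transcripts}
    tag_set = set(tag_pool)
    usable_non_tag = [
        t for t in transcripts if t.usable and t.gene_id not in tag_set
    ]
    tag_tx: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        if t.gene_id in tag_set:
            tag_tx.setdefault(t.gene_id, []).append(t)

    # --- tumor expression (transcript level) ---
    tx_ids = [t.transcript_id for t in transcripts]
    feature_map = {t.transcript_id: (t.gene_id, t.gene_symbol) for t in transcripts}
    expr = pd.DataFrame(
        rng.lognormal(0.7, 0.8, size=(len(tx_ids), len(patient_ids))),
        index=pd.Index(tx_ids, name="transcript_id"),
        columns=patient_ids,
    )
    # TAG-pool genes start silent everywhere; planted per patient below
    for g in tag_pool:
        for t in tag_tx[g]:
            expr.loc[t.transcript_id, :] = rng.uniform(0.0, 0.25, size=len(patient_ids))

    truth_tags: dict[str, list[str]] = {}
    truth_variants: dict[str, list[str]] = {}
    truth_fusions: dict[str, list[str]] = {pid: [] for pid in patient_ids}
    variants: dict[str, list[Variant]] = {}
    fusions: dict[str, list[FusionEvent]] = {pid: [] for pid in patient_ids}

    for pid in patient_ids:
        # per-patient TAG burden varies around the configured mean
        n_tags = int(rng.integers(1, 2 * params.n_planted_tags_per_patient))
        chosen = sorted(
            tag_pool[j] for j in rng.choice(len(tag_pool), size=n_tags, replace=False)
        )
        truth_tags[pid] = chosen
        for g in chosen:
            txs = sorted(tag_tx[g], key=lambda t: t.transcript_id)
            expr.loc[txs[0].transcript_id, pid] = rng.uniform(
                params.tumor_tpm_floor + 0.5, 8.0
            )
            for t in txs[1:]:
                expr.loc[t.transcript_id, pid] = rng.uniform(0.0, 0.4)

    # --- variants: per-patient burden ~ Poisson around the mean ---
    missense_info: dict[str, list[tuple[Variant, TranscriptModel, int, str]]] = {}
    for pid in patient_ids:
        n_var = max(2, int(rng.poisson(params.n_variants_per_patient)))
        n_syn = max(0, round(n_var * params.frac_synonymous))
        n_fs = max(0, round(n_var * params.frac_frameshift))
        n_mis = n_var - n_syn - n_fs
        plist: list[Variant] = []
        truth_variants[pid] = []
        missense_info[pid] = []
        seen_pos: set[tuple[str, int]] = set()

        def _register(v: Variant, tx: TranscriptModel, non_syn: bool) -> bool:
            if v is None or (v.chrom, v.pos) in seen_pos:
                return False
            seen_pos.add((v.chrom, v.pos))
            plist.append(v)
            expr.loc[tx.transcript_id, pid] = max(
                float(expr.loc[tx.transcript_id, pid]), float(rng.uniform(1.6, 5.0))
            )
            if non_syn:
                truth_variants[pid].append(v.id)
            return True

        kinds = ["missense"] * n_mis + ["synonymous"] * n_syn + ["frameshift"] * n_fs
        for kind in kinds:
            for _ in range(20):
                tx = usable_non_tag[int(rng.integers(len(usable_non_tag)))]
                vaf = rng.uniform(params.vaf_low, params.vaf_high)
                if kind == "frameshift":
                    v = _plant_frameshift(rng, tx, pid, vaf)
                else:
                    v = _plant_snv(rng, tx, pid, kind == "synonymous", vaf)
                if v is not None and _register(v, tx, kind != "synonymous"):
                    if kind == "missense":
                        missense_info[pid].append((v, tx, -1, ""))
                    break
        for _ in range(params.n_low_vaf_decoys_per_patient):
            for _try in range(20):
                tx = usable_non_tag[int(rng.integers(len(usable_non_tag)))]
                v = _plant_snv(rng, tx, pid, False, rng.uniform(0.2, 0.5))
                if v is not None and _register(v, tx, False):
                    break
        variants[pid] = sorted(plist, key=lambda v: (v.chrom, v.pos))

    # --- fusions ---
    fusion_candidates = [
        t for t in usable_non_tag if t.transcript_id.endswith(".1") and t.cds_length >= 90
    ]
    for fi in range(params.n_fusions_total):
        pid = patient_ids[int(rng.integers(len(patient_ids)))]
        left, right = [
            fusion_candidates[int(j)]
            for j in rng.choice(len(fusion_candidates), size=2, replace=False)
        ]
        if left.gene_id == right.gene_id:
            continue
        left_codons = left.cds_length // 3
        right_codons = right.cds_length // 3
        k = int(rng.integers(5, left_codons - 5))
        j = int(rng.integers(5, right_codons - 10))
        in_frame = fi % 2 == 0
        left_break = 3 * k if in_frame else 3 * k + 1
        event = FusionEvent(
            patient_id=pid,
            left_gene=left.gene_symbol,
            left_transcript=left.transcript_id,
            left_breakpoint=left_break,
            right_gene=right.gene_symbol,
            right_transcript=right.transcript_id,
            right_breakpoint=3 * j + 1,
            junction_reads=int(rng.integers(5, 60)),
        )
        fusions[pid].append(event)
        truth_fusions[pid].append(event.id)
        for t in (left, right):
            expr.loc[t.transcript_id, pid] = max(
                float(expr.loc[t.transcript_id, pid]), float(rng.uniform(1.6, 5.0))
            )

    # --- clinical + HLA ---
    burden_proxy = np.array(
        [
            len(truth_tags[pid]) + len(truth_variants[pid]) + len(truth_fusions[pid])
            for pid in patient_ids
        ],
        dtype=float,
    )
    rho = params.survival_correlation
    noise = rng.normal(0.0, 1.0, size=len(patient_ids))
    if rho != 0.0 and np.ptp(burden_proxy) > 0:
        z = (burden_proxy - burden_proxy.mean()) / burden_proxy.std()
        latent = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
    else:
        latent = noise
    os_days = np.round(1500.0 + 500.0 * latent).clip(30)
    patients = []
    for idx, pid in enumerate(patient_ids):
        n_i = int(rng.integers(4, 7))
        n_ii = int(rng.integers(2, 4))
        hla_i = tuple(sorted(_HLA_I_POOL[j] for j in rng.choice(len(_HLA_I_POOL), n_i, replace=False)))
        hla_ii = tuple(sorted(_HLA_II_POOL[j] for j in rng.choice(len(_HLA_II_POOL), n_ii, replace=False)))
        patients.append(
            PatientRecord(
                patient_id=pid,
                subgroup=subgroup_of[pid],
                sex="M" if rng.random() < 0.5 else "F",
                age_years=float(rng.integers(1, 18)),
                vital_status="alive" if rng.random() < 0.6 else "deceased",
                os_days=float(os_days[idx]),
                pfs_days=float(np.round(os_days[idx] * rng.uniform(0.4, 1.0))),
                hla_class_i=hla_i,
                hla_class_ii=hla_ii,
            )
        )

    # --- MS peptides: flanked windows around planted missense residues ---
    ms_rows = []
    for pid in patient_ids[: params.n_ms_patients]:
        for v, tx, _ci, _aa in missense_info[pid][:2]:
            from .variants import build_mutant_protein  # local import avoids a cycle

            pair = build_mutant_protein(v, tx)
            if pair is None or pair.consequence != "missense":
                continue
            r = pair.altered_span[0]
            window = pair.mut_protein[max(0, r - 5) : r + 7]
            if len(window) >= 9:
                ms_rows.append(
                    {
                        "patient_id": pid,
                        "peptide": window,
                        "probability": round(float(rng.uniform(0.75, 0.99)), 3),
                    }
                )
        for _ in range(3):  # sub-threshold decoys
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
            ms_rows.append(
                {
                    "patient_id": pid,
                    "peptide": pep,
                    "probability": round(float(rng.uniform(0.3, 0.65)), 3),
                }
            )
    ms_df = pd.DataFrame(ms_rows, columns=["patient_id", "peptide", "probability"])

    tumor = ExpressionMatrix(expr.round(4), "transcript", feature_map)
    truth = TruthManifest(tags=truth_tags, variants=truth_variants, fusions=truth_fusions)
    return patients, tumor, variants, fusions, ms_df, truth


def generate_cohort(params: SimParams | None = None) -> SyntheticCohort:
    """Generate the full synthetic bundle from one seed."""
    params = params or SimParams()
    streams = np.random.SeedSequence(params.rng_seed).spawn(3)
    genome, transcripts, gtf_lines, proteome = generate_reference(
        params, np.random.default_rng(streams[0])
    )
    gene_ids = sorted({t.gene_id for t in transcripts})
    panel, organ_map, tag_pool, cta_pool, fetal_pool = generate_normal_panel(
        params, gene_ids, np.random.default_rng(streams[1])
    )
    patients, tumor, variants, fusions, ms_df, truth = generate_tumor_cohort(
        params, transcripts, tag_pool, np.random.default_rng(streams[2])
    )
    return SyntheticCohort(
        params=params,
        genome=genome,
        transcripts=transcripts,
        gtf_lines=gtf_lines,
        proteome=proteome,
        panel=panel,
        organ_map=organ_map,
        tag_pool=tag_pool,
        cta_pool=cta_pool,
        fetal_pool=fetal_pool,
        patients=patients,
        tumor_expr=tumor,
        variants=variants,
        fusions=fusions,
        ms_peptides=ms_df,
        truth=truth,
    )
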