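"""Mutant protein construction from SNVs/indels and neoantigen aggregation.

A variant is applied to the transcript's CDS on the forward genomic strand
(the strand VCF alleles live on), the edited segments are re-spliced in
transcript orientation and translated to the first stop codon.  Candidate
peptides are the length-k windows of the mutant protein that overlap the
altered residue span; an immunogenic mutation with several passing epitopes
is still reported as a single neoantigen.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .config import PipelineConfig
from .models import (
    AntigenCall,
    EpitopeCandidate,
    MutantProteinPair,
    ReferenceMismatchError,
    TranscriptModel,
    Variant,
    revcomp,
    translate_cds,
)
from .peptides import windows_overlapping

log = logging.getLogger("oran")


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def apply_variant_to_cds(variant: Variant, transcript: TranscriptModel) -> str | None:
    """Return the mutant CDS (transcript orientation), or None if the
    variant does not fall inside the transcript's CDS.

    The edit must lie within a single CDS segment (indels spanning a
    splice boundary are not modelled).  Raises ReferenceMismatchError if
    the REF allele disagrees with the genome.
    """
    pos0 = variant.pos0
    seg_idx = None
    for i, (s, e) in enumerate(transcript.cds_segments):
        if s <= pos0 < e:
            seg_idx = i
            break
    if seg_idx is None:
        return None
    s, e = transcript.cds_segments[seg_idx]
    if pos0 + len(variant.ref) > e:
        log.warning(
            "%s at %s spans a CDS segment boundary of %s; skipped",
            variant.id,
            variant.chrom,
            transcript.transcript_id,
        )
        return None
    offset = pos0 - s
    seg_seq = transcript.segment_seqs[seg_idx]
    observed = seg_seq[offset : offset + len(variant.ref)]
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.id}: genome has {observed!r} at {variant.chrom}:{variant.pos} "
            f"(transcript {transcript.transcript_id}), expected REF {variant.ref!r}"
        )
    edited = seg_seq[:offset] + variant.alt + seg_seq[offset + len(variant.ref) :]
    pieces = list(transcript.segment_seqs)
    pieces[seg_idx] = edited
    if transcript.strand == "+":
        return "".join(pieces)
    return "".join(revcomp(p) for p in pieces)


def _classify(variant: Variant, ref_protein: str, mut_protein: str) -> str:
    if mut_protein == ref_protein:
        return "synonymous"
    dlen = len(variant.alt) - len(variant.ref)
    if dlen % 3 != 0:
        return "frameshift"
    if variant.vtype == "SNV":
        if len(mut_protein) < len(ref_protein):
            return "stop_gain"
        if len(mut_protein) > len(ref_protein):
            return "stop_loss"
        return "missense"
    return "inframe_ins" if dlen > 0 else "inframe_del"


def build_mutant_protein(
    variant: Variant, transcript: TranscriptModel
) -> MutantProteinPair | None:
    """Apply a variant to a transcript and derive the mutant protein.

    Returns None when the variant lies outside the CDS or the transcript is
    not usable.  The altered span covers every residue of the mutant protein
    that differs from the reference; for frameshifts and stop-losses it
    extends to the mutant protein end.  A stop-gain whose mutant protein is
    a clean prefix of the reference has an empty span (no altered residue
    exists) and contributes no peptides.
    """
    if not transcript.usable:
        return None
    mutant_cds = apply_variant_to_cds(variant, transcript)
    if mutant_cds is None:
        return None
    ref_protein = transcript.protein
    mut_protein = translate_cds(mutant_cds, to_stop=True)
    consequence = _classify(variant, ref_protein, mut_protein)
    p = _common_prefix_len(ref_protein, mut_protein)
    if consequence == "synonymous":
        span = (p, p)
    elif consequence in ("frameshift", "stop_loss"):
        span = (p, len(mut_protein))
    elif consequence == "stop_gain":
        span = (p, len(mut_protein)) if p < len(mut_protein) else (p, p)
    else:
        s = _common_suffix_len(ref_protein[p:], mut_protein[p:])
        end = len(mut_protein) - s
        if end <= p:
            # clean in-frame deletion/duplication: mark the junction residue
            span = (max(p - 1, 0), p) if mut_protein else (0, 0)
        else:
            span = (p, end)
    return MutantProteinPair(
        variant_id=variant.id,
        transcript_id=transcript.transcript_id,
        ref_protein=ref_protein,
        mut_protein=mut_protein,
        altered_span=span,
        consequence=consequence,
    )


def extract_mutation_peptides(
    pair: MutantProteinPair, mhc_class: str, config: PipelineConfig
) -> set[tuple[str, int]]:
    """Mutation-spanning k-mer windows of the mutant protein.

    Class I uses the 8-12mer set, class II 15mers; every window overlaps the
    altered span by at least one residue.  Synonymous pairs yield nothing.
    """
    if pair.consequence == "synonymous":
        return set()
    lengths = config.lengths_for(mhc_class, "SNV")
    peptides: set[tuple[str, int]] = set()
    for k in lengths:
        peptides |= windows_overlapping(pair.mut_protein, pair.altered_span, k)
    return peptides


def mutation_peptides_for_variant(
    variant: Variant,
    transcripts: Sequence[TranscriptModel],
    mhc_class: str,
    config: PipelineConfig,
) -> set[tuple[str, int]]:
    """Union of mutation peptides over all (expressed) transcripts of a
    variant, deduplicated at the sequence level."""
    peptides: set[tuple[str, int]] = set()
    for tx in transcripts:
        pair = build_mutant_protein(variant, tx)
        if pair is None:
            continue
        peptides |= extract_mutation_peptides(pair, mhc_class, config)
    return peptides


def call_neoantigens(passing_epitopes: Iterable[EpitopeCandidate]) -> list[AntigenCall]:
    """Aggregate passing epitopes into one call per (patient, class, source).

    Applies to every category: a mutation, fusion or TAA harbouring several
    epitopes is a single antigen.
    """
    groups: dict[tuple[str, str, str], list[EpitopeCandidate]] = {}
    for e in passing_epitopes:
        groups.setdefault((e.patient_id, e.mhc_class, e.source_id), []).append(e)
    calls = []
    for (patient, mhc_class, source_id), members in sorted(groups.items()):
        calls.append(
            AntigenCall(
                patient_id=patient,
                mhc_class=mhc_class,
                category=members[0].category,
                source_id=source_id,
                gene_symbol=members[0].gene_symbol,
                n_epitopes=len(members),
                best_ic50_nM=min(m.ic50_nM for m in members),
            )
        )
    return calls
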