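"""Fusion protein assembly and junction peptide enumeration.

The fused CDS keeps the left partner through its breakpoint (1-based, last
retained base) and the right partner from its breakpoint (first retained
base) onward.  The fusion is in frame when the right side lands back in its
native reading frame; otherwise the right portion is retranslated in the
shifted frame up to the first stop.
"""
from __future__ import annotations

import logging
from typing import Mapping

from .config import PipelineConfig
from .models import FusionEvent, FusionProtein, OranError, TranscriptModel, translate_cds
from .peptides import windows_overlapping, windows_spanning_boundary

log = logging.getLogger("oran")


def build_fusion_protein(
    event: FusionEvent, transcripts: Mapping[str, TranscriptModel]
) -> FusionProtein:
    """Assemble and translate the chimeric CDS of a fusion call.

    A breakpoint inside a codon makes the junction residue chimeric; that
    residue is assigned to the junction and flagged novel.  A stop codon
    formed at (or before) the junction leaves an empty novel span and the
    protein is flagged truncated.
    """
    for tx_id in (event.left_transcript, event.right_transcript):
        if tx_id not in transcripts:
            raise OranError(f"fusion {event.id}: unknown transcript {tx_id}")
    left = transcripts[event.left_transcript]
    right = transcripts[event.right_transcript]
    for tx in (left, right):
        if not tx.usable:
            raise OranError(f"fusion {event.id}: transcript {tx.transcript_id} unusable")
    left_cds = left.cds_sequence
    right_cds = right.cds_sequence
    if event.left_breakpoint > len(left_cds):
        raise OranError(
            f"fusion {event.id}: left breakpoint {event.left_breakpoint} beyond "
            f"CDS length {len(left_cds)}"
        )
    if event.right_breakpoint > len(right_cds):
        raise OranError(
            f"fusion {event.id}: right breakpoint {event.right_breakpoint} beyond "
            f"CDS length {len(right_cds)}"
        )
    fused = left_cds[: event.left_breakpoint] + right_cds[event.right_breakpoint - 1 :]
    in_frame = (event.left_breakpoint % 3) == ((event.right_breakpoint - 1) % 3)
    frame = "in_frame" if in_frame else "frameshift"
    protein = translate_cds(fused, to_stop=True)
    junction_index = event.left_breakpoint // 3  # residue containing 1st right base
    chimeric_codon = event.left_breakpoint % 3 != 0
    # No residue encoded with right-partner nucleotides survives translation:
    truncated_before_junction = len(protein) <= junction_index
    if truncated_before_junction:
        log.warning(
            "fusion %s: stop codon at/before junction; empty novel contribution",
            event.id,
        )
        novel_span = (len(protein), len(protein))
    elif frame == "frameshift":
        novel_span = (junction_index, len(protein))
    elif chimeric_codon:
        novel_span = (junction_index, junction_index + 1)
    else:
        novel_span = (junction_index, junction_index)  # junction lies between residues
    return FusionProtein(
        fusion_id=event.id,
        protein=protein,
        junction_index=min(junction_index, len(protein)),
        frame=frame,
        novel_span=novel_span,
        left_protein=left.protein,
        right_protein=right.protein,
        truncated_before_junction=truncated_before_junction,
    )


def extract_fusion_peptides(
    fusion_protein: FusionProtein, mhc_class: str, config: PipelineConfig
) -> set[tuple[str, int]]:
    """Junction-spanning and novel-residue k-mers of the fusion protein.

    Windows either overlap the novel span (chimeric/frameshifted residues)
    or straddle the junction boundary (contain residues from both
    partners).  Peptides occurring verbatim in either parent protein are
    dropped — those cannot distinguish the fusion from its parents.
    """
    if fusion_protein.truncated_before_junction:
        return set()
    lengths = config.lengths_for(mhc_class, "fusion")
    peptides: set[tuple[str, int]] = set()
    for k in lengths:
        peptides |= windows_overlapping(fusion_protein.protein, fusion_protein.novel_span, k)
        peptides |= windows_spanning_boundary(
            fusion_protein.protein, fusion_protein.junction_index, k
        )
    return {
        (pep, k)
        for pep, k in peptides
        if pep not in fusion_protein.left_protein and pep not in fusion_protein.right_protein
    }
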