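"""Peptide-MHC affinity backends, the filter cascade and the novelty filter.

Two affinity backends are provided: a deterministic hash surrogate (so
every stage of the pipeline is exercisable hermetically) and a file-based
adapter for affinity tables precomputed by an external predictor such as
NetMHCpan / NetMHCIIpan.
"""
from __future__ import annotations

import hashlib
import logging
import math
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .config import PipelineConfig
from .models import EpitopeCandidate, OranError

log = logging.getLogger("oran")

IC50_CEILING_NM = 50000.0


def surrogate_affinity(peptide: str, allele: str, salt: str = "oran") -> float:
    """Deterministic, platform-independent pseudo-affinity in (1, 50000] nM.

    ic50 = exp(u * ln(50000)) with u the first 8 bytes of
    SHA-256("allele|peptide|salt") scaled to [0, 1).  Log-uniform, so a
    fixed fraction of peptides falls under any affinity threshold.
    """
    if not peptide or not allele:
        raise ValueError("peptide and allele must be non-empty")
    digest = hashlib.sha256(f"{allele}|{peptide}|{salt}".encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    return math.exp(u * math.log(IC50_CEILING_NM))


class AffinityBackend(Protocol):
    def ic50(self, peptide: str, allele: str) -> float: ...


class SurrogateBackend:
    def __init__(self, salt: str = "oran"):
        self.salt = salt

    def ic50(self, peptide: str, allele: str) -> float:
        return surrogate_affinity(peptide, allele, self.salt)


class AffinityTable:
    """(peptide, allele) -> IC50 nM lookup read from a TSV.

    Columns: peptide, allele, ic50_nM.  Duplicate keys are an error, as is
    any requested pair missing from the table.
    """

    def __init__(self, mapping: dict[tuple[str, str], float]):
        self.mapping = mapping

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AffinityTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("peptide", "allele", "ic50_nM") if c not in df.columns]
        if missing:
            raise OranError(f"affinity table missing column(s): {', '.join(missing)}")
        mapping: dict[tuple[str, str], float] = {}
        for row in df.itertuples():
            key = (row.peptide.upper(), row.allele)
            if key in mapping:
                raise OranError(f"duplicate (peptide, allele) key {key} in affinity table")
            mapping[key] = float(row.ic50_nM)
        return cls(mapping)

    def ic50(self, peptide: str, allele: str) -> float:
        key = (peptide.upper(), allele)
        if key not in self.mapping:
            raise OranError(f"affinity table has no entry for {key}")
        return self.mapping[key]


def make_backend(spec: str, salt: str = "oran") -> AffinityBackend:
    """Parse a backend spec: 'surrogate' or 'table:<path>'."""
    if spec == "surrogate":
        return SurrogateBackend(salt)
    if spec.startswith("table:"):
        return AffinityTable.from_tsv(spec[len("table:") :])
    raise OranError(f"unknown predictor backend {spec!r}")


def predict_affinity(
    peptides: Iterable[tuple[str, int]],
    alleles: Sequence[str],
    backend: AffinityBackend,
    *,
    patient_id: str,
    mhc_class: str,
    category: str,
    source_id: str,
    gene_symbol: str,
    rna_vaf: float | None = None,
    expression_tpm: float = 0.0,
) -> list[EpitopeCandidate]:
    """Score every (peptide, allele) pair: one candidate per pair.

    A table backend raises listing every missing pair before scoring.
    """
    ordered = sorted({p for p, _k in peptides})
    if isinstance(backend, AffinityTable):
        missing = [
            (p, a) for p in ordered for a in alleles if (p, a) not in backend.mapping
        ]
        if missing:
            raise OranError(f"affinity table missing {len(missing)} pair(s): {missing[:10]}")
    return [
        EpitopeCandidate(
            patient_id=patient_id,
            peptide=p,
            mhc_class=mhc_class,
            allele=a,
            ic50_nM=backend.ic50(p, a),
            category=category,
            source_id=source_id,
            gene_symbol=gene_symbol,
            rna_vaf=rna_vaf,
            expression_tpm=expression_tpm,
        )
        for p in ordered
        for a in alleles
    ]


def filter_epitopes(
    candidates: Iterable[EpitopeCandidate], config: PipelineConfig
) -> list[EpitopeCandidate]:
    """The stepwise filter cascade (a pure conjunction of strict gates).

    1. IC50 < 500 nM (class I) / < 1000 nM (class II)
    2. supporting expression > 1 TPM
    3. RNA-VAF > 0.6 — mutation-derived candidates only
    Per-step drop counts are logged.
    """
    candidates = list(candidates)
    step1 = [c for c in candidates if c.ic50_nM < config.ic50_max(c.mhc_class)]
    step2 = [c for c in step1 if c.expression_tpm > config.tpm_min]
    step3 = [
        c
        for c in step2
        if c.category not in ("SNV", "indel")
        or (c.rna_vaf is not None and c.rna_vaf > config.rna_vaf_min)
    ]
    n0 = len(candidates)
    log.debug(
        "filter cascade: %d -> %d (affinity) -> %d (expression) -> %d (VAF)",
        n0,
        len(step1),
        len(step2),
        len(step3),
    )
    return step3


class ProteomeIndex:
    """Exact-substring screen of peptides against a reference proteome.

    Matching is case-insensitive (both sides uppercased) and within each
    protein sequence (no cross-entry concatenation artifacts).
    """

    def __init__(self, entries: Sequence[tuple[str, str, str]]):
        # entries: (protein_id, gene_symbol, sequence)
        self.entries = [(pid, gene, seq.upper()) for pid, gene, seq in entries]
        self._by_gene: dict[str, str] = {}
        for _pid, gene, seq in self.entries:
            self._by_gene[gene] = self._by_gene.get(gene, "") + "#" + seq
        self._all = "#".join(seq for _pid, _gene, seq in self.entries)
        self._excl_cache: dict[str, str] = {}

    def contains(self, peptide: str) -> bool:
        return peptide.upper() in self._all

    def contains_outside_gene(self, peptide: str, gene: str) -> bool:
        if gene not in self._excl_cache:
            self._excl_cache[gene] = "#".join(
                seq for _pid, g, seq in self.entries if g != gene
            )
        return peptide.upper() in self._excl_cache[gene]

    @property
    def has_gene_tags(self) -> bool:
        return all(gene for _pid, gene, _seq in self.entries)


def novelty_filter(
    candidates: Iterable[EpitopeCandidate],
    proteome: ProteomeIndex,
    mode: str,
) -> list[EpitopeCandidate]:
    """Keep only epitopes absent from the reference proteome.

    mode="neoantigen" (also fusions): a peptide found anywhere is not novel.
    mode="TAA": hits within the TAA's own gene are expected and ignored; a
    hit in any *other* gene's protein removes the peptide.
    """
    if mode not in ("neoantigen", "TAA"):
        raise OranError(f"unknown novelty mode {mode!r}")
    if mode == "TAA" and not proteome.has_gene_tags:
        raise OranError("TAA novelty mode requires gene= tags on every proteome entry")
    kept = []
    for c in candidates:
        if mode == "neoantigen":
            c.novel = not proteome.contains(c.peptide)
        else:
            c.novel = not proteome.contains_outside_gene(c.peptide, c.gene_symbol)
        if c.novel:
            kept.append(c)
    return kept
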