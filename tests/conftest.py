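import numpy as np
import pytest

from oran.config import PipelineConfig
from oran.models import TranscriptModel, revcomp
from oran.pipeline import inputs_from_cohort, run_pipeline
from oran.simulate import SimParams, generate_cohort

# Independent standard-genetic-code table, written out by hand so that
# translation checks do not share code with the implementation.
ORACLE_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(cds: str, to_stop: bool = True) -> str:
    """Brute-force translation against the hand-written codon table."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        residue = ORACLE_CODONS[cds[i : i + 3]]
        if residue == "*" and to_stop:
            break
        aa.append(residue)
    return "".join(aa)


def make_transcript(
    cds: str,
    strand: str = "+",
    chrom: str = "chrT",
    start: int = 100,
    n_segments: int = 1,
    tx_id: str = "TX1",
    gene_id: str = "G1",
    gene_symbol: str = "GENE1",
) -> TranscriptModel:
    """Lay a CDS onto a toy genome as 1+ segments with 10-nt gaps.

    For '-' strand the forward genome carries the reverse complement and
    segments are stored in transcription (descending genomic) order.
    """
    bounds = np.linspace(0, len(cds), n_segments + 1).astype(int)
    pieces = [cds[bounds[i] : bounds[i + 1]] for i in range(n_segments)]
    genomic_pieces = pieces if strand == "+" else [revcomp(p) for p in reversed(pieces)]
    cursor = start
    intervals = []
    for p in genomic_pieces:
        intervals.append((cursor, cursor + len(p)))
        cursor += len(p) + 10
    if strand == "-":
        intervals = list(reversed(intervals))
    seg_seqs = tuple(p if strand == "+" else revcomp(p) for p in pieces)
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        gene_symbol=gene_symbol,
        chrom=chrom,
        strand=strand,
        cds_segments=tuple(intervals),
        segment_seqs=seg_seqs,
    )


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seeded study conditions)."""
    return generate_cohort(SimParams())


@pytest.fixture(scope="session")
def default_result(default_cohort):
    return run_pipeline(inputs_from_cohort(default_cohort))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit-level checks."""
    return generate_cohort(
        SimParams(
            rng_seed=7,
            n_genes=60,
            n_tag_pool=12,
            n_cta_pool=4,
            n_fetal_pool=2,
            cohort_sizes={"WNT": 2, "SHH": 3, "Group3": 2, "Group4": 3},
            n_variants_per_patient=5,
            n_fusions_total=4,
        )
    )
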