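"""Normal-panel statistics, TAG identification and TAA classification."""
import numpy as np
import pandas as pd
import pytest

from oran.config import PipelineConfig
from oran.models import ExpressionMatrix, OranError
from oran.taa import (
    classify_taa_category,
    compute_normal_stats,
    enumerate_tag_peptides,
    identify_tags,
)

from conftest import make_transcript


def _panel(gene_values: dict[str, dict[str, list[float]]]) -> tuple[ExpressionMatrix, dict]:
    """gene -> organ -> sample values."""
    organs = sorted({o for g in gene_values.values() for o in g})
    samples, organ_map, columns = [], {}, {}
    for o in organs:
        n = len(next(iter(gene_values.values()))[o])
        for j in range(n):
            s = f"{o}_s{j}"
            samples.append(s)
            organ_map[s] = o
    data = {
        g: [v for o in organs for v in gene_values[g][o]] for g in gene_values
    }
    df = pd.DataFrame(data, index=samples).T
    df.index.name = "gene_id"
    return ExpressionMatrix(df, "gene"), organ_map


class TestNormalStats:
    def test_constant_samples_hi_equals_value(self):
        panel, organs = _panel({"G1": {"organA": [0.7, 0.7, 0.7]}})
        stats = compute_normal_stats(panel, organs)
        assert stats.hi.loc["G1", "organA"] == pytest.approx(0.7)

    def test_hand_computed_mu_sigma(self):
        panel, organs = _panel({"G1": {"organA": [0.2, 0.4, 0.6]}})
        stats = compute_normal_stats(panel, organs)
        # sample sd with n-1 denominator: sd([.2,.4,.6]) = 0.2
        assert stats.mu.loc["G1", "organA"] == pytest.approx(0.4)
        assert stats.sigma.loc["G1", "organA"] == pytest.approx(0.2)
        assert stats.hi.loc["G1", "organA"] == pytest.approx(0.8)

    def test_testis_and_fetal_held_out_of_normal_max(self):
        panel, organs = _panel(
            {
                "G1": {
                    "organA": [0.3, 0.3],
                    "organB": [0.9, 0.9],
                    "testis": [5.0, 5.0],
                    "fetal_cerebellum": [4.0, 4.0],
                }
            }
        )
        stats = compute_normal_stats(panel, organs)
        assert stats.normal_max["G1"] == pytest.approx(0.9)
        assert stats.testis_hi["G1"] == pytest.approx(5.0)
        assert stats.fetal_hi["G1"] == pytest.approx(4.0)

    def test_unlabelled_sample_errors(self):
        panel, organs = _panel({"G1": {"organA": [1.0]}})
        with pytest.raises(OranError, match="unlabelled"):
            compute_normal_stats(panel, {})


def _tumor(tx_values: dict[str, tuple[str, float]], patient="P1") -> ExpressionMatrix:
    """transcript -> (gene, tpm) for one patient."""
    df = pd.DataFrame({patient: {t: v for t, (_g, v) in tx_values.items()}})
    df.index.name = "transcript_id"
    fmap = {t: (g, g.replace("G", "SYM")) for t, (g, _v) in tx_values.items()}
    return ExpressionMatrix(df, "transcript", fmap)


def _stats_for(normal_max: dict[str, float]):
    panel, organs = _panel({g: {"organA": [v, v]} for g, v in normal_max.items()})
    return compute_normal_stats(panel, organs)


class TestIdentifyTags:
    def test_qualifying_gene(self, config):
        tumor = _tumor({"T1": ("G1", 1.5), "T2": ("G1", 0.2)})
        stats = _stats_for({"G1": 0.3})
        (rec,) = identify_tags(tumor, stats, "P1", config)
        assert rec.qualifies
        assert rec.tumor_gene_tpm == pytest.approx(1.7)
        assert rec.top_transcript_tpm == pytest.approx(1.5)

    def test_top_transcript_rule(self, config):
        # gene TPM 1.8 > 1 but the best isoform is 0.9 <= 1
        tumor = _tumor({"T1": ("G1", 0.9), "T2": ("G1", 0.9)})
        stats = _stats_for({"G1": 0.5})
        (rec,) = identify_tags(tumor, stats, "P1", config)
        assert not rec.qualifies

    def test_normal_max_boundary_strict(self, config):
        tumor = _tumor({"T1": ("G1", 5.0)})
        stats = _stats_for({"G1": 1.0})
        (rec,) = identify_tags(tumor, stats, "P1", config)
        assert rec.normal_max == pytest.approx(1.0)
        assert not rec.qualifies

    def test_gene_absent_from_panel_defaults_to_zero(self, config):
        tumor = _tumor({"T1": ("G1", 5.0)})
        stats = _stats_for({"G9": 0.5})
        (rec,) = identify_tags(tumor, stats, "P1", config)
        assert rec.qualifies and rec.unverified_normal

    @staticmethod
    def _brute_force(tumor, stats, patient, config):
        """Independent re-statement of the three rules."""
        out = set()
        genes = {}
        for t, (g, _s) in tumor.feature_map.items():
            genes.setdefault(g, []).append(t)
        for g, txs in genes.items():
            vals = [float(tumor.values.loc[t, patient]) for t in txs]
            nm = float(stats.normal_max[g]) if g in stats.normal_max.index else 0.0
            if nm < config.normal_max_lt and sum(vals) > config.tpm_min and max(vals) > config.tpm_min:
                out.add(g)
        return out

    def test_oracle_equivalence_random_panels(self, config):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_genes = 40
            genes = [f"G{i}" for i in range(n_genes)]
            panel_vals = {
                g: {f"organ{o}": list(rng.uniform(0, 1.4, size=3)) for o in range(6)}
                for g in genes
            }
            panel, organs = _panel(panel_vals)
            stats = compute_normal_stats(panel, organs)
            tx_vals = {}
            for g in genes:
                for j in range(2):
                    tx_vals[f"{g}.T{j}"] = (g, float(rng.uniform(0, 2.5)))
            tumor = _tumor(tx_vals)
            got = {r.gene_id for r in identify_tags(tumor, stats, "P1", config) if r.qualifies}
            assert got == self._brute_force(tumor, stats, "P1", config)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(30)]
        panel_vals = {
            g: {f"organ{o}": list(rng.uniform(0, 1.4, size=3)) for o in range(4)}
            for g in genes
        }
        panel, organs = _panel(panel_vals)
        stats = compute_normal_stats(panel, organs)
        tumor = _tumor({f"{g}.T0": (g, float(rng.uniform(0, 3))) for g in genes})
        base = {
            r.gene_id
            for r in identify_tags(tumor, stats, "P1", PipelineConfig())
            if r.qualifies
        }
        tighter_tpm = {
            r.gene_id
            for r in identify_tags(tumor, stats, "P1", PipelineConfig(tpm_min=1.5))
            if r.qualifies
        }
        tighter_normal = {
            r.gene_id
            for r in identify_tags(tumor, stats, "P1", PipelineConfig(normal_max_lt=0.6))
            if r.qualifies
        }
        assert tighter_tpm <= base
        assert tighter_normal <= base


class TestTagPeptides:
    def _protein20_transcript(self):
        # 20 aa protein: 60 nt coding + stop
        rng = np.random.default_rng(2)
        from oran.simulate import _NON_STOP_CODONS

        cds = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=19)) + "TAA"
        return make_transcript(cds, tx_id="T1", gene_id="G1", gene_symbol="SYM1")

    def _tag(self, **kw):
        from oran.taa import TAGRecord

        defaults = dict(
            patient_id="P1",
            gene_id="G1",
            gene_symbol="SYM1",
            tumor_gene_tpm=5.0,
            top_transcript_id="T1",
            top_transcript_tpm=5.0,
            normal_max=0.1,
            qualifies=True,
        )
        defaults.update(kw)
        return TAGRecord(**defaults)

    def test_class_i_count_is_sum_of_lmk1(self, config):
        tx = self._protein20_transcript()
        assert len(tx.protein) == 20
        tumor = _tumor({"T1": ("G1", 5.0)})
        peptides = enumerate_tag_peptides(self._tag(), [tx], tumor, "I", config)
        assert len(peptides) == sum(20 - k + 1 for k in (9, 10, 11, 12))  # 42

    def test_class_ii_fifteen_mers(self, config):
        tx = self._protein20_transcript()
        tumor = _tumor({"T1": ("G1", 5.0)})
        peptides = enumerate_tag_peptides(self._tag(), [tx], tumor, "II", config)
        assert len(peptides) == 6

    def test_shared_kmers_deduplicated(self, config):
        tx1 = self._protein20_transcript()
        tx2 = make_transcript(
            tx1.cds_sequence, tx_id="T2", gene_id="G1", gene_symbol="SYM1", start=500
        )
        tumor = _tumor({"T1": ("G1", 5.0), "T2": ("G1", 5.0)})
        both = enumerate_tag_peptides(self._tag(), [tx1, tx2], tumor, "I", config)
        solo = enumerate_tag_peptides(self._tag(), [tx1], tumor, "I", config)
        assert both == solo

    def test_non_qualifying_tag_yields_nothing(self, config):
        tx = self._protein20_transcript()
        tumor = _tumor({"T1": ("G1", 5.0)})
        assert (
            enumerate_tag_peptides(self._tag(qualifies=False), [tx], tumor, "I", config)
            == set()
        )


class TestTaaCategory:
    def test_cta_when_testis_high(self, config):
        stats = _stats_for({"G1": 0.2})
        stats.testis_hi = pd.Series({"G1": 7.2})
        stats.fetal_hi = pd.Series({"G1": 0.1})
        assert classify_taa_category("G1", stats, config).category == "CTA"

    def test_oncofetal_when_only_fetal_high(self, config):
        stats = _stats_for({"G1": 0.2})
        stats.testis_hi = pd.Series({"G1": 0.2})
        stats.fetal_hi = pd.Series({"G1": 3.0})
        assert classify_taa_category("G1", stats, config).category == "oncofetal"

    def test_other_when_both_low(self, config):
        stats = _stats_for({"G1": 0.2})
        stats.testis_hi = pd.Series({"G1": 0.9})
        stats.fetal_hi = pd.Series({"G1": 1.0})
        assert classify_taa_category("G1", stats, config).category == "other"
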