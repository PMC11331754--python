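"""Cohort analytics: burdens, fractions, recurrence, statistics, MS matching."""
import numpy as np
import pandas as pd
import pytest

from oran.config import PipelineConfig
from oran.landscape import (
    antigen_survival_correlation,
    bonferroni,
    burden_table,
    ms_concordance,
    recurring_antigens,
    shared_antigens,
    significance_code,
    subgroup_comparison,
    targetable_fraction_table,
)
from oran.models import AntigenCall, EpitopeCandidate, OranError, PatientRecord


def _patients(spec):
    """spec: list of (pid, subgroup, os, pfs)."""
    return [
        PatientRecord(pid, sg, os_days=os, pfs_days=pfs)
        for pid, sg, os, pfs in spec
    ]


def _call(pid, gene, category="SNV", mhc="I", source=None):
    return AntigenCall(
        patient_id=pid,
        mhc_class=mhc,
        category=category,
        source_id=source or f"{gene}:src",
        gene_symbol=gene,
        n_epitopes=1,
        best_ic50_nM=100.0,
    )


FOUR = _patients(
    [("P1", "WNT", 1000, 800), ("P2", "SHH", 900, 700), ("P3", "Group3", 800, 600), ("P4", "Group4", 700, 500)]
)


class TestBurden:
    def test_zero_filled_and_counts(self):
        calls = [_call("P1", "A"), _call("P1", "B"), _call("P1", "C"), _call("P2", "D", "TAA", "II")]
        burden = burden_table(calls, FOUR)
        assert burden.loc["P1", ("I", "SNV")] == 3
        assert burden.loc["P2", ("II", "TAA")] == 1
        assert burden.loc["P3"].drop("subgroup").sum() == 0

    def test_unknown_patient_errors(self):
        with pytest.raises(OranError, match="unknown patient"):
            burden_table([_call("PX", "A")], FOUR)

    def test_both_classes_counted(self):
        calls = [_call("P1", "A", mhc="I"), _call("P1", "A", mhc="II")]
        burden = burden_table(calls, FOUR)
        assert burden.loc["P1", ("I", "SNV")] == 1
        assert burden.loc["P1", ("II", "SNV")] == 1


class TestTargetableFractions:
    def test_counting_example(self):
        patients = _patients([(f"P{i}", "WNT", None, None) for i in range(4)])
        calls = []
        for i, n in enumerate([0, 1, 2, 3]):
            calls += [_call(f"P{i}", f"G{j}", source=f"s{i}.{j}") for j in range(n)]
        tf = targetable_fraction_table(burden_table(calls, patients), "I", ("SNV", "indel"))
        assert tf.loc["WNT", "1+"] == pytest.approx(75.0)
        assert tf.loc["WNT", "2+"] == pytest.approx(50.0)
        assert tf.loc["WNT", "3+"] == pytest.approx(25.0)

    def test_all_zero_and_all_high(self):
        patients = _patients([("P1", "SHH", None, None), ("P2", "SHH", None, None)])
        tf0 = targetable_fraction_table(burden_table([], patients))
        assert (tf0.loc["SHH"] == 0).all()
        calls = [_call(p, f"G{j}", source=f"{p}.{j}") for p in ("P1", "P2") for j in range(3)]
        tf3 = targetable_fraction_table(burden_table(calls, patients))
        assert (tf3.loc["SHH"] == 100.0).all()

    def test_rows_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        patients = _patients(
            [(f"P{i}", sg, None, None) for i, sg in enumerate(["WNT", "SHH", "Group3", "Group4"] * 5)]
        )
        calls = []
        for p in patients:
            for j in range(int(rng.integers(0, 6))):
                calls.append(_call(p.patient_id, f"G{j}", source=f"{p.patient_id}.{j}"))
        tf = targetable_fraction_table(burden_table(calls, patients), thresholds=(1, 2, 3))
        for _sg, row in tf.iterrows():
            assert row["1+"] >= row["2+"] >= row["3+"]


class TestRecurrenceAndSharing:
    def test_recurring_within_subgroup(self):
        patients = _patients(
            [("P1", "SHH", None, None), ("P2", "SHH", None, None), ("P3", "Group3", None, None)]
        )
        calls = [_call("P1", "G"), _call("P2", "G")]
        recs = recurring_antigens(calls, patients, "subgroup")
        assert len(recs) == 1 and recs[0].subgroup == "SHH" and recs[0].n_patients == 2

    def test_split_across_subgroups_only_pan(self):
        patients = _patients([("P1", "SHH", None, None), ("P3", "Group3", None, None)])
        calls = [_call("P1", "G"), _call("P3", "G")]
        assert recurring_antigens(calls, patients, "subgroup") == []
        pan = recurring_antigens(calls, patients, "pan")
        assert len(pan) == 1 and pan[0].n_patients == 2

    def test_one_patient_two_epitope_calls_not_recurring(self):
        patients = _patients([("P1", "SHH", None, None), ("P2", "SHH", None, None)])
        calls = [_call("P1", "G", mhc="I"), _call("P1", "G", mhc="II")]
        assert recurring_antigens(calls, patients, "subgroup") == []

    def test_pan_count_is_sum_over_subgroups(self, default_result, default_cohort):
        calls = default_result.calls
        patients = default_cohort.patients
        per_sub = recurring_antigens(calls, patients, "subgroup")
        pan = recurring_antigens(calls, patients, "pan")
        # for keys recurring pan-wide, pan count equals the number of
        # distinct patients across subgroup-level groups of the same key
        from oran.landscape import antigen_keys

        keys = antigen_keys(calls)
        sub_map = {p.patient_id: p.subgroup for p in patients}
        for rec in pan[:20]:
            grp = keys[(keys.antigen_key == rec.antigen_key) & (keys.kind == rec.category)]
            assert rec.n_patients == grp.patient_id.nunique()

    def test_shared_antigens_table(self):
        patients = _patients(
            [("P1", "WNT", None, None), ("P2", "WNT", None, None), ("P3", "WNT", None, None),
             ("P4", "Group4", None, None), ("P5", "SHH", None, None)]
        )
        calls = [
            _call("P1", "A"), _call("P2", "A"), _call("P3", "A"),  # one-subgroup share
            _call("P1", "B"), _call("P4", "B"),  # cross-subgroup share
            _call("P5", "C"),  # private
        ]
        df = shared_antigens(calls, patients)
        assert set(df.antigen_key) == {"A", "B"}
        a = df[df.antigen_key == "A"].iloc[0]
        assert a.n_patients == 3 and a.subgroups == "WNT" and not a.cross_subgroup
        b = df[df.antigen_key == "B"].iloc[0]
        assert b.n_subgroups == 2 and b.cross_subgroup

    def test_fusion_key_is_unordered_pair(self):
        patients = _patients([("P1", "SHH", None, None), ("P2", "SHH", None, None)])
        calls = [
            _call("P1", "GA--GB", "fusion", source="GA--GB:1-2"),
            _call("P2", "GB--GA", "fusion", source="GB--GA:3-4"),
        ]
        recs = recurring_antigens(calls, patients, "subgroup")
        assert len(recs) == 1 and recs[0].antigen_key == "GA--GB"


class TestStatistics:
    def test_significance_code_boundaries_exact(self):
        assert significance_code(0.05) == "ns"
        assert significance_code(0.0499999) == "*"
        assert significance_code(0.01) == "*"
        assert significance_code(0.0099) == "**"
        assert significance_code(0.001) == "**"
        assert significance_code(0.00099) == "***"
        assert significance_code(0.0001) == "***"
        assert significance_code(0.00009) == "****"
        assert significance_code(0.2) == "ns"

    def test_bonferroni(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.5, 6) == 1.0
        for p in np.random.default_rng(1).uniform(0, 1, 50):
            assert p <= bonferroni(float(p), 4) <= 1.0

    def test_subgroup_comparison_pipeline(self):
        rng = np.random.default_rng(2)
        patients = _patients(
            [(f"P{i}", sg, None, None) for i, sg in enumerate(["WNT"] * 5 + ["SHH"] * 5 + ["Group3"] * 5)]
        )
        calls = []
        for i, p in enumerate(patients):
            n = 5 if p.subgroup == "WNT" else int(rng.integers(0, 2))
            calls += [_call(p.patient_id, f"G{j}", source=f"{p.patient_id}.{j}") for j in range(n)]
        comp = subgroup_comparison(burden_table(calls, patients), "I", ("SNV", "indel"))
        assert 0 <= comp.overall_p <= 1
        assert comp.n_comparisons == 3
        for row in comp.pairwise.itertuples():
            assert row.p_adj == pytest.approx(min(1.0, row.p_raw * 3))
            assert row.code == significance_code(row.p_adj)

    def test_degenerate_all_identical_gives_p1(self):
        patients = _patients(
            [(f"P{i}", sg, None, None) for i, sg in enumerate(["WNT", "WNT", "SHH", "SHH"])]
        )
        comp = subgroup_comparison(burden_table([], patients))
        assert comp.overall_p == 1.0
        assert (comp.pairwise.p_raw == 1.0).all()


class TestSurvivalCorrelation:
    def _burden_with_counts(self, counts, subgroup="WNT", os=None):
        patients = _patients(
            [
                (f"P{i}", subgroup, os[i] if os else None, os[i] if os else None)
                for i in range(len(counts))
            ]
        )
        calls = []
        for i, n in enumerate(counts):
            calls += [_call(f"P{i}", f"G{j}", source=f"P{i}.{j}") for j in range(n)]
        return burden_table(calls, patients), patients

    def test_perfect_monotone(self):
        burden, patients = self._burden_with_counts([1, 2, 3], os=[10, 20, 30])
        out = antigen_survival_correlation(burden, patients, "OS", "spearman")
        snv = [c for c in out if c.category == "SNV" and c.mhc_class == "I"]
        assert snv[0].coefficient == pytest.approx(1.0)

    def test_perfect_inverse(self):
        burden, patients = self._burden_with_counts([1, 2, 3], os=[30, 20, 10])
        out = antigen_survival_correlation(burden, patients, "OS", "spearman")
        snv = [c for c in out if c.category == "SNV" and c.mhc_class == "I"]
        assert snv[0].coefficient == pytest.approx(-1.0)

    def test_constant_counts_skipped(self):
        burden, patients = self._burden_with_counts([2, 2, 2], os=[10, 20, 30])
        out = antigen_survival_correlation(burden, patients, "OS")
        assert not [c for c in out if c.category == "SNV"]

    def test_missing_endpoint_dropped_and_small_n_skipped(self):
        burden, patients = self._burden_with_counts([1, 2, 3])  # os all missing
        assert antigen_survival_correlation(burden, patients, "OS") == []

    @staticmethod
    def _pearson(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        xm, ym = x - x.mean(), y - y.mean()
        return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))

    @staticmethod
    def _rank(v):
        """Average ranks, computed independently."""
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    def test_correlations_match_textbook_formulas(self):
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.uniform(100, 3000, size=n)
            if np.ptp(x) == 0:
                continue
            assert sps.pearsonr(x, y)[0] == pytest.approx(self._pearson(x, y), abs=1e-12)
            assert sps.spearmanr(x, y)[0] == pytest.approx(
                self._pearson(self._rank(x), self._rank(y)), abs=1e-12
            )


class TestMsConcordance:
    def _epitope(self, pid, peptide):
        return EpitopeCandidate(
            patient_id=pid,
            peptide=peptide,
            mhc_class="I",
            allele="HLA-A*02:01",
            ic50_nM=50.0,
            category="SNV",
            source_id="v1",
            gene_symbol="G",
            rna_vaf=0.8,
            expression_tpm=2.0,
        )

    def test_substring_match(self, config):
        ms = pd.DataFrame(
            [{"patient_id": "P1", "peptide": "KSIINFEKLM", "probability": 0.9}]
        )
        reports = ms_concordance([self._epitope("P1", "SIINFEKL")], ms, config)
        assert reports[0].n_ms_matched == 1

    def test_low_probability_excluded(self, config):
        ms = pd.DataFrame(
            [{"patient_id": "P1", "peptide": "KSIINFEKLM", "probability": 0.6}]
        )
        reports = ms_concordance([self._epitope("P1", "SIINFEKL")], ms, config)
        assert reports[0].n_ms_matched == 0

    def test_no_ms_rows_for_patient(self, config):
        ms = pd.DataFrame(columns=["patient_id", "peptide", "probability"])
        reports = ms_concordance([self._epitope("P1", "SIINFEKL")], ms, config)
        assert reports[0].n_predicted == 1 and reports[0].n_ms_matched == 0

    def test_matched_bounded_by_predicted(self, config):
        ms = pd.DataFrame(
            [
                {"patient_id": "P1", "peptide": "KSIINFEKLM", "probability": 0.95},
                {"patient_id": "P1", "peptide": "AAAAAAAAAA", "probability": 0.95},
            ]
        )
        eps = [self._epitope("P1", "SIINFEKL"), self._epitope("P1", "WWWWWWWW")]
        (report,) = ms_concordance(eps, ms, config)
        assert report.n_ms_matched <= report.n_predicted
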