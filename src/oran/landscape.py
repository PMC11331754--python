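"""Cohort-level antigen analytics.

Per-patient burdens, targetable-fraction tables, recurring and shared
antigens, subgroup comparisons (Kruskal-Wallis + pairwise rank-sum with
Bonferroni), antigen-load vs survival correlations and MS concordance.

Antigen identity for recurrence and sharing is gene-level: the gene symbol
for mutations and TAAs, the unordered gene-symbol pair for fusions; MHC
classes are merged (a patient expresses an antigen if it passes in either
class) while SNV and indel calls are pooled as "mutation".
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .models import AntigenCall, EpitopeCandidate, OranError, PatientRecord, SUBGROUPS

log = logging.getLogger("oran")

BURDEN_CATEGORIES = ("SNV", "indel", "fusion", "TAA")


def _subgroup_map(manifest: Sequence[PatientRecord]) -> dict[str, str]:
    return {p.patient_id: p.subgroup for p in manifest}


def burden_table(
    calls: Iterable[AntigenCall], manifest: Sequence[PatientRecord]
) -> pd.DataFrame:
    """Antigen counts per patient: columns (mhc_class, category), zero-filled.

    A source passing in both classes is counted in both class columns.
    """
    subgroups = _subgroup_map(manifest)
    columns = pd.MultiIndex.from_product([("I", "II"), BURDEN_CATEGORIES])
    table = pd.DataFrame(
        0, index=pd.Index([p.patient_id for p in manifest], name="patient_id"), columns=columns
    )
    for c in calls:
        if c.patient_id not in subgroups:
            raise OranError(f"antigen call for unknown patient {c.patient_id!r}")
        table.loc[c.patient_id, (c.mhc_class, c.category)] += 1
    table.insert(0, "subgroup", [subgroups[p] for p in table.index])
    return table


def _category_counts(
    burden: pd.DataFrame,
    mhc_class: str | None = None,
    categories: Sequence[str] | None = None,
) -> pd.Series:
    """Per-patient count summed over the selected class(es)/categor(ies)."""
    counts = burden.drop(columns="subgroup", level=0)
    classes = [mhc_class] if mhc_class else ["I", "II"]
    cats = list(categories) if categories else list(BURDEN_CATEGORIES)
    cols = [(cl, ca) for cl in classes for ca in cats if (cl, ca) in counts.columns]
    return counts[cols].sum(axis=1)


def targetable_fraction_table(
    burden: pd.DataFrame,
    mhc_class: str | None = None,
    categories: Sequence[str] | None = None,
    thresholds: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Percentage of patients per subgroup with >= t antigens, t in thresholds.

    Rows are subgroups, columns "1+", "2+", "3+"; rows are monotone
    non-increasing across thresholds.
    """
    counts = _category_counts(burden, mhc_class, categories)
    subgroup = burden["subgroup"]
    rows = {}
    for sg in [s for s in SUBGROUPS if (subgroup == s).any()]:
        in_sg = counts[subgroup[subgroup == sg].index]
        if len(in_sg) == 0:
            raise OranError(f"empty subgroup {sg!r}")
        rows[sg] = {
            f"{t}+": 100.0 * float((in_sg >= t).sum()) / len(in_sg) for t in thresholds
        }
    return pd.DataFrame(rows).T


def antigen_keys(calls: Iterable[AntigenCall]) -> pd.DataFrame:
    """Gene-level antigen identity per call: (patient, key, kind)."""
    rows = []
    for c in calls:
        if c.category == "fusion":
            genes = c.gene_symbol.split("--")
            key = "--".join(sorted(genes))
            kind = "fusion"
        elif c.category == "TAA":
            key, kind = c.gene_symbol, "TAA"
        else:
            key, kind = c.gene_symbol, "mutation"
        rows.append({"patient_id": c.patient_id, "antigen_key": key, "kind": kind})
    return pd.DataFrame(rows, columns=["patient_id", "antigen_key", "kind"]).drop_duplicates()


@dataclass(frozen=True)
class RecurrenceRecord:
    antigen_key: str
    category: str  # mutation | fusion | TAA
    subgroup: str  # subgroup name, or "pan"
    n_patients: int
    patients: tuple[str, ...]


def recurring_antigens(
    calls: Iterable[AntigenCall],
    manifest: Sequence[PatientRecord],
    scope: str = "subgroup",
) -> list[RecurrenceRecord]:
    """Antigens expressed by >= 2 distinct patients within the scope.

    scope="subgroup": counted within each molecular subgroup;
    scope="pan": counted cohort-wide.  Sorted by n_patients desc, then key.
    """
    if scope not in ("subgroup", "pan"):
        raise OranError(f"scope must be 'subgroup' or 'pan', got {scope!r}")
    keys = antigen_keys(calls)
    if keys.empty:
        return []
    subgroups = _subgroup_map(manifest)
    keys = keys.assign(
        subgroup="pan" if scope == "pan" else keys["patient_id"].map(subgroups)
    )
    records = []
    for (key, kind, sg), grp in keys.groupby(["antigen_key", "kind", "subgroup"]):
        patients = tuple(sorted(grp["patient_id"].unique()))
        if len(patients) >= 2:
            records.append(
                RecurrenceRecord(
                    antigen_key=key,
                    category=kind,
                    subgroup=sg,
                    n_patients=len(patients),
                    patients=patients,
                )
            )
    records.sort(key=lambda r: (-r.n_patients, r.antigen_key, r.subgroup))
    return records


def shared_antigens(
    calls: Iterable[AntigenCall], manifest: Sequence[PatientRecord]
) -> pd.DataFrame:
    """Upset-style table of antigens expressed by >= 2 patients cohort-wide.

    One row per antigen key: kind, total patients, the set of subgroups with
    at least one expressing patient, and whether it crosses subgroups.
    """
    keys = antigen_keys(calls)
    subgroups = _subgroup_map(manifest)
    rows = []
    if not keys.empty:
        for (key, kind), grp in keys.groupby(["antigen_key", "kind"]):
            patients = sorted(grp["patient_id"].unique())
            if len(patients) < 2:
                continue
            sgs = sorted({subgroups[p] for p in patients}, key=SUBGROUPS.index)
            rows.append(
                {
                    "antigen_key": key,
                    "kind": kind,
                    "n_patients": len(patients),
                    "subgroups": ";".join(sgs),
                    "n_subgroups": len(sgs),
                    "cross_subgroup": len(sgs) >= 2,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["antigen_key", "kind", "n_patients", "subgroups", "n_subgroups", "cross_subgroup"],
    )
    return df.sort_values(
        ["n_patients", "antigen_key"], ascending=[False, True]
    ).reset_index(drop=True)


SIGNIFICANCE_CODES = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p_adj: float) -> str:
    """Map an adjusted p value to the ns/*/**/***/**** convention."""
    for cutoff, code in SIGNIFICANCE_CODES:
        if p_adj < cutoff:
            return code
    return "ns"


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


@dataclass
class ComparisonResult:
    overall_p: float
    pairwise: pd.DataFrame  # group1, group2, p_raw, p_adj, code
    n_comparisons: int


def subgroup_comparison(
    burden: pd.DataFrame,
    mhc_class: str | None = None,
    categories: Sequence[str] | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis across subgroups plus all pairwise two-sided rank-sum
    tests, Bonferroni-corrected over the number of pairs.

    Degenerate all-identical data takes the p = 1 path instead of raising.
    """
    counts = _category_counts(burden, mhc_class, categories)
    subgroup = burden["subgroup"]
    groups = {
        sg: counts[subgroup[subgroup == sg].index].to_numpy()
        for sg in SUBGROUPS
        if (subgroup == sg).sum() >= 2
    }
    if len(groups) < 2:
        raise OranError("subgroup comparison needs >= 2 subgroups with >= 2 patients")
    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:
        overall_p = 1.0
    else:
        overall_p = float(sps.kruskal(*samples).pvalue)
    pairs = list(itertools.combinations(sorted(groups, key=SUBGROUPS.index), 2))
    rows = []
    for g1, g2 in pairs:
        a, b = groups[g1], groups[g2]
        if np.ptp(np.concatenate([a, b])) == 0:
            p_raw = 1.0
        else:
            p_raw = float(sps.ranksums(a, b).pvalue)
        p_adj = bonferroni(p_raw, len(pairs))
        rows.append(
            {"group1": g1, "group2": g2, "p_raw": p_raw, "p_adj": p_adj, "code": significance_code(p_adj)}
        )
    return ComparisonResult(
        overall_p=overall_p,
        pairwise=pd.DataFrame(rows, columns=["group1", "group2", "p_raw", "p_adj", "code"]),
        n_comparisons=len(pairs),
    )


@dataclass(frozen=True)
class SurvivalCorrelation:
    subgroup: str
    mhc_class: str
    category: str
    endpoint: str  # OS | PFS
    method: str  # pearson | spearman
    coefficient: float
    n: int


def antigen_survival_correlation(
    burden: pd.DataFrame,
    manifest: Sequence[PatientRecord],
    endpoint: str = "OS",
    method: str = "spearman",
) -> list[SurvivalCorrelation]:
    """Correlate per-patient antigen counts with survival time per stratum.

    Strata are (subgroup, mhc_class, category); patients with a missing
    endpoint are dropped (count logged); strata with n < 3 or zero count
    variance are skipped with a warning.
    """
    if endpoint not in ("OS", "PFS"):
        raise OranError("endpoint must be OS or PFS")
    corr_fn = {"spearman": sps.spearmanr, "pearson": sps.pearsonr}[method]
    times = {
        p.patient_id: (p.os_days if endpoint == "OS" else p.pfs_days) for p in manifest
    }
    n_missing = sum(1 for t in times.values() if t is None)
    if n_missing:
        log.info("%d patient(s) missing %s dropped from correlation", n_missing, endpoint)
    subgroup = burden["subgroup"]
    out = []
    for sg in [s for s in SUBGROUPS if (subgroup == s).any()]:
        patients = [p for p in subgroup[subgroup == sg].index if times[p] is not None]
        for mhc_class in ("I", "II"):
            for category in BURDEN_CATEGORIES:
                counts = _category_counts(burden, mhc_class, [category])[patients]
                if len(patients) < 3:
                    log.warning("stratum %s/%s/%s: n < 3, skipped", sg, mhc_class, category)
                    continue
                y = np.array([times[p] for p in patients], dtype=float)
                x = counts.to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    log.warning(
                        "stratum %s/%s/%s: zero variance, correlation undefined", sg, mhc_class, category
                    )
                    continue
                coeff = float(corr_fn(x, y)[0])
                out.append(
                    SurvivalCorrelation(
                        subgroup=sg,
                        mhc_class=mhc_class,
                        category=category,
                        endpoint=endpoint,
                        method=method,
                        coefficient=coeff,
                        n=len(patients),
                    )
                )
    return out


@dataclass
class ConcordanceReport:
    patient_id: str
    n_predicted: int
    n_ms_matched: int
    matched: tuple[str, ...] = ()


def ms_concordance(
    predicted_epitopes: Iterable[EpitopeCandidate],
    ms_peptides: pd.DataFrame,
    config: PipelineConfig,
) -> list[ConcordanceReport]:
    """Match predicted epitopes against MS-identified peptides per patient.

    MS rows are filtered to identification probability > the configured
    minimum (0.7); a predicted epitope is matched when it is an exact
    substring of (or equal to) a retained MS peptide of the same patient.
    """
    retained = ms_peptides[ms_peptides["probability"] > config.ms_probability_min]
    ms_by_patient: dict[str, list[str]] = {
        pid: grp["peptide"].tolist() for pid, grp in retained.groupby("patient_id")
    }
    by_patient: dict[str, set[str]] = {}
    for e in predicted_epitopes:
        by_patient.setdefault(e.patient_id, set()).add(e.peptide)
    reports = []
    for pid in sorted(by_patient):
        predicted = sorted(by_patient[pid])
        ms = ms_by_patient.get(pid, [])
        matched = tuple(p for p in predicted if any(p in m for m in ms))
        reports.append(
            ConcordanceReport(
                patient_id=pid,
                n_predicted=len(predicted),
                n_ms_matched=len(matched),
                matched=matched,
            )
        )
    return reports
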