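"""The packaged patient table and the published-results reproduction.

The study's individual patient characteristics (16 paroxysmal-AF patients
referred for pulmonary vein isolation: sex, age, AF duration, coronary
disease, CT-derived left atrial volume, radiofrequency duration, relapse
status, antiarrhythmic medication) ship as a CSV fixture.  Patient-level
images were never deposited, but the published group-level defect counts
(10 deficit-positive patients with 4 relapses; 6 deficit-negative with 1)
combined with the table's relapse column determine the full 2x2 table, the
diagnostic performance of a post-PVI innervation deficit for AF relapse,
and the left-atrial-volume comparison between relapse groups.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import (
    PatientRecord,
    crosstab,
    diagnostic_metrics,
    group_summary,
)

__all__ = [
    "table1_path",
    "load_table1",
    "parse_cohort_table",
    "assign_printed_defects",
    "reproduce_published_results",
]

_RELAPSE_TOKENS = {"Yes, re-PVI": True, "Yes, no re-PVI": True, "None": False}


def table1_path():
    """Filesystem path of the packaged patient-table CSV."""
    return resources.files("mibgtools.data") / "table1_patients.csv"


def parse_cohort_table(source) -> list[PatientRecord]:
    """Read a patient table CSV into records.

    ``N/A`` parses as missing; the free-text relapse column maps
    "Yes, re-PVI" / "Yes, no re-PVI" to True and "None" to False — any other
    token raises, naming the offending row.
    """
    # "None" is a meaningful relapse token; only "N/A" marks missing data.
    df = pd.read_csv(source, na_values=["N/A"], keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        token = str(row["relapse"]).strip()
        if token not in _RELAPSE_TOKENS:
            raise ValueError(
                f"patient {row['id']}: unknown relapse token {token!r} "
                f"(expected one of {sorted(_RELAPSE_TOKENS)})"
            )
        records.append(
            PatientRecord(
                id=int(row["id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                af_duration=float(row["duration_years"]),
                chd=str(row["chd"]),
                la_volume_ml=None if pd.isna(row["la_volume_ml"]) else float(row["la_volume_ml"]),
                relapse=_RELAPSE_TOKENS[token],
            )
        )
    return records


def load_table1() -> list[PatientRecord]:
    """The packaged 16-patient table as records."""
    with resources.as_file(table1_path()) as p:
        return parse_cohort_table(p)


def assign_printed_defects(
    cohort: list[PatientRecord],
    n_defect_relapse: int = 4,
    n_defect_no_relapse: int = 6,
) -> list[PatientRecord]:
    """Distribute post-PVI deficit labels consistently with published counts.

    The table reports relapse per patient but not deficit status; only the
    group counts are published.  Deficits are assigned to the first
    ``n_defect_relapse`` relapsing and first ``n_defect_no_relapse``
    non-relapsing patients in id order — the resulting 2x2 table (and hence
    every diagnostic metric) is invariant to which specific patients are
    picked within each relapse stratum.
    """
    relapsers = [p for p in cohort if p.relapse]
    non_relapsers = [p for p in cohort if not p.relapse]
    if n_defect_relapse > len(relapsers) or n_defect_no_relapse > len(non_relapsers):
        raise ValueError("printed defect counts exceed the cohort's relapse strata")
    for p in cohort:
        p.defect_post = False
    for p in relapsers[:n_defect_relapse]:
        p.defect_post = True
    for p in non_relapsers[:n_defect_no_relapse]:
        p.defect_post = True
    return cohort


def reproduce_published_results() -> dict:
    """Recompute the study's tabulated results from the packaged fixture.

    Returns the 2x2 table, rounded and raw diagnostic metrics, the relapse
    proportions by deficit status, and the left-atrial-volume group summary
    (the one patient without a CT volume excluded).
    """
    cohort = assign_printed_defects(load_table1())
    table = crosstab(cohort)
    metrics = diagnostic_metrics(table)
    la = group_summary(cohort, "la_volume_ml", "relapse")
    prop_defect = 100.0 * table.tp / (table.tp + table.fp)
    prop_no_defect = 100.0 * table.fn / (table.fn + table.tn)
    return {
        "crosstab": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "diagnostics_pct": metrics.as_printed(),
        "diagnostics_raw_pct": {
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv,
            "npv": metrics.npv,
        },
        "relapse_proportion_pct": {
            "with_defect": round(prop_defect, 1),
            "without_defect": round(prop_no_defect, 1),
        },
        "la_volume_ml": {
            ("relapse" if g else "no_relapse"): {
                "mean": round(s.mean),
                "sd": None if s.sd is None else round(s.sd),
                "n": s.n,
                "n_missing": s.n_missing,
            }
            for g, s in la.items()
        },
    }
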