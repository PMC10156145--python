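"""CSF biomarker classification, motion QC, and cohort table handling.

Amyloid positivity (A+) is CSF Abeta1-42 strictly below 1000 pg/mL; tau
positivity (T+) is CSF p-tau strictly above 27 pg/mL.  The pair defines the
four AT groups; A-T+ is treated as suspected non-AD pathology and flagged for
exclusion from AT-group contrasts (and, optionally, from the A+/A- contrast).

Motion QC excludes subjects whose mean framewise displacement exceeds the
cohort mean + 2 SD, with mean and SD computed on the full input cohort in a
single pass before any exclusion.

Cohort tables are plain pandas DataFrames serialized as TSV.  Column
dictionary (one row per subject):

    subject_id    unique identifier
    csf_abeta42   CSF Abeta1-42, pg/mL
    csf_ptau      CSF p-tau, pg/mL
    age           years
    sex           0 = F, 1 = M
    education     years
    mmse          MMSE total (0-30)
    rbans_attention, rbans_language, rbans_delayed_memory,
    rbans_immediate_memory, rbans_visuoconstructional
                  RBANS index scores (mean 100, SD 15 in norms)
    mean_fd       mean framewise displacement, mm

Derived columns added by this module: amyloid_status (A+/A-), tau_status
(T+/T-), at_group, unclassifiable, at_excluded, qc_pass, and 0/1 codes
amyloid_pos (A- = 0, A+ = 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ABETA_THRESHOLD_PG_ML",
    "PTAU_THRESHOLD_PG_ML",
    "RBANS_DOMAINS",
    "classify_amyloid_tau",
    "fd_qc",
    "load_cohort",
    "save_cohort",
]

ABETA_THRESHOLD_PG_ML = 1000.0
PTAU_THRESHOLD_PG_ML = 27.0

RBANS_DOMAINS = (
    "rbans_attention",
    "rbans_language",
    "rbans_delayed_memory",
    "rbans_immediate_memory",
    "rbans_visuoconstructional",
)


def classify_amyloid_tau(
    cohort: pd.DataFrame,
    abeta_threshold: float = ABETA_THRESHOLD_PG_ML,
    ptau_threshold: float = PTAU_THRESHOLD_PG_ML,
) -> pd.DataFrame:
    """Add amyloid/tau statuses and the AT group to a cohort table.

    A+ iff csf_abeta42 < threshold (strict); T+ iff csf_ptau > threshold
    (strict); boundary values are negative.  Subjects missing either
    biomarker are flagged ``unclassifiable`` and receive no statuses.
    A-T+ subjects are flagged ``at_excluded`` (suspected non-AD pathology).
    Idempotent: re-running overwrites the derived columns.
    """
    df = cohort.copy()
    abeta = pd.to_numeric(df["csf_abeta42"], errors="coerce")
    ptau = pd.to_numeric(df["csf_ptau"], errors="coerce")
    ok = abeta.notna() & ptau.notna()
    a_pos = abeta < abeta_threshold
    t_pos = ptau > ptau_threshold
    df["unclassifiable"] = ~ok
    df["amyloid_status"] = np.where(ok, np.where(a_pos, "A+", "A-"), None)
    df["tau_status"] = np.where(ok, np.where(t_pos, "T+", "T-"), None)
    df["at_group"] = np.where(
        ok, df["amyloid_status"].astype(str) + df["tau_status"].astype(str), None
    )
    df["amyloid_pos"] = np.where(ok, a_pos.astype(float), np.nan)
    df["at_excluded"] = ok & (df["at_group"] == "A-T+")
    return df


def fd_qc(cohort: pd.DataFrame) -> pd.DataFrame:
    """Flag subjects with mean FD above cohort mean + 2 SD (``qc_pass``).

    One-sided: only excessive motion fails QC.  The threshold uses the mean
    and SD of the full input cohort, before exclusion.
    """
    df = cohort.copy()
    fd = pd.to_numeric(df["mean_fd"], errors="coerce")
    if fd.isna().any():
        raise ValueError("mean_fd missing for some subjects")
    if len(df) < 3:
        raise ValueError("FD QC needs at least 3 subjects for a usable SD")
    cutoff = fd.mean() + 2.0 * fd.std(ddof=1)
    df["qc_pass"] = fd <= cutoff
    return df


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")
    return df


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)
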