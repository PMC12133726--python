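"""Reference cohort: published per-subject ERD/AMI/TBR values.

Two validation tables from the 14-subject lower-limb motor-imagery study
this package analyses, shipped as plain TSV.  They serve as ground truth
for the summary-statistics and correlation routines and as calibration
targets for the synthetic-cohort defaults (e.g. the group-mean alpha ERD
of -1.77 dB under Attention).

Known quirks of the source tables, preserved as printed: the two tables
disagree on the Attention ERD of subjects S11-S14 (each table is loaded
as its own dataset), and the TBR table's printed group t-statistic is not
recoverable from its own columns -- the package always reports what the
column data give.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .indices import SubjectIndices
from .paradigm import ATTENTION, INATTENTION


def _load(name: str) -> pd.DataFrame:
    with resources.files("miattn.data").joinpath(name).open() as f:
        return pd.read_csv(f, sep="\t")


def erd_ami_table() -> pd.DataFrame:
    """Per-subject ERD (dB) and AMI per condition, 14 subjects."""
    return _load("table_erd_ami.tsv")


def erd_tbr_table() -> pd.DataFrame:
    """Per-subject ERD (dB) and TBR per condition, 14 subjects."""
    return _load("table_erd_tbr.tsv")


def as_subject_indices(df: pd.DataFrame) -> list[SubjectIndices]:
    """Flatten a reference table into SubjectIndices rows."""
    metric = "ami" if "attention_ami" in df.columns else "tbr"
    out = []
    for cond, prefix in ((ATTENTION, "attention"), (INATTENTION, "inattention")):
        for _, row in df.iterrows():
            out.append(SubjectIndices(
                subject=row["subject"], condition=cond,
                erd=float(row[f"{prefix}_erd"]),
                **{metric: float(row[f"{prefix}_{metric}"])}))
    return out
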