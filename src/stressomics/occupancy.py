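"""Site occupancy and methyl stoichiometry from integrated XIC areas.

Relative phosphorylation (occupancy) of a site is the area of its
phosphopeptide divided by the summed area of the unphosphorylated peptide
and all singly phosphorylated versions of the same peptide backbone.
Relative methylation of a histone lysine state is the summed area of that
state's chemical forms over the total across all methylation states.

Input is a tidy table of integrated chromatographic peak areas, one row per
peptidoform x sample x replicate:

=============  ======================================================
column         meaning
=============  ======================================================
group_id       quantification group: shared backbone sequence and
               missed-cleavage form (missed-cleavage variants are
               separate groups, never pooled)
form_id        peptidoform within the group
site_labels    semicolon-separated site names carried by the form
               (empty for the unmodified form; multiple labels when
               localization is ambiguous or forms co-elute)
n_phospho      number of phosphate groups on the form (optional;
               defaults to 0 when site_labels is empty, else 1)
area           integrated peak area, >= 0
sample         condition label
replicate      replicate id
=============  ======================================================

A replicate whose total area is zero yields an explicit missing value
(NaN fraction, ``missing=True``): absence of signal is not evidence of
zero occupancy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "phospho_occupancy",
    "methyl_stoichiometry",
    "summarize_occupancy",
    "METHYL_STATES",
    "METHYL_FORMS",
]

#: Methyl states and the chemical forms contributing to each (the me1
#: state sums its free mono-methyl and propionylated mono-methyl forms).
METHYL_FORMS: dict[str, tuple[str, ...]] = {
    "me0": ("me0",),
    "me1": ("me1-free", "me1-prop"),
    "me2": ("me2",),
    "me3": ("me3",),
}
METHYL_STATES = tuple(METHYL_FORMS)

_REQUIRED_COLUMNS = ("group_id", "form_id", "site_labels", "area", "sample", "replicate")


def _validate_xic_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"XIC table missing columns: {missing}")
    df = records.copy()
    df["site_labels"] = df["site_labels"].fillna("").astype(str)
    if (df["area"] < 0).any():
        raise ValueError("negative XIC areas")
    keys = ["group_id", "form_id", "sample", "replicate"]
    if "charge" in df.columns:
        keys.append("charge")
    if df.duplicated(keys).any():
        dupes = df.loc[df.duplicated(keys), keys].iloc[0].tolist()
        raise ValueError(f"duplicate XIC record for {dupes}")
    if "n_phospho" not in df.columns:
        df["n_phospho"] = (df["site_labels"] != "").astype(int)
    else:
        df["n_phospho"] = df["n_phospho"].astype(int)
    return df


def phospho_occupancy(records: pd.DataFrame) -> pd.DataFrame:
    """Per-form site occupancy within each (group, sample, replicate).

    Each singly phosphorylated form's fraction is its area divided by the
    summed area of the unmodified form and *all* singly phosphorylated
    forms of the group.  Forms carrying several site labels (ambiguous
    localization / co-elution) are single rows whose labels stay pooled.
    Multiply phosphorylated forms, when present, are pooled into one
    flagged result computed against the unmodified form only, and are
    excluded from the singly-phosphorylated denominator.

    Returns a tidy frame: group_id, site_labels, sample, replicate,
    fraction, missing, is_multiphospho.
    """
    df = _validate_xic_table(records)
    out = []
    for (group, sample, replicate), sub in df.groupby(
        ["group_id", "sample", "replicate"], sort=True
    ):
        unmod = sub[sub["n_phospho"] == 0]
        if len(unmod) == 0:
            raise ValueError(f"group {group!r} has no unmodified form")
        if len(unmod) > 1:
            raise ValueError(f"group {group!r} has multiple unmodified forms")
        singly = sub[sub["n_phospho"] == 1]
        multi = sub[sub["n_phospho"] >= 2]
        unmod_area = float(unmod["area"].iloc[0])
        denom = unmod_area + float(singly["area"].sum())
        for _, row in singly.iterrows():
            frac = row["area"] / denom if denom > 0 else np.nan
            out.append(
                {
                    "group_id": group,
                    "site_labels": row["site_labels"],
                    "sample": sample,
                    "replicate": replicate,
                    "fraction": frac,
                    "missing": denom <= 0,
                    "is_multiphospho": False,
                }
            )
        if len(multi) > 0:
            multi_area = float(multi["area"].sum())
            multi_denom = unmod_area + multi_area
            labels = sorted(
                {lab for labs in multi["site_labels"] for lab in labs.split(";") if lab}
            )
            out.append(
                {
                    "group_id": group,
                    "site_labels": ";".join(labels),
                    "sample": sample,
                    "replicate": replicate,
                    "fraction": multi_area / multi_denom if multi_denom > 0 else np.nan,
                    "missing": multi_denom <= 0,
                    "is_multiphospho": True,
                }
            )
    return pd.DataFrame(out)


def methyl_stoichiometry(
    records: pd.DataFrame, charge: int | None = 3
) -> pd.DataFrame:
    """Methyl-state stoichiometry per (sample, replicate).

    ``form_id`` must use the five chemical form names (me0, me1-free,
    me1-prop, me2, me3); all five must be present (areas may be zero).
    By default only charge-3 areas are used when the table has a
    ``charge`` column; pass ``charge=None`` to sum all charge states.

    Returns a tidy frame: sample, replicate, state, fraction, missing.
    The four state fractions sum to 1 whenever the total area is positive.
    """
    df = records.copy()
    if "group_id" not in df.columns:
        df["group_id"] = "h3k36"
    if "site_labels" not in df.columns:
        df["site_labels"] = ""
    df = _validate_xic_table(df)
    if charge is not None and "charge" in df.columns:
        df = df[df["charge"] == charge]
    known_forms = {f for forms in METHYL_FORMS.values() for f in forms}
    unknown = set(df["form_id"]) - known_forms
    if unknown:
        raise ValueError(f"unknown methyl form ids: {sorted(unknown)}")
    out = []
    for (sample, replicate), sub in df.groupby(["sample", "replicate"], sort=True):
        present = set(sub["form_id"])
        absent = known_forms - present
        if absent:
            raise ValueError(
                f"sample {sample!r} replicate {replicate!r} lacks forms {sorted(absent)}"
            )
        areas = sub.groupby("form_id")["area"].sum()
        total = float(areas.sum())
        for state, forms in METHYL_FORMS.items():
            state_area = float(sum(areas.get(f, 0.0) for f in forms))
            out.append(
                {
                    "sample": sample,
                    "replicate": replicate,
                    "state": state,
                    "fraction": state_area / total if total > 0 else np.nan,
                    "missing": total <= 0,
                }
            )
    return pd.DataFrame(out)


def summarize_occupancy(
    results: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Mean, sd and n of fractions across replicates.

    Missing (flagged) replicates are excluded from n; sd is NaN for a
    single replicate.  ``by`` defaults to every grouping column present
    among group_id, site_labels, state and sample.
    """
    if by is None:
        by = [
            c for c in ("group_id", "site_labels", "state", "sample")
            if c in results.columns
        ]
    if not by:
        raise ValueError("no grouping columns found")
    ok = results[~results.get("missing", pd.Series(False, index=results.index))]
    summary = (
        ok.groupby(by, sort=True)["fraction"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    summary["n"] = summary["n"].astype(int)
    return summary
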