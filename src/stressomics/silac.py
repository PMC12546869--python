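"""Label-swap SILAC differential-abundance pipeline.

Processes per-protein median log2 heavy-to-light (H/L) ratios from a
forward/reverse label-swap design (reverse = wildtype heavy): filtering,
per-replicate median-centring, orientation to mutant:wildtype, one-sample
t-testing with Benjamini-Hochberg FDR, and the two label-QC estimators
(heavy-label incorporation and arginine-to-proline conversion).

The protein-level input is a long table with columns: protein_id,
replicate_id, orientation ("forward"/"reverse"), median_log2_hl,
n_peptides, is_contaminant, is_decoy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "LabelQc",
    "filter_proteins",
    "normalize_and_orient",
    "differential_abundance",
    "estimate_incorporation",
    "estimate_proline_conversion",
    "CONTAMINANT_PREFIX",
    "DECOY_PREFIX",
]

logger = logging.getLogger(__name__)

#: Default id prefixes marking contaminant/decoy entries in search-engine
#: output when explicit flag columns are absent.
CONTAMINANT_PREFIX = "contam_"
DECOY_PREFIX = "rev_"

_PROTEIN_COLUMNS = (
    "protein_id",
    "replicate_id",
    "orientation",
    "median_log2_hl",
    "n_peptides",
)


@dataclass(frozen=True)
class LabelQc:
    """SILAC labelling quality metrics, both fractions in [0, 1]."""

    incorporation_fraction: float
    proline_conversion_fraction: float

    def __post_init__(self) -> None:
        for name in ("incorporation_fraction", "proline_conversion_fraction"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")


def _validate_protein_table(summaries: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _PROTEIN_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"protein table missing columns: {missing}")
    df = summaries.copy()
    bad = set(df["orientation"]) - {"forward", "reverse"}
    if bad:
        raise ValueError(f"invalid orientation values: {sorted(bad)}")
    if "is_contaminant" not in df.columns:
        df["is_contaminant"] = df["protein_id"].str.startswith(CONTAMINANT_PREFIX)
    if "is_decoy" not in df.columns:
        df["is_decoy"] = df["protein_id"].str.startswith(DECOY_PREFIX)
    return df


def filter_proteins(summaries: pd.DataFrame) -> pd.DataFrame:
    """Apply identification-quality filters to the protein table.

    Removes contaminant and decoy entries, drops any protein identified by
    fewer than 2 peptides in either replicate, and retains only proteins
    with a ratio in every replicate of the experiment.  Filter counts are
    logged.
    """
    df = _validate_protein_table(summaries)
    n_in = len(df)
    df = df[~(df["is_contaminant"] | df["is_decoy"])]
    n_flagged = n_in - len(df)

    low = df.loc[df["n_peptides"] < 2, "protein_id"].unique()
    df = df[~df["protein_id"].isin(low)]

    all_reps = set(summaries["replicate_id"].unique())
    rep_counts = df.groupby("protein_id")["replicate_id"].nunique()
    complete = rep_counts[rep_counts == len(all_reps)].index
    df = df[df["protein_id"].isin(complete)]
    logger.info(
        "filter_proteins: %d rows in, %d contaminant/decoy, %d low-peptide "
        "proteins, %d rows out",
        n_in, n_flagged, len(low), len(df),
    )
    return df.reset_index(drop=True)


def normalize_and_orient(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median-centre log2 H/L ratios per replicate, then orient to
    mutant:wildtype by multiplying reverse-label replicates by -1.

    Adds the column ``oriented_log2fc``.  A replicate with no retained
    proteins is an error.
    """
    df = _validate_protein_table(summaries)
    out = []
    for rep, sub in df.groupby("replicate_id", sort=True):
        if len(sub) == 0 or sub["median_log2_hl"].isna().all():
            raise ValueError(f"replicate {rep!r} has no retained proteins")
        orientations = sub["orientation"].unique()
        if len(orientations) != 1:
            raise ValueError(f"replicate {rep!r} mixes label orientations")
        centred = sub["median_log2_hl"] - sub["median_log2_hl"].median()
        sign = -1.0 if orientations[0] == "reverse" else 1.0
        sub = sub.copy()
        sub["oriented_log2fc"] = sign * centred
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def differential_abundance(
    oriented: pd.DataFrame,
    fc_threshold: float = 0.8,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-protein one-sample t-test of oriented log2 ratios against 0,
    with BH FDR across all tested proteins.

    Proteins with fewer than 2 replicate values are excluded (logged).
    Zero-variance proteins have no distributional basis for a t-test:
    their p and q are NaN and they are excluded from the BH adjustment.
    A call of up/down additionally requires |mean log2 FC| >= fc_threshold.
    With only two replicates the t-test has a single degree of freedom and
    minimal power; a warning notes this.
    """
    if "oriented_log2fc" not in oriented.columns:
        raise ValueError("run normalize_and_orient first (no oriented_log2fc column)")
    wide = oriented.pivot_table(
        index="protein_id", columns="replicate_id", values="oriented_log2fc"
    )
    n_values = wide.notna().sum(axis=1)
    excluded = wide.index[n_values < 2]
    if len(excluded):
        logger.info(
            "differential_abundance: %d protein(s) excluded with <2 replicate values",
            len(excluded),
        )
    wide = wide[n_values >= 2]
    values = wide.to_numpy()
    n = np.sum(~np.isnan(values), axis=1)
    if n.size and int(n.max()) <= 2:
        warnings.warn(
            "t-test with 2 replicates has 1 degree of freedom; power is minimal",
            stacklevel=2,
        )
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    if degenerate.any():
        logger.info(
            "differential_abundance: %d zero-variance protein(s) not tested",
            int(degenerate.sum()),
        )
    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_fdr(p[tested])
    significant = (q < q_threshold) & ~np.isnan(q)
    call = np.where(
        significant & (mean >= fc_threshold),
        "up",
        np.where(significant & (mean <= -fc_threshold), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "protein_id": wide.index,
            "mean_log2_fc": mean,
            "n_replicates": n,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "call": call,
        }
    ).reset_index(drop=True)


def estimate_incorporation(peptides: pd.DataFrame) -> float:
    """Mean heavy-label incorporation across K/R-containing peptides of a
    heavy-labelled sample: per peptide H/(H+L), zero-sum peptides skipped.

    Expects columns ``sequence``, ``heavy_intensity``, ``light_intensity``.
    """
    df = peptides[peptides["sequence"].str.contains("[KR]", regex=True)]
    h = df["heavy_intensity"].astype(float).to_numpy()
    l = df["light_intensity"].astype(float).to_numpy()
    total = h + l
    ok = total > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(h[ok] / total[ok]))


def estimate_proline_conversion(peptides: pd.DataFrame) -> float:
    """Mean arginine-to-proline conversion across proline-containing
    peptides: per peptide Pro6 / (Pro6 + Pro0) intensity, zero-sum
    peptides skipped.

    Expects columns ``sequence``, ``pro6_intensity``, ``pro0_intensity``.
    """
    df = peptides[peptides["sequence"].str.contains("P")]
    if len(df) == 0:
        raise ValueError("no proline-containing peptides")
    p6 = df["pro6_intensity"].astype(float).to_numpy()
    p0 = df["pro0_intensity"].astype(float).to_numpy()
    total = p6 + p0
    ok = total > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(p6[ok] / total[ok]))
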