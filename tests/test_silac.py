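"""Label-swap SILAC filtering, normalization, testing and label QC."""

import numpy as np
import pandas as pd
import pytest

from stressomics.silac import (
    differential_abundance,
    estimate_incorporation,
    estimate_proline_conversion,
    filter_proteins,
    normalize_and_orient,
)
from stressomics.synthetic import gen_silac_experiment


def protein_rows(pid, values, n_peptides=(5, 5), contaminant=False, decoy=False):
    rows = []
    for rep, (orientation, value, npep) in enumerate(
        zip(("forward", "reverse"), values, n_peptides), start=1
    ):
        rows.append({
            "protein_id": pid, "replicate_id": rep, "orientation": orientation,
            "median_log2_hl": value, "n_peptides": npep,
            "is_contaminant": contaminant, "is_decoy": decoy,
        })
    return rows


# --- filtering -----------------------------------------------------------

def test_filter_removes_low_peptide_protein_in_either_replicate():
    df = pd.DataFrame(
        protein_rows("A", (0.1, 0.2), n_peptides=(5, 1))
        + protein_rows("B", (0.1, 0.2), n_peptides=(2, 2))
    )
    out = filter_proteins(df)
    assert set(out["protein_id"]) == {"B"}  # exactly-2 peptides retained


def test_filter_removes_decoys_and_contaminants_regardless_of_peptides():
    df = pd.DataFrame(
        protein_rows("rev_X", (0.0, 0.0), n_peptides=(10, 10), decoy=True)
        + protein_rows("contam_K", (0.0, 0.0), n_peptides=(10, 10), contaminant=True)
        + protein_rows("A", (0.0, 0.0))
    )
    assert set(filter_proteins(df)["protein_id"]) == {"A"}


def test_filter_requires_presence_in_both_replicates():
    rows = protein_rows("A", (0.1, 0.2)) + protein_rows("B", (0.1, 0.2))[:1]
    out = filter_proteins(pd.DataFrame(rows))
    assert set(out["protein_id"]) == {"A"}


# --- normalization and orientation --------------------------------------

def test_reverse_label_sign_flip():
    # two proteins so medians centre symmetrically; reverse values flip sign
    df = pd.DataFrame(
        protein_rows("A", (0.5, -0.5)) + protein_rows("B", (-0.5, 0.5))
    )
    out = normalize_and_orient(df).set_index(["protein_id", "replicate_id"])
    assert out.loc[("A", 2), "oriented_log2fc"] == pytest.approx(0.5)
    assert out.loc[("B", 2), "oriented_log2fc"] == pytest.approx(-0.5)


def test_median_centring_removes_mixing_offset():
    rng = np.random.default_rng(0)
    values = rng.normal(0.3, 0.1, size=21)  # offset +0.3
    rows = []
    for i, v in enumerate(values):
        rows += protein_rows(f"P{i}", (v, -v + 0.6))
    out = normalize_and_orient(pd.DataFrame(rows))
    medians = out.groupby("replicate_id")["oriented_log2fc"].median()
    assert np.all(np.abs(medians.to_numpy()) < 1e-12)


def test_orientation_flip_is_involution_on_centred_values():
    df = pd.DataFrame(protein_rows("A", (0.2, -0.4)) + protein_rows("B", (-0.2, 0.4)))
    once = normalize_and_orient(df)
    # feed the centred (un-flipped) values back in: medians are already 0,
    # so a second pass must reproduce the same oriented values
    again = once.copy()
    sign = np.where(again["orientation"] == "reverse", -1.0, 1.0)
    again["median_log2_hl"] = sign * again["oriented_log2fc"]
    twice = normalize_and_orient(again.drop(columns=["oriented_log2fc"]))
    merged = once.merge(twice, on=["protein_id", "replicate_id"],
                        suffixes=("_1", "_2"))
    assert np.allclose(merged["oriented_log2fc_1"], merged["oriented_log2fc_2"])


# --- differential testing ------------------------------------------------

def _pipeline(df, **kwargs):
    with pytest.warns(UserWarning, match="1 degree of freedom"):
        return differential_abundance(normalize_and_orient(filter_proteins(df)),
                                      **kwargs)


def test_zero_variance_protein_flagged_not_tested():
    rng = np.random.default_rng(1)
    oriented = pd.DataFrame({
        "protein_id": ["const", "const"]
        + [f"P{i}" for i in range(20) for _ in (0, 1)],
        "replicate_id": [1, 2] * 21,
        "oriented_log2fc": [0.7, 0.7] + list(rng.normal(0, 0.1, 40)),
    })
    with pytest.warns(UserWarning, match="1 degree of freedom"):
        res = differential_abundance(oriented).set_index("protein_id")
    # identical replicate values: t undefined, excluded from BH, no call
    assert np.isnan(res.loc["const", "p_value"])
    assert np.isnan(res.loc["const", "q_value"])
    assert res.loc["const", "call"] == "unchanged"
    assert res.drop("const")["q_value"].notna().all()


def test_null_experiment_yields_no_calls():
    table, _truth = gen_silac_experiment(
        n_proteins=400, n_shifted=0, replicate_noise_sd=0.2, seed=11
    )
    res = _pipeline(table)
    assert (res["call"] == "unchanged").all()


def test_shifted_proteins_recovered_within_two_se():
    table, truth = gen_silac_experiment(
        n_proteins=500, n_shifted=20, effect_log2=1.5,
        replicate_noise_sd=0.2, seed=7,
    )
    oriented = normalize_and_orient(filter_proteins(table))
    wide = oriented.pivot_table(index="protein_id", columns="replicate_id",
                                values="oriented_log2fc")
    effects = truth.params["effects"]
    se = 0.2 / np.sqrt(2)
    recovered = 0
    for pid, eff in effects.items():
        if pid not in wide.index:
            continue  # removed by a planted low-peptide filter
        est = wide.loc[pid].mean()
        if abs(est - eff) <= 2 * se + 0.05:  # small allowance for centring shift
            recovered += 1
    assert recovered >= 0.9 * len([p for p in effects if p in wide.index])


def test_call_thresholds_require_fold_change_and_q():
    # 'big' and 'tiny' both have near-zero replicate scatter, hence huge t
    # and small q; only 'big' also clears the |log2 FC| >= 0.8 gate
    oriented = pd.DataFrame({
        "protein_id": ["big"] * 2 + ["tiny"] * 2
        + [f"null{i}" for i in range(10) for _ in (0, 1)],
        "replicate_id": [1, 2] * 12,
        "oriented_log2fc": [2.0, 2.001, 0.05, 0.0501] + list(
            np.random.default_rng(3).normal(0, 0.05, 20)
        ),
    })
    with pytest.warns(UserWarning, match="1 degree of freedom"):
        res = differential_abundance(oriented).set_index("protein_id")
    assert res.loc["big", "call"] == "up"
    assert res.loc["tiny", "q_value"] < 0.05
    assert res.loc["tiny", "call"] == "unchanged"
    assert (res.loc[[f"null{i}" for i in range(10)], "call"] == "unchanged").all()


# --- label QC estimators -------------------------------------------------

@pytest.mark.parametrize(
    "h, l, expected",
    [([99.0], [1.0], 0.99), ([1.0], [0.0], 1.0)],
)
def test_incorporation_single_peptide(h, l, expected):
    df = pd.DataFrame({
        "sequence": ["PEPTIDEK"] * len(h),
        "heavy_intensity": h,
        "light_intensity": l,
    })
    assert estimate_incorporation(df) == pytest.approx(expected)


def test_incorporation_mean_across_peptides_skips_zero_sum():
    df = pd.DataFrame({
        "sequence": ["AAK", "AAR", "CCK"],
        "heavy_intensity": [995.0, 985.0, 0.0],
        "light_intensity": [5.0, 15.0, 0.0],
    })
    assert estimate_incorporation(df) == pytest.approx(0.99)


def test_incorporation_ignores_peptides_without_k_or_r():
    df = pd.DataFrame({
        "sequence": ["AAGG", "AAK"],
        "heavy_intensity": [0.0, 99.0],
        "light_intensity": [100.0, 1.0],
    })
    assert estimate_incorporation(df) == pytest.approx(0.99)


def test_proline_conversion_matches_definition_scale():
    df = pd.DataFrame({
        "sequence": ["APK"],
        "pro6_intensity": [6.3],
        "pro0_intensity": [93.7],
    })
    assert estimate_proline_conversion(df) == pytest.approx(0.063)


def test_proline_conversion_mean_and_zero():
    df = pd.DataFrame({
        "sequence": ["APK", "PPR"],
        "pro6_intensity": [5.0, 7.0],
        "pro0_intensity": [95.0, 93.0],
    })
    assert estimate_proline_conversion(df) == pytest.approx(0.06)
    zero = pd.DataFrame({
        "sequence": ["APK"], "pro6_intensity": [0.0], "pro0_intensity": [90.0],
    })
    assert estimate_proline_conversion(zero) == 0.0


def test_proline_conversion_requires_proline():
    df = pd.DataFrame({
        "sequence": ["AAK"], "pro6_intensity": [1.0], "pro0_intensity": [9.0],
    })
    with pytest.raises(ValueError, match="proline"):
        estimate_proline_conversion(df)
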