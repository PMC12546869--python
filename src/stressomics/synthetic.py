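"""Synthetic-data generators with persisted ground truth.

Every input the pipeline consumes can be generated here with known true
parameters, so each estimator is testable end-to-end without any external
download.  All intensity-like quantities (XIC areas, OD600) carry
multiplicative lognormal noise: they are positive and their noise scales
with signal.

Seeding: a single root seed fans out to per-scenario child seeds through
``numpy.random.SeedSequence(root_seed, spawn_key=(counter,))`` where each
generator owns a fixed counter (xic=1, silac=2, growth=3, methyl=4,
enrichment=5).  Identical seeds reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthCurve

__all__ = [
    "SyntheticTruth",
    "gen_xic_table",
    "gen_silac_experiment",
    "gen_growth_curves",
    "gen_methyl_profiles",
    "gen_enrichment_universe",
]

_SCENARIO_COUNTERS = {"xic": 1, "silac": 2, "growth": 3, "methyl": 4, "enrichment": 5}


@dataclass(frozen=True)
class SyntheticTruth:
    """True parameters behind one generated dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)


def _rng(scenario: str, seed: int) -> np.random.Generator:
    counter = _SCENARIO_COUNTERS[scenario]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(counter,)))


def _lognoise(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    if sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if sd == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, sd, size=size))


# ---------------------------------------------------------------------------
# XIC area tables (phosphosite occupancy)
# ---------------------------------------------------------------------------

def gen_xic_table(
    occupancies: Mapping[str, float | Mapping[str, float]],
    n_replicates: int = 4,
    noise_sd: float = 0.2,
    missed_cleavage_fraction: float = 0.0,
    base_abundance: float = 1e6,
    sample: str = "NaCl",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate an XIC area table with known site occupancies.

    ``occupancies`` maps group id to either a single occupancy (one
    phosphosite) or a site -> occupancy mapping (multi-site group; the
    occupancies of one group must sum to <= 1).  Each group gets one
    unmodified form plus one form per site; areas are
    ``base_abundance x form-fraction x lognormal(0, noise_sd)``.  A
    leading fraction of groups is duplicated as a missed-cleavage variant
    (suffix ``__mc1``) with the same true occupancy, quantified as its own
    group.
    """
    truth_occ: dict[str, dict[str, float]] = {}
    for gid, value in occupancies.items():
        sites = {"S1": float(value)} if np.isscalar(value) else {
            k: float(v) for k, v in value.items()
        }
        if any(not 0.0 <= th <= 1.0 for th in sites.values()):
            raise ValueError(f"occupancies of group {gid!r} outside [0, 1]")
        if sum(sites.values()) > 1.0 + 1e-12:
            raise ValueError(f"occupancies of group {gid!r} sum above 1")
        truth_occ[gid] = sites

    group_ids = list(truth_occ)
    n_mc = int(round(missed_cleavage_fraction * len(group_ids)))
    for gid in group_ids[:n_mc]:
        truth_occ[f"{gid}__mc1"] = dict(truth_occ[gid])

    rng = _rng("xic", seed)
    rows = []
    for gid, sites in truth_occ.items():
        unmod_frac = 1.0 - sum(sites.values())
        forms = [("unmod", "", unmod_frac), *[
            (f"p{site}", site, theta) for site, theta in sites.items()
        ]]
        for rep in range(1, n_replicates + 1):
            for form_id, site_labels, frac in forms:
                noise = _lognoise(rng, noise_sd, None)
                rows.append(
                    {
                        "group_id": gid,
                        "form_id": form_id,
                        "site_labels": site_labels,
                        "area": base_abundance * frac * float(noise),
                        "sample": sample,
                        "replicate": rep,
                    }
                )
    truth = SyntheticTruth(
        scenario="xic",
        seed=seed,
        params={
            "occupancies": truth_occ,
            "n_replicates": n_replicates,
            "noise_sd": noise_sd,
        },
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# label-swap SILAC experiments
# ---------------------------------------------------------------------------

def gen_silac_experiment(
    n_proteins: int = 3000,
    n_shifted: int = 50,
    effect_log2: float = 1.5,
    replicate_noise_sd: float = 0.2,
    mixing_offsets: tuple[float, float] = (0.3, -0.3),
    contaminant_fraction: float = 0.01,
    low_peptide_fraction: float = 0.05,
    peptide_count_mean: float = 6.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a forward/reverse label-swap protein table with known truth.

    A random subset of ``n_shifted`` proteins is shifted by
    ``+-effect_log2`` (random sign) in the mutant.  The forward replicate
    (mutant heavy) stores ``truth + noise + offset``; the reverse replicate
    (wildtype heavy) stores ``-truth + noise + offset``, so the raw tables
    carry a global mixing offset that per-replicate median-centring must
    remove.  Contaminant/decoy entries and proteins with a single peptide
    are planted to exercise the filters.
    """
    if n_shifted > n_proteins:
        raise ValueError("n_shifted exceeds n_proteins")
    rng = _rng("silac", seed)
    ids = [f"P{i:05d}" for i in range(1, n_proteins + 1)]
    shifted_idx = rng.choice(n_proteins, size=n_shifted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_shifted)
    effects = np.zeros(n_proteins)
    effects[shifted_idx] = signs * effect_log2

    n_peptides = 2 + rng.poisson(max(peptide_count_mean - 2.0, 0.0), size=n_proteins)
    n_low = int(round(low_peptide_fraction * n_proteins))
    low_idx = rng.choice(n_proteins, size=n_low, replace=False)
    n_peptides[low_idx] = 1

    rows = []
    for rep, (orientation, offset) in enumerate(
        zip(("forward", "reverse"), mixing_offsets), start=1
    ):
        sign = 1.0 if orientation == "forward" else -1.0
        noise = rng.normal(0.0, replicate_noise_sd, size=n_proteins)
        raw = sign * effects + noise + offset
        for i, pid in enumerate(ids):
            rows.append(
                {
                    "protein_id": pid,
                    "replicate_id": rep,
                    "orientation": orientation,
                    "median_log2_hl": raw[i],
                    "n_peptides": int(n_peptides[i]),
                    "is_contaminant": False,
                    "is_decoy": False,
                }
            )
        n_contam = int(round(contaminant_fraction * n_proteins))
        for j in range(n_contam):
            flag = "contam" if j % 2 == 0 else "rev"
            rows.append(
                {
                    "protein_id": f"{flag}_X{j:03d}",
                    "replicate_id": rep,
                    "orientation": orientation,
                    "median_log2_hl": float(rng.normal(0.0, replicate_noise_sd) + offset),
                    "n_peptides": int(2 + rng.poisson(4)),
                    "is_contaminant": flag == "contam",
                    "is_decoy": flag == "rev",
                }
            )
    truth = SyntheticTruth(
        scenario="silac",
        seed=seed,
        params={
            "effects": {ids[i]: float(effects[i]) for i in shifted_idx},
            "mixing_offsets": list(mixing_offsets),
            "replicate_noise_sd": replicate_noise_sd,
            "low_peptide_ids": [ids[i] for i in sorted(low_idx)],
        },
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def logistic_od(
    t: np.ndarray,
    doubling_min: float,
    od0: float = 0.005,
    carrying_capacity: float | None = 1.2,
    lag_min: float = 0.0,
) -> np.ndarray:
    """Noise-free growth model: logistic with exponential-phase doubling
    time ``doubling_min`` (pure exponential when carrying_capacity is
    None); flat at od0 when doubling_min is not finite or non-positive."""
    t = np.asarray(t, dtype=float)
    if not np.isfinite(doubling_min) or doubling_min <= 0:
        return np.full_like(t, od0)
    r = np.log(2.0) / doubling_min
    te = np.maximum(t - lag_min, 0.0)
    if carrying_capacity is None:
        return od0 * np.exp(r * te)
    K = carrying_capacity
    return K / (1.0 + (K - od0) / od0 * np.exp(-r * te))


def gen_growth_curves(
    doubling_times: Mapping[tuple[str, str], float],
    n_replicates: int = 6,
    lag_min: float = 60.0,
    od0: float = 0.005,
    carrying_capacity: float | None = 1.2,
    noise_sd: float = 0.0,
    sampling_interval_min: float = 10.0,
    duration_min: float = 1500.0,
    seed: int = 0,
) -> tuple[list[GrowthCurve], SyntheticTruth]:
    """Generate logistic growth curves sampled every 10 min by default.

    ``doubling_times`` maps (strain, condition) to the exponential-phase
    doubling time in minutes (inf or <= 0 for a non-growing well).  Noise
    is multiplicative lognormal on OD.
    """
    rng = _rng("growth", seed)
    t = np.arange(0.0, duration_min + sampling_interval_min / 2, sampling_interval_min)
    curves = []
    for (strain, condition), dbl in sorted(doubling_times.items()):
        for rep in range(1, n_replicates + 1):
            od = logistic_od(t, dbl, od0=od0, carrying_capacity=carrying_capacity,
                             lag_min=lag_min)
            od = od * _lognoise(rng, noise_sd, t.size)
            curves.append(
                GrowthCurve(
                    times=t,
                    od=od,
                    strain=strain,
                    condition=condition,
                    well=f"{strain}-{condition}-{rep}",
                    replicate=rep,
                )
            )
    truth = SyntheticTruth(
        scenario="growth",
        seed=seed,
        params={
            "doubling_times": {f"{s}|{c}": v for (s, c), v in doubling_times.items()},
            "od0": od0,
            "carrying_capacity": carrying_capacity,
            "lag_min": lag_min,
            "noise_sd": noise_sd,
        },
    )
    return curves, truth


# ---------------------------------------------------------------------------
# methyl-state profiles
# ---------------------------------------------------------------------------

def gen_methyl_profiles(
    state_distribution: Mapping[str, float],
    me1_prop_fraction: float = 0.5,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    base_abundance: float = 1e6,
    sample: str = "NaCl",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate five-form XIC areas from a known methyl-state distribution.

    ``state_distribution`` maps me0..me3 to fractions summing to 1; the
    me1 state splits between its free and propionylated chemical forms by
    ``me1_prop_fraction``.  Rows carry charge 3 (the quantified charge
    state).
    """
    states = ("me0", "me1", "me2", "me3")
    dist = {s: float(state_distribution.get(s, 0.0)) for s in states}
    if any(v < 0 for v in dist.values()) or abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError("state distribution must be non-negative and sum to 1")
    if not 0.0 <= me1_prop_fraction <= 1.0:
        raise ValueError("me1_prop_fraction outside [0, 1]")
    form_fracs = {
        "me0": dist["me0"],
        "me1-free": dist["me1"] * (1.0 - me1_prop_fraction),
        "me1-prop": dist["me1"] * me1_prop_fraction,
        "me2": dist["me2"],
        "me3": dist["me3"],
    }
    rng = _rng("methyl", seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for form_id, frac in form_fracs.items():
            rows.append(
                {
                    "group_id": "h3k36",
                    "form_id": form_id,
                    "site_labels": "",
                    "n_phospho": 0,
                    "charge": 3,
                    "area": base_abundance * frac * float(_lognoise(rng, noise_sd, None)),
                    "sample": sample,
                    "replicate": rep,
                }
            )
    truth = SyntheticTruth(
        scenario="methyl",
        seed=seed,
        params={
            "state_distribution": dist,
            "me1_prop_fraction": me1_prop_fraction,
            "noise_sd": noise_sd,
            "n_replicates": n_replicates,
        },
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# annotation universes with planted enrichment
# ---------------------------------------------------------------------------

def gen_enrichment_universe(
    n_genes: int = 6000,
    study_size: int = 100,
    planted_terms: Mapping[str, tuple[int, float]] | None = None,
    n_null_terms: int = 50,
    null_term_size: int = 20,
    seed: int = 0,
) -> tuple[list[str], list[str], dict[str, list[str]], SyntheticTruth]:
    """Generate a gene universe, a study set, and term annotations.

    ``planted_terms`` maps term id to (term size, odds ratio): the term's
    genes are drawn without replacement with study genes weighted by the
    odds ratio, so the term is over-represented in the study set at that
    odds.  Null terms are drawn uniformly.  Returns (study, background,
    annotations, truth).
    """
    planted_terms = dict(planted_terms or {})
    if any(size > n_genes for size, _ in planted_terms.values()):
        raise ValueError("planted term size exceeds universe")
    rng = _rng("enrichment", seed)
    background = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    study_idx = rng.choice(n_genes, size=study_size, replace=False)
    in_study = np.zeros(n_genes, dtype=bool)
    in_study[study_idx] = True
    study = [background[i] for i in sorted(study_idx)]

    annotations: dict[str, list[str]] = {}
    for term, (size, odds) in sorted(planted_terms.items()):
        weights = np.where(in_study, odds, 1.0).astype(float)
        weights /= weights.sum()
        members = rng.choice(n_genes, size=size, replace=False, p=weights)
        annotations[term] = [background[i] for i in sorted(members)]
    for j in range(n_null_terms):
        members = rng.choice(n_genes, size=null_term_size, replace=False)
        annotations[f"NULL{j:03d}"] = [background[i] for i in sorted(members)]

    truth = SyntheticTruth(
        scenario="enrichment",
        seed=seed,
        params={
            "planted_terms": {t: list(v) for t, v in planted_terms.items()},
            "study_size": study_size,
            "n_genes": n_genes,
        },
    )
    return study, background, annotations, truth
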