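"""Repeatable simulation studies over the full analysis path.

These functions run the pipeline's operational code on freshly simulated
studies and summarise whether the planted structure is recovered:

* :func:`feature_recovery_trial` — classify genes from simulated SG/Total
  counts, test the enriched-vs-depleted length / GC / abundance contrasts,
  and correlate eCLIP peak counts (replicate-intersected, gene-assigned)
  with transcript length and GC.
* :func:`module_association_trial` — run the proteomics module stage on a
  simulated bundle, either without planted effects (null calibration) or
  with a single planted (module, enriched) diagnosis shift.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import partition as part
from . import peaks as pk
from . import stats as st
from . import synthetic as syn
from .disease import run_module_association
from .synthetic import PlantedModuleEffect, SyntheticConfig

#: Seeds derived from a base seed stay below 2**31.
_SEED_MOD = 2**31 - 1


def derive_seed(base: int, offset: int) -> int:
    return (base * 1_000_003 + offset) % _SEED_MOD


def feature_recovery_trial(
    seed: int,
    n_genes: int = 5000,
    protein: str = "G3BP1",
    condition: str = "Ctrl",
) -> dict:
    """One end-to-end recovery trial on a fresh simulated study.

    Returns the Wilcoxon p-values and median differences for the
    enriched-vs-depleted contrasts (length, GC, abundance) and the Pearson
    correlations of per-gene common-peak counts with log length and GC.
    """
    config = SyntheticConfig(seed=seed, n_genes=n_genes)
    rngs = syn._stage_rngs(config.seed)
    models, features = syn.generate_annotation(config, rngs["annotation"])
    tracks = syn.generate_peaks(
        models, features, config, rngs["peaks"],
        proteins=(protein,), conditions=(condition,),
    )
    expression, _ = syn.generate_expression(features, config, rngs["expression"])

    tpm_sg = part.tpm_from_expression(expression, "SG")
    tpm_total = part.tpm_from_expression(expression, "Total")
    classes = part.classify_sg(tpm_sg, tpm_total)
    merged = classes.merge(features, on="gene_id")

    out: dict = {"seed": seed, "n_genes": n_genes}
    enr = merged[merged["sg_class"] == "enriched"]
    dep = merged[merged["sg_class"] == "depleted"]
    out["n_enriched"] = len(enr)
    out["n_depleted"] = len(dep)
    for name, col in (
        ("length", "length_total"),
        ("gc", "gc_fraction"),
        ("abundance", "tpm_total"),
    ):
        res = st.wilcoxon_rank_sum(enr[col].to_numpy(), dep[col].to_numpy(), mode="normal")
        out[f"{name}_p"] = res.p_value
        out[f"{name}_median_diff"] = float(enr[col].median() - dep[col].median())

    common = pk.intersect_replicates(
        tracks[(protein, condition, 1)], tracks[(protein, condition, 2)]
    )
    assigned = pk.assign_peaks(common, models)
    profiles = pk.gene_binding_profiles(assigned)
    counts = (
        features.set_index("gene_id")
        .join(profiles.set_index("gene_id")["peak_count"])["peak_count"]
        .fillna(0.0)
        .to_numpy()
    )
    log_len = np.log(features["length_total"].to_numpy(dtype=float))
    gc = features["gc_fraction"].to_numpy(dtype=float)
    out["peak_length_r"] = st.pearson(log_len, counts).statistic
    out["peak_gc_r"] = st.pearson(gc, counts).statistic
    out["n_common_peaks"] = int(len(common))
    dist = pk.region_distribution(assigned)
    frac_3utr = dist.loc[dist["region"] == "3UTR", "fraction"]
    out["utr3_peak_fraction"] = float(frac_3utr.iloc[0]) if len(frac_3utr) else 0.0
    return out


def feature_recovery_success(trial: dict, alpha: float = 0.01) -> bool:
    """Planted orderings recovered: enriched longer, AT-richer, less abundant;
    peak counts rise with length and fall with GC."""
    return (
        trial["length_p"] < alpha
        and trial["length_median_diff"] > 0
        and trial["gc_p"] < alpha
        and trial["gc_median_diff"] < 0
        and trial["abundance_p"] < alpha
        and trial["abundance_median_diff"] < 0
        and trial["peak_length_r"] > 0
        and trial["peak_gc_r"] < 0
    )


def module_association_trial(
    seed: int,
    planted: tuple[PlantedModuleEffect, ...] = (),
    n_genes: int = 5000,
) -> dict:
    """One module-stage trial on a simulated proteomics bundle.

    Classes come from the planted true TPMs (the classification rules are
    exercised, the sequencing-noise stage is not needed for this stage).
    Returns the per-set q-values, which set attained the family minimum,
    and the Braak/CERAD correlations of every planted set.
    """
    config = SyntheticConfig(seed=seed, n_genes=n_genes)
    config.proteomics = dataclasses.replace(config.proteomics, planted_effects=tuple(planted))
    rngs = syn._stage_rngs(config.seed)
    features = syn.generate_features(config, rngs["annotation"])
    _, truth = syn.generate_expression(features, config, rngs["expression"], with_counts=False)
    classes = part.classify_sg(truth["sg_tpm"], truth["total_tpm"])
    bundle = syn.generate_proteomics(classes, config, rngs["proteomics"])
    results = run_module_association(bundle, classes)
    tested = results[results["p"].notna()]
    out = {
        "seed": seed,
        "n_evaluated": int(len(tested)),
        "n_q05": int((tested["q"] < 0.05).sum()),
        "q_values": tested["q"].to_numpy(),
    }
    if len(tested):
        imin = tested["q"].idxmin()
        out["min_q_set"] = (results.loc[imin, "module"], results.loc[imin, "sg_class"])
    for effect in planted:
        row = results[
            (results["module"] == effect.module) & (results["sg_class"] == effect.sg_class)
        ]
        if not row.empty:
            out[f"braak_r_{effect.module}_{effect.sg_class}"] = float(row["braak_r"].iloc[0])
            out[f"q_{effect.module}_{effect.sg_class}"] = float(row["q"].iloc[0])
    return out


def null_calibration(n_trials: int, base_seed: int, n_genes: int = 5000) -> dict:
    """Fraction of (module, class) sets reaching q < 0.05 with nothing planted."""
    total_sets = 0
    total_hits = 0
    for t in range(n_trials):
        trial = module_association_trial(derive_seed(base_seed, t), planted=())
        total_sets += trial["n_evaluated"]
        total_hits += trial["n_q05"]
    return {
        "n_trials": n_trials,
        "total_sets": total_sets,
        "total_hits": total_hits,
        "hit_fraction": total_hits / total_sets if total_sets else float("nan"),
    }


def planted_module_study(
    n_trials: int,
    base_seed: int,
    module: str = "M1",
    shifts: tuple[float, float, float] = (0.0, -0.5, -1.0),
) -> dict:
    """Repeated planted-shift trials: does the planted set attain the
    family-minimum q, and does its Braak correlation carry the planted sign?"""
    effect = PlantedModuleEffect(module, "enriched", shifts)
    n_min_q = 0
    n_sign_ok = 0
    planted_sign = np.sign(shifts[2] - shifts[0])
    for t in range(n_trials):
        trial = module_association_trial(derive_seed(base_seed, t), planted=(effect,))
        if trial.get("min_q_set") == (module, "enriched"):
            n_min_q += 1
        braak_r = trial.get(f"braak_r_{module}_enriched")
        if braak_r is not None and np.sign(braak_r) == planted_sign:
            n_sign_ok += 1
    return {
        "n_trials": n_trials,
        "n_min_q": n_min_q,
        "n_braak_sign_ok": n_sign_ok,
        "min_q_fraction": n_min_q / n_trials,
        "braak_sign_fraction": n_sign_ok / n_trials,
    }
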