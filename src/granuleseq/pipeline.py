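"""End-to-end orchestration: simulate, run every stage, manifest, report.

``run_pipeline`` executes the stages in dependency order (annotation ->
peaks -> partition -> feature statistics -> disease -> modules), writing
every table as TSV under a run directory together with a JSON manifest
(input digests, thresholds in effect, per-stage row counts).  The run is
fully determined by the configuration and seed; re-running on identical
inputs reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import annotation as ann
from . import disease as dis
from . import partition as part
from . import peaks as pk
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger(__name__)

PROTEINS = ("G3BP1", "G3BP2")
CONDITIONS = ("Ctrl", "AS")
CONTRASTS = ("siG3BP1", "siG3BP2", "AS")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: syn.SyntheticConfig,
    outdir: str | Path,
    skip_stages: set[str] = frozenset(),
    thresholds: part.SGThresholds = part.SGThresholds(),
) -> dict:
    """Simulate a study and run every analysis stage; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": _plain(dataclasses.asdict(config)),
        "thresholds": dataclasses.asdict(thresholds),
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    # --- simulate -------------------------------------------------------
    study = syn.simulate_study(config, with_sequences=True)
    fixture_paths = syn.write_study(study, outdir / "inputs")
    manifest["inputs"] = {k: str(v) for k, v in fixture_paths.items()}
    manifest["stages"]["simulate"] = {"n_genes": config.n_genes}

    # --- annotation features -------------------------------------------
    models = ann.load_annotation(fixture_paths["gtf"])
    seqs = Fasta(str(fixture_paths["fasta"]))
    features = ann.features_table(models, seqs)
    _write(features, outdir / "features.tsv", manifest)
    biotypes = features.set_index("gene_id")["biotype"].to_dict()

    # --- peaks ----------------------------------------------------------
    if "peaks" not in skip_stages:
        common_tracks: dict[tuple[str, str], pd.DataFrame] = {}
        assignments = []
        for protein in PROTEINS:
            for condition in CONDITIONS:
                rep1 = pk.read_peaks(
                    fixture_paths[f"peaks_{protein}_{condition}_rep1"], protein, condition, 1
                )
                rep2 = pk.read_peaks(
                    fixture_paths[f"peaks_{protein}_{condition}_rep2"], protein, condition, 2
                )
                common = pk.intersect_replicates(rep1, rep2)
                common_tracks[(protein, condition)] = common
                assignments.append(pk.assign_peaks(common, models))
        assigned = pd.concat(assignments, ignore_index=True)
        _write(assigned, outdir / "peak_assignments.tsv", manifest)
        _write(pk.region_distribution(assigned, biotypes), outdir / "region_distribution.tsv", manifest)
        profiles = pk.gene_binding_profiles(assigned)
        _write(profiles, outdir / "binding_profiles.tsv", manifest)
        overlap = pk.peak_set_overlap(
            {f"{p}_{c}": df for (p, c), df in common_tracks.items()}
        )
        _write(overlap, outdir / "peak_set_overlap.tsv", manifest)
        manifest["stages"]["peaks"] = {
            "common_peaks": {f"{p}_{c}": int(len(df)) for (p, c), df in common_tracks.items()}
        }
    else:
        profiles = None
        manifest["stages"]["peaks"] = "skipped"

    # --- SG partition ---------------------------------------------------
    expr = part.read_expression(fixture_paths["expression"])
    tpm_sg = part.tpm_from_expression(expr, "SG")
    tpm_total = part.tpm_from_expression(expr, "Total")
    classes = part.classify_sg(tpm_sg, tpm_total, thresholds)
    _write(classes, outdir / "sg_classification.tsv", manifest)
    _write(
        part.composition(classes["sg_class"]), outdir / "sg_class_composition.tsv", manifest
    )
    de_frames = []
    tpm_ctrl = part.tpm_from_expression(expr, "Ctrl")
    for contrast in CONTRASTS:
        tpm_treat = part.tpm_from_expression(expr, contrast)
        de_frames.append(part.classify_de(tpm_ctrl, tpm_treat, contrast=contrast))
    de = pd.concat(de_frames, ignore_index=True)
    _write(de, outdir / "de_classification.tsv", manifest)

    merged = classes.merge(features, on="gene_id")

    # cross-tabulation of DE calls, SG enrichment, and eCLIP binding
    universe = set(classes["gene_id"])
    bound = (
        set(profiles["gene_id"]) if profiles is not None else set()
    )
    sets = {
        "up_siG3BP1": set(de.loc[(de["contrast"] == "siG3BP1") & (de["de_class"] == "up"), "gene_id"]),
        "down_siG3BP1": set(de.loc[(de["contrast"] == "siG3BP1") & (de["de_class"] == "down"), "gene_id"]),
        "sg_enriched": set(classes.loc[classes["sg_class"] == "enriched", "gene_id"]),
        "eclip_bound": bound & universe,
    }
    _write(part.cross_tabulate(sets, universe), outdir / "cross_tabulation.tsv", manifest)

    # --- feature statistics (class comparisons + peak correlations) -----
    stat_rows = []
    for biotype in (ann.PROTEIN_CODING, ann.LNCRNA):
        sub = merged[merged["biotype"] == biotype]
        metrics = (
            ["length_total", "length_5utr", "length_cds", "length_3utr", "gc_fraction", "tpm_total"]
            if biotype == ann.PROTEIN_CODING
            else ["length_total", "gc_fraction", "tpm_total"]
        )
        for metric in metrics:
            for a, b in (("enriched", "depleted"), ("enriched", "neither"), ("depleted", "neither")):
                xa = sub.loc[sub["sg_class"] == a, metric].to_numpy()
                xb = sub.loc[sub["sg_class"] == b, metric].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    logger.info("skipping %s %s %s-vs-%s: empty stratum", biotype, metric, a, b)
                    continue
                res = st.wilcoxon_rank_sum(xa, xb, mode="normal")
                stat_rows.append(
                    {
                        "biotype": biotype, "metric": metric, "group_a": a, "group_b": b,
                        "n_a": len(xa), "n_b": len(xb),
                        "median_a": float(pd.Series(xa).median()),
                        "median_b": float(pd.Series(xb).median()),
                        "U": res.statistic, "p": res.p_value,
                    }
                )
    feature_tests = pd.DataFrame(stat_rows)
    if not feature_tests.empty:
        feature_tests["q"] = st.bh_fdr(feature_tests["p"].to_numpy())
    _write(feature_tests, outdir / "feature_tests.tsv", manifest)

    corr_rows = []
    if profiles is not None:
        for protein in PROTEINS:
            for condition in CONDITIONS:
                sub = profiles[(profiles["protein"] == protein) & (profiles["condition"] == condition)]
                counts = (
                    features.set_index("gene_id")
                    .join(sub.set_index("gene_id")["peak_count"])
                    ["peak_count"].fillna(0.0)
                )
                feats = features.set_index("gene_id")
                for covariate, col in (("log_length", "length_total"), ("gc_fraction", "gc_fraction")):
                    x = feats[col].astype(float).to_numpy()
                    if covariate == "log_length":
                        x = np.log(x)
                    res = st.pearson(x, counts.to_numpy())
                    corr_rows.append(
                        {
                            "protein": protein, "condition": condition,
                            "covariate": covariate, "r": res.statistic, "p": res.p_value,
                            "n": int(len(counts)),
                        }
                    )
    correlations = pd.DataFrame(corr_rows)
    _write(correlations, outdir / "peak_correlations.tsv", manifest)

    # --- disease --------------------------------------------------------
    if "disease" not in skip_stages:
        crosstab = dis.crosstab_disease(classes, study.disease_genes, features)
        _write(crosstab["fractions"], outdir / "disease_fractions.tsv", manifest)
        _write(crosstab["comparisons"], outdir / "disease_comparisons.tsv", manifest)
        manifest["stages"]["disease"] = {"n_disease_genes": len(study.disease_genes)}
    else:
        manifest["stages"]["disease"] = "skipped"

    # --- modules --------------------------------------------------------
    if "modules" not in skip_stages:
        module_results = dis.run_module_association(study.proteomics, classes)
        _write(module_results, outdir / "module_association.tsv", manifest)
        manifest["stages"]["modules"] = {
            "n_evaluated_sets": int(module_results.attrs["n_evaluated"]),
            "n_significant_q05": int((module_results["q"] < 0.05).sum()),
        }
    else:
        manifest["stages"]["modules"] = "skipped"

    for name, path in manifest["inputs"].items():
        manifest["inputs"][name] = {"path": path, "sha256": _digest(Path(path))}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["outputs"][path.name] = {
        "path": str(path),
        "rows": int(len(df)),
        "sha256": _digest(path),
    }


def render_report(outdir: str | Path) -> str:
    """Human-readable run summary assembled from the manifest and TSVs."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = ["# granuleseq run report", ""]
    lines.append(f"Seed: {manifest['seed']}")
    lines.append(f"Thresholds: {manifest['thresholds']}")
    lines.append("")

    def table(name: str, title: str, max_rows: int = 20) -> None:
        path = outdir / name
        if name not in manifest["outputs"]:
            return
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing table {path}")
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {title}")
        lines.append("")
        lines.append(df.head(max_rows).to_string(index=False))
        lines.append("")

    table("sg_class_composition.tsv", "SG class composition")
    table("region_distribution.tsv", "Peak region distribution")
    table("peak_set_overlap.tsv", "Peak set overlap (UpSet counts)", 16)
    table("feature_tests.tsv", "Class feature comparisons (Wilcoxon)", 40)
    table("peak_correlations.tsv", "Peak count correlations (Pearson)")
    table("disease_fractions.tsv", "Disease gene fractions by SG class")
    table("cross_tabulation.tsv", "DE x SG x eCLIP cross-tabulation", 16)
    if "module_association.tsv" in manifest["outputs"]:
        df = pd.read_csv(outdir / "module_association.tsv", sep="\t")
        sig = df[df["q"] < 0.05]
        lines.append("## Module eigenprotein associations")
        lines.append("")
        lines.append(f"Evaluated sets: {int(df['p'].notna().sum())}")
        lines.append(f"Significant at q < 0.05: {len(sig)}")
        lines.append("")
        if not sig.empty:
            lines.append(sig.to_string(index=False))
            lines.append("")
    report = "\n".join(lines)
    with open(outdir / "report.md", "w") as fh:
        fh.write(report)
    return report
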