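"""Disease-gene cross-classification and protein co-expression module stage.

Two analyses connect the stress-granule (SG) transcript classes to
Alzheimer's disease (AD):

1. :func:`crosstab_disease` cross-classifies genes by SG class and a
   disease gene list and compares transcript length / GC / abundance
   between disease and non-disease genes within each class.

2. :func:`run_module_association` maps proteins of a co-expression
   network (44 AD-correlated modules, M1-M44 style) onto SG classes via
   their coding genes, summarises each (module, class) protein set with
   an eigenprotein (first principal component of the standardized
   abundance sub-matrix, WGCNA-style), and tests eigenprotein differences
   across diagnosis groups (Control / AsymAD / AD; one-way ANOVA + Tukey
   HSD, BH FDR over all evaluated sets) and Pearson correlation with the
   Braak and CERAD neuropathological scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import anova_tukey, bh_fdr, pearson, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DIAGNOSIS_ORDER = ("Control", "AsymAD", "AD")
TESTED_CLASSES = ("enriched", "depleted", "neither")

MODULE_RESULT_COLUMNS = [
    "module", "sg_class", "n", "F", "p", "q",
    "tukey_Control_AsymAD", "tukey_Control_AD", "tukey_AsymAD_AD",
    "braak_r", "braak_p", "cerad_r", "cerad_p",
]


@dataclass
class ProteomicsBundle:
    """Protein abundance matrix plus the metadata the module stage needs."""

    abundance: pd.DataFrame        # proteins x samples, log-scale
    sample_meta: pd.DataFrame      # index: sample; diagnosis, braak, cerad
    module_map: pd.Series          # protein -> module label
    protein_gene_map: pd.Series    # protein -> gene_id

    def validate(self) -> None:
        if not set(self.abundance.index) <= set(self.module_map.index):
            raise ValueError("every abundance row needs a module assignment")
        if not set(self.abundance.columns) <= set(self.sample_meta.index):
            raise ValueError("sample metadata must cover every abundance column")
        if self.sample_meta["diagnosis"].nunique() < 2:
            raise ValueError("need at least two diagnosis levels")


def compute_eigenprotein(submatrix: pd.DataFrame) -> pd.Series:
    """First principal component of the row-standardized abundance sub-matrix.

    Rows (proteins) are standardized to zero mean, unit variance; constant
    rows are dropped with a warning.  The per-sample score is scaled to
    unit variance and oriented to correlate positively with the mean
    standardized profile, so higher scores mean higher module abundance.
    """
    X = submatrix.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 3:
        raise ValueError("need >=1 protein and >=3 samples")
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant protein rows", int((~keep).sum()))
    if not keep.any():
        raise ValueError("all protein rows are constant")
    X = X[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    score = score / score.std()
    mean_profile = Z.mean(axis=0)
    if np.dot(score, mean_profile - mean_profile.mean()) < 0:
        score = -score
    return pd.Series(score, index=submatrix.columns, name="eigenprotein")


def _first_mapping(mapping: pd.Series) -> pd.Series:
    if mapping.index.has_duplicates:
        n = int(mapping.index.duplicated().sum())
        logger.warning("%d proteins map to multiple genes; using the first mapping", n)
        mapping = mapping[~mapping.index.duplicated(keep="first")]
    return mapping


def run_module_association(
    bundle: ProteomicsBundle,
    classes: pd.DataFrame,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Module x SG-class eigenprotein association with diagnosis and pathology.

    ``classes`` is the SG classification table (gene_id, sg_class); genes
    in the 'low' class are excluded.  Every (module, class) combination is
    reported; sets below ``min_set_size`` carry NaN statistics and are
    outside the BH family.
    """
    bundle.validate()
    gene_class = (
        classes[classes["sg_class"].isin(TESTED_CLASSES)]
        .set_index("gene_id")["sg_class"]
    )
    protein_gene = _first_mapping(bundle.protein_gene_map)
    protein_class = protein_gene.map(gene_class)
    module_map = bundle.module_map
    meta = bundle.sample_meta.loc[bundle.abundance.columns]
    diagnosis = meta["diagnosis"].to_numpy()
    levels = [lv for lv in DIAGNOSIS_ORDER if lv in set(diagnosis)]

    modules = sorted(module_map.unique(), key=_module_sort_key)
    rows = []
    eigen_rows = {}
    for module in modules:
        module_proteins = module_map.index[module_map == module]
        for sg_class in TESTED_CLASSES:
            proteins = [
                p for p in module_proteins
                if p in bundle.abundance.index and protein_class.get(p) == sg_class
            ]
            row = {"module": module, "sg_class": sg_class, "n": len(proteins)}
            if len(proteins) < min_set_size:
                rows.append(row)
                continue
            eigen = compute_eigenprotein(bundle.abundance.loc[proteins])
            eigen_rows[(module, sg_class)] = eigen
            try:
                anova, tukey = anova_tukey(eigen.to_numpy(), diagnosis)
            except ValueError as exc:
                logger.warning("set (%s, %s) not testable: %s", module, sg_class, exc)
                rows.append(row)
                continue
            row["F"] = anova.statistic
            row["p"] = anova.p_value
            for a, b in ((("Control", "AsymAD")), ("Control", "AD"), ("AsymAD", "AD")):
                key = f"tukey_{a}_{b}"
                row[key] = tukey.get((a, b), tukey.get((b, a), np.nan))
            for score_col in ("braak", "cerad"):
                score = meta[score_col].to_numpy(dtype=float)
                ok = ~np.isnan(score)
                res = pearson(eigen.to_numpy()[ok], score[ok])
                row[f"{score_col}_r"] = res.statistic
                row[f"{score_col}_p"] = res.p_value
            rows.append(row)
    out = pd.DataFrame(rows).reindex(columns=MODULE_RESULT_COLUMNS)
    tested = out["p"].notna()
    out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out.attrs["n_evaluated"] = int(tested.sum())
    out.attrs["eigenproteins"] = eigen_rows
    return out


def _module_sort_key(label: str):
    # M1 < M2 < ... < M44 when labels follow the M<number> style
    if isinstance(label, str) and label.startswith("M") and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, str(label))


def crosstab_disease(
    classes: pd.DataFrame,
    disease_genes: set,
    features: pd.DataFrame,
    min_stratum: int = 2,
) -> dict[str, pd.DataFrame]:
    """SG class x disease cross-classification and within-class comparisons.

    Returns a fraction table (per class: counts and fractions of disease
    and non-disease genes) and Wilcoxon comparisons of transcript length,
    GC and total abundance between disease and non-disease genes within
    each class.  Strata with fewer than ``min_stratum`` genes on either
    side are skipped with a logged note.
    """
    df = classes.merge(features, on="gene_id", how="left")
    df = df[df["sg_class"].isin(TESTED_CLASSES)]
    df["disease"] = df["gene_id"].isin(disease_genes)
    if not df["disease"].any():
        logger.warning("disease gene list is disjoint from the classified universe")
    n_dis = max(int(df["disease"].sum()), 1)
    n_non = max(int((~df["disease"]).sum()), 1)
    frac_rows = []
    for sg_class, grp in df.groupby("sg_class"):
        n_ad = int(grp["disease"].sum())
        n_other = len(grp) - n_ad
        frac_rows.append(
            {
                "sg_class": sg_class,
                "n_disease": n_ad,
                "n_other": n_other,
                "frac_of_disease_genes": n_ad / n_dis,
                "frac_of_other_genes": n_other / n_non,
            }
        )
    metrics = {
        "length_total": "length_total",
        "gc_fraction": "gc_fraction",
        "abundance": "tpm_total",
    }
    cmp_rows = []
    for sg_class, grp in df.groupby("sg_class"):
        for metric, col in metrics.items():
            a = grp.loc[grp["disease"], col].dropna().to_numpy()
            b = grp.loc[~grp["disease"], col].dropna().to_numpy()
            if len(a) < min_stratum or len(b) < min_stratum:
                logger.info(
                    "skipping %s/%s comparison: stratum too small (%d vs %d)",
                    sg_class, metric, len(a), len(b),
                )
                continue
            res = wilcoxon_rank_sum(a, b, mode="normal")
            cmp_rows.append(
                {
                    "sg_class": sg_class,
                    "metric": metric,
                    "n_disease": len(a),
                    "n_other": len(b),
                    "median_disease": float(np.median(a)),
                    "median_other": float(np.median(b)),
                    "U": res.statistic,
                    "p": res.p_value,
                }
            )
    return {
        "fractions": pd.DataFrame(frac_rows),
        "comparisons": pd.DataFrame(
            cmp_rows,
            columns=["sg_class", "metric", "n_disease", "n_other",
                     "median_disease", "median_other", "U", "p"],
        ),
    }


# --- plain-text IO ------------------------------------------------------------

def read_proteomics(
    abundance_path: str | Path,
    meta_path: str | Path,
    module_map_path: str | Path,
    gene_map_path: str | Path,
) -> ProteomicsBundle:
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    module_map = pd.read_csv(module_map_path, sep="\t", index_col=0).iloc[:, 0]
    gene_map = pd.read_csv(gene_map_path, sep="\t", index_col=0).iloc[:, 0]
    return ProteomicsBundle(abundance, meta, module_map, gene_map)


def read_disease_table(path: str | Path, disease: str | None = None) -> set:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("disease table needs a gene_id column")
    if disease is not None and "disease" in df.columns:
        df = df[df["disease"] == disease]
    return set(df["gene_id"])
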