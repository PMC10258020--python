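"""TPM normalization and stress-granule enrichment / differential classes.

Genes are partitioned by comparing length-normalized abundance (TPM)
between the purified stress-granule (SG) fraction and the total lysate:

* ``enriched``  — fold change > 2 and SG TPM > 1
* ``depleted``  — fold change < 0.5 and Total TPM > 1
* ``low``       — both TPMs at or below 1 (excluded from most analyses)
* ``neither``   — everything else

Fold change uses a small pseudocount (default 0.01 TPM) so that zero
abundances are well-defined; with pseudocount 0 the thresholds reproduce
the strict published rules exactly.  The same symmetric machinery
classifies differential response to knockdown or arsenite stress.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SG_CLASSES = ("enriched", "depleted", "neither", "low")
DE_CLASSES = ("up", "down", "unchanged", "low")


@dataclass(frozen=True)
class SGThresholds:
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    tpm_min: float = 1.0
    pseudocount: float = 0.01


def compute_tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million from counts and effective lengths (nt).

    rate_i = count_i / (length_i / 1000); tpm_i = 1e6 * rate_i / sum(rate).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    if np.any(lengths <= 0):
        raise ValueError("all effective lengths must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / (lengths / 1000.0)
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    return rate / total * 1e6


def classify_sg(
    tpm_sg: pd.Series,
    tpm_total: pd.Series,
    thresholds: SGThresholds = SGThresholds(),
) -> pd.DataFrame:
    """Classify genes into SG enrichment classes from paired TPM vectors.

    The two series must share an index of gene identifiers.  Rules are
    applied in order enriched, depleted, low; anything left is neither.
    """
    tpm_sg, tpm_total = tpm_sg.align(tpm_total, join="inner")
    sg = tpm_sg.to_numpy(dtype=float)
    total = tpm_total.to_numpy(dtype=float)
    if np.any(sg < 0) or np.any(total < 0):
        raise ValueError("TPM values must be non-negative")
    eps = thresholds.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (sg + eps) / (total + eps)
    enriched = (fc > thresholds.fc_hi) & (sg > thresholds.tpm_min)
    depleted = ~enriched & (fc < thresholds.fc_lo) & (total > thresholds.tpm_min)
    low = (
        ~enriched
        & ~depleted
        & (sg <= thresholds.tpm_min)
        & (total <= thresholds.tpm_min)
    )
    sg_class = np.select([enriched, depleted, low], ["enriched", "depleted", "low"], "neither")
    return pd.DataFrame(
        {
            "gene_id": tpm_sg.index,
            "tpm_sg": sg,
            "tpm_total": total,
            "fold_change": fc,
            "sg_class": sg_class,
        }
    ).reset_index(drop=True)


def classify_de(
    tpm_ctrl: pd.Series,
    tpm_treat: pd.Series,
    contrast: str = "",
    fc: float = 2.0,
    tpm_min: float = 1.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Threshold differential classification (up/down/unchanged/low)."""
    tpm_ctrl, tpm_treat = tpm_ctrl.align(tpm_treat, join="inner")
    ctrl = tpm_ctrl.to_numpy(dtype=float)
    treat = tpm_treat.to_numpy(dtype=float)
    if np.any(ctrl < 0) or np.any(treat < 0):
        raise ValueError("TPM values must be non-negative")
    ratio = (treat + pseudocount) / (ctrl + pseudocount)
    up = (ratio > fc) & (treat > tpm_min)
    down = ~up & (ratio < 1.0 / fc) & (ctrl > tpm_min)
    low = ~up & ~down & (ctrl <= tpm_min) & (treat <= tpm_min)
    de_class = np.select([up, down, low], ["up", "down", "low"], "unchanged")
    return pd.DataFrame(
        {
            "gene_id": tpm_ctrl.index,
            "contrast": contrast,
            "tpm_ctrl": ctrl,
            "tpm_treat": treat,
            "fold_change": ratio,
            "de_class": de_class,
        }
    ).reset_index(drop=True)


def composition(labels: pd.Series) -> pd.DataFrame:
    """Per-label counts and fractions (fractions sum to 1)."""
    if len(labels) == 0:
        raise ValueError("no records to summarise")
    counts = labels.groupby(labels).size()
    return (
        pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
        .rename_axis("label")
        .reset_index()
    )


def cross_tabulate(sets: Mapping[str, set], universe: set) -> pd.DataFrame:
    """Exclusive-subset (UpSet-style) counts over a shared gene universe.

    Returns one row per membership signature (boolean column per set name,
    including the all-False row); counts sum to the universe size.
    """
    names = sorted(sets)
    for name in names:
        extra = set(sets[name]) - universe
        if extra:
            raise ValueError(f"set {name!r} has genes outside the universe: {sorted(extra)[:5]}")
    signature_counts: dict[tuple[bool, ...], int] = {}
    for gene in universe:
        sig = tuple(gene in sets[name] for name in names)
        signature_counts[sig] = signature_counts.get(sig, 0) + 1
    rows = []
    for sig in itertools.product([False, True], repeat=len(names)):
        row = {name: flag for name, flag in zip(names, sig)}
        row["count"] = signature_counts.get(sig, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Long-format expression TSV: gene_id, sample, count|tpm [, effective_length]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample"}
    if not required <= set(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    if "count" not in df.columns and "tpm" not in df.columns:
        raise ValueError("expression table needs a 'count' or 'tpm' column")
    dup = df.duplicated(subset=["gene_id", "sample"])
    if dup.any():
        raise ValueError("duplicate (gene_id, sample) rows in expression table")
    return df


def tpm_from_expression(df: pd.DataFrame, sample: str) -> pd.Series:
    """TPM vector for one sample; computed from counts when needed."""
    sub = df[df["sample"] == sample].set_index("gene_id")
    if sub.empty:
        raise ValueError(f"sample {sample!r} absent from expression table")
    if "tpm" in sub.columns and sub["tpm"].notna().all():
        return sub["tpm"].astype(float)
    return pd.Series(
        compute_tpm(sub["count"], sub["effective_length"]), index=sub.index, name="tpm"
    )
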