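"""eCLIP peak ingestion, replicate intersection, and transcript-region assignment.

Peaks live in DataFrames with the columns ``chrom start end strand score
protein condition replicate`` (genomic coordinates 0-based half-open, score
a log2 enrichment over the size-matched input).  Replicate tracks are
reduced to "common peaks" by strand-aware interval intersection; common
peaks are then assigned to the exonic region of a gene's canonical
transcript with the largest overlap (ties resolved 3'UTR > 5'UTR > CDS >
non-coding exon, mirroring the 3'UTR-first binding preference of the G3BP
proteins).  Per-gene peak counts and mean peak scores summarise binding.

The module also provides IUPAC RNA reverse complementation, used to verify
that the G3BP consensus motif CCAGSCUGG is a sequence palindrome.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import PROTEIN_CODING, TranscriptModel, canonical_by_gene

PEAK_COLUMNS = ["chrom", "start", "end", "strand", "score", "protein", "condition", "replicate"]
ASSIGNMENT_COLUMNS = PEAK_COLUMNS + ["gene_id", "region", "overlap_nt"]

#: Region tie-break order (most to least preferred) for equal overlaps.
REGION_PRECEDENCE = ("3UTR", "5UTR", "CDS", "noncoding_exon")
UNASSIGNED = "unassigned"


def read_peaks(
    path: str | Path,
    protein: str = "",
    condition: str = "",
    replicate: int = 0,
) -> pd.DataFrame:
    """Read a BED6 or narrowPeak file into the peak frame layout.

    narrowPeak (10 columns) uses the signalValue column as the score;
    BED6 uses the score column.  A '.' strand is rejected because every
    downstream overlap is strand-aware.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected >=6 columns, got {df.shape[1]}")
    score = df[6] if df.shape[1] >= 10 else df[4]
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5].astype(str),
            "score": score.astype(float),
        }
    )
    bad_strand = ~out["strand"].isin(["+", "-"])
    if bad_strand.any():
        row = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: row {row} has strand {out['strand'].iloc[row - 1]!r}; "
            "stranded peaks are required"
        )
    bad_iv = out["end"] <= out["start"]
    if bad_iv.any():
        row = int(np.flatnonzero(bad_iv.to_numpy())[0]) + 1
        raise ValueError(f"{path}: row {row} has end <= start")
    out["protein"] = protein
    out["condition"] = condition
    out["replicate"] = replicate
    return out[PEAK_COLUMNS]


def _trees_by_group(df: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for key, grp in df.groupby(["chrom", "strand"], sort=False):
        trees[key] = IntervalTree.from_tuples(
            (s, e, i) for i, (s, e) in enumerate(zip(grp["start"], grp["end"]))
        )
    return trees


def intersect_replicates(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> pd.DataFrame:
    """Common peaks: pairwise strand-aware interval intersections.

    Every same-chrom same-strand pair with >=1 nt overlap contributes the
    intersected interval with the mean of the two scores.  The result is
    sorted and de-duplicated, labelled with replicate 0.
    """
    for col in ("protein", "condition"):
        labels = set(rep_a[col]) | set(rep_b[col])
        if len(labels) > 1:
            raise ValueError(f"replicates disagree on {col}: {sorted(labels)}")
    rows = []
    b_groups = {k: g.reset_index(drop=True) for k, g in rep_b.groupby(["chrom", "strand"], sort=False)}
    b_trees = {k: _trees_by_group(g)[k] for k, g in b_groups.items()}
    for rec in rep_a.itertuples(index=False):
        key = (rec.chrom, rec.strand)
        tree = b_trees.get(key)
        if tree is None:
            continue
        grp = b_groups[key]
        for hit in tree.overlap(rec.start, rec.end):
            other = grp.iloc[hit.data]
            rows.append(
                (
                    rec.chrom,
                    max(rec.start, hit.begin),
                    min(rec.end, hit.end),
                    rec.strand,
                    (rec.score + other["score"]) / 2.0,
                    rec.protein,
                    rec.condition,
                    0,
                )
            )
    out = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    out = out.drop_duplicates(subset=["chrom", "start", "end", "strand"])
    return out.sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)


def peak_set_overlap(sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """UpSet-style membership counts across named peak sets.

    Peaks from different sets that overlap (same chrom/strand, >=1 nt) are
    merged into connected components; each component is counted once under
    the union of the set names it contains, so identical single-peak sets
    A and B yield {A,B}: 1.
    """
    if len(sets) < 2:
        raise ValueError("need at least two named peak sets")
    nodes: list[tuple[str, str, int, int, str]] = []  # name, chrom, start, end, strand
    for name, df in sets.items():
        for rec in df.itertuples(index=False):
            nodes.append((name, rec.chrom, int(rec.start), int(rec.end), rec.strand))
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for idx, (_, chrom, start, end, strand) in enumerate(nodes):
        trees[(chrom, strand)].addi(start, end, idx)
    for idx, (name, chrom, start, end, strand) in enumerate(nodes):
        for hit in trees[(chrom, strand)].overlap(start, end):
            if nodes[hit.data][0] != name:
                union(idx, hit.data)
    members: dict[int, set[str]] = defaultdict(set)
    for idx, (name, *_rest) in enumerate(nodes):
        members[find(idx)].add(name)
    counts = Counter(frozenset(m) for m in members.values())
    all_names = sorted(sets)
    rows = []
    for combo_size in range(1, len(all_names) + 1):
        for combo in itertools.combinations(all_names, combo_size):
            rows.append(
                {"members": "&".join(combo), "count": counts.get(frozenset(combo), 0)}
            )
    return pd.DataFrame(rows)


def _region_index(
    models: Iterable[TranscriptModel],
) -> dict[tuple[str, str], IntervalTree]:
    """Interval index of canonical-transcript exonic sub-regions."""
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for gene_id, model in canonical_by_gene(models).items():
        if model.biotype == PROTEIN_CODING and model.cds:
            regions = {"5UTR": model.utr5, "CDS": model.cds, "3UTR": model.utr3}
        else:
            regions = {"noncoding_exon": model.exons}
        for region, ivs in regions.items():
            for s, e in ivs:
                if e > s:
                    trees[(model.chrom, model.strand)].addi(s, e, (gene_id, region))
    return trees


def assign_peaks(
    peaks: pd.DataFrame, models: Iterable[TranscriptModel]
) -> pd.DataFrame:
    """Assign each peak to (gene, region) by maximal same-strand exonic overlap.

    The gene is the canonical transcript's gene with the largest total
    overlap (ties: lexicographically first gene_id); within the gene, the
    region with the largest overlap wins, ties resolved by
    ``REGION_PRECEDENCE``.  Peaks touching no exon are kept as unassigned.
    """
    trees = _region_index(models)
    precedence = {r: i for i, r in enumerate(REGION_PRECEDENCE)}
    genes, regions, overlaps = [], [], []
    for rec in peaks.itertuples(index=False):
        tree = trees.get((rec.chrom, rec.strand))
        per_gene: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        if tree is not None:
            for hit in tree.overlap(rec.start, rec.end):
                gene_id, region = hit.data
                per_gene[gene_id][region] += min(rec.end, hit.end) - max(rec.start, hit.begin)
        if not per_gene:
            genes.append(pd.NA)
            regions.append(UNASSIGNED)
            overlaps.append(0)
            continue
        gene = min(per_gene, key=lambda g: (-sum(per_gene[g].values()), g))
        region = min(per_gene[gene], key=lambda r: (-per_gene[gene][r], precedence[r]))
        genes.append(gene)
        regions.append(region)
        overlaps.append(per_gene[gene][region])
    out = peaks.copy()
    out["gene_id"] = genes
    out["region"] = regions
    out["overlap_nt"] = overlaps
    return out


def region_distribution(
    assignments: pd.DataFrame, biotypes: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Fractions of assigned peaks per region (optionally per gene biotype)."""
    assigned = assignments[assignments["region"] != UNASSIGNED]
    if assigned.empty:
        raise ValueError("no assigned peaks")
    counts = assigned.groupby("region", sort=True).size()
    out = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()}).reset_index()
    if biotypes is not None:
        bt = assigned["gene_id"].map(biotypes)
        bt_counts = bt.groupby(bt).size()
        bt_frame = pd.DataFrame(
            {"region": "any", "count": bt_counts, "fraction": bt_counts / bt_counts.sum()}
        ).reset_index(names="biotype")
        out.insert(0, "biotype", "any")
        out = pd.concat([out, bt_frame[["biotype", "region", "count", "fraction"]]])
    return out.reset_index(drop=True)


def gene_binding_profiles(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, protein, condition): peak count and mean peak score."""
    assigned = assignments[assignments["region"] != UNASSIGNED]
    keys = [k for k in ("gene_id", "protein", "condition") if k in assigned.columns]
    grouped = assigned.groupby(keys, sort=True)["score"]
    out = grouped.agg(peak_count="count", binding_level="mean").reset_index()
    out["peak_count"] = out["peak_count"].astype(int)
    return out


# --- IUPAC RNA motif utilities ------------------------------------------------

_RNA_COMPLEMENT = {
    "A": "U", "U": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def iupac_reverse_complement(motif: str) -> str:
    """Reverse complement of an IUPAC RNA string (S<->S, W<->W, R<->Y, ...)."""
    motif = motif.upper()
    try:
        return "".join(_RNA_COMPLEMENT[b] for b in reversed(motif))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC RNA character {exc.args[0]!r} in motif") from exc


def is_palindrome(motif: str) -> bool:
    """True iff the motif equals its own IUPAC reverse complement."""
    return motif.upper() == iupac_reverse_complement(motif)
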