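"""Gene annotation parsing and per-gene physical transcript features.

Transcripts are represented as sets of genomic intervals (0-based,
half-open) for exons, CDS, and the two untranslated regions.  UTRs are
inferred by interval arithmetic (exon minus CDS span, oriented by strand)
so that for every protein-coding transcript the 5'UTR, CDS and 3'UTR
exonic widths sum exactly to the spliced transcript length.

The per-gene feature table (one row per gene via a longest-isoform
canonical rule) carries the physical covariates used throughout the
analysis: region lengths, GC fraction of the spliced transcript, and a
collapsed biotype (protein_coding / lncRNA / other).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction as _bp_gc_fraction

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
OTHER = "other"

#: Collapsing map from annotation biotypes to the three analysis categories.
#: The lncRNA umbrella follows the GENCODE long non-coding grouping.  The
#: map is an ordinary dict and may be edited or passed per-call.
BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": PROTEIN_CODING,
    "lncRNA": LNCRNA,
    "lincRNA": LNCRNA,
    "antisense": LNCRNA,
    "sense_intronic": LNCRNA,
    "sense_overlapping": LNCRNA,
    "bidirectional_promoter_lncRNA": LNCRNA,
    "macro_lncRNA": LNCRNA,
    "3prime_overlapping_ncRNA": LNCRNA,
}

FEATURE_COLUMNS = [
    "gene_id",
    "biotype",
    "length_total",
    "length_5utr",
    "length_cds",
    "length_3utr",
    "gc_fraction",
]

Interval = tuple[int, int]


class GTFParseError(ValueError):
    """Raised for a structurally malformed GTF line (names the line number)."""


@dataclass
class TranscriptModel:
    """One transcript: genomic intervals are 0-based half-open."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class TranscriptFeature:
    """Per-gene physical features derived from the canonical transcript."""

    gene_id: str
    biotype: str
    length_total: int
    length_5utr: int
    length_cds: int
    length_3utr: int
    gc_fraction: float


def collapse_biotype(raw: str, mapping: Mapping[str, str] | None = None) -> str:
    mapping = BIOTYPE_MAP if mapping is None else mapping
    return mapping.get(raw, OTHER)


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _clip_before(ivs: Sequence[Interval], bound: int) -> list[Interval]:
    return [(s, min(e, bound)) for s, e in ivs if s < bound]


def _clip_after(ivs: Sequence[Interval], bound: int) -> list[Interval]:
    return [(max(s, bound), e) for s, e in ivs if e > bound]


def _infer_utrs(
    exons: Sequence[Interval], cds: Sequence[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Exonic parts outside the CDS span, oriented by strand (utr5, utr3)."""
    if not cds:
        return [], []
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left = _clip_before(exons, cds_start)
    right = _clip_after(exons, cds_end)
    return (left, right) if strand == "+" else (right, left)


def _prescan_gtf(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"line {lineno}: invalid 1-based range {start}-{end}"
                )


def _first_attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def load_annotation(
    path: str | Path, biotype_map: Mapping[str, str] | None = None
) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into transcript models.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    UTRs are inferred from the exon/CDS set difference.  Records lacking
    gene_id or transcript_id are skipped with a logged warning and counted.
    """
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    n_skipped = 0
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gene_id = _first_attr(feat, "gene_id")
        tx_id = _first_attr(feat, "transcript_id")
        if gene_id is None or tx_id is None:
            n_skipped += 1
            logger.warning(
                "skipping %s record at %s:%d-%d: missing gene_id/transcript_id",
                feat.featuretype,
                feat.seqid,
                feat.start,
                feat.end,
            )
            continue
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tx_id, []).append(iv)
        else:
            cds.setdefault(tx_id, []).append(iv)
        if tx_id not in meta:
            raw_biotype = _first_attr(
                feat, "transcript_type", "transcript_biotype", "gene_type", "gene_biotype"
            )
            if raw_biotype is None:
                logger.warning("transcript %s: no biotype attribute, using 'other'", tx_id)
                raw_biotype = OTHER
            meta[tx_id] = (gene_id, feat.seqid, feat.strand, raw_biotype)
    if n_skipped:
        logger.warning("%d records skipped for missing mandatory attributes", n_skipped)

    models: list[TranscriptModel] = []
    for tx_id, (gene_id, chrom, strand, raw_biotype) in meta.items():
        tx_exons = _merge_intervals(exons.get(tx_id, []))
        if not tx_exons:
            n_skipped += 1
            continue
        tx_cds = _merge_intervals(cds.get(tx_id, []))
        utr5, utr3 = _infer_utrs(tx_exons, tx_cds, strand)
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx_id,
                chrom=chrom,
                strand=strand,
                biotype=collapse_biotype(raw_biotype, biotype_map),
                exons=tx_exons,
                cds=tx_cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def canonical_transcript(models: Sequence[TranscriptModel]) -> TranscriptModel:
    """Longest isoform (summed exon length); ties broken by transcript_id."""
    if not models:
        raise ValueError("no transcripts supplied")
    return min(models, key=lambda m: (-m.exonic_length(), m.transcript_id))


def _fetch(seqs, chrom: str, start: int, end: int) -> str:
    record = seqs[chrom]
    n = len(record)
    if start < 0 or end > n:
        raise ValueError(
            f"interval [{start},{end}) outside {chrom} (length {n})"
        )
    segment = record[start:end]
    # pyfaidx returns a Sequence object; plain strings slice directly
    return str(segment.seq) if hasattr(segment, "seq") else str(segment)


def spliced_sequence(model: TranscriptModel, seqs) -> str:
    """Spliced transcript sequence in 5'->3' orientation (strand-corrected)."""
    seq = "".join(_fetch(seqs, model.chrom, s, e) for s, e in sorted(model.exons))
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def compute_gc(seq: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both sides; NaN if empty."""
    unambiguous = sum(seq.count(b) for b in "ACGTU")
    if unambiguous == 0:
        logger.warning("sequence has no unambiguous bases; gc_fraction undefined")
        return math.nan
    return _bp_gc_fraction(seq, "remove")


def compute_features(model: TranscriptModel, seqs) -> TranscriptFeature:
    seq = spliced_sequence(model, seqs)
    return TranscriptFeature(
        gene_id=model.gene_id,
        biotype=model.biotype,
        length_total=model.exonic_length(),
        length_5utr=sum(e - s for s, e in model.utr5),
        length_cds=sum(e - s for s, e in model.cds),
        length_3utr=sum(e - s for s, e in model.utr3),
        gc_fraction=compute_gc(seq),
    )


def canonical_by_gene(models: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return {g: canonical_transcript(ms) for g, ms in by_gene.items()}


def features_table(models: Iterable[TranscriptModel], seqs) -> pd.DataFrame:
    """One feature row per gene from its canonical transcript."""
    rows = [
        compute_features(model, seqs).__dict__
        for _, model in sorted(canonical_by_gene(models).items())
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FEATURE_COLUMNS)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df[FEATURE_COLUMNS]
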