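"""Synthetic study generator with planted, recoverable structure.

Every input the pipeline consumes can be simulated here: a gene
annotation (GTF) with sequences (FASTA) on synthetic chromosomes,
duplicate eCLIP peak tracks for two RNA-binding proteins under two
conditions, paired SG/Total and control/knockdown/stress expression
tables, a disease gene list biased toward long transcripts, and a
proteomics bundle with module structure and planted diagnosis effects.

Planted effects mirror the biology under study:

* per-gene eCLIP peak counts follow a Poisson model whose log-rate
  increases with log transcript length and AT fraction;
* the log SG/Total abundance ratio increases with log length and AT
  fraction and decreases with log abundance, so SG-enriched transcripts
  are longer, AT-richer and less abundant;
* disease labels are sampled with weight increasing in the transcript
  length quantile;
* protein abundances follow a module latent factor plus per-(module,
  SG-class) diagnosis shifts, with Braak/CERAD scores generated as noisy
  monotone functions of diagnosis.

A single integer seed fully determines the output; independent stage
streams (annotation, sequences, peaks, expression, proteomics) are
spawned from it so that skipping the expensive sequence stage does not
perturb the rest.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import LNCRNA, PROTEIN_CODING, Interval, TranscriptModel
from .disease import ProteomicsBundle
from .partition import SGThresholds, classify_sg

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LengthModel:
    """Log-normal region length model (natural-log parameters, nt floor)."""

    meanlog: float
    sdlog: float
    minimum: int = 20


@dataclass(frozen=True)
class PlantedModuleEffect:
    """Per-diagnosis latent-mean shifts for one (module, SG class) cell."""

    module: str
    sg_class: str
    shifts: tuple[float, float, float]  # Control, AsymAD, AD


def _default_planted_effects() -> tuple[PlantedModuleEffect, ...]:
    down = (0.0, -0.5, -1.0)
    up = (0.0, 0.5, 1.0)
    return (
        PlantedModuleEffect("M1", "enriched", down),
        PlantedModuleEffect("M5", "enriched", down),
        PlantedModuleEffect("M8", "enriched", down),
        PlantedModuleEffect("M11", "enriched", up),
        PlantedModuleEffect("M20", "enriched", up),
        PlantedModuleEffect("M42", "enriched", up),
    )


@dataclass
class ProteomicsPlan:
    """Shape and planted effects of the simulated proteomics bundle.

    Group sizes default to the AD cohort of the source proteomic network
    study (106 control / 200 AsymAD / 182 AD) and 44 modules.
    """

    n_control: int = 106
    n_asymad: int = 200
    n_ad: int = 182
    n_modules: int = 44
    proteins_per_class: int = 5
    loading_low: float = 0.5
    loading_high: float = 1.0
    noise_sd: float = 1.0
    braak_base: float = 1.0
    braak_slope: float = 1.8
    braak_sd: float = 0.8
    braak_max: float = 6.0
    cerad_base: float = 0.5
    cerad_slope: float = 1.0
    cerad_sd: float = 0.5
    cerad_max: float = 3.0
    planted_effects: tuple[PlantedModuleEffect, ...] = field(
        default_factory=_default_planted_effects
    )

    @property
    def group_sizes(self) -> tuple[int, int, int]:
        return (self.n_control, self.n_asymad, self.n_ad)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    n_genes: int = 5000
    lncrna_fraction: float = 0.25
    # region length models (log-normal, nt)
    utr5_model: LengthModel = field(default_factory=lambda: LengthModel(math.log(150), 0.8, 20))
    cds_model: LengthModel = field(default_factory=lambda: LengthModel(math.log(1200), 0.7, 150))
    utr3_model: LengthModel = field(default_factory=lambda: LengthModel(math.log(900), 1.0, 30))
    lnc_model: LengthModel = field(default_factory=lambda: LengthModel(math.log(800), 1.0, 200))
    # per-gene GC fraction ~ Beta(a, b)
    gc_alpha: float = 9.0
    gc_beta: float = 11.0
    # genomic layout
    genes_per_chrom: int = 250
    gene_spacing: int = 1000
    max_exons: int = 4
    min_intron: int = 200
    max_intron: int = 2000
    background_gc: float = 0.40
    # eCLIP peak model: log-rate = intercept + b_length*ln(L) + b_at*(1-GC)
    peak_intercept: float = -6.8
    peak_b_length: float = 0.8
    peak_b_at: float = 2.0
    peak_width_min: int = 30
    peak_width_max: int = 80
    utr3_weight: float = 0.5
    score_mean: float = 3.0
    score_sd: float = 1.0
    replicate_retention: float = 0.8
    replicate_jitter: int = 10
    # SG partition model: ln(SG/Total) on centred covariates
    sg_b_length: float = 0.6
    sg_b_at: float = 2.0
    sg_b_abundance: float = 0.5
    sg_noise_sd: float = 0.8
    # total abundance ~ log-normal (then normalized to TPM scale)
    abundance_meanlog: float = math.log(5.0)
    abundance_sdlog: float = 1.5
    depth: int = 5_000_000
    # differential response (knockdown / stress)
    de_frac_up: float = 0.03
    de_frac_down: float = 0.045
    de_lfc: float = 1.2
    de_lfc_sd: float = 0.3
    # disease labels
    ad_fraction: float = 0.15
    ad_bias_power: float = 2.0
    proteomics: ProteomicsPlan = field(default_factory=ProteomicsPlan)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        kwargs = dict(raw)
        for key in ("utr5_model", "cds_model", "utr3_model", "lnc_model"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = LengthModel(**kwargs[key])
        if "proteomics" in kwargs and isinstance(kwargs["proteomics"], dict):
            plan = dict(kwargs["proteomics"])
            effects = plan.get("planted_effects", ())
            plan["planted_effects"] = tuple(
                PlantedModuleEffect(e["module"], e["sg_class"], tuple(e["shifts"]))
                if isinstance(e, dict) else e
                for e in effects
            )
            kwargs["proteomics"] = ProteomicsPlan(**plan)
        return cls(**kwargs)


@dataclass
class SyntheticStudy:
    """All generated inputs plus the planted ground truth."""

    config: SyntheticConfig
    models: list[TranscriptModel]
    features: pd.DataFrame
    chroms: dict[str, str] | None
    peaks: dict[tuple[str, str, int], pd.DataFrame]
    expression: pd.DataFrame
    truth: dict
    disease_genes: set
    proteomics: ProteomicsBundle


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("annotation", "sequences", "peaks", "expression", "disease", "proteomics")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_lengths(rng, model: LengthModel, n: int) -> np.ndarray:
    x = rng.lognormal(model.meanlog, model.sdlog, size=n)
    return np.maximum(np.rint(x).astype(int), model.minimum)


def _split_exons_by_bands(
    exons: list[Interval], band_lengths: list[int]
) -> list[list[Interval]]:
    """Partition genome-ordered exon intervals into consecutive spliced bands."""
    bands: list[list[Interval]] = [[] for _ in band_lengths]
    bounds = np.cumsum(band_lengths)
    offset = 0
    band = 0
    for s, e in exons:
        pos = s
        while pos < e:
            while band < len(bounds) and offset >= bounds[band]:
                band += 1
            take = min(e - pos, int(bounds[band]) - offset)
            if take > 0:
                bands[band].append((pos, pos + take))
            pos += take
            offset += take
    return [b for b in bands]


def generate_features(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the gene-level feature frame (lengths, GC, biotype) only.

    Fast vectorized path for simulation studies that need covariates and
    expression but no genomic layout.  Uses the same stage stream as
    :func:`generate_annotation`, which extends it with the layout.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["annotation"]
    n = config.n_genes
    is_lnc = rng.random(n) < config.lncrna_fraction
    u5 = _draw_lengths(rng, config.utr5_model, n)
    cds = _draw_lengths(rng, config.cds_model, n)
    cds = np.maximum((cds // 3) * 3, config.cds_model.minimum)
    u3 = _draw_lengths(rng, config.utr3_model, n)
    lnc_len = _draw_lengths(rng, config.lnc_model, n)
    gc = rng.beta(config.gc_alpha, config.gc_beta, size=n)
    total = np.where(is_lnc, lnc_len, u5 + cds + u3)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:05d}" for i in range(n)],
            "biotype": np.where(is_lnc, LNCRNA, PROTEIN_CODING),
            "length_total": total.astype(int),
            "length_5utr": np.where(is_lnc, 0, u5).astype(int),
            "length_cds": np.where(is_lnc, 0, cds).astype(int),
            "length_3utr": np.where(is_lnc, 0, u3).astype(int),
            "gc_fraction": gc,
        }
    )


def generate_annotation(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Transcript models on synthetic chromosomes plus the ground-truth features."""
    rng = rng if rng is not None else _stage_rngs(config.seed)["annotation"]
    features = generate_features(config, rng)
    n = config.n_genes
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    is_lnc = (features["biotype"] == LNCRNA).to_numpy()
    u5 = features["length_5utr"].to_numpy()
    cds = features["length_cds"].to_numpy()
    u3 = features["length_3utr"].to_numpy()
    total = features["length_total"].to_numpy()

    models: list[TranscriptModel] = []
    cursor = 0
    current_chrom = ""
    for i in range(n):
        chrom = f"chrS{i // config.genes_per_chrom + 1}"
        if chrom != current_chrom:
            current_chrom = chrom
            cursor = 0
        gene_id = f"G{i + 1:05d}"
        tx_id = f"{gene_id}.t1"
        L = int(total[i])
        n_exons = int(rng.integers(1, config.max_exons + 1))
        n_exons = min(n_exons, L)  # cannot cut shorter than 1 nt exons
        if n_exons > 1:
            cuts = np.sort(rng.choice(L - 1, size=n_exons - 1, replace=False) + 1)
            exon_lens = np.diff(np.concatenate([[0], cuts, [L]]))
        else:
            exon_lens = np.array([L])
        introns = rng.integers(config.min_intron, config.max_intron + 1, size=n_exons - 1)
        start = cursor + config.gene_spacing
        exons: list[Interval] = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_exons - 1:
                pos += int(introns[j])
        cursor = pos
        strand = str(strands[i])
        if is_lnc[i]:
            model = TranscriptModel(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom, strand=strand,
                biotype=LNCRNA, exons=exons,
            )
        else:
            # genome-order band lengths: 5'UTR/CDS/3'UTR on +, reversed on -
            if strand == "+":
                band_lens = [int(u5[i]), int(cds[i]), int(u3[i])]
            else:
                band_lens = [int(u3[i]), int(cds[i]), int(u5[i])]
            bands = _split_exons_by_bands(exons, band_lens)
            utr5_ivs, cds_ivs, utr3_ivs = (
                (bands[0], bands[1], bands[2]) if strand == "+" else (bands[2], bands[1], bands[0])
            )
            model = TranscriptModel(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom, strand=strand,
                biotype=PROTEIN_CODING, exons=exons, cds=cds_ivs,
                utr5=utr5_ivs, utr3=utr3_ivs,
            )
        models.append(model)
    return models, features


def generate_sequences(
    models: list[TranscriptModel],
    features: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Chromosome sequences whose exonic bases match each gene's drawn GC."""
    rng = rng if rng is not None else _stage_rngs(config.seed)["sequences"]
    chrom_len: dict[str, int] = {}
    for m in models:
        end = max(e for _, e in m.exons) + config.gene_spacing
        chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), end)
    gc_bg = config.background_gc
    p_bg = np.array([(1 - gc_bg) / 2, gc_bg / 2, gc_bg / 2, (1 - gc_bg) / 2])
    arrays = {
        c: BASES[rng.choice(4, size=ln, p=p_bg)].copy() for c, ln in sorted(chrom_len.items())
    }
    gc_by_gene = features.set_index("gene_id")["gc_fraction"]
    for m in models:
        gc = float(gc_by_gene[m.gene_id])
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for s, e in m.exons:
            arrays[m.chrom][s:e] = BASES[rng.choice(4, size=e - s, p=p)]
    return {c: a.tobytes().decode("ascii") for c, a in arrays.items()}


def _peak_rate(features: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    return np.exp(
        config.peak_intercept
        + config.peak_b_length * np.log(features["length_total"].to_numpy())
        + config.peak_b_at * (1.0 - features["gc_fraction"].to_numpy())
    )


def generate_peaks(
    models: list[TranscriptModel],
    features: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    proteins: tuple[str, ...] = ("G3BP1", "G3BP2"),
    conditions: tuple[str, ...] = ("Ctrl", "AS"),
) -> dict[tuple[str, str, int], pd.DataFrame]:
    """Duplicate peak tracks per protein x condition.

    Per-gene counts are Poisson with log-rate increasing in log length
    and AT fraction; positions are uniform over exon pieces with extra
    mass (``utr3_weight``) on the 3'UTR; replicate 2 is a jittered
    resample of replicate 1 keeping ~``replicate_retention`` of peaks.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["peaks"]
    rate = _peak_rate(features, config)
    model_by_gene = {m.gene_id: m for m in models}
    gene_ids = features["gene_id"].tolist()
    tracks: dict[tuple[str, str, int], pd.DataFrame] = {}
    for protein in proteins:
        for condition in conditions:
            counts = rng.poisson(rate)
            rows = []
            for gid, k in zip(gene_ids, counts):
                if k == 0:
                    continue
                m = model_by_gene[gid]
                exon_pieces = [iv for iv in m.exons]
                utr3_pieces = [iv for iv in m.utr3 if iv[1] > iv[0]]
                for _ in range(int(k)):
                    if utr3_pieces and rng.random() < config.utr3_weight:
                        pieces = utr3_pieces
                    else:
                        pieces = exon_pieces
                    lens = np.array([e - s for s, e in pieces], dtype=float)
                    piece = pieces[int(rng.choice(len(pieces), p=lens / lens.sum()))]
                    width = int(
                        min(
                            piece[1] - piece[0],
                            rng.integers(config.peak_width_min, config.peak_width_max + 1),
                        )
                    )
                    start = int(rng.integers(piece[0], piece[1] - width + 1))
                    score = float(max(0.5, rng.normal(config.score_mean, config.score_sd)))
                    rows.append((m.chrom, start, start + width, m.strand, score))
            rep1 = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])
            rep1["protein"] = protein
            rep1["condition"] = condition
            rep1["replicate"] = 1
            keep = rng.random(len(rep1)) < config.replicate_retention
            rep2 = rep1[keep].copy()
            j = config.replicate_jitter
            d1 = rng.integers(-j, j + 1, size=len(rep2))
            d2 = rng.integers(-j, j + 1, size=len(rep2))
            new_s = np.maximum(rep2["start"].to_numpy() + d1, 0)
            new_e = rep2["end"].to_numpy() + d2
            ok = new_e - new_s >= 5
            rep2.loc[:, "start"] = np.where(ok, new_s, rep2["start"])
            rep2.loc[:, "end"] = np.where(ok, new_e, rep2["end"])
            rep2["replicate"] = 2
            rep1 = rep1.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
            rep2 = rep2.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
            tracks[(protein, condition, 1)] = rep1
            tracks[(protein, condition, 2)] = rep2
    return tracks


def generate_expression(
    features: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    with_counts: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Long-format count table for SG/Total and Ctrl/knockdown/AS samples.

    Returns the table plus the planted truth (true TPM vectors and the
    planted log SG/Total ratio and per-contrast log fold changes).
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["expression"]
    n = len(features)
    length = features["length_total"].to_numpy(dtype=float)
    gc = features["gc_fraction"].to_numpy(dtype=float)
    raw = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, size=n)
    total_tpm = raw / raw.sum() * 1e6
    log_len = np.log(length)
    at = 1.0 - gc
    log_ab = np.log(total_tpm)
    lr = (
        config.sg_b_length * (log_len - log_len.mean())
        + config.sg_b_at * (at - at.mean())
        - config.sg_b_abundance * (log_ab - log_ab.mean())
        + rng.normal(0.0, config.sg_noise_sd, size=n)
    )
    sg_raw = total_tpm * np.exp(lr)
    sg_tpm = sg_raw / sg_raw.sum() * 1e6

    contrasts = ("siG3BP1", "siG3BP2", "AS")
    lfc: dict[str, np.ndarray] = {}
    treat_tpm: dict[str, np.ndarray] = {}
    for contrast in contrasts:
        v = np.zeros(n)
        n_up = int(round(config.de_frac_up * n))
        n_down = int(round(config.de_frac_down * n))
        chosen = rng.choice(n, size=n_up + n_down, replace=False)
        v[chosen[:n_up]] = config.de_lfc + rng.normal(0, config.de_lfc_sd, n_up)
        v[chosen[n_up:]] = -config.de_lfc + rng.normal(0, config.de_lfc_sd, n_down)
        lfc[contrast] = v
        t = total_tpm * np.exp(v)
        treat_tpm[contrast] = t / t.sum() * 1e6

    sample_tpms = {"Total": total_tpm, "SG": sg_tpm, "Ctrl": total_tpm}
    sample_tpms.update(treat_tpm)
    frames = []
    for sample, tpm in sample_tpms.items() if with_counts else ():
        weights = tpm * length / 1000.0
        mean = config.depth * weights / weights.sum()
        counts = rng.poisson(mean)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": features["gene_id"],
                    "sample": sample,
                    "count": counts,
                    "effective_length": length.astype(int),
                }
            )
        )
    if frames:
        expression = pd.concat(frames, ignore_index=True)
    else:
        expression = pd.DataFrame(columns=["gene_id", "sample", "count", "effective_length"])
    truth = {
        "total_tpm": pd.Series(total_tpm, index=features["gene_id"]),
        "sg_tpm": pd.Series(sg_tpm, index=features["gene_id"]),
        "log_ratio": pd.Series(lr, index=features["gene_id"]),
        "lfc": {c: pd.Series(v, index=features["gene_id"]) for c, v in lfc.items()},
    }
    return expression, truth


def generate_disease(
    features: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> set:
    """Disease gene labels with sampling weight rising in length quantile."""
    rng = rng if rng is not None else _stage_rngs(config.seed)["disease"]
    n = len(features)
    ranks = features["length_total"].rank(method="average").to_numpy()
    weights = (ranks / n) ** config.ad_bias_power
    weights = weights / weights.sum()
    n_ad = int(round(config.ad_fraction * n))
    idx = rng.choice(n, size=n_ad, replace=False, p=weights)
    return set(features["gene_id"].to_numpy()[np.sort(idx)])


def generate_proteomics(
    classes: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> ProteomicsBundle:
    """Proteomics bundle whose proteins map 1:1 onto classified genes.

    Each module receives ``proteins_per_class`` proteins from every SG
    class so the full module x class grid is populated.  Abundance is a
    module latent factor times a positive loading plus noise; planted
    (module, class) cells additionally shift the latent mean per
    diagnosis group.
    """
    rng = rng if rng is not None else _stage_rngs(config.seed)["proteomics"]
    plan = config.proteomics
    pools: dict[str, list[str]] = {}
    for sg_class in ("enriched", "depleted", "neither"):
        pool = classes.loc[classes["sg_class"] == sg_class, "gene_id"].tolist()
        pools[sg_class] = [pool[i] for i in rng.permutation(len(pool))]
        needed = plan.n_modules * plan.proteins_per_class
        if len(pool) < needed:
            raise ValueError(
                f"not enough {sg_class} genes for the proteomics plan "
                f"({len(pool)} available, {needed} needed)"
            )
    sizes = plan.group_sizes
    n_samples = sum(sizes)
    diag_idx = np.repeat([0, 1, 2], sizes)
    diagnosis = np.array(["Control", "AsymAD", "AD"])[diag_idx]
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    braak = np.clip(
        plan.braak_base + plan.braak_slope * diag_idx + rng.normal(0, plan.braak_sd, n_samples),
        0.0, plan.braak_max,
    )
    cerad = np.clip(
        plan.cerad_base + plan.cerad_slope * diag_idx + rng.normal(0, plan.cerad_sd, n_samples),
        0.0, plan.cerad_max,
    )
    planted = {(e.module, e.sg_class): np.asarray(e.shifts) for e in plan.planted_effects}
    for module, _cls in planted:
        if not (module.startswith("M") and module[1:].isdigit()
                and 1 <= int(module[1:]) <= plan.n_modules):
            raise ValueError(f"planted effect references unknown module {module!r}")

    protein_rows = []
    abundances = []
    pool_cursor = {c: 0 for c in pools}
    p_idx = 0
    for mi in range(1, plan.n_modules + 1):
        module = f"M{mi}"
        latent = rng.normal(size=n_samples)
        for sg_class in ("enriched", "depleted", "neither"):
            shift = planted.get((module, sg_class))
            shift_vec = shift[diag_idx] if shift is not None else 0.0
            for _ in range(plan.proteins_per_class):
                gene = pools[sg_class][pool_cursor[sg_class]]
                pool_cursor[sg_class] += 1
                p_idx += 1
                protein = f"P{p_idx:05d}"
                loading = rng.uniform(plan.loading_low, plan.loading_high)
                noise = rng.normal(0, plan.noise_sd, n_samples)
                abundances.append(loading * (latent + shift_vec) + noise)
                protein_rows.append((protein, module, gene))
    proteins = [r[0] for r in protein_rows]
    abundance = pd.DataFrame(np.vstack(abundances), index=proteins, columns=samples)
    sample_meta = pd.DataFrame(
        {"diagnosis": diagnosis, "braak": braak, "cerad": cerad}, index=samples
    )
    sample_meta.index.name = "sample"
    module_map = pd.Series([r[1] for r in protein_rows], index=proteins, name="module")
    gene_map = pd.Series([r[2] for r in protein_rows], index=proteins, name="gene_id")
    return ProteomicsBundle(abundance, sample_meta, module_map, gene_map)


def simulate_study(
    config: SyntheticConfig, with_sequences: bool = False
) -> SyntheticStudy:
    """Generate the full study; sequences only when requested (FASTA output)."""
    rngs = _stage_rngs(config.seed)
    models, features = generate_annotation(config, rngs["annotation"])
    chroms = (
        generate_sequences(models, features, config, rngs["sequences"])
        if with_sequences
        else None
    )
    tracks = generate_peaks(models, features, config, rngs["peaks"])
    expression, truth = generate_expression(features, config, rngs["expression"])
    disease_genes = generate_disease(features, config, rngs["disease"])
    classes_true = classify_sg(truth["sg_tpm"], truth["total_tpm"], SGThresholds())
    truth["classes_true"] = classes_true
    proteomics = generate_proteomics(classes_true, config, rngs["proteomics"])
    return SyntheticStudy(
        config=config,
        models=models,
        features=features,
        chroms=chroms,
        peaks=tracks,
        expression=expression,
        truth=truth,
        disease_genes=disease_genes,
        proteomics=proteomics,
    )


# --- fixture writers ----------------------------------------------------------

def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """GENCODE-style GTF (1-based inclusive) with exon and CDS features."""
    with open(path, "w") as fh:
        fh.write("##description: synthetic annotation (granuleseq simulator)\n")
        for m in models:
            raw_biotype = m.biotype if m.biotype in (PROTEIN_CODING, LNCRNA) else "misc_RNA"
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "{raw_biotype}"; transcript_type "{raw_biotype}";'
            )
            tx_start = min(s for s, _ in m.exons) + 1
            tx_end = max(e for _, e in m.exons)
            fh.write(
                f"{m.chrom}\tgranuleseq\ttranscript\t{tx_start}\t{tx_end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tgranuleseq\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for s, e in m.cds:
                fh.write(
                    f"{m.chrom}\tgranuleseq\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}\n"
                )


def write_fasta(chroms: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(chroms):
            fh.write(f">{name}\n")
            seq = chroms[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """BED6 with the peak score in column 5."""
    with open(path, "w") as fh:
        for i, rec in enumerate(peaks.itertuples(index=False)):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\tpeak_{i + 1}\t{rec.score:.4f}\t{rec.strand}\n"
            )


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index=False)


def write_disease(disease_genes: set, path: str | Path, disease: str = "AD") -> None:
    pd.DataFrame(
        {"gene_id": sorted(disease_genes), "disease": disease, "source": "synthetic"}
    ).to_csv(path, sep="\t", index=False)


def write_proteomics(bundle: ProteomicsBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "proteomics_abundance.tsv",
        "meta": outdir / "proteomics_meta.tsv",
        "modules": outdir / "proteomics_modules.tsv",
        "genes": outdir / "proteomics_genes.tsv",
    }
    bundle.abundance.round(6).to_csv(paths["abundance"], sep="\t", index_label="protein")
    bundle.sample_meta.round(4).to_csv(paths["meta"], sep="\t")
    bundle.module_map.rename("module").to_csv(paths["modules"], sep="\t", index_label="protein")
    bundle.protein_gene_map.rename("gene_id").to_csv(paths["genes"], sep="\t", index_label="protein")
    return paths


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture the pipeline readers consume; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["gtf"] = outdir / "annotation.gtf"
    write_gtf(study.models, paths["gtf"])
    if study.chroms is not None:
        paths["fasta"] = outdir / "genome.fa"
        write_fasta(study.chroms, paths["fasta"])
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (protein, condition, rep), df in sorted(study.peaks.items()):
        p = peak_dir / f"{protein}_{condition}_rep{rep}.bed"
        write_bed(df, p)
        paths[f"peaks_{protein}_{condition}_rep{rep}"] = p
    paths["expression"] = outdir / "expression.tsv"
    write_expression(study.expression, paths["expression"])
    paths["disease"] = outdir / "disease_genes.tsv"
    write_disease(study.disease_genes, paths["disease"])
    paths.update(write_proteomics(study.proteomics, outdir))
    paths["config"] = outdir / "config.yaml"
    study.config.to_yaml(paths["config"])
    return paths
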