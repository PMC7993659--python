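"""Coupled multi-omics simulator with planted subtypes.

Generates a bundle of CNV segments, promoter methylation probes, expression
(FPKM and raw counts), mutation calls and clinical outcomes for a cohort with
``n_subtypes`` planted groups. The planted structure mirrors what the analysis
stages assume:

* a per-sample "burden" factor scales the noise of both the CNV and the
  methylation layers, so per-sample event tallies (gain/loss/hyper/hypo) are
  mutually positively correlated;
* a fraction of genes is dosage-coupled — their expression tracks their copy
  number with a configurable positive correlation — and a disjoint fraction is
  methylation-coupled with a configurable negative correlation;
* coupled genes carry subtype-specific mean shifts (blocks), so subtypes are
  recoverable from any single layer and, more strongly, from all layers
  jointly;
* survival times are exponential with per-subtype hazard multipliers and
  independent censoring.

Everything is driven by one integer seed: identical config + seed gives
byte-identical bundles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .matrix import OmicsMatrix

_CLASSIFICATIONS = np.array(
    ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site", "Silent", "Intron"]
)
_CLASS_PROBS = np.array([0.50, 0.10, 0.10, 0.10, 0.10, 0.10])

_GENE_SPACING = 1_000_000
_GENE_LENGTH = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 159
    n_genes: int = 2000
    n_subtypes: int = 3
    frac_coupled_cnv: float = 0.1
    frac_coupled_met: float = 0.1
    coupling_r_cnv: float = 0.6
    coupling_r_met: float = -0.6
    block_effect: float = 0.4
    hazard_ratios: tuple[float, ...] = (1.0, 2.0, 4.0)
    censor_rate: float = 0.3
    mutation_rate_per_gene: float = 0.02
    seed: int = 0
    beta_missing_rate: float = 0.0  # optional planted missingness for the imputation stage
    n_decoy_segments: int = 5  # per sample, probe count < 5, exercises the probe filter

    def validate(self) -> None:
        numeric = [
            self.frac_coupled_cnv, self.frac_coupled_met, self.coupling_r_cnv,
            self.coupling_r_met, self.block_effect, self.censor_rate,
            self.mutation_rate_per_gene, self.beta_missing_rate, *self.hazard_ratios,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise InvalidConfigError("config contains non-finite values")
        if self.n_samples < 1 or self.n_genes < 1:
            raise InvalidConfigError("n_samples and n_genes must be positive")
        if self.n_subtypes < 1:
            raise InvalidConfigError("n_subtypes must be >= 1")
        if self.n_subtypes > self.n_samples:
            raise InvalidConfigError("n_subtypes cannot exceed n_samples")
        for name, v in [
            ("frac_coupled_cnv", self.frac_coupled_cnv),
            ("frac_coupled_met", self.frac_coupled_met),
            ("censor_rate", self.censor_rate),
            ("mutation_rate_per_gene", self.mutation_rate_per_gene),
            ("beta_missing_rate", self.beta_missing_rate),
        ]:
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_coupled_cnv + self.frac_coupled_met > 1.0:
            raise InvalidConfigError("coupled fractions must sum to <= 1")
        if not 0.0 < self.coupling_r_cnv < 1.0:
            raise InvalidConfigError("coupling_r_cnv must lie in (0, 1)")
        if not -1.0 < self.coupling_r_met < 0.0:
            raise InvalidConfigError("coupling_r_met must lie in (-1, 0)")
        if len(self.hazard_ratios) != self.n_subtypes:
            raise InvalidConfigError("hazard_ratios must have one entry per subtype")
        if any(h <= 0 for h in self.hazard_ratios):
            raise InvalidConfigError("hazard ratios must be positive")


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    cnv_segments: pd.DataFrame  # Sample, Chromosome, Start, End, Num_Probes, Segment_Mean
    beta_matrix: OmicsMatrix  # probe-level
    probe_annotation: pd.DataFrame  # probe, chrom, position, gene, region_class
    gene_annotation: pd.DataFrame  # gene, chrom, strand, tss, gene_start, gene_end
    expression_fpkm: OmicsMatrix
    expression_counts: OmicsMatrix
    mutations: pd.DataFrame  # Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification
    clinical: pd.DataFrame
    truth_subtypes: pd.Series  # sample -> planted subtype
    truth_genes: pd.DataFrame  # gene -> coupled_cnv, coupled_met, block_group

    @property
    def samples(self) -> list[str]:
        return list(self.truth_subtypes.index)


def _gene_annotation(n_genes: int) -> pd.DataFrame:
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    chrom = [str(1 + i % 22) for i in range(n_genes)]
    idx_on_chrom = [i // 22 for i in range(n_genes)]
    start = np.array([1 + j * _GENE_SPACING for j in idx_on_chrom], dtype=int)
    end = start + _GENE_LENGTH - 1
    strand = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    tss = np.where(strand == "+", start, end)
    return pd.DataFrame(
        {"gene": genes, "chrom": chrom, "strand": strand, "tss": tss,
         "gene_start": start, "gene_end": end}
    )


def generate_multiomics(config: SimulationConfig) -> SyntheticBundle:
    """Generate one coupled multi-omics bundle. Deterministic given the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_samples, config.n_genes, config.n_subtypes

    samples = [f"S{i + 1:04d}" for i in range(n)]
    anno = _gene_annotation(g)
    genes = list(anno["gene"])

    subtype = np.resize(np.arange(k), n)
    rng.shuffle(subtype)

    n_cnv = int(round(config.frac_coupled_cnv * g))
    n_met = int(round(config.frac_coupled_met * g))
    coupled_cnv = np.zeros(g, dtype=bool)
    coupled_met = np.zeros(g, dtype=bool)
    coupled_cnv[:n_cnv] = True
    coupled_met[n_cnv:n_cnv + n_met] = True
    # block group: which subtype a coupled gene is shifted in (-1 = none)
    block_group = np.full(g, -1, dtype=int)
    block_group[:n_cnv] = np.resize(np.arange(k), n_cnv)
    block_group[n_cnv:n_cnv + n_met] = np.resize(np.arange(k), n_met)

    burden = np.exp(rng.normal(0.0, 0.5, size=n))  # shared event-rate factor

    # --- CNV layer (gene x sample log-ratios) ---
    cnv_mu = np.zeros((g, n))
    blk = config.block_effect
    for j in range(k):
        rows = coupled_cnv & (block_group == j)
        cnv_mu[np.ix_(rows, subtype == j)] += blk
    cnv = cnv_mu + burden[None, :] * rng.normal(0.0, 0.25, size=(g, n))

    # --- methylation layer on the logit scale; block shifts scaled so the
    # beta-scale shift is roughly block_effect at beta ~ 0.5 ---
    met_base = rng.normal(0.0, 0.5, size=(g, 1))
    met_mu = np.tile(met_base, (1, n))
    for j in range(k):
        rows = coupled_met & (block_group == j)
        met_mu[np.ix_(rows, subtype == j)] += 4.0 * blk
    met_logit = met_mu + burden[None, :] * rng.normal(0.0, 1.0, size=(g, n))
    beta_gene = 1.0 / (1.0 + np.exp(-met_logit))

    # --- expression coupled to dosage / methylation ---
    def _standardize_rows(m):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (m - mu) / sd

    eps = rng.normal(0.0, 1.0, size=(g, n))
    x = eps.copy()
    r_cnv = config.coupling_r_cnv
    r_met = config.coupling_r_met
    zc = _standardize_rows(cnv)
    zm = _standardize_rows(met_logit)
    x[coupled_cnv] = r_cnv * zc[coupled_cnv] + math.sqrt(1 - r_cnv ** 2) * eps[coupled_cnv]
    x[coupled_met] = r_met * zm[coupled_met] + math.sqrt(1 - r_met ** 2) * eps[coupled_met]

    log2_mu = rng.uniform(3.0, 8.0, size=(g, 1))
    fpkm = np.exp2(log2_mu + 0.8 * x)

    gene_len_kb = rng.uniform(0.5, 5.0, size=(g, 1))
    lib_factor = rng.uniform(0.4, 0.6, size=(1, n))  # library size / 1e6
    count_mu = fpkm * gene_len_kb * lib_factor
    disp = 0.1
    counts = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * count_mu)).astype(float)

    # --- probe-level methylation: one promoter probe per gene plus decoys ---
    tss, strand = anno["tss"].to_numpy(), anno["strand"].to_numpy()
    probe_pos = np.where(strand == "+", tss + 100, tss - 100)
    probes = [f"cg{i + 1:07d}" for i in range(g)]
    region = np.where(np.arange(g) % 3 == 0, "Island", "N_Shore")
    n_decoy_probes = max(1, g // 10)
    decoy_idx = np.arange(n_decoy_probes) % g
    decoy_probes = [f"cg9{i + 1:06d}" for i in range(n_decoy_probes)]
    decoy_pos = np.where(strand[decoy_idx] == "+", tss[decoy_idx] + 5000, tss[decoy_idx] - 5000)
    probe_annotation = pd.DataFrame(
        {
            "probe": probes + decoy_probes,
            "chrom": np.concatenate([anno["chrom"].to_numpy(), anno["chrom"].to_numpy()[decoy_idx]]),
            "position": np.concatenate([probe_pos, decoy_pos]).astype(int),
            "gene": np.concatenate([anno["gene"].to_numpy(), anno["gene"].to_numpy()[decoy_idx]]),
            "region_class": np.concatenate([region, np.full(n_decoy_probes, "OpenSea")]),
        }
    )
    decoy_beta = rng.uniform(0.0, 1.0, size=(n_decoy_probes, n))
    beta_values = np.round(np.vstack([beta_gene, decoy_beta]), 6)
    if config.beta_missing_rate > 0:
        mask = rng.random(size=beta_values.shape) < config.beta_missing_rate
        beta_values = np.where(mask, np.nan, beta_values)
    beta_matrix = OmicsMatrix(
        "beta", pd.DataFrame(beta_values, index=probes + decoy_probes, columns=samples)
    )

    # --- CNV segments: one covering segment per gene per sample + decoys ---
    cnv_rounded = np.round(cnv, 6)
    seg_sample = np.repeat(samples, g)
    seg_chrom = np.tile(anno["chrom"].to_numpy(), n)
    seg_start = np.tile(anno["gene_start"].to_numpy(), n)
    seg_end = np.tile(anno["gene_end"].to_numpy(), n)
    seg_probes = rng.integers(5, 50, size=n * g)
    seg_mean = cnv_rounded.T.reshape(-1)
    frames = [pd.DataFrame({
        "Sample": seg_sample, "Chromosome": seg_chrom, "Start": seg_start,
        "End": seg_end, "Num_Probes": seg_probes, "Segment_Mean": seg_mean,
    })]
    nd = config.n_decoy_segments
    if nd > 0:
        max_pos = int(anno["gene_end"].max()) + _GENE_SPACING
        frames.append(pd.DataFrame({
            "Sample": np.repeat(samples, nd),
            "Chromosome": "1",
            "Start": np.tile(max_pos + np.arange(nd) * 1000, n),
            "End": np.tile(max_pos + np.arange(nd) * 1000 + 500, n),
            "Num_Probes": rng.integers(1, 5, size=n * nd),
            "Segment_Mean": np.round(rng.normal(0, 0.3, size=n * nd), 6),
        }))
    cnv_segments = pd.concat(frames, ignore_index=True)

    # --- mutations ---
    mut_mask = rng.random(size=(g, n)) < config.mutation_rate_per_gene
    gi, si = np.nonzero(mut_mask)
    classes = rng.choice(_CLASSIFICATIONS, size=gi.size, p=_CLASS_PROBS)
    mutations = pd.DataFrame({
        "Hugo_Symbol": [genes[i] for i in gi],
        "Tumor_Sample_Barcode": [samples[j] for j in si],
        "Variant_Classification": classes,
    })

    # --- clinical / survival ---
    base_hazard = 0.02
    hr = np.asarray(config.hazard_ratios, dtype=float)[subtype]
    true_time = rng.exponential(1.0 / (base_hazard * hr))
    event = (rng.random(n) >= config.censor_rate).astype(int)
    observed = np.where(event == 1, true_time, true_time * rng.random(n))
    observed = np.maximum(observed, 1e-3)
    clinical = pd.DataFrame({
        "sample": samples,
        "OS_time": np.round(observed, 4),
        "OS_event": event,
        "T_stage": rng.integers(1, 5, size=n),
        "N_stage": rng.integers(0, 4, size=n),
        "M_stage": rng.integers(0, 2, size=n),
        "stage": rng.integers(1, 5, size=n),
        "age": rng.integers(35, 85, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "histology": rng.choice(["SCC", "AC"], size=n),
    }).set_index("sample")

    truth_subtypes = pd.Series(subtype, index=samples, name="subtype")
    truth_genes = pd.DataFrame({
        "gene": genes,
        "coupled_cnv": coupled_cnv,
        "coupled_met": coupled_met,
        "block_group": block_group,
    }).set_index("gene")

    fpkm_df = pd.DataFrame(np.round(fpkm, 4), index=genes, columns=samples)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    return SyntheticBundle(
        config=config,
        cnv_segments=cnv_segments,
        beta_matrix=beta_matrix,
        probe_annotation=probe_annotation,
        gene_annotation=anno,
        expression_fpkm=OmicsMatrix("fpkm", fpkm_df),
        expression_counts=OmicsMatrix("counts", counts_df),
        mutations=mutations,
        clinical=clinical,
        truth_subtypes=truth_subtypes,
        truth_genes=truth_genes,
    )


def gene_level_cnv(bundle: SyntheticBundle) -> OmicsMatrix:
    """Gene x sample CNV matrix recovered from the per-gene covering segments.

    Shortcut equivalent to running segment merging + gene mapping on the
    bundle's segment table (each gene is covered by exactly one >=5-probe
    segment per sample by construction); used where the preprocessing route
    itself is not under test.
    """
    seg = bundle.cnv_segments
    seg = seg[seg["Num_Probes"] >= 5]
    wide = seg.pivot_table(index=["Chromosome", "Start"], columns="Sample",
                           values="Segment_Mean")
    ann = bundle.gene_annotation.set_index(["chrom", "gene_start"])
    genes = [ann.loc[(c, s), "gene"] for c, s in wide.index]
    wide.index = genes
    ordered = wide.loc[bundle.gene_annotation["gene"], bundle.samples]
    return OmicsMatrix("cnv_logratio", ordered)


def promoter_beta(bundle: SyntheticBundle) -> OmicsMatrix:
    """Gene x sample promoter methylation (the one promoter probe per gene)."""
    g = bundle.config.n_genes
    df = bundle.beta_matrix.values.iloc[:g].copy()
    df.index = list(bundle.gene_annotation["gene"])
    return OmicsMatrix("beta", df)


def write_bundle(bundle: SyntheticBundle, directory) -> dict:
    """Write the bundle as plain TSV files; returns a manifest of paths + shapes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def _write(name: str, df: pd.DataFrame, index: bool) -> None:
        path = directory / name
        df.to_csv(path, sep="\t", index=index)
        manifest[name] = {
            "path": str(path),
            "n_rows": int(df.shape[0]),
            "n_cols": int(df.shape[1]) + (1 if index else 0),
        }

    _write("cnv_segments.seg", bundle.cnv_segments, index=False)
    _write("beta.tsv", bundle.beta_matrix.values.rename_axis("probe"), index=True)
    _write("probe_annotation.tsv", bundle.probe_annotation, index=False)
    _write("gene_annotation.tsv", bundle.gene_annotation, index=False)
    _write("expression_fpkm.tsv", bundle.expression_fpkm.values.rename_axis("gene"), index=True)
    _write("expression_counts.tsv",
           bundle.expression_counts.values.astype(int).rename_axis("gene"), index=True)
    _write("mutations.maf", bundle.mutations, index=False)
    _write("clinical.tsv", bundle.clinical.reset_index(), index=False)
    truth = bundle.truth_subtypes.rename_axis("sample").reset_index()
    _write("truth_subtypes.tsv", truth, index=False)
    _write("truth_genes.tsv", bundle.truth_genes.reset_index(), index=False)
    pd.Series({k: str(v) for k, v in asdict(bundle.config).items()}).rename_axis("key").rename(
        "value"
    ).reset_index().to_csv(directory / "config.tsv", sep="\t", index=False)
    manifest["config.tsv"] = {"path": str(directory / "config.tsv")}
    return manifest
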