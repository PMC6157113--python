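"""Simulator for pharmaco-epigenetic drug-response datasets.

Emulates the structure of the GAW20-style triglyceride-response
simulation so that every analysis stage can be exercised without the
access-restricted GOLDN data:

* ``n`` independent individuals (default 111, the size of the simulated-
  data analysis set) with age and pre-treatment log-triglyceride
  (pre-lnTG) covariates;
* 10 regions of interest, each on its own chromosome with an anchor CpG
  and a small cloud of flanking CpGs; 5 regions are causal (they carry a
  SNP with a phenotypic effect) and 5 are non-causal;
* pre-treatment methylation drawn per CpG from a Beta distribution;
  post-treatment methylation is the pre value perturbed by Gaussian noise
  on the logit scale, with the noise SD multiplied by an inflation factor
  (> 1) at the 10 anchor CpGs — the "designated" variance-inflated sites;
* 5 causal SNPs in Hardy-Weinberg proportions whose effect on
  post-treatment log-triglyceride attenuates linearly with the anchor
  CpG's post-treatment methylation: full effect at beta value 0, no
  effect at beta value 1,

      post-lnTG = a0 + a1*pre-lnTG + a2*age
                  + sum_j  beta_j * g_j * (1 - m_j)  + eps;

* per-SNP effect sizes ``beta_j`` calibrated from target heritabilities
  that decrease strictly across the causal regions.  Heritability h_j is
  the fraction of the covariate-adjusted phenotypic variance contributed
  by term j:  Var(beta_j g_j (1 - m_j)) = h_j * sigma_T^2  with
  sigma_T^2 = sigma_eps^2 / (1 - sum_j h_j).  The moments of
  g_j (1 - m_j) are evaluated by deterministic quadrature against the
  configured genotype and methylation distributions, so "decreasing
  heritability" is well defined marginally.

The generator emulates the statistical structure of the original
simulation (variance inflation, attenuation, effect ordering), not its
exact numbers: polygenic background, pedigree structure and the original
genotype panel are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .core_data import (MarkerAnnotation, MarkerMatrix, Region, RegionSet,
                        SampleTable, write_annotation, write_marker_matrix,
                        write_sample_table)
from .exceptions import ConfigurationError
from .roi_builder import build_window_region

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: base-pair offsets of each region's CpGs relative to its anchor (offset 0)
DEFAULT_CPG_OFFSETS = (-12000, -2500, 0, 2500, 12000)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; defaults are the study conditions.

    Heritabilities must be strictly decreasing, one per causal region.
    ``methylation_mean``/``methylation_concentration`` parameterize the
    Beta distribution of pre-treatment beta values (Beta(mu*c, (1-mu)*c)).
    ``logit_noise_sd`` is the SD of the treatment perturbation on the
    logit scale; at the 10 anchor CpGs it is multiplied by
    ``variance_inflation``.
    """

    n: int = 111
    n_causal: int = 5
    n_noncausal: int = 5
    heritabilities: tuple[float, ...] = (0.10, 0.07, 0.05, 0.03, 0.01)
    maf: float = 0.3
    cpg_offsets: tuple[int, ...] = DEFAULT_CPG_OFFSETS
    snp_offset: int = 500
    anchor_position: int = 1_000_000
    methylation_mean: float = 0.75
    methylation_concentration: float = 5.0
    logit_noise_sd: float = 0.3
    variance_inflation: float = 3.0
    age_mean: float = 49.0
    age_sd: float = 12.0
    pre_lntg_mean: float = 4.9
    pre_lntg_sd: float = 0.5
    intercept: float = 0.5
    coef_pre_lntg: float = 0.8
    coef_age: float = 0.002
    residual_sd: float = 0.35
    default_window_kbp: float = 3.0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigurationError("need n >= 10")
        h = self.heritabilities
        if len(h) != self.n_causal:
            raise ConfigurationError(
                f"{self.n_causal} causal regions need {self.n_causal} "
                f"heritabilities, got {len(h)}")
        if any(not (0.0 <= hj < 1.0) for hj in h):
            raise ConfigurationError("heritabilities must lie in [0, 1)")
        # all-zero is the designated null configuration; otherwise the
        # causal effects must strictly decrease across regions
        if any(hj > 0 for hj in h) and \
                any(a <= b for a, b in zip(h, h[1:])):
            raise ConfigurationError("heritabilities must strictly decrease")
        if sum(h) >= 1.0:
            raise ConfigurationError(
                f"total heritability {sum(h):.3f} must be < 1")
        if not 0.05 <= self.maf <= 0.5:
            raise ConfigurationError("minor allele frequency must lie in "
                                     "[0.05, 0.5]")
        if self.variance_inflation <= 1.0:
            raise ConfigurationError("variance_inflation must exceed 1")
        if 0 not in self.cpg_offsets:
            raise ConfigurationError("cpg_offsets must include 0 (the anchor)")
        if not 0.0 < self.methylation_mean < 1.0:
            raise ConfigurationError("methylation_mean must lie in (0, 1)")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be positive")

    @property
    def n_regions(self) -> int:
        return self.n_causal + self.n_noncausal

    # --- marker naming / layout ------------------------------------------

    def region_name(self, r: int) -> str:
        return f"ROI-{r + 1}"

    def chrom(self, r: int) -> str:
        return str(r + 1)

    def cpg_id(self, r: int, j: int) -> str:
        return f"roi{r + 1}_cg{j + 1}"

    def anchor_cpg_id(self, r: int) -> str:
        return self.cpg_id(r, self.cpg_offsets.index(0))

    def snp_id(self, r: int) -> str:
        return f"roi{r + 1}_snp"

    def is_causal(self, r: int) -> bool:
        return r < self.n_causal


# ---------------------------------------------------------------------------
# effect-size calibration
# ---------------------------------------------------------------------------

def _post_methylation_moments(config: SimulationConfig,
                              inflated: bool) -> tuple[float, float]:
    """E[1 - m] and E[(1 - m)^2] of post-treatment methylation.

    Deterministic quadrature: Beta quantile midpoints for the pre value
    crossed with Gauss-Hermite nodes for the logit-scale perturbation.
    """
    mu, c = config.methylation_mean, config.methylation_concentration
    a, b = mu * c, (1.0 - mu) * c
    sd = config.logit_noise_sd * (config.variance_inflation if inflated
                                  else 1.0)
    qs = (np.arange(512) + 0.5) / 512
    pre = stats.beta.ppf(qs, a, b)
    z, w = np.polynomial.hermite.hermgauss(41)
    w = w / np.sqrt(np.pi)
    post = expit(logit(pre)[:, None] + np.sqrt(2.0) * sd * z[None, :])
    u = 1.0 - post
    e1 = float(np.mean(u @ w))
    e2 = float(np.mean((u ** 2) @ w))
    return e1, e2


def calibrate_effect_sizes(config: SimulationConfig) -> np.ndarray:
    """Per-causal-SNP effect size beta_j from the target heritabilities.

    Var(g (1 - m)) is computed from the Hardy-Weinberg genotype moments
    and the quadrature moments of post-treatment methylation at an
    inflated (anchor) CpG; g and m are independent in the generator.
    """
    p = config.maf
    eg, eg2 = 2.0 * p, 2.0 * p * (1.0 - p) + 4.0 * p * p
    e1, e2 = _post_methylation_moments(config, inflated=True)
    var_gu = eg2 * e2 - (eg * e1) ** 2
    total_h = sum(config.heritabilities)
    sigma_t2 = config.residual_sd ** 2 / (1.0 - total_h)
    betas = np.sqrt(np.array(config.heritabilities) * sigma_t2 / var_gu)
    return betas


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def _sample_ids(config: SimulationConfig) -> tuple[str, ...]:
    return tuple(f"S{i + 1:04d}" for i in range(config.n))


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator) -> MarkerMatrix:
    """One Hardy-Weinberg SNP per causal region: dosage ~ Binomial(2, MAF)."""
    dosages = rng.binomial(2, config.maf,
                           size=(config.n, config.n_causal)).astype(float)
    return MarkerMatrix(
        sample_ids=_sample_ids(config),
        marker_ids=tuple(config.snp_id(r) for r in range(config.n_causal)),
        values=dosages,
        marker_kind="genotype",
    )


def simulate_methylation(config: SimulationConfig, rng: np.random.Generator,
                         ) -> tuple[MarkerMatrix, MarkerMatrix]:
    """Pre- and post-treatment methylation for every region CpG.

    Post = inverse-logit(logit(pre) + noise); the noise SD carries the
    inflation factor at the 10 anchor CpGs, reproducing the designated
    variance-inflated sites.  All values stay in (0, 1) by construction.
    """
    mu, c = config.methylation_mean, config.methylation_concentration
    ids, inflated = [], []
    for r in range(config.n_regions):
        for j, off in enumerate(config.cpg_offsets):
            ids.append(config.cpg_id(r, j))
            inflated.append(off == 0)
    m = len(ids)
    pre = rng.beta(mu * c, (1.0 - mu) * c, size=(config.n, m))
    sd = np.where(inflated,
                  config.logit_noise_sd * config.variance_inflation,
                  config.logit_noise_sd)
    post = expit(logit(pre) + rng.normal(0.0, 1.0, size=pre.shape) * sd)
    sample_ids = _sample_ids(config)
    make = lambda vals: MarkerMatrix(sample_ids=sample_ids,
                                     marker_ids=tuple(ids), values=vals,
                                     marker_kind="methylation")
    return make(pre), make(post)


def simulate_phenotype(config: SimulationConfig, genotypes: MarkerMatrix,
                       post_methylation: MarkerMatrix,
                       rng: np.random.Generator) -> SampleTable:
    """Covariates plus the attenuated causal-SNP effects and noise.

    The causal term for region j is beta_j * g_j * (1 - m_j) with m_j the
    individual's post-treatment methylation at that region's anchor CpG:
    full SNP effect in an unmethylated region, none at full methylation.
    """
    n = config.n
    age = rng.normal(config.age_mean, config.age_sd, size=n).clip(20, 85)
    pre_lntg = rng.normal(config.pre_lntg_mean, config.pre_lntg_sd, size=n)
    y = (config.intercept + config.coef_pre_lntg * pre_lntg
         + config.coef_age * age)
    betas = calibrate_effect_sizes(config)
    for r in range(config.n_causal):
        g = genotypes.restrict_markers([config.snp_id(r)]).values[:, 0]
        m = post_methylation.restrict_markers(
            [config.anchor_cpg_id(r)]).values[:, 0]
        y = y + betas[r] * g * (1.0 - m)
    y = y + rng.normal(0.0, config.residual_sd, size=n)
    return SampleTable(
        sample_ids=_sample_ids(config),
        response=y,
        covariates=pd.DataFrame({"pre_lntg": pre_lntg, "age": age}),
    )


def build_annotation(config: SimulationConfig) -> MarkerAnnotation:
    """Lay each region out on its own chromosome, anchor CpG centered."""
    rows = []
    for r in range(config.n_regions):
        chrom = config.chrom(r)
        for j, off in enumerate(config.cpg_offsets):
            rows.append((config.cpg_id(r, j), chrom,
                         config.anchor_position + off, "methylation"))
        if config.is_causal(r):
            rows.append((config.snp_id(r), chrom,
                         config.anchor_position + config.snp_offset,
                         "genotype"))
    return MarkerAnnotation(table=pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos", "kind"]))


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionTruth:
    region: str
    causal: bool
    anchor_cpg: str
    snp: str | None
    heritability: float
    effect_size: float


@dataclass(frozen=True)
class SimulatedDataset:
    samples: SampleTable
    methylation_pre: MarkerMatrix
    methylation_post: MarkerMatrix
    genotypes: MarkerMatrix
    annotation: MarkerAnnotation
    regions: RegionSet
    truth: tuple[RegionTruth, ...]
    seed: int | None
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if sum(t.causal for t in self.truth) != \
                sum(1 for t in self.truth if t.snp is not None):
            raise ConfigurationError("causal flags inconsistent with SNPs")


def null_config(**overrides) -> SimulationConfig:
    """Default configuration with every causal effect set to zero."""
    overrides.setdefault("heritabilities",
                         tuple(0.0 for _ in range(5)))
    return SimulationConfig(**overrides)


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate one fully aligned dataset; deterministic under ``seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    genotypes = simulate_genotypes(config, rng)
    meth_pre, meth_post = simulate_methylation(config, rng)
    samples = simulate_phenotype(config, genotypes, meth_post, rng)
    annotation = build_annotation(config)
    cpg_universe = list(meth_post.marker_ids)
    regions = RegionSet(regions=tuple(
        build_window_region(config.region_name(r), config.anchor_cpg_id(r),
                            config.default_window_kbp, annotation,
                            cpg_universe)
        for r in range(config.n_regions)
    ))
    betas = calibrate_effect_sizes(config)
    truth = tuple(
        RegionTruth(
            region=config.region_name(r),
            causal=config.is_causal(r),
            anchor_cpg=config.anchor_cpg_id(r),
            snp=config.snp_id(r) if config.is_causal(r) else None,
            heritability=(config.heritabilities[r]
                          if config.is_causal(r) else 0.0),
            effect_size=float(betas[r]) if config.is_causal(r) else 0.0,
        )
        for r in range(config.n_regions)
    )
    return SimulatedDataset(
        samples=samples, methylation_pre=meth_pre, methylation_post=meth_post,
        genotypes=genotypes, annotation=annotation, regions=regions,
        truth=truth, seed=seed, config=config,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write all dataset components in the delimited interchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_table(dataset.samples, outdir / "phenotypes.tsv")
    write_marker_matrix(dataset.methylation_pre,
                        outdir / "methylation_pre.tsv")
    write_marker_matrix(dataset.methylation_post,
                        outdir / "methylation_post.tsv")
    write_marker_matrix(dataset.genotypes, outdir / "genotypes.tsv")
    write_annotation(dataset.annotation, outdir / "annotation.tsv")
    pd.DataFrame([t.__dict__ for t in dataset.truth]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "regions.tsv", "w") as fh:
        for region in dataset.regions:
            fh.write(f"{region.name}\t{region.anchor}\t"
                     f"{region.window_kbp}\n")
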