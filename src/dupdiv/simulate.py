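"""Synthetic inputs with known truth for every downstream analysis stage.

Three generators:

* ``simulate_populations`` — three-population SNP panels (wild -> landrace ->
  improved) with successive Balding–Nichols-style drift bottlenecks and
  localized diversity-reducing sweep tracts, emulating a wild/landrace/
  improved resequencing panel;
* ``simulate_codon_pair`` — a pair of coding sequences diverged to a target
  synonymous divergence Ks at a chosen Ka/Ks ratio omega, with NG86 site
  counting defining the targets;
* ``simulate_expression_trait`` — cultivar expression/trait tables in which
  the trait is a linear function of per-gene expression plus noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .genetic_code import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, BASES
from .io import CodonAlignmentPair, GenotypeMatrix, TraitTable
from .kaks import count_sites_ng86

import pandas as pd

__all__ = [
    "PopSimParams",
    "SweepTract",
    "CodonSimParams",
    "ExprSimParams",
    "simulate_populations",
    "simulate_codon_pair",
    "simulate_expression_trait",
    "beta_for_target_r2",
]


# ---------------------------------------------------------------------------
# population panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepTract:
    """A diversity-reducing tract: expected heterozygosity of the target
    population inside [start, end) is multiplied by rho (rho=1 -> no sweep)."""

    start: int
    end: int
    population: str
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.start >= self.end:
            raise ValueError("tract start must be < end")


@dataclass
class PopSimParams:
    """Conditions for the three-population panel.

    Defaults emulate a 302-accession wild/landrace/improved soybean panel
    (62/130/110 diploid samples) on a 1-Mb chromosome with wild per-site
    diversity 0.003, a moderate domestication bottleneck (F = 0.10) and a
    weaker improvement bottleneck (F = 0.05).  snp_density (SNPs per bp) is
    optional: when None the SNP count is calibrated so the expected wild pi
    equals theta_wild under the generator's allele-frequency distribution.
    """

    chrom_length: int = 1_000_000
    theta_wild: float = 0.003
    snp_density: float | None = None
    bottleneck_landrace: float = 0.10
    bottleneck_improved: float = 0.05
    sweep_tracts: list[SweepTract] = field(default_factory=list)
    n_wild: int = 62
    n_landrace: int = 130
    n_improved: int = 110
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.sweep_tracts = [
            t if isinstance(t, SweepTract)
            else SweepTract(**t) if isinstance(t, dict)
            else SweepTract(*t)
            for t in self.sweep_tracts
        ]
        for name, n in (("n_wild", self.n_wild), ("n_landrace", self.n_landrace),
                        ("n_improved", self.n_improved)):
            if n < 2:
                raise ValueError(f"{name} must be >= 2, got {n}")
        for f, name in ((self.bottleneck_landrace, "bottleneck_landrace"),
                        (self.bottleneck_improved, "bottleneck_improved")):
            if not 0.0 <= f < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {f}")
        for t in self.sweep_tracts:
            if t.start < 0 or t.end > self.chrom_length:
                raise ValueError(
                    f"sweep tract [{t.start}, {t.end}) outside chromosome "
                    f"[0, {self.chrom_length})"
                )
            if t.population not in ("wild", "landrace", "improved"):
                raise ValueError(f"unknown tract population {t.population!r}")


def _sfs_mean_het(eps: float) -> float:
    """E[2p(1-p)] under the truncated neutral SFS f(p) ∝ 1/p on (eps, 1-eps)."""
    return (1.0 - 2.0 * eps) / math.log((1.0 - eps) / eps)


_DEFAULT_EPS = 0.05


def _drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols drift kernel: Beta with mean p, variance f*p*(1-p)."""
    if f == 0.0:
        return p.copy()
    seg = (p > 0.0) & (p < 1.0)
    out = p.copy()
    scale = (1.0 - f) / f
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def simulate_populations(params: PopSimParams) -> GenotypeMatrix:
    """Generate a three-population GenotypeMatrix.

    Wild allele frequencies are drawn from a low-frequency-enriched neutral
    SFS (density ∝ 1/p, truncated); landrace and improved frequencies are
    obtained by successive Balding–Nichols drift with intensities
    bottleneck_landrace and bottleneck_improved (each multiplies expected
    heterozygosity by 1-F); inside each sweep tract the target population's
    frequencies are pushed to fixation with probability 1-rho, multiplying
    its expected heterozygosity by rho.  Genotypes are binomial draws of two
    allele copies from the population frequency.
    """
    rng = np.random.default_rng(params.seed)
    L = params.chrom_length

    if params.snp_density is None:
        eps = _DEFAULT_EPS
        n_snps = int(round(params.theta_wild * L / _sfs_mean_het(eps)))
    else:
        target_het = params.theta_wild / params.snp_density
        if target_het >= 0.5:
            raise ValueError(
                f"theta_wild={params.theta_wild} unattainable at snp_density="
                f"{params.snp_density}: required mean site heterozygosity "
                f"{target_het:.3f} exceeds the maximum 0.5"
            )
        eps = brentq(lambda e: _sfs_mean_het(e) - target_het, 1e-9, 0.5 - 1e-9)
        n_snps = int(round(params.snp_density * L))
    if n_snps < 1 or n_snps > L:
        raise ValueError(f"SNP count {n_snps} outside [1, chrom_length]")

    positions = np.sort(rng.choice(L, size=n_snps, replace=False))

    # inverse-CDF draw from f(p) ∝ 1/p on (eps, 1-eps)
    u = rng.random(n_snps)
    p_wild = eps * ((1.0 - eps) / eps) ** u

    p_land = _drift(p_wild, params.bottleneck_landrace, rng)
    p_impr = _drift(p_land, params.bottleneck_improved, rng)
    freqs = {"wild": p_wild, "landrace": p_land, "improved": p_impr}

    for tract in params.sweep_tracts:
        in_tract = (positions >= tract.start) & (positions < tract.end)
        p = freqs[tract.population]
        fix = in_tract & (rng.random(n_snps) < 1.0 - tract.rho)
        p[fix] = (rng.random(n_snps)[fix] < p[fix]).astype(float)

    counts = {"wild": params.n_wild, "landrace": params.n_landrace,
              "improved": params.n_improved}
    blocks = []
    sample_ids: list[str] = []
    pop_map: dict[str, str] = {}
    for pop in ("wild", "landrace", "improved"):
        n = counts[pop]
        blocks.append(rng.binomial(2, freqs[pop][:, None], size=(n_snps, n)).astype(np.int8))
        for k in range(n):
            sid = f"{pop}_{k:03d}"
            sample_ids.append(sid)
            pop_map[sid] = pop

    ref = np.full(n_snps, "A")
    alt = np.full(n_snps, "G")
    return GenotypeMatrix(
        chrom=params.chrom,
        positions=positions,
        ref=ref,
        alt=alt,
        calls=np.hstack(blocks),
        sample_ids=sample_ids,
        pop_map=pop_map,
        chrom_length=L,
    )


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------

@dataclass
class CodonSimParams:
    """Conditions for a diverged codon pair.

    target_ks is the expected synonymous substitutions per synonymous site
    between the two sequences; omega scales the nonsynonymous rate, so the
    regime omega < 1 emulates purifying selection.
    """

    n_codons: int = 300
    target_ks: float = 0.05
    omega: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")


def simulate_codon_pair(params: CodonSimParams, return_counts: bool = False):
    """Evolve one branch away from a random stop-free ancestor.

    Synonymous and nonsynonymous single-base changes are applied in Poisson
    numbers with means target_ks*S and omega*target_ks*N, where S and N are
    the ancestor's NG86 site counts.  Changes creating stop codons are never
    applied; each applied change is classified in its current codon context
    and the true counts are returned when return_counts is True.
    """
    rng = np.random.default_rng(params.seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), params.n_codons)]
    ancestor = "".join(codons)

    s_sites = sum(count_sites_ng86(c)[0] for c in codons)
    n_sites = 3.0 * params.n_codons - s_sites
    n_syn = int(rng.poisson(params.target_ks * s_sites))
    n_non = int(rng.poisson(params.omega * params.target_ks * n_sites))

    seq = list(codons)
    applied_syn = applied_non = 0
    max_tries = 1000 * (n_syn + n_non + 10)
    tries = 0
    while (applied_syn < n_syn or applied_non < n_non) and tries < max_tries:
        tries += 1
        ci = int(rng.integers(0, params.n_codons))
        pos = int(rng.integers(0, 3))
        base = BASES[int(rng.integers(0, 4))]
        codon = seq[ci]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[mutant] == CODON_TO_AA[codon]
        if synonymous and applied_syn < n_syn:
            seq[ci] = mutant
            applied_syn += 1
        elif not synonymous and applied_non < n_non:
            seq[ci] = mutant
            applied_non += 1
    if applied_syn < n_syn or applied_non < n_non:
        raise RuntimeError(
            f"could not place requested substitutions without stop codons "
            f"({applied_syn}/{n_syn} synonymous, {applied_non}/{n_non} nonsynonymous)"
        )
    pair = CodonAlignmentPair(ancestor, "".join(seq))
    if return_counts:
        return pair, {"syn": applied_syn, "nonsyn": applied_non,
                      "s_sites": s_sites, "n_sites": n_sites}
    return pair


# ---------------------------------------------------------------------------
# expression/trait tables
# ---------------------------------------------------------------------------

DEFAULT_GENES = ("GmCYP78A70", "GmCYP78A57", "GmCYP78A72")


@dataclass
class ExprSimParams:
    """Conditions for a cultivar expression/trait panel.

    Emulates a 30-cultivar qRT-PCR panel with three replicates: per-gene
    cultivar expression is log-normal (positive, right-skewed, matching the
    2^-ddCt scale), the trait is intercept + sum(beta_g * expr_g) + Gaussian
    noise, and replicate-level expression adds small multiplicative noise.
    Optional promoter-genotype groups shift the first gene's expression.
    """

    n_cultivars: int = 30
    betas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 1.0
    expr_means: tuple[float, float, float] = (1.0, 1.0, 1.0)
    expr_sds: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_replicates: int = 3
    replicate_cv: float = 0.05
    intercept: float = 10.0
    genes: tuple[str, ...] = DEFAULT_GENES
    genotype_groups: int = 0
    genotype_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cultivars < 3:
            raise ValueError("n_cultivars must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (len(self.betas) == len(self.expr_means) == len(self.expr_sds) == len(self.genes)):
            raise ValueError("betas, expr_means, expr_sds and genes must have equal length")


def beta_for_target_r2(target_r2: float, expr_sd: float, noise_sd: float) -> float:
    """Effect size giving a population R^2 for one gene when others are null.

    Solves beta^2*sd^2 / (beta^2*sd^2 + noise^2) = target_r2.
    """
    if not 0.0 <= target_r2 < 1.0:
        raise ValueError("target_r2 must be in [0, 1)")
    return noise_sd / expr_sd * math.sqrt(target_r2 / (1.0 - target_r2))


def _lognormal(rng, mean: float, sd: float, size) -> np.ndarray:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def simulate_expression_trait(params: ExprSimParams) -> TraitTable:
    """Generate a replicate-level TraitTable with known linear effects."""
    rng = np.random.default_rng(params.seed)
    g = len(params.genes)
    expr = np.column_stack([
        _lognormal(rng, params.expr_means[j], params.expr_sds[j], params.n_cultivars)
        for j in range(g)
    ])
    genotype = None
    if params.genotype_groups > 1:
        genotype = np.arange(params.n_cultivars) % params.genotype_groups
        expr[:, 0] = expr[:, 0] + params.genotype_shift * params.expr_sds[0] * genotype
    trait = (
        params.intercept
        + expr @ np.asarray(params.betas)
        + rng.normal(0.0, params.noise_sd, params.n_cultivars)
    )
    rows = []
    for i in range(params.n_cultivars):
        for rep in range(1, params.n_replicates + 1):
            noise = rng.lognormal(0.0, params.replicate_cv, g) if params.replicate_cv > 0 else 1.0
            row = {
                "cultivar": f"cv{i:03d}",
                "replicate": rep,
                "trait": trait[i],
            }
            rep_expr = expr[i] * noise
            for j, gene in enumerate(params.genes):
                row[gene] = rep_expr[j]
            if genotype is not None:
                row["genotype"] = f"Genotype {genotype[i] + 1}"
            rows.append(row)
    df = pd.DataFrame(rows)
    return TraitTable(
        data=df,
        genes=list(params.genes),
        trait="trait",
        genotype="genotype" if genotype is not None else None,
    )
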