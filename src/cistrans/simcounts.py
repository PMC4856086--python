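"""Synthetic count data with known regulatory architecture.

Emulates the data structures produced by a replicated two-population +
F1-hybrid RNA-seq experiment (3 + 3 + 3 libraries) downstream of read
mapping:

* an allelic count matrix at fixed-difference SNP sites — 12 columns: one per
  parental sample (each parent expresses only its own fixed allele, so that
  single-allele count stands in for its total expression) and two per hybrid
  (one per allele);
* a gene-level count matrix over the 9 libraries with configurable
  inheritance architecture;

together with truth tables of the generating parameters so that downstream
tests, classification and parameter recovery can be scored exactly.

Generative model for a site with baseline ``b`` (expected parental
population-1 count), cis effect ``c`` and trans effect ``t`` (both log2):

* population-1 parental expectation  ``b``
* population-2 parental expectation  ``b * 2**(c + t)``   (parental log2
  ratio = cis + trans)
* hybrid allele-A expectation        ``b / 2``            (total split
  across the two alleles)
* hybrid allele-B expectation        ``(b / 2) * 2**c``   (hybrid allelic
  log2 ratio = cis; both alleles share one trans environment)

Every expectation is multiplied by its column's size factor and counts are
drawn NB with variance ``mu + alpha * mu**2``. Randomness is counter-split:
one root seed, one independent Philox stream per feature, so row order and
subsetting never change the draws for a given feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nbcore import CountMatrix

REG_CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
)
INH_CATEGORIES = (
    "conserved",
    "additive",
    "dominant_P1",
    "dominant_P2",
    "overdominant",
    "underdominant",
)

__all__ = [
    "SimConfig",
    "REG_CATEGORIES",
    "INH_CATEGORIES",
    "simulate_regulatory_sites",
    "simulate_inheritance_genes",
    "simulate_null",
    "write_sim_vcf",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Parameters
    ----------
    n_features
        Number of sites (or genes).
    n_per_group
        Individuals per population; the replicated design of the emulated
        study uses 3.
    mean_log_baseline
        log2 of the median expected parental count (9 -> ~512 reads/site).
    baseline_log2_sd
        log2-scale spread of baselines across features, giving the matrix a
        realistic dynamic range; 0 makes every baseline identical.
    dispersion
        NB overdispersion alpha; variance = mu + alpha mu^2.
    size_factor_spread
        sd of natural-log library size factors (multiplicative, geometric
        mean fixed at 1).
    cis_effect_sd, trans_effect_sd
        log2-scale sd of the zero-truncated normal effect magnitudes.
    min_effect
        magnitude floor (log2) of nonzero effects, keeping categories
        identifiable at replicated-desk scale.
    fixed_effect_log2
        If set, every nonzero effect has exactly this magnitude (random
        sign); used for power/recovery configurations.
    misexpression_offset_log2
        log2 offset above/below the parental range for over/underdominant
        genes (gene-level generator).
    category_fractions
        Map true-category -> proportion (must sum to 1). Regulatory
        categories for the site generator, inheritance categories for the
        gene generator.
    seed
        Root seed for all randomness.
    """

    n_features: int
    n_per_group: int = 3
    mean_log_baseline: float = 9.0
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.05
    size_factor_spread: float = 0.1
    cis_effect_sd: float = 1.0
    trans_effect_sd: float = 1.0
    min_effect: float = 0.5
    fixed_effect_log2: float | None = None
    misexpression_offset_log2: float = 1.0
    category_fractions: dict = field(default_factory=lambda: {"conserved": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (replication is required)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("size_factor_spread", "cis_effect_sd", "trans_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_fractions must sum to 1 (got {total})")
        if any(v < 0 for v in self.category_fractions.values()):
            raise ValueError("category_fractions must be nonnegative")


def _feature_rng(seed: int, i: int) -> np.random.Generator:
    # counter-based splitting: independent stream per feature index
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed, spawn_key=(i,))))


def _root_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed, spawn_key=(0xFFFF,))))


def _size_factors(cfg: SimConfig, n_cols: int) -> np.ndarray:
    rng = _root_rng(cfg.seed)
    log_s = rng.normal(0.0, cfg.size_factor_spread, size=n_cols)
    log_s -= log_s.mean()  # geometric mean 1
    return np.exp(log_s)


def _draw_magnitude(rng: np.random.Generator, sd: float, cfg: SimConfig) -> float:
    if cfg.fixed_effect_log2 is not None:
        return float(cfg.fixed_effect_log2)
    # zero-truncated (folded, floored) normal magnitude
    for _ in range(1000):
        x = abs(rng.normal(0.0, max(sd, 1e-12)))
        if x >= cfg.min_effect:
            return float(x)
    return float(cfg.min_effect)


def _draw_effects(rng: np.random.Generator, category: str, cfg: SimConfig) -> tuple[float, float]:
    """(cis, trans) log2 effects for one feature of the given category."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if category == "conserved":
        return 0.0, 0.0
    if category == "cis_only":
        return sign * _draw_magnitude(rng, cfg.cis_effect_sd, cfg), 0.0
    if category == "trans_only":
        return 0.0, sign * _draw_magnitude(rng, cfg.trans_effect_sd, cfg)
    if category == "compensatory":
        c = sign * _draw_magnitude(rng, cfg.cis_effect_sd, cfg)
        return c, -c
    if category == "cis_plus_trans":
        c = sign * _draw_magnitude(rng, cfg.cis_effect_sd, cfg)
        t = sign * _draw_magnitude(rng, cfg.trans_effect_sd, cfg)
        return c, t
    if category == "cis_times_trans":
        # opposite signs with |trans| = 2|cis| so the parental ratio
        # (cis + trans) is nonzero and opposite in sign to the ASE effect
        c = sign * _draw_magnitude(rng, cfg.cis_effect_sd, cfg)
        return c, -2.0 * c
    raise ValueError(f"unknown category {category!r}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mu, dtype=float)))


def _categories(cfg: SimConfig, valid: tuple[str, ...]) -> list[str]:
    names = list(cfg.category_fractions)
    unknown = set(names) - set(valid)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}; expected subset of {valid}")
    return names


# ---------------------------------------------------------------------------
# site-level generator
# ---------------------------------------------------------------------------


def _allelic_columns(n: int) -> tuple[list[str], pd.DataFrame]:
    cols, rows = [], []
    for k in range(1, n + 1):
        cols.append(f"AUS{k}")
        rows.append(("AUS", "P", "A", f"AUS{k}"))
    for k in range(1, n + 1):
        cols.append(f"TIM{k}")
        rows.append(("TIM", "P", "B", f"TIM{k}"))
    for k in range(1, n + 1):
        for allele in ("A", "B"):
            cols.append(f"HYB{k}_{allele}")
            rows.append(("HYB", "H", allele, f"HYB{k}"))
    meta = pd.DataFrame(rows, columns=["population", "type", "allele", "sample"], index=cols)
    return cols, meta


def simulate_regulatory_sites(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Allelic count matrix at fixed-difference sites plus its truth table.

    Columns: ``n_per_group`` population-1 parental samples (allele A counts),
    the same number of population-2 samples (allele B counts), and two
    columns per hybrid. Truth rows align 1:1 with matrix rows.
    """
    names = _categories(cfg, REG_CATEGORIES)
    probs = np.array([cfg.category_fractions[c] for c in names])
    n = cfg.n_per_group
    cols, meta = _allelic_columns(n)
    sf = _size_factors(cfg, len(cols))

    counts = np.empty((cfg.n_features, len(cols)), dtype=np.int64)
    truth_rows = []
    for i in range(cfg.n_features):
        rng = _feature_rng(cfg.seed, i)
        category = names[rng.choice(len(names), p=probs)]
        cis, trans = _draw_effects(rng, category, cfg)
        b = 2.0 ** (cfg.mean_log_baseline + rng.normal(0.0, cfg.baseline_log2_sd))
        mu = np.empty(len(cols))
        mu[:n] = b                                  # population 1 parentals
        mu[n:2 * n] = b * 2.0 ** (cis + trans)      # population 2 parentals
        mu[2 * n::2] = b / 2.0                      # hybrid allele A
        mu[2 * n + 1::2] = (b / 2.0) * 2.0 ** cis   # hybrid allele B
        counts[i] = _nb_draw(rng, mu * sf, cfg.dispersion)
        truth_rows.append((f"site{i:05d}", cis, trans, category))
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "true_cis", "true_trans", "true_category"]
    ).set_index("feature")
    frame = pd.DataFrame(counts, index=truth.index, columns=cols)
    return CountMatrix(frame, meta), truth


def simulate_null(cfg: SimConfig) -> CountMatrix:
    """All-conserved allelic matrix (type-I-error / calibration input)."""
    null_cfg = replace(cfg, category_fractions={"conserved": 1.0})
    matrix, _ = simulate_regulatory_sites(null_cfg)
    return matrix


# ---------------------------------------------------------------------------
# gene-level generator
# ---------------------------------------------------------------------------


def _gene_columns(n: int) -> tuple[list[str], pd.DataFrame]:
    cols, pops = [], []
    for pop in ("AUS", "TIM", "HYB"):
        for k in range(1, n + 1):
            cols.append(f"{pop}{k}")
            pops.append(pop)
    meta = pd.DataFrame({"population": pops}, index=cols)
    return cols, meta


def simulate_inheritance_genes(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Gene-level counts over 3 populations with known inheritance mode.

    Parental divergence (AUS vs TIM, log2) is drawn like a cis effect; the
    hybrid expectation follows the mode: arithmetic midpoint of the parental
    expectations (additive), the matching parent's expectation (dominant_P1 =
    AUS-like, dominant_P2 = TIM-like), or ``misexpression_offset_log2`` log2
    units above/below the parental range (over/underdominant).
    """
    names = _categories(cfg, INH_CATEGORIES)
    probs = np.array([cfg.category_fractions[c] for c in names])
    n = cfg.n_per_group
    cols, meta = _gene_columns(n)
    sf = _size_factors(cfg, len(cols))

    counts = np.empty((cfg.n_features, len(cols)), dtype=np.int64)
    truth_rows = []
    off = 2.0 ** cfg.misexpression_offset_log2
    for i in range(cfg.n_features):
        rng = _feature_rng(cfg.seed, i)
        category = names[rng.choice(len(names), p=probs)]
        b = 2.0 ** (cfg.mean_log_baseline + rng.normal(0.0, cfg.baseline_log2_sd))
        if category == "conserved":
            delta = 0.0
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            delta = sign * _draw_magnitude(rng, cfg.cis_effect_sd, cfg)
        mu_aus = b
        mu_tim = b * 2.0 ** delta
        if category in ("conserved", "additive"):
            mu_hyb = 0.5 * (mu_aus + mu_tim)
        elif category == "dominant_P1":
            mu_hyb = mu_aus
        elif category == "dominant_P2":
            mu_hyb = mu_tim
        elif category == "overdominant":
            mu_hyb = max(mu_aus, mu_tim) * off
        elif category == "underdominant":
            mu_hyb = min(mu_aus, mu_tim) / off
        else:  # pragma: no cover - guarded by _categories
            raise ValueError(category)
        mu = np.concatenate([np.full(n, mu_aus), np.full(n, mu_tim), np.full(n, mu_hyb)])
        counts[i] = _nb_draw(rng, mu * sf, cfg.dispersion)
        truth_rows.append((f"gene{i:05d}", delta, category))
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "true_parental_log2", "true_inheritance"]
    ).set_index("feature")
    frame = pd.DataFrame(counts, index=truth.index, columns=cols)
    return CountMatrix(frame, meta), truth


# ---------------------------------------------------------------------------
# minimal VCF export
# ---------------------------------------------------------------------------


def write_sim_vcf(matrix: CountMatrix, path, *, chrom: str = "chr1", spacing: int = 100) -> None:
    """Write simulated allelic sites as a minimal VCF with AD fields.

    One biallelic SNP record per matrix row (REF=A, ALT=G at evenly spaced
    positions). Parental samples are homozygous with all depth on their
    population's fixed allele; hybrids are heterozygous with the two allele
    columns as their AD pair. Round-tripping this file through the allelic
    module reproduces the matrix exactly.
    """
    meta = matrix.col_meta
    parental = meta.index[meta["type"] == "P"]
    hybrids = sorted(meta.loc[meta["type"] == "H", "sample"].unique())
    samples = list(parental) + hybrids
    h_cols = {
        (s, a): meta.index[(meta["type"] == "H") & (meta["sample"] == s) & (meta["allele"] == a)][0]
        for s in hybrids
        for a in ("A", "B")
    }
    n_sites = len(matrix.counts)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={spacing * (n_sites + 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i, (site, row) in enumerate(matrix.counts.iterrows()):
            fields = [chrom, str(spacing * (i + 1)), str(site), "A", "G", ".", "PASS", ".", "GT:AD"]
            for col in parental:
                c = int(row[col])
                if meta.loc[col, "allele"] == "A":
                    fields.append(f"0/0:{c},0")
                else:
                    fields.append(f"1/1:0,{c}")
            for s in hybrids:
                a = int(row[h_cols[(s, "A")]])
                b = int(row[h_cols[(s, "B")]])
                fields.append(f"0/1:{a},{b}")
            fh.write("\t".join(fields) + "\n")
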