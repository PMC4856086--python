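"""Contrasts and categorical classification of inheritance and regulatory mode.

Gene level: four pairwise NB Wald contrasts over the 9 libraries (population
1 vs population 2, hybrids vs pooled parentals, hybrids vs each parental
population), each BH-adjusted as its own family, then a rule-based
inheritance call per gene (additive / dominant / misexpressed / conserved /
ambiguous).

Site level: three component tests per fixed-difference site —

* parental divergence: two-group NB test on the six parental columns
  (estimates cis + trans, the net expression divergence);
* allele-specific expression (ASE): two-group NB test of allele B vs allele
  A across the hybrid columns (estimates cis, since both alleles share one
  trans environment);
* trans: NB GLM over all 12 columns with factors type (hybrid-allelic
  baseline vs parental) and allele (A baseline vs B) plus their interaction;
  the interaction coefficient is the parental log-ratio minus the hybrid
  allelic log-ratio, i.e. the trans effect.

The three significance flags plus the two effect signs then map each site to
cis_only / trans_only / cis_plus_trans / cis_times_trans / compensatory /
conserved / ambiguous. Compensatory is (parental not significant, ASE
significant, trans significant): offsetting cis and trans changes with no
net divergence.

Chromosome-scale helpers: variance-ratio F test of fold-change spread,
Pearson chi-square enrichment (no continuity correction), and an exact
binomial direction test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nbcore
from .nbcore import CountMatrix, DispersionSet, GlmError

logger = logging.getLogger(__name__)

INHERITANCE_CALLS = (
    "additive",
    "dominant_AUS",
    "dominant_TIM",
    "misexpressed_over",
    "misexpressed_under",
    "conserved",
    "ambiguous",
)
REGULATORY_CALLS = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)
CONTRASTS = ("aus_vs_tim", "hyb_vs_parental", "hyb_vs_aus", "hyb_vs_tim")

__all__ = [
    "Thresholds",
    "INHERITANCE_CALLS",
    "REGULATORY_CALLS",
    "CONTRASTS",
    "run_inheritance_contrasts",
    "classify_inheritance",
    "classify_inheritance_table",
    "site_tests",
    "test_parental_divergence",
    "test_ase",
    "test_trans",
    "classify_regulatory",
    "classify_regulatory_table",
    "variance_ratio_test",
    "enrichment_chisq",
    "direction_binomial",
]


@dataclass(frozen=True)
class Thresholds:
    """Adjusted-p cutoffs.

    ``de_alpha`` governs the gene-level parental-DE and inheritance
    contrasts; ``reg_alpha`` the three site-level regulatory tests;
    ``misexpression_alpha_relaxed`` is the secondary, less stringent cutoff
    reported alongside the headline misexpression count.
    """

    de_alpha: float = 0.05
    reg_alpha: float = 0.1
    misexpression_alpha_relaxed: float = 0.1

    def __post_init__(self) -> None:
        for name in ("de_alpha", "reg_alpha", "misexpression_alpha_relaxed"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# gene-level contrasts and inheritance classification
# ---------------------------------------------------------------------------


def _contrast_groups(populations: pd.Series) -> dict[str, tuple[np.ndarray, str]]:
    """Column masks and reference level for each of the four pairwise tests."""
    pop = populations.to_numpy()
    out = {}
    out["aus_vs_tim"] = (np.isin(pop, ["AUS", "TIM"]), "AUS")
    out["hyb_vs_parental"] = (np.isin(pop, ["AUS", "TIM", "HYB"]), "parental")
    out["hyb_vs_aus"] = (np.isin(pop, ["AUS", "HYB"]), "AUS")
    out["hyb_vs_tim"] = (np.isin(pop, ["TIM", "HYB"]), "TIM")
    return out


def run_inheritance_contrasts(
    matrix: CountMatrix,
    thresholds: Thresholds = Thresholds(),
    *,
    size_factors: pd.Series | None = None,
    dispersions: DispersionSet | None = None,
    fixed_alpha: float | None = None,
) -> dict[str, pd.DataFrame]:
    """The four pairwise NB contrasts over a 9-library gene matrix.

    Size factors are estimated once on all columns and shared; the
    per-feature dispersion is estimated once under the 3-level one-way
    design and reused by every contrast. Each contrast is BH-adjusted as a
    separate family. Returns a dict of DE-result frames keyed by contrast
    name, each with columns baseMean, log2FC, lfcSE, stat, pvalue, padj,
    status.
    """
    pops = matrix.col_meta["population"]
    for needed in ("AUS", "TIM", "HYB"):
        if needed not in set(pops):
            raise ValueError(f"population {needed!r} missing from column metadata")
    counts = matrix.counts
    if size_factors is None:
        size_factors = nbcore.estimate_size_factors(counts, fallback="positive-subset")
    if dispersions is None:
        design = pd.get_dummies(pops, drop_first=True).to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(pops)), design])
        dispersions = nbcore.estimate_dispersions(
            counts, size_factors, design, fixed_alpha=fixed_alpha
        )
    results: dict[str, pd.DataFrame] = {}
    sf_all = size_factors.to_numpy(dtype=float)
    pop_arr = pops.to_numpy()
    for name, (mask, reference) in _contrast_groups(pops).items():
        groups = pop_arr[mask].copy()
        if name == "hyb_vs_parental":
            groups = np.where(groups == "HYB", "HYB", "parental")
        rows = []
        for fid in counts.index:
            y = counts.loc[fid].to_numpy(dtype=float)[mask]
            row = nbcore.nb_two_group_test(
                y, sf_all[mask], float(dispersions.final.loc[fid]), groups, reference
            )
            row["feature"] = fid
            rows.append(row)
        frame = pd.DataFrame(rows).set_index("feature")
        frame["padj"] = nbcore.bh_adjust(frame["pvalue"].to_numpy())
        results[name] = frame
    return results


def classify_inheritance(
    sig: dict[str, bool],
    mean_aus: float,
    mean_tim: float,
    mean_hyb: float,
) -> str:
    """Inheritance call from the four contrasts' significance flags and the
    three group means.

    * conserved: no contrast significant;
    * misexpressed_over/under: hybrids differ significantly from both
      parental populations and the hybrid mean lies above/below both;
    * additive: parental populations differ, the hybrid mean is strictly
      between them, and hybrids differ from neither parent;
    * dominant_X: hybrid mean intermediate and hybrids differ from exactly
      one parent; X is the parent the hybrids do NOT differ from (whose
      expression pattern is dominant);
    * anything else: ambiguous.
    """
    missing = [k for k in CONTRASTS if k not in sig]
    if missing:
        raise KeyError(f"missing contrast flags: {missing}")
    if not any(sig[k] for k in CONTRASTS):
        return "conserved"
    lo, hi = min(mean_aus, mean_tim), max(mean_aus, mean_tim)
    if sig["hyb_vs_aus"] and sig["hyb_vs_tim"]:
        if mean_hyb > hi:
            return "misexpressed_over"
        if mean_hyb < lo:
            return "misexpressed_under"
        return "ambiguous"
    intermediate = lo < mean_hyb < hi
    if sig["aus_vs_tim"] and intermediate and not sig["hyb_vs_aus"] and not sig["hyb_vs_tim"]:
        return "additive"
    if intermediate and sig["hyb_vs_aus"] != sig["hyb_vs_tim"]:
        return "dominant_TIM" if sig["hyb_vs_aus"] else "dominant_AUS"
    return "ambiguous"


def classify_inheritance_table(
    contrasts: dict[str, pd.DataFrame],
    matrix: CountMatrix,
    thresholds: Thresholds = Thresholds(),
    *,
    size_factors: pd.Series | None = None,
    restrict_to_de: bool = False,
) -> pd.DataFrame:
    """Per-gene inheritance calls for every gene tested in all four families.

    ``restrict_to_de`` limits classification to genes significant in the
    parental (AUS vs TIM) contrast, reporting all others unclassified.
    """
    if size_factors is None:
        size_factors = nbcore.estimate_size_factors(matrix.counts, fallback="positive-subset")
    norm = nbcore.normalize_counts(matrix.counts, size_factors)
    pops = matrix.col_meta["population"]
    means = {p: norm.loc[:, pops[pops == p].index].mean(axis=1) for p in ("AUS", "TIM", "HYB")}
    rows = []
    for fid in matrix.feature_ids:
        flags, failed = {}, False
        for name in CONTRASTS:
            res = contrasts[name].loc[fid]
            if res["status"] != "tested" or not np.isfinite(res["padj"]):
                failed = True
                break
            flags[name] = bool(res["padj"] < thresholds.de_alpha)
        if failed:
            call = "ambiguous"
            flags = {k: False for k in CONTRASTS}
        elif restrict_to_de and not flags["aus_vs_tim"]:
            call = "unclassified"
        else:
            call = classify_inheritance(
                flags, means["AUS"].loc[fid], means["TIM"].loc[fid], means["HYB"].loc[fid]
            )
        rows.append(
            {
                "feature": fid,
                "call": call,
                "mean_AUS": means["AUS"].loc[fid],
                "mean_TIM": means["TIM"].loc[fid],
                "mean_HYB": means["HYB"].loc[fid],
                **{f"sig_{k}": flags[k] for k in CONTRASTS},
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# site-level component tests
# ---------------------------------------------------------------------------


def _allelic_meta_checks(meta: pd.DataFrame) -> None:
    for col in ("type", "allele"):
        if col not in meta:
            raise ValueError("allelic matrix metadata requires 'type' and 'allele' columns")


def test_parental_divergence(
    y: np.ndarray, size_factors: np.ndarray, alpha: float, meta: pd.DataFrame
) -> dict:
    """Two-group NB Wald test between parental populations on one site row.

    log2FC is population 2 over population 1 (allele B carriers over allele A
    carriers) and estimates cis + trans.
    """
    _allelic_meta_checks(meta)
    mask = (meta["type"] == "P").to_numpy()
    groups = meta["allele"].to_numpy()[mask]
    return nbcore.nb_two_group_test(
        np.asarray(y, dtype=float)[mask], np.asarray(size_factors)[mask], alpha, groups, "A"
    )


def test_ase(
    y: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
    meta: pd.DataFrame,
    *,
    paired: bool = False,
) -> dict:
    """Allele-B vs allele-A NB Wald test across hybrid columns (cis evidence).

    Unpaired by default: the two alleles of one hybrid enter as separate
    observations, mirroring a plain two-group contrast. ``paired=True`` adds
    per-hybrid blocking covariates so the allele effect is estimated within
    birds.
    """
    _allelic_meta_checks(meta)
    mask = (meta["type"] == "H").to_numpy()
    groups = meta["allele"].to_numpy()[mask]
    y = np.asarray(y, dtype=float)[mask]
    sf = np.asarray(size_factors)[mask]
    if not paired:
        return nbcore.nb_two_group_test(y, sf, alpha, groups, "A")
    samples = meta["sample"].to_numpy()[mask]
    levels = pd.unique(samples)
    blocks = np.column_stack([(samples == s).astype(float) for s in levels[1:]])
    X = np.column_stack([np.ones(len(y)), blocks, (groups == "B").astype(float)])
    names = ["intercept", *[f"sample_{s}" for s in levels[1:]], "B_vs_A"]
    base_mean = float(np.mean(y / sf))
    try:
        fit = nbcore.fit_nb_glm(y, sf, alpha, X, names)
        l2fc, se, z, p = nbcore.wald_test(fit, "B_vs_A")
        return {"baseMean": base_mean, "log2FC": l2fc, "lfcSE": se, "stat": z,
                "pvalue": p, "status": "tested"}
    except GlmError:
        return {"baseMean": base_mean, "log2FC": np.nan, "lfcSE": np.nan,
                "stat": np.nan, "pvalue": np.nan, "status": "failed"}


def _trans_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    is_p = (meta["type"] == "P").to_numpy(dtype=float)
    is_b = (meta["allele"] == "B").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(meta)), is_p, is_b, is_p * is_b])
    return X, ["intercept", "typeP", "alleleB", "typeP:alleleB"]


def test_trans(
    y: np.ndarray, size_factors: np.ndarray, alpha: float, meta: pd.DataFrame
) -> dict:
    """Interaction test over all 12 columns: is the parental expression ratio
    equal to the hybrid allelic ratio?

    Factors: type (hybrid-allelic baseline, parental) and allele (A baseline,
    B); parental columns carry allele A for population-1 samples and allele B
    for population-2 samples. The interaction coefficient's log2 estimate is
    the trans effect (parental log-ratio minus hybrid allelic log-ratio).
    """
    _allelic_meta_checks(meta)
    y = np.asarray(y, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    base_mean = float(np.mean(y / sf))
    X, names = _trans_design(meta)
    try:
        fit = nbcore.fit_nb_glm(y, sf, alpha, X, names)
        l2fc, se, z, p = nbcore.wald_test(fit, "typeP:alleleB")
        return {"baseMean": base_mean, "log2FC": l2fc, "lfcSE": se, "stat": z,
                "pvalue": p, "status": "tested"}
    except GlmError:
        return {"baseMean": base_mean, "log2FC": np.nan, "lfcSE": np.nan, "stat": np.nan,
                "pvalue": np.nan, "status": "failed"}


def site_tests(
    matrix: CountMatrix,
    *,
    size_factors: pd.Series | None = None,
    dispersions: DispersionSet | None = None,
    fixed_alpha: float | None = None,
) -> pd.DataFrame:
    """Run all three component tests on every site of an allelic matrix.

    Normalization is joint over the 12 columns; one dispersion per site is
    estimated under the type*allele design and shared by the three tests
    (which keeps the trans interaction estimate algebraically equal to the
    parental minus ASE log2 effects). Each test family is BH-adjusted
    separately. Returns a frame with ``<test>_{log2FC,pvalue,padj,status}``
    columns for test in parental / ase / trans.
    """
    meta = matrix.col_meta
    _allelic_meta_checks(meta)
    counts = matrix.counts
    if size_factors is None:
        size_factors = nbcore.estimate_size_factors(counts, fallback="positive-subset")
    if dispersions is None:
        X, _ = _trans_design(meta)
        dispersions = nbcore.estimate_dispersions(
            counts, size_factors, X, fixed_alpha=fixed_alpha
        )
    sf = size_factors.to_numpy(dtype=float)
    rows = []
    for fid in counts.index:
        y = counts.loc[fid].to_numpy(dtype=float)
        alpha = float(dispersions.final.loc[fid])
        row: dict = {"feature": fid}
        for name, func in (
            ("parental", test_parental_divergence),
            ("ase", test_ase),
            ("trans", test_trans),
        ):
            res = func(y, sf, alpha, meta)
            for key in ("baseMean", "log2FC", "lfcSE", "stat", "pvalue", "status"):
                row[f"{name}_{key}"] = res[key]
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("feature")
    for name in ("parental", "ase", "trans"):
        frame[f"{name}_padj"] = nbcore.bh_adjust(frame[f"{name}_pvalue"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# regulatory-mode classification
# ---------------------------------------------------------------------------


def classify_regulatory(
    parental_sig: bool,
    ase_sig: bool,
    trans_sig: bool,
    parental_log2fc: float = 0.0,
    ase_log2fc: float = 0.0,
    *,
    failed: bool = False,
) -> str:
    """Regulatory-mode call from the three significance flags and effect signs.

    (parental, ASE, trans) = (Y,Y,N) cis_only; (Y,N,Y) trans_only; (Y,Y,Y)
    cis_plus_trans when parental and ASE effects share a sign, else
    cis_times_trans; (N,Y,Y) compensatory; (N,N,N) conserved; every other
    triple, and any failed component test, is ambiguous.
    """
    if failed:
        return "ambiguous"
    triple = (parental_sig, ase_sig, trans_sig)
    if triple == (True, True, False):
        return "cis_only"
    if triple == (True, False, True):
        return "trans_only"
    if triple == (True, True, True):
        same = np.sign(parental_log2fc) == np.sign(ase_log2fc)
        return "cis_plus_trans" if same else "cis_times_trans"
    if triple == (False, True, True):
        return "compensatory"
    if triple == (False, False, False):
        return "conserved"
    return "ambiguous"


def classify_regulatory_table(
    tests: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.Series:
    """Vectorised classification of a :func:`site_tests` result frame."""
    calls = []
    for fid, row in tests.iterrows():
        failed = any(row[f"{t}_status"] != "tested" for t in ("parental", "ase", "trans"))
        if failed:
            calls.append("ambiguous")
            continue
        calls.append(
            classify_regulatory(
                bool(row["parental_padj"] < thresholds.reg_alpha),
                bool(row["ase_padj"] < thresholds.reg_alpha),
                bool(row["trans_padj"] < thresholds.reg_alpha),
                row["parental_log2FC"],
                row["ase_log2FC"],
            )
        )
    return pd.Series(calls, index=tests.index, name="call")


# ---------------------------------------------------------------------------
# chromosome-scale helpers
# ---------------------------------------------------------------------------


def variance_ratio_test(values1, values2) -> tuple[float, float]:
    """Two-sided F test of equal fold-change variance between feature sets."""
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each set needs >= 2 finite values")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v2 == 0:
        raise ValueError("zero variance in the second set")
    F = v1 / v2
    df1, df2 = len(x1) - 1, len(x2) - 1
    cdf = stats.f.cdf(F, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(F), float(min(p, 1.0))


def enrichment_chisq(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def direction_binomial(k: int, n: int, p0: float = 0.5) -> tuple[float, float]:
    """Exact binomial direction test; returns (one_sided, two_sided) p-values.

    One-sided is the upper tail P(X >= k); two-sided sums the probabilities
    of all outcomes no more likely than the observed one.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    one_sided = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    two_sided = float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    return one_sided, two_sided
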