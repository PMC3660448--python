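"""Multi-variant burden tests: CMC collapsing, weighted-sum, C-alpha.

All three tests compare hyper-aggregator cases with hypo-aggregator
controls over a set of variants (typically the exonic variants of a gene),
optionally restricted to rare variants.

* CMC collapses the set to a per-subject carrier indicator (any minor
  allele at any set variant) and applies a 1-df Pearson chi-square to the
  carrier x group table, falling back to Fisher's exact test when an
  expected cell is below 5.
* The weighted-sum (WS) test scores each subject by the sum of dosages
  weighted inversely to the control-estimated allele frequency
  (Madsen-Browning construction) and compares the case rank-sum with a
  permutation null; weights are re-estimated from the permuted controls in
  every permutation.
* The C-alpha test asks whether the case/control split of minor-allele
  copies is over-dispersed across variants relative to binomial sampling,
  which keeps power when variant effects point in opposite directions.

Missing genotypes inside a burden set count as dosage 0 (non-carrier) so
that per-subject scores stay comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from extremevar.errors import AssociationError
from extremevar.single_tests import AssociationResult
from extremevar.variant_io import GenotypeMatrix, filter_by_class, maf_vector


@dataclass
class BurdenConfig:
    """Configuration shared by the burden tests."""

    rarity_filter: str = "rare_only"  # 'rare_only' | 'all'
    maf_threshold: float = 0.05
    n_permutations: int = 2000
    rng_seed: int | None = None

    def __post_init__(self):
        if self.rarity_filter not in ("rare_only", "all"):
            raise ValueError("rarity_filter must be 'rare_only' or 'all'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def _zero_filled(gm: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix with missing calls as 0 (non-carrier convention)."""
    dose = np.asarray(gm.dosage, dtype=float).copy()
    dose[gm.missing] = 0.0
    return dose


def collapse_carriers(gm: GenotypeMatrix) -> np.ndarray:
    """Per-subject indicator: carries >=1 minor allele at >=1 set variant."""
    if gm.n_variants == 0:
        raise AssociationError("variant set is empty")
    return (_zero_filled(gm) > 0).any(axis=1).astype(np.int8)


def _perm_case_masks(n: int, n_cases: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B random case assignments of fixed size, as a (B, n) boolean array."""
    u = rng.random((B, n))
    order = np.argsort(u, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(B)[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return ranks < n_cases


def cmc_test(gm: GenotypeMatrix, hyper_mask, config: BurdenConfig | None = None,
             set_id: str = "set", stratum: str = "") -> AssociationResult:
    """Combined multivariate collapsing test on rare variants.

    1-df Pearson chi-square (no continuity correction) on the 2x2 carrier x
    group table; Fisher's exact fallback when any expected cell is < 5.
    """
    config = config or BurdenConfig()
    gm = _apply_rarity(gm, config)
    hyper = np.asarray(hyper_mask, dtype=bool)
    carrier = collapse_carriers(gm)
    a = int(carrier[hyper].sum())          # carriers among hyper
    b = int(carrier[~hyper].sum())         # carriers among hypo
    c = int(hyper.sum()) - a
    d = int((~hyper).sum()) - b
    table = np.array([[a, b], [c, d]], dtype=float)
    rate_diff = a / max(hyper.sum(), 1) - b / max((~hyper).sum(), 1)
    direction = "+" if rate_diff > 0 else "-" if rate_diff < 0 else "0"
    if carrier.sum() == 0 or carrier.sum() == carrier.size:
        return AssociationResult(set_id, "cmc", 0.0, 1.0, "0", gm.n_variants, stratum,
                                 note="degenerate carrier table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 5:
        p = float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])
        return AssociationResult(set_id, "cmc", math.nan, p, direction, gm.n_variants,
                                 stratum, note="fisher fallback")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(set_id, "cmc", float(chi2), float(p), direction,
                             gm.n_variants, stratum)


def _ws_rank_sum(dose: np.ndarray, case_mask: np.ndarray) -> float:
    """Observed weighted-sum case rank-sum statistic x."""
    ctrl = ~case_mask
    n_ctrl = int(ctrl.sum())
    m_ctrl = dose[ctrl].sum(axis=0)
    q = (m_ctrl + 1.0) / (2.0 * n_ctrl + 2.0)
    n_total = dose.shape[0]
    w = np.sqrt(n_total * q * (1.0 - q))
    gamma = dose @ (1.0 / w)
    ranks = stats.rankdata(gamma, method="average")
    return float(ranks[case_mask].sum())


def ws_test(gm: GenotypeMatrix, hyper_mask, config: BurdenConfig | None = None,
            set_id: str = "set", stratum: str = "") -> AssociationResult:
    """Weighted-sum rank test with a permutation null.

    Per variant j, the control allele frequency with pseudocount is
    q_j = (m_j + 1) / (2 n_ctrl + 2); the weight is
    w_j = sqrt(n q_j (1 - q_j)) over the n scored subjects.  Each subject's
    genetic score is gamma_i = sum_j dosage_ij / w_j and the statistic is
    the rank-sum (midranks for ties) of the case subjects.  The one-sided
    permutation p is (#{x_perm >= x_obs} + 1) / (B + 1); weights and q are
    re-estimated from each permuted control group.
    """
    config = config or BurdenConfig()
    gm = _apply_rarity(gm, config)
    if gm.n_variants == 0:
        raise AssociationError("variant set empty after rarity filtering")
    case = np.asarray(hyper_mask, dtype=bool)
    n = case.size
    n_cases = int(case.sum())
    if n_cases == 0 or n_cases == n:
        raise AssociationError("both groups must be non-empty")
    dose = _zero_filled(gm)
    x_obs = _ws_rank_sum(dose, case)

    B = config.n_permutations
    rng = config.rng()
    perm_case = _perm_case_masks(n, n_cases, B, rng)          # (B, n)
    perm_ctrl_counts = (~perm_case).sum(axis=1)               # all == n - n_cases
    m_ctrl = dose.T @ (~perm_case).T.astype(float)            # (m, B)
    q = (m_ctrl + 1.0) / (2.0 * perm_ctrl_counts[None, :] + 2.0)
    w = np.sqrt(n * q * (1.0 - q))                            # (m, B)
    gamma = dose @ (1.0 / w)                                  # (n, B)
    ranks = stats.rankdata(gamma, method="average", axis=0)   # (n, B)
    x_perm = (ranks * perm_case.T).sum(axis=0)                # (B,)

    k = int((x_perm >= x_obs - 1e-9).sum())
    p = (k + 1.0) / (B + 1.0)
    mean, sd = float(x_perm.mean()), float(x_perm.std(ddof=1))
    z = (x_obs - mean) / sd if sd > 0 else 0.0
    direction = "+" if x_obs > mean else "-" if x_obs < mean else "0"
    return AssociationResult(set_id, "ws", z, p, direction, gm.n_variants, stratum)


def c_alpha_components(dose: np.ndarray, case_mask: np.ndarray) -> tuple[float, float, float]:
    """(T, c, p0) for the C-alpha dispersion statistic.

    p0 is the case fraction of subjects; per variant i with n_i total minor
    copies and y_i copies in cases,
    ``T = sum_i [(y_i - n_i p0)^2 - n_i p0 (1 - p0)]`` and c is the exact
    binomial variance of T under the null.
    """
    case = np.asarray(case_mask, dtype=bool)
    p0 = case.sum() / case.size
    n_i = dose.sum(axis=0)
    y_i = dose[case].sum(axis=0)
    keep = n_i >= 1
    n_i, y_i = n_i[keep], y_i[keep]
    T = float((((y_i - n_i * p0) ** 2) - n_i * p0 * (1 - p0)).sum())
    c = 0.0
    q0 = 1 - p0
    for ni in n_i:
        u = np.arange(int(ni) + 1)
        pmf = stats.binom.pmf(u, int(ni), p0)
        term = (u - ni * p0) ** 2 - ni * p0 * q0
        c += float((pmf * term**2).sum())
    return T, c, p0


def c_alpha_test(gm: GenotypeMatrix, hyper_mask, config: BurdenConfig | None = None,
                 set_id: str = "set", stratum: str = "") -> AssociationResult:
    """C-alpha dispersion test: one-sided analytic z plus a permutation p.

    When the analytic variance c degenerates to 0 only the permutation p is
    reported.  The permutation scheme matches :func:`ws_test` (fixed group
    sizes, seeded generator); the permutation p is stored in the note field
    as ``perm_p=<value>`` alongside the analytic p-value.
    """
    config = config or BurdenConfig()
    gm = _apply_rarity(gm, config)
    if gm.n_variants == 0:
        raise AssociationError("variant set empty after rarity filtering")
    case = np.asarray(hyper_mask, dtype=bool)
    if case.sum() == 0 or case.sum() == case.size:
        raise AssociationError("both groups must be non-empty")
    dose = _zero_filled(gm)
    if dose.sum() == 0:
        raise AssociationError("no minor alleles observed in the set")
    T, c, p0 = c_alpha_components(dose, case)

    B = config.n_permutations
    rng = config.rng()
    perm_case = _perm_case_masks(case.size, int(case.sum()), B, rng)  # (B, n)
    n_i = dose.sum(axis=0)
    y_perm = dose.T @ perm_case.T.astype(float)                       # (m, B)
    centered = (y_perm - n_i[:, None] * p0) ** 2 - (n_i * p0 * (1 - p0))[:, None]
    T_perm = centered.sum(axis=0)
    k = int((T_perm >= T - 1e-9).sum())
    perm_p = (k + 1.0) / (B + 1.0)

    direction = "+" if T > 0 else "-" if T < 0 else "0"
    if c > 0:
        z = T / math.sqrt(c)
        p = float(stats.norm.sf(z))
        return AssociationResult(set_id, "calpha", z, p, direction, gm.n_variants,
                                 stratum, note=f"perm_p={perm_p:.6g}")
    return AssociationResult(set_id, "calpha", math.nan, perm_p, direction,
                             gm.n_variants, stratum, note="permutation only (c=0)")


def _apply_rarity(gm: GenotypeMatrix, config: BurdenConfig) -> GenotypeMatrix:
    if config.rarity_filter == "all":
        return gm
    mafs = maf_vector(gm)
    keep = np.isfinite(mafs) & (mafs > 0) & (mafs < config.maf_threshold)
    if not keep.any():
        raise AssociationError("no rare polymorphic variants in the set")
    return gm.subset_variants(keep)


CLASS_GRID = (
    ("missense_synonymous", ("missense", "synonymous")),
    ("missense", ("missense",)),
    ("synonymous", ("synonymous",)),
)

METHOD_GRID = (
    ("cmc", "rare_only"),
    ("ws", "rare_only"),
    ("ws", "all"),
)


def burden_suite(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame,
    hyper_mask,
    stratum: str = "",
    maf_threshold: float = 0.05,
    n_permutations: int = 2000,
    rng_seed: int | None = None,
    include_calpha: bool = False,
) -> pd.DataFrame:
    """Burden-test grid: functional classes x (CMC rare, WS rare, WS all).

    ``gm`` must be the stratum view restricted to the analysis subjects.
    Polymorphic variants only; cells that end up empty are reported as
    "no test" rows with NaN p.  Setting ``include_calpha`` appends a
    C-alpha row per class over all polymorphic variants of the class.
    """
    rows = []
    mafs = maf_vector(gm)
    poly = np.isfinite(mafs) & (mafs > 0)
    method_grid = METHOD_GRID + (("calpha", "all"),) if include_calpha else METHOD_GRID
    for class_name, classes in CLASS_GRID:
        ann_sub = filter_by_class(annotations, classes)
        in_class = np.isin(gm.variant_ids, ann_sub["variant_id"].to_numpy())
        for method, rarity in method_grid:
            keep = in_class & poly
            if rarity == "rare_only":
                keep &= mafs < maf_threshold
            base = {
                "stratum": stratum,
                "classes": class_name,
                "method": method,
                "rarity": "rare" if rarity == "rare_only" else "all",
                "n_variants": int(keep.sum()),
            }
            if not keep.any():
                rows.append({**base, "statistic": np.nan, "p_value": np.nan,
                             "direction": "0", "note": "no test"})
                continue
            sub = gm.subset_variants(keep)
            cfg = BurdenConfig(rarity_filter="all", maf_threshold=maf_threshold,
                               n_permutations=n_permutations, rng_seed=rng_seed)
            fn = {"cmc": cmc_test, "ws": ws_test, "calpha": c_alpha_test}[method]
            res = fn(sub, hyper_mask, cfg, set_id=class_name, stratum=stratum)
            rows.append({**base, "statistic": res.statistic, "p_value": res.p_value,
                         "direction": res.direction, "note": res.note})
    return pd.DataFrame(rows)
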