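"""Per-variant association tests for the extreme-phenotype design.

Rare variants (within-stratum MAF below the threshold) are tested with a
two-sided Fisher exact test on the 2x2 allele-count table (minor/major x
hyper/hypo); common variants with a logistic regression of group on
minor-allele dosage under an additive model.  No covariates enter the
models: phenotypes were adjusted before the extremes were selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from extremevar.errors import AssociationError
from extremevar.variant_io import GenotypeMatrix, classify_rarity, maf_vector


@dataclass(frozen=True)
class AlleleTable2x2:
    """Allele counts split by group: rows minor/major, columns hyper/hypo."""

    minor_hyper: int
    minor_hypo: int
    major_hyper: int
    major_hypo: int

    def __post_init__(self):
        for v in (self.minor_hyper, self.minor_hypo, self.major_hyper, self.major_hypo):
            if v < 0:
                raise ValueError("allele counts must be non-negative")

    @property
    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.minor_hyper, self.minor_hypo], [self.major_hyper, self.major_hypo]],
            dtype=np.int64,
        )


@dataclass
class AssociationResult:
    """One association test outcome (single variant or burden set)."""

    id: str
    method: str  # fisher | logistic | cmc | ws | calpha | none
    statistic: float
    p_value: float
    direction: str  # '+', '-', or '0'
    n_variants: int
    stratum: str
    maf: float = float("nan")
    note: str = ""

    def signed_neglog10(self) -> float:
        return signed_neglog10(self.p_value, self.direction)


def fisher_exact_two_sided(table: AlleleTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 allele table.

    The two-sided p is the sum of hypergeometric point probabilities, over
    all tables with the observed margins, that do not exceed the observed
    table's probability.  A table with no minor alleles at all is
    monomorphic: p = 1 by convention.
    """
    if table.minor_hyper + table.minor_hypo == 0:
        return 1.0
    if table.minor_hyper + table.major_hyper == 0 or table.minor_hypo + table.major_hypo == 0:
        raise AssociationError("empty group: both group margins must be positive")
    return float(stats.fisher_exact(table.as_array, alternative="two-sided")[1])


def fisher_direction(table: AlleleTable2x2) -> str:
    """'+' if the minor allele is enriched in hyper, '-' if in hypo."""
    n_hyper = table.minor_hyper + table.major_hyper
    n_hypo = table.minor_hypo + table.major_hypo
    diff = table.minor_hyper / n_hyper - table.minor_hypo / n_hypo
    if diff > 0:
        return "+"
    if diff < 0:
        return "-"
    return "0"


def logistic_additive(dosage_vector, group_labels) -> tuple[float, float, bool]:
    """Additive-model logistic regression of group on minor-allele dosage.

    Parameters
    ----------
    dosage_vector : minor-allele counts (0,1,2) per subject.
    group_labels : boolean or {0,1}; 1/True = hyper.

    Returns
    -------
    (beta, p_value, converged).  On complete separation or non-convergence
    the result is flagged: ``converged`` is False and p is NaN, never
    fabricated.
    """
    x = np.asarray(dosage_vector, dtype=float)
    y = np.asarray(group_labels, dtype=float)
    if x.size != y.size:
        raise ValueError("dosage and label lengths differ")
    if y.sum() == 0 or y.sum() == y.size:
        raise AssociationError("both groups must be non-empty")
    if np.ptp(x) == 0:
        raise AssociationError("dosage has no variation")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return math.nan, math.nan, False
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    converged = bool(fit.mle_retvals.get("converged", False)) and se < 50 and abs(beta) < 25
    if not converged:
        return beta, math.nan, False
    return beta, float(fit.pvalues[1]), True


def allele_table(dosage_col, missing_col, hyper_mask) -> AlleleTable2x2:
    """Build the 2x2 allele-count table for one variant (complete-case)."""
    dose = np.asarray(dosage_col)
    obs = ~np.asarray(missing_col, dtype=bool)
    hyper = np.asarray(hyper_mask, dtype=bool)
    mh = int(dose[obs & hyper].sum())
    mo = int(dose[obs & ~hyper].sum())
    nh = int((obs & hyper).sum())
    no = int((obs & ~hyper).sum())
    return AlleleTable2x2(mh, mo, 2 * nh - mh, 2 * no - mo)


def single_variant_scan(
    gm: GenotypeMatrix,
    hyper_mask,
    stratum: str = "",
    maf_threshold: float = 0.05,
) -> list[AssociationResult]:
    """Per-variant scan dispatching on rarity class.

    ``gm`` must already be restricted to the analysis subjects of one
    stratum and minor-allele coded within it (see
    :meth:`GenotypeMatrix.stratum_view`).  Variants monomorphic among the
    non-missing calls yield a ``none`` result with NaN p (no test).
    """
    hyper = np.asarray(hyper_mask, dtype=bool)
    mafs = maf_vector(gm)
    results: list[AssociationResult] = []
    for j, vid in enumerate(gm.variant_ids):
        maf = float(mafs[j])
        if not np.isfinite(maf) or maf == 0.0:
            results.append(
                AssociationResult(vid, "none", math.nan, math.nan, "0", 1, stratum, maf,
                                  note="monomorphic" if maf == 0 else "all missing")
            )
            continue
        table = allele_table(gm.dosage[:, j], gm.missing[:, j], hyper)
        direction = fisher_direction(table)
        if classify_rarity(maf, maf_threshold) == "rare":
            p = fisher_exact_two_sided(table)
            odds = math.nan
            results.append(
                AssociationResult(vid, "fisher", odds, p, direction, 1, stratum, maf)
            )
        else:
            obs = ~gm.missing[:, j]
            try:
                beta, p, converged = logistic_additive(gm.dosage[obs, j], hyper[obs])
            except AssociationError:
                results.append(
                    AssociationResult(vid, "none", math.nan, math.nan, "0", 1, stratum, maf,
                                      note="degenerate")
                )
                continue
            d = "+" if beta > 0 else "-" if beta < 0 else "0"
            note = "" if converged else "not converged"
            results.append(
                AssociationResult(vid, "logistic", beta, p, d, 1, stratum, maf, note=note)
            )
    return results


def signed_neglog10(p_value: float, direction: str) -> float:
    """Signed -log10(p): '+' for risk (enrichment in hyper), '-' for
    protective; a '0' direction maps to +."""
    if not p_value > 0:
        raise ValueError("p-value must be positive")
    mag = -math.log10(p_value)
    return -mag if direction == "-" else mag


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m over m tests (exact value)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def display_threshold(threshold: float) -> str:
    """Display convention: round to one significant figure (0.05/235 shows
    as 0.0002)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    rounded = round(threshold, -exponent)
    return f"{rounded:.{max(0, -exponent)}f}" if exponent >= -6 else f"{rounded:.0e}"


def scan_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "variant_id": r.id,
                "stratum": r.stratum,
                "method": r.method,
                "maf": r.maf,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
                "signed_neglog10_p": (
                    r.signed_neglog10() if np.isfinite(r.p_value) and r.p_value > 0 else np.nan
                ),
                "n_variants": r.n_variants,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
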