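"""Synthetic two-stratum resequencing cohort generator.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage is testable without access-restricted genotype data:

* a ~235-variant panel over a single gene region with exonic position
  clusters, functional classes, novelty flags, and stratum-specific allele
  frequency spectra (substantially more rare variants segregating in one
  ancestry stratum than the other);
* block-structured LD, generated by a Gaussian-copula haplotype model with
  AR(1) within-block latent correlation;
* three correlated agonist phenotypes (percent aggregation, 0-100) driven
  by a designated common intronic variant, an exonic (synonymous) burden
  effect in one stratum, clinical covariates, and Gaussian noise;
* missing genotype calls, completely at random, at a configurable mean
  rate (default 8.6%).

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from extremevar.variant_io import GenotypeMatrix, variant_key

STRATA = ("AA", "EA")

# Functional-class counts of the 235-variant panel (exonic classes sized
# like a single-gene resequencing panel; the rest non-coding).
CLASS_COUNTS = {
    "missense": 16,
    "synonymous": 14,
    "utr5": 6,
    "utr3": 10,
    "intergenic": 48,
    "intronic": 141,
}

REGION_START = 156_860_000
REGION_END = 156_892_000

_COV_NAMES = ("age", "sex", "diabetes", "hypertension", "bmi", "ldl", "smoking", "fibrinogen")
# sampling distribution (mean, sd) for continuous covariates, prevalence for binary
_COV_SAMPLING = {
    "age": (52.0, 13.0),
    "sex": 0.45,
    "diabetes": 0.12,
    "hypertension": 0.35,
    "bmi": (29.0, 5.5),
    "ldl": (125.0, 32.0),
    "smoking": 0.18,
    "fibrinogen": (330.0, 65.0),
}
# effect of each standardized covariate on the shared aggregation factor
_COV_EFFECTS = {
    "age": 0.15, "sex": -0.10, "diabetes": 0.20, "hypertension": 0.15,
    "bmi": 0.10, "ldl": 0.10, "smoking": 0.20, "fibrinogen": 0.15,
}


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions.

    ``n_subjects`` is the base cohort per stratum *before* extreme
    selection; with agonist correlation 0.8 and quartile selection on all
    three phenotypes, the defaults yield a selected cohort of roughly 104
    subjects.  ``variance_explained_index`` sets the share of adjusted
    phenotype variance carried by the designated common intronic variant
    per stratum (0.39 / 0.16); ``variance_explained_burden`` the share
    carried by the synonymous burden set (present in EA only).
    """

    n_subjects: dict = field(default_factory=lambda: {"AA": 190, "EA": 195})
    n_haplotypes: dict = field(default_factory=lambda: {"AA": 700, "EA": 700})
    n_variants: int = 235
    # non-coding rare-spectrum composition (counts of panel variants)
    n_rare_aa_only: int = 98
    n_rare_ea_only: int = 29
    n_rare_shared: int = 18
    rare_maf_range: tuple = (0.01, 0.04)
    common_maf_range: tuple = (0.08, 0.45)
    # LD structure
    block_size_mean: float = 10.0
    block_rho_range: tuple = (0.40, 0.95)
    exon_block_rho: float = 0.98
    # effect model
    variance_explained_index: dict = field(default_factory=lambda: {"AA": 0.39, "EA": 0.16})
    variance_explained_burden: dict = field(default_factory=lambda: {"AA": 0.0, "EA": 0.10})
    agonist_correlation: float = 0.8
    # missingness
    missing_rate: float = 0.086
    rng_seed: int = 0

    def __post_init__(self):
        for p in (self.missing_rate, self.agonist_correlation):
            if not 0 <= p < 1:
                raise ValueError("probabilities must lie in [0, 1)")


@dataclass
class VariantPanel:
    """Panel of variants with per-stratum target MAFs and LD blocks."""

    annotations: pd.DataFrame          # chrom,pos,rsid,ref,alt,func_class,novel,prediction
    target_maf: dict                   # stratum -> array of target MAFs
    blocks: list                       # list of index arrays
    block_rho: np.ndarray              # AR(1) rho per block
    index_variant: str                 # designated common intronic variant id
    burden_set: list                   # designated synonymous burden variant ids


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix          # full base cohort, dosage = derived-allele count
    cohort: pd.DataFrame               # covariates + phenotypes (+ subject_id, stratum)
    annotations: pd.DataFrame
    panel: VariantPanel


def _spawn(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


def build_panel(config: SimConfig) -> VariantPanel:
    """Lay out the variant panel: positions, classes, target MAF spectra,
    LD blocks, and the designated causal variants."""
    rng = _spawn(config.rng_seed, 0)
    counts = dict(CLASS_COUNTS)
    total = sum(counts.values())
    if config.n_variants != total:
        # scale the intronic bulk to hit the requested panel size
        counts["intronic"] += config.n_variants - total

    # exons: 12 clusters of coding/UTR positions; non-coding fills the rest
    exonic_classes = [c for c in ("utr5", "missense", "synonymous", "utr3")
                      for _ in range(counts[c])]
    rng.shuffle(exonic_classes)
    n_exonic = len(exonic_classes)
    exon_centers = np.linspace(REGION_START + 3000, REGION_END - 3000, 12)
    exon_pos = np.sort(
        np.concatenate([
            int(c) + rng.integers(-400, 400, size=len(chunk))
            for c, chunk in zip(exon_centers, np.array_split(np.arange(n_exonic), 12))
        ])
    ).astype(np.int64)
    n_noncoding = config.n_variants - n_exonic
    noncoding_pos = np.sort(rng.choice(
        np.arange(REGION_START, REGION_END), size=n_noncoding, replace=False))
    noncoding_classes = (["intergenic"] * counts["intergenic"]
                         + ["intronic"] * (n_noncoding - counts["intergenic"]))
    rng.shuffle(noncoding_classes)

    pos = np.concatenate([exon_pos, noncoding_pos])
    func = np.array(exonic_classes + noncoding_classes, dtype=object)
    order = np.argsort(pos, kind="stable")
    pos, func = pos[order], func[order]
    # de-duplicate positions deterministically
    while len(np.unique(pos)) < len(pos):
        dup = pd.Series(pos).duplicated().to_numpy()
        pos[dup] += 1
        order = np.argsort(pos, kind="stable")
        pos, func = pos[order], func[order]

    m = config.n_variants
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref])

    # per-stratum target MAFs
    maf = {s: np.zeros(m) for s in STRATA}
    is_exonic = np.isin(func, ["missense", "synonymous", "utr5", "utr3"])
    noncoding_idx = np.flatnonzero(~is_exonic)
    rng.shuffle(noncoding_idx)
    lo, hi = config.rare_maf_range
    clo, chi = config.common_maf_range
    cursor = 0

    def take(k):
        nonlocal cursor
        out = noncoding_idx[cursor:cursor + k]
        cursor += k
        return out

    for j in take(config.n_rare_aa_only):
        maf["AA"][j] = rng.uniform(lo, hi)
    for j in take(config.n_rare_ea_only):
        maf["EA"][j] = rng.uniform(lo, hi)
    for j in take(config.n_rare_shared):
        maf["AA"][j] = rng.uniform(lo, hi)
        maf["EA"][j] = rng.uniform(lo, hi)
    common_idx = noncoding_idx[cursor:]
    for j in common_idx:
        base = rng.uniform(clo, chi)
        maf["AA"][j] = np.clip(base + rng.normal(0, 0.05), clo, 0.5)
        maf["EA"][j] = np.clip(base + rng.normal(0, 0.05), clo, 0.5)

    # exonic spectra: one stratum carries more polymorphic exonic variation
    syn_idx = np.flatnonzero(func == "synonymous")
    mis_idx = np.flatnonzero(func == "missense")
    utr_idx = np.flatnonzero((func == "utr3") | (func == "utr5"))
    # synonymous: 8 EA-polymorphic (6 common, 2 rare); all polymorphic in AA.
    # The common members share a narrow MAF band so that high pairwise r2
    # (hence non-trivial tagging) is attainable.
    ea_syn = np.sort(rng.choice(syn_idx, size=8, replace=False))
    for k, j in enumerate(ea_syn):
        if k < 5:
            maf["EA"][j] = rng.uniform(0.13, 0.18)
        elif k == 5:
            maf["EA"][j] = 0.245
        else:
            maf["EA"][j] = rng.uniform(0.015, 0.04)
    for j in syn_idx:
        maf["AA"][j] = (rng.uniform(0.10, 0.42) if rng.random() < 0.5
                        else rng.uniform(0.01, 0.03))
    # missense: mostly rare; EA polymorphic at about half
    for j in mis_idx:
        maf["AA"][j] = rng.uniform(0.008, 0.035) if rng.random() < 0.75 else rng.uniform(0.06, 0.27)
        if rng.random() < 0.45:
            maf["EA"][j] = (rng.uniform(0.008, 0.04) if rng.random() < 0.6
                            else rng.uniform(0.1, 0.38))
    for j in utr_idx:
        maf["AA"][j] = rng.uniform(lo, hi) if rng.random() < 0.7 else rng.uniform(clo, 0.3)
        if rng.random() < 0.5:
            maf["EA"][j] = rng.uniform(lo, hi) if rng.random() < 0.6 else rng.uniform(clo, 0.3)

    # designated common intronic index variant near the region centre
    intronic_idx = np.flatnonzero(func == "intronic")
    centre = (REGION_START + REGION_END) / 2
    index_j = int(intronic_idx[np.argmin(np.abs(pos[intronic_idx] - centre))])
    maf["AA"][index_j] = 0.35
    maf["EA"][index_j] = 0.30

    # LD blocks over consecutive panel positions; the designated synonymous
    # set forms its own tight block (long-range within-gene LD), so a
    # handful of tags can cover it
    blocks: list = []
    start = 0
    while start < m:
        size = int(np.clip(rng.geometric(1.0 / config.block_size_mean), 2, 25))
        blk = np.arange(start, min(start + size, m))
        blk = blk[~np.isin(blk, ea_syn)]
        if blk.size:
            blocks.append(blk)
        start += size
    blocks.append(ea_syn.copy())
    block_rho = rng.uniform(*config.block_rho_range, size=len(blocks))
    block_rho[-1] = config.exon_block_rho

    vid = variant_key(pd.Series(["1"] * m), pd.Series(pos)).to_numpy()
    novel = np.zeros(m, dtype=bool)
    rare_any = ((maf["AA"] > 0) & (maf["AA"] < 0.05)) | ((maf["EA"] > 0) & (maf["EA"] < 0.05))
    cand = np.flatnonzero(rare_any & (func != "synonymous"))
    novel[rng.choice(cand, size=min(61, len(cand)), replace=False)] = True
    rsid = np.where(novel, "-", [f"rs{700000 + int(p) % 10**6}{i}" for i, p in enumerate(pos)])

    prediction = np.where(
        func == "missense",
        rng.choice(["benign", "possibly damaging", "probably damaging"], size=m,
                   p=[0.5, 0.2, 0.3]),
        "-",
    )
    ann = pd.DataFrame({
        "chrom": "1", "pos": pos.astype(int), "rsid": rsid, "ref": ref, "alt": alt,
        "func_class": func, "novel": novel.astype(int), "prediction": prediction,
    })
    ann["variant_id"] = vid
    ann["novel"] = ann["novel"].astype(bool)
    return VariantPanel(
        annotations=ann,
        target_maf={s: maf[s] for s in STRATA},
        blocks=blocks,
        block_rho=block_rho,
        index_variant=vid[index_j],
        burden_set=[vid[j] for j in sorted(ea_syn)],
    )


def generate_haplotype_pool(config: SimConfig, panel: VariantPanel | None = None) -> dict:
    """Per-stratum binary haplotype matrices (n_haplotypes x n_variants).

    Within each LD block, latent Gaussians follow an AR(1) correlation and
    are thresholded at the upper ``maf`` tail, so the derived allele at
    each site has the target frequency and neighbouring sites are
    positively correlated; blocks are mutually independent.
    """
    panel = panel or build_panel(config)
    pools = {}
    for si, stratum in enumerate(STRATA):
        rng = _spawn(config.rng_seed, 1, si)
        K = config.n_haplotypes[stratum]
        m = config.n_variants
        H = np.zeros((K, m), dtype=np.int8)
        maf = panel.target_maf[stratum]
        for blk, rho in zip(panel.blocks, panel.block_rho):
            k = len(blk)
            cov = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(k))
            z = rng.standard_normal((K, k)) @ L.T
            thresh = stats.norm.ppf(1.0 - maf[blk])  # maf=0 -> +inf -> never
            H[:, blk] = (z > thresh[None, :]).astype(np.int8)
        pools[stratum] = H
    return pools


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Full base cohort: genotypes from random haplotype pairs, covariates,
    and three correlated agonist phenotypes on the percent scale.

    The latent aggregation score is
    ``L = b_g * g_index + b_burden * sum(burden dosages) + covariates + u``
    with ``b_g``/``b_burden`` chosen per stratum so the index variant and
    the burden set explain the configured shares of adjusted phenotype
    variance; each agonist phenotype adds independent noise sized so the
    inter-agonist correlation matches ``agonist_correlation``, then is
    rescaled to mean 50, sd 15 and clipped to [0, 100].
    """
    panel = build_panel(config)
    pools = generate_haplotype_pool(config, panel)
    ann = panel.annotations
    index_j = int(np.flatnonzero(ann["variant_id"] == panel.index_variant)[0])
    burden_j = np.flatnonzero(ann["variant_id"].isin(panel.burden_set))

    all_dosage, all_ids, all_strata, rows = [], [], [], []
    for si, stratum in enumerate(STRATA):
        rng = _spawn(config.rng_seed, 2, si)
        n = config.n_subjects[stratum]
        H = pools[stratum]
        pick = rng.integers(0, H.shape[0], size=(n, 2))
        dose = (H[pick[:, 0]] + H[pick[:, 1]]).astype(np.int8)
        ids = [f"{stratum}{i:04d}" for i in range(n)]

        cov = {}
        for name, spec in _COV_SAMPLING.items():
            if isinstance(spec, tuple):
                cov[name] = rng.normal(spec[0], spec[1], size=n)
            else:
                cov[name] = rng.binomial(1, spec, size=n).astype(float)
        cov_term = sum(_COV_EFFECTS[k] * _standardize(cov[k]) for k in _COV_NAMES)

        # genetic terms, scaled to the configured variance shares
        rho = config.agonist_correlation
        g_index = dose[:, index_j].astype(float)
        v_idx = config.variance_explained_index[stratum]
        g_term = np.zeros(n)
        if v_idx > 0 and g_index.std() > 0:
            g_term = np.sqrt(v_idx) * _standardize(g_index)
        g_burden = dose[:, burden_j].astype(float).sum(axis=1)
        v_bur = config.variance_explained_burden[stratum]
        b_term = np.zeros(n)
        if v_bur > 0 and g_burden.std() > 0:
            b_term = np.sqrt(v_bur) * _standardize(g_burden)
        v_shared_noise = max(rho - v_idx - v_bur, 0.02)
        shared = g_term + b_term + cov_term + rng.normal(0, np.sqrt(v_shared_noise), size=n)
        sd_pheno = np.sqrt(max(1.0 - rho, 1e-6))
        for i in range(n):
            rows.append({"subject_id": ids[i], "stratum": stratum,
                         **{k: cov[k][i] for k in _COV_NAMES}})
        phenos = {}
        for name in ("pheno_col", "pheno_epi", "pheno_adp"):
            raw = shared + rng.normal(0, sd_pheno, size=n)
            phenos[name] = np.clip(50.0 + 15.0 * _standardize(raw), 0.0, 100.0)
        for i, rid in enumerate(range(len(rows) - n, len(rows))):
            for name in phenos:
                rows[rid][name] = phenos[name][i]

        all_dosage.append(dose)
        all_ids.extend(ids)
        all_strata.extend([stratum] * n)

    dosage = np.vstack(all_dosage)
    gm = GenotypeMatrix(
        subject_ids=np.array(all_ids, dtype=object),
        variant_ids=ann["variant_id"].to_numpy(),
        dosage=dosage,
        missing=np.zeros(dosage.shape, dtype=bool),
        stratum=np.array(all_strata, dtype=object),
    )
    cohort = pd.DataFrame(rows).set_index("subject_id", drop=False)
    return SimulatedCohort(genotypes=gm, cohort=cohort, annotations=ann, panel=panel)


def apply_missingness(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask calls missing-completely-at-random at the given mean rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return gm
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    extra = rng.random(gm.dosage.shape) < rate
    missing = gm.missing | extra
    dosage = gm.dosage.copy()
    dosage[missing] = 0
    return replace(gm, dosage=dosage, missing=missing)


def write_dataset(sim: SimulatedCohort, outdir, gm: GenotypeMatrix | None = None) -> dict:
    """Write VCF + annotation + phenotype tables; returns the paths."""
    from pathlib import Path

    from extremevar.variant_io import write_genotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = gm if gm is not None else sim.genotypes
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "annotations": outdir / "annotations.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    write_genotypes(gm, sim.annotations, paths["vcf"])
    ann = sim.annotations.copy()
    ann["novel"] = ann["novel"].astype(int)
    ann.drop(columns=["variant_id"]).to_csv(paths["annotations"], sep="\t", index=False)
    keep = sim.cohort["subject_id"].isin(gm.subject_ids)
    sim.cohort.loc[keep].to_csv(paths["phenotypes"], sep="\t", index=False,
                                float_format="%.6g")
    return paths
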