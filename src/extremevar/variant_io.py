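"""Genotype and annotation I/O, allele frequencies, rarity classes.

Genotypes are held as an individuals x variants matrix of minor-allele
dosages (0, 1, 2) with an explicit missingness mask.  A VCF stores the
alternate-allele count per call; on read, any variant whose alternate
allele is the major allele in the cohort is flipped so that the coded
allele is always the minor one.  Analyses that run within an ancestry
stratum re-fold frequencies within that stratum via
:meth:`GenotypeMatrix.stratum_view`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from extremevar.errors import UndefinedFrequencyError, VCFParseError

FUNC_CLASSES = ("intronic", "intergenic", "missense", "synonymous", "utr3", "utr5")

ANNOTATION_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt", "func_class", "novel", "prediction"]


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with missingness mask and strata.

    Attributes
    ----------
    subject_ids, variant_ids : arrays of identifiers.
    dosage : int8 array, shape (n_subjects, n_variants), values in {0,1,2};
        entries under the missing mask are zeroed and must be ignored.
    missing : boolean array, same shape; True where the call is missing.
    stratum : per-subject ancestry label.
    flipped : per-variant flag; True where the coded (minor) allele is the
        VCF REF allele rather than ALT.
    """

    subject_ids: np.ndarray
    variant_ids: np.ndarray
    dosage: np.ndarray
    missing: np.ndarray
    stratum: np.ndarray
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.stratum = np.asarray(self.stratum, dtype=object)
        if self.flipped is None:
            self.flipped = np.zeros(len(self.variant_ids), dtype=bool)
        n, m = self.dosage.shape
        if self.missing.shape != (n, m):
            raise ValueError("dosage and missing mask shapes differ")
        if len(self.subject_ids) != n or len(self.variant_ids) != m:
            raise ValueError("identifier lengths inconsistent with matrix shape")
        if len(self.stratum) != n:
            raise ValueError("stratum vector length inconsistent")
        ok = self.missing | ((self.dosage >= 0) & (self.dosage <= 2))
        if not ok.all():
            raise ValueError("dosage outside {0,1,2} at a non-missing call")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_subjects(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return replace(
            self,
            subject_ids=self.subject_ids[idx],
            dosage=self.dosage[idx],
            missing=self.missing[idx],
            stratum=self.stratum[idx],
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            variant_ids=self.variant_ids[idx],
            dosage=self.dosage[:, idx],
            missing=self.missing[:, idx],
            flipped=self.flipped[idx],
        )

    def stratum_view(self, label: str) -> "GenotypeMatrix":
        """Subjects of one stratum, dosages re-folded to the within-stratum
        minor allele."""
        sub = self.subset_subjects(self.stratum == label)
        dosage, flip = fold_to_minor(sub.dosage, sub.missing)
        return replace(sub, dosage=dosage, flipped=sub.flipped ^ flip)


def fold_to_minor(dosage: np.ndarray, missing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip dosage columns whose coded-allele frequency exceeds 0.5.

    Returns the folded dosage matrix and the per-column flip mask.
    All-missing columns are left untouched.
    """
    dosage = np.asarray(dosage, dtype=np.int8)
    missing = np.asarray(missing, dtype=bool)
    obs = ~missing
    n_obs = obs.sum(axis=0)
    counts = np.where(obs, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, counts / np.maximum(2 * n_obs, 1), 0.0)
    flip = freq > 0.5
    out = dosage.copy()
    out[:, flip] = 2 - out[:, flip]
    out[missing] = 0
    return out, flip


def compute_maf(dosage_column: np.ndarray, missing_column: np.ndarray | None = None) -> float:
    """Minor-allele frequency of one variant, folded to [0, 0.5].

    ``(sum of dosages over non-missing calls) / (2 x non-missing calls)``,
    flipped to the complementary frequency when above 0.5.

    Raises
    ------
    UndefinedFrequencyError
        If every call is missing.
    """
    dosage_column = np.asarray(dosage_column)
    if missing_column is None:
        missing_column = np.zeros(dosage_column.shape, dtype=bool)
    obs = ~np.asarray(missing_column, dtype=bool)
    n = int(obs.sum())
    if n == 0:
        raise UndefinedFrequencyError("all calls missing; allele frequency undefined")
    freq = float(dosage_column[obs].sum()) / (2.0 * n)
    return min(freq, 1.0 - freq)


def maf_vector(gm: GenotypeMatrix) -> np.ndarray:
    """Folded MAF per variant; NaN for all-missing columns."""
    obs = ~gm.missing
    n_obs = obs.sum(axis=0)
    counts = np.where(obs, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / (2.0 * n_obs)
    freq = np.where(n_obs > 0, freq, np.nan)
    return np.minimum(freq, 1.0 - freq)


def classify_rarity(maf: float, threshold: float = 0.05) -> str:
    """``rare`` iff maf < threshold (strict), else ``common``."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf {maf} outside [0, 0.5]")
    return "rare" if maf < threshold else "common"


def read_annotations(path) -> pd.DataFrame:
    """Read the tab-separated variant annotation table.

    Expected columns: chrom, pos (1-based), rsid ("-" if absent), ref, alt,
    func_class, novel (0/1), prediction (free text, may be "-").
    """
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str, "prediction": str})
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {sorted(missing_cols)}")
    bad = set(ann["func_class"]) - set(FUNC_CLASSES)
    if bad:
        raise ValueError(f"unknown functional classes: {sorted(bad)}")
    ann["novel"] = ann["novel"].astype(int).astype(bool)
    ann["variant_id"] = variant_key(ann["chrom"], ann["pos"])
    return ann


def variant_key(chrom, pos) -> pd.Series | str:
    """Canonical variant identifier ``chrom:pos``."""
    if np.isscalar(chrom):
        return f"{chrom}:{pos}"
    return pd.Series(chrom).astype(str) + ":" + pd.Series(pos).astype(str)


def filter_by_class(annotations: pd.DataFrame, classes) -> pd.DataFrame:
    """Order-preserving subset of the annotation table by functional class."""
    classes = set(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    unknown = classes - set(FUNC_CLASSES)
    if unknown:
        raise ValueError(f"unknown functional classes: {sorted(unknown)}")
    return annotations[annotations["func_class"].isin(classes)].copy()


def read_genotypes(vcf_path, stratum_map: dict) -> GenotypeMatrix:
    """Read a diploid VCF into a minor-allele-coded :class:`GenotypeMatrix`.

    Parameters
    ----------
    vcf_path : path to a VCF v4.x file with GT fields; ``./.`` allowed.
    stratum_map : subject id -> ancestry stratum; every VCF sample must be
        present.

    Raises
    ------
    VCFParseError
        On malformed records or multi-allelic sites.
    KeyError
        If a VCF sample is absent from ``stratum_map``.
    """
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise VCFParseError(f"cannot open VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    for s in samples:
        if s not in stratum_map:
            raise KeyError(f"VCF sample {s!r} absent from stratum map")
    dosages, missings, vids = [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise VCFParseError(
                f"{vcf_path}: record {i + 1} at {rec.CHROM}:{rec.POS} is not bi-allelic"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        miss = gt == 2
        dose = np.where(gt == 3, 2, gt).astype(np.int8)
        dose[miss] = 0
        dosages.append(dose)
        missings.append(miss)
        vids.append(variant_key(rec.CHROM, rec.POS))
    if not dosages:
        raise VCFParseError(f"{vcf_path}: no variant records")
    dosage = np.stack(dosages, axis=1)
    missing = np.stack(missings, axis=1)
    dosage, flip = fold_to_minor(dosage, missing)
    stratum = np.array([stratum_map[s] for s in samples], dtype=object)
    return GenotypeMatrix(
        subject_ids=np.array(samples, dtype=object),
        variant_ids=np.array(vids, dtype=object),
        dosage=dosage,
        missing=missing,
        stratum=stratum,
        flipped=flip,
    )


def write_genotypes(gm: GenotypeMatrix, annotations: pd.DataFrame, path) -> None:
    """Write a VCF v4.2 text file; inverse of :func:`read_genotypes`.

    The REF/ALT alleles come from the annotation table (matched on
    variant_id); columns flipped on read are unflipped so the file stores
    alternate-allele counts again.
    """
    ann = annotations.set_index("variant_id")
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(annotations["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.subject_ids))
            + "\n"
        )
        for j, vid in enumerate(gm.variant_ids):
            row = ann.loc[vid]
            dose = gm.dosage[:, j]
            if gm.flipped[j]:
                dose = 2 - dose
            calls = [
                "./." if gm.missing[i, j] else gt_strings[int(dose[i])]
                for i in range(gm.n_subjects)
            ]
            rsid = row["rsid"] if row["rsid"] not in ("-", "", None) else "."
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{rsid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write an association results table as TSV (round-trips with
    :func:`read_results_table`); missing rsIDs serialize as ``-``."""
    out = results.copy()
    if "rsid" in out.columns:
        out["rsid"] = out["rsid"].fillna("-").replace("", "-")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True,
                       dtype={"rsid": str} )
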