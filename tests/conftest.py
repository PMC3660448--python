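"""Shared fixtures: small genotype matrices and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from extremevar.variant_io import GenotypeMatrix


def make_gm(dosage, missing=None, stratum=None, variant_ids=None):
    """GenotypeMatrix from a plain dosage array (helper, not a fixture)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if missing is None:
        missing = np.zeros((n, m), dtype=bool)
    if stratum is None:
        stratum = np.array(["X"] * n, dtype=object)
    if variant_ids is None:
        variant_ids = np.array([f"1:{j + 1}" for j in range(m)], dtype=object)
    return GenotypeMatrix(
        subject_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        variant_ids=np.asarray(variant_ids, dtype=object),
        dosage=dosage,
        missing=np.asarray(missing, dtype=bool),
        stratum=np.asarray(stratum, dtype=object),
    )


def toy_annotations(func_classes, pos=None):
    """Annotation frame from a list of functional classes."""
    m = len(func_classes)
    if pos is None:
        pos = np.arange(1, m + 1)
    ann = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "rsid": "-",
            "ref": "A",
            "alt": "G",
            "func_class": func_classes,
            "novel": False,
            "prediction": "-",
        }
    )
    ann["variant_id"] = ann["chrom"].astype(str) + ":" + ann["pos"].astype(str)
    return ann


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated base cohort shared across tests."""
    from extremevar.syndata import SimConfig, generate_cohort

    return generate_cohort(SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def selected_sim(small_sim):
    """The small cohort after adjustment, selection and missingness."""
    from extremevar import design
    from extremevar.syndata import apply_missingness

    adjusted = design.adjust_cohort(small_sim.cohort)
    adjusted["group"] = design.select_extremes(adjusted)
    sel = adjusted["group"].isin(["hyper", "hypo"])
    keep = pd.Index(small_sim.genotypes.subject_ids).isin(adjusted.loc[sel, "subject_id"])
    gm = small_sim.genotypes.subset_subjects(np.asarray(keep))
    gm = apply_missingness(gm, 0.086, 11)
    groups = adjusted.set_index("subject_id").loc[list(gm.subject_ids), "group"]
    return gm, groups, small_sim
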