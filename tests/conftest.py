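import numpy as np
import pandas as pd
import pytest

from meiodrive.data_model import Dataset
from meiodrive.simulate import CrossConfig, simulate_cross


def toy_config(**overrides) -> CrossConfig:
    """A small but complete breeding design for fast tests."""
    base = dict(
        n_chromosomes=5,
        bc1_samples=120,
        bc2_samples=200,
        bc1_adult_males=12,
        bc1_adult_females=12,
        bc1_breeder_males=8,
        bc1_breeder_females=10,
        n_aus_founders=50,
        rng_seed=11,
    )
    base.update(overrides)
    return CrossConfig(**base)


@pytest.fixture(scope="session")
def toy_run():
    cfg = toy_config()
    return simulate_cross(cfg) + (cfg,)


@pytest.fixture(scope="session")
def clean_run():
    """Nuisance-free toy cross: truth log reconciles exactly."""
    cfg = toy_config(apply_nuisance=False, founder_introgression=0.0, rng_seed=13)
    return simulate_cross(cfg) + (cfg,)


def build_dataset(individuals, genotypes, markers=None) -> Dataset:
    """Hand-rolled dataset builder for unit tests.

    individuals: list of (id, sex, dam, sire, cohort, fate)
    genotypes: dict (id, marker) -> tuple of alleles
    markers: list of (marker_id, chromosome, position_class, cm, is_z)
    """
    if markers is None:
        markers = [("m1", "chr1", "centromeric", 0.0, False)]
    ped = pd.DataFrame(
        individuals,
        columns=["individual_id", "sex", "dam_id", "sire_id", "cohort", "fate"],
    )
    rows = []
    for (iid, m), alleles in genotypes.items():
        alleles = sorted(alleles)
        extra = ",".join(str(a) for a in alleles[2:])
        rows.append((iid, m, alleles[0], alleles[1], extra))
    gen = pd.DataFrame(
        rows,
        columns=["individual_id", "marker_id", "allele1", "allele2", "extra_alleles"],
    )
    mk = pd.DataFrame(
        markers,
        columns=["marker_id", "chromosome", "position_class",
                 "cm_from_centromere", "is_z_linked"],
    )
    ds = Dataset(individuals=ped, genotypes=gen, markers=mk)
    ds.validate()
    return ds


def founder_trio(dam_g, sire_g, off_g, marker="m1"):
    """One founder x founder pair with a single F1 offspring."""
    individuals = [
        ("D", "F", None, None, "FOUNDER_TIM", "adult"),
        ("S", "M", None, None, "FOUNDER_AUS", "adult"),
        ("O", "U", "D", "S", "F1", "sampled_embryo"),
    ]
    genotypes = {("D", marker): dam_g, ("S", marker): sire_g}
    if off_g is not None:
        genotypes[("O", marker)] = off_g
    return build_dataset(individuals, genotypes)
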