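"""Domain types, TSV readers/writers and dataset validation.

The package analyses transmission of microsatellite alleles through a
hybrid backcross pedigree (Timor x Australian zebra finches and their
backcrosses to the Australian subspecies).  Three plain-text tables carry
a dataset:

* ``genotypes.tsv`` — individual_id, marker_id, allele1, allele2
  (+ optional ``extra_alleles`` for non-diploid genotypes)
* ``pedigree.tsv``  — individual_id, sex, dam_id, sire_id, cohort, fate
* ``markers.tsv``   — marker_id, chromosome, position_class,
  cm_from_centromere, is_z_linked

Allele lengths are positive integers (base pairs).  Two sentinels are
used: ``NULL_ALLELE = 0`` for an inferred allelic dropout and
``W_PLACEHOLDER = -1`` for the hemizygous slot of a ZW female at a
Z-linked marker.  Missing values are written as ``NA``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NULL_ALLELE = 0
W_PLACEHOLDER = -1

SEXES = ("F", "M", "U")
COHORTS = ("FOUNDER_AUS", "FOUNDER_TIM", "F1", "BC1", "BC2")
FATES = ("adult", "sampled_embryo", "dead_chick", "infertile_egg", "lost")

#: cohort of offspring implied by (dam cohort, sire cohort), either order
_CROSS_RULES = {
    frozenset({"FOUNDER_AUS", "FOUNDER_TIM"}): "F1",
    frozenset({"F1", "FOUNDER_AUS"}): "BC1",
    frozenset({"BC1", "FOUNDER_AUS"}): "BC2",
}

GENOTYPE_COLUMNS = ["individual_id", "marker_id", "allele1", "allele2"]
PEDIGREE_COLUMNS = ["individual_id", "sex", "dam_id", "sire_id", "cohort", "fate"]
MARKER_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_class",
    "cm_from_centromere",
    "is_z_linked",
]


class DatasetError(ValueError):
    """Base class for dataset construction/validation failures."""


class FormatError(DatasetError):
    """A required column is missing or a value cannot be parsed."""


class ReferentialError(DatasetError):
    """A row references an unknown or inconsistent individual/marker."""


class DuplicationError(DatasetError):
    """Duplicate (individual, marker) genotype rows."""


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # F, M or U (unknown; embryos/infertile eggs only)
    dam_id: str | None
    sire_id: str | None
    cohort: str
    fate: str


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chromosome: str
    position_class: str  # "centromeric" or "distal"
    cm_from_centromere: float
    is_z_linked: bool


@dataclass
class Dataset:
    """Validated container for pedigree, genotypes and marker map.

    ``genotypes`` rows hold integer alleles; ``extra_alleles`` is a string
    of comma-joined additional alleles ("" for a normal diploid row).
    """

    individuals: pd.DataFrame
    genotypes: pd.DataFrame
    markers: pd.DataFrame
    _geno_lookup: dict | None = field(default=None, repr=False, compare=False)
    _ind_lookup: dict | None = field(default=None, repr=False, compare=False)

    # -- accessors --------------------------------------------------------
    def individual(self, ind_id: str) -> Individual:
        if self._ind_lookup is None:
            self._ind_lookup = {
                r.individual_id: Individual(
                    r.individual_id, r.sex, r.dam_id, r.sire_id, r.cohort, r.fate
                )
                for r in self.individuals.itertuples()
            }
        return self._ind_lookup[ind_id]

    def genotype_lookup(self) -> dict:
        """dict (individual_id, marker_id) -> tuple of alleles (len >= 1)."""
        if self._geno_lookup is None:
            lut = {}
            for r in self.genotypes.itertuples():
                alleles = [int(r.allele1), int(r.allele2)]
                if r.extra_alleles:
                    alleles.extend(int(a) for a in r.extra_alleles.split(","))
                lut[(r.individual_id, r.marker_id)] = tuple(sorted(alleles))
            self._geno_lookup = lut
        return self._geno_lookup

    def invalidate_caches(self) -> None:
        self._geno_lookup = None
        self._ind_lookup = None

    def marker_info(self) -> dict:
        return {
            r.marker_id: Marker(
                r.marker_id,
                r.chromosome,
                r.position_class,
                float(r.cm_from_centromere),
                bool(r.is_z_linked),
            )
            for r in self.markers.itertuples()
        }

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        _validate(self)


def alleles_from_row(allele1, allele2, extra: str = "") -> tuple:
    alleles = [int(allele1), int(allele2)]
    if extra:
        alleles.extend(int(a) for a in extra.split(","))
    return tuple(sorted(alleles))


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_dataset(genotype_path, pedigree_path, map_path) -> Dataset:
    """Read and validate the three TSV tables into a :class:`Dataset`."""
    ped = _read_tsv(pedigree_path)
    _require_columns(ped, PEDIGREE_COLUMNS, pedigree_path)
    ped = ped[PEDIGREE_COLUMNS].copy()
    ped["dam_id"] = ped["dam_id"].replace("NA", None)
    ped["sire_id"] = ped["sire_id"].replace("NA", None)

    gen = _read_tsv(genotype_path)
    _require_columns(gen, GENOTYPE_COLUMNS, genotype_path)
    if "extra_alleles" not in gen.columns:
        gen["extra_alleles"] = ""
    gen = gen[GENOTYPE_COLUMNS + ["extra_alleles"]].copy()
    gen["extra_alleles"] = gen["extra_alleles"].replace("NA", "")
    try:
        gen["allele1"] = gen["allele1"].astype(int)
        gen["allele2"] = gen["allele2"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{genotype_path}: non-integer allele length: {exc}") from exc

    mk = _read_tsv(map_path)
    _require_columns(mk, MARKER_COLUMNS, map_path)
    mk = mk[MARKER_COLUMNS].copy()
    mk["cm_from_centromere"] = mk["cm_from_centromere"].astype(float)
    mk["is_z_linked"] = mk["is_z_linked"].map(
        {"True": True, "False": False, "1": True, "0": False}
    )
    if mk["is_z_linked"].isna().any():
        raise FormatError(f"{map_path}: is_z_linked must be True/False")

    ds = Dataset(individuals=ped, genotypes=gen, markers=mk)
    ds.validate()
    return ds


def write_dataset(ds: Dataset, out_dir) -> dict:
    """Write the three TSVs in the dialect of :func:`read_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "pedigree": out / "pedigree.tsv",
        "markers": out / "markers.tsv",
    }
    gen = ds.genotypes.copy()
    gen["extra_alleles"] = gen["extra_alleles"].replace("", "NA")
    gen.to_csv(paths["genotypes"], sep="\t", index=False)
    ped = ds.individuals.copy()
    ped["dam_id"] = ped["dam_id"].fillna("NA")
    ped["sire_id"] = ped["sire_id"].fillna("NA")
    ped.to_csv(paths["pedigree"], sep="\t", index=False)
    ds.markers.to_csv(paths["markers"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate(ds: Dataset) -> None:
    ped, gen, mk = ds.individuals, ds.genotypes, ds.markers

    dup_ind = ped["individual_id"][ped["individual_id"].duplicated()]
    if len(dup_ind):
        raise DuplicationError(
            f"duplicate individual ids: {sorted(set(dup_ind))[:5]}"
        )
    bad_sex = ped[~ped["sex"].isin(SEXES)]
    if len(bad_sex):
        raise FormatError(f"invalid sex values: {sorted(set(bad_sex['sex']))}")
    bad_cohort = ped[~ped["cohort"].isin(COHORTS)]
    if len(bad_cohort):
        raise FormatError(
            f"invalid cohort values: {sorted(set(bad_cohort['cohort']))}"
        )
    bad_fate = ped[~ped["fate"].isin(FATES)]
    if len(bad_fate):
        raise FormatError(f"invalid fate values: {sorted(set(bad_fate['fate']))}")
    # unknown sex only for embryos / infertile eggs / lost
    unknown_adult = ped[(ped["sex"] == "U") & (ped["fate"] == "adult")]
    if len(unknown_adult):
        raise ReferentialError(
            "adults must have known sex: "
            f"{sorted(unknown_adult['individual_id'])[:5]}"
        )

    ids = set(ped["individual_id"])
    sex_of = dict(zip(ped["individual_id"], ped["sex"]))
    cohort_of = dict(zip(ped["individual_id"], ped["cohort"]))

    offenders = []
    for r in ped.itertuples():
        for pid, want_sex, role in ((r.dam_id, "F", "dam"), (r.sire_id, "M", "sire")):
            if pid is None:
                continue
            if pid not in ids:
                offenders.append(f"{r.individual_id}: unknown {role} {pid}")
            elif sex_of[pid] != want_sex:
                offenders.append(
                    f"{r.individual_id}: {role} {pid} has sex {sex_of[pid]}"
                )
        if r.cohort not in ("FOUNDER_AUS", "FOUNDER_TIM"):
            if r.dam_id is None or r.sire_id is None:
                offenders.append(f"{r.individual_id}: non-founder missing parents")
            elif r.dam_id in ids and r.sire_id in ids:
                expect = _CROSS_RULES.get(
                    frozenset({cohort_of[r.dam_id], cohort_of[r.sire_id]})
                )
                if expect != r.cohort:
                    offenders.append(
                        f"{r.individual_id}: cohort {r.cohort} inconsistent with "
                        f"parents ({cohort_of[r.dam_id]} x {cohort_of[r.sire_id]})"
                    )
    if offenders:
        raise ReferentialError("pedigree errors: " + "; ".join(offenders[:10]))

    _check_no_ancestry_cycles(ped)

    dup = gen.duplicated(subset=["individual_id", "marker_id"])
    if dup.any():
        rows = gen.loc[dup, ["individual_id", "marker_id"]].head(5)
        raise DuplicationError(
            f"duplicate genotype rows: {rows.to_dict('records')}"
        )
    unknown_gi = set(gen["individual_id"]) - ids
    if unknown_gi:
        raise ReferentialError(
            f"genotypes reference unknown individuals: {sorted(unknown_gi)[:5]}"
        )
    unknown_gm = set(gen["marker_id"]) - set(mk["marker_id"])
    if unknown_gm:
        raise ReferentialError(
            f"genotypes reference unknown markers: {sorted(unknown_gm)[:5]}"
        )
    bad_len = gen[(gen["allele1"] < W_PLACEHOLDER) | (gen["allele2"] < W_PLACEHOLDER)]
    if len(bad_len):
        raise FormatError("allele lengths must be positive (0=NULL, -1=W)")
    both_placeholder = gen[(gen["allele1"] <= 0) & (gen["allele2"] <= 0)]
    if len(both_placeholder):
        raise FormatError(
            "at most one NULL/W placeholder per genotype; offending rows: "
            f"{both_placeholder[['individual_id', 'marker_id']].head(3).to_dict('records')}"
        )

    if mk["marker_id"].duplicated().any():
        raise DuplicationError("duplicate marker ids in marker map")
    bad_class = mk[~mk["position_class"].isin(("centromeric", "distal"))]
    if len(bad_class):
        raise FormatError(
            f"invalid position_class: {sorted(set(bad_class['position_class']))}"
        )
    too_far = mk[(mk["position_class"] == "centromeric") & (mk["cm_from_centromere"] > 27)]
    if len(too_far):
        raise FormatError(
            "centromeric markers must be <= 27 cM from the centromere: "
            f"{sorted(too_far['marker_id'])}"
        )
    per_chrom = mk.groupby(["chromosome", "position_class"]).size()
    if (per_chrom > 1).any():
        raise DuplicationError(
            "at most one centromeric and one distal marker per chromosome"
        )


def _check_no_ancestry_cycles(ped: pd.DataFrame) -> None:
    parents = {
        r.individual_id: tuple(p for p in (r.dam_id, r.sire_id) if p)
        for r in ped.itertuples()
    }
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(node: str) -> None:
        stack = [(node, iter(parents.get(node, ())))]
        state[node] = 0
        while stack:
            nid, it = stack[-1]
            advanced = False
            for p in it:
                if state.get(p) == 0:
                    raise ReferentialError(f"ancestry cycle involving {p}")
                if p not in state:
                    state[p] = 0
                    stack.append((p, iter(parents.get(p, ()))))
                    advanced = True
                    break
            if not advanced:
                state[nid] = 1
                stack.pop()

    for ind in parents:
        if ind not in state:
            visit(ind)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    individual_id: str
    marker_id: str
    reason: str


def _gamete_values(alleles: tuple) -> set:
    """Distinct transmittable slot values of a diploid genotype."""
    return set(alleles)


def trio_consistent(dam: tuple, sire: tuple, off: tuple) -> bool:
    """True if some one-allele-per-parent assignment explains ``off``.

    A parent's NULL/W placeholder pairs with the offspring's matching
    placeholder slot; an offspring apparent homozygote {x,x} is also
    explained by x from one parent plus a NULL carried by the other.
    """
    off_s = tuple(sorted(off))
    for gd, gs in itertools.product(_gamete_values(dam), _gamete_values(sire)):
        if tuple(sorted((gd, gs))) == off_s:
            return True
    if len(off_s) == 2 and off_s[0] == off_s[1] and off_s[0] > 0:
        x = off_s[0]
        if x in dam and NULL_ALLELE in sire:
            return True
        if x in sire and NULL_ALLELE in dam:
            return True
    return False


def check_mendelian_consistency(ds: Dataset) -> list[Violation]:
    """Report trios whose offspring genotype no parental assignment explains.

    Report-only: non-diploid genotypes (``> 2`` alleles) are flagged as
    deferred to the anomaly screen, and apparent homozygotes that would be
    explained by an uninferred null allele are flagged as such rather than
    as hard violations.
    """
    lut = ds.genotype_lookup()
    violations: list[Violation] = []
    markers = ds.markers["marker_id"].tolist()
    for r in ds.individuals.itertuples():
        if r.dam_id is None or r.sire_id is None:
            continue
        for m in markers:
            off = lut.get((r.individual_id, m))
            if off is None:
                continue
            if len(off) > 2:
                violations.append(
                    Violation(r.individual_id, m, "non-diploid, defer to anomaly_screen")
                )
                continue
            dam = lut.get((r.dam_id, m))
            sire = lut.get((r.sire_id, m))
            if dam is None or sire is None:
                continue
            if trio_consistent(dam, sire, off):
                continue
            if off[0] == off[1] and off[0] > 0 and (off[0] in dam or off[0] in sire):
                violations.append(
                    Violation(r.individual_id, m, "possible_null_allele")
                )
            else:
                violations.append(Violation(r.individual_id, m, "mendelian_violation"))
    return violations
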