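"""Allele-origin tracing and transmission counting.

Every statistic downstream rests on the counts produced here.  The engine

1. labels each (marker, allele length) as Australian (AUS), Timor (TIM)
   or ambiguous (AMBIG) from the founder genotypes,
2. infers null alleles (allelic dropouts) from pedigree inconsistencies,
3. classifies each parental pair at each marker as fully informative,
   partially informative (the AB x AB constellation) or uninformative,
4. deduces, for every offspring genotype, which origin the focal
   (AUS/TIM-heterozygous) parent transmitted, and
5. tallies transmission records (1 = AUS, 0 = TIM) with a ledger of every
   exclusion.

The informativeness rule is algorithmic rather than a table of genotype
constellations: a pair is fully informative iff every genotype it can
produce pins down the focal parent's transmitted origin uniquely.  The
single exception with partial information is AB x AB (both parents carry
the same two lengths, one AUS and one TIM in the focal parent): there a
homozygous offspring identifies both transmitted alleles while a
heterozygous offspring is ambiguous and is never counted.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .data_model import Dataset, NULL_ALLELE, W_PLACEHOLDER

AUS = "AUS"
TIM = "TIM"
AMBIG = "AMBIG"

FULLY_INFORMATIVE = "fully_informative"
PARTIAL_ABXAB = "partial_ABxAB"
UNINFORMATIVE = "uninformative"


class RegistryError(ValueError):
    """A marker has no founder genotypes to anchor allele origins."""


@dataclass
class OriginRegistry:
    """Per-locus map allele length -> {AUS, TIM, AMBIG}."""

    origins: dict  # (marker_id, allele) -> origin
    warnings: list = field(default_factory=list)

    def origin(self, marker_id: str, allele: int) -> str:
        if allele <= 0:
            raise ValueError("placeholders carry no origin")
        return self.origins.get((marker_id, allele), AMBIG)

    def set(self, marker_id: str, allele: int, origin: str) -> None:
        self.origins[(marker_id, allele)] = origin


def build_origin_registry(ds: Dataset, policy: str = "exclude") -> OriginRegistry:
    """Label alleles by the founder pool(s) they were observed in.

    policy="exclude" (default): a length seen in both founder pools is
    AMBIG.  policy="founder_label": such a length is assigned to the pool
    with the majority of founder carriers (ties stay AMBIG), mimicking a
    study that treats founder-pool labels as ground truth.
    """
    if policy not in ("exclude", "founder_label"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    cohort_of = dict(
        zip(ds.individuals["individual_id"], ds.individuals["cohort"])
    )
    seen: dict = defaultdict(Counter)  # (marker, allele) -> Counter of pools
    founder_markers = set()
    for r in ds.genotypes.itertuples():
        pool = cohort_of[r.individual_id]
        if pool not in ("FOUNDER_AUS", "FOUNDER_TIM"):
            continue
        founder_markers.add(r.marker_id)
        for a in (r.allele1, r.allele2):
            if a > 0:
                seen[(r.marker_id, a)][AUS if pool == "FOUNDER_AUS" else TIM] += 1

    all_markers = set(ds.markers["marker_id"])
    missing = sorted(all_markers - founder_markers)
    if missing:
        raise RegistryError(
            f"markers with no founder genotypes: {missing[:10]}"
        )

    reg = OriginRegistry(origins={})
    for (marker, allele), pools in seen.items():
        if len(pools) == 1:
            reg.set(marker, allele, next(iter(pools)))
        elif policy == "founder_label":
            (top, n1), (_, n2) = pools.most_common(2)
            reg.set(marker, allele, top if n1 > n2 else AMBIG)
        else:
            reg.set(marker, allele, AMBIG)

    # descendant alleles never seen in founders -> AMBIG with a warning
    for r in ds.genotypes.itertuples():
        if cohort_of[r.individual_id] in ("FOUNDER_AUS", "FOUNDER_TIM"):
            continue
        for a in (r.allele1, r.allele2):
            if a > 0 and (r.marker_id, a) not in reg.origins:
                reg.set(r.marker_id, a, AMBIG)
                reg.warnings.append(
                    f"allele {a} at {r.marker_id} absent from founders "
                    "(possible mutation or dropout); labelled AMBIG"
                )
    return reg


# ---------------------------------------------------------------------------
# W coding and null-allele inference
# ---------------------------------------------------------------------------

def apply_w_coding(ds: Dataset) -> Dataset:
    """Code the hemizygous slot of known females at Z-linked markers as W.

    ZW females carry a single Z; a two-equal-allele genotype recorded for a
    female at a Z-linked marker is rewritten to {allele, W}.  Sex-unknown
    individuals are left untouched.
    """
    z_markers = set(ds.markers.loc[ds.markers["is_z_linked"], "marker_id"])
    if not z_markers:
        return ds
    females = set(
        ds.individuals.loc[ds.individuals["sex"] == "F", "individual_id"]
    )
    gen = ds.genotypes
    mask = (
        gen["marker_id"].isin(z_markers)
        & gen["individual_id"].isin(females)
        & (gen["allele1"] == gen["allele2"])
        & (gen["allele1"] > 0)
    )
    if mask.any():
        gen = gen.copy()
        gen.loc[mask, "allele2"] = gen.loc[mask, "allele1"]
        gen.loc[mask, "allele1"] = W_PLACEHOLDER
        ds = Dataset(individuals=ds.individuals, genotypes=gen, markers=ds.markers)
    return ds


@dataclass(frozen=True)
class NullCall:
    individual_id: str
    marker_id: str
    reason: str


def infer_null_alleles(ds: Dataset) -> tuple[Dataset, list[NullCall]]:
    """Rewrite genotype slots to NULL where pedigree logic forces a dropout.

    Conservative: a slot becomes NULL only when no assignment of observed
    alleles explains a trio and a single hidden allele in one specific
    genotype resolves it.  Unresolvable conflicts are left untouched (the
    Mendelian checker surfaces them).  Returns the updated dataset and the
    list of (individual, marker) null calls.
    """
    lut = dict(ds.genotype_lookup())
    calls: list[NullCall] = []
    markers = ds.markers["marker_id"].tolist()

    def provides(g: tuple, v: int) -> bool:
        return v in g

    def apparent_hom(g: tuple) -> bool:
        return len(g) == 2 and g[0] == g[1] and g[0] > 0

    for r in ds.individuals.itertuples():
        if r.dam_id is None or r.sire_id is None:
            continue
        for m in markers:
            off = lut.get((r.individual_id, m))
            if off is None or len(off) != 2:
                continue
            dam = lut.get((r.dam_id, m))
            sire = lut.get((r.sire_id, m))
            if dam is None or sire is None:
                continue
            x, y = off
            if W_PLACEHOLDER in off:
                continue
            if x == y and x > 0:
                # apparent homozygote: one parent may have transmitted a null
                dam_ok = provides(dam, x) or NULL_ALLELE in dam
                sire_ok = provides(sire, x) or NULL_ALLELE in sire
                if dam_ok != sire_ok:
                    failing = sire if dam_ok else dam
                    if apparent_hom(failing):
                        # the failing parent could itself hide x behind a
                        # dropout; attribution ambiguous, make no call
                        continue
                    # the failing parent carries two observable alleles and
                    # none is x: the offspring's second slot did not amplify
                    lut[(r.individual_id, m)] = (NULL_ALLELE, x)
                    calls.append(
                        NullCall(r.individual_id, m, "forced_by_parent_genotype")
                    )
            elif x > 0 and y > 0:
                a1 = provides(dam, x) and provides(sire, y)
                a2 = provides(dam, y) and provides(sire, x)
                if a1 or a2:
                    continue
                # a hidden allele in exactly one apparent-homozygous parent?
                fixes = []
                if apparent_hom(dam) and (provides(sire, x) or provides(sire, y)):
                    fixes.append(r.dam_id)
                if apparent_hom(sire) and (provides(dam, x) or provides(dam, y)):
                    fixes.append(r.sire_id)
                if len(fixes) == 1:
                    pid = fixes[0]
                    pg = lut[(pid, m)]
                    lut[(pid, m)] = (NULL_ALLELE, pg[1])
                    calls.append(NullCall(pid, m, "forced_by_offspring_genotype"))

    if not calls:
        return ds, []
    gen = ds.genotypes.copy()
    changed = {(c.individual_id, c.marker_id) for c in calls}
    a1_new, a2_new = [], []
    for row in gen.itertuples():
        key = (row.individual_id, row.marker_id)
        if key in changed:
            g = lut[key]
            a1_new.append(g[0])
            a2_new.append(g[1])
        else:
            a1_new.append(row.allele1)
            a2_new.append(row.allele2)
    gen["allele1"] = a1_new
    gen["allele2"] = a2_new
    out = Dataset(individuals=ds.individuals, genotypes=gen, markers=ds.markers)
    return out, calls


# ---------------------------------------------------------------------------
# pair classification and deduction
# ---------------------------------------------------------------------------

@dataclass
class PairClassification:
    marker_id: str
    focal: str  # "dam" or "sire"
    status: str  # FULLY_INFORMATIVE / PARTIAL_ABXAB / UNINFORMATIVE
    #: observed offspring genotype -> set of focal origins that produce it
    deduction: dict = field(default_factory=dict)


def _display(gf: int, gp: int) -> tuple:
    """Observed genotype for focal gamete gf (real) and partner gamete gp.

    A transmitted null allele leaves the offspring an apparent homozygote;
    a transmitted W is observed explicitly (sexed ZW daughter).
    """
    if gp == NULL_ALLELE:
        return (gf, gf)
    return tuple(sorted((gf, gp)))


def _focal_eligible(alleles: tuple, marker_id: str, registry: OriginRegistry):
    """Return {allele: origin} if the parent is AUS/TIM heterozygous with
    two distinct observable alleles, else None."""
    if len(alleles) != 2:
        return None
    a, b = alleles
    if a <= 0 or b <= 0 or a == b:
        return None
    oa, ob = registry.origin(marker_id, a), registry.origin(marker_id, b)
    if {oa, ob} != {AUS, TIM}:
        return None
    return {a: oa, b: ob}


def classify_pair(
    dam_alleles: tuple,
    sire_alleles: tuple,
    marker_id: str,
    registry: OriginRegistry,
) -> list[PairClassification]:
    """Classify a parental pair at one marker, one result per focal parent.

    Both parents are examined; whichever is heterozygous for one AUS and
    one TIM allele (distinct lengths, no null) can be focal, so a pair of
    two such hybrids yields two classifications.
    """
    out = []
    for focal_name, focal, partner in (
        ("dam", dam_alleles, sire_alleles),
        ("sire", sire_alleles, dam_alleles),
    ):
        origin_of = _focal_eligible(focal, marker_id, registry)
        if origin_of is None:
            continue
        mapping: dict = defaultdict(set)
        for gf, gp in itertools.product(set(focal), set(partner)):
            mapping[_display(gf, gp)].add(origin_of[gf])
        mapping = dict(mapping)
        if all(len(v) == 1 for v in mapping.values()):
            status = FULLY_INFORMATIVE
        elif tuple(sorted(set(focal))) == tuple(sorted(set(partner))):
            status = PARTIAL_ABXAB
        else:
            status = UNINFORMATIVE
        out.append(PairClassification(marker_id, focal_name, status, mapping))
    return out


DEDUCED_AUS = 1
DEDUCED_TIM = 0
AMBIGUOUS = "ambiguous"
EXCLUDED = "excluded"


def deduce_transmission(pc: PairClassification, offspring_alleles):
    """Deduce the focal parent's transmitted origin for one offspring.

    Returns 1 (AUS), 0 (TIM), "ambiguous" (AB x AB heterozygote) or
    "excluded" (missing genotype, non-diploid, uninformative pair, or
    Mendelian-inconsistent offspring).
    """
    if pc.status == UNINFORMATIVE:
        return EXCLUDED
    if offspring_alleles is None:
        return EXCLUDED
    off = tuple(sorted(offspring_alleles))
    if len(off) != 2:
        return EXCLUDED  # non-diploid, handled by the anomaly screen
    if NULL_ALLELE in off:
        # explicit inferred null: the partner transmitted it (the focal
        # parent carries two observable alleles), so the observed form is
        # the apparent homozygote of the other slot
        other = off[0] if off[1] == NULL_ALLELE else off[1]
        if other <= 0:
            return EXCLUDED
        off = (other, other)
    origins = pc.deduction.get(off)
    if origins is None:
        return EXCLUDED  # Mendelian-inconsistent with this pair
    if len(origins) > 1:
        return AMBIGUOUS
    return DEDUCED_AUS if next(iter(origins)) == AUS else DEDUCED_TIM


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "parent_id",
    "parent_sex",
    "parent_cohort",
    "offspring_id",
    "marker_id",
    "chromosome",
    "position_class",
    "transmitted",
]

HYBRID_COHORTS = ("F1", "BC1")


@dataclass
class CountResult:
    records: pd.DataFrame
    summary: pd.DataFrame
    ledger: dict


def count_transmissions(
    ds: Dataset,
    registry: OriginRegistry,
    policy: str = "exclude",
    excluded_offspring_chromosomes: set | None = None,
) -> CountResult:
    """Tally deduced transmissions for every F1/BC1 parent.

    One potential transmission exists per (offspring, marker, hybrid
    parent) with an observed offspring genotype; the ledger reports how
    many were informative and why the rest were excluded.
    ``excluded_offspring_chromosomes`` is a set of (offspring_id,
    chromosome) pairs dropped because of chromosomal abnormalities
    contributed by a hybrid parent (see the anomaly screen).
    """
    del policy  # origin policy is applied when the registry is built
    excl = excluded_offspring_chromosomes or set()
    lut = ds.genotype_lookup()
    minfo = ds.marker_info()
    cohort_of = dict(zip(ds.individuals["individual_id"], ds.individuals["cohort"]))
    sex_of = dict(zip(ds.individuals["individual_id"], ds.individuals["sex"]))

    ledger = Counter()
    rows = []
    pc_cache: dict = {}
    markers = list(minfo)

    for r in ds.individuals.itertuples():
        if r.dam_id is None or r.sire_id is None:
            continue
        hybrid_roles = [
            role
            for role, pid in (("dam", r.dam_id), ("sire", r.sire_id))
            if cohort_of.get(pid) in HYBRID_COHORTS
        ]
        if not hybrid_roles:
            continue
        for m in markers:
            off = lut.get((r.individual_id, m))
            if off is None:
                continue
            dam_g = lut.get((r.dam_id, m))
            sire_g = lut.get((r.sire_id, m))
            for role in hybrid_roles:
                pid = r.dam_id if role == "dam" else r.sire_id
                ledger["total"] += 1
                if (r.individual_id, minfo[m].chromosome) in excl:
                    ledger["anomaly_excluded"] += 1
                    continue
                pg = dam_g if role == "dam" else sire_g
                if pg is None:
                    ledger["parent_genotype_missing"] += 1
                    continue
                if NULL_ALLELE in pg:
                    ledger["parent_null"] += 1
                    continue
                partner_g = sire_g if role == "dam" else dam_g
                if partner_g is None:
                    ledger["partner_genotype_missing"] += 1
                    continue
                key = (m, dam_g, sire_g, role)
                if key not in pc_cache:
                    pcs = classify_pair(
                        dam_g if dam_g else (), sire_g if sire_g else (), m, registry
                    )
                    for rr in ("dam", "sire"):
                        pc_cache[(m, dam_g, sire_g, rr)] = next(
                            (p for p in pcs if p.focal == rr), None
                        )
                pc = pc_cache[key]
                if pc is None:
                    ledger["parent_not_heterozygous_AT"] += 1
                    continue
                if pc.status == UNINFORMATIVE:
                    ledger["pair_uninformative"] += 1
                    continue
                res = deduce_transmission(pc, off)
                if res == AMBIGUOUS:
                    ledger["abxab_ambiguous_offspring"] += 1
                    continue
                if res == EXCLUDED:
                    ledger["mendelian_inconsistent"] += 1
                    continue
                ledger["informative"] += 1
                rows.append(
                    (
                        pid,
                        sex_of[pid],
                        cohort_of[pid],
                        r.individual_id,
                        m,
                        minfo[m].chromosome,
                        minfo[m].position_class,
                        res,
                    )
                )

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if len(records):
        summary = (
            records.groupby(
                ["marker_id", "parent_sex", "parent_cohort", "position_class"],
                as_index=False,
            )
            .agg(n=("transmitted", "size"), successes=("transmitted", "sum"))
            .sort_values(["marker_id", "parent_sex", "parent_cohort"])
            .reset_index(drop=True)
        )
    else:
        summary = pd.DataFrame(
            columns=[
                "marker_id",
                "parent_sex",
                "parent_cohort",
                "position_class",
                "n",
                "successes",
            ]
        )
    led = dict(ledger)
    led.setdefault("total", 0)
    led.setdefault("informative", 0)
    led["informative_percent"] = (
        100.0 * led["informative"] / led["total"] if led["total"] else float("nan")
    )
    return CountResult(records=records, summary=summary, ledger=led)


def informativeness_ledger(total: int, informative: int, **exclusions) -> dict:
    """Assemble the informativeness ledger from printed or computed totals."""
    return {
        "total": int(total),
        "informative": int(informative),
        "informative_percent": 100.0 * informative / total if total else float("nan"),
        **exclusions,
    }


def subset_transmissions(
    records: pd.DataFrame,
    ds: Dataset,
    registry: OriginRegistry,
    which: str,
) -> pd.DataFrame:
    """Filter transmission records to one of the robustness subsets.

    ``heterozygous_parents``: both parents heterozygous (two distinct
    observable alleles, no null) at the marker — removes trios where an
    undetected null could hide.  ``no_inbreeding``: pairs that cannot
    produce offspring homozygous for any Australian allele — removes
    trios where inbreeding depression could mimic drive.
    """
    if which not in ("heterozygous_parents", "no_inbreeding"):
        raise ValueError(f"unknown subset {which!r}")
    if not len(records):
        return records.copy()
    lut = ds.genotype_lookup()
    parents_of = {
        r.individual_id: (r.dam_id, r.sire_id) for r in ds.individuals.itertuples()
    }

    def is_het(g) -> bool:
        return (
            g is not None
            and len(g) == 2
            and g[0] != g[1]
            and g[0] > 0
            and g[1] > 0
        )

    cache: dict = {}
    keep = []
    for rec in records.itertuples():
        dam_id, sire_id = parents_of[rec.offspring_id]
        key = (dam_id, sire_id, rec.marker_id)
        if key not in cache:
            dg = lut.get((dam_id, rec.marker_id))
            sg = lut.get((sire_id, rec.marker_id))
            if which == "heterozygous_parents":
                cache[key] = is_het(dg) and is_het(sg)
            else:
                if dg is None or sg is None:
                    cache[key] = False
                else:
                    shared_aus = any(
                        a > 0
                        and a in sg
                        and registry.origin(rec.marker_id, a) == AUS
                        for a in set(dg)
                    )
                    cache[key] = not shared_aus
        keep.append(cache[key])
    return records[pd.Series(keep, index=records.index)].reset_index(drop=True)
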