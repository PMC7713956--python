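"""Screen for chromosomal abnormalities from marker genotypes.

Microsatellite length genotypes carry no dosage, so ploidy errors are
visible only through the number of *distinct* alleles per marker:

* >= 3 distinct alleles at a marker imply >= 3 chromosome copies there;
* triploidy is called when at least 2 chromosomes show 3 alleles,
  tetraploidy when at least 2 show 4, trisomy when exactly one shows 3;
* haploidy when every marker shows a single allele, all attributable to
  one parent; monosomy when one chromosome shows single-parent-only
  inheritance against a heterozygous-parent expectation.

The mechanism of a doubled parental contribution is read off
centromere-linked markers (tight linkage, <= 5 cM by default): a
contributor heterozygous there shows *both* homologs under MI
nondisjunction, a *single* allele under MII nondisjunction, and an
independent mixture across chromosomes under polyspermy (paternal only).
Calls carry an informative-marker count because parents homozygous at
the diagnostic markers leave the mechanism undetermined.

Following the study convention, a transmission record is excluded only
when the parent contributing the abnormal chromosome set is a hybrid or
backcrossed individual, and only for the affected chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model import Dataset

HYBRID_COHORTS = ("F1", "BC1", "BC2")


@dataclass
class ScreenConfig:
    min_multiallelic_chromosomes: int = 2  # for ploidy-level calls
    mechanism_max_cm: float = 5.0          # centromere linkage for mechanism
    min_haploidy_markers: int = 3          # exclusive markers needed per parent
    min_monosomy_markers: int = 2


@dataclass
class AnomalyCall:
    offspring_id: str
    type: str  # tetraploidy | triploidy | haploidy | trisomy | monosomy
    chromosomes: list  # ["all"] for ploidy-level types
    contributing_parent: str  # "dam" | "sire" | "unknown"
    mechanism: str = "unknown"
    informative_markers: int = 0
    note: str = ""


def _distinct_real(alleles: tuple) -> set:
    return {a for a in alleles if a > 0}


def detect_anomalies(ds: Dataset, config: ScreenConfig | None = None) -> list:
    """Detect non-diploid offspring; report-only.

    Length genotypes cannot reveal isodisomic errors (two copies of one
    chromatid in a parent homozygous at the diagnostic markers), so every
    call carries the count of markers that informed it.
    """
    cfg = config or ScreenConfig()
    lut = ds.genotype_lookup()
    minfo = ds.marker_info()
    calls: list[AnomalyCall] = []

    for r in ds.individuals.itertuples():
        if r.dam_id is None or r.sire_id is None:
            continue
        geno = {
            m: _distinct_real(lut[(r.individual_id, m)])
            for m in minfo
            if (r.individual_id, m) in lut
        }
        if not geno:
            continue
        chrom_max: dict = {}
        for m, alleles in geno.items():
            c = minfo[m].chromosome
            chrom_max[c] = max(chrom_max.get(c, 0), len(alleles))
        multi3 = sorted(c for c, v in chrom_max.items() if v >= 3)
        multi4 = sorted(c for c, v in chrom_max.items() if v >= 4)

        call = None
        if len(multi4) >= cfg.min_multiallelic_chromosomes:
            call = AnomalyCall(r.individual_id, "tetraploidy", ["all"], "unknown")
        elif len(multi3) >= cfg.min_multiallelic_chromosomes:
            call = AnomalyCall(r.individual_id, "triploidy", ["all"], "unknown")
        elif len(multi3) == 1:
            call = AnomalyCall(r.individual_id, "trisomy", multi3, "unknown")
        else:
            call = _haploidy_or_monosomy(r, geno, lut, minfo, cfg)
        if call is None:
            continue
        if call.type in ("tetraploidy", "triploidy", "trisomy"):
            _attribute_contributor(call, r, geno, lut, minfo)
            classify_mechanism(call, ds, cfg, _ctx=(r, geno, lut, minfo))
        calls.append(call)
    return calls


def _haploidy_or_monosomy(r, geno, lut, minfo, cfg):
    dam = {m: _distinct_real(lut.get((r.dam_id, m), ())) for m in geno}
    sire = {m: _distinct_real(lut.get((r.sire_id, m), ())) for m in geno}

    if all(len(a) == 1 for a in geno.values()):
        # haploidy: single allele everywhere, one parent explains all
        dam_only = sire_only = 0
        explained = {"dam": True, "sire": True}
        for m, alleles in geno.items():
            a = next(iter(alleles))
            in_d, in_s = a in dam.get(m, ()), a in sire.get(m, ())
            if in_d and not in_s:
                dam_only += 1
            elif in_s and not in_d:
                sire_only += 1
            if not in_d:
                explained["dam"] = False
            if not in_s:
                explained["sire"] = False
        if explained["dam"] and not explained["sire"] and dam_only >= cfg.min_haploidy_markers:
            return AnomalyCall(r.individual_id, "haploidy", ["all"], "dam",
                               informative_markers=dam_only)
        if explained["sire"] and not explained["dam"] and sire_only >= cfg.min_haploidy_markers:
            return AnomalyCall(r.individual_id, "haploidy", ["all"], "sire",
                               informative_markers=sire_only)
        return None

    # monosomy: one chromosome single-parent-only against het expectation
    by_chrom: dict = {}
    for m in geno:
        by_chrom.setdefault(minfo[m].chromosome, []).append(m)
    hits = []
    for chrom, ms in by_chrom.items():
        if minfo[ms[0]].is_z_linked or len(ms) < cfg.min_monosomy_markers:
            continue
        if not all(len(geno[m]) == 1 for m in ms):
            continue
        lost = None
        informative = 0
        consistent = True
        for m in ms:
            a = next(iter(geno[m]))
            in_d, in_s = a in dam.get(m, ()), a in sire.get(m, ())
            if in_d and not in_s and len(sire.get(m, ())) == 2:
                side, informative = "sire", informative + 1
            elif in_s and not in_d and len(dam.get(m, ())) == 2:
                side, informative = "dam", informative + 1
            elif in_d or in_s:
                continue  # uninformative marker (shared or hom parent)
            else:
                consistent = False
                break
            if lost is None:
                lost = side
            elif lost != side:
                consistent = False
                break
        if consistent and lost is not None and informative >= cfg.min_monosomy_markers:
            hits.append((chrom, lost, informative))
    if len(hits) == 1:
        chrom, lost, informative = hits[0]
        return AnomalyCall(
            r.individual_id, "monosomy", [chrom], lost,
            informative_markers=informative,
            note="dropout can mimic monosomy; dosage unavailable",
        )
    return None


def _attribute_contributor(call, r, geno, lut, minfo):
    """Which parent contributed two gametes' worth of alleles?

    At a marker with >= 3 distinct alleles, two of them belong to the
    doubled contributor; majority vote across such markers.
    """
    votes = {"dam": 0, "sire": 0}
    for m, alleles in geno.items():
        if len(alleles) < 3:
            continue
        dam = _distinct_real(lut.get((r.dam_id, m), ()))
        sire = _distinct_real(lut.get((r.sire_id, m), ()))
        from_dam_only = {a for a in alleles if a in dam and a not in sire}
        from_sire_only = {a for a in alleles if a in sire and a not in dam}
        if len(from_dam_only) >= 2 and len(from_sire_only) < 2:
            votes["dam"] += 1
        elif len(from_sire_only) >= 2 and len(from_dam_only) < 2:
            votes["sire"] += 1
    if votes["dam"] > votes["sire"]:
        call.contributing_parent = "dam"
    elif votes["sire"] > votes["dam"]:
        call.contributing_parent = "sire"


def classify_mechanism(call: AnomalyCall, ds: Dataset,
                       config: ScreenConfig | None = None, _ctx=None):
    """Assign MI/MII nondisjunction or polyspermy to an extra-set call.

    Uses centromere-linked markers where the contributor is heterozygous:
    both contributor homologs present at every such marker -> MI; a
    single contributor allele at every such marker -> MII; an
    independent mixture (paternal contributor) -> polyspermy.
    """
    cfg = config or ScreenConfig()
    if call.contributing_parent not in ("dam", "sire"):
        call.mechanism = "unknown"
        return call
    if _ctx is not None:
        r, geno, lut, minfo = _ctx
    else:
        lut = ds.genotype_lookup()
        minfo = ds.marker_info()
        row = ds.individuals[
            ds.individuals["individual_id"] == call.offspring_id
        ].iloc[0]
        r = row
        geno = {
            m: _distinct_real(lut[(call.offspring_id, m)])
            for m in minfo
            if (call.offspring_id, m) in lut
        }
    if call.contributing_parent == "dam":
        parent_id, other_id = r.dam_id, r.sire_id
    else:
        parent_id, other_id = r.sire_id, r.dam_id
    relevant = None if call.chromosomes == ["all"] else set(call.chromosomes)

    n_both = n_single = 0
    for m, alleles in geno.items():
        info = minfo[m]
        if info.position_class != "centromeric" or info.cm_from_centromere > cfg.mechanism_max_cm:
            continue
        if info.is_z_linked:
            continue
        if relevant is not None and info.chromosome not in relevant:
            continue
        pg = _distinct_real(lut.get((parent_id, m), ()))
        if len(pg) != 2:
            continue  # contributor homozygous: uninformative
        og = _distinct_real(lut.get((other_id, m), ()))
        if pg & og:
            continue  # shared length with the partner: not diagnostic
        present = pg & alleles
        if len(present) == 2:
            n_both += 1
        elif len(present) == 1:
            n_single += 1
    call.informative_markers = n_both + n_single
    if call.informative_markers == 0:
        call.mechanism = "unknown"
    elif n_single == 0:
        call.mechanism = "MI_nondisjunction"
    elif n_both == 0:
        call.mechanism = "MII_nondisjunction"
    elif call.contributing_parent == "sire":
        call.mechanism = "polyspermy"
    else:
        call.mechanism = "unknown"
    return call


@dataclass
class ExclusionResult:
    records: pd.DataFrame
    dropped: pd.DataFrame
    excluded_pairs: set = field(default_factory=set)


def exclusion_set(calls: list, ds: Dataset, hybrid_parent_ids: set | None = None) -> set:
    """(offspring_id, chromosome) pairs to drop from transmission counting.

    A pair is excluded iff the parent contributing the abnormal set is a
    hybrid/backcross individual; an unresolved contributor is excluded
    conservatively when either parent is one.
    """
    if hybrid_parent_ids is None:
        hybrid_parent_ids = set(
            ds.individuals.loc[
                ds.individuals["cohort"].isin(HYBRID_COHORTS), "individual_id"
            ]
        )
    parents_of = {
        r.individual_id: {"dam": r.dam_id, "sire": r.sire_id}
        for r in ds.individuals.itertuples()
    }
    all_chroms = ds.markers["chromosome"].unique().tolist()
    excl = set()
    for call in calls:
        parents = parents_of[call.offspring_id]
        if call.contributing_parent in ("dam", "sire"):
            contributor_hybrid = parents[call.contributing_parent] in hybrid_parent_ids
        else:
            contributor_hybrid = any(p in hybrid_parent_ids for p in parents.values())
        if not contributor_hybrid:
            continue
        chroms = all_chroms if call.chromosomes == ["all"] else call.chromosomes
        for c in chroms:
            excl.add((call.offspring_id, c))
    return excl


def apply_exclusions(records: pd.DataFrame, calls: list, ds: Dataset,
                     hybrid_parent_ids: set | None = None) -> ExclusionResult:
    """Drop transmission records on chromosomes affected by an abnormality
    contributed by a hybrid/backcross parent; drops are ledgered."""
    excl = exclusion_set(calls, ds, hybrid_parent_ids)
    if not excl or not len(records):
        return ExclusionResult(records=records.copy(),
                               dropped=records.iloc[0:0].copy(),
                               excluded_pairs=excl)
    mask = [
        (r.offspring_id, r.chromosome) in excl for r in records.itertuples()
    ]
    mask = pd.Series(mask, index=records.index)
    return ExclusionResult(
        records=records[~mask].reset_index(drop=True),
        dropped=records[mask].reset_index(drop=True),
        excluded_pairs=excl,
    )


def calls_to_frame(calls: list) -> pd.DataFrame:
    rows = [
        (
            c.offspring_id, c.type, ",".join(map(str, c.chromosomes)),
            c.contributing_parent, c.mechanism, c.informative_markers, c.note,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["offspring_id", "type", "chromosomes", "contributing_parent",
                 "mechanism", "informative_markers", "note"],
    )
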