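"""Forward simulator of the hybrid backcross breeding design.

Emulates the study system: two Timor founders crossed to Australian
birds give an F1 generation (11 birds, 7 m / 4 f), F1 hybrids are
backcrossed to Australian partners (~443 BC1-generation egg samples, 51
adults), and BC1 birds are backcrossed again (~905 BC2-generation
samples).  Meiosis is simulated explicitly on the four-chromatid bundle
of each ZW/ZZ parent, with configurable segregation bias:

* MI drive — in females, the homolog whose centromere is of the focal
  (Australian) origin enters the oocyte with probability ``d`` instead
  of 0.5; marker alleles travel with the chromatid they sit on, given
  the simulated crossover.
* MII drive — when a crossover between centromere and distal locus has
  made the retained dyad heterozygous at the distal locus, the chromatid
  carrying the focal origin is retained with probability ``d``;
  otherwise segregation is fair (the neocentromere mechanism needs that
  crossover).

Nuisance processes mirror the field realities of such a dataset:
apparently infertile eggs (~12 %), allelic dropouts, genotyping
failures, chromosomal abnormalities (triploidy etc. with an MI / MII /
polyspermy mechanism mix), optional inbreeding-linked mortality, and a
small heterozygous Australian admixture in one Timor founder (~4.78 %
of the diploid genome).  Every stochastic event is written to a truth
log so downstream inference can be validated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import Dataset, NULL_ALLELE, W_PLACEHOLDER

AUS_ORG = 0
TIM_ORG = 1
_ORG_NAME = {AUS_ORG: "AUS", TIM_ORG: "TIM"}

W_HAP = ("W",)  # sentinel haplotype for the female-specific W chromosome

MI_STAGE = "MI_centromere"
MII_STAGE = "MII_distal"


class ConfigError(ValueError):
    """Invalid simulator configuration."""


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromSpec:
    name: str
    centro_marker: str
    centro_cm: float
    distal_marker: str | None
    distal_cm: float | None
    is_z: bool

    @property
    def arm_length(self) -> float:
        # one obligate crossover on a 50-cM arm puts a 50-cM marker at r = 0.5
        return max(50.0, self.distal_cm or 0.0)


# centromeric offsets (<= 27 cM, median 0) and distal positions
# (>= 18 cM, median 50) for the full 29-chromosome map
_CENTRO_TAIL = [2, 3, 4, 6, 8, 10, 12, 14, 16, 18, 21, 24, 27]
_DISTAL_SUB50 = {13: 18, 14: 22, 15: 26, 16: 30, 17: 34, 18: 38,
                 19: 42, 20: 46, 21: 39, 22: 33, 23: 43, 24: 46}


def default_marker_map(n_chromosomes: int = 29, include_z: bool = True):
    """Build the marker map: one centromeric marker per chromosome and a
    distal marker on all but the last two autosomes.

    Returns (markers DataFrame, list of ChromSpec).  The full default
    (29 chromosomes incl. Z) gives 29 centromeric and 27 distal markers
    with centromeric median 0 cM and distal median 50 cM.
    """
    if n_chromosomes < 1:
        raise ConfigError("need at least one chromosome")
    n_autosomes = n_chromosomes - 1 if include_z else n_chromosomes
    names = [f"chr{i}" for i in range(1, n_autosomes + 1)]
    if include_z:
        names.append("chrZ")

    specs, rows = [], []
    no_distal = set(names[n_autosomes - 2:n_autosomes]) if n_autosomes >= 2 else set()
    for idx, name in enumerate(names, start=1):
        is_z = name == "chrZ"
        if is_z or idx <= 15:
            c_cm = 0.0
        else:
            c_cm = float(_CENTRO_TAIL[(idx - 16) % len(_CENTRO_TAIL)])
        cm_id = f"{name}_cen"
        specs_kwargs = dict(name=name, centro_marker=cm_id, centro_cm=c_cm, is_z=is_z)
        rows.append((cm_id, name, "centromeric", c_cm, is_z))
        if name in no_distal:
            specs.append(ChromSpec(distal_marker=None, distal_cm=None, **specs_kwargs))
            continue
        if is_z:
            d_cm = 50.0
        else:
            d_cm = float(_DISTAL_SUB50.get(idx, 50.0))
        d_cm = max(d_cm, c_cm + 17.0)  # minimum inter-marker distance
        d_id = f"{name}_dis"
        rows.append((d_id, name, "distal", d_cm, is_z))
        specs.append(ChromSpec(distal_marker=d_id, distal_cm=d_cm, **specs_kwargs))

    markers = pd.DataFrame(
        rows,
        columns=["marker_id", "chromosome", "position_class",
                 "cm_from_centromere", "is_z_linked"],
    )
    return markers, specs


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CrossConfig:
    """All simulator parameters; defaults reproduce the study design."""

    # cohort sizes
    n_f1: int = 11
    f1_males: int = 7
    f1_females: int = 4
    bc1_samples: int = 443
    bc1_adult_males: int = 26
    bc1_adult_females: int = 25
    bc1_breeder_males: int = 18
    bc1_breeder_females: int = 23
    bc2_samples: int = 905
    n_aus_founders: int = 100

    # marker map and allele pools
    n_chromosomes: int = 29
    include_z: bool = True
    n_alleles_aus: int = 8
    n_alleles_tim: int = 3
    allele_overlap_fraction: float = 0.1

    # meiosis
    drive: dict = field(default_factory=dict)  # (chrom|'all', sex, stage) -> d
    crossover_model: str = "obligate_one"  # or "poisson"
    w_transmission_rate: float = 0.5

    # nuisance processes
    infertile_egg_rate: float = 0.12
    null_allele_rate: float = 0.02
    genotype_missing_rate: float = 0.01
    dead_chick_fraction: float = 0.1
    embryo_mortality_rate: float = 0.0
    inbreeding_penalty: float = 0.0
    abnormality_rates: dict = field(
        default_factory=lambda: {
            "triploidy": 0.015,
            "trisomy": 0.008,
            "haploidy": 0.003,
            "monosomy": 0.002,
            "tetraploidy": 0.001,
        }
    )
    mechanism_mix: dict = field(
        default_factory=lambda: {
            "MI_nondisjunction": 0.4,
            "MII_nondisjunction": 0.3,
            "polyspermy": 0.3,
        }
    )
    founder_introgression: float = 0.0478

    apply_nuisance: bool = True
    track_truth: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        rates = {
            "infertile_egg_rate": self.infertile_egg_rate,
            "null_allele_rate": self.null_allele_rate,
            "genotype_missing_rate": self.genotype_missing_rate,
            "dead_chick_fraction": self.dead_chick_fraction,
            "embryo_mortality_rate": self.embryo_mortality_rate,
            "inbreeding_penalty": self.inbreeding_penalty,
            "founder_introgression": self.founder_introgression,
            "w_transmission_rate": self.w_transmission_rate,
            **{f"abnormality[{k}]": v for k, v in self.abnormality_rates.items()},
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        for n in (self.n_f1, self.bc1_samples, self.bc2_samples, self.n_aus_founders):
            if n < 1:
                raise ConfigError("cohort sizes must be positive")
        if self.f1_males + self.f1_females != self.n_f1:
            raise ConfigError("f1_males + f1_females must equal n_f1")
        if self.bc1_adult_males + self.bc1_adult_females > self.bc1_samples:
            raise ConfigError("more BC1 adults requested than samples")
        if (self.bc1_breeder_males > self.bc1_adult_males
                or self.bc1_breeder_females > self.bc1_adult_females):
            raise ConfigError("more BC1 breeders than adults (mothers missing)")
        need_partners = 2 + self.n_f1 + self.bc1_breeder_males + self.bc1_breeder_females
        if need_partners > self.n_aus_founders:
            raise ConfigError(
                f"{need_partners} Australian partners needed but only "
                f"{self.n_aus_founders} founders configured"
            )
        for (chrom, sex, stage), d in self.drive.items():
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"drive d = {d} outside [0, 1]")
            if stage not in (MI_STAGE, MII_STAGE):
                raise ConfigError(f"unknown drive stage {stage!r}")
            if sex == "M":
                raise ConfigError(
                    "drive is female-specific (asymmetric meiosis); male "
                    "transmission biases are post-meiotic and out of scope"
                )
        if self.crossover_model not in ("obligate_one", "poisson"):
            raise ConfigError(f"unknown crossover model {self.crossover_model!r}")
        total_abn = sum(self.abnormality_rates.values())
        if total_abn > 1.0:
            raise ConfigError("abnormality rates sum above 1")

    def d_for(self, chrom: str, sex: str, stage: str) -> float:
        if sex != "F":
            return 0.5
        for key in ((chrom, "F", stage), ("all", "F", stage)):
            if key in self.drive:
                return self.drive[key]
        return 0.5

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["drive"] = [
            {"chromosome": c, "parent_sex": s, "stage": st, "d": v}
            for (c, s, st), v in self.drive.items()
        ]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CrossConfig":
        data = dict(data)
        drive_list = data.pop("drive", [])
        if isinstance(drive_list, dict):
            drive = dict(drive_list)
        else:
            drive = {
                (e["chromosome"], e["parent_sex"], e["stage"]): float(e["d"])
                for e in drive_list
            }
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(drive=drive, **data)

    @classmethod
    def from_yaml(cls, path) -> "CrossConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthLog:
    """Ground truth for every meiosis and injected nuisance event."""

    meioses: pd.DataFrame
    transmissions: pd.DataFrame
    nuisance: pd.DataFrame
    genomes: dict = field(default_factory=dict, repr=False, compare=False)
    introgressed_markers: set = field(default_factory=set)
    anomalies: pd.DataFrame | None = None

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "truth_log.tsv"
        self.meioses.to_csv(path, sep="\t", index=False)
        self.transmissions.to_csv(out / "truth_transmissions.tsv", sep="\t", index=False)
        self.nuisance.to_csv(out / "truth_nuisance.tsv", sep="\t", index=False)
        return path


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def gamete_batch(
    hap_a,
    hap_b,
    n: int,
    rng: np.random.Generator,
    *,
    female: bool,
    d_mi: float = 0.5,
    d_mii: float = 0.5,
    centro_cm: float = 0.0,
    distal_cm: float | None = None,
    arm_length: float = 50.0,
    model: str = "obligate_one",
    w_rate: float = 0.5,
    forced_w=None,
):
    """Vectorised simulation of ``n`` independent meioses of one parent
    chromosome pair.

    Haplotypes are tuples (centro_len, centro_org, distal_len,
    distal_org); ``hap_b`` may be the W sentinel for a female Z.  Returns
    a dict of arrays: transmitted alleles/origins, crossover position,
    retained homolog, whether the recombinant chromatid was chosen, the
    MII-heterozygosity flag and (Z/W only) the W indicator.
    """
    out: dict = {}
    if hap_b == W_HAP:
        # female Z/W: no recombination modelled between Z and W
        if forced_w is not None:
            is_w = np.asarray(forced_w, dtype=bool)
        else:
            is_w = rng.random(n) < w_rate
        out["is_w"] = is_w
        out["c_len"] = np.where(is_w, W_PLACEHOLDER, hap_a[0])
        out["c_org"] = np.where(is_w, -1, hap_a[1])
        out["d_len"] = np.where(is_w, W_PLACEHOLDER, hap_a[2])
        out["d_org"] = np.where(is_w, -1, hap_a[3])
        out["x"] = np.full(n, np.nan)
        out["homolog"] = np.where(is_w, 1, 0)
        out["recomb"] = np.zeros(n, dtype=bool)
        out["mii_het"] = np.zeros(n, dtype=bool)
        return out

    if model == "poisson":
        cols = ("c_len", "c_org", "d_len", "d_org", "x", "homolog", "recomb", "mii_het")
        acc = {k: [] for k in cols}
        for _ in range(n):
            g = _meiosis_single_poisson(
                hap_a, hap_b, rng, d_mi=d_mi, d_mii=d_mii, female=female,
                centro_cm=centro_cm, distal_cm=distal_cm, arm_length=arm_length,
            )
            for k in cols:
                acc[k].append(g[k])
        out = {k: np.asarray(v) for k, v in acc.items()}
        out["is_w"] = np.zeros(n, dtype=bool)
        return out
    if model != "obligate_one":
        raise ConfigError(f"unknown crossover model {model!r}")

    L = arm_length
    x = rng.uniform(0.0, L, n)

    # MI: retain the homolog whose centromere has the focal (AUS) origin
    # with probability d (drive only exists in females)
    if female and hap_a[1] != hap_b[1]:
        p_a = d_mi if hap_a[1] == AUS_ORG else 1.0 - d_mi
    else:
        p_a = 0.5
    keep_a = rng.random(n) < p_a
    homolog = np.where(keep_a, 0, 1)

    ca, cb = (hap_a, hap_b)
    c_len_h = np.where(keep_a, ca[0], cb[0])
    c_org_h = np.where(keep_a, ca[1], cb[1])
    c_len_o = np.where(keep_a, cb[0], ca[0])
    c_org_o = np.where(keep_a, cb[1], ca[1])
    d_len_h = np.where(keep_a, ca[2], cb[2])
    d_org_h = np.where(keep_a, ca[3], cb[3])
    d_len_o = np.where(keep_a, cb[2], ca[2])
    d_org_o = np.where(keep_a, cb[3], ca[3])

    # retained dyad = plain sister + the crossover-involved sister whose
    # segment beyond x comes from the other homolog
    if distal_cm is not None:
        recombines_distal = x < distal_cm
        mii_het = recombines_distal & (np.asarray(d_org_h) != np.asarray(d_org_o))
        p_recomb = np.full(n, 0.5)
        if female and d_mii != 0.5:
            # pick the AUS-carrying chromatid with probability d_mii
            plain_is_aus = np.asarray(d_org_h) == AUS_ORG
            p_recomb = np.where(
                mii_het, np.where(plain_is_aus, 1.0 - d_mii, d_mii), 0.5
            )
    else:
        mii_het = np.zeros(n, dtype=bool)
        p_recomb = np.full(n, 0.5)
    recomb = rng.random(n) < p_recomb

    swap_c = recomb & (centro_cm > x)
    out["c_len"] = np.where(swap_c, c_len_o, c_len_h)
    out["c_org"] = np.where(swap_c, c_org_o, c_org_h)
    if distal_cm is not None:
        swap_d = recomb & (distal_cm > x)
        out["d_len"] = np.where(swap_d, d_len_o, d_len_h)
        out["d_org"] = np.where(swap_d, d_org_o, d_org_h)
    else:
        out["d_len"] = np.full(n, -1)
        out["d_org"] = np.full(n, -1)
    out["x"] = x
    out["homolog"] = homolog
    out["recomb"] = recomb
    out["mii_het"] = mii_het
    out["is_w"] = np.zeros(n, dtype=bool)
    return out


def _meiosis_single_poisson(
    hap_a, hap_b, rng, *, d_mi, d_mii, female, centro_cm, distal_cm, arm_length
):
    """One meiosis under the Poisson crossover model (no interference).

    Bundle crossover rate lambda = L/50 makes the expected exchanges per
    chromatid L/100 Morgans, which reproduces Haldane's map function for
    any marker position.
    """
    L = arm_length
    positions = np.sort(rng.uniform(0.0, L, rng.poisson(L / 50.0)))
    # source homolog per chromatid at each tracked position
    tracked = [centro_cm] + ([distal_cm] if distal_cm is not None else [])
    src = np.array([[0] * len(tracked), [0] * len(tracked),
                    [1] * len(tracked), [1] * len(tracked)])
    for xpos in positions:
        i = rng.integers(0, 2)      # sister of homolog A
        j = rng.integers(2, 4)      # sister of homolog B
        for t, m in enumerate(tracked):
            if m > xpos:
                src[i, t], src[j, t] = src[j, t], src[i, t]
    if female and hap_a[1] != hap_b[1]:
        p_a = d_mi if hap_a[1] == AUS_ORG else 1.0 - d_mi
    else:
        p_a = 0.5
    dyad = (0, 1) if rng.random() < p_a else (2, 3)
    haps = (hap_a, hap_b)
    if distal_cm is not None:
        d_orgs = [haps[src[c, 1]][3] for c in dyad]
        het = d_orgs[0] != d_orgs[1]
        if het and female and d_mii != 0.5:
            aus_first = d_orgs[0] == AUS_ORG
            p_first = d_mii if aus_first else 1.0 - d_mii
            chosen = dyad[0] if rng.random() < p_first else dyad[1]
        else:
            chosen = dyad[rng.integers(0, 2)]
    else:
        het = False
        chosen = dyad[rng.integers(0, 2)]
    c_hap = haps[src[chosen, 0]]
    res = {
        "c_len": c_hap[0], "c_org": c_hap[1],
        "x": positions[0] if len(positions) else np.nan,
        "homolog": 0 if chosen in (0, 1) else 1,
        "recomb": bool(len(positions)), "mii_het": bool(het),
    }
    if distal_cm is not None:
        d_hap = haps[src[chosen, 1]]
        res["d_len"], res["d_org"] = d_hap[2], d_hap[3]
    else:
        res["d_len"], res["d_org"] = -1, -1
    return res


def simulate_meiosis(genome: dict, parent_sex: str, cfg: CrossConfig,
                     specs: list, rng: np.random.Generator) -> dict:
    """Simulate one complete gamete of a parent.

    ``genome`` maps chromosome name -> (hap_a, hap_b).  Returns
    chromosome -> transmitted (c_len, c_org, d_len, d_org) plus, for a
    female Z, the W indicator under key ``("chrZ", "is_w")``-style entry
    ``is_w``.
    """
    gamete = {}
    for spec in specs:
        hap_a, hap_b = genome[spec.name]
        g = gamete_batch(
            hap_a, hap_b, 1, rng,
            female=parent_sex == "F",
            d_mi=cfg.d_for(spec.name, parent_sex, MI_STAGE),
            d_mii=cfg.d_for(spec.name, parent_sex, MII_STAGE),
            centro_cm=spec.centro_cm, distal_cm=spec.distal_cm,
            arm_length=spec.arm_length, model=cfg.crossover_model,
            w_rate=cfg.w_transmission_rate,
        )
        gamete[spec.name] = {k: v[0] for k, v in g.items()}
    return gamete


# ---------------------------------------------------------------------------
# cross simulation
# ---------------------------------------------------------------------------

class _Builder:
    """Mutable accumulation state while a cross is generated."""

    def __init__(self, cfg: CrossConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.markers, self.specs = default_marker_map(
            cfg.n_chromosomes, cfg.include_z
        )
        self.ped_rows: list = []  # (id, sex, dam, sire, cohort, fate)
        self.genomes: dict = {}
        self.truth_meiosis: list = []     # column arrays, concatenated later
        self.truth_trans: list = []
        self.nuisance_rows: list = []
        self.anomaly_rows: list = []
        self.geno_frames: list = []       # per-generation genotype frames
        self.introgressed_markers: set = set()
        self.pools: dict = {}             # marker -> (aus lengths, tim lengths)

    # -- founders ---------------------------------------------------------
    def build_pools(self):
        cfg, rng = self.cfg, self.rng
        marker_ids = self.markers["marker_id"].tolist()
        n_overlap = int(round(cfg.allele_overlap_fraction * len(marker_ids)))
        overlap_markers = set(
            rng.choice(marker_ids, size=n_overlap, replace=False)
        ) if n_overlap else set()
        for i, m in enumerate(marker_ids):
            aus = [150 + 4 * j for j in range(cfg.n_alleles_aus)]
            tim = [250 + 4 * j for j in range(cfg.n_alleles_tim)]
            if m in overlap_markers:
                tim[0] = aus[0]  # shared length between the pools
            self.pools[m] = (aus, tim)

    def founder_genome(self, origin: int, sex: str) -> dict:
        """Draw a founder genome; alleles uniform over the pool."""
        rng = self.rng
        genome = {}
        for spec in self.specs:
            pool_idx = 0 if origin == AUS_ORG else 1
            ca = self.pools[spec.centro_marker][pool_idx]
            da = self.pools[spec.distal_marker][pool_idx] if spec.distal_marker else None

            def hap():
                c = int(rng.choice(ca))
                d = int(rng.choice(da)) if da is not None else -1
                return (c, origin, d, origin if da is not None else -1)

            if spec.is_z and sex == "F":
                genome[spec.name] = (hap(), W_HAP)
            else:
                genome[spec.name] = (hap(), hap())
        return genome

    def apply_introgression(self, tim_id: str):
        """Give one Timor founder heterozygous Australian segments."""
        cfg, rng = self.cfg, self.rng
        p_marker = min(1.0, 2.0 * cfg.founder_introgression)
        if p_marker <= 0:
            return
        genome = self.genomes[tim_id]
        novel_next = [max(a for aus, _ in self.pools.values() for a in aus) + 2]
        for spec in self.specs:
            hap_a, hap_b = genome[spec.name]
            if hap_b == W_HAP:
                continue
            for pos, marker in ((0, spec.centro_marker),
                                (2, spec.distal_marker)):
                if marker is None or rng.random() >= p_marker:
                    continue
                aus_pool = self.pools[marker][0]
                if rng.random() < 0.5:
                    new_len = int(rng.choice(aus_pool))
                else:
                    new_len = novel_next[0]  # AUS haplotype never sampled
                    novel_next[0] += 2       # among the AUS founders
                hap = list(hap_a)
                hap[pos] = new_len
                hap[pos + 1] = AUS_ORG
                hap_a = tuple(hap)
                self.introgressed_markers.add(marker)
            genome[spec.name] = (hap_a, hap_b)

    def add_individual(self, iid, sex, dam, sire, cohort, fate, genome):
        self.ped_rows.append((iid, sex, dam, sire, cohort, fate))
        self.genomes[iid] = genome

    def genotype_frame_for(self, ids: list) -> pd.DataFrame:
        """Materialise true genotypes (with per-allele origins) for ids."""
        rows = []
        for iid in ids:
            genome = self.genomes[iid]
            for spec in self.specs:
                hap_a, hap_b = genome[spec.name]
                for pos, marker in ((0, spec.centro_marker), (2, spec.distal_marker)):
                    if marker is None:
                        continue
                    if hap_b == W_HAP:
                        a1, o1 = W_PLACEHOLDER, -1
                    else:
                        a1, o1 = hap_b[pos], hap_b[pos + 1]
                    rows.append((iid, marker, hap_a[pos], hap_a[pos + 1], a1, o1))
        return pd.DataFrame(
            rows, columns=["individual_id", "marker_id", "mat", "mat_org", "pat", "pat_org"]
        )

    # -- offspring generation --------------------------------------------
    def produce(self, dam_id, sire_id, n, cohort, id_start, forced_sexes=None):
        """Generate n offspring of one pair; returns their ids and a
        genotype frame (columns mat/pat hold dam/sire gamete alleles)."""
        cfg, rng = self.cfg, self.rng
        ids = [f"{cohort}_{id_start + i:05d}" for i in range(n)]
        col_ind, col_marker, col_mat, col_mat_org, col_pat, col_pat_org = \
            [], [], [], [], [], []
        sexes = None
        offspring_genomes = [dict() for _ in range(n)]
        for spec in self.specs:
            gametes = {}
            for parent_id, parent_sex in ((dam_id, "F"), (sire_id, "M")):
                hap_a, hap_b = self.genomes[parent_id][spec.name]
                fw = None
                if spec.is_z and parent_sex == "F" and forced_sexes is not None:
                    fw = np.array([s == "F" for s in forced_sexes])
                g = gamete_batch(
                    hap_a, hap_b, n, rng,
                    female=parent_sex == "F",
                    d_mi=cfg.d_for(spec.name, parent_sex, MI_STAGE),
                    d_mii=cfg.d_for(spec.name, parent_sex, MII_STAGE),
                    centro_cm=spec.centro_cm, distal_cm=spec.distal_cm,
                    arm_length=spec.arm_length, model=cfg.crossover_model,
                    w_rate=cfg.w_transmission_rate, forced_w=fw,
                )
                gametes[parent_sex] = g
                if cfg.track_truth:
                    self.truth_meiosis.append(
                        (
                            np.asarray(ids, dtype=object),
                            np.full(n, parent_id, dtype=object),
                            np.full(n, spec.name, dtype=object),
                            g["homolog"].astype(int),
                            np.round(np.asarray(g["x"], dtype=float), 4),
                            g["recomb"].astype(bool),
                            g["mii_het"].astype(bool),
                            g["is_w"].astype(bool),
                        )
                    )
            gm, gp = gametes["F"], gametes["M"]
            if spec.is_z:
                sexes = np.where(gm["is_w"], "F", "M")
            for i in range(n):
                pat_hap = (int(gp["c_len"][i]), int(gp["c_org"][i]),
                           int(gp["d_len"][i]), int(gp["d_org"][i]))
                if spec.is_z and gm["is_w"][i]:
                    # ZW daughter: single Z (paternal), W second by convention
                    offspring_genomes[i][spec.name] = (pat_hap, W_HAP)
                else:
                    mat_hap = (int(gm["c_len"][i]), int(gm["c_org"][i]),
                               int(gm["d_len"][i]), int(gm["d_org"][i]))
                    offspring_genomes[i][spec.name] = (mat_hap, pat_hap)
            for key_c, key_o, marker in (
                ("c_len", "c_org", spec.centro_marker),
                ("d_len", "d_org", spec.distal_marker),
            ):
                if marker is None:
                    continue
                col_ind.append(np.asarray(ids, dtype=object))
                col_marker.append(np.full(n, marker, dtype=object))
                col_mat.append(gm[key_c].astype(int))
                col_mat_org.append(gm[key_o].astype(int))
                col_pat.append(gp[key_c].astype(int))
                col_pat_org.append(gp[key_o].astype(int))
                if cfg.track_truth:
                    self.truth_trans.append(
                        (
                            np.asarray(ids, dtype=object),
                            np.full(n, dam_id, dtype=object),
                            np.full(n, marker, dtype=object),
                            gm[key_c].astype(int),
                            gm[key_o].astype(int),
                        )
                    )
                    self.truth_trans.append(
                        (
                            np.asarray(ids, dtype=object),
                            np.full(n, sire_id, dtype=object),
                            np.full(n, marker, dtype=object),
                            gp[key_c].astype(int),
                            gp[key_o].astype(int),
                        )
                    )
        # the maternal Z gamete fixes the sex; flip the W slot genotypes
        if sexes is None:
            sexes = np.where(rng.random(n) < 0.5, "F", "M")
        if forced_sexes is not None:
            sexes = np.asarray(forced_sexes)
        for i, iid in enumerate(ids):
            self.ped_rows.append(
                (iid, str(sexes[i]), dam_id, sire_id, cohort, "sampled_embryo")
            )
            self.genomes[iid] = offspring_genomes[i]
        frame = pd.DataFrame(
            {
                "individual_id": np.concatenate(col_ind),
                "marker_id": np.concatenate(col_marker),
                "mat": np.concatenate(col_mat),
                "mat_org": np.concatenate(col_mat_org),
                "pat": np.concatenate(col_pat),
                "pat_org": np.concatenate(col_pat_org),
            }
        )
        return ids, frame


def _split_even(total: int, parts: int) -> list:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_cross(cfg: CrossConfig, rng: np.random.Generator | None = None):
    """Run the full breeding design; returns (Dataset, TruthLog)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    b = _Builder(cfg, rng)
    b.build_pools()

    # founders
    aus_ids = []
    for i in range(cfg.n_aus_founders):
        sex = "F" if i % 2 == 0 else "M"
        iid = f"AUS_{sex}{i:03d}"
        b.add_individual(iid, sex, None, None, "FOUNDER_AUS", "adult",
                         b.founder_genome(AUS_ORG, sex))
        aus_ids.append(iid)
    aus_f = [i for i in aus_ids if i.startswith("AUS_F")]
    aus_m = [i for i in aus_ids if i.startswith("AUS_M")]
    tim_m, tim_f = "TIM_M000", "TIM_F000"
    b.add_individual(tim_m, "M", None, None, "FOUNDER_TIM", "adult",
                     b.founder_genome(TIM_ORG, "M"))
    b.add_individual(tim_f, "F", None, None, "FOUNDER_TIM", "adult",
                     b.founder_genome(TIM_ORG, "F"))
    b.apply_introgression(tim_m)  # one admixed Timor founder

    partners_f = iter(aus_f)
    partners_m = iter(aus_m)

    # F1: two Timor x Australian pairs produce the 11 adults (sexes fixed
    # by design counts; the study's F1 cohort is conditioned on maturity)
    f1_sexes = ["M"] * cfg.f1_males + ["F"] * cfg.f1_females
    rng.shuffle(f1_sexes)
    n_pair1 = (cfg.n_f1 + 1) // 2
    f1_ids = []
    for (dam, sire), count, sexes in (
        ((next(partners_f), tim_m), n_pair1, f1_sexes[:n_pair1]),
        ((tim_f, next(partners_m)), cfg.n_f1 - n_pair1, f1_sexes[n_pair1:]),
    ):
        if count == 0:
            continue
        ids, frame = b.produce(dam, sire, count, "F1", len(f1_ids) + 1,
                               forced_sexes=sexes)
        b.geno_frames.append(frame)
        f1_ids.extend(ids)
    _set_fate(b, f1_ids, "adult")

    # BC1 generation: each F1 backcrossed to an Australian founder
    bc1_ids = _breed_generation(
        b, f1_ids, partners_f, partners_m, cfg.bc1_samples, "BC1", rng
    )
    _apply_generation_nuisance(b, bc1_ids, "BC1")
    bc1_adults = _select_adults(
        b, bc1_ids, cfg.bc1_adult_males, cfg.bc1_adult_females
    )
    breeders = _select_breeders(
        b, bc1_adults, cfg.bc1_breeder_males, cfg.bc1_breeder_females
    )

    # BC2 generation
    bc2_ids = _breed_generation(
        b, breeders, partners_f, partners_m, cfg.bc2_samples, "BC2", rng
    )
    _apply_generation_nuisance(b, bc2_ids, "BC2")

    # founders and F1 are genotyped too; dropouts can hit them as well
    parent_frame = b.genotype_frame_for(aus_ids + [tim_m, tim_f])
    b.geno_frames.insert(0, parent_frame)
    if cfg.apply_nuisance:
        _mask_nulls(b, parent_frame, rng)

    return _finalise(b)


def _set_fate(b: _Builder, ids, fate):
    idset = set(ids)
    b.ped_rows = [
        (i, s, d, si, c, fate if i in idset else f)
        for (i, s, d, si, c, f) in b.ped_rows
    ]


def _breed_generation(b, hybrid_parents, partners_f, partners_m, n_samples,
                      cohort, rng):
    cfg = b.cfg
    sex_of = {r[0]: r[1] for r in b.ped_rows}
    n_eggs_total = (
        int(round(n_samples / (1.0 - cfg.infertile_egg_rate)))
        if cfg.apply_nuisance else n_samples
    )
    counts = _split_even(n_eggs_total, len(hybrid_parents))
    ids = []
    start = 1
    for hybrid, n in zip(hybrid_parents, counts):
        if n == 0:
            continue
        if sex_of[hybrid] == "F":
            dam, sire = hybrid, next(partners_m)
        else:
            dam, sire = next(partners_f), hybrid
        new_ids, frame = b.produce(dam, sire, n, cohort, start)
        b.geno_frames.append(frame)
        ids.extend(new_ids)
        start += n
    return ids


def _generation_frames(b: _Builder, ids) -> list:
    idset = set(ids)
    return [f for f in b.geno_frames if f["individual_id"].iloc[0] in idset]


def _apply_generation_nuisance(b: _Builder, ids, cohort, protected=frozenset()):
    if not b.cfg.apply_nuisance:
        return
    cfg, rng = b.cfg, b.rng
    frames = _generation_frames(b, ids)
    frame = pd.concat(frames, ignore_index=True)
    # replace the per-pair frames with the merged, mutated one
    drop_ids = {id(f) for f in frames}
    b.geno_frames = [f for f in b.geno_frames if id(f) not in drop_ids]
    # infertile eggs: unfertilised, no genotype, unknown sex
    infertile = [
        i for i in ids
        if rng.random() < cfg.infertile_egg_rate and i not in protected
    ]
    inf_set = set(infertile)
    for iid in infertile:
        b.nuisance_rows.append((iid, "", "infertile_egg", ""))
    b.ped_rows = [
        (i, "U" if i in inf_set else s, d, si, c,
         "infertile_egg" if i in inf_set else f)
        for (i, s, d, si, c, f) in b.ped_rows
    ]
    frame = frame[~frame["individual_id"].isin(inf_set)].reset_index(drop=True)

    fertile = [i for i in ids if i not in inf_set]
    frame = _inject_abnormalities(b, frame, [i for i in fertile if i not in protected])
    _apply_mortality(b, frame, [i for i in fertile if i not in protected])
    _mask_nulls(b, frame, rng)
    if cfg.genotype_missing_rate > 0:
        drop = rng.random(len(frame)) < cfg.genotype_missing_rate
        for r in frame[drop].itertuples():
            b.nuisance_rows.append(
                (r.individual_id, r.marker_id, "genotype_missing", "")
            )
        frame = frame[~drop].reset_index(drop=True)
    b.geno_frames.append(frame)


def _mask_nulls(b: _Builder, frame: pd.DataFrame, rng):
    """Allelic dropout: one allele of a genotype fails to amplify, the
    record becomes an apparent homozygote."""
    rate = b.cfg.null_allele_rate
    if rate <= 0:
        return
    ok = (
        (frame["mat"] > 0) & (frame["pat"] > 0)
        & (~frame.get("extra", pd.Series("", index=frame.index)).astype(bool))
    )
    hit = ok & (rng.random(len(frame)) < rate)
    if not hit.any():
        return
    mask_mat = rng.random(len(frame)) < 0.5
    was_het = frame["mat"] != frame["pat"]
    for r in frame[hit & was_het].itertuples():
        b.nuisance_rows.append(
            (r.individual_id, r.marker_id, "null_masked",
             f"hidden={r.mat if mask_mat[r.Index] else r.pat}")
        )
    idx_m = hit & mask_mat
    idx_p = hit & ~mask_mat
    frame.loc[idx_m, "mat"] = frame.loc[idx_m, "pat"]
    frame.loc[idx_m, "mat_org"] = frame.loc[idx_m, "pat_org"]
    frame.loc[idx_p, "pat"] = frame.loc[idx_p, "mat"]
    frame.loc[idx_p, "pat_org"] = frame.loc[idx_p, "mat_org"]


def _apply_mortality(b: _Builder, frame: pd.DataFrame, fertile):
    """Optional inbreeding-linked death: offspring homozygous
    identical-by-state for an Australian allele die with extra probability."""
    cfg, rng = b.cfg, b.rng
    dead = set()
    if cfg.inbreeding_penalty > 0:
        hom_aus = frame[
            (frame["mat"] == frame["pat"]) & (frame["mat"] > 0)
            & (frame["mat_org"] == AUS_ORG) & (frame["pat_org"] == AUS_ORG)
        ]["individual_id"].unique()
        for iid in hom_aus:
            if rng.random() < cfg.inbreeding_penalty:
                dead.add(iid)
                b.nuisance_rows.append((iid, "", "inbreeding_death", ""))
    if cfg.embryo_mortality_rate > 0:
        for iid in fertile:
            if iid not in dead and rng.random() < cfg.embryo_mortality_rate:
                dead.add(iid)
                b.nuisance_rows.append((iid, "", "random_death", ""))
    if dead:
        b.ped_rows = [
            (i, s, d, si, c, "dead_chick" if i in dead else f)
            for (i, s, d, si, c, f) in b.ped_rows
        ]


def _select_adults(b: _Builder, ids, n_males, n_females):
    info = {r[0]: (r[1], r[5]) for r in b.ped_rows}
    eligible = [i for i in ids if info[i][1] == "sampled_embryo"]
    males = [i for i in eligible if info[i][0] == "M"][:n_males]
    females = [i for i in eligible if info[i][0] == "F"][:n_females]
    adults = males + females
    _set_fate(b, adults, "adult")
    return adults


def _select_breeders(b: _Builder, adults, n_males, n_females):
    sex_of = {r[0]: r[1] for r in b.ped_rows}
    males = [i for i in adults if sex_of[i] == "M"][:n_males]
    females = [i for i in adults if sex_of[i] == "F"][:n_females]
    return males + females


# -- chromosomal abnormalities ----------------------------------------------

def _extra_chromatid(b: _Builder, offspring_id, parent_id, spec, mechanism):
    """Alleles of the additional chromatid implied by a nondisjunction,
    reconstructed from the logged meiosis of this offspring/parent."""
    rng = b.rng
    rec = b._meiosis_lookup.get((offspring_id, parent_id, spec.name))
    if rec is None:
        return None
    homolog, x, recomb = rec
    hap_a, hap_b = b.genomes[parent_id][spec.name]
    if W_HAP in (hap_a, hap_b):
        return None
    hap_h = hap_a if homolog == 0 else hap_b
    hap_o = hap_b if homolog == 0 else hap_a

    def chromatid(base, other, recombinant):
        if not recombinant or math.isnan(x):
            return base
        c = base[0] if spec.centro_cm <= x else other[0]
        if spec.distal_cm is None:
            return (c, base[1], -1, -1)
        d = base[2] if spec.distal_cm <= x else other[2]
        return (c, base[1], d, base[3])

    if mechanism == "MII_nondisjunction":
        # the sister of the transmitted chromatid stays in the egg
        return chromatid(hap_h, hap_o, not recomb)
    # MI nondisjunction: a chromatid of the other homolog stays
    return chromatid(hap_o, hap_h, bool(rng.integers(0, 2)))


def _fresh_gamete(b: _Builder, parent_id, parent_sex):
    return {
        spec.name: _single_gamete(b, parent_id, parent_sex, spec)
        for spec in b.specs
    }


def _single_gamete(b, parent_id, parent_sex, spec):
    cfg = b.cfg
    hap_a, hap_b = b.genomes[parent_id][spec.name]
    g = gamete_batch(
        hap_a, hap_b, 1, b.rng, female=parent_sex == "F",
        d_mi=cfg.d_for(spec.name, parent_sex, MI_STAGE),
        d_mii=cfg.d_for(spec.name, parent_sex, MII_STAGE),
        centro_cm=spec.centro_cm, distal_cm=spec.distal_cm,
        arm_length=spec.arm_length, model=cfg.crossover_model,
        w_rate=cfg.w_transmission_rate,
    )
    return (int(g["c_len"][0]), int(g["c_org"][0]),
            int(g["d_len"][0]), int(g["d_org"][0]))


def _inject_abnormalities(b: _Builder, frame: pd.DataFrame, fertile):
    cfg, rng = b.cfg, b.rng
    total = sum(cfg.abnormality_rates.values())
    if total <= 0 or not fertile:
        return frame
    types = list(cfg.abnormality_rates)
    probs = np.array([cfg.abnormality_rates[t] for t in types]) / total
    mechs = list(cfg.mechanism_mix)
    mech_p = np.array([cfg.mechanism_mix[m] for m in mechs])
    mech_p = mech_p / mech_p.sum()

    hit = [i for i in fertile if rng.random() < total]
    hit_set = set(hit)

    # lookup of logged meioses (hit offspring only) for chromatid reconstruction
    b._meiosis_lookup = {}
    for cols in b.truth_meiosis:
        ids_arr, par_arr, chrom_arr, hom_arr, x_arr, rec_arr = cols[:6]
        for i in range(len(ids_arr)):
            if ids_arr[i] in hit_set:
                b._meiosis_lookup[(ids_arr[i], par_arr[i], chrom_arr[i])] = (
                    int(hom_arr[i]), float(x_arr[i]), bool(rec_arr[i])
                )

    frame = frame.copy()
    frame["extra"] = ""
    idx_map = {
        (r.individual_id, r.marker_id): r.Index for r in frame.itertuples()
    }
    parents_of = {r[0]: (r[2], r[3]) for r in b.ped_rows}
    autosomal = [s for s in b.specs if not s.is_z]

    for iid in hit:
        atype = types[int(rng.choice(len(types), p=probs))]
        dam_id, sire_id = parents_of[iid]
        if atype in ("triploidy", "trisomy", "tetraploidy"):
            mech = mechs[int(rng.choice(len(mechs), p=mech_p))]
            if mech == "polyspermy":
                parent, parent_sex = sire_id, "M"
            else:
                parent, parent_sex = (dam_id, "F") if rng.random() < 0.5 else (sire_id, "M")
            chroms = autosomal if atype != "trisomy" else \
                [autosomal[int(rng.integers(0, len(autosomal)))]]
            _add_extra_set(b, frame, idx_map, iid, parent, parent_sex, chroms, mech)
            if atype == "tetraploidy":
                # a second paternal gamete on top of the doubled set
                other = sire_id if parent != sire_id else dam_id
                other_sex = "M" if other == sire_id else "F"
                _add_extra_set(b, frame, idx_map, iid, other, other_sex,
                               autosomal, "polyspermy")
            affected = "all" if atype != "trisomy" else chroms[0].name
        elif atype == "haploidy":
            # androgenetic: only the paternal contribution develops
            mech, parent = "unknown", sire_id
            for spec in b.specs:
                for marker in (spec.centro_marker, spec.distal_marker):
                    if marker is None or (iid, marker) not in idx_map:
                        continue
                    ridx = idx_map[(iid, marker)]
                    frame.loc[ridx, ["mat", "mat_org"]] = (
                        frame.loc[ridx, "pat"], frame.loc[ridx, "pat_org"]
                    )
            _set_sex(b, iid, "U")
            affected = "all"
        else:  # monosomy
            mech = "unknown"
            spec = autosomal[int(rng.integers(0, len(autosomal)))]
            lost_dam = rng.random() < 0.5
            parent = dam_id if lost_dam else sire_id
            keep, keep_org = ("pat", "pat_org") if lost_dam else ("mat", "mat_org")
            for marker in (spec.centro_marker, spec.distal_marker):
                if marker is None or (iid, marker) not in idx_map:
                    continue
                ridx = idx_map[(iid, marker)]
                val, org = frame.loc[ridx, keep], frame.loc[ridx, keep_org]
                frame.loc[ridx, ["mat", "pat"]] = (val, val)
                frame.loc[ridx, ["mat_org", "pat_org"]] = (org, org)
            affected = spec.name
        b.anomaly_rows.append((iid, atype, affected, parent, mech))
        b.nuisance_rows.append((iid, "", f"abnormality_{atype}",
                                f"parent={parent};mechanism={mech}"))
    return frame


def _add_extra_set(b, frame, idx_map, iid, parent_id, parent_sex, chroms, mech):
    for spec in chroms:
        if mech == "polyspermy":
            extra = _single_gamete(b, parent_id, parent_sex, spec)
        else:
            extra = _extra_chromatid(b, iid, parent_id, spec, mech)
        if extra is None:
            continue
        for pos, marker in ((0, spec.centro_marker), (2, spec.distal_marker)):
            if marker is None or (iid, marker) not in idx_map:
                continue
            ridx = idx_map[(iid, marker)]
            allele = int(extra[pos])
            if allele <= 0:
                continue
            present = {int(frame.at[ridx, "mat"]), int(frame.at[ridx, "pat"])}
            extras = frame.at[ridx, "extra"]
            if extras:
                present |= {int(a) for a in extras.split(",")}
            if allele in present:
                continue  # same length: invisible without dosage
            frame.at[ridx, "extra"] = (
                f"{extras},{allele}" if extras else str(allele)
            )


def _set_sex(b: _Builder, iid, sex):
    b.ped_rows = [
        (i, sex if i == iid else s, d, si, c, f)
        for (i, s, d, si, c, f) in b.ped_rows
    ]


# -- finalisation -----------------------------------------------------------

def _finalise(b: _Builder):
    geno = pd.concat(b.geno_frames, ignore_index=True)
    if "extra" not in geno.columns:
        geno["extra"] = ""
    geno["extra"] = geno["extra"].fillna("")
    a1 = np.minimum(geno["mat"], geno["pat"])
    a2 = np.maximum(geno["mat"], geno["pat"])
    genotypes = pd.DataFrame(
        {
            "individual_id": geno["individual_id"],
            "marker_id": geno["marker_id"],
            "allele1": a1.astype(int),
            "allele2": a2.astype(int),
            "extra_alleles": geno["extra"],
        }
    )
    individuals = pd.DataFrame(
        b.ped_rows,
        columns=["individual_id", "sex", "dam_id", "sire_id", "cohort", "fate"],
    )
    ds = Dataset(individuals=individuals, genotypes=genotypes, markers=b.markers)
    ds.validate()

    if b.truth_meiosis:
        cols = list(zip(*b.truth_meiosis))
        meioses = pd.DataFrame(
            {
                "offspring_id": np.concatenate(cols[0]),
                "parent_id": np.concatenate(cols[1]),
                "chromosome": np.concatenate(cols[2]),
                "homolog_retained": np.concatenate(cols[3]),
                "crossover_cm": np.concatenate(cols[4]),
                "chromatid_recombinant": np.concatenate(cols[5]),
                "mii_het": np.concatenate(cols[6]),
                "is_w": np.concatenate(cols[7]),
            }
        )
    else:
        meioses = pd.DataFrame(
            columns=["offspring_id", "parent_id", "chromosome", "homolog_retained",
                     "crossover_cm", "chromatid_recombinant", "mii_het", "is_w"]
        )
    if b.truth_trans:
        cols = list(zip(*b.truth_trans))
        trans = pd.DataFrame(
            {
                "offspring_id": np.concatenate(cols[0]),
                "parent_id": np.concatenate(cols[1]),
                "marker_id": np.concatenate(cols[2]),
                "allele": np.concatenate(cols[3]),
                "origin": np.concatenate(cols[4]),
            }
        )
        trans["origin"] = trans["origin"].map(lambda o: _ORG_NAME.get(int(o), "W"))
    else:
        trans = pd.DataFrame(
            columns=["offspring_id", "parent_id", "marker_id", "allele", "origin"]
        )
    nuis = pd.DataFrame(
        b.nuisance_rows, columns=["individual_id", "marker_id", "event", "detail"]
    )
    anomalies = pd.DataFrame(
        b.anomaly_rows,
        columns=["individual_id", "type", "affected", "contributing_parent",
                 "mechanism"],
    )
    truth = TruthLog(
        meioses=meioses, transmissions=trans, nuisance=nuis,
        genomes=b.genomes, introgressed_markers=b.introgressed_markers,
        anomalies=anomalies,
    )
    return ds, truth


def _specs_from_markers(markers: pd.DataFrame) -> list:
    specs = []
    for chrom, grp in markers.groupby("chromosome", sort=False):
        cen = grp[grp["position_class"] == "centromeric"].iloc[0]
        dis_rows = grp[grp["position_class"] == "distal"]
        dis = dis_rows.iloc[0] if len(dis_rows) else None
        specs.append(
            ChromSpec(
                name=chrom,
                centro_marker=cen["marker_id"],
                centro_cm=float(cen["cm_from_centromere"]),
                distal_marker=None if dis is None else dis["marker_id"],
                distal_cm=None if dis is None else float(dis["cm_from_centromere"]),
                is_z=bool(cen["is_z_linked"]),
            )
        )
    return specs


_ORG_CODE = {"AUS": AUS_ORG, "TIM": TIM_ORG, "W": -1}


def inject_nuisance(ds: Dataset, truth: TruthLog, cfg: CrossConfig,
                    rng: np.random.Generator):
    """Apply the nuisance processes to a clean simulated dataset.

    ``ds``/``truth`` must come from a ``apply_nuisance=False`` run with
    truth tracking on (the genomes and per-meiosis records are needed to
    build abnormal chromosome sets consistently).  Individuals that
    appear as parents in the pedigree are never flagged infertile or
    dead — they demonstrably reproduced.  Returns (Dataset, TruthLog).
    """
    if not truth.genomes or not len(truth.meioses):
        raise ConfigError("inject_nuisance needs a truth log with genomes "
                          "and meiosis records (track_truth=True)")
    cfg = CrossConfig.from_dict({**cfg.to_dict(), "apply_nuisance": True})
    b = _Builder(cfg, rng)
    b.markers = ds.markers.copy()
    b.specs = _specs_from_markers(ds.markers)
    b.ped_rows = [
        (r.individual_id, r.sex, r.dam_id, r.sire_id, r.cohort, r.fate)
        for r in ds.individuals.itertuples()
    ]
    b.genomes = truth.genomes
    m = truth.meioses
    b.truth_meiosis = [
        (
            m["offspring_id"].to_numpy(dtype=object),
            m["parent_id"].to_numpy(dtype=object),
            m["chromosome"].to_numpy(dtype=object),
            m["homolog_retained"].to_numpy(),
            m["crossover_cm"].to_numpy(dtype=float),
            m["chromatid_recombinant"].to_numpy(dtype=bool),
            m["mii_het"].to_numpy(dtype=bool),
            m["is_w"].to_numpy(dtype=bool),
        )
    ]
    cohort_of = dict(zip(ds.individuals["individual_id"], ds.individuals["cohort"]))
    dam_of = dict(zip(ds.individuals["individual_id"], ds.individuals["dam_id"]))

    parent_ids = [
        i for i, c in cohort_of.items()
        if c in ("FOUNDER_AUS", "FOUNDER_TIM", "F1")
    ]
    b.geno_frames = [b.genotype_frame_for(parent_ids)]

    t = truth.transmissions.copy()
    t["cohort"] = t["offspring_id"].map(cohort_of)
    t["role"] = np.where(
        t["parent_id"] == t["offspring_id"].map(dam_of), "mat", "pat"
    )
    t["org_code"] = t["origin"].map(_ORG_CODE)
    generations = []
    for cohort in ("BC1", "BC2"):
        sub = t[t["cohort"] == cohort]
        if not len(sub):
            continue
        wide = sub.pivot_table(
            index=["offspring_id", "marker_id"], columns="role",
            values=["allele", "org_code"], aggfunc="first",
        ).reset_index()
        frame = pd.DataFrame(
            {
                "individual_id": wide["offspring_id"],
                "marker_id": wide["marker_id"],
                "mat": wide[("allele", "mat")].astype(int),
                "mat_org": wide[("org_code", "mat")].astype(int),
                "pat": wide[("allele", "pat")].astype(int),
                "pat_org": wide[("org_code", "pat")].astype(int),
            }
        )
        b.geno_frames.append(frame)
        generations.append((cohort, sorted(frame["individual_id"].unique())))

    protected = (
        set(ds.individuals["dam_id"].dropna())
        | set(ds.individuals["sire_id"].dropna())
    )
    _mask_nulls(b, b.geno_frames[0], rng)
    for cohort, ids in generations:
        _apply_generation_nuisance(b, ids, cohort, protected=protected)
    b.truth_meiosis = []  # keep the original truth tables
    out_ds, out_truth = _finalise(b)
    out_truth.meioses = truth.meioses
    out_truth.transmissions = truth.transmissions
    out_truth.introgressed_markers = truth.introgressed_markers
    return out_ds, out_truth


def draw_infertile_flags(n_eggs: int, rate: float, rng) -> np.ndarray:
    """Per-egg Bernoulli infertility flags (apparent infertility)."""
    if not 0 <= rate <= 1:
        raise ConfigError("infertile rate outside [0, 1]")
    return rng.random(n_eggs) < rate


# ---------------------------------------------------------------------------
# SNP site table for the introgression scan
# ---------------------------------------------------------------------------

def simulate_snp_sites(
    rng: np.random.Generator,
    n_chromosomes: int = 20,
    chrom_length: int = 25_000_000,
    window: int = 500_000,
    introgressed_diploid_fraction: float = 0.0478,
    specific_rate_background: float = 300.0,
    specific_rate_introgressed: float = 20.0,
):
    """Simulate Timor-specific SNP counts along a genome with
    heterozygous Australian tracts.

    Heterozygous tracts cover twice the diploid admixture fraction of
    the genome length.  Returns (sites DataFrame with columns chromosome,
    position, focal_state, present_in_reference_pool; chrom_lengths
    dict; true diploid admixed fraction).
    """
    p_window = min(1.0, 2.0 * introgressed_diploid_fraction)
    chrom_lengths = {f"chr{i}": chrom_length for i in range(1, n_chromosomes + 1)}
    rows = []
    n_windows_total = 0
    n_introgressed = 0
    for chrom, length in chrom_lengths.items():
        n_windows = math.ceil(length / window)
        n_windows_total += n_windows
        for wi in range(n_windows):
            start = wi * window
            end = min(length, start + window)
            introg = rng.random() < p_window
            n_introgressed += introg
            mu = specific_rate_introgressed if introg else specific_rate_background
            count = rng.poisson(mu * (end - start) / window)
            pos = np.sort(rng.integers(start, end, count))
            for p in pos:
                rows.append((chrom, int(p), "hom_nonref", False))
    sites = pd.DataFrame(
        rows,
        columns=["chromosome", "position", "focal_state",
                 "present_in_reference_pool"],
    )
    true_fraction = n_introgressed / n_windows_total / 2.0
    return sites, chrom_lengths, true_fraction
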