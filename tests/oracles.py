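"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected behaviour from first principles
(exhaustive enumeration, closed-form probability, direct integration)
without importing the implementation's algorithms.
"""

import itertools

NULL = 0
W = -1


def display(gf: int, gp: int):
    """Observed offspring genotype for focal gamete gf (a real allele)
    and partner gamete gp: a transmitted null leaves an apparent
    homozygote; a transmitted W is observed explicitly."""
    if gp == NULL:
        return (gf, gf)
    return tuple(sorted((gf, gp)))


def eligible_focal(genotype, origin_of):
    a = sorted(set(genotype))
    if len(genotype) != 2 or genotype[0] == genotype[1]:
        return False
    if any(x <= 0 for x in genotype):
        return False
    return {origin_of[genotype[0]], origin_of[genotype[1]]} == {"AUS", "TIM"}


def enumerate_pair(focal, partner, origin_of):
    """For every observed genotype, the set of focal origins consistent
    with some one-gamete-per-parent assignment."""
    out = {}
    for gf, gp in itertools.product(set(focal), set(partner)):
        obs = display(gf, gp)
        out.setdefault(obs, set()).add(origin_of[gf])
    return out


def oracle_classify(dam, sire, origin_of):
    """Brute-force pair classification, one entry per focal parent."""
    results = {}
    for name, focal, partner in (("dam", dam, sire), ("sire", sire, dam)):
        if not eligible_focal(focal, origin_of):
            continue
        mapping = enumerate_pair(focal, partner, origin_of)
        ambiguous = [o for o, origins in mapping.items() if len(origins) > 1]
        if not ambiguous:
            status = "fully_informative"
        elif sorted(set(focal)) == sorted(set(partner)):
            status = "partial_ABxAB"
        else:
            status = "uninformative"
        results[name] = (status, mapping)
    return results


def oracle_deduce(mapping, status, observed):
    """Brute-force deduction verdict for one observed genotype."""
    if status == "uninformative":
        return "excluded"
    origins = mapping.get(tuple(sorted(observed)))
    if origins is None:
        return "excluded"
    if len(origins) > 1:
        return "ambiguous"
    return 1 if next(iter(origins)) == "AUS" else 0


def all_genotypes(alleles, with_null=True, with_w=False):
    """All unordered diploid genotypes over an allele set (at most one
    placeholder per genotype)."""
    out = [tuple(sorted(p)) for p in itertools.combinations_with_replacement(alleles, 2)]
    if with_null:
        out += [tuple(sorted((NULL, a))) for a in alleles]
    if with_w:
        out += [tuple(sorted((W, a))) for a in alleles]
    return out


def mendelian_consistent(dam, sire, off):
    """Brute force: some one-allele-per-parent assignment explains the
    offspring, allowing an apparent homozygote to hide a parental null."""
    off_s = tuple(sorted(off))
    for gd, gs in itertools.product(set(dam), set(sire)):
        if tuple(sorted((gd, gs))) == off_s:
            return True
    if len(off_s) == 2 and off_s[0] == off_s[1] and off_s[0] > 0:
        x = off_s[0]
        if (x in dam and NULL in sire) or (x in sire and NULL in dam):
            return True
    return False


def bucket_counts(positions, length, window):
    """Direct interval bucketing of SNP positions into windows."""
    import math

    n = math.ceil(length / window)
    counts = [0] * n
    for p in positions:
        counts[p // window] += 1
    return counts


def obligate_one_centromeric_k(d, cm, arm=50.0):
    """P(AUS allele transmitted) for a marker ``cm`` from the centromere
    under MI drive d with one obligate crossover uniform on [0, arm]:
    the chosen chromatid is recombinant at the marker with probability
    r = cm / (2 * arm)."""
    r = cm / (2.0 * arm)
    return d * (1 - r) + (1 - d) * r


def obligate_one_mii_distal_k(d_mii, cm, arm=50.0):
    """P(AUS at a distal marker) under MII drive only: the retained dyad
    is heterozygous at the marker iff the crossover fell below it
    (probability cm/arm); drive applies only then."""
    p_het = cm / arm
    return p_het * d_mii + (1 - p_het) * 0.5
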