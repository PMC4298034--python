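"""Independent brute-force oracles, deliberately dumber than the package.

Everything here enumerates explicit genotype configurations (3^n vectors)
with plain loops/itertools, classifying each vector by literally counting
CC and heterozygous loci — no closed forms, no prefix-sum tricks — so these
results are an independent check on the package's algebra.
"""

from __future__ import annotations

import itertools

import numpy as np


def hwe(c: float) -> np.ndarray:
    return np.array([(1 - c) ** 2, 2 * c * (1 - c), c**2])


def mendel(a: int, b: int) -> np.ndarray:
    x, y = a / 2.0, b / 2.0
    return np.array([(1 - x) * (1 - y), x * (1 - y) + (1 - x) * y, x * y])


def penetrance_of_vector(genotype: tuple[int, ...], levels) -> float:
    """Damage rule read directly off the genotype vector."""
    if any(g == 2 for g in genotype):
        return levels[2]
    if any(g == 1 for g in genotype):
        return levels[1]
    return levels[0]


def enumerate_left_rate(c_values, levels) -> float:
    """Population left-handedness by exhaustive 3^n genotype enumeration."""
    total = 0.0
    per_locus = [hwe(c) for c in c_values]
    for genotype in itertools.product(range(3), repeat=len(c_values)):
        prob = 1.0
        for g, dist in zip(genotype, per_locus):
            prob *= dist[g]
        total += prob * penetrance_of_vector(genotype, levels)
    return total


def dz_single_locus(c: float, levels) -> tuple[float, float, float]:
    """Full-sibling pair distribution at one locus: enumerate all 3x3 ordered
    matings, 3x3 sibling genotype pairs, and 2x2 phenotype outcomes."""
    g = hwe(c)
    p_rr = p_rl = p_ll = 0.0
    for a in range(3):
        for b in range(3):
            seg = mendel(a, b)
            for o1 in range(3):
                for o2 in range(3):
                    w = g[a] * g[b] * seg[o1] * seg[o2]
                    p1, p2 = levels[o1], levels[o2]
                    p_rr += w * (1 - p1) * (1 - p2)
                    p_ll += w * p1 * p2
                    p_rl += w * (p1 * (1 - p2) + (1 - p1) * p2)
    return p_rr, p_rl, p_ll


def _genotype_vectors(n: int) -> np.ndarray:
    return np.array(list(itertools.product(range(3), repeat=n)), dtype=int)


def multilocus_family_enumeration(c: float, n: int, levels):
    """Exhaustive 3^n x 3^n x 3^n enumeration of (parent1, parent2,
    offspring) genotype vectors under random mating and free recombination.

    Returns offspring left-handedness by parental phenotype pair, the
    stratum probabilities, and the MZ/DZ pair distributions, all exact.
    Feasible up to n = 4 (531,441 parent-pair/offspring combinations).
    """
    vecs = _genotype_vectors(n)
    k = len(vecs)
    dist = hwe(c)
    pvec = np.prod(dist[vecs], axis=1)  # HWE probability of each vector
    seg = np.array([[mendel(a, b) for b in range(3)] for a in range(3)])
    # P(offspring vector | parents i, j) = product over loci of seg tables
    off_prob = np.ones((k, k, k))
    for locus in range(n):
        off_prob *= seg[vecs[:, locus][:, None, None], vecs[None, :, locus][:, :, None],
                        vecs[None, None, :, locus]]
    pen = np.array([penetrance_of_vector(tuple(v), levels) for v in vecs])
    mating = np.outer(pvec, pvec)

    pheno = {"R": 1 - pen, "L": pen}
    strata = {
        "RxR": np.outer(pheno["R"], pheno["R"]),
        "RxL": np.outer(pheno["R"], pheno["L"]) + np.outer(pheno["L"], pheno["R"]),
        "LxL": np.outer(pheno["L"], pheno["L"]),
    }
    family = {}
    stratum_prob = {}
    for label, w in strata.items():
        weight = mating * w
        stratum_prob[label] = weight.sum()
        off_left = np.einsum("ij,ijo,o->", weight, off_prob, pen)
        family[label] = off_left / weight.sum()

    # MZ: one shared genotype vector
    mz_rr = float(pvec @ (1 - pen) ** 2)
    mz_ll = float(pvec @ pen**2)
    mz = (mz_rr, 1 - mz_rr - mz_ll, mz_ll)
    # DZ: two offspring of the same mating, conditionally independent
    mean_pen = np.einsum("ijo,o->ij", off_prob, pen)
    dz_ll = float((mating * mean_pen**2).sum())
    dz_rr = float((mating * (1 - mean_pen) ** 2).sum())
    dz = (dz_rr, 1 - dz_rr - dz_ll, dz_ll)
    return {"family": family, "stratum_prob": stratum_prob, "mz": mz, "dz": dz}


def case_control_freqs_enumeration(c_values, levels) -> tuple[float, float]:
    """Allele frequency at locus 0 in left- and right-handers by exhaustive
    enumeration over all 3^n genotype vectors."""
    n = len(c_values)
    per_locus = [hwe(ci) for ci in c_values]
    num_l = num_r = den_l = den_r = 0.0
    for genotype in itertools.product(range(3), repeat=n):
        prob = 1.0
        for g, dist in zip(genotype, per_locus):
            prob *= dist[g]
        pen = penetrance_of_vector(genotype, levels)
        af = genotype[0] / 2.0
        num_l += prob * pen * af
        den_l += prob * pen
        num_r += prob * (1 - pen) * af
        den_r += prob * (1 - pen)
    return num_l / den_l, num_r / den_r
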