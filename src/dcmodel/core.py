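"""Exact single-locus dextral-chance (DC) model algebra.

The DC model describes handedness as the product of a single autosomal locus
with two alleles: D ("dextral"), which enforces right-handedness, and C
("chance"), which introduces irreducible randomness into lateralization.
The three genotypes DD, DC and CC are left-handed with probabilities 0, 1/4
and 1/2.  The CC phenotype is *deep chance* (fluctuating asymmetry): the
50:50 outcome reflects no residual genetic or environmental variance, so
conditional on genotype every phenotypic outcome — each twin of a pair, each
offspring, handedness and language dominance within one person — is an
independent Bernoulli draw.

Everything in this module is computed by exact enumeration over genotypes
under random mating and Hardy-Weinberg proportions; there is no simulation
here.  With the default penetrances and a chance-allele frequency of 20%,
population left-handedness is 10%, offspring of two right-handers are 7.78%
left-handed, offspring of two left-handers only 30%, monozygotic twin pairs
are 14% discordant and dizygotic pairs 16% — the classical, initially
puzzling, family and twin patterns of human handedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateConditionError, InvalidParameterError

__all__ = [
    "Hand",
    "Zygosity",
    "ParentPair",
    "PenetranceModel",
    "GenotypeDistribution",
    "TwinDistribution",
    "FamilyPrediction",
    "LateralizationTable",
    "hwe_genotypes",
    "population_left_rate",
    "genotype_given_hand",
    "offspring_left_rate",
    "family_prediction",
    "mz_twin_distribution",
    "dz_twin_distribution",
    "twin_distribution_by_parents",
    "lateralization_table",
]

_DIST_TOL = 1e-12


class Hand(str, Enum):
    R = "R"
    L = "L"


class Zygosity(str, Enum):
    MZ = "MZ"
    DZ = "DZ"


class ParentPair(str, Enum):
    """Unordered parental phenotype pair (no maternal/paternal distinction)."""

    RxR = "RxR"
    RxL = "RxL"
    LxL = "LxL"


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise InvalidParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class PenetranceModel:
    """Probability of the left/atypical phenotype for each genotype class.

    The same triple serves handedness (probability of left-handedness) and,
    through pleiotropy, language dominance (probability of right-hemisphere
    language).  Defaults are the standard DC values 0 / 0.25 / 0.5.
    """

    p_left_homozygous_major: float = 0.0  # DD
    p_left_heterozygous: float = 0.25  # DC
    p_left_homozygous_minor: float = 0.5  # CC

    def __post_init__(self) -> None:
        _check_prob(self.p_left_homozygous_major, "p_left_homozygous_major")
        _check_prob(self.p_left_heterozygous, "p_left_heterozygous")
        _check_prob(self.p_left_homozygous_minor, "p_left_homozygous_minor")

    def as_array(self) -> np.ndarray:
        """Penetrances indexed by genotype code 0=DD, 1=DC, 2=CC."""
        return np.array(
            [
                self.p_left_homozygous_major,
                self.p_left_heterozygous,
                self.p_left_homozygous_minor,
            ]
        )


@dataclass(frozen=True)
class GenotypeDistribution:
    p_dd: float
    p_dc: float
    p_cc: float

    def __post_init__(self) -> None:
        total = self.p_dd + self.p_dc + self.p_cc
        if abs(total - 1.0) > _DIST_TOL:
            raise InvalidParameterError(f"genotype distribution sums to {total!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_dd, self.p_dc, self.p_cc])


@dataclass(frozen=True)
class TwinDistribution:
    """Probabilities of the unordered pair phenotypes R-R, R-L and L-L."""

    p_rr: float
    p_rl: float
    p_ll: float
    zygosity: Zygosity

    def __post_init__(self) -> None:
        total = self.p_rr + self.p_rl + self.p_ll
        if abs(total - 1.0) > _DIST_TOL:
            raise InvalidParameterError(f"twin distribution sums to {total!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rr, self.p_rl, self.p_ll])


@dataclass(frozen=True)
class FamilyPrediction:
    """Left-handedness among offspring, by parental phenotype pair."""

    p_left_given_rr_parents: float
    p_left_given_rl_parents: float
    p_left_given_ll_parents: float

    def __getitem__(self, parents: ParentPair) -> float:
        return {
            ParentPair.RxR: self.p_left_given_rr_parents,
            ParentPair.RxL: self.p_left_given_rl_parents,
            ParentPair.LxL: self.p_left_given_ll_parents,
        }[ParentPair(parents)]


@dataclass(frozen=True)
class LateralizationTable:
    """Joint distribution of handedness and language dominance.

    Hand and language are each drawn independently given genotype, so the
    association between them arises purely through the shared genotype.
    """

    p_righthand_leftlang: float
    p_righthand_rightlang: float
    p_lefthand_leftlang: float
    p_lefthand_rightlang: float
    p_rightlang_given_righthand: float
    p_rightlang_given_lefthand: float

    def __post_init__(self) -> None:
        total = (
            self.p_righthand_leftlang
            + self.p_righthand_rightlang
            + self.p_lefthand_leftlang
            + self.p_lefthand_rightlang
        )
        if abs(total - 1.0) > _DIST_TOL:
            raise InvalidParameterError(f"lateralization joint sums to {total!r}, not 1")

    def joint(self) -> np.ndarray:
        """2x2 array indexed [hand, language] with 0=typical (R hand / left
        language) and 1=atypical (L hand / right language)."""
        return np.array(
            [
                [self.p_righthand_leftlang, self.p_righthand_rightlang],
                [self.p_lefthand_leftlang, self.p_lefthand_rightlang],
            ]
        )

    @property
    def p_lefthand(self) -> float:
        return self.p_lefthand_leftlang + self.p_lefthand_rightlang

    @property
    def p_rightlang(self) -> float:
        return self.p_righthand_rightlang + self.p_lefthand_rightlang


# Mendelian segregation: MENDEL[a, b, o] = P(offspring genotype o | parent
# genotypes a, b), genotypes coded as the number of C alleles (0, 1, 2).
_GAMETE_C = np.array([0.0, 0.5, 1.0])


def _mendel_table() -> np.ndarray:
    table = np.zeros((3, 3, 3))
    for a in range(3):
        for b in range(3):
            x, y = _GAMETE_C[a], _GAMETE_C[b]
            table[a, b] = [(1 - x) * (1 - y), x * (1 - y) + (1 - x) * y, x * y]
    return table


MENDEL = _mendel_table()


def hwe_genotypes(c: float) -> GenotypeDistribution:
    """Hardy-Weinberg genotype proportions ((1-c)^2, 2c(1-c), c^2) for
    chance-allele frequency ``c``."""
    c = _check_prob(c, "c")
    return GenotypeDistribution((1 - c) ** 2, 2 * c * (1 - c), c**2)


def population_left_rate(model: PenetranceModel, c: float) -> float:
    """Population prevalence of left-handedness, sum over genotypes of
    P(g) * P(L|g).  For the default penetrances this is exactly c/2."""
    g = hwe_genotypes(c).as_array()
    return float(g @ model.as_array())


def _phenotype_weights(model: PenetranceModel, hand: Hand) -> np.ndarray:
    p = model.as_array()
    return p if Hand(hand) is Hand.L else 1 - p


def genotype_given_hand(model: PenetranceModel, c: float, hand: Hand) -> GenotypeDistribution:
    """Bayes posterior over genotypes given the observed hand phenotype.

    Left-handers can only be DC or CC (the DD component of the posterior is
    zero under the default penetrances), and most are DC.
    """
    g = hwe_genotypes(c).as_array()
    w = g * _phenotype_weights(model, hand)
    total = w.sum()
    if total == 0.0:
        raise DegenerateConditionError(
            f"phenotype {Hand(hand).value} has probability zero under this model"
        )
    post = w / total
    return GenotypeDistribution(*post)


def _parent_pair_weights(model: PenetranceModel, c: float, parents: ParentPair) -> np.ndarray:
    """Joint weight over ordered parental genotype pairs (a, b): random-mating
    probability times the probability of the requested phenotype pair.

    Parental phenotypes are independent given their genotypes (the deep-chance
    assumption applied to the parents); "RxL" is unordered.
    """
    g = hwe_genotypes(c).as_array()
    p = model.as_array()
    mating = np.outer(g, g)
    parents = ParentPair(parents)
    if parents is ParentPair.RxR:
        pheno = np.outer(1 - p, 1 - p)
    elif parents is ParentPair.LxL:
        pheno = np.outer(p, p)
    else:
        pheno = np.outer(1 - p, p) + np.outer(p, 1 - p)
    w = mating * pheno
    if w.sum() == 0.0:
        raise DegenerateConditionError(
            f"parental phenotype pair {parents.value} has probability zero under this model"
        )
    return w


def offspring_left_rate(model: PenetranceModel, c: float, parents: ParentPair) -> float:
    """Expected left-handedness among offspring of a parental phenotype pair.

    Exact enumeration: parental genotype pairs under random mating are
    conditioned on the observed parental phenotypes, one offspring genotype is
    produced by Mendelian segregation, and its penetrance is averaged.
    """
    w = _parent_pair_weights(model, c, parents)
    offspring = np.einsum("ab,abo->o", w, MENDEL)
    return float(offspring @ model.as_array() / w.sum())


def family_prediction(model: PenetranceModel, c: float) -> FamilyPrediction:
    """Offspring left-handedness for all three parental phenotype pairs."""
    return FamilyPrediction(
        offspring_left_rate(model, c, ParentPair.RxR),
        offspring_left_rate(model, c, ParentPair.RxL),
        offspring_left_rate(model, c, ParentPair.LxL),
    )


def _pair_distribution(weights: np.ndarray, penetrance: np.ndarray) -> tuple[float, float, float]:
    """R-R / R-L / L-L probabilities for a genotype-class distribution.

    ``weights`` may be any non-negative weighting over genotype codes; it is
    normalized internally.  Both members of a pair draw their phenotype
    independently given genotype.
    """
    q = weights / weights.sum()
    p_rr = float(q @ (1 - penetrance) ** 2)
    p_ll = float(q @ penetrance**2)
    return p_rr, 1.0 - p_rr - p_ll, p_ll


def mz_twin_distribution(model: PenetranceModel, c: float) -> TwinDistribution:
    """Monozygotic pairs share one genotype; each twin's phenotype is an
    independent draw, so a DC pair is discordant with probability
    2 * (1/4) * (3/4) = 6/16."""
    g = hwe_genotypes(c).as_array()
    rr, rl, ll = _pair_distribution(g, model.as_array())
    return TwinDistribution(rr, rl, ll, Zygosity.MZ)


def dz_twin_distribution(model: PenetranceModel, c: float) -> TwinDistribution:
    """Dizygotic pairs modeled as full siblings: enumerate random-mating
    parental genotype pairs; given the parents, sibling genotypes are
    independent Mendelian draws and phenotypes independent given genotype."""
    g = hwe_genotypes(c).as_array()
    mating = np.outer(g, g)
    p = model.as_array()
    # siblings independent given mating: E[pen1*pen2] = E_mating[(mean offspring pen)^2]
    mean_pen = MENDEL @ p  # (a, b) -> expected offspring penetrance
    p_ll = float((mating * mean_pen**2).sum())
    p_rr = float((mating * (1 - mean_pen) ** 2).sum())
    return TwinDistribution(p_rr, 1.0 - p_rr - p_ll, p_ll, Zygosity.DZ)


def twin_distribution_by_parents(
    model: PenetranceModel, c: float, parents: ParentPair, zygosity: Zygosity
) -> TwinDistribution:
    """Twin pair distribution additionally conditioned on the parental
    phenotype pair.  Discordant pairs are more frequent when the parents are
    left-handed, because such parents carry more C alleles."""
    w = _parent_pair_weights(model, c, parents)
    p = model.as_array()
    zygosity = Zygosity(zygosity)
    if zygosity is Zygosity.MZ:
        shared = np.einsum("ab,abo->o", w, MENDEL)
        rr, rl, ll = _pair_distribution(shared, p)
    else:
        mean_pen = MENDEL @ p
        total = w.sum()
        ll = float((w * mean_pen**2).sum() / total)
        rr = float((w * (1 - mean_pen) ** 2).sum() / total)
        rl = 1.0 - rr - ll
    return TwinDistribution(rr, rl, ll, zygosity)


def lateralization_table(
    model: PenetranceModel,
    c: float,
    language_penetrance: PenetranceModel | None = None,
) -> LateralizationTable:
    """Joint distribution of handedness and language dominance under
    pleiotropy: both traits depend on the same genotype but are conditionally
    independent given it.

    By default language uses the handedness penetrances (DC and CC have 25%
    and 50% probability of right-hemisphere language).  The result is the
    counterintuitive empirical pattern: only a minority of left-handers are
    right-language dominant (30%), versus 7.8% of right-handers.
    """
    if language_penetrance is None:
        language_penetrance = model
    g = hwe_genotypes(c).as_array()
    ph = model.as_array()
    pl = language_penetrance.as_array()
    joint = np.einsum("g,gh,gl->hl", g, np.stack([1 - ph, ph], axis=1), np.stack([1 - pl, pl], axis=1))
    row_r, row_l = joint[0].sum(), joint[1].sum()
    if row_r == 0.0 or row_l == 0.0:
        raise DegenerateConditionError("one hand phenotype has probability zero; conditionals undefined")
    return LateralizationTable(
        p_righthand_leftlang=float(joint[0, 0]),
        p_righthand_rightlang=float(joint[0, 1]),
        p_lefthand_leftlang=float(joint[1, 0]),
        p_lefthand_rightlang=float(joint[1, 1]),
        p_rightlang_given_righthand=float(joint[0, 1] / row_r),
        p_rightlang_given_lefthand=float(joint[1, 1] / row_l),
    )
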