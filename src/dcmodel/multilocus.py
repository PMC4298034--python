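"""Multilocus DC model with the damage-precedence penetrance rule.

The single-locus DC model generalizes to n unlinked loci, each with a
dextral allele D_i and a rare chance allele C_i (frequency c_i).  Penetrance
follows a *damage rule* modeled on locus-heterogeneous disorders such as
primary ciliary dyskinesia: being C_iC_i at any locus is enough to randomize
lateralization completely (50% left-handed), regardless of how many further
loci are damaged; otherwise carrying a single C_i allele at any locus gives
the heterozygote penetrance (25%); individuals homozygous D_iD_i everywhere
are all right-handed.  An individual's phenotype therefore depends on its
genotype vector only through its *damage class*:

    class 2  -- at least one C_iC_i locus          (penetrance 0.5)
    class 1  -- no C_iC_i, at least one D_iC_i     (penetrance 0.25)
    class 0  -- D_iD_i at every locus              (penetrance 0)

Population prevalence has the closed form (for general, possibly unequal
frequencies; the equal-c case is the usual presentation)

    p(L) = l2 * [1 - prod_i (1 - c_i^2)]
         + l1 * [prod_i (1 - c_i^2) - prod_i (1 - c_i)^2]
         + l0 * prod_i (1 - c_i)^2

which is inverted for c by bracketed root search to produce the equal-c
frequency required for a target prevalence (e.g. 10% left-handedness needs
c = 0.2 at one locus but only c = 0.00025 at 1000 loci).

This module also provides *exact* family and twin predictions for any number
of loci.  Because loci are independent and phenotype depends only on the
damage class, the joint class distribution of a set of relatives is obtained
by prefix-summing the per-locus joint genotype distribution of those
relatives, raising to the n-th power (or multiplying across unequal loci)
and finite-differencing — an inclusion-exclusion over the events "no locus
is CC" and "every locus is DD".  These exact values back the Monte Carlo
simulator in :mod:`dcmodel.simulate` and reduce to the single-locus algebra
of :mod:`dcmodel.core` at n = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (
    MENDEL,
    FamilyPrediction,
    ParentPair,
    PenetranceModel,
    TwinDistribution,
    Zygosity,
    _check_prob,
    hwe_genotypes,
)
from .errors import DegenerateConditionError, InvalidParameterError, NoSolutionError

__all__ = [
    "MultilocusModel",
    "PrevalenceEquation",
    "damage_class",
    "damage_rule_penetrance",
    "left_rate_closed_form",
    "solve_equal_c",
    "sample_genotype",
    "meiosis",
    "exact_family_prediction",
    "family_stratum_probs",
    "exact_twin_distribution",
]

_SOLVER_XTOL = 1e-12


@dataclass(frozen=True)
class MultilocusModel:
    """n unlinked diallelic loci with chance-allele frequencies ``c_values``
    and a shared penetrance triple applied through the damage rule.

    ``MultilocusModel.equal(1, 0.2)`` is numerically identical to the
    single-locus model of :mod:`dcmodel.core`.
    """

    c_values: tuple[float, ...]
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)

    def __post_init__(self) -> None:
        if len(self.c_values) < 1:
            raise InvalidParameterError("a multilocus model needs at least one locus")
        object.__setattr__(
            self, "c_values", tuple(_check_prob(c, "c") for c in self.c_values)
        )

    @property
    def n_loci(self) -> int:
        return len(self.c_values)

    @property
    def is_equal_c(self) -> bool:
        return len(set(self.c_values)) == 1

    @classmethod
    def equal(
        cls, n_loci: int, c: float, penetrance: PenetranceModel | None = None
    ) -> "MultilocusModel":
        if n_loci < 1:
            raise InvalidParameterError("n_loci must be >= 1")
        return cls((float(c),) * int(n_loci), penetrance or PenetranceModel())

    @classmethod
    def for_prevalence(
        cls,
        n_loci: int,
        prevalence: float = 0.10,
        penetrance: PenetranceModel | None = None,
    ) -> "MultilocusModel":
        """Equal-frequency model whose allele frequency is solved so the
        population left-handedness rate equals ``prevalence``."""
        penetrance = penetrance or PenetranceModel()
        eq = solve_equal_c(n_loci, prevalence, penetrance)
        return cls.equal(n_loci, eq.solved_c, penetrance)

    def population_left_rate(self) -> float:
        return left_rate_closed_form(self.c_values, self.penetrance)

    def spec(self) -> dict:
        """JSON-serializable description (for output metadata)."""
        return {
            "n_loci": self.n_loci,
            "c_values": list(self.c_values),
            "penetrance": list(self.penetrance.as_array()),
        }


@dataclass(frozen=True)
class PrevalenceEquation:
    """Solved equal-frequency prevalence equation."""

    target_prevalence: float
    n_loci: int
    solved_c: float


def damage_class(genotypes: np.ndarray) -> np.ndarray:
    """Damage class (0/1/2, see module docstring) of genotype vectors.

    ``genotypes`` holds per-locus C-allele counts in the last axis; any
    leading axes are preserved, so a (replicates, n_loci) array maps to
    (replicates,) classes.
    """
    g = np.asarray(genotypes)
    if g.ndim == 0 or g.shape[-1] == 0:
        raise InvalidParameterError("genotype vector must have at least one locus")
    any_cc = (g == 2).any(axis=-1)
    any_het = (g == 1).any(axis=-1)
    return np.where(any_cc, 2, np.where(any_het, 1, 0))


def damage_rule_penetrance(genotypes: np.ndarray, levels: PenetranceModel) -> np.ndarray | float:
    """Probability of left-handedness for genotype vectors under the damage
    rule.  Scalar for a single vector, array for a batch."""
    pen = levels.as_array()[damage_class(genotypes)]
    return float(pen) if np.ndim(pen) == 0 else pen


def _class_probs(c_values: Sequence[float]) -> np.ndarray:
    """(P(class 0), P(class 1), P(class 2)) for one individual under HWE."""
    c = np.asarray(c_values, dtype=float)
    all_dd = np.prod((1 - c) ** 2)
    no_cc = np.prod(1 - c**2)
    return np.array([all_dd, no_cc - all_dd, 1 - no_cc])


def left_rate_closed_form(
    c_values: Sequence[float], levels: PenetranceModel | None = None
) -> float:
    """Closed-form population left-handedness for the damage-rule model.

    For default levels and equal frequencies this is
    0.5[1-(1-c^2)^n] + 0.25[(1-c^2)^n - (1-c)^{2n}]; the implementation keeps
    the product form so unequal frequencies need no separate code path.
    """
    levels = levels or PenetranceModel()
    for c in c_values:
        _check_prob(c, "c")
    return float(_class_probs(c_values) @ levels.as_array())


def solve_equal_c(
    n: int, target_prevalence: float, levels: PenetranceModel | None = None
) -> PrevalenceEquation:
    """Solve the prevalence equation for the common allele frequency.

    The prevalence is continuous and monotone in c (for penetrances ordered
    l0 <= l1 <= l2), so bracketed bisection on [0, 1] finds the unique root.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    target = _check_prob(target_prevalence, "target_prevalence")
    levels = levels or PenetranceModel()
    lo = left_rate_closed_form([0.0] * n, levels)
    hi = left_rate_closed_form([1.0] * n, levels)
    if not min(lo, hi) <= target <= max(lo, hi):
        raise NoSolutionError(
            f"prevalence {target} is unattainable: range is [{min(lo, hi)}, {max(lo, hi)}]"
        )
    if target == lo:
        c = 0.0
    elif target == hi:
        c = 1.0
    else:
        c = brentq(
            lambda x: left_rate_closed_form([x] * n, levels) - target,
            0.0,
            1.0,
            xtol=_SOLVER_XTOL,
        )
    return PrevalenceEquation(target, int(n), float(c))


def sample_genotype(
    model: MultilocusModel, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw genotype vectors under HWE: the per-locus C-allele count is
    Binomial(2, c_i), loci independent.  Shape (n_loci,) or (size, n_loci)."""
    c = np.asarray(model.c_values)
    if size is None:
        return rng.binomial(2, c)
    return rng.binomial(2, np.broadcast_to(c, (int(size), model.n_loci)))


def meiosis(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete: at each locus, one of the parent's two alleles chosen
    uniformly; unlinked loci segregate independently.  Returns per-locus
    C-allele counts (0 or 1)."""
    parent = np.asarray(parent)
    return rng.binomial(1, parent / 2.0)


# ---------------------------------------------------------------------------
# Exact predictions via the damage-class joint distribution


def _trio_cells(c: float) -> np.ndarray:
    """Per-locus joint P(parent1, parent2, offspring genotype codes): parents
    in HWE, offspring by Mendelian segregation.  Shape (3, 3, 3)."""
    g = hwe_genotypes(c).as_array()
    return np.einsum("a,b,abo->abo", g, g, MENDEL)


def _sib_quad_cells(c: float) -> np.ndarray:
    """Per-locus joint over (parent1, parent2, sib1, sib2).  Shape (3,)*4."""
    g = hwe_genotypes(c).as_array()
    return np.einsum("a,b,abo,abq->aboq", g, g, MENDEL, MENDEL)


def _damage_class_joint(cells: np.ndarray, c_values: Sequence[float], builder) -> np.ndarray:
    """Joint distribution of damage classes for k individuals.

    ``cells`` is the per-locus genotype joint (3,)*k for the common frequency;
    when frequencies are unequal, ``builder(c)`` rebuilds it per locus.  The
    cumulative-probability trick: prefix-sum along each genotype axis gives
    P(every individual's genotype <= threshold) per locus; the product over
    loci gives the same event for the whole genome; finite differences
    recover the exact joint over classes (genotype 0/1/2 thresholds map to
    classes all-DD / no-CC / anything).
    """
    unique = set(c_values)
    if len(unique) == 1:
        cum = cells
        for ax in range(cells.ndim):
            cum = np.cumsum(cum, axis=ax)
        joint = cum ** len(c_values)
    else:
        joint = None
        for c in c_values:
            cum = builder(c)
            for ax in range(cum.ndim):
                cum = np.cumsum(cum, axis=ax)
            joint = cum if joint is None else joint * cum
    for ax in range(joint.ndim):
        joint = np.diff(joint, axis=ax, prepend=0.0)
    return joint


def _individual_class_joint(model: MultilocusModel) -> np.ndarray:
    return _class_probs(model.c_values)


def trio_class_joint(model: MultilocusModel) -> np.ndarray:
    """Exact joint damage-class distribution of (parent1, parent2, offspring)."""
    c0 = model.c_values[0]
    return _damage_class_joint(_trio_cells(c0), model.c_values, _trio_cells)


def _sib_quad_class_joint(model: MultilocusModel) -> np.ndarray:
    c0 = model.c_values[0]
    return _damage_class_joint(_sib_quad_cells(c0), model.c_values, _sib_quad_cells)


def _parent_pheno_weights(levels: np.ndarray, parents: ParentPair) -> np.ndarray:
    parents = ParentPair(parents)
    if parents is ParentPair.RxR:
        return np.outer(1 - levels, 1 - levels)
    if parents is ParentPair.LxL:
        return np.outer(levels, levels)
    return np.outer(1 - levels, levels) + np.outer(levels, 1 - levels)


def exact_family_prediction(model: MultilocusModel) -> FamilyPrediction:
    """Exact offspring left-handedness by parental phenotype pair, any n.

    With more loci, two left-handed parents can carry C alleles at different
    loci, so their offspring may inherit single C_i alleles only (25% class)
    rather than a CC genotype — L x L offspring left-handedness drops from
    30% (n=1) toward ~20% while R x R rises from 7.78% toward ~8.5%.
    """
    joint = trio_class_joint(model)
    lev = model.penetrance.as_array()
    rates = []
    for parents in ParentPair:
        w = np.einsum("abo,ab->abo", joint, _parent_pheno_weights(lev, parents))
        total = w.sum()
        if total == 0.0:
            raise DegenerateConditionError(
                f"parental phenotype pair {parents.value} has probability zero"
            )
        rates.append(float(np.einsum("abo,o->", w, lev) / total))
    return FamilyPrediction(*rates)


def family_stratum_probs(model: MultilocusModel) -> dict[ParentPair, float]:
    """Probability that a random family falls in each parental phenotype
    stratum (used for Monte Carlo standard errors)."""
    joint = trio_class_joint(model).sum(axis=2)
    lev = model.penetrance.as_array()
    return {
        parents: float((joint * _parent_pheno_weights(lev, parents)).sum())
        for parents in ParentPair
    }


def exact_twin_distribution(
    model: MultilocusModel,
    zygosity: Zygosity,
    parents: ParentPair | None = None,
) -> TwinDistribution:
    """Exact R-R / R-L / L-L pair probabilities for MZ or DZ twins,
    optionally conditioned on the parental phenotype pair."""
    lev = model.penetrance.as_array()
    zygosity = Zygosity(zygosity)
    if zygosity is Zygosity.MZ:
        if parents is None:
            q = _individual_class_joint(model)
        else:
            joint = trio_class_joint(model)
            w = np.einsum("abo,ab->abo", joint, _parent_pheno_weights(lev, parents))
            if w.sum() == 0.0:
                raise DegenerateConditionError(
                    f"parental phenotype pair {ParentPair(parents).value} has probability zero"
                )
            q = w.sum(axis=(0, 1))
        q = q / q.sum()
        rr = float(q @ (1 - lev) ** 2)
        ll = float(q @ lev**2)
    else:
        joint = _sib_quad_class_joint(model)
        if parents is None:
            w = joint
        else:
            w = np.einsum("aboq,ab->aboq", joint, _parent_pheno_weights(lev, parents))
        total = w.sum()
        if total == 0.0:
            raise DegenerateConditionError(
                f"parental phenotype pair {ParentPair(parents).value} has probability zero"
            )
        pair = w.sum(axis=(0, 1)) / total  # (class sib1, class sib2)
        rr = float(np.einsum("oq,o,q->", pair, 1 - lev, 1 - lev))
        ll = float(np.einsum("oq,o,q->", pair, lev, lev))
    return TwinDistribution(rr, 1.0 - rr - ll, ll, zygosity)
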