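"""Seedable Monte Carlo simulation of nuclear families and twin pairs.

Simulates families under any :class:`~dcmodel.multilocus.MultilocusModel`:
two parents drawn from Hardy-Weinberg proportions, phenotypes assigned from
damage-rule penetrances, offspring produced by Mendelian segregation.
Families are simulated *unconditionally* and then stratified by the realized
parental phenotype pair, so per-stratum counts vary between runs and the
reported confidence intervals reflect the actual stratum sizes (two
left-handed parents are rare — about 1% of families at 10% prevalence).

Because loci are independent and identically distributed (for equal
frequencies) and the phenotype depends on the genotype vector only through
its damage class, the simulator does not need to store per-locus genotypes:
for each family it draws the multinomial counts of the 27 per-locus
(parent1, parent2, offspring) genotype-trio cell types and reads the three
damage classes off the counts.  This is distributionally exact and makes the
cost per family independent of the number of loci, so the full published
12-row table at one million replicates per row runs in minutes.  Models with
unequal frequencies fall back to an explicit per-locus path built on
:func:`~dcmodel.multilocus.sample_genotype` and
:func:`~dcmodel.multilocus.meiosis`; tests verify the two paths agree.

All randomness flows through one named :class:`numpy.random.Generator` per
run, seeded from the config, so a fixed seed reproduces estimates exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ParentPair, TwinDistribution, Zygosity
from .multilocus import (
    MultilocusModel,
    _sib_quad_cells,
    _trio_cells,
    damage_class,
    exact_family_prediction,
    exact_twin_distribution,
    meiosis,
    sample_genotype,
)
from .errors import InvalidParameterError

__all__ = [
    "SimulationConfig",
    "SimEstimate",
    "FamilySimulation",
    "TwinSimulation",
    "ci_halfwidth",
    "simulate_families",
    "simulate_twins",
    "reproduce_table2",
]

_BATCH = 200_000


def ci_halfwidth(p: float, m: int) -> float:
    """Half-width of the approximate 95% normal confidence interval for a
    proportion ``p`` estimated from ``m`` observations: 1.96*sqrt(p(1-p)/m)."""
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    return 1.96 * math.sqrt(p * (1.0 - p) / m)


@dataclass(frozen=True)
class SimulationConfig:
    model: MultilocusModel
    replicates: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")


@dataclass(frozen=True)
class SimEstimate:
    """Monte Carlo proportion with its stratum size and 95% CI half-width.

    An empty stratum yields a flagged undefined estimate (NaN proportion,
    zero count) rather than a silently biased zero.
    """

    proportion: float
    replicates_in_stratum: int
    ci_halfwidth: float

    @property
    def defined(self) -> bool:
        return self.replicates_in_stratum > 0

    @property
    def se(self) -> float:
        return self.ci_halfwidth / 1.96 if self.defined else float("nan")

    @classmethod
    def from_counts(cls, successes: int, total: int) -> "SimEstimate":
        if total == 0:
            return cls(float("nan"), 0, float("nan"))
        p = successes / total
        return cls(p, int(total), ci_halfwidth(p, total))


@dataclass(frozen=True)
class FamilySimulation:
    estimates: dict[ParentPair, SimEstimate]
    overall_left: SimEstimate
    replicates: int
    seed: int | None
    model: MultilocusModel

    def __getitem__(self, parents: ParentPair) -> SimEstimate:
        return self.estimates[ParentPair(parents)]


@dataclass(frozen=True)
class TwinSimulation:
    p_rr: SimEstimate
    p_rl: SimEstimate
    p_ll: SimEstimate
    zygosity: Zygosity
    pairs_in_stratum: int
    replicates: int
    seed: int | None
    model: MultilocusModel

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rr.proportion, self.p_rl.proportion, self.p_ll.proportion])


def _classes_from_cell_counts(counts: np.ndarray, cell_codes: np.ndarray) -> np.ndarray:
    """Damage classes per individual from per-locus cell-type counts.

    ``counts``: (batch, n_cells) multinomial draws; ``cell_codes``:
    (k, n_cells) genotype code of each individual in each cell.  Returns
    (k, batch) int8 classes.
    """
    k = cell_codes.shape[0]
    out = np.empty((k, counts.shape[0]), dtype=np.int8)
    for axis in range(k):
        any_cc = counts[:, cell_codes[axis] == 2].sum(axis=1) > 0
        any_het = counts[:, cell_codes[axis] == 1].sum(axis=1) > 0
        out[axis] = np.where(any_cc, 2, np.where(any_het, 1, 0))
    return out


def _iter_relative_classes(model: MultilocusModel, cells: np.ndarray, replicates: int,
                           rng: np.random.Generator, n_offspring: int):
    """Yield batches of damage classes for (parent1, parent2, *offspring).

    ``cells`` is the per-locus joint genotype distribution of the relatives
    (equal-c fast path); unequal-c models use explicit per-locus sampling.
    """
    k = cells.ndim
    if model.is_equal_c:
        flat = cells.ravel()
        codes = np.array(np.unravel_index(np.arange(flat.size), cells.shape))
        done = 0
        while done < replicates:
            b = min(_BATCH, replicates - done)
            counts = rng.multinomial(model.n_loci, flat, size=b)
            yield _classes_from_cell_counts(counts, codes)
            done += b
    else:
        done = 0
        while done < replicates:
            b = min(_BATCH, replicates - done)
            p1 = sample_genotype(model, rng, b)
            p2 = sample_genotype(model, rng, b)
            offs = [meiosis(p1, rng) + meiosis(p2, rng) for _ in range(n_offspring)]
            yield np.stack(
                [damage_class(p1), damage_class(p2)] + [damage_class(o) for o in offs]
            ).astype(np.int8)
            done += b


def _phenotypes(classes: np.ndarray, levels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli left-handedness draws (one per individual per family)."""
    return rng.random(classes.shape) < levels[classes]


def _stratum_codes(left1: np.ndarray, left2: np.ndarray) -> np.ndarray:
    """0 = RxR, 1 = RxL (unordered), 2 = LxL."""
    return left1.astype(np.int8) + left2.astype(np.int8)


def simulate_families(config: SimulationConfig) -> FamilySimulation:
    """Monte Carlo family table: left-handed offspring proportion stratified
    by realized parental phenotype pair, with per-stratum 95% CIs."""
    model = config.model
    rng = np.random.default_rng(config.seed)
    levels = model.penetrance.as_array()
    cells = _trio_cells(model.c_values[0])
    left = np.zeros(3, dtype=np.int64)   # left-handed offspring per stratum
    total = np.zeros(3, dtype=np.int64)  # families per stratum
    for classes in _iter_relative_classes(model, cells, config.replicates, rng, 1):
        pheno = _phenotypes(classes, levels, rng)
        strata = _stratum_codes(pheno[0], pheno[1])
        total += np.bincount(strata, minlength=3)
        left += np.bincount(strata, weights=pheno[2], minlength=3).astype(np.int64)
    estimates = {
        parents: SimEstimate.from_counts(int(left[i]), int(total[i]))
        for i, parents in enumerate([ParentPair.RxR, ParentPair.RxL, ParentPair.LxL])
    }
    overall = SimEstimate.from_counts(int(left.sum()), int(total.sum()))
    return FamilySimulation(estimates, overall, config.replicates, config.seed, model)


def simulate_twins(
    config: SimulationConfig,
    zygosity: Zygosity,
    parents: ParentPair | None = None,
) -> TwinSimulation:
    """Monte Carlo twin-pair distribution (R-R / R-L / L-L).

    MZ pairs share one genotype and draw two independent phenotypes; DZ pairs
    are two offspring of the same simulated parents.  With ``parents`` given,
    pairs are stratified by the realized parental phenotypes and only the
    matching stratum is tallied.
    """
    model = config.model
    zygosity = Zygosity(zygosity)
    rng = np.random.default_rng(config.seed)
    levels = model.penetrance.as_array()

    need_parents = parents is not None or zygosity is Zygosity.DZ
    if not need_parents:
        # MZ, unconditional: just one shared genotype per pair
        counts = np.zeros(3, dtype=np.int64)
        done = 0
        while done < config.replicates:
            b = min(_BATCH, config.replicates - done)
            if model.is_equal_c:
                g = rng.multinomial(model.n_loci, _hwe_cells(model.c_values[0]), size=b)
                any_cc = g[:, 2] > 0
                any_het = g[:, 1] > 0
                cls = np.where(any_cc, 2, np.where(any_het, 1, 0)).astype(np.int8)
            else:
                cls = damage_class(sample_genotype(model, rng, b)).astype(np.int8)
            p = levels[cls]
            t1 = rng.random(b) < p
            t2 = rng.random(b) < p
            counts += np.bincount(t1.astype(int) + t2.astype(int), minlength=3)
            done += b
        pairs = int(counts.sum())
        return TwinSimulation(
            SimEstimate.from_counts(int(counts[0]), pairs),
            SimEstimate.from_counts(int(counts[1]), pairs),
            SimEstimate.from_counts(int(counts[2]), pairs),
            zygosity, pairs, config.replicates, config.seed, model,
        )

    if zygosity is Zygosity.MZ:
        cells = _trio_cells(model.c_values[0])
        n_off = 1
    else:
        cells = _sib_quad_cells(model.c_values[0])
        n_off = 2
    target = None if parents is None else ParentPair(parents)
    counts = np.zeros(3, dtype=np.int64)
    for classes in _iter_relative_classes(model, cells, config.replicates, rng, n_off):
        par_pheno = _phenotypes(classes[:2], levels, rng)
        if zygosity is Zygosity.MZ:
            p = levels[classes[2]]
            b = classes.shape[1]
            t1 = rng.random(b) < p
            t2 = rng.random(b) < p
        else:
            t1 = rng.random(classes.shape[1]) < levels[classes[2]]
            t2 = rng.random(classes.shape[1]) < levels[classes[3]]
        if target is None:
            mask = np.ones(classes.shape[1], dtype=bool)
        else:
            strata = _stratum_codes(par_pheno[0], par_pheno[1])
            code = {ParentPair.RxR: 0, ParentPair.RxL: 1, ParentPair.LxL: 2}[target]
            mask = strata == code
        n_left = t1[mask].astype(int) + t2[mask].astype(int)
        counts += np.bincount(n_left, minlength=3)
    pairs = int(counts.sum())
    return TwinSimulation(
        SimEstimate.from_counts(int(counts[0]), pairs),
        SimEstimate.from_counts(int(counts[1]), pairs),
        SimEstimate.from_counts(int(counts[2]), pairs),
        zygosity, pairs, config.replicates, config.seed, model,
    )


def _hwe_cells(c: float) -> np.ndarray:
    return np.array([(1 - c) ** 2, 2 * c * (1 - c), c**2])


def reproduce_table2(
    n_list: list[int],
    prevalence: float = 0.10,
    replicates: int = 1_000_000,
    seed: int | None = None,
    analytic: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Family and MZ-twin predictions across locus numbers at a fixed target
    prevalence: for each n, solve the equal-c prevalence equation, then either
    simulate (``analytic=False``) or evaluate the exact class-joint formulas.

    Returns a DataFrame (proportions as fractions; ``*_ci`` half-widths and
    ``*_m`` stratum counts for simulated tables) plus a metadata dict
    recording seed, replicates and the per-row model.
    """
    rows = []
    meta: dict = {
        "prevalence": prevalence,
        "replicates": None if analytic else replicates,
        "seed": None if analytic else seed,
        "analytic": analytic,
        "models": [],
    }
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    row_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(n_list))]
    for n, row_seed in zip(n_list, row_seeds):
        model = MultilocusModel.for_prevalence(n, prevalence)
        meta["models"].append(model.spec())
        rec: dict = {"n_loci": n, "c": model.c_values[0]}
        if analytic:
            fam = exact_family_prediction(model)
            twins = exact_twin_distribution(model, Zygosity.MZ)
            for parents in ParentPair:
                rec[parents.value] = fam[parents]
            rec["RR"], rec["RL"], rec["LL"] = twins.p_rr, twins.p_rl, twins.p_ll
        else:
            config = SimulationConfig(model, replicates, row_seed)
            fam_sim = simulate_families(config)
            twin_sim = simulate_twins(
                SimulationConfig(model, replicates, row_seed + 1), Zygosity.MZ
            )
            for parents in ParentPair:
                est = fam_sim[parents]
                rec[parents.value] = est.proportion
                rec[f"{parents.value}_ci"] = est.ci_halfwidth
                rec[f"{parents.value}_m"] = est.replicates_in_stratum
            for label, est in zip(("RR", "RL", "LL"), (twin_sim.p_rr, twin_sim.p_rl, twin_sim.p_ll)):
                rec[label] = est.proportion
                rec[f"{label}_ci"] = est.ci_halfwidth
                rec[f"{label}_m"] = est.replicates_in_stratum
        rows.append(rec)
    return pd.DataFrame(rows), meta
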