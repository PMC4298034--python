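"""GWAS power and sample-size machinery for penetrance-based genetic models.

Why a 99%-powered GWAS finding nothing matters: under a single-locus DC
model the chance-allele frequency differs sharply between left-handers
(60%) and right-handers (15.6%), so even a few hundred cases give essentially
certain detection at genome-wide significance (alpha = 5e-8, i.e. 0.05
Bonferroni-corrected for ~1e6 independent tests).  A null GWAS therefore
rejects the single-locus model outright.  Under the multilocus damage-rule
model each locus's frequency contrast shrinks with n, and per-locus power
decays — quantifying how many loci are needed before a null result stops
being surprising.

Power is estimated by Monte Carlo: case and control allele counts are drawn
from binomials at the phenotype-conditional allele frequencies and tested
with the standard 1-df allelic chi-square (no continuity correction).  The
default assumes perfect tagging (r^2 = 1) between the genotyped marker and
the causal locus, which upper-bounds the power of any real chip; imperfect
tagging deflates the case-control frequency difference by sqrt(r^2).  A
closed-form normal-approximation power formula is provided as an
independent cross-check, and a pooled-variance two-proportion sample-size
formula covers the classical-genetics question of how many families or twin
pairs would be needed to tell single- from multilocus predictions apart
(tens of thousands — hence "effectively indistinguishable").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Hand
from .errors import DegenerateConditionError, InvalidParameterError, NoSolutionError
from .multilocus import MultilocusModel, left_rate_closed_form
from .simulate import ci_halfwidth

__all__ = [
    "StudyDesign",
    "PowerResult",
    "SampleSizeSpec",
    "ContingencyTable2x2",
    "genomewide_threshold",
    "case_control_allele_freqs",
    "allelic_chisq",
    "analytic_power",
    "gwas_power_mc",
    "sample_size_two_proportions",
    "simulate_cohort",
    "write_vcf",
    "write_plink",
    "plot_power_curve",
]


@dataclass(frozen=True)
class StudyDesign:
    """Case-control GWAS design: left-handers are cases."""

    n_cases: int
    n_controls: int
    alpha: float = 5e-8
    tagging_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise InvalidParameterError("counts must be >= 0")
        if not 0 < self.alpha <= 1:
            raise InvalidParameterError("alpha must be in (0, 1]")
        if not 0 <= self.tagging_r2 <= 1:
            raise InvalidParameterError("tagging_r2 must be in [0, 1]")


@dataclass(frozen=True)
class PowerResult:
    per_locus_power: tuple[float, ...]
    any_locus_power: float
    replicates: int
    ci_halfwidth: float  # on the any-locus power

    @property
    def max_per_locus(self) -> float:
        return max(self.per_locus_power)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Two-proportion comparison: alpha two-sided, target power."""

    p1: float
    p2: float
    alpha_two_sided: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "alpha_two_sided", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidParameterError(f"{name} must be in (0, 1), got {v!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele-count table: rows cases/controls, columns C/D alleles."""

    cases_c: int
    cases_d: int
    controls_c: int
    controls_d: int

    def __post_init__(self) -> None:
        if min(self.cases_c, self.cases_d, self.controls_c, self.controls_d) < 0:
            raise InvalidParameterError("counts must be >= 0")


def genomewide_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Bonferroni per-test threshold: 0.05 over 1e6 tests gives the
    conventional genome-wide 5e-8."""
    if n_tests < 1:
        raise InvalidParameterError("n_tests must be >= 1")
    return family_alpha / n_tests


def case_control_allele_freqs(
    model: MultilocusModel, locus_index: int = 0
) -> tuple[float, float]:
    """Chance-allele frequency at one locus among cases (left-handers) and
    controls (right-handers), by exact Bayes inversion of the damage rule.

    The marginal is closed-form for any n: condition on the focal locus's
    genotype, aggregate the other loci into their "any CC" / "any het"
    probabilities, and weight the penetrance levels accordingly.
    """
    if not 0 <= locus_index < model.n_loci:
        raise InvalidParameterError("locus_index out of range")
    lev = model.penetrance.as_array()
    c = model.c_values[locus_index]
    others = np.array([model.c_values[j] for j in range(model.n_loci) if j != locus_index])
    no_cc_o = float(np.prod(1 - others**2)) if others.size else 1.0
    all_dd_o = float(np.prod((1 - others) ** 2)) if others.size else 1.0
    # P(L | focal genotype g): the focal genotype caps the best class reachable
    p_l_given_g = np.array(
        [
            lev[2] * (1 - no_cc_o) + lev[1] * (no_cc_o - all_dd_o) + lev[0] * all_dd_o,
            lev[2] * (1 - no_cc_o) + lev[1] * no_cc_o,
            lev[2],
        ]
    )
    g = np.array([(1 - c) ** 2, 2 * c * (1 - c), c**2])
    p_l = float(g @ p_l_given_g)
    if p_l <= 0.0 or p_l >= 1.0:
        raise DegenerateConditionError(
            "population prevalence must be strictly between 0 and 1 to condition on phenotype"
        )
    allele = np.array([0.0, 0.5, 1.0])
    f_cases = float(g * p_l_given_g @ allele / p_l)
    f_controls = float(g * (1 - p_l_given_g) @ allele / (1 - p_l))
    return f_cases, f_controls


def _chisq_stat(x1, m1, x2, m2):
    """Vectorized 1-df allelic chi-square statistic; zero-margin cells give 0."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = m1 + m2
    col_c = x1 + x2
    col_d = n - col_c
    denom = m1 * m2 * col_c * col_d
    num = n * (x1 * (m2 - x2) - (m1 - x1) * x2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return stat


def allelic_chisq(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    allele-count table; returns (statistic, p-value).  A zero margin yields
    statistic 0 and p = 1."""
    m1 = table.cases_c + table.cases_d
    m2 = table.controls_c + table.controls_d
    if m1 + m2 == 0:
        raise InvalidParameterError("total count must be > 0")
    stat = float(_chisq_stat(table.cases_c, m1, table.controls_c, m2))
    if stat == 0.0:
        return 0.0, 1.0
    return stat, float(stats.chi2.sf(stat, 1))


def analytic_power(
    f_cases: float, f_controls: float, n_cases: int, n_controls: int, alpha: float
) -> float:
    """Normal-approximation power of the two-sided allelic test: null SE from
    the pooled frequency, alternative SE from the separate frequencies.
    Independent cross-check for :func:`gwas_power_mc`."""
    m1, m2 = 2 * n_cases, 2 * n_controls
    if m1 == 0 or m2 == 0:
        raise InvalidParameterError("case and control counts must be > 0")
    pbar = (m1 * f_cases + m2 * f_controls) / (m1 + m2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m2))
    se1 = np.sqrt(f_cases * (1 - f_cases) / m1 + f_controls * (1 - f_controls) / m2)
    delta = abs(f_cases - f_controls)
    za = stats.norm.isf(alpha / 2)
    if se1 == 0.0:
        return 1.0 if delta > za * se0 else 0.0
    return float(stats.norm.sf((za * se0 - delta) / se1) + stats.norm.sf((za * se0 + delta) / se1))


def _attenuate(f: np.ndarray, pooled: np.ndarray, r2: float) -> np.ndarray:
    """Imperfect tagging shrinks the observable frequency contrast toward the
    pooled frequency by sqrt(r^2)."""
    return pooled + np.sqrt(r2) * (f - pooled)


def gwas_power_mc(
    model: MultilocusModel,
    design: StudyDesign,
    replicates: int = 100_000,
    seed: int | None = None,
) -> PowerResult:
    """Monte Carlo GWAS power for every locus of ``model`` under ``design``.

    Per replicate, case and control allele counts at each locus are drawn
    from binomials at the phenotype-conditional frequencies (alleles treated
    as 2N independent draws) and tested with the allelic chi-square at
    ``design.alpha``.  Reports per-locus power and the probability that at
    least one locus reaches significance (any-locus power).
    """
    if design.n_cases == 0 or design.n_controls == 0:
        raise InvalidParameterError("case and control counts must be > 0")
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.array([case_control_allele_freqs(model, i) for i in range(model.n_loci)])
    m1, m2 = 2 * design.n_cases, 2 * design.n_controls
    pooled = (m1 * freqs[:, 0] + m2 * freqs[:, 1]) / (m1 + m2)
    f1 = _attenuate(freqs[:, 0], pooled, design.tagging_r2)
    f2 = _attenuate(freqs[:, 1], pooled, design.tagging_r2)
    crit = stats.chi2.isf(design.alpha, 1)
    per_locus = np.zeros(model.n_loci, dtype=np.int64)
    any_hits = 0
    batch = max(1, min(replicates, 20_000_000 // max(1, model.n_loci)))
    done = 0
    while done < replicates:
        b = min(batch, replicates - done)
        x1 = rng.binomial(m1, f1, size=(b, model.n_loci))
        x2 = rng.binomial(m2, f2, size=(b, model.n_loci))
        sig = _chisq_stat(x1, m1, x2, m2) > crit
        per_locus += sig.sum(axis=0)
        any_hits += int(sig.any(axis=1).sum())
        done += b
    per = per_locus / replicates
    any_p = any_hits / replicates
    return PowerResult(
        tuple(float(p) for p in per), float(any_p), replicates, ci_halfwidth(any_p, replicates)
    )


def sample_size_two_proportions(spec: SampleSizeSpec) -> int:
    """Per-group sample size to distinguish two proportions with a two-sided
    pooled-variance normal-approximation test (no continuity correction):

        N = (z_{a/2} sqrt(2 pbar qbar) + z_b sqrt(p1 q1 + p2 q2))^2 / (p1-p2)^2

    rounded to the nearest integer.
    """
    if spec.p1 == spec.p2:
        raise NoSolutionError("p1 == p2: no finite sample size distinguishes them")
    za = stats.norm.isf(spec.alpha_two_sided / 2)
    zb = stats.norm.isf(1 - spec.power)
    pbar = (spec.p1 + spec.p2) / 2
    n = (
        za * np.sqrt(2 * pbar * (1 - pbar))
        + zb * np.sqrt(spec.p1 * (1 - spec.p1) + spec.p2 * (1 - spec.p2))
    ) ** 2 / (spec.p1 - spec.p2) ** 2
    return int(round(float(n)))


# ---------------------------------------------------------------------------
# Cohort export (interoperability smoke-testing)


def simulate_cohort(
    model: MultilocusModel,
    n_cases: int,
    n_controls: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate individual-level genotypes for a case-control cohort by
    rejection sampling from the population (genotype-level, not allele-level).
    Returns (cases, controls) arrays of per-locus C-allele counts."""
    from .multilocus import damage_rule_penetrance, sample_genotype

    rng = np.random.default_rng(seed)
    out = {Hand.L: [], Hand.R: []}
    need = {Hand.L: n_cases, Hand.R: n_controls}
    guard = 0
    while (len(out[Hand.L]) < need[Hand.L] or len(out[Hand.R]) < need[Hand.R]):
        guard += 1
        if guard > 10_000:
            raise DegenerateConditionError("rejection sampling failed to fill the cohort")
        g = sample_genotype(model, rng, 4096)
        pen = damage_rule_penetrance(g, model.penetrance)
        left = rng.random(len(g)) < pen
        for hand, mask in ((Hand.L, left), (Hand.R, ~left)):
            short = need[hand] - len(out[hand])
            if short > 0:
                out[hand].extend(g[mask][:short])
    return np.array(out[Hand.L]), np.array(out[Hand.R])


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, cases: np.ndarray, controls: np.ndarray) -> None:
    """Write the cohort as a minimal plain-text VCF v4.2: one biallelic
    record per locus (REF=A, ALT=C), samples case_* then control_*."""
    n_loci = cases.shape[1]
    samples = [f"case_{i+1}" for i in range(len(cases))] + [
        f"control_{i+1}" for i in range(len(controls))
    ]
    geno = np.vstack([cases, controls])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dcmodel\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(n_loci):
            gts = "\t".join(_VCF_GT[int(g)] for g in geno[:, j])
            fh.write(f"1\t{1000 * (j + 1)}\tlocus_{j+1}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def write_plink(prefix, cases: np.ndarray, controls: np.ndarray) -> None:
    """Write PLINK PED/MAP text files; phenotype 2 = case, 1 = control."""
    n_loci = cases.shape[1]
    alleles = {0: "A A", 1: "A C", 2: "C C"}
    with open(f"{prefix}.map", "w") as fh:
        for j in range(n_loci):
            fh.write(f"1\tlocus_{j+1}\t0\t{1000 * (j + 1)}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for label, geno, pheno in (("case", cases, 2), ("control", controls, 1)):
            for i, row in enumerate(geno):
                cols = [f"F{label}{i+1}", f"{label}_{i+1}", "0", "0", "0", str(pheno)]
                cols += [alleles[int(g)] for g in row]
                fh.write("\t".join(cols) + "\n")


def plot_power_curve(
    loci_counts: list[int],
    design: StudyDesign,
    path,
    prevalence: float = 0.10,
    replicates: int = 20_000,
    seed: int | None = None,
):
    """Per-locus and any-locus power as a function of the number of loci,
    saved as a figure.  Requires matplotlib (``pip install dcmodel[plot]``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per, any_ = [], []
    for n in loci_counts:
        model = MultilocusModel.for_prevalence(n, prevalence)
        res = gwas_power_mc(model, design, replicates, seed)
        per.append(np.mean(res.per_locus_power))
        any_.append(res.any_locus_power)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(loci_counts, per, "o-", label="mean per-locus power")
    ax.plot(loci_counts, any_, "s-", label="any-locus power")
    ax.set_xscale("log")
    ax.set_xlabel("number of loci")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
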