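"""Genotype-phenotype association for two-locus segregating populations.

An F2 from a biparental cross segregates 1:2:1 at each locus, giving
nine two-locus genotype classes; a BC1 to the wild-type parent gives
four.  Given per-class trait summaries (e.g. seed oleic-acid percent),
the classical biometrical decomposition estimates, per locus,

* additive effect ``A`` — half the difference between the mutant- and
  wild-type-homozygote phenotypes,
* dominance effect ``D`` — the heterozygote's deviation from the
  homozygote midpoint,

and a two-locus epistasis term
``I = [(aabb + AABB) - (marginal(aa) + marginal(bb))]/2``.

"Phenotype value of a genotype" at one locus is taken as the unweighted
mean of the three class means sharing that genotype (marginalizing over
the other locus without weighting by class counts).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import PopulationLine

__all__ = [
    "ClassStats",
    "GenotypeClassTable",
    "GeneticEffects",
    "ContrastResult",
    "EpistasisConventionWarning",
    "F2_CLASSES",
    "BC1_CLASSES",
    "summarize_by_genotype",
    "class_table_from_means",
    "read_class_means",
    "default_f2_class_tables",
    "genetic_effects",
    "marginal_allele_contrast",
    "anova_oneway",
    "tukey_pairwise",
    "compact_letter_display",
    "cld_from_data",
    "chi_square_segregation",
]

_L1 = ("AA", "Aa", "aa")
_L2 = ("BB", "Bb", "bb")

#: the nine F2 two-locus classes
F2_CLASSES = tuple(g1 + g2 for g1 in _L1 for g2 in _L2)
#: the four BC1 classes (backcross to the wild-type AABB parent)
BC1_CLASSES = ("AABB", "AABb", "AaBB", "AaBb")


class EpistasisConventionWarning(UserWarning):
    """The epistasis term follows the stated two-locus formula literally;
    its value depends on the marginal-mean convention and is not
    comparable across software without checking that convention."""


class ClassStats(NamedTuple):
    n: int
    mean: float
    sd: float  # sample SD (n-1); NaN when n == 1


@dataclass(frozen=True)
class GenotypeClassTable:
    """Per-genotype-class summary of one trait."""

    trait: str
    classes: dict[str, ClassStats]
    n_excluded: int = 0  # lines dropped for unknown genotype

    def mean(self, genotype: str) -> float:
        return self.classes[genotype].mean

    @property
    def is_f2_complete(self) -> bool:
        return all(c in self.classes for c in F2_CLASSES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"genotype": g, "n": s.n, "mean": s.mean, "sd": s.sd}
                for g, s in self.classes.items()
            ]
        )


@dataclass(frozen=True)
class GeneticEffects:
    """Additive (per locus), dominance (per locus) and epistasis effects,
    in trait units."""

    a1: float
    a2: float
    d1: float
    d2: float
    i: float
    convention_note: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": ["A-1", "A-2", "D-1", "D-2", "I"],
                "value": [self.a1, self.a2, self.d1, self.d2, self.i],
            }
        )


class ContrastResult(NamedTuple):
    difference: float
    ci_low: float
    ci_high: float


def summarize_by_genotype(
    pop: Sequence[PopulationLine], trait: str
) -> GenotypeClassTable:
    """n, mean and sample SD of ``trait`` per two-locus genotype class.

    Lines with an unknown genotype at either locus (or a missing trait
    value) are excluded and counted in ``n_excluded``.
    """
    values: dict[str, list[float]] = {}
    excluded = 0
    for ln in pop:
        if "unknown" in (ln.genotype_locus1, ln.genotype_locus2):
            excluded += 1
            continue
        try:
            v = getattr(ln.profile, trait)
        except AttributeError:
            raise ValueError(f"unknown trait {trait!r}")
        if v is None:
            excluded += 1
            continue
        values.setdefault(ln.genotype, []).append(float(v))
    if not values:
        raise ValueError("no lines with known genotypes at both loci")
    classes = {
        g: ClassStats(
            n=len(v),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
        )
        for g, v in values.items()
    }
    return GenotypeClassTable(trait=trait, classes=classes, n_excluded=excluded)


def class_table_from_means(
    means: Mapping[str, tuple[int, float, float]], trait: str
) -> GenotypeClassTable:
    """Build a class table directly from published-style (n, mean, sd)
    summaries keyed by two-locus genotype."""
    return GenotypeClassTable(
        trait=trait,
        classes={g: ClassStats(*v) for g, v in means.items()},
    )


def read_class_means(path) -> dict[tuple[str, str], GenotypeClassTable]:
    """Read a class-mean TSV (trial, location, genotype, n_lines,
    <trait>_mean, <trait>_sd) into one table per (trial, location)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    mean_cols = [c for c in df.columns if c.endswith("_mean")]
    if len(mean_cols) != 1:
        raise ValueError(f"{path}: expected exactly one *_mean column")
    trait = mean_cols[0][: -len("_mean")]
    out: dict[tuple[str, str], GenotypeClassTable] = {}
    for (trial, location), sub in df.groupby(["trial", "location"], sort=False):
        out[(trial, location)] = class_table_from_means(
            {
                row["genotype"]: (
                    int(row["n_lines"]),
                    float(row[f"{trait}_mean"]),
                    float(row[f"{trait}_sd"]),
                )
                for _, row in sub.iterrows()
            },
            trait=trait,
        )
    return out


def default_f2_class_tables() -> dict[tuple[str, str], GenotypeClassTable]:
    """The packaged two-site F2 oleic-acid class-mean tables."""
    return read_class_means(
        Path(__file__).parent / "data" / "f2_class_means_c18_1.tsv"
    )


def _marginal(table: GenotypeClassTable, genotype: str) -> float:
    """Unweighted marginal mean of one single-locus genotype over the
    three classes of the other locus."""
    if genotype in _L1:
        cells = [genotype + g2 for g2 in _L2]
    elif genotype in _L2:
        cells = [g1 + genotype for g1 in _L1]
    else:
        raise ValueError(f"unknown single-locus genotype {genotype!r}")
    missing = [c for c in cells if c not in table.classes]
    if missing:
        raise ValueError(f"classes absent for marginal {genotype}: {missing}")
    return float(np.mean([table.mean(c) for c in cells]))


_CONVENTION_NOTE = (
    "Single-locus phenotype values are unweighted means of the three "
    "two-locus class means sharing that genotype; A = (mut hom - WT hom)/2, "
    "D = het - (mut hom + WT hom)/2, I = [(aabb + AABB) - "
    "(marginal(aa) + marginal(bb))]/2."
)


def genetic_effects(table: GenotypeClassTable) -> GeneticEffects:
    """Additive/dominance/epistasis decomposition of an F2 class table.

    Requires all nine two-locus classes (a BC1 table lacks the mutant
    homozygotes, so A and I are undefined there and the call refuses).
    """
    missing = [c for c in F2_CLASSES if c not in table.classes]
    if missing:
        raise ValueError(
            "genetic effects need all 9 F2 genotype classes; absent: "
            + ", ".join(missing)
        )
    m = {g: _marginal(table, g) for g in _L1 + _L2}
    a1 = (m["aa"] - m["AA"]) / 2.0
    a2 = (m["bb"] - m["BB"]) / 2.0
    d1 = m["Aa"] - (m["aa"] + m["AA"]) / 2.0
    d2 = m["Bb"] - (m["bb"] + m["BB"]) / 2.0
    i = ((table.mean("aabb") + table.mean("AABB")) - (m["aa"] + m["bb"])) / 2.0
    warnings.warn(
        "epistasis term I computed with unweighted marginal means; see "
        "convention_note",
        EpistasisConventionWarning,
        stacklevel=2,
    )
    return GeneticEffects(
        a1=a1, a2=a2, d1=d1, d2=d2, i=i, convention_note=_CONVENTION_NOTE
    )


def marginal_allele_contrast(
    pop: Sequence[PopulationLine],
    locus: int,
    reference_genotype: str,
    test_genotype: str,
    trait: str = "c18_1",
    n_boot: int = 2000,
    seed: int = 0,
) -> ContrastResult:
    """Difference in unweighted marginal trait means between two
    genotypes at one locus (e.g. aa vs AA), with a bootstrap 95% CI.

    The bootstrap resamples lines with replacement within each of the
    contributing two-locus classes, preserving the class structure.
    """
    if locus not in (1, 2):
        raise ValueError("locus must be 1 or 2")
    groups: dict[str, list[float]] = {}
    for ln in pop:
        if "unknown" in (ln.genotype_locus1, ln.genotype_locus2):
            continue
        v = getattr(ln.profile, trait)
        if v is not None:
            groups.setdefault(ln.genotype, []).append(float(v))

    other = _L2 if locus == 1 else _L1

    def cells(genotype: str) -> list[str]:
        return [
            genotype + o if locus == 1 else o + genotype for o in other
        ]

    needed = cells(reference_genotype) + cells(test_genotype)
    missing = [c for c in needed if not groups.get(c)]
    if missing:
        raise ValueError(f"genotype classes absent: {missing}")

    def contrast(sample: Mapping[str, Sequence[float]]) -> float:
        m_test = np.mean([np.mean(sample[c]) for c in cells(test_genotype)])
        m_ref = np.mean(
            [np.mean(sample[c]) for c in cells(reference_genotype)]
        )
        return float(m_test - m_ref)

    point = contrast(groups)
    rng = np.random.default_rng(seed)
    arrays = {c: np.asarray(groups[c]) for c in set(needed)}
    boot = np.empty(n_boot)
    for b in range(n_boot):
        resampled = {
            c: a[rng.integers(0, len(a), len(a))] for c, a in arrays.items()
        }
        boot[b] = contrast(resampled)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ContrastResult(point, float(lo), float(hi))


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate input where every observation is identical returns
    F = 0, p = 1 instead of NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)


def tukey_pairwise(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[frozenset, bool]:
    """Tukey HSD pairwise decisions: pair -> reject equality."""
    labels = []
    values = []
    for name, vals in groups.items():
        labels.extend([name] * len(vals))
        values.extend(vals)
    res = pairwise_tukeyhsd(np.asarray(values, float), np.asarray(labels),
                            alpha=alpha)
    pairs = itertools.combinations(res.groupsunique, 2)
    return {
        frozenset(pair): bool(rej) for pair, rej in zip(pairs, res.reject)
    }


def compact_letter_display(
    means: Mapping[str, float], significant: Mapping[frozenset, bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Letters
    are assigned in ascending order of group mean (the smallest-mean
    group gets an 'a'), matching the usual table presentation.
    """
    levels = sorted(means, key=lambda k: means[k])
    columns: list[set[str]] = [set(levels)]
    for pair, reject in sorted(
        significant.items(), key=lambda kv: sorted(kv[0])
    ):
        if not reject:
            continue
        i, j = sorted(pair)
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for new in (col - {i}, col - {j}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        # absorb columns that became redundant
        columns = [
            c
            for c in columns
            if not any(c < o for o in columns if o is not c)
        ]
    rank = {lv: k for k, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(rank[lv] for lv in c))
    letters = {lv: "" for lv in levels}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx)
        for lv in levels:
            if lv in col:
                letters[lv] += letter
    return letters


def cld_from_data(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Tukey HSD at ``alpha`` followed by the compact letter display."""
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    return compact_letter_display(means, tukey_pairwise(groups, alpha))


def chi_square_segregation(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> tuple[float, float]:
    """Pearson chi-square goodness of fit of genotype counts to a
    Mendelian ratio (df = classes - 1)."""
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and ratio must have equal length")
    if (obs < 0).any() or (ratio <= 0).any():
        raise ValueError("counts must be >= 0 and ratio strictly positive")
    total = obs.sum()
    if total == 0:
        raise ValueError("all-zero counts")
    expected = ratio / ratio.sum() * total
    stat, p = stats.chisquare(obs, expected)
    return float(stat), float(p)
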