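"""Band-pattern interpretation: from gel bands to centromeric KIR genotypes.

A sample's multiplex band pattern is compared against the expected pattern
of every diploid genotype the centromeric haplotype structure permits.
Each centromeric haplotype carries exactly one of {a KIR2DL2 allele, a
KIR2DL3 allele} (the two genes are allelic at one locus) and either a
KIR2DL1 allele together with non-variant KIR3DP1, or no KIR2DL1 together
with the KIR3DP1V variant.  Those two identities — n(2DL2)+n(2DL3)=2 and
n(2DL1)+n(3DP1V)=2 — are what allow copy-number inference from a
presence/absence assay.

Band semantics are union-only: gel electrophoresis is not quantitative, so
a reaction is expected positive iff at least one carried allele amplifies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alleles import DP1_ROW, DP1V_ROW
from .arms import PatternMatrix

#: Reaction column ids for the two bands of the 3DP1/3DP1V multiplex
#: (KIR2DL1 reaction 7: 649 bp for 3DP1, 382 bp for 3DP1V).
R7_DP1 = "2DL1 Reaction 7 (3DP1)"
R7_DP1V = "2DL1 Reaction 7 (3DP1V)"


@dataclass
class BandPattern:
    """Observed band pattern for one sample.

    ``bands`` maps reaction id → band present; ``controls`` maps reaction
    id → control band present.  A reaction whose control band failed is
    *invalid* (uninterpretable), not negative; reactions without control
    primers are always interpretable.
    """

    sample_id: str
    bands: dict[str, bool]
    controls: dict[str, bool] = field(default_factory=dict)
    control_free: frozenset = frozenset()

    def valid_reactions(self) -> list[str]:
        out = []
        for rid in self.bands:
            if rid in self.control_free or self.controls.get(rid, True):
                out.append(rid)
        return out


@dataclass(frozen=True, order=True)
class GenotypeCall:
    """A diploid centromeric genotype: ≤2 KIR2DL1 alleles, exactly 2
    alleles over the KIR2DL2/KIR2DL3 locus, and the implied 3DP1V count."""

    dl1: tuple[str, ...]
    dl23: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.dl1) > 2:
            raise ValueError("more than two KIR2DL1 alleles")
        if len(self.dl23) != 2:
            raise ValueError("the KIR2DL2/KIR2DL3 locus must carry exactly 2 alleles")
        object.__setattr__(self, "dl1", tuple(sorted(self.dl1)))
        object.__setattr__(self, "dl23", tuple(sorted(self.dl23)))

    @property
    def n_3dp1v(self) -> int:
        return 2 - len(self.dl1)

    @property
    def alleles(self) -> tuple[str, ...]:
        return self.dl1 + self.dl23

    def label(self) -> str:
        dl1 = "/".join(self.dl1) if self.dl1 else "-"
        return f"[2DL1: {dl1} | 2DL2/3: {'/'.join(self.dl23)} | 3DP1V x{self.n_3dp1v}]"


class HaplotypeModel:
    """Enumerates the diploid genotypes the centromeric structure permits
    over a knowledge base's alleles."""

    def __init__(self, dl1_alleles: list[str], dl23_alleles: list[str]):
        self.dl1_alleles = sorted(dl1_alleles)
        self.dl23_alleles = sorted(dl23_alleles)

    @classmethod
    def from_pattern_matrix(cls, pm: PatternMatrix) -> "HaplotypeModel":
        dl1 = [a for a in pm.alleles if a.startswith("KIR2DL1")]
        dl23 = [a for a in pm.alleles if a.startswith(("KIR2DL2", "KIR2DL3"))]
        return cls(dl1, dl23)

    def enumerate_genotypes(self):
        dl23_pairs = list(
            itertools.combinations_with_replacement(self.dl23_alleles, 2)
        )
        dl1_sets: list[tuple[str, ...]] = [()]
        dl1_sets += [(a,) for a in self.dl1_alleles]
        dl1_sets += list(itertools.combinations_with_replacement(self.dl1_alleles, 2))
        for dl1 in dl1_sets:
            for dl23 in dl23_pairs:
                yield GenotypeCall(dl1=dl1, dl23=dl23)


def expected_pattern(genotype: GenotypeCall, pm: PatternMatrix) -> BandPattern:
    """Expected band pattern of *genotype*: union of its alleles' matrix
    rows, plus the 3DP1/3DP1V bands implied by the haplotype structure
    (when the matrix carries those pseudo-allele rows)."""
    carried = list(genotype.alleles)
    if DP1_ROW in pm.df.index and len(genotype.dl1) > 0:
        carried.append(DP1_ROW)
    if DP1V_ROW in pm.df.index and genotype.n_3dp1v > 0:
        carried.append(DP1V_ROW)
    missing = [a for a in carried if a not in pm.df.index]
    if missing:
        raise KeyError(f"alleles missing from pattern matrix: {missing}")
    rows = pm.df.loc[carried].to_numpy(dtype=bool)
    union = rows.any(axis=0)
    return BandPattern(
        sample_id="expected",
        bands={rid: bool(v) for rid, v in zip(pm.reactions, union)},
    )


@dataclass
class InterpretationResult:
    """All genotypes consistent with one observed band pattern."""

    sample_id: str
    candidates: list[GenotypeCall]
    ambiguity: bool
    ambiguity_label: str | None = None
    recommended_reactions: list[str] = field(default_factory=list)
    valid_reactions: list[str] = field(default_factory=list)

    @property
    def unique_call(self) -> GenotypeCall | None:
        return self.candidates[0] if len(self.candidates) == 1 else None


def interpret(
    observed: BandPattern,
    pm: PatternMatrix,
    model: HaplotypeModel | None = None,
    ambiguity_labels: dict[frozenset, str] | None = None,
) -> InterpretationResult:
    """Enumerate all model-permitted genotypes whose expected pattern
    matches *observed* on every valid (control-passed) reaction.

    Reactions whose control band failed are excluded from the consistency
    test rather than treated as negative.  Candidates are returned in
    lexicographic order; an empty list means no knowledge-base genotype
    explains the pattern (the "unknown allele" hypothesis is out of scope).
    """
    if model is None:
        model = HaplotypeModel.from_pattern_matrix(pm)
    valid = [r for r in observed.valid_reactions() if r in pm.df.columns]
    if not valid:
        raise ValueError(f"sample {observed.sample_id}: no interpretable reactions")
    obs_vec = np.array([observed.bands[r] for r in valid], dtype=bool)
    cols = [pm.reactions.index(r) for r in valid]
    row_cache = {a: pm.df.loc[a].to_numpy(dtype=bool) for a in pm.alleles}
    candidates = []
    for g in model.enumerate_genotypes():
        carried = list(g.alleles)
        if DP1_ROW in row_cache and len(g.dl1) > 0:
            carried.append(DP1_ROW)
        if DP1V_ROW in row_cache and g.n_3dp1v > 0:
            carried.append(DP1V_ROW)
        exp = np.zeros(len(pm.reactions), dtype=bool)
        for a in carried:
            exp |= row_cache[a]
        if np.array_equal(exp[cols], obs_vec):
            candidates.append(g)
    candidates.sort()
    ambiguity = len(candidates) > 1
    label = None
    if ambiguity and ambiguity_labels:
        label = ambiguity_labels.get(frozenset(candidates))
    recommended: list[str] = []
    if ambiguity:
        unused = [r for r in pm.reactions if r not in observed.bands]
        recommended = recommend_disambiguation(candidates, pm, unused)
    return InterpretationResult(
        sample_id=observed.sample_id,
        candidates=candidates,
        ambiguity=ambiguity,
        ambiguity_label=label,
        recommended_reactions=recommended,
        valid_reactions=valid,
    )


def recommend_disambiguation(
    candidates: list[GenotypeCall],
    pm: PatternMatrix,
    unused_reactions: list[str],
) -> list[str]:
    """Smallest set of as-yet-unrun reactions whose expected patterns
    pairwise differ across all *candidates*; ties broken lexicographically.
    Empty when no subset separates them (irreducible ambiguity)."""
    if len(candidates) < 2:
        raise ValueError("disambiguation needs at least two candidate genotypes")
    unused = sorted(r for r in unused_reactions if r in pm.df.columns)
    if not unused:
        return []
    exp = {
        id(g): expected_pattern(g, pm).bands for g in candidates
    }
    for size in range(1, len(unused) + 1):
        for combo in itertools.combinations(unused, size):
            ok = True
            for g1, g2 in itertools.combinations(candidates, 2):
                if all(exp[id(g1)][r] == exp[id(g2)][r] for r in combo):
                    ok = False
                    break
            if ok:
                return list(combo)
    return []


def ambiguity_classes(
    pm: PatternMatrix, model: HaplotypeModel | None = None
) -> dict[frozenset, str]:
    """Discover the irresolvable-by-current-panel ambiguity classes of a
    knowledge base: groups of ≥2 genotypes sharing one expected pattern.

    Classes are labelled deterministically with the footnote-style symbols
    ``*``, ``#``, ``$``, ``&`` (then ``&2``, ``&3``, ...) in order of their
    lexicographically smallest genotype."""
    if model is None:
        model = HaplotypeModel.from_pattern_matrix(pm)
    by_pattern: dict[tuple, list[GenotypeCall]] = {}
    for g in model.enumerate_genotypes():
        key = tuple(expected_pattern(g, pm).bands.values())
        by_pattern.setdefault(key, []).append(g)
    classes = sorted(
        (sorted(gs) for gs in by_pattern.values() if len(gs) > 1),
        key=lambda gs: gs[0],
    )
    symbols = ["*", "#", "$", "&"]
    out = {}
    for i, gs in enumerate(classes):
        sym = symbols[i] if i < len(symbols) else f"&{i - len(symbols) + 2}"
        out[frozenset(gs)] = sym
    return out


def infer_2dl1_copy_number(observed: BandPattern) -> tuple[int, str]:
    """KIR2DL1 copy number from the 3DP1/3DP1V reaction.

    3DP1V marks a KIR2DL1-absent haplotype, so: no 3DP1V band → 2 copies;
    3DP1V plus ≥1 positive KIR2DL1 reaction → 1; 3DP1V with all KIR2DL1
    reactions negative → 0.  The framework 3DP1 band is expected in every
    sample; its absence triggers a warning, not an error.
    """
    if R7_DP1V not in observed.bands:
        raise ValueError("3DP1/3DP1V reaction not observed; cannot infer copy number")
    dp1v = observed.bands[R7_DP1V]
    dp1 = observed.bands.get(R7_DP1, False)
    dl1_positive = any(
        present
        for rid, present in observed.bands.items()
        if rid.startswith("2DL1 ") and rid not in (R7_DP1, R7_DP1V)
    )
    if not dp1 and not dp1v:
        warnings.warn(
            f"sample {observed.sample_id}: no 3DP1 framework band observed",
            stacklevel=2,
        )
    if not dp1v:
        return 2, "no 3DP1V: both haplotypes carry KIR2DL1"
    if dl1_positive:
        return 1, "3DP1V present with KIR2DL1 bands: one KIR2DL1-bearing haplotype"
    return 0, "3DP1V present, no KIR2DL1 band: both haplotypes lack KIR2DL1"
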