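"""Linkage disequilibrium, haplotype frequencies and Mendelian checks.

Two estimation routes are provided for pairwise allele association:

* a phenotype-based ("Mattiuz-style") estimator in the classical HLA
  serology tradition, which assumes Hardy–Weinberg equilibrium and
  estimates haplotype frequencies from carrier/non-carrier 2×2 tables via
  square roots of phenotype frequencies — usable when only presence/absence
  of each allele is known; and

* an EM algorithm over the centromeric haplotype structure, used when
  full unphased allele-level genotypes are available (the situation this
  typing kit produces).

Mendelian-consistency checking of pedigrees enumerates phase resolutions
of child and parents exhaustively and asks whether some child haplotype
could come from the father and the other from the mother.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: A centromeric haplotype: (KIR2DL1 allele or None, KIR2DL2/2DL3 allele,
#: KIR2DS2 carried).  None at the first slot implies KIR3DP1V.
Haplotype = tuple[str | None, str, bool]


# ---------------------------------------------------------------------------
# Phenotype-based (Mattiuz-style) LD
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable2x2:
    """Carrier/non-carrier counts for two alleles A and B.

    a = A+B+, b = A+B-, c = A-B+, d = A-B- individuals.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative counts")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class LDResult:
    """Pairwise association between two alleles on the haplotype scale.

    The parameterization follows the absence haplotypes: p_not_a and
    p_not_b are the estimated frequencies of the haplotypes *lacking* A
    and B, h00 the estimated frequency of the doubly-absent haplotype, and
    D = h00 - p_not_a * p_not_b.  Under HWE a non-carrier of A is
    homozygous absent, so p_not_a = sqrt((c+d)/N) etc.
    """

    p_not_a: float
    p_not_b: float
    h00: float
    D: float
    D_prime: float
    chi2: float
    p_value: float
    n: int
    degenerate: bool = False


def ld_d_statistic(a, b, c, d):
    """Vectorized closed-form D-hat on phenotype counts (arrays allowed).

    Returns (p_not_a, p_not_b, h00, D)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    p_not_a = np.sqrt((c + d) / n)
    p_not_b = np.sqrt((b + d) / n)
    h00 = np.sqrt(d / n)
    return p_not_a, p_not_b, h00, h00 - p_not_a * p_not_b


def ld_from_phenotypes(t: PhenotypeTable2x2) -> LDResult:
    """Mattiuz-style LD from a carrier 2×2 table under HWE.

    The χ² statistic uses the large-sample variance of D-hat under the
    null, Var(D) = (1 - p_not_a²)(1 - p_not_b²) / (4N) (delta method on the
    square-root estimators; asymptotically this χ² equals Pearson's 2×2
    phenotype test).  Margins at 0 or 1 leave the statistic undefined (NaN).
    """
    n = t.n
    p_not_a, p_not_b, h00, D = (float(x) for x in ld_d_statistic(t.a, t.b, t.c, t.d))
    degenerate = False
    if t.d == n:
        warnings.warn("no carriers of either allele; D degenerate at 0", stacklevel=2)
        degenerate = True
        D = 0.0
    # Lewontin normalization on the absence-haplotype scale
    d_max = min(p_not_a, p_not_b) - p_not_a * p_not_b
    d_min = -p_not_a * p_not_b
    if D > 0 and d_max > 0:
        d_prime = D / d_max
    elif D < 0 and d_min < 0:
        d_prime = D / abs(d_min)
    else:
        d_prime = 0.0
    var_factor = (1.0 - p_not_a**2) * (1.0 - p_not_b**2)
    if p_not_a in (0.0, 1.0) or p_not_b in (0.0, 1.0) or var_factor <= 0:
        chi2 = float("nan")
        p_value = float("nan")
    else:
        chi2 = 4.0 * n * D * D / var_factor
        p_value = float(stats.chi2.sf(chi2, df=1))
    return LDResult(
        p_not_a=p_not_a,
        p_not_b=p_not_b,
        h00=h00,
        D=D,
        D_prime=d_prime,
        chi2=chi2,
        p_value=p_value,
        n=n,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Cohort genotypes
# ---------------------------------------------------------------------------


@dataclass
class SampleGenotype:
    """Unphased centromeric genotype of one sample."""

    sample_id: str
    dl1: tuple[str, ...]  # 0-2 KIR2DL1 alleles
    dl23: tuple[str, str]  # exactly 2 alleles over KIR2DL2/KIR2DL3
    ds2: bool = False  # KIR2DS2 presence flag (per sample, not per haplotype)

    def __post_init__(self) -> None:
        self.dl1 = tuple(sorted(self.dl1))
        self.dl23 = tuple(sorted(self.dl23))
        if len(self.dl1) > 2:
            raise ValueError(f"{self.sample_id}: more than 2 KIR2DL1 alleles")
        if len(self.dl23) != 2:
            raise ValueError(f"{self.sample_id}: KIR2DL2/3 locus must carry 2 alleles")

    @property
    def n_3dp1v(self) -> int:
        return 2 - len(self.dl1)


class CohortGenotypes:
    """A collection of :class:`SampleGenotype` with TSV round-trip."""

    def __init__(self, samples: list[SampleGenotype]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [s.sample_id for s in self.samples],
                "kir2dl1_alleles": [",".join(s.dl1) for s in self.samples],
                "kir2dl23_alleles": [",".join(s.dl23) for s in self.samples],
                "kir3dp1v_count": [s.n_3dp1v for s in self.samples],
                "kir2ds2": [int(s.ds2) for s in self.samples],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortGenotypes":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        samples = []
        for _, row in df.iterrows():
            dl1 = tuple(x for x in row["kir2dl1_alleles"].split(",") if x)
            dl23 = tuple(x for x in row["kir2dl23_alleles"].split(",") if x)
            s = SampleGenotype(
                sample_id=row["sample"],
                dl1=dl1,
                dl23=dl23,  # type: ignore[arg-type]
                ds2=bool(int(row.get("kir2ds2", 0) or 0)),
            )
            if "kir3dp1v_count" in row and row["kir3dp1v_count"] != "":
                if int(row["kir3dp1v_count"]) != s.n_3dp1v:
                    raise ValueError(
                        f"{s.sample_id}: 3DP1V count inconsistent with KIR2DL1 allele count"
                    )
            samples.append(s)
        return cls(samples)


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------


def _phase_resolutions(s: SampleGenotype, with_ds2: bool = True):
    """All unordered haplotype pairs compatible with an unphased sample."""
    k = len(s.dl1)
    if k == 2:
        dl1_pairs = [(s.dl1[0], s.dl1[1])]
    elif k == 1:
        dl1_pairs = [(s.dl1[0], None)]
    else:
        dl1_pairs = [(None, None)]
    x, y = s.dl23
    dl23_pairs = [(x, y)] if x == y else [(x, y), (y, x)]
    if not with_ds2:
        ds2_pairs = [(False, False)]
    elif s.ds2:
        ds2_pairs = [(True, True), (True, False), (False, True)]
    else:
        ds2_pairs = [(False, False)]
    out = set()
    for (a1, a2), (b1, b2), (c1, c2) in itertools.product(
        dl1_pairs, dl23_pairs, ds2_pairs
    ):
        h1: Haplotype = (a1, b1, c1)
        h2: Haplotype = (a2, b2, c2)
        out.add(tuple(sorted((h1, h2), key=repr)))
    return sorted(out, key=repr)


@dataclass
class HaplotypeFrequencies:
    """EM results: haplotype frequencies with convergence diagnostics."""

    freqs: dict[Haplotype, float]
    log_likelihood: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_samples: int = 0

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "kir2dl1": h[0] if h[0] is not None else "absent (3DP1V)",
                "kir2dl23": h[1],
                "kir2ds2": "+" if h[2] else "-",
                "frequency": f,
            }
            for h, f in sorted(self.freqs.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def em_haplotype_freqs(
    cohort: CohortGenotypes,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> HaplotypeFrequencies:
    """Maximum-likelihood haplotype frequencies by EM under HWE.

    Initialization is the (deterministic) product of marginal component
    frequencies; convergence is declared when the largest absolute
    frequency change drops below *tol*.  The log-likelihood is guaranteed
    non-decreasing, which the loglik trace lets callers verify.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    resolutions = {}
    for s in cohort:
        res = _phase_resolutions(s)
        if not res:
            raise ValueError(f"sample {s.sample_id} incompatible with the haplotype model")
        resolutions[s.sample_id] = res
    support = sorted(
        {h for res in resolutions.values() for pair in res for h in pair}, key=repr
    )
    idx = {h: i for i, h in enumerate(support)}
    # marginal-product initialization
    dl1_counts: dict = {}
    dl23_counts: dict = {}
    ds2_count = 0.0
    for s in cohort:
        for a in s.dl1:
            dl1_counts[a] = dl1_counts.get(a, 0) + 1
        dl1_counts[None] = dl1_counts.get(None, 0) + s.n_3dp1v
        for b in s.dl23:
            dl23_counts[b] = dl23_counts.get(b, 0) + 1
        ds2_count += 1.0 if s.ds2 else 0.0
    n2 = 2.0 * len(cohort)
    p_ds2 = min(max(ds2_count / n2, 1e-6), 1 - 1e-6)
    f = np.array(
        [
            (dl1_counts.get(h[0], 0) / n2)
            * (dl23_counts.get(h[1], 0) / n2)
            * (p_ds2 if h[2] else 1 - p_ds2)
            for h in support
        ]
    )
    f = np.where(f <= 0, 1e-12, f)
    f /= f.sum()

    pair_index = {
        s.sample_id: [
            (idx[h1], idx[h2]) for h1, h2 in resolutions[s.sample_id]
        ]
        for s in cohort
    }
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros_like(f)
        loglik = 0.0
        for s in cohort:
            pairs = pair_index[s.sample_id]
            w = np.array(
                [(1.0 if i == j else 2.0) * f[i] * f[j] for i, j in pairs]
            )
            tot = w.sum()
            if tot <= 0:
                raise ValueError(
                    f"sample {s.sample_id} has zero likelihood under current frequencies"
                )
            loglik += np.log(tot)
            w /= tot
            for (i, j), wk in zip(pairs, w):
                new[i] += wk
                new[j] += wk
        new /= 2.0 * len(cohort)
        trace.append(float(loglik))
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol:
            converged = True
            break
    # final likelihood at the converged frequencies
    loglik = 0.0
    for s in cohort:
        tot = sum(
            (1.0 if i == j else 2.0) * f[i] * f[j] for i, j in pair_index[s.sample_id]
        )
        loglik += np.log(tot)
    trace.append(float(loglik))
    f = f / f.sum()
    return HaplotypeFrequencies(
        freqs={h: float(f[idx[h]]) for h in support},
        log_likelihood=float(loglik),
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        n_samples=len(cohort),
    )


# ---------------------------------------------------------------------------
# Pairwise LD matrix over a cohort
# ---------------------------------------------------------------------------


def _carrier_sets(cohort: CohortGenotypes) -> dict[str, dict[str, set]]:
    """Per locus, allele → set of carrier sample ids."""
    loci: dict[str, dict[str, set]] = {
        "KIR2DL1": {},
        "KIR2DL2": {},
        "KIR2DL3": {},
        "KIR3DP1": {},
        "KIR2DS2": {},
    }
    for s in cohort:
        for a in set(s.dl1):
            loci["KIR2DL1"].setdefault(a, set()).add(s.sample_id)
        for b in set(s.dl23):
            gene = "KIR2DL2" if b.startswith("KIR2DL2") else "KIR2DL3"
            loci[gene].setdefault(b, set()).add(s.sample_id)
        if s.n_3dp1v >= 1:
            loci["KIR3DP1"].setdefault("KIR3DP1V", set()).add(s.sample_id)
        if s.ds2:
            loci["KIR2DS2"].setdefault("KIR2DS2", set()).add(s.sample_id)
    return {locus: alleles for locus, alleles in loci.items() if alleles}


def pairwise_ld_matrix(cohort: CohortGenotypes, alpha: float = 0.05) -> pd.DataFrame:
    """Mattiuz-style LD for every cross-locus allele pair in a cohort.

    Each allele is collapsed to carrier/non-carrier status; monomorphic
    pairs are flagged non-computable.  Significance carries a Bonferroni
    adjustment over the computable pairs.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    loci = _carrier_sets(cohort)
    if len(loci) < 2:
        raise ValueError("need >=2 loci with >=1 segregating allele")
    ids = {s.sample_id for s in cohort}
    n = len(ids)
    rows = []
    for (loc_a, alleles_a), (loc_b, alleles_b) in itertools.combinations(
        sorted(loci.items()), 2
    ):
        for allele_a, carriers_a in sorted(alleles_a.items()):
            for allele_b, carriers_b in sorted(alleles_b.items()):
                a = len(carriers_a & carriers_b)
                b = len(carriers_a - carriers_b)
                c = len(carriers_b - carriers_a)
                d = n - a - b - c
                computable = 0 < len(carriers_a) < n and 0 < len(carriers_b) < n
                rec = {
                    "locus_a": loc_a,
                    "allele_a": allele_a,
                    "locus_b": loc_b,
                    "allele_b": allele_b,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "computable": computable,
                }
                if computable:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ld = ld_from_phenotypes(PhenotypeTable2x2(a, b, c, d))
                    rec.update(
                        D=ld.D,
                        D_prime=ld.D_prime,
                        chi2=ld.chi2,
                        p_value=ld.p_value,
                    )
                else:
                    rec.update(D=np.nan, D_prime=np.nan, chi2=np.nan, p_value=np.nan)
                rows.append(rec)
    df = pd.DataFrame(rows)
    m = int(df["computable"].sum())
    df["p_bonferroni"] = (df["p_value"] * max(m, 1)).clip(upper=1.0)
    df["significant"] = df["p_bonferroni"] < alpha
    return df


# ---------------------------------------------------------------------------
# Pedigrees and Mendelian checks
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    genotype: SampleGenotype | None = None


class Pedigree:
    """One family: individuals with optional parent references and genotypes."""

    def __init__(self, family_id: str, individuals: list[Individual]):
        self.family_id = family_id
        self.individuals = {ind.individual_id: ind for ind in individuals}
        if len(self.individuals) != len(individuals):
            raise ValueError("duplicate individual ids")
        for ind in individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    raise ValueError(
                        f"{ind.individual_id}: referenced parent {pid} missing"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise ValueError(f"pedigree cycle involving {iid}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self.individuals[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 2

        for iid in self.individuals:
            visit(iid)

    def children(self) -> list[Individual]:
        return [
            ind
            for ind in self.individuals.values()
            if ind.father_id is not None or ind.mother_id is not None
        ]


def _possible_haplotypes(s: SampleGenotype) -> set:
    """All (dl1, dl23) haplotypes appearing in some phase resolution."""
    return {
        h[:2] for pair in _phase_resolutions(s, with_ds2=False) for h in pair
    }


def mendelian_check(ped: Pedigree) -> pd.DataFrame:
    """Per-child Mendelian-consistency verdicts for one family.

    A child is consistent iff some phase resolution of its genotype splits
    into one haplotype available from the father and one from the mother
    (over the 2DL1/2DL2/2DL3/3DP1V structure; the per-sample KIR2DS2 flag
    only supports the necessary condition that a positive child has at
    least one positive parent).  When the paternal/maternal transmission
    is unique it is reported.
    """
    rows = []
    for child in sorted(ped.children(), key=lambda i: i.individual_id):
        rec = {"family": ped.family_id, "individual": child.individual_id}
        father = ped.individuals.get(child.father_id) if child.father_id else None
        mother = ped.individuals.get(child.mother_id) if child.mother_id else None
        if (
            child.genotype is None
            or father is None
            or mother is None
            or father.genotype is None
            or mother.genotype is None
        ):
            rec.update(status="skipped", transmission=None)
            rows.append(rec)
            continue
        hf = _possible_haplotypes(father.genotype)
        hm = _possible_haplotypes(mother.genotype)
        assignments = set()
        for pair in _phase_resolutions(child.genotype, with_ds2=False):
            c1, c2 = (h[:2] for h in pair)
            for pat, mat in ((c1, c2), (c2, c1)):
                if pat in hf and mat in hm:
                    assignments.add((pat, mat))
        consistent = bool(assignments)
        if consistent and child.genotype.ds2:
            if not (father.genotype.ds2 or mother.genotype.ds2):
                consistent = False
                assignments = set()
        rec["status"] = "consistent" if consistent else "inconsistent"
        rec["transmission"] = (
            next(iter(assignments)) if len(assignments) == 1 else None
        )
        rows.append(rec)
    return pd.DataFrame(rows, columns=["family", "individual", "status", "transmission"])
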