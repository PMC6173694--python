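"""Synthetic data: designed allele sets, HWE cohorts, pedigrees, noisy bands.

Everything downstream of sequence data can be exercised without any
database download: this module emits allele sequences whose discriminating
SNPs sit exactly under ARMS primer 3' termini (so the in silico PCR engine
reproduces a designed truth table), cohorts drawn under Hardy–Weinberg
equilibrium from centromeric haplotype frequencies, multi-generation
pedigrees with faithful (or deliberately violated) Mendelian transmission,
and band patterns with independent Bernoulli dropout/false-band noise.

All generators are bit-reproducible given (design, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alleles import AlleleRecord, DP1_ROW, DP1V_ROW
from .arms import ArmsPolicy, PatternMatrix, Primer, ReactionDef, build_pattern_matrix
from .interpret import BandPattern, GenotypeCall, R7_DP1, R7_DP1V, expected_pattern
from .popgen import CohortGenotypes, Haplotype, Individual, Pedigree, SampleGenotype

_BASES = "ACGT"


@dataclass
class SynthDesign:
    """Specification of a synthetic allele set.

    ``truth`` is the designed allele × reaction boolean table the emitted
    sequences must realize under the default ARMS policy.  Each reaction
    gets its own discriminating SNP, so any boolean table is realizable;
    the post-hoc round-trip check still guards against accidental primer
    collisions on the random backbone.
    """

    gene: str
    truth: np.ndarray
    seed: int = 0
    allele_names: list[str] = field(default_factory=list)
    reaction_ids: list[str] = field(default_factory=list)
    primer_len: int = 25
    amplicon_len: int = 80

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.truth.ndim != 2 or self.truth.size == 0:
            raise ValueError("truth table must be a non-empty 2-D boolean array")
        n_a, n_r = self.truth.shape
        if not self.allele_names:
            self.allele_names = [f"{self.gene}*9{i:02d}" for i in range(1, n_a + 1)]
        if not self.reaction_ids:
            self.reaction_ids = [f"{self.gene} SynthReaction {j + 1}" for j in range(n_r)]
        if len(self.allele_names) != n_a or len(self.reaction_ids) != n_r:
            raise ValueError("names do not match truth table shape")


def simulate_allele_set(
    design: SynthDesign, policy: ArmsPolicy | None = None
) -> tuple[list[AlleleRecord], list[ReactionDef], PatternMatrix]:
    """Emit allele sequences + ARMS reactions realizing ``design.truth``.

    All alleles share one random backbone; reaction *j*'s forward primer
    ends (3') on SNP position *j*, where positive alleles carry the primer
    base and negative alleles a substituted base.  The reverse primer of
    each reaction is non-discriminating.  The returned PatternMatrix is the
    engine's own verification that the truth table is realized exactly
    (a mismatch raises, catching backbone collisions).
    """
    if policy is None:
        policy = ArmsPolicy()
    rng = np.random.default_rng(design.seed)
    n_a, n_r = design.truth.shape
    spacing = max(design.primer_len + design.amplicon_len + 15, 40)
    length = max(40 * n_r, n_r * spacing + 100)
    backbone = rng.integers(0, 4, size=length)

    snp_pos = []  # 0-based index of the discriminating base for reaction j
    reactions = []
    for j in range(n_r):
        site_start = 50 + j * spacing
        snp = site_start + design.primer_len - 1
        snp_pos.append(snp)
        fwd_seq = "".join(_BASES[b] for b in backbone[site_start : snp + 1])
        rev_start = snp + design.amplicon_len - design.primer_len
        rev_end = rev_start + design.primer_len
        rev_plus = "".join(_BASES[b] for b in backbone[rev_start:rev_end])
        rev_seq = _revcomp(rev_plus)
        fwd = Primer(name=f"SYN{j + 1}F", sequence=fwd_seq, role="forward")
        rev = Primer(name=f"SYN{j + 1}R", sequence=rev_seq, role="reverse")
        reactions.append(
            ReactionDef(
                reaction_id=design.reaction_ids[j],
                gene_panel=design.gene,
                forward_primers=[fwd],
                reverse_primers=[rev],
                expected_amplicon_bp=rev_end - site_start,
                includes_control=True,
            )
        )

    # one fixed alternative (refractory) base per reaction
    alt_base = [(int(backbone[p]) + 1 + int(rng.integers(0, 3))) % 4 for p in snp_pos]
    alleles = []
    for i in range(n_a):
        seq = backbone.copy()
        for j in range(n_r):
            if not design.truth[i, j]:
                seq[snp_pos[j]] = alt_base[j]
        alleles.append(
            AlleleRecord(
                allele_name=design.allele_names[i],
                genomic_sequence="".join(_BASES[b] for b in seq),
                tested=True,
            )
        )

    pm = build_pattern_matrix(reactions, alleles, policy)
    if not np.array_equal(pm.df.to_numpy(), design.truth):
        raise RuntimeError(
            "synthetic allele set does not realize the designed truth table "
            "(primer site collision on the random backbone); change the seed"
        )
    return alleles, reactions, pm


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Packaged study-conditions defaults
# ---------------------------------------------------------------------------

#: Synthetic default centromeric haplotype frequencies.  Constructed once to
#: mirror the published structure of the European-derived centromeric KIR
#: region: seven common 2DL1 x 2DL2/3 x 2DS2 combinations (three
#: centromeric-A carrying KIR2DL1+KIR2DL3+KIR3DP1, four centromeric-B)
#: carrying 98% of haplotype mass — hence ~96% of diploid genotypes are
#: composed of the seven alone — including a rare
#: KIR2DL1*004/KIR2DL2*006/2DS2-negative haplotype whose carriers make up
#: ~2.3% of individuals.  Exact values are this package's synthetic study
#: conditions, not published estimates.
DEFAULT_HAPLOTYPE_FREQS: dict[Haplotype, float] = {
    ("KIR2DL1*003", "KIR2DL3*001", False): 0.30,   # cen-A
    ("KIR2DL1*001", "KIR2DL3*002", False): 0.17,   # cen-A
    ("KIR2DL1*002", "KIR2DL3*005", False): 0.135,  # cen-A
    ("KIR2DL1*004", "KIR2DL2*001", True): 0.17,    # cen-B
    (None, "KIR2DL2*003", True): 0.10,             # cen-B, 2DL1-absent (3DP1V)
    (None, "KIR2DL2*001", True): 0.093,            # cen-B
    ("KIR2DL1*004", "KIR2DL2*006", False): 0.012,  # cen-B, rare
    ("KIR2DL1*006", "KIR2DL3*003", False): 0.010,
    ("KIR2DL1*003", "KIR2DL3*006", False): 0.010,
}

#: The seven common combinations above (everything except the last two).
COMMON_HAPLOTYPES = tuple(list(DEFAULT_HAPLOTYPE_FREQS)[:7])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    haplo_freqs: dict[Haplotype, float],
    n: int,
    seed: int = 0,
) -> tuple[CohortGenotypes, list[tuple[Haplotype, Haplotype]]]:
    """Draw *n* diploid samples under HWE (two i.i.d. haplotypes each).

    Returns the unphased cohort plus the hidden true phases, which oracle
    tests use as ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(haplo_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    haps = list(haplo_freqs)
    probs = np.array([haplo_freqs[h] for h in haps])
    draws = rng.choice(len(haps), size=(n, 2), p=probs)
    samples = []
    phases = []
    for i in range(n):
        h1, h2 = haps[draws[i, 0]], haps[draws[i, 1]]
        phases.append((h1, h2))
        dl1 = tuple(h[0] for h in (h1, h2) if h[0] is not None)
        dl23 = (h1[1], h2[1])
        samples.append(
            SampleGenotype(
                sample_id=f"S{i + 1:04d}",
                dl1=dl1,
                dl23=dl23,
                ds2=h1[2] or h2[2],
            )
        )
    return CohortGenotypes(samples), phases


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


def three_generation_structure(
    family_id: str = "FAM1", n_sibs_g2: int = 2, n_sibs_g3: int = 2
) -> list[tuple[str, str, str | None, str | None]]:
    """A CEPH-like structure: 4 grandparents, a sibship marrying in, and a
    third generation.  Entries are (family, individual, father, mother)."""
    rows: list[tuple[str, str, str | None, str | None]] = [
        (family_id, "GF1", None, None),
        (family_id, "GM1", None, None),
        (family_id, "GF2", None, None),
        (family_id, "GM2", None, None),
    ]
    rows.append((family_id, "F1", "GF1", "GM1"))
    rows.append((family_id, "M1", "GF2", "GM2"))
    for k in range(1, n_sibs_g2 + 1):
        rows.append((family_id, f"C{k}", "GF1", "GM1"))
    for k in range(1, n_sibs_g3 + 1):
        rows.append((family_id, f"G{k}", "F1", "M1"))
    return rows


def simulate_pedigree(
    founder_freqs: dict[Haplotype, float],
    structure: list[tuple[str, str, str | None, str | None]],
    seed: int = 0,
    n_denovo: int = 0,
) -> tuple[Pedigree, dict]:
    """Simulate genotypes down a family tree with Mendelian transmission.

    Founders are drawn from *founder_freqs* under HWE; every child receives
    one uniformly chosen haplotype from each parent.  ``n_denovo`` children
    (chosen at random among non-founders) get a de novo KIR2DL2/3 allele
    substituted after transmission; the injections are logged in the truth
    sidecar so checker tests know exactly which children must be flagged.
    """
    rng = np.random.default_rng(seed)
    ids = [row[1] for row in structure]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in structure")
    known = set(ids)
    for _, iid, fid, mid in structure:
        for pid in (fid, mid):
            if pid is not None and pid not in known:
                raise ValueError(f"{iid}: structure references missing individual {pid}")
    haps = list(founder_freqs)
    probs = np.array([founder_freqs[h] for h in haps])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("founder frequencies must sum to 1")
    phased: dict[str, tuple[Haplotype, Haplotype]] = {}
    family_id = structure[0][0]
    # founders first, then children in structure order (assumed topological)
    for _, iid, fid, mid in structure:
        if fid is None and mid is None:
            i, j = rng.choice(len(haps), size=2, p=probs)
            phased[iid] = (haps[i], haps[j])
        else:
            if fid is None or mid is None or fid not in phased or mid not in phased:
                raise ValueError(f"{iid}: both parents must precede the child")
            pat = phased[fid][int(rng.integers(0, 2))]
            mat = phased[mid][int(rng.integers(0, 2))]
            phased[iid] = (pat, mat)
    parents_of_someone = {row[2] for row in structure} | {row[3] for row in structure}
    # only leaf children are eligible: a de novo event in a mid-pedigree
    # individual would also corrupt its (already drawn) descendants
    children = [
        row[1]
        for row in structure
        if row[2] is not None and row[1] not in parents_of_someone
    ]
    injected: dict[str, str] = {}
    if n_denovo > 0:
        if n_denovo > len(children):
            raise ValueError("more de novo events than leaf children")
        victims = rng.choice(len(children), size=n_denovo, replace=False)
        for v in victims:
            iid = children[int(v)]
            h1, h2 = phased[iid]
            novel = "KIR2DL3*990"
            phased[iid] = ((h1[0], novel, h1[2]), h2)
            injected[iid] = novel
    individuals = []
    for _, iid, fid, mid in structure:
        h1, h2 = phased[iid]
        geno = SampleGenotype(
            sample_id=iid,
            dl1=tuple(h[0] for h in (h1, h2) if h[0] is not None),
            dl23=(h1[1], h2[1]),
            ds2=h1[2] or h2[2],
        )
        individuals.append(
            Individual(individual_id=iid, father_id=fid, mother_id=mid, genotype=geno)
        )
    truth = {"phases": phased, "injected_denovo": injected}
    return Pedigree(family_id, individuals), truth


# ---------------------------------------------------------------------------
# Band-pattern noise
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Independent Bernoulli band noise (per band / per control)."""

    band_dropout_rate: float = 0.0
    false_band_rate: float = 0.0
    control_failure_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("band_dropout_rate", "false_band_rate", "control_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def genotype_to_bands(
    g: GenotypeCall,
    pm: PatternMatrix,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
    control_free: frozenset = frozenset(),
) -> BandPattern:
    """Observed-band simulation: expected pattern of *g* with noise flips.

    Zero noise is the identity on :func:`expected_pattern`.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    expected = expected_pattern(g, pm)
    bands = {}
    controls = {}
    for rid in pm.reactions:
        v = expected.bands[rid]
        if v and rng.random() < noise.band_dropout_rate:
            v = False
        elif not v and rng.random() < noise.false_band_rate:
            v = True
        bands[rid] = v
        if rid not in control_free:
            controls[rid] = not (rng.random() < noise.control_failure_rate)
    return BandPattern(
        sample_id=sample_id, bands=bands, controls=controls, control_free=control_free
    )


def random_toy_kb(n_dl1: int, n_dl23: int, n_reactions: int, seed: int) -> PatternMatrix:
    """A random miniature typing KB over two gene panels plus 3DP1 rows.

    Row patterns are random booleans, so duplicate rows — and hence
    genotype ambiguity — arise naturally; that is the interesting regime
    for interpreter soundness/completeness checks.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    dl1 = [f"KIR2DL1*9{i:02d}" for i in range(1, n_dl1 + 1)]
    dl23 = [f"KIR2DL3*9{i:02d}" for i in range(1, n_dl23 + 1)]
    reactions = [f"ToyR{j}" for j in range(1, n_reactions + 1)]
    alleles = dl1 + dl23 + [DP1_ROW, DP1V_ROW]
    cols = reactions + [R7_DP1, R7_DP1V]
    df = pd.DataFrame(False, index=alleles, columns=cols)
    df.loc[dl1 + dl23, reactions] = rng.random((n_dl1 + n_dl23, n_reactions)) < 0.5
    df.loc[DP1_ROW, R7_DP1] = True
    df.loc[DP1V_ROW, R7_DP1V] = True
    return PatternMatrix(df)


# ---------------------------------------------------------------------------
# Random trees for topology-recovery checks
# ---------------------------------------------------------------------------


def random_additive_tree(n_leaves: int, seed: int = 0):
    """A random binary unrooted tree with U(0.1, 1) branch lengths and its
    additive leaf-to-leaf distance matrix.

    Used to test tree reconstruction: neighbor joining is guaranteed to
    recover the generating topology from exactly additive distances.
    Returns (PhyloTree, DistanceMatrix).
    """
    import networkx as nx

    from .alleles import DistanceMatrix, PhyloTree

    if n_leaves < 4:
        raise ValueError("need >= 4 leaves for a nontrivial unrooted topology")
    rng = np.random.default_rng(seed)
    labels = [f"T{i:02d}" for i in range(1, n_leaves + 1)]
    g = nx.Graph()
    active: list = list(labels)
    nxt = itertools.count()
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        u = next(nxt)
        a, b = active[i], active[j]
        g.add_edge(a, u, length=float(rng.uniform(0.1, 1.0)))
        g.add_edge(b, u, length=float(rng.uniform(0.1, 1.0)))
        active = [x for x in active if x not in (a, b)] + [u]
    u = next(nxt)
    for x in active:
        g.add_edge(x, u, length=float(rng.uniform(0.1, 1.0)))
    tree = PhyloTree(g, labels)
    vals = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        d = tree.path_length(labels[i], labels[j])
        vals[i, j] = vals[j, i] = d
    return tree, DistanceMatrix(labels, vals)


# ---------------------------------------------------------------------------
# Synthetic reference templates
# ---------------------------------------------------------------------------


def synthetic_reference_for_reaction(
    reaction: ReactionDef, seed: int = 0, flank: int = 60
) -> AlleleRecord:
    """A synthetic template on which *reaction* must amplify at its printed
    product size.

    This is a stand-in for the real IPD reference accessions (which name
    the coordinate system of the kit's primers): the primer footprints are
    planted at their published target coordinates — shifted so the template
    starts shortly before the amplicon — on an otherwise random backbone.
    Product-size arithmetic (5' end to 5' end) is translation-invariant,
    so the predicted amplicon length must equal the published one.  Primers
    without published coordinates (the 3DP1/3DP1V reaction) are planted at
    synthesized positions consistent with their product size.
    """
    rng = np.random.default_rng(seed)
    plants: list[tuple[int, str]] = []  # (1-based plus-strand start, sequence)
    fwd = reaction.forward_primers[0]
    rev = reaction.reverse_primers[0]
    if fwd.target_position is not None and rev.target_position is not None:
        f3 = fwd.target_position + fwd.position_offset
        r3 = rev.target_position + rev.position_offset
        f_start = f3 - len(fwd.sequence) + 1
        r_start = r3
    else:
        f_start = 101
        f3 = f_start + len(fwd.sequence) - 1
        r_start = f_start + reaction.expected_amplicon_bp - len(rev.sequence)
    plants.append((f_start, fwd.sequence))
    plants.append((r_start, _revcomp(rev.sequence)))
    origin = min(s for s, _ in plants) - flank  # becomes template position 1
    length = max(s + len(seq) - 1 for s, seq in plants) - origin + 1 + flank
    seq = [
        _BASES[b] for b in rng.integers(0, 4, size=length)
    ]
    for start, sub in plants:
        off = start - origin  # 0-based
        seq[off : off + len(sub)] = list(sub)
    return AlleleRecord(
        allele_name=f"{reaction.gene_panel}*999",
        genomic_sequence="".join(seq),
        tested=False,
    )


# ---------------------------------------------------------------------------
# Paper-like full-loop helpers
# ---------------------------------------------------------------------------


def full_loop_kb(
    n_dl1: int = 4,
    n_dl23: int = 3,
    seed: int = 0,
) -> tuple[PatternMatrix, list[str], list[str]]:
    """A small sequence-realized typing KB for end-to-end recovery tests.

    Builds identity-structured synthetic panels for a KIR2DL1-like gene and
    a KIR2DL3-like gene, then appends the 3DP1/3DP1V pseudo-allele rows and
    their two reaction columns so copy-number logic participates in the
    loop.  Returns (pattern matrix, dl1 allele names, dl23 allele names).
    """
    import pandas as pd

    d1 = SynthDesign(gene="KIR2DL1", truth=np.eye(n_dl1, dtype=bool), seed=seed)
    d2 = SynthDesign(gene="KIR2DL3", truth=np.eye(n_dl23, dtype=bool), seed=seed + 1)
    _, _, pm1 = simulate_allele_set(d1)
    _, _, pm2 = simulate_allele_set(d2)
    alleles = pm1.alleles + pm2.alleles + [DP1_ROW, DP1V_ROW]
    reactions = pm1.reactions + pm2.reactions + [R7_DP1, R7_DP1V]
    df = pd.DataFrame(False, index=alleles, columns=reactions)
    df.loc[pm1.alleles, pm1.reactions] = pm1.df.values
    df.loc[pm2.alleles, pm2.reactions] = pm2.df.values
    df.loc[DP1_ROW, R7_DP1] = True
    df.loc[DP1V_ROW, R7_DP1V] = True
    return PatternMatrix(df), pm1.alleles, pm2.alleles
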